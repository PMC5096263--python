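"""Simulation runners: noise-grid heat maps and randomized box-plot studies.

Two experiment designs evaluate inference accuracy on synthetic data:

* **heatmap** — fixed ground-truth density, a grid of noise means (μ1, μ2);
  each cell repeats generate → corrupt → infer and records false-positive /
  false-negative rates and Jaccard similarity for MANIA and for the
  Jaccard-optimal-threshold oracle (both post-symmetrized).  Cell summaries
  are medians over replicates.

* **boxplot** — density drawn uniformly on (0, 1) and μ1, μ2 uniformly on
  (0, 0.3) per experiment; compares (a) each method with vs without
  post-symmetrization and (b) MANIA against a ladder of fixed thresholds.
  Sampling is paired: every method sees the same instances.

Each replicate derives an independent child seed from the global seed, so
any cell or experiment can be reproduced in isolation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .inference import StrengthMatrix, _infer_fast, infer_threshold, post_symmetrize
from .synthetic import (
    NoiseModel,
    corrupt,
    error_rates,
    generate_ground_truth,
    jaccard,
    optimal_threshold,
)

__all__ = [
    "DEFAULT_MU_GRID",
    "DEFAULT_THRESHOLDS",
    "run_heatmap_experiment",
    "summarize_heatmap",
    "run_boxplot_experiment",
    "summarize_boxplot",
]

#: Noise-mean grid for the heat-map study, spanning the usable range (0, 0.3].
DEFAULT_MU_GRID: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

#: Fixed-threshold baseline ladder, evenly spaced across the low-τ range.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)


def _child_seeds(seed: int, count: int) -> np.ndarray:
    """Fan one global seed out to independent per-replicate child seeds."""
    return np.random.SeedSequence(seed).generate_state(count) % (2**31)


def run_heatmap_experiment(
    n: int,
    rho: float,
    mu_grid: Sequence[float] = DEFAULT_MU_GRID,
    reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate accuracy of MANIA across a (μ1, μ2) noise grid.

    Returns a tidy frame with one row per (μ1, μ2, replicate):
    ``p_f``, ``p_m``, ``j_mania``, ``j_opt`` (optimal-threshold oracle), all
    with post-symmetrization.  Use :func:`summarize_heatmap` for cell medians.
    """
    models = {
        (m1, m2): NoiseModel(m1, m2) for m1 in mu_grid for m2 in mu_grid
    }
    cells = sorted(models)
    seeds = _child_seeds(seed, len(cells) * reps).reshape(len(cells), reps)
    rows = []
    for c_idx, (mu1, mu2) in enumerate(cells):
        model = models[(mu1, mu2)]
        for r in range(reps):
            rng = np.random.default_rng(int(seeds[c_idx, r]))
            g = generate_ground_truth(n, rho, rng)
            s = corrupt(g, model, rng)
            net, _, _, _ = _infer_fast(s, post_symmetrize_result=True)
            p_f, p_m = error_rates(g, net)
            j_mania = jaccard(g, net)
            j_opt = optimal_threshold(s, g, post_symmetrize_result=True).jaccard
            rows.append(
                {
                    "rho_g": rho,
                    "mu1": mu1,
                    "mu2": mu2,
                    "replicate": r,
                    "seed": int(seeds[c_idx, r]),
                    "p_f": p_f,
                    "p_m": p_m,
                    "j_mania": j_mania,
                    "j_opt": j_opt,
                }
            )
    return pd.DataFrame(rows)


def summarize_heatmap(records: pd.DataFrame) -> pd.DataFrame:
    """Cell medians of the heat-map records, plus the oracle gap ΔJ."""
    out = (
        records.groupby(["rho_g", "mu1", "mu2"])[["p_f", "p_m", "j_mania", "j_opt"]]
        .median()
        .reset_index()
    )
    gap = (
        records.assign(dj=records["j_opt"] - records["j_mania"])
        .groupby(["rho_g", "mu1", "mu2"])["dj"]
        .median()
        .reset_index(drop=True)
    )
    out["dj_opt_minus_mania"] = gap
    return out


def run_boxplot_experiment(
    n: int,
    reps: int = 1000,
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Randomized-design comparison of MANIA and fixed-threshold baselines.

    Per experiment: ρ ~ U(0,1) (redrawn if it would give zero or all
    undirected edges), μ1, μ2 ~ U(0, 0.3).  Records Jaccard similarity with
    and without post-symmetrization for MANIA and each fixed τ0, paired
    across methods.  One row per experiment.
    """
    seeds = _child_seeds(seed, reps)
    rows = []
    total_pairs = n * (n - 1) // 2
    for r in range(reps):
        rng = np.random.default_rng(int(seeds[r]))
        while True:
            rho = rng.uniform(0.0, 1.0)
            k = int(np.floor(rho * total_pairs + 0.5))
            if 0 < k < total_pairs:
                break
        mu1 = rng.uniform(0.0, 0.3)
        mu2 = rng.uniform(0.0, 0.3)
        model = NoiseModel(mu1, mu2)
        g = generate_ground_truth(n, rho, rng)
        s = corrupt(g, model, rng)

        raw_net, tau_star, _, phi_min = _infer_fast(s, post_symmetrize_result=False)
        sym_net = (
            post_symmetrize(raw_net, s, tau_star) if phi_min > 0.0 else raw_net
        )
        row = {
            "replicate": r,
            "seed": int(seeds[r]),
            "rho_g": rho,
            "mu1": mu1,
            "mu2": mu2,
            "j_mania_sym": jaccard(g, sym_net),
            "j_mania_nosym": jaccard(g, raw_net),
        }
        for tau0 in thresholds:
            raw = infer_threshold(s, tau0, post_symmetrize_result=False)
            sym = post_symmetrize(raw, s, tau0)
            row[f"j_tau{tau0:g}_sym"] = jaccard(g, sym)
            row[f"j_tau{tau0:g}_nosym"] = jaccard(g, raw)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_boxplot(
    records: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Median ΔJ and one-sided Mann–Whitney p-values for both comparisons.

    ``delta_sym``: J with minus without post-symmetrization, per method.
    ``delta_mania``: J_MANIA minus J_τ0, both post-symmetrized, per τ0.
    The p-value tests whether the first sample is stochastically larger.
    """
    rows = []
    methods = [("mania", "j_mania_sym", "j_mania_nosym")] + [
        (f"tau{t:g}", f"j_tau{t:g}_sym", f"j_tau{t:g}_nosym") for t in thresholds
    ]
    for name, sym_col, nosym_col in methods:
        delta = records[sym_col] - records[nosym_col]
        p = mannwhitneyu(
            records[sym_col], records[nosym_col], alternative="greater"
        ).pvalue
        rows.append(
            {
                "comparison": "delta_sym",
                "method": name,
                "median_dj": float(delta.median()),
                "p_value": float(p),
            }
        )
    for t in thresholds:
        delta = records["j_mania_sym"] - records[f"j_tau{t:g}_sym"]
        p = mannwhitneyu(
            records["j_mania_sym"],
            records[f"j_tau{t:g}_sym"],
            alternative="greater",
        ).pvalue
        rows.append(
            {
                "comparison": "delta_mania",
                "method": f"tau{t:g}",
                "median_dj": float(delta.median()),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
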