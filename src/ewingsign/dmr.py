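"""Differentially methylated window selection and feature ranking.

Per window a Welch two-sample t-test compares beta-values between two groups;
Benjamini-Hochberg adjustment is applied across the tested windows of each
comparison separately. A window becomes a classifier feature when it is
significant (q < 0.05) in ALL THREE pairwise comparisons (EwS vs NCC, CIC vs
NCC, EwS vs CIC), is not already methylated in control plasma (median NCC
training beta <= 0.25), and ranks in the top 200 by its minimum absolute
delta-beta across the comparisons. This module is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COMPARISONS = ("EwS_vs_NCC", "CIC_vs_NCC", "EwS_vs_CIC")

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_NCC_BETA_CAP = 0.25
DEFAULT_TOP_K = 200


@dataclass
class FeatureSet:
    """Top-ranked DMR windows for one ensemble split."""

    ensemble_index: int
    window_ids: np.ndarray  # ordered descending by min |delta beta|
    min_abs_delta_beta: np.ndarray

    def __post_init__(self) -> None:
        self.window_ids = np.asarray(self.window_ids, dtype=np.int64)
        self.min_abs_delta_beta = np.asarray(self.min_abs_delta_beta, dtype=float)
        if len(self.window_ids) != len(self.min_abs_delta_beta):
            raise ValueError("window_ids and deltas must align")

    def __len__(self) -> int:
        return len(self.window_ids)


def pairwise_dmr(
    group_a: np.ndarray | pd.DataFrame,
    group_b: np.ndarray | pd.DataFrame,
    comparison: str = "A_vs_B",
    statistic: str = "welch",
) -> pd.DataFrame:
    """Per-window two-sided test of beta between two groups (samples x windows).

    Returns a frame indexed by window id with columns p_value, q_value and
    delta_beta = mean(A) - mean(B). Windows with zero variance in both groups
    and equal means get p = 1 (no evidence, not an error). Windows containing
    missing betas in either group are skipped and reported with NaN p/q.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with identical window grids")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")

    complete = ~(np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0))
    delta = np.nanmean(a, axis=0) - np.nanmean(b, axis=0)
    p = np.full(a.shape[1], np.nan)

    if complete.any():
        if statistic == "welch":
            res = stats.ttest_ind(a[:, complete], b[:, complete], equal_var=False, axis=0)
            p_c = np.asarray(res.pvalue)
        elif statistic == "wilcoxon":
            p_c = np.array(
                [
                    stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
                    for j in np.where(complete)[0]
                ]
            )
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        # degenerate windows: both groups constant. equal means -> p=1,
        # unequal means -> perfectly separated, smallest attainable evidence
        var_a = np.var(a[:, complete], axis=0)
        var_b = np.var(b[:, complete], axis=0)
        degen = (var_a <= 1e-12) & (var_b <= 1e-12)
        d_c = delta[complete]
        p_c = np.where(degen & (d_c == 0), 1.0, p_c)
        p_c = np.where(degen & (d_c != 0), 0.0, p_c)
        p[complete] = p_c

    q = np.full_like(p, np.nan)
    if complete.any():
        q[complete] = multipletests(p[complete], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "p_value": p,
            "q_value": q,
            "delta_beta": delta,
            "comparison": comparison,
        },
        index=pd.RangeIndex(a.shape[1], name="window_id"),
    )


def select_features(
    results: dict[str, pd.DataFrame],
    ncc_train_betas: np.ndarray | pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    ncc_beta_cap: float = DEFAULT_NCC_BETA_CAP,
    top_k: int = DEFAULT_TOP_K,
    ensemble_index: int = 1,
) -> FeatureSet:
    """Apply the FDR / NCC-cap / three-way-intersection / ranking pipeline.

    Steps: q < ``q_threshold`` per comparison; drop windows whose median beta
    across NCC training samples exceeds ``ncc_beta_cap``; intersect the three
    surviving sets; rank descending by the minimum |delta beta| over the
    comparisons (ties broken by ascending window id); keep the top ``top_k``.
    An empty intersection yields an empty FeatureSet, not an error.
    """
    missing = [c for c in COMPARISONS if c not in results]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")

    ncc = np.asarray(ncc_train_betas, dtype=float)
    ncc_median = np.median(ncc, axis=0)

    surviving: list[set[int]] = []
    for comp in COMPARISONS:
        df = results[comp]
        sig = df.index[(df["q_value"] < q_threshold).fillna(False)]
        sig = [w for w in sig if ncc_median[w] <= ncc_beta_cap]
        surviving.append(set(sig))
    common = sorted(set.intersection(*surviving))
    if not common:
        import warnings

        warnings.warn("no DMR window survived all three comparisons", stacklevel=2)
        return FeatureSet(ensemble_index, np.array([], dtype=np.int64), np.array([]))

    min_abs_delta = np.min(
        np.vstack(
            [np.abs(results[c]["delta_beta"].to_numpy())[common] for c in COMPARISONS]
        ),
        axis=0,
    )
    order = sorted(range(len(common)), key=lambda i: (-min_abs_delta[i], common[i]))
    order = order[:top_k]
    return FeatureSet(
        ensemble_index,
        np.array([common[i] for i in order], dtype=np.int64),
        min_abs_delta[order],
    )


def run_dmr_selection(
    ews_betas,
    cic_betas,
    ncc_train_betas,
    ensemble_index: int = 1,
    statistic: str = "welch",
    **select_kwargs,
) -> tuple[dict[str, pd.DataFrame], FeatureSet]:
    """Convenience wrapper: three pairwise tests then feature selection."""
    results = {
        "EwS_vs_NCC": pairwise_dmr(ews_betas, ncc_train_betas, "EwS_vs_NCC", statistic),
        "CIC_vs_NCC": pairwise_dmr(cic_betas, ncc_train_betas, "CIC_vs_NCC", statistic),
        "EwS_vs_CIC": pairwise_dmr(ews_betas, cic_betas, "EwS_vs_CIC", statistic),
    }
    features = select_features(
        results, ncc_train_betas, ensemble_index=ensemble_index, **select_kwargs
    )
    return results, features
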