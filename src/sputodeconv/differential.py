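"""Differential expression/methylation testing with Welch statistics.

Two Welch (unequal-variance) t variants are provided: one on per-sample
values (mixed-cell matrices) and one on deconvolved estimates, where each
group contributes a point estimate, its regression standard error and the
residual degrees of freedom, combined by the Welch-Satterthwaite formula.
P values are Benjamini-Hochberg adjusted; significance cutoffs follow the
study's context-specific policy, deliberately stricter on deconvolved
estimates where the normality assumption is least trustworthy:

    mixed-cell DEG:    BH p < 0.05,  |log2FC|    >= 1.5
    mixed-cell DMP:    BH p < 0.05,  |delta beta| >= 0.1
    deconvolved DEG:   BH p < 0.005, |log2FC|    >= 1.5
    deconvolved DMP:   BH p < 0.001, |delta beta| >= 0.1
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DifferentialTable, MixedOmicsMatrix, SchemaError
from .deconvolution import CellProfileEstimate


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdPolicy:
    """Context-specific significance cutoffs, immutable per run."""

    name: str
    p_adj: dict
    min_effect: dict

    def cutoffs(self, context: str, modality: str) -> tuple[float, float]:
        key = (context, modality)
        if key not in self.p_adj:
            raise ConfigurationError(f"no policy entry for context {key}")
        return self.p_adj[key], self.min_effect[key]


PAPER_POLICY = ThresholdPolicy(
    name="paper",
    p_adj={
        ("mixed", "expression"): 0.05,
        ("mixed", "methylation"): 0.05,
        ("deconvolved", "expression"): 0.005,
        ("deconvolved", "methylation"): 0.001,
    },
    min_effect={
        ("mixed", "expression"): 1.5,
        ("mixed", "methylation"): 0.1,
        ("deconvolved", "expression"): 1.5,
        ("deconvolved", "methylation"): 0.1,
    },
)


def welch_from_samples(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t test: statistic, Welch-Satterthwaite df, two-sided p.

    Degenerate zero-variance cases are defined explicitly: equal means give
    (0, df, 1); unequal means with no variance give an underflow-guarded
    minimal p.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise SchemaError("each group needs at least 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        df = float(len(x) + len(y) - 2)
        if np.isclose(x.mean(), y.mean()):
            return 0.0, df, 1.0
        return np.inf if x.mean() > y.mean() else -np.inf, df, np.nextafter(0, 1)
    res = stats.ttest_ind(x, y, equal_var=False)
    se2 = v1 / len(x) + v2 / len(y)
    df = se2**2 / (v1**2 / (len(x) ** 2 * (len(x) - 1))
                   + v2**2 / (len(y) ** 2 * (len(y) - 1)))
    return float(res.statistic), float(df), float(res.pvalue)


def welch_from_estimates(
    b1: float, se1: float, df1: float, b2: float, se2: float, df2: float
) -> tuple[float, float, float]:
    """Welch t test on two estimates with standard errors and dfs.

    ``t = (b1 - b2) / sqrt(se1^2 + se2^2)`` with Welch-Satterthwaite
    ``df = (se1^2 + se2^2)^2 / (se1^4/df1 + se2^4/df2)``.  A zero SE on one
    side reduces to a one-sample t against the exact value; both SEs zero is
    the degenerate exact-difference mode.
    """
    if se1 < 0 or se2 < 0 or df1 < 1 or df2 < 1:
        raise SchemaError("SEs must be >= 0 and dfs >= 1")
    s2 = se1**2 + se2**2
    if s2 == 0:
        if np.isclose(b1, b2):
            return 0.0, float(df1 + df2), 1.0
        return (np.inf if b1 > b2 else -np.inf), float(df1 + df2), np.nextafter(0, 1)
    t = (b1 - b2) / np.sqrt(s2)
    denom = (se1**4 / df1 if se1 > 0 else 0.0) + (se2**4 / df2 if se2 > 0 else 0.0)
    df = s2**2 / denom
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, original order.

    NaNs are propagated (not counted in the number of tests).
    """
    arr = np.asarray(p, dtype=float)
    out = np.full_like(arr, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        if ((arr[ok] < 0) | (arr[ok] > 1)).any():
            raise SchemaError("p values must lie in [0, 1]")
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def effects_from_samples(
    matrix: MixedOmicsMatrix, g1: pd.Index, g2: pd.Index
) -> pd.Series:
    """Mixed-cell effect sizes: delta beta, or difference of log2 means."""
    if matrix.modality == "methylation-beta":
        return matrix.data[g1].mean(axis=1) - matrix.data[g2].mean(axis=1)
    if matrix.modality == "expression-log2":
        return matrix.data[g1].mean(axis=1) - matrix.data[g2].mean(axis=1)
    raise SchemaError(
        "mixed-cell effects need methylation-beta or expression-log2 input")


def effects_from_estimates(
    modality: str, est1: pd.Series, est2: pd.Series, mode: str = "ratio"
) -> pd.Series:
    """Deconvolved effect sizes.

    Methylation: delta beta (difference of estimates).  Expression (linear
    estimates, positive by the box bounds): ``log2(est1/est2)`` by default,
    or difference of re-logged values under ``mode='difference'`` (identical
    for point estimates; the switch exists for clarity of reporting).
    """
    if modality == "methylation":
        return est1 - est2
    if modality == "expression":
        vals = pd.concat([est1, est2], axis=1).to_numpy()
        if (vals <= 0).any():
            raise AssertionError(
                "deconvolved expression estimates must be positive under the "
                "declared bounds")
        if mode == "ratio":
            return np.log2(est1 / est2)
        if mode == "difference":
            return np.log2(est1) - np.log2(est2)
        raise ConfigurationError(f"unknown effect mode {mode!r}")
    raise ConfigurationError(f"unknown modality {modality!r}")


def call_significant(
    table: pd.DataFrame, context: str, modality: str,
    policy: ThresholdPolicy = PAPER_POLICY,
) -> DifferentialTable:
    """Apply the context's cutoffs and attach up/down summary counts."""
    p_cut, e_cut = policy.cutoffs(context, modality)
    out = table.copy()
    out["significant"] = (out["p_adj"] < p_cut) & (out["effect"].abs() >= e_cut)
    n_up = int((out["significant"] & (out["effect"] > 0)).sum())
    n_down = int((out["significant"] & (out["effect"] < 0)).sum())
    return DifferentialTable(
        data=out, context=context, modality=modality, policy_name=policy.name,
        summary={"n_significant": n_up + n_down, "n_up": n_up, "n_down": n_down,
                 "p_adj_cutoff": p_cut, "effect_cutoff": e_cut},
    )


def differential_mixed(
    matrix: MixedOmicsMatrix, groups: pd.Series, group1: str, group2: str,
    policy: ThresholdPolicy = PAPER_POLICY,
) -> DifferentialTable:
    """Feature-wise Welch screen on a mixed-cell matrix (group1 vs group2).

    Expression input may be linear (log2-transformed internally: the test
    statistics are computed on the log2 scale) or already log2.
    """
    if matrix.modality == "expression-linear":
        matrix = matrix.to_log2()
    modality = ("methylation" if matrix.modality == "methylation-beta"
                else "expression")
    g1 = groups[groups == group1].index.intersection(matrix.samples)
    g2 = groups[groups == group2].index.intersection(matrix.samples)
    if len(g1) < 2 or len(g2) < 2:
        raise SchemaError("need >= 2 samples per group")
    X1 = matrix.data[g1].to_numpy()
    X2 = matrix.data[g2].to_numpy()
    rows = [welch_from_samples(X1[i], X2[i]) for i in range(X1.shape[0])]
    tab = pd.DataFrame(rows, columns=["t", "df", "p"], index=matrix.features)
    tab.insert(0, "effect", effects_from_samples(matrix, g1, g2))
    tab["p_adj"] = bh_adjust(tab["p"])
    return call_significant(tab, "mixed", modality, policy)


def differential_deconvolved(
    est1: CellProfileEstimate, est2: CellProfileEstimate, cell_type: str,
    modality: str, policy: ThresholdPolicy = PAPER_POLICY,
    effect_mode: str = "ratio",
) -> DifferentialTable:
    """Welch screen on one cell type's deconvolved estimates across groups."""
    for est in (est1, est2):
        if cell_type not in est.estimates.index:
            raise ConfigurationError(
                f"cell type {cell_type!r} not estimated for group {est.group!r}")
    b1, s1 = est1.estimates.loc[cell_type], est1.se.loc[cell_type]
    b2, s2 = est2.estimates.loc[cell_type], est2.se.loc[cell_type]
    common = b1.index.intersection(b2.index)
    rows = [
        welch_from_estimates(b1[f], s1[f], est1.residual_df,
                             b2[f], s2[f], est2.residual_df)
        for f in common
    ]
    tab = pd.DataFrame(rows, columns=["t", "df", "p"], index=common)
    tab.insert(0, "effect", effects_from_estimates(
        modality, b1[common], b2[common], mode=effect_mode))
    tab["p_adj"] = bh_adjust(tab["p"])
    out = call_significant(tab, "deconvolved", modality, policy)
    out.summary["cell_type"] = cell_type
    return out
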