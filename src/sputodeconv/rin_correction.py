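"""RNA-degradation (RIN) diagnostics and correction for log2 expression.

Partial RNA degradation shifts probe intensities in a probe-specific way;
after quantile normalization this manifests as probe-RIN correlations of
both signs, and the integrity axis can rival biology in a PCA.  Two
remedies are offered: (a) removing probes whose expression correlates with
RIN beyond a threshold, and (b) a per-probe linear model in RIN whose
fitted RIN term is subtracted, re-anchoring each probe at a reference
integrity.  Least squares makes the corrected residuals exactly orthogonal
to RIN in the covariate-free mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MixedOmicsMatrix, SchemaError


@dataclass
class RinCorrelationSpectrum:
    """Per-probe Pearson correlation with RIN plus summary fractions."""

    r: pd.Series
    p: pd.Series
    zero_variance: pd.Index
    frac_positive: float
    frac_negative: float


def rin_correlations(
    expr_log2: MixedOmicsMatrix, rin: pd.Series, r_threshold: float = 0.0
) -> RinCorrelationSpectrum:
    """Correlate every probe with RIN across samples.

    Zero-variance probes are flagged and excluded from the spectrum rather
    than scored.  ``frac_positive``/``frac_negative`` count scored probes
    with r beyond ``+/- r_threshold``.
    """
    rin = rin.reindex(expr_log2.samples).astype(float)
    if len(rin) < 3:
        raise SchemaError("need at least 3 samples for a correlation spectrum")
    if np.isclose(rin.std(ddof=0), 0.0):
        raise SchemaError("RIN has no variance: no degradation axis to score")
    X = expr_log2.data.to_numpy(dtype=float)
    n = X.shape[1]
    sd = X.std(axis=1, ddof=0)
    nonconst = sd > 0
    Xc = X[nonconst] - X[nonconst].mean(axis=1, keepdims=True)
    rc = (rin - rin.mean()).to_numpy()
    r = (Xc @ rc) / (np.linalg.norm(Xc, axis=1) * np.linalg.norm(rc))
    r = np.clip(r, -1.0, 1.0)
    # two-sided p via the exact t transform of Pearson r
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    idx = expr_log2.features[nonconst]
    r_s = pd.Series(r, index=idx, name="r")
    return RinCorrelationSpectrum(
        r=r_s, p=pd.Series(p, index=idx, name="p"),
        zero_variance=expr_log2.features[~nonconst],
        frac_positive=float((r_s > r_threshold).mean()) if len(r_s) else 0.0,
        frac_negative=float((r_s < -r_threshold).mean()) if len(r_s) else 0.0,
    )


def correlation_filter(
    expr_log2: MixedOmicsMatrix, rin: pd.Series, r_threshold: float
) -> tuple[MixedOmicsMatrix, pd.Index]:
    """Drop probes with ``|r| >= r_threshold`` against RIN.

    The threshold is a required, explicit parameter: how aggressively to
    filter trades degradation robustness against transcriptome coverage
    and must be a deliberate analysis choice.
    """
    if not (0.0 < r_threshold <= 1.0):
        raise SchemaError("r_threshold must lie in (0, 1]")
    spec = rin_correlations(expr_log2, rin)
    removed = spec.r.index[spec.r.abs() >= r_threshold - 1e-12]
    kept = expr_log2.features.difference(removed, sort=False)
    return (
        MixedOmicsMatrix(expr_log2.data.loc[kept], expr_log2.modality),
        removed,
    )


def linear_correction(
    expr_log2: MixedOmicsMatrix,
    rin: pd.Series,
    covariates: pd.Series | None = None,
    rin_ref: float | None = None,
) -> tuple[MixedOmicsMatrix, pd.Series]:
    """Fit ``value ~ intercept + b*RIN (+ group)`` per probe; subtract the
    RIN term.

    Corrected value = observed - b * (RIN - rin_ref), so every sample is
    re-anchored at the reference integrity (default: cohort mean RIN, which
    keeps corrected values on the observed scale).  With group covariates
    only the RIN coefficient is removed, preserving group differences.  No
    probes are lost; singular per-probe fits fall back to no correction.
    Returns the corrected matrix and the per-probe RIN slopes.
    """
    rin = rin.reindex(expr_log2.samples).astype(float)
    n = len(rin)
    if n < 3:
        raise SchemaError("need at least 3 samples for the linear model")
    if np.isclose(rin.std(ddof=0), 0.0):
        raise SchemaError("RIN has no variance: nothing to correct")
    if rin_ref is None:
        rin_ref = float(rin.mean())

    cols = [np.ones(n), rin.to_numpy()]
    if covariates is not None:
        dummies = pd.get_dummies(covariates.reindex(expr_log2.samples),
                                 drop_first=True, dtype=float)
        cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    D = np.column_stack(cols)
    cond = np.linalg.cond(D)
    if cond > 1e8:
        warnings.warn(
            f"design nearly collinear with RIN (condition number {cond:.3g}); "
            "RIN slopes are unstable")

    Y = expr_log2.data.to_numpy(dtype=float).T      # samples x probes
    coef, _, rank, _ = np.linalg.lstsq(D, Y, rcond=None)
    slopes = coef[1].copy()
    if rank < D.shape[1]:
        warnings.warn("singular design: probes left uncorrected")
        slopes[:] = 0.0
    corrected = Y - np.outer(rin.to_numpy() - rin_ref, slopes)
    return (
        MixedOmicsMatrix(
            pd.DataFrame(corrected.T, index=expr_log2.features,
                         columns=expr_log2.samples),
            expr_log2.modality),
        pd.Series(slopes, index=expr_log2.features, name="rin_slope"),
    )


def pca_scores(
    matrix: MixedOmicsMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample scores on the top principal components of the feature space.

    Features are centered internally; components are ordered by variance
    explained, with the sign fixed so each component's largest-magnitude
    feature loading is positive (deterministic up to that convention).
    """
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[0] < n_components:
        warnings.warn("fewer features than requested components")
        n_components = X.shape[0]
    Xc = (X - X.mean(axis=1, keepdims=True)).T   # samples x features
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    if rank < n_components:
        warnings.warn(f"matrix rank {rank} < requested {n_components} components")
        n_components = max(rank, 1)
    # sign convention: largest-|loading| feature positive per component
    for i in range(n_components):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    total_var = (S**2).sum()
    var_explained = (S[:n_components] ** 2) / total_var * 100.0 if total_var > 0 \
        else np.zeros(n_components)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.samples, columns=pcs),
        pd.Series(var_explained, index=pcs, name="percent_variance"),
    )
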