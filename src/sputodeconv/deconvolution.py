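"""Cell-type deconvolution by box-constrained least squares.

For each sample group and each feature, the mixed-cell measurement ``y`` is
modelled as ``y = F b + e`` where the rows of ``F`` are the counted cell
fractions: one column per major cell type plus a weighed-intercept column
holding the summed minor-cell fractions (absorbing their pooled profile and
preserving degrees of freedom).  The coefficients ``b`` are the cell-type-
specific feature values and are estimated by

    min ||y - F b||^2   subject to   lower <= b <= upper

a quadratic program per feature, with bounds [0, 1] for methylation beta
values and the array's dynamic range for linear-scale expression.  Standard
errors use the classical regression formula sigma^2 (F'F)^-1 with
sigma^2 = RSS / (n - p); features where box constraints are active are
flagged, since there the classical formula is an approximation.

Expression must enter on the linear scale and methylation on the beta scale:
only there is the measurement a fraction-weighted linear combination of the
cell-type values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .datatypes import CellCountTable, MixedOmicsMatrix, SchemaError

DEFAULT_EXCLUDED = ("MO",)   # near-absent, non-determinant: excluded ab initio

#: majors used in the study: eosinophils only where they are prevalent enough
DEFAULT_MAJORS = {
    "asthma": ("AM", "NG", "EO"),
    "COPD": ("AM", "NG"),
    "control": ("AM", "NG"),
}


@dataclass
class BoxBounds:
    """Box constraints per modality: [0,1] betas, dynamic range for expression."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise SchemaError("bounds require lower < upper")

    @classmethod
    def methylation(cls) -> "BoxBounds":
        return cls(0.0, 1.0)

    @classmethod
    def expression_auto(cls, matrix: MixedOmicsMatrix) -> "BoxBounds":
        """Dynamic range of the observed (normalized) array."""
        vals = matrix.data.to_numpy()
        lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
        if lo <= 0:
            raise SchemaError("expression dynamic range requires positive values")
        return cls(lo, hi)

    @classmethod
    def for_matrix(cls, matrix: MixedOmicsMatrix) -> "BoxBounds":
        if matrix.modality == "methylation-beta":
            return cls.methylation()
        if matrix.modality == "expression-linear":
            return cls.expression_auto(matrix)
        raise SchemaError(
            "deconvolution requires expression-linear or methylation-beta input; "
            "linearize log2 expression first")


@dataclass
class DesignMatrix:
    """Per-group deconvolution design built from the differential counts.

    ``data`` is samples x (majors + 'minor') with entries in [0, 1] and rows
    summing to 1; the 'minor' column is the weighed intercept (summed minor
    fractions after exclusions).
    """

    data: pd.DataFrame
    major_types: tuple[str, ...]
    minor_types: tuple[str, ...]
    excluded: tuple[str, ...]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.data.to_numpy()))

    def __post_init__(self) -> None:
        X = self.data.to_numpy()
        if (X < -1e-9).any() or (X > 1 + 1e-9).any():
            raise SchemaError("design entries must lie in [0, 1]")
        if np.abs(X.sum(axis=1) - 1.0).max() > 1e-6:
            raise SchemaError("design rows must sum to 1")


def build_design(
    cell_counts: CellCountTable,
    major_types: tuple[str, ...],
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED,
    renormalize: bool = True,
) -> DesignMatrix:
    """Turn counted percentages into a simplex design with a weighed intercept.

    Excluded cell types (default: monocytes) are removed and the remaining
    fractions renormalized to sum 1 per sample; the minor types' sum forms
    the intercept column.
    """
    counts = cell_counts.data
    missing = [t for t in major_types if t not in counts.columns]
    if missing:
        raise SchemaError(f"major types absent from counts: {missing}")
    kept = [c for c in counts.columns if c not in excluded]
    frac = counts[kept].to_numpy(dtype=float) / 100.0
    row_sum = frac.sum(axis=1)
    if (row_sum <= 0).any():
        bad = cell_counts.samples[row_sum <= 0]
        raise SchemaError(f"rows sum to 0 after exclusion: {list(bad)}")
    if renormalize:
        frac = frac / row_sum[:, None]
    frac_df = pd.DataFrame(frac, index=counts.index, columns=kept)
    minors = tuple(c for c in kept if c not in major_types)
    design = frac_df[list(major_types)].copy()
    design["minor"] = frac_df[list(minors)].sum(axis=1) if minors else 0.0
    return DesignMatrix(design, tuple(major_types), minors, tuple(excluded))


def solve_box_ls(
    F: np.ndarray, y: np.ndarray, bounds: BoxBounds, tol: float = 1e-12
) -> tuple[np.ndarray, dict]:
    """Solve ``min ||y - F b||^2`` s.t. ``lower <= b <= upper``.

    Returns the coefficient vector and diagnostics: the objective, which
    bounds are active, and whether the solver converged.  When the
    unconstrained least-squares solution is interior to the box it is
    returned (within solver tolerance).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise SchemaError("response contains non-finite values")
    res = lsq_linear(F, y, bounds=(bounds.lower, bounds.upper), tol=tol)
    beta = np.clip(res.x, bounds.lower, bounds.upper)
    at_lower = np.isclose(beta, bounds.lower, atol=1e-9)
    at_upper = np.isclose(beta, bounds.upper, atol=1e-9)
    return beta, {
        "objective": float(res.cost * 2.0),       # lsq_linear reports 1/2 ||r||^2
        "active_lower": at_lower,
        "active_upper": at_upper,
        "n_active": int((at_lower | at_upper).sum()),
        "converged": bool(res.status > 0),
    }


def estimate_ses(
    F: np.ndarray, residuals: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, int]:
    """Classical regression standard errors for the fitted coefficients.

    ``SE_j = sigma_hat * sqrt(((F'F)^-1)_jj)`` with
    ``sigma_hat^2 = RSS / (n - p)``.  ``residuals`` may be a vector or a
    (n x features) matrix; the returned SEs then have one column per
    feature.  Requires ``n > p``.
    """
    n, p = F.shape
    if n <= p:
        raise SchemaError(f"need n > p for standard errors (n={n}, p={p})")
    G = F.T @ F
    if ridge > 0:
        G = G + ridge * np.eye(p)
    diag = np.diag(np.linalg.inv(G))
    res = np.atleast_2d(residuals.T).T      # n x m
    rss = (res**2).sum(axis=0)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.outer(diag, sigma2))
    if residuals.ndim == 1:
        return se[:, 0], n - p
    return se, n - p


@dataclass
class CellProfileEstimate:
    """Deconvolved cell-type profiles for one sample group.

    ``estimates``/``se`` are (majors + 'minor') x features; ``residual_df``
    is shared across coefficients of a feature; ``diagnostics`` records
    per-feature active-constraint counts, objective and convergence.
    """

    group: str
    estimates: pd.DataFrame
    se: pd.DataFrame
    residual_df: int
    diagnostics: pd.DataFrame
    bounds: BoxBounds
    design: DesignMatrix = field(repr=False, default=None)


def deconvolve_group(
    matrix: MixedOmicsMatrix,
    design: DesignMatrix,
    bounds: BoxBounds | None = None,
    group: str = "",
    ridge_fallback: float = 1e-8,
) -> CellProfileEstimate:
    """Estimate one group's cell-type profiles, one QP per feature.

    The input must be on a linearly combinable scale (linear expression or
    beta methylation).  Near-rank-deficient designs are handled by a tiny
    ridge in the SE computation plus a warning; per-feature solver failures
    are recorded as missing values and the run continues.
    """
    if matrix.modality == "expression-log2":
        raise SchemaError(
            "deconvolution requires linear-scale expression: call .to_linear() "
            "on the log2 matrix first")
    if matrix.modality not in ("expression-linear", "methylation-beta"):
        raise SchemaError(f"unsupported modality {matrix.modality!r}")
    bounds = bounds or BoxBounds.for_matrix(matrix)

    missing = design.data.index.difference(matrix.samples)
    if len(missing):
        raise SchemaError(f"design samples absent from matrix: {list(missing[:5])}")
    Y = matrix.data[design.data.index].to_numpy(dtype=float)   # features x n
    F = design.data.to_numpy(dtype=float)
    n, p = F.shape
    if n <= p:
        raise SchemaError(f"group needs more samples than coefficients ({n} <= {p})")

    ridge = 0.0
    if np.linalg.cond(F) > 1e6:
        ridge = ridge_fallback
        warnings.warn(
            f"design nearly rank-deficient (cond {np.linalg.cond(F):.3g}); "
            f"applying ridge {ridge_fallback} in SE computation")

    nfeat = Y.shape[0]
    B = np.full((p, nfeat), np.nan)
    resid = np.zeros((n, nfeat))
    diag_rows = []
    for j in range(nfeat):
        try:
            beta, d = solve_box_ls(F, Y[j], bounds)
        except Exception as exc:             # pragma: no cover - defensive
            diag_rows.append(dict(n_active=-1, objective=np.nan,
                                  converged=False, error=str(exc)))
            continue
        B[:, j] = beta
        resid[:, j] = Y[j] - F @ beta
        diag_rows.append(dict(n_active=d["n_active"], objective=d["objective"],
                              converged=d["converged"], error=""))

    se, df = estimate_ses(F, resid, ridge=ridge)
    cols = list(design.data.columns)
    return CellProfileEstimate(
        group=group,
        estimates=pd.DataFrame(B, index=cols, columns=matrix.features),
        se=pd.DataFrame(se, index=cols, columns=matrix.features),
        residual_df=df,
        diagnostics=pd.DataFrame(diag_rows, index=matrix.features),
        bounds=bounds,
        design=design,
    )


def deconvolve_by_group(
    matrix: MixedOmicsMatrix,
    cell_counts: CellCountTable,
    groups: pd.Series,
    majors: dict[str, tuple[str, ...]] | None = None,
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED,
    bounds: BoxBounds | None = None,
) -> dict[str, CellProfileEstimate]:
    """Run the per-group estimation over every sample group.

    ``majors`` maps group -> major cell types (defaults mirror the cohort:
    eosinophils only in asthma).  Bounds default to the modality rule
    computed on the full matrix, shared across groups.
    """
    majors = majors or DEFAULT_MAJORS
    bounds = bounds or BoxBounds.for_matrix(matrix)
    out = {}
    for g in pd.unique(groups):
        samples = groups[groups == g].index
        counts_g = CellCountTable(cell_counts.data.loc[samples])
        design = build_design(counts_g, tuple(majors.get(g, ("AM", "NG"))),
                              excluded)
        sub = MixedOmicsMatrix(matrix.data[samples], matrix.modality)
        out[g] = deconvolve_group(sub, design, bounds, group=str(g))
    return out
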