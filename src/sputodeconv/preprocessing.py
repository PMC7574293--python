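"""Array preprocessing: background correction, quantile normalization,
flag-based probe filtering, replicate averaging, CpG filtering.

Expression matrices follow the two-color-array convention: median foreground
minus mean background ("minimum" rule for nonpositive values), cross-array
quantile normalization, removal of control probes and probes flagged
non-uniform / saturated / population-outlier on any array, a 50%-found-and-
significant rule evaluated per sample group, and arithmetic averaging of
replicate probes.  Methylation matrices arrive as beta values and are
filtered by detection p value, sex chromosomes, SNP affection and
cross-hybridization potential.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (
    CpGAnnotation,
    MixedOmicsMatrix,
    ProbeFlagTable,
    SampleMetadata,
    SchemaError,
)


def background_correct(
    foreground_median: pd.DataFrame, background_mean: pd.DataFrame
) -> MixedOmicsMatrix:
    """Subtract mean background from median foreground, per spot.

    Nonpositive corrected values are replaced by half the minimum positive
    corrected value on that array (the "minimum" convention), so every
    output is strictly positive and log-transformable.
    """
    if foreground_median.shape != background_mean.shape:
        raise SchemaError("foreground and background shapes differ")
    corrected = foreground_median.to_numpy(dtype=float) - background_mean.to_numpy(dtype=float)
    out = corrected.copy()
    for j in range(corrected.shape[1]):
        col = corrected[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise SchemaError(
                f"array {foreground_median.columns[j]!r} has no positive "
                "background-corrected value")
        out[col <= 0, j] = positive.min() / 2.0
    return MixedOmicsMatrix(
        pd.DataFrame(out, index=foreground_median.index,
                     columns=foreground_median.columns),
        "expression-linear")


def quantile_normalize(matrix: MixedOmicsMatrix) -> MixedOmicsMatrix:
    """Force every column onto the cross-column mean quantile distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values; ties within a column receive the mean of the
    tied rank values (average ranks), making the result order-independent
    and idempotent.
    """
    if matrix.data.shape[1] == 1:
        warnings.warn("single-column input: quantile normalization is a no-op")
        return MixedOmicsMatrix(matrix.data.copy(), matrix.modality)
    X = matrix.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise SchemaError("missing values must be handled before normalization")
    mean_quantiles = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, X.shape[0] + 1), mean_quantiles)
    return MixedOmicsMatrix(
        pd.DataFrame(out, index=matrix.features, columns=matrix.samples),
        matrix.modality)


def filter_expression_probes(
    flags: ProbeFlagTable, metadata: SampleMetadata,
    found_fraction: float = 0.5,
) -> tuple[pd.Series, dict[str, int]]:
    """Boolean keep mask over probes plus per-rule drop counts.

    Drops control probes; drops any probe flagged non-uniform, saturated or
    population-outlier on any array; keeps a probe only if, in at least one
    sample group, at least ``found_fraction`` of its arrays are both found
    and positive-and-significant.
    """
    groups = metadata.groups
    sizes = groups.value_counts()
    if (sizes == 0).any():
        raise SchemaError("every group must contain at least one sample")
    long = flags.flags.set_index(["probe_id", "sample_id"])
    probes = flags.probe_info.index

    bad_quality = (
        long[["non_uniform", "saturated", "population_outlier"]]
        .any(axis=1).groupby(level="probe_id").any()
        .reindex(probes, fill_value=False))

    ok = (long["found"] & long["positive_and_significant"]).rename("ok").reset_index()
    ok["group"] = ok["sample_id"].map(groups)
    frac = ok.groupby(["probe_id", "group"])["ok"].mean().unstack(fill_value=0.0)
    detected = (frac >= found_fraction).any(axis=1).reindex(probes, fill_value=False)

    is_control = flags.probe_info["is_control"].astype(bool)
    keep = ~is_control & ~bad_quality & detected
    drops = {
        "control": int(is_control.sum()),
        "quality_flag": int((~is_control & bad_quality).sum()),
        "detection": int((~is_control & ~bad_quality & ~detected).sum()),
    }
    return keep, drops


def average_replicates(
    matrix: MixedOmicsMatrix, replicate_groups: pd.Series
) -> MixedOmicsMatrix:
    """Collapse replicate probes to their arithmetic per-sample mean.

    ``replicate_groups`` maps feature id -> replicate-group id; singleton
    groups pass through unchanged.  The output index is the replicate-group
    id, ordered by first appearance.
    """
    missing = matrix.features.difference(replicate_groups.index)
    if len(missing):
        raise SchemaError(f"features without replicate group: {list(missing[:5])}")
    gid = replicate_groups.reindex(matrix.features)
    if gid.isna().any():
        raise SchemaError("replicate-group ids must be non-missing")
    order = gid.drop_duplicates().tolist()
    avg = matrix.data.groupby(gid, sort=False).mean().reindex(order)
    return MixedOmicsMatrix(avg, matrix.modality)


def filter_cpgs(
    beta: MixedOmicsMatrix, ann: CpGAnnotation,
    detection_threshold: float = 0.01, detection_rule: str = "any",
    detection_fraction: float = 0.5,
) -> tuple[pd.Series, dict[str, int]]:
    """Boolean keep mask over CpGs plus per-rule drop counts.

    A CpG is dropped if its detection p value is at or above the threshold
    (``any`` sample by default, or in more than ``detection_fraction`` of
    samples under the ``fraction`` rule), if it maps to chrX/chrY, is
    SNP-affected, or is potentially cross-hybridizing.  Drop counts are
    attributed in that order (each CpG counted once).
    """
    ann.require_cover(beta.features)
    info = ann.info.loc[beta.features]
    detp = ann.detection_p.loc[beta.features, beta.samples]
    fail = detp >= detection_threshold
    if detection_rule == "any":
        det_bad = fail.any(axis=1)
    elif detection_rule == "fraction":
        det_bad = fail.mean(axis=1) > detection_fraction
    else:
        raise SchemaError(f"unknown detection rule {detection_rule!r}")
    sex = info["chrom"].isin(["chrX", "chrY", "X", "Y"])
    snp = info["snp_affected"].astype(bool)
    cross = info["cross_reactive"].astype(bool)
    keep = ~(det_bad | sex | snp | cross)
    drops = {
        "detection_p": int(det_bad.sum()),
        "sex_chromosome": int((~det_bad & sex).sum()),
        "snp": int((~det_bad & ~sex & snp).sum()),
        "cross_reactive": int((~det_bad & ~sex & ~snp & cross).sum()),
    }
    return keep, drops
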