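"""Core data containers shared across the pipeline.

Everything is a thin, validated wrapper around a :class:`pandas.DataFrame`
so that TSV round-trips, joins and slicing stay idiomatic pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("expression-linear", "expression-log2", "methylation-beta")

CELL_TYPES = ("AM", "NG", "EO", "LY", "MO", "CC", "SC")


class SchemaError(ValueError):
    """Raised when an input table violates the pipeline's schema contracts."""


@dataclass
class MixedOmicsMatrix:
    """Features x samples numeric matrix with a modality tag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample.
    modality
        One of ``expression-linear``, ``expression-log2``,
        ``methylation-beta``.
    """

    data: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise SchemaError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not self.data.index.is_unique:
            raise SchemaError("feature ids must be unique")
        if self.modality == "methylation-beta":
            vals = self.data.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise SchemaError("beta values must lie in [0, 1]")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def to_log2(self) -> "MixedOmicsMatrix":
        if self.modality != "expression-linear":
            raise SchemaError("log2 transform only applies to expression-linear")
        return MixedOmicsMatrix(np.log2(self.data), "expression-log2")

    def to_linear(self) -> "MixedOmicsMatrix":
        if self.modality != "expression-log2":
            raise SchemaError("linearization only applies to expression-log2")
        return MixedOmicsMatrix(2.0 ** self.data, "expression-linear")

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path, modality: str) -> "MixedOmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, modality)


@dataclass
class CellCountTable:
    """Samples x cell-type percentages from the differential cell count.

    Rows must sum to 100% (within ``tol``); these fractions are the
    deconvolution design source, not an estimate.
    """

    data: pd.DataFrame
    tol: float = 1e-6

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in CELL_TYPES]
        if missing:
            raise SchemaError(f"unknown cell types in counts: {missing}")
        sums = self.data.sum(axis=1)
        bad = sums[(sums - 100.0).abs() > max(self.tol, 1e-6) * 100.0]
        if len(bad):
            raise SchemaError(
                f"cell-count rows must sum to 100%: offending samples {list(bad.index)}"
            )
        if (self.data.to_numpy() < -1e-12).any():
            raise SchemaError("cell-count percentages must be nonnegative")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellCountTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class SampleMetadata:
    """Per-sample group label, RIN and preservation method.

    ``data`` is indexed by sample id with columns ``group``, ``rin``,
    ``preservation``.  ``min_rin`` implements the intake rule that samples
    below a minimum RNA integrity are excluded from expression analysis
    (default threshold 3.0, configurable).
    """

    data: pd.DataFrame
    min_rin: float = 3.0

    REQUIRED = ("group", "rin", "preservation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise SchemaError(f"sample metadata missing columns: {missing}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def rin(self) -> pd.Series:
        return self.data["rin"].astype(float)

    def rin_pass_mask(self) -> pd.Series:
        """True for samples meeting the minimum-RIN intake rule."""
        return self.rin >= self.min_rin

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, min_rin: float = 3.0) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0), min_rin=min_rin)


@dataclass
class ProbeFlagTable:
    """Per probe x array quality flags from array feature extraction.

    ``flags`` is a long-format DataFrame with columns ``probe_id``,
    ``sample_id`` and the boolean flag columns; ``probe_info`` carries
    per-probe ``is_control`` and ``replicate_group``.
    """

    flags: pd.DataFrame
    probe_info: pd.DataFrame

    FLAG_COLS = (
        "found",
        "positive_and_significant",
        "non_uniform",
        "saturated",
        "population_outlier",
    )

    def __post_init__(self) -> None:
        missing = [c for c in ("probe_id", "sample_id", *self.FLAG_COLS)
                   if c not in self.flags.columns]
        if missing:
            raise SchemaError(f"flag table missing columns: {missing}")
        for c in self.FLAG_COLS:
            if self.flags[c].isna().any():
                raise SchemaError(f"flag column {c!r} has missing values")
        for c in ("is_control", "replicate_group"):
            if c not in self.probe_info.columns:
                raise SchemaError(f"probe info missing column {c!r}")


@dataclass
class CpGAnnotation:
    """Per-CpG genomic annotation and detection p values.

    ``info`` columns: ``chrom``, ``pos`` (1-based, as on array manifests),
    ``snp_affected``, ``cross_reactive``; ``detection_p`` is CpGs x samples.
    """

    info: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "pos", "snp_affected", "cross_reactive")
                   if c not in self.info.columns]
        if missing:
            raise SchemaError(f"CpG annotation missing columns: {missing}")
        dp = self.detection_p.to_numpy()
        if dp.size and ((dp < 0) | (dp > 1)).any():
            raise SchemaError("detection p values must lie in [0, 1]")

    def require_cover(self, cpgs: pd.Index) -> None:
        missing = cpgs.difference(self.info.index)
        if len(missing):
            raise SchemaError(
                f"{len(missing)} CpGs lack annotation, e.g. {list(missing[:5])}"
            )


@dataclass
class DifferentialTable:
    """Per-feature differential-test results with significance calls."""

    data: pd.DataFrame
    context: str
    modality: str
    policy_name: str = "paper"
    summary: dict = field(default_factory=dict)

    COLUMNS = ("effect", "t", "df", "p", "p_adj", "significant")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"differential table missing columns: {missing}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# context={self.context} modality={self.modality} "
                     f"policy={self.policy_name}\n")
            for k, v in self.summary.items():
                fh.write(f"# {k}={v}\n")
            self.data.to_csv(fh, sep="\t", index_label="feature_id")
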