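"""Synthetic mixed-cell sputum dataset generator with known ground truth.

The generator emulates the statistical structure of a sputum-omics cohort:
per-group Dirichlet cell-fraction distributions parameterized by the cohort's
differential cell counts, latent cell-type-specific expression (linear array
scale) and methylation (beta) profiles with spiked group effects, truncated-
normal RIN distributions per preservation route, and probe-specific
exponential RNA degradation in ``rin_ref - RIN``.  Every downstream stage of
the pipeline can thereby be tested against planted truth without downloads.

Cell-fraction defaults (mean percent, by group)::

    group    AM    NG    EO   LY   MO   CC   SC   concentration
    asthma   27.9  54.7  12.9 0.7  0.1  1.6  2.1  3.2
    COPD      9.0  88.9   1.0 0.2  0.0  0.4  0.6  22.0
    control  52.3  40.3   0.2 2.0  0.2  1.6  3.4  3.0

The per-group Dirichlet concentration is fitted so that the marginal SDs of
the dominant cell types (AM, NG) match the cohort SDs via
``Var = m(1-m)/(c+1)``.  Cell types with a zero mean in a group (MO in COPD)
are structural zeros: the Dirichlet is sampled over the positive components
only.  RIN defaults: RLT-preserved samples 8.6 +/- 0.4 truncated to
[7.6, 9.1]; HOPE-preserved 4.3 +/- 0.6 truncated to [3.2, 5.1].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datatypes import (
    CELL_TYPES,
    CellCountTable,
    CpGAnnotation,
    MixedOmicsMatrix,
    ProbeFlagTable,
    SampleMetadata,
    SchemaError,
)


class ConfigurationError(ValueError):
    """Raised for unknown labels or invalid generator parameters."""


# --------------------------------------------------------------------------
# fraction model


@dataclass
class FractionModel:
    """Dirichlet sampling law for cell-type proportions, per group.

    ``means`` maps group -> mean percentage per cell type (summing to ~100,
    renormalized exactly on construction); ``concentration`` maps group ->
    the single Dirichlet concentration parameter c, with alpha = mean * c.
    Zero-mean cell types are structural zeros.
    """

    means: dict[str, dict[str, float]]
    concentration: dict[str, float]

    def __post_init__(self) -> None:
        for group, m in self.means.items():
            total = sum(m.values())
            if total <= 0:
                raise ConfigurationError(f"group {group!r} has nonpositive means")
            self.means[group] = {k: v / total for k, v in m.items()}
            if any(v < 0 for v in m.values()):
                raise ConfigurationError(f"group {group!r} has negative means")

    def mean_vector(self, group: str) -> pd.Series:
        if group not in self.means:
            raise ConfigurationError(f"unknown group {group!r}")
        return pd.Series(self.means[group], dtype=float)

    @classmethod
    def default(cls) -> "FractionModel":
        return cls(
            means={
                "asthma": dict(AM=27.9, NG=54.7, EO=12.9, LY=0.7, MO=0.1,
                               CC=1.6, SC=2.1),
                "COPD": dict(AM=9.0, NG=88.9, EO=1.0, LY=0.2, MO=0.0,
                             CC=0.4, SC=0.6),
                "control": dict(AM=52.3, NG=40.3, EO=0.2, LY=2.0, MO=0.2,
                                CC=1.6, SC=3.4),
            },
            concentration={"asthma": 3.2, "COPD": 22.0, "control": 3.0},
        )


def generate_cell_fractions(
    group: str, n: int, model: FractionModel, seed: int | np.random.Generator
) -> CellCountTable:
    """Sample ``n`` cell-differential rows (percentages summing to 100).

    Infinite concentration degenerates to every row equalling the mean
    vector, which is useful for noiseless recovery tests.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    means = model.mean_vector(group)
    conc = model.concentration.get(group)
    if conc is None:
        raise ConfigurationError(f"no concentration for group {group!r}")
    pos = means[means > 0]
    out = np.zeros((n, len(means)))
    if np.isinf(conc):
        out[:, means.to_numpy() > 0] = np.tile(pos.to_numpy(), (n, 1))
    else:
        alpha = pos.to_numpy() * conc
        out[:, means.to_numpy() > 0] = rng.dirichlet(alpha, size=n)
    idx = [f"{group}_{i + 1:02d}" for i in range(n)]
    return CellCountTable(
        pd.DataFrame(out * 100.0, index=idx, columns=means.index)
    )


# --------------------------------------------------------------------------
# profiles and effects


@dataclass
class EffectSpec:
    """One block of spiked group effects in a single cell type."""

    group: str
    cell_type: str
    modality: str            # "expression" | "methylation"
    size: float              # log2FC or delta beta (nominal)
    n_features: int


@dataclass
class ProfileConfig:
    """Distribution parameters for the latent cell-type profiles."""

    n_features_expr: int = 2000
    n_features_meth: int = 2000
    dyn_lo: float = 1.0
    dyn_hi: float = 65536.0
    expr_log2_range: tuple[float, float] = (6.0, 14.0)
    expr_celltype_sd: float = 1.0       # log2 units
    meth_celltype_sd: float = 0.08      # beta units
    n_markers_per_type: int = 20
    marker_expr_log2_shift: float = 3.0
    marker_meth_shift: float = 0.3
    effects: list[EffectSpec] = field(default_factory=list)

    @classmethod
    def default(cls) -> "ProfileConfig":
        # disease-group effects in the reliably estimable cell types;
        # monocytes deliberately carry no signal (pure nuisance)
        effects = [
            EffectSpec("asthma", ct, "methylation", 0.2, 25) for ct in ("AM", "NG", "EO")
        ] + [
            EffectSpec("asthma", ct, "expression", 1.5, 25) for ct in ("AM", "NG", "EO")
        ] + [
            EffectSpec("COPD", ct, "methylation", 0.2, 25) for ct in ("AM", "NG")
        ] + [
            EffectSpec("COPD", ct, "expression", 1.5, 25) for ct in ("AM", "NG")
        ]
        return cls(effects=effects)


@dataclass
class CellTypeProfileTruth:
    """Latent per-cell-type profiles plus the planted-effect bookkeeping.

    ``expression`` / ``methylation`` are cell types x features DataFrames on
    the linear / beta scale (the control-group truth).  ``effect_truth`` has
    one row per spiked feature x group with both the nominal and the achieved
    (post-clipping) effect.  Group-specific truth is obtained via
    :meth:`profiles_for_group`.
    """

    cell_types: list[str]
    expression: pd.DataFrame
    methylation: pd.DataFrame
    marker_assignments: pd.Series
    effect_truth: pd.DataFrame
    dyn_lo: float
    dyn_hi: float

    def profiles_for_group(self, group: str, modality: str) -> pd.DataFrame:
        base = (self.expression if modality == "expression" else self.methylation).copy()
        et = self.effect_truth
        rows = et[(et["group"] == group) & (et["modality"] == modality)]
        for _, r in rows.iterrows():
            if modality == "expression":
                base.loc[r["cell_type"], r["feature_id"]] *= 2.0 ** r["achieved_effect"]
            else:
                base.loc[r["cell_type"], r["feature_id"]] += r["achieved_effect"]
        return base


def generate_profiles(
    n_features: int | None = None,
    config: ProfileConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> CellTypeProfileTruth:
    """Draw latent cell-type profiles and record spiked effects.

    Expression profiles are log2-uniform across features with Gaussian
    cell-type deviations, exponentiated and clipped to the dynamic range.
    Methylation profiles are bimodal (mixture of low/high/intermediate Beta
    components) with Gaussian cell-type jitter, clipped to [0.01, 0.99] so
    mixtures stay strictly interior.  Effects that would leave the valid
    range are clipped and the achieved effect recorded.
    """
    config = config or ProfileConfig()
    if n_features is not None:
        config.n_features_expr = config.n_features_meth = n_features
    if config.n_features_expr < 1 or config.n_features_meth < 1:
        raise ConfigurationError("n_features must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cts = list(CELL_TYPES)
    k = len(cts)

    expr_ids = [f"P{i:06d}" for i in range(config.n_features_expr)]
    lo, hi = config.expr_log2_range
    base_lg = rng.uniform(lo, hi, config.n_features_expr)
    lg = base_lg[None, :] + rng.normal(0.0, config.expr_celltype_sd,
                                       (k, config.n_features_expr))
    expr = pd.DataFrame(
        np.clip(2.0 ** lg, config.dyn_lo, config.dyn_hi), index=cts, columns=expr_ids
    )

    meth_ids = [f"cg{i:06d}" for i in range(config.n_features_meth)]
    comp = rng.choice(3, config.n_features_meth, p=[0.4, 0.4, 0.2])
    base_b = np.where(
        comp == 0, rng.beta(2, 8, config.n_features_meth),
        np.where(comp == 1, rng.beta(8, 2, config.n_features_meth),
                 rng.beta(5, 5, config.n_features_meth)),
    )
    bb = base_b[None, :] + rng.normal(0.0, config.meth_celltype_sd,
                                      (k, config.n_features_meth))
    meth = pd.DataFrame(np.clip(bb, 0.01, 0.99), index=cts, columns=meth_ids)

    # marker spikes: per cell type, shift a dedicated feature block
    markers = pd.Series(pd.NA, index=pd.Index(expr_ids + meth_ids, name="feature_id"),
                        dtype="object")
    pool_e = list(expr_ids)
    pool_m = list(meth_ids)
    for ct in cts:
        if ct == "MO":
            continue  # monocytes stay marker-free by design
        if config.n_markers_per_type * 2 > min(len(pool_e), len(pool_m)):
            break
        pick_e = [pool_e.pop(0) for _ in range(config.n_markers_per_type)]
        pick_m = [pool_m.pop(0) for _ in range(config.n_markers_per_type)]
        expr.loc[ct, pick_e] = np.clip(
            expr.loc[ct, pick_e] * 2.0 ** config.marker_expr_log2_shift,
            config.dyn_lo, config.dyn_hi)
        shift = np.where(meth.loc[ct, pick_m] < 0.5, config.marker_meth_shift,
                         -config.marker_meth_shift)
        meth.loc[ct, pick_m] = np.clip(meth.loc[ct, pick_m] + shift, 0.01, 0.99)
        markers.loc[pick_e] = ct
        markers.loc[pick_m] = ct

    # spiked group effects on non-marker features, with clip bookkeeping
    rows = []
    free_e = [f for f in pool_e]
    free_m = [f for f in pool_m]
    for spec in config.effects:
        if spec.cell_type not in cts:
            raise ConfigurationError(f"unknown cell type {spec.cell_type!r}")
        pool = free_e if spec.modality == "expression" else free_m
        if spec.n_features > len(pool):
            raise ConfigurationError("not enough free features for spiked effects")
        picked = [pool.pop(0) for _ in range(spec.n_features)]
        for fid in picked:
            if spec.modality == "expression":
                b = expr.loc[spec.cell_type, fid]
                new = float(np.clip(b * 2.0 ** spec.size, config.dyn_lo, config.dyn_hi))
                achieved = float(np.log2(new / b))
            else:
                b = meth.loc[spec.cell_type, fid]
                new = float(np.clip(b + spec.size, 0.0, 1.0))
                achieved = new - b
            rows.append(dict(feature_id=fid, group=spec.group,
                             cell_type=spec.cell_type, modality=spec.modality,
                             nominal_effect=spec.size, achieved_effect=achieved,
                             clipped=abs(achieved - spec.size) > 1e-12))
    effect_truth = pd.DataFrame(
        rows, columns=["feature_id", "group", "cell_type", "modality",
                       "nominal_effect", "achieved_effect", "clipped"])

    return CellTypeProfileTruth(
        cell_types=cts, expression=expr, methylation=meth,
        marker_assignments=markers, effect_truth=effect_truth,
        dyn_lo=config.dyn_lo, dyn_hi=config.dyn_hi)


# --------------------------------------------------------------------------
# mixing


def mix(
    profiles: CellTypeProfileTruth,
    fractions: CellCountTable,
    noise_sd: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    groups: pd.Series | None = None,
) -> tuple[MixedOmicsMatrix, MixedOmicsMatrix, dict[str, int]]:
    """Form mixed-cell observations ``y = F B + noise`` per modality.

    ``groups`` assigns each sample to a group so the group-specific truth
    (base profiles plus achieved spiked effects) enters the mixture; samples
    without a group use the control truth.  Methylation is clipped to [0, 1]
    and expression to the dynamic range; clip events are counted and
    returned.
    """
    noise_sd = dict(noise_sd or {})
    sd_e = float(noise_sd.get("expression", 0.0))
    sd_m = float(noise_sd.get("methylation", 0.0))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    missing = [c for c in profiles.cell_types if c not in fractions.data.columns]
    if missing:
        raise SchemaError(f"fraction table lacks cell types: {missing}")
    F = fractions.data[profiles.cell_types].to_numpy() / 100.0

    if groups is None:
        groups = pd.Series("control", index=fractions.samples)
    groups = groups.reindex(fractions.samples)

    clip_counts = {"expression": 0, "methylation": 0}
    mats = {}
    for modality, sd, lo, hi in (
        ("expression", sd_e, profiles.dyn_lo, profiles.dyn_hi),
        ("methylation", sd_m, 0.0, 1.0),
    ):
        by_group = {g: profiles.profiles_for_group(g, modality).to_numpy()
                    for g in groups.dropna().unique()}
        base = (profiles.expression if modality == "expression"
                else profiles.methylation)
        nfeat = base.shape[1]
        obs = np.empty((len(fractions.samples), nfeat))
        for i, s in enumerate(fractions.samples):
            g = groups.loc[s]
            B = by_group.get(g, base.to_numpy())
            obs[i] = F[i] @ B
        if sd > 0:
            obs = obs + rng.normal(0.0, sd, obs.shape)
        clipped = np.clip(obs, lo, hi)
        clip_counts[modality] = int((clipped != obs).sum())
        mats[modality] = pd.DataFrame(clipped.T, index=base.columns,
                                      columns=fractions.samples)

    return (
        MixedOmicsMatrix(mats["expression"], "expression-linear"),
        MixedOmicsMatrix(mats["methylation"], "methylation-beta"),
        clip_counts,
    )


# --------------------------------------------------------------------------
# RIN and degradation


@dataclass
class DegradationModel:
    """RIN sampling laws per preservation route plus probe susceptibility.

    ``rin_laws`` maps preservation -> (mean, sd, min, max) of a truncated
    normal.  ``lambdas`` holds per-probe decay rates (1/RIN-unit, on the
    log2 scale); probes with lambda 0 are insusceptible.  ``rin_ref`` is the
    integrity at which no decay occurs.
    """

    rin_laws: dict[str, tuple[float, float, float, float]]
    rin_ref: float = 9.0
    lambdas: pd.Series | None = None
    frac_susceptible: float = 0.5
    lambda_range: tuple[float, float] = (0.02, 0.3)

    @classmethod
    def default(cls) -> "DegradationModel":
        return cls(rin_laws={
            "RLT": (8.6, 0.4, 7.6, 9.1),
            "HOPE": (4.3, 0.6, 3.2, 5.1),
        })

    def sample_lambdas(self, features: pd.Index,
                       rng: np.random.Generator) -> pd.Series:
        lam = np.zeros(len(features))
        susceptible = rng.random(len(features)) < self.frac_susceptible
        lam[susceptible] = rng.uniform(*self.lambda_range, susceptible.sum())
        self.lambdas = pd.Series(lam, index=features, name="lambda")
        return self.lambdas


def generate_rin(
    preservation: str, n: int, model: DegradationModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample RIN values from the preservation route's truncated normal."""
    if preservation not in model.rin_laws:
        raise ConfigurationError(f"unknown preservation {preservation!r}")
    mean, sd, lo, hi = model.rin_laws[preservation]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def inject_degradation(
    expr: MixedOmicsMatrix,
    rin: pd.Series,
    model: DegradationModel,
    seed: int | np.random.Generator = 0,
) -> MixedOmicsMatrix:
    """Apply probe-specific exponential decay in ``rin_ref - RIN``.

    ``value -> value * 2^(-lambda_p * (rin_ref - RIN_s))``, floored at the
    simulated dynamic-range minimum via the max with zero decay direction:
    samples at the reference integrity are untouched.  Decay rates come from
    ``model.lambdas`` (sampled here if absent, seeded for reproducibility).
    """
    if expr.modality != "expression-linear":
        raise SchemaError("degradation applies to expression-linear matrices")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if model.lambdas is None:
        model.sample_lambdas(expr.features, rng)
    lam = model.lambdas.reindex(expr.features)
    if (lam < 0).any():
        raise ConfigurationError("decay rates must be nonnegative")
    rin = rin.reindex(expr.samples).astype(float)
    deficit = np.maximum(model.rin_ref - rin.to_numpy(), 0.0)  # no boost above ref
    factor = 2.0 ** (-np.outer(lam.to_numpy(), deficit))
    return MixedOmicsMatrix(
        pd.DataFrame(expr.data.to_numpy() * factor, index=expr.features,
                     columns=expr.samples),
        "expression-linear",
    )


# --------------------------------------------------------------------------
# quality flags, CpG annotation, gene models (planted-truth plumbing)


def generate_probe_flags(
    probes: pd.Index, samples: pd.Index, seed: int | np.random.Generator = 0,
    n_control: int = 10, n_nonuniform: int = 5, n_saturated: int = 5,
    n_outlier: int = 5, n_low_detection: int = 10, n_replicate_pairs: int = 10,
) -> tuple[ProbeFlagTable, dict[str, list[str]]]:
    """Plant known flag patterns for the expression filtering rules.

    Returns the flag table plus the planted truth (probe ids per rule) so
    tests can assert exact drop counts.  Planted categories are disjoint.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probes = list(probes)
    need = n_control + n_nonuniform + n_saturated + n_outlier + n_low_detection
    if need > len(probes):
        raise ConfigurationError("not enough probes for requested plantings")
    picked = list(rng.choice(probes, size=need, replace=False))
    truth = {
        "control": picked[:n_control],
        "non_uniform": picked[n_control:n_control + n_nonuniform],
        "saturated": picked[n_control + n_nonuniform:
                            n_control + n_nonuniform + n_saturated],
        "population_outlier": picked[n_control + n_nonuniform + n_saturated:
                                     need - n_low_detection],
        "low_detection": picked[need - n_low_detection:need],
    }
    n_p, n_s = len(probes), len(samples)
    found = np.ones((n_p, n_s), bool)
    possig = np.ones((n_p, n_s), bool)
    nonuni = np.zeros((n_p, n_s), bool)
    sat = np.zeros((n_p, n_s), bool)
    outl = np.zeros((n_p, n_s), bool)
    pos = {p: i for i, p in enumerate(probes)}
    for p in truth["non_uniform"]:
        nonuni[pos[p], rng.integers(n_s)] = True
    for p in truth["saturated"]:
        sat[pos[p], rng.integers(n_s)] = True
    for p in truth["population_outlier"]:
        outl[pos[p], rng.integers(n_s)] = True
    for p in truth["low_detection"]:
        found[pos[p], :] = False   # fails the 50%-found rule in every group
        possig[pos[p], :] = False
    long = pd.DataFrame({
        "probe_id": np.repeat(probes, n_s),
        "sample_id": np.tile(samples, n_p),
        "found": found.ravel(),
        "positive_and_significant": possig.ravel(),
        "non_uniform": nonuni.ravel(),
        "saturated": sat.ravel(),
        "population_outlier": outl.ravel(),
    })
    rep = pd.Series(probes, index=probes, name="replicate_group")
    kept = [p for p in probes if p not in set(picked)]
    for i in range(min(n_replicate_pairs, len(kept) // 2)):
        a, b = kept[2 * i], kept[2 * i + 1]
        rep.loc[b] = a
    info = pd.DataFrame({
        "is_control": [p in set(truth["control"]) for p in probes],
        "replicate_group": rep,
    }, index=pd.Index(probes, name="probe_id"))
    return ProbeFlagTable(long, info), truth


def generate_gene_models(
    n_genes: int = 60, seed: int | np.random.Generator = 0,
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3"),
    body_len: tuple[int, int] = (2000, 20000), spacing: int = 30000,
) -> pd.DataFrame:
    """Lay out synthetic gene bodies on a few chromosomes.

    Output columns: gene_id, chrom, start, end (1-based inclusive, the
    GFF-like input convention), strand.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    per = int(np.ceil(n_genes / len(chroms)))
    g = 0
    for chrom in chroms:
        cursor = 10000
        for _ in range(per):
            if g >= n_genes:
                break
            length = int(rng.integers(*body_len))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(dict(gene_id=f"G{g:04d}", chrom=chrom, start=cursor + 1,
                             end=cursor + length, strand=strand))
            cursor += length + spacing
            g += 1
    return pd.DataFrame(rows)


def generate_cpg_annotation(
    cpgs: pd.Index, samples: pd.Index, seed: int | np.random.Generator = 0,
    genes: pd.DataFrame | None = None,
    n_chrx: int = 20, n_chry: int = 5, n_snp: int = 15,
    n_cross_reactive: int = 15, n_detection_fail: int = 10,
) -> tuple[CpGAnnotation, dict[str, list[str]]]:
    """Plant CpG annotation with known per-rule filter truth.

    Autosomal CpGs are placed inside or just upstream of gene bodies (when
    ``genes`` is given) so region mapping has realistic targets; planted
    filter categories are disjoint.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cpgs = list(cpgs)
    need = n_chrx + n_chry + n_snp + n_cross_reactive + n_detection_fail
    if need > len(cpgs):
        raise ConfigurationError("not enough CpGs for requested plantings")
    picked = list(rng.choice(cpgs, size=need, replace=False))
    truth = {
        "chrX": picked[:n_chrx],
        "chrY": picked[n_chrx:n_chrx + n_chry],
        "snp": picked[n_chrx + n_chry:n_chrx + n_chry + n_snp],
        "cross_reactive": picked[n_chrx + n_chry + n_snp:need - n_detection_fail],
        "detection": picked[need - n_detection_fail:need],
    }
    chrom = pd.Series("chr1", index=cpgs, dtype="object")
    pos = pd.Series(0, index=cpgs, dtype=int)
    sexed = set(truth["chrX"]) | set(truth["chrY"])
    auto = [c for c in cpgs if c not in sexed]
    if genes is not None and len(genes):
        gi = genes.sample(n=len(auto), replace=True, random_state=rng)
        for c, (_, grow) in zip(auto, gi.iterrows()):
            chrom.loc[c] = grow["chrom"]
            lo = max(1, int(grow["start"]) - 1500)
            pos.loc[c] = int(rng.integers(lo, int(grow["end"]) + 1))
    else:
        for c in auto:
            chrom.loc[c] = f"chr{rng.integers(1, 23)}"
            pos.loc[c] = int(rng.integers(1, 10_000_000))
    for c in truth["chrX"]:
        chrom.loc[c], pos.loc[c] = "chrX", int(rng.integers(1, 1_000_000))
    for c in truth["chrY"]:
        chrom.loc[c], pos.loc[c] = "chrY", int(rng.integers(1, 1_000_000))
    info = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "snp_affected": [c in set(truth["snp"]) for c in cpgs],
        "cross_reactive": [c in set(truth["cross_reactive"]) for c in cpgs],
    }, index=pd.Index(cpgs, name="cpg_id"))
    detp = pd.DataFrame(rng.uniform(0, 0.005, (len(cpgs), len(samples))),
                        index=info.index, columns=samples)
    for c in truth["detection"]:
        detp.loc[c, rng.choice(samples)] = 0.02
    return CpGAnnotation(info, detp), truth


def generate_gene_sets(
    gene_ids: list[str], n_sets: int = 15, set_size: tuple[int, int] = (5, 15),
    seed: int | np.random.Generator = 0,
) -> dict[str, list[str]]:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return {
        f"SET_{i:03d}": sorted(rng.choice(
            gene_ids, size=int(rng.integers(*set_size)), replace=False))
        for i in range(n_sets)
    }


# --------------------------------------------------------------------------
# full scenario


@dataclass
class ScenarioConfig:
    """One full synthetic cohort: groups, sizes, noise, degradation."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"asthma": 10, "COPD": 10, "control": 10})
    fractions: FractionModel = field(default_factory=FractionModel.default)
    profiles: ProfileConfig = field(default_factory=ProfileConfig.default)
    degradation: DegradationModel = field(default_factory=DegradationModel.default)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"expression": 25.0, "methylation": 0.02})
    confound_group_preservation: bool = False
    apply_degradation: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        deg = d["degradation"]
        deg.pop("lambdas", None)
        return d


@dataclass
class SimulatedDataset:
    """Everything a pipeline run needs, plus the planted truth."""

    expression: MixedOmicsMatrix            # degraded, linear scale
    expression_clean: MixedOmicsMatrix      # pre-degradation
    methylation: MixedOmicsMatrix
    cell_counts: CellCountTable
    metadata: SampleMetadata
    truth: CellTypeProfileTruth
    lambdas: pd.Series
    clip_counts: dict[str, int]
    config: ScenarioConfig
    seed: int


def simulate_dataset(config: ScenarioConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Generate a complete cohort from one seed, deterministically.

    Preservation is RLT/HOPE 50:50 at random within each group unless
    ``confound_group_preservation`` is set, in which case COPD samples are
    all HOPE-preserved (heavily degraded) and the other groups all RLT —
    the degradation-confounded regime.
    """
    config = config or ScenarioConfig()
    ss = np.random.SeedSequence(seed)
    keys = ("fractions", "profiles", "mix", "rin", "lambdas", "flags", "annot")
    rngs = dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))

    counts = []
    for group, n in config.n_per_group.items():
        counts.append(generate_cell_fractions(group, n, config.fractions,
                                              rngs["fractions"]))
    cell_counts = CellCountTable(pd.concat([c.data for c in counts]))
    groups = pd.Series(
        np.concatenate([[g] * n for g, n in config.n_per_group.items()]),
        index=cell_counts.samples, name="group")

    truth = generate_profiles(config=config.profiles, seed=rngs["profiles"])
    expr_clean, meth, clip_counts = mix(
        truth, cell_counts, config.noise_sd, rngs["mix"], groups)

    pres = pd.Series(index=cell_counts.samples, dtype="object", name="preservation")
    for g in config.n_per_group:
        idx = groups[groups == g].index
        if config.confound_group_preservation:
            pres.loc[idx] = "HOPE" if g == "COPD" else "RLT"
        else:
            pres.loc[idx] = np.where(rngs["rin"].random(len(idx)) < 0.5,
                                     "RLT", "HOPE")
    rin = pd.Series(index=cell_counts.samples, dtype=float, name="rin")
    for route in ("RLT", "HOPE"):
        idx = pres[pres == route].index
        if len(idx):
            rin.loc[idx] = generate_rin(route, len(idx), config.degradation,
                                        rngs["rin"])

    lambdas = config.degradation.sample_lambdas(expr_clean.features,
                                                rngs["lambdas"])
    if config.apply_degradation:
        expr = inject_degradation(expr_clean, rin, config.degradation)
    else:
        expr = MixedOmicsMatrix(expr_clean.data.copy(), "expression-linear")

    metadata = SampleMetadata(pd.DataFrame({
        "group": groups, "rin": rin, "preservation": pres}))

    return SimulatedDataset(
        expression=expr, expression_clean=expr_clean, methylation=meth,
        cell_counts=cell_counts, metadata=metadata, truth=truth,
        lambdas=lambdas, clip_counts=clip_counts, config=config, seed=seed)


# --------------------------------------------------------------------------
# on-disk form


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path,
                  overwrite: bool = False) -> dict[str, Path]:
    """Write the TSV/YAML file set that re-creates the dataset bit-identically."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    dataset.expression.to_tsv(out / "expression.tsv")
    dataset.methylation.to_tsv(out / "methylation.tsv")
    dataset.cell_counts.to_tsv(out / "cell_counts.tsv")
    dataset.metadata.to_tsv(out / "samples.tsv")
    tp = pd.concat({
        "expression": dataset.truth.expression.T,
        "methylation": dataset.truth.methylation.T,
    }, names=["modality", "feature_id"])
    tp.to_csv(out / "truth_profiles.tsv", sep="\t")
    dataset.truth.effect_truth.to_csv(out / "truth_effects.tsv", sep="\t",
                                      index=False)
    dataset.lambdas.to_frame().to_csv(out / "truth_lambdas.tsv", sep="\t",
                                      index_label="feature_id")
    cfg = dataset.config.to_dict()
    cfg["seed"] = dataset.seed
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    for name in ("expression", "methylation", "cell_counts", "samples",
                 "truth_profiles", "truth_effects", "truth_lambdas"):
        paths[name] = out / f"{name}.tsv"
    paths["config"] = out / "config.yaml"
    return paths


def dataset_digest(out_dir: str | Path) -> str:
    """SHA-256 over the written file set (stable across identical runs)."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).glob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
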