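"""End-to-end pipeline: simulate/ingest -> preprocess -> RIN-correct ->
deconvolve -> differential -> regions/enrichment, from a single YAML config,
with a JSON manifest for provenance and bit-identical reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .datatypes import CellCountTable, MixedOmicsMatrix, SampleMetadata
from .deconvolution import BoxBounds, DEFAULT_MAJORS, deconvolve_by_group
from .differential import (
    PAPER_POLICY,
    differential_deconvolved,
    differential_mixed,
)
from .preprocessing import filter_cpgs, quantile_normalize
from .regions import (
    hypergeom_enrich,
    intersect_dmr_deg,
    map_regions,
    merge_dmps,
    read_gene_models,
    write_bed,
)
from .rin_correction import (
    correlation_filter,
    linear_correction,
    pca_scores,
    rin_correlations,
)

STAGES = ("simulate", "preprocess", "rincorrect", "deconvolve",
          "differential", "regions")


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 17
    out_dir: str = "run_out"
    scenario: dict = field(default_factory=dict)
    comparison: tuple[str, str] = ("asthma", "control")
    majors: dict | None = None
    excluded: tuple[str, ...] = ("MO",)
    bounds_mode: str = "auto"
    rin_mode: str = "linear"              # linear | filter | none
    r_threshold: float | None = None
    rin_covariates: bool = False
    min_rin: float = 3.0
    policy: str = "paper"
    max_gap: int = 1000
    min_cpgs: int = 2
    min_overlap: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "comparison" in raw:
            raw["comparison"] = tuple(raw["comparison"])
        if "excluded" in raw:
            raw["excluded"] = tuple(raw["excluded"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def validate_inputs(
    matrix: MixedOmicsMatrix, counts: CellCountTable, metadata: SampleMetadata,
    min_rin: float = 3.0,
) -> list[dict]:
    """Report-only consistency checks across matrix, counts and metadata."""
    violations = []
    for s in matrix.samples:
        if s not in counts.samples:
            violations.append(dict(rule="counts_cover_samples", sample=str(s)))
        if s not in metadata.samples:
            violations.append(dict(rule="metadata_cover_samples", sample=str(s)))
    sums = counts.data.sum(axis=1)
    for s, v in sums.items():
        if abs(v - 100.0) > 1e-4:
            violations.append(dict(rule="fractions_sum_100", sample=str(s),
                                   value=float(v)))
    if "rin" in metadata.data.columns:
        for s, v in metadata.rin.items():
            if v < min_rin:
                violations.append(dict(rule="min_rin", sample=str(s),
                                       value=float(v)))
    return violations


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(), "seed": config.seed, "stages": [],
        "files": {},
    }

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})

    try:
        # --- 1. simulate -------------------------------------------------
        scen = simulate.ScenarioConfig(**config.scenario) if config.scenario \
            else simulate.ScenarioConfig()
        ds = simulate.simulate_dataset(scen, seed=config.seed)
        sim_dir = out / "simulated"
        simulate.write_dataset(ds, sim_dir, overwrite=True)
        violations = validate_inputs(ds.expression, ds.cell_counts,
                                     ds.metadata, config.min_rin)
        record("simulate", n_samples=len(ds.metadata.samples),
               n_expr_features=len(ds.expression.features),
               n_meth_features=len(ds.methylation.features),
               n_validation_violations=len(violations))

        # --- 2. preprocess ----------------------------------------------
        rin_ok = ds.metadata.rin_pass_mask()
        keep_samples = rin_ok[rin_ok].index
        expr = MixedOmicsMatrix(ds.expression.data[keep_samples],
                                "expression-linear")
        expr_qn = quantile_normalize(expr)
        ss = np.random.SeedSequence([config.seed, 1])
        ann, _ = simulate.generate_cpg_annotation(
            ds.methylation.features, ds.methylation.samples,
            seed=np.random.default_rng(ss),
            genes=simulate.generate_gene_models(
                seed=np.random.default_rng(np.random.SeedSequence(
                    [config.seed, 2]))))
        keep_cpgs, cpg_drops = filter_cpgs(ds.methylation, ann)
        meth = MixedOmicsMatrix(ds.methylation.data.loc[keep_cpgs[keep_cpgs].index],
                                "methylation-beta")
        expr_qn.to_tsv(out / "expression_normalized.tsv")
        meth.to_tsv(out / "methylation_filtered.tsv")
        record("preprocess", n_samples_rin_pass=len(keep_samples),
               n_cpgs_kept=int(keep_cpgs.sum()), cpg_drops=cpg_drops)

        # --- 3. RIN correction -------------------------------------------
        rin = ds.metadata.rin.loc[keep_samples]
        expr_log2 = expr_qn.to_log2()
        spectrum = rin_correlations(expr_log2, rin)
        if config.rin_mode == "linear":
            cov = ds.metadata.groups.loc[keep_samples] if config.rin_covariates \
                else None
            corrected_log2, slopes = linear_correction(expr_log2, rin, cov)
            slopes.to_frame().to_csv(out / "rin_slopes.tsv", sep="\t")
        elif config.rin_mode == "filter":
            if config.r_threshold is None:
                raise ValidationError(
                    "rin_mode 'filter' requires an explicit r_threshold")
            corrected_log2, _removed = correlation_filter(
                expr_log2, rin, config.r_threshold)
        elif config.rin_mode == "none":
            corrected_log2 = expr_log2
        else:
            raise ValidationError(f"unknown rin_mode {config.rin_mode!r}")
        scores, varexp = pca_scores(corrected_log2, n_components=2)
        scores.to_csv(out / "pca_scores.tsv", sep="\t")
        corrected_log2.to_tsv(out / "expression_corrected_log2.tsv")
        record("rincorrect", mode=config.rin_mode,
               frac_positive=spectrum.frac_positive,
               frac_negative=spectrum.frac_negative,
               pc1_percent_variance=float(varexp.iloc[0]))

        # --- 4. deconvolution --------------------------------------------
        groups = ds.metadata.groups
        majors = {g: tuple(v) for g, v in (config.majors or DEFAULT_MAJORS).items()}
        expr_lin = corrected_log2.to_linear()
        bounds_e = BoxBounds.for_matrix(expr_lin) if config.bounds_mode == "auto" \
            else BoxBounds(*config.bounds_mode)
        est_expr = deconvolve_by_group(
            expr_lin, CellCountTable(ds.cell_counts.data.loc[keep_samples]),
            groups.loc[keep_samples], majors, config.excluded, bounds_e)
        est_meth = deconvolve_by_group(
            meth, ds.cell_counts, groups, majors, config.excluded,
            BoxBounds.methylation())
        for g, est in est_meth.items():
            est.estimates.T.to_csv(out / f"estimates_methylation_{g}.tsv",
                                   sep="\t")
            est.se.T.to_csv(out / f"se_methylation_{g}.tsv", sep="\t")
        for g, est in est_expr.items():
            est.estimates.T.to_csv(out / f"estimates_expression_{g}.tsv",
                                   sep="\t")
        record("deconvolve", groups=sorted(est_meth),
               majors={g: list(m) for g, m in majors.items()})

        # --- 5. differential ----------------------------------------------
        g1, g2 = config.comparison
        mixed_expr = differential_mixed(corrected_log2, groups, g1, g2)
        mixed_meth = differential_mixed(meth, groups, g1, g2)
        shared_ct = [c for c in majors.get(g1, ()) if c in majors.get(g2, ())]
        dec_meth = {ct: differential_deconvolved(
            est_meth[g1], est_meth[g2], ct, "methylation")
            for ct in shared_ct}
        mixed_expr.to_tsv(out / "differential_mixed_expression.tsv")
        mixed_meth.to_tsv(out / "differential_mixed_methylation.tsv")
        for ct, t in dec_meth.items():
            t.to_tsv(out / f"differential_deconvolved_methylation_{ct}.tsv")
        record("differential",
               mixed_expression=mixed_expr.summary,
               mixed_methylation=mixed_meth.summary,
               deconvolved_methylation={ct: t.summary
                                        for ct, t in dec_meth.items()})

        # --- 6. regions + enrichment --------------------------------------
        genes_tab = simulate.generate_gene_models(
            seed=np.random.default_rng(np.random.SeedSequence([config.seed, 2])))
        genes = read_gene_models(genes_tab)
        sig = mixed_meth.data[mixed_meth.data["significant"]]
        dmp_tab = pd.DataFrame({
            "cpg_id": sig.index,
            "chrom": ann.info.loc[sig.index, "chrom"].to_numpy(),
            "pos": ann.info.loc[sig.index, "pos"].to_numpy(),
            "delta_beta": sig["effect"].to_numpy(),
        })
        dmrs = merge_dmps(dmp_tab, config.max_gap, config.min_cpgs)
        mapping = map_regions(dmrs, genes, config.min_overlap)
        write_bed(dmrs, out / "dmrs.bed")
        mapping.to_csv(out / "dmr_gene_mapping.tsv", sep="\t", index=False)
        gene_ids = [g.gene_id for g in genes]
        sets = simulate.generate_gene_sets(
            gene_ids, seed=np.random.default_rng(
                np.random.SeedSequence([config.seed, 3])))
        dmr_genes = set(mapping["gene_id"]) if len(mapping) else set()
        enrich = hypergeom_enrich(dmr_genes, sets, set(gene_ids))
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        overlap = intersect_dmr_deg(
            dmr_genes, set())   # DEG-gene mapping requires a probe->gene map
        record("regions", n_dmrs=len(dmrs), n_mapped=len(mapping),
               n_enriched=int(enrich["enriched"].sum()) if len(enrich) else 0,
               n_dmr_deg_overlap=overlap.attrs["n_overlap"])

    except Exception as exc:
        record("FAILED", error=f"{type(exc).__name__}: {exc}")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        raise

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _file_digest(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
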