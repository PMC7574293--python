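"""DMP merging into regions, gene mapping and gene-set enrichment.

Internally every interval is 0-based half-open (the BED convention);
GFF-like 1-based-inclusive gene tables are converted at the boundary.
Significant CpGs are merged into differentially methylated regions by a
transparent distance rule (consecutive significant CpGs within ``max_gap``
base pairs, at least ``min_cpgs`` CpGs, and at least one CpG with
|delta beta| above 0.1).  Regions map to a gene's promoter (1500 bp
upstream of the TSS, strand-aware, clipped at the chromosome start) or gene
body when the overlap reaches ``min_overlap`` (default 200 bp).  Gene-set
overrepresentation uses the upper-tail hypergeometric test against a custom
background universe with BH q values across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SchemaError
from .differential import bh_adjust

PROMOTER_BP = 1500
MIN_OVERLAP_BP = 200


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise SchemaError("chromosome must be non-empty")
        if not self.start < self.end:
            raise SchemaError(f"require start < end ({self.start}, {self.end})")

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """Gene body plus the derived promoter interval.

    The promoter covers up to 1500 bp immediately upstream of the TSS on
    the strand-appropriate side, clipped at the chromosome start.
    """

    gene_id: str
    body: GenomicInterval
    strand: str

    @property
    def promoter(self) -> GenomicInterval:
        if self.strand == "-":
            return GenomicInterval(self.body.chrom, self.body.end,
                                   self.body.end + PROMOTER_BP, self.strand)
        start = max(0, self.body.start - PROMOTER_BP)
        if start == self.body.start:      # gene at position 0: empty upstream
            start = max(0, self.body.start - 1)
        return GenomicInterval(self.body.chrom, start, self.body.start,
                               self.strand)


def read_gene_models(table: pd.DataFrame | str | Path) -> list[GeneModel]:
    """Build gene models from a GFF-like table (1-based inclusive coords)."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    for _, r in table.iterrows():
        body = GenomicInterval(r["chrom"], int(r["start"]) - 1, int(r["end"]),
                               r["strand"])
        genes.append(GeneModel(r["gene_id"], body, r["strand"]))
    return genes


def merge_dmps(
    dmps: pd.DataFrame, max_gap: int = 1000, min_cpgs: int = 2,
    min_peak_delta: float = 0.1,
) -> pd.DataFrame:
    """Merge significant CpGs into regions by a distance rule.

    ``dmps`` columns: ``cpg_id``, ``chrom``, ``pos`` (1-based manifest
    coordinate), ``delta_beta``.  Consecutive CpGs on one chromosome within
    ``max_gap`` bp are merged; a region is retained only with at least
    ``min_cpgs`` CpGs and at least one CpG with ``|delta beta|`` above
    ``min_peak_delta``.  Output intervals are 0-based half-open spanning the
    first through last CpG.
    """
    required = {"cpg_id", "chrom", "pos", "delta_beta"}
    missing = required - set(dmps.columns)
    if missing:
        raise SchemaError(f"DMP table missing columns: {sorted(missing)}")
    if dmps.empty:
        return pd.DataFrame(columns=["region_id", "chrom", "start", "end",
                                     "n_cpgs", "max_abs_delta", "mean_delta",
                                     "cpg_ids"])
    df = dmps.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    regions = []
    for chrom, sub in df.groupby("chrom", sort=True):
        block = [sub.iloc[0]]
        for _, row in sub.iloc[1:].iterrows():
            if row["pos"] - block[-1]["pos"] <= max_gap:
                block.append(row)
            else:
                regions.append((chrom, block))
                block = [row]
        regions.append((chrom, block))
    rows = []
    for chrom, block in regions:
        deltas = np.array([b["delta_beta"] for b in block], float)
        if len(block) < min_cpgs or np.abs(deltas).max() <= min_peak_delta:
            continue
        positions = [int(b["pos"]) for b in block]
        rows.append(dict(
            chrom=chrom,
            start=positions[0],                  # span: first to last CpG + 1
            end=positions[-1] + 1,
            n_cpgs=len(block),
            max_abs_delta=float(np.abs(deltas).max()),
            mean_delta=float(deltas.mean()),
            cpg_ids=",".join(b["cpg_id"] for b in block),
        ))
    cols = ["chrom", "start", "end", "n_cpgs", "max_abs_delta", "mean_delta",
            "cpg_ids"]
    out = pd.DataFrame(rows, columns=cols)
    out.insert(0, "region_id",
               [f"DMR_{c}_{s}" for c, s in zip(out["chrom"], out["start"])])
    return out


def map_regions(
    regions: pd.DataFrame, genes: list[GeneModel],
    min_overlap: int = MIN_OVERLAP_BP,
) -> pd.DataFrame:
    """Assign regions to gene promoters/bodies by bp overlap.

    A region maps to each feature (promoter or body) it overlaps by at
    least ``min_overlap`` bp; one region may map to several genes.
    """
    rows = []
    for _, r in regions.iterrows():
        iv = GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
        for gene in genes:
            for feature, target in (("promoter", gene.promoter),
                                    ("body", gene.body)):
                ov = iv.overlap(target)
                if ov >= min_overlap:
                    rows.append(dict(region_id=r.get("region_id", ""),
                                     gene_id=gene.gene_id, feature=feature,
                                     overlap_bp=ov))
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "feature",
                                       "overlap_bp"])


def intersect_dmr_deg(dmr_genes: set[str] | list[str],
                      degs: set[str] | list[str]) -> pd.DataFrame:
    """Overlap between DMR-associated genes and differentially expressed genes."""
    a, b = set(dmr_genes), set(degs)
    shared = sorted(a & b)
    out = pd.DataFrame({"gene_id": shared})
    out.attrs["n_dmr_genes"] = len(a)
    out.attrs["n_degs"] = len(b)
    out.attrs["n_overlap"] = len(shared)
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def hypergeom_enrich(
    hits: set[str] | list[str],
    gene_sets: dict[str, list[str]],
    universe: set[str] | list[str],
    p_cutoff: float = 0.1,
    q_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation against a custom universe.

    Per set: overlap ``k`` between hits and the set, set size ``K`` (within
    the universe), ``n`` hits, ``N`` universe genes;
    ``p = P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``; BH q across sets.
    Hits and set members outside the universe are pruned (counted in attrs).
    The returned table flags sets passing ``p < p_cutoff and q < q_cutoff``.
    """
    universe = set(universe)
    if not universe:
        raise SchemaError("empty background universe")
    hits = set(hits)
    pruned_hits = hits - universe
    hits &= universe
    n = len(hits)
    N = len(universe)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        K = len(inset)
        k = len(inset & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(dict(gene_set=name, k=k, K=K, n=n, N=N, p=p))
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["enriched"] = (out["p"] < p_cutoff) & (out["q"] < q_cutoff)
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    out.attrs["n_pruned_hits"] = len(pruned_hits)
    return out


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    extra = [c for c in ("region_id",) if c in regions.columns]
    regions[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chrom", "start", "end"] + (
        ["region_id"] if df.shape[1] > 3 else [])[: df.shape[1] - 3]
    return df
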