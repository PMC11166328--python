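"""Replicate intersection into high-confidence target sets, and
wild-type-versus-mutant comparisons (shared/unique genes and sites,
editing-efficiency ratios, replicate correlations).

A high-confidence target site must pass the coverage and fraction
thresholds independently in every biological replicate; its gene is a
target gene. Comparisons between genotypes are made at both granularities:
exact site coordinates for efficiency ratios, gene identity for target
overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import EditSite
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

SiteKey = tuple[str, int, str]


@dataclass
class SiteRecord:
    """One replicate-intersected site with per-replicate measurements."""

    contig: str
    pos: int
    strand: str
    gene_id: str | None
    fractions: list[float]
    coverages: list[int]
    edited: list[int]

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.pos, self.strand)

    def combined_fraction(self, combiner: str = "mean") -> float:
        if combiner == "mean":
            return float(np.mean(self.fractions))
        if combiner == "min":
            return float(np.min(self.fractions))
        if combiner == "pooled":
            return float(sum(self.edited) / sum(self.coverages))
        raise ConfigError(f"unknown combiner {combiner!r}")


@dataclass
class TargetSet:
    """Replicate-intersected, gene-level target set for one genotype."""

    genotype: str
    sites: dict[SiteKey, SiteRecord] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return {r.gene_id for r in self.sites.values() if r.gene_id is not None}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in sorted(self.sites.values(), key=lambda r: r.key):
            row = {
                "contig": r.contig,
                "pos": r.pos,
                "pos_1based": r.pos + 1,
                "strand": r.strand,
                "gene_id": r.gene_id,
                "mean_fraction": r.combined_fraction("mean"),
            }
            for i, (f, c) in enumerate(zip(r.fractions, r.coverages), start=1):
                row[f"fraction_rep{i}"] = f
                row[f"coverage_rep{i}"] = c
            rows.append(row)
        return pd.DataFrame(rows)


def intersect_replicates(
    per_replicate_sites: Sequence[Iterable[EditSite]],
    genotype: str = "",
    allow_single: bool = False,
) -> TargetSet:
    """Keep only sites called above threshold in every replicate.

    Sites are keyed by exact (contig, position, strand); each replicate's
    edit fraction is retained. Order-invariant and idempotent.
    """
    site_maps = [{s.key: s for s in reps} for reps in per_replicate_sites]
    if len(site_maps) < 2 and not allow_single:
        raise DataError(
            "replicate intersection needs >= 2 replicates "
            "(pass allow_single=True to override)"
        )
    if not site_maps:
        return TargetSet(genotype=genotype)
    common = set(site_maps[0])
    for m in site_maps[1:]:
        common &= set(m)
    ts = TargetSet(genotype=genotype)
    for key in sorted(common):
        recs = [m[key] for m in site_maps]
        gene_ids = {r.gene_id for r in recs}
        ts.sites[key] = SiteRecord(
            contig=key[0],
            pos=key[1],
            strand=key[2],
            gene_id=recs[0].gene_id if len(gene_ids) == 1 else sorted(
                g for g in gene_ids if g
            )[0],
            fractions=[r.fraction for r in recs],
            coverages=[r.coverage for r in recs],
            edited=[r.edited_count for r in recs],
        )
    return ts


@dataclass
class ComparisonResult:
    """Shared/unique partition of two genotypes' targets, genes and sites."""

    genotype_a: str
    genotype_b: str
    shared_genes: set[str]
    unique_genes_a: set[str]
    unique_genes_b: set[str]
    shared_sites: set[SiteKey]
    unique_sites_a: set[SiteKey]
    unique_sites_b: set[SiteKey]

    def counts(self) -> dict:
        return {
            "genotype_a": self.genotype_a,
            "genotype_b": self.genotype_b,
            "genes_a": len(self.shared_genes) + len(self.unique_genes_a),
            "genes_b": len(self.shared_genes) + len(self.unique_genes_b),
            "shared_genes": len(self.shared_genes),
            "unique_genes_a": len(self.unique_genes_a),
            "unique_genes_b": len(self.unique_genes_b),
            "sites_a": len(self.shared_sites) + len(self.unique_sites_a),
            "sites_b": len(self.shared_sites) + len(self.unique_sites_b),
            "shared_sites": len(self.shared_sites),
            "unique_sites_a": len(self.unique_sites_a),
            "unique_sites_b": len(self.unique_sites_b),
        }


def compare_targets(set_a: TargetSet, set_b: TargetSet) -> ComparisonResult:
    """Partition two target sets into shared and unique genes and sites."""
    ga, gb = set_a.genes, set_b.genes
    ka, kb = set(set_a.sites), set(set_b.sites)
    return ComparisonResult(
        genotype_a=set_a.genotype,
        genotype_b=set_b.genotype,
        shared_genes=ga & gb,
        unique_genes_a=ga - gb,
        unique_genes_b=gb - ga,
        shared_sites=ka & kb,
        unique_sites_a=ka - kb,
        unique_sites_b=kb - ka,
    )


def efficiency_ratios(
    set_a: TargetSet,
    set_b: TargetSet,
    combiner: str = "mean",
) -> tuple[pd.DataFrame, dict]:
    """Per-shared-site editing-efficiency ratio, B relative to A.

    ratio = (replicate-combined fraction in B) / (same in A). Shared sites
    have passed the fraction threshold in both genotypes, so the
    denominator is never zero. Summary gives the median ratio and the
    fraction of sites with ratio < 1 (lower efficiency in B).
    """
    shared = sorted(set(set_a.sites) & set(set_b.sites))
    rows = []
    for key in shared:
        fa = set_a.sites[key].combined_fraction(combiner)
        fb = set_b.sites[key].combined_fraction(combiner)
        rows.append(
            {
                "contig": key[0],
                "pos": key[1],
                "strand": key[2],
                "gene_id": set_a.sites[key].gene_id,
                f"fraction_{set_a.genotype or 'A'}": fa,
                f"fraction_{set_b.genotype or 'B'}": fb,
                "ratio": fb / fa,
            }
        )
    df = pd.DataFrame(rows)
    ratios = df["ratio"].to_numpy() if len(df) else np.array([])
    summary = {
        "n_shared_sites": int(len(ratios)),
        "median_ratio": float(np.median(ratios)) if len(ratios) else float("nan"),
        "fraction_below_1": float(np.mean(ratios < 1)) if len(ratios) else float("nan"),
    }
    return df, summary


def replicate_correlation(
    sites_a: Iterable[EditSite],
    sites_b: Iterable[EditSite],
) -> tuple[float, int]:
    """Pearson r of per-site edit fractions between two samples.

    Taken over the union of the two samples' called sites; a site absent
    from one sample contributes fraction 0 there (explicit zero-fill, as
    needed when the two samples' site sets differ). Returns (r, n_union);
    r is NaN with fewer than 2 union sites or zero variance.
    """
    fa = {s.key: s.fraction for s in sites_a}
    fb = {s.key: s.fraction for s in sites_b}
    keys = sorted(set(fa) | set(fb))
    n = len(keys)
    if n < 2:
        warnings.warn("fewer than 2 union sites; correlation undefined")
        return float("nan"), n
    va = np.array([fa.get(k, 0.0) for k in keys])
    vb = np.array([fb.get(k, 0.0) for k in keys])
    if not fa or not fb:
        warnings.warn("one sample has no called sites; correlation over zero-fill")
    if va.std() == 0 or vb.std() == 0:
        return float("nan"), n
    r, _ = stats.pearsonr(va, vb)
    return float(r), n
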