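"""Metagene localization of edit sites (5'UTR / CDS / 3'UTR) and
expression diagnostics (FPKM, target-expression spectrum).

Edits are classified against each gene's canonical transcript (longest
CDS) and given a relative position in transcript coordinates, 0 at the
5' end and 1 at the 3' end, so distributions are comparable between
genotypes regardless of transcript length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .calling import EditSite
from .errors import DataError
from .io import Annotation
from .targets import TargetSet

log = logging.getLogger(__name__)

FEATURE_LABELS = {"utr5": "5'UTR", "cds": "CDS", "utr3": "3'UTR"}


def assign_edit_to_feature(
    site: EditSite, annotation: Annotation
) -> tuple[str, float]:
    """Classify one edit site against its gene's canonical transcript.

    Returns (feature class, relative position in [0, 1)). Sites on
    CDS-only transcripts or outside the transcript's exons classify as
    "unresolvable" with position NaN.
    """
    if site.gene_id is None or site.gene_id not in annotation.canonical:
        return "unresolvable", float("nan")
    t = annotation.canonical[site.gene_id]
    tpos = t.genomic_to_transcript(site.pos)
    if tpos is None:
        return "unresolvable", float("nan")
    rel = tpos / t.transcript_length
    if t.cds_only:
        return "unresolvable", rel
    feat = t.feature_at(site.pos)
    if feat is None:
        return "unresolvable", rel
    return feat, rel


@dataclass
class MetageneDistribution:
    """Counts/fractions of edits per feature class + relative positions."""

    counts: dict[str, int]
    fractions: dict[str, float]  # over resolvable classes only
    relative_positions: np.ndarray
    n_unresolvable: int

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        pos = self.relative_positions[~np.isnan(self.relative_positions)]
        return np.histogram(pos, bins=bins, range=(0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": ["utr5", "cds", "utr3"],
                "count": [self.counts.get(f, 0) for f in ("utr5", "cds", "utr3")],
                "fraction": [
                    self.fractions.get(f, 0.0) for f in ("utr5", "cds", "utr3")
                ],
            }
        )


def metagene_distribution(
    sites: TargetSet | Iterable[EditSite],
    annotation: Annotation,
) -> MetageneDistribution:
    """Aggregate feature classification over a target set's edit sites."""
    if isinstance(sites, TargetSet):
        site_list = [
            EditSite(r.contig, r.pos, r.strand, max(r.coverages), max(r.edited),
                     gene_id=r.gene_id)
            for r in sites.sites.values()
        ]
    else:
        site_list = list(sites)
    counts = {"utr5": 0, "cds": 0, "utr3": 0}
    rels = []
    n_unres = 0
    for s in site_list:
        feat, rel = assign_edit_to_feature(s, annotation)
        if feat == "unresolvable":
            n_unres += 1
            continue
        counts[feat] += 1
        rels.append(rel)
    n_resolved = sum(counts.values())
    if n_resolved == 0:
        raise DataError("no edit site could be assigned to a transcript feature")
    if n_unres:
        log.info("%d sites unresolvable for metagene assignment", n_unres)
    fractions = {f: c / n_resolved for f, c in counts.items()}
    return MetageneDistribution(
        counts=counts,
        fractions=fractions,
        relative_positions=np.array(rels, dtype=float),
        n_unresolvable=n_unres,
    )


def feature_length_shares(annotation: Annotation) -> dict[str, float]:
    """Genome-wide share of transcript length per feature class
    (canonical transcripts; the null for uniformly placed edits)."""
    tot = {"utr5": 0, "cds": 0, "utr3": 0}
    for t in annotation.canonical.values():
        if t.cds_only:
            continue
        tot["utr5"] += sum(e - s for s, e in t.utr5)
        tot["cds"] += t.cds_length
        tot["utr3"] += sum(e - s for s, e in t.utr3)
    total = sum(tot.values())
    return {f: v / total for f, v in tot.items()}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def compute_fpkm(reads, annotation: Annotation) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    One fragment per mapped read record (single-end convention). A
    fragment is assigned to a gene when its midpoint falls inside exactly
    one gene span; midpoints in zero or multiple gene spans stay
    unassigned. Gene length is the union-exon length.

    FPKM = fragments x 10^9 / (gene length x total mapped fragments),
    where the total counts every filtered read, assigned or not.
    """
    trees: dict[str, IntervalTree] = {}
    for g, ts in annotation.by_gene.items():
        contig = ts[0].contig
        start = min(t.span[0] for t in ts)
        end = max(t.span[1] for t in ts)
        trees.setdefault(contig, IntervalTree()).addi(start, end, g)

    counts: dict[str, int] = {g: 0 for g in annotation.by_gene}
    total = 0
    unassigned = 0
    for rec in reads:
        total += 1
        tree = trees.get(rec.reference_name)
        if tree is None:
            unassigned += 1
            continue
        mid = (rec.reference_start + rec.reference_end) // 2
        hits = tree[mid]
        if len(hits) != 1:
            unassigned += 1
            continue
        counts[next(iter(hits)).data] += 1
    if total == 0:
        raise DataError("zero mapped fragments; cannot normalize")

    lengths = annotation.gene_lengths()
    genes = sorted(counts)
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "fragments": [counts[g] for g in genes],
            "length": [lengths[g] for g in genes],
        }
    )
    df["fpkm"] = df["fragments"] * 1e9 / (df["length"] * total)
    df.attrs["total_fragments"] = total
    df.attrs["unassigned_fragments"] = unassigned
    return df


def target_expression_profile(
    target_genes: Iterable[str], expression: pd.DataFrame
) -> dict:
    """Where do the targets sit in the expression spectrum?

    Compares target-gene FPKM against all other genes with a two-sided
    Mann-Whitney rank-sum test (descriptive: a large p is consistent with
    targets spread across the spectrum rather than biased to high
    expression). Returns summary statistics; empty target set gives an
    empty summary with a warning.
    """
    targets = set(target_genes)
    if not targets:
        warnings.warn("empty target set; no expression profile computed")
        return {"n_targets": 0}
    is_t = expression["gene_id"].isin(targets)
    t_fpkm = expression.loc[is_t, "fpkm"].to_numpy()
    o_fpkm = expression.loc[~is_t, "fpkm"].to_numpy()
    out = {
        "n_targets": int(is_t.sum()),
        "n_other": int((~is_t).sum()),
        "target_median_fpkm": float(np.median(t_fpkm)) if len(t_fpkm) else float("nan"),
        "other_median_fpkm": float(np.median(o_fpkm)) if len(o_fpkm) else float("nan"),
    }
    if len(t_fpkm) and len(o_fpkm):
        u, p = stats.mannwhitneyu(t_fpkm, o_fpkm, alternative="two-sided")
        out["ranksum_p"] = float(p)
    return out
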