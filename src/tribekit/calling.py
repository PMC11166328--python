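"""Per-position pileup and thresholded A-to-G edit-site calling.

ADAR editing converts adenosine to inosine, which sequencers read as G.
A candidate site is therefore a genomic A->G mismatch column on plus-strand
genes or a T->C column on minus-strand genes, reported on the annotated
sense strand. A site is called when its coverage and edit fraction both
reach their thresholds (defaults: >= 20 reads and >= 15% edited reads,
applied per replicate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

from .errors import ConfigError, DataError
from .io import Annotation

log = logging.getLogger(__name__)

BASES = "ACGTN"
_LUT = np.full(256, 4, dtype=np.uint8)  # everything unknown counts as N
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


@dataclass
class PileupColumn:
    """One covered reference position with per-base read counts.

    ``coverage`` counts A/C/G/T only; N bases are excluded.
    """

    contig: str
    pos: int
    ref: str
    counts: tuple[int, int, int, int, int]  # A, C, G, T, N

    @property
    def coverage(self) -> int:
        return sum(self.counts[:4])


@dataclass(frozen=True)
class EditSite:
    """A called edit site, reported on the annotated transcript's strand."""

    contig: str
    pos: int  # 0-based genomic
    strand: str
    coverage: int
    edited_count: int
    gene_id: str | None = None
    ref_base: str = "A"  # sense-strand reference base

    @property
    def fraction(self) -> float:
        return self.edited_count / self.coverage

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.strand)


@dataclass
class EditCallingConfig:
    """Thresholds and options for edit-site calling.

    c_min: minimum read coverage at the site (default 20).
    f_min: minimum edited-read fraction (default 0.15).
    inclusive: whether the thresholds are >= (default) or strictly >.
    strand_mode: how site strand is resolved; only "annotation" is supported.
    blacklist: (contig, 0-based position) pairs never reported (e.g. SNPs).
    """

    c_min: int = 20
    f_min: float = 0.15
    inclusive: bool = True
    strand_mode: str = "annotation"
    blacklist: frozenset = field(default_factory=frozenset)

    def validate(self) -> None:
        if self.c_min < 1:
            raise ConfigError(f"c_min must be >= 1, got {self.c_min}")
        if not 0.0 < self.f_min <= 1.0:
            raise ConfigError(f"f_min must be in (0, 1], got {self.f_min}")
        if self.strand_mode != "annotation":
            raise NotImplementedError(
                f"strand_mode {self.strand_mode!r}; only 'annotation' is supported"
            )


class Pileup:
    """Base counts per reference position, one (5, L) array per contig."""

    def __init__(self, reference: dict[str, str]):
        self.reference = reference
        self.counts: dict[str, np.ndarray] = {}
        self._ref_idx: dict[str, np.ndarray] = {}

    def _arr(self, contig: str) -> np.ndarray:
        if contig not in self.counts:
            if contig not in self.reference:
                raise DataError(f"contig {contig!r} absent from reference")
            L = len(self.reference[contig])
            self.counts[contig] = np.zeros((5, L), dtype=np.int64)
        return self.counts[contig]

    def ref_index(self, contig: str) -> np.ndarray:
        if contig not in self._ref_idx:
            self._ref_idx[contig] = _LUT[
                np.frombuffer(self.reference[contig].encode(), dtype=np.uint8)
            ]
        return self._ref_idx[contig]

    def add_read(self, rec: pysam.AlignedSegment) -> None:
        contig = rec.reference_name
        arr = self._arr(contig)
        seq = rec.query_sequence
        if seq is None:
            return
        bidx = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        cig = rec.cigartuples
        if cig is not None and len(cig) == 1 and cig[0][0] in (0, 7, 8):
            start = rec.reference_start
            if start + len(seq) > arr.shape[1]:
                raise DataError(
                    f"read {rec.query_name} extends past end of {contig}"
                )
            pos = np.arange(start, start + len(seq))
        else:  # gapped/clipped alignments: walk aligned pairs
            pairs = [
                (q, r) for q, r in rec.get_aligned_pairs(matches_only=True)
            ]
            if not pairs:
                return
            q, r = map(np.asarray, zip(*pairs))
            if r.max() >= arr.shape[1]:
                raise DataError(
                    f"read {rec.query_name} extends past end of {contig}"
                )
            bidx = bidx[q]
            pos = r
        np.add.at(arr, (bidx, pos), 1)

    def columns(self) -> Iterator[PileupColumn]:
        """Yield one column per covered position, in genomic order."""
        for contig in self.counts:
            arr = self.counts[contig]
            cov = arr.sum(axis=0)
            ref = self.reference[contig]
            for p in np.nonzero(cov)[0]:
                yield PileupColumn(
                    contig, int(p), ref[p], tuple(int(x) for x in arr[:, p])
                )


def build_pileup(
    reads: Iterable[pysam.AlignedSegment], reference: dict[str, str]
) -> Pileup:
    """Tally per-position base counts from (already filtered) reads."""
    pileup = Pileup(reference)
    for rec in reads:
        pileup.add_read(rec)
    return pileup


def call_edit_sites(
    pileup: Pileup,
    annotation: Annotation,
    config: EditCallingConfig | None = None,
) -> list[EditSite]:
    """Emit A->G edit sites passing the coverage and fraction thresholds.

    Strand comes from the annotation: an A->G column inside a plus-strand
    gene, or a T->C column inside a minus-strand gene, is an edit on that
    gene's sense strand. Columns passing thresholds but outside any
    annotated transcript are dropped and counted in a log line. N bases do
    not count toward coverage.
    """
    config = config or EditCallingConfig()
    config.validate()

    def _passes(cov: np.ndarray, edited: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov > 0, edited / np.maximum(cov, 1), 0.0)
        if config.inclusive:
            return (cov >= config.c_min) & (frac >= config.f_min)
        return (cov > config.c_min) & (frac > config.f_min)

    sites: list[EditSite] = []
    n_outside = 0
    for contig in sorted(pileup.counts):
        arr = pileup.counts[contig]
        L = arr.shape[1]
        cov = arr[:4].sum(axis=0)
        ref = pileup.ref_index(contig)
        plus_idx, minus_idx, genes = annotation.strand_gene_index(contig, L)

        # plus-strand genes: genomic A with G mismatches
        cand_plus = (ref == 0) & _passes(cov, arr[2])
        # minus-strand genes: genomic T with C mismatches (sense A->G)
        cand_minus = (ref == 3) & _passes(cov, arr[1])

        n_outside += int((cand_plus & (plus_idx < 0)).sum())
        n_outside += int((cand_minus & (minus_idx < 0)).sum())

        for pos in np.nonzero(cand_plus & (plus_idx >= 0))[0]:
            p = int(pos)
            if (contig, p) in config.blacklist:
                continue
            sites.append(
                EditSite(
                    contig, p, "+", int(cov[p]), int(arr[2, p]),
                    gene_id=genes[plus_idx[p]],
                )
            )
        for pos in np.nonzero(cand_minus & (minus_idx >= 0))[0]:
            p = int(pos)
            if (contig, p) in config.blacklist:
                continue
            sites.append(
                EditSite(
                    contig, p, "-", int(cov[p]), int(arr[1, p]),
                    gene_id=genes[minus_idx[p]],
                )
            )
    if n_outside:
        log.info("%d threshold-passing columns outside annotated transcripts", n_outside)
    sites.sort(key=lambda s: s.key)
    return sites


def subtract_background(
    sites: Iterable[EditSite], background: Iterable[EditSite]
) -> list[EditSite]:
    """Drop sites present in a background set (control sample or SNP list)."""
    bg = {s.key for s in background}
    return [s for s in sites if s.key not in bg]


def sites_to_frame(sites: Iterable[EditSite]):
    """Site table with 1-based positions for human-readable TSV output."""
    import pandas as pd

    rows = [
        {
            "contig": s.contig,
            "pos": s.pos,
            "pos_1based": s.pos + 1,
            "strand": s.strand,
            "ref": s.ref_base,
            "coverage": s.coverage,
            "edited": s.edited_count,
            "fraction": s.fraction,
            "gene_id": s.gene_id,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "pos_1based", "strand", "ref",
            "coverage", "edited", "fraction", "gene_id",
        ],
    )
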