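"""Readers/writers and the coordinate contract shared by all stages.

All internal coordinates are 0-based half-open. File-format conventions
(GFF3: 1-based closed; SAM: handled by pysam; BED: 0-based half-open) are
converted exactly once, at this module's boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

log = logging.getLogger(__name__)

Interval = tuple[int, int]

#: feature-type spellings accepted for the three transcript regions
_FEATURE_CLASS = {
    "five_prime_utr": "utr5",
    "5utr": "utr5",
    "five_prime_UTR": "utr5",
    "cds": "cds",
    "three_prime_utr": "utr3",
    "3utr": "utr3",
    "three_prime_UTR": "utr3",
}


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class TranscriptModel:
    """One transcript: stranded genomic intervals for 5'UTR, CDS and 3'UTR.

    Intervals are 0-based half-open genomic ranges on ``contig``. On the
    minus strand the 3'UTR occupies the smallest genomic coordinates.
    A transcript lacking UTR annotation is flagged ``cds_only`` and is
    excluded from metagene fractions but still usable for edit calling.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    utr5: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    cds_only: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError(f"bad strand {self.strand!r} for {self.transcript_id}")
        self.utr5 = sorted(self.utr5)
        self.cds = sorted(self.cds)
        self.utr3 = sorted(self.utr3)
        self.cds_only = self.cds_only or (not self.utr5 and not self.utr3)

    # -- geometry -----------------------------------------------------------

    @property
    def exons(self) -> list[Interval]:
        return _merge_intervals(self.utr5 + self.cds + self.utr3)

    @property
    def span(self) -> Interval:
        ex = self.exons
        return ex[0][0], ex[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def validate(self) -> None:
        ivs = sorted(self.utr5 + self.cds + self.utr3)
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise DataError(
                    f"{self.transcript_id}: overlapping feature intervals "
                    f"[{s0},{e0}) and [{s1},{e1})"
                )
        for s, e in ivs:
            if e <= s:
                raise DataError(f"{self.transcript_id}: empty interval [{s},{e})")
        # the three classes must tile the exon union exactly
        if sum(e - s for s, e in ivs) != self.transcript_length:
            raise DataError(f"{self.transcript_id}: features do not tile transcript")
        if not self.cds_only and self.utr3 and self.utr5:
            if self.strand == "+" and self.utr3[0][0] < self.utr5[-1][1]:
                raise DataError(f"{self.transcript_id}: 3'UTR upstream of 5'UTR on +")
            if self.strand == "-" and self.utr3[-1][1] > self.utr5[0][0]:
                raise DataError(f"{self.transcript_id}: 3'UTR downstream of 5'UTR on -")

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Stranded offset from the transcript 5' end; None if not exonic."""
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= gpos < e:
                    return off + (gpos - s)
                off += e - s
            return None
        for s, e in reversed(self.exons):
            if s <= gpos < e:
                return off + (e - 1 - gpos)
            off += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.transcript_length:
            raise DataError(f"transcript position {tpos} outside {self.transcript_id}")
        off = tpos
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        for s, e in exons:
            n = e - s
            if off < n:
                return s + off if self.strand == "+" else e - 1 - off
            off -= n
        raise AssertionError("unreachable")

    def feature_at(self, gpos: int) -> str | None:
        """Feature class ('utr5'|'cds'|'utr3') containing a genomic position."""
        for name, ivs in (("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3)):
            for s, e in ivs:
                if s <= gpos < e:
                    return name
        return None


class Annotation:
    """A set of transcript models with per-gene canonical choice.

    The canonical transcript of a gene is the one with the longest CDS
    (ties broken by transcript_id) and is used for metagene assignment.
    """

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts = list(transcripts)
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        self.by_contig: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)
            self.by_contig.setdefault(t.contig, []).append(t)
        self.canonical: dict[str, TranscriptModel] = {
            g: max(ts, key=lambda t: (t.cds_length, t.transcript_id))
            for g, ts in self.by_gene.items()
        }

    def __len__(self) -> int:
        return len(self.transcripts)

    def genes(self) -> list[str]:
        return sorted(self.by_gene)

    def validate(self) -> None:
        for t in self.transcripts:
            t.validate()

    def gene_lengths(self) -> dict[str, int]:
        """Union-exon length per gene (merged over all its transcripts)."""
        out = {}
        for g, ts in self.by_gene.items():
            merged = _merge_intervals(iv for t in ts for iv in t.exons)
            out[g] = sum(e - s for s, e in merged)
        return out

    def strand_gene_index(self, contig: str, length: int):
        """Per-position gene index arrays (plus, minus); -1 where no gene.

        Positions covered by more than one gene of the same strand keep the
        first gene in sorted order (logged once).
        """
        plus = np.full(length, -1, dtype=np.int32)
        minus = np.full(length, -1, dtype=np.int32)
        genes = sorted({t.gene_id for t in self.by_contig.get(contig, [])})
        gene_no = {g: i for i, g in enumerate(genes)}
        clashes = 0
        for t in sorted(
            self.by_contig.get(contig, []), key=lambda t: (t.gene_id, t.transcript_id)
        ):
            arr = plus if t.strand == "+" else minus
            for s, e in t.exons:
                seg = arr[s:e]
                other = (seg >= 0) & (seg != gene_no[t.gene_id])
                clashes += int(other.sum())
                seg[seg < 0] = gene_no[t.gene_id]
        if clashes:
            log.info("%s: %d positions shared by same-strand genes", contig, clashes)
        return plus, minus, genes


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> Annotation:
    """Load GFF3 or GTF into transcript models (0-based half-open internally).

    Accepts five_prime_UTR/CDS/three_prime_UTR (GFF3) or 5UTR/CDS/3UTR (GTF)
    feature rows; gene and transcript identity resolved from Parent/ID or
    gene_id/transcript_id attributes, in that order. Transcripts lacking any
    UTR feature are kept but flagged CDS-only (with a warning).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def _attr(feat, *keys):
        for k in keys:
            if k in feat.attributes:
                v = feat.attributes[k]
                return v[0] if isinstance(v, list) else v
        return None

    # map transcript -> gene via mRNA/transcript rows where present
    tx_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            tid = _attr(feat, "ID", "transcript_id")
            gid = _attr(feat, "Parent", "gene_id") or tid
            if tid:
                tx_gene[tid] = gid

    buckets: dict[str, dict] = {}
    for feat in db.all_features():
        cls = _FEATURE_CLASS.get(feat.featuretype) or _FEATURE_CLASS.get(
            feat.featuretype.lower()
        )
        if cls is None:
            continue
        tid = _attr(feat, "Parent", "transcript_id")
        if tid is None:
            raise DataError(f"{path}: feature at {feat.seqid}:{feat.start} has no parent")
        if feat.start < 1 or feat.end < feat.start:
            raise DataError(
                f"{path}: malformed coordinates {feat.start}-{feat.end} for {tid}"
            )
        b = buckets.setdefault(
            tid,
            {
                "contig": feat.seqid,
                "strand": feat.strand,
                "utr5": [],
                "cds": [],
                "utr3": [],
            },
        )
        # GFF3/GTF are 1-based closed -> 0-based half-open
        b[cls].append((feat.start - 1, feat.end))

    transcripts = []
    for tid, b in buckets.items():
        gid = tx_gene.get(tid, tid)
        t = TranscriptModel(
            gene_id=gid,
            transcript_id=tid,
            contig=b["contig"],
            strand=b["strand"],
            utr5=b["utr5"],
            cds=b["cds"],
            utr3=b["utr3"],
        )
        if t.cds_only:
            log.warning("transcript %s has no UTR features; marked CDS-only", tid)
        t.validate()
        transcripts.append(t)
    if not transcripts:
        raise DataError(f"{path}: no UTR/CDS features found")
    return Annotation(transcripts)


def write_gff3(annotation: Annotation, path: str | Path) -> None:
    """Emit GFF3 (1-based closed) for gene/mRNA/UTR/CDS features."""
    rows = []
    for gid in annotation.genes():
        ts = sorted(annotation.by_gene[gid], key=lambda t: t.transcript_id)
        contig = ts[0].contig
        strand = ts[0].strand
        gs = min(t.span[0] for t in ts)
        ge = max(t.span[1] for t in ts)
        rows.append((contig, "gene", gs + 1, ge, strand, f"ID={gid}"))
        for t in ts:
            s, e = t.span
            rows.append((contig, "mRNA", s + 1, e, strand, f"ID={t.transcript_id};Parent={gid}"))
            for ftype, ivs in (
                ("five_prime_UTR", t.utr5),
                ("CDS", t.cds),
                ("three_prime_UTR", t.utr3),
            ):
                for s0, e0 in ivs:
                    rows.append(
                        (contig, ftype, s0 + 1, e0, strand, f"Parent={t.transcript_id}")
                    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, ftype, start, end, strand, attrs in rows:
            fh.write(
                f"{contig}\ttribekit\t{ftype}\t{start}\t{end}\t.\t{strand}\t"
                f"{'0' if ftype == 'CDS' else '.'}\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------


def read_alignments(
    path: str | Path,
    unique_only: bool = True,
    reference: dict[str, str] | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Iterate mapped SAM records, optionally restricted to unique mappers.

    "Uniquely mapped" means: primary, mapped, MAPQ > 0, not secondary or
    supplementary. With ``unique_only=False`` every mapped record is yielded.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if unique_only and (
                rec.is_secondary or rec.is_supplementary or rec.mapping_quality == 0
            ):
                continue
            if reference is not None and rec.reference_name not in reference:
                raise DataError(
                    f"{path}: contig {rec.reference_name!r} absent from reference"
                )
            yield rec


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample table: one row per (sample_id, genotype, replicate, SAM path)."""

    rows: pd.DataFrame

    REQUIRED = ("sample_id", "genotype", "replicate", "sam_path")

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
        missing = [c for c in cls.REQUIRED if c not in df.columns]
        if missing:
            raise DataError(f"{path}: sample sheet missing columns {missing}")
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def validate(self, min_replicates: int = 2) -> None:
        counts = self.rows.groupby("genotype")["replicate"].nunique()
        bad = counts[counts < min_replicates]
        if len(bad):
            raise DataError(
                f"genotypes with fewer than {min_replicates} replicates: "
                f"{', '.join(bad.index)}"
            )

    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.rows["genotype"]))

    def samples_for(self, genotype: str) -> pd.DataFrame:
        return self.rows[self.rows["genotype"] == genotype].sort_values("replicate")


# ---------------------------------------------------------------------------
# tabular output helpers
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """BED6 from a site table with contig/pos (0-based)/strand columns."""
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            name = r.get("gene_id", ".") or "."
            score = int(round(1000 * float(r.get("fraction", 0.0))))
            fh.write(
                f"{r['contig']}\t{int(r['pos'])}\t{int(r['pos']) + 1}\t{name}\t"
                f"{score}\t{r['strand']}\n"
            )
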