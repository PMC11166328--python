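"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's pileup/calling code paths (and
pysam): the SAM text is parsed by hand and every read is re-walked
base by base.
"""

from __future__ import annotations

from collections import defaultdict


def brute_force_pileup(sam_path, unique_only: bool = True):
    """Per-position base counts from raw SAM text, one read at a time.

    Only handles ungapped single-M CIGARs (all the simulator emits).
    Returns {(contig, pos0): {base: count}}.
    """
    counts: dict[tuple[str, int], dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            flag = int(fields[1])
            if flag & 0x4:  # unmapped
                continue
            mapq = int(fields[4])
            if unique_only and (flag & 0x100 or flag & 0x800 or mapq == 0):
                continue
            contig = fields[2]
            start = int(fields[3]) - 1  # SAM is 1-based
            cigar = fields[5]
            seq = fields[9]
            assert cigar == f"{len(seq)}M", f"oracle only handles ungapped: {cigar}"
            for i, base in enumerate(seq):
                counts[(contig, start + i)][base] += 1
    return counts


def brute_force_call(
    pileup_counts,
    reference: dict[str, str],
    gene_strand_spans: dict[str, tuple[str, int, int]],
    c_min: int = 20,
    f_min: float = 0.15,
):
    """Thresholded A->G calls recomputed from the brute-force pileup.

    gene_strand_spans: contig -> (strand, start, end) of its single gene.
    Returns {(contig, pos, strand): (coverage, edited)}.
    """
    out = {}
    for (contig, pos), bc in pileup_counts.items():
        if contig not in gene_strand_spans:
            continue
        strand, start, end = gene_strand_spans[contig]
        if not start <= pos < end:
            continue
        ref = reference[contig][pos]
        cov = sum(bc.get(b, 0) for b in "ACGT")
        if strand == "+" and ref == "A":
            edited = bc.get("G", 0)
        elif strand == "-" and ref == "T":
            edited = bc.get("C", 0)
        else:
            continue
        if cov >= c_min and edited / cov >= f_min:
            out[(contig, pos, strand)] = (cov, edited)
    return out


def spans_from_annotation(annotation):
    """contig -> (strand, start, end) for one-gene-per-contig annotations."""
    spans = {}
    for t in annotation.transcripts:
        s, e = t.span
        spans[t.contig] = (t.strand, s, e)
    return spans
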