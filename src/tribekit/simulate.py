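"""Synthetic TRIBE data: reference, annotation, aligned reads, granule images.

The generator emulates the statistical structure the downstream analyses
assume: per-site binomial editing at known true fractions, per-transcript
mean depths spanning orders of magnitude (log-uniform), two biological
replicates per genotype, genotype-specific target-gene sets, 3'UTR-restricted
versus uniform edit placement, and two-channel granule images with a known
marker enrichment and fluorophore bleed-through. Every random draw derives
from one integer seed, so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io import Annotation, TranscriptModel

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _sample_len(rng: np.random.Generator, spec) -> int:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass
class GenotypeDesign:
    """Editing design for one genotype.

    positional_mode: "utr3_only" plants every site strictly inside the
    3'UTR; "uniform" plants sites uniformly over the whole transcript.
    edit_fraction is the per-site true editing probability: a float for a
    single shared value, or a (lo, hi) pair sampled uniformly per planted
    site (real sites are edited at heterogeneous efficiencies).
    site_positions, when given, pins transcript positions for specific
    genes (used to share exact sites between genotypes).
    """

    name: str
    n_target_genes: int
    positional_mode: str = "utr3_only"
    edit_fraction: float | tuple = 0.5
    sites_per_target: int = 2
    target_genes: list[str] | None = None
    site_positions: dict[str, list[int]] | None = None

    def validate(self) -> None:
        ef = self.edit_fraction
        for v in ef if isinstance(ef, (tuple, list)) else (ef,):
            _check_prob(f"edit_fraction({self.name})", v)
        if self.positional_mode not in ("utr3_only", "uniform"):
            raise ConfigError(f"unknown positional_mode {self.positional_mode!r}")
        if self.n_target_genes < 0 or self.sites_per_target < 1:
            raise ConfigError("target/site counts must be positive")


@dataclass
class SimulationConfig:
    """Shape of a simulated TRIBE experiment.

    Lengths may be fixed ints or (lo, hi) ranges sampled per gene.
    ``coverage`` is the mean per-transcript read depth: a float for constant
    depth, or a (lo, hi) pair sampled log-uniformly per gene so expression
    spans several orders of magnitude, as in real libraries.
    """

    n_genes: int = 300
    utr5_len: int | tuple = 100
    cds_len: int | tuple = 600
    utr3_len: int | tuple = 300
    n_replicates: int = 2
    genotypes: tuple[GenotypeDesign, ...] = ()
    coverage: float | tuple = (1.0, 1000.0)
    read_length: int = 100
    seq_error_rate: float = 0.001
    multimapper_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            v = getattr(self, name)
            lo = v[0] if isinstance(v, (tuple, list)) else v
            if lo < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")
        _check_prob("seq_error_rate", self.seq_error_rate)
        _check_prob("multimapper_fraction", self.multimapper_fraction)
        for g in self.genotypes:
            g.validate()
        names = [g.name for g in self.genotypes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate genotype names")


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    transcript_pos: int
    genomic_pos: int
    strand: str
    true_fraction: float
    genotype: str


@dataclass
class SimulationTruth:
    """Ground truth: planted sites, per-gene depth, realized counts.

    ``realized[(genotype, replicate)]`` is filled by :func:`simulate_reads`
    with the per-site edited/total counts actually emitted, both over all
    reads and over uniquely-mapped reads only.
    """

    planted: list[PlantedSite]
    expression: dict[str, float]  # gene -> mean depth
    seed: int
    realized: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)

    def planted_for(self, genotype: str) -> list[PlantedSite]:
        return [s for s in self.planted if s.genotype == genotype]

    def planted_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.planted])


# ---------------------------------------------------------------------------
# reference + annotation
# ---------------------------------------------------------------------------


def simulate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], Annotation]:
    """Random reference with one intronless gene per contig.

    Genes alternate between the two strands. On a minus-strand gene the
    3'UTR occupies the lowest genomic coordinates. Feature extents tile
    each transcript exactly. Each contig carries a read-length flank on
    both sides of its transcript so read coverage is uniform across the
    whole transcript (no end falloff).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    reference: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    flank = config.read_length
    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        u5 = _sample_len(rng, config.utr5_len)
        cds = _sample_len(rng, config.cds_len)
        u3 = _sample_len(rng, config.utr3_len)
        L = u5 + cds + u3
        strand = "+" if i % 2 == 0 else "-"
        seq = rng.integers(0, 4, size=L + 2 * flank)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[seq].tobytes().decode()
        contig = f"chr_{gid}"
        reference[contig] = seq
        f = flank
        if strand == "+":
            utr5, cdsiv, utr3 = (f, f + u5), (f + u5, f + u5 + cds), (f + u5 + cds, f + L)
        else:
            utr3, cdsiv, utr5 = (f, f + u3), (f + u3, f + u3 + cds), (f + u3 + cds, f + L)
        transcripts.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                contig=contig,
                strand=strand,
                utr5=[utr5],
                cds=[cdsiv],
                utr3=[utr3],
            )
        )
    ann = Annotation(transcripts)
    ann.validate()
    return reference, ann


def _sense_base(seq: str, t: TranscriptModel, tpos: int) -> str:
    g = t.transcript_to_genomic(tpos)
    b = seq[g]
    return b if t.strand == "+" else _COMPLEMENT[b]


def plant_sites(
    config: SimulationConfig,
    reference: dict[str, str],
    annotation: Annotation,
) -> SimulationTruth:
    """Choose target genes, per-gene depth, and editable (sense-A) positions."""
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    genes = annotation.genes()

    # per-gene mean depth: constant or log-uniform across the stated range
    if isinstance(config.coverage, (tuple, list)):
        lo, hi = config.coverage
        if lo <= 0 or hi < lo:
            raise ConfigError(f"bad coverage range {config.coverage}")
        depth = 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=len(genes))
    else:
        depth = np.full(len(genes), float(config.coverage))
    expression = dict(zip(genes, depth.tolist()))

    planted: list[PlantedSite] = []
    for design in config.genotypes:
        if design.target_genes is not None:
            targets = list(design.target_genes)
        else:
            if design.n_target_genes > len(genes):
                raise ConfigError(
                    f"{design.name}: {design.n_target_genes} targets > {len(genes)} genes"
                )
            targets = sorted(
                str(g)
                for g in rng.choice(genes, size=design.n_target_genes, replace=False)
            )
        for gid in targets:
            t = annotation.canonical[gid]
            seq = reference[t.contig]
            pinned = (design.site_positions or {}).get(gid)
            if pinned is not None:
                tpositions = list(pinned)
            else:
                L = t.transcript_length
                if design.positional_mode == "utr3_only":
                    u3len = sum(e - s for s, e in t.utr3)
                    lo_t, hi_t = L - u3len, L
                else:
                    lo_t, hi_t = 0, L
                cands = [
                    tp
                    for tp in range(lo_t, hi_t)
                    if _sense_base(seq, t, tp) == "A"
                ]
                if len(cands) < design.sites_per_target:
                    raise DataError(
                        f"{gid}: only {len(cands)} sense-A positions available"
                    )
                tpositions = sorted(
                    rng.choice(cands, size=design.sites_per_target, replace=False)
                )
            for tp in tpositions:
                if _sense_base(seq, t, tp) != "A":
                    raise DataError(f"{gid}: position {tp} is not a sense A")
                ef = design.edit_fraction
                frac = (
                    float(rng.uniform(*ef))
                    if isinstance(ef, (tuple, list))
                    else float(ef)
                )
                planted.append(
                    PlantedSite(
                        gene_id=gid,
                        transcript_pos=int(tp),
                        genomic_pos=int(t.transcript_to_genomic(tp)),
                        strand=t.strand,
                        true_fraction=frac,
                        genotype=design.name,
                    )
                )
    return SimulationTruth(planted=planted, expression=expression, seed=config.seed)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX_OF = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _IDX_OF[_b] = _i


def simulate_reads(
    config: SimulationConfig,
    reference: dict[str, str],
    annotation: Annotation,
    truth: SimulationTruth,
    genotype: str,
    replicate: int,
    sam_path: str | Path,
) -> pd.DataFrame:
    """Write one sample's aligned reads as coordinate-sorted SAM.

    Reads are ungapped full-length matches to the reference except at
    planted sites (each covering read carries the edited base independently
    with probability true_fraction: G on plus-strand genes, C — the genomic
    representation of a sense G — on minus-strand genes) and uniform
    substitution sequencing errors. A configurable fraction of reads is
    emitted as MAPQ-0 secondary records to exercise the unique-mapper
    filter. Returns (and stores in the truth object) the realized per-site
    edited/total counts, over all reads and over unique reads.
    """
    config.validate()
    geno_names = [g.name for g in config.genotypes]
    if genotype not in geno_names:
        raise ConfigError(f"unknown genotype {genotype!r}")
    rng = np.random.default_rng(
        [config.seed, 303, geno_names.index(genotype), replicate]
    )
    rl = config.read_length
    sites_by_gene: dict[str, list[PlantedSite]] = {}
    for s in truth.planted_for(genotype):
        sites_by_gene.setdefault(s.gene_id, []).append(s)

    contigs = sorted(reference)
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{c}\tLN:{len(reference[c])}" for c in contigs]

    qual = "I" * rl
    realized_rows = []
    sample_tag = f"{genotype}_r{replicate}"

    with open(sam_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for contig in contigs:
            seq = reference[contig]
            L = len(seq)
            if L < rl:
                raise ConfigError(f"{contig} shorter than read length")
            txs = annotation.by_contig.get(contig, [])
            gid = txs[0].gene_id if txs else None
            strand = txs[0].strand if txs else "+"
            depth = truth.expression.get(gid, 0.0) if gid else 0.0
            n_reads = int(rng.poisson(depth * (L - rl + 1) / rl))
            if n_reads == 0:
                continue
            starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))
            seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            mat = seq_arr[starts[:, None] + np.arange(rl)].copy()

            # plant edits (before sequencing errors)
            gene_sites = sites_by_gene.get(gid, [])
            site_cols = {}
            for site in gene_sites:
                col = site.genomic_pos - starts
                covering = np.nonzero((col >= 0) & (col < rl))[0]
                edited_byte = ord("G") if site.strand == "+" else ord("C")
                hit = covering[rng.random(len(covering)) < site.true_fraction]
                mat[hit, col[hit]] = edited_byte
                site_cols[site.genomic_pos] = (site, covering, edited_byte)

            # uniform substitution errors over the three alternatives
            if config.seq_error_rate > 0:
                err = rng.random(mat.shape) < config.seq_error_rate
                if err.any():
                    ei = np.nonzero(err)
                    cur = _IDX_OF[mat[ei]]
                    mat[ei] = _BASE_BYTES[
                        (cur + rng.integers(1, 4, size=len(ei[0]))) % 4
                    ]

            multi = (
                rng.random(n_reads) < config.multimapper_fraction
                if config.multimapper_fraction > 0
                else np.zeros(n_reads, dtype=bool)
            )

            # realized per-site bookkeeping from the final read matrix
            for gpos, (site, covering, edited_byte) in sorted(site_cols.items()):
                col = gpos - starts[covering]
                is_edit = mat[covering, col] == edited_byte
                uniq = ~multi[covering]
                realized_rows.append(
                    {
                        "sample": sample_tag,
                        "gene_id": site.gene_id,
                        "contig": contig,
                        "genomic_pos": gpos,
                        "strand": site.strand,
                        "transcript_pos": site.transcript_pos,
                        "true_fraction": site.true_fraction,
                        "coverage_all": int(len(covering)),
                        "edited_all": int(is_edit.sum()),
                        "coverage_unique": int(uniq.sum()),
                        "edited_unique": int(is_edit[uniq].sum()),
                    }
                )

            base_flag = 16 if strand == "-" else 0
            cigar = f"{rl}M"
            lines = []
            for i in range(n_reads):
                flag = base_flag | (0x100 if multi[i] else 0)
                mapq = 0 if multi[i] else 50
                lines.append(
                    f"{sample_tag}:{contig}:{i}\t{flag}\t{contig}\t{starts[i] + 1}"
                    f"\t{mapq}\t{cigar}\t*\t0\t0\t{mat[i].tobytes().decode()}\t{qual}"
                )
            fh.write("\n".join(lines) + "\n")

    df = pd.DataFrame(
        realized_rows,
        columns=[
            "sample", "gene_id", "contig", "genomic_pos", "strand",
            "transcript_pos", "true_fraction", "coverage_all", "edited_all",
            "coverage_unique", "edited_unique",
        ],
    )
    truth.realized[(genotype, replicate)] = df
    return df


# ---------------------------------------------------------------------------
# granule images
# ---------------------------------------------------------------------------


@dataclass
class GranuleImageTruth:
    """Planted granule centers (integer pixels) and per-granule parameters."""

    centers: pd.DataFrame  # y, x, sigma, enrichment, diameter


def simulate_granule_image(
    n_granules: int,
    enrichment: float | Sequence[float] = 2.0,
    bleed_coeff: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    sigma: float = 3.0,
    background: tuple[float, float] = (100.0, 100.0),
    amplitude: float = 300.0,
    trunc_sigma: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, GranuleImageTruth]:
    """Two-channel image with planted Gaussian granules of known enrichment.

    Channel 1 (granule stain): constant background plus truncated-Gaussian
    granules of the given amplitude. Channel 2 (marker): its own background,
    plus (enrichment - 1) x background at granule centers with the same
    Gaussian profile, plus bleed_coeff x channel 1, plus Gaussian noise.
    Granule profiles have compact support (zero beyond trunc_sigma sigmas)
    and centers sit on integer pixels, so closed-form checks are exact.
    """
    enr = np.broadcast_to(np.asarray(enrichment, dtype=float), (n_granules,)).copy()
    if np.any(enr < 0):
        raise ConfigError("enrichment must be >= 0")
    if bleed_coeff < 0:
        raise ConfigError("bleed_coeff must be >= 0")
    rng = np.random.default_rng([seed, 404])
    H, W = shape
    R = trunc_sigma * sigma
    margin = int(math.ceil(R)) + 2
    min_sep = 2 * R + 2
    if 2 * margin >= min(H, W):
        raise ConfigError("image too small for requested granule size")

    centers: list[tuple[int, int]] = []
    for _ in range(n_granules):
        for _try in range(2000):
            y = int(rng.integers(margin, H - margin))
            x = int(rng.integers(margin, W - margin))
            if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
                centers.append((y, x))
                break
        else:
            raise ConfigError(
                f"could not place {n_granules} non-overlapping granules in {shape}"
            )

    bg1, bg2 = background
    ch1 = np.full(shape, bg1, dtype=float)
    ch2 = np.full(shape, bg2, dtype=float)
    yy, xx = np.mgrid[0:H, 0:W]
    for (y, x), e in zip(centers, enr):
        r2 = (yy - y) ** 2 + (xx - x) ** 2
        prof = np.exp(-r2 / (2 * sigma**2))
        prof[r2 > R**2] = 0.0
        ch1 += amplitude * prof
        ch2 += (e - 1.0) * bg2 * prof
    ch2 = ch2 + bleed_coeff * ch1
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, size=shape)
        ch2 = ch2 + rng.normal(0.0, noise_sd, size=shape)
        np.clip(ch1, 0.0, None, out=ch1)
        np.clip(ch2, 0.0, None, out=ch2)

    truth = GranuleImageTruth(
        centers=pd.DataFrame(
            {
                "y": [c[0] for c in centers],
                "x": [c[1] for c in centers],
                "sigma": sigma,
                "enrichment": enr,
                "diameter": 2 * R,
            }
        )
    )
    return ch1, ch2, truth


# ---------------------------------------------------------------------------
# whole-dataset convenience
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write reference, annotation, per-sample SAMs, sample sheet and truth.

    Returns a dict of paths plus the in-memory truth object.
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, annotation = simulate_reference(config)
    truth = plant_sites(config, reference, annotation)

    ref_path = outdir / "reference.fa"
    gff_path = outdir / "annotation.gff3"
    tio.write_fasta(reference, ref_path)
    tio.write_gff3(annotation, gff_path)

    rows = []
    for design in config.genotypes:
        for rep in range(1, config.n_replicates + 1):
            sam = outdir / f"{design.name}_rep{rep}.sam"
            simulate_reads(
                config, reference, annotation, truth, design.name, rep, sam
            )
            rows.append(
                {
                    "sample_id": f"{design.name}_rep{rep}",
                    "genotype": design.name,
                    "replicate": rep,
                    "sam_path": str(sam),
                }
            )
    sheet = tio.SampleSheet(pd.DataFrame(rows))
    sheet_path = outdir / "sample_sheet.tsv"
    sheet.write(sheet_path)

    truth_path = outdir / "truth_planted.tsv"
    tio.write_tsv(truth.planted_frame(), truth_path)
    expr_path = outdir / "truth_expression.tsv"
    tio.write_tsv(
        pd.DataFrame(
            {"gene_id": list(truth.expression), "mean_depth": list(truth.expression.values())}
        ),
        expr_path,
    )
    realized_path = outdir / "truth_realized.tsv"
    if truth.realized:
        tio.write_tsv(pd.concat(truth.realized.values(), ignore_index=True), realized_path)

    log.info("simulated dataset written to %s (seed=%d)", outdir, config.seed)
    return {
        "reference": ref_path,
        "annotation": gff_path,
        "sample_sheet": sheet_path,
        "truth_planted": truth_path,
        "truth_expression": expr_path,
        "truth_realized": realized_path,
        "truth": truth,
        "config": config,
    }
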