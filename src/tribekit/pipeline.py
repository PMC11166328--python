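"""End-to-end orchestration: call -> intersect -> compare -> metagene ->
expression, with a content-hashed run manifest, plus a self-contained demo
dataset generator mirroring the two-genotype TRIBE design.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from .calling import EditCallingConfig, build_pileup, call_edit_sites, sites_to_frame
from .errors import StageError
from .metagene import (
    compute_fpkm,
    feature_length_shares,
    metagene_distribution,
    target_expression_profile,
)
from .simulate import GenotypeDesign, SimulationConfig, simulate_dataset
from .targets import (
    compare_targets,
    efficiency_ratios,
    intersect_replicates,
    replicate_correlation,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one TRIBE pipeline run needs."""

    reference: Path
    annotation: Path
    sample_sheet: Path
    outdir: Path
    calling: EditCallingConfig = field(default_factory=EditCallingConfig)
    ratio_combiner: str = "mean"
    metagene_bins: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reference", "annotation", "sample_sheet"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise StageError("config", f"{name} path does not exist: {p}")
        self.outdir = Path(self.outdir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_tribe_pipeline(config: RunConfig) -> dict:
    """Run every TRIBE stage in order and write a hashed manifest.

    Stages: per-sample edit calling, per-genotype replicate intersection,
    pairwise genotype comparison with efficiency ratios and correlations,
    per-genotype metagene distributions, per-sample FPKM and the target
    expression profile. Any stage failure aborts with the stage name.
    Reruns with the same inputs and seed are bit-identical.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        p = outdir / name
        tio.write_tsv(df, p)
        outputs.append(p)
        return p

    # ---- load inputs ------------------------------------------------------
    try:
        reference = tio.read_fasta(config.reference)
        annotation = tio.read_annotation(config.annotation)
        sheet = tio.SampleSheet.read(config.sample_sheet)
        sheet.validate()
    except StageError:
        raise
    except Exception as e:
        raise StageError("load_inputs", str(e)) from e

    # ---- edit calling per sample -----------------------------------------
    calls_by_sample: dict[str, list] = {}
    try:
        for _, row in sheet.rows.iterrows():
            reads = tio.read_alignments(
                row["sam_path"], unique_only=True, reference=reference
            )
            pileup = build_pileup(reads, reference)
            sites = call_edit_sites(pileup, annotation, config.calling)
            calls_by_sample[row["sample_id"]] = sites
            emit(sites_to_frame(sites), f"edits_{row['sample_id']}.tsv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("edit_calling", str(e)) from e

    # ---- replicate intersection per genotype ------------------------------
    target_sets = {}
    try:
        for genotype in sheet.genotypes():
            samples = sheet.samples_for(genotype)
            per_rep = [calls_by_sample[s] for s in samples["sample_id"]]
            ts = intersect_replicates(per_rep, genotype=genotype)
            target_sets[genotype] = ts
            emit(ts.to_frame(), f"targets_{genotype}_sites.tsv")
            emit(
                pd.DataFrame({"gene_id": sorted(ts.genes)}),
                f"targets_{genotype}_genes.tsv",
            )
    except StageError:
        raise
    except Exception as e:
        raise StageError("replicate_intersection", str(e)) from e

    # ---- genotype comparison ---------------------------------------------
    genotypes = sheet.genotypes()
    comparison_summary = {}
    try:
        if len(genotypes) >= 2:
            a, b = genotypes[0], genotypes[1]
            cmp = compare_targets(target_sets[a], target_sets[b])
            comparison_summary = cmp.counts()
            _write_json(comparison_summary, outdir / "comparison_counts.json")
            outputs.append(outdir / "comparison_counts.json")
            emit(
                pd.DataFrame({"gene_id": sorted(cmp.shared_genes)}),
                "shared_genes.tsv",
            )
            ratio_df, ratio_summary = efficiency_ratios(
                target_sets[a], target_sets[b], combiner=config.ratio_combiner
            )
            emit(ratio_df, "efficiency_ratios.tsv")
            comparison_summary["efficiency"] = ratio_summary

            corr_rows = []
            for genotype in genotypes:
                ids = list(sheet.samples_for(genotype)["sample_id"])
                for i in range(len(ids)):
                    for j in range(i + 1, len(ids)):
                        r, n = replicate_correlation(
                            calls_by_sample[ids[i]], calls_by_sample[ids[j]]
                        )
                        corr_rows.append(
                            {"sample_a": ids[i], "sample_b": ids[j],
                             "scope": "within", "r": r, "n_union": n}
                        )
            for sa in sheet.samples_for(a)["sample_id"]:
                for sb in sheet.samples_for(b)["sample_id"]:
                    r, n = replicate_correlation(
                        calls_by_sample[sa], calls_by_sample[sb]
                    )
                    corr_rows.append(
                        {"sample_a": sa, "sample_b": sb,
                         "scope": "cross", "r": r, "n_union": n}
                    )
            emit(pd.DataFrame(corr_rows), "correlations.tsv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("target_comparison", str(e)) from e

    # ---- metagene ---------------------------------------------------------
    metagene_summary = {"feature_length_shares": feature_length_shares(annotation)}
    try:
        for genotype, ts in target_sets.items():
            if ts.n_sites == 0:
                log.warning("genotype %s has no target sites; metagene skipped", genotype)
                continue
            dist = metagene_distribution(ts, annotation)
            emit(dist.to_frame(), f"metagene_{genotype}.tsv")
            hist, edges = dist.histogram(bins=config.metagene_bins)
            emit(
                pd.DataFrame(
                    {"bin_start": edges[:-1], "bin_end": edges[1:], "count": hist}
                ),
                f"metagene_positions_{genotype}.tsv",
            )
            metagene_summary[genotype] = {
                "fractions": dist.fractions,
                "n_sites": ts.n_sites,
                "n_unresolvable": dist.n_unresolvable,
            }
        _write_json(metagene_summary, outdir / "metagene_summary.json")
        outputs.append(outdir / "metagene_summary.json")
    except StageError:
        raise
    except Exception as e:
        raise StageError("metagene", str(e)) from e

    # ---- expression -------------------------------------------------------
    expression_summary = {}
    try:
        fpkm_by_sample = {}
        for _, row in sheet.rows.iterrows():
            reads = tio.read_alignments(
                row["sam_path"], unique_only=True, reference=reference
            )
            fpkm = compute_fpkm(reads, annotation)
            fpkm_by_sample[row["sample_id"]] = fpkm
            emit(fpkm, f"fpkm_{row['sample_id']}.tsv")
        first = sheet.rows.iloc[0]["sample_id"]
        for genotype, ts in target_sets.items():
            expression_summary[genotype] = target_expression_profile(
                ts.genes, fpkm_by_sample[first]
            )
        _write_json(expression_summary, outdir / "expression_summary.json")
        outputs.append(outdir / "expression_summary.json")
    except StageError:
        raise
    except Exception as e:
        raise StageError("expression", str(e)) from e

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "calling": {
            "c_min": config.calling.c_min,
            "f_min": config.calling.f_min,
            "inclusive": config.calling.inclusive,
        },
        "comparison": comparison_summary,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    _write_json(manifest, outdir / "manifest.json")
    log.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
    return manifest


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------


def make_demo(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 320,
    wt_targets: int = 250,
    mut_targets: int = 100,
    shared_targets: int = 36,
    wt_fraction: float = 0.5,
    mut_fraction: float = 0.25,
    coverage: float | tuple = (1.0, 1000.0),
    sites_per_target: int = 2,
    seq_error_rate: float = 0.001,
) -> dict:
    """Synthetic two-genotype TRIBE experiment mirroring the study design.

    Genotype "WT": many target genes, edits confined to 3'UTRs, high edit
    fraction. Genotype "dPAM2": fewer targets partially overlapping WT's,
    edits placed uniformly along transcripts, lower edit fraction. Shared
    target genes reuse WT's exact site positions so shared-site efficiency
    ratios are defined. Two replicates per genotype; per-gene depth is
    log-uniform across the coverage range.
    """
    from .simulate import plant_sites, simulate_reference

    if not (0 <= shared_targets <= min(wt_targets, mut_targets)):
        raise StageError("demo", "shared_targets out of range")

    base = SimulationConfig(
        n_genes=n_genes,
        genotypes=(
            GenotypeDesign(
                "WT", wt_targets, "utr3_only", wt_fraction,
                sites_per_target=sites_per_target,
            ),
        ),
        coverage=coverage,
        seq_error_rate=seq_error_rate,
        seed=seed,
    )
    reference, annotation = simulate_reference(base)
    wt_truth = plant_sites(base, reference, annotation)
    wt_genes = sorted({s.gene_id for s in wt_truth.planted})
    wt_positions: dict[str, list[int]] = {}
    for s in wt_truth.planted:
        wt_positions.setdefault(s.gene_id, []).append(s.transcript_pos)

    import numpy as np

    rng = np.random.default_rng([seed, 707])
    shared = sorted(rng.choice(wt_genes, size=shared_targets, replace=False).tolist())
    others = sorted(set(annotation.genes()) - set(wt_genes))
    uniq = sorted(
        rng.choice(others, size=mut_targets - shared_targets, replace=False).tolist()
    )
    mut_design = GenotypeDesign(
        "dPAM2",
        mut_targets,
        "uniform",
        mut_fraction,
        sites_per_target=sites_per_target,
        target_genes=shared + uniq,
        site_positions={g: wt_positions[g] for g in shared},
    )
    full = SimulationConfig(
        n_genes=n_genes,
        genotypes=(base.genotypes[0], mut_design),
        coverage=coverage,
        seq_error_rate=seq_error_rate,
        seed=seed,
    )
    return simulate_dataset(full, outdir)
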