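"""Metagene feature assignment, distributions, FPKM and expression profile."""

from dataclasses import dataclass

import numpy as np
import pytest
from scipy import stats

import tribekit.io as tio
from tribekit.calling import EditSite, build_pileup, call_edit_sites
from tribekit.errors import DataError
from tribekit.io import Annotation, TranscriptModel
from tribekit.metagene import (
    assign_edit_to_feature,
    compute_fpkm,
    feature_length_shares,
    metagene_distribution,
    target_expression_profile,
)
from tribekit.simulate import GenotypeDesign, SimulationConfig, simulate_dataset


def _plus_tx():
    return TranscriptModel(
        "g1", "t1", "c1", "+", [(0, 100)], [(100, 400)], [(400, 600)]
    )


def _minus_tx():
    # mirror gene: 3'UTR at lowest genomic coordinates
    return TranscriptModel(
        "g2", "t2", "c2", "-", [(500, 600)], [(200, 500)], [(0, 200)]
    )


def _site(contig, pos, gene, strand="+"):
    return EditSite(contig, pos, strand, 30, 10, gene_id=gene)


class TestAssignment:
    def test_plus_strand_utr3_relative_position(self):
        ann = Annotation([_plus_tx()])
        feat, rel = assign_edit_to_feature(_site("c1", 450, "g1"), ann)
        assert feat == "utr3"
        assert rel == pytest.approx(0.75)

    def test_first_cds_base_half_open_boundary(self):
        ann = Annotation([_plus_tx()])
        feat, _ = assign_edit_to_feature(_site("c1", 100, "g1"), ann)
        assert feat == "cds"
        feat, _ = assign_edit_to_feature(_site("c1", 99, "g1"), ann)
        assert feat == "utr5"

    def test_minus_strand_mirror_classification_unchanged(self):
        """Same relative transcript position classifies identically after
        the strand flip."""
        ann = Annotation([_minus_tx()])
        t = _minus_tx()
        g = t.transcript_to_genomic(450)  # transcript offset 450 of 600
        feat, rel = assign_edit_to_feature(_site("c2", g, "g2", "-"), ann)
        assert feat == "utr3"
        assert rel == pytest.approx(0.75)

    def test_intergenic_site_unresolvable(self):
        ann = Annotation([_plus_tx()])
        feat, rel = assign_edit_to_feature(_site("c1", 10, None), ann)
        assert feat == "unresolvable"

    def test_agrees_with_interval_membership_oracle(self, sim_depth50):
        ann = tio.read_annotation(sim_depth50["annotation"])
        for s in sim_depth50["truth"].planted:
            t = ann.canonical[s.gene_id]
            oracle = None
            for name, ivs in (("utr5", t.utr5), ("cds", t.cds), ("utr3", t.utr3)):
                for lo, hi in ivs:
                    if lo <= s.genomic_pos < hi:
                        oracle = name
            site = EditSite(t.contig, s.genomic_pos, s.strand, 30, 10, gene_id=s.gene_id)
            feat, _ = assign_edit_to_feature(site, ann)
            assert feat == oracle


class TestDistribution:
    def test_single_cds_site(self):
        ann = Annotation([_plus_tx()])
        dist = metagene_distribution([_site("c1", 250, "g1")], ann)
        assert dist.fractions == {"utr5": 0.0, "cds": 1.0, "utr3": 0.0}

    def test_all_unresolvable_errors(self):
        ann = Annotation([_plus_tx()])
        with pytest.raises(DataError):
            metagene_distribution([_site("c9", 5, None)], ann)

    def test_utr3_only_genotype_fraction_exactly_one(self, sim_depth50):
        ref = tio.read_fasta(sim_depth50["reference"])
        ann = tio.read_annotation(sim_depth50["annotation"])
        sam = sim_depth50["sample_sheet"].parent / "WT_rep1.sam"
        sites = call_edit_sites(build_pileup(tio.read_alignments(sam), ref), ann)
        dist = metagene_distribution(sites, ann)
        assert dist.fractions["utr3"] == 1.0

    def test_uniform_genotype_matches_length_shares(self, sim_depth50):
        """Uniformly placed edits spread over features proportionally to
        feature length (3 sigma binomial)."""
        ref = tio.read_fasta(sim_depth50["reference"])
        ann = tio.read_annotation(sim_depth50["annotation"])
        sam = sim_depth50["sample_sheet"].parent / "MUT_rep1.sam"
        sites = call_edit_sites(build_pileup(tio.read_alignments(sam), ref), ann)
        dist = metagene_distribution(sites, ann)
        shares = feature_length_shares(ann)
        n = sum(dist.counts.values())
        for feat in ("utr5", "cds", "utr3"):
            p = shares[feat]
            sd = np.sqrt(n * p * (1 - p))
            assert abs(dist.counts[feat] - n * p) <= 3 * sd + 1

    def test_relative_position_histogram_bounds(self, sim_depth50):
        ann = tio.read_annotation(sim_depth50["annotation"])
        sites = [
            EditSite(f"chr_{s.gene_id}", s.genomic_pos, s.strand, 30, 10,
                     gene_id=s.gene_id)
            for s in sim_depth50["truth"].planted_for("MUT")
        ]
        dist = metagene_distribution(sites, ann)
        assert ((dist.relative_positions >= 0) & (dist.relative_positions < 1)).all()
        hist, edges = dist.histogram(bins=20)
        assert hist.sum() == len(dist.relative_positions)


@dataclass
class FakeRead:
    reference_name: str
    reference_start: int
    reference_end: int


class TestFPKM:
    def _one_gene_annotation(self):
        return Annotation(
            [TranscriptModel("g1", "t1", "c1", "+", [(0, 100)], [(100, 800)], [(800, 1000)])]
        )

    def test_closed_form(self):
        """1,000 bp gene, 1,000 fragments, 10^6-fragment library -> FPKM 1,000."""
        ann = self._one_gene_annotation()
        reads = [FakeRead("c1", 100, 200)] * 1000
        reads += [FakeRead("other", 0, 100)] * 999_000
        df = compute_fpkm(reads, ann)
        assert df.loc[df.gene_id == "g1", "fpkm"].iloc[0] == pytest.approx(1000.0)

    def test_scale_invariance_under_count_doubling(self):
        ann = self._one_gene_annotation()
        reads = [FakeRead("c1", 100, 200)] * 500 + [FakeRead("other", 0, 100)] * 1500
        f1 = compute_fpkm(reads, ann)
        f2 = compute_fpkm(reads * 2, ann)
        assert np.allclose(f1["fpkm"], f2["fpkm"])

    def test_zero_fragments_errors(self):
        with pytest.raises(DataError):
            compute_fpkm([], self._one_gene_annotation())

    def test_rank_correlation_with_true_expression(self, tmp_path):
        """Depths spanning three orders of magnitude: FPKM recovers the
        true expression ranking (Spearman >= 0.95)."""
        cfg = SimulationConfig(
            n_genes=100,
            utr5_len=50, cds_len=300, utr3_len=150,
            genotypes=(GenotypeDesign("WT", 10, "utr3_only", 0.5),),
            coverage=(1.0, 1000.0),
            n_replicates=1,
            seq_error_rate=0.0,
            seed=83,
        )
        out = simulate_dataset(cfg, tmp_path)
        ref = tio.read_fasta(out["reference"])
        ann = tio.read_annotation(out["annotation"])
        fpkm = compute_fpkm(
            tio.read_alignments(tmp_path / "WT_rep1.sam"), ann
        )
        truth = out["truth"].expression
        rho, _ = stats.spearmanr(
            fpkm["fpkm"], [truth[g] for g in fpkm["gene_id"]]
        )
        assert rho >= 0.95


class TestTargetExpression:
    def _fpkm_table(self, n=200, seed=5):
        rng = np.random.default_rng(seed)
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "fpkm": 10 ** rng.uniform(0, 3, n),
            }
        )

    def test_uniform_targets_show_no_shift(self):
        """Targets drawn uniformly from all genes: rank-sum p stays large
        for most seeds (null behaviour)."""
        ps = []
        for seed in range(20):
            expr = self._fpkm_table(seed=1)
            rng = np.random.default_rng(seed)
            targets = rng.choice(expr["gene_id"], 40, replace=False)
            ps.append(target_expression_profile(targets, expr)["ranksum_p"])
        assert np.mean(np.array(ps) < 0.05) <= 0.25  # ~5% expected under null

    def test_top_decile_targets_detected(self):
        expr = self._fpkm_table()
        top = expr.nlargest(20, "fpkm")["gene_id"]
        out = target_expression_profile(top, expr)
        assert out["ranksum_p"] < 1e-6
        assert out["target_median_fpkm"] > out["other_median_fpkm"]

    def test_empty_targets_warns(self):
        with pytest.warns(UserWarning):
            out = target_expression_profile([], self._fpkm_table())
        assert out == {"n_targets": 0}
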