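"""Pileup correctness and thresholded A->G edit-site calling."""

import itertools

import numpy as np
import pytest
from scipy import stats

import tribekit.io as tio
from helpers import brute_force_call, brute_force_pileup, spans_from_annotation
from tribekit.calling import (
    EditCallingConfig,
    EditSite,
    Pileup,
    build_pileup,
    call_edit_sites,
    subtract_background,
)
from tribekit.errors import ConfigError
from tribekit.io import Annotation, TranscriptModel
from tribekit.simulate import GenotypeDesign, SimulationConfig, simulate_dataset


def _manual_pileup(ref_seq: str, column_counts: dict[int, dict[str, int]]) -> Pileup:
    """Build a pileup with exact per-column counts, bypassing read I/O."""
    pu = Pileup({"c1": ref_seq})
    arr = pu._arr("c1")
    for pos, bc in column_counts.items():
        for base, n in bc.items():
            arr["ACGTN".index(base), pos] = n
    return pu


def _plus_annotation(length: int = 100) -> Annotation:
    third = length // 3
    return Annotation(
        [
            TranscriptModel(
                "g1", "t1", "c1", "+",
                [(0, third)], [(third, 2 * third)], [(2 * third, length)],
            )
        ]
    )


class TestPileup:
    def test_empty_reads_empty_pileup(self):
        pu = build_pileup([], {"c1": "ACGT" * 10})
        assert list(pu.columns()) == []

    def test_identical_full_match_reads(self, tmp_path):
        ref = {"c1": "ACGTA" * 10}
        sam = tmp_path / "five.sam"
        lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:c1\tLN:50"]
        for i in range(5):
            lines.append(
                f"r{i}\t0\tc1\t1\t50\t50M\t*\t0\t0\t{ref['c1']}\t{'I' * 50}"
            )
        sam.write_text("\n".join(lines) + "\n")
        pu = build_pileup(tio.read_alignments(sam), ref)
        cols = list(pu.columns())
        assert len(cols) == 50
        for col in cols:
            assert col.coverage == 5
            assert col.counts["ACGTN".index(col.ref)] == 5

    def test_matches_brute_force_oracle(self, sim_depth50):
        """Package pileup equals a hand-rolled per-read re-walk of the SAM."""
        ref = tio.read_fasta(sim_depth50["reference"])
        sam = sim_depth50["sample_sheet"].parent / "WT_rep1.sam"
        pu = build_pileup(tio.read_alignments(sam, unique_only=True), ref)
        oracle = brute_force_pileup(sam)
        for (contig, pos), bc in oracle.items():
            arr = pu.counts[contig]
            for base, n in bc.items():
                assert arr["ACGTN".index(base), pos] == n
        # and nothing extra: total counts agree
        total_pkg = sum(int(a.sum()) for a in pu.counts.values())
        total_orc = sum(sum(bc.values()) for bc in oracle.values())
        assert total_pkg == total_orc


class TestThresholds:
    def test_boundary_inclusive_20_reads_15_percent(self):
        ann = _plus_annotation(100)
        ref = "A" * 100
        pu = _manual_pileup(ref, {10: {"A": 17, "G": 3}})  # cov 20, frac 0.15
        sites = call_edit_sites(pu, ann)
        assert [(s.pos, s.coverage, s.edited_count) for s in sites] == [(10, 20, 3)]

    def test_coverage_19_not_emitted(self):
        pu = _manual_pileup("A" * 100, {10: {"G": 19}})  # frac 1.0, cov 19
        assert call_edit_sites(pu, _plus_annotation(100)) == []

    def test_fraction_just_below_threshold_not_emitted(self):
        pu = _manual_pileup("A" * 100, {10: {"A": 851, "G": 149}})  # 0.149
        assert call_edit_sites(pu, _plus_annotation(100)) == []
        pu = _manual_pileup("A" * 100, {10: {"A": 850, "G": 150}})  # 0.150
        assert len(call_edit_sites(pu, _plus_annotation(100))) == 1

    def test_non_a_reference_never_emitted(self):
        pu = _manual_pileup("C" * 100, {10: {"G": 100}, 11: {"T": 50, "G": 50}})
        assert call_edit_sites(pu, _plus_annotation(100)) == []

    def test_n_bases_excluded_from_coverage(self):
        pu = _manual_pileup("A" * 100, {10: {"A": 16, "G": 3, "N": 10}})
        assert call_edit_sites(pu, _plus_annotation(100)) == []  # cov 19, not 29

    def test_minus_strand_t_to_c_called_as_sense_edit(self):
        ann = Annotation(
            [TranscriptModel("g1", "t1", "c1", "-", [(66, 100)], [(33, 66)], [(0, 33)])]
        )
        pu = _manual_pileup("T" * 100, {20: {"T": 50, "C": 50}})
        sites = call_edit_sites(pu, ann)
        assert len(sites) == 1
        assert sites[0].strand == "-" and sites[0].fraction == 0.5

    def test_thresholds_monotone_over_grid(self, sim_depth50):
        ref = tio.read_fasta(sim_depth50["reference"])
        ann = tio.read_annotation(sim_depth50["annotation"])
        sam = sim_depth50["sample_sheet"].parent / "WT_rep1.sam"
        pu = build_pileup(tio.read_alignments(sam), ref)
        grid_c = [5, 10, 20, 40, 80]
        grid_f = [0.05, 0.10, 0.15, 0.30, 0.60]
        counts = {}
        for c, f in itertools.product(grid_c, grid_f):
            counts[(c, f)] = len(
                call_edit_sites(pu, ann, EditCallingConfig(c_min=c, f_min=f))
            )
        for (c0, c1), (f0, f1) in itertools.product(
            itertools.combinations(grid_c, 2), itertools.combinations(grid_f, 2)
        ):
            assert counts[(c1, f1)] <= counts[(c0, f0)]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            EditCallingConfig(c_min=0).validate()
        with pytest.raises(ConfigError):
            EditCallingConfig(f_min=0.0).validate()
        with pytest.raises(NotImplementedError):
            EditCallingConfig(strand_mode="read-flag").validate()


class TestCallerVsTruth:
    def test_emitted_iff_realized_counts_pass(self, sim_depth50):
        """Site emitted <=> realized coverage >= 20 and fraction >= 0.15."""
        ref = tio.read_fasta(sim_depth50["reference"])
        ann = tio.read_annotation(sim_depth50["annotation"])
        for genotype in ("WT", "MUT"):
            sam = sim_depth50["sample_sheet"].parent / f"{genotype}_rep1.sam"
            pu = build_pileup(tio.read_alignments(sam), ref)
            called = {
                (s.contig, s.pos) for s in call_edit_sites(pu, ann)
            }
            tr = sim_depth50["truth"].realized[(genotype, 1)]
            expected = {
                (r.contig, r.genomic_pos)
                for r in tr.itertuples()
                if r.coverage_unique >= 20
                and r.edited_unique / r.coverage_unique >= 0.15
            }
            assert called == expected

    def test_full_recall_no_false_positives_at_depth50(self, sim_depth50):
        """True fraction 0.5 at depth 50, zero error: every planted site and
        nothing else."""
        ref = tio.read_fasta(sim_depth50["reference"])
        ann = tio.read_annotation(sim_depth50["annotation"])
        sam = sim_depth50["sample_sheet"].parent / "WT_rep1.sam"
        pu = build_pileup(tio.read_alignments(sam), ref)
        called = {(s.contig, s.pos) for s in call_edit_sites(pu, ann)}
        planted = {
            (f"chr_{s.gene_id}", s.genomic_pos)
            for s in sim_depth50["truth"].planted_for("WT")
        }
        recall = len(called & planted) / len(planted)
        assert recall >= 0.99
        assert not called - planted

    def test_low_fraction_call_rate_matches_binomial_tail(self, tmp_path):
        """True fraction 0.05: calls arise only from the binomial tail
        P(X/n >= 0.15); observed count within 3 sigma of expectation."""
        cfg = SimulationConfig(
            n_genes=100,
            genotypes=(GenotypeDesign("LO", 100, "utr3_only", 0.05, sites_per_target=2),),
            coverage=30.0,
            seq_error_rate=0.0,
            seed=61,
        )
        out = simulate_dataset(cfg, tmp_path)
        ref = tio.read_fasta(out["reference"])
        ann = tio.read_annotation(out["annotation"])
        pu = build_pileup(
            tio.read_alignments(tmp_path / "LO_rep1.sam"), ref
        )
        called = {(s.contig, s.pos) for s in call_edit_sites(pu, ann)}
        tr = out["truth"].realized[("LO", 1)]
        p_call = np.array(
            [
                stats.binom.sf(np.ceil(0.15 * n) - 1, n, 0.05) if n >= 20 else 0.0
                for n in tr["coverage_unique"]
            ]
        )
        mean, sd = p_call.sum(), np.sqrt((p_call * (1 - p_call)).sum())
        assert abs(len(called) - mean) <= 3 * max(sd, 1.0)


class TestBackgroundSubtraction:
    def _sites(self, positions):
        return [EditSite("c1", p, "+", 30, 10, gene_id="g") for p in positions]

    def test_empty_background_is_identity(self):
        s = self._sites([1, 2, 3])
        assert subtract_background(s, []) == s

    def test_full_background_empties(self):
        s = self._sites([1, 2, 3])
        assert subtract_background(s, s) == []

    def test_planted_snp_positions_removed_exactly(self):
        s = self._sites(range(10))
        snps = self._sites([2, 5, 7])
        kept = subtract_background(s, snps)
        assert [x.pos for x in kept] == [0, 1, 3, 4, 6, 8, 9]


def test_oracle_call_equivalence_with_errors(tmp_path):
    """End-to-end: package calls equal brute-force recomputation from the SAM
    even with sequencing errors and both strands."""
    cfg = SimulationConfig(
        n_genes=60,
        genotypes=(GenotypeDesign("WT", 40, "uniform", 0.4, sites_per_target=3),),
        coverage=60.0,
        seq_error_rate=0.005,
        seed=71,
    )
    out = simulate_dataset(cfg, tmp_path)
    ref = tio.read_fasta(out["reference"])
    ann = tio.read_annotation(out["annotation"])
    sam = tmp_path / "WT_rep1.sam"
    pu = build_pileup(tio.read_alignments(sam), ref)
    called = {
        s.key: (s.coverage, s.edited_count) for s in call_edit_sites(pu, ann)
    }
    oracle = brute_force_call(
        brute_force_pileup(sam), ref, spans_from_annotation(ann)
    )
    assert called == oracle
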