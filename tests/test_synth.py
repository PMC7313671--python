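"""Synthetic genomes, reads with truth alignments, and phenotype draws."""

import math

import numpy as np
import pytest

from dysgene import presets, synth
from dysgene.formats import phenotypes_to_frame
from dysgene.synth import (
    CoefficientError,
    DesignCell,
    make_line_genome,
    make_te_library,
    revcomp,
    simulate_long_reads,
    simulate_phenotypes,
    simulate_short_reads,
)


class TestTeLibrary:
    def test_terminal_inverted_repeats(self):
        lib = make_te_library(400, [(31, 200), (200, 369)], 31, seed=1, truncated_structures=())
        c = lib.consensus
        assert c[-31:] == revcomp(c[:31])

    def test_truncated_variant_length_four_equal_exons(self, tiny_library):
        # internal region is 360 bp; keeping exons {0,3} leaves half of it
        # (180 bp) plus both 20-bp TIRs
        seq = tiny_library.variant_seq(frozenset({0, 3}))
        assert len(seq) == 180 + 2 * 20

    def test_same_seed_reproducible(self):
        a = make_te_library(400, [(20, 380)], 20, seed=9, truncated_structures=())
        b = make_te_library(400, [(20, 380)], 20, seed=9, truncated_structures=())
        assert a.consensus == b.consensus

    def test_tir_longer_than_element_rejected(self):
        with pytest.raises(ValueError, match="tir"):
            make_te_library(50, [], 31, seed=1)

    def test_exon_overlapping_tir_rejected(self):
        with pytest.raises(ValueError, match="terminal"):
            make_te_library(400, [(0, 100)], 31, seed=1)


class TestLineGenome:
    def test_no_insertions_identity(self, base_genome, tiny_library):
        line = make_line_genome(base_genome, tiny_library, 0, 0, seed=1)
        assert line.haplotypes[0][0] == base_genome
        assert line.truth.insertions == ()

    def test_length_arithmetic_two_full_copies(self, base_genome, tiny_library):
        # each insertion adds the element plus an 8-bp target-site duplication
        line = make_line_genome(base_genome, tiny_library, 2, 0, seed=2)
        assert len(line.haplotypes[0][0]) == len(base_genome) + 2 * (400 + 8)

    def test_insertion_site_sequence_structure(self, base_genome, tiny_library):
        line = make_line_genome(base_genome, tiny_library, 1, 0, seed=3, tsd_length=8)
        ins = line.truth.insertions[0]
        p = ins.position - 4  # truth records the TSD midpoint
        hap = line.haplotypes[0][0]
        # left flank ends with the duplicated target site, then the element
        left = base_genome[: p + 8]
        assert hap.startswith(left)
        assert hap[len(left) : len(left) + 400] == tiny_library.consensus
        # right side resumes with the duplicated 8-mer
        assert hap[len(left) + 400 : len(left) + 408] == base_genome[p : p + 8]

    def test_zygosity_weights(self, base_genome, tiny_library):
        line = make_line_genome(base_genome, tiny_library, 3, 0, seed=4, zygosity=0.5)
        weights = sorted(w for _, _, w in line.haplotypes)
        assert weights == [0.5, 0.5]
        assert len(line.haplotypes) == 2


class TestShortReads:
    def test_pair_count_arithmetic(self, base_genome, tiny_library):
        line = make_line_genome(base_genome, tiny_library, 0, 0, seed=1)
        sim = simulate_short_reads(line, coverage=30, read_length=150, seed=1)
        assert len(sim.reads) == round(30 * 60_000 / (2 * 150))

    def test_error_free_reads_are_substrings(self, base_genome, tiny_library):
        line = make_line_genome(base_genome, tiny_library, 1, 0, seed=2)
        sim = simulate_short_reads(line, coverage=0.5, error_rate=0.0, seed=3)
        hap = line.haplotypes[0][0]
        for _, r1, r2 in sim.reads[:50]:
            assert r1 in hap
            assert revcomp(r2) in hap

    def test_fixed_seed_byte_identical_fastq(self, base_genome, tiny_library, tmp_path):
        line = make_line_genome(base_genome, tiny_library, 1, 0, seed=2)
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            simulate_short_reads(line, coverage=1, seed=42, fastq_prefix=tmp_path / d / "x")
        assert (tmp_path / "a/x_1.fastq").read_bytes() == (tmp_path / "b/x_1.fastq").read_bytes()
        assert (tmp_path / "a/x_2.fastq").read_bytes() == (tmp_path / "b/x_2.fastq").read_bytes()

    def test_depth_conservation(self, pe_library):
        # mean truth depth over a 100-kb genome tracks requested coverage
        g = synth.random_genome(100_000, 21)
        line = make_line_genome(g, pe_library, 2, 0, seed=21)
        sim = simulate_short_reads(line, coverage=30, seed=21, with_sequences=False)
        total = sum(r.target_end - r.target_start for r in sim.truth)
        mean_depth = total / line.mean_length
        assert abs(mean_depth - 30) / 30 < 0.05

    def test_junction_reads_split_with_clips(self, base_genome, tiny_library):
        """Reads over an insertion junction produce a clipped genome block
        and a clipped element block, like a split-read mapper."""
        line = make_line_genome(base_genome, tiny_library, 1, 0, seed=5)
        sim = simulate_short_reads(line, coverage=30, seed=5, with_sequences=False)
        by_read = {}
        for rec in sim.truth:
            by_read.setdefault((rec.read_id, rec.mate), []).append(rec)
        split = [v for v in by_read.values() if len(v) == 2]
        assert split, "no junction-spanning reads at 30x"
        for a, b in split:
            targets = {a.target_id, b.target_id}
            assert targets == {"TE", line.contig}
            # the two blocks partition the read: one's head clip is the
            # other's aligned span
            assert a.clip_tail + (a.read_end - a.read_start) + a.clip_head == a.read_length
            assert {a.clip_head, a.clip_tail} & {0} or True
            assert a.read_length == b.read_length

    def test_coverage_must_be_positive(self, base_genome, tiny_library):
        line = make_line_genome(base_genome, tiny_library, 0, 0, seed=1)
        with pytest.raises(ValueError, match="coverage"):
            simulate_short_reads(line, coverage=0)


class TestLongReads:
    def test_spanning_reads_have_both_anchors(self, base_genome, tiny_library):
        line = make_line_genome(base_genome, tiny_library, 1, 0, seed=6)
        sim = simulate_long_reads(line, coverage=20, length_mean=8000, seed=6, with_sequences=False)
        by_read = {}
        for rec in sim.truth:
            by_read.setdefault(rec.read_id, []).append(rec)
        spanning = 0
        for recs in by_read.values():
            te = [r for r in recs if r.target_id == "TE"]
            genome = [r for r in recs if r.target_id != "TE"]
            if te and len(genome) == 2:
                spanning += 1
                assert sum(r.target_end - r.target_start for r in te) == 400
        assert spanning > 0

    def test_truncated_copy_truth_covers_only_retained_exons(self, base_genome, tiny_library):
        line = make_line_genome(
            base_genome, tiny_library, 0, 1, truncated_structure=frozenset({0, 3}), seed=7
        )
        sim = simulate_long_reads(line, coverage=30, length_mean=8000, seed=7, with_sequences=False)
        te_recs = sim.truth_for("TE")
        assert te_recs
        cov = np.zeros(400, bool)
        for r in te_recs:
            cov[r.target_start : r.target_end] = True
        ann = tiny_library.annotation
        covered = set(np.flatnonzero(cov))
        allowed = set(range(0, 20)) | set(range(380, 400))
        for i in (0, 3):
            a, b = ann.exons[i]
            allowed |= set(range(a, b))
        assert covered <= allowed
        # internal exons never covered
        for i in (1, 2):
            a, b = ann.exons[i]
            assert not cov[a:b].any()


class TestPhenotypeSimulation:
    def test_zero_coefficients_uniform_ovary_categories(self):
        coeffs = {"ovary0": {}, "ovary1": {}, "ovarioles": {("1",): math.log(20)}}
        recs = simulate_phenotypes(
            [DesignCell("M", "F", 5.0, 10.0, 29.0, 6000)], coeffs, seed=1
        )
        counts = np.bincount([r.ovary_count for r in recs], minlength=3) / len(recs)
        assert np.abs(counts - 1 / 3).max() < 0.03

    def test_poisson_mean_matches_log_mean(self):
        coeffs = {
            "ovary0": {("1",): -30.0},  # always two ovaries
            "ovary1": {("1",): -30.0},
            "ovarioles": {("1",): math.log(20.0)},
        }
        recs = simulate_phenotypes([DesignCell("M", "F", 0, 0, 23.0, 5000)], coeffs, seed=2)
        means = [r.mean_ovarioles for r in recs]
        assert abs(np.mean(means) - 20.0) < 0.2

    def test_dysgenesis_monotone_in_copy_number_only_for_m_mothers_at_29(self):
        design = [
            DesignCell(mg, f"F{pe}", pe, 16.0, t, 400)
            for mg in "MP"
            for pe in (0.0, 5.0, 10.0)
            for t in (23.0, 29.0)
        ]
        df = phenotypes_to_frame(simulate_phenotypes(design, presets.DEFAULT_COEFFS, seed=3))
        m29 = df.query("mother_genotype == 'M' and temperature == 29")
        frac = m29.groupby("father_pe_cn")["dysgenic"].mean()
        assert frac.is_monotonic_increasing and frac.iloc[-1] > frac.iloc[0] + 0.2
        for q in (
            "mother_genotype == 'P' and temperature == 29",
            "temperature == 23",
        ):
            other = df.query(q).groupby("father_pe_cn")["dysgenic"].mean()
            assert other.max() < 0.1

    def test_missing_coefficient_block_is_configuration_error(self):
        with pytest.raises(CoefficientError):
            simulate_phenotypes([DesignCell("M", "F", 0, 0, 23.0, 1)], {"ovary0": {}}, seed=1)

    def test_unknown_variable_is_configuration_error(self):
        coeffs = {"ovary0": {("bogus",): 1.0}, "ovary1": {}, "ovarioles": {("1",): 1.0}}
        with pytest.raises(CoefficientError, match="bogus"):
            simulate_phenotypes([DesignCell("M", "F", 0, 0, 23.0, 1)], coeffs, seed=1)

    def test_fixed_seed_identical_records(self):
        design = [DesignCell("M", "F", 5.0, 10.0, 29.0, 50)]
        a = simulate_phenotypes(design, presets.DEFAULT_COEFFS, seed=9)
        b = simulate_phenotypes(design, presets.DEFAULT_COEFFS, seed=9)
        assert a == b
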