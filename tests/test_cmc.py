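"""CMC amplicon quantification: UMI collapse, anchor matching, rates,
standard normalization, and parameter recovery against the simulator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from psiquant.cmc import (NoDataError, ReadRecord, collapse_by_umi,
                          count_locus, effective_psi, extract_umi,
                          match_anchors, quantify_reads, read_fastq, revcomp,
                          signature_rates)
from psiquant.simulate import CmcSimParams, simulate_cmc_reads, simulate_standard


def brute_force_first_occurrence(records):
    """Quadratic oracle: keep a read iff no earlier read shares its UMI."""
    kept = []
    for i, rec in enumerate(records):
        if not any(prev.umi == rec.umi for prev in records[:i]):
            kept.append(rec)
    return kept


class TestReadFastq:
    def test_file_order_preserved(self, tmp_path):
        path = tmp_path / "two.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nGGCC\n+\nIIII\n")
        reads = list(read_fastq(path))
        assert [r[0] for r in reads] == ["r1", "r2"]
        assert reads[0][1] == "ACGT"

    def test_empty_file_yields_nothing(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        assert list(read_fastq(path)) == []

    @pytest.mark.parametrize("content", [
        "@r1\nACGT\n+\nIII\n",        # quality shorter than sequence
        "@r1\nACGT\n+\n",             # truncated record
    ])
    def test_malformed_record_raises(self, tmp_path, content):
        path = tmp_path / "bad.fastq"
        path.write_text(content)
        with pytest.raises(ValueError):
            list(read_fastq(path))


class TestExtractUmi:
    def test_prefix_umi(self):
        rec = extract_umi(("r", "ACGTACGTAC" + "GGGG"), umi_length=10)
        assert rec.umi == "ACGTACGTAC" and rec.payload == "GGGG"

    def test_offset_retains_head_bases(self):
        rec = extract_umi(("r", "TTACGTACGTACGG"), umi_length=10, umi_offset=2)
        assert rec.umi == "ACGTACGTAC"
        assert rec.payload == "TTGG"

    def test_short_read_raises(self):
        with pytest.raises(ValueError, match="too short"):
            extract_umi(("r", "ACGTACGTA"), umi_length=10)

    def test_quality_sliced_alongside_sequence(self):
        rec = extract_umi(("r", "ACGTACGTACGG", "0123456789AB"), umi_length=10)
        assert rec.quality == "AB"


class TestCollapseByUmi:
    def test_first_occurrence_rule(self):
        recs = [ReadRecord(str(i), u, "P") for i, u in
                enumerate(["A", "B", "A", "C"])]
        kept = collapse_by_umi(recs)
        assert [r.read_id for r in kept] == ["0", "1", "3"]

    def test_all_distinct_is_identity(self):
        recs = [ReadRecord(str(i), f"U{i}", "P") for i in range(10)]
        assert collapse_by_umi(recs) == recs

    def test_matches_quadratic_oracle_and_idempotent(self):
        rng = np.random.default_rng(42)
        umis = ["".join("ACGT"[b] for b in rng.integers(0, 4, 4))
                for _ in range(1000)]
        recs = [ReadRecord(str(i), u, "P") for i, u in enumerate(umis)]
        kept = collapse_by_umi(recs)
        assert kept == brute_force_first_occurrence(recs)
        assert collapse_by_umi(kept) == kept

    @given(st.lists(st.text(alphabet="ACGT", min_size=2, max_size=2), max_size=60))
    def test_property_oracle_equivalence(self, umis):
        recs = [ReadRecord(str(i), u, "P") for i, u in enumerate(umis)]
        assert collapse_by_umi(recs) == brute_force_first_occurrence(recs)


class TestMatchAnchors:
    def test_gap_two(self, target):
        payload = "CC" + target.anchor_up + "GA" + target.anchor_down + "TT"
        m = match_anchors(payload, target)
        assert (m.gap_length, m.gap_sequence, m.orientation) == (2, "GA", "sense")

    def test_gap_three(self, target):
        m = match_anchors(target.anchor_up + "GTG" + target.anchor_down, target)
        assert (m.gap_length, m.gap_sequence) == (3, "GTG")

    def test_single_substitution_disqualifies(self, target):
        up = "T" + target.anchor_up[1:]
        assert match_anchors(up + "GA" + target.anchor_down, target) is None

    def test_revcomp_reported_in_sense_orientation(self, target):
        payload = target.anchor_up + "GTG" + target.anchor_down
        m = match_anchors(revcomp(payload), target)
        assert (m.gap_length, m.gap_sequence, m.orientation) == (3, "GTG", "revcomp")

    def test_gap_above_max_gap_is_no_match(self, target):
        payload = target.anchor_up + "A" * 11 + target.anchor_down
        assert match_anchors(payload, target, max_gap=10) is None
        assert match_anchors(payload, target, max_gap=11).gap_length == 11

    def test_single_anchor_mode_tolerates_one_corrupt_anchor(self, target):
        down_bad = "A" + target.anchor_down[1:]
        if down_bad == target.anchor_down:
            down_bad = "C" + target.anchor_down[1:]
        payload = target.anchor_up + "GA" + down_bad
        assert match_anchors(payload, target) is None
        m = match_anchors(payload, target, single_anchor=True)
        assert m.gap_length == 2

    def test_empty_payload_is_an_error(self, target):
        with pytest.raises(ValueError):
            match_anchors("", target)


class TestCountLocus:
    def make_reads(self, target, gaps_and_middles):
        reads = []
        for i, (gap, middle) in enumerate(gaps_and_middles):
            if gap == 2:
                mid = "GA"
            elif gap == 3:
                mid = "G" + middle + "A"
            else:
                mid = "A" * gap
            reads.append(ReadRecord(str(i), f"U{i:04d}",
                                    target.anchor_up + mid + target.anchor_down))
        return reads

    def test_hand_counted_classification(self, target):
        spec = [(2, None)] * 4 + [(3, "T")] * 5 + [(3, "G")]
        counts = count_locus(self.make_reads(target, spec), target)
        assert (counts.n_del, counts.n_ret_T, counts.n_ret_nonT,
                counts.n_other_gap) == (4, 5, 1, 0)
        assert counts.n_anchor_matched == 10

    def test_other_gap_stays_in_denominator(self, target):
        spec = [(2, None), (5, None), (0, None)]
        counts = count_locus(self.make_reads(target, spec), target)
        assert counts.n_other_gap == 2 and counts.n_anchor_matched == 3
        assert signature_rates(counts)[0] == pytest.approx(1 / 3)

    def test_all_reads_failing_anchors(self, target):
        reads = [ReadRecord("0", "UUUUUUUUUU", "ACGT" * 10)]
        counts = count_locus(reads, target)
        assert counts.n_anchor_matched == 0
        with pytest.raises(NoDataError, match="DEMO1"):
            signature_rates(counts)

    def test_orientation_invariance(self, target):
        spec = [(2, None)] * 3 + [(3, "T")] * 6 + [(3, "C")] * 2 + [(4, None)]
        reads = self.make_reads(target, spec)
        flipped = [dataclasses.replace(r, payload=revcomp(r.payload)) for r in reads]
        a, b = count_locus(reads, target), count_locus(flipped, target)
        assert (a.n_del, a.n_ret_T, a.n_ret_nonT, a.n_other_gap) == \
               (b.n_del, b.n_ret_T, b.n_ret_nonT, b.n_other_gap)

    def test_count_conservation_on_simulated_reads(self, target):
        p = CmcSimParams(psi_fraction=0.5, p_del_psi=0.7, p_del_u=0.05,
                         p_mut_psi=0.1, seq_error=0.02, n_molecules=2000,
                         dup_mean=2.0, seed=17)
        reads, _ = simulate_cmc_reads(target, p)
        records = [extract_umi(r) for r in reads]
        counts = count_locus(collapse_by_umi(records), target)
        counts.validate()  # partition + monotone-stage invariants
        assert counts.n_anchor_matched > 0


class TestRatesAndNormalization:
    def test_rates_from_hand_counts(self, target):
        counts = count_locus(TestCountLocus().make_reads(
            target, [(2, None)] * 4 + [(3, "T")] * 5 + [(3, "G")]), target)
        assert signature_rates(counts) == (pytest.approx(0.4), pytest.approx(0.1))

    @pytest.mark.parametrize("sample, standard, expected", [
        (0.35, 0.70, 0.5), (0.42, 0.42, 1.0), (0.0, 0.5, 0.0),
    ])
    def test_effective_psi_ratio(self, sample, standard, expected):
        value, clamped = effective_psi(sample, standard)
        assert value == pytest.approx(expected) and not clamped

    def test_above_one_unclamped_by_default(self):
        value, clamped = effective_psi(0.9, 0.8)
        assert value == pytest.approx(1.125) and not clamped
        value, clamped = effective_psi(0.9, 0.8, clamp=True)
        assert value == 1.0 and clamped

    def test_failed_standard_is_an_error(self):
        with pytest.raises(ValueError, match="standard"):
            effective_psi(0.3, 0.0)


class TestQuantifyEndToEnd:
    def simulate_pair(self, target, theta, seed=101, **kw):
        p = CmcSimParams(psi_fraction=theta, p_del_psi=0.8, n_molecules=4000,
                         seed=seed, **kw)
        reads, _ = simulate_cmc_reads(target, p)
        std, _ = simulate_standard(target, dataclasses.replace(p, seed=seed + 1),
                                   "psi100")
        return reads, std

    def test_recovers_theta(self, target):
        reads, std = self.simulate_pair(target, 0.5)
        res = quantify_reads(reads, std, target)
        assert res.effective_psi == pytest.approx(0.5, abs=0.04)

    def test_sample_equal_to_standard_gives_exactly_one(self, target):
        _, std = self.simulate_pair(target, 0.5)
        res = quantify_reads(std, std, target)
        assert res.effective_psi == 1.0

    def test_theta_zero_gives_zero(self, target):
        reads, std = self.simulate_pair(target, 0.0)
        res = quantify_reads(reads, std, target)
        assert res.effective_psi == 0.0

    def test_duplicates_do_not_bias(self, target):
        reads, std = self.simulate_pair(target, 0.5, dup_mean=4.0, seq_error=0.01)
        res = quantify_reads(reads, std, target)
        assert res.effective_psi == pytest.approx(0.5, abs=0.05)
        sc = res.sample_counts
        assert sc.n_after_umi < sc.n_input_reads  # duplicates were removed
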