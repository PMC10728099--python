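"""Read assignment, indel filtering, methylation counting, beta values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linemeth.panel import AmpliconPanel, reverse_complement
from linemeth.quant import (
    AssignedRead,
    ConversionEstimate,
    ProbeCounts,
    QuantConfig,
    assign_reads,
    compute_beta,
    count_methylation,
    estimate_conversion_rate,
    filter_indel_reads,
    quantify_sample,
    required_reads,
)
from linemeth.simulate import simulate_reads

CFG = QuantConfig(min_depth=1)


class TestAssignReads:
    def test_watson_template_assigned_with_zero_edits(self, toy_panel):
        watson = toy_panel["P1"].reference_seq.replace("C", "T")
        assigned, n_un = assign_reads([("r1", watson)], toy_panel)
        assert n_un == 0
        (read,) = assigned
        assert (read.probe_id, read.strand) == ("P1", "watson")
        assert read.n_edits == 0

    def test_reverse_complement_of_crick_template(self, toy_panel):
        crick = toy_panel["P1"].reference_seq.replace("G", "A")
        assigned, _ = assign_reads([("r1", reverse_complement(crick))], toy_panel)
        (read,) = assigned
        assert (read.probe_id, read.strand) == ("P1", "crick")

    def test_empty_read_set_yields_empty_output(self, toy_panel):
        assigned, n_un = assign_reads([], toy_panel)
        assert assigned == [] and n_un == 0

    def test_malformed_record_raises_with_index(self, toy_panel):
        with pytest.raises(ValueError, match="index 0"):
            assign_reads([("bad", "ACGT!!")], toy_panel)

    def test_short_reads_dropped(self, toy_panel):
        assigned, n_un = assign_reads([("r", "ACGTACGT")], toy_panel)
        assert assigned == [] and n_un == 1

    def test_simulated_reads_match_truth_labels(self, toy_panel):
        reads, truth = simulate_reads(
            toy_panel, 0.6, conversion_rate=0.99, depth=500, seed=7
        )
        assigned, n_un = assign_reads(reads, toy_panel)
        tmap = {
            row.read_name: (row.probe_id, row.strand)
            for row in truth.itertuples()
        }
        agree = sum(
            1 for r in assigned if tmap[r.read_name] == (r.probe_id, r.strand)
        )
        assert agree / len(reads) >= 0.99
        assert n_un / len(reads) <= 0.01


def _mkread(probe_id, strand, bases, indels=()):
    return AssignedRead(
        probe_id=probe_id,
        strand=strand,
        bases=dict(bases),
        indel_ref_positions=tuple(indels),
        n_edits=0,
    )


class TestIndelFilter:
    def test_indel_inside_target_region_removed(self, toy_panel):
        start, _ = toy_panel["P1"].region
        read = _mkread("P1", "watson", {}, indels=(start,))
        kept, removed = filter_indel_reads([read], toy_panel)
        assert kept == [] and removed == 1

    def test_indel_just_outside_window_retained(self, toy_panel):
        probe = toy_panel["P2"]
        # window is half-open: position region.end + 30 is the first safe one
        read_out = _mkread("P2", "watson", {}, indels=(probe.region[1] + 30,))
        read_in = _mkread("P2", "watson", {}, indels=(probe.region[1] + 29,))
        kept, removed = filter_indel_reads([read_out, read_in], toy_panel, window=30)
        assert [r is read_out for r in kept] == [True]
        assert removed == 1

    def test_counts_match_hand_enumeration(self, toy_panel):
        start, end = toy_panel["P1"].region
        reads = [_mkread("P1", "watson", {}) for _ in range(7)]
        reads += [_mkread("P1", "watson", {}, indels=(start + 1,)) for _ in range(3)]
        kept, removed = filter_indel_reads(reads, toy_panel)
        assert len(kept) == 7 and removed == 3

    def test_order_independent(self, toy_panel):
        start, _ = toy_panel["P1"].region
        reads = [
            _mkread("P1", "watson", {}, indels=(start,)),
            _mkread("P1", "watson", {}),
            _mkread("P1", "watson", {}, indels=(start - 100,)),
        ]
        kept_fwd, _ = filter_indel_reads(reads, toy_panel)
        kept_rev, _ = filter_indel_reads(reads[::-1], toy_panel)
        assert {id(r) for r in kept_fwd} == {id(r) for r in kept_rev}

    def test_negative_window_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="non-negative"):
            filter_indel_reads([], toy_panel, window=-1)


class TestCountMethylation:
    def test_fully_methylated_watson_reads(self, toy_probe):
        off = toy_probe.cpg_offsets()[0]
        reads = [_mkread("P1", "watson", {off: "C"}) for _ in range(10)]
        counts = count_methylation(reads, toy_probe, "cpg_only")
        # only the covered site contributes
        assert (counts.M, counts.U) == (10, 0)
        assert counts.depth == 10

    def test_strand_pooling(self, toy_probe):
        off = toy_probe.cpg_offsets()[0]
        reads = (
            [_mkread("P1", "watson", {off: "C"}) for _ in range(5)]
            + [_mkread("P1", "watson", {off: "T"}) for _ in range(5)]
            + [_mkread("P1", "crick", {off + 1: "G"}) for _ in range(5)]
            + [_mkread("P1", "crick", {off + 1: "A"}) for _ in range(5)]
        )
        counts = count_methylation(reads, toy_probe, "cpg_only")
        assert (counts.M, counts.U) == (10, 10)

    def test_crick_reads_ignore_cpa_sites(self, bundled_panel):
        probe = bundled_panel["P8"]
        cpa = [o for o, c in zip(probe.target_offsets, probe.site_context) if c == "CpA"]
        reads = [_mkread("P8", "crick", {o + 1: "G" for o in cpa})]
        counts = count_methylation(reads, probe, "cpg_and_cpa")
        assert (counts.M, counts.U) == (0, 0)

    def test_simulated_counts_recover_methylation(self, toy_panel):
        reads, _ = simulate_reads(toy_panel, 0.7, conversion_rate=1.0, depth=2500, seed=3)
        assigned, _ = assign_reads(reads, toy_panel)
        probe = toy_panel["P1"]
        p1 = [r for r in assigned if r.probe_id == "P1"]
        counts = count_methylation(p1, probe, "cpg_only")
        assert counts.M / (counts.M + counts.U) == pytest.approx(0.7, abs=0.02)

    def test_probe_without_targets_rejected(self, toy_probe):
        bare = toy_probe.__class__(
            probe_id="P1",
            reference_seq=toy_probe.reference_seq,
            target_offsets=(),
            site_context=(),
            primer_fwd="",
            primer_rev="",
            naive_c_offsets=(),
        )
        with pytest.raises(ValueError, match="no target offsets"):
            count_methylation([], bare, "cpg_only")


class TestConversionRate:
    def test_fully_converted_gives_rate_one(self, toy_panel):
        naive = toy_panel["P1"].naive_c_offsets
        reads = [_mkread("P1", "watson", {o: "T" for o in naive})] * 5
        est = estimate_conversion_rate(reads, toy_panel)
        assert est.rate == 1.0

    def test_two_position_mean(self, toy_panel):
        n0, n1 = toy_panel["P1"].naive_c_offsets[:2]
        # position n0: 49/50 converted; position n1: fully converted
        reads = [_mkread("P1", "watson", {n0: "T", n1: "T"}) for _ in range(49)]
        reads.append(_mkread("P1", "watson", {n0: "C", n1: "T"}))
        est = estimate_conversion_rate(reads, toy_panel)
        assert est.rate == pytest.approx((0.98 + 1.0) / 2)

    def test_no_observations_is_an_error(self, toy_panel):
        with pytest.raises(ValueError, match="conversion rate unavailable"):
            estimate_conversion_rate([], toy_panel)

    def test_simulated_rate_recovered(self, toy_panel):
        reads, _ = simulate_reads(toy_panel, 0.5, conversion_rate=0.99, depth=2500, seed=5)
        assigned, _ = assign_reads(reads, toy_panel)
        est = estimate_conversion_rate(assigned, toy_panel)
        assert est.rate == pytest.approx(0.99, abs=0.005)


class TestComputeBeta:
    @pytest.mark.parametrize(
        "M,U,rate,expected",
        [
            (50, 50, 1.0, 0.5),
            (0, 200, 0.99, 0.0),
            (90, 10, 0.99, 0.891),
        ],
    )
    def test_printed_formula(self, M, U, rate, expected):
        counts = ProbeCounts(probe_id="P1", M=M, U=U, depth=M + U)
        assert compute_beta(counts, rate) == pytest.approx(expected)

    def test_zero_counts_is_missing(self):
        counts = ProbeCounts(probe_id="P1", M=0, U=0, depth=0)
        assert math.isnan(compute_beta(counts, 1.0))

    def test_below_min_depth_is_missing(self):
        counts = ProbeCounts(probe_id="P1", M=10, U=10, depth=20)
        assert math.isnan(compute_beta(counts, 1.0, min_depth=100))

    def test_rate_above_one_rejected(self):
        counts = ProbeCounts(probe_id="P1", M=1, U=1, depth=2)
        with pytest.raises(ValueError):
            compute_beta(counts, 1.2)

    @given(
        M=st.integers(0, 500),
        U=st.integers(0, 500),
        rate=st.floats(0.8, 1.0),
        scale=st.integers(2, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_beta_bounds_monotonicity_scale_invariance(self, M, U, rate, scale):
        if M + U == 0:
            return
        mk = lambda m, u: ProbeCounts(probe_id="P", M=m, U=u, depth=m + u)
        beta = compute_beta(mk(M, U), rate)
        assert 0.0 <= beta <= 1.0
        # monotone in M holding U fixed
        assert compute_beta(mk(M + 1, U), rate) >= beta
        # jointly scale-invariant
        assert compute_beta(mk(M * scale, U * scale), rate) == pytest.approx(beta)


class TestQuantifySample:
    def test_zero_reads_all_missing(self, toy_panel):
        vec = quantify_sample([], toy_panel, CFG, sample_id="empty")
        assert all(math.isnan(b) for b in vec.beta.values())
        assert vec.n_assigned == 0

    def test_recovers_truth_at_full_conversion(self, toy_panel):
        truth = {"P1": 0.9, "P2": 0.6}
        reads, _ = simulate_reads(toy_panel, truth, conversion_rate=1.0, depth=1500, seed=9)
        vec = quantify_sample(reads, toy_panel, CFG)
        for pid, m in truth.items():
            assert vec.beta[pid] == pytest.approx(m, abs=0.02)

    def test_matches_measurement_model_closed_form(self, toy_panel):
        m, c = 0.7, 0.99
        reads, _ = simulate_reads(toy_panel, m, conversion_rate=c, depth=1500, seed=13)
        vec = quantify_sample(reads, toy_panel, CFG)
        expected = (m + (1 - m) * (1 - c)) * c
        for pid in toy_panel.probe_ids:
            assert vec.beta[pid] == pytest.approx(expected, abs=0.02)

    def test_indel_reads_are_removed(self, toy_panel):
        reads, truth = simulate_reads(
            toy_panel, 0.7, conversion_rate=1.0, depth=200, indel_rate=0.3, seed=21
        )
        vec = quantify_sample(reads, toy_panel, CFG)
        assert vec.n_indel_removed > 0
        # beta still accurate after filtering
        for pid in toy_panel.probe_ids:
            assert vec.beta[pid] == pytest.approx(0.7, abs=0.04)


def test_read_budget_for_half_percent_resolution():
    assert required_reads(resolution=0.005, n_loci=2000) == 400_000
    with pytest.raises(ValueError):
        required_reads(resolution=0.0)
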