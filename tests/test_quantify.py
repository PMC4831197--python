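import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bstrace as b
from bstrace.quantify import (
    LOW_SIGNAL,
    OK,
    UNCOVERED,
    EmptyProfileError,
    QuantConfig,
    TraceRejectedError,
)

from conftest import make_flat_trace

# ---------------------------------------------------------------------------
# Alignment


def _score(a, r, match=1.0, mismatch=-1.0):
    if a == "Y":
        return match if r in "CT" else mismatch
    if a == "R":
        return match if r in "GA" else mismatch
    return match if a == r else mismatch


def brute_force_best_score(template, read, match=1.0, mismatch=-1.0, gap=-2.0):
    """Independent oracle: exhaustive scoring over the global-alignment graph."""
    from functools import cache

    @cache
    def rec(i, j):
        if i == len(template) and j == len(read):
            return 0.0
        best = -math.inf
        if i < len(template) and j < len(read):
            best = max(best, _score(template[i], read[j], match, mismatch) + rec(i + 1, j + 1))
        if i < len(template):
            best = max(best, gap + rec(i + 1, j))
        if j < len(read):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def _trace_for_read(read, orientation=b.FORWARD):
    heights = [{base: 100.0} for base in read]
    return make_flat_trace(heights, orientation=orientation)


def test_self_alignment_full_identity(locus10):
    template = b.convert_reference(locus10, b.FORWARD)
    read = template.expected_bases.replace("Y", "C")
    amap = b.align_read(_trace_for_read(read), template)
    assert amap.identity == 1.0
    assert amap.gap_count == 0
    assert amap.template_to_read == {i: i for i in range(len(read))}


def test_internal_deletion_offsets_downstream_cpgs(locus10):
    template = b.convert_reference(locus10, b.FORWARD)
    resolved = template.expected_bases.replace("Y", "T")
    drop = 5  # upstream of all but the first CpG
    read = resolved[:drop] + resolved[drop + 1 :]
    amap = b.align_read(_trace_for_read(read), template)
    for site in locus10.cpg_sites:
        tpos = template.read_position(site)
        if tpos < drop:
            assert amap.template_to_read[tpos] == tpos
        elif tpos > drop:
            assert amap.template_to_read[tpos] == tpos - 1


def test_unrelated_read_is_rejected(locus10):
    template = b.convert_reference(locus10, b.FORWARD)
    with pytest.raises(TraceRejectedError):
        b.align_read(_trace_for_read("A" * len(template.expected_bases)), template)


def test_orientation_mismatch_is_rejected(locus10):
    template = b.convert_reference(locus10, b.REVERSE)
    with pytest.raises(TraceRejectedError):
        b.align_read(_trace_for_read("ACGT", orientation=b.FORWARD), template)


@given(st.data())
def test_alignment_score_matches_enumeration_oracle(data):
    """On toy templates (<= 12 bases) the aligner reaches the enumerated optimum."""
    template_seq = data.draw(
        st.text(alphabet="ACGTYR", min_size=2, max_size=10), label="template"
    )
    read = data.draw(st.text(alphabet="ACGT", min_size=2, max_size=10), label="read")
    cfg = QuantConfig(identity_floor=0.0)
    tmpl = b.ConvertedTemplate("t", b.FORWARD, template_seq, {})
    amap = b.align_read(_trace_for_read(read), tmpl, cfg)
    assert amap.score == pytest.approx(brute_force_best_score(template_seq, read))


# ---------------------------------------------------------------------------
# bin_level


@pytest.mark.parametrize(
    "proportion, level",
    [(0.0, 1), (0.15, 1), (0.2, 1), (0.200001, 2), (0.4, 2), (0.41, 3),
     (0.6, 3), (0.61, 4), (0.8, 4), (0.81, 5), (1.0, 5)],
)
def test_bin_level_intervals(proportion, level):
    assert b.bin_level(proportion) == level


def test_bin_level_exhaustive_grid_monotone():
    grid = np.round(np.arange(0, 1.0001, 0.001), 9)
    levels = [b.bin_level(float(p)) for p in grid]
    # matches the interval rule with half-open bins
    expected = [1 if p <= 0.2 else 2 if p <= 0.4 else 3 if p <= 0.6 else 4 if p <= 0.8 else 5
                for p in grid]
    assert levels == expected
    assert all(b2 >= b1 for b1, b2 in zip(levels, levels[1:]))  # monotone step


@pytest.mark.parametrize("proportion", [-0.1, 1.1])
def test_bin_level_out_of_range(proportion):
    with pytest.raises(ValueError):
        b.bin_level(proportion)


# ---------------------------------------------------------------------------
# call_site on hand-built traces


def _call_single_cpg(h_meth, h_unmeth, orientation):
    locus = b.ReferenceLocus("t", "TACGTT", 0)
    template = b.convert_reference(locus, orientation)
    if orientation == b.FORWARD:
        # read TAYGTT with heights at the CpG position
        heights = [{"T": 100.0}, {"A": 100.0},
                   {"C": h_meth, "T": h_unmeth},
                   {"G": 100.0}, {"T": 100.0}, {"T": 100.0}]
    else:
        # reverse read: AACRTA
        heights = [{"A": 100.0}, {"A": 100.0}, {"C": 100.0},
                   {"G": h_meth, "A": h_unmeth},
                   {"T": 100.0}, {"A": 100.0}]
    trace = make_flat_trace(heights, orientation=orientation)
    amap = b.align_read(trace, template)
    return b.call_site(trace, amap, locus.cpg_sites[0], template)


def test_single_blue_peak_is_homogeneous_methylated():
    call = _call_single_cpg(120.0, 0.0, b.FORWARD)
    assert call.proportion == 1.0 and call.homogeneous and call.qc_pass
    assert call.level == 5


def test_equal_peaks_give_half():
    call = _call_single_cpg(50.0, 50.0, b.FORWARD)
    assert call.proportion == 0.5 and not call.homogeneous
    assert call.level == 3


def test_reverse_primer_reads_g_over_a():
    call = _call_single_cpg(30.0, 70.0, b.REVERSE)
    assert call.proportion == pytest.approx(0.30)
    assert call.level == 2


def test_minor_peak_below_threshold_snaps_to_homogeneous():
    call = _call_single_cpg(5.0, 100.0, b.FORWARD)
    assert call.proportion == 0.0 and call.homogeneous


def test_dead_signal_fails_qc():
    call = _call_single_cpg(0.5, 0.5, b.FORWARD)  # both far below signal floor
    assert call.status == LOW_SIGNAL and not call.qc_pass
    assert call.proportion is None


def test_uncovered_site_is_missing():
    locus = b.ReferenceLocus("t", "TACGTT", 0)
    template = b.convert_reference(locus, b.FORWARD)
    trace = _trace_for_read("TAYGTT".replace("Y", "C"))
    amap = b.align_read(trace, template)
    amap.template_to_read.pop(template.read_position(locus.cpg_sites[0]))
    call = b.call_site(trace, amap, locus.cpg_sites[0], template)
    assert call.status == UNCOVERED and call.proportion is None


def test_call_level_consistent_with_bin_level(locus10):
    design = b.SimulationDesign(
        locus=locus10, true_methylation=np.linspace(0, 1, 10), noise_sd=5.0, seed=2
    )
    trace = b.simulate_trace(design, "s")
    for call in b.call_trace(trace, locus10).calls:
        if call.status == OK:
            assert call.level == b.bin_level(call.proportion)
            if call.homogeneous:
                assert call.proportion in (0.0, 1.0)


# ---------------------------------------------------------------------------
# Exact recovery / strand equivalence on simulated traces

proportions = st.lists(
    st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0]), min_size=3, max_size=3
)


@given(proportions)
def test_noiseless_recovery_both_orientations(locus3, truth):
    for orientation in (b.FORWARD, b.REVERSE):
        design = b.SimulationDesign(
            locus=locus3, true_methylation=truth, orientation=orientation, noise_sd=0.0
        )
        calls = b.call_trace(b.simulate_trace(design, "s"), locus3).calls
        for call, t in zip(calls, truth):
            assert call.proportion == pytest.approx(t, abs=1e-12)


def test_strand_estimates_agree_in_noiseless_limit(locus10):
    truth = np.round(np.linspace(0.1, 0.9, 10), 3)
    estimates = {}
    for orientation in (b.FORWARD, b.REVERSE):
        design = b.SimulationDesign(
            locus=locus10, true_methylation=truth, orientation=orientation, noise_sd=0.0
        )
        calls = b.call_trace(b.simulate_trace(design, "s"), locus10).calls
        estimates[orientation] = [c.proportion for c in calls]
    np.testing.assert_allclose(
        estimates[b.FORWARD], estimates[b.REVERSE], atol=1e-12
    )


# ---------------------------------------------------------------------------
# Conversion QC


def test_conversion_qc_perfect_trace(locus10):
    design = b.SimulationDesign(locus=locus10, true_methylation=[0.5] * 10, noise_sd=0.0)
    result = b.call_trace(b.simulate_trace(design, "s"), locus10)
    assert result.conversion.efficiency == 1.0
    assert result.conversion.qc_pass is True


def test_conversion_qc_not_assessable_without_noncpg_c():
    locus = b.ReferenceLocus("t", "TACGTT", 0)  # single CpG, no other C
    design = b.SimulationDesign(locus=locus, true_methylation=[0.5])
    result = b.call_trace(b.simulate_trace(design, "s"), locus)
    assert not result.conversion.assessable
    assert result.conversion.qc_pass is None


def test_half_converted_trace_fails_qc(locus10):
    # aggregate over traces: binomial(n_positions, 0.5) within 3 sigma
    n_tot = 0
    n_conv = 0
    rng = np.random.default_rng(9)
    for seed in range(10):
        design = b.SimulationDesign(
            locus=locus10,
            true_methylation=[0.5] * 10,
            conversion_failure_rate=0.5,
            noise_sd=0.0,
            seed=int(rng.integers(2**31)),
        )
        result = b.call_trace(b.simulate_trace(design, f"s{seed}"), locus10)
        assert result.conversion.qc_pass is False  # far below the 0.95 threshold
        n_tot += result.conversion.n_positions
        n_conv += result.conversion.n_converted
    assert abs(n_conv / n_tot - 0.5) < 3 * math.sqrt(0.25 / n_tot)


# ---------------------------------------------------------------------------
# profile_locus


def test_profile_shapes_and_exact_columns(locus3):
    truth = [0.0, 0.5, 1.0]
    design = b.SimulationDesign(locus=locus3, true_methylation=truth, noise_sd=0.0)
    traces, _, samples = b.simulate_experiment(design)
    profile = b.profile_locus(
        traces, locus3, groups=dict(samples.itertuples(index=False))
    )
    assert profile.proportions.shape == (3, 3)
    for sample in profile.samples:
        np.testing.assert_allclose(profile.proportions[sample], truth, atol=1e-12)


def test_profile_preserves_missing_cells(locus3):
    design = b.SimulationDesign(locus=locus3, true_methylation=[0.5] * 3, noise_sd=0.0)
    trace = b.simulate_trace(design, "s1")
    # blank out the second CpG's signal in both relevant channels
    template = b.convert_reference(locus3, b.FORWARD)
    pos = trace.peak_positions[template.read_position(locus3.cpg_sites[1])]
    for ch in ("C", "T"):
        trace.channels[ch][pos - 6 : pos + 7] = 0.0
    profile = b.profile_locus([trace], locus3)
    col = profile.proportions["s1"]
    assert math.isnan(col.iloc[1])
    assert not math.isnan(col.iloc[0]) and not math.isnan(col.iloc[2])
    assert profile.status["s1"].iloc[1] == LOW_SIGNAL


def test_profile_excludes_conversion_failures(locus10, caplog):
    good = b.SimulationDesign(locus=locus10, true_methylation=[0.5] * 10, noise_sd=0.0)
    bad = b.SimulationDesign(
        locus=locus10, true_methylation=[0.5] * 10,
        conversion_failure_rate=0.5, noise_sd=0.0, seed=3,
    )
    traces = [b.simulate_trace(good, "good"), b.simulate_trace(bad, "bad")]
    profile = b.profile_locus(traces, locus10)
    assert profile.samples == ["good"]


def test_all_traces_rejected_raises(locus10):
    bad = b.SimulationDesign(
        locus=locus10, true_methylation=[0.5] * 10,
        conversion_failure_rate=0.9, noise_sd=0.0, seed=4,
    )
    with pytest.raises(EmptyProfileError):
        b.profile_locus([b.simulate_trace(bad, "bad")], locus10)
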