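"""Boundary regions, partner location, pair confirmation, mechanism calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taqsv.breakpoints import (
    BoundaryRegion,
    classify_mechanism,
    confirm_discordant_pairs,
    find_boundary_regions,
    call_junctions,
)
from taqsv.evidence import Evidence, empty_pairs
from taqsv.junctions import Junction, Locus
from conftest import truth_junction_keys


def clips_frame(rows):
    return pd.DataFrame(rows, columns=["haplotype", "chrom", "pos", "side", "seq"])


def test_fraction_at_or_below_threshold_is_not_a_region():
    # 9 clips at depth 100 -> fraction 0.09 <= 0.10
    rows = [("A", "c1", 5_000, "R", "ACGT" * 15)] * 9
    ev = Evidence(clips=clips_frame(rows), pairs=empty_pairs(), depth=100)
    assert find_boundary_regions(ev) == []
    # 11 clips -> 0.11 > 0.10
    ev2 = Evidence(clips=clips_frame(rows + rows[:2]), pairs=empty_pairs(), depth=100)
    regions = find_boundary_regions(ev2)
    assert len(regions) == 1 and regions[0].partially_unmapped_fraction > 0.10


def test_clean_genome_zero_regions():
    ev = Evidence(depth=80)
    assert find_boundary_regions(ev) == []


def test_region_fraction_invariant():
    with pytest.raises(ValueError):
        BoundaryRegion("A", "c", 0, 10, "R", 1.5)


def test_noise_only_run_yields_no_junctions(small_ref):
    """Scattered background clips never clear clustering thresholds."""
    from taqsv.simulate import EventSpec, plant_events, simulate_junction_evidence

    spec = EventSpec(n_taqi_tl=0, n_homologous_tl=0, n_bir=0, n_sgc=0,
                     n_aneuploidy_gain=0, n_aneuploidy_loss=0, n_snv=0)
    rg, truth = plant_events(small_ref, spec, seed=2)
    ev = simulate_junction_evidence(rg, truth, small_ref, depth=80, seed=3,
                                    noise_clips_per_kb=0.2)
    assert len(ev.clips) > 0  # background records exist...
    assert call_junctions(ev, small_ref) == []  # ...but none pass thresholds


def test_discordant_pair_orientation():
    pairs = pd.DataFrame(
        [
            ("A", "c1", 9_500, "+", "B", "c2", 20_100, "-"),  # consistent
            ("B", "c2", 20_200, "-", "A", "c1", 9_600, "+"),  # consistent, swapped mates
            ("A", "c1", 9_500, "-", "B", "c2", 20_100, "+"),  # wrong orientation
            ("A", "c1", 30_000, "+", "B", "c2", 20_100, "-"),  # out of window
        ],
        columns=[
            "haplotype_a", "chrom_a", "pos_a", "strand_a",
            "haplotype_b", "chrom_b", "pos_b", "strand_b",
        ],
    )
    ev = Evidence(pairs=pairs, depth=30)
    n = confirm_discordant_pairs(("A", "c1", 10_000), ("B", "c2", 20_000), ev)
    assert n == 2


def make_junction(**kw) -> Junction:
    base = dict(
        locus_a=Locus("A", "c1", 100),
        locus_b=Locus("B", "c2", 200),
        overlap_seq="",
        contains_restriction_site=False,
        repeat_context=(None, None),
    )
    base.update(kw)
    return Junction(**base)


def test_mechanism_priority_rules():
    ty = make_junction(repeat_context=("Ty-like", "Ty-like"), overlap_seq="AC")
    assert classify_mechanism(ty).mechanism == "homologous"
    direct = make_junction(contains_restriction_site=True)
    assert classify_mechanism(direct).mechanism == "taqi_direct"
    mh = make_junction(overlap_seq="AG")
    assert classify_mechanism(mh).mechanism == "microhomology"
    blunt = make_junction()
    assert classify_mechanism(blunt).mechanism == "unclassified"
    # motif presence blocks the microhomology rule even at 2-3 nt overlap
    both = make_junction(overlap_seq="CG", contains_restriction_site=True)
    assert classify_mechanism(both).mechanism == "taqi_direct"


@given(
    ov=st.integers(0, 6),
    motif=st.booleans(),
    rep_a=st.sampled_from([None, "Ty-like", "rDNA"]),
    rep_b=st.sampled_from([None, "Ty-like", "rDNA"]),
    deleted=st.integers(0, 3),
)
@settings(max_examples=300, deadline=None)
def test_exactly_one_rule_fires(ov, motif, rep_a, rep_b, deleted):
    j = make_junction(
        overlap_seq="A" * ov,
        contains_restriction_site=motif,
        repeat_context=(rep_a, rep_b),
        deleted_a=deleted,
    )
    call = classify_mechanism(j)
    fired = {
        "homologous": rep_a is not None and rep_a == rep_b,
        "taqi_direct": motif and deleted == 0,
        "microhomology": 2 <= ov <= 3 and not motif,
    }
    expected = next(
        (m for m in ("homologous", "taqi_direct", "microhomology") if fired[m]),
        "unclassified",
    )
    assert call.mechanism == expected


def test_round_trip_junctions_base_exact(study_case, study_result):
    """Noise-free round trip: every planted junction, base-exact, mechanism-true."""
    truth = truth_junction_keys(study_case)
    calls = {
        j.junction.canonical_key(): j.mechanism.mechanism for j in study_result.junctions
    }
    assert set(truth) == set(calls)
    for key, mech in truth.items():
        assert calls[key] == mech


def test_reciprocal_best_hit_holds_for_unique_junctions(study_result):
    for call in study_result.junctions:
        if call.mechanism.mechanism == "taqi_direct":
            assert call.reciprocal


def test_pair_support_meets_minimum(study_result):
    assert all(c.n_pairs >= 2 for c in study_result.junctions)
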