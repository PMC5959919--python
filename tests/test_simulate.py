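"""Simulator contracts: mechanism-faithful edits, truth audit, derived data."""

import numpy as np
import pytest

from taqsv.genome import scan_restriction_sites
from taqsv.junctions import build_junction, repeat_lookup
from taqsv.simulate import (
    EventSpec,
    RepeatSpec,
    plant_events,
    simulate_acgh,
    simulate_coordinate_model,
    simulate_coverage,
    simulate_junction_evidence,
    simulate_parental_pair,
)

ZERO_SPEC = EventSpec(
    n_taqi_tl=0,
    n_homologous_tl=0,
    n_bir=0,
    n_sgc=0,
    n_aneuploidy_gain=0,
    n_aneuploidy_loss=0,
    n_snv=0,
    n_indel=0,
)


def _sequences(dual_ref):
    return {
        (h.name, c): s
        for h in (dual_ref.haplome_a, dual_ref.haplome_b)
        for c, s in h.chromosomes.items()
    }


def test_zero_divergence_gives_identical_haplomes():
    ref = simulate_parental_pair(
        [50_000],
        snp_per_kb=0,
        indel_per_kb=0,
        repeat_spec=RepeatSpec(ty_copies=0, rdna_copies=0, transposon_copies=0),
        seed=0,
    )
    assert ref.haplome_a.chromosomes == ref.haplome_b.chromosomes
    assert ref.variants == []


def test_repeat_copies_near_identical(small_ref):
    """Dispersed same-family copies keep >=99% pairwise identity."""
    ty = [r for r in small_ref.haplome_a.repeats if r.family == "Ty-like"]
    assert len(ty) == 2
    seqs = [small_ref.haplome_a.chromosomes[r.chrom][r.start : r.end] for r in ty]
    ident = np.mean([a == b for a, b in zip(*seqs)])
    assert ident >= 0.97  # two copies, each ~1% diverged from the master


def test_zero_event_spec_is_identity(small_ref):
    rg, truth = plant_events(small_ref, ZERO_SPEC, seed=3)
    assert truth.events == []
    for hap in (small_ref.haplome_a, small_ref.haplome_b):
        for chrom, seq in hap.chromosomes.items():
            assert rg.copies[f"{hap.name}_{chrom}"].seq == seq


def test_same_seed_byte_identical(small_ref):
    spec = EventSpec(n_taqi_tl=1, n_homologous_tl=0, n_bir=1, n_sgc=2,
                     n_aneuploidy_gain=0, n_aneuploidy_loss=0)
    rg1, t1 = plant_events(small_ref, spec, seed=9)
    rg2, t2 = plant_events(small_ref, spec, seed=9)
    assert {n: c.seq for n, c in rg1.copies.items()} == {n: c.seq for n, c in rg2.copies.items()}
    assert [e.event_id for e in t1.events] == [e.event_id for e in t2.events]
    assert t1.metadata["seed"] == 9


def test_truth_invariants_audited_from_sequences(study_case):
    """Mechanism signatures hold on the emitted sequences, not just labels."""
    dual_ref = study_case.dual_ref
    sequences = _sequences(dual_ref)
    repeats = repeat_lookup(
        {dual_ref.haplome_a.name: dual_ref.haplome_a, dual_ref.haplome_b.name: dual_ref.haplome_b}
    )
    site_sets = {
        h.name: scan_restriction_sites(h).sites for h in (dual_ref.haplome_a, dual_ref.haplome_b)
    }
    for event in study_case.truth.by_type("TL", "deletion", "tandem_duplication"):
        for junc in event.junctions:
            rebuilt = build_junction(
                sequences, junc.locus_a.key(), junc.locus_b.key(), repeats=repeats
            )
            if event.mechanism == "taqi_direct":
                assert rebuilt.contains_restriction_site
                assert rebuilt.net_deleted == 0
            elif event.mechanism == "microhomology":
                assert 2 <= rebuilt.overlap_len <= 3
                assert not rebuilt.contains_restriction_site
            elif event.mechanism == "homologous":
                fa, fb = rebuilt.repeat_context
                assert fa is not None and fa == fb


def test_sgc_lengths_within_bounds(study_case):
    lengths = [e.length for e in study_case.truth.by_type("SGC")]
    assert len(lengths) == 40
    assert all(700 <= l <= 30_000 for l in lengths)


def test_coverage_flat_without_events(small_ref):
    rg, truth = plant_events(small_ref, ZERO_SPEC, seed=3)
    tracks = simulate_coverage(rg, small_ref, mean_depth=50, noise="none", seed=0)
    for track in tracks.values():
        for chrom, vals in track.values.items():
            assert np.allclose(vals, 50.0)


def test_sgc_coverage_signature(small_ref):
    """Acceptor depth 0 and donor depth 2x over the converted tract."""
    spec = EventSpec(n_taqi_tl=0, n_homologous_tl=0, n_bir=0, n_sgc=1,
                     n_aneuploidy_gain=0, n_aneuploidy_loss=0, n_snv=0)
    rg, truth = plant_events(small_ref, spec, seed=4)
    ev = truth.by_type("SGC")[0]
    tracks = simulate_coverage(rg, small_ref, mean_depth=80, noise="none", seed=0)
    bs = 100
    s_bin, e_bin = ev.interval[0] // bs + 1, ev.interval[1] // bs - 1
    acc = tracks[ev.haplotype].values[ev.chrom][s_bin:e_bin]
    assert np.allclose(acc, 0.0)
    dchrom = ev.donor_chrom
    dual = small_ref
    ds = dual.lift_pos(ev.haplotype, ev.chrom, ev.interval[0]) // bs + 1
    de = dual.lift_pos(ev.haplotype, ev.chrom, ev.interval[1]) // bs - 1
    don = tracks[ev.donor_haplotype].values[dchrom][ds:de]
    assert np.allclose(don, 160.0)


def test_trisomy_mean_ratio(small_ref):
    spec = EventSpec(n_taqi_tl=0, n_homologous_tl=0, n_bir=0, n_sgc=0,
                     n_aneuploidy_gain=1, n_aneuploidy_loss=0, n_snv=0)
    rg, truth = plant_events(small_ref, spec, seed=5)
    ev = truth.by_type("aneuploidy_gain")[0]
    tracks = simulate_coverage(rg, small_ref, mean_depth=80, noise="none", seed=0)
    gained = tracks[ev.haplotype].values[ev.chrom]
    med = np.median(np.concatenate([t.unmasked_values() for t in tracks.values()]))
    # (2+1)/2 per homolog pair: the gained haplotype copy doubles
    assert np.isclose(np.median(gained) / med, 2.0, rtol=0.01)


def test_copy_number_conservation(study_case):
    """Planted gains minus losses equal the integral of (track - baseline)."""
    truth, rg, dual = study_case.truth, study_case.restructured, study_case.dual_ref
    expected = 0
    for e in truth.by_type("aneuploidy_gain"):
        expected += dual.haplome(e.haplotype).length(e.chrom)
    for e in truth.by_type("aneuploidy_loss"):
        expected -= dual.haplome(e.haplotype).length(e.chrom)
    for e in truth.by_type("BIR", "SGC"):
        expected += (
            dual.lift_pos(e.haplotype, e.chrom, e.interval[1])
            - dual.lift_pos(e.haplotype, e.chrom, e.interval[0])
        ) - (e.interval[1] - e.interval[0])
    total = 0
    for hap in (dual.haplome_a, dual.haplome_b):
        for chrom, length in hap.chrom_lengths.items():
            cn = rg.copy_number_per_bp(hap.name, chrom, length)
            total += int(cn.sum()) - length
    assert total == expected


def test_acgh_closed_forms(small_ref):
    rg, _ = plant_events(small_ref, ZERO_SPEC, seed=3)
    arr = simulate_acgh(rg, small_ref, noise_sd=0.0, seed=0)
    assert abs(arr["log10_ratio"].mean()) < 1e-12
    # tetraploid losing one copy: log10(3/4)
    arr4 = simulate_acgh(rg, small_ref, noise_sd=0.0, baseline_ploidy=2, seed=0)
    assert np.allclose(arr4["log10_ratio"], 0.0)
    spec = EventSpec(n_taqi_tl=0, n_homologous_tl=0, n_bir=0, n_sgc=0,
                     n_aneuploidy_gain=0, n_aneuploidy_loss=1, n_snv=0)
    rg2, truth = plant_events(small_ref, spec, seed=6)
    ev = truth.by_type("aneuploidy_loss")[0]
    arr2 = simulate_acgh(rg2, small_ref, noise_sd=0.0, seed=0)
    chrom_a = ev.chrom if ev.haplotype == "A" else small_ref.pairing_rev[ev.chrom]
    med = arr2.loc[arr2["chrom"] == chrom_a, "log10_ratio"].median()
    assert np.isclose(med, np.log10(0.5), atol=1e-9)


def test_junction_evidence_depth_zero(study_case):
    ev = simulate_junction_evidence(
        study_case.restructured, study_case.truth, study_case.dual_ref, depth=0, seed=0
    )
    assert len(ev.clips) == 0 and len(ev.pairs) == 0


def test_junction_evidence_read_len_guard(study_case):
    with pytest.raises(ValueError, match="read length"):
        simulate_junction_evidence(
            study_case.restructured, study_case.truth, study_case.dual_ref, read_len=40, seed=0
        )


def test_clipped_tails_match_partner_locus(study_case):
    """Each clip tail is a verbatim copy of partner-side sequence."""
    sequences = _sequences(study_case.dual_ref)
    juncs = {
        (j.locus_a.haplotype, j.locus_a.chrom): j for j in study_case.truth.junctions()
    }
    clips = study_case.evidence.clips
    checked = 0
    for j in study_case.truth.junctions()[:6]:
        ha, ca, pa = j.locus_a.key()
        ov = j.overlap_len
        sel = clips[(clips.haplotype == ha) & (clips.chrom == ca) & (clips.pos == pa + ov) & (clips.side == "R")]
        for seq in sel["seq"].head(3):
            hb, cb, pb = j.locus_b.key()
            assert sequences[(hb, cb)][pb + ov : pb + ov + len(seq)] == seq
            checked += 1
    assert checked > 0


def test_coordinate_model_confined_to_nucleus(small_ref):
    model = simulate_coordinate_model(small_ref, nuclear_diameter_um=2.0, seed=0)
    for chrom, (pos, xyz) in model.anchors.items():
        assert np.all(np.linalg.norm(xyz, axis=1) <= 1.0 + 1e-9)
    assert model.pair_distance(("chr01", 0), ("chr01", 0)) == 0.0


def test_coordinate_model_invalid_diameter(small_ref):
    with pytest.raises(ValueError):
        simulate_coordinate_model(small_ref, nuclear_diameter_um=-1, seed=0)


def test_cnv_boundary_junctions_and_detection():
    """Deletions/duplications: planted junction signatures hold and the
    depth segmentation plus junction scan recover them."""
    from taqsv.breakpoints import call_junctions
    from taqsv.cnv import combine_haplotype_ratios, normalize_coverage, segment_local_cnv
    from taqsv.simulate import RepeatSpec

    ref = simulate_parental_pair(
        [120_000] * 4, seed=9,
        repeat_spec=RepeatSpec(ty_copies=2, rdna_copies=1, transposon_copies=2),
    )
    for mh_frac, mech in ((1.0, "microhomology"), (0.0, "taqi_direct")):
        spec = EventSpec(
            n_taqi_tl=0, n_homologous_tl=0, n_bir=0, n_sgc=0,
            n_aneuploidy_gain=0, n_aneuploidy_loss=0, n_snv=0,
            n_large_deletion=2, n_tandem_duplication=1,
            deletion_len_range=(15_000, 30_000), microhomology_fraction=mh_frac,
        )
        rg, truth = plant_events(ref, spec, seed=3)
        for e in truth.events:
            assert e.mechanism == mech
            for j in e.junctions:
                if mech == "microhomology":
                    assert 2 <= j.overlap_len <= 3 and not j.contains_restriction_site
                else:
                    assert j.contains_restriction_site and j.net_deleted == 0
        tracks = simulate_coverage(rg, ref, noise="none", seed=0)
        ratio = {h: normalize_coverage(t) for h, t in tracks.items()}
        comb = combine_haplotype_ratios(ratio["A"], ratio["B"], ref.pairing)
        segs = segment_local_cnv(comb, min_length=5_000)
        assert len(segs) == 3
        directions = sorted(c.direction for c in segs)
        assert directions == ["gain", "loss", "loss"]
        ev = simulate_junction_evidence(rg, truth, ref, seed=1)
        calls = call_junctions(ev, ref)
        truth_keys = {j.canonical_key() for j in truth.junctions()}
        assert {c.junction.canonical_key() for c in calls} == truth_keys
        assert all(c.mechanism.mechanism == mech for c in calls)
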