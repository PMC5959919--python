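"""Dual-reference model: site scanning, variant map, liftover."""

import numpy as np
import pytest

from taqsv.genome import (
    DualReference,
    Haplome,
    build_variant_map,
    scan_restriction_sites,
)


def brute_force_sites(seq: str, motif: str) -> list[int]:
    k = len(motif)
    return [i for i in range(len(seq) - k + 1) if seq[i : i + k] == motif]


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("TCGA", [0]),
        ("TGCAT", []),
        ("TCGATCGA", [0, 4]),
        ("TCGTCGA", [3]),
        ("TCNGA", []),  # N never matches
    ],
)
def test_scan_sites_examples(seq, expected):
    hap = Haplome(name="h", chromosomes={"c": seq})
    idx = scan_restriction_sites(hap)
    assert list(idx.sites["c"]) == expected


def test_scan_sites_matches_brute_force_oracle(rng):
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        hap = Haplome(name="h", chromosomes={"c": seq})
        idx = scan_restriction_sites(hap)
        assert list(idx.sites["c"]) == brute_force_sites(seq, "TCGA")


def test_site_density_near_one_per_256bp(rng):
    """A 4-bp motif hits an i.i.d. uniform sequence once per 4^4 = 256 bp."""
    n = 1_000_000
    seq = "".join(rng.choice(list("ACGT"), size=n))
    hap = Haplome(name="h", chromosomes={"c": seq})
    idx = scan_restriction_sites(hap)
    p = 1.0 / 256.0
    sd = np.sqrt(n * p * (1 - p))
    assert abs(idx.n_sites() - n * p) < 3 * sd


def test_non_palindromic_motif_requires_both_strands():
    hap = Haplome(name="h", chromosomes={"c": "GAATTCGGATCC"})
    with pytest.raises(ValueError, match="palindromic"):
        scan_restriction_sites(hap, motif="GGATCG")
    idx = scan_restriction_sites(hap, motif="GGATCC", both_strands=True)
    assert idx.n_sites() == 1


def test_variant_map_identical_sequences():
    seq = "ACGT" * 2500
    a = Haplome(name="A", chromosomes={"c": seq})
    b = Haplome(name="B", chromosomes={"c": seq})
    ref = build_variant_map(a, b, {"c": (seq, seq)})
    assert ref.variants == []
    assert ref.variant_density_per_kb()["c"] == 0.0


def test_variant_map_single_substitution():
    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=200))
    alt = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
    a = Haplome(name="A", chromosomes={"c": seq})
    b = Haplome(name="B", chromosomes={"c": alt})
    ref = build_variant_map(a, b, {"c": (seq, alt)})
    assert len(ref.variants) == 1
    v = ref.variants[0]
    assert (v.pos_a, v.pos_b, v.kind) == (100, 100, "SNV")


def test_variant_map_indel_and_liftover():
    """A 3-bp deletion in B shifts all downstream homolog coordinates by -3."""
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    alt = seq[:100] + seq[103:]
    ga = seq
    gb = seq[:100] + "---" + seq[103:]
    a = Haplome(name="A", chromosomes={"c": seq})
    b = Haplome(name="B", chromosomes={"c": alt})
    ref = build_variant_map(a, b, {"c": (ga, gb)})
    indels = [v for v in ref.variants if v.kind == "InDel"]
    assert len(indels) == 1 and indels[0].net_indel == -3
    assert ref.liftover("A", "c", (10, 50)) == ("c", 10, 50)
    assert ref.liftover("A", "c", (150, 200)) == ("c", 147, 197)
    # whole chromosome maps to whole homolog
    assert ref.liftover("A", "c", (0, 300)) == ("c", 0, 297)


def test_liftover_is_its_own_inverse(small_ref: DualReference):
    rng = np.random.default_rng(7)
    name_a = small_ref.haplome_a.name
    for chrom, length in small_ref.haplome_a.chrom_lengths.items():
        for _ in range(20):
            s = int(rng.integers(0, length - 1000))
            e = s + int(rng.integers(100, 1000))
            hc, hs, he = small_ref.liftover(name_a, chrom, (s, e))
            _, rs, re_ = small_ref.liftover(small_ref.haplome_b.name, hc, (hs, he))
            # round trip contains the original up to InDel ambiguity
            assert rs - 12 <= s and e <= re_ + 12


def test_liftover_unpaired_chromosome_errors(small_ref):
    with pytest.raises(KeyError):
        small_ref.homolog_chrom("A", "nope")


def test_simulated_divergence_recovers_generator_densities():
    """Observed densities within 10% of the 6.5/0.7 per-kb settings.

    Repeat-free pair: the generator routes InDels around repeat
    annotations, so repeats would bias the genome-wide InDel density.
    """
    from taqsv.simulate import RepeatSpec, simulate_parental_pair

    ref = simulate_parental_pair(
        [500_000, 500_000],
        repeat_spec=RepeatSpec(ty_copies=0, rdna_copies=0, transposon_copies=0),
        seed=21,
    )
    snv = np.mean(list(ref.variant_density_per_kb("SNV").values()))
    indel = np.mean(list(ref.variant_density_per_kb("InDel").values()))
    assert abs(snv - 6.5) / 6.5 < 0.10
    assert abs(indel - 0.7) / 0.7 < 0.10


def test_overlapping_variant_records_rejected():
    seq = "ACGTACGTAC"
    a = Haplome(name="A", chromosomes={"c": seq})
    b = Haplome(name="B", chromosomes={"c": seq})
    with pytest.raises(ValueError, match="span"):
        build_variant_map(a, b, {"c": (seq[:-1], seq[:-1])})
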