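"""Synthetic restriction-enzyme-induced genome restructuring.

Generates a fused hybrid of two diverged parental haplomes, plants
mechanism-faithful rearrangements (direct religation at cut sites,
microhomology joins, repeat-mediated recombination, break-induced
repair, short gene conversion, aneuploidy), and emits the derived data
every caller consumes: per-haplotype coverage tracks, aCGH probe
ratios, soft-clip/discordant junction evidence, and a 3D coordinate
model.  Each planted edit is audited at the sequence level against the
truth invariants (motif reconstitution with zero loss at direct joins,
exact 2–3 nt overlaps without a spanning site at microhomology joins,
same-family repeat flanks at recombination joins).

Default condition values follow the study system this emulates: parental
divergence 6.5 SNPs/kb + 0.7 InDels/kb (~0.72%), ~200 DSBs per cell of
which only a sampled handful resolve into recorded events, gene
conversions 0.7–30 kb, sequencing depth 80x (reported range 73–254x),
2 x 300 bp reads, a ~2 µm nuclear diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import Evidence, empty_clips, empty_pairs
from .genome import (
    DEFAULT_MOTIF,
    DualReference,
    Haplome,
    RepeatFeature,
    RestrictionSiteIndex,
    Variant,
    scan_restriction_sites,
)
from .junctions import Junction, build_junction, repeat_lookup
from .proximity import CoordinateModel
from .tracks import CoverageTrack, array_track

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# specs


@dataclass
class RepeatSpec:
    """Repeat families planted into the ancestral genome."""

    ty_copies: int = 12
    ty_length: int = 5_000
    rdna_copies: int = 2
    rdna_unit: int = 9_000
    transposon_copies: int = 5
    transposon_length: int = 2_000
    copy_divergence: float = 0.01  # per-base substitutions per dispersed copy


@dataclass
class EventSpec:
    """Counts and shape parameters of planted rearrangement events.

    TL counts default to the observed yeast spectrum (6 direct-join, 3
    repeat-mediated), BIR/SGC to 10/40, one gained and one lost
    chromosome.  Gene-conversion lengths are log-uniform on 0.7–30 kb.
    ``microhomology_fraction`` sets the share of CNV-boundary junctions
    (deletions/duplications) joined by 2–3 nt microhomology instead of
    direct religation at cut sites.
    """

    n_taqi_tl: int = 6
    n_homologous_tl: int = 3
    n_bir: int = 10
    n_sgc: int = 40
    n_aneuploidy_gain: int = 1
    n_aneuploidy_loss: int = 1
    n_large_deletion: int = 0
    n_tandem_duplication: int = 0
    n_snv: int = 1
    n_indel: int = 0
    sgc_len_range: tuple[float, float] = (700.0, 30_000.0)
    deletion_len_range: tuple[float, float] = (150_000.0, 400_000.0)
    microhomology_fraction: float = 0.31
    dsb_mean: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "n_taqi_tl",
            "n_homologous_tl",
            "n_bir",
            "n_sgc",
            "n_aneuploidy_gain",
            "n_aneuploidy_loss",
            "n_large_deletion",
            "n_tandem_duplication",
            "n_snv",
            "n_indel",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def total_events(self) -> int:
        return (
            self.n_taqi_tl
            + self.n_homologous_tl
            + self.n_bir
            + self.n_sgc
            + self.n_aneuploidy_gain
            + self.n_aneuploidy_loss
            + self.n_large_deletion
            + self.n_tandem_duplication
            + self.n_snv
            + self.n_indel
        )


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class Segment:
    """A forward-strand slice of one parental chromosome."""

    haplotype: str
    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DerivedChromosome:
    name: str
    segments: list[Segment]
    seq: str = ""


@dataclass
class RestructuredGenome:
    """The rearranged cell genome as derived chromosome copies."""

    copies: dict[str, DerivedChromosome]

    def copy_number_per_bp(self, haplotype: str, chrom: str, length: int) -> np.ndarray:
        delta = np.zeros(length + 1, dtype=np.int32)
        for copy in self.copies.values():
            for seg in copy.segments:
                if seg.haplotype == haplotype and seg.chrom == chrom:
                    delta[seg.start] += 1
                    delta[seg.end] -= 1
        return np.cumsum(delta[:-1])


@dataclass
class TruthEvent:
    event_id: str
    type: str  # TL | BIR | SGC | aneuploidy_gain | aneuploidy_loss | deletion | tandem_duplication | SNV | InDel
    mechanism: str | None = None
    haplotype: str | None = None
    chrom: str | None = None
    interval: tuple[int, int] | None = None
    donor_haplotype: str | None = None
    donor_chrom: str | None = None
    length: int | None = None
    repeat_family: str | None = None
    junctions: list[Junction] = field(default_factory=list)


@dataclass
class TruthSet:
    events: list[TruthEvent]
    metadata: dict = field(default_factory=dict)

    def by_type(self, *types: str) -> list[TruthEvent]:
        return [e for e in self.events if e.type in types]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.type] = out.get(e.type, 0) + 1
        return out

    def junctions(self) -> list[Junction]:
        return [j for e in self.events for j in e.junctions]


# ---------------------------------------------------------------------------
# parental pair


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _mutate_copy(rng: np.random.Generator, master: np.ndarray, rate: float) -> np.ndarray:
    out = master.copy()
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


def simulate_parental_pair(
    chrom_lengths: dict[str, int] | list[int],
    snp_per_kb: float = 6.5,
    indel_per_kb: float = 0.7,
    repeat_spec: RepeatSpec | None = None,
    seed: int = 0,
    telomere_len: int = 5_000,
    centromere_halfwidth: int = 500,
    haplotype_names: tuple[str, str] = ("A", "B"),
    max_indel: int = 10,
) -> DualReference:
    """Two diverged haplomes with planted repeat families and annotations.

    Haplome A is the ancestor; haplome B derives from it by planting
    SNVs and short InDels at the requested densities (InDels are routed
    around repeat annotations so dispersed copies keep a common length).
    Liftover anchors are laid at every InDel, making coordinate
    correspondence exact outside the InDels themselves.
    """
    if snp_per_kb < 0 or indel_per_kb < 0:
        raise ValueError("divergence densities must be >= 0")
    if isinstance(chrom_lengths, list):
        chrom_lengths = {f"chr{i + 1:02d}": l for i, l in enumerate(chrom_lengths)}
    if not chrom_lengths:
        raise ValueError("at least one chromosome required")
    if (snp_per_kb + indel_per_kb) / 1000.0 > 0.05:
        warnings.warn("divergence above 5%: homolog pairing may be ambiguous", stacklevel=2)
    repeat_spec = repeat_spec or RepeatSpec()
    rng = np.random.default_rng(seed)
    name_a, name_b = haplotype_names

    arrays = {c: _random_seq(rng, l) for c, l in chrom_lengths.items()}
    repeats_a = _plant_repeats(rng, arrays, repeat_spec, telomere_len)

    chroms_a: dict[str, str] = {}
    chroms_b: dict[str, str] = {}
    variants: list[Variant] = []
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    repeats_b: list[RepeatFeature] = []
    cent_a: dict[str, tuple[int, int]] = {}
    cent_b: dict[str, tuple[int, int]] = {}
    telo_a: dict[str, list[tuple[int, int]]] = {}
    telo_b: dict[str, list[tuple[int, int]]] = {}

    for chrom, arr in arrays.items():
        length = len(arr)
        seq_a = _decode(arr)
        chroms_a[chrom] = seq_a
        rep_ivs = [(r.start, r.end) for r in repeats_a if r.chrom == chrom]

        snv_pos = np.flatnonzero(rng.random(length) < snp_per_kb / 1000.0)
        indel_pos = np.flatnonzero(rng.random(length) < indel_per_kb / 1000.0)
        indel_pos = np.array(
            [p for p in indel_pos if not _in_any(p, rep_ivs, pad=max_indel + 2)],
            dtype=np.int64,
        )
        events: list[tuple[int, str]] = [(int(p), "SNV") for p in snv_pos]
        events += [(int(p), "InDel") for p in indel_pos]
        events.sort()
        # drop events closer than the max indel footprint to keep records disjoint
        cleaned: list[tuple[int, str]] = []
        last_end = -1
        for pos, kind in events:
            if pos <= last_end:
                continue
            cleaned.append((pos, kind))
            last_end = pos + (max_indel + 1 if kind == "InDel" else 0)

        parts: list[str] = []
        anc_a = [0]
        anc_b = [0]
        cur_a = 0
        pos_b = 0
        for pos, kind in cleaned:
            parts.append(seq_a[cur_a:pos])
            pos_b += pos - cur_a
            if kind == "SNV":
                old = seq_a[pos]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                variants.append(Variant(chrom, pos, chrom, pos_b, "SNV", old, new))
                parts.append(new)
                cur_a = pos + 1
                pos_b += 1
            else:
                size = int(rng.integers(1, max_indel + 1))
                if rng.random() < 0.5 and pos + 1 + size <= length:  # deletion in B
                    ref = seq_a[pos : pos + 1 + size]
                    alt = seq_a[pos]
                    parts.append(seq_a[pos])
                    variants.append(Variant(chrom, pos, chrom, pos_b, "InDel", ref, alt))
                    anc_a += [pos, pos + 1 + size]
                    anc_b += [pos_b, pos_b + 1]
                    cur_a = pos + 1 + size
                    pos_b += 1
                else:  # insertion in B
                    ins = _decode(_random_seq(rng, size))
                    ref = seq_a[pos]
                    alt = seq_a[pos] + ins
                    parts.append(alt)
                    variants.append(Variant(chrom, pos, chrom, pos_b, "InDel", ref, alt))
                    anc_a += [pos, pos + 1]
                    anc_b += [pos_b, pos_b + 1 + size]
                    cur_a = pos + 1
                    pos_b += 1 + size
        parts.append(seq_a[cur_a:])
        pos_b += length - cur_a
        seq_b = "".join(parts)
        assert len(seq_b) == pos_b
        anc_a.append(length)
        anc_b.append(pos_b)
        aa = np.array(anc_a, dtype=np.int64)
        ab = np.array(anc_b, dtype=np.int64)
        keep = np.concatenate(([True], (np.diff(aa) > 0) & (np.diff(ab) > 0)))
        anchors[chrom] = (aa[keep], ab[keep])
        chroms_b[chrom] = seq_b

        mid = length // 2
        cent_a[chrom] = (mid - centromere_halfwidth, mid + centromere_halfwidth)
        telo_a[chrom] = [(0, min(telomere_len, length)), (max(0, length - telomere_len), length)]

    haplome_a = Haplome(
        name=name_a,
        chromosomes=chroms_a,
        centromeres=cent_a,
        telomere_masks=telo_a,
        repeats=repeats_a,
    )
    # B annotations via provisional liftover
    provisional = DualReference(
        haplome_a=haplome_a,
        haplome_b=Haplome(name=name_b, chromosomes=chroms_b),
        variants=[],
        pairing={c: c for c in chroms_a},
        anchors=anchors,
    )
    for chrom in chroms_a:
        lb = len(chroms_b[chrom])
        s, e = cent_a[chrom]
        cent_b[chrom] = (
            provisional.lift_pos(name_a, chrom, s),
            provisional.lift_pos(name_a, chrom, e),
        )
        telo_b[chrom] = [
            (0, min(telomere_len, lb)),
            (max(0, lb - telomere_len), lb),
        ]
    for r in repeats_a:
        repeats_b.append(
            RepeatFeature(
                chrom=r.chrom,
                start=provisional.lift_pos(name_a, r.chrom, r.start),
                end=provisional.lift_pos(name_a, r.chrom, r.end),
                family=r.family,
                name=r.name + "_B" if r.name else "",
            )
        )
    haplome_b = Haplome(
        name=name_b,
        chromosomes=chroms_b,
        centromeres=cent_b,
        telomere_masks=telo_b,
        repeats=repeats_b,
    )
    return DualReference(
        haplome_a=haplome_a,
        haplome_b=haplome_b,
        variants=variants,
        pairing={c: c for c in chroms_a},
        anchors=anchors,
    )


def _in_any(pos: int, intervals: list[tuple[int, int]], pad: int = 0) -> bool:
    return any(s - pad <= pos < e + pad for s, e in intervals)


def _plant_repeats(
    rng: np.random.Generator,
    arrays: dict[str, np.ndarray],
    spec: RepeatSpec,
    telomere_len: int,
) -> list[RepeatFeature]:
    repeats: list[RepeatFeature] = []
    chroms = list(arrays)
    lengths = np.array([len(arrays[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(length: int, margin: int = 2_000) -> tuple[str, int] | None:
        for _ in range(200):
            c = chroms[int(rng.choice(len(chroms), p=probs))]
            l = len(arrays[c])
            lo = telomere_len + margin
            hi = l - telomere_len - margin - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            if not any(start - margin < e and start + length + margin > s for s, e in occupied[c]):
                occupied[c].append((start, start + length))
                return c, start
        return None

    def plant_family(family: str, n: int, length: int) -> None:
        if n <= 0:
            return
        master = _random_seq(rng, length)
        for i in range(n):
            loc = place(length)
            if loc is None:
                warnings.warn(f"could not place all {family} copies", stacklevel=3)
                return
            c, start = loc
            copy = _mutate_copy(rng, master, spec.copy_divergence)
            arrays[c][start : start + length] = copy
            repeats.append(RepeatFeature(c, start, start + length, family, f"{family}_{i + 1}"))

    plant_family("Ty-like", spec.ty_copies, spec.ty_length)
    plant_family("transposon", spec.transposon_copies, spec.transposon_length)
    # rDNA: one tandem array of near-identical units
    if spec.rdna_copies > 0:
        total = spec.rdna_copies * spec.rdna_unit
        loc = place(total)
        if loc is not None:
            c, start = loc
            unit = _random_seq(rng, spec.rdna_unit)
            for i in range(spec.rdna_copies):
                copy = _mutate_copy(rng, unit, spec.copy_divergence / 5)
                arrays[c][start + i * spec.rdna_unit : start + (i + 1) * spec.rdna_unit] = copy
            repeats.append(RepeatFeature(c, start, start + total, "rDNA", "rDNA_array"))
    return repeats


# ---------------------------------------------------------------------------
# event planting


class _Reservations:
    """Per parental chromosome interval bookkeeping to avoid event collisions."""

    def __init__(self, margin: int = 2_000) -> None:
        self.margin = margin
        self.taken: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def free(self, haplotype: str, chrom: str, start: int, end: int) -> bool:
        for s, e in self.taken.get((haplotype, chrom), []):
            if start - self.margin < e and end + self.margin > s:
                return False
        return True

    def reserve(self, haplotype: str, chrom: str, start: int, end: int) -> None:
        self.taken.setdefault((haplotype, chrom), []).append((start, end))


def _find_copy(
    copies: dict[str, DerivedChromosome], haplotype: str, chrom: str, pos: int
) -> tuple[str, int] | None:
    for name, copy in copies.items():
        for i, seg in enumerate(copy.segments):
            if seg.haplotype == haplotype and seg.chrom == chrom and seg.start <= pos < seg.end:
                return name, i
    return None


def _cut(copy: DerivedChromosome, seg_idx: int, pos: int) -> tuple[list[Segment], list[Segment]]:
    seg = copy.segments[seg_idx]
    left = copy.segments[:seg_idx]
    right = copy.segments[seg_idx + 1 :]
    if pos > seg.start:
        left = left + [Segment(seg.haplotype, seg.chrom, seg.start, pos)]
    if pos < seg.end:
        right = [Segment(seg.haplotype, seg.chrom, pos, seg.end)] + right
    return left, right


class EventCollisionError(RuntimeError):
    pass


def plant_events(
    dual_ref: DualReference,
    event_spec: EventSpec | None = None,
    seed: int = 0,
    site_index: RestrictionSiteIndex | None = None,
    motif: str = DEFAULT_MOTIF,
    retry_cap: int = 300,
) -> tuple[RestructuredGenome, TruthSet]:
    """Apply mechanism-faithful sequence edits and record the truth.

    Direct-religation joins cut ``T^CGA`` on both strands and rejoin two
    half-sites through the 2-nt cohesive overhang, reconstituting the
    motif with zero net loss.  Repeat-mediated joins recombine two
    dispersed same-family copies with the crossover in the distal part
    of the element.  BIR copies the homolog from an internal breakpoint
    to the chromosome end; SGC swaps an internal tract for homolog
    sequence.  Aneuploidy duplicates or drops whole chromosome copies.
    Every junction is audited against its mechanism signature.
    """
    spec = event_spec or EventSpec()
    rng = np.random.default_rng(seed)
    hap_a = dual_ref.haplome_a
    hap_b = dual_ref.haplome_b
    names = (hap_a.name, hap_b.name)
    sequences = {
        (hap_a.name, c): s for c, s in hap_a.chromosomes.items()
    } | {(hap_b.name, c): s for c, s in hap_b.chromosomes.items()}
    repeats = repeat_lookup({hap_a.name: hap_a, hap_b.name: hap_b})
    if site_index is None:
        site_index = scan_restriction_sites(hap_a, motif)
    site_index_b = scan_restriction_sites(hap_b, motif)
    sites = {hap_a.name: site_index.sites, hap_b.name: site_index_b.sites}

    copies: dict[str, DerivedChromosome] = {}
    for hap in (hap_a, hap_b):
        for chrom, seq in hap.chromosomes.items():
            nm = f"{hap.name}_{chrom}"
            copies[nm] = DerivedChromosome(nm, [Segment(hap.name, chrom, 0, len(seq))])

    res = _Reservations()
    events: list[TruthEvent] = []
    eid = iter(range(1, 10_000))

    def exclusion_ok(haplotype: str, chrom: str, pos: int, flank: int = 600) -> bool:
        hap = dual_ref.haplome(haplotype)
        length = hap.length(chrom)
        for s, e in hap.telomere_masks.get(chrom, []):
            if s - flank <= pos < e + flank:
                return False
        cen = hap.centromeres.get(chrom)
        if cen and cen[0] - flank <= pos < cen[1] + flank:
            return False
        for r in hap.repeats_on(chrom):
            if r.start - flank <= pos < r.end + flank:
                return False
        return 2 * flank < pos < length - 2 * flank

    # --- aneuploidy first: those chromosomes host no other event
    aneuploid_pairs: set[str] = set()
    pair_ids = list(dual_ref.pairing)

    def reserve_pair(chrom_a_id: str) -> None:
        aneuploid_pairs.add(chrom_a_id)
        res.reserve(hap_a.name, chrom_a_id, 0, hap_a.length(chrom_a_id))
        cb = dual_ref.pairing[chrom_a_id]
        res.reserve(hap_b.name, cb, 0, hap_b.length(cb))

    n_aneu = spec.n_aneuploidy_gain + spec.n_aneuploidy_loss
    if n_aneu > len(pair_ids) - 1:
        raise EventCollisionError("not enough chromosomes to host aneuploidies")
    chosen = list(rng.choice(pair_ids, size=n_aneu, replace=False)) if n_aneu else []
    for i, chrom_a_id in enumerate(chosen):
        gain = i < spec.n_aneuploidy_gain
        haplotype = str(rng.choice(names))
        chrom = chrom_a_id if haplotype == hap_a.name else dual_ref.pairing[chrom_a_id]
        nm = f"{haplotype}_{chrom}"
        if gain:
            copies[nm + "_gain"] = DerivedChromosome(
                nm + "_gain", list(copies[nm].segments)
            )
        else:
            del copies[nm]
        reserve_pair(chrom_a_id)
        events.append(
            TruthEvent(
                event_id=f"E{next(eid):03d}",
                type="aneuploidy_gain" if gain else "aneuploidy_loss",
                haplotype=haplotype,
                chrom=chrom,
                interval=(0, dual_ref.haplome(haplotype).length(chrom)),
            )
        )

    def pair_of(chrom: str, haplotype: str) -> str:
        return chrom if haplotype == hap_a.name else dual_ref.pairing_rev[chrom]

    def pick_taqi_locus() -> tuple[str, str, int] | None:
        haplotype = str(rng.choice(names))
        chrom = str(rng.choice(list(dual_ref.haplome(haplotype).chromosomes)))
        if pair_of(chrom, haplotype) in aneuploid_pairs:
            return None
        chrom_sites = sites[haplotype].get(chrom)
        if chrom_sites is None or len(chrom_sites) == 0:
            return None
        p = int(rng.choice(chrom_sites))
        if not exclusion_ok(haplotype, chrom, p) or not res.free(haplotype, chrom, p, p + 4):
            return None
        return haplotype, chrom, p

    def reciprocal_exchange(
        locus1: tuple[str, str, int], locus2: tuple[str, str, int]
    ) -> bool:
        h1, c1, p1 = locus1
        h2, c2, p2 = locus2
        f1 = _find_copy(copies, h1, c1, p1)
        f2 = _find_copy(copies, h2, c2, p2)
        if f1 is None or f2 is None:
            return False
        (n1, i1), (n2, i2) = f1, f2
        if n1 == n2:
            return False
        left1, right1 = _cut(copies[n1], i1, p1)
        left2, right2 = _cut(copies[n2], i2, p2)
        copies[n1].segments = left1 + right2
        copies[n2].segments = left2 + right1
        return True

    def audit(junction: Junction, mechanism: str, expected_overlap: str | None = None) -> None:
        if mechanism == "taqi_direct":
            assert junction.contains_restriction_site and junction.net_deleted == 0
        elif mechanism == "microhomology":
            assert 2 <= junction.overlap_len <= 3 and not junction.contains_restriction_site
        elif mechanism == "homologous":
            fa, fb = junction.repeat_context
            assert fa is not None and fa == fb
        if expected_overlap is not None:
            assert junction.overlap_seq == expected_overlap

    # --- direct-religation translocations
    for _ in range(spec.n_taqi_tl):
        for _ in range(retry_cap):
            l1 = pick_taqi_locus()
            l2 = pick_taqi_locus()
            if l1 is None or l2 is None:
                continue
            h1, c1, s1 = l1
            h2, c2, s2 = l2
            if (pair_of(c1, h1)) == (pair_of(c2, h2)):
                continue  # keep TLs off homolog pairs: coverage stays clean
            j1 = build_junction(sequences, (h1, c1, s1 + 1), (h2, c2, s2 + 1), motif, repeats=repeats)
            j2 = build_junction(sequences, (h2, c2, s2 + 1), (h1, c1, s1 + 1), motif, repeats=repeats)
            if j1.repeat_context != (None, None) or j2.repeat_context != (None, None):
                continue
            if not reciprocal_exchange((h1, c1, s1 + 1), (h2, c2, s2 + 1)):
                continue
            audit(j1, "taqi_direct")
            audit(j2, "taqi_direct")
            res.reserve(h1, c1, s1 - 400, s1 + 404)
            res.reserve(h2, c2, s2 - 400, s2 + 404)
            events.append(
                TruthEvent(
                    event_id=f"E{next(eid):03d}",
                    type="TL",
                    mechanism="taqi_direct",
                    junctions=[j1, j2],
                )
            )
            break
        else:
            raise EventCollisionError("could not place direct-religation TL")

    # --- repeat-mediated translocations
    ty_copies = [
        (hap.name, r)
        for hap in (hap_a, hap_b)
        for r in hap.repeats
        if r.family == "Ty-like"
    ]
    for _ in range(spec.n_homologous_tl):
        usable = [
            (h, r)
            for h, r in ty_copies
            if pair_of(r.chrom, h) not in aneuploid_pairs
            and res.free(h, r.chrom, r.start, r.end)
        ]
        rng.shuffle(usable)
        placed = False
        for a in range(len(usable)):
            if placed:
                break
            for b in range(a + 1, len(usable)):
                (ha, ra), (hb, rb) = usable[a], usable[b]
                if pair_of(ra.chrom, ha) == pair_of(rb.chrom, hb):
                    continue
                length = min(ra.end - ra.start, rb.end - rb.start)
                k = int(rng.integers(length - 600, length - 200))
                pa, pb = ra.start + k, rb.start + k
                j1 = build_junction(sequences, (ha, ra.chrom, pa), (hb, rb.chrom, pb), motif, repeats=repeats)
                j2 = build_junction(sequences, (hb, rb.chrom, pb), (ha, ra.chrom, pa), motif, repeats=repeats)
                fa1, fb1 = j1.repeat_context
                if fa1 != "Ty-like" or fb1 != "Ty-like":
                    continue
                if not reciprocal_exchange((ha, ra.chrom, pa), (hb, rb.chrom, pb)):
                    continue
                audit(j1, "homologous")
                audit(j2, "homologous")
                res.reserve(ha, ra.chrom, ra.start, ra.end)
                res.reserve(hb, rb.chrom, rb.start, rb.end)
                events.append(
                    TruthEvent(
                        event_id=f"E{next(eid):03d}",
                        type="TL",
                        mechanism="homologous",
                        repeat_family="Ty-like",
                        junctions=[j1, j2],
                    )
                )
                placed = True
                break
        if not placed:
            raise EventCollisionError("could not place homologous TL")

    # --- inter-homolog events: BIR (either arm, adaptive) then SGC
    def pick_homolog_locus(
        tract_len: int | None,
    ) -> tuple[str, str, int, str] | None:
        haplotype = str(rng.choice(names))
        hap = dual_ref.haplome(haplotype)
        chrom = str(rng.choice(list(hap.chromosomes)))
        if pair_of(chrom, haplotype) in aneuploid_pairs:
            return None
        length = hap.length(chrom)
        donor_h = dual_ref.other_haplotype(haplotype)
        donor_c = dual_ref.homolog_chrom(haplotype, chrom)
        arm = "internal"
        if tract_len is None:  # BIR: breakpoint in one arm, tract to that end
            arm = str(rng.choice(["left", "right"]))
            if arm == "right":
                lo, hi = length // 2, length - 20_000
                for key in ((haplotype, chrom), (donor_h, donor_c)):
                    for rs, re_ in res.taken.get(key, []):
                        if re_ > lo:  # distal-arm reservation pushes lo up
                            lo = max(lo, re_ + res.margin)
            else:
                lo, hi = 20_000, length // 2
                for key in ((haplotype, chrom), (donor_h, donor_c)):
                    for rs, re_ in res.taken.get(key, []):
                        if rs < hi:  # proximal-arm reservation pulls hi down
                            hi = min(hi, rs - res.margin)
        else:
            lo, hi = 8_000, length - 8_000 - tract_len
        if hi <= lo:
            return None
        s = int(rng.integers(lo, hi))
        # breakpoints inside masked/repeat context are invisible to the caller
        if not exclusion_ok(haplotype, chrom, s):
            return None
        if tract_len is not None and not exclusion_ok(haplotype, chrom, s + tract_len):
            return None
        return haplotype, chrom, s, arm

    def plant_homolog(kind: str) -> None:
        for _ in range(retry_cap):
            tract_len = (
                None
                if kind == "BIR"
                else int(
                    np.exp(
                        rng.uniform(
                            np.log(spec.sgc_len_range[0]), np.log(spec.sgc_len_range[1])
                        )
                    )
                )
            )
            loc = pick_homolog_locus(tract_len)
            if loc is None:
                continue
            haplotype, chrom, pos, arm = loc
            hap = dual_ref.haplome(haplotype)
            donor_h = dual_ref.other_haplotype(haplotype)
            donor_c = dual_ref.homolog_chrom(haplotype, chrom)
            donor_len = dual_ref.haplome(donor_h).length(donor_c)
            if kind == "BIR":
                s, e = (0, pos) if arm == "left" else (pos, hap.length(chrom))
                ds = 0 if arm == "left" else dual_ref.lift_pos(haplotype, chrom, pos)
                de = dual_ref.lift_pos(haplotype, chrom, pos) if arm == "left" else donor_len
            else:
                s, e = pos, pos + tract_len
                ds = dual_ref.lift_pos(haplotype, chrom, s)
                de = dual_ref.lift_pos(haplotype, chrom, e)
            if not (res.free(haplotype, chrom, s, e) and res.free(donor_h, donor_c, ds, de)):
                continue
            found = _find_copy(copies, haplotype, chrom, pos)
            if found is None:
                continue
            name, i = found
            copy = copies[name]
            left, right = _cut(copy, i, pos)
            donor_seg = Segment(donor_h, donor_c, ds, de)
            if kind == "BIR":
                copy.segments = ([donor_seg] + right) if arm == "left" else (left + [donor_seg])
            else:
                f2 = _find_copy({name: copy}, haplotype, chrom, e)
                if f2 is None:
                    continue
                _, right_e = _cut(copy, f2[1], e)
                copy.segments = left + [donor_seg] + right_e
            res.reserve(haplotype, chrom, s, e)
            res.reserve(donor_h, donor_c, ds, de)
            events.append(
                TruthEvent(
                    event_id=f"E{next(eid):03d}",
                    type=kind,
                    mechanism="homologous",
                    haplotype=haplotype,
                    chrom=chrom,
                    interval=(s, e),
                    donor_haplotype=donor_h,
                    donor_chrom=donor_c,
                    length=e - s,
                )
            )
            return
        raise EventCollisionError(f"could not place {kind}")

    for _ in range(spec.n_bir):
        plant_homolog("BIR")
    for _ in range(spec.n_sgc):
        plant_homolog("SGC")

    # --- CNV-boundary events (deletions / tandem duplications)
    def plant_cnv_junction(kind: str) -> None:
        lo, hi = spec.deletion_len_range
        use_mh = rng.random() < spec.microhomology_fraction
        for _ in range(retry_cap):
            haplotype = str(rng.choice(names))
            chrom = str(rng.choice(list(dual_ref.haplome(haplotype).chromosomes)))
            if pair_of(chrom, haplotype) in aneuploid_pairs:
                continue
            seq = sequences[(haplotype, chrom)]
            target = float(rng.uniform(lo, hi))
            if use_mh:
                got = _find_mh_pair(rng, seq, target, motif)
            else:
                got = _find_site_pair(rng, sites[haplotype].get(chrom), target)
            if got is None:
                continue
            s, e, overlap = got
            if not (exclusion_ok(haplotype, chrom, s) and exclusion_ok(haplotype, chrom, e)):
                continue
            if not res.free(haplotype, chrom, s, e):
                continue
            hom_h = dual_ref.other_haplotype(haplotype)
            hom_c = dual_ref.homolog_chrom(haplotype, chrom)
            hs = dual_ref.lift_pos(haplotype, chrom, s)
            he = dual_ref.lift_pos(haplotype, chrom, e)
            if not res.free(hom_h, hom_c, hs, he):
                continue
            if kind == "deletion":
                locus1, locus2 = (haplotype, chrom, s), (haplotype, chrom, e)
            else:
                locus1, locus2 = (haplotype, chrom, e), (haplotype, chrom, s)
            junc = build_junction(sequences, locus1, locus2, motif, repeats=repeats)
            mech = "microhomology" if use_mh else "taqi_direct"
            if use_mh and (junc.overlap_len != len(overlap) or junc.contains_restriction_site):
                continue
            found = _find_copy(copies, haplotype, chrom, s)
            if found is None:
                continue
            name, i = found
            copy = copies[name]
            left, mid_right = _cut(copy, i, s)
            f2 = _find_copy({name: copy}, haplotype, chrom, e)
            if f2 is None:
                continue
            if kind == "deletion":
                _, right = _cut(copy, f2[1], e)
                copy.segments = left + right
            else:
                left_e, right_e = _cut(copy, f2[1], e)
                copy.segments = left_e + [Segment(haplotype, chrom, s, e)] + right_e
            audit(junc, mech, expected_overlap=overlap if use_mh else None)
            res.reserve(haplotype, chrom, s - 400, e + 400)
            res.reserve(hom_h, hom_c, hs, he)
            events.append(
                TruthEvent(
                    event_id=f"E{next(eid):03d}",
                    type=kind,
                    mechanism=mech,
                    haplotype=haplotype,
                    chrom=chrom,
                    interval=(s, e),
                    length=e - s,
                    junctions=[junc],
                )
            )
            return
        raise EventCollisionError(f"could not place {kind}")

    for _ in range(spec.n_large_deletion):
        plant_cnv_junction("deletion")
    for _ in range(spec.n_tandem_duplication):
        plant_cnv_junction("tandem_duplication")

    # --- small induced variants (recorded in truth; applied post-build)
    small: list[tuple[str, str, int, str]] = []
    for kind in ["SNV"] * spec.n_snv + ["InDel"] * spec.n_indel:
        for _ in range(retry_cap):
            haplotype = str(rng.choice(names))
            hap = dual_ref.haplome(haplotype)
            chrom = str(rng.choice(list(hap.chromosomes)))
            if pair_of(chrom, haplotype) in aneuploid_pairs:
                continue
            p = int(rng.integers(8_000, hap.length(chrom) - 8_000))
            if not res.free(haplotype, chrom, p, p + 1):
                continue
            res.reserve(haplotype, chrom, p, p + 1)
            small.append((kind, haplotype, chrom, p))
            events.append(
                TruthEvent(
                    event_id=f"E{next(eid):03d}",
                    type=kind,
                    haplotype=haplotype,
                    chrom=chrom,
                    interval=(p, p + 1),
                )
            )
            break
        else:
            raise EventCollisionError("could not place small variant")

    # build derived sequences
    for copy in copies.values():
        copy.seq = "".join(
            sequences[(seg.haplotype, seg.chrom)][seg.start : seg.end] for seg in copy.segments
        )
    _apply_small_variants(rng, copies, small)

    n_dsb = int(rng.poisson(spec.dsb_mean))
    truth = TruthSet(
        events=events,
        metadata={
            "seed": int(seed),
            "n_dsb_sampled": n_dsb,
            "note": "unresolved DSBs religate silently and leave no record",
            "event_spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__},
        },
    )
    return RestructuredGenome(copies=copies), truth


def _apply_small_variants(
    rng: np.random.Generator,
    copies: dict[str, DerivedChromosome],
    small: list[tuple[str, str, int, str]] | list,
) -> None:
    for kind, haplotype, chrom, p in small:
        found = _find_copy(copies, haplotype, chrom, p)
        if found is None:
            continue
        name, i = found
        copy = copies[name]
        offset = sum(len(s) for s in copy.segments[:i]) + (p - copy.segments[i].start)
        old = copy.seq[offset]
        if kind == "SNV":
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            copy.seq = copy.seq[:offset] + new + copy.seq[offset + 1 :]
        else:
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            copy.seq = copy.seq[: offset + 1] + ins + copy.seq[offset + 1 :]


def _find_site_pair(
    rng: np.random.Generator, chrom_sites: np.ndarray | None, target: float
) -> tuple[int, int, str] | None:
    """Two cut positions ~target apart; both at restriction sites."""
    if chrom_sites is None or len(chrom_sites) < 2:
        return None
    s_site = int(rng.choice(chrom_sites))
    want = s_site + target
    j = int(np.argmin(np.abs(chrom_sites - want)))
    e_site = int(chrom_sites[j])
    if e_site <= s_site or not 0.5 * target <= e_site - s_site <= 1.5 * target:
        return None
    return s_site + 1, e_site + 1, ""


def _find_mh_pair(
    rng: np.random.Generator, seq: str, target: float, motif: str
) -> tuple[int, int, str] | None:
    """Deletion endpoints sharing an exact 2-3 nt overlap and no spanning motif."""
    from .junctions import canonicalize_breakpoints, motif_spans_junction

    length = len(seq)
    for _ in range(50):
        ov = int(rng.integers(2, 4))
        s = int(rng.integers(10_000, max(10_001, length - int(target) - 10_000)))
        m = seq[s - ov : s]
        lo = s + int(0.6 * target)
        hi = min(length - 10_000, s + int(1.4 * target))
        if hi <= lo:
            return None
        j = seq.find(m, lo)
        while j != -1 and j + ov <= hi:
            e = j + ov
            _, _, ov_l, ov_r = canonicalize_breakpoints(seq, s, seq, e)
            if ov_l == ov and ov_r == 0 and not motif_spans_junction(seq, s, seq, e, motif):
                return s, e, m
            j = seq.find(m, j + 1)
    return None


# ---------------------------------------------------------------------------
# derived data


def simulate_coverage(
    restructured: RestructuredGenome,
    dual_ref: DualReference,
    mean_depth: float = 80.0,
    bin_size: int = 100,
    noise: str = "nb",
    dispersion: float = 0.1,
    seed: int = 0,
) -> dict[str, CoverageTrack]:
    """Per-haplotype binned depth from the copy-number oracle.

    Expected depth per bin is ``mean_depth`` x (copies of that parental
    segment in the restructured genome); the diploid baseline is one
    copy per haplotype.  ``noise="nb"`` draws negative-binomial
    (gamma-Poisson) depths with the given dispersion; ``noise="none"``
    returns the expectation.  Telomere and rDNA bins are mask-flagged.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, CoverageTrack] = {}
    for hap in (dual_ref.haplome_a, dual_ref.haplome_b):
        values: dict[str, np.ndarray] = {}
        mask: dict[str, np.ndarray] = {}
        for chrom, seq in hap.chromosomes.items():
            length = len(seq)
            if bin_size > length:
                raise ValueError(f"bin size {bin_size} exceeds chromosome {chrom}")
            cn = restructured.copy_number_per_bp(hap.name, chrom, length)
            n_bins = (length + bin_size - 1) // bin_size
            edges = np.arange(n_bins) * bin_size
            sums = np.add.reduceat(cn.astype(float), edges)
            widths = np.minimum(edges + bin_size, length) - edges
            mu = mean_depth * sums / widths
            if noise == "none":
                depth = mu
            elif noise == "nb":
                depth = np.zeros_like(mu)
                pos = mu > 0
                lam = rng.gamma(1.0 / dispersion, mu[pos] * dispersion)
                depth[pos] = rng.poisson(lam).astype(float)
            else:
                raise ValueError(f"unknown noise model {noise!r}")
            m = np.zeros(n_bins, dtype=bool)
            for s, e in hap.telomere_masks.get(chrom, []):
                m[s // bin_size : (e + bin_size - 1) // bin_size] = True
            for r in hap.repeats_on(chrom):
                if r.family == "rDNA":
                    m[r.start // bin_size : (r.end + bin_size - 1) // bin_size] = True
            values[chrom] = depth
            mask[chrom] = m
        out[hap.name] = CoverageTrack(
            haplotype=hap.name, bin_size=bin_size, values=values, mask=mask
        )
    return out


def simulate_acgh(
    restructured: RestructuredGenome,
    dual_ref: DualReference,
    probe_spacing: int = 1_000,
    noise_sd: float = 0.05,
    baseline_ploidy: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """aCGH probe log10(sample/control) ratios on haplome-A coordinates.

    Array probes hybridise both alleles, so the signal is the combined
    copy number of the homologous locus pair over the baseline ploidy,
    plus Gaussian noise.  Zero-copy loci are floored at 0.05 copies
    (background hybridisation) to keep ratios finite.
    """
    if probe_spacing <= 0:
        raise ValueError("probe spacing must be positive")
    rng = np.random.default_rng(seed)
    hap_a = dual_ref.haplome_a
    hap_b = dual_ref.haplome_b
    chroms, positions, ratios = [], [], []
    for chrom_a, chrom_b in dual_ref.pairing.items():
        la = hap_a.length(chrom_a)
        cn_a = restructured.copy_number_per_bp(hap_a.name, chrom_a, la)
        cn_b = restructured.copy_number_per_bp(
            hap_b.name, chrom_b, hap_b.length(chrom_b)
        )
        pos = np.arange(probe_spacing // 2, la, probe_spacing)
        for p in pos:
            pb = dual_ref.lift_pos(hap_a.name, chrom_a, int(p))
            total = float(cn_a[p]) + float(cn_b[min(pb, len(cn_b) - 1)])
            ratio = np.log10(max(total, 0.05) / baseline_ploidy)
            chroms.append(chrom_a)
            positions.append(int(p))
            ratios.append(ratio + rng.normal(0.0, noise_sd))
    return array_track(np.array(chroms), np.array(positions), np.array(ratios))


def simulate_junction_evidence(
    restructured: RestructuredGenome,
    truth: TruthSet,
    dual_ref: DualReference,
    read_len: int = 300,
    depth: float = 80.0,
    clip_fraction: float = 0.33,
    pair_fraction: float = 0.25,
    noise_clips_per_kb: float = 0.05,
    seed: int = 0,
    min_clip: int = 50,
) -> Evidence:
    """Soft-clip and discordant-pair records around every truth junction.

    Reads crossing a non-homologous junction align up to the end of the
    homologous overlap and soft-clip into partner sequence; inter-homolog
    conversion boundaries (BIR/SGC) emit no clips, since reads cross them
    with only SNP-level mismatches.  Background clip records with random
    tails are scattered at ``noise_clips_per_kb``.
    """
    if read_len < 2 * min_clip - 40:
        raise ValueError("read length too short for anchored clipped tails")
    rng = np.random.default_rng(seed)
    sequences = {
        (h.name, c): s
        for h in (dual_ref.haplome_a, dual_ref.haplome_b)
        for c, s in h.chromosomes.items()
    }
    max_clip = min(250, read_len - 40)
    clip_rows, pair_rows = [], []
    if depth > 0:
        for junc in truth.junctions():
            ha, ca, pa = junc.locus_a.haplotype, junc.locus_a.chrom, junc.locus_a.pos
            hb, cb, pb = junc.locus_b.haplotype, junc.locus_b.chrom, junc.locus_b.pos
            ov = junc.overlap_len
            ref_a, ref_b = sequences[(ha, ca)], sequences[(hb, cb)]
            # reads anchored left of the junction clip at the end of the overlap
            for _ in range(int(rng.poisson(depth * clip_fraction))):
                ln = int(rng.integers(min_clip, max_clip + 1))
                tail = ref_b[pb + ov : pb + ov + ln]
                if len(tail) >= min_clip:
                    clip_rows.append((ha, ca, pa + ov, "R", tail))
            for _ in range(int(rng.poisson(depth * clip_fraction))):
                ln = int(rng.integers(min_clip, max_clip + 1))
                tail = ref_a[max(0, pa - ln) : pa]
                if len(tail) >= min_clip:
                    pair_pos = pb  # left-aligned junction start on B
                    clip_rows.append((hb, cb, pair_pos, "L", tail))
            for _ in range(int(rng.poisson(depth * pair_fraction))):
                da = int(rng.integers(150, 500))
                db = int(rng.integers(100, 450))
                pair_rows.append(
                    (ha, ca, max(0, pa - da), "+", hb, cb, pb + ov + db, "-")
                )
    # background noise (only when there is sequencing at all)
    total_kb = sum(len(s) for s in sequences.values()) / 1000.0 if depth > 0 else 0.0
    for _ in range(int(rng.poisson(noise_clips_per_kb * total_kb))):
        key = list(sequences)[int(rng.integers(len(sequences)))]
        pos = int(rng.integers(0, len(sequences[key])))
        tail = "".join(rng.choice(list("ACGT"), size=int(rng.integers(min_clip, max_clip + 1))))
        clip_rows.append((key[0], key[1], pos, str(rng.choice(["L", "R"])), tail))
    clips = (
        pd.DataFrame(clip_rows, columns=["haplotype", "chrom", "pos", "side", "seq"])
        if clip_rows
        else empty_clips()
    )
    pairs = (
        pd.DataFrame(
            pair_rows,
            columns=[
                "haplotype_a",
                "chrom_a",
                "pos_a",
                "strand_a",
                "haplotype_b",
                "chrom_b",
                "pos_b",
                "strand_b",
            ],
        )
        if pair_rows
        else empty_pairs()
    )
    return Evidence(clips=clips, pairs=pairs, depth=depth, read_len=read_len)


def simulate_coordinate_model(
    dual_ref: DualReference,
    nuclear_diameter_um: float = 2.0,
    anchor_spacing: int = 10_000,
    step_sd_um: float = 0.08,
    seed: int = 0,
) -> CoordinateModel:
    """Confined random-walk polylines, one per haplome-A chromosome.

    Each chromosome is a Gaussian random walk whose anchors are folded
    back into the nuclear sphere (radius = diameter/2), emulating a
    territorial chromosome arrangement at the scale the distance null
    needs.
    """
    if nuclear_diameter_um <= 0:
        raise ValueError("nuclear diameter must be positive")
    rng = np.random.default_rng(seed)
    radius = nuclear_diameter_um / 2.0
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in dual_ref.haplome_a.chrom_lengths.items():
        pos = np.arange(0, length, anchor_spacing, dtype=float)
        if pos[-1] != length - 1:
            pos = np.append(pos, length - 1)
        start = rng.normal(0.0, radius / 3.0, size=3)
        steps = rng.normal(0.0, step_sd_um, size=(len(pos) - 1, 3))
        xyz = np.vstack([start, start + np.cumsum(steps, axis=0)])
        norms = np.linalg.norm(xyz, axis=1)
        outside = norms > radius * 0.98
        if np.any(outside):
            # fold escapes radially back inside the sphere
            xyz[outside] *= (
                (2 * radius * 0.98 - norms[outside]).clip(min=0.01) / norms[outside]
            )[:, None]
        anchors[chrom] = (pos, xyz)
    return CoordinateModel(anchors=anchors)
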