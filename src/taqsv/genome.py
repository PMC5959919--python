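"""Dual-haplotype hybrid reference model.

A fused hybrid carries two parental haploid genomes ("haplomes") that
remain distinguishable because the parents diverged at high density
(~6.5 SNPs/kb and ~0.7 InDels/kb between the yeast parents, ~0.72%
overall).  All downstream callers operate on parental coordinates, so
this module provides the reference container, a restriction-site index
for the 4-bp cutter motif, an inter-haplotype variant map, and an
anchor-based liftover between homologous chromosomes.

Coordinates are 0-based half-open throughout; 1-based conversions happen
only at VCF/BED boundaries (see :mod:`taqsv.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = set("ACGTN")
DEFAULT_MOTIF = "TCGA"
#: 5' cohesive overhang left by cleavage of T^CGA on both strands.
DEFAULT_OVERHANG = "CG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatFeature:
    """An annotated repeat interval on one haplome."""

    chrom: str
    start: int
    end: int
    family: str  # Ty-like | rDNA | transposon | other
    name: str = ""


@dataclass
class Haplome:
    """One parental haploid genome with its annotations.

    Parameters
    ----------
    name:
        Parent label (e.g. ``"A"``, ``"B"``).
    chromosomes:
        Ordered mapping of chromosome id to uppercase sequence.
    centromeres:
        Per-chromosome ``(start, end)`` interval, optional.
    telomere_masks:
        Per-chromosome list of end intervals treated as unreliable.
    repeats:
        Annotated repeat intervals.
    """

    name: str
    chromosomes: dict[str, str]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    telomere_masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    repeats: list[RepeatFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("chromosome ids must be unique")
        for chrom, (s, e) in self.centromeres.items():
            self._check_interval(chrom, s, e, "centromere")
        for chrom, ivs in self.telomere_masks.items():
            length = self.length(chrom)
            for s, e in ivs:
                self._check_interval(chrom, s, e, "telomere mask")
                if s != 0 and e != length:
                    raise ValueError(
                        f"telomere mask [{s},{e}) on {chrom} does not touch a chromosome end"
                    )
        for rep in self.repeats:
            self._check_interval(rep.chrom, rep.start, rep.end, "repeat")

    def _check_interval(self, chrom: str, s: int, e: int, what: str) -> None:
        if chrom not in self.chromosomes:
            raise ValueError(f"{what} on unknown chromosome {chrom!r}")
        if not (0 <= s < e <= self.length(chrom)):
            raise ValueError(f"{what} [{s},{e}) outside chromosome {chrom}")

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def repeats_on(self, chrom: str) -> list[RepeatFeature]:
        return [r for r in self.repeats if r.chrom == chrom]


@dataclass
class RestrictionSiteIndex:
    """Sorted forward-strand positions of a recognition motif per chromosome."""

    motif: str
    sites: dict[str, np.ndarray]
    overhang: str = DEFAULT_OVERHANG

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.sites.get(chrom, ()))
        return sum(len(v) for v in self.sites.values())

    def density_per_bp(self, haplome: Haplome) -> float:
        total = haplome.total_length
        return self.n_sites() / total if total else 0.0


def is_palindromic(motif: str) -> bool:
    return revcomp(motif) == motif


def scan_restriction_sites(
    haplome: Haplome,
    motif: str = DEFAULT_MOTIF,
    overhang: str = DEFAULT_OVERHANG,
    both_strands: bool = False,
) -> RestrictionSiteIndex:
    """Index every occurrence of *motif* in a haplome.

    For a palindromic motif (TCGA is its own reverse complement) the
    forward scan is exhaustive.  Non-palindromic motifs require
    ``both_strands=True``; reverse-strand hits are reported at the
    forward-strand start of the reverse-complement occurrence.  N bases
    never match.
    """
    motif = motif.upper()
    if len(motif) < 2:
        raise ValueError("motif must be at least 2 nt")
    if set(motif) - DNA_ALPHABET or "N" in motif:
        raise ValueError(f"invalid motif {motif!r}")
    if not is_palindromic(motif) and not both_strands:
        raise ValueError(
            f"motif {motif!r} is not palindromic; enable both_strands to scan both strands"
        )
    sites: dict[str, np.ndarray] = {}
    queries = [motif]
    if both_strands and not is_palindromic(motif):
        queries.append(revcomp(motif))
    for chrom, seq in haplome.chromosomes.items():
        hits: list[int] = []
        for q in queries:
            start = seq.find(q)
            while start != -1:
                hits.append(start)
                start = seq.find(q, start + 1)
        sites[chrom] = np.array(sorted(set(hits)), dtype=np.int64)
    return RestrictionSiteIndex(motif=motif, sites=sites, overhang=overhang)


@dataclass(frozen=True)
class Variant:
    """An inter-haplotype difference anchored on both parental coordinates.

    ``ref``/``alt`` are the A- and B-haplome alleles.  InDels follow VCF
    anchoring: the shared preceding base is included, so an insertion in
    B has ``len(alt) > len(ref)``.
    """

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    kind: str  # "SNV" | "InDel"
    ref: str
    alt: str

    @property
    def net_indel(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class DualReference:
    """Two parental haplomes plus the variant map relating them.

    ``anchors`` stores, per A-chromosome, two equal-length sorted integer
    arrays of corresponding positions (A, B).  Positions between anchors
    lift by linear interpolation; with anchors at every InDel boundary
    this is exact outside the InDels themselves.
    """

    haplome_a: Haplome
    haplome_b: Haplome
    variants: list[Variant]
    pairing: dict[str, str]
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.pairing.values())) != len(self.pairing):
            raise ValueError("homolog pairing must be a bijection")
        for ca, cb in self.pairing.items():
            if ca not in self.haplome_a.chromosomes:
                raise ValueError(f"paired chromosome {ca!r} missing from haplome A")
            if cb not in self.haplome_b.chromosomes:
                raise ValueError(f"paired chromosome {cb!r} missing from haplome B")
        self.pairing_rev = {v: k for k, v in self.pairing.items()}
        for v in self.variants:
            if self.pairing.get(v.chrom_a) != v.chrom_b:
                raise ValueError(
                    f"variant at {v.chrom_a}:{v.pos_a} references unpaired chromosomes"
                )
        for ca in self.pairing:
            if ca not in self.anchors:
                la = self.haplome_a.length(ca)
                lb = self.haplome_b.length(self.pairing[ca])
                self.anchors[ca] = (
                    np.array([0, la], dtype=np.int64),
                    np.array([0, lb], dtype=np.int64),
                )

    def haplome(self, label: str) -> Haplome:
        if label == self.haplome_a.name:
            return self.haplome_a
        if label == self.haplome_b.name:
            return self.haplome_b
        raise KeyError(f"unknown haplotype {label!r}")

    def other_haplotype(self, label: str) -> str:
        if label == self.haplome_a.name:
            return self.haplome_b.name
        if label == self.haplome_b.name:
            return self.haplome_a.name
        raise KeyError(f"unknown haplotype {label!r}")

    def homolog_chrom(self, haplotype: str, chrom: str) -> str:
        if haplotype == self.haplome_a.name:
            try:
                return self.pairing[chrom]
            except KeyError:
                raise KeyError(f"chromosome {chrom!r} has no homolog") from None
        try:
            return self.pairing_rev[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} has no homolog") from None

    def sequence(self, haplotype: str, chrom: str) -> str:
        return self.haplome(haplotype).chromosomes[chrom]

    def _anchor_arrays(self, haplotype: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if haplotype == self.haplome_a.name:
            xa, xb = self.anchors[chrom]
            return xa, xb
        xa, xb = self.anchors[self.pairing_rev[chrom]]
        return xb, xa

    def lift_pos(self, haplotype: str, chrom: str, pos: int) -> int:
        """Map a position to its homolog coordinate (rounded interpolation)."""
        src, dst = self._anchor_arrays(haplotype, chrom)
        if not (src[0] <= pos <= src[-1]):
            raise ValueError(f"position {pos} outside anchored span of {chrom}")
        return int(round(float(np.interp(pos, src, dst))))

    def liftover(
        self, haplotype: str, chrom: str, interval: tuple[int, int]
    ) -> tuple[str, int, int]:
        """Lift an interval to the homolog; length changes only by net InDels."""
        s, e = interval
        if s >= e:
            raise ValueError(f"empty interval {interval}")
        homolog = self.homolog_chrom(haplotype, chrom)
        return homolog, self.lift_pos(haplotype, chrom, s), self.lift_pos(haplotype, chrom, e)

    def variant_density_per_kb(self, kind: str | None = None) -> dict[str, float]:
        """Per-A-chromosome variant density (variants per kb)."""
        out: dict[str, float] = {}
        for ca in self.pairing:
            n = sum(
                1
                for v in self.variants
                if v.chrom_a == ca and (kind is None or v.kind == kind)
            )
            out[ca] = 1000.0 * n / self.haplome_a.length(ca)
        return out


def build_variant_map(
    haplome_a: Haplome,
    haplome_b: Haplome,
    alignments: dict[str, tuple[str, str]],
    pairing: dict[str, str] | None = None,
) -> DualReference:
    """Build a :class:`DualReference` from per-chromosome pairwise alignments.

    ``alignments`` maps each A-chromosome id to a gapped alignment pair
    ``(aligned_a, aligned_b)`` (e.g. from ``Bio.Align.PairwiseAligner``),
    with ``-`` gaps.  Adjacent alignment columns are walked once to emit
    SNV and InDel records and to lay liftover anchors at InDel
    boundaries.
    """
    if pairing is None:
        pairing = {c: c for c in alignments}
    variants: list[Variant] = []
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom_a, (ga, gb) in alignments.items():
        chrom_b = pairing[chrom_a]
        if chrom_a not in haplome_a.chromosomes or chrom_b not in haplome_b.chromosomes:
            raise ValueError(f"alignment references unpaired chromosome {chrom_a!r}")
        if len(ga) != len(gb):
            raise ValueError(f"misaligned rows for {chrom_a}")
        pa = pb = 0
        anc_a = [0]
        anc_b = [0]
        i = 0
        n = len(ga)
        while i < n:
            ca, cb = ga[i], gb[i]
            if ca != "-" and cb != "-":
                if ca != cb:
                    variants.append(
                        Variant(chrom_a, pa, chrom_b, pb, "SNV", ca, cb)
                    )
                pa += 1
                pb += 1
                i += 1
            else:
                # gap run: anchor both flanks, emit one VCF-style InDel
                j = i
                ins_b = []
                del_a = []
                while j < n and (ga[j] == "-" or gb[j] == "-"):
                    if ga[j] == "-":
                        ins_b.append(gb[j])
                    else:
                        del_a.append(ga[j])
                    j += 1
                if pa == 0 or pb == 0:
                    raise ValueError("leading gap without anchor base is unsupported")
                ref = ga[i - 1] + "".join(del_a)
                alt = gb[i - 1] + "".join(ins_b)
                variants.append(
                    Variant(chrom_a, pa - 1, chrom_b, pb - 1, "InDel", ref, alt)
                )
                anc_a.append(pa - 1)
                anc_b.append(pb - 1)
                pa += len(del_a)
                pb += len(ins_b)
                anc_a.append(pa)
                anc_b.append(pb)
                i = j
        anc_a.append(pa)
        anc_b.append(pb)
        if pa != haplome_a.length(chrom_a) or pb != haplome_b.length(chrom_b):
            raise ValueError(f"alignment for {chrom_a} does not span both sequences")
        aa = np.array(anc_a, dtype=np.int64)
        ab = np.array(anc_b, dtype=np.int64)
        keep = np.concatenate(([True], np.diff(aa) > 0)) & np.concatenate(
            ([True], np.diff(ab) > 0)
        )
        anchors[chrom_a] = (aa[keep], ab[keep])
    _check_no_overlap(variants)
    return DualReference(
        haplome_a=haplome_a,
        haplome_b=haplome_b,
        variants=variants,
        pairing=pairing,
        anchors=anchors,
    )


def _check_no_overlap(variants: list[Variant]) -> None:
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom_a, []).append(v)
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: v.pos_a)
        prev_end = -1
        for v in vs:
            if v.pos_a < prev_end:
                raise ValueError(f"overlapping variant records on {chrom} at {v.pos_a}")
            prev_end = v.pos_a + len(v.ref)
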