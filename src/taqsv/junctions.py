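"""Breakpoint-junction accounting.

A junction joins the left flank of locus A (``refA[:pos_a]``) to the
right flank of locus B (``refB[pos_b:]``); both flanks are on the
forward strand of their parental reference.  Because the two flanks may
share sequence at the join (microhomology, or a reconstituted
restriction motif), the physical breakpoint can slide within an
ambiguity window.  All comparisons therefore go through a left-aligned
canonical form: the junction is shifted left by the common suffix of the
two left flanks.

The repair-mechanism signatures encoded here:

* ``taqi_direct`` — religation of two cohesive restriction half-sites;
  the 4-bp motif is reconstituted across the join with zero net loss.
* ``microhomology`` — a 2–3 nt exact overlap shared by both flanks, with
  no restriction site spanning the join (MMEJ/A-NHEJ signature).
* ``homologous`` — both breakpoints fall inside annotated repeats of the
  same family (HR between dispersed repeats; positions approximate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import DEFAULT_MOTIF, Haplome, RepeatFeature

MECHANISMS = ("taqi_direct", "microhomology", "homologous", "unclassified")


def common_prefix_len(a: str, b: str, cap: int | None = None) -> int:
    n = min(len(a), len(b))
    if cap is not None:
        n = min(n, cap)
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def common_suffix_len(a: str, b: str, cap: int | None = None) -> int:
    n = min(len(a), len(b))
    if cap is not None:
        n = min(n, cap)
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


@dataclass(frozen=True)
class Locus:
    haplotype: str
    chrom: str
    pos: int
    strand: str = "+"

    def key(self) -> tuple[str, str, int]:
        return (self.haplotype, self.chrom, self.pos)


def canonicalize_breakpoints(
    ref_a: str, pos_a: int, ref_b: str, pos_b: int, cap: int = 50_000
) -> tuple[int, int, int, int]:
    """Left-align a junction ``refA[:pos_a] + refB[pos_b:]``.

    Returns ``(pos_a_left, pos_b_left, ov_left, ov_right)`` where the
    total homologous overlap at the join is ``ov_left + ov_right`` and
    the left-aligned breakpoint pair is the canonical representative of
    the ambiguity window.
    """
    ov_right = common_prefix_len(ref_a[pos_a : pos_a + cap], ref_b[pos_b : pos_b + cap])
    ov_left = common_suffix_len(ref_a[max(0, pos_a - cap) : pos_a], ref_b[max(0, pos_b - cap) : pos_b])
    return pos_a - ov_left, pos_b - ov_left, ov_left, ov_right


def junction_sequence(
    ref_a: str, pos_a: int, ref_b: str, pos_b: int, flank: int = 30, inserted: str = ""
) -> tuple[str, int]:
    """Reconstructed sequence across the join and the join offset within it."""
    left = ref_a[max(0, pos_a - flank) : pos_a]
    right = ref_b[pos_b : pos_b + flank]
    return left + inserted + right, len(left)


def motif_spans_junction(
    ref_a: str,
    pos_a: int,
    ref_b: str,
    pos_b: int,
    motif: str = DEFAULT_MOTIF,
    inserted: str = "",
) -> bool:
    """True if a motif occurrence straddles some admissible breakpoint.

    The breakpoint may slide across the homologous overlap, so the motif
    counts as junction-spanning when it strictly contains at least one
    position of the ambiguity window ``[join-ov_left, join+ov_right]``.
    """
    if inserted:
        # untemplated bases interrupt the join; a motif can still span it
        # only through the insertion, checked directly on the reconstruction
        seq, j = junction_sequence(ref_a, pos_a, ref_b, pos_b, flank=len(motif) + 2, inserted=inserted)
        lo, hi = j, j + len(inserted)
    else:
        _, _, ov_left, ov_right = canonicalize_breakpoints(ref_a, pos_a, ref_b, pos_b)
        seq, j = junction_sequence(
            ref_a, pos_a, ref_b, pos_b, flank=max(ov_left, ov_right) + len(motif) + 2
        )
        lo, hi = j - ov_left, j + ov_right
    start = seq.find(motif)
    while start != -1:
        # motif interior positions are (start, start+len) exclusive ends
        if start + 1 <= hi and start + len(motif) - 1 >= lo:
            return True
        start = seq.find(motif, start + 1)
    return False


@dataclass
class Junction:
    """A reconstructed breakpoint junction with repair-signature accounting."""

    locus_a: Locus
    locus_b: Locus
    overlap_seq: str = ""
    inserted: str = ""
    deleted_a: int = 0
    deleted_b: int = 0
    contains_restriction_site: bool = False
    repeat_context: tuple[str | None, str | None] = (None, None)
    n_clips: int = 0
    n_pairs: int = 0
    low_confidence: bool = False
    ambiguous_partner: bool = False

    @property
    def overlap_len(self) -> int:
        return len(self.overlap_seq)

    @property
    def net_deleted(self) -> int:
        return self.deleted_a + self.deleted_b

    @property
    def is_interchromosomal(self) -> bool:
        return (self.locus_a.haplotype, self.locus_a.chrom) != (
            self.locus_b.haplotype,
            self.locus_b.chrom,
        )

    def canonical_key(self) -> tuple:
        return (self.locus_a.key(), self.locus_b.key())


def build_junction(
    sequences: dict[tuple[str, str], str],
    locus_a: tuple[str, str, int],
    locus_b: tuple[str, str, int],
    motif: str = DEFAULT_MOTIF,
    inserted: str = "",
    repeats: dict[str, list[RepeatFeature]] | None = None,
    repeat_margin: int = 50,
) -> Junction:
    """Construct a left-aligned :class:`Junction` from raw breakpoints.

    ``sequences`` maps ``(haplotype, chrom)`` to the parental sequence.
    The same constructor serves the simulator's audit and the detector's
    reconstruction so that truth and calls live in one canonical space.
    """
    ha, ca, pa = locus_a
    hb, cb, pb = locus_b
    ref_a = sequences[(ha, ca)]
    ref_b = sequences[(hb, cb)]
    if inserted:
        pa_l, pb_l, ov_l, ov_r = pa, pb, 0, 0
        overlap = ""
    else:
        pa_l, pb_l, ov_l, ov_r = canonicalize_breakpoints(ref_a, pa, ref_b, pb)
        overlap = ref_a[pa - ov_l : pa + ov_r]
    has_motif = motif_spans_junction(ref_a, pa, ref_b, pb, motif=motif, inserted=inserted)
    ctx_a = ctx_b = None
    if repeats is not None:
        ctx_a = _repeat_family_at(repeats, ha, ca, pa_l, repeat_margin)
        ctx_b = _repeat_family_at(repeats, hb, cb, pb_l, repeat_margin)
    return Junction(
        locus_a=Locus(ha, ca, pa_l),
        locus_b=Locus(hb, cb, pb_l),
        overlap_seq=overlap,
        inserted=inserted,
        contains_restriction_site=has_motif,
        repeat_context=(ctx_a, ctx_b),
    )


def _repeat_family_at(
    repeats: dict[str, list[RepeatFeature]], haplotype: str, chrom: str, pos: int, margin: int
) -> str | None:
    for rep in repeats.get(haplotype, []):
        if rep.chrom == chrom and rep.start - margin <= pos < rep.end + margin:
            return rep.family
    return None


def repeat_lookup(haplomes: dict[str, Haplome]) -> dict[str, list[RepeatFeature]]:
    return {name: hap.repeats for name, hap in haplomes.items()}
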