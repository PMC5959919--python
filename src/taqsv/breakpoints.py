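"""Translocation and CNV-boundary junction detection and classification.

The three-step procedure mirrors standard split-read SV validation:

1. boundary regions — windows where the soft-clipped fraction of reads
   exceeds 10% (around CNV boundaries or genome-wide);
2. partner location — the clip-tail consensus is aligned against the
   full reference (best local hit under e < 1e-4) with a reciprocal
   best-hit check from the partner side;
3. discordant-pair confirmation — at least 2 properly oriented pairs
   bridging the two regions.

Resolved junctions are reconstructed, canonicalised (left-aligned) and
classified by repair mechanism in the priority order homologous →
direct restriction-site religation → microhomology → unclassified;
repeat context is checked first because repeat-mediated joins need not
preserve any junction-level signature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Hit, LocalAligner
from .evidence import Evidence
from .genome import DEFAULT_MOTIF, DualReference, RestrictionSiteIndex
from .junctions import Junction, MECHANISMS, build_junction, repeat_lookup


@dataclass
class ClipRecord:
    pos: int
    side: str
    seq: str


@dataclass
class BoundaryRegion:
    """A window of accumulated partially-unmapped (soft-clipped) reads."""

    haplotype: str
    chrom: str
    start: int
    end: int
    side: str
    partially_unmapped_fraction: float
    clips: list[ClipRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.partially_unmapped_fraction <= 1.0:
            raise ValueError("clip fraction outside [0,1]")

    @property
    def clip_pos(self) -> int:
        return int(Counter(c.pos for c in self.clips).most_common(1)[0][0])


@dataclass
class MechanismCall:
    mechanism: str
    rationale: str

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


def find_boundary_regions(
    evidence: Evidence,
    cnv_calls: list | None = None,
    window: int = 200,
    min_fraction: float = 0.10,
    min_clips: int = 3,
    genome_wide: bool = True,
    boundary_pad: int = 2_000,
) -> list[BoundaryRegion]:
    """Cluster soft-clip records into candidate breakpoint regions.

    Clips are grouped per (haplotype, chromosome, side) within
    ``window`` bp; a cluster becomes a region when its read fraction
    (cluster size over sequencing depth) exceeds ``min_fraction`` —
    the >10% partially-unmapped rule.  With ``genome_wide=False`` only
    clusters within ``boundary_pad`` of a CNV call boundary are kept.
    """
    if not genome_wide and not cnv_calls:
        return []
    regions: list[BoundaryRegion] = []
    if len(evidence.clips) == 0 or evidence.depth <= 0:
        return regions
    for (hap, chrom, side), grp in evidence.clips.groupby(
        ["haplotype", "chrom", "side"], sort=False
    ):
        grp = grp.sort_values("pos")
        positions = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(positions) > window)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(positions)]))
        for s, e in zip(starts, ends):
            n = e - s
            fraction = min(1.0, n / evidence.depth)
            if fraction <= min_fraction or n < min_clips:
                continue
            lo, hi = int(positions[s]), int(positions[e - 1]) + 1
            if not genome_wide and not _near_cnv_boundary(hap, chrom, lo, hi, cnv_calls, boundary_pad):
                continue
            clips = [
                ClipRecord(int(r.pos), str(r.side), str(r.seq))
                for r in grp.iloc[s:e].itertuples()
            ]
            regions.append(
                BoundaryRegion(
                    haplotype=str(hap),
                    chrom=str(chrom),
                    start=lo,
                    end=hi,
                    side=str(side),
                    partially_unmapped_fraction=fraction,
                    clips=clips,
                )
            )
    return regions


def _near_cnv_boundary(hap, chrom, lo, hi, cnv_calls, pad) -> bool:
    for call in cnv_calls or []:
        if getattr(call, "chrom", None) != chrom:
            continue
        for edge in (call.start, call.end):
            if lo - pad <= edge <= hi + pad:
                return True
    return False


def clip_consensus(region: BoundaryRegion, max_len: int = 250) -> str:
    """Per-column majority vote over clip tails anchored at the junction.

    Right-clips are anchored at their first base, left-clips at their
    last base (both abut the junction), so columns line up without
    alignment.
    """
    seqs = [c.seq for c in region.clips if c.pos == region.clip_pos]
    if not seqs:
        return ""
    if region.side == "L":
        seqs = [s[::-1] for s in seqs]
    length = min(max(len(s) for s in seqs), max_len)
    out = []
    for i in range(length):
        col = Counter(s[i] for s in seqs if len(s) > i)
        out.append(col.most_common(1)[0][0])
    cons = "".join(out)
    return cons[::-1] if region.side == "L" else cons


@dataclass
class PartnerHit:
    hit: Hit
    ambiguous: bool
    tied: list[Hit]


def locate_partner(
    region: BoundaryRegion,
    aligner: LocalAligner,
    e_threshold: float = 1e-4,
    min_clip: int = 20,
) -> PartnerHit | None:
    """Best local-alignment hit of the clip consensus, ties flagged.

    Returns None when no hit clears the E-value threshold (junction
    left open).  Ties on score are broken deterministically (chromosome
    then position) and flagged ambiguous.
    """
    cons = clip_consensus(region)
    if len(cons) < min_clip:
        return None
    hits = [
        h
        for h in aligner.search(cons, e_threshold=e_threshold)
        # the clip tail must match near its junction-abutting end
        if (h.q_start <= 5 if region.side == "R" else h.q_end >= len(cons) - 5)
    ]
    if not hits:
        return None
    best = hits[0]
    tied = [h for h in hits if h.score == best.score]
    return PartnerHit(hit=best, ambiguous=len(tied) > 1, tied=tied)


def reciprocal_check(
    region: BoundaryRegion,
    partner: PartnerHit,
    regions: list[BoundaryRegion],
    aligner: LocalAligner,
    e_threshold: float = 1e-4,
    tolerance: int = 2_000,
) -> bool:
    """Reciprocal best hit: the partner-side region must point back.

    Finds the boundary region at the partner locus (opposite side) and
    requires that its own best partner hit (or any tied hit) falls back
    on the original region within ``tolerance`` bp.
    """
    key = partner.hit.chrom_key
    want_side = "L" if region.side == "R" else "R"
    back_pos = partner.hit.ref_start if region.side == "R" else partner.hit.ref_end
    for other in regions:
        if (other.haplotype, other.chrom) != key or other.side != want_side:
            continue
        if abs(other.clip_pos - back_pos) > tolerance:
            continue
        back = locate_partner(other, aligner, e_threshold)
        if back is None:
            continue
        for h in back.tied:
            if (
                h.chrom_key == (region.haplotype, region.chrom)
                and abs((h.ref_end if other.side == "L" else h.ref_start) - region.clip_pos)
                <= tolerance
            ):
                return True
    return False


def confirm_discordant_pairs(
    locus_left: tuple[str, str, int],
    locus_right: tuple[str, str, int],
    evidence: Evidence,
    window: int = 2_000,
    min_pairs: int = 2,
) -> int:
    """Count properly oriented pairs bridging the two junction flanks.

    ``locus_left``/``locus_right`` are the (haplotype, chrom, pos) whose
    left/right flanks form the junction.  A supporting pair has one end
    on the + strand just upstream of the left breakpoint and the mate on
    the − strand just downstream of the right one (either mate order);
    mis-oriented pairs are not counted.  ``min_pairs`` defaults to 2
    reads.
    """
    ha, ca, pa = locus_left
    hb, cb, pb = locus_right
    n = 0
    for row in evidence.pairs.itertuples():
        fwd = (
            row.haplotype_a == ha
            and row.chrom_a == ca
            and row.strand_a == "+"
            and pa - window <= row.pos_a <= pa
            and row.haplotype_b == hb
            and row.chrom_b == cb
            and row.strand_b == "-"
            and pb <= row.pos_b <= pb + window
        )
        rev = (
            row.haplotype_b == ha
            and row.chrom_b == ca
            and row.strand_b == "+"
            and pa - window <= row.pos_b <= pa
            and row.haplotype_a == hb
            and row.chrom_a == cb
            and row.strand_a == "-"
            and pb <= row.pos_a <= pb + window
        )
        if fwd or rev:
            n += 1
    return n


def reconstruct_junction(
    region: BoundaryRegion,
    partner: PartnerHit,
    dual_ref: DualReference,
    motif: str = DEFAULT_MOTIF,
) -> Junction:
    """Canonical junction from a boundary region and its located partner.

    For a right-clip region, the junction's left flank ends at the clip
    position on the region's chromosome and the right flank starts at
    the partner match; microhomology and motif accounting then run on
    the canonicalised breakpoints.  Untemplated bases between flank and
    partner match are recorded as an insertion.
    """
    sequences = {
        (h.name, c): s
        for h in (dual_ref.haplome_a, dual_ref.haplome_b)
        for c, s in h.chromosomes.items()
    }
    repeats = repeat_lookup(
        {dual_ref.haplome_a.name: dual_ref.haplome_a, dual_ref.haplome_b.name: dual_ref.haplome_b}
    )
    hit = partner.hit
    if region.side == "R":
        locus_a = (region.haplotype, region.chrom, region.clip_pos)
        locus_b = (hit.chrom_key[0], hit.chrom_key[1], hit.ref_start - hit.q_start)
        inserted = ""
        if hit.q_start > 0:
            inserted = clip_consensus(region)[: hit.q_start]
            locus_b = (hit.chrom_key[0], hit.chrom_key[1], hit.ref_start)
    else:
        cons = clip_consensus(region)
        locus_a = (
            hit.chrom_key[0],
            hit.chrom_key[1],
            hit.ref_end + (len(cons) - hit.q_end),
        )
        locus_b = (region.haplotype, region.chrom, region.clip_pos)
        inserted = ""
        if hit.q_end < len(cons):
            inserted = cons[hit.q_end :]
            locus_a = (hit.chrom_key[0], hit.chrom_key[1], hit.ref_end)
    junc = build_junction(sequences, locus_a, locus_b, motif=motif, inserted=inserted, repeats=repeats)
    junc.n_clips = len(region.clips)
    junc.ambiguous_partner = partner.ambiguous
    # clip disagreement beyond the consensus majority flags low confidence
    seqs = [c.seq for c in region.clips if c.pos == region.clip_pos]
    if len(seqs) >= 3:
        cons = clip_consensus(region)
        mism = 0
        total = 0
        for s in seqs:
            s_cmp = s[::-1] if region.side == "L" else s
            c_cmp = cons[::-1] if region.side == "L" else cons
            n = min(len(s_cmp), len(c_cmp))
            total += n
            mism += sum(1 for i in range(n) if s_cmp[i] != c_cmp[i])
        if total and mism / total > 0.2:
            junc.low_confidence = True
    return junc


def classify_mechanism(
    junction: Junction,
    site_index: RestrictionSiteIndex | None = None,
    motif: str = DEFAULT_MOTIF,
) -> MechanismCall:
    """Repair-mechanism call in priority order.

    homologous (same-family repeat context on both flanks) →
    direct religation (motif spans the join, zero net loss) →
    microhomology (2–3 nt overlap, no spanning site) → unclassified.
    """
    fa, fb = junction.repeat_context
    if fa is not None and fa == fb:
        return MechanismCall(
            "homologous", f"both breakpoints within {fa} repeat annotations"
        )
    if junction.contains_restriction_site and junction.net_deleted == 0 and not junction.inserted:
        return MechanismCall(
            "taqi_direct",
            f"{motif} reconstituted across the join with no net loss",
        )
    if 2 <= junction.overlap_len <= 3 and not junction.contains_restriction_site:
        return MechanismCall(
            "microhomology",
            f"{junction.overlap_len} nt exact overlap, no restriction site at the join",
        )
    return MechanismCall("unclassified", "no mechanism signature matched")


@dataclass
class JunctionCall:
    junction: Junction
    mechanism: MechanismCall
    n_pairs: int
    reciprocal: bool
    rdna_flag: bool = False

    @property
    def is_translocation(self) -> bool:
        return self.junction.is_interchromosomal


def call_junctions(
    evidence: Evidence,
    dual_ref: DualReference,
    cnv_calls: list | None = None,
    aligner: LocalAligner | None = None,
    e_threshold: float = 1e-4,
    min_pairs: int = 2,
    window: int = 200,
    motif: str = DEFAULT_MOTIF,
    genome_wide: bool = True,
) -> list[JunctionCall]:
    """Full junction scan: regions → partners → pairs → mechanism.

    Junctions seen from both sides collapse onto one canonical call.
    rDNA-context junctions are reported but flagged non-verifiable.
    """
    if aligner is None:
        sequences = {
            (h.name, c): s
            for h in (dual_ref.haplome_a, dual_ref.haplome_b)
            for c, s in h.chromosomes.items()
        }
        aligner = LocalAligner(sequences)
    regions = find_boundary_regions(
        evidence, cnv_calls, window=window, genome_wide=genome_wide
    )
    calls: dict[tuple, JunctionCall] = {}
    for region in regions:
        partner = locate_partner(region, aligner, e_threshold)
        if partner is None:
            continue
        junc, n_pairs, partner = _resolve_with_pairs(
            region, partner, evidence, dual_ref, motif, min_pairs
        )
        recip = reciprocal_check(region, partner, regions, aligner, e_threshold)
        junc.n_pairs = n_pairs
        mech = classify_mechanism(junc, motif=motif)
        rdna = "rDNA" in (junc.repeat_context[0] or "", junc.repeat_context[1] or "")
        key = junc.canonical_key()
        call = JunctionCall(
            junction=junc,
            mechanism=mech,
            n_pairs=n_pairs,
            reciprocal=recip,
            rdna_flag=rdna,
        )
        prev = calls.get(key)
        if prev is None or (call.n_pairs, junc.n_clips) > (prev.n_pairs, prev.junction.n_clips):
            if prev is not None:
                call.junction.n_clips += prev.junction.n_clips
            calls[key] = call
    return _drop_ambiguous_duplicates(list(calls.values()))


def _resolve_with_pairs(
    region: BoundaryRegion,
    partner: PartnerHit,
    evidence: Evidence,
    dual_ref: DualReference,
    motif: str,
    min_pairs: int,
) -> tuple[Junction, int, PartnerHit]:
    """Pick among tied partner hits by discordant-pair support.

    Clip tails that end inside a locally identical stretch (homolog
    without nearby SNPs, repeat copy) tie across near-identical loci;
    the discordant pairs spanning the junction carry the haplotype and
    copy identity of the true partner.  A unique pair-supported hit
    clears the ambiguity flag.
    """
    candidates = partner.tied if partner.ambiguous else [partner.hit]
    best: tuple[Junction, int, Hit] | None = None
    n_best = 0
    for hit in candidates:
        cand = PartnerHit(hit=hit, ambiguous=False, tied=[hit])
        junc = reconstruct_junction(region, cand, dual_ref, motif=motif)
        n = confirm_discordant_pairs(
            junc.locus_a.key(), junc.locus_b.key(), evidence, min_pairs=min_pairs
        )
        if best is None or n > best[1]:
            n_best = 1
            best = (junc, n, hit)
        elif n == best[1]:
            n_best += 1
    junc, n, hit = best
    resolved = PartnerHit(hit=hit, ambiguous=partner.ambiguous and n_best > 1, tied=partner.tied)
    junc.ambiguous_partner = resolved.ambiguous
    return junc, n, resolved


def _drop_ambiguous_duplicates(calls: list[JunctionCall]) -> list[JunctionCall]:
    """Remove partner-ambiguous calls that re-describe a resolved junction.

    When the clip consensus ties across near-identical repeat or homolog
    copies and no discordant pair settles it, the losing side of a
    junction can resolve to the wrong copy.  Such a call shares its
    trusted (clip-derived) breakpoint locus, in the same junction role,
    with the unambiguous call made from the other side; keep the
    unambiguous one.  (Same-role matching keeps the two reciprocal
    junctions of one exchange, which share both loci in swapped roles.)
    """
    unamb_a: set[tuple] = set()
    unamb_b: set[tuple] = set()
    for c in calls:
        if not c.junction.ambiguous_partner:
            unamb_a.add(c.junction.locus_a.key())
            unamb_b.add(c.junction.locus_b.key())
    kept = []
    for c in calls:
        if c.junction.ambiguous_partner and (
            c.junction.locus_a.key() in unamb_a or c.junction.locus_b.key() in unamb_b
        ):
            continue
        kept.append(c)
    return kept
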