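"""Inter-homolog event calling: break-induced repair and gene conversion.

On a dual-haplotype reference, a non-reciprocal transfer of sequence
from one homolog to the other leaves a reciprocal coverage signature:
zero depth on the acceptor haplotype over the converted tract, doubled
depth on the donor.  Tracts reaching a chromosome end are break-induced
repair (BIR); internal tracts are short gene conversions (SGC).  Tracts
covering the whole chromosome are routed out to aneuploidy/LOH review.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DualReference
from .tracks import CoverageTrack


@dataclass
class Candidate:
    haplotype: str
    chrom: str
    start: int
    end: int


@dataclass
class ReciprocitySupport:
    candidate: Candidate
    homolog_chrom: str
    homolog_interval: tuple[int, int]
    acceptor_zero_fraction: float
    donor_ratio: float
    passed: bool
    reason: str = ""


@dataclass
class HomologEvent:
    type: str  # BIR | SGC
    donor_haplotype: str
    acceptor_haplotype: str
    chrom: str  # acceptor chromosome
    donor_chrom: str
    start: int
    end: int
    extends_to_end: bool
    length: int
    support: ReciprocitySupport

    def __post_init__(self) -> None:
        if self.donor_haplotype == self.acceptor_haplotype:
            raise ValueError("donor and acceptor haplotypes must differ")
        if self.type == "BIR" and not self.extends_to_end:
            raise ValueError("BIR must extend to the chromosome end")
        if self.type == "SGC" and self.extends_to_end:
            raise ValueError("SGC must be internal")


def find_zero_coverage_regions(
    track: CoverageTrack,
    min_len: int = 500,
    merge_gap: int = 200,
    zero_depth_cutoff: float = 0.0,
) -> list[Candidate]:
    """Maximal unmasked runs of (near-)zero depth.

    Bins at or below ``zero_depth_cutoff`` (raw reads per bin) seed
    candidate regions; runs are merged across gaps up to ``merge_gap``
    bp and reported when at least ``min_len`` bp long.
    """
    bs = track.bin_size
    out: list[Candidate] = []
    for chrom, depth in track.values.items():
        mask = track.mask[chrom]
        zero = (depth <= zero_depth_cutoff) & ~mask
        idx = np.flatnonzero(zero)
        if len(idx) == 0:
            continue
        start = prev = int(idx[0])
        runs = []
        for i in idx[1:]:
            i = int(i)
            if (i - prev - 1) * bs <= merge_gap or np.all(mask[prev + 1 : i]):
                prev = i
            else:
                runs.append((start, prev + 1))
                start = prev = i
        runs.append((start, prev + 1))
        for s_bin, e_bin in runs:
            if (e_bin - s_bin) * bs >= min_len:
                out.append(Candidate(track.haplotype, chrom, s_bin * bs, e_bin * bs))
    return out


def test_homolog_reciprocity(
    candidate: Candidate,
    homolog_ratio_track: CoverageTrack,
    dual_ref: DualReference,
    double_cov_threshold: float = 1.6,
) -> ReciprocitySupport:
    """Does the homolog show doubled coverage over the lifted interval?

    The candidate interval is lifted to the homolog; the mean normalized
    depth ratio there must reach ``double_cov_threshold`` (expected 2.0
    for a clean conversion).  A ratio near 1.0 means the dropout is a
    plain deletion and belongs to the CNV caller.
    """
    try:
        hom_chrom, hs, he = dual_ref.liftover(
            candidate.haplotype, candidate.chrom, (candidate.start, candidate.end)
        )
    except KeyError:
        return ReciprocitySupport(
            candidate, "", (0, 0), 1.0, 0.0, False, reason="unpaired chromosome"
        )
    bs = homolog_ratio_track.bin_size
    vals = homolog_ratio_track.values[hom_chrom]
    mask = homolog_ratio_track.mask[hom_chrom]
    s_bin, e_bin = hs // bs, max(hs // bs + 1, (he + bs - 1) // bs)
    seg = vals[s_bin:e_bin][~mask[s_bin:e_bin]]
    ratio = float(np.mean(seg)) if len(seg) else 0.0
    return ReciprocitySupport(
        candidate=candidate,
        homolog_chrom=hom_chrom,
        homolog_interval=(hs, he),
        acceptor_zero_fraction=1.0,
        donor_ratio=ratio,
        passed=ratio >= double_cov_threshold,
        reason="" if ratio >= double_cov_threshold else "homolog not doubled",
    )


def classify_homolog_event(
    support: ReciprocitySupport,
    dual_ref: DualReference,
    end_slack: int = 1_000,
) -> HomologEvent | None:
    """BIR if the chimeric tract reaches a chromosome end, else SGC.

    "Reaches the end" means within the telomere mask plus ``end_slack``
    bp; a tract spanning the entire chromosome is neither (routed to
    aneuploidy/LOH review, returns None).  Boundary positions are
    approximate: homologous tracts have no base-exact junction.
    """
    if not support.passed:
        raise ValueError("reciprocity must pass before classification")
    cand = support.candidate
    hap = dual_ref.haplome(cand.haplotype)
    length = hap.length(cand.chrom)
    telo = hap.telomere_masks.get(cand.chrom, [])
    lead = telo[0][1] if telo else 0
    tail = telo[-1][0] if telo else length
    touches_start = cand.start <= lead + end_slack
    touches_end = cand.end >= tail - end_slack
    if touches_start and touches_end:
        return None
    kind = "BIR" if (touches_start or touches_end) else "SGC"
    # a BIR tract extends through the (masked) telomere to the chromosome end
    start = 0 if kind == "BIR" and touches_start else cand.start
    end = length if kind == "BIR" and touches_end else cand.end
    return HomologEvent(
        type=kind,
        donor_haplotype=dual_ref.other_haplotype(cand.haplotype),
        acceptor_haplotype=cand.haplotype,
        chrom=cand.chrom,
        donor_chrom=support.homolog_chrom,
        start=start,
        end=end,
        extends_to_end=kind == "BIR",
        length=end - start,
        support=support,
    )


def call_homolog_events(
    raw_tracks: dict[str, CoverageTrack],
    ratio_tracks: dict[str, CoverageTrack],
    dual_ref: DualReference,
    min_len: int = 500,
    merge_gap: int = 200,
    zero_depth_cutoff: float = 0.0,
    double_cov_threshold: float = 1.6,
    end_slack: int = 1_000,
) -> list[HomologEvent]:
    """Full BIR/SGC scan over both haplotypes.

    Every reciprocity-passing candidate becomes exactly one of BIR, SGC
    or routed-out; failing candidates are left to the CNV caller.
    """
    events: list[HomologEvent] = []
    for hap_name, track in raw_tracks.items():
        other = dual_ref.other_haplotype(hap_name)
        for cand in find_zero_coverage_regions(track, min_len, merge_gap, zero_depth_cutoff):
            support = test_homolog_reciprocity(
                cand, ratio_tracks[other], dual_ref, double_cov_threshold
            )
            if not support.passed:
                continue
            ev = classify_homolog_event(support, dual_ref, end_slack)
            if ev is not None:
                events.append(ev)
    return events


def events_to_frame(events: list[HomologEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "type": e.type,
                "acceptor_haplotype": e.acceptor_haplotype,
                "donor_haplotype": e.donor_haplotype,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "length": e.length,
                "extends_to_end": e.extends_to_end,
                "donor_ratio": e.support.donor_ratio,
            }
            for e in events
        ]
    )
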