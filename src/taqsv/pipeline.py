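"""End-to-end drivers: simulate a restructured hybrid, run all callers.

These glue functions fix the hand-offs between modules: raw coverage
feeds the zero-coverage scan, normalized per-haplotype ratios feed
reciprocity testing, the combined ratio plus array feeds aneuploidy and
local-CNV calling, and the clip/pair evidence feeds junction calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import LocalAligner
from .breakpoints import JunctionCall, call_junctions
from .cnv import CnvCall, call_aneuploidy, combine_haplotype_ratios, normalize_coverage, segment_local_cnv
from .genome import DualReference
from .homolog import HomologEvent, call_homolog_events
from .evidence import Evidence
from .simulate import (
    EventSpec,
    RepeatSpec,
    RestructuredGenome,
    TruthSet,
    plant_events,
    simulate_acgh,
    simulate_coverage,
    simulate_junction_evidence,
    simulate_parental_pair,
)
from .tracks import CoverageTrack


@dataclass
class SimulatedCase:
    dual_ref: DualReference
    restructured: RestructuredGenome
    truth: TruthSet
    tracks: dict[str, CoverageTrack]
    array: pd.DataFrame
    evidence: Evidence


@dataclass
class DetectionResult:
    aneuploidy: list[CnvCall] = field(default_factory=list)
    local_cnv: list[CnvCall] = field(default_factory=list)
    homolog_events: list[HomologEvent] = field(default_factory=list)
    junctions: list[JunctionCall] = field(default_factory=list)

    @property
    def translocations(self) -> list[JunctionCall]:
        return [j for j in self.junctions if j.is_translocation]


def simulate_case(
    chrom_lengths: dict[str, int] | list[int],
    event_spec: EventSpec | None = None,
    repeat_spec: RepeatSpec | None = None,
    seed: int = 0,
    mean_depth: float = 80.0,
    bin_size: int = 100,
    noise: str = "nb",
    dispersion: float = 0.1,
    snp_per_kb: float = 6.5,
    indel_per_kb: float = 0.7,
) -> SimulatedCase:
    """One fully simulated restructured hybrid with all derived data.

    Sub-seeds for the genome, events, coverage, array and evidence are
    derived deterministically from ``seed``.
    """
    dual_ref = simulate_parental_pair(
        chrom_lengths,
        snp_per_kb=snp_per_kb,
        indel_per_kb=indel_per_kb,
        repeat_spec=repeat_spec,
        seed=seed,
    )
    restructured, truth = plant_events(dual_ref, event_spec, seed=seed + 1)
    tracks = simulate_coverage(
        restructured,
        dual_ref,
        mean_depth=mean_depth,
        bin_size=bin_size,
        noise=noise,
        dispersion=dispersion,
        seed=seed + 2,
    )
    array = simulate_acgh(restructured, dual_ref, seed=seed + 3)
    evidence = simulate_junction_evidence(
        restructured, truth, dual_ref, depth=mean_depth, seed=seed + 4
    )
    return SimulatedCase(dual_ref, restructured, truth, tracks, array, evidence)


def renoise_case(case: SimulatedCase, seed: int, dispersion: float = 0.1) -> SimulatedCase:
    """Fresh coverage/evidence noise on a fixed restructured genome."""
    depth = case.evidence.depth
    bin_size = next(iter(case.tracks.values())).bin_size
    tracks = simulate_coverage(
        case.restructured,
        case.dual_ref,
        mean_depth=depth,
        bin_size=bin_size,
        noise="nb",
        dispersion=dispersion,
        seed=seed,
    )
    array = simulate_acgh(case.restructured, case.dual_ref, seed=seed + 1)
    evidence = simulate_junction_evidence(
        case.restructured, case.truth, case.dual_ref, depth=depth, seed=seed + 2
    )
    return SimulatedCase(case.dual_ref, case.restructured, case.truth, tracks, array, evidence)


def run_detection(
    dual_ref: DualReference,
    tracks: dict[str, CoverageTrack],
    array: pd.DataFrame | None,
    evidence: Evidence | None,
    ploidy: int = 2,
    aligner: LocalAligner | None = None,
    min_local_cnv: int = 100_000,
) -> DetectionResult:
    """All callers on one sample's tracks and evidence."""
    name_a = dual_ref.haplome_a.name
    name_b = dual_ref.haplome_b.name
    ratio = {h: normalize_coverage(t) for h, t in tracks.items()}
    combined = combine_haplotype_ratios(ratio[name_a], ratio[name_b], dual_ref.pairing)
    result = DetectionResult()
    result.aneuploidy = call_aneuploidy(combined, array, ploidy=ploidy)
    aneuploid_chroms = {c.chrom for c in result.aneuploidy}
    local = segment_local_cnv(combined, min_length=min_local_cnv, array_track=array, ploidy=ploidy)
    result.local_cnv = [c for c in local if c.chrom not in aneuploid_chroms]
    result.homolog_events = call_homolog_events(tracks, ratio, dual_ref)
    if evidence is not None:
        result.junctions = call_junctions(
            evidence, dual_ref, cnv_calls=result.local_cnv, aligner=aligner
        )
    return result
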