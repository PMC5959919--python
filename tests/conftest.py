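"""Shared fixtures: simulated hybrid genomes at two scales.

``small_ref`` is a light dual reference for unit tests; ``study_case``
is the full-scale noise-free restructured hybrid (two ~2 Mb parental
genomes, full event spectrum) shared by the pipeline round-trip and
acceptance tests.  Session scope keeps the expensive simulations to one
run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from taqsv.align import LocalAligner
from taqsv.pipeline import SimulatedCase, run_detection, simulate_case
from taqsv.simulate import RepeatSpec, simulate_parental_pair

#: 13 chromosomes x 154 kb ~ 2.0 Mb per parental haplome
STUDY_CHROMS = [154_000] * 13
STUDY_SEED = 11


@pytest.fixture(scope="session")
def small_ref():
    return simulate_parental_pair(
        [80_000, 60_000],
        repeat_spec=RepeatSpec(ty_copies=2, rdna_copies=1, transposon_copies=2),
        seed=5,
    )


@pytest.fixture(scope="session")
def study_case() -> SimulatedCase:
    return simulate_case(STUDY_CHROMS, seed=STUDY_SEED, noise="none")


@pytest.fixture(scope="session")
def study_aligner(study_case) -> LocalAligner:
    dual_ref = study_case.dual_ref
    sequences = {
        (h.name, c): s
        for h in (dual_ref.haplome_a, dual_ref.haplome_b)
        for c, s in h.chromosomes.items()
    }
    return LocalAligner(sequences)


@pytest.fixture(scope="session")
def study_result(study_case, study_aligner):
    return run_detection(
        study_case.dual_ref,
        study_case.tracks,
        study_case.array,
        study_case.evidence,
        aligner=study_aligner,
    )


def truth_junction_keys(case: SimulatedCase) -> dict[tuple, str]:
    return {
        j.canonical_key(): e.mechanism
        for e in case.truth.by_type("TL")
        for j in e.junctions
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
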