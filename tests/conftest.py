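import numpy as np
import pytest

from somascape import (
    SNPMap,
    State,
    StatusMatrix,
    call_profile,
    firestorm_spec,
    generate_cohort,
    sawtooth_spec,
)


@pytest.fixture(scope="session")
def small_map() -> SNPMap:
    """Reduced default genome: 100 probes per chromosome, 23 chromosomes."""
    return SNPMap.default(probes_per_chromosome=100)


@pytest.fixture(scope="session")
def tiny_map() -> SNPMap:
    """Single synthetic chromosome with 200 evenly spaced probes."""
    return SNPMap(
        chromosomes=("1",),
        positions={"1": np.arange(1, 200_001, 1000, dtype=np.int64)},
    )


@pytest.fixture(scope="session")
def cohort(small_map):
    """Two-archetype cohort (10 + 10, plant probability 0.95) plus matrix."""
    profiles, truth = generate_cohort(
        [(sawtooth_spec(0.95), 10), (firestorm_spec(0.95), 10)],
        small_map,
        seed=1,
    )
    status = [call_profile(p, small_map) for p in profiles]
    matrix = StatusMatrix.from_profiles(status, small_map)
    return profiles, truth, matrix


def make_matrix(states: np.ndarray, snp_map: SNPMap) -> StatusMatrix:
    """StatusMatrix from a raw (n_samples, n_probes) state array."""
    states = np.asarray(states, dtype=np.int8)
    return StatusMatrix(
        snp_map=snp_map,
        sample_ids=[f"s{i}" for i in range(states.shape[0])],
        states=states,
    )


def run_length_breakpoint_oracle(profile) -> int:
    """Independent oracle: (# maximal constant runs) - (# chromosomes)."""
    runs = 0
    chroms = set()
    prev = None
    for seg in profile.segments:
        chroms.add(seg.chrom)
        key = (seg.chrom, seg.total, seg.minor)
        if key != prev:
            runs += 1
        prev = key
    return runs - len(chroms)


ALL_STATES = [State.LOSS, State.NEUTRAL, State.GAIN, State.AMP]
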