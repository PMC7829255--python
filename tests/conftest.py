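import numpy as np
import pytest

from fuseload.labels import individual_label
from fuseload.segmentation import SampleSet, build_sample_set
from fuseload.synth import ParticipantProfile, SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One short simulated session (3 puzzles, ~90 markers worth of time)."""
    cfg = SimConfig(
        n_puzzles=3,
        puzzle_difficulties=(1, 3, 5),
        puzzle_duration=120.0,
        rest_duration=15.0,
        seed=42,
    )
    return cfg, *simulate_session(cfg)


@pytest.fixture(scope="session")
def small_sample_set(small_session) -> SampleSet:
    _, rec, truth = small_session
    ratings = {p: individual_label(r) for p, r in truth.ratings.items()}
    return build_sample_set(rec, ratings)


def make_study_data(seed: int, n_sessions: int = 4,
                    puzzle_duration: float = 240.0) -> SampleSet:
    """The reduced-scale study dataset: several participants, 5 puzzles each."""
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sessions):
        prof = ParticipantProfile(rating_bias=float(rng.normal(0, 0.5)))
        cfg = SimConfig(
            puzzle_duration=puzzle_duration,
            rest_duration=15.0,
            profile=prof,
            participant_id=f"p{i}",
            seed=int(rng.integers(2**31)),
        )
        rec, truth = simulate_session(cfg)
        ratings = {p: individual_label(r) for p, r in truth.ratings.items()}
        sets.append(build_sample_set(rec, ratings))
    return SampleSet.concat(sets)
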