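"""Shared fixtures: synthetic records with ground truth, reused per session."""

import numpy as np
import pytest

from rqtecg.core import Morphology
from rqtecg.delineation import delineate_record
from rqtecg.synth import SyntheticSpec, generate_ecg

ALL_CLASSES = list(Morphology)
FIVE_CLASSES = [
    Morphology.MONOPHASIC_POS,
    Morphology.BIPHASIC_PN,
    Morphology.BIPHASIC_NP,
    Morphology.NOTCHED,
    Morphology.FLAT,
]


def class_spec(morph: Morphology, n_beats: int = 100, noise_sd: float = 0.0, seed: int = 11) -> SyntheticSpec:
    """Study-condition spec for one morphology class (flat uses a small T)."""
    return SyntheticSpec(
        n_beats=n_beats,
        t_morphology=morph,
        t_amp_frac=0.05 if morph is Morphology.FLAT else 0.35,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_monophasic():
    """Noise-free 100-beat monophasic record with ground truth."""
    return generate_ecg(class_spec(Morphology.MONOPHASIC_POS))


@pytest.fixture(scope="session")
def delineated_monophasic(clean_monophasic):
    record, truth = clean_monophasic
    return record, truth, delineate_record(record)


@pytest.fixture(scope="session")
def bazett_series():
    """Interval series of a Bazett-consistent record, from truth fiducials."""
    from rqtecg.intervals import build_interval_series

    record, truth = generate_ecg(SyntheticSpec(n_beats=300, seed=3))
    return build_interval_series(truth, record.fs), truth, record


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
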