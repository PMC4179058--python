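import numpy as np
import pytest

from thermotrack import SceneSpec, ThermalFrame
from thermotrack import synthetic as syn

#: Contrast-decay study condition for altitude-sweep experiments (per meter
#: above the 5 m reference); see docs/methods.md.
SWEEP_DECAY = 0.04


def make_frame(values, **kwargs) -> ThermalFrame:
    return ThermalFrame(values=np.asarray(values, dtype=float), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20140730)


@pytest.fixture
def square_frame():
    """7x7 frame at 20 C with a 3x3 block at 30 C."""
    vals = np.full((7, 7), 20.0)
    vals[2:5, 2:5] = 30.0
    return make_frame(vals)


@pytest.fixture(scope="session")
def small_training_set():
    """Low-altitude synthetic training set shared across tests."""
    return syn.generate_training_set(n_animal=60, n_nonanimal=100, seed=11)


@pytest.fixture(scope="session")
def sweep_training_set():
    """Training set spanning 3-18 m under the contrast-decay condition."""
    return syn.generate_training_set(
        n_animal=60, n_nonanimal=100, seed=11,
        altitude_range=(3.0, 18.0), contrast_decay=SWEEP_DECAY,
    )


def random_blob_mask(rng, shape=(24, 24)) -> np.ndarray:
    """A random connected blob mask grown from a seed pixel."""
    mask = np.zeros(shape, dtype=bool)
    r, c = shape[0] // 2, shape[1] // 2
    mask[r, c] = True
    frontier = [(r, c)]
    n_target = int(rng.integers(3, 60))
    while frontier and mask.sum() < n_target:
        i = int(rng.integers(len(frontier)))
        r, c = frontier.pop(i)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 1 <= rr < shape[0] - 1 and 1 <= cc < shape[1] - 1 and not mask[rr, cc]:
                if rng.random() < 0.7:
                    mask[rr, cc] = True
                    frontier.append((rr, cc))
    return mask
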