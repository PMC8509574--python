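"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from pleurovol.phantom import PhantomSpec, generate_phantom
from pleurovol.recist import measure_burden
from pleurovol.segmentation import segment_lungs


class PhantomCase:
    """A generated phantom with its segmentation and burden measurement."""

    def __init__(self, spec):
        self.spec = spec
        self.vol, self.truth = generate_phantom(spec)
        self.seg = segment_lungs(self.vol)
        self.masks = {"left": self.seg.left_mask, "right": self.seg.right_mask}

    def burden(self):
        return measure_burden(self.vol, self.masks, self.spec.level_planes)


@pytest.fixture(scope="session")
def phantom_clean():
    """Disease-free phantom (no rind, no noise)."""
    return PhantomCase(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_uniform20():
    """20 mm rind at every level on the right, noise-free."""
    return PhantomCase(PhantomSpec(rind_mm=(20.0, 20.0, 20.0)))


@pytest.fixture(scope="session")
def phantom_graded():
    """Graded 10/20/30 mm rind, noise-free."""
    return PhantomCase(PhantomSpec(rind_mm=(10.0, 20.0, 30.0)))


@pytest.fixture(scope="session")
def phantom_noisy():
    """20 mm rind with 50 HU Gaussian noise."""
    return PhantomCase(PhantomSpec(rind_mm=(20.0, 20.0, 20.0), noise_sd_hu=50.0, seed=3))


@pytest.fixture(scope="session")
def table2():
    from pleurovol.fixtures import load_table2

    return load_table2()
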