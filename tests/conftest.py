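"""Shared fixtures: random masks and probability maps for oracle tests."""

import numpy as np
import pytest

from omgeye.mask import LabelMask, ProbMap


def make_random_mask(rng: np.random.Generator, h: int = 8, w: int = 8, m: int = 5) -> LabelMask:
    return LabelMask(rng.integers(0, m, size=(h, w)))


def make_random_probmap(rng: np.random.Generator, h: int = 8, w: int = 8, m: int = 5) -> ProbMap:
    raw = rng.random((h, w, m)) + 1e-3
    return ProbMap(raw / raw.sum(axis=2, keepdims=True))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
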