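"""Shared fixtures: ideal (noise-free) peak tables and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ctg18 import (
    Assay,
    CallerParams,
    ClassificationRule,
    Peak,
    PeakTable,
    SimConfig,
    SizingModel,
    tp_ladder_sizes,
)


@pytest.fixture
def model() -> SizingModel:
    return SizingModel()


@pytest.fixture
def rule() -> ClassificationRule:
    return ClassificationRule()


@pytest.fixture
def params() -> CallerParams:
    return CallerParams()


def make_str_table(sizes, heights=None, sample_id="S1") -> PeakTable:
    heights = heights or [1000.0] * len(sizes)
    return PeakTable(
        sample_id=sample_id,
        assay=Assay.STR,
        peaks=[Peak(s, h) for s, h in zip(sizes, heights)],
    )


def make_tp_table(alleles, amplitude=1000.0, decay=1.0, sample_id="S1") -> PeakTable:
    """Ideal TP ladder for one or two alleles: rung k covered by every
    allele of >= k repeats, intensity per covering allele decaying
    geometrically along the tract."""
    model = SizingModel()
    heights: dict[float, float] = {}
    for n in alleles:
        for k, size in enumerate(tp_ladder_sizes(n, model)):
            heights[size] = heights.get(size, 0.0) + amplitude * decay**k
    peaks = [Peak(s, h) for s, h in sorted(heights.items())]
    return PeakTable(sample_id=sample_id, assay=Assay.TP, peaks=peaks)


@pytest.fixture
def noise_free_config() -> SimConfig:
    return SimConfig().noise_free()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
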