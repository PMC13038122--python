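"""Shared fixtures: small synthetic cells and straight-cable builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from tmscouple.morphology import (
    Morphology,
    Section,
    SectionKind,
    SyntheticMorphSpec,
    compartmentalize,
    generate_synthetic,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def straight_cable_morphology(
    length: float = 1000.0,
    diameter: float = 1.0,
    kind: SectionKind = SectionKind.AXON,
    direction: np.ndarray | None = None,
    soma_diameter: float = 15.0,
    n_points: int = 2,
) -> Morphology:
    """Soma plus one straight section of given length along ``direction``.

    The axon grows along -z (down the somatodendritic axis) by default.
    """
    if direction is None:
        direction = np.array([0.0, 0.0, -1.0])
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    half = soma_diameter / 2.0
    soma = Section(
        id=0,
        parent_id=None,
        kind=SectionKind.SOMA,
        points=np.array([[0.0, 0.0, -half], [0.0, 0.0, half]]),
        diameters=np.array([soma_diameter, soma_diameter]),
    )
    start = half * np.sign(direction[2]) if direction[2] != 0 else 0.0
    origin = np.array([0.0, 0.0, start])
    ts = np.linspace(0.0, length, n_points)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    cable = Section(
        id=1,
        parent_id=0,
        kind=kind,
        points=pts,
        diameters=np.full(n_points, diameter),
    )
    return Morphology(
        sections=[soma, cable],
        soma_center=np.zeros(3),
        somatodendritic_axis=np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture
def small_cell():
    """Branched synthetic presynaptic cell (12 axon terminals)."""
    return generate_synthetic(SyntheticMorphSpec(n_axon_terminals=12, rng_seed=3))


@pytest.fixture
def small_model(small_cell):
    return compartmentalize(small_cell, 20.0)


@pytest.fixture
def straight_axon_model():
    """Unbranched 1 mm axon discretized at 10 um."""
    return compartmentalize(straight_cable_morphology(length=1000.0), 10.0)
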