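"""Shared fixtures: small morphologies and a warm simulator."""

from __future__ import annotations

import numpy as np
import pytest

from stellate import MorphologyConfig, generate_morphology
from stellate.morphology import Morphology


@pytest.fixture(scope="session")
def default_morph() -> Morphology:
    return generate_morphology(seed=1)


@pytest.fixture(scope="session")
def soma_only() -> Morphology:
    d = float(np.sqrt(757.0 / np.pi))
    return Morphology(
        parent=[-1], length=[d], diameter=[d], area=[757.0],
        path_distance=[0.0], region=[0],
    )


def chain_morphology(n_links: int = 10, link_um: float = 20.0, diam: float = 1.0) -> Morphology:
    """Soma plus a single unbranched dendrite of n equal compartments."""
    parent = [-1] + list(range(n_links))
    d_soma = float(np.sqrt(757.0 / np.pi))
    length = [d_soma] + [link_um] * n_links
    diameter = [d_soma] + [diam] * n_links
    area = [757.0] + [np.pi * diam * link_um] * n_links
    pd = [0.0] + [link_um / 2 + link_um * k for k in range(n_links)]
    region = [0] + [1] * n_links
    return Morphology(parent=parent, length=length, diameter=diameter,
                      area=area, path_distance=pd, region=region)


@pytest.fixture(scope="session")
def chain10() -> Morphology:
    return chain_morphology(10)
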