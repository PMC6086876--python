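"""Shared fixtures: small decoy systems with planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import surfchannel as sc


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_system():
    """150-frame decoy with the default planted channel (3 scripted walkers)."""
    spec = sc.DecoySpec(n_frames=150, n_protein_residues=150, seed=11)
    structure, truth, traj = sc.generate(spec)
    return spec, structure, truth, traj


@pytest.fixture(scope="session")
def small_series(small_system):
    _, _, _, traj = small_system
    return sc.extract_centroid_series(traj)


@pytest.fixture(scope="session")
def default_sites():
    return [
        sc.SiteDefinition("empty", "resname PLP"),
        sc.SiteDefinition("occupied", "resname PLX"),
    ]
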