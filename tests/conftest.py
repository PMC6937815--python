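"""Shared fixtures: deterministic synthetic structures for all test modules."""

from __future__ import annotations

import numpy as np
import pytest

from epimimic.core import AtomRecord, ProteinStructure, Residue
from epimimic.fixtures import FixtureSpec, make_structure


def toy_structure(
    ca_coords,
    sequence=None,
    accessible=None,
    sasa_rel=None,
    chain="A",
    structure_id="toy",
):
    """Structure with one CA atom per residue at given coordinates.

    Convenient for tests that plant exact distances; not a valid backbone.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    n = len(ca_coords)
    sequence = sequence or "A" * n
    residues = []
    for i in range(n):
        key = (chain, i + 1, "")
        r = Residue(
            key=key,
            aa=sequence[i],
            atoms=[AtomRecord(name="CA", element="C", coord=ca_coords[i], residue_key=key)],
        )
        r.accessible = True if accessible is None else bool(accessible[i])
        r.sasa_rel = (1.0 if r.accessible else 0.0) if sasa_rel is None else sasa_rel[i]
        r.sasa_abs = (r.sasa_rel or 0.0) * 100.0
        residues.append(r)
    return ProteinStructure(id=structure_id, chains={chain: residues})


@pytest.fixture(scope="session")
def helix20():
    return make_structure(FixtureSpec(n_residues=20, geometry="helix", seed=11))


@pytest.fixture(scope="session")
def strand30():
    return make_structure(FixtureSpec(n_residues=30, geometry="strand", seed=7))


@pytest.fixture(scope="session")
def masked_structure():
    """40-residue coil with every 5th residue buried: 8 segments of 4."""
    return make_structure(
        FixtureSpec(
            n_residues=40,
            geometry="coil",
            seed=2,
            accessibility_mask=[i % 5 != 4 for i in range(40)],
        )
    )


@pytest.fixture(scope="session")
def masked_model(masked_structure):
    from epimimic.surface_model import build_surface_model

    return build_surface_model(masked_structure)
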