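"""Deterministic synthetic structures and toy antigen-antibody complexes.

Every other module is testable offline: the builders produce ideal-geometry
backbones (N, CA, C, O, CB) from dihedral templates, optionally force an
accessibility pattern (annotation mask or a physical burial cage of
occluding pseudo-atoms), and plant inter-chain contacts at exact distances
so that epitope extraction and every design method can run on structures
generated from a seed.

Limitations by construction: side chains stop at CB, glycine and proline
are excluded from default sequences, and planted antibody "residues" are
minimal glycine-like probes placed outward from the antigen surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    MAX_ASA,
    AgAbComplex,
    AtomRecord,
    ProteinStructure,
    Residue,
)
from .geometry import place_atom
from .structure_io import compute_accessibility, write_structure

__all__ = ["FixtureSpec", "make_structure", "make_complex", "random_complex_spec"]

#: Dihedral templates (phi, psi) for the ideal geometries.
GEOMETRY_TEMPLATES = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 130.0),
}

#: (phi, psi) pool for the "coil" template (broad allowed-region sample).
COIL_POOL = [
    (-57.0, -47.0), (-120.0, 130.0), (-75.0, 150.0), (-90.0, 0.0),
    (-140.0, 160.0), (-60.0, -30.0), (-100.0, 120.0), (-80.0, 80.0),
]

#: Default fixture alphabet (no Gly/Pro: every residue gets an ideal CB).
FIXTURE_AA = "ACDEFHIKLMNQRSTVWY"


def _geometry_constants() -> dict[str, float]:
    path = resources.files("epimimic.data") / "backbone_geometry.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["parameter"], df["value"]))


GEO = _geometry_constants()


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure or complex.

    ``planted_contacts`` is a list of ``(ag_residue_number, distance_A)``
    pairs; each gets a dedicated antibody probe residue placed outward so
    that the minimum atom distance between the pair equals the requested
    distance within 0.01 A.
    """

    n_residues: int = 20
    geometry: str = "strand"  # helix | strand | coil
    sequence: Optional[str] = None
    accessibility_mask: Optional[Sequence[bool]] = None
    buried_residues: Sequence[int] = field(default_factory=tuple)  # 1-based
    planted_contacts: Sequence[tuple[int, float]] = field(default_factory=tuple)
    seed: int = 0
    chain_id: str = "A"

    def dihedrals(self, rng: np.random.Generator) -> list[tuple[float, float]]:
        if self.geometry in GEOMETRY_TEMPLATES:
            return [GEOMETRY_TEMPLATES[self.geometry]] * self.n_residues
        if self.geometry == "coil":
            idx = rng.integers(0, len(COIL_POOL), size=self.n_residues)
            return [COIL_POOL[i] for i in idx]
        raise ValueError(f"unknown geometry {self.geometry!r}")


def _build_backbone(dihedrals: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Residue atom dictionaries (N, CA, C, O, CB) from (phi, psi) pairs."""
    phis = [d[0] for d in dihedrals]
    psis = [d[1] for d in dihedrals]
    n = len(phis)
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([GEO["bond_N_CA"], 0.0, 0.0])
    c0 = place_atom(
        np.array([0.0, 1.0, 0.0]), n0, ca0, GEO["bond_CA_C"], GEO["angle_N_CA_C"], phis[0]
    )
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = res[-1]
        ni = place_atom(
            prev["N"], prev["CA"], prev["C"], GEO["bond_C_N"], GEO["angle_CA_C_N"], psis[i - 1]
        )
        cai = place_atom(
            prev["CA"], prev["C"], ni, GEO["bond_N_CA"], GEO["angle_C_N_CA"], GEO["omega"]
        )
        ci = place_atom(prev["C"], ni, cai, GEO["bond_CA_C"], GEO["angle_N_CA_C"], phis[i])
        res.append({"N": ni, "CA": cai, "C": ci})
    for i, r in enumerate(res):
        if i + 1 < n:  # carbonyl O in the peptide plane, anti to CA(i+1)
            r["O"] = place_atom(
                res[i + 1]["CA"], res[i + 1]["N"], r["C"], GEO["bond_C_O"],
                GEO["angle_CA_C_O"], 0.0,
            )
        else:
            r["O"] = place_atom(
                r["N"], r["CA"], r["C"], GEO["bond_C_O"], GEO["angle_CA_C_O"],
                psis[i] + 180.0,
            )
        r["CB"] = place_atom(
            r["C"], r["N"], r["CA"], GEO["bond_CA_CB"], GEO["angle_N_CA_CB"],
            GEO["torsion_CB"],
        )
    return res


def _cage_coords(center: np.ndarray, radius: float = 6.0, n_points: int = 400) -> np.ndarray:
    """Two dense concentric shells of occluder points around a centre."""
    shells = []
    for rad, npt in ((radius, n_points), (radius + 1.5, n_points)):
        i = np.arange(npt)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        z = 1.0 - 2.0 * (i + 0.5) / npt
        r = np.sqrt(1.0 - z * z)
        theta = golden * i
        pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1) * rad
        shells.append(center + pts)
    return np.concatenate(shells)


def make_structure(
    spec: FixtureSpec,
    path: Optional[str | Path] = None,
    compute_sasa: bool = False,
) -> ProteinStructure:
    """Build a single-chain ideal-geometry structure from a spec.

    Accessibility: an ``accessibility_mask`` is applied as a direct
    synthetic annotation; ``buried_residues`` triggers a real SASA
    computation with dense occluder cages around the listed residues;
    ``compute_sasa`` forces a plain SASA computation. Otherwise all
    residues are annotated fully accessible. Writes a PDB file when
    ``path`` is given; identical specs give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    dihedrals = spec.dihedrals(rng)
    seq = spec.sequence or "".join(
        rng.choice(list(FIXTURE_AA)) for _ in range(spec.n_residues)
    )
    if len(seq) != spec.n_residues:
        raise ValueError("sequence length does not match n_residues")
    backbone = _build_backbone(dihedrals)
    residues = []
    cid = spec.chain_id
    for i, (aa, atoms) in enumerate(zip(seq, backbone), start=1):
        key = (cid, i, "")
        records = [
            AtomRecord(name=name, element=name[0], coord=coord, residue_key=key)
            for name, coord in atoms.items()
        ]
        residues.append(Residue(key=key, aa=aa, atoms=records))
    structure = ProteinStructure(
        id=f"fixture-{spec.geometry}-{spec.seed}", chains={cid: residues}
    )
    if spec.accessibility_mask is not None:
        mask = list(spec.accessibility_mask)
        if len(mask) != spec.n_residues:
            raise ValueError("accessibility mask length mismatch")
        for r, acc in zip(residues, mask):
            r.accessible = bool(acc)
            r.sasa_rel = 1.0 if acc else 0.0
            r.sasa_abs = r.sasa_rel * MAX_ASA.get(r.aa, 150.0)
    elif spec.buried_residues:
        occluders = np.concatenate(
            [
                _cage_coords(
                    np.mean([a.coord for a in residues[i - 1].atoms], axis=0)
                )
                for i in spec.buried_residues
            ]
        )
        compute_accessibility(structure, occluders=occluders)
    elif compute_sasa:
        compute_accessibility(structure)
    else:
        for r in residues:
            r.accessible, r.sasa_rel = True, 1.0
            r.sasa_abs = MAX_ASA.get(r.aa, 150.0)
    if path is not None:
        write_structure(structure, path)
    return structure


def make_complex(
    spec: FixtureSpec,
    path: Optional[str | Path] = None,
    ab_chain: str = "B",
    complex_key: str = "",
    guard: float = 4.2,
) -> AgAbComplex:
    """Build a two-chain complex with contacts planted at exact distances.

    The antigen chain follows the spec; one antibody probe residue is
    planted per ``(residue_number, distance)`` entry, outward along the
    local surface normal, and the construction is validated: each planted
    antigen residue's minimum distance to the antibody equals the planted
    distance within 0.01 A, and every unplanted residue stays farther than
    ``guard`` from all antibody atoms (raises if unrealizable).
    """
    antigen = make_structure(spec)
    ag_res = antigen.chains[spec.chain_id]
    ca = np.array([r.coord("CA") for r in ag_res])
    centroid = ca.mean(axis=0)
    axis = np.array([1.0, 0.0, 0.0])
    if len(ca) > 2:  # principal axis of the chain
        u, s, vt = np.linalg.svd(ca - centroid)
        axis = vt[0]
    ab_residues = []
    for j, (resnum, dist) in enumerate(sorted(spec.planted_contacts), start=1):
        target = ag_res[resnum - 1]
        anchor = target.coord("CB", fallback="CA")
        radial = anchor - (centroid + np.dot(anchor - centroid, axis) * axis)
        norm = np.linalg.norm(radial)
        direction = radial / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
        perp = np.cross(axis, direction)
        perp /= np.linalg.norm(perp)
        ca_pos = anchor + direction * dist
        key = (ab_chain, j, "")
        coords = {
            "CA": ca_pos,
            "N": ca_pos + direction * 1.2 + perp * 0.9,
            "C": ca_pos + direction * 1.2 - perp * 0.9,
            "O": ca_pos + direction * 2.4,
        }
        ab_residues.append(
            Residue(
                key=key,
                aa="G",
                atoms=[
                    AtomRecord(name=n, element=n[0], coord=c, residue_key=key)
                    for n, c in coords.items()
                ],
            )
        )
    chains = {spec.chain_id: ag_res}
    if ab_residues:
        chains[ab_chain] = ab_residues
    structure = ProteinStructure(
        id=f"complex-{spec.geometry}-{spec.seed}", chains=chains
    )
    _validate_contacts(structure, spec, ab_chain, guard)
    if path is not None:
        write_structure(structure, path)
    return AgAbComplex(
        structure=structure,
        ag_chains=(spec.chain_id,),
        ab_chains=(ab_chain,) if ab_residues else (ab_chain,),
        complex_key=complex_key or structure.id,
    )


def _validate_contacts(structure, spec, ab_chain, guard):
    planted = {resnum: dist for resnum, dist in spec.planted_contacts}
    ab_coords = structure.coords([ab_chain])
    if not len(ab_coords):
        return
    for r in structure.chains[spec.chain_id]:
        coords = np.array([a.coord for a in r.atoms])
        dmin = float(
            np.min(np.linalg.norm(coords[:, None, :] - ab_coords[None, :, :], axis=-1))
        )
        want = planted.get(r.key[1])
        if want is not None:
            if abs(dmin - want) > 0.01:
                raise ValueError(
                    f"unrealizable contact: residue {r.key} min distance "
                    f"{dmin:.3f} != planted {want:.3f}"
                )
        elif dmin <= guard:
            raise ValueError(
                f"unrealizable spec: unplanted residue {r.key} within "
                f"{dmin:.2f} A of the antibody probe"
            )


def random_complex_spec(
    seed: int,
    n_residues: int = 90,
    n_epitope_segments: tuple[int, int] = (3, 8),
    segment_length: tuple[int, int] = (1, 4),
    contact_distance: tuple[float, float] = (3.2, 3.95),
) -> FixtureSpec:
    """A randomized complex spec with a discontinuous planted epitope.

    Draws a number of epitope segments and per-segment lengths within the
    given ranges and places them along an extended antigen chain with at
    least two residues between consecutive segments (mirroring the
    segment-rich composition of crystallographic discontinuous epitopes).
    """
    rng = np.random.default_rng(seed)
    n_seg = int(rng.integers(n_epitope_segments[0], n_epitope_segments[1] + 1))
    lengths = rng.integers(segment_length[0], segment_length[1] + 1, size=n_seg)
    gaps = rng.integers(2, 6, size=n_seg)
    contacts = []
    pos = int(rng.integers(3, 6))
    for length, gap in zip(lengths, gaps):
        for k in range(int(length)):
            if pos + k <= n_residues - 3:
                d = float(rng.uniform(*contact_distance))
                contacts.append((pos + k, round(d, 2)))
        pos += int(length) + int(gap)
    return FixtureSpec(
        n_residues=n_residues,
        geometry="strand",
        planted_contacts=tuple(contacts),
        seed=seed,
    )
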