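"""Protein-blocks (PB) structural alphabet machinery.

The PB alphabet approximates local backbone conformation with 16 prototype
fragments of five residues, each described by 8 reference dihedrals
(psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1),
phi(i+2)). A residue is encoded by the prototype with minimal RMSDA (root
mean square deviation over the 8 angle differences, with wrap-around) to
its sliding window. Consecutive windows overlap by four residues, so only
some PB-to-PB transitions are conformationally possible; the bundled
transition table and the per-position amino-acid preference table drive the
structural-alphabet linker choices of the design methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ProteinStructure, ResidueKey
from .geometry import dihedral, rmsda

__all__ = [
    "PBLibrary",
    "load_default_library",
    "encode_pb",
    "encode_chain",
    "allowed_transition",
    "best_linker_pbs",
    "pb_preferred_aa",
]

PB_LABELS = "abcdefghijklmnop"
NULL_PB = "Z"  # label for residues whose window is incomplete


def _data_path(name: str):
    return resources.files("epimimic.data") / name


@dataclass
class PBLibrary:
    """Bundled PB data: prototype dihedrals, transition weights, propensities.

    ``transition_threshold`` is the minimal weight for a transition to count
    as allowed (default: any strictly positive weight).
    """

    prototypes: dict[str, np.ndarray]
    transitions: pd.DataFrame  # 16x16, rows = preceding PB
    propensities: pd.DataFrame  # index (pb, position), columns aa
    transition_threshold: float = 0.0

    def __post_init__(self):
        if sorted(self.prototypes) != list(PB_LABELS):
            raise ValueError("prototype library must hold exactly PBs a..p")
        for label, angles in self.prototypes.items():
            angles = np.asarray(angles, dtype=float)
            if angles.shape != (8,):
                raise ValueError(f"PB {label}: expected 8 dihedrals")
            if np.any(angles <= -180.0) or np.any(angles > 180.0):
                raise ValueError(f"PB {label}: angles must lie in (-180, 180]")
            self.prototypes[label] = angles

    def weight(self, pb1: str, pb2: str) -> float:
        self._check(pb1), self._check(pb2)
        return float(self.transitions.loc[pb1, pb2])

    @staticmethod
    def _check(label: str) -> None:
        if label not in PB_LABELS:
            raise KeyError(f"unknown PB label {label!r}")


_default_library: Optional[PBLibrary] = None


def load_default_library() -> PBLibrary:
    """Load (and cache) the PB tables bundled with the package."""
    global _default_library
    if _default_library is None:
        proto = pd.read_csv(_data_path("pb_prototypes.tsv"), sep="\t", comment="#")
        prototypes = {
            row["pb"]: row.iloc[1:].to_numpy(dtype=float) for _, row in proto.iterrows()
        }
        trans = pd.read_csv(
            _data_path("pb_transitions_synthetic.tsv"), sep="\t", comment="#", index_col=0
        )
        prop = pd.read_csv(
            _data_path("pb_propensities_synthetic.tsv"), sep="\t", comment="#"
        ).set_index(["pb", "position"])
        _default_library = PBLibrary(prototypes, trans, prop)
    return _default_library


def _backbone_angles(
    structure: ProteinStructure, keys: Sequence[ResidueKey]
) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) arrays over a run of residues; NaN where undefined."""
    n = len(keys)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    res = [structure[k] for k in keys]
    bb = [(r.atom("N"), r.atom("CA"), r.atom("C")) for r in res]
    for i in range(n):
        n_i, ca_i, c_i = bb[i]
        if i > 0:
            c_prev = bb[i - 1][2]
            if all(a is not None for a in (c_prev, n_i, ca_i, c_i)):
                phi[i] = dihedral(c_prev.coord, n_i.coord, ca_i.coord, c_i.coord)
        if i + 1 < n:
            n_next = bb[i + 1][0]
            if all(a is not None for a in (n_i, ca_i, c_i, n_next)):
                psi[i] = dihedral(n_i.coord, ca_i.coord, c_i.coord, n_next.coord)
    return phi, psi


def window_angles(phi: np.ndarray, psi: np.ndarray, i: int) -> np.ndarray:
    """The 8-dihedral window of residue ``i`` (NaN-padded at run edges)."""
    n = len(phi)

    def get(arr, j):
        return arr[j] if 0 <= j < n else np.nan

    return np.array(
        [
            get(psi, i - 2), get(phi, i - 1), get(psi, i - 1),
            get(phi, i), get(psi, i),
            get(phi, i + 1), get(psi, i + 1), get(phi, i + 2),
        ]
    )


def assign_pb(window: np.ndarray, library: Optional[PBLibrary] = None) -> str:
    """PB label with minimal RMSDA to an 8-dihedral window (NaN-tolerant)."""
    library = library or load_default_library()
    best, best_d = NULL_PB, float("inf")
    for label in PB_LABELS:
        d = rmsda(window, library.prototypes[label])
        if d < best_d:
            best, best_d = label, d
    return best


def encode_pb(
    structure: ProteinStructure,
    keys: Sequence[ResidueKey],
    library: Optional[PBLibrary] = None,
) -> str:
    """Encode an ordered run of residues into a PB string.

    One letter per residue; the two residues at each end of the run, whose
    5-residue window is incomplete, receive the null label ``Z``. Runs
    shorter than 5 residues cannot form a window and yield an empty string.
    """
    if len(keys) < 5:
        warnings.warn("fewer than 5 residues: PB encoding empty")
        return ""
    library = library or load_default_library()
    phi, psi = _backbone_angles(structure, keys)
    out = []
    for i in range(len(keys)):
        if i < 2 or i >= len(keys) - 2:
            out.append(NULL_PB)
            continue
        window = window_angles(phi, psi, i)
        if np.isnan(window).any():
            out.append(NULL_PB)
        else:
            out.append(assign_pb(window, library))
    return "".join(out)


def encode_chain(
    structure: ProteinStructure, chain: str, library: Optional[PBLibrary] = None
) -> dict[ResidueKey, str]:
    """PB label per residue of a whole chain (null labels at termini)."""
    keys = [r.key for r in structure.chains[chain]]
    if len(keys) < 5:
        return {k: NULL_PB for k in keys}
    encoding = encode_pb(structure, keys, library)
    return dict(zip(keys, encoding))


def allowed_transition(
    pb1: str, pb2: str, library: Optional[PBLibrary] = None
) -> bool:
    """True iff the pb1 -> pb2 transition weight exceeds the threshold."""
    library = library or load_default_library()
    return library.weight(pb1, pb2) > library.transition_threshold


def best_linker_pbs(
    pb_end: str,
    pb_start: str,
    max_insert: int = 2,
    library: Optional[PBLibrary] = None,
) -> Optional[list[str]]:
    """PB insertions bridging two segment ends, or None if impossible.

    Returns ``[]`` when the direct transition is already allowed; otherwise
    the single PB ``x`` maximising ``min(w(end->x), w(x->start))`` over the
    candidates making both hops allowed; otherwise the best pair ``(x, y)``
    by the same min-weight criterion over all three hops; otherwise None
    ("peptide not possible"). Ties break alphabetically.
    """
    library = library or load_default_library()
    if allowed_transition(pb_end, pb_start, library):
        return []
    if max_insert >= 1:
        best, best_w = None, -1.0
        for x in PB_LABELS:
            w1, w2 = library.weight(pb_end, x), library.weight(x, pb_start)
            if min(w1, w2) > library.transition_threshold and min(w1, w2) > best_w:
                best, best_w = [x], min(w1, w2)
        if best is not None:
            return best
    if max_insert >= 2:
        best, best_w = None, -1.0
        for x in PB_LABELS:
            for y in PB_LABELS:
                ws = (
                    library.weight(pb_end, x),
                    library.weight(x, y),
                    library.weight(y, pb_start),
                )
                if min(ws) > library.transition_threshold and min(ws) > best_w:
                    best, best_w = [x, y], min(ws)
        if best is not None:
            return best
    return None


def pb_preferred_aa(
    pb: str, position: int = 3, library: Optional[PBLibrary] = None
) -> str:
    """Most favourable amino acid at a PB window position (1..5).

    Arg-max over the propensity table; ties break alphabetically.
    """
    library = library or load_default_library()
    PBLibrary._check(pb)
    if position not in (1, 2, 3, 4, 5):
        raise ValueError("position must be 1..5")
    row = library.propensities.loc[(pb, position)]
    best = row.max()
    return sorted(aa for aa in row.index if row[aa] == best)[0]
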