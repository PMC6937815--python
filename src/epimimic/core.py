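"""Domain types shared across the package.

The vocabulary follows the peptide-mimicry literature: a protein antigen is
decomposed into *segments* (maximal runs of chain-contiguous, surface-
accessible residues); segments are grouped into *clusters* (spatial
agglomeration over the whole antigen) or *patches* (fixed- or varying-radius
neighbourhoods of a reference anchor); design methods assemble segments or
single accessible residues into linear peptides intended to mimic a
discontinuous epitope.

Residues are identified throughout by a ``ResidueKey`` triple
``(chain_id, residue_number, insertion_code)`` exactly as written in the
source PDB file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

import numpy as np

ResidueKey = tuple[str, int, str]

#: One-letter codes of the 20 canonical amino acids.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Hydrophobic set used by the segment score (kept configurable there).
HYDROPHOBIC_AA = frozenset("ACFILMVW")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common modified residues mapped to their parent amino acid.
MODIFIED_PARENT = {
    "MSE": "M", "SEC": "C", "CSO": "C", "CME": "C", "OCS": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y", "MLY": "K", "HYP": "P",
    "PCA": "E", "KCX": "K", "LLP": "K", "CSD": "C", "M3L": "K",
}

#: Theoretical maximum accessible surface area per residue (A^2) in an
#: extended Gly-X-Gly context (Tien et al. 2013, theoretical values).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Van der Waals radii by element used for surface computations (A).
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


@dataclass(frozen=True)
class AtomRecord:
    """A heavy atom with its position and owning residue."""

    name: str
    element: str
    coord: np.ndarray
    residue_key: ResidueKey

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """One amino-acid residue with accessibility annotations.

    ``sasa_rel`` is the absolute solvent-accessible surface area divided by
    the residue's theoretical maximum in an extended Gly-X-Gly context,
    clipped to [0, 1]. ``accessible`` is ``sasa_rel >= threshold`` for the
    threshold used at annotation time.
    """

    key: ResidueKey
    aa: str
    atoms: list[AtomRecord] = field(default_factory=list)
    sasa_abs: Optional[float] = None
    sasa_rel: Optional[float] = None
    accessible: Optional[bool] = None
    standard: bool = True

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str, fallback: str = "CA") -> np.ndarray:
        """Coordinate of atom ``name``, falling back to ``fallback`` then to
        the first atom (robust to incomplete residues)."""
        a = self.atom(name) or self.atom(fallback)
        if a is None:
            a = self.atoms[0]
        return a.coord


class ProteinStructure:
    """A protein structure as ordered residues per chain.

    Chains preserve file order; within a chain residues are ordered by
    (residue number, insertion code). Residue keys are unique.
    """

    def __init__(self, id: str, chains: dict[str, list[Residue]], source: str = ""):
        self.id = id
        self.chains = chains
        self.source = source
        self._index: dict[ResidueKey, Residue] = {}
        for residues in chains.values():
            for r in residues:
                if r.key in self._index:
                    raise ValueError(f"duplicate residue key {r.key}")
                self._index[r.key] = r

    def __getitem__(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index

    def residues(self, chains: Optional[Sequence[str]] = None) -> Iterator[Residue]:
        for cid, residues in self.chains.items():
            if chains is None or cid in chains:
                yield from residues

    @property
    def n_residues(self) -> int:
        return len(self._index)

    def atoms(self, chains: Optional[Sequence[str]] = None) -> list[AtomRecord]:
        return [a for r in self.residues(chains) for a in r.atoms]

    def coords(self, chains: Optional[Sequence[str]] = None) -> np.ndarray:
        atoms = self.atoms(chains)
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coord for a in atoms])

    def subset(self, chains: Sequence[str]) -> "ProteinStructure":
        missing = [c for c in chains if c not in self.chains]
        if missing:
            raise KeyError(f"chain(s) {missing} absent from structure {self.id}")
        return ProteinStructure(
            self.id, {c: self.chains[c] for c in chains}, source=self.source
        )

    def accessible_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.accessible]

    def sequence(self, chain: str) -> str:
        return "".join(r.aa for r in self.chains[chain])


@dataclass
class AgAbComplex:
    """An antigen-antibody complex: one structure, two disjoint chain sets."""

    structure: ProteinStructure
    ag_chains: tuple[str, ...]
    ab_chains: tuple[str, ...]
    complex_key: str = ""

    def __post_init__(self):
        self.ag_chains = tuple(self.ag_chains)
        self.ab_chains = tuple(self.ab_chains)
        if not self.ag_chains or not self.ab_chains:
            raise ValueError("both antigen and antibody chain sets must be non-empty")
        if set(self.ag_chains) & set(self.ab_chains):
            raise ValueError("antigen and antibody chains overlap")

    @property
    def antigen(self) -> ProteinStructure:
        return self.structure.subset(self.ag_chains)


@dataclass
class Epitope:
    """Antigen residues in atomic contact with the antibody.

    ``sequence_segments`` are the maximal runs of chain-contiguous epitope
    residues; they partition ``residues``.
    """

    residues: frozenset[ResidueKey]
    sequence_segments: list[list[ResidueKey]]

    @property
    def size(self) -> int:
        return len(self.residues)

    @property
    def n_segments(self) -> int:
        return len(self.sequence_segments)

    def letters(self, structure: ProteinStructure) -> list[str]:
        return [structure[k].aa for k in sorted(self.residues)]


@dataclass
class Segment:
    """A maximal run of contiguous surface-accessible residues.

    ``cog`` is the unweighted mean of all member heavy-atom coordinates;
    the terminus coordinates are the CA positions of the first (N) and last
    (C) residue.
    """

    id: int
    residues: list[ResidueKey]
    sequence: str
    cog: np.ndarray
    n_term_coord: np.ndarray
    c_term_coord: np.ndarray
    chain: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SurfaceArea:
    """A cluster of segments or a patch around a reference anchor."""

    kind: str  # cluster | patch10 | patch15 | varying_patch
    reference: Union[int, ResidueKey, None]
    members: list  # segment ids (int) or residue keys
    radius: Optional[float]
    n_aa: int

    def __post_init__(self):
        if not self.members:
            raise ValueError("surface area must have at least one member")


LINKER_ORIGINS = ("ALA", "SA", "SAS", "RND")


@dataclass(frozen=True)
class LinkerPosition:
    """Provenance marker for an inserted (non-antigen) peptide position."""

    origin: str  # one of LINKER_ORIGINS

    def __post_init__(self):
        if self.origin not in LINKER_ORIGINS:
            raise ValueError(f"unknown linker origin {self.origin!r}")


PositionProvenance = Union[ResidueKey, LinkerPosition]


@dataclass
class DesignedPeptide:
    """A designed linear peptide with full per-position provenance.

    ``positions[i]`` is either the antigen residue key the i-th letter came
    from, or a :class:`LinkerPosition` for inserted linker residues.
    ``segments_used`` records ``(segment_id, orientation)`` with orientation
    ``"nat"`` or ``"rev"``, in peptide (N to C) order.
    """

    sequence: str
    positions: list[PositionProvenance]
    segments_used: list[tuple[int, str]]
    method: str
    requested_length: Optional[int]
    reference: Union[int, ResidueKey, str, None] = None
    path_distance: float = 0.0
    score: Optional[float] = None
    status: str = "ok"  # ok | short | impossible

    def __post_init__(self):
        if len(self.sequence) != len(self.positions):
            raise ValueError("sequence and positions lengths differ")

    @property
    def final_length(self) -> int:
        return len(self.sequence)

    def stripped(self) -> "DesignedPeptide":
        """Copy with all linker-marked positions removed (prime parent)."""
        keep = [
            (c, p)
            for c, p in zip(self.sequence, self.positions)
            if not isinstance(p, LinkerPosition)
        ]
        return DesignedPeptide(
            sequence="".join(c for c, _ in keep),
            positions=[p for _, p in keep],
            segments_used=list(self.segments_used),
            method=self.method,
            requested_length=self.requested_length,
            reference=self.reference,
            path_distance=self.path_distance,
            status=self.status,
        )


# --- method registry -------------------------------------------------------

PRIME_METHODS = ("NN", "uNN", "FN", "ONN", "OFN", "OPP")
ALA_METHODS = ("NNala", "uNNala", "ONNala", "FNala", "OFNala", "OPPala")
SA_METHODS = ("NNsa", "ONNsa", "FNsa", "OFNsa", "OPPsa")
SAS_METHODS = ("NNsas", "ONNsas", "FNsas", "OFNsas", "OPPsas")
LINKER_METHODS = ALA_METHODS + SA_METHODS + SAS_METHODS
SEGMENT_GRAPH_METHODS = (
    "SHPnat", "SHPrev",
    "TSPnat1", "TSPnat2", "TSPnat3", "TSPnat4",
    "TSPrev1", "TSPrev2", "TSPrev3", "TSPrev4",
)
AA_GRAPH_METHODS = ("SHPaa", "TSPaa")
GRAPH_METHODS = SEGMENT_GRAPH_METHODS + AA_GRAPH_METHODS

#: All 34 discontinuous-peptide design methods.
ALL_METHODS = PRIME_METHODS + LINKER_METHODS + GRAPH_METHODS


def method_family(method: str) -> str:
    """Family of a method id: ``prime``, ``linker`` or ``graph``."""
    if method in PRIME_METHODS:
        return "prime"
    if method in LINKER_METHODS:
        return "linker"
    if method in GRAPH_METHODS:
        return "graph"
    raise ValueError(f"unknown method {method!r}")


def linker_parts(method: str) -> tuple[str, str]:
    """Split a linker method id into (prime base, linker kind)."""
    for suffix, kind in (("ala", "ALA"), ("sas", "SAS"), ("sa", "SA")):
        if method.endswith(suffix):
            return method[: -len(suffix)], kind
    raise ValueError(f"{method!r} is not a linker method")


@dataclass
class EvaluationResult:
    """TP/FP/FN counts and Se/PPV for one peptide against one epitope."""

    tp: int
    fp: int
    fn: int
    mode: str  # composition | position_aware
    peptide_id: str = ""
    epitope_id: str = ""
    valid: bool = True

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else float("nan")


@dataclass
class MethodSummary:
    """Aggregate performance of one design method over a benchmark."""

    method: str
    n_peptides: int
    mean_se: float
    mean_ppv: float
    prop_above: float
    n_antigens_hit: int
    threshold: float
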