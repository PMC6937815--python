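"""Structure input, surface accessibility and crystallographic epitopes.

PDB files are parsed with gemmi; per-residue solvent accessibility is the
Shrake-Rupley accessible surface area (biotite implementation) normalised
by the residue's theoretical maximum in an extended Gly-X-Gly context. An
epitope is the set of antigen residues having at least one heavy atom within
a distance cutoff (default 4.0 A, inclusive) of any antibody atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    MAX_ASA,
    MODIFIED_PARENT,
    THREE_TO_ONE,
    VDW_RADII,
    AgAbComplex,
    AtomRecord,
    Epitope,
    ProteinStructure,
    Residue,
    ResidueKey,
)

__all__ = [
    "read_structure",
    "write_structure",
    "compute_accessibility",
    "assign_turns",
    "extract_epitope",
    "epitope_statistics",
    "ComplexEntry",
    "deduplicate_complexes",
    "read_manifest",
    "write_epitope_report",
    "write_epitope_fasta",
]

DEFAULT_CONTACT_CUTOFF = 4.0
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_REL_THRESHOLD = 0.05


def read_structure(
    path: str | Path,
    chains: Optional[Sequence[str] | str] = None,
    include_nonstandard: bool = False,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Hetero-compounds and waters are excluded; known modified residues
    (MSE, SEP, ...) are mapped to their parent amino acid; unknown residue
    types are dropped with a warning unless ``include_nonstandard``. Only
    the first model is used and the highest-occupancy alternate conformer
    of each atom is kept.

    Parameters
    ----------
    chains:
        Optional chain selection, e.g. ``"A"`` or ``["A", "B"]``. All
        requested chains must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(chains, str):
        chains = list(chains)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise ValueError(f"{path}: no model in file")
    model = st[0]
    out_chains: dict[str, list[Residue]] = {}
    for chain in model:
        cid = chain.name
        if chains is not None and cid not in chains:
            continue
        residues: list[Residue] = []
        for res in chain:
            name = res.name.strip().upper()
            if name in THREE_TO_ONE:
                aa, standard = THREE_TO_ONE[name], True
            elif name in MODIFIED_PARENT:
                aa, standard = MODIFIED_PARENT[name], True
            elif include_nonstandard:
                aa, standard = "X", False
            else:
                if res.het_flag != "H":
                    warnings.warn(f"{path.name}: skipping unknown residue {name}")
                continue
            key: ResidueKey = (cid, res.seqid.num, res.seqid.icode.strip())
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    residue_key=key,
                )
                for a in res
                if not a.is_hydrogen()
            ]
            if atoms:
                residues.append(Residue(key=key, aa=aa, atoms=atoms, standard=standard))
        if residues:
            out_chains[cid] = residues
    if chains is not None:
        missing = [c for c in chains if c not in out_chains]
        if missing:
            raise KeyError(f"{path}: requested chain(s) {missing} absent")
    if not out_chains:
        raise ValueError(f"{path}: no protein chain found")
    for residues in out_chains.values():
        residues.sort(key=lambda r: (r.key[1], r.key[2]))
    return ProteinStructure(id=path.stem, chains=out_chains, source=str(path))


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure to a PDB file (one model, ATOM records)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = one_to_three.get(r.aa, "UNK")
            res.seqid = gemmi.SeqId(r.key[1], r.key[2] or " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coord)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def compute_accessibility(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    point_number: int = 1000,
    occluders: Optional[np.ndarray] = None,
) -> ProteinStructure:
    """Annotate every residue with absolute/relative SASA and accessibility.

    Shrake-Rupley with element-based van der Waals radii; relative SASA is
    clipped to [0, 1] after division by the Gly-X-Gly theoretical maximum.
    ``occluders`` are optional extra coordinates (carbon radius) that shade
    the protein without receiving any area themselves (used by synthetic
    burial cages). Annotation is in place; the structure is returned.
    """
    import biotite.structure as struc

    records = [(r, a) for r in structure.residues() for a in r.atoms]
    for r in structure.residues():
        if not r.atoms:
            warnings.warn(f"residue {r.key} has no atoms; flagged inaccessible")
            r.sasa_abs, r.sasa_rel, r.accessible = 0.0, 0.0, False
    n_extra = 0 if occluders is None else len(occluders)
    atoms = struc.AtomArray(len(records) + n_extra)
    radii = np.empty(len(records) + n_extra)
    for i, (r, a) in enumerate(records):
        atoms.coord[i] = a.coord
        atoms.chain_id[i] = r.key[0][:4]
        atoms.res_id[i] = i  # unique ids; grouping is done on our side
        atoms.atom_name[i] = a.name[:6]
        atoms.res_name[i] = "XXX"
        atoms.element[i] = a.element
        radii[i] = VDW_RADII.get(a.element.upper(), 1.70)
    if n_extra:
        atoms.coord[len(records):] = occluders
        atoms.chain_id[len(records):] = "Z"
        atoms.res_id[len(records):] = np.arange(len(records), len(records) + n_extra)
        atoms.atom_name[len(records):] = "C"
        atoms.res_name[len(records):] = "CAG"
        atoms.element[len(records):] = "C"
        radii[len(records):] = VDW_RADII["C"]
    mask = np.zeros(len(atoms), dtype=bool)
    mask[: len(records)] = True
    sasa = struc.sasa(
        atoms,
        probe_radius=probe_radius,
        atom_filter=mask,
        point_number=point_number,
        vdw_radii=radii,
    )
    per_res: dict[ResidueKey, float] = {}
    for i, (r, _) in enumerate(records):
        per_res[r.key] = per_res.get(r.key, 0.0) + float(sasa[i])
    for r in structure.residues():
        if not r.atoms:
            continue
        r.sasa_abs = per_res.get(r.key, 0.0)
        ref = MAX_ASA.get(r.aa, np.mean(list(MAX_ASA.values())))
        r.sasa_rel = float(np.clip(r.sasa_abs / ref, 0.0, 1.0))
        r.accessible = r.sasa_rel >= rel_threshold
    return structure


def assign_turns(structure: ProteinStructure, energy_cutoff: float = -0.5) -> set[ResidueKey]:
    """Residues involved in hydrogen-bonded turns (3-, 4- or 5-turns).

    Backbone H-bonds are detected with the Kabsch-Sander electrostatic
    model (amide H inferred from the preceding carbonyl); a CO(i)..HN(i+n)
    bond for n in {3, 4, 5} marks residues i..i+n as turn residues.
    Residues lacking full backbones are skipped.
    """
    turns: set[ResidueKey] = set()
    q = 0.084 * 332.0
    for cid, residues in structure.chains.items():
        bb = []
        for r in residues:
            n, ca, c, o = (r.atom(x) for x in ("N", "CA", "C", "O"))
            bb.append((r, n, ca, c, o))
        # infer amide H: 1.0 A from N, opposite the previous carbonyl O->C
        hpos: list[Optional[np.ndarray]] = [None] * len(bb)
        for i in range(1, len(bb)):
            n_i = bb[i][1]
            c_prev, o_prev = bb[i - 1][3], bb[i - 1][4]
            if n_i is None or c_prev is None or o_prev is None:
                continue
            d = c_prev.coord - o_prev.coord
            norm = np.linalg.norm(d)
            if norm > 1e-6:
                hpos[i] = n_i.coord + d / norm
        for i in range(len(bb)):
            c_i, o_i = bb[i][3], bb[i][4]
            if c_i is None or o_i is None:
                continue
            for n_off in (3, 4, 5):
                j = i + n_off
                if j >= len(bb):
                    continue
                n_j, h_j = bb[j][1], hpos[j]
                if n_j is None or h_j is None:
                    continue
                r_on = np.linalg.norm(o_i.coord - n_j.coord)
                r_ch = np.linalg.norm(c_i.coord - h_j)
                r_oh = np.linalg.norm(o_i.coord - h_j)
                r_cn = np.linalg.norm(c_i.coord - n_j.coord)
                if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                    continue
                energy = q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
                if energy < energy_cutoff:
                    turns.update(bb[k][0].key for k in range(i, j + 1))
    return turns


def extract_epitope(complex: AgAbComplex, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> Epitope:
    """Antigen residues with >=1 atom within ``cutoff`` (inclusive) of the antibody.

    Also reports the maximal chain-contiguous runs of epitope residues
    (contiguity = consecutive position in the chain's residue ordering).
    An empty contact set yields a valid empty epitope.
    """
    ab_coords = complex.structure.coords(complex.ab_chains)
    hits: set[ResidueKey] = set()
    if len(ab_coords):
        tree = cKDTree(ab_coords)
        for r in complex.structure.residues(complex.ag_chains):
            for a in r.atoms:
                d, _ = tree.query(a.coord)
                if d <= cutoff + 1e-9:
                    hits.add(r.key)
                    break
    segments: list[list[ResidueKey]] = []
    for cid in complex.ag_chains:
        run: list[ResidueKey] = []
        for r in complex.structure.chains.get(cid, []):
            if r.key in hits:
                run.append(r.key)
            elif run:
                segments.append(run)
                run = []
        if run:
            segments.append(run)
    return Epitope(residues=frozenset(hits), sequence_segments=segments)


def epitope_statistics(epitopes: Iterable[Epitope]) -> dict[str, float]:
    """Mean/median epitope size and segment composition over a dataset.

    ``mean_residues_per_segment`` pools all segments of all epitopes.
    """
    epitopes = list(epitopes)
    if not epitopes:
        raise ValueError("no epitopes given")
    sizes = np.array([e.size for e in epitopes], dtype=float)
    seg_lengths = [len(s) for e in epitopes for s in e.sequence_segments]
    return {
        "n_epitopes": float(len(epitopes)),
        "mean_size": float(sizes.mean()),
        "median_size": float(np.median(sizes)),
        "mean_segments_per_epitope": float(
            np.mean([e.n_segments for e in epitopes])
        ),
        "mean_residues_per_segment": float(np.mean(seg_lengths)) if seg_lengths else 0.0,
    }


@dataclass(frozen=True)
class ComplexEntry:
    """One row of a benchmark manifest of antigen-antibody complexes."""

    structure_id: str
    path: str
    ag_chains: tuple[str, ...]
    ab_chains: tuple[str, ...]
    complex_key: str
    resolution: float = float("nan")


def deduplicate_complexes(
    manifest: Sequence[ComplexEntry],
) -> tuple[list[ComplexEntry], list[ComplexEntry]]:
    """Keep exactly one crystal structure per antigen-antibody pair.

    Retention is deterministic: the entry with the best (lowest) stated
    resolution wins; missing resolutions rank last; ties break on the
    lexicographically smallest structure id. Returns (kept, rejected).
    """
    def rank(e: ComplexEntry):
        res = e.resolution if np.isfinite(e.resolution) else float("inf")
        return (res, e.structure_id)

    best: dict[str, ComplexEntry] = {}
    for entry in manifest:
        cur = best.get(entry.complex_key)
        if cur is None or rank(entry) < rank(cur):
            best[entry.complex_key] = entry
    kept_set = {id(v) for v in best.values()}
    kept = [e for e in manifest if id(e) in kept_set]
    rejected = [e for e in manifest if id(e) not in kept_set]
    return kept, rejected


def read_manifest(path: str | Path) -> list[ComplexEntry]:
    """Read a TSV manifest: structure_id, path, ag_chains, ab_chains,
    complex_key, resolution (chains as comma- or bare-letter strings)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")

    def split(s: str) -> tuple[str, ...]:
        s = s.replace(",", "")
        return tuple(s)

    entries = []
    for _, row in df.iterrows():
        entries.append(
            ComplexEntry(
                structure_id=row["structure_id"],
                path=row.get("path", ""),
                ag_chains=split(row["ag_chains"]),
                ab_chains=split(row["ab_chains"]),
                complex_key=row["complex_key"],
                resolution=float(row["resolution"]) if row.get("resolution") else float("nan"),
            )
        )
    return entries


def write_epitope_report(
    epitope: Epitope, structure: ProteinStructure, path: str | Path
) -> None:
    """Write an epitope as TSV: chain, number, icode, aa, segment index."""
    rows = []
    for si, seg in enumerate(epitope.sequence_segments, start=1):
        for key in seg:
            rows.append(
                {
                    "chain": key[0],
                    "number": key[1],
                    "icode": key[2],
                    "aa": structure[key].aa,
                    "segment": si,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_epitope_fasta(
    epitope: Epitope, structure: ProteinStructure, path: str | Path, name: str = "epitope"
) -> None:
    """Write epitope segment sequences as FASTA (one record per segment)."""
    with open(path, "w") as fh:
        for si, seg in enumerate(epitope.sequence_segments, start=1):
            seq = "".join(structure[k].aa for k in seg)
            fh.write(f">{name}|segment{si}|n={len(seg)}\n{seq}\n")
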