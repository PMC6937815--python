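"""The 34 discontinuous-peptide design methods.

Three families assemble surface elements into linear peptides:

* prime methods (NN, uNN, FN and their order-optimised versions ONN, OFN,
  OPP) greedily collect segments around a reference segment and concatenate
  them; the optimised versions reorder the collected set to minimise the
  total inter-segment centre-of-gravity distance;
* linker methods (ALA / SA / SAS variants of the prime methods) insert
  alanines or structural-alphabet-chosen residues between consecutive
  segments;
* graph-based methods (SHP*, TSP*) model segments or single accessible
  residues as nodes of a distance-weighted graph over a cluster or patch
  and cut the peptide out of a shortest path (SHP) or an open
  travelling-salesman path (TSP).

All tie-breaks are lexicographic on element ids, making every method
deterministic without seeds.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np

from .core import (
    AA_GRAPH_METHODS,
    ALL_METHODS,
    HYDROPHOBIC_AA,
    DesignedPeptide,
    LinkerPosition,
    ProteinStructure,
    ResidueKey,
    Segment,
    SurfaceArea,
    linker_parts,
    method_family,
)
from .structural_alphabet import (
    NULL_PB,
    PBLibrary,
    assign_pb,
    best_linker_pbs,
    encode_chain,
    load_default_library,
    pb_preferred_aa,
)
from .surface_model import SurfaceModel

__all__ = [
    "shortest_open_path",
    "design_nn",
    "design_unn",
    "design_fn",
    "design_optimized",
    "add_linkers",
    "build_design_graph",
    "design_shp",
    "design_tsp",
    "segment_score",
    "score_peptide",
    "design",
    "generate_peptide_bank",
    "write_bank_fasta",
    "write_bank_tsv",
]

#: Virtual span of one peptide bond (A), used by the alanine-linker rule.
PEPTIDE_BOND_SPAN = 3.8

#: Largest element count solved exactly (Held-Karp); beyond this a
#: nearest-neighbour construction plus local improvement is used.
EXACT_TSP_LIMIT = 12

DEFAULT_ACCESS_SCALE = 10.0


# --------------------------------------------------------------------------
# path optimisation
# --------------------------------------------------------------------------

def shortest_open_path(
    weights: np.ndarray, directed: bool = False
) -> tuple[list[int], float]:
    """Minimum-total-distance open path visiting every node exactly once.

    Exact dynamic programming (Held-Karp) up to :data:`EXACT_TSP_LIMIT`
    nodes; deterministic nearest-neighbour + improvement heuristic beyond.
    For undirected instances the returned order is canonicalised against
    its reversal (lexicographically smaller end first). Returns
    ``(order, total_distance)`` with node indices into ``weights``.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if n == 1:
        return [0], 0.0
    if n <= EXACT_TSP_LIMIT:
        order, total = _held_karp(w)
    else:
        order, total = _heuristic_path(w)
    if not directed:
        rev = order[::-1]
        if rev < order:
            order = rev
    return order, total


def _held_karp(w: np.ndarray) -> tuple[list[int], float]:
    n = w.shape[0]
    full = (1 << n) - 1
    # dp[(mask, j)] = (cost, path tuple) of the best path over mask ending at j
    dp: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {
        (1 << i, i): (0.0, (i,)) for i in range(n)
    }
    for mask in range(1, full + 1):
        for j in range(n):
            if not mask & (1 << j):
                continue
            cur = dp.get((mask, j))
            if cur is None:
                continue
            cost, path = cur
            for k in range(n):
                if mask & (1 << k):
                    continue
                cand = (cost + w[j, k], path + (k,))
                key = (mask | (1 << k), k)
                if key not in dp or cand < dp[key]:
                    dp[key] = cand
    best = min(dp[(full, j)] for j in range(n) if (full, j) in dp)
    return list(best[1]), best[0]


def _heuristic_path(w: np.ndarray) -> tuple[list[int], float]:
    n = w.shape[0]

    def total(order):
        o = np.asarray(order)
        return float(w[o[:-1], o[1:]].sum())

    best_order, best_cost = None, np.inf
    for start in range(n):  # nearest-neighbour from every start
        left = set(range(n)) - {start}
        order = [start]
        while left:
            j = order[-1]
            k = min(sorted(left), key=lambda x: w[j, x])
            order.append(k)
            left.discard(k)
        c = total(order)
        if c < best_cost:
            best_order, best_cost = order, c
    improved = True
    while improved:  # 2-opt style segment reversals, fixed scan order
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = best_order[:i] + best_order[i : j + 1][::-1] + best_order[j + 1 :]
                c = total(cand)
                if c < best_cost - 1e-12:
                    best_order, best_cost = cand, c
                    improved = True
    return best_order, best_cost


# --------------------------------------------------------------------------
# prime methods
# --------------------------------------------------------------------------

def _assemble(
    parts: Sequence[tuple[Segment, str]],
    method: str,
    requested_length: Optional[int],
    reference,
    path_distance: float = 0.0,
    status: str = "ok",
) -> DesignedPeptide:
    seq, pos = "", []
    for seg, orient in parts:
        if orient == "nat":
            seq += seg.sequence
            pos.extend(seg.residues)
        else:
            seq += seg.sequence[::-1]
            pos.extend(reversed(seg.residues))
    return DesignedPeptide(
        sequence=seq,
        positions=pos,
        segments_used=[(s.id, o) for s, o in parts],
        method=method,
        requested_length=requested_length,
        reference=reference,
        path_distance=path_distance,
        status=status,
    )


def _grow_chained(
    reference: Segment, segments: Sequence[Segment], requested_length: int
) -> list[Segment]:
    """Greedy chained collection: next = unused segment nearest (cog) to the
    most recently appended segment, until the length is reached."""
    chosen = [reference]
    unused = {s.id: s for s in segments if s.id != reference.id}
    length = len(reference)
    while length < requested_length and unused:
        anchor = chosen[-1].cog
        nxt = min(
            sorted(unused),
            key=lambda sid: (float(np.linalg.norm(unused[sid].cog - anchor)), sid),
        )
        chosen.append(unused.pop(nxt))
        length += len(chosen[-1])
    return chosen


def design_nn(
    reference: Segment, segments: Sequence[Segment], requested_length: int
) -> DesignedPeptide:
    """Nearest-neighbour: append the nearest unused segment C-terminally,
    in natural sense, until the requested length is reached (the
    overshooting segment is added whole)."""
    if requested_length < 1:
        raise ValueError("requested_length must be >= 1")
    chosen = _grow_chained(reference, segments, requested_length)
    status = "ok"
    if sum(len(s) for s in chosen) < requested_length:
        warnings.warn("segments exhausted before the requested length")
        status = "short"
    return _assemble(
        [(s, "nat") for s in chosen], "NN", requested_length, reference.id, status=status
    )


def design_unn(
    reference: Segment, segments: Sequence[Segment], requested_length: int
) -> DesignedPeptide:
    """Upset nearest-neighbour: like NN, but each appended segment joins
    through whichever terminus is closer to the forming peptide's
    C-terminal residue (reverse sense if its C-terminus is closer; ties go
    to the natural sense)."""
    if requested_length < 1:
        raise ValueError("requested_length must be >= 1")
    chosen = _grow_chained(reference, segments, requested_length)
    parts: list[tuple[Segment, str]] = [(reference, "nat")]
    tail = reference.c_term_coord
    for seg in chosen[1:]:
        d_n = float(np.linalg.norm(tail - seg.n_term_coord))
        d_c = float(np.linalg.norm(tail - seg.c_term_coord))
        if d_c < d_n:
            parts.append((seg, "rev"))
            tail = seg.n_term_coord
        else:
            parts.append((seg, "nat"))
            tail = seg.c_term_coord
    status = "ok" if sum(len(s) for s, _ in parts) >= requested_length else "short"
    return _assemble(parts, "uNN", requested_length, reference.id, status=status)


def design_fn(
    reference: Segment, segments: Sequence[Segment], requested_length: int
) -> DesignedPeptide:
    """Flanking nearest-neighbour: the segments NN would collect are placed
    alternately C-terminally then N-terminally, keeping the reference
    centrally placed (selection order is NN's chained-nearest rule; only
    the placement side alternates)."""
    if requested_length < 1:
        raise ValueError("requested_length must be >= 1")
    chosen = _grow_chained(reference, segments, requested_length)
    c_side: list[Segment] = []
    n_side: list[Segment] = []
    for i, seg in enumerate(chosen[1:]):
        (c_side if i % 2 == 0 else n_side).append(seg)
    parts = [(s, "nat") for s in reversed(n_side)] + [(reference, "nat")] + [
        (s, "nat") for s in c_side
    ]
    length = sum(len(s) for s in chosen)
    status = "ok" if length >= requested_length else "short"
    return _assemble(parts, "FN", requested_length, reference.id, status=status)


def design_optimized(
    method: str,
    reference: Segment,
    segments: Sequence[Segment],
    requested_length: int,
    model: Optional[SurfaceModel] = None,
) -> DesignedPeptide:
    """ONN / OFN / OPP: reorder a collected segment set to the arrangement
    with the shortest total centre-of-gravity distance.

    The set is the one selected by NN (ONN), by FN (OFN), or the members of
    the reference's 10 A patch (OPP; requires ``model``). No extra residue
    is added; segments are concatenated in natural sense.
    """
    if method == "ONN":
        base = design_nn(reference, segments, requested_length)
        ids = [sid for sid, _ in base.segments_used]
        by_id = {s.id: s for s in segments}
    elif method == "OFN":
        base = design_fn(reference, segments, requested_length)
        ids = [sid for sid, _ in base.segments_used]
        by_id = {s.id: s for s in segments}
    elif method == "OPP":
        if model is None:
            raise ValueError("OPP needs the surface model (10 A patches)")
        ids = sorted(model.patch10_of(reference.id).members)
        by_id = model.by_id
    else:
        raise ValueError(f"not an optimised prime method: {method}")
    members = [by_id[i] for i in sorted(ids)]
    cogs = np.array([s.cog for s in members])
    dmat = np.linalg.norm(cogs[:, None, :] - cogs[None, :, :], axis=-1)
    order, total = shortest_open_path(dmat, directed=False)
    parts = [(members[i], "nat") for i in order]
    return _assemble(
        parts, method, requested_length, reference.id, path_distance=total
    )


# --------------------------------------------------------------------------
# linker methods
# --------------------------------------------------------------------------

def _oriented_residues(seg: Segment, orient: str) -> list[ResidueKey]:
    return list(seg.residues) if orient == "nat" else list(reversed(seg.residues))


def _junction_gap(
    structure: ProteinStructure, exit_key: ResidueKey, entry_key: ResidueKey
) -> float:
    """Distance between the carbonyl C of the residue ending a segment and
    the amide N of the residue starting the next one (CA fallback)."""
    c = structure[exit_key].coord("C")
    n = structure[entry_key].coord("N")
    return float(np.linalg.norm(c - n))


def _sas_junction_aa(
    structure: ProteinStructure,
    before: list[ResidueKey],
    after: list[ResidueKey],
    library: PBLibrary,
) -> str:
    """One linker residue by structural superposition of the junction.

    The four real residues framing the junction (two on each side, fewer at
    segment ends) are treated as the outer positions of a 5-residue PB
    window whose centre is the residue to insert; the window's computable
    pseudo-dihedrals are matched against the 16 prototypes (NaN-tolerant
    RMSDA) and the winning PB's preferred central amino acid is inserted.
    """
    a2 = structure[before[-2]] if len(before) >= 2 else None
    a1 = structure[before[-1]]
    b1 = structure[after[0]]
    b2 = structure[after[1]] if len(after) >= 2 else None

    def atom(res, name):
        if res is None:
            return None
        a = res.atom(name)
        return None if a is None else a.coord

    from .geometry import dihedral as dih

    def safe(p0, p1, p2, p3):
        if any(x is None for x in (p0, p1, p2, p3)):
            return np.nan
        return dih(p0, p1, p2, p3)

    window = np.full(8, np.nan)
    window[0] = safe(atom(a2, "N"), atom(a2, "CA"), atom(a2, "C"), atom(a1, "N"))
    window[1] = safe(atom(a2, "C"), atom(a1, "N"), atom(a1, "CA"), atom(a1, "C"))
    window[2] = safe(atom(a1, "N"), atom(a1, "CA"), atom(a1, "C"), atom(b1, "N"))
    window[5] = safe(atom(a1, "C"), atom(b1, "N"), atom(b1, "CA"), atom(b1, "C"))
    window[6] = safe(atom(b1, "N"), atom(b1, "CA"), atom(b1, "C"), atom(b2, "N"))
    window[7] = safe(atom(b1, "C"), atom(b2, "N"), atom(b2, "CA"), atom(b2, "C"))
    if np.isnan(window).all():
        return "A"  # no geometry at all: neutral alanine
    pb = assign_pb(window, library)
    if pb == NULL_PB:
        return "A"
    return pb_preferred_aa(pb, 3, library)


def add_linkers(
    peptide: DesignedPeptide,
    linker: str,
    structure: ProteinStructure,
    model: SurfaceModel,
    library: Optional[PBLibrary] = None,
    pb_labels: Optional[dict[ResidueKey, str]] = None,
) -> DesignedPeptide:
    """Insert linker residues between the consecutive segments of a prime
    peptide.

    ``linker`` is ``"ALA"`` (alanines filling the spatial gap, one per
    peptide bond the gap accommodates beyond the first), ``"SA"`` (zero to
    two residues chosen via allowed protein-block transitions; an
    unbridgeable junction makes the peptide impossible) or ``"SAS"``
    (exactly one residue chosen by structural superposition of the
    junction). Linker positions carry provenance markers; stripping them
    recovers the prime peptide exactly.
    """
    if linker not in ("ALA", "SA", "SAS"):
        raise ValueError(f"unknown linker kind {linker!r}")
    library = library or load_default_library()
    if linker == "SA" and pb_labels is None:
        pb_labels = {}
        for cid in structure.chains:
            pb_labels.update(encode_chain(structure, cid, library))
    parts = [
        (model.by_id[sid], orient) for sid, orient in peptide.segments_used
    ]
    seq, pos = "", []
    status = peptide.status
    for i, (seg, orient) in enumerate(parts):
        res_keys = _oriented_residues(seg, orient)
        seq += seg.sequence if orient == "nat" else seg.sequence[::-1]
        pos.extend(res_keys)
        if i + 1 >= len(parts):
            break
        nxt_seg, nxt_orient = parts[i + 1]
        nxt_keys = _oriented_residues(nxt_seg, nxt_orient)
        if linker == "ALA":
            gap = _junction_gap(structure, res_keys[-1], nxt_keys[0])
            n_ala = max(0, int(np.floor(gap / PEPTIDE_BOND_SPAN + 0.5)) - 1)
            seq += "A" * n_ala
            pos.extend(LinkerPosition("ALA") for _ in range(n_ala))
        elif linker == "SA":
            pb_end = pb_labels.get(res_keys[-1], NULL_PB)
            pb_start = pb_labels.get(nxt_keys[0], NULL_PB)
            if NULL_PB in (pb_end, pb_start):
                continue  # no usable window at the junction: no insertion
            bridge = best_linker_pbs(pb_end, pb_start, 2, library)
            if bridge is None:
                status = "impossible"
                break
            for pb in bridge:
                seq += pb_preferred_aa(pb, 3, library)
                pos.append(LinkerPosition("SA"))
        else:  # SAS
            aa = _sas_junction_aa(structure, res_keys, nxt_keys, library)
            seq += aa
            pos.append(LinkerPosition("SAS"))
    base, kind = (peptide.method, linker)
    return DesignedPeptide(
        sequence=seq if status != "impossible" else "",
        positions=pos if status != "impossible" else [],
        segments_used=list(peptide.segments_used),
        method=base + kind.lower(),
        requested_length=peptide.requested_length,
        reference=peptide.reference,
        path_distance=peptide.path_distance,
        status=status,
    )


# --------------------------------------------------------------------------
# graph-based methods
# --------------------------------------------------------------------------

def build_design_graph(
    structure: ProteinStructure,
    elements: Sequence[Union[Segment, ResidueKey]],
    mode: str,
) -> nx.Graph:
    """Distance-weighted design graph over segments or accessible residues.

    ``natural``: complete directed graph over segments, edge i->j weighted
    by the distance from i's C-terminus to j's N-terminus (segments can
    only be traversed N to C). ``reversed``: complete undirected graph,
    weighted by the minimum over the four terminus pairings. ``aa``:
    complete undirected graph over residues with CA-CA distances.
    """
    if mode == "natural":
        g: nx.Graph = nx.DiGraph()
        for s in elements:
            g.add_node(s.id, segment=s)
        for s1 in elements:
            for s2 in elements:
                if s1.id != s2.id:
                    w = float(np.linalg.norm(s1.c_term_coord - s2.n_term_coord))
                    g.add_edge(s1.id, s2.id, weight=w)
        return g
    if mode == "reversed":
        g = nx.Graph()
        for s in elements:
            g.add_node(s.id, segment=s)
        for s1, s2 in itertools.combinations(elements, 2):
            d = min(
                float(np.linalg.norm(c1 - c2))
                for c1 in (s1.n_term_coord, s1.c_term_coord)
                for c2 in (s2.n_term_coord, s2.c_term_coord)
            )
            g.add_edge(s1.id, s2.id, weight=d)
        return g
    if mode == "aa":
        g = nx.Graph()
        for k in elements:
            g.add_node(k)
        for k1, k2 in itertools.combinations(sorted(elements), 2):
            d = float(
                np.linalg.norm(structure[k1].coord("CA") - structure[k2].coord("CA"))
            )
            g.add_edge(k1, k2, weight=d)
        return g
    raise ValueError(f"unknown graph mode {mode!r}")


def _graph_mode(method: str) -> str:
    if method.endswith("aa"):
        return "aa"
    return "natural" if "nat" in method else "reversed"


def _area_elements(
    area: SurfaceArea, model: SurfaceModel, mode: str
) -> list:
    """Resolve an area to graph elements for the given mode."""
    if mode == "aa":
        if area.kind in ("cluster", "patch10", "patch15"):
            keys: list[ResidueKey] = []
            for sid in sorted(area.members):
                keys.extend(model.by_id[sid].residues)
            return sorted(set(keys))
        return sorted(area.members)
    return [model.by_id[sid] for sid in sorted(area.members)]


def _orient_path(segments: list[Segment]) -> list[tuple[Segment, str]]:
    """Chained orientation along an undirected segment path: each segment
    enters through the terminus nearest the previous exit."""
    if len(segments) == 1:
        return [(segments[0], "nat")]
    first, second = segments[0], segments[1]
    pairs = {
        (e1, e2): float(np.linalg.norm(c1 - c2))
        for e1, c1 in (("N", first.n_term_coord), ("C", first.c_term_coord))
        for e2, c2 in (("N", second.n_term_coord), ("C", second.c_term_coord))
    }
    (exit1, _), _ = min(sorted(pairs.items()), key=lambda kv: (kv[1], kv[0]))
    parts = [(first, "nat" if exit1 == "C" else "rev")]
    exit_coord = first.c_term_coord if exit1 == "C" else first.n_term_coord
    for seg in segments[1:]:
        d_n = float(np.linalg.norm(exit_coord - seg.n_term_coord))
        d_c = float(np.linalg.norm(exit_coord - seg.c_term_coord))
        if d_c < d_n:
            parts.append((seg, "rev"))
            exit_coord = seg.n_term_coord
        else:
            parts.append((seg, "nat"))
            exit_coord = seg.c_term_coord
    return parts


def _peptide_from_elements(
    elements: list,
    mode: str,
    method: str,
    structure: ProteinStructure,
    reference,
    requested_length: Optional[int],
    path_distance: float,
    status: str = "ok",
) -> DesignedPeptide:
    if mode == "aa":
        seq = "".join(structure[k].aa for k in elements)
        return DesignedPeptide(
            sequence=seq,
            positions=list(elements),
            segments_used=[],
            method=method,
            requested_length=requested_length,
            reference=reference,
            path_distance=path_distance,
            status=status,
        )
    parts = (
        [(s, "nat") for s in elements] if mode == "natural" else _orient_path(elements)
    )
    pep = _assemble(parts, method, requested_length, reference, path_distance, status)
    return pep


MAX_SHORTEST_PATHS_PER_PAIR = 200


def design_shp(
    method: str,
    area: SurfaceArea,
    model: SurfaceModel,
    graph: Optional[nx.Graph] = None,
) -> Optional[DesignedPeptide]:
    """Shortest-path methods: over all pairs of area elements, the peptide
    is the shortest path covering the most residues.

    Ties break on smaller total distance, then lexicographic element ids.
    Disconnected pairs are skipped; if every pair is disconnected there is
    no peptide. The requested length plays no role.
    """
    if method not in ("SHPnat", "SHPrev", "SHPaa"):
        raise ValueError(f"not a shortest-path method: {method}")
    mode = _graph_mode(method)
    structure = model.structure
    elements = _area_elements(area, model, mode)
    if graph is None:
        graph = build_design_graph(structure, elements, mode)
    nodes = sorted(graph.nodes)
    if len(nodes) == 1:
        return _peptide_from_elements(
            _resolve(nodes, model, mode), mode, method, structure,
            _area_ref(area), None, 0.0,
        )

    def n_aa(path):
        if mode == "aa":
            return len(path)
        return sum(len(model.by_id[sid]) for sid in path)

    def length(path):
        return float(
            sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
        )

    best = None  # (-n_aa, dist, tuple(path))
    pairs = (
        itertools.permutations(nodes, 2)
        if graph.is_directed()
        else itertools.combinations(nodes, 2)
    )
    for u, v in pairs:
        try:
            it = nx.all_shortest_paths(graph, u, v, weight="weight")
            for i, path in enumerate(it):
                if i >= MAX_SHORTEST_PATHS_PER_PAIR:
                    break
                cand = (-n_aa(path), length(path), tuple(path))
                if best is None or cand < best:
                    best = cand
        except nx.NetworkXNoPath:
            continue
    if best is None:
        return None
    path = list(best[2])
    return _peptide_from_elements(
        _resolve(path, model, mode), mode, method, structure,
        _area_ref(area), None, best[1],
    )


def _resolve(path: list, model: SurfaceModel, mode: str) -> list:
    return path if mode == "aa" else [model.by_id[sid] for sid in path]


def _area_ref(area: SurfaceArea) -> str:
    ref = area.reference
    if ref is None:
        return f"{area.kind}:{','.join(map(str, sorted(map(str, area.members))))}"[:80]
    return f"{area.kind}:{ref}"


def design_tsp(
    method: str,
    area: SurfaceArea,
    model: SurfaceModel,
    requested_length: int,
    turns: Optional[set[ResidueKey]] = None,
) -> Optional[DesignedPeptide]:
    """Travelling-salesman methods: order the area elements along the
    minimum-distance open path, enumerate every contiguous run that first
    reaches the requested length, and select the final run by the variant
    rule.

    Variants: 1 = highest segment-sum score, 2 = shortest travelled
    distance, 3 = shortest distance per segment, 4 = contains the two
    closest elements of the area, ``aa`` = shortest travelled distance.
    An area holding fewer residues than requested yields the whole path,
    flagged short.
    """
    if not (method.startswith("TSP")):
        raise ValueError(f"not a TSP method: {method}")
    if requested_length < 1:
        raise ValueError("requested_length must be >= 1")
    mode = _graph_mode(method)
    structure = model.structure
    elements = _area_elements(area, model, mode)
    graph = build_design_graph(structure, elements, mode)
    nodes = sorted(graph.nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u in nodes:
        for v in nodes:
            if u != v:
                w[idx[u], idx[v]] = graph[u][v]["weight"] if graph.has_edge(u, v) else np.inf
    order, _ = shortest_open_path(w, directed=graph.is_directed())
    path = [nodes[i] for i in order]

    def aa_count(node):
        return 1 if mode == "aa" else len(model.by_id[node])

    runs: list[tuple[int, int]] = []
    for s in range(len(path)):
        total = 0
        for e in range(s, len(path)):
            total += aa_count(path[e])
            if total >= requested_length:
                runs.append((s, e))
                break
    status = "ok"
    if not runs:
        runs = [(0, len(path) - 1)]
        status = "short"

    def run_distance(run):
        s, e = run
        return float(sum(w[order[i], order[i + 1]] for i in range(s, e)))

    def run_ids(run):
        s, e = run
        return tuple(path[s : e + 1])

    variant = method[-1]
    if variant in ("1",) and mode != "aa":
        seg_by_id = model.by_id

        def key(run):
            score = sum(
                segment_score(seg_by_id[sid], structure, turns)
                for sid in run_ids(run)
            )
            return (-score, run_distance(run), run_ids(run))
    elif variant == "3":
        def key(run):
            s, e = run
            return (run_distance(run) / (e - s + 1), run_distance(run), run_ids(run))
    elif variant == "4":
        best_pair = min(
            (
                (min(w[i, j], w[j, i]), (nodes[i], nodes[j]))
                for i in range(n)
                for j in range(i + 1, n)
            ),
            key=lambda t: (t[0], t[1]),
            default=(0.0, None),
        )[1]

        def key(run):
            ids = set(run_ids(run))
            contains = best_pair is not None and set(best_pair) <= ids
            return (not contains, run_distance(run), run_ids(run))
    else:  # variants 2 and aa: shortest travelled distance
        def key(run):
            return (run_distance(run), run_ids(run))

    chosen = min(runs, key=key)
    run_elems = _resolve(list(run_ids(chosen)), model, mode)
    return _peptide_from_elements(
        run_elems, mode, method, structure, _area_ref(area),
        requested_length, run_distance(chosen), status,
    )


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def segment_score(
    segment: Segment,
    structure: ProteinStructure,
    turns: Optional[set[ResidueKey]] = None,
    hydrophobic: frozenset = HYDROPHOBIC_AA,
    access_scale: float = DEFAULT_ACCESS_SCALE,
) -> float:
    """Segment score Ss = Naa + Naccess + Nhyd + Nwryp + Nturn.

    Naa is the residue count; Naccess the mean relative accessibility
    scaled by ``access_scale`` (default 10, commensurate with counts);
    Nhyd counts hydrophobic residues; Nwryp counts W/R/Y/P (independently
    of Nhyd); Nturn counts residues assigned to hydrogen-bonded turns
    (0 when no turn assignment is supplied).
    """
    residues = [structure[k] for k in segment.residues]
    naa = len(residues)
    rels = [r.sasa_rel for r in residues if r.sasa_rel is not None]
    naccess = access_scale * float(np.mean(rels)) if rels else 0.0
    nhyd = sum(1 for r in residues if r.aa in hydrophobic)
    nwryp = sum(1 for r in residues if r.aa in "WRYP")
    nturn = sum(1 for r in residues if turns and r.key in turns)
    return naa + naccess + nhyd + nwryp + nturn


def score_peptide(
    peptide: DesignedPeptide,
    structure: ProteinStructure,
    model: SurfaceModel,
    turns: Optional[set[ResidueKey]] = None,
) -> float:
    """Peptide score Sp: sum of the scores of its constituent segments."""
    return float(
        sum(
            segment_score(model.by_id[sid], structure, turns)
            for sid, _ in peptide.segments_used
        )
    )


# --------------------------------------------------------------------------
# dispatch and bank generation
# --------------------------------------------------------------------------

def design(
    method: str,
    model: SurfaceModel,
    reference,
    requested_length: int,
    turns: Optional[set[ResidueKey]] = None,
    library: Optional[PBLibrary] = None,
) -> Optional[DesignedPeptide]:
    """Design one peptide with one method from one reference.

    ``reference`` is a :class:`Segment` (prime/linker methods) or a
    :class:`SurfaceArea` (graph methods).
    """
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}")
    family = method_family(method)
    structure = model.structure
    if family == "graph":
        if method.startswith("SHP"):
            return design_shp(method, reference, model)
        return design_tsp(method, reference, model, requested_length, turns)
    if family == "prime":
        pep = _design_prime(method, reference, model, requested_length)
    else:
        base, kind = linker_parts(method)
        prime = _design_prime(base, reference, model, requested_length)
        pep = add_linkers(prime, kind, structure, model, library)
    if pep is not None:
        pep.score = score_peptide(pep, structure, model, turns)
    return pep


def _design_prime(method, reference, model, requested_length):
    segments = model.segments
    if method == "NN":
        return design_nn(reference, segments, requested_length)
    if method == "uNN":
        return design_unn(reference, segments, requested_length)
    if method == "FN":
        return design_fn(reference, segments, requested_length)
    return design_optimized(method, reference, segments, requested_length, model)


def generate_peptide_bank(
    model: SurfaceModel,
    method: str,
    requested_length: int,
    turns: Optional[set[ResidueKey]] = None,
    library: Optional[PBLibrary] = None,
) -> list[DesignedPeptide]:
    """All peptides one method designs over the whole antigen surface.

    Prime and linker methods use every segment as reference; segment-graph
    methods design one peptide per cluster and one per 15 A patch;
    aa-graph methods one per cluster and one per varying patch. Within a
    method, duplicate sequences are removed (first reference wins) and
    failed (impossible) peptides are excluded.
    """
    family = method_family(method)
    refs: list = []
    if family in ("prime", "linker"):
        refs = list(model.segments)
    elif method in AA_GRAPH_METHODS:
        refs = list(model.clusters) + list(model.varying_patches)
    else:
        refs = list(model.clusters) + list(model.patches15)
    bank: list[DesignedPeptide] = []
    seen: set[str] = set()
    for ref in refs:
        pep = design(method, model, ref, requested_length, turns, library)
        if pep is None or pep.status == "impossible" or not pep.sequence:
            continue
        if pep.sequence in seen:
            continue
        seen.add(pep.sequence)
        bank.append(pep)
    return bank


def write_bank_fasta(bank: Sequence[DesignedPeptide], path) -> None:
    """Write a peptide bank as FASTA; headers carry method, reference,
    score and final length."""
    with open(path, "w") as fh:
        for i, p in enumerate(bank, start=1):
            score = f"{p.score:.2f}" if p.score is not None else "NA"
            fh.write(
                f">pep{i}|method={p.method}|ref={p.reference}"
                f"|score={score}|len={p.final_length}\n{p.sequence}\n"
            )


def write_bank_tsv(bank: Sequence[DesignedPeptide], path) -> None:
    """Write per-position provenance of a peptide bank as TSV."""
    import pandas as pd

    rows = []
    for i, p in enumerate(bank, start=1):
        for j, (aa, prov) in enumerate(zip(p.sequence, p.positions), start=1):
            if isinstance(prov, LinkerPosition):
                src = f"linker:{prov.origin}"
            else:
                src = f"{prov[0]}:{prov[1]}{prov[2]}"
            rows.append(
                {
                    "peptide": f"pep{i}",
                    "method": p.method,
                    "reference": str(p.reference),
                    "position": j,
                    "aa": aa,
                    "source": src,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
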