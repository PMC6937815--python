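"""Surface vocabulary: segments, clusters, fixed-radius and varying patches.

A *segment* is a maximal run of chain-contiguous surface-accessible
residues. Segments are grouped into *clusters* by average-linkage
hierarchical clustering on centre-of-gravity distances (a functional
stand-in for tree-based aggregation of inter-segment distances, cut at a
configurable height). A *patch* gathers the segments whose centre of
gravity lies within a fixed radius (10 or 15 A, inclusive) of a reference
segment's centre of gravity; a *varying patch* gathers the accessible
residues within an adaptive radius (15-20 A) of a reference residue's CA.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import ProteinStructure, Residue, ResidueKey, Segment, SurfaceArea

__all__ = [
    "build_segments",
    "segment_distance",
    "build_clusters",
    "build_patches",
    "build_varying_patch",
    "build_varying_patches",
    "SurfaceModel",
    "build_surface_model",
    "write_areas_tsv",
]

DEFAULT_CLUSTER_CUTOFF = 20.0
VARYING_RADII = (15.0, 16.0, 17.0, 18.0, 19.0, 20.0)


def build_segments(structure: ProteinStructure) -> list[Segment]:
    """Maximal runs of accessible residues per chain, in chain order.

    Every accessible residue belongs to exactly one segment. Requires
    accessibility annotations (:func:`structure_io.compute_accessibility`
    or a fixture mask).
    """
    segments: list[Segment] = []
    for cid, residues in structure.chains.items():
        run: list[Residue] = []
        for r in residues:
            if r.accessible is None:
                raise ValueError("accessibility not computed")
            if r.accessible:
                run.append(r)
            elif run:
                segments.append(_make_segment(len(segments) + 1, cid, run))
                run = []
        if run:
            segments.append(_make_segment(len(segments) + 1, cid, run))
    if not segments:
        warnings.warn(f"structure {structure.id}: no accessible residue")
    return segments


def _make_segment(seg_id: int, chain: str, run: list[Residue]) -> Segment:
    coords = np.array([a.coord for r in run for a in r.atoms])
    return Segment(
        id=seg_id,
        residues=[r.key for r in run],
        sequence="".join(r.aa for r in run),
        cog=coords.mean(axis=0),
        n_term_coord=run[0].coord("CA"),
        c_term_coord=run[-1].coord("CA"),
        chain=chain,
    )


def segment_distance(
    s1: Segment, s2: Segment, anchor: str = "cog"
) -> float | tuple[float, tuple[str, str]]:
    """Euclidean distance between two segments.

    ``anchor="cog"`` returns the distance between centres of gravity;
    ``anchor="termini"`` returns ``(distance, (end1, end2))`` for the
    minimum over the four N/C-terminus pairings.
    """
    if anchor == "cog":
        return float(np.linalg.norm(s1.cog - s2.cog))
    if anchor == "termini":
        pairs = {}
        for e1, c1 in (("N", s1.n_term_coord), ("C", s1.c_term_coord)):
            for e2, c2 in (("N", s2.n_term_coord), ("C", s2.c_term_coord)):
                pairs[(e1, e2)] = float(np.linalg.norm(c1 - c2))
        best = min(sorted(pairs), key=lambda k: pairs[k])
        return pairs[best], best
    raise ValueError(f"unknown anchor {anchor!r}")


def build_clusters(
    segments: list[Segment], cutoff: float = DEFAULT_CLUSTER_CUTOFF
) -> list[SurfaceArea]:
    """Group segments into clusters by spatial proximity.

    Average-linkage hierarchical clustering on pairwise centre-of-gravity
    distances, cut at ``cutoff`` (A). Deterministic; a single segment gives
    one singleton cluster. Every segment belongs to exactly one cluster.
    """
    if not segments:
        raise ValueError("no segments to cluster")
    if len(segments) == 1:
        return [
            SurfaceArea(
                kind="cluster",
                reference=None,
                members=[segments[0].id],
                radius=None,
                n_aa=len(segments[0]),
            )
        ]
    cogs = np.array([s.cog for s in segments])
    dmat = np.linalg.norm(cogs[:, None, :] - cogs[None, :, :], axis=-1)
    z = linkage(squareform(dmat, checks=False), method="average")
    labels = fcluster(z, t=cutoff, criterion="distance")
    clusters: list[SurfaceArea] = []
    for lab in sorted(set(labels)):
        members = [s for s, l in zip(segments, labels) if l == lab]
        clusters.append(
            SurfaceArea(
                kind="cluster",
                reference=None,
                members=[s.id for s in members],
                radius=None,
                n_aa=sum(len(s) for s in members),
            )
        )
    return clusters


def build_patches(segments: list[Segment], radius: float) -> list[SurfaceArea]:
    """One fixed-radius patch per segment (each segment used as reference).

    A patch holds every segment whose centre of gravity lies within
    ``radius`` (inclusive) of the reference segment's centre of gravity;
    the reference always belongs to its own patch, so the number of patches
    equals the number of segments.
    """
    if not segments:
        raise ValueError("no segments")
    kind = f"patch{int(radius)}"
    patches = []
    for ref in segments:
        members = [
            s.id
            for s in segments
            if np.linalg.norm(s.cog - ref.cog) <= radius + 1e-9
        ]
        patches.append(
            SurfaceArea(
                kind=kind,
                reference=ref.id,
                members=members,
                radius=radius,
                n_aa=sum(len(s) for s in segments if s.id in members),
            )
        )
    return patches


def build_varying_patch(
    structure: ProteinStructure, reference_aa: ResidueKey
) -> SurfaceArea:
    """Adaptive-radius residue patch around one accessible reference residue.

    Counts the accessible residues within each radius 15..20 A (CA-CA,
    inclusive) of the reference CA, takes the mean of the six counts, and
    selects the smallest radius whose count reaches that mean; the patch
    members are the accessible residues within the selected radius.
    """
    ref = structure[reference_aa]
    if not ref.accessible:
        raise ValueError(f"reference residue {reference_aa} is not accessible")
    ref_ca = ref.coord("CA")
    acc = structure.accessible_residues()
    dists = {r.key: float(np.linalg.norm(r.coord("CA") - ref_ca)) for r in acc}
    counts = [sum(1 for d in dists.values() if d <= rad + 1e-9) for rad in VARYING_RADII]
    mean_count = float(np.mean(counts))
    radius = VARYING_RADII[-1]
    for rad, cnt in zip(VARYING_RADII, counts):
        if cnt >= mean_count:
            radius = rad
            break
    members = sorted(k for k, d in dists.items() if d <= radius + 1e-9)
    return SurfaceArea(
        kind="varying_patch",
        reference=reference_aa,
        members=members,
        radius=radius,
        n_aa=len(members),
    )


def build_varying_patches(structure: ProteinStructure) -> list[SurfaceArea]:
    """One varying patch per accessible residue, in chain order."""
    return [
        build_varying_patch(structure, r.key) for r in structure.accessible_residues()
    ]


class SurfaceModel:
    """The full surface decomposition of one antigen.

    Holds the segments and every area type the design methods draw from,
    with id-based lookups.
    """

    def __init__(
        self,
        structure: ProteinStructure,
        segments: list[Segment],
        clusters: list[SurfaceArea],
        patches10: list[SurfaceArea],
        patches15: list[SurfaceArea],
        varying_patches: list[SurfaceArea],
    ):
        self.structure = structure
        self.segments = segments
        self.clusters = clusters
        self.patches10 = patches10
        self.patches15 = patches15
        self.varying_patches = varying_patches
        self.by_id = {s.id: s for s in segments}

    def segment_of(self, key: ResidueKey) -> Optional[int]:
        for s in self.segments:
            if key in s.residues:
                return s.id
        return None

    def patch10_of(self, seg_id: int) -> SurfaceArea:
        return next(p for p in self.patches10 if p.reference == seg_id)

    def patch15_of(self, seg_id: int) -> SurfaceArea:
        return next(p for p in self.patches15 if p.reference == seg_id)


def build_surface_model(
    structure: ProteinStructure, cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF
) -> SurfaceModel:
    """Build segments, clusters and all patch types for a structure."""
    segments = build_segments(structure)
    if segments:
        clusters = build_clusters(segments, cutoff=cluster_cutoff)
        patches10 = build_patches(segments, 10.0)
        patches15 = build_patches(segments, 15.0)
    else:
        clusters, patches10, patches15 = [], [], []
    varying = build_varying_patches(structure)
    return SurfaceModel(structure, segments, clusters, patches10, patches15, varying)


def write_areas_tsv(model: SurfaceModel, path) -> None:
    """Dump all areas as TSV: id, kind, reference, members, n_aa, radius."""
    rows = []
    for i, s in enumerate(model.segments):
        rows.append(
            {
                "area_id": f"segment{s.id}",
                "kind": "segment",
                "reference": "",
                "members": ",".join(f"{c}:{n}{ic}" for c, n, ic in s.residues),
                "n_aa": len(s),
                "radius": "",
            }
        )
    for name, areas in (
        ("cluster", model.clusters),
        ("patch10", model.patches10),
        ("patch15", model.patches15),
        ("varying", model.varying_patches),
    ):
        for i, a in enumerate(areas, start=1):
            members = (
                ",".join(str(m) for m in a.members)
                if a.kind != "varying_patch"
                else ",".join(f"{c}:{n}{ic}" for c, n, ic in a.members)
            )
            rows.append(
                {
                    "area_id": f"{name}{i}",
                    "kind": a.kind,
                    "reference": str(a.reference) if a.reference is not None else "",
                    "members": members,
                    "n_aa": a.n_aa,
                    "radius": a.radius if a.radius is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
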