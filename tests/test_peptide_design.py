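"""Prime, linker and graph-based design methods, scoring and banks."""

import itertools

import numpy as np
import pytest

from conftest import toy_structure
from epimimic.core import ALL_METHODS, LinkerPosition
from epimimic.peptide_design import (
    add_linkers,
    build_design_graph,
    design,
    design_fn,
    design_nn,
    design_optimized,
    design_shp,
    design_tsp,
    design_unn,
    generate_peptide_bank,
    score_peptide,
    segment_score,
    shortest_open_path,
    write_bank_fasta,
)
from epimimic.surface_model import build_segments, build_surface_model


def singleton_structure(centres, sequence=None):
    """One singleton segment per centre (buried spacers in between)."""
    coords, access, seq = [], [], ""
    sequence = sequence or "A" * len(centres)
    for c, aa in zip(centres, sequence):
        coords.extend([c, [c[0], 500.0, 0.0]])
        access.extend([True, False])
        seq += aa + "A"
    return toy_structure(coords, sequence=seq, accessible=access)


class TestShortestOpenPath:
    def brute(self, w):
        n = len(w)
        best = None
        for perm in itertools.permutations(range(n)):
            cost = sum(w[perm[i], perm[i + 1]] for i in range(n - 1))
            if best is None or cost < best[0] - 1e-12:
                best = (cost, list(perm))
        return best

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_exact_regime_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        pts = rng.uniform(0, 30, size=(n, 3))
        w = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        order, total = shortest_open_path(w)
        assert total == pytest.approx(self.brute(w)[0])

    def test_directed_instance(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(1, 10, size=(5, 5))
        np.fill_diagonal(w, 0)
        order, total = shortest_open_path(w, directed=True)
        assert total == pytest.approx(self.brute(w)[0])

    def test_heuristic_regime_not_worse_than_greedy(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 50, size=(15, 3))
        w = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        order, total = shortest_open_path(w)
        assert sorted(order) == list(range(15))
        greedy = [0]
        left = set(range(1, 15))
        while left:
            nxt = min(left, key=lambda j: w[greedy[-1], j])
            greedy.append(nxt)
            left.discard(nxt)
        greedy_cost = sum(w[greedy[i], greedy[i + 1]] for i in range(14))
        assert total <= greedy_cost + 1e-9


class TestPrimeMethods:
    def test_reference_alone_when_long_enough(self):
        st = toy_structure([[i * 3.8, 0, 0] for i in range(10)])
        (seg,) = build_segments(st)
        pep = design_nn(seg, [seg], requested_length=8)
        assert pep.sequence == seg.sequence
        assert pep.final_length == 10

    def test_collinear_segments_appended_in_spatial_order(self):
        st = singleton_structure([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]])
        segs = build_segments(st)
        pep = design_nn(segs[0], segs, requested_length=4)
        assert [sid for sid, _ in pep.segments_used] == [s.id for s in segs]

    def test_unn_joins_closer_terminus_first(self):
        # reference 1-10 along +x; candidate segment runs back toward it, so
        # its C-terminus is nearest the reference C-terminus -> reversed
        coords = [[i * 3.8, 0, 0] for i in range(4)]
        coords += [[500, 500, 500]]  # buried spacer
        coords += [[30 - i * 3.8, 8, 0] for i in range(4)]
        access = [True] * 4 + [False] + [True] * 4
        st = toy_structure(coords, accessible=access)
        ref, other = build_segments(st)
        pep = design_unn(ref, [ref, other], requested_length=8)
        assert pep.segments_used == [(ref.id, "nat"), (other.id, "rev")]
        assert pep.positions[4:] == list(reversed(other.residues))

    def test_unn_tie_keeps_natural_sense(self):
        coords = [[0, 0, 0], [500, 500, 500], [10, -5, 0], [10, 5, 0]]
        access = [True, False, True, True]
        st = toy_structure(coords, accessible=access)
        ref, other = build_segments(st)
        pep = design_unn(ref, [ref, other], requested_length=3)
        assert pep.segments_used[1] == (other.id, "nat")

    def test_unn_orientations_match_end_distances(self, masked_model):
        for ref in masked_model.segments:
            pep = design_unn(ref, masked_model.segments, requested_length=20)
            tail = masked_model.by_id[pep.segments_used[0][0]].c_term_coord
            for sid, orient in pep.segments_used[1:]:
                seg = masked_model.by_id[sid]
                d_n = np.linalg.norm(tail - seg.n_term_coord)
                d_c = np.linalg.norm(tail - seg.c_term_coord)
                assert orient == ("rev" if d_c < d_n else "nat")
                tail = seg.c_term_coord if orient == "nat" else seg.n_term_coord

    def test_fn_reference_stays_central(self):
        st = singleton_structure(
            [[0, 0, 0], [5, 0, 0], [-5, 0, 0], [10, 0, 0], [-10, 0, 0]]
        )
        segs = build_segments(st)
        pep = design_fn(segs[0], segs, requested_length=5)
        ids = [sid for sid, _ in pep.segments_used]
        centre = ids.index(segs[0].id)
        assert abs(centre - (len(ids) - 1 - centre)) <= 1

    def test_fn_uses_same_segment_multiset_as_nn(self, masked_model):
        ref = masked_model.segments[2]
        nn = design_nn(ref, masked_model.segments, requested_length=16)
        fn = design_fn(ref, masked_model.segments, requested_length=16)
        if len(nn.segments_used) == len(fn.segments_used):
            assert sorted(s for s, _ in nn.segments_used) == sorted(
                s for s, _ in fn.segments_used
            )

    def test_fn_closer_neighbour_goes_c_terminal(self):
        st = singleton_structure([[0, 0, 0], [4, 0, 0], [-9, 0, 0]])
        ref, near, far = build_segments(st)
        pep = design_fn(ref, [ref, near, far], requested_length=3)
        assert [sid for sid, _ in pep.segments_used] == [far.id, ref.id, near.id]


class TestOptimized:
    def test_three_segments_match_brute_force(self):
        st = singleton_structure([[0, 0, 0], [9, 1, 0], [4, 8, 0]])
        segs = build_segments(st)
        pep = design_optimized("ONN", segs[0], segs, requested_length=3)
        cogs = {s.id: s.cog for s in segs}
        best = min(
            (
                sum(
                    np.linalg.norm(cogs[p[i]] - cogs[p[i + 1]])
                    for i in range(len(p) - 1)
                )
                for p in itertools.permutations([s.id for s in segs])
            )
        )
        assert pep.path_distance == pytest.approx(best)

    def test_single_segment_identity(self):
        st = toy_structure([[0, 0, 0]])
        (seg,) = build_segments(st)
        pep = design_optimized("ONN", seg, [seg], requested_length=1)
        assert pep.segments_used == [(seg.id, "nat")]

    def test_never_worse_than_greedy_ordering(self, masked_model):
        for ref in masked_model.segments[:4]:
            nn = design_nn(ref, masked_model.segments, requested_length=16)
            onn = design_optimized("ONN", ref, masked_model.segments, 16)
            cogs = {s.id: s.cog for s in masked_model.segments}

            def total(ids):
                return sum(
                    np.linalg.norm(cogs[ids[i]] - cogs[ids[i + 1]])
                    for i in range(len(ids) - 1)
                )

            assert total([s for s, _ in onn.segments_used]) <= total(
                [s for s, _ in nn.segments_used]
            ) + 1e-9

    def test_opp_uses_patch_members(self, masked_model):
        ref = masked_model.segments[0]
        pep = design_optimized("OPP", ref, masked_model.segments, 12, masked_model)
        assert sorted(s for s, _ in pep.segments_used) == sorted(
            masked_model.patch10_of(ref.id).members
        )


class TestLinkers:
    def two_segment_structure(self, gap):
        """Two 3-residue strand-like segments with an exact C..N junction gap.

        Residues carry N, CA and C atoms 1.2 A apart along x; the second
        segment starts so that C(seg1 last) to N(seg2 first) equals ``gap``.
        """
        from epimimic.core import AtomRecord, ProteinStructure, Residue

        def residue(key, x0, aa="A"):
            atoms = [
                AtomRecord("N", "N", np.array([x0, 0.0, 0.0]), key),
                AtomRecord("CA", "C", np.array([x0 + 1.2, 0.0, 0.0]), key),
                AtomRecord("C", "C", np.array([x0 + 2.4, 0.0, 0.0]), key),
            ]
            r = Residue(key=key, aa=aa, atoms=atoms)
            r.accessible, r.sasa_rel, r.sasa_abs = True, 1.0, 100.0
            return r

        residues = []
        for i in range(3):
            residues.append(residue(("A", i + 1, ""), i * 3.8))
        buried = residue(("A", 4, ""), 500.0)
        buried.accessible, buried.sasa_rel = False, 0.0
        residues.append(buried)
        start2 = 2 * 3.8 + 2.4 + gap  # N of residue 5
        for i in range(3):
            residues.append(residue(("A", i + 5, ""), start2 + i * 3.8))
        return ProteinStructure(id=f"gap{gap}", chains={"A": residues})

    @pytest.mark.parametrize("gap,n_ala", [(3.8, 0), (7.6, 1), (11.4, 2), (2.0, 0)])
    def test_alanine_count_follows_gap_rule(self, gap, n_ala):
        st = self.two_segment_structure(gap)
        model = build_surface_model(st)
        prime = design_nn(model.segments[0], model.segments, requested_length=6)
        pep = add_linkers(prime, "ALA", st, model)
        linkers = [p for p in pep.positions if isinstance(p, LinkerPosition)]
        assert len(linkers) == n_ala
        assert all(p.origin == "ALA" for p in linkers)
        assert pep.sequence.count("A") >= n_ala

    @pytest.mark.parametrize("kind", ["ALA", "SA", "SAS"])
    def test_stripping_linkers_recovers_prime_parent(self, kind, masked_model):
        st = masked_model.structure
        for ref in masked_model.segments[:3]:
            prime = design_nn(ref, masked_model.segments, requested_length=12)
            pep = add_linkers(prime, kind, st, masked_model)
            if pep.status == "impossible":
                continue
            stripped = pep.stripped()
            assert stripped.sequence == prime.sequence
            assert stripped.positions == prime.positions

    def test_sas_inserts_exactly_one_residue_per_junction(self, masked_model):
        st = masked_model.structure
        prime = design_nn(masked_model.segments[0], masked_model.segments, 16)
        pep = add_linkers(prime, "SAS", st, masked_model)
        n_junctions = len(prime.segments_used) - 1
        linkers = [p for p in pep.positions if isinstance(p, LinkerPosition)]
        assert len(linkers) == n_junctions

    def test_sa_bridge_failure_flags_peptide_impossible(self, masked_model):
        import pandas as pd

        from epimimic.structural_alphabet import PB_LABELS, PBLibrary, load_default_library

        base = load_default_library()
        dead = PBLibrary(
            prototypes=dict(base.prototypes),
            transitions=pd.DataFrame(
                0.0, index=list(PB_LABELS), columns=list(PB_LABELS)
            ),
            propensities=base.propensities,
        )
        st = masked_model.structure
        prime = design_nn(masked_model.segments[0], masked_model.segments, 16)
        pep = add_linkers(prime, "SA", st, masked_model, library=dead)
        assert pep.status == "impossible"
        assert pep.sequence == ""


class TestDesignGraphs:
    def test_edge_counts(self, masked_model):
        segs = masked_model.segments[:3]
        nat = build_design_graph(masked_model.structure, segs, "natural")
        rev = build_design_graph(masked_model.structure, segs, "reversed")
        assert nat.number_of_edges() == 6
        assert rev.number_of_edges() == 3

    def test_aa_graph_node_count(self, masked_model):
        keys = [r.key for r in masked_model.structure.accessible_residues()]
        g = build_design_graph(masked_model.structure, keys, "aa")
        assert g.number_of_nodes() == len(keys)

    def test_undirected_weights_symmetric(self, masked_model):
        segs = masked_model.segments[:4]
        rev = build_design_graph(masked_model.structure, segs, "reversed")
        for u, v, data in rev.edges(data=True):
            assert rev[v][u]["weight"] == data["weight"]


class TestSHP:
    def test_two_element_area_is_single_path(self, masked_model):
        from epimimic.core import SurfaceArea

        ids = [s.id for s in masked_model.segments[:2]]
        area = SurfaceArea(kind="cluster", reference=None, members=ids,
                           radius=None, n_aa=8)
        pep = design_shp("SHPrev", area, masked_model)
        assert sorted(s for s, _ in pep.segments_used) == sorted(ids)

    def test_collinear_aa_graph_prefers_most_residues(self):
        # residues 1..4 equally spaced on a line: the path 1-2-3-4 ties the
        # direct 1-4 edge in length but covers 4 residues; residue 5 is off
        from epimimic.core import SurfaceArea

        st = toy_structure(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [10, 20, 0]],
            sequence="ACDEF",
        )
        area = SurfaceArea(
            kind="varying_patch", reference=("A", 1, ""),
            members=[r.key for r in st.residues()], radius=20.0, n_aa=5,
        )
        model = build_surface_model(st)
        pep = design_shp("SHPaa", area, model)
        assert pep.final_length == 4
        assert pep.sequence in ("ACDE", "EDCA")

    def test_output_ignores_requested_length(self, masked_model):
        peps = [
            design_shp("SHPnat", masked_model.clusters[0], masked_model)
            for _ in range(2)
        ]
        assert peps[0].sequence == peps[1].sequence
        assert peps[0].requested_length is None


class TestTSP:
    def test_order_matches_brute_force_on_planted_graph(self, masked_model):
        from epimimic.core import SurfaceArea

        segs = masked_model.segments[:4]
        area = SurfaceArea(kind="cluster", reference=None,
                           members=[s.id for s in segs], radius=None,
                           n_aa=sum(len(s) for s in segs))
        pep = design_tsp("TSPrev2", area, masked_model, requested_length=100)
        g = build_design_graph(masked_model.structure, segs, "reversed")
        best = min(
            sum(g[p[i]][p[i + 1]]["weight"] for i in range(len(p) - 1))
            for p in itertools.permutations([s.id for s in segs])
        )
        assert pep.status == "short"  # length 100 unreachable: whole path
        assert pep.path_distance == pytest.approx(best)

    def test_tspaa_exact_requested_length(self, masked_model):
        for area in masked_model.varying_patches[:5]:
            if area.n_aa >= 8:
                pep = design_tsp("TSPaa", area, masked_model, requested_length=8)
                assert pep.final_length == 8

    def test_tspnat4_contains_two_closest_segments(self):
        centres = [[0, 0, 0], [3, 0, 0], [20, 0, 0], [40, 0, 0], [60, 0, 0]]
        st = singleton_structure(centres)
        model = build_surface_model(st)
        from epimimic.core import SurfaceArea

        area = SurfaceArea(
            kind="cluster", reference=None,
            members=[s.id for s in model.segments], radius=None, n_aa=5,
        )
        pep = design_tsp("TSPnat4", area, model, requested_length=2)
        used = {sid for sid, _ in pep.segments_used}
        assert {model.segments[0].id, model.segments[1].id} <= used

    def test_short_area_flagged(self, masked_model):
        area = masked_model.patches15[0]
        pep = design_tsp("TSPrev2", area, masked_model, requested_length=500)
        assert pep.status == "short"
        assert pep.final_length == area.n_aa


class TestScoring:
    def test_hand_example_gg_half_accessible(self):
        st = toy_structure([[0, 0, 0], [3.8, 0, 0]], sequence="GG",
                           sasa_rel=[0.5, 0.5])
        (seg,) = build_segments(st)
        assert segment_score(seg, st, turns=None) == pytest.approx(7.0)

    def test_tryptophan_raises_score(self):
        st_g = toy_structure([[0, 0, 0], [3.8, 0, 0]], sequence="GG")
        st_w = toy_structure([[0, 0, 0], [3.8, 0, 0]], sequence="GW")
        (sg,) = build_segments(st_g)
        (sw,) = build_segments(st_w)
        assert segment_score(sw, st_w) >= segment_score(sg, st_g) + 2

    def test_peptide_score_is_sum_of_segment_scores(self, masked_model):
        st = masked_model.structure
        pep = design_nn(masked_model.segments[0], masked_model.segments, 16)
        expected = sum(
            segment_score(masked_model.by_id[sid], st)
            for sid, _ in pep.segments_used
        )
        assert score_peptide(pep, st, masked_model) == pytest.approx(expected)


class TestBanks:
    def test_prime_bank_size_bounded_by_segments(self, masked_model):
        bank = generate_peptide_bank(masked_model, "NN", 12)
        assert 0 < len(bank) <= len(masked_model.segments)

    def test_graph_bank_size_bounded_by_clusters_plus_patches(self, masked_model):
        bank = generate_peptide_bank(masked_model, "TSPnat2", 16)
        assert len(bank) <= len(masked_model.clusters) + len(masked_model.patches15)
        bank_aa = generate_peptide_bank(masked_model, "TSPaa", 16)
        assert len(bank_aa) <= len(masked_model.clusters) + len(
            masked_model.varying_patches
        )

    def test_duplicate_sequences_removed(self, masked_model):
        for method in ("NN", "TSPaa", "SHPrev"):
            bank = generate_peptide_bank(masked_model, method, 12)
            seqs = [p.sequence for p in bank]
            assert len(seqs) == len(set(seqs))

    def test_banks_byte_identical_across_runs(self, masked_model, tmp_path):
        paths = []
        for run in (1, 2):
            peps = []
            for method in ("NN", "uNNala", "ONNsa", "TSPrev3", "SHPaa"):
                peps.extend(generate_peptide_bank(masked_model, method, 12))
            p = tmp_path / f"bank{run}.fasta"
            write_bank_fasta(peps, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_every_position_maps_to_accessible_residue(self, masked_model):
        st = masked_model.structure
        for method in ALL_METHODS:
            for pep in generate_peptide_bank(masked_model, method, 10):
                for aa, prov in zip(pep.sequence, pep.positions):
                    if isinstance(prov, LinkerPosition):
                        continue
                    assert st[prov].accessible
                    assert st[prov].aa == aa


def test_design_dispatch_rejects_unknown_method(masked_model):
    with pytest.raises(ValueError):
        design("XXX", masked_model, masked_model.segments[0], 12)
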