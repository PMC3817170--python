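"""Superposition, grafting, backbone closure and replacement locality."""

import numpy as np
import pytest

from rnasaxs import geometry as geo
from rnasaxs import synthetic as syn
from rnasaxs.assembly import (LibraryCoverageError, close_backbone,
                              random_initial_model, replace_element,
                              replace_strand)
from rnasaxs.fragments import (ideal_strand, make_fixture_library,
                               tree_topologies)


def quaternion_superpose_rmsd(mobile, target):
    """Independent closed-form (Horn quaternion) superposition oracle."""
    mobile = mobile - mobile.mean(axis=0)
    target = target - target.mean(axis=0)
    m = mobile.T @ target
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = np.sum(mobile ** 2) + np.sum(target ** 2)
    return float(np.sqrt(max(0.0, e0 - 2 * lam) / len(mobile)))


class TestSuperpose:
    def test_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        rot, t = geo.superpose(pts, pts)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)

    def test_recovers_known_rotation(self):
        rot90 = geo.rotation_about_axis(np.array([0.0, 0, 1]), np.pi / 2)
        pts = np.array([[1.0, 0, 0], [0, 1, 0], [2, 1, 3]])
        rot, t = geo.superpose(pts, pts @ rot90.T)
        assert np.allclose(rot, rot90, atol=1e-6)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_quaternion_oracle_on_random_sets(self, rng):
        for _ in range(25):
            a = rng.normal(size=(6, 3))
            rot_true = geo.rotation_about_axis(rng.normal(size=3),
                                               rng.uniform(0, np.pi))
            b = a @ rot_true.T + rng.normal(size=(6, 3)) * 0.3 + 5.0
            assert geo.superposed_rmsd(a, b) == pytest.approx(
                quaternion_superpose_rmsd(a, b), abs=1e-6)

    def test_collinear_triple_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(geo.DegenerateFrameError):
            geo.superpose(pts, pts)


class TestCloseBackbone:
    def test_contiguous_junction_unchanged(self, stemloop_native):
        _, native = stemloop_native
        closed, residual = close_backbone(native, (4, 5))
        assert residual < 0.05
        # a link already at reference length moves (nearly) nothing
        assert np.allclose(closed.coords, native.coords, atol=0.2)

    def test_displaced_graft_repaired(self, stemloop_native):
        _, native = stemloop_native
        broken = native.copy()
        # displace the hairpin loop (residues 5..) rigidly by ~0.5 A
        broken.coords[5:] += np.array([0.3, 0.3, 0.2])
        closed, residual = close_backbone(broken, (4, 5))
        d = np.linalg.norm(closed.atom(4, "O3'") - closed.atom(5, "P"))
        assert 1.4 <= d <= 1.8
        assert residual < 0.05

    def test_only_upstream_residue_moves(self, stemloop_native):
        _, native = stemloop_native
        broken = native.copy()
        broken.coords[5:] += 0.4
        closed, _ = close_backbone(broken, (4, 5))
        assert np.array_equal(closed.coords[:4], broken.coords[:4])
        assert np.array_equal(closed.coords[5:], broken.coords[5:])
        # within residue 4, only atoms distal to the first pivot move
        assert np.array_equal(closed.coords[4, :2], broken.coords[4, :2])


class TestReplaceElement:
    def test_idempotent_replacement(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        node = 3  # hairpin loop
        out = replace_element(native, node, native.fragments[node])
        assert np.allclose(out.coords, native.coords, atol=1e-9)

    def test_leaf_replacement_is_local(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        loop_node = next(i for i, e in enumerate(tree.nodes)
                         if e.kind == "hairpin_loop")
        frag = lib.query_element(tree.node(loop_node),
                                 tree.secondary.sequence)[2]
        out = replace_element(native, loop_node, frag)
        outside = tree.node(loop_node).residues()
        mask = np.ones(native.n_residues, bool)
        mask[outside] = False
        assert np.array_equal(out.coords[mask], native.coords[mask])

    def test_rotated_root_moves_everything_rigidly(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        root_frag = native.fragments[tree.root]
        rot = geo.rotation_about_axis(np.array([1.0, 1, 0]), 0.8)
        t = np.array([3.0, -2.0, 5.0])
        import dataclasses
        moved = dataclasses.replace(
            root_frag,
            coords=root_frag.coords @ rot.T + t,
            entry_frame=root_frag.entry_frame @ rot.T + t,
            exit_frames=[e @ rot.T + t for e in root_frag.exit_frames])
        out = replace_element(native, tree.root, moved)
        # whole model follows rigidly: element-internal RMSD vs itself is 0
        for node in range(len(tree.nodes)):
            res = tree.node(node).residues()
            before = native.coords[res].reshape(-1, 3)
            after = out.coords[res].reshape(-1, 3)
            assert geo.superposed_rmsd(before, after) < 1e-6

    def test_subtree_follows_decoy_replacement(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        inner_helix = 1
        frag = lib.query_element(tree.node(inner_helix),
                                 tree.secondary.sequence)[3]
        out = replace_element(native, inner_helix, frag)
        # the hairpin child keeps its internal geometry apart from the
        # closure adjustment of its single boundary residue
        loop_node = next(i for i, e in enumerate(tree.nodes)
                         if e.kind == "hairpin_loop")
        res = tree.node(loop_node).residues()
        before = native.coords[res].reshape(-1, 3)
        after = out.coords[res].reshape(-1, 3)
        assert geo.superposed_rmsd(before, after) < 1.0

    def test_key_mismatch_rejected(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        helix_frag = native.fragments[0]
        loop_node = next(i for i, e in enumerate(tree.nodes)
                         if e.kind == "hairpin_loop")
        with pytest.raises(ValueError, match="key"):
            replace_element(native, loop_node, helix_frag)


class TestReplaceStrand:
    def test_identical_strand_is_noop(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        node = next(i for i, e in enumerate(tree.nodes)
                    if e.kind == "internal_loop")
        elem = tree.node(node)
        # strand fragment cut from the currently placed element fragment
        # (fragment coordinates are already in the element's local frame)
        placed = native.fragments[node]
        sl = placed.strand_slices()[0]
        frag = ideal_strand(elem.sequences(tree.secondary.sequence)[0])
        frag.coords[:] = placed.coords[sl]
        frag.entry_frame[:] = placed.coords[sl.start, 0:3]
        out = replace_strand(native, node, 0, frag)
        assert np.allclose(out.coords, native.coords, atol=1e-9)

    def test_translated_strand_shows_gap(self, two_helix_system):
        from rnasaxs.scoring import contiguity
        tree, native, lib, _ = two_helix_system
        node = next(i for i, e in enumerate(tree.nodes)
                    if e.kind == "internal_loop")
        elem = tree.node(node)
        seq = elem.sequences(tree.secondary.sequence)[0]
        base = ideal_strand(seq)
        shifted = ideal_strand(seq)
        shifted.coords[:] = base.coords + np.array([0.0, 0.0, 4.0])
        out_base = replace_strand(native, node, 0, base)
        out_shift = replace_strand(native, node, 0, shifted)
        assert contiguity(out_shift) > contiguity(out_base)

    def test_other_strands_untouched(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        node = next(i for i, e in enumerate(tree.nodes)
                    if e.kind == "internal_loop")
        elem = tree.node(node)
        frag = ideal_strand(elem.sequences(tree.secondary.sequence)[0])
        out = replace_strand(native, node, 0, frag)
        s, e = elem.strands[1]
        assert np.array_equal(out.coords[s:e + 1], native.coords[s:e + 1])
        s0, e0 = elem.strands[0]
        mask = np.ones(native.n_residues, bool)
        mask[s0:e0 + 1] = False
        assert np.array_equal(out.coords[mask], native.coords[mask])

    def test_strand_length_mismatch_rejected(self, two_helix_system):
        tree, native, lib, _ = two_helix_system
        node = next(i for i, e in enumerate(tree.nodes)
                    if e.kind == "internal_loop")
        with pytest.raises(ValueError, match="length"):
            replace_strand(native, node, 0, ideal_strand("GAAAC"))


class TestRandomInitialModel:
    def test_deterministic_per_seed(self, two_helix_system):
        tree, _, lib, _ = two_helix_system
        a, _ = random_initial_model(tree, lib, seed=11)
        b, _ = random_initial_model(tree, lib, seed=11)
        assert np.array_equal(a.coords, b.coords)

    def test_covers_every_residue(self, cloverleaf_tree):
        lib = make_fixture_library(
            tree_topologies(cloverleaf_tree, with_strands=True),
            copies=2, seed=3)
        model, _ = random_initial_model(cloverleaf_tree, lib, seed=0)
        assert model.n_residues == len(cloverleaf_tree.secondary.sequence)
        assert not np.any(np.isnan(model.coords))

    def test_missing_coverage_reported(self, two_helix_system):
        tree, _, _, _ = two_helix_system
        empty = make_fixture_library([("helix", (4, 4))], copies=1, seed=0)
        with pytest.raises(LibraryCoverageError, match="no fragments"):
            random_initial_model(tree, empty, seed=0)

    def test_variant_b_flagged_for_uncovered_elements(self, two_helix_system):
        tree, _, _, _ = two_helix_system
        keys = [k for k in tree_topologies(tree, with_strands=True)
                if k[0] != "internal_loop"]
        lib = make_fixture_library(keys, copies=2, seed=3)
        model, variant_b = random_initial_model(tree, lib, seed=5)
        assert [tree.node(v).kind for v in variant_b] == ["internal_loop"]
        assert not np.any(np.isnan(model.coords))
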