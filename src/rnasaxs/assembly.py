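"""Model assembly: grafting fragments onto the secondary-structure tree.

A full-chain model is assembled in pre-order from the tree root.  Each
fragment is placed by least-squares superposition of its entry boundary
frame onto the exit frame handed down by its parent, so replacing the
fragment at any node rigidly re-places exactly the subtree below that
node and nothing else.  After grafting, the three terminal backbone
dihedrals of the residue upstream of each element boundary are adjusted
(cyclic coordinate descent) to restore the O3'-P phosphodiester linkage.

Variant B: when the library holds no fragment for an element, the
element's ideal template provides the skeleton (child attachment
geometry) and its strands are sampled individually from the strand
library; backbone consistency of the strands is then judged by the
contiguity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .fragments import Fragment, FragmentLibrary, ideal_fragment_for
from .secondary import HELIX, ElementTree


class LibraryCoverageError(RuntimeError):
    """An element has neither element fragments nor full strand coverage."""


@dataclass
class RnaModel:
    """Reduced-atom RNA model: (n_residues, 8, 3) coordinates.

    Atom order per residue follows :data:`rnasaxs.geometry.ATOM_NAMES`.
    Models assembled from a tree also carry the residue-to-element map,
    per-node placement transforms and fragment provenance.
    """

    sequence: str
    coords: np.ndarray
    tree: ElementTree | None = None
    element_map: np.ndarray | None = None
    fragments: dict = field(default_factory=dict)  # node -> Fragment
    strand_fragments: dict = field(default_factory=dict)  # (node, strand) -> Fragment
    attach_frames: dict = field(default_factory=dict)  # node -> (3,3) or None
    placements: dict = field(default_factory=dict)  # node -> (R, t)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), geo.N_ATOMS, 3):
            raise ValueError("coords must be (n_residues, 8, 3)")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def copy(self) -> "RnaModel":
        return RnaModel(self.sequence, self.coords.copy(), self.tree,
                        None if self.element_map is None else self.element_map.copy(),
                        dict(self.fragments), dict(self.strand_fragments),
                        dict(self.attach_frames), dict(self.placements))

    def atom(self, residue: int, name: str) -> np.ndarray:
        return self.coords[residue, geo.ATOM_INDEX[name]]

    def flat_coords(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)

    def atoms_named(self, name: str) -> np.ndarray:
        """(n_residues, 3) coordinates of one named atom per residue."""
        return self.coords[:, geo.ATOM_INDEX[name], :]

    @property
    def provenance(self) -> dict:
        """Fragment source id placed at each tree node."""
        return {n: f.source_id for n, f in self.fragments.items()}


def place_fragment(fragment: Fragment, target_triple: np.ndarray | None):
    """Rigid placement of a fragment's atoms and exit frames.

    ``target_triple`` is where the fragment's entry frame must land;
    ``None`` keeps the fragment in its local frame (tree root).
    """
    if target_triple is None:
        rot, t = np.eye(3), np.zeros(3)
    else:
        rot, t = geo.superpose(fragment.entry_frame, target_triple)
    coords = geo.apply_transform(rot, t, fragment.coords)
    exits = [geo.apply_transform(rot, t, e) for e in fragment.exit_frames]
    return coords, exits, (rot, t)


def compose_variant_b(elem, sequence: str, strand_frags: dict) -> Fragment:
    """Element fragment built from an ideal skeleton plus per-strand fragments.

    The skeleton fixes the child attachment frames; each non-empty strand
    is replaced by the chosen strand fragment placed in the skeleton
    frame (strand fragments share the canonical local frame, so they are
    inserted without re-superposition and any induced backbone gaps are
    charged to the contiguity score).
    """
    skeleton = ideal_fragment_for(elem, sequence)
    coords = skeleton.coords.copy()
    for s, sl in enumerate(skeleton.strand_slices()):
        frag = strand_frags.get(s)
        if frag is None:
            continue
        if frag.strand_lengths[0] != sl.stop - sl.start:
            raise ValueError("strand fragment length mismatch")
        if sl.stop == sl.start:
            continue
        # express the strand fragment relative to the skeleton strand start
        rot, t = geo.superpose(frag.entry_frame, skeleton.coords[sl.start, 0:3])
        coords[sl] = geo.apply_transform(rot, t, frag.coords)
    sid = "+".join(["vB", skeleton.source_id]
                   + [f.source_id for f in strand_frags.values()])
    return Fragment(skeleton.kind, skeleton.strand_lengths, skeleton.sequences,
                    coords, skeleton.entry_frame, skeleton.exit_frames,
                    source_id=sid)


def _write_subtree(model: RnaModel, tree: ElementTree, node: int,
                   target, choice: dict) -> None:
    """Place ``node``'s fragment at ``target`` and recurse over its subtree."""
    elem = tree.node(node)
    frag = choice[node]
    coords, exits, placement = place_fragment(frag, target)
    residues = elem.residues()
    if len(residues) != frag.n_residues:
        raise ValueError(f"fragment {frag.source_id} does not cover element "
                         f"{elem.key}")
    if residues:
        model.coords[residues] = coords
    model.fragments[node] = frag
    model.attach_frames[node] = None if target is None else np.array(target)
    model.placements[node] = placement
    kids = tree.children.get(node, [])
    if len(kids) != len(exits):
        raise ValueError(f"element {elem.key} has {len(kids)} children but the "
                         f"fragment provides {len(exits)} exit frames")
    for child, exit_frame in zip(kids, exits):
        _write_subtree(model, tree, child, exit_frame, choice)


def _element_boundaries(model: RnaModel) -> list:
    """Residue indices i where residues i, i+1 belong to different elements."""
    em = model.element_map
    if em is None:
        return []
    return [i for i in range(model.n_residues - 1) if em[i] != em[i + 1]]


def assemble(tree: ElementTree, choice: dict, closure: bool = True) -> RnaModel:
    """Assemble a full model from one fragment choice per tree node."""
    seq = tree.secondary.sequence
    model = RnaModel(seq, np.full((len(seq), geo.N_ATOMS, 3), np.nan), tree)
    element_map = np.full(len(seq), -1, dtype=int)
    for i, elem in enumerate(tree.nodes):
        for r in elem.residues():
            element_map[r] = i
    model.element_map = element_map
    _write_subtree(model, tree, tree.root, None, choice)
    if closure:
        for i in _element_boundaries(model):
            close_backbone(model, (i, i + 1), in_place=True)
    return model


# ---------------------------------------------------------------------------
# backbone closure

_PIVOTS = (("O5'", "C5'", ("C4'", "C3'", "O3'", "C1'", "N")),
           ("C5'", "C4'", ("C3'", "O3'", "C1'", "N")),
           ("C4'", "C3'", ("O3'",)))


def _best_rotation_angle(point, axis_a, axis_b, target, bond):
    """Angle rotating ``point`` about axis (a,b) whose distance to
    ``target`` is closest to ``bond``; closed form on the rotation circle."""
    axis = axis_b - axis_a
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return 0.0
    u = axis / norm
    rel = point - axis_a
    par = (rel @ u) * u
    center = axis_a + par
    e1 = rel - par
    rad = np.linalg.norm(e1)
    if rad < 1e-9:
        return 0.0
    e1 /= rad
    e2 = np.cross(u, e1)
    w = target - center
    # |x(theta) - target|^2 = A - B cos(theta) - C sin(theta)
    a0 = rad ** 2 + w @ w
    b0 = 2 * rad * (w @ e1)
    c0 = 2 * rad * (w @ e2)
    amp = np.hypot(b0, c0)
    phase = np.arctan2(c0, b0)
    want = a0 - bond ** 2  # need B cos + C sin = want
    if amp < 1e-12:
        return 0.0
    if abs(want) <= amp:
        delta = np.arccos(np.clip(want / amp, -1.0, 1.0))
        cands = [phase + delta, phase - delta]
        # pick the smaller rotation
        cands = [((c + np.pi) % (2 * np.pi)) - np.pi for c in cands]
        return min(cands, key=abs)
    # unreachable: go to the extremum nearest the target distance
    theta = phase if want > 0 else phase + np.pi
    return ((theta + np.pi) % (2 * np.pi)) - np.pi


def close_backbone(model: RnaModel, junction, max_iter: int = 50,
                   tol: float = 0.05, in_place: bool = False):
    """Restore the O3'(i)-P(i+1) linkage across a graft.

    Cyclic coordinate descent over the three terminal backbone dihedrals
    (O5'-C5', C5'-C4', C4'-C3') of the upstream residue; only that
    residue's distal atoms move.  Returns ``(model, residual)`` where the
    residual is the remaining deviation of the linkage from its
    reference length.
    """
    i, j = junction
    if j != i + 1:
        raise ValueError("junction residues must be consecutive")
    out = model if in_place else model.copy()
    target = out.atom(j, "P")
    if np.any(np.isnan(target)) or np.any(np.isnan(out.coords[i])):
        return out, float("nan")
    bond = geo.O3_P_BOND

    def residual():
        return abs(np.linalg.norm(out.atom(i, "O3'") - target) - bond)

    prev = residual()
    for _ in range(max_iter):
        if prev < tol:
            break
        for a_name, b_name, moved in _PIVOTS:
            a = out.atom(i, a_name).copy()
            b = out.atom(i, b_name).copy()
            theta = _best_rotation_angle(out.atom(i, "O3'"), a, b, target, bond)
            if abs(theta) < 1e-12:
                continue
            rot = geo.rotation_about_axis(b - a, theta)
            idx = [geo.ATOM_INDEX[m] for m in moved]
            out.coords[i, idx] = (out.coords[i, idx] - b) @ rot.T + b
        cur = residual()
        if prev - cur < 1e-4:  # stalled: target unreachable from here
            prev = cur
            break
        prev = cur
    return out, prev


# ---------------------------------------------------------------------------
# replacements (annealing moves)

def replace_element(model: RnaModel, node: int, fragment: Fragment,
                    closure: bool = True) -> RnaModel:
    """Replace the fragment at a tree node; the subtree follows rigidly.

    Residues outside the node's subtree are untouched.  Backbone closure
    is applied at element boundaries whose upstream residue lies inside
    the replaced subtree.
    """
    tree = model.tree
    if tree is None:
        raise ValueError("model carries no element tree")
    elem = tree.node(node)
    if fragment.key != elem.key:
        raise ValueError(f"fragment key {fragment.key} != element key {elem.key}")
    out = model.copy()
    choice = dict(model.fragments)
    choice[node] = fragment
    _write_subtree(out, tree, node, model.attach_frames.get(node), choice)
    if closure:
        inside = set(tree.subtree_residues(node))
        for i in _element_boundaries(out):
            if i in inside:
                close_backbone(out, (i, i + 1), in_place=True)
    return out


def replace_strand(model: RnaModel, node: int, strand_index: int,
                   strand_fragment: Fragment) -> RnaModel:
    """Variant-B move: replace one strand of an element.

    The strand fragment is placed using the element's stored placement
    transform (strand fragments share the canonical local frame), so
    backbone gaps it introduces are visible to the contiguity score.
    Other strands and all other elements are untouched.
    """
    tree = model.tree
    if tree is None:
        raise ValueError("model carries no element tree")
    elem = tree.node(node)
    lengths = elem.strand_lengths
    if strand_index >= len(lengths):
        raise ValueError("strand index out of range")
    if strand_fragment.strand_lengths[0] != lengths[strand_index]:
        raise ValueError(f"strand length {strand_fragment.strand_lengths[0]} != "
                         f"{lengths[strand_index]}")
    if node not in model.placements:
        raise ValueError("element has no recorded placement")
    out = model.copy()
    rot, t = model.placements[node]
    s, e = elem.strands[strand_index]
    if e >= s:
        out.coords[s:e + 1] = geo.apply_transform(rot, t, strand_fragment.coords)
    out.strand_fragments[(node, strand_index)] = strand_fragment
    return out


def random_initial_model(tree: ElementTree, lib: FragmentLibrary, seed: int,
                         closure: bool = True):
    """Random full-length starting model, reproducible per seed.

    Returns ``(model, variant_b_nodes)`` where ``variant_b_nodes`` lists
    tree nodes lacking element fragments (sampled strand-wise instead).
    """
    rng = np.random.default_rng(seed)
    seq = tree.secondary.sequence
    choice = {}
    variant_b = []
    for node, elem in enumerate(tree.nodes):
        hits = lib.query_element(elem, seq)
        if hits:
            choice[node] = hits[rng.integers(len(hits))]
            continue
        variant_b.append(node)
        strand_frags = {}
        for s, length in enumerate(elem.strand_lengths):
            if length == 0:
                continue
            cands = lib.query_strand(length)
            if not cands:
                raise LibraryCoverageError(
                    f"no fragments for element key {elem.key} and no strand "
                    f"fragments of length {length}")
            strand_frags[s] = cands[rng.integers(len(cands))]
        choice[node] = compose_variant_b(elem, seq, strand_frags)
    model = assemble(tree, choice, closure=closure)
    return model, variant_b
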