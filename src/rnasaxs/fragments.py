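"""Fragment library: coordinate fragments keyed by element topology.

A fragment holds the reduced-atom coordinates for one secondary-structure
element (or, for variant-B sampling, a single strand), expressed in a
local frame where the attachment to the parent helix is canonical.  Each
fragment carries boundary frames: an *entry* triple (the P, O5', C5'
positions of the first residue continuing the parent strand) and one
*exit* triple per child helix attachment giving the pose where the
child's entry triple must be grafted.

Fragments of real structures would normally be harvested from the PDB;
this package generates idealized geometries internally (A-form duplexes,
arc-capped hairpin loops, coaxially stacked internal loops, fanned
junction hubs) and a seeded fixture generator that perturbs them, which
stands in for a curated fragment database while using the same library
interface and on-disk format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as geo
from .secondary import (BULGE, EXTERNAL, HAIRPIN, HELIX, INTERNAL, JUNCTION,
                        Element, ElementTree)

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

ENTRY_TRIPLE = geo.template_residue()[0:3]  # canonical (P, O5', C5') at level 0


def _advance_points(points: np.ndarray, n: float) -> np.ndarray:
    rot, t = geo.helix_level(n)
    return geo.apply_transform(rot, t, points)


@dataclass
class Fragment:
    """Coordinates of one element (or strand) in its local grafting frame."""

    kind: str
    strand_lengths: tuple
    sequences: tuple
    coords: np.ndarray  # (n_residues, 8, 3), residues strand-by-strand in chain order
    entry_frame: np.ndarray  # (3, 3)
    exit_frames: list  # of (3, 3) arrays, one per child attachment
    source_id: str = ""

    def __post_init__(self):
        n_res = sum(self.strand_lengths)
        if self.coords.shape != (n_res, geo.N_ATOMS, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"strand lengths {self.strand_lengths}")

    @property
    def key(self) -> tuple:
        return (self.kind, self.strand_lengths)

    @property
    def n_residues(self) -> int:
        return sum(self.strand_lengths)

    def strand_slices(self) -> list:
        out, start = [], 0
        for length in self.strand_lengths:
            out.append(slice(start, start + length))
            start += length
        return out

    def boundary_frame(self, strand: int, end: str) -> np.ndarray:
        """3-atom grafting frame at a strand terminus.

        ``end='5'`` returns (P, O5', C5') of the strand's first residue;
        ``end='3'`` returns (C4', C3', O3') of its last residue.
        """
        sl = self.strand_slices()[strand]
        if sl.start == sl.stop:
            raise ValueError("empty strand has no boundary frame")
        if end == "5":
            return self.coords[sl.start, 0:3].copy()
        if end == "3":
            return self.coords[sl.stop - 1, 3:6].copy()
        raise ValueError("end must be '5' or '3'")


def sequence_match(fragment_seq, target_seq) -> float:
    """Fragment/target sequence consistency score in [0, 1].

    Defined as the mean over strands of the fraction of identical
    nucleotides; 1 for identity, 0 when no position matches.
    """
    if isinstance(fragment_seq, str):
        fragment_seq, target_seq = (fragment_seq,), (target_seq,)
    if len(fragment_seq) != len(target_seq):
        raise ValueError("strand count mismatch")
    fractions = []
    for f, t in zip(fragment_seq, target_seq):
        if len(f) != len(t):
            raise ValueError(f"strand length mismatch: {len(f)} vs {len(t)}")
        if len(f) == 0:
            continue
        fractions.append(sum(a == b for a, b in zip(f.upper(), t.upper())) / len(f))
    return float(np.mean(fractions)) if fractions else 1.0


# ---------------------------------------------------------------------------
# ideal geometry builders

def _residues_along_path(points: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Place template residues along a polyline of P-atom anchor points.

    ``points`` has one more vertex than residues; residue k's P sits at
    ``points[k]`` with its O3' aimed at ``points[k+1]``.  ``normal``
    fixes the roll angle around the local chain direction.
    """
    templ = geo.template_residue()
    p_t = templ[0]
    x_m = templ[5] - p_t  # P -> O3'
    x_m = x_m / np.linalg.norm(x_m)
    v = templ[6] - p_t  # P -> C1'
    y_m = v - (v @ x_m) * x_m
    y_m /= np.linalg.norm(y_m)
    z_m = np.cross(x_m, y_m)
    frame_m = np.stack([x_m, y_m, z_m])
    n_res = len(points) - 1
    out = np.empty((n_res, geo.N_ATOMS, 3))
    for k in range(n_res):
        x = points[k + 1] - points[k]
        nx = np.linalg.norm(x)
        x = x / nx if nx > 1e-9 else np.array([0.0, 0.0, 1.0])
        y = normal - (normal @ x) * x
        ny = np.linalg.norm(y)
        if ny < 1e-9:
            y = np.cross(np.array([1.0, 0.0, 0.0]), x)
            ny = np.linalg.norm(y)
        y /= ny
        z = np.cross(x, y)
        rot = np.stack([x, y, z]).T @ frame_m
        # helical roll per residue staggers consecutive residues so their
        # side atoms do not overlap on straightened paths
        roll = geo.rotation_about_axis(x_m, k * geo.TWIST)
        out[k] = (templ - p_t) @ roll.T @ rot.T + points[k]
    return out


def _strand_a(levels) -> np.ndarray:
    """Template-side residues at the given (possibly fractional) helix levels."""
    templ = geo.template_residue()
    return np.stack([_advance_points(templ, lv) for lv in levels]) \
        if len(levels) else np.empty((0, geo.N_ATOMS, 3))


def _strand_b(levels) -> np.ndarray:
    """Paired-strand residues at the given helix levels (chain order as given)."""
    templ = geo.paired_residue()
    return np.stack([_advance_points(templ, lv) for lv in levels]) \
        if len(levels) else np.empty((0, geo.N_ATOMS, 3))


def _return_anchor(level: float) -> np.ndarray:
    """P position where a returning (paired-side) chain continues at a level."""
    return _advance_points(geo.paired_residue()[0][None, :], level)[0]


def ideal_helix(seq5: str, seq3: str) -> Fragment:
    """Ideal A-form duplex fragment for two antiparallel strands.

    ``seq5`` is the 5' strand in chain order, ``seq3`` the complementary
    strand in its own 5'->3' order (so ``seq3`` pairs with ``seq5``
    reversed).  Non-complementary inputs trigger a warning, but the
    geometry is built regardless: low-resolution helices are treated as
    near-ideal whatever the sequence.
    """
    if len(seq5) != len(seq3):
        raise ValueError("helix strands must have equal length")
    n = len(seq5)
    if n < 1:
        raise ValueError("helix needs at least one base pair")
    for a, b in zip(seq5.upper(), reversed(seq3.upper())):
        if (a, b) not in WC:
            warnings.warn(f"non-complementary base pair {a}-{b} in helix",
                          stacklevel=2)
            break
    strand_a = _strand_a(range(n))
    strand_b = _strand_b(range(n - 1, -1, -1))
    coords = np.concatenate([strand_a, strand_b])
    exit_frame = _advance_points(ENTRY_TRIPLE, n)
    return Fragment(HELIX, (n, n), (seq5.upper(), seq3.upper()), coords,
                    ENTRY_TRIPLE.copy(), [exit_frame], source_id=f"ideal-helix-{n}")


def ideal_hairpin(seq: str) -> Fragment:
    """Hairpin loop capping a helix: residues on an arc over the helix end."""
    n = len(seq)
    p0 = geo.template_residue()[0]
    pe = _return_anchor(-1.0)
    mid = 0.5 * (p0 + pe)
    # apex height such that the arc length gives ~5.9 A between residues,
    # keeping the rigid pseudo-residues from overlapping on short loops
    chord = np.linalg.norm(pe - p0)
    height = max(6.0, np.sqrt(max(0.0, (2.95 * (n + 1)) ** 2 - (chord / 2) ** 2)))
    apex = mid + np.array([0.0, 0.0, height])
    # quadratic Bezier from p0 through apex to pe, sampled at equal arc length
    tt = np.linspace(0.0, 1.0, 256)
    dense = ((1 - tt)[:, None] ** 2 * p0 + 2 * ((1 - tt) * tt)[:, None] * apex
             + (tt[:, None] ** 2) * pe)
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    targets = np.linspace(0.0, arc[-1], n + 1)
    points = np.stack([np.interp(targets, arc, dense[:, k]) for k in range(3)],
                      axis=1)
    chord = pe - p0
    normal = np.cross(chord, apex - p0)
    nn = np.linalg.norm(normal)
    normal = normal / nn if nn > 1e-9 else np.array([1.0, 0.0, 0.0])
    coords = _residues_along_path(points, normal)
    return Fragment(HAIRPIN, (n,), (seq.upper(),), coords, ENTRY_TRIPLE.copy(),
                    [], source_id=f"ideal-hairpin-{n}")


def ideal_internal(seq_a: str, seq_b: str) -> Fragment:
    """Internal loop or bulge continuing the helix axis coaxially.

    Unpaired residues are kept on (fractionally spaced) helical paths so
    a symmetric internal loop stacks seamlessly; the shorter side of an
    asymmetric loop or bulge is stretched across the spanned levels.
    """
    m, n = len(seq_a), len(seq_b)
    span = max(m, n, 1)
    levels_a = np.linspace(0, span - 1, m) if m else []
    levels_b = np.linspace(span - 1, 0, n) if n else []
    coords = np.concatenate([_strand_a(levels_a), _strand_b(levels_b)])
    exit_frame = _advance_points(ENTRY_TRIPLE, span)
    kind = BULGE if min(m, n) == 0 else INTERNAL
    return Fragment(kind, (m, n), (seq_a.upper(), seq_b.upper()), coords,
                    ENTRY_TRIPLE.copy(), [exit_frame],
                    source_id=f"ideal-{kind}-{m}x{n}")


def _fan_poses(n_children: int, spread_deg: float = 55.0, base_level: float = 2.0):
    """Rigid poses (R, t) fanning child helices out of a junction hub.

    Children leave the hub on a cone: each is tilted by ``spread_deg``
    from the parent axis with evenly spread azimuths, which keeps the
    ~19 A wide A-form branches from interpenetrating near the hub.
    """
    if n_children == 1:
        dirs = [(0.0, 0.0)]
    else:
        beta = np.deg2rad(spread_deg)
        dirs = [(beta, 2 * np.pi * c / n_children) for c in range(n_children)]
    pivot = np.array([0.0, 0.0, geo.RISE * base_level])
    # children additionally start a few A out along their own axis so the
    # branch cylinders clear each other at the hub
    offset = 0.0 if n_children == 1 else 8.0
    poses = []
    for beta, gamma in dirs:
        rot = (geo.rotation_about_axis(np.array([0.0, 0.0, 1.0]), gamma)
               @ geo.rotation_about_axis(np.array([0.0, 1.0, 0.0]), beta))
        t = pivot - rot @ pivot + rot @ np.array([0.0, 0.0, offset])
        poses.append((rot, t))
    return poses


def _segments_between(anchors_start, anchors_end, lengths, normal):
    """Straight-line unpaired segments between attachment anchor points."""
    residues = []
    for a, b, L in zip(anchors_start, anchors_end, lengths):
        if L == 0:
            residues.append(np.empty((0, geo.N_ATOMS, 3)))
            continue
        ts = np.linspace(0.0, 1.0, L + 2)[1:-1]
        pts = (1 - ts)[:, None] * a + ts[:, None] * b
        step = (b - a) / (L + 1)
        path = np.vstack([pts, pts[-1] + step])
        residues.append(_residues_along_path(path, normal))
    return residues


def ideal_junction(sequences: tuple, kind: str = JUNCTION,
                   spread_deg: float = 65.0) -> Fragment:
    """Multi-branch junction (or external loop) hub with fanned-out children.

    ``sequences`` holds the k+1 unpaired segments in chain order for k
    child helices; empty strings denote absent segments.  Child helix c
    is fanned in the x-z plane by an angle interpolated across
    ``+-spread_deg`` around the parent axis direction.
    """
    n_children = len(sequences) - 1
    if n_children < 1:
        raise ValueError("junction needs at least one child attachment")
    poses = _fan_poses(n_children, spread_deg)
    exit_frames = []
    child_entry_p = []
    child_return_p = []
    base = _advance_points(ENTRY_TRIPLE, 1.0)
    ret = _return_anchor(0.0)
    for rot, t in poses:
        exit_frames.append(geo.apply_transform(rot, t, base))
        child_entry_p.append(geo.apply_transform(rot, t, base[0][None])[0])
        child_return_p.append(geo.apply_transform(rot, t, ret[None])[0])
    # chain anchors: seg 0 runs from the parent strand continuation to
    # child 1's entry; seg c from child c's return to child c+1's entry;
    # the last seg from child k's return to the parent's returning strand.
    starts = [geo.template_residue()[0]] + child_return_p
    ends = child_entry_p + [_return_anchor(-1.0)]
    normal = np.array([0.0, 1.0, 0.0])
    segs = _segments_between(starts, ends, [len(s) for s in sequences], normal)
    coords = np.concatenate(segs) if segs else np.empty((0, geo.N_ATOMS, 3))
    lengths = tuple(len(s) for s in sequences)
    return Fragment(kind, lengths, tuple(s.upper() for s in sequences), coords,
                    ENTRY_TRIPLE.copy(), exit_frames,
                    source_id=f"ideal-{kind}-{'x'.join(map(str, lengths))}")


def ideal_external(sequences: tuple) -> Fragment:
    """External element: root helices plus 5'/3' single-stranded tails.

    With a single root helix the helix keeps the canonical pose and the
    tails continue the two strand paths below the helix (stacked
    single-stranded tails); with several root helices they are fanned
    like a junction.
    """
    n_children = len(sequences) - 1
    if n_children >= 2:
        return ideal_junction(sequences, kind=EXTERNAL)
    if n_children == 1:
        len5, len3 = len(sequences[0]), len(sequences[1])
        exit_frames = [ENTRY_TRIPLE.copy()]
        tail5 = _strand_a(np.arange(-len5, 0)) if len5 else np.empty((0, geo.N_ATOMS, 3))
        tail3 = _strand_b(-1.0 - np.arange(len3)) if len3 else np.empty((0, geo.N_ATOMS, 3))
        coords = np.concatenate([tail5, tail3])
        return Fragment(EXTERNAL, (len5, len3),
                        tuple(s.upper() for s in sequences), coords,
                        ENTRY_TRIPLE.copy(), exit_frames,
                        source_id=f"ideal-external-{len5}x{len3}")
    # no pairs at all: a free single strand along the template path
    n = len(sequences[0])
    coords = _strand_a(range(n))
    return Fragment(EXTERNAL, (n,), (sequences[0].upper(),), coords,
                    ENTRY_TRIPLE.copy(), [], source_id=f"ideal-external-ss-{n}")


def ideal_strand(seq: str) -> Fragment:
    """Single-strand fragment (variant-B sampling) along the helical path."""
    n = len(seq)
    if n < 1:
        raise ValueError("strand fragment needs at least one residue")
    coords = _strand_a(range(n))
    return Fragment("strand", (n,), (seq.upper(),), coords, ENTRY_TRIPLE.copy(),
                    [], source_id=f"ideal-strand-{n}")


def ideal_fragment_for(elem: Element, sequence: str) -> Fragment:
    """Ideal fragment matching an element of a decomposed structure."""
    seqs = elem.sequences(sequence)
    if elem.kind == HELIX:
        return ideal_helix(seqs[0], seqs[1])
    if elem.kind == HAIRPIN:
        return ideal_hairpin(seqs[0])
    if elem.kind in (INTERNAL, BULGE):
        return ideal_internal(seqs[0], seqs[1])
    if elem.kind == JUNCTION:
        return ideal_junction(seqs)
    if elem.kind == EXTERNAL:
        return ideal_external(seqs)
    raise ValueError(f"unknown element kind {elem.kind}")


# ---------------------------------------------------------------------------
# library

@dataclass
class FragmentLibrary:
    """Fragments indexed by (kind, strand lengths) and by strand length."""

    index: dict = field(default_factory=dict)
    strand_index: dict = field(default_factory=dict)

    def add(self, fragment: Fragment) -> None:
        if fragment.kind == "strand":
            self.strand_index.setdefault(fragment.strand_lengths[0], []).append(fragment)
        else:
            self.index.setdefault(fragment.key, []).append(fragment)

    def get(self, key: tuple) -> list:
        return list(self.index.get(tuple(key), []))

    def get_strands(self, length: int) -> list:
        return list(self.strand_index.get(length, []))

    def __len__(self):
        return sum(len(v) for v in self.index.values()) + \
            sum(len(v) for v in self.strand_index.values())

    def query_element(self, elem: Element, sequence: str | None = None) -> list:
        """Fragments matching an element's key, best sequence match first.

        An empty result is the signal to fall back to strand-wise
        (variant B) sampling for this element.
        """
        hits = self.get(elem.key)
        if not hits and elem.kind == HELIX:
            # reverse-complement lookup: strand order swap doubles coverage
            swapped = (elem.kind, elem.strand_lengths[::-1])
            hits = self.get(swapped)
        if sequence is None:
            return sorted(hits, key=lambda f: f.source_id)
        target = elem.sequences(sequence)
        return sorted(hits, key=lambda f: (-sequence_match(f.sequences, target),
                                           f.source_id))

    def query_strand(self, length: int) -> list:
        return sorted(self.get_strands(length), key=lambda f: f.source_id)

    # -- serialization ------------------------------------------------------

    def save(self, directory) -> None:
        """Write the library as PDB fragment files plus a JSON index."""
        from .pdbio import write_fragment_pdb
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        counter = 0
        for frags in list(self.index.values()) + list(self.strand_index.values()):
            for f in frags:
                fname = f"frag{counter:05d}.pdb"
                write_fragment_pdb(directory / fname, f)
                entries.append({
                    "file": fname, "kind": f.kind,
                    "strand_lengths": list(f.strand_lengths),
                    "sequences": list(f.sequences),
                    "source_id": f.source_id,
                    "entry_frame": f.entry_frame.tolist(),
                    "exit_frames": [e.tolist() for e in f.exit_frames],
                })
                counter += 1
        (directory / "index.json").write_text(json.dumps(entries, indent=1))

    @classmethod
    def load(cls, directory) -> "FragmentLibrary":
        from .pdbio import read_fragment_pdb
        directory = Path(directory)
        entries = json.loads((directory / "index.json").read_text())
        lib = cls()
        for e in entries:
            coords = read_fragment_pdb(directory / e["file"])
            frag = Fragment(e["kind"], tuple(e["strand_lengths"]),
                            tuple(e["sequences"]), coords,
                            np.array(e["entry_frame"]),
                            [np.array(x) for x in e["exit_frames"]],
                            source_id=e["source_id"])
            lib.add(frag)
        return lib


# ---------------------------------------------------------------------------
# fixture generator

def _perturb(fragment: Fragment, rng: np.random.Generator, noise_sigma: float,
             max_bend: float, source_id: str) -> Fragment:
    """Randomized copy: coordinate noise plus, for branching elements, a
    random bend of everything above the element's mid-height (including
    the exit frames), emulating the conformational spread of a database."""
    coords = fragment.coords.copy()
    exit_frames = [e.copy() for e in fragment.exit_frames]
    if fragment.kind in (INTERNAL, BULGE, JUNCTION, EXTERNAL) and max_bend > 0 \
            and fragment.exit_frames:
        zs = np.concatenate([coords.reshape(-1, 3)[:, 2] if coords.size else
                             np.array([0.0])] +
                            [e[:, 2] for e in exit_frames])
        z_mid = 0.5 * (zs.min() + zs.max())
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, max_bend)
        rot = geo.rotation_about_axis(axis, angle)
        pivot = np.array([0.0, 0.0, z_mid])
        moved = coords.reshape(-1, 3)
        mask = moved[:, 2] > z_mid
        moved[mask] = (moved[mask] - pivot) @ rot.T + pivot
        coords = moved.reshape(coords.shape)
        exit_frames = [(e - pivot) @ rot.T + pivot for e in exit_frames]
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    return Fragment(fragment.kind, fragment.strand_lengths, fragment.sequences,
                    coords, fragment.entry_frame.copy(), exit_frames,
                    source_id=source_id)


def _random_sequences(kind: str, lengths: tuple, rng: np.random.Generator) -> tuple:
    bases = np.array(list("AUGC"))
    if kind == HELIX:
        s5 = "".join(rng.choice(bases, size=lengths[0]))
        s3 = "".join(COMPLEMENT[b] for b in reversed(s5))
        return (s5, s3)
    return tuple("".join(rng.choice(bases, size=L)) for L in lengths)


def _ideal_for_key(kind: str, lengths: tuple, sequences: tuple) -> Fragment:
    if kind == HELIX:
        return ideal_helix(sequences[0], sequences[1])
    if kind == HAIRPIN:
        return ideal_hairpin(sequences[0])
    if kind in (INTERNAL, BULGE):
        return ideal_internal(sequences[0], sequences[1])
    if kind == JUNCTION:
        return ideal_junction(sequences)
    if kind == EXTERNAL:
        return ideal_external(sequences)
    if kind == "strand":
        return ideal_strand(sequences[0])
    raise ValueError(f"unknown fragment kind {kind}")


def make_fixture_library(topologies, copies: int, seed: int,
                         noise_sigma: float = 0.3,
                         max_bend_deg: float = 60.0,
                         include_ideal: bool = True,
                         sequences: dict | None = None) -> FragmentLibrary:
    """Reproducible fixture library of perturbed ideal fragments.

    Parameters
    ----------
    topologies : iterable of (kind, strand_lengths) keys to populate.
    copies : fragments per key; with ``include_ideal`` the first copy of
        each key is the unperturbed ideal template.
    seed : seed of the single generator driving all randomness.
    noise_sigma : Gaussian coordinate noise [A] applied to perturbed copies.
    max_bend_deg : maximum random inter-helix bend for branching elements.
    sequences : optional map key -> tuple of strand sequences used for the
        ideal copy; random sequences are drawn otherwise.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(seed)
    max_bend = np.deg2rad(max_bend_deg)
    lib = FragmentLibrary()
    for kind, lengths in topologies:
        lengths = tuple(lengths)
        for c in range(copies):
            if sequences is not None and (kind, lengths) in sequences:
                seqs = tuple(sequences[(kind, lengths)])
            else:
                seqs = _random_sequences(kind, lengths, rng)
            ideal = _ideal_for_key(kind, lengths, seqs)
            sid = f"fix-{kind}-{'x'.join(map(str, lengths))}-{c:03d}"
            if c == 0 and include_ideal:
                frag = Fragment(ideal.kind, ideal.strand_lengths, ideal.sequences,
                                ideal.coords, ideal.entry_frame,
                                ideal.exit_frames, source_id=sid)
            else:
                frag = _perturb(ideal, rng, noise_sigma, max_bend, sid)
            lib.add(frag)
    return lib


def tree_topologies(tree: ElementTree, with_strands: bool = False) -> list:
    """Library keys covering every element (and optionally strand) of a tree."""
    keys = []
    seen = set()
    for elem in tree.nodes:
        if elem.key not in seen:
            seen.add(elem.key)
            keys.append(elem.key)
        if with_strands:
            for L in elem.strand_lengths:
                if L > 0 and ("strand", (L,)) not in seen:
                    seen.add(("strand", (L,)))
                    keys.append(("strand", (L,)))
    return keys
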