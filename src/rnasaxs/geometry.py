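"""Rigid-body geometry primitives and the coarse A-form helix template.

The package models RNA at low resolution with 8 pseudo-atoms per
nucleotide: the backbone atoms P, O5', C5', C4', C3', O3', the sugar
anchor C1', and a single base pseudo-atom placed at the glycosidic
nitrogen (N9 for purines, N1 for pyrimidines).

The A-form duplex is generated from a single-residue template expressed
in a helical frame (twist 32.7 deg per residue, rise 2.81 A per residue,
right-handed, axis = +z).  Template coordinates were obtained once by
least-squares against standard backbone bond lengths, the 5.9 A
consecutive P-P spacing, and Watson-Crick pairing geometry of the
dyad-flipped partner strand (glycosidic N-N 8.9 A, C1'-C1' 10.4 A).
"""

from __future__ import annotations

import numpy as np

TWIST = np.deg2rad(32.7)  # helical twist per residue [rad]
RISE = 2.81  # helical rise per residue [A]

#: canonical atom order of the reduced nucleotide representation
ATOM_NAMES = ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'", "N")
N_ATOMS = len(ATOM_NAMES)
ATOM_INDEX = {name: i for i, name in enumerate(ATOM_NAMES)}

#: indices of backbone atoms (used by the clash score's x5 rule)
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

#: reference O3'(i) -> P(i+1) phosphodiester bond length [A]
O3_P_BOND = 1.607

# Single-residue template, strand 1, level 0 (see module docstring).
_TEMPLATE = np.array([
    [9.211582, -0.000000, 0.000000],   # P
    [8.845239, 0.214794, 1.535352],    # O5'
    [8.098079, 0.455403, 2.742605],    # C5'
    [8.346358, 1.879942, 2.307696],    # C4'
    [9.005298, 3.187651, 2.729919],    # C3'
    [8.509717, 4.064980, 1.725119],    # O3'
    [8.249713, 2.186699, -0.000000],   # C1'
    [6.883945, 1.643028, -0.000000],   # N
])

#: rotation about z applied after the dyad flip to build the paired strand
PAIR_ALPHA = 1.8285262233687045


def template_residue() -> np.ndarray:
    """Copy of the (8, 3) template residue at helix level 0, strand 1."""
    return _TEMPLATE.copy()


def helix_level(n: float) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) advancing coordinates by ``n`` helix levels."""
    c, s = np.cos(n * TWIST), np.sin(n * TWIST)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, np.array([0.0, 0.0, n * RISE])


def paired_residue() -> np.ndarray:
    """Template residue of the complementary strand at level 0.

    Obtained by the duplex dyad operation: 180 deg rotation about x
    followed by rotation about z by ``PAIR_ALPHA``.  The partner strand
    runs antiparallel (its chain direction is towards decreasing level).
    """
    flipped = _TEMPLATE * np.array([1.0, -1.0, -1.0])
    c, s = np.cos(PAIR_ALPHA), np.sin(PAIR_ALPHA)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return flipped @ rot.T


def apply_transform(rot: np.ndarray, t: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply rigid transform x -> R x + t to an (..., 3) coordinate array."""
    return coords @ rot.T + t


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through origin."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / norm
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


class DegenerateFrameError(ValueError):
    """Raised when a boundary frame's three atoms are (nearly) collinear."""


def _check_triple(triple: np.ndarray, tol: float = 1e-6) -> None:
    v1 = triple[1] - triple[0]
    v2 = triple[2] - triple[0]
    if np.linalg.norm(np.cross(v1, v2)) < tol:
        raise DegenerateFrameError("boundary atoms are collinear")


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of point sets (Kabsch).

    Returns the proper rotation ``R`` (det = +1) and translation ``t``
    minimizing the RMSD of ``R @ mobile + t`` against ``target``.  For
    the three-atom boundary frames used in grafting, collinear triples
    raise :class:`DegenerateFrameError`.

    Parameters
    ----------
    mobile, target : (n, 3) arrays with n >= 3.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("superpose needs matched point sets of >= 3 points")
    if mobile.shape[0] == 3:
        _check_triple(mobile)
        _check_triple(target)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ct - rot @ cm
    return rot, t


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Minimum RMSD between two point sets under rigid superposition."""
    rot, t = superpose(mobile, target)
    moved = apply_transform(rot, t, np.asarray(mobile, dtype=float))
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
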