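"""Composite scoring: fragment sequence match, geometry, and SAXS fit.

The total score (lower is better) is the weighted sum

    E = w_m * E_m + w_g * E_g + w_x * E_x

where E_m penalizes sequence mismatch of the placed fragments, E_g is a
geometric quality term combining backbone contiguity (sum of excess
O3'-P link lengths) with a steric clash count in which clashes between
phosphorus and backbone atoms are multiplied by 5, and E_x is the
reduced chi-square fit to the experimental SAXS curve, which dominates
the default weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as geo
from .fragments import sequence_match
from .saxs import ScatteringCurve, chi2_fit, debye_intensity

#: non-bonded contact distance below which two atoms count as clashing [A]
CLASH_CUTOFF = 2.5


@dataclass
class ScoreWeights:
    """Weights of the composite score; all configuration.

    The SAXS term dominates by default; the published weighting was
    obtained by regression against model quality, but only its
    SAXS-dominated character is reproducible, so the geometric and
    sequence terms default to small stabilizing values.
    """

    w_m: float = 0.1
    w_g: float = 0.1
    w_x: float = 1.0
    contiguity_weight: float = 1.0
    clash_weight: float = 1.0
    p_backbone_multiplier: float = 5.0

    def __post_init__(self):
        if min(self.w_m, self.w_g, self.w_x, self.contiguity_weight,
               self.clash_weight) < 0:
            raise ValueError("weights must be >= 0")


@dataclass
class ScoreBreakdown:
    e_m: float
    e_g: float
    e_x: float
    contiguity: float
    clashes: float
    total: float


def contiguity(model) -> float:
    """Sum of excess backbone O3'(i)-P(i+1) link lengths [A].

    Zero for a perfectly bonded chain; each link contributes
    max(0, length - reference) with the ideal phosphodiester reference.
    """
    o3 = model.atoms_named("O3'")[:-1]
    p = model.atoms_named("P")[1:]
    d = np.linalg.norm(o3 - p, axis=1)
    d = d[~np.isnan(d)]
    return float(np.sum(np.maximum(0.0, d - geo.O3_P_BOND)))


def clash_score(model, cutoff: float = CLASH_CUTOFF,
                p_backbone_multiplier: float = 5.0) -> float:
    """Weighted count of clashing non-bonded atom pairs.

    Atom pairs of residues at least two apart in sequence closer than
    ``cutoff`` are counted; pairs joining a phosphorus to a backbone atom
    are multiplied by ``p_backbone_multiplier`` to weight backbone
    integrity more heavily.
    """
    coords = model.flat_coords()
    n_res = model.n_residues
    res_idx = np.repeat(np.arange(n_res), geo.N_ATOMS)
    atom_idx = np.tile(np.arange(geo.N_ATOMS), n_res)
    ok = ~np.any(np.isnan(coords), axis=1)
    coords, res_idx, atom_idx = coords[ok], res_idx[ok], atom_idx[ok]
    if len(coords) < 2:
        return 0.0
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    sep = np.abs(res_idx[pairs[:, 0]] - res_idx[pairs[:, 1]])
    pairs = pairs[sep >= 2]
    if len(pairs) == 0:
        return 0.0
    backbone = np.array([name in geo.BACKBONE_ATOMS for name in geo.ATOM_NAMES])
    is_p = atom_idx[pairs] == geo.ATOM_INDEX["P"]
    is_bb = backbone[atom_idx[pairs]]
    p_bb = (is_p[:, 0] & is_bb[:, 1]) | (is_p[:, 1] & is_bb[:, 0])
    return float(np.sum(np.where(p_bb, p_backbone_multiplier, 1.0)))


def fragment_match_penalty(model) -> float:
    """E_m term: total sequence mismatch of the fragments placed on the tree.

    Each element contributes 1 - (sequence match of its fragment against
    the modeled sequence); a model built entirely from identical-sequence
    fragments scores 0.
    """
    if model.tree is None or not model.fragments:
        return 0.0
    total = 0.0
    for node, frag in model.fragments.items():
        target = model.tree.node(node).sequences(model.sequence)
        total += 1.0 - sequence_match(frag.sequences, target)
    return total


def total_score(model, exp_curve: ScatteringCurve | None,
                weights: ScoreWeights | None = None,
                debye_bin_width: float | None = None) -> ScoreBreakdown:
    """Composite score of a model; components are reported separately.

    ``exp_curve`` may be None, in which case the SAXS term is 0 (scored
    as if w_x were 0).
    """
    weights = weights or ScoreWeights()
    e_m = fragment_match_penalty(model) if weights.w_m > 0 else 0.0
    if weights.w_g > 0:
        cont = contiguity(model)
        clash = clash_score(model,
                            p_backbone_multiplier=weights.p_backbone_multiplier)
    else:
        cont = clash = 0.0
    e_g = weights.contiguity_weight * cont + weights.clash_weight * clash
    if exp_curve is not None and weights.w_x > 0:
        theor = debye_intensity(model, exp_curve.q, bin_width=debye_bin_width)
        e_x = chi2_fit(exp_curve, theor).chi2
    else:
        e_x = 0.0
    total = weights.w_m * e_m + weights.w_g * e_g + weights.w_x * e_x
    return ScoreBreakdown(e_m, e_g, e_x, cont, clash, total)


def accept_probability(delta_e: float, temperature: float) -> float:
    """Metropolis acceptance: 1 if the score improves, exp(-dE/T) otherwise."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0:
        return 1.0
    return float(np.exp(-delta_e / temperature))


def initial_temperature(e_init: float) -> float:
    """Starting temperature: 20% of the initial score, floored at 1.0."""
    if not np.isfinite(e_init):
        raise ValueError("initial score must be finite")
    return max(0.2 * e_init, 1.0)
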