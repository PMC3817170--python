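"""Model-quality metrics for RNA 3D structures.

Implements the standard accuracy measures used to benchmark
low-resolution RNA models: single-reference-atom RMSD under optimal
rigid superposition, Interaction Network Fidelity (INF, a Matthews-style
correlation over base-pair networks) with its sensitivity/specificity
components, the Deformation Index DI = RMSD/INF, the Global Distance
Test on phosphorus atoms with the classic (1/2/4/8 A) and RNA-adapted
(1.5/3/6/12 A) threshold ladders, a composite Fidelity Index, and the
chance model estimating how good an RMSD is expected by chance for an
RNA of N nucleotides with known secondary structure (power-law
regression of Hajdin et al., E(RMSD) = a*N^0.41 - b) together with its
Z-score and tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import geometry as geo

CLASSIC_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
RNA_THRESHOLDS = (1.5, 3.0, 6.0, 12.0)

#: chance-model regression parameters (molecular-dynamics benchmark of
#: Hajdin et al.); exposed as configuration
CHANCE_A = 5.1
CHANCE_B = 15.8
CHANCE_EXP = 0.41
CHANCE_SIGMA = 1.8


@dataclass
class InfResult:
    tp: int
    fp: int
    fn: int
    sty: float
    ppv: float
    inf: float


@dataclass
class GdtResult:
    thresholds: tuple
    fractions: tuple
    gdt_ts: float


@dataclass
class ChanceResult:
    n: int
    expected_rmsd: float
    z: float
    p: float
    neg_log10_p: float


def _paired_atoms(model, reference, atom: str):
    if model.n_residues != reference.n_residues:
        raise ValueError(f"residue count mismatch: {model.n_residues} vs "
                         f"{reference.n_residues}")
    a = model.atoms_named(atom)
    b = reference.atoms_named(atom)
    ok = ~(np.any(np.isnan(a), axis=1) | np.any(np.isnan(b), axis=1))
    if ok.sum() < 3:
        raise ValueError(f"fewer than 3 paired '{atom}' atoms")
    return a[ok], b[ok]


def rmsd_single_atom(model, reference, atom: str = "P") -> float:
    """Minimum RMSD over rigid superposition of one named atom per residue."""
    a, b = _paired_atoms(model, reference, atom)
    return geo.superposed_rmsd(a, b)


def annotate_pairs(model, nn_window=(7.8, 10.0), c1_window=(9.2, 11.6),
                   min_separation: int = 3) -> frozenset:
    """Base-pair network annotated from coordinates.

    Two residues are called paired when their glycosidic-nitrogen
    pseudo-atoms and their C1' atoms both fall inside distance windows
    centred on the Watson-Crick geometry of the helix generator
    (N-N 8.9 A, C1'-C1' 10.4 A) and the local strand directions are
    antiparallel.  Deterministic and invariant under rigid motion.
    """
    nn = model.atoms_named("N")
    c1 = model.atoms_named("C1'")
    n = model.n_residues
    pairs = set()
    # local 5'->3' direction at each residue from C1' neighbours
    direction = np.zeros((n, 3))
    if n > 1:
        direction[:-1] = c1[1:] - c1[:-1]
        direction[-1] = direction[-2] if n > 1 else direction[-1]
    for i in range(n):
        for j in range(i + min_separation, n):
            dn = np.linalg.norm(nn[i] - nn[j])
            if not (nn_window[0] <= dn <= nn_window[1]):
                continue
            dc = np.linalg.norm(c1[i] - c1[j])
            if not (c1_window[0] <= dc <= c1_window[1]):
                continue
            if direction[i] @ direction[j] > 0:
                continue
            pairs.add((i, j))
    # enforce at most one partner per residue: keep the geometrically best
    best = {}
    for (i, j) in sorted(pairs, key=lambda p: abs(
            np.linalg.norm(nn[p[0]] - nn[p[1]]) - 8.9)):
        if i not in best and j not in best:
            best[i] = j
            best[j] = i
    return frozenset((i, j) for i, j in best.items() if i < j)


def inf_score(model_pairs, reference_pairs) -> InfResult:
    """Interaction Network Fidelity between two base-pair networks.

    STY = TP/(TP+FN) (sensitivity), PPV = TP/(TP+FP) (specificity),
    INF = sqrt(STY * PPV).
    """
    mp = {tuple(sorted(p)) for p in model_pairs}
    rp = {tuple(sorted(p)) for p in reference_pairs}
    tp = len(mp & rp)
    fp = len(mp - rp)
    fn = len(rp - mp)
    if tp + fn == 0:
        raise ValueError("reference network is empty: INF undefined")
    sty = tp / (tp + fn)
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    return InfResult(tp, fp, fn, sty, ppv, float(np.sqrt(sty * ppv)))


def _gdt_fraction(mob, ref, threshold: float, seeds) -> float:
    """Largest fraction of atoms superposable within a threshold.

    Iterative inclusion from each seed subset: superpose on the seed,
    collect atoms within the threshold, re-superpose on them, repeat to
    convergence; the best seed wins.
    """
    n = len(mob)
    best = 0
    for seed_idx in seeds:
        sel = np.asarray(seed_idx)
        for _ in range(10):
            if len(sel) < 3:
                break
            rot, t = geo.superpose(mob[sel], ref[sel])
            moved = geo.apply_transform(rot, t, mob)
            within = np.flatnonzero(np.linalg.norm(moved - ref, axis=1)
                                    <= threshold)
            if len(within) == len(sel) and np.array_equal(within, sel):
                break
            if len(within) < 3:
                break
            sel = within
        rot, t = geo.superpose(mob[sel], ref[sel]) if len(sel) >= 3 else (None, None)
        if rot is not None:
            moved = geo.apply_transform(rot, t, mob)
            count = int(np.sum(np.linalg.norm(moved - ref, axis=1) <= threshold))
            best = max(best, count)
    return best / n


def gdt(model, reference, thresholds=RNA_THRESHOLDS, atom: str = "P",
        window: int = 5) -> GdtResult:
    """Global Distance Test on backbone phosphorus atoms.

    Superpositions are seeded from the global alignment plus sliding
    windows of ``window`` consecutive residues, iterating atom inclusion
    at each threshold; GDT_TS is the mean over-threshold fraction.
    """
    mob, ref = _paired_atoms(model, reference, atom)
    n = len(mob)
    seeds = [np.arange(n)]
    for start in range(0, max(1, n - window + 1), max(1, window // 2)):
        idx = np.arange(start, min(start + window, n))
        if len(idx) >= 3:
            seeds.append(idx)
    fractions = tuple(_gdt_fraction(mob, ref, th, seeds) for th in thresholds)
    return GdtResult(tuple(thresholds), fractions, float(np.mean(fractions)))


def di(rmsd: float, inf: float) -> float:
    """Deformation Index DI = RMSD / INF (infinite for INF = 0)."""
    if inf == 0:
        return float("inf")
    return rmsd / inf


def fidelity_index(inf: float, gdt_rna: float) -> float:
    """Composite Fidelity Index in [0, 1].

    Default combination is the arithmetic mean of INF and the
    RNA-threshold GDT_TS; 1.0 corresponds to perfect accuracy.
    """
    for v in (inf, gdt_rna):
        if not (0.0 <= v <= 1.0):
            raise ValueError("FI inputs must lie in [0, 1]")
    return 0.5 * (inf + gdt_rna)


def expected_rmsd(n: int, a: float = CHANCE_A, b: float = CHANCE_B,
                  exponent: float = CHANCE_EXP) -> float:
    """Expected by-chance RMSD [A] for an RNA of ``n`` nucleotides.

    Power-law regression over molecular-dynamics models built with known
    secondary structure: E(RMSD) = a * N^0.41 - b.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return a * n ** exponent - b


def chance_significance(rmsd: float, n: int, sigma: float = CHANCE_SIGMA,
                        a: float = CHANCE_A, b: float = CHANCE_B) -> ChanceResult:
    """Significance of an RMSD against the by-chance expectation.

    Z = (E(RMSD) - RMSD) / sigma_RMSD, P = upper-tail standard normal
    probability of Z; reported with -log10 P.
    """
    e = expected_rmsd(n, a=a, b=b)
    z = (e - rmsd) / sigma
    p = float(norm.sf(z))
    return ChanceResult(n, e, float(z), p, float(-np.log10(p)))


def evaluate(model, reference) -> dict:
    """Full metric report of a model against a reference structure."""
    rmsd = rmsd_single_atom(model, reference, "P")
    ref_pairs = annotate_pairs(reference)
    mod_pairs = annotate_pairs(model)
    inf_res = inf_score(mod_pairs, ref_pairs)
    gdt_classic = gdt(model, reference, CLASSIC_THRESHOLDS)
    gdt_rna = gdt(model, reference, RNA_THRESHOLDS)
    chance = chance_significance(rmsd, model.n_residues)
    return {
        "rmsd_p": rmsd,
        "inf": inf_res.inf,
        "sty": inf_res.sty,
        "ppv": inf_res.ppv,
        "di": di(rmsd, inf_res.inf),
        "gdt_ts": gdt_classic.gdt_ts,
        "gdt_ts_rna": gdt_rna.gdt_ts,
        "fi": fidelity_index(inf_res.inf, gdt_rna.gdt_ts),
        "expected_rmsd": chance.expected_rmsd,
        "z": chance.z,
        "neg_log10_p": chance.neg_log10_p,
    }
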