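"""Forward scattering, chi-square fitting and SAXS diagnostics.

Forward intensities use the Debye equation on the reduced pseudo-atom
representation with constant per-atom form factors proportional to the
electron count of the chemical group each pseudo-atom stands for.  No
hydration shell or excluded-volume correction is applied: curves are
coarse-grained, which is adequate for shape-driven fitting, Guinier
analysis and pair-distance diagnostics at low resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from . import geometry as geo

#: electrons per pseudo-atom group; the base is lumped at the glycosidic N
#: and sugar/backbone hydrogens at their heavy atoms.  Configuration, not
#: physics: only relative weights matter for curve shapes.
FORM_FACTORS = {
    "P": 47.0,   # phosphate group PO2 + esterified charge
    "O5'": 8.0,
    "C5'": 8.0,
    "C4'": 7.0,
    "C3'": 7.0,
    "O3'": 8.0,
    "C1'": 15.0,  # C1' + O4' + C2'/O2' share
    "N": 45.0,    # aromatic base, averaged over A/U/G/C
}


class SaxsError(ValueError):
    pass


@dataclass
class ScatteringCurve:
    """1-D scattering curve: momentum transfer q [1/A], intensity, error."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise SaxsError("q, I, sigma must have equal lengths")
        if np.any(self.q < 0):
            raise SaxsError("q must be non-negative")
        if np.any(np.diff(self.q) < 0):
            order = np.argsort(self.q)
            self.q, self.I, self.sigma = self.q[order], self.I[order], self.sigma[order]

    def __len__(self):
        return len(self.q)


@dataclass
class Chi2Fit:
    chi2: float
    scale: float
    n_points: int


@dataclass
class GuinierResult:
    rg: float
    i0: float
    q_range: tuple
    n_points: int


@dataclass
class NoiseParams:
    """Benchmark noise model: sigma(q) combines a relative component and an
    absolute component scaled to the minimum intensity, in quadrature."""

    relative: float = 0.02
    absolute: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.relative < 0 or self.absolute < 0:
            raise SaxsError("noise fractions must be >= 0")


def _atom_arrays(model_or_coords, weights=None):
    """Flat coordinates and per-atom form factors for a model or raw array."""
    table = FORM_FACTORS if weights is None else weights
    if hasattr(model_or_coords, "coords"):
        coords = model_or_coords.flat_coords()
        f = np.tile([table[a] for a in geo.ATOM_NAMES],
                    model_or_coords.n_residues).astype(float)
    else:
        coords = np.asarray(model_or_coords, dtype=float).reshape(-1, 3)
        f = np.ones(len(coords))
    keep = ~np.any(np.isnan(coords), axis=1)
    return coords[keep], f[keep]


def debye_intensity(model_or_coords, q, weights=None,
                    bin_width: float | None = None) -> ScatteringCurve:
    """Debye forward intensity I(q) = sum_ij f_i f_j sinc(q d_ij).

    Exact pairwise evaluation by default; ``bin_width`` [A] switches to a
    pair-distance histogram approximation (used inside the annealing loop
    where thousands of evaluations are needed).  The returned curve's
    sigma column is set to 1.
    """
    q = np.asarray(q, dtype=float)
    coords, f = _atom_arrays(model_or_coords, weights)
    if len(coords) == 0:
        raise SaxsError("empty model")
    i0_self = float(np.sum(f ** 2))
    if len(coords) == 1:
        return ScatteringCurve(q, np.full_like(q, i0_self), np.ones_like(q))
    d = pdist(coords)
    n = len(f)
    iu = np.triu_indices(n, k=1)
    w = f[iu[0]] * f[iu[1]]
    if bin_width:
        nbins = int(np.ceil(d.max() / bin_width)) + 1
        idx = (d / bin_width).astype(int)
        hist = np.bincount(idx, weights=w, minlength=nbins)
        centers = (np.arange(nbins) + 0.5) * bin_width
        mask = hist > 0
        cross = 2.0 * hist[mask] @ np.sinc(np.outer(centers[mask], q) / np.pi)
    else:
        cross = np.empty_like(q)
        step = max(1, int(4e6 // max(len(d), 1)))
        for k in range(0, len(q), step):
            qq = q[k:k + step]
            cross[k:k + step] = 2.0 * w @ np.sinc(np.outer(d, qq) / np.pi)
    return ScatteringCurve(q, i0_self + cross, np.ones_like(q))


def chi2_fit(exp: ScatteringCurve, theor: ScatteringCurve) -> Chi2Fit:
    """Reduced chi-square of a theoretical curve against data.

    The theoretical curve is interpolated onto the experimental q grid
    and scaled by the closed-form weighted least-squares factor c; the
    statistic is normalized by N - 1 (one fitted parameter), making it
    invariant to any positive rescaling of the theoretical curve.
    """
    if len(exp) < 2:
        raise SaxsError("need at least 2 points")
    if np.any(exp.sigma <= 0):
        raise SaxsError("experimental sigma must be > 0")
    it = np.interp(exp.q, theor.q, theor.I)
    w = 1.0 / exp.sigma ** 2
    denom = np.sum(w * it * it)
    if denom == 0:
        raise SaxsError("theoretical curve is identically zero")
    c = float(np.sum(w * exp.I * it) / denom)
    chi2 = float(np.sum(w * (exp.I - c * it) ** 2) / (len(exp) - 1))
    return Chi2Fit(chi2, c, len(exp))


def guinier_fit(exp: ScatteringCurve, qrg_limit: float = 1.3,
                min_points: int = 5, iterations: int = 2) -> GuinierResult:
    """Guinier analysis: ln I = ln I0 - (q Rg)^2 / 3 at low q.

    Fits the largest low-q window satisfying q*Rg <= ``qrg_limit``,
    iterating the window limit to self-consistency.
    """
    pos = exp.I > 0
    if pos.sum() < min_points:
        raise SaxsError("not enough positive intensities for Guinier fit")
    q, logi = exp.q[pos], np.log(exp.I[pos])
    lo = 1 if q[0] == 0 else 0  # exclude the extrapolated zero-angle point
    n = max(min_points, min(20, len(q)))
    rg = None
    for _ in range(max(1, iterations)):
        sel = slice(lo, lo + n)
        slope, intercept = np.polyfit(q[sel] ** 2, logi[sel], 1)
        if slope >= 0:
            raise SaxsError("non-decreasing low-q intensity: Guinier fit failed")
        rg = float(np.sqrt(-3.0 * slope))
        within = np.flatnonzero(q * rg <= qrg_limit)
        n = max(min_points, int(within.max()) + 1 - lo) if within.size else min_points
    sel = slice(lo, lo + n)
    slope, intercept = np.polyfit(q[sel] ** 2, logi[sel], 1)
    if slope >= 0:
        raise SaxsError("non-decreasing low-q intensity: Guinier fit failed")
    rg = float(np.sqrt(-3.0 * slope))
    return GuinierResult(rg, float(np.exp(intercept)),
                         (float(q[sel][0]), float(q[sel][-1])), n)


def rg_from_model(model_or_coords, weights=None) -> float:
    """Scattering-weighted radius of gyration of the model coordinates."""
    coords, f = _atom_arrays(model_or_coords, weights)
    if len(coords) < 2:
        raise SaxsError("need at least 2 atoms")
    center = np.average(coords, axis=0, weights=f)
    return float(np.sqrt(np.average(np.sum((coords - center) ** 2, axis=1),
                                    weights=f)))


def dmax_from_model(model_or_coords) -> float:
    """Maximum intra-particle distance (support limit of P(r))."""
    coords, _ = _atom_arrays(model_or_coords)
    if len(coords) < 2:
        raise SaxsError("need at least 2 atoms")
    return float(pdist(coords).max())


def pr_from_model(model_or_coords, bin_width: float = 1.0, weights=None):
    """Pair-distance distribution histogram P(r).

    Returns ``(r_centers, p)`` where p integrates (sums) to the total
    off-diagonal pair weight sum_{i != j} f_i f_j.
    """
    if bin_width <= 0:
        raise SaxsError("bin width must be > 0")
    coords, f = _atom_arrays(model_or_coords, weights)
    d = pdist(coords)
    n = len(f)
    iu = np.triu_indices(n, k=1)
    w = 2.0 * f[iu[0]] * f[iu[1]]
    nbins = int(np.ceil(d.max() / bin_width)) + 1
    idx = np.minimum((d / bin_width).astype(int), nbins - 1)
    p = np.bincount(idx, weights=w, minlength=nbins)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return centers, p


def simulate_benchmark_curve(model, n_points: int = 200, q_max: float = 0.5,
                             noise: NoiseParams | None = None,
                             weights=None, perturb: bool = True) -> ScatteringCurve:
    """Back-calculated noisy benchmark curve for a model.

    The noise-free Debye curve I_sim is perturbed by a single Gaussian
    draw per point with standard deviation

        sigma_sim(q) = sqrt[(rel * I_sim(q))^2 + (abs * min I_sim)^2]

    (relative and minimum-intensity-scaled absolute components combined
    in quadrature); sigma_sim is reported as the curve's error column.
    With ``perturb=False`` the intensities stay noise-free but the error
    column still follows the apparent-error law (useful for idealized
    recovery benchmarks).
    """
    noise = noise or NoiseParams()
    q = np.linspace(0.0, q_max, n_points)
    clean = debye_intensity(model, q, weights=weights)
    sigma = np.sqrt((noise.relative * clean.I) ** 2
                    + (noise.absolute * clean.I.min()) ** 2)
    intensity = clean.I
    if perturb:
        rng = np.random.default_rng(noise.seed)
        intensity = intensity + rng.normal(0.0, 1.0, size=len(q)) * sigma
    reported = np.where(sigma > 0, sigma, 1.0)
    return ScatteringCurve(q, intensity, reported)


# ---------------------------------------------------------------------------
# .dat files

def read_saxs_dat(path) -> ScatteringCurve:
    """Read a whitespace-separated 3-column (q, I, sigma) SAXS file.

    Lines starting with '#' (and non-numeric header lines) are skipped;
    2-column files are accepted with sigma imputed as 1% of I.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split()
        try:
            vals = [float(x) for x in parts[:3]]
        except ValueError:
            if not rows:
                continue  # tolerate a leading header line
            raise SaxsError(f"{path}:{lineno}: non-numeric row {text!r}")
        if len(vals) < 2:
            raise SaxsError(f"{path}:{lineno}: need at least 2 columns")
        rows.append(vals)
    if len(rows) < 2:
        raise SaxsError(f"{path}: fewer than 2 data rows")
    q = np.array([r[0] for r in rows])
    intensity = np.array([r[1] for r in rows])
    sigma = np.array([r[2] if len(r) > 2 else abs(r[1]) * 0.01 for r in rows])
    return ScatteringCurve(q, intensity, sigma)


def write_saxs_dat(path, curve: ScatteringCurve, header: str = "") -> None:
    lines = [f"# {header}"] if header else []
    lines.append("# q[1/A] I sigma")
    for qv, iv, sv in zip(curve.q, curve.I, curve.sigma):
        lines.append(f"{qv:.6e} {iv:.6e} {sv:.6e}")
    Path(path).write_text("\n".join(lines) + "\n")
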