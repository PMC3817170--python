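"""High-level modeling interface: RnaSaxsModel.fit() -> RnaSaxsResults.

The model object is built from the data of a run — sequence, secondary
structure, an optional experimental SAXS curve and a fragment library —
and ``fit`` performs the simulated-annealing fragment assembly.  The
results object carries the best-scoring structure, the score breakdown,
structural parameters and the annealing trajectory, and renders a text
summary in the spirit of statistical modeling packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import saxs as saxs_mod
from .anneal import AnnealResult, AnnealSchedule, run_annealing
from .assembly import RnaModel
from .fragments import FragmentLibrary, make_fixture_library, tree_topologies
from .pdbio import write_pdb
from .scoring import ScoreWeights
from .secondary import decompose, degrees_of_freedom, parse_dotbracket


class RnaSaxsModel:
    """SAXS-guided fragment-assembly model of one RNA.

    Parameters
    ----------
    sequence, structure : the RNA and its dot-bracket secondary structure.
    saxs : optional experimental :class:`~rnasaxs.saxs.ScatteringCurve`;
        without it the fit is driven by the geometric terms only.
    library : :class:`~rnasaxs.fragments.FragmentLibrary`; by default a
        seeded fixture library covering the element tree is generated.
    weights, schedule : scoring weights and annealing schedule.
    """

    def __init__(self, sequence: str, structure: str, saxs=None,
                 library: FragmentLibrary | None = None,
                 weights: ScoreWeights | None = None,
                 schedule: AnnealSchedule | None = None,
                 debye_bin_width: float | None = None):
        self.secondary = parse_dotbracket(sequence, structure)
        self.tree = decompose(self.secondary)
        self.saxs = saxs
        self.library = library
        self.weights = weights or ScoreWeights()
        self.schedule = schedule or AnnealSchedule()
        self.debye_bin_width = debye_bin_width

    @classmethod
    def from_files(cls, dotbracket_path, saxs_path=None, library_dir=None,
                   **kwargs) -> "RnaSaxsModel":
        from .secondary import read_dotbracket
        ss = read_dotbracket(dotbracket_path)
        curve = saxs_mod.read_saxs_dat(saxs_path) if saxs_path else None
        lib = FragmentLibrary.load(library_dir) if library_dir else None
        return cls(ss.sequence, ss.to_dotbracket(), saxs=curve, library=lib,
                   **kwargs)

    @property
    def degrees_of_freedom(self) -> int:
        return degrees_of_freedom(self.tree)

    def _library(self, seed: int) -> FragmentLibrary:
        if self.library is not None:
            return self.library
        seq = self.secondary.sequence
        sequences = {e.key: e.sequences(seq) for e in self.tree.nodes}
        return make_fixture_library(tree_topologies(self.tree, with_strands=True),
                                    copies=20, seed=seed, sequences=sequences)

    def fit(self, seed: int = 0) -> "RnaSaxsResults":
        lib = self._library(seed)
        result = run_annealing(self.tree, lib, exp_curve=self.saxs,
                               weights=self.weights, schedule=self.schedule,
                               seed=seed, debye_bin_width=self.debye_bin_width)
        return RnaSaxsResults(self, result)


class RnaSaxsResults:
    """Fit results: best model, scores, diagnostics, trajectory."""

    def __init__(self, model: RnaSaxsModel, anneal: AnnealResult):
        self.model = model
        self.anneal = anneal

    @property
    def best_model(self) -> RnaModel:
        return self.anneal.best_model

    @property
    def score(self):
        return self.anneal.best_score

    @property
    def chi2(self) -> float:
        return self.anneal.best_score.e_x

    @property
    def rg(self) -> float:
        return saxs_mod.rg_from_model(self.best_model)

    @property
    def dmax(self) -> float:
        return saxs_mod.dmax_from_model(self.best_model)

    @property
    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.anneal.stage_log])

    def guinier(self):
        """Guinier analysis of the experimental curve (if any)."""
        if self.model.saxs is None:
            raise ValueError("model was built without SAXS data")
        return saxs_mod.guinier_fit(self.model.saxs)

    def theoretical_curve(self):
        grid = (self.model.saxs.q if self.model.saxs is not None
                else np.linspace(0.0, 0.5, 200))
        return saxs_mod.debye_intensity(self.best_model, grid)

    def write_pdb(self, path, which: str = "best") -> None:
        model = self.best_model if which == "best" else self.anneal.final_model
        write_pdb(path, model, remark=f"rnasaxs {which} model, seed "
                                      f"{self.anneal.seed}")

    def summary(self) -> str:
        s = self.anneal
        lines = [
            "RNA SAXS fragment-assembly fit",
            "=" * 46,
            f"{'residues':<28}{self.best_model.n_residues:>18d}",
            f"{'secondary elements':<28}{len(self.model.tree.nodes):>18d}",
            f"{'degrees of freedom':<28}{self.model.degrees_of_freedom:>18d}",
            f"{'seed':<28}{s.seed:>18d}",
            f"{'iterations':<28}{s.iterations:>18d}",
            f"{'iteration of best model':<28}{s.iteration_found:>18d}",
            f"{'starting temperature T0':<28}{s.t0:>18.4f}",
            "-" * 46,
            f"{'initial score':<28}{s.initial_score.total:>18.4f}",
            f"{'best score':<28}{s.best_score.total:>18.4f}",
            f"{'  SAXS chi^2 (E_x)':<28}{s.best_score.e_x:>18.4f}",
            f"{'  geometry (E_g)':<28}{s.best_score.e_g:>18.4f}",
            f"{'    contiguity [A]':<28}{s.best_score.contiguity:>18.4f}",
            f"{'    clash count':<28}{s.best_score.clashes:>18.1f}",
            f"{'  sequence mismatch (E_m)':<28}{s.best_score.e_m:>18.4f}",
            "-" * 46,
            f"{'model Rg [A]':<28}{self.rg:>18.2f}",
            f"{'model Dmax [A]':<28}{self.dmax:>18.2f}",
        ]
        if self.model.saxs is not None:
            g = self.guinier()
            lines.append(f"{'Guinier Rg (data) [A]':<28}{g.rg:>18.2f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------

    def plot_fit(self, ax=None):
        """Log-intensity data-vs-model plot."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        theor = self.theoretical_curve()
        if self.model.saxs is not None:
            exp = self.model.saxs
            from .saxs import chi2_fit
            fit = chi2_fit(exp, theor)
            ax.errorbar(exp.q, exp.I, yerr=exp.sigma, fmt=".", color="0.6",
                        label="data")
            ax.plot(theor.q, fit.scale * theor.I, "r-",
                    label=f"model (chi2={fit.chi2:.2f})")
        else:
            ax.plot(theor.q, theor.I, "r-", label="model")
        ax.set_yscale("log")
        ax.set_xlabel(r"q [$\AA^{-1}$]")
        ax.set_ylabel("I(q)")
        ax.legend()
        return ax

    def plot_pr(self, ax=None, bin_width: float = 2.0):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        r, p = saxs_mod.pr_from_model(self.best_model, bin_width=bin_width)
        ax.plot(r, p / p.max(), "-")
        ax.set_xlabel(r"r [$\AA$]")
        ax.set_ylabel("P(r) (normalized)")
        return ax
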