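"""Synthetic benchmark systems: fixture targets, libraries and stand-ins.

This module defines the study conditions of the package's own benchmark:
small multi-helix RNAs with known ("native") coordinates, seeded decoy
fragment libraries that contain the native fragments, and back-calculated
noisy SAXS curves.  It also provides synthetic stand-in models for the
7SK stem-loops HP3 and HP4 (the deposited models and measured curves are
not redistributable here); the stand-ins are extended stem-loops built by
the package's own A-form generator from construct-level secondary
structures, and are labelled synthetic wherever they are written out.
"""

from __future__ import annotations

import numpy as np

from .assembly import RnaModel, assemble
from .fragments import (FragmentLibrary, ideal_fragment_for,
                        make_fixture_library, tree_topologies)
from .saxs import NoiseParams, ScatteringCurve, simulate_benchmark_curve
from .secondary import ElementTree, decompose, parse_dotbracket

#: two-helix-plus-internal-loop target used by the self-recovery benchmark
TWO_HELIX_STRUCTURE = "((((..((((....))))..))))"

#: tRNA-like cloverleaf: 4 helices, 3 hairpin loops, 1 four-way junction
CLOVERLEAF_STRUCTURE = ("((((("
                        "..((((....))))"
                        ".(((((..)))))"
                        "...."
                        "((((....))))"
                        ")))))")


def sequence_for_structure(structure: str) -> str:
    """Deterministic sequence compatible with a dot-bracket string.

    Paired positions alternate G-C and C-G (wobble-free); unpaired
    positions cycle A, A, U to avoid accidental complementarity.
    """
    stack = []
    seq = [""] * len(structure)
    unpaired = 0
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            seq[j], seq[i] = ("G", "C") if len(stack) % 2 == 0 else ("C", "G")
        else:
            seq[i] = "AAU"[unpaired % 3]
            unpaired += 1
    return "".join(seq)


def fixture_tree(structure: str, sequence: str | None = None) -> ElementTree:
    seq = sequence or sequence_for_structure(structure)
    return decompose(parse_dotbracket(seq, structure))


def native_model(tree: ElementTree) -> RnaModel:
    """Model assembled entirely from ideal template fragments."""
    seq = tree.secondary.sequence
    choice = {i: ideal_fragment_for(elem, seq) for i, elem in enumerate(tree.nodes)}
    return assemble(tree, choice)


def benchmark_system(structure: str = TWO_HELIX_STRUCTURE, seed: int = 0,
                     copies: int = 21, noise: NoiseParams | None = None,
                     n_points: int = 200, q_max: float = 0.5):
    """Complete benchmark fixture: target, decoy library and SAXS data.

    Returns ``(tree, native, library, curve)``.  The library holds
    ``copies`` fragments per element key, the first of which is the
    native (ideal) geometry, the rest seeded decoys with coordinate
    noise and random inter-helix bends; the curve is back-calculated
    from the native model (noise-free when ``noise`` has zero fractions).
    """
    tree = fixture_tree(structure)
    native = native_model(tree)
    seq = tree.secondary.sequence
    sequences = {elem.key: elem.sequences(seq) for elem in tree.nodes}
    lib = make_fixture_library(tree_topologies(tree, with_strands=True),
                               copies=copies, seed=seed, sequences=sequences)
    if noise is None:
        # noise-free intensities with the benchmark apparent-error column
        curve = simulate_benchmark_curve(native, n_points=n_points, q_max=q_max,
                                         noise=NoiseParams(seed=seed),
                                         perturb=False)
    else:
        curve = simulate_benchmark_curve(native, n_points=n_points, q_max=q_max,
                                         noise=noise)
    return tree, native, lib, curve


# ---------------------------------------------------------------------------
# synthetic stand-ins for the 7SK stem-loops

#: synthetic HP4 stand-in: 31-nt hairpin (10-bp stem, tetraloop) with a
#: single-stranded stacked 3' tail of 7 nt, mimicking the SAXS construct
HP4_STANDIN_STRUCTURE = "((((((((((....))))))))))......."

#: synthetic HP3 stand-in: 72-nt extended stem (31 bp in seven segments
#: separated by six 1-nt bulges) capped by a tetraloop; the length follows
#: the construct's molecular mass and the extended conformation the SAXS
#: data support
HP3_STANDIN_STRUCTURE = ("(((((.(((((.(((((.((((.((((.((((.(((("
                         "...." + ")" * 31)


def _standin(structure: str) -> RnaModel:
    tree = fixture_tree(structure)
    return native_model(tree)


def synthetic_hp4_model() -> RnaModel:
    """Synthetic stand-in for the HP4 stem-loop model (not the deposited one)."""
    return _standin(HP4_STANDIN_STRUCTURE)


def synthetic_hp3_model() -> RnaModel:
    """Synthetic stand-in for the HP3 stem-loop model (not the deposited one)."""
    return _standin(HP3_STANDIN_STRUCTURE)


def synthetic_saxs_curve(model: RnaModel, seed: int = 0,
                         n_points: int = 200, q_max: float = 0.5) -> ScatteringCurve:
    """Benchmark-noise SAXS curve back-calculated from a stand-in model."""
    return simulate_benchmark_curve(model, n_points=n_points, q_max=q_max,
                                    noise=NoiseParams(seed=seed))
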