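# Methods

## Model representation

RNA is represented at low resolution with 8 pseudo-atoms per nucleotide:
the six backbone atoms (P, O5', C5', C4', C3', O3'), the sugar anchor
C1', and one base pseudo-atom at the glycosidic nitrogen (N9 for
purines, N1 for pyrimidines).  This resolution suffices for shape-driven
SAXS fitting and for the P-atom-based quality metrics; it does not
support base-pair hydrogen-bond geometry or all-atom refinement, which
are out of scope.

Helices are generated from a single-residue A-form template on a helical
lattice (twist 32.7°/bp, rise 2.81 Å/bp).  The template's cylindrical
coordinates were solved once by least squares against standard backbone
bond lengths (P–O5' 1.593 Å … O3'–P 1.607 Å), the 5.9 Å consecutive
intra-strand P–P spacing, and Watson–Crick pairing geometry of the
dyad-flipped complementary strand (glycosidic N–N 8.9 Å, C1'–C1'
10.4 Å); the solved constants are frozen in `geometry.py`.  The
generated duplex is strictly periodic, so the paired strand is
antiparallel and continuous by construction.

## Secondary structure and the element tree

A non-pseudoknotted dot-bracket structure is decomposed into maximal
helices (runs of perfectly nested pairs — any interruption, including a
1-nt bulge, ends the helix) and non-helical elements: hairpin loops,
internal loops, bulges (one empty strand), junctions (≥3 strands) and an
external element holding 5'/3' tails and multiple root helices.  The
elements form a rooted tree along nesting; every residue belongs to
exactly one element.  Bulges and internal loops are distinguished by
name but treated identically downstream.  Lone pairs are helices of
length 1.  Pseudoknots are rejected rather than approximated: the
subtree-locality property that makes element replacement cheap requires
nesting.  The number of non-helical elements is reported as the
degree-of-freedom count of the low-resolution conformational search.

## Fragments and grafting

A fragment stores the coordinates of one element in a local frame in
which the attachment to the parent helix is canonical, plus boundary
frames: an entry triple (P, O5', C5' of the first residue continuing the
parent strand) and one exit triple per child helix.  Grafting superposes
the entry triple onto the parent's exit triple (Kabsch, proper rotation);
the child subtree follows rigidly, so replacing the fragment at a node
moves exactly that subtree.  After each graft the three terminal
dihedrals (O5'–C5', C5'–C4', C4'–C3') of the upstream boundary residue
are adjusted by cyclic coordinate descent (≤50 sweeps, closed-form angle
per pivot, convergence at |d(O3'–P) − 1.607| < 0.05 Å, early stop on
stagnation) to restore the phosphodiester linkage; only that residue's
distal atoms move, preserving locality.

Ideal element geometries stand in for a curated fragment database (the
library format and interfaces accept imported fragments): hairpin loops
follow an equal-arclength Bezier arc over the helix end, sized so
residues are spaced ~5.9 Å, with a per-residue helical roll to avoid
self-overlap; internal loops and bulges continue the helix coaxially,
spreading unpaired residues over max(m, n) fractional helix levels;
junctions fan their children on a 55° cone with evenly spread azimuths,
the hub two levels above the parent and each child offset 8 Å along its
own axis so the ~19 Å-wide branches clear each other; single-stranded
tails stack on the continued helical path.  The fixture-library
generator perturbs these templates with Gaussian coordinate noise
(default σ = 0.3 Å) and, for branching elements, a random bend of
everything above the element's mid-height by up to 60°, which emulates
the conformational spread of database junction fragments.  Copy 0 of
each key is the unperturbed template, so recovery benchmarks always
contain the native geometry among the decoys.  What the fixtures do not
emulate: sequence-dependent loop conformations, non-canonical pairs, and
the broad length/topology coverage of a real database; tests passing on
fixtures therefore validate the algorithmic machinery, not database
quality on real RNAs.

When the library has no fragment for an element (variant B), the
element's ideal template provides the skeleton and child frames, and
individual strands are drawn from a strand library; their backbone gaps
are charged to the contiguity score.  Strand moves replace one strand at
a time (configurable in principle; the one-at-a-time choice keeps move
sizes comparable to element moves).

## Scoring

E = w_m·E_m + w_g·E_g + w_x·E_x, minimized; defaults w_x = 1,
w_m = w_g = 0.1 keep the fit SAXS-dominated while mildly penalizing
implausible geometry.  E_m sums 1 − (mean per-strand fraction sequence
identity) over placed fragments.  E_g combines the contiguity score —
the summed excess of O3'(i)–P(i+1) links over the 1.607 Å reference —
with a clash count of non-bonded atom pairs closer than 2.5 Å between
residues ≥2 apart in sequence, phosphorus-versus-backbone pairs
multiplied by 5.  E_x is the reduced chi-square

    chi² = 1/(N−1) Σ [(I_exp − c·I_theor)/σ]²

with the closed-form weighted least-squares scale c, making chi²
invariant to any positive rescaling of the theoretical curve.

## Forward scattering

Intensities use the Debye equation over pseudo-atoms with constant form
factors proportional to group electron counts (configuration in
`saxs.FORM_FACTORS`; phosphate and base dominate).  No hydration shell
or excluded-volume term is modeled, so absolute comparison with
solvent-corrected programs is approximate; all internal analyses (Rg,
Dmax, P(r), Guinier consistency) are self-consistent.  The exact
pairwise sum is the default; the annealing loop may use a pair-distance
histogram approximation (default bin 0.05–0.1 Å, relative error ~1e-3)
whose accuracy is tested against the exact path.  Guinier fits use the
largest low-q window with q·Rg ≤ 1.3 (≥5 points, two self-consistency
iterations); the q = 0 point is excluded.  P(r) is the form-factor
weighted pair-distance histogram; Dmax is the exact maximum pair
distance.

## Benchmark noise model

Simulated benchmark curves sample 200 points on q ∈ [0, 0.5] Å⁻¹ and
perturb each point with a single Gaussian draw of standard deviation
σ_sim(q) = sqrt[(0.02·I_sim(q))² + (0.05·min I_sim)²] — 2% relative
noise and an absolute component worth 5% of the minimal intensity,
combined in quadrature, which is the standard apparent-error
composition; σ_sim is reported as the curve's error column.  For
idealized recovery studies the intensities can be left unperturbed while
keeping the σ_sim column, so chi-square retains its natural scale.

## Annealing

T0 = max(0.2·E_init, 1.0).  Default schedule: 20 stages, cooling factor
0.8, 100 attempts per stage, extended to 30 stages by the default
3000-attempt cap.  Moves pick a tree node uniformly; acceptance is
standard Metropolis, min(1, exp(−ΔE/T)).  All randomness flows through
one `numpy` generator seeded from the run seed; identical seeds give
bit-identical trajectories.  The best-so-far model and score are
tracked, making the reported best trajectory monotone by construction.

## Quality metrics

RMSD is computed on one named atom per residue (default P) under optimal
rigid superposition (Kabsch; an independent quaternion closed form backs
it in the tests).  Base pairs are annotated from coordinates by distance
windows around the generator's Watson–Crick geometry (N–N 8.9 Å, C1'–C1'
10.4 Å) with an antiparallel local-direction check and best-partner
uniqueness; INF, STY, PPV follow from the TP/FP/FN counts and
DI = RMSD/INF.  GDT fractions use iterative-inclusion superposition
seeded from the global alignment and 5-residue sliding windows — a
standard approximation to the full GDT search, asserted on controlled
constructions rather than on bit-equality with any particular
implementation.  The Fidelity Index defaults to the arithmetic mean of
INF and GDT_TS^RNA, a monotone combination on [0, 1] chosen because the
original combination rule is not fully specified.  The chance model uses
E(RMSD) = a·N^0.41 − b and Z = (E(RMSD) − RMSD)/σ with a = 5.1,
b = 15.8, σ = 1.8 (the published molecular-dynamics regression; all
three are configuration), P as the upper-tail normal probability.

## Problem sizes and numerical choices

The shipped benchmark system is a 24-nt two-helix target with one
internal loop and one hairpin, 21 fragments per key (native + 20
decoys), scored on 200-point curves with the 0.1 Å Debye binning; a
ten-seed recovery study at the default 3000-attempt schedule runs in a
few minutes on one core and recovers the native to < 3 Å P-RMSD in
virtually every seed.  These sizes were chosen as the smallest systems
that exercise every code path (multi-element tree, decoy bends, variant
B) while keeping the study quick to repeat.  Degenerate inputs are
handled explicitly: empty strands carry no boundary frames, collinear
superposition triples raise errors, chi-square requires positive sigmas
and ≥2 points, and Guinier fitting fails loudly on non-decaying low-q
intensity.

## Synthetic stand-ins for the 7SK stem-loops

The deposited HP3/HP4 models and measured curves are not
redistributable with the package, so `synthetic.py` provides stand-ins
labelled synthetic: extended stem-loops built by the package's own
A-form generator — HP4 as a 31-nt hairpin (10-bp stem, tetraloop,
stacked 7-nt 3' tail), HP3 as a 72-nt stem (31 bp in seven segments
with six 1-nt bulges, tetraloop), with lengths taken from the published
construct masses and the extended conformation the scattering data
support.  Their simulated curves reproduce the qualitative structural
parameters of the real molecules (elongated P(r), Guinier Rg within a
few ångströms of the published values) but are not the deposited
coordinates; analyses that require the real files are expected to
deviate at the ångström level, and do.

## Known limitations

Pseudoknots, multi-chain assemblies and RDC restraints are unsupported.
The clash and contiguity terms are heuristics, not energies.  Fragment
quality bounds model quality: with only idealized fixtures, loop
conformational diversity is caricatured.  Chi-square against
solvent-corrected reference curves is biased by the missing hydration
shell; comparisons should use curves computed with the same forward
model.
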