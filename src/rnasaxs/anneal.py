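"""Simulated-annealing driver for SAXS-guided fragment assembly.

The sampler cools through stages (default 20, each at 80% of the
previous temperature, 100 fragment-exchange attempts per stage; extra
stages are appended while the total attempt cap allows).  Each attempt
replaces the fragment of one uniformly chosen tree element (variant A)
or, for elements without library coverage, one of its strands
(variant B), and accepts the move with the Metropolis probability
min(1, exp(-dE/T)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import random_initial_model, replace_element, replace_strand
from .fragments import FragmentLibrary
from .scoring import (ScoreBreakdown, ScoreWeights, accept_probability,
                      initial_temperature, total_score)
from .secondary import ElementTree


@dataclass
class AnnealSchedule:
    """Cooling schedule; T0 = None derives the start from the initial score."""

    t0: float | None = None
    stages: int = 20
    cooling: float = 0.8
    attempts_per_stage: int = 100
    max_iterations: int = 3000

    def __post_init__(self):
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be > 0")

    def n_stages(self) -> int:
        """Scheduled stages, extended while the attempt cap allows."""
        if self.stages <= 0:
            return 0
        by_cap = self.max_iterations // max(1, self.attempts_per_stage)
        return max(self.stages, by_cap) if self.max_iterations else self.stages

    def temperature(self, stage: int, t0: float) -> float:
        return t0 * self.cooling ** stage


@dataclass
class StageLog:
    stage: int
    temperature: float
    attempts: int
    accepted: int
    best_total: float
    current_total: float


@dataclass
class AnnealResult:
    best_model: object
    best_score: ScoreBreakdown
    initial_score: ScoreBreakdown
    final_model: object
    iteration_found: int
    iterations: int
    seed: int
    t0: float
    stage_log: list = field(default_factory=list)
    best_trajectory: list = field(default_factory=list)


def run_annealing(tree: ElementTree, lib: FragmentLibrary,
                  exp_curve=None, weights: ScoreWeights | None = None,
                  schedule: AnnealSchedule | None = None, seed: int = 0,
                  debye_bin_width: float | None = None) -> AnnealResult:
    """Anneal fragment replacements against the composite score.

    Reproducible per seed; the reported best-so-far trajectory is
    monotone non-increasing by construction.
    """
    weights = weights or ScoreWeights()
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    sequence = tree.secondary.sequence

    model, variant_b = random_initial_model(tree, lib, seed=int(rng.integers(2 ** 31)))
    score = total_score(model, exp_curve, weights, debye_bin_width)
    initial = score
    best_model, best_score = model, score
    iteration_found = 0
    t0 = schedule.t0 if schedule.t0 is not None else initial_temperature(score.total)

    nodes = list(range(len(tree.nodes)))
    vb = set(variant_b)
    stage_log = []
    best_traj = []
    iteration = 0
    n_stages = schedule.n_stages()
    for stage in range(n_stages):
        temp = schedule.temperature(stage, t0)
        accepted = 0
        attempts = 0
        for _ in range(schedule.attempts_per_stage):
            if schedule.max_iterations and iteration >= schedule.max_iterations:
                break
            iteration += 1
            attempts += 1
            node = nodes[rng.integers(len(nodes))]
            elem = tree.node(node)
            if node in vb:
                lengths = [s for s, L in enumerate(elem.strand_lengths) if L > 0]
                if not lengths:
                    continue
                s = lengths[rng.integers(len(lengths))]
                cands = lib.query_strand(elem.strand_lengths[s])
                frag = cands[rng.integers(len(cands))]
                proposal = replace_strand(model, node, s, frag)
            else:
                cands = lib.query_element(elem, sequence)
                if not cands:
                    continue
                frag = cands[rng.integers(len(cands))]
                proposal = replace_element(model, node, frag)
            new_score = total_score(proposal, exp_curve, weights, debye_bin_width)
            delta = new_score.total - score.total
            if rng.random() < accept_probability(delta, temp):
                model, score = proposal, new_score
                accepted += 1
                if score.total < best_score.total:
                    best_model, best_score = model, score
                    iteration_found = iteration
            best_traj.append(best_score.total)
        stage_log.append(StageLog(stage, temp, attempts, accepted,
                                  best_score.total, score.total))
        if schedule.max_iterations and iteration >= schedule.max_iterations:
            break
    return AnnealResult(best_model, best_score, initial, model, iteration_found,
                        iteration, seed, t0, stage_log, best_traj)
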