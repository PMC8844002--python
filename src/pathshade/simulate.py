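"""Synthetic path-choice experiments with the structure the model assumes.

Generates cohorts of participants who each face a series of binary path
choices between options decomposed into sun-lit, tree-shaded and
building-shaded stretches, mirroring the courtyard study design: ~46
participants x 13 trials (one of them a designated test trial with a clearly
dominated, much longer and sunnier option), two choice sets with their own
cost-difference scales, participant-specific sun coefficients beta_j drawn
from a Gamma population distribution, and Bernoulli outcomes from the
logistic choice probability.

The defaults are the study conditions; a larger "recovery scale"
(200 participants) is available for parameter-recovery simulation, because
13 trials per participant deliberately under-identify beta_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .choice import (
    LENGTH_SCALE,
    PathComposition,
    TrialRecord,
    choice_probability,
    cost_difference,
)
from .scene import Building, PathOption, Scene, TreeCrown

__all__ = [
    "SimulationConfig",
    "generate_choice_set",
    "draw_participants",
    "simulate_decisions",
    "trials_to_frame",
    "simulate_study",
    "generate_scene",
]

_MAX_REJECTION_ATTEMPTS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic experiment.

    Hyperparameters follow the hierarchical model: beta_j ~ Gamma with shape
    exp(d + e) and rate exp(d - e), so the population mean of beta is
    exp(2e).  The defaults put that mean at 1.16 with a population standard
    deviation of 0.2 — a moderately sun-averse cohort — and use a common
    cost-difference scale tau = 0.2 on hectometre-scaled lengths for both
    choice sets.
    """

    n_participants: int = 46
    n_trials_per_participant: int = 13  # includes 1 designated test trial
    test_trial_id: int = 13
    true_rho: float = 0.5
    true_tau: dict[int, float] = field(default_factory=lambda: {1: 0.2, 2: 0.2})
    #: population mean of beta (exp(2e)) and its standard deviation
    beta_mean: float = 1.16
    beta_sd: float = 0.2
    #: option total lengths are drawn from this range (m)
    length_range: tuple[float, float] = (40.0, 250.0)
    #: option length difference range (m); study averages ~20 m
    length_diff_range: tuple[float, float] = (5.0, 40.0)
    #: fraction of non-test trials that are sun/distance trade-offs at rho=1
    trade_off_fraction: float = 0.7
    #: test-trial dominance margins: dominated option at least this much
    #: longer and at least this much sunnier (effective sun at rho=1)
    test_length_factor: float = 1.5
    test_sun_factor: float = 2.0
    #: probability that a trial happens with the sun out (treatment)
    p_sun_present: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 0 or self.n_trials_per_participant <= 0:
            raise ValueError("participant/trial counts must be positive")
        if not 0.0 <= self.trade_off_fraction <= 1.0:
            raise ValueError("trade_off_fraction must lie in [0, 1]")
        if not 0.0 <= self.true_rho <= 1.0:
            raise ValueError("true_rho must lie in [0, 1]")
        if any(t <= 0 for t in self.true_tau.values()):
            raise ValueError("true_tau values must be > 0")
        if self.length_range[0] <= 0 or self.length_range[1] <= self.length_range[0]:
            raise ValueError("length_range must be a positive, increasing interval")
        if self.beta_mean <= 0 or self.beta_sd <= 0:
            raise ValueError("beta_mean and beta_sd must be > 0")

    @property
    def hyper_d(self) -> float:
        """d such that the beta population variance equals beta_sd**2.

        Gamma(exp(d+e), exp(d-e)) has mean exp(2e) and variance exp(3e - d).
        """
        return 3.0 * self.hyper_e - math.log(self.beta_sd**2)

    @property
    def hyper_e(self) -> float:
        return math.log(self.beta_mean) / 2.0


def _split_remainder(total: float, rng: np.random.Generator) -> tuple[float, float]:
    """Split a non-sun length into tree and building shade."""
    w = rng.uniform()
    return total * w, total * (1.0 - w)


def _make_trade_off(cfg: SimulationConfig, rng: np.random.Generator):
    """Option A shorter but sunnier; option B longer with more shade (rho=1)."""
    lo, hi = cfg.length_range
    dlo, dhi = cfg.length_diff_range
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        L_B = rng.uniform(lo + dhi, hi)
        L_A = L_B - rng.uniform(dlo, dhi)
        s_A = rng.uniform(0.5, 1.0) * L_A
        s_B = rng.uniform(0.1, 0.9) * s_A
        t_A, h_A = _split_remainder(L_A - s_A, rng)
        t_B, h_B = _split_remainder(L_B - s_B, rng)
        A = PathComposition(s_A, t_A, h_A)
        B = PathComposition(s_B, t_B, h_B)
        if s_A > s_B and L_A < L_B:
            return A, B
    raise RuntimeError("could not generate a trade-off trial under this configuration")


def _make_dominance(cfg: SimulationConfig, rng: np.random.Generator):
    """Option B both shorter and less sunny (it dominates at rho=1)."""
    lo, hi = cfg.length_range
    dlo, dhi = cfg.length_diff_range
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        L_A = rng.uniform(lo + dhi, hi)
        L_B = L_A - rng.uniform(dlo, dhi)
        s_A = rng.uniform(0.4, 1.0) * L_A
        s_B = rng.uniform(0.1, 0.9) * min(s_A, L_B)
        if not (s_B < s_A and L_B < L_A):
            continue
        t_A, h_A = _split_remainder(L_A - s_A, rng)
        t_B, h_B = _split_remainder(L_B - s_B, rng)
        return PathComposition(s_A, t_A, h_A), PathComposition(s_B, t_B, h_B)
    raise RuntimeError("could not generate a dominance trial under this configuration")


def _make_test_trial(cfg: SimulationConfig, rng: np.random.Generator):
    """Dominated option A much longer and much sunnier than B."""
    lo, hi = cfg.length_range
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        L_B = rng.uniform(lo, hi / cfg.test_length_factor)
        L_A = L_B * rng.uniform(cfg.test_length_factor, cfg.test_length_factor + 0.5)
        if L_A > hi:
            continue
        s_B = rng.uniform(0.1, 0.5) * L_B
        s_A = s_B * rng.uniform(cfg.test_sun_factor, cfg.test_sun_factor + 1.0)
        if s_A > L_A:
            continue
        t_A, h_A = _split_remainder(L_A - s_A, rng)
        t_B, h_B = _split_remainder(L_B - s_B, rng)
        return PathComposition(s_A, t_A, h_A), PathComposition(s_B, t_B, h_B)
    raise RuntimeError("could not generate a test trial under this configuration")


def _assign_choice_set(participant_index: int, cfg: SimulationConfig) -> int:
    """First half of the cohort gets choice set 1, the rest set 2 (the study
    split participants by season)."""
    sets = sorted(cfg.true_tau)
    if len(sets) == 1:
        return sets[0]
    return sets[0] if participant_index < cfg.n_participants / 2 else sets[1]


def generate_choice_set(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[TrialRecord]:
    """Trial templates (no outcomes) for every participant.

    Non-test trials are trade-offs with probability ``trade_off_fraction``
    and dominance trials otherwise, verified via ``classify_trial`` at
    rho = 1; each participant additionally gets one designated test trial
    whose dominated option is much longer and sunnier.
    """
    trials: list[TrialRecord] = []
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:03d}"
        k = _assign_choice_set(p, cfg)
        for t in range(1, cfg.n_trials_per_participant + 1):
            if t == cfg.test_trial_id:
                A, B = _make_test_trial(cfg, rng)
            elif rng.uniform() < cfg.trade_off_fraction:
                A, B = _make_trade_off(cfg, rng)
            else:
                A, B = _make_dominance(cfg, rng)
            sun_state = "full_sun" if rng.uniform() < cfg.p_sun_present else "no_sun"
            trials.append(
                TrialRecord(
                    participant_id=pid,
                    trial_id=t,
                    choice_set=k,
                    option_A=A,
                    option_B=B,
                    sun_state=sun_state,
                )
            )
    return trials


def draw_participants(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """beta_j for each participant, i.i.d. Gamma(exp(d+e), rate exp(d-e))."""
    shape = math.exp(cfg.hyper_d + cfg.hyper_e)
    rate = math.exp(cfg.hyper_d - cfg.hyper_e)
    return rng.gamma(shape, 1.0 / rate, size=cfg.n_participants)


def simulate_decisions(
    trials: list[TrialRecord],
    betas: np.ndarray | dict[str, float],
    rho: float,
    tau: dict[int, float],
    rng: np.random.Generator,
    length_scale: float = LENGTH_SCALE,
) -> list[TrialRecord]:
    """Draw a Bernoulli outcome for every trial from the choice probability."""
    if not isinstance(betas, dict):
        ids = sorted({t.participant_id for t in trials})
        if len(ids) != len(betas):
            raise ValueError(f"{len(betas)} betas given for {len(ids)} participants")
        betas = dict(zip(ids, betas))
    completed = []
    for trial in trials:
        dc = cost_difference(trial, betas[trial.participant_id], rho) * length_scale
        p_A = choice_probability(dc, tau[trial.choice_set])
        completed.append(replace(trial, chose_A=bool(rng.uniform() < p_A)))
    return completed


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Decisions table in the standard delimited layout."""
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "trial_id": [t.trial_id for t in trials],
            "choice_set": [t.choice_set for t in trials],
            "a_sun_A": [t.option_A.a_sun for t in trials],
            "a_tree_A": [t.option_A.a_tree for t in trials],
            "a_shade_A": [t.option_A.a_shade for t in trials],
            "a_sun_B": [t.option_B.a_sun for t in trials],
            "a_tree_B": [t.option_B.a_tree for t in trials],
            "a_shade_B": [t.option_B.a_shade for t in trials],
            "sun_state": [t.sun_state for t in trials],
            "chose_A": [None if t.chose_A is None else int(t.chose_A) for t in trials],
        }
    )


def simulate_study(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full synthetic experiment: trials, participants and outcomes.

    Returns the completed decisions table plus the generating truth
    (betas, rho, tau, hyperparameters) for recovery checks.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    trials = generate_choice_set(cfg, rng)
    betas = draw_participants(cfg, rng)
    completed = simulate_decisions(trials, betas, cfg.true_rho, cfg.true_tau, rng)
    frame = trials_to_frame(completed)
    frame["is_test"] = frame["trial_id"] == cfg.test_trial_id
    truth = {
        "beta": dict(zip(sorted(frame["participant_id"].unique()), betas)),
        "beta_mean": cfg.beta_mean,
        "rho": cfg.true_rho,
        "tau": dict(cfg.true_tau),
        "d": cfg.hyper_d,
        "e": cfg.hyper_e,
    }
    return frame, truth


def generate_scene(
    n_trees: int = 4,
    rng: np.random.Generator | None = None,
    site_latitude: float = 1.3483,
    site_longitude: float = 103.6831,
) -> Scene:
    """A synthetic courtyard exercising the full shading pipeline.

    Two east-west buildings frame a lawn; a wide 6 m path (5 strips of 1.2 m)
    runs along each building, and two narrow paths cross the lawn.  Tree
    crowns are scattered along the lawn edge.  Geometry is in a local metric
    east-north-up frame; the site is placed at the study's tropical latitude
    so midday shadows are short and morning/afternoon shadows sweep the
    paths.
    """
    from shapely.geometry import box

    rng = rng or np.random.default_rng(0)
    court_w = 80.0
    buildings = (
        Building(footprint=box(0.0, -10.0, court_w, 0.0), height=15.0),   # south
        Building(footprint=box(0.0, 40.0, court_w, 50.0), height=15.0),   # north
    )
    trees = tuple(
        TreeCrown(
            center=(float(rng.uniform(10, court_w - 10)), float(rng.uniform(12, 28)), 5.0),
            semi_axes=(3.0, 3.0, 2.0),
        )
        for _ in range(n_trees)
    )

    def wide_path(option_id: str, y0: float) -> PathOption:
        strips = tuple(
            box(0.0, y0 + i * 1.2, court_w, y0 + (i + 1) * 1.2) for i in range(5)
        )
        return PathOption(option_id=option_id, strips=strips, length=court_w, is_wide=True)

    def lawn_path(option_id: str, x0: float) -> PathOption:
        return PathOption(
            option_id=option_id,
            strips=(box(x0, 6.0, x0 + 1.5, 34.0),),
            length=28.0,
            is_wide=False,
        )

    options = {
        "south_walk": wide_path("south_walk", 0.0),
        "north_walk": wide_path("north_walk", 34.0),
        "lawn_west": lawn_path("lawn_west", 20.0),
        "lawn_east": lawn_path("lawn_east", 55.0),
    }
    return Scene(
        site_latitude=site_latitude,
        site_longitude=site_longitude,
        buildings=buildings,
        trees=trees,
        path_options=options,
    )
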