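"""Path-option cost, binary choice probability, and choice-strategy taxonomy.

A pedestrian facing two path options weighs walking distance against sun
exposure.  The cost of a path option decomposed into sun-lit, tree-shaded and
building-shaded stretches is

    c = beta * [a_sun + (1 - rho) * a_tree] + a_shade + rho * a_tree

where ``beta > 0`` is the walker's distance-inflating coefficient for the sun
(beta > 1 means sun aversion), and ``rho`` in [0, 1] is the perceived tree-shade
intensity: rho = 1 treats tree shade exactly like building shade, rho = 0
treats it like full sun.  The probability of choosing option A over B is the
logistic function of the cost difference, with a per-choice-set temperature
``tau``:

    p(choose A) = 1 / (1 + exp((c_A - c_B) / tau))
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
import numpy as np
from scipy.special import expit

__all__ = [
    "LENGTH_SCALE",
    "PathComposition",
    "ChoiceParams",
    "TrialRecord",
    "TrialType",
    "ChosenStrategy",
    "StrategyLabel",
    "cost",
    "cost_difference",
    "choice_probability",
    "effective_sun_length",
    "classify_trial",
    "sun_equivalent_distance",
    "mixed_exposure_sun_component",
]

#: Global down-scaling of metric lengths before they enter the choice
#: likelihood: lengths are expressed in hectometres (factor 0.01), which puts a
#: typical option-length difference of ~20 m at 0.2 on the scaled axis — the
#: scale on which the tau prior is defined.  Because the cost function is
#: linear in the lengths, applying the factor to the cost difference is
#: equivalent to applying it to each length; this package applies it to the
#: cost difference, inside the likelihood (see ``model``).  The functions in
#: this module are unit-agnostic: they work in whatever unit you feed them.
LENGTH_SCALE = 0.01


@dataclass(frozen=True)
class PathComposition:
    """Metric decomposition of one path option.

    Attributes
    ----------
    a_sun, a_tree, a_shade
        Lengths (m) of the sun-lit, tree-shaded and building-shaded stretches.
        The total path length is their sum.
    """

    a_sun: float
    a_tree: float
    a_shade: float

    def __post_init__(self) -> None:
        for name in ("a_sun", "a_tree", "a_shade"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.a_sun + self.a_tree + self.a_shade


@dataclass(frozen=True)
class ChoiceParams:
    """Parameters of one walker's choice rule: beta, rho and tau."""

    beta: float
    rho: float
    tau: float

    def __post_init__(self) -> None:
        _check_beta(self.beta)
        _check_rho(self.rho)
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau!r}")


class TrialType(str, Enum):
    TRADE_OFF = "trade_off"
    DOMINANCE = "dominance"
    INDIFFERENT = "indifferent"


class ChosenStrategy(str, Enum):
    SUN_MINIMISING = "sun_minimising"
    DISTANCE_MINIMISING = "distance_minimising"
    OPTIMAL = "optimal"
    NON_OPTIMAL = "non_optimal"
    INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class StrategyLabel:
    trial_type: TrialType
    chosen_strategy: ChosenStrategy


@dataclass(frozen=True)
class TrialRecord:
    """One binary choice situation.

    Option B conventionally denotes the generally more building-shaded path.
    ``chose_A`` is present only for observed (or simulated) outcomes.
    """

    participant_id: str
    trial_id: int
    choice_set: int
    option_A: PathComposition
    option_B: PathComposition
    sun_state: str = "full_sun"
    chose_A: bool | None = None


def _check_beta(beta: float) -> None:
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta!r}")


def _check_rho(rho: float) -> None:
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho!r}")


def cost(option: PathComposition, beta: float, rho: float) -> float:
    """Perceived cost of walking a path option, in the option's length unit.

    ``beta`` inflates the effective sun-exposed length; tree shade is split
    between sun-like and building-shade-like parts by ``rho``.  At beta = 1
    the rho terms cancel and the cost equals the total length.
    """
    _check_beta(beta)
    _check_rho(rho)
    return beta * (option.a_sun + (1.0 - rho) * option.a_tree) + option.a_shade + rho * option.a_tree


def cost_difference(trial: TrialRecord, beta: float, rho: float) -> float:
    """c(A) - c(B); antisymmetric under swapping the option labels."""
    return cost(trial.option_A, beta, rho) - cost(trial.option_B, beta, rho)


def choice_probability(delta_c: float | np.ndarray, tau: float) -> float | np.ndarray:
    """Probability of choosing option A given the cost difference c(A) - c(B).

    Logistic in -delta_c / tau: the cheaper option is the more likely one,
    and tau sets how deterministically costs are minimised.  Numerically
    saturates to 0/1 for extreme arguments instead of overflowing.
    """
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau!r}")
    p = expit(-np.asarray(delta_c, dtype=float) / tau)
    if np.isscalar(delta_c) or np.ndim(delta_c) == 0:
        return float(p)
    return p


def effective_sun_length(option: PathComposition, rho: float) -> float:
    """Sun-equivalent exposed length: a_sun + (1 - rho) * a_tree.

    A tree-shaded stretch of perceived intensity rho behaves like a mix of
    (1 - rho) full sun and rho building shade; e.g. 100 m of 50%-intense tree
    shade is equivalent to 50 m of sun plus 50 m of building shade.
    """
    _check_rho(rho)
    return option.a_sun + (1.0 - rho) * option.a_tree


def classify_trial(trial: TrialRecord, rho: float) -> StrategyLabel:
    """Label an observed choice by the strategy it reveals.

    With L the total length and S the effective sun length of each option:

    * one option strictly shorter, the other strictly less sunny -> a
      trade-off trial; the chosen option is ``sun_minimising`` (smaller S) or
      ``distance_minimising`` (smaller L);
    * one option <= in both with at least one strict inequality -> a
      dominance trial; choosing the dominating option is ``optimal``,
      the other ``non_optimal``;
    * equal in both -> ``indifferent``.
    """
    if trial.chose_A is None:
        raise ValueError(f"trial {trial.trial_id!r} of {trial.participant_id!r} has no outcome")
    L_A, L_B = trial.option_A.total, trial.option_B.total
    S_A = effective_sun_length(trial.option_A, rho)
    S_B = effective_sun_length(trial.option_B, rho)

    chosen_shorter = (L_A < L_B) == trial.chose_A and L_A != L_B
    chosen_less_sunny = (S_A < S_B) == trial.chose_A and S_A != S_B

    if (L_A < L_B and S_A > S_B) or (L_A > L_B and S_A < S_B):
        strategy = ChosenStrategy.SUN_MINIMISING if chosen_less_sunny else ChosenStrategy.DISTANCE_MINIMISING
        return StrategyLabel(TrialType.TRADE_OFF, strategy)
    if L_A == L_B and S_A == S_B:
        return StrategyLabel(TrialType.INDIFFERENT, ChosenStrategy.INDIFFERENT)
    # one option is <= in both dimensions with at least one strict inequality;
    # the chosen option is optimal iff it is smaller in every strict dimension
    strategy = ChosenStrategy.OPTIMAL if (chosen_shorter or chosen_less_sunny) else ChosenStrategy.NON_OPTIMAL
    return StrategyLabel(TrialType.DOMINANCE, strategy)


def sun_equivalent_distance(shade_length: float, beta: float, *, rounded: bool = True) -> float:
    """Sun-walked distance with the same cost as ``shade_length`` of full shade.

    Solves beta * s = shade_length, i.e. s = shade_length / beta.  Reported
    values are rounded to the nearest metre by default, matching how such
    equivalences are usually quoted.
    """
    _check_beta(beta)
    s = shade_length / beta
    return float(round(s)) if rounded else s


def mixed_exposure_sun_component(
    shade_target: float, fixed_shade: float, beta: float, *, rounded: bool = True
) -> float:
    """Sun stretch s such that fixed_shade + beta * s costs like shade_target of shade.

    E.g. at beta = 1.16, 100 m of full shade is matched by 50 m of shade plus
    43 m of sun (a 93 m mixed-exposure walk).
    """
    _check_beta(beta)
    if fixed_shade > shade_target:
        raise ValueError(
            f"fixed_shade ({fixed_shade}) exceeds shade_target ({shade_target})"
        )
    s = (shade_target - fixed_shade) / beta
    return float(round(s)) if rounded else s
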