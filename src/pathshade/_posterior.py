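"""Log posterior (with analytic gradient) of the hierarchical choice model.

Model, for participant j, trial i in choice set k:

    d, e   ~ Normal(0, 1)
    beta_j ~ Gamma(shape = exp(d + e), rate = exp(d - e))
    tau_k  ~ Gamma(shape = 12.5, rate = 50)        (mean 0.25)
    rho    ~ Beta(1, 1)
    y_ji   ~ Bernoulli( 1 / (1 + exp(dc_ji / tau_k)) )

with dc the cost difference of the two options under the cost function
``choice.cost``, on lengths down-scaled by ``LENGTH_SCALE``.  The (d, e)
parameterisation of the Gamma hyperparameters decorrelates shape and rate
(prior mean of beta_j given (d, e) is exp(2e)).

Sampling happens in an unconstrained space:

    theta = [d, e, log beta_1..J, logit rho, log tau_1..K]

with the log-Jacobian of each transform included, so the NUTS sampler can run
without boundary handling.  All gradients are exact (scipy digamma for the
Gamma-shape terms) and fully vectorised over trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln

from .choice import LENGTH_SCALE

__all__ = ["ChoicePosterior", "TAU_PRIOR_SHAPE", "TAU_PRIOR_RATE"]

TAU_PRIOR_SHAPE = 12.5
TAU_PRIOR_RATE = 50.0


@dataclass
class ChoicePosterior:
    """Unnormalised log posterior of the choice model on one decisions table.

    Parameters
    ----------
    y : (n,) 0/1 array — 1 if option A was chosen.
    d_sun, d_tree, d_shade : (n,) arrays — per-trial composition differences
        A minus B, already multiplied by the global length scale.
    j_idx : (n,) participant index in 0..J-1; k_idx : (n,) choice-set index.
    """

    y: np.ndarray
    d_sun: np.ndarray
    d_tree: np.ndarray
    d_shade: np.ndarray
    j_idx: np.ndarray
    k_idx: np.ndarray
    n_participants: int
    n_sets: int
    tau_shape: float = TAU_PRIOR_SHAPE
    tau_rate: float = TAU_PRIOR_RATE

    @classmethod
    def from_dataframe(
        cls,
        decisions: pd.DataFrame,
        length_scale: float = LENGTH_SCALE,
        tau_shape: float = TAU_PRIOR_SHAPE,
        tau_rate: float = TAU_PRIOR_RATE,
    ) -> tuple["ChoicePosterior", list, list]:
        """Build the posterior from a decisions table.

        Returns the posterior plus the ordered participant and choice-set
        labels that index the beta and tau axes.
        """
        required = {
            "participant_id", "choice_set", "chose_A",
            "a_sun_A", "a_tree_A", "a_shade_A", "a_sun_B", "a_tree_B", "a_shade_B",
        }
        missing = required - set(decisions.columns)
        if missing:
            raise ValueError(f"decisions table is missing columns: {sorted(missing)}")
        if decisions["chose_A"].isna().any():
            raise ValueError("decisions table contains rows without an outcome (chose_A)")
        participants = sorted(decisions["participant_id"].unique())
        sets = sorted(decisions["choice_set"].unique())
        j_idx = decisions["participant_id"].map({p: i for i, p in enumerate(participants)})
        k_idx = decisions["choice_set"].map({s: i for i, s in enumerate(sets)})
        post = cls(
            y=decisions["chose_A"].to_numpy(dtype=float),
            d_sun=(decisions["a_sun_A"] - decisions["a_sun_B"]).to_numpy(dtype=float) * length_scale,
            d_tree=(decisions["a_tree_A"] - decisions["a_tree_B"]).to_numpy(dtype=float) * length_scale,
            d_shade=(decisions["a_shade_A"] - decisions["a_shade_B"]).to_numpy(dtype=float) * length_scale,
            j_idx=j_idx.to_numpy(dtype=np.intp),
            k_idx=k_idx.to_numpy(dtype=np.intp),
            n_participants=len(participants),
            n_sets=len(sets),
            tau_shape=tau_shape,
            tau_rate=tau_rate,
        )
        return post, participants, sets

    @property
    def dim(self) -> int:
        return 2 + self.n_participants + 1 + self.n_sets

    # slices into the unconstrained vector
    @property
    def _sl_beta(self) -> slice:
        return slice(2, 2 + self.n_participants)

    @property
    def _i_rho(self) -> int:
        return 2 + self.n_participants

    @property
    def _sl_tau(self) -> slice:
        return slice(self._i_rho + 1, self._i_rho + 1 + self.n_sets)

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray | float]:
        """Constrained parameter values from an unconstrained vector."""
        return {
            "d": float(theta[0]),
            "e": float(theta[1]),
            "beta": np.exp(theta[self._sl_beta]),
            "rho": float(expit(theta[self._i_rho])),
            "tau": np.exp(theta[self._sl_tau]),
        }

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Jittered start near the prior centre (beta ~ 1, rho ~ 0.5, tau ~ 0.25)."""
        theta = rng.uniform(-0.5, 0.5, size=self.dim)
        theta[self._sl_tau] = np.log(0.25) + rng.uniform(-0.3, 0.3, size=self.n_sets)
        return theta

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Unnormalised log posterior density and its gradient at ``theta``."""
        d, e = theta[0], theta[1]
        b = theta[self._sl_beta]          # log beta_j
        r = theta[self._i_rho]            # logit rho
        t = theta[self._sl_tau]           # log tau_k
        beta = np.exp(b)
        rho = expit(r)
        tau = np.exp(t)

        grad = np.zeros_like(theta)

        # --- priors ---------------------------------------------------------
        logp = -0.5 * (d * d + e * e)
        grad[0] -= d
        grad[1] -= e

        alpha = np.exp(d + e)             # Gamma shape of beta_j
        lam = np.exp(d - e)               # Gamma rate of beta_j
        J = self.n_participants
        # Gamma log-density at beta_j plus the log-Jacobian of beta = exp(b):
        # alpha*(d-e) - lgamma(alpha) + alpha*b_j - lam*exp(b_j)
        logp += J * (alpha * (d - e) - gammaln(alpha)) + alpha * b.sum() - lam * beta.sum()
        psi = digamma(alpha)
        grad[0] += J * alpha * ((d - e) + 1.0 - psi) + alpha * b.sum() - lam * beta.sum()
        grad[1] += J * alpha * ((d - e) - 1.0 - psi) + alpha * b.sum() + lam * beta.sum()
        grad[self._sl_beta] += alpha - lam * beta

        # tau_k ~ Gamma(shape, rate) with log transform
        logp += float(np.sum(self.tau_shape * t - self.tau_rate * tau))
        grad[self._sl_tau] += self.tau_shape - self.tau_rate * tau

        # rho ~ Beta(1,1): flat; only the logit-transform Jacobian contributes
        # log rho + log(1 - rho) = -logaddexp(0, -r) - logaddexp(0, r), stable in the tails
        logp += float(-np.logaddexp(0.0, -r) - np.logaddexp(0.0, r))
        grad[self._i_rho] += 1.0 - 2.0 * rho

        # --- likelihood ------------------------------------------------------
        beta_n = beta[self.j_idx]
        tau_n = tau[self.k_idx]
        sun_term = self.d_sun + (1.0 - rho) * self.d_tree
        dc = beta_n * sun_term + self.d_shade + rho * self.d_tree
        eta = -dc / tau_n
        # log p(y) = y*eta - log(1 + exp(eta)), computed stably
        logp += float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        g = self.y - expit(eta)           # d loglik / d eta, per trial

        grad[self._sl_beta] += np.bincount(
            self.j_idx, weights=g * (-sun_term / tau_n) * beta_n, minlength=J
        )
        grad[self._i_rho] += float(
            np.sum(g * (-(1.0 - beta_n) * self.d_tree / tau_n)) * rho * (1.0 - rho)
        )
        grad[self._sl_tau] += np.bincount(
            self.k_idx, weights=g * (-eta), minlength=self.n_sets
        )
        return logp, grad
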