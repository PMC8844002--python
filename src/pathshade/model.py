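"""Hierarchical Bayesian model of sun-avoiding path choice.

``PathChoiceModel`` is built from a decisions table (one row per binary
choice, with the sun/tree-shade/building-shade metre decomposition of both
options); ``fit()`` runs the no-U-turn sampler and returns a
``PathChoiceResults`` carrying the posterior draws, credible intervals,
convergence diagnostics and summary tables.

The model, for participant j, trial i in choice set k:

    c_ji      = beta_j * [a_sun + (1 - rho) a_tree] + a_shade + rho a_tree
    p(y_ji=1) = 1 / (1 + exp(dc_ji / tau_k))
    d, e      ~ Normal(0, 1)
    beta_j    ~ Gamma(exp(d + e), exp(d - e))     (shape/rate)
    tau_k     ~ Gamma(12.5, 50)
    rho       ~ Beta(1, 1)

Lengths are down-scaled by 0.01 (hectometres) before entering the
likelihood, the scale on which the tau prior is meaningful.  The prior mean
of beta_j given the hyperparameters is exp(2e), so the population-level sun
coefficient can be summarised either as the pooled distribution of the
participants' beta_j draws or via exp(2e); results expose both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

from ._nuts import sample_nuts
from ._posterior import TAU_PRIOR_RATE, TAU_PRIOR_SHAPE, ChoicePosterior
from .choice import LENGTH_SCALE

__all__ = ["PathChoiceModel", "PathChoiceResults"]

logger = logging.getLogger(__name__)

#: Runs whose fraction of divergent post-warmup transitions exceeds this are
#: flagged as unreliable.
DIVERGENCE_RATE_THRESHOLD = 1e-3


class PathChoiceModel:
    """Two-alternative path-choice model with partial pooling over participants.

    Parameters
    ----------
    decisions
        Table with columns ``participant_id``, ``trial_id``, ``choice_set``,
        ``a_sun_A``, ``a_tree_A``, ``a_shade_A``, ``a_sun_B``, ``a_tree_B``,
        ``a_shade_B`` and the binary outcome ``chose_A``.  Rows should be the
        treatment decisions only (choices made with the sun out); see
        ``pathshade.events`` for the filtering pipeline.
    length_scale
        Factor applied to metre lengths before the likelihood (default 0.01).
    tau_prior
        (shape, rate) of the Gamma prior on each choice set's tau.
    """

    def __init__(
        self,
        decisions: pd.DataFrame,
        *,
        length_scale: float = LENGTH_SCALE,
        tau_prior: tuple[float, float] = (TAU_PRIOR_SHAPE, TAU_PRIOR_RATE),
    ) -> None:
        decisions = decisions.copy()
        if "chose_A" not in decisions.columns:
            raise ValueError("decisions table has no 'chose_A' column")
        usable = decisions["chose_A"].notna()
        if not usable.all():
            dropped = decisions.loc[~usable, "participant_id"].unique()
            raise ValueError(
                f"decisions without outcomes for participants {list(dropped)}; "
                "filter or complete them first"
            )
        counts = decisions.groupby("participant_id").size()
        empty = [p for p in counts.index if counts[p] == 0]
        if empty:
            logger.warning("excluding participants with zero usable decisions: %s", empty)
            decisions = decisions[~decisions["participant_id"].isin(empty)]
        self.decisions = decisions.reset_index(drop=True)
        self.length_scale = length_scale
        self.posterior, self.participants, self.choice_sets = ChoicePosterior.from_dataframe(
            self.decisions, length_scale=length_scale,
            tau_shape=tau_prior[0], tau_rate=tau_prior[1],
        )

    @classmethod
    def from_dataframe(cls, decisions: pd.DataFrame, **kwargs) -> "PathChoiceModel":
        return cls(decisions, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PathChoiceModel":
        return cls(pd.read_csv(path), **kwargs)

    @property
    def n_participants(self) -> int:
        return self.posterior.n_participants

    @property
    def n_decisions(self) -> int:
        return len(self.decisions)

    def fit(
        self,
        *,
        chains: int = 4,
        tune: int = 2000,
        draws: int = 10000,
        seed: int | None = None,
        target_accept: float = 0.8,
        max_treedepth: int = 10,
    ) -> "PathChoiceResults":
        """Sample the posterior with NUTS (defaults: 4 chains, 2000 tuning
        steps, 10000 draws per chain) and return the results object."""
        rng = np.random.default_rng(seed)
        inits = [self.posterior.initial_point(rng) for _ in range(chains)]
        raw = sample_nuts(
            self.posterior.logp_grad,
            inits,
            tune=tune,
            draws=draws,
            seed=None if seed is None else int(seed) + 1,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
        )
        idata = self._to_inference_data(raw)
        results = PathChoiceResults(model=self, idata=idata, raw=raw)
        if results.divergence_rate > DIVERGENCE_RATE_THRESHOLD:
            warnings.warn(
                f"{raw.n_divergent} divergent transitions "
                f"({results.divergence_rate:.2%} of post-warmup draws); "
                "posterior estimates may be biased",
                RuntimeWarning,
                stacklevel=2,
            )
        return results

    def _to_inference_data(self, raw) -> az.InferenceData:
        p = self.posterior
        th = raw.draws
        d = th[:, :, 0]
        e = th[:, :, 1]
        beta = np.exp(th[:, :, p._sl_beta])
        from scipy.special import expit

        rho = expit(th[:, :, p._i_rho])
        tau = np.exp(th[:, :, p._sl_tau])
        posterior = xr.Dataset(
            {
                "d": (("chain", "draw"), d),
                "e": (("chain", "draw"), e),
                "beta": (("chain", "draw", "participant"), beta),
                "rho": (("chain", "draw"), rho),
                "tau": (("chain", "draw", "choice_set"), tau),
                "beta_pop": (("chain", "draw"), np.exp(2.0 * e)),
            },
            coords={
                "participant": list(self.participants),
                "choice_set": list(self.choice_sets),
            },
        )
        sample_stats = xr.Dataset(
            {
                "diverging": (("chain", "draw"), raw.diverging),
                "tree_depth": (("chain", "draw"), raw.tree_depth),
                "acceptance_rate": (("chain", "draw"), raw.accept_stat),
                "energy": (("chain", "draw"), raw.energy),
            }
        )
        return az.InferenceData(posterior=posterior, sample_stats=sample_stats)


@dataclass
class PathChoiceResults:
    """Posterior draws and summaries of a fitted :class:`PathChoiceModel`."""

    model: PathChoiceModel
    idata: az.InferenceData
    raw: object = None

    # -- convenience accessors ------------------------------------------------
    @property
    def posterior(self) -> xr.Dataset:
        return self.idata.posterior

    @property
    def divergence_rate(self) -> float:
        return float(self.idata.sample_stats["diverging"].mean())

    @property
    def flagged(self) -> bool:
        """True if the run exceeded the divergence-rate threshold."""
        return self.divergence_rate > DIVERGENCE_RATE_THRESHOLD

    def beta_draws(self, participant=None) -> np.ndarray:
        """Flattened posterior draws of beta_j (all chains)."""
        da = self.posterior["beta"]
        if participant is not None:
            da = da.sel(participant=participant)
        return da.values.reshape(-1, *da.shape[2:])

    def population_beta_draws(
        self, method: str = "pooled", choice_set=None
    ) -> np.ndarray:
        """Population-level beta draws.

        ``method='pooled'``: concatenate every participant's beta_j draws
        (optionally restricted to participants of one choice set) — the
        posterior of the population beta distribution.  ``method='hyper'``:
        draws of the prior mean exp(2e).
        """
        if method == "hyper":
            return self.posterior["beta_pop"].values.ravel()
        if method != "pooled":
            raise ValueError(f"unknown method {method!r}")
        da = self.posterior["beta"]
        if choice_set is not None:
            members = (
                self.model.decisions.loc[
                    self.model.decisions["choice_set"] == choice_set, "participant_id"
                ]
                .unique()
                .tolist()
            )
            if not members:
                raise ValueError(f"no participants in choice set {choice_set!r}")
            da = da.sel(participant=members)
        return da.values.ravel()

    def population_beta(self, method: str = "pooled", choice_set=None) -> float:
        return float(self.population_beta_draws(method, choice_set).mean())

    def prob_beta_above(self, threshold: float = 1.0, choice_set=None) -> float:
        """Posterior mass of the pooled population beta above ``threshold``."""
        draws = self.population_beta_draws("pooled", choice_set)
        return float((draws > threshold).mean())

    # -- tables ---------------------------------------------------------------
    def summary(self, var_names=None, level: float = 0.95) -> pd.DataFrame:
        """Per-parameter posterior mean, central credible interval, rank-
        normalised R-hat and bulk effective sample size."""
        lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
        rows = []
        diags = self.diagnostics()
        post = self.posterior
        names = var_names or ["d", "e", "beta", "rho", "tau", "beta_pop"]
        for name in names:
            da = post[name]
            extra_dims = [d for d in da.dims if d not in ("chain", "draw")]
            if extra_dims:
                dim = extra_dims[0]
                for val in da[dim].values:
                    flat = da.sel({dim: val}).values.ravel()
                    rows.append(self._summary_row(f"{name}[{val}]", flat, lo, hi))
            else:
                rows.append(self._summary_row(name, da.values.ravel(), lo, hi))
        table = pd.DataFrame(rows).set_index("parameter")
        return table.join(diags.set_index("parameter"))

    @staticmethod
    def _summary_row(name: str, flat: np.ndarray, lo: float, hi: float) -> dict:
        qlo, qhi = np.quantile(flat, [lo, hi])
        return {
            "parameter": name,
            "mean": float(flat.mean()),
            f"q{100 * lo:g}%": float(qlo),
            f"q{100 * hi:g}%": float(qhi),
        }

    def diagnostics(self) -> pd.DataFrame:
        """Rank-normalised split R-hat and bulk ESS for every scalar parameter."""
        if self.posterior.sizes["chain"] < 2:
            raise ValueError("R-hat requires at least 2 chains")
        rhat = az.rhat(self.idata, method="rank")
        ess = az.ess(self.idata, method="bulk")
        rows = []
        for name in self.posterior.data_vars:
            r, n = rhat[name], ess[name]
            extra_dims = [d for d in r.dims]
            if extra_dims:
                dim = extra_dims[0]
                for val in r[dim].values:
                    rows.append(
                        {
                            "parameter": f"{name}[{val}]",
                            "rhat": float(r.sel({dim: val})),
                            "ess_bulk": float(n.sel({dim: val})),
                        }
                    )
            else:
                rows.append({"parameter": name, "rhat": float(r), "ess_bulk": float(n)})
        return pd.DataFrame(rows)

    def min_ess(self) -> float:
        return float(self.diagnostics()["ess_bulk"].min())

    def max_rhat(self) -> float:
        return float(self.diagnostics()["rhat"].max())

    # -- plots ----------------------------------------------------------------
    def plot_forest(self, ax=None):
        """Forest plot of per-participant beta_j means and 95% intervals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.25 * len(self.model.participants) + 1))
        da = self.posterior["beta"]
        means = da.mean(("chain", "draw")).values
        q = da.quantile([0.025, 0.975], dim=("chain", "draw")).values
        ypos = np.arange(len(self.model.participants))
        ax.errorbar(
            means, ypos,
            xerr=[means - q[0], q[1] - means],
            fmt="o", ms=3, lw=1, capsize=2, color="k",
        )
        ax.axvline(1.0, color="crimson", lw=0.8, ls="--")
        ax.set_yticks(ypos, self.model.participants, fontsize=6)
        ax.set_xlabel(r"$\beta_j$ (distance-inflating coefficient of the sun)")
        return ax

    def plot_population(self, ax=None, choice_set=None):
        """Density of the pooled population beta with the mass above 1 hatched."""
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        if ax is None:
            _, ax = plt.subplots()
        draws = self.population_beta_draws("pooled", choice_set)
        kde = gaussian_kde(draws)
        grid = np.linspace(draws.min(), draws.max(), 400)
        dens = kde(grid)
        ax.plot(grid, dens, color="k")
        above = grid > 1.0
        ax.fill_between(grid[above], dens[above], alpha=0.4, hatch="///", color="tan")
        ax.axvline(float(draws.mean()), color="crimson", lw=1)
        ax.set_xlabel(r"population $\beta$")
        ax.set_ylabel("posterior density")
        return ax
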