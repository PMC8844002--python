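"""Study-style outputs: posterior tables, indifference arithmetic, strategy counts.

Turns a fitted :class:`~pathshade.model.PathChoiceResults` into the tables a
report needs — per-participant forest summaries, pooled and per-choice-set
population summaries with the posterior mass above beta = 1, the
tree-shade-intensity and temperature summaries — plus the indifference-curve
arithmetic (how many metres of sun trade against a shaded stretch at a given
beta) and the strategy-classification tabulation over a grid of perceived
tree-shade intensities.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .choice import (
    PathComposition,
    TrialRecord,
    classify_trial,
    mixed_exposure_sun_component,
    sun_equivalent_distance,
)

__all__ = [
    "indifference_table",
    "report_posterior",
    "report_strategies",
    "headline_numbers",
    "DEFAULT_RHO_GRID",
]

DEFAULT_RHO_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def indifference_table(
    betas,
    shade_length: float = 100.0,
    fixed_shade: float = 50.0,
) -> pd.DataFrame:
    """Sun-equivalents of a fully shaded walk for each beta.

    Each row gives the sun distance with the same cost as ``shade_length``
    of building shade, and the sun component of a mixed walk that starts
    with ``fixed_shade`` of shade.  Rounded to whole metres as reported.
    """
    rows = []
    for beta in np.atleast_1d(np.asarray(betas, dtype=float)):
        rows.append(
            {
                "beta": float(beta),
                "shade_length_m": shade_length,
                "equivalent_sun_m": sun_equivalent_distance(shade_length, beta),
                "mixed_fixed_shade_m": fixed_shade,
                "mixed_sun_m": mixed_exposure_sun_component(shade_length, fixed_shade, beta),
            }
        )
    return pd.DataFrame(rows)


def report_posterior(results, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Posterior summary tables of a fitted path-choice model.

    Returns (and optionally writes as CSV):

    * ``participants`` — per-participant beta_j mean, 95% interval, P(beta_j > 1);
    * ``population`` — pooled-draws population beta (overall and per choice
      set) and the hyperprior mean exp(2e), each with P(beta > 1);
    * ``rho`` and ``tau`` — tree-shade intensity and choice-set temperatures;
    * ``diagnostics`` — rank-normalised R-hat and bulk ESS per parameter.
    """
    post = results.posterior
    participants = []
    for pid in post["participant"].values:
        draws = results.beta_draws(pid)
        qlo, qhi = np.quantile(draws, [0.025, 0.975])
        participants.append(
            {
                "participant_id": pid,
                "beta_mean": draws.mean(),
                "q2.5%": qlo,
                "q97.5%": qhi,
                "p_beta_gt_1": (draws > 1.0).mean(),
            }
        )
    participants = pd.DataFrame(participants)

    population_rows = []
    pooled = results.population_beta_draws("pooled")
    population_rows.append(_pop_row("pooled_all", pooled))
    for k in post["choice_set"].values:
        population_rows.append(_pop_row(f"pooled_set_{k}", results.population_beta_draws("pooled", choice_set=k)))
    population_rows.append(_pop_row("hyper_exp_2e", results.population_beta_draws("hyper")))
    population = pd.DataFrame(population_rows)

    rho_draws = post["rho"].values.ravel()
    rho = pd.DataFrame([{
        "mean": rho_draws.mean(),
        "q2.5%": np.quantile(rho_draws, 0.025),
        "q97.5%": np.quantile(rho_draws, 0.975),
    }])
    tau_rows = []
    for k in post["choice_set"].values:
        d = post["tau"].sel(choice_set=k).values.ravel()
        tau_rows.append({
            "choice_set": k,
            "mean": d.mean(),
            "q2.5%": np.quantile(d, 0.025),
            "q97.5%": np.quantile(d, 0.975),
        })
    tau = pd.DataFrame(tau_rows)

    tables = {
        "participants": participants,
        "population": population,
        "rho": rho,
        "tau": tau,
        "diagnostics": results.diagnostics(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
    return tables


def _pop_row(label: str, draws: np.ndarray) -> dict:
    return {
        "summary": label,
        "mean": draws.mean(),
        "q2.5%": np.quantile(draws, 0.025),
        "q97.5%": np.quantile(draws, 0.975),
        "p_beta_gt_1": (draws > 1.0).mean(),
    }


def _row_to_trial(row: pd.Series) -> TrialRecord:
    return TrialRecord(
        participant_id=str(row["participant_id"]),
        trial_id=int(row["trial_id"]),
        choice_set=int(row.get("choice_set", 1)),
        option_A=PathComposition(row["a_sun_A"], row["a_tree_A"], row["a_shade_A"]),
        option_B=PathComposition(row["a_sun_B"], row["a_tree_B"], row["a_shade_B"]),
        chose_A=bool(row["chose_A"]),
    )


def classify_decisions(decisions: pd.DataFrame, rho: float) -> pd.DataFrame:
    """Strategy label of every decision at a given tree-shade intensity."""
    labels = [classify_trial(_row_to_trial(row), rho) for _, row in decisions.iterrows()]
    out = decisions[["participant_id", "trial_id"]].copy()
    out["trial_type"] = [l.trial_type.value for l in labels]
    out["chosen_strategy"] = [l.chosen_strategy.value for l in labels]
    return out

def report_strategies(decisions: pd.DataFrame, rho_grid=DEFAULT_RHO_GRID) -> pd.DataFrame:
    """Counts of each chosen strategy at every rho in the grid.

    Lowering rho moves tree-shaded options toward "sunny", so choices of a
    longer tree-shaded option that look non-optimal at rho = 1 re-classify
    as sun-minimising at lower rho.  One row per rho with one column per
    strategy; every decision is counted exactly once per row.
    """
    rows = []
    for rho in rho_grid:
        if len(decisions) == 0:
            continue
        labels = classify_decisions(decisions, rho)
        counts = labels["chosen_strategy"].value_counts()
        rows.append({
            "rho": rho,
            "sun_minimising": int(counts.get("sun_minimising", 0)),
            "distance_minimising": int(counts.get("distance_minimising", 0)),
            "optimal": int(counts.get("optimal", 0)),
            "non_optimal": int(counts.get("non_optimal", 0)),
            "indifferent": int(counts.get("indifferent", 0)),
        })
    columns = ["rho", "sun_minimising", "distance_minimising", "optimal", "non_optimal", "indifferent"]
    return pd.DataFrame(rows, columns=columns)


def headline_numbers(results) -> dict[str, float]:
    """The headline quantities of a fitted model, with their derivations.

    * population beta (pooled posterior draws of every beta_j, and the
      hyperprior mean exp(2e));
    * per-choice-set pooled beta;
    * rho (perceived tree-shade intensity) posterior mean;
    * the shade discount factor 1/beta; and the percentage by which a fully
      shaded path feels closer than a sunny one, 100 * (1 - 1/beta).
    """
    beta_pooled = results.population_beta("pooled")
    out = {
        "beta_population_pooled": round(beta_pooled, 2),
        "beta_population_hyper": round(results.population_beta("hyper"), 2),
        "rho_mean": round(float(results.posterior["rho"].mean()), 2),
        "shade_discount_factor": round(1.0 / beta_pooled, 2),
        "percent_closer": round(100.0 * (1.0 - 1.0 / beta_pooled)),
    }
    for k in results.posterior["choice_set"].values:
        out[f"beta_pooled_set_{k}"] = round(results.population_beta("pooled", choice_set=k), 2)
        out[f"tau_set_{k}"] = round(float(results.posterior["tau"].sel(choice_set=k).mean()), 3)
    return out
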