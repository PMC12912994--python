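"""Simulate-and-refit pipelines: model recovery, parameter recovery, and
the self-fulfilling-prophecy dynamics experiment.

The prophecy experiment encodes the family's central theoretical contrast:
with a single learning rate, both cues' expectancies converge to the mean
stimulus value and the cue effect extinguishes; with a confirmation bias
(alpha_c > alpha_i) the cue-induced gap can persist — or grow — despite the
cues carrying no objective information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import Prior, fit_cohort, rfx_bms
from .models import ModelSpec, Params, run_model
from .synthdata import DesignSpec, PopulationSpec, default_population, generate_design, simulate_cohort
from .trialdata import RATING_COLUMNS

logger = logging.getLogger(__name__)

#: theoretically pivotal reduced model set used by recovery defaults
DEFAULT_RECOVERY_MODELS = ("M1", "M2a", "M2c", "M3a", "M3c")


@dataclass
class ConfusionMatrix:
    """Generating model x selected model counts over replicate cohorts."""

    counts: pd.DataFrame
    proportions: pd.DataFrame
    selection_rule: str
    winners: pd.DataFrame  # one row per (generator, replicate)

    @property
    def diagonal_fraction(self) -> float:
        c = self.counts.to_numpy(dtype=float)
        return float(np.trace(c) / c.sum())


def model_recovery(
    model_ids=DEFAULT_RECOVERY_MODELS,
    design: DesignSpec | None = None,
    n_subjects: int = 20,
    n_reps: int = 3,
    sigma: float = 0.02,
    seed: int = 0,
    n_starts: int = 2,
) -> ConfusionMatrix:
    """Confusion matrix over generator x candidate model space.

    For each generating model and replicate: simulate a cohort from the
    default population for that model, fit every candidate model to every
    subject, and select the winner by highest random-effects model
    frequency (pxp as tie-break).
    """
    if len(model_ids) < 2:
        raise ValueError("need at least 2 candidate models")
    design = design or DesignSpec()
    specs = [ModelSpec(m) for m in model_ids]
    ss = np.random.SeedSequence(seed)
    win_rows = []
    for gen in model_ids:
        for rep in range(n_reps):
            child = ss.spawn(1)[0]
            s = int(child.generate_state(1)[0] % (2**31))
            pop = default_population(gen, n_subjects=n_subjects, sigma=sigma)
            table, _ = simulate_cohort(design, pop, n_tasks=1, seed=s)
            evidence, _ = fit_cohort(specs, table, n_starts=n_starts, seed=s)
            cmp_res = rfx_bms(evidence, n_draws=100_000, seed=s)
            order = np.lexsort((cmp_res.pxp, cmp_res.frequencies))
            winner = cmp_res.model_ids[order[-1]]
            win_rows.append({"generator": gen, "replicate": rep, "selected": winner,
                             "frequency": cmp_res.frequencies[order[-1]]})
            logger.info("model_recovery: gen=%s rep=%d -> %s", gen, rep, winner)
    winners = pd.DataFrame(win_rows)
    counts = (
        winners.groupby(["generator", "selected"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=list(model_ids), columns=list(model_ids), fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    return ConfusionMatrix(counts, props, "model_frequency", winners)


@dataclass
class ParameterRecovery:
    """True vs. MAP-estimated parameters for one generating model."""

    model_id: str
    table: pd.DataFrame  # participant, parameter, true, estimated
    spearman: dict  # parameter -> rho (NaN when truth is constant)
    bias: dict  # parameter -> mean(estimated - true)


def parameter_recovery(
    model_id: str = "M3c",
    design: DesignSpec | None = None,
    pop: PopulationSpec | None = None,
    seed: int = 0,
    n_starts: int = 4,
    prior: Prior | None = None,
) -> ParameterRecovery:
    """Simulate a cohort from one model, refit the same model, and score
    per-parameter recovery (Spearman correlation and mean bias)."""
    design = design or DesignSpec()
    pop = pop or default_population(model_id)
    spec = ModelSpec(model_id)
    table, truth = simulate_cohort(design, pop, n_tasks=1, seed=seed)
    _, params_df = fit_cohort([spec], table, prior=prior, n_starts=n_starts, seed=seed)
    est = params_df[params_df["model_id"] == model_id]
    merged = truth.merge(
        est, on=["participant_id", "task"], suffixes=("_true", "_est")
    )
    rows, rho, bias = [], {}, {}
    for name in spec.param_names:
        t = merged[f"{name}_true"].to_numpy(dtype=float)
        e = merged[f"{name}_est"].to_numpy(dtype=float)
        for pid, tv, ev in zip(merged["participant_id"], t, e):
            rows.append({"participant_id": pid, "parameter": name,
                         "true": tv, "estimated": ev})
        if np.ptp(t) == 0:
            rho[name] = np.nan
        else:
            rho[name] = float(stats.spearmanr(t, e).statistic)
        bias[name] = float(np.mean(e - t))
    return ParameterRecovery(model_id, pd.DataFrame(rows), rho, bias)


def _long_design(n_trials: int, design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """A single-session design skeleton with ``n_trials`` trials (balanced
    cells per 6-trial block), for long-horizon dynamics runs."""
    tpc = max(1, n_trials // 6)
    d = DesignSpec(
        n_sessions=1,
        runs_per_session=1,
        trials_per_cell_per_run=tpc,
        cue_display_mean_high=design.cue_display_mean_high,
        cue_display_mean_low=design.cue_display_mean_low,
        cue_display_sd=design.cue_display_sd,
        rating_scale_max=design.rating_scale_max,
    )
    return generate_design(d, rng)


def prophecy_experiment(
    param_grid: list[dict],
    design: DesignSpec | None = None,
    horizon_trials: int = 2000,
    n_blocks: int = 10,
    n_seeds: int = 10,
    first_window: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-horizon cue-gap dynamics per parameter-grid cell.

    Each grid cell is a dict with ``model_id`` and parameter values (e.g.
    ``{"model_id": "M3c", "alpha_c": 0.5, "alpha_i": 0.05, "omega": 0.3,
    "beta_O": 0.3}``).  For each cell the model generates ratings over
    ``horizon_trials`` trials; the per-block mean high-cue minus low-cue
    gap in expectation and perceptual ratings is averaged over ``n_seeds``
    runs.  The persistence ratio is final-block gap / initial-window gap of
    the expectation ratings (0 = full extinction, ~1 = fully persistent);
    the baseline window covers only the first ``first_window`` trials so it
    measures the cue-seeded gap before extinction can dilute it.
    """
    design = design or DesignSpec()
    rows = []
    for cell_id, cell in enumerate(param_grid):
        cell = dict(cell)
        spec = ModelSpec(cell.pop("model_id"))
        cell.setdefault("sigma2_E", 0.02**2)
        cell.setdefault("sigma2_O", 0.02**2)
        params = Params.for_model(spec, **cell)
        ss = np.random.SeedSequence((seed, cell_id))
        gaps_E = np.zeros((n_seeds, n_blocks))
        gaps_O = np.zeros((n_seeds, n_blocks))
        first_E = np.zeros(n_seeds)
        for r, child in enumerate(ss.spawn(n_seeds)):
            rng = np.random.default_rng(child)
            skel = _long_design(horizon_trials, design, rng)
            unit = skel.copy()
            unit[RATING_COLUMNS] = unit[RATING_COLUMNS] / design.rating_scale_max
            traj = run_model(spec, params, unit, mode="generative", rng=rng)
            cue = unit["cue_type"].to_numpy()
            idx = np.arange(len(unit))
            block = np.minimum((idx * n_blocks) // len(unit), n_blocks - 1)
            w = idx < first_window
            first_E[r] = (
                traj.sim_expectation[w & (cue == "high")].mean()
                - traj.sim_expectation[w & (cue == "low")].mean()
            )
            for b in range(n_blocks):
                hi = (block == b) & (cue == "high")
                lo = (block == b) & (cue == "low")
                gaps_E[r, b] = traj.sim_expectation[hi].mean() - traj.sim_expectation[lo].mean()
                gaps_O[r, b] = traj.sim_perception[hi].mean() - traj.sim_perception[lo].mean()
        mE, mO = gaps_E.mean(axis=0), gaps_O.mean(axis=0)
        base = first_E.mean()
        persistence = float(mE[-1] / base) if base != 0 else np.nan
        for b in range(n_blocks):
            rows.append(
                {
                    "cell": cell_id,
                    "model_id": spec.model_id,
                    **{k: params.get(k) for k in spec.param_names},
                    "block": b,
                    "expectation_gap": mE[b],
                    "perception_gap": mO[b],
                    "persistence_ratio": persistence,
                }
            )
    return pd.DataFrame(rows)


def persistence_ratios(traj_df: pd.DataFrame) -> pd.Series:
    """Per-cell persistence ratio from a prophecy trajectory table."""
    return traj_df.groupby("cell")["persistence_ratio"].first()
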