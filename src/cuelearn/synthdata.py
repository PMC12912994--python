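"""Synthetic cohorts under the factorial cue x stimulus design.

Emulates the paradigm: a 2 (high/low social cue) x 3 (stimulus intensity)
design with 12 trials per cell, spread over 3 sessions x 2 runs, cue display
means drawn independently of stimulus intensity, and ratings generated by a
model from the family with Gaussian rating noise.  Ground-truth parameters
are emitted alongside every cohort so recovery can be scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import PARAM_BOUNDS, ModelSpec, Params, run_model, fill_ratings
from .trialdata import DEFAULT_SCALE, RATING_COLUMNS, TASKS, TrialTable


@dataclass
class DesignSpec:
    """Layout of one subject x task: sessions, runs, and per-run cell counts.

    Defaults give the canonical 3 sessions x 2 runs x (6 cells x 2 trials)
    = 72 trials, i.e. 12 trials per cue x intensity condition overall.
    Cue display means (the averaged dots participants see) are drawn per
    trial from a Normal per cue type, independent of stimulus intensity.
    """

    n_sessions: int = 3
    runs_per_session: int = 2
    trials_per_cell_per_run: int = 2
    cue_display_mean_high: float = 120.0
    cue_display_mean_low: float = 60.0
    cue_display_sd: float = 8.0
    rating_scale_max: float = DEFAULT_SCALE

    def __post_init__(self):
        if self.cue_display_sd < 0:
            raise ValueError("cue display sd must be >= 0")
        if min(self.n_sessions, self.runs_per_session, self.trials_per_cell_per_run) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_trials(self) -> int:
        return 6 * self.trials_per_cell_per_run * self.runs_per_session * self.n_sessions


@dataclass
class PopulationSpec:
    """Group-level parameter distribution for a generating model.

    ``dists`` maps a parameter name to (mean, sd); subjects are drawn from
    the Normal truncated to the parameter's legal range.  ``rho`` optionally
    imposes a cross-task correlation on selected parameters via a shared
    Gaussian copula factor per subject.
    """

    model_id: str = "M3c"
    n_subjects: int = 40
    dists: dict = field(default_factory=dict)
    rho: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (m, s) in self.dists.items():
            if s < 0:
                raise ValueError(f"{name}: sd must be >= 0")
        for name, r in self.rho.items():
            if abs(r) > 1:
                raise ValueError(f"{name}: |rho| must be <= 1")


#: group distributions used by recovery defaults (sigma = 0.05 on unit scale)
DEFAULT_DISTS = {
    "M1": {"E_low_fix": (0.33, 0.10), "E_high_fix": (0.67, 0.10),
           "omega": (0.2, 0.08)},
    "single": {"alpha": (0.30, 0.15), "omega": (0.2, 0.08)},
    "dual": {"alpha_c": (0.45, 0.20), "alpha_i": (0.15, 0.10), "omega": (0.2, 0.08)},
    "carry_E": {"beta_E": (0.3, 0.15)},
    "carry_O": {"beta_O": (0.3, 0.15)},
    "tracker": {"b_low": (-0.15, 0.08), "b_high": (0.15, 0.08)},
}
DEFAULT_SIGMA = 0.05  # rating noise sd on the unit scale


def default_population(
    model_id: str = "M3c", n_subjects: int = 40, sigma: float = DEFAULT_SIGMA,
    rho: dict | None = None,
) -> PopulationSpec:
    """Population spec with the package's default group distributions."""
    spec = ModelSpec(model_id)
    dists: dict = {}
    if not spec.learns:
        dists.update(DEFAULT_DISTS["M1"])
    else:
        dists.update(DEFAULT_DISTS["single" if spec.n_rates == 1 else "dual"])
        if spec.carryover == "expectation":
            dists.update(DEFAULT_DISTS["carry_E"])
        elif spec.carryover == "perception":
            dists.update(DEFAULT_DISTS["carry_O"])
        if spec.tracker:
            dists.update(DEFAULT_DISTS["tracker"])
    dists["sigma2_E"] = (sigma**2, 0.0)
    dists["sigma2_O"] = (sigma**2, 0.0)
    return PopulationSpec(model_id, n_subjects, dists, rho or {})


def generate_design(
    design: DesignSpec,
    rng: np.random.Generator | int | None = None,
    participant_id: str = "S001",
    task: str = "pain",
) -> pd.DataFrame:
    """One subject x task trial skeleton (ratings NaN, everything else set).

    Within each run the 6 cue x intensity cells each appear exactly
    ``trials_per_cell_per_run`` times in a uniformly shuffled order, so
    P(level | cue) = 1/3 holds exactly per run by construction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cells = list(itertools.product(("low", "high"), (1, 2, 3)))
    rows = []
    trial_index = 0
    for session in range(1, design.n_sessions + 1):
        for run in range(1, design.runs_per_session + 1):
            block = cells * design.trials_per_cell_per_run
            order = rng.permutation(len(block))
            for i in order:
                cue, level = block[i]
                trial_index += 1
                mean = (
                    design.cue_display_mean_high
                    if cue == "high"
                    else design.cue_display_mean_low
                )
                disp = float(
                    np.clip(
                        rng.normal(mean, design.cue_display_sd),
                        0.0,
                        design.rating_scale_max,
                    )
                )
                rows.append(
                    {
                        "participant_id": participant_id,
                        "task": task,
                        "session": session,
                        "run": run,
                        "trial_index": trial_index,
                        "cue_type": cue,
                        "cue_display_mean": disp,
                        "stimulus_level": level,
                        "expectation_rating": np.nan,
                        "perceptual_rating": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _truncnorm_ppf(q: float, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.ppf(q, a, b, loc=mean, scale=sd))


def _legal_range(name: str) -> tuple[float, float]:
    lo, hi = PARAM_BOUNDS[name]
    if name.startswith("sigma2"):
        lo, hi = 1e-6, 1.0  # variances: positive, bounded by the unit scale
    return lo, hi


def sample_population(
    pop: PopulationSpec, rng: np.random.Generator | int | None = None,
    n_tasks: int = 1,
) -> list[dict[str, Params]]:
    """Draw per-subject (x task) parameter sets from the group distributions.

    Returns one dict per subject mapping task name to :class:`Params`.
    Cross-task correlation rho on a parameter is induced by a Gaussian
    copula: z = sqrt(rho) z_subject + sqrt(1-rho) z_task, mapped through the
    truncated-normal quantile function (rho=1 gives identical values across
    tasks; rho=0 independent draws).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spec = ModelSpec(pop.model_id)
    tasks = TASKS[:n_tasks]
    out = []
    for _ in range(pop.n_subjects):
        shared = {name: rng.standard_normal() for name in pop.dists}
        per_task = {}
        for task in tasks:
            kw = {}
            for name, (m, s) in pop.dists.items():
                r = float(pop.rho.get(name, 0.0))
                if r < 0:
                    raise ValueError("cross-task rho must be non-negative")
                z = np.sqrt(r) * shared[name] + np.sqrt(1.0 - r) * rng.standard_normal()
                q = float(stats.norm.cdf(z))
                lo, hi = _legal_range(name)
                kw[name] = _truncnorm_ppf(q, m, s, lo, hi)
            per_task[task] = Params.for_model(spec, **kw)
        out.append(per_task)
    return out


def simulate_cohort(
    design: DesignSpec,
    pop: PopulationSpec,
    n_tasks: int = 1,
    seed: int | None = 0,
) -> tuple[TrialTable, pd.DataFrame]:
    """Simulate a full cohort: design skeletons filled by the generative model.

    Returns the trial table (on the 0-180 rating scale) and a ground-truth
    DataFrame with one row per subject x task holding model_id and the true
    parameters.
    """
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_design, rng_gen = (np.random.default_rng(s) for s in ss.spawn(3))
    spec = ModelSpec(pop.model_id)
    tasks = TASKS[:n_tasks]
    subjects = sample_population(pop, rng_pop, n_tasks=n_tasks)

    frames, truth_rows = [], []
    for i, per_task in enumerate(subjects):
        pid = f"S{i + 1:03d}"
        for task in tasks:
            params = per_task[task]
            skel = generate_design(design, rng_design, participant_id=pid, task=task)
            unit = skel.copy()
            unit[RATING_COLUMNS] = unit[RATING_COLUMNS] / design.rating_scale_max
            traj = run_model(spec, params, unit, mode="generative", rng=rng_gen)
            filled = fill_ratings(unit, traj)
            filled[RATING_COLUMNS] = filled[RATING_COLUMNS] * design.rating_scale_max
            frames.append(filled)
            row = {"participant_id": pid, "task": task, "model_id": pop.model_id}
            for name in spec.param_names:
                row[name] = params.get(name)
            truth_rows.append(row)

    df = pd.concat(frames, ignore_index=True)
    table = TrialTable(df, design.rating_scale_max, normalized=False)
    return table, pd.DataFrame(truth_rows)
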