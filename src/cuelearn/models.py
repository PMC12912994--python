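r"""The nine-model generative family linking cue expectations and perception.

Every model says perception is a biased blend of the objective stimulus and
the current expectation,

    O_hat_t = omega * Etilde_t + (1 - omega) * S_t,

and (except the no-learning base model M1) updates cue expectancies with the
delta rule

    E_{t+1}^cue = E_t^cue + alpha * delta_t,     delta_t = O_t - Etilde_t,

where O_t is the *reported* perception — the participant's own experience is
the teaching signal, closing the loop that makes self-fulfilling prophecies
possible.  Model variants differ in:

* number of learning rates: none (M1), one (M2a-d), or two (M3a-d) — with
  separate rates for cue-congruent (alpha_c) and cue-incongruent (alpha_i)
  prediction errors, the signature of confirmation bias;
* carryover: none (a), expectation carryover beta_E (b), perceptual
  carryover beta_O (c), each a convex mixture perturbing the *effective*
  expectation without touching the learned value; or a single general
  expectancy tracker with additive cue offsets (d).

All quantities live on the unit scale ([0, 1] after dividing ratings by the
scale maximum); rating likelihoods are Gaussian with variances sigma2_E and
sigma2_O shared by every model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MODEL_IDS = ("M1", "M2a", "M2b", "M2c", "M3a", "M3b", "M3c", "M3d", "M2d")
# canonical display order
MODEL_ORDER = ("M1", "M2a", "M2b", "M2c", "M2d", "M3a", "M3b", "M3c", "M3d")

_CARRYOVER = {"a": "none", "b": "expectation", "c": "perception", "d": "none"}

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one model in the family, with derived structure flags."""

    model_id: str

    def __post_init__(self):
        if self.model_id not in MODEL_ORDER:
            raise ValueError(f"unknown model_id {self.model_id!r}")

    @property
    def n_rates(self) -> int:
        return {"M1": 0, "M2": 1, "M3": 2}[self.model_id[:2]]

    @property
    def learns(self) -> bool:
        return self.n_rates > 0

    @property
    def variant(self) -> str:
        return self.model_id[2] if len(self.model_id) == 3 else ""

    @property
    def carryover(self) -> str:
        return _CARRYOVER.get(self.variant, "none")

    @property
    def tracker(self) -> bool:
        return self.variant == "d"

    @property
    def param_names(self) -> tuple[str, ...]:
        """Free parameters of this model, in canonical order."""
        names: list[str] = []
        if self.n_rates == 1:
            names.append("alpha")
        elif self.n_rates == 2:
            names += ["alpha_c", "alpha_i"]
        names.append("omega")
        if self.carryover == "expectation":
            names.append("beta_E")
        elif self.carryover == "perception":
            names.append("beta_O")
        if self.tracker:
            names += ["b_low", "b_high"]
        if not self.learns:
            names += ["E_low_fix", "E_high_fix"]
        names += ["sigma2_E", "sigma2_O"]
        return tuple(names)


#: legal range of each parameter on the constrained scale
PARAM_BOUNDS = {
    "alpha": (0.0, 1.0),
    "alpha_c": (0.0, 1.0),
    "alpha_i": (0.0, 1.0),
    "omega": (0.0, 1.0),
    "beta_E": (0.0, 1.0),
    "beta_O": (0.0, 1.0),
    "b_low": (-0.5, 0.5),
    "b_high": (-0.5, 0.5),
    "E_low_fix": (0.0, 1.0),
    "E_high_fix": (0.0, 1.0),
    "sigma2_E": (0.0, np.inf),
    "sigma2_O": (0.0, np.inf),
}


@dataclass
class Params:
    """Free parameters of one model (unit scale).

    ``alpha`` fills both rates for single-rate models; parameters irrelevant
    to a given :class:`ModelSpec` may be left None and are ignored.
    """

    alpha_c: float | None = None
    alpha_i: float | None = None
    omega: float | None = None
    beta_E: float | None = None
    beta_O: float | None = None
    b_low: float | None = None
    b_high: float | None = None
    E_low_fix: float | None = None
    E_high_fix: float | None = None
    sigma2_E: float = 0.0025
    sigma2_O: float = 0.0025

    @property
    def alpha(self) -> float | None:
        return self.alpha_c

    def get(self, name: str) -> float:
        if name == "alpha":
            return self.alpha_c
        return getattr(self, name)

    @classmethod
    def for_model(cls, spec: ModelSpec, **kwargs) -> "Params":
        """Build a parameter set for ``spec``; ``alpha=`` sets both rates."""
        if "alpha" in kwargs:
            a = kwargs.pop("alpha")
            kwargs.setdefault("alpha_c", a)
            kwargs.setdefault("alpha_i", a)
        p = cls(**kwargs)
        if spec.n_rates == 1 and p.alpha_i is None:
            p.alpha_i = p.alpha_c
        p.validate(spec)
        return p

    def validate(self, spec: ModelSpec) -> None:
        for name in spec.param_names:
            v = self.get(name)
            if v is None:
                raise ValueError(f"{spec.model_id} requires parameter {name}")
            lo, hi = PARAM_BOUNDS[name]
            if name.startswith("sigma2"):
                if not v > 0:
                    raise ValueError(f"{name} must be > 0, got {v}")
            elif not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass
class LatentState:
    """Learner state carried across trials (all unit scale)."""

    E_low: float = 0.5
    E_high: float = 0.5
    G: float = 0.5
    prev_O: float | None = None
    prev_Etilde: float | None = None
    n_clips: int = 0


@dataclass
class Trajectory:
    """Per-trial latents implied by a model on one subject's trial sequence."""

    Etilde: np.ndarray
    O_hat: np.ndarray
    delta: np.ndarray
    congruent: np.ndarray
    E_low: np.ndarray  # state *after* each trial's update
    E_high: np.ndarray
    sim_expectation: np.ndarray | None = None
    sim_perception: np.ndarray | None = None
    n_clips: int = 0

    def __len__(self):
        return len(self.Etilde)


_ANCHORS = {1: 0.25, 2: 0.50, 3: 0.75}


def stimulus_value(stimulus_level: int) -> float:
    """Fixed unit-scale anchor of a stimulus intensity level.

    Equally spaced interior anchors {0.25, 0.50, 0.75} keep model
    predictions inside the rating scale for every omega; the mapping is
    shared by all models and is not a free parameter.
    """
    try:
        return _ANCHORS[int(stimulus_level)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"stimulus_level must be 1, 2 or 3; got {stimulus_level!r}")


def _clip01(x: float, state: LatentState) -> float:
    if x < 0.0:
        state.n_clips += 1
        return 0.0
    if x > 1.0:
        state.n_clips += 1
        return 1.0
    return x


def initialize_state(spec: ModelSpec, params: Params, trials: pd.DataFrame) -> LatentState:
    """Initial latent state for one subject's (unit-scale) trial sequence.

    Learning models seed each cue expectancy from the displayed cue mean of
    the first trial of that cue type (0.5 if the cue type never occurs);
    tracker variants start the general expectancy at 0.5; the no-learning
    model M1 uses its free fixed expectancies.
    """
    if len(trials) == 0:
        raise ValueError("cannot initialize state from an empty trial table")
    state = LatentState()
    if not spec.learns:
        state.E_low = float(params.E_low_fix)
        state.E_high = float(params.E_high_fix)
    elif spec.tracker:
        state.G = 0.5
    else:
        for cue, attr in (("low", "E_low"), ("high", "E_high")):
            sub = trials[trials["cue_type"] == cue]
            val = float(sub["cue_display_mean"].iloc[0]) if len(sub) else 0.5
            setattr(state, attr, val)
    return state


def effective_expectation(
    state: LatentState, params: Params, cue_type: str, spec: ModelSpec
) -> float:
    """The expectation the participant acts on (and reports) this trial.

    Carryover variants mix the learned cue expectancy with the previous
    trial's effective expectation (beta_E) or reported perception (beta_O);
    tracker variants offset the general expectancy by a cue-specific bias.
    """
    E_cue = state.E_high if cue_type == "high" else state.E_low
    if spec.tracker:
        b = params.b_high if cue_type == "high" else params.b_low
        return _clip01(state.G + b, state)
    if spec.carryover == "expectation" and state.prev_Etilde is not None:
        return (1.0 - params.beta_E) * E_cue + params.beta_E * state.prev_Etilde
    if spec.carryover == "perception" and state.prev_O is not None:
        return (1.0 - params.beta_O) * E_cue + params.beta_O * state.prev_O
    return E_cue


def predict_outcome(Etilde: float, stimulus_level: int, omega: float) -> float:
    """Perception as a convex blend of expectation and stimulus anchor."""
    return omega * Etilde + (1.0 - omega) * stimulus_value(stimulus_level)


def prediction_error(observed_O: float, Etilde: float) -> float:
    """delta = reported perception minus effective expectation."""
    return observed_O - Etilde


def is_congruent(cue_type: str, delta: float) -> bool:
    """A prediction error confirms the cue when its sign matches the cue's
    valence: aversive surprise (delta > 0) under a high cue, appetitive
    surprise (delta < 0) under a low cue.  delta == 0 counts incongruent
    (inconsequential: the update is zero)."""
    return (cue_type == "high" and delta > 0) or (cue_type == "low" and delta < 0)


def update_state(
    state: LatentState,
    cue_type: str,
    delta: float,
    params: Params,
    spec: ModelSpec,
    observed_O: float | None = None,
    Etilde: float | None = None,
) -> LatentState:
    """Apply the delta-rule update for one trial, in place.

    The rate is alpha_c on cue-congruent trials and alpha_i otherwise
    (identical for single-rate models).  Non-tracker models update only the
    current cue's expectancy; tracker variants update the general expectancy.
    ``observed_O`` / ``Etilde`` refresh the carryover memory.
    """
    if not spec.learns:
        raise ValueError("M1 has no learning update")
    rate = params.alpha_c if is_congruent(cue_type, delta) else params.alpha_i
    if spec.tracker:
        state.G = _clip01(state.G + rate * delta, state)
    elif cue_type == "high":
        state.E_high = _clip01(state.E_high + rate * delta, state)
    else:
        state.E_low = _clip01(state.E_low + rate * delta, state)
    if observed_O is not None:
        state.prev_O = observed_O
    if Etilde is not None:
        state.prev_Etilde = Etilde
    return state


def run_model(
    spec: ModelSpec,
    params: Params,
    trials: pd.DataFrame,
    mode: str = "conditioned",
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Iterate one subject's trials chronologically under a model.

    conditioned mode (used by the likelihood): latents evolve from the
    *observed* perceptual ratings.  generative mode: expectation and
    perceptual ratings are drawn from the Gaussian rating model
    (clipped to [0, 1]) and the drawn perception drives learning; pass the
    same ``rng`` seed to reproduce draws.

    ``trials`` must be unit-scale and chronologically ordered.
    """
    params.validate(spec)
    if mode not in ("conditioned", "generative"):
        raise ValueError(f"unknown mode {mode!r}")
    generative = mode == "generative"
    if generative:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    cues = trials["cue_type"].to_numpy()
    levels = trials["stimulus_level"].to_numpy()
    obs_O = trials["perceptual_rating"].to_numpy(dtype=float)
    n = len(trials)

    state = initialize_state(spec, params, trials)
    omega = float(params.omega)
    sd_E = math.sqrt(params.sigma2_E)
    sd_O = math.sqrt(params.sigma2_O)

    Etilde_a = np.empty(n)
    Ohat_a = np.empty(n)
    delta_a = np.empty(n)
    congr_a = np.empty(n, dtype=bool)
    Elow_a = np.empty(n)
    Ehigh_a = np.empty(n)
    sim_E = np.empty(n) if generative else None
    sim_O = np.empty(n) if generative else None

    for t in range(n):
        cue = cues[t]
        Etilde = effective_expectation(state, params, cue, spec)
        O_hat = predict_outcome(Etilde, levels[t], omega)
        if generative:
            e_draw = min(1.0, max(0.0, Etilde + sd_E * rng.standard_normal()))
            o_draw = min(1.0, max(0.0, O_hat + sd_O * rng.standard_normal()))
            sim_E[t] = e_draw
            sim_O[t] = o_draw
            O_t = o_draw
        else:
            O_t = obs_O[t]
        delta = prediction_error(O_t, Etilde)
        congr = is_congruent(cue, delta)
        if O_t != O_t:  # missed response: no teaching signal, state frozen
            state.prev_Etilde = Etilde
        elif spec.learns:
            update_state(state, cue, delta, params, spec, observed_O=O_t, Etilde=Etilde)
        else:
            state.prev_O = O_t
            state.prev_Etilde = Etilde
        Etilde_a[t] = Etilde
        Ohat_a[t] = O_hat
        delta_a[t] = delta
        congr_a[t] = congr
        Elow_a[t] = state.E_low
        Ehigh_a[t] = state.E_high

    return Trajectory(
        Etilde_a, Ohat_a, delta_a, congr_a, Elow_a, Ehigh_a,
        sim_expectation=sim_E, sim_perception=sim_O, n_clips=state.n_clips,
    )


def fill_ratings(trials: pd.DataFrame, traj: Trajectory) -> pd.DataFrame:
    """Copy a generative trajectory's drawn ratings into a trial skeleton."""
    if traj.sim_expectation is None:
        raise ValueError("trajectory was not produced in generative mode")
    out = trials.copy()
    out["expectation_rating"] = traj.sim_expectation
    out["perceptual_rating"] = traj.sim_perception
    return out


def log_likelihood(spec: ModelSpec, params: Params, trials: pd.DataFrame) -> float:
    """Gaussian log-likelihood of observed expectation and perceptual
    ratings under the model's conditioned trajectory.

    Trials with a missing rating contribute only the term that is observed.
    """
    if params.sigma2_E <= 0 or params.sigma2_O <= 0:
        raise ValueError("rating variances must be strictly positive")
    traj = run_model(spec, params, trials, mode="conditioned")
    obs_E = trials["expectation_rating"].to_numpy(dtype=float)
    obs_O = trials["perceptual_rating"].to_numpy(dtype=float)

    ll = 0.0
    var_E, var_O = params.sigma2_E, params.sigma2_O
    cE = -0.5 * math.log(2.0 * math.pi * var_E)
    cO = -0.5 * math.log(2.0 * math.pi * var_O)
    for t in range(len(trials)):
        e, o = obs_E[t], obs_O[t]
        if e == e:  # not NaN
            r = e - traj.Etilde[t]
            ll += cE - 0.5 * r * r / var_E
        if o == o:
            r = o - traj.O_hat[t]
            ll += cO - 0.5 * r * r / var_O
    return ll


def model_catalogue() -> pd.DataFrame:
    """One row per model: structure flags and free parameters."""
    rows = []
    for mid in MODEL_ORDER:
        s = ModelSpec(mid)
        rows.append(
            {
                "model_id": mid,
                "n_rates": s.n_rates,
                "carryover": s.carryover,
                "tracker": s.tracker,
                "n_params": len(s.param_names),
                "parameters": ", ".join(s.param_names),
            }
        )
    return pd.DataFrame(rows)
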