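"""Long-format trial tables: validation, I/O, normalization, design checks.

The unit of data is one row per trial: a participant sees a social cue
(the averaged ratings of supposed previous participants), reports an
expectation, receives a stimulus at one of three intensity levels, and
reports a perceptual rating.  Both ratings live on a 0-180 generalized
labeled magnitude scale (gLMS).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical column order of the on-disk CSV
COLUMNS = [
    "participant_id",
    "task",
    "session",
    "run",
    "trial_index",
    "cue_type",
    "cue_display_mean",
    "stimulus_level",
    "expectation_rating",
    "perceptual_rating",
]

#: columns on the rating scale (normalized/denormalized together)
RATING_COLUMNS = ["cue_display_mean", "expectation_rating", "perceptual_rating"]

TASKS = ("pain", "vicarious", "effort")
CUE_TYPES = ("low", "high")

DEFAULT_SCALE = 180.0

#: minimum trials per participant x task for inclusion in analyses
MIN_TRIALS = 24


class TrialValidationError(ValueError):
    """A trial table violates a structural or range invariant."""


@dataclass
class TrialTable:
    """An ordered collection of trial records for one or more participants.

    ``df`` holds one row per trial with the :data:`COLUMNS` columns, sorted
    by (participant_id, task, trial_index).  ``rating_scale_max`` records the
    scale ratings were collected on; ``normalized`` is True once ratings have
    been mapped to [0, 1] for model computations.
    """

    df: pd.DataFrame
    rating_scale_max: float = DEFAULT_SCALE
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.df)

    def subjects(self):
        """Iterate (participant_id, task, per-subject DataFrame) groups."""
        for key, g in self.df.groupby(["participant_id", "task"], sort=True):
            yield key[0], key[1], g.sort_values("trial_index")

    def subject(self, participant_id: str, task: str) -> pd.DataFrame:
        g = self.df[
            (self.df["participant_id"] == participant_id) & (self.df["task"] == task)
        ]
        return g.sort_values("trial_index")


def _validate_df(df: pd.DataFrame, scale: float, normalized: bool) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing column(s): {missing}")
    df = df[COLUMNS].copy()

    bad_task = ~df["task"].isin(TASKS)
    if bad_task.any():
        row = int(np.flatnonzero(bad_task.to_numpy())[0])
        raise TrialValidationError(f"row {row}: unknown task {df['task'].iloc[row]!r}")
    bad_cue = ~df["cue_type"].isin(CUE_TYPES)
    if bad_cue.any():
        row = int(np.flatnonzero(bad_cue.to_numpy())[0])
        raise TrialValidationError(
            f"row {row}: unknown cue_type {df['cue_type'].iloc[row]!r}"
        )
    bad_level = ~df["stimulus_level"].isin([1, 2, 3])
    if bad_level.any():
        row = int(np.flatnonzero(bad_level.to_numpy())[0])
        raise TrialValidationError(
            f"row {row}: stimulus_level {df['stimulus_level'].iloc[row]!r} not in 1..3"
        )

    hi = 1.0 if normalized else scale
    for col in RATING_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        # NaN = missed response, permitted for the two ratings
        out = (vals < 0) | (vals > hi)
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise TrialValidationError(
                f"row {row}: {col}={df[col].iloc[row]!r} outside [0, {hi}]"
            )
        df[col] = vals
    if df["cue_display_mean"].isna().any():
        row = int(np.flatnonzero(df["cue_display_mean"].isna().to_numpy())[0])
        raise TrialValidationError(f"row {row}: cue_display_mean missing")

    df = df.sort_values(["participant_id", "task", "trial_index"], kind="stable")
    for (pid, task), g in df.groupby(["participant_id", "task"], sort=False):
        ti = g["trial_index"].to_numpy()
        if (ti < 1).any():
            raise TrialValidationError(f"{pid}/{task}: trial_index must be >= 1")
        if len(np.unique(ti)) != len(ti):
            raise TrialValidationError(f"{pid}/{task}: duplicate trial_index")
        if not np.all(np.diff(ti) > 0):
            raise TrialValidationError(f"{pid}/{task}: trial_index not increasing")
    return df.reset_index(drop=True)


def make_table(
    df: pd.DataFrame, rating_scale_max: float = DEFAULT_SCALE, normalized: bool = False
) -> TrialTable:
    """Validate a raw DataFrame and wrap it as a :class:`TrialTable`."""
    return TrialTable(
        _validate_df(df, rating_scale_max, normalized), rating_scale_max, normalized
    )


def read_trials(path, rating_scale_max: float = DEFAULT_SCALE) -> TrialTable:
    """Read and validate a long-format trial CSV.

    Raises :class:`TrialValidationError` naming the offending row for any
    missing column, out-of-range rating, or non-monotone trial index.
    """
    df = pd.read_csv(path)
    return make_table(df, rating_scale_max=rating_scale_max)


def write_trials(table: TrialTable, path) -> None:
    """Write a trial table as CSV readable by :func:`read_trials`."""
    table.df[COLUMNS].to_csv(path, index=False)


def to_csv_string(table: TrialTable) -> str:
    buf = io.StringIO()
    write_trials(table, buf)
    return buf.getvalue()


def normalize_ratings(table: TrialTable, force: bool = False) -> TrialTable:
    """Map all rating columns onto the unit scale (divide by scale max).

    Model computations run on [0, 1]; user-facing outputs are reported back
    on the original scale via :func:`denormalize_ratings`.
    """
    if table.normalized and not force:
        raise TrialValidationError("table is already normalized (pass force=True)")
    finite_max = table.df[RATING_COLUMNS].max().max()
    if not table.normalized and finite_max <= 1.0 and not force:
        raise TrialValidationError(
            "ratings already appear unit-scale (max <= 1); pass force=True"
        )
    df = table.df.copy()
    df[RATING_COLUMNS] = df[RATING_COLUMNS] / table.rating_scale_max
    return TrialTable(df, table.rating_scale_max, normalized=True)


def denormalize_ratings(table: TrialTable) -> TrialTable:
    """Inverse of :func:`normalize_ratings`."""
    if not table.normalized:
        raise TrialValidationError("table is not normalized")
    df = table.df.copy()
    df[RATING_COLUMNS] = df[RATING_COLUMNS] * table.rating_scale_max
    return TrialTable(df, table.rating_scale_max, normalized=False)


@dataclass
class DesignReport:
    """Per-cell trial counts for one participant x task and design flags."""

    participant_id: str
    task: str
    n_trials: int
    cell_counts: pd.DataFrame  # index: cue_type, columns: stimulus_level
    complete: bool  # all six cells at 12
    eligible: bool  # >= MIN_TRIALS trials
    independence_ok: bool  # stimulus levels equally frequent within each cue
    notes: list = field(default_factory=list)


def validate_design(table: TrialTable) -> list[DesignReport]:
    """Check each participant x task against the 2 (cue) x 3 (intensity)
    factorial design with 12 trials per cell; report-only, never raises.

    Independence requires each stimulus level equally frequent within each
    cue type whenever the cue's total count is divisible by 3.
    """
    reports = []
    for pid, task, g in table.subjects():
        counts = (
            g.groupby(["cue_type", "stimulus_level"]).size().unstack(fill_value=0)
        )
        counts = counts.reindex(index=list(CUE_TYPES), columns=[1, 2, 3], fill_value=0)
        notes = []
        complete = bool((counts.to_numpy() == 12).all())
        eligible = len(g) >= MIN_TRIALS
        if not complete:
            notes.append(f"cells deviate from 12 per condition (n={len(g)})")
        if not eligible:
            notes.append(f"fewer than {MIN_TRIALS} trials: excluded from analyses")
        independence_ok = True
        for cue in CUE_TYPES:
            row = counts.loc[cue]
            if row.sum() and row.sum() % 3 == 0 and row.nunique() != 1:
                independence_ok = False
                notes.append(
                    f"stimulus levels not balanced within {cue} cues: "
                    f"{row.to_dict()}"
                )
        reports.append(
            DesignReport(pid, task, len(g), counts, complete, eligible,
                         independence_ok, notes)
        )
    return reports


def split_odd_even(table: TrialTable) -> tuple[TrialTable, TrialTable]:
    """Partition trials by parity of chronological rank within each
    participant x task (rank 1, 3, 5, ... -> odd half)."""
    df = table.df
    rank = df.groupby(["participant_id", "task"])["trial_index"].rank(method="first")
    odd = df[(rank % 2) == 1].reset_index(drop=True)
    even = df[(rank % 2) == 0].reset_index(drop=True)
    mk = lambda d: TrialTable(d, table.rating_scale_max, table.normalized)
    return mk(odd), mk(even)


def drop_missing(table: TrialTable) -> tuple[TrialTable, int]:
    """Drop trials with a missing expectation or perceptual rating.

    Returns the filtered table and the number of dropped trials (the default
    policy for operations that cannot consume null cells).
    """
    keep = table.df["expectation_rating"].notna() & table.df[
        "perceptual_rating"
    ].notna()
    n_dropped = int((~keep).sum())
    return replace(table, df=table.df[keep].reset_index(drop=True)), n_dropped
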