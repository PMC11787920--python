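"""Data model and I/O for EMA ideation ratings, baseline covariates and follow-up.

Three study file types are handled, all plain CSV:

* ``ema.csv`` — long-format prompt-level records: four 0-10 ideation items
  (desire to live, desire to die, thoughts of killing oneself, intent to act),
  one row per answered prompt, plus optional self-initiated entries;
* ``baseline.csv`` — one row per participant with demographics, diagnosis
  flags, symptom-scale totals and suicide-attempt history;
* ``followup.csv`` — weekly follow-up reports over one year (responded
  yes/no, suicide attempt yes/no).

Per-participant EMA data are represented as an :class:`EmaSeries`: a fixed
grid of every scheduled slot (``n_days`` x ``n_prompts`` rows, missed prompts
kept as all-missing rows so that slot adjacency is preserved), with
self-initiated entries carried separately.

Composite scoring follows the two-item definition of each outcome: passive
ideation is the mean of the reverse-coded desire-to-live item and the
desire-to-die item; active ideation is the mean of the thoughts and intent
items.  When exactly one constituent item is present the composite equals
the available (reverse-coded where applicable) item.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ITEM_COLUMNS = ["desire_live", "desire_die", "thoughts", "intent"]
EMA_COLUMNS = ["participant_id", "day", "prompt", "timestamp", *ITEM_COLUMNS, "self_initiated"]
SCALE_MAX = 10

#: Baseline columns treated as categorical / flags in downstream group tests.
BASELINE_FLAG_COLUMNS = [
    "MDD", "anxiety", "PTSD", "BPD", "OCD", "ADHD", "ASD", "comorbidity",
    "antidepressants", "anxiolytics", "stimulants", "recent_attempt",
]
BASELINE_NUMERIC_COLUMNS = ["age", "BSSI", "BDI", "HADS_A", "QLESQ", "LEIDSR", "STAXI_T"]


class EmaValidationError(ValueError):
    """Raised when an input file violates the data contract."""


@dataclass
class EmaSeries:
    """One participant's scheduled EMA grid plus self-initiated entries.

    ``data`` holds exactly ``n_days * n_prompts`` rows ordered by (day,
    prompt); unanswered slots are rows whose item cells are all NaN.
    ``extra`` holds self-initiated entries ordered by timestamp.
    """

    participant_id: str
    n_days: int
    n_prompts: int
    data: pd.DataFrame
    extra: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_slots(self) -> int:
        return self.n_days * self.n_prompts

    @property
    def n_completed(self) -> int:
        """Scheduled slots with at least one item answered."""
        return int(self.data[ITEM_COLUMNS].notna().any(axis=1).sum())

    def composite(self, outcome: str, include_self_initiated: bool = False) -> np.ndarray:
        """Per-slot composite values (NaN at missed slots), in slot order.

        With ``include_self_initiated`` the self-initiated entries are merged
        into the sequence by timestamp, so they become ordinary time points
        for adjacency-based statistics.
        """
        if outcome not in ("passive", "active"):
            raise ValueError(f"unknown outcome {outcome!r}")
        if outcome not in self.data.columns:
            raise ValueError("composites not scored; call score_composites first")
        if not include_self_initiated or self.extra.empty:
            return self.data[outcome].to_numpy(dtype=float)
        merged = pd.concat([self.data, self.extra], ignore_index=True)
        # missed scheduled slots have NaT timestamps; keep them in grid order
        # by filling with the slot's neighbours via stable sort on (day, prompt)
        merged = merged.sort_values(["day", "prompt", "timestamp"], kind="stable")
        return merged[outcome].to_numpy(dtype=float)


def _validate_items(df: pd.DataFrame, path: str = "<data>") -> None:
    for col in ITEM_COLUMNS:
        vals = df[col]
        present = vals.notna()
        bad = present & ((vals < 0) | (vals > SCALE_MAX) | (vals != np.floor(vals)))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise EmaValidationError(
                f"{path}: column {col!r} out of range 0..{SCALE_MAX} at data row "
                f"{df.index[row]} (value {vals.iloc[row]!r})"
            )


def load_ema(path, schedule: tuple[int, int] = (21, 4)) -> list[EmaSeries]:
    """Read an EMA CSV into one :class:`EmaSeries` per participant.

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``participant_id, day, prompt, timestamp,
        desire_live, desire_die, thoughts, intent, self_initiated``; item
        cells empty (missing) or integers 0-10.
    schedule : (n_days, n_prompts)
        The scheduled design; every scheduled slot appears in the returned
        grid whether or not it was answered.
    """
    n_days, n_prompts = schedule
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = set(EMA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise EmaValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["self_initiated"] = df["self_initiated"].astype(bool)
    _validate_items(df, str(path))

    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        sched = grp[~grp["self_initiated"]]
        dup = sched.duplicated(subset=["day", "prompt"])
        if dup.any():
            d, p = sched.loc[dup.idxmax(), ["day", "prompt"]]
            raise EmaValidationError(
                f"{path}: duplicate scheduled record for participant {pid} day {d} prompt {p}"
            )
        bad_slot = (
            (sched["day"] < 1) | (sched["day"] > n_days)
            | (sched["prompt"] < 1) | (sched["prompt"] > n_prompts)
        )
        if bad_slot.any():
            raise EmaValidationError(
                f"{path}: participant {pid} has records outside the "
                f"{n_days}x{n_prompts} schedule"
            )
        grid = pd.MultiIndex.from_product(
            [range(1, n_days + 1), range(1, n_prompts + 1)], names=["day", "prompt"]
        )
        data = (
            sched.set_index(["day", "prompt"])
            .reindex(grid)
            .reset_index()
            .assign(participant_id=pid, self_initiated=False)
        )[EMA_COLUMNS]
        ts = data["timestamp"].dropna()
        if not ts.is_monotonic_increasing:
            raise EmaValidationError(f"{path}: non-monotone timestamps for participant {pid}")
        extra = (
            grp[grp["self_initiated"]]
            .sort_values("timestamp", kind="stable")
            .reset_index(drop=True)[EMA_COLUMNS]
        )
        out.append(EmaSeries(pid, n_days, n_prompts, data.reset_index(drop=True), extra))
    return out


def write_ema(series: list[EmaSeries], path) -> None:
    """Write series back to CSV (answered scheduled slots + self-initiated rows)."""
    parts = []
    for s in series:
        answered = s.data[s.data[ITEM_COLUMNS].notna().any(axis=1)]
        parts += [answered[EMA_COLUMNS], s.extra[EMA_COLUMNS] if not s.extra.empty else None]
    frames = [p for p in parts if p is not None and not p.empty]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def score_composites(series: EmaSeries) -> EmaSeries:
    """Return a copy with per-slot passive/active composites filled in.

    passive = mean(10 - desire_live, desire_die); active = mean(thoughts,
    intent); a composite with exactly one constituent present equals that
    item (reverse-coded for desire to live); both missing -> missing.
    """

    def _score(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        rev_live = SCALE_MAX - df["desire_live"]
        df["passive"] = pd.concat([rev_live, df["desire_die"]], axis=1).mean(axis=1)
        df["active"] = df[["thoughts", "intent"]].mean(axis=1)
        return df

    return replace(
        series,
        data=_score(series.data),
        extra=_score(series.extra) if not series.extra.empty else series.extra,
    )


def load_baseline(path) -> pd.DataFrame:
    """Read baseline covariates, one row per participant.

    Known flag columns become nullable booleans, symptom totals floats;
    unknown columns are preserved as numeric covariates where possible.
    ``attempt_history`` is kept as the categorical none/single/multiple.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise EmaValidationError(f"{path}: missing participant_id column")
    if df["participant_id"].duplicated().any():
        raise EmaValidationError(f"{path}: duplicate participant rows")
    if "attempt_history" in df.columns:
        bad = ~df["attempt_history"].isin(["none", "single", "multiple"]) & df[
            "attempt_history"
        ].notna()
        if bad.any():
            raise EmaValidationError(
                f"{path}: invalid attempt_history value "
                f"{df.loc[bad.idxmax(), 'attempt_history']!r}"
            )
    for col in BASELINE_FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    if (
        "recent_attempt" in df.columns
        and "attempt_history" in df.columns
        and (df["recent_attempt"].fillna(False) & (df["attempt_history"] == "none")).any()
    ):
        raise EmaValidationError(f"{path}: recent_attempt set without any attempt history")
    return df.set_index("participant_id")


def write_baseline(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True)


def load_followup(path) -> pd.DataFrame:
    """Read weekly follow-up reports (participant_id, week, responded, attempt).

    An attempt can only be reported on a responded week.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    need = {"participant_id", "week", "responded", "attempt"}
    if not need <= set(df.columns):
        raise EmaValidationError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    df["responded"] = df["responded"].astype(bool)
    df["attempt"] = df["attempt"].astype(bool)
    bad = df["attempt"] & ~df["responded"]
    if bad.any():
        raise EmaValidationError(
            f"{path}: attempt reported on a non-responded week "
            f"(participant {df.loc[bad.idxmax(), 'participant_id']}, "
            f"week {df.loc[bad.idxmax(), 'week']})"
        )
    if ((df["week"] < 1) | (df["week"] > 52)).any():
        raise EmaValidationError(f"{path}: week outside 1..52")
    return df


def write_followup(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["responded"] = out["responded"].astype(int)
    out["attempt"] = out["attempt"].astype(int)
    out.to_csv(path, index=False)


def aggregate_followup(
    records: pd.DataFrame,
    total_weeks: int = 52,
    completion_window: int = 4,
) -> pd.DataFrame:
    """Aggregate weekly reports into per-participant prospective outcomes.

    ``any_attempt`` is 1 iff any responded week reports an attempt.
    ``included`` (eligible for the prospective analysis) is true iff the
    participant reported an attempt, or responded within the final
    ``completion_window`` weeks — the operationalization of having completed
    the follow-up; participants lost to follow-up without a reported attempt
    are excluded so that non-responders are never classified as
    non-attempters.
    """
    rows = []
    for pid, grp in records.groupby("participant_id", sort=True):
        attempts = int((grp["responded"] & grp["attempt"]).sum())
        completed = bool(
            grp.loc[grp["week"] > total_weeks - completion_window, "responded"].any()
        )
        rows.append(
            {
                "participant_id": pid,
                "any_attempt": int(attempts > 0),
                "n_attempt_weeks": attempts,
                "included": attempts > 0 or completed,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["any_attempt", "n_attempt_weeks", "included"],
            index=pd.Index([], name="participant_id"),
        )
    return pd.DataFrame(rows).set_index("participant_id")
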