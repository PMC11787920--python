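"""Within-person ideation-dynamics features and variance-components ICC.

Ten features per participant feed the latent profile analysis, five per
outcome (passive, active): person mean, within-person SD, peak (highest
recorded value), frequency (% of completed ratings above zero) and RMSSD
(root mean square of successive differences).  RMSSD is computed over
consecutive *scheduled* slots only: the slot grid keeps missed prompts in
place, and a successive difference is formed only when both adjacent slots
were answered, so differences never bridge a gap.  Night-to-morning
transitions (last prompt of a day to the first of the next) count as
ordinary lag-1 pairs.

The intraclass correlation (ICC) decomposes total variance of a composite
into between-person and within-person components under the intercept-only
random-effects model y_it = mu + u_i + e_it, u_i ~ N(0, sigma_b^2),
e_it ~ N(0, sigma_w^2).  ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2); REML
estimation profiles the likelihood down to a scalar search over the
variance ratio, and an unbalanced one-way ANOVA (method-of-moments,
Searle) estimator is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .ema_data import EmaSeries

FEATURE_COLUMNS = [
    "mean_passive", "mean_active",
    "sd_passive", "sd_active",
    "peak_passive", "peak_active",
    "freq_passive", "freq_active",
    "rmssd_passive", "rmssd_active",
]


def rmssd_adjacent(values: Sequence[float]) -> float:
    """RMSSD over adjacent slot pairs where both values are present.

    ``values`` is the full per-slot sequence with missing entries kept as
    NaN so that adjacency reflects the schedule.  Returns NaN when no valid
    adjacent pair exists (the statistic is undefined, not zero).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sequence of per-slot values")
    if len(x) < 2:
        return np.nan
    d = np.diff(x)
    valid = ~np.isnan(d)
    if not valid.any():
        return np.nan
    return float(np.sqrt(np.mean(d[valid] ** 2)))


def _outcome_features(x: np.ndarray) -> dict:
    done = x[~np.isnan(x)]
    n = len(done)
    d = np.diff(x)
    n_pairs = int((~np.isnan(d)).sum()) if len(x) > 1 else 0
    if n == 0:
        return {"mean": np.nan, "sd": np.nan, "peak": np.nan, "freq": np.nan,
                "rmssd": np.nan, "n_completed": 0, "n_pairs": 0}
    return {
        "mean": float(done.mean()),
        "sd": float(done.std(ddof=1)) if n > 1 else np.nan,
        "peak": float(done.max()),
        "freq": float(100.0 * (done > 0).sum() / n),
        "rmssd": rmssd_adjacent(x),
        "n_completed": n,
        "n_pairs": n_pairs,
    }


def person_features(series: EmaSeries, include_self_initiated: bool = False) -> pd.Series:
    """The ten dynamics features for one participant.

    Within-person SD uses the n-1 denominator.  Frequency is the percentage
    of *completed* ratings that are non-zero.  Participants with a single
    completed value get a defined mean/peak/frequency but undefined SD and
    RMSSD; with zero completed values every feature is missing.
    """
    out = {}
    for outcome in ("passive", "active"):
        x = series.composite(outcome, include_self_initiated=include_self_initiated)
        f = _outcome_features(x)
        out[f"mean_{outcome}"] = f["mean"]
        out[f"sd_{outcome}"] = f["sd"]
        out[f"peak_{outcome}"] = f["peak"]
        out[f"freq_{outcome}"] = f["freq"]
        out[f"rmssd_{outcome}"] = f["rmssd"]
        out[f"n_completed_{outcome}"] = f["n_completed"]
        out[f"n_pairs_{outcome}"] = f["n_pairs"]
    return pd.Series(out, name=series.participant_id)


def feature_matrix(
    cohort: Iterable[EmaSeries], include_self_initiated: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Stack person features into the persons x 10 LPA input matrix.

    Returns the matrix (fixed column order ``FEATURE_COLUMNS``, participant
    id index, extra ``n_completed_*``/``n_pairs_*`` bookkeeping columns) and
    the list of excluded participant ids (any undefined feature).
    """
    rows = [person_features(s, include_self_initiated) for s in cohort]
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(rows)
    df = df[FEATURE_COLUMNS + [c for c in df.columns if c not in FEATURE_COLUMNS]]
    df.index.name = "participant_id"
    ok = df[FEATURE_COLUMNS].notna().all(axis=1)
    excluded = list(df.index[~ok])
    df = df[ok]
    if df.empty:
        raise ValueError("no participant has fully defined features")
    return df, excluded


@dataclass
class IccEstimate:
    """Variance decomposition of a composite under a random-intercept model."""

    sigma2_between: float
    sigma2_within: float
    estimator: str  # "reml" | "mom"

    @property
    def icc(self) -> float:
        total = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / total


def _person_groups(values_by_person: Iterable[Sequence[float]]) -> list[np.ndarray]:
    groups = []
    for v in values_by_person:
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr):
            groups.append(arr)
    return groups


def _mom_components(groups: list[np.ndarray]) -> tuple[float, float]:
    """Unbalanced one-way ANOVA (Searle) variance components, truncated at 0."""
    a = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    n = n_i.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_w = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    ss_b = float((n_i * (means - grand) ** 2).sum())
    ms_w = ss_w / (n - a)
    ms_b = ss_b / (a - 1)
    n0 = (n - (n_i**2).sum() / n) / (a - 1)
    s2b = max(0.0, (ms_b - ms_w) / n0)
    return s2b, ms_w


def estimate_icc(values_by_person: Iterable[Sequence[float]], method: str = "reml") -> IccEstimate:
    """Estimate the ICC of a composite from per-person value lists.

    ``method="reml"`` profiles the restricted likelihood of the
    random-intercept model over the ratio lambda = sigma_b^2/sigma_w^2 and
    optimizes the scalar; ``method="mom"`` uses the one-way ANOVA
    method-of-moments estimator.  Negative variance estimates are truncated
    at zero.
    """
    groups = _person_groups(values_by_person)
    if len(groups) < 2:
        raise ValueError("need at least two persons with data")
    y = np.concatenate(groups)
    n = len(y)
    if n < len(groups) + 1:
        raise ValueError("need more observations than persons")
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: zero total variance")

    n_i = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups))

    if method == "mom":
        s2b, s2w = _mom_components(groups)
        return IccEstimate(s2b, s2w, "mom")
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")

    if ss_w == 0.0:
        # every person constant but persons differ: all variance is between
        return IccEstimate(float(np.var(means)), 0.0, "reml")

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = n_i / (1.0 + lam * n_i)
        mu = float((w * means).sum() / w.sum())
        q = ss_w + float((w * (means - mu) ** 2).sum())
        s2w = q / (n - 1)
        return (
            (n - 1) * np.log(s2w)
            + float(np.log1p(lam * n_i).sum())
            + np.log(w.sum())
        )

    res = minimize_scalar(neg2_reml, bounds=(-25.0, 25.0), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    w = n_i / (1.0 + lam * n_i)
    mu = float((w * means).sum() / w.sum())
    q = ss_w + float((w * (means - mu) ** 2).sum())
    s2w = q / (n - 1)
    s2b = lam * s2w
    if lam < 2e-11:  # boundary: no between-person variance
        s2b = 0.0
    return IccEstimate(s2b, s2w, "reml")
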