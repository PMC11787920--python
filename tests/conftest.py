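import numpy as np
import pandas as pd
import pytest

from phenotyper import ema_data
from phenotyper.ema_data import EMA_COLUMNS, EmaSeries
from phenotyper.synthetic_cohort import GeneratorConfig, simulate_cohort


def make_series(passive_items=None, active_items=None, n_days=2, n_prompts=3,
                pid="p001"):
    """Build an EmaSeries directly from per-slot item values (NaN = missing).

    ``passive_items``/``active_items`` are lists of (item1, item2) pairs:
    (desire_live, desire_die) and (thoughts, intent).
    """
    n = n_days * n_prompts
    days = np.repeat(np.arange(1, n_days + 1), n_prompts)
    prompts = np.tile(np.arange(1, n_prompts + 1), n_days)
    base = pd.Timestamp("2026-01-05")
    hours = 7 + (prompts - 1) * 5 + 0.5
    data = pd.DataFrame({
        "participant_id": pid, "day": days, "prompt": prompts,
        "timestamp": base + pd.to_timedelta((days - 1) * 24 + hours, unit="h"),
        "desire_live": np.nan, "desire_die": np.nan,
        "thoughts": np.nan, "intent": np.nan,
        "self_initiated": False,
    })
    for col_pair, items in (
        (("desire_live", "desire_die"), passive_items),
        (("thoughts", "intent"), active_items),
    ):
        if items is None:
            continue
        assert len(items) == n
        for i, pair in enumerate(items):
            if pair is None:
                continue
            data.loc[i, col_pair[0]] = pair[0]
            data.loc[i, col_pair[1]] = pair[1]
    miss = data[["desire_live", "desire_die", "thoughts", "intent"]].isna().all(axis=1)
    data.loc[miss, "timestamp"] = pd.NaT
    series = EmaSeries(pid, n_days, n_prompts, data,
                       pd.DataFrame(columns=EMA_COLUMNS))
    return ema_data.score_composites(series)


def series_from_passive(values, n_prompts=3, pid="p001"):
    """EmaSeries whose passive composite equals ``values`` (None = missing).

    Values must sit on the 0.5 grid; items are back-solved as in the
    generator.  Active items mirror the passive ones.
    """
    n = len(values)
    n_days = (n + n_prompts - 1) // n_prompts
    padded = list(values) + [None] * (n_days * n_prompts - n)
    p_items, a_items = [], []
    for v in padded:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            p_items.append(None)
            a_items.append(None)
        else:
            s = int(round(2 * v))
            lo, hi = s // 2, s - s // 2
            p_items.append((10 - lo, hi))
            a_items.append((hi, lo))
    return make_series(p_items, a_items, n_days=n_days, n_prompts=n_prompts, pid=pid)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (N=82), scored, with truth labels."""
    dataset, truth = simulate_cohort(GeneratorConfig(), seed=20260930)
    scored = [ema_data.score_composites(s) for s in dataset.ema]
    return dataset, scored, truth


@pytest.fixture()
def small_config():
    return GeneratorConfig(n_participants=16, n_days=5, prompts_per_day=3,
                           self_initiated_rate=1.0)
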