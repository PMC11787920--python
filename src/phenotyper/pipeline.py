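"""End-to-end orchestration: data -> features -> profiles -> statistics.

``run_pipeline`` executes the full analysis on a study dataset (loaded from
the three CSVs or simulated in memory): composite scoring, descriptives
(compliance, ICCs), the ten-feature matrix, latent-profile model search,
canonical profile ordering (profile 1 = highest mean active ideation),
profile feature comparisons, baseline correlates, and the prospective
attempt analysis.  Everything is deterministic given the single pipeline
seed, which fans out into independent per-stage seed streams (generator,
EM restarts, BLRT resampling, Monte-Carlo exact tests).

``write_report`` materializes a report as CSV/JSON artifacts plus a
human-readable markdown summary; ``plot_series`` draws per-participant
time-series plots with the person mean (solid) and mean +/- SD (dashed)
reference lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

from . import __version__, correlates, dynamics, ema_data, latent_profiles
from .synthetic_cohort import GeneratorConfig, StudyDataset, simulate_cohort

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

#: Plot colors per canonical profile (1 = highest intensity).
PROFILE_COLORS = {1: "tab:red", 2: "tab:blue", 3: "tab:green"}

FEATURE_LABELS = {
    "mean_passive": "M, Passive", "mean_active": "M, Active",
    "sd_passive": "SD, Passive", "sd_active": "SD, Active",
    "peak_passive": "Peak, Passive", "peak_active": "Peak, Active",
    "freq_passive": "% Non-zero, Passive", "freq_active": "% Non-zero, Active",
    "rmssd_passive": "RMSSD, Passive", "rmssd_active": "RMSSD, Active",
}


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (file mode or simulate mode)."""

    ema_path: str | None = None
    baseline_path: str | None = None
    followup_path: str | None = None
    generator: GeneratorConfig | None = None       # simulate mode
    schedule: tuple[int, int] = (21, 4)
    g_range: tuple[int, int] = (1, 6)
    families: tuple[str, ...] = latent_profiles.DEFAULT_SEARCH_FAMILIES
    blrt_resamples: int = 1000
    alpha: float = 0.05
    seed: int = 0
    standardize: bool = False
    include_self_initiated: bool = False
    pooled_followup_table: bool = False
    completion_window: int = 4

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    descriptives: dict
    selection: pd.DataFrame
    profile_table: pd.DataFrame
    assignments: pd.DataFrame
    features: pd.DataFrame
    correlates_table: pd.DataFrame | None
    followup: dict | None
    provenance: dict
    excluded: list = field(default_factory=list)


def _load_dataset(config: PipelineConfig) -> StudyDataset:
    if config.generator is not None:
        dataset, _ = simulate_cohort(config.generator, seed=config.seed)
        return dataset
    if config.ema_path is None:
        raise ValueError("either generator config or ema_path is required")
    ema = ema_data.load_ema(config.ema_path, schedule=config.schedule)
    baseline = (
        ema_data.load_baseline(config.baseline_path) if config.baseline_path else None
    )
    followup = (
        ema_data.load_followup(config.followup_path)
        if config.followup_path
        else pd.DataFrame(columns=["participant_id", "week", "responded", "attempt"])
    )
    return StudyDataset(ema, baseline, followup)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages."""
    ss = np.random.SeedSequence(config.seed)
    seed_lpa, seed_fisher = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    dataset = _load_dataset(config)
    scored = [ema_data.score_composites(s) for s in dataset.ema]

    n_slots = scored[0].n_slots if scored else 0
    compliance = float(np.mean([s.n_completed / s.n_slots for s in scored]))
    icc = {
        o: dynamics.estimate_icc(
            [s.composite(o, config.include_self_initiated) for s in scored]
        )
        for o in ("passive", "active")
    }

    features, excluded = dynamics.feature_matrix(
        scored, include_self_initiated=config.include_self_initiated
    )
    X = features[dynamics.FEATURE_COLUMNS].to_numpy()
    if config.standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    lo, hi = config.g_range
    sel = latent_profiles.select_profiles(
        X, g_range=range(lo, hi + 1), families=config.families,
        B=config.blrt_resamples, seed=seed_lpa,
    )
    fit = latent_profiles.canonical_order(
        sel.best, by_column=dynamics.FEATURE_COLUMNS.index("mean_active")
    )
    labels, max_post = latent_profiles.posterior_assign(fit)
    assignments = pd.DataFrame(
        {"phenotype": labels + 1, "max_posterior": max_post}, index=features.index
    )

    phenos = sorted(assignments["phenotype"].unique())
    rows = []
    for col in dynamics.FEATURE_COLUMNS:
        groups = [
            features.loc[assignments["phenotype"] == g, col].to_numpy() for g in phenos
        ]
        try:
            F, _, _, p = correlates.oneway_anova(groups)
            letters = correlates.pairwise_letters(groups, config.alpha, method="welch")
        except ValueError:
            F, p, letters = np.nan, np.nan, [""] * len(groups)
        rows.append(
            correlates.GroupComparison(
                FEATURE_LABELS[col], "continuous", f"{features[col].mean():.2f}",
                [f"{g.mean():.2f}" for g in groups], F, p, letters,
            )
        )
    group_names = [f"phenotype_{g} (n={int((assignments['phenotype'] == g).sum())})"
                   for g in phenos]
    profile_table = correlates.comparisons_frame(rows, group_names)

    correlates_table = None
    history = None
    if dataset.baseline is not None:
        comp_rows, _skipped = correlates.profile_correlates(
            assignments["phenotype"], dataset.baseline, config.alpha
        )
        correlates_table = correlates.comparisons_frame(comp_rows, group_names)
        if "attempt_history" in dataset.baseline.columns:
            history = dataset.baseline["attempt_history"] != "none"

    followup_out = None
    if len(dataset.followup):
        summaries = ema_data.aggregate_followup(
            dataset.followup, completion_window=config.completion_window
        )
        assoc = correlates.followup_association(
            assignments["phenotype"], summaries,
            pooled=config.pooled_followup_table, history=history, seed=seed_fisher,
        )
        followup_out = {
            "table": assoc.table.counts.tolist(),
            "row_labels": assoc.table.row_labels,
            "fisher_p": assoc.p_value,
            "cramers_v": assoc.cramers_v,
            "attempters": assoc.attempters,
            "group_sizes": assoc.group_sizes,
            "attempts_per_phenotype": assoc.attempts,
            "total_attempts": assoc.total_attempts,
            "n_included": int(sum(assoc.group_sizes)),
            "history_stratum": assoc.history,
        }

    report = RunReport(
        descriptives={
            "n_participants": len(scored),
            "n_slots": n_slots,
            "compliance": round(compliance, 4),
            "icc_passive": round(icc["passive"].icc, 4),
            "icc_active": round(icc["active"].icc, 4),
            "mean_completed": round(compliance * n_slots, 1),
        },
        selection=sel.table,
        profile_table=profile_table,
        assignments=assignments,
        features=features,
        correlates_table=correlates_table,
        followup=followup_out,
        provenance={
            "seed": config.seed,
            "version": __version__,
            "config_hash": config.digest(),
            "chosen_G": fit.n_components,
            "chosen_family": fit.spec.family,
        },
        excluded=excluded,
    )
    return report


def _summary_md(report: RunReport) -> str:
    d = report.descriptives
    p = report.provenance
    lines = [
        "# Digital phenotyping run summary",
        "",
        f"seed {p['seed']} | config {p['config_hash']} | phenotyper {p['version']}",
        "",
        "## Descriptives",
        f"- participants: {d['n_participants']} (excluded from LPA: {len(report.excluded)})",
        f"- compliance: {100 * d['compliance']:.1f}% of {d['n_slots']} scheduled prompts "
        f"(mean {d['mean_completed']} completed)",
        f"- ICC passive: {d['icc_passive']:.2f}; ICC active: {d['icc_active']:.2f}",
        "",
        "## Model selection (chosen: "
        f"G={p['chosen_G']}, {p['chosen_family']})",
        "",
    ]
    sel = report.selection.copy()
    sel["chosen"] = (sel["G"] == p["chosen_G"]) & (sel["family"] == p["chosen_family"])
    show = sel[sel["family"] == p["chosen_family"]][
        ["G", "bic", "entropy", "total_entropy", "blrt_stat", "blrt_p",
         "eligible", "chosen"]
    ]
    lines.append(show.round(3).to_markdown(index=False))
    lines += ["", "## Profile features", "", report.profile_table.to_markdown(index=False)]
    if report.correlates_table is not None:
        lines += ["", "## Baseline correlates", "",
                  report.correlates_table.to_markdown(index=False)]
    if report.followup is not None:
        f = report.followup
        lines += [
            "", "## Prospective suicide attempts",
            f"- included: {f['n_included']}; attempters per phenotype: {f['attempters']} "
            f"of {f['group_sizes']}",
            f"- attempts per phenotype: {f['attempts_per_phenotype']} "
            f"(total {f['total_attempts']})",
            f"- Fisher exact p = {f['fisher_p']:.4g}; Cramer's V = {f['cramers_v']:.2f}",
        ]
        if f.get("history_stratum"):
            h = f["history_stratum"]
            lines.append(
                f"- past-attempt-history stratum (n={h['n_history']}): repeat rate "
                f"{h['repeat_rate_upper']:.0f}% in upper phenotypes vs "
                f"{h['repeat_rate_lowest']:.0f}% in the lowest-intensity phenotype"
            )
    return "\n".join(lines) + "\n"


def write_report(report: RunReport, outdir, force: bool = False) -> list[Path]:
    """Write all artifacts; refuses a non-empty directory unless ``force``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [f for f in ("summary.md", "selection_table.csv") if (out / f).exists()]
    if existing and not force:
        raise FileExistsError(
            f"{out} already holds report artifacts ({existing}); pass force=True"
        )
    written = []

    def _w(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    _w("features.csv", lambda p: report.features.to_csv(p))
    _w("selection_table.csv", lambda p: report.selection.to_csv(p, index=False))
    _w("profiles.csv", lambda p: report.profile_table.to_csv(p, index=False))
    _w("assignments.csv", lambda p: report.assignments.to_csv(p))
    if report.correlates_table is not None:
        _w("correlates.csv", lambda p: report.correlates_table.to_csv(p, index=False))
    payload = {"descriptives": report.descriptives, "provenance": report.provenance,
               "followup": report.followup, "excluded": report.excluded}
    _w("followup.json", lambda p: p.write_text(json.dumps(payload, indent=2)))
    _w("summary.md", lambda p: p.write_text(_summary_md(report)))
    return written


def plot_series(series, outcome: str, path, profile: int | None = None) -> Path:
    """Per-slot trajectory with mean (solid) and mean +/- SD (dashed) lines.

    Gaps are left at missed prompts.  ``profile`` selects the line color by
    canonical profile number (1 red, 2 blue, 3 green).
    """
    x = series.composite(outcome)
    done = x[~np.isnan(x)]
    if done.size == 0:
        raise ValueError(f"participant {series.participant_id}: no completed values")
    mean = done.mean()
    sd = done.std(ddof=1) if done.size > 1 else 0.0
    color = PROFILE_COLORS.get(profile, "tab:red")

    fig, ax = plt.subplots(figsize=(8, 2.6))
    ax.plot(np.arange(1, len(x) + 1), x, color=color, lw=0.9)
    ax.axhline(mean, color=color, lw=1.4)
    for ref in (mean - sd, mean + sd):
        ax.axhline(ref, color=color, lw=1.0, ls="--")
    ax.set_ylim(-0.3, 10.3)
    ax.set_xlabel("scheduled prompt")
    ax.set_ylabel(f"{outcome} ideation")
    ax.set_title(f"{series.participant_id} ({outcome}); M={mean:.2f}, SD={sd:.2f}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_cohort(series_list, assignments: pd.DataFrame, outdir,
                outcome: str = "passive") -> Path:
    """One plot per participant plus an index CSV; returns the index path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series_list:
        profile = (
            int(assignments.loc[s.participant_id, "phenotype"])
            if s.participant_id in assignments.index
            else None
        )
        name = f"{s.participant_id}_{outcome}.png"
        try:
            plot_series(s, outcome, out / name, profile=profile)
        except ValueError:
            continue
        rows.append({"participant_id": s.participant_id, "phenotype": profile,
                     "file": name})
    index = out / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index
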