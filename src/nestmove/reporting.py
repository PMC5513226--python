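"""End-to-end pipeline driver and output surfaces.

``run_pipeline`` takes fix and nest tables (files or in-memory objects) and
produces the study's full results bundle: the per-bird summary table
(days of prenesting, nest membership and areas of the 50/95/99% prenesting
isopleths, mean (SD) / minimum nest distance, day of closest approach),
population membership proportions, day-window counts of closest approach,
per-day intersection frequencies, logistic fits per buffer region, and the
windowed odds ratios. Figures mirror the two-panel layout: relative
intersection frequency by day on the left, fitted probability curves on the
right, day axis running 45 -> 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nest_metrics
from .buffer_intersection import (
    BufferSet,
    build_buffers,
    classify_segments,
    intersection_frequencies,
)
from .inference import (
    LogisticFit,
    OddsRatioResult,
    SeparationError,
    fit_intersection_model,
    predict_probability,
    window_odds_ratio,
)
from .phenology import delineate_phases
from .range_estimation import extract_isopleth, fit_brownian_bridge, fit_fixed_kernel
from .tracks_io import (
    AnalysisConfig,
    NestAttempt,
    Track,
    ValidationError,
    get_logger,
    read_fixes,
    read_nests,
)

RESULTS_SCHEMA_VERSION = 1

# regions shown in the figures, smallest last
FIGURE_REGIONS = ("fixed_500m", "fixed_100m", "mean_incubation_circle")


@dataclass
class ResultsBundle:
    subspecies: str
    summary: pd.DataFrame  # one row per bird, study-table schema
    membership: pd.DataFrame  # percent of nests outside each level
    window_counts: pd.DataFrame
    mean_day_closest: float
    frequencies: pd.DataFrame
    logistic: dict  # region -> LogisticFit
    odds_ratios: list  # list of (label, OddsRatioResult)
    errors: list = field(default_factory=list)  # (bird_id, stage, message)
    segments: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        return {
            "schema_version": RESULTS_SCHEMA_VERSION,
            "subspecies": self.subspecies,
            "n_birds": int(len(self.summary)),
            "aggregates": table_aggregates(self.summary),
            "window_counts": self.window_counts.to_dict(orient="records"),
            "mean_day_closest": self.mean_day_closest,
            "logistic": {
                r: dataclasses.asdict(f) for r, f in self.logistic.items()
            },
            "odds_ratios": [
                {"comparison": lab, **dataclasses.asdict(orr)}
                for lab, orr in self.odds_ratios
            ],
            "errors": self.errors,
        }


def table_aggregates(summary: pd.DataFrame) -> dict:
    """Footer aggregates of a per-bird summary table.

    Column means and SDs over birds, percent of nests Out per isopleth
    level, and the mean day of closest approach; a censored minimum-distance
    cell is excluded from the minimum's mean/SD with a footnote count.
    Rounding (2 decimals) happens here, at presentation.
    """
    if summary.empty:
        raise ValidationError("summary table is empty")
    out: dict = {}
    censored = (
        summary["min_censored"]
        if "min_censored" in summary.columns
        else pd.Series(False, index=summary.index)
    )
    minima = summary.loc[~censored, "min_m"]

    def _sd(s: pd.Series) -> float:
        return float(s.std(ddof=1)) if len(s) > 1 else 0.0

    out["n_birds"] = int(len(summary))
    out["mean_days_of_prenest"] = round(float(summary["days_of_prenest"].mean()), 2)
    out["sd_days_of_prenest"] = round(_sd(summary["days_of_prenest"]), 2)
    out["mean_mean_distance_m"] = round(float(summary["mean_m"].mean()), 2)
    out["sd_mean_distance_m"] = round(_sd(summary["mean_m"]), 2)
    out["mean_min_distance_m"] = round(float(minima.mean()), 2)
    out["sd_min_distance_m"] = round(_sd(minima), 2)
    out["n_censored_min"] = int(censored.sum())
    out["mean_day_closest"] = round(float(summary["day_closest"].mean()), 2)
    for pct in (50, 75, 95, 99):
        col = f"in_{pct}"
        if col in summary.columns and summary[col].notna().any():
            n_out = int((summary[col] == "Out").sum())
            out[f"percent_out_{pct}"] = round(100.0 * n_out / len(summary), 2)
    return out


def run_pipeline(
    fixes: str | Path | list[Track],
    nests: str | Path | list[NestAttempt],
    config: AnalysisConfig | None = None,
    subspecies: str = "rio_grande",
    outdir: str | Path | None = None,
    estimate_ranges: bool = True,
    make_figures: bool = False,
) -> ResultsBundle:
    """Run every stage over all birds; per-bird failures are logged and the
    pipeline continues over the remaining birds.

    ``estimate_ranges=False`` skips the UD estimators (membership columns
    and kernel-derived buffers are then absent), which is useful when only
    the distance metrics and fixed-buffer inference are needed.
    """
    config = config or AnalysisConfig()
    log = get_logger("reporting")
    if not isinstance(fixes, list):
        fixes, row_errors = read_fixes(fixes, schedule=config.schedule_hours)
        for e in row_errors:
            log.warning("fix row %d rejected: %s", e.line, e.message)
    if not isinstance(nests, list):
        nests = read_nests(nests)
    nests_by_bird = {a.bird_id: a for a in nests}

    summaries: list[nest_metrics.DistanceSummary] = []
    all_segments: list[pd.DataFrame] = []
    errors: list[tuple[str, str, str]] = []

    for track in sorted(fixes, key=lambda t: t.bird_id):
        bird = track.bird_id
        nest = nests_by_bird.get(bird)
        if nest is None:
            errors.append((bird, "nests", "no nest record"))
            continue
        stage = "phenology"
        try:
            phase = delineate_phases(track, nest, config)
            stage = "nest_metrics"
            dists = nest_metrics.fix_nest_distances(
                track, nest.nest, phase, config.gps_exclusion_m, apply_exclusion=True
            )
            summ = nest_metrics.summarize_prenesting(
                dists, phase, fate=nest.fate, mean_mode=config.mean_distance_mode
            )
            incubation_ud = None
            if estimate_ranges:
                stage = "range_estimation"
                pre_track = Track(
                    bird,
                    [f for f, ph in zip(track.fixes, phase.phase) if ph == "prenesting"],
                    schedule=track.schedule,
                )
                if len(pre_track) >= 10:
                    ud = fit_brownian_bridge(
                        pre_track, location_error=config.location_error_m
                    )
                    isos = {
                        lev: extract_isopleth(ud, lev)
                        for lev in (0.50, 0.95, 0.99)
                    }
                    summ.membership = nest_metrics.nest_range_membership(
                        nest.nest, isos
                    )
                inc_pts = phase.frame.loc[
                    phase.frame["phase"] == "incubation", ["x", "y"]
                ].to_numpy()
                if len(inc_pts) >= 5:
                    try:
                        incubation_ud = fit_fixed_kernel(inc_pts)
                    except ValidationError as exc:
                        log.warning("bird %s incubation kernel: %s", bird, exc)
            stage = "buffer_intersection"
            buffers = build_buffers(nest.nest, incubation_ud, subspecies, config)
            buffers.bird_id = bird
            segs = classify_segments(
                track, phase, buffers, semantics=config.intersection_semantics
            )
            all_segments.append(segs)
            summaries.append(summ)
        except (ValidationError, SeparationError) as exc:
            log.error("bird %s failed at %s: %s", bird, stage, exc)
            errors.append((bird, stage, str(exc)))

    if not summaries:
        raise ValidationError("no bird completed the pipeline")

    summary = nest_metrics.summary_table(summaries)
    memberships = [s.membership for s in summaries if s.membership]
    membership = (
        nest_metrics.membership_proportions(memberships)
        if memberships
        else pd.DataFrame(columns=["level", "n", "n_out", "percent_out"])
    )
    windows = nest_metrics.bin_day_closest(summaries, config.day_windows)
    segments = (
        pd.concat(all_segments, ignore_index=True) if all_segments else pd.DataFrame()
    )
    freqs = intersection_frequencies(segments, max_day=config.prenesting_days)

    logistic: dict[str, LogisticFit] = {}
    region_cols = [
        c
        for c in segments.columns
        if c not in ("bird_id", "t_start", "t_end", "day_before_laying")
    ]
    for region in region_cols:
        try:
            logistic[region] = fit_intersection_model(segments, region)
        except SeparationError as exc:
            errors.append(("-", f"logistic:{region}", str(exc)))

    odds: list[tuple[str, OddsRatioResult]] = []
    or_region = (
        "mean_incubation_circle"
        if "mean_incubation_circle" in segments.columns
        else region_cols[0]
    )
    w = config.day_windows
    for wa, wb in zip(w, w[1:]):
        label = f"{wa[0]}-{wa[1]} vs {wb[0]}-{wb[1]}"
        try:
            odds.append((label, window_odds_ratio(segments, or_region, wa, wb)))
        except ValidationError as exc:
            errors.append(("-", f"odds:{label}", str(exc)))

    bundle = ResultsBundle(
        subspecies=subspecies,
        summary=summary,
        membership=membership,
        window_counts=windows,
        mean_day_closest=windows.attrs["mean_day_closest"],
        frequencies=freqs,
        logistic=logistic,
        odds_ratios=odds,
        errors=[list(e) for e in errors],
        segments=segments,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary.csv", index=False)
        membership.to_csv(outdir / "membership.csv", index=False)
        freqs.to_csv(outdir / "frequencies.csv", index=False)
        segments.to_csv(outdir / "segments.csv", index=False)
        with open(outdir / "results.json", "w") as fh:
            json.dump(bundle.to_json_dict(), fh, indent=2, sort_keys=True)
        if make_figures:
            plot_interaction_figure(bundle, outdir / f"figure_{subspecies}.png")
    return bundle


def plot_interaction_figure(bundle: ResultsBundle, path: str | Path) -> None:
    """Two-panel figure: per-day intersection frequency and fitted curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_l, ax_r) = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    days = np.arange(1, int(bundle.frequencies["day_before_laying"].max()) + 1)
    for region in FIGURE_REGIONS:
        sub = bundle.frequencies[bundle.frequencies["region"] == region]
        if sub.empty:
            continue
        ax_l.plot(sub["day_before_laying"], sub["frequency"], label=region, lw=1)
        if region in bundle.logistic:
            ax_r.plot(
                days,
                predict_probability(bundle.logistic[region], days),
                label=region,
                lw=1.5,
            )
    for ax, title in ((ax_l, "relative frequency"), (ax_r, "fitted probability")):
        ax.set_xlim(days.max(), 1)  # day axis runs 45 -> 1
        ax.set_xlabel("days before laying")
        ax.set_ylabel(title)
        ax.legend(fontsize=7)
    fig.suptitle(f"Nest-buffer interaction, {bundle.subspecies}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
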