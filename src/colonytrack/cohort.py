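"""Pipeline orchestration: from TrackSets (measured or simulated) to the
full per-condition report.

A cohort is a set of colonies spanning leader percentages N (the mixing
ratio of mesenchymal leader cells into an epithelial follower population).
``run_pipeline`` computes, for every colony, the colony-level shape and
center-of-mass summaries and the per-cell trajectory metrics, then pools
them into condition × phenotype group summaries, pooled direction-angle
histograms, and a paired start-vs-end circularity comparison per condition.
All outputs are plain delimited text plus a flat-text manifest; a rerun from
the same configuration reproduces every table byte-identically.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EmptyInputError, InsufficientDataError, ValidationError
from .io import (
    ColonyMaskStack,
    TrackSet,
    read_mask_stack,
    read_tracks_table,
    write_tracks_table,
)
from .migration import angle_histogram, metrics_table, summarize_group, rebase_trajectory
from .morphology import (
    ColonyShapeRecord,
    centroid_path,
    circularity,
    colony_area,
    colony_perimeter,
    compare_endpoint_circularity,
)
from .simulate import SimulationParams, default_params, sweep_conditions

__all__ = [
    "RunConfig",
    "CohortReport",
    "run_pipeline",
    "trajectory_panel",
    "condition_contrast",
    "largest_component_records",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``inputs`` names track tables (with optional mask stacks) per
    condition, or ``fractions``/``seeds`` request a simulation sweep with
    ``params`` as the shared base parameters. Cells tracked for less than
    ``min_track_fraction`` of the colony's frame span are excluded from group
    summaries (short tracks bias straightness upward); they remain in the
    per-cell table, flagged.
    """

    fractions: tuple[float, ...] | None = None
    seeds: tuple[int, ...] | None = None
    params: SimulationParams | None = None
    inputs: tuple[dict, ...] | None = None  # {'tracks': path, 'condition': N, 'masks': path?, 'pixel_size': µm?}
    frame_interval: float = 15.0
    fiber_axis: str = "y"
    min_track_fraction: float = 0.25
    bin_width_deg: float = 10.0
    t0_h: float = 0.0
    t1_h: float = 24.0
    circularity_test: str = "wilcoxon"
    render: bool = True
    write_tracks: bool = False

    def __post_init__(self):
        sim_mode = self.fractions is not None or self.seeds is not None
        if sim_mode and self.inputs is not None:
            raise ConfigError("configure either a simulation sweep or inputs, not both")
        if not sim_mode and self.inputs is None:
            raise ConfigError("configuration names neither input files nor a sweep")
        if sim_mode and (not self.fractions or not self.seeds):
            raise ConfigError("sweep mode needs both fractions and seeds")
        if not 0.0 <= self.min_track_fraction <= 1.0:
            raise ConfigError("min_track_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortReport:
    """All tables of one run plus a complete provenance block."""

    cell_metrics: pd.DataFrame
    group_summary: pd.DataFrame
    angle_histograms: pd.DataFrame
    shape: pd.DataFrame
    centroids: pd.DataFrame
    circularity_comparison: pd.DataFrame
    tracksets: dict  # colony_id -> TrackSet
    provenance: dict


def largest_component_records(stack: ColonyMaskStack) -> list[ColonyShapeRecord | None]:
    """Shape record of the largest-area colony per frame (None for empty frames).

    After colonies fragment the dominant component stands in for "the colony";
    per-fragment analysis is out of scope.
    """
    records: list[ColonyShapeRecord | None] = []
    for k in range(len(stack)):
        page = stack.masks[k]
        labels, counts = np.unique(page[page > 0], return_counts=True)
        if labels.size == 0:
            records.append(None)
            continue
        best = int(labels[np.argmax(counts)])
        area = colony_area(page, best, stack.pixel_size)
        perim = colony_perimeter(page, best, stack.pixel_size)
        records.append(
            ColonyShapeRecord(
                frame=k,
                time_h=k * stack.frame_interval / 60.0,
                area_um2=area,
                perimeter_um=perim,
                circularity=circularity(area, perim),
            )
        )
    return records


def _gather_colonies(config: RunConfig) -> list[tuple[str, TrackSet, ColonyMaskStack | None, str]]:
    """Returns (colony_id, trackset, masks, digest) per colony."""
    colonies = []
    if config.inputs is not None:
        for spec_entry in config.inputs:
            path = Path(spec_entry["tracks"])
            ts = read_tracks_table(path, config.frame_interval, config.fiber_axis)
            declared = spec_entry.get("condition")
            if declared is not None:
                implied = ts.condition_from_phenotypes()
                if implied is not None:
                    n_cells = len(ts)
                    if abs(implied - declared) * n_cells / 100.0 > 1.0:
                        warnings.warn(
                            f"{path}: declared N={declared} differs from phenotype-"
                            f"implied N={implied:.1f} by more than one cell",
                            stacklevel=2,
                        )
                ts = ts.with_condition(float(declared))
            masks = None
            if spec_entry.get("masks"):
                masks = read_mask_stack(
                    spec_entry["masks"],
                    pixel_size=float(spec_entry.get("pixel_size", 1.0)),
                    frame_interval=config.frame_interval,
                )
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            colonies.append((spec_entry.get("id", path.stem), ts, masks, digest))
    else:
        base = config.params if config.params is not None else default_params()
        base = replace(base, frame_interval=config.frame_interval, fiber_axis=config.fiber_axis)
        outputs = sweep_conditions(
            base, config.fractions, config.seeds, render=config.render
        )
        for out in outputs:
            cid = f"N{int(out.params.condition):03d}_seed{out.params.seed}"
            colonies.append((cid, out.trackset, out.mask_stack, out.rng_state_digest))
    if not colonies:
        raise EmptyInputError("no colonies to analyze")
    intervals = {ts.frame_interval for _, ts, _, _ in colonies}
    if len(intervals) > 1:
        raise ValidationError(f"inconsistent frame intervals across conditions: {intervals}")
    return colonies


def run_pipeline(config: RunConfig, out_dir=None) -> CohortReport:
    """Run the full cohort analysis; optionally write all tables to ``out_dir``.

    Deterministic given the configuration and seeds: identical reruns produce
    byte-identical tables and manifest.
    """
    colonies = _gather_colonies(config)

    metric_frames = []
    shape_rows = []
    centroid_rows = []
    records_by_condition: dict[float, list] = {}
    tracksets = {}
    n_short_excluded = 0
    for colony_id, ts, masks, _digest in colonies:
        tracksets[colony_id] = ts
        table = metrics_table(ts)
        if not table.empty:
            lo, hi = ts.frame_range
            span = hi - lo + 1
            lengths = {t.cell_id: len(t) for t in ts.metric_eligible_tracks}
            table.insert(0, "colony_id", colony_id)
            table["included_in_summary"] = table["cell_id"].map(
                lambda cid: lengths[cid] >= config.min_track_fraction * span
            )
            n_short_excluded += int((~table["included_in_summary"]).sum())
            metric_frames.append(table)
        cp = centroid_path(ts)
        for t_h, (x, y) in zip(cp.times_h, cp.xy):
            centroid_rows.append(
                {"colony_id": colony_id, "time_h": t_h, "x_um": x, "y_um": y}
            )
        if masks is not None:
            records = largest_component_records(masks)
            cond = ts.condition if ts.condition is not None else float("nan")
            records_by_condition.setdefault(cond, []).append(records)
            for r in records:
                if r is None:
                    continue
                shape_rows.append(
                    {
                        "colony_id": colony_id,
                        "frame": r.frame,
                        "time_h": r.time_h,
                        "area_um2": r.area_um2,
                        "perimeter_um": r.perimeter_um,
                        "circularity": r.circularity,
                    }
                )

    if not metric_frames:
        raise EmptyInputError("no metric-eligible tracks in any colony")
    cell_metrics = pd.concat(metric_frames, ignore_index=True)

    summary_input = cell_metrics[cell_metrics["included_in_summary"]]
    group_summary = summarize_group(summary_input)

    hist_rows = []
    for cond, grp in summary_input.groupby("condition_N", dropna=False, sort=True):
        pooled = np.concatenate(list(grp["step_angles_deg"]))
        hist = angle_histogram(pooled, config.bin_width_deg)
        edges = hist["bin_edges_deg"]
        for lo_e, hi_e, count in zip(edges[:-1], edges[1:], hist["counts"]):
            hist_rows.append(
                {
                    "condition_N": cond,
                    "bin_lo_deg": lo_e,
                    "bin_hi_deg": hi_e,
                    "count": int(count),
                    "mean_deg": hist["mean_deg"],
                    "sd_deg": hist["sd_deg"],
                }
            )
    angle_histograms = pd.DataFrame(hist_rows)

    comparison_rows = []
    for cond, record_lists in sorted(records_by_condition.items()):
        if len(record_lists) < 3:
            warnings.warn(
                f"condition N={cond}: only {len(record_lists)} colonies with masks; "
                "skipping paired circularity comparison",
                stacklevel=2,
            )
            continue
        summary = compare_endpoint_circularity(
            record_lists, config.t0_h, config.t1_h, method=config.circularity_test
        )
        comparison_rows.append({"condition_N": cond, **summary})
    circularity_comparison = pd.DataFrame(comparison_rows)

    shape = pd.DataFrame(
        shape_rows,
        columns=["colony_id", "frame", "time_h", "area_um2", "perimeter_um", "circularity"],
    )
    centroids = pd.DataFrame(
        centroid_rows, columns=["colony_id", "time_h", "x_um", "y_um"]
    )

    from . import __version__

    provenance = {
        "software_version": __version__,
        "config": _config_to_flat(config),
        "colony_digests": {cid: digest for cid, _, _, digest in colonies},
        "n_short_tracks_excluded_from_summaries": n_short_excluded,
    }
    report = CohortReport(
        cell_metrics=cell_metrics,
        group_summary=group_summary,
        angle_histograms=angle_histograms,
        shape=shape,
        centroids=centroids,
        circularity_comparison=circularity_comparison,
        tracksets=tracksets,
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, out_dir, config)
    return report


def _config_to_flat(config: RunConfig) -> dict:
    flat = {}
    for name in (
        "frame_interval",
        "fiber_axis",
        "min_track_fraction",
        "bin_width_deg",
        "t0_h",
        "t1_h",
        "circularity_test",
        "render",
        "write_tracks",
    ):
        flat[name] = getattr(config, name)
    if config.fractions is not None:
        flat["fractions"] = ",".join(str(int(N)) for N in config.fractions)
        flat["seeds"] = ",".join(str(s) for s in config.seeds)
        params = config.params if config.params is not None else default_params()
        for f in sorted(vars(params)):
            flat[f"params.{f}"] = getattr(params, f)
    else:
        for k, entry in enumerate(config.inputs):
            flat[f"input{k}.tracks"] = str(entry["tracks"])
            if entry.get("condition") is not None:
                flat[f"input{k}.condition"] = entry["condition"]
            if entry.get("masks"):
                flat[f"input{k}.masks"] = str(entry["masks"])
    return flat


def write_report(report: CohortReport, out_dir, config: RunConfig | None = None) -> None:
    """Write every table (and the manifest) as delimited text under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "cell_metrics.csv": report.cell_metrics.drop(columns=["step_angles_deg"]),
        "group_summary.csv": report.group_summary,
        "angle_histograms.csv": report.angle_histograms,
        "shape.csv": report.shape,
        "centroids.csv": report.centroids,
        "circularity_comparison.csv": report.circularity_comparison,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.6f")
    if config is not None and config.write_tracks:
        tracks_dir = out / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        for colony_id, ts in report.tracksets.items():
            write_tracks_table(ts, tracks_dir / f"{colony_id}.csv")
    lines = []
    for key, value in sorted(report.provenance["config"].items()):
        lines.append(f"config.{key} = {value}")
    for cid, digest in sorted(report.provenance["colony_digests"].items()):
        lines.append(f"digest.{cid} = {digest}")
    lines.append(
        "n_short_tracks_excluded = "
        f"{report.provenance['n_short_tracks_excluded_from_summaries']}"
    )
    lines.append(f"software_version = {report.provenance['software_version']}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


def trajectory_panel(ts: TrackSet, stratify: str = "all"):
    """Rebased trajectories for a Fig-style panel, with per-track extents.

    ``stratify`` selects ``'all'``, ``'leader'`` or ``'follower'`` tracks;
    every returned track starts at (0, 0). The extents table carries each
    track's max |x| and max |y| so axis ranges can be compared across panels.
    """
    if stratify not in ("all", "leader", "follower"):
        raise ConfigError(f"stratify must be all/leader/follower, got {stratify!r}")
    if len(ts) == 0:
        raise EmptyInputError("empty TrackSet")
    selected = [
        t
        for t in ts.metric_eligible_tracks
        if stratify == "all" or t.phenotype == stratify
    ]
    if not selected:
        warnings.warn(f"no tracks match filter {stratify!r}; empty panel", stacklevel=2)
        return [], pd.DataFrame(columns=["cell_id", "phenotype", "max_abs_x_um", "max_abs_y_um"])
    rebased = [rebase_trajectory(t) for t in selected]
    extents = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in rebased],
            "phenotype": [t.phenotype for t in rebased],
            "max_abs_x_um": [float(np.abs(t.xy[:, 0]).max()) for t in rebased],
            "max_abs_y_um": [float(np.abs(t.xy[:, 1]).max()) for t in rebased],
        }
    )
    return rebased, extents


_CONTRAST_METRICS = (
    "straightness",
    "mean_speed_um_h",
    "net_speed_um_h",
    "d_total_um",
    "d_euclid_um",
)


def condition_contrast(
    report: CohortReport,
    metric: str,
    g1: float,
    g2: float,
    phenotype: str = "all",
) -> dict:
    """Welch two-sample comparison of a per-cell metric between conditions.

    Exploratory by design: the underlying study reports mean ± SD without a
    named test, so this contrast is labeled as such in the output.
    """
    if metric not in _CONTRAST_METRICS:
        raise ConfigError(f"unknown metric {metric!r}; choose from {_CONTRAST_METRICS}")
    if phenotype not in ("all", "leader", "follower"):
        raise ConfigError(f"phenotype must be all/leader/follower, got {phenotype!r}")
    df = report.cell_metrics
    df = df[df["included_in_summary"]]
    if phenotype != "all":
        df = df[df["phenotype"] == phenotype]

    def _values(N):
        vals = df.loc[df["condition_N"] == N, metric].to_numpy(dtype=float)
        return vals[~np.isnan(vals)]

    a, b = _values(g1), _values(g2)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"need >=3 cells per group, got {a.size} (N={g1}) and {b.size} (N={g2})"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return {
        "metric": metric,
        "phenotype": phenotype,
        "g1_N": g1,
        "g2_N": g2,
        "n1": int(a.size),
        "n2": int(b.size),
        "mean1": float(a.mean()),
        "sd1": float(a.std(ddof=1)),
        "mean2": float(b.mean()),
        "sd2": float(b.std(ddof=1)),
        "difference": float(a.mean() - b.mean()),
        "ci95_low": float(ci.low),
        "ci95_high": float(ci.high),
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "note": "exploratory Welch contrast",
    }
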