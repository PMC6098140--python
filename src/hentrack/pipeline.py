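"""End-to-end orchestration: simulate -> preprocess -> features ->
classify (lda | hc | dtw) -> report, with figure output.

Every delimited artifact carries a header comment with the config hash
and master seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cluster, dtw, features, lda, plots, sim, tracking
from .core import AnalysisWindow, DEFAULT_WINDOW, GroupingReport

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

METHODS = ("lda", "hc", "dtw")


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    seed: int = 0
    n_days: int = 7
    flock: tuple[tuple[str, str], ...] = sim.DEFAULT_FLOCK
    day_noise: float | None = None
    misread_rate: float | None = None
    schedule: sim.ScheduleConfig = field(default_factory=sim.ScheduleConfig)
    window: AnalysisWindow = DEFAULT_WINDOW
    clean_max_gap_s: int = 60
    clean_min_dwell_s: int = 0
    dtw_config: dtw.DTWConfig = field(default_factory=dtw.DTWConfig)
    hc_scale: bool = False
    lda_threshold: float = 0.05
    methods: tuple[str, ...] = METHODS
    make_plots: bool = True

    def __post_init__(self) -> None:
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {METHODS}")

    def canonical(self) -> str:
        payload = {
            "seed": self.seed,
            "n_days": self.n_days,
            "flock": list(map(list, self.flock)),
            "day_noise": self.day_noise,
            "misread_rate": self.misread_rate,
            "schedule": [
                self.schedule.lights_on_s,
                self.schedule.lights_off_s,
                self.schedule.pophole_open_s,
                self.schedule.pophole_close_s,
            ],
            "window": [self.window.start_s, self.window.end_s],
            "clean": [self.clean_max_gap_s, self.clean_min_dwell_s],
            "dtw": [
                self.dtw_config.window_frac,
                self.dtw_config.local_cost,
                self.dtw_config.downsample_s,
            ],
            "hc_scale": self.hc_scale,
            "lda_threshold": self.lda_threshold,
            "methods": list(self.methods),
        }
        return json.dumps(payload, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


_KNOWN_KEYS = {
    "seed",
    "n_days",
    "hens",
    "day_noise",
    "misread_rate",
    "schedule",
    "window",
    "clean_max_gap_s",
    "clean_min_dwell_s",
    "dtw",
    "hc_scale",
    "lda_threshold",
    "methods",
    "make_plots",
}


def load_pipeline_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("seed", "n_days", "day_noise", "misread_rate", "clean_max_gap_s",
                "clean_min_dwell_s", "hc_scale", "lda_threshold", "make_plots"):
        if key in raw:
            kwargs[key] = raw[key]
    if "hens" in raw:
        kwargs["flock"] = tuple((str(h["hen_id"]), h["archetype"]) for h in raw["hens"])
    if "schedule" in raw:
        s = raw["schedule"]
        kwargs["schedule"] = sim.ScheduleConfig(
            lights_on_s=sim._parse_clock(s.get("lights_on", "02:00:00")),
            lights_off_s=sim._parse_clock(s.get("lights_off", "17:00:00")),
            pophole_open_s=sim._parse_clock(s.get("pophole_open", "10:00:00")),
            pophole_close_s=sim._parse_clock(s.get("pophole_close", "16:45:00")),
        )
    if "window" in raw:
        w = raw["window"]
        kwargs["window"] = AnalysisWindow(
            sim._parse_clock(w["start"]), sim._parse_clock(w["end"])
        )
    if "dtw" in raw:
        d = raw["dtw"]
        kwargs["dtw_config"] = dtw.DTWConfig(
            window_frac=d.get("window_frac", 0.10),
            local_cost=d.get("local_cost", "abs"),
            downsample_s=d.get("downsample_s", 60),
        )
    if "methods" in raw:
        kwargs["methods"] = tuple(raw["methods"])
    return PipelineConfig(**kwargs)


def _stamp(config: PipelineConfig) -> str:
    return f"# config_hash={config.config_hash} seed={config.seed}\n"


def _write_stamped(path: Path, config: PipelineConfig, body: str) -> None:
    path.write_text(_stamp(config) + body)


def _write_frame(path: Path, config: PipelineConfig, df) -> None:
    _write_stamped(path, config, df.to_csv(index=False))


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all configured stages into ``outdir``; returns the results summary.

    Artifacts: per-hen logs are kept in memory (use the CLI ``simulate``
    subcommand to export them); the run directory receives the feature
    table, flock summary, per-method matrices/trees/reports, figures and
    ``results.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "methods": {},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        profiles = sim.default_profiles(
            config.seed,
            flock=config.flock,
            day_noise=config.day_noise,
            misread_rate=config.misread_rate,
        )
        logs = sim.simulate_flock(
            profiles, config.schedule, n_days=config.n_days, master_seed=config.seed
        )
        logger.info("stage simulate: %.2fs", time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        cleaned = [
            tracking.clean_log(lg, config.clean_max_gap_s, config.clean_min_dwell_s)
            for lg in logs
        ]
        hendays = tracking.build_hen_days(cleaned, window=config.window)
        summary["n_hen_days"] = len(hendays)
        summary["samples_per_hen_day"] = config.window.length
        logger.info("stage preprocess: %.2fs", time.perf_counter() - t0)

        stage = "features"
        t0 = time.perf_counter()
        feats = [features.summarize(hd) for hd in hendays]
        table = features.feature_table(feats)
        _write_frame(outdir / "features.csv", config, table)
        flock = features.flock_summary(feats)
        _write_stamped(
            outdir / "flock_summary.txt", config, features.render_flock_summary(flock) + "\n"
        )
        summary["flock_mean_total"] = round(flock.mean["total"], 2)
        logger.info("stage features: %.2fs", time.perf_counter() - t0)

        labels = [f.label for f in feats]
        hen_labels = [f.hen_id for f in feats]

        if "lda" in config.methods:
            stage = "classify:lda"
            t0 = time.perf_counter()
            model, report = lda.evaluate_lda(
                feats, hen_labels, threshold=config.lda_threshold
            )
            report.method = "lda"
            _write_stamped(
                outdir / "lda_report.txt",
                config,
                f"selected variables: {', '.join(model.selected_vars)}\n"
                f"discriminant eigenvalues: "
                + ", ".join(f"{v:.4g}" for v in model.eigvals[: model.n_discriminants])
                + "\n\n"
                + report.to_text()
                + "\n",
            )
            summary["methods"]["lda"] = _report_summary(report)
            summary["methods"]["lda"]["selected_vars"] = list(model.selected_vars)
            logger.info("stage classify:lda: %.2fs", time.perf_counter() - t0)

        tree_for_plot = None
        if "hc" in config.methods:
            stage = "classify:hc"
            t0 = time.perf_counter()
            D = cluster.feature_distances(feats, scale=config.hc_scale)
            tree = cluster.ward_linkage(D)
            cluster.write_linkage(tree, outdir / "hc_linkage.tsv")
            (outdir / "hc_dendrogram.nwk").write_text(cluster.to_newick(tree) + "\n")
            grouping, report = cluster.best_grouping(tree, labels)
            report.method = "hc"
            _write_stamped(outdir / "hc_report.txt", config, report.to_text() + "\n")
            summary["methods"]["hc"] = _report_summary(report)
            tree_for_plot = (tree, grouping, "hc_dendrogram.png")
            logger.info("stage classify:hc: %.2fs", time.perf_counter() - t0)

        dtw_plot = None
        if "dtw" in config.methods:
            stage = "classify:dtw"
            t0 = time.perf_counter()
            D = dtw.dtw_matrix(hendays, config.dtw_config)
            dtw.write_matrix(D, outdir / "dtw_matrix.csv")
            tree = cluster.ward_linkage(D)
            cluster.write_linkage(tree, outdir / "dtw_linkage.tsv")
            grouping, report = cluster.best_grouping(tree, labels)
            report.method = "dtw"
            _write_stamped(outdir / "dtw_report.txt", config, report.to_text() + "\n")
            summary["methods"]["dtw"] = _report_summary(report)
            summary["dtw_matrix_size"] = D.n
            summary["dtw_band_width"] = dtw.band_width(
                config.window.length // config.dtw_config.downsample_s,
                config.window.length // config.dtw_config.downsample_s,
                config.dtw_config.window_frac,
            )
            dtw_plot = (tree, grouping, "dtw_dendrogram.png")
            logger.info("stage classify:dtw: %.2fs", time.perf_counter() - t0)

        if config.make_plots:
            stage = "plots"
            t0 = time.perf_counter()
            first_hen = hendays[0].hen_id if hendays else None
            if first_hen is not None:
                plots.plot_location(
                    [hd for hd in hendays if hd.hen_id == first_hen],
                    outdir / f"location_hen_{first_hen}.png",
                )
            plots.plot_boxes(feats, outdir / "boxes.png")
            for item in (tree_for_plot, dtw_plot):
                if item is not None:
                    tree, grouping, name = item
                    plots.plot_dendrogram(tree, grouping, outdir / name)
            logger.info("stage plots: %.2fs", time.perf_counter() - t0)

        stage = "report"
        (outdir / "results.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return summary


def _report_summary(report: GroupingReport) -> dict:
    out = {
        "overall_pct": round(report.overall_pct, 2),
        "total_count": report.total_count,
        "total_days": report.total_days,
        "per_hen": {s.hen_id: s.count for s in report.scores},
        "footnotes": list(report.footnotes),
    }
    if report.k is not None:
        out["k"] = report.k
    return out
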