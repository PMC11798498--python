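"""End-to-end orchestration and the JSON analysis report."""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .groupstats import one_way_anova
from .io import Micrograph
from .mechanics import LoadSeries, cycle_energies, energy_trend
from .morphometry import AUTO, analyze_micrograph
from .risk import summarize_risk

__all__ = ["RunConfig", "run_full_analysis", "write_report"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one validated place."""

    scale_um_per_px: float | None = None
    k_range: tuple[int, int] = (2, 6)
    seed: int = 0
    max_iter: int = 100
    restarts: int = 1
    pe_variant: str = "occupancy"
    threshold: float = 0.5
    particle_is_dark: bool = True
    min_pixels: int = 5
    target_cluster: object = AUTO
    fill_holes: bool = True
    dimension: str = "major"
    period_s: float = 4.0
    window: int = 250
    drop_ratio: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid k_range {self.k_range}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.dimension not in ("major", "minor", "area"):
            raise ValueError("dimension must be major, minor or area")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not 0 < self.drop_ratio < 1:
            raise ValueError("drop_ratio must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in d:
            d = dict(d, k_range=tuple(d["k_range"]))
        return cls(**d)


def run_full_analysis(
    images: list[Micrograph] | None = None,
    load_log: LoadSeries | None = None,
    group_tables: dict[str, pd.DataFrame] | None = None,
    anova_column: str = "area_um2",
    cfg: RunConfig | None = None,
) -> dict:
    """Run every applicable stage and assemble the versioned report dict.

    Any subset of inputs may be present (at least one); missing stages are
    simply absent from the report. The report is losslessly serialisable
    to JSON and, minus timestamps, is a pure function of inputs + config.
    """
    if not images and load_log is None and not group_tables:
        raise ValueError("no inputs: provide images, a load log, or group tables")
    cfg = cfg or RunConfig()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": {k: (v if not isinstance(v, tuple) else list(v)) for k, v in asdict(cfg).items()},
    }
    if images:
        image_blocks = []
        for m in images:
            res = analyze_micrograph(
                m,
                k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
                seed=cfg.seed,
                threshold=cfg.threshold,
                particle_is_dark=cfg.particle_is_dark,
                min_pixels=cfg.min_pixels,
                target_cluster=cfg.target_cluster,
                fill=cfg.fill_holes,
                max_iter=cfg.max_iter,
                restarts=cfg.restarts,
                pe_variant=cfg.pe_variant,
            )
            log.info(
                "image %s: k*=%d, target cluster %d, %d particles",
                m.source_id, res.k_star, res.target_cluster, len(res.measurements),
            )
            risk = summarize_risk(res.measurements, dimension=cfg.dimension, missing="drop")
            image_blocks.append(
                {
                    "source_id": m.source_id,
                    "scale_um_per_px": m.scale_um_per_px,
                    "k_star": res.k_star,
                    "pe_scores": [{"k": s.k, "pe": s.pe} for s in res.pe_scores],
                    "target_cluster": res.target_cluster,
                    "n_particles": int(len(res.measurements)),
                    "measurements": res.measurements.to_dict(orient="records"),
                    "risk_summary": {
                        "dimension": cfg.dimension,
                        "counts": risk["count"].to_dict() if len(risk) else {},
                        "fractions": risk["fraction"].to_dict() if len(risk) else {},
                    },
                }
            )
        report["images"] = image_blocks
    if load_log is not None:
        energies = cycle_energies(load_log, period_s=cfg.period_s)
        trend = energy_trend(energies, window=cfg.window, drop_ratio=cfg.drop_ratio)
        report["mechanics"] = {
            "n_cycles": len(energies),
            "mean_energy_Nmm": float(pd.Series([e.energy_Nmm for e in energies]).mean()),
            "window": trend.window,
            "window_mean_Nmm": [float(x) for x in trend.window_mean_Nmm],
            "window_variance": [float(x) for x in trend.window_variance],
            "drop_events": [
                {"cycle": c, "before_Nmm": b, "after_Nmm": a} for c, b, a in trend.drop_events
            ],
        }
    if group_tables:
        col = anova_column
        groups = [tbl[col].to_numpy(float) for tbl in group_tables.values()]
        res = one_way_anova(groups, missing="drop")
        report["anova"] = {
            "column": col,
            "groups": list(group_tables.keys()),
            "F": res.F,
            "df_between": res.df_between,
            "df_within": res.df_within,
            "p": res.p,
            "group_ns": list(res.group_ns),
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
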