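"""Cyclic-compression analysis: hysteresis-loop energy and damage detection.

A compression test log is a time/force/displacement series sampled at a
nominal 20 Hz while the machine runs a programmed four-step cycle (ramp to
peak force in 1 s, hold 1 s, ramp down 1 s, hold 1 s; 4 s period). The
energy a specimen absorbs in one cycle is the area enclosed by its
force-displacement hysteresis loop, computed here as the absolute shoelace
area of the closed (displacement, force) polygon, in N*mm. A sustained
step-down in per-cycle energy marks a damage event (e.g. crack growth
releasing stored energy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadSeries",
    "CycleEnergy",
    "EnergyTrend",
    "read_load_series",
    "write_load_series",
    "segment_cycles",
    "loop_energy",
    "cycle_energies",
    "energy_trend",
]


@dataclass
class LoadSeries:
    """Equal-length time (s), force (N), displacement (mm) records.

    Compression is positive; small negative force readings down to
    ``force_tolerance_N`` are accepted as load-cell noise.
    """

    time_s: np.ndarray
    force_N: np.ndarray
    displacement_mm: np.ndarray
    sample_rate_hz: float = 20.0
    force_tolerance_N: float = 0.5

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        n = self.time_s.size
        if self.force_N.size != n or self.displacement_mm.size != n:
            raise ValueError("time, force and displacement must have equal length")
        if n >= 2 and not (np.diff(self.time_s) > 0).all():
            raise ValueError("time must be strictly increasing")
        if n and self.force_N.min() < -self.force_tolerance_N:
            raise ValueError(
                f"force dips to {self.force_N.min():.3g} N below the compressive "
                f"convention tolerance of -{self.force_tolerance_N} N"
            )

    def __len__(self) -> int:
        return self.time_s.size

    def slice(self, start: int, stop: int) -> "LoadSeries":
        return LoadSeries(
            self.time_s[start:stop],
            self.force_N[start:stop],
            self.displacement_mm[start:stop],
            sample_rate_hz=self.sample_rate_hz,
            force_tolerance_N=self.force_tolerance_N,
        )


@dataclass(frozen=True)
class CycleEnergy:
    cycle_index: int          # 1-based
    energy_Nmm: float
    start_s: float
    end_s: float


@dataclass
class EnergyTrend:
    window: int
    window_mean_Nmm: np.ndarray
    window_variance: np.ndarray
    drop_events: list[tuple[int, float, float]] = field(default_factory=list)
    # each event: (cycle_index, median energy before, energy at the drop)


def read_load_series(path: str | Path, sample_rate_hz: float = 20.0) -> LoadSeries:
    """Read a ``time_s, force_N, displacement_mm`` CSV (header required)."""
    df = pd.read_csv(path)
    required = ["time_s", "force_N", "displacement_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"load log {path} lacks required columns {missing}")
    return LoadSeries(
        df["time_s"].to_numpy(float),
        df["force_N"].to_numpy(float),
        df["displacement_mm"].to_numpy(float),
        sample_rate_hz=sample_rate_hz,
    )


def write_load_series(s: LoadSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": s.time_s, "force_N": s.force_N, "displacement_mm": s.displacement_mm}
    ).to_csv(Path(path), index=False)


def segment_cycles(s: LoadSeries, period_s: float = 4.0, mode: str = "fixed") -> list[LoadSeries]:
    """Split a log into per-cycle slices.

    ``mode="fixed"`` (default) slices at exact multiples of ``period_s``
    anchored at the first timestamp — appropriate for a machine-programmed
    cycle. ``mode="trigger"`` instead splits at upward crossings of 5% of
    the peak force, tolerating clock drift. A trailing partial cycle is
    discarded with a warning. Sample conservation holds: the slice lengths
    plus the discarded tail sum to the input length.
    """
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    if len(s) < 2:
        raise ValueError("load series too short to segment")
    duration = s.time_s[-1] - s.time_s[0]
    dt = 1.0 / s.sample_rate_hz
    if duration + dt < period_s:
        raise ValueError(
            f"series spans {duration:.3g} s, shorter than one {period_s:.3g} s cycle"
        )
    if mode == "fixed":
        rel = s.time_s - s.time_s[0]
        idx = np.floor(rel / period_s + 1e-9).astype(int)
        n_full = int(np.ceil((duration + dt) / period_s - 1e-9))
        bounds = np.searchsorted(idx, np.arange(n_full + 1))
        slices = []
        for i in range(n_full):
            start, stop = bounds[i], bounds[i + 1]
            if stop <= start:
                continue
            # a full cycle must span (almost) the whole period
            if s.time_s[stop - 1] - s.time_s[start] + 1.5 / s.sample_rate_hz >= period_s:
                slices.append(s.slice(start, stop))
            else:
                warnings.warn(
                    f"discarding trailing partial cycle of {stop - start} samples"
                )
        return slices
    if mode == "trigger":
        thresh = 0.05 * s.force_N.max()
        rising = np.where((s.force_N[:-1] < thresh) & (s.force_N[1:] >= thresh))[0] + 1
        if len(rising) < 2:
            raise ValueError("fewer than two trigger crossings; cannot segment")
        slices = [s.slice(rising[i], rising[i + 1]) for i in range(len(rising) - 1)]
        warnings.warn("discarding samples outside the first/last trigger crossing")
        return slices
    raise ValueError(f"unknown segmentation mode {mode!r}")


def loop_energy(cycle: LoadSeries, cycle_index: int = 1) -> CycleEnergy:
    """Absorbed energy of one cycle: |shoelace area| of the closed loop.

    The polygon lives in the (displacement_mm, force_N) plane and is closed
    from the last sample back to the first; the result is in N*mm and is
    invariant under cyclic rotation of the sample order.
    """
    x = cycle.displacement_mm
    y = cycle.force_N
    if len(np.unique(np.column_stack([x, y]), axis=0)) < 3:
        warnings.warn("degenerate cycle (<3 distinct points); energy set to 0")
        area = 0.0
    else:
        area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return CycleEnergy(
        cycle_index=cycle_index,
        energy_Nmm=area,
        start_s=float(cycle.time_s[0]),
        end_s=float(cycle.time_s[-1]),
    )


def cycle_energies(s: LoadSeries, period_s: float = 4.0, mode: str = "fixed") -> list[CycleEnergy]:
    """Segment a log and compute the energy of every cycle."""
    return [
        loop_energy(c, cycle_index=i)
        for i, c in enumerate(segment_cycles(s, period_s=period_s, mode=mode), start=1)
    ]


def energy_trend(
    energies: list[CycleEnergy],
    window: int = 250,
    drop_ratio: float = 0.3,
) -> EnergyTrend:
    """Windowed statistics and sudden-drop detection on per-cycle energies.

    Means and sample variances are computed over non-overlapping windows of
    ``window`` cycles (a final shorter window is kept; if there are fewer
    cycles than one window, a single window covers them all). A drop event
    is recorded at the onset cycle c where energy(c) falls below
    (1 - drop_ratio) times the median of the up-to-``window`` preceding
    cycles while the previous cycle did not — so one sustained step-down
    yields exactly one event.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 < drop_ratio < 1:
        raise ValueError("drop_ratio must lie in (0, 1)")
    if not energies:
        raise ValueError("no cycle energies given")
    e = np.array([ce.energy_Nmm for ce in energies])
    n = e.size
    starts = range(0, n, window) if n > window else [0]
    means, variances = [], []
    for s0 in starts:
        chunk = e[s0 : s0 + window]
        means.append(chunk.mean())
        variances.append(chunk.var(ddof=1) if chunk.size > 1 else 0.0)

    def _triggers(i: int) -> tuple[bool, float]:
        prev = e[max(0, i - window) : i]
        med = float(np.median(prev))
        return bool(e[i] < (1.0 - drop_ratio) * med), med

    events = []
    prev_hit = False
    for i in range(1, n):
        hit, med = _triggers(i)
        if hit and not prev_hit:
            events.append((energies[i].cycle_index, med, float(e[i])))
        prev_hit = hit
    return EnergyTrend(
        window=window,
        window_mean_Nmm=np.array(means),
        window_variance=np.array(variances),
        drop_events=events,
    )
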