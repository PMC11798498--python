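"""Synthetic fixtures with exact ground truth.

Two generators make every pipeline stage testable without the original
laboratory data (which was never published):

* micrographs — dark irregular/elliptical particles of known micrometre
  dimensions on a bright, mildly graded, noisy background, emulating
  transmitted-light images of saliva residue on a glass slide;
* cyclic-compression logs — the four-step 0-to-peak force cycle (1 s ramp
  up, 1 s hold, 1 s ramp down, 1 s hold) with a displacement trace
  constructed so each cycle's closed force-displacement loop encloses a
  requested area exactly.

Everything is a pure function of (spec, seed): the same spec generates
bit-identical output every time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Micrograph
from .mechanics import CycleEnergy, LoadSeries
from .morphometry import LabelledRegions, measure_particle

__all__ = [
    "ParticleSpec",
    "SceneSpec",
    "LoadSpec",
    "generate_micrograph",
    "generate_load_series",
    "random_scene",
]


@dataclass(frozen=True)
class ParticleSpec:
    """One particle to rasterize: ellipse or irregular blob.

    ``center_um`` is (row, col) from the top-left corner; ``orientation_rad``
    is counter-clockwise from the +col axis. Blobs are ellipses whose
    radius is modulated by a seeded low-order radial Fourier perturbation
    (harmonics 2-6, total amplitude <= 20% of the radius), mimicking
    irregular fracture fragments without creating touching-particle
    ambiguity.
    """

    shape: str = "ellipse"                    # "ellipse" | "blob"
    center_um: tuple[float, float] = (0.0, 0.0)
    major_um: float = 40.0
    minor_um: float = 20.0
    orientation_rad: float = 0.0
    color: tuple[float, float, float] = (0.35, 0.30, 0.28)
    blob_amplitude: float = 0.15


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic micrograph scene."""

    shape: tuple[int, int] = (160, 160)       # (H, W) pixels
    scale_um_per_px: float = 1.0
    background_rgb: tuple[float, float, float] = (0.85, 0.83, 0.80)
    gradient_amplitude: float = 0.05
    noise_sigma: float = 0.02
    particles: tuple[ParticleSpec, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class LoadSpec:
    """A cyclic-compression log specification.

    ``loop_area_Nmm`` is the energy each loop must enclose (a scalar or a
    per-cycle schedule); ``drop`` optionally replaces it with
    ``drop["new_area"]`` from cycle ``drop["at_cycle"]`` (1-based) onward,
    modelling a sudden damage event. ``compliance_mm_per_N`` sets the
    elastic displacement line (default gives 0.1 mm at 50 N);
    ``drift_mm`` is a slow linear baseline drift over the whole test.
    """

    n_cycles: int = 100
    peak_force_N: float = 50.0
    period_s: float = 4.0
    samples_per_cycle: int = 80
    loop_area_Nmm: float | tuple[float, ...] = 5.0
    compliance_mm_per_N: float = 0.002
    drift_mm: float = 0.0
    drop: dict | None = None                  # {"at_cycle": int, "new_area": float}
    noise_sigma: float = 0.0
    seed: int = 0


def _particle_mask(p: ParticleSpec, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    s = spec.scale_um_per_px
    a = p.major_um / 2.0 / s        # semi-axes in px
    b = p.minor_um / 2.0 / s
    if not (a > 0 and b > 0 and a >= b):
        raise ValueError("particle axes must satisfy major >= minor > 0")
    r0, c0 = p.center_um[0] / s, p.center_um[1] / s
    rows, cols = np.mgrid[0:h, 0:w]
    dr, dc = rows - r0, cols - c0
    th = p.orientation_rad
    u = dc * np.cos(th) - dr * np.sin(th)     # along major axis
    v = dr * np.cos(th) + dc * np.sin(th)     # along minor axis
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if p.shape == "ellipse":
        return rho <= 1.0
    if p.shape == "blob":
        if not 0.0 <= p.blob_amplitude <= 0.2:
            raise ValueError("blob_amplitude must lie in [0, 0.2]")
        orders = np.arange(2, 7)
        amps = rng.uniform(0, 1, size=orders.size)
        amps *= p.blob_amplitude / max(amps.sum(), 1e-12)
        phases = rng.uniform(0, 2 * np.pi, size=orders.size)
        phi = np.arctan2(v, u)
        mod = 1.0 + sum(
            amp * np.cos(k * phi + ph) for amp, k, ph in zip(amps, orders, phases)
        )
        return rho <= mod
    raise ValueError(f"unknown particle shape {p.shape!r}")


def generate_micrograph(spec: SceneSpec) -> tuple[Micrograph, pd.DataFrame]:
    """Rasterize a scene and return (micrograph, ground-truth table).

    Ground truth is measured on each particle's clean rasterized mask
    (before gradient and noise): pixel-count area and equivalent-ellipse
    axis lengths, in micrometres, sorted by decreasing area with 1-based
    ``particle_id`` matching that order. Particles that overlap, touch
    (8-adjacency), or cross the frame border are rejected so the truth
    stays unambiguous.
    """
    h, w = spec.shape
    if h < 3 or w < 3:
        raise ValueError("scene must be at least 3 x 3 pixels")
    rng = np.random.default_rng(spec.seed)
    masks = [_particle_mask(p, spec, rng) for p in spec.particles]

    occupied = np.zeros((h, w), dtype=bool)
    for i, mask in enumerate(masks):
        if not mask.any():
            raise ValueError(f"particle {i + 1} rasterizes to zero pixels at this scale")
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise ValueError(f"particle {i + 1} touches the frame border")
        dil = _dilate8(mask)
        if (occupied & dil).any():
            raise ValueError(f"particle {i + 1} overlaps or touches another particle")
        occupied |= mask

    # background: base colour + linear gradient along a seeded direction
    theta = rng.uniform(0, 2 * np.pi)
    rows, cols = np.mgrid[0:h, 0:w]
    t = (rows / max(h - 1, 1) - 0.5) * np.sin(theta) + (cols / max(w - 1, 1) - 0.5) * np.cos(theta)
    img = np.empty((h, w, 3))
    for ch in range(3):
        img[:, :, ch] = spec.background_rgb[ch] + spec.gradient_amplitude * t
    for p, mask in zip(spec.particles, masks):
        for ch in range(3):
            img[:, :, ch][mask] = p.color[ch]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    m = Micrograph(img, spec.scale_um_per_px, source_id=f"synthetic-seed{spec.seed}")

    records = []
    for mask in masks:
        regions = LabelledRegions(mask.astype(int), 1)
        meas = measure_particle(regions, 1, spec.scale_um_per_px)
        records.append(meas)
    records.sort(key=lambda r: -r.area_um2)
    truth = pd.DataFrame(
        {
            "source_id": m.source_id,
            "particle_id": np.arange(1, len(records) + 1),
            "area_um2": [r.area_um2 for r in records],
            "major_um": [r.major_um for r in records],
            "minor_um": [r.minor_um for r in records],
            "pixel_count": [r.pixel_count for r in records],
        }
    )
    return m, truth


def _dilate8(mask: np.ndarray) -> np.ndarray:
    # one-pixel 8-neighbourhood dilation: vertical pass then horizontal pass
    tmp = mask.copy()
    tmp[1:, :] |= mask[:-1, :]
    tmp[:-1, :] |= mask[1:, :]
    out = tmp.copy()
    out[:, 1:] |= tmp[:, :-1]
    out[:, :-1] |= tmp[:, 1:]
    return out


def _area_schedule(spec: LoadSpec) -> np.ndarray:
    if np.isscalar(spec.loop_area_Nmm):
        areas = np.full(spec.n_cycles, float(spec.loop_area_Nmm))
    else:
        areas = np.asarray(spec.loop_area_Nmm, dtype=float)
        if areas.size != spec.n_cycles:
            raise ValueError("loop_area schedule length must equal n_cycles")
        areas = areas.copy()
    if spec.drop is not None:
        at = int(spec.drop["at_cycle"])
        if not 1 <= at <= spec.n_cycles:
            raise ValueError("drop.at_cycle must lie within 1..n_cycles")
        areas[at - 1 :] = float(spec.drop["new_area"])
    if (areas < 0).any():
        raise ValueError("loop areas must be non-negative")
    return areas


def generate_load_series(spec: LoadSpec) -> tuple[LoadSeries, list[CycleEnergy]]:
    """Generate a four-step cyclic load log with exact per-cycle loop areas.

    Within each cycle the force ramps 0 -> peak over the first quarter
    period, holds, ramps back to 0, and holds again. Displacement follows
    the elastic line ``compliance * F`` plus a hysteretic creep offset: it
    advances by ``delta = area / peak_force`` during the high hold and
    recovers during the zero hold, so the closed loop is a parallelogram
    of exactly the requested area. With ``samples_per_cycle`` divisible by
    4 every loop vertex is sampled and the discretised (shoelace) energy
    equals the requested one to rounding error.

    Returns the log and the per-cycle truth (the requested areas).
    """
    if spec.n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if spec.samples_per_cycle < 4:
        raise ValueError(
            "samples_per_cycle must be >= 4 to represent the four-step cycle"
        )
    if spec.peak_force_N <= 0:
        raise ValueError("peak_force_N must be positive")
    areas = _area_schedule(spec)
    rng = np.random.default_rng(spec.seed)
    spc = spec.samples_per_cycle
    n_total = spec.n_cycles * spc
    dt = spec.period_s / spc
    time = np.arange(n_total) * dt
    u = (np.arange(spc) * (4.0 / spc))        # phase within cycle, in [0, 4)

    force_cycle = np.empty(spc)
    for j, uj in enumerate(u):
        if uj < 1.0:
            force_cycle[j] = spec.peak_force_N * uj
        elif uj < 2.0:
            force_cycle[j] = spec.peak_force_N
        elif uj < 3.0:
            force_cycle[j] = spec.peak_force_N * (3.0 - uj)
        else:
            force_cycle[j] = 0.0
    force = np.tile(force_cycle, spec.n_cycles)

    # hysteretic offset h(u): 0 on the loading ramp, linear 0->delta during
    # the high hold, delta on the unloading ramp, linear delta->0 after
    offset_shape = np.empty(spc)
    for j, uj in enumerate(u):
        if uj < 1.0:
            offset_shape[j] = 0.0
        elif uj < 2.0:
            offset_shape[j] = uj - 1.0
        elif uj < 3.0:
            offset_shape[j] = 1.0
        else:
            offset_shape[j] = 4.0 - uj
    deltas = areas / spec.peak_force_N
    disp = spec.compliance_mm_per_N * force + np.repeat(deltas, spc) * np.tile(
        offset_shape, spec.n_cycles
    )
    if spec.drift_mm:
        disp = disp + spec.drift_mm * (time / time[-1] if time[-1] > 0 else 0.0)
    if spec.noise_sigma > 0:
        disp = disp + rng.normal(0.0, spec.noise_sigma, size=disp.shape)

    series = LoadSeries(time, force, disp, sample_rate_hz=1.0 / dt)
    truth = [
        CycleEnergy(
            cycle_index=i + 1,
            energy_Nmm=float(areas[i]),
            start_s=float(time[i * spc]),
            end_s=float(time[(i + 1) * spc - 1]),
        )
        for i in range(spec.n_cycles)
    ]
    return series, truth


def random_scene(
    seed: int,
    shape: tuple[int, int] = (160, 160),
    n_particles: tuple[int, int] = (1, 5),
    major_um: tuple[float, float] = (14.0, 44.0),
    aspect: tuple[float, float] = (1.0, 3.0),
    scale_um_per_px: float = 1.0,
    noise_sigma: float = 0.02,
    blob_fraction: float = 0.5,
) -> SceneSpec:
    """Draw a valid random scene: seeded particle count, sizes and poses.

    Particles are placed by rejection sampling with a one-pixel clearance
    so they never overlap or touch; the scene is reproducible from the
    seed alone.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    n = int(rng.integers(n_particles[0], n_particles[1] + 1))
    particles: list[ParticleSpec] = []
    placed_boxes: list[tuple[float, float, float]] = []   # (row, col, radius_px)
    attempts = 0
    while len(particles) < n and attempts < 2000:
        attempts += 1
        maj = float(rng.uniform(*major_um))
        minr = maj / float(rng.uniform(*aspect))
        minr = max(minr, 6.0 * scale_um_per_px)           # keep regions above noise floor
        if minr > maj:
            minr = maj
        rad_px = maj / 2.0 / scale_um_per_px * 1.25 + 2   # blob modulation margin
        r0 = rng.uniform(rad_px + 2, h - rad_px - 2)
        c0 = rng.uniform(rad_px + 2, w - rad_px - 2)
        if r0 <= rad_px + 1 or c0 <= rad_px + 1:
            continue
        if any(np.hypot(r0 - r, c0 - c) < rad_px + rr + 3 for r, c, rr in placed_boxes):
            continue
        shape_kind = "blob" if rng.uniform() < blob_fraction else "ellipse"
        particles.append(
            ParticleSpec(
                shape=shape_kind,
                center_um=(r0 * scale_um_per_px, c0 * scale_um_per_px),
                major_um=maj,
                minor_um=minr,
                orientation_rad=float(rng.uniform(0, np.pi)),
                color=(0.35, 0.30, 0.28),
            )
        )
        placed_boxes.append((r0, c0, rad_px))
    if len(particles) < n:
        particles = particles[: len(particles)]
    return SceneSpec(
        shape=shape,
        scale_um_per_px=scale_um_per_px,
        noise_sigma=noise_sigma,
        particles=tuple(particles),
        seed=seed,
    )
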