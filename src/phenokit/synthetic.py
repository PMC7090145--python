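"""Seeded synthetic data standing in for the study's raw measurements.

The source study deposited no raw data, so every input of the pipeline is
generated here with known ground truth:

* toy top-view leaf scenes (green ellipse blobs + a 1 cm² black reference
  square) with exact ground-truth pixel counts,
* leaf-area growth trajectories from the piecewise exponential model,
* diel gas-exchange traces — control plants run a C₃ template (daytime
  half-sine between ``day_floor`` and ``day_peak``, constant negative
  nocturnal exchange), salt-treated plants ramp their nightly mean toward
  zero and beyond over a parameterised transition window while daytime
  assimilation collapses, with dawn/dusk anticipation transients injected
  once the plant is CAM,
* stomatal aperture tables with a parameterised day/night inversion day,
* daily physiology tables (weights, areas, absorbances) backed out of target
  succulence / RWC / MDA trajectories.

All generators are driven by ``numpy.random.default_rng`` on an explicit
seed: same seed, same bytes.  Each output carries its latent truth (true
areas, transition day, inversion day, target trajectories) in a sidecar
``truth`` record so downstream estimators can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diel import DielTrace
from .growth import GrowthModel, evaluate

__all__ = [
    "SimConfig",
    "DielSimParams",
    "StomataSimParams",
    "RenderedScene",
    "render_leaf_scene",
    "simulate_growth",
    "simulate_diel_trace",
    "simulate_stomata",
    "simulate_physio",
    "SceneSizingError",
]


@dataclass
class SimConfig:
    """Shared simulation settings.

    ``samples_per_day`` defaults to 2880 (one gas-exchange log every 30 s)
    and the photoperiod to 12 h light / 12 h dark, matching the growth-
    chamber schedule of the study.
    """

    seed: int = 0
    n_days: int = 14
    samples_per_day: int = 2880
    light_hours: float = 12.0
    dark_hours: float = 12.0
    group: str = "control"

    def __post_init__(self) -> None:
        if self.light_hours + self.dark_hours != 24.0:
            raise ValueError("photoperiod must sum to 24 h")
        if self.group not in ("control", "salt"):
            raise ValueError(f"group must be 'control' or 'salt', got {self.group!r}")
        if self.n_days < 1 or self.samples_per_day < 2:
            raise ValueError("need n_days >= 1 and samples_per_day >= 2")


@dataclass
class DielSimParams:
    """Shape parameters of the simulated diel assimilation trace.

    All rates in μmol m⁻² s⁻¹.  Control daytime rides a half-sine between
    ``day_floor`` and ``day_peak``; nights sit at ``night_level``.  For the
    salt group the nightly mean ramps linearly from ``night_level`` (at
    ``onset_ramp_start_day`` − 1) to −0.05 at ``night_zero_day`` and +0.3
    thereafter, daytime amplitude decays toward ~0 over the same window, and
    from ``inversion_spikes_from_day`` dawn/dusk transients of
    ``spike_amplitude`` are injected.
    """

    day_peak: float = 10.5
    day_floor: float = 6.5
    night_level: float = -1.0
    noise_sd: float = 0.3
    onset_ramp_start_day: int = 6
    night_zero_day: int = 8
    inversion_spikes_from_day: int = 9
    spike_amplitude: float = 2.5
    night_target_at_zero_day: float = -0.05
    night_level_after: float = 0.3
    residual_day_scale: float = 0.05

    def __post_init__(self) -> None:
        if not self.day_floor < self.day_peak:
            raise ValueError("need day_floor < day_peak")
        if not self.onset_ramp_start_day < self.night_zero_day:
            raise ValueError("need onset_ramp_start_day < night_zero_day")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class StomataSimParams:
    """Aperture sampling parameters.

    Open/closed apertures are drawn uniformly within the observed ranges
    (1.7–3.0 μm open, 0.7–1.1 μm closed).  At an open-phase timepoint a
    stoma is open with probability ``open_fraction_when_open_phase``; at the
    opposite timepoint with the complementary probability.
    """

    open_range: tuple[float, float] = (1.7, 3.0)
    closed_range: tuple[float, float] = (0.7, 1.1)
    n_stomata_per_timepoint: int = 150
    inversion_day: int = 7
    open_fraction_when_open_phase: float = 0.8

    def __post_init__(self) -> None:
        o, c = self.open_range, self.closed_range
        if not (0 < c[0] < c[1] and 0 < o[0] < o[1]):
            raise ValueError("aperture ranges must be positive and ordered")
        if not 0.0 <= self.open_fraction_when_open_phase <= 1.0:
            raise ValueError("open fraction must be in [0, 1]")


# --------------------------------------------------------------------------
# leaf-scene renderer

class SceneSizingError(ValueError):
    """Canvas too small to place the requested shapes without overlap."""


@dataclass
class RenderedScene:
    """A rendered toy scene plus its ground truth."""

    image: np.ndarray            # uint8 RGB
    green_mask: np.ndarray       # ground-truth foliage pixels
    reference_mask: np.ndarray   # ground-truth reference-square pixels
    px_per_cm: int
    truth: dict = field(default_factory=dict)

    @property
    def true_area_cm2(self) -> float:
        return self.truth["area_cm2"]


def _exact_ellipse(n_px: int, aspect: float, rng) -> np.ndarray:
    """Boolean patch: the n_px pixels closest (in ellipse metric) to a centre."""
    rx = np.sqrt(n_px / (np.pi * aspect)) + 1.0
    ry = aspect * rx
    h, w = int(np.ceil(2 * ry)) + 3, int(np.ceil(2 * rx)) + 3
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    d = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    flat = np.argsort(d, axis=None, kind="stable")[:n_px]
    patch = np.zeros(h * w, dtype=bool)
    patch[flat] = True
    return patch.reshape(h, w)


def render_leaf_scene(
    areas_cm2,
    px_per_cm: int = 50,
    seed: int = 0,
    canvas_shape: tuple[int, int] | None = None,
    max_tries: int = 400,
) -> RenderedScene:
    """Render green leaf blobs plus a 1 cm² black reference square.

    Total ground-truth green pixel count is exactly
    ``round(sum(areas_cm2) * px_per_cm**2)``; the square is exactly
    ``px_per_cm ** 2`` black pixels.  Shapes never overlap; the background is
    white with per-pixel channel jitter kept small enough that the default
    segmentation rule classifies every pixel correctly by construction.
    """
    areas = [float(a) for a in areas_cm2]
    if any(a < 0 for a in areas):
        raise ValueError("areas must be >= 0")
    if px_per_cm < 10:
        raise ValueError("px_per_cm must be >= 10")
    rng = np.random.default_rng(seed)
    ppcm2 = px_per_cm * px_per_cm

    total_target = int(round(sum(areas) * ppcm2))
    counts = [int(round(a * ppcm2)) for a in areas]
    if counts:
        counts[-1] += total_target - sum(counts)
        counts = [c for c in counts if c > 0]

    shape_px = sum(counts) + ppcm2
    if canvas_shape is None:
        side = int(np.ceil(np.sqrt(6.0 * shape_px))) + 4 * px_per_cm
        canvas_shape = (side, side)
    H, W = canvas_shape

    green_mask = np.zeros((H, W), dtype=bool)
    ref_mask = np.zeros((H, W), dtype=bool)
    occupied = np.zeros((H, W), dtype=bool)

    def place(patch: np.ndarray, target: np.ndarray) -> None:
        ph, pw = patch.shape
        if ph + 4 > H or pw + 4 > W:
            raise SceneSizingError(
                f"canvas {canvas_shape} too small for a {patch.shape} shape"
            )
        for _ in range(max_tries):
            y = int(rng.integers(2, H - ph - 1))
            x = int(rng.integers(2, W - pw - 1))
            window = occupied[y - 2:y + ph + 2, x - 2:x + pw + 2]
            if not window.any():
                target[y:y + ph, x:x + pw] |= patch
                occupied[y:y + ph, x:x + pw] = True
                return
        raise SceneSizingError(
            f"could not place a {patch.shape} shape after {max_tries} tries; "
            f"canvas {canvas_shape} too crowded"
        )

    place(np.ones((px_per_cm, px_per_cm), dtype=bool), ref_mask)
    for n_px in counts:
        aspect = float(rng.uniform(0.55, 0.95))
        place(_exact_ellipse(n_px, aspect, rng), green_mask)

    image = np.full((H, W, 3), 255, dtype=np.uint8)
    ng, nb = int(green_mask.sum()), int(ref_mask.sum())
    # green: (0,180,0) with channel jitter <= 20; black: <= 10 per channel
    image[green_mask, 0] = rng.integers(0, 21, ng)
    image[green_mask, 1] = rng.integers(160, 201, ng)
    image[green_mask, 2] = rng.integers(0, 21, ng)
    image[ref_mask] = rng.integers(0, 11, (nb, 3)).astype(np.uint8)

    truth = {
        "areas_cm2": areas,
        "area_cm2": total_target / ppcm2,
        "green_px": int(green_mask.sum()),
        "ref_px": int(ref_mask.sum()),
        "px_per_cm": px_per_cm,
    }
    assert truth["green_px"] == total_target and truth["ref_px"] == ppcm2
    return RenderedScene(image=image, green_mask=green_mask,
                         reference_mask=ref_mask, px_per_cm=px_per_cm,
                         truth=truth)


# --------------------------------------------------------------------------
# growth trajectories

def simulate_growth(model: GrowthModel, day_range: tuple[int, int],
                    noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Daily (day, area) table from a growth model plus Gaussian noise.

    With ``noise_sd = 0`` the model values are reproduced exactly.  Noisy
    draws are floored at zero (areas are physical); the model itself raising
    on negative predicted area surfaces as a domain error naming the day.
    """
    d0, d1 = day_range
    days = np.arange(d0, d1 + 1, dtype=float)
    areas = np.atleast_1d(evaluate(model, days)).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        areas = np.maximum(0.0, areas + rng.normal(0.0, noise_sd, areas.shape))
    df = pd.DataFrame({"day": days, "area_cm2": areas})
    df.attrs["truth"] = {"model": asdict(model), "noise_sd": noise_sd,
                         "seed": seed}
    return df


# --------------------------------------------------------------------------
# diel gas exchange

def _edge_shape(n: int, rising: bool, plateau: int = 5) -> np.ndarray:
    """Transient weight across a window: quartic ramp plus a full-amplitude
    plateau of ``plateau`` samples at the light edge.

    The quartic concentrates the transient near the edge so it barely moves
    whole-night means, while the plateau keeps the excursion past ±2 visible
    even after the analysis side smooths the trace against sampling noise.
    """
    p = min(plateau, n // 2)
    ramp = ((np.arange(n - p) + 1.0) / (n - p)) ** 4
    w = np.concatenate([ramp, np.ones(p)])
    return w if rising else w[::-1]


def diel_template(cfg: SimConfig, params: DielSimParams) -> np.ndarray:
    """Noise-free assimilation template for the configured group."""
    n_per_day = cfg.samples_per_day
    light_n = int(round(n_per_day * cfg.light_hours / 24.0))
    dark_n = n_per_day - light_n
    spike_n = min(int(round(15 * 60 / (86400 / n_per_day))), light_n // 2, dark_n // 2)

    def night_mean_target(day: int) -> float:
        if cfg.group == "control" or day < params.onset_ramp_start_day:
            return params.night_level
        if day >= params.night_zero_day + 1:
            return params.night_level_after
        t0 = params.onset_ramp_start_day - 1
        frac = (day - t0) / (params.night_zero_day - t0)
        return params.night_level + frac * (params.night_target_at_zero_day
                                            - params.night_level)

    def day_scale(day: int) -> float:
        if cfg.group == "control" or day < params.onset_ramp_start_day:
            return 1.0
        if day >= params.night_zero_day:
            return params.residual_day_scale
        t0 = params.onset_ramp_start_day - 1
        frac = (day - t0) / (params.night_zero_day - t0)
        return 1.0 + frac * (params.residual_day_scale - 1.0)

    u = (np.arange(light_n) + 0.5) / light_n
    half_sine = params.day_floor + (params.day_peak - params.day_floor) * np.sin(np.pi * u)

    chunks = []
    for day in range(1, cfg.n_days + 1):
        day_part = day_scale(day) * half_sine
        night_part = np.full(dark_n, night_mean_target(day))
        if cfg.group == "salt" and spike_n >= 2:
            amp = params.spike_amplitude
            if day >= params.inversion_spikes_from_day:
                # dawn burst: first light samples decay from +amp
                w = _edge_shape(spike_n, rising=False)
                day_part = day_part.copy()
                day_part[:spike_n] += (amp - day_part[:spike_n]) * w
                # dusk: last light samples rise toward +amp * 0.6 (> +1)
                w = _edge_shape(spike_n, rising=True)
                day_part[-spike_n:] += (0.6 * amp - day_part[-spike_n:]) * w
                # post-dusk drop: first dark samples recover from -amp
                w = _edge_shape(spike_n, rising=False)
                night_part[:spike_n] += (-amp - night_part[:spike_n]) * w
            if day + 1 >= params.inversion_spikes_from_day:
                # pre-dawn dip ahead of the next day's burst
                w = _edge_shape(spike_n, rising=True)
                night_part[-spike_n:] += (-amp - night_part[-spike_n:]) * w
        chunks.append(np.concatenate([day_part, night_part]))
    return np.concatenate(chunks)


def simulate_diel_trace(cfg: SimConfig,
                        params: DielSimParams | None = None) -> DielTrace:
    """Simulate a logged diel net-assimilation trace for one plant group."""
    params = params or DielSimParams()
    n = cfg.n_days * cfg.samples_per_day
    dt = 86400.0 / cfg.samples_per_day
    time = np.arange(n) * dt
    template = diel_template(cfg, params)
    rng = np.random.default_rng(cfg.seed)
    values = template + (rng.normal(0.0, params.noise_sd, n)
                         if params.noise_sd > 0 else 0.0)
    truth = {
        "group": cfg.group,
        "params": asdict(params),
        "transition_night_zero_day": (params.night_zero_day
                                      if cfg.group == "salt" else None),
        "spikes_from_day": (params.inversion_spikes_from_day
                            if cfg.group == "salt" else None),
    }
    return DielTrace.from_samples(time, values, cfg.light_hours,
                                  cfg.dark_hours, truth=truth)


# --------------------------------------------------------------------------
# stomata

def simulate_stomata(cfg: SimConfig,
                     params: StomataSimParams | None = None) -> pd.DataFrame:
    """Per-stoma aperture table at the 4 pm / 4 am timepoints of every day.

    Control plants keep the C₃ pattern (open by day, closed by night); the
    salt group swaps it from ``inversion_day`` on.  150 stomata per
    timepoint from 15 images of 3 plants, as in the source sampling design.
    """
    params = params or StomataSimParams()
    if cfg.group == "salt" and not 1 <= params.inversion_day <= cfg.n_days:
        raise ValueError(
            f"inversion_day {params.inversion_day} outside 1..{cfg.n_days}"
        )
    rng = np.random.default_rng(cfg.seed)
    n = params.n_stomata_per_timepoint
    rows = []
    for day in range(1, cfg.n_days + 1):
        inverted = cfg.group == "salt" and day >= params.inversion_day
        for tp in ("4pm", "4am"):
            open_phase = (tp == "4pm") != inverted
            p_open = (params.open_fraction_when_open_phase if open_phase
                      else 1.0 - params.open_fraction_when_open_phase)
            is_open = rng.random(n) < p_open
            ap = np.where(
                is_open,
                rng.uniform(*params.open_range, n),
                rng.uniform(*params.closed_range, n),
            )
            for i in range(n):
                rows.append({
                    "day": day, "timepoint": tp,
                    "plant": f"p{i % 3 + 1}", "image": f"img{i % 15 + 1}",
                    "aperture_um": float(ap[i]),
                })
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "group": cfg.group,
        "inversion_day": params.inversion_day if cfg.group == "salt" else None,
        "params": asdict(params),
    }
    return df


# --------------------------------------------------------------------------
# physiology

#: target trajectories of the daily physiology generator (both groups)
PHYSIO_DRY_MATTER_FRACTION = 0.4
PHYSIO_N_REPLICATES = 4
PHYSIO_TISSUE_G = 0.2
_MDA_NMOLG_PER_UMOLL = 30.0  # protocol volumes: 0.004 L * (3/2) / 0.2 g * 1000


def physio_targets(day: int, group: str) -> dict:
    """Noise-free target succulence (g/cm²), RWC (%) and MDA (nmol/g)."""
    succ = 0.12 + 0.04 * min(day, 5) / 5.0
    if group == "salt" and day > 5:
        succ += 0.02 * min(day - 5, 6) / 6.0
    rwc = 62.5 + (80.0 - 62.5) * min(day, 14) / 14.0
    if group == "salt" and 4 <= day <= 11:
        rwc += 5.0
    mda = 1.15
    if group == "salt" and day >= 7:
        mda = 1.75
    return {"succulence_g_cm2": succ, "rwc_pct": rwc, "mda_nmol_g": mda}


def simulate_physio(cfg: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Daily physiology table (both groups, 4 replicates per cell).

    Fresh/turgid/dry weights, leaf areas and absorbance pairs are backed out
    of the target succulence, RWC and MDA trajectories with multiplicative
    replicate noise, so computing the indices from this table reproduces the
    targets up to that noise.  ``cfg.group`` is ignored: the table always
    holds both groups, since every downstream comparison needs both.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for day in range(0, cfg.n_days + 1):
        for group in ("control", "salt"):
            t = physio_targets(day, group)
            for rep in range(1, PHYSIO_N_REPLICATES + 1):
                area = 8.0 * (1.0 + 0.08 * day) * (1.0 + rng.normal(0, 0.03))
                succ = t["succulence_g_cm2"] * (1.0 + rng.normal(0, 0.04))
                rwc_t = t["rwc_pct"] * (1.0 + rng.normal(0, 0.015))
                rwc_t = min(rwc_t, 98.0)
                mda_t = t["mda_nmol_g"] * (1.0 + rng.normal(0, 0.08))
                fw = succ * area
                dw = PHYSIO_DRY_MATTER_FRACTION * fw
                tw = fw + 100.0 * (fw - dw) / rwc_t  # printed-formula inversion
                od450 = max(0.0, 0.04 * (1.0 + rng.normal(0, 0.1)))
                conc = mda_t / _MDA_NMOLG_PER_UMOLL
                od532 = (conc + 0.56 * od450) / 6.45
                rows.append({
                    "day": day, "group": group, "plant": f"r{rep}",
                    "fw_g": fw, "tw_g": tw, "dw_g": dw, "area_cm2": area,
                    "od532": od532, "od450": od450,
                    "tissue_g": PHYSIO_TISSUE_G,
                })
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "targets": {g: {d: physio_targets(d, g) for d in range(cfg.n_days + 1)}
                    for g in ("control", "salt")},
        "dry_matter_fraction": PHYSIO_DRY_MATTER_FRACTION,
        "n_replicates": PHYSIO_N_REPLICATES,
    }
    return df
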