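"""Synthetic screening experiments with the colour-trajectory structure the
analysis layer assumes.

The generator produces, for a set of variety profiles:

* daily per-patch channel means under three arms (control, brown
  planthopper ``bph``, whitebacked planthopper ``wbph``), driven by a
  latent logistic damage-severity curve whose rate scales with
  ``1 - resistance``;
* a shared control arm per replicate (both infestation tests finish
  together and share their non-infested reference);
* final-day damage records (0-9 score, dead counts, dry weights);
* optional rendered patch images with exact ground-truth masks.

Trajectory parameters are calibrated only to reproduce qualitative
orderings (rising red and blue under infestation, a mid-test greening of
controls, a stronger red gain under bph than wbph, larger between-replicate
variance under wbph); they are not estimates of any real experiment.

All randomness flows from one root seed through named substreams
(``trajectory`` / ``damage`` / ``render`` / ``design``) so each stage is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .colorspace import ChannelMeans
from .errors import ConfigurationError, DomainError
from .imaging import ForegroundMask, PatchImage

__all__ = [
    "TREATMENTS",
    "VarietyProfile",
    "SimulationConfig",
    "RenderConfig",
    "DamageRecord",
    "PatchObservation",
    "ScreeningExperiment",
    "severity_curve",
    "simulate_trajectory",
    "severity_to_score",
    "simulate_experiment",
    "render_patch_image",
    "make_profiles",
    "default_seed_palette",
]

TREATMENTS = ("control", "bph", "wbph")
INFESTED = ("bph", "wbph")


@dataclass(frozen=True)
class VarietyProfile:
    """Colour baseline and graded resistance of one test variety.

    Resistance 1 means fully resistant (no damage accrues); 0 means fully
    susceptible. ``aging_drift`` is the per-day additive drift of
    (R, G, B) in healthy plants; ``green_rise`` is the amplitude of the
    mid-test greening bump applied to the green channel.
    """

    name: str
    resistance_bph: float
    resistance_wbph: float
    baseline: ChannelMeans = ChannelMeans(60.0, 115.0, 45.0)
    aging_drift: tuple[float, float, float] = (0.8, -0.2, 0.4)
    green_rise: float = 8.0

    def __post_init__(self) -> None:
        for attr in ("resistance_bph", "resistance_wbph"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr}={v} outside [0, 1]")

    def resistance(self, treatment: str) -> float:
        if treatment == "bph":
            return self.resistance_bph
        if treatment == "wbph":
            return self.resistance_wbph
        return 1.0  # control: no herbivore pressure


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the screening simulation; defaults emulate the study design
    (3 replicates, 25 thinned seedlings per patch, 8 nymphs per seedling,
    6-10 day tests ended by the death of the susceptible check)."""

    n_replicates: int = 3
    seedlings_per_patch: int = 25
    infestation_density: int = 8  # nymphs per seedling; metadata only
    check_variety: str = "TN1"
    # the check is sown to several squares per tray (corners + centre);
    # its sub-replicates anchor the many-to-one comparisons
    check_patches_per_tray: int = 7
    # severity model: s = logistic in effective exposure x = pressure*(1-rho)*t
    logistic_slope: float = 1.2
    logistic_midpoint: float = 4.0
    exposure_death: float = 8.0  # exposure at which severity is defined as 1
    pressure_bph: float = 1.0
    pressure_wbph: float = 0.8
    # per-replicate multiplier on pressure, drawn uniformly; varies durations
    replicate_pressure_jitter: tuple[float, float] = (1.0, 1.35)
    duration_bounds: tuple[int, int] = (6, 10)
    # colour forcing: additive (R, G, B) shift at severity 1
    shift_bph: tuple[float, float, float] = (90.0, -30.0, 70.0)
    shift_wbph: tuple[float, float, float] = (55.0, -10.0, 55.0)
    noise_sd: float = 2.0
    wbph_noise_multiplier: float = 2.0
    # damage records
    healthy_weight_mg: float = 400.0
    weight_noise_sd: float = 15.0
    weight_loss_kappa: float = 0.6
    dead_threshold: float = 0.3
    dropout_prob: float = 0.0  # per (variety, replicate) germination failure
    # capture-condition nuisance offsets, e.g. {"flash_off": (4, 4, 9)}
    nuisance_offsets: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    nuisance_condition: str | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.weight_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        lo, hi = self.duration_bounds
        if not (1 <= lo <= hi):
            raise ValueError(f"bad duration bounds {self.duration_bounds}")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")

    def pressure(self, treatment: str) -> float:
        return {"control": 0.0, "bph": self.pressure_bph, "wbph": self.pressure_wbph}[treatment]

    def shift(self, treatment: str) -> tuple[float, float, float]:
        return {
            "control": (0.0, 0.0, 0.0),
            "bph": self.shift_bph,
            "wbph": self.shift_wbph,
        }[treatment]


@dataclass(frozen=True)
class DamageRecord:
    """Final-day evaluation of one patch."""

    ses_score: int
    dead_count: int
    dry_weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.ses_score <= 9:
            raise ValueError(f"ses_score={self.ses_score} outside [0, 9]")
        if self.dead_count < 0 or self.dry_weight < 0:
            raise ValueError("dead_count and dry_weight must be >= 0")


@dataclass(frozen=True)
class PatchObservation:
    """One (variety, treatment, replicate, day) record."""

    variety: str
    treatment: str
    replicate: int
    day: int
    proportional_time: float
    channel_means: ChannelMeans
    damage: DamageRecord | None = None
    patch_id: str = ""


@dataclass
class ScreeningExperiment:
    """A full plate-mapped collection of patch observations."""

    config: SimulationConfig
    observations: list[PatchObservation]
    plate_map: pd.DataFrame
    durations: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.observations:
            rows.append(
                {
                    "patchId": o.patch_id,
                    "variety": o.variety,
                    "treatment": o.treatment,
                    "replicate": o.replicate,
                    "day": o.day,
                    "proportionalTime": o.proportional_time,
                    "meanR": o.channel_means.mean_r,
                    "meanG": o.channel_means.mean_g,
                    "meanB": o.channel_means.mean_b,
                    "nPixels": o.channel_means.n_pixels,
                    "sesScore": o.damage.ses_score if o.damage else pd.NA,
                    "deadCount": o.damage.dead_count if o.damage else pd.NA,
                    "dryWeight": o.damage.dry_weight if o.damage else pd.NA,
                }
            )
        return pd.DataFrame(rows)


def _logistic(x: float, slope: float, midpoint: float) -> float:
    return 1.0 / (1.0 + math.exp(-slope * (x - midpoint)))


def severity_curve(
    t: float, resistance: float, pressure: float, cfg: SimulationConfig
) -> float:
    """Latent damage severity in [0, 1] at time ``t`` days.

    A logistic in effective exposure ``x = pressure * (1 - resistance) * t``,
    rescaled so that severity is exactly 0 at x = 0 and exactly 1 at
    ``cfg.exposure_death`` (clipped above). Non-decreasing in t; the rate
    is 0 for controls (pressure 0).
    """
    x = pressure * (1.0 - resistance) * t
    g0 = _logistic(0.0, cfg.logistic_slope, cfg.logistic_midpoint)
    g1 = _logistic(cfg.exposure_death, cfg.logistic_slope, cfg.logistic_midpoint)
    s = (_logistic(x, cfg.logistic_slope, cfg.logistic_midpoint) - g0) / (g1 - g0)
    return min(max(s, 0.0), 1.0)


def _mean_channels(
    v: VarietyProfile, treatment: str, cfg: SimulationConfig, t: float, duration: int, pressure_mult: float
) -> tuple[float, float, float, float]:
    """Noise-free expected (R, G, B, severity) at day ``t``."""
    s = severity_curve(t, v.resistance(treatment), cfg.pressure(treatment) * pressure_mult, cfg)
    tau = t / duration
    bump = v.green_rise * math.exp(-((tau - 0.5) ** 2) / (2.0 * 0.18**2))
    shift = cfg.shift(treatment)
    off = (0.0, 0.0, 0.0)
    if cfg.nuisance_condition is not None:
        off = cfg.nuisance_offsets.get(cfg.nuisance_condition, (0.0, 0.0, 0.0))
    r = v.baseline.mean_r + v.aging_drift[0] * t + s * shift[0] + off[0]
    g = v.baseline.mean_g + v.aging_drift[1] * t + bump + s * shift[1] + off[1]
    b = v.baseline.mean_b + v.aging_drift[2] * t + s * shift[2] + off[2]
    clamp = lambda x: min(max(x, 0.0), 255.0)
    return clamp(r), clamp(g), clamp(b), s


def simulate_trajectory(
    v: VarietyProfile,
    treatment: str,
    cfg: SimulationConfig,
    seed: int,
    duration: int = 10,
    replicate: int = 0,
    pressure_mult: float = 1.0,
    patch: int = 0,
) -> list[ChannelMeans]:
    """Daily channel means for days 1..duration; deterministic given seed."""
    if treatment not in TREATMENTS:
        raise ConfigurationError(f"unknown treatment {treatment!r}")
    rng = substream(seed, "trajectory", v.name, treatment, replicate, patch)
    sd = cfg.noise_sd * (cfg.wbph_noise_multiplier if treatment == "wbph" else 1.0)
    out = []
    for day in range(1, duration + 1):
        r, g, b, _ = _mean_channels(v, treatment, cfg, day, duration, pressure_mult)
        noise = rng.normal(0.0, sd, size=3) if sd > 0 else np.zeros(3)
        out.append(
            ChannelMeans(
                float(np.clip(r + noise[0], 0, 255)),
                float(np.clip(g + noise[1], 0, 255)),
                float(np.clip(b + noise[2], 0, 255)),
                n_pixels=1,
            )
        )
    return out


def severity_to_score(s: float) -> int:
    """Map severity in [0, 1] to the 0-9 damage score, half rounded up."""
    if not 0.0 <= s <= 1.0:
        raise DomainError(f"severity {s} outside [0, 1]")
    return int(math.floor(9.0 * s + 0.5))


def _proportional_time(day: int, duration: int) -> float:
    # nearest 0.1, half up (same rule as scoring.standardize_time; duplicated
    # here to keep the generator importable without the scoring layer)
    return math.floor(10.0 * day / duration + 0.5 + 1e-9) / 10.0


def _death_day(resistance: float, pressure: float, cfg: SimulationConfig) -> float:
    """First (real) day at which severity reaches 1, or inf."""
    rate = pressure * (1.0 - resistance)
    if rate <= 0.0:
        return math.inf
    return cfg.exposure_death / rate


def simulate_experiment(
    cfg: SimulationConfig, profiles: list[VarietyProfile], seed: int
) -> ScreeningExperiment:
    """Run the full screen: trajectories, plate map and final-day damage.

    The test duration of each replicate is the first day the susceptible
    check reaches severity 1 under the slower infestation (both planthopper
    tests end together and share one control arm), bounded to the
    configured range.
    """
    names = [p.name for p in profiles]
    if not profiles:
        raise ConfigurationError("no variety profiles supplied")
    if cfg.check_variety not in names:
        raise ConfigurationError(f"check variety {cfg.check_variety!r} missing from profiles")
    check = profiles[names.index(cfg.check_variety)]

    rng_design = substream(seed, "design")
    rng_damage = substream(seed, "damage")
    lo, hi = cfg.duration_bounds
    observations: list[PatchObservation] = []
    plate_rows: list[dict] = []
    durations: dict[int, int] = {}

    for rep in range(1, cfg.n_replicates + 1):
        mult = float(rng_design.uniform(*cfg.replicate_pressure_jitter))
        day_death = max(
            _death_day(check.resistance(tr), cfg.pressure(tr) * mult, cfg) for tr in INFESTED
        )
        duration = int(min(max(math.ceil(day_death), lo), hi))
        durations[rep] = duration

        # tray layout: one 45-square tray per (replicate, treatment); the
        # check is sown to cfg.check_patches_per_tray squares (corners +
        # centre convention), test varieties to one square each, shuffled.
        for treatment in TREATMENTS:
            sowing = [(cfg.check_variety, k) for k in range(cfg.check_patches_per_tray)]
            others = [n for n in names if n != cfg.check_variety]
            rng_design.shuffle(others)
            sowing += [(n, 0) for n in others]
            for square, (vname, sub) in enumerate(sowing):
                v = profiles[names.index(vname)]
                if (
                    cfg.dropout_prob > 0.0
                    and vname != cfg.check_variety
                    and rng_design.uniform() < cfg.dropout_prob
                ):
                    continue
                suffix = f".s{sub + 1}" if vname == cfg.check_variety and cfg.check_patches_per_tray > 1 else ""
                patch_id = f"r{rep}-{treatment}-{vname}{suffix}".replace(" ", "_")
                plate_rows.append(
                    {
                        "patchId": patch_id,
                        "variety": vname,
                        "tray": f"r{rep}-{treatment}",
                        "row": square // 9,
                        "col": square % 9,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )
                series = simulate_trajectory(
                    v, treatment, cfg, seed, duration=duration, replicate=rep,
                    pressure_mult=mult, patch=sub,
                )
                s_final = severity_curve(
                    duration, v.resistance(treatment), cfg.pressure(treatment) * mult, cfg
                )
                weight = cfg.healthy_weight_mg * (1.0 - cfg.weight_loss_kappa * s_final)
                if cfg.weight_noise_sd > 0:
                    weight += float(rng_damage.normal(0.0, cfg.weight_noise_sd))
                weight = max(weight, 0.0)
                p_dead = (
                    max(0.0, (s_final - cfg.dead_threshold) / (1.0 - cfg.dead_threshold))
                    if cfg.dead_threshold < 1.0
                    else float(s_final >= 1.0)
                )
                dead = int(rng_damage.binomial(cfg.seedlings_per_patch, min(p_dead, 1.0)))
                damage = DamageRecord(severity_to_score(s_final), dead, float(weight))
                for day, cm in enumerate(series, start=1):
                    observations.append(
                        PatchObservation(
                            variety=vname,
                            treatment=treatment,
                            replicate=rep,
                            day=day,
                            proportional_time=_proportional_time(day, duration),
                            channel_means=cm,
                            damage=damage if day == duration else None,
                            patch_id=patch_id,
                        )
                    )

    return ScreeningExperiment(
        config=cfg,
        observations=observations,
        plate_map=pd.DataFrame(plate_rows),
        durations=durations,
    )


def make_profiles(
    n_varieties: int = 39,
    seed: int = 0,
    check_name: str = "TN1",
    rho_max: float = 0.95,
) -> list[VarietyProfile]:
    """A graded panel: the susceptible check (resistance 0 to both
    planthoppers) plus varieties whose resistances sit on a grid in
    [0, rho_max], shuffled independently for the two herbivores."""
    if n_varieties < 2:
        raise ConfigurationError("need at least the check and one test variety")
    rng = substream(seed, "profiles")
    n = n_varieties - 1
    grid_b = np.linspace(0.0, rho_max, n)
    grid_w = np.array(grid_b)
    rng.shuffle(grid_w)
    profiles = [VarietyProfile(check_name, 0.0, 0.0)]
    for i in range(n):
        base = ChannelMeans(
            60.0 + float(rng.uniform(-6, 6)),
            115.0 + float(rng.uniform(-8, 8)),
            45.0 + float(rng.uniform(-5, 5)),
        )
        profiles.append(
            VarietyProfile(
                name=f"V{i + 1:02d}",
                resistance_bph=float(grid_b[i]),
                resistance_wbph=float(grid_w[i]),
                baseline=base,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# patch rendering


@dataclass(frozen=True)
class RenderConfig:
    """Geometry of a rendered synthetic patch photograph."""

    height: int = 256
    width: int = 256
    background: str = "blue"  # frame colours: 'blue' or 'black'
    coverage: float = 0.35
    jitter_sd: float = 3.0
    stroke_width: int = 2
    background_jitter_sd: float = 2.0

    BG_COLOURS = {"blue": (0, 0, 160), "black": (12, 12, 12)}

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ConfigurationError("image size must be at least 32 x 32")
        if not 0.0 < self.coverage < 1.0:
            raise ConfigurationError(f"coverage {self.coverage} outside (0, 1)")
        if self.background not in self.BG_COLOURS:
            raise ConfigurationError(f"unknown background {self.background!r}")


def render_patch_image(
    target: ChannelMeans,
    geometry: RenderConfig | None = None,
    seed: int = 0,
    patch_id: str = "render",
) -> tuple[PatchImage, ForegroundMask]:
    """Draw seedling-like strokes around ``target`` on a frame-coloured
    background and return the image with its exact ground-truth mask.

    Target channels are quantized to 8 bits, so with ``jitter_sd = 0`` the
    mean of the masked pixels equals the (rounded) target exactly.
    """
    geo = geometry or RenderConfig()
    rng = substream(seed, "render", patch_id)
    h, w = geo.height, geo.width
    mask = np.zeros((h, w), dtype=bool)
    rows = np.arange(h)
    # slanted vertical strokes until the requested coverage is reached
    while mask.mean() < geo.coverage:
        x0 = rng.uniform(0, w)
        slope = rng.uniform(-0.25, 0.25)
        cols = np.clip(np.round(x0 + slope * rows).astype(int), 0, w - 1)
        for off in range(geo.stroke_width):
            cc = np.clip(cols + off, 0, w - 1)
            mask[rows, cc] = True

    bg = np.array(geo.BG_COLOURS[geo.background], dtype=np.float64)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = bg
    if geo.background_jitter_sd > 0:
        img += rng.normal(0.0, geo.background_jitter_sd, size=img.shape)
    tgt = np.array([target.mean_r, target.mean_g, target.mean_b], dtype=np.float64)
    nfg = int(mask.sum())
    fg = np.tile(tgt, (nfg, 1))
    if geo.jitter_sd > 0:
        fg += rng.normal(0.0, geo.jitter_sd, size=fg.shape)
    img[mask] = fg
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return PatchImage(pixels, patch_id, metadata={"background": geo.background}), ForegroundMask(mask)


def default_seed_palette(
    cfg: SimulationConfig | None = None, profile: VarietyProfile | None = None
) -> np.ndarray:
    """Reference colours for segmentation covering healthy through dead
    foliage: the generator's own noise-free colour model sampled over
    severity, treatment and test time (includes senescent tones so dead
    seedlings stay foreground)."""
    cfg = cfg or SimulationConfig()
    v = profile or VarietyProfile("palette", 0.0, 0.0)
    colours = []
    for treatment in TREATMENTS:
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            for t in (1.0, 5.0, 10.0):
                shift = cfg.shift(treatment)
                r = v.baseline.mean_r + v.aging_drift[0] * t + s * shift[0]
                g = v.baseline.mean_g + v.aging_drift[1] * t + s * shift[1]
                b = v.baseline.mean_b + v.aging_drift[2] * t + s * shift[2]
                colours.append((min(max(r, 0), 255), min(max(g, 0), 255), min(max(b, 0), 255)))
    uniq = sorted({(round(c[0] / 8) * 8, round(c[1] / 8) * 8, round(c[2] / 8) * 8) for c in colours})
    return np.array(uniq, dtype=np.float64)
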