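"""Forward simulation of screen-illuminated video acquisitions.

The measurement being emulated: a phone screen sweeps a colour gradient
from purple to red while the front camera records the pressed-powder
sample it illuminates. The sample's surface reflectance shapes how each
screen colour comes back to the camera, so the per-frame ROI channel
means form a sample-specific "spectrum".

Forward model, per frame f and channel c:

    pixel = clamp(round(screen[f, c] * reflectance_c(f) + eps), 0, 255)

with eps i.i.d. Gaussian pixel noise. Reflectance is a smooth function of
frame index (constant offset plus Gaussian bumps), so classes can separate
in mid-gradient variables, and adulteration acts by affine mixing of the
base and adulterant reflectance curves. Within-class variability is a
seeded multiplicative jitter on the curve coefficients.

The study design covers five tasks on whey protein concentrate (WPC):
brand identification over 15 brands (task 1), fat and energy
quantification (tasks 2-3), adulterant-type detection (task 4) and
milk-powder adulteration-level quantification (task 5), with the
certified per-brand fat (g/100 g) and energy (kJ/100 g) values embedded
as ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import FrameSequence, write_frame_dir, DEFAULT_FRAME_COUNT, DEFAULT_ROI_SIZE
from .spectra import SpectraDataset, frames_to_spectrum

__all__ = [
    "ScreenSequence",
    "ChannelCurve",
    "ReflectanceProfile",
    "StudyDesign",
    "NoiseModel",
    "ConfigurationError",
    "make_screen_gradient",
    "mix_profiles",
    "render_frames",
    "generate_design",
    "simulate_dataset",
    "simulate_task_spectra",
    "default_brand_profiles",
    "default_adulterant_profiles",
    "write_dataset",
    "BRANDS",
    "ADULTERANTS",
    "BRAND_FAT",
    "BRAND_ENERGY",
    "DEFAULT_LEVELS",
]

# Certified composition of the 15 WPC brands (fat g/100 g, energy kJ/100 g).
BRANDS = tuple(f"B{i}" for i in range(1, 16))
BRAND_FAT = dict(zip(BRANDS, (3.3, 3.1, 4.3, 7.3, 3.2, 3.1, 5.6, 7.6,
                              3.6, 10.1, 4.8, 2.6, 1.4, 4.2, 1.3)))
BRAND_ENERGY = dict(zip(BRANDS, (1657, 1633, 1655, 1717, 1654, 1607, 1654, 1713,
                                 1638, 1776, 1660, 1628, 1611, 1641, 1621)))

ADULTERANTS = ("maltodextrin", "wheat_flour", "milk_powder")
DEFAULT_LEVELS = tuple(round(0.05 * i, 2) for i in range(1, 11))  # 5% .. 50%
REPLICATES_PER_BRAND = 12
REPLICATES_PER_LEVEL = 5

TASK_LABEL_COLUMN = {1: "brand", 2: "fat", 3: "energy", 4: "adulterant", 5: "level"}
CLASSIFICATION_TASKS = (1, 4)


class ConfigurationError(ValueError):
    """The simulation request is inconsistent (e.g. a class has no profile)."""


# ---------------------------------------------------------------------------
# Screen illumination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSequence:
    """Ordered RGB screen colours, one per frame."""

    colors: np.ndarray  # (F, 3) uint8

    @property
    def frame_count(self) -> int:
        return self.colors.shape[0]


def make_screen_gradient(frame_count: int = DEFAULT_FRAME_COUNT) -> ScreenSequence:
    """Purple-to-red screen gradient: a linear hue sweep 270° -> 0° in HSV
    at full saturation and value, quantized to integer colour levels.

    A single frame degenerates to the purple endpoint.
    """
    if frame_count < 1:
        raise ValueError(f"frame count must be >= 1, got {frame_count}")
    hues = np.linspace(270.0, 0.0, frame_count) if frame_count > 1 else np.array([270.0])
    h6 = hues / 60.0
    x = 1.0 - np.abs(h6 % 2.0 - 1.0)  # secondary component of HSV->RGB at S=V=1
    rgb = np.zeros((frame_count, 3))
    sector = np.floor(h6).astype(int) % 6
    primary = np.ones(frame_count)
    table = {  # sector -> (r, g, b) in terms of (primary, x, 0)
        0: (primary, x, 0.0), 1: (x, primary, 0.0), 2: (0.0, primary, x),
        3: (0.0, x, primary), 4: (x, 0.0, primary), 5: (primary, 0.0, x),
    }
    for s, (r, g, b) in table.items():
        m = sector == s
        rgb[m, 0] = np.broadcast_to(r, (frame_count,))[m]
        rgb[m, 1] = np.broadcast_to(g, (frame_count,))[m]
        rgb[m, 2] = np.broadcast_to(b, (frame_count,))[m]
    return ScreenSequence(colors=np.round(rgb * 255.0).astype(np.uint8))


# ---------------------------------------------------------------------------
# Surface reflectance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelCurve:
    """Smooth reflectance curve over normalised frame position t in [0, 1]:
    offset + sum_k amp_k * exp(-(t - center_k)^2 / (2 width_k^2)).

    With offset >= 0, amplitudes >= 0 and offset + sum(amp) <= 1 the raw
    curve stays in [0, 1]; evaluation clips defensively anyway.
    """

    offset: float
    amplitudes: tuple[float, ...] = ()
    centers: tuple[float, ...] = ()
    widths: tuple[float, ...] = ()

    def evaluate(self, frame_count: int) -> np.ndarray:
        t = (np.linspace(0.0, 1.0, frame_count) if frame_count > 1
             else np.zeros(1))
        out = np.full(frame_count, self.offset)
        for a, c, w in zip(self.amplitudes, self.centers, self.widths):
            out += a * np.exp(-((t - c) ** 2) / (2.0 * w * w))
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class ReflectanceProfile:
    """Per-channel reflectance curves of one sample class."""

    red: ChannelCurve
    green: ChannelCurve
    blue: ChannelCurve

    def evaluate(self, frame_count: int) -> np.ndarray:
        """(F, 3) reflectance in [0, 1], columns R, G, B."""
        return np.stack(
            [c.evaluate(frame_count) for c in (self.red, self.green, self.blue)],
            axis=1,
        )


def _mix_curves(a: ChannelCurve, b: ChannelCurve, level: float) -> ChannelCurve:
    return ChannelCurve(
        offset=(1.0 - level) * a.offset + level * b.offset,
        amplitudes=tuple((1.0 - level) * x for x in a.amplitudes)
        + tuple(level * x for x in b.amplitudes),
        centers=a.centers + b.centers,
        widths=a.widths + b.widths,
    )


def mix_profiles(
    base: ReflectanceProfile, adulterant: ReflectanceProfile, level: float
) -> ReflectanceProfile:
    """Affine mixture: the evaluated curve of the result equals
    (1 - level) * base + level * adulterant at every frame and channel."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"mixing level must be in [0, 1], got {level}")
    if level == 0.0:
        return base
    if level == 1.0:
        return adulterant
    return ReflectanceProfile(
        red=_mix_curves(base.red, adulterant.red, level),
        green=_mix_curves(base.green, adulterant.green, level),
        blue=_mix_curves(base.blue, adulterant.blue, level),
    )


def _jitter_curve(curve: ChannelCurve, scale: float, rng: np.random.Generator) -> ChannelCurve:
    """Multiplicative coefficient jitter: each offset/amplitude scaled by
    (1 + scale * z), clipped non-negative."""
    off = max(0.0, curve.offset * (1.0 + scale * rng.standard_normal()))
    amps = tuple(
        max(0.0, a * (1.0 + scale * rng.standard_normal())) for a in curve.amplitudes
    )
    return replace(curve, offset=off, amplitudes=amps)


def jitter_profile(
    profile: ReflectanceProfile, scale: float, rng: np.random.Generator
) -> ReflectanceProfile:
    if scale == 0.0:
        return profile
    return ReflectanceProfile(
        red=_jitter_curve(profile.red, scale, rng),
        green=_jitter_curve(profile.green, scale, rng),
        blue=_jitter_curve(profile.blue, scale, rng),
    )


# ---------------------------------------------------------------------------
# Noise and rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise: i.i.d. Gaussian pixel noise (colour levels, applied
    before rounding/clamping) and per-sample reflectance coefficient jitter
    (relative scale). Defaults emulate a modest sensor read noise and a
    2% sample-to-sample surface variability."""

    pixel_sd: float = 2.0
    jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_sd < 0 or self.jitter < 0:
            raise ValueError("noise scales must be >= 0")


ZERO_NOISE = NoiseModel(pixel_sd=0.0, jitter=0.0, seed=0)


def render_frames(
    profile: ReflectanceProfile,
    screen: ScreenSequence,
    roi_size: int = DEFAULT_ROI_SIZE,
    noise: NoiseModel = ZERO_NOISE,
    rng: np.random.Generator | None = None,
    source_id: str = "synthetic",
) -> FrameSequence:
    """Render one acquisition: roi_size × roi_size pixels per frame.

    Pixel values follow the forward model
    clamp(round(screen * reflectance + eps), 0, 255). ``rng`` defaults to a
    generator seeded from ``noise.seed`` for reproducibility.
    """
    if roi_size < 1:
        raise ValueError(f"roi_size must be >= 1, got {roi_size}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    F = screen.frame_count
    base = screen.colors.astype(np.float64) * profile.evaluate(F)  # (F, 3)
    px = np.broadcast_to(base[:, None, None, :], (F, roi_size, roi_size, 3))
    if noise.pixel_sd > 0:
        px = px + rng.normal(0.0, noise.pixel_sd, size=px.shape)
    frames = np.clip(np.round(px), 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, source_id=source_id)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """One task's sample plan plus per-sample ground truth.

    ``samples`` has columns sample_id, task, brand, adulterant, level,
    fat, energy; adulterant/level are empty/0 for the brand tasks and
    fat/energy are NaN for the adulteration tasks.
    """

    task: int
    samples: pd.DataFrame
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def generate_design(task: int, seed: int = 0) -> StudyDesign:
    """Sample plan for one of the five tasks.

    Tasks 1-3: 15 brands × 12 replicates = 180 samples (brand label plus
    certified fat/energy). Task 4: 3 adulterants × 10 levels × 5
    replicates = 150, all in a B1 base. Task 5: the milk-powder series,
    10 levels × 5 replicates plus 5 pure (level 0) B1 samples = 55.
    """
    if task not in (1, 2, 3, 4, 5):
        raise ValueError(f"task must be 1..5, got {task}")
    rows = []
    if task in (1, 2, 3):
        for brand in BRANDS:
            for r in range(REPLICATES_PER_BRAND):
                rows.append(dict(
                    sample_id=f"t{task}_{brand}_r{r:02d}", task=task, brand=brand,
                    adulterant="", level=0.0,
                    fat=BRAND_FAT[brand], energy=BRAND_ENERGY[brand],
                ))
    elif task == 4:
        for adulterant in ADULTERANTS:
            for level in DEFAULT_LEVELS:
                for r in range(REPLICATES_PER_LEVEL):
                    rows.append(dict(
                        sample_id=f"t4_{adulterant}_l{int(level * 100):02d}_r{r}",
                        task=4, brand="B1", adulterant=adulterant, level=level,
                        fat=np.nan, energy=np.nan,
                    ))
    else:
        for level in (0.0,) + DEFAULT_LEVELS:
            for r in range(REPLICATES_PER_LEVEL):
                rows.append(dict(
                    sample_id=f"t5_milk_powder_l{int(level * 100):02d}_r{r}",
                    task=5, brand="B1",
                    adulterant="milk_powder" if level > 0 else "",
                    level=level, fat=np.nan, energy=np.nan,
                ))
    return StudyDesign(task=task, samples=pd.DataFrame(rows), seed=seed)


# ---------------------------------------------------------------------------
# Default class profiles
# ---------------------------------------------------------------------------

def _unit(values: dict[str, float]) -> dict[str, float]:
    lo, hi = min(values.values()), max(values.values())
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def default_brand_profiles() -> dict[str, ReflectanceProfile]:
    """One reflectance profile per brand, separated by construction.

    Each brand gets a unique Gaussian bump centre in the green channel
    (mid-gradient separability), a red-channel amplitude that scales
    linearly with certified fat content and a blue-channel amplitude that
    scales linearly with certified energy, giving the spectra a documented
    monotone link to the regression targets.
    """
    fat01 = _unit(BRAND_FAT)
    en01 = _unit(BRAND_ENERGY)
    profiles = {}
    for i, brand in enumerate(BRANDS):
        sig_center = 0.08 + 0.056 * i  # 0.08 .. 0.864, unique per brand
        profiles[brand] = ReflectanceProfile(
            red=ChannelCurve(
                offset=0.30,
                amplitudes=(0.15 + 0.40 * fat01[brand], 0.10),
                centers=(0.35, 0.80), widths=(0.16, 0.10),
            ),
            green=ChannelCurve(
                offset=0.30,
                amplitudes=(0.40, 0.10 * fat01[brand]),
                centers=(sig_center, 0.55), widths=(0.055, 0.25),
            ),
            blue=ChannelCurve(
                offset=0.25,
                amplitudes=(0.12 + 0.45 * en01[brand],),
                centers=(0.60,), widths=(0.18,),
            ),
        )
    return profiles


def default_adulterant_profiles() -> dict[str, ReflectanceProfile]:
    """Reflectance profiles of the three pure adulterants.

    Milk powder is made clearly distinct (yellowish: high red/green, low
    blue); maltodextrin and wheat flour are both near-white and
    deliberately closer to each other than to milk powder, mirroring
    their visual similarity.
    """
    return {
        "maltodextrin": ReflectanceProfile(
            red=ChannelCurve(offset=0.78, amplitudes=(0.10,), centers=(0.50,), widths=(0.30,)),
            green=ChannelCurve(offset=0.80, amplitudes=(0.08,), centers=(0.45,), widths=(0.30,)),
            blue=ChannelCurve(offset=0.78, amplitudes=(0.10,), centers=(0.40,), widths=(0.25,)),
        ),
        "wheat_flour": ReflectanceProfile(
            red=ChannelCurve(offset=0.70, amplitudes=(0.10,), centers=(0.55,), widths=(0.28,)),
            green=ChannelCurve(offset=0.70, amplitudes=(0.12,), centers=(0.35,), widths=(0.22,)),
            blue=ChannelCurve(offset=0.66, amplitudes=(0.08,), centers=(0.45,), widths=(0.25,)),
        ),
        "milk_powder": ReflectanceProfile(
            red=ChannelCurve(offset=0.82, amplitudes=(0.12,), centers=(0.30,), widths=(0.25,)),
            green=ChannelCurve(offset=0.74, amplitudes=(0.10,), centers=(0.65,), widths=(0.20,)),
            blue=ChannelCurve(offset=0.35, amplitudes=(0.15,), centers=(0.75,), widths=(0.15,)),
        ),
    }


def default_profiles() -> dict[str, ReflectanceProfile]:
    out = default_brand_profiles()
    out.update(default_adulterant_profiles())
    return out


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _sample_profile(
    row: pd.Series, class_profiles: dict[str, ReflectanceProfile]
) -> ReflectanceProfile:
    brand = row["brand"]
    if brand not in class_profiles:
        raise ConfigurationError(f"no reflectance profile for brand {brand!r}")
    profile = class_profiles[brand]
    adulterant = row["adulterant"]
    level = float(row["level"])
    if adulterant:
        if adulterant not in class_profiles:
            raise ConfigurationError(f"no reflectance profile for adulterant {adulterant!r}")
        profile = mix_profiles(profile, class_profiles[adulterant], level)
    return profile


def simulate_dataset(
    design: StudyDesign,
    class_profiles: dict[str, ReflectanceProfile] | None = None,
    noise: NoiseModel = ZERO_NOISE,
    frame_count: int = DEFAULT_FRAME_COUNT,
    roi_size: int = DEFAULT_ROI_SIZE,
):
    """Yield ``(FrameSequence, meta_row)`` per sample of the design.

    Per-sample profile = class profile (mixed with the adulterant profile
    at the sample's level where applicable) plus seeded within-class
    jitter. Each sample draws from its own child generator of
    ``noise.seed``, so the output is reproducible and independent of
    iteration order.
    """
    if class_profiles is None:
        class_profiles = default_profiles()
    screen = make_screen_gradient(frame_count)
    children = np.random.SeedSequence(noise.seed).spawn(design.n_samples)
    for i, (_, row) in enumerate(design.samples.iterrows()):
        rng = np.random.default_rng(children[i])
        profile = jitter_profile(_sample_profile(row, class_profiles), noise.jitter, rng)
        seq = render_frames(profile, screen, roi_size=roi_size, noise=noise,
                            rng=rng, source_id=row["sample_id"])
        yield seq, row


def simulate_task_spectra(
    task: int,
    seed: int = 0,
    noise: NoiseModel | None = None,
    frame_count: int = DEFAULT_FRAME_COUNT,
    roi_size: int = DEFAULT_ROI_SIZE,
    class_profiles: dict[str, ReflectanceProfile] | None = None,
) -> SpectraDataset:
    """Simulate one task end-to-end and return spectra directly.

    Frames are rendered per sample and reduced to channel-mean spectra
    immediately, so memory stays flat. ``noise`` defaults to the standard
    noise model reseeded with ``seed``.
    """
    if noise is None:
        noise = NoiseModel(seed=seed)
    else:
        noise = replace(noise, seed=seed)
    design = generate_design(task, seed=seed)
    rows, meta = [], []
    for seq, row in simulate_dataset(design, class_profiles, noise,
                                     frame_count, roi_size):
        rows.append(frames_to_spectrum(seq))
        meta.append(row)
    return SpectraDataset(X=np.vstack(rows), meta=pd.DataFrame(meta).reset_index(drop=True))


def write_dataset(
    design: StudyDesign,
    out_dir: str | os.PathLike,
    class_profiles: dict[str, ReflectanceProfile] | None = None,
    noise: NoiseModel = ZERO_NOISE,
    frame_count: int = DEFAULT_FRAME_COUNT,
    roi_size: int = DEFAULT_ROI_SIZE,
) -> pd.DataFrame:
    """Write one frame directory per sample plus a ``manifest.csv`` with
    the ground truth; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    for seq, row in simulate_dataset(design, class_profiles, noise,
                                     frame_count, roi_size):
        write_frame_dir(seq, os.path.join(out_dir, row["sample_id"]))
    manifest = design.samples.copy()
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
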