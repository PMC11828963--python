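"""Synthetic crystalline-ice micrograph generator and episodic task families.

Real training data for this problem are tilt-series micrographs in which
crystalline (non-vitrified) ice shows up as bright, high-frequency, strongly
oriented texture on top of a smooth low-frequency cellular background, with
occasional dark contamination blobs and FIB-damage bubbles that tempt the
segmenter into false positives. This module emulates exactly those features:

* background: Gaussian-smoothed random field (cellular context) + i.i.d. noise;
* crystalline patches: elliptical supports filled with oriented sinusoidal
  carriers — one carrier for cubic ice, three carriers 60° apart for hexagonal
  ice, a random mixture of orientations for stacking-disordered ice;
* artifacts: dark discs and bright-rimmed bubbles, deliberately *excluded*
  from the ground-truth mask.

A "dataset" (one :class:`SyntheticDatasetConfig`) fixes the rendering
parameters the way one microscope session fixes optics, sample content and
preparation; a meta-learning task draws its support and query micrographs from
a single dataset. Domain shift between datasets comes from drawing configs
from a prior. Everything is a pure function of (config, seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import Micrograph, SegmentationMask

__all__ = [
    "IcePhaseParams", "SyntheticDatasetConfig", "ConfigPrior",
    "sample_dataset_config", "render_micrograph", "make_task", "Task",
]

PHASES = ("hexagonal", "cubic", "stacking_disordered")


@dataclass
class IcePhaseParams:
    """Texture parameters for one crystalline ice phase within a dataset."""

    phase: str
    carrier_freq: float = 0.25      # cycles / pixel, must stay below Nyquist
    orientation_deg: float = 0.0
    contrast: float = 1.0
    patch_scale_px: float = 10.0

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown ice phase {self.phase!r}")
        if not (0.0 < self.carrier_freq < 0.5):
            raise ValueError("carrier_freq must be in (0, 0.5) cycles/pixel")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.patch_scale_px <= 0:
            raise ValueError("patch_scale_px must be positive")


@dataclass
class SyntheticDatasetConfig:
    """Latent rendering parameters shared by every micrograph of one dataset."""

    dataset_id: str
    image_size: tuple[int, int] = (64, 64)
    background_smoothness_px: float = 8.0
    noise_sd: float = 0.08
    ice_fraction_target: float = 0.06
    phases: list[IcePhaseParams] = field(default_factory=list)
    artifact_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ice_fraction_target <= 0.5):
            raise ValueError("ice_fraction_target must be in [0, 0.5]")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.background_smoothness_px <= 0 or self.noise_sd <= 0:
            raise ValueError("background_smoothness_px and noise_sd must be positive")
        if self.ice_fraction_target > 0 and not self.phases:
            raise ValueError("at least one ice phase is required when ice is present")


@dataclass
class Task:
    """Support/query bundle drawn from one dataset: the meta-learning unit."""

    support: list[tuple[Micrograph, SegmentationMask]]
    query: list[tuple[Micrograph, SegmentationMask]]
    dataset_id: str

    def __post_init__(self):
        if not self.support or not self.query:
            raise ValueError("support and query must both be non-empty")


# ---------------------------------------------------------------------------
# config priors
# ---------------------------------------------------------------------------

@dataclass
class ConfigPrior:
    """Interval bounds from which dataset configs are drawn, one per field.

    This is the task distribution p(T): datasets (tasks) are i.i.d. draws.
    Defaults mimic the regime reported for real lamellae: small foreground
    fractions (a few percent), moderate noise, texture clearly above Nyquist/4.
    """

    image_size: tuple[int, int] = (64, 64)
    background_smoothness_px: tuple[float, float] = (4.0, 12.0)
    noise_sd: tuple[float, float] = (0.05, 0.12)
    ice_fraction_target: tuple[float, float] = (0.02, 0.10)
    carrier_freq: tuple[float, float] = (0.18, 0.38)
    orientation_deg: tuple[float, float] = (0.0, 180.0)
    contrast: tuple[float, float] = (1.0, 2.0)
    patch_scale_px: tuple[float, float] = (6.0, 12.0)
    artifact_rate: tuple[float, float] = (0.0, 0.8)
    phase_choices: tuple[str, ...] = PHASES

    def __post_init__(self):
        if not self.phase_choices:
            raise ValueError("phase prior must contain at least one phase")
        for name in ("background_smoothness_px", "noise_sd", "ice_fraction_target",
                     "carrier_freq", "orientation_deg", "contrast",
                     "patch_scale_px", "artifact_rate"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"invalid interval for {name}: ({lo}, {hi})")


def sample_dataset_config(prior: ConfigPrior, seed: int) -> SyntheticDatasetConfig:
    """Draw one dataset config with every field uniform over its prior interval.

    The phase set is a uniformly chosen non-empty subset of the prior's phase
    choices; per-phase texture parameters are drawn independently.
    """
    rng = np.random.default_rng(seed)

    def u(bounds):
        lo, hi = bounds
        return float(lo) if lo == hi else float(rng.uniform(lo, hi))

    n_choices = len(prior.phase_choices)
    n_phases = int(rng.integers(1, n_choices + 1))
    picked = list(rng.choice(n_choices, size=n_phases, replace=False))
    phases = [
        IcePhaseParams(
            phase=prior.phase_choices[i],
            carrier_freq=u(prior.carrier_freq),
            orientation_deg=u(prior.orientation_deg),
            contrast=u(prior.contrast),
            patch_scale_px=u(prior.patch_scale_px),
        )
        for i in sorted(picked)
    ]
    return SyntheticDatasetConfig(
        dataset_id=f"synth-{seed}",
        image_size=tuple(prior.image_size),
        background_smoothness_px=u(prior.background_smoothness_px),
        noise_sd=u(prior.noise_sd),
        ice_fraction_target=u(prior.ice_fraction_target),
        phases=phases,
        artifact_rate=u(prior.artifact_rate),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_support(shape, center, axes, angle_rad) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _carrier_orientations(phase: IcePhaseParams, rng) -> list[float]:
    base = np.deg2rad(phase.orientation_deg)
    if phase.phase == "cubic":
        return [base]
    if phase.phase == "hexagonal":
        return [base, base + np.pi / 3, base + 2 * np.pi / 3]
    # stacking-disordered: a random mixture of >= 2 orientations
    n = int(rng.integers(2, 4))
    return [base + float(rng.uniform(0, np.pi)) for _ in range(n)]


def _texture(shape, phase: IcePhaseParams, rng) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    acc = np.zeros(shape)
    orients = _carrier_orientations(phase, rng)
    for th in orients:
        ph0 = float(rng.uniform(0, 2 * np.pi))
        acc += np.sin(2 * np.pi * phase.carrier_freq
                      * (cols * np.cos(th) + rows * np.sin(th)) + ph0)
    return acc / len(orients)


_MAX_IMAGE_RETRIES = 20
# sized so that at contrast >= 1 the local gradient energy inside ice patches
# exceeds the background's by >= 2x (keeps tasks learnable by construction)
_TEXTURE_AMPLITUDE = 0.30
_BACKGROUND_AMPLITUDE = 0.15


def render_micrograph(cfg: SyntheticDatasetConfig,
                      image_seed: int) -> tuple[Micrograph, SegmentationMask]:
    """Render one (micrograph, mask) pair; deterministic in (cfg, image_seed).

    Patches are placed by rejection until the foreground fraction lands within
    [0.5, 2.0] x ice_fraction_target (exactly zero when the target is zero);
    a bounded number of whole-image retries guards against pathological
    configs. Artifacts are placed so they overlap the positive mask by at most
    10% of their own area and are never added to the mask.
    """
    h, w = cfg.image_size
    target = cfg.ice_fraction_target
    last_frac = 0.0
    for attempt in range(_MAX_IMAGE_RETRIES):
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF,
                                     int(image_seed) & 0x7FFFFFFF, attempt])
        img = 0.5 + _BACKGROUND_AMPLITUDE * _smooth_field(
            (h, w), cfg.background_smoothness_px, rng)
        mask = np.zeros((h, w), dtype=np.uint8)
        ok = True
        if target > 0:
            lo, hi = 0.5 * target, 2.0 * target
            aim = float(rng.uniform(0.8 * target, 1.3 * target))
            for _ in range(200):
                frac = mask.mean()
                if frac >= aim:
                    break
                phase = cfg.phases[int(rng.integers(len(cfg.phases)))]
                scale = phase.patch_scale_px
                axes = (float(rng.uniform(0.6, 1.4)) * scale,
                        float(rng.uniform(0.6, 1.4)) * scale)
                center = (float(rng.uniform(0, h)), float(rng.uniform(0, w)))
                support = _ellipse_support((h, w), center, axes,
                                           float(rng.uniform(0, np.pi)))
                new_mask = mask | support.astype(np.uint8)
                if new_mask.mean() > hi:
                    continue
                tex = _texture((h, w), phase, rng)
                img = np.where(support,
                               img + _TEXTURE_AMPLITUDE * phase.contrast * tex,
                               img)
                mask = new_mask
            last_frac = mask.mean()
            ok = lo <= last_frac <= hi
        if not ok:
            continue
        img = _add_artifacts(img, mask, cfg, rng)
        img = img + cfg.noise_sd * rng.standard_normal((h, w))
        mic = Micrograph(
            image=img, pixel_size_A=None, source_id=cfg.dataset_id,
            lamella_id=f"{cfg.dataset_id}/lam{image_seed}",
            series_id=f"{cfg.dataset_id}/ts{image_seed}",
            tilt_index=int(image_seed) % 61,
        )
        return mic, SegmentationMask(mask=mask, image_ref=mic.lamella_id)
    raise RuntimeError(
        f"could not place ice patches within [0.5, 2.0] x target "
        f"{target:.3f} after {_MAX_IMAGE_RETRIES} attempts "
        f"(last achieved fraction {last_frac:.4f})")


def _smooth_field(shape, smoothness_px, rng) -> np.ndarray:
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=smoothness_px,
                             mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _add_artifacts(img, mask, cfg: SyntheticDatasetConfig, rng) -> np.ndarray:
    """Dark contamination discs and bright-rimmed bubbles, kept off the mask."""
    n_art = int(rng.poisson(2.0 * cfg.artifact_rate))
    h, w = img.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(n_art):
        for _try in range(20):
            r = float(rng.uniform(3.0, 7.0))
            cy, cx = float(rng.uniform(0, h)), float(rng.uniform(0, w))
            d2 = (rows - cy) ** 2 + (cols - cx) ** 2
            disc = d2 <= r * r
            area = disc.sum()
            if area == 0 or (disc & (mask > 0)).sum() > 0.10 * area:
                continue
            if rng.uniform() < 0.5:          # contamination: dark blob
                img = np.where(disc, img - float(rng.uniform(0.15, 0.3)), img)
            else:                            # bubble: dark core, bright rim
                rim = (d2 <= (r + 1.5) ** 2) & ~disc
                img = np.where(disc, img - float(rng.uniform(0.1, 0.2)), img)
                img = np.where(rim, img + float(rng.uniform(0.15, 0.25)), img)
            break
    return img


# ---------------------------------------------------------------------------
# tasks
# ---------------------------------------------------------------------------

K_SHOT_MIN, K_SHOT_MAX = 1, 10


def make_task(cfg: SyntheticDatasetConfig, k_support: int, n_query: int,
              seed: int) -> Task:
    """Render a support/query task from one dataset.

    Each pair gets a distinct image seed and a distinct (lamella, series,
    tilt) identity, mirroring how a real task mixes lamellae, tilt series and
    projections from one acquisition session. k_support is limited to the
    tool's 1–10 micrograph fine-tuning range.
    """
    if not (K_SHOT_MIN <= k_support <= K_SHOT_MAX):
        raise ValueError(
            f"k_support must be in [{K_SHOT_MIN}, {K_SHOT_MAX}], got {k_support}")
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    n = k_support + n_query
    base = (int(seed) & 0x7FFFFFF) * 1000
    pairs = [render_micrograph(cfg, base + i) for i in range(n)]
    return Task(support=pairs[:k_support], query=pairs[k_support:],
                dataset_id=cfg.dataset_id)
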