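"""Synthetic disc-tracing studies: true discs plus simulated raters.

The generator emulates the ingredients of a two-rater disc-tracing
study without any image downloads:

* a true disc per image — an ellipse, optionally modulated by a smooth
  low-order angular perturbation so the truth is not exactly elliptic;
* simulated raters who trace the boundary with zero-mean Gaussian
  radial jitter, occasional *misalignment* strokes (one contiguous arc
  radially displaced, mimicking a stylus calibration slip), and an
  optional condition-dependent outward sector bias that models
  confusing peripapillary atrophy (PPA) with the disc border in
  glaucomatous images.

Rater boundaries are generated in polar form about the true center, so
they are star-convex except inside misaligned arcs; that keeps the
ray-casting metrics well defined and the failure modes controllable.

Default image shapes preserve the resolution asymmetry of common
public fundus datasets: a "drishti"-like high-resolution cohort at
quarter scale (724 x 486) and an "aria"-like cohort at its native
768 x 576.  The default study composition is 69 glaucoma + 37 normal
(drishti-like) and 53 diabetic-retinopathy (aria-like) images, 159 in
total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .agreement_metrics import cast_radii
from .ellipse_fit import EllipseParams, ellipse_to_mask
from .errors import InputError
from .trace_io import CONDITIONS, ImageRecord, Polyline, TraceMask, polyline_to_mask

__all__ = [
    "ObserverModel",
    "SyntheticStudyConfig",
    "DEFAULT_PPA_BIAS",
    "default_config",
    "generate_true_disc",
    "simulate_tracing",
    "generate_study",
]

#: Default PPA-confusion bias: outward displacement in the superior and
#: inferior sectors, where disc/PPA discrimination is hardest.
DEFAULT_PPA_BIAS = (((60.0, 120.0), 6.0), ((240.0, 300.0), 6.0))


@dataclass(frozen=True)
class ObserverModel:
    """Stochastic model of one rater tracing a disc boundary.

    Parameters
    ----------
    radial_jitter_sd
        Std. dev. (px) of zero-mean Gaussian noise on the traced radius.
    misalignment_prob
        Per-image probability of one misaligned stroke arc.
    misalignment_arc
        Angular width (degrees) of the misaligned arc.
    misalignment_offset
        Signed radial displacement (px) of the arc.
    sector_bias
        ``(((lo_deg, hi_deg), offset_px), ...)`` — systematic radial
        offsets applied only when the image's condition enables them.
    smoothing_window
        Odd number of neighboring 1-degree samples averaged (circular),
        emulating the smoothness of a hand stroke.
    """

    radial_jitter_sd: float = 1.5
    misalignment_prob: float = 0.1
    misalignment_arc: float = 60.0
    misalignment_offset: float = 8.0
    sector_bias: tuple[tuple[tuple[float, float], float], ...] = ()
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if self.radial_jitter_sd < 0:
            raise InputError("radial_jitter_sd must be >= 0")
        if not 0 <= self.misalignment_prob <= 1:
            raise InputError("misalignment_prob must be in [0, 1]")
        if not 0 < self.misalignment_arc < 360:
            raise InputError("misalignment_arc must be in (0, 360)")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise InputError("smoothing_window must be odd and >= 1")


def _default_observers() -> dict[str, ObserverModel]:
    # od1 is deliberately the more precise rater; the asymmetry lets
    # tests detect rater-order bugs
    return {
        "od1": ObserverModel(radial_jitter_sd=1.5, sector_bias=DEFAULT_PPA_BIAS),
        "od2": ObserverModel(radial_jitter_sd=2.5, sector_bias=DEFAULT_PPA_BIAS),
    }


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Everything needed to generate a reproducible synthetic study."""

    counts: Mapping[str, int] = field(
        default_factory=lambda: {"glaucoma": 69, "dr": 53, "normal": 37}
    )
    dataset_shapes: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"drishti": (486, 724), "aria": (576, 768)}
    )
    condition_dataset: Mapping[str, str] = field(
        default_factory=lambda: {"glaucoma": "drishti", "normal": "drishti", "dr": "aria"}
    )
    semi_axis_frac: tuple[float, float] = (0.08, 0.14)
    center_frac_box: tuple[float, float] = (0.38, 0.62)
    rotation_range: tuple[float, float] = (0.0, math.pi)
    perturbation_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"glaucoma": 0.05, "dr": 0.05, "normal": 0.05}
    )
    perturbation_orders: tuple[int, ...] = (2, 3, 4)
    observers: Mapping[str, ObserverModel] = field(default_factory=_default_observers)
    ppa_bias_conditions: frozenset[str] = frozenset({"glaucoma"})
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, n in self.counts.items():
            if cond not in CONDITIONS:
                raise InputError(f"unknown condition {cond!r}")
            if n < 0:
                raise InputError(f"count for {cond!r} must be >= 0")
            if cond not in self.condition_dataset:
                raise InputError(f"no dataset mapped for condition {cond!r}")
        lo, hi = self.semi_axis_frac
        if not 0 < lo <= hi:
            raise InputError("semi_axis_frac must be positive and ordered")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticStudyConfig":
        """Build a config from a plain (YAML/JSON-loaded) mapping."""
        kwargs = dict(data)
        if "observers" in kwargs:
            obs = {}
            for name, spec in kwargs["observers"].items():
                spec = dict(spec)
                if "sector_bias" in spec:
                    spec["sector_bias"] = tuple(
                        ((float(lo), float(hi)), float(off))
                        for (lo, hi), off in (
                            ((s[0][0], s[0][1]), s[1]) for s in spec["sector_bias"]
                        )
                    )
                obs[name] = ObserverModel(**spec)
            kwargs["observers"] = obs
        for key in ("dataset_shapes",):
            if key in kwargs:
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
        if "ppa_bias_conditions" in kwargs:
            kwargs["ppa_bias_conditions"] = frozenset(kwargs["ppa_bias_conditions"])
        for key in ("semi_axis_frac", "center_frac_box", "rotation_range", "perturbation_orders"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def default_config(seed: int = 0, **overrides) -> SyntheticStudyConfig:
    """The study-scale default configuration (159 images)."""
    return replace(SyntheticStudyConfig(seed=seed), **overrides)


def _perturbation(
    orders: tuple[int, ...], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth angular modulation, normalized to peak amplitude 1."""
    coeffs = rng.uniform(-1.0, 1.0, size=len(orders))
    phases = rng.uniform(0.0, 2 * math.pi, size=len(orders))
    return coeffs, phases


def _eval_perturbation(
    theta: np.ndarray, orders: tuple[int, ...], coeffs: np.ndarray, phases: np.ndarray
) -> np.ndarray:
    f = np.zeros_like(theta)
    for k, c, p in zip(orders, coeffs, phases):
        f += c * np.cos(k * theta - p)
    dense = np.linspace(0, 2 * math.pi, 1441)
    fd = np.zeros_like(dense)
    for k, c, p in zip(orders, coeffs, phases):
        fd += c * np.cos(k * dense - p)
    peak = np.abs(fd).max()
    return f / peak if peak > 0 else f


def generate_true_disc(
    condition: str,
    shape: tuple[int, int],
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> tuple[EllipseParams, TraceMask]:
    """Sample one true disc for a condition and rasterize it.

    With zero perturbation amplitude the mask is exactly the raster of
    the returned ellipse parameters.  With a positive amplitude the
    boundary radius is the ellipse radius modulated by a smooth
    low-order angular perturbation, and the returned parameters record
    the base ellipse.
    """
    h, w = shape
    lo, hi = config.semi_axis_frac
    ax = rng.uniform(lo * w, hi * w, size=2)
    a, b = float(ax.max()), float(ax.min())
    rot = float(rng.uniform(*config.rotation_range))
    clo, chi = config.center_frac_box
    cx = float(rng.uniform(clo * w, chi * w))
    cy = float(rng.uniform(clo * h, chi * h))
    amp = float(config.perturbation_amplitude.get(condition, 0.0))
    reach = a * (1 + amp) + 2
    if cx - reach < 0 or cx + reach >= w or cy - reach < 0 or cy + reach >= h:
        raise InputError(
            f"disc (semi-major {a:.1f}px, perturbation {amp}) does not fit "
            f"inside image shape {shape}"
        )
    params = EllipseParams((cx, cy), a, b, rot)
    if amp == 0:
        return params, ellipse_to_mask(params, shape)
    coeffs, phases = _perturbation(config.perturbation_orders, rng)
    theta = np.deg2rad(np.arange(0.0, 360.0, 0.5))
    r = params.radius_at(theta) * (
        1.0 + amp * _eval_perturbation(theta, config.perturbation_orders, coeffs, phases)
    )
    pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    mask = polyline_to_mask(Polyline(pts, closed=True), shape)
    return params, mask


def _in_sector(angles_deg: np.ndarray, lo: float, hi: float) -> np.ndarray:
    a = np.mod(angles_deg, 360.0)
    lo, hi = lo % 360.0, hi % 360.0
    if lo <= hi:
        return (a >= lo) & (a < hi)
    return (a >= lo) | (a < hi)


def simulate_tracing(
    true_mask: TraceMask,
    true_params: EllipseParams,
    observer: ObserverModel,
    condition: str,
    rng: np.random.Generator,
    bias_conditions: frozenset[str] = frozenset({"glaucoma"}),
    step_deg: float = 1.0,
) -> Polyline:
    """Simulate one rater's closed tracing of a true disc.

    The true boundary is sampled at ``step_deg`` steps by radial casting
    from the true center; Gaussian radial jitter, sector bias (when the
    condition enables it), at most one misaligned arc, and circular
    moving-average smoothing are then applied in that order.
    """
    angles = np.arange(0.0, 360.0, step_deg)
    r = cast_radii(true_mask, true_params.center, angles)
    if np.isnan(r).any():  # should not occur for star-convex truths
        good = ~np.isnan(r)
        if not good.any():
            raise InputError("true mask has no boundary visible from its center")
        r = np.interp(angles, angles[good], r[good], period=360.0)
    if observer.radial_jitter_sd > 0:
        r = r + rng.normal(0.0, observer.radial_jitter_sd, size=r.shape)
    if condition in bias_conditions:
        for (lo, hi), off in observer.sector_bias:
            r = np.where(_in_sector(angles, lo, hi), r + off, r)
    if observer.misalignment_prob > 0 and rng.random() < observer.misalignment_prob:
        width = max(1, int(round(observer.misalignment_arc / step_deg)))
        start = int(rng.integers(0, len(angles)))
        idx = (start + np.arange(width)) % len(angles)
        r[idx] += observer.misalignment_offset
    if observer.smoothing_window > 1:
        r = ndimage.uniform_filter1d(r, size=observer.smoothing_window, mode="wrap")
    r = np.clip(r, 1.0, None)
    theta = np.deg2rad(angles)
    cx, cy = true_params.center
    pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return Polyline(pts, closed=True)


def generate_study(config: SyntheticStudyConfig) -> list[ImageRecord]:
    """Generate the full synthetic study, reproducible from the seed.

    One record per image: a ``ground_truth`` mask plus one polyline per
    configured rater.  Image ids encode dataset and condition
    (``drishti_glaucoma_000`` ...).  Each image gets an independent
    child RNG spawned from the study seed, so per-image content is
    stable under changes to the composition of other conditions.
    """
    root = np.random.SeedSequence(config.seed)
    records: list[ImageRecord] = []
    for cond in CONDITIONS:
        n = int(config.counts.get(cond, 0))
        if n == 0:
            continue
        dataset = config.condition_dataset[cond]
        shape = tuple(config.dataset_shapes[dataset])
        for i in range(n):
            rng = np.random.default_rng(root.spawn(1)[0])
            params, true_mask = generate_true_disc(cond, shape, config, rng)
            tracings: dict = {"ground_truth": true_mask}
            for rater in sorted(config.observers):
                tracings[rater] = simulate_tracing(
                    true_mask,
                    params,
                    config.observers[rater],
                    cond,
                    rng,
                    bias_conditions=config.ppa_bias_conditions,
                )
            records.append(
                ImageRecord(
                    image_id=f"{dataset}_{cond}_{i:03d}",
                    dataset=dataset,
                    condition=cond,
                    shape=shape,
                    tracings=tracings,
                )
            )
    return records
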