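"""Synthetic vessel centerlines, images and two-group cohorts.

Real ocular photographs from the original case-control study are not
publicly deposited, so this module provides a fully parametric stand-in
with known ground truth:

* parametric centerlines (line, circular arc, sinusoid, random-curvature
  walk) sampled at uniform arc-length spacing, giving a one-parameter
  tortuosity axis — at fixed wavelength, sinusoid amplitude drives all
  three tortuosity indexes monotonically;
* rasterization into vessel-like 8-bit images: a dark Gaussian-profile
  ridge on a bright background (vessels appear darker than the fundus /
  sclera in ocular photography), with optional additive Gaussian noise;
* cohort simulation emulating the study design: two groups of subjects,
  two eyes each, five ocular sites (retina plus four conjunctival
  sectors), with a shared lognormal subject-level tortuosity factor and
  independent per-segment noise, and a site-specific multiplicative group
  effect on amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .metrics import resample_polyline
from .stats import SubjectRecord

__all__ = [
    "SITES",
    "CurveParams",
    "RasterParams",
    "CohortParams",
    "VesselImage",
    "gen_centerline",
    "rasterize_vessel",
    "gen_cohort",
    "place_centerline",
]

#: Ocular imaging sites: posterior pole plus the four bulbar conjunctiva sectors.
SITES = ("retina", "conj_nasal", "conj_temporal", "conj_superior", "conj_inferior")

#: Segments traced per site in the imaging protocol (5 retinal, 3 per sector).
DEFAULT_SEGMENTS_PER_SITE = {
    "retina": 5,
    "conj_nasal": 3,
    "conj_temporal": 3,
    "conj_superior": 3,
    "conj_inferior": 3,
}

#: Segment chord-length windows (px) used when drawing synthetic segments.
CHORD_WINDOWS = {
    "retina": (350.0, 500.0),
    "conj_nasal": (250.0, 400.0),
    "conj_temporal": (250.0, 400.0),
    "conj_superior": (250.0, 400.0),
    "conj_inferior": (250.0, 400.0),
}

_FAMILIES = ("line", "arc", "sinusoid", "random_curvature")


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one synthetic centerline.

    ``span_px`` is the chord length for ``line`` and ``sinusoid``; for
    ``arc`` it is the arc length along a circle of radius ``amplitude_px``.
    ``curvature_sd`` (radians per step) only applies to the
    ``random_curvature`` family. Identical parameters and seed always
    produce the identical curve.
    """

    family: str = "sinusoid"
    span_px: float = 400.0
    amplitude_px: float = 10.0
    wavelength_px: float = 100.0
    curvature_sd: float = 0.05
    sample_spacing_px: float = 2.0
    phase: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown curve family {self.family!r}; expected one of {_FAMILIES}")
        if self.span_px <= 0:
            raise ValueError("span_px must be positive")
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be >= 0")
        if self.wavelength_px <= 0:
            raise ValueError("wavelength_px must be positive")
        if self.sample_spacing_px <= 0:
            raise ValueError("sample_spacing_px must be positive")


@dataclass(frozen=True)
class RasterParams:
    """Parameters of the vessel image model.

    The cross-section is Gaussian: intensity(d) = background_level -
    vessel_contrast * exp(-d^2 / (2 sigma^2)) where d is the distance to
    the centerline and sigma is derived from ``vessel_width_px``, the
    full width at half depth. Image size follows the study protocol
    (1536 x 1024 px, 8-bit).
    """

    image_size: Tuple[int, int] = (1024, 1536)  # (height, width)
    vessel_width_px: float = 10.0
    vessel_contrast: float = 80.0
    background_level: float = 200.0
    noise_sd: float = 0.0
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be in [0, 255]")
        if not (0 <= self.vessel_contrast <= self.background_level):
            raise ValueError("vessel_contrast must be in [0, background_level]")
        if self.vessel_width_px <= 0:
            raise ValueError("vessel_width_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.profile != "gaussian":
            raise ValueError("only the 'gaussian' profile is implemented")

    @property
    def sigma_px(self) -> float:
        """Gaussian sigma of the profile (from full width at half depth)."""
        return self.vessel_width_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class CohortParams:
    """Two-group cohort simulation parameters.

    Each subject carries a shared lognormal tortuosity factor
    (``subject_sd_log``); each segment adds independent lognormal noise
    (``segment_sd_log``). In the affected (FD) group, sinusoid amplitude is
    further multiplied by ``effect_multiplier[site]`` — above 1 at the
    retina and nasal conjunctiva by default, mirroring where the disease
    effect was observed.

    The turning-angle indexes increase with sinusoid amplitude only up to
    roughly 0.2 x wavelength (beyond that, arc length in the denominator
    outgrows total turning and SOAM/PAD decline). The default baseline
    amplitude (2 px at wavelength 100) keeps essentially the whole
    lognormal amplitude distribution inside this monotone regime even at
    a 3x group effect, so amplitude remains a faithful one-parameter
    ground-truth tortuosity axis.
    """

    n_per_group: int = 11
    sites: Tuple[str, ...] = SITES
    segments_per_site: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS_PER_SITE)
    )
    base_amplitude_px: float = 2.0
    effect_multiplier: Dict[str, float] = field(
        default_factory=lambda: {
            "retina": 2.0,
            "conj_nasal": 2.0,
            "conj_temporal": 1.0,
            "conj_superior": 1.0,
            "conj_inferior": 1.0,
        }
    )
    subject_sd_log: float = 0.5
    segment_sd_log: float = 0.15
    wavelength_px: float = 100.0
    age_range: Tuple[float, float] = (30.0, 71.0)
    sample_spacing_px: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for site in self.sites:
            if site not in CHORD_WINDOWS:
                raise ValueError(f"unknown site {site!r}")
            if self.segments_per_site.get(site, 0) < 1:
                raise ValueError(f"segments_per_site[{site!r}] must be >= 1")
        for site, m in self.effect_multiplier.items():
            if m <= 0:
                raise ValueError(f"effect_multiplier[{site!r}] must be > 0")
        if self.subject_sd_log < 0 or self.segment_sd_log < 0:
            raise ValueError("lognormal SDs must be >= 0")


@dataclass
class VesselImage:
    """An 8-bit raster with optional acquisition metadata."""

    pixels: np.ndarray
    site: Optional[str] = None
    eye: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("VesselImage requires 8-bit (uint8) pixels")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("VesselImage must be 2-D grayscale or 3-channel")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("3-D images must have 3 channels")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.pixels.shape


def gen_centerline(params: CurveParams) -> np.ndarray:
    """Generate one centerline at approximately uniform arc-length spacing.

    Curves start at the origin with the chord along +x; rasterization or
    placement translates them into image coordinates. Deterministic for a
    given parameter set and seed.
    """
    spacing = params.sample_spacing_px
    if params.family == "line":
        n = int(math.floor(params.span_px / spacing))
        xs = np.arange(n + 1) * spacing
        if params.span_px - xs[-1] > 1e-9:
            xs = np.concatenate((xs, [params.span_px]))
        return np.column_stack((xs, np.zeros_like(xs)))

    if params.family == "arc":
        r = params.amplitude_px
        if r <= 0:
            raise ValueError("arc family requires amplitude_px (radius) > 0")
        total_angle = params.span_px / r  # span_px is arc length here
        n = max(int(math.ceil(params.span_px / spacing)), 2)
        t = np.linspace(0.0, total_angle, n + 1)
        return np.column_stack((r * np.sin(t), r * (1.0 - np.cos(t))))

    if params.family == "sinusoid":
        # densely parameterize y = A sin(2 pi x / lambda + phase), then
        # resample to uniform arc length
        n_dense = max(int(params.span_px * 2), 64)
        x = np.linspace(0.0, params.span_px, n_dense)
        y = params.amplitude_px * np.sin(2.0 * np.pi * x / params.wavelength_px + params.phase)
        y -= y[0]  # start at origin
        dense = np.column_stack((x, y))
        return resample_polyline(dense, spacing)

    # random_curvature: a direction random walk with N(0, curvature_sd)
    # heading increments per arc-length step
    rng = np.random.default_rng(params.rng_seed)
    n_steps = max(int(math.ceil(params.span_px / spacing)), 2)
    headings = np.concatenate(([0.0], np.cumsum(rng.normal(0.0, params.curvature_sd, n_steps))))
    steps = spacing * np.column_stack((np.cos(headings), np.sin(headings)))
    pts = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
    return pts


def place_centerline(centerline: np.ndarray, rp: RasterParams) -> np.ndarray:
    """Translate a curve starting at the origin to the image center."""
    c = np.asarray(centerline, dtype=float)
    h, w = rp.image_size
    lo = c.min(axis=0)
    hi = c.max(axis=0)
    extent = hi - lo
    offset = np.array([(w - extent[0]) / 2.0, (h - extent[1]) / 2.0]) - lo
    return c + offset


def rasterize_vessel(
    centerline: np.ndarray,
    rp: RasterParams = RasterParams(),
    rng_seed: int = 0,
    site: Optional[str] = None,
    eye: Optional[str] = None,
) -> VesselImage:
    """Render a centerline as a dark Gaussian-profile vessel on a flat background.

    The distance field to the centerline is evaluated exactly (nearest
    point on a densely resampled polyline) inside a window around the
    curve; outside the window the profile is numerically zero. Raises if
    the curve does not fit in the image with a ``vessel_width_px`` margin.
    """
    from scipy.spatial import cKDTree

    c = np.asarray(centerline, dtype=float)
    h, w = rp.image_size
    margin = rp.vessel_width_px
    if (c[:, 0].min() < margin or c[:, 0].max() > w - 1 - margin
            or c[:, 1].min() < margin or c[:, 1].max() > h - 1 - margin):
        raise ValueError(
            "centerline does not fit inside the image with a vessel-width margin"
        )

    img = np.full((h, w), rp.background_level, dtype=float)
    if rp.vessel_contrast > 0:
        dense = resample_polyline(c, 0.25) if c.shape[0] > 1 else c
        sigma = rp.sigma_px
        reach = int(math.ceil(4.0 * sigma)) + 1
        x0 = max(int(math.floor(c[:, 0].min())) - reach, 0)
        x1 = min(int(math.ceil(c[:, 0].max())) + reach, w - 1)
        y0 = max(int(math.floor(c[:, 1].min())) - reach, 0)
        y1 = min(int(math.ceil(c[:, 1].max())) + reach, h - 1)
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack((gx.ravel(), gy.ravel()))
        d, _ = cKDTree(dense).query(pts, workers=-1)
        depth = rp.vessel_contrast * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
        img[y0 : y1 + 1, x0 : x1 + 1] -= depth.reshape(gy.shape)

    if rp.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img += rng.normal(0.0, rp.noise_sd, img.shape)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return VesselImage(pixels=pixels, site=site, eye=eye)


def gen_cohort(cp: CohortParams = CohortParams(), return_truth: bool = False):
    """Simulate a two-group cohort of per-site vessel centerlines.

    Returns ``(records, traces)`` where ``records`` is a list of
    :class:`~ocutort.stats.SubjectRecord` (FD and control groups, balanced
    sexes, uniform ages; renal and cardiac covariates only for the FD
    group, as in a healthy-volunteer control design) and ``traces`` maps
    ``(subject_id, eye, site, segment_id)`` to a centerline polyline.

    Each FD subject's sinusoid amplitude at a site is
    ``base * effect_multiplier[site] * exp(N(0, subject_sd_log))`` with
    additional independent ``exp(N(0, segment_sd_log))`` noise per
    segment; controls omit the multiplier. The two eyes share the subject
    factor but draw independent segment noise.

    With ``return_truth=True`` a third element maps each segment key to
    its ground-truth sinusoid amplitude (px).
    """
    rng = np.random.default_rng(cp.rng_seed)
    records: List[SubjectRecord] = []
    traces: Dict[Tuple[str, str, str, str], np.ndarray] = {}
    truth: Dict[Tuple[str, str, str, str], float] = {}

    for group in ("FD", "control"):
        for i in range(cp.n_per_group):
            subject_id = f"{group}{i + 1:03d}"
            sex = "F" if i % 2 == 0 else "M"
            age = float(rng.uniform(*cp.age_range))
            if group == "FD":
                gfr = float(rng.uniform(20.0, 170.0))
                mwt = float(rng.uniform(8.0, 21.0))
                nyha = int(rng.integers(1, 3))
                stroke = bool(rng.integers(0, 2))
            else:
                gfr = mwt = nyha = stroke = None
            records.append(
                SubjectRecord(
                    subject_id=subject_id, group=group, sex=sex, age=age,
                    gfr=gfr, mwt=mwt, nyha=nyha, stroke=stroke,
                )
            )
            subj_factor = math.exp(rng.normal(0.0, cp.subject_sd_log))
            for eye in ("OD", "OS"):
                for site in cp.sites:
                    mult = cp.effect_multiplier.get(site, 1.0) if group == "FD" else 1.0
                    lo, hi = CHORD_WINDOWS[site]
                    for k in range(cp.segments_per_site[site]):
                        amp = (
                            cp.base_amplitude_px * mult * subj_factor
                            * math.exp(rng.normal(0.0, cp.segment_sd_log))
                        )
                        span = float(rng.uniform(lo, hi))
                        phase = float(rng.uniform(0.0, 2.0 * np.pi))
                        curve = gen_centerline(
                            CurveParams(
                                family="sinusoid",
                                span_px=span,
                                amplitude_px=amp,
                                wavelength_px=cp.wavelength_px,
                                sample_spacing_px=cp.sample_spacing_px,
                                phase=phase,
                            )
                        )
                        key = (subject_id, eye, site, f"seg{k + 1}")
                        traces[key] = curve
                        truth[key] = amp
    if return_truth:
        return records, traces, truth
    return records, traces
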