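"""Seeded generators for every input the pipeline consumes.

These emulate the statistical structure of the real measurements — log-normal
grain sizes (median 290 µm), band-limited surface roughness of a few to a few
tens of micrometres, patchy colonization with two-thirds of the colonized
perimeter consuming and one-third producing O2, ratiometric sensor-image
stacks generated from known rate fields through the Stern-Volmer forward
model with intensity-proportional noise, and site tables spanning the ranges
observed across sandy shelf sediments (grain sizes 102-700 µm, bottom-water
velocities 0.1-0.2 m s^-1, denitrification rates 0.04-11.8 µmol N L^-1 h^-1).

Every generator is deterministic given (spec, seed): the same inputs yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ratiometric import CalibrationCurve, RatioStack
from .upscaling import SiteRecord

__all__ = [
    "SyntheticSpec",
    "ColonizationMap",
    "make_grain_outline",
    "make_colonization_map",
    "make_ratio_series",
    "make_site_table",
    "sample_grain_diameters",
]


@dataclass
class SyntheticSpec:
    """Shared settings for the generators.

    ``consumer_fraction`` / ``producer_fraction`` partition the *colonized*
    perimeter (defaults 2/3 and 1/3); ``colonized_fraction`` is the colonized
    share of the whole perimeter. ``grain_diameter_gsd`` is the geometric
    standard deviation of the log-normal diameter distribution.
    """

    seed: int = 0
    grain_count: int = 50
    grain_diameter_median_um: float = 290.0
    grain_diameter_gsd: float = 1.3
    roughness_amplitude_um: float = 10.0
    colonized_fraction: float = 0.5
    consumer_fraction: float = 2.0 / 3.0
    producer_fraction: float = 1.0 / 3.0
    colony_pairs: int = 4
    areal_cell_density_mean_per_cm2: float = 8.57e5
    areal_cell_density_sd_per_cm2: float = 2.8e5
    noise_cv: float = 0.02
    frame_times_h: tuple[float, ...] = (0.0, 4.0)
    n_outline_vertices: int = 256

    def __post_init__(self) -> None:
        if self.grain_diameter_median_um <= 0 or self.grain_diameter_gsd < 1.0:
            raise ValueError("median diameter must be > 0 and GSD >= 1")
        if self.roughness_amplitude_um < 0:
            raise ValueError("roughness amplitude must be non-negative")
        if self.consumer_fraction + self.producer_fraction > 1.0 + 1e-12:
            raise ValueError("consumer + producer fractions exceed 1")
        if not 0.0 <= self.colonized_fraction <= 1.0:
            raise ValueError("colonized fraction must lie in [0, 1]")
        if np.any(np.diff(self.frame_times_h) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def _rng(spec: SyntheticSpec, *streams: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *streams])


def sample_grain_diameters(spec: SyntheticSpec, n: int | None = None) -> np.ndarray:
    """Log-normal grain diameters (µm) with the spec's median and GSD."""
    n = spec.grain_count if n is None else n
    rng = _rng(spec, 1)
    return np.exp(rng.normal(np.log(spec.grain_diameter_median_um),
                             np.log(spec.grain_diameter_gsd), size=n))


def make_grain_outline(spec: SyntheticSpec, index: int = 0) -> np.ndarray:
    """Closed grain outline (n, 2) in µm with band-limited roughness.

    The radius of grain ``index`` is sampled from the diameter distribution
    and perturbed by Fourier modes 5-25 with random phases, rescaled so the
    peak radial perturbation equals ``roughness_amplitude_um``; amplitude 0
    gives a regular polygonal circle. The first vertex is not repeated.
    """
    rng = _rng(spec, 2, index)
    d = np.exp(rng.normal(np.log(spec.grain_diameter_median_um),
                          np.log(spec.grain_diameter_gsd)))
    r0 = d / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_outline_vertices, endpoint=False)
    pert = np.zeros_like(theta)
    if spec.roughness_amplitude_um > 0:
        for m in range(5, 26):
            amp = rng.normal() / m
            phase = rng.uniform(0.0, 2.0 * np.pi)
            pert += amp * np.cos(m * theta + phase)
        pert *= spec.roughness_amplitude_um / np.max(np.abs(pert))
    r = np.maximum(r0 + pert, 0.1 * r0)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@dataclass
class ColonizationMap:
    """Angular surface-class map of one grain: alternating labelled arcs."""

    grain_diameter_um: float
    arcs: list = field(default_factory=list)  # (theta0, theta1, label, colony_idx)

    def classify(self, theta: float) -> tuple[str, int]:
        """(label, colony index) of the surface at angle theta (rad)."""
        t = float(np.mod(theta, 2.0 * np.pi))
        for t0, t1, label, idx in self.arcs:
            if t0 <= t < t1:
                return label, idx
        return "bare", -1

    def arc_lengths_um(self, label: str) -> np.ndarray:
        r = self.grain_diameter_um / 2.0
        return np.array([(t1 - t0) * r for t0, t1, lab, _ in self.arcs
                         if lab == label])


def make_colonization_map(
    spec: SyntheticSpec, grain_diameter_um: float | None = None
) -> ColonizationMap:
    """Alternating consumer/producer/bare arcs along one grain's perimeter.

    Each of the ``colony_pairs`` periods carries one consumer arc and one
    producer arc, sized from the colonized fraction and its consumer/producer
    split; at defaults on a 290 µm grain this gives four 76 µm consumer and
    four 38 µm producer arcs (the two bare gaps per period make up the rest).
    The construction is deterministic (no randomness enters the layout).
    """
    d = spec.grain_diameter_median_um if grain_diameter_um is None else grain_diameter_um
    a = spec.colony_pairs
    period = 2.0 * np.pi / a
    q = spec.colonized_fraction * spec.consumer_fraction   # consumer share of period
    p = spec.colonized_fraction * spec.producer_fraction
    arcs = []
    for k in range(a):
        start = k * period
        # consumer arc centred at 1/4 period, producer at 3/4 period
        c_mid = start + 0.25 * period
        p_mid = start + 0.75 * period
        arcs.append((c_mid - 0.5 * q * period, c_mid + 0.5 * q * period,
                     "consumer", k))
        arcs.append((p_mid - 0.5 * p * period, p_mid + 0.5 * p * period,
                     "producer", k))
    arcs = [(t0, t1, lab, idx) for t0, t1, lab, idx in arcs if t1 > t0]
    return ColonizationMap(grain_diameter_um=d, arcs=sorted(arcs))


def make_ratio_series(
    rate_field_umol_L_h: np.ndarray,
    calibration: CalibrationCurve,
    spec: SyntheticSpec,
    initial_o2_umol_L: float = 250.0,
    green_level: float = 1000.0,
    pixel_size_um: float = 1.0,
) -> RatioStack:
    """Two-channel image series from a known volumetric O2 rate field.

    Per pixel, O2 at frame time t is ``clip(C(t0) + rate * t, 0, inf)`` —
    oxygen cannot go negative, it simply runs out — mapped through the
    Stern-Volmer calibration to a red/green ratio. The green (reference)
    channel is flat at ``green_level``; both channels receive independent
    multiplicative Gaussian noise of CV ``spec.noise_cv``.
    """
    rate = np.asarray(rate_field_umol_L_h, dtype=float)
    times = np.asarray(spec.frame_times_h, dtype=float)
    rng = _rng(spec, 3)
    reds, greens = [], []
    for t in times:
        o2 = np.clip(initial_o2_umol_L + rate * t, 0.0, None)
        ratio = calibration.ratio(o2)
        green = np.full_like(rate, green_level)
        red = ratio * green
        if spec.noise_cv > 0:
            red = red * (1.0 + spec.noise_cv * rng.standard_normal(rate.shape))
            green = green * (1.0 + spec.noise_cv * rng.standard_normal(rate.shape))
        reds.append(np.clip(red, 0.0, None))
        greens.append(np.clip(green, 0.0, None))
    return RatioStack(times_h=times, red=np.stack(reds), green=np.stack(greens),
                      pixel_size_um=pixel_size_um)


def make_site_table(
    seed: int, n_sites: int, overrides: dict | None = None
) -> list[SiteRecord]:
    """Synthetic site records spanning the global sandy-shelf envelope.

    Grain sizes 102-700 µm (log-uniform), bottom-water velocities
    0.1-0.2 m s^-1, temperate marine T and S, bottom-water O2 at air
    saturation, nitrate 2-30 µmol L^-1, bulk O2 consumption 1-50 µmol L^-1
    h^-1 and denitrification 0.04-11.8 µmol N L^-1 h^-1 (log-uniform).
    ``overrides`` fixes any SiteRecord field to a constant for all sites.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng([seed, 4])
    overrides = overrides or {}
    sites = []
    for _ in range(n_sites):
        fields = {
            "grain_size_um": float(np.exp(rng.uniform(np.log(102.0), np.log(700.0)))),
            "u_bw_m_s": float(rng.uniform(0.1, 0.2)),
            "temperature_C": float(rng.uniform(5.0, 25.0)),
            "salinity": float(rng.uniform(30.0, 36.0)),
            "no3_bw_umol_L": float(rng.uniform(2.0, 30.0)),
            "r_o2_umol_L_h": float(np.exp(rng.uniform(np.log(1.0), np.log(50.0)))),
            "r_den_umol_N_L_h": float(np.exp(rng.uniform(np.log(0.04), np.log(11.8)))),
            "porosity": float(rng.uniform(0.35, 0.45)),
        }
        fields.update(overrides)
        sites.append(SiteRecord(**fields))
    return sites
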