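"""Synthetic potato hypercubes with planted spectral and textural starch signal.

The generator emulates the statistical structure the analysis pipeline
assumes, so the full chain is testable without instrument data:

* Reference values: 96 tubers of two varieties, starch (g/100 g) drawn from
  truncated normals matching the varieties' reported mean/SD/min/max
  (Kexin No.1: 68 samples, 10.23 +/- 2.95 on [1.77, 18.31]; Holland No.15:
  28 samples, 18.96 +/- 1.29 on [17.01, 22.81]).
* Spectra: a flat 0.6 reflectance baseline over 428 bands (382-1004 nm) minus
  Gaussian absorption dips (sigma 15 nm) at 410, 680 and 980 nm whose depth
  grows affinely with starch, plus per-sample multiplicative/additive scatter
  (which SNV removes) and i.i.d. band noise.
* Texture: every pixel's spectrum is the sample spectrum modulated by two
  random spatial fields — one scaling overall brightness, one perturbing the
  absorption-dip direction — built from Gaussian-filtered white noise whose
  correlation length shrinks with starch, plus sparse impulse speckle whose
  density falls with starch. Impulses stretch the min-max quantization range
  (concentrating the gray-level histogram, hence raising GLCM uniformity) and
  are spatially incoherent (lowering GLCM correlation), so across samples
  uniformity decreases and GLCM correlation increases with starch, matching
  the sign pattern the texture-selection stage expects. A per-sample jitter on
  the texture-driving starch value keeps these feature-starch correlations at
  moderate magnitude (|r| around 0.6) rather than deterministic.

Determinism: every operation takes an integer seed; a dataset derives
per-sample seeds as ``seed + sample index``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cube_io import Hypercube, default_wavelength_grid

__all__ = [
    "VarietySpec",
    "SimConfig",
    "KEXIN",
    "HOLLAND",
    "simulate_reference",
    "simulate_spectrum",
    "simulate_cube",
    "simulate_dataset",
    "iter_dataset",
]


@dataclass(frozen=True)
class VarietySpec:
    """Starch-content distribution of one potato variety (g/100 g)."""

    name: str
    n_samples: int
    starch_mean: float
    starch_sd: float
    starch_min: float
    starch_max: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.starch_sd <= 0:
            raise ValueError("starch_sd must be positive")
        if not self.starch_min < self.starch_max:
            raise ValueError("starch_min must be below starch_max")


#: the two study varieties (n, mean, sd, min, max in g/100 g)
KEXIN = VarietySpec("Kexin No.1", 68, 10.23, 2.95, 1.77, 18.31)
HOLLAND = VarietySpec("Holland No.15", 28, 18.96, 1.29, 17.01, 22.81)


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the 96-sample study design."""

    varieties: list[VarietySpec] = field(default_factory=lambda: [KEXIN, HOLLAND])
    cube_rows: int = 120
    cube_cols: int = 120
    roi_size: int = 100
    n_bands: int = 428
    wl_lo: float = 382.0
    wl_hi: float = 1004.0
    # spectral model
    baseline: float = 0.6
    peak_centers: tuple[float, ...] = (410.0, 680.0, 980.0)
    peak_width_nm: float = 15.0
    # dip depth at peak c: peak_starch_gain * scale_c * (offset_c + starch);
    # distinct per-peak affine responses keep the dip-depth *ratios* moving
    # with starch, so the signal survives SNV's per-spectrum rescaling
    peak_starch_gain: float = 1.0
    peak_gain_scales: tuple[float, ...] = (0.010, 0.006, 0.004)
    peak_depth_offsets: tuple[float, ...] = (2.0, 12.0, 30.0)  # g/100 g equivalents
    spectral_noise_sd: float = 0.004  # per-sample i.i.d. band noise (reflectance units)
    scatter_slope_sd: float = 0.08    # per-sample multiplicative scatter (SNV-removable)
    scatter_offset_sd: float = 0.03   # per-sample additive offset (SNV-removable)
    # texture model
    texture_amplitude: float = 0.05       # brightness-field modulation depth
    texture_chem_amplitude: float = 0.03  # dip-direction field amplitude (reflectance units)
    texture_grain_base: float = 6.0       # correlation length (px) at starch 0
    texture_grain_slope: float = 0.18     # px lost per g/100 g
    texture_grain_min: float = 1.2
    impulse_fraction_max: float = 0.10    # speckle density at starch 0
    impulse_starch_scale: float = 25.0    # g/100 g at which speckle density reaches 0
    impulse_amplitude: float = 5.0        # speckle value in field-SD units
    texture_starch_jitter_sd: float = 5.0  # per-sample blur of the texture-starch link (g/100 g)
    pixel_noise_sd: float = 0.002         # per-pixel per-band noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cube_rows < self.roi_size or self.cube_cols < self.roi_size:
            raise ValueError(
                f"cube {self.cube_rows}x{self.cube_cols} cannot hold a {self.roi_size}x{self.roi_size} ROI"
            )
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        for name in (
            "peak_starch_gain", "spectral_noise_sd", "scatter_slope_sd", "scatter_offset_sd",
            "texture_amplitude", "texture_chem_amplitude", "texture_grain_base",
            "texture_grain_slope", "impulse_fraction_max", "impulse_amplitude", "pixel_noise_sd",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not (len(self.peak_centers) == len(self.peak_gain_scales) == len(self.peak_depth_offsets)):
            raise ValueError("peak_centers, peak_gain_scales and peak_depth_offsets must align")
        if not self.varieties:
            raise ValueError("at least one variety required")

    @property
    def wavelengths(self) -> np.ndarray:
        return default_wavelength_grid(self.n_bands, self.wl_lo, self.wl_hi)

    @property
    def n_samples(self) -> int:
        return sum(v.n_samples for v in self.varieties)

    def grain_for(self, starch: float) -> float:
        """Spatial correlation length (px) of the texture fields; shrinks with starch."""
        return max(self.texture_grain_min, self.texture_grain_base - self.texture_grain_slope * starch)

    def impulse_fraction_for(self, starch: float) -> float:
        """Speckle pixel fraction; falls linearly to 0 at ``impulse_starch_scale``."""
        return self.impulse_fraction_max * float(np.clip(1.0 - starch / self.impulse_starch_scale, 0.0, 1.0))

    def dip_profile(self) -> np.ndarray:
        """Unit-peak sum of the Gaussian absorption-dip shapes over the grid."""
        wl = self.wavelengths
        prof = np.zeros_like(wl)
        for c in self.peak_centers:
            prof += np.exp(-((wl - c) ** 2) / (2.0 * self.peak_width_nm ** 2))
        return prof


def simulate_reference(spec: VarietySpec, seed: int) -> np.ndarray:
    """Draw ``spec.n_samples`` starch values from Normal(mean, sd) truncated
    to [min, max], by rejection (exact for these acceptance rates)."""
    if spec.starch_sd <= 0:
        raise ValueError("starch_sd must be positive")
    rng = np.random.default_rng(seed)
    out: list[float] = []
    while len(out) < spec.n_samples:
        draws = rng.normal(spec.starch_mean, spec.starch_sd, size=max(64, spec.n_samples))
        keep = draws[(draws >= spec.starch_min) & (draws <= spec.starch_max)]
        out.extend(keep.tolist())
    return np.array(out[: spec.n_samples])


def simulate_spectrum(starch: float, config: SimConfig, seed: int) -> np.ndarray:
    """One sample's 428-point reflectance spectrum.

    Baseline minus starch-scaled Gaussian dips, then per-sample scatter
    (slope/offset) and i.i.d. band noise; clipped to (0, 1].
    """
    if starch < 0:
        raise ValueError("starch must be non-negative")
    rng = np.random.default_rng(seed)
    wl = config.wavelengths
    r = np.full(config.n_bands, config.baseline)
    for c, scale, off in zip(config.peak_centers, config.peak_gain_scales, config.peak_depth_offsets):
        depth = config.peak_starch_gain * scale * (off + starch)
        r = r - depth * np.exp(-((wl - c) ** 2) / (2.0 * config.peak_width_nm ** 2))
    slope = 1.0 + config.scatter_slope_sd * rng.standard_normal()
    offset = config.scatter_offset_sd * rng.standard_normal()
    r = slope * r + offset
    r = r + config.spectral_noise_sd * rng.standard_normal(config.n_bands)
    return np.clip(r, 1e-6, 1.0)


def _texture_field(rng: np.random.Generator, shape: tuple[int, int], grain: float,
                   impulse_fraction: float, impulse_amplitude: float) -> np.ndarray:
    """Unit-scale spatial field: smoothed white noise plus sparse impulses."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=grain, mode="reflect")
    sd = z.std()
    if sd > 0:
        z /= sd
    mask = rng.random(shape) < impulse_fraction
    signs = rng.choice([-1.0, 1.0], size=shape)
    z[mask] = (signs * impulse_amplitude)[mask]
    return z


def simulate_cube(starch: float, config: SimConfig, seed: int) -> Hypercube:
    """One sample's hypercube (float32).

    The sample spectrum (from ``simulate_spectrum`` with the same seed) is
    modulated per pixel by a brightness field V1 and a dip-direction field V2
    (see module docstring), plus small per-pixel band noise.
    """
    spectrum = simulate_spectrum(starch, config, seed)
    rng = np.random.default_rng([seed, 1])
    shape = (config.cube_rows, config.cube_cols)
    # the texture-starch link is deliberately noisy: surface texture tracks
    # composition only loosely, so feature-starch correlations land near the
    # moderate (|r| ~ 0.6) regime rather than being deterministic
    s_tex = max(0.0, starch + config.texture_starch_jitter_sd * rng.standard_normal())
    grain = config.grain_for(s_tex)
    frac = config.impulse_fraction_for(s_tex)
    v1 = _texture_field(rng, shape, grain, frac, config.impulse_amplitude)
    v2 = _texture_field(rng, shape, grain, frac, config.impulse_amplitude)

    data = spectrum[None, None, :].astype(np.float32) * (
        1.0 + config.texture_amplitude * v1[:, :, None]
    ).astype(np.float32)
    if config.texture_chem_amplitude:
        dip = config.dip_profile().astype(np.float32)
        data = data - (config.texture_chem_amplitude * v2[:, :, None]).astype(np.float32) * dip[None, None, :]
    if config.pixel_noise_sd:
        data = data + rng.standard_normal(data.shape, dtype=np.float32) * np.float32(config.pixel_noise_sd)
    np.clip(data, 1e-6, 1.0, out=data)
    return Hypercube(data, config.wavelengths)


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    index = 0
    for vi, spec in enumerate(config.varieties):
        starch = simulate_reference(spec, seed=config.seed + 500_000_000 + vi)
        for s in starch:
            rows.append({"sample_id": f"S{index + 1:03d}", "variety": spec.name,
                         "starch_g_per_100g": float(s)})
            index += 1
    return pd.DataFrame(rows)


def iter_dataset(config: SimConfig) -> Iterator[tuple[str, str, float, Hypercube]]:
    """Yield ``(sample_id, variety, starch, cube)`` one sample at a time,
    so a full-size dataset never has to sit in memory at once."""
    table = _sample_table(config)
    for i, row in table.iterrows():
        cube = simulate_cube(row["starch_g_per_100g"], config, seed=config.seed + int(i))
        yield row["sample_id"], row["variety"], row["starch_g_per_100g"], cube


def simulate_dataset(config: SimConfig) -> tuple[list[Hypercube], pd.DataFrame]:
    """Materialise the whole dataset: one cube per sample plus the reference
    table (columns sample_id, variety, starch_g_per_100g)."""
    table = _sample_table(config)
    cubes = [
        simulate_cube(row["starch_g_per_100g"], config, seed=config.seed + int(i))
        for i, row in table.iterrows()
    ]
    return cubes, table
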