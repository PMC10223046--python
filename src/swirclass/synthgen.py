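"""Seeded synthetic Vis-SWIR reflectance generator.

Emulates a two-product, two-physical-state pasta study design: 6 samples per
product class, each measured frozen and thawed with 50 replicate spectra, on
the canonical 350-2500 nm grid (1200 spectra of 2151 variables by default).

Each spectrum is a gentle quadratic reflectance continuum minus Gaussian
water-absorption dips near 1450 and 1940 nm, plus structured effects that
reproduce the qualitative findings of the study design it emulates:

* the frozen state deepens the 1450-1550 / 1900-2100 nm bands and raises the
  continuum over 350-1450, 1600-1850 and 2100-2400 nm;
* product class 1 sits above class 0 over 1300-2500 nm, strongly in the
  thawed state and only marginally in the frozen state, so the two classes
  are much easier to separate after thawing;
* replicate spectra of one physical sample share a random baseline shift,
  and every point carries independent Gaussian noise.

All magnitudes are configuration, not measured fact: the generator is tuned
to reproduce orderings, not any particular accuracy value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from swirclass.spectra_io import (
    CANONICAL_GRID,
    FROZEN,
    THAWED,
    SampleMeta,
    SpectraDataset,
    Spectrum,
    WavelengthGrid,
)


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorption dip: center, width (sd) and depth in reflectance."""

    center_nm: float
    width_nm: float
    depth: float

    def __post_init__(self) -> None:
        if not 350 <= self.center_nm <= 2500:
            raise ValueError("center_nm must lie within 350-2500 nm")
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")


def default_bands() -> tuple[BandSpec, ...]:
    """Water absorption bands near 1450 and 1940 nm."""
    return (BandSpec(1450.0, 40.0, 0.15), BandSpec(1940.0, 40.0, 0.20))


#: Wavelength windows where the frozen state reflects more than thawed.
FROZEN_BOOST_RANGES = ((350.0, 1450.0), (1600.0, 1850.0), (2100.0, 2400.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic dataset.

    ``continuum_coeffs`` are polynomial coefficients (highest power first, as
    for numpy.polyval) evaluated on the wavelength axis rescaled to [0, 1];
    the default rises from about 0.45 at 350 nm to 0.65 at 2500 nm.
    ``class_offset_*`` is added to class-1 spectra over 1300-2500 nm; the
    thawed offset is much larger than the frozen one.  ``frozen_boost`` is
    added to frozen spectra over the ranges in :data:`FROZEN_BOOST_RANGES`,
    and ``state_band_scale_frozen`` multiplies the band depths when frozen.
    """

    n_samples_per_class: int = 6
    n_spectra_per_sample_per_state: int = 50
    continuum_coeffs: tuple[float, ...] = (-0.05, 0.25, 0.45)
    bands: tuple[BandSpec, ...] = field(default_factory=default_bands)
    class_offset_thawed: float = 0.03
    class_offset_frozen: float = 0.005
    state_band_scale_frozen: float = 1.3
    frozen_boost: float = 0.02
    noise_sd: float = 0.01
    sample_effect_sd: float = 0.01
    seed: int = 0
    grid: WavelengthGrid = CANONICAL_GRID

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 1 or self.n_spectra_per_sample_per_state < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0 or self.sample_effect_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.class_offset_thawed >= self.class_offset_frozen >= 0:
            # the defaults encode the study's larger thawed-state separation
            raise ValueError("require class_offset_thawed >= class_offset_frozen >= 0")


def continuum(cfg: GeneratorConfig) -> np.ndarray:
    """Baseline reflectance over the grid (no bands, offsets or noise)."""
    w = cfg.grid.wavelengths()
    u = (w - w[0]) / (w[-1] - w[0])
    return np.polyval(cfg.continuum_coeffs, u)


def _band_profile(cfg: GeneratorConfig, scale: float) -> np.ndarray:
    w = cfg.grid.wavelengths()
    total = np.zeros(w.shape, dtype=float)
    for band in cfg.bands:
        total += scale * band.depth * np.exp(-0.5 * ((w - band.center_nm) / band.width_nm) ** 2)
    return total


def _range_mask(grid: WavelengthGrid, lo: float, hi: float) -> np.ndarray:
    w = grid.wavelengths()
    return (w >= lo) & (w <= hi)


def generate_spectrum(
    cfg: GeneratorConfig,
    meta: SampleMeta,
    rng: np.random.Generator,
    sample_effect: float | None = None,
) -> Spectrum:
    """One synthetic spectrum for the given metadata.

    ``sample_effect`` is the per-physical-sample baseline shift; when None it
    is drawn from the stream, but dataset generation draws it once per sample
    so replicates stay correlated.  Output is clipped to [0, 1].
    """
    w = cfg.grid.wavelengths()
    frozen = meta.physical_state == FROZEN
    band_scale = cfg.state_band_scale_frozen if frozen else 1.0
    r = continuum(cfg) - _band_profile(cfg, band_scale)
    if frozen:
        for lo, hi in FROZEN_BOOST_RANGES:
            r = r + cfg.frozen_boost * _range_mask(cfg.grid, lo, hi)
    if meta.product_class == 1:
        offset = cfg.class_offset_frozen if frozen else cfg.class_offset_thawed
        r = r + offset * _range_mask(cfg.grid, 1300.0, 2500.0)
    if sample_effect is None:
        sample_effect = rng.normal(0.0, cfg.sample_effect_sd) if cfg.sample_effect_sd > 0 else 0.0
    r = r + sample_effect
    if cfg.noise_sd > 0:
        r = r + rng.normal(0.0, cfg.noise_sd, size=w.shape)
    return Spectrum(meta, np.clip(r, 0.0, 1.0))


def generate_dataset(cfg: GeneratorConfig = GeneratorConfig()) -> SpectraDataset:
    """Full factorial dataset: 2 classes x samples x 2 states x replicates.

    Deterministic for a fixed ``cfg.seed``.  Row order is class, then sample,
    then state, then replicate, giving a stable file order for the
    deterministic systematic split.
    """
    rng = np.random.default_rng(cfg.seed)
    spectra: list[Spectrum] = []
    for product_class in (0, 1):
        for sample_idx in range(cfg.n_samples_per_class):
            sample_id = f"C{product_class}S{sample_idx:02d}"
            sample_effect = (
                rng.normal(0.0, cfg.sample_effect_sd) if cfg.sample_effect_sd > 0 else 0.0
            )
            for state in (FROZEN, THAWED):
                meta = SampleMeta(sample_id, product_class, state)
                for _ in range(cfg.n_spectra_per_sample_per_state):
                    spectra.append(generate_spectrum(cfg, meta, rng, sample_effect))
    return SpectraDataset(cfg.grid, spectra)
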