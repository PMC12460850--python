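"""Class-structured synthetic NIR spectra.

Each class is defined by a smooth absorbance template: a shared set of
Gaussian absorption bands whose centers are shifted per class by a
controllable separation.  Samples add multiplicative scatter, a random
low-order polynomial baseline (which the SG-derivative preprocessing is
designed to remove), and white noise.  With ``class_separation = 0`` the
class templates coincide, so any classifier can only reach chance level
— the generator's negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

from .spectra import SpectralDataset, WavelengthGrid

__all__ = ["SyntheticSpec", "generate", "snr_profile", "sorghum_like", "PRESETS"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a multi-class synthetic spectral dataset.

    Units: band centers/widths and class separation in nm; absorbance is
    unitless with band amplitudes of order 1.
    """

    n_classes: int = 10
    samples_per_class: int = 50
    n_bands: int = 4
    band_center_range: tuple[float, float] = (760.0, 1050.0)
    band_width_range: tuple[float, float] = (10.0, 60.0)
    class_separation: float = 16.0
    baseline_poly_degree: int = 2
    baseline_scale: float = 0.1
    noise_sd: float = 0.01
    scatter_sd: float = 0.05
    n_points: int = 331
    wavelength_range: tuple[float, float] = (740.0, 1070.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_classes, self.samples_per_class, self.n_bands,
               self.n_points) < 1:
            raise ValueError("counts must be positive")
        if self.class_separation < 0 or self.noise_sd < 0 or self.scatter_sd < 0:
            raise ValueError("separation and noise levels must be nonnegative")


def _templates(spec: SyntheticSpec, grid: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Noiseless per-class absorbance templates, shape (K, m)."""
    lo, hi = spec.band_center_range
    centers = rng.uniform(lo, hi, spec.n_bands)
    widths = rng.uniform(*spec.band_width_range, spec.n_bands)
    amps = rng.uniform(0.2, 1.0, spec.n_bands)
    # class-specific center shifts; zero separation -> identical templates
    shifts = rng.normal(0.0, 1.0, (spec.n_classes, spec.n_bands)) * spec.class_separation
    tmpl = np.zeros((spec.n_classes, grid.size))
    for c in range(spec.n_classes):
        for b in range(spec.n_bands):
            mu = centers[b] + shifts[c, b]
            tmpl[c] += amps[b] * np.exp(-0.5 * ((grid - mu) / widths[b]) ** 2)
    return tmpl


def generate(spec: SyntheticSpec) -> SpectralDataset:
    """Draw a balanced, deterministic dataset from the generative model."""
    rng = np.random.default_rng(spec.seed)
    grid = np.linspace(*spec.wavelength_range, spec.n_points)
    tmpl = _templates(spec, grid, rng)
    t = np.linspace(-1.0, 1.0, spec.n_points)
    n = spec.n_classes * spec.samples_per_class
    spectra = np.empty((n, spec.n_points))
    labels = np.empty(n, dtype=int)
    row = 0
    for c in range(spec.n_classes):
        for _ in range(spec.samples_per_class):
            scatter = 1.0 + rng.normal(0.0, spec.scatter_sd)
            coefs = rng.normal(0.0, spec.baseline_scale,
                               spec.baseline_poly_degree + 1)
            baseline = np.polynomial.polynomial.polyval(t, coefs)
            noise = rng.normal(0.0, spec.noise_sd, spec.n_points)
            spectra[row] = tmpl[c] * scatter + baseline + noise
            labels[row] = c
            row += 1
    names = tuple(f"variety_{c:02d}" for c in range(spec.n_classes))
    return SpectralDataset(spectra, WavelengthGrid(grid), labels, names)


def snr_profile(ds: SpectralDataset) -> dict:
    """Between- vs within-class variance per wavelength.

    Used to calibrate separability in tests: the mean between/within
    ratio grows with the generator's class separation.
    """
    if ds.n_classes < 2:
        raise ValueError("need at least 2 classes")
    grand = ds.spectra.mean(axis=0)
    between = np.zeros(ds.n_features)
    within = np.zeros(ds.n_features)
    for c in range(ds.n_classes):
        rows = ds.spectra[ds.labels == c]
        if rows.size == 0:
            continue
        w = rows.shape[0] / ds.n_samples
        between += w * (rows.mean(axis=0) - grand) ** 2
        within += w * rows.var(axis=0)
    eps = np.finfo(float).tiny
    return {"between": between, "within": within,
            "ratio": between / (within + eps),
            "mean_ratio": float(np.mean(between / (within + eps)))}


def sorghum_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """10 classes x 50 samples on the default 331-point grid."""
    return replace(SyntheticSpec(seed=seed), **overrides)


PRESETS = {
    "sorghum-like": sorghum_like,
    "chickpea-like": lambda seed=0, **kw: replace(
        SyntheticSpec(n_classes=19, samples_per_class=50, seed=seed), **kw),
    "barley-like": lambda seed=0, **kw: replace(
        SyntheticSpec(n_classes=24, samples_per_class=50, seed=seed), **kw),
}
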