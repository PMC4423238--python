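"""Synthetic two-class serum-SERS-like spectrum generator.

Emulates the statistical structure of a serum SERS case/control study:
Lorentzian Raman peaks on a broad autofluorescence background, with
class-dependent relative intensity shifts at diagnostic bands, per-spectrum
multiplicative scale variability, peak-amplitude jitter and additive noise.

The default cohort is 55 "cancer" + 36 "normal" spectra on a 1270-point
400-1800 cm^-1 grid, with 15 peaks at the canonical serum SERS positions.
Eight peaks carry a signed class effect (relative amplitude change in the
cancer class): negative at 481, 1219, 1445 and 1585 cm^-1, positive at 683,
1025, 1314 and 1640 cm^-1.  The six-band restriction used for band-recovery
experiments keeps effects only at the 481/683/1025/1314/1445/1585 diagnostic
bands (see :func:`six_band_config`).

Determinism: spectrum ``i`` of class ``c`` draws from
``numpy.random.default_rng([seed, class_code, i])`` (class_code 0 = cancer,
1 = normal), so enlarging one class never perturbs previously generated
spectra of either class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import (
    DEFAULT_SEG_LEN,
    LABEL_CANCER,
    LABEL_NORMAL,
    SegmentIndex,
    SpectraSet,
    Spectrum,
    WavenumberGrid,
    build_segment_index,
)


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian peak.

    ``class_effect`` is the signed relative amplitude change in the cancer
    class: amplitude is multiplied by ``1 + class_effect`` for cancer rows.
    ``width`` is the Lorentzian half-width at half-maximum (cm^-1).
    """

    center: float
    width: float = 9.0
    base_amplitude: float = 1.0
    class_effect: float = 0.0
    peak_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be non-negative")
        if not abs(self.class_effect) < 1:
            raise ValueError("|class_effect| must be < 1 (amplitudes stay positive)")
        if self.peak_jitter_sd < 0:
            raise ValueError("peak_jitter_sd must be non-negative")


def _default_peaks() -> tuple[PeakSpec, ...]:
    # (center, base_amplitude, class_effect); strongest bands at 481, 1135,
    # 1219, 1445 and 1585 cm^-1.  Effect magnitude 0.15 at the signed bands.
    table = [
        (481.0, 1.00, -0.15),
        (650.0, 0.55, 0.0),
        (683.0, 0.60, +0.15),
        (725.0, 0.65, 0.0),
        (830.0, 0.45, 0.0),
        (859.0, 0.50, 0.0),
        (915.0, 0.45, 0.0),
        (1025.0, 0.60, +0.15),
        (1135.0, 1.00, 0.0),
        (1219.0, 1.00, -0.15),
        (1314.0, 0.65, +0.15),
        (1346.0, 0.60, 0.0),
        (1445.0, 1.00, -0.15),
        (1585.0, 1.00, -0.15),
        (1640.0, 0.55, +0.15),
    ]
    return tuple(PeakSpec(center=c, base_amplitude=a, class_effect=e) for c, a, e in table)


#: Centers of the six diagnostic bands used in recovery experiments.
SIX_DIAGNOSTIC_CENTERS = (481.0, 683.0, 1025.0, 1314.0, 1445.0, 1585.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults reproduce the study-sized cohort."""

    n_normal: int = 36
    n_cancer: int = 55
    grid_lo: float = 400.0
    grid_hi: float = 1800.0
    n_points: int = 1270
    peaks: tuple[PeakSpec, ...] = field(default_factory=_default_peaks)
    # Per-spectrum fifth-order polynomial background, in Chebyshev basis on
    # the grid mapped to [-1, 1]: constant term ~ U(offset range), higher
    # coefficients ~ U(-coeff_range, coeff_range); shifted up if needed so
    # the baseline stays >= baseline_floor everywhere.
    baseline_order: int = 5
    baseline_offset_range: tuple[float, float] = (5.0, 10.0)
    baseline_coeff_range: float = 1.5
    baseline_floor: float = 0.5
    scale_sigma: float = 0.2  # lognormal sd of the per-spectrum global scale
    noise_sd: float = 0.12  # additive Gaussian noise, a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal <= 0 or self.n_cancer <= 0:
            raise ValueError("class counts must be positive")
        if self.noise_sd < 0 or self.scale_sigma < 0:
            raise ValueError("noise_sd and scale_sigma must be non-negative")
        if self.baseline_floor <= 0:
            raise ValueError("baseline_floor must be positive")
        lo, hi = self.baseline_offset_range
        if lo > hi:
            raise ValueError("baseline_offset_range reversed")

    def grid(self) -> WavenumberGrid:
        return WavenumberGrid(np.linspace(self.grid_lo, self.grid_hi, self.n_points))

    def quiet(self) -> "SyntheticConfig":
        """Copy with all randomness off (no noise/jitter/scale/baseline spread)."""
        peaks = tuple(replace(p, peak_jitter_sd=0.0) for p in self.peaks)
        return replace(
            self,
            peaks=peaks,
            noise_sd=0.0,
            scale_sigma=0.0,
            baseline_offset_range=(0.0, 0.0),
            baseline_coeff_range=0.0,
            baseline_floor=1e-12,
        )


def six_band_config(**overrides) -> SyntheticConfig:
    """Default config with class effects only at the six diagnostic bands.

    Zeroes the effects at 1219 and 1640 cm^-1 (present in the full
    difference-spectrum signature but not among the six consensus bands).
    """
    base = SyntheticConfig(**overrides)
    peaks = tuple(
        p if p.center in SIX_DIAGNOSTIC_CENTERS else replace(p, class_effect=0.0)
        for p in base.peaks
    )
    return replace(base, peaks=peaks)


def lorentzian(nu: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Lorentzian with HWHM ``width``."""
    return width**2 / ((np.asarray(nu, dtype=float) - center) ** 2 + width**2)


def baseline_polynomial(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one random positive fifth-order background, evaluated on the grid.

    The result is exactly a degree-``baseline_order`` polynomial of the
    wavenumber (a Chebyshev series of that degree), the same family the
    preprocessing stage removes.
    """
    lo, hi = config.baseline_offset_range
    coeffs = np.empty(config.baseline_order + 1)
    coeffs[0] = rng.uniform(lo, hi)
    coeffs[1:] = rng.uniform(-config.baseline_coeff_range, config.baseline_coeff_range,
                             size=config.baseline_order)
    grid = config.grid()
    cheb = np.polynomial.Chebyshev(coeffs, domain=[grid.lo, grid.hi])
    base = cheb(grid.values)
    deficit = config.baseline_floor - base.min()
    if deficit > 0:  # shift constant term; still the same polynomial family
        base = base + deficit
    return base


def simulate_spectrum(
    config: SyntheticConfig, label: str, rng: np.random.Generator, sample_id: str = ""
) -> Spectrum:
    """Draw one spectrum: baseline + scaled jittered Lorentzians + noise.

    Draw order (fixed contract): baseline coefficients, global scale, one
    amplitude jitter per peak, then the additive noise vector.
    """
    if label not in (LABEL_NORMAL, LABEL_CANCER):
        raise ValueError(f"label must be normal/cancer, got {label!r}")
    grid = config.grid()
    nu = grid.values
    y = baseline_polynomial(config, rng)
    scale = float(np.exp(rng.normal(0.0, config.scale_sigma))) if config.scale_sigma > 0 else 1.0
    is_cancer = label == LABEL_CANCER
    for peak in config.peaks:
        jitter = float(rng.normal(0.0, peak.peak_jitter_sd)) if peak.peak_jitter_sd > 0 else 0.0
        effect = 1.0 + (peak.class_effect if is_cancer else 0.0)
        amplitude = peak.base_amplitude * scale * effect * (1.0 + jitter)
        if amplitude < 0:
            raise ValueError(
                f"negative amplitude for peak at {peak.center} cm^-1 "
                f"(jitter {jitter:.3f}); reduce peak_jitter_sd"
            )
        if amplitude:
            y = y + amplitude * lorentzian(nu, peak.center, peak.width)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=nu.size)
    return Spectrum(grid=grid, intensities=y, label=label, sample_id=sample_id)


_CLASS_CODE = {LABEL_CANCER: 0, LABEL_NORMAL: 1}


def _row_rng(seed: int, label: str, i: int) -> np.random.Generator:
    return np.random.default_rng([seed, _CLASS_CODE[label], i])


def simulate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Simulate the full two-class cohort (cancer rows first, then normal)."""
    grid = config.grid()
    rows, labels, ids = [], [], []
    for label, n in ((LABEL_CANCER, config.n_cancer), (LABEL_NORMAL, config.n_normal)):
        for i in range(n):
            sid = f"{label}_{i:03d}"
            spec = simulate_spectrum(config, label, _row_rng(config.seed, label, i), sid)
            rows.append(spec.intensities)
            labels.append(label)
            ids.append(sid)
    return SpectraSet(grid=grid, matrix=np.vstack(rows),
                      labels=np.array(labels, dtype=object),
                      ids=np.array(ids, dtype=object))


def planted_truth(
    config: SyntheticConfig, seg_len: int = DEFAULT_SEG_LEN
) -> list[int]:
    """Segment ids holding a nonzero-class-effect peak center (ground truth).

    A center falling in the gap between two segments' closed wavenumber
    intervals is assigned to the segment of its nearest grid point.
    """
    idx = build_segment_index(config.n_points, seg_len)
    grid = config.grid()
    segs = {
        idx.segment_of(grid.nearest_index(p.center))
        for p in config.peaks
        if p.class_effect != 0.0
    }
    return sorted(segs)
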