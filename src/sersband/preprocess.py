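"""Batch preprocessing: baseline removal, smoothing, area normalization.

Autofluorescence background is removed by iterative modified polynomial
fitting (peak clipping): fit a fifth-order polynomial by least squares,
replace every point above the fit with the fitted value, refit, and stop
when the working signal stops changing.  Sharp Raman peaks are progressively
excluded from the fit while the broad fluorescence background is retained.
The implemented variant is the plain peak-clipping iterate, without a
noise-dependent dead band.

Default stage order is baseline -> smooth -> normalize; set
``smooth_before_normalize=False`` to normalize first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet, Spectrum


@dataclass(frozen=True)
class PreprocessConfig:
    poly_order: int = 5
    max_iterations: int = 100
    tolerance: float = 1e-6  # relative change of the working signal
    smooth_window: int = 5  # odd, > smooth_order
    smooth_order: int = 3
    smooth_before_normalize: bool = True

    def __post_init__(self) -> None:
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.smooth_window % 2 == 0:
            raise ValueError(f"smooth_window must be odd, got {self.smooth_window}")
        if self.smooth_window <= self.smooth_order:
            raise ValueError("smooth_window must exceed smooth_order")


@dataclass
class BaselineFit:
    """Fitted background plus convergence diagnostics.

    ``history`` (kept on request) holds the working signal after each
    clipping step; it is pointwise non-increasing across iterations.
    """

    baseline: np.ndarray
    iterations: int
    converged: bool
    history: list[np.ndarray] | None = None


def _polyfit_eval(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    # Chebyshev basis for conditioning; mathematically an order-`order` polynomial.
    return np.polynomial.Chebyshev.fit(x, y, order)(x)


def fit_baseline(
    spectrum: Spectrum,
    config: PreprocessConfig = PreprocessConfig(),
    keep_history: bool = False,
) -> BaselineFit:
    """Iterative peak-clipping polynomial baseline.

    The working signal is pointwise non-increasing across iterations
    (clipping takes the minimum of signal and fit).  Convergence is declared
    when ``max|delta| / max|working|`` falls below ``tolerance``; if the
    iteration cap is hit first the last iterate is returned with
    ``converged=False``.
    """
    x = spectrum.grid.values
    if x.size <= config.poly_order + 1:
        raise ValueError(
            f"grid length {x.size} too short for order-{config.poly_order} baseline"
        )
    work = spectrum.intensities.astype(float).copy()
    fit = _polyfit_eval(x, work, config.poly_order)
    converged = False
    iterations = 0
    history: list[np.ndarray] | None = [work.copy()] if keep_history else None
    for iterations in range(1, config.max_iterations + 1):
        clipped = np.minimum(work, fit)
        denom = np.max(np.abs(work))
        change = np.max(np.abs(clipped - work)) / denom if denom > 0 else 0.0
        work = clipped
        if history is not None:
            history.append(work.copy())
        fit = _polyfit_eval(x, work, config.poly_order)
        if change < config.tolerance:
            converged = True
            break
    return BaselineFit(baseline=fit, iterations=iterations, converged=converged,
                       history=history)


def subtract_baseline(spectrum: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Pointwise difference; negative residuals are permitted."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != spectrum.intensities.shape:
        raise ValueError(
            f"baseline length {baseline.size} != spectrum length "
            f"{spectrum.intensities.size}"
        )
    return Spectrum(
        grid=spectrum.grid,
        intensities=spectrum.intensities - baseline,
        label=spectrum.label,
        sample_id=spectrum.sample_id,
    )


def smooth(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Savitzky-Golay local polynomial smoothing.

    Exactly reproduces any input that is globally a polynomial of degree
    <= ``smooth_order``.
    """
    n = spectrum.intensities.size
    if config.smooth_window >= n:
        raise ValueError(f"smooth_window {config.smooth_window} >= spectrum length {n}")
    y = savgol_filter(spectrum.intensities, config.smooth_window, config.smooth_order)
    return Spectrum(spectrum.grid, y, spectrum.label, spectrum.sample_id)


def area_normalize(spectrum: Spectrum) -> Spectrum:
    """Rescale so the trapezoidal area over the stored grid equals 1."""
    area = float(np.trapezoid(spectrum.intensities, spectrum.grid.values))
    if area <= 0:
        raise ValueError(
            f"non-positive area ({area:.3g}) for sample {spectrum.sample_id!r}; "
            "cannot area-normalize"
        )
    return Spectrum(
        spectrum.grid, spectrum.intensities / area, spectrum.label, spectrum.sample_id
    )


def preprocess_spectrum(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> tuple[Spectrum, BaselineFit]:
    """baseline -> smooth -> normalize (order switchable) for one spectrum."""
    bl = fit_baseline(spectrum, config)
    out = subtract_baseline(spectrum, bl.baseline)
    if config.smooth_before_normalize:
        out = area_normalize(smooth(out, config))
    else:
        out = smooth(area_normalize(out), config)
    return out, bl


def preprocess_set(
    sset: SpectraSet, config: PreprocessConfig = PreprocessConfig()
) -> tuple[SpectraSet, list[BaselineFit]]:
    """Apply the full pipeline to every row independently; order preserved."""
    rows = []
    fits: list[BaselineFit] = []
    for i in range(sset.n_spectra):
        try:
            out, bl = preprocess_spectrum(sset.spectrum(i), config)
        except ValueError as exc:
            raise ValueError(f"preprocessing failed for sample {sset.ids[i]!r}: {exc}") from exc
        rows.append(out.intensities)
        fits.append(bl)
    return (
        SpectraSet(grid=sset.grid, matrix=np.vstack(rows),
                   labels=sset.labels.copy(), ids=sset.ids.copy()),
        fits,
    )
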