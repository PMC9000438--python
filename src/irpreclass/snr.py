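"""First-derivative signal-to-noise annotation statistic.

Signal is the peak-to-peak range of the first derivative in the
polysaccharide-associated region 920–1200 cm⁻¹; Noise is the same
statistic in the band-free region 2000–2100 cm⁻¹, where a tissue
spectrum should be flat and the derivative reflects instrument noise
only.  Their ratio ranks spectra by analyte content: analyte-poor
(water-like) spectra score low.  No SNR cutoff is prescribed —
annotation by SNR is exposed as a ranking, not a classifier.

The derivative estimator is a plain finite difference (central in the
interior, one-sided at the ends, with respect to wavenumber).  It is
isolated in :func:`first_derivative` so a smoothing estimator could be
swapped in without touching the statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation, RangeError, RegionError
from .msc import region_mask
from .spectra import SpectralDataset, Spectrum

__all__ = ["SNRResult", "first_derivative", "snr", "snr_dataset"]

DEFAULT_SIGNAL_REGION = (920.0, 1200.0)
DEFAULT_NOISE_REGION = (2000.0, 2100.0)


@dataclass
class SNRResult:
    """Signal, noise, and their ratio for one spectrum.

    ``ratio`` is NaN when the noise peak-to-peak is exactly zero
    (undefined, not an error); check :attr:`ratio_defined`.
    """

    signal: float
    noise: float
    ratio: float
    signal_region: tuple[float, float]
    noise_region: tuple[float, float]

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.ratio)


def first_derivative(spectrum: Spectrum) -> Spectrum:
    """dA/dν̃ by finite differences; the axis need not be uniform."""
    if len(spectrum) < 3:
        raise ContractViolation(
            f"first derivative needs ≥ 3 channels, got {len(spectrum)}"
        )
    spacings = np.diff(spectrum.wavenumbers)
    h = spacings.mean()
    # uniform axes (the usual FTIR digital grid) take the scalar-spacing
    # path so flat spectra differentiate to exactly zero
    if np.ptp(spacings) <= 1e-9 * h:
        deriv = np.gradient(spectrum.absorbance, h)
    else:
        deriv = np.gradient(spectrum.absorbance, spectrum.wavenumbers)
    return Spectrum(spectrum.wavenumbers.copy(), deriv, spectrum.id)


def _region_ptp(deriv: Spectrum, region: tuple[float, float], name: str) -> float:
    lo, hi = region
    axis = deriv.wavenumbers
    if hi < axis[0] or lo > axis[-1]:
        raise RangeError(
            f"{name} region [{lo:g}, {hi:g}] lies outside the axis "
            f"[{axis[0]:g}, {axis[-1]:g}]"
        )
    mask = region_mask(axis, region)
    n = int(mask.sum())
    if n < 3:
        raise RegionError(f"{name} region [{lo:g}, {hi:g}] selects only {n} channel(s)")
    vals = deriv.absorbance[mask]
    return float(vals.max() - vals.min())


def snr(
    spectrum: Spectrum,
    signal_region: tuple[float, float] = DEFAULT_SIGNAL_REGION,
    noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
) -> SNRResult:
    """Peak-to-peak first-derivative Signal/Noise ratio of one spectrum."""
    deriv = first_derivative(spectrum)
    signal = _region_ptp(deriv, tuple(signal_region), "signal")
    noise = _region_ptp(deriv, tuple(noise_region), "noise")
    ratio = signal / noise if noise > 0 else math.nan
    return SNRResult(
        signal=signal,
        noise=noise,
        ratio=ratio,
        signal_region=tuple(signal_region),
        noise_region=tuple(noise_region),
    )


def snr_dataset(
    dataset: SpectralDataset,
    signal_region: tuple[float, float] = DEFAULT_SIGNAL_REGION,
    noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
) -> pd.DataFrame:
    """SNR statistics for every spectrum; columns id, signal, noise, ratio."""
    rows = []
    for spec in dataset:
        r = snr(spec, signal_region, noise_region)
        rows.append({"id": spec.id, "signal": r.signal, "noise": r.noise, "ratio": r.ratio})
    return pd.DataFrame(rows, columns=["id", "signal", "noise", "ratio"])
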