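"""Synthetic ATR-FTIR spectrum generator with known ground truth.

Generates labelled water-like and cartilage-like absorbance spectra with
exactly the structure the MSC preclassification model assumes: an
additive baseline ``a``, a multiplicative scaling ``b`` of a water
reference, an optional cartilage contribution ``c``, and i.i.d. Gaussian
channel noise:

    water row:      a + b·W(ν̃) + noise
    cartilage row:  a + b·W(ν̃) + c·C(ν̃) + noise

Band shapes are Gaussian.  The water reference W has two broad bands
near 1630 cm⁻¹ (H–O–H bending) and 800 cm⁻¹ (libration) and is flat
elsewhere in the fingerprint region.  The cartilage signature C carries
the lipid C=O (1745), amide I (1620, dominant), amide II (1560),
amide III (1210), carbohydrate C–O (1080) and water-libration (850)
bands.  The default axis is 400–4000 cm⁻¹ at 1.0292 cm⁻¹ digital
spacing, matching a single-reflection diamond ATR FTIR bench.

Every simulation is fully determined by its seed: the returned
:class:`SyntheticTruth` plus the axis regenerate the matrix bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractViolation, RangeError
from .msc import CARTILAGE, WATER
from .spectra import SpectralDataset, Spectrum

__all__ = [
    "BandModel",
    "SimParams",
    "SyntheticTruth",
    "default_axis",
    "water_band_model",
    "cartilage_band_model",
    "make_water_reference",
    "make_cartilage_spectrum",
    "simulate_dataset",
    "regenerate",
]


@dataclass
class BandModel:
    """Sum-of-Gaussians band model: centers (cm⁻¹), σ widths, peak amplitudes."""

    centers: np.ndarray
    widths: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=np.float64)
        w = np.asarray(self.widths, dtype=np.float64)
        a = np.asarray(self.amplitudes, dtype=np.float64)
        if not (c.size == w.size == a.size):
            raise ContractViolation("centers, widths, amplitudes must have equal length")
        if np.any(w <= 0):
            raise ContractViolation("band widths must be > 0")
        if np.any(a < 0):
            raise ContractViolation("band amplitudes must be ≥ 0")
        self.centers, self.widths, self.amplitudes = c, w, a

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis, dtype=np.float64)
        out = np.zeros_like(axis)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            out += a * np.exp(-0.5 * ((axis - c) / w) ** 2)
        return out


def water_band_model() -> BandModel:
    """Two broad water bands: 1630 cm⁻¹ (σ 60, amp 1.0), 800 cm⁻¹ (σ 120, amp 0.6)."""
    return BandModel(centers=[800.0, 1630.0], widths=[120.0, 60.0], amplitudes=[0.6, 1.0])


def cartilage_band_model() -> BandModel:
    """Cartilage signature bands; amide I at 1620 cm⁻¹ dominates."""
    return BandModel(
        centers=[850.0, 1080.0, 1210.0, 1560.0, 1620.0, 1745.0],
        widths=[30.0, 25.0, 30.0, 20.0, 18.0, 15.0],
        amplitudes=[0.30, 0.55, 0.45, 0.70, 1.00, 0.25],
    )


def default_axis(start: float = 400.0, stop: float = 4000.0, spacing: float = 1.0292) -> np.ndarray:
    """Wavenumber axis from ``start`` to ≤ ``stop`` at the given digital spacing."""
    if spacing <= 0:
        raise ContractViolation("spacing must be > 0")
    n = int(np.floor((stop - start) / spacing)) + 1
    return start + spacing * np.arange(n)


def _check_coverage(axis: np.ndarray, what: str) -> np.ndarray:
    axis = np.asarray(axis, dtype=np.float64)
    if axis[0] > 700.0 or axis[-1] < 1900.0:
        raise RangeError(
            f"axis [{axis[0]:g}, {axis[-1]:g}] does not cover 700–1900 cm⁻¹ "
            f"needed for the {what} band model"
        )
    return axis


def make_water_reference(axis, bands: BandModel | None = None) -> Spectrum:
    """Noise-free synthetic pure-water reference spectrum on ``axis``."""
    axis = _check_coverage(axis, "water")
    bands = water_band_model() if bands is None else bands
    return Spectrum(axis, bands.evaluate(axis), "water_reference")


def make_cartilage_spectrum(axis, band_scale=None, bands: BandModel | None = None) -> Spectrum:
    """Noise-free synthetic cartilage signature, optionally scaled per band."""
    axis = _check_coverage(axis, "cartilage")
    bands = cartilage_band_model() if bands is None else bands
    if band_scale is not None:
        scale = np.asarray(band_scale, dtype=np.float64)
        if scale.size != bands.centers.size:
            raise ContractViolation(
                f"band_scale has {scale.size} entries for {bands.centers.size} bands"
            )
        if np.any(scale < 0):
            raise ContractViolation("band_scale entries must be ≥ 0")
        bands = BandModel(bands.centers, bands.widths, bands.amplitudes * scale)
    return Spectrum(axis, bands.evaluate(axis), "cartilage_signature")


@dataclass
class SimParams:
    """Draw ranges for the affine/mixture parameters and the noise level.

    ``a`` additive baseline, ``b`` multiplicative scaling of the water
    reference, ``c`` cartilage fraction (cartilage rows only),
    ``sigma_noise`` i.i.d. Gaussian channel noise σ (absorbance units).
    """

    a_range: tuple[float, float] = (-0.05, 0.05)
    b_range: tuple[float, float] = (0.8, 1.2)
    c_range: tuple[float, float] = (0.3, 1.0)
    sigma_noise: float = 0.005


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a simulated dataset bitwise.

    ``table`` holds one row per spectrum: id, label, and the drawn
    (a, b, c) — c is 0.0 for water rows.
    """

    table: pd.DataFrame
    params: SimParams = field(default_factory=SimParams)
    seed: int = 0
    n_water: int = 0
    n_cartilage: int = 0


def simulate_dataset(
    axis,
    n_water: int,
    n_cartilage: int,
    params: SimParams | None = None,
    seed: int = 0,
) -> tuple[SpectralDataset, SyntheticTruth]:
    """Simulate a labelled two-class dataset on ``axis``.

    Water rows come first, then cartilage rows; ids encode the truth
    (``water_0007``, ``cartilage_0003``).  All randomness flows through
    one ``numpy.random.default_rng(seed)``, so the same seed reproduces
    the matrix bitwise.
    """
    params = SimParams() if params is None else params
    if n_water < 0 or n_cartilage < 0:
        raise ContractViolation("spectrum counts must be ≥ 0")
    if params.sigma_noise < 0:
        raise ContractViolation(f"sigma_noise must be ≥ 0, got {params.sigma_noise}")
    axis = np.asarray(axis, dtype=np.float64)
    water = make_water_reference(axis).absorbance
    cart = make_cartilage_spectrum(axis).absorbance
    n = n_water + n_cartilage
    rng = np.random.default_rng(seed)
    a = rng.uniform(*params.a_range, n)
    b = rng.uniform(*params.b_range, n)
    c = rng.uniform(*params.c_range, n)
    c_eff = c.copy()
    c_eff[:n_water] = 0.0
    noise = rng.normal(0.0, params.sigma_noise, (n, axis.size)) if n else np.zeros((0, axis.size))
    matrix = a[:, None] + b[:, None] * water[None, :] + c_eff[:, None] * cart[None, :] + noise
    labels = [WATER] * n_water + [CARTILAGE] * n_cartilage
    ids = [f"water_{i:04d}" for i in range(n_water)] + [
        f"cartilage_{i:04d}" for i in range(n_cartilage)
    ]
    table = pd.DataFrame(
        {"id": ids, "label": labels, "a": a, "b": b, "c": c_eff}
    )
    dataset = SpectralDataset(axis, matrix, ids)
    truth = SyntheticTruth(
        table=table, params=params, seed=seed, n_water=n_water, n_cartilage=n_cartilage
    )
    return dataset, truth


def regenerate(axis, truth: SyntheticTruth) -> SpectralDataset:
    """Re-run the simulation recorded in ``truth``; bitwise identical output."""
    dataset, _ = simulate_dataset(
        axis, truth.n_water, truth.n_cartilage, truth.params, truth.seed
    )
    return dataset
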