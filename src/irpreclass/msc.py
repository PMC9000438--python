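"""Multiplicative signal correction (MSC) fit and residual-RMSE preclassification.

Each measured spectrum Z(ν̃) is modelled around a reference spectrum
Z_ref(ν̃) — for preclassification, a pure water spectrum — as

    Z(ν̃) = a + b · Z_ref(ν̃) + ε(ν̃)

where ``a`` absorbs additive baseline variation, ``b`` multiplicative
scaling (path-length / contact effects), and ε is the residual.  The
parameters (a, b) are the ordinary-least-squares solution over a chosen
fit region; the dissimilarity of Z to the reference is summarised by

    RMSE(ε) = sqrt( (1/n) Σᵢ εᵢ² )

with n the number of channels in the region.  A spectrum is labelled
*water* (analyte-poor) when RMSE(ε) ≤ θ and *cartilage* (analyte-rich)
when RMSE(ε) > θ, for a user-supplied, dataset-dependent threshold θ.
MSC is used here purely as a similarity gauge: the scatter-corrected
spectra (Z − a)/b are deliberately not produced.

The solver is the closed-form 2×2 normal-equations solution with the
reference mean-centred internally for conditioning; parameters are
mapped back to the (a, b) parameterisation above.  Extending the model
with polynomial wavenumber terms (EMSC) is intentionally out of scope:
on seven-channel sparse data the extra degrees of freedom are not
affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    ContractViolation,
    RankDeficiencyError,
    RegionError,
)
from .spectra import SpectralDataset, Spectrum

__all__ = [
    "WATER",
    "CARTILAGE",
    "MSCFit",
    "PreclassResult",
    "fit_msc",
    "rmse_of",
    "classify",
    "preclassify_dataset",
    "separation_midpoint",
]

WATER = "water"
CARTILAGE = "cartilage"

#: Fit region shown throughout the broadband figures; the CLI default.
DEFAULT_FIT_REGION = (800.0, 1900.0)

Region = tuple[float, float]


def normalize_region(region) -> list[Region]:
    """Normalise a region argument to a list of (lo, hi) intervals.

    Accepts a single ``(lo, hi)`` pair, an iterable of pairs, or ``None``
    meaning the full axis.
    """
    if region is None:
        return []
    region = list(region)
    if len(region) == 2 and all(np.isscalar(x) for x in region):
        region = [tuple(region)]
    out = []
    for lo, hi in region:
        lo, hi = float(lo), float(hi)
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
            raise ContractViolation(f"invalid region interval ({lo}, {hi})")
        out.append((lo, hi))
    return out


def region_mask(axis: np.ndarray, region) -> np.ndarray:
    """Boolean mask of axis channels inside the region (endpoints inclusive)."""
    intervals = normalize_region(region)
    if not intervals:
        return np.ones(axis.shape, dtype=bool)
    mask = np.zeros(axis.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (axis >= lo) & (axis <= hi)
    return mask


@dataclass
class MSCFit:
    """Least-squares fit of one spectrum to the reference.

    Attributes
    ----------
    a, b : float
        Additive baseline (absorbance units) and multiplicative scaling
        (unitless) parameters.
    residual : ndarray
        ε over the fit region, in axis order (absorbance units).
    rmse : float
        sqrt(mean(ε²)) over the fit region.
    region : list of (lo, hi)
        Wavenumber interval(s) used; empty list means the full axis.
    n_channels : int
        Number of channels entering the fit (the n of the RMSE).
    """

    a: float
    b: float
    residual: np.ndarray
    rmse: float
    region: list[Region]
    n_channels: int


@dataclass
class PreclassResult:
    """Per-spectrum preclassification outcome."""

    id: str
    fit: MSCFit
    threshold: float
    label: str


def fit_msc(spectrum: Spectrum, reference: Spectrum, region=None) -> MSCFit:
    """Fit Z = a + b·Z_ref + ε by ordinary least squares over ``region``.

    ``spectrum`` and ``reference`` must share the same axis (resample the
    reference first if needed); the region must select at least three
    channels and the reference must not be constant over it.
    """
    if not np.array_equal(spectrum.wavenumbers, reference.wavenumbers):
        raise ContractViolation(
            "spectrum and reference are on different axes; "
            "resample the reference onto the spectrum axis first"
        )
    mask = region_mask(spectrum.wavenumbers, region)
    n = int(mask.sum())
    if n < 3:
        raise RegionError(
            f"fit region selects only {n} channel(s); at least 3 are required"
        )
    z = spectrum.absorbance[mask]
    ref = reference.absorbance[mask]
    ref_mean = ref.mean()
    refc = ref - ref_mean
    sxx = float(refc @ refc)
    scale = max(1.0, float(np.max(np.abs(ref))))
    if sxx <= (1e-14 * scale) ** 2 * n:
        raise RankDeficiencyError(
            "reference spectrum is constant over the fit region; "
            "the MSC design matrix is rank deficient"
        )
    b = float(refc @ z) / sxx
    a = float(z.mean()) - b * ref_mean
    residual = z - a - b * ref
    return MSCFit(
        a=a,
        b=b,
        residual=residual,
        rmse=rmse_of(residual),
        region=normalize_region(region),
        n_channels=n,
    )


def rmse_of(residual: np.ndarray) -> float:
    """Root mean squared error sqrt(Σ εᵢ² / n) of a residual vector."""
    eps = np.asarray(residual, dtype=np.float64)
    if eps.size == 0:
        raise ContractViolation("RMSE of an empty residual is undefined")
    if not np.all(np.isfinite(eps)):
        raise ContractViolation("residual contains non-finite values")
    return float(np.sqrt(np.mean(eps * eps)))


def classify(rmse: float, threshold: float) -> str:
    """Label a spectrum water (RMSE ≤ θ, boundary inclusive) or cartilage."""
    if not (math.isfinite(threshold) and threshold > 0):
        raise ContractViolation(f"threshold θ must be finite and > 0, got {threshold}")
    if not math.isfinite(rmse) or rmse < 0:
        raise ContractViolation(f"rmse must be finite and ≥ 0, got {rmse}")
    return WATER if rmse <= threshold else CARTILAGE


def preclassify_dataset(
    dataset: SpectralDataset,
    reference: Spectrum,
    threshold: float,
    region=None,
) -> list[PreclassResult]:
    """Fit and classify every spectrum in a dataset, preserving row order.

    The reference must already be on the dataset axis.  Fully
    deterministic; errors from individual fits carry the spectrum id.
    """
    if not np.array_equal(dataset.axis, reference.wavenumbers):
        raise ContractViolation(
            "reference is not on the dataset axis; resample it first"
        )
    results: list[PreclassResult] = []
    for spec in dataset:
        try:
            fit = fit_msc(spec, reference, region)
        except (ContractViolation, RegionError, RankDeficiencyError) as e:
            raise type(e)(f"spectrum {spec.id!r}: {e}") from e
        results.append(
            PreclassResult(
                id=spec.id,
                fit=fit,
                threshold=float(threshold),
                label=classify(fit.rmse, threshold),
            )
        )
    return results


def separation_midpoint(
    water_rmse: np.ndarray, analyte_rmse: np.ndarray, method: str = "gap"
) -> float:
    """Threshold θ halfway between two labelled RMSE clusters.

    ``method="gap"`` (default) returns the midpoint of the separation gap,
    (max water RMSE + min analyte RMSE)/2, which yields zero
    misclassifications whenever the two distributions are disjoint.
    ``method="means"`` returns the midpoint of the cluster means.
    """
    w = np.asarray(water_rmse, dtype=np.float64)
    c = np.asarray(analyte_rmse, dtype=np.float64)
    if w.size == 0 or c.size == 0:
        raise ContractViolation("both clusters must be non-empty")
    if method == "gap":
        return float((w.max() + c.min()) / 2.0)
    if method == "means":
        return float((w.mean() + c.mean()) / 2.0)
    raise ValueError(f"unknown method {method!r}")
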