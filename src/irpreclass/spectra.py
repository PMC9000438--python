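"""Core in-memory containers for absorbance spectra.

A :class:`Spectrum` is one absorbance trace on a wavenumber axis (cm⁻¹);
a :class:`SpectralDataset` is a collection of spectra sharing one axis.
The canonical internal axis order is strictly ascending wavenumber.
Files with descending axes (the conventional IR display order) are
reversed on ingestion; computation never depends on display order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AxisError, ContractViolation, RangeError, ShapeError

__all__ = ["Spectrum", "SpectralDataset", "resample_to_axis"]


def _canonical_axis(wavenumbers: np.ndarray) -> tuple[np.ndarray, bool]:
    """Validate a wavenumber axis and report whether it must be reversed."""
    wn = np.asarray(wavenumbers, dtype=np.float64)
    if wn.ndim != 1:
        raise ShapeError(f"wavenumber axis must be 1-D, got shape {wn.shape}")
    if wn.size == 0:
        raise AxisError("wavenumber axis is empty")
    if not np.all(np.isfinite(wn)):
        raise AxisError("wavenumber axis contains non-finite values")
    if np.any(wn <= 0):
        raise AxisError("wavenumbers must be strictly positive (cm⁻¹)")
    d = np.diff(wn)
    if np.all(d > 0):
        return wn, False
    if np.all(d < 0):
        return wn[::-1].copy(), True
    if np.any(d == 0):
        dup = wn[:-1][d == 0][0]
        raise AxisError(f"duplicated wavenumber {dup:g} cm⁻¹ on axis")
    raise AxisError("wavenumber axis is not monotonic")


def _check_absorbance(values: np.ndarray, where: str) -> np.ndarray:
    a = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise AxisError(f"non-finite absorbance value in {where}")
    return a


@dataclass
class Spectrum:
    """One absorbance trace on a strictly ascending wavenumber axis."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        wn, reversed_ = _canonical_axis(self.wavenumbers)
        ab = _check_absorbance(self.absorbance, f"spectrum {self.id!r}")
        if ab.ndim != 1 or ab.size != wn.size:
            raise ShapeError(
                f"spectrum {self.id!r}: absorbance shape {ab.shape} does not "
                f"match axis length {wn.size}"
            )
        if reversed_:
            ab = ab[::-1].copy()
        self.wavenumbers = wn
        self.absorbance = ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, values: np.ndarray, id: str | None = None) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), values, self.id if id is None else id)


@dataclass
class SpectralDataset:
    """n_spectra × n_channels absorbance matrix on one shared axis."""

    axis: np.ndarray
    matrix: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        wn, reversed_ = _canonical_axis(self.axis)
        m = _check_absorbance(self.matrix, "dataset matrix")
        if m.ndim != 2:
            raise ShapeError(f"dataset matrix must be 2-D, got shape {m.shape}")
        if m.shape[1] != wn.size:
            raise ShapeError(
                f"matrix has {m.shape[1]} channels but axis has {wn.size}"
            )
        if reversed_:
            m = m[:, ::-1].copy()
        ids = [str(i) for i in self.ids]
        if len(ids) != m.shape[0]:
            raise ShapeError(
                f"{len(ids)} ids for {m.shape[0]} spectra"
            )
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ContractViolation(f"duplicate spectrum id {dup!r} in dataset")
        self.axis = wn
        self.matrix = m
        self.ids = ids

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def spectrum(self, index: int) -> Spectrum:
        return Spectrum(self.axis.copy(), self.matrix[index].copy(), self.ids[index])

    def __iter__(self):
        for i in range(len(self)):
            yield self.spectrum(i)


def resample_to_axis(spectrum: Spectrum, target_axis: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_axis``.

    Every target wavenumber must lie within the source axis range — no
    extrapolation is performed.  Targets that coincide with a source
    channel pass through exactly.
    """
    target, _ = _canonical_axis(np.atleast_1d(np.asarray(target_axis, dtype=np.float64)))
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    if target[0] < lo or target[-1] > hi:
        bad = target[0] if target[0] < lo else target[-1]
        raise RangeError(
            f"target wavenumber {bad:g} cm⁻¹ outside source range [{lo:g}, {hi:g}]"
        )
    values = np.interp(target, spectrum.wavenumbers, spectrum.absorbance)
    return Spectrum(target, values, spectrum.id)
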