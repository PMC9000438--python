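"""Sparse channel selection emulating fixed-wavelength QCL acquisition.

A fixed-wavelength quantum-cascade-laser probe measures absorbance at a
handful of discrete emission lines instead of a broadband axis.  This
module subsets broadband spectra to such a sparse set of target
wavenumbers.  The default seven channels cover the diagnostically
relevant cartilage bands — water libration (850), carbohydrate C–O
(1080), amide III (1210), amide II (1560), amide I (1620), lipid C=O
(1745) — plus a baseline point at 1800 cm⁻¹ where tissue and water are
nearly transparent.

The default matching rule picks the nearest axis channel within a
tolerance (QCL hardware emits at fixed lines, so no interpolation);
ties break toward the lower wavenumber for determinism.  Interpolated
picking is available behind ``mode="interpolate"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ChannelCollisionError, ContractViolation, RangeError, UnmatchedTargetError
from .spectra import SpectralDataset

__all__ = ["ChannelSelection", "default_qcl_channels", "select_channels"]

#: The seven fixed QCL emission wavenumbers (cm⁻¹), ascending.
DEFAULT_QCL_WAVENUMBERS = (850.0, 1080.0, 1210.0, 1560.0, 1620.0, 1745.0, 1800.0)


def default_qcl_channels() -> np.ndarray:
    """Return the seven default QCL target wavenumbers, ascending (cm⁻¹)."""
    return np.array(DEFAULT_QCL_WAVENUMBERS)


@dataclass
class ChannelSelection:
    """Record of a sparse channel selection.

    ``matched[k]`` is the axis wavenumber chosen for ``targets[k]``;
    ``indices`` are the positions in the source axis (strictly
    increasing, no repeats); ``tolerance`` bounds |target − matched|.
    """

    targets: np.ndarray
    matched: np.ndarray
    indices: np.ndarray
    tolerance: float


def _nearest_index(axis: np.ndarray, target: float) -> int:
    # tie between two equidistant neighbours breaks toward lower wavenumber
    j = int(np.searchsorted(axis, target))
    if j == 0:
        return 0
    if j == axis.size:
        return axis.size - 1
    below, above = axis[j - 1], axis[j]
    return j - 1 if target - below <= above - target else j


def select_channels(
    dataset: SpectralDataset,
    targets=None,
    tolerance: float | None = None,
    mode: str = "nearest",
) -> tuple[SpectralDataset, ChannelSelection]:
    """Subset a dataset to sparse target wavenumbers.

    Parameters
    ----------
    targets : array-like of cm⁻¹, optional
        Requested wavenumbers (default: the seven QCL lines).  Sorted
        ascending internally.
    tolerance : float, optional
        Maximum |target − matched| in cm⁻¹.  Defaults to one axis
        spacing (the largest spacing on a non-uniform axis).
    mode : {"nearest", "interpolate"}
        Nearest-channel pick (default) or linear interpolation at the
        exact target wavenumbers.
    """
    if mode not in ("nearest", "interpolate"):
        raise ValueError(f"mode must be 'nearest' or 'interpolate', got {mode!r}")
    targets = (
        default_qcl_channels()
        if targets is None
        else np.sort(np.asarray(targets, dtype=np.float64))
    )
    if targets.size == 0:
        raise ContractViolation("at least one target wavenumber is required")
    axis = dataset.axis
    if tolerance is None:
        tolerance = float(np.max(np.diff(axis))) if axis.size > 1 else 0.0
    if tolerance < 0:
        raise ContractViolation(f"tolerance must be ≥ 0, got {tolerance}")

    lo, hi = axis[0], axis[-1]
    indices = []
    for t in targets:
        if t < lo or t > hi:
            raise RangeError(
                f"target {t:g} cm⁻¹ outside dataset axis range [{lo:g}, {hi:g}]"
            )
        j = _nearest_index(axis, t)
        if abs(axis[j] - t) > tolerance:
            raise UnmatchedTargetError(
                f"no axis channel within {tolerance:g} cm⁻¹ of target {t:g} "
                f"(nearest is {axis[j]:g})"
            )
        indices.append(j)
    for k in range(1, len(indices)):
        if indices[k] == indices[k - 1]:
            raise ChannelCollisionError(
                f"targets {targets[k - 1]:g} and {targets[k]:g} both map to "
                f"axis channel {axis[indices[k]]:g}"
            )
    indices = np.array(indices, dtype=np.intp)
    matched = axis[indices]

    if mode == "nearest":
        sub_axis = matched.copy()
        sub_matrix = dataset.matrix[:, indices].copy()
    else:
        sub_axis = targets.copy()
        sub_matrix = np.vstack([np.interp(targets, axis, row) for row in dataset.matrix])
    subset = SpectralDataset(sub_axis, sub_matrix, list(dataset.ids))
    selection = ChannelSelection(
        targets=targets, matched=matched, indices=indices, tolerance=float(tolerance)
    )
    return subset, selection
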