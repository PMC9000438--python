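"""PCA score computation for visual annotation, plus an advisory θ suggester.

Scores are computed on raw spectra — no derivative, no normalisation, no
scaling.  Mean-centring is intrinsic to PCA and is the only operation
applied; the subtracted mean spectrum is returned so the choice is
auditable.  Score plots of the first two components typically separate
water-like from cartilage-like clusters and are used to sanity-check the
RMSE threshold, not to classify automatically.

`suggest_threshold` is an extension beyond the core method: an Otsu
between-class-variance split of the RMSE values, offered as an advisory
starting point for the dataset-dependent threshold θ, never applied
silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import ContractViolation
from .msc import region_mask
from .spectra import SpectralDataset

__all__ = ["PCAScores", "ThresholdSuggestion", "pca_scores", "suggest_threshold"]


@dataclass
class PCAScores:
    """Scores and bookkeeping of a PCA decomposition.

    ``scores`` is n_spectra × k; ``explained_variance_fraction`` per
    component (zeros when the data have no variance at all);
    ``centering`` is the subtracted mean spectrum over the channels
    used; ``loadings`` is k × n_channels_used.  The sign convention is
    deterministic: the largest-magnitude loading of each component is
    positive.
    """

    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    centering: np.ndarray
    loadings: np.ndarray


def pca_scores(dataset: SpectralDataset, k: int = 2, region=None) -> PCAScores:
    """First-``k`` principal-component scores of mean-centred raw spectra.

    ``region`` restricts the channels entering the decomposition
    (default: full axis).  Requires n_spectra ≥ 2 and
    1 ≤ k ≤ min(n_spectra − 1, n_channels).
    """
    n = len(dataset)
    if n < 2:
        raise ContractViolation(f"PCA needs at least 2 spectra, got {n}")
    mask = region_mask(dataset.axis, region)
    x = dataset.matrix[:, mask]
    p = x.shape[1]
    if not (1 <= k <= min(n - 1, p)):
        raise ContractViolation(
            f"k={k} out of range 1..min(n_spectra−1, n_channels)={min(n - 1, p)}"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.copy()
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    centered = x - pca.mean_
    total_var = float((centered**2).sum()) / max(n - 1, 1)
    if total_var > 0:
        # clip ulp-level overshoot so each fraction stays within [0, 1]
        evf = np.clip(pca.explained_variance_ / total_var, 0.0, 1.0)
    else:
        evf = np.zeros(k)
    return PCAScores(
        scores=scores,
        explained_variance_fraction=np.asarray(evf),
        centering=pca.mean_.copy(),
        loadings=loadings,
    )


@dataclass
class ThresholdSuggestion:
    """Advisory Otsu split of an RMSE distribution (never auto-applied)."""

    threshold: float
    counts: np.ndarray
    bin_edges: np.ndarray
    note: str


def suggest_threshold(rmse_values, bins: int = 64) -> ThresholdSuggestion:
    """Suggest a θ by Otsu's between-class-variance-maximising split.

    Purely advisory: the operative threshold remains a user decision
    (it is dataset dependent).  With ≥ 4 values required; if all values
    are identical there is nothing to split and the common value is
    returned with a warning note.
    """
    vals = np.asarray(rmse_values, dtype=np.float64)
    if vals.size < 4:
        raise ContractViolation(f"need ≥ 4 RMSE values, got {vals.size}")
    if not np.all(np.isfinite(vals)):
        raise ContractViolation("RMSE values must be finite")
    counts, edges = np.histogram(vals, bins=bins)
    if np.ptp(vals) == 0:
        return ThresholdSuggestion(
            threshold=float(vals[0]),
            counts=counts,
            bin_edges=edges,
            note="all RMSE values identical; no split exists (advisory)",
        )
    # exact Otsu on the values themselves (no histogram binning): maximise
    # w0·w1·(μ0 − μ1)² over every split of the sorted values; the threshold
    # is placed midway between the two values straddling the best split
    v = np.sort(vals)
    n = v.size
    cum = np.cumsum(v)
    i = np.arange(1, n)
    w0 = i / n
    m0 = cum[:-1] / i
    m1 = (cum[-1] - cum[:-1]) / (n - i)
    between = w0 * (1.0 - w0) * (m0 - m1) ** 2
    k = int(np.argmax(between))
    thr = float((v[k] + v[k + 1]) / 2.0)
    return ThresholdSuggestion(
        threshold=thr,
        counts=counts,
        bin_edges=edges,
        note="advisory Otsu suggestion; θ is dataset dependent — inspect before use",
    )
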