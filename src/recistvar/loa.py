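"""Root transforms and Bland-Altman limits of agreement (LOA).

Lesion-diameter measurement error grows with lesion size, so raw-scale LOAs
fit the data poorly.  Computing the difference on an nth-root scale and
back-transforming the limits at a given mean produces size-dependent
("fan-shaped") limits on the millimetre scale.  The square root (n=2) is the
transform used throughout the rest of the package; identity, cube root and
log are available for the exploratory comparison of candidate transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_ALLOWED_ROOTS = (1, 2, 3)
Z_LOA = 1.96  # conventional limits-of-agreement multiplier


class InsufficientDataError(ValueError):
    """Not enough measurement pairs to form limits of agreement."""


@dataclass(frozen=True)
class LoaResult:
    """Limits of agreement on a transformed scale.

    ``loa_trans = (mean_diff - 1.96*sd, mean_diff + 1.96*sd)`` with the SD of
    the pairwise differences (denominator n-1).  ``log_scale`` marks results
    computed on the natural-log scale instead of an nth root.
    """

    n_root: int
    mean_diff_trans: float
    sd_diff_trans: float
    loa_trans: tuple[float, float]
    n_pairs: int = 0
    log_scale: bool = False


def transform(value: float, n_root: int) -> float:
    """nth-root transform of a non-negative measurement (1=identity, 2=sqrt, 3=cbrt)."""
    if n_root not in _ALLOWED_ROOTS:
        raise ValueError(f"n_root must be one of {_ALLOWED_ROOTS}, got {n_root}")
    if np.any(np.asarray(value) < 0):
        raise ValueError("transform requires non-negative input")
    if n_root == 1:
        return value
    return np.asarray(value) ** (1.0 / n_root) if np.ndim(value) else float(value) ** (1.0 / n_root)


def bland_altman(pairs: Sequence[tuple[float, float]], n_root: int = 2, log: bool = False) -> LoaResult:
    """Limits of agreement for measurement pairs on a root (or log) scale.

    Differences are taken after transforming each measurement; the limits are
    mean difference +/- 1.96 SD.  With ``n_root=1`` this is the classical
    Bland-Altman computation on raw values.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (first, second) measurements")
    if len(arr) < 3:
        raise InsufficientDataError(f"need at least 3 measurement pairs, got {len(arr)}")
    if np.any(arr <= 0):
        raise ValueError("measurements must be positive")
    if log:
        t = np.log(arr)
    else:
        if n_root not in _ALLOWED_ROOTS:
            raise ValueError(f"n_root must be one of {_ALLOWED_ROOTS}, got {n_root}")
        t = arr ** (1.0 / n_root)
    diffs = t[:, 0] - t[:, 1]
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return LoaResult(
        n_root=n_root,
        mean_diff_trans=mean,
        sd_diff_trans=sd,
        loa_trans=(mean - Z_LOA * sd, mean + Z_LOA * sd),
        n_pairs=len(arr),
        log_scale=log,
    )


def _back_transform_limit(mean_value: float, limit: float, n_root: int) -> float:
    """Original-scale difference corresponding to a transformed-scale limit.

    Assumes the two transformed measurements straddle ``mean_value**(1/n)``
    symmetrically, giving the exact difference-of-powers identity
    ``(m^(1/n) + L/2)^n - (m^(1/n) - L/2)^n``.  For n=2 this collapses to
    ``2*sqrt(m)*L``; for n=1 it is L itself.
    """
    if n_root == 1:
        return limit
    a = mean_value ** (1.0 / n_root)
    lo = a - limit / 2.0
    if lo < 0:
        warnings.warn(
            f"back-transform at mean {mean_value} with limit {limit}: inner term "
            "negative, clamped at 0 (limit wider than the mean allows)",
            RuntimeWarning,
            stacklevel=3,
        )
        lo = 0.0
    return (a + limit / 2.0) ** n_root - lo ** n_root


def loa_original_scale(
    mean_value: float, loa_trans: tuple[float, float], n_root: int
) -> tuple[float, float]:
    """Back-transform both LOA limits to original-scale differences at a given mean."""
    if not mean_value > 0:
        raise ValueError("mean_value must be > 0")
    if n_root not in _ALLOWED_ROOTS:
        raise ValueError(f"n_root must be one of {_ALLOWED_ROOTS}, got {n_root}")
    return (
        _back_transform_limit(mean_value, loa_trans[0], n_root),
        _back_transform_limit(mean_value, loa_trans[1], n_root),
    )


def plot_bland_altman(pairs, results: Sequence[LoaResult], path=None, ax=None):
    """Bland-Altman panel: raw-scale differences vs means, with back-transformed
    LOA curves overlaid for each candidate transform (one line style each)."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=12, color="0.3", alpha=0.6)
    grid = np.linspace(max(means.min(), 1e-6), means.max(), 200)
    styles = {1: ":", 2: "--", 3: "-.", "log": "-"}
    for res in results:
        key = "log" if res.log_scale else res.n_root
        label = "log" if res.log_scale else f"n={res.n_root}"
        if res.log_scale:
            # symmetric straddle on the log scale: diff = m*(e^{L/2} - e^{-L/2})
            lo = grid * (np.exp(res.loa_trans[0] / 2) - np.exp(-res.loa_trans[0] / 2))
            hi = grid * (np.exp(res.loa_trans[1] / 2) - np.exp(-res.loa_trans[1] / 2))
        else:
            lims = np.array([loa_original_scale(m, res.loa_trans, res.n_root) for m in grid])
            lo, hi = lims[:, 0], lims[:, 1]
        ax.plot(grid, lo, styles.get(key, "-"), lw=1, label=f"LOA {label}")
        ax.plot(grid, hi, styles.get(key, "-"), lw=1)
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("mean of measurements (mm)")
    ax.set_ylabel("difference (mm)")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
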