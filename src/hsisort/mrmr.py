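"""Minimum-redundancy maximum-relevance (mRMR) wavelength selection.

Candidate wavelengths from the full 261-band set Ω are ranked by the
mutual information quotient

    MIQ(λ) = V(λ) / W(λ)

where relevance V(λ) = I(λ; y) measures dependence between a band and the
product class y (legume vs. contaminant) and redundancy
W(λ) = (1/|S|) Σ_{z∈S} I(λ; z) is the mean dependence on the bands already
selected.  A forward-addition scheme grows the selected set S from Ω: the
first pick maximises relevance alone, each later pick maximises MIQ over
the complement Sc = Ω − S, and after every addition a wrapper classifier
is trained on S and scored on held-out data.  Selection stops once the
wrapper's correct-classification rate reaches the target (the working
criterion is a rate above 99%), the size cap is hit, or Ω is exhausted.

Mutual information is the plug-in estimate on discretised reflectances
(equal-frequency binning by default), in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .containers import SpectrumTable

#: Guard for the MIQ division, Eq. undefined at W = 0.
MIQ_EPS = 1e-12


@dataclass
class DiscretizedTable:
    """Integer-coded reflectances over which mutual information is computed."""

    codes: np.ndarray      # n_objects x n_bands, ints in [0, n_bins)
    n_bins: int
    binning: str
    labels: np.ndarray     # integer class codes
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.min() < 0 or self.codes.max() >= self.n_bins:
            raise ValueError("codes out of [0, n_bins) range")
        if self.codes.shape[0] != self.labels.size:
            raise ValueError("row count mismatch between codes and labels")


@dataclass
class SelectionResult:
    """Ordered selected set S with per-step scores and the stopping trace."""

    selected: List[float]
    scores: List[Tuple[float, float, float, float]]  # (λ, V, W, MIQ) per step
    stop_reason: str       # target_reached | max_size | exhausted
    target_ccr: float
    trace: List[float] = field(default_factory=list)  # validation CCR per step


def discretize(
    table: SpectrumTable,
    n_bins: int = 8,
    binning: str = "equal_frequency",
) -> DiscretizedTable:
    """Bin each band's reflectances into integer codes.

    Equal-frequency binning uses per-band empirical quantiles (robust to
    scale and heavy tails); equal-width splits each band's observed range
    uniformly.
    """
    x = table.spectra
    if binning == "equal_frequency":
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.quantile(x, qs, axis=0)  # (n_bins-1, n_bands)
        codes = np.empty_like(x, dtype=np.int64)
        for j in range(x.shape[1]):
            codes[:, j] = np.searchsorted(edges[:, j], x[:, j], side="right")
    elif binning == "equal_width":
        lo = x.min(axis=0)
        span = np.where(np.ptp(x, axis=0) > 0, np.ptp(x, axis=0), 1.0)
        codes = np.minimum((n_bins * (x - lo) / span).astype(np.int64), n_bins - 1)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    y = np.asarray(table.binary_labels())
    _, y_codes = np.unique(y, return_inverse=True)
    return DiscretizedTable(
        codes=codes,
        n_bins=n_bins,
        binning=binning,
        labels=y_codes,
        wavelengths=table.wavelengths.copy(),
    )


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information of two integer code vectors, in bits."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def relevance(band_codes: np.ndarray, y: np.ndarray) -> float:
    """V(λ) = I(λ; y): dependence of a band on the product class."""
    return mutual_information(band_codes, y)


def redundancy(band_codes: np.ndarray, selected_codes: Sequence[np.ndarray]) -> float:
    """W(λ) = mean over z in S of I(λ; z); S must be non-empty."""
    if len(selected_codes) == 0:
        raise ValueError("redundancy is undefined for an empty selected set")
    return float(
        np.mean([mutual_information(band_codes, z) for z in selected_codes])
    )


def miq(v: float, w: float) -> float:
    """Mutual information quotient V/W with a division guard at W = 0."""
    if v < 0 or w < 0:
        raise ValueError("relevance and redundancy must be non-negative")
    return v / max(w, MIQ_EPS)


WrapperFn = Callable[[SpectrumTable, List[float]], float]


def forward_select(
    table: SpectrumTable,
    wrapper: WrapperFn,
    target_ccr: float = 99.0,
    max_size: int = 10,
    n_bins: int = 8,
    binning: str = "equal_frequency",
    rng_seed: int = 0,
    candidate_wavelengths: Optional[Sequence[float]] = None,
) -> SelectionResult:
    """Greedy mRMR forward selection with a wrapper stopping rule.

    ``wrapper(table, selected_wavelengths)`` must train a classifier on the
    current selection and return a held-out correct-classification rate in
    percent.  Ties in the per-step argmax are broken toward the lower
    wavelength, making the procedure fully deterministic.  ``rng_seed`` is
    accepted for interface uniformity; the selection itself is
    deterministic given the table and the wrapper.
    """
    if not (50.0 < target_ccr <= 100.0):
        raise ValueError("target_ccr must be in (50, 100]")
    disc = discretize(table, n_bins=n_bins, binning=binning)
    if candidate_wavelengths is None:
        cand_idx = np.arange(disc.wavelengths.size)
    else:
        cand_idx = np.array([table.band_index(w) for w in candidate_wavelengths])
    if max_size > cand_idx.size:
        max_size = cand_idx.size

    v = np.array([relevance(disc.codes[:, j], disc.labels) for j in cand_idx])
    red_sum = np.zeros(cand_idx.size)  # running Σ_{z∈S} I(λ, z) per candidate
    available = np.ones(cand_idx.size, dtype=bool)

    selected: List[float] = []
    selected_idx: List[int] = []
    scores: List[Tuple[float, float, float, float]] = []
    trace: List[float] = []
    stop_reason = "exhausted"

    while available.any() and len(selected) < max_size:
        if not selected:
            w_arr = np.zeros(cand_idx.size)
            crit = v.copy()
        else:
            w_arr = red_sum / len(selected)
            crit = v / np.maximum(w_arr, MIQ_EPS)
        crit_masked = np.where(available, crit, -np.inf)
        best = crit_masked.max()
        # tie-break: lowest wavelength among the maximisers
        tied = np.flatnonzero(np.isclose(crit_masked, best, rtol=0, atol=1e-12))
        pick = tied[np.argmin(disc.wavelengths[cand_idx[tied]])]
        lam = float(disc.wavelengths[cand_idx[pick]])
        selected.append(lam)
        selected_idx.append(int(cand_idx[pick]))
        scores.append((lam, float(v[pick]), float(w_arr[pick]),
                       float(miq(v[pick], w_arr[pick]))))
        available[pick] = False
        # update running redundancy sums against the newly selected band
        new_codes = disc.codes[:, cand_idx[pick]]
        for j in np.flatnonzero(available):
            red_sum[j] += mutual_information(disc.codes[:, cand_idx[j]], new_codes)

        try:
            ccr = float(wrapper(table, list(selected)))
        except Exception as exc:
            raise RuntimeError(
                f"wrapper failed at step {len(selected)} with S={selected}"
            ) from exc
        trace.append(ccr)
        if ccr >= target_ccr:
            stop_reason = "target_reached"
            break
    else:
        if len(selected) == max_size and available.any():
            stop_reason = "max_size"

    return SelectionResult(
        selected=selected,
        scores=scores,
        stop_reason=stop_reason,
        target_ccr=target_ccr,
        trace=trace,
    )
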