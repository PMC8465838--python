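"""Transfer entropy on binary rasters, split into local E/I components.

For binary processes X (target) and Y (source), transfer entropy is the
plug-in estimate of

    TE_{Y->X} = sum P(x_n, x_past, y_past)
                log2 [ P(x_n | x_past, y_past) / P(x_n | x_past) ]

with Markov embeddings x_past = [x_{n-1}, ..., x_{n-k_x}] and
y_past = [y_{n-d}, ..., y_{n-d-k_y+1}].  A bin delay d = 0 includes the
same-bin source value, which matters when the imaging bin is longer than
the excitatory synaptic time constant.

The local split routes each summand by comparing the target's current state
with the source embedding's *activity* (active iff any entry is 1): matching
states accumulate into the excitatory component, opposing states into the
inhibitory component.  Silent-source states are routed by the same rule:
{source inactive, target silent} is a hidden excitatory signature and
{source inactive, target active} a hidden inhibitory one.  The two subsets
partition all states, so TE_E + TE_I equals the total exactly.

Estimation can be conditioned on the network's dynamical state (ROI
selection): only time bins where the network-average fluorescence lies
below a threshold enter the counts, excluding globally synchronous bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .calcium import BinaryRaster

__all__ = [
    "TEConfig",
    "LocalTEResult",
    "embed_states",
    "transfer_entropy",
    "local_te_split",
    "select_roi",
    "te_matrix",
    "te_matrix_sweep",
]


@dataclass(frozen=True)
class TEConfig:
    """Estimator settings: Markov orders, source bin delay, ROI threshold."""

    k_x: int = 1
    k_y: int = 2
    delay_bins: int = 0
    roi_threshold: float | str = "all"

    def __post_init__(self):
        if self.k_x < 1 or self.k_y < 1:
            raise ValueError("Markov orders must be >= 1")
        if self.delay_bins < 0:
            raise ValueError("delay_bins must be >= 0")

    @property
    def n_min(self) -> int:
        """First time index with a complete embedding."""
        return max(self.k_x, self.delay_bins + self.k_y - 1)


@dataclass
class LocalTEResult:
    """Pairwise TE matrices in bits; entry [i, j] is source j -> target i."""

    te_total: np.ndarray
    te_e: np.ndarray
    te_i: np.ndarray
    config: TEConfig
    n_samples_used: int

    def component(self, which: str) -> np.ndarray:
        if which == "E":
            return self.te_e
        if which == "I":
            return self.te_i
        if which == "total":
            return self.te_total
        raise ValueError(f"unknown component {which!r}")


def embed_states(x: np.ndarray, y: np.ndarray, cfg: TEConfig):
    """Build the (x_n, x_past, y_past) state tuples for every valid index n.

    Returns ``(n_idx, x_n, x_past, y_past)`` where ``x_past[t]`` is
    ``[x_{n-1}, ..., x_{n-k_x}]`` and ``y_past[t]`` is
    ``[y_{n-d}, ..., y_{n-d-k_y+1}]`` for ``n = n_idx[t]``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    t_len = len(x)
    if t_len <= cfg.n_min:
        raise ValueError(
            f"series of length {t_len} too short for embedding (need > {cfg.n_min})"
        )
    n_idx = np.arange(cfg.n_min, t_len)
    x_n = x[n_idx]
    x_past = np.stack([x[n_idx - m] for m in range(1, cfg.k_x + 1)], axis=1)
    y_past = np.stack(
        [y[n_idx - cfg.delay_bins - m] for m in range(cfg.k_y)], axis=1
    )
    return n_idx, x_n, x_past, y_past


def _pair_codes(x_n, x_past, y_past):
    """Encode each tuple as an integer: x_n is bit 0, then x_past, then y_past."""
    k_x = x_past.shape[1]
    xc = x_n.astype(np.int64)
    for m in range(k_x):
        xc = xc + (x_past[:, m].astype(np.int64) << (m + 1))
    yc = np.zeros(len(x_n), dtype=np.int64)
    for m in range(y_past.shape[1]):
        yc = yc + (y_past[:, m].astype(np.int64) << m)
    return xc, yc


def _te_from_counts(counts: np.ndarray, k_x: int, k_y: int):
    """Plug-in TE (total, E, I) from joint state counts.

    ``counts`` has shape (..., 2**k_y, 2**k_x, 2): source embedding, target
    embedding, current target state.  Zero-count states contribute 0.
    """
    counts = counts.reshape(counts.shape[:-1] + (1 << k_y, 1 << k_x, 2))
    c = counts.astype(float)
    n_tot = c.sum(axis=(-3, -2, -1), keepdims=True)
    c_xpyp = c.sum(axis=-1, keepdims=True)            # over x_n
    c_xpxn = c.sum(axis=-3, keepdims=True)            # over y_past
    c_xp = c.sum(axis=(-3, -1), keepdims=True)        # over y_past and x_n
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log2(c * c_xp) - np.log2(c_xpyp * c_xpxn)
        summand = np.where(c > 0, c / np.where(n_tot > 0, n_tot, 1) * log_term, 0.0)
    x_n_state = np.arange(2).reshape(1, 1, 2)
    y_active = (np.arange(1 << k_y) > 0).astype(int).reshape(-1, 1, 1)
    same_event = x_n_state == y_active
    te_e = np.where(same_event, summand, 0.0).sum(axis=(-3, -2, -1))
    te_i = np.where(~same_event, summand, 0.0).sum(axis=(-3, -2, -1))
    return te_e + te_i, te_e, te_i


def _counts_for_pair(x, y, cfg: TEConfig, roi_mask=None):
    n_idx, x_n, x_past, y_past = embed_states(x, y, cfg)
    xc, yc = _pair_codes(x_n, x_past, y_past)
    if roi_mask is not None:
        sel = np.asarray(roi_mask, dtype=bool)[n_idx]
        xc, yc = xc[sel], yc[sel]
    if len(xc) < 1:
        raise ValueError("insufficient data: no time indices selected")
    n_x = 1 << (cfg.k_x + 1)
    code = xc + n_x * yc
    return np.bincount(code, minlength=n_x << cfg.k_y), len(xc)


def transfer_entropy(x, y, cfg: TEConfig | None = None, roi_mask=None) -> float:
    """Plug-in transfer entropy from source ``y`` to target ``x``, in bits."""
    cfg = cfg or TEConfig()
    counts, _ = _counts_for_pair(x, y, cfg, roi_mask)
    total, _, _ = _te_from_counts(counts, cfg.k_x, cfg.k_y)
    return float(total)


def local_te_split(x, y, cfg: TEConfig | None = None, roi_mask=None):
    """Excitatory and inhibitory local TE components (te_E, te_I), in bits."""
    cfg = cfg or TEConfig()
    counts, _ = _counts_for_pair(x, y, cfg, roi_mask)
    _, te_e, te_i = _te_from_counts(counts, cfg.k_x, cfg.k_y)
    return float(te_e), float(te_i)


def select_roi(average_trace: np.ndarray, threshold: float | str) -> np.ndarray:
    """Dynamical-state mask: bins whose network-average signal is below threshold.

    ``"all"`` selects every bin (no conditioning).
    """
    average_trace = np.asarray(average_trace)
    if isinstance(threshold, str):
        if threshold != "all":
            raise ValueError(f"unknown ROI threshold {threshold!r}")
        return np.ones(len(average_trace), dtype=bool)
    return average_trace < threshold


def roi_threshold_grid(average_trace: np.ndarray, n_levels: int = 20) -> np.ndarray:
    """Evenly spaced candidate ROI levels strictly between min and max."""
    lo, hi = float(np.min(average_trace)), float(np.max(average_trace))
    return np.linspace(lo, hi, n_levels + 2)[1:-1]


def te_matrix(
    raster: BinaryRaster,
    cfg: TEConfig | None = None,
    average_trace: np.ndarray | None = None,
) -> LocalTEResult:
    """All-pairs local TE for one configuration (single ROI level)."""
    cfg = cfg or TEConfig()
    thresholds = None
    if not (isinstance(cfg.roi_threshold, str) and cfg.roi_threshold == "all"):
        if average_trace is None:
            raise ValueError("a numeric roi_threshold requires average_trace")
        thresholds = np.array([float(cfg.roi_threshold)])
    results = te_matrix_sweep(
        raster, cfg.k_x, cfg.k_y, cfg.delay_bins, average_trace, thresholds
    )
    return results[-1] if thresholds is not None else results[0]


def te_matrix_sweep(
    raster: BinaryRaster,
    k_x: int = 1,
    k_y: int = 2,
    delay_bins: int = 0,
    average_trace: np.ndarray | None = None,
    thresholds: np.ndarray | None = None,
) -> list[LocalTEResult]:
    """All-pairs local TE, optionally swept over nested ROI levels.

    With ``thresholds`` given (ascending ROI levels on the network-average
    trace), returns one :class:`LocalTEResult` per level; the level masks are
    nested, so state counts are accumulated once per pair and cumulated over
    levels.  With ``thresholds=None`` a single unconditioned result is
    returned.
    """
    states = np.ascontiguousarray(raster.states, dtype=np.int64)
    n, t_len = states.shape
    if n < 2:
        raise ValueError("need at least 2 neurons")
    cfg0 = TEConfig(k_x=k_x, k_y=k_y, delay_bins=delay_bins)
    n_min = cfg0.n_min
    if t_len <= n_min:
        raise ValueError("raster too short for the requested embedding")
    n_idx = np.arange(n_min, t_len)

    # per-neuron integer codes for target and source embeddings
    xc = states[:, n_idx].copy()
    for m in range(1, k_x + 1):
        xc += states[:, n_idx - m] << m
    yc = np.zeros_like(xc)
    for m in range(k_y):
        yc += states[:, n_idx - delay_bins - m] << m

    n_x = 1 << (k_x + 1)
    n_states = n_x << k_y

    if thresholds is None:
        buckets = np.zeros(len(n_idx), dtype=np.int64)
        n_levels = 1
        level_cfgs = [replace(cfg0, roi_threshold="all")]
    else:
        thresholds = np.sort(np.asarray(thresholds, dtype=float))
        if average_trace is None:
            raise ValueError("ROI sweep requires the network-average trace")
        avg = np.asarray(average_trace)[n_idx]
        # bucket b: first threshold strictly above the sample; level l keeps b <= l
        buckets = np.searchsorted(thresholds, avg, side="right")
        n_levels = len(thresholds)
        level_cfgs = [replace(cfg0, roi_threshold=float(th)) for th in thresholds]

    n_buckets = n_levels + 1 if thresholds is not None else 1
    offset = (buckets * n_states).astype(np.int64)
    y_off = yc * n_x + offset[np.newaxis, :]

    counts = np.zeros((n, n, n_buckets * n_states), dtype=np.int64)
    for i in range(n):
        xi = xc[i]
        for j in range(n):
            if i == j:
                continue
            counts[i, j] = np.bincount(xi + y_off[j], minlength=n_buckets * n_states)

    counts = counts.reshape(n, n, n_buckets, n_states)
    level_counts = np.cumsum(counts, axis=2)[:, :, :n_levels, :]
    level_samples = np.bincount(buckets, minlength=n_buckets).cumsum()[:n_levels]

    total, te_e, te_i = _te_from_counts(
        level_counts.transpose(2, 0, 1, 3), k_x, k_y
    )  # shape (n_levels, n, n)

    results = []
    diag = np.eye(n, dtype=bool)
    for lvl in range(n_levels):
        tt, ee, ii = total[lvl].copy(), te_e[lvl].copy(), te_i[lvl].copy()
        if level_samples[lvl] < 1:
            warnings.warn(
                f"ROI level {level_cfgs[lvl].roi_threshold!r} selects no time bins; "
                "recording NaN matrices"
            )
            tt[:], ee[:], ii[:] = np.nan, np.nan, np.nan
        tt[diag] = np.nan
        ee[diag] = np.nan
        ii[diag] = np.nan
        results.append(
            LocalTEResult(
                te_total=tt,
                te_e=ee,
                te_i=ii,
                config=level_cfgs[lvl],
                n_samples_used=int(level_samples[lvl]),
            )
        )
    return results
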