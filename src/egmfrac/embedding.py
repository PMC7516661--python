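"""Time-delay phase-space reconstruction and mutual-information lag
selection.

A scalar series ``x_1..x_N`` is embedded into m-dimensional delay vectors

    Y_p = (x_p, x_{p+tau}, ..., x_{p+(m-1)tau}),  p = 1..N-(m-1)tau,

which (for suitable m, tau) preserve the geometry of the underlying
dynamics.  The lag tau is conventionally taken at the first local minimum
of the time-delayed mutual information; the defaults (m=4, tau=8 samples
at 1 kHz, Nref=334) are the operating point established for 1-s bipolar
atrial electrogram epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateSignalError, LengthError, ParameterError

__all__ = ["EmbeddingConfig", "PhasePortrait", "reconstruct", "first_mi_minimum"]


@dataclass(frozen=True)
class EmbeddingConfig:
    """All CGCD numerics hang off this config.

    m : embedding dimension (default 4).
    tau_samples : delay in samples (default 8, i.e. 8 ms at 1 kHz).
    nref : number of reference vectors per epoch (default 334, one third
        of a 1-s epoch at 1 kHz).
    slope_halfwidth_ln : half-width delta of the symmetric ln-r offsets
        used for the finite-difference slope at r_cg (default 0.1).
    mi_bins / mi_max_lag_samples : mutual-information estimator settings.
    """

    m: int = 4
    tau_samples: int = 8
    nref: int = 334
    slope_halfwidth_ln: float = 0.1
    mi_bins: int = 16
    mi_max_lag_samples: int = 50

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.tau_samples < 1:
            raise ParameterError("tau_samples must be >= 1")
        if self.nref < 2:
            raise ParameterError("nref must be >= 2")
        if self.slope_halfwidth_ln <= 0:
            raise ParameterError("slope_halfwidth_ln must be positive")
        if self.mi_bins < 2:
            raise ParameterError("mi_bins must be >= 2")

    def min_segment_length(self) -> int:
        """Smallest epoch length (samples) that yields nref delay vectors."""
        return (self.m - 1) * self.tau_samples + self.nref


class PhasePortrait(NamedTuple):
    """Delay-embedded vectors: ``vectors[p, k] = x[p + k*tau]`` (0-based)."""

    vectors: np.ndarray
    m: int
    tau_samples: int

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]


class MILagResult(NamedTuple):
    lag: int
    mi_curve: np.ndarray  # mi_curve[i] is MI at lag i+1
    fallback: bool  # True when no strict local minimum existed


def reconstruct(x: np.ndarray, m: int, tau_samples: int) -> PhasePortrait:
    """Build the delay-vector matrix; exactly ``N - (m-1)*tau`` rows."""
    x = np.asarray(x, dtype=float)
    if m < 1 or tau_samples < 1:
        raise ParameterError("m and tau_samples must be >= 1")
    span = (m - 1) * tau_samples
    if len(x) <= span:
        raise LengthError(
            f"need more than {span} samples for m={m}, tau={tau_samples}; got {len(x)}"
        )
    n_vec = len(x) - span
    if m == 1:
        vectors = x[:, None].copy()
    else:
        windows = np.lib.stride_tricks.sliding_window_view(x, span + 1)
        vectors = windows[:n_vec, ::tau_samples].copy()
    return PhasePortrait(vectors=vectors, m=m, tau_samples=tau_samples)


def _mutual_information(x: np.ndarray, lag: int, bins: int) -> float:
    """Plug-in MI (nats) of (x_t, x_{t+lag}) from an equal-width joint
    histogram over the observed range."""
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    denom = np.outer(px, py)
    return float(np.sum(p[nz] * np.log(p[nz] / denom[nz])))


def first_mi_minimum(
    x: np.ndarray, mi_bins: int = 16, mi_max_lag_samples: int = 50
) -> MILagResult:
    """Delay at the first strict local minimum of the mutual information.

    MI is estimated at lags 1..mi_max_lag_samples and the first valley is
    located: the smallest lag with MI(lag-1) > MI(lag) < MI(lag+1), then
    expanded to the surrounding plateau of lags whose MI lies within 5% of
    the curve's range above that minimum (binned MI curves of strongly
    periodic signals bottom out in a flat valley whose center — e.g. the
    quarter period of a sinusoid — is the meaningful delay; the tolerance
    makes the estimate robust to estimator noise inside the valley).  The
    plateau's central lag is returned.  If no strict local minimum exists
    within the range (e.g. a constant-MI curve), the argmin over the range
    is returned with ``fallback=True``.
    """
    x = np.asarray(x, dtype=float)
    if mi_max_lag_samples < 1:
        raise ParameterError("mi_max_lag_samples must be >= 1")
    if len(x) < 10 * mi_max_lag_samples:
        raise LengthError(
            f"need at least {10 * mi_max_lag_samples} samples, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise DegenerateSignalError("mutual information undefined for constant signal")
    lags = np.arange(1, mi_max_lag_samples + 1)
    mi = np.array([_mutual_information(x, int(k), mi_bins) for k in lags])
    tol = 0.05 * float(np.ptp(mi))
    for i in range(1, len(mi) - 1):
        if mi[i - 1] > mi[i] < mi[i + 1]:
            lo = hi = i
            while lo > 0 and mi[lo - 1] <= mi[i] + tol:
                lo -= 1
            while hi < len(mi) - 1 and mi[hi + 1] <= mi[i] + tol:
                hi += 1
            return MILagResult(lag=int(lags[(lo + hi) // 2]), mi_curve=mi,
                               fallback=False)
    return MILagResult(lag=int(lags[np.argmin(mi)]), mi_curve=mi, fallback=True)
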