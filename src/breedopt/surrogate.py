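"""Kernel machinery shared by surrogate-assisted selection and optimum derivation.

All estimators use the product Gaussian kernel

    K(y_1, ..., y_p) = prod_j K_j(y_j),   K_j(u) = exp(-u^2/2) / sqrt(2 pi)

over the *continuous* decision variables, with per-dimension adaptive
bandwidths ``h_j`` equal to the empirical standard deviation of the
settings in a recent window (floored at a tiny fraction of the domain width
so degenerate, fully converged populations do not divide by zero).

Class variables carry no distance: they enter by exact-match
stratification — only archive rows whose class values equal the query's
contribute.  For the Nadaraya-Watson regression a query whose stratum is
empty either raises or, at the caller's request, falls back to all rows
with a logged warning.  For the density estimate the categorical part acts
as an indicator kernel, i.e. non-matching rows contribute zero while the
normalization keeps the total row count ``n``, which makes the mixed
continuous/categorical estimator a proper density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "KernelConfig",
    "EstimateUndefinedError",
    "gaussian_kernel",
    "adaptive_bandwidths",
    "kernel_regression_estimate",
    "kernel_density_estimate",
    "nadaraya_watson",
    "kernel_density",
]

logger = logging.getLogger(__name__)

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class EstimateUndefinedError(ValueError):
    """No archive row matches the query's class stratum."""


@dataclass(frozen=True)
class KernelConfig:
    """Bandwidth policy for the kernel estimators.

    ``window`` is the number of most recent iterations whose settings define
    the per-dimension bandwidths (1 = current iteration only, 5 for optimum
    derivation); ``floor_rel`` floors each bandwidth at this fraction of the
    variable's domain width; ``stratify`` toggles exact-match handling of
    class variables.
    """

    window: int = 5
    floor_rel: float = 1e-8
    stratify: bool = True


def gaussian_kernel(u) -> np.ndarray | float:
    """Standard Gaussian kernel K(u) = exp(-u^2/2)/sqrt(2*pi)."""
    u = np.asarray(u, dtype=float)
    out = np.exp(-0.5 * u * u) / _SQRT_2PI
    return float(out) if out.ndim == 0 else out


def adaptive_bandwidths(points: np.ndarray, floor) -> np.ndarray:
    """Per-dimension bandwidths: sample SD (n-1 denominator) of ``points``, floored.

    ``points`` is an (n, p) array of continuous setting components; with a
    single point (or a collapsed dimension) the floor applies.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("adaptive_bandwidths needs at least one point")
    floor = np.broadcast_to(np.asarray(floor, dtype=float), (X.shape[1],))
    if np.any(floor <= 0):
        raise ValueError("bandwidth floor must be positive")
    if X.shape[0] == 1:
        return floor.copy()
    return np.maximum(X.std(axis=0, ddof=1), floor)


def _class_match(query_class: Sequence[tuple], support_class: Sequence[tuple]) -> np.ndarray:
    """(n_query, n_support) boolean mask of exact class-tuple matches."""
    codes: dict[tuple, int] = {}

    def encode(ts):
        return np.asarray([codes.setdefault(t, len(codes)) for t in ts])

    q = encode(query_class)
    s = encode(support_class)
    return q[:, None] == s[None, :]


def _log_kernel_weights(Q: np.ndarray, X: np.ndarray, h: np.ndarray) -> np.ndarray:
    """(n_q, n_x) log of the unnormalized product-Gaussian weights."""
    D = (Q[:, None, :] - X[None, :, :]) / h
    return -0.5 * np.einsum("qxp,qxp->qx", D, D)


def nadaraya_watson(
    queries: np.ndarray,
    support: np.ndarray,
    values: np.ndarray,
    bandwidths: np.ndarray,
    query_class: Sequence[tuple] | None = None,
    support_class: Sequence[tuple] | None = None,
    on_empty: str = "raise",
) -> np.ndarray:
    """Kernel-regression estimates at ``queries``.

    The estimate is the kernel-weighted average of ``values`` over the
    support rows in the query's class stratum; it is always a convex
    combination of observed values.  Weights are computed with a per-query
    log-shift so far-away queries do not underflow to 0/0.  ``on_empty``
    says what to do when a query's stratum is empty: ``"raise"`` or
    ``"widen"`` (fall back to all rows, with a warning).
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    X = np.atleast_2d(np.asarray(support, dtype=float))
    y = np.asarray(values, dtype=float)
    h = np.asarray(bandwidths, dtype=float)
    if np.any(h <= 0):
        raise ValueError("bandwidths must be positive")
    if X.shape[0] != y.shape[0]:
        raise ValueError("support and values disagree in length")
    lw = _log_kernel_weights(Q, X, h)
    if query_class is not None and support_class is not None:
        match = _class_match(query_class, support_class)
        empty = ~match.any(axis=1)
        if empty.any():
            if on_empty == "widen":
                logger.warning(
                    "%d quer(y/ies) had no class-matching rows; widening to all rows",
                    int(empty.sum()),
                )
                match[empty, :] = True
            else:
                raise EstimateUndefinedError(
                    "no support rows share the query's class values"
                )
        lw = np.where(match, lw, -np.inf)
    shift = lw.max(axis=1, keepdims=True)
    w = np.exp(lw - shift)
    return (w @ y) / w.sum(axis=1)


def kernel_density(
    queries: np.ndarray,
    points: np.ndarray,
    bandwidths: np.ndarray,
    query_class: Sequence[tuple] | None = None,
    points_class: Sequence[tuple] | None = None,
) -> np.ndarray:
    """Multivariate KDE ``f(y) = (1/(n h_1...h_p)) sum_i prod_j K((y_j - x_ij)/h_j)``.

    With class stratification, non-matching points contribute zero while
    ``n`` stays the total point count (indicator kernel on the categorical
    part), so the estimator remains a proper density.
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    X = np.atleast_2d(np.asarray(points, dtype=float))
    h = np.asarray(bandwidths, dtype=float)
    if np.any(h <= 0):
        raise ValueError("bandwidths must be positive")
    n, p = X.shape
    lw = _log_kernel_weights(Q, X, h)
    w = np.exp(lw)
    if query_class is not None and points_class is not None:
        w = np.where(_class_match(query_class, points_class), w, 0.0)
    norm = n * float(np.prod(h)) * _SQRT_2PI**p
    return w.sum(axis=1) / norm


def kernel_regression_estimate(
    query,
    support,
    values,
    bandwidths,
    query_class: tuple | None = None,
    support_class: Sequence[tuple] | None = None,
    on_empty: str = "raise",
) -> float:
    """Scalar Nadaraya-Watson estimate at a single query point."""
    qc = None if query_class is None else [tuple(query_class)]
    est = nadaraya_watson(
        np.atleast_2d(np.asarray(query, dtype=float)),
        support,
        values,
        bandwidths,
        query_class=qc,
        support_class=support_class,
        on_empty=on_empty,
    )
    return float(est[0])


def kernel_density_estimate(
    query,
    points,
    bandwidths,
    query_class: tuple | None = None,
    points_class: Sequence[tuple] | None = None,
) -> float:
    """Scalar KDE value at a single query point."""
    qc = None if query_class is None else [tuple(query_class)]
    dens = kernel_density(
        np.atleast_2d(np.asarray(query, dtype=float)), points, bandwidths,
        query_class=qc, points_class=points_class,
    )
    return float(dens[0])
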