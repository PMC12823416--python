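"""Mincer human capital.

Each worker of age ``a`` with ``ys`` years of schooling carries

    h = exp(eta1*ys + eta2*exp_ + eta3*exp_**2),  exp_ = a - ys - 5,

where ``exp_`` is potential labor-market experience under a school entry
age of 5, ``eta1`` is the semi-elasticity of human capital with respect to
schooling and ``eta2``/``eta3`` the semi-elasticities with respect to
experience and experience squared (eta3 is typically negative:
concavity of the experience profile). Aggregate human capital is the
effective-labor-weighted sum ``H = sum_a h(a) * L(a)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ShapeError

__all__ = ["MincerParams", "mincer_h", "aggregate_H"]

logger = logging.getLogger(__name__)

SCHOOL_ENTRY_AGE = 5


@dataclass(frozen=True)
class MincerParams:
    eta1: float
    eta2: float
    eta3: float
    school_entry_age: int = SCHOOL_ENTRY_AGE


def mincer_h(age, ys, params: MincerParams):
    """Human capital per worker; scalar or elementwise over arrays."""
    age = np.asarray(age, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.any(ys < 0):
        raise DomainError("years of schooling must be nonnegative")
    exp_ = age - ys - params.school_entry_age
    neg = exp_ < 0
    if np.any(neg):
        # below-schooling-age cells (children) legitimately hit this; keep quiet
        # unless a worker-age cell is affected
        logger.debug("experience floored at 0 in %d cells", int(np.sum(neg)))
        exp_ = np.maximum(exp_, 0.0)
    h = np.exp(params.eta1 * ys + params.eta2 * exp_ + params.eta3 * exp_ ** 2)
    return float(h) if h.ndim == 0 else h


def aggregate_H(h, L):
    """Aggregate human capital ``H = sum h * L`` over the trailing grid axes.

    ``h`` and ``L`` must be conformable; with (T, A, S) inputs the sum runs
    over age and sex, returning H per year.
    """
    h = np.asarray(h, dtype=float)
    L = np.asarray(L, dtype=float)
    if h.shape != L.shape:
        raise ShapeError(f"h and L grids must match; got {h.shape} vs {L.shape}")
    if h.ndim <= 1:
        return float(np.sum(h * L))
    return np.sum(h * L, axis=tuple(range(1, h.ndim)))
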