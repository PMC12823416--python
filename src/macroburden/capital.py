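"""Physical capital accumulation.

Capital evolves by ``K[t+1] = (1 - delta) K[t] + s[t] Y[t]`` where the
saving rate is defined net of disease treatment cost,
``s = 1 - (C + TC) / Y``. In the counterfactual, a fraction ``chi`` of the
averted treatment cost is diverted to investment, so
``Ibar = s*Ybar + rho*chi*TC`` and the counterfactual saving rate is
``sbar = (s*Ybar + rho*chi*TC) / Ybar``.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import DomainError

__all__ = ["saving_rate", "step_capital", "counterfactual_saving", "capital_path"]

logger = logging.getLogger(__name__)


def saving_rate(C, TC, Y):
    """Saving rate ``s = 1 - (C + TC) / Y`` implied by the resource identity."""
    C, TC, Y = (np.asarray(v, dtype=float) for v in (C, TC, Y))
    if np.any(Y <= 0):
        raise DomainError("output Y must be positive")
    if np.any(C < 0) or np.any(TC < 0):
        raise DomainError("consumption and treatment cost must be nonnegative")
    s = 1.0 - (C + TC) / Y
    if np.any(s < 0):
        logger.warning("implied saving rate negative in %d cells", int(np.sum(s < 0)))
    return float(s) if s.ndim == 0 else s


def step_capital(K, Y, s, delta):
    """One accumulation step ``K' = (1 - delta) K + s Y``."""
    K, Y = np.asarray(K, dtype=float), np.asarray(Y, dtype=float)
    if np.any(K < 0) or np.any(Y < 0):
        raise DomainError("capital and output must be nonnegative")
    if not 0.0 <= delta <= 1.0:
        raise DomainError("depreciation rate delta must lie in [0, 1]")
    out = (1.0 - delta) * K + np.asarray(s, dtype=float) * Y
    return float(out) if out.ndim == 0 else out


def counterfactual_saving(s, Y_cf, TC, chi, rho=1.0):
    """Counterfactual saving rate ``sbar = (s*Ybar + rho*chi*TC) / Ybar``.

    Capped at 1 (the whole of output saved) with a logged warning.
    """
    Y_cf = np.asarray(Y_cf, dtype=float)
    if np.any(Y_cf <= 0):
        raise DomainError("counterfactual output must be positive")
    if not 0.0 <= chi <= 1.0:
        raise DomainError("chi must lie in [0, 1]")
    if not 0.0 <= rho <= 1.0:
        raise DomainError("rho must lie in [0, 1]")
    sbar = (np.asarray(s, dtype=float) * Y_cf + rho * chi * np.asarray(TC, dtype=float)) / Y_cf
    if np.any(sbar > 1.0):
        logger.warning("counterfactual saving rate capped at 1 in %d cells",
                       int(np.sum(sbar > 1.0)))
        sbar = np.minimum(sbar, 1.0)
    return float(sbar) if sbar.ndim == 0 else sbar


def capital_path(K0, Y, s, delta):
    """Full capital path from ``K0`` given exogenous output and saving paths."""
    Y = np.asarray(Y, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), Y.shape)
    K = np.empty_like(Y)
    K[0] = K0
    for t in range(len(Y) - 1):
        K[t + 1] = step_capital(K[t], Y[t], s[t], delta)
    return K
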