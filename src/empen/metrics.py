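"""Error metrics used throughout: geometric (multiplicative) error and R2.

Count and density data in this problem vary on a logarithmic scale, so
errors are reported multiplicatively: a k-fold over- or underestimate has
the same geometric error (k - 1) * 100 percent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["geometric_error", "mean_geometric_error", "r_squared"]


def geometric_error(pred, obs):
    """Per-point geometric error in percent: (exp(|ln(pred/obs)|) - 1) * 100.

    Symmetric in its arguments and zero iff pred == obs.  A 1.25-fold over-
    or underestimate both give 25 %.  Inputs must be positive.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("geometric error requires positive pred and obs")
    out = (np.exp(np.abs(np.log(pred / obs))) - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def mean_geometric_error(pred, obs):
    """Aggregate geometric error: averaged on the log scale, then transformed."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("geometric error requires positive pred and obs")
    return float((np.exp(np.mean(np.abs(np.log(pred / obs)))) - 1.0) * 100.0)


def r_squared(pred, obs):
    """Coefficient of determination 1 - SS_res / SS_tot on the linear scale."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ss_res = np.sum((obs - pred) ** 2)
    ss_tot = np.sum((obs - np.mean(obs)) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(1.0 - ss_res / ss_tot)
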