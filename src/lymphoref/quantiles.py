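"""The repo-wide quantile rule.

Percentiles (Tukey quartiles and the 2.5th/50th/97.5th reference-interval
endpoints alike) use the rank convention r = p*(n+1) with linear
interpolation between order statistics, clamped to [1, n]. This is the
nonparametric convention of clinical reference-interval practice and equals
numpy's "weibull" quantile method.
"""

from __future__ import annotations

import numpy as np


def rank_quantile(values: np.ndarray, p: float | np.ndarray) -> float | np.ndarray:
    """Quantile at rank r = p*(n+1), linearly interpolated, clamped to [1, n].

    Parameters
    ----------
    values : array of finite numbers, any order.
    p : probability or array of probabilities in [0, 1].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return np.quantile(v, p, method="weibull")
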