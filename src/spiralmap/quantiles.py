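"""Nearest-rank empirical quantiles.

One quantile rule is used everywhere in the package (noise thresholds,
macromolecule thresholds): the nearest-rank definition, q-quantile of n
sorted values = the ceil(q*n)-th smallest, with q=0 giving the minimum.
Under this rule at most a fraction (1-q) of the sample can exceed the
q-quantile strictly, which the noise-suppression contract relies on.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["nearest_rank_quantile"]


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank q-quantile of a 1D sample (q in [0, 1])."""
    a = np.sort(np.asarray(values).ravel())
    n = a.size
    if n == 0:
        raise ValueError("empty sample has no quantiles")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile must be in [0, 1], got {q}")
    if q == 0.0:
        return float(a[0])
    k = min(max(math.ceil(q * n), 1), n)
    return float(a[k - 1])
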