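"""Brute-force oracles shared across test modules."""

import numpy as np


def simplex_grid_objective(L, resolution=1e-3):
    """Exhaustive simplex-grid maximisation of the mixture objective
    sum_i log sum_j w_j L_ij (supports 2- and 3-column matrices)."""
    n, k = L.shape
    steps = int(round(1.0 / resolution))
    if k == 2:
        w1 = np.linspace(0.0, 1.0, steps + 1)
        W = np.stack([w1, 1 - w1], axis=1)
    elif k == 3:
        pts = []
        for i in range(steps + 1):
            a = i * resolution
            b = np.linspace(0.0, 1.0 - a, steps + 1 - i)
            pts.append(np.stack([np.full_like(b, a), b, 1 - a - b], axis=1))
        W = np.vstack(pts)
    else:
        raise ValueError("oracle supports 2 or 3 columns")
    with np.errstate(divide="ignore"):
        obj = np.sum(np.log(L @ W.T), axis=0)
    j = int(np.argmax(obj))
    return W[j], float(obj[j])
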