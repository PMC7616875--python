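"""Independent direct-formula reference implementations used only by tests.

Deliberately written with explicit loops and no code shared with the
package, so they exercise the definitions rather than the implementation.
"""

import math

import numpy as np


def lee_L_oracle(x, y, V):
    """Lee's L from its definition, elementwise."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    num = 0.0
    denom_rows = 0.0
    for i in range(n):
        lag_x = sum(V[i][j] * (x[j] - xbar) for j in range(n))
        lag_y = sum(V[i][j] * (y[j] - ybar) for j in range(n))
        num += lag_x * lag_y
        denom_rows += sum(V[i]) ** 2
    sx = math.sqrt(sum((xi - xbar) ** 2 for xi in x))
    sy = math.sqrt(sum((yi - ybar) ** 2 for yi in y))
    return n / denom_rows * num / (sx * sy)


def moran_I_oracle(x, V):
    """Moran's I from its definition, elementwise."""
    n = len(x)
    xbar = sum(x) / n
    s0 = sum(sum(row) for row in V)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += V[i][j] * (x[i] - xbar) * (x[j] - xbar)
    return n / s0 * num / sum((xi - xbar) ** 2 for xi in x)


def wls_normal_equations_oracle(X, y, w):
    """(X'WX)^-1 X'Wy and classical SEs via explicit matrix assembly."""
    X = np.asarray(X, float)
    W = np.diag(np.asarray(w, float))
    XtWX = X.T @ W @ X
    beta = np.linalg.inv(XtWX) @ X.T @ W @ y
    resid = y - X @ beta
    sigma2 = (resid @ W @ resid) / (X.shape[0] - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtWX)))
    return beta, se


def random_weight_matrix(rng, n, row_standardize=False, density=0.3):
    """Random sparse non-negative weight matrix with zero diagonal."""
    V = rng.random((n, n)) * (rng.random((n, n)) < density)
    V = (V + V.T) / 2.0
    np.fill_diagonal(V, 0.0)
    # guarantee no zero rows
    for i in range(n):
        if V[i].sum() == 0:
            j = (i + 1) % n
            V[i, j] = V[j, i] = 1.0
    if row_standardize:
        V = V / V.sum(axis=1, keepdims=True)
    return V
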