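"""Independent reference implementations used only as test oracles."""

import numpy as np


def nipals_pls_fitted(X, y, a_max):
    """Classic NIPALS PLS (unnormalized scores), fitted values for a=1..a_max.

    Deliberately parametrized differently from the package's kernel
    algorithm: scores are left unnormalized and the response loading is
    q = f't/(t't).  Returns an (n, a_achieved) matrix whose column a-1 holds
    the fitted values using the first a components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    E = X - X.mean(axis=0)
    f = y - y.mean()
    fitted = []
    acc = np.full(len(y), y.mean())
    for _ in range(a_max):
        s = E.T @ f
        ns = np.linalg.norm(s)
        if ns < 1e-12:
            break
        w = s / ns
        t = E @ w
        tt = t @ t
        if tt < 1e-24:
            break
        p = E.T @ t / tt
        q = f @ t / tt
        E = E - np.outer(t, p)
        f = f - t * q
        acc = acc + t * q
        fitted.append(acc.copy())
    return np.column_stack(fitted)


def gls_fixed_effects(y, X, Z_blocks, var_blocks, var_resid):
    """Generalized least squares by direct inversion of the marginal covariance."""
    n = len(y)
    V = var_resid * np.eye(n)
    for Z, v in zip(Z_blocks, var_blocks):
        V = V + v * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def blup_posterior_mean(y, K, var_u, var_e):
    """Exact posterior mean of u under a flat prior on the intercept."""
    n = len(y)
    V = var_u * K + var_e * np.eye(n)
    Vi = np.linalg.inv(V)
    one = np.ones((n, 1))
    mu = (np.linalg.solve(one.T @ Vi @ one, one.T @ Vi @ y)).item()
    return var_u * K @ Vi @ (y - mu)
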