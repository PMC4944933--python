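"""Independent exhaustive grid minimizer of the fitting objective.

Evaluates the residual sum of squares of ``A * f_p(x) + C`` (the same
monoexponential-with-offset objective the fitter minimizes) over a dense
3-D grid of (parameter, A, C) and returns the per-pixel argmin. Written
directly from the model definitions — no code shared with the fitter — so
agreement is an independent check of the nonlinear solver.
"""

import numpy as np


def _basis(kind, x, p_grid):
    """f_p(x) for every grid value of the nonlinear parameter."""
    x = x[None, :]
    p = p_grid[:, None]
    if kind == "cpmg":
        return np.exp(-x / p)
    if kind == "satrec":
        return 1.0 - np.exp(-x / p)
    if kind == "mt":
        return np.exp(-p * x)
    if kind == "diffusion":
        return np.exp(-x * p)
    raise ValueError(kind)


def grid_argmin(signals, x, kind, p_grid, a_grid, c_grid):
    """Exhaustive RSS minimization over the (p, A, C) grid.

    Parameters
    ----------
    signals : (n_pixels, n_frames) array
    x : (n_frames,) schedule
    kind : model kind
    p_grid, a_grid, c_grid : 1-D grids

    Returns
    -------
    (p_hat, a_hat, c_hat) : arrays of shape (n_pixels,)
        Grid coordinates of the RSS minimum per pixel.
    """
    S = np.asarray(signals, dtype=float)
    x = np.asarray(x, dtype=float)
    M = _basis(kind, x, np.asarray(p_grid, dtype=float))  # (P, T)
    T = x.size
    # expand RSS = a^2 m2 + 2ac m1 - 2a M.S + T c^2 - 2c s1 + s2
    m2 = np.sum(M * M, axis=1)          # (P,)
    m1 = np.sum(M, axis=1)              # (P,)
    MS = M @ S.T                        # (P, N)
    s1 = np.sum(S, axis=1)              # (N,)
    s2 = np.sum(S * S, axis=1)          # (N,)

    n = S.shape[0]
    best = np.full(n, np.inf)
    bi = np.zeros(n, dtype=int)   # p index
    ba = np.zeros(n, dtype=int)
    bc = np.zeros(n, dtype=int)
    for ia, a in enumerate(a_grid):
        for ic, c in enumerate(c_grid):
            rss = (a * a * m2 + 2 * a * c * m1)[:, None] \
                - 2.0 * a * MS + (T * c * c) - 2.0 * c * s1[None, :] \
                + s2[None, :]
            pidx = np.argmin(rss, axis=0)
            val = rss[pidx, np.arange(n)]
            better = val < best
            best[better] = val[better]
            bi[better] = pidx[better]
            ba[better] = ia
            bc[better] = ic
    p_grid = np.asarray(p_grid, dtype=float)
    a_grid = np.asarray(a_grid, dtype=float)
    c_grid = np.asarray(c_grid, dtype=float)
    return p_grid[bi], a_grid[ba], c_grid[bc], bi
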