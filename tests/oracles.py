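"""Independent brute-force oracles used by the test suite.

Each of these recomputes a quantity by a different route from the package
implementation it checks: explicit OLS projections for the balanced ANOVA,
exhaustive simplex enumeration for the constrained least-squares
deconvolution, and a direct normal-equations evaluation for LOESS.
"""

import numpy as np


def anova_projection_oracle(y):
    """Interaction F via explicit OLS projections on dummy design matrices.

    SS(term) is the drop in residual sum of squares when the term's one-hot
    columns join the design; with balanced data this matches the classical
    decomposition. The Treatment x Haplotype mean square is tested against
    the Replicate x Treatment x Haplotype residual.
    """
    r, t, f = y.shape
    obs = y.reshape(-1)

    def onehot(levels, index):
        X = np.zeros((r * t * f, levels))
        X[np.arange(r * t * f), index] = 1.0
        return X

    ri, ti, fi = np.meshgrid(np.arange(r), np.arange(t), np.arange(f),
                             indexing="ij")
    ri, ti, fi = ri.ravel(), ti.ravel(), fi.ravel()
    blocks = {
        "R": onehot(r, ri), "T": onehot(t, ti), "H": onehot(f, fi),
        "RT": onehot(r * t, ri * t + ti), "RH": onehot(r * f, ri * f + fi),
        "TH": onehot(t * f, ti * f + fi),
    }

    def rss(names):
        X = np.hstack([np.ones((obs.size, 1))] + [blocks[n] for n in names])
        beta, *_ = np.linalg.lstsq(X, obs, rcond=None)
        resid = obs - X @ beta
        return float(resid @ resid)

    base = ["R", "T", "H", "RT", "RH"]
    ss_th = rss(base) - rss(base + ["TH"])
    ss_rth = rss(base + ["TH"])  # what remains is the three-way interaction
    df1 = (t - 1) * (f - 1)
    df2 = (r - 1) * df1
    return (ss_th / df1) / (ss_rth / df2)


def grid_search_simplex(A, y, resolution=0.01):
    """Exhaustive simplex search: best composition of 1/resolution parts."""
    k = int(round(1 / resolution))
    F = A.shape[1]

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for head in range(total + 1):
            for rest in compositions(total - head, parts - 1):
                yield (head, *rest)

    best, best_val = None, np.inf
    for comp in compositions(k, F):
        h = np.array(comp) / k
        val = np.sum((A @ h - y) ** 2)
        if val < best_val:
            best, best_val = h, val
    return best


def loess_direct_oracle(x, y, span, degree):
    """Per-point tricube weighted polynomial fit via normal equations."""
    n = x.size
    q = min(int(np.ceil(span * n)), n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nearest = np.sort(np.argsort(d, kind="stable")[:q])
        dmax = d[nearest].max()
        w = (1 - (d[nearest] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(q)
        X = np.column_stack([(x[nearest] - x[i]) ** k for k in range(degree + 1)])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[nearest])
        out[i] = beta[0]
    return out
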