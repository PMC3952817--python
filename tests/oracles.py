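"""Independent reference implementations used only to check the package.

These oracles re-derive the quantities they check from first principles
(exhaustive enumeration, grid refinement, direct formula evaluation) without
reusing the package's solver code paths.
"""

import numpy as np


def os_error_direct(y, s, domains, nu, eps):
    """Relative scaling error evaluated directly from its definition."""
    e = ((np.asarray(y, float) - np.asarray(s, float)) / (nu + eps)) ** 2
    return float(np.sqrt(sum(e[np.asarray(d, int)].mean() for d in domains)))


def _os_eval_grid(V, y, ranks, domains, n_cat, d_min, g_min, lb, nu, eps):
    """Errors for a batch of slack vectors (G, 2·n_cat) → (G,)."""
    G = V.shape[0]
    L = np.empty((G, n_cat))
    U = np.empty((G, n_cat))
    L[:, 0] = lb + V[:, 0]
    U[:, 0] = L[:, 0] + d_min + V[:, 1]
    for r in range(1, n_cat):
        L[:, r] = U[:, r - 1] + g_min + V[:, 2 * r]
        U[:, r] = L[:, r] + d_min + V[:, 2 * r + 1]
    s = np.clip(y[None, :], L[:, ranks - 1], U[:, ranks - 1])
    e = ((y[None, :] - s) / (nu + eps)) ** 2
    inner = np.zeros(G)
    for d in domains:
        inner += e[:, np.asarray(d, int)].mean(axis=1)
    return np.sqrt(inner)


def os_bruteforce(y, ranks, domains, n_cat, d_min, g_min, lb, nu, eps,
                  grid=6, rounds=4, topk=8):
    """Nested-grid brute force over interval boundary placements.

    Boundaries are parameterized by non-negative slacks (first lower bound
    above ``lb``, extra widths, extra gaps).  Each round lays a full grid
    over every live box; the ``topk`` best grid points spawn the next
    round's (shrunken) boxes, so refinement cannot be trapped by a single
    coarse incumbent.  Returns the minimal error found.
    """
    y = np.asarray(y, float)
    ranks = np.asarray(ranks, int)
    nv = 2 * n_cat
    span = max(y.max() + d_min - lb, d_min)
    boxes = [(np.zeros(nv), np.full(nv, span))]
    best = np.inf
    for _ in range(rounds):
        Vs, errs = [], []
        for lo, hi in boxes:
            axes = [np.linspace(lo[j], hi[j], grid) for j in range(nv)]
            mesh = np.meshgrid(*axes, indexing="ij")
            V = np.stack([m.ravel() for m in mesh], axis=1)
            Vs.append(V)
            errs.append(_os_eval_grid(V, y, ranks, domains, n_cat,
                                      d_min, g_min, lb, nu, eps))
        V = np.vstack(Vs)
        err = np.concatenate(errs)
        best = min(best, float(err.min()))
        order = np.argsort(err)[:topk]
        w = max(float((hi - lo).max()) for lo, hi in boxes) / (grid - 1)
        boxes = [(np.clip(V[i] - w, 0.0, span), np.clip(V[i] + w, None, span))
                 for i in order]
    return best


def os_zero_feasible(y, ranks, n_cat, d_min, g_min, lb):
    """Direct existence check for an exact rank-consistent interval fit."""
    y = np.asarray(y, float)
    ranks = np.asarray(ranks, int)
    prev_u = None
    for r in range(1, n_cat + 1):
        lo_limit = lb if prev_u is None else prev_u + g_min
        vals = y[ranks == r]
        if vals.size and vals.min() < lo_limit - 1e-12:
            return False
        top = max(vals.max(), lo_limit + d_min) if vals.size else lo_limit + d_min
        prev_u = top
    return True


def pareto_bruteforce(F):
    """O(n²) dominance scan; duplicates keep their first occurrence."""
    F = np.asarray(F, float)
    keep = []
    for i in range(len(F)):
        dominated = False
        for j in range(len(F)):
            if i == j:
                continue
            if np.all(F[j] <= F[i]) and (np.any(F[j] < F[i]) or
                                         (np.all(F[j] == F[i]) and j < i)):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


def antichain_bruteforce(edge_sets):
    """Indices of sets containing no strictly smaller set in the collection."""
    out = []
    for i, es in enumerate(edge_sets):
        if not any(j != i and other < es for j, other in enumerate(edge_sets)):
            out.append(i)
    return out
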