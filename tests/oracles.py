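"""Independent brute-force reference implementations used by the tests.

Deliberately written with explicit Python loops and no shared code with
the package, so they can serve as oracles for the vectorized versions.
"""

import numpy as np

from scopesim import population_merit


def fscore_oracle(Z, p):
    total = 0.0
    for j in range(Z.shape[1]):
        if p[j]:
            col = Z[:, j]
            m = col.mean()
            total += ((col - m) ** 2).sum() / (len(col) - 1)
    return total


def vanraden_oracle(Z, src):
    P = np.array([(src[:, i] + 1).mean() / 2 for i in range(Z.shape[1])])
    M = np.array(
        [[Z[r, i] - 2 * (P[i] - 0.5) for i in range(Z.shape[1])] for r in range(Z.shape[0])]
    )
    denom = 2 * sum(P[i] * (1 - P[i]) for i in range(Z.shape[1]))
    n = Z.shape[0]
    return np.array(
        [
            [sum(M[r, i] * M[s, i] for i in range(Z.shape[1])) / denom for s in range(n)]
            for r in range(n)
        ]
    )


def mvt_oracle(G_sel):
    n = G_sel.shape[0]
    gbar = np.mean([G_sel[i, j] for i in range(n) for j in range(n) if i != j])
    return np.mean([(1 + (G_sel[i, i] - 1)) - 2 * gbar for i in range(n)])


def merit_of(sel, g, G, c):
    sel = list(sel)
    phi = np.mean([G[i, j] for i in sel for j in sel if i != j])
    return population_merit(float(np.mean(g[sel])), c, phi)


def scoping_oracle(gebv, Z, SR, n_couples):
    """Step-by-step greedy selection, one couple at a time."""
    n = len(gebv)
    m = int(np.ceil(SR * n))
    cand = list(np.argsort(-gebv, kind="stable")[:m])
    selected, couples = [], []
    p = np.ones(Z.shape[1], dtype=int)
    for _ in range(n_couples):
        p1 = cand.pop(0)
        selected.append(p1)
        best, best_score = None, -np.inf
        for c in cand:
            s = fscore_oracle(Z[selected + [c]], p)
            if s > best_score + 1e-15:
                best, best_score = c, s
        cand.remove(best)
        selected.append(best)
        couples.append((p1, best))
        sel_Z = Z[selected]
        both = np.array(
            [np.any(sel_Z[:, j] <= 0) and np.any(sel_Z[:, j] >= 0) for j in range(Z.shape[1])]
        )
        p = (~both).astype(int)
        if not p.any():
            p = np.ones(Z.shape[1], dtype=int)
    return couples
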