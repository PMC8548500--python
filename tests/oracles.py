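"""Naive loop-based reference implementations used as independent oracles.

Everything here works on raw arrays and explicit Python loops, written
directly from the stage definitions, and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def all_paths_contribution(ancestors, edges, term, delta):
    """D_term(t) = max over upward paths term->t of delta^len(path)."""
    parents = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
    best = {term: 1.0}
    stack = [(term, 1.0)]
    while stack:
        node, value = stack.pop()
        for p in parents.get(node, ()):  # walk every upward path
            v = value * delta
            if v > best.get(p, -1.0):
                best[p] = v
            stack.append((p, v))
    # even dominated paths must be explored for completeness
    for t in ancestors:
        assert t in best, f"ancestor {t} unreachable from {term}"
    return best


def dss_value(contrib_i, contrib_j):
    shared = set(contrib_i) & set(contrib_j)
    if not shared:
        return 0.0
    num = sum(contrib_i[t] + contrib_j[t] for t in shared)
    den = sum(contrib_i.values()) + sum(contrib_j.values())
    return num / den


def mfs_value(terms_i, terms_j, dss, didx):
    def ss(d, terms):
        return max(dss[didx[d], didx[t]] for t in terms)

    total = sum(ss(d, terms_j) for d in terms_i)
    total += sum(ss(d, terms_i) for d in terms_j)
    return total / (len(terms_i) + len(terms_j))


def gip_matrix(profiles, gamma_prime=1.0):
    n = len(profiles)
    gamma = gamma_prime / (sum(float(p @ p) for p in profiles) / n)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = profiles[i] - profiles[j]
            K[i, j] = np.exp(-gamma * float(diff @ diff))
    return K


def integrate_matrix(primary, gip):
    n = primary.shape[0]
    out = np.empty_like(primary)
    for i in range(n):
        for j in range(n):
            out[i, j] = primary[i, j] if primary[i, j] > 0 else gip[i, j]
    np.fill_diagonal(out, 1.0)
    return out


def wknkn_matrix(A, dsim, msim, d_labels, m_labels, K, r):
    """Triple-loop WKNKN on raw arrays, neighbor rules spelled out."""
    n_d, n_m = A.shape
    known_d = [i for i in range(n_d) if A[i].sum() > 0]
    known_m = [j for j in range(n_m) if A[:, j].sum() > 0]

    Yd = np.zeros_like(A, dtype=float)
    for i in range(n_d):
        nbrs = sorted(
            (j for j in known_d if j != i),
            key=lambda j: (-dsim[i, j], d_labels[j]),
        )[:K]
        denom = sum(dsim[i, j] for j in nbrs)
        if denom > 0:
            for t, j in enumerate(nbrs):
                for col in range(n_m):
                    Yd[i, col] += r**t * dsim[i, j] * A[j, col]
            Yd[i] /= denom

    Ym = np.zeros_like(A, dtype=float)
    for j in range(n_m):
        nbrs = sorted(
            (k for k in known_m if k != j),
            key=lambda k: (-msim[j, k], m_labels[k]),
        )[:K]
        denom = sum(msim[j, k] for k in nbrs)
        if denom > 0:
            for t, k in enumerate(nbrs):
                for row in range(n_d):
                    Ym[row, j] += r**t * msim[j, k] * A[row, k]
            Ym[:, j] /= denom

    out = np.empty_like(A, dtype=float)
    for i in range(n_d):
        for j in range(n_m):
            out[i, j] = 1.0 if A[i, j] == 1 else min(1.0, (Yd[i, j] + Ym[i, j]) / 2.0)
    return out


def base_disease(ISD, A_new):
    n_d, n_m = A_new.shape
    out = np.zeros((n_d, n_m))
    for i in range(n_d):
        for j in range(n_m):
            out[i, j] = sum(ISD[i, k] * A_new[k, j] for k in range(n_d))
    return out


def base_mirna(A_new, ISM):
    n_d, n_m = A_new.shape
    out = np.zeros((n_d, n_m))
    for i in range(n_d):
        for j in range(n_m):
            out[i, j] = sum(A_new[i, k] * ISM[k, j] for k in range(n_m))
    return out


def t_dm(A_new, mirna_base, phi):
    n_d, n_m = A_new.shape
    out = np.zeros((n_d, n_m))
    for i in range(n_d):
        denom = sum(A_new[i, l] * mirna_base[i, l] for l in range(n_m))
        if denom > 0:
            for j in range(n_m):
                out[i, j] = phi * A_new[i, j] * mirna_base[i, j] / denom
    return out


def t_md(A_new, disease_base, phi):
    n_d, n_m = A_new.shape
    out = np.zeros((n_d, n_m))
    for j in range(n_m):
        denom = sum(A_new[l, j] * disease_base[l, j] for l in range(n_d))
        if denom > 0:
            for i in range(n_d):
                out[i, j] = phi * A_new[i, j] * disease_base[i, j] / denom
    return out


def intra(sim, degrees, phi):
    n = sim.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        rowsum = sum(sim[i, k] for k in range(n))
        if rowsum == 0:
            continue
        for j in range(n):
            out[i, j] = sim[i, j] / rowsum
            if degrees[i] > 0:
                out[i, j] *= 1.0 - phi
    return out


def initial_matrix(n_d, n_m, delta):
    P0 = np.zeros((n_d + n_m, n_d + n_m))
    for i in range(n_d):
        P0[i, i] = (1.0 - delta) / n_d
    for j in range(n_m):
        P0[n_d + j, n_d + j] = delta / n_m
    return P0


def rwr_closed_form(W, P0, gamma, t):
    """Exact unrolling: P_t = ((1-g)W)^t P0 + g * sum_{k<t} ((1-g)W)^k P0."""
    M = (1.0 - gamma) * W
    power = np.eye(W.shape[0])
    series = np.zeros_like(P0)
    for _ in range(t):
        series = series + power @ P0
        power = power @ M
    return power @ P0 + gamma * series


def combine(P1, P2, delta, n_d, n_m):
    P = (1.0 - delta) * P1 + delta * P2
    scores = np.zeros((n_d, n_m))
    for i in range(n_d):
        for j in range(n_m):
            scores[i, j] = (P[i, n_d + j] + P[n_d + j, i]) / 2.0
    return scores


def auc_pair_count(scores, labels):
    """Wilcoxon-Mann-Whitney pair counting with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))


def random_symmetric_similarity(rng, n):
    """Symmetric matrix in [0,1] with unit diagonal (exactly symmetric)."""
    M = rng.random((n, n))
    M = np.triu(M, 1)
    M = M + M.T
    np.fill_diagonal(M, 1.0)
    return M
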