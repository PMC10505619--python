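"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(exhaustive enumeration, naive double loops, direct path walks) and
deliberately avoids the package's optimized code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from adaptscan.codons import encode_codon_sequence
from adaptscan.selection import codon_rate_matrix, substitution_rate


def enumeration_codon_loglik(tree, aln, params, foreground, pi):
    """Codon log-likelihood by exhaustive summation over internal states.

    Enumerates every joint assignment of the 61 sense codons to internal
    nodes (61^n_internal terms per site and class) with transition
    matrices from scipy's expm; feasible for <=4 taxa and a handful of
    codons.
    """
    props = params.proportions
    bgw, fgw = params.background_omegas, params.foreground_omegas
    Qs = {w: codon_rate_matrix(params.kappa, w, pi) for w in set(bgw) | set(fgw)}
    r = sum(props[k] * substitution_rate(Qs[bgw[k]], pi) for k in range(4))
    X = {rec.id: encode_codon_sequence(rec.seq) for rec in aln.records}
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internal)}
    n_sites = aln.length // 3
    A = np.indices((61,) * len(internal)).reshape(len(internal), -1)
    site_lik = np.zeros(n_sites)
    for k in range(4):
        if props[k] == 0:
            continue
        P = {}
        for n in nodes:
            if n.parent_node is None:
                continue
            is_fg = (
                n.is_leaf()
                and foreground is not None
                and n.taxon.label == foreground
            )
            w = fgw[k] if is_fg else bgw[k]
            P[id(n)] = expm(Qs[w] * (n.edge.length / r))
        contrib = np.repeat(pi[A[idx[id(tree.seed_node)]]][:, None], n_sites, axis=1)
        for n in nodes:
            if n.parent_node is None:
                continue
            pstates = A[idx[id(n.parent_node)]]
            if n.is_leaf():
                contrib *= P[id(n)][np.ix_(pstates, X[n.taxon.label])]
            else:
                contrib *= P[id(n)][pstates, A[idx[id(n)]]][:, None]
        site_lik += props[k] * contrib.sum(axis=0)
    return float(np.log(site_lik).sum())


def naive_unique_substitution_scan(aln, focal, window):
    """Column-by-column scan with an O(L^2) gap window, no vectorization."""
    n = aln.length
    columns = [aln.column(c) for c in range(n)]
    gap_cols = [c for c in range(n) if "-" in columns[c]]
    focal_idx = aln.ids.index(focal)
    hits = []
    for c in range(n):
        if any(abs(c - g) <= window for g in gap_cols):
            continue
        col = columns[c]
        background = [col[i] for i in range(len(col)) if i != focal_idx]
        if "-" in background or len(set(background)) != 1:
            continue
        f = col[focal_idx]
        if f != "-" and f != background[0]:
            hits.append(c)
    return hits


def walk_root_to_tip(tree):
    """Per-tip distance by walking parent chains, one edge at a time."""
    out = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up, computed longhand."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def enumeration_family_loglik(counts, ct, transition_stack, prior):
    """Family likelihood by summing over every internal-state assignment."""
    import itertools

    internal = [n for n, _ in ct.postorder]
    total = 0.0
    n_states = len(prior)
    for assign in itertools.product(range(n_states), repeat=len(internal)):
        st = dict(zip(internal, assign))
        p = prior[st[ct.root]]
        for node, children in ct.postorder:
            for child, eidx in children:
                j = (
                    counts[ct.tip_species[child]]
                    if child in ct.tip_species
                    else st[child]
                )
                p *= transition_stack[eidx][st[node], j]
        total += p
    return float(np.log(total))
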