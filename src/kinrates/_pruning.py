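"""Low-level pruning-likelihood and MCMC kernels.

Trees are flattened to postorder arrays once per analysis; the Felsenstein
pruning recursion and the Metropolis sampler then run inside numba-compiled
loops. The transition kernel uses the closed form of the frequency-scaled
single-rate (F81-style) model, p_ij(t) = pi_j + (delta_ij - pi_j) e^(-mu t),
so each child message costs O(k). All randomness is pre-generated outside the
kernels from a seeded generator, which makes runs bit-reproducible.
"""
from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np
from numba import njit


def pack_tree(tree: dendropy.Tree, taxon_index: dict, scale: float = 1.0):
    """Flatten one tree into postorder arrays.

    Returns (child_ptr, child_idx, edge_len, leaf_taxon) with nodes numbered
    in postorder (children before parents, root last). ``edge_len`` is the
    length of the edge above each node, times ``scale``.
    """
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    child_ptr = np.zeros(n + 1, dtype=np.int64)
    child_idx_list: list[int] = []
    edge_len = np.zeros(n, dtype=np.float64)
    leaf_taxon = np.full(n, -1, dtype=np.int64)
    for i, nd in enumerate(nodes):
        kids = nd.child_nodes()
        child_ptr[i + 1] = child_ptr[i] + len(kids)
        for c in kids:
            child_idx_list.append(index[id(c)])
        edge_len[i] = (nd.edge.length or 0.0) * scale
        if not kids:
            label = nd.taxon.label
            if label not in taxon_index:
                raise KeyError(f"tree leaf {label!r} not in taxon index")
            leaf_taxon[i] = taxon_index[label]
    return child_ptr, np.asarray(child_idx_list, dtype=np.int64), edge_len, leaf_taxon


def pack_sample(trees: Sequence[dendropy.Tree], taxon_index: dict, scale: float = 1.0):
    """Flatten a tree sample into concatenated arrays plus per-tree offsets."""
    packed = [pack_tree(t, taxon_index, scale) for t in trees]
    node_offset = np.zeros(len(trees) + 1, dtype=np.int64)
    for i, (_, _, el, _) in enumerate(packed):
        node_offset[i + 1] = node_offset[i] + len(el)
    child_ptr = np.zeros(node_offset[-1] + 1, dtype=np.int64)
    flat_children: list[int] = []
    for i, (cp, ci, el, _) in enumerate(packed):
        base = node_offset[i]
        for local in range(len(el)):
            kids = ci[cp[local]:cp[local + 1]] + base
            child_ptr[base + local + 1] = child_ptr[base + local] + len(kids)
            flat_children.extend(kids.tolist())
    child_idx = np.asarray(flat_children, dtype=np.int64)
    edge_len = np.concatenate([p[2] for p in packed])
    leaf_taxon = np.concatenate([p[3] for p in packed])
    return node_offset, child_ptr, child_idx, edge_len, leaf_taxon


@njit(cache=True)
def tree_loglik(mu, pi, off0, off1, child_ptr, child_idx, edge_len, leaf_taxon, tipstate):
    """Pruning log-likelihood for one flattened tree under the F81-style model.

    ``tipstate`` maps taxon index -> state (or -1 for missing, giving a
    partial-likelihood vector of ones). Returns -inf for impossible data.
    """
    k = pi.shape[0]
    n = off1 - off0
    part = np.empty((n, k))
    logscale = 0.0
    for li in range(n):
        g = off0 + li
        c0, c1 = child_ptr[g], child_ptr[g + 1]
        if c1 == c0:
            s = tipstate[leaf_taxon[g]]
            if s < 0:
                for j in range(k):
                    part[li, j] = 1.0
            else:
                for j in range(k):
                    part[li, j] = 0.0
                part[li, s] = 1.0
        else:
            for j in range(k):
                part[li, j] = 1.0
            for ci in range(c0, c1):
                c = child_idx[ci]
                cl = c - off0
                e = np.exp(-mu * edge_len[c])
                dot = 0.0
                for j in range(k):
                    dot += pi[j] * part[cl, j]
                for j in range(k):
                    part[li, j] *= e * part[cl, j] + (1.0 - e) * dot
            m = part[li, 0]
            for j in range(1, k):
                if part[li, j] > m:
                    m = part[li, j]
            if m <= 0.0:
                return -np.inf
            for j in range(k):
                part[li, j] /= m
            logscale += np.log(m)
    tot = 0.0
    for j in range(k):
        tot += pi[j] * part[n - 1, j]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


@njit(cache=True)
def _log_prior(logmu, prior_kind, p1, p2):
    """Log prior density of mu plus the log-Jacobian of the log transform.

    prior_kind 0: exponential(rate=p1) on mu -> -p1*mu + logmu (+const).
    prior_kind 1: uniform(p1, p2) on mu -> logmu if inside, else -inf.
    """
    mu = np.exp(logmu)
    if prior_kind == 0:
        return -p1 * mu + logmu
    if mu < p1 or mu > p2:
        return -np.inf
    return logmu


@njit(cache=True)
def joint_loglik(param, pi_flat, pi_off, fac, tipstates, off0, off1,
                 child_ptr, child_idx, edge_len, leaf_taxon):
    """Sum of pruning log-likelihoods over characters sharing one rate
    parameter: character c evolves with mu_c = param * fac[c]."""
    tot = 0.0
    for c in range(fac.shape[0]):
        pi = pi_flat[pi_off[c]:pi_off[c + 1]]
        tot += tree_loglik(param * fac[c], pi, off0, off1,
                           child_ptr, child_idx, edge_len, leaf_taxon, tipstates[c])
        if tot == -np.inf:
            return -np.inf
    return tot


@njit(cache=True)
def run_chain(
    logmu0,
    tree0,
    pi_flat,
    pi_off,
    fac,
    node_offset,
    child_ptr,
    child_idx,
    edge_len,
    leaf_taxon,
    tipstates,
    z,
    u_acc,
    u_move,
    tree_prop,
    total,
    burn_in,
    thin,
    step0,
    prior_kind,
    p1,
    p2,
    power,
    scheme,
    adapt_interval,
):
    """Metropolis sampler on log mu with tree moves over the sample.

    scheme 0 ("random"): each iteration proposes, with probability 0.5, a
    uniform tree swap (MH-accepted), else a Gaussian step on log mu.
    scheme 1 ("sequential"): the tree cycles deterministically through the
    sample in equal chunks; every iteration is a rate move.

    The likelihood enters with exponent ``power`` (1 = posterior, 0 = prior
    only; intermediate values give the stepping-stone power posteriors). The
    proposal step adapts toward 0.2-0.4 acceptance during burn-in only.

    Returns (logmu draws, tree index draws, unpowered loglik draws,
    rate-move acceptance rate, final step).
    """
    n_trees = node_offset.shape[0] - 1
    n_out = (total - burn_in) // thin
    out_logmu = np.empty(n_out)
    out_tree = np.empty(n_out, dtype=np.int64)
    out_ll = np.empty(n_out)

    logmu = logmu0
    tree = tree0
    mu = np.exp(logmu)
    ll = joint_loglik(mu, pi_flat, pi_off, fac, tipstates,
                      node_offset[tree], node_offset[tree + 1],
                      child_ptr, child_idx, edge_len, leaf_taxon)
    lp = _log_prior(logmu, prior_kind, p1, p2)

    step = step0
    acc = 0
    tries = 0
    acc_total = 0
    tries_total = 0
    chunk = max(1, total // n_trees) if scheme == 1 else 1
    out_i = 0
    for i in range(total):
        if scheme == 1:
            want = (i // chunk) % n_trees
            if want != tree:
                tree = want
                ll = joint_loglik(mu, pi_flat, pi_off, fac, tipstates,
                                  node_offset[tree], node_offset[tree + 1],
                                  child_ptr, child_idx, edge_len, leaf_taxon)
            do_tree_move = False
        else:
            do_tree_move = n_trees > 1 and u_move[i] < 0.5
        if do_tree_move:
            cand = tree_prop[i]
            ll_new = joint_loglik(mu, pi_flat, pi_off, fac, tipstates,
                                  node_offset[cand], node_offset[cand + 1],
                                  child_ptr, child_idx, edge_len, leaf_taxon)
            if np.log(u_acc[i]) < power * (ll_new - ll):
                tree = cand
                ll = ll_new
        else:
            logmu_new = logmu + step * z[i]
            mu_new = np.exp(logmu_new)
            lp_new = _log_prior(logmu_new, prior_kind, p1, p2)
            if lp_new > -np.inf:
                ll_new = joint_loglik(mu_new, pi_flat, pi_off, fac, tipstates,
                                       node_offset[tree], node_offset[tree + 1],
                                       child_ptr, child_idx, edge_len, leaf_taxon)
                ratio = power * (ll_new - ll) + (lp_new - lp)
            else:
                ll_new = -np.inf
                ratio = -np.inf
            tries += 1
            tries_total += 1
            if np.log(u_acc[i]) < ratio:
                logmu = logmu_new
                mu = mu_new
                ll = ll_new
                lp = lp_new
                acc += 1
                acc_total += 1
            if i < burn_in and tries >= adapt_interval:
                frac = acc / tries
                if frac < 0.2:
                    step *= 0.8
                elif frac > 0.4:
                    step *= 1.25
                acc = 0
                tries = 0
        if i + 1 > burn_in and (i + 1 - burn_in) % thin == 0:
            out_logmu[out_i] = logmu
            out_tree[out_i] = tree
            out_ll[out_i] = ll
            out_i += 1
    acc_rate = acc_total / tries_total if tries_total > 0 else 0.0
    return out_logmu, out_tree, out_ll, acc_rate, step
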