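"""Compiled inner loops for the diploid haplotype-copying HMM.

The hidden state at site m is the ordered pair (i, j) of copied reference
haplotypes; the two chains transition independently with the exchangeable
"stay or jump to a uniform haplotype" kernel A = (1-tau) I + (tau/K) 11'.
That kernel is doubly stochastic, so transitions preserve total forward mass;
messages are kept as K x K matrices and updated in O(K^2) per site via the
rank structure of A:

    F'[i,j] = q^2 F[i,j] + q*theta*(r_i + c_j) + theta^2 * S

with q = 1-tau, theta = tau/K, r/c the row/column sums and S the total mass.
Emissions depend on the copied allele pair only, so each site contributes a
4-value lookup expanded once into two length-K vectors (one per allele of
chain one), keeping the K x K sweeps branch-free and vectorizable.  Messages
are rescaled to unit mass at every site, so nothing underflows even at
L = 1e5.

Memory: storing forward messages at every site would need L*K^2 floats, so
the backward pass recomputes them blockwise from sqrt(L)-spaced forward
checkpoints (classic checkpointing; costs one extra forward sweep).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _forward_step(F, out, e0, e1, a_is_alt, tau):
    """out = emission o (A x A) F across one gap; returns total mass of out.

    e0/e1 are the per-site emission vectors over chain-two haplotypes given
    chain-one copies a REF (e0) or ALT (e1) allele; a_is_alt flags chain-one
    rows carrying ALT at this site.
    """
    K = F.shape[0]
    q = 1.0 - tau
    theta = tau / K
    # fused row/column sums
    r = np.empty(K)
    c = np.zeros(K)
    S = 0.0
    for i in range(K):
        ri = 0.0
        Fi = F[i]
        for j in range(K):
            v = Fi[j]
            ri += v
            c[j] += v
        r[i] = ri
        S += ri
    q2 = q * q
    qt = q * theta
    t2 = theta * theta * S
    tot = 0.0
    for i in range(K):
        base_i = qt * r[i] + t2
        e = e1 if a_is_alt[i] else e0
        Fi = F[i]
        Oi = out[i]
        for j in range(K):
            v = (q2 * Fi[j] + qt * c[j] + base_i) * e[j]
            Oi[j] = v
            tot += v
    return tot


@njit(cache=True, fastmath=True)
def _backward_step(B, e0, e1, a_is_alt, tau):
    """B <- (A x A)(E_m o B) in place (A is symmetric); returns total mass."""
    K = B.shape[0]
    q = 1.0 - tau
    theta = tau / K
    r = np.empty(K)
    c = np.zeros(K)
    S = 0.0
    for i in range(K):
        e = e1 if a_is_alt[i] else e0
        Bi = B[i]
        ri = 0.0
        for j in range(K):
            v = Bi[j] * e[j]
            Bi[j] = v
            ri += v
            c[j] += v
        r[i] = ri
        S += ri
    q2 = q * q
    qt = q * theta
    t2 = theta * theta * S
    tot = 0.0
    for i in range(K):
        base_i = qt * r[i] + t2
        Bi = B[i]
        for j in range(K):
            v = q2 * Bi[j] + qt * c[j] + base_i
            Bi[j] = v
            tot += v
    return tot


@njit(cache=True, fastmath=True)
def _scale(M, tot):
    inv = 1.0 / tot
    K = M.shape[0]
    for i in range(K):
        for j in range(K):
            M[i, j] *= inv


@njit(cache=True, fastmath=True)
def diploid_forward_backward(alleles_t, em, tau, gpred):
    """Exact genotype posteriors for the diploid copying HMM.

    Parameters
    ----------
    alleles_t : (L, K) uint8 site-major panel alleles
    em : (L, 4) emission lookup per allele class (2*a1 + a2); all-ones rows at
        missing sites
    tau : (L,) switch probability across the gap ending at each site (tau[0]
        is ignored)
    gpred : (4, 3) genotype predictive P(g | a1, a2, eps) per allele class

    Returns
    -------
    post : (L, 3) posterior P(G_m = g | all observations); rows sum to 1
    loglik : float, log total observation likelihood
    """
    L, K = alleles_t.shape
    post = np.zeros((L, 3))
    if L == 0:
        return post, 0.0

    # per-site emission vectors and allele flags/floats
    aflag = alleles_t != 0  # (L, K) bool
    afl = alleles_t.astype(np.float64)  # float mask for branch-free sweeps
    e0 = np.empty((L, K))
    e1 = np.empty((L, K))
    for m in range(L):
        for j in range(K):
            aj = alleles_t[m, j]
            e0[m, j] = em[m, aj]
            e1[m, j] = em[m, 2 + aj]

    block = int(math.sqrt(L)) + 1
    n_blocks = (L + block - 1) // block
    checkpoints = np.empty((n_blocks, K, K))
    buf = np.empty((block, K, K))

    # ---- forward pass, storing block-start checkpoints ----
    F = np.empty((K, K))
    tot = 0.0
    for i in range(K):
        e = e1[0] if aflag[0, i] else e0[0]
        for j in range(K):
            F[i, j] = e[j]
            tot += e[j]
    loglik = math.log(tot / (K * K))
    _scale(F, tot)
    scratch = np.empty((K, K))
    for m in range(L):
        if m % block == 0:
            checkpoints[m // block] = F
        if m + 1 < L:
            tot = _forward_step(F, scratch, e0[m + 1], e1[m + 1], aflag[m + 1], tau[m + 1])
            loglik += math.log(tot)
            _scale(scratch, tot)
            F, scratch = scratch, F

    # ---- backward pass with blockwise forward recomputation ----
    B = np.full((K, K), 1.0 / (K * K))
    for b in range(n_blocks - 1, -1, -1):
        s = b * block
        e = min(s + block, L)
        buf[0] = checkpoints[b]
        for m in range(s + 1, e):
            t = _forward_step(buf[m - s - 1], buf[m - s], e0[m], e1[m], aflag[m], tau[m])
            _scale(buf[m - s], t)
        for m in range(e - 1, s - 1, -1):
            Fm = buf[m - s]
            # genotype posterior via the 2x2 allele-class mass of gamma = F o B
            c0 = 0.0  # (ref, ref)
            c1 = 0.0  # (ref, alt)
            c2 = 0.0  # (alt, ref)
            c3 = 0.0  # (alt, alt)
            am = afl[m]
            for i in range(K):
                Fi = Fm[i]
                Bi = B[i]
                s_ref = 0.0
                s_alt = 0.0
                for j in range(K):
                    w = Fi[j] * Bi[j]
                    wa = w * am[j]
                    s_alt += wa
                    s_ref += w - wa
                if aflag[m, i]:
                    c2 += s_ref
                    c3 += s_alt
                else:
                    c0 += s_ref
                    c1 += s_alt
            z = c0 + c1 + c2 + c3
            for g in range(3):
                post[m, g] = (
                    c0 * gpred[0, g] + c1 * gpred[1, g] + c2 * gpred[2, g] + c3 * gpred[3, g]
                ) / z
            if m > 0:
                t = _backward_step(B, e0[m], e1[m], aflag[m], tau[m])
                _scale(B, t)
    return post, loglik
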