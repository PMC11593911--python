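"""Independent oracles and small instance builders shared across tests.

The brute-force posterior here enumerates every hidden-state path of the
diploid copying model explicitly (transition matrices built densely, path
weights multiplied out), sharing no code path with the package's
forward-backward implementation.
"""

from __future__ import annotations

import numpy as np

from snpimpute.types import MISSING, HaplotypePanel, ObservedGenotypes, SiteTable, TruthGenotypes


def make_sites(positions, chrom="1", rate_cm_per_mb=1.0) -> SiteTable:
    positions = np.asarray(positions, dtype=np.int64)
    L = len(positions)
    return SiteTable(
        chrom,
        positions,
        np.array(["A"] * L),
        np.array(["C"] * L),
        rate_cm_per_mb * positions / 1e6,
    )


def make_panel(alleles, positions=None, pops=None) -> HaplotypePanel:
    alleles = np.asarray(alleles, dtype=np.uint8)
    K, L = alleles.shape
    if positions is None:
        positions = 1000 * (1 + np.arange(L))
    labels = np.array(["pop1"] * K if pops is None else pops, dtype=object)
    return HaplotypePanel(make_sites(positions), alleles, labels)


def make_obs(sites: SiteTable, g_obs, truth=None) -> ObservedGenotypes:
    return ObservedGenotypes(sites, np.asarray(g_obs, dtype=np.int8), truth=truth)


def make_truth(sites: SiteTable, g) -> TruthGenotypes:
    return TruthGenotypes(sites, np.asarray(g, dtype=np.int8))


def genotype_table(eps: float) -> np.ndarray:
    """P(g | a1, a2) per allele class, written out independently of the package."""
    t = np.empty((4, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            pa = [1 - eps, eps] if a1 == 0 else [eps, 1 - eps]
            pb = [1 - eps, eps] if a2 == 0 else [eps, 1 - eps]
            t[2 * a1 + a2] = [pa[0] * pb[0], pa[0] * pb[1] + pa[1] * pb[0], pa[1] * pb[1]]
    return t


def brute_force_posteriors(alleles, g_obs, cm, ne, eps):
    """Genotype posteriors by exhaustive enumeration over all (K^2)^L paths."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    g_obs = np.asarray(g_obs)
    K, L = alleles.shape
    S = K * K
    gtab = genotype_table(eps)
    # per-state allele class at each site
    cls = np.empty((S, L), dtype=np.int64)
    s = 0
    for i in range(K):
        for j in range(K):
            cls[s] = 2 * alleles[i] + alleles[j]
            s += 1
    E = np.ones((S, L))
    for m in range(L):
        if g_obs[m] != MISSING:
            E[:, m] = gtab[cls[:, m], g_obs[m]]
    joint_T = []
    for m in range(1, L):
        tau = 1.0 - np.exp(-4.0 * ne * ((cm[m] - cm[m - 1]) / 100.0) / K)
        A = np.full((K, K), tau / K) + (1.0 - tau) * np.eye(K)
        joint_T.append(np.kron(A, A))
    n_paths = S**L
    idx = np.arange(n_paths)
    states = np.empty((n_paths, L), dtype=np.int64)
    for m in range(L):
        states[:, m] = (idx // S**m) % S
    w = np.full(n_paths, 1.0 / S)
    for m in range(L):
        w *= E[states[:, m], m]
        if m + 1 < L:
            w *= joint_T[m][states[:, m], states[:, m + 1]]
    post = np.empty((L, 3))
    for m in range(L):
        c = cls[states[:, m], m]
        for g in range(3):
            post[m, g] = np.sum(w * gtab[c, g])
    post /= post.sum(axis=1, keepdims=True)
    return post


def random_small_instance(rng, k_max=4, l_max=5):
    """A random tiny HMM instance (panel, observation, cm, ne, eps)."""
    K = int(rng.integers(2, k_max + 1))
    L = int(rng.integers(1, l_max + 1))
    alleles = rng.integers(0, 2, size=(K, L)).astype(np.uint8)
    g_obs = rng.choice([MISSING, 0, 1, 2], size=L).astype(np.int8)
    pos = np.cumsum(rng.integers(1, 3000, size=L))
    ne = float(rng.uniform(100, 50_000))
    eps = float(rng.uniform(1e-4, 0.1))
    return alleles, g_obs, pos, ne, eps
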