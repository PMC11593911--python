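"""Diploid Li-Stephens haplotype-copying HMM for genotype imputation.

The target's unphased genotype sequence is modelled as emissions from an
ordered pair of hidden reference haplotypes (K^2 states for a K-haplotype
panel).  Each chain copies one panel haplotype and switches with probability
tau(d) = 1 - exp(-4 Ne (d/100) / K) across a gap of d centiMorgans; copied
alleles are mis-read with per-allele probability eps.  Forward-backward gives
the exact posterior over the three diploid genotypes at every site; the
maximum posterior is the genotype probability (GP) used for threshold calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import diploid_forward_backward
from .types import MISSING, GeneticMap, HaplotypePanel, ObservedGenotypes

SOURCE_NONE = -1
SOURCE_OBSERVED = 0
SOURCE_IMPUTED = 1


@dataclass
class HMMParams:
    """Copying-model parameters.

    ne scales recombination intensity (default 10,000 — a conventional
    human-scale value for this parameterization); eps is the per-allele
    miscopy probability.  With auto_eps the Watterson-theta heuristic
    eps = theta/(2(theta+K)), theta = 1/sum_{i<K} 1/i, replaces eps.
    """

    ne: float = 1e4
    eps: float = 1e-3
    auto_eps: bool = False

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must be in [0, 0.5)")

    def effective_eps(self, k: int) -> float:
        if not self.auto_eps:
            return self.eps
        theta = 1.0 / sum(1.0 / i for i in range(1, max(k, 2)))
        return theta / (2.0 * (theta + k))


@dataclass
class PosteriorField:
    """Per-site genotype posteriors plus derived dosage / GP summaries."""

    p: np.ndarray  # (L, 3) posterior over genotypes 0/1/2
    loglik: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 2 or self.p.shape[1] != 3:
            raise ValueError("posterior must be (L, 3)")

    @property
    def L(self) -> int:
        return self.p.shape[0]

    @property
    def dosage(self) -> np.ndarray:
        return self.p[:, 1] + 2.0 * self.p[:, 2]

    @property
    def gp(self) -> np.ndarray:
        return self.p.max(axis=1)

    @property
    def argmax_genotype(self) -> np.ndarray:
        # np.argmax takes the first maximum: ties break toward the lower code
        return self.p.argmax(axis=1).astype(np.int8)


@dataclass
class CalledGenotypes:
    """Observed genotypes merged with threshold-passing imputed genotypes."""

    sites: object
    genotype: np.ndarray  # (L,) int8 in {0,1,2} or MISSING
    source: np.ndarray  # (L,) SOURCE_* codes
    gp: np.ndarray  # (L,) GP of the call (1.0 at observed sites by convention)
    q_gp: float = float("nan")

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.source == SOURCE_OBSERVED))

    @property
    def n_imputed(self) -> int:
        return int(np.sum(self.source == SOURCE_IMPUTED))


def switch_probability(d_cm: float, ne: float, k: int) -> float:
    """tau = 1 - exp(-4 Ne (d/100) / K): probability the copying chain jumps
    (to a uniformly chosen haplotype, possibly itself) across a d-cM gap."""
    if d_cm < 0:
        raise ValueError("distance must be non-negative")
    if ne <= 0 or k < 1:
        raise ValueError("ne must be > 0 and k >= 1")
    return 1.0 - math.exp(-4.0 * ne * (d_cm / 100.0) / k)


def genotype_predictive_table(eps: float) -> np.ndarray:
    """(4, 3) table P(g | a1, a2, eps) indexed by allele class 2*a1 + a2.

    Per-allele copy distribution P(x | a) = 1-eps if x == a else eps; genotype
    0/2 multiply the two per-allele terms, the heterozygote sums both
    orderings.  Rows sum to 1.
    """
    out = np.empty((4, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            p0_1 = 1.0 - eps if a1 == 0 else eps
            p0_2 = 1.0 - eps if a2 == 0 else eps
            out[2 * a1 + a2, 0] = p0_1 * p0_2
            out[2 * a1 + a2, 1] = p0_1 * (1.0 - p0_2) + (1.0 - p0_1) * p0_2
            out[2 * a1 + a2, 2] = (1.0 - p0_1) * (1.0 - p0_2)
    return out


def emission_probability(g_obs: int, a1: int, a2: int, eps: float) -> float:
    """P(observed genotype | copied allele pair); MISSING observations emit 1."""
    if a1 not in (0, 1) or a2 not in (0, 1):
        raise ValueError("alleles must be 0/1")
    if g_obs == MISSING:
        return 1.0
    if g_obs not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {g_obs}")
    return float(genotype_predictive_table(eps)[2 * a1 + a2, g_obs])


def forward_backward(
    panel: HaplotypePanel,
    obs: ObservedGenotypes,
    gmap: GeneticMap,
    params: HMMParams | None = None,
) -> PosteriorField:
    """Exact posterior genotype probabilities at every target site.

    The panel and the observation must share one ordered site list (use
    :func:`align_to_panel` to expand a target typed on a subset of the panel's
    sites).
    """
    params = params or HMMParams()
    if panel.K < 2:
        raise ValueError("panel must contain at least 2 haplotypes")
    if not panel.sites.equals(obs.sites):
        raise ValueError("panel and observation site lists differ")
    L, K = panel.L, panel.K
    eps = params.effective_eps(K)
    gpred = genotype_predictive_table(eps)
    if L == 0:
        return PosteriorField(np.zeros((0, 3)), 0.0)

    cm = gmap.cm_at(panel.sites.pos)
    d_cm = np.diff(cm, prepend=cm[0] if L else 0.0)
    tau = 1.0 - np.exp(-4.0 * params.ne * (np.maximum(d_cm, 0.0) / 100.0) / K)

    em = np.ones((L, 4))
    typed = obs.g_obs != MISSING
    em[typed] = gpred[:, obs.g_obs[typed]].T

    alleles_t = np.ascontiguousarray(panel.alleles.T)
    post, loglik = diploid_forward_backward(alleles_t, em, tau, gpred)
    return PosteriorField(post, float(loglik))


def call_imputed(
    post: PosteriorField, obs: ObservedGenotypes, q_gp: float
) -> CalledGenotypes:
    """Merge observations with imputed genotypes whose GP meets the threshold.

    Observed sites pass through unchanged; a missing site is imputed with the
    argmax genotype when its GP >= q_gp (inclusive, "met or exceeded"), and
    stays missing otherwise.
    """
    if not 0.0 <= q_gp <= 1.0:
        raise ValueError("q_gp must be in [0, 1]")
    if post.L != obs.L:
        raise ValueError("posterior/observation length mismatch")
    genotype = obs.g_obs.copy()
    source = np.full(obs.L, SOURCE_NONE, dtype=np.int8)
    gp_out = np.zeros(obs.L)
    typed = obs.g_obs != MISSING
    source[typed] = SOURCE_OBSERVED
    gp_out[typed] = 1.0
    gp = post.gp
    imp = (~typed) & (gp >= q_gp)
    genotype[imp] = post.argmax_genotype[imp]
    source[imp] = SOURCE_IMPUTED
    gp_out[imp] = gp[imp]
    return CalledGenotypes(obs.sites, genotype, source, gp_out, q_gp)


def align_to_panel(obs: ObservedGenotypes, panel: HaplotypePanel):
    """Expand a target typed on a subset of panel sites onto the panel's list.

    Returns (aligned ObservedGenotypes, unimputable mask over the *original*
    obs sites).  Target sites absent from the panel cannot be imputed (their
    alleles are unrepresented in the reference) and are reported in the mask.
    """
    key_panel = {(int(p), r, a): m for m, (p, r, a) in enumerate(
        zip(panel.sites.pos, panel.sites.ref, panel.sites.alt))}
    g_new = np.full(panel.L, MISSING, dtype=np.int8)
    unimputable = np.zeros(obs.L, dtype=bool)
    for m, (p, r, a) in enumerate(zip(obs.sites.pos, obs.sites.ref, obs.sites.alt)):
        idx = key_panel.get((int(p), r, a))
        if idx is None:
            unimputable[m] = True
        else:
            g_new[idx] = obs.g_obs[m]
    return ObservedGenotypes(panel.sites, g_new, truth=None), unimputable
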