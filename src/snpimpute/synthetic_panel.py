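"""Synthetic phased reference panels with tunable LD and population structure.

The generator stands in for a real phased panel (e.g. 1000 Genomes chr22): it
draws founder haplotypes with a Beta allele-frequency spectrum, then expands
them into a larger panel of founder *mosaics* whose switch points follow a
Poisson process on the centiMorgan scale.  Mosaic copying from a finite founder
pool is exactly the statistical structure a haplotype-copying imputation model
exploits, which makes it a controlled test bed: LD strength is set by the
number of mosaic generations, divergence between populations by a
Balding-Nichols frequency perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import GeneticMap, HaplotypePanel, SiteTable, TruthGenotypes, TruthSample

_NUCS = np.array(list("ACGT"))


@dataclass
class PopulationSplitConfig:
    """How to split founders into diverged populations.

    divergence is interpreted as the target Fst between each population and the
    founder (ancestral) pool, Balding-Nichols style; 0 means the populations are
    statistically identical.
    """

    n_pops: int
    divergence: float
    sizes: tuple

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if len(self.sizes) != self.n_pops:
            raise ValueError("sizes must have one entry per population")
        if any(s < 0 for s in self.sizes):
            raise ValueError("population sizes must be non-negative")


def make_genetic_map(positions, rate_cm_per_mb: float) -> GeneticMap:
    """Exact linear map: cm(pos) = rate * pos / 1e6."""
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) == 0:
        raise ValueError("need at least one position")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted ascending")
    if rate_cm_per_mb < 0:
        raise ValueError("rate must be non-negative")
    return GeneticMap(positions.astype(float), rate_cm_per_mb * positions / 1e6)


def simulate_founders(
    n_founders: int,
    n_sites: int,
    maf_min: float = 0.02,
    seed: int = 0,
    *,
    beta_a: float = 0.8,
    beta_b: float = 0.8,
    chrom: str = "22",
    mean_spacing_bp: int = 1000,
    rate_cm_per_mb: float = 1.0,
    pop_label: str = "pop1",
) -> HaplotypePanel:
    """Independent-site founder haplotypes with a truncated-Beta frequency spectrum.

    Target ALT frequencies are drawn from Beta(beta_a, beta_b) truncated to
    [maf_min, 1 - maf_min]; each site's allele column is redrawn (fresh
    frequency included) until the panel minor-allele count reaches
    max(1, ceil(maf_min * n_founders)), so every site is polymorphic.
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    min_count = max(1, math.ceil(maf_min * n_founders))
    if min_count > n_founders // 2:
        raise ValueError(
            f"maf_min={maf_min} unreachable with {n_founders} founders "
            f"(minimum representable MAF is 1/{n_founders})"
        )
    rng = np.random.default_rng(seed)

    gaps = rng.integers(1, 2 * mean_spacing_bp, size=n_sites)
    pos = np.cumsum(gaps)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    def draw_freqs(n: int) -> np.ndarray:
        lo, hi = maf_min, 1.0 - maf_min
        out = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.beta(beta_a, beta_b, size=max(n - filled, 16))
            cand = cand[(cand >= lo) & (cand <= hi)]
            take = min(len(cand), n - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
        return out

    p = draw_freqs(n_sites)
    alleles = (rng.random((n_founders, n_sites)) < p).astype(np.uint8)
    while True:
        counts = alleles.sum(axis=0)
        bad = np.flatnonzero(np.minimum(counts, n_founders - counts) < min_count)
        if len(bad) == 0:
            break
        p_bad = draw_freqs(len(bad))
        alleles[:, bad] = (rng.random((n_founders, len(bad))) < p_bad).astype(np.uint8)

    sites = SiteTable(chrom, pos, _NUCS[ref_idx], _NUCS[alt_idx], rate_cm_per_mb * pos / 1e6)
    return HaplotypePanel(sites, alleles, np.array([pop_label] * n_founders, dtype=object))


def _mosaic_rows(
    founder_alleles: np.ndarray,
    n_out: int,
    cm: np.ndarray,
    n_generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mosaic haplotypes: copy a founder, switch to a uniformly drawn founder at
    Poisson(n_generations per Morgan) points along the cM axis."""
    k_f, n_sites = founder_alleles.shape
    if n_sites == 0:
        return np.zeros((n_out, 0), dtype=np.uint8)
    if n_generations == 0:
        idx = np.arange(n_out) % k_f  # balanced cycling: conserves frequencies
        return founder_alleles[idx].copy()
    d_cm = np.diff(cm)
    p_switch = 1.0 - np.exp(-n_generations * d_cm / 100.0)
    out = np.empty((n_out, n_sites), dtype=np.uint8)
    cols = np.arange(n_sites)
    for h in range(n_out):
        switches = np.concatenate(([True], rng.random(n_sites - 1) < p_switch))
        seg_id = np.cumsum(switches) - 1
        seg_founder = rng.integers(0, k_f, size=seg_id[-1] + 1)
        out[h] = founder_alleles[seg_founder[seg_id], cols]
    return out


def recombine_panel(
    founders: HaplotypePanel,
    n_haplotypes: int,
    gmap: GeneticMap,
    n_generations: int,
    seed: int = 0,
) -> HaplotypePanel:
    """Expand a founder set into n_haplotypes mosaic haplotypes.

    n_generations = 0 returns balanced copies of the founder rows (cycled), so
    allele frequencies are conserved exactly when n_haplotypes is a multiple of
    the founder count.
    """
    if founders.K == 0:
        raise ValueError("founder panel is empty")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    cm = gmap.cm_at(founders.sites.pos)
    alleles = _mosaic_rows(founders.alleles, n_haplotypes, cm, n_generations, rng)
    labels = founders.pop_labels.astype(str)
    label = labels[0] if len(set(labels)) <= 1 else "mixed"
    return HaplotypePanel(founders.sites, alleles, np.array([label] * n_haplotypes, dtype=object))


def _perturb_founders(
    founder_alleles: np.ndarray, p_target: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Flip the minimum number of entries per site so the founder ALT count hits
    round(p_target * K); flips chosen uniformly among eligible rows.  Keeps the
    founder haplotype backbone (hence LD) while shifting frequencies."""
    out = founder_alleles.copy()
    k_f = out.shape[0]
    target = np.rint(p_target * k_f).astype(int)
    current = out.sum(axis=0).astype(int)
    delta = target - current
    for m in np.flatnonzero(delta):
        d = delta[m]
        if d > 0:
            eligible = np.flatnonzero(out[:, m] == 0)
            flip = rng.choice(eligible, size=min(d, len(eligible)), replace=False)
            out[flip, m] = 1
        else:
            eligible = np.flatnonzero(out[:, m] == 1)
            flip = rng.choice(eligible, size=min(-d, len(eligible)), replace=False)
            out[flip, m] = 0
    return out


def split_populations(
    founders: HaplotypePanel,
    config: PopulationSplitConfig,
    gmap: GeneticMap,
    seed: int = 0,
    *,
    n_generations: int = 1000,
) -> HaplotypePanel:
    """Derive labelled populations from one founder pool.

    Per population: draw site frequencies from the Balding-Nichols distribution
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the founder frequency p with
    F = divergence, shift the shared founder matrix to those frequencies by
    exact-count allele flips, then re-simulate that population's haplotypes as
    mosaics of its perturbed founders.
    """
    rng = np.random.default_rng(seed)
    p = founders.allele_freqs()
    cm = gmap.cm_at(founders.sites.pos)
    blocks, labels = [], []
    for k, size in enumerate(config.sizes):
        tag = f"pop{k + 1}"
        if config.divergence > 0 and founders.L > 0:
            F = config.divergence
            scale = (1.0 - F) / F
            p_k = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))
            pf = _perturb_founders(founders.alleles, p_k, rng)
        else:
            pf = founders.alleles
        blocks.append(_mosaic_rows(pf, size, cm, n_generations, rng))
        labels.extend([tag] * size)
    alleles = (
        np.concatenate(blocks, axis=0)
        if blocks
        else np.zeros((0, founders.L), dtype=np.uint8)
    )
    return HaplotypePanel(founders.sites, alleles, np.array(labels, dtype=object))


def _copying_path_hap(
    alleles: np.ndarray, cm: np.ndarray, ne: float, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype sampled from the copying process over the given rows:
    switch with probability 1 - exp(-4 Ne (d/100) / k) per cM gap, jumping to a
    uniformly drawn row."""
    k, n_sites = alleles.shape
    tau = 1.0 - np.exp(-4.0 * ne * (np.diff(cm) / 100.0) / k)
    switches = np.concatenate(([True], rng.random(n_sites - 1) < tau))
    seg_id = np.cumsum(switches) - 1
    seg_row = rng.integers(0, k, size=seg_id[-1] + 1)
    return alleles[seg_row[seg_id], np.arange(n_sites)]


def sample_truth_individual(
    panel: HaplotypePanel,
    pop: str = "any",
    seed: int = 0,
    *,
    recombine: bool = False,
    ne: float = 1e4,
) -> TruthSample:
    """Draw a diploid test individual from the panel.

    Default: two panel haplotypes without replacement (their row indices are
    reported and must be excluded from the reference before imputation).  With
    recombine=True each drawn haplotype is passed through one extra
    recombination step: it is re-sampled as a copying-process mosaic of the
    *other* eligible panel haplotypes, so the test individual is a recombinant
    relative of the reference population rather than a literal copy of two
    panel donors — the situation a real test sample is in once removed from
    the panel it came from.
    """
    rng = np.random.default_rng(seed)
    if pop == "any":
        eligible = np.arange(panel.K)
    else:
        eligible = np.flatnonzero(panel.pop_labels.astype(str) == pop)
    if len(eligible) < 2:
        raise ValueError(f"fewer than 2 haplotypes with tag {pop!r}")
    i, j = rng.choice(eligible, size=2, replace=False)
    others = eligible[(eligible != i) & (eligible != j)]
    if recombine and len(others) >= 2 and panel.L > 0:
        cm = panel.sites.cm
        h1 = _copying_path_hap(panel.alleles[others], cm, ne, rng)
        h2 = _copying_path_hap(panel.alleles[others], cm, ne, rng)
        g = h1.astype(np.int8) + h2.astype(np.int8)
    else:
        g = panel.alleles[i].astype(np.int8) + panel.alleles[j].astype(np.int8)
    tag = pop if pop != "any" else str(panel.pop_labels[i])
    return TruthSample(TruthGenotypes(panel.sites, g), (int(i), int(j)), tag)


def estimate_fst(panel: HaplotypePanel, pop_a: str, pop_b: str) -> float:
    """Hudson ratio-of-averages Fst between two labelled haploid samples."""
    labels = panel.pop_labels.astype(str)
    xa = panel.alleles[labels == pop_a]
    xb = panel.alleles[labels == pop_b]
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 haplotypes per population")
    p1, p2 = xa.mean(axis=0), xb.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (na - 1) - p2 * (1 - p2) / (nb - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def mean_r2_by_distance(
    panel: HaplotypePanel, bins_cm, max_pairs_per_bin: int = 20000, seed: int = 0
) -> np.ndarray:
    """Mean pairwise r² between sites, binned by cM distance (LD-decay summary)."""
    rng = np.random.default_rng(seed)
    cm = panel.sites.cm
    x = panel.alleles.astype(np.float64)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    usable = sd > 0
    out = np.full(len(bins_cm) - 1, np.nan)
    for b in range(len(bins_cm) - 1):
        lo, hi = bins_cm[b], bins_cm[b + 1]
        pairs = []
        for _ in range(max_pairs_per_bin):
            i = rng.integers(0, panel.L)
            # find a partner within the distance window
            j_lo = np.searchsorted(cm, cm[i] + lo)
            j_hi = np.searchsorted(cm, cm[i] + hi)
            if j_hi <= j_lo:
                continue
            j = rng.integers(j_lo, j_hi)
            if usable[i] and usable[j]:
                pairs.append((i, j))
            if len(pairs) >= max_pairs_per_bin // 10:
                break
        if pairs:
            idx = np.array(pairs)
            r = (x[:, idx[:, 0]] * x[:, idx[:, 1]]).mean(axis=0) / (
                sd[idx[:, 0]] * sd[idx[:, 1]]
            )
            out[b] = float(np.mean(r**2))
    return out
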