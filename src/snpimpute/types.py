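"""Core containers shared across the pipeline.

Conventions used throughout the package:

* genotypes are alt-allele counts in ``{0, 1, 2}``; ``MISSING = -1``
* haplotype alleles are ``{0, 1}`` (0 = REF, 1 = ALT)
* physical positions are 1-based (VCF convention); genetic-map positions are
  centiMorgans and non-decreasing with position
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

# provenance codes for observed genotypes
OBSERVED = 0
OBSERVED_ERRONEOUS = 1
PROV_MISSING = 2

PROV_CHAR = {OBSERVED: "O", OBSERVED_ERRONEOUS: "E", PROV_MISSING: "M"}
PROV_FROM_CHAR = {v: k for k, v in PROV_CHAR.items()}


@dataclass
class SiteTable:
    """Ordered biallelic-SNP site metadata (struct-of-arrays form of per-site records)."""

    chrom: str
    pos: np.ndarray  # int64, 1-based, strictly increasing
    ref: np.ndarray  # single-character nucleotide codes
    alt: np.ndarray
    cm: np.ndarray  # float64, non-decreasing genetic-map position

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        self.alt = np.asarray(self.alt, dtype="<U1")
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if not (len(self.pos) == len(self.ref) == len(self.alt) == len(self.cm)):
            raise ValueError("site arrays must have equal length")
        if len(self.pos) > 1:
            if np.any(np.diff(self.pos) <= 0):
                raise ValueError("positions must be strictly increasing")
            if np.any(np.diff(self.cm) < 0):
                raise ValueError("cM positions must be non-decreasing")
        if len(self.pos) and np.any(self.ref == self.alt):
            raise ValueError("ref and alt alleles must differ")

    def __len__(self) -> int:
        return len(self.pos)

    def subset(self, idx: np.ndarray) -> "SiteTable":
        return SiteTable(self.chrom, self.pos[idx], self.ref[idx], self.alt[idx], self.cm[idx])

    def equals(self, other: "SiteTable") -> bool:
        return (
            self.chrom == other.chrom
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        )


def _default_hap_ids(k: int) -> np.ndarray:
    return np.array([f"S{i // 2:04d}_{i % 2}" for i in range(k)], dtype=object)


@dataclass
class HaplotypePanel:
    """A phased reference panel: K haplotypes over L ordered biallelic sites."""

    sites: SiteTable
    alleles: np.ndarray  # (K, L) uint8 in {0, 1}
    pop_labels: np.ndarray  # (K,) population tag per haplotype
    hap_ids: np.ndarray | None = None  # (K,) "sample_0"/"sample_1" style ids

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a (K, L) matrix")
        if self.alleles.shape[1] != len(self.sites):
            raise ValueError("alleles/site length mismatch")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be 0/1")
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if len(self.pop_labels) != self.alleles.shape[0]:
            raise ValueError("pop_labels length must equal K")
        if self.hap_ids is None:
            self.hap_ids = _default_hap_ids(self.alleles.shape[0])
        else:
            self.hap_ids = np.asarray(self.hap_ids, dtype=object)
            if len(self.hap_ids) != self.alleles.shape[0]:
                raise ValueError("hap_ids length must equal K")

    @property
    def K(self) -> int:
        return self.alleles.shape[0]

    @property
    def L(self) -> int:
        return self.alleles.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Per-site ALT-allele frequency across the panel."""
        if self.K == 0:
            return np.zeros(self.L)
        return self.alleles.mean(axis=0)

    def exclude_rows(self, rows) -> "HaplotypePanel":
        """Panel with the given haplotype rows removed (e.g. a sampled individual)."""
        keep = np.setdiff1d(np.arange(self.K), np.asarray(rows, dtype=int))
        return HaplotypePanel(
            self.sites, self.alleles[keep], self.pop_labels[keep], self.hap_ids[keep]
        )

    def restrict_pops(self, pops) -> "HaplotypePanel":
        keep = np.flatnonzero(np.isin(self.pop_labels.astype(str), list(pops)))
        return HaplotypePanel(
            self.sites, self.alleles[keep], self.pop_labels[keep], self.hap_ids[keep]
        )


@dataclass
class GeneticMap:
    """Piecewise-linear physical→genetic map.

    Queries interpolate linearly between knots and extrapolate with a constant
    beyond the first/last knot.
    """

    pos: np.ndarray  # bp knots, ascending
    cm: np.ndarray  # cM knots, non-decreasing

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if len(self.pos) != len(self.cm) or len(self.pos) == 0:
            raise ValueError("map needs matched, non-empty knot arrays")
        if np.any(np.diff(self.pos) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("map cM must be non-decreasing")

    def cm_at(self, pos) -> np.ndarray:
        return np.interp(np.asarray(pos, dtype=np.float64), self.pos, self.cm)


@dataclass
class TruthGenotypes:
    """Complete (no-missing) diploid genotypes on the target site list."""

    sites: SiteTable
    g: np.ndarray  # (L,) int8 in {0,1,2}

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int8)
        if len(self.g) != len(self.sites):
            raise ValueError("genotype/site length mismatch")
        if len(self.g) and (self.g.min() < 0 or self.g.max() > 2):
            raise ValueError("truth genotypes must be in {0,1,2}")


@dataclass
class TruthSample:
    """A sampled test individual plus the panel rows it came from.

    ``panel_rows`` must be excluded from the reference before imputing this
    individual (the sampled person may not sit in their own reference panel).
    """

    genotypes: TruthGenotypes
    panel_rows: tuple
    pop: str


@dataclass
class ObservedGenotypes:
    """A degraded observation of a truth sample: pruned and possibly error-injected.

    ``truth`` (when available, i.e. in simulation) lets provenance be recomputed
    exactly; observations read back from VCF carry a stored provenance instead.
    """

    sites: SiteTable
    g_obs: np.ndarray  # (L,) int8 in {0,1,2} or MISSING
    truth: np.ndarray | None = None  # (L,) int8, the generating truth genotypes
    stored_provenance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.g_obs = np.asarray(self.g_obs, dtype=np.int8)
        if len(self.g_obs) != len(self.sites):
            raise ValueError("genotype/site length mismatch")
        ok = (self.g_obs == MISSING) | ((self.g_obs >= 0) & (self.g_obs <= 2))
        if not np.all(ok):
            raise ValueError("observed genotypes must be in {0,1,2,MISSING}")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=np.int8)
            if len(self.truth) != len(self.g_obs):
                raise ValueError("truth length mismatch")

    @property
    def L(self) -> int:
        return len(self.g_obs)

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.g_obs != MISSING))

    def provenance(self) -> np.ndarray:
        """Per-site provenance code (OBSERVED / OBSERVED_ERRONEOUS / PROV_MISSING)."""
        if self.truth is not None:
            prov = np.full(self.L, OBSERVED, dtype=np.int8)
            prov[self.g_obs == MISSING] = PROV_MISSING
            wrong = (self.g_obs != MISSING) & (self.g_obs != self.truth)
            prov[wrong] = OBSERVED_ERRONEOUS
            return prov
        if self.stored_provenance is not None:
            return np.asarray(self.stored_provenance, dtype=np.int8)
        prov = np.full(self.L, OBSERVED, dtype=np.int8)
        prov[self.g_obs == MISSING] = PROV_MISSING
        return prov
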