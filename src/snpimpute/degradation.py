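"""Forensic-style degradation of complete genotype sets.

Two stages, mirroring how partial forensic SNP profiles arise: random pruning
to a target marker count (the typed panel), then per-genotype allelic error
injection.  Drop-in turns a homozygote into a false heterozygote (one spurious
allele of the opposite type); drop-out removes one allele of a heterozygote,
leaving a false homozygote for the uniformly chosen surviving allele.  Errors
are injected after pruning: only typed genotypes can be erroneous, and error
injection never creates or removes missing entries.

Randomness is counter-based: every per-site draw is a hashed uniform keyed on
(seed, stage salt, site position), so draws are i.i.d. across sites but
attached to site *identity*.  Pruning and error injection therefore commute
exactly with site reordering, and each stage's draws are reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import MISSING, ObservedGenotypes, TruthGenotypes

_SALT_PRUNE = 0x1B873593
_SALT_DROPIN = 0xCC9E2D51
_SALT_DROPOUT = 0x85EBCA6B
_SALT_SURVIVOR = 0xC2B2AE35
_MASK64 = 0xFFFFFFFFFFFFFFFF


def _site_uniforms(seed: int, salt: int, positions: np.ndarray) -> np.ndarray:
    """Uniforms in [0, 1) keyed on (seed, salt, site position).

    splitmix64-style finalizer over a keyed input; vectorized, deterministic,
    and independent of array order.
    """
    z = positions.astype(np.uint64) * np.uint64(0x9E3779B97F4A7C15)
    z ^= np.uint64((seed * 0xFF51AFD7ED558CCD) & _MASK64)
    z ^= np.uint64((salt * 0xC4CEB9FE1A85EC53) & _MASK64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z.astype(np.float64) / 2.0**64


@dataclass
class DegradationConfig:
    """One degradation condition: pruning target plus error rates.

    Exactly one of n_target / fraction_target must be set.  dropin_rate applies
    per observed homozygous genotype, dropout_rate per observed heterozygous
    genotype.
    """

    n_target: int | None = None
    fraction_target: float | None = None
    dropin_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_target is None) == (self.fraction_target is None):
            raise ValueError("set exactly one of n_target / fraction_target")
        for r in (self.dropin_rate, self.dropout_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


def prune_to_panel(truth: TruthGenotypes, n_target: int, seed: int = 0) -> ObservedGenotypes:
    """Keep a uniform random subset of exactly n_target sites; rest become MISSING.

    The retained subset is the n_target sites with the smallest per-site hashed
    uniforms — a uniform random subset without replacement.
    """
    L = len(truth.g)
    if not 0 <= n_target <= L:
        raise ValueError(f"n_target={n_target} out of range for {L} sites")
    u = _site_uniforms(seed, _SALT_PRUNE, truth.sites.pos)
    keep = np.argsort(u, kind="stable")[:n_target]
    g_obs = np.full(L, MISSING, dtype=np.int8)
    g_obs[keep] = truth.g[keep]
    return ObservedGenotypes(truth.sites, g_obs, truth=truth.g.copy())


def prune_to_fraction(truth: TruthGenotypes, fraction: float, seed: int = 0) -> ObservedGenotypes:
    """As prune_to_panel with n_target = round(fraction * L)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return prune_to_panel(truth, int(round(fraction * len(truth.g))), seed=seed)


def inject_dropin(obs: ObservedGenotypes, rate: float, seed: int = 0) -> ObservedGenotypes:
    """Allelic drop-in: each observed homozygote independently becomes a
    heterozygote with probability `rate`.  Limited to homozygous genotypes."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    g = obs.g_obs.copy()
    hom = (g == 0) | (g == 2)
    hit = hom & (_site_uniforms(seed, _SALT_DROPIN, obs.sites.pos) < rate)
    g[hit] = 1
    return ObservedGenotypes(obs.sites, g, truth=None if obs.truth is None else obs.truth.copy())


def inject_dropout(
    obs: ObservedGenotypes, rate: float, seed: int = 0, *, per_allele: bool = False
) -> ObservedGenotypes:
    """Allelic drop-out.

    Default (genotype-level) model: each observed heterozygote independently
    loses one allele with probability `rate`, becoming homozygous for a
    uniformly chosen survivor.  The per_allele variant drops each of the two
    alleles independently with probability `rate`, conditioned on at least one
    allele surviving (so a typed genotype never becomes missing); losing one of
    two identical alleles is unobservable, so only heterozygotes change under
    either model.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    g = obs.g_obs.copy()
    het = g == 1
    u = _site_uniforms(seed, _SALT_DROPOUT, obs.sites.pos)
    if per_allele:
        if rate >= 1.0:
            raise ValueError("per-allele mode requires rate < 1 (a surviving allele)")
        # conditional on >=1 surviving allele:
        # P(hom-alt) = P(hom-ref) = rate(1-rate) / (1-rate^2)
        p_one = rate * (1.0 - rate) / (1.0 - rate * rate)
        g[het & (u < p_one)] = 2
        g[het & (u >= p_one) & (u < 2 * p_one)] = 0
    else:
        hit = het & (u < rate)
        survivor_alt = _site_uniforms(seed, _SALT_SURVIVOR, obs.sites.pos) < 0.5
        g[hit & survivor_alt] = 2
        g[hit & ~survivor_alt] = 0
    return ObservedGenotypes(obs.sites, g, truth=None if obs.truth is None else obs.truth.copy())


def degrade(truth: TruthGenotypes, config: DegradationConfig) -> ObservedGenotypes:
    """Prune then inject errors; stage salts keep the draws independent."""
    if config.n_target is not None:
        obs = prune_to_panel(truth, config.n_target, seed=config.seed)
    else:
        obs = prune_to_fraction(truth, config.fraction_target, seed=config.seed)
    if config.dropin_rate > 0:
        obs = inject_dropin(obs, config.dropin_rate, seed=config.seed)
    if config.dropout_rate > 0:
        obs = inject_dropout(obs, config.dropout_rate, seed=config.seed)
    return obs
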