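"""Monte Carlo gene-dropping oracle for the analytic results.

Simulates the generative model behind every exact quantity in the
package: l unrelated lines with inbreeding F, m plants per line drawn
from the selfed-progeny array, then random mating of the ml plants.
Each analytic probability (genotype inclusion, gene loss, allele-ratio
preservation) and the synthetic's inbreeding coefficient can be
estimated empirically and compared with its exact value via a z-score.

For the inbreeding target the default sample construction is the
*grouped* one that the closed formula assumes: each complete group of
four plants contains all four GA4 genotypes and the e leftovers have
distinct genotypes.  An ``iid`` mode draws all m plants independently
from GA4 instead; it deliberately does NOT reproduce the formula (its
within-group crosses average (1+F)/2, not (5+7F)/12) and exists to
quantify that modelling difference.  The retention/allele targets are
multinomial by construction and use i.i.d. draws, matching their exact
counterparts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .allele_stats import (
    SampleCounts,
    equal_allele_freq_closed_form,
    gene_loss_probability,
)
from .genetic_model import collapse_to_ga3, selfed_line_array
from .inbreeding import synthetic_ic
from .retention import inclusion_probability

__all__ = ["SimConfig", "SimResult", "simulate_sample", "simulate_f_syn", "simulate_statistic", "TARGETS"]

TARGETS = ("inclusion_ga4", "inclusion_ga3", "gene_loss", "equal_freq", "f_syn")

#: GA4 genotype codes: bit 1 = first allele, bit 0 = second allele
#: (0=A1A1, 1=A1A2, 2=A2A1, 3=A2A2); both bits name a founder allele.


@dataclass(frozen=True)
class SimConfig:
    """One Monte Carlo run: statistic, model parameters, replicates, seed."""

    target: str
    m: int
    F: Fraction = Fraction(0)
    l: int = 1
    n_reps: int = 100_000
    seed: int = 0
    sampling: str = "grouped"  # f_syn only: grouped | iid
    within_line: bool = False  # f_syn only: mate within one line (per-line scale)

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}; choose from {TARGETS}")
        if self.m < 1 or self.l < 1 or self.n_reps < 1:
            raise ValueError("m, l and n_reps must all be >= 1")
        if not (0 <= Fraction(self.F) <= 1):
            raise ValueError("F must lie in [0, 1]")
        if self.sampling not in ("grouped", "iid"):
            raise ValueError("sampling must be 'grouped' or 'iid'")


@dataclass(frozen=True)
class SimResult:
    """Estimate with its binomial standard error and analytic reference."""

    config: SimConfig
    estimate: float
    standard_error: float
    analytic_value: float
    z_score: float

    @property
    def n_reps(self) -> int:
        return self.config.n_reps


def _finish(cfg: SimConfig, hits: np.ndarray, analytic: Fraction) -> SimResult:
    n = cfg.n_reps
    p_hat = float(hits.mean())
    se = math.sqrt(p_hat * (1.0 - p_hat) / n)
    ana = float(analytic)
    if se == 0.0:
        z = 0.0 if p_hat == ana else math.inf
    else:
        z = (p_hat - ana) / se
    return SimResult(cfg, p_hat, se, ana, z)


def simulate_sample(m: int, rng: np.random.Generator) -> SampleCounts:
    """One multinomial draw of m genotypes from GA4."""
    counts = rng.multinomial(m, [0.25] * 4)
    return SampleCounts(*(int(c) for c in counts))


def _genotype_at(pos, g, e, leftover_perm, n_reps):
    """Genotype code of the plant at within-line position `pos` (grouped)."""
    in_group = pos % 4
    if e == 0:
        return in_group
    slot = np.clip(pos - 4 * g, 0, 3)
    leftover = leftover_perm[np.arange(n_reps), slot]
    return np.where(pos < 4 * g, in_group, leftover)


def simulate_f_syn(cfg: SimConfig) -> SimResult:
    """Gene-dropping estimate of the synthetic's inbreeding coefficient.

    Per replicate: build the m plants of each line (grouped by default),
    pick an ordered parent pair uniformly with replacement from the ml
    plants (selfing included), drop one random gamete allele from each
    parent, and record whether the two alleles are identical by descent.
    Alleles from different lines are never IBD; within a line the two
    founder alleles are declared IBD with probability F.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, l = cfg.n_reps, cfg.m, cfg.l
    g, e = divmod(m, 4)

    if cfg.within_line:
        idx1 = rng.integers(0, m, n)
        idx2 = rng.integers(0, m, n)
        line1 = line2 = np.zeros(n, dtype=np.int64)
        pos1, pos2 = idx1, idx2
        same_plant = idx1 == idx2
    else:
        idx1 = rng.integers(0, m * l, n)
        idx2 = rng.integers(0, m * l, n)
        line1, pos1 = np.divmod(idx1, m)
        line2, pos2 = np.divmod(idx2, m)
        same_plant = idx1 == idx2

    if cfg.sampling == "grouped":
        # one random leftover-genotype assignment per replicate; only the
        # shared line's assignment matters (cross-line pairs are never IBD)
        perm = np.argsort(rng.random((n, 4)), axis=1) if e else None
        geno1 = _genotype_at(pos1, g, e, perm, n)
        geno2 = _genotype_at(pos2, g, e, perm, n)
    else:
        geno1 = rng.integers(0, 4, n)
        geno2 = np.where(same_plant, geno1, rng.integers(0, 4, n))

    side1 = rng.integers(0, 2, n)
    side2 = rng.integers(0, 2, n)
    allele1 = np.where(side1 == 1, geno1 & 1, geno1 >> 1)
    allele2 = np.where(side2 == 1, geno2 & 1, geno2 >> 1)

    founders_ibd = rng.random(n) < float(cfg.F)
    ibd = (line1 == line2) & ((allele1 == allele2) | founders_ibd)

    exact = synthetic_ic(m, cfg.F, cfg.l)
    analytic = exact.per_line_value if cfg.within_line else exact.f_syn_l
    return _finish(cfg, ibd, analytic)


def simulate_statistic(cfg: SimConfig) -> SimResult:
    """Estimate any supported statistic and compare with its exact value."""
    if cfg.target == "f_syn":
        return simulate_f_syn(cfg)

    rng = np.random.default_rng(cfg.seed)
    counts = rng.multinomial(cfg.m, [0.25] * 4, size=cfg.n_reps)
    m = cfg.m
    if cfg.target == "inclusion_ga4":
        hits = (counts > 0).all(axis=1)
        analytic = inclusion_probability(m, selfed_line_array())
    elif cfg.target == "inclusion_ga3":
        hits = (counts[:, 0] > 0) & (counts[:, 1] + counts[:, 2] > 0) & (counts[:, 3] > 0)
        analytic = inclusion_probability(m, collapse_to_ga3(selfed_line_array()))
    elif cfg.target == "gene_loss":
        hits = (counts[:, 0] == m) | (counts[:, 3] == m)
        analytic = gene_loss_probability(m)
    else:  # equal_freq
        hits = 2 * counts[:, 0] + counts[:, 1] + counts[:, 2] == m
        analytic = equal_allele_freq_closed_form(m)
    return _finish(cfg, hits, analytic)
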