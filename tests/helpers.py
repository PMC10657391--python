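"""Shared oracles and simulation helpers for the test suite.

The oracles here deliberately re-derive model quantities by direct
enumeration or grid search, independent of the implementation paths they
check.  Expensive simulation summaries are cached so several tests can share
one computation.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

import tadote as td


def oracle_pollen_fertility(genotype: td.DiploidGenotype, panel: td.Panel) -> float:
    """Exhaustive-enumeration oracle for the viable pollen fraction.

    Enumerates every meiotic outcome (per-locus parental choice x transgene
    carriage) and applies the exposure/protection rule inline.
    """
    tgs = genotype.transgenes
    locus_choices = [
        [genotype.hapA.alleles[i], genotype.hapB.alleles[i]] for i in range(len(panel))
    ]
    carriage_options = [
        [True, False] if t.zygosity == "hemizygous" else [True] for t in tgs
    ]
    total = 0.0
    for alleles in itertools.product(*locus_choices):
        for carried in itertools.product(*carriage_options):
            prob = 0.5 ** len(panel)
            for t, c in zip(tgs, carried):
                if t.zygosity == "hemizygous":
                    prob *= 0.5
            surv = 1.0
            for i, loc in enumerate(panel.loci):
                toxin_present = (
                    genotype.hapA.alleles[i].toxin_functional
                    or genotype.hapB.alleles[i].toxin_functional
                    or any(
                        t.payload == "toxin" and t.target_locus == loc.locus_id
                        for t in tgs
                    )
                )
                protected = alleles[i].antidote_functional or any(
                    c and t.payload == "antidote" and t.target_locus == loc.locus_id
                    for t, c in zip(tgs, carried)
                )
                if toxin_present and not protected:
                    surv *= 1.0 - loc.killing_efficiency
            total += prob * surv
    return total


def grid_search_mle_k(counts: dict, step: float = 1e-4) -> float:
    """Grid-search ML oracle for the self-het killing efficiency.

    Evaluates the multinomial log-likelihood of (func/func, het, null/null)
    counts on a dense k grid using the closed-form class probabilities
    P = (1/(2(2-k)), 1/2, (1-k)/(2(2-k))).
    """
    a = counts.get("1M1M", counts.get("M/M", 0))
    b = counts.get("1D1M", counts.get("M/D", 0))
    c = counts.get("1D1D", counts.get("D/D", 0))
    ks = np.arange(0.0, 1.0 + step / 2, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_mm = 1.0 / (2.0 * (2.0 - ks))
        p_dd = (1.0 - ks) / (2.0 * (2.0 - ks))
        ll = a * np.log(p_mm) + b * np.log(0.5) + np.where(
            c > 0, c * np.log(np.where(p_dd > 0, p_dd, np.nan)), 0.0
        )
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return float(ks[int(np.argmax(ll))])


@lru_cache(maxsize=None)
def k_ci_coverage(k_true: float, n: int, replicates: int, seed: int) -> float:
    """Fraction of replicates whose profile-likelihood 95% CI covers k_true."""
    hits = 0
    for r in range(replicates):
        table = td.gen_cross_counts("self_het", n, seed + r, k=k_true)
        fit = td.fit_killing_efficiency(table, design="self_het")
        lo, hi = fit.ci["k"]
        if lo - 1e-12 <= k_true <= hi + 1e-12:
            hits += 1
    return hits / replicates


@lru_cache(maxsize=None)
def k_recovery(k_true: float, n: int, seed: int) -> float:
    table = td.gen_cross_counts("self_het", n, seed, k=k_true)
    return td.fit_killing_efficiency(table, design="self_het").estimates["k"]
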