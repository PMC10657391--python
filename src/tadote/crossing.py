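"""Progeny genotype distributions for crosses, selfs and scripted pedigrees.

A cross combines *unselected* female gametes (single TA loci do not affect
ovules; an optional joint-gamete weight vector expresses the female
transmission bias seen when two loci are stacked) with the *post-selection*
male gamete pool from :func:`tadote.model.male_gamete_distribution`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import (
    DiploidGenotype,
    Haplotype,
    Panel,
    SterileMaleError,
    Transgene,
    ValidationError,
    _enumerate_gamete_classes,
    edit_genotype,
    male_gamete_distribution,
    pollen_fertility,
)
from .panel import gamete_key, genotype_key

__all__ = [
    "FemaleTransmissionWeights",
    "GenotypeDistribution",
    "female_gamete_classes",
    "cross",
    "self_progeny",
    "f2_from_double_het",
    "pedigree",
]

_PRUNE = 1e-15


@dataclass(frozen=True)
class FemaleTransmissionWeights:
    """Relative transmission weights of joint female gamete classes.

    Keys are gamete haplotype keys (e.g. ``"1M/7D"``); weights are
    nonnegative and are normalized over the gamete classes actually produced
    by the mother.  The default (no weights) is uniform Mendelian
    transmission.
    """

    weights: dict

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("empty female transmission weight table")
        for k, w in self.weights.items():
            if w < 0:
                raise ValidationError(f"negative weight {w!r} for gamete {k!r}")
        if sum(self.weights.values()) <= 0:
            raise ValidationError("female transmission weights sum to zero")

    def weight(self, key: str) -> float:
        try:
            return float(self.weights[key])
        except KeyError:
            raise ValidationError(
                f"no female transmission weight for gamete class {key!r}; "
                f"known classes: {sorted(self.weights)}"
            ) from None


@dataclass
class GenotypeDistribution:
    """Probability distribution over canonical progeny genotype classes."""

    entries: dict  # key -> probability
    genotypes: dict = field(default_factory=dict)  # key -> representative genotype

    def probability(self, key: str) -> float:
        return self.entries.get(key, 0.0)

    def items(self):
        return self.entries.items()

    def total(self) -> float:
        return sum(self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genotype": k, "probability": p, "percent": round(100.0 * p, 1)}
            for k, p in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["genotype", "probability", "percent"])


def _normalized(entries: dict, genotypes: dict) -> GenotypeDistribution:
    total = sum(entries.values())
    if total <= 0:
        raise ValidationError("progeny distribution has zero total mass")
    entries = {k: v / total for k, v in entries.items() if v / total >= _PRUNE}
    total = sum(entries.values())
    entries = {k: v / total for k, v in entries.items()}
    return GenotypeDistribution(entries, {k: genotypes[k] for k in entries})


def female_gamete_classes(
    genotype: DiploidGenotype,
    panel: Panel,
    weights: Optional[FemaleTransmissionWeights] = None,
):
    """Female gamete classes ``(haplotype, carried, freq)``.

    Mendelian enumeration with no per-locus killing; if ``weights`` is given
    each class is reweighted by the weight of its haplotype key (transgene
    carriage stays Mendelian within a haplotype class) and renormalized.
    """
    classes = [
        (hap, carried, prior)
        for hap, carried, prior, _kill in _enumerate_gamete_classes(genotype, panel)
    ]
    if weights is None:
        return classes
    weighted = [
        (hap, carried, prior * weights.weight(gamete_key(hap, panel)))
        for hap, carried, prior in classes
    ]
    total = sum(f for _, _, f in weighted)
    if total <= 0:
        raise ValidationError("female transmission weights eliminate every gamete class")
    return [(hap, carried, f / total) for hap, carried, f in weighted]


def _offspring(
    f_hap: Haplotype,
    f_carried: frozenset,
    m_hap: Haplotype,
    m_carried: frozenset,
) -> DiploidGenotype:
    counts: dict = {}
    for ident in list(f_carried) + list(m_carried):
        counts[ident] = counts.get(ident, 0) + 1
    tgs = tuple(
        Transgene(p, t, "homozygous" if c >= 2 else "hemizygous")
        for (p, t), c in sorted(counts.items())
    )
    return DiploidGenotype(f_hap, m_hap, tgs)


def cross(
    female: DiploidGenotype,
    male: DiploidGenotype,
    panel: Panel,
    weights: Optional[FemaleTransmissionWeights] = None,
) -> GenotypeDistribution:
    """Progeny genotype distribution of ``female x male``.

    Raises :class:`SterileMaleError` when the pollen parent is fully
    male-sterile (viable fraction 0).
    """
    male_dist = male_gamete_distribution(male, panel)
    if male_dist.viable_fraction <= 0.0:
        raise SterileMaleError("male parent fully sterile; cross yields no progeny")
    fem = female_gamete_classes(female, panel, weights)

    entries: dict = {}
    genos: dict = {}
    for f_hap, f_carried, f_freq in fem:
        if f_freq <= 0.0:
            continue
        for mc in male_dist.surviving():
            p = f_freq * mc.post_freq
            child = _offspring(f_hap, f_carried, mc.haplotype, mc.transgenes_carried)
            key = genotype_key(child, panel)
            entries[key] = entries.get(key, 0.0) + p
            genos.setdefault(key, child)
    return _normalized(entries, genos)


def self_progeny(
    genotype: DiploidGenotype,
    panel: Panel,
    weights: Optional[FemaleTransmissionWeights] = None,
) -> GenotypeDistribution:
    """Self-pollination progeny distribution (``cross(g, g)``)."""
    return cross(genotype, genotype, panel, weights)


def f2_from_double_het(
    panel: Panel, weights: Optional[FemaleTransmissionWeights] = None
) -> GenotypeDistribution:
    """F2 distribution from selfing the stacked double heterozygote.

    With complete killing at both loci only one pollen class (functional
    haplotype at every locus) survives, so the four F2 genotype classes map
    one-to-one onto the four female gamete classes and their probabilities
    equal the female transmission weights (uniform 1:1:1:1 by default).
    """
    from .panel import double_heterozygote

    return self_progeny(double_heterozygote(panel), panel, weights)


# ---------------------------------------------------------------------------
# pedigrees


def _point_mass(genotype: DiploidGenotype, panel: Panel) -> GenotypeDistribution:
    key = genotype_key(genotype, panel)
    return GenotypeDistribution({key: 1.0}, {key: genotype})


def _mixture_cross(
    female: GenotypeDistribution,
    male: GenotypeDistribution,
    panel: Panel,
    weights: Optional[FemaleTransmissionWeights],
) -> GenotypeDistribution:
    # Pollen contribution of a male class scales with its frequency times its
    # viable pollen fraction; ovule contribution with frequency alone.
    male_w = {
        k: p * pollen_fertility(male.genotypes[k], panel) for k, p in male.items()
    }
    tot = sum(male_w.values())
    if tot <= 0.0:
        raise SterileMaleError("male parent fully sterile; cross yields no progeny")
    entries: dict = {}
    genos: dict = {}
    for fk, fp in female.items():
        for mk, mw in male_w.items():
            if fp <= 0.0 or mw <= 0.0:
                continue
            sub = cross(female.genotypes[fk], male.genotypes[mk], panel, weights)
            for k, p in sub.items():
                entries[k] = entries.get(k, 0.0) + fp * (mw / tot) * p
                genos.setdefault(k, sub.genotypes[k])
    return _normalized(entries, genos)


def _mixture_self(
    dist: GenotypeDistribution,
    panel: Panel,
    weights: Optional[FemaleTransmissionWeights],
) -> GenotypeDistribution:
    # Only plants with viable pollen can self; their seed shares follow their
    # population frequencies (equal ovule output), renormalized.
    fertile = {
        k: p for k, p in dist.items() if pollen_fertility(dist.genotypes[k], panel) > 0.0
    }
    tot = sum(fertile.values())
    if tot <= 0.0:
        raise SterileMaleError("male parent fully sterile; cross yields no progeny")
    entries: dict = {}
    genos: dict = {}
    for k, p in fertile.items():
        sub = self_progeny(dist.genotypes[k], panel, weights)
        for ck, cp in sub.items():
            entries[ck] = entries.get(ck, 0.0) + (p / tot) * cp
            genos.setdefault(ck, sub.genotypes[ck])
    return _normalized(entries, genos)


def pedigree(
    steps: list,
    start_genotypes: dict,
    panel: Panel,
    weights: Optional[FemaleTransmissionWeights] = None,
) -> dict:
    """Run a scripted pedigree; returns ``{step_name: GenotypeDistribution}``.

    Each step is a dict with ``op`` in {``"cross"``, ``"self"``, ``"edit"``}
    and a ``name`` under which its result is stored.  Operand fields
    (``female``/``male`` for cross, ``genotype`` for self/edit) reference
    start genotypes or earlier step names.  ``edit`` additionally takes
    ``locus``, ``gene`` and optional ``mode``.  An empty step list returns an
    empty mapping (identity).
    """
    env: dict = {
        name: _point_mass(g, panel) for name, g in start_genotypes.items()
    }
    results: dict = {}

    def resolve(name: str) -> GenotypeDistribution:
        try:
            return env[name]
        except KeyError:
            raise ValidationError(f"pedigree step references undefined name {name!r}") from None

    for i, step in enumerate(steps):
        op = step.get("op")
        name = step.get("name", f"step{i}")
        if op == "cross":
            dist = _mixture_cross(resolve(step["female"]), resolve(step["male"]), panel, weights)
        elif op == "self":
            dist = _mixture_self(resolve(step["genotype"]), panel, weights)
        elif op == "edit":
            src = resolve(step["genotype"])
            entries: dict = {}
            genos: dict = {}
            for k, p in src.items():
                g = edit_genotype(
                    src.genotypes[k],
                    step["locus"],
                    step["gene"],
                    mode=step.get("mode", "knockout_both"),
                    panel=panel,
                )
                nk = genotype_key(g, panel)
                entries[nk] = entries.get(nk, 0.0) + p
                genos.setdefault(nk, g)
            dist = _normalized(entries, genos)
        else:
            raise ValidationError(f"unknown pedigree op {op!r} in step {name!r}")
        env[name] = dist
        results[name] = dist
    return results
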