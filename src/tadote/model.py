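"""Core gamete-killing model for tightly linked toxin-antidote (TA) loci.

A TA locus couples a toxin gene and an antidote gene in absolute linkage on
one haplotype.  The toxin acts *sporophytically*: it is produced by the
diploid plant and delivered to every developing pollen grain regardless of
which haplotype that grain inherited.  The antidote acts *gametophytically in
cis*: only pollen that itself carries a functional antidote copy (on its own
haplotype, or on a transgene it happens to carry) is protected.  An exposed,
unprotected pollen grain is eliminated with probability ``k`` (the killing
efficiency of the locus) at a locus-specific developmental stage.

This module represents loci, haplotypes, diploid genotypes and transgenes,
and computes exact male-gamete distributions, pollen fertility and
stage-resolved abortion profiles by enumeration.  All probabilities are exact
floating-point computations; sampling lives in :mod:`tadote.simulate`.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterator, Optional

__all__ = [
    "ConfigurationError",
    "InputError",
    "SterileMaleError",
    "ValidationError",
    "DEFAULT_STAGES",
    "LocusSpec",
    "Panel",
    "HaplotypeAllele",
    "Haplotype",
    "Transgene",
    "DiploidGenotype",
    "GameteClass",
    "GameteDistribution",
    "toxin_exposure",
    "gamete_protected",
    "male_gamete_distribution",
    "pollen_fertility",
    "abortion_profile",
    "edit_genotype",
]


class ConfigurationError(ValueError):
    """Invalid locus panel / parameter configuration (e.g. unknown locus id)."""


class InputError(ValueError):
    """Malformed user input (sequences, tokens, tables)."""


class ValidationError(ValueError):
    """Inconsistent data passed between operations (class mismatch etc.)."""


class SterileMaleError(ValueError):
    """A cross was requested with a fully male-sterile pollen parent."""


#: Ordered pollen developmental stages used by the default panel.  qHMS1-type
#: abortion manifests at the uninucleate stage, qHMS7-type at the binucleate
#: stage; the vocabulary is extensible through :class:`Panel`.
DEFAULT_STAGES: tuple[str, ...] = ("uninucleate", "binucleate")

_TOXIN_ACTIONS = ("sporophytic",)
_ANTIDOTE_ACTIONS = ("gametophytic_cis",)
_PAYLOADS = ("toxin", "antidote")
_ZYGOSITIES = ("hemizygous", "homozygous")


@dataclass(frozen=True)
class LocusSpec:
    """One toxin-antidote locus.

    Parameters
    ----------
    locus_id
        Name of the locus, e.g. ``"qHMS1"``.
    chromosome
        Chromosome label (informational).
    killing_efficiency
        Probability ``k`` in [0, 1] that an exposed, unprotected gamete is
        eliminated.  ``k = 1`` is complete killing; ``k < 1`` models
        leak-through (rare survival of unprotected gametes).
    abortion_stage
        Stage label at which killing by this locus manifests; must be a
        member of the panel's ordered stage vocabulary.
    functional_origin
        Which parental origin carries the functional (toxin+, antidote+)
        haplotype, e.g. ``"Mer"`` for qHMS1 and ``"DJY1"`` for qHMS7.
    aliases
        Pairs ``(alias, state_token)`` mapping short allele labels (the
        customary ``"M"`` / ``"D"``) onto functionality states; state tokens
        are ``"FA"``, ``"fA"``, ``"Fa"``, ``"fa"`` with uppercase meaning
        functional toxin (F) / antidote (A).
    """

    locus_id: str
    chromosome: str = ""
    killing_efficiency: float = 1.0
    abortion_stage: str = "uninucleate"
    functional_origin: str = ""
    toxin_action: str = "sporophytic"
    antidote_action: str = "gametophytic_cis"
    aliases: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.killing_efficiency <= 1.0:
            raise ConfigurationError(
                f"killing efficiency must lie in [0, 1], got "
                f"{self.killing_efficiency!r} for locus {self.locus_id!r}"
            )
        if self.toxin_action not in _TOXIN_ACTIONS:
            raise ConfigurationError(f"unsupported toxin action {self.toxin_action!r}")
        if self.antidote_action not in _ANTIDOTE_ACTIONS:
            raise ConfigurationError(
                f"unsupported antidote action {self.antidote_action!r}"
            )

    @property
    def alias_map(self) -> dict[str, str]:
        return dict(self.aliases)

    @property
    def prefix(self) -> str:
        """Digit prefix used in compact genotype tokens (``"1"`` for qHMS1)."""
        return "".join(ch for ch in self.locus_id if ch.isdigit())


@dataclass(frozen=True)
class Panel:
    """An ordered set of unlinked TA loci plus the stage vocabulary."""

    loci: tuple[LocusSpec, ...]
    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate locus ids in panel: {ids}")
        for loc in self.loci:
            if loc.abortion_stage not in self.stages:
                raise ConfigurationError(
                    f"abortion stage {loc.abortion_stage!r} of locus "
                    f"{loc.locus_id!r} is not in the stage vocabulary {self.stages}"
                )

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[LocusSpec]:
        return iter(self.loci)

    def index(self, locus_id: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.locus_id == locus_id:
                return i
        raise ConfigurationError(f"unknown locus id {locus_id!r}")

    def locus(self, locus_id: str) -> LocusSpec:
        return self.loci[self.index(locus_id)]

    def stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise ConfigurationError(f"unknown stage {stage!r}") from None

    def with_killing_efficiency(self, k) -> "Panel":
        """Return a panel with killing efficiencies replaced.

        ``k`` may be a scalar (applied to every locus) or a mapping
        ``{locus_id: k}`` (unlisted loci keep their value).
        """
        if isinstance(k, dict):
            loci = tuple(
                replace(loc, killing_efficiency=k.get(loc.locus_id, loc.killing_efficiency))
                for loc in self.loci
            )
        else:
            loci = tuple(replace(loc, killing_efficiency=float(k)) for loc in self.loci)
        return Panel(loci, self.stages)


@dataclass(frozen=True)
class HaplotypeAllele:
    """Functionality state of one haplotype at one TA locus."""

    toxin_functional: bool
    antidote_functional: bool
    alias: Optional[str] = None

    @property
    def state(self) -> tuple[bool, bool]:
        return (self.toxin_functional, self.antidote_functional)


@dataclass(frozen=True)
class Haplotype:
    """Ordered alleles, one per panel locus (absolute within-locus linkage)."""

    alleles: tuple[HaplotypeAllele, ...]

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class Transgene:
    """An unlinked single-insertion transgene carrying a toxin or antidote.

    The transgene occupies one unlinked locus of its own and is transmitted
    Mendelianly: a hemizygous insertion is carried by half the gametes, a
    homozygous one by all.
    """

    payload: str
    target_locus: str
    zygosity: str = "hemizygous"

    def __post_init__(self) -> None:
        if self.payload not in _PAYLOADS:
            raise ConfigurationError(f"unknown transgene payload {self.payload!r}")
        if self.zygosity not in _ZYGOSITIES:
            raise ConfigurationError(f"unknown zygosity {self.zygosity!r}")

    @property
    def identity(self) -> tuple[str, str]:
        return (self.payload, self.target_locus)


@dataclass(frozen=True)
class DiploidGenotype:
    """Unordered pair of haplotypes plus any transgenes.

    All derived quantities are invariant under swapping ``hapA``/``hapB``.
    """

    hapA: Haplotype
    hapB: Haplotype
    transgenes: tuple[Transgene, ...] = ()

    def __post_init__(self) -> None:
        if len(self.hapA) != len(self.hapB):
            raise ConfigurationError("haplotypes differ in length")
        idents = [t.identity for t in self.transgenes]
        if len(set(idents)) != len(idents):
            raise ConfigurationError(
                "duplicate transgene identities in one genotype; use "
                "zygosity='homozygous' for a two-copy insertion"
            )

    def swapped(self) -> "DiploidGenotype":
        return DiploidGenotype(self.hapB, self.hapA, self.transgenes)


@dataclass(frozen=True)
class GameteClass:
    """One male gamete class with pre/post-selection frequencies."""

    haplotype: Haplotype
    transgenes_carried: frozenset  # of (payload, target_locus) identities
    prior_freq: float
    survival_prob: float
    abortion_stage: Optional[str]
    post_freq: float


@dataclass(frozen=True)
class GameteDistribution:
    classes: tuple[GameteClass, ...]
    viable_fraction: float

    def surviving(self) -> tuple[GameteClass, ...]:
        return tuple(c for c in self.classes if c.post_freq > 0.0)


# ---------------------------------------------------------------------------
# operations


def _check_genotype(genotype: DiploidGenotype, panel: Panel) -> None:
    if len(genotype.hapA) != len(panel):
        raise ConfigurationError(
            f"genotype defined at {len(genotype.hapA)} loci but the panel has "
            f"{len(panel)}"
        )
    for t in genotype.transgenes:
        panel.index(t.target_locus)  # raises on unknown locus


def toxin_exposure(genotype: DiploidGenotype, locus_id: str, panel: Panel) -> bool:
    """Is every gamete of this plant exposed to the toxin of ``locus_id``?

    Sporophytic action: exposure holds if either haplotype carries a
    functional toxin at the locus, or any toxin-payload transgene targets it;
    it then applies to *all* gametes of the plant.
    """
    _check_genotype(genotype, panel)
    i = panel.index(locus_id)
    if genotype.hapA.alleles[i].toxin_functional or genotype.hapB.alleles[i].toxin_functional:
        return True
    return any(
        t.payload == "toxin" and t.target_locus == locus_id for t in genotype.transgenes
    )


def gamete_protected(gamete: GameteClass, locus_id: str, panel: Panel) -> bool:
    """Is this gamete protected against the toxin of ``locus_id``?

    Strictly gametophytic and cis-acting: only the gamete's own haplotype (or
    an antidote transgene it carries) protects; the other parental
    haplotype's antidote never does.
    """
    i = panel.index(locus_id)
    if gamete.haplotype.alleles[i].antidote_functional:
        return True
    return ("antidote", locus_id) in gamete.transgenes_carried


def _allele_sort_key(allele: HaplotypeAllele):
    return (not allele.toxin_functional, not allele.antidote_functional, allele.alias or "")


def _class_sort_key(item):
    (hap, carried), _prior = item
    return (tuple(_allele_sort_key(a) for a in hap.alleles), tuple(sorted(carried)))


def _enumerate_gamete_classes(genotype: DiploidGenotype, panel: Panel):
    """Enumerate male meiotic products before selection.

    Yields ``(haplotype, carried, prior_freq, kill_locus_indices)`` where
    ``kill_locus_indices`` lists panel loci at which a kill term < 1 applies
    to this gamete (toxin exposed, gamete unprotected, k > 0), sorted by
    abortion stage then panel order.
    """
    _check_genotype(genotype, panel)
    exposure = [toxin_exposure(genotype, loc.locus_id, panel) for loc in panel.loci]

    per_locus = []
    for i in range(len(panel)):
        a, b = genotype.hapA.alleles[i], genotype.hapB.alleles[i]
        per_locus.append(((a, 0.5), (b, 0.5)))

    tg_options = []
    for t in genotype.transgenes:
        if t.zygosity == "homozygous":
            tg_options.append(((t.identity, 1.0),))
        else:
            tg_options.append(((t.identity, 0.5), (None, 0.5)))

    agg: dict = {}
    for allele_choice in itertools.product(*per_locus):
        for tg_choice in itertools.product(*tg_options):
            prob = 1.0
            for _, p in allele_choice:
                prob *= p
            for _, p in tg_choice:
                prob *= p
            hap = Haplotype(tuple(a for a, _ in allele_choice))
            carried = frozenset(ident for ident, _ in tg_choice if ident is not None)
            key = (hap, carried)
            agg[key] = agg.get(key, 0.0) + prob

    stage_order = lambda i: (panel.stage_index(panel.loci[i].abortion_stage), i)
    for (hap, carried), prior in sorted(agg.items(), key=_class_sort_key):
        kill = []
        for i, loc in enumerate(panel.loci):
            if not exposure[i] or loc.killing_efficiency <= 0.0:
                continue
            protected = (
                hap.alleles[i].antidote_functional
                or ("antidote", loc.locus_id) in carried
            )
            if not protected:
                kill.append(i)
        kill.sort(key=stage_order)
        yield hap, carried, prior, kill


def male_gamete_distribution(genotype: DiploidGenotype, panel: Panel) -> GameteDistribution:
    """Post-selection male gamete pool of a plant.

    Each gamete class has Mendelian prior frequency (free recombination
    between loci, independent transgene segregation); its survival
    probability is the product over loci of ``1 - k`` for every locus at
    which the gamete is exposed and unprotected.  A class killed at multiple
    loci is attributed to the earliest abortion stage.  ``viable_fraction``
    may be 0 (complete male sterility); the surviving set is then empty.
    """
    raw = list(_enumerate_gamete_classes(genotype, panel))
    viable = 0.0
    survivals = []
    for hap, carried, prior, kill in raw:
        surv = 1.0
        for i in kill:
            surv *= 1.0 - panel.loci[i].killing_efficiency
        survivals.append(surv)
        viable += prior * surv

    classes = []
    for (hap, carried, prior, kill), surv in zip(raw, survivals):
        stage = panel.loci[kill[0]].abortion_stage if kill else None
        post = prior * surv / viable if viable > 0.0 else 0.0
        classes.append(
            GameteClass(
                haplotype=hap,
                transgenes_carried=carried,
                prior_freq=prior,
                survival_prob=surv,
                abortion_stage=stage,
                post_freq=post,
            )
        )
    return GameteDistribution(tuple(classes), viable)


def pollen_fertility(genotype: DiploidGenotype, panel: Panel) -> float:
    """Fraction of viable pollen, in [0, 1]."""
    return male_gamete_distribution(genotype, panel).viable_fraction


def abortion_profile(genotype: DiploidGenotype, panel: Panel) -> dict[str, float]:
    """Aborted pollen fraction per developmental stage.

    Within each gamete class the kill terms are applied in stage order, so a
    gamete subject to killing at several loci is counted once, at the
    earliest stage at which it dies.  Stages with zero abortion are omitted;
    the returned fractions plus the viable fraction sum to 1.
    """
    profile: dict[str, float] = {}
    for hap, carried, prior, kill in _enumerate_gamete_classes(genotype, panel):
        remaining = prior
        for i in kill:
            loc = panel.loci[i]
            killed = remaining * loc.killing_efficiency
            if killed > 0.0:
                profile[loc.abortion_stage] = profile.get(loc.abortion_stage, 0.0) + killed
            remaining *= 1.0 - loc.killing_efficiency
    return profile


def edit_genotype(
    genotype: DiploidGenotype,
    locus_id: str,
    gene: str,
    mode: str = "knockout_both",
    panel: Optional[Panel] = None,
    haplotype: str = "A",
) -> DiploidGenotype:
    """CRISPR-style knockout of the toxin or antidote gene at one locus.

    By default both haplotype copies are edited (biallelic editing, the
    typical outcome); ``mode="knockout_hap"`` edits only the named haplotype
    (``"A"`` or ``"B"``).  Alias labels are dropped from edited alleles since
    their functionality state no longer matches the named natural allele.
    """
    if gene not in _PAYLOADS:
        raise ConfigurationError(f"unknown gene {gene!r}; expected 'toxin' or 'antidote'")
    if mode not in ("knockout_both", "knockout_hap"):
        raise ConfigurationError(f"unknown edit mode {mode!r}")
    if panel is not None:
        i = panel.index(locus_id)
    else:
        i = None
    if i is None:
        # without a panel the locus must be addressed by position
        raise ConfigurationError("edit_genotype requires the panel to resolve the locus id")

    def knock(hap: Haplotype) -> Haplotype:
        alleles = list(hap.alleles)
        al = alleles[i]
        if gene == "toxin":
            al = HaplotypeAllele(False, al.antidote_functional, None)
        else:
            al = HaplotypeAllele(al.toxin_functional, False, None)
        alleles[i] = al
        return Haplotype(tuple(alleles))

    if mode == "knockout_both":
        return DiploidGenotype(knock(genotype.hapA), knock(genotype.hapB), genotype.transgenes)
    if haplotype.upper() == "A":
        return DiploidGenotype(knock(genotype.hapA), genotype.hapB, genotype.transgenes)
    if haplotype.upper() == "B":
        return DiploidGenotype(genotype.hapA, knock(genotype.hapB), genotype.transgenes)
    raise ConfigurationError(f"unknown haplotype {haplotype!r}; expected 'A' or 'B'")
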