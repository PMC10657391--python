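"""Locus panels, allele tokens, genotype string grammar and JSON config.

Genotype strings use within-locus token pairs joined by ``";"`` across loci,
mirroring the customary notation for stacked hybrid-sterility loci:
``"1M1D;7D7M"`` is heterozygous at both qHMS1 (alleles M and D) and qHMS7.
Tokens are either locus-specific aliases (optionally digit-prefixed, ``1M``
== ``M``) resolved through the locus alias table, or explicit functionality
state tokens ``FA``/``fA``/``Fa``/``fa`` (uppercase = functional toxin F /
antidote A).
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

from .model import (
    DEFAULT_STAGES,
    ConfigurationError,
    DiploidGenotype,
    Haplotype,
    HaplotypeAllele,
    InputError,
    LocusSpec,
    Panel,
    Transgene,
)

__all__ = [
    "STATE_TOKENS",
    "default_panel",
    "single_locus_panel",
    "allele_from_token",
    "allele_token",
    "parse_genotype",
    "parse_haplotype",
    "gamete_key",
    "genotype_key",
    "double_heterozygote",
    "homozygote",
    "load_panel",
    "panel_to_dict",
]

#: Explicit state tokens: (toxin_functional, antidote_functional).
STATE_TOKENS: dict[str, tuple[bool, bool]] = {
    "FA": (True, True),
    "fA": (False, True),
    "Fa": (True, False),
    "fa": (False, False),
}
_TOKEN_FOR_STATE = {v: k for k, v in STATE_TOKENS.items()}

_ZYG_SHORT = {"hemizygous": "hemi", "homozygous": "homo"}


def default_panel(k_qhms1: float = 1.0, k_qhms7: float = 1.0) -> Panel:
    """The two-locus qHMS1 + qHMS7 panel.

    At qHMS1 the functional (toxin+, antidote+) haplotype is the wild-rice
    ``M`` (O. meridionalis) allele and ``D`` (cultivated DJY1) is the
    non-functional null; killing manifests at the uninucleate stage.  At
    qHMS7 the polarity is reversed: the cultivated ``D`` allele is the
    functional element, ``M`` the null, and killing manifests at the later
    binucleate stage.
    """
    return Panel(
        loci=(
            LocusSpec(
                locus_id="qHMS1",
                chromosome="1",
                killing_efficiency=k_qhms1,
                abortion_stage="uninucleate",
                functional_origin="Mer",
                aliases=(("M", "FA"), ("D", "fa")),
            ),
            LocusSpec(
                locus_id="qHMS7",
                chromosome="7",
                killing_efficiency=k_qhms7,
                abortion_stage="binucleate",
                functional_origin="DJY1",
                aliases=(("D", "FA"), ("M", "fa")),
            ),
        ),
        stages=DEFAULT_STAGES,
    )


def single_locus_panel(locus_id: str = "qHMS1", k: float = 1.0, base: Optional[Panel] = None) -> Panel:
    """A one-locus sub-panel of ``base`` (default: the qHMS1/qHMS7 panel)."""
    from dataclasses import replace

    base = base if base is not None else default_panel()
    loc = replace(base.locus(locus_id), killing_efficiency=k)
    return Panel((loc,), base.stages)


# ---------------------------------------------------------------------------
# tokens


def allele_from_token(token: str, locus: LocusSpec) -> HaplotypeAllele:
    t = token.lstrip("0123456789")
    amap = locus.alias_map
    if t in amap:
        tox, anti = STATE_TOKENS[amap[t]]
        return HaplotypeAllele(tox, anti, alias=t)
    if t in STATE_TOKENS:
        tox, anti = STATE_TOKENS[t]
        return HaplotypeAllele(tox, anti, alias=None)
    raise InputError(
        f"cannot resolve allele token {token!r} at locus {locus.locus_id!r}; "
        f"known aliases: {sorted(amap)}, state tokens: {sorted(STATE_TOKENS)}"
    )


def allele_token(allele: HaplotypeAllele, locus: LocusSpec, prefixed: bool = True) -> str:
    """Compact token for an allele: its alias if consistent, else the state."""
    amap = locus.alias_map
    if (
        allele.alias is not None
        and allele.alias in amap
        and STATE_TOKENS[amap[allele.alias]] == allele.state
    ):
        return (locus.prefix if prefixed else "") + allele.alias
    return _TOKEN_FOR_STATE[allele.state]


def _token_regex(locus: LocusSpec) -> re.Pattern:
    alts = sorted(set(locus.alias_map) | set(STATE_TOKENS), key=len, reverse=True)
    return re.compile(r"\d*(?:" + "|".join(re.escape(a) for a in alts) + ")")


def parse_haplotype(text: str, panel: Panel) -> Haplotype:
    """Parse a single-haplotype string like ``"1M/7D"`` or ``"FA;fa"``."""
    parts = re.split(r"[/;]", text.strip())
    if len(parts) != len(panel):
        raise InputError(
            f"haplotype string {text!r} has {len(parts)} loci, panel has {len(panel)}"
        )
    return Haplotype(
        tuple(allele_from_token(p.strip(), loc) for p, loc in zip(parts, panel.loci))
    )


def parse_genotype(
    text: str, panel: Panel, transgenes: tuple[Transgene, ...] = ()
) -> DiploidGenotype:
    """Parse a genotype string like ``"1M1D;7D7M"`` or ``"FAfa"``."""
    parts = [p.strip() for p in text.strip().split(";")]
    if len(parts) != len(panel):
        raise InputError(
            f"genotype string {text!r} has {len(parts)} loci, panel has {len(panel)}"
        )
    hapA, hapB = [], []
    for part, loc in zip(parts, panel.loci):
        tokens = _token_regex(loc).findall(part.replace("/", "").replace(" ", ""))
        if len(tokens) != 2 or "".join(tokens) != part.replace("/", "").replace(" ", ""):
            raise InputError(
                f"cannot split {part!r} into two allele tokens for locus {loc.locus_id!r}"
            )
        hapA.append(allele_from_token(tokens[0], loc))
        hapB.append(allele_from_token(tokens[1], loc))
    return DiploidGenotype(Haplotype(tuple(hapA)), Haplotype(tuple(hapB)), transgenes)


# ---------------------------------------------------------------------------
# canonical keys


def gamete_key(haplotype: Haplotype, panel: Panel, carried: frozenset = frozenset()) -> str:
    """Canonical key of a (joint) gamete class, e.g. ``"1M/7D"``."""
    base = "/".join(
        allele_token(a, loc) for a, loc in zip(haplotype.alleles, panel.loci)
    )
    if carried:
        base += "|" + ",".join(f"{p}@{t}" for p, t in sorted(carried))
    return base


def _transgene_suffix(transgenes) -> str:
    if not transgenes:
        return ""
    items = sorted(
        f"{t.payload}@{t.target_locus}:{_ZYG_SHORT[t.zygosity]}" for t in transgenes
    )
    return "|" + ",".join(items)


def genotype_key(genotype: DiploidGenotype, panel: Panel) -> str:
    """Canonical order-independent genotype key, e.g. ``"1D1M;7D7M"``.

    Per locus the two allele tokens are sorted, so swapped haplotypes map to
    the same key.  Transgenes append a ``|payload@locus:zygosity`` suffix.
    """
    parts = []
    for i, loc in enumerate(panel.loci):
        toks = sorted(
            [
                allele_token(genotype.hapA.alleles[i], loc),
                allele_token(genotype.hapB.alleles[i], loc),
            ]
        )
        parts.append("".join(toks))
    return ";".join(parts) + _transgene_suffix(genotype.transgenes)


# ---------------------------------------------------------------------------
# convenience genotype builders


def _alias_for_state(locus: LocusSpec, state_token: str) -> HaplotypeAllele:
    for alias, st in locus.aliases:
        if st == state_token:
            tox, anti = STATE_TOKENS[st]
            return HaplotypeAllele(tox, anti, alias=alias)
    tox, anti = STATE_TOKENS[state_token]
    return HaplotypeAllele(tox, anti, alias=None)


def double_heterozygote(panel: Panel, transgenes: tuple[Transgene, ...] = ()) -> DiploidGenotype:
    """Heterozygote carrying the functional haplotype at every locus on one
    chromosome set and the full null on the other (e.g. 1M,7D / 1D,7M)."""
    hapA = Haplotype(tuple(_alias_for_state(loc, "FA") for loc in panel.loci))
    hapB = Haplotype(tuple(_alias_for_state(loc, "fa") for loc in panel.loci))
    return DiploidGenotype(hapA, hapB, transgenes)


def homozygote(panel: Panel, state_token: str = "fa") -> DiploidGenotype:
    hap = Haplotype(tuple(_alias_for_state(loc, state_token) for loc in panel.loci))
    return DiploidGenotype(hap, hap)


# ---------------------------------------------------------------------------
# JSON config


def panel_to_dict(panel: Panel) -> dict:
    return {
        "stages": list(panel.stages),
        "loci": [
            {
                "id": loc.locus_id,
                "chromosome": loc.chromosome,
                "k": loc.killing_efficiency,
                "stage": loc.abortion_stage,
                "functional_origin": loc.functional_origin,
                "aliases": dict(loc.aliases),
            }
            for loc in panel.loci
        ],
    }


def load_panel(source: Union[str, Path, dict], k_override: Optional[dict] = None) -> Panel:
    """Load a panel from a JSON file/dict of the form produced by
    :func:`panel_to_dict`; ``k_override`` maps locus ids to replacement
    killing efficiencies."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = json.load(fh)
    else:
        cfg = source
    try:
        stages = tuple(cfg.get("stages", DEFAULT_STAGES))
        loci = tuple(
            LocusSpec(
                locus_id=entry["id"],
                chromosome=str(entry.get("chromosome", "")),
                killing_efficiency=float(entry.get("k", 1.0)),
                abortion_stage=entry.get("stage", stages[0]),
                functional_origin=entry.get("functional_origin", ""),
                aliases=tuple(sorted(entry.get("aliases", {}).items())),
            )
            for entry in cfg["loci"]
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed panel config: {exc}") from exc
    panel = Panel(loci, stages)
    if k_override:
        panel = panel.with_killing_efficiency(k_override)
    return panel
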