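"""Seeded generators for every input the other modules consume.

Each generator is a pure function of its parameters and a single integer
seed.  Per-generator substreams are derived from the seed plus a stable hash
of the generator name, so adding a generator never perturbs the output of
another.  Generated data carry the statistical structure the analysis
assumes: multinomial genotype counts drawn from model-predicted cross
distributions, multinomial pollen tallies from the abortion profile,
coupling-constrained variety surveys and toy HPT/HPA sequences engineered
with the diagnostic lesions (premature-stop truncation of the toxin,
promoter transposon silencing of the antidote, benign Asn-to-Thr
substitution).
"""
from __future__ import annotations

import zlib
from typing import Optional, Union

import numpy as np

from .alleles import AlleleCallHPA, AlleleCallHPT, ReferenceSpec, VarietyRecord
from .crossing import (
    FemaleTransmissionWeights,
    GenotypeDistribution,
    cross,
    f2_from_double_het,
    self_progeny,
)
from .inference import CountTable
from .model import (
    ConfigurationError,
    DiploidGenotype,
    Panel,
    abortion_profile,
)
from .panel import default_panel, double_heterozygote, homozygote

__all__ = [
    "stream_rng",
    "design_distribution",
    "gen_cross_counts",
    "gen_pollen_counts",
    "gen_survey",
    "gen_reference_toys",
    "reference_fasta",
    "survey_fasta",
    "hpt_truncated_cds",
    "hpa_silenced_promoter",
    "hpa_benign_snp_cds",
]

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named-substream RNG: one global seed, independent per-generator streams."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF])
    )


# ---------------------------------------------------------------------------
# cross count tables


def design_distribution(
    design: str,
    panel: Optional[Panel] = None,
    k: Optional[Union[float, dict]] = None,
    weights: Optional[FemaleTransmissionWeights] = None,
) -> GenotypeDistribution:
    """Model-predicted progeny distribution for a named cross design."""
    panel = panel if panel is not None else default_panel()
    if k is not None:
        panel = panel.with_killing_efficiency(k)
    if design == "self_het":
        from .panel import single_locus_panel

        sub = (
            panel
            if len(panel) == 1
            else single_locus_panel(panel.loci[0].locus_id, panel.loci[0].killing_efficiency, panel)
        )
        return self_progeny(double_heterozygote(sub), sub, weights)
    if design == "testcross":
        from .panel import single_locus_panel

        sub = (
            panel
            if len(panel) == 1
            else single_locus_panel(panel.loci[0].locus_id, panel.loci[0].killing_efficiency, panel)
        )
        return cross(homozygote(sub, "fa"), double_heterozygote(sub), sub, weights)
    if design == "f2_double_het":
        return f2_from_double_het(panel, weights)
    raise ConfigurationError(f"unknown cross design {design!r}")


def gen_cross_counts(
    design: str,
    n: int,
    seed: int,
    panel: Optional[Panel] = None,
    k: Optional[Union[float, dict]] = None,
    weights: Optional[FemaleTransmissionWeights] = None,
) -> CountTable:
    """Draw ``n`` progeny genotypes multinomially from the model-predicted
    distribution of a cross design; bit-reproducible per seed."""
    dist = design_distribution(design, panel, k, weights)
    labels = sorted(dist.entries)
    probs = np.array([dist.entries[l] for l in labels])
    rng = stream_rng(seed, f"cross_counts:{design}")
    counts = rng.multinomial(int(n), probs / probs.sum())
    return CountTable(dict(zip(labels, (int(c) for c in counts))), design=design)


def gen_pollen_counts(
    genotype: DiploidGenotype,
    n_pollen: int,
    seed: int,
    panel: Optional[Panel] = None,
) -> dict:
    """Multinomial pollen tally of one plant: viable count plus aborted
    counts per developmental stage (emulating microscopy scoring of a few
    hundred grains per spikelet)."""
    panel = panel if panel is not None else default_panel()
    profile = abortion_profile(genotype, panel)
    labels = ["viable"] + [f"aborted_{s}" for s in panel.stages]
    probs = np.array(
        [1.0 - sum(profile.values())] + [profile.get(s, 0.0) for s in panel.stages]
    )
    rng = stream_rng(seed, "pollen_counts")
    counts = rng.multinomial(int(n_pollen), probs / probs.sum())
    return dict(zip(labels, (int(c) for c in counts)))


# ---------------------------------------------------------------------------
# toy reference sequences

_REF_SEED_DEFAULT = 20231118  # fixed: the toy reference is a stable artifact


def _random_codons(rng: np.random.Generator, n: int) -> list:
    return [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n)]


def gen_reference_toys(seed: int = _REF_SEED_DEFAULT) -> ReferenceSpec:
    """Deterministic toy reference for allele typing.

    HPT: 902 sense codons plus a single terminal stop, with codon 671
    engineered as GAA so that the diagnostic G-to-T change at CDS nucleotide
    2011 creates a premature stop (TAA) truncating the product to 670 aa.
    HPA: 361 sense codons plus stop (the F-box antidote), with codon 100
    engineered as AAT (Asn) for the benign Asn-to-Thr variant; a 200-bp
    promoter; and a 1391-bp transposon whose flanking bases are chosen to
    keep the insertion point at -11 unambiguous.
    """
    rng = stream_rng(seed, "reference_toys")
    hpt_codons = _random_codons(rng, 902)
    hpt_codons[670] = "GAA"  # codon 671: G->T at its first base gives TAA
    hpt_cds = "".join(hpt_codons) + "TAA"

    hpa_codons = _random_codons(rng, 361)
    hpa_codons[99] = "AAT"  # codon 100: Asn, site of the benign N->T variant
    hpa_cds = "".join(hpa_codons) + "TAA"

    bases = "ACGT"
    promoter = "".join(bases[i] for i in rng.integers(0, 4, size=200))
    te = list(bases[i] for i in rng.integers(0, 4, size=1391))
    # unambiguous flanks: TE must not extend the promoter match at either end
    ins_at = len(promoter) - 11  # string index of the base at position -11
    choices0 = [b for b in bases if b != promoter[ins_at]]
    te[0] = choices0[int(rng.integers(0, 3))]
    choices1 = [b for b in bases if b != promoter[ins_at - 1]]
    te[-1] = choices1[int(rng.integers(0, 3))]

    return ReferenceSpec(
        hpt_cds=hpt_cds,
        hpa_cds=hpa_cds,
        hpa_promoter=promoter,
        te_sequence="".join(te),
    )


def hpt_truncated_cds(reference: ReferenceSpec) -> str:
    """The DJY1-type toxin allele: G->T at the diagnostic CDS position."""
    pos = reference.hpt_diagnostic_stop_nt - 1
    s = reference.hpt_cds
    if s[pos] != "G":
        raise ConfigurationError("reference lacks G at the diagnostic stop position")
    return s[:pos] + "T" + s[pos + 1 :]


def hpa_silenced_promoter(reference: ReferenceSpec) -> str:
    """The DJY1-type antidote promoter: transposon inserted at position -11."""
    prom = reference.hpa_promoter
    cut = len(prom) - 11
    return prom[:cut] + reference.te_sequence + prom[cut:]


def hpa_benign_snp_cds(reference: ReferenceSpec) -> str:
    """HPA CDS carrying the benign Asn->Thr substitution at codon 100."""
    s = reference.hpa_cds
    i = 99 * 3
    codon = s[i : i + 3]
    if codon != "AAT":
        raise ConfigurationError("reference lacks the engineered Asn codon")
    return s[:i] + "ACT" + s[i + 3 :]


def reference_fasta(reference: ReferenceSpec) -> str:
    """Reference toys as FASTA text (HPT CDS, HPA CDS, HPA promoter, TE)."""
    parts = [
        (">HPT_CDS reference", reference.hpt_cds),
        (">HPA_CDS reference", reference.hpa_cds),
        (">HPA_promoter reference", reference.hpa_promoter),
        (">TE insertion_element", reference.te_sequence),
    ]
    lines = []
    for header, seq in parts:
        lines.append(header)
        lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# variety surveys


def _calls_for_class(
    cls: str, benign_snp: bool, hpt_absent: bool, reference: ReferenceSpec
) -> tuple[AlleleCallHPT, AlleleCallHPA]:
    if cls[0] == "F":
        hpt = AlleleCallHPT("functional", reference.hpt_protein_length, "full-length")
    elif hpt_absent:
        hpt = AlleleCallHPT("absent", None, "gene lost")
    else:
        hpt = AlleleCallHPT("truncated", 670, "premature stop after 670 aa")
    if cls[1] == "A":
        hpa = AlleleCallHPA(
            "expressed_functional",
            coding_variants=("N100T",) if benign_snp else (),
            evidence="promoter clean",
        )
    else:
        hpa = AlleleCallHPA(
            "te_silenced",
            promoter_insertion_length=len(reference.te_sequence),
            coding_variants=("N100T",) if benign_snp else (),
            evidence=f"{len(reference.te_sequence)}-bp insertion at -11",
        )
    return hpt, hpa


def gen_survey(
    n: int,
    seed: int,
    class_freqs: Optional[dict] = None,
    species: str = "O_rufipogon",
    constraint: bool = True,
    benign_snp_prob: float = 0.5,
    hpt_absent_prob: float = 0.0,
    reference: Optional[ReferenceSpec] = None,
) -> list:
    """Sample ``n`` :class:`~tadote.alleles.VarietyRecord` accessions.

    ``class_freqs`` is a distribution over haplotype classes; by default it
    follows the wild Asian progenitor survey (functional element in 53/76,
    toxin-dead antidote-expressed in 18/76, fully silenced in 5/76).  With
    the coupling constraint on (default), any requested ``Fa`` frequency is
    an error — a free-standing functional toxin does not survive in nature.
    ``hpt_absent_prob`` lets toxin-dead classes carry gene loss instead of
    the truncation.
    """
    if class_freqs is None:
        class_freqs = {"FA": 53 / 76, "fA": 18 / 76, "fa": 5 / 76}
    if constraint and class_freqs.get("Fa", 0.0) > 0.0:
        raise ConfigurationError(
            "coupling constraint: haplotype class Fa (functional toxin, "
            "silenced antidote) cannot be generated; pass constraint=False "
            "to override"
        )
    reference = reference if reference is not None else gen_reference_toys()
    classes = sorted(class_freqs)
    probs = np.array([class_freqs[c] for c in classes], dtype=float)
    if probs.min() < 0 or probs.sum() <= 0:
        raise ConfigurationError("class frequencies must be nonnegative with positive sum")
    probs = probs / probs.sum()
    rng = stream_rng(seed, f"survey:{species}")
    draws = rng.choice(len(classes), size=int(n), p=probs)
    benign = rng.random(int(n)) < benign_snp_prob
    absent = rng.random(int(n)) < hpt_absent_prob
    records = []
    for i, d in enumerate(draws):
        cls = classes[d]
        hpt, hpa = _calls_for_class(cls, bool(benign[i]), bool(absent[i]), reference)
        records.append(
            VarietyRecord(
                accession=f"{species}_{i + 1:04d}",
                species=species,
                hpt=hpt,
                hpa=hpa,
            )
        )
    return records


def survey_fasta(records, reference: Optional[ReferenceSpec] = None) -> str:
    """Toy sequences for surveyed accessions, engineered with the
    class-defining variants; round-trips through the FASTA classifier."""
    reference = reference if reference is not None else gen_reference_toys()
    trunc = hpt_truncated_cds(reference)
    silenced_prom = hpa_silenced_promoter(reference)
    benign_cds = hpa_benign_snp_cds(reference)
    lines = []

    def emit(header: str, seq: str) -> None:
        lines.append(header)
        lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))

    for r in records:
        desc = f"species={r.species} class={r.haplotype_class}"
        if r.hpt.allele_class == "functional":
            emit(f">{r.accession}|HPT_CDS {desc}", reference.hpt_cds)
        elif r.hpt.allele_class == "truncated":
            emit(f">{r.accession}|HPT_CDS {desc}", trunc)
        # absent: no HPT record at all
        prom = (
            silenced_prom
            if r.hpa.allele_class == "te_silenced"
            else reference.hpa_promoter
        )
        cds = benign_cds if "N100T" in r.hpa.coding_variants else reference.hpa_cds
        if r.hpa.allele_class != "absent":
            emit(f">{r.accession}|HPA_promoter_cds {desc}", prom + cds)
    return "\n".join(lines) + "\n"
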