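"""Rule-based typing of toxin (HPT) and antidote (HPA) alleles.

The diagnostic lesions, established by the cloning work this package models,
are desk-scale and rule-based:

* HPT (a 902-aa DEAD-box-helicase-family toxin): a G-to-T substitution
  creates a premature stop, truncating the protein to 670 aa and abolishing
  toxicity; in some lineages the gene is lost outright.  Classification
  translates the CDS to the first stop and compares lengths.
* HPA (a 361-aa F-box antidote): a 1391-bp transposon inserted 11 bp
  upstream of the ATG silences transcription; a benign Asn-to-Thr coding
  substitution does not affect function.  Classification looks for a long
  insertion inside the promoter window; coding variants are reported but
  never change the class.

Typed accessions yield a haplotype class (FA / fA / Fa / fa: functional
toxin F, expressed antidote A); surveys respect the coupling rule that a
functional toxin is always accompanied by an expressed antidote (class Fa
is a violation), and pairwise cross-compatibility follows from the
gamete-killing model.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio.Seq import Seq

from .model import InputError
from .panel import single_locus_panel, STATE_TOKENS
from .model import DiploidGenotype, Haplotype, HaplotypeAllele, pollen_fertility

__all__ = [
    "ReferenceSpec",
    "AlleleCallHPT",
    "AlleleCallHPA",
    "VarietyRecord",
    "classify_hpt",
    "classify_hpa",
    "classify_from_variants",
    "type_variety",
    "classify_fasta",
    "survey_summarize",
    "coupling_audit",
    "predict_cross_sterility",
    "records_to_frame",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class ReferenceSpec:
    """Reference sequences and rule thresholds for allele typing.

    Coordinates: CDS positions are 1-based from the A of ATG (= +1);
    promoter positions are negative, with -1 the base immediately 5' of the
    ATG.  The promoter window is half-open ``[-200, -1]`` by default; an
    insertion's position is that of the base immediately 3' of the insertion
    point.
    """

    hpt_cds: str
    hpa_cds: str
    hpa_promoter: str
    te_sequence: str = ""
    hpt_protein_length: int = 902
    hpa_protein_length: int = 361
    hpt_diagnostic_stop_nt: int = 2011  # first base of the stop-creating codon
    promoter_window: tuple[int, int] = (-200, -1)
    te_min_length: int = 50

    def to_dict(self) -> dict:
        return {
            "hpt_cds": self.hpt_cds,
            "hpa_cds": self.hpa_cds,
            "hpa_promoter": self.hpa_promoter,
            "te_sequence": self.te_sequence,
            "hpt_protein_length": self.hpt_protein_length,
            "hpa_protein_length": self.hpa_protein_length,
            "hpt_diagnostic_stop_nt": self.hpt_diagnostic_stop_nt,
            "promoter_window": list(self.promoter_window),
            "te_min_length": self.te_min_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceSpec":
        d = dict(d)
        d["promoter_window"] = tuple(d.get("promoter_window", (-200, -1)))
        return cls(**d)


@dataclass(frozen=True)
class AlleleCallHPT:
    allele_class: str  # functional | truncated | absent
    protein_length: Optional[int]
    evidence: str = ""


@dataclass(frozen=True)
class AlleleCallHPA:
    allele_class: str  # expressed_functional | te_silenced | absent
    promoter_insertion_length: Optional[int] = None
    coding_variants: tuple = ()
    evidence: str = ""


@dataclass(frozen=True)
class VarietyRecord:
    accession: str
    species: str
    hpt: AlleleCallHPT
    hpa: AlleleCallHPA

    @property
    def haplotype_class(self) -> str:
        f = "F" if self.hpt.allele_class == "functional" else "f"
        a = "A" if self.hpa.allele_class == "expressed_functional" else "a"
        return f + a


def _clean_seq(seq, what: str) -> str:
    s = str(getattr(seq, "seq", seq)).upper()
    bad = set(s) - _VALID
    if bad:
        raise InputError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return s


def _translate_to_stop(cds: str) -> str:
    return str(Seq(cds).translate(to_stop=True))


def classify_hpt(cds, reference: ReferenceSpec) -> AlleleCallHPT:
    """Classify an HPT coding sequence as functional / truncated / absent.

    ``cds`` may be a string, Seq/SeqRecord, or None/empty (gene lost).  The
    sequence is translated to the first stop codon; a product shorter than
    the reference protein is a truncation (loss of toxicity), equal length is
    functional.
    """
    if cds is None or (isinstance(cds, str) and not cds):
        return AlleleCallHPT("absent", None, evidence="no record")
    s = _clean_seq(cds, "HPT CDS")
    if len(s) % 3 != 0:
        raise InputError(f"HPT CDS length {len(s)} is not divisible by 3")
    prot_len = len(_translate_to_stop(s))
    ref_len = reference.hpt_protein_length
    if prot_len < ref_len:
        return AlleleCallHPT("truncated", prot_len, evidence=f"premature stop after {prot_len} aa")
    if prot_len == ref_len:
        return AlleleCallHPT("functional", prot_len, evidence=f"full-length {prot_len} aa")
    raise InputError(
        f"HPT product of {prot_len} aa exceeds the {ref_len}-aa reference "
        "(stop codon lost); outside the classification vocabulary"
    )


def _find_insertion(query: str, ref: str) -> tuple[int, int]:
    """Locate a single inserted block: returns (0-based ref prefix, length)."""
    ins_len = len(query) - len(ref)
    lcp = 0
    while lcp < len(ref) and query[lcp] == ref[lcp]:
        lcp += 1
    lcs = 0
    while lcs < len(ref) - lcp and query[len(query) - 1 - lcs] == ref[len(ref) - 1 - lcs]:
        lcs += 1
    if lcp + lcs < len(ref):
        # flanks do not reconstruct the reference: not a clean single insertion
        lcp = min(lcp, len(ref) - lcs)
    return lcp, ins_len


def classify_hpa(
    promoter,
    cds,
    reference: ReferenceSpec,
) -> AlleleCallHPA:
    """Classify an HPA allele as expressed_functional / te_silenced / absent.

    Silencing requires an insertion of at least ``te_min_length`` bases whose
    position (the base immediately 3' of the insertion point, ATG A = +1,
    upstream negative) falls inside the promoter window.  Coding variants
    (amino-acid substitutions against the reference) are reported but do not
    change the class: a merely substituted antidote remains functional once
    transcribed.
    """
    if (promoter is None or promoter == "") and (cds is None or cds == ""):
        return AlleleCallHPA("absent", evidence="no record")
    if promoter is None or promoter == "":
        raise InputError("cannot assess silencing: promoter region missing")
    prom = _clean_seq(promoter, "HPA promoter")
    ref_prom = reference.hpa_promoter
    L = len(ref_prom)

    ins_len: Optional[int] = None
    silenced = False
    evidence = "promoter matches reference"
    if len(prom) > len(ref_prom):
        prefix, ins_len = _find_insertion(prom, ref_prom)
        position = prefix - L  # base immediately 3' of the insertion point
        lo, hi = reference.promoter_window
        in_window = lo <= position <= hi
        if ins_len >= reference.te_min_length and in_window:
            silenced = True
            evidence = f"{ins_len}-bp insertion at {position} within promoter window"
        else:
            evidence = f"{ins_len}-bp insertion at {position} (below threshold or outside window)"
    elif len(prom) < len(ref_prom):
        evidence = f"promoter {L - len(prom)}-bp shorter than reference"

    variants: list[str] = []
    if cds:
        s = _clean_seq(cds, "HPA CDS")
        if len(s) % 3 != 0:
            raise InputError(f"HPA CDS length {len(s)} is not divisible by 3")
        prot = str(Seq(s).translate(to_stop=True))
        ref_prot = str(Seq(reference.hpa_cds).translate(to_stop=True))
        if len(prot) < len(ref_prot):
            variants.append(f"premature_stop@{len(prot) + 1}")
        for i, (a, b) in enumerate(zip(ref_prot, prot), start=1):
            if a != b:
                variants.append(f"{a}{i}{b}")

    return AlleleCallHPA(
        "te_silenced" if silenced else "expressed_functional",
        promoter_insertion_length=ins_len,
        coding_variants=tuple(variants),
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# variant-table route


def _apply_variants(ref: str, variants: Sequence[dict], offset: int = 0) -> str:
    """Apply snp/ins/del records (1-based positions, after ``offset``) to a
    reference string; coordinates refer to the reference."""
    edits = sorted(variants, key=lambda v: int(v["pos"]), reverse=True)
    s = ref
    for v in edits:
        pos = int(v["pos"]) - 1 - offset
        if not 0 <= pos <= len(s):
            raise InputError(f"variant position {v['pos']} outside the reference")
        vt = v["type"]
        if vt == "snp":
            if s[pos] != str(v.get("ref", s[pos])).upper():
                raise InputError(f"reference mismatch at position {v['pos']}")
            s = s[:pos] + str(v["alt"]).upper() + s[pos + 1 :]
        elif vt == "ins":
            alt = str(v.get("alt", "")).upper()
            if not alt and "length" in v:
                alt = "A" * int(v["length"])
            s = s[:pos] + alt + s[pos:]
        elif vt == "del":
            length = int(v.get("length", len(str(v.get("ref", "")))))
            s = s[:pos] + s[pos + length :]
        else:
            raise InputError(f"unknown variant type {vt!r}")
    return s


def classify_from_variants(
    gene: str, variants: Sequence[dict], reference: ReferenceSpec
):
    """Classify a gene from a variant record list against the reference.

    Records are dicts with keys ``type`` (snp/ins/del/absent), ``pos``
    (1-based; A of ATG = +1, promoter positions negative), ``ref``, ``alt``,
    ``length``.  A single ``absent`` record marks gene loss.
    """
    if any(v["type"] == "absent" for v in variants):
        if gene.upper() == "HPT":
            return AlleleCallHPT("absent", None, evidence="marked absent")
        return AlleleCallHPA("absent", evidence="marked absent")
    if gene.upper() == "HPT":
        cds = _apply_variants(reference.hpt_cds, variants)
        return classify_hpt(cds, reference)
    if gene.upper() == "HPA":
        prom_vars = [v for v in variants if int(v["pos"]) < 0]
        cds_vars = [v for v in variants if int(v["pos"]) > 0]
        L = len(reference.hpa_promoter)
        # promoter coordinates -L..-1 map onto string positions 1..L
        shifted = [{**v, "pos": int(v["pos"]) + L + 1} for v in prom_vars]
        prom = _apply_variants(reference.hpa_promoter, shifted)
        cds = _apply_variants(reference.hpa_cds, cds_vars)
        return classify_hpa(prom, cds, reference)
    raise InputError(f"unknown gene {gene!r}; expected 'HPT' or 'HPA'")


# ---------------------------------------------------------------------------
# surveys


def type_variety(
    accession: str,
    species: str,
    hpt_cds,
    hpa_promoter,
    hpa_cds,
    reference: ReferenceSpec,
) -> VarietyRecord:
    return VarietyRecord(
        accession=accession,
        species=species,
        hpt=classify_hpt(hpt_cds, reference),
        hpa=classify_hpa(hpa_promoter, hpa_cds, reference),
    )


def classify_fasta(path: Union[str, Path], reference: ReferenceSpec) -> list:
    """Type every accession in a FASTA panel.

    Record ids follow ``<accession>|HPT_CDS`` and
    ``<accession>|HPA_promoter_cds`` (promoter immediately followed by the
    fixed-length CDS); descriptions may carry ``species=<label>``.  A missing
    HPT record is called absent (gene loss).
    """
    from Bio import SeqIO

    by_acc: dict = {}
    species: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise InputError(f"FASTA id {rec.id!r} lacks the '<acc>|<part>' form")
        acc, part = rec.id.split("|", 1)
        by_acc.setdefault(acc, {})[part] = str(rec.seq).upper()
        for tok in rec.description.split():
            if tok.startswith("species="):
                species[acc] = tok.split("=", 1)[1]
    cds_len = len(reference.hpa_cds)
    records = []
    for acc in sorted(by_acc):
        parts = by_acc[acc]
        hpt = parts.get("HPT_CDS")
        combo = parts.get("HPA_promoter_cds")
        if combo is None:
            prom, cds = None, None
        else:
            if len(combo) <= cds_len:
                raise InputError(
                    f"record {acc}|HPA_promoter_cds shorter than the reference CDS; "
                    "cannot split promoter from coding region"
                )
            prom, cds = combo[:-cds_len], combo[-cds_len:]
        records.append(
            VarietyRecord(
                accession=acc,
                species=species.get(acc, "unknown"),
                hpt=classify_hpt(hpt, reference),
                hpa=classify_hpa(prom, cds, reference),
            )
        )
    return records


def survey_summarize(records: Iterable[VarietyRecord], group_by: str = "species") -> pd.DataFrame:
    """Per-group counts and percentages of haplotype and allele classes.

    Percentages are rounded to one decimal.  Empty input yields an empty
    frame.
    """
    recs = list(records)
    rows = []
    for r in recs:
        rows.append(
            {
                "accession": r.accession,
                "species": r.species,
                "haplotype_class": r.haplotype_class,
                "hpt_class": r.hpt.allele_class,
                "hpa_class": r.hpa.allele_class,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["group", "category", "class", "count", "total", "percent"]
        )
    out = []
    for grp, sub in df.groupby(group_by):
        total = len(sub)
        for category in ("haplotype_class", "hpt_class", "hpa_class"):
            for cls, cnt in sub[category].value_counts().items():
                out.append(
                    {
                        "group": grp,
                        "category": category,
                        "class": cls,
                        "count": int(cnt),
                        "total": total,
                        "percent": round(100.0 * cnt / total, 1),
                    }
                )
    return pd.DataFrame(out).sort_values(["group", "category", "class"]).reset_index(drop=True)


def coupling_audit(records: Iterable[VarietyRecord]) -> list:
    """Return every record violating the toxin-antidote coupling rule.

    A functional toxin must ride with an expressed antidote (a free-standing
    toxin would sterilize its own carrier), so haplotype class ``Fa`` is a
    violation; an empty list is an audit pass.
    """
    return [r for r in records if r.haplotype_class == "Fa"]


def _class_allele(cls: str) -> HaplotypeAllele:
    tox, anti = STATE_TOKENS[cls]
    return HaplotypeAllele(tox, anti)


def predict_cross_sterility(parent1, parent2) -> dict:
    """Predicted F1 pollen fertility for a cross of two typed varieties.

    Parents may be :class:`VarietyRecord` objects or haplotype-class strings.
    The F1 genotype is built at the toxin-antidote locus with complete
    killing (k = 1); the prediction is symmetric in the parents.  Labels:
    ``compatible`` (fertility 1), ``semi-sterile`` (0.5), ``sterile`` (0).
    """
    classes = []
    for p in (parent1, parent2):
        if isinstance(p, VarietyRecord):
            classes.append(p.haplotype_class)
        elif isinstance(p, str) and p in STATE_TOKENS:
            classes.append(p)
        else:
            raise InputError(f"parent {p!r} is not typed at the locus")
    panel = single_locus_panel("qHMS1", k=1.0)
    geno = DiploidGenotype(
        Haplotype((_class_allele(classes[0]),)), Haplotype((_class_allele(classes[1]),))
    )
    fert = pollen_fertility(geno, panel)
    if fert >= 1.0 - 1e-12:
        label = "compatible"
    elif abs(fert - 0.5) < 1e-12:
        label = "semi-sterile"
    elif fert <= 1e-12:
        label = "sterile"
    else:
        label = "partially-sterile"
    return {
        "parents": tuple(classes),
        "f1_pollen_fertility": fert,
        "label": label,
    }


def records_to_frame(records: Iterable[VarietyRecord]) -> pd.DataFrame:
    rows = [
        {
            "accession": r.accession,
            "species": r.species,
            "hpt_class": r.hpt.allele_class,
            "hpt_protein_length": r.hpt.protein_length,
            "hpa_class": r.hpa.allele_class,
            "hpa_insertion_length": r.hpa.promoter_insertion_length,
            "haplotype_class": r.haplotype_class,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
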