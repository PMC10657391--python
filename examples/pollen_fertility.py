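"""Pollen fertility predicted by the gamete-killing model.

Builds the classical genotype series at the qHMS1 toxin-antidote locus
(null homozygote, functional homozygote, heterozygote, CRISPR knockouts,
transgene carriers) and prints percent viable pollen for each.  The toxin is
sporophytic (made by the plant, delivered to every pollen grain); the
antidote is gametophytic and cis-acting (protects only the grains that carry
it), so the heterozygote loses exactly the pollen carrying the null
haplotype.
"""
import tadote as td

sub1 = td.single_locus_panel("qHMS1", k=1.0)
het = td.parse_genotype("1M1D", sub1)

cases = [
    ("D/D  (cultivated parent)", td.homozygote(sub1, "fa")),
    ("M/M  (introgression line)", td.parse_genotype("1M1M", sub1)),
    ("M/D  (F1 hybrid)", het),
    ("M/D, toxin knocked out", td.edit_genotype(het, "qHMS1", "toxin", panel=sub1)),
    ("M/D, antidote knocked out", td.edit_genotype(het, "qHMS1", "antidote", panel=sub1)),
    ("D/D + toxin transgene", td.parse_genotype("1D1D", sub1, (td.Transgene("toxin", "qHMS1"),))),
    ("M/D + antidote transgene", td.parse_genotype("1M1D", sub1, (td.Transgene("antidote", "qHMS1"),))),
]

print(f"{'genotype':<30} viable pollen")
for label, genotype in cases:
    fert = td.pollen_fertility(genotype, sub1)
    print(f"{label:<30} {100 * fert:5.1f}%")

print()
print("The heterozygote is semi-sterile (50%): its null-haplotype pollen is")
print("exposed to the toxin but carries no antidote.  Removing the toxin")
print("restores full fertility; removing the antidote kills every grain; one")
print("hemizygous antidote transgene rescues half of the doomed class (75%).")
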