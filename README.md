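# tadote

Toxin-antidote gamete-killer genetics: an exact model of pollen killing by
tightly linked toxin-antidote (TA) hybrid-sterility loci of the rice
qHMS1/qHMS7 type, with cross simulation, likelihood inference, gene-drive
dynamics, allele typing and seeded synthetic data.

## The problem

Hybrids between cultivated rice and its wild relatives are often
male-sterile because of selfish TA loci: a **toxin** made sporophytically
by the diploid plant poisons *all* of its developing pollen, while the
linked **antidote** acts gametophytically in cis and rescues only the
grains that inherit it.  In a heterozygote carrying one functional element
(haplotype `FA`) opposite a null (`fa`), the half of the pollen carrying
the null haplotype dies — 50% pollen abortion and complete distortion of
male transmission.  Stacking two such loci with opposite functional origins
kills 75% of pollen in two developmental stages and leaves a single viable
pollen class.

For a genotype `G` over unlinked TA loci, each gamete class with Mendelian
prior frequency `p_g` survives with probability

```
s_g = prod over loci l [ 1 - k_l * exposed_l(G) * (1 - protected_l(g)) ]
```

where `k_l` is the locus killing efficiency, `exposed_l(G)` says the plant
carries a functional toxin (or toxin transgene) at `l`, and
`protected_l(g)` says the gamete itself carries a functional antidote (or
antidote transgene).  Pollen fertility is `sum p_g s_g`.  Everything else —
cross progeny distributions, the likelihood for estimating `k` from
leak-through counts, the female-transmission-weight MLE in the stacked F2,
and the haplotype-frequency recursion for drive dynamics — is built on this
rule.  See `docs/methods.md` for the full account.

This package is for geneticists and modelers who want to predict cross
outcomes at such loci, fit killing efficiency and transmission bias from
genotype count tables, explore when TA haplotypes invade or decay in
populations, and type toxin/antidote alleles from diagnostic variants.

## Worked example

```python
import tadote as td

sub1 = td.single_locus_panel("qHMS1", k=1.0)   # one TA locus, complete killing
het  = td.parse_genotype("1M1D", sub1)          # functional / null heterozygote

td.pollen_fertility(het, sub1)                  # 0.5
td.pollen_fertility(td.edit_genotype(het, "qHMS1", "antidote", panel=sub1), sub1)  # 0.0
```

Running `python examples/pollen_fertility.py` prints the classical genotype
series:

```
genotype                       viable pollen
D/D  (cultivated parent)       100.0%
M/M  (introgression line)      100.0%
M/D  (F1 hybrid)                50.0%
M/D, toxin knocked out         100.0%
M/D, antidote knocked out        0.0%
D/D + toxin transgene            0.0%
M/D + antidote transgene        75.0%
```

The heterozygote is semi-sterile because its null-haplotype pollen is
exposed but unprotected; knocking out the toxin restores full fertility,
knocking out the antidote kills every grain, and a single hemizygous
antidote transgene rescues half the doomed class.  The other examples cover
reciprocal crosses and killing-efficiency estimation from leak-through
(`crosses_and_leak_through.py`), the stacked two-locus hybrid and the
female-bias likelihood-ratio test (`stacked_loci.py`), drive trajectories
and the mutation-order experiment (`drive_trajectories.py`), and allele
typing with survey summaries and compatibility prediction
(`allele_survey.py`).

A thin CLI mirrors the library:

```bash
tadote fertility --genotype "1M1D;7D7M"
tadote cross --female "1M1D" --male "1D1D" --config panel.json
tadote fit --design self_het --counts counts.tsv
tadote drive --init FA=0.05,fa=0.95 --selfing 0.0 --generations 200
```

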