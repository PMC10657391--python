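"""Gamete-killing model: phenotype table, invariants, enumeration oracle."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tadote as td
from helpers import oracle_pollen_fertility


def _het(sub1, transgenes=()):
    return td.parse_genotype("1M1D", sub1, transgenes=transgenes)


# ---------------------------------------------------------------------------
# the experimental phenotype table (complete killing, k = 1)

TOXIN_TG = td.Transgene("toxin", "qHMS1", "hemizygous")
ANTIDOTE_TG = td.Transgene("antidote", "qHMS1", "hemizygous")


def _ko(genotype_str, gene, mode="knockout_both", hap="A"):
    def build(sub):
        g = td.parse_genotype(genotype_str, sub)
        return td.edit_genotype(g, "qHMS1", gene, mode=mode, panel=sub, haplotype=hap)

    return build


PHENOTYPES = [
    # null homozygote (cultivated parent): fully fertile
    ("1D1D", lambda s: td.parse_genotype("1D1D", s), 1.0),
    # functional-element homozygote (near-isogenic introgression line): fertile
    ("1M1M", lambda s: td.parse_genotype("1M1M", s), 1.0),
    # F1 heterozygote: semi-sterile
    ("1M1D", lambda s: td.parse_genotype("1M1D", s), 0.5),
    # antidote knockout in the F1: complete sterility
    ("1M1D antidote-KO", _ko("1M1D", "antidote"), 0.0),
    # antidote knockout in the M homozygote: complete sterility
    ("1M1M antidote-KO", _ko("1M1M", "antidote"), 0.0),
    # toxin transgene dropped into the null background: full sterility
    ("1D1D + toxin tg", lambda s: td.parse_genotype("1D1D", s, (TOXIN_TG,)), 0.0),
    # toxin knocked out on the functional haplotype: fully fertile F1
    ("toxin-KO F1", _ko("1M1D", "toxin"), 1.0),
    # toxin knocked out on the (already dead) null haplotype: still semi-sterile
    ("1M x toxin-KO null", _ko("1M1D", "toxin", mode="knockout_hap", hap="B"), 0.5),
    # one hemizygous antidote transgene rescues half the killed pollen
    ("1M1D + antidote tg", lambda s: td.parse_genotype("1M1D", s, (ANTIDOTE_TG,)), 0.75),
]


@pytest.mark.parametrize("label,build,expected", PHENOTYPES, ids=[p[0] for p in PHENOTYPES])
def test_single_locus_phenotypes(sub1, label, build, expected):
    assert td.pollen_fertility(build(sub1), sub1) == pytest.approx(expected, abs=1e-12)


def test_double_het_fertility_and_surviving_pool(panel):
    """Stacking both loci leaves a quarter of pollen alive: the single class
    carrying the functional haplotype at both loci."""
    dh = td.double_heterozygote(panel)
    assert td.pollen_fertility(dh, panel) == pytest.approx(0.25, abs=1e-12)
    surviving = td.male_gamete_distribution(dh, panel).surviving()
    assert len(surviving) == 1
    assert td.gamete_key(surviving[0].haplotype, panel) == "1M/7D"
    assert surviving[0].post_freq == pytest.approx(1.0, abs=1e-12)


def test_abortion_profile_examples(panel, sub1):
    dh = td.double_heterozygote(panel)
    profile = td.abortion_profile(dh, panel)
    assert profile == pytest.approx({"uninucleate": 0.5, "binucleate": 0.25}, abs=1e-12)
    het = _het(sub1)
    assert td.abortion_profile(het, sub1) == pytest.approx({"uninucleate": 0.5}, abs=1e-12)
    assert td.abortion_profile(td.homozygote(sub1, "fa"), sub1) == {}


def test_toxin_exposure_rules(sub1):
    het = _het(sub1)
    assert td.toxin_exposure(het, "qHMS1", sub1)
    dd = td.homozygote(sub1, "fa")
    assert not td.toxin_exposure(dd, "qHMS1", sub1)
    dd_tg = td.parse_genotype("1D1D", sub1, (TOXIN_TG,))
    assert td.toxin_exposure(dd_tg, "qHMS1", sub1)
    with pytest.raises(td.ConfigurationError):
        td.toxin_exposure(het, "qHMS9", sub1)


def test_gamete_protection_is_cis_only(sub1):
    het = _het(sub1)
    dist = td.male_gamete_distribution(het, sub1)
    by_key = {td.gamete_key(c.haplotype, sub1): c for c in dist.classes}
    assert td.gamete_protected(by_key["1M"], "qHMS1", sub1)
    assert not td.gamete_protected(by_key["1D"], "qHMS1", sub1)
    # an antidote transgene protects exactly the gametes that carry it
    het_tg = _het(sub1, (ANTIDOTE_TG,))
    dist = td.male_gamete_distribution(het_tg, sub1)
    for c in dist.classes:
        expect = c.haplotype.alleles[0].antidote_functional or bool(c.transgenes_carried)
        assert td.gamete_protected(c, "qHMS1", sub1) == expect


def test_edit_genotype_null_background_is_inert(sub1):
    dd = td.homozygote(sub1, "fa")
    edited = td.edit_genotype(dd, "qHMS1", "toxin", panel=sub1)
    assert td.pollen_fertility(edited, sub1) == 1.0
    # knockout of the antidote without any toxin is equally inert
    edited = td.edit_genotype(dd, "qHMS1", "antidote", panel=sub1)
    assert td.pollen_fertility(edited, sub1) == 1.0


def test_complete_sterility_is_not_an_error(sub1):
    ko = td.edit_genotype(_het(sub1), "qHMS1", "antidote", panel=sub1)
    dist = td.male_gamete_distribution(ko, sub1)
    assert dist.viable_fraction == 0.0
    assert dist.surviving() == ()


# ---------------------------------------------------------------------------
# hypothesis strategies for random panels and genotypes


@st.composite
def panels(draw, max_loci=3):
    n_loci = draw(st.integers(1, max_loci))
    stages = ("uninucleate", "binucleate", "tricellular")
    loci = tuple(
        td.LocusSpec(
            locus_id=f"L{i}",
            killing_efficiency=draw(
                st.floats(0.0, 1.0, allow_nan=False, allow_infinity=False)
            ),
            abortion_stage=stages[draw(st.integers(0, 2))],
        )
        for i in range(n_loci)
    )
    return td.Panel(loci, stages)


@st.composite
def genotypes(draw, panel, max_transgenes=2):
    def hap():
        return td.Haplotype(
            tuple(
                td.HaplotypeAllele(draw(st.booleans()), draw(st.booleans()))
                for _ in panel.loci
            )
        )

    n_tg = draw(st.integers(0, max_transgenes))
    idents = draw(
        st.lists(
            st.tuples(
                st.sampled_from(["toxin", "antidote"]),
                st.sampled_from([loc.locus_id for loc in panel.loci]),
            ),
            min_size=n_tg,
            max_size=n_tg,
            unique=True,
        )
    )
    tgs = tuple(
        td.Transgene(p, t, draw(st.sampled_from(["hemizygous", "homozygous"])))
        for p, t in idents
    )
    return td.DiploidGenotype(hap(), hap(), tgs)


@st.composite
def panel_and_genotype(draw):
    p = draw(panels())
    return p, draw(genotypes(p))


@given(panel_and_genotype())
def test_distribution_normalizes(pg):
    p, g = pg
    dist = td.male_gamete_distribution(g, p)
    assert sum(c.prior_freq for c in dist.classes) == pytest.approx(1.0, abs=1e-12)
    assert dist.viable_fraction == pytest.approx(
        sum(c.prior_freq * c.survival_prob for c in dist.classes), abs=1e-12
    )
    if dist.viable_fraction > 0:
        assert sum(c.post_freq for c in dist.classes) == pytest.approx(1.0, abs=1e-12)
    profile = td.abortion_profile(g, p)
    assert sum(profile.values()) + dist.viable_fraction == pytest.approx(1.0, abs=1e-12)


@given(panel_and_genotype())
def test_haplotype_order_symmetry(pg):
    p, g = pg
    swapped = g.swapped()
    assert td.pollen_fertility(g, p) == pytest.approx(
        td.pollen_fertility(swapped, p), abs=1e-15
    )
    assert td.abortion_profile(g, p) == pytest.approx(td.abortion_profile(swapped, p))
    assert td.genotype_key(g, p) == td.genotype_key(swapped, p)


@given(panel_and_genotype())
def test_mendelian_limit(pg):
    """With k = 0 everywhere no selection acts: full fertility, post == prior."""
    p, g = pg
    p0 = p.with_killing_efficiency(0.0)
    dist = td.male_gamete_distribution(g, p0)
    assert dist.viable_fraction == pytest.approx(1.0, abs=1e-12)
    for c in dist.classes:
        assert c.post_freq == pytest.approx(c.prior_freq, abs=1e-12)
    assert td.abortion_profile(g, p0) == {}


@given(panel_and_genotype())
def test_no_toxin_neutrality(pg):
    """Without any functional toxin, antidote states are irrelevant."""
    p, g = pg
    no_toxin = td.DiploidGenotype(
        td.Haplotype(
            tuple(td.HaplotypeAllele(False, a.antidote_functional) for a in g.hapA.alleles)
        ),
        td.Haplotype(
            tuple(td.HaplotypeAllele(False, a.antidote_functional) for a in g.hapB.alleles)
        ),
        tuple(t for t in g.transgenes if t.payload != "toxin"),
    )
    assert td.pollen_fertility(no_toxin, p) == 1.0
    stripped = td.DiploidGenotype(
        td.Haplotype(tuple(td.HaplotypeAllele(False, False) for _ in p.loci)),
        td.Haplotype(tuple(td.HaplotypeAllele(False, False) for _ in p.loci)),
        (),
    )
    assert td.pollen_fertility(stripped, p) == 1.0


@given(panel_and_genotype())
def test_brute_force_enumeration_oracle(pg):
    """Exhaustive per-meiosis enumeration equals the model to 1e-12."""
    p, g = pg
    assert td.pollen_fertility(g, p) == pytest.approx(
        oracle_pollen_fertility(g, p), abs=1e-12
    )


def test_invalid_configuration_rejected():
    with pytest.raises(td.ConfigurationError):
        td.LocusSpec(locus_id="L0", killing_efficiency=1.5)
    with pytest.raises(td.ConfigurationError):
        td.Panel((td.LocusSpec(locus_id="L0", abortion_stage="vacuolated"),))
    with pytest.raises(td.ConfigurationError):
        td.Transgene("poison", "qHMS1")
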