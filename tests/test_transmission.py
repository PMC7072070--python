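"""Meiosis, UCO gamete formation, crosses, selfing screens."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flocuscnv import (
    Genotype,
    UCOParams,
    build_line_structure,
    confirm_mutants,
    cross,
    dosage_phenotype,
    enumerate_gametes,
    evolve_selfing,
    expected_screen,
    hap,
    self_population,
    simulate_meiosis,
)
from flocuscnv.transmission import ScreenDesign, SexPhenotype, _uco_pairs
from flocuscnv.synthetic_data import table1_populations

G = Genotype.from_string

haplotypes = st.text(alphabet="AG", min_size=1, max_size=4)
genotypes = st.builds(lambda a, b: Genotype(hap(a), hap(b)),
                      haplotypes, haplotypes)


# ---------------------------------------------------------------------------
# dosage phenotype
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("geno, expected", [
    ("A/A", "M"), ("AG/A", "SubG"), ("AGG/A", "G"),
    ("AG/AG", "G"), ("AGG/AGG", "G"),
])
def test_dosage_phenotype_map(geno, expected):
    assert dosage_phenotype(G(geno)).value == expected


def test_table1_expected_sex_column_reproduced():
    """Every population's printed expected sex follows from the dosage model."""
    mu0 = UCOParams(0.0)
    for _, row in table1_populations().iterrows():
        g1, g2 = G(row["parent1"]), G(row["parent2"])
        phenos = cross(g1, g2, mu0).phenotypes()
        support = {ph.value for ph, q in phenos.items() if q > 0}
        expected = row["expected_sex"]
        if expected.startswith("Segregating"):
            ratios = dict(zip(("G", "SubG", "M"),
                              (phenos[SexPhenotype.G], phenos[SexPhenotype.SUBG],
                               phenos[SexPhenotype.M])))
            if "1G:2SubG:1M" in expected:
                assert ratios == {"G": 0.25, "SubG": 0.5, "M": 0.25}
            else:
                assert ratios == {"G": 0.75, "SubG": 0.0, "M": 0.25}
        else:
            assert support == {expected}


# ---------------------------------------------------------------------------
# gamete formation
# ---------------------------------------------------------------------------

def test_forced_uco_produces_deletion_and_duplication(rng):
    gy14 = G("AG/AG")
    p = UCOParams(1.0)
    products = {str(simulate_meiosis(gy14, p, rng, force_uco=(1, 2)).haplotype)
                for _ in range(50)}
    assert products == {"A", "AGG"}


def test_single_unit_homozygote_never_recombines(rng):
    mono = G("A/A")
    p = UCOParams(1.0)  # even at certain-UCO rate there is no register
    assert _uco_pairs(1, 1, p) == {}
    for _ in range(20):
        assert str(simulate_meiosis(mono, p, rng).haplotype) == "A"


def test_forced_offset_one_on_triple_homozygote():
    p = UCOParams(1.0)
    dist = enumerate_gametes(G("AGG/AGG"), p)
    sizes = sorted(h.n_units for h in dist)
    assert sizes == [2, 4]  # reciprocal 2- and 4-unit products only


@settings(deadline=None, max_examples=60, derandomize=True)
@given(g=genotypes)
def test_reciprocal_gametes_conserve_unit_counts(g):
    n1, n2 = g.hap1.n_units, g.hap2.n_units
    for i, j in _uco_pairs(n1, n2, UCOParams(1.0, max_offset=3,
                                             offset_weights=(1, 1, 1))):
        from flocuscnv.transmission import _recombinants
        r1, r2 = _recombinants(g, i, j)
        assert r1.n_units + r2.n_units == n1 + n2


@settings(deadline=None, max_examples=60, derandomize=True)
@given(g=genotypes, mu=st.floats(0.0, 1.0))
def test_gamete_distribution_sums_to_one(g, mu):
    dist = enumerate_gametes(g, UCOParams(mu))
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(q >= 0 for q in dist.values())


@pytest.mark.parametrize("geno, mu, expected", [
    ("AG/A", 0.0, {"AG": 0.5, "A": 0.5}),
    ("AG/AG", 0.0, {"AG": 1.0}),
    ("AG/AG", 0.001, {"AG": 0.999, "A": 0.0005, "AGG": 0.0005}),
])
def test_enumerate_gametes_examples(geno, mu, expected):
    dist = enumerate_gametes(G(geno), UCOParams(mu))
    got = {str(h): q for h, q in dist.items() if q > 0}
    assert got.keys() == expected.keys()
    for k, v in expected.items():
        assert got[k] == pytest.approx(v, abs=1e-15)


def test_simulated_meioses_match_enumeration_within_4_sigma(rng):
    g = G("AG/AG")
    p = UCOParams(0.01)
    n = 100_000
    counts: dict[str, int] = {}
    for _ in range(n):
        h = str(simulate_meiosis(g, p, rng).haplotype)
        counts[h] = counts.get(h, 0) + 1
    for h, q in enumerate_gametes(g, p).items():
        obs = counts.get(str(h), 0)
        sigma = np.sqrt(n * q * (1 - q))
        assert abs(obs - n * q) <= 4 * sigma


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

def test_selfing_heterozygote_segregates_1_2_1():
    het = G("AG/A")
    phenos = cross(het, het, UCOParams(0.0)).phenotypes()
    assert phenos[SexPhenotype.G] == 0.25
    assert phenos[SexPhenotype.SUBG] == 0.5
    assert phenos[SexPhenotype.M] == 0.25


def test_triple_repeat_f2_has_no_subgynoecious_class():
    """Two CsACS1G copies on one haplotype co-segregate: 3 G : 1 M, SubG = 0."""
    f1 = G("AGG/A")
    phenos = cross(f1, f1, UCOParams(0.0)).phenotypes()
    assert phenos[SexPhenotype.SUBG] == 0.0
    assert phenos[SexPhenotype.G] == 0.75
    assert phenos[SexPhenotype.M] == 0.25


def test_gynoecious_by_monecious_f1_all_subgynoecious():
    dist = cross(G("AG/AG"), G("A/A"), UCOParams(0.0))
    assert dist.phenotypes()[SexPhenotype.SUBG] == 1.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(g1=genotypes, g2=genotypes, mu=st.floats(0.0, 0.5))
def test_cross_is_symmetric_in_parents(g1, g2, mu):
    p = UCOParams(mu)
    assert cross(g1, g2, p) == cross(g2, g1, p)


# ---------------------------------------------------------------------------
# selfing populations and mutant confirmation
# ---------------------------------------------------------------------------

def test_selfed_homozygotes_are_uniform_without_uco(rng):
    p = UCOParams(0.0)
    for founder, pheno in (("AG/AG", "G"), ("A/A", "M")):
        pop = self_population(G(founder), 200, 2, p, rng)
        assert set(pop.table["phenotype"]) == {pheno}
        assert pop.counts()[f"n_{pheno}"] == 200


def test_screen_produces_heterozygotes_at_expected_order(rng):
    founder = build_line_structure("gynoecious_Gy14_like")
    mu = 2e-3
    pop = self_population(founder, 4000, 2, UCOParams(mu), rng)
    n_subg = pop.counts()["n_SubG"]
    expect = expected_screen(founder, mu, ScreenDesign())["p_SubG"] * 4000
    assert 0 < n_subg < 10 * expect  # Poisson-scale agreement, loose


def test_confirm_mutants_accepts_hets_rejects_transient_g(rng):
    p = UCOParams(0.0)
    pop = self_population(G("AG/A"), 30, 1, p, rng)
    tagged = pop.table["tagged"]
    assert tagged.sum() > 0  # SubG and M plants are always tagged
    out = confirm_mutants(pop, progeny_size=40, p=p, rng=rng)
    by_geno = out.groupby("genotype")["confirmed"].mean()
    assert by_geno.get("AG/AG", 0.0) == 0.0          # true G never confirms
    if "AG/A" in by_geno.index:
        assert by_geno["AG/A"] > 0.9                 # 1 - (3/4)^40
    assert out[out["genotype"] == "A/A"]["confirmed"].all()


def test_confirmed_stable_m_line_breeds_true(rng):
    p = UCOParams(0.0)
    pop = self_population(G("A/A"), 50, 6, p, rng)
    assert set(pop.table["phenotype"]) == {"M"}


def test_low_progeny_size_warns(rng):
    pop = self_population(G("AG/A"), 5, 1, UCOParams(0.0), rng)
    with pytest.warns(UserWarning, match="low power"):
        confirm_mutants(pop, progeny_size=4, p=UCOParams(0.0), rng=rng)


def test_evolve_selfing_matches_single_cross():
    g = G("AG/A")
    p = UCOParams(0.0)
    assert evolve_selfing(g, 1, p) == cross(g, g, p)


def test_expected_screen_scales_linearly_in_small_mu():
    founder = build_line_structure("gynoecious_Gy14_like")
    d = ScreenDesign()
    r1 = expected_screen(founder, 1e-4, d)["p_confirmed"]
    r2 = expected_screen(founder, 2e-4, d)["p_confirmed"]
    assert r2 / r1 == pytest.approx(2.0, rel=5e-3)
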