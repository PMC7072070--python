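"""Structural model: promoter arithmetic, locus assembly, in-silico PCR."""

import pytest
from hypothesis import given, settings, strategies as st

from flocuscnv import (
    Genotype,
    Haplotype,
    LocusParams,
    PrimerPair,
    assemble_locus_sequence,
    build_line_structure,
    build_recombinant_promoter,
    default_gene_models,
    insilico_pcr,
)
from flocuscnv.locus_model import (
    INTRON8_FULL,
    INTRON8_KEPT,
    JUNCTION_AMPLICON_LEN,
    RECOMBINANT_PROMOTER_LEN,
    predict_junction_products,
)

unit_strings = st.text(alphabet="AG", min_size=1, max_size=4)


# ---------------------------------------------------------------------------
# line structures and haplotype basics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("line, per_hap, total_g", [
    ("monecious_9930_like", "A", 0),
    ("gynoecious_Gy14_like", "AG", 2),
    ("triple_AM297_like", "AGG", 4),
])
def test_reference_line_structures(line, per_hap, total_g):
    g = build_line_structure(line)
    assert str(g.hap1) == str(g.hap2) == per_hap
    assert g.g_dosage == total_g


def test_unknown_line_names_valid_options():
    with pytest.raises(ValueError, match="monecious_9930_like"):
        build_line_structure("not_a_line")


def test_genotype_is_swap_invariant():
    a = Genotype(Haplotype.from_string("AG"), Haplotype.from_string("A"))
    b = Genotype(Haplotype.from_string("A"), Haplotype.from_string("AG"))
    assert a == b and hash(a) == hash(b)


def test_empty_haplotype_rejected():
    with pytest.raises(ValueError):
        Haplotype(())


# ---------------------------------------------------------------------------
# recombinant promoter arithmetic
# ---------------------------------------------------------------------------

def test_recombinant_promoter_default_components():
    block = build_recombinant_promoter(default_gene_models()["CsBCAT"])
    assert block.total_length == 1504
    assert dict(block.components) == {"intron8": 928, "exon9": 113,
                                      "intron9": 350, "exon10": 113}
    assert block.missing_intron8_tail == INTRON8_FULL - INTRON8_KEPT == 56


def test_recombinant_promoter_truncation_extremes():
    bcat = default_gene_models()["CsBCAT"]
    assert build_recombinant_promoter(bcat, 0).total_length == 576
    with pytest.raises(ValueError):
        build_recombinant_promoter(bcat, INTRON8_FULL + 1)


def test_promoter_sequence_matches_component_lengths(small_params):
    bcat = default_gene_models(small_params.gene_scale)["CsBCAT"]
    # any sequence of the right genomic length works for the slicing check
    seq = "ACGT" * (bcat.genomic_length // 4 + 1)
    block = build_recombinant_promoter(bcat, INTRON8_KEPT,
                                       bcat_sequence=seq[:bcat.genomic_length])
    assert len(block.sequence) == block.total_length == RECOMBINANT_PROMOTER_LEN


# ---------------------------------------------------------------------------
# locus assembly
# ---------------------------------------------------------------------------

def test_assembly_is_deterministic(small_params):
    a = assemble_locus_sequence("AG", small_params)
    b = assemble_locus_sequence("AG", small_params)
    assert a.sequence == b.sequence
    assert a.annotation.features == b.annotation.features


def test_gene_order_and_junctions(loci):
    assert loci["A"].annotation.gene_names() == ["CsACS1", "CsMYB", "CsBCAT"]
    assert loci["AG"].annotation.gene_names() == [
        "CsACS1", "CsMYB", "CsACS1G", "CsMYB", "CsBCAT"]
    for h, n in (("A", 0), ("AG", 1), ("AGG", 2)):
        assert len(loci[h].annotation.junctions) == n


@settings(deadline=None, max_examples=20, derandomize=True)
@given(units=unit_strings)
def test_junction_count_equals_g_units_and_length_additivity(units):
    params = LocusParams.small(seed=2)
    locus = assemble_locus_sequence(units, params)
    hp = Haplotype.from_string(units)
    assert len(locus.annotation.junctions) == hp.g_dosage
    a_len = params.unit_length - RECOMBINANT_PROMOTER_LEN
    unit_total = sum(params.unit_length if u == "G" else a_len for u in units)
    bcat_len = default_gene_models(params.gene_scale)["CsBCAT"].genomic_length
    assert len(locus.sequence) == (2 * params.flank_length + unit_total
                                   + bcat_len)


def test_g_unit_exceeds_a_unit_by_promoter_block(loci):
    units = {f.attributes["variant"]: f.length
             for f in loci["AG"].annotation.of_type("repeat_unit")}
    assert units["G"] - units["A"] == RECOMBINANT_PROMOTER_LEN == 1504


def test_promoter_offsets_match_tss_convention(loci):
    ann = loci["AG"].annotation
    prox = ann.of_type("promoter_proximal")[0]
    dist = ann.of_type("promoter_distal")[0]
    assert prox.attributes["tss_offset"] == (-410, -1)
    assert dist.attributes["tss_offset"] == (-1914, -411)
    assert dist.length == 1504 and prox.length == 410


def test_shared_cores_identical_and_snp_injection(small_params):
    plain = assemble_locus_sequence("AG", small_params)
    assert plain.components["core"] == plain.components["core_g"]
    snp = assemble_locus_sequence(
        "AG", LocusParams.small(seed=small_params.seed, inject_snps=True))
    diff = [i for i, (x, y) in enumerate(zip(snp.components["core"],
                                             snp.components["core_g"]))
            if x != y]
    assert diff == list(snp.params.snp_core_offsets)


def test_reverse_complement_roundtrip_preserves_feature_lengths(loci):
    ann = loci["AGG"].annotation
    flipped = ann.reverse_complement()
    assert sorted(f.length for f in flipped.features) == \
        sorted(f.length for f in ann.features)
    assert flipped.reverse_complement().features == ann.features


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def test_junction_pcr_products_by_architecture(loci):
    primers = loci["AG"].junction_primers()
    assert insilico_pcr(loci["A"], primers) == []
    one = insilico_pcr(loci["AG"], primers)
    assert [p.length for p in one] == [JUNCTION_AMPLICON_LEN]
    two = insilico_pcr(loci["AGG"], primers)
    assert [p.length for p in two] == [JUNCTION_AMPLICON_LEN] * 2


def test_pcr_agrees_with_annotation_prediction(loci):
    primers = loci["AG"].junction_primers()
    for h in ("A", "AG", "AGG"):
        seq_products = [p.length for p in insilico_pcr(loci[h], primers)]
        assert seq_products == predict_junction_products(loci[h].annotation)


def test_missing_primer_warns_and_returns_empty(loci, caplog):
    ghost = PrimerPair("ghost", "A" * 20, "C" * 20)
    with caplog.at_level("WARNING"):
        assert insilico_pcr(loci["AG"], ghost) == []
    assert "not found" in caplog.text


def test_short_primer_rejected():
    with pytest.raises(ValueError):
        PrimerPair("tiny", "ACGTACGTAC", "ACGTACGTACGTACGT")
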