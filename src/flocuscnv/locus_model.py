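"""Structural model of the cucumber *F* (femaleness) locus.

The *F* locus is a tandem-repeat copy-number variant: monecious plants carry a
single ~30-kb unit holding *CsACS1* and *CsMYB* (followed by the complete
*CsBCAT* gene), while gynoecious plants carry one or more extra units whose
*CsACS1* copy (*CsACS1G*) sits behind a recombinant distal promoter built from
*CsBCAT* material (truncated intron 8, exon 9, intron 9 and exon 10 — 1504 bp
in total, reaching −1914 relative to the transcription start; the proximal
promoter from −410 inward is identical between *CsACS1* and *CsACS1G*).

This module builds annotated synthetic haplotype sequences with that exact
architecture and runs in-silico PCR against them, which is enough to reproduce
the diagnostic junction amplicon (111 bp per *CsACS1G* unit, none in
monecious material because the two primer binding sites point apart).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Fixed length targets (bp) that hold at every locus scale.
PROXIMAL_PROMOTER_LEN = 410
DISTAL_PROMOTER_EXTENT = 1914
INTRON8_FULL = 984
INTRON8_KEPT = 928
EXON9_LEN = 113
INTRON9_LEN = 350
EXON10_LEN = 113
RECOMBINANT_PROMOTER_LEN = INTRON8_KEPT + EXON9_LEN + INTRON9_LEN + EXON10_LEN
JUNCTION_AMPLICON_LEN = 111
DEFAULT_UNIT_LENGTH = 30_200
DEFAULT_FLANK_LENGTH = 10_000

assert RECOMBINANT_PROMOTER_LEN == 1504
assert DISTAL_PROMOTER_EXTENT == RECOMBINANT_PROMOTER_LEN + PROXIMAL_PROMOTER_LEN


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatUnit:
    """One repeat unit of the tandem array.

    ``variant`` is ``"A"`` (native *CsACS1* + *CsMYB*) or ``"G"``
    (*CsACS1G*: the same core preceded by the 1504-bp recombinant distal
    promoter).  ``unit_length`` is the unit's total span in bp.
    """

    variant: str
    unit_length: int

    def __post_init__(self) -> None:
        if self.variant not in ("A", "G"):
            raise ValueError(f"variant must be 'A' or 'G', got {self.variant!r}")
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")


@dataclass(frozen=True)
class Haplotype:
    """Ordered (5'→3') repeat-unit composition of one chromosome's allele.

    ``units`` holds variant letters, e.g. ``("A", "G")`` for the classic
    gynoecious arrangement.  The complete downstream *CsBCAT* gene
    (``trailing_bcat``) is always present; its exons 1–8 lie outside the CNV.
    """

    units: tuple[str, ...]
    trailing_bcat: bool = True

    def __post_init__(self) -> None:
        if len(self.units) < 1:
            raise ValueError("a haplotype needs at least one repeat unit")
        bad = set(self.units) - {"A", "G"}
        if bad:
            raise ValueError(f"unknown unit variants: {sorted(bad)}")
        if not self.trailing_bcat:
            raise ValueError("trailing_bcat must be true: BCAT exons 1-8 flank the CNV")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def g_dosage(self) -> int:
        """Functional dosage = number of CsACS1G-bearing units."""
        return sum(1 for u in self.units if u == "G")

    def __str__(self) -> str:
        return "".join(self.units)

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        return cls(tuple(s.strip().upper()))


def hap(units: str | Iterable[str]) -> Haplotype:
    """Shorthand: ``hap("AG")`` or ``hap(["A", "G"])``."""
    if isinstance(units, str):
        return Haplotype.from_string(units)
    return Haplotype(tuple(units))


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid pair of haplotypes (hap1/hap2 swap-invariant)."""

    hap1: Haplotype
    hap2: Haplotype

    def canonical(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return tuple(sorted((self.hap1.units, self.hap2.units)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    @property
    def g_dosage(self) -> int:
        return self.hap1.g_dosage + self.hap2.g_dosage

    @property
    def total_units(self) -> int:
        return self.hap1.n_units + self.hap2.n_units

    def __str__(self) -> str:
        return f"{self.hap1}/{self.hap2}"

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        h1, h2 = s.split("/")
        return cls(Haplotype.from_string(h1), Haplotype.from_string(h2))


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron architecture of one gene."""

    name: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly len(exons) - 1 introns")
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError("all exon/intron lengths must be positive")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def genomic_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def intron_offset(self, i: int) -> int:
        """0-based offset of intron ``i`` (1-based numbering) within the gene."""
        if not 1 <= i <= len(self.intron_lengths):
            raise ValueError(f"gene {self.name} has no intron {i}")
        return sum(self.exon_lengths[:i]) + sum(self.intron_lengths[: i - 1])

    def exon_offset(self, i: int) -> int:
        """0-based offset of exon ``i`` (1-based numbering) within the gene."""
        if not 1 <= i <= len(self.exon_lengths):
            raise ValueError(f"gene {self.name} has no exon {i}")
        return sum(self.exon_lengths[: i - 1]) + sum(self.intron_lengths[: i - 1])


@dataclass(frozen=True)
class Feature:
    feature_id: str
    type: str  # gene | promoter_proximal | promoter_distal | junction | repeat_unit | flank
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.feature_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


FEATURE_TYPES = {"gene", "promoter_proximal", "promoter_distal", "junction",
                 "repeat_unit", "flank"}


@dataclass
class LocusAnnotation:
    """Feature set over one assembled haplotype sequence (0-based half-open)."""

    seq_id: str
    seq_length: int
    features: list[Feature]

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    @property
    def junctions(self) -> list[Feature]:
        return self.of_type("junction")

    def gene_names(self) -> list[str]:
        return [f.attributes.get("name", f.feature_id) for f in self.of_type("gene")]

    def reverse_complement(self) -> "LocusAnnotation":
        """Re-express all features on the reverse-complemented sequence."""
        flipped = [
            replace(
                f,
                start=self.seq_length - f.end,
                end=self.seq_length - f.start,
                strand="-" if f.strand == "+" else "+",
            )
            for f in self.features
        ]
        flipped.sort(key=lambda f: (f.start, f.end))
        return LocusAnnotation(self.seq_id, self.seq_length, flipped)


@dataclass(frozen=True)
class PrimerPair:
    """A left (forward) and right (reverse) primer, both given 5'→3'."""

    name: str
    left_seq: str
    right_seq: str
    max_product: int = 1000

    def __post_init__(self) -> None:
        for s in (self.left_seq, self.right_seq):
            if len(s) < 15:
                raise ValueError("sequence-based primers must be >= 15 nt")
            if set(s.upper()) - set("ACGT"):
                raise ValueError("primers must be plain ACGT")


@dataclass(frozen=True)
class PcrProduct:
    length: int
    start: int  # 0-based on the template
    end: int


# ---------------------------------------------------------------------------
# parameters and default gene architecture
# ---------------------------------------------------------------------------

def default_gene_models(gene_scale: float = 1.0) -> dict[str, GeneModel]:
    """Gene architectures used by the synthetic locus.

    *CsBCAT*'s intron 8 (984 bp), exon 9 (113 bp), intron 9 (350 bp) and exon
    10 (113 bp) are held fixed at every scale because the recombinant-promoter
    arithmetic depends on them; everything else shrinks with ``gene_scale``.
    """

    def sc(x: int) -> int:
        return max(20, round(x * gene_scale))

    acs1 = GeneModel("CsACS1", (sc(200), sc(180), sc(220), sc(300)),
                     (sc(150), sc(200), sc(180)))
    myb = GeneModel("CsMYB", (sc(250), sc(300)), (sc(180),))
    bcat = GeneModel(
        "CsBCAT",
        tuple(sc(150) for _ in range(8)) + (EXON9_LEN, EXON10_LEN),
        tuple(sc(120) for _ in range(7)) + (INTRON8_FULL, INTRON9_LEN),
    )
    return {"CsACS1": acs1, "CsMYB": myb, "CsBCAT": bcat}


@dataclass(frozen=True)
class LocusParams:
    """Geometry + randomness controls for synthetic locus assembly.

    ``unit_length`` is the length of a full G unit (recombinant promoter
    included); an A unit is exactly 1504 bp shorter.  Background sequence is
    seeded-random at cucumber-like GC (0.35); the homologous cores of all
    units are byte-identical unless ``inject_snps`` plants the two reported
    core SNPs into G units.
    """

    seed: int
    unit_length: int = DEFAULT_UNIT_LENGTH
    flank_length: int = DEFAULT_FLANK_LENGTH
    gc: float = 0.35
    gene_scale: float = 1.0
    spacer1: int = 2000
    inject_snps: bool = False
    snp_core_offsets: tuple[int, int] = (500, 900)
    primer_length: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        core = self.core_length
        genes = default_gene_models(self.gene_scale)
        needed = (PROXIMAL_PROMOTER_LEN + genes["CsACS1"].genomic_length
                  + self.spacer1 + genes["CsMYB"].genomic_length + 50)
        if core < needed:
            raise ValueError(
                f"unit_length {self.unit_length} too small: shared core is "
                f"{core} bp but gene layout needs >= {needed} bp"
            )

    @property
    def core_length(self) -> int:
        return self.unit_length - RECOMBINANT_PROMOTER_LEN

    @classmethod
    def small(cls, seed: int, **overrides) -> "LocusParams":
        """A ~4-kb-unit locus for fast tests; length targets stay fixed."""
        kw = dict(seed=seed, unit_length=4000, flank_length=800,
                  gene_scale=0.25, spacer1=150)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_json(cls, path) -> "LocusParams":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        d = {
            "seed": self.seed, "unit_length": self.unit_length,
            "flank_length": self.flank_length, "gc": self.gc,
            "gene_scale": self.gene_scale, "spacer1": self.spacer1,
            "inject_snps": self.inject_snps,
            "snp_core_offsets": list(self.snp_core_offsets),
            "primer_length": self.primer_length,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

KNOWN_LINES = {
    "monecious_9930_like": "A",
    "gynoecious_Gy14_like": "AG",
    "triple_AM297_like": "AGG",
}


def build_line_structure(line: str | Sequence[Sequence[str]],
                         unit_length: int = DEFAULT_UNIT_LENGTH) -> Genotype:
    """Genotype of a named reference line, or of explicit per-haplotype units.

    The three named lines are homozygous: the monecious reference carries
    [A]/[A], the classic gynoecious line [A,G]/[A,G], and the triple-repeat
    gynoecious line [A,G,G]/[A,G,G].
    """
    if isinstance(line, str):
        if line not in KNOWN_LINES:
            raise ValueError(
                f"unknown line {line!r}; valid options: {sorted(KNOWN_LINES)}"
            )
        h = Haplotype.from_string(KNOWN_LINES[line])
        return Genotype(h, h)
    units1, units2 = line
    return Genotype(hap(units1), hap(units2))


@dataclass(frozen=True)
class PromoterBlock:
    """The recombinant distal promoter and its per-component bookkeeping."""

    components: tuple[tuple[str, int], ...]  # (name, length) 5'→3'
    missing_intron8_tail: int
    sequence: str | None = None

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.components)


def build_recombinant_promoter(bcat: GeneModel,
                               truncate_intron8_to: int = INTRON8_KEPT,
                               bcat_sequence: str | None = None) -> PromoterBlock:
    """Compose the CsACS1G distal promoter from *CsBCAT* parts.

    The block is intron 8 truncated to ``truncate_intron8_to`` bp, then exon 9,
    intron 9 and exon 10; at the defaults this totals 1504 bp and the missing
    intron-8 tail is 56 bp.  If ``bcat_sequence`` (the gene's genomic sequence)
    is supplied the concatenated block sequence is returned too.
    """
    if len(bcat.exon_lengths) < 10:
        raise ValueError("BCAT model must have >= 10 exons")
    full_i8 = bcat.intron_lengths[7]
    if truncate_intron8_to > full_i8:
        raise ValueError(
            f"cannot keep {truncate_intron8_to} bp of a {full_i8}-bp intron"
        )
    if truncate_intron8_to < 0:
        raise ValueError("truncated length must be >= 0")
    comps = []
    if truncate_intron8_to > 0:
        comps.append(("intron8", truncate_intron8_to))
    comps += [("exon9", bcat.exon_lengths[8]),
              ("intron9", bcat.intron_lengths[8]),
              ("exon10", bcat.exon_lengths[9])]
    seq = None
    if bcat_sequence is not None:
        if len(bcat_sequence) != bcat.genomic_length:
            raise ValueError("bcat_sequence length does not match the model")
        i8 = bcat.intron_offset(8)
        e9 = bcat.exon_offset(9)
        e10 = bcat.exon_offset(10)
        seq = (bcat_sequence[i8:i8 + truncate_intron8_to]
               + bcat_sequence[e9:e10 + bcat.exon_lengths[9]])
    return PromoterBlock(tuple(comps), full_i8 - truncate_intron8_to, seq)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=n, p=probs))


@dataclass
class SyntheticLocus:
    """An assembled haplotype sequence plus annotation and raw components."""

    sequence: str
    annotation: LocusAnnotation
    params: LocusParams
    haplotype: Haplotype
    components: dict[str, str]  # core / bcat / block / flank5 / flank3

    def junction_primers(self, name: str = "F-gDNA") -> PrimerPair:
        """The junction-spanning diagnostic pair.

        The left primer is the last ``primer_length`` bp of the recombinant
        promoter (the exon-10 end); the right primer reverse-primes within the
        shared sequence just inside the −410 proximal boundary, so the product
        spans the junction and is exactly 111 bp on G units.  Both binding
        sites exist in monecious material too (in the complete *CsBCAT* gene
        and upstream of *CsACS1* respectively) but point away from each other,
        so no product forms there.
        """
        k = self.params.primer_length
        block = self.components["block"]
        core = self.components["core"]
        inner = JUNCTION_AMPLICON_LEN - 2 * k  # core bases between the primers
        left = block[-k:]
        right = str(Seq(core[inner:inner + k]).reverse_complement())
        return PrimerPair(name, left, right, max_product=500)


def assemble_locus_sequence(haplotype: Haplotype | str,
                            params: LocusParams) -> SyntheticLocus:
    """Deterministically assemble one haplotype's sequence and annotation.

    Layout (5'→3'): 5' flank, then each repeat unit (G units open with the
    1504-bp recombinant distal promoter; every unit continues with the shared
    core: −410 proximal promoter, CsACS1[G] gene body, spacer, CsMYB, spacer),
    then the complete *CsBCAT* gene, then the 3' flank.  All random draws come
    from one generator seeded with ``params.seed``, in the fixed order
    flank5, core, CsBCAT, flank3, so the same seed reproduces identical bytes
    and different haplotypes at the same seed share component sequences.
    """
    if isinstance(haplotype, str):
        haplotype = Haplotype.from_string(haplotype)
    p = params
    genes = default_gene_models(p.gene_scale)
    acs1, myb, bcat = genes["CsACS1"], genes["CsMYB"], genes["CsBCAT"]

    rng = np.random.default_rng(p.seed)
    flank5 = _random_dna(rng, p.flank_length, p.gc)
    core = _random_dna(rng, p.core_length, p.gc)
    bcat_seq = _random_dna(rng, bcat.genomic_length, p.gc)
    flank3 = _random_dna(rng, p.flank_length, p.gc)

    block = build_recombinant_promoter(bcat, INTRON8_KEPT, bcat_seq).sequence
    assert block is not None and len(block) == RECOMBINANT_PROMOTER_LEN

    core_g = core
    if p.inject_snps:
        chars = list(core)
        for off in p.snp_core_offsets:
            chars[off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[off]]
        core_g = "".join(chars)

    parts: list[str] = [flank5]
    feats: list[Feature] = []
    pos = len(flank5)
    feats.append(Feature("flank5", "flank", 0, pos))

    n_g_seen = 0
    for k, variant in enumerate(haplotype.units, start=1):
        unit_start = pos
        unit_core = core_g if variant == "G" else core
        if variant == "G":
            n_g_seen += 1
            parts.append(block)
            feats.append(Feature(
                f"distal_promoter_u{k}", "promoter_distal",
                pos, pos + RECOMBINANT_PROMOTER_LEN,
                attributes={"tss_offset": (-DISTAL_PROMOTER_EXTENT,
                                           -(PROXIMAL_PROMOTER_LEN + 1))},
            ))
            pos += RECOMBINANT_PROMOTER_LEN
            feats.append(Feature(
                f"junction_{n_g_seen}", "junction", pos - 1, pos + 1,
                attributes={"note": "recombinant promoter / proximal boundary"},
            ))
        parts.append(unit_core)
        feats.append(Feature(
            f"proximal_promoter_u{k}", "promoter_proximal",
            pos, pos + PROXIMAL_PROMOTER_LEN,
            attributes={"tss_offset": (-PROXIMAL_PROMOTER_LEN, -1)},
        ))
        gene_start = pos + PROXIMAL_PROMOTER_LEN
        gene_name = "CsACS1G" if variant == "G" else "CsACS1"
        feats.append(Feature(
            f"{gene_name}_u{k}", "gene", gene_start,
            gene_start + acs1.genomic_length, attributes={"name": gene_name},
        ))
        myb_start = gene_start + acs1.genomic_length + p.spacer1
        feats.append(Feature(
            f"CsMYB_u{k}", "gene", myb_start, myb_start + myb.genomic_length,
            attributes={"name": "CsMYB"},
        ))
        pos += len(unit_core)
        feats.append(Feature(
            f"unit_{k}", "repeat_unit", unit_start, pos,
            attributes={"variant": variant},
        ))
        assert pos - unit_start == (p.unit_length if variant == "G"
                                    else p.unit_length - RECOMBINANT_PROMOTER_LEN)

    parts.append(bcat_seq)
    feats.append(Feature("CsBCAT", "gene", pos, pos + bcat.genomic_length,
                         attributes={"name": "CsBCAT"}))
    pos += bcat.genomic_length
    parts.append(flank3)
    feats.append(Feature("flank3", "flank", pos, pos + len(flank3)))
    pos += len(flank3)

    seq = "".join(parts)
    assert len(seq) == pos
    ann = LocusAnnotation(f"Flocus_{haplotype}", len(seq),
                          sorted(feats, key=lambda f: (f.start, f.end)))
    comps = {"flank5": flank5, "core": core, "core_g": core_g,
             "bcat": bcat_seq, "block": block, "flank3": flank3}
    return SyntheticLocus(seq, ann, p, haplotype, comps)


def _find_all(template: str, query: str) -> list[int]:
    hits, i = [], template.find(query)
    while i != -1:
        hits.append(i)
        i = template.find(query, i + 1)
    return hits


def insilico_pcr(template: str | SyntheticLocus, primers: PrimerPair) -> list[PcrProduct]:
    """Exact-match in-silico PCR.

    A product forms wherever a primer annealing in forward orientation lies
    upstream of (and faces) a primer annealing in reverse orientation, within
    ``primers.max_product``.  A primer found nowhere on either strand raises a
    'not found' warning in the log, distinct from a plain orientation failure.
    """
    if isinstance(template, SyntheticLocus):
        template = template.sequence
    template = template.upper()

    plus_hits: list[tuple[int, int]] = []   # (start, primer_len)
    minus_hits: list[tuple[int, int]] = []  # (end, primer_len)
    for label, seq in (("left", primers.left_seq), ("right", primers.right_seq)):
        seq = seq.upper()
        rc = str(Seq(seq).reverse_complement())
        fwd = _find_all(template, seq)
        rev = _find_all(template, rc)
        plus_hits += [(s, len(seq)) for s in fwd]
        minus_hits += [(s + len(seq), len(seq)) for s in rev]
        if not fwd and not rev:
            logger.warning("primer %s (%s) not found in template", primers.name, label)

    products = []
    for s, l1 in plus_hits:
        for e, l2 in minus_hits:
            if e - s >= max(l1, l2) and e - s <= primers.max_product:
                products.append(PcrProduct(e - s, s, e))
    products = sorted(set(products), key=lambda pr: (pr.start, pr.end))
    if not products and (plus_hits or minus_hits):
        logger.info("primer pair %s: sites found but no facing pair within "
                    "%d bp (orientation/distance failure)",
                    primers.name, primers.max_product)
    return products


def predict_junction_products(annotation: LocusAnnotation) -> list[int]:
    """Annotation-level junction-PCR prediction: one 111-bp product per G unit."""
    return [JUNCTION_AMPLICON_LEN for _ in annotation.junctions]
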