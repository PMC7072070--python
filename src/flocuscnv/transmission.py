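"""Meiotic transmission of the F-locus tandem repeat, with unequal crossing over.

The model: each meiosis offers at most one crossover opportunity between the
two homologous repeat arrays.  With probability ``1 - uco_rate`` (or whenever
no misaligned register exists, e.g. in single-unit homozygotes) the gamete is
simply one parental haplotype drawn uniformly — equal crossovers and
no-crossover meioses are indistinguishable at the level of unit composition.
With probability ``uco_rate`` the arrays pair out of register: crossover
positions i (after unit i of hap1) and j (after unit j of hap2) with i ≠ j and
|i - j| within the allowed offset produce the reciprocal gametes
hap1[:i] + hap2[j:] and hap2[:j] + hap1[i:], one of which is transmitted with
probability 1/2.  Unit identity (A vs G) travels with its 5' promoter.

Applied to the classic gynoecious genotype [A,G]/[A,G] this yields the
deletion gamete [A] and the duplication gamete [A,G,G] — the proposed origin
of 'gynoecy loss' monecious mutants and of triple-repeat gynoecious lines.

Sex phenotype is a deterministic function of diploid CsACS1G dosage:
0 → monecious (M), 1 → subgynoecious (SubG), ≥2 → gynoecious (G).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .locus_model import Genotype, Haplotype

__all__ = [
    "SexPhenotype", "UCOParams", "Gamete", "GameteDistribution",
    "GenotypeDistribution", "PopulationTable", "ScreenDesign",
    "dosage_phenotype", "simulate_meiosis", "enumerate_gametes", "cross",
    "self_population", "confirm_mutants", "evolve_selfing", "expected_screen",
]


class SexPhenotype(str, Enum):
    M = "M"          # monecious
    SUBG = "SubG"    # subgynoecious
    G = "G"          # gynoecious

    def __str__(self) -> str:
        return self.value


def dosage_phenotype(g: Genotype) -> SexPhenotype:
    """Map diploid CsACS1G dosage to sex phenotype (0→M, 1→SubG, ≥2→G)."""
    d = g.g_dosage
    if d == 0:
        return SexPhenotype.M
    if d == 1:
        return SexPhenotype.SUBG
    return SexPhenotype.G


@dataclass(frozen=True)
class UCOParams:
    """Unequal-crossing-over parameters.

    ``uco_rate`` (μ) is the per-meiosis probability of a misaligned crossover,
    given that a misalignable register exists.  ``offset_weights`` distributes
    the misalignment distance |i - j|; the default allows single-register
    slippage only.  μ itself is a free parameter of the model (the field
    observes realized mutant frequencies, not μ); the default reflects the
    ~0.12% gynoecy-loss rate under a single-meiosis reading of the screen.
    """

    uco_rate: float = 1.25e-3
    max_offset: int = 1
    offset_weights: tuple[float, ...] = (1.0,)  # weight for offsets 1..max_offset

    def __post_init__(self) -> None:
        if not 0.0 <= self.uco_rate <= 1.0:
            raise ValueError("uco_rate must be in [0, 1]")
        if self.max_offset < 1:
            raise ValueError("max_offset must be >= 1")
        if len(self.offset_weights) != self.max_offset:
            raise ValueError("need one weight per offset 1..max_offset")
        if any(w < 0 for w in self.offset_weights) or sum(self.offset_weights) <= 0:
            raise ValueError("offset weights must be non-negative and not all zero")


class GameteOrigin(str, Enum):
    EQUAL = "equal"
    UCO_DELETION = "uco_deletion"
    UCO_DUPLICATION = "uco_duplication"


@dataclass(frozen=True)
class Gamete:
    haplotype: Haplotype
    origin: GameteOrigin


def _uco_pairs(n1: int, n2: int, p: UCOParams) -> dict[tuple[int, int], float]:
    """Misaligned crossover registers (i, j) and their probabilities.

    i ∈ 1..n1, j ∈ 1..n2, i ≠ j, |i - j| ≤ max_offset; weights follow
    ``offset_weights`` renormalised over the offsets actually available, and
    are uniform among pairs sharing an offset.  Empty for n1 = n2 = 1.
    """
    by_offset: dict[int, list[tuple[int, int]]] = {}
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            d = abs(i - j)
            if i != j and d <= p.max_offset:
                by_offset.setdefault(d, []).append((i, j))
    total_w = sum(p.offset_weights[d - 1] for d in by_offset)
    if total_w <= 0:
        return {}
    out: dict[tuple[int, int], float] = {}
    for d, pairs in by_offset.items():
        w = p.offset_weights[d - 1] / total_w
        for pair in pairs:
            out[pair] = w / len(pairs)
    return out


def _recombinants(g: Genotype, i: int, j: int) -> tuple[Haplotype, Haplotype]:
    h1, h2 = g.hap1.units, g.hap2.units
    return (Haplotype(h1[:i] + h2[j:]), Haplotype(h2[:j] + h1[i:]))


def simulate_meiosis(g: Genotype, p: UCOParams,
                     rng: np.random.Generator,
                     force_uco: tuple[int, int] | None = None) -> Gamete:
    """Draw one gamete.

    Draw order: (1) one uniform for the UCO-vs-equal decision (skipped when no
    misaligned register exists or when ``force_uco`` supplies the register);
    (2) on the UCO branch, one draw for the register (i, j); (3) one uniform
    choosing which reciprocal product (or which parental haplotype) is
    transmitted.
    """
    pairs = _uco_pairs(g.hap1.n_units, g.hap2.n_units, p)
    if force_uco is not None:
        if force_uco not in pairs:
            raise ValueError(f"register {force_uco} is not a valid misalignment")
        i, j = force_uco
    elif pairs and rng.random() < p.uco_rate:
        keys = list(pairs)
        i, j = keys[rng.choice(len(keys), p=np.array([pairs[k] for k in keys]))]
    else:
        h = g.hap1 if rng.random() < 0.5 else g.hap2
        return Gamete(h, GameteOrigin.EQUAL)

    rec1, rec2 = _recombinants(g, i, j)
    chosen = rec1 if rng.random() < 0.5 else rec2
    parental_min = min(g.hap1.n_units, g.hap2.n_units)
    origin = (GameteOrigin.UCO_DELETION if chosen.n_units <= parental_min
              else GameteOrigin.UCO_DUPLICATION)
    return Gamete(chosen, origin)


class GameteDistribution(dict):
    """Haplotype → exact probability; a plain dict with a sampler."""

    def sample(self, rng: np.random.Generator, n: int = 1) -> list[Haplotype]:
        haps = list(self)
        idx = rng.choice(len(haps), size=n, p=np.array([self[h] for h in haps]))
        return [haps[k] for k in idx]

    def truncated(self, max_units: int) -> "GameteDistribution":
        """Drop haplotypes above ``max_units`` and renormalise."""
        kept = {h: q for h, q in self.items() if h.n_units <= max_units}
        z = sum(kept.values())
        return GameteDistribution({h: q / z for h, q in kept.items()})


def enumerate_gametes(g: Genotype, p: UCOParams) -> GameteDistribution:
    """Exact gamete distribution implied by the meiosis model."""
    dist: dict[Haplotype, float] = {}

    def add(h: Haplotype, q: float) -> None:
        if q > 0:
            dist[h] = dist.get(h, 0.0) + q

    pairs = _uco_pairs(g.hap1.n_units, g.hap2.n_units, p)
    mu = p.uco_rate if pairs else 0.0
    add(g.hap1, (1 - mu) / 2)
    add(g.hap2, (1 - mu) / 2)
    for (i, j), w in pairs.items():
        rec1, rec2 = _recombinants(g, i, j)
        add(rec1, mu * w / 2)
        add(rec2, mu * w / 2)
    return GameteDistribution(dist)


class GenotypeDistribution(dict):
    """Genotype → exact probability, with phenotype push-forward and sampler."""

    def phenotypes(self) -> dict[SexPhenotype, float]:
        out = {ph: 0.0 for ph in SexPhenotype}
        for g, q in self.items():
            out[dosage_phenotype(g)] += q
        return out

    def sample(self, rng: np.random.Generator, n: int = 1) -> list[Genotype]:
        gs = list(self)
        idx = rng.choice(len(gs), size=n, p=np.array([self[g] for g in gs]))
        return [gs[k] for k in idx]

    def sample_counts(self, rng: np.random.Generator, n: int) -> dict[Genotype, int]:
        gs = list(self)
        counts = rng.multinomial(n, np.array([self[g] for g in gs]))
        return {g: int(c) for g, c in zip(gs, counts) if c}


def cross(parent1: Genotype, parent2: Genotype, p: UCOParams,
          max_units: int | None = None) -> GenotypeDistribution:
    """Exact offspring genotype distribution of a cross (selfing: parent1 == parent2).

    The distribution is the product of the two parental gamete distributions
    and is symmetric in the parents.  ``max_units`` optionally truncates each
    gamete distribution (renormalised) to keep multi-generation compositions
    finite; the discarded mass is O(μ²) per generation at small μ.
    """
    d1 = enumerate_gametes(parent1, p)
    d2 = enumerate_gametes(parent2, p)
    if max_units is not None:
        d1 = d1.truncated(max_units)
        d2 = d2.truncated(max_units)
    terms: dict[Genotype, list[float]] = {}
    for (h1, q1), (h2, q2) in itertools.product(d1.items(), d2.items()):
        terms.setdefault(Genotype(h1, h2), []).append(q1 * q2)
    # summing contributions in sorted order makes the parent swap exact
    return GenotypeDistribution(
        {g: math.fsum(sorted(qs)) for g, qs in terms.items()})


@dataclass
class PopulationTable:
    """Final-generation plants of a selfing/cross experiment, with truth."""

    table: pd.DataFrame  # plant_id, genotype, phenotype, tagged, generation
    founder: Genotype
    params: UCOParams
    genotypes: list[Genotype] = field(repr=False, default_factory=list)

    @property
    def n(self) -> int:
        return len(self.table)

    def counts(self) -> dict[str, int]:
        c = self.table["phenotype"].value_counts()
        out = {"n_G": int(c.get("G", 0)), "n_SubG": int(c.get("SubG", 0)),
               "n_M": int(c.get("M", 0))}
        assert sum(out.values()) == self.n
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def self_population(founder: Genotype, n_plants: int, generations: int,
                    p: UCOParams, rng: np.random.Generator,
                    p_transient: float = 0.0,
                    intermediate_size: int | None = None,
                    max_units: int = 8) -> PopulationTable:
    """Self a founder for ``generations`` rounds and phenotype the final plants.

    Each generation, every offspring takes a uniformly chosen parent from the
    previous generation and is formed by selfing it (two gametes from the same
    plant).  Intermediate generations have ``intermediate_size`` plants
    (default: ``n_plants``); the final one has ``n_plants``.  True-G plants
    are spuriously tagged (transient male flowers) at rate ``p_transient``;
    SubG and M plants are always tagged.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    inter = n_plants if intermediate_size is None else intermediate_size
    pop: dict[Genotype, int] = {founder: 1}
    for gen in range(1, generations + 1):
        size = n_plants if gen == generations else inter
        total = sum(pop.values())
        parent_counts = rng.multinomial(
            size, np.array([c / total for c in pop.values()]))
        nxt: dict[Genotype, int] = {}
        for parent, n_off in zip(list(pop), parent_counts):
            if not n_off:
                continue
            dist = cross(parent, parent, p, max_units=max_units)
            for g, c in dist.sample_counts(rng, int(n_off)).items():
                nxt[g] = nxt.get(g, 0) + c
        pop = nxt

    genotypes: list[Genotype] = []
    for g, c in pop.items():
        genotypes.extend([g] * c)
    perm = rng.permutation(len(genotypes))
    genotypes = [genotypes[k] for k in perm]

    rows = []
    for k, g in enumerate(genotypes, start=1):
        ph = dosage_phenotype(g)
        tagged = ph != SexPhenotype.G or bool(rng.random() < p_transient)
        rows.append((f"S{generations}-{k:05d}", str(g), ph.value, tagged,
                     generations))
    df = pd.DataFrame(rows, columns=["plant_id", "genotype", "phenotype",
                                     "tagged", "generation"])
    return PopulationTable(df, founder, p, genotypes)


def confirm_mutants(pop: PopulationTable, progeny_size: int, p: UCOParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Progeny-test every tagged plant by selfing.

    A tagged plant is confirmed as a gynoecy-loss product when monecious
    plants appear among its selfed progeny: true heterozygotes confirm with
    probability 1 - (3/4)^progeny_size, already-monecious plants trivially so,
    and spuriously tagged true-G plants are rejected.  Returns one row per
    tagged plant with the confirmation outcome and the derived stable-M line
    flag (confirmed plants whose M progeny breed true).
    """
    import warnings

    if progeny_size < 8:
        warnings.warn("progeny_size < 8 gives low power to observe segregation",
                      stacklevel=2)
    tagged_idx = pop.table.index[pop.table["tagged"]]
    rows = []
    for idx in tagged_idx:
        g = pop.genotypes[idx]
        dist = cross(g, g, p).phenotypes()
        counts = rng.multinomial(progeny_size,
                                 np.array([dist[ph] for ph in SexPhenotype]))
        n_m = int(counts[list(SexPhenotype).index(SexPhenotype.M)])
        confirmed = n_m > 0
        rows.append({
            "plant_id": pop.table.loc[idx, "plant_id"],
            "genotype": str(g),
            "phenotype": pop.table.loc[idx, "phenotype"],
            "progeny_size": progeny_size,
            "progeny_M": n_m,
            "confirmed": confirmed,
            "stable_M_line": confirmed and g.g_dosage <= 1,
        })
    return pd.DataFrame(rows, columns=["plant_id", "genotype", "phenotype",
                                       "progeny_size", "progeny_M",
                                       "confirmed", "stable_M_line"])


# ---------------------------------------------------------------------------
# exact multi-generation composition (oracle for the simulator)
# ---------------------------------------------------------------------------

def evolve_selfing(founder: Genotype, generations: int, p: UCOParams,
                   max_units: int = 6) -> GenotypeDistribution:
    """Exact genotype distribution after repeated selfing of a founder line.

    Composes ``cross(g, g)`` over generations on the full distribution (every
    plant selfed, expectation over the pedigree), truncating haplotypes above
    ``max_units`` units to keep the state space finite.
    """
    dist = GenotypeDistribution({founder: 1.0})
    for _ in range(generations):
        nxt: dict[Genotype, float] = {}
        for g, q in dist.items():
            for g2, q2 in cross(g, g, p, max_units=max_units).items():
                nxt[g2] = nxt.get(g2, 0.0) + q * q2
        dist = GenotypeDistribution(nxt)
    return dist


@dataclass(frozen=True)
class ScreenDesign:
    """Design of a gynoecy-loss field screen.

    ``generations`` counts the selfing rounds between the single founder plant
    and the phenotyped population (the screens here used two).  Setting
    ``observed_generation_only`` attributes mutants solely to the final
    meiosis, the alternative reading of the screen.  Confirmation is by
    selfing ``progeny_size`` offspring of each tagged plant;
    ``count_stable_m`` includes already-monecious plants among confirmed
    mutants.
    """

    generations: int = 2
    progeny_size: int = 20
    count_stable_m: bool = True
    observed_generation_only: bool = False


def expected_screen(founder: Genotype, mu: float, design: ScreenDesign,
                    base: UCOParams | None = None) -> dict[str, float]:
    """Exact expected phenotype and confirmed-mutant frequencies of a screen."""
    base = base or UCOParams()
    p = UCOParams(mu, base.max_offset, base.offset_weights)
    gens = 1 if design.observed_generation_only else design.generations
    dist = evolve_selfing(founder, gens, p)
    phenos = dist.phenotypes()
    confirmed = 0.0
    for g, q in dist.items():
        ph = dosage_phenotype(g)
        if ph == SexPhenotype.SUBG:
            p_m = cross(g, g, p).phenotypes()[SexPhenotype.M]
            confirmed += q * (1.0 - (1.0 - p_m) ** design.progeny_size)
        elif ph == SexPhenotype.M and design.count_stable_m:
            confirmed += q
    return {
        "p_G": phenos[SexPhenotype.G],
        "p_SubG": phenos[SexPhenotype.SUBG],
        "p_M": phenos[SexPhenotype.M],
        "p_confirmed": confirmed,
    }
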