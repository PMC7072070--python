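"""Scenario generator: every input the pipeline needs, with known truth.

The generator emulates the study's data-generating conditions — field screens
of selfed gynoecious inbreds (thousands of plants, two prior selfing
generations, transient-male-flower tagging noise), segregation tables of
crosses among zero/one/two-CsACS1G-unit lines, 15–30× windowed read-depth
profiles over a 50-kb single-unit reference, seven-replicate genomic-qPCR Ct
tables, and actin2-normalised expression panels — and records every latent
quantity (genotypes, template copies, μ, fold changes) in a truth object so
each pipeline stage can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .locus_model import (Genotype, LocusParams, assemble_locus_sequence,
                          build_line_structure, hap)
from .transmission import UCOParams, self_population
from .copy_number import (GENOMIC_AMPLICONS, ReferenceGeometry, simulate_depth,
                          simulate_qpcr, template_copies)

SCENARIOS = ("gy14_screen", "g06_screen", "table1_crosses", "fig1_depth",
             "fig3_qpcr_panel", "fig5_expression")

# tagging noise default: tagged-minus-confirmed over screen size (63/2236)
DEFAULT_P_TRANSIENT = 63 / 2236


@dataclass(frozen=True)
class ScenarioConfig:
    """Named scenario plus the knobs that define its statistical structure."""

    scenario: str
    seed: int
    locus_scale: float = 0.1       # 1.0 = full 30.2-kb units
    p_transient: float = DEFAULT_P_TRANSIENT
    ct_sd: float = 0.15            # genomic-qPCR Ct noise, cycles
    expr_ct_sd: float = 0.05       # expression-qPCR Ct noise, cycles
    coverage: tuple[float, float] = (15.0, 30.0)  # per-line fold range
    uco_rate: float = UCOParams().uco_rate
    n_plants: int | None = None    # screen size override
    generations: int = 2
    qpcr_replicates: int = 7
    include_loci: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"valid: {SCENARIOS}")
        for r in (self.p_transient, self.ct_sd, self.expr_ct_sd):
            if r < 0:
                raise ValueError("noise parameters must be >= 0")


@dataclass
class SimBundle:
    """In-memory scenario output: named artefacts plus machine-readable truth."""

    config: ScenarioConfig
    files: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        """Write every artefact (TSV/FASTA/GFF3/JSON) plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, obj in self.files.items():
            if isinstance(obj, pd.DataFrame):
                path = out / f"{name}.tsv"
                fio.write_tsv(obj, path)
            elif hasattr(obj, "sequence") and hasattr(obj, "annotation"):
                fio.write_fasta(obj, out / f"{name}.fasta")
                fio.write_gff3(obj.annotation, out / f"{name}.gff3")
                fio.write_unit_bed(obj.annotation, out / f"{name}.units.bed")
                written += [f"{name}.fasta", f"{name}.gff3", f"{name}.units.bed"]
                continue
            else:
                path = out / f"{name}.json"
                fio.write_json(obj, path)
            written.append(path.name)
        fio.write_json(self.truth, out / "truth.json")
        manifest = {"scenario": self.config.scenario, "seed": self.config.seed,
                    "config": asdict(self.config),
                    "files": sorted(written) + ["truth.json"]}
        fio.write_json(manifest, out / "manifest.json")
        return out


def _line_genotypes() -> dict[str, Genotype]:
    return {
        "monecious": build_line_structure("monecious_9930_like"),
        "gynoecious": build_line_structure("gynoecious_Gy14_like"),
        "triple": build_line_structure("triple_AM297_like"),
    }


def _locus_params(cfg: ScenarioConfig) -> LocusParams:
    if cfg.locus_scale >= 1.0:
        return LocusParams(seed=cfg.seed)
    return LocusParams.small(seed=cfg.seed)


def _screen(cfg: ScenarioConfig, default_n: int) -> SimBundle:
    rng = np.random.default_rng(cfg.seed)
    founder = build_line_structure("gynoecious_Gy14_like")
    n = cfg.n_plants or default_n
    p = UCOParams(cfg.uco_rate)
    pop = self_population(founder, n, cfg.generations, p, rng,
                          p_transient=cfg.p_transient)
    counts = pop.counts()
    confirmable = [pid for pid, g in zip(pop.table["plant_id"], pop.genotypes)
                   if g.g_dosage == 1]
    stable_m = [pid for pid, g in zip(pop.table["plant_id"], pop.genotypes)
                if g.g_dosage == 0]
    bundle = SimBundle(cfg)
    bundle.files["population"] = pop.table
    bundle.truth = {
        "founder": str(founder),
        "uco_rate": cfg.uco_rate,
        "generations": cfg.generations,
        "p_transient": cfg.p_transient,
        "n_plants": n,
        "counts": counts,
        "n_tagged": int(pop.table["tagged"].sum()),
        "confirmable_plants": confirmable,   # true heterozygotes (SubG)
        "stable_m_plants": stable_m,         # true zero-dosage plants
        "genotypes": [str(g) for g in pop.genotypes],
    }
    return bundle


# Printed segregation table used as downstream input: each row's parents,
# CsACS1G copy total, expected sex expression, and observed class counts.
_TABLE1_ROWS = [
    # name, parent1, parent2, generation, copies, expected, n, (G, SubG, M)
    ("Gy14", "AG/AG", None, "inbred", 2, "G", 2236, (2170, 0, 3)),
    ("G06", "AG/AG", None, "inbred", 2, "G", 2573, (2537, 0, 3)),
    ("9930", "A/A", None, "inbred", 0, "M", 20, (0, 0, 20)),
    ("S52", "A/A", None, "inbred", 0, "M", 20, (0, 0, 20)),
    ("XTMC", "A/A", None, "inbred", 0, "M", 20, (0, 0, 20)),
    ("AM297", "AGG/AGG", None, "inbred", 4, "G", 20, (20, 0, 0)),
    ("(Gy14 x 9930) F1", "AG/AG", "A/A", "F1", 1, "SubG", 16, (1, 15, 0)),
    ("(Gy14 x XTMC) F1", "AG/AG", "A/A", "F1", 1, "SubG", 16, (2, 14, 0)),
    ("(Gy14 x S52) F1", "AG/AG", "A/A", "F1", 1, "SubG", 16, (0, 16, 0)),
    ("(Gy14 x 9930) F2", "AG/A", "AG/A", "F2", None,
     "Segregating, 1G:2SubG:1M", 200, (47, 98, 55)),
    ("(AM297 x 9930) F1", "AGG/AGG", "A/A", "F1", 2, "G", 16, (16, 0, 0)),
    ("(AM297 x XTMC) F1", "AGG/AGG", "A/A", "F1", 2, "G", 16, (16, 0, 0)),
    ("(AM297 x S52) F1", "AGG/AGG", "A/A", "F1", 2, "G", 16, (16, 0, 0)),
    ("(AM297 x 9930) F2", "AGG/A", "AGG/A", "F2", None,
     "Segregating, 3G:1M", 1000, (735, 0, 265)),
    # printed counts for this row are internally inconsistent in the source
    # table; reproduced qualitatively (all-M expectation) only.
    ("(Gy14M-17 x 9930) F1", "A/A", "A/A", "F1", 0, "M", 14, None),
]


def table1_populations() -> pd.DataFrame:
    rows = []
    for (name, p1, p2, gen, copies, expected, n, obs) in _TABLE1_ROWS:
        rows.append({
            "population": name, "parent1": p1, "parent2": p2 or p1,
            "generation": gen, "csacs1g_copies": copies,
            "expected_sex": expected, "n_observed": n,
            "n_G": None if obs is None else obs[0],
            "n_SubG": None if obs is None else obs[1],
            "n_M": None if obs is None else obs[2],
        })
    return pd.DataFrame(rows)


def _table1_crosses(cfg: ScenarioConfig) -> SimBundle:
    from .transmission import cross, dosage_phenotype, GenotypeDistribution

    p0 = UCOParams(0.0)
    df = table1_populations()
    truth_rows = {}
    for _, row in df.iterrows():
        g1 = Genotype.from_string(row["parent1"])
        g2 = Genotype.from_string(row["parent2"])
        if row["generation"] == "inbred":
            phenos = {str(dosage_phenotype(g1)): 1.0}
        else:
            phenos = {str(k): v
                      for k, v in cross(g1, g2, p0).phenotypes().items() if v}
        truth_rows[row["population"]] = phenos
    bundle = SimBundle(cfg)
    bundle.files["table1"] = df
    bundle.truth = {"expected_phenotype_dist": truth_rows, "uco_rate": 0.0}
    return bundle


def _fig1_depth(cfg: ScenarioConfig) -> SimBundle:
    rng = np.random.default_rng(cfg.seed)
    lines = [("Gy14", "gynoecious"), ("G421", "gynoecious"),
             ("WI2757", "gynoecious"), ("PI183967", "monecious"),
             ("WI7167", "monecious"), ("PI190788", "monecious")]
    genos = _line_genotypes()
    geo = (ReferenceGeometry() if cfg.locus_scale >= 1.0
           else ReferenceGeometry.small())
    bundle = SimBundle(cfg)
    truth = {}
    lo, hi = cfg.coverage
    for name, cls in lines:
        cov = float(rng.uniform(lo, hi))
        g = genos[cls]
        prof = simulate_depth(g, geo, cov, rng)
        bundle.files[f"depth_{name}"] = prof.to_frame(chrom="Fref")
        truth[name] = {"genotype": str(g), "coverage": cov,
                       "expected_ratio": g.total_units / 2.0}
    params = _locus_params(cfg)
    for label, h in (("locus_monecious", "A"), ("locus_gynoecious", "AG"),
                     ("locus_triple", "AGG")):
        bundle.files[label] = assemble_locus_sequence(h, params)
    bundle.truth = {"geometry": asdict(geo), "samples": truth}
    return bundle


def _fig3_panel(cfg: ScenarioConfig) -> SimBundle:
    rng = np.random.default_rng(cfg.seed)
    genos = _line_genotypes()
    samples: list[tuple[str, Genotype]] = []
    for k in range(1, 6):
        samples.append((f"H{k}", genos["gynoecious"]))
    for k in range(1, 15):
        g = genos["triple"] if k == 14 else genos["gynoecious"]
        samples.append((f"G{k}", g))  # G14 is the triple-repeat line (AM297)
    for k in range(1, 9):
        samples.append((f"M{k}", genos["monecious"]))
    subg = Genotype(hap("AG"), hap("A"))
    for k in range(1, 4):
        samples.append((f"SubG{k}", subg))

    tables = []
    truth = {}
    for sid, g in samples:
        tables.append(simulate_qpcr(g, GENOMIC_AMPLICONS, cfg.ct_sd,
                                    cfg.qpcr_replicates, rng, sample_id=sid))
        truth[sid] = {
            "genotype": str(g),
            "copies_per_haploid": {a: template_copies(g, a) / 2.0
                                   for a in GENOMIC_AMPLICONS},
        }
    bundle = SimBundle(cfg)
    bundle.files["ct_table"] = pd.concat(tables, ignore_index=True)
    bundle.truth = {"samples": truth, "replicates": cfg.qpcr_replicates,
                    "ct_sd": cfg.ct_sd, "reference_amplicon": "BCAT1_8"}
    return bundle


# expression truth: fold change vs the gynoecious wild type in gynoecy-loss
# mutants (ethylene-pathway genes down ~4-fold, CsMYB unchanged)
EXPRESSION_TRUTH = {"CsACS1": 0.25, "CsACS2": 0.25, "CsMYB": 1.0}


def simulate_expression_qpcr(fold_changes: dict[str, float], ct_sd: float,
                             rng: np.random.Generator, sample_id: str,
                             n_bio: int = 3, n_tech: int = 3,
                             base_ct: float = 24.0, ref_ct: float = 18.0,
                             efficiency: float = 2.0) -> pd.DataFrame:
    """Expression Ct rows for one sample: genes at given fold vs baseline 1.

    Each biological replicate is one RNA/cDNA preparation measured for every
    gene and the reference, so its loading shift (sd ``ct_sd``) is shared
    across amplicons and cancels in ΔCt; technical wells add independent
    noise at half that sd.
    """
    rows = []
    for b in range(n_bio):
        bio_shift = rng.normal(0.0, ct_sd)
        for gene, fold in fold_changes.items():
            for t in range(n_tech):
                ct = (base_ct - math.log(fold, efficiency) + bio_shift
                      + rng.normal(0.0, ct_sd / 2.0))
                rows.append((sample_id, gene, b * n_tech + t + 1, ct))
        for t in range(n_tech):
            rows.append((sample_id, "actin2", b * n_tech + t + 1,
                         ref_ct + bio_shift + rng.normal(0.0, ct_sd / 2.0)))
    return pd.DataFrame(rows, columns=["sample", "amplicon", "replicate", "ct"])


def _fig5_expression(cfg: ScenarioConfig) -> SimBundle:
    rng = np.random.default_rng(cfg.seed)
    wild = {g: 1.0 for g in EXPRESSION_TRUTH}
    tables = [simulate_expression_qpcr(wild, cfg.expr_ct_sd, rng, "Gy14")]
    for m in ("Gy14M-17", "Gy14M-42", "Gy14M-63"):
        tables.append(simulate_expression_qpcr(EXPRESSION_TRUTH, cfg.expr_ct_sd,
                                               rng, m))
    bundle = SimBundle(cfg)
    bundle.files["expression_ct"] = pd.concat(tables, ignore_index=True)
    bundle.truth = {
        "calibrator": "Gy14",
        "fold_changes": EXPRESSION_TRUTH,
        "down_regulated": [g for g, f in EXPRESSION_TRUTH.items() if f < 1.0],
        "unchanged": [g for g, f in EXPRESSION_TRUTH.items() if f == 1.0],
        "ct_sd": cfg.expr_ct_sd,
    }
    return bundle


def generate_scenario(cfg: ScenarioConfig) -> SimBundle:
    """Build the named scenario's artefact bundle, deterministically per seed."""
    if cfg.scenario == "gy14_screen":
        return _screen(cfg, default_n=2236)
    if cfg.scenario == "g06_screen":
        return _screen(cfg, default_n=2573)
    if cfg.scenario == "table1_crosses":
        return _table1_crosses(cfg)
    if cfg.scenario == "fig1_depth":
        return _fig1_depth(cfg)
    if cfg.scenario == "fig3_qpcr_panel":
        return _fig3_panel(cfg)
    if cfg.scenario == "fig5_expression":
        return _fig5_expression(cfg)
    raise ValueError(f"unknown scenario {cfg.scenario!r}")


def truth_report(bundle: SimBundle) -> dict:
    """Machine-readable ground truth plus scenario provenance."""
    return {"scenario": bundle.config.scenario, "seed": bundle.config.seed,
            "truth": bundle.truth}
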