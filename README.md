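# flocuscnv

Modelling gynoecy and its instability at the cucumber *F* (*femaleness*)
locus — a tandem-repeat copy-number variant whose meiotic dynamics this
package simulates, measures and tests.

## The problem

Gynoecious cucumber inbreds (all-female flowering, the backbone of hybrid
production) owe their sex expression to a duplicated ~30.2-kb unit at the
*F* locus. The extra unit carries *CsACS1G*, a copy of the
ethylene-biosynthesis gene *CsACS1* placed behind a recombinant distal
promoter assembled from *CsBCAT* material: truncated intron 8 (928 of
984 bp), exon 9 (113 bp), intron 9 (350 bp) and exon 10 (113 bp) — 1504 bp
reaching −1914 from the transcription start, while the proximal promoter
(−410 inward) is identical to *CsACS1*'s. Sex phenotype is a dosage read-out
of diploid *CsACS1G* copies *d*:

    d = 0 → monecious (M),  d = 1 → subgynoecious (SubG),  d ≥ 2 → gynoecious (G)

Gynoecious lines occasionally throw monecious offspring ("gynoecy loss", at
~0.1% per screened plant). The mechanistic model is unequal crossing over
(UCO): during meiosis the repeat arrays pair one register out of alignment,
and a crossover at misaligned positions *i* ≠ *j* produces reciprocal
deletion and duplication gametes

    hap1[:i] + hap2[j:]   and   hap2[:j] + hap1[i:]

so an [A,G]/[A,G] plant yields [A] (loss) and [A,G,G] (triple-repeat)
gametes, explaining both the monecious mutants and naturally occurring
three-copy gynoecious lines.

The package is aimed at quantitative geneticists and breeders who want to
simulate such screens, calibrate the per-meiosis UCO rate μ from observed
mutant frequencies, and validate the molecular read-outs (read-depth ratios,
genomic-qPCR copy calls, junction-spanning PCR) on synthetic data with known
truth.

## What's inside

| module | role |
| --- | --- |
| `locus_model` | haplotype/genotype types, annotated synthetic locus assembly (FASTA/GFF3/BED), recombinant-promoter arithmetic, in-silico PCR |
| `transmission` | meiosis with UCO, exact gamete enumeration, crosses/selfing, field-screen simulation and mutant confirmation |
| `copy_number` | windowed read-depth CNV calling, genomic-qPCR copy estimation (ΔCt vs a single-copy reference), ΔΔCt expression |
| `segregation_stats` | χ² goodness of fit (closed forms for df 1–2), Clopper–Pearson rates, Welch's t, μ calibration by inverting the screen expectation |
| `synthetic_data` | named scenario generators with machine-readable truth |
| `cli` | `flocus` command-line front end |

## Worked example

```python
>>> import flocuscnv as fc
>>> het = fc.Genotype.from_string("AG/A")          # subgynoecious F1
>>> {str(k): v for k, v in fc.cross(het, het, fc.UCOParams(0.0)).phenotypes().items()}
{'M': 0.25, 'SubG': 0.5, 'G': 0.25}
```

The selfed heterozygote segregates 1 G : 2 SubG : 1 M — the dosage model's
signature ratio. With UCO switched on, a gynoecious homozygote is no longer
a pure breeder:

```python
>>> gy14 = fc.build_line_structure("gynoecious_Gy14_like")   # [A,G]/[A,G]
>>> {str(h): p for h, p in fc.enumerate_gametes(gy14, fc.UCOParams(1.25e-3)).items()}
{'AG': 0.99875, 'A': 0.000625, 'AGG': 0.000625}
```

and the matching statistics on a real screen's counts:

```bash
$ flocus mutation-rate --hits 3 --n 2236
{"rate": 0.0013416815742397137, "percent": 0.13, "ci": [0.0002767725059918494, 0.0039159091241603985]}
$ flocus segregate --observed 47,98,55 --ratio 1:2:1
{"chi2": 0.72, "df": 2, "p_value": 0.697676326071031}
```

3 mutants in 2236 plants is 0.13% (exact 95% CI 0.028–0.392%), and the
1 : 2 : 1 F2 fit gives χ² = 0.72 (p ≈ 0.698, df = 2). The full pipeline
report — promoter arithmetic, junction-PCR products, copy-call recovery,
expected segregation of every cross — comes from

```bash
flocus reproduce-paper --out out/ --seed 1
```

which prints one pass/fail row per quantity.

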