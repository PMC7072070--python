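# Methods

## Locus architecture

A haplotype is an ordered list of repeat units, each `A` (native *CsACS1* +
*CsMYB*) or `G` (*CsACS1G*: the same shared core preceded by the 1504-bp
recombinant distal promoter), followed by the complete *CsBCAT* gene and
flanking sequence. Unit boundaries are defined so that a unit begins at the
5' end of its distal promoter and ends just before the next unit's promoter
(or before *CsBCAT*); this makes the UCO concatenation rule unambiguous and
means unit identity travels with its promoter. An `A` unit carries no
distal block of its own — it begins at the −410 proximal boundary — so a
`G` unit is exactly 1504 bp longer than an `A` unit.

The recombinant promoter is composed, 5'→3' on the assembled strand, of
*CsBCAT* intron 8 truncated to 928 bp (of 984; the 56-bp tail is lost at
the recombination breakpoint), exon 9 (113 bp), intron 9 (350 bp) and exon
10 (113 bp), with exon 10 abutting the −410 proximal boundary. The
downstream *CsBCAT* gene is laid out colinearly on the + strand, so the
promoter block is a byte-identical copy of the corresponding *CsBCAT*
substring. Real genomes realise this homology through a strand flip; the
synthetic locus abstracts that away, which changes nothing the package
measures (lengths, copy counts, primer-site orientations). The diagnostic
consequence is preserved exactly: the junction primer pair (left primer at
the exon-10 end of the block, right primer reverse-priming just inside the
shared −410 region) faces across the junction only in `G` units, yielding
one 111-bp product per `G` unit and none in monecious material, where both
binding sites exist (in the intact *CsBCAT* and upstream of *CsACS1*) but
point away from each other.

Background sequence is seeded-random at GC 0.35 (cucumber-like). All unit
cores are byte-identical by default; an option plants the two reported core
SNPs into `G` units. Coordinates are 0-based half-open internally, 1-based
inclusive in GFF3 output, and promoter extents are additionally annotated
as negative offsets from the transcription start (−410, −1914). The default
`G`-unit length is 30,200 bp with 10-kb flanks; `LocusParams.small()`
builds ~4-kb units for fast tests while holding every length-derived
diagnostic (1504, 56, 111, 410/1914) fixed. In-silico PCR is exact-match on
both strands, with no thermodynamics — the assays being modelled used
designed primers against known sequence.

## Meiotic transmission

Each meiosis offers at most one crossover opportunity in the locus (the
interval is short on the genetic map). With probability 1 − μ, or whenever
no misaligned register exists (single-unit homozygotes), the transmitted
gamete is a uniformly chosen parental haplotype — equal crossovers are
invisible at unit resolution. With probability μ the arrays misalign:
registers (i, j), i ≠ j, |i − j| ≤ `max_offset` (default 1, single-register
slippage), weighted by `offset_weights` renormalised over available
offsets and uniform within an offset. The reciprocal products
`hap1[:i] + hap2[j:]` and `hap2[:j] + hap1[i:]` conserve total unit count
and are transmitted with probability ½ each.

`enumerate_gametes` is the exact counterpart of the stochastic simulator
and the oracle for it; `cross` multiplies two gamete distributions
(contributions are accumulated in sorted order, so the parent swap is exact
at the float level), and `evolve_selfing` composes selfing generations on
the full distribution, truncating haplotypes above a unit cap (default 6;
discarded mass is O(μ²) per generation).

μ is a free parameter: the field observes realised mutant frequencies, not
μ. The default 1.25 × 10⁻³ reflects the ~0.12% gynoecy-loss rate under a
single-meiosis reading; `calibrate_uco_rate` is the principled route — it
inverts the exact screen expectation (selfing composition + confirmation
power) by bisection and maps the observed rate's Clopper–Pearson interval
through the same inverse. For the two-generation screen design the expected
confirmed-mutant frequency is ≈ 1.75 μ (1.5 μ of heterozygotes from the two
meioses, discounted by progeny-test power, plus 0.25 μ of already-monecious
segregants), so the calibrated μ is ~0.7 × 10⁻³ for a 0.125% observed rate.

Phenotype is strictly deterministic in dosage. Transient male flowers on
true-gynoecious plants are observation noise, not phenotype state: the
screen simulator tags true-G plants spuriously at `p_transient`
(default 63/2236, the tagged-minus-confirmed fraction of the original
screen), and confirmation by selfing `progeny_size` offspring rejects them,
because only genuine heterozygotes (probability 1 − (3/4)^n) and stable
monecious plants show monecious progeny.

## Copy-number estimation

**Read depth.** The reference is one unit plus flanks; expected reads per
window are (diploid copies/2) × coverage × window/read-length, Poisson by
default (negative-binomial with dispersion 0.1 available — no dispersion
information exists for the original data, so independence is the default).
The caller takes 10%-trimmed means of per-window depth in the CNV interval
and flanks, excluding boundary-straddling windows; their ratio is copies
per haploid equivalent, rounded to the half-integer grid with ties to the
even half. Windows are 500 bp at full scale, 50 bp on the small reference.

**Genomic qPCR.** Ct = baseCt − log_E(template/2) + noise, efficiency E
fixed at 2.0 (no standard-curve module; none was reported). Template
bookkeeping per diploid: *CsACS1* and *CsMYB* amplicons count every unit;
BCAT9–10 counts the two intact *CsBCAT* genes plus one per `G` unit; the
junction amplicon counts `G` units only (and records a no-amplification
sentinel at zero template, propagated as 0 copies — the orientation
argument, not a large Ct); BCAT1–8 is always 2 and is the normaliser, so
copies are reported per haploid equivalent with monecious = 1. A replicate
is one template aliquot measured across all amplicons: half the noise
variance (marginally N(0, σ), σ = 0.15 cycles by default, 7 replicates) is
a shared per-replicate loading shift that cancels in the replicate-paired
ΔCt the estimator uses — this is what makes index-wise replicate pairing
meaningful. Copy estimates are within-sample ΔCt (no calibrator line);
the ΔΔCt calibrator variant is `relative_expression`, used for the
actin2-normalised expression contrasts, where the biological-replicate
shift is likewise shared across genes.

## Statistics

χ² goodness of fit uses the uncorrected statistic (the published 3:1 row
matches it without continuity correction) with closed-form tails for df 1
(erfc(√(x/2))) and df 2 (exp(−x/2)), both property-tested against the
regularised incomplete gamma to 1e-10. p-values are reported to four
decimals; the published table appears to truncate rather than round its
p (0.6976 vs computed 0.69768), so comparisons at that precision allow
2 × 10⁻⁴. Rates use exact Clopper–Pearson intervals (appropriate at ≤ 3
successes); the displayed percentage truncates at the second decimal,
which is the convention the quoted screen rates follow (3/2573 = 0.11659%
is quoted as 0.11%). Two-sample contrasts use Welch's t (safer than
Student at n = 3); no multiple-testing correction is applied, matching
how the individual tests are reported.

## Synthetic scenarios and what they do not show

Scenario generators reproduce the study conditions: screens of 2236 and
2573 plants two selfing generations from a single founder; the segregation
table of crosses among 0/1/2-unit lines (printed class counts stored as
downstream input, including one row whose printed counts are internally
inconsistent and is reproduced qualitatively only); six 15–30× depth
profiles (three gynoecious, three monecious); a 30-line qPCR panel
(5 hermaphroditic, 14 gynoecious of which one triple-repeat, 8 monecious,
3 heterozygous F1 — line identities are synthetic labels); and a
four-sample expression panel with *CsACS1*/*CsACS2* at 0.25-fold and
*CsMYB* unchanged, 3 biological × 3 technical replicates at σ = 0.05.
Every bundle is byte-deterministic per seed and carries a truth object.

Passing recovery tests therefore demonstrates estimator correctness under
the stated noise model, not robustness to what real data add: mapping and
GC bias in depth profiles, amplification-efficiency differences between
amplicons, segmental variation outside the modelled locus, genotype ×
environment effects on sex expression beyond the tagging-noise flag, and
somatic (mitotic) copy-number change are all out of model. The depth
caller assumes known CNV boundaries (as in the original analysis) and does
no segmentation.

## Problem sizes

The default test and acceptance runs use the small locus (4-kb units),
the small depth reference (5-kb span, 50-bp windows), 100–1000 qPCR trials
per recovery check, 10⁵ meioses for the simulator-vs-enumeration check,
and 50 replicate screens of 4809 plants for the μ round trip — sizes
chosen so each check completes in seconds while keeping Monte-Carlo error
well inside the tested tolerances.
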