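"""Copy-number estimation for the F locus: read depth and genomic qPCR.

Two estimators, mirroring how the tandem duplication is measured in practice:

* **Windowed read depth** over a single-unit reference (CNV interval plus
  flanks).  Each extra repeat unit in the diploid raises expected depth inside
  the interval; the caller reports the trimmed-mean depth ratio CNV/flank,
  which equals copies per haploid equivalent (flank ≡ 1).

* **Genomic qPCR** quantification cycles, normalised to an amplicon outside
  the CNV (*CsBCAT* exons 1–8 ≡ 1 copy per haploid, i.e. 2 per diploid).
  With per-cycle efficiency E, Ct = baseCt − log_E(template/2); copies are
  recovered per replicate as E^(Ct_ref − Ct_target) and averaged.

A ΔΔCt relative-expression helper covers the expression contrasts
(actin2-normalised fold changes against a calibrator sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .locus_model import Genotype
from .transmission import dosage_phenotype  # noqa: F401  (re-exported convenience)

NO_AMP = float("nan")  # 'no amplification' sentinel in Ct tables

GENOMIC_AMPLICONS = ("CsACS1", "CsMYB", "BCAT9_10", "BCAT1_8", "F_junction")


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceGeometry:
    """Single-unit reference: 5' flank + CNV interval + 3' flank (bp)."""

    flank5: int = 10_000
    cnv: int = 30_000
    flank3: int = 10_000
    window: int = 500
    read_length: int = 150

    @property
    def length(self) -> int:
        return self.flank5 + self.cnv + self.flank3

    @property
    def cnv_interval(self) -> tuple[int, int]:
        return (self.flank5, self.flank5 + self.cnv)

    @classmethod
    def small(cls) -> "ReferenceGeometry":
        return cls(flank5=1000, cnv=3000, flank3=1000, window=50)


@dataclass
class DepthProfile:
    """Per-window read counts tiling the reference without overlap."""

    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    mean_coverage: float
    geometry: ReferenceGeometry

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("window counts must be >= 0")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError("windows must tile the reference without gaps")

    def to_frame(self, chrom: str = "Fref") -> pd.DataFrame:
        return pd.DataFrame({"chrom": chrom, "start": self.starts,
                             "end": self.ends, "count": self.counts})

    def to_tsv(self, path, chrom: str = "Fref") -> None:
        self.to_frame(chrom).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, geometry: ReferenceGeometry,
                   mean_coverage: float = float("nan")) -> "DepthProfile":
        return cls(df["start"].to_numpy(), df["end"].to_numpy(),
                   df["count"].to_numpy().astype(float), mean_coverage, geometry)


@dataclass(frozen=True)
class CopyCall:
    """Point estimate of copies per haploid equivalent, CI, and rounded call."""

    target: str
    estimate: float
    ci_low: float
    ci_high: float
    rounded: float
    n: int  # windows or replicates behind the estimate

    def __post_init__(self) -> None:
        if self.estimate < 0:
            raise ValueError("copy estimate must be >= 0")


def round_half_copies(x: float) -> float:
    """Round to the nearest half-integer, ties to the nearest even half."""
    return round(x * 2.0) / 2.0  # banker's rounding on the half grid


def simulate_depth(g: Genotype, geometry: ReferenceGeometry,
                   mean_coverage: float, rng: np.random.Generator,
                   dispersion: float | None = None) -> DepthProfile:
    """Simulate windowed read counts for a genotype.

    Expected reads per window = (diploid segment copies / 2) × mean_coverage ×
    window / read_length; flanks carry 2 copies per diploid, the CNV interval
    carries the genotype's total unit count.  Counts are Poisson, or
    negative-binomial when ``dispersion`` > 0 (variance = m + dispersion·m²).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    geo = geometry
    edges = np.arange(0, geo.length + geo.window, geo.window)
    edges = edges[edges <= geo.length]
    if edges[-1] != geo.length:
        edges = np.append(edges, geo.length)
    starts, ends = edges[:-1], edges[1:]
    cnv_lo, cnv_hi = geo.cnv_interval
    centers = (starts + ends) / 2
    copies = np.where((centers >= cnv_lo) & (centers < cnv_hi),
                      float(g.total_units), 2.0)
    expect = (copies / 2.0) * mean_coverage * (ends - starts) / geo.read_length
    if dispersion:
        # NB via gamma-Poisson mixture: shape r = 1/dispersion
        r = 1.0 / dispersion
        lam = rng.gamma(shape=r, scale=expect / r)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = rng.poisson(expect).astype(float)
    return DepthProfile(starts, ends, counts, mean_coverage, geo)


def call_cnv_from_depth(profile: DepthProfile,
                        cnv_interval: tuple[int, int] | None = None,
                        trim: float = 0.1) -> CopyCall:
    """Depth-ratio CNV call: trimmed-mean depth(CNV) / trimmed-mean depth(flank).

    Windows straddling a CNV boundary are excluded.  The ratio is copies per
    haploid equivalent directly, since the flank is single copy per haploid.
    """
    lo, hi = cnv_interval if cnv_interval is not None else profile.geometry.cnv_interval
    starts, ends, counts = profile.starts, profile.ends, profile.counts
    widths = (ends - starts).astype(float)
    depth = counts / widths
    in_cnv = (starts >= lo) & (ends <= hi)
    in_flank = (ends <= lo) | (starts >= hi)
    if in_cnv.sum() < 5 or in_flank.sum() < 5:
        raise ValueError("need >= 5 whole windows in both CNV and flanks")
    flank_depth = stats.trim_mean(depth[in_flank], trim)
    if flank_depth <= 0:
        raise ValueError("reference coverage absent")
    cnv_depth = stats.trim_mean(depth[in_cnv], trim)
    ratio = cnv_depth / flank_depth
    # normal-approximation CI on the ratio from window spread (delta method)
    se_c = depth[in_cnv].std(ddof=1) / math.sqrt(in_cnv.sum())
    se_f = depth[in_flank].std(ddof=1) / math.sqrt(in_flank.sum())
    se = ratio * math.sqrt((se_c / cnv_depth) ** 2 + (se_f / flank_depth) ** 2)
    return CopyCall("cnv_depth_ratio", float(ratio),
                    float(ratio - 1.96 * se), float(ratio + 1.96 * se),
                    round_half_copies(ratio), int(in_cnv.sum()))


# ---------------------------------------------------------------------------
# genomic qPCR
# ---------------------------------------------------------------------------

def template_copies(g: Genotype, amplicon: str) -> int:
    """Diploid template copies of an amplicon for a genotype.

    CsACS1 primers amplify both CsACS1 and CsACS1G gene bodies (one per unit);
    CsMYB likewise sits in every unit.  BCAT9_10 exists once per complete
    CsBCAT gene (2 per diploid) plus once per recombinant promoter (G units).
    F_junction spans the promoter junction, so G units only.  BCAT1_8 and the
    expression references are outside the CNV: always 2.
    """
    if amplicon in ("CsACS1", "CsMYB"):
        return g.total_units
    if amplicon == "BCAT9_10":
        return 2 + g.g_dosage
    if amplicon == "F_junction":
        return g.g_dosage
    if amplicon in ("BCAT1_8", "actin2", "CsACS2"):
        return 2
    raise ValueError(f"unknown amplicon {amplicon!r}")


def simulate_qpcr(g: Genotype, amplicons=GENOMIC_AMPLICONS,
                  noise_sd: float = 0.15, k: int = 7,
                  rng: np.random.Generator | None = None,
                  sample_id: str = "sample", base_ct: float = 22.0,
                  efficiency: float = 2.0,
                  shared_noise_fraction: float = 0.5) -> pd.DataFrame:
    """Simulate a genomic-qPCR Ct table (long format, one row per replicate).

    Ct = baseCt − log_E(copies/2) + noise, with marginal noise N(0, noise_sd)
    per well.  Replicate index r denotes one template aliquot measured across
    all amplicons, so a fraction of the noise variance
    (``shared_noise_fraction``, template-loading error) is shared by every
    well of replicate r and cancels in replicate-paired ΔCt; the remainder is
    well-specific.  Zero-template amplicons (the junction assay in monecious
    material) record the no-amplification sentinel (NaN).

    Draw order: for each replicate, first the shared component, then one
    well-specific deviate per amplicon in the given amplicon order.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= shared_noise_fraction <= 1.0:
        raise ValueError("shared_noise_fraction must be in [0, 1]")
    if k < 3:
        raise ValueError("need >= 3 replicates")
    rng = rng if rng is not None else np.random.default_rng()
    sd_shared = noise_sd * math.sqrt(shared_noise_fraction)
    sd_well = noise_sd * math.sqrt(1.0 - shared_noise_fraction)
    copies = {amp: template_copies(g, amp) for amp in amplicons}
    rows = []
    for rep in range(1, k + 1):
        shared = rng.normal(0.0, sd_shared) if noise_sd else 0.0
        for amp in amplicons:
            c = copies[amp]
            if c == 0:
                ct = NO_AMP
            else:
                well = rng.normal(0.0, sd_well) if noise_sd else 0.0
                ct = (base_ct - math.log(c / 2.0, efficiency) + shared + well)
            rows.append((sample_id, amp, rep, ct))
    out = pd.DataFrame(rows, columns=["sample", "amplicon", "replicate", "ct"])
    return out.sort_values(["amplicon", "replicate"], kind="stable",
                           ignore_index=True)


def validate_ct_table(ct: pd.DataFrame) -> None:
    required = {"sample", "amplicon", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    finite = ct["ct"].dropna()
    if (finite <= 0).any():
        raise ValueError("Ct values must be positive cycles")


def estimate_copy_qpcr(ct: pd.DataFrame, reference_amplicon: str = "BCAT1_8",
                       efficiency: float = 2.0) -> list[CopyCall]:
    """Per-sample, per-amplicon copy estimate relative to a single-copy reference.

    Replicates are paired index-wise with the reference; copies per haploid
    equivalent = E^(Ct_ref − Ct_target).  The point estimate is the replicate
    mean, the CI a normal approximation from the replicate spread, and the
    rounded call lands on the half-integer grid.  All-NaN targets (no
    amplification) are called 0 copies.
    """
    validate_ct_table(ct)
    calls: list[CopyCall] = []
    for sample, sub in ct.groupby("sample", sort=False):
        ref = sub[sub["amplicon"] == reference_amplicon].sort_values("replicate")
        if len(ref) < 3 or ref["ct"].isna().all():
            raise ValueError(
                f"reference amplicon {reference_amplicon!r} needs >= 3 "
                f"replicates in sample {sample!r}")
        ref_ct = ref["ct"].to_numpy()
        for amp, tgt in sub.groupby("amplicon", sort=False):
            if amp == reference_amplicon:
                continue
            tgt = tgt.sort_values("replicate")
            t_ct = tgt["ct"].to_numpy()
            if np.isnan(t_ct).all():
                calls.append(CopyCall(f"{sample}:{amp}", 0.0, 0.0, 0.0, 0.0,
                                      len(t_ct)))
                continue
            m = min(len(ref_ct), len(t_ct))
            per_rep = efficiency ** (ref_ct[:m] - t_ct[:m])
            per_rep = per_rep[~np.isnan(per_rep)]
            est = float(per_rep.mean())
            se = float(per_rep.std(ddof=1) / math.sqrt(len(per_rep))) \
                if len(per_rep) > 1 else 0.0
            calls.append(CopyCall(f"{sample}:{amp}", est,
                                  est - 1.96 * se, est + 1.96 * se,
                                  round_half_copies(est), len(per_rep)))
    return calls


def calls_to_frame(calls: list[CopyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"target": c.target, "estimate": c.estimate, "ci_low": c.ci_low,
          "ci_high": c.ci_high, "rounded": c.rounded, "n": c.n}
         for c in calls])


# ---------------------------------------------------------------------------
# relative expression (ΔΔCt)
# ---------------------------------------------------------------------------

def relative_expression(ct: pd.DataFrame, calibrator_sample: str,
                        reference_amplicon: str = "actin2",
                        efficiency: float = 2.0) -> pd.DataFrame:
    """ΔΔCt fold changes versus a calibrator sample.

    For each sample and gene, ΔCt = mean Ct(gene) − mean Ct(reference);
    fold = E^−(ΔCt_sample − ΔCt_calibrator).  Per-replicate ΔCt values are
    also returned (as a list column) so downstream tests can compare groups.
    """
    validate_ct_table(ct)
    if calibrator_sample not in set(ct["sample"]):
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")

    def dcts(sample: str, gene: str) -> np.ndarray:
        sub = ct[ct["sample"] == sample]
        g = sub[sub["amplicon"] == gene].sort_values("replicate")["ct"].to_numpy()
        r = sub[sub["amplicon"] == reference_amplicon] \
            .sort_values("replicate")["ct"].to_numpy()
        if len(g) == 0 or len(r) == 0:
            raise ValueError(f"missing Ct rows for {sample}/{gene}")
        m = min(len(g), len(r))
        return g[:m] - r[:m]

    genes = [a for a in ct["amplicon"].unique() if a != reference_amplicon]
    rows = []
    for sample in ct["sample"].unique():
        for gene in genes:
            d_s = dcts(sample, gene)
            d_c = dcts(calibrator_sample, gene)
            fold = efficiency ** -(np.nanmean(d_s) - np.nanmean(d_c))
            rows.append({"sample": sample, "gene": gene, "fold_change": fold,
                         "delta_ct": d_s.tolist()})
    return pd.DataFrame(rows)
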