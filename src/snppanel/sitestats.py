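"""Per-site statistics and the screening rules used to pick panel candidates.

The module covers four screens:

* a GATK-style hard filter on site annotations (FS, HaplotypeScore, MQ, QD,
  ReadPosRankSum, MQRankSum);
* a high-polymorphism screen on MAF / missing rate / depth / observed
  heterozygosity, in a lenient "candidate" mode and a stricter "panel" mode;
* an Fst screen (Weir & Cockerham 1984 per-site estimator, two populations,
  pass iff Fst > 0.5);
* a Hardy-Weinberg exact test (Wigginton-style full conditional enumeration).

Undefined statistics (all-missing site, zero Fst denominator) are signalled
as NaN; every screen treats NaN as a failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrix import MISSING, GenotypeMatrix, PopulationSpec

# hard-filter thresholds: (annotation, comparator, bound)
HARD_FILTER_RULES = (
    ("FS", "le", 60.0),
    ("HaplotypeScore", "le", 13.0),
    ("MQ", "ge", 40.0),
    ("QD", "ge", 2.0),
    ("ReadPosRankSum", "ge", -8.0),
    ("MQRankSum", "gt", -12.5),
)

_CMP = {
    "le": lambda v, b: v <= b,
    "ge": lambda v, b: v >= b,
    "gt": lambda v, b: v > b,
}


@dataclass
class SiteStats:
    """Per-site summary: folded MAF, missing rate, observed het, depth, Fst, HWE p."""

    maf: float
    missing_rate: float
    obs_het: float
    mean_depth: float
    fst: float = float("nan")
    hwe_p: float = float("nan")


def hard_filter(site, strict: bool = False) -> tuple[bool, str | None]:
    """Apply the annotation hard filter to one variant record.

    Returns ``(passed, reason)`` where ``reason`` names the first violated
    criterion.  By default an absent annotation does not fail its criterion
    (rank-sum annotations are legitimately absent at sites with no
    heterozygotes); ``strict=True`` makes absence a failure.
    """
    ann = site.annotations if hasattr(site, "annotations") else site
    for name, op, bound in HARD_FILTER_RULES:
        if name not in ann:
            if strict:
                return False, f"{name} absent"
            continue
        if not _CMP[op](ann[name], bound):
            return False, name
    return True, None


# -- elementary per-site statistics ----------------------------------------


def maf(codes) -> float:
    """Folded minor-allele frequency over non-missing calls; NaN if all missing."""
    codes = np.asarray(codes)
    called = codes[codes != MISSING]
    if called.size == 0:
        return float("nan")
    p_alt = called.sum() / (2.0 * called.size)
    return float(min(p_alt, 1.0 - p_alt))


def obs_het(codes) -> float:
    """Fraction of non-missing calls that are heterozygous; NaN if all missing."""
    codes = np.asarray(codes)
    called = codes[codes != MISSING]
    if called.size == 0:
        return float("nan")
    return float((called == 1).sum() / called.size)


def missing_rate(codes) -> float:
    """Missing calls / total samples."""
    codes = np.asarray(codes)
    if codes.size == 0:
        return float("nan")
    return float((codes == MISSING).sum() / codes.size)


def mean_depth(depths, codes=None, called_only: bool = False) -> float:
    """Mean read depth at a site, averaged over all samples by default.

    ``called_only=True`` averages only over samples with a non-missing
    genotype (requires ``codes``).
    """
    depths = np.asarray(depths, dtype=float)
    if called_only:
        if codes is None:
            raise ValueError("called_only requires genotype codes")
        depths = depths[np.asarray(codes) != MISSING]
    if depths.size == 0:
        return float("nan")
    return float(depths.mean())


# -- Weir & Cockerham Fst ----------------------------------------------------


def _wc_components(codes: np.ndarray, masks: list[np.ndarray]):
    """Weir & Cockerham (1984) variance components a, b, c for one or more sites.

    ``codes`` is (n_samples,) or (n_samples, n_sites); ``masks`` is a list of
    two boolean sample masks.  Returns arrays (a, b, c) per site.
    """
    codes = np.atleast_2d(np.asarray(codes))
    if codes.shape[0] == 1 and len(masks[0]) != 1:
        codes = codes.reshape(len(masks[0]), -1) if codes.size == len(masks[0]) else codes
    r = len(masks)
    n_i, p_i, h_i = [], [], []
    for m in masks:
        sub = codes[m, :]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)  # individuals called per site
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, ((sub == 1) & called).sum(axis=0) / n, np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # (r, n_sites)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    n_total = n_i.sum(axis=0)
    nbar = n_total / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_total
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_total

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    # undefined when a population has no calls or nbar <= 1
    bad = (n_i == 0).any(axis=0) | (nbar <= 1)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def wc_fst(codes, pops: PopulationSpec | None = None, matrix: GenotypeMatrix | None = None,
           masks: list[np.ndarray] | None = None) -> float:
    """Per-site Weir & Cockerham theta between two populations.

    May be negative; returns NaN when undefined (zero denominator, a
    population entirely missing at the site, or a single individual).
    Either ``masks`` (two boolean sample masks) or ``pops`` together with the
    ``matrix`` the codes came from must be given.
    """
    if masks is None:
        if pops is None or matrix is None:
            raise ValueError("need masks, or pops together with matrix")
        pops.validate(matrix)
        masks = list(pops.masks(matrix).values())
    if len(masks) != 2:
        raise ValueError("exactly two populations required")
    codes = np.asarray(codes).reshape(-1, 1)
    a, b, c = _wc_components(codes, masks)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    if not np.isfinite(denom[0]) or denom[0] == 0:
        return float("nan")
    return float(theta[0])


def wc_fst_sites(matrix: GenotypeMatrix, pops: PopulationSpec) -> np.ndarray:
    """Vectorised per-site W&C theta over every site in the matrix."""
    pops.validate(matrix)
    masks = list(pops.masks(matrix).values())
    a, b, c = _wc_components(matrix.codes, masks)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where((denom != 0) & np.isfinite(denom), a / denom, np.nan)
    return theta


def wc_fst_global(matrix: GenotypeMatrix, pops: PopulationSpec) -> float:
    """Multi-site Weir & Cockerham theta: ratio of summed variance components.

    This is the weighted combination (sum of a over sites divided by the sum
    of a+b+c) that per-site ratio averaging does not provide unbiasedly; it
    recovers the simulated differentiation parameter in parameter-recovery
    tests where the unweighted mean of per-site ratios is biased low.
    """
    pops.validate(matrix)
    masks = list(pops.masks(matrix).values())
    a, b, c = _wc_components(matrix.codes, masks)
    denom = np.nansum(a + b + c)
    if denom == 0:
        return float("nan")
    return float(np.nansum(a) / denom)


# -- screens -----------------------------------------------------------------


def high_poly_screen(stats: SiteStats, mode: str = "candidate",
                     biallelic_snp: bool = True) -> bool:
    """High-polymorphism screen.

    ``candidate`` mode (inclusive bounds): MAF >= 0.05, missing rate <= 0.1,
    mean depth >= 2, observed het <= 0.3.  ``panel`` mode is stricter:
    MAF > 0.1, missing rate < 0.1, and the record must be a biallelic SNP.
    """
    vals = (stats.maf, stats.missing_rate, stats.obs_het, stats.mean_depth)
    if any(not np.isfinite(v) for v in vals):
        return False
    if mode == "candidate":
        return (
            stats.maf >= 0.05
            and stats.missing_rate <= 0.1
            and stats.mean_depth >= 2
            and stats.obs_het <= 0.3
        )
    if mode == "panel":
        return (
            biallelic_snp
            and stats.maf > 0.1
            and stats.missing_rate < 0.1
            and stats.mean_depth >= 2
            and stats.obs_het <= 0.3
        )
    raise ValueError(f"unknown mode {mode!r}")


def fst_screen(stats: SiteStats | float, threshold: float = 0.5) -> bool:
    """Pass iff Fst is defined and strictly greater than the threshold."""
    fst = stats.fst if isinstance(stats, SiteStats) else stats
    return bool(np.isfinite(fst) and fst > threshold)


# -- Hardy-Weinberg exact test -----------------------------------------------


def hwe_exact_p(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities of configurations no more probable
    than the observed one (standard exact formulation, no mid-p).
    Monomorphic sites return 1.0.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_alt = n_het + 2 * n_homalt
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0
    # log P(h hets | allele counts) up to a shared constant
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_p_sites(codes: np.ndarray) -> np.ndarray:
    """Exact HWE p per site for a (samples x sites) code array."""
    codes = np.asarray(codes)
    out = np.empty(codes.shape[1])
    for j in range(codes.shape[1]):
        col = codes[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact_p(
            int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
        )
    return out


# -- full per-site table ------------------------------------------------------


def site_stats_table(
    matrix: GenotypeMatrix,
    pops: PopulationSpec | None = None,
    hwe: bool = False,
    screen_mode: str = "candidate",
) -> pd.DataFrame:
    """Compute the per-site stats table (vectorised), with screen flags.

    Columns: chrom, pos, maf, missing_rate, obs_het, mean_depth, fst (if
    ``pops`` given), hwe_p (if ``hwe``), pass_high_poly, pass_fst.
    """
    codes = matrix.codes
    called = codes != MISSING
    n_called = called.sum(axis=0).astype(float)
    n = codes.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(called, codes, 0).sum(axis=0) / (2 * n_called)
        maf_v = np.minimum(p_alt, 1 - p_alt)
        het_v = ((codes == 1) & called).sum(axis=0) / n_called
    miss_v = (~called).sum(axis=0) / n
    depth_v = (
        matrix.depths.mean(axis=0)
        if matrix.depths is not None
        else np.full(matrix.n_sites, np.nan)
    )
    df = pd.DataFrame(
        {
            "chrom": matrix.site_chroms(),
            "pos": matrix.site_positions(),
            "maf": maf_v,
            "missing_rate": miss_v,
            "obs_het": het_v,
            "mean_depth": depth_v,
        }
    )
    if pops is not None:
        df["fst"] = wc_fst_sites(matrix, pops)
        df["pass_fst"] = np.isfinite(df["fst"]) & (df["fst"] > 0.5)
    if hwe:
        df["hwe_p"] = hwe_exact_p_sites(codes)
    df["pass_high_poly"] = [
        high_poly_screen(
            SiteStats(row.maf, row.missing_rate, row.obs_het, row.mean_depth),
            mode=screen_mode,
        )
        for row in df.itertuples(index=False)
    ]
    return df
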