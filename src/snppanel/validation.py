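"""Chip-verification metrics: per-sample QC, polymorphism, genotype
concordance and repeatability, the MAF spectrum, and a depth-vs-concordance
simulation experiment.

Concordance and repeatability follow the NA-exclusion rule: a site missing in
either of the two callsets being compared is dropped from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

DEFAULT_MAF_BINS = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class SampleQC:
    """Per-sample panel metrics."""

    sample_id: str
    call_rate: float
    het_rate: float
    mean_depth: float
    frac_depth_ge_10: float


@dataclass
class ConcordanceResult:
    """Genotype agreement between two callsets of one individual.

    ``n_compared`` counts sites non-missing in both callsets; the rate is
    symmetric in the two callsets.
    """

    n_compared: int
    n_discordant: int

    @property
    def rate(self) -> float:
        if self.n_compared == 0:
            return float("nan")
        return (self.n_compared - self.n_discordant) / self.n_compared


def sample_qc(matrix: GenotypeMatrix, depth_threshold: int = 10) -> list[SampleQC]:
    """Call rate, heterozygosity rate and depth profile for every sample."""
    out = []
    for i, sid in enumerate(matrix.sample_ids):
        codes = matrix.codes[i, :]
        called = codes != MISSING
        n_called = int(called.sum())
        call_rate = n_called / matrix.n_sites if matrix.n_sites else float("nan")
        het_rate = float((codes == 1).sum() / n_called) if n_called else float("nan")
        if matrix.depths is not None:
            depths = matrix.depths[i, :]
            mean_d = float(depths.mean()) if matrix.n_sites else float("nan")
            frac10 = (
                float((depths[called] >= depth_threshold).mean()) if n_called else float("nan")
            )
        else:
            mean_d = frac10 = float("nan")
        out.append(SampleQC(sid, call_rate, het_rate, mean_d, frac10))
    return out


def sample_qc_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame([vars(q) for q in sample_qc(matrix)])


def polymorphic_fraction(matrix: GenotypeMatrix) -> float:
    """Fraction of sites with at least two distinct alleles among non-missing calls.

    A site is polymorphic if any heterozygote is present or if both
    homozygote classes occur.
    """
    if matrix.n_sites == 0:
        return float("nan")
    codes = matrix.codes
    called = codes != MISSING
    any_het = ((codes == 1) & called).any(axis=0)
    has_rr = ((codes == 0) & called).any(axis=0)
    has_aa = ((codes == 2) & called).any(axis=0)
    poly = any_het | (has_rr & has_aa)
    return float(poly.mean())


def concordance(callset_a: np.ndarray, callset_b: np.ndarray) -> ConcordanceResult:
    """Genotype-level concordance over sites called in both callsets.

    Both arguments are genotype-code vectors over the same site list for the
    same individual.
    """
    a = np.asarray(callset_a)
    b = np.asarray(callset_b)
    if a.shape != b.shape:
        raise ValueError("callsets must cover the same site list")
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    disc = int((a[both] != b[both]).sum())
    return ConcordanceResult(n, disc)


def repeatability_report(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Per-duplicate-pair concordance table plus the mean rate across pairs.

    ``pairs`` maps a pair label to the two genotype-code vectors of the
    duplicate detections.  The returned frame has one row per pair
    (n_compared, n_discordant, rate) and a trailing ``mean`` row whose rate
    is the unweighted mean of the per-pair rates.
    """
    rows = []
    for label, (a, b) in pairs.items():
        r = concordance(a, b)
        rows.append(
            {"pair": label, "n_compared": r.n_compared,
             "n_discordant": r.n_discordant, "rate": r.rate}
        )
    df = pd.DataFrame(rows, columns=["pair", "n_compared", "n_discordant", "rate"])
    if len(df):
        mean_row = pd.DataFrame(
            [{"pair": "mean", "n_compared": df.n_compared.sum(),
              "n_discordant": df.n_discordant.sum(), "rate": df.rate.mean()}]
        )
        df = pd.concat([df, mean_row], ignore_index=True)
    return df


def maf_spectrum(
    matrix: GenotypeMatrix,
    bin_edges: tuple[float, ...] = DEFAULT_MAF_BINS,
    pass_threshold: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """MAF histogram over panel sites plus the fraction passing a MAF floor.

    Sites that are entirely missing are excluded.  Returns ``(histogram,
    pass_fraction)`` where pass_fraction = sites with MAF >= threshold /
    total scored sites.
    """
    codes = matrix.codes
    called = codes != MISSING
    n_called = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(called, codes, 0).sum(axis=0) / (2 * n_called)
    mafs = np.minimum(p_alt, 1 - p_alt)
    mafs = mafs[np.isfinite(mafs)]
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(mafs, bins=edges)
    # np.histogram puts maf == last edge (0.5) into the last bin, as intended
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    pass_fraction = float((mafs >= pass_threshold).mean()) if mafs.size else float("nan")
    return hist, pass_fraction


def depth_concordance_experiment(
    truth_matrix: GenotypeMatrix,
    depth_low: float,
    depth_high: float,
    seed: int,
    min_call_depth: int = 2,
) -> dict:
    """Regenotype one truth matrix at two sequencing depths and compare.

    Both callsets are regenerated from the same truth under binomial allele
    sampling (see :func:`snppanel.simulate.call_genotypes_at_depth`); the
    summary reports each callset's concordance with truth and with the
    other.  In expectation concordance is non-decreasing in depth.
    """
    from .simulate import call_genotypes_at_depth

    rng = np.random.default_rng(seed)
    calls_low = call_genotypes_at_depth(
        truth_matrix, depth_low, int(rng.integers(2**31)), min_call_depth
    )
    calls_high = call_genotypes_at_depth(
        truth_matrix, depth_high, int(rng.integers(2**31)), min_call_depth
    )

    def _overall(a: GenotypeMatrix, b: GenotypeMatrix) -> ConcordanceResult:
        r = concordance(a.codes.ravel(), b.codes.ravel())
        return r

    vs_truth_low = _overall(calls_low, truth_matrix)
    vs_truth_high = _overall(calls_high, truth_matrix)
    cross = _overall(calls_low, calls_high)
    return {
        "depth_low": depth_low,
        "depth_high": depth_high,
        "concordance_low_vs_truth": vs_truth_low.rate,
        "concordance_high_vs_truth": vs_truth_high.rate,
        "concordance_low_vs_high": cross.rate,
        "n_compared_low": vs_truth_low.n_compared,
        "n_compared_high": vs_truth_high.n_compared,
    }


def validation_report(matrix: GenotypeMatrix) -> dict:
    """Bundle the sample QC, polymorphism and MAF-spectrum summaries as JSON-able dict."""
    qc = sample_qc(matrix)
    hist, pass_frac = maf_spectrum(matrix)
    call_rates = [q.call_rate for q in qc]
    return {
        "n_samples": matrix.n_samples,
        "n_sites": matrix.n_sites,
        "call_rate_min": min(call_rates) if call_rates else None,
        "call_rate_max": max(call_rates) if call_rates else None,
        "polymorphic_fraction": polymorphic_fraction(matrix),
        "maf_pass_fraction": pass_frac,
        "maf_histogram": hist.to_dict(orient="records"),
        "samples": [vars(q) for q in qc],
    }
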