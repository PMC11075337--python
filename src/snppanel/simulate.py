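"""Synthetic data generation for the whole pipeline.

Emulates the inputs a panel-design study consumes, with no external data:

* a random reference genome at a chosen GC content;
* a two-population genotype panel under the Balding-Nichols model, so the
  between-population differentiation has a known target Fst ``F``
  (subpopulation allele frequencies are Beta-distributed around a shared
  ancestral frequency with variance p(1-p)F);
* a depth-dependent genotype caller (Poisson depth, binomial allele
  sampling) to reproduce the depth-vs-concordance phenomenon;
* duplicate samples with a per-genotype error rate for repeatability QC.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix, PopulationSpec

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the two-population simulation.

    Defaults mirror a desk-scale two-reference-population design: 50
    diploid samples per population, 5000 sites with target Fst 0.3, a 5%
    ancestral-MAF floor, mean sequencing depth 30x, 2% missingness and a
    0.1% per-genotype duplicate error rate.
    """

    seed: int
    n_pop1: int = 50
    n_pop2: int = 50
    n_sites: int = 5000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000}
    )
    F: float = 0.3
    maf_floor: float = 0.05
    depth_mean: float = 30.0
    missing_rate: float = 0.02
    dup_error_rate: float = 0.001
    pop_names: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        for name in ("F", "maf_floor", "missing_rate", "dup_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.F >= 1:
            raise ValueError("F must be < 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def simulate_reference(
    chrom_lengths: dict[str, int], gc: float = 0.42, seed: int = 0
) -> dict[str, str]:
    """Random reference genome: i.i.d. bases at the given GC content."""
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        chrom: "".join(rng.choice(BASES, size=length, p=probs))
        for chrom, length in chrom_lengths.items()
    }


def simulate_two_pop_genotypes(
    cfg: SimConfig, genome: dict[str, str] | None = None
) -> tuple[GenotypeMatrix, PopulationSpec]:
    """Two-population genotypes under the Balding-Nichols model.

    Per site an ancestral frequency p ~ Uniform(maf_floor, 1 - maf_floor) is
    drawn; each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F)
    (equal to p when F = 0), and genotypes are Binomial(2, p_k) per sample,
    i.e. Hardy-Weinberg within populations.  Missingness is i.i.d.; depths
    are Poisson(depth_mean).  If ``genome`` is given, reference alleles are
    read from it so downstream probe design is consistent.
    """
    rng = np.random.default_rng(cfg.seed)
    n1, n2, S = cfg.n_pop1, cfg.n_pop2, cfg.n_sites

    # site placement: distinct positions across the chromosomes
    chroms = sorted(cfg.chrom_lengths)
    total_len = sum(cfg.chrom_lengths.values())
    per_chrom = {
        c: max(1, round(S * cfg.chrom_lengths[c] / total_len)) for c in chroms
    }
    # adjust rounding drift on the largest chromosome
    drift = S - sum(per_chrom.values())
    per_chrom[max(chroms, key=lambda c: cfg.chrom_lengths[c])] += drift
    sites: list[tuple[str, int, str, str]] = []
    for c in chroms:
        k = per_chrom[c]
        if k <= 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(1, cfg.chrom_lengths[c] + 1), size=k, replace=False)
        )
        for p in pos:
            if genome is not None:
                ref = genome[c][p - 1]
            else:
                ref = str(rng.choice(BASES))
            alt = str(rng.choice(BASES[BASES != ref]))
            sites.append((c, int(p), ref, alt))
    S = len(sites)

    p_anc = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, S)
    if cfg.F == 0:
        p1 = p2 = p_anc
    else:
        shape = (1 - cfg.F) / cfg.F
        p1 = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        p2 = rng.beta(p_anc * shape, (1 - p_anc) * shape)
    codes = np.empty((n1 + n2, S), dtype=np.int8)
    codes[:n1] = rng.binomial(2, p1, size=(n1, S))
    codes[n1:] = rng.binomial(2, p2, size=(n2, S))
    if cfg.missing_rate > 0:
        codes[rng.random((n1 + n2, S)) < cfg.missing_rate] = MISSING
    depths = rng.poisson(cfg.depth_mean, size=(n1 + n2, S)).astype(np.int32)

    ids = [f"{cfg.pop_names[0]}_{i:03d}" for i in range(n1)] + [
        f"{cfg.pop_names[1]}_{i:03d}" for i in range(n2)
    ]
    labels = {s: (cfg.pop_names[0] if i < n1 else cfg.pop_names[1])
              for i, s in enumerate(ids)}
    matrix = GenotypeMatrix(ids, sites, codes, depths, labels)
    return matrix, PopulationSpec(labels)


def call_genotypes_at_depth(
    truth: GenotypeMatrix,
    depth_mean: float,
    seed: int,
    min_call_depth: int = 2,
) -> GenotypeMatrix:
    """Re-call genotypes from truth under binomial read sampling.

    Per genotype a depth d ~ Poisson(depth_mean) is drawn and d reads are
    sampled Binomial(d, dosage/2) for the alternate allele.  The call is
    homozygous if only one allele is seen, heterozygous if both are, and
    missing if d < ``min_call_depth``.  Truth-missing genotypes stay missing.
    At low depth true heterozygotes are systematically miscalled homozygous,
    which is what degrades concordance between callsets at unequal depths.
    """
    rng = np.random.default_rng(seed)
    shape = truth.codes.shape
    d = rng.poisson(depth_mean, size=shape)
    dosage = np.clip(truth.codes, 0, 2).astype(float) / 2.0
    alt_reads = rng.binomial(d, dosage)
    calls = np.where(
        alt_reads == 0, 0, np.where(alt_reads == d, 2, 1)
    ).astype(np.int8)
    calls[d < min_call_depth] = MISSING
    calls[truth.codes == MISSING] = MISSING
    d = d.astype(np.int32)
    d[truth.codes == MISSING] = 0
    return GenotypeMatrix(truth.sample_ids, truth.sites, calls, d, truth.pop_labels)


def make_duplicate(
    sample_codes: np.ndarray, dup_error_rate: float, seed: int
) -> np.ndarray:
    """Duplicate detection of one sample with independent genotype errors.

    Each called genotype is replaced, with probability ``dup_error_rate``,
    by one of the two other codes (uniformly); missing stays missing.
    """
    rng = np.random.default_rng(seed)
    codes = np.asarray(sample_codes, dtype=np.int8).copy()
    called = codes != MISSING
    flip = called & (rng.random(codes.shape) < dup_error_rate)
    if flip.any():
        # pick one of the two codes different from the current one
        offset = rng.integers(1, 3, size=int(flip.sum()))
        codes[flip] = (codes[flip] + offset) % 3
    return codes


def simulate_annotations(
    n_sites: int, seed: int, fail_fraction: float = 0.05
) -> list[dict[str, float]]:
    """Plausible GATK-style site annotations, a set fraction failing the hard filter.

    Passing sites draw comfortably inside the retained ranges; failing sites
    violate one randomly chosen criterion.
    """
    rng = np.random.default_rng(seed)
    out: list[dict[str, float]] = []
    for _ in range(n_sites):
        ann = {
            "FS": float(rng.exponential(5.0)) % 60.0,
            "HaplotypeScore": float(rng.uniform(0, 13.0)),
            "MQ": float(rng.uniform(40, 60)),
            "QD": float(rng.uniform(2, 35)),
            "ReadPosRankSum": float(np.clip(rng.normal(0, 2), -8.0, 8.0)),
            "MQRankSum": float(np.clip(rng.normal(0, 2), -12.4, 12.4)),
        }
        if rng.random() < fail_fraction:
            which = rng.integers(0, 6)
            if which == 0:
                ann["FS"] = float(rng.uniform(60.01, 200))
            elif which == 1:
                ann["HaplotypeScore"] = float(rng.uniform(13.01, 50))
            elif which == 2:
                ann["MQ"] = float(rng.uniform(0, 39.99))
            elif which == 3:
                ann["QD"] = float(rng.uniform(0, 1.99))
            elif which == 4:
                ann["ReadPosRankSum"] = float(rng.uniform(-20, -8.01))
            else:
                ann["MQRankSum"] = float(rng.uniform(-20, -12.5))
        out.append(ann)
    return out
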