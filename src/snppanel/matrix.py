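"""Core in-memory containers: variant records, the genotype matrix, population specs.

Genotype codes follow the usual dosage convention: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, ``MISSING`` (-1) = no call.  All
genomic coordinates held in memory are 1-based inclusive; conversion to
0-based half-open happens only at the BED boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

#: site-level quality annotations the hard filter understands
ANNOTATION_FIELDS = ("FS", "MQ", "QD", "ReadPosRankSum", "MQRankSum", "HaplotypeScore")


@dataclass
class VariantSite:
    """One biallelic SNP with site-level annotations and per-sample calls.

    ``genotypes`` and ``depths`` share one sample ordering.  Annotation
    values absent from the source VCF are simply absent from the mapping
    (absence is semantically distinct from 0 for the hard filter).
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    annotations: dict[str, float] = field(default_factory=dict)
    genotypes: np.ndarray | None = None  # int8 codes, MISSING = -1
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")
        if (
            self.genotypes is not None
            and self.depths is not None
            and len(self.genotypes) != len(self.depths)
        ):
            raise ValueError("genotypes and depths must share sample ordering")


class GenotypeMatrix:
    """Samples x sites genotype codes with optional depths and population labels.

    Sites are kept sorted by (chrom, pos) with no duplicate positions; this is
    enforced at construction.
    """

    def __init__(
        self,
        sample_ids: list[str],
        sites: list[tuple[str, int, str, str]],
        codes: np.ndarray,
        depths: np.ndarray | None = None,
        pop_labels: dict[str, str] | None = None,
    ):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(sample_ids), len(sites)):
            raise ValueError(
                f"codes shape {codes.shape} != (n_samples={len(sample_ids)}, "
                f"n_sites={len(sites)})"
            )
        if depths is not None:
            depths = np.asarray(depths, dtype=np.int32)
            if depths.shape != codes.shape:
                raise ValueError("depths shape must match codes shape")
            if (depths < 0).any():
                raise ValueError("depths must be non-negative")
        keys = [(c, p) for c, p, _, _ in sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) in site list")
        order = sorted(range(len(sites)), key=lambda i: keys[i])
        if order != list(range(len(sites))):
            sites = [sites[i] for i in order]
            codes = codes[:, order]
            if depths is not None:
                depths = depths[:, order]
        if pop_labels is not None:
            unknown = set(pop_labels) - set(sample_ids)
            if unknown:
                raise KeyError(f"pop_labels reference unknown samples: {sorted(unknown)}")
        self.sample_ids = list(sample_ids)
        self.sites = list(sites)
        self.codes = codes
        self.depths = depths
        self.pop_labels = dict(pop_labels) if pop_labels else None

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def site_positions(self) -> np.ndarray:
        return np.array([p for _, p, _, _ in self.sites], dtype=np.int64)

    def site_chroms(self) -> list[str]:
        return [c for c, _, _, _ in self.sites]

    # -- subsetting ----------------------------------------------------------

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a matrix restricted to sites where ``keep`` is True (or indexed)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            self.sample_ids,
            [self.sites[i] for i in idx],
            self.codes[:, idx],
            self.depths[:, idx] if self.depths is not None else None,
            self.pop_labels,
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        labels = (
            {s: self.pop_labels[s] for s in sample_ids if s in self.pop_labels}
            if self.pop_labels
            else None
        )
        return GenotypeMatrix(
            list(sample_ids),
            self.sites,
            self.codes[idx, :],
            self.depths[idx, :] if self.depths is not None else None,
            labels,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_sites} sites>"


@dataclass
class PopulationSpec:
    """Assignment of samples to exactly two population labels for Fst screening."""

    assignments: dict[str, str]

    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def validate(self, matrix: GenotypeMatrix, require_two: bool = True) -> None:
        missing = set(self.assignments) - set(matrix.sample_ids)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        labels = self.labels()
        if require_two and len(labels) != 2:
            raise ValueError(f"exactly two population labels required, got {labels}")
        for lab in labels:
            n = sum(1 for v in self.assignments.values() if v == lab)
            if n < 2:
                raise ValueError(f"population {lab!r} has {n} sample(s); need >= 2")

    def masks(self, matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Boolean sample masks per label, in the matrix's sample order."""
        out: dict[str, np.ndarray] = {}
        for lab in self.labels():
            out[lab] = np.array(
                [self.assignments.get(s) == lab for s in matrix.sample_ids]
            )
        return out
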