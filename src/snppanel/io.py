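"""Readers and writers for the formats the pipeline touches.

VCF v4.2 is read through cyvcf2 and written by a small plain-text emitter
(only GT and DP are round-tripped, plus the six site-level annotations the
hard filter uses).  Internal coordinates are 1-based inclusive everywhere;
BED output converts to 0-based half-open at the boundary and nowhere else.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import ANNOTATION_FIELDS, MISSING, GenotypeMatrix, VariantSite
from .panel import CandidateSite, CaptureInterval, PanelSite, Probe

logger = logging.getLogger(__name__)

_SEX_CHROMS = {"X", "Y", "MT", "M", "W", "Z"}


def _is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr").removeprefix("Chr") not in _SEX_CHROMS


def read_vcf(
    path: str | Path,
    region_filter: list[str] | None = None,
    autosomes_only: bool = False,
) -> tuple[GenotypeMatrix, list[VariantSite]]:
    """Read a multi-sample VCF into a genotype matrix plus per-site records.

    Only biallelic SNPs are admitted; multiallelic and non-SNP records are
    skipped with a logged count.  Genotypes with any missing allele (``./.``
    or half calls) become missing.

    Parameters
    ----------
    path : VCF (optionally bgzipped) with per-sample GT and optionally DP.
    region_filter : if given, keep only these chromosome names.
    autosomes_only : drop sex/mitochondrial chromosomes (X, Y, MT, ...).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[tuple[str, int, str, str]] = []
    records: list[VariantSite] = []
    code_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    n_skipped = 0
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if region_filter is not None and v.CHROM not in region_filter:
            continue
        if autosomes_only and not _is_autosome(v.CHROM):
            continue
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF not in "ACGT"
            or v.ALT[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        if (v.CHROM, v.POS) in seen:
            n_skipped += 1
            continue
        seen.add((v.CHROM, v.POS))
        gts = np.asarray(v.genotypes, dtype=np.int64)  # (n, >=3): a1, a2, phased
        codes = gts[:, 0] + gts[:, 1]
        codes[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = MISSING
        codes = codes.astype(np.int8)
        dp_raw = v.format("DP")
        if dp_raw is None:
            dp = np.zeros(len(samples), dtype=np.int32)
        else:
            dp = dp_raw.ravel().astype(np.int32)
            dp[dp < 0] = 0
        ann = {}
        for k in ANNOTATION_FIELDS:
            val = v.INFO.get(k)
            if val is not None:
                ann[k] = float(val)
        records.append(
            VariantSite(v.CHROM, v.POS, v.REF, v.ALT[0], ann, codes.copy(), dp.copy())
        )
        sites.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        code_cols.append(codes)
        depth_cols.append(dp)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP/duplicate records", n_skipped)
    codes = (
        np.column_stack(code_cols)
        if code_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depths = (
        np.column_stack(depth_cols)
        if depth_cols
        else np.zeros((len(samples), 0), dtype=np.int32)
    )
    matrix = GenotypeMatrix(samples, sites, codes, depths)
    matrix.n_skipped = n_skipped  # type: ignore[attr-defined]
    return matrix, records


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              annotations: dict[tuple[str, int], dict[str, float]] | None = None) -> None:
    """Write the matrix as an uncompressed VCF v4.2 with GT and DP."""
    chrom_order: list[str] = []
    for c in matrix.site_chroms():
        if c not in chrom_order:
            chrom_order.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for k in ANNOTATION_FIELDS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, (chrom, pos, ref, alt) in enumerate(matrix.sites):
            info = "."
            if annotations:
                ann = annotations.get((chrom, pos))
                if ann:
                    info = ";".join(f"{k}={v:g}" for k, v in ann.items())
            fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", info, "GT:DP"]
            for i in range(matrix.n_samples):
                d = int(matrix.depths[i, j]) if matrix.depths is not None else 0
                fields.append(f"{gt_str[int(matrix.codes[i, j])]}:{d}")
            fh.write("\t".join(fields) + "\n")


# -- FASTA ---------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into a chrom -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_probe_fasta(probes: list[Probe], path: str | Path) -> None:
    """Probe FASTA with ids ``chrom:start-end`` (1-based inclusive)."""
    write_fasta({f"{p.chrom}:{p.start}-{p.end}": p.sequence for p in probes}, path)


# -- population table ------------------------------------------------------


def read_population_tsv(path: str | Path) -> dict[str, str]:
    """Two-column sample -> population TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0].lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_population_tsv(assignments: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in assignments.items():
            fh.write(f"{s}\t{p}\n")


# -- candidate / panel TSV --------------------------------------------------

PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "source", "maf", "fst"]


def read_candidates_tsv(path: str | Path, source_tag: str) -> list[CandidateSite]:
    """Read an externally sourced candidate-site TSV (chrom, pos, ref, alt).

    Duplicate (chrom, pos) rows are returned as-is; deduplication is the
    panel-design step's job.  Extra columns named ``maf``/``fst`` are kept.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CandidateSite(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                source=source_tag,
                maf=float(row.maf) if hasattr(row, "maf") and pd.notna(row.maf) else None,
                fst=float(row.fst) if hasattr(row, "fst") and pd.notna(row.fst) else None,
            )
        )
    return out


def write_panel_tsv(panel: list[PanelSite | CandidateSite], path: str | Path) -> None:
    """Write a panel TSV (1-based positions); an empty panel yields the header only."""
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for s in panel:
            maf = "" if s.maf is None else f"{s.maf:.6g}"
            fst = "" if s.fst is None else f"{s.fst:.6g}"
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.source}\t{maf}\t{fst}\n")


def read_panel_tsv(path: str | Path) -> list[CandidateSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CandidateSite(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                source=str(row.source),
                maf=None if pd.isna(row.maf) else float(row.maf),
                fst=None if pd.isna(row.fst) else float(row.fst),
            )
        )
    return out


# -- intervals --------------------------------------------------------------


def write_bed(
    intervals: list[CaptureInterval],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write capture intervals as BED (0-based half-open): start-1, end."""
    with open(path, "w") as fh:
        for iv in intervals:
            if chrom_lengths is not None:
                limit = chrom_lengths.get(iv.chrom)
                if limit is not None and (iv.start < 1 or iv.end > limit):
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} outside "
                        f"chromosome length {limit}"
                    )
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def write_intervals_tsv(intervals: list[CaptureInterval], path: str | Path) -> None:
    """1-based inclusive interval table (chrom, start, end, n_sites)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_sites\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{len(iv.sites)}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file, returning 1-based inclusive (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out
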