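"""Panel assembly: candidate merging, evenly spaced site selection, capture
probe design and capture-interval construction.

The design constraints implemented here are those of hybridization-capture
genotyping panels: 100 bp probes with 20-80% GC, single-copy in the genome,
free of strong hairpins/homopolymers, covering few other variants; sites
within 100 bp of each other share one probe; each target SNP is captured by
a window extending 100-200 bp up- and downstream, and overlapping windows
are merged into their hull.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: candidate origins, in dedup priority order (highest first)
SOURCE_PRIORITY = ("RESEQ_FST", "GGVD_IMMUNE", "LITERATURE", "RESEQ_POLY", "GGVD_POLY")
#: sources always retained by the spaced-panel selection
FORCED_KEEP_SOURCES = frozenset({"RESEQ_FST", "GGVD_IMMUNE", "LITERATURE"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CandidateSite:
    """A screened biallelic SNP with its origin tag and optional statistics."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    source: str
    maf: float | None = None
    fst: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCE_PRIORITY:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of {SOURCE_PRIORITY}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


# a panel site is a candidate that survived selection; alias keeps intent clear
PanelSite = CandidateSite


@dataclass
class Probe:
    """A 100 bp capture probe and the panel sites it covers."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    gc: float
    covered_sites: list[int]

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("probe coordinates do not match sequence length")


@dataclass
class CaptureInterval:
    """Genomic window (1-based inclusive) enriched around one or more sites."""

    chrom: str
    start: int
    end: int
    sites: list[int] = field(default_factory=list)

    def overlaps(self, other: "CaptureInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass
class DesignReport:
    """Audit trail of a panel-design run."""

    counts_per_source: dict[str, int] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)
    undesignable: list[tuple[str, int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts_per_source": self.counts_per_source,
            "conflicts": self.conflicts,
            "undesignable": [
                {"chrom": c, "pos": p, "reason": r} for c, p, r in self.undesignable
            ],
        }


# -- candidate merging --------------------------------------------------------


def merge_candidates(
    source_lists: list[list[CandidateSite]],
    report: DesignReport | None = None,
) -> list[CandidateSite]:
    """Merge candidate lists into one record per (chrom, pos).

    When a position appears in several sources the surviving record follows
    the priority RESEQ_FST > GGVD_IMMUNE > LITERATURE > RESEQ_POLY >
    GGVD_POLY.  A ref/alt disagreement between duplicate records is logged to
    the report and the higher-priority record kept.  Output is sorted by
    (chrom, pos).
    """
    rank = {s: i for i, s in enumerate(SOURCE_PRIORITY)}
    best: dict[tuple[str, int], CandidateSite] = {}
    for lst in source_lists:
        for cand in lst:
            cur = best.get(cand.key)
            if cur is None:
                best[cand.key] = cand
                continue
            hi, lo = (cand, cur) if rank[cand.source] < rank[cur.source] else (cur, cand)
            if (hi.ref, hi.alt) != (lo.ref, lo.alt) and report is not None:
                report.conflicts.append(
                    f"{cand.chrom}:{cand.pos} ref/alt conflict "
                    f"{lo.source}={lo.ref}>{lo.alt} vs {hi.source}={hi.ref}>{hi.alt}; "
                    f"kept {hi.source}"
                )
            best[cand.key] = hi
    merged = sorted(best.values(), key=lambda c: c.key)
    if report is not None:
        counts: dict[str, int] = {}
        for c in merged:
            counts[c.source] = counts.get(c.source, 0) + 1
        report.counts_per_source = counts
    return merged


# -- spaced panel selection -----------------------------------------------------


def select_spaced_panel(
    candidates: list[CandidateSite],
    target_size: int,
    window_bp: int = 200_000,
) -> list[PanelSite]:
    """Select an evenly spaced panel of exactly ``target_size`` sites.

    Forced-keep sources (Fst-screened, immune-gene, literature) are always
    retained.  Remaining slots are filled by round-robin over genomic windows
    of ``window_bp``: each round takes, from every window that still has
    unselected candidates, the highest-MAF candidate (ties broken by smaller
    position), so the panel density tracks the window grid rather than the
    raw candidate density.
    """
    if target_size > len(candidates):
        raise ValueError("target_size exceeds number of candidates")
    forced = [c for c in candidates if c.source in FORCED_KEEP_SOURCES]
    if len(forced) > target_size:
        raise ValueError(
            f"target_size {target_size} smaller than forced-keep count {len(forced)}"
        )
    optional = [c for c in candidates if c.source not in FORCED_KEEP_SOURCES]
    slots = target_size - len(forced)

    windows: dict[tuple[str, int], list[CandidateSite]] = {}
    for c in optional:
        windows.setdefault((c.chrom, (c.pos - 1) // window_bp), []).append(c)
    for key in windows:
        # best-first within each window: high MAF, then small position
        windows[key].sort(key=lambda c: (-(c.maf if c.maf is not None else -1.0), c.pos))

    chosen: list[CandidateSite] = []
    window_keys = sorted(windows)
    depth = 0
    while len(chosen) < slots:
        took = False
        for key in window_keys:
            if len(chosen) >= slots:
                break
            lst = windows[key]
            if depth < len(lst):
                chosen.append(lst[depth])
                took = True
        if not took:  # all windows exhausted; cannot happen if sizes checked
            break
        depth += 1
    return sorted(forced + chosen, key=lambda c: c.key)


# -- probe design ----------------------------------------------------------------


def extract_flank(
    genome: dict[str, str], chrom: str, pos: int, flank: int = 100,
    ref_allele: str | None = None,
) -> tuple[str, bool]:
    """Return the sequence window of ``flank`` bases either side of a site.

    The full window is ``2*flank + 1`` bases centred on the site (201 bp at
    the default).  Near a chromosome end the window is truncated and the
    returned flag is True.  If ``ref_allele`` is given, the base at the site
    must match it.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {chrom}:{pos} outside chromosome length {len(seq)}")
    center = seq[pos - 1]
    if ref_allele is not None and center != ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {center}, "
            f"site says {ref_allele}"
        )
    lo = max(1, pos - flank)
    hi = min(len(seq), pos + flank)
    truncated = (lo != pos - flank) or (hi != pos + flank)
    return seq[lo - 1 : hi], truncated


def gc_content(sequence: str) -> float:
    """Fraction of G/C bases in a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def single_copy_check(probe_seq: str, genome: dict[str, str], core: int = 50) -> bool:
    """Pass iff the probe's central ``core``-mer occurs exactly once in the
    genome, counting both strands (exact match)."""
    probe_seq = probe_seq.upper()
    mid = len(probe_seq) // 2
    kmer = probe_seq[mid - core // 2 : mid - core // 2 + core]
    rc = revcomp(kmer)
    total = 0
    for seq in genome.values():
        total += _count_overlapping(seq, kmer)
        if rc != kmer:
            total += _count_overlapping(seq, rc)
        if total > 1:
            return False
    return total == 1


def _count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def hairpin_dimer_screen(
    probe_seq: str, max_selfcomp: int = 12, max_homopolymer: int = 10
) -> bool:
    """Pass unless the probe can fold on itself or has a long homopolymer.

    Fails iff the sequence contains two disjoint segments of length
    ``max_selfcomp`` that are perfect reverse complements of each other
    (a stem of that length, i.e. a hairpin or self-dimer proxy) or a
    homopolymer run longer than ``max_homopolymer``.
    """
    s = probe_seq.upper()
    run, prev = 1, ""
    for ch in s:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > max_homopolymer:
            return False
    k = max_selfcomp
    if len(s) >= 2 * k:
        positions: dict[str, list[int]] = {}
        for i in range(len(s) - k + 1):
            positions.setdefault(s[i : i + k], []).append(i)
        for i in range(len(s) - k + 1):
            hits = positions.get(revcomp(s[i : i + k]))
            # disjoint occurrence downstream => stem of length k
            if hits and hits[-1] >= i + k:
                return False
    return True


def group_probe_sites(positions: list[int], share_dist: int = 100) -> list[list[int]]:
    """Greedy left-to-right grouping of same-chromosome site positions.

    A site joins the open group iff its distance to the group's *first* site
    is at most ``share_dist``; each group will share one probe.
    """
    groups: list[list[int]] = []
    for pos in sorted(positions):
        if groups and pos - groups[-1][0] <= share_dist:
            groups[-1].append(pos)
        else:
            groups.append([pos])
    return groups


def assign_probes(
    panel_sites: list[PanelSite],
    genome: dict[str, str],
    share_dist: int = 100,
    probe_len: int = 100,
    gc_bounds: tuple[float, float] = (0.20, 0.80),
    max_covered_snps: int = 3,
    known_variants: list[tuple[str, int]] | None = None,
    report: DesignReport | None = None,
) -> tuple[list[Probe], list[PanelSite]]:
    """Group panel sites into shared probes and design the probe sequences.

    Sites on a chromosome are grouped greedily left to right: a site joins
    the open group iff its distance to the group's first site is at most
    ``share_dist``.  Each group receives one ``probe_len`` bp probe centred
    on the midpoint of the group's span.  Probes must pass the GC,
    single-copy and hairpin screens and may cover at most
    ``max_covered_snps`` known variants; sites whose probe fails any screen
    are flagged undesignable and dropped from the returned panel.

    Returns ``(probes, designable_sites)``.
    """
    known = known_variants if known_variants is not None else [
        (s.chrom, s.pos) for s in panel_sites
    ]
    known_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c for c, _ in known}:
        known_by_chrom[chrom] = np.array(sorted(p for c, p in known if c == chrom))

    by_chrom: dict[str, list[PanelSite]] = {}
    for s in sorted(panel_sites, key=lambda x: x.key):
        by_chrom.setdefault(s.chrom, []).append(s)

    probes: list[Probe] = []
    kept: list[PanelSite] = []
    for chrom, sites in by_chrom.items():
        by_pos = {s.pos: s for s in sites}
        groups = [
            [by_pos[p] for p in grp]
            for grp in group_probe_sites([s.pos for s in sites], share_dist)
        ]
        for grp in groups:
            first, last = grp[0].pos, grp[-1].pos
            mid = (first + last) // 2
            start = mid - probe_len // 2 + 1
            seq = genome.get(chrom, "")
            start = max(1, min(start, len(seq) - probe_len + 1)) if seq else start
            end = start + probe_len - 1
            reason = None
            if not seq or end > len(seq) or start < 1:
                reason = "probe outside chromosome"
                probe_seq = ""
            else:
                probe_seq = seq[start - 1 : end]
                gc = gc_content(probe_seq)
                if not gc_bounds[0] <= gc <= gc_bounds[1]:
                    reason = f"gc {gc:.2f} outside {gc_bounds}"
                elif not single_copy_check(probe_seq, genome):
                    reason = "not single copy"
                elif not hairpin_dimer_screen(probe_seq):
                    reason = "hairpin/homopolymer"
                else:
                    kp = known_by_chrom.get(chrom)
                    n_cov = 0
                    if kp is not None:
                        n_cov = int(np.searchsorted(kp, end, "right") - np.searchsorted(kp, start, "left"))
                    if n_cov > max_covered_snps:
                        reason = f"covers {n_cov} known variants (max {max_covered_snps})"
            if reason is not None:
                if report is not None:
                    for s in grp:
                        report.undesignable.append((chrom, s.pos, reason))
                continue
            probes.append(
                Probe(chrom, start, end, probe_seq, gc_content(probe_seq),
                      [s.pos for s in grp])
            )
            kept.extend(grp)
    return probes, sorted(kept, key=lambda s: s.key)


# -- capture intervals --------------------------------------------------------------


def capture_interval(
    chrom: str, pos: int, flank_up: int = 150, flank_down: int = 150
) -> CaptureInterval:
    """Capture window around one site: [pos - flank_up, pos + flank_down].

    Flanks must lie in [100, 200] bp.
    """
    for f in (flank_up, flank_down):
        if not 100 <= f <= 200:
            raise ValueError(f"flank {f} outside the allowed 100-200 bp range")
    return CaptureInterval(chrom, pos - flank_up, pos + flank_down, [pos])


def merge_intervals(intervals: list[CaptureInterval]) -> list[CaptureInterval]:
    """Collapse overlapping or book-ended per-site intervals into their hull.

    Output is disjoint and sorted; every input site lands in exactly one
    output interval.  Idempotent.
    """
    out: list[CaptureInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + 1:
            prev = out[-1]
            prev.end = max(prev.end, iv.end)
            prev.sites = sorted(set(prev.sites) | set(iv.sites))
        else:
            out.append(CaptureInterval(iv.chrom, iv.start, iv.end, sorted(iv.sites)))
    return out


def design_intervals(
    panel_sites: list[PanelSite], flank_up: int = 150, flank_down: int = 150
) -> list[CaptureInterval]:
    """Per-site capture intervals, merged."""
    return merge_intervals(
        [capture_interval(s.chrom, s.pos, flank_up, flank_down) for s in panel_sites]
    )
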