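"""Candidate merging, spaced selection, probe design and capture intervals,
including the printed worked examples the design rules must reproduce."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from snppanel.panel import (
    CandidateSite,
    CaptureInterval,
    DesignReport,
    assign_probes,
    capture_interval,
    design_intervals,
    extract_flank,
    gc_content,
    group_probe_sites,
    hairpin_dimer_screen,
    merge_candidates,
    merge_intervals,
    revcomp,
    select_spaced_panel,
    single_copy_check,
)
from snppanel.simulate import simulate_reference


def cand(chrom, pos, source, maf=0.2, ref="A", alt="G"):
    return CandidateSite(chrom, pos, ref, alt, source, maf=maf)


# ------------------------------------------------------------ candidate merge


def test_merge_candidates_priority():
    merged = merge_candidates([
        [cand("chr1", 100, "RESEQ_POLY")],
        [cand("chr1", 100, "LITERATURE")],
    ])
    assert len(merged) == 1 and merged[0].source == "LITERATURE"


def test_merge_candidates_disjoint_counts_sum():
    lists = [
        [cand("chr1", 10 + i, "RESEQ_POLY") for i in range(3)],
        [cand("chr1", 100, "RESEQ_FST")],
        [cand("chr2", 5 + i, "GGVD_POLY") for i in range(2)],
        [cand("chr2", 50, "GGVD_IMMUNE")],
        [cand("chr3", 7 + i, "LITERATURE") for i in range(2)],
    ]
    merged = merge_candidates(lists)
    assert len(merged) == 9
    assert merged == sorted(merged, key=lambda c: c.key)


def test_merge_candidates_conflict_reported():
    report = DesignReport()
    merged = merge_candidates([
        [cand("chr1", 100, "GGVD_POLY", ref="A", alt="G")],
        [cand("chr1", 100, "RESEQ_FST", ref="A", alt="T")],
    ], report)
    assert merged[0].source == "RESEQ_FST" and merged[0].alt == "T"
    assert len(report.conflicts) == 1


# -------------------------------------------------------------- spaced panel


def test_select_spaced_panel_greedy_max_maf():
    cands = [cand("chr1", 1000 + i, "RESEQ_POLY", maf=0.1 + 0.01 * i)
             for i in range(10)]
    picked = select_spaced_panel(cands, 1)
    assert len(picked) == 1 and picked[0].pos == 1009  # highest MAF


def test_select_spaced_panel_tie_breaks_smaller_position():
    cands = [cand("chr1", 2000, "RESEQ_POLY", maf=0.3),
             cand("chr1", 1000, "RESEQ_POLY", maf=0.3)]
    assert select_spaced_panel(cands, 1)[0].pos == 1000


def test_select_spaced_panel_even_occupancy():
    """Uniform candidates over 10 windows, target 10 -> one per window."""
    window = 200_000
    cands = [cand("chr1", w * window + 50 + i * 97, "RESEQ_POLY",
                  maf=0.05 + (i % 7) * 0.05)
             for w in range(10) for i in range(20)]
    picked = select_spaced_panel(cands, 10, window_bp=window)
    occupancy = np.bincount([(c.pos - 1) // window for c in picked], minlength=10)
    assert occupancy.tolist() == [1] * 10  # zero coefficient of variation


def test_select_spaced_panel_forced_sources_retained():
    cands = [cand("chr1", 100, "RESEQ_FST", maf=0.01),
             cand("chr1", 200, "GGVD_IMMUNE", maf=None),
             cand("chr1", 300, "LITERATURE", maf=None)] + [
        cand("chr1", 400 + i, "RESEQ_POLY", maf=0.4) for i in range(5)]
    picked = select_spaced_panel(cands, 4)
    sources = [c.source for c in picked]
    assert sources.count("RESEQ_FST") == 1
    assert sources.count("GGVD_IMMUNE") == 1
    assert sources.count("LITERATURE") == 1
    with pytest.raises(ValueError, match="forced-keep"):
        select_spaced_panel(cands, 2)


# ------------------------------------------------------------ probe sequence ops


def test_extract_flank_window_and_truncation():
    genome = {"chr1": "".join("ACGT"[i % 4] for i in range(400))}
    seq, truncated = extract_flank(genome, "chr1", 150)
    assert len(seq) == 201 and not truncated
    assert seq == genome["chr1"][49:250]  # bases 50..250, 1-based
    seq, truncated = extract_flank(genome, "chr1", 30)
    assert truncated and len(seq) == 130  # bases 1..130
    with pytest.raises(ValueError, match="mismatch"):
        extract_flank(genome, "chr1", 150, ref_allele="T")  # base 150 is C


@pytest.mark.parametrize("seq, gc", [("ATATAT", 0.0), ("GCGC", 1.0), ("ACGT", 0.5)])
def test_gc_content(seq, gc):
    assert gc_content(seq) == gc


def test_single_copy_check():
    rng = np.random.default_rng(3)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 10_000))}
    probe = genome["chr1"][500:600]
    assert single_copy_check(probe, genome)
    dup = {"chr1": genome["chr1"] + genome["chr1"][400:700]}
    assert not single_copy_check(probe, dup)
    # a reverse-complement occurrence elsewhere counts as a second copy
    rc_genome = {"chr1": genome["chr1"] + revcomp(probe)}
    assert not single_copy_check(probe, rc_genome)


def test_hairpin_dimer_screen():
    assert not hairpin_dimer_screen("A" * 100)  # homopolymer
    stem = "ACGTTGCAGGTC"
    seq = "ATCGAT" + stem + "CCATAG" + revcomp(stem) + "GTACCA" * 12
    assert not hairpin_dimer_screen(seq[:100])
    rng = np.random.default_rng(11)
    ok = sum(
        hairpin_dimer_screen("".join(rng.choice(list("ACGT"), 100)))
        for _ in range(50)
    )
    assert ok >= 48  # random 100-mers pass with high probability


# ---------------------------------------------------------------- probe sharing


def test_probe_sharing_worked_example():
    """Sites 54 bp apart share one probe; 101 bp apart do not."""
    assert group_probe_sites([34235967, 34236021]) == [[34235967, 34236021]]
    assert group_probe_sites([1000, 1101]) == [[1000], [1101]]
    assert group_probe_sites([1000, 1100]) == [[1000, 1100]]  # inclusive <= 100
    # greedy: distance measured to the group's first site
    assert group_probe_sites([1000, 1090, 1180]) == [[1000, 1090], [1180]]


def test_assign_probes_on_synthetic_genome():
    genome = simulate_reference({"chr1": 5000}, seed=5)
    sites = [cand("chr1", 1000, "RESEQ_POLY", ref=genome["chr1"][999]),
             cand("chr1", 1054, "RESEQ_POLY", ref=genome["chr1"][1053]),
             cand("chr1", 3000, "RESEQ_POLY", ref=genome["chr1"][2999])]
    probes, kept = assign_probes(sites, genome)
    assert len(probes) == 2 and len(kept) == 3
    shared = next(p for p in probes if len(p.covered_sites) == 2)
    assert shared.covered_sites == [1000, 1054]
    assert shared.end - shared.start + 1 == 100 == len(shared.sequence)
    assert shared.start <= 1000 and shared.end >= 1054
    lone = next(p for p in probes if len(p.covered_sites) == 1)
    assert lone.start <= 3000 <= lone.end
    assert abs((lone.start + lone.end) / 2 - 3000) <= 1  # centred on the site
    for p in probes:
        assert 0.20 <= p.gc <= 0.80
        assert p.sequence == genome["chr1"][p.start - 1 : p.end]


def test_assign_probes_undesignable_flagged():
    # low-complexity genome: probe fails the homopolymer screen
    genome = {"chr1": "A" * 2000}
    report = DesignReport()
    probes, kept = assign_probes(
        [CandidateSite("chr1", 1000, "A", "G", "RESEQ_POLY")], genome, report=report
    )
    assert probes == [] and kept == []
    assert report.undesignable and report.undesignable[0][:2] == ("chr1", 1000)


# -------------------------------------------------------------- capture intervals


def test_capture_interval_worked_example():
    iv = capture_interval("chr1", 316747, 150, 150)
    assert (iv.start, iv.end) == (316597, 316897)


def test_capture_interval_bounds():
    iv = capture_interval("chr1", 1000, 100, 100)
    assert (iv.start, iv.end) == (900, 1100)
    with pytest.raises(ValueError, match="flank"):
        capture_interval("chr1", 1000, 99, 150)
    with pytest.raises(ValueError, match="flank"):
        capture_interval("chr1", 1000, 150, 201)


def test_merged_interval_worked_example():
    a = capture_interval("chr19", 19216460, 140, 150)
    b = capture_interval("chr19", 19216471, 150, 160)
    merged = merge_intervals([a, b])
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (19216320, 19216631)
    assert merged[0].sites == [19216460, 19216471]


def test_merge_intervals_distant_sites_untouched():
    a = capture_interval("chr1", 1000)
    b = capture_interval("chr1", 11_000)
    merged = merge_intervals([a, b])
    assert len(merged) == 2
    assert merge_intervals(merged) == merged  # idempotent


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    positions=hst.lists(hst.integers(1000, 100_000), min_size=1, max_size=25,
                        unique=True),
    flank=hst.integers(100, 200),
)
def test_merge_intervals_union_oracle(positions, flank):
    """Merged intervals equal the brute-force union of per-site windows, every
    site lands in exactly one interval, and merging is idempotent."""
    ivs = [capture_interval("chr1", p, flank, flank) for p in positions]
    merged = merge_intervals(ivs)
    # brute-force union on an integer grid (padded by 1 for adjacency)
    covered = set()
    for p in positions:
        covered.update(range(p - flank, p + flank + 1))
    runs = []
    for x in sorted(covered):
        if runs and x <= runs[-1][1] + 1:
            runs[-1][1] = x
        else:
            runs.append([x, x])
    assert [(iv.start, iv.end) for iv in merged] == [tuple(r) for r in runs]
    for p in positions:
        assert sum(iv.start <= p <= iv.end for iv in merged) == 1
    assert merge_intervals(merged) == merged
    # clustered sites collapse to one interval
    if max(positions) - min(positions) <= flank:
        assert len(merged) == 1


def test_pipeline_count_inequality(sim_study):
    """|merged intervals| <= |probes| <= |panel sites| on simulated data."""
    _, genome, matrix, _ = sim_study
    sites = [CandidateSite(c, p, r, a, "RESEQ_POLY", maf=0.2)
             for c, p, r, a in matrix.sites[:400]]
    probes, kept = assign_probes(sites, genome)
    intervals = design_intervals(kept)
    assert len(intervals) <= len(probes) <= len(kept) <= len(sites)
    for iv in intervals:
        for s in iv.sites:
            assert iv.start <= s <= iv.end
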