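"""End-to-end panel design and validation on one genotype matrix.

This wires the stages together in the order a panel study runs them:
annotation hard filter -> per-site screens (high-polymorphism, Fst) ->
candidate merging across sources -> evenly spaced panel selection -> probe
design -> capture intervals -> validation metrics -> clustering QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import GenotypeMatrix, PopulationSpec
from . import panel as pnl
from . import sitestats as st
from . import validation as val
from . import clustering as cl
from .simulate import SimConfig, make_duplicate, simulate_reference, \
    simulate_annotations, simulate_two_pop_genotypes


@dataclass
class PipelineResult:
    """Counts and reports from one full design-and-validate run."""

    n_input_sites: int
    n_hard_filter_pass: int
    n_candidates: int
    panel_sites: list = field(default_factory=list)
    probes: list = field(default_factory=list)
    intervals: list = field(default_factory=list)
    design_report: pnl.DesignReport | None = None
    validation: dict = field(default_factory=dict)
    repeatability: object = None
    newick: str | None = None

    def summary(self) -> dict:
        out = {
            "n_input_sites": self.n_input_sites,
            "n_hard_filter_pass": self.n_hard_filter_pass,
            "n_candidates": self.n_candidates,
            "n_panel_sites": len(self.panel_sites),
            "n_probes": len(self.probes),
            "n_intervals": len(self.intervals),
        }
        if self.design_report is not None:
            out["counts_per_source"] = self.design_report.counts_per_source
            out["n_undesignable"] = len(self.design_report.undesignable)
        if self.validation:
            out["validation"] = {
                k: v for k, v in self.validation.items() if k != "samples"
            }
        return out


def design_panel(
    matrix: GenotypeMatrix,
    pops: PopulationSpec,
    genome: dict[str, str],
    annotations: list[dict[str, float]] | None = None,
    external_sources: dict[str, list[pnl.CandidateSite]] | None = None,
    target_size: int | None = None,
    window_bp: int = 200_000,
    flank_up: int = 150,
    flank_down: int = 150,
) -> PipelineResult:
    """Screen sites, merge candidate sources and design probes/intervals."""
    report = pnl.DesignReport()

    keep = np.ones(matrix.n_sites, dtype=bool)
    if annotations is not None:
        keep = np.array([st.hard_filter(ann)[0] for ann in annotations])
    filtered = matrix.subset_sites(keep)

    stats = st.site_stats_table(filtered, pops=pops)
    reseq_poly: list[pnl.CandidateSite] = []
    reseq_fst: list[pnl.CandidateSite] = []
    for (chrom, pos, ref, alt), row in zip(filtered.sites, stats.itertuples(index=False)):
        if row.pass_fst:
            reseq_fst.append(
                pnl.CandidateSite(chrom, pos, ref, alt, "RESEQ_FST", row.maf, row.fst)
            )
        elif row.pass_high_poly:
            reseq_poly.append(
                pnl.CandidateSite(chrom, pos, ref, alt, "RESEQ_POLY", row.maf, row.fst)
            )
    lists = [reseq_fst, reseq_poly]
    if external_sources:
        lists.extend(external_sources.values())
    candidates = pnl.merge_candidates(lists, report)

    if target_size is None:
        target_size = len(candidates)
    selected = pnl.select_spaced_panel(candidates, target_size, window_bp)
    probes, designable = pnl.assign_probes(selected, genome, report=report)
    intervals = pnl.design_intervals(designable, flank_up, flank_down)
    return PipelineResult(
        n_input_sites=matrix.n_sites,
        n_hard_filter_pass=filtered.n_sites,
        n_candidates=len(candidates),
        panel_sites=designable,
        probes=probes,
        intervals=intervals,
        design_report=report,
    )


def run_synthetic_end_to_end(
    cfg: SimConfig,
    target_size: int | None = None,
    n_duplicates: int = 4,
    with_tree: bool = True,
) -> PipelineResult:
    """Simulate a study and run design plus the full validation suite on it."""
    rng = np.random.default_rng(cfg.seed)
    genome = simulate_reference(cfg.chrom_lengths, seed=int(rng.integers(2**31)))
    matrix, pops = simulate_two_pop_genotypes(cfg, genome=genome)
    annotations = simulate_annotations(matrix.n_sites, int(rng.integers(2**31)))
    result = design_panel(
        matrix, pops, genome, annotations=annotations, target_size=target_size
    )

    # validate on the designed panel: restrict the matrix to panel sites
    panel_keys = {(s.chrom, s.pos) for s in result.panel_sites}
    keep = np.array([(c, p) in panel_keys for c, p, _, _ in matrix.sites])
    panel_matrix = matrix.subset_sites(keep)
    result.validation = val.validation_report(panel_matrix)

    dup_ids = list(panel_matrix.sample_ids[: n_duplicates])
    pairs = {}
    for sid in dup_ids:
        i = panel_matrix.sample_index(sid)
        orig = panel_matrix.codes[i, :]
        dup = make_duplicate(orig, cfg.dup_error_rate, int(rng.integers(2**31)))
        pairs[f"{sid}&{sid}-re"] = (orig, dup)
    result.repeatability = val.repeatability_report(pairs)

    if with_tree:
        qc = cl.cluster_qc_filter(panel_matrix)
        if qc.n_sites > 0 and qc.n_samples >= 3:
            result.newick = cl.nj_tree(cl.ibs_distance(qc))
    return result
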