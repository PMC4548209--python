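"""End-to-end orchestration of the DamID tiling-array analysis.

``run_all`` ties the stages together on a study directory (as produced
by :func:`damidtile.simulate.write_study`, or assembled by hand from
real probe-level data): quantile normalization, peak calling with
permutation FDR per factor, WT/mutant A/B/C decomposition, motif
presence fractions, regulatory-domain gene assignment with TSS-distance
profiles, a gene-set Fisher test between the factors' targets, and
(when an expression matrix is supplied) tissue-expression profiles.

Every output carries a provenance header with version, seed and
parameters; one global seed deterministically derives all stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arrays import (PeakCallParams, SampleDesign, estimate_fdr,
                     load_intensity_table)
from .expression import (collapse_replicates, random_background_profile,
                         relative_profile)
from .genes import assign_peaks, regulatory_domains, tss_distance_profile
from .genome import Interval, read_fasta
from .motifs import MotifCatalog, motif_presence_fraction, peak_motif_counts, word_enrichment
from .peaksets import decompose_sets, gene_set_fisher, merge_intervals, random_peak_null

logger = logging.getLogger("damidtile")

__all__ = ["RunConfig", "run_all", "stage_seed", "probe_territory"]

_STAGES = ("peaks", "null", "motifs", "expression")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) deterministically from one seed."""
    ss = np.random.SeedSequence([global_seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Paths and parameters of one end-to-end run."""

    study_dir: str
    out_dir: str
    seed: int = 0
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    factors: tuple[str, str] = ("WT", "MUT")
    min_overlap_bp: int = 1
    n_null_iter: int = 200
    n_enrichment_draws: int = 200
    motif_catalog_path: str | None = None
    expression_path: str | None = None       # genes x tissues NME TSV
    basal_up: int = 6500
    basal_down: int = 2500
    ext_max: int = 100_000
    bg_n_genes: int = 1000
    bg_n_draws: int = 100


def probe_territory(probes: pd.DataFrame, gap: int = 300) -> list[Interval]:
    """Merged probe-covered blocks — the array's effective territory.

    Probes within ``gap`` bp (default: the peak-calling max gap) are
    merged, so a tiling of non-touching probes yields contiguous blocks.
    """
    ivs = [Interval(str(r.chrom), int(r.start), int(r.end))
           for r in probes.itertuples(index=False)]
    return merge_intervals(ivs, gap=gap)


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "damidtile",
        "version": __version__,
        "seed": config.seed,
        "peak_params": asdict(config.peak_params),
        "parameters": {k: v for k, v in asdict(config).items()
                       if k != "peak_params"},
    }


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline on a study directory; returns the summary.

    Any stage failure aborts with the stage name in the error message;
    outputs written before the failure are flagged in the run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = Path(config.study_dir)
    summary: dict = {"provenance": _provenance(config), "stages_completed": []}
    log_path = out / "run_log.json"

    def checkpoint(stage: str) -> None:
        summary["stages_completed"].append(stage)
        with open(log_path, "w") as fh:
            json.dump(summary, fh, indent=2, default=str)

    def fail(stage: str, err: Exception) -> None:
        summary["failed_stage"] = stage
        summary["error"] = str(err)
        summary["partial_outputs"] = True
        with open(log_path, "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # ---- load inputs -----------------------------------------------------
    try:
        genome = read_fasta(study / "genome.fasta")
        genes = pd.read_csv(study / "genes.tsv", sep="\t")
        probes = pd.read_csv(study / "probes.bed", sep="\t", header=None,
                             names=["chrom", "start", "end", "probe_id"])
        territory = probe_territory(probes)
        catalog = (MotifCatalog.from_tsv(config.motif_catalog_path)
                   if config.motif_catalog_path else MotifCatalog.default())
    except Exception as err:
        fail("load_inputs", err)
    checkpoint("load_inputs")

    # ---- per-factor peak calling with FDR --------------------------------
    peak_sets = {}
    try:
        params = replace(config.peak_params,
                         seed=stage_seed(config.seed, "peaks"))
        summary["peaks"] = {}
        for factor in config.factors:
            table = load_intensity_table(study / f"intensities_{factor}.tsv")
            design = SampleDesign.from_tsv(study / f"design_{factor}.tsv")
            res = estimate_fdr(table, design, params, name=factor)
            peak_sets[factor] = res.peaks
            res.peaks.to_bed(out / f"peaks_{factor}.bed")
            res.curve.to_csv(out / f"fdr_curve_{factor}.tsv",
                             sep="\t", index=False)
            summary["peaks"][factor] = {
                "n_peaks": len(res.peaks),
                "fdr_at_cutoff": res.fdr_at_cutoff,
                "n_permutations": res.n_permutations_used,
            }
            logger.info("factor %s: %d peaks, FDR %.3g", factor,
                        len(res.peaks), res.fdr_at_cutoff)
    except Exception as err:
        fail("peak_calling", err)
    checkpoint("peak_calling")

    # ---- A/B/C decomposition + randomized overlap null --------------------
    wt, mut = config.factors
    try:
        decomp = decompose_sets(peak_sets[wt], peak_sets[mut],
                                min_bp=config.min_overlap_bp)
        decomp.to_bed(out / "decomposition.bed")
        summary["set_decomposition"] = decomp.summary()
        if len(decomp.C) and len(peak_sets[wt]):
            null = random_peak_null(decomp.C, peak_sets[wt], territory,
                                    n_iter=config.n_null_iter,
                                    seed=stage_seed(config.seed, "null"),
                                    min_bp=config.min_overlap_bp)
            summary["c_set_random_null"] = {
                "observed_fraction": null.observed_fraction,
                "null_mean_fraction": float(null.null_fractions.mean()),
                "empirical_p": null.p_value,
                "n_iter": null.n_iter,
            }
    except Exception as err:
        fail("set_decomposition", err)
    checkpoint("set_decomposition")

    # ---- motif counting ----------------------------------------------------
    try:
        summary["motifs"] = {}
        for factor in config.factors:
            if not len(peak_sets[factor]):
                continue
            counts = peak_motif_counts(peak_sets[factor], genome, catalog)
            counts.to_csv(out / f"motif_counts_{factor}.tsv", sep="\t")
            summary["motifs"][factor] = {
                m: motif_presence_fraction(counts, m)["fraction_present"]
                for m in catalog.names
            }
        if len(peak_sets[wt]):
            enr = word_enrichment(peak_sets[wt], territory, genome,
                                  catalog["NKE"],
                                  n_draws=config.n_enrichment_draws,
                                  seed=stage_seed(config.seed, "motifs"))
            summary["nke_enrichment_wt"] = {
                k: v for k, v in enr.items() if k != "motif"}
    except Exception as err:
        fail("motif_analysis", err)
    checkpoint("motif_analysis")

    # ---- gene assignment + TSS profiles -----------------------------------
    try:
        chrom_lengths = {c: genome.chrom_length(c) for c in genome.chrom_names}
        domains = regulatory_domains(genes, config.basal_up,
                                     config.basal_down, config.ext_max,
                                     chrom_lengths)
        target_sets = {}
        summary["gene_assignment"] = {}
        for factor in config.factors:
            res = assign_peaks(peak_sets[factor], domains)
            res["assignments"].to_csv(out / f"assignments_{factor}.tsv",
                                      sep="\t", index=False)
            target_sets[factor] = set(res["target_genes"])
            prof = tss_distance_profile(peak_sets[factor], genes)
            prof.histogram.to_csv(out / f"tss_profile_{factor}.tsv",
                                  sep="\t", index=False)
            summary["gene_assignment"][factor] = {
                "n_target_genes": len(target_sets[factor]),
                "n_unassigned_peaks": len(res["unassigned_peaks"]),
                "median_abs_tss_distance_bp": (
                    float(np.median(np.abs(prof.distances)))
                    if prof.distances.size else None),
            }
        # universe: genes whose basal domain overlaps >= 1 probe
        universe = set()
        probe_blocks = territory
        for d in domains:
            for b in probe_blocks:
                if b.chrom == d.chrom and \
                        min(b.end, d.basal.end) - max(b.start, d.basal.start) >= 1:
                    universe.add(d.gene_id)
                    break
        if target_sets[wt] and target_sets[mut]:
            fisher = gene_set_fisher(target_sets[wt] & universe,
                                     target_sets[mut] & universe, universe)
            summary["target_gene_fisher"] = fisher
    except Exception as err:
        fail("gene_assignment", err)
    checkpoint("gene_assignment")

    # ---- tissue-expression profiles (optional) -----------------------------
    if config.expression_path:
        try:
            expr = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            bg = random_background_profile(
                expr, list(expr.index), n_genes=min(config.bg_n_genes,
                                                    len(expr.index)),
                n_draws=config.bg_n_draws,
                seed=stage_seed(config.seed, "expression"))
            prof = relative_profile(sorted(target_sets[wt] & set(expr.index)),
                                    expr, bg)
            ranked = prof["ratio"]
            ranked.rename("ratio").to_csv(out / "expression_profile_wt.tsv",
                                          sep="\t")
            summary["expression_profile"] = {
                "top_tissue": str(ranked.index[0]),
                "top_ratio": float(ranked.iloc[0]),
                "direction": prof["direction"],
            }
        except Exception as err:
            fail("expression_profile", err)
        checkpoint("expression_profile")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(log_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
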