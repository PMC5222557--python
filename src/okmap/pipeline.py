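"""End-to-end pipeline: simulate (optional) -> bin -> smooth/normalize ->
call -> annotate -> downstream association stages, with provenance sidecars.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, chromatin, io, origins as origins_mod, simulate, timecourse
from .config import RunConfig
from .core import StrandedTrack

logger = logging.getLogger(__name__)


def _sidecar(path: Path, config: RunConfig, stage: str, extra: dict | None = None
             ) -> None:
    meta = {
        "tool": "okmap",
        "version": __version__,
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.hash(),
    }
    if extra:
        meta.update(extra)
    path.write_text(json.dumps(meta, indent=2, default=str) + "\n")


def call_origins_from_track(track: StrandedTrack, config: RunConfig
                            ) -> tuple[pd.DataFrame, StrandedTrack]:
    """Smooth, normalize, scan and annotate: the core origin-calling chain.

    Returns the annotated origin table and the smoothed+normalized track.
    """
    smoothed = origins_mod.smooth_track(track, config.smooth_window)
    normalized = origins_mod.normalize_track(smoothed)
    metric = origins_mod.origin_transition_metric(normalized, config.oem_window)
    calls = origins_mod.call_origins(
        metric, track.bin_size, config.threshold, config.min_separation
    )
    logger.info("called %d origins", len(calls))
    if len(calls):
        calls = origins_mod.annotate_efficiency(
            calls, normalized, config.efficiency_radius
        )
        step = origins_mod.annotate_efficiency(
            calls, normalized, config.efficiency_radius, mode="rfd_step"
        )
        calls["firing_rate_estimate"] = step["efficiency"]
        calls = origins_mod.annotate_transition_zone(
            calls, normalized, config.tz_radius
        )
    return calls, normalized


def run_pipeline(config: RunConfig, outdir, fragments_bed=None,
                 chrom_sizes_path=None, peaks_path=None,
                 timecourse_path=None, stages: tuple[str, ...] = ("simulate", "call")
                 ) -> dict:
    """Execute the requested stages, writing artifacts plus JSON sidecars.

    With ``"simulate"`` in ``stages`` the replication program, fragments,
    peaks and time course are generated from the config's model parameters;
    otherwise fragment/peak/time-course inputs must be provided.  Outputs are
    deterministic for a fixed config (including its seed).
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    model = None
    if "simulate" in stages:
        model = simulate.simulate_genome_model(
            n_chrom=config.n_chrom, chrom_length=config.chrom_length,
            n_origins=config.n_origins,
            efficiency_distribution=(config.efficiency_family,
                                     config.efficiency_params),
            seed=config.seed, fork_speed=config.fork_speed,
        )
        frags = simulate.simulate_fragments(
            model, config.n_cells, config.fragments_per_cell,
            seed=config.seed + 1,
        )
        io.write_genome_model(model, out / "truth_origins.tsv",
                              out / "genome.chrom.sizes")
        io.write_fragments_bed(frags, out / "fragments.bed")
        chrom_sizes = dict(model.chrom_sizes)
        _sidecar(out / "simulate.meta.json", config, "simulate",
                 {"n_fragments": int(len(frags)),
                  "n_discarded": frags.attrs.get("n_discarded", 0)})
        artifacts["fragments"] = out / "fragments.bed"
        artifacts["truth"] = out / "truth_origins.tsv"
    else:
        if fragments_bed is None or chrom_sizes_path is None:
            raise ValueError(
                "stage 'call' without 'simulate' needs fragments_bed and "
                "chrom_sizes_path"
            )
        frags = io.read_fragments_bed(fragments_bed)
        chrom_sizes = io.read_chrom_sizes(chrom_sizes_path)

    if "call" in stages:
        track = io.bin_fragments(frags, chrom_sizes, config.bin_size)
        calls, normalized = call_origins_from_track(track, config)
        io.write_origins_bed(calls, out / "origins.bed")
        stats = origins_mod.spacing_stats(calls)
        pd.DataFrame([
            {"metric": "n_origins", "value": stats["n_origins"]},
            {"metric": "median_spacing_bp", "value": stats["median_spacing"]},
            {"metric": "fraction_within_100kb",
             "value": stats["fraction_within_100kb"]},
        ]).to_csv(out / "spacing_stats.tsv", sep="\t", index=False)
        io.write_stranded_bedgraph(track, out / "watson.bedgraph",
                                   out / "crick.bedgraph")
        extra = {"n_origins": int(len(calls))}
        if model is not None:
            recovery = simulate.score_recovery(calls, model)
            extra["recovery"] = {
                k: v for k, v in recovery.items() if k != "matched"
            }
        _sidecar(out / "call.meta.json", config, "call", extra)
        artifacts["origins"] = out / "origins.bed"
        artifacts["calls"] = calls

    if "assoc" in stages:
        peaks = io.read_peaks(peaks_path) if peaks_path else None
        if peaks is None and model is not None:
            peaks = simulate.simulate_chip_peaks(model, seed=config.seed + 2)
        if peaks is None:
            raise ValueError("stage 'assoc' needs peaks_path (or simulate)")
        kept = chromatin.filter_peaks(peaks, config.min_fold)
        table = chromatin.peak_association_pvalues(
            kept, artifacts["calls"], chrom_sizes, config.origin_halfwidth
        )
        kept.join(table).to_csv(out / "peak_associations.tsv", sep="\t",
                                index=False)
        _sidecar(out / "assoc.meta.json", config, "assoc",
                 {"n_peaks_kept": int(len(kept)),
                  "n_peaks_total": int(len(peaks))})
        artifacts["peak_associations"] = out / "peak_associations.tsv"

    if "timecourse" in stages:
        tc = io.read_timecourse(timecourse_path) if timecourse_path else None
        if tc is None and model is not None:
            tc = simulate.simulate_timecourse(model, seed=config.seed + 3)
        if tc is None:
            raise ValueError("stage 'timecourse' needs timecourse_path (or simulate)")
        labeled = timecourse.classify_maternal(
            timecourse.normalize_timecourse(tc),
            k_clusters=config.k_clusters, seed=config.seed,
        )
        hm = timecourse.coupling_heatmap(
            labeled, artifacts["calls"], top_n=config.top_n,
            flank=config.flank, bin_size=config.gene_bin,
        )
        stat = timecourse.coupling_statistic(hm)
        pd.DataFrame(hm["matrix"],
                     index=[f"t{t}" for t in hm["timepoints"]],
                     columns=[str(int(c)) for c in hm["bin_centers"]]
                     ).to_csv(out / "coupling_heatmap.tsv", sep="\t")
        pd.DataFrame({"timepoint": hm["timepoints"],
                      "log2_proximal_distal": stat}
                     ).to_csv(out / "coupling_statistic.tsv", sep="\t",
                              index=False)
        labeled[["gene_id", "label"]].to_csv(out / "gene_labels.tsv",
                                             sep="\t", index=False)
        _sidecar(out / "timecourse.meta.json", config, "timecourse",
                 {"n_genes": int(len(labeled))})
        artifacts["coupling_statistic"] = out / "coupling_statistic.tsv"

    return artifacts
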