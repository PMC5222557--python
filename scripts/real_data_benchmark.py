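"""Genome-scale benchmark runner for real OK-seq inputs.

The embryo-scale reference numbers (>2000 origins, 40 kb median spacing,
96% of origins within 100 kb of another, ~50% median efficiency, 75% of
>30%-efficiency origins within 1 kb of an enhancer mark) require the real
Okazaki-fragment sequencing data (GEO accession GSE90939, WS220 build) and
the modENCODE histone-mark peak calls.  This script reproduces those
summaries from locally supplied files; it downloads nothing.

Usage:
    python scripts/real_data_benchmark.py \
        --fragments okseq_fragments.bed --chrom-sizes ws220.chrom.sizes \
        [--peaks h3k27ac.narrowPeak] [--out benchmark.json]

The fragment BED must be stranded (column 6 = +/-); peak files are ENCODE
narrowPeak with fold enrichment in the signalValue column.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from okmap import chromatin, io, origins  # noqa: E402
from okmap.config import RunConfig  # noqa: E402
from okmap.pipeline import call_origins_from_track  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fragments", required=True)
    ap.add_argument("--chrom-sizes", required=True)
    ap.add_argument("--peaks", default=None)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    cfg = RunConfig()
    sizes = io.read_chrom_sizes(args.chrom_sizes)
    frags = io.read_fragments_bed(args.fragments)
    track = io.bin_fragments(frags, sizes, cfg.bin_size)
    calls, _ = call_origins_from_track(track, cfg)
    stats = origins.spacing_stats(calls)

    summary = {
        "n_origins": int(stats["n_origins"]),
        "median_spacing_kb": stats["median_spacing"] / 1000.0,
        "percent_within_100kb": 100.0 * stats["fraction_within_100kb"],
        "median_efficiency": float(calls["efficiency"].median()),
    }
    if args.peaks:
        peaks = chromatin.filter_peaks(io.read_peaks(args.peaks), cfg.min_fold)
        grid = chromatin.association_grid(peaks, calls,
                                          efficiency_cutoff=0.30,
                                          summary_distance=1000.0)
        summary["percent_efficient_origins_with_peak_within_1kb"] = (
            100.0 * grid["fraction_efficient_origins_with_peak"]
        )
    text = json.dumps(summary, indent=2)
    print(text)
    if args.out:
        Path(args.out).write_text(text + "\n")


if __name__ == "__main__":
    main()
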