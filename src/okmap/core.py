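"""Shared containers and validators for the OK-seq pipeline.

Record-like collections (Okazaki fragments, ChIP peaks, genes, origin calls)
are plain :class:`pandas.DataFrame` objects with fixed column schemas,
validated by the ``validate_*`` functions below.  Binned stranded coverage
lives in :class:`StrandedTrack`.

Coordinate convention: all intervals are 0-based half-open, the BED standard.
The Watson strand is the reference forward strand (``+``), Crick the reverse
(``-``).  Watson-strand Okazaki fragments derive from leftward-moving
replication forks, Crick-strand fragments from rightward-moving forks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WATSON = "+"
CRICK = "-"

#: Half-width (bp) of the fixed window an origin call occupies in BED output:
#: each origin is represented as a 5 kb block centred on its midpoint.
ORIGIN_HALFWIDTH = 2500

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand"]
PEAK_COLUMNS = ["chrom", "start", "end", "name", "fold_enrichment", "summit"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
ORIGIN_COLUMNS = [
    "chrom",
    "midpoint",
    "score",
    "efficiency",
    "transition_zone",
    "watson_max_pos",
    "crick_max_pos",
    "flagged",
]


class FormatError(ValueError):
    """Raised when an input file or in-memory table violates its schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing columns: {missing}")


def validate_fragments(frags: pd.DataFrame) -> pd.DataFrame:
    """Validate an Okazaki fragment table (chrom, start, end, strand)."""
    _require_columns(frags, FRAGMENT_COLUMNS, "fragment")
    if len(frags):
        bad = frags["start"] >= frags["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"fragment record {i}: start >= end "
                f"({frags['start'].iat[i]} >= {frags['end'].iat[i]})"
            )
        strands = set(frags["strand"].unique())
        if not strands <= {WATSON, CRICK}:
            raise FormatError(
                f"fragment strand must be '+' or '-' (Okazaki fragments are "
                f"strand-essential); found {sorted(strands - {WATSON, CRICK})}"
            )
    return frags


def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    _require_columns(peaks, ["chrom", "start", "end", "fold_enrichment"], "peak")
    if len(peaks):
        if (peaks["start"] >= peaks["end"]).any():
            raise FormatError("peak with start >= end")
        if (peaks["fold_enrichment"] < 0).any():
            raise FormatError("negative fold enrichment")
    return peaks


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    _require_columns(genes, GENE_COLUMNS, "gene")
    if len(genes):
        if (genes["start"] >= genes["end"]).any():
            raise FormatError("gene with start >= end")
        strands = set(genes["strand"].unique())
        if not strands <= {WATSON, CRICK}:
            raise FormatError(f"gene strand outside {{+,-}}: {sorted(strands)}")
    return genes


def validate_origins(origins: pd.DataFrame) -> pd.DataFrame:
    _require_columns(origins, ["chrom", "midpoint"], "origin")
    if "efficiency" in origins.columns and len(origins):
        eff = origins["efficiency"].dropna()
        if ((eff < 0) | (eff > 1)).any():
            raise FormatError("origin efficiency outside [0, 1]")
    return origins


def empty_origins() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "midpoint": pd.Series(dtype=int),
            "score": pd.Series(dtype=float),
            "efficiency": pd.Series(dtype=float),
            "transition_zone": pd.Series(dtype=float),
            "watson_max_pos": pd.Series(dtype=float),
            "crick_max_pos": pd.Series(dtype=float),
            "flagged": pd.Series(dtype=bool),
        }
    )


@dataclass
class StrandedTrack:
    """Binned, strand-resolved Okazaki fragment coverage.

    Parameters
    ----------
    bin_size
        Bin width in bp.
    chrom_sizes
        Ordered mapping chromosome name -> length in bp.
    watson, crick
        Per-chromosome count (or smoothed count) arrays, one value per bin;
        array length is ``ceil(length / bin_size)``.
    frac_watson, frac_crick
        Optional per-bin normalized strand fractions, ``f_W + f_C = 1`` on
        unmasked bins; NaN where masked.

    Bins with zero total coverage are *masked*: they carry no strand
    information and are excluded from smoothing and normalization rather
    than being treated as ``f_W = 0``.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    watson: dict[str, np.ndarray] = field(default_factory=dict)
    crick: dict[str, np.ndarray] = field(default_factory=dict)
    frac_watson: dict[str, np.ndarray] = field(default_factory=dict)
    frac_crick: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        for name, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            nb = self.n_bins(name)
            for d in (self.watson, self.crick):
                if name not in d:
                    d[name] = np.zeros(nb)
                elif len(d[name]) != nb:
                    raise ValueError(
                        f"{name}: expected {nb} bins, got {len(d[name])}"
                    )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def mask(self, chrom: str) -> np.ndarray:
        """Boolean array, True where a bin has zero total coverage."""
        return (self.watson[chrom] + self.crick[chrom]) <= 0

    def bin_centers(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom)) * self.bin_size + self.bin_size // 2

    def total_fragments(self) -> float:
        return float(
            sum(self.watson[c].sum() + self.crick[c].sum() for c in self.chrom_sizes)
        )

    def copy(self) -> "StrandedTrack":
        return StrandedTrack(
            bin_size=self.bin_size,
            chrom_sizes=dict(self.chrom_sizes),
            watson={c: v.copy() for c, v in self.watson.items()},
            crick={c: v.copy() for c, v in self.crick.items()},
            frac_watson={c: v.copy() for c, v in self.frac_watson.items()},
            frac_crick={c: v.copy() for c, v in self.frac_crick.items()},
        )
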