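"""Readers, writers and binning for the genomic text formats the pipeline touches.

Supported dialects: BED6 (Okazaki fragments, genes), ENCODE narrowPeak
(ChIP peaks; a BED5+fold layout is also accepted), bedGraph (binned signal,
one record per run of constant value), two-column chrom.sizes, and the
gene x time-point expression TSV.  All reads are gzip-transparent (by file
extension, via pandas).  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    CRICK,
    ORIGIN_HALFWIDTH,
    WATSON,
    FormatError,
    StrandedTrack,
    validate_fragments,
    validate_genes,
    validate_origins,
    validate_peaks,
)
from .simulate import FragmentLengthModel, GenomeModel

_BED6 = ["chrom", "start", "end", "name", "score", "strand"]
_NARROWPEAK = _BED6 + ["signalValue", "pValue", "qValue", "peak"]


def _read_table(path, names, min_cols, what):
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    if df.shape[1] < min_cols:
        raise FormatError(
            f"{path}: {what} needs >= {min_cols} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    return df


def _to_int(df, col, path):
    try:
        return df[col].astype(int)
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise FormatError(
            f"{path}: line {bad + 1}: field {col!r} is not an integer "
            f"({df[col].iat[bad]!r})"
        ) from None


def _check_intervals(df, path):
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        i = bad[0]
        raise FormatError(
            f"{path}: line {i + 1}: start >= end "
            f"({df['start'].iat[i]} >= {df['end'].iat[i]})"
        )


# ---------------------------------------------------------------------------
# chrom.sizes

def read_chrom_sizes(path) -> dict[str, int]:
    df = _read_table(path, ["chrom", "length"], 2, "chrom.sizes")
    sizes = {}
    for i, row in df.iterrows():
        try:
            sizes[row["chrom"]] = int(row["length"])
        except ValueError:
            raise FormatError(
                f"{path}: line {i + 1}: chromosome length not an integer"
            ) from None
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    pd.DataFrame(sizes.items()).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# fragments (BED6)

def read_fragments_bed(path) -> pd.DataFrame:
    """Read stranded Okazaki fragments from BED6.

    Strand is essential for OK-seq; records with strand ``.`` are rejected.
    """
    df = _read_table(path, _BED6, 6, "fragment BED6")
    df["start"] = _to_int(df, "start", path)
    df["end"] = _to_int(df, "end", path)
    _check_intervals(df, path)
    bad = df.index[~df["strand"].isin([WATSON, CRICK])]
    if len(bad):
        i = bad[0]
        raise FormatError(
            f"{path}: line {i + 1}: fragment strand must be '+' or '-', "
            f"got {df['strand'].iat[i]!r}"
        )
    return validate_fragments(df[["chrom", "start", "end", "strand"]].copy())


def write_fragments_bed(frags: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": frags["chrom"],
            "start": frags["start"],
            "end": frags["end"],
            "name": [f"frag_{i}" for i in range(len(frags))],
            "score": 0,
            "strand": frags["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# ChIP peaks (narrowPeak / BED5+fold)

def read_peaks(path) -> pd.DataFrame:
    """Read ChIP peaks from narrowPeak (fold enrichment = signalValue column)
    or a 5-column BED with fold enrichment in column 5.

    No fold-enrichment filtering happens here; see
    :func:`okmap.chromatin.filter_peaks`.
    """
    raw = _read_table(path, _NARROWPEAK, 5, "peak file")
    raw["start"] = _to_int(raw, "start", path)
    raw["end"] = _to_int(raw, "end", path)
    _check_intervals(raw, path)
    if "signalValue" in raw.columns:  # narrowPeak
        fold = pd.to_numeric(raw["signalValue"], errors="coerce")
        summit = (
            pd.to_numeric(raw["peak"], errors="coerce")
            if "peak" in raw.columns
            else pd.Series(-1, index=raw.index)
        )
    else:  # BED5+fold: fold enrichment sits in the score slot
        fold = pd.to_numeric(raw["score"], errors="coerce")
        summit = pd.Series(-1.0, index=raw.index)
    if fold.isna().any():
        i = raw.index[fold.isna()][0]
        raise FormatError(f"{path}: line {i + 1}: fold enrichment not numeric")
    peaks = pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "start": raw["start"],
            "end": raw["end"],
            "name": raw.get("name", pd.Series([f"peak_{i}" for i in raw.index])),
            "fold_enrichment": fold,
            "summit": summit.fillna(-1).astype(int),
        }
    )
    return validate_peaks(peaks)


def write_peaks_narrowpeak(peaks: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "name": peaks.get("name", [f"peak_{i}" for i in range(len(peaks))]),
            "score": np.minimum(
                np.rint(100 * peaks["fold_enrichment"]), 1000
            ).astype(int),
            "strand": ".",
            "signalValue": peaks["fold_enrichment"],
            "pValue": -1,
            "qValue": -1,
            "peak": peaks.get("summit", pd.Series(-1, index=peaks.index)),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# genes (BED6, name = gene id)

def read_genes(path) -> pd.DataFrame:
    df = _read_table(path, _BED6, 6, "gene BED6")
    df["start"] = _to_int(df, "start", path)
    df["end"] = _to_int(df, "end", path)
    _check_intervals(df, path)
    bad = df.index[~df["strand"].isin([WATSON, CRICK])]
    if len(bad):
        i = bad[0]
        raise FormatError(
            f"{path}: line {i + 1}: gene strand must be '+' or '-', "
            f"got {df['strand'].iat[i]!r}"
        )
    genes = df.rename(columns={"name": "gene_id"})[
        ["gene_id", "chrom", "start", "end", "strand"]
    ].copy()
    return validate_genes(genes)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression time course TSV

def read_timecourse(path) -> pd.DataFrame:
    """Read a gene x time-point expression TSV.

    Layout: header row, columns ``gene_id chrom start end strand [class]
    t1 ... tN``.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: time-course TSV missing columns {missing}")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    if not tcols:
        raise FormatError(f"{path}: no time-point columns (t1..tN) found")
    return df


def write_timecourse(tc: pd.DataFrame, path) -> None:
    tc.to_csv(path, sep="\t", index=False)


def timepoint_columns(tc: pd.DataFrame) -> list[str]:
    cols = [c for c in tc.columns if c.startswith("t") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


# ---------------------------------------------------------------------------
# gene sets (two-column TSV: set name, gene id)

def read_gene_sets(path) -> dict[str, set[str]]:
    df = _read_table(path, ["set", "gene_id"], 2, "gene-set TSV")
    sets: dict[str, set[str]] = {}
    for s, g in zip(df["set"], df["gene_id"]):
        sets.setdefault(s, set()).add(g)
    return sets


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(values: dict[str, np.ndarray], chrom_sizes: dict[str, int],
                   bin_size: int, path) -> None:
    """Write per-bin values as bedGraph, one record per run of constant value.

    NaN bins (masked) are omitted, as are zero runs; absence reads back as 0.
    """
    records = []
    for chrom, v in values.items():
        v = np.asarray(v, dtype=float)
        length = chrom_sizes[chrom]
        change = np.flatnonzero(np.diff(v) != 0)  # NaN != NaN splits runs; merged below
        starts = np.r_[0, change + 1]
        ends = np.r_[change + 1, len(v)]
        for s, e in zip(starts, ends):
            val = v[s]
            if np.isnan(val) or val == 0:
                continue
            records.append(
                (chrom, s * bin_size, min(e * bin_size, length), val)
            )
    pd.DataFrame(records, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path, chrom_sizes: dict[str, int], bin_size: int
                  ) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-bin value arrays (uncovered bins read as 0)."""
    df = _read_table(path, ["chrom", "start", "end", "value"], 4, "bedGraph")
    out = {
        c: np.zeros(-(-length // bin_size)) for c, length in chrom_sizes.items()
    }
    if not len(df):
        return out
    df["start"] = _to_int(df, "start", path)
    df["end"] = _to_int(df, "end", path)
    unknown = sorted(set(df["chrom"]) - set(chrom_sizes))
    if unknown:
        raise FormatError(f"{path}: chromosomes not in chrom.sizes: {unknown}")
    for chrom, s, e, val in zip(df["chrom"], df["start"], df["end"],
                                pd.to_numeric(df["value"])):
        b0 = s // bin_size
        b1 = -(-e // bin_size)
        out[chrom][b0:b1] = val
    return out


def read_stranded_bedgraph(watson_path, crick_path,
                           chrom_sizes: dict[str, int],
                           bin_size: int = 100) -> StrandedTrack:
    """Assemble a StrandedTrack from a Watson/Crick bedGraph pair."""
    return StrandedTrack(
        bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes),
        watson=read_bedgraph(watson_path, chrom_sizes, bin_size),
        crick=read_bedgraph(crick_path, chrom_sizes, bin_size),
    )


def write_stranded_bedgraph(track: StrandedTrack, watson_path, crick_path) -> None:
    write_bedgraph(track.watson, track.chrom_sizes, track.bin_size, watson_path)
    write_bedgraph(track.crick, track.chrom_sizes, track.bin_size, crick_path)


# ---------------------------------------------------------------------------
# origin calls (BED6+2)

def write_origins_bed(origins: pd.DataFrame, path) -> None:
    """Write origin calls as BED: each origin occupies the fixed 5 kb window
    centred on its midpoint; score = round(1000 x efficiency); extra columns
    carry efficiency and transition-zone width.
    """
    validate_origins(origins)
    eff = origins.get("efficiency", pd.Series(np.nan, index=origins.index))
    tz = origins.get("transition_zone", pd.Series(np.nan, index=origins.index))
    out = pd.DataFrame(
        {
            "chrom": origins["chrom"],
            "start": (origins["midpoint"] - ORIGIN_HALFWIDTH).astype(int),
            "end": (origins["midpoint"] + ORIGIN_HALFWIDTH).astype(int),
            "name": [f"origin_{i}" for i in range(len(origins))],
            "score": np.where(eff.notna(), np.rint(1000 * eff.fillna(0)), 0).astype(int),
            "strand": ".",
            "efficiency": eff,
            "transition_zone": tz,
        }
    )
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tefficiency\ttransition_zone\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_origins_bed(path) -> pd.DataFrame:
    cols = _BED6 + ["efficiency", "transition_zone"]
    df = _read_table(path, cols, 6, "origins BED")
    df["start"] = _to_int(df, "start", path)
    df["end"] = _to_int(df, "end", path)
    origins = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "midpoint": ((df["start"] + df["end"]) // 2).astype(int),
            "score": pd.to_numeric(df["score"], errors="coerce"),
            "efficiency": pd.to_numeric(df.get("efficiency"), errors="coerce"),
            "transition_zone": pd.to_numeric(
                df.get("transition_zone"), errors="coerce"
            ),
        }
    )
    return validate_origins(origins)


# ---------------------------------------------------------------------------
# genome model sidecar

def write_genome_model(model: GenomeModel, origins_tsv, chrom_sizes_path) -> None:
    """Persist a GenomeModel as an origins TSV plus a chrom.sizes file."""
    model.origins_frame().to_csv(origins_tsv, sep="\t", index=False)
    write_chrom_sizes(model.chrom_sizes, chrom_sizes_path)


def read_genome_model(origins_tsv, chrom_sizes_path,
                      fork_speed: float = 2.5) -> GenomeModel:
    sizes = read_chrom_sizes(chrom_sizes_path)
    df = pd.read_csv(origins_tsv, sep="\t")
    positions = {}
    efficiencies = {}
    for chrom in sizes:
        sub = df[df["chrom"] == chrom].sort_values("position")
        positions[chrom] = sub["position"].to_numpy(dtype=int)
        efficiencies[chrom] = sub["efficiency"].to_numpy(dtype=float)
    return GenomeModel(
        chrom_sizes=sizes,
        origin_positions=positions,
        origin_efficiencies=efficiencies,
        fork_speed=fork_speed,
        fragment_length_model=FragmentLengthModel(),
    )


# ---------------------------------------------------------------------------
# binning

def bin_fragments(frags: pd.DataFrame, chrom_sizes: dict[str, int],
                  bin_size: int = 100) -> StrandedTrack:
    """Bin stranded fragments into fixed-width intervals, keeping strand identity.

    Each fragment increments exactly one bin on its strand's counter: the bin
    containing its 5' end (Watson fragments: ``start``; Crick fragments:
    ``end - 1``).  The 5' end marks the initiation point of each Okazaki
    fragment, which is the conventional anchor for OK-seq strand profiles.
    """
    validate_fragments(frags)
    unknown = sorted(set(frags["chrom"].unique()) - set(chrom_sizes))
    if unknown:
        raise FormatError(f"fragments on unknown chromosomes: {unknown}")
    track = StrandedTrack(bin_size=bin_size, chrom_sizes=dict(chrom_sizes))
    if not len(frags):
        return track
    is_watson = (frags["strand"] == WATSON).to_numpy()
    anchor = np.where(is_watson, frags["start"].to_numpy(),
                      frags["end"].to_numpy() - 1)
    out_of_bounds = (anchor < 0) | (
        anchor >= frags["chrom"].map(chrom_sizes).to_numpy()
    )
    if out_of_bounds.any():
        raise FormatError(
            f"{int(out_of_bounds.sum())} fragments extend past chromosome ends"
        )
    bins = anchor // bin_size
    for chrom, sub_idx in frags.groupby("chrom", sort=False).indices.items():
        nb = track.n_bins(chrom)
        w_mask = is_watson[sub_idx]
        track.watson[chrom] = np.bincount(
            bins[sub_idx][w_mask], minlength=nb
        ).astype(float)
        track.crick[chrom] = np.bincount(
            bins[sub_idx][~w_mask], minlength=nb
        ).astype(float)
    return track
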