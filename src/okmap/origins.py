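"""Replication-origin calling from stranded Okazaki-fragment coverage.

The pipeline follows the OK-seq convention: 100 bp stranded bins are
partially smoothed with a 1.5 kb sliding median, normalized per bin so the
Watson + Crick fractions sum to 1, and scanned with an origin-efficiency-
metric (OEM)-style statistic — the difference between the Watson-read
fraction in a fixed window (default 12 kb) immediately left of a position
and the same fraction immediately right.  Leftward forks lay Watson-strand
Okazaki fragments, so this difference peaks where leftward-fork territory
(left of an origin) abuts rightward-fork territory: local maxima above a
threshold are origin calls.

Because initiation occurs in broad zones, a call's *efficiency* — the
likelihood the origin fires in a given S phase — is taken as the maximum
normalized strand fraction within 20 kb of the midpoint (Watson side left,
Crick side right), and the distance between the flanking Watson and Crick
normalized maxima defines the *transition zone* width.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import StrandedTrack, empty_origins, validate_origins

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# smoothing and normalization

def smooth_track(track: StrandedTrack, window: int = 1500) -> StrandedTrack:
    """Partially smooth both strands with a centred sliding median.

    ``window`` (bp) is coerced up to an odd multiple of the bin size; edges
    use the truncated window; zero-coverage (masked) bins are excluded from
    each median rather than contributing zeros.
    """
    bs = track.bin_size
    if window < bs:
        raise ValueError(f"smoothing window {window} < bin size {bs}")
    n_bins_w = window // bs
    if n_bins_w % 2 == 0:
        n_bins_w += 1
        logger.info("smoothing window coerced up to %d bp (odd bin multiple)",
                    n_bins_w * bs)
    out = track.copy()
    for chrom in track.chromosomes:
        mask = track.mask(chrom)
        for counts, dest in ((track.watson[chrom], out.watson),
                             (track.crick[chrom], out.crick)):
            s = pd.Series(np.where(mask, np.nan, counts.astype(float)))
            med = s.rolling(n_bins_w, center=True, min_periods=1).median()
            dest[chrom] = med.fillna(0.0).to_numpy()
    out.frac_watson = {}
    out.frac_crick = {}
    return out


def normalize_track(track: StrandedTrack) -> StrandedTrack:
    """Per-bin strand fractions: f_W = W/(W+C), f_C = C/(W+C); masked where
    the bin has no coverage (fractions NaN there)."""
    out = track.copy()
    for chrom in track.chromosomes:
        w = track.watson[chrom].astype(float)
        c = track.crick[chrom].astype(float)
        tot = w + c
        with np.errstate(invalid="ignore", divide="ignore"):
            fw = np.where(tot > 0, w / tot, np.nan)
        out.frac_watson[chrom] = fw
        out.frac_crick[chrom] = 1.0 - fw
    return out


# ---------------------------------------------------------------------------
# transition metric and peak calling

def origin_transition_metric(track: StrandedTrack, window: int = 12_000
                             ) -> dict[str, np.ndarray]:
    """OEM-style origin transition metric per bin.

    ``M(b) = F_W(left) - F_W(right)`` where ``F_W`` is the aggregate Watson
    fraction ``sum(W) / (sum(W) + sum(C))`` of the smoothed counts over the
    ``window`` bp immediately left (bins ``[b-n, b)``) and right (bins
    ``[b, b+n)``) of bin ``b``.  ``M`` lies in [-1, 1] and peaks at
    Watson-to-Crick transitions, i.e. replication origins.  NaN where either
    window leaves the chromosome or has zero total coverage.
    """
    n = window // track.bin_size
    if n < 2:
        raise ValueError(
            f"transition window {window} bp spans < 2 bins of {track.bin_size} bp"
        )
    metric: dict[str, np.ndarray] = {}
    for chrom in track.chromosomes:
        w = track.watson[chrom].astype(float)
        c = track.crick[chrom].astype(float)
        nb = len(w)
        cw = np.r_[0.0, np.cumsum(w)]
        cc = np.r_[0.0, np.cumsum(c)]
        m = np.full(nb, np.nan)
        b = np.arange(n, max(nb - n + 1, n))
        if len(b):
            wl = cw[b] - cw[b - n]
            cl = cc[b] - cc[b - n]
            wr = cw[b + n] - cw[b]
            cr = cc[b + n] - cc[b]
            with np.errstate(invalid="ignore", divide="ignore"):
                fl = np.where(wl + cl > 0, wl / (wl + cl), np.nan)
                fr = np.where(wr + cr > 0, wr / (wr + cr), np.nan)
            m[b] = fl - fr
        metric[chrom] = m
    return metric


def call_origins(metric: dict[str, np.ndarray], bin_size: int,
                 threshold: float = 0.1,
                 min_separation: int = 12_000) -> pd.DataFrame:
    """Call origins as local maxima of the transition metric.

    Maxima above ``threshold`` closer than ``min_separation`` bp are merged
    keeping the larger (ties: the leftmost — on a flat plateau the leftmost
    bin is the candidate).  Midpoints are bin centres.  Deterministic; may
    return an empty table.
    """
    rows = []
    for chrom, m in metric.items():
        v = np.where(np.isfinite(m), m, -np.inf)
        left = np.r_[-np.inf, v[:-1]]
        right = np.r_[v[1:], -np.inf]
        cand = np.flatnonzero((v > threshold) & (v > left) & (v >= right))
        if len(cand) == 0:
            continue
        # merge within min_separation, greedily keeping the larger score
        order = sorted(cand, key=lambda i: (-v[i], i))
        kept: list[int] = []
        min_bins = min_separation / bin_size
        for i in order:
            if all(abs(i - j) >= min_bins for j in kept):
                kept.append(i)
        for i in sorted(kept):
            rows.append((chrom, i * bin_size + bin_size // 2, float(v[i])))
    if not rows:
        return empty_origins()
    calls = pd.DataFrame(rows, columns=["chrom", "midpoint", "score"])
    calls["efficiency"] = np.nan
    calls["transition_zone"] = np.nan
    calls["watson_max_pos"] = np.nan
    calls["crick_max_pos"] = np.nan
    calls["flagged"] = False
    return calls


# ---------------------------------------------------------------------------
# annotation

def _window_bins(track: StrandedTrack, chrom: str, lo: int, hi: int
                 ) -> np.ndarray:
    """Bin indices whose centres fall in [lo, hi], clipped to the chromosome."""
    nb = track.n_bins(chrom)
    b0 = max(0, lo // track.bin_size)
    b1 = min(nb - 1, hi // track.bin_size)
    return np.arange(b0, b1 + 1) if b1 >= b0 else np.arange(0)


def _nanargmax(values: np.ndarray, bins: np.ndarray | None = None,
               center_bin: int | None = None) -> int | None:
    """Index of the maximum; ties resolved toward ``center_bin`` when given.

    Saturated stretches (f = 1 over many bins) are common near efficient
    origins, so the innermost maximum is the meaningful one for transition
    geometry; plain first-occurrence tie-breaking would instead report the
    window edge.
    """
    if len(values) == 0 or not np.isfinite(values).any():
        return None
    if bins is None or center_bin is None:
        return int(np.nanargmax(values))
    best = np.nanmax(values)
    ties = np.flatnonzero(values == best)
    return int(ties[np.argmin(np.abs(bins[ties] - center_bin))])


def annotate_efficiency(origins: pd.DataFrame, track: StrandedTrack,
                        radius: int = 20_000,
                        strand_aware: bool = True,
                        mode: str = "fraction_max") -> pd.DataFrame:
    """Attach origin efficiencies.

    ``mode="fraction_max"`` (default): the maximum normalized strand
    fraction within ``radius`` bp of each midpoint.  In the default
    strand-aware form the Watson fraction is searched left of the midpoint
    and the Crick fraction right of it — the sides where each strand's
    lagging-strand signal belongs — so a neighbouring origin's
    opposite-strand peak cannot inflate the estimate; ``strand_aware=False``
    searches both strands over the full +/- radius.  Note this estimator
    reads the *absolute* strand fraction, which also reflects passive
    replication by forks from neighbouring origins.

    ``mode="rfd_step"``: the jump in aggregate Crick fraction across the
    midpoint — ``sum(C)/(sum(W)+sum(C))`` over the ``radius`` bp right of
    the midpoint minus the same quantity over the ``radius`` bp left of it,
    clipped to [0, 1].  The step in replication-fork directionality across
    an origin equals the origin's own (conditional) firing probability, so
    this variant is the one that recovers per-origin firing rates from
    simulated populations.
    """
    if mode not in ("fraction_max", "rfd_step"):
        raise ValueError(f"unknown efficiency mode {mode!r}")
    if not track.frac_watson:
        raise ValueError("track is not normalized; call normalize_track first")
    out = origins.copy()
    for idx, row in origins.iterrows():
        chrom = row["chrom"]
        if chrom not in track.chrom_sizes:
            raise ValueError(f"origin on unknown chromosome {chrom!r}")
        mid = int(row["midpoint"])
        if not 0 <= mid < track.chrom_sizes[chrom]:
            raise ValueError(f"origin midpoint {mid} outside {chrom}")
        fw = track.frac_watson[chrom]
        fc = track.frac_crick[chrom]
        bs = track.bin_size
        if mode == "rfd_step":
            left = _window_bins(track, chrom, mid - radius, mid)
            right = _window_bins(track, chrom, mid, mid + radius)
            w, c = track.watson[chrom], track.crick[chrom]
            tl = w[left].sum() + c[left].sum()
            tr = w[right].sum() + c[right].sum()
            if tl > 0 and tr > 0:
                eff = float(np.clip(c[right].sum() / tr - c[left].sum() / tl,
                                    0.0, 1.0))
                out.at[idx, "efficiency"] = eff
            else:
                out.at[idx, "efficiency"] = np.nan
                out.at[idx, "flagged"] = True
            continue
        if strand_aware:
            left = _window_bins(track, chrom, mid - radius, mid)
            right = _window_bins(track, chrom, mid, mid + radius)
            mid_bin = mid // bs
            iw = _nanargmax(fw[left], left, mid_bin)
            ic = _nanargmax(fc[right], right, mid_bin)
            best_w = fw[left[iw]] if iw is not None else np.nan
            best_c = fc[right[ic]] if ic is not None else np.nan
            eff = np.nanmax([best_w, best_c]) if (iw is not None or ic is not None) else np.nan
            if iw is not None:
                out.at[idx, "watson_max_pos"] = left[iw] * bs + bs // 2
            if ic is not None:
                out.at[idx, "crick_max_pos"] = right[ic] * bs + bs // 2
        else:
            both = _window_bins(track, chrom, mid - radius, mid + radius)
            vals = np.concatenate([fw[both], fc[both]])
            i = _nanargmax(vals)
            eff = vals[i] if i is not None else np.nan
        out.at[idx, "efficiency"] = float(eff) if np.isfinite(eff) else np.nan
        if not np.isfinite(eff):
            out.at[idx, "flagged"] = True
    return validate_origins(out)


def annotate_transition_zone(origins: pd.DataFrame, track: StrandedTrack,
                             search_radius: int = 25_000) -> pd.DataFrame:
    """Attach transition-zone widths: the distance between the normalized
    Watson maximum left of the midpoint and the Crick maximum right of it,
    each searched within ``search_radius`` bp.  Negative widths (possible
    only with degenerate windows) are kept but flagged.
    """
    if not track.frac_watson:
        raise ValueError("track is not normalized; call normalize_track first")
    out = origins.copy()
    bs = track.bin_size
    for idx, row in origins.iterrows():
        chrom = row["chrom"]
        mid = int(row["midpoint"])
        fw = track.frac_watson[chrom]
        fc = track.frac_crick[chrom]
        left = _window_bins(track, chrom, mid - search_radius, mid)
        right = _window_bins(track, chrom, mid, mid + search_radius)
        mid_bin = mid // bs
        iw = _nanargmax(fw[left], left, mid_bin)
        ic = _nanargmax(fc[right], right, mid_bin)
        if iw is None or ic is None:
            out.at[idx, "flagged"] = True
            continue
        wpos = left[iw] * bs + bs // 2
        cpos = right[ic] * bs + bs // 2
        out.at[idx, "watson_max_pos"] = wpos
        out.at[idx, "crick_max_pos"] = cpos
        out.at[idx, "transition_zone"] = cpos - wpos
        if cpos < wpos:
            out.at[idx, "flagged"] = True
    return out


# ---------------------------------------------------------------------------
# summary statistics

def spacing_stats(origins: pd.DataFrame) -> dict:
    """Inter-origin spacing statistics.

    Spacings are consecutive midpoint differences within chromosomes; the
    "within 100 kb" fraction counts origins whose nearest neighbour is at
    most 100 kb away.  With fewer than two origins everywhere, the result is
    empty (not an error).
    """
    spacings = []
    frac_flags = []
    for chrom, sub in origins.groupby("chrom", sort=False):
        mids = np.sort(sub["midpoint"].to_numpy())
        if len(mids) < 2:
            continue
        gaps = np.diff(mids)
        spacings.append(gaps)
        nn = np.minimum(np.r_[np.inf, gaps], np.r_[gaps, np.inf])
        frac_flags.append(nn <= 100_000)
    if not spacings:
        return {
            "median_spacing": float("nan"),
            "fraction_within_100kb": float("nan"),
            "spacings": np.array([]),
            "n_origins": int(len(origins)),
        }
    all_gaps = np.concatenate(spacings)
    all_flags = np.concatenate(frac_flags)
    return {
        "median_spacing": float(np.median(all_gaps)),
        "fraction_within_100kb": float(all_flags.mean()),
        "spacings": all_gaps,
        "n_origins": int(len(origins)),
    }


def compare_origin_maps(a: pd.DataFrame, b: pd.DataFrame,
                        window: int = 5000) -> dict:
    """Compare two origin maps (e.g. developmental stages).

    Origins are paired when their 5 kb blocks overlap (midpoints closer than
    ``window`` bp), greedily by distance with each origin used once.  Returns
    the Spearman correlation of paired efficiencies and the percentage of
    map ``a`` that found a partner.
    """
    pairs = []
    for chrom in a["chrom"].unique():
        a_sub = a[a["chrom"] == chrom]
        b_sub = b[b["chrom"] == chrom]
        if not len(b_sub):
            continue
        b_mid = b_sub["midpoint"].to_numpy()
        for ia, ma in zip(a_sub.index, a_sub["midpoint"].to_numpy()):
            d = np.abs(b_mid - ma)
            for j in np.flatnonzero(d < window):
                pairs.append((float(d[j]), ia, b_sub.index[j]))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    eff_a, eff_b = [], []
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        eff_a.append(a.loc[ia, "efficiency"])
        eff_b.append(b.loc[ib, "efficiency"])
    n_paired = len(eff_a)
    if n_paired >= 2 and np.isfinite(eff_a).any():
        r = float(stats.spearmanr(eff_a, eff_b).statistic)
    else:
        r = float("nan")
    return {
        "spearman_r": r,
        "percent_overlap": 100.0 * n_paired / len(a) if len(a) else float("nan"),
        "n_paired": n_paired,
        "window": window,
    }


def origin_strand_heatmap(origins: pd.DataFrame, track: StrandedTrack,
                          flank: int = 25_000) -> dict:
    """Per-origin strand-signal matrix, normalized for cross-origin display.

    For each origin the smoothed Watson and Crick counts over the midpoint
    +/- ``flank`` are extracted, mean-centred, and scaled to unit sum of
    squares (an all-constant row becomes the zero vector and is flagged).
    Rows are ordered by ascending transition-zone width; origins with a
    flagged (negative/undefined) transition zone or a window leaving the
    chromosome are excluded.
    """
    bs = track.bin_size
    n_flank = flank // bs
    width = 2 * n_flank
    usable = origins[
        origins["transition_zone"].notna() & ~origins["flagged"].astype(bool)
    ].sort_values(["transition_zone", "chrom", "midpoint"], kind="stable")
    rows_w, rows_c, kept_idx, degenerate = [], [], [], []
    for idx, row in usable.iterrows():
        chrom = row["chrom"]
        c_bin = int(row["midpoint"]) // bs
        lo, hi = c_bin - n_flank, c_bin + n_flank
        if lo < 0 or hi > track.n_bins(chrom):
            continue
        rows_w.append(track.watson[chrom][lo:hi].astype(float))
        rows_c.append(track.crick[chrom][lo:hi].astype(float))
        kept_idx.append(idx)
    w = np.array(rows_w).reshape(-1, width)
    c = np.array(rows_c).reshape(-1, width)
    for mat in (w, c):
        for i in range(mat.shape[0]):
            r = mat[i] - mat[i].mean()
            ss = np.sqrt((r ** 2).sum())
            if ss > 0:
                mat[i] = r / ss
            else:
                mat[i] = 0.0
                degenerate.append(i)
    return {
        "watson": w,
        "crick": c,
        "origin_index": kept_idx,
        "transition_zone": usable.loc[kept_idx, "transition_zone"].to_numpy(),
        "degenerate_rows": sorted(set(degenerate)),
        "flank": flank,
        "bin_size": bs,
    }


def replication_time(origin_spacing_kb: float, fork_speed_kb_min: float) -> float:
    """Minutes to duplicate a genome with uniformly spaced, always-firing
    origins: each inter-origin interval is closed by two converging forks,
    so ``t = spacing / (2 * speed)``.

    With origins every ~75 kb and forks at 2.5 kb/min this gives ~15 min,
    the back-of-envelope bound for complete embryonic genome duplication.
    """
    if fork_speed_kb_min <= 0:
        raise ValueError("fork speed must be positive")
    if origin_spacing_kb < 0:
        raise ValueError("origin spacing must be non-negative")
    return origin_spacing_kb / (2.0 * fork_speed_kb_min)
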