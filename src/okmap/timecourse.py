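"""Origin-transcription coupling through the embryonic time course.

The whole-embryo transcriptome is measured at 50 successive time points.
Each expressed gene's profile is normalized to sum to 1, genes are split
into maternal (oocyte-deposited, expression mass concentrated in the first
five points) and zygotic classes, and zygotic transcript abundance is
stacked relative to replication-origin midpoints.  Early-to-mid
embryogenesis transcription clusters at origins; after embryonic cell
division ceases, active transcription moves origin-distal.  The coupling
statistic — a per-time-point log2 proximal/distal abundance ratio — renders
that switch as a single curve.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import validate_origins
from .genes import gene_anchor
from .io import timepoint_columns

logger = logging.getLogger(__name__)


def normalize_timecourse(tc: pd.DataFrame) -> pd.DataFrame:
    """Normalize each gene's profile so its 50 time points sum to 1.

    All-zero rows carry no expression: they are labelled ``unexpressed``
    (column ``expressed`` False) and left untouched.
    """
    out = tc.copy()
    tcols = timepoint_columns(tc)
    mat = out[tcols].to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    expressed = totals > 0
    mat[expressed] = mat[expressed] / totals[expressed, None]
    out[tcols] = mat
    out["expressed"] = expressed
    return out


def classify_maternal(tc: pd.DataFrame, k_clusters: int = 6,
                      early_window: int = 5, seed: int = 0,
                      rule: str = "cluster") -> pd.DataFrame:
    """Partition expressed genes into maternal and zygotic classes.

    ``rule="cluster"`` (default): k-means clusters the normalized profiles
    (fixed seed); a cluster is maternal iff its centroid's expression mass
    within time points 1..``early_window`` exceeds the mass in every other
    contiguous ``early_window``-point span of the centroid.  Members of
    maternal clusters are labelled maternal, every other expressed gene
    zygotic.

    ``rule="argmax"``: deterministic audit rule — a gene is maternal iff its
    own profile peaks at a time point <= ``early_window``.
    """
    if rule == "cluster" and k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    tcols = timepoint_columns(tc)
    out = tc.copy()
    if "expressed" not in out.columns:
        out = normalize_timecourse(out)
    labels = np.array(["unexpressed"] * len(out), dtype=object)
    expr = out["expressed"].to_numpy()
    mat = out.loc[expr, tcols].to_numpy(dtype=float)
    if rule == "argmax":
        maternal = mat.argmax(axis=1) + 1 <= early_window
    elif rule == "cluster":
        km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10)
        assign = km.fit_predict(mat)
        maternal_clusters = []
        for ci, centroid in enumerate(km.cluster_centers_):
            window_mass = np.convolve(centroid, np.ones(early_window), "valid")
            if np.argmax(window_mass) == 0:
                maternal_clusters.append(ci)
        maternal = np.isin(assign, maternal_clusters)
    else:
        raise ValueError(f"rule must be 'cluster' or 'argmax', got {rule!r}")
    lab = np.where(maternal, "maternal", "zygotic")
    labels[np.flatnonzero(expr)] = lab
    out["label"] = labels
    return out


def coupling_heatmap(tc: pd.DataFrame, origins: pd.DataFrame,
                     top_n: int = 1000, flank: int = 25_000,
                     bin_size: int = 2500, zygotic_only: bool = True,
                     anchor: str = "midpoint",
                     dedupe: bool = False) -> dict:
    """Sum normalized transcript abundance around the most efficient origins.

    Origins are ranked by efficiency and the top ``top_n`` retained (clipped
    with a warning when fewer exist).  For each time point and signed
    distance bin within +/- ``flank`` of an origin midpoint, the normalized
    expression of (by default zygotic) genes whose anchor falls in that bin
    is summed.  A gene within the flank of several retained origins
    contributes to each (per-origin stacking); ``dedupe=True`` restricts it
    to its nearest retained origin.

    Returns the (n_timepoints x n_bins) matrix plus axis metadata.
    """
    validate_origins(origins)
    tcols = timepoint_columns(tc)
    if "label" not in tc.columns:
        raise ValueError("time course is unlabelled; run classify_maternal first")
    if top_n > len(origins):
        logger.warning("top_n=%d exceeds %d available origins; clipping",
                       top_n, len(origins))
        top_n = len(origins)
    retained = origins.sort_values(
        "efficiency", ascending=False, kind="stable"
    ).head(top_n)
    genes = tc[tc["label"] == "zygotic"] if zygotic_only else tc[tc["expressed"]]
    edges = np.arange(-flank, flank + bin_size, bin_size)
    n_bins = len(edges) - 1
    heat = np.zeros((len(tcols), n_bins))
    if len(genes):
        anchors = gene_anchor(genes, anchor)
        expr = genes[tcols].to_numpy(dtype=float)
        for chrom, sub_idx in genes.groupby("chrom", sort=False).indices.items():
            mids = np.sort(
                retained.loc[retained["chrom"] == chrom, "midpoint"].to_numpy()
            )
            if len(mids) == 0:
                continue
            a = anchors[sub_idx]
            lo = np.searchsorted(mids, a - flank, side="left")
            hi = np.searchsorted(mids, a + flank, side="right")
            for gi, l, h in zip(sub_idx, lo, hi):
                if h <= l:
                    continue
                hits = mids[l:h]
                if dedupe and len(hits) > 1:
                    hits = hits[[np.argmin(np.abs(hits - anchors[gi]))]]
                for m in hits:
                    b = int((anchors[gi] - m + flank) // bin_size)
                    if 0 <= b < n_bins:
                        heat[:, b] += expr[gi]
    return {
        "matrix": heat,
        "bin_edges": edges,
        "bin_centers": (edges[:-1] + edges[1:]) / 2.0,
        "timepoints": np.arange(1, len(tcols) + 1),
        "top_n": top_n,
        "flank": flank,
        "bin_size": bin_size,
        "zygotic_only": zygotic_only,
    }


def coupling_statistic(heatmap: dict, proximal: int = 5000,
                       distal: tuple[int, int] = (15_000, 25_000),
                       pseudocount: float = 1e-9) -> np.ndarray:
    """Per-time-point log2 ratio of origin-proximal to origin-distal abundance.

    Proximal bins lie within +/- ``proximal`` bp of the origin midpoint;
    distal bins have ``distal[0] <= |distance| <= distal[1]``.  A small
    pseudo-count keeps empty bins finite; a uniform heatmap scores 0
    everywhere.  Positive values mean transcription clusters at origins,
    negative values that it has moved away.
    """
    centers = heatmap["bin_centers"]
    prox = np.abs(centers) <= proximal
    dist = (np.abs(centers) >= distal[0]) & (np.abs(centers) <= distal[1])
    if not prox.any() or not dist.any():
        raise ValueError("proximal/distal bands select no bins at this bin size")
    m = heatmap["matrix"]
    return np.log2(
        (m[:, prox].mean(axis=1) + pseudocount)
        / (m[:, dist].mean(axis=1) + pseudocount)
    )
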