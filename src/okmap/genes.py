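"""Gene organization around replication origins.

Two analyses: the strand-orientation profile of genes flanking origins
(replication and transcription tend to be co-directional, avoiding head-on
fork-polymerase collisions), and positional gene-set enrichment — whether a
gene set concentrates at particular distances from origins, scored with
log2 observed/expected ratios and hypergeometric tail probabilities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import CRICK, WATSON, validate_genes, validate_origins

logger = logging.getLogger(__name__)

ANCHORS = ("midpoint", "start", "tss")


def gene_anchor(genes: pd.DataFrame, anchor: str = "midpoint") -> np.ndarray:
    """Per-gene reference coordinate: interval midpoint, start, or the
    strand-aware 5' end (transcription start)."""
    if anchor == "midpoint":
        return ((genes["start"] + genes["end"]) // 2).to_numpy()
    if anchor == "start":
        return genes["start"].to_numpy()
    if anchor == "tss":
        return np.where(genes["strand"] == WATSON,
                        genes["start"], genes["end"] - 1)
    raise ValueError(f"anchor must be one of {ANCHORS}, got {anchor!r}")


def _nearest_origin_offsets(genes: pd.DataFrame, origins: pd.DataFrame,
                            anchor: str) -> np.ndarray:
    """Signed distance (gene anchor - nearest origin midpoint); NaN when the
    gene's chromosome has no origins."""
    anchors = gene_anchor(genes, anchor)
    offsets = np.full(len(genes), np.nan)
    for chrom, idx in genes.groupby("chrom", sort=False).indices.items():
        mids = np.sort(origins.loc[origins["chrom"] == chrom, "midpoint"].to_numpy())
        if len(mids) == 0:
            continue
        a = anchors[idx]
        j = np.clip(np.searchsorted(mids, a), 1, len(mids)) - 1
        jr = np.clip(j + 1, 0, len(mids) - 1)
        d_left = a - mids[j]
        d_right = a - mids[jr]
        offsets[idx] = np.where(np.abs(d_right) < np.abs(d_left), d_right, d_left)
    return offsets


def orientation_bias(genes: pd.DataFrame, origins: pd.DataFrame,
                     flank: int = 25_000, bin_size: int = 2500,
                     anchor: str = "midpoint") -> pd.DataFrame:
    """Strand bias and length of genes as a function of signed origin distance.

    Each gene is assigned to its nearest origin when within ``flank`` bp;
    per signed-distance bin the table reports Watson ("+", transcribed
    rightward) and Crick ("-") gene counts, the log2 Watson:Crick ratio
    (NaN and flagged when either count is zero), and the median gene length.
    A co-directional genome shows negative log-ratios left of origins and
    positive right of them.
    """
    validate_genes(genes)
    validate_origins(origins)
    offsets = _nearest_origin_offsets(genes, origins, anchor)
    within = np.abs(offsets) <= flank
    edges = np.arange(-flank, flank + bin_size, bin_size)
    rows = []
    strands = genes["strand"].to_numpy()
    lengths = (genes["end"] - genes["start"]).to_numpy()
    idx = np.digitize(offsets[within], edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    sub_strand = strands[within]
    sub_len = lengths[within]
    for b in range(len(edges) - 1):
        m = idx == b
        n_w = int((sub_strand[m] == WATSON).sum())
        n_c = int((sub_strand[m] == CRICK).sum())
        ratio = np.log2(n_w / n_c) if n_w > 0 and n_c > 0 else np.nan
        rows.append({
            "bin_start": int(edges[b]),
            "bin_end": int(edges[b + 1]),
            "bin_center": float((edges[b] + edges[b + 1]) / 2),
            "n_watson": n_w,
            "n_crick": n_c,
            "log2_watson_crick": ratio,
            "median_gene_length": float(np.median(sub_len[m])) if m.any() else np.nan,
            "flagged": n_w == 0 or n_c == 0,
        })
    return pd.DataFrame(rows)


def positional_enrichment(gene_sets: dict[str, set[str]],
                          genes: pd.DataFrame, origins: pd.DataFrame,
                          distance_bins: np.ndarray | None = None,
                          anchor: str = "midpoint") -> pd.DataFrame:
    """Gene-set enrichment by distance from the nearest origin.

    For each absolute-distance bin and gene set: with N genes total, K in
    the set, n in the bin, and k set genes in the bin, enrichment is
    ``log2((k/n) / (K/N))`` and the p-value the hypergeometric upper tail
    ``P(X >= k)`` (lower tail ``P(X <= k)`` when depleted; the ``direction``
    column carries the sign).  Benjamini-Hochberg-adjusted p-values are
    reported across the whole set x bin grid alongside the raw ones.
    Set members absent from the gene table are logged and skipped.
    """
    if distance_bins is None:
        distance_bins = np.array([0, 2500, 5000, 10_000, 15_000, 20_000, 25_000,
                                  50_000, np.inf])
    distance_bins = np.asarray(distance_bins, dtype=float)
    validate_genes(genes)
    offsets = _nearest_origin_offsets(genes, origins, anchor)
    dist = np.abs(offsets)
    known = set(genes["gene_id"])
    N = len(genes)
    bin_idx = np.digitize(dist, distance_bins) - 1
    in_grid = (bin_idx >= 0) & (bin_idx < len(distance_bins) - 1) & np.isfinite(dist)
    rows = []
    for set_name, members in gene_sets.items():
        missing = members - known
        if missing:
            logger.warning("gene set %r: %d ids not in gene table; skipped",
                           set_name, len(missing))
        members = members & known
        K = len(members)
        is_member = genes["gene_id"].isin(members).to_numpy()
        for b in range(len(distance_bins) - 1):
            sel = in_grid & (bin_idx == b)
            n = int(sel.sum())
            k = int((sel & is_member).sum())
            if n == 0 or K == 0:
                rows.append({
                    "set": set_name, "bin_start": distance_bins[b],
                    "bin_end": distance_bins[b + 1], "N": N, "K": K,
                    "n": n, "k": k, "log2_obs_exp": np.nan,
                    "pvalue": np.nan, "direction": 0, "flagged": True,
                })
                continue
            expected = K / N
            observed = k / n
            ratio = (np.log2(observed / expected) if k > 0
                     else -np.inf if expected > 0 else np.nan)
            if observed >= expected:
                p = float(hypergeom.sf(k - 1, N, K, n))   # P(X >= k)
                direction = 1
            else:
                p = float(hypergeom.cdf(k, N, K, n))      # P(X <= k)
                direction = -1
            rows.append({
                "set": set_name, "bin_start": distance_bins[b],
                "bin_end": distance_bins[b + 1], "N": N, "K": K,
                "n": n, "k": k, "log2_obs_exp": ratio,
                "pvalue": p, "direction": direction, "flagged": False,
            })
    result = pd.DataFrame(rows)
    ok = result["pvalue"].notna()
    result["qvalue"] = np.nan
    if ok.any():
        result.loc[ok, "qvalue"] = multipletests(
            result.loc[ok, "pvalue"], method="fdr_bh"
        )[1]
    return result
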