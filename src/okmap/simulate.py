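"""Stochastic replication simulator with known ground truth.

The simulator emulates the data-generating process behind OK-seq: in each
cell of a population, a subset of licensed replication origins fires, forks
move bidirectionally outward at uniform speed, and lagging-strand (Okazaki)
fragments are emitted everywhere — Watson-strand fragments where the local
fork moves leftward (left of the nearest fired origin), Crick-strand where
it moves rightward.  Every origin carries a firing probability ("efficiency")
so that the population-level strand bias at any position has an exact
closed form (:func:`expected_watson_fraction`), which serves as the oracle
for the whole downstream origin-calling pipeline.

It also generates the two ancillary data types the downstream analyses
consume: enhancer-mark ChIP peaks whose fold-enrichment scales with origin
efficiency, and an embryonic expression time course with maternal,
origin-proximal early-zygotic, and origin-distal late-zygotic gene classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CRICK, WATSON, validate_fragments

logger = logging.getLogger(__name__)

LEFTWARD = -1
RIGHTWARD = 1

#: Enumeration cap for the exact strand-bias oracle.
MAX_ENUMERATION_ORIGINS = 20


class EnumerationLimitError(ValueError):
    """Exact enumeration requested for a chromosome with too many origins."""


@dataclass(frozen=True)
class FragmentLengthModel:
    """Nucleosome-periodic Okazaki fragment length distribution.

    Lengths are drawn from a mixture over integer multiples ``k`` of the
    nucleosome repeat length ``period`` (k = 1..len(weights)), plus Gaussian
    jitter, truncated to ``[min_bp, max_bp]``.  This reproduces the periodic
    fragment-size ladder of ligase-depleted embryos without modelling gel
    physics.
    """

    min_bp: int = 100
    max_bp: int = 600
    period: int = 172
    weights: tuple[float, ...] = (0.5, 0.35, 0.15)
    jitter_sd: float = 25.0

    def __post_init__(self) -> None:
        if self.min_bp <= 0 or self.max_bp <= self.min_bp:
            raise ValueError("require 0 < min_bp < max_bp")
        if not self.weights or min(self.weights) < 0 or sum(self.weights) <= 0:
            raise ValueError("mixture weights must be non-negative, not all zero")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        k = rng.choice(np.arange(1, len(w) + 1), size=n, p=w / w.sum())
        lengths = k * self.period + rng.normal(0.0, self.jitter_sd, size=n)
        return np.clip(np.rint(lengths), self.min_bp, self.max_bp).astype(int)


@dataclass
class GenomeModel:
    """Ground-truth replication program.

    Fields
    ------
    chrom_sizes
        Ordered mapping chromosome -> length (bp).
    origin_positions, origin_efficiencies
        Per chromosome, strictly increasing positions (bp) and per-origin
        firing probabilities in [0, 1].
    fork_speed
        Replication fork speed in kb/min (affects the analytic replication
        time only; fragment emission is speed-independent at steady state).
    """

    chrom_sizes: dict[str, int]
    origin_positions: dict[str, np.ndarray]
    origin_efficiencies: dict[str, np.ndarray]
    fork_speed: float = 2.5
    fragment_length_model: FragmentLengthModel = field(
        default_factory=FragmentLengthModel
    )

    def __post_init__(self) -> None:
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r}: non-positive length")
            pos = np.asarray(self.origin_positions[chrom])
            eff = np.asarray(self.origin_efficiencies[chrom])
            if len(pos) < 1:
                raise ValueError(f"chromosome {chrom!r} has no origins")
            if len(pos) != len(eff):
                raise ValueError(f"chromosome {chrom!r}: positions/efficiencies differ")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {chrom!r}: positions not increasing")
            if np.any((eff < 0) | (eff > 1)):
                raise ValueError(f"chromosome {chrom!r}: efficiency outside [0,1]")
            self.origin_positions[chrom] = pos.astype(int)
            self.origin_efficiencies[chrom] = eff.astype(float)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_origins(self) -> int:
        return sum(len(p) for p in self.origin_positions.values())

    def origins_frame(self) -> pd.DataFrame:
        """All origins as a (chrom, position, efficiency) table."""
        rows = [
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "position": self.origin_positions[chrom],
                    "efficiency": self.origin_efficiencies[chrom],
                }
            )
            for chrom in self.chromosomes
        ]
        return pd.concat(rows, ignore_index=True)


@dataclass
class CellReplicationOutcome:
    """Fired-origin subset for one simulated cell."""

    fired_positions: dict[str, np.ndarray]

    def fork_direction(self, chrom: str, positions: np.ndarray,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Fork direction (LEFTWARD/RIGHTWARD) at each position.

        Direction is RIGHTWARD iff the nearest fired origin lies strictly to
        the left, LEFTWARD iff strictly to the right.  Exact ties (position
        equidistant from two fired origins, or sitting on one) are broken
        uniformly at random, matching the 1/2 contribution of the analytic
        oracle; pass an ``rng`` to resolve them reproducibly.
        """
        return _fork_direction(self.fired_positions[chrom], np.asarray(positions), rng)


def _fork_direction(fired: np.ndarray, positions: np.ndarray,
                    rng: np.random.Generator | None) -> np.ndarray:
    idx = np.searchsorted(fired, positions)
    left = np.where(idx > 0, fired[np.clip(idx - 1, 0, None)], -np.inf)
    right = np.where(idx < len(fired), fired[np.clip(idx, None, len(fired) - 1)], np.inf)
    d_left = positions - left
    d_right = right - positions
    direction = np.where(d_left < d_right, RIGHTWARD, LEFTWARD)
    ties = d_left == d_right
    if ties.any():
        if rng is None:
            rng = np.random.default_rng()
        direction[ties] = np.where(rng.random(int(ties.sum())) < 0.5,
                                   RIGHTWARD, LEFTWARD)
    return direction


# ---------------------------------------------------------------------------
# model construction

def simulate_genome_model(
    n_chrom: int = 2,
    chrom_length: int = 5_000_000,
    n_origins: int = 125,
    efficiency_distribution: tuple[str, tuple] = ("beta", (2.0, 2.0)),
    seed: int = 0,
    fork_speed: float = 2.5,
    fragment_length_model: FragmentLengthModel | None = None,
    placement: str = "jittered_lattice",
    min_origin_gap: int = 5_000,
) -> GenomeModel:
    """Draw a random replication program.

    Origin positions are drawn per chromosome and sorted; firing
    probabilities are i.i.d. from the requested family: ``("beta", (a, b))``,
    ``("uniform", (lo, hi))`` or ``("fixed", (value,))``.  The default
    ``"jittered_lattice"`` placement jitters a regular grid (spacing
    ``chrom_length / n_origins``, Gaussian jitter with sd a quarter of the
    spacing), giving a median inter-origin distance equal to the mean —
    the 40 kb median the embryo shows — with realistic dispersion;
    ``placement="uniform"`` draws positions uniformly instead (exponential-
    flavoured spacings whose median falls well below the mean).  The
    defaults — two 5 Mb chromosomes with 125 origins each (40 kb spacing)
    and beta(2,2) efficiencies (median 0.5) — reproduce the embryonic
    spacing/efficiency regime at desk scale.
    """
    if n_chrom < 1 or n_origins < 1 or chrom_length <= 0:
        raise ValueError("n_chrom, n_origins and chrom_length must be positive")
    family, params = efficiency_distribution
    rng = np.random.default_rng(seed)
    chrom_sizes: dict[str, int] = {}
    positions: dict[str, np.ndarray] = {}
    efficiencies: dict[str, np.ndarray] = {}
    for i in range(n_chrom):
        chrom = f"chr{_roman(i + 1)}"
        chrom_sizes[chrom] = int(chrom_length)
        pos = _sample_positions(rng, chrom_length, n_origins, placement,
                                min_origin_gap)
        if family == "beta":
            eff = rng.beta(params[0], params[1], size=n_origins)
        elif family == "uniform":
            eff = rng.uniform(params[0], params[1], size=n_origins)
        elif family == "fixed":
            eff = np.full(n_origins, float(params[0]))
        else:
            raise ValueError(f"unknown efficiency distribution family {family!r}")
        positions[chrom] = pos
        efficiencies[chrom] = eff
    return GenomeModel(
        chrom_sizes=chrom_sizes,
        origin_positions=positions,
        origin_efficiencies=efficiencies,
        fork_speed=fork_speed,
        fragment_length_model=fragment_length_model or FragmentLengthModel(),
    )


def _sample_positions(rng: np.random.Generator, length: int, n: int,
                      placement: str, min_gap: int) -> np.ndarray:
    if placement == "jittered_lattice":
        spacing = length / n
        centers = (np.arange(n) + 0.5) * spacing
        pos = centers + rng.normal(0.0, spacing / 4.0, size=n)
        pos = np.sort(np.clip(np.rint(pos), 0, length - 1)).astype(int)
        # enforce strict increase (jitter collisions are rare but possible)
        for i in range(1, n):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        return np.minimum(pos, length - 1)
    if placement == "uniform":
        slack = length - 1 - (n - 1) * min_gap
        if slack <= 0:
            return np.sort(rng.choice(length, size=n, replace=False))
        base = np.sort(rng.integers(0, slack, size=n))
        return base + np.arange(n) * min_gap
    raise ValueError(f"unknown placement {placement!r}")


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if n <= len(numerals) else str(n)


def default_model(seed: int = 0) -> GenomeModel:
    """The default desk-scale model used throughout the test battery."""
    return simulate_genome_model(seed=seed)


# ---------------------------------------------------------------------------
# per-cell replication

def _draw_fired(positions: np.ndarray, eff: np.ndarray,
                rng: np.random.Generator,
                jitter_sd: float = 0.0, chrom_length: int | None = None
                ) -> np.ndarray:
    """Fired-origin positions for one cell, rejection-conditioned on >=1 firing.

    Every chromosome must replicate each cycle, so a firing vector with no
    fired origin is redrawn.  This conditioning biases low-efficiency origins
    slightly upward; the enumeration oracle applies the same conditioning.
    """
    while True:
        fired = rng.random(len(eff)) < eff
        if fired.any():
            break
    pos = positions[fired].astype(float)
    if jitter_sd > 0:
        pos = pos + rng.normal(0.0, jitter_sd, size=len(pos))
        if chrom_length is not None:
            pos = np.clip(pos, 0, chrom_length - 1)
        pos = np.sort(pos)
    return pos


def simulate_cell(model: GenomeModel, seed: int | np.random.Generator = 0,
                  origin_jitter_sd: float = 0.0) -> CellReplicationOutcome:
    """Simulate one cell: independent origin firing plus fork directions.

    ``origin_jitter_sd`` (bp) jitters each fired origin's initiation point
    per cell, turning point origins into broad initiation zones.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    fired = {
        chrom: _draw_fired(
            model.origin_positions[chrom], model.origin_efficiencies[chrom],
            rng, origin_jitter_sd, model.chrom_sizes[chrom],
        )
        for chrom in model.chromosomes
    }
    return CellReplicationOutcome(fired_positions=fired)


def simulate_fragments(
    model: GenomeModel,
    n_cells: int = 2000,
    fragments_per_cell: int = 500,
    seed: int = 0,
    origin_jitter_sd: float = 0.0,
    min_fragment_length: int = 30,
) -> pd.DataFrame:
    """Emit Okazaki fragments from a simulated cell population.

    For each cell, fragment 5' anchors are sampled uniformly over the genome;
    fragment length comes from the periodic mixture; the strand is Watson
    where the local fork moves leftward and Crick where it moves rightward.
    The anchor is the fragment's 5' end on its template strand: a Watson
    fragment spans ``[anchor, anchor + L)``, a Crick fragment
    ``[anchor - L + 1, anchor + 1)``.  Fragments are truncated at chromosome
    ends (shortened, and discarded only if shorter than
    ``min_fragment_length``); the discard count is logged and stored in
    ``result.attrs["n_discarded"]``.
    """
    if n_cells < 1 or fragments_per_cell < 1:
        raise ValueError("n_cells and fragments_per_cell must be positive")
    rng = np.random.default_rng(seed)
    chroms = model.chromosomes
    lengths_bp = np.array([model.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_prob = lengths_bp / lengths_bp.sum()

    out_chrom: list[np.ndarray] = []
    out_start: list[np.ndarray] = []
    out_end: list[np.ndarray] = []
    out_strand: list[np.ndarray] = []
    n_discarded = 0

    for _ in range(n_cells):
        cell = simulate_cell(model, rng, origin_jitter_sd)
        ci = rng.choice(len(chroms), size=fragments_per_cell, p=chrom_prob)
        anchors = (rng.random(fragments_per_cell) * lengths_bp[ci]).astype(int)
        frag_len = model.fragment_length_model.sample(fragments_per_cell, rng)
        for k, chrom in enumerate(chroms):
            sel = ci == k
            if not sel.any():
                continue
            a = anchors[sel]
            L = frag_len[sel]
            direction = _fork_direction(cell.fired_positions[chrom], a, rng)
            watson = direction == LEFTWARD
            start = np.where(watson, a, a - L + 1)
            end = np.where(watson, a + L, a + 1)
            np.clip(start, 0, model.chrom_sizes[chrom], out=start)
            np.clip(end, 0, model.chrom_sizes[chrom], out=end)
            keep = (end - start) >= min_fragment_length
            n_discarded += int((~keep).sum())
            out_chrom.append(np.full(int(keep.sum()), chrom, dtype=object))
            out_start.append(start[keep])
            out_end.append(end[keep])
            out_strand.append(np.where(watson[keep], WATSON, CRICK))

    frags = pd.DataFrame(
        {
            "chrom": np.concatenate(out_chrom),
            "start": np.concatenate(out_start).astype(int),
            "end": np.concatenate(out_end).astype(int),
            "strand": np.concatenate(out_strand),
        }
    )
    frags.attrs["n_discarded"] = n_discarded
    frags.attrs["n_requested"] = n_cells * fragments_per_cell
    if n_discarded:
        logger.info("discarded %d end-truncated fragments (< %d bp)",
                    n_discarded, min_fragment_length)
    return validate_fragments(frags)


# ---------------------------------------------------------------------------
# exact strand-bias oracle

def expected_watson_fraction(model: GenomeModel, chrom: str,
                             position: int | np.ndarray) -> np.ndarray | float:
    """Exact population Watson-strand fraction at one or more positions.

    Enumerates every firing combination of the chromosome's origins, weights
    it by its probability renormalized to exclude the all-unfired event
    (matching the simulator's rejection conditioning), and scores the
    indicator that the nearest fired origin lies to the *right* of the
    position (leftward fork => Watson fragment); an exact distance tie
    contributes 1/2.  Limited to ``MAX_ENUMERATION_ORIGINS`` origins.
    """
    pos_arr = np.atleast_1d(np.asarray(position, dtype=float))
    origins = model.origin_positions[chrom].astype(float)
    eff = model.origin_efficiencies[chrom]
    k = len(origins)
    if k > MAX_ENUMERATION_ORIGINS:
        raise EnumerationLimitError(
            f"{chrom} has {k} origins; exact enumeration is limited to "
            f"{MAX_ENUMERATION_ORIGINS}"
        )
    total = np.zeros(len(pos_arr))
    norm = 0.0
    d = np.abs(pos_arr[:, None] - origins[None, :])        # (P, k)
    is_right = origins[None, :] > pos_arr[:, None]
    is_left = origins[None, :] < pos_arr[:, None]
    chunk = 1 << 14
    n_combos = 1 << k
    bits = np.arange(k)
    for lo in range(0, n_combos, chunk):
        codes = np.arange(lo, min(lo + chunk, n_combos))
        F = (codes[:, None] >> bits[None, :]) & 1            # (C, k) in {0,1}
        Fb = F.astype(bool)
        w = np.prod(np.where(Fb, eff[None, :], 1.0 - eff[None, :]), axis=1)
        live = (w > 0) & Fb.any(axis=1)
        if not live.any():
            continue
        Fb = Fb[live]
        w = w[live]
        norm += w.sum()
        # nearest fired distance on each side, per position x combo
        dL = np.where(Fb[None, :, :] & is_left[:, None, :], d[:, None, :], np.inf)
        dL = dL.min(axis=2)
        dR = np.where(Fb[None, :, :] & is_right[:, None, :], d[:, None, :], np.inf)
        dR = dR.min(axis=2)
        at = (Fb[None, :, :] & (d[:, None, :] == 0)).any(axis=2)
        watson = np.where(at | (dR == dL), 0.5, (dR < dL).astype(float))
        total += watson @ w
    result = total / norm
    return float(result[0]) if np.isscalar(position) else result


def conditional_firing_probability(model: GenomeModel, chrom: str) -> np.ndarray:
    """Per-origin firing frequency under the >=1-firing rejection condition.

    ``P(origin i fires | >=1 fires) = e_i / (1 - prod_j (1 - e_j))`` because
    firing draws are independent and conditioning only removes the all-unfired
    event, in which no origin fires.
    """
    eff = model.origin_efficiencies[chrom]
    p_none = np.prod(1.0 - eff)
    return eff / (1.0 - p_none)


# ---------------------------------------------------------------------------
# ancillary data: ChIP peaks and the embryonic time course

def simulate_chip_peaks(
    model: GenomeModel,
    intensity_slope: float = 8.0,
    baseline_fold: float = 2.0,
    noise_sd: float = 0.5,
    background_peak_rate: float = 5.0,
    background_fold_range: tuple[float, float] = (1.0, 3.0),
    center_jitter_sd: float = 500.0,
    peak_width: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Enhancer-mark ChIP peaks whose intensity scales with origin efficiency.

    One peak per origin, centre jittered by ``center_jitter_sd`` bp, with
    fold-enrichment ``baseline_fold + intensity_slope * efficiency + noise``
    floored at 1; plus ``background_peak_rate`` peaks/Mb placed uniformly with
    low fold-enrichment.
    """
    if background_peak_rate < 0 or noise_sd < 0 or center_jitter_sd < 0:
        raise ValueError("rates and noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    half = peak_width // 2
    for chrom in model.chromosomes:
        length = model.chrom_sizes[chrom]
        pos = model.origin_positions[chrom]
        eff = model.origin_efficiencies[chrom]
        centers = pos + rng.normal(0.0, center_jitter_sd, size=len(pos))
        centers = np.clip(np.rint(centers), half, length - half).astype(int)
        fold = baseline_fold + intensity_slope * eff
        if noise_sd > 0:
            fold = fold + rng.normal(0.0, noise_sd, size=len(pos))
        fold = np.maximum(fold, 1.0)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": centers - half, "end": centers + half,
            "name": [f"{chrom}_origin_peak_{i}" for i in range(len(pos))],
            "fold_enrichment": fold, "summit": half, "is_background": False,
        }))
        n_bg = rng.poisson(background_peak_rate * length / 1e6)
        if n_bg:
            bg_centers = rng.integers(half, length - half, size=n_bg)
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": bg_centers - half, "end": bg_centers + half,
                "name": [f"{chrom}_bg_peak_{i}" for i in range(n_bg)],
                "fold_enrichment": rng.uniform(*background_fold_range, size=n_bg),
                "summit": half, "is_background": True,
            }))
    peaks = pd.concat(rows, ignore_index=True)
    return peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_timecourse(
    model: GenomeModel,
    n_genes: int = 2000,
    n_timepoints: int = 50,
    coupling_window: int = 25_000,
    class_proportions: tuple[float, float, float] = (0.40, 0.35, 0.25),
    orientation_bias: float = 0.5,
    noise_sd: float = 0.3,
    distal_min: int = 15_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic whole-embryo expression time course with origin coupling.

    Three gene classes (proportions = ``class_proportions``):

    * ``maternal`` — transcripts deposited in the oocyte: expression decays
      exponentially from time point 1, so the mass sits in points 1-5;
      genomic positions uniform.
    * ``early_zygotic`` — first-wave zygotic genes: placed within
      ``coupling_window`` of an origin, preferentially near high-efficiency
      origins (origin chosen with probability proportional to efficiency);
      unimodal expression peaking in points 9-25.
    * ``late_zygotic`` — morphogenesis-phase genes: placed at least
      ``distal_min`` from any origin; expression peaking from point ~40 on.

    Within the coupling window, gene strand is biased co-directionally with
    the predominant fork direction: genes left of an origin preferentially
    ``-`` (leftward-transcribed), right of it ``+``, with
    ``P(co-directional) = 0.5 + orientation_bias/2``.  Profiles carry
    multiplicative log-normal noise of scale ``noise_sd``.
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be at least 10")
    if abs(sum(class_proportions) - 1.0) > 1e-9 or min(class_proportions) < 0:
        raise ValueError("class_proportions must be non-negative and sum to 1")
    if not 0 <= orientation_bias <= 1:
        raise ValueError("orientation_bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = model.chromosomes
    lengths = np.array([model.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_prob = lengths / lengths.sum()
    all_pos = {c: model.origin_positions[c] for c in chroms}
    all_eff = {c: model.origin_efficiencies[c] for c in chroms}

    n_mat = int(round(class_proportions[0] * n_genes))
    n_early = int(round(class_proportions[1] * n_genes))
    n_late = n_genes - n_mat - n_early
    classes = (["maternal"] * n_mat + ["early_zygotic"] * n_early
               + ["late_zygotic"] * n_late)

    gene_chrom = np.empty(n_genes, dtype=object)
    anchor = np.zeros(n_genes, dtype=int)

    # flat origin table weighted by efficiency, for early-zygotic placement
    flat_chrom = np.concatenate([[c] * len(all_pos[c]) for c in chroms])
    flat_pos = np.concatenate([all_pos[c] for c in chroms])
    flat_eff = np.concatenate([all_eff[c] for c in chroms])
    origin_weight = flat_eff / flat_eff.sum()

    for i, cls in enumerate(classes):
        if cls == "early_zygotic":
            j = rng.choice(len(flat_pos), p=origin_weight)
            c = str(flat_chrom[j])
            offset = rng.normal(0.0, coupling_window / 3.0)
            offset = float(np.clip(offset, -coupling_window, coupling_window))
            gene_chrom[i] = c
            anchor[i] = int(np.clip(flat_pos[j] + offset, 0,
                                    model.chrom_sizes[c] - 1))
        elif cls == "late_zygotic":
            while True:
                ci = rng.choice(len(chroms), p=chrom_prob)
                c = chroms[ci]
                a = int(rng.integers(0, model.chrom_sizes[c]))
                if np.abs(all_pos[c] - a).min() >= distal_min:
                    break
            gene_chrom[i] = c
            anchor[i] = a
        else:  # maternal: uniform
            ci = rng.choice(len(chroms), p=chrom_prob)
            c = chroms[ci]
            gene_chrom[i] = c
            anchor[i] = int(rng.integers(0, model.chrom_sizes[c]))

    gene_len = np.clip(
        np.rint(rng.lognormal(np.log(1500.0), 0.6, size=n_genes)), 200, 20_000
    ).astype(int)
    start = np.maximum(anchor - gene_len // 2, 0)
    end = start + gene_len

    # co-directional strand bias within the coupling window
    strand = np.empty(n_genes, dtype=object)
    for i in range(n_genes):
        c = gene_chrom[i]
        deltas = anchor[i] - all_pos[c]
        j = int(np.argmin(np.abs(deltas)))
        if abs(deltas[j]) <= coupling_window and deltas[j] != 0:
            codirectional = CRICK if deltas[j] < 0 else WATSON
            other = WATSON if codirectional == CRICK else CRICK
            p = 0.5 + orientation_bias / 2.0
            strand[i] = codirectional if rng.random() < p else other
        else:
            strand[i] = WATSON if rng.random() < 0.5 else CRICK

    t = np.arange(1, n_timepoints + 1, dtype=float)
    profiles = np.zeros((n_genes, n_timepoints))
    for i, cls in enumerate(classes):
        if cls == "maternal":
            base = np.exp(-(t - 1.0) / 2.5)
        elif cls == "early_zygotic":
            center = rng.uniform(11.0, 22.0)
            base = np.exp(-0.5 * ((t - center) / 3.5) ** 2)
        else:
            center = rng.uniform(0.84 * n_timepoints, 0.96 * n_timepoints)
            base = np.exp(-0.5 * ((t - center) / 3.5) ** 2)
        noise = rng.lognormal(0.0, noise_sd, size=n_timepoints) if noise_sd > 0 else 1.0
        profiles[i] = base * noise

    tc = pd.DataFrame({
        "gene_id": [f"gene_{i:05d}" for i in range(n_genes)],
        "chrom": gene_chrom, "start": start, "end": end, "strand": strand,
        "class": classes,
    })
    for j in range(n_timepoints):
        tc[f"t{j + 1}"] = profiles[:, j]
    return tc


# ---------------------------------------------------------------------------
# recovery scoring against ground truth

def score_recovery(
    calls: pd.DataFrame,
    model: GenomeModel,
    match_window: int = 5000,
    min_efficiency: float = 0.5,
    min_isolation: int = 30_000,
) -> dict:
    """Score origin calls against the simulator's ground truth.

    Calls and true origins are matched greedily by distance, each used at
    most once, within ``match_window`` bp.  Returns recall over the
    well-resolved truth subset (efficiency >= ``min_efficiency`` and
    nearest-neighbour distance >= ``min_isolation``), the false-call rate
    (unmatched calls / all calls), the median absolute midpoint error of
    matched pairs, and the matched (true efficiency, estimated efficiency)
    pairs for rank-recovery analysis.
    """
    truth = model.origins_frame()
    nn = np.full(len(truth), np.inf)
    for chrom in model.chromosomes:
        pos = model.origin_positions[chrom]
        if len(pos) > 1:
            gaps = np.diff(pos)
            d = np.minimum(np.r_[np.inf, gaps], np.r_[gaps, np.inf])
        else:
            d = np.array([np.inf])
        nn[truth.index[truth["chrom"] == chrom]] = d
    truth = truth.assign(nn_dist=nn)

    pairs = []  # (distance, call_idx, truth_idx)
    for chrom, sub in calls.groupby("chrom", sort=False):
        t_idx = truth.index[truth["chrom"] == chrom].to_numpy()
        if len(t_idx) == 0:
            continue
        t_pos = truth.loc[t_idx, "position"].to_numpy()
        for ci, mid in zip(sub.index, sub["midpoint"].to_numpy()):
            d = np.abs(t_pos - mid)
            for j in np.flatnonzero(d <= match_window):
                pairs.append((float(d[j]), ci, int(t_idx[j])))
    pairs.sort()
    used_calls: set = set()
    used_truth: set = set()
    matches = []
    for dist, ci, ti in pairs:
        if ci in used_calls or ti in used_truth:
            continue
        used_calls.add(ci)
        used_truth.add(ti)
        matches.append((dist, ci, ti))

    qualified = truth[(truth["efficiency"] >= min_efficiency)
                      & (truth["nn_dist"] >= min_isolation)]
    n_qual_recalled = sum(1 for _, _, ti in matches if ti in set(qualified.index))
    recall = n_qual_recalled / len(qualified) if len(qualified) else float("nan")
    false_rate = (len(calls) - len(matches)) / len(calls) if len(calls) else 0.0
    median_err = float(np.median([d for d, _, _ in matches])) if matches else float("nan")

    matched = pd.DataFrame(
        {
            "true_efficiency": [truth.loc[ti, "efficiency"] for _, _, ti in matches],
            "estimated_efficiency": [
                calls.loc[ci, "efficiency"] if "efficiency" in calls.columns else np.nan
                for _, ci, _ in matches
            ],
            "distance": [d for d, _, _ in matches],
        }
    )
    return {
        "recall": recall,
        "n_qualified": int(len(qualified)),
        "false_call_rate": false_rate,
        "n_calls": int(len(calls)),
        "n_matched": len(matches),
        "median_midpoint_error": median_err,
        "matched": matched,
    }
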