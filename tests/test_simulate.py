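"""Simulator unit and property tests: determinism, firing logic, strand
assignment, the exact enumeration oracle, and the ancillary generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from okmap import simulate
from okmap.core import CRICK, WATSON
from okmap.simulate import (
    EnumerationLimitError,
    FragmentLengthModel,
    GenomeModel,
    conditional_firing_probability,
    expected_watson_fraction,
    simulate_cell,
    simulate_chip_peaks,
    simulate_fragments,
    simulate_genome_model,
    simulate_timecourse,
)


def single_origin_model(position=500_000, efficiency=1.0, length=1_000_000):
    return GenomeModel(
        chrom_sizes={"chrT": length},
        origin_positions={"chrT": np.array([position])},
        origin_efficiencies={"chrT": np.array([efficiency])},
    )


def two_origin_model(e1=0.8, e2=0.4, p1=250_000, p2=750_000):
    return GenomeModel(
        chrom_sizes={"chrT": 1_000_000},
        origin_positions={"chrT": np.array([p1, p2])},
        origin_efficiencies={"chrT": np.array([e1, e2])},
    )


class TestGenomeModel:
    def test_fixed_distribution_sets_all_probabilities(self):
        m = simulate_genome_model(1, 1_000_000, 25, ("fixed", (0.5,)), seed=7)
        assert len(m.origin_positions["chrI"]) == 25
        assert np.all(m.origin_efficiencies["chrI"] == 0.5)

    def test_seed_determinism(self):
        a = simulate_genome_model(2, 5_000_000, 125, ("beta", (2, 2)), seed=1)
        b = simulate_genome_model(2, 5_000_000, 125, ("beta", (2, 2)), seed=1)
        for c in a.chromosomes:
            np.testing.assert_array_equal(a.origin_positions[c],
                                          b.origin_positions[c])
            np.testing.assert_array_equal(a.origin_efficiencies[c],
                                          b.origin_efficiencies[c])

    def test_beta_median_matches_distribution(self):
        m = simulate_genome_model(1, 1_000_000, 25, ("beta", (2, 2)), seed=1)
        # beta(2,2) median is 0.5
        assert abs(np.median(m.origin_efficiencies["chrI"]) - 0.5) <= 0.1

    def test_positions_strictly_increasing(self):
        for seed in range(5):
            m = simulate_genome_model(1, 2_000_000, 50, ("beta", (2, 2)),
                                      seed=seed)
            assert np.all(np.diff(m.origin_positions["chrI"]) > 0)

    @pytest.mark.parametrize("kwargs", [
        dict(n_chrom=0), dict(n_origins=0), dict(chrom_length=-5),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_chrom=1, chrom_length=1_000_000, n_origins=5)
        base.update(kwargs)
        with pytest.raises(ValueError):
            simulate_genome_model(**base)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError, match="no origins"):
            GenomeModel(chrom_sizes={"c": 1000},
                        origin_positions={"c": np.array([])},
                        origin_efficiencies={"c": np.array([])})
        with pytest.raises(ValueError, match="efficiency"):
            single_origin_model(efficiency=1.5)


class TestSimulateCell:
    def test_certain_origin_always_fires_and_directions_split(self):
        m = single_origin_model(position=600_000, efficiency=1.0)
        cell = simulate_cell(m, seed=3)
        assert cell.fired_positions["chrT"].tolist() == [600_000.0]
        pos = np.array([100_000, 599_000, 601_000, 900_000])
        d = cell.fork_direction("chrT", pos, np.random.default_rng(0))
        assert d.tolist() == [simulate.LEFTWARD, simulate.LEFTWARD,
                              simulate.RIGHTWARD, simulate.RIGHTWARD]

    def test_two_certain_origins_flip_at_midpoint(self):
        m = two_origin_model(1.0, 1.0, 200_000, 800_000)
        cell = simulate_cell(m, seed=0)
        d = cell.fork_direction("chrT", np.array([499_999, 500_001]),
                                np.random.default_rng(0))
        assert d.tolist() == [simulate.RIGHTWARD, simulate.LEFTWARD]

    def test_firing_frequency_matches_rejection_conditioned_enumeration(self):
        # independent oracle: enumerate the 2^2 firing combinations by hand
        e1, e2 = 0.8, 0.4
        m = two_origin_model(e1, e2)
        p_any = 1 - (1 - e1) * (1 - e2)
        expected = np.array([e1 / p_any, e2 / p_any])
        np.testing.assert_allclose(
            conditional_firing_probability(m, "chrT"), expected
        )
        rng = np.random.default_rng(42)
        n = 10_000
        counts = np.zeros(2)
        for _ in range(n):
            fired = simulate_cell(m, rng).fired_positions["chrT"]
            counts[0] += 250_000 in fired
            counts[1] += 750_000 in fired
        freq = counts / n
        sd = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) <= 3 * sd)


class TestSimulateFragments:
    def test_strand_split_around_certain_origin(self):
        m = single_origin_model(position=500_000, efficiency=1.0)
        frags = simulate_fragments(m, n_cells=50, fragments_per_cell=200, seed=5)
        watson = frags[frags["strand"] == WATSON]
        crick = frags[frags["strand"] == CRICK]
        # anchors: Watson 5' = start, Crick 5' = end - 1
        assert (watson["start"] < 500_000).all()
        assert (crick["end"] - 1 > 500_000).all()

    def test_count_conservation_including_discards(self):
        m = single_origin_model()
        frags = simulate_fragments(m, n_cells=20, fragments_per_cell=100, seed=1)
        assert len(frags) + frags.attrs["n_discarded"] == 20 * 100

    def test_seed_determinism(self):
        m = single_origin_model()
        a = simulate_fragments(m, 10, 50, seed=9)
        b = simulate_fragments(m, 10, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_lengths_respect_bounds_and_periodicity(self):
        flm = FragmentLengthModel()
        lengths = flm.sample(20_000, np.random.default_rng(0))
        assert lengths.min() >= flm.min_bp and lengths.max() <= flm.max_bp
        # histogram modes should sit near multiples of the nucleosome period
        hist, edges = np.histogram(lengths, bins=np.arange(100, 601, 4))
        centers = (edges[:-1] + edges[1:]) / 2
        for k in (1, 2, 3):
            window = np.abs(centers - k * flm.period) <= 2 * flm.jitter_sd
            far = np.abs(centers - k * flm.period) > 3 * flm.jitter_sd
            assert hist[window].max() > hist[(centers > (k - 0.5) * flm.period)
                                             & (centers < (k + 0.5) * flm.period)
                                             & far].max()

    def test_fragment_coordinates_valid(self):
        m = single_origin_model(length=200_000, position=100_000)
        frags = simulate_fragments(m, 50, 100, seed=3)
        assert (frags["start"] < frags["end"]).all()
        assert frags["start"].min() >= 0
        assert frags["end"].max() <= 200_000


class TestExpectedWatsonFraction:
    def test_sole_certain_origin(self):
        m = single_origin_model(position=500_000, efficiency=1.0)
        assert expected_watson_fraction(m, "chrT", 100_000) == 1.0
        assert expected_watson_fraction(m, "chrT", 900_000) == 0.0

    def test_midpoint_of_two_certain_origins_is_half(self):
        m = two_origin_model(1.0, 1.0, 200_000, 800_000)
        assert expected_watson_fraction(m, "chrT", 500_000) == 0.5

    def test_two_origin_hand_enumeration(self):
        # position x between origins, nearer the left one:
        # combos (renormalized to exclude the all-unfired case):
        #   both fire      p=e1*e2      nearest is left  -> Watson 0
        #   only left      p=e1*(1-e2)  nearest left     -> 0
        #   only right     p=(1-e1)*e2  nearest right    -> 1
        e1, e2 = 0.8, 0.4
        m = two_origin_model(e1, e2)
        x = 400_000  # 150 kb from left origin, 350 kb from right
        p_any = 1 - (1 - e1) * (1 - e2)
        expected = (1 - e1) * e2 / p_any
        assert expected_watson_fraction(m, "chrT", x) == pytest.approx(expected)

    def test_exact_tie_contributes_half(self):
        m = two_origin_model(1.0, 1.0, 200_000, 800_000)
        # renormalized: both always fire; position equidistant -> 1/2
        assert expected_watson_fraction(m, "chrT", 500_000) == 0.5

    def test_enumeration_limit(self):
        m = simulate_genome_model(1, 5_000_000, 25, ("fixed", (0.5,)), seed=0)
        with pytest.raises(EnumerationLimitError):
            expected_watson_fraction(m, "chrI", 1_000_000)

    def test_empirical_convergence(self, small_model):
        """Empirical Watson fraction from simulated cells matches the exact
        enumeration oracle within 3 binomial SDs in every probed window."""
        frags = simulate_fragments(small_model, n_cells=5000,
                                   fragments_per_cell=60, seed=21)
        chrom = small_model.chromosomes[0]
        anchors = np.where(frags["strand"] == WATSON, frags["start"],
                           frags["end"] - 1).astype(float)
        is_w = (frags["strand"] == WATSON).to_numpy()
        window = 10_000
        rng = np.random.default_rng(0)
        probes = rng.integers(window, 1_000_000 - window, size=50)
        for probe in probes:
            sel = np.abs(anchors - probe) <= window / 2
            n = int(sel.sum())
            if n < 20:
                continue
            grid = np.linspace(probe - window / 2, probe + window / 2, 11)
            p = float(np.mean(expected_watson_fraction(small_model, chrom, grid)))
            sd = np.sqrt(max(p * (1 - p), 1e-4) / n)
            assert abs(is_w[sel].mean() - p) <= 3 * sd + 1e-9


class TestChipPeaks:
    def test_zero_slope_zero_noise_uniform_folds(self):
        m = simulate_genome_model(1, 1_000_000, 10, ("beta", (2, 2)), seed=0)
        peaks = simulate_chip_peaks(m, intensity_slope=0.0, noise_sd=0.0,
                                    background_peak_rate=0.0, seed=1)
        assert peaks["fold_enrichment"].nunique() == 1

    def test_noiseless_rank_order_matches_efficiency(self):
        m = simulate_genome_model(1, 2_000_000, 20, ("beta", (2, 2)), seed=3)
        peaks = simulate_chip_peaks(m, noise_sd=0.0, background_peak_rate=0.0,
                                    seed=1)
        origin_peaks = peaks[~peaks["is_background"]].sort_values("name")
        eff = m.origin_efficiencies["chrI"]
        # names are indexed by origin order
        order = [int(n.rsplit("_", 1)[1]) for n in origin_peaks["name"]]
        r = spearmanr(eff[order], origin_peaks["fold_enrichment"]).statistic
        assert r == pytest.approx(1.0)

    def test_default_parameters_strong_rank_correlation(self):
        m = simulate_genome_model(2, 5_000_000, 125, ("beta", (2, 2)), seed=4)
        peaks = simulate_chip_peaks(m, seed=5)
        op = peaks[~peaks["is_background"]]
        eff = np.concatenate([m.origin_efficiencies[c] for c in m.chromosomes])
        by_name = {n: f for n, f in zip(op["name"], op["fold_enrichment"])}
        folds = [by_name[f"{c}_origin_peak_{i}"]
                 for c in m.chromosomes
                 for i in range(len(m.origin_positions[c]))]
        assert spearmanr(eff, folds).statistic >= 0.8

    def test_negative_rate_rejected(self):
        m = single_origin_model()
        with pytest.raises(ValueError):
            simulate_chip_peaks(m, background_peak_rate=-1.0)


class TestTimecourse:
    def test_all_maternal_peaks_early(self):
        m = simulate_genome_model(1, 2_000_000, 20, ("beta", (2, 2)), seed=0)
        tc = simulate_timecourse(m, n_genes=100,
                                 class_proportions=(1.0, 0.0, 0.0), seed=1)
        tcols = [f"t{i}" for i in range(1, 51)]
        assert (tc[tcols].to_numpy().argmax(axis=1) + 1 <= 5).all()

    def test_too_few_timepoints_rejected(self):
        m = single_origin_model()
        with pytest.raises(ValueError):
            simulate_timecourse(m, n_genes=10, n_timepoints=5)

    def test_late_genes_are_origin_distal(self):
        m = simulate_genome_model(1, 2_000_000, 20, ("beta", (2, 2)), seed=0)
        tc = simulate_timecourse(m, n_genes=200, seed=2)
        late = tc[tc["class"] == "late_zygotic"]
        pos = m.origin_positions["chrI"]
        anchors = ((late["start"] + late["end"]) // 2).to_numpy()
        for a in anchors:
            assert np.abs(pos - a).min() >= 15_000 - 10_000  # anchor shifts < len/2

    def test_seed_determinism(self):
        m = simulate_genome_model(1, 2_000_000, 20, ("beta", (2, 2)), seed=0)
        a = simulate_timecourse(m, n_genes=50, seed=7)
        b = simulate_timecourse(m, n_genes=50, seed=7)
        pd.testing.assert_frame_equal(a, b)
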