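import itertools
import math

import numpy as np
import pytest

from founderage.genmap import Marker, build_marker_map
from founderage.goldgar import (
    CI_CUTOFF_1LOD,
    AgeEstimate,
    GoldgarError,
    GoldgarModel,
    corrected_age,
    dataset_loglik,
    haplotype_loglik,
    mle_age,
)
from founderage.haplotypes import (
    AlleleFrequencies,
    AncestralHaplotype,
    HaplotypeDistribution,
    allele_frequencies,
)

from conftest import simulate_conditioned


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive enumeration of event placements.
#
# For each flank, every interval either never recombines in g meioses or has
# its first recombination at a specific meiosis t; every marker still on the
# ancestral segment either never mutates or first mutates at meiosis t toward
# a specific neighbouring allele. The oracle sums the probability of the
# observed alleles over this whole event lattice, sharing nothing with the
# scan implementation beyond the model definition.

def _emission_cases(marker, anc, mu, g):
    """[(allele, probability)] for an intact marker after g generations,
    enumerating the first-mutation meiosis explicitly."""
    cases = {anc: (1.0 - mu) ** g}
    if mu > 0.0:
        if marker.marker_type.endswith("_str"):
            j = marker.alleles.index(anc)
            targets = [
                marker.alleles[k]
                for k in (j - 1, j + 1)
                if 0 <= k < len(marker.alleles)
            ]
        else:
            targets = [a for a in marker.alleles if a != anc]
        for t in range(1, g + 1):
            p_first = (1.0 - mu) ** (t - 1) * mu
            for a in targets:
                cases[a] = cases.get(a, 0.0) + p_first / len(targets)
    return cases


def enumeration_loglik(hap, g, model):
    """Brute-force likelihood over all recombination/mutation placements."""
    mmap = model.marker_map
    hap = tuple(str(a) for a in hap)
    total = 1.0
    pop_all = 1.0
    for order in mmap.side_orders():
        k = len(order)
        if k == 0:
            continue
        side_total = 0.0
        # state per interval: 0 = never recombined, t in 1..g = first event
        for states in itertools.product(range(g + 1), repeat=k):
            prob = 1.0
            for pos, t in enumerate(states):
                th = mmap.theta_interval[order[pos]]
                prob *= (1.0 - th) ** g if t == 0 else (1.0 - th) ** (t - 1) * th
            # innermost interval with an event determines the breakpoint
            bp = k
            for pos, t in enumerate(states):
                if t != 0:
                    bp = pos
                    break
            for pos in range(bp):
                i = order[pos]
                cases = _emission_cases(
                    mmap.markers[i],
                    model.ancestral.alleles[i],
                    model.mu[i],
                    g,
                )
                prob *= cases.get(hap[i], 0.0)
            for pos in range(bp, k):
                i = order[pos]
                prob *= model.freqs.p_N(i, hap[i])
            side_total += prob
        total *= side_total
        for i in order:
            pop_all *= model.freqs.p_N(i, hap[i])
    if model.pi_recurrence > 0:
        total = (1 - model.pi_recurrence) * total + model.pi_recurrence * pop_all
    return math.log(total) if total > 0 else -math.inf


def _random_model(rng, n_markers, with_str=False, pi=0.0):
    markers = []
    positions = sorted(rng.choice(np.arange(2, 60) * 1e5, n_markers, replace=False))
    locus = float(rng.integers(1, 50)) * 1e4
    for i, pos in enumerate(positions):
        if with_str and i % 2 == 1:
            markers.append(
                Marker(f"s{i}", int(pos), "dinucleotide_str",
                       ("10", "12", "14"), float(rng.uniform(0.001, 0.01)))
            )
        else:
            markers.append(
                Marker(f"m{i}", int(pos), "snp", ("A", "B"),
                       float(rng.uniform(0.0, 0.005)))
            )
    mmap = build_marker_map(markers, int(locus))
    control, carrier = [], []
    anc_alleles = []
    for m in mmap.markers:
        f = rng.dirichlet(np.ones(len(m.alleles)) * 3)
        control.append({a: float(p) for a, p in zip(m.alleles, f)})
        carrier.append({a: float(p) for a, p in zip(m.alleles, f)})
        anc_alleles.append(m.alleles[int(rng.integers(len(m.alleles)))])
    freqs = AlleleFrequencies(control=control, carrier=carrier)
    anc = AncestralHaplotype(tuple(anc_alleles), np.ones(len(mmap)))
    return GoldgarModel(mmap, anc, freqs, pi_recurrence=pi)


def _random_hap(rng, model):
    return tuple(
        m.alleles[int(rng.integers(len(m.alleles)))]
        for m in model.marker_map.markers
    )


class TestHaplotypeLoglik:
    def test_age_zero_ancestral_is_certain(self, one_marker_scene):
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs, mu=np.array([0.0]))
        assert haplotype_loglik(("A",), 0, model) == 0.0

    def test_age_zero_mismatch_is_impossible(self, one_marker_scene):
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs, mu=np.array([0.0]))
        assert haplotype_loglik(("B",), 0, model) == -math.inf

    def test_one_marker_closed_form(self, one_marker_scene):
        # (1-theta)^g + (1-(1-theta)^g) p at g=10, theta=0.01, p=0.1
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs, mu=np.array([0.0]))
        got = math.exp(haplotype_loglik(("A",), 10, model))
        expected = 0.99**10 + (1 - 0.99**10) * 0.1
        assert got == pytest.approx(expected, abs=1e-12)
        assert round(got, 5) == 0.91394

    def test_two_marker_recombination_paths(self):
        # match at the inner marker, mismatch outside: either the segment
        # survives to marker 1 and is lost in interval 2, or it is lost in
        # interval 1 and both markers emit at population frequency
        markers = [
            Marker("m1", 1_000_000, "snp", ("A", "B"), 0.0),
            Marker("m2", 2_000_000, "snp", ("C", "D"), 0.0),
        ]
        mmap = build_marker_map(markers, 0, map_function="linear")
        anc = AncestralHaplotype(("A", "C"), np.ones(2))
        freqs = AlleleFrequencies(
            control=[{"A": 0.6, "B": 0.4}, {"C": 0.7, "D": 0.3}],
            carrier=[{"A": 1.0}, {"C": 1.0}],
        )
        model = GoldgarModel(mmap, anc, freqs, mu=np.zeros(2))
        s = 0.99**5
        expected = s * ((1 - s) * 0.3) + (1 - s) * 0.6 * 0.3
        got = math.exp(haplotype_loglik(("A", "D"), 5, model))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonincreasing_in_g_for_ancestral_hap(self, msh2_like_map):
        rng = np.random.default_rng(0)
        model = _random_model(rng, 3)
        model.mu[:] = 0.0
        anc_hap = model.ancestral.alleles
        curve = haplotype_loglik(anc_hap, np.arange(0.0, 40.0), model)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_intact_emissions_normalize(self):
        rng = np.random.default_rng(1)
        model = _random_model(rng, 3, with_str=True)
        for g in (0, 3, 17):
            for i, m in enumerate(model.marker_map.markers):
                total = 0.0
                for a in m.alleles:
                    match, coeff = model._intact_emission_terms(i, a)
                    keep = (1 - model.mu[i]) ** g
                    total += keep if match else coeff * (1 - keep)
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_unknown_allele_rejected(self, one_marker_scene):
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs)
        with pytest.raises(Exception):
            haplotype_loglik(("Z",), 3, model)

    def test_negative_age_rejected(self, one_marker_scene):
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs)
        with pytest.raises(GoldgarError):
            haplotype_loglik(("A",), -1, model)


class TestEnumerationOracle:
    @pytest.mark.parametrize("n_markers", [1, 2, 3])
    @pytest.mark.parametrize("g", [0, 1, 3, 5])
    def test_scan_matches_enumeration(self, n_markers, g):
        rng = np.random.default_rng(100 * n_markers + g)
        for rep in range(4):
            model = _random_model(rng, n_markers, with_str=(rep % 2 == 1))
            hap = _random_hap(rng, model)
            scan = haplotype_loglik(hap, g, model)
            brute = enumeration_loglik(hap, g, model)
            if math.isinf(scan):
                assert math.isinf(brute)
            else:
                assert scan == pytest.approx(brute, abs=1e-10)

    def test_scan_matches_enumeration_with_recurrence(self):
        rng = np.random.default_rng(42)
        model = _random_model(rng, 2, pi=0.05)
        hap = _random_hap(rng, model)
        assert haplotype_loglik(hap, 4, model) == pytest.approx(
            enumeration_loglik(hap, 4, model), abs=1e-10
        )


class TestDatasetLoglik:
    def test_single_carrier_reduces_to_haplotype(self, one_marker_scene):
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs, mu=np.array([0.0]))
        d = HaplotypeDistribution.certain("c", ("A",))
        assert dataset_loglik([d], 7, model) == haplotype_loglik(("A",), 7, model)

    def test_duplicated_carrier_doubles(self, one_marker_scene):
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs, mu=np.array([0.0]))
        d = HaplotypeDistribution.certain("c", ("A",))
        assert dataset_loglik([d, d], 7, model) == pytest.approx(
            2 * dataset_loglik([d], 7, model)
        )

    def test_mixture_is_log_of_average(self, one_marker_scene):
        mmap, anc, freqs = one_marker_scene
        model = GoldgarModel(mmap, anc, freqs, mu=np.array([0.0]))
        d = HaplotypeDistribution("c", [(("A",), 0.5), (("B",), 0.5)])
        la = math.exp(haplotype_loglik(("A",), 7, model))
        lb = math.exp(haplotype_loglik(("B",), 7, model))
        assert dataset_loglik([d], 7, model) == pytest.approx(
            math.log(0.5 * la + 0.5 * lb)
        )


class TestMleAge:
    def test_all_ancestral_carriers_give_minimum_age(self, three_marker_map):
        freqs = AlleleFrequencies(
            control=[{"A": 0.5, "a": 0.5}, {"B": 0.5, "b": 0.5}, {"C": 0.5, "c": 0.5}],
            carrier=[{"A": 1.0}, {"B": 1.0}, {"C": 1.0}],
        )
        anc = AncestralHaplotype(("A", "B", "C"), np.ones(3))
        model = GoldgarModel(three_marker_map, anc, freqs, mu=np.zeros(3))
        dists = [
            HaplotypeDistribution.certain(f"c{i}", ("A", "B", "C")) for i in range(5)
        ]
        est = mle_age(dists, model, 0, 50)
        assert est.g_hat == 0
        assert "maximum_at_boundary" in est.flags

    def test_single_point_grid_degenerate(self, three_marker_map):
        freqs = AlleleFrequencies(
            control=[{"A": 0.5, "a": 0.5}, {"B": 0.5, "b": 0.5}, {"C": 0.5, "c": 0.5}],
            carrier=[{"A": 1.0}, {"B": 1.0}, {"C": 1.0}],
        )
        anc = AncestralHaplotype(("A", "B", "C"), np.ones(3))
        model = GoldgarModel(three_marker_map, anc, freqs, mu=np.zeros(3))
        d = [HaplotypeDistribution.certain("c", ("A", "B", "C"))]
        est = mle_age(d, model, 7, 7)
        assert (est.g_hat, est.ci_low, est.ci_high) == (7, 7, 7)

    def test_recovery_and_coverage_on_star_data(self, msh2_like_map):
        # given the true ancestral haplotype, the likelihood-ratio CI is
        # approximately calibrated on star-genealogy data
        cover = 0
        ghats = []
        n = 60
        for s in range(n):
            ds, truth, _pool = simulate_conditioned(
                msh2_like_map, g_true=20, r=1.5, n_cases=50, n_controls=109,
                seed=40_000 + 13 * s, genealogy="star",
            )
            freqs = allele_frequencies(
                ds.control_haplotypes, ds.carriers, msh2_like_map
            )
            anc = AncestralHaplotype(truth.ancestral_alleles, np.ones(19))
            est = mle_age(ds.carriers, GoldgarModel(msh2_like_map, anc, freqs), 0, 120)
            ghats.append(est.g_hat)
            cover += est.ci_low <= 20 <= est.ci_high
        assert cover >= round(0.85 * n)
        assert abs(np.median(ghats) - 20) <= 3

    def test_lod_interval_wider_than_chi_square(self, msh2_like_map):
        ds, truth, _pool = simulate_conditioned(
            msh2_like_map, g_true=20, r=1.5, n_cases=50, n_controls=100,
            seed=55_000, genealogy="star",
        )
        freqs = allele_frequencies(ds.control_haplotypes, ds.carriers, msh2_like_map)
        anc = AncestralHaplotype(truth.ancestral_alleles, np.ones(19))
        model = GoldgarModel(msh2_like_map, anc, freqs)
        a = mle_age(ds.carriers, model, 0, 120)
        b = mle_age(ds.carriers, model, 0, 120, ci_cutoff=CI_CUTOFF_1LOD)
        assert b.ci_low <= a.ci_low and b.ci_high >= a.ci_high


class TestCorrectedAge:
    @pytest.mark.parametrize(
        "g_hat, delta, expected",
        [(9, 24.31, 33.31), (17, 24.31, 41.31), (15, 0.0, 15.0)],
    )
    def test_additive_transfer(self, g_hat, delta, expected):
        est = AgeEstimate(
            method="goldgar", g_hat=g_hat, ci_low=1, ci_high=70,
            loglik_at_max=-10.0, flags=("ci_low_at_boundary",),
        )
        out = corrected_age(est, delta)
        assert out.g_corrected == pytest.approx(expected)
        assert out.ci_corrected == (1 + delta, 70 + delta)
        assert out.flags == est.flags  # boundary rendering preserved

    def test_boundary_rendering(self):
        est = AgeEstimate(
            method="goldgar", g_hat=9, ci_low=1, ci_high=124,
            loglik_at_max=-10.0, flags=("ci_low_at_boundary",),
        )
        assert est.format_ci() == "[<= 1, 124]"
        out = corrected_age(est, 23.31)
        assert out.format_ci(corrected=True) == "[<= 24.31, 147.31]"

    def test_negative_correction_rejected(self):
        est = AgeEstimate("goldgar", 5, 1, 9, -1.0)
        with pytest.raises(GoldgarError):
            corrected_age(est, -2.0)
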