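"""Binding isotherm, FRET ratio, stoichiometry, ATPase and statistics."""

import numpy as np
import pytest
from scipy import optimize as opt
from scipy import stats

from recombikit import biochem, synthgen
from recombikit.biochem import (
    BindingTitration,
    Chromatogram,
    EmissionSpectrum,
    TlcAssay,
    atpase_hydrolysis,
    compare_groups,
    fit_binding_isotherm,
    fret_emission_ratio,
    integrate_nucleotide_peaks,
    nucleotide_stoichiometry,
    protein_concentration,
    quadratic_binding_model,
)


def mass_balance_oracle(x, L, kd, a_min, a_max):
    """Independent 1:1 equilibrium solution: solve for bound probe by root
    finding on the mass balance, not via the closed-form quadratic."""
    if x == 0:
        return a_min

    def f(c):  # c = bound probe concentration
        return (x - c) * (L - c) - kd * c

    c = opt.brentq(f, 0.0, min(x, L))
    return a_min + (a_max - a_min) * c / L


class TestQuadraticBindingModel:
    def test_no_protein_gives_a_min(self):
        assert quadratic_binding_model(0.0, 0.05, 0.5, 0.07, 0.2) == pytest.approx(0.07)

    def test_stoichiometric_limit(self):
        # kd = 0 with x = L: all probe bound, discriminant exactly zero
        assert quadratic_binding_model(0.05, 0.05, 0.0, 0.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("x,kd", [(0.16, 0.16), (0.05, 1.0), (2.0, 0.3)])
    def test_matches_mass_balance_root_oracle(self, x, kd):
        got = quadratic_binding_model(x, 0.05, kd, 0.0, 1.0)
        want = mass_balance_oracle(x, 0.05, kd, 0.0, 1.0)
        assert got == pytest.approx(want, rel=1e-10)

    def test_printed_example_value(self):
        # frozen from the mass-balance oracle at x = kd = 0.16, L = 0.05
        assert quadratic_binding_model(0.16, 0.05, 0.16, 0.0, 1.0) == pytest.approx(
            0.4612, abs=1e-4)

    def test_monotone_and_bounded(self):
        x = np.logspace(-4, 2, 200)
        y = quadratic_binding_model(x, 0.05, 0.3, 0.05, 0.25)
        assert np.all(np.diff(y) >= -1e-12)
        assert y.min() >= 0.05 - 1e-12 and y.max() <= 0.25 + 1e-12

    def test_hyperbolic_limit(self):
        # L << K_D: quadratic converges to the Langmuir hyperbola
        kd, L = 1.0, 0.01
        x = np.logspace(-3, 2, 60)
        quad = quadratic_binding_model(x, L, kd, 0.0, 1.0)
        hyp = x / (x + kd)
        assert np.max(np.abs(quad - hyp) / np.maximum(hyp, 1e-9)) < 0.01

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            quadratic_binding_model(1.0, 0.0, 0.5, 0, 1)
        with pytest.raises(ValueError):
            quadratic_binding_model(-1.0, 0.05, 0.5, 0, 1)


class TestFitBindingIsotherm:
    def test_noise_free_recovery(self):
        t, _ = synthgen.simulate_titration(0.5, noise_sd=0.0, seed=0)
        fit = fit_binding_isotherm(t)
        assert fit.converged
        assert fit.kd_uM == pytest.approx(0.5, rel=1e-6)
        assert fit.a_min == pytest.approx(0.05, rel=1e-4)
        assert fit.a_max == pytest.approx(0.22, rel=1e-4)

    def test_beats_log_grid_oracle(self):
        t, _ = synthgen.simulate_titration(0.3, noise_sd=0.01, seed=7)
        fit = fit_binding_isotherm(t)
        x, y, L = t.protein_concs_uM, t.anisotropy, t.probe_conc_uM
        best = np.inf
        for kd in np.logspace(-3, 2, 200):
            frac = (quadratic_binding_model(x, L, kd, 0.0, 1.0))
            design = np.column_stack([1.0 - frac, frac])
            coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = float(((design @ coef - y) ** 2).sum())
            best = min(best, sse)
        assert fit.residual_sse <= best + 1e-12

    def test_flat_data_flags_nonconvergence(self):
        t = BindingTitration(np.logspace(-3, 1, 10), np.full(10, 0.08), 0.05)
        fit = fit_binding_isotherm(t)
        assert not fit.converged

    def test_ci_coverage_near_nominal(self):
        hits = total = 0
        for s in range(200):
            t, _ = synthgen.simulate_titration(0.5, noise_sd=0.005, seed=s)
            fit = fit_binding_isotherm(t)
            if fit.converged:
                total += 1
                hits += fit.ci95_kd[0] <= 0.5 <= fit.ci95_kd[1]
        assert total >= 190
        assert 0.90 <= hits / total <= 0.99


class TestFretEmissionRatio:
    def test_simple_ratio(self):
        w = np.arange(550, 801)
        inten = np.ones(w.size)
        inten[w == 555] = 100.0
        inten[w == 647] = 30.0
        s = EmissionSpectrum(w, inten)
        assert fret_emission_ratio(s) == pytest.approx(0.30)

    def test_acceptor_gain_doubles_ratio(self):
        w = np.arange(550.0, 801.0)
        donor = 100 * np.exp(-0.5 * ((w - 570) / 15) ** 2)
        acc = np.where(w > 610, 40 * np.exp(-0.5 * ((w - 660) / 30) ** 2), 0.0)
        base = EmissionSpectrum(w, donor + acc)
        gained = EmissionSpectrum(w, donor + 2 * acc)
        r0, r1 = fret_emission_ratio(base), fret_emission_ratio(gained)
        assert r1 == pytest.approx(2 * r0, rel=1e-4)

    def test_zero_donor_errors(self):
        w = np.arange(550.0, 801.0)
        inten = np.ones(w.size)
        inten[w == 555] = 0.0
        with pytest.raises(ValueError, match="donor"):
            fret_emission_ratio(EmissionSpectrum(w, inten))


class TestProteinConcentration:
    def test_zero_absorbance(self):
        assert protein_concentration(0.0, 4) == 0.0

    def test_beer_lambert_printed_epsilons(self):
        # 0.08978 / (80220 + 4 x 2390) = 1.000 uM
        assert protein_concentration(0.08978, 4) == pytest.approx(1.000, abs=5e-4)

    def test_more_nucleotides_means_lower_concentration(self):
        assert protein_concentration(0.1, 4) < protein_concentration(0.1, 3)


class TestChromatogramIntegration:
    WINDOWS = {"ADP": (6.0, 7.0), "ATP": (8.5, 9.5)}
    STD = {"ADP": [(1.0, 1.0), (2.0, 2.0)], "ATP": [(1.0, 1.0), (2.0, 2.0)]}

    def test_flat_trace_zero_areas(self):
        t = np.arange(0, 15, 0.01)
        table = integrate_nucleotide_peaks(Chromatogram(t, np.ones(t.size)),
                                           self.WINDOWS, self.STD)
        assert np.allclose(table["area"], 0.0, atol=1e-9)

    def test_gaussian_area_closed_form(self):
        t = np.arange(0, 15, 0.001)
        y = np.exp(-0.5 * ((t - 6.5) / 0.1) ** 2)
        table = integrate_nucleotide_peaks(Chromatogram(t, y),
                                           {"ADP": (6.0, 7.0)}, self.STD)
        assert table["area"].iloc[0] == pytest.approx(0.1 * np.sqrt(2 * np.pi),
                                                      rel=1e-3)

    def test_standard_curve_recovers_concentration(self):
        chrom, _ = synthgen.simulate_chromatogram({"ADP": 3.7, "ATP": 1.2})
        std1, _ = synthgen.simulate_chromatogram({"ADP": 1.0, "ATP": 1.0})
        std2, _ = synthgen.simulate_chromatogram({"ADP": 5.0, "ATP": 5.0})
        standards = {}
        for std, conc in ((std1, 1.0), (std2, 5.0)):
            tab = integrate_nucleotide_peaks(std, self.WINDOWS, self.STD)
            for row in tab.itertuples():
                standards.setdefault(row.species, []).append((row.area, conc))
        table = integrate_nucleotide_peaks(chrom, self.WINDOWS, standards)
        got = dict(zip(table["species"], table["concentration_uM"]))
        assert got["ADP"] == pytest.approx(3.7, rel=1e-2)
        assert got["ATP"] == pytest.approx(1.2, rel=1e-2)

    def test_window_outside_axis_errors(self):
        t = np.arange(0, 15, 0.01)
        with pytest.raises(ValueError, match="outside"):
            integrate_nucleotide_peaks(Chromatogram(t, np.ones(t.size)),
                                       {"ATP": (14.0, 16.0)}, self.STD)

    def test_stoichiometry_totals(self):
        chrom, _ = synthgen.simulate_chromatogram({"ADP": 1.9, "ATP": 2.1})
        table = integrate_nucleotide_peaks(chrom, self.WINDOWS, self.STD)
        res = nucleotide_stoichiometry(table, 1.0)
        assert res.total_nt == pytest.approx(sum(res.nt_per_complex.values()))


class TestAtpase:
    def test_no_adp_no_hydrolysis(self):
        res = atpase_hydrolysis(TlcAssay([0.0], [500.0]))
        assert res.percent_hydrolysis[0] == 0.0

    def test_equal_spots_fifty_percent(self):
        res = atpase_hydrolysis(TlcAssay([250.0], [250.0]))
        assert res.percent_hydrolysis[0] == pytest.approx(50.0)

    def test_scale_invariance(self):
        a = atpase_hydrolysis(TlcAssay([120.0, 30.0], [280.0, 370.0]))
        b = atpase_hydrolysis(TlcAssay([1200.0, 300.0], [2800.0, 3700.0]))
        assert np.allclose(a.percent_hydrolysis, b.percent_hydrolysis)

    def test_turnover_rate_units(self):
        # 40% of 15 uM in 30 min at 1 uM enzyme = 0.2 ATP/min/enzyme
        res = atpase_hydrolysis(TlcAssay([400.0], [600.0]),
                                atp_total_uM=15.0, enzyme_uM=1.0, time_min=30.0)
        assert res.rate_uM_per_min_per_uM[0] == pytest.approx(0.2)

    def test_both_spots_zero_errors(self):
        with pytest.raises(ValueError):
            atpase_hydrolysis(TlcAssay([0.0], [0.0]))


def exact_mw_enumeration(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating all group
    assignments of the pooled sample (distinct values assumed)."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(ga, gb):
        return sum(x > y for x in ga for y in gb) + 0.5 * sum(
            x == y for x in ga for y in gb)

    u_obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_mannwhitney_tiny_exact(self):
        res = compare_groups([1, 2], [3, 4], test="mannwhitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-6)

    @pytest.mark.parametrize("n1,n2,shift", [(4, 5, 1.0), (8, 8, 0.5), (3, 7, 2.0)])
    def test_exact_path_matches_enumeration_oracle(self, n1, n2, shift):
        rng = np.random.default_rng(n1 * 100 + n2)
        a = list(rng.normal(size=n1))
        b = list(rng.normal(size=n2) + shift)
        res = compare_groups(a, b, test="mannwhitney")
        assert res.note == "exact"
        assert res.p_value == pytest.approx(exact_mw_enumeration(a, b), abs=1e-9)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(30):
            a, b = rng.normal(size=8), rng.normal(size=8) + 0.7
            pe = stats.mannwhitneyu(a, b, method="exact").pvalue
            pa = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
            worst = max(worst, abs(pe - pa))
        assert worst <= 0.02

    def test_welch_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        res = compare_groups(a, b, test="t")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / 3 + vb / 3)
        t_hand = (a.mean() - b.mean()) / se
        dof = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), dof)
        assert res.statistic == pytest.approx(t_hand, rel=1e-9)
        assert res.p_value == pytest.approx(p_hand, rel=1e-6)

    def test_degenerate_variance_falls_back(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = compare_groups([1.0, 1.0], [2.0, 2.0], test="t")
        assert res.test == "mannwhitney"

    def test_auto_annotates_normality_without_switching(self):
        rng = np.random.default_rng(3)
        res = compare_groups(rng.normal(size=10), rng.normal(size=10) + 1,
                             test="auto")
        assert res.test == "welch-t"
        assert res.normality_p is not None and len(res.normality_p) == 2


class TestModelProperties:
    """Seeded property tests over the isotherm's full parameter range."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(kd=st.floats(0.0, 50.0), L=st.floats(1e-3, 1.0),
           x=st.floats(0.0, 200.0))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_isotherm_always_within_anisotropy_window(self, kd, L, x):
        y = quadratic_binding_model(x, L, kd, 0.05, 0.25)
        assert 0.05 - 1e-9 <= y <= 0.25 + 1e-9

    @given(kd=st.floats(1e-3, 10.0), L=st.floats(1e-3, 1.0),
           scale=st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_isotherm_monotone_in_protein_concentration(self, kd, L, scale):
        x = np.linspace(0.0, 20.0 * scale, 50)
        y = quadratic_binding_model(x, L, kd, 0.0, 1.0)
        assert np.all(np.diff(y) >= -1e-10)
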