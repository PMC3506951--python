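"""The exponential growth law, divergence profiles, classification, clustering."""

import itertools

import numpy as np
import pytest

from phscreen.errors import FitError, ValidationError
from phscreen.ph_growth_model import (
    CATEGORY_DECOUPLED,
    CATEGORY_SLOW,
    CATEGORY_WT,
    DivergenceProfile,
    WtResidualStats,
    classify_cohort,
    classify_mutant,
    cluster_profiles,
    cut_clusters,
    divergence_profile,
    fit_ph_growth,
    predict_mu,
    wildtype_correction_factor,
    wt_residual_stats,
)

A_TRUE, B_TRUE = -7.24, 0.73


class TestPredict:
    def test_printed_parameters_at_low_ph(self):
        # at pH_c 6.7 the law gives 0.18 / h
        assert predict_mu((A_TRUE, B_TRUE), 6.7) == pytest.approx(0.18, abs=0.005)

    def test_zero_exponent_gives_unity(self):
        assert predict_mu((A_TRUE, B_TRUE), 7.24) == pytest.approx(1.0, abs=1e-12)

    def test_early_exponential_value(self):
        assert predict_mu((A_TRUE, B_TRUE), 7.0) == pytest.approx(0.469, abs=5e-4)

    def test_log_mu_is_affine_with_slope_one_over_b(self):
        grid = np.linspace(6.0, 7.5, 50)
        logmu = np.log10(predict_mu((A_TRUE, B_TRUE), grid))
        slopes = np.diff(logmu) / np.diff(grid)
        np.testing.assert_allclose(slopes, 1.0 / B_TRUE, atol=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(5.0, 8.0, 100)
        mu = predict_mu((A_TRUE, B_TRUE), grid)
        assert np.all(np.diff(mu) > 0)


class TestFit:
    def test_noiseless_roundtrip_recovers_parameters(self):
        ph = np.linspace(6.5, 7.2, 20)
        mu = predict_mu((A_TRUE, B_TRUE), ph)
        fit = fit_ph_growth(ph, mu)
        assert fit.a == pytest.approx(A_TRUE, abs=1e-9)
        assert fit.b == pytest.approx(B_TRUE, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        ph = np.array([6.6, 7.1])
        mu = predict_mu((A_TRUE, B_TRUE), ph)
        fit = fit_ph_growth(ph, mu)
        assert fit.a == pytest.approx(A_TRUE, abs=1e-9)
        assert fit.r2 == 1.0

    def test_noisy_estimate_within_three_standard_errors(self, rng):
        ph = rng.uniform(6.5, 7.2, 500)
        logmu = (ph + A_TRUE) / B_TRUE + rng.normal(0, 0.05, 500)
        fit = fit_ph_growth(ph, 10.0 ** logmu)
        assert abs(fit.a - A_TRUE) < 3 * fit.se_a
        assert abs(fit.b - B_TRUE) < 3 * fit.se_b

    def test_early_timepoints_excluded(self):
        ph = np.linspace(6.5, 7.2, 10)
        mu = predict_mu((A_TRUE, B_TRUE), ph)
        times = np.linspace(0.0, 9.0, 10)
        # corrupt the early points; they must not influence the fit
        mu_bad = mu.copy()
        mu_bad[times < 1.5] = 1e3
        fit = fit_ph_growth(ph, mu_bad, times=times, t_exclusion=1.5)
        assert fit.a == pytest.approx(A_TRUE, abs=1e-9)
        assert fit.fit_window[0] >= 1.5

    def test_nonpositive_mu_excluded_and_counted(self):
        ph = np.linspace(6.5, 7.2, 10)
        mu = predict_mu((A_TRUE, B_TRUE), ph)
        mu[3] = -0.01
        fit = fit_ph_growth(ph, mu)
        assert fit.n_points == 9
        assert fit.n_excluded == 1
        assert fit.a == pytest.approx(A_TRUE, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(FitError):
            fit_ph_growth([7.0, 7.1, 7.2], [-1.0, -1.0, -1.0])
        with pytest.raises(FitError):
            fit_ph_growth([7.0, 7.0, 7.0], [0.3, 0.4, 0.5])


def make_wt_cohort(rng, n=20, n_t=31, sd=0.03):
    """Wild-type curves scattered around the law on a t = 4..9 h grid."""
    times = np.linspace(4.0, 9.0, n_t)
    curves = []
    for _ in range(n):
        ph = 7.0 - 0.05 * (times - 4.0) + rng.normal(0, 0.01, n_t)
        mu = predict_mu((A_TRUE, B_TRUE), ph) + rng.normal(0, sd, n_t)
        curves.append((times, mu, ph))
    return times, curves


class TestDivergence:
    def test_exact_offset_curve_has_zero_profile(self):
        times = np.linspace(4.0, 9.0, 11)
        stats = WtResidualStats(times=times, mean=np.full(11, 0.01),
                                sd=np.full(11, 0.02), n_curves=10)
        ph = np.full(11, 7.0)
        mu = predict_mu((A_TRUE, B_TRUE), ph) + 0.01  # exactly wt_mean above
        prof = divergence_profile("s", times, mu, ph, (A_TRUE, B_TRUE),
                                  stats, window=(4.0, 9.0))
        np.testing.assert_allclose(prof.z_t, 0.0, atol=1e-9)

    def test_wildtype_replicate_self_normalises(self, rng):
        times, curves = make_wt_cohort(rng)
        stats = wt_residual_stats(curves, (A_TRUE, B_TRUE))
        profs = [divergence_profile(f"wt{i}", times, mu, ph,
                                    (A_TRUE, B_TRUE), stats)
                 for i, (_, mu, ph) in enumerate(curves)]
        for p in profs:
            assert abs(p.mean_z) < 3.0 / np.sqrt(len(p.z_t))

    def test_zero_wt_sd_masks_point_with_warning(self):
        times = np.linspace(4.0, 9.0, 5)
        sd = np.array([0.02, 0.0, 0.02, 0.02, 0.02])
        stats = WtResidualStats(times=times, mean=np.zeros(5), sd=sd,
                                n_curves=10)
        ph = np.full(5, 7.0)
        mu = predict_mu((A_TRUE, B_TRUE), ph)
        with pytest.warns(UserWarning, match="zero"):
            prof = divergence_profile("s", times, mu, ph, (A_TRUE, B_TRUE),
                                      stats)
        assert np.isnan(prof.z_t[1])
        assert np.isfinite(prof.z_t[0])

    def test_decoupled_strain_has_strongly_positive_profile(self, rng):
        # fixed 0.30/h growth while pH_c sits at 6.7: the law expects 0.18/h
        times, curves = make_wt_cohort(rng)
        stats = wt_residual_stats(curves, (A_TRUE, B_TRUE))
        ph = np.full(len(times), 6.7)
        mu = np.full(len(times), 0.30)
        prof = divergence_profile("dec", times, mu, ph, (A_TRUE, B_TRUE),
                                  stats)
        assert prof.mean_z > 3.0


class TestClassification:
    def test_refused_below_ten_wildtype_profiles(self, rng):
        times, curves = make_wt_cohort(rng, n=5)
        stats = wt_residual_stats(curves, (A_TRUE, B_TRUE))
        profs = [divergence_profile(f"wt{i}", times, mu, ph,
                                    (A_TRUE, B_TRUE), stats)
                 for i, (_, mu, ph) in enumerate(curves)]
        with pytest.raises(ValidationError, match="refused"):
            classify_mutant(profs[0], profs[1:])

    def test_correction_factor_silences_every_reference_profile(self, rng):
        times, curves = make_wt_cohort(rng)
        stats = wt_residual_stats(curves, (A_TRUE, B_TRUE))
        profs = [divergence_profile(f"wt{i}", times, mu, ph,
                                    (A_TRUE, B_TRUE), stats)
                 for i, (_, mu, ph) in enumerate(curves)]
        factor = wildtype_correction_factor(profs, alpha=0.01)
        assert factor >= 1.0
        calls = classify_cohort(profs, profs, alpha=0.01)
        assert all(c.category == CATEGORY_WT for c in calls)

    def test_planted_categories_recovered(self, rng):
        times, curves = make_wt_cohort(rng)
        stats = wt_residual_stats(curves, (A_TRUE, B_TRUE))
        wt_profs = [divergence_profile(f"wt{i}", times, mu, ph,
                                       (A_TRUE, B_TRUE), stats)
                    for i, (_, mu, ph) in enumerate(curves)]
        ph = 7.0 - 0.05 * (times - 4.0)
        slow = divergence_profile(
            "slow", times, 0.5 * predict_mu((A_TRUE, B_TRUE), ph), ph,
            (A_TRUE, B_TRUE), stats)
        dec = divergence_profile(
            "dec", times, np.full_like(times, 0.30), np.full_like(times, 6.7),
            (A_TRUE, B_TRUE), stats)
        calls = {c.strain_id: c for c in
                 classify_cohort([slow, dec], wt_profs)}
        assert calls["slow"].category == CATEGORY_SLOW
        assert calls["dec"].category == CATEGORY_DECOUPLED

    def test_invariant_to_strain_relabelling(self, rng):
        times, curves = make_wt_cohort(rng)
        stats = wt_residual_stats(curves, (A_TRUE, B_TRUE))
        wt_profs = [divergence_profile(f"wt{i}", times, mu, ph,
                                       (A_TRUE, B_TRUE), stats)
                    for i, (_, mu, ph) in enumerate(curves)]
        ph = np.full_like(times, 6.7)
        prof_a = divergence_profile("aaa", times, np.full_like(times, 0.3),
                                    ph, (A_TRUE, B_TRUE), stats)
        prof_z = DivergenceProfile("zzz", prof_a.times, prof_a.z_t,
                                   prof_a.mean_z)
        calls = classify_cohort([prof_a, prof_z], wt_profs)
        assert calls[0].category == calls[1].category
        assert calls[0].p_corrected == calls[1].p_corrected


def profile_from(strain_id, z):
    z = np.asarray(z, dtype=float)
    times = np.arange(len(z), dtype=float)
    return DivergenceProfile(strain_id=strain_id, times=times, z_t=z,
                             mean_z=float(np.nanmean(z)))


def brute_force_complete_linkage(X):
    """Exhaustive agglomeration: at every step merge the pair of clusters with
    the smallest maximum pairwise distance.  Returns sorted merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for (ia, a), (ib, b) in itertools.combinations(enumerate(clusters), 2):
            d = max(np.linalg.norm(X[i] - X[j]) for i in a for j in b)
            if best is None or d < best[0]:
                best = (d, ia, ib)
        d, ia, ib = best
        heights.append(d)
        merged = clusters[ia] + clusters[ib]
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)
    return sorted(heights)


class TestClustering:
    def test_identical_profiles_merge_at_height_zero(self):
        p1 = profile_from("a", [1.0, 2.0, 3.0])
        p2 = profile_from("b", [1.0, 2.0, 3.0])
        result = cluster_profiles([p1, p2])
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_planted_groups_recovered_by_flat_cut(self, rng):
        profs = [profile_from(f"g1_{i}", rng.normal(0, 0.1, 8))
                 for i in range(3)]
        profs += [profile_from(f"g2_{i}", 5.0 + rng.normal(0, 0.1, 8))
                  for i in range(3)]
        result = cluster_profiles(profs)
        labels = cut_clusters(result, 2)
        g1 = {labels[f"g1_{i}"] for i in range(3)}
        g2 = {labels[f"g2_{i}"] for i in range(3)}
        assert len(g1) == 1 and len(g2) == 1 and g1 != g2

    def test_merge_heights_match_brute_force_oracle(self, rng):
        for n in (4, 6, 8):
            profs = [profile_from(f"s{i}", rng.normal(0, 1, 5))
                     for i in range(n)]
            result = cluster_profiles(profs)
            X = np.vstack([p.z_t for p in sorted(profs,
                                                 key=lambda p: p.strain_id)])
            np.testing.assert_allclose(
                sorted(result.linkage[:, 2]),
                brute_force_complete_linkage(X), atol=1e-9,
            )

    def test_deterministic_under_input_order(self, rng):
        profs = [profile_from(f"s{i}", rng.normal(0, 1, 6)) for i in range(7)]
        r1 = cluster_profiles(profs)
        r2 = cluster_profiles(list(reversed(profs)))
        assert r1.newick == r2.newick
        np.testing.assert_allclose(r1.linkage, r2.linkage)

    def test_single_profile_gives_single_leaf(self):
        result = cluster_profiles([profile_from("only", [1.0, 2.0])])
        assert result.linkage is None
        assert result.newick.startswith("only")

    def test_newick_is_parseable_with_correct_leaves(self, rng):
        import dendropy

        profs = [profile_from(f"s{i}", rng.normal(0, 1, 6)) for i in range(5)]
        result = cluster_profiles(profs)
        tree = dendropy.Tree.get(data=result.newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {f"s{i}" for i in range(5)}
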