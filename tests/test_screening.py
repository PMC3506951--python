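"""Z-values, candidate selection, confirmation t-tests, Jackknife, profiling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phscreen.errors import BatchError, ValidationError
from phscreen.screening import (
    condition_profile,
    confirm_hits,
    cross_condition_sets,
    false_negative_rate,
    jackknife_retest,
    replicate_z_values,
    select_candidates,
    trim_extremes,
    two_sample_t,
)


def make_batch(wt_values, mutant_values):
    rows = [{"strain_id": "WT", "role": "wild_type", "mean_ph": v}
            for v in wt_values]
    rows += [{"strain_id": f"m{i}", "role": "mutant", "mean_ph": v}
             for i, v in enumerate(mutant_values)]
    return pd.DataFrame(rows)


class TestReplicateZ:
    def test_arithmetic_of_the_z_definition(self):
        # wild-type population with mean 7.08 and sample SD exactly 0.05
        batch = make_batch([7.03, 7.08, 7.13], [6.93, 7.08])
        out, wt_mean, wt_sd = replicate_z_values(batch)
        assert wt_mean == pytest.approx(7.08)
        assert wt_sd == pytest.approx(0.05)
        z = out.set_index("strain_id")["z"]
        assert z["m0"] == pytest.approx(-3.0, abs=1e-12)
        assert z["m1"] == pytest.approx(0.0, abs=1e-12)

    def test_wildtype_z_population_is_standardised(self, rng):
        batch = make_batch(rng.normal(7.08, 0.05, 40), rng.normal(7.0, 0.1, 10))
        out, _, _ = replicate_z_values(batch)
        wt_z = out.loc[out["role"] == "wild_type", "z"]
        assert wt_z.mean() == pytest.approx(0.0, abs=1e-9)
        assert wt_z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        wt = rng.normal(7.08, 0.05, 20)
        mut = rng.normal(7.0, 0.1, 30)
        out, _, _ = replicate_z_values(make_batch(wt, mut))
        m, s = wt.mean(), wt.std(ddof=1)
        got = out.loc[out["role"] == "mutant", "z"].to_numpy()
        np.testing.assert_allclose(got, (mut - m) / s, atol=1e-12)

    def test_needs_two_wildtype_wells(self):
        with pytest.raises(BatchError):
            replicate_z_values(make_batch([7.08], [7.0]))
        with pytest.raises(BatchError):
            replicate_z_values(make_batch([7.08, 7.08], [7.0]))


class TestCandidateRule:
    @pytest.mark.parametrize("z1,z2,expected", [
        (2.5, 1.2, True),
        (2.5, 0.5, False),
        (2.5, -1.5, False),      # opposite directions are incoherent
        (1.2, 2.5, True),        # symmetric in the two screens
        (-2.1, -1.0, True),
        (2.0, 1.0, True),        # inclusive thresholds ("at least")
        (1.9, 1.9, False),
        (-2.0, -0.99, False),
    ])
    def test_rule_table(self, z1, z2, expected):
        assert select_candidates(z1, z2) is expected

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(z1=st.floats(-5, 5), z2=st.floats(-5, 5))
    def test_symmetry_property(self, z1, z2):
        assert select_candidates(z1, z2) == select_candidates(z2, z1)

    def test_same_sign_requirement_is_configurable(self):
        assert select_candidates(2.5, -1.5, require_same_sign=False)

    def test_vectorised(self):
        got = select_candidates([2.5, 2.5], [1.2, 0.5])
        np.testing.assert_array_equal(got, [True, False])


class TestTwoSampleT:
    def test_matches_pooled_variance_textbook_formula(self):
        x = np.array([7.1, 7.3, 6.9, 7.2, 7.0, 7.4])
        y = np.array([6.8, 7.0, 6.9, 6.7, 7.1, 6.95, 6.85, 7.05])
        t, p = two_sample_t(x, y)
        # independent oracle: hand-computed pooled-variance formula
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_hand = 2 * stats.t.sf(abs(t_hand), n1 + n2 - 2)
        assert t == pytest.approx(t_hand, abs=1e-9)
        assert p == pytest.approx(p_hand, abs=1e-9)

    def test_degenerate_zero_variance(self):
        assert two_sample_t([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        t, p = two_sample_t([2.0, 2.0], [1.0, 1.0])
        assert p == 0.0 and t == np.inf


class TestConfirmation:
    def test_null_mutant_not_confirmed(self, rng):
        wt = rng.standard_normal(50)
        mut = rng.standard_normal(6)
        call = confirm_hits("m", mut, wt, alpha=0.01)
        assert call.status in ("candidate",)  # same distribution, no hit
        assert call.p_value > 0.01

    def test_large_shift_confirmed_high(self, rng):
        wt = rng.standard_normal(50)
        call = confirm_hits("m", wt[:6] + 10.0, wt, alpha=0.01)
        assert call.status == "confirmed"
        assert call.direction == "high"

    def test_fewer_than_three_replicates_is_nd(self):
        call = confirm_hits("m", [1.0, 2.0], np.zeros(10), alpha=0.01)
        assert call.status == "nd"
        assert np.isnan(call.p_value)


class TestJackknife:
    def wt_pool(self):
        rng = np.random.default_rng(7)
        wt = rng.standard_normal(100)
        return (wt - wt.mean()) / wt.std(ddof=1)

    def test_trims_exactly_one_min_and_one_max(self):
        np.testing.assert_array_equal(
            trim_extremes([6.9, 7.0, 7.0, 7.0, 7.0, 8.5]),
            [7.0, 7.0, 7.0, 7.0],
        )

    def test_outlier_driven_hit_is_discarded(self):
        wt = self.wt_pool()
        mut = np.array([0.7] * 5 + [8.0])   # one extreme replicate drives p
        call = confirm_hits("m", mut, wt, alpha=0.01)
        assert call.status == "confirmed"
        call = jackknife_retest(call, mut, wt, alpha_jk=0.1)
        assert call.status == "discarded_jackknife"
        assert call.p_jackknife > 0.1

    def test_uniformly_shifted_vector_survives(self):
        wt = self.wt_pool()
        mut = np.full(6, 5.0) + np.linspace(-0.1, 0.1, 6)
        call = confirm_hits("m", mut, wt, alpha=0.01)
        call = jackknife_retest(call, mut, wt, alpha_jk=0.1)
        assert call.status == "confirmed"

    def test_fewer_than_four_replicates_skips_with_warning(self):
        wt = self.wt_pool()
        mut = np.array([5.0, 5.1, 4.9])
        call = confirm_hits("m", mut, wt, alpha=0.01)
        with pytest.warns(UserWarning, match="Jackknife skipped"):
            out = jackknife_retest(call, mut, wt)
        assert out.status == call.status

    def test_never_promotes_a_non_hit(self, rng):
        wt = self.wt_pool()
        for _ in range(50):
            mut = rng.normal(0.0, 1.5, 6)
            call = confirm_hits("m", mut, wt, alpha=0.01)
            out = jackknife_retest(call, mut, wt, alpha_jk=0.1)
            if call.status != "confirmed":
                assert out.status != "confirmed"


class TestConditionProfiling:
    conditions = ["glc_pH5.0", "glc_pH3.0", "glc_pH7.5"]

    def parent(self, rng):
        return {c: rng.normal(m, 0.03, 12) for c, m in
                zip(self.conditions, [7.08, 7.08, 7.20])}

    def test_single_condition_deviant(self, rng):
        parent = self.parent(rng)
        mutant = {c: parent[c][:4] + (0.4 if c == "glc_pH3.0" else 0.0)
                  for c in self.conditions}
        calls = condition_profile("m", mutant, parent)
        sig = {c for c, call in calls.items() if call.status == "confirmed"}
        assert sig == {"glc_pH3.0"}

    def test_consistently_low_and_fragile_sets(self, rng):
        parent = self.parent(rng)
        low_all = {c: parent[c][:4] - 0.3 for c in self.conditions}
        fragile = {c: parent[c][:4] + (0.3 if c == "glc_pH7.5" else
                                       -0.3 if c == "glc_pH3.0" else 0.0)
                   for c in self.conditions}
        profiles = {
            "lowboy": condition_profile("lowboy", low_all, parent),
            "frag": condition_profile("frag", fragile, parent),
        }
        sets = cross_condition_sets(profiles, conditions=self.conditions)
        assert "lowboy" in sets["consistently_low"]
        assert sets["ph_fragile"] == {"frag"}

    def test_missing_condition_omitted_with_warning(self, rng):
        parent = self.parent(rng)
        mutant = {"glc_pH5.0": parent["glc_pH5.0"][:4]}
        with pytest.warns(UserWarning, match="omitted"):
            calls = condition_profile("m", mutant, parent)
        assert set(calls) == {"glc_pH5.0"}


class TestFalseNegativeRate:
    def test_arithmetic(self):
        truth = {f"s{i}": "low" for i in range(10)}
        truth.update({f"h{i}": "high" for i in range(4)})
        selected = {f"s{i}": i != 0 for i in range(10)}
        selected.update({f"h{i}": True for i in range(4)})
        out = false_negative_rate(truth, selected)
        assert out["fn_low"] == pytest.approx(0.10)
        assert out["fn_high"] == 0.0

    def test_empty_direction_is_nan(self):
        out = false_negative_rate({"a": "low"}, {"a": True})
        assert np.isnan(out["fn_high"])
        assert out["fn_low"] == 0.0
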