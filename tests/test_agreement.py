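"""Krippendorff's alpha: hand examples, brute-force oracle, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelgt.agreement import (
    AgreementError,
    UndefinedAgreementError,
    alpha_by_round,
    coincidence_matrix,
    exhaustive_pairing_alpha,
    krippendorff_alpha,
    percent_agreement,
    random_reader_alpha,
)
from panelgt.simulate import SimulationConfig, simulate_study
from panelgt.labels import Finding

from conftest import NOISE_FREE


def alpha_bruteforce(units):
    """Independent nominal alpha: explicit enumeration of ordered pairs.

    Observed disagreement sums mismatching ordered pairs within each unit
    (weight 1/(m_u - 1)); expected disagreement enumerates every ordered pair
    of the pooled values.  No coincidence matrix is formed.
    """
    units = [list(u) for u in units if len(u) >= 2]
    values = [v for u in units for v in u]
    n = len(values)
    d_o = sum(
        (u[i] != u[j]) / (len(u) - 1)
        for u in units
        for i in range(len(u))
        for j in range(len(u))
        if i != j
    )
    d_e = sum(
        values[i] != values[j] for i in range(n) for j in range(n) if i != j
    ) / (n - 1)
    return 1.0 - d_o / d_e


def random_units(rng):
    n_units = rng.integers(2, 11)
    n_cat = rng.integers(2, 4)
    cats = [chr(ord("a") + i) for i in range(n_cat)]
    units = []
    for _ in range(n_units):
        m = rng.integers(1, 5)
        units.append([cats[i] for i in rng.integers(0, n_cat, m)])
    return units


class TestCoincidenceMatrix:
    def test_two_unanimous_pair_units(self):
        cm = coincidence_matrix([["Present", "Present"], ["Present", "Absent"]])
        i = cm.categories.index("Present")
        # unit 1 contributes 2 ordered (P,P) pairs / (2-1); total must equal n
        assert cm.counts[i, i] == 2.0
        assert cm.total == 4.0

    def test_singleton_units_dropped(self):
        cm_with = coincidence_matrix([["Present", "Absent"], ["Present"]])
        cm_without = coincidence_matrix([["Present", "Absent"]])
        assert np.array_equal(cm_with.counts, cm_without.counts)
        assert cm_with.n_units == 1

    def test_symmetry_and_total_on_random_units(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            units = random_units(rng)
            try:
                cm = coincidence_matrix(units)
            except AgreementError:
                continue
            assert np.allclose(cm.counts, cm.counts.T)
            n_expected = sum(len(u) for u in units if len(u) >= 2)
            assert cm.total == pytest.approx(n_expected)

    def test_all_singletons_error(self):
        with pytest.raises(AgreementError, match="no unit"):
            coincidence_matrix([["Present"], ["Absent"]])


class TestAlpha:
    def test_unanimous_units_give_exactly_one(self):
        units = [["Present"] * 3] * 12 + [["Absent"] * 3] * 8
        assert krippendorff_alpha(units).alpha == 1.0

    def test_two_rater_hand_example(self):
        # units (A,B) and (B,A): D_o = 4, D_e = 2*2*2/3 -> alpha = -1/2
        assert krippendorff_alpha([["A", "B"], ["B", "A"]]).alpha == pytest.approx(-0.5)

    def test_nine_unit_hand_example(self):
        # one disagreeing pair among 9 two-rater units; marginals 5,7,4,2:
        # D_o = 2, D_e = (18^2 - 94)/17 -> alpha = 1 - 34/230
        a = [1, 2, 3, 3, 2, 1, 4, 1, 2]
        b = [1, 2, 3, 3, 2, 2, 4, 1, 2]
        units = [[str(x), str(y)] for x, y in zip(a, b)]
        assert krippendorff_alpha(units).alpha == pytest.approx(1 - 34 / 230)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 120:
            units = random_units(rng)
            try:
                mine = krippendorff_alpha(units).alpha
            except AgreementError:
                continue
            assert mine == pytest.approx(alpha_bruteforce(units), abs=1e-12)
            checked += 1

    def test_chance_level_shuffle_is_near_zero(self):
        rng = np.random.default_rng(3)
        units = rng.choice(["Present", "Absent"], size=(4000, 3))
        alpha = krippendorff_alpha(units).alpha
        assert abs(alpha) < 0.02

    def test_single_category_is_undefined_not_sentinel(self):
        with pytest.raises(UndefinedAgreementError):
            krippendorff_alpha([["Present", "Present"]] * 5)

    def test_invariant_to_category_relabeling_and_orderings(self):
        rng = np.random.default_rng(9)
        units = [list(u) for u in rng.choice(["x", "y", "z"], size=(30, 3))]
        base = krippendorff_alpha(units).alpha
        relabeled = [[{"x": "q", "y": "r", "z": "s"}[v] for v in u] for u in units]
        assert krippendorff_alpha(relabeled).alpha == pytest.approx(base)
        shuffled = [list(reversed(u)) for u in reversed(units)]
        assert krippendorff_alpha(shuffled).alpha == pytest.approx(base)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        units=st.lists(
            st.lists(st.sampled_from(["a", "b", "c"]), min_size=2, max_size=4),
            min_size=2,
            max_size=10,
        )
    )
    def test_alpha_properties_hold_on_arbitrary_units(self, units):
        """alpha is oracle-equal, bounded above by 1, and symmetric in units."""
        try:
            res = krippendorff_alpha(units)
        except AgreementError:
            return
        assert res.alpha == pytest.approx(alpha_bruteforce(units), abs=1e-12)
        assert res.alpha <= 1.0 + 1e-12
        assert krippendorff_alpha(list(reversed(units))).alpha == pytest.approx(res.alpha)

    def test_dropping_unpairable_units_matches_oracle_that_never_saw_them(self):
        units = [["a", "b", "a"], ["b", "b"], ["a"], ["b"]]
        with_singletons = krippendorff_alpha(units).alpha
        assert with_singletons == pytest.approx(
            alpha_bruteforce([u for u in units if len(u) >= 2]), abs=1e-12
        )


class TestPercentAgreement:
    def test_counting(self):
        a = {f"u{i}": "Present" for i in range(10)}
        assert percent_agreement(a, a) == 1.0
        b = {k: "Absent" for k in a}
        assert percent_agreement(a, b) == 0.0
        c = dict(a)
        for k in list(a)[:3]:
            c[k] = "Absent"
        assert percent_agreement(a, c) == pytest.approx(0.7)

    def test_unit_mismatch(self):
        with pytest.raises(AgreementError, match="unit"):
            percent_agreement({"u1": "Present"}, {"u2": "Present"})


class TestRandomReaderAlpha:
    def test_noise_free_is_one_with_zero_sd(self, noise_free_study):
        _, ls, _, _ = noise_free_study
        res = random_reader_alpha(ls, "cardiomegaly", n_reps=5, seed=1)
        assert res.alpha == 1.0
        assert res.resampling == (5, 1.0, 0.0)

    def test_deterministic_under_fixed_seed(self, small_study):
        _, ls, _, _ = small_study
        r1 = random_reader_alpha(ls, "edema", n_reps=1, seed=123)
        r2 = random_reader_alpha(ls, "edema", n_reps=1, seed=123)
        assert r1.alpha == r2.alpha

    def test_mean_matches_exhaustive_pairing(self, small_study):
        _, ls, _, _ = small_study
        res = random_reader_alpha(ls, "airspace_opacity", n_reps=100, seed=2)
        exact = exhaustive_pairing_alpha(ls, "airspace_opacity")
        n_reps, mean, sd = res.resampling
        # the exhaustive average estimates the same expectation; allow a few
        # standard errors of the 100-rep mean
        assert abs(mean - exact) < 4 * sd / np.sqrt(n_reps) + 1e-9


class TestAlphaByRound:
    def _single_finding_cfg(self, **kw):
        return SimulationConfig(
            findings=(Finding("cardiomegaly"),),
            prevalence={"cardiomegaly": 0.3},
            detail_vocab={},
            n_images=kw.pop("n_images", 2000),
            **kw,
        )

    def test_no_persuasion_keeps_alpha_constant(self):
        cfg = self._single_finding_cfg(
            seed=21, rho={"detection": 0.0, "thresholding": 0.0, "classification": 0.0}
        )
        ls, _, _ = simulate_study(cfg)
        results = alpha_by_round(ls, "cardiomegaly", rounds=[0, 1, 2])
        assert len({round(r.alpha, 12) for r in results}) == 1

    def test_noise_free_alpha_one_every_round(self, noise_free_study):
        _, ls, _, _ = noise_free_study
        for res in alpha_by_round(ls, "cardiomegaly", rounds=[0, 1, 2]):
            assert res.alpha == 1.0

    def test_adjudication_toward_truth_raises_alpha(self):
        cfg = self._single_finding_cfg(seed=8)
        ls, _, _ = simulate_study(cfg)
        results = alpha_by_round(ls, "cardiomegaly", rounds=[0, 2])
        assert results[-1].alpha > results[0].alpha + 0.02
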