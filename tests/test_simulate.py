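"""Simulator: determinism, prevalence, closed-form operating points,
panel sampling, hedge monotonicity, arm independence, round dynamics."""

import numpy as np
import pandas as pd
import pytest

from panelgt.adjudicate import detect_disagreements
from panelgt.labels import HEDGE, PRESENT, Finding, write_reads
from panelgt.simulate import (
    ConfigError,
    SimulationConfig,
    default_reader_profiles,
    reader_operating_point,
    sample_truth,
    simulate_adjudication,
    simulate_reads,
    simulate_study,
)

from conftest import NOISE_FREE


def one_finding_cfg(name="fracture", prevalence=0.3, **kw):
    return SimulationConfig(
        findings=(Finding(name, hedge_allowed=kw.pop("hedge_allowed", False)),),
        prevalence={name: prevalence},
        detail_vocab={},
        **kw,
    )


class TestSampleTruth:
    def test_degenerate_prevalence_one_gives_all_positive(self):
        cfg = one_finding_cfg(prevalence=1.0, n_images=50, seed=1)
        truth = sample_truth(cfg)
        assert (truth.table["truth"] == 1).all()

    def test_prevalence_out_of_range_rejected(self):
        with pytest.raises(ConfigError, match="prevalence"):
            one_finding_cfg(prevalence=0.0)
        with pytest.raises(ConfigError, match="prevalence"):
            one_finding_cfg(prevalence=1.2)

    def test_empirical_prevalence_within_binomial_ci(self):
        n, p = 10_000, 0.1
        cfg = one_finding_cfg(prevalence=p, n_images=n, seed=17)
        truth = sample_truth(cfg)
        emp = truth.table["truth"].mean()
        assert abs(emp - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_same_seed_gives_identical_truth(self):
        cfg = one_finding_cfg(n_images=200, seed=9)
        t1, t2 = sample_truth(cfg), sample_truth(cfg)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_confusion_induces_cooccurrence(self):
        cfg = SimulationConfig(
            n_images=4000,
            seed=4,
            confusion={"airspace_opacity": {"airspace_opacity": 0.5, "edema": 0.5}},
        )
        truth = sample_truth(cfg)
        piv = truth.table.pivot(index="image_id", columns="finding", values="truth")
        both = ((piv["airspace_opacity"] == 1) & (piv["edema"] == 1)).mean()
        indep = piv["airspace_opacity"].mean() * SimulationConfig().prevalence["edema"]
        assert both > 1.5 * indep


class TestSimulateReads:
    def test_full_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_images=40, seed=13)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_reads(simulate_study(cfg)[0], p1)
        write_reads(simulate_study(cfg)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_noise_free_reads_equal_truth(self, noise_free_study):
        _, ls, truth, _ = noise_free_study
        t = truth.table.set_index(["image_id", "finding"])["truth"]
        r0 = ls.reads[ls.reads["round"] == 0]
        for row in r0.itertuples(index=False):
            assert (row.label == PRESENT) == bool(t.loc[(row.image_id, row.finding)])

    def test_operating_point_recovery_against_closed_form(self):
        """Empirical per-reader sens/spec match the Gaussian tail integrals."""
        cfg = SimulationConfig(
            findings=(Finding("fracture"), Finding("nodule", hedge_allowed=True)),
            prevalence={"fracture": 0.3, "nodule": 0.3},
            detail_vocab={},
            n_images=10_000,
            image_poor_quality_rate=0.0,
            seed=23,
        )
        truth = sample_truth(cfg)
        profiles = default_reader_profiles(cfg)
        ls = simulate_reads(truth, profiles, cfg)
        t = truth.table.set_index(["image_id", "finding"])["truth"]
        df = ls.reads.merge(
            truth.table[["image_id", "finding", "truth"]], on=["image_id", "finding"]
        )
        df["called_pos"] = df["label"].isin([PRESENT, HEDGE])
        by_profile = {p.reader_id: p for arm in (1, 2) for p in profiles[arm]}
        checked = 0
        for (reader, fnd), grp in df.groupby(["reader_id", "finding"]):
            sens_th, spec_th = reader_operating_point(by_profile[reader], fnd, cfg)
            pos, neg = grp[grp["truth"] == 1], grp[grp["truth"] == 0]
            for sub, theory, positive in (
                (pos, sens_th, True), (neg, 1 - spec_th, True)
            ):
                emp = sub["called_pos"].mean()
                se = np.sqrt(theory * (1 - theory) / len(sub))
                assert abs(emp - theory) < 3 * se + 1e-9, (reader, fnd)
                checked += 1
        assert checked >= 16

    def test_panel_sampling_fractions(self):
        cfg = one_finding_cfg(n_images=3000, seed=3)
        ls, _, _ = simulate_study(cfg)
        n = len(ls.images())
        for arm, cohort_size in zip((1, 2), cfg.cohort_sizes):
            counts = pd.Series(
                [r for (img, a), panel in ls.panels.items() if a == arm for r in panel]
            ).value_counts()
            expect = 3 / cohort_size
            for reader, c in counts.items():
                se = np.sqrt(expect * (1 - expect) / n)
                assert abs(c / n - expect) < 4 * se

    def test_hedge_rate_monotone_in_hedge_width(self):
        rates = []
        for width in (0.05, 0.35, 0.8):
            cfg = one_finding_cfg(
                name="nodule", hedge_allowed=True, n_images=1500, seed=6,
                hedge_width=width,
            )
            ls, _, _ = simulate_study(cfg)
            r0 = ls.reads[ls.reads["round"] == 0]
            rates.append((r0["label"] == HEDGE).mean())
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_arms_conditionally_independent_given_truth(self):
        # with sigma_img = 0 the truth fixes z, so per-image panel error rates
        # in the two arms are independent; their correlation should vanish
        cfg = one_finding_cfg(n_images=4000, seed=31, sigma_img=0.0)
        ls, truth, _ = simulate_study(cfg)
        t = truth.table.set_index("image_id")["truth"]
        r0 = ls.reads[ls.reads["round"] == 0].copy()
        r0["wrong"] = (r0["label"] == PRESENT) != r0["image_id"].map(t).astype(bool)
        err = r0.pivot_table(index="image_id", columns="arm", values="wrong", aggfunc="mean")
        corr = err[1].corr(err[2])
        assert abs(corr) < 0.06

    def test_missing_profile_finding_is_config_error(self):
        cfg = one_finding_cfg(n_images=10, seed=1)
        truth = sample_truth(cfg)
        profiles = default_reader_profiles(cfg)
        bad = dict(profiles)
        p0 = profiles[1][0]
        bad[1] = [type(p0)(p0.reader_id, {}, p0.delta, {})] + list(profiles[1][1:])
        with pytest.raises(ConfigError, match="missing finding"):
            simulate_reads(truth, bad, cfg)


class TestSimulateAdjudication:
    def _study(self, rho, seed=19, **kw):
        cfg = one_finding_cfg(
            n_images=kw.pop("n_images", 600),
            seed=seed,
            rho={"detection": rho, "thresholding": rho, "classification": rho},
            **kw,
        )
        return cfg, *simulate_study(cfg)

    def test_certain_persuasion_resolves_everything_in_round_one(self):
        _, ls, _, _ = self._study(rho=1.0)
        assert detect_disagreements(ls, round=1) == set()

    def test_zero_persuasion_changes_nothing(self):
        _, ls, _, _ = self._study(rho=0.0)
        r0 = ls.effective_reads(0).sort_values(
            ["image_id", "arm", "reader_id", "finding"]).reset_index(drop=True)
        r2 = ls.effective_reads(2).sort_values(
            ["image_id", "arm", "reader_id", "finding"]).reset_index(drop=True)
        assert r0["label"].equals(r2["label"])
        assert ls.max_round() == 0  # no re-entries were ever emitted

    def test_geometric_decay_of_unresolved_fraction(self):
        # per-round resolution prob 0.75 => P(still contested after 2) = 0.0625
        unresolved, contested = 0, 0
        for seed in (101, 102, 103):
            cfg, ls, _, _ = self._study(rho=0.75, seed=seed, n_images=1500)
            c0 = detect_disagreements(ls, round=0)
            c2 = detect_disagreements(ls, round=2)
            contested += len(c0)
            unresolved += len(c2 & c0)
        frac = unresolved / contested
        se = np.sqrt(0.0625 * 0.9375 / contested)
        assert abs(frac - 0.0625) < 4 * se

    def test_max_rounds_below_one_rejected(self):
        with pytest.raises(ConfigError, match="max_rounds"):
            one_finding_cfg(max_rounds=0)
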