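"""Stacked prey composition, PAUC, delta-PAUC, Fligner-Killeen diversity."""

import numpy as np
import pytest

from dielaccess import density as dn
from dielaccess import prey_access as pa
from dielaccess.density import TWO_PI, DielSample


def _vm_model(name, mu, kappa, n=500, seed=0, zone="low"):
    rng = np.random.default_rng(seed)
    s = DielSample(name, zone, rng.vonmises(mu, kappa, n) % TWO_PI)
    return dn.fit_activity(s)


class TestStackPrey:
    def test_identical_curves_split_evenly(self):
        m1 = _vm_model("a", 0.0, 2.0, seed=1)
        m2 = dn.ActivityModel(sample=DielSample("b", "low", m1.sample.times),
                              kappa=m1.kappa, adjust=1.0, grid=m1.grid,
                              density=m1.density.copy())
        comp = pa.stack_prey([m1, m2])
        assert np.allclose(comp.contributions, 0.5)

    def test_contributions_sum_to_one_everywhere(self):
        models = [_vm_model(f"s{i}", mu, 2.0 + i, seed=i)
                  for i, mu in enumerate([0.0, 2.0, 4.0])]
        comp = pa.stack_prey(models)
        assert np.allclose(comp.contributions.sum(axis=0), 1.0, atol=1e-9)

    def test_nocturnal_vs_diurnal_contributions(self):
        noct = _vm_model("night", 0.0, 4.0, seed=2)      # midnight peak
        diur = _vm_model("day", np.pi, 4.0, seed=3)      # noon peak
        comp = pa.stack_prey([noct, diur])
        at_midnight = comp.contributions[0, 0]
        at_noon = comp.contributions[0, 256]
        assert at_midnight > 0.5 > at_noon

    def test_detection_weighting(self):
        m1 = _vm_model("a", 0.0, 2.0, n=900, seed=4)
        m2 = _vm_model("b", 0.0, 2.0, n=100, seed=5)
        comp = pa.stack_prey([m1, m2], weights="detections")
        assert comp.weights.tolist() == [900.0, 100.0]
        assert comp.contributions[0].mean() > 0.7

    def test_grid_mismatch_rejected(self):
        m1 = _vm_model("a", 0.0, 2.0, seed=6)
        s = DielSample("b", "low", m1.sample.times)
        m2 = dn.fit_activity(s, grid_size=256)
        with pytest.raises(ValueError):
            pa.stack_prey([m1, m2])

    def test_needs_two_prey(self):
        with pytest.raises(ValueError):
            pa.stack_prey([_vm_model("a", 0.0, 2.0, seed=7)])


class TestComputePAUC:
    def test_degenerate_single_prey_is_100(self):
        pred = _vm_model("pred", 0.0, 3.0, seed=8)
        comp = pa.PreyComposition(grid=pred.grid,
                                  contributions=np.ones((1, len(pred.grid))),
                                  weights=np.ones(1), species=["only"])
        assert pa.compute_pauc(pred, comp)["only"] == pytest.approx(100.0, abs=1e-6)

    def test_identical_prey_split(self):
        pred = _vm_model("pred", 0.0, 3.0, seed=9)
        k = 4
        comp = pa.PreyComposition(grid=pred.grid,
                                  contributions=np.full((k, len(pred.grid)), 1.0 / k),
                                  weights=np.ones(k), species=[f"s{i}" for i in range(k)])
        vals = pa.compute_pauc(pred, comp)
        assert np.allclose(vals, 100.0 / k, atol=1e-6)

    def test_sums_to_100(self):
        pred = _vm_model("pred", 5.0, 2.0, seed=10)
        models = [_vm_model(f"s{i}", mu, 3.0, seed=20 + i)
                  for i, mu in enumerate([0.0, 1.5, 3.0, 4.5])]
        vals = pa.compute_pauc(pred, pa.stack_prey(models))
        assert vals.sum() == pytest.approx(100.0, abs=1e-6)

    def test_fine_grid_oracle(self):
        """Nocturnal predator with one nocturnal and one diurnal prey: the
        nocturnal prey takes >50% and the 512-grid value matches a
        10,000-point quadrature within 0.1 pp."""
        pred = _vm_model("pred", 0.0, 4.0, n=1500, seed=11)
        noct = _vm_model("night", 0.0, 4.0, n=1500, seed=12)
        diur = _vm_model("day", np.pi, 4.0, n=1500, seed=13)
        vals = pa.compute_pauc(pred, pa.stack_prey([noct, diur]))
        assert vals["night"] > 50.0

        fine = np.linspace(0, TWO_PI, 10_000, endpoint=False)
        fp = dn.density_at(pred, fine)
        fn = np.maximum(dn.density_at(noct, fine), pa.DENSITY_FLOOR)
        fd = np.maximum(dn.density_at(diur, fine), pa.DENSITY_FLOOR)
        oracle = 100.0 * (fn / (fn + fd) * fp).sum() * TWO_PI / 10_000
        assert vals["night"] == pytest.approx(oracle, abs=0.1)

    def test_uniform_predator_closed_form(self):
        """Flat predator: PAUC_s is the grid mean of p_s(t) x 100."""
        models = [_vm_model(f"s{i}", mu, 3.0, seed=30 + i)
                  for i, mu in enumerate([0.5, 2.5, 4.5])]
        comp = pa.stack_prey(models)
        pred = dn.ActivityModel(
            sample=DielSample("pred", "low", models[0].sample.times),
            kappa=0.0, adjust=1.0, grid=comp.grid,
            density=np.full(len(comp.grid), 1.0 / TWO_PI))
        vals = pa.compute_pauc(pred, comp)
        expected = 100.0 * comp.contributions.mean(axis=1)
        assert np.allclose(vals.to_numpy(), expected, atol=1e-9)

    def test_joint_rotation_invariance(self):
        shift = 64  # grid nodes
        rot = shift * TWO_PI / 512
        pred = _vm_model("pred", 0.0, 3.0, seed=14)
        prey = [_vm_model("a", 1.0, 2.0, seed=15), _vm_model("b", 4.0, 2.0, seed=16)]
        base = pa.compute_pauc(pred, pa.stack_prey(prey))

        def rotated(m):
            s = DielSample(m.sample.name, m.sample.zone, (m.sample.times + rot) % TWO_PI)
            return dn.fit_activity(s)

        rot_vals = pa.compute_pauc(rotated(pred), pa.stack_prey([rotated(m) for m in prey]))
        assert np.allclose(base.to_numpy(), rot_vals.to_numpy(), atol=1e-9)


def _zone_pair(name, mu_low, mu_high, kappa=2.5, n=300, seed=0):
    r1 = np.random.default_rng(seed)
    r2 = np.random.default_rng(seed + 10_000)
    return {
        "low": DielSample(name, "low", r1.vonmises(mu_low, kappa, n) % TWO_PI),
        "high": DielSample(name, "high", r2.vonmises(mu_high, kappa, n) % TWO_PI),
    }


class TestDeltaPAUC:
    def test_identical_zones_null(self):
        """Same event data in both zones: every delta is exactly 0."""
        rng = np.random.default_rng(40)
        preds = {}
        t = rng.vonmises(0.0, 2.0, 200) % TWO_PI
        preds["low"] = DielSample("pred", "low", t)
        preds["high"] = DielSample("pred", "high", t.copy())
        prey = {}
        for i, mu in enumerate([0.5, 2.5, 4.5]):
            tt = rng.vonmises(mu, 2.0, 200) % TWO_PI
            prey[f"s{i}"] = {"low": DielSample(f"s{i}", "low", tt),
                             "high": DielSample(f"s{i}", "high", tt.copy())}
        res = pa.delta_pauc(preds, prey, n_boot=100, seed=1)
        assert np.allclose(res.pauc_high.to_numpy() - res.pauc_low.to_numpy(), 0.0, atol=1e-9)
        assert not res.table["significant"].any()

    def test_deltas_sum_to_zero_and_ci_orders(self):
        preds = _zone_pair("pred", 0.0, 0.3, seed=50)
        prey = {f"s{i}": _zone_pair(f"s{i}", mu, mu + 0.4, seed=60 + i)
                for i, mu in enumerate([0.0, 2.0, 4.0])}
        res = pa.delta_pauc(preds, prey, n_boot=200, seed=2)
        assert res.table["delta_pauc"].sum() == pytest.approx(0.0, abs=1e-6)
        assert (res.table["ci_low"] <= res.table["ci_high"]).all()
        assert res.pauc_low.sum() == pytest.approx(100.0, abs=1e-6)
        assert res.pauc_high.sum() == pytest.approx(100.0, abs=1e-6)

    def test_directional_shift_detected(self):
        """Prey that swings toward the nocturnal predator in the high zone
        gains access share with a positive, significant delta."""
        preds = _zone_pair("pred", 0.0, 0.0, kappa=3.0, n=400, seed=70)
        prey = {
            "shifter": _zone_pair("shifter", np.pi, 0.8, kappa=2.0, n=500, seed=80),
            "stable1": _zone_pair("stable1", 2.0, 2.0, kappa=2.0, n=500, seed=81),
            "stable2": _zone_pair("stable2", 4.0, 4.0, kappa=2.0, n=500, seed=82),
        }
        res = pa.delta_pauc(preds, prey, n_boot=300, seed=3)
        row = res.table.set_index("prey").loc["shifter"]
        assert row["delta_pauc"] > 0
        assert row["significant"]


class TestAccessDiversity:
    def test_identical_groups(self):
        x = np.array([5.0, 9.0, 13.0, 20.0, 53.0])
        res = pa.access_diversity_test(x, x.copy())
        assert res.fk_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.interpretation == "no_difference"

    def test_spread_vs_tight_groups(self):
        """A clearly dispersed group against a near-constant one: the
        dispersed zone is the less even one."""
        rng = np.random.default_rng(0)
        tight = 3.0 + rng.uniform(-0.01, 0.01, 11)   # 11 prey, like the analysis
        spread = np.linspace(1.0, 5.0, 11)
        res = pa.access_diversity_test(tight, spread)
        assert res.p_value < 0.05
        assert res.interpretation == "less_even"  # high zone (spread) less even

    def test_matches_inline_normal_scores_oracle(self):
        """Cross-check against a direct transcription of the normal-scores
        statistic: ranks of |x - group median|, a_i = Phi^-1(.5 + i/(2(N+1))),
        chi-square with k-1 df."""
        from scipy.stats import norm, chi2, rankdata
        x = np.array([12.1, 5.3, 7.8, 9.9, 14.2, 6.6])
        y = np.array([8.0, 8.4, 8.1, 7.9, 8.3, 8.6])
        dev = np.concatenate([np.abs(x - np.median(x)), np.abs(y - np.median(y))])
        n = len(dev)
        a = norm.ppf(0.5 + rankdata(dev) / (2.0 * (n + 1.0)))
        abar = a.mean()
        v = ((a - abar) ** 2).sum() / (n - 1)
        groups = [a[:6], a[6:]]
        stat = sum(len(g) * (g.mean() - abar) ** 2 for g in groups) / v
        p = chi2.sf(stat, df=1)
        res = pa.access_diversity_test(x, y)
        assert res.fk_statistic == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_location_shift_invariant(self):
        x = np.array([1.0, 3.0, 6.0, 10.0, 2.0])
        y = np.array([2.0, 2.5, 3.0, 3.5, 4.0])
        r1 = pa.access_diversity_test(x, y)
        r2 = pa.access_diversity_test(x + 100.0, y)
        assert r1.fk_statistic == pytest.approx(r2.fk_statistic, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pa.access_diversity_test([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pa.access_diversity_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            pa.access_diversity_test([1.0, 2.0, 3.0], [1.0, 2.0])
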