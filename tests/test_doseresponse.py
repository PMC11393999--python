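"""Log-logistic model forms, constrained fitting, ECx, and control tests."""

import math

import numpy as np
import pytest
from scipy import optimize

from jc1screen import doseresponse as dr
from jc1screen.doseresponse import ResponsePoint
from jc1screen.io_plate import ImmobilizationRecord
from jc1screen.quantify import IndividualResult
from jc1screen.io_plate import PlateEntry, PlateLayout

CCCP = (0.5, 5.0, 25.0, 50.0, 250.0, 500.0, 2500.0)


def make_records(concs, n, counts):
    return [
        ImmobilizationRecord(f"w{i}", c, "ug/L", n, k, "E1", 2.0)
        for i, (c, k) in enumerate(zip(concs, counts))
    ]


def make_points(concs, responses, n_rep=1):
    return [
        ResponsePoint(c, r, f"E{j}", 5, "jc1")
        for j in range(n_rep)
        for c, r in zip(concs, responses)
    ]


# ---------------------------------------------------------------------------
# closed forms


class TestModelForms:
    def test_inflection_is_midpoint(self):
        for b in (-4.0, -0.5, 0.7, 2.0):
            assert dr.ll2_response(100.0, b, 100.0) == pytest.approx(0.5)
            assert dr.ll4_response(7.3, b, 0.2, 0.9, 7.3) == pytest.approx(0.55)

    def test_asymptotes(self):
        assert dr.ll2_response(1e12, -2.0, 100.0) == pytest.approx(1.0)
        assert dr.ll2_response(0.0, -2.0, 100.0) == 0.0
        assert dr.ll4_response(0.0, 2.0, 0.2, 1.0, 100.0) == 1.0
        assert dr.ll4_response(1e12, 2.0, 0.2, 1.0, 100.0) == pytest.approx(0.2)

    def test_direct_arithmetic(self):
        # brute-force evaluation of the formula at x=50, b=-2, e=100
        expected = 1.0 / (1.0 + math.exp(-2.0 * (math.log(50) - math.log(100))))
        assert dr.ll2_response(50.0, -2.0, 100.0) == pytest.approx(expected, abs=1e-12)

    def test_ll4_nests_ll2(self):
        x = np.geomspace(1e-3, 1e5, 200)
        for b in (-3.0, -1.0, 1.0, 4.0):
            np.testing.assert_allclose(
                dr.ll4_response(x, b, 0.0, 1.0, 42.0),
                dr.ll2_response(x, b, 42.0),
                rtol=0, atol=1e-14,
            )

    def test_monotone_in_concentration(self):
        x = np.geomspace(0.01, 1e4, 300)
        falling = dr.ll4_response(x, 2.0, 0.2, 1.0, 50.0)
        rising = dr.ll2_response(x, -3.0, 50.0)
        assert np.all(np.diff(falling) <= 0)
        assert np.all(np.diff(rising) >= 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dr.ll2_response(1.0, 2.0, -5.0)
        with pytest.raises(ValueError):
            dr.ll4_response(1.0, 2.0, 1.0, 0.2, 10.0)


# ---------------------------------------------------------------------------
# effect concentrations


def _fit_from_exact_curve(b, c, d, e):
    pts = make_points(CCCP, [dr.ll4_response(x, b, c, d, e) for x in CCCP])
    return dr.fit_ll4(pts, c_fixed=c)


class TestECx:
    def test_ec50_equals_inflection(self):
        fit = _fit_from_exact_curve(2.0, 0.2, 1.0, 100.0)
        assert dr.ec_x(fit, 50).value == pytest.approx(fit.e, rel=1e-9)

    def test_ec10_closed_form(self):
        fit = _fit_from_exact_curve(1.0, 0.0, 1.0, 100.0)
        assert dr.ec_x(fit, 10).value == pytest.approx(100 * 10 / 90, rel=1e-4)

    @pytest.mark.parametrize("b,c,d,e", [(2.0, 0.2, 1.0, 100.0),
                                         (-3.0, 0.0, 1.0, 500.0),
                                         (0.8, 0.1, 0.9, 12.0)])
    @pytest.mark.parametrize("p", [5.0, 10.0, 50.0, 90.0])
    def test_matches_numeric_root_solve(self, b, c, d, e, p):
        # oracle: solve ll4(x) = response at p% of the span toward the
        # high-concentration asymptote by bisection
        target = (d - (d - c) * p / 100.0) if b > 0 else (c + (d - c) * p / 100.0)
        root = optimize.brentq(
            lambda x: dr.ll4_response(x, b, c, d, e) - target, 1e-9, 1e12,
            xtol=1e-12, rtol=1e-15,
        )
        value = dr.ec_x(dr.LogLogisticFit("LL4", b, c, d, e), p).value
        assert value == pytest.approx(root, rel=1e-6)

    def test_monotone_in_p(self):
        fit = dr.LogLogisticFit("LL4", 2.0, 0.2, 1.0, 100.0)
        ecs = [dr.ec_x(fit, p).value for p in (5, 10, 25, 50, 75, 95)]
        assert ecs == sorted(ecs)

    def test_self_consistency(self):
        for b in (2.0, -4.0):
            fit = dr.LogLogisticFit("LL4", b, 0.2, 1.0, 100.0)
            ec = dr.ec_x(fit, 30.0)
            resp = dr.ll4_response(ec.value, b, 0.2, 1.0, 100.0)
            expected = 1.0 - 0.8 * 0.30 if b > 0 else 0.2 + 0.8 * 0.30
            assert resp == pytest.approx(expected, abs=1e-6)

    def test_zero_slope_is_undefined(self):
        with pytest.raises(ValueError):
            dr.ec_x(dr.LogLogisticFit("LL4", 0.0, 0.2, 1.0, 100.0), 10)

    def test_delta_vs_bootstrap(self, rng):
        pts = [
            ResponsePoint(c, dr.ll4_response(c, 2, 0.2, 1, 100.0)
                          + rng.normal(0, 0.05), f"E{j}", 1, "jc1")
            for j in range(3) for c in CCCP
        ]
        fit = dr.fit_ll4(pts, 0.2)
        delta = dr.ec_x(fit, 50)
        boot = dr.ec_x(fit, 50, ci_method="bootstrap",
                       rng=np.random.default_rng(5))
        assert delta.ci_low < boot.ci_high and boot.ci_low < delta.ci_high
        mid_d = (delta.ci_low + delta.ci_high) / 2
        mid_b = (boot.ci_low + boot.ci_high) / 2
        assert mid_b == pytest.approx(mid_d, rel=0.15)


# ---------------------------------------------------------------------------
# fitting


class TestFitLL2:
    def test_noise_free_limit(self):
        # exact curve values as fractions with huge n recover the truth
        n = 10 ** 6
        counts = [round(n * dr.ll2_response(c, -4.0, 500.0)) for c in CCCP]
        fit = dr.fit_ll2(make_records(CCCP, n, counts))
        assert fit.converged
        assert fit.b == pytest.approx(-4.0, abs=1e-3)
        assert fit.e == pytest.approx(500.0, abs=0.05)

    def test_grid_search_oracle(self):
        concs = (10.0, 30.0, 100.0, 300.0, 1000.0)
        counts = (1, 4, 11, 17, 20)
        recs = make_records(concs, 20, counts)
        fit = dr.fit_ll2(recs)

        def nll(b, log_e):
            p = np.clip(dr.ll2_response(np.array(concs), b, math.exp(log_e)),
                        1e-12, 1 - 1e-12)
            k = np.array(counts, dtype=float)
            return -np.sum(k * np.log(p) + (20 - k) * np.log1p(-p))

        bs = np.linspace(-6, -0.2, 120)
        les = np.linspace(math.log(10), math.log(1000), 200)
        vals = np.array([[nll(b, le) for le in les] for b in bs])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        assert fit.b == pytest.approx(bs[i], abs=np.diff(bs)[0])
        assert math.log(fit.e) == pytest.approx(les[j], abs=np.diff(les)[0])

    def test_recovery_simulation(self):
        # truth b=-4, e=500 at the CCCP design, n=20: median within 5%
        rng = np.random.default_rng(42)
        est = []
        for _ in range(200):
            counts = [int(rng.binomial(20, dr.ll2_response(c, -4.0, 500.0)))
                      for c in CCCP]
            fit = dr.fit_ll2(make_records(CCCP, 20, counts))
            if fit.converged:
                est.append(fit.e)
        assert len(est) > 100
        assert np.median(est) == pytest.approx(500.0, rel=0.05)

    def test_plateau_data_non_identifiable(self):
        with pytest.raises(ValueError, match="identifiable"):
            dr.fit_ll2(make_records(CCCP, 20, [0] * 7))
        with pytest.raises(ValueError, match="identifiable"):
            dr.fit_ll2(make_records(CCCP, 20, [20] * 7))

    def test_quasi_separated_counts_flagged(self):
        # partial response at a single concentration: slope unbounded
        fit = dr.fit_ll2(make_records(CCCP, 20, [0, 0, 0, 0, 0, 1, 20]))
        assert not fit.converged
        assert "slope unbounded" in fit.message


class TestFitLL4:
    def test_noise_free_limit(self):
        pts = make_points(CCCP, [dr.ll4_response(x, 2, 0.2, 1, 100.0)
                                 for x in CCCP])
        fit = dr.fit_ll4(pts, c_fixed=0.2)
        assert fit.converged
        assert fit.b == pytest.approx(2.0, abs=1e-4)
        assert fit.d == pytest.approx(1.0, abs=1e-4)
        assert fit.e == pytest.approx(100.0, abs=1e-2)

    def test_grid_search_oracle(self, rng):
        concs = (10.0, 50.0, 100.0, 500.0, 1000.0)
        y = [dr.ll4_response(c, 2, 0.2, 1, 120.0) + rng.normal(0, 0.03)
             for c in concs]
        fit = dr.fit_ll4(make_points(concs, y), c_fixed=0.2)

        def sse(b, d, log_e):
            pred = dr.ll4_response(np.array(concs), b, 0.2, d, math.exp(log_e))
            return np.sum((pred - np.array(y)) ** 2)

        bs = np.linspace(0.5, 5, 60)
        ds = np.linspace(0.8, 1.2, 40)
        les = np.linspace(math.log(20), math.log(600), 80)
        vals = np.array([[[sse(b, d, le) for le in les] for d in ds] for b in bs])
        i, j, k = np.unravel_index(vals.argmin(), vals.shape)
        assert fit.b == pytest.approx(bs[i], abs=2 * np.diff(bs)[0])
        assert fit.d == pytest.approx(ds[j], abs=2 * np.diff(ds)[0])
        assert math.log(fit.e) == pytest.approx(les[k], abs=2 * np.diff(les)[0])

    def test_recovery_simulation(self):
        # truth (2, 0.2, 1, 100), 3 replicates x 7 concentrations, sd 0.05
        rng = np.random.default_rng(7)
        est = []
        for _ in range(200):
            pts = [
                ResponsePoint(c, dr.ll4_response(c, 2, 0.2, 1, 100.0)
                              + rng.normal(0, 0.05), f"E{j}", 1, "jc1")
                for j in range(3) for c in CCCP
            ]
            fit = dr.fit_ll4(pts, 0.2)
            if fit.converged:
                est.append(fit.e)
        assert len(est) > 150
        assert np.median(est) == pytest.approx(100.0, rel=0.10)

    def test_floor_above_responses_rejected(self):
        pts = make_points(CCCP, [0.5] * 7)
        with pytest.raises(ValueError):
            dr.fit_ll4(pts, c_fixed=0.9)


class TestRecoveryGrid:
    @pytest.mark.parametrize("b_true", [1.0, 2.0, 4.0, -1.0, -2.0, -4.0])
    def test_median_inflection_bias(self, b_true):
        # over the slope grid with EC50 inside the design, median relative
        # bias of the estimated inflection stays within 10%
        rng = np.random.default_rng(abs(hash(b_true)) % 2 ** 31)
        est = []
        for _ in range(60):
            pts = [
                ResponsePoint(c, dr.ll4_response(c, b_true, 0.2, 1, 100.0)
                              + rng.normal(0, 0.05), f"E{j}", 1, "jc1")
                for j in range(3) for c in CCCP
            ]
            fit = dr.fit_ll4(pts, 0.2)
            if fit.converged:
                est.append(fit.e)
        assert len(est) > 30
        assert abs(np.median(est) / 100.0 - 1) <= 0.10


# ---------------------------------------------------------------------------
# normalization, floor, aggregation


def _layout_two_experiments():
    entries = []
    for exp in ("E1", "E2"):
        entries.append(PlateEntry(f"{exp}CTRL", "CCCP", 0.0, "ug/L",
                                  "control", exp, 2.0, 1))
        entries.append(PlateEntry(f"{exp}T1", "CCCP", 100.0, "ug/L",
                                  "treatment", exp, 2.0, 1))
    return PlateLayout(entries=tuple(entries))


def _ind(well, ratio, qc=True, norm=None):
    return IndividualResult(well_id=well, ratio=ratio, n_z_total=10,
                           n_z_correct=10 if qc else 2, qc_pass=qc,
                           normalized_ratio=norm)


class TestNormalization:
    def test_treated_divided_by_control_mean(self):
        layout = PlateLayout(entries=(
            PlateEntry("C1", "X", 0.0, "ug/L", "control", "E1", 2.0, 1),
            PlateEntry("C2", "X", 0.0, "ug/L", "control", "E1", 2.0, 1),
            PlateEntry("T1", "X", 10.0, "ug/L", "treatment", "E1", 2.0, 1),
        ))
        inds = [_ind("C1", 2.0), _ind("C2", 2.0), _ind("T1", 1.0)]
        out = dr.normalize_to_control(inds, layout)
        assert out[2].normalized_ratio == pytest.approx(0.5)
        ctrl = [o.normalized_ratio for o in out[:2]]
        assert np.mean(ctrl) == pytest.approx(1.0)

    def test_per_experiment_blocks(self):
        layout = _layout_two_experiments()
        inds = [_ind("E1CTRL", 2.0), _ind("E1T1", 1.0),
                _ind("E2CTRL", 4.0), _ind("E2T1", 1.0)]
        out = {o.well_id: o for o in dr.normalize_to_control(inds, layout)}
        assert out["E1T1"].normalized_ratio == pytest.approx(0.5)
        assert out["E2T1"].normalized_ratio == pytest.approx(0.25)

    def test_idempotent(self):
        layout = _layout_two_experiments()
        inds = [_ind("E1CTRL", 2.0), _ind("E1T1", 1.0),
                _ind("E2CTRL", 4.0), _ind("E2T1", 3.0)]
        once = dr.normalize_to_control(inds, layout)
        again = dr.normalize_to_control(
            [_ind(o.well_id, o.normalized_ratio) for o in once], layout
        )
        for a, b in zip(once, again):
            assert b.normalized_ratio == pytest.approx(a.normalized_ratio)

    def test_missing_control_raises(self):
        layout = PlateLayout(entries=(
            PlateEntry("T1", "X", 10.0, "ug/L", "treatment", "E9", 2.0, 1),
        ))
        with pytest.raises(ValueError, match="E9"):
            dr.normalize_to_control([_ind("T1", 1.0)], layout)


class TestDeadControlFloor:
    def test_mean_of_dead_controls(self):
        inds = [_ind("D1", 0.5, norm=0.18), _ind("D2", 0.5, norm=0.22)]
        assert dr.dead_control_floor(inds) == pytest.approx(0.20)
        assert dr.dead_control_floor([_ind("D", 1, norm=0.3)]) == pytest.approx(0.3)

    def test_no_dead_controls_is_config_error(self):
        with pytest.raises(ValueError, match="floor"):
            dr.dead_control_floor([])

    def test_estimator_accuracy_simulation(self):
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(50):
            inds = [_ind(f"D{i}", 1, norm=0.2 + rng.normal(0, 0.05))
                    for i in range(10)]
            errs.append(dr.dead_control_floor(inds) - 0.2)
        assert np.mean(np.abs(errs)) <= 0.03


class TestReplicateMeans:
    def _layout(self, concs, n_exp=3, n_rep=5):
        entries = []
        for e in range(1, n_exp + 1):
            for i, c in enumerate(concs):
                for r in range(n_rep):
                    entries.append(PlateEntry(
                        f"E{e}C{i}R{r}", "X", c, "mg/L", "treatment",
                        f"E{e}", 2.0, 1))
        return PlateLayout(entries=tuple(entries))

    def test_full_grid_counts(self):
        concs = [1, 2, 4, 8, 16, 32, 64, 128]
        layout = self._layout(concs)
        inds = [_ind(e.well_id, 1.0, norm=1.0) for e in layout.entries]
        points = dr.aggregate_replicate_means(inds, layout)
        assert len(points) == 24  # 3 experiments x 8 concentrations

    def test_qc_failed_cell_dropped_with_warning(self, caplog):
        concs = [1, 2, 4, 8, 16, 32, 64, 128]
        layout = self._layout(concs)
        inds = []
        for e in layout.entries:
            failed = e.experiment_id == "E1" and e.concentration == 1
            inds.append(_ind(e.well_id, np.nan if failed else 1.0,
                             qc=not failed, norm=None if failed else 1.0))
        with caplog.at_level("WARNING"):
            points = dr.aggregate_replicate_means(inds, layout)
        assert len(points) == 23
        assert any("no QC-passing" in r.message for r in caplog.records)

    def test_mean_of_five(self):
        layout = self._layout([10.0], n_exp=1, n_rep=5)
        vals = [1.0, 1.2, 0.8, 1.1, 0.9]
        inds = [_ind(e.well_id, v, norm=v)
                for e, v in zip(layout.entries, vals)]
        points = dr.aggregate_replicate_means(inds, layout)
        assert len(points) == 1
        assert points[0].response == pytest.approx(1.0)
        assert points[0].n_individuals == 5


# ---------------------------------------------------------------------------
# control comparison and immobile fraction


class TestCompareControls:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95]
        rep = dr.compare_controls(vals, vals)
        assert rep.pvalue > 0.9
        assert not rep.significant

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(17)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(1.0, 0.1, size=10)
            b = rng.normal(1.0, 0.1, size=10)
            rejections += dr.compare_controls(a, b).significant
        assert abs(rejections / n_sim - 0.05) <= 0.02

    def test_power_large_shift(self):
        rng = np.random.default_rng(23)
        hits = sum(
            dr.compare_controls(rng.normal(0, 1, 15),
                                rng.normal(3, 1, 15)).significant
            for _ in range(100)
        )
        assert hits >= 99

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            dr.compare_controls([1.0, 2.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("n,k,expected", [(5, 5, 1.0), (5, 0, 0.0),
                                          (20, 9, 0.45)])
def test_immobile_fraction(n, k, expected):
    rec = ImmobilizationRecord("w", 1.0, "mg/L", n, k, "E1", 24.0)
    assert dr.immobile_fraction(rec) == pytest.approx(expected)
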