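"""Competing-risk stack: KM, log-rank, Aalen-Johansen, Gray, Fine-Gray."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ecmolung import survival_analysis as sv


def _records(times, events, groups=None):
    df = pd.DataFrame({"time_days": times, "event_code": events})
    if groups is not None:
        df["group"] = groups
    return df


def _step_at(xs, ys, t):
    idx = np.searchsorted(np.asarray(xs), t, side="right") - 1
    return 1.0 if idx < 0 else np.asarray(ys)[idx]


def simulate_competing(n, seed, shr_group=1.0, p_base=0.35, cens_rate=0.15):
    """Fine-Gray style data: P(event1 | x) = 1-(1-p_base)^exp(beta x)."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    beta = np.log(shr_group)
    p1 = 1 - (1 - p_base) ** np.exp(beta * x)
    is1 = rng.random(n) < p1
    u = rng.random(n)
    t = np.where(is1, -np.log(1 - u * (1 - np.exp(-3.0))), rng.exponential(1.0, n))
    e = np.where(is1, 1, 2)
    c = rng.exponential(1.0 / cens_rate, n)
    time = np.minimum(t, c)
    ev = np.where(t <= c, e, 0)
    return _records(np.maximum(time, 1e-9), ev, x.astype(int))


class TestKM:
    def test_textbook_product_limit(self):
        r = sv.km_estimate(_records([1, 2, 3], [1, 1, 1]))
        # curve starts at S(0)=1 and drops by 1/3 at each event time
        np.testing.assert_allclose(r["survival"], [1.0, 2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(r["times"], [0, 1, 2, 3])

    def test_five_subject_hand_oracle(self):
        """Events at 2, 4, 7 with a censoring at 3: S = 4/5, then 4/5*2/3
        at t=4, then 0 at t=7."""
        r = sv.km_estimate(_records([2, 3, 4, 7, 7], [1, 0, 1, 1, 1]))
        assert _step_at(r["times"], r["survival"], 2) == pytest.approx(4 / 5)
        assert _step_at(r["times"], r["survival"], 4) == pytest.approx(4 / 5 * 2 / 3)
        assert _step_at(r["times"], r["survival"], 7) == pytest.approx(0.0)

    def test_time_shift_equivariance(self):
        base = _records([1.0, 2.5, 4.0, 6.0], [1, 0, 1, 1])
        shifted = base.copy()
        shifted["time_days"] += 5.0
        a = sv.km_estimate(base)
        b = sv.km_estimate(shifted)
        # ignore the S(0)=1 baseline row: every step moves by +5 days
        np.testing.assert_allclose(np.asarray(b["times"])[1:], np.asarray(a["times"])[1:] + 5.0)
        np.testing.assert_allclose(b["survival"], a["survival"])

    def test_all_censored_flagged(self):
        r = sv.km_estimate(_records([1, 2, 3], [0, 0, 0]))
        assert r["all_censored"]
        assert np.all(np.asarray(r["survival"]) == 1.0)
        assert r["restricted_mean"] == pytest.approx(r["horizon"])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        df = _records([1, 2, 3, 4] * 2, [1, 1, 0, 1] * 2, [0] * 4 + [1] * 4)
        r = sv.logrank_test(df)
        assert r["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_sized_example_matches_manual_computation(self):
        """n=8, no ties across groups: the observed-minus-expected sums are
        accumulated by hand below and must match."""
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 1, 1, 0, 1, 1, 0, 1]
        groups = [0, 1, 0, 0, 1, 1, 0, 1]
        df = _records(times, events, groups)
        o_minus_e, var = 0.0, 0.0
        t_arr, e_arr, g_arr = map(np.array, (times, events, groups))
        for tk in np.sort(t_arr[e_arr == 1]):
            at = t_arr >= tk
            n, n1 = at.sum(), (at & (g_arr == 1)).sum()
            d = ((t_arr == tk) & (e_arr == 1)).sum()
            d1 = ((t_arr == tk) & (e_arr == 1) & (g_arr == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        r = sv.logrank_test(df)
        assert r["chi2"] == pytest.approx(expected_chi2, rel=1e-9)

    def test_p_value_approximates_permutation_null(self):
        rng = np.random.default_rng(3)
        n = 60
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.8).astype(int)
        g = rng.integers(0, 2, n)
        df = _records(t, e, g)
        observed = sv.logrank_test(df)["chi2"]
        perm_stats = []
        for _ in range(500):
            gp = rng.permutation(g)
            perm_stats.append(sv.logrank_test(_records(t, e, gp))["chi2"])
        p_perm = np.mean(np.asarray(perm_stats) >= observed)
        p_asym = sv.logrank_test(df)["p"]
        assert abs(p_perm - p_asym) < 0.1


class TestCIF:
    def test_reduces_to_one_minus_km_without_competing_events(self):
        df = _records([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        cif = sv.cif_estimate(df, event=1)
        km = sv.km_estimate(df, event=1)
        for t in cif["time"]:
            s = _step_at(km["times"], km["survival"], t)
            c = _step_at(cif["time"], cif["cif"], t)
            assert c == pytest.approx(1.0 - s, abs=1e-12)

    def test_six_subject_hand_oracle(self):
        """Times 1..6: event1 at 1, death at 2, event1 at 3, censor at 4,
        event1 at 5, censor at 6.  Hand Aalen-Johansen:
        CIF(1)=1/6; S(1)=5/6; CIF(3)=1/6+5/6*4/6*(1/4)=0.34722...;
        CIF(5)=...+S(5-)*1/2."""
        df = _records([1, 2, 3, 4, 5, 6], [1, 2, 1, 0, 1, 0])
        cif = sv.cif_estimate(df, event=1)
        c1 = 1 / 6
        s_before_3 = (1 - 1 / 6) * (1 - 1 / 5)
        c3 = c1 + s_before_3 * (1 / 4)
        s_before_5 = s_before_3 * (1 - 1 / 4)
        c5 = c3 + s_before_5 * (1 / 2)
        got = dict(zip(cif["time"], cif["cif"]))
        assert got[1.0] == pytest.approx(c1, abs=1e-12)
        assert got[3.0] == pytest.approx(c3, abs=1e-12)
        assert got[5.0] == pytest.approx(c5, abs=1e-12)

    def test_naive_km_overestimates_cif_with_competing_events(self):
        for seed in range(5):
            df = simulate_competing(400, seed)
            cif = sv.cif_estimate(df, event=1)
            km = sv.km_estimate(df, event=1)
            for t in cif["time"]:
                naive = 1.0 - _step_at(km["times"], km["survival"], t)
                aj = _step_at(cif["time"], cif["cif"], t)
                assert naive >= aj - 1e-12

    def test_monotone_bounded(self):
        df = simulate_competing(300, 9)
        cif1 = sv.cif_estimate(df, event=1)
        cif2 = sv.cif_estimate(df, event=2)
        assert (np.diff(cif1["cif"]) >= -1e-12).all()
        assert cif1["cif"].iloc[0] >= 0
        grid = np.union1d(cif1["time"], cif2["time"])
        total = [
            _step_at(cif1["time"], cif1["cif"], t) + _step_at(cif2["time"], cif2["cif"], t)
            for t in grid
        ]
        assert max(total) <= 1.0 + 1e-9

    def test_no_target_events_gives_zero_curve(self):
        df = _records([1, 2, 3], [2, 2, 0])
        cif = sv.cif_estimate(df, event=1)
        assert (cif["cif"] == 0).all()


class TestGray:
    def test_identical_groups_null(self):
        df = simulate_competing(100, 1)
        dup = pd.concat(
            [df.assign(group=0), df.assign(group=1)], ignore_index=True
        )
        r = sv.grays_test(dup)
        assert r["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert r["p"] > 0.99

    def test_agrees_with_logrank_without_competing_events(self):
        rng = np.random.default_rng(4)
        n = 500
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.where(g == 1, 0.7, 1.0))
        c = rng.exponential(2.0, n)
        df = _records(np.minimum(t, c), (t <= c).astype(int), g)
        gray = sv.grays_test(df, event=1)
        lr = sv.logrank_test(df, event=1)
        assert gray["statistic"] == pytest.approx(lr["chi2"], rel=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_power_on_separated_subdistributions(self, seed):
        df = simulate_competing(600, seed, shr_group=3.0)
        assert sv.grays_test(df, event=1)["p"] < 0.001

    def test_close_to_cmprsk_reference(self, tmp_path):
        """The score-form statistic tracks the classical Gray variance as
        implemented in R's cmprsk; the two are asymptotically equivalent
        and agree here within 20% with matching significance calls."""
        df = simulate_competing(400, 21, shr_group=2.0)
        csv = tmp_path / "records.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            library(cmprsk)
            d <- read.csv("{csv}")
            r <- cuminc(d$time_days, d$event_code, group=d$group)
            cat(r$Tests[1, "stat"], r$Tests[1, "pv"], sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        r_stat, r_p = float(lines[-2]), float(lines[-1])
        mine = sv.grays_test(df, event=1)
        assert mine["statistic"] == pytest.approx(r_stat, rel=0.2)
        assert (mine["p"] < 0.05) == (r_p < 0.05)


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        import statsmodels.api as sm

        df = simulate_competing(600, 2, shr_group=1.5)
        df = df[df["event_code"] != 2].reset_index(drop=True)
        res = sv.fine_gray_fit(df)
        cox = sm.PHReg(
            df["time_days"], df[["group"]], status=(df["event_code"] == 1).astype(int),
            ties="breslow",
        ).fit()
        assert res.coef == pytest.approx(float(cox.params[0]), abs=1e-6)
        assert res.se == pytest.approx(float(cox.bse[0]), rel=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_true_shr(self, seed):
        df = simulate_competing(2000, seed, shr_group=2.0)
        res = sv.fine_gray_fit(df)
        assert abs(res.coef - np.log(2.0)) < 3 * res.se

    def test_null_covariate_ci_coverage(self):
        """Under no group effect the 95% CI covers SHR=1 at roughly the
        nominal rate (scaled-down coverage simulation)."""
        covered = 0
        reps = 120
        for seed in range(reps):
            df = simulate_competing(250, 1000 + seed, shr_group=1.0)
            res = sv.fine_gray_fit(df)
            covered += res.ci_lower <= 1.0 <= res.ci_upper
        assert 0.88 <= covered / reps <= 0.99

    def test_shr_direction_matches_gray(self):
        for seed in range(5):
            df = simulate_competing(500, seed, shr_group=2.5)
            res = sv.fine_gray_fit(df)
            gray_p = sv.grays_test(df, event=1)["p"]
            assert res.shr > 1.0
            assert (res.p < 0.05) == (gray_p < 0.05) or res.p < 0.05

    def test_no_variation_rejected(self):
        df = simulate_competing(100, 3)
        df["group"] = 1
        with pytest.raises(ValueError, match="variation"):
            sv.fine_gray_fit(df)


class TestValidation:
    def test_bad_event_codes_rejected(self):
        with pytest.raises(ValueError):
            sv.km_estimate(_records([1, 2], [1, 7]))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            sv.km_estimate(_records([0.0, 2.0], [1, 1]))
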