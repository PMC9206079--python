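import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gluquanta.deconv import ReleaseEvent
from gluquanta.movie import APTrain
from gluquanta.quantal import (
    BoutonStats,
    QuantalFit,
    QuantalMixtureModel,
    binomial_release,
    bootstrap_histogram,
    bouton_stats,
    classify_modes,
    fit_quantal_mixture,
    group_summaries,
    is_single_quantum,
    quantize_events,
    two_vesicle_outcomes,
)


def _event(amplitude=1.0, latency=None, mode=None, time=100.0, flagged=False, nq=None):
    return ReleaseEvent(
        bouton_id=0,
        frame=int(time / 4),
        time=time,
        amplitude=amplitude,
        latency=latency,
        mode=mode,
        flagged=flagged,
        n_quanta=nq,
    )


class TestBootstrap:
    def test_single_amplitude_zero_noise(self):
        draws = bootstrap_histogram(np.array([2.5]), 0.0, m=1000, seed=0)
        assert np.all(draws == 2.5)

    def test_mean_matches_bootstrap_expectation(self, rng):
        amps = rng.uniform(0.5, 3.0, 40)
        m = 100_000
        draws = bootstrap_histogram(amps, 0.3, m=m, seed=1)
        spread = np.sqrt(amps.var() + 0.3**2)
        assert abs(draws.mean() - amps.mean()) < 3 * spread / np.sqrt(m) * 3
        # generous 3x on the SE since resampling adds variance

    def test_distribution_is_noise_convolution(self, rng):
        # KS distance to the analytic convolution CDF < 0.01 at m = 100000
        amps = rng.normal(1.0, 0.2, 30)
        sigma = 0.15
        draws = np.sort(bootstrap_histogram(amps, sigma, m=100_000, seed=2))
        grid_cdf = np.mean(
            stats.norm.cdf((draws[None, :] - amps[:, None]) / sigma), axis=0
        )
        emp = (np.arange(draws.size) + 0.5) / draws.size
        assert np.max(np.abs(emp - grid_cdf)) < 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_histogram(np.array([]), 0.1)


class TestMixtureFit:
    def test_center_recursion_arithmetic(self):
        fit = QuantalFit(q=1.0, lam=0.9, sigma_AN=0.1, sigma_BN=0.1, A=np.ones(4))
        assert np.allclose(fit.mu, [1.0, 1.9, 2.71, 3.439])
        fit_lin = QuantalFit(q=1.0, lam=1.0, sigma_AN=0.1, sigma_BN=0.1, A=np.ones(4))
        assert np.allclose(fit_lin.mu, [1, 2, 3, 4])

    def test_recovers_parameters_from_synthetic_amplitudes(self, rng):
        mu = np.cumsum(0.9 ** np.arange(4))
        w = np.array([0.7, 0.25, 0.05, 0.0])
        cls = rng.choice(4, size=150, p=w)
        sigma_bn = 0.1
        amps = mu[cls] + rng.normal(0, sigma_bn, 150)
        res = QuantalMixtureModel(amps, sigma_bn).fit(m=20_000, seed=0)
        assert res.success
        assert res.fit.q == pytest.approx(1.0, abs=0.05)
        assert res.fit.lam == pytest.approx(0.9, abs=0.1)

    def test_lambda_one_centers_near_integers(self, rng):
        mu = np.arange(1, 5, dtype=float)
        cls = rng.choice(4, size=200, p=[0.5, 0.3, 0.15, 0.05])
        amps = mu[cls] + rng.normal(0, 0.08, 200)
        fit = fit_quantal_mixture(amps, 0.08, m=20_000, seed=1)
        assert np.allclose(fit.mu, [1, 2, 3, 4], atol=0.15)

    def test_summary_and_params(self, rng):
        amps = np.concatenate([rng.normal(1, 0.1, 60), rng.normal(1.9, 0.1, 20)])
        res = QuantalMixtureModel(amps, 0.1).fit(m=10_000, seed=2)
        s = res.summary()
        assert "q" in s and "lambda" in s and "sigma_BN" in s
        assert set(res.params.index) >= {"q", "lambda", "sigma_AN"}

    def test_too_few_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            QuantalMixtureModel(np.array([1.0]), 0.1)


class TestQuantization:
    @pytest.fixture
    def fit(self):
        return QuantalFit(q=1.0, lam=0.9, sigma_AN=0.05, sigma_BN=0.05, A=np.ones(4))

    def test_amplitude_near_q_is_single_quantum(self, fit):
        e = _event(amplitude=1.2)
        quantize_events([e], fit)
        assert e.n_quanta == 1
        assert is_single_quantum(e, fit)  # below the 1.25 q gate

    def test_exact_q_is_one(self, fit):
        e = _event(amplitude=1.0)
        quantize_events([e], fit)
        assert e.n_quanta == 1

    def test_above_gate_not_single(self, fit):
        e = _event(amplitude=1.3)
        assert not is_single_quantum(e, fit)

    def test_overflow_capped_with_warning(self, fit):
        e = _event(amplitude=10.0)
        with pytest.warns(UserWarning, match="capped"):
            quantize_events([e], fit)
        assert e.n_quanta == 4

    def test_two_quantum_misclassification_low(self, rng, fit):
        # draws from the true 2-quantum peak at SNR 10 assign >= 90% correctly
        amps = 1.9 + rng.normal(0, np.sqrt(2) * 0.1, 1000)
        events = [_event(amplitude=a) for a in amps]
        quantize_events(events, fit)
        frac2 = np.mean([e.n_quanta == 2 for e in events])
        assert frac2 >= 0.90


class TestModeClassification:
    def test_latency_rules(self):
        train = APTrain.train_5hz(51)
        evs = [
            _event(latency=6.0, time=106.0),
            _event(latency=12.0, time=112.0),
            _event(latency=10.0, time=110.0),
        ]
        classify_modes(evs, train)
        assert [e.mode for e in evs] == ["synchronous", "asynchronous", "synchronous"]

    def test_no_stimulation_is_spontaneous(self):
        evs = [_event()]
        classify_modes(evs, None)
        assert evs[0].mode == "spontaneous"

    def test_pre_first_ap_event_has_no_mode(self):
        train = APTrain.train_5hz(51)
        e = _event(flagged=True, latency=None)
        classify_modes([e], train)
        assert e.mode is None


class TestBoutonStats:
    def _paired_events(self, quanta_first, quanta_second):
        train = APTrain.paired_pulse(10)
        evs = []
        for i, (q1, q2) in enumerate(zip(quanta_first, quanta_second)):
            t0 = train.ap_times[2 * i]
            if q1:
                evs.append(_event(nq=q1, latency=4.0, mode="synchronous", time=t0 + 4))
            if q2:
                evs.append(
                    _event(nq=q2, latency=4.0, mode="synchronous", time=t0 + 54)
                )
        return evs, train

    def test_ppr_pure_facilitation(self):
        evs, train = self._paired_events([0] * 10, [1] * 10)
        st = bouton_stats(evs, train)
        assert st.PPR == pytest.approx(2.0)

    def test_ppr_pure_depression(self):
        evs, train = self._paired_events([1] * 10, [0] * 10)
        st = bouton_stats(evs, train)
        assert st.PPR == pytest.approx(0.0)

    def test_ppr_balanced(self):
        evs, train = self._paired_events([1] * 10, [1] * 10)
        st = bouton_stats(evs, train)
        assert st.PPR == pytest.approx(1.0)

    def test_ppr_undefined_when_no_release(self):
        st = bouton_stats([], APTrain.paired_pulse(10))
        assert st.PPR is None

    def test_ppr_scale_invariant_and_bounded(self, rng):
        for _ in range(20):
            q1 = rng.integers(0, 5, 10)
            q2 = rng.integers(0, 5, 10)
            if q1.sum() + q2.sum() == 0:
                continue
            evs, train = self._paired_events(q1, q2)
            ppr = bouton_stats(evs, train).PPR
            assert 0.0 <= ppr <= 2.0
            evs3, _ = self._paired_events(3 * q1, 3 * q2)
            assert bouton_stats(evs3, train).PPR == pytest.approx(ppr)

    def test_conservation_and_rates(self):
        train = APTrain.train_5hz(51)
        evs = [
            _event(nq=2, latency=4.0, mode="synchronous", time=104),
            _event(nq=1, latency=30.0, mode="asynchronous", time=130),
            _event(nq=1, latency=None, mode="spontaneous", time=10),
        ]
        st = bouton_stats(evs, train)
        assert st.n_T == pytest.approx(3 / 51)
        assert st.n_S + st.n_A == pytest.approx(st.n_T)
        assert st.n_A == pytest.approx(1 / 51)  # spontaneous never counted

    def test_spontaneous_rate(self):
        evs = [_event(mode="spontaneous"), _event(mode="spontaneous", time=5000)]
        st = bouton_stats(evs, None, duration_ms=10_000.0)
        assert st.spont_rate == pytest.approx(0.2)


class TestBinomialRelease:
    def test_m_one_identity(self):
        p_rel, n_t = binomial_release(0.3, 1)
        assert p_rel == pytest.approx(0.3)
        assert n_t == pytest.approx(0.3)

    def test_low_probability_regime(self):
        # n_T ~ P_rel within 5% relative when n_T <= 0.1
        for m in (2, 5, 10):
            p_v = 0.1 / m
            p_rel, n_t = binomial_release(p_v, m)
            assert abs(n_t - p_rel) / n_t < 0.05

    @pytest.mark.parametrize("bad", [(-0.1, 2), (1.5, 2), (0.5, 0), (0.5, 2.5)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            binomial_release(*bad)

    def test_two_vesicle_enumeration(self):
        out = two_vesicle_outcomes(0.5)
        assert out["both_sync"] == pytest.approx(0.25)
        assert out["one_each"] == pytest.approx(0.50)
        assert out["both_async"] == pytest.approx(0.25)


def _stats_frame(n, frac, n_t, rng, n_events=10):
    return pd.DataFrame(
        {
            "bouton_id": np.arange(n),
            "n_T": n_t,
            "n_S": n_t * (1 - frac),
            "n_A": n_t * frac,
            "frac_async": frac,
            "n_events": np.full(n, n_events),
        }
    )


class TestGroupSummaries:
    def test_21_boutons_split_7_7_7(self, rng):
        df = _stats_frame(21, rng.uniform(0, 1, 21), rng.uniform(0.05, 2, 21), rng)
        out = group_summaries(df)
        assert list(out["terciles"]["n"]) == [7, 7, 7]

    def test_too_few_boutons_rejected(self, rng):
        df = _stats_frame(15, rng.uniform(0, 1, 15), rng.uniform(0.05, 2, 15), rng)
        with pytest.raises(ValueError, match="excluded"):
            group_summaries(df)

    def test_constant_fraction_null(self, rng):
        df = _stats_frame(60, np.full(60, 0.25), rng.uniform(0.05, 2, 60), rng)
        out = group_summaries(df)
        t = out["terciles"]
        assert np.allclose(t["frac_async_mean"], 0.25, atol=1e-12)

    def test_inverse_relation_detected_in_terciles(self, rng):
        # built-in inverse frac_async(n_T): T1 mean must exceed T3 mean
        wins = 0
        for s in range(20):
            r = np.random.default_rng(s)
            n_t = r.uniform(0.05, 2.0, 45)
            frac = np.clip(0.5 - 0.2 * n_t + r.normal(0, 0.05, 45), 0, 1)
            out = group_summaries(_stats_frame(45, frac, n_t, r))
            t = out["terciles"].set_index("tercile")
            wins += (
                t.loc["T1", "frac_async_mean"] > t.loc["T3", "frac_async_mean"]
            )
        assert wins >= 18
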