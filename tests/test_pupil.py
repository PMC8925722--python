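import numpy as np
import pytest

from pupilrl.agents import ModelParams, latent_trajectory
from pupilrl.envs import TimingConfig
from pupilrl.pupil import (
    DesignMatrix,
    PupilTrace,
    TrialResponseMatrix,
    build_design,
    cumulative_reward_fraction,
    eye_coefficient_correlation,
    moving_average_reward,
    preprocess_trace,
    regress_and_summarize,
    regress_session,
    rpe_sign_split,
    trial_responses,
)
from pupilrl.simulation import simulate_session

from .conftest import make_session

HYBRID = ModelParams("FQ_RPE_CK", alpha=0.6, alpha_k=0.13, beta=0.52, beta_k=1.63)


class TestPreprocess:
    def test_constant_trace_zero_z(self):
        trace = preprocess_trace(np.full(30_000, 7.3), fs=20.0)
        assert np.allclose(trace.z_filled, 0.0)
        assert trace.valid.all()

    def test_spike_masked(self, rng):
        x = rng.standard_normal(30_000)
        x[15_000] += 10 * x.std()
        trace = preprocess_trace(x, fs=20.0, lowpass_hz=None)
        assert not trace.valid[15_000]
        # non-spike frames keep sane z values
        assert np.nanmax(np.abs(trace.z[trace.valid])) < 6

    def test_lowpass_attenuates_8hz(self):
        t = np.arange(0, 600, 0.05)
        x = np.sin(2 * np.pi * 8.0 * t)
        trace = preprocess_trace(x, fs=20.0, mad_thresh=None, zscore="none")
        assert np.abs(trace.z_filled[200:-200]).max() < 0.1 * 1.0

    def test_lowpass_preserves_slow_component(self):
        t = np.arange(0, 600, 0.05)
        x = np.sin(2 * np.pi * 0.5 * t)
        trace = preprocess_trace(x, fs=20.0, mad_thresh=None, zscore="none")
        assert np.abs(trace.z_filled[200:-200]).max() > 0.9

    def test_short_trace_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            trace = preprocess_trace(np.random.default_rng(0).standard_normal(1000))
        assert np.isfinite(trace.z_filled).all()

    def test_masking_changes_output_on_spiky_trace(self, rng):
        x = rng.standard_normal(30_000)
        x[::5000] += 20.0
        with_mask = preprocess_trace(x, fs=20.0)
        without = preprocess_trace(x, fs=20.0, mad_thresh=None)
        assert not np.allclose(with_mask.z_filled, without.z_filled)

    def test_nonfinite_rejected(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(ValueError):
            preprocess_trace(x)


class TestTrialResponses:
    def test_constant_trace_zero_responses(self):
        cues = [20.0, 40.0, 60.0]
        trace = preprocess_trace(np.full(2000, 5.0), fs=20.0, cue_times=cues)
        resp = trial_responses(trace)
        assert resp.responses.shape == (3, 80)
        assert np.allclose(resp.responses, 0.0)

    def test_boxcar_construction(self):
        fs = 20.0
        cues = np.array([30.0, 60.0])
        z = np.zeros(2000)
        for cue in cues:
            i0 = int(cue * fs)
            z[i0 : i0 + 40] = 1.0  # height 1 on [0, 2) s post cue
        resp = trial_responses(PupilTrace.from_z(z, cues, fs=fs))
        starts = resp.bin_starts
        inside = (starts >= 0.0) & (starts < 2.0 - 1e-9)
        baseline = (starts >= -2.0) & (starts < -1.0)
        assert np.allclose(resp.responses[:, inside], 1.0)
        assert np.allclose(resp.responses[:, baseline], 0.0)

    def test_bin_grid(self):
        trace = PupilTrace.from_z(np.zeros(4000), [50.0], fs=20.0)
        resp = trial_responses(trace)
        assert resp.n_bins == 80
        assert resp.bin_edges[0] == pytest.approx(-3.0)
        assert resp.bin_edges[-1] == pytest.approx(5.0)

    def test_out_of_range_trials_dropped(self):
        trace = PupilTrace.from_z(np.zeros(2000), [1.0, 50.0, 99.9], fs=20.0)
        resp = trial_responses(trace)
        assert list(resp.trial_indices) == [2]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        trace = PupilTrace.from_z(rng.standard_normal(4000), [50.0, 80.0], fs=20.0)
        a = trial_responses(trace)
        b = trial_responses(trace)
        assert np.array_equal(a.responses, b.responses)


class TestDesign:
    def test_all_rewarded_moving_average_and_cumulative(self):
        n = 30
        session = make_session("LR" * 15, [1] * n)
        design = build_design(session, None, spec="observable")
        X = design.X
        assert np.allclose(X["r_ma"], 1.0)
        # normalized cumulative reward ramps to 1 over the session
        expected = design.trial_indices / n
        assert np.allclose(X["r_cum"], expected)

    def test_moving_average_window_arithmetic(self):
        # reward only on trial 1: at trial 21 the 20-trial window excludes it
        outcomes = [0] * 40
        outcomes[0] = 1
        ma = moving_average_reward(np.array(outcomes))
        assert ma[20] == 0.0  # trial 21 (0-based 20): window covers trials 2..21
        assert ma[19] == pytest.approx(1 / 20)  # trial 20: window covers 1..20
        # early trials renormalize over the available history
        assert ma[0] == 1.0
        assert ma[4] == pytest.approx(1 / 5)

    def test_cumulative_no_rewards(self):
        assert np.allclose(cumulative_reward_fraction(np.zeros(10)), 0.0)

    def test_observable_row_count(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 50, rng)
        design = build_design(session, traj, spec="observable")
        assert len(design.X) == 50 - 3
        assert design.trial_indices[0] == 3 and design.trial_indices[-1] == 49

    def test_selection_and_updating_row_counts(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 50, rng)
        for spec in ("selection", "updating"):
            design = build_design(session, traj, spec=spec)
            assert len(design.X) == 49
            assert design.trial_indices[0] == 2

    def test_dummy_coding(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 40, rng)
        design = build_design(session, traj, spec="observable")
        choices = session.choices[design.trial_indices - 1]
        assert np.array_equal(design.X["c"].to_numpy(), (choices == "R").astype(float))

    def test_updating_columns(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 40, rng)
        design = build_design(session, traj, spec="updating")
        assert {"c", "c_prev1", "r_prev1", "dq", "rpe", "dk", "cke", "r_ma", "r_cum"} <= set(
            design.predictors
        )
        idx = design.trial_indices - 1
        assert np.allclose(design.X["rpe"], traj.rpe[idx])

    def test_requires_trajectory(self, rng):
        session, _ = simulate_session(HYBRID, "mp", 20, rng)
        with pytest.raises(ValueError):
            build_design(session, None, spec="updating")

    def test_mismatched_trajectory_error(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 20, rng)
        other, other_traj = simulate_session(HYBRID, "mp", 30, rng)
        with pytest.raises(ValueError):
            build_design(session, other_traj, spec="selection")

    def test_unknown_spec(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 20, rng)
        with pytest.raises(ValueError):
            build_design(session, traj, spec="nope")


def _planted_pair(session, traj, rng, coef=2.0, noise=1.0, spec="observable"):
    """Synthesize a response matrix: coef * r_n on bins [1, 4) s plus noise."""
    design = build_design(session, traj, spec=spec)
    n_bins = 80
    starts = -3.0 + 0.1 * np.arange(n_bins)
    active = (starts >= 1.0) & (starts < 4.0)
    r = design.X["r"].to_numpy() if "r" in design.X else session.outcomes[
        design.trial_indices - 1
    ].astype(float)
    responses = np.outer(r, coef * active.astype(float))
    responses += noise * rng.standard_normal(responses.shape)
    resp = TrialResponseMatrix(
        responses=responses,
        bin_edges=np.concatenate([starts, [5.0]]),
        trial_indices=design.trial_indices.copy(),
        baselines=np.zeros(len(r)),
    )
    return resp, design


class TestRegression:
    def test_planted_coefficient_recovery(self, rng):
        pairs = []
        for _ in range(20):
            session, traj = simulate_session(HYBRID, "mp", 200, rng)
            pairs.append(_planted_pair(session, traj, rng))
        summ = regress_and_summarize(pairs, rng=rng, n_boot=200)
        i = summ.predictor_index("r")
        active = (summ.bin_starts >= 1.0) & (summ.bin_starts < 4.0)
        assert summ.mean_coef[i, active].mean() == pytest.approx(2.0, abs=0.1)
        assert summ.frac_significant[i, active].mean() > 0.9
        # chi-square flags the planted predictor
        assert np.nanmax(summ.chi2_pvalues[i, active]) < 0.01
        # bootstrap CI brackets the planted value on average over active bins
        assert summ.ci_low[i, active].mean() < 2.0 < summ.ci_high[i, active].mean()

    def test_null_predictor_calibrated(self, rng):
        pairs = []
        for _ in range(30):
            session, traj = simulate_session(HYBRID, "mp", 150, rng)
            pairs.append(_planted_pair(session, traj, rng, coef=0.0))
        summ = regress_and_summarize(pairs, rng=rng, n_boot=100)
        idx = [summ.predictor_index(p) for p in summ.predictors if p != "intercept"]
        overall = np.nanmean(summ.frac_significant[idx])
        assert 0.0 <= overall < 0.05
        # chi-square accepts chance level almost everywhere
        frac_rejected = np.nanmean(summ.chi2_pvalues[idx] < 0.05)
        assert frac_rejected < 0.2

    def test_duplicate_session_identical_coefficients(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 150, rng)
        pair = _planted_pair(session, traj, rng)
        summ = regress_and_summarize([pair, pair], rng=rng, n_boot=50)
        assert np.allclose(summ.coefs[0], summ.coefs[1], equal_nan=True)

    def test_rank_deficient_design_drops_column(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 100, rng)
        resp, design = _planted_pair(session, traj, rng)
        X = design.X.copy()
        X["dup"] = X["r"]  # aliased column
        bad = DesignMatrix(X=X, trial_indices=design.trial_indices, spec=design.spec)
        with pytest.warns(UserWarning):
            coefs, pvals = regress_session(resp, bad)
        assert np.isnan(coefs[-1]).all()

    def test_mismatched_bins_error(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 100, rng)
        a = _planted_pair(session, traj, rng)
        resp_b, design_b = _planted_pair(session, traj, rng)
        resp_b.bin_edges = resp_b.bin_edges + 0.5
        with pytest.raises(ValueError):
            regress_and_summarize([a, (resp_b, design_b)], rng=rng, n_boot=10)


def _rpe_pair(session, traj, rng, coef=1.0, noise=0.3):
    design = build_design(session, traj, spec="updating")
    n_bins = 80
    starts = -3.0 + 0.1 * np.arange(n_bins)
    active = (starts >= 1.0) & (starts < 3.0)
    rpe = design.X["rpe"].to_numpy()
    responses = np.outer(rpe, coef * active.astype(float))
    responses += noise * rng.standard_normal(responses.shape)
    resp = TrialResponseMatrix(
        responses=responses,
        bin_edges=np.concatenate([starts, [5.0]]),
        trial_indices=design.trial_indices.copy(),
        baselines=np.zeros(len(rpe)),
    )
    return resp, design


class TestRpeSignSplit:
    def test_planted_rpe_positive_in_both_groups(self, rng):
        pairs = []
        for _ in range(10):
            session, traj = simulate_session(HYBRID, "mp", 300, rng)
            pairs.append(_rpe_pair(session, traj, rng))
        pos, neg = rpe_sign_split(pairs, rng=rng, n_boot=50)
        assert pos is not None and neg is not None
        active = (pos.bin_starts >= 1.0) & (pos.bin_starts < 3.0)
        i = pos.predictor_index("rpe")
        assert pos.mean_coef[i, active].mean() > 0
        assert neg.mean_coef[neg.predictor_index("rpe"), active].mean() > 0

    def test_all_rewarded_negative_group_absent(self, rng):
        session = make_session("LR" * 100, [1] * 200)
        traj = latent_trajectory(HYBRID, session)
        pair = _rpe_pair(session, traj, rng)
        pos, neg = rpe_sign_split([pair], rng=rng, n_boot=10)
        assert neg is None

    def test_partition_preserves_row_counts(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 300, rng)
        design = build_design(session, traj, spec="updating")
        rpe = design.X["rpe"].to_numpy()
        assert (rpe > 0).sum() + (rpe < 0).sum() + (rpe == 0).sum() == len(design.X)

    def test_requires_updating_design(self, rng):
        session, traj = simulate_session(HYBRID, "mp", 100, rng)
        pair = _planted_pair(session, traj, rng, spec="observable")
        with pytest.raises(ValueError):
            rpe_sign_split([pair])


class TestEyeCorrelation:
    def _two_eye_summaries(self, rng, mirror=False, noise=0.5):
        pairs_l, pairs_r = [], []
        for s_i in range(10):
            session, traj = simulate_session(HYBRID, "mp", 250, rng)
            design = build_design(session, traj, spec="observable")
            starts = -3.0 + 0.1 * np.arange(80)
            # shared choice signal ramping over the 3-5 s window, per-session gain
            shape = np.where((starts >= 3.0), 1.0 + (starts - 3.0), 0.0)
            gain = 1.0 + 0.5 * rng.standard_normal()
            c = design.X["c"].to_numpy()
            base = np.outer(c, gain * shape)

            def make(sign):
                resp = sign * base + noise * rng.standard_normal(base.shape)
                return (
                    TrialResponseMatrix(
                        responses=resp,
                        bin_edges=np.concatenate([starts, [5.0]]),
                        trial_indices=design.trial_indices.copy(),
                        baselines=np.zeros(len(c)),
                    ),
                    design,
                )

            pairs_l.append(make(1.0))
            pairs_r.append(make(-1.0 if mirror else 1.0))
        left = regress_and_summarize(pairs_l, rng=rng, n_boot=20)
        right = regress_and_summarize(pairs_r, rng=rng, n_boot=20)
        return left, right

    def test_identical_summaries_r_one(self, rng):
        left, _ = self._two_eye_summaries(rng)
        r, p = eye_coefficient_correlation(left, left)
        assert r == pytest.approx(1.0)

    def test_negated_summaries_r_minus_one(self, rng):
        left, _ = self._two_eye_summaries(rng)
        import copy

        right = copy.deepcopy(left)
        right.coefs = -right.coefs
        r, _ = eye_coefficient_correlation(left, right)
        assert r == pytest.approx(-1.0)

    def test_shared_signal_correlates(self, rng):
        left, right = self._two_eye_summaries(rng, noise=0.5)
        r, p = eye_coefficient_correlation(left, right)
        assert r > 0.6
        assert p < 1e-6

    def test_mismatched_sessions_error(self, rng):
        left, right = self._two_eye_summaries(rng)
        import copy

        bad = copy.deepcopy(right)
        bad.coefs = bad.coefs[:5]
        with pytest.raises(ValueError):
            eye_coefficient_correlation(left, bad)
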