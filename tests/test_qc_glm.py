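"""DVARS censoring and LSS single-trial beta estimation."""

import numpy as np
import pytest

from rewardrs.design import TaskConfig, generate_session_design
from rewardrs.glm import (build_lss_design, convolve_events,
                          estimate_trial_betas, TrialBetaStack)
from rewardrs.hrf import HRFSpec, hrf_kernel
from rewardrs.qc import (CensorSet, DvarsSeries, compute_dvars,
                         flag_outlier_volumes)
from rewardrs.simulate import SubjectTruth, SimConfig, simulate_session_bold


class TestDvars:
    def test_constant_run_all_zeros(self):
        run = np.full((4, 4, 4, 10), 5.0)
        mask = np.ones((4, 4, 4), dtype=bool)
        assert np.all(compute_dvars(run, mask).values == 0)

    def test_uniform_jump_matches_formula(self):
        # every masked voxel jumps by +d between volumes 9 and 10, then
        # returns: DVARS (post-normalization scale) equals the scaled d
        run = np.full((3, 3, 3, 20), 500.0)
        run[..., 10] += 7.0
        mask = np.ones((3, 3, 3), dtype=bool)
        dv = compute_dvars(run, mask).values
        scale = 1000.0 / 500.0
        assert dv[10] == pytest.approx(7.0 * scale, rel=1e-6)
        assert dv[11] == pytest.approx(7.0 * scale, rel=1e-6)
        others = np.delete(dv, [10, 11])
        assert np.all(others == 0)

    def test_intensity_scaling_invariance(self):
        rng = np.random.default_rng(0)
        run = 300 + rng.normal(0, 2, (4, 4, 4, 30))
        mask = np.ones((4, 4, 4), dtype=bool)
        a = compute_dvars(run, mask).values
        b = compute_dvars(2 * run, mask).values
        assert np.allclose(a, b)

    def test_empty_mask_raises(self):
        run = np.ones((2, 2, 2, 5))
        with pytest.raises(ValueError, match="mask"):
            compute_dvars(run, np.zeros((2, 2, 2), dtype=bool))


class TestFlagOutliers:
    def test_constant_series_flags_nothing(self):
        dv = DvarsSeries(np.full(50, 2.0))
        assert flag_outlier_volumes(dv).n_excluded == 0

    def test_single_spike_flagged_exactly(self):
        vals = np.ones(100)
        vals[37] = 10.0
        cs = flag_outlier_volumes(DvarsSeries(vals))
        assert cs.excluded_volumes == (37,)

    def test_injected_spikes_recovered(self, small_task_cfg, cube_phantom):
        # end-to-end: spike volumes injected into simulated runs must be
        # flagged with sensitivity >= 0.9 at the default spike magnitude
        design = generate_session_design("neutral", 2, small_task_cfg)
        hits = total = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            spikes = sorted(rng.choice(np.arange(5, 195), 5, replace=False))
            truth = SubjectTruth(f"s{seed}", "AN", 14.0,
                                 {"neutral_rewarded": 0.3,
                                  "neutral_nonrewarded": 0.3},
                                 noise_sd=2.0,
                                 spike_volumes={"neutral": list(spikes)})
            data, _ = simulate_session_bold(design, cube_phantom, truth,
                                            seed)
            cs = flag_outlier_volumes(compute_dvars(data,
                                                    cube_phantom.union_mask))
            hits += sum(int(t) in cs.excluded_volumes for t in spikes)
            total += len(spikes)
        assert hits / total >= 0.9


class TestHrf:
    def test_default_kernel_peaks_between_4_and_6_s(self):
        k = hrf_kernel(HRFSpec(), tr=0.1)
        t_peak = np.argmax(k) * 0.1
        assert 4.0 <= t_peak <= 6.0

    def test_kernel_starts_at_zero_and_integrates_positive(self):
        k = hrf_kernel(HRFSpec(), tr=0.5)
        assert k[0] == 0
        assert k.sum() > 0

    def test_halving_tr_doubles_sample_count(self):
        assert len(hrf_kernel(HRFSpec(), tr=0.5)) == \
            2 * len(hrf_kernel(HRFSpec(), tr=1.0))


class TestLssDesign:
    def test_single_feedback_event_drops_other_column(self, small_task_cfg):
        cfg = TaskConfig(n_volumes=60, n_trials=1)
        design = generate_session_design("neutral", 1, cfg)
        dm = build_lss_design(design, 0)
        assert "other_trials" not in dm.names

    def test_widely_separated_trials_disjoint_support(self):
        cfg = TaskConfig(n_volumes=300, n_trials=2)
        design = generate_session_design("neutral", 5, cfg)
        # artificially move the second trial far from the first
        from rewardrs.design import SessionDesign, TrialEvent
        events = [TrialEvent(e.onset + (0.0 if e.trial_index == 0 else 150.0),
                             e.duration, e.phase, e.trial_index,
                             e.word_type, e.rewarded)
                  for e in design.events]
        d2 = SessionDesign(events, "neutral", 1.0, 300)
        dm = build_lss_design(d2, 0)
        target = dm.matrix[:, dm.names.index("target")]
        other = dm.matrix[:, dm.names.index("other_trials")]
        assert np.all((np.abs(target) > 1e-10).astype(int)
                      + (np.abs(other) > 1e-10).astype(int) <= 1)

    def test_censoring_target_support_raises(self, small_task_cfg):
        design = generate_session_design("neutral", 1, small_task_cfg)
        fb = design.feedback_events()[0]
        start = int(fb.onset)
        excluded = tuple(range(max(0, start - 2),
                               min(small_task_cfg.n_volumes, start + 35)))
        censor = CensorSet("r", excluded, small_task_cfg.n_volumes)
        with pytest.raises(ValueError, match="rank|target"):
            build_lss_design(design, fb.trial_index, censor)


def _isolated_trials_data(n_trials=3, sep_s=120.0, n_volumes=400):
    """Feedback-only design with trials far beyond the kernel length
    apart; noiseless data from known per-trial amplitudes."""
    from rewardrs.design import SessionDesign, TrialEvent

    events = [TrialEvent(10.0 + sep_s * i, 1.0, "feedback", i, "neutral",
                         i % 2 == 0) for i in range(n_trials)]
    design = SessionDesign(events, "neutral", 1.0, n_volumes)
    rng = np.random.default_rng(3)
    mask = np.ones((3, 3, 3), dtype=bool)
    amps = rng.normal(0, 1, (n_trials, 27))
    data = np.zeros((3, 3, 3, n_volumes))
    for e in design.feedback_events():
        reg = convolve_events([e], n_volumes, 1.0)
        data += (amps[e.trial_index][:, None] * reg).reshape(3, 3, 3,
                                                             n_volumes)
    return design, data, amps, mask


def _overlapping_pair_data():
    """Two feedback events 6 s apart (responses overlap heavily)."""
    from rewardrs.design import SessionDesign, TrialEvent

    events = [TrialEvent(10.0 + 6.0 * i, 1.0, "feedback", i, "neutral",
                         True) for i in range(2)]
    design = SessionDesign(events, "neutral", 1.0, 100)
    rng = np.random.default_rng(5)
    mask = np.ones((3, 3, 3), dtype=bool)
    amps = rng.normal(0, 1, (2, 27))
    data = np.zeros((3, 3, 3, 100))
    for e in design.feedback_events():
        reg = convolve_events([e], 100, 1.0)
        data += (amps[e.trial_index][:, None] * reg).reshape(3, 3, 3, 100)
    return design, data, amps, mask


@pytest.fixture(scope="module")
def noiseless(small_task_cfg, cube_phantom):
    design = generate_session_design("neutral", 4, small_task_cfg)
    truth = SubjectTruth("s", "AN", 14.0,
                         {"neutral_rewarded": 0.4,
                          "neutral_nonrewarded": 0.4}, noise_sd=0.0)
    sim = SimConfig(nuisance_scale=0.5)
    data, info = simulate_session_bold(design, cube_phantom, truth, 9, sim)
    return design, data, info, cube_phantom


class TestEstimateTrialBetas:
    def _true_patterns_in_trial_order(self, info):
        order = []
        pats = []
        for cond, idx in info["trial_order"].items():
            order.extend(idx)
            pats.extend(info["patterns"][cond])
        pats = np.asarray(pats)[np.argsort(order)]
        return pats

    def test_noiseless_nonoverlapping_recovery_exact(self):
        # trials separated far beyond the kernel length, no drift basis:
        # LSS recovers the generating amplitudes to machine precision
        design, data, amps, mask = _isolated_trials_data()
        stack = estimate_trial_betas(data, design, mask, highpass_s=1e9)
        assert np.abs(stack.betas - amps).max() < 1e-10

    def test_lss_beats_naive_single_trial_model(self):
        # two heavily overlapping trials: the other-trial regressor makes
        # the LSS model span the truth exactly; a per-trial-only model
        # misattributes the neighbour's response
        design, data, amps, mask = _overlapping_pair_data()
        stack = estimate_trial_betas(data, design, mask)
        lss_err = np.abs(stack.betas - amps).max()

        naive_betas = []
        Y = data[mask, :].T
        for e in sorted(design.feedback_events(),
                        key=lambda ev: ev.trial_index):
            dm = build_lss_design(design, e.trial_index)
            keep = [j for j, nm in enumerate(dm.names)
                    if nm != "other_trials"]
            coef, *_ = np.linalg.lstsq(dm.matrix[:, keep], Y, rcond=None)
            naive_betas.append(coef[0])
        naive_err = np.abs(np.asarray(naive_betas) - amps).max()
        assert lss_err < 1e-8 < 0.01 < naive_err

    def test_simulated_run_betas_track_true_patterns(self, noiseless):
        # overlapping 20-trial run: LSS is approximate (other trials are
        # summed into one regressor) but each estimated pattern must stay
        # tightly correlated with its generating pattern
        design, data, info, phantom = noiseless
        stack = estimate_trial_betas(data, design, phantom.union_mask)
        truth = self._true_patterns_in_trial_order(info)
        rs = [np.corrcoef(b, t)[0, 1] for b, t in zip(stack.betas, truth)]
        assert min(rs) > 0.85
        # and the RS statistic computed from estimated betas matches the
        # one computed from the generating patterns
        from rewardrs.rsa import mean_pairwise_rs

        est_rs = mean_pairwise_rs(np.corrcoef(stack.betas))
        true_rs = mean_pairwise_rs(np.corrcoef(truth))
        assert abs(est_rs - true_rs) < 0.05

    def test_residuals_orthogonal_to_design(self, noiseless):
        design, data, _, phantom = noiseless
        dm = build_lss_design(design, 0)
        Y = data[phantom.union_mask, :].T[dm.rows]
        coef, *_ = np.linalg.lstsq(dm.matrix, Y, rcond=None)
        resid = Y - dm.matrix @ coef
        assert np.abs(dm.matrix.T @ resid).max() < 1e-5

    def test_constant_shift_absorbed_by_intercept(self, noiseless):
        design, data, _, phantom = noiseless
        data = data.astype(float)
        a = estimate_trial_betas(data, design, phantom.union_mask)
        b = estimate_trial_betas(data + 50.0, design, phantom.union_mask)
        assert np.allclose(a.betas, b.betas, atol=1e-8)

    def test_censoring_outside_event_support_changes_nothing(
            self, noiseless, small_task_cfg):
        design, data, _, phantom = noiseless
        # censor the final volumes, after every convolved response decays
        n = small_task_cfg.n_volumes
        last_end = max(e.onset + e.duration for e in design.events)
        start = int(np.ceil(last_end + 33))
        if start < n:
            censor = CensorSet("r", tuple(range(start, n)), n)
            a = estimate_trial_betas(data, design, phantom.union_mask)
            b = estimate_trial_betas(data, design, phantom.union_mask,
                                     censor)
            # drift columns change with row deletion; betas stay close
            assert np.allclose(a.betas, b.betas, atol=1e-2)

    def test_isolated_trials_match_single_trial_ols(self):
        # orthogonality limit: with trials separated far beyond the
        # kernel length, the LSS estimate of a trial equals the OLS
        # estimate computed on a run containing only that trial
        design, data, amps, mask = _isolated_trials_data()
        lss = estimate_trial_betas(data, design, mask, highpass_s=1e9)
        for e in design.feedback_events():
            solo = np.zeros_like(data)
            reg = convolve_events([e], design.n_volumes, design.tr)
            solo += (amps[e.trial_index][:, None] * reg).reshape(solo.shape)
            dm = build_lss_design(design, e.trial_index, highpass_s=1e9)
            keep = [j for j, nm in enumerate(dm.names)
                    if nm != "other_trials"]
            coef, *_ = np.linalg.lstsq(dm.matrix[:, keep],
                                       solo[mask, :].T, rcond=None)
            row = lss.meta.index[lss.meta["trial_index"]
                                 == e.trial_index][0]
            assert np.allclose(lss.betas[row], coef[0], atol=1e-8)

    def test_stack_roundtrip_and_selection(self, noiseless, tmp_path):
        design, data, _, phantom = noiseless
        stack = estimate_trial_betas(data, design, phantom.union_mask,
                                     subject_id="s01", session="neutral")
        stack.save(tmp_path / "stack")
        back = TrialBetaStack.load(tmp_path / "stack")
        assert np.allclose(back.betas, stack.betas)
        assert back.subject_id == "s01"
        rew = back.select(rewarded=True)
        assert rew.betas.shape[0] == int(design.rewarded.sum())
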