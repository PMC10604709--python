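"""Leave-last-out prediction, bias/imprecision, pcVPC, NPC and NPDE."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from adapk.data import Cohort, DoseEvent, Observation, Subject, hold_out_last
from adapk.evaluation import (
    PredictionPair,
    bootstrap_performance,
    leave_last_out_predict,
    mpe,
    npc,
    npde,
    pcvpc,
    rmspe,
)
from adapk.population import RandomEffects, final_parameters
from adapk.simulate import DesignSpec, generate_cohort
from adapk.structural import concentration, individual_params

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def _pairs(obs, pred):
    return [
        PredictionPair(subject_id=f"S{i}", y_obs=o, y_pred=p)
        for i, (o, p) in enumerate(zip(obs, pred))
    ]


class TestMetrics:
    def test_mpe_hand_arithmetic(self):
        assert mpe(_pairs([4, 6, 10], [5, 5, 9])) == pytest.approx(-1 / 3)
        assert mpe(_pairs([8], [10])) == pytest.approx(2.0)
        assert mpe(_pairs([3, 3], [3, 3])) == 0.0

    def test_rmspe_hand_arithmetic(self):
        assert rmspe(_pairs([4, 6, 10], [5, 5, 9])) == pytest.approx(1.0)
        assert rmspe(_pairs([3, 3], [3, 3])) == 0.0
        # constant error: equality case of rmspe >= |mpe|
        p = _pairs([4, 6], [6, 8])
        assert rmspe(p) == pytest.approx(abs(mpe(p))) == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mpe([])
        with pytest.raises(ValueError):
            rmspe([])

    def test_rmspe_dominates_mpe(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(1, 30)
            p = _pairs(rng.uniform(0, 20, n), rng.uniform(0, 20, n))
            assert rmspe(p) >= abs(mpe(p)) - 1e-12


class TestLeaveLastOut:
    def test_noiseless_self_consistency(self, final_pop):
        # held-out point generated exactly from the subject's own parameters
        # with near-zero residual noise is recovered by its own EBE prediction
        pop = final_pop.with_values(err_prop=1e-6)
        eta = RandomEffects(0.3, -0.2)
        params = individual_params(pop, eta, albumin=3.5, aaa=0)
        doses = tuple(DoseEvent(336.0 * k, 40.0) for k in range(8))
        times = (400.0, 900.0, 1400.0, 2000.0)
        obs = tuple(
            Observation(t, concentration(params, doses, t)) for t in times
        )
        s = Subject(id="X", doses=doses, observations=obs, albumin=3.5, aaa=0)
        cohort = hold_out_last(Cohort(subjects=(s, replace(s, id="Y")), meta={}))
        pairs = leave_last_out_predict(cohort, pop)
        for p in pairs:
            assert p.y_pred == pytest.approx(p.y_obs, rel=1e-6)

    def test_one_pair_per_subject(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        pairs = leave_last_out_predict(hold_out_last(cohort), final_pop)
        assert len(pairs) == cohort.n_subjects
        assert len({p.subject_id for p in pairs}) == cohort.n_subjects

    def test_requires_hold_out_flags(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        with pytest.raises(ValueError, match="hold_out_last"):
            leave_last_out_predict(cohort, final_pop)

    def test_seeing_the_point_improves_prediction(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        held = hold_out_last(cohort)
        pairs_loo = leave_last_out_predict(held, final_pop)
        # same point predicted with ALL observations available to the EBEs
        full = Cohort(
            subjects=tuple(
                replace(
                    s,
                    observations=tuple(
                        replace(o, held_out=(k == len(s.observations) - 1))
                        for k, o in enumerate(s.observations)
                    ),
                )
                for s in cohort
            ),
            meta={},
        )
        from adapk._core import CohortArrays, predict, solve_ebes

        arr = CohortArrays(full, use_held_out=True)  # EBEs see everything
        eta, *_ = solve_ebes(arr, final_pop)
        pred = predict(arr, final_pop, eta)
        errs_full = []
        for i in range(arr.n):
            j = int(np.argmax(arr.held_mask[i]))
            errs_full.append(abs(pred[i, j] - arr.y[i, j]))
        errs_loo = [abs(p.y_pred - p.y_obs) for p in pairs_loo]
        assert np.median(errs_full) <= np.median(errs_loo)


class TestBootstrapPerformance:
    def test_identical_models_difference_centered_at_zero(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        held = hold_out_last(cohort)
        summaries, diffs = bootstrap_performance(
            held, {"a": final_pop, "b": final_pop}, n_reps=200, seed=4
        )
        assert summaries["a"].mpe == summaries["b"].mpe
        for _, row in diffs.iterrows():
            assert row["difference"] == pytest.approx(0.0, abs=1e-12)
            assert row["ci95_low"] <= 0.0 <= row["ci95_high"]

    def test_constructed_bias_gap_is_detected(self):
        rng = np.random.default_rng(11)
        truth = rng.uniform(2, 12, size=54)
        obs = truth
        pred_a = truth + rng.normal(0, 0.1, 54)
        pred_b = truth + 3 + rng.normal(0, 0.1, 54)
        cohort_pairs = {
            "a": _pairs(obs, np.clip(pred_a, 0, None)),
            "b": _pairs(obs, pred_b),
        }

        # feed precomputed pairs through the resampling core via a stub
        from adapk import evaluation as ev

        orig = ev.leave_last_out_predict
        try:
            ev.leave_last_out_predict = lambda c, m: cohort_pairs[m]
            held = object.__new__(Cohort)  # placeholder; stub ignores it
            summaries, diffs = ev.bootstrap_performance(
                held, {"a": "a", "b": "b"}, n_reps=300, seed=7
            )
        finally:
            ev.leave_last_out_predict = orig
        row = diffs[(diffs.metric == "mpe")].iloc[0]
        assert row["significant"]
        assert row["ci95_high"] < 0  # model a is less biased than b

    def test_same_seed_identical_cis(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        held = hold_out_last(cohort)
        s1, _ = bootstrap_performance(held, {"m": final_pop}, n_reps=100, seed=5)
        s2, _ = bootstrap_performance(held, {"m": final_pop}, n_reps=100, seed=5)
        assert s1["m"].ci_mpe == s2["m"].ci_mpe
        assert s1["m"].ci_rmspe == s2["m"].ci_rmspe


def _homogeneous_cohort(final_pop, n=8):
    # two shared design points, one per quantile bin, so the prediction
    # correction is exactly 1 for every observation
    doses = tuple(DoseEvent(336.0 * k, 40.0) for k in range(6))
    times = (700.0, 1000.0)
    rng = np.random.default_rng(2)
    subs = []
    for i in range(n):
        obs = tuple(Observation(t, float(rng.uniform(1, 8))) for t in times)
        subs.append(
            Subject(id=f"H{i}", doses=doses, observations=obs, albumin=3.77, aaa=0)
        )
    return Cohort(subjects=tuple(subs), meta={})


class TestPcvpc:
    def test_homogeneous_design_has_unit_correction(self, final_pop):
        cohort = _homogeneous_cohort(final_pop)
        table = pcvpc(cohort, final_pop, n_sim=100, bins=2, seed=3)
        ys = np.array([o.concentration for s in cohort for o in s.observations])
        tads = np.array(
            [o.time - max(d.time for d in s.doses if d.time <= o.time)
             for s in cohort for o in s.observations]
        )
        for _, row in table.iterrows():
            sel = (tads >= row["tad_low"]) & (tads <= row["tad_high"])
            assert row["obs_p50"] == pytest.approx(np.median(ys[sel]), rel=1e-9)

    def test_correction_commutes_with_dose_scaling(self, final_pop):
        cohort = _homogeneous_cohort(final_pop)
        scaled = Cohort(
            subjects=tuple(
                replace(
                    s,
                    doses=tuple(replace(d, amount=2 * d.amount) for d in s.doses),
                    observations=tuple(
                        replace(o, concentration=2 * o.concentration)
                        for o in s.observations
                    ),
                )
                for s in cohort
            ),
            meta={},
        )
        t1 = pcvpc(cohort, final_pop, n_sim=200, bins=2, seed=9)
        t2 = pcvpc(scaled, final_pop, n_sim=200, bins=2, seed=9)
        for col in ("obs_p5", "obs_p50", "obs_p95"):
            assert np.allclose(t2[col], 2 * t1[col], rtol=1e-9)
        for col in ("sim_p50_low", "sim_p50_high"):
            # same seed, linear kinetics, proportional error: bands scale too
            assert np.allclose(t2[col], 2 * t1[col], rtol=0.05)

    def test_self_simulated_data_calibrated(self, final_pop):
        # observed medians inside the simulated 95% band in >= ~90% of bins
        inside = total = 0
        for seed in range(10):
            cohort, _ = generate_cohort(DesignSpec(seed=600 + seed), final_pop)
            table = pcvpc(cohort, final_pop, n_sim=200, seed=700 + seed)
            inside += int(
                ((table["obs_p50"] >= table["sim_p50_low"])
                 & (table["obs_p50"] <= table["sim_p50_high"])).sum()
            )
            total += len(table)
        assert inside / total >= 0.8


class TestNpc:
    def test_calibrated_on_self_simulated_data(self, final_pop):
        fracs = {0.5: [], 0.9: []}
        for seed in range(6):
            cohort, _ = generate_cohort(DesignSpec(seed=620 + seed), final_pop)
            table = npc(cohort, final_pop, n_sim=300, seed=720 + seed)
            t = table.set_index("interval")
            fracs[0.5].append(t.loc[0.5, "observed"])
            fracs[0.9].append(t.loc[0.9, "observed"])
        n = 148
        for level, vals in fracs.items():
            tol = 2.5 * np.sqrt(level * (1 - level) / n)
            assert abs(np.mean(vals) - level) < tol

    def test_conservative_model_detected(self, final_pop):
        cohort, _ = generate_cohort(DesignSpec(seed=9), final_pop)
        wide = final_pop.with_values(err_prop=2 * final_pop.err_prop)
        table = npc(cohort, wide, n_sim=300, seed=10).set_index("interval")
        assert table.loc[0.5, "observed"] > 0.5

    def test_no_observations_gives_empty_table(self, final_pop):
        s = Subject(id="N", doses=(DoseEvent(0.0, 40.0),), observations=(),
                    albumin=3.77, aaa=0)
        table = npc(Cohort(subjects=(s,), meta={}), final_pop, n_sim=200, seed=1)
        assert table.empty

    def test_small_nsim_warns(self, final_pop, study_cohort):
        cohort, _ = study_cohort
        with pytest.warns(RuntimeWarning, match="n_sim"):
            npc(cohort, final_pop, n_sim=50, seed=1)


class TestNpde:
    def test_calibrated_on_self_simulated_data(self, final_pop):
        cohort, _ = generate_cohort(DesignSpec(seed=8), final_pop)
        res = npde(cohort, final_pop, n_sim=1000, seed=18)
        assert abs(res.mean) < 0.2
        assert 0.7 < res.variance < 1.3
        assert len(res.table) == cohort.n_obs

    def test_single_observation_reduces_to_marginal_transform(self, final_pop):
        doses = tuple(DoseEvent(336.0 * k, 40.0) for k in range(4))
        subs = tuple(
            Subject(id=f"U{i}", doses=doses,
                    observations=(Observation(700.0 + 30 * i, 2.0 + i),),
                    albumin=3.77, aaa=0)
            for i in range(6)
        )
        cohort = Cohort(subjects=subs, meta={})
        n_sim = 500
        res = npde(cohort, final_pop, n_sim=n_sim, seed=21)
        # manual marginal transform with the same simulated replicates
        from adapk._core import CohortArrays
        from adapk.evaluation import _simulate_observations

        arr = CohortArrays(cohort)
        sims = _simulate_observations(
            arr, final_pop, n_sim, np.random.default_rng(21)
        )
        for i in range(arr.n):
            S = sims[:, i, 0]
            y = arr.y[i, 0]
            sd = S.std()
            ys = (y - S.mean()) / sd
            ss = (S - S.mean()) / sd
            below = (ss < ys).sum()
            ties = (ss == ys).sum()
            u = (below + 0.5 * ties + 0.5) / (n_sim + 1)
            assert res.table.iloc[i]["npde"] == pytest.approx(stats.norm.ppf(u))

    def test_ties_at_assay_floor_stay_finite(self, final_pop):
        # troughs reported exactly at the quantification limit tie with
        # floored simulated values; midranking keeps the npde finite
        doses = tuple(DoseEvent(336.0 * k, 10.0) for k in range(4))
        subs = tuple(
            Subject(id=f"F{i}", doses=doses,
                    observations=(Observation(1340.0, 0.1), Observation(1672.0, 0.1)),
                    albumin=1.97 + i * 0.1, aaa=1)
            for i in range(4)
        )
        res = npde(Cohort(subjects=subs, meta={}), final_pop, n_sim=400, seed=2)
        assert np.isfinite(res.values).all()
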