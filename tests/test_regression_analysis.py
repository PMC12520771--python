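import math

import numpy as np
import pandas as pd
import pytest

from loudadapt.design import make_exp1_design, make_exp3_design
from loudadapt.observer import ObserverParams, simulate_session
from loudadapt.psychometrics import PsychometricFit, aggregate_proportions, fit_cumulative_gaussian
from loudadapt.regression_analysis import (
    InsufficientLevelsError,
    MissingPhaseError,
    SubjectSummary,
    UnclassifiableError,
    adaptation_index,
    context_effects,
    half_split_contrast,
    pse_deviations,
    with_adaptation_index,
)


def fit_at(probe, pse, converged=True):
    return PsychometricFit(pse_db=pse, sigma_db=3.0, sse_or_loglik=0.0,
                           converged=converged, n_points=7, probe_db=probe)


def summary_with(devs, block_order=None, subject="s0", condition="baseline"):
    return SubjectSummary(subject=subject, condition=condition, deviations=devs,
                          block_order=block_order)


class TestPseDeviations:
    def test_signed_deviations(self):
        s = pse_deviations([fit_at(40.0, 44.0), fit_at(80.0, 76.0)], "s0", "baseline")
        assert s.deviations == {40.0: 4.0, 80.0: -4.0}

    def test_nonconverged_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            s = pse_deviations(
                [fit_at(40.0, 44.0), fit_at(60.0, 0.0, converged=False)], "s0", "baseline"
            )
        assert 60.0 not in s.deviations
        assert "non-converged" in caplog.text

    def test_all_nonconverged_raises(self):
        with pytest.raises(InsufficientLevelsError):
            pse_deviations([fit_at(40.0, 40.0, converged=False)], "s0", "baseline")

    def test_cohort_mean_matches_closed_form(self):
        # (1 - w)(mu - L) with w = 0.8, mu = 60
        params = ObserverParams(w_by_condition={"baseline": 0.8}, anchor_init_db=60.0,
                                anchor_lr=0.0, noise_probe_db=3.0, noise_comp_db=3.0,
                                lapse=0.0)
        devs40, devs80 = [], []
        for seed in range(25):
            design = make_exp1_design("baseline", seed)
            recs = simulate_session(design, params, seed + 2000, "s0")
            for probe, sink in ((40.0, devs40), (80.0, devs80)):
                fit = fit_cumulative_gaussian(aggregate_proportions(recs, "s0", probe))
                sink.append(fit.pse_db - probe)
        assert np.mean(devs40) == pytest.approx(4.0, abs=0.5)
        assert np.mean(devs80) == pytest.approx(-4.0, abs=0.5)


class TestAdaptationIndex:
    def test_zero_deviations(self):
        s = summary_with({40.0: 0.0, 60.0: 0.0, 80.0: 0.0})
        assert adaptation_index(s) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        devs = {L: (1 - 0.8) * (60.0 - L) for L in (40.0, 50.0, 60.0, 70.0, 80.0)}
        assert adaptation_index(summary_with(devs)) == pytest.approx(-0.2, abs=1e-12)

    def test_hand_computed_ols(self):
        # OLS on (40,3) (50,2) (60,0) (70,-1) (80,-3): slope -0.15, intercept 9.2
        s = summary_with({40.0: 3.0, 50.0: 2.0, 60.0: 0.0, 70.0: -1.0, 80.0: -3.0})
        filled = with_adaptation_index(s)
        assert filled.adaptation_slope == pytest.approx(-0.15, abs=1e-12)
        assert filled.adaptation_intercept == pytest.approx(9.2, abs=1e-12)

    def test_intercept_absorbs_constant_shift(self):
        devs = {40.0: 3.0, 60.0: 0.0, 80.0: -3.0}
        shifted = {k: v + 5.0 for k, v in devs.items()}
        assert adaptation_index(summary_with(devs)) == pytest.approx(
            adaptation_index(summary_with(shifted)), abs=1e-12
        )

    def test_single_level_raises(self):
        with pytest.raises(InsufficientLevelsError):
            adaptation_index(summary_with({40.0: 1.0}))


class TestHalfSplit:
    def test_classification(self):
        s = summary_with({40.0: 1.0, 80.0: -1.0},
                         block_order=(40.0, 50.0, 60.0, 70.0, 80.0))
        table = half_split_contrast([s])
        by_level = table.set_index("probe_db")["half"]
        assert by_level[40.0] == "first_half"
        assert by_level[80.0] == "second_half"

    def test_middle_block_dropped(self):
        s = summary_with({40.0: 1.0, 80.0: -1.0},
                         block_order=(50.0, 80.0, 40.0, 60.0, 70.0))
        table = half_split_contrast([s])
        assert set(table["probe_db"]) == {80.0}

    def test_unclassifiable_raises(self):
        # only one target level present and it sits in the middle block
        s = summary_with({40.0: 1.0}, block_order=(50.0, 80.0, 40.0, 60.0, 70.0))
        with pytest.raises(UnclassifiableError):
            half_split_contrast([s])

    @pytest.mark.parametrize("alpha,expect_effect", [(0.01, True), (0.0, False)])
    def test_order_effect_sign_from_simulation(self, alpha, expect_effect):
        params = ObserverParams(w_by_condition={"baseline": 0.9}, anchor_init_db=60.0,
                                anchor_lr=alpha, noise_probe_db=3.0, noise_comp_db=3.0,
                                lapse=0.0)
        summaries = []
        for seed in range(60):
            design = make_exp1_design("baseline", seed)
            recs = simulate_session(design, params, seed + 4000, "s0")
            fits = [fit_cumulative_gaussian(aggregate_proportions(recs, "s0", p))
                    for p in design.probe_levels]
            order = []
            for t in design.trials:
                if t.probe_db not in order:
                    order.append(t.probe_db)
            summaries.append(pse_deviations(fits, f"s{seed}", "baseline", order))
        table = half_split_contrast(summaries)
        at40 = table[table["probe_db"] == 40.0].groupby("half")["deviation_db"].mean()
        if expect_effect:
            # 40 dB block later in session: anchor pulled up by louder blocks
            assert at40["second_half"] > at40["first_half"]
        else:
            assert abs(at40["second_half"] - at40["first_half"]) < 1.0


def make_context_fits(subject, context, pses):
    majority = 40.0 if context == "quiet" else 80.0
    minority = 120.0 - majority
    rows = [
        {"subject": subject, "context": context, "phase": "baseline1",
         "probe_db": minority, "pse_db": pses["baseline_minority"], "converged": True},
        {"subject": subject, "context": context, "phase": "baseline2",
         "probe_db": majority, "pse_db": pses["baseline_majority"], "converged": True},
        {"subject": subject, "context": context, "phase": "test",
         "probe_db": majority, "pse_db": pses["test_majority"], "converged": True},
        {"subject": subject, "context": context, "phase": "test",
         "probe_db": minority, "pse_db": pses["test_minority"], "converged": True},
    ]
    return pd.DataFrame(rows)


class TestContextEffects:
    def test_labelling_and_deviation_values(self):
        fits = make_context_fits("s0", "quiet", {
            "baseline_minority": 79.0, "baseline_majority": 41.0,
            "test_majority": 41.5, "test_minority": 76.0,
        })
        table = context_effects(fits)
        cell = table.set_index("cell")["deviation_db"]
        assert cell["baseline_minority"] == pytest.approx(-1.0)
        assert cell["baseline_majority"] == pytest.approx(1.0)
        assert cell["test_minority"] == pytest.approx(-4.0)
        assert table.set_index("cell")["probe_db"]["test_majority"] == 40.0

    def test_missing_phase_raises(self):
        fits = make_context_fits("s0", "loud", {
            "baseline_minority": 41.0, "baseline_majority": 79.0,
            "test_majority": 78.0, "test_minority": 45.0,
        })
        with pytest.raises(MissingPhaseError):
            context_effects(fits[fits["phase"] != "baseline1"])

    @pytest.mark.parametrize("context", ["quiet", "loud"])
    def test_simulated_sign_pattern(self, context):
        params = ObserverParams(w_by_condition={"baseline": 0.94, "active": 0.88},
                                anchor_init_db=60.0, anchor_lr=0.005,
                                noise_probe_db=3.0, noise_comp_db=3.0, lapse=0.0)
        frames = []
        for seed in range(12):
            design = make_exp3_design(context, seed)
            recs = simulate_session(design, params, seed + 6000, f"s{seed}")
            rows = []
            for phase in ("baseline1", "baseline2", "test"):
                phase_recs = [r for r in recs if r.spec.phase == phase]
                for probe in sorted({r.spec.probe_db for r in phase_recs}):
                    fit = fit_cumulative_gaussian(
                        aggregate_proportions(phase_recs, f"s{seed}", probe)
                    )
                    rows.append({"subject": f"s{seed}", "context": context, "phase": phase,
                                 "probe_db": probe, "pse_db": fit.pse_db,
                                 "converged": fit.converged})
            frames.append(pd.DataFrame(rows))
        table = context_effects(pd.concat(frames, ignore_index=True))
        means = table.groupby("cell")["deviation_db"].mean()
        if context == "quiet":
            # rare loud tones in a quiet context: attenuated vs their baseline
            assert means["test_minority"] < means["baseline_minority"] - 0.5
        else:
            # rare quiet tones in a loud context: strongly enhanced
            assert means["test_minority"] > means["baseline_minority"] + 0.5
            assert means["test_minority"] > 2.0

    def test_no_learning_no_context_effect(self):
        params = ObserverParams(w_by_condition={"baseline": 0.94, "active": 0.88},
                                anchor_init_db=60.0, anchor_lr=0.0,
                                noise_probe_db=3.0, noise_comp_db=3.0, lapse=0.0)
        frames = []
        for seed in range(12):
            design = make_exp3_design("quiet", seed)
            recs = simulate_session(design, params, seed + 7000, f"s{seed}")
            rows = []
            for phase in ("baseline1", "baseline2", "test"):
                phase_recs = [r for r in recs if r.spec.phase == phase]
                for probe in sorted({r.spec.probe_db for r in phase_recs}):
                    fit = fit_cumulative_gaussian(
                        aggregate_proportions(phase_recs, f"s{seed}", probe)
                    )
                    rows.append({"subject": f"s{seed}", "context": "quiet", "phase": phase,
                                 "probe_db": probe, "pse_db": fit.pse_db,
                                 "converged": fit.converged})
            frames.append(pd.DataFrame(rows))
        table = context_effects(pd.concat(frames, ignore_index=True))
        wide = table.pivot_table(index="subject", columns="cell", values="deviation_db")
        diff = wide["test_minority"] - wide["baseline_minority"]
        # baseline phases use w=0.94, test uses w=0.88: expected gap is the
        # extra anchor pull (0.06 * (60 - 80) = -1.2 dB), not a context effect
        expected = (0.94 - 0.88) * (60.0 - 80.0)
        se = diff.std(ddof=1) / math.sqrt(len(diff))
        assert abs(diff.mean() - expected) < 3 * se + 0.3
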