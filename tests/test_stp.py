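"""Single-time-point dosimetry: reference, STP grids, nTIA, jackknife."""

from dataclasses import replace

import numpy as np
import pytest

from thyrostp.cohort import default_population, generate_cohort
from thyrostp.nlme import FitConfig
from thyrostp.stp import (
    MissingObservationError,
    TIAEstimate,
    jackknife_cell,
    jackknife_validate,
    ntp_tia,
    reference_fit,
    run_stp_grid,
    stp_fit,
)

#: cheap settings for tests that only exercise bookkeeping, not accuracy
CHEAP = FitConfig(
    seed=1, n_starts=20, n_refine=1, max_outer=5, obj_tol=1e-3,
    laplace_polish=False,
)


class TestTIAEstimate:
    def test_time_point_required_for_stp_methods(self):
        with pytest.raises(ValueError):
            TIAEstimate("P1", "s1TIA", 10.0)  # missing time point
        with pytest.raises(ValueError):
            TIAEstimate("P1", "rTIA", 10.0, 24.0)  # spurious time point

    def test_positive_value_required(self):
        with pytest.raises(ValueError):
            TIAEstimate("P1", "rTIA", 0.0)


@pytest.fixture(scope="module")
def degenerate_results(degenerate_cohort, fast_fit_config):
    """Reference fit + full s1TIA grid on the no-variability cohort."""
    recs = list(degenerate_cohort.records)
    pop, individuals = reference_fit(recs, fast_fit_config)
    grid, audit = run_stp_grid(
        recs, "a4c", [2.0, 6.0, 24.0, 48.0, 120.0], fast_fit_config
    )
    return degenerate_cohort, pop, individuals, grid, audit


class TestDegenerateCohort:
    """With no inter-individual variability and no noise, every estimator
    must reproduce the single true TIA."""

    def test_rtia_equals_truth(self, degenerate_results):
        cohort, _, individuals, _, _ = degenerate_results
        for ind in individuals:
            assert ind.tia == pytest.approx(
                cohort.truth_tia[ind.patient_id], rel=1e-3
            )

    def test_s1tia_equals_truth_at_every_time_point(self, degenerate_results):
        cohort, _, _, grid, _ = degenerate_results
        for est in grid:
            assert est.value == pytest.approx(
                cohort.truth_tia[est.patient_id], rel=1e-3
            ), f"at {est.time_point_h} h"

    def test_ntia_equals_truth(self, degenerate_results):
        cohort, pop, individuals, _, _ = degenerate_results
        ntp = ntp_tia(pop, individuals)
        truth = next(iter(cohort.truth_tia.values()))
        assert ntp.value == pytest.approx(truth, rel=1e-3)

    def test_ntia_from_population_mean_matches_definition(self, degenerate_results):
        from thyrostp.soef import analytic_tia

        _, pop, _, _, _ = degenerate_results
        assert ntp_tia(pop).value == analytic_tia(pop.fixed_effects)


class TestStpFit:
    def test_missing_observation_signals_skip(self, degenerate_cohort):
        recs = list(degenerate_cohort.records)
        with pytest.raises(MissingObservationError):
            stp_fit(recs, "P1", 96.0, "a4c", CHEAP)

    def test_unknown_patient_rejected(self, degenerate_cohort):
        with pytest.raises(ValueError):
            stp_fit(list(degenerate_cohort.records), "PX", 24.0, "a4c", CHEAP)

    def test_single_patient_single_time_gives_one_estimate(self, degenerate_cohort):
        est, audit = stp_fit(
            list(degenerate_cohort.records), "P2", 24.0, "a4c", CHEAP
        )
        assert est.patient_id == "P2"
        assert est.method == "s1TIA"
        assert est.time_point_h == 24.0

    def test_exclusion_contract_audited(self, degenerate_results):
        """Every STP fit uses exactly one observation of the target."""
        cohort, _, _, _, audit = degenerate_results
        assert (audit["n_target_obs"] == 1).all()
        n = len(cohort.patient_ids)
        obs_per_patient = len(cohort.records) // n
        assert (audit["n_obs_dataset"] == (n - 1) * obs_per_patient + 1).all()

    def test_frozen_prior_mode_close_to_joint(self, degenerate_cohort, fast_fit_config):
        recs = list(degenerate_cohort.records)
        joint, _ = stp_fit(recs, "P3", 48.0, "a4c", fast_fit_config)
        frozen, _ = stp_fit(
            recs, "P3", 48.0, "a4c", replace(fast_fit_config, stp_mode="frozen_prior")
        )
        assert frozen.value == pytest.approx(joint.value, rel=1e-3)


class TestRunStpGrid:
    def test_study_design_cell_counts(self, study_cohort):
        """The study design gives grid columns of 73/72/73/73/53/20 cells
        at 2/6/24/48/96/120 h (one patient lacks the 6-h point)."""
        grid, _ = run_stp_grid(
            list(study_cohort.records),
            "a4c",
            [2.0, 6.0, 24.0, 48.0, 96.0, 120.0],
            CHEAP,
        )
        counts = {}
        for est in grid:
            counts[est.time_point_h] = counts.get(est.time_point_h, 0) + 1
        assert [counts[t] for t in (2.0, 6.0, 24.0, 48.0, 96.0, 120.0)] == [
            73, 72, 73, 73, 53, 20,
        ]

    def test_unobserved_time_rejected(self, degenerate_cohort):
        with pytest.raises(ValueError):
            run_stp_grid(list(degenerate_cohort.records), "a4c", [72.0], CHEAP)

    def test_empty_grid_rejected(self, degenerate_cohort):
        with pytest.raises(ValueError):
            run_stp_grid(list(degenerate_cohort.records), "a4c", [], CHEAP)


class TestJackknife:
    def test_degenerate_cohort_zero_spread(self, degenerate_cohort, fast_fit_config):
        """Identical patients: removing any one of them cannot move the
        target's TIA."""
        report = jackknife_validate(
            list(degenerate_cohort.records), "a4c", [120.0], fast_fit_config
        )
        n = len(degenerate_cohort.patient_ids)
        assert len(report) == n
        assert (report["n_replicates"] == n - 1).all()
        assert np.all(report["tia_sd"] / report["tia_mean"] < 1e-6)

    def test_leaving_out_target_rejected(self, degenerate_cohort):
        with pytest.raises(ValueError):
            jackknife_cell(
                list(degenerate_cohort.records), "P1", 24.0, "P1", "a4c", CHEAP
            )

    def test_too_few_patients_rejected(self, degenerate_cohort):
        two = [r for r in degenerate_cohort.records if r.patient_id in ("P1", "P2")]
        with pytest.raises(ValueError):
            jackknife_validate(two, "a4c", [24.0], CHEAP)


class TestDirectionOnNoisyCohort:
    """Statistical direction checks on one moderate synthetic cohort."""

    def test_s1_and_s2_agree_without_background_truth(self):
        """Generated without a blood-pool term, the a4c and a3b STP fits
        must give nearly the same TIAs (median within 5%)."""
        from thyrostp.cohort import Schedule
        from thyrostp.soef import SOEFParams

        pop = replace(
            default_population(),
            typical_params=SOEFParams(0.04, 0.04, 0.0015, 1e-12),
            schedule=Schedule(common_times_h=(2.0, 24.0, 48.0, 120.0)),
        )
        cohort = generate_cohort(pop, 20, seed=29)
        cfg = FitConfig(seed=30)
        s1, _ = run_stp_grid(list(cohort.records), "a4c", [48.0], cfg)
        s2, _ = run_stp_grid(list(cohort.records), "a3b", [48.0], cfg)
        v1 = {e.patient_id: e.value for e in s1}
        v2 = {e.patient_id: e.value for e in s2}
        rel = [abs(v1[p] / v2[p] - 1.0) for p in v1]
        assert np.median(rel) < 0.05

    def test_late_stp_beats_ntp(self):
        """A single late measurement must carry real information: s1TIA at
        120 h has smaller MAPE vs rTIA than the no-time-point estimate."""
        cohort = generate_cohort(default_population(), 40, seed=23)
        recs = list(cohort.records)
        cfg = FitConfig(seed=24)
        pop, individuals = reference_fit(recs, cfg)
        rtia = {i.patient_id: i.tia for i in individuals}
        s1, _ = run_stp_grid(recs, "a4c", [120.0], cfg)
        mape_s1 = np.mean([abs(e.value / rtia[e.patient_id] - 1.0) for e in s1])
        ntp = ntp_tia(pop, individuals)
        late_ids = {e.patient_id for e in s1}
        mape_ntp = np.mean(
            [abs(ntp.value / rtia[p] - 1.0) for p in late_ids]
        )
        assert mape_s1 < mape_ntp
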