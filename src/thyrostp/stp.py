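"""Single-time-point and no-time-point TIA estimation.

Four TIA estimates per patient, all derived from the population model:

rTIA
    reference: empirical-Bayes TIA from the all-time-point ``a4c``
    population fit.
s1TIA / s2TIA
    single-time-point: the population model (``a4c`` for s1, ``a3b`` for
    s2) is refitted on a dataset holding every *other* patient's complete
    profile plus the target patient's single observation at the chosen time
    point; the target's empirical-Bayes TIA is reported.  A faster
    ``frozen_prior`` mode fits the population on the other patients only
    and runs a single MAP step for the target — an approximation of the
    joint refit.
nTIA
    no-time-point: the analytic TIA of the arithmetic mean of the
    patients' individual parameters from the all-time-point fit (one value
    for the whole cohort, emulating dosimetry without any measurement).

A jackknife report quantifies, for each single-time-point fit, how much
the target's TIA moves when single other patients are removed from the
population data, and audits that the target contributed exactly one
observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import BiokineticRecord
from .nlme import (
    FitConfig,
    IndividualEstimate,
    PopulationEstimate,
    empirical_bayes,
    fit_population,
)
from .soef import analytic_tia

__all__ = [
    "TIAEstimate",
    "MissingObservationError",
    "compute_reference_tias",
    "reference_fit",
    "stp_fit",
    "run_stp_grid",
    "ntp_tia",
    "expand_ntp",
    "jackknife_cell",
    "jackknife_validate",
]

_STP_METHODS = ("s1TIA", "s2TIA", "hTIA")
_METHODS = _STP_METHODS + ("rTIA", "nTIA")


class MissingObservationError(ValueError):
    """The target patient has no observation at the requested time point."""


@dataclass(frozen=True)
class TIAEstimate:
    """A TIA value tagged with its method and provenance."""

    patient_id: str
    method: str
    value: float
    time_point_h: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.value > 0.0:
            raise ValueError(f"TIA must be > 0, got {self.value}")
        has_tp = self.time_point_h is not None
        if has_tp != (self.method in _STP_METHODS):
            raise ValueError(
                "time_point_h must be present exactly for the "
                f"single-time-point methods, got {self.method} / {self.time_point_h}"
            )


def _split(records: Sequence[BiokineticRecord], patient_id: str):
    target = [r for r in records if r.patient_id == patient_id]
    others = [r for r in records if r.patient_id != patient_id]
    return target, others


def _obs_at(records: Sequence[BiokineticRecord], time_h: float, tol=1e-9):
    return [r for r in records if abs(r.time_h - time_h) <= tol]


def reference_fit(
    records: Sequence[BiokineticRecord], config: FitConfig = FitConfig()
) -> tuple[PopulationEstimate, list[IndividualEstimate]]:
    """All-time-point ``a4c`` population fit plus per-patient
    empirical-Bayes estimates (the reference dosimetry)."""
    pop = fit_population(records, "a4c", config)
    individuals = []
    for pid in pop.patient_ids:
        params = pop.individual_params(pid)
        individuals.append(
            IndividualEstimate(pid, params, analytic_tia(params),
                               pop.individual_eta[pop.patient_ids.index(pid)])
        )
    return pop, individuals


def compute_reference_tias(
    records: Sequence[BiokineticRecord], config: FitConfig = FitConfig()
) -> list[TIAEstimate]:
    """Reference TIAs (rTIA): all-time-point a4c fit, empirical-Bayes TIA
    per patient."""
    _, individuals = reference_fit(records, config)
    return [
        TIAEstimate(ind.patient_id, "rTIA", ind.tia) for ind in individuals
    ]


@dataclass(frozen=True)
class StpFitAudit:
    """Audit trail of one single-time-point fit."""

    patient_id: str
    time_point_h: float
    n_patients: int
    n_obs_dataset: int
    n_target_obs: int
    objective: float
    converged: bool


def stp_fit(
    records: Sequence[BiokineticRecord],
    target_patient: str,
    time_point_h: float,
    model_id: str,
    config: FitConfig = FitConfig(),
    warm_start: PopulationEstimate | None = None,
) -> tuple[TIAEstimate, StpFitAudit]:
    """Single-time-point TIA for one patient.

    Builds the dataset {all other patients' complete profiles} plus the
    target patient's single observation at ``time_point_h``, fits the
    population model on it, and returns the target's empirical-Bayes TIA.
    ``model_id="a4c"`` yields an s1TIA, ``"a3b"`` an s2TIA.

    Raises :class:`MissingObservationError` if the target was not measured
    at the requested time (callers building grids treat this as a skip).
    """
    method = "s1TIA" if model_id == "a4c" else "s2TIA"
    target, others = _split(records, target_patient)
    if not target:
        raise ValueError(f"unknown patient {target_patient!r}")
    single = _obs_at(target, time_point_h)
    if not single:
        raise MissingObservationError(
            f"{target_patient} has no observation at {time_point_h} h"
        )
    single = single[:1]
    if config.stp_mode == "joint_refit":
        dataset = list(others) + single
        pop = fit_population(dataset, model_id, config, warm_start=warm_start)
        params = pop.individual_params(target_patient)
        tia = analytic_tia(params)
    else:  # frozen_prior
        pop = (
            warm_start
            if warm_start is not None and _fits_others(warm_start, others)
            else fit_population(others, model_id, config)
        )
        tia = empirical_bayes(pop, single).tia
    audit = StpFitAudit(
        patient_id=target_patient,
        time_point_h=time_point_h,
        n_patients=len({r.patient_id for r in others}) + 1,
        n_obs_dataset=len(others) + 1,
        n_target_obs=1,
        objective=pop.objective,
        converged=pop.converged,
    )
    est = TIAEstimate(target_patient, method, tia, time_point_h)
    return est, audit


def _fits_others(pop: PopulationEstimate, others: Sequence[BiokineticRecord]) -> bool:
    return set(pop.patient_ids) == {r.patient_id for r in others}


def _cell_seed(global_seed: int, time_index: int, patient_index: int) -> int:
    ss = np.random.SeedSequence((int(global_seed), time_index, patient_index))
    return int(ss.generate_state(1)[0] % (2**31))


def run_stp_grid(
    records: Sequence[BiokineticRecord],
    model_id: str,
    time_points: Sequence[float],
    config: FitConfig = FitConfig(),
) -> tuple[list[TIAEstimate], pd.DataFrame]:
    """Single-time-point fits over every (patient, time point) cell.

    Patients lacking a measurement at a requested time are skipped (the
    96/120 h subgroups).  Each cell derives its own random-start seed from
    the global seed and the cell index, so results are independent of
    execution order.  Returns the estimates and an audit table.
    """
    records = list(records)
    time_points = list(time_points)
    if not time_points:
        raise ValueError("empty time-point grid")
    observed = sorted({r.time_h for r in records})
    for tp in time_points:
        if not any(abs(tp - t) <= 1e-9 for t in observed):
            raise ValueError(f"time point {tp} h was never observed")
    patient_ids = list(dict.fromkeys(r.patient_id for r in records))

    warm = None
    if config.stp_mode == "joint_refit" and len(patient_ids) > 2:
        warm = fit_population(records, model_id, config)
        cell_cfg_base = _reduced_config(config)
    else:
        cell_cfg_base = config

    frozen_cache: dict[str, PopulationEstimate] = {}
    estimates: list[TIAEstimate] = []
    audits = []
    for ti, tp in enumerate(time_points):
        for pi, pid in enumerate(patient_ids):
            cfg = _with_seed(cell_cfg_base, _cell_seed(config.seed, ti, pi))
            try:
                if config.stp_mode == "frozen_prior":
                    if pid not in frozen_cache:
                        _, others = _split(records, pid)
                        frozen_cache[pid] = fit_population(others, model_id, config)
                    est, audit = stp_fit(
                        records, pid, tp, model_id, cfg,
                        warm_start=frozen_cache[pid],
                    )
                else:
                    est, audit = stp_fit(
                        records, pid, tp, model_id, cfg, warm_start=warm
                    )
            except MissingObservationError:
                continue
            estimates.append(est)
            audits.append(audit)
    if not estimates:
        raise ValueError("no (patient, time point) cell had data")
    audit_df = pd.DataFrame([a.__dict__ for a in audits])
    return estimates, audit_df


def _reduced_config(config: FitConfig) -> FitConfig:
    """Cheaper settings for warm-started grid cells: fewer random starts
    and a tighter outer-iteration budget (the warm start carries most of
    the information; the refit only has to absorb one changed profile)."""
    from dataclasses import replace

    return replace(
        config,
        n_starts=max(config.n_starts // 20, 1),
        n_refine=1,
        max_outer=min(config.max_outer, 60),
        warm_only=True,
        laplace_polish=False,
    )


def _with_seed(config: FitConfig, seed: int) -> FitConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


def ntp_tia(
    population: PopulationEstimate,
    individuals: Sequence[IndividualEstimate] | None = None,
) -> TIAEstimate:
    """No-time-point TIA: the analytic TIA of the mean parameter vector.

    With ``individuals`` given (the usual case), the arithmetic mean of the
    patients' empirical-Bayes parameters from the all-time-point fit is
    used; otherwise the population typical values.  The single value stands
    in for every patient's dosimetry when no measurement is available.
    """
    if individuals:
        mat = np.stack([ind.params.as_array() for ind in individuals])
        mean_params = population.fixed_effects.with_values(mat.mean(axis=0))
    else:
        mean_params = population.fixed_effects
    return TIAEstimate("population", "nTIA", analytic_tia(mean_params))


def expand_ntp(
    ntp: TIAEstimate, patient_ids: Sequence[str]
) -> list[TIAEstimate]:
    """Replicate the cohort-level nTIA value onto each patient (for the
    accuracy table, which compares per patient)."""
    if ntp.method != "nTIA":
        raise ValueError("expand_ntp expects an nTIA estimate")
    return [TIAEstimate(pid, "nTIA", ntp.value) for pid in patient_ids]


def jackknife_cell(
    records: Sequence[BiokineticRecord],
    target_patient: str,
    time_point_h: float,
    leave_out_patient: str,
    model_id: str,
    config: FitConfig = FitConfig(),
    warm_start: PopulationEstimate | None = None,
) -> TIAEstimate:
    """One leave-one-out replicate of a single-time-point fit: the cohort
    minus ``leave_out_patient`` (never the target itself)."""
    if leave_out_patient == target_patient:
        raise ValueError("cannot leave out the target patient itself")
    reduced = [r for r in records if r.patient_id != leave_out_patient]
    est, _ = stp_fit(reduced, target_patient, time_point_h, model_id, config,
                     warm_start=warm_start)
    return est


def jackknife_validate(
    records: Sequence[BiokineticRecord],
    model_id: str,
    time_points: Sequence[float],
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Leave-one-out robustness report for every single-time-point fit.

    For each (target patient, time point) cell the population set is
    perturbed by removing one other patient at a time; the spread (mean,
    population SD) of the target's TIA across the replicates measures the
    fit's sensitivity to single patients.  The exclusion contract (exactly
    one target observation in every replicate dataset) is audited by
    construction through :func:`stp_fit`.
    """
    records = list(records)
    patient_ids = list(dict.fromkeys(r.patient_id for r in records))
    if len(patient_ids) < 3:
        raise ValueError("jackknife needs at least 3 patients")
    if not time_points:
        raise ValueError("empty time-point grid")
    warm = None
    if config.stp_mode == "joint_refit":
        warm = fit_population(records, model_id, config)
        cell_cfg = _reduced_config(config)
    else:
        cell_cfg = config
    rows = []
    for ti, tp in enumerate(time_points):
        for pi, pid in enumerate(patient_ids):
            target, _ = _split(records, pid)
            if not _obs_at(target, tp):
                continue
            cfg = _with_seed(cell_cfg, _cell_seed(config.seed, ti, pi))
            tias = []
            for other in patient_ids:
                if other == pid:
                    continue
                rep = jackknife_cell(
                    records, pid, tp, other, model_id, cfg, warm_start=warm
                )
                tias.append(rep.value)
            tias = np.asarray(tias)
            rows.append(
                {
                    "patient_id": pid,
                    "time_h": tp,
                    "n_replicates": tias.size,
                    "tia_mean": float(tias.mean()),
                    "tia_sd": float(tias.std()),
                }
            )
    if not rows:
        raise ValueError("no (patient, time point) cell had data")
    return pd.DataFrame(rows)
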