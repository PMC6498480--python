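"""Trial-level evaluation: reassessed-rate central ranges, coverage checks,
and the reproducibility simulation-study runner.

For each evaluable patient the probability that a hypothetical reassessment
would designate a response (and, separately, progression) is looked up or
simulated from the fitted error model.  Repeating the trial many times with
Bernoulli events at those probabilities yields the distribution of
reassessed ORRs (a Poisson-binomial law over the patient probabilities); its
2.5th-97.5th percentile interval is the 95% central range — a measure of
reproducibility under measurement variability, distinct from a sampling-error
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .error_model import ErrorDistribution, PosteriorDraws, intra_error_cov, inter_error_cov
from .io import TrialDataset, TrialRecord, summarize_burden
from .response_sim import (
    PR_CUTOFF,
    _EPS,
    ProbabilityTable,
    TumorBurden,
    _perturb_arrays,
    lookup_probability,
)
from .synthetic import TrialGenConfig, generate_trial


@dataclass
class EvaluationResult:
    """Distribution of simulated reassessed rates (percent)."""

    rates: np.ndarray
    median: float
    central_range_95: tuple[float, float]
    kind: Literal["ORR", "progression"]
    n_reps: int

    def __post_init__(self) -> None:
        lo, hi = self.central_range_95
        if not (0.0 <= lo <= self.median <= hi <= 100.0):
            raise ValueError("central range must satisfy 0 <= lower <= median <= upper <= 100")
        if len(self.rates) != self.n_reps:
            raise ValueError("rates length must equal n_reps")


@dataclass(frozen=True)
class CoverageReport:
    n_total: int
    n_covered: int

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.n_covered / self.n_total


def _central_range(values: np.ndarray) -> tuple[float, float]:
    # linear interpolation between order statistics (numpy default)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def _result(rates: np.ndarray, kind: str) -> EvaluationResult:
    return EvaluationResult(
        rates=rates,
        median=float(np.median(rates)),
        central_range_95=_central_range(rates),
        kind=kind,
        n_reps=len(rates),
    )


def _simulate_rates(
    p_response: np.ndarray,
    p_progression: np.ndarray,
    n_definitive: int,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[EvaluationResult, EvaluationResult]:
    m = len(p_response)
    n_total = m + n_definitive
    if n_total == 0:
        raise ValueError("no patients to evaluate")
    if m:
        resp_counts = (rng.random((n_reps, m)) < p_response).sum(axis=1)
        prog_counts = (rng.random((n_reps, m)) < p_progression).sum(axis=1)
    else:
        resp_counts = np.zeros(n_reps, dtype=int)
        prog_counts = np.zeros(n_reps, dtype=int)
    orr = 100.0 * resp_counts / n_total
    prog = 100.0 * (prog_counts + n_definitive) / n_total
    return _result(orr, "ORR"), _result(prog, "progression")


def patient_probabilities(
    trial: TrialDataset,
    table_or_posterior,
    reader_mode: str,
    n_iter: int = 100,
    n_burdens: int = 100,
    rng: np.random.Generator | None = None,
    posterior_short: PosteriorDraws | None = None,
) -> pd.DataFrame:
    """Per-patient reassessment probabilities.

    With a :class:`ProbabilityTable` the values come from grid lookup (c on
    the 0.01 grid, single-lesion baselines on the 1 mm grid).  With a
    :class:`PosteriorDraws` or :class:`ErrorDistribution` they are simulated
    on demand at the patient's exact burden (medians over ``n_iter`` draws
    for a posterior; a single estimate for a fixed error distribution).
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for rec in trial.records:
        summary = summarize_burden(rec)
        if isinstance(table_or_posterior, ProbabilityTable):
            p_resp, p_prog = lookup_probability(table_or_posterior, summary, reader_mode)
        else:
            p_resp, p_prog = _on_demand_probability(
                rec, table_or_posterior, reader_mode, n_iter, n_burdens, rng, posterior_short
            )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "n_solid": summary.n_solid,
                "n_lymph": summary.n_lymph,
                "burden_baseline_mm": summary.burden_baseline_mm,
                "burden_post_mm": summary.burden_post_mm,
                "percent_change": summary.percent_change,
                "p_response": p_resp,
                "p_progression": p_prog,
            }
        )
    return pd.DataFrame(rows)


def _single_lesion_probability(
    burden: TumorBurden, err: ErrorDistribution, n_burdens: int, rng, err_lymph=None
) -> tuple[float, float]:
    """Exact-burden Monte-Carlo probability for one patient's observed burden."""
    lymph = np.array([o == "lymph" for o, *_ in burden.lesions])
    Yb = np.tile([b for _, b, _ in burden.lesions], (n_burdens, 1))
    Yp = np.tile([p for _, _, p in burden.lesions], (n_burdens, 1))
    Yb2, Yp2 = _perturb_arrays(Yb, Yp, lymph, err, rng, err_lymph)
    sb, sp = Yb2.sum(axis=1), Yp2.sum(axis=1)
    ok = sb > 0
    c2 = (sp[ok] - sb[ok]) / sb[ok]
    return (
        float(np.mean(c2 <= PR_CUTOFF + _EPS)),
        float(np.mean(c2 >= 0.20 - _EPS)),
    )


def _on_demand_probability(
    rec: TrialRecord, source, reader_mode, n_iter, n_burdens, rng, posterior_short
) -> tuple[float, float]:
    burden = TumorBurden(tuple((l.organ, l.baseline_mm, l.post_mm) for l in rec.lesions))
    err_fn = intra_error_cov if reader_mode == "intra" else inter_error_cov
    if isinstance(source, ErrorDistribution):
        return _single_lesion_probability(burden, source, n_burdens, rng)
    if isinstance(source, PosteriorDraws):
        pr = np.empty(n_iter)
        pp = np.empty(n_iter)
        for t in range(n_iter):
            vc = source.draws[rng.integers(len(source.draws))]
            err = err_fn(vc)
            err_lymph = None
            if posterior_short is not None:
                vc_s = posterior_short.draws[rng.integers(len(posterior_short.draws))]
                err_lymph = err_fn(vc_s)
            pr[t], pp[t] = _single_lesion_probability(burden, err, n_burdens, rng, err_lymph)
        return float(np.median(pr)), float(np.median(pp))
    raise TypeError(f"unsupported probability source {type(source)!r}")


def evaluate_trial(
    trial: TrialDataset,
    table: ProbabilityTable | PosteriorDraws | ErrorDistribution,
    reader_mode: str,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[EvaluationResult, EvaluationResult]:
    """Simulated distribution of reassessed ORR and progression rate.

    Per repetition, each evaluable patient contributes a Bernoulli response
    event and (independently) a Bernoulli progression event at the looked-up
    probabilities; definitive-progression patients contribute progression
    with probability 1 and no response, and are counted in both denominators.
    Probabilities come from a pre-built :class:`ProbabilityTable` (grid
    lookup) or are simulated on demand from a posterior / fixed error
    distribution (see :func:`patient_probabilities`).
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    probs = patient_probabilities(trial, table, reader_mode, rng=rng)
    p_resp = probs["p_response"].to_numpy() if len(probs) else np.empty(0)
    p_prog = probs["p_progression"].to_numpy() if len(probs) else np.empty(0)
    return _simulate_rates(p_resp, p_prog, trial.n_definitive_progression, n_reps, rng)


def burden_second_reading_ranges(
    trial: TrialDataset,
    err: ErrorDistribution,
    n_sims: int = 1000,
    rng: np.random.Generator | None = None,
    err_lymph: ErrorDistribution | None = None,
) -> pd.DataFrame:
    """95% central ranges of hypothetical second readings of each burden.

    Returns one row per patient and phase with the observed burden and the
    2.5th/97.5th percentiles of ``n_sims`` simulated second readings.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for stable percentile estimates")
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for rec in trial.records:
        lymph = np.array([l.organ == "lymph" for l in rec.lesions])
        Yb = np.tile([l.baseline_mm for l in rec.lesions], (n_sims, 1))
        Yp = np.tile([l.post_mm for l in rec.lesions], (n_sims, 1))
        Yb2, Yp2 = _perturb_arrays(Yb, Yp, lymph, err, rng, err_lymph)
        for phase, sums, observed in (
            ("baseline", Yb2.sum(axis=1), float(Yb[0].sum())),
            ("post", Yp2.sum(axis=1), float(Yp[0].sum())),
        ):
            lo, hi = _central_range(sums)
            rows.append(
                {"patient_id": rec.patient_id, "phase": phase, "observed_mm": observed,
                 "lower_mm": lo, "upper_mm": hi}
            )
    return pd.DataFrame(rows)


def coverage_of_second_readings(ranges: pd.DataFrame, actual_second: TrialDataset) -> CoverageReport:
    """Fraction of central ranges containing the actually re-measured burden sizes."""
    actual = {
        rec.patient_id: summarize_burden(rec) for rec in actual_second.records
    }
    missing = set(ranges["patient_id"]) - set(actual)
    if missing:
        raise ValueError(f"second-reading dataset lacks patients {sorted(missing)}")
    n_total = 0
    n_covered = 0
    for row in ranges.itertuples():
        summary = actual[row.patient_id]
        value = summary.burden_baseline_mm if row.phase == "baseline" else summary.burden_post_mm
        n_total += 1
        if row.lower_mm <= value <= row.upper_mm:
            n_covered += 1
    return CoverageReport(n_total=n_total, n_covered=n_covered)


def observed_orr(trial: TrialDataset) -> float:
    """Observed ORR (percent): burdens with change <= -30%, over all patients
    including definitive-progression ones (who cannot be responders)."""
    n_resp = sum(
        1
        for rec in trial.records
        if summarize_burden(rec).percent_change / 100.0 <= PR_CUTOFF + _EPS
    )
    return 100.0 * n_resp / trial.n_patients_total


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion, in percent."""
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return 100.0 * lo, 100.0 * hi


def bootstrap_orr_coverage(
    trial_first: TrialDataset,
    trial_second: TrialDataset,
    table: ProbabilityTable,
    reader_mode: str,
    n_boot: int = 100,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> CoverageReport:
    """Coverage of simulated ORR central ranges over observed second-reading ORRs.

    Per bootstrap resample of patients (with replacement), the 95% central
    range of reassessed ORRs is computed from the first readings and compared
    with the observed ORR of the *same* resample under the second readings.
    The definitive-progression count is kept fixed across resamples.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    firsts = {rec.patient_id: rec for rec in trial_first.records}
    seconds = {rec.patient_id: rec for rec in trial_second.records}
    if set(firsts) != set(seconds):
        raise ValueError("first and second datasets must share the same patients")
    ids = sorted(firsts)
    probs = patient_probabilities(trial_first, table, reader_mode, rng=rng)
    p_by_id = dict(zip(probs["patient_id"], probs["p_response"]))
    second_resp = {
        pid: summarize_burden(seconds[pid]).percent_change / 100.0 <= PR_CUTOFF + _EPS
        for pid in ids
    }
    n_def = trial_first.n_definitive_progression
    n_total = len(ids) + n_def
    n_covered = 0
    for _ in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        p = np.array([p_by_id[pid] for pid in sample])
        counts = (rng.random((n_reps, len(sample))) < p).sum(axis=1)
        lo, hi = _central_range(100.0 * counts / n_total)
        observed = 100.0 * sum(second_resp[pid] for pid in sample) / n_total
        if lo <= observed <= hi:
            n_covered += 1
    return CoverageReport(n_total=n_boot, n_covered=n_covered)


@dataclass
class SimStudyConfig:
    """One cell of the reproducibility simulation study.

    ``baseline`` is either a fixed lesion size in mm or (log-mean, log-SD) of
    a log-normal; the percent change of each single-lesion burden is
    ``change_mean + N(change_shift, change_sd^2)`` on the percent scale.
    """

    name: str
    n_patients: int = 50
    baseline: float | tuple[float, float] = 30.0
    change_mean: float = -30.0
    change_shift: float = 0.0
    change_sd: float = 5.0
    true_orr: float | None = None
    n_replicates: int = 1


def run_simulation_study(
    configs: Sequence[SimStudyConfig],
    err_or_posterior,
    rng: np.random.Generator | None = None,
    reader_mode: str = "inter",
    n_reps: int = 1000,
    n_iter: int = 20,
    n_burdens: int = 100,
) -> pd.DataFrame:
    """Observed ORR (with exact binomial CI) vs reassessed central range.

    For each configuration and replicate, a trial of single-lesion solid
    burdens is generated, its observed ORR and Clopper-Pearson 95% CI are
    computed, and the reassessed-ORR distribution is simulated from the
    error model (probabilities computed at each patient's exact burden).
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for cfg in configs:
        for rep in range(cfg.n_replicates):
            trial = generate_trial(
                TrialGenConfig(
                    n_patients=cfg.n_patients,
                    baseline=cfg.baseline,
                    change_mean=cfg.change_mean + cfg.change_shift,
                    change_sd=cfg.change_sd,
                    true_orr=cfg.true_orr,
                ),
                rng,
            )
            orr_obs = observed_orr(trial)
            k = int(round(orr_obs / 100.0 * trial.n_patients_total))
            ci_lo, ci_hi = clopper_pearson(k, trial.n_patients_total)
            probs = patient_probabilities(
                trial, err_or_posterior, reader_mode, n_iter=n_iter,
                n_burdens=n_burdens, rng=rng,
            )
            orr_result, _ = _simulate_rates(
                probs["p_response"].to_numpy(),
                probs["p_progression"].to_numpy(),
                trial.n_definitive_progression,
                n_reps,
                rng,
            )
            lo, hi = orr_result.central_range_95
            rows.append(
                {
                    "config": cfg.name,
                    "replicate": rep,
                    "true_orr": cfg.true_orr,
                    "observed_orr": orr_obs,
                    "ci_lower": ci_lo,
                    "ci_upper": ci_hi,
                    "reassessed_median": orr_result.median,
                    "range_lower": lo,
                    "range_upper": hi,
                    "range_width": hi - lo,
                }
            )
    return pd.DataFrame(rows)
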