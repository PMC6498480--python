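"""Synthetic-data generators with known ground truth.

Two emulations: (1) a repeated-readings table built additively from the
bivariate crossed random-effects model on the sqrt scale (lesion + reader +
interaction + residual), mirroring a study in which every target lesion is
read by several radiologists twice per phase; (2) single-lesion trial tables
with log-normal baseline sizes and normal percent changes, the designs used
in the reproducibility simulation studies.  Both let every downstream stage
be tested against a known truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .error_model import ErrorDistribution, VarianceComponents, _chol2
from .io import Lesion, ReadingRecord, RepeatedReadingDataset, TrialDataset, TrialRecord
from .response_sim import _perturb_arrays

# Ground-truth components for synthetic studies, on the sqrt-mm scale.
# Chosen so that a single re-measurement changes a burden's size mostly by
# less than ~10% (intra) and ~±10% (inter) — the reported magnitude of
# radiologic re-measurement variability — while lesion-to-lesion spread
# matches LN(3.55, 0.53^2) millimetre sizes.  Baseline/post correlations are
# high for lesion identity and moderate for error terms.
_DEFAULTS = {
    "long": dict(
        mu=(5.9, 5.4),
        sd_lesion=(1.5, 1.5), rho_lesion=0.9,
        sd_reader=(0.05, 0.05), rho_reader=0.7,
        sd_interaction=(0.08, 0.08), rho_interaction=0.5,
        sd_residual=(0.12, 0.12), rho_residual=0.5,
    ),
    "short": dict(
        mu=(4.0, 3.7),
        sd_lesion=(1.0, 1.0), rho_lesion=0.9,
        sd_reader=(0.04, 0.04), rho_reader=0.7,
        sd_interaction=(0.06, 0.06), rho_interaction=0.5,
        sd_residual=(0.10, 0.10), rho_residual=0.5,
    ),
}


def _cov(sd: tuple[float, float], rho: float) -> np.ndarray:
    off = rho * sd[0] * sd[1]
    return np.array([[sd[0] ** 2, off], [off, sd[1] ** 2]])


def default_variance_components(axis: str = "long") -> VarianceComponents:
    """Documented ground-truth components used by the synthetic studies."""
    d = _DEFAULTS[axis]
    return VarianceComponents(
        mu=np.array(d["mu"]),
        cov_lesion=_cov(d["sd_lesion"], d["rho_lesion"]),
        cov_reader=_cov(d["sd_reader"], d["rho_reader"]),
        cov_interaction=_cov(d["sd_interaction"], d["rho_interaction"]),
        cov_residual=_cov(d["sd_residual"], d["rho_residual"]),
    )


def _draw(cov: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal((n, 2)) @ _chol2(cov[None])[0].T


def generate_readings(
    vc_true: VarianceComponents,
    n_lesions: int = 249,
    n_readers: int = 6,
    n_sessions: int = 2,
    rng: np.random.Generator | None = None,
    axis: str = "long",
    lesions_per_patient: int = 3,
) -> RepeatedReadingDataset:
    """Repeated readings drawn from the additive sqrt-scale model.

    Default shape mirrors the model-fitting design: 249 lesions read by 6
    radiologists with 2 sessions at each of the two phases.  Sqrt-scale
    values are built as mu + alpha_i + beta_j + gamma_ij + eps_ijk, clamped
    at zero, then squared to millimetres.
    """
    if n_lesions < 2 or n_readers < 2 or n_sessions < 1:
        raise ValueError("need n_lesions >= 2, n_readers >= 2, n_sessions >= 1")
    rng = np.random.default_rng() if rng is None else rng
    organ = "lymph" if axis == "short" else "solid"

    alpha = _draw(vc_true.cov_lesion, n_lesions, rng)
    beta = _draw(vc_true.cov_reader, n_readers, rng)
    gamma = _draw(vc_true.cov_interaction, n_lesions * n_readers, rng).reshape(
        n_lesions, n_readers, 2
    )
    eps = _draw(vc_true.cov_residual, n_lesions * n_readers * n_sessions, rng).reshape(
        n_lesions, n_readers, n_sessions, 2
    )
    sqrt_vals = (
        vc_true.mu[None, None, None, :]
        + alpha[:, None, None, :]
        + beta[None, :, None, :]
        + gamma[:, :, None, :]
        + eps
    )
    # floor on the sqrt scale: a reading must stay a positive measurement
    vals = np.clip(sqrt_vals, 0.1, None) ** 2

    records = []
    width = len(str(n_lesions))
    for i in range(n_lesions):
        lesion_id = f"L{i + 1:0{width}d}"
        patient_id = f"P{i // lesions_per_patient + 1:03d}"
        for j in range(n_readers):
            reader_id = f"R{j + 1}"
            for k in range(n_sessions):
                for ph, phase in enumerate(("baseline", "post")):
                    records.append(
                        ReadingRecord(
                            lesion_id=lesion_id,
                            patient_id=patient_id,
                            reader_id=reader_id,
                            session=k + 1,
                            phase=phase,
                            axis=axis,
                            organ=organ,
                            diameter_mm=float(vals[i, j, k, ph]),
                        )
                    )
    return RepeatedReadingDataset(records=records, axis_kind=axis)


@dataclass
class TrialGenConfig:
    """Design of a synthetic single-lesion solid-tumor trial.

    ``baseline`` is a fixed size in mm or (log-mean, log-SD) of a log-normal
    truncated at 10 mm; percent changes are Normal(change_mean, change_sd^2)
    on the percent scale.  When ``true_orr`` (percent) is set, patients are a
    mixture: responders draw their change truncated to <= -30%, the rest to
    > -30%, with responder weight true_orr — so the expected observed ORR
    equals the known truth exactly.
    """

    n_patients: int = 50
    baseline: float | tuple[float, float] = (3.55, 0.53)
    change_mean: float = -30.0
    change_sd: float = 5.0
    true_orr: float | None = None
    n_definitive_progression: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.change_sd < 0:
            raise ValueError("change_sd must be >= 0 (0 = point mass)")
        if self.true_orr is not None:
            if not 0.0 <= self.true_orr <= 100.0:
                raise ValueError("true_orr must be a percentage in [0, 100]")
            if self.change_sd == 0:
                raise ValueError("true_orr calibration needs change_sd > 0")


def generate_trial(config: TrialGenConfig, rng: np.random.Generator | None = None) -> TrialDataset:
    """Single-lesion solid-tumor trial table from the configured distributions."""
    rng = np.random.default_rng() if rng is None else rng
    n = config.n_patients
    if isinstance(config.baseline, tuple):
        lm, ls = config.baseline
        # truncate at the 10 mm measurability limit
        a = (np.log(10.0) - lm) / ls
        logs = stats.truncnorm.rvs(a, np.inf, loc=lm, scale=ls, size=n, random_state=rng)
        base = np.exp(logs)
    else:
        base = np.full(n, float(config.baseline))

    if config.true_orr is None:
        if config.change_sd == 0:
            change = np.full(n, config.change_mean)
        else:
            change = rng.normal(config.change_mean, config.change_sd, size=n)
    else:
        cut = (-30.0 - config.change_mean) / config.change_sd
        responder = rng.random(n) < config.true_orr / 100.0
        change = np.empty(n)
        n_resp = int(responder.sum())
        if n_resp:
            change[responder] = stats.truncnorm.rvs(
                -np.inf, cut, loc=config.change_mean, scale=config.change_sd,
                size=n_resp, random_state=rng,
            )
        if n - n_resp:
            change[~responder] = stats.truncnorm.rvs(
                cut, np.inf, loc=config.change_mean, scale=config.change_sd,
                size=n - n_resp, random_state=rng,
            )
    change = np.clip(change, -100.0, None)
    post = np.clip(base * (1.0 + change / 100.0), 0.0, None)
    records = [
        TrialRecord(
            patient_id=f"P{i + 1:04d}",
            lesions=[Lesion(organ="solid", baseline_mm=float(base[i]), post_mm=float(post[i]))],
        )
        for i in range(n)
    ]
    return TrialDataset(records=records,
                        n_definitive_progression=config.n_definitive_progression)


def generate_second_readings(
    trial: TrialDataset,
    err: ErrorDistribution,
    rng: np.random.Generator | None = None,
    err_lymph: ErrorDistribution | None = None,
) -> TrialDataset:
    """Paired "second assessment" of a trial via the sqrt-scale error mechanism.

    Each lesion's baseline and post sizes are perturbed exactly as a
    hypothetical reassessment would be, producing a dataset suitable for the
    coverage-validation procedures.
    """
    rng = np.random.default_rng() if rng is None else rng
    records = []
    for rec in trial.records:
        lymph = np.array([l.organ == "lymph" for l in rec.lesions])
        Yb = np.array([[l.baseline_mm for l in rec.lesions]])
        Yp = np.array([[l.post_mm for l in rec.lesions]])
        Yb2, Yp2 = _perturb_arrays(Yb, Yp, lymph, err, rng, err_lymph)
        lesions = [
            Lesion(organ=l.organ, baseline_mm=float(Yb2[0, j]), post_mm=float(Yp2[0, j]))
            for j, l in enumerate(rec.lesions)
        ]
        records.append(TrialRecord(patient_id=rec.patient_id, lesions=lesions))
    return TrialDataset(records=records,
                        n_definitive_progression=trial.n_definitive_progression)
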