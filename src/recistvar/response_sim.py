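"""RECIST categorization and reassessment-probability simulation.

Given a first reading of a tumor burden (n target lesions, baseline and
post-treatment sizes summing to a percent change c), a hypothetical second
assessment perturbs each lesion on the square-root scale with correlated
(baseline, post) measurement errors and re-categorises the re-measured
burden.  Repeating this over an artificial set of burdens sharing the same
composition and c estimates

    p_response    = P[ second-assessment percent change <= -0.30 ]
    p_progression = P[ second-assessment percent change >= +0.20 ]

and iterating over random posterior draws of the error covariance yields the
median probabilities stored in a scenario-indexed table.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .error_model import ErrorDistribution, PosteriorDraws, _chol2, intra_error_cov, inter_error_cov
from .io import BurdenSummary

logger = logging.getLogger(__name__)

PR_CUTOFF = -0.30  # partial response: percent change <= -30%
PD_CUTOFF = 0.20  # progression: percent change >= +20%
_EPS = 1e-12

# defaults estimated from multi-lesion burdens (fraction-scale variance of
# per-lesion percent change around the burden-level change)
CHANGE_VARIANCE = {"long": 0.17, "short": 0.10}
# empirical log-normal of baseline lesion sizes (log-mean, log-SD), mm
BASELINE_LOGNORMAL = {"long": (3.55, 0.53), "short": (3.55, 0.53)}
SIZE_RANGE = {"long": (10.0, 150.0), "short": (10.0, 80.0)}


class ResponseCategory(enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


def categorize_response(c: float) -> ResponseCategory:
    """RECIST category of a fractional percent change of the tumor burden.

    CR at c = -1 (complete disappearance), PR for -1 < c <= -0.3, SD for
    -0.3 < c < 0.2, PD for c >= 0.2.
    """
    if c < -1.0 - 1e-9:
        raise ValueError(f"percent change cannot be below -100%, got {c}")
    if c <= -1.0 + _EPS:
        return ResponseCategory.CR
    if c <= PR_CUTOFF + _EPS:
        return ResponseCategory.PR
    if c < PD_CUTOFF - _EPS:
        return ResponseCategory.SD
    return ResponseCategory.PD


@dataclass(frozen=True)
class TumorBurden:
    """First-reading sizes of the target lesions of one (possibly artificial) patient."""

    lesions: tuple[tuple[str, float, float], ...]  # (organ, baseline_mm, post_mm)

    def __post_init__(self) -> None:
        if not 1 <= len(self.lesions) <= 5:
            raise ValueError("a tumor burden has 1 to 5 target lesions")
        if sum(1 for o, *_ in self.lesions if o == "lymph") > 2:
            raise ValueError("at most 2 lymph-node target lesions")

    @property
    def baseline_sum(self) -> float:
        return sum(b for _, b, _ in self.lesions)

    @property
    def post_sum(self) -> float:
        return sum(p for _, _, p in self.lesions)

    @property
    def percent_change(self) -> float:
        return (self.post_sum - self.baseline_sum) / self.baseline_sum


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid.

    ``baseline_mm`` is set only for single-lesion scenarios (grid 10-150 mm
    long axis, 10-80 mm short axis, 1 mm steps); multi-lesion scenarios are
    indexed by composition only.  ``c`` lies on the [-1, 1] grid at 0.01.
    """

    n_solid: int
    n_lymph: int
    c: float
    reader_mode: str
    baseline_mm: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_solid <= 5 or not 0 <= self.n_lymph <= 2:
            raise ValueError("n_solid in 0..5 and n_lymph in 0..2 required")
        n = self.n_solid + self.n_lymph
        if n < 1 or n > 5:
            raise ValueError("total lesion count must be 1..5")
        if self.reader_mode not in ("intra", "inter"):
            raise ValueError("reader_mode must be 'intra' or 'inter'")
        if not -1.0 - 1e-9 <= self.c <= 1.0 + 1e-9:
            raise ValueError("c must lie in [-1, 1]")
        object.__setattr__(self, "c", round(self.c, 2))
        if (self.baseline_mm is not None) != (n == 1):
            raise ValueError("baseline_mm must be set iff the scenario has a single lesion")
        if self.baseline_mm is not None:
            axis = "short" if self.n_lymph == 1 else "long"
            lo, hi = SIZE_RANGE[axis]
            if not lo <= self.baseline_mm <= hi:
                raise ValueError(
                    f"single-lesion baseline must lie in [{lo}, {hi}] mm for the {axis} axis"
                )
            object.__setattr__(self, "baseline_mm", float(round(self.baseline_mm)))

    @property
    def key(self) -> tuple:
        base = None if self.baseline_mm is None else int(round(self.baseline_mm))
        return (self.n_solid, self.n_lymph, base, int(round(self.c * 100)), self.reader_mode)


def _organs(scenario: Scenario) -> np.ndarray:
    return np.array([False] * scenario.n_solid + [True] * scenario.n_lymph)  # True = lymph


def _truncated_lognormal(n, log_mean, log_sd, lo, hi, rng):
    """Rejection-sample a log-normal restricted to [lo, hi] mm."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(log_mean, log_sd, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _sample_burden_arrays(
    scenario: Scenario,
    n_burdens: int,
    rng: np.random.Generator,
    size_dist: dict | None = None,
    change_variance: dict | None = None,
):
    """Vectorised burden-set construction: (baseline, post) arrays (B, L)."""
    size_dist = {**BASELINE_LOGNORMAL, **(size_dist or {})}
    change_variance = {**CHANGE_VARIANCE, **(change_variance or {})}
    lymph = _organs(scenario)
    L = len(lymph)
    if L == 1:
        Yb = np.full((n_burdens, 1), float(scenario.baseline_mm))
        cx = np.full((n_burdens, 1), scenario.c)
    else:
        Yb = np.empty((n_burdens, L))
        for col in range(L):
            axis = "short" if lymph[col] else "long"
            lo, hi = SIZE_RANGE[axis]
            lm, ls = size_dist[axis]
            Yb[:, col] = _truncated_lognormal(n_burdens, lm, ls, lo, hi, rng)
        sd = np.where(lymph, np.sqrt(change_variance["short"]), np.sqrt(change_variance["long"]))
        cx = rng.normal(scenario.c, sd, size=(n_burdens, L))
        cx = _constrain_changes(cx, Yb, scenario.c)
    Yp = np.clip(Yb * (1.0 + cx), 0.0, None)
    return Yb, Yp, lymph


def _constrain_changes(cx: np.ndarray, Yb: np.ndarray, c: float) -> np.ndarray:
    """Shift per-lesion changes so the burden-weighted mean equals c exactly,
    keeping every change >= -1 (a lesion cannot shrink past disappearance).

    A uniform shift restores the weighted mean; any change pushed below -1 is
    clamped there and the residual discrepancy redistributed over the free
    lesions (water-filling; converges in at most L passes since clamps only
    accumulate).
    """
    cx = cx.copy()
    fixed = np.zeros_like(cx, dtype=bool)
    target = c * Yb.sum(axis=1)
    for _ in range(cx.shape[1]):
        free_w = np.where(fixed, 0.0, Yb)
        denom = free_w.sum(axis=1)
        active = denom > 0
        shift = np.zeros(len(cx))
        shift[active] = (target[active] - (cx * Yb)[active].sum(axis=1)) / denom[active]
        cx = np.where(fixed, cx, cx + shift[:, None])
        below = (cx < -1.0) & ~fixed
        if not below.any():
            break
        cx[below] = -1.0
        fixed |= below
    return cx


def sample_burden_set(
    scenario: Scenario,
    n_burdens: int = 100,
    rng: np.random.Generator | None = None,
    size_dist: dict | None = None,
    change_variance: dict | None = None,
) -> list[TumorBurden]:
    """Artificial set of first-reading burdens sharing composition and percent change c.

    Baseline sizes come from the empirical log-normal truncated to the
    measurable range per axis (single-lesion scenarios use the fixed grid
    baseline); per-lesion changes are normal around c and shifted so that the
    burden-weighted mean change equals c exactly.
    """
    if n_burdens < 1:
        raise ValueError("n_burdens must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    Yb, Yp, lymph = _sample_burden_arrays(scenario, n_burdens, rng, size_dist, change_variance)
    organs = ["lymph" if q else "solid" for q in lymph]
    return [
        TumorBurden(tuple((organs[j], float(Yb[i, j]), float(Yp[i, j])) for j in range(len(organs))))
        for i in range(n_burdens)
    ]


def _perturb_arrays(Yb, Yp, lymph, err: ErrorDistribution, rng, err_lymph: ErrorDistribution | None):
    B, L = Yb.shape
    eps = np.empty((B, L, 2))
    chol_solid = _chol2(err.cov[None])[0]
    z = rng.standard_normal((B, L, 2))
    eps[:] = z @ chol_solid.T
    if lymph.any():
        if err_lymph is not None:
            chol_l = _chol2(err_lymph.cov[None])[0]
            eps[:, lymph, :] = z[:, lymph, :] @ chol_l.T
    sb = np.clip(np.sqrt(Yb) + eps[..., 0], 0.0, None)
    sp = np.clip(np.sqrt(Yp) + eps[..., 1], 0.0, None)
    return sb**2, sp**2


def perturb_burden(
    burden: TumorBurden,
    err: ErrorDistribution,
    rng: np.random.Generator,
    err_lymph: ErrorDistribution | None = None,
) -> TumorBurden:
    """Hypothetical second assessment of one burden.

    Each lesion's sizes become ((sqrt(Y_b)+eps_b)^2, (sqrt(Y_p)+eps_p)^2)
    with correlated errors drawn from the axis-matched distribution
    (``err`` for solid/long, ``err_lymph`` for lymph/short when provided);
    errors are independent across lesions.  Sqrt-scale values are clamped at
    zero before squaring so a "measured below zero" never yields a positive
    size.
    """
    lymph = np.array([o == "lymph" for o, *_ in burden.lesions])
    Yb = np.array([[b for _, b, _ in burden.lesions]])
    Yp = np.array([[p for _, _, p in burden.lesions]])
    Yb2, Yp2 = _perturb_arrays(Yb, Yp, lymph, err, rng, err_lymph)
    organs = [o for o, *_ in burden.lesions]
    return TumorBurden(
        tuple((organs[j], float(Yb2[0, j]), float(Yp2[0, j])) for j in range(len(organs)))
    )


def estimate_probabilities(
    scenario: Scenario,
    err: ErrorDistribution,
    n_burdens: int = 100,
    rng: np.random.Generator | None = None,
    err_lymph: ErrorDistribution | None = None,
    size_dist: dict | None = None,
    change_variance: dict | None = None,
) -> tuple[float, float]:
    """One Monte-Carlo estimate of (p_response, p_progression) for a scenario.

    Builds a burden set, perturbs each burden once, and reports the
    proportions of second-assessment percent changes beyond the -30% / +20%
    cut-offs.  A perturbed baseline burden of exactly zero is redrawn (the
    percent change would be undefined); redraws are counted in the log.
    """
    rng = np.random.default_rng() if rng is None else rng
    Yb, Yp, lymph = _sample_burden_arrays(scenario, n_burdens, rng, size_dist, change_variance)
    Yb2, Yp2 = _perturb_arrays(Yb, Yp, lymph, err, rng, err_lymph)
    sb = Yb2.sum(axis=1)
    sp = Yp2.sum(axis=1)
    n_redraws = 0
    while np.any(sb == 0.0):
        bad = np.flatnonzero(sb == 0.0)
        n_redraws += len(bad)
        if n_redraws > 100 * n_burdens:
            raise RuntimeError("perturbed baseline burdens keep collapsing to zero")
        Yb_b, Yp_b, _ = _sample_burden_arrays(scenario, len(bad), rng, size_dist, change_variance)
        Yb2_b, Yp2_b = _perturb_arrays(Yb_b, Yp_b, lymph, err, rng, err_lymph)
        sb[bad] = Yb2_b.sum(axis=1)
        sp[bad] = Yp2_b.sum(axis=1)
    if n_redraws:
        logger.info("redrew %d burden(s) with zero perturbed baseline", n_redraws)
    c2 = (sp - sb) / sb
    p_response = float(np.mean(c2 <= PR_CUTOFF + _EPS))
    p_progression = float(np.mean(c2 >= PD_CUTOFF - _EPS))
    return p_response, p_progression


@dataclass
class ProbabilityTable:
    """Scenario-indexed medians of reassessment designation probabilities."""

    entries: dict[tuple, tuple[float, float]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def compositions(self) -> set[tuple[int, int, str]]:
        return {(k[0], k[1], k[4]) for k in self.entries}

    def baselines_for(self, n_solid: int, n_lymph: int, reader_mode: str) -> list[int]:
        return sorted(
            {
                k[2]
                for k in self.entries
                if k[0] == n_solid and k[1] == n_lymph and k[4] == reader_mode and k[2] is not None
            }
        )

    def c_grid_for(self, n_solid: int, n_lymph: int, baseline, reader_mode: str) -> list[int]:
        """Available percent-change grid points (centi-units) for one scenario slice."""
        return sorted(
            {
                k[3]
                for k in self.entries
                if k[0] == n_solid and k[1] == n_lymph and k[2] == baseline
                and k[4] == reader_mode
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n_solid": k[0],
                "n_lymph": k[1],
                "baseline_mm": k[2],
                "c": k[3] / 100.0,
                "reader_mode": k[4],
                "p_response": v[0],
                "p_progression": v[1],
            }
            for k, v in sorted(self.entries.items(), key=lambda kv: tuple(
                (x is None, x) for x in kv[0]))
        ]
        return pd.DataFrame(
            rows,
            columns=["n_solid", "n_lymph", "baseline_mm", "c", "reader_mode",
                     "p_response", "p_progression"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ProbabilityTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        entries = {}
        for row in frame.itertuples():
            base = None if pd.isna(row.baseline_mm) else int(row.baseline_mm)
            key = (int(row.n_solid), int(row.n_lymph), base, int(round(row.c * 100)),
                   str(row.reader_mode))
            entries[key] = (float(row.p_response), float(row.p_progression))
        return cls(entries=entries)


def build_probability_table(
    grid: Sequence[Scenario],
    posterior: PosteriorDraws,
    n_iter: int = 100,
    n_burdens: int = 100,
    rng: np.random.Generator | None = None,
    posterior_short: PosteriorDraws | None = None,
    size_dist: dict | None = None,
    change_variance: dict | None = None,
) -> ProbabilityTable:
    """Median designation probabilities over random posterior draws.

    Per scenario, ``n_iter`` probability estimates are computed, each under
    the error covariance of a randomly selected posterior draw (long-axis
    model for solid lesions; ``posterior_short`` for lymph nodes), and the
    medians are stored.  Scenarios involving lymph nodes require
    ``posterior_short``.
    """
    if len(grid) == 0:
        raise ValueError("empty scenario grid")
    rng = np.random.default_rng() if rng is None else rng
    entries: dict[tuple, tuple[float, float]] = {}
    for scenario in grid:
        uses_short = scenario.n_lymph > 0
        if uses_short and posterior_short is None:
            raise ValueError(
                "scenario includes lymph nodes: a short-axis posterior is required"
            )
        pr = np.empty(n_iter)
        pp = np.empty(n_iter)
        err_fn = intra_error_cov if scenario.reader_mode == "intra" else inter_error_cov
        for t in range(n_iter):
            vc_long = posterior.draws[rng.integers(len(posterior.draws))]
            err = err_fn(vc_long)
            err_lymph = None
            if uses_short:
                vc_short = posterior_short.draws[rng.integers(len(posterior_short.draws))]
                err_lymph = err_fn(vc_short)
                if scenario.n_solid == 0:
                    err = err_lymph  # all-lymph burdens only use the short-axis model
            pr[t], pp[t] = estimate_probabilities(
                scenario, err, n_burdens=n_burdens, rng=rng, err_lymph=err_lymph,
                size_dist=size_dist, change_variance=change_variance,
            )
        entries[scenario.key] = (float(np.median(pr)), float(np.median(pp)))
    return ProbabilityTable(
        entries=entries,
        provenance={"n_iter": n_iter, "n_burdens": n_burdens, "n_posterior_draws": len(posterior)},
    )


def lookup_probability(
    table: ProbabilityTable, summary: BurdenSummary, reader_mode: str
) -> tuple[float, float]:
    """Table entry for a patient's burden summary.

    The fractional change is rounded to the 0.01 grid and clamped to [-1, 1]
    (growth beyond +100% is designated progression with probability ~1, so
    the clamp is benign).  Single-lesion burdens snap to the nearest 1 mm
    grid baseline, clamped to the grid range; multi-lesion burdens match by
    composition only.
    """
    c = summary.percent_change / 100.0
    if c > 1.0:
        warnings.warn(
            f"patient {summary.patient_id}: percent change {summary.percent_change:.1f}% "
            "clamped to +100% for table lookup",
            RuntimeWarning,
            stacklevel=2,
        )
    c = float(np.clip(c, -1.0, 1.0))
    comp = (summary.n_solid, summary.n_lymph, reader_mode)
    if comp not in table.compositions():
        available = sorted(table.compositions())
        raise KeyError(
            f"composition (n_solid={comp[0]}, n_lymph={comp[1]}, mode={comp[2]!r}) not in "
            f"table; available compositions: {available}"
        )
    base_key = None
    if summary.n_solid + summary.n_lymph == 1:
        baselines = table.baselines_for(summary.n_solid, summary.n_lymph, reader_mode)
        target = summary.burden_baseline_mm
        nearest = min(baselines, key=lambda b: abs(b - target))
        if not baselines[0] <= target <= baselines[-1]:
            warnings.warn(
                f"patient {summary.patient_id}: baseline {target:.1f} mm outside the "
                f"table grid [{baselines[0]}, {baselines[-1]}]; clamped to {nearest} mm",
                RuntimeWarning,
                stacklevel=2,
            )
        base_key = nearest
    c_centi = int(round(c * 100))
    available = table.c_grid_for(summary.n_solid, summary.n_lymph, base_key, reader_mode)
    if not available:
        raise KeyError(f"no percent-change grid for composition {comp} at {base_key} mm")
    # snap to the table's c grid (identical to 0.01 rounding on a full table)
    c_centi = min(available, key=lambda g: abs(g - c_centi))
    key = (summary.n_solid, summary.n_lymph, base_key, c_centi, reader_mode)
    return table.entries[key]
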