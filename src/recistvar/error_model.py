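"""Bivariate hierarchical measurement-error model for repeated lesion readings.

Square-root-transformed diameters at baseline (b) and post-treatment (p) are
modelled jointly as

    (sqrt(Y_b), sqrt(Y_p)) = mu + alpha_lesion + beta_reader + gamma_interaction + eps

where each random effect is mean-zero bivariate normal with its own 2x2
covariance matrix.  The residual covariance is the *intra*-reader measurement
error (one reader re-measuring a lesion); the *inter*-reader error combines
reader, interaction and half the residual covariance:

    Sigma_inter = Sigma_reader + Sigma_interaction + Sigma_residual / 2.

Fitting is Bayesian: a blocked Gibbs sampler with conjugate inverse-Wishart
priors on the four covariance components and a flat prior on the fixed means.
A fast method-of-moments estimator (crossed two-way ANOVA expected mean
squares, generalised to 2x2 cross-product matrices) is available both as a
fallback for quick runs and as an independent check on the sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .io import PHASES, RepeatedReadingDataset

COMPONENT_NAMES = ("lesion", "reader", "interaction", "residual")

_PSD_TOL = 1e-10


def _as_psd(mat: np.ndarray, tol: float = _PSD_TOL) -> np.ndarray:
    """Symmetrise and clip eigenvalues at zero (moment estimates can dip below)."""
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < -tol * max(1.0, vals.max()):
        vals = np.clip(vals, 0.0, None)
        sym = (vecs * vals) @ vecs.T
        sym = 0.5 * (sym + sym.T)
    return sym


def _check_cov2(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"{name} must be a 2x2 matrix")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    vals = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    if vals.min() < -1e-8 * max(1.0, abs(vals).max()):
        raise ValueError(f"{name} must be positive semi-definite (eigenvalues {vals})")
    return _as_psd(mat)


@dataclass
class VarianceComponents:
    """Fixed means and the four 2x2 covariance components on the sqrt-mm scale."""

    mu: np.ndarray  # (mu_b, mu_p)
    cov_lesion: np.ndarray
    cov_reader: np.ndarray
    cov_interaction: np.ndarray
    cov_residual: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        self.cov_lesion = _check_cov2(self.cov_lesion, "cov_lesion")
        self.cov_reader = _check_cov2(self.cov_reader, "cov_reader")
        self.cov_interaction = _check_cov2(self.cov_interaction, "cov_interaction")
        self.cov_residual = _check_cov2(self.cov_residual, "cov_residual")

    def component(self, name: str) -> np.ndarray:
        return getattr(self, f"cov_{name}")

    def to_row(self) -> dict[str, float]:
        row = {"mu_b": self.mu[0], "mu_p": self.mu[1]}
        for name in COMPONENT_NAMES:
            c = self.component(name)
            row[f"{name}_var_b"] = c[0, 0]
            row[f"{name}_var_p"] = c[1, 1]
            row[f"{name}_cov_bp"] = c[0, 1]
        return row

    @classmethod
    def from_row(cls, row) -> "VarianceComponents":
        def mat(name):
            return np.array(
                [
                    [row[f"{name}_var_b"], row[f"{name}_cov_bp"]],
                    [row[f"{name}_cov_bp"], row[f"{name}_var_p"]],
                ]
            )

        return cls(
            mu=np.array([row["mu_b"], row["mu_p"]]),
            cov_lesion=mat("lesion"),
            cov_reader=mat("reader"),
            cov_interaction=mat("interaction"),
            cov_residual=mat("residual"),
        )


@dataclass(frozen=True)
class ErrorDistribution:
    """Mean-zero bivariate normal for (baseline, post) errors on the sqrt scale."""

    mode: Literal["intra", "inter"]
    cov: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cov", _check_cov2(self.cov, "cov"))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n correlated (eps_b, eps_p) pairs."""
        chol = _chol2(self.cov[None])[0]
        return rng.standard_normal((n, 2)) @ chol.T


def intra_error_cov(vc: VarianceComponents) -> ErrorDistribution:
    """Intra-reader error: the residual covariance (same lesion, same reader)."""
    return ErrorDistribution(mode="intra", cov=vc.cov_residual)


def inter_error_cov(vc: VarianceComponents) -> ErrorDistribution:
    """Inter-reader error: reader + interaction + half the residual covariance."""
    cov = vc.cov_reader + vc.cov_interaction + vc.cov_residual / 2.0
    return ErrorDistribution(mode="inter", cov=cov)


@dataclass
class PosteriorDraws:
    """Posterior (or point-estimate) draws of the variance components."""

    draws: list[VarianceComponents]
    n_chains: int
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    warning: str | None = None
    axis_kind: str | None = None

    def __len__(self) -> int:
        return len(self.draws)

    def median_components(self) -> VarianceComponents:
        """Elementwise posterior medians, re-projected to valid covariances."""
        frame = self.to_frame()
        med = frame.drop(columns=["chain", "draw"], errors="ignore").median()
        return VarianceComponents.from_row(med)

    def to_frame(self) -> pd.DataFrame:
        rows = [vc.to_row() for vc in self.draws]
        frame = pd.DataFrame(rows)
        per_chain = len(self.draws) // max(self.n_chains, 1)
        frame.insert(0, "draw", np.arange(len(frame)) % max(per_chain, 1))
        frame.insert(0, "chain", np.arange(len(frame)) // max(per_chain, 1))
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PosteriorDraws":
        frame = pd.read_csv(path, float_precision="round_trip")
        draws = [VarianceComponents.from_row(row) for _, row in frame.iterrows()]
        n_chains = int(frame["chain"].max()) + 1 if "chain" in frame else 1
        return cls(draws=draws, n_chains=n_chains)


# ---------------------------------------------------------------------------
# outlier trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimResult:
    dataset: RepeatedReadingDataset
    removed: pd.DataFrame  # columns: lesion_id, reader_id, session, phase, reason


def _phase_standardized_residuals(frame: pd.DataFrame) -> np.ndarray:
    """Standardised residuals of sqrt diameters under the one-phase crossed model.

    Variance components are estimated by moments and random effects predicted
    by shrinkage of the (lesion / reader / cell) means, i.e. an empirical-BLUP
    fit: good enough to rank outlying records.
    """
    v = np.sqrt(frame["diameter_mm"].to_numpy(float))
    li, lesions = pd.factorize(frame["lesion_id"])
    rj, readers = pd.factorize(frame["reader_id"])
    I, J = len(lesions), len(readers)
    cell = li * J + rj
    cell_idx, cells = pd.factorize(cell)
    C = len(cells)
    grand = v.mean()

    cell_sum = np.bincount(cell_idx, weights=v, minlength=C)
    cell_n = np.bincount(cell_idx, minlength=C)
    cell_mean = cell_sum / cell_n
    K = len(v) / C

    les_of_cell = (cells // J).astype(int)
    rdr_of_cell = (cells % J).astype(int)
    les_mean = np.bincount(les_of_cell, weights=cell_mean, minlength=I) / np.bincount(
        les_of_cell, minlength=I
    )
    rdr_mean = np.bincount(rdr_of_cell, weights=cell_mean, minlength=J) / np.bincount(
        rdr_of_cell, minlength=J
    )
    g = cell_mean.mean()

    # moments: within-cell -> residual; interaction contrast -> gamma; margins
    if len(v) > C:
        s2_eps = float(np.sum((v - cell_mean[cell_idx]) ** 2) / (len(v) - C))
    else:
        s2_eps = 0.0
    inter_contrast = cell_mean - les_mean[les_of_cell] - rdr_mean[rdr_of_cell] + g
    df_ab = max((I - 1) * (J - 1), 1)
    ms_ab = K * float(np.sum(inter_contrast**2)) / df_ab
    s2_gam = max((ms_ab - s2_eps) / K, 0.0)
    s2_alpha = max(float(np.var(les_mean, ddof=1)) - (s2_gam + s2_eps / K) / J, 0.0) if I > 1 else 0.0
    s2_beta = max(float(np.var(rdr_mean, ddof=1)) - (s2_gam + s2_eps / K) / I, 0.0) if J > 1 else 0.0

    def shrink(s2_effect, noise):
        tot = s2_effect + noise
        return s2_effect / tot if tot > 0 else 0.0

    a = shrink(s2_alpha, (s2_gam + s2_eps / K) / J) * (les_mean - g)
    b = shrink(s2_beta, (s2_gam + s2_eps / K) / I) * (rdr_mean - g)
    gam = shrink(s2_gam, s2_eps / K) * (
        cell_mean - g - a[les_of_cell] - b[rdr_of_cell]
    )
    fitted = g + a[li] + b[rj] + gam[cell_idx]
    resid = v - fitted
    sd = resid.std(ddof=1)
    if sd == 0:
        return np.zeros_like(resid)
    return resid / sd


def trim_outliers(data: RepeatedReadingDataset, fraction: float = 0.05) -> TrimResult:
    """Drop the stated fraction of records with the largest |standardised residual|.

    Trimming is done per phase on the sqrt scale under the one-phase crossed
    random-effects model (single pass).  When one phase's record of a
    (lesion, reader, session) pair is removed, its partner record in the
    other phase is removed too, so the bivariate fit sees complete pairs.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    if fraction == 0.0:
        return TrimResult(dataset=data, removed=pd.DataFrame(
            columns=["lesion_id", "reader_id", "session", "phase", "reason"]))
    if len(data.lesion_ids) < 2 or len(data.reader_ids) < 2:
        raise ValueError("trimming requires at least 2 lesions and 2 readers")

    frame = data.to_frame()
    removed_keys: set[tuple[str, str, int, str]] = set()
    removed_rows: list[dict] = []
    for phase in PHASES:
        sub = frame[frame["phase"] == phase].reset_index(drop=True)
        if len(sub) == 0:
            continue
        z = np.abs(_phase_standardized_residuals(sub))
        n_remove = int(round(fraction * len(sub)))
        if n_remove == 0:
            continue
        order = np.argsort(-z, kind="stable")[:n_remove]
        for pos in order:
            row = sub.iloc[pos]
            key = (row.lesion_id, row.reader_id, int(row.session), phase)
            removed_keys.add(key)
            removed_rows.append(
                {"lesion_id": key[0], "reader_id": key[1], "session": key[2],
                 "phase": phase, "reason": "outlier", "std_resid": float(z[pos])}
            )
    # pair completion: drop the other-phase partner of every removed record
    outlier_keys = set(removed_keys)
    all_keys = {rec.key for rec in data.records}
    for lesion, reader, session, phase in outlier_keys:
        other = "post" if phase == "baseline" else "baseline"
        partner = (lesion, reader, session, other)
        if partner in all_keys and partner not in removed_keys:
            removed_keys.add(partner)
            removed_rows.append(
                {"lesion_id": lesion, "reader_id": reader, "session": session,
                 "phase": other, "reason": "pair", "std_resid": np.nan}
            )
    kept = [rec for rec in data.records if rec.key not in removed_keys]
    return TrimResult(
        dataset=RepeatedReadingDataset(records=kept, axis_kind=data.axis_kind),
        removed=pd.DataFrame(removed_rows,
                             columns=["lesion_id", "reader_id", "session", "phase",
                                      "reason", "std_resid"]),
    )


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def _paired_design(data: RepeatedReadingDataset):
    """Arrange records as complete (baseline, post) pairs with design indices."""
    frame = data.to_frame()
    wide = frame.pivot_table(
        index=["lesion_id", "reader_id", "session"],
        columns="phase",
        values="diameter_mm",
        aggfunc="first",
    ).dropna()
    if len(wide) == 0:
        raise ValueError("no complete (baseline, post) measurement pairs")
    wide = wide.reset_index()
    y = np.sqrt(wide[["baseline", "post"]].to_numpy(float))
    li, lesions = pd.factorize(wide["lesion_id"])
    rj, readers = pd.factorize(wide["reader_id"])
    J = len(readers)
    cell_codes, cells = pd.factorize(li.astype(np.int64) * J + rj)
    les_of_cell = (np.asarray(cells) // J).astype(int)
    rdr_of_cell = (np.asarray(cells) % J).astype(int)
    return y, li, rj, cell_codes, len(lesions), J, len(cells), les_of_cell, rdr_of_cell


def _inv2(a: np.ndarray) -> np.ndarray:
    """Inverse of a stack of 2x2 matrices, closed form."""
    det = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    out = np.empty_like(a)
    out[..., 0, 0] = a[..., 1, 1]
    out[..., 1, 1] = a[..., 0, 0]
    out[..., 0, 1] = -a[..., 0, 1]
    out[..., 1, 0] = -a[..., 1, 0]
    return out / det[..., None, None]


def _chol2(a: np.ndarray) -> np.ndarray:
    """Lower Cholesky of a stack of 2x2 PSD matrices, tolerant of zeros."""
    l11 = np.sqrt(np.clip(a[..., 0, 0], 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        l21 = np.where(l11 > 0, a[..., 1, 0] / np.where(l11 > 0, l11, 1.0), 0.0)
    l22 = np.sqrt(np.clip(a[..., 1, 1] - l21**2, 0.0, None))
    out = np.zeros(a.shape)
    out[..., 0, 0] = l11
    out[..., 1, 0] = l21
    out[..., 1, 1] = l22
    return out


def moments_estimate(data: RepeatedReadingDataset) -> VarianceComponents:
    """Method-of-moments (expected-mean-squares) estimate of the components.

    Uses the crossed two-way ANOVA decomposition applied to 2x2 cross-product
    matrices of the paired sqrt-scale measurements; assumes a (near-)balanced
    design.  Negative-definite differences are projected back to PSD.
    Requires replicate sessions so the residual is separable from the
    interaction.
    """
    y, li, rj, cell, I, J, C, les_of_cell, rdr_of_cell = _paired_design(data)
    N = len(y)
    if N <= C:
        raise ValueError("moments estimate needs replicate sessions per (lesion, reader)")
    if I < 2 or J < 2:
        raise ValueError("moments estimate needs at least 2 lesions and 2 readers")

    cell_sum = np.zeros((C, 2))
    np.add.at(cell_sum, cell, y)
    cell_n = np.bincount(cell, minlength=C)
    cell_mean = cell_sum / cell_n[:, None]
    K = N / C

    resid = y - cell_mean[cell]
    S_eps = resid.T @ resid / (N - C)

    # margins of cell means (unweighted, balanced assumption)
    les_mean = np.zeros((I, 2))
    np.add.at(les_mean, les_of_cell, cell_mean)
    les_mean /= np.bincount(les_of_cell, minlength=I)[:, None]
    rdr_mean = np.zeros((J, 2))
    np.add.at(rdr_mean, rdr_of_cell, cell_mean)
    rdr_mean /= np.bincount(rdr_of_cell, minlength=J)[:, None]
    g = cell_mean.mean(axis=0)

    inter = cell_mean - les_mean[les_of_cell] - rdr_mean[rdr_of_cell] + g
    MS_AB = K * (inter.T @ inter) / ((I - 1) * (J - 1))
    dev_a = les_mean - g
    MS_A = J * K * (dev_a.T @ dev_a) / (I - 1)
    dev_b = rdr_mean - g
    MS_B = I * K * (dev_b.T @ dev_b) / (J - 1)

    S_gam = _as_psd((MS_AB - S_eps) / K)
    S_alp = _as_psd((MS_A - MS_AB) / (J * K))
    S_bet = _as_psd((MS_B - MS_AB) / (I * K))
    return VarianceComponents(
        mu=g,
        cov_lesion=S_alp,
        cov_reader=S_bet,
        cov_interaction=S_gam,
        cov_residual=_as_psd(S_eps),
    )


def _sample_effects(resid, idx, n_groups, Se_inv, Sprior_inv, rng):
    """Gibbs update of one block of bivariate random effects."""
    S = np.zeros((n_groups, 2))
    np.add.at(S, idx, resid)
    counts = np.bincount(idx, minlength=n_groups).astype(float)
    P = counts[:, None, None] * Se_inv[None] + Sprior_inv[None]
    V = _inv2(P)
    b = S @ Se_inv  # Se_inv symmetric
    mean = np.einsum("gij,gj->gi", V, b)
    L = _chol2(V)
    z = rng.standard_normal((n_groups, 2))
    return mean + np.einsum("gij,gj->gi", L, z)


def _translate_block(child, parent_rows, group_of_child, n_groups, S_child_inv,
                     S_parent_inv, rng):
    """Interweaving move: shift per-group means of one effect block into its
    additively confounded partner (e.g. interaction row means into the lesion
    effects).  The translation leaves the likelihood invariant; drawing it
    from the prior-induced Gaussian is a generalized-Gibbs step that restores
    mixing of the confounded means."""
    sums = np.zeros((n_groups, 2))
    np.add.at(sums, group_of_child, child)
    counts = np.bincount(group_of_child, minlength=n_groups).astype(float)
    P = counts[:, None, None] * S_child_inv[None] + S_parent_inv[None]
    V = _inv2(P)
    b = sums @ S_child_inv - parent_rows @ S_parent_inv
    mean = np.einsum("gij,gj->gi", V, b)
    delta = mean + np.einsum("gij,gj->gi", _chol2(V), rng.standard_normal((n_groups, 2)))
    return delta


def _translate_to_mu(effects, S_inv, rng):
    """Shift the global mean of an effect block into the (flat-prior) mu."""
    n = len(effects)
    V = _inv2((n * S_inv)[None])[0]
    mean = V @ (S_inv @ effects.sum(axis=0))
    return mean + _chol2(V[None])[0] @ rng.standard_normal(2)


def _safe_inv2(mat: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    m = mat.copy()
    m[0, 0] = max(m[0, 0], floor)
    m[1, 1] = max(m[1, 1], floor)
    # keep correlation strictly below 1 so the inverse exists
    lim = 0.999999 * np.sqrt(m[0, 0] * m[1, 1])
    m[0, 1] = m[1, 0] = np.clip(m[0, 1], -lim, lim)
    return np.linalg.inv(m)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of one scalar parameter; chains shape (n_chains, n_draws)."""
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


_IW_NU0 = 3.0
_IW_SCALE0 = 0.01  # diffuse on sqrt-mm scale where error SDs are O(0.05-1.5)


def fit_bivariate_model(
    data: RepeatedReadingDataset,
    method: Literal["gibbs", "moments"] = "gibbs",
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int | None = None,
    rhat_threshold: float = 1.1,
) -> PosteriorDraws:
    """Fit the bivariate crossed random-effects model on sqrt-scale diameters.

    ``method="gibbs"`` runs the blocked Gibbs sampler (conjugate
    inverse-Wishart updates for the four covariances, normal updates for the
    effects and means) and reports split-R-hat per scalar component.
    ``method="moments"`` returns the fast point estimate wrapped as a single
    draw, which downstream posterior-driven steps treat as a degenerate
    posterior.
    """
    y, li, rj, cell, I, J, C, les_of_cell, rdr_of_cell = _paired_design(data)
    if J < 2:
        raise ValueError(
            "only one reader in the dataset: reader/interaction components are not "
            "identifiable; fit an intra-only (residual) model instead"
        )
    if I < 2:
        raise ValueError("need at least 2 lesions")

    if method == "moments":
        vc = moments_estimate(data)
        return PosteriorDraws(draws=[vc], n_chains=1, axis_kind=data.axis_kind)
    if method != "gibbs":
        raise ValueError(f"unknown method {method!r}")

    N = len(y)
    if N <= C:
        raise ValueError(
            "no replicate sessions: residual and interaction components are confounded"
        )
    try:
        vc0 = moments_estimate(data)
    except ValueError:
        vc0 = None

    rng_master = np.random.default_rng(seed)
    all_rows: list[dict] = []
    draws: list[VarianceComponents] = []
    chain_rows: list[list[dict]] = []
    for _ in range(n_chains):
        rng = np.random.default_rng(rng_master.integers(2**31))
        # initialise near the moments estimate, jittered per chain
        def init_cov(base, default):
            mat = base if base is not None else np.eye(2) * default
            jitter = np.exp(rng.normal(0, 0.2))
            out = mat * jitter
            out = out + np.eye(2) * 1e-6
            return out

        Sa = init_cov(vc0.cov_lesion if vc0 else None, 1.0)
        Sb = init_cov(vc0.cov_reader if vc0 else None, 0.01)
        Sg = init_cov(vc0.cov_interaction if vc0 else None, 0.01)
        Se = init_cov(vc0.cov_residual if vc0 else None, 0.02)
        mu = y.mean(axis=0)
        alpha = np.zeros((I, 2))
        beta = np.zeros((J, 2))
        gamma = np.zeros((C, 2))
        Psi0 = _IW_SCALE0 * np.eye(2)
        rows_this_chain: list[dict] = []

        for it in range(n_warmup + n_draws):
            Se_inv = _safe_inv2(Se)
            alpha = _sample_effects(y - mu - beta[rj] - gamma[cell], li, I, Se_inv, _safe_inv2(Sa), rng)
            beta = _sample_effects(y - mu - alpha[li] - gamma[cell], rj, J, Se_inv, _safe_inv2(Sb), rng)
            gamma = _sample_effects(y - mu - alpha[li] - beta[rj], cell, C, Se_inv, _safe_inv2(Sg), rng)

            # interweaving translations between additively confounded blocks
            Sa_inv, Sb_inv, Sg_inv = _safe_inv2(Sa), _safe_inv2(Sb), _safe_inv2(Sg)
            d = _translate_block(gamma, alpha, les_of_cell, I, Sg_inv, Sa_inv, rng)
            gamma -= d[les_of_cell]
            alpha += d
            d = _translate_block(gamma, beta, rdr_of_cell, J, Sg_inv, Sb_inv, rng)
            gamma -= d[rdr_of_cell]
            beta += d
            d = _translate_to_mu(alpha, Sa_inv, rng)
            alpha -= d
            mu = mu + d
            d = _translate_to_mu(beta, Sb_inv, rng)
            beta -= d
            mu = mu + d

            r = y - alpha[li] - beta[rj] - gamma[cell]
            mu_mean = r.mean(axis=0)
            mu = mu_mean + _chol2((Se / N)[None])[0] @ rng.standard_normal(2)
            eps = r - mu
            Se = invwishart.rvs(df=_IW_NU0 + N, scale=Psi0 + eps.T @ eps, random_state=rng)
            Sa = invwishart.rvs(df=_IW_NU0 + I, scale=Psi0 + alpha.T @ alpha, random_state=rng)
            Sb = invwishart.rvs(df=_IW_NU0 + J, scale=Psi0 + beta.T @ beta, random_state=rng)
            Sg = invwishart.rvs(df=_IW_NU0 + C, scale=Psi0 + gamma.T @ gamma, random_state=rng)
            if it >= n_warmup:
                vc = VarianceComponents(
                    mu=mu, cov_lesion=Sa, cov_reader=Sb, cov_interaction=Sg, cov_residual=Se
                )
                draws.append(vc)
                rows_this_chain.append(vc.to_row())
        chain_rows.append(rows_this_chain)

    # split-R-hat per scalar parameter across chains
    params = list(chain_rows[0][0].keys())
    diag_rows = []
    for p in params:
        arr = np.array([[row[p] for row in chain] for chain in chain_rows])
        diag_rows.append({"parameter": p, "rhat": _split_rhat(arr)})
    diagnostics = pd.DataFrame(diag_rows)
    warning = None
    bad = diagnostics[diagnostics["rhat"] > rhat_threshold]
    if len(bad):
        warning = (
            "possible non-convergence: split-R-hat > "
            f"{rhat_threshold} for {', '.join(bad['parameter'])}"
        )
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    return PosteriorDraws(
        draws=draws,
        n_chains=n_chains,
        diagnostics=diagnostics,
        warning=warning,
        axis_kind=data.axis_kind,
    )
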