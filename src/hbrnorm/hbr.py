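"""Hierarchical Bayesian Regression (HBR) normative model, one ROI at a time.

Model for a single region of interest with observations grouped into batches
b (site x sex cells, or wave x sex cells for a longitudinal target):

    y_i     = alpha_{b(i)} + beta_{b(i)} * x_i + eps_i,  eps_i ~ N(0, sigma_b^2)
    alpha_b ~ N(mu_alpha, tau_alpha^2)
    beta_b  ~ N(mu_beta,  tau_beta^2)
    log sigma_b ~ N(mu_logsigma, tau_logsigma^2)

with x the standardized age.  The noise is parameterized on the log scale so
that positivity is automatic and the between-batch spread of noise levels is
itself a transferable hyperparameter.

Inference is a blocked Gibbs sampler: the per-batch (alpha_b, beta_b) pair
and the mu_* hyperparameters are conjugate (exact bivariate/univariate
normal draws); log sigma_b and the log tau_* scales use adaptive random-walk
Metropolis steps.  Joint translation moves that shift a hierarchy's batch
parameters together with its mu_* hyperparameter keep the chain mixing even
when tau_* is pinned near zero (where centered Gibbs alone stalls).
All updates are vectorized across batches and across ROIs, so fitting ten
regions costs little more than fitting one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CovariateTransform",
    "NormalPrior",
    "TruncNormalPrior",
    "HalfNormalPrior",
    "PriorSpec",
    "SamplerConfig",
    "BatchSummary",
    "ROIPosterior",
    "NormativeModel",
    "ReferenceModel",
    "UnknownBatchError",
    "ModelValidationError",
    "default_priors",
    "fit_reference",
    "fit_rois",
    "predict",
    "summarize_hyperposterior",
]

HYPER_NAMES = ("mu_alpha", "tau_alpha", "mu_beta", "tau_beta",
               "mu_logsigma", "tau_logsigma")

_LOGTAU_MIN, _LOGTAU_MAX = -13.0, 4.0
_LOGSIG_MIN, _LOGSIG_MAX = -13.0, 6.0


class ModelValidationError(ValueError):
    pass


class UnknownBatchError(KeyError):
    """Raised when a scan's (site-or-wave, sex) batch is not in the model.

    For batches from a new scanner, transfer the model first (see
    :mod:`hbrnorm.transfer`).
    """


@dataclass
class CovariateTransform:
    """Affine age standardization fitted on the reference training data."""

    center: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ModelValidationError("CovariateTransform.scale must be > 0")

    @classmethod
    def fit(cls, ages) -> "CovariateTransform":
        ages = np.asarray(ages, dtype=float)
        sd = float(ages.std())
        if sd <= 0:
            raise ModelValidationError(
                "cannot standardize ages with zero variance")
        return cls(center=float(ages.mean()), scale=sd)

    def apply(self, ages):
        return (np.asarray(ages, dtype=float) - self.center) / self.scale

    def invert(self, x):
        return np.asarray(x, dtype=float) * self.scale + self.center


@dataclass(frozen=True)
class NormalPrior:
    loc: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ModelValidationError("prior scale must be > 0")


@dataclass(frozen=True)
class TruncNormalPrior:
    """Normal(loc, scale) truncated below at ``lower`` (default 0)."""

    loc: float
    scale: float
    lower: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ModelValidationError("prior scale must be > 0")


def HalfNormalPrior(scale: float) -> TruncNormalPrior:
    return TruncNormalPrior(0.0, scale)


@dataclass(frozen=True)
class PriorSpec:
    """Priors over the six hyperparameters of one ROI's model."""

    mu_alpha: NormalPrior
    tau_alpha: TruncNormalPrior
    mu_beta: NormalPrior
    tau_beta: TruncNormalPrior
    mu_logsigma: NormalPrior
    tau_logsigma: TruncNormalPrior


def default_priors(y) -> PriorSpec:
    """Weak, scale-aware default hyperpriors built from the response."""
    y = np.asarray(y, dtype=float)
    sd = float(y.std())
    if sd <= 0:
        sd = 1.0
    # location/scale priors are proportional to the response spread so the
    # model is equivariant under affine re-units of y (mm vs um)
    return PriorSpec(
        mu_alpha=NormalPrior(float(y.mean()), 10.0 * sd),
        tau_alpha=HalfNormalPrior(5.0 * sd),
        mu_beta=NormalPrior(0.0, 10.0 * sd),
        tau_beta=HalfNormalPrior(5.0 * sd),
        mu_logsigma=NormalPrior(float(np.log(sd)), 2.0),
        tau_logsigma=HalfNormalPrior(1.0),
    )


@dataclass
class SamplerConfig:
    chains: int = 2
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    sample_hypers: bool = True
    rhat_threshold: float = 1.05
    target_accept: float = 0.44


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _suff_stats(y: np.ndarray, x: np.ndarray, batch_idx: np.ndarray,
                B: int) -> dict[str, np.ndarray]:
    n = np.bincount(batch_idx, minlength=B).astype(float)
    Sx = np.bincount(batch_idx, weights=x, minlength=B)
    Sxx = np.bincount(batch_idx, weights=x * x, minlength=B)
    R = y.shape[1]
    Sy = np.empty((B, R))
    Sxy = np.empty((B, R))
    Syy = np.empty((B, R))
    for r in range(R):
        Sy[:, r] = np.bincount(batch_idx, weights=y[:, r], minlength=B)
        Sxy[:, r] = np.bincount(batch_idx, weights=x * y[:, r], minlength=B)
        Syy[:, r] = np.bincount(batch_idx, weights=y[:, r] ** 2, minlength=B)
    return {"n": n, "Sx": Sx, "Sxx": Sxx, "Sy": Sy, "Sxy": Sxy, "Syy": Syy}


def _rss(st, alpha, beta):
    n = st["n"][:, None]
    Sx = st["Sx"][:, None]
    Sxx = st["Sxx"][:, None]
    rss = (st["Syy"] - 2 * alpha * st["Sy"] - 2 * beta * st["Sxy"]
           + 2 * alpha * beta * Sx + alpha ** 2 * n + beta ** 2 * Sxx)
    return np.maximum(rss, 1e-12)


def _ols_init(st):
    n = st["n"][:, None]
    Sx = st["Sx"][:, None]
    Sxx = st["Sxx"][:, None]
    sxx = Sxx - Sx ** 2 / n
    sxy = st["Sxy"] - Sx * st["Sy"] / n
    beta = sxy / np.maximum(sxx, 1e-8)
    alpha = (st["Sy"] - beta * Sx) / n
    rss = _rss(st, alpha, beta)
    sigma2 = np.maximum(rss / np.maximum(n - 2, 1.0), 1e-8)
    return alpha, beta, 0.5 * np.log(sigma2)


@dataclass
class _PriorArrays:
    # indexed by hierarchy g in {0: alpha, 1: beta, 2: logsigma}; shape (3, R)
    mu_loc: np.ndarray
    mu_scale: np.ndarray
    tau_loc: np.ndarray
    tau_scale: np.ndarray

    @classmethod
    def from_specs(cls, specs: list[PriorSpec]) -> "_PriorArrays":
        def col(fn):
            return np.array([fn(s) for s in specs], dtype=float)
        mu_loc = np.stack([col(lambda s: s.mu_alpha.loc),
                           col(lambda s: s.mu_beta.loc),
                           col(lambda s: s.mu_logsigma.loc)])
        mu_scale = np.stack([col(lambda s: s.mu_alpha.scale),
                             col(lambda s: s.mu_beta.scale),
                             col(lambda s: s.mu_logsigma.scale)])
        tau_loc = np.stack([col(lambda s: s.tau_alpha.loc),
                            col(lambda s: s.tau_beta.loc),
                            col(lambda s: s.tau_logsigma.loc)])
        tau_scale = np.stack([col(lambda s: s.tau_alpha.scale),
                              col(lambda s: s.tau_beta.scale),
                              col(lambda s: s.tau_logsigma.scale)])
        return cls(mu_loc, mu_scale, tau_loc, tau_scale)


def _run_chain(st, pri: _PriorArrays, cfg: SamplerConfig,
               rng: np.random.Generator):
    B = st["n"].shape[0]
    R = st["Sy"].shape[1]
    n = st["n"][:, None]
    Sx = st["Sx"][:, None]
    Sxx = st["Sxx"][:, None]

    alpha, beta, s = _ols_init(st)

    def jit(shape):
        return 0.05 * rng.standard_normal(shape)

    alpha = alpha + jit((B, R)) * np.exp(s)
    beta = beta + jit((B, R)) * np.exp(s)
    s = np.clip(s + jit((B, R)), _LOGSIG_MIN, _LOGSIG_MAX)

    mu = np.stack([alpha.mean(0), beta.mean(0), s.mean(0)])  # (3, R)
    spread = np.stack([alpha.std(0), beta.std(0), s.std(0)])
    logtau = np.clip(np.log(np.maximum(spread, 1e-4)),
                     _LOGTAU_MIN, _LOGTAU_MAX)
    if not cfg.sample_hypers:
        mu = pri.mu_loc.copy()
        logtau = np.clip(np.log(np.maximum(pri.tau_loc, 1e-6)),
                         _LOGTAU_MIN, _LOGTAU_MAX)

    step_s = np.full((B, R), 0.3)
    step_tau = np.full((3, R), 0.5)
    step_shift = np.full((3, R), 0.1)
    step_resc = np.full((3, R), 0.5)
    gamma = 0.07  # Robbins-Monro-style step adaptation rate during warmup

    n_iter = cfg.warmup + cfg.draws
    out = {k: np.empty((cfg.draws,) + shape) for k, shape in {
        "alpha": (B, R), "beta": (B, R), "logsigma": (B, R),
        "mu": (3, R), "tau": (3, R)}.items()}

    def tau_logprior(tau, g):
        return -(tau - pri.tau_loc[g]) ** 2 / (2 * pri.tau_scale[g] ** 2)

    # Per-batch OLS summaries: with x centered within batch, the batch mean
    # m_hat_b = Sy/n and slope bhat_b are independent given (alpha_b, beta_b),
    # so integrating the batch effects out leaves a closed-form 2x2 Gaussian
    # marginal per batch.  MH on the log tau pair and exact conjugate draws
    # of (mu_alpha, mu_beta) under that marginal remove the funnel coupling
    # between the hyperparameters and the batch-level deviations.
    xbar = Sx / n
    sxx_c = np.maximum(Sxx - Sx ** 2 / n, 1e-10)
    m_hat = st["Sy"] / n
    bhat = (st["Sxy"] - xbar * st["Sy"]) / sxx_c

    def _marg_pieces(ta2, tb2, sigma2):
        v1 = ta2 + xbar ** 2 * tb2 + sigma2 / n
        v2 = tb2 + sigma2 / sxx_c
        c = xbar * tb2
        det = np.maximum(v1 * v2 - c ** 2, 1e-300)
        return v1, v2, c, det

    def _marg_ll(ta2, tb2, sigma2):
        v1, v2, c, det = _marg_pieces(ta2, tb2, sigma2)
        d1 = m_hat - mu[0] - mu[1] * xbar
        d2 = bhat - mu[1]
        return (-0.5 * np.log(det)
                - (v2 * d1 ** 2 - 2 * c * d1 * d2 + v1 * d2 ** 2)
                / (2 * det)).sum(0)

    def collapsed_regression_hypers(sigma2, warm):
        # alternating MH on log tau_alpha and log tau_beta under the marginal
        for _ in range(3):
            for g in (0, 1):
                t = logtau[g]
                p = np.clip(t + step_tau[g] * rng.standard_normal(R),
                            _LOGTAU_MIN, _LOGTAU_MAX)
                cur = [np.exp(2 * logtau[0]), np.exp(2 * logtau[1])]
                prop = list(cur)
                prop[g] = np.exp(2 * p)
                dlog = (_marg_ll(prop[0], prop[1], sigma2)
                        - _marg_ll(cur[0], cur[1], sigma2))
                dlog += (tau_logprior(np.exp(p), g)
                         - tau_logprior(np.exp(t), g) + (p - t))
                acc = np.log(rng.uniform(size=R)) < dlog
                logtau[g] = np.where(acc, p, t)
                if warm:
                    step_tau[g] *= np.exp(gamma * (acc - cfg.target_accept))
        # exact conjugate draw of (mu_alpha, mu_beta) under the marginal:
        # z_b = (m_hat, bhat) ~ N(M_b mu, V_b), M_b = [[1, xbar], [0, 1]]
        v1, v2, c, det = _marg_pieces(np.exp(2 * logtau[0]),
                                      np.exp(2 * logtau[1]), sigma2)
        iv11, iv12, iv22 = v2 / det, -c / det, v1 / det
        P11 = iv11.sum(0) + 1.0 / pri.mu_scale[0] ** 2
        P12 = (iv11 * xbar + iv12).sum(0)
        P22 = ((iv11 * xbar ** 2 + 2 * iv12 * xbar + iv22).sum(0)
               + 1.0 / pri.mu_scale[1] ** 2)
        w1 = iv11 * m_hat + iv12 * bhat
        r1 = w1.sum(0) + pri.mu_loc[0] / pri.mu_scale[0] ** 2
        r2 = ((xbar * w1 + iv12 * m_hat + iv22 * bhat).sum(0)
              + pri.mu_loc[1] / pri.mu_scale[1] ** 2)
        detP = np.maximum(P11 * P22 - P12 ** 2, 1e-300)
        mm1 = (P22 * r1 - P12 * r2) / detP
        mm2 = (P11 * r2 - P12 * r1) / detP
        C11, C12, C22 = P22 / detP, -P12 / detP, P11 / detP
        L11 = np.sqrt(np.maximum(C11, 1e-300))
        L21 = C12 / L11
        L22 = np.sqrt(np.maximum(C22 - L21 ** 2, 1e-300))
        za = rng.standard_normal(R)
        zb = rng.standard_normal(R)
        mu[0] = mm1 + L11 * za
        mu[1] = mm2 + L21 * za + L22 * zb

    for it in range(n_iter):
        warm = it < cfg.warmup
        inv_s2 = np.exp(-2 * s)
        sigma2 = np.exp(2 * s)

        if cfg.sample_hypers:
            # --- collapsed hyperparameter updates for intercepts/slopes ---
            collapsed_regression_hypers(sigma2, warm)

        tau2 = np.exp(2 * logtau)  # (3, R)

        # --- conjugate joint update of (alpha_b, beta_b) ------------------
        A11 = n * inv_s2 + 1.0 / tau2[0]
        A12 = Sx * inv_s2
        A22 = Sxx * inv_s2 + 1.0 / tau2[1]
        b1 = st["Sy"] * inv_s2 + mu[0] / tau2[0]
        b2 = st["Sxy"] * inv_s2 + mu[1] / tau2[1]
        det = np.maximum(A11 * A22 - A12 ** 2, 1e-300)
        m1 = (A22 * b1 - A12 * b2) / det
        m2 = (A11 * b2 - A12 * b1) / det
        C11 = A22 / det
        C12 = -A12 / det
        C22 = A11 / det
        L11 = np.sqrt(np.maximum(C11, 1e-300))
        L21 = C12 / L11
        L22 = np.sqrt(np.maximum(C22 - L21 ** 2, 1e-300))
        z1 = rng.standard_normal((B, R))
        z2 = rng.standard_normal((B, R))
        alpha = m1 + L11 * z1
        beta = m2 + L21 * z1 + L22 * z2

        if cfg.sample_hypers:
            # --- translation moves: shift (all batch params, mu) jointly.
            # These keep the chain mobile when a tau prior pins the
            # hierarchy spread near zero (centered Gibbs then stalls).
            resid_a = st["Sy"] - alpha * n - beta * Sx
            resid_b = st["Sxy"] - alpha * Sx - beta * Sxx
            for g, (coef, resid) in enumerate(
                    [(n, resid_a), (Sxx, resid_b)]):
                d = step_shift[g] * rng.standard_normal(R)
                dlog = (-(d ** 2 * coef - 2 * d * resid) * inv_s2 / 2).sum(0)
                dlog += (-((mu[g] + d - pri.mu_loc[g]) ** 2
                           - (mu[g] - pri.mu_loc[g]) ** 2)
                         / (2 * pri.mu_scale[g] ** 2))
                acc = np.log(rng.uniform(size=R)) < dlog
                if g == 0:
                    alpha = alpha + acc * d
                else:
                    beta = beta + acc * d
                mu[g] = mu[g] + acc * d
                if warm:
                    step_shift[g] *= np.exp(gamma * (acc - cfg.target_accept))

        # The noise hierarchy has no analytic collapse; repeating its
        # whole block shortens the tau_logsigma autocorrelation.
        for _rep in range(3):
            # --- log sigma_b: adaptive random-walk MH -------------------------
            rss = _rss(st, alpha, beta)
            prop = s + step_s * rng.standard_normal((B, R))
            prop = np.clip(prop, _LOGSIG_MIN, _LOGSIG_MAX)
            dlog = (-n * (prop - s)
                    - rss / 2 * (np.exp(-2 * prop) - np.exp(-2 * s))
                    - ((prop - mu[2]) ** 2 - (s - mu[2]) ** 2) / (2 * tau2[2]))
            acc = np.log(rng.uniform(size=(B, R))) < dlog
            s = np.where(acc, prop, s)
            if warm:
                step_s *= np.exp(gamma * (acc - cfg.target_accept))

            if cfg.sample_hypers:
                # translation move for the noise hierarchy
                d = step_shift[2] * rng.standard_normal(R)
                dlog = (-n * d - rss / 2
                        * (np.exp(-2 * (s + d)) - np.exp(-2 * s))).sum(0)
                dlog += (-((mu[2] + d - pri.mu_loc[2]) ** 2
                           - (mu[2] - pri.mu_loc[2]) ** 2)
                         / (2 * pri.mu_scale[2] ** 2))
                acc = np.log(rng.uniform(size=R)) < dlog
                s = s + acc * d
                mu[2] = mu[2] + acc * d
                if warm:
                    step_shift[2] *= np.exp(gamma * (acc - cfg.target_accept))

                # --- noise hierarchy (mu_s, tau_s): centered Gibbs + MH -------
                tau2s = np.exp(2 * logtau[2])
                prec = B / tau2s + 1.0 / pri.mu_scale[2] ** 2
                mean = ((s.sum(0) / tau2s
                         + pri.mu_loc[2] / pri.mu_scale[2] ** 2) / prec)
                mu[2] = mean + rng.standard_normal(R) / np.sqrt(prec)

                ss_dev = ((s - mu[2]) ** 2).sum(0)
                for _ in range(3):
                    t = logtau[2]
                    prop_t = np.clip(t + step_tau[2] * rng.standard_normal(R),
                                     _LOGTAU_MIN, _LOGTAU_MAX)
                    dlog = (-B * (prop_t - t)
                            - ss_dev / 2 * (np.exp(-2 * prop_t) - np.exp(-2 * t))
                            + tau_logprior(np.exp(prop_t), 2)
                            - tau_logprior(np.exp(t), 2)
                            + (prop_t - t))  # Jacobian of tau = exp(t)
                    acc = np.log(rng.uniform(size=R)) < dlog
                    logtau[2] = np.where(acc, prop_t, t)
                    if warm:
                        step_tau[2] *= np.exp(gamma * (acc - cfg.target_accept))

                # non-centered rescale move for the noise hierarchy (funnel)
                t = logtau[2]
                prop_t = np.clip(t + step_resc[2] * rng.standard_normal(R),
                                 _LOGTAU_MIN, _LOGTAU_MAX)
                fac = np.exp(prop_t - t)
                new = np.clip(mu[2] + (s - mu[2]) * fac,
                              _LOGSIG_MIN, _LOGSIG_MAX)
                dlog = (-n * (new - s) - rss / 2
                        * (np.exp(-2 * new) - np.exp(-2 * s))).sum(0)
                dlog += (tau_logprior(np.exp(prop_t), 2)
                         - tau_logprior(np.exp(t), 2) + (prop_t - t))
                acc = np.log(rng.uniform(size=R)) < dlog
                s = np.where(acc, new, s)
                logtau[2] = np.where(acc, prop_t, t)
                if warm:
                    step_resc[2] *= np.exp(gamma * (acc - cfg.target_accept))

        if not warm:
            k = it - cfg.warmup
            out["alpha"][k] = alpha
            out["beta"][k] = beta
            out["logsigma"][k] = s
            out["mu"][k] = mu
            out["tau"][k] = np.exp(logtau)
    return out


def _split_rhat(x: np.ndarray) -> np.ndarray:
    """Split-chain rank-normalized R-hat over (chain, draw) axes of ``x``."""
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.asarray(az.rhat(az.convert_to_dataset(x))["x"])
    return np.nan_to_num(r, nan=1.0)  # constant chains: treat as converged


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class BatchSummary:
    """Posterior summaries per batch, sufficient for Gaussian prediction.

    Arrays over batches: posterior means of alpha/beta, the 2x2 posterior
    covariance of (alpha, beta), and the posterior mean of sigma^2.
    """

    mean_alpha: np.ndarray
    mean_beta: np.ndarray
    var_alpha: np.ndarray
    var_beta: np.ndarray
    cov_ab: np.ndarray
    mean_sigma2: np.ndarray

    def to_dict(self):
        return {k: getattr(self, k).tolist() for k in (
            "mean_alpha", "mean_beta", "var_alpha", "var_beta",
            "cov_ab", "mean_sigma2")}

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class ROIPosterior:
    """Per-ROI fit results: batch summaries, hyperposterior, diagnostics."""

    batch: BatchSummary
    hyper_mean: dict[str, float]
    hyper_sd: dict[str, float]
    rhat_max: float
    converged: bool

    def to_dict(self):
        return {
            "batch": self.batch.to_dict(),
            "hyper_mean": self.hyper_mean,
            "hyper_sd": self.hyper_sd,
            "rhat_max": self.rhat_max,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(batch=BatchSummary.from_dict(d["batch"]),
                   hyper_mean={k: float(v) for k, v in d["hyper_mean"].items()},
                   hyper_sd={k: float(v) for k, v in d["hyper_sd"].items()},
                   rhat_max=float(d["rhat_max"]),
                   converged=bool(d["converged"]))


class NormativeModel:
    """A fitted normative model over one or more ROIs.

    ``batch_by`` names the cohort column that, crossed with sex, defines the
    batch key (``"site"`` for reference fits; adapted models may add
    wave- or scanner-keyed batches on top).
    """

    kind = "reference"

    def __init__(self, transform: CovariateTransform, batch_by: str,
                 batches: list[str], rois: list[str],
                 roi_posteriors: dict[str, ROIPosterior],
                 predictive: str = "full"):
        self.transform = transform
        self.batch_by = batch_by
        self.batches = list(batches)
        self._batch_index = {b: i for i, b in enumerate(self.batches)}
        self.rois = list(rois)
        self.roi_posteriors = roi_posteriors
        self.predictive = predictive
        self.draws: dict[str, dict[str, np.ndarray]] | None = None

    @property
    def converged(self) -> bool:
        return all(p.converged for p in self.roi_posteriors.values())

    def batch_index(self, key: str) -> int:
        try:
            return self._batch_index[key]
        except KeyError:
            raise UnknownBatchError(
                f"batch {key!r} unknown to this model; adapt the model to "
                f"the new site first (hbrnorm.transfer.adapt)") from None

    def resolve_batch_keys(self, cohort: pd.DataFrame) -> pd.Series:
        """Map each cohort row to a model batch key, trying ``batch_by``
        first and falling back to the site column for mixed cohorts."""
        cols = [self.batch_by] + [c for c in ("site", "scanner", "wave")
                                  if c != self.batch_by]
        keys = pd.Series([""] * len(cohort), index=cohort.index, dtype=object)
        resolved = np.zeros(len(cohort), dtype=bool)
        for col in cols:
            if col not in cohort.columns:
                continue
            cand = cohort[col].astype(str) + "|" + cohort["sex"].astype(str)
            ok = cand.isin(self._batch_index) & ~resolved
            keys[ok] = cand[ok]
            resolved |= ok.to_numpy()
        if not resolved.all():
            bad = cohort.loc[~resolved]
            raise UnknownBatchError(
                f"{(~resolved).sum()} rows in unknown batches, e.g. "
                f"{bad.iloc[0][self.batch_by if self.batch_by in bad else 'site']!r}; "
                f"adapt the model to the new site first")
        return keys

    def predict_arrays(self, roi: str, batch_keys, ages,
                       predictive: str | None = None):
        """Vectorized predictive mean and SD for one ROI."""
        mode = predictive or self.predictive
        post = self.roi_posteriors[roi].batch
        idx = np.array([self.batch_index(k) for k in batch_keys])
        x = self.transform.apply(ages)
        mean = post.mean_alpha[idx] + post.mean_beta[idx] * x
        var = post.mean_sigma2[idx]
        if mode == "full":
            var = (var + post.var_alpha[idx] + x ** 2 * post.var_beta[idx]
                   + 2 * x * post.cov_ab[idx])
        return mean, np.sqrt(np.maximum(var, 1e-300))


class ReferenceModel(NormativeModel):
    kind = "reference"


def _validate_fit_inputs(cohort: pd.DataFrame, rois: list[str],
                         batch_by: str) -> None:
    for col in (batch_by, "sex", "age"):
        if col not in cohort.columns:
            raise ModelValidationError(f"cohort lacks column {col!r}")
    for roi in rois:
        col = f"roi_{roi}"
        if col not in cohort.columns:
            raise ModelValidationError(f"cohort lacks ROI column {col!r}")
        vals = pd.to_numeric(cohort[col], errors="coerce")
        if vals.isna().any():
            raise ModelValidationError(
                f"missing/non-numeric thickness in {col!r}; only complete "
                f"ROI data can be modelled")
    keys = cohort[batch_by].astype(str) + "|" + cohort["sex"].astype(str)
    counts = keys.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ModelValidationError(
            f"batches with fewer than 3 observations: "
            f"{dict(small.astype(int))}")
    return None


def fit_rois(cohort: pd.DataFrame, rois: list[str],
             priors: list[PriorSpec] | PriorSpec | None = None,
             sampler_config: SamplerConfig | None = None,
             batch_by: str = "site",
             transform: CovariateTransform | None = None,
             require_multiple_batches: bool = True,
             keep_draws: bool = True) -> ReferenceModel:
    """Fit the HBR model jointly-vectorized over the listed ROIs.

    ROIs are statistically independent; vectorizing simply shares the
    sampler loop.  ``priors`` may be one spec (shared) or one per ROI.
    """
    cfg = sampler_config or SamplerConfig()
    _validate_fit_inputs(cohort, rois, batch_by)
    keys = (cohort[batch_by].astype(str) + "|"
            + cohort["sex"].astype(str)).to_numpy()
    batches = sorted(set(keys))
    if require_multiple_batches and len(batches) < 2:
        raise ModelValidationError(
            "need >= 2 batches to identify the hierarchy; got "
            f"{batches}")
    bidx = np.array([batches.index(k) for k in keys])
    y = cohort[[f"roi_{r}" for r in rois]].to_numpy(dtype=float)
    tr = transform or CovariateTransform.fit(cohort["age"])
    x = tr.apply(cohort["age"])

    if priors is None:
        specs = [default_priors(y[:, r]) for r in range(len(rois))]
    elif isinstance(priors, PriorSpec):
        specs = [priors] * len(rois)
    else:
        specs = list(priors)
        if len(specs) != len(rois):
            raise ModelValidationError("one PriorSpec per ROI required")
    pri = _PriorArrays.from_specs(specs)

    st = _suff_stats(y, x, bidx, len(batches))
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    chains = [_run_chain(st, pri, cfg, np.random.default_rng(ss))
              for ss in seeds]
    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    return _summarize_fit(draws, tr, batch_by, batches, rois, cfg,
                          keep_draws=keep_draws)


def _summarize_fit(draws, tr, batch_by, batches, rois, cfg,
                   keep_draws=True) -> ReferenceModel:
    R = len(rois)
    rhats = {k: _split_rhat(v) for k, v in draws.items()}
    roi_posteriors = {}
    for r, roi in enumerate(rois):
        a = draws["alpha"][..., r].reshape(-1, len(batches))
        b = draws["beta"][..., r].reshape(-1, len(batches))
        s2 = np.exp(2 * draws["logsigma"][..., r]).reshape(-1, len(batches))
        batch = BatchSummary(
            mean_alpha=a.mean(0), mean_beta=b.mean(0),
            var_alpha=a.var(0), var_beta=b.var(0),
            cov_ab=((a - a.mean(0)) * (b - b.mean(0))).mean(0),
            mean_sigma2=s2.mean(0),
        )
        hyper_mean, hyper_sd = {}, {}
        for g, (mname, tname) in enumerate(
                [("mu_alpha", "tau_alpha"), ("mu_beta", "tau_beta"),
                 ("mu_logsigma", "tau_logsigma")]):
            mdraws = draws["mu"][:, :, g, r].ravel()
            tdraws = draws["tau"][:, :, g, r].ravel()
            for name, dd in ((mname, mdraws), (tname, tdraws)):
                m = float(dd.mean())
                sd = float(dd.std())
                floor = max(1e-6 * abs(m), 1e-8)
                hyper_mean[name] = m
                hyper_sd[name] = max(sd, floor)
        rhat_max = float(max(
            rhats["alpha"][..., r].max(), rhats["beta"][..., r].max(),
            rhats["logsigma"][..., r].max(),
            rhats["mu"][:, r].max() if cfg.sample_hypers else 1.0,
            rhats["tau"][:, r].max() if cfg.sample_hypers else 1.0,
        ))
        converged = bool(rhat_max < cfg.rhat_threshold)
        if not converged:
            warnings.warn(
                f"ROI {roi!r}: split R-hat {rhat_max:.3f} exceeds "
                f"{cfg.rhat_threshold}; treat results with caution",
                RuntimeWarning, stacklevel=2)
        roi_posteriors[roi] = ROIPosterior(batch, hyper_mean, hyper_sd,
                                           rhat_max, converged)
    model = ReferenceModel(tr, batch_by, batches, rois, roi_posteriors)
    if keep_draws:
        model.draws = draws
    return model


def fit_reference(cohort: pd.DataFrame, roi: str,
                  priors: PriorSpec | None = None,
                  sampler_config: SamplerConfig | None = None,
                  **kwargs) -> ReferenceModel:
    """Fit the reference HBR normative model for a single ROI."""
    return fit_rois(cohort, [roi], priors=priors,
                    sampler_config=sampler_config, **kwargs)


def predict(model: NormativeModel, age, sex: str, site: str, roi: str,
            predictive: str | None = None) -> tuple[float, float]:
    """Predictive mean (mm) and SD (mm) for one scan.

    The predictive SD combines the posterior variance of the regression line
    with the posterior mean noise variance (``predictive="full"``, default)
    or uses the noise alone (``predictive="noise"``).
    """
    key = f"{site}|{sex}"
    model.batch_index(key)  # raises UnknownBatchError with guidance
    scalar = np.isscalar(age)
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    mean, sd = model.predict_arrays(roi, [key] * len(ages), ages,
                                    predictive=predictive)
    if scalar:
        return float(mean[0]), float(sd[0])
    return mean, sd


def summarize_hyperposterior(model: NormativeModel) -> pd.DataFrame:
    """Posterior mean and SD of each hyperparameter, per ROI.

    These are the quantities transferred to a new site as informed priors.
    SDs are floored (1e-6 of the mean scale) so downstream priors are proper.
    """
    if not model.rois:
        raise ModelValidationError("model has no fitted ROIs")
    if not model.converged:
        warnings.warn("summarizing a non-converged model", RuntimeWarning,
                      stacklevel=2)
    rows = []
    for roi in model.rois:
        post = model.roi_posteriors[roi]
        if not post.hyper_mean:
            raise ModelValidationError(f"ROI {roi!r} has no hyperposterior")
        row = {"roi": roi}
        for name in HYPER_NAMES:
            row[f"{name}_mean"] = post.hyper_mean[name]
            row[f"{name}_sd"] = post.hyper_sd[name]
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi")
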