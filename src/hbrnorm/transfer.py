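"""Transfer of a reference normative model to unseen batches.

The reference model's hyperparameter posterior (mean and SD per
hyperparameter, per ROI) is re-expressed as informed priors — Normal for
the mu's, zero-truncated Normal for the tau's — under which the batch
parameters of a new scanner or measurement wave are learned from a small
adaptation set.  Hyperparameters are re-sampled jointly with the new batch
parameters under those informed priors, so their uncertainty propagates into
the adapted posterior; a frozen point-estimate mode is available for
comparison.  Approximating the hyperposterior by independent (truncated)
Gaussians is what makes the transfer portable: only twelve numbers per ROI
cross the site boundary, never subject-level data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hbr import (
    HYPER_NAMES,
    ModelValidationError,
    NormalPrior,
    NormativeModel,
    BatchSummary,
    PriorSpec,
    ROIPosterior,
    ReferenceModel,
    SamplerConfig,
    TruncNormalPrior,
    fit_rois,
    summarize_hyperposterior,
)

__all__ = [
    "AdaptationSet",
    "AdaptedModel",
    "AdaptationError",
    "build_transfer_priors",
    "sample_adaptation_set",
    "split_validation_rows",
    "adapt",
]

BATCH_DEFINITIONS = {"per_wave": "wave", "per_scanner": "scanner"}


class AdaptationError(ValueError):
    pass


@dataclass
class AdaptationSet:
    """A small holdout subset of the target cohort used for recalibration.

    Disjoint (by row id) from both the evaluation remainder and the withheld
    validation rows (all-three-wave subjects; wave-1 scans in the overlap
    age window), which must never inform the adaptation.
    """

    table: pd.DataFrame
    batch_by: str
    strategy: str
    seed: int
    withheld: pd.DataFrame = field(repr=False, default=None)

    @property
    def row_ids(self) -> set[int]:
        return set(self.table["row_id"].tolist())

    @property
    def counts(self) -> dict[str, int]:
        keys = (self.table[self.batch_by].astype(str) + "|"
                + self.table["sex"].astype(str))
        return keys.value_counts().to_dict()


class AdaptedModel(NormativeModel):
    """Reference model extended with posteriors for new, transferred batches."""

    kind = "adapted"

    def __init__(self, *args, reference_batches=None, new_batches=None,
                 transfer_priors=None, batch_definition="per_wave",
                 source_hash=None, **kwargs):
        super().__init__(*args, **kwargs)
        self.reference_batches = list(reference_batches or [])
        self.new_batches = list(new_batches or [])
        self.transfer_priors = transfer_priors
        self.batch_definition = batch_definition
        self.source_hash = source_hash


def build_transfer_priors(summary: pd.DataFrame) -> dict[str, PriorSpec]:
    """Turn a hyperposterior summary into informed priors, one per ROI.

    Location hyperparameters become Normal(posterior mean, posterior SD);
    scale hyperparameters become the same Normal truncated below at zero.
    """
    specs: dict[str, PriorSpec] = {}
    for roi, row in summary.iterrows():
        kwargs = {}
        for name in HYPER_NAMES:
            mcol, scol = f"{name}_mean", f"{name}_sd"
            if mcol not in row.index or scol not in row.index:
                raise ModelValidationError(
                    f"hyperposterior summary lacks {name!r}")
            loc, sd = float(row[mcol]), float(row[scol])
            if name.startswith("tau"):
                kwargs[name] = TruncNormalPrior(loc, sd)
            else:
                kwargs[name] = NormalPrior(loc, sd)
        specs[str(roi)] = PriorSpec(**kwargs)
    return specs


def split_validation_rows(
        cohort: pd.DataFrame,
        overlap_window: tuple[float, float] = (8.6, 10.7),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate the validation rows the adaptation must never see.

    Withheld: all scans of subjects measured in all three waves, plus wave-1
    scans inside the overlapping age window of waves 1 and 2.  Returns
    ``(withheld, rest)``.
    """
    if "wave" in cohort.columns and cohort["wave"].notna().any():
        n_waves = cohort.groupby("subject_id")["wave"].nunique()
        long_subjects = set(n_waves[n_waves >= 3].index)
    else:
        long_subjects = set()
    lo, hi = overlap_window
    is_long = cohort["subject_id"].isin(long_subjects)
    in_overlap_w1 = (cohort.get("wave") == "wave1") & \
        cohort["age"].between(lo, hi)
    withheld_mask = is_long | in_overlap_w1
    return cohort[withheld_mask].copy(), cohort[~withheld_mask].copy()


def sample_adaptation_set(
        cohort: pd.DataFrame,
        n_per_batch: int,
        strategy: str = "random",
        seed: int = 0,
        batch_by: str = "wave",
        overlap_window: tuple[float, float] = (8.6, 10.7),
        pool: pd.DataFrame | None = None,
) -> tuple[AdaptationSet, pd.DataFrame]:
    """Draw an adaptation sample per batch and return it with the remainder.

    Validation rows (see :func:`split_validation_rows`) are excluded before
    sampling and also removed from the remainder; they stay available on the
    returned set's ``withheld`` attribute.  ``strategy="age_uniform"``
    stratifies each batch's age range into ``n_per_batch`` equal-width bins
    and draws one scan per nonempty bin (shortfall filled at random), the
    pseudorandom scheme that secures uniform age coverage when a wave's age
    distribution is narrow and peaked.  ``pool`` optionally restricts the
    rows eligible for adaptation (the remainder is still everything not
    sampled and not withheld).
    """
    if strategy not in ("random", "age_uniform"):
        raise AdaptationError(f"unknown strategy {strategy!r}")
    if batch_by not in cohort.columns:
        raise AdaptationError(f"cohort lacks batch column {batch_by!r}")
    rng = np.random.default_rng(seed)
    withheld, eligible = split_validation_rows(cohort, overlap_window)
    frame = eligible if pool is None else \
        eligible[eligible["row_id"].isin(pool["row_id"])]
    keys = frame[batch_by].astype(str) + "|" + frame["sex"].astype(str)
    chosen: list[pd.Index] = []
    for key in sorted(keys.unique()):
        grp = frame[keys == key]
        if len(grp) < n_per_batch:
            raise AdaptationError(
                f"batch {key!r} has only {len(grp)} eligible rows; "
                f"{n_per_batch} requested")
        if strategy == "random":
            idx = rng.choice(grp.index, size=n_per_batch, replace=False)
        else:
            ages = grp["age"].to_numpy()
            edges = np.linspace(ages.min(), ages.max(), n_per_batch + 1)
            bins = np.clip(np.searchsorted(edges, ages, side="right") - 1,
                           0, n_per_batch - 1)
            idx_list = []
            for b in range(n_per_batch):
                members = grp.index[bins == b]
                if len(members):
                    idx_list.append(rng.choice(members))
            short = n_per_batch - len(idx_list)
            if short > 0:
                unused = grp.index.difference(pd.Index(idx_list))
                idx_list.extend(rng.choice(unused, size=short, replace=False))
            idx = np.array(idx_list)
        chosen.append(pd.Index(idx))
    sel = pd.Index(np.concatenate([c.to_numpy() for c in chosen]))
    adaptation = cohort.loc[sel].copy()
    remainder = eligible.drop(index=sel).copy()
    aset = AdaptationSet(adaptation, batch_by=batch_by, strategy=strategy,
                         seed=seed, withheld=withheld)
    return aset, remainder


def _trunc_moments(prior: TruncNormalPrior) -> tuple[float, float]:
    a = (prior.lower - prior.loc) / prior.scale
    d = stats.truncnorm(a, np.inf, loc=prior.loc, scale=prior.scale)
    return float(d.mean()), float(d.var())


def _prior_only_posterior(spec: PriorSpec, n_draws: int,
                          rng: np.random.Generator) -> ROIPosterior:
    """No-data limit: the batch 'posterior' is the hierarchical prior.

    Predictive means are set exactly to the hyperprior means; the dispersion
    terms are Monte-Carlo estimates over the prior hierarchy.
    """
    def tdraw(p: TruncNormalPrior, size):
        a = (p.lower - p.loc) / p.scale
        return stats.truncnorm(a, np.inf, loc=p.loc, scale=p.scale).rvs(
            size=size, random_state=rng)

    mu_a = rng.normal(spec.mu_alpha.loc, spec.mu_alpha.scale, n_draws)
    mu_b = rng.normal(spec.mu_beta.loc, spec.mu_beta.scale, n_draws)
    mu_s = rng.normal(spec.mu_logsigma.loc, spec.mu_logsigma.scale, n_draws)
    ta = tdraw(spec.tau_alpha, n_draws)
    tb = tdraw(spec.tau_beta, n_draws)
    ts = tdraw(spec.tau_logsigma, n_draws)
    alpha = mu_a + ta * rng.standard_normal(n_draws)
    beta = mu_b + tb * rng.standard_normal(n_draws)
    lsig = mu_s + ts * rng.standard_normal(n_draws)
    batch = BatchSummary(
        mean_alpha=np.array([spec.mu_alpha.loc]),
        mean_beta=np.array([spec.mu_beta.loc]),
        var_alpha=np.array([alpha.var()]),
        var_beta=np.array([beta.var()]),
        cov_ab=np.array([0.0]),
        mean_sigma2=np.array([float(np.exp(2 * lsig).mean())]),
    )
    hyper_mean = {"mu_alpha": spec.mu_alpha.loc, "mu_beta": spec.mu_beta.loc,
                  "mu_logsigma": spec.mu_logsigma.loc,
                  "tau_alpha": _trunc_moments(spec.tau_alpha)[0],
                  "tau_beta": _trunc_moments(spec.tau_beta)[0],
                  "tau_logsigma": _trunc_moments(spec.tau_logsigma)[0]}
    hyper_sd = {"mu_alpha": spec.mu_alpha.scale,
                "mu_beta": spec.mu_beta.scale,
                "mu_logsigma": spec.mu_logsigma.scale,
                "tau_alpha": np.sqrt(_trunc_moments(spec.tau_alpha)[1]),
                "tau_beta": np.sqrt(_trunc_moments(spec.tau_beta)[1]),
                "tau_logsigma": np.sqrt(_trunc_moments(spec.tau_logsigma)[1])}
    return ROIPosterior(batch, hyper_mean, hyper_sd, rhat_max=1.0,
                        converged=True)


def model_hash(model: NormativeModel) -> str:
    """Deterministic digest of a model's serializable state."""
    payload = {
        "transform": [model.transform.center, model.transform.scale],
        "batch_by": model.batch_by,
        "batches": model.batches,
        "rois": model.rois,
        "posteriors": {roi: model.roi_posteriors[roi].to_dict()
                       for roi in model.rois},
    }
    text = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def adapt(reference: ReferenceModel,
          adaptation: AdaptationSet | None,
          batch_definition: str = "per_wave",
          sampler_config: SamplerConfig | None = None,
          prior_only: bool = False,
          frozen_hypers: bool = False,
          new_batches: list[str] | None = None) -> AdaptedModel:
    """Fit new-batch parameters under informed priors from the reference.

    ``batch_definition`` controls how target batches are keyed: each
    measurement wave as its own batch (``per_wave``, the default — robust to
    software upgrades between waves on the same scanner) or each physical
    scanner (``per_scanner``).  Reference batches are carried over untouched.
    ``prior_only`` builds an adapted model from the transfer priors alone
    (requires ``new_batches``); predictions then revert to hyperprior means.
    """
    if batch_definition not in BATCH_DEFINITIONS:
        raise AdaptationError(
            f"batch_definition must be one of {sorted(BATCH_DEFINITIONS)}")
    batch_by = BATCH_DEFINITIONS[batch_definition]
    if not reference.converged:
        import warnings
        warnings.warn("adapting from a non-converged reference model",
                      RuntimeWarning, stacklevel=2)
    summary = summarize_hyperposterior(reference)
    priors = build_transfer_priors(summary)
    specs = [priors[roi] for roi in reference.rois]
    cfg = sampler_config or SamplerConfig()
    source = model_hash(reference)

    if prior_only:
        if adaptation is not None and len(adaptation.table):
            raise AdaptationError(
                "prior_only mode takes no adaptation data")
        if not new_batches:
            raise AdaptationError("prior_only mode needs new_batches keys")
        rng = np.random.default_rng(cfg.seed)
        keys = list(new_batches)
        roi_posteriors = {}
        for roi, spec in zip(reference.rois, specs):
            p = _prior_only_posterior(spec, 4000, rng)
            batch = BatchSummary(**{
                k: np.repeat(getattr(p.batch, k), len(keys))
                for k in ("mean_alpha", "mean_beta", "var_alpha", "var_beta",
                          "cov_ab", "mean_sigma2")})
            roi_posteriors[roi] = ROIPosterior(batch, p.hyper_mean,
                                               p.hyper_sd, 1.0, True)
        new_model = None
    else:
        if adaptation is None or not len(adaptation.table):
            raise AdaptationError(
                "adaptation set is empty; use prior_only=True for the "
                "no-data limit")
        table = adaptation.table
        if batch_by not in table.columns:
            raise AdaptationError(f"adaptation rows lack {batch_by!r}")
        keys_ser = (table[batch_by].astype(str) + "|"
                    + table["sex"].astype(str))
        keys = sorted(keys_ser.unique())
        collisions = set(keys) & set(reference.batches)
        if collisions:
            raise AdaptationError(
                f"adaptation batches collide with reference batches: "
                f"{sorted(collisions)}")
        fit_cfg = SamplerConfig(
            chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup,
            seed=cfg.seed, sample_hypers=not frozen_hypers,
            rhat_threshold=cfg.rhat_threshold,
            target_accept=cfg.target_accept)
        new_model = fit_rois(
            table, reference.rois, priors=specs, sampler_config=fit_cfg,
            batch_by=batch_by, transform=reference.transform,
            require_multiple_batches=False)
        keys = new_model.batches
        roi_posteriors = new_model.roi_posteriors

    merged_batches = reference.batches + [k for k in keys
                                          if k not in reference.batches]
    merged = {}
    for roi in reference.rois:
        ref_post = reference.roi_posteriors[roi]
        new_post = roi_posteriors[roi]
        batch = BatchSummary(**{
            k: np.concatenate([getattr(ref_post.batch, k),
                               getattr(new_post.batch, k)])
            for k in ("mean_alpha", "mean_beta", "var_alpha", "var_beta",
                      "cov_ab", "mean_sigma2")})
        merged[roi] = ROIPosterior(
            batch, new_post.hyper_mean, new_post.hyper_sd,
            max(ref_post.rhat_max, new_post.rhat_max),
            ref_post.converged and new_post.converged)

    model = AdaptedModel(
        reference.transform, batch_by, merged_batches, reference.rois,
        merged, predictive=reference.predictive,
        reference_batches=reference.batches, new_batches=list(keys),
        transfer_priors=priors, batch_definition=batch_definition,
        source_hash=source)
    if new_model is not None:
        model.draws = new_model.draws
    return model
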