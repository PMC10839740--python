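"""Model evaluation metrics, the adaptation-size sweep, and validation checks.

Metrics follow the conventions of normative-modelling toolkits, all with
population (1/n) moments:

* explained variance  EV   = 1 - Var(y - yhat) / Var(y)
* standardized MSE    SMSE = mean((y - yhat)^2) / Var(y)   (1 = trivial mean)
* mean standardized log loss
                      MSLL = mean Gaussian NLPD under the model minus that
                             of a trivial Gaussian fitted to the training
                             (adaptation) targets; negative is better.

The validation procedures mirror a longitudinal multi-scanner study design:
within-subject stability of z across waves, the raw-vs-z comparison in the
age window where two scanners overlap, and the wave-as-batch vs
scanner-as-batch adaptation comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .hbr import NormativeModel, ReferenceModel, SamplerConfig
from .deviation import compute_zscores
from .transfer import (
    AdaptationError,
    adapt,
    sample_adaptation_set,
    split_validation_rows,
)

__all__ = [
    "LeakageError",
    "explained_variance",
    "smse",
    "msll",
    "evaluate",
    "sweep_adaptation_size",
    "plateau_size",
    "first_negative_msll_size",
    "within_subject_stability",
    "overlap_range_comparison",
    "batch_config_comparison",
    "area_metric_correlation",
    "DEFAULT_SWEEP_GRID",
]

DEFAULT_SWEEP_GRID = (5, 10, 15, 25, 50, 75, 100, 150, 200, 300)


class LeakageError(ValueError):
    """Evaluation rows overlap rows the model was adapted on."""


def _check(y, pred_mean):
    y = np.asarray(y, dtype=float)
    pred_mean = np.asarray(pred_mean, dtype=float)
    if y.shape != pred_mean.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("need 1-d y and pred_mean of equal length >= 2")
    v = y.var()
    if v <= 0:
        warnings.warn("zero target variance; metric undefined",
                      RuntimeWarning, stacklevel=3)
        return y, pred_mean, np.nan
    return y, pred_mean, v


def explained_variance(y, pred_mean) -> float:
    y, pred_mean, v = _check(y, pred_mean)
    if np.isnan(v):
        return np.nan
    return float(1.0 - (y - pred_mean).var() / v)


def smse(y, pred_mean) -> float:
    y, pred_mean, v = _check(y, pred_mean)
    if np.isnan(v):
        return np.nan
    return float(np.mean((y - pred_mean) ** 2) / v)


def msll(y, pred_mean, pred_sd, baseline_mean: float,
         baseline_sd: float) -> float:
    y = np.asarray(y, dtype=float)
    pred_mean = np.asarray(pred_mean, dtype=float)
    pred_sd = np.asarray(pred_sd, dtype=float)
    if np.any(pred_sd <= 0) or baseline_sd <= 0:
        raise ValueError("predictive and baseline SDs must be > 0")
    nlpd = (0.5 * np.log(2 * np.pi * pred_sd ** 2)
            + (y - pred_mean) ** 2 / (2 * pred_sd ** 2))
    base = (0.5 * np.log(2 * np.pi * baseline_sd ** 2)
            + (y - baseline_mean) ** 2 / (2 * baseline_sd ** 2))
    return float(np.mean(nlpd - base))


def evaluate(model: NormativeModel, test: pd.DataFrame,
             baseline_source: pd.DataFrame,
             predictive: str | None = None) -> pd.DataFrame:
    """Per-ROI EV/SMSE/MSLL on held-out rows, with an across-ROI mean row.

    ``baseline_source`` supplies the trivial-predictor baseline for MSLL
    (the adaptation/training targets of the same ROI — never the test
    targets).  Raises :class:`LeakageError` if test rows overlap it.
    """
    if "row_id" in test.columns and "row_id" in baseline_source.columns:
        overlap = set(test["row_id"]) & set(baseline_source["row_id"])
        if overlap:
            raise LeakageError(
                f"{len(overlap)} rows are in both the test set and the "
                f"baseline/adaptation source")
    dev = compute_zscores(model, test, predictive=predictive)
    rows = []
    for roi in model.rois:
        y = test[f"roi_{roi}"].to_numpy(dtype=float)
        mean = dev[f"mu_{roi}"].to_numpy()
        sd = dev[f"sd_{roi}"].to_numpy()
        base_y = baseline_source[f"roi_{roi}"].to_numpy(dtype=float)
        rows.append({
            "roi": roi,
            "ev": explained_variance(y, mean),
            "smse": smse(y, mean),
            "msll": msll(y, mean, sd, float(base_y.mean()),
                         float(base_y.std())),
            "n_test": len(y),
        })
    report = pd.DataFrame(rows).set_index("roi")
    agg = report[["ev", "smse", "msll"]].agg(["mean", "std"])
    mean_row = {"ev": agg.loc["mean", "ev"], "smse": agg.loc["mean", "smse"],
                "msll": agg.loc["mean", "msll"], "n_test": len(test)}
    report.loc["mean"] = mean_row
    report.attrs["roi_sd"] = agg.loc["std"].to_dict()
    return report


# ---------------------------------------------------------------------------
# adaptation-size sweep
# ---------------------------------------------------------------------------

def sweep_adaptation_size(
        reference: ReferenceModel,
        target: pd.DataFrame,
        sizes=DEFAULT_SWEEP_GRID,
        replicates: int = 10,
        strategy: str = "random",
        seed: int = 0,
        sampler_config: SamplerConfig | None = None,
        batch_definition: str = "per_wave",
        pool_margin: int = 100,
) -> pd.DataFrame:
    """Adapt at each sample size and evaluate on one common test remainder.

    A fixed adaptation *pool* (largest size plus ``pool_margin`` rows per
    batch, drawn once from the master seed) is reserved per batch; every
    replicate's adaptation set comes from that pool, so the test remainder
    is identical across all sizes and replicates.  Infeasible sizes are
    skipped with a warning.  Returns a tidy frame with one row per
    (size, replicate, ROI); ``roi == "mean"`` rows carry across-ROI means.
    """
    from .transfer import BATCH_DEFINITIONS
    batch_by = BATCH_DEFINITIONS[batch_definition]
    cfg = sampler_config or SamplerConfig(draws=500, warmup=500)
    rng = np.random.default_rng(seed)
    withheld, eligible = split_validation_rows(target)
    keys = eligible[batch_by].astype(str) + "|" + eligible["sex"].astype(str)
    max_size = max(sizes)
    pool_idx = []
    for key in sorted(keys.unique()):
        grp = eligible[keys == key]
        # reserve the pool but keep at least 1/3 of the batch for testing
        n_pool = min(max_size + pool_margin, (2 * len(grp)) // 3)
        pool_idx.append(rng.choice(grp.index, size=n_pool, replace=False))
    pool = eligible.loc[np.concatenate(pool_idx)]
    test = eligible.drop(index=pool.index)

    records = []
    for size in sizes:
        feasible = all(
            (keys[pool.index] == key).sum() > size
            for key in sorted(keys.unique()))
        if not feasible:
            warnings.warn(f"adaptation size {size} infeasible for at least "
                          f"one batch; skipped", RuntimeWarning, stacklevel=2)
            continue
        for rep in range(replicates):
            rep_seed = int(
                np.random.SeedSequence([seed, size, rep]).generate_state(1)[0]
                % (2 ** 31))
            aset, _ = sample_adaptation_set(
                target, size, strategy=strategy, seed=rep_seed,
                batch_by=batch_by, pool=pool)
            fit_cfg = SamplerConfig(
                chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup,
                seed=rep_seed, sample_hypers=cfg.sample_hypers,
                rhat_threshold=cfg.rhat_threshold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = adapt(reference, aset,
                              batch_definition=batch_definition,
                              sampler_config=fit_cfg)
                report = evaluate(model, test, aset.table)
            for roi, row in report.iterrows():
                records.append({
                    "n_per_batch": size, "replicate": rep, "seed": rep_seed,
                    "roi": roi, "ev": row["ev"], "smse": row["smse"],
                    "msll": row["msll"]})
    out = pd.DataFrame(records)
    out.attrs["n_test"] = len(test)
    return out


def _mean_msll_by_size(sweep: pd.DataFrame) -> pd.Series:
    mean_rows = sweep[sweep["roi"] == "mean"]
    return mean_rows.groupby("n_per_batch")["msll"].mean().sort_index()


def plateau_size(sweep: pd.DataFrame, tol: float = 0.01) -> int:
    """Smallest size whose mean MSLL is within ``tol`` nats of the largest
    swept size's mean (one-sided: being better than the largest size also
    counts as plateaued)."""
    m = _mean_msll_by_size(sweep)
    target = m.iloc[-1]
    ok = m[m <= target + tol]
    return int(ok.index[0])


def first_negative_msll_size(sweep: pd.DataFrame) -> int | None:
    """Smallest size at which mean MSLL beats the trivial predictor (< 0)."""
    m = _mean_msll_by_size(sweep)
    neg = m[m < 0]
    return int(neg.index[0]) if len(neg) else None


# ---------------------------------------------------------------------------
# validation procedures
# ---------------------------------------------------------------------------

def within_subject_stability(dev: pd.DataFrame,
                             raw: pd.DataFrame) -> tuple[pd.DataFrame,
                                                         pd.DataFrame]:
    """Within-subject spread of z across waves vs raw thickness change.

    For each subject measured in >= 2 waves and each ROI: the SD of z
    across that subject's waves, and the SD of raw thickness across waves
    divided by the cross-sectional raw SD.  Site-effect-free z-scores of the
    same child should sit in a similar range across waves even though raw
    thickness declines and switches scanner.  Returns (per-subject table,
    cohort-median summary).
    """
    rois = [c[2:] for c in dev.columns if c.startswith("z_")]
    counts = dev.groupby("subject_id")["wave"].nunique()
    keep = counts[counts >= 2].index
    if not len(keep):
        warnings.warn("no subjects with repeated measurements",
                      RuntimeWarning, stacklevel=2)
        return pd.DataFrame(), pd.DataFrame()
    dsub = dev[dev["subject_id"].isin(keep)]
    rsub = raw[raw["subject_id"].isin(keep)]
    rows = []
    for roi in rois:
        z_sd = dsub.groupby("subject_id")[f"z_{roi}"].std(ddof=0)
        y_sd = rsub.groupby("subject_id")[f"roi_{roi}"].std(ddof=0)
        cross_sd = raw[f"roi_{roi}"].std(ddof=0)
        for subject in z_sd.index:
            rows.append({"subject_id": subject, "roi": roi,
                         "z_sd": z_sd[subject],
                         "raw_sd_ratio": y_sd[subject] / cross_sd})
    per_subject = pd.DataFrame(rows)
    summary = per_subject.groupby("roi")[["z_sd", "raw_sd_ratio"]].median()
    summary.loc["median"] = per_subject[["z_sd", "raw_sd_ratio"]].median()
    return per_subject, summary


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    res = stats.ttest_ind(a, b, equal_var=True)  # pooled-variance Student t
    df = len(a) + len(b) - 2
    return float(res.statistic), df, float(res.pvalue)


def overlap_range_comparison(raw: pd.DataFrame, dev: pd.DataFrame,
                             window: tuple[float, float] = (8.6, 10.7),
                             batch_a: str = "wave1",
                             batch_b: str = "wave2") -> pd.DataFrame:
    """Raw-vs-z two-sample t-tests inside the scanner-overlap age window.

    Scans from two waves acquired on different scanners but at overlapping
    ages should differ in raw thickness (scanner effect) but not in z.
    Pooled-variance Student t with df = n1 + n2 - 2, per ROI.
    """
    lo, hi = window
    rois = [c[2:] for c in dev.columns if c.startswith("z_")]

    def side(frame, batch, col):
        m = (frame["wave"] == batch) & frame["age"].between(lo, hi)
        return frame.loc[m, col].to_numpy(dtype=float)

    rows = []
    for roi in rois:
        ra, rb = side(raw, batch_a, f"roi_{roi}"), side(raw, batch_b,
                                                        f"roi_{roi}")
        za, zb = side(dev, batch_a, f"z_{roi}"), side(dev, batch_b,
                                                      f"z_{roi}")
        if min(len(ra), len(rb), len(za), len(zb)) < 2:
            raise ValueError(
                f"fewer than 2 rows per side in the overlap window for "
                f"{roi!r}")
        t_raw, df, p_raw = _pooled_t(ra, rb)
        t_z, _, p_z = _pooled_t(za, zb)
        rows.append({"roi": roi, "df": df, "raw_t": t_raw, "raw_p": p_raw,
                     "z_t": t_z, "z_p": p_z})
    return pd.DataFrame(rows).set_index("roi")


def batch_config_comparison(
        reference: ReferenceModel, target: pd.DataFrame,
        configs=("per_wave", "per_scanner"), n_per_batch: int = 100,
        seed: int = 0,
        sampler_config: SamplerConfig | None = None) -> pd.DataFrame:
    """Compare per-wave median z under different batch definitions.

    Adapting with each wave as its own batch absorbs wave-specific shifts
    (e.g. a scanner software upgrade between waves on the same hardware);
    adapting per physical scanner cannot, which shows up as opposite-signed
    median-z offsets in the waves sharing a scanner.
    """
    from .transfer import BATCH_DEFINITIONS
    records = []
    for config in configs:
        batch_by = BATCH_DEFINITIONS[config]
        aset, remainder = sample_adaptation_set(
            target, n_per_batch, strategy="random", seed=seed,
            batch_by=batch_by)
        cfg = sampler_config or SamplerConfig(draws=500, warmup=500,
                                              seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = adapt(reference, aset, batch_definition=config,
                          sampler_config=cfg)
            dev = compute_zscores(model, target)
        for wave, grp in dev.groupby("wave"):
            for roi in reference.rois:
                records.append({
                    "config": config, "wave": wave, "roi": roi,
                    "median_z": float(grp[f"z_{roi}"].median()),
                    "n": len(grp)})
    return pd.DataFrame(records)


def area_metric_correlation(report: pd.DataFrame,
                            areas: pd.Series | dict) -> pd.DataFrame:
    """Pearson correlation of ROI area with each evaluation metric.

    Larger parcels average over more vertices and are measured with less
    noise, so they tend to be predicted better.
    """
    areas = pd.Series(areas)
    rois = [r for r in report.index if r in areas.index]
    if len(rois) < 3:
        raise ValueError("need >= 3 ROIs with areas")
    rows = []
    for metric in ("ev", "smse", "msll"):
        vals = report.loc[rois, metric].to_numpy(dtype=float)
        if np.allclose(vals, vals[0]):
            warnings.warn(f"metric {metric} constant across ROIs; "
                          f"correlation undefined", RuntimeWarning,
                          stacklevel=2)
            rows.append({"metric": metric, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(areas[rois].to_numpy(dtype=float), vals)
        rows.append({"metric": metric, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("metric")
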