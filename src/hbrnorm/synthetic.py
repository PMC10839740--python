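"""Synthetic multi-site cortical-thickness cohorts with known ground truth.

The generator emulates the data situation of a lifespan reference collection
(many scanners, heterogeneous age windows covering roughly 5-100 years)
plus a narrow-age-range longitudinal target study: three measurement waves
acquired on two scanners, an overlapping age window between waves 1 and 2,
repeated-measure subjects across all waves, and a preterm-born subgroup with
ROI-specific mean shifts.

Every batch (site x sex, or wave x sex for the target) gets its own true
intercept, age slope and residual SD drawn from shared hyperdistributions,
which is exactly the generative structure the hierarchical Bayesian
regression model assumes -- except for a subject-level random intercept
``u_j`` that the fitted model deliberately omits (its variance is absorbed
into the batch noise, which is what makes within-subject deviation scores
stable across waves).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "TruthRecord",
    "default_roi_names",
    "generate_reference",
    "generate_target",
    "true_zscores",
]

SEX_LEVELS = ("F", "M")


class ConfigError(ValueError):
    """Raised when a generator configuration violates an invariant."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def default_roi_names(n: int) -> list[str]:
    base = [
        "s_front_inf", "s_temp_sup", "g_precentral", "s_calcarine",
        "g_front_sup", "s_intrapariet", "g_temp_mid", "s_orbital",
        "g_cingul_ant", "s_collat_ant",
    ]
    if n <= len(base):
        return base[:n]
    return base + [f"roi{i:02d}" for i in range(len(base), n)]


@dataclass
class WaveSpec:
    wave: str
    scanner: str
    age_range: tuple[float, float]
    n_subjects: int


def _default_waves() -> list[WaveSpec]:
    return [
        WaveSpec("wave1", "scannerA", (6.0, 10.0), 400),
        WaveSpec("wave2", "scannerB", (9.0, 12.0), 400),
        WaveSpec("wave3", "scannerB", (13.0, 17.0), 400),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic reference and target cohorts.

    Units: thickness in mm, age in years, slopes in mm/year. ROI areas are
    arbitrary positive weights; residual SD scales as
    ``sigma0 * (area/mean_area) ** (-area_noise_exponent)`` so that small
    parcels are noisier, mirroring surface-based thickness estimates.
    """

    n_rois: int = 10
    roi_names: list[str] = field(default_factory=lambda: default_roi_names(10))
    roi_area: np.ndarray = field(
        default_factory=lambda: np.linspace(20.0, 200.0, 10))
    n_sites_ref: int = 20
    subjects_per_site_ref: int = 150
    age_low: float = 5.0
    age_high: float = 100.0
    mu_alpha: np.ndarray = field(
        default_factory=lambda: 2.2 + 0.06 * np.arange(10))
    mu_beta: np.ndarray = field(
        default_factory=lambda: -0.016 + 0.001 * np.arange(10))
    sex_offset: np.ndarray = field(default_factory=lambda: np.full(10, 0.03))
    tau_alpha: float = 0.10
    tau_beta: float = 0.002
    sigma0: np.ndarray = field(default_factory=lambda: np.full(10, 0.12))
    tau_logsigma: float = 0.15
    area_noise_exponent: float = 0.25
    omega: float = 0.15
    target_waves: list[WaveSpec] = field(default_factory=_default_waves)
    overlap_window: tuple[float, float] = (8.6, 10.7)
    longitudinal_fraction: float = 0.10
    wave2_peaked: bool = True
    wave3_offset: float = 0.05
    scanner_offsets: dict = field(default_factory=dict)
    preterm_fraction: float = 0.06
    delta: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.25, -0.25, 0.0, 0.2, -0.2, 0.0, 0.0, 0.0, 0.0, 0.0]))
    seed: int = 0

    def __post_init__(self):
        for name in ("roi_area", "mu_alpha", "mu_beta", "sex_offset",
                     "sigma0", "delta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        R = self.n_rois
        if R < 1:
            raise ConfigError("n_rois", "must be >= 1")
        if len(self.roi_names) != R:
            raise ConfigError("roi_names", f"expected {R} names")
        for name in ("roi_area", "mu_alpha", "mu_beta", "sex_offset",
                     "sigma0", "delta"):
            arr = getattr(self, name)
            if arr.shape != (R,):
                raise ConfigError(name, f"expected shape ({R},)")
        if np.any(self.roi_area <= 0):
            raise ConfigError("roi_area", "must be strictly positive")
        if np.any(self.sigma0 <= 0):
            raise ConfigError("sigma0", "must be strictly positive")
        for name in ("tau_alpha", "tau_beta", "tau_logsigma", "omega"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        for name in ("longitudinal_fraction", "preterm_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, "must lie in [0, 1]")
        if self.n_sites_ref < 1:
            raise ConfigError("n_sites_ref", "must be >= 1")
        if self.subjects_per_site_ref < 1:
            raise ConfigError("subjects_per_site_ref", "must be >= 1")
        if len(self.target_waves) != 3:
            raise ConfigError("target_waves", "expected exactly 3 waves")
        w1, w2, w3 = self.target_waves
        if w2.scanner != w3.scanner:
            raise ConfigError("target_waves",
                              "waves 2 and 3 must share a scanner id")
        if w1.scanner == w2.scanner:
            raise ConfigError("target_waves",
                              "wave 1 must use a distinct scanner id")
        lo, hi = self.overlap_window
        if not (w1.age_range[0] <= lo and hi <= w2.age_range[1]
                and lo < w1.age_range[1] and w2.age_range[0] < hi):
            raise ConfigError("overlap_window",
                              "must intersect both wave-1 and wave-2 windows")

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["target_waves"] = [
            {"wave": w.wave, "scanner": w.scanner,
             "age_range": list(w.age_range), "n_subjects": w.n_subjects}
            for w in self.target_waves
        ]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        d["target_waves"] = [
            WaveSpec(w["wave"], w["scanner"], tuple(w["age_range"]),
                     int(w["n_subjects"]))
            for w in d["target_waves"]
        ]
        d["overlap_window"] = tuple(d["overlap_window"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground-truth parameters behind a generated cohort.

    ``batch_params[key]`` holds per-ROI arrays ``alpha`` (mm), ``beta``
    (mm/year) and ``sigma`` (mm) for batch ``key`` (``"<site-or-wave>|<sex>"``).
    ``hyper[roi]`` stores the realized across-batch moments of those
    parameters, the quantities a hierarchical fit should recover.
    """

    batch_by: str  # column ("site" or "wave") that keys batches with sex
    roi_names: list[str]
    batch_params: dict[str, dict[str, np.ndarray]]
    subject_u: dict[str, float]
    delta: np.ndarray
    omega: float

    def batch_key(self, row) -> str:
        return f"{row[self.batch_by]}|{row['sex']}"

    def realized_hyper(self, transform=None,
                       subject_var_in_noise: bool = True) -> pd.DataFrame:
        """Across-batch mean/SD of true intercepts, slopes and log-SDs.

        With ``transform`` (a fitted age standardization), parameters are
        expressed on the scale a model fitted to standardized age sees:
        slope ``beta * scale``, intercept ``alpha + beta * center``.  With
        ``subject_var_in_noise`` the subject intercept variance ``omega**2``
        is folded into the batch noise, which is where a model without
        subject terms absorbs it.
        """
        keys = sorted(self.batch_params)
        alpha = np.array([self.batch_params[k]["alpha"] for k in keys])
        beta = np.array([self.batch_params[k]["beta"] for k in keys])
        sigma = np.array([self.batch_params[k]["sigma"] for k in keys])
        if subject_var_in_noise:
            sigma = np.sqrt(sigma ** 2 + self.omega ** 2)
        if transform is not None:
            alpha = alpha + beta * transform.center
            beta = beta * transform.scale
        ls = np.log(sigma)
        rows = []
        for r, roi in enumerate(self.roi_names):
            rows.append({
                "roi": roi,
                "mu_alpha": alpha[:, r].mean(), "tau_alpha": alpha[:, r].std(),
                "mu_beta": beta[:, r].mean(), "tau_beta": beta[:, r].std(),
                "mu_logsigma": ls[:, r].mean(), "tau_logsigma": ls[:, r].std(),
            })
        return pd.DataFrame(rows).set_index("roi")

    def to_json(self) -> str:
        return json.dumps({
            "batch_by": self.batch_by,
            "roi_names": self.roi_names,
            "batch_params": {
                k: {p: v.tolist() for p, v in d.items()}
                for k, d in self.batch_params.items()
            },
            "subject_u": self.subject_u,
            "delta": self.delta.tolist(),
            "omega": self.omega,
        })

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            batch_by=d["batch_by"],
            roi_names=d["roi_names"],
            batch_params={
                k: {p: np.asarray(v) for p, v in sub.items()}
                for k, sub in d["batch_params"].items()
            },
            subject_u={k: float(v) for k, v in d["subject_u"].items()},
            delta=np.asarray(d["delta"]),
            omega=float(d["omega"]),
        )


def _batch_sigma(config: GeneratorConfig, logsig_dev: float) -> np.ndarray:
    rel_area = config.roi_area / config.roi_area.mean()
    return (config.sigma0 * rel_area ** (-config.area_noise_exponent)
            * np.exp(logsig_dev))


def _draw_batch_params(config: GeneratorConfig, sex: str,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    R = config.n_rois
    sexoff = config.sex_offset if sex == "F" else np.zeros(R)
    alpha = config.mu_alpha + sexoff + config.tau_alpha * rng.standard_normal(R)
    beta = config.mu_beta + config.tau_beta * rng.standard_normal(R)
    sigma = np.empty(R)
    for r in range(R):
        sigma[r] = _batch_sigma(config, config.tau_logsigma
                                * rng.standard_normal())[r]
    return {"alpha": alpha, "beta": beta, "sigma": sigma}


def _site_windows(config: GeneratorConfig,
                  rng: np.random.Generator) -> list[tuple[float, float]]:
    # Centers spread over the lifespan with jitter; widths 15-30 y.  With the
    # default 20 sites the union always covers the target range [6, 17].
    n = config.n_sites_ref
    centers = np.linspace(config.age_low + 5.0, config.age_high - 10.0,
                          max(n, 2))[:n]
    spacing = centers[1] - centers[0] if n > 1 else 0.0
    centers = centers + rng.uniform(-3.0, 3.0, size=n)
    # lower bound keeps adjacent windows overlapping despite the jitter
    lo_half = max(7.5, spacing / 2 + 4.0)
    half = rng.uniform(lo_half, max(15.0, lo_half + 2.0), size=n)
    wins = [(max(config.age_low, c - h), min(config.age_high, c + h))
            for c, h in zip(centers, half)]
    # invariant: target age range must be covered by the union
    lo_t, hi_t = 6.0, 17.0
    grid = np.linspace(lo_t, hi_t, 200)
    covered = np.zeros_like(grid, dtype=bool)
    for lo, hi in wins:
        covered |= (grid >= lo) & (grid <= hi)
    if not covered.all():
        raise ConfigError("age_window_policy",
                          "site windows do not jointly cover [6, 17]")
    return wins


def _emit(rows: list[dict], config: GeneratorConfig, subject: str, site: str,
          scanner: str, wave: str | None, sex: str, age: float, group: str,
          y: np.ndarray) -> None:
    rec = {
        "subject_id": subject, "site": site, "scanner": scanner,
        "wave": wave, "sex": sex, "age": age, "group": group,
    }
    for name, val in zip(config.roi_names, y):
        rec[f"roi_{name}"] = val
    rows.append(rec)


def _finish(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.insert(0, "row_id", np.arange(len(df)))
    return df


def generate_reference(config: GeneratorConfig,
                       seed: int) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the multi-site reference cohort (one scan per subject).

    Each site contributes ``subjects_per_site_ref`` cross-sectional scans with
    ages uniform in that site's window; batches are site x sex cells with
    their own true intercept, slope and residual SD.
    """
    rng = np.random.default_rng(seed)
    windows = _site_windows(config, rng)
    batch_params: dict[str, dict[str, np.ndarray]] = {}
    subject_u: dict[str, float] = {}
    rows: list[dict] = []
    for s in range(config.n_sites_ref):
        site = f"site{s + 1:02d}"
        lo, hi = windows[s]
        for sex in SEX_LEVELS:
            batch_params[f"{site}|{sex}"] = _draw_batch_params(config, sex, rng)
        n = config.subjects_per_site_ref
        sexes = np.array(SEX_LEVELS)[rng.integers(0, 2, size=n)]
        ages = rng.uniform(lo, hi, size=n)
        for j in range(n):
            subject = f"ref_{site}_{j:04d}"
            u = config.omega * rng.standard_normal()
            subject_u[subject] = u
            p = batch_params[f"{site}|{sexes[j]}"]
            eps = p["sigma"] * rng.standard_normal(config.n_rois)
            y = p["alpha"] + p["beta"] * ages[j] + u + eps
            _emit(rows, config, subject, site, site, None, sexes[j],
                  float(ages[j]), "control", y)
    truth = TruthRecord("site", list(config.roi_names), batch_params,
                        subject_u, np.zeros(config.n_rois), config.omega)
    return _finish(rows), truth


def _triangular_ages(lo: float, hi: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    # peaked age distribution centred between lo and hi
    return rng.triangular(lo, 0.5 * (lo + hi), hi, size=n)


def generate_target(config: GeneratorConfig,
                    seed: int) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the three-wave, two-scanner longitudinal target cohort.

    Scanner-level batch parameters are drawn once per scanner x sex; waves 2
    and 3 therefore share true parameters apart from ``wave3_offset`` (a
    software-upgrade-like additive shift applied to wave-3 intercepts).
    A ``longitudinal_fraction`` of subjects is measured in all three waves
    with strictly increasing ages and a shared subject intercept ``u_j``;
    a ``preterm_fraction`` of subjects receives the per-ROI shift ``delta``.
    """
    rng = np.random.default_rng(seed)
    w1, w2, w3 = config.target_waves
    scanner_params = {}
    for sc in sorted({w.scanner for w in config.target_waves}):
        for sex in SEX_LEVELS:
            p = _draw_batch_params(config, sex, rng)
            # deterministic injected scanner offset (e.g. hardware change)
            p["alpha"] = p["alpha"] + float(
                config.scanner_offsets.get(sc, 0.0))
            scanner_params[(sc, sex)] = p
    batch_params: dict[str, dict[str, np.ndarray]] = {}
    for w in config.target_waves:
        for sex in SEX_LEVELS:
            p = scanner_params[(w.scanner, sex)]
            alpha = p["alpha"].copy()
            if w.wave == "wave3":
                alpha = alpha + config.wave3_offset
            batch_params[f"{w.wave}|{sex}"] = {
                "alpha": alpha, "beta": p["beta"].copy(),
                "sigma": p["sigma"].copy(),
            }

    n_long = int(round(config.longitudinal_fraction
                       * min(w.n_subjects for w in config.target_waves)))
    subject_u: dict[str, float] = {}
    rows: list[dict] = []

    def draw_rows(subject: str, sex: str, group: str, wave: WaveSpec,
                  age: float) -> None:
        p = batch_params[f"{wave.wave}|{sex}"]
        eps = p["sigma"] * rng.standard_normal(config.n_rois)
        y = p["alpha"] + p["beta"] * age + subject_u[subject] + eps
        if group == "preterm":
            y = y + config.delta
        _emit(rows, config, subject, wave.scanner, wave.scanner, wave.wave,
              sex, age, group, y)

    def new_subject(tag: str) -> tuple[str, str, str]:
        subject = f"tgt_{tag}"
        subject_u[subject] = config.omega * rng.standard_normal()
        sex = SEX_LEVELS[rng.integers(0, 2)]
        group = "preterm" if rng.uniform() < config.preterm_fraction \
            else "control"
        return subject, sex, group

    for j in range(n_long):
        subject, sex, group = new_subject(f"long_{j:05d}")
        a1 = rng.uniform(*w1.age_range)
        a2 = rng.uniform(max(w2.age_range[0], a1 + 0.5), w2.age_range[1])
        a3 = rng.uniform(max(w3.age_range[0], a2 + 0.5), w3.age_range[1])
        for wave, age in zip(config.target_waves, (a1, a2, a3)):
            draw_rows(subject, sex, group, wave, float(age))

    for wave in config.target_waves:
        n_cs = wave.n_subjects - n_long
        lo, hi = wave.age_range
        if wave.wave == "wave2" and config.wave2_peaked:
            ages = _triangular_ages(lo, hi, n_cs, rng)
        else:
            ages = rng.uniform(lo, hi, size=n_cs)
        for j in range(n_cs):
            subject, sex, group = new_subject(f"{wave.wave}_{j:05d}")
            draw_rows(subject, sex, group, wave, float(ages[j]))

    truth = TruthRecord("wave", list(config.roi_names), batch_params,
                        subject_u, config.delta.copy()
                        if config.preterm_fraction > 0
                        else np.zeros(config.n_rois), config.omega)
    return _finish(rows), truth


class UnknownBatchError(KeyError):
    """A cohort row references a batch the truth/model does not know."""


def true_zscores(cohort: pd.DataFrame, truth: TruthRecord) -> pd.DataFrame:
    """Oracle deviation scores from the generating parameters.

    Restricted to control rows of cross-sectional (single-scan) subjects so
    that observations are independent; the subject intercept variance
    ``omega**2`` is folded into the denominator, making the scores exactly
    standard normal by construction.
    """
    counts = cohort["subject_id"].value_counts()
    single = cohort["subject_id"].map(counts).eq(1)
    sub = cohort[(cohort["group"] == "control") & single]
    roi_cols = [f"roi_{r}" for r in truth.roi_names]
    out = sub[["row_id", "subject_id", "site", "scanner", "wave", "sex",
               "age", "group"]].copy()
    z = np.empty((len(sub), len(truth.roi_names)))
    for i, (_, row) in enumerate(sub.iterrows()):
        key = truth.batch_key(row)
        if key not in truth.batch_params:
            raise UnknownBatchError(key)
        p = truth.batch_params[key]
        denom = np.sqrt(p["sigma"] ** 2 + truth.omega ** 2)
        y = row[roi_cols].to_numpy(dtype=float)
        z[i] = (y - p["alpha"] - p["beta"] * row["age"]) / denom
    for r, roi in enumerate(truth.roi_names):
        out[f"z_{roi}"] = z[:, r]
    return out.reset_index(drop=True)
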