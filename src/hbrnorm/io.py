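"""Cohort/model/report readers and writers plus the run manifest.

Cohort files are wide CSV — one row per scan, one ``roi_<name>`` column per
region (the shape of a typical FreeSurfer stats export); reports are tidy
long CSV.  Models serialize to JSON from their posterior summaries, which
are sufficient for prediction, so a save/load round-trip reproduces
``predict`` outputs bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hbr import (
    CovariateTransform,
    NormalPrior,
    PriorSpec,
    ROIPosterior,
    ReferenceModel,
    TruncNormalPrior,
)
from .transfer import AdaptedModel

__all__ = [
    "SchemaError",
    "MODEL_FORMAT_VERSION",
    "read_cohort",
    "write_cohort",
    "save_model",
    "load_model",
    "RunManifest",
]

MODEL_FORMAT_VERSION = 1

REQUIRED_COLS = ("subject_id", "site", "sex", "age")


class SchemaError(ValueError):
    pass


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a wide-format cohort CSV.

    Required columns: subject_id, site, sex, age, and at least one
    ``roi_``-prefixed thickness column; scanner/wave/group are optional.
    Rows with missing or non-numeric thickness are rejected (the models
    require complete ROI data), as are duplicate (subject_id, wave) pairs.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in REQUIRED_COLS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    if not roi_cols:
        raise SchemaError("no roi_-prefixed thickness columns found")
    age = pd.to_numeric(df["age"], errors="coerce")
    if age.isna().any():
        raise SchemaError(
            f"non-numeric age at rows {df.index[age.isna()].tolist()[:5]}")
    df["age"] = age
    for col in roi_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all():
            bad = df.index[~np.isfinite(
                pd.to_numeric(df[col], errors="coerce"))].tolist()
            raise SchemaError(
                f"missing/non-numeric thickness in {col!r} at rows "
                f"{bad[:5]}; only scans with complete ROI data are usable")
        df[col] = vals
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise SchemaError(
            f"sex must be F or M; offending rows "
            f"{df.index[bad_sex].tolist()[:5]}")
    if "wave" in df.columns:
        dup = df.duplicated(subset=["subject_id", "wave"], keep=False)
        if dup.any():
            raise SchemaError(
                f"duplicate (subject_id, wave) pairs at rows "
                f"{df.index[dup].tolist()[:5]}")
    for col, default in (("scanner", df["site"]), ("wave", None),
                         ("group", None)):
        if col not in df.columns:
            df[col] = default
    if "row_id" not in df.columns:
        df.insert(0, "row_id", np.arange(len(df)))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _prior_to_dict(p):
    if isinstance(p, TruncNormalPrior):
        return {"kind": "truncnormal", "loc": p.loc, "scale": p.scale,
                "lower": p.lower}
    return {"kind": "normal", "loc": p.loc, "scale": p.scale}


def _prior_from_dict(d):
    if d["kind"] == "truncnormal":
        return TruncNormalPrior(d["loc"], d["scale"], d["lower"])
    return NormalPrior(d["loc"], d["scale"])


def save_model(model, path) -> None:
    """Serialize a reference or adapted model to JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "transform": {"center": model.transform.center,
                      "scale": model.transform.scale},
        "batch_by": model.batch_by,
        "batches": model.batches,
        "rois": model.rois,
        "predictive": model.predictive,
        "roi_posteriors": {roi: model.roi_posteriors[roi].to_dict()
                           for roi in model.rois},
    }
    if isinstance(model, AdaptedModel):
        payload["adapted"] = {
            "reference_batches": model.reference_batches,
            "new_batches": model.new_batches,
            "batch_definition": model.batch_definition,
            "source_hash": model.source_hash,
            "transfer_priors": {
                roi: {name: _prior_to_dict(getattr(spec, name))
                      for name in ("mu_alpha", "tau_alpha", "mu_beta",
                                   "tau_beta", "mu_logsigma",
                                   "tau_logsigma")}
                for roi, spec in (model.transfer_priors or {}).items()},
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path):
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"unparseable model file {path}: {e}") from None
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise SchemaError(
            f"model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})")
    tr = CovariateTransform(**payload["transform"])
    posts = {roi: ROIPosterior.from_dict(d)
             for roi, d in payload["roi_posteriors"].items()}
    common = dict(transform=tr, batch_by=payload["batch_by"],
                  batches=payload["batches"], rois=payload["rois"],
                  roi_posteriors=posts, predictive=payload["predictive"])
    if payload["kind"] == "adapted":
        ad = payload["adapted"]
        priors = {
            roi: PriorSpec(**{name: _prior_from_dict(d)
                              for name, d in specs.items()})
            for roi, specs in ad["transfer_priors"].items()} or None
        return AdaptedModel(
            common.pop("transform"), common.pop("batch_by"),
            common.pop("batches"), common.pop("rois"),
            common.pop("roi_posteriors"),
            predictive=common.pop("predictive"),
            reference_batches=ad["reference_batches"],
            new_batches=ad["new_batches"],
            batch_definition=ad["batch_definition"],
            source_hash=ad["source_hash"], transfer_priors=priors)
    return ReferenceModel(**common)


@dataclass
class RunManifest:
    """Provenance of one pipeline run: seeds, partitions, convergence."""

    master_seed: int
    command: str
    config: dict = field(default_factory=dict)
    adaptation_row_ids: list[int] = field(default_factory=list)
    test_row_ids: list[int] = field(default_factory=list)
    withheld_row_ids: list[int] = field(default_factory=list)
    convergence: dict = field(default_factory=dict)

    def validate_partitions(self, cohort: pd.DataFrame) -> None:
        parts = [set(self.adaptation_row_ids), set(self.test_row_ids),
                 set(self.withheld_row_ids)]
        union = set().union(*parts)
        total = sum(len(p) for p in parts)
        if total != len(union):
            raise SchemaError("run-manifest partitions overlap")
        if union and union != set(cohort["row_id"]):
            raise SchemaError(
                "run-manifest partitions do not cover the cohort")

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
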