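"""Perturbation-based ("pseudo-SHAP") feature attribution for the subtype model.

The procedure is a four-step first-order audit of a fitted multinomial
logit: (1) predict class probabilities for every patient; (2) perturb one
covariate at a time, holding the others fixed; (3) record the change in
probability (dP) per class; (4) average dP over the cohort into a
feature-by-class table of directional importance scores. Because
probabilities sum to one, each feature's dP vector sums to zero across
classes — a conservation law the table enforces.

Two conventions are offered for binary covariates. ``binary_contrast``
(the default) compares set-to-positive against set-to-negative for every
patient, so the score is undiluted by the feature's prevalence;
``binary_toggle_up`` compares set-to-positive against the observed value,
so patients already positive contribute zero and the mean is diluted by
the positive prevalence. Both are reported distinctly, never mixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DesignMatrix
from .model import FittedSubtypeModel, predict_probabilities

__all__ = [
    "PerturbationSpec",
    "AttributionTable",
    "default_perturbation_specs",
    "perturb",
    "delta_p",
    "mean_attributions",
    "average_attribution_tables",
]

KINDS = ("binary_contrast", "binary_toggle_up", "ordinal_shift", "continuous_shift")
_ORDINAL_RANGE = (1.0, 3.0)  # AJCC stage grades I-III


@dataclass(frozen=True)
class PerturbationSpec:
    """One single-feature perturbation: which column, how, and how far."""

    feature: str
    kind: str
    shift: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}; one of {KINDS}")
        if self.kind in ("ordinal_shift", "continuous_shift"):
            if self.shift is None or not np.isfinite(self.shift) or self.shift == 0:
                raise ValueError(f"{self.kind} requires a finite nonzero shift")


def default_perturbation_specs(design: DesignMatrix,
                               binary_kind: str = "binary_contrast") -> list[PerturbationSpec]:
    """One spec per covariate: contrast for the receptor dummies, +1 grade
    for stage (clamped at III), +1 observed SD for age."""
    specs = []
    for name in design.features:
        col = design.column(name)
        if set(np.unique(col)) <= {0.0, 1.0}:
            specs.append(PerturbationSpec(name, binary_kind))
        elif name == "stage_ord":
            specs.append(PerturbationSpec(name, "ordinal_shift", 1.0))
        else:
            sd = float(col.std(ddof=1))
            specs.append(PerturbationSpec(name, "continuous_shift", sd))
    return specs


def _is_binary(col: np.ndarray) -> bool:
    return set(np.unique(col)) <= {0.0, 1.0}


def perturb(design: DesignMatrix, spec: PerturbationSpec, arm: str) -> DesignMatrix:
    """Return a copy of the design with one covariate moved to the given arm.

    Arms: ``hi`` is the perturbed state, ``lo`` the baseline it is compared
    to, ``observed`` the untouched input. For ``binary_contrast`` lo sets
    the column to 0 and hi to 1; for the toggle/shift kinds lo is the
    observed column. Ordinal shifts clamp to the stage range 1..3.
    """
    if arm not in ("hi", "lo", "observed"):
        raise ValueError(f"arm must be hi/lo/observed, got {arm!r}")
    if spec.feature not in design.column_names:
        raise KeyError(f"unknown feature {spec.feature!r}; design has {design.features}")
    X = design.X.copy()
    j = design.column_names.index(spec.feature)
    col = X[:, j]
    if spec.kind in ("ordinal_shift", "continuous_shift") and _is_binary(col):
        raise ValueError(f"{spec.kind} is not defined for binary feature {spec.feature!r}")
    if spec.kind in ("binary_contrast", "binary_toggle_up") and not _is_binary(col):
        raise ValueError(f"{spec.kind} requires a 0/1 column, got {spec.feature!r}")

    if arm == "observed":
        pass
    elif spec.kind == "binary_contrast":
        X[:, j] = 1.0 if arm == "hi" else 0.0
    elif spec.kind == "binary_toggle_up":
        if arm == "hi":
            X[:, j] = 1.0
    elif spec.kind == "ordinal_shift":
        if arm == "hi":
            X[:, j] = np.clip(col + spec.shift, *_ORDINAL_RANGE)
    elif spec.kind == "continuous_shift":
        if arm == "hi":
            X[:, j] = col + spec.shift
    return design.replace_X(X)


def delta_p(model: FittedSubtypeModel, design: DesignMatrix,
            spec: PerturbationSpec) -> np.ndarray:
    """Per-observation dP: P(class | hi arm) - P(class | lo arm), shape (n, K)."""
    p_hi = predict_probabilities(model, perturb(design, spec, "hi"))
    p_lo = predict_probabilities(model, perturb(design, spec, "lo"))
    return p_hi - p_lo


@dataclass
class AttributionTable:
    """Feature-by-class mean dP table with optional per-observation detail."""

    mean_delta_p: pd.DataFrame  # index: feature, columns: class labels
    n_obs: int
    perturbation_specs: list[PerturbationSpec]
    model_fingerprint: str
    per_obs_delta_p: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        row_sums = self.mean_delta_p.sum(axis=1).to_numpy()
        if np.max(np.abs(row_sums)) > 1e-10:
            raise ValueError(f"dP conservation violated: row sums {row_sums}")
        if (self.mean_delta_p.abs() > 1.0 + 1e-12).any().any():
            raise ValueError("|dP| cannot exceed 1")

    @property
    def features(self) -> list[str]:
        return list(self.mean_delta_p.index)

    @property
    def class_labels(self) -> list[str]:
        return list(self.mean_delta_p.columns)

    def to_long_frame(self) -> pd.DataFrame:
        long = self.mean_delta_p.stack().rename("mean_delta_p").reset_index()
        long.columns = ["feature", "class", "mean_delta_p"]
        long["n_obs"] = self.n_obs
        return long

    def to_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        return json.dumps({
            "mean_delta_p": {f: self.mean_delta_p.loc[f].to_dict() for f in self.features},
            "n_obs": self.n_obs,
            "model_fingerprint": self.model_fingerprint,
            "perturbation_specs": [
                {"feature": s.feature, "kind": s.kind, "shift": s.shift}
                for s in self.perturbation_specs
            ],
        }, indent=1, sort_keys=True)


def mean_attributions(model: FittedSubtypeModel, design: DesignMatrix,
                      specs: list[PerturbationSpec] | None = None,
                      keep_per_obs: bool = False) -> AttributionTable:
    """Average per-observation dP over the cohort for each perturbation spec."""
    if design.n == 0:
        raise ValueError("empty design matrix")
    if specs is None:
        specs = default_perturbation_specs(design)
    if not specs:
        raise ValueError("at least one perturbation spec is required")
    K = model.n_classes
    means = np.empty((len(specs), K))
    per_obs = np.empty((design.n, len(specs), K)) if keep_per_obs else None
    for s_idx, spec in enumerate(specs):
        dp = delta_p(model, design, spec)
        means[s_idx] = dp.mean(axis=0)
        if keep_per_obs:
            per_obs[:, s_idx, :] = dp
    frame = pd.DataFrame(means, index=[s.feature for s in specs],
                         columns=model.class_labels)
    return AttributionTable(frame, design.n, list(specs), model.fingerprint(),
                            per_obs_delta_p=per_obs)


def average_attribution_tables(tables: list[AttributionTable]) -> AttributionTable:
    """Element-wise average of attribution tables, e.g. across imputations."""
    if not tables:
        raise ValueError("no tables to average")
    first = tables[0]
    for t in tables[1:]:
        if t.features != first.features or t.class_labels != first.class_labels:
            raise ValueError("attribution tables have mismatched labels")
    mean = sum(t.mean_delta_p for t in tables) / len(tables)
    return AttributionTable(mean, first.n_obs, list(first.perturbation_specs),
                            "+".join(sorted({t.model_fingerprint for t in tables})))
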