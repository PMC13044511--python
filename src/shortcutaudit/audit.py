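"""Attribution auditing: oracle concordance, label-shift tables, alerts, drift.

This is the operational layer of the shortcut-learning audit. Concordance
validates the cheap perturbation scores against the exact Shapley oracle by
Spearman rank correlation; the label-shift table cross-tabulates predicted
subtypes before and after a perturbation to show where probability mass
migrates; threshold alerts flag feature-class pairs whose mean |dP| exceeds
a cutoff (default 0.25, the proposed quality-assurance trigger); and batch
drift flags pairs that stay above the cutoff for k consecutive data batches.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import AttributionTable, PerturbationSpec, perturb
from .cohort import DesignMatrix
from .model import FittedSubtypeModel, predict_probabilities
from .oracle import ShapleyTable

__all__ = [
    "ConcordanceResult",
    "Alert",
    "DriftFlag",
    "AuditReport",
    "spearman",
    "concordance",
    "label_shift_table",
    "threshold_alerts",
    "batch_drift",
]

DEFAULT_THRESHOLD = 0.25
DEFAULT_PERSISTENCE = 3


def spearman(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and a two-sided p.

    The statistic and the t-approximation p-value come from
    ``scipy.stats.spearmanr``; for n <= ``exact_max_n`` the p-value is
    replaced by an exact permutation computation (all n! orderings of one
    vector).

    Raises
    ------
    ValueError
        On unequal lengths, n < 3, non-finite entries, or a constant vector
        (the correlation is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(a)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input vector: rank correlation is undefined")
    r, p = stats.spearmanr(a, b)
    if n <= exact_max_n:
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        observed = abs(np.corrcoef(ra, rb)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(rb):
            total += 1
            if abs(np.corrcoef(ra, perm)[0, 1]) >= observed - 1e-12:
                count += 1
        p = count / total
    return float(r), float(p)


@dataclass
class ConcordanceResult:
    """Rank agreement between the perturbation scores and the exact oracle."""

    spearman_r: float
    p_value: float
    n_pairs: int
    granularity: str

    def __post_init__(self):
        if abs(self.spearman_r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


def concordance(attr: AttributionTable, shap: ShapleyTable,
                granularity: str = "feature_class_means") -> ConcordanceResult:
    """Spearman concordance between mean dP and mean exact Shapley values.

    ``feature_class_means`` (default) flattens the two feature-by-class mean
    matrices into paired vectors; ``per_observation`` pools the
    per-observation values (both tables must retain them).
    """
    if sorted(attr.features) != sorted(shap.features) or \
            sorted(attr.class_labels) != sorted(shap.class_labels):
        raise ValueError(
            "label mismatch: attribution has features "
            f"{attr.features} / classes {attr.class_labels}, oracle has "
            f"{shap.features} / {shap.class_labels}"
        )
    if granularity == "feature_class_means":
        aligned = shap.phi.loc[attr.features, attr.class_labels]
        a = attr.mean_delta_p.to_numpy().ravel()
        b = aligned.to_numpy().ravel()
    elif granularity == "per_observation":
        if attr.per_obs_delta_p is None or shap.per_obs_phi is None:
            raise ValueError("per-observation granularity needs retained per-obs arrays")
        a = attr.per_obs_delta_p.ravel()
        b = shap.per_obs_phi.ravel()
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    r, p = spearman(a, b)
    return ConcordanceResult(r, p, len(a), granularity)


def label_shift_table(model: FittedSubtypeModel, design: DesignMatrix,
                      spec: PerturbationSpec) -> pd.DataFrame:
    """Cross-tabulate argmax predicted subtype under the lo arm vs the hi arm.

    Rows index the baseline (lo) label, columns the perturbed (hi) label;
    argmax ties resolve to the earlier class in label order (reference
    first), which is deterministic.
    """
    p_lo = predict_probabilities(model, perturb(design, spec, "lo"))
    p_hi = predict_probabilities(model, perturb(design, spec, "hi"))
    labels = model.class_labels
    lo_lab = np.argmax(p_lo, axis=1)
    hi_lab = np.argmax(p_hi, axis=1)
    table = np.zeros((len(labels), len(labels)), dtype=int)
    np.add.at(table, (lo_lab, hi_lab), 1)
    return pd.DataFrame(table, index=pd.Index(labels, name="from"),
                        columns=pd.Index(labels, name="to"))


@dataclass(frozen=True)
class Alert:
    """A feature-class pair whose |mean dP| exceeded its threshold."""

    feature: str
    class_label: str
    mean_delta_p: float
    threshold: float
    batch_index: int | None = None


def threshold_alerts(attr: AttributionTable,
                     thresholds: float | dict[str, float] = DEFAULT_THRESHOLD,
                     batch_index: int | None = None) -> list[Alert]:
    """Alerts for every (feature, class) with |mean dP| strictly above threshold.

    ``thresholds`` is a global cutoff or a per-feature mapping (features
    absent from the mapping fall back to the default 0.25).
    """
    def cutoff(feature: str) -> float:
        if isinstance(thresholds, dict):
            return float(thresholds.get(feature, DEFAULT_THRESHOLD))
        return float(thresholds)

    alerts = []
    for feature in attr.features:
        t = cutoff(feature)
        if t <= 0:
            raise ValueError(f"threshold for {feature!r} must be positive, got {t}")
        for lab in attr.class_labels:
            value = float(attr.mean_delta_p.loc[feature, lab])
            if abs(value) > t:
                alerts.append(Alert(feature, lab, value, t, batch_index))
    return alerts


@dataclass(frozen=True)
class DriftFlag:
    """Persistent exceedance of the attribution threshold across batches."""

    feature: str
    class_label: str
    window_start: int  # 0-based index of the first batch of the qualifying run
    run_length: int
    threshold: float


def batch_drift(batch_tables: list[AttributionTable],
                threshold: float = DEFAULT_THRESHOLD,
                persistence_k: int = DEFAULT_PERSISTENCE) -> list[DriftFlag]:
    """Flag feature-class pairs above threshold in >= k consecutive batches.

    With k = 1 this reduces to the union of per-batch threshold alerts.
    """
    if not batch_tables:
        raise ValueError("at least one batch table is required")
    if persistence_k < 1:
        raise ValueError("persistence_k must be >= 1")
    first = batch_tables[0]
    for t in batch_tables[1:]:
        if t.features != first.features or t.class_labels != first.class_labels:
            raise ValueError("batches have inconsistent feature/class label sets")
    flags = []
    for feature in first.features:
        for lab in first.class_labels:
            exceed = [abs(float(t.mean_delta_p.loc[feature, lab])) > threshold
                      for t in batch_tables]
            run = 0
            for i, hit in enumerate(exceed):
                run = run + 1 if hit else 0
                if run == persistence_k:
                    total = run
                    for later in exceed[i + 1:]:
                        if later:
                            total += 1
                        else:
                            break
                    flags.append(DriftFlag(feature, lab, i - persistence_k + 1,
                                           total, threshold))
                    break
    return flags


@dataclass
class AuditReport:
    """Bundle of the audit outputs plus the configuration that produced them."""

    concordance: ConcordanceResult | None
    shift_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    alerts: list[Alert] = field(default_factory=list)
    drift_flags: list[DriftFlag] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    @property
    def has_alerts(self) -> bool:
        return bool(self.alerts or self.drift_flags)

    def to_json(self) -> str:
        doc = {
            "concordance": None if self.concordance is None else {
                "spearman_r": self.concordance.spearman_r,
                "p_value": self.concordance.p_value,
                "n_pairs": self.concordance.n_pairs,
                "granularity": self.concordance.granularity,
            },
            "shift_tables": {
                feat: {"labels": list(tab.index), "counts": tab.to_numpy().tolist()}
                for feat, tab in self.shift_tables.items()
            },
            "alerts": [
                {"feature": a.feature, "class": a.class_label,
                 "mean_delta_p": a.mean_delta_p, "threshold": a.threshold,
                 "batch_index": a.batch_index}
                for a in self.alerts
            ],
            "drift_flags": [
                {"feature": f.feature, "class": f.class_label,
                 "window_start": f.window_start, "run_length": f.run_length,
                 "threshold": f.threshold}
                for f in self.drift_flags
            ],
            "config_echo": self.config_echo,
        }
        return json.dumps(doc, indent=1, sort_keys=True)
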