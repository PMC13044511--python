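"""Exact interventional Shapley values by full coalition enumeration.

With only five clinical covariates the 2^5 coalitions can be enumerated
exactly, so this module provides the ground-truth attribution the
perturbation-based scores are validated against. The value function is the
interventional (marginal) convention of the canonical SHAP implementation:
v(S) is the mean predicted probability over a background sample in which
features inside the coalition S are pinned to the explained patient's
values and features outside S keep the background rows' values. The exact
Shapley value for feature j is the coalition-weighted average of its
marginal contributions,

    phi_j = sum_{S subset F\\{j}} |S|! (p-|S|-1)! / p! * [v(S u {j}) - v(S)],

which satisfies efficiency per class: sum_j phi_j = P(class | x) - mean
background prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DesignMatrix
from .model import FittedSubtypeModel, _softmax

__all__ = [
    "ShapleyTable",
    "coalition_value",
    "exact_shapley",
    "mean_shapley",
]

MAX_FEATURES = 12  # enumeration guard: 2^12 coalitions is the supported ceiling


def _feature_indices(model: FittedSubtypeModel) -> list[int]:
    return [j for j, c in enumerate(model.column_names) if c != "intercept"]


def _check_features(model: FittedSubtypeModel) -> list[str]:
    feats = [c for c in model.column_names if c != "intercept"]
    if len(feats) > MAX_FEATURES:
        raise ValueError(
            f"{len(feats)} features exceeds the exact-enumeration guard of "
            f"{MAX_FEATURES}; a sampling approximation would be required"
        )
    return feats


def _value_for_mask(model: FittedSubtypeModel, X: np.ndarray,
                    background: np.ndarray, mask: int) -> np.ndarray:
    """v(S) for one coalition bitmask: array (n_rows, n_classes).

    Bit b of the mask corresponds to the b-th non-intercept feature: set
    bits take the explained rows' values, clear bits the background's.
    """
    feat_idx = _feature_indices(model)
    n, B = X.shape[0], background.shape[0]
    K = model.n_classes
    hybrid = np.broadcast_to(background, (n, B, X.shape[1])).copy()
    for b, j in enumerate(feat_idx):
        if mask >> b & 1:
            hybrid[:, :, j] = X[:, j][:, None]
    probs = _softmax(hybrid.reshape(n * B, -1) @ model.coefficients.T)
    return probs.reshape(n, B, K).mean(axis=1)


def _all_coalition_values(model: FittedSubtypeModel, X: np.ndarray,
                          background: np.ndarray) -> np.ndarray:
    """v(S) for every coalition bitmask: array (2^p, n_rows, n_classes)."""
    p = len(_feature_indices(model))
    out = np.empty((1 << p, X.shape[0], model.n_classes))
    for mask in range(1 << p):
        out[mask] = _value_for_mask(model, X, background, mask)
    return out


def coalition_value(model: FittedSubtypeModel, x: np.ndarray,
                    coalition: set[str] | list[str],
                    background: DesignMatrix | np.ndarray) -> np.ndarray:
    """Interventional value v(S) per class for a single covariate row ``x``.

    ``x`` is a full design row (intercept included); features in the
    coalition take their values from x, the rest are marginalized over the
    background rows.
    """
    feats = _check_features(model)
    unknown = set(coalition) - set(feats)
    if unknown:
        raise KeyError(f"coalition names not in the feature set: {sorted(unknown)}")
    bg = background.X if isinstance(background, DesignMatrix) else np.asarray(background, float)
    if bg.shape[0] == 0:
        raise ValueError("background sample is empty")
    mask = 0
    for b, name in enumerate(feats):
        if name in set(coalition):
            mask |= 1 << b
    values = _all_coalition_values(model, np.asarray(x, float)[None, :], bg)
    return values[mask, 0]


def _shapley_from_values(values: np.ndarray, p: int) -> np.ndarray:
    """Combine coalition values (2^p, n, K) into phi (n, p, K)."""
    n, K = values.shape[1], values.shape[2]
    phi = np.zeros((n, p, K))
    fact = [math.factorial(i) for i in range(p + 1)]
    weight = [fact[s] * fact[p - s - 1] / fact[p] for s in range(p)]
    for mask in range(1 << p):
        s = bin(mask).count("1")
        for b in range(p):
            if mask >> b & 1:
                continue
            w = weight[s]
            phi[:, b, :] += w * (values[mask | (1 << b)] - values[mask])
    return phi


def exact_shapley(model: FittedSubtypeModel, x: np.ndarray,
                  background: DesignMatrix | np.ndarray) -> pd.DataFrame:
    """Exact per-class Shapley values for one covariate row.

    Returns a feature-by-class frame; efficiency (column sums equal
    P(class|x) minus the mean background prediction) holds to numerical
    precision by construction.
    """
    feats = _check_features(model)
    bg = background.X if isinstance(background, DesignMatrix) else np.asarray(background, float)
    if bg.shape[0] == 0:
        raise ValueError("background sample is empty")
    values = _all_coalition_values(model, np.asarray(x, float)[None, :], bg)
    phi = _shapley_from_values(values, len(feats))[0]
    return pd.DataFrame(phi, index=feats, columns=model.class_labels)


@dataclass
class ShapleyTable:
    """Cohort-mean exact Shapley attributions per feature and class.

    ``mode`` records the construction: ``contrast`` rows are
    phi_j(hi arm) - phi_j(lo arm) for the feature's perturbation — the
    Shapley analogue of dP; ``observed`` rows are the raw phi_j(x) means
    (which cancel toward zero over a cohort under an empirical background).
    """

    phi: pd.DataFrame  # index: feature, columns: class labels
    background_size: int
    background_seed: int
    mode: str = "contrast"
    per_obs_phi: np.ndarray | None = field(default=None, repr=False)

    @property
    def features(self) -> list[str]:
        return list(self.phi.index)

    @property
    def class_labels(self) -> list[str]:
        return list(self.phi.columns)

    def to_long_frame(self) -> pd.DataFrame:
        long = self.phi.stack().rename("mean_delta_p").reset_index()
        long.columns = ["feature", "class", "mean_delta_p"]
        long["n_obs"] = self.background_size
        return long

    def to_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


def _contrast_phi(model: FittedSubtypeModel, design: DesignMatrix, spec,
                  bg: np.ndarray) -> np.ndarray:
    """phi_j(hi arm) - phi_j(lo arm) per observation for spec's feature j.

    Coalition values for coalitions excluding j cancel between the arms, so
    only the 2^(p-1) coalitions containing j are evaluated, on each arm.
    Shape (n, K).
    """
    from .attribution import perturb  # local import avoids a module cycle

    feats = _check_features(model)
    b = feats.index(spec.feature)
    p = len(feats)
    X_hi = perturb(design, spec, "hi").X
    X_lo = perturb(design, spec, "lo").X
    fact = [math.factorial(i) for i in range(p + 1)]
    out = np.zeros((design.n, model.n_classes))
    for mask in range(1 << p):
        if not mask >> b & 1:
            continue
        s = bin(mask).count("1") - 1  # |S| of the coalition without j
        w = fact[s] * fact[p - s - 1] / fact[p]
        out += w * (_value_for_mask(model, X_hi, bg, mask)
                    - _value_for_mask(model, X_lo, bg, mask))
    return out


def mean_shapley(model: FittedSubtypeModel, design: DesignMatrix,
                 specs=None, background_size: int = 200,
                 background_seed: int = 0, mode: str = "contrast",
                 keep_per_obs: bool = False) -> ShapleyTable:
    """Cohort-mean exact Shapley attribution table.

    The background is a seeded without-replacement subsample of the design
    (all rows when the design is smaller than ``background_size``).

    In ``contrast`` mode (default) each feature's row is the mean over
    observations of phi_j at the perturbed-hi instance minus phi_j at the
    perturbed-lo instance of that feature's perturbation spec — the exact
    coalition-weighted counterpart of the perturbation dP, directly
    comparable to an :class:`~shortcutaudit.attribution.AttributionTable`.
    In ``observed`` mode each row is the plain mean of phi_j(x) over the
    cohort; under an empirical background those signed means cancel toward
    zero by the law of total expectation, so this mode characterizes the
    attribution distribution rather than directional importance.
    """
    if design.n == 0:
        raise ValueError("empty design matrix")
    feats = _check_features(model)
    if list(design.column_names) != list(model.column_names):
        raise ValueError("design columns do not match model columns")
    rng = np.random.default_rng(background_seed)
    if design.n > background_size:
        idx = rng.choice(design.n, size=background_size, replace=False)
        bg = design.X[np.sort(idx)]
    else:
        bg = design.X

    if mode == "observed":
        values = _all_coalition_values(model, design.X, bg)
        phi = _shapley_from_values(values, len(feats))
    elif mode == "contrast":
        from .attribution import default_perturbation_specs

        if specs is None:
            specs = default_perturbation_specs(design)
        if [s.feature for s in specs] != feats:
            raise ValueError(
                f"contrast mode needs one spec per feature in order {feats}; "
                f"got {[s.feature for s in specs]}"
            )
        phi = np.empty((design.n, len(feats), model.n_classes))
        for b, spec in enumerate(specs):
            phi[:, b, :] = _contrast_phi(model, design, spec, bg)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'contrast' or 'observed'")

    frame = pd.DataFrame(phi.mean(axis=0), index=feats, columns=model.class_labels)
    return ShapleyTable(frame, bg.shape[0], background_seed, mode=mode,
                        per_obs_phi=phi if keep_per_obs else None)
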