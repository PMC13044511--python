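"""Clinical cohort data model, CSV I/O, stage harmonization and design-matrix encoding.

The cohort is a patient-level table of the five clinical covariates used to
predict PAM50 intrinsic subtype: age at diagnosis (years), ER/PR/HER2
receptor status (positive/negative), and AJCC tumor stage harmonized to the
ordinal grades I-III. Stage IV and unstageable records are excluded with a
warning so that the ordinal stage covariate stays well-defined.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalCohort",
    "DesignMatrix",
    "SchemaError",
    "EmptyInputError",
    "StageParseError",
    "MissingDataError",
    "DegenerateResponseError",
    "SUBTYPE_LABELS",
    "CANONICAL_COLUMNS",
    "harmonize_stage",
    "read_cohort",
    "write_cohort",
    "encode_design_matrix",
]

SUBTYPE_LABELS = ("LumA", "LumB", "Her2E", "Basal", "Normal")
CANONICAL_COLUMNS = ("patient_id", "age", "er", "pr", "her2", "stage", "subtype")

#: default normalization of receptor-status strings (lower-cased before lookup)
DEFAULT_VALUE_MAP = {
    "positive": "positive", "pos": "positive", "1": "positive", "+": "positive",
    "negative": "negative", "neg": "negative", "0": "negative", "-": "negative",
}

_SUBTYPE_ALIASES = {
    "luma": "LumA", "luminal a": "LumA", "lumb": "LumB", "luminal b": "LumB",
    "her2e": "Her2E", "her2-enriched": "Her2E", "her2 enriched": "Her2E",
    "basal": "Basal", "basal-like": "Basal", "normal": "Normal",
    "normal-like": "Normal",
}


class SchemaError(ValueError):
    """A mandatory column is absent from the input table."""


class EmptyInputError(ValueError):
    """The input table has a header but no data rows."""


class StageParseError(ValueError):
    """A stage label could not be interpreted as an AJCC stage."""


class MissingDataError(ValueError):
    """An operation requiring complete cases encountered missing cells."""


class DegenerateResponseError(ValueError):
    """Fewer than two subtype classes are observed."""


_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}
_STAGE_RE = re.compile(r"^(?:stage\s*)?(IV|III|II|I|X)\s*([ABC]?)$", re.IGNORECASE)


def harmonize_stage(raw_label: str) -> int | None:
    """Harmonize an AJCC pathologic stage label to the ordinal grade 1-3.

    Substages collapse to their parent stage ("Stage IIA" -> 2). Stage IV and
    stage X (unstageable) return ``None`` as an exclusion signal: the analysis
    cohort is restricted to stages I-III.

    Raises
    ------
    StageParseError
        If the label is empty or not a recognizable AJCC stage.
    """
    if not isinstance(raw_label, str) or not raw_label.strip():
        raise StageParseError(f"empty or non-string stage label: {raw_label!r}")
    m = _STAGE_RE.match(raw_label.strip())
    if m is None:
        raise StageParseError(f"unrecognized stage label: {raw_label!r}")
    numeral = m.group(1).upper()
    if numeral == "X" or _ROMAN.get(numeral, 0) > 3:
        return None
    return _ROMAN[numeral]


@dataclass
class ClinicalCohort:
    """Patient-level clinical table backed by a pandas DataFrame.

    Columns are the canonical set ``patient_id, age, er, pr, her2, stage,
    subtype``; receptor columns hold ``"positive"``/``"negative"`` or NaN,
    ``stage`` holds 1/2/3 or NaN, ``subtype`` one of the five PAM50 labels
    or NaN. Missing cells are NaN throughout; :attr:`missing_mask` mirrors
    them exactly.
    """

    data: pd.DataFrame
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort frame lacks columns: {missing}")
        self.data = self.data.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        self.validate()

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True exactly where a cell is missing."""
        return self.data.drop(columns=["patient_id"]).isna()

    def validate(self) -> None:
        df = self.data
        age = pd.to_numeric(df["age"], errors="coerce")
        observed_age = age.dropna()
        if len(observed_age) and not (
            np.isfinite(observed_age).all()
            and (observed_age > 0).all()
            and (observed_age < 130).all()
        ):
            raise ValueError("ages must be finite and in (0, 130)")
        for col in ("er", "pr", "her2"):
            bad = set(df[col].dropna()) - {"positive", "negative"}
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")
        bad_stage = set(pd.to_numeric(df["stage"], errors="coerce").dropna()) - {1, 2, 3}
        if bad_stage:
            raise ValueError(f"invalid stage values: {sorted(bad_stage)}")
        bad_sub = set(df["subtype"].dropna()) - set(SUBTYPE_LABELS)
        if bad_sub:
            raise ValueError(f"invalid subtype labels: {sorted(bad_sub)}")

    def complete_cases(self) -> "ClinicalCohort":
        """Subset to rows with no missing cell in any analysis column."""
        keep = ~self.missing_mask.any(axis=1)
        return ClinicalCohort(self.data.loc[keep].reset_index(drop=True), seed=self.seed)

    def copy(self) -> "ClinicalCohort":
        return ClinicalCohort(self.data.copy(), seed=self.seed)

    def equals(self, other: "ClinicalCohort") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            x, y = a[c], b[c]
            if c in ("age", "stage"):
                x = pd.to_numeric(x, errors="coerce")
                y = pd.to_numeric(y, errors="coerce")
                if not np.allclose(x.fillna(np.inf), y.fillna(np.inf), equal_nan=True):
                    return False
            else:
                if not (x.fillna("\0") == y.fillna("\0")).all():
                    return False
        return True


def _normalize_receptor(value, value_map: dict[str, str], column: str):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip().lower()
    if not text or text in ("nan", "na", ""):
        return np.nan
    if text not in value_map:
        return np.nan  # unparseable cells are treated as missing
    return value_map[text]


def _normalize_subtype(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip()
    if not text or text.lower() in ("nan", "na"):
        return np.nan
    if text in SUBTYPE_LABELS:
        return text
    return _SUBTYPE_ALIASES.get(text.lower(), np.nan)


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    value_map: dict[str, str] | None = None,
) -> ClinicalCohort:
    """Read a clinical cohort from a delimited text file.

    Parameters
    ----------
    path : str, Path or file-like
        CSV with a header row. Lines beginning with ``#`` are ignored (the
        writer records the generator seed in such a comment line).
    schema : dict, optional
        Mapping from canonical column names to the names used in the file,
        e.g. ``{"age": "age_at_diagnosis"}``. Unmapped canonical names are
        looked up verbatim.
    value_map : dict, optional
        Receptor-status normalization dictionary replacing the default
        (covering positive/negative, pos/neg, 1/0, +/-).

    Raises
    ------
    SchemaError
        If a mandatory column (all canonical ones except patient_id) is
        absent, naming the column.
    EmptyInputError
        If the file has no data rows.
    """
    schema = dict(schema or {})
    value_map = dict(value_map or DEFAULT_VALUE_MAP)
    raw = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    for canonical in CANONICAL_COLUMNS:
        source = schema.get(canonical, canonical)
        if source not in raw.columns:
            if canonical == "patient_id":
                continue
            raise SchemaError(f"mandatory column missing: {canonical!r} (looked for {source!r})")
    if len(raw) == 0:
        raise EmptyInputError("input has a header but zero data rows")

    out = pd.DataFrame(index=raw.index)
    pid_source = schema.get("patient_id", "patient_id")
    if pid_source in raw.columns:
        out["patient_id"] = raw[pid_source].astype(str)
    else:
        out["patient_id"] = [f"P{i:05d}" for i in range(len(raw))]
    out["age"] = pd.to_numeric(raw[schema.get("age", "age")], errors="coerce")
    for col in ("er", "pr", "her2"):
        out[col] = raw[schema.get(col, col)].map(
            lambda v: _normalize_receptor(v, value_map, col)
        )

    def _stage(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        text = str(v).strip()
        if not text or text.lower() in ("nan", "na"):
            return np.nan
        if text in ("1", "2", "3"):
            return int(text)
        try:
            harmonized = harmonize_stage(text)
        except StageParseError:
            return np.nan
        return np.nan if harmonized is None else harmonized

    out["stage"] = raw[schema.get("stage", "stage")].map(_stage)
    out["subtype"] = raw[schema.get("subtype", "subtype")].map(_normalize_subtype)
    return ClinicalCohort(out)


def write_cohort(cohort: ClinicalCohort, path, seed: int | None = None) -> None:
    """Write the normalized cohort CSV; the seed is recorded as a ``#`` header comment."""
    seed = cohort.seed if seed is None else seed
    buf = io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    df = cohort.data.copy()
    df["stage"] = df["stage"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


@dataclass
class DesignMatrix:
    """Complete-case model matrix for the subtype multinomial logit.

    ``X`` columns are ordered ``intercept, age, er_pos, pr_pos, her2_pos,
    stage_ord``; ``y`` holds integer class codes with the reference class
    coded 0 (``class_labels[0]``).
    """

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    class_labels: list[str]
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes disagree")
        if not np.isfinite(self.X).all():
            raise MissingDataError("design matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def features(self) -> list[str]:
        return [c for c in self.column_names if c != "intercept"]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.X[:, self.column_names.index(name)]
        except ValueError as exc:
            raise KeyError(f"no such design column: {name!r}") from exc

    def replace_X(self, X: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(X, self.y.copy(), list(self.column_names),
                            list(self.class_labels), self.patient_ids.copy())


DESIGN_COLUMNS = ["intercept", "age", "er_pos", "pr_pos", "her2_pos", "stage_ord"]


def encode_design_matrix(
    cohort: ClinicalCohort,
    reference_class: str = "LumA",
    center_age: bool = False,
) -> DesignMatrix:
    """Encode a complete-case cohort into the model design matrix.

    Receptor statuses are dummy-encoded (positive -> 1), stage enters as a
    single ordinal numeric 1-3 and age in raw years (optionally centered).
    The reference subtype (default Luminal A) is listed first in
    ``class_labels``; observed classes with zero cases are dropped with a
    warning.

    Raises
    ------
    MissingDataError
        If any analysis cell is missing — impute or take complete cases first.
    DegenerateResponseError
        If fewer than two subtype classes are observed.
    """
    df = cohort.data
    mask = cohort.missing_mask
    if mask.any().any():
        bad = [c for c in mask.columns if mask[c].any()]
        raise MissingDataError(
            f"cohort contains missing cells in {bad}; restrict to complete cases or impute"
        )

    present = [lab for lab in SUBTYPE_LABELS if (df["subtype"] == lab).any()]
    dropped = [lab for lab in SUBTYPE_LABELS if lab not in present]
    if dropped:
        warnings.warn(f"subtype classes with zero observations dropped: {dropped}")
    if len(present) < 2:
        raise DegenerateResponseError(f"only {len(present)} subtype class observed")
    if reference_class not in present:
        raise ValueError(f"reference class {reference_class!r} not observed; present: {present}")
    class_labels = [reference_class] + [lab for lab in present if lab != reference_class]

    age = df["age"].to_numpy(dtype=float)
    if center_age:
        age = age - age.mean()
    X = np.column_stack([
        np.ones(len(df)),
        age,
        (df["er"] == "positive").to_numpy(dtype=float),
        (df["pr"] == "positive").to_numpy(dtype=float),
        (df["her2"] == "positive").to_numpy(dtype=float),
        df["stage"].to_numpy(dtype=float),
    ])
    code = {lab: k for k, lab in enumerate(class_labels)}
    y = df["subtype"].map(code).to_numpy(dtype=int)
    return DesignMatrix(X, y, list(DESIGN_COLUMNS), class_labels,
                        df["patient_id"].to_numpy())
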