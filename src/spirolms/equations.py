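"""Typed reference-equation sets: representation, JSON (de)serialization, evaluation.

A reference-equation set models each spirometric index (FEV1, FVC,
FEV1/FVC, FEF25-75) for one sex with a BCCG or BCPE distribution whose
parameters (mu, sigma, nu and, for BCPE, tau) are each a linear model on
the link scale in ln(height) and ln(age), optionally plus a smooth
age spline carried as a knot table.  Heights are in centimetres, ages in
years, logarithms natural; volumes in litres, flows in L/s, the
FEV1/FVC ratio as a fraction in (0, 1].

The package ships the Iraqi Spirometric Equations (ISE) for both sexes.
Their published form declares age splines on several mu/sigma models but
the spline shapes themselves were never published, so the packaged sets
carry empty spline tables together with an explicit
``acknowledge_missing_splines`` flag; refitting on cohort data can
populate them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .distributions import BCCGParams, BCPEParams, quantile, zscore

__all__ = [
    "INDICES",
    "EXCLUSION_FLAGS",
    "SplineTable",
    "ParameterModel",
    "IndexModel",
    "EquationSet",
    "Subject",
    "SpiroRecord",
    "EquationSchemaError",
    "normalize_index",
    "normalize_ratio",
    "evaluate_parameter",
    "predict_median",
    "percent_predicted",
    "zscore_for",
    "load_equation_set",
    "save_equation_set",
    "load_ise",
]

#: canonical index keys, in reporting order
INDICES = ("fev1", "fvc", "fev1_fvc", "fef2575")

_INDEX_ALIASES = {
    "fev1": "fev1",
    "fev_1": "fev1",
    "fvc": "fvc",
    "fev1/fvc": "fev1_fvc",
    "fev1_fvc": "fev1_fvc",
    "ratio": "fev1_fvc",
    "fef25-75": "fef2575",
    "fef25_75": "fef2575",
    "fef2575": "fef2575",
}

#: questionnaire exclusion flags, in the eligibility-criteria listing order
#: (this order fixes the precedence of reported exclusion reasons)
EXCLUSION_FLAGS = (
    "current_smoker",
    "lives_with_smoker",
    "former_smoker",
    "chronic_disease",
    "pregnant",
    "recent_surgery_or_acute_symptoms",
)

_PARAM_NAMES = ("mu", "sigma", "nu", "tau")
_LINKS = ("identity", "log")
_FAMILIES = ("BCCG", "BCPE", "normal")


class EquationSchemaError(ValueError):
    """Raised when an equation-set document violates the schema."""


def normalize_index(index: str) -> str:
    key = str(index).strip().lower().replace("%", "")
    if key not in _INDEX_ALIASES:
        raise KeyError(
            f"unknown spirometric index {index!r}; expected one of {sorted(set(_INDEX_ALIASES))}"
        )
    return _INDEX_ALIASES[key]


def normalize_ratio(value: float | np.ndarray) -> np.ndarray:
    """Coerce FEV1/FVC to a fraction; values above 1.5 are treated as percent."""
    value = np.asarray(value, dtype=float)
    return np.where(value > 1.5, value / 100.0, value)


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class SplineTable:
    """Smooth age contribution tabulated at knots (link-scale units).

    Evaluated by natural-cubic interpolation between knots and clamped to
    the end values outside the knot range.
    """

    age_knots: tuple
    values: tuple

    def __post_init__(self):
        knots = np.asarray(self.age_knots, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if knots.size < 2:
            raise EquationSchemaError("spline table needs at least 2 knots")
        if knots.size != vals.size:
            raise EquationSchemaError("spline knots and values differ in length")
        if np.any(np.diff(knots) <= 0):
            raise EquationSchemaError("spline age knots must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise EquationSchemaError("spline values must be finite")
        object.__setattr__(self, "age_knots", tuple(knots.tolist()))
        object.__setattr__(self, "values", tuple(vals.tolist()))

    def __call__(self, age):
        knots = np.asarray(self.age_knots)
        vals = np.asarray(self.values)
        cs = CubicSpline(knots, vals, bc_type="natural")
        age = np.clip(np.asarray(age, dtype=float), knots[0], knots[-1])
        return cs(age)


@dataclass(frozen=True)
class ParameterModel:
    """One distribution-parameter model on its link scale.

    link-scale value = intercept + beta_log_height*ln(height)
    + beta_log_age*ln(age) + spline(age); the link inverse (exp for the
    log link) maps it to the parameter scale.
    """

    link: str
    intercept: float
    beta_log_height: float = 0.0
    beta_log_age: float = 0.0
    spline: SplineTable | None = None
    spline_declared: bool = False

    def __post_init__(self):
        if self.link not in _LINKS:
            raise EquationSchemaError(f"unknown link {self.link!r}; expected one of {_LINKS}")
        for name in ("intercept", "beta_log_height", "beta_log_age"):
            if not np.isfinite(getattr(self, name)):
                raise EquationSchemaError(f"{name} must be finite")

    def linear_predictor(self, height, age):
        eta = (
            self.intercept
            + self.beta_log_height * np.log(np.asarray(height, dtype=float))
            + self.beta_log_age * np.log(np.asarray(age, dtype=float))
        )
        if self.spline is not None:
            eta = eta + self.spline(age)
        return eta

    def __call__(self, height, age):
        eta = self.linear_predictor(height, age)
        return np.exp(eta) if self.link == "log" else eta


@dataclass(frozen=True)
class IndexModel:
    """Distribution family plus the per-parameter models for one index."""

    family: str
    mu: ParameterModel
    sigma: ParameterModel
    nu: ParameterModel | None = None
    tau: ParameterModel | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise EquationSchemaError(f"unknown family {self.family!r}")
        if self.family in ("BCCG", "BCPE") and self.nu is None:
            raise EquationSchemaError(f"family {self.family} requires a nu model")
        if self.family == "BCPE" and self.tau is None:
            raise EquationSchemaError("family BCPE requires a tau model")
        if self.family != "BCPE" and self.tau is not None:
            raise EquationSchemaError(f"tau model not allowed for family {self.family}")

    def params_at(self, height, age):
        """Subject-specific distribution parameters (BCCGParams or BCPEParams)."""
        mu = self.mu(height, age)
        sigma = self.sigma(height, age)
        if self.family == "BCPE":
            return BCPEParams(mu, sigma, self.nu(height, age), self.tau(height, age))
        nu = self.nu(height, age) if self.nu is not None else np.zeros_like(np.asarray(mu))
        return BCCGParams(mu, sigma, nu)


@dataclass(frozen=True)
class EquationSet:
    """A full sex-specific reference-equation set (all four indices)."""

    name: str
    sex: str
    indices: Mapping[str, IndexModel]
    valid_age_range: tuple = (18.0, 70.0)
    acknowledge_missing_splines: bool = False

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise EquationSchemaError("sex must be 'male' or 'female'")
        missing = [k for k in INDICES if k not in self.indices]
        if missing:
            raise EquationSchemaError(f"equation set missing indices: {missing}")
        for idx, model in self.indices.items():
            for pname in _PARAM_NAMES:
                pm = getattr(model, pname, None)
                if pm is not None and pm.spline_declared and pm.spline is None:
                    if not self.acknowledge_missing_splines:
                        raise EquationSchemaError(
                            f"indices.{idx}.{pname}: declares an age spline but carries no "
                            "knot table; set acknowledge_missing_splines=true to evaluate "
                            "with the spline contribution approximated as zero"
                        )

    def __getitem__(self, index: str) -> IndexModel:
        return self.indices[normalize_index(index)]


@dataclass(frozen=True)
class Subject:
    """Demographics needed to evaluate an equation set."""

    sex: str
    age: float
    height: float

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not self.age > 0:
            raise ValueError("age must be > 0 years")
        if not self.height > 0:
            raise ValueError("height must be > 0 cm")


@dataclass(frozen=True)
class SpiroRecord:
    """One participant: demographics, measured indices and questionnaire flags."""

    sex: str
    age: float
    height: float
    fev1: float
    fvc: float
    fev1_fvc: float
    fef2575: float
    current_smoker: bool = False
    lives_with_smoker: bool = False
    former_smoker: bool = False
    chronic_disease: bool = False
    pregnant: bool = False
    recent_surgery_or_acute_symptoms: bool = False

    def __post_init__(self):
        Subject(self.sex, self.age, self.height)
        object.__setattr__(self, "fev1_fvc", float(normalize_ratio(self.fev1_fvc)))
        if not (0.0 < self.fev1_fvc <= 1.0):
            raise ValueError("FEV1/FVC must normalize to a fraction in (0, 1]")
        if self.fev1 > self.fvc * (1.0 + 1e-9):
            raise ValueError("FEV1 cannot exceed FVC")

    @property
    def subject(self) -> Subject:
        return Subject(self.sex, self.age, self.height)

    def measured(self, index: str) -> float:
        return float(getattr(self, normalize_index(index)))


# ---------------------------------------------------------------------------
# evaluation

def _check_age_range(eq: EquationSet, age) -> None:
    lo, hi = eq.valid_age_range
    age = np.asarray(age, dtype=float)
    if np.any((age < lo) | (age > hi)):
        warnings.warn(
            f"age outside the {eq.name} validity range [{lo:g}, {hi:g}] years; "
            "spline contributions are clamped and extrapolation is unvalidated",
            stacklevel=3,
        )


def evaluate_parameter(m: ParameterModel, s: Subject):
    """Evaluate one parameter model for a subject (link-inverted)."""
    return float(m(s.height, s.age))


def predict_median(eq: EquationSet, s: Subject, index: str):
    """Predicted (median) value of an index for a subject: the mu model."""
    _check_age_range(eq, s.age)
    return float(eq[index].mu(s.height, s.age))


def percent_predicted(measured, predicted):
    """100 * measured / predicted — the classical percent-predicted scale."""
    return 100.0 * np.asarray(measured, dtype=float) / np.asarray(predicted, dtype=float)


def zscore_for(eq: EquationSet, rec: SpiroRecord, index: str):
    """Z-score of a record's measurement under the set's subject-specific distribution."""
    index = normalize_index(index)
    y = rec.measured(index)
    if not y > 0:
        raise ValueError(f"measured {index} must be > 0")
    _check_age_range(eq, rec.age)
    p = eq[index].params_at(rec.height, rec.age)
    return float(zscore(y, p))


def lln_for(eq: EquationSet, s: Subject, index: str, centile: float = 0.05):
    """Lower limit of normal of an index for a subject (default 5th centile)."""
    _check_age_range(eq, s.age)
    p = eq[index].params_at(s.height, s.age)
    return float(quantile(centile, p))


# ---------------------------------------------------------------------------
# JSON serialization

def _parameter_to_dict(pm: ParameterModel) -> dict:
    return {
        "link": pm.link,
        "intercept": pm.intercept,
        "beta_log_height": pm.beta_log_height,
        "beta_log_age": pm.beta_log_age,
        "spline": None
        if pm.spline is None
        else {"age_knots": list(pm.spline.age_knots), "values": list(pm.spline.values)},
        "spline_declared": pm.spline_declared,
    }


def _parameter_from_dict(doc: dict, path: str) -> ParameterModel:
    if not isinstance(doc, dict):
        raise EquationSchemaError(f"{path}: expected an object")
    try:
        spline_doc = doc.get("spline")
        spline = (
            None
            if spline_doc is None
            else SplineTable(tuple(spline_doc["age_knots"]), tuple(spline_doc["values"]))
        )
        return ParameterModel(
            link=doc["link"],
            intercept=float(doc["intercept"]),
            beta_log_height=float(doc.get("beta_log_height", 0.0)),
            beta_log_age=float(doc.get("beta_log_age", 0.0)),
            spline=spline,
            spline_declared=bool(doc.get("spline_declared", False)),
        )
    except KeyError as exc:
        raise EquationSchemaError(f"{path}: missing field {exc.args[0]!r}") from exc
    except EquationSchemaError as exc:
        raise EquationSchemaError(f"{path}: {exc}") from exc


def equation_set_to_dict(eq: EquationSet) -> dict:
    doc = {
        "schema_version": 1,
        "name": eq.name,
        "sex": eq.sex,
        "valid_age_range": list(eq.valid_age_range),
        "acknowledge_missing_splines": eq.acknowledge_missing_splines,
        "indices": {},
    }
    for idx in INDICES:
        model = eq.indices[idx]
        entry = {"family": model.family}
        for pname in _PARAM_NAMES:
            pm = getattr(model, pname)
            if pm is not None:
                entry[pname] = _parameter_to_dict(pm)
        doc["indices"][idx] = entry
    return doc


def equation_set_from_dict(doc: dict) -> EquationSet:
    if not isinstance(doc, dict):
        raise EquationSchemaError("equation set document must be a JSON object")
    for fieldname in ("name", "sex", "indices"):
        if fieldname not in doc:
            raise EquationSchemaError(f"missing top-level field {fieldname!r}")
    indices = {}
    for idx, entry in doc["indices"].items():
        key = normalize_index(idx)
        path = f"indices.{key}"
        if "family" not in entry:
            raise EquationSchemaError(f"{path}: missing field 'family'")
        family = entry["family"]
        if family not in _FAMILIES:
            raise EquationSchemaError(f"{path}.family: unknown family {family!r}")
        kwargs = {}
        for pname in _PARAM_NAMES:
            if pname in entry and entry[pname] is not None:
                kwargs[pname] = _parameter_from_dict(entry[pname], f"{path}.{pname}")
        if "mu" not in kwargs or "sigma" not in kwargs:
            raise EquationSchemaError(f"{path}: mu and sigma models are required")
        if family == "BCPE" and "tau" not in kwargs:
            raise EquationSchemaError(f"{path}: family BCPE requires a tau model")
        try:
            indices[key] = IndexModel(family=family, **kwargs)
        except EquationSchemaError as exc:
            raise EquationSchemaError(f"{path}: {exc}") from exc
    return EquationSet(
        name=str(doc["name"]),
        sex=str(doc["sex"]),
        indices=indices,
        valid_age_range=tuple(doc.get("valid_age_range", (18.0, 70.0))),
        acknowledge_missing_splines=bool(doc.get("acknowledge_missing_splines", False)),
    )


def load_equation_set(source) -> EquationSet:
    """Load an equation set from a path, file object, JSON string or dict."""
    if isinstance(source, dict):
        return equation_set_from_dict(source)
    if hasattr(source, "read"):
        return equation_set_from_dict(json.load(source))
    text = str(source)
    if text.lstrip().startswith("{"):
        return equation_set_from_dict(json.loads(text))
    with open(text, "r", encoding="utf-8") as fh:
        return equation_set_from_dict(json.load(fh))


def save_equation_set(eq: EquationSet, sink) -> None:
    """Write an equation set as JSON (round-trip stable)."""
    doc = equation_set_to_dict(eq)
    if hasattr(sink, "write"):
        json.dump(doc, sink, indent=2, sort_keys=True)
    else:
        with open(str(sink), "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_ise(sex: str | None = None):
    """Packaged Iraqi Spirometric Equations.

    ``load_ise('male')`` / ``load_ise('female')`` return one set;
    ``load_ise()`` returns the ``{'male': ..., 'female': ...}`` pair.
    """
    if sex is None:
        return {"male": load_ise("male"), "female": load_ise("female")}
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    ref = resources.files("spirolms.data") / f"ise_{sex}.json"
    return equation_set_from_dict(json.loads(ref.read_text(encoding="utf-8")))
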