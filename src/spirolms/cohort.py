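"""Synthetic cohorts with the demographic structure of an adult spirometry study.

The generator emulates a two-sex adult reference population: right-skewed
age distributions (mass concentrated in the twenties/thirties, a long
tail toward old age), sex-specific height distributions, and spirometric
outcomes drawn from the BCCG/BCPE models of a "truth" equation set at
each subject's own (mu, sigma, nu[, tau]).  FVC and the FEV1/FVC ratio
are drawn directly (with a negative cross-correlation, since larger
lungs empty proportionally slower) and FEV1 is derived as ratio x FVC so
the physical constraint FEV1 <= FVC always holds.

A cohort is carried as a pandas DataFrame with one row per subject and
the documented CSV header; helpers convert to/from lists of
:class:`~spirolms.equations.SpiroRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import draw_within_support
from .equations import (
    EXCLUSION_FLAGS,
    INDICES,
    EquationSet,
    SpiroRecord,
    load_ise,
    normalize_ratio,
)

__all__ = [
    "COHORT_COLUMNS",
    "AgeModel",
    "HeightModel",
    "CohortSpec",
    "generate_cohort",
    "apply_inclusion_filters",
    "split_phases",
    "cohort_to_records",
    "records_to_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

COHORT_COLUMNS = (
    "sex",
    "age_years",
    "height_cm",
    "fev1_l",
    "fvc_l",
    "ratio",
    "fef2575_ls",
) + EXCLUSION_FLAGS

_NUMERIC = ("age_years", "height_cm", "fev1_l", "fvc_l", "ratio", "fef2575_ls")


@dataclass(frozen=True)
class AgeModel:
    """Shifted log-normal age model truncated to [lo, hi] years.

    age = lo + LogNormal(log_median, log_sd), resampled until inside the
    range — a right-skewed shape whose median and quartiles are
    calibrated to the study population (young adults dominate).
    """

    log_median: float
    log_sd: float
    lo: float = 18.0
    hi: float = 70.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = self.lo + np.exp(rng.normal(self.log_median, self.log_sd, size=2 * (n - filled)))
            draw = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out


@dataclass(frozen=True)
class HeightModel:
    """Normal height model (cm) truncated to the observed range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=2 * (n - filled))
            draw = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out


# Defaults calibrated to the derivation-cohort descriptives: male median age
# 28.6 y (Q1-Q3 22.7-40.7), female 34.8 y (24.3-45.9); median heights 174 cm
# (males, range 155-193) and 157 cm (females, range 154-176); IQR-matched SDs.
_DEFAULT_AGE = {
    "male": AgeModel(log_median=float(np.log(28.57 - 18.0)), log_sd=1.16),
    "female": AgeModel(log_median=float(np.log(34.79 - 18.0)), log_sd=1.10),
}
_DEFAULT_HEIGHT = {
    "male": HeightModel(mean=174.0, sd=5.93, lo=155.0, hi=193.0),
    "female": HeightModel(mean=157.0, sd=5.19, lo=154.0, hi=176.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a reproducible synthetic cohort."""

    n: int
    female_fraction: float = 0.331
    age_models: dict = field(default_factory=lambda: dict(_DEFAULT_AGE))
    height_models: dict = field(default_factory=lambda: dict(_DEFAULT_HEIGHT))
    truth: dict | None = None  # sex -> EquationSet; defaults to the packaged ISE
    exclusion_prevalence: dict = field(default_factory=dict)  # flag -> probability
    ratio_fvc_correlation: float = -0.4
    seed: int = 0

    def __post_init__(self):
        if not self.n > 0:
            raise ValueError("n must be > 0")
        if not 0.0 < self.female_fraction < 1.0:
            raise ValueError("female_fraction must lie in (0, 1)")
        for flag, p in self.exclusion_prevalence.items():
            if flag not in EXCLUSION_FLAGS:
                raise ValueError(f"unknown exclusion flag {flag!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {flag!r} must lie in [0, 1]")
        if not -1.0 < self.ratio_fvc_correlation < 1.0:
            raise ValueError("ratio_fvc_correlation must lie in (-1, 1)")

    def resolved_truth(self) -> dict:
        truth = self.truth if self.truth is not None else load_ise()
        for sex in ("male", "female"):
            if sex not in truth:
                raise ValueError(f"truth equation set missing for sex {sex!r}")
            eq = truth[sex]
            missing = [k for k in INDICES if k not in eq.indices]
            if missing:
                raise ValueError(f"truth set for {sex} missing indices {missing}")
        return truth


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort DataFrame from a :class:`CohortSpec` (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    truth = spec.resolved_truth()

    n_female = int(round(spec.n * spec.female_fraction))
    n_female = min(max(n_female, 1), spec.n - 1) if spec.n > 1 else n_female
    sexes = np.array(["male"] * (spec.n - n_female) + ["female"] * n_female)
    rng.shuffle(sexes)

    age = np.empty(spec.n)
    height = np.empty(spec.n)
    fvc = np.empty(spec.n)
    ratio = np.empty(spec.n)
    fef = np.empty(spec.n)

    rho = spec.ratio_fvc_correlation
    for sex in ("male", "female"):
        mask = sexes == sex
        m = int(mask.sum())
        if m == 0:
            continue
        age[mask] = spec.age_models[sex].sample(m, rng)
        height[mask] = spec.height_models[sex].sample(m, rng)
        eq: EquationSet = truth[sex]
        z_fvc = rng.standard_normal(m)
        z_ratio = rho * z_fvc + np.sqrt(1.0 - rho * rho) * rng.standard_normal(m)
        z_fef = rng.standard_normal(m)
        h, a = height[mask], age[mask]
        fvc[mask] = draw_within_support(z_fvc, eq["fvc"].params_at(h, a))
        ratio[mask] = draw_within_support(z_ratio, eq["fev1_fvc"].params_at(h, a))
        fef[mask] = draw_within_support(z_fef, eq["fef2575"].params_at(h, a))

    # physical bound: the ratio model is unbounded above, real ratios are not
    ratio = np.minimum(ratio, 1.0)
    fev1 = ratio * fvc

    data = {
        "sex": sexes,
        "age_years": age,
        "height_cm": height,
        "fev1_l": fev1,
        "fvc_l": fvc,
        "ratio": ratio,
        "fef2575_ls": fef,
    }
    for flag in EXCLUSION_FLAGS:
        p = spec.exclusion_prevalence.get(flag, 0.0)
        raised = rng.random(spec.n) < p if p > 0 else np.zeros(spec.n, dtype=bool)
        if flag == "pregnant":
            raised &= sexes == "female"
        data[flag] = raised
    df = pd.DataFrame(data, columns=list(COHORT_COLUMNS))
    df.attrs["cohort_spec"] = {
        "n": spec.n,
        "female_fraction": spec.female_fraction,
        "seed": spec.seed,
        "age_model": "shifted lognormal, truncated [18, 70]",
        "ratio_fvc_correlation": rho,
    }
    return df


# ---------------------------------------------------------------------------
# eligibility filter

def apply_inclusion_filters(records):
    """Partition records into (kept, excluded-with-reason).

    A record is kept iff age >= 18 and every questionnaire exclusion flag
    is false.  Excluded records carry their first matching reason, with
    precedence following the eligibility-criteria listing order.
    Accepts a cohort DataFrame or a list of SpiroRecord; returns the same
    kind.  Pure partition: kept + excluded reassemble the input, and the
    operation is idempotent.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        reason = pd.Series([""] * len(df), index=df.index, dtype=object)
        under_age = df["age_years"] < 18.0
        reason[under_age] = "under_18"
        for flag in EXCLUSION_FLAGS:
            hit = df[flag].astype(bool) & (reason == "")
            reason[hit] = flag
        kept = df[reason == ""].copy()
        excluded = df[reason != ""].copy()
        excluded["exclusion_reason"] = reason[reason != ""]
        return kept, excluded

    kept, excluded = [], []
    for rec in records:
        why = None
        if rec.age < 18.0:
            why = "under_18"
        else:
            for flag in EXCLUSION_FLAGS:
                if getattr(rec, flag):
                    why = flag
                    break
        if why is None:
            kept.append(rec)
        else:
            excluded.append((rec, why))
    return kept, excluded


def split_phases(cohort: pd.DataFrame, n_validation: int, min_per_sex: int, seed: int = 0):
    """Split a cohort into disjoint (derivation, validation) frames.

    The validation sample has exactly ``n_validation`` subjects with at
    least ``min_per_sex`` of each sex (stratified draw); raises if the
    cohort cannot satisfy the minima.
    """
    rng = np.random.default_rng(seed)
    if n_validation < 2 * min_per_sex:
        raise ValueError(
            f"n_validation={n_validation} cannot contain {min_per_sex} of each sex"
        )
    if n_validation > len(cohort):
        raise ValueError("n_validation exceeds the cohort size")
    idx_by_sex = {
        sex: cohort.index[cohort["sex"] == sex].to_numpy() for sex in ("male", "female")
    }
    for sex, idx in idx_by_sex.items():
        if idx.size < min_per_sex:
            raise ValueError(
                f"cohort has only {idx.size} {sex} subjects; needs >= {min_per_sex}"
            )
    chosen = []
    pool = []
    for sex in ("male", "female"):
        perm = rng.permutation(idx_by_sex[sex])
        chosen.append(perm[:min_per_sex])
        pool.append(perm[min_per_sex:])
    pool = np.concatenate(pool)
    extra = n_validation - 2 * min_per_sex
    if extra > pool.size:
        raise ValueError("cohort too small for the requested validation size")
    chosen.append(rng.permutation(pool)[:extra])
    val_idx = np.concatenate(chosen)
    validation = cohort.loc[np.sort(val_idx)]
    derivation = cohort.drop(index=val_idx)
    return derivation, validation


# ---------------------------------------------------------------------------
# record/frame/CSV plumbing

def cohort_to_records(cohort: pd.DataFrame) -> list:
    return [
        SpiroRecord(
            sex=row["sex"],
            age=float(row["age_years"]),
            height=float(row["height_cm"]),
            fev1=float(row["fev1_l"]),
            fvc=float(row["fvc_l"]),
            fev1_fvc=float(row["ratio"]),
            fef2575=float(row["fef2575_ls"]),
            **{flag: bool(row[flag]) for flag in EXCLUSION_FLAGS},
        )
        for _, row in cohort.iterrows()
    ]


def records_to_cohort(records) -> pd.DataFrame:
    rows = [
        {
            "sex": r.sex,
            "age_years": r.age,
            "height_cm": r.height,
            "fev1_l": r.fev1,
            "fvc_l": r.fvc,
            "ratio": r.fev1_fvc,
            "fef2575_ls": r.fef2575,
            **{flag: getattr(r, flag) for flag in EXCLUSION_FLAGS},
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort_csv(cohort: pd.DataFrame, sink) -> None:
    """UTF-8, comma-separated, '.' decimal, header required."""
    out = cohort.loc[:, list(COHORT_COLUMNS)].copy()
    for flag in EXCLUSION_FLAGS:
        out[flag] = out[flag].astype(bool)
    text = out.to_csv(index=False, lineterminator="\n")
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(str(sink), "w", encoding="utf-8", newline="") as fh:
            fh.write(text)


def read_cohort_csv(source) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending line."""
    df = pd.read_csv(source if hasattr(source, "read") else str(source))
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        line = int(df.index[bad_sex][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"line {line}: sex must be 'male' or 'female'")
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"line {line}: column {col!r} is not a finite number")
        df[col] = vals.astype(float)
    df["ratio"] = normalize_ratio(df["ratio"].to_numpy())
    for flag in EXCLUSION_FLAGS:
        df[flag] = df[flag].astype(bool)
    return df.loc[:, list(COHORT_COLUMNS)]
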