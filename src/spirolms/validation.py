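"""Validation-phase statistics for reference-equation sets.

Given an independent cohort and a candidate equation set, these
operations compute per-index summaries of predicted values, percent
predicted and z-scores; apply the |mean z| < 0.5 population-suitability
rule; rank competing equation sets; and run the supporting tests
(Mann-Whitney U between study phases, Kolmogorov-Smirnov residual
normality, minimum validation-sample size).

Summary convention: reference-equation reports usually print
"median (Q1-Q3)" for predicted values/percents but "mean (SD)" for
z-scores (the suitability rule is about the mean); both z summaries are
emitted.  Quantiles use linear interpolation (numpy default / type 7).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .distributions import zscore
from .equations import INDICES, EquationSet, normalize_index, percent_predicted
from .gamlss import _INDEX_COLUMN

__all__ = [
    "ZSummary",
    "summarize_validation",
    "validate_cohort",
    "suitability_check",
    "compare_equation_sets",
    "mann_whitney_u",
    "sample_size_check",
    "ks_normality",
    "validation_report",
]


@dataclass(frozen=True)
class ZSummary:
    """Per-index, per-sex validation summary (one table row)."""

    index: str
    sex: str
    n: int
    mean_z: float
    sd_z: float
    median_z: float
    q1_z: float
    q3_z: float
    median_predicted: float
    q1_predicted: float
    q3_predicted: float
    median_percent: float
    q1_percent: float
    q3_percent: float

    def as_dict(self) -> dict:
        return asdict(self)


def _q(values, p):
    return float(np.quantile(values, p))  # linear interpolation (type 7)


def summarize_validation(eq: EquationSet, cohort: pd.DataFrame, index: str) -> ZSummary:
    """Predicted value / percent / z-score summary of one index on a cohort.

    Records of the other sex are ignored (an equation set is
    sex-specific); only rows with a positive measurement enter.
    """
    index = normalize_index(index)
    col = _INDEX_COLUMN[index]
    sub = cohort[(cohort["sex"] == eq.sex)]
    sub = sub[np.isfinite(sub[col]) & (sub[col] > 0)]
    if len(sub) == 0:
        raise ValueError(f"no usable {eq.sex} records with positive {index}")
    y = sub[col].to_numpy(dtype=float)
    h = sub["height_cm"].to_numpy(dtype=float)
    a = sub["age_years"].to_numpy(dtype=float)
    model = eq[index]
    predicted = np.asarray(model.mu(h, a), dtype=float)
    pct = percent_predicted(y, predicted)
    z = np.asarray(zscore(y, model.params_at(h, a)), dtype=float)
    return ZSummary(
        index=index,
        sex=eq.sex,
        n=int(y.size),
        mean_z=float(np.mean(z)),
        sd_z=float(np.std(z, ddof=1)) if y.size > 1 else 0.0,
        median_z=_q(z, 0.5),
        q1_z=_q(z, 0.25),
        q3_z=_q(z, 0.75),
        median_predicted=_q(predicted, 0.5),
        q1_predicted=_q(predicted, 0.25),
        q3_predicted=_q(predicted, 0.75),
        median_percent=_q(pct, 0.5),
        q1_percent=_q(pct, 0.25),
        q3_percent=_q(pct, 0.75),
    )


def validate_cohort(equations: dict, cohort: pd.DataFrame) -> list:
    """All index/sex summaries for a {'male': set, 'female': set} pair."""
    out = []
    for sex in ("male", "female"):
        if sex not in equations or not (cohort["sex"] == sex).any():
            continue
        for index in INDICES:
            out.append(summarize_validation(equations[sex], cohort, index))
    return out


def suitability_check(summary: ZSummary, cutoff: float = 0.5):
    """GLI-style population suitability: pass iff |mean z| strictly < cutoff.

    Returns (passed, margin) with margin = cutoff - |mean z| (negative
    when failing).
    """
    margin = cutoff - abs(summary.mean_z)
    return margin > 0.0, margin


def compare_equation_sets(cohort: pd.DataFrame, sets: dict, index: str) -> pd.DataFrame:
    """Rank named equation sets on one index by |mean z| (tie: |SD - 1|).

    Negative mean z means the set overestimates (predictions sit above
    the measurements); positive means it underestimates.  Returns a
    DataFrame ordered best first with rank 1 at the top.
    """
    if not sets:
        raise ValueError("no equation sets supplied")
    rows = []
    for name, eq in sets.items():
        s = summarize_validation(eq, cohort, index)
        rows.append(
            {
                "equation_set": name,
                **s.as_dict(),
                "abs_mean_z": abs(s.mean_z),
                "bias": "overestimates"
                if s.mean_z < 0
                else ("underestimates" if s.mean_z > 0 else "unbiased"),
                "suitable": suitability_check(s)[0],
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["abs_mean_z", "sd_z"],
        key=lambda col: col if col.name == "abs_mean_z" else (col - 1.0).abs(),
        kind="stable",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _u_from_ranks(ranks, n_a):
    r_a = float(np.sum(ranks[:n_a]))
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney_u(sample_a, sample_b, *, exact_limit: int = 8, max_enumeration: int = 500_000):
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties.  When the
    smaller sample has at most ``exact_limit`` observations (and the
    enumeration is tractable) the two-sided p-value is exact, by
    enumerating all assignments of the pooled ranks; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction is used.  Returns ``(U, z, p)``; z is nan in the exact
    branch.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u = _u_from_ranks(ranks, n_a)
    mean_u = n_a * n_b / 2.0

    use_exact = min(n_a, n_b) <= exact_limit and math.comb(n_a + n_b, n_a) <= max_enumeration
    if use_exact:
        dev = abs(u - mean_u)
        count = 0
        total = 0
        idx = range(n_a + n_b)
        for combo in itertools.combinations(idx, n_a):
            r_a = ranks[list(combo)].sum()
            u_perm = r_a - n_a * (n_a + 1) / 2.0
            if abs(u_perm - mean_u) >= dev - 1e-12:
                count += 1
            total += 1
        return float(u), float("nan"), count / total

    # tie-corrected variance
    n = n_a + n_b
    _, t = np.unique(pooled, return_counts=True)
    tie_term = np.sum(t**3 - t) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(u), 0.0, 1.0
    # continuity correction toward the mean
    dev = abs(u - mean_u)
    z = max(dev - 0.5, 0.0) / np.sqrt(var_u)
    p = 2.0 * special.ndtr(-z)
    return float(u), float(np.sign(u - mean_u) * z), min(p, 1.0)


# ---------------------------------------------------------------------------

def sample_size_check(cohort: pd.DataFrame, total_min: int = 300, per_sex_min: int = 150) -> dict:
    """Minimum validation-sample rule: >= 300 subjects, >= 150 per sex."""
    n_male = int((cohort["sex"] == "male").sum())
    n_female = int((cohort["sex"] == "female").sum())
    n = n_male + n_female
    failures = []
    if n < total_min:
        failures.append(f"total {n} < {total_min}")
    if n_male < per_sex_min:
        failures.append(f"males {n_male} < {per_sex_min}")
    if n_female < per_sex_min:
        failures.append(f"females {n_female} < {per_sex_min}")
    return {
        "n": n,
        "n_male": n_male,
        "n_female": n_female,
        "passed": not failures,
        "failures": failures,
    }


def ks_normality(values):
    """One-sample Kolmogorov-Smirnov test against the standard normal."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    res = stats.kstest(values, "norm", mode="asymp")
    return float(res.statistic), float(res.pvalue)


def validation_report(equations: dict, cohort: pd.DataFrame, cutoff: float = 0.5) -> dict:
    """JSON-ready validation report mirroring the per-index/sex table layout."""
    summaries = validate_cohort(equations, cohort)
    rows = []
    for s in summaries:
        passed, margin = suitability_check(s, cutoff)
        rows.append({**s.as_dict(), "suitable": passed, "margin": margin})
    return {
        "cutoff": cutoff,
        "sample": sample_size_check(cohort),
        "rows": rows,
        "all_suitable": all(r["suitable"] for r in rows),
    }
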