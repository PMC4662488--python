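"""Cohort summaries and normality-gated correlation with tumor T stage.

The T component of a TNM string (tumor size/extent, T1-T4) is treated as a
numeric 1-4 score for correlation. Feature levels are first checked with the
Shapiro-Wilk normality test; Pearson correlation is used for normally
distributed levels and nonparametric Spearman otherwise, which also makes
the ordinal encoding of T stage safe.
"""

from __future__ import annotations

import math
import re

from scipy import stats

from .core import CohortRecord, DegenerateInputError, InputError

_TNM_RE = re.compile(r"^T([1-4])N([0-3])M([01])$")

DEFAULT_NORMALITY_ALPHA = 0.05


def parse_t_stage(tnm: str) -> int:
    """Extract the integer T component from a TNM string like ``T4N2M0``."""
    match = _TNM_RE.match(str(tnm).strip())
    if not match:
        raise InputError(f"malformed TNM string {tnm!r}")
    return int(match.group(1))


def format_tnm(t: int, n: int = 0, m: int = 0) -> str:
    s = f"T{t}N{n}M{m}"
    parse_t_stage(s)
    return s


def cohort_summary(records: list) -> dict:
    """Per-group subject count, mean age and sample (n-1) SD, to one decimal.

    A single-subject group reports SD as ``None`` (not estimable).
    """
    groups: dict = {}
    for rec in records:
        groups.setdefault(rec.group, []).append(rec.age)
    if not groups:
        raise InputError("empty cohort")
    out = {}
    for grp, ages in groups.items():
        n = len(ages)
        mean = sum(ages) / n
        if n > 1:
            sd = math.sqrt(sum((a - mean) ** 2 for a in ages) / (n - 1))
            sd = round(sd, 1)
        else:
            sd = None
        out[grp] = {"n": n, "mean_age": round(mean, 1), "sd_age": sd}
    return out


def correlate_with_stage(
    levels: dict, stages: dict, alpha: float = DEFAULT_NORMALITY_ALPHA
) -> dict:
    """Correlate per-subject feature levels with T stage, gated on normality.

    Shapiro-Wilk is run on the paired levels; if its p >= ``alpha`` the
    levels are treated as normal and Pearson correlation is used, otherwise
    Spearman. Returns method, r, two-sided p and the normality p.
    """
    subjects = sorted(set(levels) & set(stages))
    if len(subjects) < 4:
        raise InputError("need >= 4 paired observations")
    x = [float(levels[s]) for s in subjects]
    y = [float(stages[s]) for s in subjects]
    if len(set(y)) < 2:
        raise DegenerateInputError("all T stages equal")
    if len(set(x)) < 2:
        raise DegenerateInputError("feature levels are constant")
    sw_stat, sw_p = stats.shapiro(x)
    if sw_p >= alpha:
        method = "pearson"
        r, p = stats.pearsonr(x, y)
    else:
        method = "spearman"
        r, p = stats.spearmanr(x, y)
    return {
        "method": method,
        "r": float(r),
        "pvalue": float(p),
        "normality_p": float(sw_p),
        "n": len(subjects),
    }


def records_from_frame(df) -> list:
    """Build cohort records from a Table-1-style DataFrame."""
    records = []
    for _, row in df.iterrows():
        tnm = row.get("tnm")
        tnm = None if (tnm is None or (isinstance(tnm, float) and math.isnan(tnm)) or tnm in ("", "N/A")) else str(tnm)
        loc = row.get("localization")
        loc = None if (loc is None or (isinstance(loc, float) and math.isnan(loc)) or loc in ("", "N/A")) else str(loc)
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=int(row["age"]),
                tnm=tnm,
                localization=loc,
            )
        )
    return records
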