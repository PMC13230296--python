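"""Cohort-level statistics for the segmentation audit.

Calcium burden is stratified into the conventional Agatston bins
(0 / 1-99 / 100-399 / >=400).  Associations between Dice scores and image
quality or vessel geometry are Pearson correlations with two-sided
p-values from the t transform on n-2 degrees of freedom; group contrasts
are Welch's t-tests (unequal variances, Welch-Satterthwaite df).
Significance is flagged at p < 0.05 with NO multiplicity correction: the
analysis is exploratory and every raw p-value is reported alongside its n.
Cells with fewer than 3 observations (or zero variance) are reported as
not-estimable rather than dropped or raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05

STRATA = ("none", "low", "moderate", "high")


@dataclass(frozen=True)
class CalciumStratum:
    value: str

    def __post_init__(self) -> None:
        if self.value not in STRATA:
            raise ValueError(f"unknown calcium stratum {self.value!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    x_name: str = "x"
    y_name: str = "y"

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def stratify_calcium(score: float) -> CalciumStratum:
    """Bin an Agatston-type calcium score: 0 / 1-99 / 100-399 / >=400.

    Non-integer scores in (0, 1) fall into the low stratum: any non-zero
    burden counts as calcified.
    """
    if score < 0:
        raise ValueError("calcium score must be non-negative")
    if score == 0:
        return CalciumStratum("none")
    if score < 100:
        return CalciumStratum("low")
    if score < 400:
        return CalciumStratum("moderate")
    return CalciumStratum("high")


def pearson(x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Sample Pearson correlation with two-sided p from t on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("pearson needs n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0 or syy == 0:
        raise ValueError("undefined correlation: zero variance in x or y")
    r = float(xd @ yd) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrelationResult(r=r, p=float(p), n=n, x_name=x_name, y_name=y_name)


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with sample (ddof=1)
    variances; degrees of freedom by Welch-Satterthwaite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if va == 0 and vb == 0:
        if float(a.mean()) == float(b.mean()):
            return WelchResult(0.0, float(na + nb - 2), 1.0, float(a.mean()), float(b.mean()), 0.0, 0.0, na, nb)
        raise ValueError("zero variance in both groups with unequal means")
    sa2, sb2 = va / na, vb / nb
    t = (float(a.mean()) - float(b.mean())) / math.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(
        t=float(t), df=float(df), p=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=na, n_b=nb,
    )


# ---------------------------------------------------------------------------
# cohort analysis over CaseRecord rows (defined in pipeline to avoid cycles;
# any object with the required attributes works)

_QUALITY_VARS = ("cnr", "contrast_enhancement", "edge_sharpness")


def _not_estimable(n: int, x_name: str, y_name: str) -> dict:
    return {"x": x_name, "y": y_name, "r": None, "p": None, "n": n, "estimable": False, "significant": False}


def _corr_cell(x: list[float], y: list[float], x_name: str, y_name: str) -> dict:
    pairs = [(a, b) for a, b in zip(x, y) if a is not None and b is not None
             and np.isfinite(a) and np.isfinite(b)]
    if len(pairs) < 3:
        return _not_estimable(len(pairs), x_name, y_name)
    xs, ys = zip(*pairs)
    try:
        res = pearson(xs, ys, x_name, y_name)
    except ValueError:
        return _not_estimable(len(pairs), x_name, y_name)
    return {"x": x_name, "y": y_name, "r": res.r, "p": res.p, "n": res.n,
            "estimable": True, "significant": res.significant}


def cohort_analysis(records: Iterable) -> dict:
    """The full statistical report over per-case records.

    Returns a dict with three blocks:

    * ``quality_correlations`` — Pearson r/p of tree DSC against CNR,
      contrast enhancement and edge sharpness, over all cases;
    * ``calcium_welch`` — per calcium stratum, Welch's t-test of tree DSC
      between the two cohorts present in the records;
    * ``branch_geometry_correlations`` — per branch and per sex, Pearson
      r/p of branch DSC against branch mean diameter and mean |curvature|.

    Cells with n < 3 per group (or degenerate variance) are flagged
    ``estimable: false``.  Output is invariant to record order.
    """
    recs = sorted(records, key=lambda r: str(getattr(r, "id", "")))
    if len(recs) < 3:
        raise ValueError("cohort_analysis needs >= 3 records")

    # --- tree DSC vs image-quality metrics ---------------------------------
    dsc = [getattr(r, "tree_dsc", None) for r in recs]
    quality_rows = [
        _corr_cell([getattr(r, var, None) for r in recs], dsc, var, "tree_dsc")
        for var in _QUALITY_VARS
    ]

    # --- Welch tests of tree DSC between cohorts per calcium stratum -------
    cohorts = sorted({r.cohort for r in recs if getattr(r, "cohort", None)})
    welch_rows = []
    for stratum in STRATA:
        row: dict = {"stratum": stratum}
        in_stratum = [r for r in recs if getattr(r, "calcium_stratum", None) == stratum]
        if len(cohorts) == 2:
            ga = [r.tree_dsc for r in in_stratum if r.cohort == cohorts[0] and r.tree_dsc is not None]
            gb = [r.tree_dsc for r in in_stratum if r.cohort == cohorts[1] and r.tree_dsc is not None]
            row.update(cohort_a=cohorts[0], cohort_b=cohorts[1], n_a=len(ga), n_b=len(gb))
            if len(ga) >= 3 and len(gb) >= 3:
                try:
                    w = welch_t(ga, gb)
                    row.update(t=w.t, df=w.df, p=w.p, mean_a=w.mean_a, sd_a=w.sd_a,
                               mean_b=w.mean_b, sd_b=w.sd_b, estimable=True,
                               significant=w.significant)
                except ValueError:
                    row.update(estimable=False, significant=False)
            else:
                row.update(estimable=False, significant=False)
        else:
            row.update(cohort_a=cohorts[0] if cohorts else None, cohort_b=None,
                       n_a=len(in_stratum), n_b=0, estimable=False, significant=False)
        welch_rows.append(row)

    # --- per-branch, sex-stratified geometry correlations ------------------
    branch_names = sorted({b for r in recs for b in (getattr(r, "branch_dsc", None) or {})})
    geo_rows = []
    for branch in branch_names:
        for sex in ("male", "female"):
            sel = [r for r in recs if getattr(r, "sex", None) == sex]
            bdsc = [(r.branch_dsc or {}).get(branch) for r in sel]
            for var, attr in (("mean_diameter", "branch_diameter"),
                              ("mean_abs_curvature", "branch_curvature")):
                vals = [(getattr(r, attr, None) or {}).get(branch) for r in sel]
                cell = _corr_cell(vals, bdsc, var, "branch_dsc")
                cell.update(branch=branch, sex=sex)
                geo_rows.append(cell)

    return {
        "alpha": ALPHA,
        "multiplicity_correction": "none",
        "quality_correlations": quality_rows,
        "calcium_welch": welch_rows,
        "branch_geometry_correlations": geo_rows,
    }
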