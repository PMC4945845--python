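"""Cohort-level statistics: group comparisons, pre/post bronchodilator
deltas, multiplicity correction across airway generations, and
structure--function correlation screens.

Group contrasts use the Welch (unequal-variance) two-sample t-test, either
from raw samples or from printed summary statistics (mean, SD, n); pre/post
contrasts use the paired t-test.  Tests repeated across airway generations
are Bonferroni-corrected.  Structure--function relationships are screened
with Pearson correlation plus an ordinary least-squares line.  All tests
are two-sided at alpha = 0.05 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .airways import GenerationSummary
from .density import DensityMetrics, percent_change

__all__ = [
    "SubjectRecord",
    "ComparisonResult",
    "independent_t",
    "independent_t_from_stats",
    "paired_t",
    "bonferroni_adjust",
    "correlate",
    "build_study_tables",
]

SPIRO_VARS = ("fvc_pct", "fev1_pct", "fef2575_pct", "pef_pct")
DENSITY_VARS = ("mean_hu", "skewness", "kurtosis", "fwhm", "pct_gt_m500")


@dataclass
class SubjectRecord:
    """One subject's physiology, density metrics and airway tables.

    ``post_*`` fields are absent (None) for subjects without a
    post-bronchodilator scan; those subjects contribute to baseline tables
    but are dropped from paired analyses.
    """

    subject_id: str
    group: str  # "control" | "hf"
    tlc: float  # L
    spirometry: dict[str, float] = field(default_factory=dict)  # % predicted
    pre_density: DensityMetrics | None = None
    post_density: DensityMetrics | None = None
    pre_generations: list[GenerationSummary] = field(default_factory=list)
    post_generations: list[GenerationSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("control", "hf"):
            raise ValueError(f"group must be 'control' or 'hf', got {self.group!r}")

    @property
    def has_post(self) -> bool:
        return self.post_density is not None


@dataclass
class ComparisonResult:
    variable: str
    mean_x: float
    sd_x: float
    n_x: int
    mean_y: float
    sd_y: float
    n_y: int
    t: float
    df: float
    p: float
    p_adjusted: float | None = None
    test: str = "independent"  # independent | paired
    significant: bool | None = None


def independent_t(x: np.ndarray, y: np.ndarray, variable: str = "") -> ComparisonResult:
    """Welch two-sample t-test between two raw samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = stats.ttest_ind(x, y, equal_var=False)
    return ComparisonResult(
        variable=variable,
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)), n_x=int(x.size),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)), n_y=int(y.size),
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
    )


def independent_t_from_stats(
    mean_x: float, sd_x: float, n_x: int,
    mean_y: float, sd_y: float, n_y: int,
    variable: str = "",
) -> ComparisonResult:
    """Welch t-test from summary statistics (mean, SD, n) per group —
    the form needed to recompute tests from printed tables."""
    if n_x < 2 or n_y < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = stats.ttest_ind_from_stats(
        mean_x, sd_x, n_x, mean_y, sd_y, n_y, equal_var=False
    )
    vx, vy = sd_x**2 / n_x, sd_y**2 / n_y
    df = (vx + vy) ** 2 / (vx**2 / (n_x - 1) + vy**2 / (n_y - 1))
    return ComparisonResult(
        variable=variable,
        mean_x=mean_x, sd_x=sd_x, n_x=n_x,
        mean_y=mean_y, sd_y=sd_y, n_y=n_y,
        t=float(t), df=float(df), p=float(p),
    )


def paired_t(pre: np.ndarray, post: np.ndarray, variable: str = "") -> ComparisonResult:
    """Paired t-test (one-sample t on post - pre differences)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"length mismatch: {pre.shape} vs {post.shape}")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = post - pre
    if np.ptp(diff) == 0:
        # zero-variance differences: identical pairs (t=0, p=1) or a
        # constant nonzero shift (degenerate, p -> 0)
        if diff[0] == 0:
            t, p = 0.0, 1.0
        else:
            t = float(np.sign(diff[0]) * np.inf)
            p = 0.0
    else:
        res = stats.ttest_rel(post, pre)
        t, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        variable=variable,
        mean_x=float(pre.mean()), sd_x=float(pre.std(ddof=1)), n_x=int(pre.size),
        mean_y=float(post.mean()), sd_y=float(post.std(ddof=1)), n_y=int(post.size),
        t=t, df=float(pre.size - 1), p=p, test="paired",
    )


def bonferroni_adjust(
    p_values: list[float] | np.ndarray,
    alpha: float = 0.05,
    m: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction across generation-level tests.

    Returns ``(adjusted, significant)`` with adjusted = min(1, p * m);
    ``m`` defaults to the number of p-values supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    adjusted = np.minimum(1.0, p * m)
    return adjusted, adjusted < alpha


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Pearson correlation and OLS line between two samples.

    Returns ``(r, slope, intercept, p)`` with the two-sided p-value of r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance sample")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept), float(res.pvalue)


# ---------------------------------------------------------------------------
# study tables


def _records_by_group(records: list[SubjectRecord]) -> dict[str, list[SubjectRecord]]:
    groups: dict[str, list[SubjectRecord]] = {"control": [], "hf": []}
    for r in records:
        groups[r.group].append(r)
    for g, rs in groups.items():
        if len(rs) < 2:
            raise ValueError(f"need at least 2 subjects in group {g!r}, got {len(rs)}")
    return groups


def build_study_tables(
    records: list[SubjectRecord],
    alpha: float = 0.05,
    max_generation: int = 6,
) -> dict[str, pd.DataFrame]:
    """Assemble the four cohort tables from per-subject records.

    * ``characteristics`` — group means +/- SD of TLC and spirometry with a
      Welch-test group-difference marker.
    * ``density`` — baseline density indices per group plus mean +/- SD of
      per-subject percent change after bronchodilator, with both a
      group-difference marker (Welch) and a change-from-zero marker
      (paired t on the baseline vs post values).
    * ``structure_function`` — per-group Pearson r between each airway
      generation's baseline luminal area and each spirometry variable.
    * ``baseline_vs_change`` — per-group Pearson r between each density
      index's baseline value and its percent change after bronchodilator.

    Subjects without a post scan are excluded from paired analyses only;
    ``exclusions`` lists them.
    """
    groups = _records_by_group(records)
    out: dict[str, pd.DataFrame] = {}

    # --- characteristics -------------------------------------------------
    rows = []
    for var in ("tlc",) + SPIRO_VARS:
        def get(r):
            return r.tlc if var == "tlc" else r.spirometry.get(var, np.nan)
        xc = np.array([get(r) for r in groups["control"]], dtype=float)
        xh = np.array([get(r) for r in groups["hf"]], dtype=float)
        if np.isnan(xc).all() or np.isnan(xh).all():
            continue
        res = independent_t(xc[~np.isnan(xc)], xh[~np.isnan(xh)], variable=var)
        rows.append({
            "variable": var,
            "control_mean": res.mean_x, "control_sd": res.sd_x, "n_control": res.n_x,
            "hf_mean": res.mean_y, "hf_sd": res.sd_y, "n_hf": res.n_y,
            "t": res.t, "p": res.p, "significant": res.p < alpha,
        })
    out["characteristics"] = pd.DataFrame(rows)

    # --- density indices: baseline and percent change --------------------
    rows = []
    for var in DENSITY_VARS:
        row: dict = {"variable": var}
        base = {}
        for g in ("control", "hf"):
            vals = np.array([getattr(r.pre_density, var) for r in groups[g]
                             if r.pre_density is not None], dtype=float)
            base[g] = vals
            row[f"{g}_baseline_mean"] = float(vals.mean())
            row[f"{g}_baseline_sd"] = float(vals.std(ddof=1))
        bres = independent_t(base["control"], base["hf"], variable=var)
        row["baseline_group_p"] = bres.p
        row["baseline_group_significant"] = bres.p < alpha
        for g in ("control", "hf"):
            paired = [r for r in groups[g] if r.has_post]
            if len(paired) >= 2:
                pc = np.array([
                    percent_change(r.pre_density, r.post_density)[var] for r in paired
                ], dtype=float)
                pres = paired_t(
                    np.array([getattr(r.pre_density, var) for r in paired]),
                    np.array([getattr(r.post_density, var) for r in paired]),
                    variable=var,
                )
                row[f"{g}_change_mean"] = float(np.nanmean(pc))
                row[f"{g}_change_sd"] = float(np.nanstd(pc, ddof=1))
                row[f"{g}_change_p"] = pres.p
                row[f"{g}_change_significant"] = pres.p < alpha
        rows.append(row)
    out["density"] = pd.DataFrame(rows)

    # --- structure-function correlations ---------------------------------
    rows = []
    for g in ("control", "hf"):
        for gen in range(1, max_generation + 1):
            areas, spiro_vals = [], {v: [] for v in SPIRO_VARS}
            for r in groups[g]:
                summ = next((s for s in r.pre_generations if s.generation == gen), None)
                if summ is None or summ.flag == "absent":
                    continue
                areas.append(summ.mean_area)
                for v in SPIRO_VARS:
                    spiro_vals[v].append(r.spirometry.get(v, np.nan))
            if len(areas) < 3:
                continue
            row = {"group": g, "generation": gen, "n": len(areas)}
            pvals = []
            for v in SPIRO_VARS:
                r_, slope, intercept, p_ = correlate(np.array(areas), np.array(spiro_vals[v]))
                row[f"r_{v}"] = r_
                row[f"p_{v}"] = p_
                pvals.append(p_)
            rows.append(row)
    sf = pd.DataFrame(rows)
    if not sf.empty:
        # Bonferroni across the generations within each group x variable
        for v in SPIRO_VARS:
            for g in ("control", "hf"):
                sel = sf["group"] == g
                adj, sig = bonferroni_adjust(sf.loc[sel, f"p_{v}"].to_numpy(),
                                             alpha=alpha, m=max_generation)
                sf.loc[sel, f"p_adj_{v}"] = adj
                sf.loc[sel, f"sig_{v}"] = sig
    out["structure_function"] = sf

    # --- baseline value vs percent change --------------------------------
    rows = []
    for g in ("control", "hf"):
        paired = [r for r in groups[g] if r.has_post]
        if len(paired) < 3:
            continue
        row = {"group": g, "n": len(paired)}
        for var in DENSITY_VARS:
            base = np.array([getattr(r.pre_density, var) for r in paired], dtype=float)
            chg = np.array([
                percent_change(r.pre_density, r.post_density)[var] for r in paired
            ], dtype=float)
            ok = np.isfinite(base) & np.isfinite(chg)
            if ok.sum() < 3 or np.ptp(base[ok]) == 0 or np.ptp(chg[ok]) == 0:
                row[f"r_{var}"] = np.nan
                continue
            r_, _, _, p_ = correlate(base[ok], chg[ok])
            row[f"r_{var}"] = r_
            row[f"p_{var}"] = p_
        rows.append(row)
    out["baseline_vs_change"] = pd.DataFrame(rows)

    # --- bookkeeping ------------------------------------------------------
    out["exclusions"] = pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group, "reason": "no post scan"}
         for r in records if not r.has_post]
    )
    return out
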