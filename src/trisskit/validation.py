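"""Validation of TRISS survival predictions: discrimination and calibration.

Three analyses on a scored cohort (each patient carrying a TRISS ``Ps`` and an
observed survival outcome):

1. **Descriptive comparison** across pediatric age groups (neonates/infants 0 y,
   preschool 1-5 y, schoolchildren 6-11 y, adolescents 12-18 y) with
   Mann-Whitney U / Kruskal-Wallis tests for continuous variables and Pearson
   chi-square for categorical ones.
2. **Threshold and ROC validation**: sensitivity, specificity, PPV, NPV and
   accuracy at a survival-probability threshold (default 0.5, survival is the
   positive class), plus the rank-based AUC with a DeLong large-sample 95% CI
   — overall and stratified by age group or Ps interval.
3. **Calibration by Ps interval**: six closed intervals (0.00-0.25, 0.26-0.50,
   0.51-0.75, 0.76-0.90, 0.91-0.95, 0.96-1.00); per interval the expected
   number of survivors is the (3-decimal) mean Ps times n, and the
   observed/expected (O/E) ratio flags miscalibration (O/E > 1: the model
   underestimates survival).

Display conventions follow trauma-registry reporting: percentages at one
decimal, half-up rounding, zero-denominator metrics printed as 0.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import round_half_up

__all__ = [
    "AGE_GROUPS",
    "PS_BINS",
    "AgeGroup",
    "PsBinSummary",
    "ConfusionSummary",
    "StratumResult",
    "ValidationReport",
    "GroupComparison",
    "ValidationError",
    "age_group_label",
    "assign_ps_bin",
    "classify_survival",
    "confusion_metrics",
    "auc_rank",
    "ps_bin_table",
    "bin_table_to_dataframe",
    "stratified_report",
    "compare_groups",
    "descriptive_table",
    "percent",
]


class ValidationError(ValueError):
    """Raised for degenerate validation inputs (empty cohort, single class)."""


def percent(numerator: float, denominator: float) -> float:
    """Percentage at one decimal, half-up — the tables' display convention.

    A zero denominator yields 0.0 (the degenerate-cell convention used in the
    threshold-metric tables).
    """
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# Strata: age groups and Ps intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeGroup:
    """A closed integer age band; the four defaults partition ages 0-18."""

    label: str
    lo: int
    hi: int

    def contains(self, age_years: int) -> bool:
        return self.lo <= age_years <= self.hi


AGE_GROUPS = (
    AgeGroup("neonates/infants", 0, 0),
    AgeGroup("preschool", 1, 5),
    AgeGroup("schoolchildren", 6, 11),
    AgeGroup("adolescents", 12, 18),
)


def age_group_label(age_years: int, groups: Sequence[AgeGroup] = AGE_GROUPS) -> Optional[str]:
    for g in groups:
        if g.contains(age_years):
            return g.label
    return None


#: The six closed Ps intervals, on the 2-decimal display lattice.
PS_BINS = (
    ("0.00-0.25", 0.00, 0.25),
    ("0.26-0.50", 0.26, 0.50),
    ("0.51-0.75", 0.51, 0.75),
    ("0.76-0.90", 0.76, 0.90),
    ("0.91-0.95", 0.91, 0.95),
    ("0.96-1.00", 0.96, 1.00),
)


def assign_ps_bin(ps: float) -> str:
    """Assign a survival probability to its Ps interval.

    ``ps`` is first rounded half-up to 2 decimals, then matched against the
    closed printed intervals; the rounding closes the gaps between interval
    labels (e.g. 0.253 → 0.25 → "0.00-0.25", 0.255 → 0.26 → "0.26-0.50"), so
    every value in (0, 1) maps to exactly one bin.
    """
    if not np.isfinite(ps):
        raise ValidationError(f"ps must be finite, got {ps!r}")
    r = round_half_up(ps, 2)
    for label, lo, hi in PS_BINS:
        # compare on the integer-cent lattice to dodge float edge noise
        if round(lo * 100) <= round(r * 100) <= round(hi * 100):
            return label
    raise ValidationError(f"ps out of (0,1): {ps!r}")


def classify_survival(ps: float, threshold: float = 0.5) -> bool:
    """Predict survival iff ``ps >= threshold`` (boundary counts as survivor)."""
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must be in (0,1), got {threshold!r}")
    return ps >= threshold


# ---------------------------------------------------------------------------
# Threshold (confusion) metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionSummary:
    """Threshold metrics (percent, 1 decimal; survival = positive class) plus AUC.

    ``auc``/``auc_ci`` are ``None`` when undefined (single outcome class).
    """

    n: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None


def confusion_metrics(predicted: Iterable[bool], actual: Iterable[bool]) -> ConfusionSummary:
    """Sensitivity/specificity/PPV/NPV/accuracy from predicted vs observed survival.

    Survival is the positive class.  Metrics with a zero denominator are
    reported as 0.0, matching the printed-table convention for degenerate
    strata (e.g. a bin where no patient is predicted to survive has PPV 0.0).
    """
    pred = np.asarray(list(predicted), dtype=bool)
    act = np.asarray(list(actual), dtype=bool)
    if pred.shape != act.shape or pred.size == 0:
        raise ValidationError("confusion_metrics needs n >= 1 aligned (predicted, actual) pairs")
    tp = int(np.sum(pred & act))
    tn = int(np.sum(~pred & ~act))
    fp = int(np.sum(pred & ~act))
    fn = int(np.sum(~pred & act))
    return ConfusionSummary(
        n=pred.size,
        sensitivity=percent(tp, tp + fn),
        specificity=percent(tn, tn + fp),
        ppv=percent(tp, tp + fp),
        npv=percent(tn, tn + fn),
        accuracy=percent(tp + tn, pred.size),
    )


# ---------------------------------------------------------------------------
# Rank-based AUC with DeLong confidence interval
# ---------------------------------------------------------------------------


def auc_rank(ps: Iterable[float], survived: Iterable[bool], alpha: float = 0.05):
    """AUC as the two-sample rank statistic, with a DeLong large-sample CI.

    AUC is the probability that a randomly chosen survivor has a higher Ps
    than a randomly chosen non-survivor, ties counted 1/2 — computed from
    midranks, so it equals exhaustive pairwise enumeration exactly.  The CI
    uses the DeLong structural-component variance estimate, truncated to
    [0, 1].

    Returns ``(auc, (lo, hi))``; raises :class:`ValidationError` when only one
    outcome class is present.
    """
    scores = np.asarray(list(ps), dtype=float)
    out = np.asarray(list(survived), dtype=bool)
    pos = scores[out]
    neg = scores[~out]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValidationError("AUC undefined: need at least one survivor and one non-survivor")
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos, r_neg = all_ranks[:m], all_ranks[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components: v10[i] = P(neg < pos_i) + P(neg == pos_i)/2
    v10 = (r_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Ps-interval calibration table (expected survivors, O/E)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsBinSummary:
    """Calibration summary of one Ps interval.

    ``expected_survivors_raw`` is the 3-decimal mean Ps times n (the unrounded
    product); ``expected_survivors_display`` rounds it half-up to an integer;
    ``oe_ratio`` divides observed by the *raw* expected count (``None`` when
    the bin is empty or expected is 0).
    """

    label: str
    n: int
    mean_ps: Optional[float]
    observed_survivors: int
    expected_survivors_raw: Optional[float]
    expected_survivors_display: Optional[int]
    oe_ratio: Optional[float]

    @classmethod
    def from_stats(cls, label: str, mean_ps: float, n: int, observed: int) -> "PsBinSummary":
        """Build a summary from a (mean Ps, n, observed survivors) triple."""
        if n == 0:
            return cls(label, 0, None, 0, None, None, None)
        if not (0 <= observed <= n):
            raise ValidationError(f"observed survivors must be in 0..n, got {observed}/{n}")
        mean3 = round_half_up(mean_ps, 3)
        expected_raw = mean3 * n
        oe = None if expected_raw == 0 else round_half_up(observed / expected_raw, 2)
        return cls(
            label=label,
            n=n,
            mean_ps=mean3,
            observed_survivors=observed,
            expected_survivors_raw=expected_raw,
            expected_survivors_display=int(round_half_up(expected_raw, 0)),
            oe_ratio=oe,
        )


def ps_bin_table(ps: Iterable[float], survived: Iterable[bool]) -> list[PsBinSummary]:
    """Calibration table over the six Ps intervals for a scored cohort.

    Per interval: n, mean Ps (3 decimals), observed survivors, expected
    survivors (mean Ps x n, displayed as a half-up integer) and the O/E ratio
    on the unrounded expected count.  Empty intervals yield n=0 rows with
    undefined (``None``) mean/expected/O-E.
    """
    scores = np.asarray(list(ps), dtype=float)
    out = np.asarray(list(survived), dtype=bool)
    if scores.size == 0:
        raise ValidationError("ps_bin_table needs a non-empty cohort")
    labels = np.array([assign_ps_bin(p) for p in scores])
    table = []
    for label, _, _ in PS_BINS:
        mask = labels == label
        n = int(mask.sum())
        if n == 0:
            table.append(PsBinSummary.from_stats(label, 0.0, 0, 0))
            continue
        table.append(
            PsBinSummary.from_stats(label, float(scores[mask].mean()), n, int(out[mask].sum()))
        )
    return table


def bin_table_to_dataframe(table: Sequence[PsBinSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ps_interval": [b.label for b in table],
            "mean_ps": [b.mean_ps for b in table],
            "n": [b.n for b in table],
            "observed_survivors": [b.observed_survivors for b in table],
            "expected_survivors": [b.expected_survivors_display for b in table],
            "oe_ratio": [b.oe_ratio for b in table],
        }
    )


# ---------------------------------------------------------------------------
# Stratified threshold/ROC report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumResult:
    label: str
    summary: ConfusionSummary


@dataclass
class ValidationReport:
    """Per-stratum confusion metrics + AUC, with the pooled cohort as 'total'."""

    stratifier: str
    overall: StratumResult
    strata: list[StratumResult]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for res in [self.overall, *self.strata]:
            s = res.summary
            rows.append(
                {
                    "stratum": res.label,
                    "n": s.n,
                    "sensitivity_pct": s.sensitivity,
                    "specificity_pct": s.specificity,
                    "ppv_pct": s.ppv,
                    "npv_pct": s.npv,
                    "accuracy_pct": s.accuracy,
                    "auc": None if s.auc is None else round_half_up(s.auc, 3),
                    "auc_ci_lo": None if s.auc_ci is None else round_half_up(s.auc_ci[0], 3),
                    "auc_ci_hi": None if s.auc_ci is None else round_half_up(s.auc_ci[1], 3),
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        df = self.to_dataframe()

        def fmt_auc(row):
            if pd.isna(row["auc"]):
                return "undefined"
            return f"{row['auc']:.3f} ({row['auc_ci_lo']:.3f}-{row['auc_ci_hi']:.3f})"

        disp = pd.DataFrame(
            {
                "stratum": df["stratum"],
                "n": df["n"],
                "Sens%": df["sensitivity_pct"].map("{:.1f}".format),
                "Spec%": df["specificity_pct"].map("{:.1f}".format),
                "PPV%": df["ppv_pct"].map("{:.1f}".format),
                "NPV%": df["npv_pct"].map("{:.1f}".format),
                "Acc%": df["accuracy_pct"].map("{:.1f}".format),
                "AUC (95% CI)": df.apply(fmt_auc, axis=1),
            }
        )
        return disp.to_string(index=False)


def _summary_for(ps: np.ndarray, survived: np.ndarray, threshold: float) -> ConfusionSummary:
    predicted = ps >= threshold
    base = confusion_metrics(predicted, survived)
    if survived.all() or not survived.any():
        return base  # AUC undefined; threshold metrics still reported
    auc, ci = auc_rank(ps, survived)
    return ConfusionSummary(
        n=base.n,
        sensitivity=base.sensitivity,
        specificity=base.specificity,
        ppv=base.ppv,
        npv=base.npv,
        accuracy=base.accuracy,
        auc=auc,
        auc_ci=ci,
    )


def stratified_report(
    scored: pd.DataFrame,
    stratifier: str = "age",
    threshold: float = 0.5,
    age_groups: Sequence[AgeGroup] = AGE_GROUPS,
) -> ValidationReport:
    """Threshold metrics and AUC per stratum plus the pooled row.

    ``scored`` needs columns ``ps`` and ``survived`` (and ``age_years`` when
    stratifying by age).  ``stratifier`` is ``"age"`` or ``"ps_bin"``.  Strata
    with a single outcome class keep their threshold metrics and carry an
    undefined AUC.
    """
    if scored.empty:
        raise ValidationError("empty cohort")
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must be in (0,1), got {threshold!r}")
    ps = scored["ps"].to_numpy(dtype=float)
    survived = scored["survived"].to_numpy(dtype=bool)
    overall = StratumResult("total", _summary_for(ps, survived, threshold))

    strata: list[StratumResult] = []
    if stratifier == "age":
        ages = scored["age_years"].to_numpy(dtype=int)
        for g in age_groups:
            mask = np.array([g.contains(a) for a in ages])
            if mask.any():
                strata.append(StratumResult(g.label, _summary_for(ps[mask], survived[mask], threshold)))
    elif stratifier == "ps_bin":
        labels = np.array([assign_ps_bin(p) for p in ps])
        for label, _, _ in PS_BINS:
            mask = labels == label
            if mask.any():
                strata.append(StratumResult(label, _summary_for(ps[mask], survived[mask], threshold)))
    else:
        raise ValidationError(f"unknown stratifier {stratifier!r}")
    return ValidationReport(stratifier=stratifier, overall=overall, strata=strata)


# ---------------------------------------------------------------------------
# Group comparison tests (descriptive-table support)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    pvalue: float

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def compare_groups(groups, kind: str = "continuous") -> GroupComparison:
    """Compare 2+ groups: rank-sum / Kruskal-Wallis (continuous) or chi-square.

    ``continuous``: ``groups`` is a sequence of value arrays — Mann-Whitney U
    for two groups, Kruskal-Wallis for more.  ``categorical``: ``groups`` is a
    contingency table (rows = categories, columns = groups) — Pearson
    chi-square without continuity correction.  Degenerate inputs (all values
    tied, zero-expected cells) emit a warning and return NaN statistics.
    """
    if kind == "continuous":
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if len(arrays) < 2 or any(a.size == 0 for a in arrays):
            raise ValidationError("compare_groups needs >= 2 non-empty groups")
        pooled = np.concatenate(arrays)
        if np.all(pooled == pooled[0]):
            warnings.warn("all values tied across groups; test statistic undefined")
            return GroupComparison("degenerate", float("nan"), float("nan"))
        if len(arrays) == 2:
            stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            return GroupComparison("mann-whitney-u", float(stat), float(p))
        stat, p = stats.kruskal(*arrays)
        return GroupComparison("kruskal-wallis", float(stat), float(p))
    if kind == "categorical":
        table = np.asarray(groups, dtype=float)
        if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
            raise ValidationError("categorical comparison needs a 2-D contingency table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            warnings.warn("zero marginal in contingency table; chi-square undefined")
            return GroupComparison("degenerate", float("nan"), float("nan"))
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison("chi-square", float(stat), float(p))
    raise ValidationError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Descriptive table (per-age-group characteristics)
# ---------------------------------------------------------------------------


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    if float(med).is_integer() and float(q1).is_integer() and float(q3).is_integer():
        return f"{med:.0f} ({q1:.0f}-{q3:.0f})"
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def descriptive_table(scored: pd.DataFrame, age_groups: Sequence[AgeGroup] = AGE_GROUPS) -> pd.DataFrame:
    """Per-age-group cohort characteristics with cross-group p-values.

    Rows: n, median (IQR) age/ISS/RTS/Ps, % male, % per injured region with
    AIS >= 3, % per Ps interval, mortality %.  The p-value column uses
    Kruskal-Wallis for continuous rows and chi-square for categorical rows.
    """
    from .scoring import ISS_REGIONS

    if scored.empty:
        raise ValidationError("empty cohort")
    ages = scored["age_years"].to_numpy(dtype=int)
    masks = {g.label: np.array([g.contains(a) for a in ages]) for g in age_groups}
    masks = {k: m for k, m in masks.items() if m.any()}
    cols = ["total", *masks]
    rows: dict[str, dict] = {}

    def add_continuous(name: str, values: np.ndarray) -> None:
        row = {"total": _median_iqr(values)}
        groups = []
        for label, m in masks.items():
            row[label] = _median_iqr(values[m])
            groups.append(values[m])
        if len(groups) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["p"] = compare_groups(groups, "continuous").pvalue
        rows[name] = row

    def add_binary(name: str, flag: np.ndarray) -> None:
        row = {"total": f"{int(flag.sum())} ({percent(flag.sum(), flag.size):.1f}%)"}
        table = []
        for label, m in masks.items():
            row[label] = f"{int(flag[m].sum())} ({percent(flag[m].sum(), m.sum()):.1f}%)"
            table.append([flag[m].sum(), (~flag[m]).sum()])
        if len(table) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["p"] = compare_groups(np.array(table).T, "categorical").pvalue
        rows[name] = row

    rows["n"] = {"total": len(scored), **{lbl: int(m.sum()) for lbl, m in masks.items()}}
    add_continuous("age_years", ages.astype(float))
    if "sex" in scored:
        add_binary("male", (scored["sex"] == "male").to_numpy())
    for region in ISS_REGIONS:
        col = f"ais_{region}"
        if col in scored:
            add_binary(f"{region}_ais3plus", (scored[col].to_numpy(dtype=float) >= 3))
    for name in ("iss", "rts", "ps"):
        if name in scored:
            add_continuous(name, scored[name].to_numpy(dtype=float))
    if "ps" in scored:
        labels = np.array([assign_ps_bin(p) for p in scored["ps"]])
        for label, _, _ in PS_BINS[::-1]:
            add_binary(f"ps_{label}", labels == label)
    add_binary("mortality", ~scored["survived"].to_numpy(dtype=bool))
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=[*cols, "p"])


def plot_roc(scored: pd.DataFrame, path) -> None:
    """Write a ROC-curve plot for the scored cohort (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ps = scored["ps"].to_numpy(dtype=float)
    survived = scored["survived"].to_numpy(dtype=bool)
    thresholds = np.unique(np.concatenate([[0.0, 1.0], ps]))[::-1]
    tpr = [(survived & (ps >= t)).sum() / max(survived.sum(), 1) for t in thresholds]
    fpr = [((~survived) & (ps >= t)).sum() / max((~survived).sum(), 1) for t in thresholds]
    auc, _ = auc_rank(ps, survived)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, lw=1.5, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
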