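"""Screening evaluation of the vitality index.

Subjects fall into three groups: healthy controls (no clinician severity
rating), and patients split by the Zimmerman HAM-D cutoffs into *no
depression* (HAM-D <= 7) and *depression* (HAM-D >= 8). The evaluation
asks how well vitality separates the groups:

- Pearson correlation between HAM-D severity and vitality (patients);
- Tukey-Kramer pairwise comparison of the three group means (the Kramer
  form handles unequal group sizes);
- empirical ROC of healthy vs. depression, where higher vitality indicates
  health; the AUC equals the normalized Mann-Whitney pair-win statistic;
- an operating point maximizing Youden's J = sensitivity + specificity - 1
  (a fixed-specificity rule is available as an option);
- Cohen's d with the pooled standard deviation;
- power of the two-sided two-sample t-test at the observed d, from the
  noncentral t distribution, and the (fractional) group size required to
  reach a target power.

`ScreeningModel(cohort).fit()` runs all of it and returns a
`ScreeningResults` with a `summary()` table; the individual statistics are
also exposed as module-level functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "GROUPS",
    "HAMD_NO_DEPRESSION_MAX",
    "HAMD_DEPRESSION_MIN",
    "assign_groups",
    "pearson_r",
    "tukey_kramer",
    "roc_auc",
    "best_cutpoint",
    "cohens_d",
    "power_two_sample_t",
    "required_n_two_sample_t",
    "evaluate_cohort",
    "EvalReport",
    "ScreeningModel",
    "ScreeningResults",
]

GROUPS = ("healthy", "no_depression", "depression")

#: Zimmerman HAM-D severity cutoffs.
HAMD_NO_DEPRESSION_MAX = 7
HAMD_DEPRESSION_MIN = 8


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the grouping contract."""


class InfeasiblePowerError(ValueError):
    """Raised when no finite group size can attain the target power."""


def assign_groups(rows: pd.DataFrame) -> pd.DataFrame:
    """Label cohort rows healthy / no_depression / depression.

    Expects columns ``is_patient`` (bool) and ``hamd`` (integer, may be
    missing for non-patients). Patient rows with HAM-D <= 7 become
    ``no_depression`` and >= 8 ``depression``; non-patient rows become
    ``healthy`` and must not carry a HAM-D score requirement.

    Raises
    ------
    CohortValidationError
        If a patient row has no HAM-D score.
    """
    df = rows.copy()
    patient = df["is_patient"].astype(bool)
    hamd = pd.to_numeric(df.get("hamd"), errors="coerce").astype(float)
    if (patient & hamd.isna()).any():
        bad = int((patient & hamd.isna()).idxmax())
        raise CohortValidationError(f"patient row {bad} is missing its HAM-D score")
    if (hamd.dropna() < 0).any():
        raise CohortValidationError("HAM-D scores must be >= 0")
    group = np.where(~patient, "healthy",
                     np.where(hamd <= HAMD_NO_DEPRESSION_MAX, "no_depression", "depression"))
    df["group"] = group
    return df


def pearson_r(x: Sequence[float], y: Sequence[float],
              method: str = "pearson") -> tuple[float, float]:
    """Correlation between severity and vitality with a two-sided p-value.

    ``method`` is ``"pearson"`` (default, t-based p) or ``"spearman"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def tukey_kramer(groups: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Tukey-Kramer pairwise p-values from the studentized range.

    Unequal group sizes use the Kramer adjustment. Keys of the returned
    mapping are sorted name pairs.
    """
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for n, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {n!r} needs at least 2 values")
    res = stats.tukey_hsd(*samples)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair = tuple(sorted((names[i], names[j])))
            out[pair] = float(res.pvalue[i, j])
    return out


def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]
            ) -> tuple[float, pd.DataFrame]:
    """Empirical ROC and AUC for healthy (positive) vs. depression scores.

    Higher vitality indicates the positive (healthy) class. The trapezoidal
    area under the empirical ROC equals the Mann-Whitney statistic
    (wins + 0.5*ties) / (n_pos * n_neg).

    Returns
    -------
    auc : float
    curve : DataFrame with columns threshold, fpr, tpr (sensitivity).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, thr = _sk_roc_curve(y, s)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return float(_trapezoid_auc(fpr, tpr)), curve


def best_cutpoint(curve: pd.DataFrame, rule: str = "youden",
                  min_specificity: float = 0.8) -> tuple[float, float, float]:
    """Operating point on an ROC curve.

    ``rule="youden"`` maximizes J = sensitivity + specificity - 1, ties
    broken toward higher sensitivity (a screening instrument prefers not to
    miss cases). ``rule="fixed_specificity"`` picks the highest-sensitivity
    point with specificity >= *min_specificity*.

    Returns (cutpoint, sensitivity, specificity); a sample is called
    positive (healthy) when its score >= cutpoint.
    """
    sens = curve["tpr"].to_numpy()
    spec = 1.0 - curve["fpr"].to_numpy()
    thr = curve["threshold"].to_numpy()
    if rule == "youden":
        j = sens + spec - 1.0
        order = np.lexsort((sens, j))  # j primary, sensitivity tiebreak
        i = int(order[-1])
    elif rule == "fixed_specificity":
        ok = np.flatnonzero(spec >= min_specificity)
        if ok.size == 0:
            raise ValueError(f"no operating point with specificity >= {min_specificity}")
        i = int(ok[np.argmax(sens[ok])])
    else:
        raise ValueError(f"unknown cutpoint rule {rule!r}")
    return float(thr[i]), float(sens[i]), float(spec[i])


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference (a - b) / pooled SD, pooled with n-1
    weights: sqrt(((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2))."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValueError("effect size undefined: zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def power_two_sample_t(d: float, n1: float, n2: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test.

    Computed from the noncentral t distribution with ``df = n1 + n2 - 2``
    and noncentrality ``d * sqrt(n1*n2/(n1+n2))``. Group sizes may be
    fractional (as in sample-size planning).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    p = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    if np.isnan(p):  # scipy's nct loses the extreme tails at large df x nc;
        # by then the Gaussian limit of the noncentral t is exact to double
        p = stats.norm.sf(tcrit - nc) + stats.norm.cdf(-tcrit - nc)
    return float(p)


def required_n_two_sample_t(d: float, n_fixed: float, power: float = 0.8,
                            alpha: float = 0.05) -> float:
    """Fractional size of the second group attaining the target power.

    Inverts :func:`power_two_sample_t` in its second group size by monotone
    root-finding. Because the noncentrality saturates at d*sqrt(n_fixed) as
    the free group grows, the target may be unattainable for small effects;
    that raises :class:`InfeasiblePowerError`.
    """
    if d == 0:
        raise InfeasiblePowerError("zero effect size: power never exceeds alpha")
    if not (alpha < power < 1.0):
        raise ValueError("target power must lie in (alpha, 1)")
    lo, hi = 2.0 + 1e-9, 1000.0
    f = lambda n: power_two_sample_t(d, n_fixed, n, alpha) - power
    if f(hi) < 0:
        raise InfeasiblePowerError(
            f"power {power} unattainable with d={d} and fixed group size {n_fixed}")
    if f(lo) >= 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-9))


@dataclass(frozen=True)
class EvalReport:
    """All screening statistics for one cohort."""

    group_means: dict[str, float]
    group_ns: dict[str, int]
    pearson_r: float
    pearson_p: float
    tukey_p: dict[tuple[str, str], float]
    auc: float
    cutpoint: float
    sensitivity: float
    specificity: float
    cohens_d: float
    power: float
    required_n: float
    roc_curve: pd.DataFrame = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        """JSON-serializable report (ROC curve excluded)."""
        return {
            "group_means": self.group_means,
            "group_ns": self.group_ns,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "tukey_p": {"|".join(k): v for k, v in self.tukey_p.items()},
            "auc": self.auc,
            "cutpoint": self.cutpoint,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cohens_d": self.cohens_d,
            "power": self.power,
            "required_n": self.required_n,
        }


class ScreeningModel:
    """Screening evaluation of vitality on a labeled cohort.

    Parameters
    ----------
    cohort : DataFrame
        One row per acquired voice with columns ``subject_id``,
        ``session_id``, ``group`` (healthy / no_depression / depression),
        ``hamd`` (integer, missing for healthy rows) and ``vitality``.
        Rows from repeated sessions of one patient are treated as
        independent data points (a deliberate simplification; a clustering
        caveat applies).
    cutpoint_rule : "youden" or "fixed_specificity"
    correlation : "pearson" or "spearman"
    alpha : float
        Significance level, default 0.05.
    target_power : float
        Target for the required-sample-size computation, default 0.8.
    """

    def __init__(self, cohort: pd.DataFrame, cutpoint_rule: str = "youden",
                 min_specificity: float = 0.8, correlation: str = "pearson",
                 alpha: float = 0.05, target_power: float = 0.8) -> None:
        required = {"group", "vitality"}
        if not required <= set(cohort.columns):
            raise CohortValidationError(f"cohort table needs columns {sorted(required)}")
        unknown = set(cohort["group"]) - set(GROUPS)
        if unknown:
            raise CohortValidationError(f"unknown group labels {sorted(unknown)}")
        self.cohort = cohort.reset_index(drop=True)
        self.cutpoint_rule = cutpoint_rule
        self.min_specificity = min_specificity
        self.correlation = correlation
        self.alpha = alpha
        self.target_power = target_power

    @classmethod
    def from_tables(cls, recordings: pd.DataFrame, metadata: pd.DataFrame,
                    **kwargs) -> "ScreeningModel":
        """Build from a recording-indices table joined with subject metadata.

        ``metadata`` has one row per subject: ``subject_id``, ``is_patient``
        and ``hamd``; groups are assigned by the HAM-D cutoffs.
        """
        merged = recordings.merge(metadata, on="subject_id", how="left", validate="m:1")
        merged = assign_groups(merged)
        cols = ["subject_id", "session_id", "group", "hamd", "vitality"]
        return cls(merged[[c for c in cols if c in merged.columns]], **kwargs)

    def fit(self) -> "ScreeningResults":
        """Compute every screening statistic and return the results."""
        df = self.cohort
        by_group = {g: df.loc[df["group"] == g, "vitality"].to_numpy() for g in GROUPS}
        for g in ("healthy", "depression"):
            if by_group[g].size < 2:
                raise CohortValidationError(
                    f"group {g!r} has {by_group[g].size} row(s); at least 2 are required")

        patients = df[df["group"].isin(["no_depression", "depression"])]
        r, p = pearson_r(patients["hamd"], patients["vitality"], method=self.correlation)

        present = {g: v for g, v in by_group.items() if v.size >= 2}
        tukey = tukey_kramer(present)

        auc_val, curve = roc_auc(by_group["healthy"], by_group["depression"])
        cut, sens, spec = best_cutpoint(curve, rule=self.cutpoint_rule,
                                        min_specificity=self.min_specificity)
        d = cohens_d(by_group["healthy"], by_group["depression"])
        n_h, n_d = by_group["healthy"].size, by_group["depression"].size
        pw = power_two_sample_t(d, n_d, n_h, alpha=self.alpha)
        try:
            req = required_n_two_sample_t(d, n_d, power=self.target_power, alpha=self.alpha)
        except InfeasiblePowerError:
            req = float("nan")

        report = EvalReport(
            group_means={g: float(v.mean()) for g, v in by_group.items() if v.size},
            group_ns={g: int(v.size) for g, v in by_group.items()},
            pearson_r=r, pearson_p=p, tukey_p=tukey,
            auc=auc_val, cutpoint=cut, sensitivity=sens, specificity=spec,
            cohens_d=d, power=pw, required_n=req, roc_curve=curve,
        )
        return ScreeningResults(self, report)


class ScreeningResults:
    """Fitted screening statistics with a text summary and ROC plot."""

    def __init__(self, model: ScreeningModel, report: EvalReport) -> None:
        self.model = model
        self.report = report
        # convenience attribute access
        for name in ("group_means", "group_ns", "pearson_r", "pearson_p",
                     "tukey_p", "auc", "cutpoint", "sensitivity",
                     "specificity", "cohens_d", "power", "required_n",
                     "roc_curve"):
            setattr(self, name, getattr(report, name))

    def summary(self) -> str:
        """Human-readable summary table of the screening evaluation."""
        rep = self.report
        lines = ["Vitality screening evaluation", "=" * 45]
        lines.append(f"{'group':<16}{'n':>5}{'mean vitality':>16}")
        for g in GROUPS:
            if rep.group_ns.get(g):
                lines.append(f"{g:<16}{rep.group_ns[g]:>5}{rep.group_means[g]:>16.3f}")
        lines.append("-" * 45)
        lines.append(f"HAM-D vs vitality r = {rep.pearson_r:+.3f} (p = {rep.pearson_p:.4f})")
        for (a, b), p in sorted(rep.tukey_p.items()):
            lines.append(f"Tukey-Kramer {a} vs {b}: p = {p:.4f}")
        lines.append(f"AUC (healthy vs depression) = {rep.auc:.3f}")
        lines.append(f"cutpoint = {rep.cutpoint:.3f} "
                     f"(sensitivity {rep.sensitivity:.2f}, specificity {rep.specificity:.2f})")
        lines.append(f"Cohen's d = {rep.cohens_d:.3f}")
        lines.append(f"power at observed d = {rep.power:.3f}; "
                     f"required n for power {self.model.target_power:g} = {rep.required_n:.2f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the empirical ROC curve (1-specificity vs sensitivity)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.report.roc_curve["fpr"], self.report.roc_curve["tpr"],
                drawstyle="steps-post", label=f"AUC = {self.report.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax


def evaluate_cohort(cohort: pd.DataFrame, **options) -> EvalReport:
    """Functional wrapper: fit :class:`ScreeningModel` and return the report."""
    return ScreeningModel(cohort, **options).fit().report
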