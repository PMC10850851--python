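"""Comparison battery for the crossover trial.

Completion-rate tests (Yates-corrected chi-square or Fisher exact), paired
Wilcoxon signed-rank with an exact small-sample distribution, one-way ANOVA
for order effects, descriptive report tables, and sample-size planning with
attrition inflation.
"""
from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "completion_rate_test",
    "format_percent",
    "order_effect_test",
    "paired_wilcoxon",
    "report_markdown",
    "required_sample_size",
    "summarize_trial",
]

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    statistic_name: str
    p_value: float
    method: str  # chi2_yates | fisher_exact | wilcoxon_signed_rank | anova
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


# -- completion rate ------------------------------------------------------


def completion_rate_test(table, method: str = "auto") -> ComparisonResult:
    """Two-sided test on a 2x2 table (rows = modality, cols = success/failure).

    ``method`` is ``chi2_yates``, ``fisher_exact``, or ``auto`` (Fisher when
    any expected cell count is below 10).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    rows = t.sum(axis=1)
    if (rows == 0).any():
        raise ValueError("zero row margin: each modality needs assessments")

    n = t.sum()
    expected = np.outer(rows, t.sum(axis=0)) / n
    if method == "auto":
        method = "fisher_exact" if expected.min() < 10 else "chi2_yates"
    if method == "fisher_exact":
        res = stats.fisher_exact(t, alternative="two-sided")
        return ComparisonResult(
            statistic=float(res.statistic),
            statistic_name="odds_ratio",
            p_value=float(res.pvalue),
            method="fisher_exact",
        )
    if method == "chi2_yates":
        if (t.sum(axis=0) == 0).any():
            raise ValueError("zero column margin: chi-square undefined, use Fisher")
        chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
        return ComparisonResult(
            statistic=float(chi2),
            statistic_name="chi2",
            p_value=float(p),
            method="chi2_yates",
        )
    raise ValueError(f"unknown method: {method!r}")


# -- paired Wilcoxon ------------------------------------------------------


def _exact_signed_rank_p(doubled_ranks: Sequence[int], w2: int) -> float:
    """Two-sided exact p over all sign flips; ranks doubled so ties stay integral."""
    dist: dict[int, int] = {0: 1}
    for r in doubled_ranks:
        nxt: dict[int, int] = defaultdict(int)
        for s, c in dist.items():
            nxt[s] += c
            nxt[s + r] += c
        dist = dict(nxt)
    total = 2 ** len(doubled_ranks)
    cdf = sum(c for s, c in dist.items() if s <= w2) / total
    sf = sum(c for s, c in dist.items() if s >= w2) / total
    return min(1.0, 2.0 * min(cdf, sf))


def paired_wilcoxon(scores_a, scores_b) -> ComparisonResult:
    """Wilcoxon signed-rank on paired scores, differences taken as a - b.

    Zero differences are dropped; |differences| are mid-ranked.  The p-value
    is the exact sign-flip distribution for n <= 25 effective pairs, else
    the tie-corrected normal approximation.  Z is always reported and its
    sign follows the (a - b) rank sums.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores must be equal-length 1-d arrays")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return ComparisonResult(
            statistic=0.0,
            statistic_name="W+",
            p_value=1.0,
            method="wilcoxon_signed_rank",
            details={"z": 0.0, "n_effective": 0},
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    z = 0.0 if var <= 0 else (w_plus - mu) / math.sqrt(var)

    if n <= _EXACT_WILCOXON_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        p = _exact_signed_rank_p(doubled.tolist(), int(round(2 * w_plus)))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        statistic=w_plus,
        statistic_name="W+",
        p_value=min(1.0, p),
        method="wilcoxon_signed_rank",
        details={"z": z, "n_effective": n},
    )


# -- order effect ---------------------------------------------------------


def order_effect_test(nurse_totals, group_labels) -> ComparisonResult:
    """One-way ANOVA of per-nurse totals across the crossover groups."""
    totals = np.asarray(nurse_totals, dtype=float)
    labels = np.asarray(group_labels)
    if totals.shape != labels.shape or totals.ndim != 1:
        raise ValueError("totals and labels must be equal-length 1-d arrays")
    groups = [totals[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("order-effect test needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two nurses")
    f, p = stats.f_oneway(*groups)
    if math.isnan(f):  # all values identical in every group
        f, p = 0.0, 1.0
    return ComparisonResult(
        statistic=float(f), statistic_name="F", p_value=float(p), method="anova"
    )


# -- descriptive report ---------------------------------------------------


def format_percent(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Percentage to fixed decimals, dropping a trailing all-zero fraction."""
    if denominator == 0:
        raise ValueError("zero denominator")
    s = f"{100.0 * numerator / denominator:.{decimals}f}"
    if decimals and s.endswith("." + "0" * decimals):
        s = s.split(".")[0]
    return s


def _coerce_frames(dataset) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    if isinstance(dataset, pd.DataFrame):
        return dataset, None
    assessments = getattr(dataset, "assessments", None)
    if assessments is None:
        raise TypeError("expected a TrialDataset or an assessments DataFrame")
    return assessments, getattr(dataset, "usability", None)


def summarize_trial(dataset, usability: Optional[pd.DataFrame] = None) -> dict:
    """Descriptive tables and comparison tests for a (simulated) trial."""
    assessments, usab = _coerce_frames(dataset)
    if usability is not None:
        usab = usability
    if len(assessments) == 0:
        raise ValueError("empty dataset")

    report: dict = {}
    modalities = sorted(assessments["modality"].unique())

    success: dict = {}
    for m in modalities:
        sub = assessments[assessments["modality"] == m]
        n_succ = int(sub["success"].sum())
        n_tot = int(len(sub))
        entry = {"n": n_succ, "N": n_tot, "pct": format_percent(n_succ, n_tot)}
        if "group" in sub:
            entry["by_group"] = {
                g: {
                    "n": int(gs["success"].sum()),
                    "N": int(len(gs)),
                    "pct": format_percent(int(gs["success"].sum()), len(gs)),
                }
                for g, gs in sub.groupby("group")
            }
        success[m] = entry
    if len(modalities) == 2:
        table = [
            [success[m]["n"], success[m]["N"] - success[m]["n"]] for m in modalities
        ]
        success["test"] = completion_rate_test(table)
    report["success"] = success

    errors: dict = {}
    for m in modalities:
        sub = assessments[assessments["modality"] == m]
        entry = {"total": int(sub["human_errors"].sum())}
        if "group" in sub:
            entry["by_group"] = {
                g: int(gs["human_errors"].sum()) for g, gs in sub.groupby("group")
            }
        errors[m] = entry
    report["human_errors"] = errors

    durations: dict = {}
    for m in modalities:
        sub = assessments[(assessments["modality"] == m) & assessments["success"]]
        if len(sub) == 0:
            continue
        q1, med, q3 = np.percentile(sub["duration_min"], [25, 50, 75])
        durations[m] = {
            "n": int(len(sub)),
            "median": float(med),
            "iqr": (float(q1), float(q3)),
            "display": f"{med:.2g} ({q1:.2g}-{q3:.2g})",
        }
    report["duration"] = durations

    per_patient = assessments.groupby("patient_id")["truth_delirium"].max()
    n_patients = int(len(per_patient))
    n_positive = int(per_patient.sum())
    report["prevalence"] = {
        "n_patients": n_patients,
        "n_positive": n_positive,
        "pct": str(int(round(100.0 * n_positive / n_patients))),
    }

    if "group" in assessments:
        nurse_groups = assessments.groupby("nurse_id")["group"].first()
        report["groups"] = {
            g: int((nurse_groups == g).sum()) for g in sorted(nurse_groups.unique())
        }

    if usab is not None and len(usab):
        report["usability"] = _summarize_usability(usab)
    return report


def _summarize_usability(usab: pd.DataFrame) -> dict:
    from .simulate import DOMAINS  # deferred to avoid a cycle

    out: dict = {}
    modalities = sorted(usab["modality"].unique())
    for m in modalities:
        sub = usab[usab["modality"] == m]
        entry = {
            "total_mean": float(sub["total"].mean()),
            "total_sd": float(sub["total"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "domains": {},
        }
        for d in DOMAINS:
            if d in sub:
                vals = sub[d]
                entry["domains"][d] = {
                    "median": float(vals.median()),
                    "range": (float(vals.min()), float(vals.max())),
                }
        out[m] = entry

    if len(modalities) == 2:
        a, b = modalities  # alphabetical: dst, paper
        wide = usab.pivot_table(index="nurse_id", columns="modality", values="total")
        paired = wide.dropna()
        if len(paired) >= 2:
            out["total_test"] = paired_wilcoxon(paired[b], paired[a])
        tests: dict = {}
        for d in DOMAINS:
            if d not in usab:
                continue
            wd = usab.pivot_table(index="nurse_id", columns="modality", values=d)
            wd = wd.dropna()
            if len(wd) >= 2:
                tests[d] = paired_wilcoxon(wd[b], wd[a])
        out["domain_tests"] = tests
        if "group" in usab:
            order_tests: dict = {}
            for m in modalities:
                sub = usab[usab["modality"] == m]
                if sub["group"].nunique() == 2 and (sub.groupby("group").size() >= 2).all():
                    order_tests[m] = order_effect_test(
                        sub["total"].to_numpy(), sub["group"].to_numpy()
                    )
            out["order_effect"] = order_tests
    return out


def report_markdown(report: dict) -> str:
    """Render the summary dict as a small markdown report."""
    lines: list[str] = ["# Trial report", ""]
    lines.append("## Successful completion rate")
    for m, e in report["success"].items():
        if m == "test":
            continue
        lines.append(f"- {m}: {e['n']}/{e['N']} ({e['pct']}%)")
    test = report["success"].get("test")
    if test is not None:
        lines.append(
            f"- {test.method}: {test.statistic_name}={test.statistic:.3f}, "
            f"P={test.p_value:.3f}"
        )
    lines.append("")
    lines.append("## Human errors")
    for m, e in report["human_errors"].items():
        by_group = e.get("by_group", {})
        groups = ", ".join(f"{g}: {v}" for g, v in sorted(by_group.items()))
        lines.append(f"- {m}: {e['total']}" + (f" ({groups})" if groups else ""))
    lines.append("")
    lines.append("## Completion time (min), median (IQR)")
    for m, e in report["duration"].items():
        lines.append(f"- {m}: {e['display']}")
    prev = report["prevalence"]
    lines.append("")
    lines.append(
        f"## Patients\n- {prev['n_positive']} of {prev['n_patients']} "
        f"({prev['pct']}%) delirium positive"
    )
    if "groups" in report:
        groups = ", ".join(f"{g} (n={n})" for g, n in report["groups"].items())
        lines.append(f"- nurse groups: {groups}")
    usab = report.get("usability")
    if usab:
        lines.append("")
        lines.append("## Usability")
        for m in sorted(k for k in usab if k in ("paper", "dst")):
            e = usab[m]
            lines.append(
                f"- {m}: total mean {e['total_mean']:.2f} (SD {e['total_sd']:.2f})"
            )
        tt = usab.get("total_test")
        if tt is not None:
            lines.append(
                f"- paired signed-rank on totals: Z={tt.details['z']:.3f}, "
                f"P={tt.p_value:.3g}"
            )
    return "\n".join(lines) + "\n"


# -- sample size ----------------------------------------------------------


def required_sample_size(
    delta: Optional[float] = None,
    sd: Optional[float] = None,
    alpha: float = 0.05,
    power: float = 0.90,
    attrition: float = 0.0,
    n_analysable: Optional[int] = None,
) -> dict:
    """Two-sample normal-approximation sample size with attrition inflation.

    Either supply ``delta`` and ``sd`` to compute the analysable sample from
    n_per_group = ceil(2 (z_{1-alpha/2} + z_{power})^2 sd^2 / delta^2), or
    pass ``n_analysable`` directly to apply the inflation step alone:
    n_enrol = ceil(n_analysable / (1 - attrition)).
    """
    if not 0.0 <= attrition < 1.0:
        raise ValueError("attrition must lie in [0, 1)")
    n_per_group: Optional[int] = None
    if n_analysable is None:
        if delta is None or sd is None:
            raise ValueError("provide delta and sd, or n_analysable")
        if delta <= 0 or sd <= 0:
            raise ValueError("delta and sd must be positive")
        if not (0 < alpha < 1 and 0 < power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        z_a = stats.norm.ppf(1 - alpha / 2)
        z_b = stats.norm.ppf(power)
        raw = 2 * (z_a + z_b) ** 2 * sd**2 / delta**2
        n_per_group = math.ceil(round(raw, 10))
        n_analysable = 2 * n_per_group
    elif n_analysable <= 0:
        raise ValueError("n_analysable must be positive")
    n_enrol = math.ceil(round(n_analysable / (1.0 - attrition), 10))
    return {
        "n_per_group": n_per_group,
        "n_analysable": int(n_analysable),
        "n_enrol": int(n_enrol),
    }
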