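"""Statistics for the downstream validation assays.

Covers the growth-competition relative-fitness model (logistic decline
of the polyQ-positive fraction; linear in logit space), replicate-level
embryo-survival comparisons, worm-motility bend-count comparisons,
per-cell intensity comparisons, and neuronal-conversion purity and
efficiency ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "FitnessEstimate",
    "ConversionMetrics",
    "estimate_relative_fitness",
    "compare_fitness",
    "compare_survival",
    "compare_bends",
    "compare_intensity",
    "conversion_metrics",
]


@dataclass
class FitnessEstimate:
    """Fitted per-day relative-fitness deficit of polyQ-expressing cells.

    s > 0 means the polyQ-positive fraction declines; the model is
    logit(p_t) = logit(p0) - s t, fitted by weighted least squares with
    binomial (delta-method) weights.  The reported standard error is the
    known-variance WLS error scaled by sqrt(max(1, X^2/df)), a
    quasi-binomial guard against extra-binomial scatter.
    """

    s: float
    s_se: float
    p0_hat: float
    condition: str = ""
    dispersion: float = 1.0
    residual_df: int = 0
    corrected_timepoints: list = field(default_factory=list)


def _check_series(series: pd.DataFrame) -> pd.DataFrame:
    required = {"day", "q94_count", "control_count"}
    if not required.issubset(series.columns):
        raise ValueError(f"competition series needs columns {sorted(required)}")
    if (series.q94_count < 0).any() or (series.control_count < 0).any():
        raise ValueError("counts must be >= 0")
    tot = series.q94_count + series.control_count
    if (tot <= 0).any():
        raise ValueError("each timepoint needs at least one sampled cell")
    if 0 not in set(series.day):
        raise ValueError("day 0 must be present")
    if series.day.nunique() < 2:
        raise ValueError("need at least 2 distinct timepoints")
    return series.sort_values("day").reset_index(drop=True)


def estimate_relative_fitness(series: pd.DataFrame, condition: str = "") -> FitnessEstimate:
    """Fit the logistic-decline competition model to observed counts.

    Proportions of exactly 0 or 1 receive a Haldane continuity
    correction (half a cell added to each category) and are flagged;
    a series that stays degenerate after correction is non-identifiable
    and raises.
    """
    series = _check_series(series)
    q = series.q94_count.to_numpy(dtype=float)
    c = series.control_count.to_numpy(dtype=float)
    corrected = []
    degenerate = (q == 0) | (c == 0)
    if degenerate.all():
        raise ValueError("all proportions are 0 or 1: relative fitness is non-identifiable")
    if degenerate.any():
        corrected = series.day[degenerate].tolist()
        q = np.where(degenerate, q + 0.5, q)
        c = np.where(degenerate, c + 0.5, c)
    n = q + c
    p = q / n
    t = series.day.to_numpy(dtype=float)
    y = logit(p)

    # WLS with known binomial delta-method variance Var(logit p) = 1/(n p (1-p))
    w = n * p * (1 - p)
    X = np.column_stack([np.ones_like(t), -t])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    resid = y - X @ beta
    df = len(t) - 2
    chi2 = float((w * resid ** 2).sum())
    phi = max(1.0, chi2 / df) if df > 0 else 1.0
    s_se = float(np.sqrt(phi * cov[1, 1]))
    return FitnessEstimate(
        s=float(beta[1]), s_se=s_se, p0_hat=float(expit(beta[0])),
        condition=condition, dispersion=phi, residual_df=df,
        corrected_timepoints=corrected)


def compare_fitness(series_by_condition: Mapping[str, pd.DataFrame],
                    reference: str | None = None) -> dict:
    """Per-condition fitness fits plus pairwise Wald contrasts on s.

    A rescue is a negative delta_s relative to the vehicle/reference
    arm (slower decline of the polyQ-positive fraction).
    """
    if len(series_by_condition) < 2:
        raise ValueError("need at least 2 conditions to compare")
    estimates = {}
    for label, series in series_by_condition.items():
        try:
            estimates[label] = estimate_relative_fitness(series, condition=label)
        except ValueError as exc:
            raise ValueError(f"condition {label!r}: {exc}") from exc
    labels = list(estimates)
    if reference is None:
        reference = labels[0]
    if reference not in estimates:
        raise KeyError(f"reference condition {reference!r} not among arms")
    contrasts = []
    for label in labels:
        if label == reference:
            continue
        a, b = estimates[label], estimates[reference]
        delta = a.s - b.s
        se = float(np.hypot(a.s_se, b.s_se))
        z = delta / se if se > 0 else np.inf * np.sign(delta)
        contrasts.append({
            "condition": label, "reference": reference,
            "delta_s": float(delta), "se": se, "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z))),
            "rescue": bool(delta < 0),
        })
    return {"estimates": estimates, "contrasts": contrasts}


def _arm_pairs(labels: Sequence[str]):
    return [(labels[i], labels[j]) for i in range(len(labels))
            for j in range(i + 1, len(labels))]


def compare_survival(survival: pd.DataFrame, test: str = "t") -> pd.DataFrame:
    """Pairwise comparison of per-replicate embryo survival fractions.

    Default is a Welch two-sample t-test on replicate-level survival
    fractions (respecting well-level clustering, n = 3 wells per arm in
    the original design); ``test='two_proportion'`` pools eggs into a
    two-proportion z-test instead.  Survival = 1 - n_dead/n_total.
    """
    required = {"arm", "n_total", "n_dead"}
    if not required.issubset(survival.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if (survival.n_dead > survival.n_total).any() or (survival.n_dead < 0).any():
        raise ValueError("need 0 <= n_dead <= n_total in every replicate")
    if test not in ("t", "two_proportion"):
        raise ValueError("test must be 't' or 'two_proportion'")
    arms = sorted(survival.arm.unique())
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    frac = {a: 1.0 - (g.n_dead / g.n_total).to_numpy()
            for a, g in survival.groupby("arm")}
    rows = []
    for a, b in _arm_pairs(arms):
        fa, fb = frac[a], frac[b]
        if test == "t":
            if len(fa) < 2 or len(fb) < 2:
                raise ValueError(
                    "t-test needs >= 2 replicates per arm; use test='two_proportion'")
            res = stats.ttest_ind(fa, fb, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            ga = survival[survival.arm == a]
            gb = survival[survival.arm == b]
            xa, na = ga.n_total.sum() - ga.n_dead.sum(), ga.n_total.sum()
            xb, nb = gb.n_total.sum() - gb.n_dead.sum(), gb.n_total.sum()
            pool = (xa + xb) / (na + nb)
            se = np.sqrt(pool * (1 - pool) * (1 / na + 1 / nb))
            stat = float((xa / na - xb / nb) / se) if se > 0 else np.nan
            p = float(2 * stats.norm.sf(abs(stat))) if np.isfinite(stat) else np.nan
        rows.append({
            "arm_a": a, "arm_b": b,
            "survival_a": float(fa.mean()), "survival_b": float(fb.mean()),
            "sd_a": float(fa.std(ddof=1)) if len(fa) > 1 else np.nan,
            "sd_b": float(fb.std(ddof=1)) if len(fb) > 1 else np.nan,
            "sem_a": float(fa.std(ddof=1) / np.sqrt(len(fa))) if len(fa) > 1 else np.nan,
            "sem_b": float(fb.std(ddof=1) / np.sqrt(len(fb))) if len(fb) > 1 else np.nan,
            "difference": float(fa.mean() - fb.mean()),
            "statistic": stat, "p": p, "test": test,
        })
    return pd.DataFrame(rows)


def compare_bends(bends: pd.DataFrame, test: str = "t") -> pd.DataFrame:
    """Pairwise comparison of per-worm bend counts (motility readout).

    Welch t-test by default, Mann-Whitney U as option; the effect size
    is the difference of arm means (bends per 30 s).
    """
    required = {"arm", "bends_30s"}
    if not required.issubset(bends.columns):
        raise ValueError(f"bend table needs columns {sorted(required)}")
    if (bends.bends_30s < 0).any():
        raise ValueError("bend counts must be >= 0")
    if test not in ("t", "mannwhitney"):
        raise ValueError("test must be 't' or 'mannwhitney'")
    arms = sorted(bends.arm.unique())
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    counts = {a: g.bends_30s.to_numpy(dtype=float) for a, g in bends.groupby("arm")}
    for a, v in counts.items():
        if len(v) < 5:
            raise ValueError(f"arm {a!r} has fewer than 5 worms")
    rows = []
    for a, b in _arm_pairs(arms):
        va, vb = counts[a], counts[b]
        if test == "t":
            res = stats.ttest_ind(va, vb, equal_var=False)
        else:
            res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append({
            "arm_a": a, "arm_b": b,
            "mean_a": float(va.mean()), "mean_b": float(vb.mean()),
            "mean_difference": float(va.mean() - vb.mean()),
            "statistic": float(res.statistic), "p": float(res.pvalue), "test": test,
        })
    return pd.DataFrame(rows)


def compare_intensity(groups: Mapping[str, Sequence[float]]) -> dict:
    """Compare per-cell intensity distributions between treatment groups.

    Two groups: Welch t-test.  More: one-way ANOVA plus Holm-adjusted
    pairwise Welch t-tests as post-hoc.  Each group needs >= 3 cells.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 3:
            raise ValueError(f"group {k!r} has fewer than 3 cells")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {k!r} contains non-finite intensities")
    summary = {k: {"n": int(v.size), "mean": float(v.mean()),
                   "sd": float(v.std(ddof=1))} for k, v in arrays.items()}
    labels = list(arrays)
    out: dict = {"groups": summary}
    pair_rows = []
    raw = []
    for a, b in _arm_pairs(labels):
        res = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
        raw.append(float(res.pvalue))
        pair_rows.append({"group_a": a, "group_b": b,
                          "mean_difference": float(arrays[a].mean() - arrays[b].mean()),
                          "statistic": float(res.statistic), "p": float(res.pvalue)})
    if len(labels) == 2:
        out["test"] = "welch_t"
        out["pairwise"] = pair_rows
    else:
        f = stats.f_oneway(*arrays.values())
        out["test"] = "anova"
        out["anova"] = {"F": float(f.statistic), "p": float(f.pvalue)}
        order = np.argsort(raw)
        m = len(raw)
        running = 0.0
        for rank, j in enumerate(order):          # Holm step-down
            running = max(running, (m - rank) * raw[j])
            pair_rows[j]["p_adjusted"] = min(1.0, running)
        out["pairwise"] = pair_rows
    return out


@dataclass
class ConversionMetrics:
    """Neuronal-conversion readouts: purity and efficiency ratios."""

    purity: float        # TAU+ / DAPI+ fraction
    efficiency: float    # TAU+ / plated fibroblasts


def conversion_metrics(dapi_count: float, tau_count: float, plated_count: float,
                       enforce_tau_le_dapi: bool = False) -> ConversionMetrics:
    """Purity = TAU+/DAPI+; efficiency = TAU+/plated fibroblasts."""
    if min(dapi_count, tau_count, plated_count) < 0:
        raise ValueError("counts must be >= 0")
    if dapi_count == 0 or plated_count == 0:
        raise ValueError("dapi_count and plated_count must be > 0")
    if enforce_tau_le_dapi and tau_count > dapi_count:
        raise ValueError("tau_count exceeds dapi_count")
    return ConversionMetrics(purity=tau_count / dapi_count,
                             efficiency=tau_count / plated_count)
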