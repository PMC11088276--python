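"""Plate normalization, triplicate aggregation, 3SD hit calling and QC.

The screen's readout is a nuclei count per well.  Counts are normalized
to the mean of the dox-only (vehicle/DMSO) control wells within each
plate, averaged over replicate plates per compound, and a compound is a
primary hit when its normalized mean exceeds the dox-only control mean
by more than k control standard deviations (k = 3, strict, one-sided
increase).  Dose-response validation calls a compound validated when it
shows a significant increase over control at two or more doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizationError",
    "ControlStats",
    "DoseResponseResult",
    "normalize_plate",
    "normalize_plates",
    "summarize_compounds",
    "control_stats",
    "call_hits",
    "validate_dose_response",
    "zprime",
    "qc_report",
]

DOX_ONLY = "dox_only_control"
NO_DOX = "no_dox_control"


class NormalizationError(ValueError):
    """A plate cannot be normalized (no usable dox-only control wells)."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"plate table is missing columns: {missing}")


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Normalize one plate's wells to its dox-only control mean.

    Returns a copy with a ``normalized`` column; normalization is
    strictly within the plate.
    """
    _require_columns(plate, ["plate_id", "role", "nuclei_count"])
    plate_ids = plate["plate_id"].unique()
    if len(plate_ids) != 1:
        raise ValueError("normalize_plate expects wells of a single plate")
    ctrl = plate.loc[plate.role == DOX_ONLY, "nuclei_count"]
    if ctrl.empty:
        raise NormalizationError(f"plate {plate_ids[0]}: no dox-only control wells")
    denom = float(ctrl.mean())
    if denom <= 0:
        raise NormalizationError(f"plate {plate_ids[0]}: dox-only control mean is 0")
    out = plate.copy()
    out["normalized"] = out["nuclei_count"] / denom
    return out


def normalize_plates(wells: pd.DataFrame) -> pd.DataFrame:
    """Apply per-plate dox-only normalization across a whole plate set."""
    parts = [normalize_plate(g) for _, g in wells.groupby("plate_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


def summarize_compounds(wells: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized value per (compound, dose) across replicate plates.

    Returns one row per (compound_id, dose_uM) with normalized_mean and
    n_replicates; compounds missing a replicate are averaged over the
    available ones.
    """
    _require_columns(wells, ["role", "compound_id", "dose_uM", "normalized"])
    comp = wells[wells.role == "compound"]
    if comp.empty:
        return pd.DataFrame(columns=["compound_id", "dose_uM", "normalized_mean", "n_replicates"])
    grouped = comp.groupby(["compound_id", "dose_uM"], sort=True)["normalized"]
    out = grouped.agg(normalized_mean="mean", n_replicates="size").reset_index()
    return out


@dataclass
class ControlStats:
    """Location and spread of the normalized dox-only control wells."""

    mu: float
    sigma: float
    n: int
    k: float = 3.0
    estimator: str = "sd"
    scope: str = "pooled"
    flags: list = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return self.mu + self.k * self.sigma


def control_stats(
    wells: pd.DataFrame,
    scope: str = "pooled",
    estimator: str = "sd",
    k: float = 3.0,
    aggregate: str = "replicate_mean",
    self_norm_correction: bool = True,
) -> ControlStats:
    """Mean and spread of normalized dox-only controls for the hit rule.

    aggregate="replicate_mean" (default) averages each control well
    position over its replicate plates first, so the spread is on the
    same sampling scale as the compound triplicate means the threshold
    is applied to.  aggregate="well" uses individual wells.

    Because the dox-only wells are themselves part of the per-plate
    normalization denominator, their normalized values average to 1
    exactly and their spread underestimates that of an independent
    (compound) well.  With ``self_norm_correction`` each control well is
    re-expressed against the mean of the OTHER m - 1 dox-only wells on
    its plate (leave-one-out), which restores both the mean and the
    variance of the compound-well sampling distribution; the transform
    needs only the normalized value v and m: v (m - 1) / (m - v).
    """
    _require_columns(wells, ["plate_id", "role", "normalized"])
    if estimator not in ("sd", "mad"):
        raise ValueError("estimator must be 'sd' or 'mad'")
    if aggregate not in ("replicate_mean", "well"):
        raise ValueError("aggregate must be 'replicate_mean' or 'well'")
    ctrl = wells[wells.role == DOX_ONLY].copy()
    if len(ctrl) < 2:
        raise ValueError("need at least 2 dox-only control wells")

    flags = []
    if self_norm_correction:
        m = ctrl.groupby("plate_id")["normalized"].transform("size")
        v = ctrl["normalized"]
        if ((m - v) <= 0).any() or (m <= 1).any():
            raise ValueError("leave-one-out control normalization is degenerate")
        ctrl["normalized"] = v * (m - 1) / (m - v)
    if aggregate == "replicate_mean" and "layout_id" in ctrl.columns and "well" in ctrl.columns:
        values = ctrl.groupby(["layout_id", "well"], sort=True)["normalized"].mean()
    else:
        if aggregate == "replicate_mean":
            flags.append("no layout/well columns: falling back to per-well aggregation")
        values = ctrl["normalized"]

    def _stats(v: pd.Series) -> tuple[float, float]:
        if estimator == "sd":
            return float(v.mean()), float(v.std(ddof=1))
        med = float(v.median())
        return med, float(1.4826 * (v - med).abs().median())

    if scope == "pooled":
        mu, sigma = _stats(values)
        n = int(values.size)
    elif scope == "per_plate":
        per = (ctrl.groupby("plate_id", sort=True)["normalized"]
                   .apply(lambda v: _stats(v)))
        mu = float(np.mean([m for m, _ in per]))
        sigma = float(np.mean([s for _, s in per]))
        n = int(len(ctrl))
    else:
        raise ValueError("scope must be 'pooled' or 'per_plate'")

    if sigma == 0:
        flags.append("control spread is zero: threshold equals the control mean")
    if n < 8:
        flags.append("fewer than 8 control values in scope")
    return ControlStats(mu=mu, sigma=sigma, n=n, k=k,
                        estimator=estimator, scope=scope, flags=flags)


def call_hits(summaries: pd.DataFrame, ctrl: ControlStats) -> pd.DataFrame:
    """Apply the k-SD rule: hit iff normalized mean > mu + k*sigma (strict).

    One-sided (increase only); result sorted by margin descending with
    ties broken by compound_id.
    """
    _require_columns(summaries, ["compound_id", "normalized_mean"])
    out = summaries.copy()
    out["threshold"] = ctrl.threshold
    out["margin"] = out["normalized_mean"] - ctrl.threshold
    out["is_hit"] = out["margin"] > 0
    out = out.sort_values(["margin", "compound_id"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out


@dataclass
class DoseResponseResult:
    """Validation verdict of one candidate over the tested doses."""

    compound_id: str
    doses: list
    per_dose: pd.DataFrame        # dose_uM, normalized_mean, p_adjusted, significant
    anova_p: float
    n_significant_doses: int
    validated: bool


def validate_dose_response(
    wells: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "dunnett",
    min_significant_doses: int = 2,
) -> list[DoseResponseResult]:
    """Multi-dose validation against dox-only controls.

    Per compound: a one-way ANOVA across {control, each dose}, then
    per-dose comparisons vs control (Dunnett by default, Holm-adjusted
    Welch t-tests as fallback).  A dose is significant when its adjusted
    p < alpha AND its normalized mean exceeds the control mean; the
    compound is validated when >= ``min_significant_doses`` doses are
    significant increases.
    """
    _require_columns(wells, ["role", "compound_id", "dose_uM", "normalized"])
    if method not in ("dunnett", "holm"):
        raise ValueError("method must be 'dunnett' or 'holm'")
    control = wells.loc[wells.role == DOX_ONLY, "normalized"].to_numpy()
    if control.size < 2:
        raise ValueError("validation plate set lacks a dox-only control arm")
    ctrl_mean = control.mean()

    results = []
    comp = wells[wells.role == "compound"]
    for cid, g in comp.groupby("compound_id", sort=True):
        doses = sorted(g.dose_uM.unique())
        groups = [g.loc[g.dose_uM == d, "normalized"].to_numpy() for d in doses]
        if len(doses) < 2 or any(len(x) < 2 for x in groups):
            raise ValueError(f"compound {cid}: need >= 2 doses with >= 2 replicates each")
        anova_p = float(stats.f_oneway(control, *groups).pvalue)
        if method == "dunnett":
            # the multivariate-t CDF is evaluated by randomized QMC; pin its
            # stream so validation verdicts are reproducible
            padj = stats.dunnett(*groups, control=control, alternative="two-sided",
                                 random_state=np.random.default_rng(0)).pvalue
            padj = np.asarray(padj, dtype=float)
        else:
            raw = np.array([stats.ttest_ind(x, control, equal_var=False).pvalue
                            for x in groups])
            order = np.argsort(raw)
            padj = np.empty_like(raw)
            running = 0.0
            m = len(raw)
            for rank, j in enumerate(order):          # Holm step-down
                running = max(running, (m - rank) * raw[j])
                padj[j] = min(1.0, running)
        means = np.array([x.mean() for x in groups])
        significant = (padj < alpha) & (means > ctrl_mean) & (anova_p < alpha)
        per_dose = pd.DataFrame({
            "dose_uM": doses, "normalized_mean": means,
            "p_adjusted": padj, "significant": significant,
        })
        n_sig = int(significant.sum())
        results.append(DoseResponseResult(
            compound_id=str(cid), doses=list(doses), per_dose=per_dose,
            anova_p=anova_p, n_significant_doses=n_sig,
            validated=n_sig >= min_significant_doses))
    return results


def validation_table(results: Sequence[DoseResponseResult]) -> pd.DataFrame:
    """Long-form per-(compound, dose) validation table with verdicts."""
    rows = []
    for r in results:
        for _, d in r.per_dose.iterrows():
            rows.append({"compound_id": r.compound_id, "dose_uM": d.dose_uM,
                         "normalized_mean": d.normalized_mean,
                         "p_adjusted": d.p_adjusted, "significant": bool(d.significant),
                         "anova_p": r.anova_p,
                         "n_significant_doses": r.n_significant_doses,
                         "validated": r.validated})
    return pd.DataFrame(rows)


def zprime(plate: pd.DataFrame, on: str = "nuclei_count") -> Optional[float]:
    """Z' factor between no-dox (positive growth) and dox-only controls.

    Z' = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|; None when the
    control means coincide (undefined window).
    """
    _require_columns(plate, ["role", on])
    pos = plate.loc[plate.role == NO_DOX, on]
    neg = plate.loc[plate.role == DOX_ONLY, on]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 wells of each control role")
    window = abs(pos.mean() - neg.mean())
    if window == 0:
        return None
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / window)


def qc_report(wells: pd.DataFrame) -> dict:
    """Per-plate Z', control CVs and a border-vs-interior edge diagnostic."""
    _require_columns(wells, ["plate_id", "role", "nuclei_count"])
    report: dict = {"plates": {}}
    for pid, g in wells.groupby("plate_id", sort=True):
        entry: dict = {}
        try:
            entry["zprime"] = zprime(g)
        except ValueError:
            entry["zprime"] = None
        entry["zprime_undefined"] = entry["zprime"] is None
        for role, key in ((NO_DOX, "cv_no_dox"), (DOX_ONLY, "cv_dox_only")):
            v = g.loc[g.role == role, "nuclei_count"]
            entry[key] = float(v.std(ddof=1) / v.mean()) if len(v) > 1 and v.mean() > 0 else None
        if "is_edge" in g.columns:
            comp = g[g.role == "compound"]          # controls are interior by design
            edge = comp.loc[comp.is_edge.astype(bool), "nuclei_count"]
            inner = comp.loc[~comp.is_edge.astype(bool), "nuclei_count"]
            entry["edge_ratio"] = (float(edge.mean() / inner.mean())
                                   if len(edge) and len(inner) and inner.mean() > 0 else None)
        report["plates"][str(pid)] = entry
    return report
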