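"""Pipeline orchestration: simulate -> segment -> call -> validate ->
signature/connect -> phenotypes, with plain-file handoff between stages.

Every stage reads only prior stages' files from the run directory and
writes deterministic CSV/TSV/JSON, so a run is reproducible
byte-for-byte from (config, seed) and each stage is independently
testable and replaceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import imaging, phenotypes, screen, signatures
from . import synthdata
from .synthdata import ScreenSimConfig, derive_seed

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_pipeline", "make_report"]

log = logging.getLogger("polyqhcs")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs, serializable to one YAML file."""

    seed: int = 0
    out_dir: str = "run"
    # stage toggles
    run_imaging: bool = True
    run_validation: bool = True
    run_signatures: bool = True
    run_phenotypes: bool = True
    # primary screen simulation
    n_compounds: int = 1216
    n_active: int = 4
    rescue_effect: float = 1.5
    n_toxic: int = 60
    toxic_effect: float = 0.6
    baseline_count: float = 200.0
    dox_effect: float = 0.5
    plate_factor_sd: float = 0.1
    edge_effect: float = 0.95
    dispersion: float | None = None
    # hit calling
    k: float = 3.0
    scope: str = "pooled"
    estimator: str = "sd"
    # validation
    validation_doses: tuple = (0.5, 1.0, 3.0, 10.0)
    alpha: float = 0.05
    # signatures
    n_genes: int = 2000
    n_up: int = 200
    n_down: int = 200
    signature_n: int = 150
    n_drugs: int = 100
    n_class_drugs: int = 10
    class_label: str = "ppar_agonist"
    class_concordance: float = 0.7
    top_k: float = 0.05
    # imaging demo (counts cross-checked against planted nuclei)
    n_demo_images: int = 4
    nuclei_per_image: int = 20
    # phenotypes
    competition_days: tuple = (0, 5, 15)
    competition_n_cells: int = 40_000
    s_vehicle: float = 0.2
    s_drug: float = 0.05
    survival_probs: tuple = (("uninjected", 0.05), ("injected_vehicle", 0.6),
                             ("injected_drug", 0.3))
    n_eggs: int = 150
    n_survival_replicates: int = 3
    bend_means: tuple = (("vehicle", 8.0), ("drug", 14.0))
    n_worms: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("validation_doses", "competition_days", "bend_means", "survival_probs"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(tuple(x) if isinstance(x, list) else x for x in data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = [list(x) if isinstance(x, tuple) else x for x in val]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage summaries plus provenance; every number re-derivable
    from the stage outputs on disk."""

    config_hash: str
    seed: int
    version: str
    funnel: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", keep_default_na=False, na_values=[""])


def _timed(report: RunReport, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: started", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2f s", stage, dt)
            else:
                log.error("stage %s: failed after %.2f s: %s", stage, dt, exc)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full synthetic screen-to-phenotype cascade.

    Writes plates.csv, truth.json, hits.csv, qc.json, validation.csv,
    de.tsv, refmat.tsv, signature.json, connectivity.csv,
    enrichment.json, competition.csv, fitness.csv, survival.csv,
    bends.csv, contrasts.json and report.json under ``config.out_dir``.
    Any stage error aborts with the stage name; partial outputs are
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    report = RunReport(config_hash=chash, seed=config.seed, version=__version__)
    config.to_yaml(out / "config.yaml")

    # ---- stage 1: simulate the primary screen --------------------------
    with _timed(report, "simulate_screen"):
        try:
            sim_cfg = ScreenSimConfig(
                n_compounds=config.n_compounds, n_active=config.n_active,
                rescue_effects=(config.rescue_effect,), n_toxic=config.n_toxic,
                toxic_effects=(config.toxic_effect,),
                baseline_count=config.baseline_count, dox_effect=config.dox_effect,
                plate_factor_sd=config.plate_factor_sd, edge_effect=config.edge_effect,
                dispersion=config.dispersion,
                seed=derive_seed(config.seed, "primary_screen"))
            plates, truth = synthdata.simulate_screen(sim_cfg)
        except ValueError as exc:
            raise StageError("simulate_screen", str(exc)) from exc
        _write_csv(plates.wells, out / "plates.csv", chash)
        truth.to_json(out / "truth.json")
        report.stages["simulate_screen"] = {
            "n_wells": int(len(plates.wells)),
            "n_compounds": int(config.n_compounds),
            "n_planted_active": len(truth.active_ids),
            "n_planted_toxic": len(truth.toxic_ids)}

    # ---- stage 2: imaging self-check (optional) ------------------------
    if config.run_imaging:
        with _timed(report, "imaging"):
            rows = []
            for i in range(config.n_demo_images):
                img, itruth = synthdata.simulate_nuclei_image(
                    config.nuclei_per_image,
                    seed=derive_seed(config.seed, f"image_{i}"))
                mask = imaging.segment_nuclei(img)
                rows.append({"image": i, "true_n": len(itruth.nuclei_centers),
                             "detected_n": mask.count})
            df = pd.DataFrame(rows)
            _write_csv(df, out / "imaging.csv", chash)
            report.stages["imaging"] = {
                "n_images": int(len(df)),
                "exact_count_fraction": float((df.true_n == df.detected_n).mean())}

    # ---- stage 3: normalize, QC and call hits --------------------------
    with _timed(report, "call_hits"):
        wells = _read_csv(out / "plates.csv")
        try:
            normalized = screen.normalize_plates(wells)
            stats = screen.control_stats(normalized, scope=config.scope,
                                         estimator=config.estimator, k=config.k)
            summaries = screen.summarize_compounds(normalized)
            hits = screen.call_hits(summaries, stats)
        except (screen.NormalizationError, ValueError) as exc:
            raise StageError("call_hits", f"{exc} (input {out / 'plates.csv'})") from exc
        _write_csv(hits, out / "hits.csv", chash)
        with open(out / "qc.json", "w") as fh:
            json.dump({"control_stats": {"mu": stats.mu, "sigma": stats.sigma,
                                         "n": stats.n, "k": stats.k,
                                         "flags": stats.flags},
                       **screen.qc_report(normalized)},
                      fh, indent=1, sort_keys=True)
        hit_ids = hits.loc[hits.is_hit, "compound_id"].tolist()
        report.stages["call_hits"] = {
            "threshold": stats.threshold, "n_hits": len(hit_ids)}

    # ---- stage 4: dose-response validation of the hits -----------------
    validated_ids: list = []
    if config.run_validation:
        with _timed(report, "validate"):
            if hit_ids:
                truth_in = synthdata.SimTruth.from_json(out / "truth.json")
                active_hits = sorted(set(hit_ids) & set(truth_in.active_ids))
                val_cfg = ScreenSimConfig(
                    n_compounds=len(hit_ids), compound_ids=sorted(hit_ids),
                    doses=tuple(config.validation_doses),
                    n_active=len(active_hits), active_ids=active_hits,
                    rescue_effects=(config.rescue_effect,),
                    baseline_count=config.baseline_count, dox_effect=config.dox_effect,
                    plate_factor_sd=config.plate_factor_sd,
                    edge_effect=config.edge_effect, dispersion=config.dispersion,
                    seed=derive_seed(config.seed, "validation_screen"))
                vplates, _ = synthdata.simulate_screen(val_cfg)
                try:
                    vnorm = screen.normalize_plates(vplates.wells)
                    results = screen.validate_dose_response(vnorm, alpha=config.alpha)
                except (screen.NormalizationError, ValueError) as exc:
                    raise StageError("validate", str(exc)) from exc
                vtable = screen.validation_table(results)
                validated_ids = sorted(r.compound_id for r in results if r.validated)
            else:
                vtable = pd.DataFrame(columns=[
                    "compound_id", "dose_uM", "normalized_mean", "p_adjusted",
                    "significant", "anova_p", "n_significant_doses", "validated"])
            _write_csv(vtable, out / "validation.csv", chash)
            report.stages["validate"] = {"n_candidates": len(hit_ids),
                                         "n_validated": len(validated_ids)}

    report.funnel = {"n_compounds": int(config.n_compounds),
                     "n_hits": len(hit_ids), "n_validated": len(validated_ids)}

    # ---- stage 5: signature extraction and drug connectivity -----------
    if config.run_signatures:
        with _timed(report, "signatures"):
            de, de_truth = synthdata.simulate_de_table(
                config.n_genes, config.n_up, config.n_down,
                seed=derive_seed(config.seed, "de_table"))
            de["padj"] = signatures.bh_adjust(de["pvalue"].to_numpy())
            de.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.10g")
            sig = signatures.extract_signature(de, n=config.signature_n, alpha=config.alpha)
            sig.to_json(out / "signature.json")

            labels = ([config.class_label] * config.n_class_drugs +
                      ["other"] * (config.n_drugs - config.n_class_drugs))
            anchor = {config.class_label: de.set_index("gene")["lfc"].to_numpy()}
            mat, _ = synthdata.simulate_reference_matrix(
                config.n_drugs, config.n_genes, class_labels=labels,
                class_concordance=config.class_concordance,
                seed=derive_seed(config.seed, "reference_matrix"),
                class_anchor=anchor)
            mat.to_tsv(out / "refmat.tsv")
            try:
                ranked = signatures.rank_drugs(sig, mat)
                enrich = signatures.class_enrichment(ranked, config.class_label,
                                                     top_k=config.top_k)
            except (KeyError, ValueError) as exc:
                raise StageError("signatures", str(exc)) from exc
            _write_csv(ranked, out / "connectivity.csv", chash)
            with open(out / "enrichment.json", "w") as fh:
                json.dump(enrich, fh, indent=1, sort_keys=True)
            report.stages["signatures"] = {
                "n_up": len(sig.up), "n_down": len(sig.down),
                "top_drug": str(ranked.drug_id.iloc[0]) if len(ranked) else None,
                "enrichment_p": enrich["p_hypergeom"]}

    # ---- stage 6: downstream phenotype statistics ----------------------
    if config.run_phenotypes:
        with _timed(report, "phenotypes"):
            arms = {"vehicle": config.s_vehicle, "drug": config.s_drug}
            series_by_cond = {}
            comp_frames = []
            for label, s in arms.items():
                df, _ = synthdata.simulate_competition(
                    0.5, s, list(config.competition_days),
                    n_cells_sampled=config.competition_n_cells,
                    seed=derive_seed(config.seed, f"competition_{label}"),
                    condition=label)
                series_by_cond[label] = df
                comp_frames.append(df)
            comp = pd.concat(comp_frames, ignore_index=True)
            _write_csv(comp, out / "competition.csv", chash)
            fit = phenotypes.compare_fitness(series_by_cond, reference="vehicle")
            fitness_df = pd.DataFrame([
                {"condition": lab, "s": est.s, "s_se": est.s_se, "p0_hat": est.p0_hat}
                for lab, est in fit["estimates"].items()])
            _write_csv(fitness_df, out / "fitness.csv", chash)

            surv, _ = synthdata.simulate_survival(
                dict(config.survival_probs), n_eggs=config.n_eggs,
                n_replicates=config.n_survival_replicates,
                seed=derive_seed(config.seed, "survival"))
            _write_csv(surv, out / "survival.csv", chash)
            surv_cmp = phenotypes.compare_survival(surv)

            bends, _ = synthdata.simulate_bends(
                dict(config.bend_means), n_worms=config.n_worms,
                seed=derive_seed(config.seed, "bends"))
            _write_csv(bends, out / "bends.csv", chash)
            bend_cmp = phenotypes.compare_bends(bends)

            contrasts = {"fitness": fit["contrasts"],
                         "survival": surv_cmp.to_dict(orient="records"),
                         "bends": bend_cmp.to_dict(orient="records")}
            with open(out / "contrasts.json", "w") as fh:
                json.dump(contrasts, fh, indent=1, sort_keys=True)
            report.stages["phenotypes"] = {
                "s_vehicle_hat": float(fit["estimates"]["vehicle"].s),
                "s_drug_hat": float(fit["estimates"]["drug"].s),
                "n_contrasts": sum(len(v) for v in contrasts.values())}

    report.to_json(out / "report.json")
    return report


def make_report(run_dir) -> tuple[str, bool]:
    """Human-readable run summary; funnel counts recomputed from files.

    Returns (markdown text, complete flag); the text is also written to
    ``<run_dir>/report.md``.  Missing stage outputs are reported as
    explicit gaps and render the run incomplete.
    """
    run_dir = Path(run_dir)
    lines = ["# Screen run report", ""]
    complete = True

    rj = run_dir / "report.json"
    if rj.exists():
        with open(rj) as fh:
            meta = json.load(fh)
        lines += [f"- config hash: `{meta['config_hash']}`",
                  f"- seed: {meta['seed']}",
                  f"- pipeline version: {meta['version']}", ""]
    else:
        lines += ["- MISSING: report.json", ""]
        complete = False

    n_compounds = n_hits = n_validated = None
    hits_path = run_dir / "hits.csv"
    if hits_path.exists():
        hits = _read_csv(hits_path)
        n_compounds = int(hits.compound_id.nunique())
        n_hits = int((hits.is_hit.astype(str).str.lower() == "true").sum())
    else:
        lines.append("- MISSING: hits.csv")
        complete = False
    val_path = run_dir / "validation.csv"
    if val_path.exists():
        vt = _read_csv(val_path)
        n_validated = (int(vt.loc[vt.validated.astype(str).str.lower() == "true",
                                  "compound_id"].nunique())
                       if len(vt) else 0)
    else:
        lines.append("- MISSING: validation.csv")
        complete = False

    lines += ["", "## Screen funnel", ""]
    lines.append(f"compounds screened -> primary hits -> validated: "
                 f"{n_compounds} -> {n_hits} -> {n_validated}")

    enr = run_dir / "enrichment.json"
    if enr.exists():
        with open(enr) as fh:
            e = json.load(fh)
        lines += ["", "## Connectivity",
                  f"- class `{e['class']}`: {e['overlap']}/{e['top_k']} in top ranks "
                  f"(expected {e['expected']:.2f}), hypergeometric p = {e['p_hypergeom']:.3g}"]
    fit = run_dir / "fitness.csv"
    if fit.exists():
        fd = _read_csv(fit)
        lines += ["", "## Competition fitness", ""]
        for _, r in fd.iterrows():
            lines.append(f"- {r.condition}: s = {r.s:.4f} +/- {r.s_se:.4f} per day")
    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.md", "w") as fh:
        fh.write(text)
    return text, complete
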