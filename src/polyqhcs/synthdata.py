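"""Seeded generators for every input the screening pipeline consumes.

Each generator emulates one of the assay designs in the study: a
1,216-compound triplicate 384-well viability screen with scattered
controls, nuclear-stain images with known nuclei, differential-expression
tables with planted up/down genes, reference drug-signature rank matrices
with a planted agonist class, logistic-decline growth-competition
proportions, binomial embryo survival, and Poisson worm bend counts.

Every generator returns its dataset together with a :class:`SimTruth`
record of the planted ground truth, and derives its random stream from a
single integer seed through a named substream, so adding a generator
never perturbs another's stream.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenSimConfig",
    "SimTruth",
    "PlateSet",
    "PlacementError",
    "simulate_screen",
    "simulate_nuclei_image",
    "simulate_de_table",
    "simulate_reference_matrix",
    "simulate_competition",
    "simulate_survival",
    "simulate_bends",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed disjointly in the image."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from a single master seed.

    The stream key is (seed, crc32(name)), so each generator owns an
    independent, reproducible stream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def derive_seed(seed: int, name: str) -> int:
    """Deterministic child seed (< 2^31) for a named pipeline stage."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# --------------------------------------------------------------------------
# screen simulation
# --------------------------------------------------------------------------

#: 384-well geometry
N_ROWS, N_COLS = 16, 24


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study-design parameters of the simulated viability screen.

    Defaults reproduce the screen's geometry: 1,216 compounds (1,122
    approved + 94 epigenetic drugs) in triplicate 384-well plates at
    1 uM, ~100 expected nuclei per dox-only control well so that pure
    counting noise gives a control CV of ~10%.
    """

    n_compounds: int = 1216
    n_replicate_plates: int = 3
    plate_format: int = 384
    doses: Sequence[float] = (1.0,)
    baseline_count: float = 200.0       # expected nuclei, no-dox control well
    dox_effect: float = 0.5             # multiplicative viability factor of polyQ induction
    n_active: int = 0
    rescue_effects: Sequence[float] = ()
    n_toxic: int = 0
    toxic_effects: Sequence[float] = ()
    plate_factor_sd: float = 0.0        # SD of per-plate log-normal factor
    edge_effect: float = 1.0            # multiplicative factor on border wells
    dispersion: Optional[float] = None  # NB size r; None = Poisson limit
    noise: str = "negbin"               # "negbin" (counts) or "gaussian" (matched mean/variance)
    controls_per_plate: int = 16        # wells of EACH control role per plate
    compound_ids: Optional[Sequence[str]] = None
    active_ids: Optional[Sequence[str]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 0 or self.n_replicate_plates < 1:
            raise ValueError("n_compounds must be >= 0 and n_replicate_plates >= 1")
        if self.plate_format != N_ROWS * N_COLS:
            raise ValueError("only 384-well (16x24) plates are supported")
        if self.baseline_count <= 0:
            raise ValueError("baseline_count must be > 0")
        if not (0 < self.dox_effect <= 1):
            raise ValueError("dox_effect must be in (0, 1]")
        if self.n_active + self.n_toxic > self.n_compounds:
            raise ValueError("n_active + n_toxic must not exceed n_compounds")
        if self.controls_per_plate < 8:
            raise ValueError("need >= 8 scattered control wells of each role per plate")
        for eff in tuple(self.rescue_effects) + tuple(self.toxic_effects):
            if eff <= 0:
                raise ValueError("all multiplicative effects must be > 0")
        for eff in self.toxic_effects:
            if eff >= 1:
                raise ValueError("toxic_effects must be in (0, 1)")
        if self.edge_effect <= 0 or (self.dispersion is not None and self.dispersion <= 0):
            raise ValueError("edge_effect and dispersion must be > 0")
        if self.noise not in ("negbin", "gaussian"):
            raise ValueError("noise must be 'negbin' or 'gaussian'")
        if not self.doses or any(d <= 0 for d in self.doses):
            raise ValueError("doses must be a nonempty list of positive concentrations")
        if self.compound_ids is not None and len(self.compound_ids) != self.n_compounds:
            raise ValueError("compound_ids length must equal n_compounds")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside every simulated dataset."""

    active_ids: list = field(default_factory=list)
    toxic_ids: list = field(default_factory=list)
    effect_by_compound: dict = field(default_factory=dict)
    nuclei_centers: list = field(default_factory=list)   # (row, col, radius) per nucleus
    signature_truth: dict = field(default_factory=dict)  # {"up": [...], "down": [...]}
    class_truth: dict = field(default_factory=dict)      # drug_id -> class label
    fitness_truth: dict = field(default_factory=dict)    # {"s": ..., "p0": ...}
    survival_truth: dict = field(default_factory=dict)   # arm -> death probability
    bend_truth: dict = field(default_factory=dict)       # arm -> mean bends per 30 s

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


@dataclass
class PlateSet:
    """Well-level measurements of a (possibly multi-plate) screen.

    ``wells`` is a tidy table with columns plate_id, layout_id,
    replicate, row, col, well, role, compound_id, dose_uM, nuclei_count,
    is_edge.  ``replicate_of`` maps plate_id -> replicate index.
    """

    wells: pd.DataFrame

    COLUMNS = ["plate_id", "layout_id", "replicate", "row", "col", "well",
               "role", "compound_id", "dose_uM", "nuclei_count", "is_edge"]

    @property
    def replicate_of(self) -> dict:
        return dict(self.wells.drop_duplicates("plate_id")[["plate_id", "replicate"]].values)

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "PlateSet":
        df = pd.read_csv(path, dtype={"compound_id": str}, keep_default_na=False)
        df["compound_id"] = df["compound_id"].fillna("")
        return cls(wells=df)


def well_label(row: int, col: int) -> str:
    """1-based (row, col) -> 'A01'-style label."""
    return f"{chr(ord('A') + row - 1)}{col:02d}"


def simulate_screen(config: ScreenSimConfig) -> tuple[PlateSet, SimTruth]:
    """Simulate a multi-plate replicate screen with scattered controls.

    Well counts are drawn as NB(mean = baseline * dox_effect^[dox] *
    effect_c * plate_factor * edge_factor, dispersion); controls are
    scattered at seed-determined interior positions, identical across the
    replicate plates of a layout.  Each (compound, dose) pair occupies
    one well per replicate plate.
    """
    config.validate()
    rng = substream(config.seed, "screen")

    if config.compound_ids is None:
        compound_ids = [f"C{i + 1:04d}" for i in range(config.n_compounds)]
    else:
        compound_ids = [str(c) for c in config.compound_ids]

    # planted actives / toxics and their true multiplicative effects
    if config.active_ids is not None:
        if len(config.active_ids) != config.n_active:
            raise ValueError("active_ids length must equal n_active")
        unknown = set(config.active_ids) - set(compound_ids)
        if unknown:
            raise ValueError(f"active_ids not among compounds: {sorted(unknown)}")
        active = [str(c) for c in config.active_ids]
        rest = [c for c in compound_ids if c not in set(active)]
        toxic = list(rng.choice(rest, size=config.n_toxic, replace=False)) if config.n_toxic else []
    else:
        picked = rng.choice(compound_ids, size=config.n_active + config.n_toxic, replace=False)
        active = [str(c) for c in picked[:config.n_active]]
        toxic = [str(c) for c in picked[config.n_active:]]

    def _broadcast(effects, n, what):
        effects = tuple(effects)
        if n == 0:
            return ()
        if len(effects) == 1:
            return effects * n
        if len(effects) != n:
            raise ValueError(f"{what} must have length 1 or {n}")
        return effects

    rescue = _broadcast(config.rescue_effects or (1.5,), config.n_active, "rescue_effects")
    toxic_eff = _broadcast(config.toxic_effects or (0.5,), config.n_toxic, "toxic_effects")
    effect_by_compound = {c: 1.0 for c in compound_ids}
    effect_by_compound.update(dict(zip(active, rescue)))
    effect_by_compound.update(dict(zip(toxic, toxic_eff)))

    # layout geometry: (compound, dose) units fill non-control wells
    all_rc = [(r, c) for r in range(1, N_ROWS + 1) for c in range(1, N_COLS + 1)]
    interior = [(r, c) for (r, c) in all_rc
                if 1 < r < N_ROWS and 1 < c < N_COLS]
    units = [(cid, d) for cid in compound_ids for d in config.doses]
    capacity = config.plate_format - 2 * config.controls_per_plate
    n_layouts = max(1, -(-len(units) // capacity))

    frames = []
    for layout in range(n_layouts):
        chunk = units[layout * capacity:(layout + 1) * capacity]
        # scattered, seed-determined control positions (interior wells)
        ctrl_idx = rng.choice(len(interior), size=2 * config.controls_per_plate, replace=False)
        ctrl_pos = [interior[i] for i in ctrl_idx]
        nodox_pos = set(ctrl_pos[:config.controls_per_plate])
        doxonly_pos = set(ctrl_pos[config.controls_per_plate:])
        compound_pos = [p for p in all_rc if p not in nodox_pos and p not in doxonly_pos]
        pos_to_k = {p: k for k, p in enumerate(compound_pos)}

        rows, cols, roles, cids, doses = [], [], [], [], []
        for (r, c) in all_rc:
            rows.append(r)
            cols.append(c)
            if (r, c) in nodox_pos:
                roles.append("no_dox_control")
                cids.append("")
                doses.append(0.0)
            elif (r, c) in doxonly_pos:
                roles.append("dox_only_control")
                cids.append("")
                doses.append(0.0)
            else:
                k = pos_to_k[(r, c)]
                if k < len(chunk):
                    roles.append("compound")
                    cids.append(chunk[k][0])
                    doses.append(chunk[k][1])
                else:                       # unused wells on the last layout
                    roles.append("unused")
                    cids.append("")
                    doses.append(0.0)
        lay = pd.DataFrame({
            "layout_id": f"L{layout + 1:03d}", "row": rows, "col": cols,
            "well": [well_label(r, c) for r, c in zip(rows, cols)],
            "role": roles, "compound_id": cids, "dose_uM": doses,
        })
        lay = lay[lay.role != "unused"].reset_index(drop=True)  # empty wells are not read out
        lay["is_edge"] = ((lay.row == 1) | (lay.row == N_ROWS) |
                          (lay.col == 1) | (lay.col == N_COLS))
        for rep in range(1, config.n_replicate_plates + 1):
            plate = lay.copy()
            plate["replicate"] = rep
            plate["plate_id"] = f"L{layout + 1:03d}R{rep}"
            frames.append(plate)

    wells = pd.concat(frames, ignore_index=True)

    # expected counts
    mean = np.full(len(wells), config.baseline_count)
    dox = wells.role != "no_dox_control"
    mean[dox] *= config.dox_effect
    eff = wells.compound_id.map(lambda c: effect_by_compound.get(c, 1.0)).to_numpy()
    mean *= eff
    mean[wells.is_edge.to_numpy()] *= config.edge_effect
    if config.plate_factor_sd > 0:
        plate_ids = wells.plate_id.unique()
        factors = dict(zip(plate_ids, rng.lognormal(0.0, config.plate_factor_sd, len(plate_ids))))
        mean *= wells.plate_id.map(factors).to_numpy()

    # noise
    if config.noise == "negbin":
        if config.dispersion is None:
            counts = rng.poisson(mean).astype(float)
        else:
            lam = rng.gamma(config.dispersion, mean / config.dispersion)
            counts = rng.poisson(lam).astype(float)
    else:  # gaussian with the same mean-variance relation
        var = mean + (0.0 if config.dispersion is None else mean ** 2 / config.dispersion)
        counts = rng.normal(mean, np.sqrt(var))
        counts = np.maximum(counts, 0.0)
    wells["nuclei_count"] = counts
    wells = wells[PlateSet.COLUMNS]

    truth = SimTruth(
        active_ids=sorted(active),
        toxic_ids=sorted(toxic),
        effect_by_compound=effect_by_compound,
    )
    return PlateSet(wells=wells), truth


# --------------------------------------------------------------------------
# nuclei images
# --------------------------------------------------------------------------

def simulate_nuclei_image(
    n_nuclei: int,
    shape: tuple[int, int] = (256, 256),
    intensity_params: Optional[Mapping[str, float]] = None,
    overlap_policy: str = "disjoint",
    seed: int = 0,
) -> tuple[np.ndarray, SimTruth]:
    """Render a 16-bit grayscale nuclear-stain image with known nuclei.

    Nuclei are Gaussian intensity spots of radius ``radius_range`` at
    recorded centers over additive Gaussian background noise.  Under the
    default ``disjoint`` policy, all pairwise center distances exceed the
    sum of the two radii plus a 2-px gap; if no such placement is found a
    :class:`PlacementError` is raised rather than silently truncating.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if min(shape) < 16:
        raise ValueError("image must be at least 16x16")
    if overlap_policy not in ("disjoint", "free"):
        raise ValueError("overlap_policy must be 'disjoint' or 'free'")
    p = {"radius_range": (6.0, 9.0), "amplitude_range": (2000.0, 4000.0),
         "background": 100.0, "noise_sd": 15.0, "gap": 2.0}
    p.update(intensity_params or {})
    rng = substream(seed, "nuclei_image")

    h, w = shape
    centers: list[tuple[float, float, float]] = []
    max_tries = 200 * max(n_nuclei, 1)
    tries = 0
    while len(centers) < n_nuclei:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_nuclei} disjoint nuclei in a {h}x{w} image")
        tries += 1
        radius = rng.uniform(*p["radius_range"])
        margin = radius + 2
        if 2 * margin >= min(h, w):
            raise PlacementError("image too small for the requested nucleus radius")
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if overlap_policy == "disjoint":
            ok = all((r - r0) ** 2 + (c - c0) ** 2 > (radius + rad0 + p["gap"]) ** 2
                     for r0, c0, rad0 in centers)
            if not ok:
                continue
        centers.append((r, c, radius))

    img = np.full(shape, p["background"], dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for r, c, radius in centers:
        amp = rng.uniform(*p["amplitude_range"])
        sigma = radius / 2.0
        img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
    img += rng.normal(0.0, p["noise_sd"], shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)

    truth = SimTruth(nuclei_centers=[(float(r), float(c), float(rad)) for r, c, rad in centers])
    return img, truth


# --------------------------------------------------------------------------
# differential expression and reference signatures
# --------------------------------------------------------------------------

def simulate_de_table(
    n_genes: int,
    n_up: int,
    n_down: int,
    lfc_magnitude: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Differential-expression table with planted up/down-regulated genes.

    Planted genes receive |LFC| >= ``lfc_magnitude`` and tiny p-values;
    null genes have LFC ~ N(0, 0.1) and Uniform(0, 1) p-values.
    """
    if n_up < 0 or n_down < 0 or n_up + n_down > n_genes:
        raise ValueError("need n_up + n_down <= n_genes and both >= 0")
    rng = substream(seed, "de_table")
    genes = [f"G{i + 1:06d}" for i in range(n_genes)]
    planted = rng.choice(genes, size=n_up + n_down, replace=False)
    up, down = set(planted[:n_up]), set(planted[n_up:])
    lfc = rng.normal(0.0, 0.1, n_genes)
    pval = rng.uniform(0.0, 1.0, n_genes)
    for i, g in enumerate(genes):
        if g in up:
            lfc[i] = lfc_magnitude + abs(rng.normal(0.0, 0.5))
            pval[i] = 10 ** (-rng.uniform(6, 12))
        elif g in down:
            lfc[i] = -(lfc_magnitude + abs(rng.normal(0.0, 0.5)))
            pval[i] = 10 ** (-rng.uniform(6, 12))
    de = pd.DataFrame({"gene": genes, "lfc": lfc, "pvalue": pval})
    truth = SimTruth(signature_truth={"up": sorted(up), "down": sorted(down)})
    return de, truth


@dataclass
class ReferenceSignatureMatrix:
    """Per-drug full gene rankings (1 = most up-regulated) with class labels."""

    ranks: pd.DataFrame          # genes x drugs, integer ranks
    classes: dict                # drug_id -> class label

    @property
    def drugs(self) -> list:
        return list(self.ranks.columns)

    @property
    def genes(self) -> list:
        return list(self.ranks.index)

    def validate(self) -> None:
        n = len(self.ranks.index)
        for d in self.ranks.columns:
            r = np.sort(self.ranks[d].to_numpy())
            if not np.array_equal(r, np.arange(1, n + 1)):
                raise ValueError(f"ranking of drug {d} is not a permutation of 1..{n}")

    def to_tsv(self, path) -> None:
        self.ranks.to_csv(path, sep="\t", index_label="gene")
        with open(str(path) + ".classes.json", "w") as fh:
            json.dump(self.classes, fh, indent=1, sort_keys=True)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceSignatureMatrix":
        ranks = pd.read_csv(path, sep="\t", index_col="gene")
        try:
            with open(str(path) + ".classes.json") as fh:
                classes = json.load(fh)
        except FileNotFoundError:
            classes = {d: "" for d in ranks.columns}
        return cls(ranks=ranks, classes=classes)


def simulate_reference_matrix(
    n_drugs: int,
    n_genes: int,
    class_labels: Optional[Sequence[str]] = None,
    class_concordance: float = 0.7,
    seed: int = 0,
    class_anchor: Optional[Mapping[str, Sequence[float]]] = None,
) -> tuple[ReferenceSignatureMatrix, SimTruth]:
    """Reference drug-signature rank matrix with correlated drug classes.

    Each drug's latent gene score is sqrt(c) * class_vector +
    sqrt(1 - c) * noise, so two drugs in the same class have score
    correlation ``class_concordance``; rankings are the descending order
    of the scores (rank 1 = most up-regulated).  ``class_anchor`` may
    supply the latent vector of specific classes (e.g. an expression
    profile a query signature was derived from), standardized before use.
    """
    if not (0.0 <= class_concordance <= 1.0):
        raise ValueError("class_concordance must be in [0, 1]")
    if n_drugs < 0 or n_genes < 0:
        raise ValueError("n_drugs and n_genes must be >= 0")
    rng = substream(seed, "reference_matrix")
    drugs = [f"D{i + 1:04d}" for i in range(n_drugs)]
    if class_labels is None:
        class_labels = ["unlabeled"] * n_drugs
    if len(class_labels) != n_drugs:
        raise ValueError("class_labels must have one label per drug")
    classes = dict(zip(drugs, class_labels))

    class_vec = {}
    for lab in dict.fromkeys(class_labels):
        if class_anchor is not None and lab in class_anchor:
            v = np.asarray(class_anchor[lab], dtype=float)
            if v.shape != (n_genes,):
                raise ValueError(f"class_anchor[{lab!r}] must have length {n_genes}")
            sd = v.std()
            if sd == 0:
                raise ValueError(f"class_anchor[{lab!r}] is constant")
            class_vec[lab] = (v - v.mean()) / sd
        else:
            class_vec[lab] = rng.normal(0.0, 1.0, n_genes)
    genes = [f"G{i + 1:06d}" for i in range(n_genes)]
    ranks = {}
    c = class_concordance
    for d in drugs:
        score = np.sqrt(c) * class_vec[classes[d]] + np.sqrt(1 - c) * rng.normal(0.0, 1.0, n_genes)
        order = np.argsort(-score, kind="stable")
        rank = np.empty(n_genes, dtype=int)
        rank[order] = np.arange(1, n_genes + 1)
        ranks[d] = rank
    mat = ReferenceSignatureMatrix(
        ranks=pd.DataFrame(ranks, index=pd.Index(genes, name="gene")), classes=classes)
    truth = SimTruth(class_truth=dict(classes))
    return mat, truth


# --------------------------------------------------------------------------
# downstream phenotype assays
# --------------------------------------------------------------------------

def logistic_proportion(p0: float, s: float, t) -> np.ndarray:
    """Expected polyQ-positive fraction after t days of co-culture.

    A constant growth-rate deficit s (per day) gives
    p_t = p0 e^(-s t) / (p0 e^(-s t) + 1 - p0).
    """
    t = np.asarray(t, dtype=float)
    w = p0 * np.exp(-s * t)
    return w / (w + (1.0 - p0))


def simulate_competition(
    p0: float,
    s: float,
    days: Sequence[float],
    n_cells_sampled: int = 40_000,
    seed: int = 0,
    condition: str = "vehicle",
) -> tuple[pd.DataFrame, SimTruth]:
    """Growth-competition time series of polyQ vs control cells.

    Observed polyQ-positive counts at each day are Binomial(n, p_t)
    around the logistic decline; default sampling depth matches the 4e4
    cells seeded per arm in the flow-cytometry competition assay.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    days = list(days)
    if sorted(days) != days or days[0] != 0:
        raise ValueError("days must be sorted ascending and start at 0")
    if n_cells_sampled < 1:
        raise ValueError("n_cells_sampled must be >= 1")
    rng = substream(seed, "competition")
    p_t = logistic_proportion(p0, s, days)
    q94 = rng.binomial(n_cells_sampled, p_t)
    df = pd.DataFrame({
        "condition": condition, "day": days,
        "q94_count": q94, "control_count": n_cells_sampled - q94,
    })
    truth = SimTruth(fitness_truth={"s": float(s), "p0": float(p0), "condition": condition})
    return df, truth


def simulate_survival(
    death_prob,
    n_eggs: int = 150,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Embryo survival counts: per-replicate dead ~ Binomial(n_eggs, p).

    ``death_prob`` may be a single probability or a mapping
    arm label -> probability; the default design (150 eggs, triplicate)
    matches the zebrafish injection experiment.
    """
    if not isinstance(death_prob, Mapping):
        death_prob = {"arm": float(death_prob)}
    for arm, pr in death_prob.items():
        if not (0.0 <= pr <= 1.0):
            raise ValueError(f"death probability of arm {arm!r} outside [0, 1]")
    if n_eggs < 1 or n_replicates < 1:
        raise ValueError("n_eggs and n_replicates must be >= 1")
    rng = substream(seed, "survival")
    rows = []
    for arm, pr in death_prob.items():
        dead = rng.binomial(n_eggs, pr, n_replicates)
        for rep, d in enumerate(dead, start=1):
            rows.append({"arm": arm, "replicate": rep, "n_total": n_eggs, "n_dead": int(d)})
    truth = SimTruth(survival_truth={a: float(p) for a, p in death_prob.items()})
    return pd.DataFrame(rows), truth


def simulate_bends(
    mean_bends,
    n_worms: int = 30,
    dispersion: Optional[float] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Worm-motility counts: per-worm body bends per 30 s.

    Counts are Poisson(mean_bends), or negative-binomial when
    ``dispersion`` (NB size) is given.  ``mean_bends`` may be a mapping
    arm label -> rate.
    """
    if not isinstance(mean_bends, Mapping):
        mean_bends = {"arm": float(mean_bends)}
    for arm, m in mean_bends.items():
        if m < 0:
            raise ValueError(f"mean_bends of arm {arm!r} must be >= 0")
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if dispersion is not None and dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = substream(seed, "bends")
    rows = []
    for arm, m in mean_bends.items():
        if dispersion is None or m == 0:
            counts = rng.poisson(m, n_worms)
        else:
            lam = rng.gamma(dispersion, m / dispersion, n_worms)
            counts = rng.poisson(lam)
        for i, c in enumerate(counts, start=1):
            rows.append({"arm": arm, "worm_id": i, "bends_30s": int(c)})
    truth = SimTruth(bend_truth={a: float(m) for a, m in mean_bends.items()})
    return pd.DataFrame(rows), truth
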