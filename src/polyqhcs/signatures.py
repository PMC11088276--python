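"""Transcriptional signatures and connectivity-based drug matching.

From a differential-expression table, the signature is the set of top
up- and down-regulated N genes (BH-adjusted p < alpha, ranked by LFC).
Connectivity against a reference drug-signature rank matrix is the
classic bidirectional Kolmogorov-Smirnov enrichment: the up and down
gene sets are scored separately along each drug's full gene ranking and
combined into tau = (ES_up - ES_down)/2 when the two enrichments point
in opposite directions, 0 otherwise.  Over-representation of a drug
class among the top-ranked drugs is assessed with a one-sided
hypergeometric test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import ReferenceSignatureMatrix

__all__ = [
    "GeneSignature",
    "ConnectivityResult",
    "bh_adjust",
    "extract_signature",
    "connectivity_score",
    "rank_drugs",
    "class_enrichment",
    "signature_from_ranking",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    adjusted_(i) = min_{j >= i} p_(j) * m / j on the sorted scale,
    clipped at 1, reported in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class GeneSignature:
    """Ordered up/down gene lists defining a transcriptional signature."""

    up: list
    down: list
    n: int = 150
    alpha: float = 0.05

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets overlap")

    def reversed(self) -> "GeneSignature":
        return GeneSignature(up=list(self.down), down=list(self.up),
                             n=self.n, alpha=self.alpha)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"up": self.up, "down": self.down,
                       "n": self.n, "alpha": self.alpha}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GeneSignature":
        with open(path) as fh:
            d = json.load(fh)
        return cls(up=d["up"], down=d["down"],
                   n=d.get("n", 150), alpha=d.get("alpha", 0.05))


def extract_signature(
    de: pd.DataFrame,
    n: int = 150,
    alpha: float = 0.05,
    rank_by: str = "lfc",
) -> GeneSignature:
    """Top up/down-regulated N genes among BH-significant genes.

    ``up``: padj < alpha and LFC > 0, sorted by LFC descending;
    ``down``: padj < alpha and LFC < 0, sorted by LFC ascending; both
    truncated at N.  LFC ties break by smaller raw p, then gene id.
    ``rank_by='pvalue'`` orders the significant sets by significance
    instead of effect size.
    """
    if de.empty:
        raise ValueError("differential-expression table is empty")
    required = {"gene", "lfc", "pvalue"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    if de["gene"].duplicated().any():
        raise ValueError("gene ids must be unique")
    if rank_by not in ("lfc", "pvalue"):
        raise ValueError("rank_by must be 'lfc' or 'pvalue'")
    de = de.copy()
    if "padj" not in de.columns:
        de["padj"] = bh_adjust(de["pvalue"].to_numpy())
    sig = de[de.padj < alpha]

    up = sig[sig.lfc > 0]
    down = sig[sig.lfc < 0]
    if rank_by == "lfc":
        up = up.sort_values(["lfc", "pvalue", "gene"], ascending=[False, True, True],
                            kind="mergesort")
        down = down.sort_values(["lfc", "pvalue", "gene"], ascending=[True, True, True],
                                kind="mergesort")
    else:
        up = up.sort_values(["pvalue", "lfc", "gene"], ascending=[True, False, True],
                            kind="mergesort")
        down = down.sort_values(["pvalue", "lfc", "gene"], ascending=[True, True, True],
                                kind="mergesort")
    return GeneSignature(up=list(up.gene.head(n)), down=list(down.gene.head(n)),
                         n=n, alpha=alpha)


@dataclass
class ConnectivityResult:
    """Bidirectional enrichment of one signature in one drug's ranking."""

    drug_id: str
    es_up: float
    es_down: float
    tau: float
    rank: int = 0
    drug_class: str = ""


def _ks_enrichment(positions: np.ndarray, n_total: int, n_hits: int) -> float:
    """Signed KS statistic of a hit set along a ranking.

    Unweighted GSEA walk: +1/n_hits at a hit, -1/(n_total - n_hits) at a
    miss; returns the walk value of largest magnitude (its sign gives
    the direction of the deviation).
    """
    # integer-scaled walk (x n_hits*(n_total-n_hits)) keeps the extremes exact
    n_miss = n_total - n_hits
    walk = np.full(n_total, -n_hits, dtype=np.int64)
    walk[positions] = n_miss
    cum = np.cumsum(walk)
    return float(cum[np.argmax(np.abs(cum))]) / (n_hits * n_miss)


def _positions(genes, ranking: pd.Series) -> np.ndarray:
    pos = ranking.reindex(genes)
    if pos.isna().any():
        missing = [g for g, v in zip(genes, pos) if pd.isna(v)]
        raise KeyError(f"signature genes absent from the reference ranking: {missing[:10]}")
    return pos.to_numpy(dtype=int) - 1


def connectivity_score(sig: GeneSignature, ranking: pd.Series,
                       drug_id: str = "") -> ConnectivityResult:
    """Score one signature against one drug's full gene ranking.

    ``ranking`` maps gene -> rank (1 = most up-regulated in the
    reference profile).  tau is near +1 when the query's up genes sit at
    the top and its down genes at the bottom (concordant signatures).
    """
    if not sig.up and not sig.down:
        raise ValueError("signature is empty")
    n = len(ranking)
    if len(sig.up) >= n or len(sig.down) >= n:
        raise ValueError("signature covers the whole gene universe")
    es_up = _ks_enrichment(_positions(sig.up, ranking), n, len(sig.up)) if sig.up else 0.0
    es_down = _ks_enrichment(_positions(sig.down, ranking), n, len(sig.down)) if sig.down else 0.0
    if es_up * es_down < 0:
        tau = (es_up - es_down) / 2.0
    else:
        tau = 0.0
    return ConnectivityResult(drug_id=drug_id, es_up=es_up, es_down=es_down, tau=tau)


def rank_drugs(
    sig: GeneSignature,
    matrix: ReferenceSignatureMatrix,
    ignore_missing: bool = False,
) -> pd.DataFrame:
    """Connectivity of the query signature against every reference drug.

    Returns one row per drug sorted by tau descending (ties by drug_id)
    with 1-based rank.  Signature genes absent from the reference
    universe raise by default; ``ignore_missing`` drops them and records
    the count in ``df.attrs['n_missing_genes']``.
    """
    universe = set(matrix.genes)
    missing = [g for g in list(sig.up) + list(sig.down) if g not in universe]
    if missing and not ignore_missing:
        raise KeyError(f"signature genes missing from reference universe: {missing[:10]}")
    if missing:
        sig = GeneSignature(up=[g for g in sig.up if g in universe],
                            down=[g for g in sig.down if g in universe],
                            n=sig.n, alpha=sig.alpha)
        if not sig.up and not sig.down:
            raise ValueError("no signature genes remain after dropping missing ones")
    rows = []
    for d in matrix.drugs:
        r = connectivity_score(sig, matrix.ranks[d], drug_id=d)
        rows.append({"drug_id": d, "drug_class": matrix.classes.get(d, ""),
                     "es_up": r.es_up, "es_down": r.es_down, "tau": r.tau})
    if not rows:
        out = pd.DataFrame(columns=["drug_id", "drug_class", "es_up", "es_down", "tau", "rank"])
    else:
        out = pd.DataFrame(rows).sort_values(
            ["tau", "drug_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["n_missing_genes"] = len(missing)
    return out


def class_enrichment(results: pd.DataFrame, class_label: str,
                     top_k: float = 0.05) -> dict:
    """Over-representation of a drug class among the top-k connectivity hits.

    ``top_k`` is an absolute count (int > 1) or a fraction of drugs;
    returns the overlap count and a one-sided hypergeometric tail p.
    """
    if results.empty:
        raise ValueError("empty connectivity result")
    labels = results["drug_class"]
    if class_label not in set(labels):
        raise KeyError(f"unknown drug class: {class_label!r}")
    n = len(results)
    k = int(round(top_k * n)) if 0 < top_k < 1 else int(top_k)
    if not (0 < k <= n):
        raise ValueError("top_k must select between 1 and n_drugs drugs")
    ranked = results.sort_values("rank")
    top = ranked.head(k)
    n_class = int((labels == class_label).sum())
    overlap = int((top["drug_class"] == class_label).sum())
    p = float(stats.hypergeom.sf(overlap - 1, n, n_class, k))
    return {"class": class_label, "top_k": k, "n_drugs": n,
            "class_size": n_class, "overlap": overlap,
            "expected": n_class * k / n, "p_hypergeom": p}


def signature_from_ranking(matrix: ReferenceSignatureMatrix, drug_id: str,
                           n: int = 150) -> GeneSignature:
    """Query signature read off one reference drug's ranking extremes.

    The up set is the drug's n most up-regulated genes, the down set its
    n most down-regulated; useful for planted-recovery studies.
    """
    if drug_id not in matrix.ranks.columns:
        raise KeyError(f"unknown drug: {drug_id}")
    r = matrix.ranks[drug_id].sort_values()
    if 2 * n >= len(r):
        raise ValueError("n too large for the gene universe")
    return GeneSignature(up=list(r.index[:n]), down=list(r.index[-n:][::-1]), n=n)
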