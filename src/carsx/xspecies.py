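"""Cross-species integration: ortholog merge, anchor signatures, joint PCA
response score, ROC evaluation, and Stouffer combined gene ranking.

The workflow mirrors a paired human/mouse responder-vs-nonresponder design:
per-species DE tables are merged on orthologous symbols, genes passing
|z| > 1.96 in both species with a consistent fold-change direction become
"anchor" features, anchor expression is z-scaled within each species and
pooled for a joint PCA whose first component serves as the therapy response
score, and a genome-wide combined ranking is obtained by Stouffer combination
of the two species' signed Z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ortholog merge
# ---------------------------------------------------------------------------

def merge_orthologs(de_h: pd.DataFrame, de_m: pd.DataFrame,
                    ortholog_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge two species' DE tables on orthologous gene symbols.

    With no map, orthology is case-insensitive symbol identity restricted to
    1:1 matches; symbols that collide after case folding (many-to-one in
    either species) are dropped and logged. An explicit ``ortholog_map`` with
    columns ``human``/``mouse`` overrides the default and is likewise
    restricted to 1:1 pairs.

    Returns a table indexed by the human-side symbol with columns
    ``z_h``, ``log2FC_h``, ``z_m``, ``log2FC_m``, ``combined_z``.
    """
    if de_h.empty or de_m.empty:
        raise ValueError("both DE tables must be nonempty")

    def _unique_keyed(index: pd.Index, keys: pd.Series) -> pd.Series:
        counts = keys.value_counts()
        dup = counts[counts > 1].index
        if len(dup):
            dropped = [g for g, k in keys.items() if k in set(dup)]
            logger.warning("dropping %d genes with ambiguous symbol mapping: %s",
                           len(dropped), dropped[:10])
        keep = keys[~keys.isin(set(dup))]
        return keep

    if ortholog_map is not None:
        om = ortholog_map.copy()
        if not {"human", "mouse"} <= set(om.columns):
            raise ValueError("ortholog_map needs columns 'human' and 'mouse'")
        for col in ("human", "mouse"):
            n0 = len(om)
            om = om[~om[col].duplicated(keep=False)]
            if len(om) < n0:
                logger.warning("dropped %d non-1:1 ortholog pairs on %s side",
                               n0 - len(om), col)
        om = om[om["human"].isin(de_h.index) & om["mouse"].isin(de_m.index)]
        h_sel = de_h.loc[om["human"]]
        m_sel = de_m.loc[om["mouse"]]
        merged_index = pd.Index(om["human"], name="gene")
    else:
        keys_h = _unique_keyed(de_h.index, pd.Series(de_h.index.str.upper(),
                                                     index=de_h.index))
        keys_m = _unique_keyed(de_m.index, pd.Series(de_m.index.str.upper(),
                                                     index=de_m.index))
        shared = keys_h[keys_h.isin(set(keys_m))]
        inv_m = pd.Series(keys_m.index, index=keys_m.values)
        h_genes = shared.index
        m_genes = inv_m.loc[shared.values].values
        h_sel = de_h.loc[h_genes]
        m_sel = de_m.loc[m_genes]
        merged_index = pd.Index(h_genes, name="gene")

    if len(merged_index) == 0:
        raise ValueError("no shared genes between the two species' DE tables")

    merged = pd.DataFrame({
        "z_h": h_sel["z"].to_numpy(),
        "log2FC_h": h_sel["log2FC"].to_numpy(),
        "z_m": m_sel["z"].to_numpy(),
        "log2FC_m": m_sel["log2FC"].to_numpy(),
    }, index=merged_index)
    merged["combined_z"] = (merged["z_h"] + merged["z_m"]) / np.sqrt(2.0)
    return merged


# ---------------------------------------------------------------------------
# anchor (shared signature) selection
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Per-species directional signatures and the shared anchor set.

    ``species_sets`` holds each species' |z|-filtered directional gene table;
    ``equalized`` holds the per-species sign-consistent lists cut to equal
    size by |log2FC|; ``anchors`` is their intersection (identical direction
    in both species by construction).
    """

    species_sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    equalized: dict[str, list[str]] = field(default_factory=dict)
    anchors: pd.DataFrame = field(default_factory=pd.DataFrame)
    universe_size: int = 0

    @property
    def anchor_genes(self) -> list[str]:
        return list(self.anchors.index)

    def __len__(self) -> int:
        return len(self.anchors)


def select_anchors(merged: pd.DataFrame, z_thresh: float = 1.96) -> SignatureSet:
    """Three-step anchor selection from a merged cross-species DE table.

    1. per species, keep genes with ``|z| > z_thresh``;
    2. among those, keep genes whose log2FC sign agrees between species;
    3. equalize the two species' lists to the smaller size, ranking by
       ``|log2FC|`` within each species (ties broken by symbol).

    An empty result is valid (warned, not an error).
    """
    if merged.empty:
        raise ValueError("merged DE table is empty")
    sig = SignatureSet(universe_size=len(merged))

    pass_h = merged[merged["z_h"].abs() > z_thresh]
    pass_m = merged[merged["z_m"].abs() > z_thresh]
    sig.species_sets["human"] = pd.DataFrame(
        {"direction": np.sign(pass_h["log2FC_h"]).astype(int)}, index=pass_h.index)
    sig.species_sets["mouse"] = pd.DataFrame(
        {"direction": np.sign(pass_m["log2FC_m"]).astype(int)}, index=pass_m.index)

    consistent = np.sign(merged["log2FC_h"]) == np.sign(merged["log2FC_m"])
    cons_h = pass_h[consistent.loc[pass_h.index]]
    cons_m = pass_m[consistent.loc[pass_m.index]]

    k = min(len(cons_h), len(cons_m))
    if k == 0:
        logger.warning("anchor selection produced an empty set "
                       "(z_thresh=%.3g, universe=%d)", z_thresh, len(merged))
        sig.equalized = {"human": [], "mouse": []}
        sig.anchors = pd.DataFrame(columns=["direction", "z_h", "z_m",
                                            "log2FC_h", "log2FC_m"])
        return sig

    def _top_k(tbl: pd.DataFrame, fc_col: str) -> list[str]:
        # |log2FC| descending; ties at the cutoff break to the smaller symbol
        ordered = sorted(tbl.index, key=lambda g: (-abs(tbl.at[g, fc_col]), g))
        return ordered[:k]

    eq_h = _top_k(cons_h, "log2FC_h")
    eq_m = _top_k(cons_m, "log2FC_m")
    sig.equalized = {"human": eq_h, "mouse": eq_m}

    shared = sorted(set(eq_h) & set(eq_m))
    anchors = merged.loc[shared, ["z_h", "z_m", "log2FC_h", "log2FC_m"]].copy()
    anchors.insert(0, "direction", np.sign(anchors["log2FC_h"]).astype(int))
    sig.anchors = anchors
    return sig


# ---------------------------------------------------------------------------
# overlap significance
# ---------------------------------------------------------------------------

def overlap_test(set_a, set_b, universe: int) -> tuple[int, float]:
    """Two-tailed Fisher exact test of the overlap between two gene sets.

    The 2x2 table counts membership in/out of each set over a universe of
    ``universe`` genes; the two-tailed p sums hypergeometric probabilities of
    tables no more likely than the observed one.
    """
    a, b = set(set_a), set(set_b)
    k = len(a & b)
    na, nb = len(a), len(b)
    if universe < len(a | b):
        raise ValueError(
            f"universe ({universe}) smaller than |A union B| ({len(a | b)})")
    table = [[k, na - k], [nb - k, universe - na - nb + k]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return k, float(p)


# ---------------------------------------------------------------------------
# joint PCA response score
# ---------------------------------------------------------------------------

class JointPCAScorer(BaseEstimator, TransformerMixin):
    """PC1 response score over z-scaled anchor features, sklearn-style.

    ``fit`` learns per-feature centering/scaling and the first principal
    axis from samples x anchors data; ``transform`` projects onto PC1. The
    PC1 sign is fixed so the anchor with the largest |loading| has a positive
    loading.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = X.columns
        x = X.to_numpy(dtype=float)
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        z = (x - self.mean_) / self.scale_
        # PC1 via SVD of the centered (already z-scaled) matrix
        zc = z - z.mean(axis=0)
        _, _, vt = np.linalg.svd(zc, full_matrices=False)
        loading = vt[0]
        if loading[np.argmax(np.abs(loading))] < 0:
            loading = -loading
        self.loadings_ = pd.Series(loading, index=self.feature_names_in_)
        self.center_ = z.mean(axis=0)
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        x = X[self.feature_names_in_].to_numpy(dtype=float)
        z = (x - self.mean_) / self.scale_ - self.center_
        return z @ self.loadings_.to_numpy()


def joint_pca_score(expr_h: ExpressionMatrix, expr_m: ExpressionMatrix,
                    anchors) -> pd.Series:
    """PC1 score per sample from jointly decomposed anchor expression.

    Each matrix is subset to the anchor genes (mouse side matched
    case-insensitively), z-scaled gene-wise within its species to remove
    location/scale and species batch offsets, column-concatenated, and
    decomposed; the first principal component is returned per sample.
    """
    if hasattr(anchors, "anchor_genes"):
        genes = list(anchors.anchor_genes)
    else:
        genes = list(anchors)
    if not genes:
        raise ValueError("anchor set is empty")

    blocks = []
    for expr in (expr_h, expr_m):
        upper = {str(g).upper(): g for g in expr.genes}
        missing = [g for g in genes if str(g).upper() not in upper]
        if missing:
            raise KeyError(
                f"anchor genes missing from {expr.species or 'a'} matrix: {missing}")
        rows = [upper[str(g).upper()] for g in genes]
        x = expr.values.loc[rows].to_numpy(dtype=float)
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        blocks.append(pd.DataFrame((x - mean) / sd, index=genes,
                                   columns=expr.samples))
    combined = pd.concat(blocks, axis=1)
    if combined.columns.has_duplicates:
        raise ValueError("sample IDs collide between the two species")

    scorer = JointPCAScorer().fit(combined.T)
    scores = scorer.transform(combined.T)
    return pd.Series(scores, index=combined.columns, name="pc1_score")


# ---------------------------------------------------------------------------
# ROC evaluation
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """AUC with bootstrap CI plus accuracy at the Youden-optimal threshold."""

    auc: float
    ci_low: float
    ci_high: float
    accuracy: float
    threshold: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "accuracy": self.accuracy, "threshold": self.threshold,
                "n_pos": self.n_pos, "n_neg": self.n_neg}


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """AUC of ``scores`` against binary ``labels`` with a stratified bootstrap CI.

    AUC is the Mann-Whitney U statistic scaled to [0, 1], ties counted 0.5.
    The CI is the percentile interval over ``n_boot`` stratified resamples.
    Accuracy is evaluated at the Youden-optimal (tpr - fpr) threshold.
    """
    s = np.asarray(pd.Series(scores), dtype=float)
    y = np.asarray(pd.Series(labels)).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    auc = float(roc_auc_score(y, s))

    pos = s[y == 1]
    neg = s[y == 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        boots[i] = roc_auc_score(
            np.r_[np.ones(len(bp)), np.zeros(len(bn))], np.r_[bp, bn])
    lo, hi = np.quantile(boots, [0.025, 0.975])

    # Youden threshold over the midpoints of consecutive distinct scores
    uniq = np.unique(s)
    cands = np.r_[uniq[0] - 1.0, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + 1.0]
    best_acc, best_j, best_thr = 0.0, -np.inf, cands[0]
    for thr in cands:
        pred = (s > thr).astype(int)
        tpr = (pred[y == 1] == 1).mean()
        fpr = (pred[y == 0] == 1).mean()
        j = tpr - fpr
        if j > best_j:
            best_j = j
            best_thr = float(thr)
            best_acc = float((pred == y).mean())
    return RocResult(auc=auc, ci_low=float(min(lo, auc)),
                     ci_high=float(max(hi, auc)), accuracy=best_acc,
                     threshold=best_thr, n_pos=len(pos), n_neg=len(neg))


# ---------------------------------------------------------------------------
# Stouffer combined ranking
# ---------------------------------------------------------------------------

def stouffer_rank(merged: pd.DataFrame) -> pd.DataFrame:
    """Rank merged genes by the Stouffer combination ``(z_h + z_m) / sqrt(2)``.

    Sorted descending by ``combined_z``; exact ties break by gene symbol
    (lexicographic, stable). Adds a 1-based ``rank`` column.
    """
    z = merged[["z_h", "z_m"]].to_numpy(dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z_h and z_m must be finite")
    out = merged.copy()
    out["combined_z"] = (out["z_h"] + out["z_m"]) / np.sqrt(2.0)
    out = out.sort_index(kind="stable")
    out = out.sort_values("combined_z", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
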