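"""ARACNe-style regulon inference, activity scoring, and hidden-driver filtering.

A desk-scale reimplementation of the mutual-information network / activity
chain used for master-regulator ("hidden driver") analysis:

* plug-in mutual information on equal-frequency (quantile) bins, natural log;
* bootstrap consensus networks — per bootstrap, driver-gene MI edges are kept
  above a permutation-null threshold and pruned by the data-processing
  inequality (DPI) within MI triangles; edges supported by improbably many
  bootstraps (binomial tail, Bonferroni) enter the consensus network;
* regulon activity as the signed, MI-weighted mean of z-scaled target
  expression ("weightedmean");
* differential activity (DA) with the same moderated two-group machinery as
  differential expression (DE); and
* the hidden-driver filter: drivers with significant DA (z > 1.96) whose own
  expression is not elevated (z_DE < 0).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix, Interactome, Regulon
from .diffexpr import moderated_two_group

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mutual information on quantile bins
# ---------------------------------------------------------------------------

def default_n_bins(n_samples: int) -> int:
    """Bin heuristic: ``max(2, floor(sqrt(n)/2))`` bins per axis."""
    return max(2, int(np.sqrt(n_samples) // 2))


def _quantile_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes along the last axis of a 1-D or 2-D array.

    Ties are split by stable sort order, so every bin holds ``n // n_bins``
    (+-1) observations regardless of the marginal distribution.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    bin_of_rank = (np.arange(n) * n_bins) // n
    order = np.argsort(x, axis=-1, kind="stable")
    codes = np.empty(x.shape, dtype=np.int64)
    if x.ndim == 1:
        codes[order] = bin_of_rank
    else:
        np.put_along_axis(codes, order,
                          np.broadcast_to(bin_of_rank, x.shape), axis=-1)
    return codes


def _mi_from_codes(d_codes: np.ndarray, g_codes: np.ndarray,
                   n_bins: int) -> np.ndarray:
    """Plug-in MI (nats) between one code vector and each row of a code matrix."""
    g_codes = np.atleast_2d(g_codes)
    n_rows, n = g_codes.shape
    nb2 = n_bins * n_bins
    idx = (np.arange(n_rows)[:, None] * nb2 + g_codes * n_bins
           + d_codes[None, :]).ravel()
    joint = np.bincount(idx, minlength=n_rows * nb2).reshape(n_rows, n_bins, n_bins)
    p = joint / n
    pi = p.sum(axis=2, keepdims=True)
    pj = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * pj))
    return np.nansum(terms, axis=(1, 2))


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in mutual information between two sample vectors (natural log).

    Both vectors are discretized on equal-frequency bins (``n_bins`` per
    axis; default ``max(2, floor(sqrt(n)/2))``). For identical vectors with
    ``n`` divisible by ``n_bins`` the estimate equals ``ln(n_bins)`` exactly.
    A constant vector carries no information and returns 0 (warned).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI set to 0")
        return 0.0
    nb = n_bins or default_n_bins(n)
    return float(_mi_from_codes(_quantile_codes(x, nb),
                                _quantile_codes(y, nb), nb)[0])


# ---------------------------------------------------------------------------
# DPI pruning
# ---------------------------------------------------------------------------

def dpi_prune(edges: dict[tuple[int, int], float],
              tolerance: float = 0.0) -> dict[tuple[int, int], float]:
    """Data-processing-inequality pruning of an undirected weighted edge set.

    For every triangle, the weakest edge is marked for removal if it is
    weaker than both other edges minus ``tolerance``; all marks are applied
    after scanning every triangle (classic ARACNe behaviour).
    """
    adj: dict[int, set[int]] = {}
    for (u, v) in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def w(a: int, b: int) -> float:
        return edges[(a, b) if a < b else (b, a)]

    doomed: set[tuple[int, int]] = set()
    for (u, v) in edges:
        common = adj[u] & adj[v]
        for t in common:
            trio = [((u, v) if u < v else (v, u), w(u, v)),
                    ((u, t) if u < t else (t, u), w(u, t)),
                    ((v, t) if v < t else (t, v), w(v, t))]
            trio.sort(key=lambda e: e[1])
            weakest, w0 = trio[0]
            if w0 < trio[1][1] - tolerance and w0 < trio[2][1] - tolerance:
                doomed.add(weakest)
    return {e: mi for e, mi in edges.items() if e not in doomed}


# ---------------------------------------------------------------------------
# network inference
# ---------------------------------------------------------------------------

class MutualInfoNetwork(BaseEstimator, TransformerMixin):
    """Bootstrap-consensus MI network inference, sklearn-style.

    ``fit(X)`` (samples x genes) infers signed, weighted regulons for the
    configured driver genes; ``transform(X)`` returns per-sample driver
    activity (samples x drivers) via the weighted-mean rule.

    Parameters
    ----------
    drivers : sequence of gene identifiers (columns of X).
    n_bootstraps : bootstrap resamples of the sample axis (default 100).
    consensus_p : binomial-tail threshold on bootstrap support, Bonferroni-
        corrected across candidate edges; ``None`` disables consensus
        filtering (any supported edge is kept).
    dpi_tolerance : DPI slack; 0 is the strict classic rule.
    alpha : per-bootstrap edge significance vs the permutation null.
    n_permutations : driver-label permutations per bootstrap for the null.
    n_bins : quantile bins per axis (default ``max(2, floor(sqrt(n)/2))``).
    random_state : seed for resampling and permutations.

    Attributes
    ----------
    interactome_ : Interactome
    regulons_ : dict of driver -> Regulon
    """

    def __init__(self, drivers=(), n_bootstraps: int = 100,
                 consensus_p: float | None = 0.01, dpi_tolerance: float = 0.0,
                 alpha: float = 0.05, n_permutations: int = 100,
                 n_bins: int | None = None, random_state: int | None = 0):
        self.drivers = drivers
        self.n_bootstraps = n_bootstraps
        self.consensus_p = consensus_p
        self.dpi_tolerance = dpi_tolerance
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        genes = list(X.columns)
        gene_pos = {g: i for i, g in enumerate(genes)}
        drivers = [d for d in self.drivers if d in gene_pos]
        if not drivers:
            raise ValueError("none of the requested drivers is in the matrix")
        skipped = [d for d in self.drivers if d not in gene_pos]
        if skipped:
            logger.warning("drivers absent from matrix: %s", skipped[:10])

        x = X.to_numpy(dtype=float).T  # genes x samples
        n_genes, n = x.shape
        if n < 30:
            warnings.warn(f"only {n} samples; MI estimates will be noisy")
        nb = self.n_bins or default_n_bins(n)
        d_idx = np.array([gene_pos[d] for d in drivers])
        rng = np.random.default_rng(self.random_state)

        support: dict[tuple[int, int], int] = {}
        mi_sum: dict[tuple[int, int], float] = {}
        B = self.n_bootstraps
        for b in range(B):
            idx = rng.integers(0, n, size=n) if B > 1 else np.arange(n)
            codes = _quantile_codes(x[:, idx], nb)
            edges: dict[tuple[int, int], float] = {}
            for di, d in zip(d_idx, drivers):
                dc = codes[di]
                mi = _mi_from_codes(dc, codes, nb)
                # Permutation null: permute the driver on the *original*
                # samples, then apply the same bootstrap index, so duplicated
                # samples stay aligned exactly as in the observed pairs.
                # alpha is family-wise per bootstrap: the threshold is the
                # (1-alpha) quantile of the per-permutation max over genes,
                # so a chance edge enters a bootstrap network with
                # probability ~alpha in total, not per gene.
                null_max = np.empty(self.n_permutations)
                for p in range(self.n_permutations):
                    dperm = rng.permutation(x[di])[idx]
                    null_max[p] = _mi_from_codes(
                        _quantile_codes(dperm, nb), codes, nb).max()
                thresh = np.quantile(null_max, 1.0 - self.alpha)
                for gi in np.nonzero(mi >= thresh)[0]:
                    if gi == di:
                        continue
                    e = (di, int(gi)) if di < gi else (int(gi), di)
                    # driver-driver pairs are evaluated from both ends; keep max
                    edges[e] = max(edges.get(e, -np.inf), float(mi[gi]))
            edges = dpi_prune(edges, self.dpi_tolerance)
            for e, mi_val in edges.items():
                support[e] = support.get(e, 0) + 1
                mi_sum[e] = mi_sum.get(e, 0.0) + mi_val

        # consensus: is the edge supported more often than chance would allow?
        kept = {}
        m = len(support)
        for e, k in support.items():
            if self.consensus_p is None or B == 1:
                keep = True
            else:
                p_tail = stats.binom.sf(k - 1, B, self.alpha)
                keep = p_tail * m < self.consensus_p
            if keep:
                kept[e] = (mi_sum[e] / k, k)

        # signs from Spearman correlation on the full (non-bootstrapped) data
        ranks = stats.rankdata(x, axis=1)
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((rc ** 2).sum(axis=1))
        norms = np.where(norms > 0, norms, 1.0)

        d_set = set(d_idx.tolist())
        regulons: dict[str, Regulon] = {}
        for di, d in zip(d_idx, drivers):
            rows = []
            for (u, v), (mi_val, k) in kept.items():
                if di not in (u, v):
                    continue
                gi = v if u == di else u
                rho = float(rc[di] @ rc[gi] / (norms[di] * norms[gi]))
                rows.append({"target": genes[gi], "mi": mi_val,
                             "sign": 1 if rho >= 0 else -1,
                             "spearman": rho, "support": k})
            regulons[d] = Regulon(d, pd.DataFrame(
                rows, columns=["target", "mi", "sign", "spearman", "support"]))
        self.regulons_ = regulons
        self.interactome_ = Interactome(regulons, params={
            "n_bootstraps": B, "consensus_p": self.consensus_p,
            "dpi_tolerance": self.dpi_tolerance, "alpha": self.alpha,
            "n_permutations": self.n_permutations, "n_bins": nb,
            "random_state": self.random_state,
        })
        return self

    def transform(self, X):
        """Weighted-mean driver activity for new samples (samples x drivers)."""
        X = pd.DataFrame(X)
        expr = ExpressionMatrix(X.T, "log2cpm")
        act = compute_activity(expr, self.interactome_)
        return act.values.T


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def infer_network(expr: ExpressionMatrix, driver_ids, n_bootstraps: int = 100,
                  consensus_p: float | None = 0.01, dpi_tolerance: float = 0.0,
                  alpha: float = 0.05, n_permutations: int = 100,
                  n_bins: int | None = None, seed: int = 0) -> Interactome:
    """Infer a driver-centric MI interactome from an expression matrix."""
    est = MutualInfoNetwork(
        drivers=list(driver_ids), n_bootstraps=n_bootstraps,
        consensus_p=consensus_p, dpi_tolerance=dpi_tolerance, alpha=alpha,
        n_permutations=n_permutations, n_bins=n_bins, random_state=seed)
    est.fit(expr.values.T)
    return est.interactome_


def compute_activity(expr: ExpressionMatrix, interactome) -> ExpressionMatrix:
    """Weighted-mean regulon activity (drivers x samples).

    Each gene is z-scaled across samples; a driver's activity in a sample is
    ``sum_t sign_t * w_t * z_t / sum_t w_t`` over its targets present in the
    matrix (absent targets are dropped with a log message; a regulon with no
    present target is omitted with a warning).
    """
    regulons = interactome.regulons if isinstance(interactome, Interactome) \
        else dict(interactome)
    x = expr.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd
    pos = {g: i for i, g in enumerate(expr.genes)}

    rows, names = [], []
    for driver, reg in regulons.items():
        t = reg.targets
        present = t["target"].isin(pos)
        if not present.any():
            warnings.warn(f"regulon {driver!r} has no target in the matrix; omitted")
            continue
        if (~present).any():
            logger.info("regulon %s: %d absent targets dropped",
                        driver, int((~present).sum()))
        tp = t[present]
        w = tp["mi"].to_numpy(dtype=float)
        s = tp["sign"].to_numpy(dtype=float)
        zi = z[[pos[g] for g in tp["target"]]]
        rows.append((s * w) @ zi / np.abs(w).sum())
        names.append(driver)
    if not rows:
        raise ValueError("no regulon had any target present in the matrix")
    act = pd.DataFrame(np.vstack(rows), index=names, columns=expr.samples)
    return ExpressionMatrix(act, "activity", expr.species)


def differential_activity(activity: ExpressionMatrix, groups,
                          case: str = "case", control: str = "control",
                          d0: float | None = None) -> pd.DataFrame:
    """Moderated two-group comparison of a driver activity matrix.

    Identical contract to :func:`carsx.diffexpr.moderated_two_group`; the
    ``log2FC`` column is the raw activity difference (activity is on the z
    scale, not log2, but the machinery is shared).
    """
    return moderated_two_group(activity, groups, case=case, control=control, d0=d0)


def hidden_drivers(da: pd.DataFrame, de: pd.DataFrame,
                   z_da_thresh: float = 1.96,
                   z_de_max: float = 0.0) -> pd.DataFrame:
    """Drivers with significant differential activity but non-elevated expression.

    Keeps drivers with ``z_DA > z_da_thresh`` and ``z_DE < z_de_max``.
    Returned sorted by ``z_da`` descending, with a secondary ordering by mean
    activity (``rank_by_activity``) also provided.
    """
    shared = da.index.intersection(de.index)
    if len(shared) == 0:
        raise ValueError("no shared driver identifiers between DA and DE tables")
    tbl = pd.DataFrame({
        "z_da": da.loc[shared, "z"],
        "z_de": de.loc[shared, "z"],
        "mean_activity": da.loc[shared, "ave_expr"],
    })
    tbl = tbl[(tbl["z_da"] > z_da_thresh) & (tbl["z_de"] < z_de_max)]
    tbl = tbl.sort_index(kind="stable").sort_values("z_da", ascending=False,
                                                    kind="stable")
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    tbl["rank_by_activity"] = tbl["mean_activity"].rank(
        ascending=False, method="first").astype(int)
    return tbl
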