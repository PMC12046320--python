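"""Normalization and empirical-Bayes moderated two-group differential expression.

The two-group test follows the limma contract: per-gene log2 fold change
(case minus control), pooled equal-variance residuals, and an empirical-Bayes
"squeeze" of the per-gene variances toward a prior estimated by method of
moments on the distribution of log sample variances (Smyth-style). The
moderated t is referred to a t distribution with ``d0 + d_g`` degrees of
freedom and converted to a signed normal-scale Z via the two-sided p-value,

    z = sign(log2FC) * Phi^{-1}(1 - p / 2),

capped at |z| = 8.21, the double-precision quantile limit, so that downstream
Stouffer combination never sees infinities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix

Z_CAP = 8.21  #: |z| ceiling guarding against p-value underflow


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log2cpm(counts: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2 counts-per-million: ``log2(count / colsum * 1e6 + pseudocount)``.

    The default pseudocount of 1 keeps zero counts finite. Columns with an
    all-zero count vector have no defined composition and raise.
    """
    if counts.normalization != "raw_counts":
        raise ValueError(f"expected raw_counts input, got {counts.normalization!r}")
    x = counts.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    colsums = x.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        bad = list(counts.samples[zero])
        raise ValueError(f"all-zero count column(s): {bad}")
    vals = np.log2(x / colsums[None, :] * 1e6 + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.genes, columns=counts.samples),
        "log2cpm", counts.species)


# ---------------------------------------------------------------------------
# empirical-Bayes variance squeezing
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` from sample variances.

    Method of moments on ``log(s2)``: under the scaled-F model the residuals
    ``e_g = log s2_g - digamma(df/2) + log(df/2)`` have mean ``log s0^2 +
    digamma(d0/2) - log(d0/2)`` and excess variance ``trigamma(d0/2)`` beyond
    ``trigamma(df/2)``. Returns ``(inf, exp(mean))`` when the observed spread
    is no larger than expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.log(s2[ok]).mean())) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


# ---------------------------------------------------------------------------
# signed Z from p
# ---------------------------------------------------------------------------

def z_from_p(p, direction_sign):
    """Signed normal-scale Z from a two-sided p-value.

    ``z = sign * Phi^{-1}(1 - p/2)`` with |z| capped at 8.21. Accepts scalars
    or arrays; ``p`` must lie in (0, 1].
    """
    p_arr = np.asarray(p, dtype=float)
    sign = np.asarray(direction_sign, dtype=float)
    if (p_arr <= 0).any() or (p_arr > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p_arr / 2.0)
    z = np.minimum(z, Z_CAP)
    out = sign * z
    if np.isscalar(p) and np.isscalar(direction_sign):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# moderated two-group test
# ---------------------------------------------------------------------------

class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-group t-test, sklearn-style.

    Parameters
    ----------
    d0 : float or None
        Prior degrees of freedom. ``None`` (default) estimates ``d0`` and
        ``s0_sq`` by method of moments; ``0`` disables moderation (ordinary
        pooled t); ``numpy.inf`` fully shrinks to the prior variance.
    s0_sq : float or None
        Prior variance; estimated when ``None`` and needed.
    min_mean : float or None
        Optional expression filter: genes with overall mean below this are
        excluded from the result table.

    Attributes
    ----------
    results_ : DataFrame
        One row per tested gene: ``log2FC``, ``t``, ``p``, ``z``,
        ``ave_expr``, ``flag``.
    d0_, s0_sq_ : float
        Hyperparameters actually used.
    """

    def __init__(self, d0: float | None = None, s0_sq: float | None = None,
                 min_mean: float | None = None):
        self.d0 = d0
        self.s0_sq = s0_sq
        self.min_mean = min_mean

    def fit(self, X, y):
        """Fit on ``X`` (samples x genes) with binary ``y`` (1 = case)."""
        if isinstance(X, pd.DataFrame):
            genes = X.columns
            x = X.to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float)
            genes = pd.RangeIndex(x.shape[1])
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1, True, False}:
            raise ValueError("y must be binary with 1 = case, 0 = control")
        y = y.astype(bool)
        n1 = int(y.sum())
        n2 = int((~y).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"each group needs >= 2 samples (case={n1}, control={n2})")

        case = x[y]
        ctrl = x[~y]
        m1 = case.mean(axis=0)
        m2 = ctrl.mean(axis=0)
        fc = m1 - m2
        ave = x.mean(axis=0)
        ss = case.var(axis=0, ddof=1) * (n1 - 1) + ctrl.var(axis=0, ddof=1) * (n2 - 1)
        df = n1 + n2 - 2
        s2 = ss / df

        d0, s0_sq = self.d0, self.s0_sq
        if d0 is None or (d0 not in (0,) and not np.isinf(d0) and s0_sq is None):
            d0_hat, s0_hat = squeeze_variances(s2, df)
            if d0 is None:
                d0 = d0_hat
            if s0_sq is None:
                s0_sq = s0_hat
        if s0_sq is None:
            s0_sq = 1.0  # unused when d0 == 0

        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = d0 + df

        se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = fc / se
        constant = (s2_tilde == 0) & (fc == 0)
        degenerate = (s2_tilde == 0) & (fc != 0)
        t = np.where(constant, 0.0, t)
        t[degenerate] = np.sign(fc[degenerate]) * np.inf

        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        p = np.where(constant, 1.0, p)

        z = z_from_p(p, np.sign(fc))
        z = np.where(constant, 0.0, z)

        flag = np.where(constant, "constant", "")
        res = pd.DataFrame({
            "log2FC": fc, "t": t, "p": p, "z": z, "ave_expr": ave, "flag": flag,
        }, index=genes)
        res.index.name = "gene"
        if self.min_mean is not None:
            res = res[res["ave_expr"] >= self.min_mean]
        self.results_ = res
        self.d0_ = float(d0)
        self.s0_sq_ = float(s0_sq)
        self.n_case_ = n1
        self.n_control_ = n2
        return self


def moderated_two_group(expr: ExpressionMatrix, groups, case: str = "case",
                        control: str = "control", d0: float | None = None,
                        s0_sq: float | None = None,
                        min_mean: float | None = None) -> pd.DataFrame:
    """Moderated DE between two sample groups of an expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples, any non-count normalization.
    groups : mapping or Series
        ``sample -> label``; labels must partition the matrix's samples into
        the ``case`` and ``control`` values.
    case, control : str
        Labels of the two groups; log2FC is case minus control.
    d0, s0_sq, min_mean : see :class:`ModeratedTTest`.

    Returns
    -------
    DataFrame indexed by gene with columns log2FC, t, p, z, ave_expr, flag.
    """
    g = pd.Series(groups)
    missing = [s for s in expr.samples if s not in g.index]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    labels = g.loc[expr.samples]
    extra = set(labels.unique()) - {case, control}
    if extra:
        raise ValueError(f"unexpected group labels: {sorted(extra)} "
                         f"(expected {case!r}/{control!r})")
    y = (labels == case).to_numpy()
    est = ModeratedTTest(d0=d0, s0_sq=s0_sq, min_mean=min_mean)
    est.fit(expr.values.T, y.astype(int))
    res = est.results_
    res.attrs["d0"] = est.d0_
    res.attrs["s0_sq"] = est.s0_sq_
    return res
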