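"""Gene-set enrichment: weighted running-sum GSEA, KS p-values, set activity.

``gsea`` implements the classic two-sided running-sum enrichment score on a
single precomputed ranking: hits advance the sum by ``|statistic|^w``
(normalized), misses retreat uniformly, and the score is the largest
excursion. Significance is reported two ways — a gene-label permutation p
(random sets of the same size, one-sided on the observed sign) and the
analytic two-sample Kolmogorov-Smirnov p comparing in-set vs out-of-set rank
positions. At weight exponent 0 the running-sum statistic reduces to the KS
statistic, which the test-suite exploits as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSet, Regulon


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set in one ranking."""

    name: str
    es: float
    nes: float
    p_perm: float
    p_ks: float
    leading_edge: list[str]
    n_hits: int

    def to_dict(self) -> dict:
        return {"name": self.name, "es": self.es, "nes": self.nes,
                "p_perm": self.p_perm, "p_ks": self.p_ks,
                "n_hits": self.n_hits, "leading_edge": self.leading_edge}


def _running_es(stat_sorted: np.ndarray, hit_mask: np.ndarray,
                weight_exponent: float) -> tuple[float, int]:
    """Max-excursion enrichment score and its position for one hit mask."""
    n = len(stat_sorted)
    nh = int(hit_mask.sum())
    w = np.abs(stat_sorted) ** weight_exponent
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit_mask.astype(float)
        denom = float(nh)
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit_mask) / (n - nh)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(np.clip(dev[i], -1.0, 1.0)), i


def gsea(ranked, gene_set, weight_exponent: float = 1.0, n_perm: int = 1000,
         seed: int = 0) -> EnrichmentResult:
    """Running-sum enrichment of a gene set in a ranked statistic.

    Parameters
    ----------
    ranked : Series or mapping
        gene -> ranking statistic (e.g. a signed Z); sorted descending
        internally, ties broken by symbol for determinism.
    gene_set : GeneSet or iterable of genes.
    weight_exponent : float
        Hit weights are ``|statistic|^exponent``; 0 gives the unweighted
        (KS-equivalent) statistic, 1 the classic weighted form.
    n_perm : int
        Gene-label permutations (random same-size sets) for NES and p_perm.
    seed : int
        Permutation seed.
    """
    s = pd.Series(ranked, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    if isinstance(gene_set, GeneSet):
        members, name = gene_set.members, gene_set.name
    else:
        members, name = list(gene_set), "gene_set"
    order = s.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable")
    genes = order.index.to_numpy()
    stat = order.to_numpy()
    hit = np.isin(genes, list(members))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError(f"gene set {name!r} does not intersect the ranking")
    if nh == len(genes):
        raise ValueError(f"gene set {name!r} covers the entire ranking")

    es, peak = _running_es(stat, hit, weight_exponent)

    n = len(genes)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        es_perm = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=nh, replace=False)] = True
            es_perm[b], _ = _running_es(stat, mask, weight_exponent)
        same_sign = (es_perm * np.sign(es) > 0 if es != 0
                     else np.ones(n_perm, bool))
        n_same = int(same_sign.sum())
        if n_same:
            nes = es / np.abs(es_perm[same_sign]).mean()
            p_perm = (1 + int((np.abs(es_perm[same_sign]) >= abs(es)).sum())) \
                / (1 + n_same)
        else:
            nes = np.sign(es) * np.inf if es else 0.0
            p_perm = 1.0 / (1 + n_perm)
    else:  # n_perm=0: analytic KS p only
        nes, p_perm = np.nan, np.nan

    positions = np.arange(n)
    p_ks = float(stats.ks_2samp(positions[hit], positions[~hit]).pvalue)

    if es >= 0:
        leading = [g for g, h in zip(genes[:peak + 1], hit[:peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hit[peak:]) if h]
    return EnrichmentResult(name=name, es=es, nes=float(nes),
                            p_perm=float(p_perm), p_ks=p_ks,
                            leading_edge=leading, n_hits=nh)


def signed_regulon_gsea(ranked, regulon: Regulon, weight_exponent: float = 1.0,
                        n_perm: int = 1000, seed: int = 0,
                        ) -> tuple[EnrichmentResult | None, EnrichmentResult | None]:
    """GSEA of a regulon's positive and negative targets, separately.

    When the driver's activity is higher in the cases at the top of the
    ranking, the positive targets enrich at the top (ES > 0) and the negative
    targets at the bottom (ES < 0). A missing partition yields ``None``.
    """
    ranked = pd.Series(ranked, dtype=float)
    in_rank = set(ranked.index)
    pos = [g for g in regulon.positive_targets if g in in_rank]
    neg = [g for g in regulon.negative_targets if g in in_rank]
    if not pos and not neg:
        raise ValueError(
            f"regulon {regulon.driver!r} has no target in the ranking")
    res_pos = gsea(ranked, GeneSet(f"{regulon.driver}_pos", pos),
                   weight_exponent, n_perm, seed) if pos else None
    res_neg = gsea(ranked, GeneSet(f"{regulon.driver}_neg", neg),
                   weight_exponent, n_perm, seed) if neg else None
    return res_pos, res_neg


def geneset_activity(expr: ExpressionMatrix, sets) -> ExpressionMatrix:
    """Per-sample gene-set activity: mean of z-scaled member expression.

    ``sets`` is an iterable of :class:`GeneSet` (or a mapping name -> genes).
    Sets with no member in the matrix are skipped with a warning. The result
    feeds :func:`carsx.network.differential_activity` for signature-level
    comparisons (e.g. M1 vs M2 macrophage polarization scoring).
    """
    import warnings

    if isinstance(sets, dict):
        sets = [GeneSet(k, list(v)) for k, v in sets.items()]
    x = expr.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd
    pos = {g: i for i, g in enumerate(expr.genes)}

    rows, names = [], []
    for gs in sets:
        idx = [pos[g] for g in gs.members if g in pos]
        if not idx:
            warnings.warn(f"gene set {gs.name!r} has no member in the matrix; skipped")
            continue
        rows.append(z[idx].mean(axis=0))
        names.append(gs.name)
    if not rows:
        raise ValueError("no gene set intersects the expression matrix")
    act = pd.DataFrame(np.vstack(rows), index=names, columns=expr.samples)
    return ExpressionMatrix(act, "activity", expr.species)
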