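"""Gene-set enrichment analysis: ranking, running-sum ES, permutation null, FDR.

The enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov-Smirnov-style running sum over a ranked gene list: walking the
ranking, the sum increases by |score|^p / sum(|score|^p over hits) at genes in
the set (p=0 gives the classic unweighted statistic) and decreases by
1/(N - N_H) at genes outside it. Significance comes from a permutation null
(phenotype relabeling when both classes are large enough, otherwise gene-set
resampling), the normalized ES (NES) divides by the mean same-signed null |ES|,
and the FDR q-value is the standard tail-ratio over pooled normalized scores.
Benjamini-Hochberg / Benjamini-Yekutieli adjustment is provided for the
unweighted hypergeometric-style path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, GeneSet, PhenotypeLabels

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_genes_snr",
    "enrichment_score",
    "gsea",
    "adjust_pvalues",
    "intersect_enriched",
]


@dataclass
class RankedList:
    """Genes ordered by descending score; ties broken by gene ID ascending."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene_ids and scores differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: set[str] = field(default_factory=set)
    n_perm: int = 0
    mode: str = "weighted"
    perm_type: str = "phenotype"
    seed: int = 0


# ---------------------------------------------------------------------------
# ranking


def _snr_scores(values: np.ndarray, pos_masks: np.ndarray, fallback_diff: bool) -> np.ndarray:
    """Signal-to-noise scores for each row of a boolean (n_perm, n_samples) mask stack.

    score = (mu_pos - mu_neg) / (sd_pos + sd_neg), each class SD floored at
    max(0.2 |mu|, 0.2) for that class (the Broad convention). With
    ``fallback_diff`` the score is the plain difference of means (used when a
    class has a single sample and an SD is undefined). Returns (n_perm, n_genes).
    """
    pos = pos_masks.astype(float)  # (P, S)
    neg = 1.0 - pos
    n_pos = pos.sum(axis=1)[:, None]  # (P, 1)
    n_neg = neg.sum(axis=1)[:, None]
    sum_x_pos = values @ pos.T  # (G, P)
    sum_x_neg = values @ neg.T
    mu_pos = (sum_x_pos / n_pos.T).T  # (P, G)
    mu_neg = (sum_x_neg / n_neg.T).T
    if fallback_diff:
        return mu_pos - mu_neg
    sq = values**2
    ss_pos = (sq @ pos.T).T
    ss_neg = (sq @ neg.T).T
    var_pos = np.maximum(ss_pos - n_pos * mu_pos**2, 0.0) / (n_pos - 1)
    var_neg = np.maximum(ss_neg - n_neg * mu_neg**2, 0.0) / (n_neg - 1)
    sd_pos = np.maximum(np.sqrt(var_pos), np.maximum(0.2 * np.abs(mu_pos), 0.2))
    sd_neg = np.maximum(np.sqrt(var_neg), np.maximum(0.2 * np.abs(mu_neg), 0.2))
    return (mu_pos - mu_neg) / (sd_pos + sd_neg)


def rank_genes_snr(matrix: ExpressionMatrix, labels: PhenotypeLabels) -> RankedList:
    """Rank genes by signal-to-noise between the two phenotype classes.

    Positive scores mean higher expression in the positive (first-named)
    class. When either class has fewer than 2 samples the score falls back to
    the difference of class means (warning); an empty class is an error.
    """
    aligned = labels.aligned_to(list(matrix.sample_ids))
    mask = aligned.mask()
    n_pos, n_neg = int(mask.sum()), int((~mask).sum())
    if n_pos < 1 or n_neg < 1:
        raise ValueError("each phenotype class needs at least one sample")
    fallback = n_pos < 2 or n_neg < 2
    if fallback:
        warnings.warn(
            "a class has <2 samples; using difference of means instead of SNR", stacklevel=2
        )
    # pre-sort genes by ID so a stable sort breaks score ties by gene ID ascending
    id_order = np.argsort(np.asarray(matrix.gene_ids, dtype=object), kind="stable")
    genes = [matrix.gene_ids[i] for i in id_order]
    scores = _snr_scores(matrix.values[id_order], mask[None, :], fallback)[0]
    order = np.argsort(-scores, kind="stable")
    return RankedList([genes[i] for i in order], scores[order])


# ---------------------------------------------------------------------------
# enrichment score


def _es_curve(scores: np.ndarray, hit: np.ndarray, weight_p: float) -> tuple[float, np.ndarray, int]:
    """Running sum, ES and extremum index for one ranked list (1-D arrays)."""
    n = scores.size
    n_h = int(hit.sum())
    if n_h == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_h == n:
        raise ValueError("gene set covers the whole ranked list; miss penalty undefined")
    w = np.where(hit, np.abs(scores) ** weight_p if weight_p else 1.0, 0.0)
    denom = w.sum()
    if denom == 0:  # all hit scores exactly 0 under p>0: fall back to unweighted
        w = hit.astype(float)
        denom = w.sum()
    p_hit = np.cumsum(w) / denom
    p_miss = np.cumsum(~hit) / (n - n_h)
    dev = p_hit - p_miss
    # first index within tolerance of the max |deviation|: ties between an
    # early -x and a later +x (equal in exact arithmetic) resolve to the first
    m = np.abs(dev)
    idx = int(np.argmax(m >= m.max() - 1e-10))
    return float(dev[idx]), dev, idx


def enrichment_score(
    ranked: RankedList, geneset: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, set[str]]:
    """ES, full running sum, and leading-edge genes for one set.

    The leading edge is the hit genes at or before the extremum of the running
    sum for positive ES, and at or after it for negative ES.
    """
    hit = np.array([g in geneset.genes for g in ranked.gene_ids])
    es, dev, idx = _es_curve(ranked.scores, hit, weight_p)
    if es >= 0:
        leading = {g for i, g in enumerate(ranked.gene_ids) if hit[i] and i <= idx}
    else:
        leading = {g for i, g in enumerate(ranked.gene_ids) if hit[i] and i >= idx}
    return es, dev, leading


def _es_batch(scores_ranked: np.ndarray, hits: np.ndarray, weight_p: float) -> np.ndarray:
    """ES for each row of (P, N) ranked scores with matching (P, N) hit masks."""
    n = scores_ranked.shape[1]
    n_h = hits.sum(axis=1)  # (P,)
    w = np.where(hits, np.abs(scores_ranked) ** weight_p if weight_p else 1.0, 0.0)
    denom = w.sum(axis=1)
    bad = denom == 0
    if bad.any():
        w[bad] = hits[bad].astype(float)
        denom = w.sum(axis=1)
    p_hit = np.cumsum(w, axis=1) / denom[:, None]
    p_miss = np.cumsum(~hits, axis=1) / (n - n_h)[:, None]
    dev = p_hit - p_miss
    m = np.abs(dev)
    idx = np.argmax(m >= m.max(axis=1, keepdims=True) - 1e-10, axis=1)
    return dev[np.arange(dev.shape[0]), idx]


# ---------------------------------------------------------------------------
# permutation GSEA


def _phenotype_null(
    values: np.ndarray,
    memberships: np.ndarray,
    mask: np.ndarray,
    n_perm: int,
    weight_p: float,
    fallback: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES (n_sets, n_perm) by relabeling samples and re-ranking each time."""
    n_samples = mask.size
    perm_masks = np.empty((n_perm, n_samples), dtype=bool)
    for p in range(n_perm):
        perm_masks[p] = mask[rng.permutation(n_samples)]
    scores = _snr_scores(values, perm_masks, fallback)  # (P, G)
    order = np.argsort(-scores, axis=1, kind="stable")
    scores_ranked = np.take_along_axis(scores, order, axis=1)
    null = np.empty((memberships.shape[0], n_perm))
    for s, member in enumerate(memberships):
        hits = member[order]
        null[s] = _es_batch(scores_ranked, hits, weight_p)
    return null


def _geneset_null(
    scores_ranked: np.ndarray,
    set_sizes: np.ndarray,
    n_perm: int,
    weight_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES (n_sets, n_perm) by drawing random gene sets of matching size."""
    n = scores_ranked.size
    tiled = np.broadcast_to(scores_ranked, (n_perm, n))
    null = np.empty((set_sizes.size, n_perm))
    for s, size in enumerate(set_sizes):
        hits = np.zeros((n_perm, n), dtype=bool)
        for p in range(n_perm):
            hits[p, rng.choice(n, size=size, replace=False)] = True
        null[s] = _es_batch(tiled, hits, weight_p)
    return null


def _tail_ratio_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """GSEA tail-ratio FDR over pooled normalized scores, monotonized within sign."""
    pool = nes_null.ravel()
    pool = pool[np.isfinite(pool)]
    q = np.ones_like(nes_obs)
    for sign in (1, -1):
        sel = np.flatnonzero(nes_obs >= 0) if sign > 0 else np.flatnonzero(nes_obs < 0)
        if sel.size == 0:
            continue
        n_null_side = max(int((pool >= 0).sum() if sign > 0 else (pool < 0).sum()), 1)
        n_obs_side = sel.size
        for i in sel:
            v = nes_obs[i]
            if sign > 0:
                frac_null = (pool >= v).sum() / n_null_side
                frac_obs = (nes_obs[sel] >= v).sum() / n_obs_side
            else:
                frac_null = (pool <= v).sum() / n_null_side
                frac_obs = (nes_obs[sel] <= v).sum() / n_obs_side
            q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
        # monotonize within sign: each set gets the min raw q among sets no more
        # extreme than itself (step-up, as in BH), so q is non-decreasing as
        # |NES| decreases
        order = sel[np.argsort(-np.abs(nes_obs[sel]), kind="stable")]
        suffix_min = np.minimum.accumulate(q[order][::-1])[::-1]
        q[order] = suffix_min
    return np.clip(q, 0.0, 1.0)


def gsea(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    genesets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    perm_type: str = "auto",
    min_size: int = 5,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Permutation GSEA for a collection of gene sets.

    ``perm_type='auto'`` uses phenotype relabeling when both classes have >=7
    samples and gene-set resampling otherwise (both can be forced). The
    nominal p uses add-one smoothing over same-signed null ES, NES divides by
    the mean same-signed null |ES|, and fdr_q is the pooled tail-ratio over
    normalized scores. Sets outside [min_size, max_size] (after intersection
    with the matrix genes) are skipped silently from the result list.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if perm_type not in ("auto", "phenotype", "gene_set"):
        raise ValueError(f"unknown perm_type {perm_type!r}")
    aligned = labels.aligned_to(list(matrix.sample_ids))
    mask = aligned.mask()
    n_pos, n_neg = int(mask.sum()), int((~mask).sum())
    fallback = n_pos < 2 or n_neg < 2
    if perm_type == "auto":
        perm_type = "phenotype" if min(n_pos, n_neg) >= 7 else "gene_set"

    id_order = np.argsort(np.asarray(matrix.gene_ids, dtype=object), kind="stable")
    genes = [matrix.gene_ids[i] for i in id_order]
    values = matrix.values[id_order]
    gene_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    kept: list[GeneSet] = []
    memberships = []
    for gs in genesets:
        member = np.zeros(n, dtype=bool)
        for g in gs.genes:
            i = gene_index.get(g)
            if i is not None:
                member[i] = True
        sz = int(member.sum())
        if sz < min_size or sz > max_size or sz == n:
            warnings.warn(f"gene set {gs.name!r} skipped (usable size {sz})", stacklevel=2)
            continue
        kept.append(gs)
        memberships.append(member)
    if not kept:
        return []
    memberships = np.array(memberships)

    scores = _snr_scores(values, mask[None, :], fallback)[0]
    order = np.argsort(-scores, kind="stable")
    scores_ranked = scores[order]
    ranked = RankedList([genes[i] for i in order], scores_ranked)

    mode = "weighted" if weight_p else "classic"
    rng = np.random.default_rng(seed)
    obs = np.empty(len(kept))
    leading: list[set[str]] = []
    for s, gs in enumerate(kept):
        hits = memberships[s][order]
        es, dev, idx = _es_curve(scores_ranked, hits, weight_p)
        obs[s] = es
        if es >= 0:
            leading.append({ranked.gene_ids[i] for i in np.flatnonzero(hits) if i <= idx})
        else:
            leading.append({ranked.gene_ids[i] for i in np.flatnonzero(hits) if i >= idx})

    if perm_type == "phenotype":
        null = _phenotype_null(values, memberships, mask, n_perm, weight_p, fallback, rng)
    else:
        null = _geneset_null(scores_ranked, memberships.sum(axis=1), n_perm, weight_p, rng)

    results = []
    nes_obs = np.empty(len(kept))
    nes_null = np.full_like(null, np.nan)
    p_nom = np.empty(len(kept))
    for s in range(len(kept)):
        ns = null[s]
        pos_mean = np.abs(ns[ns >= 0]).mean() if (ns >= 0).any() else np.abs(ns).mean()
        neg_mean = np.abs(ns[ns < 0]).mean() if (ns < 0).any() else np.abs(ns).mean()
        nes_null[s] = np.where(ns >= 0, ns / pos_mean, ns / neg_mean)
        if obs[s] >= 0:
            same = ns[ns >= 0]
            b = int((same >= obs[s]).sum())
            nes_obs[s] = obs[s] / pos_mean
        else:
            same = ns[ns < 0]
            b = int((same <= obs[s]).sum())
            nes_obs[s] = obs[s] / neg_mean
        p_nom[s] = (b + 1) / (same.size + 1)

    fdr = _tail_ratio_fdr(nes_obs, nes_null)
    for s, gs in enumerate(kept):
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                size=int(memberships[s].sum()),
                es=float(obs[s]),
                nes=float(nes_obs[s]),
                p_nominal=float(p_nom[s]),
                fdr_q=float(fdr[s]),
                leading_edge=leading[s],
                n_perm=n_perm,
                mode=mode,
                perm_type=perm_type,
                seed=seed,
            )
        )
    return results


# ---------------------------------------------------------------------------
# multiple testing and cross-dataset intersection


def adjust_pvalues(pvals, method: str = "BH") -> np.ndarray:
    """Step-up adjusted p-values (Benjamini-Hochberg or Benjamini-Yekutieli)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("BH", "BY"):
        raise ValueError(f"unknown method {method!r}")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh" if method == "BH" else "fdr_by")[1]


def intersect_enriched(
    results_a: list[EnrichmentResult],
    results_b: list[EnrichmentResult],
    q_threshold: float = 0.25,
) -> tuple[set[str], dict[str, int]]:
    """Set names enriched (fdr_q < threshold, same ES sign) in both analyses.

    Returns the intersection plus per-input pass counts for Venn-style
    reporting.
    """
    pass_a = {r.set_name: r.es for r in results_a if r.fdr_q < q_threshold}
    pass_b = {r.set_name: r.es for r in results_b if r.fdr_q < q_threshold}
    both = {
        name
        for name in pass_a.keys() & pass_b.keys()
        if np.sign(pass_a[name]) == np.sign(pass_b[name])
    }
    counts = {"a": len(pass_a), "b": len(pass_b), "both": len(both)}
    return both, counts
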