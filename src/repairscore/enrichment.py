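"""Score-correlated expression analysis and pathway enrichment.

The expression question is whether, WITHIN a group (cases or controls),
per-gene expression tracks the continuous repair score once sex, age,
smoking, and experimental batch are adjusted for — and whether the signal
concentrates in curated pathway groups (immune, cell cycle, other) rather
than in individually significant genes.

Pipeline: median-of-ratios size factors -> per-gene OLS of log2 normalized
counts on the score plus adjusters (Wald t on the score slope, BH q) ->
preranked gene-set enrichment on the signed-t ranking (weighted
Kolmogorov-Smirnov running sum, gene-label permutation null, signed NES,
pooled-null FDR) -> keyword curation of set names into pathway groups.
A subsampling loop checks that enrichment is not a sampling artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "per_gene_association",
    "preranked_gsea",
    "classify_pathways",
    "subsample_robustness",
    "DEFAULT_KEYWORDS",
]

logger = logging.getLogger(__name__)

T_CAP = 1e6  # Wald-t guard for (near-)noiseless genes

DEFAULT_KEYWORDS = {
    "immune": (
        "immune", "interferon", "cytokine", "leukocyte", "lymphocyte",
        "t_cell", "b_cell", "antigen", "inflammat", "chemokine", "mhc",
        "complement",
    ),
    "cell_cycle": (
        "cell_cycle", "mitotic", "mitosis", "dna_replication",
        "chromosome_segregation", "spindle", "checkpoint",
    ),
}


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    Uses genes with nonzero counts in every sample; each sample's factor is
    the median ratio of its counts to the gene-wise geometric mean, then the
    factors are rescaled to geometric mean 1.
    """
    c = counts.to_numpy(dtype=float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter low-coverage genes first"
        )
    logc = np.log(c[allpos])
    loggm = logc.mean(axis=1, keepdims=True)
    f = np.exp(np.median(logc - loggm, axis=0))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="size_factor")


def _association_design(scores, covariates: pd.DataFrame | None, n: int):
    cols = [np.ones(n), np.asarray(scores, dtype=float)]
    names = ["intercept", "score"]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
            else:
                levels = pd.unique(col.astype(str))
                for lv in sorted(levels)[1:]:
                    cols.append((col.astype(str) == lv).to_numpy(dtype=float))
                    names.append(f"{c}[{lv}]")
    X = np.column_stack(cols)
    # drop constant non-intercept columns (e.g. a single-level factor)
    keep = [0] + [j for j in range(1, X.shape[1]) if X[:, j].std() > 0]
    return X[:, keep], [names[j] for j in keep]


@dataclass
class GeneStats:
    """Per-gene score-association statistics and the GSEA rank metric."""

    table: pd.DataFrame  # index gene; slope, se, t, p, q, metric
    n_samples: int
    n_filtered: int

    @property
    def metric(self) -> pd.Series:
        return self.table["metric"]


def per_gene_association(
    counts: pd.DataFrame,
    scores,
    covariates: pd.DataFrame | None = None,
    *,
    min_mean: float = 5.0,
    factors: pd.Series | None = None,
) -> GeneStats:
    """OLS of log2 normalized expression on the score, per gene.

    ``counts`` is genes x samples for ONE group (cases or controls);
    ``covariates`` a sample-aligned frame of adjusters (numeric columns
    entered as-is, others dummy-coded). Genes with mean normalized count
    below ``min_mean`` are excluded before testing. The response is
    ``log2(count/size_factor + 0.5)``; the Wald t on the score slope gives
    the BH q-value and the signed-t rank metric. Exactly constant genes get
    slope 0 and t 0; near-noiseless fits are capped at |t| = 1e6.
    """
    s = np.asarray(scores, dtype=float)
    n = counts.shape[1]
    if s.shape[0] != n:
        raise ValueError("scores not aligned to count columns")
    X, names = _association_design(s, covariates, n)
    p = X.shape[1]
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples for {p} model parameters, got {n}")
    sf = size_factors(counts) if factors is None else factors
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    keep = norm.mean(axis=1) >= min_mean
    n_filtered = int((~keep).sum())
    Y = np.log2(norm[keep] + 0.5)  # genes x samples
    genes = counts.index[keep]

    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    coefs = XtXi @ (X.T @ Y.T)  # p x genes
    resid = Y.T - X @ coefs
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    slope = coefs[1]
    var_slope = sigma2 * XtXi[1, 1]
    se = np.sqrt(var_slope)

    # a gene constant across samples carries no information: exact zeros,
    # not the floating-point residue of a degenerate regression
    const_gene = (Y.max(axis=1) - Y.min(axis=1)) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    zero_var = se == 0
    t = np.where(zero_var & (np.abs(slope) < 1e-300), 0.0, t)
    t = np.where(zero_var & (np.abs(slope) >= 1e-300), np.sign(slope) * T_CAP, t)
    t = np.clip(t, -T_CAP, T_CAP)
    slope = np.where(const_gene, 0.0, slope)
    se = np.where(const_gene, 0.0, se)
    t = np.where(const_gene, 0.0, t)
    pval = 2 * stats.t.sf(np.abs(t), dof)
    q = multipletests(pval, method="fdr_bh")[1] if len(pval) else np.array([])

    table = pd.DataFrame(
        {"slope": slope, "se": se, "t": t, "p": pval, "q": q, "metric": t},
        index=pd.Index(genes, name="gene"),
    )
    return GeneStats(table=table, n_samples=n, n_filtered=n_filtered)


# ---------------------------------------------------------------------------
# preranked GSEA


def _es_candidates(pos: np.ndarray, r: np.ndarray, N: int):
    """Signed extremum of the weighted KS running sum for hit positions.

    ``pos`` is (n_draws, k) 0-based positions in the ranked list, sorted
    ascending per row; ``r`` the |metric|**weight in ranked order. The
    running sum only attains its extrema immediately after a hit (maxima)
    or immediately before one (minima), so those 2k candidates suffice.
    """
    k = pos.shape[1]
    rs = r[pos]
    R = rs.sum(axis=1, keepdims=True)
    # fall back to unweighted increments for an all-zero-weight set
    inc = np.where(R > 0, rs / np.where(R > 0, R, 1.0), 1.0 / k)
    cum = np.cumsum(inc, axis=1)
    miss = (pos - np.arange(k)[None, :]) / (N - k)
    after = cum - miss
    before = (cum - inc) - miss
    # interleave in walk order (min before hit j precedes max after hit j) so
    # an exact magnitude tie resolves to the extremum reached first
    cand = np.empty((pos.shape[0], 2 * k))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(cand.shape[0]), idx]


def enrichment_score(metric: pd.Series, members, *, weight: float = 1.0) -> float:
    """ES of one gene set against a ranked metric (descending order)."""
    vals = metric.to_numpy(dtype=float)
    ids = metric.index.to_numpy()
    # descending metric, deterministic tie-break by gene id
    o = np.lexsort((ids, -vals))
    genes = ids[o]
    r = np.abs(vals[o]) ** weight
    pos = np.flatnonzero(np.isin(genes, list(members)))
    if pos.size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if pos.size == genes.size:
        return 1.0
    return float(_es_candidates(pos[None, :], r, genes.size)[0])


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the skipped-set accounting."""

    table: pd.DataFrame  # set, size, es, nes, p, q, group
    skipped: pd.DataFrame  # set, reason
    n_perm: int
    seed: int


def preranked_gsea(
    gene_stats,
    gene_sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    min_size: int = 15,
    max_size: int = 500,
    weight: float = 1.0,
    keyword_config: dict | None = None,
) -> EnrichmentResult:
    """Weighted-KS preranked enrichment with a gene-permutation null.

    ``gene_stats`` is a :class:`GeneStats`, a frame with a ``metric``
    column, or a gene-indexed Series. Hit steps add ``|r|/sum_set|r|``,
    miss steps subtract ``1/(N-k)``; ES is the signed extremum of the
    running sum. The null permutes gene labels (equivalently draws random
    same-size sets); NES divides ES by the mean |null ES| of matching
    sign, p is the matching-sign null tail fraction, and q follows the
    positive/negative pooled-null FDR convention. Sets outside
    ``[min_size, max_size]`` after intersection are skipped with a reason.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(gene_stats, GeneStats):
        metric = gene_stats.metric
    elif isinstance(gene_stats, pd.DataFrame):
        metric = gene_stats["metric"]
    else:
        metric = pd.Series(gene_stats)
    if metric.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    if np.all(metric.to_numpy() == 0):
        raise ValueError("all-zero rank metric; ranking is uninformative")

    order = np.lexsort((metric.index.to_numpy(), -metric.to_numpy(dtype=float)))
    genes = metric.index.to_numpy()[order]
    vals = metric.to_numpy(dtype=float)[order]
    r = np.abs(vals) ** weight
    N = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows, skipped = [], []
    hits = {}
    for name, members in gene_sets.items():
        pos = np.sort([gene_pos[g] for g in set(members) if g in gene_pos])
        if pos.size == 0:
            skipped.append({"set": name, "reason": "no overlap with ranked list"})
        elif pos.size < min_size:
            skipped.append({"set": name, "reason": f"size {pos.size} < min_size {min_size}"})
        elif pos.size > max_size:
            skipped.append({"set": name, "reason": f"size {pos.size} > max_size {max_size}"})
        else:
            hits[name] = pos

    rng = np.random.default_rng(seed)
    # shared null draws per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted({p.size for p in hits.values()}):
        draws = np.argsort(rng.random((n_perm, N)), axis=1)[:, :k]
        draws.sort(axis=1)
        null_by_size[k] = _es_candidates(draws, r, N)

    obs_nes = {}
    null_nes_pool = []
    per_set = {}
    for name, pos in hits.items():
        if pos.size == N:
            es = 1.0
        else:
            es = float(_es_candidates(pos[None, :], r, N)[0])
        null = null_by_size[pos.size]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        if es >= 0:
            p = float(np.mean(pos_null >= es)) if pos_null.size else 1.0
            nes = es / mean_pos if mean_pos and np.isfinite(mean_pos) else 0.0
        else:
            p = float(np.mean(neg_null <= es)) if neg_null.size else 1.0
            nes = -(abs(es) / mean_neg) if mean_neg and np.isfinite(mean_neg) else 0.0
        nn = np.where(null >= 0, null / mean_pos if np.isfinite(mean_pos) else 0.0,
                      null / mean_neg if np.isfinite(mean_neg) else 0.0)
        null_nes_pool.append(nn)
        obs_nes[name] = nes
        per_set[name] = {"set": name, "size": int(pos.size), "es": es, "nes": float(nes), "p": p}

    if per_set:
        pool = np.concatenate(null_nes_pool)
        obs = np.array([obs_nes[n_] for n_ in per_set])
        pool_pos = pool[pool >= 0]
        pool_neg = pool[pool < 0]
        obs_pos = obs[obs >= 0]
        obs_neg = obs[obs < 0]
        for name, row in per_set.items():
            nes = obs_nes[name]
            if nes >= 0:
                num = np.mean(pool_pos >= nes) if pool_pos.size else 0.0
                den = np.mean(obs_pos >= nes) if obs_pos.size else 1.0
            else:
                num = np.mean(pool_neg <= nes) if pool_neg.size else 0.0
                den = np.mean(obs_neg <= nes) if obs_neg.size else 1.0
            row["q"] = float(min(1.0, num / den)) if den > 0 else 0.0

    table = pd.DataFrame(per_set.values()) if per_set else pd.DataFrame(
        columns=["set", "size", "es", "nes", "p", "q"]
    )
    if len(table):
        table["group"] = classify_pathways(table["set"].tolist(), keyword_config)
    else:
        table["group"] = []
    return EnrichmentResult(
        table=table.reset_index(drop=True),
        skipped=pd.DataFrame(skipped, columns=["set", "reason"]),
        n_perm=n_perm,
        seed=seed,
    )


def classify_pathways(set_names, keyword_config: dict | None = None) -> list[str]:
    """Keyword curation of set names into immune / cell_cycle / other.

    Case-insensitive substring matching; a name matching both keyword lists
    is labeled immune (precedence, logged). Unmatched names are "other".
    """
    kw = keyword_config or DEFAULT_KEYWORDS
    if not kw.get("immune") or not kw.get("cell_cycle"):
        raise ValueError("keyword lists must be non-empty")
    labels = []
    for name in set_names:
        low = str(name).lower()
        imm = any(k in low for k in kw["immune"])
        cc = any(k in low for k in kw["cell_cycle"])
        if imm and cc:
            logger.info("set %r matches both immune and cell-cycle keywords; labeling immune", name)
        labels.append("immune" if imm else ("cell_cycle" if cc else "other"))
    return labels


def subsample_robustness(
    counts: pd.DataFrame,
    scores,
    covariates: pd.DataFrame | None,
    gene_sets: dict,
    fraction: float,
    n_repeats: int,
    seed: int = 0,
    *,
    q_threshold: float = 0.05,
    n_perm: int = 500,
    min_size: int = 15,
    max_size: int = 500,
    min_mean: float = 5.0,
) -> pd.DataFrame:
    """Significant-set counts per pathway group over random sample subsets.

    Each repeat draws ``fraction`` of the samples without replacement
    (stratified by a ``batch`` covariate when present), reruns the
    association + enrichment pipeline, and counts sets at q <= threshold
    per group label. The permutation seed is held fixed across repeats so
    a fraction of 1.0 reproduces the full-data result identically.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if n_repeats < 5:
        raise ValueError("n_repeats must be >= 5")
    s = np.asarray(scores, dtype=float)
    n = counts.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        if fraction == 1.0:
            take = np.arange(n)
        elif covariates is not None and "batch" in covariates.columns:
            take = []
            for _, grp in pd.Series(np.arange(n)).groupby(covariates["batch"].to_numpy()):
                m = max(1, int(round(fraction * len(grp))))
                take.append(rng.choice(grp.to_numpy(), size=m, replace=False))
            take = np.sort(np.concatenate(take))
        else:
            m = max(1, int(round(fraction * n)))
            take = np.sort(rng.choice(n, size=m, replace=False))
        sub_cov = covariates.iloc[take] if covariates is not None else None
        gs = per_gene_association(counts.iloc[:, take], s[take], sub_cov, min_mean=min_mean)
        res = preranked_gsea(gs, gene_sets, n_perm=n_perm, seed=seed,
                             min_size=min_size, max_size=max_size)
        sig = res.table[res.table["q"] <= q_threshold]
        row = {"repeat": rep, "n_samples": len(take)}
        for grp in ("immune", "cell_cycle", "other"):
            row[grp] = int((sig["group"] == grp).sum())
        rows.append(row)
    return pd.DataFrame(rows)
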