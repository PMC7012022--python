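"""Synthetic RNA-seq counts with a score-correlated pathway signal.

Emulates the transcriptome finding this package's enrichment stage is built
to detect: a designated block of immune genes whose expression rises as the
repair score falls — in CASES ONLY — and a cell-cycle block with a (weaker)
score association in both groups. Counts are negative binomial with
gene-wise constant dispersion,

    log2 mean_gi = baseline_g + beta_g * score_i * I(group condition)
                   + batch_offset + log2(library size_i),

with baseline log2 expression drawn per gene, a lognormal library size per
sample, and an additive log-scale normal batch offset. Gene-gene
correlation structure is deliberately not modeled. A dispersion of exactly
0 is the documented degenerate-noise mode: counts are the rounded means,
with no sampling at all.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["ExpressionParams", "generate_expression", "generate_gene_sets",
           "immune_genes", "cellcycle_genes", "gene_names"]


@dataclass
class ExpressionParams:
    """Count-simulator parameters.

    ``beta_immune_case`` is the log2-fold change per score unit applied to
    immune genes in case samples only (negative = expression rises as the
    score falls); ``beta_cellcycle`` applies to cell-cycle genes in both
    groups. Defaults give a clearly detectable case-specific immune signal
    on desk-scale matrices.
    """

    n_genes: int = 2000
    n_immune_genes: int = 200
    n_cellcycle_genes: int = 100
    baseline_log_mean: float = -13.0  # log2 scale, relative to library size
    baseline_log_sd: float = 1.5
    dispersion: float = 0.2
    beta_immune_case: float = -0.5
    beta_cellcycle: float = -0.25
    library_size_median: float = 1e6
    library_size_log_sd: float = 0.2  # natural-log sd of the lognormal
    batch_effect_sd: float = 0.1
    n_batches: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_immune_genes + self.n_cellcycle_genes > self.n_genes:
            raise ValueError("immune + cell-cycle gene counts exceed n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")

    def to_dict(self) -> dict:
        return asdict(self)


def gene_names(params: ExpressionParams) -> list[str]:
    return [f"G{i:05d}" for i in range(params.n_genes)]


def immune_genes(params: ExpressionParams) -> list[str]:
    return gene_names(params)[: params.n_immune_genes]


def cellcycle_genes(params: ExpressionParams) -> list[str]:
    g = gene_names(params)
    return g[params.n_immune_genes : params.n_immune_genes + params.n_cellcycle_genes]


def generate_expression(
    cohort: pd.DataFrame,
    scores,
    params: ExpressionParams,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a gene x sample count matrix aligned to a cohort.

    Returns ``(counts, batch)``: an integer DataFrame indexed by gene id
    with one column per subject id, and the per-sample batch label.
    Reproducible given params and seed.
    """
    params.validate()
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != len(cohort):
        raise ValueError(f"scores (n={s.shape[0]}) not aligned to cohort (n={len(cohort)})")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_samp = len(cohort)
    genes = gene_names(params)
    is_case = (cohort["case_status"] == "case").to_numpy()

    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd, params.n_genes)
    lib = params.library_size_median * np.exp(
        rng.normal(0.0, params.library_size_log_sd, n_samp)
    )
    batch = rng.integers(0, params.n_batches, n_samp)
    batch_offset = rng.normal(0.0, params.batch_effect_sd, params.n_batches)[batch]

    ni, nc = params.n_immune_genes, params.n_cellcycle_genes
    # immune effect only in case samples; cell-cycle effect in everyone
    eff = np.zeros((params.n_genes, n_samp))
    eff[:ni, :] = params.beta_immune_case * s[None, :] * is_case[None, :]
    eff[ni : ni + nc, :] = params.beta_cellcycle * s[None, :]

    log2mu = baseline[:, None] + eff + batch_offset[None, :] + np.log2(lib)[None, :]
    mu = np.exp2(log2mu)
    if params.dispersion == 0.0:
        counts = np.rint(mu).astype(np.int64)
    else:
        r = 1.0 / params.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p).astype(np.int64)
    ids = cohort["id"].tolist() if "id" in cohort.columns else list(cohort.index)
    cdf = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=ids)
    bser = pd.Series([f"B{b}" for b in batch], index=cdf.columns, name="batch")
    return cdf, bser


def generate_gene_sets(
    params: ExpressionParams,
    *,
    n_immune_sets: int = 5,
    n_cellcycle_sets: int = 3,
    n_neutral_sets: int = 6,
    set_size: int = 20,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Fixture gene-set collection with keyword-classifiable names.

    Immune sets draw only from the immune gene block, cell-cycle sets from
    the cell-cycle block, and neutral sets from the remaining genes; all
    sets are pairwise disjoint by construction (members are sampled without
    replacement within each block), so no gene is shared between sets.
    Names embed the standard curation keywords (e.g.
    ``IMMUNE_RESPONSE_SET_03``); sizes must fit the usual enrichment bounds
    and the available block.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    genes = gene_names(params)
    ni, nc = params.n_immune_genes, params.n_cellcycle_genes
    if set_size > params.n_genes:
        raise ValueError(f"set size {set_size} exceeds number of genes {params.n_genes}")
    blocks = {
        "IMMUNE_RESPONSE_SET": (genes[:ni], n_immune_sets),
        "CELL_CYCLE_SET": (genes[ni : ni + nc], n_cellcycle_sets),
        "NEUTRAL_SET": (genes[ni + nc :], n_neutral_sets),
    }
    sets: dict[str, list[str]] = {}
    for prefix, (pool, n_sets) in blocks.items():
        if n_sets and n_sets * set_size > len(pool):
            raise ValueError(
                f"{n_sets} disjoint sets of size {set_size} exceed the "
                f"{len(pool)}-gene pool for {prefix}"
            )
        shuffled = rng.permutation(pool)
        for k in range(n_sets):
            members = shuffled[k * set_size : (k + 1) * set_size]
            sets[f"{prefix}_{k:02d}"] = sorted(members.tolist())
    return sets
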