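"""CpG-to-gene collapse and preranked gene-set enrichment analysis.

Differentially methylated CpGs are collapsed to one score per gene (the CpG
with the largest |delta-beta|), ranked most-positive first, and tested
against gene-set collections with the classic weighted Kolmogorov-Smirnov
running-sum enrichment score. Significance comes from a gene-permutation
null (random same-size draws from the ranked universe), with sign-matched
normalization (NES) and Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("pitmeth")


def build_ranked_genes(
    dmp_table: pd.DataFrame,
    manifest: pd.DataFrame,
    score_column: str = "delta_beta",
) -> pd.DataFrame:
    """Collapse a per-CpG table to one signed score per gene, ranked.

    CpGs without a gene annotation are dropped; for genes with several CpGs
    only the entry with the highest |score| is kept (ties broken toward the
    smaller genomic position). Output is ordered most positive to most
    negative, score ties broken lexicographically by gene symbol.
    """
    ann = manifest.loc[dmp_table.index]
    table = pd.DataFrame(
        {
            "gene": ann["gene"].to_numpy(),
            "pos": ann["pos"].to_numpy(),
            "score": dmp_table[score_column].to_numpy(float),
        },
        index=dmp_table.index,
    )
    table = table[table["gene"] != ""]
    if table.empty:
        raise ValueError("no CpGs carry a gene annotation")
    table = table.assign(abs_score=table["score"].abs())
    table = table.sort_values(
        ["gene", "abs_score", "pos"], ascending=[True, False, True], kind="stable"
    )
    best = table.groupby("gene", sort=False).head(1)
    ranked = best.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    )[["gene", "score"]].reset_index(names="probe")
    return ranked


def enrichment_score(
    ranked: pd.DataFrame,
    gene_set,
    weight: float = 1.0,
) -> float:
    """Signed maximal deviation of the weighted KS running sum.

    Hits step up by |score|^weight (normalized over set members), misses step
    down by 1/(N - N_hit); the enrichment score is the running-sum value of
    largest magnitude, in [-1, 1].
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(float)
    hit = np.isin(genes, list(gene_set))
    if not hit.any():
        raise ValueError("gene set has no overlap with the ranked list")
    return _es_from_hits(scores, hit, weight)


def _es_from_hits(scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    n = scores.size
    n_hit = int(hit.sum())
    w = np.abs(scores[hit]) ** weight
    total = w.sum()
    steps = np.zeros(n)
    if total > 0:
        steps[hit] = w / total
    else:  # degenerate all-zero scores: unweighted hits
        steps[hit] = 1.0 / n_hit
    if n > n_hit:
        steps[~hit] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _leading_edge(ranked: pd.DataFrame, hit: np.ndarray, weight: float) -> list[str]:
    scores = ranked["score"].to_numpy(float)
    n, n_hit = scores.size, int(hit.sum())
    w = np.abs(scores[hit]) ** weight
    steps = np.zeros(n)
    steps[hit] = w / w.sum() if w.sum() > 0 else 1.0 / n_hit
    if n > n_hit:
        steps[~hit] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    genes = ranked["gene"].to_numpy()
    if running[i] >= 0:
        mask = hit & (np.arange(n) <= i)
    else:
        mask = hit & (np.arange(n) >= i)
    return list(genes[mask])


def run_gsea(
    ranked: pd.DataFrame,
    collections: dict,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    weight: float = 1.0,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a {name: gene list} collection.

    Sets are filtered to [min_size, max_size] members after intersection with
    the ranked universe (excluded sets are logged). For each set the null is
    ``n_perm`` random same-size gene draws; NES = ES / mean |null ES| of the
    matching sign, and the nominal p-value is the matching-sign null tail
    with no lower-bound clamp, so it can reach the 1/(n_perm + 1) scale.
    Benjamini-Hochberg adjustment runs across all tested sets; rows with
    padj <= ``fdr`` carry ``enriched=True``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(float)
    n = genes.size
    universe = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows, skipped = [], []
    for name, members in collections.items():
        idx = np.array(sorted({universe[g] for g in members if g in universe}), int)
        k = idx.size
        if not min_size <= k <= max_size:
            skipped.append((name, k))
            continue
        hit = np.zeros(n, bool)
        hit[idx] = True
        es = _es_from_hits(scores, hit, weight)
        null = np.empty(n_perm)
        for p in range(n_perm):
            h = np.zeros(n, bool)
            h[rng.choice(n, size=k, replace=False)] = True
            null[p] = _es_from_hits(scores, h, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            pval, nes = 1.0 / (n_perm + 1), np.nan
        else:
            pval = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + same.size)
            nes = es / np.abs(same).mean()
        rows.append(
            {
                "pathway": name,
                "ES": es,
                "NES": nes,
                "pval": pval,
                "size": k,
                "leading_edge": ";".join(_leading_edge(ranked, hit, weight)),
            }
        )
    if skipped:
        logger.info("excluded %d gene sets outside size bounds: %s",
                    len(skipped), [s[0] for s in skipped[:5]])
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "ES", "NES", "pval", "padj", "size",
                     "leading_edge", "enriched"]
        )
    result = pd.DataFrame(rows)
    result["padj"] = multipletests(result["pval"], method="fdr_bh")[1]
    result["enriched"] = result["padj"] <= fdr
    return result[["pathway", "ES", "NES", "pval", "padj", "size",
                   "leading_edge", "enriched"]]
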