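"""Fisher-exact term enrichment with a large-term exclusion and BH control."""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .classify import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_MAX_TERM_SIZE = 3000


def read_annotations(path) -> dict[str, set[str]]:
    """Load a two-column gene→term TSV into term → gene-set form."""
    df = pd.read_csv(path, sep="\t", header=0, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(term, set()).add(gene)
    return out


def filter_large_terms(
    annotations: Mapping[str, set[str]], max_genes: int = DEFAULT_MAX_TERM_SIZE
) -> dict[str, set[str]]:
    """Drop terms annotated to strictly more than ``max_genes`` genes."""
    kept = {}
    for term, genes in annotations.items():
        if len(genes) > max_genes:
            logger.info("excluding term %s (%d genes > %d)", term, len(genes), max_genes)
        else:
            kept[term] = set(genes)
    return kept


def fisher_enrichment(
    study: Iterable[str],
    annotations: Mapping[str, set[str]],
    population: Iterable[str],
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per term, BH-adjusted.

    For each term: k = |study ∩ term|, K = |term ∩ population|, n = |study|,
    N = |population|; p is the hypergeometric upper tail P(X >= k). Returns a
    frame sorted by p with columns term, k, K, n, N, p, fdr.
    """
    study_set = set(study)
    pop_set = set(population)
    strays = sorted(study_set - pop_set)
    if strays:
        raise ValueError(f"study genes absent from population: {strays}")
    n = len(study_set)
    N = len(pop_set)
    rows = []
    for term, genes in annotations.items():
        members = genes & pop_set
        K = len(members)
        k = len(study_set & members)
        # upper tail of Hypergeometric(N, K, n) at k
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df["fdr"] = bh_adjust(df["p"].values) if len(df) else []
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
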