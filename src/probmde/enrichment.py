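"""Randomization-null gene-set enrichment on probability-weighted gene lists.

Instead of thresholding the gene list, each gene enters the enrichment
contingency table with its question probability p_g, and each (term, gene)
annotation pair with its membership weight w_g in [0, 1].  The fuzzy 2x2
table for a term over a universe of genes is

    n11 = sum p_g * w_g        n10 = sum p_g * (1 - w_g)
    n01 = sum (1-p_g) * w_g    n00 = sum (1-p_g) * (1-w_g)

which reduces to the classical 2x2 table when both p and w are crisp 0/1.
Association is measured by Yule's Q = (n11*n00 - n10*n01)/(n11*n00 + n10*n01)
in [-1, 1]; the statistic is pluggable.  Significance comes from a
randomization null: the gene -> p_g assignment is permuted over the
universe (annotation structure preserved) and the observed Q is compared
with the null distribution, with the add-one correction
p = (1 + #{null Q >= observed Q}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .counts_io import AnnotationSet
from .question_engine import GeneProbability, normalize_cutoff

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1_000


@dataclass(frozen=True)
class FuzzyContingency:
    """Probability-weighted 2x2 contingency table for one term."""

    n11: float
    n10: float
    n01: float
    n00: float

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term association, permutation p-value and gene summaries."""

    term_id: str
    association: float  # Yule's Q in [-1, 1]
    p_value: float
    n_genes_annotated: int
    sum_p_in_term: float
    n_perm: int
    bh_adjusted: float | None = None


def fuzzy_contingency(
    p: np.ndarray | Sequence[float], w: np.ndarray | Sequence[float]
) -> FuzzyContingency:
    """Build the fuzzy table from aligned probability and weight vectors."""
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != w.shape:
        raise ValueError("p and w must be aligned over the same gene universe")
    return FuzzyContingency(
        n11=float(np.sum(p * w)),
        n10=float(np.sum(p * (1.0 - w))),
        n01=float(np.sum((1.0 - p) * w)),
        n00=float(np.sum((1.0 - p) * (1.0 - w))),
    )


def yules_q(table: FuzzyContingency) -> float:
    """Yule's Q association; 0 when both diagonal products vanish."""
    ad = table.n11 * table.n00
    bc = table.n10 * table.n01
    if ad + bc == 0.0:
        return 0.0
    return (ad - bc) / (ad + bc)


def _yules_q_vec(P: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Yule's Q for every (probability-vector, term) pair.

    P has shape (n_vectors, n_genes); W has shape (n_genes, n_terms).
    Returns an (n_vectors, n_terms) matrix; 0 where both products vanish.
    """
    n11 = P @ W
    n10 = P @ (1.0 - W)
    n01 = (1.0 - P) @ W
    n00 = (1.0 - P) @ (1.0 - W)
    ad = n11 * n00
    bc = n10 * n01
    denom = ad + bc
    with np.errstate(invalid="ignore"):
        q = np.where(denom == 0.0, 0.0, (ad - bc) / np.where(denom == 0, 1.0, denom))
    return q


def _probability_vector(
    gene_probs: Mapping[str, float] | Sequence[GeneProbability],
) -> tuple[list[str], np.ndarray]:
    """Universe gene list (sorted) and aligned p_g vector."""
    if isinstance(gene_probs, Mapping):
        items = gene_probs.items()
    else:
        items = ((r.gene_id, r.p_hat) for r in gene_probs)
    pairs = sorted(items)
    genes = [g for g, _ in pairs]
    p = np.array([v for _, v in pairs], dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("gene probabilities must lie in [0, 1]")
    return genes, p


def _weight_vector(
    annotation: AnnotationSet, term_id: str, genes: Sequence[str]
) -> np.ndarray:
    members = annotation.genes_of(term_id)
    return np.array([members.get(g, 0.0) for g in genes], dtype=float)


def permutation_pvalue(
    term_id: str,
    gene_probs: Mapping[str, float] | Sequence[GeneProbability],
    annotation: AnnotationSet,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    statistic: Callable[[FuzzyContingency], float] = yules_q,
) -> EnrichmentResult:
    """Association and permutation p-value for a single term.

    The null permutes the p_g vector over the gene universe (the universe
    is all genes with a computed probability, not all annotated genes).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    genes, p = _probability_vector(gene_probs)
    w = _weight_vector(annotation, term_id, genes)
    if not np.any(w > 0):
        raise ValueError(
            f"term {term_id!r} annotates no gene in the expression universe"
        )
    observed = statistic(fuzzy_contingency(p, w))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = statistic(fuzzy_contingency(rng.permutation(p), w))
    p_value = (1.0 + float(np.count_nonzero(null >= observed))) / (n_perm + 1.0)
    in_term = w > 0
    return EnrichmentResult(
        term_id=term_id,
        association=observed,
        p_value=p_value,
        n_genes_annotated=int(np.count_nonzero(in_term)),
        sum_p_in_term=float(np.sum(p * w)),
        n_perm=n_perm,
    )


def enrich_all(
    gene_probs: Mapping[str, float] | Sequence[GeneProbability],
    annotation: AnnotationSet,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    significance_threshold: float | None = None,
    ordering: str = "significance",
    statistic: Callable[[FuzzyContingency], float] = yules_q,
) -> list[EnrichmentResult]:
    """Enrichment of every annotated term against the probability-weighted list.

    One set of ``n_perm`` permutations of the p_g vector is shared by all
    terms (the null preserves the annotation structure, so per-term nulls
    differ only through the weight vectors).  Results carry a
    Benjamini-Hochberg adjusted column; filtering by
    ``significance_threshold`` uses the raw permutation p-value.
    Terms annotating no gene in the universe are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    genes, p = _probability_vector(gene_probs)
    n_genes = len(genes)
    rng = np.random.default_rng(seed)

    kept_terms: list[str] = []
    weights: list[np.ndarray] = []
    for term in annotation.term_ids:
        w = _weight_vector(annotation, term, genes)
        if not np.any(w > 0):
            logger.warning(
                "term %r annotates no gene in the universe; skipped", term
            )
            continue
        kept_terms.append(term)
        weights.append(w)
    if not kept_terms:
        return []

    W = np.column_stack(weights)  # (n_genes, n_terms)
    if statistic is yules_q:
        observed = _yules_q_vec(p[None, :], W)[0]
        P = np.stack([rng.permutation(p) for _ in range(n_perm)])
        exceed = np.count_nonzero(_yules_q_vec(P, W) >= observed[None, :], axis=0)
    else:
        observed = np.array(
            [statistic(fuzzy_contingency(p, W[:, j])) for j in range(W.shape[1])]
        )
        exceed = np.zeros(len(kept_terms))
        for _ in range(n_perm):
            p_perm = rng.permutation(p)
            null_q = np.array(
                [
                    statistic(fuzzy_contingency(p_perm, W[:, j]))
                    for j in range(W.shape[1])
                ]
            )
            exceed += null_q >= observed
    p_values = (1.0 + exceed) / (n_perm + 1.0)

    if len(p_values) > 1:
        bh = multipletests(p_values, method="fdr_bh")[1]
    else:
        bh = p_values.copy()

    results = [
        EnrichmentResult(
            term_id=term,
            association=float(observed[j]),
            p_value=float(p_values[j]),
            n_genes_annotated=int(np.count_nonzero(W[:, j] > 0)),
            sum_p_in_term=float(np.sum(p * W[:, j])),
            n_perm=n_perm,
            bh_adjusted=float(bh[j]),
        )
        for j, term in enumerate(kept_terms)
    ]
    if significance_threshold is not None:
        results = [r for r in results if r.p_value <= significance_threshold]
    return sort_results(results, ordering)


def sort_results(
    results: Sequence[EnrichmentResult], ordering: str = "significance"
) -> list[EnrichmentResult]:
    """Order enrichment results by significance, association or term size."""
    keys = {
        "significance": lambda r: (r.p_value, -r.association, r.term_id),
        "association": lambda r: (-r.association, r.p_value, r.term_id),
        "n_genes": lambda r: (-r.n_genes_annotated, r.term_id),
    }
    if ordering not in keys:
        raise ValueError(
            f"ordering must be one of {sorted(keys)}, got {ordering!r}"
        )
    return sorted(results, key=keys[ordering])


def functional_screen(
    gene_probs: Mapping[str, float] | Sequence[GeneProbability],
    annotation: AnnotationSet,
    cutoff: float | str = 0.0,
) -> list[tuple[str, int]]:
    """Per-term count of genes with p_hat >= cutoff, sorted by count.

    Every annotated term is listed, including terms with count zero; only
    genes present in the expression universe contribute.  Ties are broken
    by term id.
    """
    c = normalize_cutoff(cutoff)
    genes, p = _probability_vector(gene_probs)
    above = {g for g, pg in zip(genes, p) if pg >= c}
    universe = set(genes)
    counts = []
    for term in annotation.term_ids:
        members = [g for g, w in annotation.terms[term] if g in universe and w > 0]
        counts.append((term, sum(1 for g in members if g in above)))
    return sorted(counts, key=lambda tc: (-tc[1], tc[0]))
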