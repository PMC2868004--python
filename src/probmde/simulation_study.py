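"""Synthetic tag-count libraries with planted monotone expression profiles.

The generator emulates a sequencing experiment across ``n_conditions``
biological conditions with ``libraries_per_condition`` replicate libraries
each.  Every gene gets a baseline abundance pi drawn log-uniformly from
``baseline_range``; a planted fraction of *positive* genes has its
abundance multiplied by ``effect_size**k`` in condition k (a monotone
increasing profile), while negatives keep the same abundance in every
condition.  Counts are then drawn N ~ Binomial(T, pi) per gene per library,
matching the urn sampling model the posterior assumes.  If planting pushes
a library's total abundance above 1, abundances in that library are
renormalized (with a warning).

The scoring harness asks a monotone ordering question ("C1 < C2 < C3") of
each gene, and detection performance over the known labels is summarized by
ROC curves and AUC.  A naive pairwise baseline — a conjunction of per-pair
one-sided two-proportion z-tests, combined as the minimum of 1 - p over the
adjacent pairs — stands in for classical paired-analysis approaches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skmetrics

from .counts_io import CountLibrary, ExpressionDataset
from .question_engine import (
    DEFAULT_N_SIMS,
    estimate_probabilities,
    parse_question,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference study: 200 genes over 3 conditions,
    single libraries of 10^5 tags, 10% of genes planted with a 4-fold
    abundance step per condition, baselines log-uniform in [1e-6, 1e-3].
    """

    n_genes: int = 200
    n_conditions: int = 3
    libraries_per_condition: int = 1
    total_tags: int = 100_000
    fraction_true_positives: float = 0.1
    effect_size: float = 4.0
    baseline_range: tuple[float, float] = (1e-6, 1e-3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_true_positives < 1.0:
            raise ValueError("fraction_true_positives must lie in (0, 1)")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        lo, hi = self.baseline_range
        if not 0 < lo <= hi < 1:
            raise ValueError("baseline_range must satisfy 0 < lo <= hi < 1")

    @property
    def condition_names(self) -> list[str]:
        return [f"C{k + 1}" for k in range(self.n_conditions)]


@dataclass
class LabeledDataset:
    """Simulated dataset plus ground truth and true abundances."""

    dataset: ExpressionDataset
    truth: dict[str, bool]
    condition_groups: dict[str, list[str]] = field(default_factory=dict)
    true_abundance: dict[str, np.ndarray] = field(default_factory=dict)
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        missing = set(self.dataset.gene_ids) - set(self.truth)
        if missing:
            raise ValueError(f"truth labels missing for genes: {sorted(missing)[:5]}")


def simulate_dataset(config: SimulationConfig) -> LabeledDataset:
    """Generate a labeled dataset with planted monotone profiles.

    Positive genes are a random subset of size
    round(fraction_true_positives * n_genes); reproducible for a fixed
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i + 1:04d}" for i in range(n)]

    lo, hi = config.baseline_range
    baseline = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)

    n_pos = int(round(config.fraction_true_positives * n))
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    is_pos = np.zeros(n, dtype=bool)
    is_pos[pos_idx] = True

    # abundance matrix: genes x conditions
    pi = np.tile(baseline[:, None], (1, config.n_conditions))
    steps = config.effect_size ** np.arange(config.n_conditions)
    pi[is_pos, :] = baseline[is_pos, None] * steps[None, :]

    # library-wise renormalization if the simplex is exceeded
    for k in range(config.n_conditions):
        s = pi[:, k].sum()
        if s > 1.0:
            warnings.warn(
                f"condition {k + 1}: total abundance {s:.3f} > 1; renormalized",
                stacklevel=2,
            )
            pi[:, k] /= s

    libraries: list[CountLibrary] = []
    condition_groups: dict[str, list[str]] = {}
    for k, cname in enumerate(config.condition_names):
        lib_ids = []
        for r in range(config.libraries_per_condition):
            counts = rng.binomial(config.total_tags, pi[:, k])
            lib_id = (
                cname
                if config.libraries_per_condition == 1
                else f"{cname}_R{r + 1}"
            )
            lib_ids.append(lib_id)
            libraries.append(
                CountLibrary(
                    library_id=lib_id,
                    counts={g: int(c) for g, c in zip(genes, counts)},
                    total_tags=config.total_tags,
                )
            )
        condition_groups[cname] = lib_ids

    return LabeledDataset(
        dataset=ExpressionDataset(libraries=libraries, gene_ids=genes),
        truth={g: bool(b) for g, b in zip(genes, is_pos)},
        condition_groups=condition_groups,
        true_abundance={g: pi[i].copy() for i, g in enumerate(genes)},
        config=config,
    )


def default_question(config: SimulationConfig) -> str:
    """The planted monotone ordering question, e.g. "C1 < C2 < C3"."""
    return " < ".join(config.condition_names)


def score_dataset(
    labeled: LabeledDataset,
    question_template: str | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> dict[str, float]:
    """Per-gene question probabilities over the simulated libraries.

    ``question_template`` defaults to the monotone increasing ordering over
    the condition names; condition names resolve to replicate groups.
    """
    if question_template is None:
        if labeled.config is None:
            raise ValueError("no config stored; pass question_template explicitly")
        question_template = default_question(labeled.config)
    known = set(labeled.dataset.library_ids) | set(labeled.condition_groups)
    ast = parse_question(question_template, known_ids=known)
    results = estimate_probabilities(
        labeled.dataset,
        ast,
        n_sims=n_sims,
        seed=seed,
        groups=labeled.condition_groups,
    )
    return {r.gene_id: r.p_hat for r in results}


# --------------------------------------------------------------------------
# ROC evaluation
# --------------------------------------------------------------------------

def roc_curve(
    scores: Mapping[str, float], truth: Mapping[str, bool]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC over genes; returns (fpr, tpr, auc).

    Equal scores are grouped into one threshold step; AUC is the trapezoid
    area (equivalently the Mann-Whitney concordance with ties counted 1/2).
    """
    genes = sorted(scores)
    if set(genes) != set(truth):
        raise ValueError("scores and truth must cover the same genes")
    y = np.array([bool(truth[g]) for g in genes])
    s = np.array([scores[g] for g in genes], dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs at least one positive and one negative gene")
    fpr, tpr, _ = _skmetrics.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skmetrics.auc(fpr, tpr))
    return fpr, tpr, auc


def auc_jackknife_se(
    scores: Mapping[str, float], truth: Mapping[str, bool]
) -> float:
    """Delete-one-gene jackknife standard error of the ROC AUC."""
    genes = sorted(scores)
    y = np.array([bool(truth[g]) for g in genes])
    s = np.array([scores[g] for g in genes], dtype=float)
    n = len(genes)
    reps = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yi, si = y[mask], s[mask]
        if yi.all() or not yi.any():
            continue
        reps.append(_skmetrics.roc_auc_score(yi, si))
    reps = np.asarray(reps)
    m = len(reps)
    return float(np.sqrt((m - 1) / m * np.sum((reps - reps.mean()) ** 2)))


# --------------------------------------------------------------------------
# Naive pairwise baseline
# --------------------------------------------------------------------------

def naive_pairwise_scores(
    labeled: LabeledDataset, question_template: str | None = None
) -> dict[str, float]:
    """Classical paired-analysis stand-in for the monotone question.

    For each adjacent condition pair (k, k+1) a one-sided two-proportion
    z-test of pi_k < pi_{k+1} is run on the pooled counts of the pair's
    replicate libraries; the per-gene score is min over pairs of
    (1 - p_value), i.e. a gene scores highly only when every step of the
    profile is individually significant.
    """
    if labeled.config is None:
        raise ValueError("naive baseline requires the stored simulation config")
    cfg = labeled.config
    names = cfg.condition_names
    ds = labeled.dataset
    scores = {g: 1.0 for g in ds.gene_ids}
    for k in range(len(names) - 1):
        libs_a = [ds.library(i) for i in labeled.condition_groups[names[k]]]
        libs_b = [ds.library(i) for i in labeled.condition_groups[names[k + 1]]]
        for g in ds.gene_ids:
            n1 = sum(lib.count(g) for lib in libs_a)
            t1 = sum(lib.total_tags for lib in libs_a)
            n2 = sum(lib.count(g) for lib in libs_b)
            t2 = sum(lib.total_tags for lib in libs_b)
            p_val = _two_proportion_less(n1, t1, n2, t2)
            scores[g] = min(scores[g], 1.0 - p_val)
    return scores


def _two_proportion_less(n1: int, t1: int, n2: int, t2: int) -> float:
    """One-sided z-test p-value for H1: rate1 < rate2 (pooled variance)."""
    p1, p2 = n1 / t1, n2 / t2
    pool = (n1 + n2) / (t1 + t2)
    var = pool * (1.0 - pool) * (1.0 / t1 + 1.0 / t2)
    if var == 0.0:
        return 1.0  # no events observed: no evidence of increase
    z = (p2 - p1) / np.sqrt(var)
    return float(stats.norm.sf(z))


def compare_methods(
    labeled: LabeledDataset,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    methods: Sequence[str] = ("probmde", "naive_pairwise"),
) -> dict[str, dict]:
    """AUC of each scoring method on the same labeled dataset.

    Returns per-method dicts with keys ``auc``, ``auc_se`` (jackknife) and
    ``scores``.
    """
    out: dict[str, dict] = {}
    for method in methods:
        if method == "probmde":
            scores = score_dataset(labeled, n_sims=n_sims, seed=seed)
        elif method == "naive_pairwise":
            scores = naive_pairwise_scores(labeled)
        else:
            raise ValueError(f"unknown method {method!r}")
        _, _, auc = roc_curve(scores, labeled.truth)
        out[method] = {
            "auc": auc,
            "auc_se": auc_jackknife_se(scores, labeled.truth),
            "scores": scores,
        }
    return out
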