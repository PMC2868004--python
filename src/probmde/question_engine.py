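"""Multi-condition expression questions: parsing, evaluation, probability.

A *question* is a boolean expression over latent abundances, e.g.::

    A < B < C
    GSM383859,GSM383860 > GSM383869,GSM383870
    (A > B AND B > C) OR A > D

Grammar (AND binds tighter than OR; parentheses group):

    question := clause (("AND" | "OR") clause)*
    clause   := operand (("<" | ">") operand)+
    operand  := id | id ("," id)+        -- replicate group (beta mixture)
              | id ("+" id)+             -- pool (counts summed, one beta)

A chained comparison ``A < B < C`` desugars to ``A < B AND B < C``.

The probability that the question holds for a gene is estimated by joint
Monte Carlo over the posterior abundances: in each simulation iteration one
abundance value is drawn per distinct operand and every atomic comparison
is evaluated on those shared draws (so ``B`` in ``A < B AND B < C`` is a
single value per iteration — the only semantics under which chaining and
explicit conjunction coincide).  The estimate is p_hat = S_t / S_n where
S_t counts the iterations in which the question returned true out of S_n
total iterations.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .counts_io import CountLibrary, ExpressionDataset
from .errors import DomainError, QuestionParseError
from .posterior_model import (
    BetaPosterior,
    GroupModel,
    beta_posterior,
    sample_abundance,
)

DEFAULT_N_SIMS = 10_000


# --------------------------------------------------------------------------
# AST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Operand:
    """A question operand: one library, a replicate group, or a pool."""

    kind: str  # "library" | "group" | "pool"
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("library", "group", "pool"):
            raise ValueError(f"bad operand kind {self.kind!r}")
        if not self.ids:
            raise ValueError("operand needs at least one id")

    @property
    def key(self) -> str:
        """Canonical key used to share posterior draws across comparisons."""
        if self.kind == "library":
            return self.ids[0]
        sep = "," if self.kind == "group" else "+"
        return sep.join(sorted(self.ids))

    def __str__(self) -> str:
        sep = {"library": "", "group": ",", "pool": "+"}[self.kind]
        return sep.join(self.ids) if len(self.ids) > 1 else self.ids[0]


@dataclass(frozen=True)
class Comparison:
    left: Operand
    op: str  # "<" or ">"
    right: Operand

    def operands(self) -> Iterable[Operand]:
        yield self.left
        yield self.right

    def evaluate(self, draws: Mapping[str, np.ndarray]) -> np.ndarray:
        lhs, rhs = draws[self.left.key], draws[self.right.key]
        return lhs < rhs if self.op == "<" else lhs > rhs

    def __str__(self) -> str:
        return f"{self.left} {self.op} {self.right}"


@dataclass(frozen=True)
class BoolOp:
    op: str  # "AND" or "OR"
    children: tuple

    def operands(self) -> Iterable[Operand]:
        for child in self.children:
            yield from child.operands()

    def evaluate(self, draws: Mapping[str, np.ndarray]) -> np.ndarray:
        results = [child.evaluate(draws) for child in self.children]
        out = results[0]
        for r in results[1:]:
            out = (out & r) if self.op == "AND" else (out | r)
        return out

    def __str__(self) -> str:
        return "(" + f" {self.op} ".join(str(c) for c in self.children) + ")"


@dataclass(frozen=True)
class QuestionAST:
    """Parsed question: a boolean tree over comparisons."""

    root: Comparison | BoolOp
    text: str = ""

    def operands(self) -> list[Operand]:
        """Distinct operands in first-appearance order."""
        seen: dict[str, Operand] = {}
        for op in self.root.operands():
            seen.setdefault(op.key, op)
        return list(seen.values())

    def evaluate(self, draws: Mapping[str, np.ndarray]) -> np.ndarray:
        for op in self.operands():
            if op.key not in draws:
                raise KeyError(f"no draw supplied for operand {op}")
        return self.root.evaluate(draws)

    def __str__(self) -> str:
        return str(self.root)


def evaluate_question(ast: QuestionAST, draws: Mapping[str, float | np.ndarray]):
    """Evaluate the question on one joint draw assignment (operand key -> pi).

    Scalar draws give a single bool; vector draws give a bool array with
    one entry per simulation iteration.
    """
    arr = {k: np.asarray(v) for k, v in draws.items()}
    out = ast.evaluate(arr)
    return bool(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Parser
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<id>[A-Za-z0-9_.:-]+)|(?P<op>[<>])|(?P<comma>,)"
    r"|(?P<plus>\+)|(?P<lparen>\()|(?P<rparen>\)))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise QuestionParseError(
                f"unexpected character {text[pos]!r}", position=pos
            )
        kind = m.lastgroup
        value = m.group(kind)
        start = m.start(kind)
        if kind == "id" and value.upper() in ("AND", "OR"):
            kind = value.lower()  # keyword token: "and" / "or"
            value = value.upper()
        tokens.append((kind, value, start))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], known_ids=None):
        self.tokens = tokens
        self.i = 0
        self.known_ids = set(known_ids) if known_ids is not None else None

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str):
        tok = self.next()
        if tok[0] != kind:
            raise QuestionParseError(
                f"expected {kind}, found {tok[1]!r}", position=tok[2]
            )
        return tok

    # question := and_expr (OR and_expr)*   -- AND binds tighter
    def parse_or(self):
        children = [self.parse_and()]
        while self.peek()[0] == "or":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else BoolOp("OR", tuple(children))

    def parse_and(self):
        children = [self.parse_atom()]
        while self.peek()[0] == "and":
            self.next()
            children.append(self.parse_atom())
        if len(children) == 1:
            return children[0]
        flat = []
        for c in children:
            if isinstance(c, BoolOp) and c.op == "AND":
                flat.extend(c.children)
            else:
                flat.append(c)
        return BoolOp("AND", tuple(flat))

    def parse_atom(self):
        if self.peek()[0] == "lparen":
            self.next()
            node = self.parse_or()
            self.expect("rparen")
            return node
        return self.parse_clause()

    # clause := operand (op operand)+  — chaining desugars to AND
    def parse_clause(self):
        operands = [self.parse_operand()]
        ops: list[str] = []
        while self.peek()[0] == "op":
            ops.append(self.next()[1])
            operands.append(self.parse_operand())
        if not ops:
            tok = self.peek()
            found = repr(tok[1]) if tok[1] else "end of input"
            raise QuestionParseError(
                f"expected comparison operator, found {found}", position=tok[2]
            )
        comparisons = tuple(
            Comparison(operands[k], ops[k], operands[k + 1]) for k in range(len(ops))
        )
        return comparisons[0] if len(comparisons) == 1 else BoolOp("AND", comparisons)

    def parse_operand(self) -> Operand:
        tok = self.next()
        if tok[0] != "id":
            found = repr(tok[1]) if tok[1] else "end of input"
            raise QuestionParseError(
                f"expected library id, found {found}", position=tok[2]
            )
        ids = [tok[1]]
        kind = "library"
        sep = {"comma": "group", "plus": "pool"}
        while self.peek()[0] in sep:
            sep_tok = self.next()
            new_kind = sep[sep_tok[0]]
            if kind != "library" and new_kind != kind:
                raise QuestionParseError(
                    "cannot mix ',' (group) and '+' (pool) in one operand",
                    position=sep_tok[2],
                )
            kind = new_kind
            ids.append(self.expect("id")[1])
        if self.known_ids is not None:
            for i in ids:
                if i not in self.known_ids:
                    raise QuestionParseError(f"unknown library id {i!r}")
        return Operand(kind=kind, ids=tuple(ids))


def parse_question(
    text: str, known_ids: Iterable[str] | None = None
) -> QuestionAST:
    """Parse a question string into a :class:`QuestionAST`.

    ``known_ids``, when given, restricts operand ids to library or group
    names present in the dataset; unknown ids raise a parse error.
    """
    parser = _Parser(_tokenize(text), known_ids=known_ids)
    root = parser.parse_or()
    tok = parser.peek()
    if tok[0] != "eof":
        raise QuestionParseError(f"unexpected token {tok[1]!r}", position=tok[2])
    return QuestionAST(root=root, text=text)


# --------------------------------------------------------------------------
# Posterior models per operand
# --------------------------------------------------------------------------

def pool_libraries(libs: Sequence[CountLibrary], gene_id: str) -> BetaPosterior:
    """Posterior after pooling libraries: counts and totals summed first.

    Pooling treats the libraries as one long sequencing run, giving
    Beta(sum N + 1, sum T - sum N + 1) — a tighter posterior than any
    single library's.
    """
    if not libs:
        raise ValueError("cannot pool an empty list of libraries")
    n = sum(lib.count(gene_id) for lib in libs)
    t = sum(lib.total_tags for lib in libs)
    return beta_posterior(n, t)


def _resolve_ids(
    operand: Operand, groups: Mapping[str, Sequence[str]] | None
) -> tuple[str, tuple[str, ...]]:
    """Expand named group aliases; return (kind, library ids)."""
    if (
        groups
        and operand.kind == "library"
        and operand.ids[0] in groups
    ):
        return "group", tuple(groups[operand.ids[0]])
    return operand.kind, operand.ids


def operand_model(
    operand: Operand,
    dataset: ExpressionDataset,
    gene_id: str,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> BetaPosterior | GroupModel:
    """Posterior model for one operand and one gene.

    A single library yields its beta posterior; a group yields the
    equal-weight beta mixture over its member libraries; a pool sums counts
    and totals into one beta posterior.  ``groups`` maps condition names to
    library lists so questions can reference named replicate groups.
    """
    kind, ids = _resolve_ids(operand, groups)
    libs = [dataset.library(i) for i in ids]
    if kind == "pool":
        return pool_libraries(libs, gene_id)
    if kind == "group" and len(libs) > 1:
        return GroupModel(
            group_id=operand.key,
            components=tuple(
                beta_posterior(lib.count(gene_id), lib.total_tags) for lib in libs
            ),
        )
    return beta_posterior(libs[0].count(gene_id), libs[0].total_tags)


# --------------------------------------------------------------------------
# Probability estimation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneProbability:
    """Monte-Carlo estimate that the question is true for one gene."""

    gene_id: str
    p_hat: float
    s_true: int
    n_sims: int
    seed: int
    all_zero: bool = False  # gene unobserved in every referenced library

    def __post_init__(self) -> None:
        if not 0 <= self.s_true <= self.n_sims:
            raise ValueError("s_true must lie in [0, n_sims]")
        if self.p_hat != self.s_true / self.n_sims:
            raise ValueError("p_hat must equal s_true / n_sims exactly")

    @property
    def mc_se(self) -> float:
        """Binomial standard error of the Monte-Carlo estimate."""
        return math.sqrt(self.p_hat * (1.0 - self.p_hat) / self.n_sims)


def estimate_probability(
    gene_id: str,
    ast: QuestionAST,
    dataset: ExpressionDataset,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> GeneProbability:
    """Estimate P(question true) for one gene by joint Monte Carlo.

    One abundance vector of length ``n_sims`` is drawn per distinct operand
    (draws are generated in sorted operand-key order from a single
    generator, so two questions over the same operands and seed consume
    identical draws — this makes p(A>B) + p(A<B) = 1 hold exactly and makes
    chained comparisons match their explicit conjunctions draw for draw).
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    rng = np.random.default_rng(seed)
    operands = ast.operands()
    models = {
        op.key: operand_model(op, dataset, gene_id, groups=groups)
        for op in operands
    }
    draws: dict[str, np.ndarray] = {}
    for key in sorted(models):
        draws[key] = sample_abundance(models[key], n_sims, rng)
    truth = ast.evaluate(draws)
    s_true = int(np.count_nonzero(truth))

    referenced: set[str] = set()
    for op in operands:
        _, ids = _resolve_ids(op, groups)
        referenced.update(ids)
    all_zero = all(dataset.library(i).count(gene_id) == 0 for i in referenced)

    return GeneProbability(
        gene_id=gene_id,
        p_hat=s_true / n_sims,
        s_true=s_true,
        n_sims=n_sims,
        seed=-1 if seed is None else int(seed),
        all_zero=all_zero,
    )


def estimate_probabilities(
    dataset: ExpressionDataset,
    ast: QuestionAST,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    groups: Mapping[str, Sequence[str]] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> list[GeneProbability]:
    """Estimate the question probability for every gene in the dataset.

    Each gene gets an independent child seed derived deterministically from
    ``seed`` and the gene's row index, so results are reproducible and
    insensitive to how the gene list is chunked.
    """
    genes = list(gene_ids) if gene_ids is not None else dataset.gene_ids
    results = []
    for idx, gene in enumerate(genes):
        child = int(
            np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31)
        )
        results.append(
            estimate_probability(
                gene, ast, dataset, n_sims=n_sims, seed=child, groups=groups
            )
        )
    return results


def normalize_cutoff(cutoff: float | str) -> float:
    """Normalize a probability cutoff given as fraction (0.8) or percent (80)."""
    c = float(cutoff)
    if c < 0 or c > 100:
        raise ValueError(f"cutoff {c} outside [0, 100]")
    return c / 100.0 if c > 1.0 else c


def rank_genes(
    results: Sequence[GeneProbability], cutoff: float | str = 0.0
) -> list[GeneProbability]:
    """Genes with p_hat >= cutoff, sorted by p_hat descending, ties by gene id."""
    c = normalize_cutoff(cutoff)
    kept = [r for r in results if r.p_hat >= c]
    return sorted(kept, key=lambda r: (-r.p_hat, r.gene_id))
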