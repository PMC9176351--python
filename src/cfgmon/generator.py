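"""Desk-scale de novo generator: SMILES token LM + virtual-loss MCTS.

The search grows SMILES strings token by token. Child nodes are scored
in the selection step with

    u_i = tR_i / (v_i + vl_i) + C * P_i * sqrt(v_p + vl_p) / (v_i + vl_i + 1)

where tR_i is the node's accumulated reward, v_i its completed visits,
vl_i its virtual (in-flight) visits, P_i the language-model probability
of the node's token given its parent prefix, and v_p/vl_p the parent's
counts. C (default 2) trades exploration against exploitation. Virtual
losses are incremented along the selected path and cleared when the
rollout's reward is backpropagated, so simultaneous selections within a
batch diversify; with a batch of one the search reduces to serial MCTS
while still exercising the vl terms.

The language model is an order-k Markov model with additive smoothing
over the token vocabulary — a deterministic, trainable-in-milliseconds
stand-in for the recurrent networks used at scale. It satisfies the
same contract (next-token distribution given a prefix), so a recurrent
model can be substituted without touching the search.

The token vocabulary covers the H/C/N/O organic subset of SMILES:
atoms C, c, N, n, O, o, bracket atoms over the same elements, bonds,
branches, ring-closure digits and E/Z slashes.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
from rdkit import Chem

from .catalog import MoleculeRecord, make_record
from .reward import RewardBreakdown

__all__ = [
    "TokenizationError",
    "tokenize",
    "detokenize",
    "TokenLM",
    "fit_language_model",
    "SearchNode",
    "SearchParams",
    "GenerationLog",
    "node_score",
    "mcts_generate",
]

END = "$"  # terminator token
BOS = "^"  # context padding symbol, never emitted

_SINGLE_CHARS = set("CcNnOo()=#123456789/\\")
_BRACKET_CHARS = set("HCNOcno0123456789+-@")


class TokenizationError(ValueError):
    """SMILES contains characters outside the H/C/N/O vocabulary."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; bracket atoms are one token."""
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(f"unclosed bracket atom in {smiles!r}")
            body = smiles[i + 1 : j]
            bad = set(body) - _BRACKET_CHARS
            if bad or not body:
                raise TokenizationError(
                    f"bracket atom [{body}] outside H/C/N/O vocabulary "
                    f"(offending: {sorted(bad)})"
                )
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch in _SINGLE_CHARS:
            tokens.append(ch)
            i += 1
        else:
            raise TokenizationError(
                f"character {ch!r} at position {i} of {smiles!r} is outside "
                "the H/C/N/O SMILES vocabulary"
            )
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize`."""
    return "".join(tokens)


class TokenLM:
    """Order-k Markov model over SMILES tokens with add-epsilon smoothing.

    Contexts are the last ``k`` symbols of the prefix, left-padded with
    a start symbol. Every training sequence is terminated with ``$``, so
    transitions into the terminator are counted and the terminator is
    reachable (with probability >= epsilon-floor) from every context.
    """

    def __init__(
        self,
        vocabulary: Sequence[str],
        order: int,
        counts: dict[tuple[str, ...], Counter],
        epsilon: float,
    ):
        if END not in vocabulary:
            raise ValueError("vocabulary must include the terminator")
        self.vocabulary = sorted(vocabulary)
        self.order = order
        self.counts = counts
        self.epsilon = epsilon
        self._index = {t: i for i, t in enumerate(self.vocabulary)}

    def context(self, prefix: Sequence[str]) -> tuple[str, ...]:
        padded = (BOS,) * self.order + tuple(prefix)
        return padded[-self.order :]

    def distribution(self, prefix: Sequence[str]) -> np.ndarray:
        """Smoothed next-token probabilities, aligned with ``vocabulary``."""
        ctx = self.context(prefix)
        counter = self.counts.get(ctx)
        v = len(self.vocabulary)
        probs = np.full(v, self.epsilon)
        total = self.epsilon * v
        if counter:
            for tok, n in counter.items():
                probs[self._index[tok]] += n
            total += sum(counter.values())
        return probs / total

    def probability(self, prefix: Sequence[str], token: str) -> float:
        """P(token | prefix) under the smoothed model."""
        return float(self.distribution(prefix)[self._index[token]])

    def sample(self, prefix: Sequence[str], rng: np.random.Generator) -> str:
        return self.vocabulary[rng.choice(len(self.vocabulary), p=self.distribution(prefix))]

    def sample_sequence(
        self, rng: np.random.Generator, max_tokens: int = 60, prefix: Sequence[str] = ()
    ) -> list[str]:
        """Extend ``prefix`` until the terminator or the length cap."""
        tokens = list(prefix)
        while len(tokens) < max_tokens:
            tok = self.sample(tokens, rng)
            if tok == END:
                break
            tokens.append(tok)
        return tokens

    # -- serialization (JSON, for the train-lm / generate CLI round trip) --

    def to_json(self) -> str:
        payload = {
            "vocabulary": self.vocabulary,
            "order": self.order,
            "epsilon": self.epsilon,
            "counts": {" ".join(ctx): dict(ctr) for ctx, ctr in self.counts.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TokenLM":
        payload = json.loads(text)
        counts = {
            tuple(ctx.split(" ")): Counter(ctr)
            for ctx, ctr in payload["counts"].items()
        }
        return cls(payload["vocabulary"], payload["order"], counts, payload["epsilon"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TokenLM":
        return cls.from_json(Path(path).read_text())


def fit_language_model(
    corpus: Sequence[str], order: int = 3, epsilon: float = 0.01
) -> TokenLM:
    """Fit the order-k Markov token model on a SMILES corpus.

    Strings that fail tokenization (characters outside the H/C/N/O
    vocabulary) are skipped. Deterministic given inputs.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive (terminator reachability)")
    counts: dict[tuple[str, ...], Counter] = defaultdict(Counter)
    vocab: set[str] = {END}
    n_used = 0
    for smiles in corpus:
        try:
            tokens = tokenize(smiles)
        except TokenizationError:
            continue
        n_used += 1
        vocab.update(tokens)
        sequence = tokens + [END]
        padded = [BOS] * order + tokens
        for i, tok in enumerate(sequence):
            ctx = tuple(padded[i : i + order])
            counts[ctx][tok] += 1
    if n_used == 0:
        raise ValueError("no tokenizable SMILES in corpus")
    return TokenLM(sorted(vocab), order, dict(counts), epsilon)


@dataclass
class SearchParams:
    """Knobs of the tree search."""

    c_explore: float = 2.0  # exploration constant C
    budget: int = 100  # number of rollouts (= generated molecules)
    n_virtual: int = 1  # selections in flight per batch
    seed: int = 0
    max_tokens: int = 60  # rollout length cap, tokens

    def __post_init__(self) -> None:
        if self.c_explore < 0:
            raise ValueError("c_explore must be >= 0")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.n_virtual < 1:
            raise ValueError("n_virtual must be >= 1")


@dataclass
class SearchNode:
    """One node of the search tree: a token appended to its parent's prefix."""

    token: str | None  # None for the root
    prefix: tuple[str, ...]  # tokens from the root, terminator excluded
    prior: float = 1.0  # P_i from the language model
    tR: float = 0.0  # accumulated reward
    v: int = 0  # completed visits
    vl: int = 0  # virtual (in-flight) visits
    parent: "SearchNode | None" = field(default=None, repr=False)
    children: "list[SearchNode] | None" = field(default=None, repr=False)

    @property
    def terminal(self) -> bool:
        return self.token == END


def node_score(node: SearchNode, parent: SearchNode, params: SearchParams) -> float:
    """Virtual-loss selection score u_i; unvisited nodes sort first (+inf)."""
    denom = node.v + node.vl
    if denom == 0:
        return math.inf
    exploit = node.tR / denom
    explore = (
        params.c_explore
        * node.prior
        * math.sqrt(parent.v + parent.vl)
        / (denom + 1)
    )
    return exploit + explore


@dataclass
class GenerationLog:
    """Ordered record of every rollout the search completed.

    ``root`` keeps the search tree for post-hoc inspection of visit
    counts and accumulated rewards.
    """

    records: list[MoleculeRecord]
    root: "SearchNode | None" = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def rewards(self) -> list[float]:
        return [
            (rec.reward_components or {}).get("r", 0.0) for rec in self.records
        ]


def _expand(node: SearchNode, lm: TokenLM) -> None:
    probs = lm.distribution(node.prefix)
    node.children = [
        SearchNode(
            token=tok,
            prefix=node.prefix if tok == END else node.prefix + (tok,),
            prior=float(p),
            parent=node,
        )
        for tok, p in zip(lm.vocabulary, probs)
    ]


def _best_child(node: SearchNode, params: SearchParams) -> SearchNode:
    # Max score; ties broken by higher prior, then lexicographic token.
    assert node.children
    best = None
    best_key: tuple[float, float] | None = None
    for child in sorted(node.children, key=lambda c: c.token or ""):
        key = (node_score(child, node, params), child.prior)
        if best_key is None or key > best_key:
            best, best_key = child, key
    assert best is not None
    return best


def _select(root: SearchNode, lm: TokenLM, params: SearchParams) -> list[SearchNode]:
    """Descend to a rollout start node, applying virtual losses on the way."""
    path = [root]
    node = root
    node.vl += 1
    while not node.terminal and len(node.prefix) < params.max_tokens:
        if node.children is None:
            _expand(node, lm)
        node = _best_child(node, params)
        node.vl += 1
        path.append(node)
        if node.v + node.vl == 1:  # fresh node: start the rollout here
            break
    return path


def mcts_generate(
    lm: TokenLM,
    reward_fn: Callable[[Chem.Mol], RewardBreakdown],
    params: SearchParams,
) -> GenerationLog:
    """Run the search for ``params.budget`` rollouts.

    Each rollout completes the selected prefix with language-model
    samples, parses the resulting SMILES and backpropagates the reward
    (0 for unparsable strings). Every rollout is logged in order, so the
    log is the "time series of generated molecules" that the enrichment
    monitor consumes. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    root = SearchNode(token=None, prefix=())
    records: list[MoleculeRecord] = []

    remaining = params.budget
    while remaining > 0:
        batch_size = min(params.n_virtual, remaining)
        batch: list[tuple[list[SearchNode], str]] = []
        for _ in range(batch_size):
            path = _select(root, lm, params)
            leaf = path[-1]
            if leaf.terminal:
                tokens = list(leaf.prefix)
            else:
                tokens = lm.sample_sequence(
                    rng, max_tokens=params.max_tokens, prefix=leaf.prefix
                )
            batch.append((path, detokenize(tokens)))

        for path, smiles in batch:
            index = len(records)
            rec = make_record(index, smiles)
            breakdown = reward_fn(rec.mol) if rec.valid else None
            if breakdown is not None:
                rec.reward_components = {
                    "r": breakdown.r,
                    "f": breakdown.f,
                    "g": breakdown.g,
                    "lambda": breakdown.lambda_value,
                    "sa": breakdown.sa_value,
                }
                r = breakdown.r
            else:
                rec.reward_components = {"r": 0.0}
                r = 0.0
            for node in path:
                node.vl -= 1
                node.v += 1
                node.tR += r
            records.append(rec)
        remaining -= batch_size

    return GenerationLog(records=records, root=root)
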