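"""Category-discriminative target-token selection.

For every token *t* in the corpus vocabulary and every event category *n*
we estimate the conditional probability p(t|n), then assign *t* to
category *j* when

    p(t|n_j) > sum over k != j of p(t|n_k)

i.e. the token's conditional probability in its home category strictly
exceeds the summed conditional probabilities everywhere else.  Because the
winning probability must exceed half the token's total conditional mass,
at most one category can satisfy the inequality, so the per-category sets
are pairwise disjoint by construction.

The mechanized rule is followed by a file-driven expert filter
(deny/allow lists) standing in for clinical-expert review.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .corpus import Corpus, tokenize
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

KEPT = "kept"
EXPERT_REMOVED = "expert_removed"


@dataclass
class TokenStats:
    """Per-category token counts and conditional probabilities.

    ``estimator`` records how p(t|n) was normalized:

    * ``"token"`` (default) — occurrences of *t* in category *n* divided by
      the total token count of *n*; probabilities sum to 1 per category.
    * ``"report"`` — fraction of category-*n* reports containing *t*
      (document frequency); rows need not sum to 1.
    """

    categories: list[str]
    tokens: list[str]
    counts: np.ndarray  # shape (n_tokens, n_categories), raw counts
    category_totals: np.ndarray  # shape (n_categories,)
    estimator: str = "token"
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def probs(self) -> np.ndarray:
        """Conditional probability matrix p(t|n), shape (n_tokens, n_categories)."""
        return self.counts / self.category_totals[np.newaxis, :]

    def prob(self, token: str, category: str) -> float:
        i = self._index.get(token)
        if i is None:
            return 0.0
        j = self.categories.index(category)
        return float(self.counts[i, j] / self.category_totals[j])

    def count(self, token: str, category: str) -> int:
        i = self._index.get(token)
        if i is None:
            return 0
        return int(self.counts[i, self.categories.index(category)])


@dataclass
class TargetTokenSets:
    """Per-category selected tokens with selection provenance.

    ``provenance`` maps each selected token to ``(category, margin,
    status)`` where margin = p(t|home) - sum of p(t|other) and status is
    ``"kept"`` or ``"expert_removed"``.  ``by_category`` holds only kept
    tokens (the working sets W fed to the sentence cover).
    """

    by_category: dict[str, set[str]]
    provenance: dict[str, tuple[str, float, str]]

    def kept(self, category: str) -> set[str]:
        return set(self.by_category.get(category, set()))


def estimate_conditional_probabilities(
    corpus: Corpus, estimator: str = "token"
) -> TokenStats:
    """Count tokens per category and form the conditional probabilities p(t|n)."""
    if estimator not in {"token", "report"}:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    categories = corpus.categories
    if len(categories) < 2:
        raise ConfigurationError(
            "token selection needs at least 2 categories; corpus has "
            f"{len(categories)}"
        )
    cat_index = {c: j for j, c in enumerate(categories)}
    token_index: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    report_counts = np.zeros(len(categories), dtype=np.int64)
    for r in corpus.reports:
        j = cat_index[r.category]
        report_counts[j] += 1
        toks = tokenize(r.text)
        if estimator == "report":
            toks = sorted(set(toks))
        for t in toks:
            i = token_index.setdefault(t, len(token_index))
            rows.append(i)
            cols.append(j)
    tokens = [t for t, _ in sorted(token_index.items(), key=lambda kv: kv[1])]
    counts = np.zeros((len(tokens), len(categories)), dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    if estimator == "token":
        totals = counts.sum(axis=0)
    else:
        totals = report_counts
    if (totals == 0).any():
        empty = [c for c, n in zip(categories, totals) if n == 0]
        raise ConfigurationError(f"categories with no tokens: {empty}")
    return TokenStats(categories, tokens, counts, totals.astype(np.int64), estimator)


def select_target_tokens(stats: TokenStats, min_count: int = 3) -> TargetTokenSets:
    """Apply the selection inequality and the minimum-support floor.

    A token is assigned to category *j* iff p(t|n_j) strictly exceeds the
    sum of its conditional probabilities in every other category and its
    raw count in *j* is at least ``min_count`` (default 3, suppressing
    hapax artifacts).  Ties never select.  An empty result is legal.
    """
    probs = stats.probs
    total = probs.sum(axis=1)
    best = probs.argmax(axis=1)
    n = np.arange(len(stats.tokens))
    p_best = probs[n, best]
    # inequality can hold only for the argmax category
    margin = p_best - (total - p_best)
    support = stats.counts[n, best]
    selected = (margin > 0) & (support >= min_count)

    by_category: dict[str, set[str]] = {c: set() for c in stats.categories}
    provenance: dict[str, tuple[str, float, str]] = {}
    for i in np.nonzero(selected)[0]:
        cat = stats.categories[best[i]]
        tok = stats.tokens[i]
        by_category[cat].add(tok)
        provenance[tok] = (cat, float(margin[i]), KEPT)
    return TargetTokenSets(by_category, provenance)


def apply_expert_filter(
    sets: TargetTokenSets,
    denylist: Mapping[str, Iterable[str]] | Iterable[str] | None = None,
    allowlist: Mapping[str, Iterable[str]] | Iterable[str] | None = None,
) -> TargetTokenSets:
    """Apply file-driven expert curation to the selected token sets.

    ``denylist`` removes tokens (marked ``expert_removed`` in provenance);
    ``allowlist``, when given, restricts each category to the listed
    tokens.  Both accept either a flat token iterable (applied to every
    category) or a mapping category -> tokens.  Deny entries that match
    nothing produce a warning, never an error.
    """

    def per_category(spec, category: str) -> set[str] | None:
        if spec is None:
            return None
        if isinstance(spec, Mapping):
            v = spec.get(category)
            return set(v) if v is not None else set()
        return set(spec)

    by_category: dict[str, set[str]] = {}
    provenance = dict(sets.provenance)
    unused_denies: set[str] = set()
    all_denied: set[str] = set()
    for cat, toks in sets.by_category.items():
        deny = per_category(denylist, cat) or set()
        all_denied |= deny
        kept = set(toks) - deny
        unused_denies |= deny - set(toks)
        allow = per_category(allowlist, cat)
        if allow is not None:
            kept &= allow
        by_category[cat] = kept
        for t in toks:
            if t not in kept:
                provenance[t] = (cat, provenance[t][1], EXPERT_REMOVED)
    if unused_denies:
        logger.warning(
            "%d denylist token(s) not present in any selected set: %s",
            len(unused_denies),
            sorted(unused_denies)[:10],
        )
    if allowlist is not None and all(not s for s in by_category.values()):
        logger.warning("allowlist removed every selected token")
    return TargetTokenSets(by_category, provenance)


# ---------------------------------------------------------------------------
# readers / writers


def write_token_sets_csv(sets: TargetTokenSets, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "token", "margin", "status"])
        for tok in sorted(sets.provenance):
            cat, margin, status = sets.provenance[tok]
            w.writerow([cat, tok, f"{margin:.10g}", status])


def read_token_sets_csv(path: str | Path) -> TargetTokenSets:
    by_category: dict[str, set[str]] = {}
    provenance: dict[str, tuple[str, float, str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            cat, tok = row["category"], row["token"]
            status = row["status"]
            provenance[tok] = (cat, float(row["margin"]), status)
            by_category.setdefault(cat, set())
            if status == KEPT:
                by_category[cat].add(tok)
    return TargetTokenSets(by_category, provenance)


def read_token_list(path: str | Path) -> list[str]:
    """Plain-text token list, one token per line; blank lines and # comments skipped."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def recovery_scores(
    sets: TargetTokenSets, planted: Mapping[str, Iterable[str]]
) -> tuple[float, float]:
    """Precision/recall of selected tokens against planted ground truth.

    A planted token counts as recovered only if selected for its own
    category.  Returns ``(precision, recall)``; precision is 1.0 when
    nothing was selected, recall is 1.0 when nothing was planted.
    """
    tp = 0
    n_selected = sum(len(s) for s in sets.by_category.values())
    n_planted = 0
    for cat, toks in planted.items():
        toks = set(toks)
        n_planted += len(toks)
        tp += len(toks & sets.by_category.get(cat, set()))
    precision = tp / n_selected if n_selected else 1.0
    recall = tp / n_planted if n_planted else 1.0
    return precision, recall


def margin_of(stats: TokenStats, token: str, category: str) -> float:
    """The inequality margin p(t|n) - sum of p(t|k), k != n, for one pair."""
    p_home = stats.prob(token, category)
    p_rest = sum(
        stats.prob(token, c) for c in stats.categories if c != category
    )
    return p_home - p_rest


__all__ = [
    "TokenStats",
    "TargetTokenSets",
    "estimate_conditional_probabilities",
    "select_target_tokens",
    "apply_expert_filter",
    "write_token_sets_csv",
    "read_token_sets_csv",
    "read_token_list",
    "recovery_scores",
    "margin_of",
    "KEPT",
    "EXPERT_REMOVED",
]
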