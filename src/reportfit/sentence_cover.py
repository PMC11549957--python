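"""Minimal target-sentence selection as a constraint-satisfaction cover.

Given one category's target tokens W, choose a small set of sentences that
together contain every token of W while visiting **at most one sentence
per report** (so no single report is oversampled).  The solver is a greedy
depth-first search: sentences are ordered by how many still-uncovered
tokens they contain (ties broken by ``(report_id, sent_index)``), the best
sentence from an unvisited report is taken, and when the greedy path dead-
ends the search backtracks, undoing the most recent selection and
forbidding it at that depth.

The per-depth exclusion sets plus a visited-state memo make the
backtracking systematic (on small instances the search provably attains
maximal coverage), an optimistic coverage bound prunes branches that
cannot improve on the best solution found, and a node-expansion cap
guarantees termination on adversarial
instances (on a cap hit the best solution found so far is frozen and the
remaining tokens are reported uncovered).  Tokens contained in no candidate
sentence at all are infeasible data, not an error: they are reported in
``uncovered`` with reason ``no_candidate``.

``exact_cover`` is an exhaustive reference solver for small instances
(one-sentence-per-report assignments, maximal coverage then minimal
cardinality); it exists to validate the greedy search, not to run at scale.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Corpus, Sentence, segment_sentences
from .errors import SizeError

logger = logging.getLogger(__name__)

NO_CANDIDATE = "no_candidate"
NOT_COVERED = "not_covered"
SEARCH_CAP = "search_cap"

DEFAULT_NODE_CAP = 10_000


@dataclass(frozen=True)
class Candidate:
    """A sentence annotated with its subset of the target tokens W."""

    sentence: Sentence
    tokens: frozenset[str]

    @property
    def report_id(self) -> str:
        return self.sentence.report_id

    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.sentence.report_id, self.sentence.sent_index)


@dataclass
class CoverInstance:
    """One category's cover problem: target tokens vs candidate sentences."""

    category: str
    target_tokens: frozenset[str]
    candidates: list[Candidate]

    def coverable_tokens(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.candidates:
            out |= c.tokens
        return frozenset(out)


@dataclass
class Selected:
    """A chosen sentence together with the tokens it newly covered."""

    candidate: Candidate
    gained: frozenset[str]


@dataclass
class CoverSolution:
    category: str
    selected: list[Selected]
    visited_reports: set[str]
    covered: set[str]
    uncovered: dict[str, str]  # token -> reason code
    backtrack_count: int
    node_expansions: int
    cap_hit: bool = False

    @property
    def sentences(self) -> list[Sentence]:
        return [s.candidate.sentence for s in self.selected]


def build_instance(
    corpus: Corpus, target_tokens: Iterable[str], category: str
) -> CoverInstance:
    """Collect the category's sentences that contain at least one target token."""
    W = frozenset(target_tokens)
    if not W:
        raise ValueError("target token set is empty")
    candidates: list[Candidate] = []
    for report in corpus.reports_in(category):
        for sent in segment_sentences(report):
            hit = W.intersection(sent.tokens)
            if hit:
                candidates.append(Candidate(sent, frozenset(hit)))
    candidates.sort(key=lambda c: c.sort_key)
    return CoverInstance(category, W, candidates)


def solve_cover(
    instance: CoverInstance, node_cap: int = DEFAULT_NODE_CAP
) -> CoverSolution:
    """Greedy depth-first search with backtracking over one cover instance."""
    no_candidate = instance.target_tokens - instance.coverable_tokens()
    W0 = set(instance.target_tokens) - no_candidate

    # report -> union of tokens obtainable from its candidate sentences
    report_tokens: dict[str, set[str]] = {}
    for c in instance.candidates:
        report_tokens.setdefault(c.report_id, set()).update(c.tokens)

    W = set(W0)
    stack: list[tuple[int, frozenset[str]]] = []  # (candidate idx, gained tokens)
    exclusions: list[set[int]] = [set()]  # exclusions[d] applies to the d-th choice
    visited_reports: set[str] = set()
    # selection sets already fully explored; identical sets reached via a
    # different selection order lead to identical subtrees
    seen_states: set[frozenset[int]] = set()
    backtracks = 0
    expansions = 0
    cap_hit = False
    best_cov = -1
    best: list[tuple[int, frozenset[str]]] = []

    def record_best() -> None:
        nonlocal best_cov, best
        covered_n = len(W0) - len(W)
        if covered_n > best_cov:
            best_cov = covered_n
            best = list(stack)

    full_cover = False
    while True:
        if not W:
            full_cover = True
            break
        if expansions >= node_cap:
            cap_hit = True
            logger.warning(
                "cover search for %r hit node cap %d", instance.category, node_cap
            )
            break
        # optimistic bound: tokens reachable through still-unvisited reports
        reachable = set()
        for rep, toks in report_tokens.items():
            if rep not in visited_reports:
                reachable |= toks & W
        potential = (len(W0) - len(W)) + len(reachable)
        dead_end = potential <= best_cov
        avail: list[tuple[int, Candidate]] = []
        if not dead_end:
            depth = len(stack)
            selected_idx = {i for i, _ in stack}
            avail = [
                (i, c)
                for i, c in enumerate(instance.candidates)
                if i not in selected_idx
                and i not in exclusions[depth]
                and c.report_id not in visited_reports
                and c.tokens & W
            ]
        if avail:
            expansions += 1
            avail.sort(key=lambda ic: (-len(ic[1].tokens & W), ic[1].sort_key))
            i, cand = avail[0]
            gained = frozenset(cand.tokens & W)
            state = frozenset({idx for idx, _ in stack} | {i})
            if state in seen_states:
                exclusions[len(stack)].add(i)
                continue
            seen_states.add(state)
            stack.append((i, gained))
            visited_reports.add(cand.report_id)
            W -= gained
            exclusions.append(set())
            continue

        # dead end: remember the best coverage seen, then undo the most
        # recent selection and forbid re-trying it at that depth
        record_best()
        if not stack:
            break
        backtracks += 1
        idx_u, gained_u = stack.pop()
        visited_reports.discard(instance.candidates[idx_u].report_id)
        W |= gained_u
        exclusions.pop()
        exclusions[len(stack)].add(idx_u)

    if full_cover:
        final = [Selected(instance.candidates[i], g) for i, g in stack]
    else:
        record_best()
        W = set(W0)
        visited_reports = set()
        final = []
        for idx, gained in best:
            cand = instance.candidates[idx]
            final.append(Selected(cand, gained))
            visited_reports.add(cand.report_id)
            W -= gained

    covered = set(W0) - W
    uncovered = {t: NO_CANDIDATE for t in no_candidate}
    for t in W:
        uncovered[t] = SEARCH_CAP if cap_hit else NOT_COVERED
    return CoverSolution(
        category=instance.category,
        selected=final,
        visited_reports=visited_reports,
        covered=covered,
        uncovered=uncovered,
        backtrack_count=backtracks,
        node_expansions=expansions,
        cap_hit=cap_hit,
    )


def exact_cover(instance: CoverInstance, max_reports: int = 10) -> CoverSolution:
    """Exhaustive reference solver: maximal coverage, then minimal cardinality.

    Enumerates one-sentence-per-report assignments (each report contributes
    one candidate sentence or none) by depth-first search with an
    optimistic coverage bound.  Intended as a test oracle on instances of
    at most ``max_reports`` reports.
    """
    by_report: dict[str, list[Candidate]] = {}
    for c in instance.candidates:
        by_report.setdefault(c.report_id, []).append(c)
    reports = sorted(by_report)
    if len(reports) > max_reports:
        raise SizeError(
            f"exact_cover limited to {max_reports} reports; instance has {len(reports)}"
        )
    no_candidate = instance.target_tokens - instance.coverable_tokens()
    W0 = frozenset(instance.target_tokens) - no_candidate

    # suffix_union[k] = tokens still obtainable from reports[k:]
    suffix_union: list[frozenset[str]] = [frozenset()] * (len(reports) + 1)
    for k in range(len(reports) - 1, -1, -1):
        u = set(suffix_union[k + 1])
        for c in by_report[reports[k]]:
            u |= c.tokens
        suffix_union[k] = frozenset(u)

    best_cov = -1
    best_size = 0
    best_sel: list[Candidate] = []

    def dfs(k: int, covered: frozenset[str], chosen: list[Candidate]) -> None:
        nonlocal best_cov, best_size, best_sel
        potential = len(covered | suffix_union[k])
        if potential < best_cov or (
            potential == best_cov and len(chosen) > best_size
        ):
            return
        if k == len(reports):
            if len(covered) > best_cov or (
                len(covered) == best_cov and len(chosen) < best_size
            ):
                best_cov = len(covered)
                best_size = len(chosen)
                best_sel = list(chosen)
            return
        for c in sorted(by_report[reports[k]], key=lambda c: c.sort_key):
            new = c.tokens - covered
            if not new:
                continue  # a non-contributing sentence can never help a minimal cover
            chosen.append(c)
            dfs(k + 1, covered | new, chosen)
            chosen.pop()
        dfs(k + 1, covered, chosen)  # skip this report

    dfs(0, frozenset(), [])

    covered: set[str] = set()
    selected: list[Selected] = []
    for c in best_sel:
        gained = frozenset(c.tokens - covered)
        selected.append(Selected(c, gained))
        covered |= gained
    uncovered = {t: NO_CANDIDATE for t in no_candidate}
    for t in W0 - covered:
        uncovered[t] = NOT_COVERED
    return CoverSolution(
        category=instance.category,
        selected=selected,
        visited_reports={c.report_id for c in best_sel},
        covered=covered,
        uncovered=uncovered,
        backtrack_count=0,
        node_expansions=0,
    )


# ---------------------------------------------------------------------------
# writers


def write_cover_csv(solutions: Sequence[CoverSolution], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "report_id", "sent_index", "sentence_text", "tokens_covered"])
        for sol in solutions:
            for sel in sol.selected:
                s = sel.candidate.sentence
                w.writerow(
                    [sol.category, s.report_id, s.sent_index, s.text, ";".join(sorted(sel.gained))]
                )


def write_uncovered_csv(solutions: Sequence[CoverSolution], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "token", "reason"])
        for sol in solutions:
            for tok in sorted(sol.uncovered):
                w.writerow([sol.category, tok, sol.uncovered[tok]])


def read_cover_csv(path: str | Path) -> dict[str, list[dict[str, str]]]:
    """Read a cover artifact back as rows grouped by category."""
    out: dict[str, list[dict[str, str]]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["category"], []).append(row)
    return out
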