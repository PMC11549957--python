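"""Greedy depth-first cover with backtracking, against the exhaustive oracle."""

import random

import pytest

from reportfit.corpus import Corpus, Report
from reportfit.errors import SizeError
from reportfit.sentence_cover import (
    NO_CANDIDATE,
    build_instance,
    exact_cover,
    read_cover_csv,
    solve_cover,
    write_cover_csv,
    write_uncovered_csv,
)


def corpus_of(reports: dict[str, list[str]], category: str = "c") -> Corpus:
    """Build a one-category corpus from {report_id: [sentence, ...]}."""
    return Corpus(
        [Report(rid, category, " ".join(s + "." for s in sents))
         for rid, sents in reports.items()]
    )


def solve(reports: dict[str, list[str]], W: set[str], **kw):
    instance = build_instance(corpus_of(reports), W, "c")
    return instance, solve_cover(instance, **kw)


def selected_ids(sol):
    return {(s.candidate.report_id, s.candidate.sentence.sent_index) for s in sol.selected}


def test_instance_restricted_to_token_bearing_sentences():
    instance = build_instance(
        corpus_of({"r1": ["aa bb", "cc dd"], "r2": ["aa", "ee"]}), {"aa"}, "c"
    )
    assert [(c.report_id, c.sentence.sent_index) for c in instance.candidates] == [
        ("r1", 0), ("r2", 0)
    ]
    assert all(c.tokens == frozenset({"aa"}) for c in instance.candidates)


def test_instance_annotations_match_membership_recount(small_config):
    from reportfit.corpus import segment_sentences
    from reportfit.synthetic import generate_corpus

    corpus, truth = generate_corpus(small_config)
    cat = corpus.categories[0]
    W = set(truth.planted[cat])
    instance = build_instance(corpus, W, cat)
    seen = set()
    for report in corpus.reports_in(cat):
        for s in segment_sentences(report):
            hit = W & set(s.tokens)
            if hit:
                seen.add((s.report_id, s.sent_index, frozenset(hit)))
    assert {(c.report_id, c.sentence.sent_index, c.tokens) for c in instance.candidates} == seen


def test_single_dominating_sentence():
    _, sol = solve({"r1": ["aa bb"], "r2": ["aa"]}, {"aa", "bb"})
    assert selected_ids(sol) == {("r1", 0)}
    assert sol.covered == {"aa", "bb"} and not sol.uncovered


def test_backtracking_worked_example():
    """Greedy first takes a sentence that blocks the only carrier of bb."""
    instance, sol = solve({"r1": ["aa", "bb"], "r2": ["aa"]}, {"aa", "bb"})
    assert sol.covered == {"aa", "bb"}
    assert sol.backtrack_count >= 1
    assert selected_ids(sol) == {("r1", 1), ("r2", 0)}
    exact = exact_cover(instance)
    assert exact.covered == sol.covered and len(exact.selected) == 2


def test_one_report_suffices_for_repeated_token():
    _, sol = solve({"r1": ["aa here", "aa again"]}, {"aa"})
    assert len(sol.selected) == 1
    assert sol.covered == {"aa"}


def test_token_without_candidate_reported_uncovered():
    _, sol = solve({"r1": ["aa bb"]}, {"aa", "bb", "cc"})
    assert sol.covered == {"aa", "bb"}
    assert sol.uncovered == {"cc": NO_CANDIDATE}


def test_one_sentence_per_report_invariant():
    _, sol = solve(
        {"r1": ["aa", "bb", "cc"], "r2": ["aa bb"], "r3": ["cc"]}, {"aa", "bb", "cc"}
    )
    reps = [s.candidate.report_id for s in sol.selected]
    assert len(reps) == len(set(reps))
    assert len(sol.selected) == len(sol.visited_reports)


def test_greedy_can_be_suboptimal_in_cardinality_but_not_coverage():
    reports = {"r1": ["aa bb"], "r2": ["aa cc"], "r3": ["bb dd"]}
    instance, sol = solve(reports, {"aa", "bb", "cc", "dd"})
    exact = exact_cover(instance)
    assert sol.covered == exact.covered == {"aa", "bb", "cc", "dd"}
    assert len(exact.selected) == 2  # {r2, r3} covers everything
    assert len(sol.selected) == 3  # greedy grabs the 2-token r1 sentence first


def test_exact_cover_empty_token_set():
    from reportfit.sentence_cover import CoverInstance

    sol = exact_cover(CoverInstance("c", frozenset(), []))
    assert not sol.selected and not sol.covered and not sol.uncovered


def test_exact_cover_size_bound():
    reports = {f"r{i}": ["aa"] for i in range(11)}
    instance = build_instance(corpus_of(reports), {"aa"}, "c")
    with pytest.raises(SizeError):
        exact_cover(instance, max_reports=10)


def random_instance(rng: random.Random, n_reports=8, n_tokens=6):
    toks = [f"t{i}" * 2 for i in range(n_tokens)]
    W = set(rng.sample(toks, rng.randint(2, n_tokens)))
    reports = {}
    for r in range(rng.randint(2, n_reports)):
        n_sents = rng.randint(1, 3)
        reports[f"r{r}"] = [
            " ".join(rng.sample(toks, rng.randint(1, 3))) for _ in range(n_sents)
        ]
    return reports, W


@pytest.mark.parametrize("seed", range(5))
def test_fuzzed_instances_match_exact_oracle(seed):
    """Greedy+backtracking never sacrifices coverage, only possibly cardinality."""
    rng = random.Random(seed)
    for _ in range(30):
        reports, W = random_instance(rng)
        instance = build_instance(corpus_of(reports), W, "c")
        sol = solve_cover(instance)
        exact = exact_cover(instance)
        # greedy+backtracking attains maximal coverage; the covered *set* is
        # only unique when the full cover is feasible
        assert len(sol.covered) == len(exact.covered)
        if exact.covered == set(instance.coverable_tokens() & W):
            assert sol.covered == exact.covered
        assert len(sol.selected) >= len(exact.selected)
        assert len(sol.selected) <= len(reports)
        reps = [s.candidate.report_id for s in sol.selected]
        assert len(reps) == len(set(reps))
        # every selection contributed at least one new token
        assert all(s.gained for s in sol.selected)
        # determinism
        again = solve_cover(build_instance(corpus_of(reports), W, "c"))
        assert selected_ids(again) == selected_ids(sol)
        assert again.backtrack_count == sol.backtrack_count


def test_termination_on_large_instance():
    rng = random.Random(99)
    toks = [f"t{i}" * 2 for i in range(50)]
    reports = {
        f"r{i:03d}": [
            " ".join(rng.sample(toks, rng.randint(1, 5)))
            for _ in range(rng.randint(1, 4))
        ]
        for i in range(200)
    }
    instance = build_instance(corpus_of(reports), set(toks), "c")
    sol = solve_cover(instance, node_cap=10_000)
    assert sol.node_expansions <= 10_000
    assert sol.covered | set(sol.uncovered) == set(toks)
    assert sol.covered.isdisjoint(sol.uncovered)


def test_cover_csv_round_trip(tmp_path):
    instance, sol = solve({"r1": ["aa bb"], "r2": ["cc"]}, {"aa", "bb", "cc", "dd"})
    write_cover_csv([sol], tmp_path / "s.csv")
    write_uncovered_csv([sol], tmp_path / "u.csv")
    rows = read_cover_csv(tmp_path / "s.csv")["c"]
    assert {(r["report_id"], int(r["sent_index"])) for r in rows} == selected_ids(sol)
    assert (tmp_path / "u.csv").read_text().strip().splitlines()[1] == "c,dd,no_candidate"
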