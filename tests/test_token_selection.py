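"""Conditional-probability estimation and the discriminative selection rule."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reportfit.corpus import Corpus, Report, tokenize
from reportfit.errors import ConfigurationError
from reportfit.token_selection import (
    EXPERT_REMOVED,
    KEPT,
    TokenStats,
    apply_expert_filter,
    estimate_conditional_probabilities,
    read_token_sets_csv,
    select_target_tokens,
    write_token_sets_csv,
)


def make_stats(counts: dict[str, dict[str, int]]) -> TokenStats:
    """Build TokenStats from {category: {token: count}} (token-frequency totals)."""
    categories = sorted(counts)
    tokens = sorted({t for c in counts.values() for t in c})
    mat = np.zeros((len(tokens), len(categories)), dtype=np.int64)
    for j, cat in enumerate(categories):
        for t, n in counts[cat].items():
            mat[tokens.index(t), j] = n
    totals = mat.sum(axis=0)
    return TokenStats(categories, tokens, mat, totals)


def test_degenerate_single_token_category():
    corpus = Corpus(
        [Report("a1", "A", "fall fall fall"), Report("b1", "B", "dose drip dose")]
    )
    stats = estimate_conditional_probabilities(corpus)
    assert stats.prob("fall", "A") == 1.0
    assert stats.prob("fall", "B") == 0.0


def test_probability_is_count_over_category_total():
    corpus = Corpus(
        [
            Report("b1", "B", "ulcer heel heel stage"),
            Report("b2", "B", "ulcer wound care skin skin dressing left heel"),
            Report("a1", "A", "fell bed"),
        ]
    )
    stats = estimate_conditional_probabilities(corpus)
    # "heel" appears 3 times among 12 tokens of category B
    assert stats.prob("heel", "B") == pytest.approx(0.25)


def test_probabilities_match_brute_force_recount(small_config):
    from reportfit.synthetic import generate_corpus

    corpus, _ = generate_corpus(small_config)
    stats = estimate_conditional_probabilities(corpus)
    # independent recount with Counter
    by_cat: dict[str, Counter] = {}
    for r in corpus.reports:
        by_cat.setdefault(r.category, Counter()).update(tokenize(r.text))
    for cat in corpus.categories:
        total = sum(by_cat[cat].values())
        j = stats.categories.index(cat)
        assert stats.probs[:, j].sum() == pytest.approx(1.0, abs=1e-9)
        for tok in list(by_cat[cat])[::17]:  # spot-check a spread of tokens
            assert stats.prob(tok, cat) == pytest.approx(by_cat[cat][tok] / total)


def test_report_frequency_estimator():
    corpus = Corpus(
        [
            Report("a1", "A", "fall fall fall"),
            Report("a2", "A", "bed rail"),
            Report("b1", "B", "dose dose"),
        ]
    )
    stats = estimate_conditional_probabilities(corpus, estimator="report")
    assert stats.prob("fall", "A") == pytest.approx(0.5)  # 1 of 2 reports


def test_single_category_rejected():
    corpus = Corpus([Report("a1", "A", "just one category here")])
    with pytest.raises(ConfigurationError, match="2 categories"):
        estimate_conditional_probabilities(corpus)


@pytest.mark.parametrize(
    "counts, expected_home",
    [
        # p(t|A)=0.6 vs p(t|B)=0.2 after normalization by equal totals
        ({"A": {"tt": 6, "xx": 4}, "B": {"tt": 2, "xx": 8}}, "A"),
        # exact tie: strict inequality fails
        ({"A": {"tt": 5, "xx": 5}, "B": {"tt": 5, "xx": 5}}, None),
        # 0.5 vs 0.3+0.3: the sum dominates
        ({"A": {"tt": 5, "xx": 5}, "B": {"tt": 3, "xx": 7}, "C": {"tt": 3, "xx": 7}}, None),
    ],
)
def test_selection_inequality(counts, expected_home):
    sets = select_target_tokens(make_stats(counts), min_count=1)
    homes = [cat for cat, toks in sets.by_category.items() if "tt" in toks]
    assert homes == ([expected_home] if expected_home else [])


def test_minimum_support_floor():
    counts = {"A": {"tt": 2, "xx": 50}, "B": {"xx": 52}}
    assert "tt" not in select_target_tokens(make_stats(counts), min_count=3).by_category["A"]
    assert "tt" in select_target_tokens(make_stats(counts), min_count=1).by_category["A"]


@given(
    st.integers(0, 2**31 - 1).map(np.random.default_rng),
    st.integers(2, 6),
    st.integers(1, 40),
)
def test_disjointness_and_brute_force_equivalence(rng, n_cats, n_tokens):
    """The strict inequality assigns each token to at most one category."""
    counts = rng.integers(0, 30, size=(n_tokens, n_cats))
    counts[0, :] = np.maximum(counts[0, :], 1)  # keep every category nonempty
    tokens = [f"tok{i:02d}" for i in range(n_tokens)]
    stats = TokenStats([f"c{j}" for j in range(n_cats)], tokens, counts,
                       counts.sum(axis=0))
    sets = select_target_tokens(stats, min_count=1)
    cats = list(sets.by_category)
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            assert not (sets.by_category[a] & sets.by_category[b])
    # brute-force evaluation of the inequality per (token, category)
    probs = counts / counts.sum(axis=0)
    for i, tok in enumerate(tokens):
        for j, cat in enumerate(cats):
            wins = probs[i, j] > (probs[i].sum() - probs[i, j])
            assert (tok in sets.by_category[cat]) == bool(wins)
    for tok, (cat, margin, status) in sets.provenance.items():
        assert margin > 0 and status == KEPT


def test_expert_denylist_and_provenance():
    counts = {"A": {f"t{i}": 10 for i in range(5)}, "B": {"zz": 10}}
    sets = select_target_tokens(make_stats(counts), min_count=1)
    assert len(sets.by_category["A"]) == 5
    filtered = apply_expert_filter(sets, denylist={"A": ["t0", "t1"]})
    assert len(filtered.by_category["A"]) == 3
    assert filtered.provenance["t0"][2] == EXPERT_REMOVED
    assert filtered.provenance["t2"][2] == KEPT


def test_empty_denylist_is_identity():
    counts = {"A": {"tt": 10}, "B": {"uu": 10}}
    sets = select_target_tokens(make_stats(counts), min_count=1)
    assert apply_expert_filter(sets, denylist=[]).by_category == sets.by_category


def test_disjoint_allowlist_empties_sets_with_warning(caplog):
    counts = {"A": {"tt": 10}, "B": {"uu": 10}}
    sets = select_target_tokens(make_stats(counts), min_count=1)
    with caplog.at_level("WARNING"):
        filtered = apply_expert_filter(sets, allowlist=["nothere"])
    assert all(not s for s in filtered.by_category.values())
    assert any("allowlist" in m for m in caplog.messages)


def test_unknown_denylist_token_warns_not_errors(caplog):
    counts = {"A": {"tt": 10}, "B": {"uu": 10}}
    sets = select_target_tokens(make_stats(counts), min_count=1)
    with caplog.at_level("WARNING"):
        apply_expert_filter(sets, denylist=["ghost"])
    assert any("denylist" in m for m in caplog.messages)


def test_token_sets_csv_round_trip(tmp_path):
    counts = {"A": {"tt": 10, "vv": 8}, "B": {"uu": 10}}
    sets = apply_expert_filter(
        select_target_tokens(make_stats(counts), min_count=1), denylist=["vv"]
    )
    p = tmp_path / "tokens.csv"
    write_token_sets_csv(sets, p)
    again = read_token_sets_csv(p)
    assert again.by_category == sets.by_category
    for tok in sets.provenance:
        assert again.provenance[tok][0] == sets.provenance[tok][0]
        assert again.provenance[tok][2] == sets.provenance[tok][2]
        assert again.provenance[tok][1] == pytest.approx(sets.provenance[tok][1])
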