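"""Seeded synthetic report corpora with planted category structure.

Real incident-report corpora are protected data, so every pipeline stage
is exercised on generated corpora that emulate their statistical shape:
several event categories share a common background vocabulary (Zipf-like
frequencies), and each category additionally over-uses a small disjoint
set of *signal* tokens — the synthetic analogue of category-distinctive
words like "armband" or "copay".  Reports are multi-sentence, sentence
and report lengths are Poisson with floors, and everything is
deterministic given the seed.

The generation model is a per-category unigram mixture: token *t* in
category *c* is drawn with probability proportional to its base weight,
multiplied by ``signal_boost`` when *t* is one of *c*'s planted signal
tokens.  Realistic clinical syntax is a non-goal; the planted structure
is exactly what the token-selection inequality, the sentence cover, the
matched/mismatched perplexity contrast, and the ANOVA need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import Corpus, Report
from .errors import ConfigurationError
from .perplexity import NgramBackend, fit_ngram_backend

DEFAULT_SEED = 20_240_901


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults: 4 categories x 200 reports, a 300-token vocabulary of which
    10 disjoint signal tokens per category are boosted 20x in their home
    category, ~3 sentences per report and ~8 tokens per sentence.  The
    background follows a mild Zipf law (exponent 0.3) and each signal
    token's base weight equals the median background weight, so planted
    tokens are unremarkable outside their home category.

    The vocabulary size and Zipf exponent are sized together so the
    generator honours its recoverability contract: a background token is
    falsely "discriminative" exactly when one category collects more
    than half of its occurrences by sampling noise, and that chance-
    majority probability decays exponentially in the token's expected
    count.  At 300 types over ~19 000 corpus tokens with exponent 0.3,
    the rarest background type is still expected ~35 times, putting the
    expected number of chance majorities across the whole background
    below one; a heavier tail (more types, or a steeper exponent)
    floods the selector with low-count artifacts instead.
    """

    n_categories: int = 4
    reports_per_category: int = 200
    sentences_per_report_mean: float = 3.0
    min_sentences: int = 1
    tokens_per_sentence_mean: float = 8.0
    min_tokens: int = 3
    shared_vocab_size: int = 300
    signal_tokens_per_category: int = 10
    signal_boost: float = 20.0
    zipf_exponent: float = 0.3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ConfigurationError("n_categories must be >= 2")
        if self.signal_boost < 1:
            raise ConfigurationError("signal_boost must be >= 1")
        if self.shared_vocab_size <= self.total_signal_tokens:
            raise ConfigurationError(
                f"vocabulary of {self.shared_vocab_size} cannot hold "
                f"{self.total_signal_tokens} signal tokens plus background"
            )

    @property
    def total_signal_tokens(self) -> int:
        return self.n_categories * self.signal_tokens_per_category

    @property
    def categories(self) -> list[str]:
        return [f"cat{j:02d}" for j in range(self.n_categories)]


@dataclass
class GroundTruth:
    """Which tokens were planted where, plus a config echo."""

    planted: dict[str, list[str]]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"planted": self.planted, "config": self.config}, indent=2),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(planted=d["planted"], config=d.get("config", {}))


def _vocabulary(config: GeneratorConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Token names: per-category signal tokens plus Zipf-weighted background."""
    planted = {
        cat: [
            f"sig{j:02d}x{i:02d}"
            for i in range(config.signal_tokens_per_category)
        ]
        for j, cat in enumerate(config.categories)
    }
    n_background = config.shared_vocab_size - config.total_signal_tokens
    background = [f"word{i:04d}" for i in range(n_background)]
    return background, planted


def category_distribution(config: GeneratorConfig, category: str) -> dict[str, float]:
    """The exact unigram distribution reports of ``category`` are drawn from."""
    background, planted = _vocabulary(config)
    n_background = len(background)
    weights: dict[str, float] = {
        t: (i + 1) ** (-config.zipf_exponent) for i, t in enumerate(background)
    }
    base_signal = (n_background // 2 + 1) ** (-config.zipf_exponent)
    for cat, toks in planted.items():
        for t in toks:
            weights[t] = base_signal * (config.signal_boost if cat == category else 1.0)
    total = sum(weights.values())
    return {t: w / total for t, w in weights.items()}


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Draw a full labelled corpus; byte-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    _, planted = _vocabulary(config)
    reports: list[Report] = []
    for cat in config.categories:
        dist = category_distribution(config, cat)
        vocab = np.array(sorted(dist))
        probs = np.array([dist[t] for t in vocab])
        for r in range(config.reports_per_category):
            n_sent = max(
                config.min_sentences,
                int(rng.poisson(config.sentences_per_report_mean)),
            )
            sentences = []
            for _ in range(n_sent):
                n_tok = max(
                    config.min_tokens,
                    int(rng.poisson(config.tokens_per_sentence_mean)),
                )
                toks = rng.choice(vocab, size=n_tok, p=probs)
                sentences.append(" ".join(toks) + ".")
            reports.append(Report(f"{cat}-{r:04d}", cat, " ".join(sentences)))
    truth = GroundTruth(planted={c: list(t) for c, t in planted.items()},
                        config=asdict(config))
    return Corpus(reports), truth


#: Configuration of the small bundled fixture corpus (40 reports), kept in
#: ``reportfit/data`` for fast deterministic unit tests; regenerating with
#: this config reproduces the file byte for byte.
FIXTURE_CONFIG = GeneratorConfig(reports_per_category=10)


def fixture_paths() -> tuple[Path, Path]:
    """Paths of the bundled fixture corpus CSV and its ground-truth JSON."""
    data = Path(__file__).parent / "data"
    return data / "fixture_corpus.csv", data / "fixture_ground_truth.json"


def load_fixture() -> tuple[Corpus, GroundTruth]:
    """Load the bundled 40-report fixture corpus and its planted tokens."""
    from .corpus import load_corpus

    corpus_path, truth_path = fixture_paths()
    return load_corpus(corpus_path, format="csv"), GroundTruth.from_json(truth_path)


def make_matched_backends(
    corpus: Corpus, order: int = 2, smoothing: float = 0.1
) -> dict[str, NgramBackend]:
    """One n-gram backend per category, trained only on that category's reports.

    The matched/mismatched perplexity contrast these enable is the
    synthetic stand-in for comparing domain-specific against general
    language models.
    """
    cats = corpus.categories
    if len(cats) < 2:
        raise ConfigurationError("matched backends need >= 2 categories")
    return {
        cat: fit_ngram_backend(
            [r.text for r in corpus.reports_in(cat)],
            order=order,
            smoothing=smoothing,
            model_id=f"ngram{order}-{cat}",
        )
        for cat in cats
    }
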