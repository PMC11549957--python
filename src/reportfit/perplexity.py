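"""Sentence perplexity under pluggable causal language-model backends.

Perplexity of a sentence is ``exp(-(1/n) * sum_i log p(w_i | w_<i))`` over
the backend's own tokenization of the sentence.  A start-of-sequence
context is always supplied so the *first* real token receives a proper
conditional probability (every scored token has positive probability, and
perplexity is at least 1 for any proper model).  Sequences longer than the
backend's ``max_sequence_length`` are truncated to their prefix; target
sentences are single sentences and virtually never truncate.

Backends:

* :class:`NgramBackend` — additive-smoothed n-gram model (orders 1-3) over
  a closed vocabulary plus an explicit unknown-token class.  The reference
  backend: trainable in milliseconds, fully deterministic, no downloads.
* :class:`FixedProbabilityBackend` / :func:`uniform_backend` — degenerate
  models with closed-form perplexity, used to validate the metric.
* :func:`transformer_backend` — optional adapter for Hugging Face causal
  checkpoints; requires ``torch`` and ``transformers`` and raises
  :class:`~reportfit.errors.BackendUnavailableError` when they (or the
  checkpoint) are absent.  The rest of the package never depends on it.

Batching (:func:`batch_score`, default batch size 16) is throughput-only:
values are bit-identical to sentence-by-sentence scoring.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

from .corpus import Sentence, tokenize
from .errors import BackendUnavailableError, ConfigurationError, ScoringError

logger = logging.getLogger(__name__)

BOS = "<s>"
UNK = "<unk>"


@runtime_checkable
class LMBackend(Protocol):
    """Contract every language-model backend satisfies.

    ``encode`` maps text to the backend's own token sequence;
    ``token_log_probs`` returns one natural-log conditional probability
    per token, each <= 0, the first token conditioned on a start-of-
    sequence context.  Both must be deterministic.
    """

    model_id: str
    max_sequence_length: int

    def encode(self, text: str) -> list[str]: ...

    def token_log_probs(self, tokens: Sequence[str]) -> list[float]: ...


@dataclass(frozen=True)
class PerplexityResult:
    report_id: str
    sent_index: int
    category: str
    model_id: str
    perplexity: float
    n_scored_tokens: int


def compute_perplexity(
    backend: LMBackend,
    sentence_text: str,
    *,
    report_id: str = "",
    sent_index: int = 0,
    category: str = "",
) -> PerplexityResult:
    """Score one sentence: exp of the mean negative token log-probability."""
    tokens = backend.encode(sentence_text)
    if not tokens:
        raise ScoringError(
            f"sentence {(report_id, sent_index)} empty after tokenization: "
            f"{sentence_text!r}"
        )
    tokens = tokens[: backend.max_sequence_length]
    logps = backend.token_log_probs(tokens)
    if len(logps) != len(tokens):
        raise ScoringError(
            f"backend {backend.model_id!r} returned {len(logps)} log-probs "
            f"for {len(tokens)} tokens"
        )
    ppl = math.exp(-sum(logps) / len(logps))
    return PerplexityResult(
        report_id=report_id,
        sent_index=sent_index,
        category=category,
        model_id=backend.model_id,
        perplexity=ppl,
        n_scored_tokens=len(tokens),
    )


def batch_score(
    backend: LMBackend,
    sentences: Sequence[Sentence],
    batch_size: int = 16,
    categories: Mapping[str, str] | None = None,
) -> list[PerplexityResult]:
    """Score many sentences in batches of ``batch_size`` (default 16).

    Batching never changes values; it only chunks the work and the
    progress log.  Per-sentence scoring failures are logged and skipped
    rather than aborting the run.  ``categories`` maps report_id to event
    category for labelling the results.
    """
    if batch_size < 1:
        raise ConfigurationError("batch_size must be >= 1")
    categories = categories or {}
    results: list[PerplexityResult] = []
    n_failed = 0
    for start in range(0, len(sentences), batch_size):
        for s in sentences[start : start + batch_size]:
            try:
                results.append(
                    compute_perplexity(
                        backend,
                        s.text,
                        report_id=s.report_id,
                        sent_index=s.sent_index,
                        category=categories.get(s.report_id, ""),
                    )
                )
            except ScoringError as exc:
                n_failed += 1
                logger.warning("skipping sentence: %s", exc)
        logger.debug(
            "%s: scored %d/%d sentences",
            backend.model_id,
            min(start + batch_size, len(sentences)),
            len(sentences),
        )
    if n_failed:
        logger.warning("%s: %d sentence(s) failed to score", backend.model_id, n_failed)
    return results


# ---------------------------------------------------------------------------
# reference backends


class FixedProbabilityBackend:
    """Assigns every token the same conditional probability ``p``.

    Perplexity of any sentence is exactly ``1/p``; used to validate the
    metric's closed form.
    """

    def __init__(self, p: float, model_id: str = "fixed", max_sequence_length: int = 1024):
        if not 0 < p <= 1:
            raise ConfigurationError("p must be in (0, 1]")
        self.p = p
        self.model_id = model_id
        self.max_sequence_length = max_sequence_length

    def encode(self, text: str) -> list[str]:
        return tokenize(text)

    def token_log_probs(self, tokens: Sequence[str]) -> list[float]:
        return [math.log(self.p)] * len(tokens)


def uniform_backend(vocab_size: int, max_sequence_length: int = 1024) -> FixedProbabilityBackend:
    """A model uniform over ``vocab_size`` tokens: perplexity equals vocab_size."""
    return FixedProbabilityBackend(
        1.0 / vocab_size, model_id=f"uniform{vocab_size}",
        max_sequence_length=max_sequence_length,
    )


class NgramBackend:
    """Additive-smoothed n-gram language model over a closed vocabulary.

    Conditional probabilities are

        p(w | ctx) = (c(ctx, w) + a) / (c(ctx) + a * (|V| + 1))

    with smoothing constant ``a > 0`` and the +1 reserving mass for an
    explicit unknown-token class, so probabilities sum to one over
    V union {unk} for every context and perplexity stays finite on
    out-of-vocabulary text.  Contexts are the previous ``order - 1``
    tokens, padded with a start-of-sequence symbol, so the first token of
    a sentence is scored conditionally.  As ``a`` grows the model tends to
    the uniform distribution over V union {unk}.
    """

    def __init__(
        self,
        order: int,
        smoothing: float,
        ngram_counts: Mapping[tuple[str, ...], Counter],
        vocabulary: frozenset[str],
        model_id: str = "ngram",
        max_sequence_length: int = 1024,
    ):
        if order not in {1, 2, 3}:
            raise ConfigurationError(f"n-gram order must be 1, 2 or 3; got {order}")
        if smoothing <= 0:
            raise ConfigurationError("smoothing must be > 0")
        self.order = order
        self.smoothing = smoothing
        self._counts = ngram_counts
        self._context_totals = {
            ctx: sum(c.values()) for ctx, c in ngram_counts.items()
        }
        self.vocabulary = vocabulary
        self.model_id = model_id
        self.max_sequence_length = max_sequence_length

    def encode(self, text: str) -> list[str]:
        return tokenize(text)

    def _map(self, tok: str) -> str:
        return tok if tok in self.vocabulary else UNK

    def conditional_prob(self, token: str, context: Sequence[str]) -> float:
        """p(token | context) after vocabulary mapping; sums to 1 over V + unk."""
        tok = self._map(token)
        ctx = tuple(self._map(c) if c != BOS else BOS for c in context)
        counts = self._counts.get(ctx)
        denom_extra = self.smoothing * (len(self.vocabulary) + 1)
        if counts is None:
            return self.smoothing / denom_extra  # unseen context: uniform
        return (counts[tok] + self.smoothing) / (self._context_totals[ctx] + denom_extra)

    def token_log_probs(self, tokens: Sequence[str]) -> list[float]:
        k = self.order - 1
        padded = [BOS] * k + [self._map(t) for t in tokens]
        out = []
        for i in range(len(tokens)):
            ctx = tuple(padded[i : i + k])
            out.append(math.log(self.conditional_prob(padded[k + i], ctx)))
        return out


def fit_ngram_backend(
    training_texts: Iterable[str],
    order: int = 2,
    smoothing: float = 0.1,
    model_id: str | None = None,
    max_sequence_length: int = 1024,
) -> NgramBackend:
    """Train an additive-smoothed n-gram backend on raw texts.

    The vocabulary is closed over the training tokens; anything unseen at
    scoring time maps to the unknown class.
    """
    if order not in {1, 2, 3}:
        raise ConfigurationError(f"n-gram order must be 1, 2 or 3; got {order}")
    if smoothing <= 0:
        raise ConfigurationError("smoothing must be > 0")
    vocab: set[str] = set()
    ngram_counts: dict[tuple[str, ...], Counter] = {}
    k = order - 1
    n_texts = 0
    for text in training_texts:
        toks = tokenize(text)
        if not toks:
            continue
        n_texts += 1
        vocab.update(toks)
        padded = [BOS] * k + toks
        for i in range(len(toks)):
            ctx = tuple(padded[i : i + k])
            ngram_counts.setdefault(ctx, Counter())[padded[k + i]] += 1
    if n_texts == 0:
        raise ConfigurationError("no nonempty training texts")
    return NgramBackend(
        order=order,
        smoothing=smoothing,
        ngram_counts=ngram_counts,
        vocabulary=frozenset(vocab),
        model_id=model_id or f"ngram{order}",
        max_sequence_length=max_sequence_length,
    )


# ---------------------------------------------------------------------------
# optional transformer adapter


def transformer_backend(
    checkpoint_ref: str, max_sequence_length: int = 1024
) -> LMBackend:
    """Adapter for a Hugging Face causal-LM checkpoint and its own tokenizer.

    Different checkpoints ship different (sometimes custom) tokenizers,
    and scoring under each model's own tokenizer is part of the method.
    Requires ``torch`` and ``transformers``; raises
    :class:`BackendUnavailableError` with a remediation hint when either
    library or the checkpoint is unavailable, so the core pipeline keeps
    working without them.
    """
    try:
        import torch  # noqa: F401
        from transformers import AutoModelForCausalLM, AutoTokenizer
    except ImportError as exc:
        raise BackendUnavailableError(
            "transformer backend requires the 'torch' and 'transformers' "
            "packages; install reportfit[transformers] to enable it"
        ) from exc
    try:
        tokenizer = AutoTokenizer.from_pretrained(checkpoint_ref)
        model = AutoModelForCausalLM.from_pretrained(checkpoint_ref)
    except OSError as exc:
        raise BackendUnavailableError(
            f"checkpoint {checkpoint_ref!r} not available locally; download it "
            "on a networked machine and pass its path"
        ) from exc
    return _TransformerBackend(checkpoint_ref, tokenizer, model, max_sequence_length)


class _TransformerBackend:
    """Causal-LM scoring with a prepended BOS so the first token is conditional."""

    def __init__(self, model_id, tokenizer, model, max_sequence_length):
        self.model_id = model_id
        self._tokenizer = tokenizer
        self._model = model.eval()
        self.max_sequence_length = max_sequence_length

    def encode(self, text: str) -> list[str]:
        return self._tokenizer.tokenize(text)

    def token_log_probs(self, tokens: Sequence[str]) -> list[float]:
        import torch

        ids = self._tokenizer.convert_tokens_to_ids(list(tokens))
        bos = self._tokenizer.bos_token_id
        if bos is None:
            bos = self._tokenizer.eos_token_id
        input_ids = torch.tensor([[bos] + ids])
        with torch.no_grad():
            logits = self._model(input_ids).logits
        logprobs = torch.log_softmax(logits[0, :-1], dim=-1)
        return [float(logprobs[i, tid]) for i, tid in enumerate(ids)]


# ---------------------------------------------------------------------------
# results writer / reader


def write_results_csv(results: Sequence[PerplexityResult], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["report_id", "sent_index", "category", "model_id", "perplexity", "n_scored_tokens"]
        )
        for r in results:
            w.writerow(
                [r.report_id, r.sent_index, r.category, r.model_id,
                 repr(r.perplexity), r.n_scored_tokens]
            )


def read_results_csv(path: str | Path) -> list[PerplexityResult]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PerplexityResult(
                    report_id=row["report_id"],
                    sent_index=int(row["sent_index"]),
                    category=row["category"],
                    model_id=row["model_id"],
                    perplexity=float(row["perplexity"]),
                    n_scored_tokens=int(row["n_scored_tokens"]),
                )
            )
    return out
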