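"""Per-category model comparison: mean/SEM summaries, one-way ANOVA, ranking.

Within each event category every target sentence is scored by every
candidate model, giving a (sentence x model) perplexity table.  The
summary reports, per model, the mean perplexity and its standard error
(sample sd / sqrt(n)), and tests the omnibus hypothesis that mean
perplexity differs between models with a one-way fixed-effects ANOVA
(model as the factor, sentence-level perplexity as the response).
Sentences are treated as independent observations and no post-hoc
pairwise tests are run; the omnibus p plus the means carry the
interpretation.  The ANOVA runs on raw perplexities by default —
perplexity is right-skewed, so a log-scale switch is provided for users
who prefer the better-behaved response.

``rank_lowest`` reproduces the qualitative review step: sentences ordered
by their average perplexity across all models, joined to the target
tokens they covered.

``null_calibration`` is a self-check, not a pipeline stage: it pushes
simulated perplexity tables through the same summary/ANOVA path and
reports how uniform the null p-values are.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .perplexity import PerplexityResult
from .sentence_cover import CoverSolution

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ModelSummary:
    mean: float
    sem: float
    n: int


@dataclass
class CategorySummary:
    category: str
    per_model: dict[str, ModelSummary]
    anova_F: float | None
    anova_p: float | None
    best_model: str

    @property
    def significant(self) -> bool | None:
        if self.anova_p is None:
            return None
        return self.anova_p < SIGNIFICANCE_LEVEL


@dataclass
class SentenceRanking:
    """Rows (token(s), category, average perplexity, sentence text), ascending."""

    rows: list[tuple[str, str, float, str]]


def results_to_frame(results: Sequence[PerplexityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "report_id": [r.report_id for r in results],
            "sent_index": [r.sent_index for r in results],
            "category": [r.category for r in results],
            "model_id": [r.model_id for r in results],
            "perplexity": [r.perplexity for r in results],
        }
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p).

    Degenerate inputs the F distribution cannot handle (all values
    identical across groups) return (0, 1): no evidence of any
    between-model difference.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ConfigurationError("ANOVA needs >= 2 groups with >= 2 observations each")
    flat = np.concatenate(arrays)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays)
    if math.isnan(f):  # zero within-group variance with equal means
        return 0.0, 1.0
    return float(f), float(p)


def summarize(
    results: Sequence[PerplexityResult], scale: str = "raw"
) -> list[CategorySummary]:
    """Per-category means, SEMs, and the between-model one-way ANOVA.

    Only sentences scored by *every* model enter the summary; incomplete
    sentences are excluded with a logged count, so n is identical across
    models within a category.  ``scale="log"`` runs the ANOVA on natural-
    log perplexities (means and SEMs stay on the raw scale).
    """
    if scale not in {"raw", "log"}:
        raise ConfigurationError(f"unknown scale {scale!r}")
    if not results:
        return []
    df = results_to_frame(results)
    models = sorted(df["model_id"].unique())
    summaries: list[CategorySummary] = []
    for category, cdf in df.groupby("category", sort=True):
        wide = cdf.pivot_table(
            index=["report_id", "sent_index"],
            columns="model_id",
            values="perplexity",
        )
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            logger.warning(
                "%s: excluded %d sentence(s) not scored by every model",
                category,
                n_dropped,
            )
        per_model: dict[str, ModelSummary] = {}
        for m in models:
            if m not in complete.columns or complete[m].empty:
                continue
            vals = complete[m].to_numpy()
            sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            per_model[m] = ModelSummary(mean=float(vals.mean()), sem=sem, n=len(vals))
        if not per_model:
            continue
        best_model = min(per_model, key=lambda m: per_model[m].mean)
        anova_F = anova_p = None
        if len(per_model) >= 2 and len(complete) >= 2:
            groups = [
                complete[m].to_numpy() if scale == "raw" else np.log(complete[m].to_numpy())
                for m in per_model
            ]
            anova_F, anova_p = one_way_anova(groups)
        else:
            logger.warning(
                "%s: ANOVA skipped (needs >= 2 models and >= 2 sentences)", category
            )
        summaries.append(
            CategorySummary(
                category=str(category),
                per_model=per_model,
                anova_F=anova_F,
                anova_p=anova_p,
                best_model=best_model,
            )
        )
    return summaries


def rank_lowest(
    results: Sequence[PerplexityResult],
    covers: Sequence[CoverSolution],
    top_k: int = 10,
) -> SentenceRanking:
    """Sentences with the lowest average perplexity across all models.

    Per category, each sentence's perplexities are averaged over the full
    model set (sentences missing any model are excluded), joined to the
    target tokens that sentence covered, and the ``top_k`` lowest are
    returned in ascending order.  Ties break on (report_id, sent_index).
    """
    if not results:
        raise ConfigurationError("no perplexity results to rank")
    df = results_to_frame(results)
    n_models = df["model_id"].nunique()
    token_map: dict[tuple[str, int], tuple[str, str]] = {}
    text_map: dict[tuple[str, int], str] = {}
    for sol in covers:
        for sel in sol.selected:
            s = sel.candidate.sentence
            token_map[(s.report_id, s.sent_index)] = (
                ";".join(sorted(sel.gained)),
                sol.category,
            )
            text_map[(s.report_id, s.sent_index)] = s.text
    agg = (
        df.groupby(["category", "report_id", "sent_index"])
        .agg(avg=("perplexity", "mean"), k=("model_id", "nunique"))
        .reset_index()
    )
    agg = agg[agg["k"] == n_models]
    rows: list[tuple[str, str, float, str]] = []
    for category, cdf in agg.groupby("category", sort=True):
        cdf = cdf.sort_values(["avg", "report_id", "sent_index"]).head(top_k)
        for _, row in cdf.iterrows():
            key = (row["report_id"], int(row["sent_index"]))
            tokens, _ = token_map.get(key, ("", str(category)))
            rows.append(
                (tokens, str(category), float(row["avg"]), text_map.get(key, ""))
            )
    rows.sort(key=lambda r: (r[1], r[2]))
    return SentenceRanking(rows)


@dataclass
class CalibrationReport:
    p_values: list[float]
    ks_distance: float
    frac_below_alpha: float
    alpha: float = SIGNIFICANCE_LEVEL


def null_calibration(
    n_sentences: int,
    n_models: int,
    n_reps: int,
    seed: int,
    effect_size: float = 0.0,
) -> CalibrationReport:
    """Simulate perplexity tables and check the ANOVA p-value distribution.

    Each replicate draws ``n_sentences`` Gaussian "perplexities" per model
    from a shared distribution (plus an ``effect_size``-sd location shift
    on the last model, for power checks) and runs the full summarize path
    for a single category.  Under the null the p-values should be uniform;
    the report carries the Kolmogorov-Smirnov distance from uniformity and
    the rejection fraction at alpha = 0.05.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    pvals: list[float] = []
    for _ in range(n_reps):
        results: list[PerplexityResult] = []
        for m in range(n_models):
            shift = effect_size if m == n_models - 1 else 0.0
            draws = 100.0 + 10.0 * (rng.standard_normal(n_sentences) + shift)
            for i, v in enumerate(draws):
                results.append(
                    PerplexityResult(
                        report_id=f"r{i}",
                        sent_index=0,
                        category="sim",
                        model_id=f"m{m}",
                        perplexity=float(v),
                        n_scored_tokens=10,
                    )
                )
        summary = summarize(results)[0]
        pvals.append(float(summary.anova_p))
    ks = float(sps.kstest(pvals, "uniform").statistic)
    frac = float(np.mean([p < SIGNIFICANCE_LEVEL for p in pvals]))
    return CalibrationReport(p_values=pvals, ks_distance=ks, frac_below_alpha=frac)


# ---------------------------------------------------------------------------
# writers


def write_summary_csv(summaries: Sequence[CategorySummary], path: str | Path) -> None:
    """Wide layout: one row per model, one column pair per category, plus ANOVA rows."""
    categories = [s.category for s in summaries]
    models = sorted({m for s in summaries for m in s.per_model})
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["row"] + categories)
        for m in models:
            w.writerow(
                [m]
                + [
                    f"{s.per_model[m].mean:.4g}" if m in s.per_model else ""
                    for s in summaries
                ]
            )
            w.writerow(
                [f"{m}_sem"]
                + [
                    f"{s.per_model[m].sem:.4g}" if m in s.per_model else ""
                    for s in summaries
                ]
            )
        w.writerow(["n_sentences"] + [
            str(next(iter(s.per_model.values())).n) for s in summaries
        ])
        w.writerow(["best_model"] + [s.best_model for s in summaries])
        w.writerow(
            ["anova_F"]
            + [f"{s.anova_F:.6g}" if s.anova_F is not None else "" for s in summaries]
        )
        w.writerow(
            ["anova_p"]
            + [f"{s.anova_p:.6g}" if s.anova_p is not None else "" for s in summaries]
        )


def write_ranking_csv(ranking: SentenceRanking, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["target_tokens", "category", "average_perplexity", "sentence_text"])
        for tokens, category, avg, text in ranking.rows:
            w.writerow([tokens, category, f"{avg:.6g}", text])
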