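"""Evaluate ranked driver-gene predictions against a gold-standard gene set.

Predictions are rows of (gene id, cohort, q-value), one per gene and cohort,
with q-values already FDR-corrected by the producer. Evaluation follows the
precision/positive-predictive-value convention: sort genes by ascending
q-value and report the cumulative fraction of gold-standard genes at each
rank, against the baseline fraction of gold genes among all tested genes.
Cutoff metrics (precision, sensitivity, Fisher enrichment) use a strict
``q < cutoff`` candidate rule, 0.1 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrecisionCurve",
    "BenchmarkResult",
    "read_predictions",
    "precision_at_rank",
    "benchmark_at_cutoff",
    "pool_cohorts",
]

DEFAULT_Q_CUTOFF = 0.1


@dataclass
class PrecisionCurve:
    """Cumulative precision along a q-value ranking."""

    cohort: str
    genes: list[str]
    q_values: list[float]
    precision: np.ndarray
    baseline: float
    n_candidates: int
    q_cutoff: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.genes) + 1),
                "gene_id": self.genes,
                "q_value": self.q_values,
                "precision": self.precision,
            }
        )


@dataclass
class BenchmarkResult:
    """Cutoff metrics for one cohort (or the pooled set of cohorts)."""

    cohort: str
    n_tested: int
    n_gold_tested: int
    n_candidates: int
    n_gold_candidates: int
    precision: float  # NaN when no candidates
    sensitivity: float
    odds_ratio: float
    fisher_p: float
    no_candidates: bool = False

    def as_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "n_tested": self.n_tested,
            "n_gold_tested": self.n_gold_tested,
            "n_candidates": self.n_candidates,
            "n_gold_candidates": self.n_gold_candidates,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
        }


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions TSV with columns gene_id, cohort, q_value
    (optional: method)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cohort": str})
    required = {"gene_id", "cohort", "q_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise ValueError(f"{path}: q_value outside [0, 1]")
    if df.duplicated(["gene_id", "cohort"]).any():
        raise ValueError(f"{path}: duplicate (gene_id, cohort) rows")
    return df


def _sorted_one_cohort(predictions: pd.DataFrame) -> pd.DataFrame:
    if predictions.empty:
        raise ValueError("empty prediction set")
    # deterministic: ascending q, ties broken lexicographically by gene id
    return predictions.sort_values(
        ["q_value", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)


def precision_at_rank(
    predictions: pd.DataFrame,
    gold: Iterable[str],
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    cohort: str = "",
) -> PrecisionCurve:
    """Cumulative precision at every rank of the q-value-sorted gene list."""
    gold = set(gold)
    df = _sorted_one_cohort(predictions)
    hits = df["gene_id"].isin(gold).to_numpy()
    ranks = np.arange(1, len(df) + 1)
    precision = np.cumsum(hits) / ranks
    baseline = hits.sum() / len(df)
    n_candidates = int((df["q_value"] < q_cutoff).sum())
    return PrecisionCurve(
        cohort=cohort or (df["cohort"].iloc[0] if "cohort" in df else ""),
        genes=df["gene_id"].tolist(),
        q_values=df["q_value"].tolist(),
        precision=precision,
        baseline=float(baseline),
        n_candidates=n_candidates,
        q_cutoff=q_cutoff,
    )


def _fisher(n_gold_cand, n_cand, n_gold_tested, n_tested, alternative="two-sided"):
    table = [
        [n_gold_cand, n_gold_tested - n_gold_cand],
        [n_cand - n_gold_cand, (n_tested - n_gold_tested) - (n_cand - n_gold_cand)],
    ]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def benchmark_at_cutoff(
    predictions: pd.DataFrame,
    gold: Iterable[str],
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    cohort: str = "",
    strict: bool = True,
    alternative: str = "two-sided",
) -> BenchmarkResult:
    """Precision/sensitivity/Fisher enrichment at a q-value cutoff.

    Candidates are genes with ``q < cutoff`` (strict by default). The Fisher
    test is on the 2x2 table (gold vs non-gold) x (candidate vs
    non-candidate) over the tested genes.
    """
    if not (0 < q_cutoff <= 1):
        raise ValueError("q_cutoff must be in (0, 1]")
    gold = set(gold)
    df = _sorted_one_cohort(predictions)
    tested = set(df["gene_id"])
    is_cand = (
        (df["q_value"] < q_cutoff) if strict else (df["q_value"] <= q_cutoff)
    ).to_numpy()
    candidates = set(df.loc[is_cand, "gene_id"])
    n_tested = len(tested)
    n_gold_tested = len(gold & tested)
    n_cand = len(candidates)
    n_gold_cand = len(gold & candidates)
    precision = n_gold_cand / n_cand if n_cand else math.nan
    sensitivity = n_gold_cand / n_gold_tested if n_gold_tested else math.nan
    odds, p = _fisher(n_gold_cand, n_cand, n_gold_tested, n_tested, alternative)
    return BenchmarkResult(
        cohort=cohort or (df["cohort"].iloc[0] if "cohort" in df else ""),
        n_tested=n_tested,
        n_gold_tested=n_gold_tested,
        n_candidates=n_cand,
        n_gold_candidates=n_gold_cand,
        precision=precision,
        sensitivity=sensitivity,
        odds_ratio=odds,
        fisher_p=p,
        no_candidates=(n_cand == 0),
    )


def pool_cohorts(
    predictions: pd.DataFrame,
    gold: Iterable[str],
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    strict: bool = True,
    alternative: str = "two-sided",
) -> BenchmarkResult:
    """Pool all cohorts/methods: a gene is a candidate if it passes the cutoff
    in at least one cohort; tested genes are the union over cohorts."""
    if predictions.empty:
        raise ValueError("empty prediction set")
    gold = set(gold)
    tested = set(predictions["gene_id"])
    passing = (
        predictions["q_value"] < q_cutoff
        if strict
        else predictions["q_value"] <= q_cutoff
    )
    candidates = set(predictions.loc[passing, "gene_id"])
    n_tested = len(tested)
    n_gold_tested = len(gold & tested)
    n_cand = len(candidates)
    n_gold_cand = len(gold & candidates)
    odds, p = _fisher(n_gold_cand, n_cand, n_gold_tested, n_tested, alternative)
    return BenchmarkResult(
        cohort="pooled",
        n_tested=n_tested,
        n_gold_tested=n_gold_tested,
        n_candidates=n_cand,
        n_gold_candidates=n_gold_cand,
        precision=n_gold_cand / n_cand if n_cand else math.nan,
        sensitivity=n_gold_cand / n_gold_tested if n_gold_tested else math.nan,
        odds_ratio=odds,
        fisher_p=p,
        no_candidates=(n_cand == 0),
    )
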