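"""End-to-end comparison pipeline and the statistics-from-counts path.

Two entry points produce the same :class:`ComparisonReport`:

* :func:`run_comparison` — evaluate two rule profiles on a cohort of visit
  records, tabulate each rule's 2×2 agreement table, and summarize;
* :func:`stats_from_counts` — start from already-tabulated per-rule counts
  (e.g. counts transcribed from a published study) and summarize only.

The published per-rule counts of the cloud-vs-local reminder comparison are
shipped as package data (``data/study_counts.csv``) and loadable with
:func:`study_counts`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    AgreementSummary,
    TwoByTwoTable,
    round_half_away,
    summarize,
    tabulate,
)
from .profiles import RuleProfile
from .records import PatientVisitRecord
from .rules import REMINDER_IDS, evaluate_all

__all__ = [
    "ComparisonReport",
    "run_comparison",
    "stats_from_counts",
    "study_counts",
    "report_to_dataframe",
    "CountsParseError",
]


class CountsParseError(ValueError):
    """A counts CSV row is malformed."""


@dataclass(frozen=True)
class ComparisonReport:
    """Per-rule agreement tables and summaries plus engine totals.

    ``total_first``/``total_second`` count all reminders delivered by each
    engine across the cohort: Σ(a+b) and Σ(a+c) over the per-rule tables.
    ``metadata`` records everything needed to re-run bit-identically.
    """

    tables: Mapping[int, TwoByTwoTable]
    summaries: Mapping[int, AgreementSummary]
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def total_first(self) -> int:
        return sum(t.a + t.b for t in self.tables.values())

    @property
    def total_second(self) -> int:
        return sum(t.a + t.c for t in self.tables.values())


def _rule_seeds(seed: int, n: int) -> List[int]:
    # Independent per-rule bootstrap streams derived from one user seed.
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_comparison(
    records: Sequence[PatientVisitRecord],
    profile_first: RuleProfile,
    profile_second: RuleProfile,
    replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ComparisonReport:
    """Evaluate both profiles on every record and summarize per-rule agreement."""
    if not records:
        raise ValueError("run_comparison requires at least one record")
    fired_first: Dict[int, List[bool]] = {rid: [] for rid in REMINDER_IDS}
    fired_second: Dict[int, List[bool]] = {rid: [] for rid in REMINDER_IDS}
    for record in records:
        for out in evaluate_all(record, profile_first):
            fired_first[out.reminder_id].append(out.fired)
        for out in evaluate_all(record, profile_second):
            fired_second[out.reminder_id].append(out.fired)

    seeds = _rule_seeds(seed, len(REMINDER_IDS))
    tables: Dict[int, TwoByTwoTable] = {}
    summaries: Dict[int, AgreementSummary] = {}
    for rid, rule_seed in zip(REMINDER_IDS, seeds):
        t = tabulate(fired_first[rid], fired_second[rid])
        tables[rid] = t
        summaries[rid] = summarize(t, replicates=replicates, alpha=alpha, seed=rule_seed)
    return ComparisonReport(
        tables=tables,
        summaries=summaries,
        metadata={
            "profile_first": profile_first.name,
            "profile_second": profile_second.name,
            "n_visits": len(records),
            "replicates": replicates,
            "alpha": alpha,
            "seed": seed,
        },
    )


def _counts_from_frame(df: pd.DataFrame, source: str) -> Dict[int, TwoByTwoTable]:
    required = ("reminder_id", "a", "b", "c", "d")
    missing = [col for col in required if col not in df.columns]
    if missing:
        raise CountsParseError(f"{source}: missing columns {missing}")
    tables: Dict[int, TwoByTwoTable] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rid = int(row.reminder_id)
            table = TwoByTwoTable(int(row.a), int(row.b), int(row.c), int(row.d))
        except (TypeError, ValueError) as exc:
            raise CountsParseError(f"{source}: row {row_no}: {exc}") from exc
        if rid in tables:
            raise CountsParseError(f"{source}: row {row_no}: duplicate reminder_id {rid}")
        tables[rid] = table
    return tables


def stats_from_counts(
    counts: str | Path | pd.DataFrame,
    replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ComparisonReport:
    """Build a report from per-rule 2×2 counts (CSV path or DataFrame).

    The CSV needs columns ``reminder_id, a, b, c, d`` (a = both engines
    fired, b = first only, c = second only, d = neither).
    """
    if isinstance(counts, pd.DataFrame):
        df, source = counts, "<dataframe>"
    else:
        source = str(counts)
        try:
            df = pd.read_csv(counts)
        except (pd.errors.ParserError, ValueError) as exc:
            raise CountsParseError(f"{source}: {exc}") from exc
    tables = _counts_from_frame(df, source)
    seeds = _rule_seeds(seed, len(tables))
    summaries = {
        rid: summarize(tables[rid], replicates=replicates, alpha=alpha, seed=s)
        for rid, s in zip(sorted(tables), seeds)
    }
    return ComparisonReport(
        tables=tables,
        summaries=summaries,
        metadata={
            "source": source,
            "replicates": replicates,
            "alpha": alpha,
            "seed": seed,
        },
    )


def study_counts() -> pd.DataFrame:
    """The published per-rule counts of the cloud-vs-local comparison (n=405)."""
    text = resources.files("reminder_agreement.data").joinpath("study_counts.csv").read_text("utf-8")
    return pd.read_csv(io.StringIO(text))


def report_to_dataframe(report: ComparisonReport, ndigits: Optional[int] = 2) -> pd.DataFrame:
    """Flatten a report into a table of counts and statistics.

    With ``ndigits`` set (default 2, the usual presentation precision)
    statistics are rounded half-away-from-zero; pass ``None`` for full
    precision.
    """

    def fmt(x: Optional[float]) -> Optional[float]:
        if x is None:
            return None
        return round_half_away(x, ndigits) if ndigits is not None else x

    rows = []
    for rid in sorted(report.tables):
        t = report.tables[rid]
        s = report.summaries[rid]
        rows.append(
            {
                "reminder_id": rid,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "n": t.n,
                "p0": fmt(s.p0),
                "kappa": fmt(s.kappa),
                "bias_index": fmt(s.bias_index),
                "prevalence_index": fmt(s.prevalence_index),
                "pabak": fmt(s.pabak),
                "ci_low": fmt(s.ci_low),
                "ci_high": fmt(s.ci_high),
                "band": s.band,
            }
        )
    return pd.DataFrame(rows)
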