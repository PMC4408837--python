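"""Span scoring and session summaries.

The task's performance measure is the *span*: the number of consecutive
correct responses from the start of a trial — the count of corrected
responses before the first mistake, or the item ceiling when no mistake is
made.  The forced first touch (step 1 shows a single stimulus) counts, so
span lies in ``[1, max_items]`` for every trial with at least one response.

Summaries aggregate spans per (stimulus category x condition x valence) cell
of the completed session, mirroring the group-table layout of the published
studies: mean and sample SD (n - 1 denominator) of trial spans plus the mean
response latency (response timestamp minus the matching display timestamp).
Cells with no trials are absent rather than zero-filled.  Scoring is a pure
function of the event log: re-scoring a stored JSONL file reproduces the
summary exactly.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd

from .engine import SessionLog, iter_trial_events


class ScoringError(ValueError):
    pass


class EndedBy(str, enum.Enum):
    mistake = "mistake"
    ceiling = "ceiling"


@dataclass(frozen=True)
class TrialLog:
    """One completed trial: its responses, span, and how it ended."""

    trial_index: int
    condition: str
    valence: str
    category: str
    responses: tuple[tuple[int, bool, int], ...]  # (chosen_location, correct, timestamp_ms)
    latencies_ms: tuple[int, ...]  # display-to-response latency per response
    span: int
    ended_by: EndedBy


@dataclass(frozen=True)
class CellStats:
    n_trials: int
    mean_span: float
    sd_span: float  # NaN when n_trials < 2
    mean_rt_ms: float


@dataclass
class SessionSummary:
    """Per-cell and overall span statistics for one completed session."""

    label: str
    max_items: int
    overall: CellStats
    cells: dict[tuple[str, str, str], CellStats] = field(default_factory=dict)
    n_excluded: int = 0  # trials with no valid response (invalid touches only)


def trial_span(trial: TrialLog) -> int:
    """Count of consecutive correct responses from the start of the trial."""
    if not trial.responses:
        raise ScoringError(f"trial {trial.trial_index} has no responses")
    span = 0
    for _, correct, _ in trial.responses:
        if not correct:
            break
        span += 1
    return span


def session_trials(log: SessionLog) -> list[TrialLog]:
    """Reconstruct per-trial records from a complete session log.

    Raises :class:`ScoringError` on a truncated log (missing ``trial_end`` or
    ``session_end`` events), listing what is missing.
    """
    if not any(e["type"] == "session_end" for e in log.events):
        raise ScoringError("truncated log: missing session_end event")
    trials: list[TrialLog] = []
    for group in iter_trial_events(log):
        end = group[-1]
        if end["type"] != "trial_end":
            raise ScoringError(
                f"truncated log: trial {group[0].get('trial_index')} has no trial_end")
        responses: list[tuple[int, bool, int]] = []
        latencies: list[int] = []
        last_display_ts: Optional[int] = None
        for ev in group:
            if ev["type"] == "display":
                last_display_ts = ev["timestamp_ms"]
            elif ev["type"] == "response":
                responses.append(
                    (ev["chosen_location"], ev["correct"], ev["timestamp_ms"]))
                if last_display_ts is None:
                    raise ScoringError(
                        f"truncated log: response without display in trial {ev['trial_index']}")
                latencies.append(ev["timestamp_ms"] - last_display_ts)
        trials.append(TrialLog(
            trial_index=end["trial_index"],
            condition=end["condition"],
            valence=end["valence"],
            category=end["category"],
            responses=tuple(responses),
            latencies_ms=tuple(latencies),
            span=end["span"],
            ended_by=EndedBy(end["ended_by"]),
        ))
    return trials


def summarize_session(log: SessionLog, label: str = "session") -> SessionSummary:
    """Per-cell mean/SD of trial spans and mean response latency.

    Trials without any valid response are excluded from span statistics and
    counted in ``n_excluded``.  The overall mean equals the trial-count
    weighted mean of the cell means (the cells partition the trials).
    """
    trials = session_trials(log)
    scored = [t for t in trials if t.responses]
    n_excluded = len(trials) - len(scored)
    if not scored:
        raise ScoringError("no scorable trials in session")
    max_items = int(log.header.get("config", {}).get("max_items", max(t.span for t in scored)))

    df = pd.DataFrame({
        "category": [t.category for t in scored],
        "condition": [t.condition for t in scored],
        "valence": [t.valence for t in scored],
        "span": [trial_span(t) for t in scored],
        "mean_rt": [sum(t.latencies_ms) / len(t.latencies_ms) for t in scored],
    })

    def stats(sub: pd.DataFrame) -> CellStats:
        return CellStats(
            n_trials=len(sub),
            mean_span=float(sub["span"].mean()),
            sd_span=float(sub["span"].std(ddof=1)) if len(sub) > 1 else math.nan,
            mean_rt_ms=float(sub["mean_rt"].mean()),
        )

    cells = {
        (cat, cond, val): stats(sub)
        for (cat, cond, val), sub in df.groupby(["category", "condition", "valence"], sort=True)
    }
    return SessionSummary(
        label=label,
        max_items=max_items,
        overall=stats(df),
        cells=cells,
        n_excluded=n_excluded,
    )


_CSV_COLUMNS = ["group_label", "stimulus_category", "condition", "valence",
                "n", "mean_span", "sd_span", "mean_rt_ms"]


def export_summary(summary: SessionSummary) -> str:
    """RFC 4180 CSV, one row per non-empty cell, stable column and row order."""
    rows = []
    for (cat, cond, val), cs in sorted(summary.cells.items()):
        rows.append({
            "group_label": summary.label,
            "stimulus_category": cat,
            "condition": cond,
            "valence": val,
            "n": cs.n_trials,
            "mean_span": cs.mean_span,
            "sd_span": cs.sd_span,
            "mean_rt_ms": cs.mean_rt_ms,
        })
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6f", lineterminator="\r\n")
    return buf.getvalue()


def summary_report(summary: SessionSummary) -> str:
    """Human-readable companion report with ``M (SD)`` cells."""
    lines = [f"Session: {summary.label}  (span ceiling {summary.max_items})",
             f"Overall: {_msd(summary.overall)}  over {summary.overall.n_trials} trials"]
    if summary.n_excluded:
        lines.append(f"Excluded (no valid response): {summary.n_excluded}")
    for (cat, cond, val), cs in sorted(summary.cells.items()):
        lines.append(f"  {cat:>10} | {cond:>6} | {val:>8} : {_msd(cs)}  n={cs.n_trials}")
    return "\n".join(lines) + "\n"


def _msd(cs: CellStats) -> str:
    sd = "-" if math.isnan(cs.sd_span) else f"{cs.sd_span:.2f}"
    return f"{cs.mean_span:.2f} ({sd})"


def summary_to_dict(summary: SessionSummary) -> dict[str, Any]:
    """JSON-ready document form of a summary."""
    return {
        "label": summary.label,
        "max_items": summary.max_items,
        "n_excluded": summary.n_excluded,
        "overall": vars(summary.overall),
        "cells": [
            {"stimulus_category": cat, "condition": cond, "valence": val, **vars(cs)}
            for (cat, cond, val), cs in sorted(summary.cells.items())
        ],
    }
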