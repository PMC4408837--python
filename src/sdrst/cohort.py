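"""Cohort simulation: groups of capacity agents through the engine.

A cohort is ``n_subjects`` simulated participants whose working-memory
parameters are drawn per subject — capacity ``m`` from an integer-rounded
normal clipped at 0, lapse rate ``eps`` from a normal truncated to [0, 1] —
each running one full session.  Group statistics weight subjects equally
(mean of subject means, never trial-pooled across subjects), the standard
convention for group tables in behavioural studies, and group contrasts are
nonparametric: subject-level bootstrap of the difference in group means with
percentile confidence intervals.

The cohort machinery reproduces the *shape* of the published group tables
(groups x stimulus type / condition / valence margins) from simulated data;
condition and valence effects are not built into the agent model.  An
optional, explicitly illustrative ``varied_m_bonus`` can raise capacity in
the varied condition to show the direction of the published condition
effect; it makes no mechanistic claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agents import AgentParams, CapacityAgent
from .config import Condition, TaskConfig
from .engine import run_with_agent
from .scoring import SessionSummary, summarize_session

Cell = Union[str, tuple[str, str]]
#: A marginal cell: "overall", or ("category"|"condition"|"valence", value).


@dataclass(frozen=True)
class CohortSpec:
    """One simulated group: its size, parameter distribution, task and seed."""

    group_label: str
    n_subjects: int
    m_mean: float
    m_sd: float = 0.0
    eps_mean: float = 0.0
    eps_sd: float = 0.0
    rt_mean_ms: float = 800.0
    rt_sd_ms: float = 250.0
    varied_m_bonus: int = 0  # illustrative capacity boost in the varied condition
    config: Optional[TaskConfig] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.m_sd < 0 or self.eps_sd < 0:
            raise ValueError("distribution sd must be non-negative")
        if not 0.0 <= self.eps_mean <= 1.0:
            raise ValueError("eps_mean must lie in [0, 1]")
        if self.config is None:
            raise ValueError("config is required")


@dataclass
class CohortResults:
    spec: CohortSpec
    subject_params: list[AgentParams]
    subject_summaries: list[SessionSummary]
    subject_trials: list[pd.DataFrame] = field(default_factory=list)


def _draw_params(spec: CohortSpec, rng: np.random.Generator) -> AgentParams:
    m = float(spec.m_mean) if spec.m_sd == 0 else rng.normal(spec.m_mean, spec.m_sd)
    m_int = max(0, int(round(m)))
    if spec.config.condition is Condition.varied:
        m_int += spec.varied_m_bonus
    if spec.eps_sd == 0:
        eps = float(np.clip(spec.eps_mean, 0.0, 1.0))
    else:
        a = (0.0 - spec.eps_mean) / spec.eps_sd
        b = (1.0 - spec.eps_mean) / spec.eps_sd
        eps = float(sps.truncnorm.ppf(rng.random(), a, b,
                                      loc=spec.eps_mean, scale=spec.eps_sd))
    return AgentParams(m=m_int, eps=eps,
                       rt_mean_ms=spec.rt_mean_ms, rt_sd_ms=spec.rt_sd_ms)


def simulate_cohort(spec: CohortSpec) -> CohortResults:
    """Run ``n_subjects`` independent sessions; fully determined by ``spec.seed``."""
    params_list: list[AgentParams] = []
    summaries: list[SessionSummary] = []
    trials: list[pd.DataFrame] = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), i]))
        params = _draw_params(spec, rng)
        cfg = spec.config.model_copy(update={"rng_seed": int(rng.integers(2**31))})
        agent_seed = int(rng.integers(2**31))
        log = run_with_agent(cfg, CapacityAgent(params), agent_seed)
        label = f"{spec.group_label}/s{i:03d}"
        summary = summarize_session(log, label=label)
        df = pd.DataFrame(
            [
                {"subject": i, "category": cat, "condition": cond, "valence": val,
                 "n": cs.n_trials, "mean_span": cs.mean_span}
                for (cat, cond, val), cs in summary.cells.items()
            ]
        )
        params_list.append(params)
        summaries.append(summary)
        trials.append(df)
    return CohortResults(spec=spec, subject_params=params_list,
                         subject_summaries=summaries, subject_trials=trials)


def subject_cell_means(results: CohortResults, cell: Cell) -> np.ndarray:
    """Per-subject trial-pooled mean span within one marginal cell.

    ``cell`` is ``"overall"`` or a ``(dimension, value)`` pair with dimension
    one of ``category``, ``condition``, ``valence``.  Raises ``KeyError`` if
    no subject has trials in the cell.
    """
    means = []
    for df in results.subject_trials:
        if cell == "overall":
            sub = df
        else:
            dim, value = cell
            if dim not in ("category", "condition", "valence"):
                raise KeyError(f"unknown cell dimension {dim!r}")
            sub = df[df[dim] == value]
        if len(sub):
            means.append(float(np.average(sub["mean_span"], weights=sub["n"])))
    if not means:
        raise KeyError(f"cell {cell!r} has no trials in cohort {results.spec.group_label!r}")
    return np.asarray(means)


def group_cell_stats(results: CohortResults, cell: Cell) -> tuple[float, float, int]:
    """Group mean, SD across subjects (ddof=1; NaN if one subject), and n."""
    means = subject_cell_means(results, cell)
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else float("nan")
    return float(means.mean()), sd, len(means)


# geometric ("none"-valence) trials appear under their stimulus-type column,
# not as an emotional valence
_VALENCE_ORDER = ["negative", "positive", "neutral"]
_CATEGORY_ORDER = ["geometric", "iaps_scene", "face", "mixed"]


def cohort_table(results: Sequence[CohortResults]) -> pd.DataFrame:
    """Group x (stimulus type, condition, valence) table of ``M (SD)`` strings.

    Rows are cohorts; columns are the marginal cells present in any cohort,
    in the layout of the published group tables.  Empty cells render as "-".
    """
    if not results:
        raise ValueError("need at least one cohort")
    cats, conds, vals = set(), set(), set()
    for r in results:
        for df in r.subject_trials:
            cats.update(df["category"])
            conds.update(df["condition"])
            vals.update(df["valence"])
    columns: list[tuple[str, str]] = []
    columns += [("Type of stimuli", c) for c in _CATEGORY_ORDER if c in cats]
    columns += [("Task condition", c.capitalize()) for c in ("unique", "varied") if c in conds]
    columns += [("Emotional valence", v.capitalize()) for v in _VALENCE_ORDER if v in vals]

    def cell_key(col: tuple[str, str]) -> Cell:
        section, value = col
        if section == "Type of stimuli":
            return ("category", value)
        if section == "Task condition":
            return ("condition", value.lower())
        return ("valence", value.lower())

    rows = {}
    for r in results:
        row = {}
        for col in columns:
            try:
                mean, sd, n = group_cell_stats(r, cell_key(col))
            except KeyError:
                row[col] = "-"
                continue
            sd_str = "-" if np.isnan(sd) else f"{sd:.2f}"
            row[col] = f"{mean:.2f} ({sd_str})"
        rows[r.spec.group_label] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(columns)
    return table


def bootstrap_group_diff(
    a: CohortResults,
    b: CohortResults,
    cell: Cell,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Subject-level bootstrap contrast of two cohorts within one cell.

    Resamples subjects with replacement within each group; returns the point
    estimate (mean_a - mean_b) and the 2.5/97.5 percentile interval of the
    bootstrap distribution.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    xa = subject_cell_means(a, cell)
    xb = subject_cell_means(b, cell)
    point = float(xa.mean() - xb.mean())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    ia = rng.integers(len(xa), size=(n_boot, len(xa)))
    ib = rng.integers(len(xb), size=(n_boot, len(xb)))
    diffs = xa[ia].mean(axis=1) - xb[ib].mean(axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return point, (float(lo), float(hi))
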