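"""Internal-consistency statistics and stepwise item refinement.

This module implements the statistical filter that reduces a draft survey
bank to a final instrument:

1. *Discrimination*: a Pearson chi-squared test of independence per item
   compares response distributions between the PPID and non-PPID groups;
   items that do not differ (p >= ``p_drop``) are removed as not specific to
   the disease.
2. *Redundancy*: within the PPID group, same-domain item pairs correlating
   above ``r_merge`` are deemed to record the same information and are
   merged (default: element-wise maximum of their scores — the worst-case
   reading of two near-identical questions).
3. *Item-total pruning*: items whose corrected item-total correlation falls
   below ``r_prune`` are removed one at a time, always removing the item
   whose removal most increases Cronbach's alpha, until no such removal
   helps.

The refinement report records every action with its justifying statistic
and the alpha trajectory, and flags whether the final alpha clears the
``alpha_adequate`` internal-consistency criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import DOMAINS, DomainWeights, InstrumentDefinition

__all__ = [
    "RefinementConfig",
    "RefinementStep",
    "RefinementReport",
    "DegenerateDataError",
    "cronbach_alpha",
    "item_total_correlations",
    "inter_item_matrix",
    "chi2_discrimination",
    "Chi2Result",
    "compute_domain_weights",
    "refine_items",
]

PPID_GROUP = "ppid"
CONTROL_GROUP = "non-ppid"


class DegenerateDataError(ValueError):
    """The data admit no defined value for the requested statistic."""


# ---------------------------------------------------------------------------
# Internal consistency


def cronbach_alpha(scores: pd.DataFrame) -> float:
    """Cronbach's alpha of an items-in-columns score matrix.

    alpha = k/(k-1) * (1 - sum_i var_i / var_total), with unbiased (n-1)
    sample variances.  Alpha is at most 1 and may be negative.
    """
    scores = _as_frame(scores)
    k = scores.shape[1]
    if k < 2:
        raise DegenerateDataError("alpha needs at least 2 items")
    if scores.shape[0] < 3:
        raise DegenerateDataError("alpha needs at least 3 respondents")
    if scores.isna().any().any():
        raise DegenerateDataError("alpha requires a complete score matrix")
    total_var = scores.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("total-score variance is zero; alpha undefined")
    item_var = scores.var(ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def item_total_correlations(scores: pd.DataFrame) -> pd.Series:
    """Corrected item-total correlations.

    For each item: the Pearson correlation between that item and the sum of
    all *other* items.  A zero-variance item yields NaN and a warning.
    """
    scores = _as_frame(scores)
    if scores.shape[1] < 2:
        raise DegenerateDataError("item-total correlation needs at least 2 items")
    total = scores.sum(axis=1)
    out = {}
    for col in scores.columns:
        item = scores[col]
        rest = total - item
        if item.var(ddof=1) == 0 or rest.var(ddof=1) == 0:
            warnings.warn(
                f"item {col!r}: zero variance; corrected item-total "
                "correlation undefined",
                stacklevel=2,
            )
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(item, rest)[0, 1])
    return pd.Series(out, name="corrected_item_total_r")


def inter_item_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson inter-item correlation matrix (unit diagonal, symmetric)."""
    scores = _as_frame(scores)
    zero_var = [c for c in scores.columns if scores[c].var(ddof=1) == 0]
    if zero_var:
        warnings.warn(
            f"zero-variance item(s) {zero_var}: correlations undefined",
            stacklevel=2,
        )
    corr = scores.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# Group discrimination


@dataclass(frozen=True)
class Chi2Result:
    """Pearson chi-squared test of independence for one item's table."""

    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    undefined: bool = False
    low_expected: bool = False

    def retain(self, p_threshold: float = 0.05) -> bool:
        """True when the item discriminates the groups at the threshold."""
        if self.undefined:
            return False
        return self.p_value < p_threshold


def chi2_discrimination(responses: Sequence, group: Sequence) -> Chi2Result:
    """Chi-squared test of item response distribution by group.

    A degenerate table (a single response category, or a single group) has
    no defined test; the result is flagged ``undefined`` for manual review.
    Expected counts below 5 trigger a warning but no category collapsing.
    """
    table = pd.crosstab(pd.Series(responses, name="response"), pd.Series(group, name="group"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        return Chi2Result(
            statistic=np.nan, df=0, p_value=np.nan, table=table, undefined=True
        )
    chi2, p, df, expected = stats.chi2_contingency(table.values, correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn(
            "chi-squared table has expected counts < 5; asymptotic p-value "
            "may be unreliable",
            stacklevel=2,
        )
    return Chi2Result(
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        table=table,
        low_expected=low,
    )


# ---------------------------------------------------------------------------
# Domain weights


def compute_domain_weights(ratings: Mapping[str, Sequence] | pd.DataFrame) -> DomainWeights:
    """Median importance rating per domain, cast to integer weights.

    Ratings are on a 1-5 importance scale.  The median uses the midpoint
    convention for even n, then rounds half-up to an integer weight (the
    published weights are integer importance levels).
    """
    if isinstance(ratings, pd.DataFrame):
        ratings = {c: ratings[c].dropna().tolist() for c in ratings.columns}
    weights = {}
    for domain, values in ratings.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            raise DegenerateDataError(f"domain {domain!r}: no importance ratings")
        if ((vals < 1) | (vals > 5)).any():
            raise ValueError(f"domain {domain!r}: importance ratings must be in 1..5")
        med = float(np.median(vals))
        weights[domain] = int(np.floor(med + 0.5))  # round half-up
    return DomainWeights(weights)


# ---------------------------------------------------------------------------
# Stepwise refinement


@dataclass(frozen=True)
class RefinementConfig:
    """Thresholds and policies for the refinement procedure."""

    p_drop: float = 0.05
    r_merge: float = 0.60
    r_prune: float = 0.30
    alpha_adequate: float = 0.70
    merge_method: str = "max"  # {"max", "mean", "first"}
    stages: tuple[str, ...] = ("chi2", "merge", "prune")

    def __post_init__(self) -> None:
        for name in ("p_drop", "r_merge", "r_prune", "alpha_adequate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.merge_method not in ("max", "mean", "first"):
            raise ValueError(f"unknown merge method {self.merge_method!r}")
        if set(self.stages) - {"chi2", "merge", "prune"}:
            raise ValueError(f"unknown stage in {self.stages}")


@dataclass(frozen=True)
class RefinementStep:
    """One action of the refinement ledger."""

    stage: str
    action: str  # retain | drop-nondiscriminating | merge-redundant | drop-low-item-total | manual-review
    items: tuple[str, ...]
    statistic: Mapping[str, float] = field(default_factory=dict)
    alpha_before: float | None = None
    alpha_after: float | None = None

    def describe(self) -> str:
        stat = ", ".join(f"{k}={v:.4g}" for k, v in self.statistic.items())
        alpha = ""
        if self.alpha_before is not None and self.alpha_after is not None:
            alpha = f"; alpha {self.alpha_before:.4f} -> {self.alpha_after:.4f}"
        return f"[{self.stage}] {self.action}: {', '.join(self.items)} ({stat}){alpha}"


@dataclass
class RefinementReport:
    """Ordered ledger of retain/drop/merge actions with the alpha trajectory."""

    steps: list[RefinementStep]
    retained: tuple[str, ...]
    final_alpha: float
    alpha_trajectory: tuple[float, ...]
    alpha_adequate: bool
    config: RefinementConfig
    warnings: tuple[str, ...] = ()
    merged_scores: pd.DataFrame | None = None

    def dispositions(self) -> dict[str, str]:
        """Terminal disposition of every input item (each appears once)."""
        out: dict[str, str] = {}
        for step in self.steps:
            for item in step.items:
                if step.action == "merge-redundant":
                    out[item] = "merge-redundant"
                elif step.action.startswith("drop"):
                    out[item] = step.action
        for item in self.retained:
            for part in item.split("+"):
                out.setdefault(part, "retain")
        return out

    def summary(self) -> str:
        lines = [
            f"refinement: {len(self.dispositions())} input items -> "
            f"{len(self.retained)} retained",
        ]
        lines += [step.describe() for step in self.steps]
        lines.append(
            f"final alpha = {self.final_alpha:.4f} "
            f"({'adequate' if self.alpha_adequate else 'below'} "
            f"criterion alpha > {self.config.alpha_adequate})"
        )
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "final_alpha": self.final_alpha,
            "alpha_adequate": self.alpha_adequate,
            "alpha_trajectory": list(self.alpha_trajectory),
            "config": {
                "p_drop": self.config.p_drop,
                "r_merge": self.config.r_merge,
                "r_prune": self.config.r_prune,
                "alpha_adequate": self.config.alpha_adequate,
                "merge_method": self.config.merge_method,
                "stages": list(self.config.stages),
            },
            "steps": [
                {
                    "stage": s.stage,
                    "action": s.action,
                    "items": list(s.items),
                    "statistic": {k: float(v) for k, v in s.statistic.items()},
                    "alpha_before": s.alpha_before,
                    "alpha_after": s.alpha_after,
                }
                for s in self.steps
            ],
            "warnings": list(self.warnings),
        }


def _as_frame(scores) -> pd.DataFrame:
    if isinstance(scores, pd.DataFrame):
        return scores
    return pd.DataFrame(np.asarray(scores, dtype=float))


def _merge_columns(a: pd.Series, b: pd.Series, method: str) -> pd.Series:
    if method == "max":
        return pd.concat([a, b], axis=1).max(axis=1)
    if method == "mean":
        return (a + b) / 2.0
    return a  # "first"


def _stage_chi2(
    scores: pd.DataFrame,
    group: pd.Series,
    config: RefinementConfig,
    item_domain: Mapping[str, str],
    steps: list[RefinementStep],
    notes: list[str],
) -> pd.DataFrame:
    drop = []
    for col in scores.columns:
        res = chi2_discrimination(scores[col], group)
        stat = {"chi2": res.statistic, "df": res.df, "p": res.p_value}
        if res.undefined:
            steps.append(RefinementStep("chi2", "manual-review", (col,), stat))
            notes.append(
                f"item {col!r}: degenerate contingency table, chi-squared "
                "undefined; retained pending manual review"
            )
        elif res.retain(config.p_drop):
            steps.append(RefinementStep("chi2", "retain", (col,), stat))
        else:
            steps.append(RefinementStep("chi2", "drop-nondiscriminating", (col,), stat))
            drop.append(col)
    return scores.drop(columns=drop)


def _stage_merge(
    ppid_scores: pd.DataFrame,
    config: RefinementConfig,
    item_domain: Mapping[str, str],
    steps: list[RefinementStep],
) -> pd.DataFrame:
    while True:
        if ppid_scores.shape[1] < 2:
            return ppid_scores
        corr = ppid_scores.corr(method="pearson")
        best: tuple[float, str, str] | None = None
        cols = list(ppid_scores.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                if item_domain.get(a) != item_domain.get(b):
                    continue
                r = corr.loc[a, b]
                if np.isnan(r) or r <= config.r_merge:
                    continue
                if best is None or r > best[0]:
                    best = (float(r), a, b)
        if best is None:
            return ppid_scores
        r, a, b = best
        merged_id = f"{a}+{b}"
        merged = _merge_columns(ppid_scores[a], ppid_scores[b], config.merge_method)
        ppid_scores = ppid_scores.drop(columns=[a, b])
        ppid_scores[merged_id] = merged
        item_domain[merged_id] = item_domain.get(a, "")  # type: ignore[index]
        steps.append(
            RefinementStep("merge", "merge-redundant", (a, b), {"r": r})
        )


def _stage_prune(
    ppid_scores: pd.DataFrame,
    config: RefinementConfig,
    steps: list[RefinementStep],
    trajectory: list[float],
) -> pd.DataFrame:
    while ppid_scores.shape[1] > 2:
        alpha_now = cronbach_alpha(ppid_scores)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_it = item_total_correlations(ppid_scores)
        candidates = [
            c for c in ppid_scores.columns
            if np.isnan(r_it[c]) or r_it[c] < config.r_prune
        ]
        if not candidates:
            break
        # among low-r candidates, remove the one whose removal most raises alpha
        gains: list[tuple[float, float, str]] = []
        for c in candidates:
            try:
                a_without = cronbach_alpha(ppid_scores.drop(columns=[c]))
            except DegenerateDataError:
                continue
            r_c = r_it[c] if not np.isnan(r_it[c]) else -np.inf
            gains.append((a_without - alpha_now, -r_c, c))
        if not gains:
            break
        # ties on alpha gain break toward the lowest item-total r, then item order
        best_gain = max(g[0] for g in gains)
        if best_gain <= 0:
            break
        tied = [g for g in gains if g[0] == best_gain]
        tied.sort(key=lambda g: (-g[1], list(ppid_scores.columns).index(g[2])))
        _, _, victim = tied[0]
        a_after = cronbach_alpha(ppid_scores.drop(columns=[victim]))
        steps.append(
            RefinementStep(
                "prune",
                "drop-low-item-total",
                (victim,),
                {"r": float(r_it[victim])},
                alpha_before=alpha_now,
                alpha_after=a_after,
            )
        )
        ppid_scores = ppid_scores.drop(columns=[victim])
        trajectory.append(a_after)
    return ppid_scores


def refine_items(
    instrument: InstrumentDefinition,
    scores: pd.DataFrame,
    group: Sequence,
    config: RefinementConfig | None = None,
) -> RefinementReport:
    """Run the staged item-refinement procedure on a scored cohort.

    ``scores`` holds raw (unweighted) item scores, one column per instrument
    item; ``group`` labels each row ``"ppid"`` or ``"non-ppid"``.  The
    chi-squared discrimination stage uses both groups; the redundancy and
    item-total stages, and all alpha values, use the PPID rows only.
    """
    config = config or RefinementConfig()
    scores = _as_frame(scores).copy()
    group = pd.Series(list(group), index=scores.index)
    missing = [i for i in instrument.item_ids if i not in scores.columns]
    if missing:
        raise ValueError(f"score matrix lacks instrument item(s): {missing}")
    if not set(group.unique()) >= {PPID_GROUP, CONTROL_GROUP}:
        raise ValueError(
            f"both groups ({PPID_GROUP!r}, {CONTROL_GROUP!r}) must be present"
        )
    scores = scores[list(instrument.item_ids)]
    item_domain: dict[str, str] = {it.item_id: it.domain for it in instrument.items}

    steps: list[RefinementStep] = []
    notes: list[str] = []
    current = scores
    ppid_current: pd.DataFrame | None = None
    trajectory: list[float] = []

    for stage in config.stages:
        if stage == "chi2":
            current = _stage_chi2(current, group, config, item_domain, steps, notes)
            ppid_current = current.loc[group == PPID_GROUP]
            trajectory.append(cronbach_alpha(ppid_current))
        else:
            if ppid_current is None:
                ppid_current = current.loc[group == PPID_GROUP]
                trajectory.append(cronbach_alpha(ppid_current))
            if stage == "merge":
                ppid_current = _stage_merge(ppid_current, config, item_domain, steps)
                trajectory.append(cronbach_alpha(ppid_current))
            elif stage == "prune":
                ppid_current = _stage_prune(ppid_current, config, steps, trajectory)

    assert ppid_current is not None
    if ppid_current.shape[1] < 2:
        raise DegenerateDataError(
            "refinement left fewer than 2 items; no instrument remains"
        )
    retained = tuple(ppid_current.columns)
    retained_domains = set()
    for item in retained:
        retained_domains.add(item_domain.get(item.split("+")[0], ""))
    emptied = [d for d in instrument.domains if d not in retained_domains]
    if emptied:
        notes.append(f"refinement emptied domain(s): {', '.join(emptied)}")
    final_alpha = cronbach_alpha(ppid_current)
    return RefinementReport(
        steps=steps,
        retained=retained,
        final_alpha=final_alpha,
        alpha_trajectory=tuple(trajectory),
        alpha_adequate=final_alpha > config.alpha_adequate,
        config=config,
        warnings=tuple(notes),
        merged_scores=ppid_current,
    )
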