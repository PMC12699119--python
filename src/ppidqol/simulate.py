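"""Synthetic owner-response cohorts with known latent structure.

Responses are generated from a latent-severity model: each horse carries

    theta = b0 + b_ppid * PPID + b_chronic * chronic + b_age * z(age) + N(0,1)

and each item i maps an underlying draw ``u_i = a_i * theta + eps_i`` (eps
standard normal) onto its ordered options through fixed cutpoints — a
graded-response / proportional-odds style mechanism that makes every item's
response distribution stochastically increasing in theta by construction.

Planted structure makes every stage of the development pipeline testable:

* *non-discriminating* items ignore theta entirely (pure noise, identical
  conditional distributions in both groups) — chi-squared fodder;
* *noise* items differ between groups but carry zero loading, so within the
  PPID group they are uncorrelated with everything — item-total fodder;
* *redundant* items copy another item's underlying draw plus small noise —
  redundancy-merge fodder.

The owner's global QoL rating (1 very good .. 5 very poor) is an ordinal
anchor increasing in theta, and the rater model shares each subject's true
score between raters/occasions with configurable rater offsets and
occasion noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .instrument import (
    DOMAINS,
    InstrumentDefinition,
    ItemDefinition,
    Option,
    DomainWeights,
    ResponseRecord,
    UNOBSERVABLE_LABEL,
    load_instrument,
    max_weighted_score,
)

__all__ = [
    "RaterParams",
    "SimulationParams",
    "CohortTable",
    "RaterStudy",
    "simulate_cohort",
    "simulate_raters",
    "default_params",
    "final_tool_params",
    "planted_bank",
    "planted_bank_params",
]

# Reference response distributions (best -> worst option) for an average
# non-PPID horse, by number of regular options; most horses sit at the
# favourable end of each scale, as owner-reported QoL data do.
_BASELINE_PROBS: dict[int, tuple[float, ...]] = {
    2: (0.80, 0.20),
    3: (0.65, 0.25, 0.10),
    4: (0.62, 0.22, 0.10, 0.06),
    5: (0.52, 0.24, 0.12, 0.08, 0.04),
}

_MEDS_NONE_LABEL = "My horse does not receive any meds/suppl."


@dataclass(frozen=True)
class RaterParams:
    """Rater-agreement noise model.

    ``subject_sd`` draws subject true scores from N(0, subject_sd^2); when
    None, true scores come from the cohort's computed HRQoL values.
    ``offset_sd`` is the sd of per-rater systematic offsets (hurts absolute
    agreement only); ``occasion_sd`` the within-rater measurement noise.
    """

    offset_sd: float = 0.02
    occasion_sd: float = 0.045
    subject_sd: float | None = None


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; the seed fully determines the output."""

    instrument: str = "ppid-survey-37"
    n_ppid: int = 343
    n_control: int = 269
    age_mean_ppid: float = 24.34
    age_sd_ppid: float = 6.60
    age_mean_control: float = 19.84
    age_sd_control: float = 5.16
    beta_0: float = 0.0
    beta_ppid: float = 0.70
    beta_chronic: float = 0.45
    beta_age: float = 0.30  # per pooled SD of age
    loading: float = 0.80
    item_loadings: Mapping[str, float] = field(default_factory=dict)
    nondiscriminating: tuple[str, ...] = ()
    noise_items: tuple[str, ...] = ()
    noise_group_shift: float = 0.8
    # (redundant item, source item, extra-noise sd)
    redundant_pairs: tuple[tuple[str, str, float], ...] = ()
    unobservable_prob: float = 0.03
    meds_none_prob_ppid: float = 0.05
    meds_none_prob_control: float = 0.25
    qol_loading: float = 0.70
    qol_cutpoints: tuple[float, ...] = (0.45, 2.36, 3.16, 3.88)
    chronic_prob_ppid: float = 0.353
    chronic_prob_control: float = 0.480
    treated_prob: float = 0.869
    years_diagnosed_median: float = 2.0
    years_diagnosed_sigma: float = 1.328  # log-scale sd matching IQR ratio 6:1
    rater: RaterParams = field(default_factory=RaterParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ppid < 1 or self.n_control < 1:
            raise ValueError("both group sizes must be positive")
        if any(sd <= 0 for sd in (self.age_sd_ppid, self.age_sd_control)):
            raise ValueError("age standard deviations must be positive")
        if not 0 <= self.unobservable_prob < 1:
            raise ValueError("unobservable_prob must lie in [0, 1)")
        if list(self.qol_cutpoints) != sorted(self.qol_cutpoints) or len(
            set(self.qol_cutpoints)
        ) != len(self.qol_cutpoints):
            raise ValueError("qol_cutpoints must be strictly increasing")

    def loading_of(self, item_id: str) -> float:
        return float(self.item_loadings.get(item_id, self.loading))


# Table-3 style marginal covariate frequencies (PPID, non-PPID).
_BREED_LEVELS = ("native", "warmblood", "thoroughbred", "arabian", "draught", "cross", "other")
_BREED_P_PPID = (0.481, 0.099, 0.093, 0.064, 0.044, 0.085, 0.134)
_BREED_P_CTRL = (0.442, 0.167, 0.164, 0.041, 0.059, 0.067, 0.060)
# sex is binary (mare/gelding): stallions are <1% of aged cohorts and a
# level with a couple of observations cannot support the factor-by-covariate
# interaction design, so their mass folds into the gelding level
_SEX_LEVELS = ("mare", "gelding")
_SEX_P_PPID = (0.437, 0.563)
_SEX_P_CTRL = (0.353, 0.647)
_BC_LEVELS = (
    "very underweight",
    "slightly underweight",
    "ideal weight",
    "slightly overweight",
    "very overweight",
)
_BC_P_PPID = (0.038, 0.207, 0.533, 0.210, 0.012)
_BC_P_CTRL = (0.007, 0.071, 0.415, 0.470, 0.037)


def _normed(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    return arr / arr.sum()


@dataclass
class CohortTable:
    """Simulated cohort: one row per horse, item answers as option labels."""

    frame: pd.DataFrame
    instrument_name: str

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    def item_columns(self, instrument: InstrumentDefinition) -> list[str]:
        return [i for i in instrument.item_ids if i in self.frame.columns]

    def score_matrix(self, instrument: InstrumentDefinition) -> pd.DataFrame:
        """Raw (unweighted) per-item numeric scores, items in columns."""
        cols = {}
        for item in instrument.items:
            mapping = {o.label: o.score for o in item.all_options}
            cols[item.item_id] = self.frame[item.item_id].map(mapping)
        return pd.DataFrame(cols, index=self.frame.index)

    def records(self) -> list[ResponseRecord]:
        item_cols = [
            c
            for c in self.frame.columns
            if c
            not in (
                "horse_id",
                "group",
                "age",
                "breed",
                "sex",
                "body_condition",
                "chronic",
                "ppid",
                "treated",
                "years_diagnosed",
                "owner_global_qol",
                "theta",
            )
        ]
        covar_cols = [
            c for c in self.frame.columns if c not in item_cols + ["horse_id", "owner_global_qol"]
        ]
        out = []
        for _, row in self.frame.iterrows():
            out.append(
                ResponseRecord(
                    horse_id=str(row["horse_id"]),
                    answers={c: row[c] for c in item_cols},
                    owner_global_qol=int(row["owner_global_qol"]),
                    covariates={c: row[c] for c in covar_cols},
                )
            )
        return out


@dataclass
class RaterStudy:
    """Paired rating matrices for the two reliability designs."""

    inter: pd.DataFrame  # two raters, same occasion
    intra: pd.DataFrame  # one rater, two occasions


def _item_cutpoints(n_options: int) -> np.ndarray:
    probs = _BASELINE_PROBS[n_options]
    return norm.ppf(np.cumsum(probs[:-1]))


def _underlying_draws(
    instrument: InstrumentDefinition,
    params: SimulationParams,
    theta: np.ndarray,
    is_ppid: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Latent draw per item; redundant items copy their source's draw."""
    redundant = {item: (src, sd) for item, src, sd in params.redundant_pairs}
    u: dict[str, np.ndarray] = {}
    n = theta.size
    for item in instrument.items:
        iid = item.item_id
        if iid in redundant:
            continue
        eps = rng.standard_normal(n)
        if iid in params.nondiscriminating:
            u[iid] = eps
        elif iid in params.noise_items:
            u[iid] = params.noise_group_shift * is_ppid + eps
        else:
            u[iid] = params.loading_of(iid) * theta + eps
    for iid, (src, sd) in redundant.items():
        if src not in u:
            raise ValueError(
                f"redundant pair source {src!r} missing or itself redundant"
            )
        u[iid] = u[src] + sd * rng.standard_normal(n)
    return u


def simulate_cohort(
    params: SimulationParams | None = None,
    seed: int | None = None,
    instrument: InstrumentDefinition | None = None,
) -> CohortTable:
    """Generate a two-group owner-response cohort.

    ``seed`` overrides ``params.seed``; identical params + seed give
    byte-identical tables.
    """
    params = params or default_params()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    instrument = instrument or resolve_instrument(params.instrument)

    n = params.n_ppid + params.n_control
    is_ppid = np.concatenate(
        [np.ones(params.n_ppid, dtype=int), np.zeros(params.n_control, dtype=int)]
    )

    age = np.where(
        is_ppid == 1,
        rng.normal(params.age_mean_ppid, params.age_sd_ppid, size=n),
        rng.normal(params.age_mean_control, params.age_sd_control, size=n),
    )
    age = np.clip(age, 1.0, None).round(1)

    # standardize age against the theoretical pooled mixture of the two groups
    w = params.n_ppid / n
    pooled_mean = w * params.age_mean_ppid + (1 - w) * params.age_mean_control
    pooled_var = (
        w * (params.age_sd_ppid**2 + (params.age_mean_ppid - pooled_mean) ** 2)
        + (1 - w)
        * (params.age_sd_control**2 + (params.age_mean_control - pooled_mean) ** 2)
    )
    z_age = (age - pooled_mean) / np.sqrt(pooled_var)

    chronic = (
        rng.random(n)
        < np.where(is_ppid == 1, params.chronic_prob_ppid, params.chronic_prob_control)
    ).astype(int)
    treated = ((rng.random(n) < params.treated_prob) & (is_ppid == 1)).astype(int)
    years = np.where(
        is_ppid == 1,
        rng.lognormal(
            mean=np.log(params.years_diagnosed_median),
            sigma=params.years_diagnosed_sigma,
            size=n,
        ).round(1),
        np.nan,
    )

    breed = np.where(
        is_ppid == 1,
        rng.choice(_BREED_LEVELS, size=n, p=_normed(_BREED_P_PPID)),
        rng.choice(_BREED_LEVELS, size=n, p=_normed(_BREED_P_CTRL)),
    )
    sex = np.where(
        is_ppid == 1,
        rng.choice(_SEX_LEVELS, size=n, p=_normed(_SEX_P_PPID)),
        rng.choice(_SEX_LEVELS, size=n, p=_normed(_SEX_P_CTRL)),
    )
    body_condition = np.where(
        is_ppid == 1,
        rng.choice(_BC_LEVELS, size=n, p=_normed(_BC_P_PPID)),
        rng.choice(_BC_LEVELS, size=n, p=_normed(_BC_P_CTRL)),
    )

    theta = (
        params.beta_0
        + params.beta_ppid * is_ppid
        + params.beta_chronic * chronic
        + params.beta_age * z_age
        + rng.standard_normal(n)
    )

    u = _underlying_draws(instrument, params, theta, is_ppid.astype(float), rng)

    data: dict[str, object] = {
        "horse_id": [f"h{i:04d}" for i in range(1, n + 1)],
        "group": np.where(is_ppid == 1, "ppid", "non-ppid"),
        "ppid": is_ppid,
        "age": age,
        "breed": breed,
        "sex": sex,
        "body_condition": body_condition,
        "chronic": chronic,
        "treated": treated,
        "years_diagnosed": years,
    }

    # ordinal global-QoL anchor, increasing in theta: 1 very good .. 5 very poor
    v = params.qol_loading * theta + rng.standard_normal(n)
    qol = 1 + (v[:, None] > np.asarray(params.qol_cutpoints)[None, :]).sum(axis=1)
    data["owner_global_qol"] = qol.astype(int)

    for item in instrument.items:
        iid = item.item_id
        options = sorted(item.options, key=lambda o: o.score)
        cuts = _item_cutpoints(len(options))
        idx = (u[iid][:, None] > cuts[None, :]).sum(axis=1)
        labels = np.array([o.label for o in options], dtype=object)[idx]
        special = {o.label for o in item.special_options}
        if UNOBSERVABLE_LABEL in special and params.unobservable_prob > 0:
            mask = rng.random(n) < params.unobservable_prob
            labels = np.where(mask, UNOBSERVABLE_LABEL, labels)
        if _MEDS_NONE_LABEL in special:
            p_none = np.where(
                is_ppid == 1, params.meds_none_prob_ppid, params.meds_none_prob_control
            )
            mask = rng.random(n) < p_none
            labels = np.where(mask, _MEDS_NONE_LABEL, labels)
        data[iid] = labels

    frame = pd.DataFrame(data)
    return CohortTable(frame=frame, instrument_name=instrument.name)


def simulate_raters(
    params: SimulationParams | None = None,
    n_subjects: int = 8,
    subject_scores: Sequence[float] | None = None,
    seed: int | None = None,
) -> RaterStudy:
    """Generate paired rating matrices for the two reliability designs.

    Both raters (or occasions) observe the same subject true score.  Per-
    rater offsets perturb only the inter-rater matrix's column means; the
    intra-rater matrix shares a single observer so its offset cancels.
    """
    params = params or default_params()
    rp = params.rater
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if rp.subject_sd is not None:
        truth = rng.normal(0.0, rp.subject_sd, size=n_subjects)
    else:
        if subject_scores is None:
            raise ValueError(
                "subject_scores required when rater.subject_sd is None"
            )
        scores = np.asarray(subject_scores, dtype=float)
        if n_subjects > scores.size:
            raise ValueError("subset size exceeds available cohort scores")
        truth = rng.choice(scores, size=n_subjects, replace=False)

    offsets = rng.normal(0.0, rp.offset_sd, size=2)
    inter = np.column_stack(
        [
            truth + offsets[j] + rng.normal(0.0, rp.occasion_sd, size=n_subjects)
            for j in range(2)
        ]
    )
    intra = np.column_stack(
        [
            truth + rng.normal(0.0, rp.occasion_sd, size=n_subjects)
            for _ in range(2)
        ]
    )
    subj = [f"s{i:03d}" for i in range(1, n_subjects + 1)]
    return RaterStudy(
        inter=pd.DataFrame(inter, columns=["rater_1", "rater_2"], index=subj),
        intra=pd.DataFrame(intra, columns=["occasion_1", "occasion_2"], index=subj),
    )


def resolve_instrument(name: str) -> InstrumentDefinition:
    """Instrument by packaged name, path, or the built-in planted bank."""
    if name == "planted-12":
        return planted_bank()
    return load_instrument(name)


# ---------------------------------------------------------------------------
# Packaged parameter presets


def default_params(**overrides) -> SimulationParams:
    """Default survey-bank cohort: the planted structure mirrors the
    published refinement ledger (7 non-discriminating items, 5 zero-loading
    items, one redundant demeanour pair)."""
    base = SimulationParams(
        instrument="ppid-survey-37",
        nondiscriminating=("svy3", "svy4", "svy5", "svy6", "svy7", "svy22", "svy23"),
        noise_items=("svy13", "svy14", "svy24", "svy29", "svy30"),
        redundant_pairs=(("svy2", "svy1", 0.3),),
    )
    return replace(base, **overrides) if overrides else base


def final_tool_params(**overrides) -> SimulationParams:
    """Final 24-item tool cohort: every item loads on the latent severity."""
    base = SimulationParams(instrument="ppid-final-24")
    return replace(base, **overrides) if overrides else base


def planted_bank() -> InstrumentDefinition:
    """A small 12-item bank with known structure for recovery experiments:
    items pl1/pl2 form a redundant demeanour pair, pl10 is a group-shifted
    zero-loading (noise) item, pl11/pl12 are non-discriminating."""
    freq = (
        Option("All the time", 3),
        Option("Often", 2),
        Option("Occasionally", 1),
        Option("Never", 0),
    )
    domains = (
        "demeanour",
        "demeanour",
        "appearance",
        "condition",
        "health",
        "health",
        "appetite",
        "ingestion",
        "management",
        "management",
        "appearance",
        "health",
    )
    items = tuple(
        ItemDefinition(
            item_id=f"pl{i + 1}",
            domain=domains[i],
            text=f"planted item {i + 1}",
            options=freq,
        )
        for i in range(12)
    )
    return InstrumentDefinition(
        name="planted-12", items=items, weights=DomainWeights.uniform(1)
    )


def planted_bank_params(**overrides) -> SimulationParams:
    """Simulation preset for the planted 12-item bank."""
    base = SimulationParams(
        instrument="planted-12",
        loading=1.0,
        nondiscriminating=("pl11", "pl12"),
        noise_items=("pl10",),
        redundant_pairs=(("pl2", "pl1", 0.3),),
    )
    return replace(base, **overrides) if overrides else base
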