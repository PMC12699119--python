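"""Instrument definition and HRQoL scoring.

The instrument is an ordered bank of Likert-type items grouped into seven
domains (demeanour, appearance, condition, health, appetite, ingestion,
management).  Each item maps its ordered response options to non-negative
numeric scores; higher scores indicate a greater negative impact on quality
of life.  Positively phrased items already carry reversed scores, so no
direction handling is needed at scoring time.

The normalized health-related quality-of-life (HRQoL) score for a complete
response record is

    hrqol = sum_i w_d(i) * s_i  /  sum_i w_d(i) * max_i

where ``s_i`` is the score of the chosen option on item *i*, ``max_i`` the
item's maximum regular-option score and ``w_d(i)`` the weight of the item's
domain (the median owner-rated importance of that domain, 1-5).  The score
runs from 0 (best possible QoL) to 1 (worst possible QoL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

try:  # Python >= 3.9
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    import importlib_resources as _resources  # type: ignore

__all__ = [
    "DOMAINS",
    "Option",
    "ItemDefinition",
    "DomainWeights",
    "InstrumentDefinition",
    "ResponseRecord",
    "ScoredResponse",
    "InstrumentValidationError",
    "ScoringError",
    "load_instrument",
    "load_bank_stub",
    "packaged_instruments",
    "score_item",
    "max_weighted_score",
    "score_response",
    "score_table",
]

#: The seven QoL domains, in canonical order.
DOMAINS: tuple[str, ...] = (
    "demeanour",
    "appearance",
    "condition",
    "health",
    "appetite",
    "ingestion",
    "management",
)

#: Names of the instrument definitions shipped with the package.
_PACKAGED = {
    "ppid-final-24": "ppid_final_24.yaml",
    "ppid-survey-37": "ppid_survey_37.yaml",
}
_STUB_FILE = "ppid_initial_bank.yaml"

#: Conventional label for the "could not observe" midpoint option.
UNOBSERVABLE_LABEL = "I have not been able to observe this"


class InstrumentValidationError(ValueError):
    """An instrument document violates the schema or an invariant."""


class ScoringError(ValueError):
    """A response record cannot be scored against the instrument."""


@dataclass(frozen=True)
class Option:
    """A single response option: display label plus its numeric score."""

    label: str
    score: float


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item.

    ``options`` are the ordered regular response options; ``special_options``
    are escape options such as "I have not been able to observe this" (scored
    at the item midpoint so the final score is neither inflated nor deflated)
    or "my horse does not receive any meds/suppl." (scored 0: no medication
    burden).  Special options are legal answers but do not define the item
    maximum.  ``polarity`` is documentation only — the scores already encode
    direction.
    """

    item_id: str
    domain: str
    text: str
    options: tuple[Option, ...]
    polarity: str = "negative"
    special_options: tuple[Option, ...] = ()

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise InstrumentValidationError(
                f"item {self.item_id!r}: unknown domain {self.domain!r}"
            )
        if len(self.options) < 2:
            raise InstrumentValidationError(
                f"item {self.item_id!r}: needs at least 2 options"
            )
        labels = [o.label for o in self.options] + [
            o.label for o in self.special_options
        ]
        if len(set(labels)) != len(labels):
            raise InstrumentValidationError(
                f"item {self.item_id!r}: duplicate option labels"
            )
        scores = [o.score for o in self.options]
        if min(scores) != 0:
            raise InstrumentValidationError(
                f"item {self.item_id!r}: option scores must start at 0 "
                f"(got minimum {min(scores)})"
            )
        if any(s < 0 for s in scores):
            raise InstrumentValidationError(
                f"item {self.item_id!r}: negative option score"
            )
        for opt in self.special_options:
            if opt.label == UNOBSERVABLE_LABEL:
                mid = (min(scores) + max(scores)) / 2
                if opt.score != mid:
                    raise InstrumentValidationError(
                        f"item {self.item_id!r}: unobservable option must "
                        f"score the item midpoint {mid}, got {opt.score}"
                    )

    @property
    def max_score(self) -> float:
        """Maximum regular-option score (the item's contribution ceiling)."""
        return max(o.score for o in self.options)

    @property
    def midpoint(self) -> float:
        return self.max_score / 2

    @property
    def all_options(self) -> tuple[Option, ...]:
        return self.options + self.special_options

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(o.label for o in self.all_options)

    def score_of(self, label: str) -> float:
        for opt in self.all_options:
            if opt.label == label:
                return opt.score
        raise ScoringError(
            f"item {self.item_id!r}: unknown response label {label!r}"
        )


@dataclass(frozen=True)
class DomainWeights:
    """Per-domain weights (median owner importance ratings on a 1-5 scale).

    Weights must be positive; importance-derived weights are integers in
    1..5 but any positive rational is accepted, since the normalized score
    is invariant under rescaling all weights by a common factor.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [d for d in DOMAINS if d not in self.weights]
        if missing:
            raise InstrumentValidationError(
                f"missing domain weight(s): {', '.join(missing)}"
            )
        for d, w in self.weights.items():
            if d not in DOMAINS:
                raise InstrumentValidationError(f"unknown domain {d!r} in weights")
            if not w > 0:
                raise InstrumentValidationError(
                    f"domain {d!r}: weight must be positive, got {w}"
                )

    def __getitem__(self, domain: str) -> float:
        return self.weights[domain]

    @classmethod
    def uniform(cls, weight: float = 1.0) -> "DomainWeights":
        return cls({d: weight for d in DOMAINS})

    def scaled(self, factor: float) -> "DomainWeights":
        return DomainWeights({d: w * factor for d, w in self.weights.items()})

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)


@dataclass(frozen=True)
class InstrumentDefinition:
    """An ordered item bank together with its domain weights."""

    name: str
    items: tuple[ItemDefinition, ...]
    weights: DomainWeights

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise InstrumentValidationError(
                f"instrument {self.name!r}: duplicate item ids {sorted(dupes)}"
            )

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(sorted({it.domain for it in self.items}, key=DOMAINS.index))

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def with_weights(self, weights: DomainWeights) -> "InstrumentDefinition":
        return InstrumentDefinition(self.name, self.items, weights)

    def subset(self, item_ids: Iterable[str], name: str | None = None) -> "InstrumentDefinition":
        wanted = list(item_ids)
        items = tuple(it for it in self.items if it.item_id in wanted)
        return InstrumentDefinition(name or f"{self.name}-subset", items, self.weights)


@dataclass(frozen=True)
class ResponseRecord:
    """One horse's answers plus owner-rated global QoL and covariates.

    ``owner_global_qol`` runs 1 ('very good') to 5 ('very poor').
    """

    horse_id: str
    answers: Mapping[str, str]
    owner_global_qol: int | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.owner_global_qol is not None and self.owner_global_qol not in (
            1,
            2,
            3,
            4,
            5,
        ):
            raise ScoringError(
                f"horse {self.horse_id!r}: owner_global_qol must be 1..5, "
                f"got {self.owner_global_qol}"
            )


@dataclass(frozen=True)
class ScoredResponse:
    """Outcome of scoring one record: per-item raw and weighted scores."""

    horse_id: str
    item_scores: Mapping[str, float]
    weighted_scores: Mapping[str, float]
    total_max: float
    hrqol: float


# ---------------------------------------------------------------------------
# Loading


def packaged_instruments() -> tuple[str, ...]:
    """Names of the instrument definitions shipped with the package."""
    return tuple(_PACKAGED)


def _data_text(filename: str) -> str:
    return (
        _resources.files("ppidqol").joinpath("data").joinpath(filename).read_text()
    )


def _parse_option(entry: Mapping, item_id: str) -> Option:
    if not isinstance(entry, Mapping) or "label" not in entry or "score" not in entry:
        raise InstrumentValidationError(
            f"item {item_id!r}: every option needs a label and a score"
        )
    return Option(label=str(entry["label"]), score=float(entry["score"]))


def instrument_from_dict(doc: Mapping) -> InstrumentDefinition:
    """Build a validated instrument from a parsed configuration document."""
    if not isinstance(doc, Mapping):
        raise InstrumentValidationError("instrument document must be a mapping")
    if doc.get("kind") == "stub":
        raise InstrumentValidationError(
            f"{doc.get('name')!r} is a metadata stub, not a loadable instrument; "
            "use load_bank_stub()"
        )
    for key in ("name", "items", "weights"):
        if key not in doc:
            raise InstrumentValidationError(f"instrument document missing {key!r}")
    weights = DomainWeights(
        {str(d): float(w) for d, w in dict(doc["weights"]).items()}
    )
    items = []
    for raw in doc["items"]:
        item_id = str(raw.get("id", "?"))
        if "options" not in raw:
            raise InstrumentValidationError(f"item {item_id!r}: no options given")
        items.append(
            ItemDefinition(
                item_id=item_id,
                domain=str(raw.get("domain", "")),
                text=str(raw.get("text", "")),
                polarity=str(raw.get("polarity", "negative")),
                options=tuple(_parse_option(o, item_id) for o in raw["options"]),
                special_options=tuple(
                    _parse_option(o, item_id) for o in raw.get("special_options", [])
                ),
            )
        )
    return InstrumentDefinition(str(doc["name"]), tuple(items), weights)


def load_instrument(source: str | Path | Mapping) -> InstrumentDefinition:
    """Load an instrument by packaged name, file path, or parsed document.

    Packaged names: ``"ppid-final-24"`` (the 24-item final tool) and
    ``"ppid-survey-37"`` (the 37-item survey bank it was refined from).
    """
    if isinstance(source, Mapping):
        return instrument_from_dict(source)
    if isinstance(source, str) and source in _PACKAGED:
        text = _data_text(_PACKAGED[source])
    else:
        path = Path(source)
        if not path.exists():
            raise InstrumentValidationError(
                f"{source!r} is neither a packaged instrument "
                f"({', '.join(_PACKAGED)}) nor an existing file"
            )
        text = path.read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise InstrumentValidationError(f"malformed instrument document: {exc}") from exc
    return instrument_from_dict(doc)


def load_bank_stub() -> dict:
    """Metadata for the initial interview-derived 42-item bank.

    Only counts and the pre-survey removal note survive; the five wordings
    removed during piloting were never recorded, so this is a stub rather
    than a loadable instrument.
    """
    return dict(yaml.safe_load(_data_text(_STUB_FILE)))


# ---------------------------------------------------------------------------
# Scoring


def score_item(item: ItemDefinition, label: str) -> float:
    """Score of the option with the given label (special options included)."""
    return item.score_of(label)


def max_weighted_score(instrument: InstrumentDefinition) -> float:
    """Denominator of the normalized score: sum of item maxima times weights."""
    return sum(
        it.max_score * instrument.weights[it.domain] for it in instrument.items
    )


def score_response(
    instrument: InstrumentDefinition,
    record: ResponseRecord,
    impute_midpoint: bool = False,
) -> ScoredResponse:
    """Score one complete response record.

    By default an incomplete record is refused (mirroring the exclusion of
    incomplete survey responses from the development analyses).  With
    ``impute_midpoint=True`` — an extension beyond the published scoring
    rule — unanswered items are scored at their midpoint instead.
    """
    missing = [
        it.item_id
        for it in instrument.items
        if it.item_id not in record.answers or record.answers[it.item_id] in ("", None)
    ]
    if missing and not impute_midpoint:
        raise ScoringError(
            f"horse {record.horse_id!r}: unanswered item(s): {', '.join(missing)}"
        )
    item_scores: dict[str, float] = {}
    weighted: dict[str, float] = {}
    for it in instrument.items:
        if it.item_id in missing:
            s = it.midpoint
        else:
            s = it.score_of(record.answers[it.item_id])
        item_scores[it.item_id] = s
        weighted[it.item_id] = s * instrument.weights[it.domain]
    total_max = max_weighted_score(instrument)
    hrqol = sum(weighted.values()) / total_max
    return ScoredResponse(
        horse_id=record.horse_id,
        item_scores=item_scores,
        weighted_scores=weighted,
        total_max=total_max,
        hrqol=hrqol,
    )


def score_table(instrument: InstrumentDefinition, table) -> "pd.Series":
    """Vectorized HRQoL score for a table of response labels.

    ``table`` is a DataFrame with one column per instrument item holding
    option labels.  Rows with a missing or illegal label raise, matching
    :func:`score_response`.
    """
    import pandas as pd  # local import keeps the core module lightweight

    missing_cols = [i for i in instrument.item_ids if i not in table.columns]
    if missing_cols:
        raise ScoringError(f"response table lacks item column(s): {missing_cols}")
    total = pd.Series(0.0, index=table.index)
    for item in instrument.items:
        mapping = {o.label: o.score for o in item.all_options}
        scores = table[item.item_id].map(mapping)
        if scores.isna().any():
            bad = table.loc[scores.isna(), item.item_id].unique()[:5]
            raise ScoringError(
                f"item {item.item_id!r}: missing or unknown label(s) {list(bad)}"
            )
        total = total + scores * instrument.weights[item.domain]
    return total / max_weighted_score(instrument)
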