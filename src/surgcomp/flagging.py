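"""Two-stage complication identification: screening flags, then adjudication.

Stage 1 (*flagging*) screens every procedure against mechanical criteria —
a prescription of an antibiotic, NSAID or opioid during post-operative days
1–8, or a post-operative observation period of 9 or more days (the standard
period is 7–8 days).  Stage 2 (*adjudication*) confirms or clears each flag.
In the original workflow that confirmation was a manual clinical-records
review; here it is (a) an authoritative per-procedure override table when
curation exists, and otherwise (b) a deterministic rule over the flag
triggers and the observation notes (matched case-insensitively against a
configurable lexicon of adverse terms).

A confirmed ("true") complication is one that required medical or surgical
treatment, or extension of the standard observation period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import (
    CareEvent,
    DrugClass,
    EventKind,
    ProcedureRecord,
)

__all__ = [
    "FlagCriteria",
    "KeywordLexicon",
    "ComplicationCall",
    "Override",
    "ConfigurationError",
    "flag_procedure",
    "adjudicate",
    "flag_and_adjudicate",
    "tally",
    "EXTENDED_OBSERVATION_TRIGGER",
]

EXTENDED_OBSERVATION_TRIGGER = "OBSERVATION_EXTENDED"

#: Adverse observation-note terms; any case-insensitive substring match counts.
DEFAULT_ADVERSE_TERMS = (
    "inappetence",
    "inflammation",
    "swelling",
    "bruising",
    "pain",
    "discharge",
    "abscess",
    "suture removal",
    "ulceration",
    "dehiscence",
)


class ConfigurationError(ValueError):
    """An override table references a procedure absent from the dataset."""


@dataclass(frozen=True)
class FlagCriteria:
    """Screening criteria for potential post-operative complications.

    window
        closed post-operative day interval inside which prescriptions flag
        (days since surgery, surgery day = 0).
    flag_drug_classes
        prescription drug classes that raise a flag.
    extended_observation_threshold
        observation length (days) at or above which a procedure flags;
        the default of 9 sits one day past the standard 7–8 day period.
    """

    window: tuple[int, int] = (1, 8)
    flag_drug_classes: frozenset[DrugClass] = frozenset(
        {DrugClass.ANTIBIOTIC, DrugClass.NSAID, DrugClass.OPIOID}
    )
    extended_observation_threshold: int = 9


@dataclass(frozen=True)
class KeywordLexicon:
    """Lowercase adverse phrases matched as case-insensitive substrings."""

    adverse_terms: tuple[str, ...] = DEFAULT_ADVERSE_TERMS

    def __post_init__(self) -> None:
        if not self.adverse_terms:
            raise ValueError("lexicon must be non-empty")
        object.__setattr__(
            self, "adverse_terms", tuple(t.lower() for t in self.adverse_terms)
        )

    def matches(self, text: str) -> list[str]:
        low = text.lower()
        return [term for term in self.adverse_terms if term in low]


@dataclass(frozen=True)
class Override:
    """Authoritative manual-review verdict for one procedure."""

    procedure_id: str
    complication: bool
    reason: str = ""


@dataclass(frozen=True)
class ComplicationCall:
    """Flag/adjudication outcome for one procedure with its evidence."""

    procedure_id: str
    flagged: bool
    complication: bool
    triggers: tuple[str, ...]
    adjudication_rule: str

    def __post_init__(self) -> None:
        if self.complication and not self.flagged:
            raise ValueError("complication implies flagged")
        if self.flagged != bool(self.triggers):
            raise ValueError("triggers must be non-empty iff flagged")


def flag_procedure(
    proc: ProcedureRecord,
    events: Sequence[tuple[CareEvent, int]],
    criteria: FlagCriteria = FlagCriteria(),
) -> tuple[bool, list[str]]:
    """Screen one procedure; returns (flagged, triggers).

    ``events`` must already be window-filtered (see
    :func:`surgcomp.records.link_events`).  Triggers enumerate every
    satisfied criterion, e.g. ``ANTIBIOTIC_DAY_3`` or
    ``OBSERVATION_EXTENDED``; their order follows the (already sorted)
    event list so identical inputs give identical trigger sequences.
    """
    triggers: list[str] = []
    for ev, offset in events:
        if ev.kind is EventKind.PRESCRIPTION and ev.drug_class in criteria.flag_drug_classes:
            triggers.append(f"{ev.drug_class.value}_DAY_{offset}")
    if proc.observation_days >= criteria.extended_observation_threshold:
        triggers.append(EXTENDED_OBSERVATION_TRIGGER)
    return bool(triggers), triggers


_TREATMENT_PREFIXES = tuple(f"{c.value}_DAY_" for c in DrugClass if c is not DrugClass.OTHER)


def adjudicate(
    proc: ProcedureRecord,
    flagged: bool,
    triggers: Sequence[str],
    notes: Sequence[tuple[CareEvent, int]],
    lexicon: KeywordLexicon = KeywordLexicon(),
    overrides: Mapping[str, Override] | None = None,
) -> ComplicationCall:
    """Confirm or clear a flagged procedure.

    An override entry for this procedure is authoritative (it stands in for
    the manual records review).  Otherwise a flag is confirmed when a
    treatment-class prescription trigger is present, when any in-window note
    matches the adverse lexicon, or when the flag arose from extended
    observation.  Unflagged procedures are never complications.
    """
    triggers = list(triggers)
    if overrides and proc.procedure_id in overrides:
        ov = overrides[proc.procedure_id]
        return ComplicationCall(
            procedure_id=proc.procedure_id,
            flagged=flagged,
            complication=bool(ov.complication) and flagged,
            triggers=tuple(triggers),
            adjudication_rule="override",
        )

    if not flagged:
        return ComplicationCall(proc.procedure_id, False, False, (), "not_flagged")

    keyword_hits: list[str] = []
    for ev, _offset in notes:
        if ev.kind is EventKind.NOTE:
            keyword_hits.extend(lexicon.matches(ev.note_text))
    # stable de-duplication preserving first occurrence
    keyword_hits = list(dict.fromkeys(keyword_hits))
    triggers.extend(f"NOTE_KEYWORD:{term}" for term in keyword_hits)

    has_treatment = any(t.startswith(_TREATMENT_PREFIXES) for t in triggers)
    has_extended = EXTENDED_OBSERVATION_TRIGGER in triggers
    if has_treatment:
        rule = "treatment_prescription"
    elif keyword_hits:
        rule = "note_keyword"
    elif has_extended:
        rule = "extended_observation"
    else:
        rule = "cleared"
    confirmed = has_treatment or bool(keyword_hits) or has_extended
    return ComplicationCall(
        procedure_id=proc.procedure_id,
        flagged=True,
        complication=confirmed,
        triggers=tuple(triggers),
        adjudication_rule=rule,
    )


def flag_and_adjudicate(
    procedures: Sequence[ProcedureRecord],
    linked_events: Mapping[str, Sequence[tuple[CareEvent, int]]],
    criteria: FlagCriteria = FlagCriteria(),
    lexicon: KeywordLexicon = KeywordLexicon(),
    overrides: Mapping[str, Override] | None = None,
) -> list[ComplicationCall]:
    """Run both stages over a cohort; output order follows ``procedures``."""
    if overrides:
        known = {p.procedure_id for p in procedures}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ConfigurationError(
                f"override table references unknown procedure_id(s): {unknown}"
            )
    calls = []
    for proc in procedures:
        events = linked_events.get(proc.procedure_id, ())
        flagged, triggers = flag_procedure(proc, events, criteria)
        notes = [(ev, off) for ev, off in events if ev.kind is EventKind.NOTE]
        calls.append(adjudicate(proc, flagged, triggers, notes, lexicon, overrides))
    return calls


def tally(
    calls: Sequence[ComplicationCall],
    procedures: Sequence[ProcedureRecord],
    stratifiers: Sequence[str] = ("procedure_type", "prophylaxis"),
) -> pd.DataFrame:
    """Per-stratum complication and procedure counts.

    Joins each call to its procedure (an orphan call is an error), groups by
    the requested procedure fields and returns a DataFrame with one row per
    stratum: the stratifier columns plus ``complications``, ``procedures``
    and ``rate_percent`` (100·complications/procedures).  Marginals are
    conserved: stratum procedure counts sum to the total number of
    procedures and complication counts to the total number of complications.
    """
    by_id = {p.procedure_id: p for p in procedures}
    orphans = [c.procedure_id for c in calls if c.procedure_id not in by_id]
    if orphans:
        raise ValueError(f"calls reference unknown procedure_id(s): {orphans}")

    rows = []
    for call in calls:
        proc = by_id[call.procedure_id]
        row = {name: getattr(proc, name) for name in stratifiers}
        for name, value in row.items():
            # enums render as their value so the table is plain text
            row[name] = value.value if hasattr(value, "value") else value
        row["complication"] = int(call.complication)
        rows.append(row)

    if not rows:
        return pd.DataFrame(
            columns=[*stratifiers, "complications", "procedures", "rate_percent"]
        )

    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(list(stratifiers), sort=True)["complication"]
        .agg(complications="sum", procedures="size")
        .reset_index()
    )
    grouped["rate_percent"] = 100.0 * grouped["complications"] / grouped["procedures"]
    return grouped
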