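"""Synthetic surgical-cohort generator with known ground truth.

Emulates the record structure of a retrospective non-human-primate surgical
cohort: ~1,056 macaques receiving ~3,629 peripheral-lymph-node (PLN) and
laparoscopic biopsies over a multi-year study window, stratified by
SIV/SHIV infection status and antibiotic prophylaxis.  Complications arise
as independent Bernoulli events per procedure at a per-stratum rate, and
every planted complication is materialized as evidence that the flagging
rules can detect: an in-window antibiotic or NSAID prescription, or an
extended (≥ 9 day) post-operative observation period, chosen uniformly.

Noise mimics the screening's false-positive sources: prescriptions
unrelated to the surgery (paired with an authoritative override entry that
clears them, standing in for manual records review) and benign observation
notes that match no adverse term.

Same-animal procedures are spaced at least 17 days apart so post-operative
windows never overlap and planted evidence attaches only to its own
procedure.  Everything is deterministic given the spec's seed.

:func:`paper_fixture` is unrelated to simulation: it rebuilds the eight
published 2×2 comparison tables from the printed (rate %, n) cells.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .flagging import Override
from .records import (
    AnimalDemographics,
    CareEvent,
    DrugClass,
    EventKind,
    InfectionStatus,
    ProcedureRecord,
    ProcedureType,
    Sex,
    Species,
    write_demographics,
    write_notes,
    write_prescriptions,
    write_procedures,
)
from .stats import TwoByTwo, reconstruct_counts

__all__ = [
    "StratumSpec",
    "DemographicsSpec",
    "NoiseSpec",
    "CohortSpec",
    "RecordsBundle",
    "GroundTruth",
    "TruthEntry",
    "SpecError",
    "default_strata",
    "default_cohort_spec",
    "generate",
    "paper_fixture",
    "PAPER_CELLS",
    "write_bundle",
]

#: minimum day gap between same-animal surgeries; > 2× the 8-day screening
#: window so no care event can straddle two procedures
_DATE_GRID_DAYS = 17


class SpecError(ValueError):
    """The cohort spec is infeasible (e.g. more procedures than capacity)."""


@dataclass(frozen=True)
class StratumSpec:
    """One analysis stratum: its size and true complication probability."""

    procedure_type: ProcedureType
    infection_status: InfectionStatus
    prophylaxis: bool
    n_procedures: int
    true_rate: float

    def __post_init__(self) -> None:
        if self.n_procedures < 0:
            raise ValueError("n_procedures must be >= 0")
        if not 0.0 <= self.true_rate <= 1.0:
            raise ValueError("true_rate must lie in [0, 1]")


@dataclass(frozen=True)
class DemographicsSpec:
    """Marginal demographic composition of the cohort."""

    rhesus_fraction: float = 1006 / 1056
    male_fraction: float = 616 / 1056
    age_range: tuple[float, float] = (0.04, 25.56)
    bcs_range: tuple[float, float] = (1.5, 5.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Rates of confounding events on procedures without a complication."""

    unrelated_prescription_rate: float = 0.02
    benign_note_rate: float = 0.10


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    strata: tuple[StratumSpec, ...]
    n_animals: int = 1056
    max_procedures_per_animal: int = 20
    demographics: DemographicsSpec = DemographicsSpec()
    noise: NoiseSpec = NoiseSpec()
    study_start: dt.date = dt.date(2018, 5, 1)
    study_end: dt.date = dt.date(2021, 1, 19)
    #: probability that a planted complication also leaves an adverse note
    adverse_note_rate: float = 0.5
    seed: int = 0

    @property
    def n_procedures(self) -> int:
        return sum(s.n_procedures for s in self.strata)


@dataclass
class RecordsBundle:
    """A generated cohort in the same shape the record readers produce."""

    procedures: list[ProcedureRecord]
    prescriptions: list[CareEvent]
    notes: list[CareEvent]
    demographics: list[AnimalDemographics]
    overrides: dict[str, Override]

    @property
    def events(self) -> list[CareEvent]:
        return self.prescriptions + self.notes


@dataclass(frozen=True)
class TruthEntry:
    complication: bool
    planted_evidence: tuple[str, ...]


@dataclass
class GroundTruth:
    """procedure_id → planted complication status and evidence."""

    entries: dict[str, TruthEntry]

    def complication_ids(self) -> set[str]:
        return {pid for pid, e in self.entries.items() if e.complication}


def default_strata() -> tuple[StratumSpec, ...]:
    """The eight published strata at their observed sizes and rates."""
    P, L = ProcedureType.PLN, ProcedureType.LAPAROSCOPIC
    I, U = InfectionStatus.INFECTED, InfectionStatus.UNINFECTED
    rows = [
        (P, I, True, 455, 0.0264),
        (P, I, False, 885, 0.0215),
        (P, U, True, 556, 0.0216),
        (P, U, False, 334, 0.0180),
        (L, I, True, 39, 0.0513),
        (L, I, False, 822, 0.0024),
        (L, U, True, 44, 0.0227),
        (L, U, False, 494, 0.0162),
    ]
    return tuple(StratumSpec(*row) for row in rows)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(strata=default_strata(), seed=seed)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_ADVERSE_NOTES = (
    "moderate swelling and bruising at incision site",
    "incision discharge noted on exam",
    "evidence of pain on palpation of surgical site",
    "inappetence observed, monitoring food intake",
    "partial dehiscence of incision, wound care initiated",
    "surgical site abscessation suspected",
)
_BENIGN_NOTES = (
    "incision clean and dry, animal bright and alert",
    "normal appetite, incision intact",
    "animal active and responsive, no concerns",
    "routine post-op check, incision looks good",
)


def generate(spec: CohortSpec) -> tuple[RecordsBundle, GroundTruth]:
    """Generate a full record bundle plus ground truth, deterministically.

    Per stratum, each procedure independently becomes a complication with
    probability ``true_rate`` (so stratum totals are Binomial).  Each
    complication is materialized through one evidence branch chosen
    uniformly: an antibiotic prescription, an NSAID prescription (each on a
    uniform day 1–8), or an observation period extended to 9–14 days.
    """
    rng = np.random.default_rng(spec.seed)
    n_slots = ((spec.study_end - spec.study_start).days // _DATE_GRID_DAYS) + 1
    capacity = min(spec.max_procedures_per_animal, n_slots)
    if spec.n_procedures > spec.n_animals * capacity:
        raise SpecError(
            f"spec asks for {spec.n_procedures} procedures but "
            f"{spec.n_animals} animals x {capacity} max each "
            f"= {spec.n_animals * capacity} capacity"
        )

    animal_ids = [f"A{i:04d}" for i in range(spec.n_animals)]
    demographics = _generate_demographics(spec, rng, animal_ids)

    # procedure -> animal assignment: uniform over animals with free capacity
    free_slots: list[list[int]] = [list(range(n_slots)) for _ in animal_ids]
    open_animals = list(range(spec.n_animals))

    procedures: list[ProcedureRecord] = []
    prescriptions: list[CareEvent] = []
    notes: list[CareEvent] = []
    overrides: dict[str, Override] = {}
    truth: dict[str, TruthEntry] = {}

    counter = 0
    for stratum in spec.strata:
        is_comp = rng.random(stratum.n_procedures) < stratum.true_rate
        for i in range(stratum.n_procedures):
            pid = f"P{counter:05d}"
            counter += 1
            a = open_animals[int(rng.integers(len(open_animals)))]
            slots = free_slots[a]
            slot = slots.pop(int(rng.integers(len(slots))))
            if len(slots) == n_slots - capacity:
                open_animals.remove(a)
            date = spec.study_start + dt.timedelta(days=slot * _DATE_GRID_DAYS)
            aid = animal_ids[a]

            evidence: list[str] = []
            observation = int(rng.integers(7, 9))  # standard 7-8 days
            if is_comp[i]:
                branch = int(rng.integers(3))
                day = int(rng.integers(1, 9))
                if branch == 0:
                    drug = ("cefazolin", "cephalexin")[int(rng.integers(2))]
                    prescriptions.append(
                        CareEvent(
                            animal_id=aid,
                            event_date=date + dt.timedelta(days=day),
                            kind=EventKind.PRESCRIPTION,
                            drug_name=drug,
                            drug_class=DrugClass.ANTIBIOTIC,
                            indication="surgical complication",
                        )
                    )
                    evidence.append(f"ANTIBIOTIC_RX_DAY_{day}")
                elif branch == 1:
                    prescriptions.append(
                        CareEvent(
                            animal_id=aid,
                            event_date=date + dt.timedelta(days=day),
                            kind=EventKind.PRESCRIPTION,
                            drug_name="meloxicam",
                            drug_class=DrugClass.NSAID,
                            indication="surgical complication",
                        )
                    )
                    evidence.append(f"NSAID_RX_DAY_{day}")
                else:
                    observation = int(rng.integers(9, 15))
                    evidence.append("EXTENDED_OBSERVATION")
                if rng.random() < spec.adverse_note_rate:
                    notes.append(
                        CareEvent(
                            animal_id=aid,
                            event_date=date + dt.timedelta(days=int(rng.integers(1, 9))),
                            kind=EventKind.NOTE,
                            note_text=_ADVERSE_NOTES[int(rng.integers(len(_ADVERSE_NOTES)))],
                        )
                    )
                    evidence.append("ADVERSE_NOTE")
            else:
                if rng.random() < spec.noise.unrelated_prescription_rate:
                    prescriptions.append(
                        CareEvent(
                            animal_id=aid,
                            event_date=date + dt.timedelta(days=int(rng.integers(1, 9))),
                            kind=EventKind.PRESCRIPTION,
                            drug_name="cephalexin",
                            drug_class=DrugClass.ANTIBIOTIC,
                            indication="dermatitis unrelated to procedure",
                        )
                    )
                    overrides[pid] = Override(
                        procedure_id=pid,
                        complication=False,
                        reason="prescription unrelated to procedure",
                    )
                if rng.random() < spec.noise.benign_note_rate:
                    notes.append(
                        CareEvent(
                            animal_id=aid,
                            event_date=date + dt.timedelta(days=int(rng.integers(1, 9))),
                            kind=EventKind.NOTE,
                            note_text=_BENIGN_NOTES[int(rng.integers(len(_BENIGN_NOTES)))],
                        )
                    )

            procedures.append(
                ProcedureRecord(
                    procedure_id=pid,
                    animal_id=aid,
                    surgery_date=date,
                    procedure_type=stratum.procedure_type,
                    infection_status=stratum.infection_status,
                    prophylaxis=stratum.prophylaxis,
                    observation_days=observation,
                )
            )
            truth[pid] = TruthEntry(bool(is_comp[i]), tuple(evidence))

    bundle = RecordsBundle(procedures, prescriptions, notes, demographics, overrides)
    return bundle, GroundTruth(truth)


def _generate_demographics(spec, rng, animal_ids) -> list[AnimalDemographics]:
    n = len(animal_ids)
    d = spec.demographics
    n_rhesus = round(d.rhesus_fraction * n)
    n_male = round(d.male_fraction * n)
    species = [Species.RHESUS] * n_rhesus + [Species.CYNOMOLGUS] * (n - n_rhesus)
    sex = [Sex.M] * n_male + [Sex.F] * (n - n_male)
    rng.shuffle(species)
    rng.shuffle(sex)
    ages = rng.uniform(*d.age_range, size=n)
    bcs = np.round(rng.uniform(*d.bcs_range, size=n), 1)
    return [
        AnimalDemographics(
            animal_id=animal_ids[i],
            species=species[i],
            sex=sex[i],
            age_years=float(round(ages[i], 2)),
            bcs=float(min(max(bcs[i], d.bcs_range[0]), d.bcs_range[1])),
        )
        for i in range(n)
    ]


def write_bundle(bundle: RecordsBundle, truth: GroundTruth, outdir) -> dict[str, Path]:
    """Write the cohort as the standard CSV schemas plus ground_truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "procedures": outdir / "procedures.csv",
        "prescriptions": outdir / "prescriptions.csv",
        "notes": outdir / "notes.csv",
        "demographics": outdir / "demographics.csv",
        "overrides": outdir / "overrides.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    write_procedures(paths["procedures"], bundle.procedures)
    write_prescriptions(paths["prescriptions"], bundle.prescriptions)
    write_notes(paths["notes"], bundle.notes)
    write_demographics(paths["demographics"], bundle.demographics)
    with paths["overrides"].open("w", encoding="utf-8") as fh:
        fh.write("procedure_id,complication,reason\n")
        for ov in bundle.overrides.values():
            fh.write(f"{ov.procedure_id},{int(ov.complication)},{ov.reason}\n")
    with paths["ground_truth"].open("w", encoding="utf-8") as fh:
        fh.write("procedure_id,complication,planted_evidence\n")
        for pid, entry in truth.entries.items():
            fh.write(f"{pid},{int(entry.complication)},{';'.join(entry.planted_evidence)}\n")
    return paths


def type_i_error_simulation(
    n_per_stratum: int = 200,
    true_rate: float = 0.021,
    n_replicates: int = 500,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Empirical type-I error of the one-sided test under equal true rates.

    Each replicate generates a fresh two-stratum cohort (same true
    complication rate in both strata, default noise), runs the full pipeline
    — link, flag, adjudicate, tally, randomization test — and records
    whether p_mc < alpha.  Because the test is one-sided with a discrete
    null, the rejection rate is expected at or below the nominal level.

    Returns (rejection_rate, p_values).
    """
    from .flagging import flag_and_adjudicate, tally
    from .records import link_events
    from .stats import run_comparisons

    comparison = [
        {
            "name": "equal_rate_null",
            "group1": {"prophylaxis": True},
            "group2": {"prophylaxis": False},
        }
    ]
    p_values = []
    for rep in range(n_replicates):
        spec = CohortSpec(
            strata=(
                StratumSpec(ProcedureType.PLN, InfectionStatus.INFECTED, True,
                            n_per_stratum, true_rate),
                StratumSpec(ProcedureType.PLN, InfectionStatus.INFECTED, False,
                            n_per_stratum, true_rate),
            ),
            n_animals=max(2, (2 * n_per_stratum) // 3),
            seed=int((seed * 100_003 + rep) % (2**31)),
        )
        bundle, _ = generate(spec)
        linked = link_events(bundle.procedures, bundle.events)
        calls = flag_and_adjudicate(bundle.procedures, linked,
                                    overrides=bundle.overrides)
        df = tally(calls, bundle.procedures, ("prophylaxis",))
        (res,) = run_comparisons(df, comparison, B=B,
                                 seed=int((seed * 7_919 + rep) % (2**31)),
                                 alpha=alpha)
        p_values.append(res.p_mc)
    rate = sum(p < alpha for p in p_values) / n_replicates
    return rate, p_values


# ---------------------------------------------------------------------------
# published comparison tables
# ---------------------------------------------------------------------------

#: The published (rate %, n) cells for the eight comparisons: for each,
#: group 1 (prophylaxis, resp. infected) first.
PAPER_CELLS: tuple[tuple[str, tuple[float, int], tuple[float, int], tuple[str, str]], ...] = (
    ("pln_prophylaxis", (2.37, 1011), (2.05, 1219), ("prophylaxis", "no prophylaxis")),
    ("lap_prophylaxis", (3.61, 83), (0.76, 1316), ("prophylaxis", "no prophylaxis")),
    ("pln_infection", (2.31, 1340), (2.02, 890), ("infected", "uninfected")),
    ("pln_infected_prophylaxis", (2.64, 455), (2.15, 885), ("prophylaxis", "no prophylaxis")),
    ("pln_uninfected_prophylaxis", (2.16, 556), (1.80, 334), ("prophylaxis", "no prophylaxis")),
    ("lap_infection", (0.46, 861), (1.67, 538), ("infected", "uninfected")),
    ("lap_infected_prophylaxis", (5.13, 39), (0.24, 822), ("prophylaxis", "no prophylaxis")),
    ("lap_uninfected_prophylaxis", (2.27, 44), (1.62, 494), ("prophylaxis", "no prophylaxis")),
)


def paper_fixture() -> list[TwoByTwo]:
    """The eight published comparisons as 2×2 tables.

    Counts are reconstructed from the printed (rate %, n) cells via
    :func:`surgcomp.stats.reconstruct_counts`; the reconstruction is exact —
    every cell's rate×n lies within 0.1 of an integer and all row/column
    sums are consistent.
    """
    tables = []
    for name, (r1, n1), (r2, n2), labels in PAPER_CELLS:
        tables.append(
            TwoByTwo(
                x1=reconstruct_counts(r1, n1),
                n1=n1,
                x2=reconstruct_counts(r2, n2),
                n2=n2,
                labels=labels,
                name=name,
            )
        )
    return tables
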