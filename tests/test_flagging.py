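"""Flagging rules, adjudication and per-stratum tallies."""

import datetime as dt
import random

import pytest

from surgcomp import synthetic
from surgcomp.flagging import (
    ComplicationCall,
    ConfigurationError,
    FlagCriteria,
    KeywordLexicon,
    Override,
    adjudicate,
    flag_and_adjudicate,
    flag_procedure,
    tally,
)
from surgcomp.records import DrugClass, link_events

from .conftest import make_note, make_procedure, make_rx


class TestFlagProcedure:
    def test_nsaid_prescription_flags_with_day_trigger(self):
        proc = make_procedure(observation=7)
        rx = make_rx(drug="meloxicam", drug_class=DrugClass.NSAID,
                     date=dt.date(2020, 1, 3))
        flagged, triggers = flag_procedure(proc, [(rx, 2)])
        assert flagged and triggers == ["NSAID_DAY_2"]

    def test_extended_observation_flags(self):
        flagged, triggers = flag_procedure(make_procedure(observation=9), [])
        assert flagged and triggers == ["OBSERVATION_EXTENDED"]

    def test_standard_observation_does_not_flag(self):
        flagged, triggers = flag_procedure(make_procedure(observation=8), [])
        assert not flagged and triggers == []

    def test_other_drug_class_does_not_flag(self):
        rx = make_rx(drug="saline", drug_class=DrugClass.OTHER)
        flagged, _ = flag_procedure(make_procedure(), [(rx, 2)])
        assert not flagged

    def test_multiple_criteria_all_enumerated(self):
        proc = make_procedure(observation=10)
        rx = make_rx(date=dt.date(2020, 1, 4))
        flagged, triggers = flag_procedure(proc, [(rx, 3)])
        assert flagged
        assert triggers == ["ANTIBIOTIC_DAY_3", "OBSERVATION_EXTENDED"]


class TestAdjudicate:
    def test_treatment_trigger_confirms(self):
        call = adjudicate(make_procedure(), True, ["ANTIBIOTIC_DAY_3"], [])
        assert call.complication and call.adjudication_rule == "treatment_prescription"

    def test_override_clears_unrelated_prescription(self):
        ov = {"P1": Override("P1", complication=False, reason="unrelated to procedure")}
        call = adjudicate(make_procedure(), True, ["ANTIBIOTIC_DAY_3"], [], overrides=ov)
        assert not call.complication and call.adjudication_rule == "override"

    def test_unflagged_never_complication(self):
        note = make_note(text="severe swelling and dehiscence")
        call = adjudicate(make_procedure(), False, [], [(note, 2)])
        assert not call.flagged and not call.complication

    def test_note_keyword_recorded_in_triggers(self):
        proc = make_procedure(observation=9)
        note = make_note(text="Partial DEHISCENCE of the incision")
        call = adjudicate(proc, True, ["OBSERVATION_EXTENDED"], [(note, 3)])
        assert call.complication
        assert "NOTE_KEYWORD:dehiscence" in call.triggers

    def test_unknown_override_id_is_configuration_error(self):
        procs = [make_procedure()]
        ov = {"NOPE": Override("NOPE", False)}
        with pytest.raises(ConfigurationError, match="NOPE"):
            flag_and_adjudicate(procs, {"P1": []}, overrides=ov)

    def test_call_invariants_enforced(self):
        with pytest.raises(ValueError):
            ComplicationCall("P1", flagged=False, complication=True, triggers=(),
                             adjudication_rule="x")
        with pytest.raises(ValueError):
            ComplicationCall("P1", flagged=True, complication=True, triggers=(),
                             adjudication_rule="x")

    def test_adverse_note_never_clears_a_complication(self):
        """Monotonicity: adding adverse-keyword notes cannot flip true -> false."""
        proc = make_procedure(observation=9)
        base = adjudicate(proc, True, ["OBSERVATION_EXTENDED"], [])
        assert base.complication
        for term in KeywordLexicon().adverse_terms:
            with_note = adjudicate(
                proc, True, ["OBSERVATION_EXTENDED"], [(make_note(text=f"marked {term}"), 2)]
            )
            assert with_note.complication


class TestDeterminism:
    def test_identical_inputs_identical_calls_any_order(self):
        bundle, _ = synthetic.generate(synthetic.default_cohort_spec(seed=3))
        procs = bundle.procedures[:300]
        ids = {p.procedure_id for p in procs}
        overrides = {k: v for k, v in bundle.overrides.items() if k in ids}
        linked = link_events(procs, bundle.events)
        calls = flag_and_adjudicate(procs, linked, overrides=overrides)
        shuffled_events = bundle.events[:]
        random.Random(0).shuffle(shuffled_events)
        linked2 = link_events(procs, shuffled_events)
        calls2 = flag_and_adjudicate(procs, linked2, overrides=overrides)
        assert calls == calls2


class TestTally:
    def test_empty_input_gives_empty_table(self):
        df = tally([], [], ("prophylaxis",))
        assert df.empty and "rate_percent" in df.columns

    def test_single_procedure_single_complication(self):
        proc = make_procedure(observation=9)
        calls = flag_and_adjudicate([proc], {"P1": []})
        df = tally(calls, [proc], ("prophylaxis",))
        assert df.loc[0, "complications"] == 1
        assert df.loc[0, "procedures"] == 1
        assert df.loc[0, "rate_percent"] == 100.0

    def test_orphan_call_is_join_error(self):
        call = ComplicationCall("GHOST", False, False, (), "not_flagged")
        with pytest.raises(ValueError, match="GHOST"):
            tally([call], [make_procedure()])

    @pytest.mark.parametrize(
        "stratifiers",
        [("prophylaxis",), ("procedure_type", "prophylaxis"),
         ("procedure_type", "infection_status", "prophylaxis")],
    )
    def test_marginals_conserved_for_any_stratifier_set(self, stratifiers):
        bundle, truth = synthetic.generate(synthetic.default_cohort_spec(seed=5))
        linked = link_events(bundle.procedures, bundle.events)
        calls = flag_and_adjudicate(bundle.procedures, linked, overrides=bundle.overrides)
        df = tally(calls, bundle.procedures, stratifiers)
        assert df["procedures"].sum() == len(bundle.procedures)
        assert df["complications"].sum() == sum(c.complication for c in calls)

    def test_reconstructed_pln_counts_sum_as_published(self):
        """49 complications among 2,230 PLN procedures split 24 + 25."""
        tables = {t.name: t for t in synthetic.paper_fixture()}
        t = tables["pln_prophylaxis"]
        assert (t.x1, t.n1, t.x2, t.n2) == (24, 1011, 25, 1219)
        assert t.x1 + t.x2 == 49 and t.n1 + t.n2 == 2230


class TestEndToEndRecovery:
    def test_noise_free_cohort_recovered_exactly(self):
        """With no confounding events, flag -> adjudicate equals ground truth."""
        spec = synthetic.CohortSpec(
            strata=synthetic.default_strata(),
            noise=synthetic.NoiseSpec(0.0, 0.0),
            seed=9,
        )
        bundle, truth = synthetic.generate(spec)
        assert not bundle.overrides
        linked = link_events(bundle.procedures, bundle.events)
        calls = flag_and_adjudicate(bundle.procedures, linked)
        recovered = {c.procedure_id for c in calls if c.complication}
        assert recovered == truth.complication_ids()

    def test_noisy_cohort_recovered_exactly_via_overrides(self):
        bundle, truth = synthetic.generate(synthetic.default_cohort_spec(seed=10))
        linked = link_events(bundle.procedures, bundle.events)
        calls = flag_and_adjudicate(bundle.procedures, linked, overrides=bundle.overrides)
        recovered = {c.procedure_id for c in calls if c.complication}
        assert recovered == truth.complication_ids()
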