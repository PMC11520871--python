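"""Unit and property tests for the study-screening rules."""

import random
from collections import defaultdict

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traumacast.errors import EmptySelectionError, ValidationError
from traumacast.screening import (
    DEFAULT_RULES,
    HELP_SEEKING,
    NOT_EXPOSURE_SPECIFIC,
    PERIOD_PREVALENCE,
    QUESTIONNAIRE_WHEN_CLINICAL,
    REANALYSIS,
    SUPERSEDED_WAVE,
    TIMING_LT_MIN,
    ScreeningDecision,
    ScreeningRuleSet,
    StudyEstimate,
    apply_correction,
    correct_corpus,
    included_records,
    screen_corpus,
    select_wave,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# independent brute-force oracle: each rule as a set operation


def brute_force_decisions(records, rules):
    idx = range(len(records))
    timing = {
        i for i in idx
        if records[i].months_post_exposure is None
        or records[i].months_post_exposure < rules.min_months_post_exposure
    }
    period = {
        i for i in idx
        if rules.require_point_prevalence and records[i].prevalence_type != "point"
    }
    helpseek = {
        i for i in idx
        if rules.exclude_help_seeking
        and records[i].population in ("help_seeking", "clinical_setting")
    }
    nonspec = {
        i for i in idx
        if rules.require_exposure_specific_for_questionnaires
        and records[i].method == "questionnaire"
        and records[i].exposure_specific != "yes"
    }
    reana = {
        i for i in idx
        if rules.exclude_reanalyses and records[i].reanalysis_of is not None
    }
    excluded = timing | period | helpseek | nonspec | reana
    survivors = set(idx) - excluded
    if any(records[i].method == "clinical" for i in survivors):
        qs = {i for i in idx if records[i].method == "questionnaire"}
        excluded |= qs
        survivors -= qs
    by_sample = defaultdict(list)
    for i in survivors:
        by_sample[(records[i].study_id, records[i].sample_id)].append(i)
    for members in by_sample.values():
        if len(members) > 1:
            best = max(members, key=lambda i: records[i].prevalence)
            excluded |= set(members) - {best}
    return {i: i not in excluded for i in idx}


def random_corpus(rnd, size=50):
    records = []
    i = 0
    while len(records) < size:
        waves = rnd.choice([1, 1, 1, 2, 3])
        sid = f"study{i}"
        for w in range(waves):
            if len(records) >= size:
                break
            records.append(
                StudyEstimate(
                    study_id=sid,
                    sample_id=f"{sid}s",
                    n=rnd.randint(30, 400),
                    prevalence=rnd.random(),  # distinct a.s. -> no argmax ties
                    method=rnd.choice(["clinical", "questionnaire"]),
                    months_post_exposure=rnd.choice([None, 0.25, 0.5, 1.0, 3.0, 12.0]),
                    prevalence_type=rnd.choice(["point", "point", "period", "unknown"]),
                    population=rnd.choice(
                        ["general", "general", "help_seeking", "clinical_setting"]
                    ),
                    exposure_specific=rnd.choice(["yes", "yes", "no", "unknown"]),
                    wave=w + 1,
                )
            )
        i += 1
    return records


# ---------------------------------------------------------------------------
# StudyEstimate validation


class TestStudyEstimate:
    def test_prevalence_filled_from_events(self):
        rec = StudyEstimate(study_id="a", sample_id="a1", n=100, events=32)
        assert rec.prevalence == pytest.approx(0.32)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValidationError, match="a/a1"):
            StudyEstimate(study_id="a", sample_id="a1", n=0, events=0)

    def test_prevalence_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            StudyEstimate(study_id="a", sample_id="a1", n=10, prevalence=1.2)

    def test_inconsistent_events_and_prevalence_rejected(self):
        with pytest.raises(ValidationError, match="prevalence"):
            StudyEstimate(study_id="a", sample_id="a1", n=100, events=32, prevalence=0.5)

    def test_missing_both_rejected(self):
        with pytest.raises(ValidationError):
            StudyEstimate(study_id="a", sample_id="a1", n=100)

    def test_decision_consistency_enforced(self):
        with pytest.raises(ValidationError):
            ScreeningDecision(study_id="a", sample_id="a1", included=True,
                              reasons=(TIMING_LT_MIN,))

    def test_correction_factor_bounds(self):
        with pytest.raises(ValidationError):
            ScreeningRuleSet(correction_factor=0.0)
        with pytest.raises(ValidationError):
            ScreeningRuleSet(correction_factor=1.2)


# ---------------------------------------------------------------------------
# screen_corpus


class TestScreenCorpus:
    def test_all_clinical_all_eligible_included(self):
        corpus = [make_record(study_id=f"s{i}", prevalence=0.1 + 0.01 * i)
                  for i in range(5)]
        decisions = screen_corpus(corpus, DEFAULT_RULES)
        assert all(d.included for d in decisions)

    def test_each_rule_fires_with_its_code(self):
        corpus = [
            make_record("ok", prevalence=0.30),
            make_record("early", months=0.5),
            make_record("nodate", months=None),
            make_record("period", prevalence_type="period"),
            make_record("unknown_type", prevalence_type="unknown"),
            make_record("help", population="help_seeking"),
            make_record("clinic", population="clinical_setting"),
            make_record("reana", reanalysis_of="ok"),
        ]
        decisions = {d.study_id: d for d in screen_corpus(corpus, DEFAULT_RULES)}
        assert decisions["ok"].included
        assert decisions["early"].reasons == (TIMING_LT_MIN,)
        assert decisions["nodate"].reasons == (TIMING_LT_MIN,)
        assert decisions["period"].reasons == (PERIOD_PREVALENCE,)
        assert decisions["unknown_type"].reasons == (PERIOD_PREVALENCE,)
        assert decisions["help"].reasons == (HELP_SEEKING,)
        assert decisions["clinic"].reasons == (HELP_SEEKING,)
        assert decisions["reana"].reasons == (REANALYSIS,)

    def test_clinical_preference_is_corpus_wide(self):
        corpus = [
            make_record("clin", method="clinical", prevalence=0.2),
            make_record("qnr", method="questionnaire", prevalence=0.4),
        ]
        decisions = {d.study_id: d for d in screen_corpus(corpus)}
        assert decisions["clin"].included
        assert decisions["qnr"].reasons == (QUESTIONNAIRE_WHEN_CLINICAL,)

    def test_no_clinical_preference_when_no_clinical_survives(self):
        corpus = [
            make_record("clin", method="clinical", months=0.5),  # filtered out
            make_record("qnr", method="questionnaire", prevalence=0.4),
        ]
        decisions = {d.study_id: d for d in screen_corpus(corpus)}
        assert not decisions["clin"].included
        assert decisions["qnr"].included

    def test_exposure_specific_rule_only_for_questionnaires(self):
        corpus = [
            make_record("clin", method="clinical", exposure_specific="no"),
            make_record("qnr", method="questionnaire", exposure_specific="no"),
        ]
        decisions = {d.study_id: d for d in screen_corpus(corpus)}
        assert decisions["clin"].included
        assert NOT_EXPOSURE_SPECIFIC in decisions["qnr"].reasons

    def test_combat_review_mirror(self):
        """27 records: 4 clean clinical survive a questionnaire-heavy corpus."""
        corpus = [make_record(f"clin{i}", prevalence=0.05 + 0.01 * i)
                  for i in range(4)]
        for i in range(23):
            kwargs = {"method": "questionnaire", "prevalence": 0.2 + 0.005 * i}
            if i < 3:
                kwargs["exposure_specific"] = "no"
            elif i < 6:
                kwargs["prevalence_type"] = "period"
            corpus.append(make_record(f"qnr{i}", **kwargs))
        decisions = screen_corpus(corpus, DEFAULT_RULES)
        kept = {d.study_id for d in decisions if d.included}
        assert kept == {"clin0", "clin1", "clin2", "clin3"}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            screen_corpus([], DEFAULT_RULES)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_on_random_corpus(self, seed):
        rnd = random.Random(seed)
        corpus = random_corpus(rnd, size=50)
        decisions = screen_corpus(corpus, DEFAULT_RULES)
        expected = brute_force_decisions(corpus, DEFAULT_RULES)
        assert [d.included for d in decisions] == [expected[i] for i in range(len(corpus))]

    @pytest.mark.parametrize("seed", range(3))
    def test_order_independence(self, seed):
        rnd = random.Random(100 + seed)
        corpus = random_corpus(rnd, size=30)
        base = {(d.study_id, d.sample_id, corpus.index(r)): d.reasons
                for r, d in zip(corpus, screen_corpus(corpus))}
        perm = corpus[:]
        rnd.shuffle(perm)
        shuffled = screen_corpus(perm)
        for rec, dec in zip(perm, shuffled):
            assert base[(dec.study_id, dec.sample_id, corpus.index(rec))] == dec.reasons

    @pytest.mark.parametrize("seed", range(3))
    def test_idempotence(self, seed):
        rnd = random.Random(200 + seed)
        corpus = random_corpus(rnd, size=40)
        kept = included_records(corpus, screen_corpus(corpus))
        if not kept:
            pytest.skip("random corpus screened to nothing")
        again = screen_corpus(kept)
        assert all(d.included for d in again)

    @pytest.mark.parametrize("seed", range(3))
    def test_relaxing_rules_never_shrinks_inclusion_count(self, seed):
        rnd = random.Random(300 + seed)
        corpus = random_corpus(rnd, size=40)
        strictest = sum(d.included for d in screen_corpus(corpus, DEFAULT_RULES))
        relaxations = [
            ScreeningRuleSet(min_months_post_exposure=0.0),
            ScreeningRuleSet(require_point_prevalence=False),
            ScreeningRuleSet(exclude_help_seeking=False),
            ScreeningRuleSet(require_exposure_specific_for_questionnaires=False),
            ScreeningRuleSet(exclude_reanalyses=False),
        ]
        for relaxed in relaxations:
            assert sum(d.included for d in screen_corpus(corpus, relaxed)) >= strictest


# ---------------------------------------------------------------------------
# select_wave


class TestSelectWave:
    def test_highest_prevalence_wins(self):
        waves = [
            make_record("s", sample_id="sa", months=1.0, prevalence=0.30, wave=1),
            make_record("s", sample_id="sa", months=6.0, prevalence=0.22, wave=2),
            make_record("s", sample_id="sa", months=12.0, prevalence=0.18, wave=3),
        ]
        assert select_wave(waves).prevalence == 0.30

    def test_sub_month_wave_ineligible(self):
        waves = [
            make_record("s", sample_id="sa", months=0.5, prevalence=0.40, wave=1),
            make_record("s", sample_id="sa", months=6.0, prevalence=0.25, wave=2),
        ]
        assert select_wave(waves).prevalence == 0.25

    def test_tie_goes_to_earliest_wave(self):
        waves = [
            make_record("s", sample_id="sa", months=6.0, prevalence=0.25, wave=2),
            make_record("s", sample_id="sa", months=1.0, prevalence=0.25, wave=1),
        ]
        assert select_wave(waves).wave == 1

    def test_no_eligible_wave_signals_empty_selection(self):
        waves = [make_record("s", sample_id="sa", months=0.2, prevalence=0.4, wave=1)]
        with pytest.raises(EmptySelectionError):
            select_wave(waves)

    def test_mixed_samples_rejected(self):
        waves = [
            make_record("s", sample_id="sa", prevalence=0.2),
            make_record("s", sample_id="sb", prevalence=0.3),
        ]
        with pytest.raises(ValidationError):
            select_wave(waves)

    @pytest.mark.parametrize("seed", range(20))
    def test_argmax_oracle(self, seed):
        rnd = random.Random(seed)
        waves = [
            make_record(
                "s", sample_id="sa", wave=w + 1,
                months=rnd.choice([0.25, 0.5, 1.0, 2.0, 6.0, 12.0]),
                prevalence=rnd.random(),
            )
            for w in range(rnd.randint(1, 6))
        ]
        eligible = [r for r in waves if r.months_post_exposure >= 1.0]
        if not eligible:
            with pytest.raises(EmptySelectionError):
                select_wave(waves)
        else:
            assert select_wave(waves) == max(eligible, key=lambda r: r.prevalence)

    def test_superseded_waves_flagged_in_corpus_screening(self):
        corpus = [
            make_record("s", sample_id="sa", months=1.0, prevalence=0.30, wave=1),
            make_record("s", sample_id="sa", months=6.0, prevalence=0.22, wave=2),
        ]
        decisions = screen_corpus(corpus)
        assert decisions[0].included
        assert decisions[1].reasons == (SUPERSEDED_WAVE,)


# ---------------------------------------------------------------------------
# correction factor


class TestCorrection:
    def test_published_example(self, rules):
        assert apply_correction(0.21, rules) == pytest.approx(0.1491)
        assert round(apply_correction(0.21, rules) + 1e-12, 2) == 0.15

    def test_zero_fixed_point(self, rules):
        assert apply_correction(0.0, rules) == 0.0

    def test_factor_itself(self, rules):
        assert apply_correction(1.0, rules) == pytest.approx(0.71)

    def test_out_of_range_rejected(self, rules):
        with pytest.raises(ValidationError):
            apply_correction(1.5, rules)

    def test_corpus_correction_marks_provenance_and_is_idempotent(self, rules):
        corpus = [make_record("q", method="questionnaire", prevalence=0.10)]
        once = correct_corpus(corpus, rules)
        assert once[0].corrected
        assert once[0].prevalence == pytest.approx(0.071)
        twice = correct_corpus(once, rules)
        assert twice == once  # no-op via provenance flag

    def test_clinical_records_never_corrected(self, rules):
        corpus = [make_record("c", method="clinical", prevalence=0.10)]
        assert correct_corpus(corpus, rules)[0].prevalence == pytest.approx(0.10)


# ---------------------------------------------------------------------------
# hypothesis properties

_record_strategy = st.builds(
    StudyEstimate,
    study_id=st.sampled_from([f"s{i}" for i in range(8)]),
    sample_id=st.sampled_from(["a", "b"]),
    n=st.integers(min_value=2, max_value=500),
    events=st.none(),
    prevalence=st.floats(min_value=0.0, max_value=1.0, allow_nan=False, width=32),
    method=st.sampled_from(["clinical", "questionnaire"]),
    months_post_exposure=st.one_of(
        st.none(), st.floats(min_value=0.0, max_value=24.0, allow_nan=False)
    ),
    prevalence_type=st.sampled_from(["point", "period", "unknown"]),
    population=st.sampled_from(["general", "help_seeking", "clinical_setting"]),
    exposure_specific=st.sampled_from(["yes", "no", "unknown"]),
    wave=st.one_of(st.none(), st.integers(min_value=1, max_value=5)),
)


@settings(max_examples=60, deadline=None)
@given(
    corpus=st.lists(_record_strategy, min_size=1, max_size=15),
    perm_seed=st.integers(min_value=0, max_value=10**6),
)
def test_property_permutation_invariance(corpus, perm_seed):
    corpus = list(dict.fromkeys(corpus))  # identical records are interchangeable
    base = screen_corpus(corpus)
    order = list(range(len(corpus)))
    random.Random(perm_seed).shuffle(order)
    permuted = screen_corpus([corpus[i] for i in order])
    for pos, i in enumerate(order):
        assert permuted[pos] == base[i]


@settings(max_examples=60, deadline=None)
@given(corpus=st.lists(_record_strategy, min_size=1, max_size=15))
def test_property_screening_idempotent(corpus):
    kept = included_records(corpus, screen_corpus(corpus))
    if kept:
        assert all(d.included for d in screen_corpus(kept))
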