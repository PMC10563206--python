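"""Engine semantics: condition evaluation, selection, post-processing.

The central check is an independent brute-force oracle: a naive
re-implementation of the whole pipeline (evaluate every rule on every
case, then post-process with plain loops) must agree with
``run_surveillance`` on hundreds of randomized cases.
"""

import datetime as dt

import numpy as np
import pytest

from haisurv import CaseTuple, EngineConfig, run_surveillance
from haisurv.engine import (
    WarningResult,
    apply_rti,
    apply_thresholds,
    classify_onset,
    evaluate_condition,
    match_rules,
    select_per_diagnosis,
)
from haisurv.rules import Condition, filter_by_source


def _case(registry, as_of=dt.date(2020, 1, 6), admission=dt.datetime(2020, 1, 1, 9), **factors):
    case = CaseTuple(patient_id="P1", episode_id="E1", as_of_date=as_of)
    case.set("PS", registry.make("admission_datetime", admission))
    case.set("PS", registry.make("hospital_days", (as_of - admission.date()).days + 1))
    for fid, value in factors.items():
        case.set(registry[fid].group, registry.make(fid, value))
    return case


class TestEvaluateCondition:
    def test_in_range_is_closed_open(self, registry):
        cond = Condition("body_temperature_max", "in_range", (38.0, 39.0))
        assert evaluate_condition(cond, _case(registry, body_temperature_max=38.5))
        assert evaluate_condition(cond, _case(registry, body_temperature_max=38.0))
        assert not evaluate_condition(cond, _case(registry, body_temperature_max=39.0))

    def test_missing_factor_is_false(self, registry):
        cond = Condition("pleural_wbc", "gt", 1000)
        assert not evaluate_condition(cond, _case(registry))
        assert evaluate_condition(cond, _case(registry, pleural_wbc=1500.0))

    @pytest.mark.parametrize("op,ref,value,expected", [
        ("eq", 1, 1, True), ("eq", 1, 0, False), ("ne", 1, 0, True),
        ("lt", 5, 4, True), ("le", 5, 5, True), ("gt", 5, 5, False),
        ("ge", 5, 5, True), ("contains_flag", None, 1, True), ("contains_flag", None, 0, False),
    ])
    def test_comparison_semantics(self, registry, op, ref, value, expected):
        fid = "urinary_catheter" if op in ("eq", "ne", "contains_flag") else "hospital_days"
        cond = Condition(fid, op, ref)
        case = _case(registry)
        case.set(registry[fid].group, registry.make(fid, value))
        assert evaluate_condition(cond, case) is expected


class TestMatchAndSelect:
    def test_conjunction_requires_all_conditions(self, registry, rule_base):
        rule = rule_base.by_id("10301")  # temp + chest pain + imaging + pleural wbc
        full = _case(registry, body_temperature_max=38.6, chest_pain=1,
                     pleural_effusion_imaging=1, pleural_wbc=1500.0)
        partial = _case(registry, body_temperature_max=38.6, chest_pain=1,
                        pleural_effusion_imaging=1)
        assert any(fr.rule_id == "10301" for fr in match_rules(full, [rule]))
        assert match_rules(partial, [rule]) == []

    def test_highest_probability_per_diagnosis_wins(self, registry, rule_base):
        case = _case(registry, body_temperature_max=38.6, chest_pain=1,
                     pleural_effusion_imaging=1, pleural_wbc=1500.0,
                     pleural_culture_positive=1)
        fired = match_rules(case, rule_base.rules_for("PCI"))
        assert len(fired) > 1
        (best,) = select_per_diagnosis(fired)
        assert best.probability == max(fr.probability for fr in fired)
        assert best.rule_id == "10304"  # 0.95, the etiologically confirmed rule

    def test_probability_tie_broken_by_lowest_rule_id(self):
        from haisurv.engine import FiredRule

        mk = lambda rid: FiredRule(rid, "LRI", "RTI", 0.8, "P1", "E1", dt.date(2020, 1, 6))
        (kept,) = select_per_diagnosis([mk("20105"), mk("20102")])
        assert kept.rule_id == "20102"

    def test_empty_input_empty_output(self):
        assert select_per_diagnosis([]) == []


class TestOnsetClassification:
    @pytest.mark.parametrize("as_of,expected", [
        (dt.date(2020, 1, 1), "community_acquired"),   # 24 - 0 h: same night
        (dt.date(2020, 1, 3), "community_acquired"),   # exactly 48 h
        (dt.date(2020, 1, 4), "hospital_acquired"),    # 72 h > 48 h
    ])
    def test_48h_boundary_strictly_greater(self, registry, as_of, expected):
        case = _case(registry, as_of=as_of, admission=dt.datetime(2020, 1, 1, 0, 0))
        assert classify_onset(case, EngineConfig()) == expected

    def test_cutoff_is_configurable(self, registry):
        case = _case(registry, as_of=dt.date(2020, 1, 2), admission=dt.datetime(2020, 1, 1, 0, 0))
        assert classify_onset(case, EngineConfig(onset_cutoff_hours=12)) == "hospital_acquired"

    def test_missing_admission_time_errors(self, registry):
        case = CaseTuple(patient_id="P1", episode_id="E1", as_of_date=dt.date(2020, 1, 5))
        with pytest.raises(ValueError):
            classify_onset(case, EngineConfig())


def _warning(day, site="RTI", diagnosis="LRI", patient="P1", prob=0.6, status="alerted"):
    return WarningResult(patient_id=patient, episode_id="E1",
                         infection_time=dt.date(2020, 1, day), site_code=site,
                         diagnosis_code=diagnosis, probability=prob, rule_id="r",
                         status=status)


class TestPostProcessing:
    def test_rti_suppresses_same_site_within_window(self):
        w = apply_rti([_warning(1), _warning(10)], rti_days=14)
        assert [x.status for x in w] == ["alerted", "suppressed_rti"]

    def test_rti_allows_recurrence_outside_window(self):
        w = apply_rti([_warning(1), _warning(16)], rti_days=14)
        assert [x.status for x in w] == ["alerted", "alerted"]

    def test_rti_keyed_by_site_not_diagnosis(self):
        w = apply_rti([_warning(1, site="RTI"), _warning(5, site="USI", diagnosis="UTI")],
                      rti_days=14)
        assert [x.status for x in w] == ["alerted", "alerted"]

    def test_suppressed_warnings_do_not_consume_window(self):
        # day-1 warning below threshold: day-10 same-site warning must alert
        first = _warning(1, prob=0.2)
        second = _warning(10)
        apply_thresholds([first], {"LRI": 0.5})
        w = apply_rti([first, second], rti_days=14)
        assert [x.status for x in w] == ["below_threshold", "alerted"]

    def test_threshold_rejection_is_strict(self):
        w = [_warning(1, prob=0.60), _warning(2, site="USI", diagnosis="UTI", prob=0.70)]
        apply_thresholds(w, {"LRI": 0.70, "UTI": 0.70})
        assert [x.status for x in w] == ["below_threshold", "alerted"]

    def test_unconfigured_diagnosis_always_passes(self):
        w = [_warning(1, prob=0.05)]
        apply_thresholds(w, {})
        assert w[0].status == "alerted"


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_condition(cond, case):
    fv = case.get(cond.factor_id)
    if fv is None:
        return False
    v, ref = fv.value, cond.operand
    return {
        "eq": lambda: v == ref, "ne": lambda: v != ref,
        "lt": lambda: v < ref, "le": lambda: v <= ref,
        "gt": lambda: v > ref, "ge": lambda: v >= ref,
        "in_range": lambda: ref[0] <= v < ref[1],
        "contains_flag": lambda: v == 1,
    }[cond.operator]()


def _oracle_pipeline(cases, rules, config):
    """Naive evaluate-every-rule re-implementation of the full pipeline."""
    out = []
    for case in sorted(cases, key=lambda c: (c.patient_id, c.as_of_date, c.episode_id)):
        fired = [r for r in rules
                 if all(_oracle_condition(c, case) for c in r.conditions)]
        per_diag = {}
        for r in fired:
            cur = per_diag.get(r.diagnosis_code)
            if cur is None or r.probability > cur.probability or (
                    r.probability == cur.probability and r.rule_id < cur.rule_id):
                per_diag[r.diagnosis_code] = r
        adm = case.get("admission_datetime").value
        hours = (dt.datetime.combine(case.as_of_date, dt.time()) - adm).total_seconds() / 3600
        for r in sorted(per_diag.values(), key=lambda r: r.rule_id):
            status = "alerted" if hours > config.onset_cutoff_hours else "community_acquired"
            if status == "alerted" and r.probability < config.thresholds.get(r.diagnosis_code, 0):
                status = "below_threshold"
            out.append([case.patient_id, case.episode_id, case.as_of_date,
                        r.site_code, r.diagnosis_code, r.probability, r.rule_id, status])
    last = {}
    for row in out:
        if row[7] != "alerted":
            continue
        key = (row[0], row[3])
        prev = last.get(key)
        if prev is not None and (row[2] - prev).days < config.rti_days:
            row[7] = "suppressed_rti"
        else:
            last[key] = row[2]
    return out


def _random_cases(registry, n, seed):
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        patient = f"P{int(rng.integers(1, 20)):03d}"
        admission = dt.datetime(2020, 1, int(rng.integers(1, 15)), int(rng.integers(0, 24)))
        as_of = admission.date() + dt.timedelta(days=int(rng.integers(0, 12)))
        case = CaseTuple(patient_id=patient, episode_id=f"E{i:03d}", as_of_date=as_of)
        case.set("PS", registry.make("admission_datetime", admission))
        case.set("PS", registry.make("hospital_days", (as_of - admission.date()).days + 1))
        for spec in registry:
            if spec.id in ("admission_datetime", "hospital_days"):
                continue
            if rng.random() < 0.3:
                continue  # leave factor missing
            if spec.kind == "binary":
                v = int(rng.integers(0, 2))
            elif spec.kind == "integer":
                v = int(rng.integers(0, 100))
            elif spec.kind == "real":
                v = float(np.round(rng.uniform(0, 2000), 1))
                if spec.id == "body_temperature_max":
                    v = float(np.round(rng.uniform(35, 42), 1))
            else:
                continue
            case.set(spec.group, registry.make(spec.id, v))
        cases.append(case)
    return cases


def test_engine_equals_bruteforce_oracle(registry, rule_base):
    cases = _random_cases(registry, 200, seed=13)
    config = EngineConfig(thresholds={"LRI": 0.55, "PCI": 0.7})
    got = run_surveillance(cases, rule_base, config)
    expected = _oracle_pipeline(cases, filter_by_source(rule_base, config.scenario).rules, config)
    assert [[w.patient_id, w.episode_id, w.infection_time, w.site_code,
             w.diagnosis_code, w.probability, w.rule_id, w.status] for w in got] == expected


class TestSurveillanceInvariants:
    def test_deterministic_output(self, registry, rule_base):
        cases = _random_cases(registry, 100, seed=5)
        a = run_surveillance(cases, rule_base, EngineConfig())
        b = run_surveillance(list(reversed(cases)), rule_base, EngineConfig())
        assert [w.to_dict() for w in a] == [w.to_dict() for w in b]

    def test_at_most_one_alert_per_patient_diagnosis_day(self, registry, rule_base):
        warnings = run_surveillance(_random_cases(registry, 200, seed=3), rule_base, EngineConfig())
        keys = [(w.patient_id, w.diagnosis_code, w.infection_time, w.episode_id)
                for w in warnings if w.status == "alerted"]
        assert len(keys) == len(set(keys))

    def test_no_two_alerts_same_patient_site_within_window(self, registry, rule_base):
        warnings = run_surveillance(_random_cases(registry, 200, seed=3), rule_base, EngineConfig())
        alerted = [w for w in warnings if w.status == "alerted"]
        for i, a in enumerate(alerted):
            for b in alerted[i + 1:]:
                if a.patient_id == b.patient_id and a.site_code == b.site_code:
                    assert abs((a.infection_time - b.infection_time).days) >= 14

    def test_raising_thresholds_never_increases_alerts(self, registry, rule_base):
        cases = _random_cases(registry, 150, seed=17)
        counts = []
        for t in (0.0, 0.55, 0.8, 1.0):
            w = run_surveillance(cases, rule_base,
                                 EngineConfig(thresholds={d: t for d in ("LRI", "UTI", "PCI")}))
            counts.append(sum(1 for x in w if x.status == "alerted"))
        assert counts == sorted(counts, reverse=True)

    def test_guideline_firings_subset_of_combined(self, registry, rule_base):
        cases = _random_cases(registry, 100, seed=23)
        guideline = filter_by_source(rule_base, "guideline_only")
        for case in cases:
            sub = {fr.rule_id for fr in match_rules(case, guideline.rules)}
            full = {fr.rule_id for fr in match_rules(case, rule_base.rules)}
            assert sub <= full

    def test_confirmed_infections_not_realerted(self, registry, rule_base, clean_cohort):
        from haisurv import build_cases, default_lexicon

        records, gold = clean_cohort
        cases = build_cases(records, default_lexicon(), registry)
        with_feedback = run_surveillance(cases, rule_base, EngineConfig(),
                                         confirmed_labels=gold)
        confirmed_sites = {(lb.episode_id, lb.site_code) for lb in gold if lb.infected}
        for w in with_feedback:
            if (w.episode_id, w.site_code) in confirmed_sites:
                assert w.status != "alerted"
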