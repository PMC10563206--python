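import datetime as dt

import numpy as np
import pytest

from haisurv import (
    CohortSpec,
    ConfusionCounts,
    EngineConfig,
    build_cases,
    default_lexicon,
    generate_cohort,
    metrics,
    run_surveillance,
    score_episode_level,
    stratified_report,
)
from haisurv.cases import GoldLabel
from haisurv.engine import WarningResult


def _gold(eid, infected, diagnosis=None, site=None, month="2020-01"):
    onset = dt.datetime(2020, 1, 10) if infected else None
    return GoldLabel(patient_id="P" + eid[1:], episode_id=eid, infected=infected,
                     diagnosis_code=diagnosis, site_code=site,
                     onset_datetime=onset, report_month=month)


def _warn(eid, diagnosis="LRI", site="RTI", status="alerted", day=10):
    return WarningResult(patient_id="P" + eid[1:], episode_id=eid,
                         infection_time=dt.date(2020, 1, day), site_code=site,
                         diagnosis_code=diagnosis, probability=0.6, rule_id="r",
                         status=status)


class TestMetrics:
    def test_screening_triple(self):
        acc, sen, spe = metrics(ConfusionCounts(tp=8, fn=2, tn=85, fp=5))
        assert sen == pytest.approx(0.8)
        assert spe == pytest.approx(85 / 90)
        assert acc == pytest.approx(0.93)

    def test_zero_denominators_are_missing(self):
        assert metrics(ConfusionCounts()) == (None, None, None)
        acc, sen, spe = metrics(ConfusionCounts(tn=10))
        assert sen is None and spe == 1.0 and acc == 1.0

    def test_counts_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestEpisodeScoring:
    def test_perfect_recovery(self):
        gold = ([_gold(f"E{i:03d}", 1, "LRI", "RTI") for i in range(10)]
                + [_gold(f"E{i:03d}", 0) for i in range(10, 100)])
        warnings = [_warn(f"E{i:03d}") for i in range(10)]
        counts = score_episode_level(warnings, gold)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (10, 90, 0, 0)
        assert metrics(counts)[1:] == (1.0, 1.0)

    def test_partial_sensitivity(self):
        gold = [_gold(f"E{i:03d}", 1, "LRI", "RTI") for i in range(100)]
        warnings = [_warn(f"E{i:03d}") for i in range(83)]
        counts = score_episode_level(warnings, gold)
        assert metrics(counts)[1] == pytest.approx(0.83)

    def test_no_infected_episodes_leaves_sen_undefined(self):
        gold = [_gold("E001", 0), _gold("E002", 0)]
        counts = score_episode_level([], gold)
        acc, sen, spe = metrics(counts)
        assert sen is None and spe == 1.0

    def test_site_match_granularity(self):
        gold = [_gold("E001", 1, "LRI", "RTI")]
        wrong_site = [_warn("E001", diagnosis="UTI", site="USI")]
        assert score_episode_level(wrong_site, gold, match="site").fn == 1
        assert score_episode_level(wrong_site, gold, match="any").tp == 1

    def test_non_alerted_warnings_do_not_count(self):
        gold = [_gold("E001", 1, "LRI", "RTI"), _gold("E002", 0)]
        warnings = [_warn("E001", status="below_threshold"),
                    _warn("E002", status="suppressed_rti")]
        counts = score_episode_level(warnings, gold)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (0, 1, 0, 1)

    def test_unknown_episode_in_warnings_errors(self):
        with pytest.raises(ValueError, match="E999"):
            score_episode_level([_warn("E999")], [_gold("E001", 0)])


class TestStratifiedReport:
    def _fixture(self):
        gold = [
            _gold("E001", 1, "LRI", "RTI", month="2020-01"),
            _gold("E002", 1, "UTI", "USI", month="2020-02"),
            _gold("E003", 0, month="2020-01"),
            _gold("E004", 0, month="2020-02"),
        ]
        warnings = [_warn("E001"), _warn("E002", diagnosis="UTI", site="USI")]
        return gold, warnings

    def test_monthly_counts_sum_to_overall(self, catalog):
        gold, warnings = self._fixture()
        report = stratified_report({"guideline_plus_expert": warnings}, gold, catalog)
        overall = report.lookup("overall", "overall", "guideline_plus_expert")
        months = [r for r in report.rows if r.stratum_type == "month"]
        summed = sum((r.counts for r in months), ConfusionCounts())
        assert (summed.tp, summed.fp, summed.fn, summed.tn) == (
            overall.counts.tp, overall.counts.fp, overall.counts.fn, overall.counts.tn)

    def test_month_without_episodes_has_all_missing_metrics(self, catalog):
        gold, warnings = self._fixture()
        report = stratified_report({"s": warnings}, gold, catalog,
                                   months=["2020-01", "2020-02", "2020-03"])
        empty = report.lookup("month", "2020-03", "s")
        assert (empty.acc, empty.sen, empty.spe) == (None, None, None)

    def test_per_diagnosis_true_negative_pool_is_large(self, catalog):
        gold, warnings = self._fixture()
        report = stratified_report({"s": warnings}, gold, catalog)
        lri = report.lookup("diagnosis", "LRI", "s")
        # 1 TP; the other 3 episodes carry neither an LRI label nor warning
        assert (lri.counts.tp, lri.counts.tn) == (1, 3)
        assert lri.spe == 1.0

    def test_expert_rules_add_sensitivity(self, catalog):
        gold, _ = self._fixture()
        guideline_w = [_warn("E002", diagnosis="UTI", site="USI")]
        combined_w = guideline_w + [_warn("E001")]
        report = stratified_report(
            {"guideline_only": guideline_w, "guideline_plus_expert": combined_w},
            gold, catalog)
        sen_g = report.lookup("overall", "overall", "guideline_only").sen
        sen_c = report.lookup("overall", "overall", "guideline_plus_expert").sen
        assert sen_c > sen_g

    def test_average_is_unweighted_over_defined_strata(self, catalog):
        gold, warnings = self._fixture()
        report = stratified_report({"s": warnings}, gold, catalog)
        sens = [r.sen for r in report.rows if r.stratum_type == "site" and r.sen is not None]
        assert report.average("site", "s", "sen") == pytest.approx(sum(sens) / len(sens))

    def test_unknown_stratum_key_rejected(self, catalog):
        with pytest.raises(ValueError):
            stratified_report({"s": []}, [], catalog, by=["weekday"])


def _random_eval_fixture(n, seed):
    rng = np.random.default_rng(seed)
    diags = ["LRI", "UTI", "PCI"]
    sites = {"LRI": "RTI", "UTI": "USI", "PCI": "RTI"}
    gold, warnings = [], []
    for i in range(n):
        eid = f"E{i:05d}"
        month = f"2020-{int(rng.integers(1, 4)):02d}"
        infected = rng.random() < 0.1
        if infected:
            d = diags[int(rng.integers(3))]
            gold.append(_gold(eid, 1, d, sites[d], month=month))
        else:
            gold.append(_gold(eid, 0, month=month))
        if rng.random() < 0.12:
            d = diags[int(rng.integers(3))]
            status = "alerted" if rng.random() < 0.8 else "below_threshold"
            warnings.append(_warn(eid, diagnosis=d, site=sites[d], status=status))
    return gold, warnings


def test_metrics_match_independent_recount_on_random_fixture(catalog):
    """Eq-style metric computation vs a naive per-episode recount."""
    gold, warnings = _random_eval_fixture(1000, seed=31)
    counts = score_episode_level(warnings, gold)
    # naive recount over the warning/gold join
    alerted_sites = {}
    for w in warnings:
        if w.status == "alerted":
            alerted_sites.setdefault(w.episode_id, set()).add(w.site_code)
    tp = sum(1 for g in gold if g.infected and g.site_code in alerted_sites.get(g.episode_id, set()))
    fn = sum(1 for g in gold if g.infected) - tp
    fp = sum(1 for g in gold if not g.infected and g.episode_id in alerted_sites)
    tn = sum(1 for g in gold if not g.infected) - fp
    assert (counts.tp, counts.fn, counts.fp, counts.tn) == (tp, fn, fp, tn)
    acc, sen, spe = metrics(counts)
    assert acc == pytest.approx((tp + tn) / len(gold))
    assert sen == pytest.approx(tp / (tp + fn))
    assert spe == pytest.approx(tn / (tn + fp))


@pytest.mark.parametrize("q", [0.0, 0.2, 0.5])
def test_sensitivity_degrades_with_factor_dropout(q, registry, rule_base, lexicon, catalog):
    """Parameter recovery: q=0 gives SEN=SPE=1; dropout degrades SEN only."""
    spec = CohortSpec(seed=11, n_patients=300, prevalence=0.05,
                      dropout_q=q, note_noise=0.0)
    records, gold = generate_cohort(spec)
    cases = build_cases(records, lexicon, registry)
    warnings = run_surveillance(cases, rule_base, EngineConfig())
    acc, sen, spe = metrics(score_episode_level(warnings, gold, catalog))
    assert spe == 1.0
    if q == 0.0:
        assert sen == 1.0
    else:
        assert sen < 1.0
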