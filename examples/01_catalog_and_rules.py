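"""Inspect the packaged infection catalog and exemplar decision tables.

Prints the site/diagnosis inventory and one parsed knowledge rule, to
show how decision-table rows become executable conjunctive rules.
"""

from haisurv import default_catalog, default_registry, default_rule_base

catalog = default_catalog()
registry = default_registry()
rules = default_rule_base(registry, catalog)

print(f"catalog: {len(catalog.site_codes())} infection sites, "
      f"{len(catalog.diagnosis_codes())} diagnoses")
print(f"respiratory-tract (RTI) diagnoses: {catalog.diagnoses_for_site('RTI')}")
print(f"rule base: {len(rules.rules)} rules over diagnoses {rules.diagnoses()}")

rule = rules.by_id("10301")
print(f"\nrule {rule.rule_id} ({rule.source}) -> {rule.diagnosis_code} "
      f"[site {rule.site_code}] with probability {rule.probability}")
for cond in rule.conditions:
    print(f"  {cond.factor_id} {cond.operator} {cond.operand}")
# Every condition must hold on a surveillance day for the rule to fire;
# the probability becomes the warning's infection probability.
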