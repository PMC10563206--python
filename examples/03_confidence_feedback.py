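"""Monthly confidence feedback for one rule.

Starts a rule at confidence 0.5 and feeds it several months of review
feedback at a constant 90% confirmation rate: the confidence converges
toward the observed accuracy (the update's fixed point).
"""

from haisurv import ConfidenceState, FeedbackBatch, monthly_update, update_confidence

print("single step: Pr=0.5, Acc=1.0 ->", update_confidence(0.5, 1.0))
print("fixed point: Pr=0.8, Acc=0.8 ->", update_confidence(0.8, 0.8))

state = ConfidenceState(pr={"10301": 0.5})
for month in range(1, 7):
    batch = FeedbackBatch(f"2020-{month:02d}", {"10301": (10, 9)})  # 90% confirmed
    state = monthly_update(state, batch)
    print(f"2020-{month:02d}: Pr = {state.pr['10301']:.4f}")
# The trajectory approaches 0.9, the constant confirmation rate.
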