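# Liverpool ADR Causality Assessment Tool decision flowchart.
#
# Transcribed as data so the engine can validate the structure: the graph is
# acyclic, every node is reachable from Q1, every traversal ends in one of the
# four ordinal causality categories, and the unrolled decision tree has exactly
# 36 root-to-outcome paths.  A "definite" outcome is reachable only through a
# positive answer on Q5a (past history of the same event with the same drug in
# the same patient) or Q5b (positive rechallenge).
#
# Response coding: a positive response is "Yes" everywhere except Q3a, where
# "Unassessable" (single-dose / intermittent / unstoppable therapy, so that
# dechallenge cannot be observed) also counts as positive, and Q4a, where the
# positive response is "Low" and "High" or "Unsure" count as negative.
start: Q1
nodes:
  Q1:
    text: Is there a temporal relationship between administration of the drug and the event?
    on_positive: Q2a
    on_negative: unlikely
  Q2a:
    text: Was the drug withdrawn?
    on_positive: Q3a
    on_negative: Q2b
  Q2b:
    text: Was the dose of the drug reduced?
    on_positive: Q3a
    on_negative: unlikely
  Q3a:
    text: Did the event improve after withdrawal of the drug or reduction of the dose?
    positive_label: Yes / Unassessable
    negative_label: "No"
    on_positive: Q4a
    on_negative: Q3b
  Q3b:
    text: Is the event likely to be irreversible, so that no improvement on dechallenge would be expected?
    on_positive: Q4a
    on_negative: unlikely
  Q4a:
    text: What is the probability that the event was due to an underlying disease?
    positive_label: Low
    negative_label: High / Unsure
    on_positive: Q5a
    on_negative: Q4b
  Q4b:
    text: Is there any objective evidence supportive of the causal ADR mechanism?
    on_positive: Q5b
    on_negative: possible
  Q5a:
    text: Has the patient previously experienced the same event with the same drug?
    on_positive: definite
    on_negative: Q5b
  Q5b:
    text: Did the event recur on re-administration of the drug (positive rechallenge)?
    on_positive: definite
    on_negative: Q6
  Q6:
    text: Is the event a previously described reaction to this drug?
    on_positive: probable
    on_negative: possible
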