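"""The two-item worked example: states, IRPs and NPC assignment.

A test with q-vectors [1,0] and [1,1] measures two attributes, so there
are four candidate knowledge states.  Under the conjunctive rule an
examinee answers an item correctly only if they master every attribute it
measures, which yields the ideal response patterns printed below; an
examinee who answers [1,0] is then classified into state [1,0] at
Hamming distance 0.
"""

from npcda import (
    QMatrix,
    ResponseMatrix,
    build_irp_table,
    enumerate_states,
    npc_classify,
)

q = QMatrix([[1, 0], [1, 1]], item_ids=("item1", "item2"),
            attribute_names=("A1", "A2"))
space = enumerate_states(2)

print(f"{space.states.shape[0]} candidate knowledge states\n")
table = build_irp_table(q, space, "conjunctive")
print("Conjunctive ideal response patterns (rows = states):")
print(table.to_frame(), "\n")

y = ResponseMatrix([[1, 0]], examinee_ids=("student",), item_ids=q.item_ids)
result = npc_classify(y, q)
print("Observed pattern [1, 0] is assigned state",
      result.state_strings()[0], "at distance", result.distances[0])
print("(the examinee masters attribute 1 but not attribute 2)")
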