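"""Interolog transfer: the ortholog cross-product rule on a tiny example.

A human interaction (A, B) is transferred to coral through its ortholog
groups.  A has two coral co-orthologs (post-speciation duplicates), so the
single source edge expands into two coral interlogs — a network expansion.
A homodimer shows both expansion conventions.
"""

from netfootprint import SourceEdge, TFSet, infer_interlogs
from netfootprint.orthology import OrthologGroup, OrthologMap

omap = OrthologMap("HS", "AM")
omap.add_group(OrthologGroup("1", "HS", "AM", (("A", 1.0),),
                             (("a1", 1.0), ("a2", 0.8))))
omap.add_group(OrthologGroup("2", "HS", "AM", (("B", 1.0),), (("b1", 1.0),)))
maps = {("HS", "AM"): omap}

tf_sets = {
    "HS": TFSet("HS", frozenset({"A", "B"}),
                {"A": ("PF00046",), "B": ("PF00170",)}),
    "AM": TFSet("AM", frozenset({"a1", "a2", "b1"}),
                {"a1": ("PF00046",), "a2": ("PF00046",), "b1": ("PF00170",)}),
}

edge = SourceEdge("HS:A--B", "A", "B", "HS", evidence="M2H")
nets = infer_interlogs([edge], maps, tf_sets, ["AM"])
print("heterodimer (A,B) with orth(A)={a1,a2}, orth(B)={b1}:")
for e in nets["AM"].edges:
    print(f"  AM interlog {e.a}--{e.b}  (from {e.source_edge_ids[0]})")
print("  -> one source edge, two interlogs: a lineage-specific expansion\n")

loop = SourceEdge("HS:A--A", "A", "A", "HS")
for mode in ("full", "diagonal"):
    nets = infer_interlogs([loop], maps, tf_sets, ["AM"],
                           homodimer_mode=mode)
    pairs = sorted(e.endpoints for e in nets["AM"].edges)
    print(f"homodimer (A,A), {mode} mode: {pairs}")
print("  full takes all paralog pairs; diagonal keeps two separate homodimers")
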