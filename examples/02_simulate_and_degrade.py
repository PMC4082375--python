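"""Simulate a simple history and degrade it into an inference problem.

A five-segment chromosome evolves through four epochs of whole-genome
replication or DCJ rearrangement with per-branch substitutions.  The
full scenario H is then stripped to its observable leaves (plus bare
homology trees) and lightly degraded, producing the kind of ambiguous
seed graph an aligner would give us.  The printed bounds show how much
of H's true cost is still pinned down by G alone.
"""

from historygraph import bounds_report, simple_history_costs, simulate_pair

h, g, log = simulate_pair(seed=7)
s, r = simple_history_costs(h)
print(f"true scenario H: {len(h.vertices())} vertices, "
      f"{s} substitutions, {r} DCJ operations")
print(f"seed graph G: {len(g.vertices())} vertices after reduction and "
      f"10% degradation ({len(log)} logged reduction operations)")
b = bounds_report(g)
print(f"G's bounds: substitutions in [{b.s_l}, {b.s_u}], "
      f"rearrangements in [{b.r_l}, {b.r_u}]")
print(f"sandwich holds: {b.s_l <= s} (s), {b.r_l <= r} (r)")
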