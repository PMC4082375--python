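"""Read a history graph and compute its parsimony cost bounds.

Builds the worked ambiguous example — three leaf threads descending from
a short ancestral chromosome, with one inferred internal allele — and
prints its ambiguities and the four cost bounds.  Any full evolutionary
scenario explaining this graph needs at least LBSC substitutions and
LBRC DCJ operations, and scenarios exist needing no more than UBSC and
UBRC; the gap is what the ambiguity counts measure.
"""

from historygraph import bounds_report
from historygraph.fixtures import fixture

f = fixture("fig2b")
g = f.graph
print(f"vertices: {len(g.vertices())}, adjacencies: "
      f"{len(g.adjacencies())}, threads: {len(g.threads())}")
b = bounds_report(g)
print(f"substitution ambiguity u_s = {b.u_s}")
print(f"rearrangement ambiguity u_r = {b.u_r}")
print(f"substitutions needed: between {b.s_l} (LBSC) and {b.s_u} (UBSC)")
print(f"DCJ operations needed: between {b.r_l} (LBRC) and {b.r_u} (UBRC)")
print(f"unambiguous (an AVG)? {b.is_avg}")
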