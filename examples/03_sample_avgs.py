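"""Sample unambiguous interpretations (AVGs) of a degraded graph.

Random walks apply G-bounded extension operations — root labelings,
bridge labels, junction-side attachments, bridge adjacencies — until the
graph becomes unambiguous, pruning any walk whose lower-bound cost
exceeds the best AVG found so far.  The summary row mirrors the
sampling-study table: ambiguities, bounds, and the retained AVGs' cost
spread.
"""

import random

from historygraph import sample_avgs, simulate_pair

h, g, _ = simulate_pair(seed=7)
report = sample_avgs(g, n_starts=50, rng=random.Random(7))
row = report.table_row()
print("seed graph:    u_s=%(u_s)d  s_l=%(s_l)d  s_u=%(s_u)d   "
      "u_r=%(u_r)d  r_l=%(r_l)d  r_u=%(r_u)d" % row)
print("retained AVGs: s in [%(s_min)s, %(s_max)s], "
      "r in [%(r_min)s, %(r_max)s]  "
      "(%(retained)d retained, %(pruned)d pruned of %(starts)d)" % row)
print(f"best interpretation costs {report.best.s} substitutions + "
      f"{report.best.r} rearrangements = {report.best.cost}")
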