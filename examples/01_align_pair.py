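"""Align one pair of sequences and inspect score, CIGAR, and counters.

The single-matrix backtrace recovers the alignment path from the M matrix
alone: when an M cell is not explained by its diagonal neighbour, the gap
ending there is resolved by testing return scores s(l) = M[i][j] - o - l*e
against stored M cells for growing gap length l.
"""

from singletrack import PenaltySet, align

q, t = "GCA", "GCCAA"
p = PenaltySet.affine_default()  # a=0, x=4, o1=6, e1=2

res = align(q, t, p, engine="classic", backtrace="singletrack")
print(f"query  = {q}")
print(f"target = {t}")
print(f"score  = {res.score}")            # total alignment cost (minimized)
print(f"cigar  = {res.cigar} ({res.cigar.expanded()})")
print(f"stored cells   = {res.stats.cells_stored_peak}")   # M + one column + one scalar
print(f"explored cells = {res.stats.cells_explored}")      # probes + committed steps
# The CIGAR MMIIM says: two matches, a two-base insertion (costing
# o1 + 2*e1 = 10), then one more match -- total cost 10.
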