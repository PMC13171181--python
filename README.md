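# singletrack

Gap-affine and dual gap-affine pairwise sequence alignment with a
single-matrix backtrace, for people who need optimal global alignments of
long or many sequences without paying the memory bill of classical
dynamic programming.

## The problem and the idea

Optimal gap-affine alignment (match `a`, mismatch `x`, gap of length `l`
costing `o1 + l·e1`; dual mode `min(o1 + l·e1, o2 + l·e2)`) is classically
computed with three DP matrices — `M`, `I1`, `D1` — or five in dual mode,
all of size `(n+1)×(m+1)`, kept alive only so the backtrace can walk them.

The indel matrices, however, depend only on `M` and themselves.  During
backtrace, when an `M` cell is not explained by its diagonal predecessor,
the gap ending there can be resolved *without reading any indel score*:
advance tentative insertion/deletion paths over growing gap length `l`
and test the closed-form return score

    s(l) = M[i][j] − o_k − l·e_k

against `M[i][j−l]` (insertion) and `M[i−l][j]` (deletion).  The first
equality found certifies an optimal path through a length-`l` gap of
class `k`.  The backtrace stays linear-time (exploring at most 2× the
cells of the classical backtrace, 4× in dual mode) while only `M` is
stored — roughly a 3× (gap-affine) or 5× (dual) storage reduction.

The same idea carries to two modern formulations, both included:

* **Suzuki-Kasahara difference encoding** (`sk` engine): stores the
  adjacent-cell differences `dH`, `dV` of `M` (2 matrices instead of 4)
  and traces on the shifted matrix `M′ = M − M[n][m]`, reconstructed on
  the fly — the single-matrix tests are shift-invariant.
* **Wavefront alignment** (`wfa` engine, requires `a = 0`): stores only
  the `M` wavefronts (1 vector per score instead of 3 or 5); indel
  wavefronts live in a small cyclic scope during the forward pass and gap
  returns are confirmed by furthest-reaching-point coverage.

## Worked example

```python
from singletrack import PenaltySet, align

res = align("GCA", "GCCAA", PenaltySet.affine_default())  # (0, 4, 6, 2)
print(res.score, res.cigar, res.cigar.expanded())
```

prints

```
10 2M2I1M MMIIM
```

two matches, a two-base insertion costing `o1 + 2·e1 = 10`, one more
match: total cost 10.  Every engine/backtrace combination returns the
same score (`examples/02_engines_and_storage.py` prints the full grid
with storage and exploration counters); `examples/` also shows synthetic
dataset generation and summaries.

The CLI wraps the same library:

```
singletrack align --query GCA --target GCCAA --engine classic --backtrace singletrack
1	10	2M2I1M
```

Note the CIGAR orientation: `I` consumes a target character and `D` a
query character (the DP convention used throughout); pass `--sam-cigar`
for SAM semantics (I/D swapped).

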