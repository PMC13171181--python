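# Methods

## Problem and cost model

The package computes optimal global pairwise alignments of DNA/protein
sequences under *minimized* integer costs.  A match costs `a` (default 0),
a mismatch `x` (with `x > a`), and a maximal gap of length `l` costs
`o1 + l·e1` (gap-affine) or `min(o1 + l·e1, o2 + l·e2)` (dual gap-affine).
The dual model prices short sequencing-error gaps (low open, high extend)
and long single-event gaps (high open, low extend) with different slopes.
Default penalties follow widely used mapper defaults: gap-affine
`(a, x, o1, e1) = (0, 4, 6, 2)`, dual adds `(o2, e2) = (24, 1)`.  An
edit-distance preset `(0, 1, 0, 1)` is exposed as a `PenaltySet`
constructor, not as a separate engine.

Character comparison is case-insensitive; bytes outside `{A, C, G, T}`
are compared literally (no ambiguity-code matching).  All scores are
exact integers; unreachable states use a per-alignment infinity sentinel
larger than `(n+m)·max(x, o1+e1, o2+e2)` with saturating addition.

CIGAR orientation: `I` consumes a target character (horizontal DP move)
and `D` a query character (vertical move).  `Cigar.to_sam()` and the CLI
flag `--sam-cigar` swap I/D for SAM interoperability; the swap is the
single most surprising convention in the package and is documented on
every surface that emits CIGARs.

## Classical engine

The gap-affine recurrences over `M`, `I1`, `D1` (plus `I2`, `D2` in dual
mode) are filled column-wise with standard initialization: `M[0][0] = 0`,
`I1[0][j] = o1 + j·e1`, `D1[0][j] = ∞`, `M[0][j] = gap_cost(j)`, and
symmetrically for column 0.  These boundary values reproduce the worked
reference instance (`q=GCA`, `t=GCCAA`, score 10 with CIGAR `MMIIM`) and
agree with the brute-force oracle on every tested instance.

Two storage modes:

* `fill_full` keeps all matrices — `3·(n+1)(m+1)` stored cells, `5·` in
  dual mode — and supports the classical backtrace.
* `fill_m_only` keeps only `M` plus, transiently, one column of `I1`
  (and `I2`) and one carried scalar of `D1` (and `D2`):
  `(n+1)(m+1) + (n+1) + 1` cells (dual: `+ (n+1) + 1` more).  The
  resulting state has no indel matrices at all, which structurally
  enforces that the single-matrix backtrace reads only `M`.

The asymptotic stored-cell ratio between the modes is 3 (gap-affine) and
5 (dual); at `n = m = 1000` the measured ratios round to exactly those
integers.

## Single-matrix backtrace

Each indel matrix depends only on `M` and itself, so its cells never need
to be read back.  At an `M` cell not explained by its diagonal
predecessor, the trace opens tentative insertion and deletion paths and
advances them in lock-step over the gap length `l`, testing the
closed-form return score `s(l) = M[i][j] − o_k − l·e_k` against
`M[i][j−l]` (insertion) and `M[i−l][j]` (deletion) for each gap class
`k`.  Soundness of early acceptance: if the equality holds, then an
optimal prefix ending at the return cell plus a length-`l` class-`k` gap
reproduces `M[i][j]` exactly, so the resolved path is optimal even when
it differs from the classical engine's choice.

Determinism and edge handling:

* Diagonal-first: if both the diagonal test and a gap return could hold,
  the diagonal wins (any optimal path is acceptable).
* Gap classes are tested in fixed order I1, D1, I2, D2 at each `l`;
  lock-step advancement makes the first hit a minimal-length resolution.
* At a border (`i = 0` or `j = 0`) only the feasible direction is opened
  and negative-index return cells are skipped.
* Tentative paths are abandoned once `s(l)` falls below the least stored
  value (0 for absolute scores, `−score` in shifted space), and the
  search is capped at `l ≤ max(i, j)`; exceeding the cap raises an
  internal-consistency error rather than looping.

Counting conventions for the exploration bound: the classical backtrace
counts one per landing cell on its path (equal to the number of CIGAR
unit operations); the single-matrix backtrace counts one per `M` cell
probed on any tentative path plus one per committed match/mismatch step.
A gap of length `l` then costs at most `2l` probes (gap-affine; `4l`
dual) against the classical `l` steps, giving the ≤2×/≤4× worst-case
bounds asserted over every random instance in the test suite.

## Difference-encoded (Suzuki-Kasahara) engine

The fill stores `dH[i][j] = M[i][j] − M[i][j−1]` and
`dV[i][j] = M[i][j] − M[i−1][j]` with transient per-column indel
differences `dE = I − M`, `dF = D − M` and temporary diagonal difference
`A = M[i][j] − M[i−1][j−1]`:

    A  = min(S(i,j), min(dE[i][j−1]+e, o+e) + dV[i][j−1],
                      min(dF[i−1][j]+e, o+e) + dH[i−1][j])   over classes
    dH[i][j] = A − dV[i][j−1];  dV[i][j] = A − dH[i−1][j]
    dE[i][j] = min(dE[i][j−1]+e, o+e) − dH[i][j]   (dF symmetric)

These recurrences are derived directly from the definitions and validated
against the finite differences of the classical fill.  Stored differences
are bounded by `x + o_max + e_max`, the property that enables narrow
(e.g. 8-bit) encodings in vectorized implementations; this reference
implementation keeps wide integers and asserts the bound instead.
Border values `dH[i][0]`/`dV[0][j]` are undefined and hold a sentinel
that is never read.

The backtrace runs on the shifted matrix `M′ = M − M[n][m]`, anchored at
`M′[n][m] = 0` and reconstructed lazily from `dH`/`dV` (each probe walks
from the nearest memoized cell; memoized values cover only the active
frontier of the trace).  Every single-matrix test is invariant under a
constant shift, so the backtrace logic is shared verbatim with the
classical engine; the score is recovered as `−M′[0][0]`.

Storage: 2 matrices in both penalty modes (`dE`/`dF` are never
retained), versus 4 for a full-retention difference fill — the
structural factor asserted in the tests.  A byte-level memory claim
would additionally depend on element widths and is deliberately not
modeled.  An optional `keep_ef=True` fill retains the indel differences
and supports a classical-style backtrace evaluated purely on
differences; it exists so that every engine offers both backtraces.

## Wavefront engine

For each score `z` and diagonal `k = j − i`, the engine stores the
furthest-reaching target column per component.  Offsets maximize under
the cost-minimizing recurrences; after the max-reduction, `M` offsets are
extended along the diagonal while characters match.  Matches must
therefore be free: the engine requires `a = 0` and refuses otherwise
(the default penalty sets satisfy this; general reparameterization is
out of scope).  The pass terminates at the first `z` whose `M` wavefront
reaches `(n, m)` on diagonal `m − n`.

Baseline mode retains all component wavefronts (3 per score, 5 dual) and
supports the classical wavefront backtrace.  Single-matrix mode retains
only the `M` wavefronts (1 per score); the indel components live in a
cyclic scope of `N = max(x, o1+e1[, o2+e2]) + 1` wavefronts per
component whose slots are recycled as scores leave the dependency
window.  The backtrace resolves gaps by testing whether the return point
lies on the `M` wavefront of score `z − o_k − l·e_k`, with membership of
`(i, j)` defined as: diagonal `j − i` in range and stored
furthest-reaching offset ≥ `j` (coverage semantics; the characters
between `j` and the f.r.p. match by construction).  Matching characters
are consumed greedily as free diagonal steps, which is always optimal
when `a = 0`.

## Synthetic data and oracle

`generate_pair` copies a uniform random base sequence with independent
per-position edits at the requested rate; edit types follow a
(mismatch, insertion, deletion) mix — default equal thirds, a neutral
choice when no platform profile is being emulated — and indel lengths
are geometric with `p = 0.5` (mean 2, matching short sequencing-error
gaps).  One seeded NumPy generator drives all randomness; identical
specs yield byte-identical pairs.  The planted edit count is an upper
bound on the optimal edit count because edits can merge or cancel, and
the realized per-base edit rate can sit slightly above the per-position
rate because one mutated position may plant a multi-base indel; tests
therefore use tolerant intervals.  The generator does not emulate
platform-specific artifacts (homopolymer errors, quality strings), so
passing tests demonstrate algorithmic correctness on realistic error
mixes, not calibration to a particular instrument.

`brute_force_score` enumerates every monotone alignment path recursively
(substitutions plus maximal gap runs, same-type runs never adjacent),
costing runs with the same rule as `cigar_cost` but sharing no DP
machinery with the engines.  It is exponential and capped at length 8;
the suite uses it on ~500 random pairs with `n, m ≤ 6` in both penalty
modes.

## Problem sizes used by the test and acceptance suites

Oracle comparisons use 500 pairs at `n, m ≤ 6`; cross-engine checks use
200 generated pairs with lengths 50–200 at error rates 1–15% in both
penalty modes; the storage-ratio check fills one `1000 × 1000` instance
per mode.  These sizes exercise every code path (multi-class gaps, long
runs, boundary gaps) while keeping the default suite fast enough for
routine development runs.

## Known limitations

* Global alignment only; no semi-global/ends-free/local modes, banding,
  drops, or early termination.
* No SIMD/narrow-integer kernels; the difference boundedness is asserted,
  not exploited.
* The wavefront engine requires `a = 0`.
* Wall-clock and peak-RSS behaviour is hardware-dependent and is not
  measured; the structural stored-cell and explored-cell counters are the
  package's instrumentation for memory and backtrace-work claims.
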