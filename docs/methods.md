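# Methods

## Model

Two (or three) input lists are assumed to be ranked by significance, most
significant first, with unique identifiers within each list. Any prefix of
a list is treated as an unordered "top-k" set. The background population
(universe) of the hypergeometric model is the union of the **full** input
lists, fixed once and reused for every cell; an item present in only one
list therefore enlarges the universe but can never contribute to an
overlap. Under the null, the two prefixes are uniformly random subsets of
the universe of their observed sizes, and the overlap statistic is the
upper tail

P(X ≥ k), X ~ Hypergeometric(N, i, j),

with equality P = 1 returned **exactly** when k equals the smallest
possible overlap max(0, i + j − N). The three-list statistic has no
standard closed form; we compute P(|X∩Y∩Z| ≥ k) for independent uniform
subsets of fixed sizes by conditioning on T = |X∩Y| (hypergeometric) and
integrating the conditional tail P(|T′∩Z| ≥ k | T = t) over t — exact, and
validated against seeded Monte Carlo in the test suite.

The model is deliberately order-free *within* a prefix: two lists whose
top-100 items agree as sets but disagree in internal order still score a
perfect overlap at (100, 100). The extreme scenarios make the consequences
visible: identical lists put the optimum at the half length (a
rank-correlation statistic would be the better tool there), and a fully
reversed list never drops below p = 1 because every prefix pair attains
its minimum possible overlap.

## Multiple testing and the optimum

All n·m (or n·m·l) cells form the adjustment pool. Benjamini–Hochberg
step-up is the default; Bonferroni and no adjustment are available. The
optimum is the cell minimising the adjusted p-value. BH's
cumulative-minimum monotonisation routinely produces a plateau of cells
sharing the minimum adjusted value, so ties are resolved by the smallest
**raw** p-value first — the strongest individual overlap inside the
plateau, and the resolution that makes the identical-lists optimum land on
the exact half-length cell rather than the plateau's low-index corner —
then by the smallest prefix-length sum, then lexicographically. The
`not_significant` flag is raised when even the best cell has raw p = 1.

## Traceback

From the optimum the walk steps to whichever admissible predecessor
((i−1, j) or (i, j−1); three predecessors in the cube) has the smaller
adjusted p, ties taking the first list, until the all-ones cell; the walk
is then extended forward from the optimum to the full-lists cell by the
same greedy rule. Reversed, this is the order in which single items are
added from empty diagrams to complete lists — `sum(dims)` steps, each item
exactly once. The first item of each list (added before the grid's 1-based
domain is entered) is emitted in list order with a null p-value, since
cells with an empty prefix are not part of the matrix.

## Numerics

Binomial coefficients are evaluated through a precomputed log-factorial
table (log Γ), tail sums through log-sum-exp; nothing is clamped except
the final cap at 1. P-values are exact to double precision down to
~1e-300, which the result JSON preserves via shortest round-trip float
serialisation. The whole-grid evaluation works one first-list prefix
length at a time, summing all admissible terms for a full row of cells in
one vectorised pass; total work grows with the cube of the list length but
stays at ~2 s for 500-item lists (250,000 cells) on one core. The cube
implementation memoises the conditional tails per distinct (i, j, m, k),
which collapses the cost on structured inputs.

Two-circle layouts solve the centre distance by Brent root bracketing on
the closed-form lens area (monotone non-increasing in distance, so the
root is unique) to relative tolerance ~1e-12; disjoint sets are drawn
externally tangent and containment internally tangent, both exact by
construction. Three-circle layouts solve each pairwise distance the same
way and place the centre triangle, falling back to least squares when the
three distances violate the triangle inequality; exact area
proportionality of all seven regions is impossible for circles in general,
so the worst relative region error is reported as a first-class
`residual`. Region areas behind that residual come from closed forms when
every circle pair is nested or disjoint, and otherwise from
high-resolution polygonal circles (2048 segments), whose discretisation
noise (~1e-5 relative) bounds how small a reported nonzero residual can
meaningfully be.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `method` | `"bh"` | adjustment over all cells: `bh`, `bonferroni`, `none` |
| pair size guard | 3000 items/list | quadratic-cost refusal threshold, `force_large` overrides |
| triple size guard | 400 items/list | cubic-cost refusal threshold |
| heatmap cap | 320 | ceiling for −log10 p where p underflows |
| scored input order | ascending | smaller score = more significant; `descending` flips |

Scored inputs are sorted with a stable sort, so tied scores keep file
order. With `descending`, scores are not attached to the returned list
(the stored convention is ascending); the ranking itself is unaffected.

The run-time estimate is a polynomial in the per-list length (degree 2
for pairs, degree 3 for triples) fitted on calibration runs; the shipped
coefficients keep only the dominant even-power term so predictions are
non-negative and monotone. It is advisory only — it feeds the size-guard
message and `--estimate-only`, never control flow.

## Synthetic data

The fixtures module generates the four extreme scenarios (identical,
seeded shuffle, full reversal, 20%/80% in-place block reversal — boundary
at round(f·n)) and seeded random ranked pairs whose shared fraction and
rank concordance are controlled. These emulate rank structure only: no
realistic score distributions, no measurement noise, no tied significance
levels. Tests passing on them demonstrate the combinatorics, the tail
computation and the optimisation machinery — not robustness to the messiness
of real expression data, where the ranking itself carries estimation error
that this model treats as exact.

## Design choices on genuinely open points

- **Universe**: union of the full input lists (the statistic's N), not a
  platform-wide background. Comparisons against tools using an external
  background will differ accordingly.
- **Reported p**: raw and adjusted are always reported side by side; the
  optimum is selected on the adjusted value.
- **Optimum tie-break**: smallest raw p, then index sum, then
  lexicographic (see above).
- **Traceback ties**: take the first list — deterministic and symmetric
  under relabelling rather than data-driven.
- **Merged-list order** in the >3-list greedy reduction: overlap items in
  order of their first addition step along the pair's traceback, so the
  merged list inherits a significance ranking from the path.
- **Prefix indexing** is 1-based with no empty-prefix row/column: a
  candidate Venn diagram must take at least one item from each list.
- **Three-list heuristic vs cube**: for three lists both the exact cube
  optimum and the greedy pairwise reduction are available; they answer
  different questions and the package never substitutes one for the other.

## Known limitations

- Cells are scored independently; no pruning of provably insignificant
  regions and no parallelism, so the cube is practical only to a few
  hundred items per list.
- More than three lists get only the greedy pairwise heuristic, which is
  order-dependent and not an exact multiway optimum.
- Adjacent grid cells are strongly dependent, which BH does not model;
  the adjusted values control FDR over the cell family in the usual
  step-up sense, not under arbitrary dependence.
- Three-circle diagrams are approximate by construction; inspect
  `residual` before trusting region areas quantitatively.
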