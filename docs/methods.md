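# Methods

## Model

`chromoswarm` infers a single-chromosome 3D structure from a Hi-C
interaction-frequency (IF) matrix under the standard distance-method
assumption: contact frequency decays monotonically with spatial
separation, inverted as

    D_ij = 1 / IF_ij ** β

for every bin pair with IF_ij > 0. The exponent β ("conversion
factor") controls how sharply frequency maps to distance. Pairs with
IF = 0 are treated as *unobserved* and excluded from the objective via
a mask — a missing contact is not evidence of maximal separation, and
no imputation rule is assumed. The diagonal is always excluded.

Raw targets are unbounded as IF → 0 and carry no absolute scale, so
all defined targets are rescaled by one common factor such that the
largest equals 1.0. This puts the targets at the same scale as the
default particle initialization range and changes no distance ratio,
hence no optimum and no correlation score.

## Optimization

Coordinates are optimized by particle swarm. Each particle is a full
N×3 candidate structure with an N×3 velocity, a personal-best memory
and a shared global best. Every iteration updates every coordinate
cell:

    V ← w·V + c1·R1·(Pbest − P) + c2·R2·(Gbest − P)
    P ← P + V

with R1, R2 fresh uniform [0,1) draws *per cell* (per-cell draws
explore a wider set of geometries than one draw per particle).
Personal and global bests are replaced only on strict improvement, so
the global best score is non-increasing by construction; the invariant
is asserted every iteration.

Parameters, with units of the normalized target scale:

| parameter | default | meaning |
|---|---|---|
| `swarm_size` (ss) | 15 | particles in the swarm |
| `max_iterations` (itt) | 30000 | iteration cap |
| `threshold` | 1e-6 | stop when global best improves less than this per window |
| `rand_range` | 1.0 | initial coordinates uniform in ±rand_range |
| `w_start`, `w_end` | 0.9, 0.4 | inertia, linear decay over the budget |
| `c1`, `c2` | 2.0, 2.0 | cognitive / social weights |
| `patience` | 100 | iterations per stop-check window |
| `stall_windows` | 5 | consecutive sub-threshold windows before stopping |

The first four defaults are the published tool's. Inertia decay
0.9 → 0.4 with c1 = c2 = 2 are the canonical swarm settings; all are
exposed in `SwarmConfig` so other values can be substituted. Velocity
components are clamped to ±rand_range (a standard divergence
safeguard, switchable off).

**Stop rule.** A plain "improvement over the last 100 iterations <
threshold" rule proved too aggressive: on the 20-bin helix fixture the
swarm routinely shows an exact-zero-improvement window mid-run and then
resumes improving, so a single stalled window stopped runs at ~300
iterations far from convergence. The rule therefore requires
`stall_windows = 5` consecutive sub-threshold windows (500 stalled
iterations at the defaults) before declaring convergence.

## Losses

Over the `ncount` masked unordered pairs, with residuals r = d − D:

* MSE = mean(r²), RMSE = √MSE, SSE = sum(r²)
* Huber = mean(h(r)), h(r) = r²/2 for |r| ≤ α, else α(|r| − α/2), α = 0.5

These satisfy RMSE² = MSE and SSE = ncount·MSE identically, and the
Huber branches join continuously (both equal α²/2 at |r| = α); the
test suite asserts all three. `ncount` counts *pairs*, not bins: the
sums run over pairs, and pair-counting is what makes the stated
identities hold. The integer selector maps 0→RMSE, 1→MSE, 2→SSE,
3→Huber.

## Evaluation and β search

Final structures are scored by the Pearson correlation (PCC) between
realized and expected distances of the masked pairs, and the Spearman
correlation (SCC), i.e. Pearson on average-rank transforms (average
ranks are the standard generalization when ties occur). Both are
computed with scipy.stats; constant input raises rather than silently
returning 0.

β is grid-searched over 0.1–1.5 in steps of 0.1 by default (bounded,
desk-scale, and bracketing the values used in published
distance-method work): the full reconstruction runs at each candidate
and the β with the highest final SCC wins, ties going to the smaller
β. Note that on noiseless data the *target ranks* are identical for
every β (a power transform is monotone), so SCC discriminates β
through attainability: only the generating exponent yields a target
set exactly embeddable in 3-space, so the swarm fits it best. On the
noiseless helix fixture the search reliably returns the generating
β at a 5000-iteration budget.

## Synthetic fixtures

The generator inverts the distance law: from a known curve with
pairwise distances d, it emits IF_ij = (1/d_ij)^(1/β), so conversion
with the same β reproduces the true distances up to the global rescale
(checked to 1e-9 in the tests). Available curves: a helix (radius 1,
~unit spacing between consecutive bins), a circle with unit arc
spacing, and a seeded unit-step random walk that rejects steps landing
within 0.7 units of an earlier bin. Optional noise is multiplicative
log-normal per unordered pair — IF values are positive and span orders
of magnitude, so additive noise would create negatives.

What the fixtures do *not* emulate: Hi-C count overdispersion,
genomic-distance decay profiles, domain (TAD) block structure,
normalization artifacts, or unmappable regions. Passing the recovery
tests therefore demonstrates that the optimizer solves the
distance-embedding problem it is given, not that real contact maps
satisfy the distance law.

Recovery tests default to 20 bins and a 5000-iteration budget: at
these sizes ten seeded reconstructions finish in seconds while leaving
the swarm enough iterations to converge (SCC ≈ 0.995, run-to-run SCC
spread ≈ 0.003–0.011).

## Numerical choices and edge cases

* Square input asymmetric by a relative 1e-6 or less is repaired as
  (M + Mᵀ)/2 (text-precision artifacts); larger asymmetry is an error.
* Sparse bin coordinates are divided by the gcd of all distinct
  coordinates, mapping both genomic positions (e.g. multiples of 1 Mb)
  and raw indices to 0-based indices with one rule.
* Duplicate sparse pairs after canonical (i ≤ j) ordering are an input
  error; expansion to square additionally rejects conflicting values.
* Best-replacement ties keep the incumbent (deterministic given the
  seed); with one seed, runs are bit-reproducible.
* PDB output multiplies coordinates by a scale factor (default: the
  structure spans 100 units) because optimizer coordinates live at
  O(1) and would collapse at the format's three-decimal precision;
  coordinates that would overflow the fixed 8.3 columns raise before
  any file is written. Beads are CA pseudo-atoms of residue `BIN`
  chained by CONECT records for viewer compatibility.

## Limitations

* Single chromosome, single resolution; no .hic/.cool input, no
  normalization of raw counts.
* One swarm, one structure: no ensemble modelling of cell-to-cell
  variability (a `replicates` option reruns with derived seeds and
  keeps the best-SCC structure).
* β is assumed shared by all pairs; no per-distance confidence
  weighting.
* The objective is non-convex; correlation scores near 1 on synthetic
  fixtures do not guarantee global optimality on real, noisy maps.
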