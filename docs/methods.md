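# Methods

This note records the package's scientific conventions: the model behind
each stage, the parameters that matter, the choices made where several
reasonable conventions exist, and what the synthetic-data tests do and do
not demonstrate about real data.

## Scaling PSMC output to natural units

A `psmc` output file contains one block per EM iteration; the last block
is taken as the converged estimate (an explicit round index can override
this). Within a block, only θ₀ from the `TR` line and the (t_k, λ_k)
pairs from the `RS` lines are consumed; all other line codes are skipped,
and trailing `RS` columns are ignored.

The conversion to individuals and years is the standard PSMC plotting
math. One unit subtlety is load-bearing: the mutation rate supplied by
the user is **per year** (default 2.3×10⁻⁹ /site/year), while PSMC's θ is
per generation, so the per-generation rate μ_gen = μ_year · g (g = 2.5 yr
by default) is formed internally before

    N₀ = θ₀ / (4 μ_gen s),   t_yr = 2 N₀ t_k g,   N_e = λ_k N₀,

with s the bin size (default 100 sites/bin). These constants rescale the
axes only; they do not change the shape of any trajectory, so the rank
statistics downstream are insensitive to moderate errors in them.

## Truncation and the per-lineage variables

Steps whose recent boundary t_k falls below 50 kyr are dropped — PSMC
estimates are unreliable near the present — with no interpolation of the
straddling segment; fewer than two surviving steps is an error naming the
taxon. The truncation cutoff is configurable.

Mean and SD of N_e are computed **unweighted over the retained steps**
(population form, divisor n) by default. Two alternatives exist behind
flags because the convention is genuinely underdetermined for this kind
of summary: `sd_ddof=1` for the sample form, and `time_weighted=True` to
weight each step by its interval width (the oldest step bounds the domain,
has no width, and is excluded from weighted moments).

The early-growth variables anchor at two points of the step function
read oldest → most recent:

- the **trough** is always the oldest retained step (the lineage's PSMC
  inception);
- the **peak** is located by one of two conventions.
  `first_turning` (default): the first step at which the running
  direction of change reverses *and* the cumulative relative change since
  the origin exceeds ε (default 0.05, a filter against step-noise
  wiggles); a monotone trajectory peaks at its most recent step.
  `global`: the maximum-N_e step, except when the maximum is the origin
  itself — an initially declining lineage — in which case the minimum is
  used, making degree = 1 − N_trough/N_peak negative, as observed for one
  resident lineage in the packaged table (degree −0.75).

Both conventions give identical results on curves with one dominant rise,
and the packaged-table statistics do not depend on the choice. When the
peak coincides with the trough (deltaT = 0), the rate is reported as an
explicit missing value rather than ±∞, so rank tests can exclude it with
a logged count.

## Group contrasts

The Mann–Whitney statistic is reported as

    U = Σ_{r ∈ residents, m ∈ migrants} [x_r > x_m] + ½[x_r = x_m],

i.e. the count of resident-beats-migrant pairs, so *small* U favors the
one-tailed alternative "migrants > residents" (the direction fixed by the
study's predictions; the output echoes it so orientation errors are
auditable). The complementary orientation n₁n₂ − U is also reported. The
p-value is exact by full enumeration of all C(n₁+n₂, n₂) label
assignments whenever n₁+n₂ ≤ 16 (3003 labelings at the 8+6 design;
ties are handled implicitly by enumerating the actual values), and a
tie-corrected normal approximation with continuity correction beyond
that. No multiple-testing adjustment is applied across the five
variables.

Two columns of a published-style table deserve a caution that the test
suite freezes rather than hides. Rank statistics computed from *rounded*
table columns can differ from those computed from full-precision values:
on the packaged table, the CV contrast gives U = 8.5 if taken from the
2-decimal CV column but U = 9 when CV is recomputed as SD/mean from the
table's own mean and SD columns — the pipeline therefore recomputes CV
from those columns whenever both are present. The rate contrast gives
U = 27 in this package's orientation (complement 21) and is far from
significance in either orientation. Group descriptive rows use the
sample SD (divisor n − 1).

## Phylogenetic-signal screen

The Abouheif–Moran test is purely topological. For tips i ≠ j the
proximity is A_ij = 1/∏ dd(v) over every internal node v on the i→j path
(the MRCA and all intermediate internal nodes), dd(v) = number of
children; the diagonal holds the row complement so each row sums to 1.
The statistic Cmean = Σ_{i≠j} W_ij z_i z_j / n uses z standardized with
divisor n and W the off-diagonal proximities row-normalized over
off-diagonal mass. Significance is one-tailed (greater) by permuting the
tip-to-value assignment, 999 permutations by default, with the add-one
estimator p = (1 + #{≥ observed})/(n_perm + 1); an exhaustive mode
enumerates all n! relabelings on small trees and is used as the oracle in
tests. Branch lengths are ignored by construction; trees are treated as
rooted as written.

The pipeline runs the screen per variable and proceeds to the group
contrast only for variables with signal p > 0.05; gated variables are
reported with status `not_run`, and `--force` overrides the gate. No
numeric reference values exist for this stage, so its tests are
property-based: a hand-derived 3-tip proximity matrix ({½, ¼, ¼} with
diagonal ¼), exhaustive-permutation agreement, affine invariance,
seeded reproducibility, and type-I-error calibration.

## Synthetic cohorts

The generator emulates the *post-inference* statistical structure of PSMC
results, not the inference itself: trajectories are built directly as Ne
step functions on a log-spaced grid (64 steps from 10 kyr plus a present-
day step at t = 0, up to the lineage origin) and converted to coalescent
scaling only on emission. Four phases, oldest to newest: origin at
`origin_time` with `origin_Ne`; log-linear growth to `peak_Ne` over
`growth_duration` (the target deltaT); a plateau modulated by a
glacial-cycle sinusoid (period 100 kyr) riding on a 30% secular decline;
and a recent decline of fraction `recent_decline`. Two numerical choices
matter here. Each plateau step carries the *interval average* of the
sinusoid, because a step function cannot resolve wiggles shorter than its
own intervals — point-sampling would alias whole glacial cycles against
the log-spaced grid and relocate the apparent historic maximum by
millions of years. The secular decline, besides matching the broadly
observed pattern that recent populations sit below their historic peaks,
guarantees the historic maximum is unique on the discrete grid, so both
peak conventions recover `growth_duration` to within one grid step.

Default archetypes: migrant-like lineages originate 4 Myr ago at
N_e = 10⁴, grow over 3 Myr to a peak of 8×10⁵ with 10% cycle amplitude
and 50% recent decline; resident-like lineages originate 2 Myr ago, grow
over 1.5 Myr to 2×10⁵ with 5% amplitude and 30% decline. These spans
match the deltaT range (≈0.6–4.3 Myr) and the group ordering of the
packaged table. Cohorts default to 8 migrants + 6 residents on a Yule
tree (birth rate 1), group labels either concentrated in a clade
(default, as in the real clade) or random; per-taxon parameters are
jittered lognormally (σ = 0.3 on sizes, 0.15 on times). Emission applies
multiplicative lognormal noise (σ = 0.1) to the relative sizes, emulating
bootstrap-replicate wobble; noise-free emission round-trips bit-exactly
through the parser and scaler.

What passing the synthetic suite shows: the parsing/scaling/summary
machinery is exact; the growth-variable estimators recover known truth to
grid resolution; the contrast has high power at the designed effect sizes
and correct size under exchangeable groups; the signal test has
calibrated type-I error on trees of the study's size. What it does not
show: robustness to PSMC inference artifacts (recent-time parameter
peaks, structure-driven pseudo-size-changes), non-lognormal estimation
error, or correlated errors between time and size — none of which the
generator models.

## Problem sizes and runtime

The test suite and the acceptance script are desk-scale by design: exact
enumeration at C(14,6) = 3003, 100-replicate power and 200-replicate size
simulations of the full parse→scale→summarize→test pipeline, and 500
trait simulations × 999 permutations for signal calibration; everything
completes in seconds on one core.

## Known limitations

- The peak-location convention on strongly non-monotone real curves is a
  judgment call; both conventions are provided and flagged, but published
  per-lineage tables rarely state theirs.
- The packaged 14-taxon tree is a synthetic stand-in constrained only by
  coarse, well-established relationships; signal-screen outcomes on it
  (e.g. deltaT tripping the gate in the worked example) illustrate the
  conditional logic and are not statements about the real clade.
- The exact test's enumeration limit (combined n ≤ 16) is far below the
  normal-approximation crossover most software uses; above it the
  tie-corrected approximation is standard but not exact.
- Replicate envelopes aggregate already-computed replicate PSMC files;
  the package does not generate bootstrap input sequences.
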