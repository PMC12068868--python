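# paleopop

Comparative paleodemography from PSMC output.

`paleopop` is for population geneticists who have run PSMC (the pairwise
sequentially Markovian coalescent) on one genome per lineage across a clade
and want to compare the resulting demographic histories between groups of
lineages — here, seasonally migratory versus resident songbird lineages.
The package converts raw `psmc` output files into effective-population-size
trajectories in natural units, derives per-lineage growth statistics,
screens each statistic for phylogenetic signal, and contrasts the groups
with an exact nonparametric test. A synthetic-data generator produces
complete PSMC-format cohorts with known truth, so the pipeline can be
exercised and calibrated without any sequencing data.

## The model and statistics

PSMC reports a piecewise-constant history in coalescent units: relative
sizes λ_k over scaled times t_k with a base scale θ₀. With a per-year
mutation rate μ (default 2.3×10⁻⁹ /site/year), generation time g (default
2.5 yr) and bin size s (default 100 sites), the conversion to natural
units is

```
μ_gen = μ · g,    N₀ = θ₀ / (4 μ_gen s),    t_yr = 2 N₀ t_k g,    N_e = λ_k N₀
```

Steps more recent than 50 kyr are discarded (PSMC is unreliable there).
Each lineage is then summarized by five variables:

- **mean N_e** and **SD of N_e** over the retained steps, and their ratio
  **CV = SD/mean**;
- the early-growth triple anchored at the oldest retained step (the
  lineage's *PSMC inception*, the trough) and its first historic extremum
  (the peak):
  **degree** = 1 − N_trough/N_peak (negative if the lineage initially
  declined), **deltaT** = t_trough − t_peak (years), and
  **rate** = degree / deltaT (yr⁻¹).

Before group comparison, each variable is screened for phylogenetic
autocorrelation with the Abouheif–Moran test (Moran's I with the
topological Abouheif proximity matrix; significance by tip permutation).
Variables without signal are contrasted between groups with a one-tailed
Mann–Whitney U test whose p-value is exact: full enumeration of all
C(n₁+n₂, n₂) group-label assignments of the pooled values (3003 labelings
at 8 + 6), which handles ties without approximation.

## Worked example

The package ships a 14-lineage thrush statistics table (8 migrants, 6
residents) and a synthetic stand-in tree. Contrasting the groups:

```
$ paleopop table-mode --packaged --force --output-dir out --seed 1
variable    U  U_complement  n1  n2  p_exact            method            direction  signal_p status
 mean_ne  7.0          41.0   8   6 0.014652 exact_enumeration migrants > residents     0.081 tested
      cv  9.0          39.0   8   6 0.029637 exact_enumeration migrants > residents     0.080 tested
  degree  9.0          39.0   8   6 0.026640 exact_enumeration migrants > residents     0.127 tested
    rate 27.0          21.0   8   6 0.668998 exact_enumeration migrants > residents     0.875 tested
  deltaT  9.0          39.0   8   6 0.029637 exact_enumeration migrants > residents     0.026 tested
overall mean deltaT = 2.51 Myr (range 0.63-4.29)
```

Reading this: U counts (resident > migrant) pairs, so small U supports
"migrants larger". Migrants have significantly larger mean N_e (U = 7,
exact p ≈ 0.015), CV, degree of early growth and deltaT (U = 9 each,
p < 0.05), while the *rate* of early growth does not differ (p ≈ 0.67).
Early growth phases are strikingly long — 0.63 to 4.29 Myr, averaging
2.51 Myr. Without `--force`, a variable whose signal screen comes out
significant on the supplied tree (here deltaT, signal_p = 0.026 on the
packaged *synthetic* stand-in topology) is reported with its contrast
marked `not_run`, mirroring the design that group tests are only
meaningful for phylogenetically independent variables.

A fully synthetic run from raw PSMC-format files:

```
paleopop simulate --out cohort --seed 3
paleopop run-all --manifest cohort/manifest.tsv --tree cohort/tree.nwk \
    --output-dir cohort_out --seed 1 --force
```

which writes `lineage_stats.tsv` (per-lineage table), `signal.tsv`,
`contrasts.tsv`, `group_descriptives.tsv` and a run log.

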