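# mpmrisk

Demographic and life-history correlates of extinction risk, computed
from stage-structured matrix population models (MPMs).

Comparative demography asks whether a species' pattern of survival,
growth and reproduction predicts how threatened it is. Databases such
as COMPADRE and COMADRE store thousands of published projection
matrices `A = U + F + C` (survival/growth, sexual recruitment, clonal
recruitment); the IUCN Red List provides an ordinal threat rank
(LC < NT < VU < EN < CR, coded 1–5); published phylogenies provide the
non-independence structure among species. `mpmrisk` implements the
full analysis chain linking the three, for ecologists who want to run
it on real matrix tables or stress-test it on synthetic data with
known truth:

1. **Metric derivation** — per matrix: net reproductive rate
   `R0 = λ_dom(F (I-U)^-1)`, generation time `T = log R0 / log λ`,
   Keyfitz entropy of survivorship, Demetrius entropy of the
   net-fertility schedule (degree of iteroparity), first-passage age
   at maturity, mature life expectancy, mean reproduction,
   progressive/retrogressive growth, and the elasticities
   `E_ij = (A_ij/λ) v_i w_j / (v·w)`.
2. **Juvenile/adult collapse** — stages are split at the first
   reproducing stage and collapsed with stable-stage-distribution
   weights (which preserves `λ` exactly), yielding juvenile survival,
   adult survival, average post-reproductive-census fecundity, and the
   elasticities of growth to juvenile and adult survival: fourteen
   species-level metrics in all.
3. **Importance screen** — a 1000-tree regression forest (mtry = 4) on
   species-mean metrics vs Red List rank, ranked by conditional
   permutation importance (permutation within strata of correlated
   covariates); predictors are kept when their importance is at least
   twice the magnitude of the most negative importance.
4. **Phylogenetic regression** — generalized least squares with
   Brownian covariance scaled by Pagel's λ (REML-estimated), starting
   from all interactions among the selected predictors and pruning the
   non-significant ones, highest order first; variance explained is
   `1 - var(residuals)/var(response)`.

A synthetic-data module generates the three inputs jointly — random
valid MPMs along a fast–slow continuum, Yule phylogenies, and ordinal
statuses from a latent linear score with phylogenetically structured
noise — so every stage is testable without downloads. See
`docs/methods.md` for conventions, assumptions and limitations.

## Worked example

Simulate 40 species whose endangerment is driven by generation time
(standardized slope +1.2), with 20% of species unassessed, then run
the full pipeline:

```sh
mpmrisk simulate --n-species 40 --seed 8 --effect generation_time=1.2 \
    --missing-frac 0.2 --out data/
mpmrisk run-all --matrices data/matrices.csv --statuses data/statuses.csv \
    --trees data/tree.nwk --out run/ --seed 4
```

The run report (`run/report.md`) prints:

```
## Importance screen

Selected predictors (threshold 0.03368): generation_time, iteroparity

## PGLS

           term  estimate       se         t            p
    (Intercept)  3.047206 0.452111  6.739951 2.139635e-07
generation_time  1.149976 0.294462  3.905345 5.170011e-04
    iteroparity -0.114414 0.293805 -0.389423 6.998081e-01

- Pagel's lambda: 0.590
- variance explained: 50.6%
- n species: 32
```

Reading this: the screen shortlists generation time (the true driver)
plus the correlated iteroparity metric; the phylogenetic regression
then separates them — generation time keeps a strong positive effect
(+1.15 per standard deviation, near the simulated +1.2), iteroparity
is correctly non-significant, their interaction was pruned, and the
estimated Pagel's λ of 0.59 reflects the simulated phylogenetic signal
(truth 0.5). The same commands accept any matrix table, status CSV and
Newick file following the documented schema (`mpmrisk metrics --help`,
`mpmrisk pgls --help` for the individual stages).

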