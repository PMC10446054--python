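# pedconnect

Pedigree-based functional connectivity for plant populations in fragmented
landscapes.

Small, isolated habitat patches are expected to suffer from reduced gene
flow, yet some patchy populations thrive. One way to find out why is to
reconstruct a multigenerational pedigree from codominant markers and read
dispersal directly off it: every offspring whose two parents are known is an
*effective dispersal event*, and events whose far parent sits on another
patch measure *functional connectivity* — the fraction of recruits that link
patches. Whether that connectivity matters in the long run depends on the
reproductive success of the migrant-derived plants themselves (*effective
connectivity*).

`pedconnect` implements this whole chain for hermaphroditic, self-incompatible
perennials genotyped at microsatellite loci (the motivating system is a
six-patch population of wild snapdragons separated by seawater, surveyed over
ten annual cohorts):

* **`simdata`** — a forward-in-time, spatially explicit simulator: gravity
  seed dispersal (exponential kernel, mean ~4 m), mostly-local pollination
  with a configurable between-patch pollination probability *m*, Mendelian
  transmission over an 18-locus panel, genotyping error and missingness, and
  a full ground-truth pedigree.
* **`genotype_io`** — genotype table container, CSV and `.dat` dialects,
  missing-data QC (loci with ≥5% missing dropped, then individuals with
  ≥10%), duplicate-genotype search.
* **`popgen`** — H<sub>obs</sub>, H<sub>exp</sub> (with the *n*/(*n*−1)
  correction), PIC, allelic richness, Nei's H<sub>S</sub> ± SE, parent-pair
  exclusion probability (PP<sub>exp</sub>, cumulated as 1 − Π(1 − P<sub>l</sub>)),
  Hardy–Weinberg tests, and Weir & Cockerham's θ<sub>ST</sub> from per-allele
  variance components *a*, *b*, *c* (multilocus θ = Σa ⁄ Σ(a+b+c)) with
  permutation p-values.
* **`parentage`** — per-offspring Bayesian parent-pair assignment: posterior
  over all eligible candidate pairs plus "one/both parents unsampled"
  alternatives, genotyping-error-aware triad likelihoods, age/year
  constraints, triads retained only above posterior 0.95.
* **`pedigree`** — triad-only pedigree graph, relationship-category counts
  (full/half sibs, grandparents, avuncular, cousins), family decomposition
  and generation depth.
* **`connectivity`** — dispersal events (closest parent = seed parent,
  farthest = pollen donor), global / per-patch inbound-outbound / pairwise
  connectivity, self-recruitment, Spearman distance-decay test, patch
  distance matrices.
* **`demofit`** — annual growth rates λ = N<sub>T</sub>/N<sub>T−1</sub> and a
  negative-binomial regression of offspring number on dispersal status
  (migrant-derived vs resident), patch fixed effects, cluster-robust errors.
* **`pipeline` / `cli`** — a declarative YAML config and a `pedconnect`
  command that runs everything end to end, with a manifest and summary.

## Worked example

The numbered scripts under `analysis/` run the study-like analysis on
simulated data (6 patches, 10 cohorts, m = 0.03, migrant fecundity ×2):

```sh
PYTHONPATH=analysis python analysis/01_simulate.py
PYTHONPATH=analysis python analysis/02_qc_genotypes.py
...
PYTHONPATH=analysis python analysis/07_reproductive_success.py
```

which printed, among other things:

```
simulated 3741 plants over 10 years; 3591 non-founders, 106 true between-patch events (3.0%)
mean Hs = 0.670; cumulative parent-pair exclusion = 1.000000
global θST = 0.0954 (permutation p = 0.005)
2915 triads among 3578 evaluated offspring (81% both parents assigned)
global connectivity 3.1% (91/2915 events); mean seed dispersal 3.57 m; mean between-patch pollen dispersal 536 m
distance decay: Spearman rho = -0.75 (p = 0.001)
```

Reading: the assignment retained 2,915 conservative triads; 3.1% of them had
their pollen donor on another patch, close to the generating m = 0.03;
seed dispersal stays within a few meters of the mother while between-patch
pollen moves hundreds of meters; and pairwise connectivity decays with
patch distance. `analysis/08_parameter_recovery.py` repeats the chain on 50
replicate populations per condition to check calibration.

The same pipeline runs from a single config:

```sh
pedconnect all --config config.example.yaml
```

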