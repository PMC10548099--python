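# paleoranges

Quantitative historical biogeography for fossil-rich clades on dated
phylogenies.

Deep-time biogeographic questions — where did a clade originate, how did
it move between landmasses, and did physiology (such as saltwater
tolerance) gate ocean crossings? — require more than reading the fossil
record off a map.  `paleoranges` implements the full analytical chain
used in modern studies of groups like neosuchian crocodyliforms:

* **Occurrence handling** — parse PBDB-flavoured occurrence CSVs with
  palaeocoordinates, drop marine and open-nomenclature taxa, bin records
  into epoch-level time slices, and reduce multi-occurrence taxa to
  geographic midpoints on the sphere.
* **Bioregionalization** — delineate areas of endemism by k-means
  clustering of palaeocoordinates on the unit sphere, choosing the
  cluster count k as the smallest value whose proportion of variance
  explained, PVE = BCSS/TSS, reaches 98%, then link clusters across
  epochs and code taxa into binary presence ranges.
* **Ancestral range estimation** — fit DEC, DIVALIKE and BAYAREALIKE,
  each with or without founder-event speciation (+J), by maximum
  likelihood on the bit-encoded range state space.  Anagenesis follows
  rate(R → R∪{a}) = d·Σ_{i∈R} m_ia and rate(R → R∖{i}) = e, with
  time-stratified dispersal multipliers m_ij = 1/(relative midpoint
  distance) and branches split at stratum boundaries; cladogenetic
  event weights follow y = s = v = (3−j)/3 with jump weight j.  Model
  choice uses AIC/AICc weights and likelihood-ratio tests for the
  nested (M, M+J) pairs; marginal ancestral ranges come from the exact
  two-pass algorithm.
* **Ancestral coordinates** — independently of any area scheme, estimate
  node locations by treating tip coordinates as Brownian-motion traits
  on the 3D unit sphere: exact GLS via message passing, plus an MCMC
  variant giving posterior medians with 95% intervals.
* **Transoceanic skew test** — extract dispersal events from the fitted
  model, classify them against per-stratum land connectivity
  (terrestrial / ambiguous / transoceanic), count minimum and maximum
  transoceanic scenarios, and test for skew between a
  saltwater-tolerant and an intolerant clade with Pearson's χ²
  (E_t = N_to·N_ct/N_T, E_i = N_to·N_ci/N_T; df = 1).
* **Synthetic data** — a first-class generator (birth–death trees with
  fossil tips, forward range histories with known d, e, j and labelled
  dispersal events, von Mises–Fisher occurrence clouds) so every stage
  is testable against known truth.

See `docs/methods.md` for models, assumptions and design decisions.

## Worked example

```python
import paleoranges as pr

# a reproducible synthetic study: tree + range history + occurrences
cfg = pr.SimulationConfig(n_tips=50, root_age=120, seed=7)
tree, history, occs = pr.simulate_dataset(cfg)

# fit two range-evolution models and compare them
fits = [
    pr.GeographicRangeModel(tree, history.presence_matrix(), model=m,
                            conditioning="branch").fit(seed=1)
    for m in ("DEC", "DEC+J")
]
print(fits[0].summary())
print(pr.compare_models(fits)[["model", "lnL", "AIC", "AIC_weight"]])
```

This prints the fit summary and comparison table:

```
Geographic range evolution model fit
============================================
model:        DEC
tips:         65
areas:        4
states:       16
stratified:   False
lnL:          -139.3074
AIC:          282.6148
AICc:         282.8083
converged:    True
--------------------------------------------
d (dispersal)    0.0166409 /Myr
e (extirpation)  0.00334178 /Myr
   model         lnL         AIC  AIC_weight
0    DEC -139.307384  282.614769    0.720236
1  DEC+J -139.253018  284.506035    0.279764
```

The 50 requested extant tips come with 15 fossil terminals (fossil
sampling rate ψ = 0.05/lineage/Myr), and the dispersal and extirpation
rates simulated into the data (d = 0.02, e = 0.01 per Myr) are recovered
within sampling error for a tree this size; founder-event speciation was
not simulated, DEC+J buys essentially no likelihood for its extra
parameter, and plain DEC keeps the higher Akaike weight.

The χ² skew test is equally direct.  A clade with 30 internal nodes and
18 observed transoceanic dispersals against a 10-node clade with 2:

```python
from paleoranges import SkewTestInput, chisq_skew
res = chisq_skew(SkewTestInput("min", O_t=18, O_i=2, N_ct=30, N_ci=10))
print(res.as_dict())
```

```
{'scenario': 'min', 'O_tolerant': 18, 'O_intolerant': 2,
 'E_tolerant': 15.0, 'E_intolerant': 5.0, 'chi2': 2.4, 'p': 0.121335,
 'significant': False}
```

The expected counts 15 and 5 apportion the 20 events by clade size; the
deficit of crossings in the small clade is not significant at this
sample size.

## Command line

```bash
paleoranges simulate --n-tips 80 --seed 3 --outdir demo
paleoranges regionalize demo/occurrences.csv --outdir demo
paleoranges fit demo/tree.nwk demo/geog.txt --models DEC,DEC+J
paleoranges skewtest --n-to 20 --o-tolerant 18 --o-intolerant 2 \
    --n-tolerant 30 --n-intolerant 10
paleoranges run-all config.yaml --outdir out
```

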