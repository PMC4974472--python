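# pa-effect

Do protected areas actually hold more biodiversity than the land around
them — and by how much, globally? `pa-effect` is a Python package for
analysing site-level biodiversity sampled **inside versus outside
terrestrial protected areas** across many independent ecological studies,
in the style of large collated site-comparison databases (many studies,
each with its own taxon pool, sampling method and spatial blocks, with
sites straddling a protected-area boundary).

It is aimed at conservation macroecologists and biodiversity statisticians
who want the full chain — site measures, protection classification,
matched designs, hierarchical models, and the counterfactual effectiveness
algebra — as tested, reusable, seed-reproducible code, exercised end to
end on synthetic data with known ground truth.

## What it computes

**Four site-level measures** from a long community table and a species
range table: within-sample species richness *S*; total abundance *N*;
analytic rarefied richness E[S_n] (hypergeometric expectation at the
study's minimum site total *n*); and endemicity, the reciprocal of the
community-weighted mean log10 geographic range size.

**Protection attributes** by point-in-polygon assignment against a
protected-area register (boundary-inclusive), a four-level IUCN management
factor (unprotected / III-VI / unknown / I-II), size/age classes (young <20
years, small <400 km²), and the within-study **matched-sites** subset that
keeps only land uses present on both sides of the boundary.

**Mixed-effects models** per measure, with study and block-within-study
random intercepts: Poisson (log link, Laplace-approximated maximum
likelihood, optional observation-level intercept for overdispersion) for
richness, Gaussian on transformed scales for the rest; likelihood-ratio
tests and marginality-respecting backward elimination; effects reported as
back-transformed percentage differences, 100·(exp β − 1), with Wald 95%
intervals.

**Global effectiveness.** With site-level biodiversity inside (*i*) and
outside (*o*) protected areas expressed as proportions of the pristine
level, the inside/outside ratio ρ = *i*/*o* (per-land-use model ratios
aggregated by global land-area weights), the protected land fraction *a*
and the global mean biodiversity loss *r* tie together through

    1 − r = a·i + (1 − a)·o        ⇒   o = (1 − r)/(1 + a(ρ − 1)),  i = ρ·o
    e = 1 − (1 − i)/(1 − o)

where *e* is 0 if protected sites are no better than unprotected ones,
100% if they match pristine sites (unbounded both ways). The package also
solves the restrictive-management scenario (all areas managed like IUCN
I-II) and the inverse question: what protected fraction *a′* would deliver
the same outcome by expansion alone. Uncertainty is propagated by seeded
parametric Monte Carlo on the link-scale contrasts.

A synthetic-data generator with exactly known multiplicative protection
effects on richness and abundance makes every stage testable without any
external download; see `docs/methods.md` for the generating mechanism and
its limits.

## Worked example

```python
import numpy as np
import paeffect as pa
from paeffect import glmm, measures, spatial
from paeffect.effectiveness import solve_io, effectiveness

# a synthetic world with a known +10.6% richness effect of protection
w = pa.generate_world(pa.WorldConfig(n_studies=30, sites_per_study=(12, 20),
                                     random_seed=7))
pas = spatial.read_protected_areas(w.protected_areas)
cls = spatial.assign_protection(w.sites, pas)
m = measures.compute_site_measures(w.community, w.sites, w.ranges)
tab = glmm.prepare_analysis_table(m, cls)

spec = glmm.ModelSpec(response="richness",
                      fixed=["protected", "elevation_z", "slope_z",
                             "ag_suitability_z"])
final, fit, trace = glmm.backward_eliminate(tab, spec)
c = glmm.percent_difference(fit, "protected")
rho = float(np.exp(c.estimate))
i, o = solve_io(rho, a=0.154, r=0.136)
print(f"richness inside vs outside: {c.percent_difference:+.1f}% "
      f"(95% CI {c.ci_low:+.1f} to {c.ci_high:+.1f}%)")
print(f"rho={rho:.4f} -> i={i:.4f}, o={o:.4f}, e={100*effectiveness(i,o):.1f}%")
```

prints

```
richness inside vs outside: +11.6% (95% CI +3.7 to +20.1%)
rho=1.1158 -> i=0.9472, o=0.8489, e=65.1%
```

Read: across 499 sites in 30 studies, samples from protected sites held
11.6% more species than unprotected ones after adjusting for elevation,
slope and agricultural suitability (the generating truth is +10.6%, well
inside the interval). If that ratio held globally with 15.4% of land
protected and site-level biodiversity at 86.4% of pristine on average, the
protected-area network would be 65% effective at retaining richness —
protected sites sit about two-thirds of the way from the unprotected
average back to the pristine level.

## Command line

```sh
pa-effect simulate --config world.yaml --out bundle/   # synthetic bundle
pa-effect validate --in bundle/                        # schema/vocabulary checks
pa-effect run --config run.yaml                        # full pipeline -> report.md
pa-effect effectiveness --contrasts contrasts.csv --weights weights.csv \
    --a 0.154 --r 0.136                                # algebra only
```

`run` writes `site_measures.csv`, `sites_classified.csv`,
`sites_matched.csv`, `fits.json`, `contrasts.csv`, `effectiveness.json` and
a human-readable `report.md` with a provenance block (config hash, seed,
version); identical config and seed give byte-identical outputs.

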