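# quadratdyn

Demography and community dynamics from long-term mapped-quadrat data in
semi-arid grasslands: genet tracking from yearly polygon maps, vital-rate
regressions with climate covariates, individual-based and integral
projection models of the multispecies community, negative frequency
dependence as a niche-difference proxy, and the decomposition of climate-
perturbation responses into direct and indirect effects.

## Who this is for

Plant population and community ecologists working with "chart quadrat"
archives — permanently marked 1-m² plots whose perennial plants were
mapped yearly as basal-cover polygons or points — or with any data of
that shape, who want a tested, scriptable pipeline from raw maps to
coexistence and climate-response quantities. Everything runs on plain
delimited-text inputs, and a synthetic-data module generates complete
ground-truth archives so each stage can be validated without historical
data.

## The models in brief

**Crowding (competition) index.** Genet *i* of species *j* experiences
crowding from species *m*:

    w_ijm = Σ_k u_k · exp(−α_jm · d²_ik)

over same-quadrat neighbours *k* (u = neighbour area, cm²; d = centroid
distance, cm; α_jm = interaction spatial scale, cm⁻²): a Gaussian
competition kernel.

**Vital rates.** Survival is Bernoulli with

    logit S = γ_t + φ_g + β·u + ω·w + (crowding×size)·u·w + η·C + Γ·(C·u)

(u = log area, C = five climate covariates + precip×temp interactions;
γ_t year effects, φ_g group effects). Growth of survivors shares the
structure for its mean v̄ and has variance a·exp(b·v̄). Recruit counts per
quadrat are negative binomial (size θ) with Ricker-type mean

    λ_j = N′_j · exp(γ_t + φ_g + ω·√N′ + η·C),    N′ = p·N_q + (1−p)·N̄_group.

**Population models.** An individual-based model (IBM) simulates every
genet with demographic stochasticity; an integral projection model (IPM)
projects per-species size densities n(u, t) through the kernel
K = S·G + fecundity, replacing individual crowding by its spatial
expectation (random heterospecifics; a conspecific "no-overlap" rule).

**Coexistence and perturbations.** The negative-frequency-dependence
slope is −IGR/f_eq, the line through (≈0, invasion growth rate) and
(equilibrium frequency, 0). Climate perturbations (+1% precipitation or
temperature means, +10% variance) are run under common random numbers to
split each species' equilibrium-cover response into full, direct, and
indirect = full − direct effects; a mixed-effects model relates |indirect|
to NFD and the community variance of direct effects across sites.

See `docs/methods.md` for assumptions, estimation details and numerical
choices.

## Worked example

Generate a synthetic two-species archive, track it, fit survival, and
estimate the community's frequency dependence:

```python
import numpy as np
from quadratdyn import synthetic_data as sd
from quadratdyn import (GenetRecord, build_transitions, crowding_table,
                        fit_survival, nfd_analysis, IPM, SizeMesh)

rng = np.random.default_rng(10)
truth = sd.scenario("symmetric-2sp")
arch = sd.generate_quadrat_series(truth, n_quadrats=4, n_years=25, rng=rng)

recs = [GenetRecord(**r) for r in arch.truth_records.to_dict("records")]
trans = crowding_table(build_transitions(recs), arch.community.alphas,
                       ["A", "B"])
fit = fit_survival(trans[trans.species == "A"], ["A", "B"], arch.climate,
                   climate_covariates=["ppt1"])
print(f"size slope     {fit.params.size:.3f}")
print(f"intra crowding {fit.params.crowding['A']:.4f}")

ipm = IPM(arch.community, SizeMesh.default())
res = nfd_analysis(ipm, rng, arch.climate,
                   [int(y) for y in arch.climate.years],
                   n_steps=400, burn_in=300, window=600)
for r in res:
    print(f"{r.species}: f_eq={r.equilibrium_frequency:.2f} "
          f"IGR={r.invasion_growth_rate:.3f} slope={r.nfd_slope:.3f}")
```

Output:

```
size slope     0.864
intra crowding -0.0294
A: f_eq=0.50 IGR=0.119 slope=-0.238
B: f_eq=0.50 IGR=0.123 slope=-0.245
```

The fitted coefficients sit near the generating values (size slope 0.8,
intraspecific crowding −0.02) at this small archive's precision. Both
species sit at equilibrium frequency 0.5 — they are exact demographic
mirror images — with positive invasion growth rates and negative
frequency dependence: each species recovers when rare, the signature of
stabilizing niche differences.

A command-line interface wraps the same pipeline:

```
quadratdyn --seed 1 --out-dir out synth --scenario symmetric-2sp --quadrats 4 --years 25
quadratdyn --seed 1 --out-dir out track out/maps.csv
quadratdyn --seed 1 --out-dir out nfd --scenario symmetric-2sp
quadratdyn --seed 1 --out-dir out perturb --scenario pure-indirect --kind precip
```

Every results table is written with a YAML sidecar embedding the full
configuration and seed, so fixed-seed runs reproduce bit-identically.

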