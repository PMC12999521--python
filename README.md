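# thermotree

Thermal tolerance of tropical insect communities: ramping-assay statistics,
phylogenetic comparative models of critical thermal limits, and a
thermal-death-time engine that converts assay tolerances into heat-coma
risk under present and projected climates.

## The problem

Field surveys of insect communities along elevational gradients measure
upper and lower critical thermal limits (CT_max, CT_min) with ramping
assays: an individual is warmed (or cooled) by 1 °C every 2 min from a
28 °C baseline until it loses coordinated mobility. Three questions follow
from such data, and this package implements the full analysis chain for
all of them:

1. **Community patterns** — how do CT limits, tolerance ranges
   (CT_max − CT_min), and thermal safety margins (CT_max minus the bio1 /
   bio5 climate normals) change along elevation, and does a sublethal
   heat/cold shock (hardening) raise or lower tolerance?
2. **Evolutionary constraint** — is CT_max phylogenetically conserved?
   The package builds OTU-level supertrees (grafting per-family subtrees
   onto a family backbone, even-interpolation age calibration, tip-height
   equalization) and provides ancestral-state reconstruction, Pagel's λ,
   Blomberg's K, Moran's-I correlograms, and phylogenetic regressions
   under Brownian motion (BM) and Ornstein–Uhlenbeck (OU) covariance,
   including the OU evolutionary optimum θ and likelihood-based
   partial-r² variance partitioning.
3. **Climate risk** — the thermal-death-time (TDT) model,
   log₁₀ t_coma = (T_L − T)/z + log₁₀ t_ref, links constant exposure
   temperature to knockdown time via the sensitivity z (°C per tenfold
   change in time). Dynamic assay CT_max values are converted to the
   static anchor T_L by inverting the injury-accumulation integral for a
   linear ramp, and any microclimate series can then be classified
   against an exposure threshold (8 h by default) for current or
   anomaly-shifted (Δbio5) future temperatures.

Every input the pipeline consumes — ultrametric phylogenies with family
structure, traits evolving under stationary OU with an elevation effect,
grid-discretized assay records, diurnal microclimate series, TDT
knockdown times, family-structured protein melting temperatures — can be
generated by `thermotree.synthdata` with known ground truth, so every
estimator ships with parameter-recovery tests and no external downloads.

## Worked example

```python
import numpy as np
from thermotree.synthdata import simulate_tree, simulate_trait_ou, TraitParams
from thermotree.phylo import fit_ou_optimum, pagel_lambda, blomberg_k

tree = simulate_tree(300, seed=1)
trait = simulate_trait_ou(
    tree, TraitParams(beta0=42.2, beta_elev=0.0, alpha=3.0, sigma2=6.0),
    np.zeros(300), seed=1,
)
fit = fit_ou_optimum(tree, trait)
print(f"theta = {fit.theta:.2f} C, alpha = {fit.alpha:.2f}, sigma2 = {fit.sigma2:.2f}")
lam = pagel_lambda(tree, trait)
k = blomberg_k(tree, trait, n_perm=999, seed=1)
print(f"lambda = {lam.lambda_hat:.2f} (p = {lam.p_value:.2g}), "
      f"K = {k.k_hat:.2f} (p = {k.p_value:.3f})")
```

prints

```
theta = 41.98 C, alpha = 2.49, sigma2 = 4.64
lambda = 1.00 (p = 3.3e-53), K = 0.35 (p = 0.001)
```

The OU optimum θ is recovered close to the generative 42.2 °C, the trait
carries full λ signal by construction, and K below 1 reflects the strong
pull toward the optimum. Converting community CT_max quantiles to
tolerance landscapes:

```python
from thermotree.tdt import community_sensitivity, critical_temperature

sens = community_sensitivity([40.0]*110 + [41.0]*150 + [42.0]*250 + [44.0]*490)
for name, p in sens.items():
    print(f"{name}: T_L = {p.t_l:.2f} C, "
          f"8-h critical temperature = {critical_temperature(p, 480):.2f} C")
```

```
q10: T_L = 41.25 C, 8-h critical temperature = 33.20 C
q25: T_L = 42.25 C, 8-h critical temperature = 34.20 C
median: T_L = 43.25 C, 8-h critical temperature = 35.20 C
```

i.e. for the most heat-sensitive 10% of this community (assay CT_max
40 °C), any constant temperature at or above 33.2 °C causes heat coma
within 8 h.

A full synthetic run (simulate → assay stats → phylo → TDT → protein) is
one command:

```sh
thermotree run --seed 1 --n-tips 200 --out demo_out
```

and the individual stages (`thermotree simulate|assay-stats|phylo|tdt|protein`)
operate on CSV/Newick files; see `--help` on each.

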