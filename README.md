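# palaeokit

Radiocarbon and ancient-DNA inference for tiny, degraded, contaminated
skeletal samples.

When only tens of milligrams of dentine or bone are available — a
Palaeolithic infant tooth, a pierced animal-tooth pendant — every stage of
the chronological and genetic workflow has to squeeze information out of
noisy, contaminated measurements. `palaeokit` implements that workflow as a
tested Python library with a thin CLI:

- **Collagen QC** — yield, elemental windows (C% 30–45, N% 11–16, atomic
  C/N 2.9–3.6 with a 3.5–3.6 contamination warning band), two-point
  isotope scale normalization against certified reference materials.
- **Radiocarbon** — F¹⁴C ↔ age conversion, blank correction with full
  error propagation, inverse-variance replicate combination with the
  Ward–Wilson χ² agreement test, calibration against a gridded curve with
  95.4% highest-density ranges, and a one-phase Bayesian model with
  per-date t-type outliers (Student-t(5) × 10^U(0,4) shifts in ¹⁴C space),
  sampled by Metropolis-within-Gibbs with the outlier component
  marginalized analytically.
- **aDNA authentication** — length/MAPQ filtering, PCR-duplicate collapse
  by majority vote, terminal C→T damage profiles in read orientation
  (single-stranded-library model: C→T at both ends), and restriction to
  putatively deaminated fragments (C→T in the first/last three aligned
  bases), which strips undamaged present-day contamination.
- **mtDNA consensus** — pileups and base calls requiring ≥5-fold coverage
  and ≥80% support (else N), haplotype comparison over jointly called
  sites, negative-control contamination checks.
- **Sex typing** — panel-adjusted coverage ratios
  `x_ratio = (Nx_o/Nauto_o)/(Nx_e/Nauto_e)` (and likewise for Y);
  Y-ratio < 0.05 ⇒ female, > 0.2 ⇒ male.
- **TMRCA** — for two mtDNA genomes with *k* observed differences, the
  coalescence-time posterior
  `f(t|k) = (1+Θ)^(1+k)/k! · t^k · e^−(1+Θ)t`, Θ = 2NμL, i.e.
  Gamma(k+1, 1+Θ), with explicit year-scale conventions.
- **f-statistics** — pseudo-haploid random-read genotyping with 3-bp
  terminal trimming, outgroup-f3 and D statistics with weighted block
  jackknife standard errors.
- **Synthetic data** — seeded generators for every input: damaged reads
  with a tunable contaminant fraction, binomial SNP-panel coverage under
  XX/XY truth, replicated AMS measurements with a blank, smooth
  calibration curves, and Balding–Nichols allele-frequency drift on a
  population tree. All defaults mirror the degraded-sample regime the
  pipeline targets (~55% contamination, 20–35% terminal deamination,
  ~50 bp fragments).

## Worked example

```python
import numpy as np
from palaeokit import simulate as sim, damage as dmg, consensus as cns
from palaeokit import radiocarbon as c14, sextyping as sx, tmrca

# --- authenticate and call a consensus from contaminated reads
ref = sim.random_reference(2000, seed=101, name="mt")
cfg = sim.ReadSimConfig(n_reads=20_000, contamination_fraction=0.5,
                        deam_rate_5p=0.25, deam_rate_3p=0.25, seed=102)
reads, truth = sim.simulate_ancient_reads(ref, cfg)
kept = dmg.filter_deaminated(dmg.filter_reads(reads), ref)
cons = cns.call_consensus(cns.build_pileup(kept, ref))
print(len(kept), cons.n_called)            # 1967 1990

# --- combine replicate dates and calibrate
res = c14.combine_replicates([c14.RadiocarbonAge("a", 25000, 200),
                              c14.RadiocarbonAge("b", 25500, 300)])
print(round(res.mean_bp), round(res.sigma_bp), round(res.chi2_stat, 2), res.passed)
# 25154 166 1.92 True

# --- sex from SNP-panel coverage counts
counts = sx.CoverageCounts(n_auto_obs=45032, n_x_obs=1312, n_y_obs=49,
                           n_auto_exp=1150639, n_x_exp=49704, n_y_exp=32670)
call = sx.classify_sex(counts)
print(round(call.x_ratio, 3), round(call.y_ratio, 3), call.call)
# 0.674 0.038 female

# --- TMRCA posterior for two identical mtDNA genomes
model = tmrca.TmrcaModel(k=0, n_e=1000, mu=2.67e-8, length=15_569,
                         generation_years=29)
post = tmrca.posterior(model)
print(round(model.theta, 4), round(post.mean_years, 1),
      round(tmrca.total_branch_years(post), 1))
# 0.8314 1154.9 2309.8
```

The first block simulates 20,000 reads of which half are undamaged
contaminants, keeps only fragments with terminal C→T (1,967 reads, 0.4%
of them contaminants), and calls 1,990 of 2,000 sites — all matching the
simulated genome. The χ² combination reproduces the inverse-variance
hand computation; the sex ratios and female call follow from the panel
counts; and the TMRCA block prints Θ, the posterior one-branch mean in
years (per-generation-rate convention) and its doubling into a total
branch length.

The same stages are available as CLI subcommands
(`palaeokit simulate|qc-collagen|c14-combine|c14-calibrate|c14-phase|damage|consensus|sextype|tmrca|fstats`).

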