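# pahkit

Source apportionment and inhalation cancer-risk assessment for
PM2.5-bound polycyclic aromatic hydrocarbons (PAHs).

Urban monitoring campaigns measure the 16 US-EPA priority PAHs in daily
PM2.5 samples and ask three questions: *how polluted* (descriptive and
limit-exceedance statistics), *from where* (source apportionment and
geolocation), and *how dangerous* (excess cancer risk). `pahkit`
implements that full analysis chain as a tested Python library:

- **Descriptive statistics** — median (P25, P75) summaries, strict
  limit-exceedance rates, molecular-weight class (LMW/MMW/HMW) mass
  fractions, Spearman correlation matrices, Mann–Whitney / Kruskal–Wallis
  comparisons.
- **Molecular diagnostic ratios (MDR)** — isomer-pair ratios
  Ant/(Ant+Phe), Flua/(Flua+Pyr), BaA/(BaA+Chr), IcdP/(IcdP+BghiP) with
  the standard petrogenic / combustion band classification.
- **Positive matrix factorization (PMF)** — a from-scratch receptor
  model decomposing the concentration matrix as `x_ij = Σ_k g_ik f_kj + e_ij`
  with `G, F ≥ 0`, minimizing the uncertainty-weighted objective
  `Q = Σ_ij (e_ij / s_ij)²` by multi-start multiplicative updates plus an
  alternating weighted-NNLS polish. Reports profiles, contributions,
  contribution percentages, and marker-based source labels.
- **Potential source contribution function (PSCF/WPSCF)** — bins HYSPLIT
  back-trajectory endpoints on a lat/lon grid and computes
  `PSCF_ij = m_ij / n_ij`, the conditional probability that crossing a
  cell ends in a pollution-exceedance arrival, with low-count weighting.
- **Incremental lifetime cancer risk (ILCR)** — BaP toxic-equivalent
  conversion `ΣTEQ = Σ C_i·TEF_i` and the inhalation risk model
  `ILCR = (TEQ·CSF·IR·EF·ED·CF)/(BW·AT)` evaluated by Monte Carlo
  (10,000 draws) with percentile reporting and rank-correlation
  sensitivity analysis for adult and child receptors.
- **Synthetic campaign generator** — a six-year, two-site series (~892
  site-days) built from five latent source factors with seasonal cycles,
  multiplicative noise, detection-limit censoring, meteorology, and
  back-trajectories from designated emission sectors, with ground truth
  returned for recovery testing.

## Worked example

```python
import numpy as np
from pahkit import SyntheticSpec, generate_samples, fit_pmf
from pahkit.pmf import records_to_matrix

spec = SyntheticSpec(n_days=75, n_sites=2, noise_cv=0.10, censor=False, seed=1)
records, g_true, f_true = generate_samples(spec)
x = records_to_matrix(records)
model = fit_pmf(x, np.maximum(0.10 * x, 1e-4), n_factors=5, n_starts=20, seed=0)
print(round(model.q, 1), [round(p, 1) for p in model.contribution_pct])
```

prints

```
1606.7 [36.7, 19.9, 17.9, 17.2, 8.3]
```

— the fitted objective `Q = 1606.7` sits near its degrees-of-freedom
reference (1570 = 150·16 − 5·166), meaning the assumed 10% uncertainty
model is consistent with the residuals, and the five factors carry
36.7/19.9/17.9/17.2/8.3% of the reconstructed mass (the generator's coal
factor is the largest, its small steel-industry factor the smallest).
Matching recovered to true profiles gives cosine similarities of
0.91–1.00 (`examples/04_pmf_source_apportionment.py` prints the full
table). The other capabilities — campaign generation, descriptive
tables, diagnostic ratios, PSCF maps, and risk simulation — each have a
narrative script under `examples/`.

A thin CLI wraps the same functions
(`pahkit synth|describe|mdr|pmf|pscf|risk|run-all`); `run-all` executes
every stage from one YAML config with a single seed fanned out to the
stochastic stages.

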