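# littorina

Analysis pipeline for studying regional adaptation of marine invertebrates to
ocean acidification along a latitudinal gradient, modelled on studies of the
common periwinkle *Littorina littorea* in the Northeast Atlantic.  The package
covers three data streams and the statistics that connect them:

1. **NMR metabolomics** (`littorina.nmr`, `littorina.discriminant`) —
   fixed-width binning of 1D projection spectra (0.005 ppm bins over
   0.2–10 ppm, residual water 4.38–5.22 ppm excluded), probabilistic quotient
   normalization, per-spectrum noise filtering (3 × s.d. of the 9.5–10 ppm
   noise region, bins kept when ≥ 10 samples exceed it), generalized-log
   transform (λ = 1.38 × 10⁻⁹), PCA summaries, and PLS-DA classification of
   *P*CO₂ treatment groups with VIP-ranked forward selection,
   venetian-blinds cross-validated balanced error rates, and a
   label-permutation significance test,
   *p* = #{permuted BER < observed BER} / *n*ₚₑᵣₘ.
2. **COI haplotype population genetics** (`littorina.popgen`) — haplotype
   collapse and diversity (*N*ₕₐₚ, *N*ₚₛ, *H*ₑ, π), uncorrected *p*-distances,
   χ² base-composition homogeneity, hierarchical AMOVA with
   Φ_ST / Φ_SC / Φ_CT and their permutation nulls, net divergence *D*ₐ,
   a neighbour-joining population tree, and a minimum-spanning haplotype
   network with a configurable connection limit.
3. **Latitudinal trend fitting** (`littorina.trendfit`) — linear-vs-quadratic
   ordinary least squares on population trait means, selected by
   AIC = *n* ln(RSS/*n*) + 2(*k*+1) (AICc behind a flag), plus Pearson
   correlation.

A synthetic-data module (`littorina.simulate`) generates binned-projection
style spectra with group-structured metabolite effects, haplotype datasets
with controllable within-/between-region differentiation, and clinal trait
tables — each with known ground truth, so every downstream stage is testable
without external data.

The intended users are molecular ecologists and metabolomics practitioners
who want the full chain — spectral matrix → discriminant signature, and
sequence alignment → Φ statistics → tree/network — as reproducible, seeded
library calls rather than a string of GUI tools.

## Worked example

```python
import numpy as np
import littorina as lt

# --- spectra: simulate, process, discriminate ---------------------------
cfg = lt.SpectraSimConfig(n_per_group=10, effect_bins=((1, 3.0),),
                          noise_sd=1.0, seed=42)
spectra, samples = lt.simulate_spectra(cfg)       # 2 groups x 10 samples
matrix = lt.process_spectra(spectra)              # bin -> PQN -> filter -> glog
print(matrix.n_bins)                              # 132 retained bins

res = lt.discriminate(matrix.values, samples["treatment"].to_numpy(),
                      k=5, n_perm=200, seed=0, n_components=2, max_subset=6)
print(np.round(matrix.bin_centers[res.selected], 4))   # [1.3925 1.2675]
print(res.optimal_ber, res.p_value)                    # 0.0 0.0

# --- haplotypes: diversity and hierarchical AMOVA -----------------------
ds = lt.simulate_haplotypes(lt.SeqSimConfig(between_group_mutations=4,
                                            within_pop_mutations=2, seed=7))
am = lt.amova(ds, n_perm=1000, seed=0)
print(f"{am.phi_st:.3f} {am.phi_sc:.3f} {am.phi_ct:.3f} {am.p_phi_ct:.3f}")
# 0.896 0.354 0.839 0.087

# --- latitudinal trend ---------------------------------------------------
cline = lt.simulate_cline(lt.ClineSimConfig(intercept=40, slope=-4.0,
                                            curvature=0.05, noise_sd=0.1,
                                            seed=3))
fit = lt.fit_trend(cline["latitude"], cline["value"], corrected=True)
print(fit.form, round(fit.r_squared, 4))          # quadratic 0.9999
```

Reading the output: the simulated 3× concentration effect on one metabolite
is recovered as two selected bins at its peak position (1.33 ± width ppm),
with a cross-validated balanced error rate of 0 and permutation *p* = 0 —
the treatment fingerprint is discriminable.  The haplotype generator's
four between-region substitutions dominate the variance decomposition
(Φ_CT = 0.839); its permutation *p* is limited below by the 90 distinct
ways of regrouping six populations.  The cline generator's curvature is
recovered by the AICc-selected quadratic.

Shell equivalents exist for each stage
(`littorina simulate | nmr-process | discriminate | popgen | trendfit`);
see `littorina --help`.

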