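"""Reproducibility studies: fixed desk-scale simulation designs.

These functions bundle the simulation studies the package uses to demonstrate
that its statistical machinery behaves as designed: type-I error calibration
and power of the PLS-DA permutation test on synthetic spectra, recovery of the
generating polynomial form by the AIC-controlled trend fit, and the
monotone response of the estimated Phi_CT to the generator's between-region
divergence.  The same designs back both the test suite and the acceptance
script, so the numbers those report are recomputed, never stored.

Problem sizes are desk scale: 2 groups x 10 samples for the spectra studies
(the field design had ~30 extracts per site x treatment), 200 permutations
per dataset and 100 datasets per arm; six latitudes for the cline studies
(the study transect's six populations), with AICc as the model-selection
criterion at that sample size.
"""

from __future__ import annotations

import numpy as np

from . import simulate
from .discriminant import discriminate
from .nmr import process_spectra
from .popgen import amova
from .trendfit import fit_trend

# frozen study conditions
CALIBRATION_N_DATASETS = 100
CALIBRATION_N_PERM = 200
CALIBRATION_EFFECT = 3.0
CALIBRATION_EFFECT_METABOLITE = 1  # the largest default peak
CALIBRATION_CV_FOLDS = 5
CALIBRATION_COMPONENTS = 2
CALIBRATION_SUBSET_CAP = 6

CLINE_N_DATASETS = 200
CLINE_STRONG_CURVATURE = dict(slope=-4.0, curvature=0.05, noise_sd=0.1)
CLINE_NO_CURVATURE = dict(slope=1.0, curvature=0.0, noise_sd=2.0)


def permutation_pvalues(
    n_datasets: int = CALIBRATION_N_DATASETS,
    n_perm: int = CALIBRATION_N_PERM,
    effect: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """P-values of the full spectra -> processing -> PLS-DA pipeline.

    ``effect`` = 1.0 gives null datasets (no group difference beyond noise and
    dilution); ``effect`` > 1 multiplies one metabolite's concentration in the
    second group.  One p-value per simulated dataset.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        ds_seed = int(rng.integers(2**31))
        effect_bins = (
            ((CALIBRATION_EFFECT_METABOLITE, effect),) if effect != 1.0 else ()
        )
        cfg = simulate.SpectraSimConfig(seed=ds_seed, effect_bins=effect_bins)
        spectra, samples = simulate.simulate_spectra(cfg)
        matrix = process_spectra(spectra)
        res = discriminate(
            matrix.values,
            samples["treatment"].to_numpy(),
            k=CALIBRATION_CV_FOLDS,
            n_perm=n_perm,
            seed=ds_seed,
            n_components=CALIBRATION_COMPONENTS,
            max_subset=CALIBRATION_SUBSET_CAP,
        )
        pvals[i] = res.p_value
    return pvals


def trend_recovery_rates(
    n_datasets: int = CLINE_N_DATASETS, seed: int = 0
) -> tuple[float, float]:
    """(quadratic rate under strong curvature, linear rate under none).

    Each arm simulates ``n_datasets`` six-latitude clines and fits the
    AICc-controlled trend (small-sample criterion at n = 6).
    """
    rng = np.random.default_rng(seed)

    def rate(params: dict, form: str) -> float:
        hits = 0
        for _ in range(n_datasets):
            t = simulate.simulate_cline(
                simulate.ClineSimConfig(seed=int(rng.integers(2**31)), **params)
            )
            fit = fit_trend(t["latitude"], t["value"], corrected=True)
            hits += fit.form == form
        return hits / n_datasets

    quad = rate(CLINE_STRONG_CURVATURE, "quadratic")
    lin = rate(CLINE_NO_CURVATURE, "linear")
    return quad, lin


def phi_ct_divergence_sweep(
    between_levels: tuple[int, ...] = (0, 2, 6),
    n_replicates: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Mean estimated Phi_CT per between-group divergence level.

    Parameter-recovery check: the mean over replicates should be
    non-decreasing in the generator's between-group mutation count.
    """
    rng = np.random.default_rng(seed)
    means = np.empty(len(between_levels))
    for j, b in enumerate(between_levels):
        vals = []
        for _ in range(n_replicates):
            ds = simulate.simulate_haplotypes(
                simulate.SeqSimConfig(
                    between_group_mutations=b,
                    within_pop_mutations=2,
                    n_per_pop=8,
                    seed=int(rng.integers(2**31)),
                )
            )
            res = amova(ds, n_perm=0)
            vals.append(res.phi_ct if res.phi_ct is not None else 0.0)
        means[j] = float(np.mean(vals))
    return means
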