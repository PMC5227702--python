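"""Synthetic data generators with known ground truth.

Three generators mirror the three data streams of the analysis pipeline:

* :func:`simulate_spectra` — binned-projection-style 1D NMR spectra with
  group-structured metabolite effects, per-sample dilution and additive noise;
* :func:`simulate_haplotypes` — aligned mtDNA-like haplotype datasets with
  controllable within-population and between-region differentiation;
* :func:`simulate_cline` — population trait means with a linear or quadratic
  latitude dependence plus Gaussian noise.

Every generator takes an explicit integer seed and draws all randomness from
one ``numpy.random.Generator`` created inside the call; fixed seed implies
bit-identical output.  The generators are deliberately simple mechanistic
models — Gaussian peaks, template-based mutation placement, polynomial
clines — not physically realistic simulators; their job is to provide data
whose true structure is known so each downstream stage can be tested for
recovery of that structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

#: default metabolite peak set: (ppm centre, width sigma in ppm, baseline
#: concentration).  Centres spread over the aliphatic/aromatic range a shellfish
#: tissue extract would populate; concentrations span one order of magnitude.
DEFAULT_PEAKS: tuple[tuple[float, float, float], ...] = (
    (0.95, 0.015, 40.0),
    (1.33, 0.020, 100.0),
    (2.15, 0.015, 60.0),
    (3.05, 0.012, 80.0),
    (3.45, 0.018, 50.0),
    (3.90, 0.015, 30.0),
    (6.90, 0.015, 20.0),
    (8.45, 0.012, 15.0),
)


@dataclass(frozen=True)
class SpectraSimConfig:
    """Configuration for the spectral generator.

    ``effect_bins`` maps metabolite index -> multiplicative group effect; the
    effect multiplies that metabolite's concentration by ``effect**g`` for a
    sample in group ``g`` (group 0 is the reference).  ``dilution_range`` is
    sampled log-uniformly per sample so probabilistic quotient normalization
    has a well-defined multiplicative artefact to remove.
    """

    n_groups: int = 2
    n_per_group: int = 10
    metabolite_peaks: tuple[tuple[float, float, float], ...] = DEFAULT_PEAKS
    effect_bins: tuple[tuple[int, float], ...] = ()
    dilution_range: tuple[float, float] = (0.7, 1.4)
    noise_sd: float = 1.0
    ppm_grid: tuple[float, float, float] = (0.2, 10.0, 0.001)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_per_group < 1:
            raise ConfigError("need at least one group and one sample per group")
        if not self.metabolite_peaks:
            raise ConfigError("metabolite_peaks must be non-empty")
        lo, hi, step = self.ppm_grid
        if not (lo < hi) or step <= 0:
            raise ConfigError("ppm_grid must satisfy low < high and step > 0")
        dmin, dmax = self.dilution_range
        if dmin <= 0 or dmax < dmin:
            raise ConfigError("dilution_range must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for idx, _ in self.effect_bins:
            if not (0 <= idx < len(self.metabolite_peaks)):
                raise ConfigError(f"effect references unknown metabolite {idx}")


def _peak_profile(ppm: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-concentration Gaussian peak, truncated at 4 sigma."""
    out = np.zeros_like(ppm)
    mask = np.abs(ppm - center) <= 4.0 * width
    out[mask] = np.exp(-0.5 * ((ppm[mask] - center) / width) ** 2)
    return out


def simulate_spectra(config: SpectraSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one spectrum per sample on a shared ppm grid.

    Each sample's intensity vector is

        dilution * sum_m  c_m * effect_m(group) * gaussian(ppm; mu_m, sigma_m)
        + Normal(0, noise_sd)

    Returns
    -------
    spectra : DataFrame with a ``ppm`` column and one column per sample id.
    samples : DataFrame with columns (sample, population, region, treatment,
        latitude); the simulated group plays the role of the treatment factor,
        population/region/latitude are filled with placeholder levels so the
        table round-trips through the same readers as field metadata.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi, step = config.ppm_grid
    ppm = np.arange(lo, hi, step)

    profiles = np.stack(
        [_peak_profile(ppm, c, w) for c, w, _ in config.metabolite_peaks]
    )  # metabolites x points
    base = np.array([conc for _, _, conc in config.metabolite_peaks])
    effects = {idx: eff for idx, eff in config.effect_bins}

    n = config.n_groups * config.n_per_group
    groups = np.repeat(np.arange(config.n_groups), config.n_per_group)
    dmin, dmax = config.dilution_range
    dilution = np.exp(rng.uniform(np.log(dmin), np.log(dmax), size=n))

    data = np.empty((n, ppm.size))
    for i, g in enumerate(groups):
        conc = base.copy()
        for idx, eff in effects.items():
            conc[idx] *= eff**g
        clean = conc @ profiles
        data[i] = dilution[i] * clean
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    sample_ids = [f"s{i:03d}" for i in range(n)]
    spectra = pd.DataFrame({"ppm": ppm})
    for sid, row in zip(sample_ids, data):
        spectra[sid] = row
    samples = pd.DataFrame(
        {
            "sample": sample_ids,
            "population": [f"pop{g}" for g in groups],
            "region": [f"region{g}" for g in groups],
            "treatment": [f"group{g}" for g in groups],
            "latitude": np.linspace(42.0, 70.0, config.n_groups)[groups],
        }
    )
    return spectra, samples


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SeqSimConfig:
    """Configuration for the template-based haplotype generator.

    A random ancestral sequence is drawn; each group's haplotype is the
    ancestor with ``between_group_mutations`` substitutions at distinct random
    sites, and each population additionally owns one private haplotype carrying
    ``within_pop_mutations`` further substitutions.  Individuals draw uniformly
    from their population's {group haplotype, private haplotype} pool.  This is
    a mutation placer, not a coalescent: it trades genealogical realism for an
    exactly controllable differentiation ground truth.
    """

    n_pops: int = 6
    pops_per_group: tuple[int, ...] = (2, 2, 2)
    n_per_pop: int = 10
    seq_length: int = 598
    within_pop_mutations: int = 1
    between_group_mutations: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        if self.within_pop_mutations < 0 or self.between_group_mutations < 0:
            raise ConfigError("mutation counts must be >= 0")
        if sum(self.pops_per_group) != self.n_pops:
            raise ConfigError("pops_per_group must partition the populations")
        if any(k < 1 for k in self.pops_per_group):
            raise ConfigError("every group needs at least one population")
        needed = self.between_group_mutations + self.within_pop_mutations
        if needed > self.seq_length:
            raise ConfigError("requested mutations exceed sequence length")


def _mutate(seq: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``n_mut`` distinct random sites to a different base."""
    out = seq.copy()
    if n_mut == 0:
        return out
    sites = rng.choice(seq.size, size=n_mut, replace=False)
    for s in sites:
        alternatives = _BASES[_BASES != out[s]]
        out[s] = rng.choice(alternatives)
    return out


def simulate_haplotypes(config: SeqSimConfig):
    """Generate an aligned haplotype dataset with known group structure.

    Returns a :class:`littorina.popgen.HaplotypeDataset`.
    """
    from .popgen import HaplotypeDataset  # local import avoids cycle

    rng = np.random.default_rng(config.seed)
    ancestor = rng.choice(_BASES, size=config.seq_length)

    sequences: list[str] = []
    sample_ids: list[str] = []
    populations: list[str] = []
    group_of: dict[str, str] = {}

    pop_index = 0
    for g, n_pops_in_group in enumerate(config.pops_per_group):
        group_hap = _mutate(ancestor, config.between_group_mutations, rng)
        for _ in range(n_pops_in_group):
            pop = f"pop{pop_index}"
            pop_index += 1
            group_of[pop] = f"region{g}"
            private_hap = _mutate(group_hap, config.within_pop_mutations, rng)
            pool = [group_hap, private_hap]
            for j in range(config.n_per_pop):
                hap = pool[rng.integers(len(pool))]
                sequences.append("".join(hap))
                sample_ids.append(f"{pop}_ind{j:02d}")
                populations.append(pop)

    groups = [group_of[p] for p in populations]
    return HaplotypeDataset(
        sequences=sequences,
        sample_ids=sample_ids,
        populations=populations,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# clines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClineSimConfig:
    """Population trait means along a latitudinal gradient.

    value = intercept + slope*lat + curvature*lat**2 + Normal(0, noise_sd).
    Default latitudes span the study transect (42–70 degrees N, six sites).
    """

    latitudes: tuple[float, ...] = (42.2, 46.2, 48.7, 50.4, 55.8, 69.7)
    intercept: float = 0.0
    slope: float = 0.0
    curvature: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.latitudes) < 3:
            raise ConfigError("need at least 3 latitudes")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def simulate_cline(config: ClineSimConfig) -> pd.DataFrame:
    """Return a (latitude, value) table from the configured polynomial."""
    rng = np.random.default_rng(config.seed)
    lat = np.asarray(config.latitudes, dtype=float)
    value = config.intercept + config.slope * lat + config.curvature * lat**2
    if config.noise_sd > 0:
        value = value + rng.normal(0.0, config.noise_sd, size=lat.size)
    else:
        value = value.copy()
    return pd.DataFrame({"latitude": lat, "value": value})
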