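"""Synthetic RNA-seq count data with planted co-expression modules and traits.

The generator emulates the structure of a multi-population thermal-acclimation
study on a small teleost: three populations (two geographic references and one
population from an anthropogenically warmed site) acclimated to 12 or 28
degrees C, gene-level 3'-RNA-seq counts for ~10,000 mRNAs, and six continuous
physiological traits per individual (whole-animal metabolic rate, critical
thermal maximum, and four substrate-specific cardiac metabolic rates).

Counts follow a negative-binomial model with a log-linear mean,

    log mu_gj = log s_j + b_g + lambda_g * e_{m(g),j}
                + delta_g^acc * 1[acc_j = 28] + delta_g^pop(pop_j)

where ``s_j`` is a log-normal library-size factor, ``b_g`` a per-gene baseline
log mean, ``e_{m,j}`` an i.i.d. standard-normal latent module factor shared by
the genes of module ``m``, and the deltas optional differential-expression
effects. Background genes carry no factor term. The NB variance is
``mu + phi * mu**2`` (dispersion parameterization standard in RNA-seq).

Traits are linear in the latent factors,

    t_{k,j} = alpha_k + gamma_k * mass_j + sum_m w_{k,m} e_{m,j} + eps_{k,j}

so the planted module-trait correlation is ``w / sqrt(sum(w^2) + sigma^2)``.

Randomness is split into named substreams (structure, counts, traits,
outliers) so that e.g. adding outliers never perturbs the counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

POPULATIONS = ("N.Ref", "TE", "S.Ref")
ACCLIMATION_TEMPS = (12, 28)
TRAITS = ("WAM", "CT_max", "CaM_GLU", "CaM_FA", "CaM_LKA", "CaM_END")

#: sample-size layout of the heart-tissue arm of the emulated study:
#: (population, acclimation temperature, n individuals)
HEART_DESIGN = (
    ("N.Ref", 12, 4), ("TE", 12, 6), ("S.Ref", 12, 9),
    ("N.Ref", 28, 4), ("TE", 28, 8), ("S.Ref", 28, 10),
)
BRAIN_DESIGN = (
    ("N.Ref", 12, 9), ("TE", 12, 11), ("S.Ref", 12, 8),
    ("N.Ref", 28, 5), ("TE", 28, 6), ("S.Ref", 28, 6),
)


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


def _default_trait_weights() -> dict[str, dict[int, float]]:
    # couple four of the planted modules to four traits at w/sqrt(w^2+1) ~ 0.55
    return {
        "WAM": {0: -0.66},
        "CT_max": {1: -0.66},
        "CaM_FA": {2: 0.66},
        "CaM_LKA": {3: -0.66},
    }


def _default_mass_model() -> dict[str, tuple[float, float, float]]:
    # trait -> (intercept alpha_k, mass slope gamma_k, residual noise sd)
    return {
        "WAM": (1.0, 0.25, 1.0),
        "CT_max": (36.0, 0.05, 1.0),
        "CaM_GLU": (20.0, 0.8, 1.0),
        "CaM_FA": (15.0, 0.8, 1.0),
        "CaM_LKA": (12.0, 0.8, 1.0),
        "CaM_END": (8.0, 0.8, 1.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic dataset.

    Defaults reproduce the heart-tissue arm of the emulated study: 41
    individuals in a 3 population x 2 acclimation-temperature layout,
    ~10,000 genes of which seven planted modules (sizes mirroring the
    detected-module scale of the study) carry latent-factor structure,
    and six traits of which four are coupled to one module each at a
    planted correlation of about 0.55.
    """

    n_genes: int = 10_000
    design: Sequence[tuple[str, int, int]] = HEART_DESIGN
    module_sizes: Sequence[int] = (336, 281, 194, 168, 147, 142, 90)
    loading_range: tuple[float, float] = (0.8, 1.2)
    baseline_logmean_range: tuple[float, float] = (3.0, 7.0)
    dispersion: float | tuple[float, float] = (0.1, 0.5)
    libsize_lognormal: tuple[float, float] = (0.0, 0.25)
    trait_weights: dict[str, dict[int, float]] = field(
        default_factory=_default_trait_weights)
    trait_noise_sd: float | dict[str, float] = 1.0
    mass_model: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_mass_model)
    mass_lognormal: tuple[float, float] = (2.3, 0.3)
    de_acclim_fraction: float = 0.04
    de_acclim_log2fc_range: tuple[float, float] = (0.5, 2.0)
    de_pop_fraction: float = 0.02
    de_pop_log2fc_range: tuple[float, float] = (0.5, 2.0)
    outliers: Sequence[tuple[int, float, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            raise ConfigurationError("n_genes must be a positive integer")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes "
                f"{self.n_genes}")
        if any(int(m) <= 0 or int(m) != m for m in self.module_sizes):
            raise ConfigurationError("module sizes must be positive integers")
        for pop, acc, n in self.design:
            if pop not in POPULATIONS:
                raise ConfigurationError(f"unknown population {pop!r}")
            if acc not in ACCLIMATION_TEMPS:
                raise ConfigurationError(f"unknown acclimation {acc!r}")
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ConfigurationError("all sample counts must be positive integers")
        disp = self.dispersion
        lo = disp[0] if isinstance(disp, tuple) else disp
        if lo <= 0:
            raise ConfigurationError("dispersion must be > 0")
        n_mod = len(self.module_sizes)
        trimmed: dict[str, dict[int, float]] = {}
        for trait, wmap in self.trait_weights.items():
            if trait not in TRAITS:
                raise ConfigurationError(f"unknown trait {trait!r}")
            if any(m < 0 for m in wmap):
                raise ConfigurationError("module indices must be >= 0")
            kept = {m: w for m, w in wmap.items() if m < n_mod}
            if len(kept) < len(wmap):
                logging.getLogger(__name__).warning(
                    "trait %s: dropping weights for modules beyond the %d "
                    "planted", trait, n_mod)
            if kept:
                trimmed[trait] = kept
        object.__setattr__(self, "trait_weights", trimmed)

    @property
    def n_samples(self) -> int:
        return int(sum(n for _, _, n in self.design))

    def noise_sd(self, trait: str) -> float:
        if isinstance(self.trait_noise_sd, dict):
            return float(self.trait_noise_sd.get(trait, 1.0))
        return float(self.trait_noise_sd)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded during simulation, for recovery tests."""

    module_labels: pd.Series          # per gene, 0 = background
    factors: pd.DataFrame             # modules x samples latent scores e
    trait_weights: pd.DataFrame       # traits x modules
    size_factors: pd.Series           # per sample s_j
    baseline_logmean: pd.Series       # per gene b_g (natural log)
    acclim_de: pd.Series              # per gene: natural-log 28C-vs-12C effect
    pop_offsets: pd.DataFrame         # genes x populations, natural-log offsets
    outlier_samples: tuple[int, ...] = ()

    def to_json(self) -> str:
        payload = {
            "module_labels": self.module_labels.to_dict(),
            "factors": self.factors.to_dict(),
            "trait_weights": self.trait_weights.to_dict(),
            "size_factors": self.size_factors.to_dict(),
            "baseline_logmean": self.baseline_logmean.to_dict(),
            "acclim_de": self.acclim_de.to_dict(),
            "pop_offsets": self.pop_offsets.to_dict(),
            "outlier_samples": list(self.outlier_samples),
        }
        return json.dumps(payload, sort_keys=True)


@dataclass(frozen=True)
class SyntheticDataset:
    counts: pd.DataFrame    # genes x samples, non-negative integers
    samples: pd.DataFrame   # per sample: population, acclimation, masses
    traits: pd.DataFrame    # per sample: the six physiological traits
    truth: SyntheticTruth
    config: SimulationConfig

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.counts.to_csv(sep="\t").encode())
        h.update(self.samples.to_csv(sep="\t").encode())
        h.update(self.traits.to_csv(sep="\t").encode())
        h.update(self.truth.to_json().encode())
        return h.hexdigest()

    def write(self, directory) -> None:
        """Write counts/samples/traits as TSV and the truth as JSON."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(directory / "counts.tsv", sep="\t",
                           index_label="gene_id")
        self.samples.to_csv(directory / "samples.tsv", sep="\t",
                            index_label="sample_id")
        self.traits.to_csv(directory / "traits.tsv", sep="\t",
                           index_label="sample_id")
        (directory / "truth.json").write_text(self.truth.to_json())


def scaled_module_sizes(n_genes: int,
                        reference: Sequence[int] = (336, 281, 194, 168, 147,
                                                    142, 90),
                        reference_total: int = 10_000) -> tuple[int, ...]:
    """Shrink the default module-size layout to a smaller gene count.

    Sizes scale proportionally but never below 30 (the minimum detectable
    module); trailing modules are dropped until the planted genes occupy at
    most half of the transcriptome.
    """
    scale = n_genes / reference_total
    sizes = [max(30, round(s * scale)) for s in reference]
    while sizes and sum(sizes) > n_genes // 2:
        sizes.pop()
    if not sizes:
        raise ConfigurationError(
            f"n_genes={n_genes} too small to plant any module of >= 30 genes")
    return tuple(sizes)


def _substreams(seed: int):
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    return {name: np.random.default_rng(k)
            for name, k in zip(("structure", "counts", "traits", "outliers"), kids)}


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + phi*mu^2."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, phi * mu)
    return rng.poisson(lam)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model described in the module docstring.

    Deterministic: the same config (including seed) always yields a
    byte-identical dataset.
    """
    rngs = _substreams(config.seed)
    rs, rc, rt = rngs["structure"], rngs["counts"], rngs["traits"]

    n_genes, n_samples = config.n_genes, config.n_samples
    n_modules = len(config.module_sizes)

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    pops, accs, sample_ids = [], [], []
    for pop, acc, n in config.design:
        for i in range(n):
            sample_ids.append(f"{pop}_{acc}C_{i + 1}")
            pops.append(pop)
            accs.append(acc)
    pops_arr = np.array(pops)
    accs_arr = np.array(accs)

    # structure stream: gene parameters, module assignment, latent factors, mass
    labels = np.zeros(n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start:start + size] = m
        start += size

    lam = rs.uniform(*config.loading_range, size=n_genes)
    lam[labels == 0] = 0.0
    b = rs.uniform(*config.baseline_logmean_range, size=n_genes)
    if isinstance(config.dispersion, tuple):
        phi = rs.uniform(*config.dispersion, size=n_genes)
    else:
        phi = np.full(n_genes, float(config.dispersion))
    meanlog, sdlog = config.libsize_lognormal
    s = rs.lognormal(meanlog, sdlog, size=n_samples)
    e = rs.standard_normal((n_modules, n_samples))
    mass = rs.lognormal(*config.mass_lognormal, size=n_samples)
    heart_mass = 0.002 * mass * rs.lognormal(0.0, 0.1, size=n_samples)

    # differential-expression effects (natural-log scale internally)
    ln2 = np.log(2.0)
    acclim_de = np.zeros(n_genes)
    n_acc = int(round(config.de_acclim_fraction * n_genes))
    if n_acc:
        idx = rs.choice(n_genes, size=n_acc, replace=False)
        mag = rs.uniform(*config.de_acclim_log2fc_range, size=n_acc) * ln2
        acclim_de[idx] = mag * rs.choice([-1.0, 1.0], size=n_acc)
    pop_offsets = np.zeros((n_genes, len(POPULATIONS)))
    n_pop = int(round(config.de_pop_fraction * n_genes))
    if n_pop:
        idx = rs.choice(n_genes, size=n_pop, replace=False)
        for which in (1, 2):  # N.Ref is the baseline population
            mag = rs.uniform(*config.de_pop_log2fc_range, size=n_pop) * ln2
            pop_offsets[idx, which] = mag * rs.choice([-1.0, 1.0], size=n_pop)

    # counts stream: NB sampling around the log-linear mean
    log_mu = b[:, None] + np.log(s)[None, :]
    in_module = labels > 0
    log_mu[in_module] += lam[in_module, None] * e[labels[in_module] - 1]
    log_mu += acclim_de[:, None] * (accs_arr == 28)[None, :]
    pop_index = np.array([POPULATIONS.index(p) for p in pops_arr])
    log_mu += pop_offsets[:, pop_index]
    counts = _nb_sample(rc, np.exp(log_mu), phi[:, None])

    # traits stream
    trait_vals = {}
    weights = np.zeros((len(TRAITS), n_modules))
    for k, trait in enumerate(TRAITS):
        alpha, gamma, _ = config.mass_model[trait]
        wmap = config.trait_weights.get(trait, {})
        for m, w in wmap.items():
            weights[k, m] = w
        t = alpha + gamma * mass + weights[k] @ e
        t = t + rt.normal(0.0, config.noise_sd(trait), size=n_samples)
        trait_vals[trait] = t

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    samples_df = pd.DataFrame(
        {"population": pops_arr, "acclimation": accs_arr,
         "body_mass": mass, "heart_mass": heart_mass},
        index=sample_ids)
    traits_df = pd.DataFrame(trait_vals, index=sample_ids)
    truth = SyntheticTruth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        factors=pd.DataFrame(e, index=[f"M{m + 1}" for m in range(n_modules)],
                             columns=sample_ids),
        trait_weights=pd.DataFrame(weights, index=list(TRAITS),
                                   columns=[f"M{m + 1}" for m in range(n_modules)]),
        size_factors=pd.Series(s, index=sample_ids, name="size_factor"),
        baseline_logmean=pd.Series(b, index=gene_ids, name="baseline"),
        acclim_de=pd.Series(acclim_de, index=gene_ids, name="acclim_de"),
        pop_offsets=pd.DataFrame(pop_offsets, index=gene_ids,
                                 columns=list(POPULATIONS)),
    )
    dataset = SyntheticDataset(counts_df, samples_df, traits_df, truth, config)

    for sample_index, trait_shift, expr_shift in config.outliers:
        dataset = inject_outlier(dataset, sample_index, trait_shift, expr_shift)
    return dataset


def inject_outlier(dataset: SyntheticDataset, sample_index: int,
                   trait_shift: float, expression_logshift: float
                   ) -> SyntheticDataset:
    """Return a copy with one sample turned into an outlier.

    The sample's traits are shifted additively by ``trait_shift`` and its
    counts rescaled by ``exp(expression_logshift)`` (rounded back to
    integers). The truth gains an outlier flag. Disjoint injections commute.
    """
    n = dataset.counts.shape[1]
    if not 0 <= sample_index < n:
        raise IndexError(
            f"sample_index {sample_index} out of range for {n} samples")
    counts = dataset.counts.copy()
    col = counts.columns[sample_index]
    counts[col] = np.rint(
        counts[col].to_numpy() * np.exp(expression_logshift)).astype(np.int64)
    traits = dataset.traits.copy()
    traits.iloc[sample_index] = traits.iloc[sample_index] + trait_shift
    truth = replace(
        dataset.truth,
        outlier_samples=tuple(sorted(
            set(dataset.truth.outlier_samples) | {sample_index})))
    return SyntheticDataset(counts, dataset.samples, traits, truth,
                            dataset.config)
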