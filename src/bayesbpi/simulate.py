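"""Synthetic genotype/phenotype generator with controlled genetic architectures.

Genotypes are drawn in Hardy-Weinberg proportions at allele frequencies
sampled from a MAF range, in linkage equilibrium by default (an optional
block-correlated mode adds within-block LD).  Phenotypes are built from a
configurable architecture: one designated major QTL carrying a chosen
fraction of the genetic variance, a polygenic tail of Gaussian small
effects, and Gaussian noise scaled to hit a target heritability.

Three presets mirror the trait architectures common in dairy-cattle
genetics: ``mfp`` (milk-fat-percentage-like; a single gene such as DGAT1
explaining ~30% of the genetic variance), ``my`` (milk-yield-like; one
moderate QTL plus many small ones) and ``scs`` (somatic-cell-score-like;
purely polygenic, no major QTL).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "ArchitectureSpec",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "preset",
    "PRESETS",
]


@dataclasses.dataclass
class ArchitectureSpec:
    """Parameters of a simulated trait architecture.

    major_qtl_fraction_of_genetic_variance is the share of total additive
    genetic variance carried by the single largest QTL (0 = no designated
    major gene); heritability is the narrow-sense h2 of the trait.
    """

    n_individuals: int
    n_markers: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 0
    major_qtl_fraction_of_genetic_variance: float = 0.0
    heritability: float = 0.5
    seed: int = 0
    ld_block_size: int = 1
    ld_block_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_markers < 1:
            raise ValueError("need n_individuals >= 2 and n_markers >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0 <= self.major_qtl_fraction_of_genetic_variance <= 1:
            raise ValueError("major QTL fraction must be in [0, 1]")
        if self.n_qtl > 0 and not 0 < self.heritability < 1:
            raise ValueError("heritability must be in (0, 1) for non-null traits")
        if self.major_qtl_fraction_of_genetic_variance > 0 and self.n_qtl == 0:
            raise ValueError("major QTL fraction > 0 requires n_qtl >= 1")


@dataclasses.dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    true_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2: float


def simulate_genotypes(spec: ArchitectureSpec) -> GenotypeMatrix:
    """Draw codes Binomial(2, p_j) per individual, p_j uniform on maf_range.

    Markers are independent (linkage equilibrium) unless ld_block_corr > 0,
    in which case markers within blocks of ld_block_size share a latent
    Gaussian with the given correlation before thresholding to HWE classes.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.n_markers
    p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    if spec.ld_block_corr <= 0 or spec.ld_block_size <= 1:
        codes = rng.binomial(2, p[np.newaxis, :], size=(n, m)).astype(float)
    else:
        # Gaussian copula within blocks: two latent draws per individual give
        # the two gametes; threshold at the allele-frequency quantile.
        rho = spec.ld_block_corr
        codes = np.empty((n, m))
        for start in range(0, m, spec.ld_block_size):
            stop = min(start + spec.ld_block_size, m)
            k = stop - start
            cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
            chol = np.linalg.cholesky(cov)
            thresh = _norm_ppf(p[start:stop])
            for gamete in range(2):
                z = rng.standard_normal((n, k)) @ chol.T
                if gamete == 0:
                    codes[:, start:stop] = (z < thresh).astype(float)
                else:
                    codes[:, start:stop] += z < thresh
    ids = [f"ind{i + 1}" for i in range(n)]
    markers = [f"snp{j + 1}" for j in range(m)]
    return GenotypeMatrix(ids, markers, codes)


def _norm_ppf(q: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(q)


def simulate_effects(spec: ArchitectureSpec, allele_freq: np.ndarray | None = None) -> np.ndarray:
    """Assign additive effects to n_qtl randomly chosen markers.

    The first chosen locus is the designated major QTL: its effect a is
    sized so that its variance contribution 2 p q a^2 equals the requested
    fraction of the total genetic variance; the remaining QTL get zero-mean
    Gaussian effects.  Off-QTL effects are exactly zero.
    """
    rng = np.random.default_rng(spec.seed + 1)
    m = spec.n_markers
    effects = np.zeros(m)
    if spec.n_qtl == 0:
        return effects
    if allele_freq is None:
        allele_freq = np.full(m, 0.3)
    qtl = rng.choice(m, size=spec.n_qtl, replace=False)
    frac = spec.major_qtl_fraction_of_genetic_variance
    small = qtl[1:] if frac > 0 else qtl
    effects[small] = rng.standard_normal(small.size)
    pq2 = 2.0 * allele_freq * (1.0 - allele_freq)
    var_small = float(np.sum(pq2[small] * effects[small] ** 2))
    if frac > 0:
        major = qtl[0]
        if spec.n_qtl == 1 or var_small == 0:
            # lone QTL: any nonzero effect realises 100% of genetic variance
            effects[major] = 1.0
        else:
            # solve 2pq a^2 = frac/(1-frac) * var_small
            target = frac / (1.0 - frac) * var_small
            effects[major] = np.sqrt(target / pq2[major])
    return effects


def simulate_phenotypes(
    g: GenotypeMatrix, effects: np.ndarray, h2: float, seed: int, trait_name: str = "trait"
) -> SimulatedDataset:
    """Add Gaussian noise to the true breeding values to hit heritability h2.

    tbv = centered codes x effects; residual variance = var(tbv)(1-h2)/h2 so
    the realized heritability var(tbv)/var(y) targets h2 up to noise-sampling
    variability.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (g.n_markers,):
        raise ValueError("effects length must equal number of markers")
    rng = np.random.default_rng(seed)
    W = g.codes - 2.0 * g.allele_freq
    tbv = W @ effects
    var_tbv = float(np.var(tbv))
    if np.all(effects == 0):
        if h2 > 0:
            raise ValueError("all-zero effects: heritability is undefined for h2 > 0")
        y = rng.standard_normal(g.n_individuals)
        realized = 0.0
    else:
        if not 0 < h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        sigma2_e = var_tbv * (1.0 - h2) / h2
        y = tbv + rng.normal(0.0, np.sqrt(sigma2_e), size=g.n_individuals)
        realized = var_tbv / float(np.var(y))
    phen = PhenotypeTable(list(g.individual_ids), [trait_name], y[:, np.newaxis])
    return SimulatedDataset(g, phen, effects, tbv, realized)


def simulate_dataset(spec: ArchitectureSpec, trait_name: str = "trait") -> SimulatedDataset:
    """Full pipeline: genotypes -> effects -> phenotypes, all from spec.seed."""
    g = simulate_genotypes(spec)
    effects = simulate_effects(spec, allele_freq=g.allele_freq)
    if spec.n_qtl == 0:
        return simulate_phenotypes(g, effects, 0.0, spec.seed + 2, trait_name)
    return simulate_phenotypes(g, effects, spec.heritability, spec.seed + 2, trait_name)


PRESETS: dict[str, dict] = {
    # one major gene at 30% of genetic variance over a polygenic tail
    "mfp": dict(n_qtl=50, major_qtl_fraction_of_genetic_variance=0.30, heritability=0.5),
    # one moderate QTL (10%) plus many small ones
    "my": dict(n_qtl=100, major_qtl_fraction_of_genetic_variance=0.10, heritability=0.5),
    # purely polygenic, no locus above background
    "scs": dict(n_qtl=200, major_qtl_fraction_of_genetic_variance=0.0, heritability=0.3),
}


def preset(name: str, n_individuals: int, n_markers: int, seed: int = 0, **overrides) -> ArchitectureSpec:
    """Build an ArchitectureSpec from a named trait-architecture preset."""
    key = name.lower().replace("-like", "")
    if key not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = {**PRESETS[key], **overrides}
    n_qtl = min(params.pop("n_qtl"), n_markers)
    return ArchitectureSpec(
        n_individuals=n_individuals,
        n_markers=n_markers,
        n_qtl=n_qtl,
        seed=seed,
        **params,
    )
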