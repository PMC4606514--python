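"""GBLUP: genomic relationship matrix, REML variance components, and the
mixed-model solution for genomic breeding values.

The relationship matrix follows VanRaden's first method,
G = WW' / (2 * sum_j p_j (1 - p_j)), with W the genotype matrix centered by
twice the observed allele frequencies.  Variance components for
y = 1*mu + u + e, u ~ N(0, sigma_u^2 G), are estimated by REML via a single
eigendecomposition of G and one-dimensional optimisation over the variance
ratio.  Breeding values for unphenotyped individuals come from the
corresponding off-diagonal blocks of G.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "VarianceComponents",
    "build_g_matrix",
    "estimate_variance_components",
    "solve_gblup",
    "write_g_matrix",
    "read_g_matrix",
]


@dataclasses.dataclass
class RelationshipMatrix:
    individual_ids: list[str]
    G: np.ndarray
    blend_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.individual_ids)
        if self.G.shape != (n, n):
            raise ValueError("G shape does not match id list")
        if np.max(np.abs(self.G - self.G.T)) > 1e-10:
            raise ValueError("G is not symmetric")


@dataclasses.dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    at_boundary: bool = False

    @property
    def lambda_(self) -> float:
        """Shrinkage ratio sigma_e^2 / sigma_u^2."""
        return np.inf if self.sigma2_u == 0 else self.sigma2_e / self.sigma2_u

    @property
    def h2(self) -> float:
        tot = self.sigma2_u + self.sigma2_e
        return 0.0 if tot == 0 else self.sigma2_u / tot


def build_g_matrix(g: GenotypeMatrix, blend_epsilon: float = 1e-6) -> RelationshipMatrix:
    """VanRaden method 1 with observed allele frequencies.

    A small multiple of the identity (blend_epsilon) is added to the diagonal
    to guarantee positive definiteness; the effect on predictions is
    negligible.
    """
    p = g.allele_freq
    poly = (p > 0) & (p < 1)
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    if denom == 0:
        raise ValueError("all markers are monomorphic: G denominator is zero")
    W = g.codes - 2.0 * p
    G = (W @ W.T) / denom
    G[np.diag_indices_from(G)] += blend_epsilon
    return RelationshipMatrix(list(g.individual_ids), G, blend_epsilon)


def estimate_variance_components(
    y: np.ndarray, rel: RelationshipMatrix, h2_fixed: float | None = None
) -> VarianceComponents:
    """REML for y = 1*mu + u + e, u ~ N(0, sigma_u^2 G).

    Works in the eigenbasis of G, profiling out sigma_e^2 and optimising the
    restricted likelihood over log(kappa), kappa = sigma_u^2/sigma_e^2.
    Deterministic for fixed input.  h2_fixed bypasses REML and splits the
    phenotypic variance at the given heritability (useful for testing and
    for replaying known variance components).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n != len(rel.individual_ids):
        raise ValueError("response length does not match G")
    if h2_fixed is not None:
        var_y = float(np.var(y, ddof=1))
        return VarianceComponents(h2_fixed * var_y, (1 - h2_fixed) * var_y)
    if n < 10:
        raise ValueError("need at least 10 phenotyped individuals for REML")

    d, U = np.linalg.eigh(rel.G)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_restricted_ll(log_kappa: float) -> float:
        kappa = np.exp(log_kappa)
        v = kappa * d + 1.0          # eigenvalues of V / sigma_e^2
        xvx = float(np.sum(xt**2 / v))
        beta = float(np.sum(xt * yt / v)) / xvx
        r = yt - xt * beta
        quad = float(np.sum(r**2 / v))
        sigma2_e = quad / (n - 1)
        return 0.5 * (
            float(np.sum(np.log(v))) + np.log(xvx) + (n - 1) * np.log(sigma2_e) + (n - 1)
        )

    res = minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded")
    if not res.success:
        raise RuntimeError(f"REML optimisation failed at log_kappa={res.x:.3f}: {res.message}")
    kappa = float(np.exp(res.x))
    v = kappa * d + 1.0
    xvx = float(np.sum(xt**2 / v))
    beta = float(np.sum(xt * yt / v)) / xvx
    quad = float(np.sum((yt - xt * beta) ** 2 / v))
    sigma2_e = quad / (n - 1)
    at_boundary = res.x <= -11.9
    sigma2_u = 0.0 if at_boundary else kappa * sigma2_e
    return VarianceComponents(sigma2_u, sigma2_e, at_boundary=at_boundary)


def solve_gblup(
    y: np.ndarray,
    rel: RelationshipMatrix,
    vc: VarianceComponents,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """BLUP of additive genetic merit for all individuals in G.

    y holds responses for the observed individuals (masked individuals'
    entries are ignored); predictions for masked individuals propagate
    through the off-diagonal blocks of G:

        u_hat = sigma_u^2 G[:, obs] V^{-1} (y_obs - mu_hat),
        V = sigma_u^2 G[obs, obs] + sigma_e^2 I.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(rel.individual_ids)
    if observed is None:
        observed = ~np.isnan(y)
    observed = np.asarray(observed, dtype=bool)
    if observed.sum() < 2:
        raise ValueError("need at least 2 observed individuals")
    yo = y[observed]
    Goo = rel.G[np.ix_(observed, observed)]
    V = vc.sigma2_u * Goo + vc.sigma2_e * np.eye(observed.sum())
    try:
        Vinv_y = np.linalg.solve(V, yo)
        Vinv_1 = np.linalg.solve(V, np.ones_like(yo))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular GBLUP coefficient matrix: {exc}") from exc
    mu = float(np.sum(Vinv_y) / np.sum(Vinv_1))
    alpha = np.linalg.solve(V, yo - mu)
    return vc.sigma2_u * (rel.G[:, observed] @ alpha)


def write_g_matrix(rel: RelationshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(rel.G, index=rel.individual_ids, columns=rel.individual_ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_g_matrix(path: str | Path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.index.astype(str).tolist(), df.to_numpy())
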