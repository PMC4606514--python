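"""Scikit-learn style estimators for genomic prediction.

All four estimators take an (n_individuals x n_markers) additive genotype
matrix ``X`` coded 0/1/2 and a quantitative response ``y`` (EBVs,
deregressed proofs, or phenotypes), and predict genomic estimated breeding
values for new individuals.  They follow the fit/predict contract, expose
their configuration through ``get_params``/``set_params`` and therefore
compose with sklearn pipelines and model selection.

* :class:`GBLUP` — mixed model on a VanRaden genomic relationship matrix,
  REML variance components.
* :class:`BayesA` — Gibbs sampler, every marker in the model.
* :class:`BayesB` — mixture prior with a constant exclusion probability pi.
* :class:`BayesBPi` — mixture prior with locus-specific pi computed from
  single-marker ANOVA p-values on the training data (so cross-validation
  with sklearn splitters automatically recomputes pi inside each training
  fold, with no leakage from held-out individuals).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .anova import locus_pi_from_data
from .gblup import RelationshipMatrix, estimate_variance_components
from .io import GenotypeMatrix
from .mcmc import ChainConfig, PriorSpec, run_mcmc

__all__ = ["GBLUP", "BayesA", "BayesB", "BayesBPi"]


def _as_genotype_matrix(X: np.ndarray) -> GenotypeMatrix:
    n, m = X.shape
    return GenotypeMatrix(
        [f"ind{i}" for i in range(n)], [f"snp{j}" for j in range(m)], X
    )


class GBLUP(RegressorMixin, BaseEstimator):
    """Genomic BLUP on a VanRaden genomic relationship matrix.

    Parameters
    ----------
    h2 : float or None
        Fix the heritability used to split the phenotypic variance; None
        (default) estimates variance components by REML.
    blend_epsilon : small diagonal blend guaranteeing an invertible G.

    Attributes
    ----------
    p_freq_ : training allele frequencies used for centering.
    vc_ : estimated :class:`~bayesbpi.gblup.VarianceComponents`.
    mu_ : generalised-least-squares estimate of the overall mean.
    """

    def __init__(self, h2: float | None = None, blend_epsilon: float = 1e-6):
        self.h2 = h2
        self.blend_epsilon = blend_epsilon

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        gm = _as_genotype_matrix(X)
        self.p_freq_ = gm.allele_freq
        poly = (self.p_freq_ > 0) & (self.p_freq_ < 1)
        self.denom_ = 2.0 * float(np.sum(self.p_freq_[poly] * (1 - self.p_freq_[poly])))
        if self.denom_ == 0:
            raise ValueError("all markers are monomorphic")
        self.W_train_ = X - 2.0 * self.p_freq_
        G = self.W_train_ @ self.W_train_.T / self.denom_
        G[np.diag_indices_from(G)] += self.blend_epsilon
        rel = RelationshipMatrix([f"ind{i}" for i in range(X.shape[0])], G, self.blend_epsilon)
        self.vc_ = estimate_variance_components(y, rel, h2_fixed=self.h2)
        V = self.vc_.sigma2_u * G + self.vc_.sigma2_e * np.eye(X.shape[0])
        ones = np.ones(X.shape[0])
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, ones)
        self.mu_ = float(ones @ Vinv_y) / float(ones @ Vinv_1)
        self.alpha_ = np.linalg.solve(V, y - self.mu_)
        self.n_features_in_ = X.shape[1]
        return self

    def genetic_values(self, X) -> np.ndarray:
        """GEBVs (no intercept) for new individuals via the G cross-block."""
        check_is_fitted(self, "alpha_")
        X = check_array(X)
        W_new = X - 2.0 * self.p_freq_
        G_cross = W_new @ self.W_train_.T / self.denom_
        return self.vc_.sigma2_u * (G_cross @ self.alpha_)

    def predict(self, X) -> np.ndarray:
        return self.mu_ + self.genetic_values(X)


class _BayesBase(RegressorMixin, BaseEstimator):
    """Shared fit machinery for the MCMC estimators."""

    _method = "bayesA"

    def __init__(
        self,
        n_iterations: int = 10_000,
        burn_in: int = 2_000,
        mh_cycles: int = 100,
        v_marker: float = 4.234,
        S_marker: float = 0.0429,
        standardize_y: bool = True,
        seed: int = 0,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.mh_cycles = mh_cycles
        self.v_marker = v_marker
        self.S_marker = S_marker
        self.standardize_y = standardize_y
        self.seed = seed

    def _pi(self, X: np.ndarray, y: np.ndarray):
        return 0.95  # overridden

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.p_freq_ = X.mean(axis=0) / 2.0
        W = X - 2.0 * self.p_freq_
        if self.standardize_y:
            self.y_mean_, self.y_sd_ = float(np.mean(y)), float(np.std(y, ddof=1))
            if self.y_sd_ == 0:
                raise ValueError("response is constant")
            y_fit = (y - self.y_mean_) / self.y_sd_
        else:
            self.y_mean_, self.y_sd_ = 0.0, 1.0
            y_fit = y
        self.pi_ = self._pi(X, y_fit)
        prior = PriorSpec(v_marker=self.v_marker, S_marker=self.S_marker, pi=self.pi_)
        config = ChainConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            mh_cycles=self.mh_cycles,
            seed=self.seed,
        )
        self.summary_ = run_mcmc(y_fit, W, prior, config, method=self._method)
        self.effect_means_ = self.summary_.effect_means
        self.inclusion_freq_ = self.summary_.inclusion_freq
        self.mu_ = self.summary_.mu_mean
        self.sigma2_e_ = self.summary_.sigma2_e_mean
        self.n_features_in_ = X.shape[1]
        return self

    def genetic_values(self, X) -> np.ndarray:
        """Posterior-mean GEBVs on the (standardized) model scale."""
        check_is_fitted(self, "effect_means_")
        X = check_array(X)
        return (X - 2.0 * self.p_freq_) @ self.effect_means_

    def predict(self, X) -> np.ndarray:
        return self.y_mean_ + self.y_sd_ * (self.mu_ + self.genetic_values(X))


class BayesA(_BayesBase):
    """BayesA: conjugate locus-specific variances, no variable selection."""

    _method = "bayesA"


class BayesB(_BayesBase):
    """BayesB with a constant prior exclusion probability pi (default 0.95)."""

    _method = "bayesB"

    def __init__(
        self,
        pi: float = 0.95,
        n_iterations: int = 10_000,
        burn_in: int = 2_000,
        mh_cycles: int = 100,
        v_marker: float = 4.234,
        S_marker: float = 0.0429,
        standardize_y: bool = True,
        seed: int = 0,
    ):
        super().__init__(
            n_iterations=n_iterations,
            burn_in=burn_in,
            mh_cycles=mh_cycles,
            v_marker=v_marker,
            S_marker=S_marker,
            standardize_y=standardize_y,
            seed=seed,
        )
        self.pi = pi

    def _pi(self, X, y):
        return float(self.pi)


class BayesBPi(_BayesBase):
    """BayesB with locus-specific pi from single-marker ANOVA p-values.

    Unless an explicit ``pi`` vector is supplied, fit() runs a one-way ANOVA
    of the response on each marker's genotype classes in the training data,
    maps p-values through omega = -log10(p) and min-max rescales omega so
    the most significant marker gets pi = 0 and the least significant pi = 1.

    Parameters
    ----------
    pi : optional externally supplied per-marker vector (e.g. read from a
        prior file); None (default) computes it from the training fold.
    anova_model : 'factor' (genotype classes) or 'additive' (dosage slope).
    p_floor : numerical floor preventing infinite omega at underflowed
        p-values.
    """

    _method = "bayesBpi"

    def __init__(
        self,
        pi: np.ndarray | None = None,
        anova_model: str = "factor",
        p_floor: float = 1e-300,
        n_iterations: int = 10_000,
        burn_in: int = 2_000,
        mh_cycles: int = 100,
        v_marker: float = 4.234,
        S_marker: float = 0.0429,
        standardize_y: bool = True,
        seed: int = 0,
    ):
        super().__init__(
            n_iterations=n_iterations,
            burn_in=burn_in,
            mh_cycles=mh_cycles,
            v_marker=v_marker,
            S_marker=S_marker,
            standardize_y=standardize_y,
            seed=seed,
        )
        self.pi = pi
        self.anova_model = anova_model
        self.p_floor = p_floor

    def _pi(self, X, y):
        if self.pi is not None:
            pi = np.asarray(self.pi, dtype=float)
            if pi.shape != (X.shape[1],):
                raise ValueError("supplied pi vector length does not match marker count")
            return pi
        import warnings

        gm = _as_genotype_matrix(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat-omega fallback is fine here
            prior = locus_pi_from_data(
                gm, y, model=self.anova_model, floor=self.p_floor
            )
        return prior.pi
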