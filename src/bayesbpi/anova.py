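"""Locus-specific mixture-prior weights from single-marker ANOVA.

For each SNP a one-way fixed-effect ANOVA of the response on the genotype
classes (0/1/2 treated as factor levels) yields a p-value; the vector of
p-values is mapped to per-marker prior exclusion probabilities by

    omega_i = -log10(p_i),     pi_i = (max(omega) - omega_i) / (max(omega) - min(omega))

so the most significant marker receives pi = 0 (always eligible for the
model) and the least significant pi = 1 (never proposed).  This min-max
rescaling is invariant to shifting all omega by a constant and to positive
scaling.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

__all__ = [
    "PValueVector",
    "LocusPrior",
    "single_marker_anova",
    "pvalues_to_omega",
    "compute_locus_pi",
    "locus_pi_from_data",
    "binned_pi",
    "write_locus_prior",
    "read_locus_prior",
]

#: fallback constant pi used when every marker is equally (in)significant,
#: matching the conventional BayesB default
DEGENERATE_PI = 0.95


@dataclasses.dataclass
class PValueVector:
    """Per-marker ANOVA p-values; NaN marks markers with an undefined test
    (monomorphic, i.e. fewer than two genotype classes)."""

    marker_ids: list[str]
    p: np.ndarray
    test_df: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        defined = self.p[~np.isnan(self.p)]
        if defined.size and (np.any(defined <= 0) or np.any(defined > 1)):
            raise ValueError("p-values must lie in (0, 1]")


@dataclasses.dataclass
class LocusPrior:
    marker_ids: list[str]
    omega: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < -1e-12) or np.any(self.pi > 1 + 1e-12):
            raise ValueError("pi must lie in [0, 1]")
        self.pi = np.clip(self.pi, 0.0, 1.0)


def single_marker_anova(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    model: str = "factor",
) -> PValueVector:
    """One-marker-at-a-time F-test of association.

    model='factor' (default) fits the class-means model: genotype codes are
    factor levels and the marker term is tested with a one-way (or, with
    covariates, added-last) F-test.  model='additive' regresses on the dosage
    0/1/2 instead; for common variants the two are nearly identical.

    Monomorphic markers (one observed class) get a NaN sentinel rather than
    an exception.  Cells imputed to fractional dosages are assigned to the
    nearest class for the factor model.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = g.n_individuals
    if y.shape[0] != n:
        raise ValueError("response length does not match genotype rows")
    if np.std(y) == 0:
        raise ValueError("response is constant")
    if covariates is not None:
        return _anova_with_covariates(g, y, covariates, model)

    m = g.n_markers
    p_out = np.full(m, np.nan)
    df_out = np.zeros(m)
    if model == "factor":
        codes = np.rint(np.clip(g.codes, 0, 2))
        # vectorised one-way ANOVA: per-class counts and sums via indicator dots
        ind = [(codes == k) for k in (0.0, 1.0, 2.0)]
        counts = np.stack([ik.sum(axis=0) for ik in ind])          # 3 x m
        sums = np.stack([y @ ik for ik in ind])                    # 3 x m
        n_classes = (counts > 0).sum(axis=0)
        grand_mean = y.mean()
        sst = float(np.sum((y - grand_mean) ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ssb = np.nansum(
                np.where(counts > 0, counts * (sums / np.maximum(counts, 1) - grand_mean) ** 2, 0.0),
                axis=0,
            )
        ssw = np.maximum(sst - ssb, 0.0)
        df1 = n_classes - 1.0
        df2 = n - n_classes
        valid = (n_classes >= 2) & (df2 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / df1) / np.where(ssw > 0, ssw / df2, np.nan)
        p = stats.f.sf(f, df1, df2)
        p = np.where(ssw == 0, np.finfo(float).tiny, p)  # perfect fit
        p_out[valid] = np.clip(p[valid], np.finfo(float).tiny, 1.0)
        df_out = np.where(valid, df1, 0.0)
    elif model == "additive":
        x = g.codes
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        sxx = np.sum(xc**2, axis=0)
        valid = sxx > 0
        sxy = yc @ xc
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            sse = float(yc @ yc) - b * sxy
            df2 = n - 2
            f = b * sxy / np.where(sse > 0, sse / df2, np.nan)
        p = stats.f.sf(f, 1, df2)
        p = np.where(sse <= 0, np.finfo(float).tiny, p)
        p_out[valid] = np.clip(p[valid], np.finfo(float).tiny, 1.0)
        df_out = np.where(valid, 1.0, 0.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    if n <= 4:
        raise ValueError("too few individuals for a three-class ANOVA")
    return PValueVector(list(g.marker_ids), p_out, df_out)


def _anova_with_covariates(
    g: GenotypeMatrix, y: np.ndarray, covariates: np.ndarray, model: str
) -> PValueVector:
    """Added-last F-test of the marker term on top of a fixed-effect design."""
    X0 = np.column_stack([np.ones(g.n_individuals), np.atleast_2d(covariates)])
    n, q = X0.shape
    p_out = np.full(g.n_markers, np.nan)
    df_out = np.zeros(g.n_markers)
    rss0 = _rss(X0, y)
    for j in range(g.n_markers):
        col = np.rint(np.clip(g.codes[:, j], 0, 2))
        classes = np.unique(col)
        if classes.size < 2:
            continue
        if model == "factor":
            dummies = np.column_stack([(col == c).astype(float) for c in classes[1:]])
        else:
            dummies = col[:, np.newaxis]
        X1 = np.column_stack([X0, dummies])
        if n <= X1.shape[1]:
            raise ValueError("fewer observations than model parameters")
        rss1 = _rss(X1, y)
        df1 = dummies.shape[1]
        df2 = n - X1.shape[1]
        if rss1 <= 0:
            p_out[j] = np.finfo(float).tiny
        else:
            f = ((rss0 - rss1) / df1) / (rss1 / df2)
            p_out[j] = float(np.clip(stats.f.sf(f, df1, df2), np.finfo(float).tiny, 1.0))
        df_out[j] = df1
    return PValueVector(list(g.marker_ids), p_out, df_out)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def pvalues_to_omega(pv: PValueVector, floor: float = 1e-300) -> np.ndarray:
    """omega_i = -log10(max(p_i, floor)); undefined markers map to omega = 0."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    p = np.where(np.isnan(pv.p), 1.0, np.maximum(pv.p, floor))
    return -np.log10(p)


def compute_locus_pi(omega: np.ndarray, marker_ids: list[str] | None = None) -> LocusPrior:
    """Min-max rescale omega into per-marker exclusion probabilities.

    All markers tied at max(omega) receive pi = 0; ties at min(omega) receive
    pi = 1.  A flat omega vector (no architecture signal) falls back to the
    constant pi = 0.95 with a warning.
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega must be finite (apply the p-value floor first)")
    if marker_ids is None:
        marker_ids = [f"snp{j + 1}" for j in range(omega.size)]
    lo, hi = float(omega.min()), float(omega.max())
    if hi == lo:
        warnings.warn(
            "all markers equally significant (flat omega); "
            f"falling back to constant pi = {DEGENERATE_PI}",
            stacklevel=2,
        )
        return LocusPrior(marker_ids, omega, np.full(omega.size, DEGENERATE_PI))
    return LocusPrior(marker_ids, omega, (hi - omega) / (hi - lo))


def binned_pi(
    omega: np.ndarray, thresholds: np.ndarray, marker_ids: list[str] | None = None
) -> LocusPrior:
    """Alternative transform: bin markers by omega before min-max rescaling.

    Markers within a bin share the bin's midpoint omega, so small p-value
    differences inside a class do not translate into different priors.  Off
    by default; thresholds are user-supplied omega cut points.
    """
    omega = np.asarray(omega, dtype=float)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    idx = np.searchsorted(thresholds, omega)
    edges = np.concatenate([[omega.min()], thresholds, [omega.max()]])
    mids = (edges[:-1] + edges[1:]) / 2
    return compute_locus_pi(mids[idx], marker_ids)


def locus_pi_from_data(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    model: str = "factor",
    floor: float = 1e-300,
) -> LocusPrior:
    """ANOVA -> omega -> pi in one call (the training-fold pipeline)."""
    pv = single_marker_anova(g, y, covariates=covariates, model=model)
    return compute_locus_pi(pvalues_to_omega(pv, floor=floor), list(g.marker_ids))


def write_locus_prior(prior: LocusPrior, path: str | Path) -> None:
    pd.DataFrame(
        {"marker_id": prior.marker_ids, "omega": prior.omega, "pi": prior.pi}
    ).to_csv(path, sep="\t", index=False)


def read_locus_prior(path: str | Path) -> LocusPrior:
    df = pd.read_csv(path, sep="\t")
    omega = df["omega"].to_numpy() if "omega" in df else np.zeros(len(df))
    return LocusPrior(df["marker_id"].astype(str).tolist(), omega, df["pi"].to_numpy())
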