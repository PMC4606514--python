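"""Cross-validation protocol: subpopulation sampling, repeated k-fold CV,
prediction accuracy, unbiasedness and the improvement statistic beta.

Accuracy is the Pearson correlation between GEBVs and the response variable
in the validation set.  Unbiasedness is the OLS regression coefficient
relating GEBVs and responses; both regression directions are computed
(GEBVs-on-response by default, the conventional response-on-GEBVs as the
alternate) because the two definitions coexist in the literature.  The
improvement of one method over a baseline is

    beta = (acc_new - acc_base) / acc_base * 100 [%].
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold

__all__ = [
    "CVPlan",
    "EvalReport",
    "make_cv_plan",
    "accuracy",
    "unbiasedness",
    "improvement_beta",
    "run_crossval",
    "summary_table",
]


@dataclasses.dataclass
class CVPlan:
    """Repeated k-fold partition of a (sub)population.

    folds[r][f] holds the validation indices (into the full dataset) of fold
    f in repeat r; individuals lists the subpopulation drawn from the full
    dataset.
    """

    n_individuals: int
    k: int
    repeats: int
    seed: int
    individuals: np.ndarray
    folds: list[list[np.ndarray]]
    subpopulation_size: int | None = None


def make_cv_plan(
    n: int,
    k: int,
    repeats: int,
    subpopulation_size: int | None = None,
    seed: int = 0,
) -> CVPlan:
    """Optionally subsample without replacement, then build `repeats`
    independent shuffled k-fold partitions (fold sizes differ by at most 1)."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    if subpopulation_size is not None:
        if subpopulation_size > n:
            raise ValueError("subpopulation_size exceeds population size")
        individuals = np.sort(rng.choice(n, size=subpopulation_size, replace=False))
    else:
        individuals = np.arange(n)
    if k > individuals.size:
        raise ValueError("more folds than individuals")
    folds: list[list[np.ndarray]] = []
    for r in range(repeats):
        splitter = KFold(n_splits=k, shuffle=True, random_state=int(seed + 1000 * (r + 1)))
        folds.append([individuals[val] for _, val in splitter.split(individuals)])
    return CVPlan(n, k, repeats, seed, individuals, folds, subpopulation_size)


def accuracy(gebv: np.ndarray, response: np.ndarray) -> float:
    """Pearson correlation between GEBVs and responses (NaN if degenerate)."""
    gebv = np.asarray(gebv, dtype=float).ravel()
    response = np.asarray(response, dtype=float).ravel()
    if gebv.shape != response.shape or gebv.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.std(gebv) == 0 or np.std(response) == 0:
        return float("nan")
    return float(np.corrcoef(gebv, response)[0, 1])


def unbiasedness(
    gebv: np.ndarray, response: np.ndarray, direction: str = "gebv_on_response"
) -> float:
    """OLS slope relating GEBVs and responses; 1 means a calibrated scale.

    direction='gebv_on_response' regresses GEBVs on the response;
    'response_on_gebv' is the conventional calibration regression.
    """
    gebv = np.asarray(gebv, dtype=float).ravel()
    response = np.asarray(response, dtype=float).ravel()
    if gebv.shape != response.shape or gebv.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if direction == "gebv_on_response":
        x, z = response, gebv
    elif direction == "response_on_gebv":
        x, z = gebv, response
    else:
        raise ValueError(f"unknown direction {direction!r}")
    vx = float(np.var(x))
    if vx == 0:
        return float("nan")
    return float(np.cov(x, z, ddof=0)[0, 1] / vx)


def improvement_beta(acc_new: float, acc_base: float) -> float:
    """Relative accuracy gain in percent: (acc_new - acc_base)/acc_base * 100."""
    if acc_base == 0:
        raise ZeroDivisionError("baseline accuracy is zero; beta undefined")
    return (acc_new - acc_base) / acc_base * 100.0


@dataclasses.dataclass
class EvalReport:
    """Tidy per-fold records plus aggregation helpers.

    records columns: method, trait, repeat, fold, n_train, n_val, accuracy,
    unbiasedness (GEBVs on response), unbiasedness_alt (response on GEBVs),
    failed.
    """

    records: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SE per method x trait over all repeat x fold validations
        (SE = SD / sqrt(number of validation folds aggregated))."""
        ok = self.records[~self.records["failed"]]
        rows = []
        for (method, trait), grp in ok.groupby(["method", "trait"], sort=False):
            nv = len(grp)
            rows.append(
                {
                    "method": method,
                    "trait": trait,
                    "n_validations": nv,
                    "accuracy_mean": grp["accuracy"].mean(),
                    "accuracy_se": grp["accuracy"].std(ddof=1) / np.sqrt(nv),
                    "unbiasedness_mean": grp["unbiasedness"].mean(),
                    "unbiasedness_se": grp["unbiasedness"].std(ddof=1) / np.sqrt(nv),
                    "unbiasedness_alt_mean": grp["unbiasedness_alt"].mean(),
                }
            )
        return pd.DataFrame(rows)


def run_crossval(
    X: np.ndarray,
    y: np.ndarray,
    methods: dict,
    plan: CVPlan,
    trait: str = "trait",
    reseed_per_fold: bool = True,
) -> EvalReport:
    """Run every method through every repeat x fold of the plan.

    methods maps a name to an unfitted estimator (cloned per fold, so any
    training-data-derived quantity — locus-specific pi, allele frequencies,
    variance components — is recomputed inside each training fold).  A
    method failure in a fold is recorded and flagged; aggregation proceeds
    on the remaining folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rows = []
    for r, rep_folds in enumerate(plan.folds):
        for f, val_idx in enumerate(rep_folds):
            train_idx = np.setdiff1d(plan.individuals, val_idx)
            for name, proto in methods.items():
                est = clone(proto)
                if reseed_per_fold and "seed" in est.get_params():
                    est.set_params(seed=int(est.get_params()["seed"] + 7919 * r + 31 * f))
                row = {
                    "method": name,
                    "trait": trait,
                    "repeat": r,
                    "fold": f,
                    "n_train": train_idx.size,
                    "n_val": val_idx.size,
                    "accuracy": np.nan,
                    "unbiasedness": np.nan,
                    "unbiasedness_alt": np.nan,
                    "failed": False,
                }
                try:
                    est.fit(X[train_idx], y[train_idx])
                    gebv = (
                        est.genetic_values(X[val_idx])
                        if hasattr(est, "genetic_values")
                        else est.predict(X[val_idx])
                    )
                    row["accuracy"] = accuracy(gebv, y[val_idx])
                    row["unbiasedness"] = unbiasedness(gebv, y[val_idx])
                    row["unbiasedness_alt"] = unbiasedness(
                        gebv, y[val_idx], direction="response_on_gebv"
                    )
                except Exception as exc:  # noqa: BLE001 - fold failures are data
                    warnings.warn(f"{name} failed in repeat {r} fold {f}: {exc}", stacklevel=2)
                    row["failed"] = True
                rows.append(row)
    return EvalReport(pd.DataFrame(rows))


def summary_table(aggregates: pd.DataFrame, metric: str = "accuracy_mean") -> pd.DataFrame:
    """Wide method-by-trait table with a per-row 'best' flag on the max mean.

    When aggregates from several subpopulation sizes are concatenated (with a
    'subpopulation' column), a 'Mean' row per trait averages the
    per-subpopulation means, i.e. the overall performance of a method for a
    trait is the arithmetic mean of its subpopulation-level mean accuracies.
    """
    df = aggregates.copy()
    index_cols = ["trait"] + (["subpopulation"] if "subpopulation" in df else [])
    wide = df.pivot_table(index=index_cols, columns="method", values=metric)
    if "subpopulation" in df:
        blocks = []
        for trait, grp in wide.groupby(level="trait", sort=False):
            mean_row = grp.mean(axis=0).to_frame().T
            mean_row.index = pd.MultiIndex.from_tuples(
                [(trait, "Mean")], names=wide.index.names
            )
            blocks.append(pd.concat([grp, mean_row]))
        wide = pd.concat(blocks)
    wide = wide.reset_index()
    method_cols = [c for c in wide.columns if c not in index_cols]
    wide["best"] = wide[method_cols].idxmax(axis=1)
    return wide
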