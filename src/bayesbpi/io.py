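"""Genotype and phenotype containers and their on-disk formats.

Genotypes are additively coded 0/1/2 (count of the second allele: genotypes
11, 12, 22).  Two plain-text dialects are supported: a simple tab-separated
table (``id<TAB>marker1<TAB>...``) and the PLINK ``--recode A`` raw export
(six leading pedigree columns, then per-SNP allele counts).  Phenotypes are a
tab-separated table with one column per trait.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "impute_missing",
    "standardize_phenotypes",
]

_VALID_CODES = (0.0, 1.0, 2.0)


class GenotypeParseError(ValueError):
    """Malformed genotype file (row length, bad code, duplicate ids)."""


@dataclasses.dataclass
class GenotypeMatrix:
    """n x m additive SNP genotype matrix.

    Attributes
    ----------
    individual_ids, marker_ids : lists of unique identifiers.
    codes : float array, entries in {0,1,2} where observed; ``nan`` where
        missing until :func:`impute_missing` fills them with column means.
    missing_mask : boolean array marking originally-missing cells; preserved
        across imputation for audit.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        n, m = self.codes.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 individuals and m >= 1 markers, got {n} x {m}")
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValueError("identifier lists do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise GenotypeParseError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise GenotypeParseError("duplicate marker ids")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.codes)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        observed = self.codes[~self.missing_mask]
        if np.isnan(observed).any():
            raise ValueError("codes contain NaN outside the missing mask")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele: column mean of non-missing codes / 2."""
        with np.errstate(invalid="ignore"):
            masked = np.where(self.missing_mask, np.nan, self.codes)
            return np.nanmean(masked, axis=0) / 2.0

    @property
    def monomorphic(self) -> np.ndarray:
        """Markers with a single observed genotype class (zero information)."""
        masked = np.where(self.missing_mask, np.nan, self.codes)
        mono = np.ones(self.n_markers, dtype=bool)
        for j in range(self.n_markers):
            col = masked[:, j]
            col = col[~np.isnan(col)]
            mono[j] = col.size == 0 or np.unique(col).size < 2
        return mono


@dataclasses.dataclass
class PhenotypeTable:
    """n x t response-variable table (EBVs, deregressed proofs, or phenotypes)."""

    individual_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.individual_ids), len(self.trait_names)):
            raise ValueError("values shape does not match id/trait lists")

    def trait(self, name: str) -> np.ndarray:
        try:
            j = self.trait_names.index(name)
        except ValueError:
            raise KeyError(
                f"trait {name!r} not found; available: {', '.join(self.trait_names)}"
            ) from None
        return self.values[:, j]


def _validate_codes(raw: np.ndarray, marker_ids: Sequence[str], ids: Sequence[str]) -> None:
    bad = ~np.isnan(raw) & ~np.isin(raw, _VALID_CODES)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"invalid genotype code {raw[i, j]!r} for individual "
            f"{ids[i]!r}, marker {marker_ids[j]!r} (row {i + 1}, column {j + 1}); "
            "codes must be 0, 1, 2 or missing"
        )


def read_genotypes(path: str | Path, dialect: str = "tabular") -> GenotypeMatrix:
    """Read a genotype file in the ``tabular`` or ``plink_raw`` dialect.

    Missing tokens: empty field or ``NA`` (both dialects).  Any code outside
    {0, 1, 2, missing} raises :class:`GenotypeParseError` naming the cell.
    """
    path = Path(path)
    if dialect == "tabular":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise GenotypeParseError(f"{path}: expected id column plus >= 1 marker column")
        ids = df.iloc[:, 0].tolist()
        marker_ids = list(df.columns[1:])
        body = df.iloc[:, 1:]
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != lead:
            raise GenotypeParseError(
                f"{path}: not a PLINK raw file (expected leading columns {' '.join(lead)})"
            )
        ids = df["IID"].tolist()
        marker_ids = list(df.columns[6:])
        body = df.iloc[:, 6:]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tabular' or 'plink_raw'")

    raw = body.replace({"NA": np.nan, "": np.nan}).apply(pd.to_numeric, errors="coerce")
    # pd.to_numeric coerces junk strings to NaN; distinguish them from true missing
    junk = raw.isna().to_numpy() & ~body.isin(["NA", ""]).to_numpy()
    if junk.any():
        i, j = np.argwhere(junk)[0]
        raise GenotypeParseError(
            f"{path}: unparseable genotype {body.iloc[i, j]!r} at row {i + 1}, "
            f"marker {marker_ids[j]!r}"
        )
    arr = raw.to_numpy(dtype=float)
    _validate_codes(arr, marker_ids, ids)
    return GenotypeMatrix(ids, marker_ids, arr)


def write_genotypes(g: GenotypeMatrix, path: str | Path, dialect: str = "tabular") -> None:
    """Write genotypes; missing cells become ``NA``. Round-trips exactly."""
    path = Path(path)
    codes = np.where(g.missing_mask, np.nan, g.codes)

    def fmt(v: float) -> str:
        if np.isnan(v):
            return "NA"
        return str(int(v)) if float(v).is_integer() else repr(v)

    with open(path, "w") as fh:
        if dialect == "tabular":
            fh.write("id\t" + "\t".join(g.marker_ids) + "\n")
            for i, iid in enumerate(g.individual_ids):
                fh.write(iid + "\t" + "\t".join(fmt(v) for v in codes[i]) + "\n")
        elif dialect == "plink_raw":
            fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(g.marker_ids) + "\n")
            for i, iid in enumerate(g.individual_ids):
                fh.write(
                    f"{iid} {iid} 0 0 0 -9 " + " ".join(fmt(v) for v in codes[i]) + "\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    traits = list(df.columns[1:])
    return PhenotypeTable(ids, traits, df.iloc[:, 1:].to_numpy(dtype=float))


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(p.values, columns=p.trait_names)
    df.insert(0, "id", p.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing cells with the column mean of non-missing codes.

    Mean imputation on the 0-2 scale leaves allele frequencies unchanged.
    The missing mask is preserved for audit.  A fully-missing column is an
    error (no information to impute from).
    """
    fully_missing = g.missing_mask.all(axis=0)
    if fully_missing.any():
        bad = [g.marker_ids[j] for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"markers with all genotypes missing: {', '.join(bad)}")
    if not g.missing_mask.any():
        return GenotypeMatrix(
            list(g.individual_ids), list(g.marker_ids), g.codes.copy(), g.missing_mask.copy()
        )
    col_means = 2.0 * g.allele_freq
    codes = np.where(g.missing_mask, col_means[np.newaxis, :], g.codes)
    return GenotypeMatrix(
        list(g.individual_ids), list(g.marker_ids), codes, g.missing_mask.copy()
    )


def standardize_phenotypes(p: PhenotypeTable, method: str = "zscore") -> PhenotypeTable:
    """Rescale each trait to a standard normal scale.

    ``zscore`` (default) subtracts the mean and divides by the sample SD
    (n-1 denominator); it preserves ordering and is reversible.  ``rank_int``
    applies a rank-based inverse-normal transform (Blom offset 3/8) for
    heavily non-Gaussian traits.
    """
    values = p.values.copy()
    n = values.shape[0]
    for j, name in enumerate(p.trait_names):
        col = values[:, j]
        if np.std(col, ddof=1) == 0:
            raise ValueError(f"trait {name!r} has zero variance; cannot standardize")
        if method == "zscore":
            values[:, j] = (col - col.mean()) / np.std(col, ddof=1)
        elif method == "rank_int":
            ranks = stats.rankdata(col)
            values[:, j] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        else:
            raise ValueError(f"unknown method {method!r}")
    return PhenotypeTable(list(p.individual_ids), list(p.trait_names), values, standardized=True)
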