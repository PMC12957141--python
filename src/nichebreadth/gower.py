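"""Host trait tables and Gower dissimilarity on mixed-type traits.

The functional facet of niche breadth is computed from a species-by-species
dissimilarity matrix built with Gower's coefficient, which averages
range-normalised absolute differences (quantitative and ordinal traits) and
simple mismatches (categorical and binary traits), skipping pairwise-missing
entries and renormalising the denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRAIT_TYPES",
    "TraitTable",
    "DissimilarityMatrix",
    "gower_matrix",
    "log_transform_columns",
]

log = logging.getLogger(__name__)

TRAIT_TYPES = ("quantitative", "ordinal", "categorical", "binary")


@dataclass
class TraitTable:
    """Species x traits with per-trait type tags, optional weights, NAs allowed.

    ``data`` is indexed by species label.  ``types`` maps every column to one
    of :data:`TRAIT_TYPES`; quantitative and ordinal columns must be numeric
    (ordinal as integer ranks).
    """

    data: pd.DataFrame
    types: Mapping[str, str]
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate species labels in trait table")
        missing = set(self.data.columns) - set(self.types)
        if missing:
            raise ValueError(f"no type tag for traits: {sorted(missing)}")
        for col, t in self.types.items():
            if t not in TRAIT_TYPES:
                raise ValueError(f"unknown trait type {t!r} for {col!r}")
            if col not in self.data.columns:
                raise ValueError(f"type tag for unknown trait {col!r}")
            if t in ("quantitative", "ordinal"):
                if not pd.api.types.is_numeric_dtype(self.data[col]):
                    raise ValueError(f"{t} trait {col!r} must be numeric")
        self.weights = {c: float(self.weights.get(c, 1.0)) for c in self.data.columns}

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def from_csv(cls, traits_path, schema_path) -> "TraitTable":
        """Load a trait CSV (first column species) plus a YAML schema.

        The schema maps column name to either a type string or a mapping with
        ``type`` and optional ``weight`` keys.
        """
        df = pd.read_csv(traits_path, index_col=0)
        with open(schema_path) as fh:
            schema = yaml.safe_load(fh)
        types, weights = {}, {}
        for col, entry in schema.items():
            if isinstance(entry, str):
                types[col] = entry
            else:
                types[col] = entry["type"]
                if "weight" in entry:
                    weights[col] = float(entry["weight"])
        return cls(data=df, types=types, weights=weights)


@dataclass
class DissimilarityMatrix:
    """Square symmetric matrix of pairwise dissimilarities in [0, 1]."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.df.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.nanmin(m) < -1e-12 or np.nanmax(m) > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def labels(self) -> list[str]:
        return list(self.df.index)

    def submatrix(self, labels) -> np.ndarray:
        labels = list(labels)
        missing = set(labels) - set(self.df.index)
        if missing:
            raise KeyError(f"species missing from dissimilarity matrix: {sorted(missing)}")
        return self.df.loc[labels, labels].to_numpy(dtype=float)


def gower_matrix(
    tt: TraitTable, ordinal_mode: str = "rank"
) -> DissimilarityMatrix:
    """Gower dissimilarity over a mixed-type trait table.

    d_ij = sum_k w_k delta_ijk s_ijk / sum_k w_k delta_ijk with
    s_ijk = |x_ik - x_jk| / range_k for quantitative (and, with
    ``ordinal_mode="rank"``, ordinal-as-ranks) traits and a 0/1 mismatch for
    categorical and binary traits; delta_ijk = 1 only when both values are
    observed and the trait is informative (range > 0).  Constant traits are
    excluded with a warning; a species pair sharing no observed trait is an
    error.
    """
    if ordinal_mode not in ("rank", "categorical"):
        raise ValueError("ordinal_mode must be 'rank' or 'categorical'")
    species = tt.species
    n = len(species)
    if n < 2:
        raise ValueError("need at least two species")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in tt.data.columns:
        kind = tt.types[col]
        if kind == "ordinal" and ordinal_mode == "categorical":
            kind = "categorical"
        w = tt.weights[col]
        vals = tt.data[col]
        if kind in ("quantitative", "ordinal"):
            x = vals.to_numpy(dtype=float)
            obs = ~np.isnan(x)
            if obs.sum() < 2:
                continue
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                warnings.warn(
                    f"trait {col!r} is constant over the table and is excluded "
                    "from Gower comparisons",
                    stacklevel=2,
                )
                continue
            s = np.abs(x[:, None] - x[None, :]) / rng
            d = obs[:, None] & obs[None, :]
            s = np.where(d, s, 0.0)
        else:
            codes = vals.astype("object")
            obs = vals.notna().to_numpy()
            arr = codes.to_numpy()
            if obs.sum() < 2:
                continue
            if len(set(arr[obs])) < 2:
                warnings.warn(
                    f"trait {col!r} is constant over the table and is excluded "
                    "from Gower comparisons",
                    stacklevel=2,
                )
                continue
            eq = arr[:, None] == arr[None, :]
            d = obs[:, None] & obs[None, :]
            s = np.where(d, (~eq).astype(float), 0.0)
        num += w * s
        den += w * d
    np.fill_diagonal(den, 1.0)  # diagonal is 0/0 by construction; define d_ii = 0
    np.fill_diagonal(num, 0.0)
    bad = np.argwhere(den == 0)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no jointly "
            "observed informative trait"
        )
    out = num / den
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return DissimilarityMatrix(pd.DataFrame(out, index=species, columns=species))


def log_transform_columns(tt: TraitTable, columns) -> TraitTable:
    """Replace the named quantitative columns by their natural logs."""
    df = tt.data.copy()
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"no trait column {col!r}")
        x = df[col].astype(float)
        bad = x[x <= 0].dropna()
        if len(bad):
            sp = bad.index[0]
            raise ValueError(
                f"cannot log-transform {col!r}: non-positive value "
                f"{bad.iloc[0]} for species {sp!r}"
            )
        df[col] = np.log(x)
    return TraitTable(data=df, types=dict(tt.types), weights=dict(tt.weights))
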