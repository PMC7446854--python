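"""OTU-count transformations and predictor-matrix assembly.

Phenotypes are believed to act on the *composition* of the community
rather than on raw counts, so OTU counts enter predictive models after
a transformation of the proportion Z/T:

* arcsine-square-root, ``arcsin(sqrt(Z/T))`` — the variance-stabilizing
  transformation for binomial proportions;
* presence/absence, ``I(Z > 0)``.

:func:`build_design` assembles the full predictor matrix x_i: an
intercept column of ones, the transformed OTU block, fixed factors
(categorical factors dummy-coded with k−1 columns, reference = first
level in sorted order), and optionally the random-factor groups as
dummy covariates.  Standardization statistics are computed on training
rows only and carried in the object so that held-out samples can be
mapped through the same affine transform without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_filters import DataError, OTUTable, SampleCovariates

ROLE_INTERCEPT = "intercept"
ROLE_OTU = "otu"
ROLE_FIXED = "fixed"
ROLE_RANDOM = "random-dummy"


def arcsin_sqrt_transform(table: OTUTable) -> np.ndarray:
    """Elementwise arcsin(sqrt(Z_ij / T_i)); range [0, pi/2]."""
    ratio = table.counts / table.totals[:, None]
    if (ratio > 1).any():
        i, j = np.argwhere(ratio > 1)[0]
        raise DataError(
            f"count exceeds total reads at sample {table.sample_ids[i]!r}, taxon {table.taxon_ids[j]!r}"
        )
    return np.arcsin(np.sqrt(ratio))


def binary_transform(table: OTUTable) -> np.ndarray:
    """Presence/absence indicator I(Z_ij > 0) as floats."""
    return (table.counts > 0).astype(float)


def transform_counts(table: OTUTable, transform: str) -> np.ndarray:
    if transform == "asin":
        return arcsin_sqrt_transform(table)
    if transform == "binary":
        return binary_transform(table)
    raise ValueError(f"unknown transform {transform!r}")


def dummy_code(values: np.ndarray, levels: tuple | None = None) -> tuple[np.ndarray, list]:
    """k−1 dummy columns for a categorical vector; reference = first sorted level.

    Returns (matrix, non-reference levels).  ``levels`` fixes the level
    order (training levels) so test rows encode consistently; unseen
    test levels encode as all-zero rows.
    """
    values = np.asarray(values)
    if levels is None:
        levels = tuple(sorted(set(values.tolist())))
    non_ref = list(levels[1:])
    mat = np.zeros((values.shape[0], len(non_ref)))
    for j, lev in enumerate(non_ref):
        mat[:, j] = values == lev
    return mat, non_ref


@dataclass
class DesignMatrix:
    """Predictor matrix with column metadata and training-scale statistics."""

    values: np.ndarray
    column_names: list[str]
    column_roles: list[str]
    # affine standardization statistics (identity when standardize=False)
    center: np.ndarray
    scale: np.ndarray
    # level orders for categorical factors, keyed by factor name
    levels: dict[str, tuple]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def columns_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero([r == role for r in self.column_roles])

    @property
    def penalized_mask(self) -> np.ndarray:
        """True for columns a LASSO penalty applies to (everything but the intercept)."""
        return np.array([r != ROLE_INTERCEPT for r in self.column_roles])

    def apply_scaling(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.center) / self.scale


def _raw_design(
    transformed: np.ndarray,
    covs: SampleCovariates,
    include_random: bool,
    levels: dict[str, tuple] | None,
    taxon_ids: tuple[str, ...] | None,
) -> tuple[np.ndarray, list[str], list[str], dict[str, tuple]]:
    n = transformed.shape[0]
    if covs.n_samples != n:
        raise DataError("covariates not aligned with the transformed matrix")
    cols = [np.ones((n, 1)), transformed]
    names = ["(intercept)"]
    if taxon_ids is not None:
        names += list(taxon_ids)
    else:
        names += [f"otu{j}" for j in range(transformed.shape[1])]
    roles = [ROLE_INTERCEPT] + [ROLE_OTU] * transformed.shape[1]
    out_levels: dict[str, tuple] = {}
    for name, v in covs.fixed.items():
        v = np.asarray(v)
        if np.issubdtype(v.dtype, np.number):
            cols.append(v.reshape(-1, 1).astype(float))
            names.append(name)
            roles.append(ROLE_FIXED)
        else:
            lv = levels.get(name) if levels else None
            if lv is None:
                lv = tuple(sorted(set(v.tolist())))
            mat, non_ref = dummy_code(v, lv)
            cols.append(mat)
            names += [f"{name}[{lev}]" for lev in non_ref]
            roles += [ROLE_FIXED] * len(non_ref)
            out_levels[name] = lv
    if include_random:
        for name, v in covs.random.items():
            v = np.asarray(v)
            lv = levels.get(name) if levels else None
            if lv is None:
                lv = tuple(sorted(set(v.tolist())))
            mat, non_ref = dummy_code(v, lv)
            cols.append(mat)
            names += [f"{name}[{lev}]" for lev in non_ref]
            roles += [ROLE_RANDOM] * len(non_ref)
            out_levels[name] = lv
    return np.hstack(cols), names, roles, out_levels


def build_design(
    transformed: np.ndarray,
    covs: SampleCovariates,
    include_random: bool = True,
    standardize: bool = True,
    taxon_ids: tuple[str, ...] | None = None,
) -> DesignMatrix:
    """Assemble the predictor matrix x_i on training rows.

    When ``standardize``, all non-intercept columns are centered and
    scaled to unit variance using these (training) rows; constant
    columns are centered but left unscaled.
    """
    raw, names, roles, levels = _raw_design(transformed, covs, include_random, None, taxon_ids)
    center = np.zeros(raw.shape[1])
    scale = np.ones(raw.shape[1])
    if standardize:
        non_int = np.array([r != ROLE_INTERCEPT for r in roles])
        center[non_int] = raw[:, non_int].mean(axis=0)
        sd = raw[:, non_int].std(axis=0)
        scale[non_int] = np.where(sd > 0, sd, 1.0)  # constant column: flagged by scale 1
    values = (raw - center) / scale
    return DesignMatrix(values, names, roles, center, scale, levels)


def apply_design(
    design: DesignMatrix,
    transformed: np.ndarray,
    covs: SampleCovariates,
    include_random: bool = True,
    taxon_ids: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Encode new (test) rows with the training design's levels and scaling."""
    raw, names, _, _ = _raw_design(transformed, covs, include_random, design.levels, taxon_ids)
    if names != design.column_names:
        raise DataError("test design columns do not match the training design")
    return design.apply_scaling(raw)
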