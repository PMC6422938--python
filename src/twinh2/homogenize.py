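"""Trait homogenization: nuisance-covariate residualisation followed by
rank-based inverse normal transformation (INT).

Variance-component models assume multivariate normality; outliers,
skewness and kurtosis in a trait bias the fast approximation estimators in
particular.  Homogenizing a trait means (1) regressing out the nuisance
covariates (age, sex and, optionally, their quadratic/interaction
expansion) by ordinary least squares, and (2) replacing the residual ranks
by standard-normal quantiles, which forces each marginal distribution to
be normal.  It cannot make the joint distribution multivariate normal, but
it removes the influence of marginal outliers.

The rank-to-quantile map uses Blom's offset, Φ⁻¹((r − 3/8)/(n + ¼)), the
standard approximation to the expected normal order statistics; ties get
average ranks so tied inputs stay tied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, DegenerateTraitError, ValidationError
from .simulate import TraitMatrix

__all__ = ["CovariateSpec", "design_matrix", "residualize",
           "inverse_normal_transform", "homogenize_traits"]


@dataclass(frozen=True)
class CovariateSpec:
    """Nuisance covariates: base ``age`` (years) and ``sex`` ({0,1});
    ``expand=True`` adds age², age×sex and age²×sex.  An intercept is
    always included."""

    columns: tuple[str, ...] = ("age", "sex")
    expand: bool = False


def design_matrix(spec: CovariateSpec, data: pd.DataFrame) -> np.ndarray:
    """Build the full-rank design matrix (intercept first); raises
    :class:`CollinearityError` naming the offending columns."""
    missing = [c for c in spec.columns if c not in data.columns]
    if missing:
        raise ValidationError(f"covariate data lacks columns: {missing}")
    cols = {"intercept": np.ones(len(data))}
    for c in spec.columns:
        cols[c] = data[c].to_numpy(float)
    if spec.expand:
        if not {"age", "sex"} <= set(spec.columns):
            raise ValidationError("expansion requires both age and sex")
        age = cols["age"]
        sex = cols["sex"]
        cols["age2"] = age**2
        cols["age_x_sex"] = age * sex
        cols["age2_x_sex"] = age**2 * sex
    x = np.column_stack(list(cols.values()))
    if not np.isfinite(x).all():
        raise ValidationError("covariate data contains non-finite values")
    # incremental rank check pins down which columns are redundant
    names = list(cols)
    offending = []
    kept = x[:, :1]
    for k in range(1, x.shape[1]):
        trial = np.column_stack([kept, x[:, k]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            offending.append(names[k])
        else:
            kept = trial
    if offending:
        raise CollinearityError(offending)
    return x


def residualize(trait: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of ``trait`` on ``design`` (which includes the
    intercept): mean zero, orthogonal to every design column."""
    y = np.asarray(trait, float)
    if not np.isfinite(y).all():
        raise ValidationError("trait contains non-finite values")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def inverse_normal_transform(values: np.ndarray, offset: str = "blom") -> np.ndarray:
    """Map values to standard-normal quantiles by rank.

    ``offset='blom'`` uses (r − 3/8)/(n + ¼); ``'waerden'`` uses r/(n + 1).
    Ties receive average ranks.  Strictly order preserving on distinct
    inputs; needs at least three observations.
    """
    v = np.asarray(values, float)
    if v.ndim != 1:
        raise ValidationError("expected a 1-D value vector")
    if v.size < 3:
        raise ValidationError("inverse normal transform needs n >= 3")
    if not np.isfinite(v).all():
        raise ValidationError("values contain non-finite entries")
    ranks = stats.rankdata(v, method="average")
    n = v.size
    if offset == "blom":
        p = (ranks - 0.375) / (n + 0.25)
    elif offset == "waerden":
        p = ranks / (n + 1.0)
    else:
        raise ValidationError(f"unknown offset convention {offset!r}")
    return stats.norm.ppf(p)


def homogenize_traits(traits: TraitMatrix, spec: CovariateSpec | None = None,
                      offset: str = "blom") -> TraitMatrix:
    """Residualise then inverse-normalise every trait column.

    The returned matrix is flagged ``homogenized`` and carries no
    covariates: downstream fits use an intercept-only nuisance model.
    """
    if spec is not None and traits.covariates is not None:
        x = design_matrix(spec, traits.covariates)
    else:
        x = np.ones((len(traits.ids), 1))
    out = np.empty_like(traits.values)
    for t, name in enumerate(traits.trait_names):
        y = traits.values[:, t]
        if np.ptp(y) == 0.0:
            raise DegenerateTraitError(f"trait {name} is constant")
        out[:, t] = inverse_normal_transform(residualize(y, x), offset=offset)
    return TraitMatrix(ids=list(traits.ids), values=out,
                       trait_names=list(traits.trait_names),
                       covariates=None, truth=traits.truth, homogenized=True)
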