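"""Simulation of quantitative traits over a pedigree.

Each trait decomposes as ``y = g + c + e``: an additive genetic deviation
``g`` drawn from a zero-mean multivariate normal with covariance
``2Φ·h²·σP²``, a common-environment deviation ``c`` shared within each
family with variance ``c²·σP²``, and an independent unique-environment
residual ``e`` with the remaining variance ``(1−h²−c²)·σP²``.  Sampling
goes through the family-block square root of ``2Φ``, so MZ co-twins share
their genetic deviation exactly and cross-family values are independent.

Each trait column has its own random stream keyed by ``(seed, trait
index)``: any subset of columns is reproducible without generating the
rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError, ValidationError
from .pedigree import Pedigree, compute_relatedness, make_twin_pedigree

__all__ = ["SimulationDesign", "TraitMatrix", "simulate_traits", "benchmark_design"]

# stream index reserved for dataset-level draws (covariates); trait columns
# use their own index and stay below this in any realistic design
_COVARIATE_STREAM = 2**30


@dataclass(frozen=True)
class SimulationDesign:
    """Per-trait variance fractions and dataset-level options.

    ``h2_values`` and ``c2_values`` hold the true additive-genetic and
    common-environment fractions of the total variance ``total_variance``
    (trait units²) for each of ``n_traits`` traits; ``h2 + c2 ≤ 1`` per
    trait.  ``covariate_effects`` maps covariate name ('age' in years,
    'sex' in {0,1}) to an additive coefficient, applied after the variance
    components are drawn.
    """

    n_traits: int
    h2_values: np.ndarray
    c2_values: np.ndarray | None = None
    total_variance: float = 1.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        h2 = np.asarray(self.h2_values, dtype=float)
        c2 = (np.zeros(self.n_traits) if self.c2_values is None
              else np.asarray(self.c2_values, dtype=float))
        if h2.shape != (self.n_traits,) or c2.shape != (self.n_traits,):
            raise ConfigurationError("h2/c2 vectors must have length n_traits")
        if (h2 < 0).any() or (c2 < 0).any() or (h2 + c2 > 1 + 1e-12).any():
            raise ConfigurationError("need 0 ≤ h2, 0 ≤ c2 and h2 + c2 ≤ 1 per trait")
        if self.total_variance <= 0:
            raise ConfigurationError("total_variance must be positive")
        object.__setattr__(self, "h2_values", h2)
        object.__setattr__(self, "c2_values", c2)
        known = {"age", "sex"}
        bad = set(self.covariate_effects) - known
        if bad:
            raise ConfigurationError(f"unknown covariates: {sorted(bad)}")


@dataclass(frozen=True)
class TraitMatrix:
    """Trait values for phenotyped individuals (rows) by trait (columns).

    ``covariates`` (optional) holds 'age'/'sex' columns aligned to ``ids``;
    ``truth`` (simulations only) records true h²/c² per trait;
    ``homogenized`` flags data already residualised and rank-normalised,
    so downstream fits use an intercept-only nuisance model.
    """

    ids: list[str]
    values: np.ndarray
    trait_names: list[str]
    covariates: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None
    homogenized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.trait_names)):
            raise ValidationError("trait matrix shape does not match ids/trait names")
        if not np.isfinite(v).all():
            raise ValidationError("trait matrix contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.trait_names)
        frame.insert(0, "id", self.ids)
        return frame


def _block_sqrt(rel_values: np.ndarray, families: list[str]) -> sparse.csr_matrix:
    """Symmetric PSD square root of the block-diagonal 2Φ, as sparse blocks."""
    codes = pd.factorize(np.asarray(families))[0]
    grouped = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    cache: dict[bytes, np.ndarray] = {}
    blocks, order = [], []
    for idx in np.split(grouped, np.cumsum(counts)[:-1]):
        block = rel_values[np.ix_(idx, idx)]
        key = block.tobytes()
        if key not in cache:
            w, u = np.linalg.eigh(block)
            cache[key] = (u * np.sqrt(np.clip(w, 0.0, None))) @ u.T
        blocks.append(cache[key])
        order.append(idx)
    perm = np.concatenate(order)
    a = sparse.block_diag(blocks, format="csr")
    # undo the family grouping permutation: rows/cols back to id order
    p = sparse.csr_matrix((np.ones(len(perm)), (perm, np.arange(len(perm)))),
                          shape=(len(perm), len(perm)))
    return p @ a @ p.T


def simulate_traits(ped: Pedigree, design: SimulationDesign) -> TraitMatrix:
    """Draw the trait matrix for ``design`` over ``ped``'s phenotyped members."""
    rel = compute_relatedness(ped)
    n = len(rel.ids)
    if n < 2:
        raise ConfigurationError("need at least 2 phenotyped individuals")
    a = _block_sqrt(rel.values, rel.families)
    fam_codes = pd.Categorical(rel.families).codes
    n_fam = fam_codes.max() + 1
    v = design.total_variance

    out = np.empty((n, design.n_traits))
    for t in range(design.n_traits):
        rng = np.random.default_rng([design.seed, t])
        h2 = design.h2_values[t]
        c2 = design.c2_values[t]
        g = a @ rng.standard_normal(n)
        c = rng.standard_normal(n_fam)[fam_codes]
        e = rng.standard_normal(n)
        out[:, t] = (np.sqrt(h2 * v) * g + np.sqrt(c2 * v) * c
                     + np.sqrt((1.0 - h2 - c2) * v) * e)

    covariates = None
    if design.covariate_effects:
        rng = np.random.default_rng([design.seed, _COVARIATE_STREAM])
        covariates = pd.DataFrame({
            "age": rng.uniform(20.0, 60.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
        })
        for name, coef in design.covariate_effects.items():
            out += coef * covariates[name].to_numpy()[:, None]

    width = max(4, len(str(design.n_traits)))
    names = [f"trait_{t + 1:0{width}d}" for t in range(design.n_traits)]
    truth = pd.DataFrame({"trait": names, "true_h2": design.h2_values,
                          "true_c2": design.c2_values})
    return TraitMatrix(ids=list(rel.ids), values=out, trait_names=names,
                       covariates=covariates, truth=truth)


def benchmark_design(seed: int, n_traits: int = 10_000) -> tuple[Pedigree, TraitMatrix]:
    """The reference twin simulation: 125 MZ + 125 DZ pair families (1,000
    persons, founders unphenotyped → 500 phenotyped twins) and ``n_traits``
    unit-variance normal traits whose true h² lies on an evenly spaced grid
    over [0, 1], with no shared-environment or covariate effects.
    """
    ped = make_twin_pedigree(125, 125, phenotype_founders=False)
    design = SimulationDesign(
        n_traits=n_traits,
        h2_values=np.linspace(0.0, 1.0, n_traits),
        seed=seed,
    )
    return ped, simulate_traits(ped, design)
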