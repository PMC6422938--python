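"""Non-iterative heritability approximations.

``fit_fphi`` works on the eigen-rotated trait: the squared rotated values
``sᵢ = zᵢ²`` have expectation ``σe² + λᵢ·σg²``, so an ordinary
least-squares line of *s* on the eigenvalues gives initial variance
components, and a single weighted-least-squares step — with weights
``1/(2·(σ̃e² + λᵢσ̃g²)²)``, the reciprocal variance of squared normals —
produces the asymptotically unbiased single-step estimate.  No further
iteration is performed (iterating to convergence would reproduce the MLE;
that path exists only behind a debug flag).

``fit_apace`` uses the squared-difference device: for a pair (i, j),
``d = ½(yᵢ − yⱼ)²`` has expectation ``σP² − cov(i, j)``, so regressing *d*
over MZ, DZ and unrelated pairs on relatedness contrasts recovers the
variance components.  AE: ``E[d] = (1−r)·σg² + σe²``; ACE adds
``(1−fam)·σc²``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateTraitError, UnidentifiableDesignError,
                     ValidationError)
from .mle import VarCompEstimate, _residualize_traits, loglik_ae
from .pedigree import KinshipEigen, RelatednessMatrix
from .simulate import TraitMatrix

__all__ = ["PairSet", "fit_fphi", "build_pairs", "fit_apace"]

_VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class PairSet:
    """Unordered subject pairs labelled with relatedness and family sharing.

    ``i``/``j`` index rows of the trait matrix; ``r = 2Φᵢⱼ``; ``same_family``
    marks pairs from one household (the shared-environment contrast).
    """

    i: np.ndarray
    j: np.ndarray
    r: np.ndarray
    same_family: np.ndarray

    def __post_init__(self) -> None:
        if (self.i == self.j).any():
            raise ValidationError("self-pairs are not allowed")
        key = np.minimum(self.i, self.j) * (max(self.i.max(), self.j.max()) + 1) \
            + np.maximum(self.i, self.j)
        if len(np.unique(key)) != len(key):
            raise ValidationError("duplicate pairs")

    def __len__(self) -> int:
        return len(self.i)

    def subsample_unrelated(self, max_ratio: float, seed: int) -> "PairSet":
        """Keep all related pairs and at most ``max_ratio`` times as many
        unrelated pairs, chosen by a fixed-seed draw."""
        related = self.r > 0
        n_keep = int(np.ceil(max_ratio * related.sum()))
        unrel_idx = np.flatnonzero(~related)
        if len(unrel_idx) <= n_keep:
            return self
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(unrel_idx, size=n_keep, replace=False))
        sel = np.sort(np.concatenate([np.flatnonzero(related), keep]))
        return PairSet(self.i[sel], self.j[sel], self.r[sel], self.same_family[sel])


def build_pairs(rel: RelatednessMatrix) -> PairSet:
    """Enumerate every unordered subject pair with its 2Φ label and
    same-family flag."""
    n = len(rel.ids)
    iu, ju = np.triu_indices(n, k=1)
    fam = np.asarray(rel.families)
    return PairSet(i=iu, j=ju, r=rel.values[iu, ju],
                   same_family=fam[iu] == fam[ju])


def fit_fphi(traits: TraitMatrix, eigen: KinshipEigen,
             debug_iterate: int = 0) -> list[VarCompEstimate]:
    """Single-step WLS heritability on the rotated trait, per trait column.

    ``debug_iterate > 0`` repeats the WLS step that many extra times
    (diagnostic only; the estimator is defined by the single step).
    """
    if traits.ids != eigen.ids:
        raise ValidationError("trait rows and eigendecomposition ids differ")
    lam = eigen.eigenvalues
    if np.ptp(lam) < 1e-12:
        raise UnidentifiableDesignError(
            "all kinship eigenvalues equal — h2 is unidentifiable")
    resid = _residualize_traits(traits)
    z = eigen.rotation.T @ resid
    s = z**2                                   # (n, T): E[s_i] = σe² + λσg²

    x = np.column_stack([np.ones_like(lam), lam])
    beta = np.linalg.lstsq(x, s, rcond=None)[0]        # stage 1, all traits
    for _ in range(1 + debug_iterate):
        fitted = x @ beta                               # predicted variances
        scale = np.maximum(np.mean(s, axis=0), _VAR_FLOOR)
        v = np.maximum(fitted, 1e-6 * scale)            # guard near-zero fits
        w = 1.0 / (2.0 * v**2)
        # per-trait 2x2 weighted normal equations, vectorised over traits
        a11 = w.sum(axis=0)
        a12 = (w * lam[:, None]).sum(axis=0)
        a22 = (w * (lam**2)[:, None]).sum(axis=0)
        b1 = (w * s).sum(axis=0)
        b2 = (w * lam[:, None] * s).sum(axis=0)
        det = a11 * a22 - a12**2
        beta = np.vstack([(a22 * b1 - a12 * b2) / det,
                          (a11 * b2 - a12 * b1) / det])

    out = []
    for t, name in enumerate(traits.trait_names):
        if np.var(resid[:, t]) <= 0:
            raise DegenerateTraitError(f"trait {name} has zero variance")
        se2 = max(float(beta[0, t]), 0.0)
        sg2 = max(float(beta[1, t]), 0.0)
        sp2 = se2 + sg2
        if sp2 <= 0:
            raise DegenerateTraitError(f"trait {name}: all components truncated to zero")
        h2 = float(np.clip(sg2 / sp2, 0.0, 1.0))
        # the likelihood is undefined at h2 = 1 when a kinship eigenvalue is 0
        ll = (None if h2 >= 1.0 and lam.min() <= 0.0
              else loglik_ae(h2, sp2, z[:, t], lam))
        out.append(VarCompEstimate(
            trait=name, method="fphi", model="AE",
            sigma_g2=h2 * sp2, sigma_e2=(1.0 - h2) * sp2, sigma_p2=sp2, h2=h2,
            loglik=ll, n_iter=1 + debug_iterate))
    return out


def fit_apace(traits: TraitMatrix, pairs: PairSet, model: str = "AE",
              max_unrelated_ratio: float | None = None,
              subsample_seed: int = 0) -> list[VarCompEstimate]:
    """Squared pair-difference regression heritability, per trait column.

    ``max_unrelated_ratio`` optionally caps the (dominant) unrelated-pair
    count at that multiple of the related-pair count via a fixed-seed
    subsample — useful beyond a few thousand subjects where the full
    enumeration is quadratic.
    """
    if model not in ("AE", "ACE"):
        raise ValidationError(f"unknown model {model!r}")
    if max_unrelated_ratio is not None:
        pairs = pairs.subsample_unrelated(max_unrelated_ratio, subsample_seed)

    cols = [1.0 - pairs.r]
    if model == "ACE":
        cols.append(1.0 - pairs.same_family.astype(float))
    cols.append(np.ones(len(pairs)))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise UnidentifiableDesignError(
            f"pair design is collinear for the {model} model "
            "(too few distinct relatedness classes)")

    resid = _residualize_traits(traits)
    d = 0.5 * (resid[pairs.i] - resid[pairs.j])**2     # (n_pairs, T)
    beta = np.linalg.lstsq(x, d, rcond=None)[0]

    out = []
    for t, name in enumerate(traits.trait_names):
        if np.var(resid[:, t]) <= 0:
            raise DegenerateTraitError(f"trait {name} has zero variance")
        comp = np.maximum(beta[:, t], 0.0)             # truncate then renormalise
        sg2 = float(comp[0])
        sc2 = float(comp[1]) if model == "ACE" else None
        se2 = float(comp[-1])
        sp2 = sg2 + se2 + (sc2 or 0.0)
        if sp2 <= 0:
            raise DegenerateTraitError(f"trait {name}: all components truncated to zero")
        h2 = float(np.clip(sg2 / sp2, 0.0, 1.0))
        out.append(VarCompEstimate(
            trait=name, method="apace", model=model,
            sigma_g2=sg2, sigma_e2=se2, sigma_c2=sc2, sigma_p2=sp2,
            h2=h2, c2=None if sc2 is None else sc2 / sp2))
    return out
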