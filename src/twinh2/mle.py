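"""Maximum-likelihood AE / ACE variance-component fitting on the
eigen-rotated likelihood.

After rotating a (residualised) trait vector by the eigenvectors of ``2Φ``,
the observations become independent with variances
``wᵢ·σP² = ((1−h²) + λᵢ·h²)·σP²``.  The total variance profiles out in
closed form, ``σ̂P²(h²) = (1/n)·Σ zᵢ²/wᵢ``, reducing the AE fit to a 1-D
bounded maximisation over h² ∈ [0, 1].  Two algorithmically independent
optimizers are provided:

* ``mle_a`` — Newton's method on h² with the analytic gradient and Hessian
  of the profile log-likelihood, safeguarded by bisection and projected to
  the unit interval;
* ``mle_b`` — a 0.01-step grid scan followed by golden-section refinement.

Significance of h² is assessed by the boundary likelihood-ratio test:
twice the log-likelihood difference against the σg² = 0 model, referred to
a ½:½ mixture of a point mass at zero and a χ² with one degree of freedom.

The ACE extension (shared twin environment σc²) is supported on designs
where ``2Φ`` and the family-sharing matrix commute — independent twin/sib
pair families — via their joint diagonalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (ConvergenceError, DegenerateTraitError,
                     UnsupportedDesignError, ValidationError)
from .pedigree import KinshipEigen, RelatednessMatrix
from .simulate import TraitMatrix

__all__ = ["VarCompEstimate", "loglik_ae", "fit_mle", "lrt_heritability",
           "estimates_to_frame"]

_H2_TOL = 1e-8
_MAX_ITER = 100
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class VarCompEstimate:
    """A fitted variance decomposition for one trait.

    Variances are in trait units²; ``h2 = sigma_g2 / sigma_p2`` and
    ``sigma_p2`` is the sum of the fitted components.  ``loglik`` is the
    attained natural-log likelihood; ``lrt_stat``/``lrt_p`` come from the
    boundary mixture test against σg² = 0 (None for estimators that do not
    evaluate a likelihood).
    """

    trait: str
    method: str            # mle_a | mle_b | fphi | apace
    model: str             # AE | ACE
    sigma_g2: float
    sigma_e2: float
    sigma_p2: float
    h2: float
    sigma_c2: float | None = None
    c2: float | None = None
    loglik: float | None = None
    lrt_stat: float | None = None
    lrt_p: float | None = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        parts = self.sigma_g2 + self.sigma_e2 + (self.sigma_c2 or 0.0)
        if min(self.sigma_g2, self.sigma_e2, self.sigma_c2 or 0.0) < 0:
            raise ValidationError("negative variance component")
        if abs(self.sigma_p2 - parts) > 1e-8 * max(1.0, parts):
            raise ValidationError("sigma_p2 is not the sum of its components")
        if self.sigma_p2 > 0 and abs(self.h2 - self.sigma_g2 / self.sigma_p2) > 1e-10:
            raise ValidationError("h2 inconsistent with sigma_g2 / sigma_p2")
        if not -1e-12 <= self.h2 <= 1 + 1e-12:
            raise ValidationError("h2 outside [0, 1]")


def estimates_to_frame(estimates) -> "pd.DataFrame":
    """Results table with one row per trait (the TSV schema)."""
    import pandas as pd
    rows = [{
        "trait": e.trait, "method": e.method, "model": e.model, "h2": e.h2,
        "sigma_g2": e.sigma_g2, "sigma_e2": e.sigma_e2,
        "sigma_c2": np.nan if e.sigma_c2 is None else e.sigma_c2,
        "sigma_p2": e.sigma_p2,
        "loglik": np.nan if e.loglik is None else e.loglik,
        "lrt_stat": np.nan if e.lrt_stat is None else e.lrt_stat,
        "lrt_p": np.nan if e.lrt_p is None else e.lrt_p,
        "converged": e.converged, "n_iter": e.n_iter,
    } for e in estimates]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# likelihood

def loglik_ae(h2: float, sigma_p2: float, z: np.ndarray, lam: np.ndarray) -> float:
    """AE log-likelihood of an eigen-rotated trait vector.

    ``−½ Σ [log(2π wᵢ σP²) + zᵢ²/(wᵢ σP²)]`` with ``wᵢ = (1−h²) + λᵢh²``;
    identical to the dense multivariate-normal log-density of the
    unrotated data under ``Ω = 2Φ·σg² + I·σe²``.
    """
    z = np.asarray(z, float)
    lam = np.asarray(lam, float)
    if z.shape != lam.shape:
        raise ValidationError("z and lambda must have the same length")
    if not 0.0 <= h2 <= 1.0:
        raise ValidationError("h2 must lie in [0, 1]")
    if sigma_p2 <= 0:
        raise ValidationError("sigma_p2 must be positive")
    w = (1.0 - h2) + lam * h2
    if w.min() <= 0:
        raise ValidationError("degenerate variance multiplier w <= 0 "
                              "(h2 = 1 with a zero kinship eigenvalue)")
    return -0.5 * float(np.sum(np.log(2.0 * np.pi * w * sigma_p2) + z**2 / (w * sigma_p2)))


# Floor on the rotated variance multipliers.  w = (1−h²) + λh² vanishes at
# h² = 1 on zero eigenvalues (MZ-pair difference components); the floor keeps
# the profile likelihood finite there while preserving its ordering: exact
# boundary data (z = 0 on those components) drives the likelihood up, noisy
# data drives it down, so boundary maxima are still found correctly.
_W_FLOOR = 1e-12


def _profile_loglik(h2: float, z2: np.ndarray, lam: np.ndarray) -> tuple[float, float]:
    """Profile log-likelihood at h² with σP² maximised out; returns
    (loglik, σ̂P²)."""
    w = np.maximum((1.0 - h2) + lam * h2, _W_FLOOR)
    n = z2.size
    sp2 = float(np.sum(z2 / w)) / n
    ll = -0.5 * (n * _LOG2PI + n * np.log(sp2) + float(np.sum(np.log(w))) + n)
    return ll, sp2


def _profile_grad_hess(h2: float, z2: np.ndarray, lam: np.ndarray) -> tuple[float, float]:
    """Analytic first and second derivative of the profile log-likelihood."""
    n = z2.size
    d = lam - 1.0
    w = np.maximum(1.0 + d * h2, _W_FLOOR)
    s0 = float(np.sum(z2 / w))
    s1 = float(np.sum(z2 * d / w**2))
    s2 = float(np.sum(z2 * d**2 / w**3))
    t1 = float(np.sum(d / w))
    t2 = float(np.sum(d**2 / w**2))
    grad = 0.5 * n * s1 / s0 - 0.5 * t1
    hess = 0.5 * n * (-2.0 * s2 * s0 + s1**2) / s0**2 + 0.5 * t2
    return grad, hess


def _fit_ae_newton(z2: np.ndarray, lam: np.ndarray) -> tuple[float, int, bool]:
    """Safeguarded Newton on h²; returns (h2, iterations, converged)."""
    g0, _ = _profile_grad_hess(0.0, z2, lam)
    if g0 <= 0.0:
        return 0.0, 0, True
    g1, _ = _profile_grad_hess(1.0, z2, lam)
    if g1 >= 0.0:
        return 1.0, 0, True
    lo, hi = 0.0, 1.0          # gradient bracket: g(lo) > 0 > g(hi)
    h = 0.5
    for it in range(1, _MAX_ITER + 1):
        g, hess = _profile_grad_hess(h, z2, lam)
        if g > 0:
            lo = h
        else:
            hi = h
        step = -g / hess if hess < 0 else np.nan
        h_new = h + step if np.isfinite(step) else np.nan
        if not (lo < h_new < hi):
            h_new = 0.5 * (lo + hi)   # bisection safeguard
        if abs(h_new - h) < _H2_TOL:
            return h_new, it, True
        h = h_new
    return h, _MAX_ITER, False


def _fit_ae_grid(z2: np.ndarray, lam: np.ndarray) -> tuple[float, int, bool]:
    """Coarse 0.01 grid scan + golden-section refinement."""
    grid = np.linspace(0.0, 1.0, 101)
    lls = np.array([_profile_loglik(h, z2, lam)[0] for h in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, 100)]
    if hi - lo < _H2_TOL:
        return grid[k], len(grid), True
    res = optimize.minimize_scalar(
        lambda h: -_profile_loglik(h, z2, lam)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": _H2_TOL / 10})
    h = float(np.clip(res.x, 0.0, 1.0))
    # snap to boundary when the edge of the unit interval wins
    for edge in (0.0, 1.0):
        if lo <= edge <= hi and _profile_loglik(edge, z2, lam)[0] >= -res.fun:
            h = edge
    return h, len(grid) + int(res.nfev), bool(res.success)


# ---------------------------------------------------------------------------
# ACE joint diagonalisation

def _ace_eigen(eigen: KinshipEigen, rel: RelatednessMatrix | None = None):
    """Joint eigenstructure of 2Φ and the family-sharing matrix C on
    independent pair/singleton families.

    Returns (rotation, lam_kin, lam_c).  Raises UnsupportedDesignError on
    families larger than two, where the two matrices need not commute.
    """
    fam = np.asarray(eigen.families)
    if fam.size == 0:
        raise UnsupportedDesignError("ACE needs family labels on the eigendecomposition")
    n = fam.size
    rot = np.zeros((n, n))
    lam_kin = np.empty(n)
    lam_c = np.empty(n)
    # recover per-pair relatedness from the original matrix if given, else
    # from the eigenvalues (per-family blocks have eigenvalues 1±r)
    col = 0
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    for f in dict.fromkeys(eigen.families):          # preserve order
        idx = np.flatnonzero(fam == f)
        if idx.size == 1:
            rot[idx[0], col] = 1.0
            lam_kin[col] = 1.0
            lam_c[col] = 1.0
            col += 1
        elif idx.size == 2:
            i, j = idx
            if rel is not None:
                r = rel.values[i, j]
            else:
                raise UnsupportedDesignError("ACE fit needs the relatedness matrix")
            rot[i, col] = rot[j, col] = inv_sqrt2          # (1,1)/√2: λ = 1+r, C: 2
            lam_kin[col], lam_c[col] = 1.0 + r, 2.0
            rot[i, col + 1], rot[j, col + 1] = inv_sqrt2, -inv_sqrt2
            lam_kin[col + 1], lam_c[col + 1] = 1.0 - r, 0.0
            col += 2
        else:
            raise UnsupportedDesignError(
                "ACE supported only on independent pair/singleton families "
                f"(family {f!r} has {idx.size} phenotyped members)")
    return rot, lam_kin, lam_c


def _profile_loglik_ace(h2: float, c2: float, z2: np.ndarray,
                        lam_kin: np.ndarray, lam_c: np.ndarray) -> tuple[float, float]:
    w = np.maximum((1.0 - h2 - c2) + lam_kin * h2 + lam_c * c2, _W_FLOOR)
    n = z2.size
    sp2 = float(np.sum(z2 / w)) / n
    ll = -0.5 * (n * _LOG2PI + n * np.log(sp2) + float(np.sum(np.log(w))) + n)
    return ll, sp2


def _fit_ace(z2: np.ndarray, lam_kin: np.ndarray, lam_c: np.ndarray):
    """Constrained maximisation over the (h², c²) simplex: coarse grid then
    SLSQP polish."""
    step = 0.02
    best, best_ll = (0.0, 0.0), -np.inf
    for h in np.arange(0.0, 1.0 + 1e-9, step):
        for c in np.arange(0.0, 1.0 - h + 1e-9, step):
            ll, _ = _profile_loglik_ace(h, c, z2, lam_kin, lam_c)
            if ll > best_ll:
                best, best_ll = (h, c), ll
    res = optimize.minimize(
        lambda p: -_profile_loglik_ace(p[0], p[1], z2, lam_kin, lam_c)[0],
        x0=np.array(best), method="SLSQP",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        constraints=[{"type": "ineq", "fun": lambda p: 1.0 - p[0] - p[1]}],
        options={"ftol": 1e-12, "maxiter": _MAX_ITER})
    h, c = np.clip(res.x, 0.0, 1.0)
    if h + c > 1.0:
        scale = 1.0 / (h + c)
        h, c = h * scale, c * scale
    if _profile_loglik_ace(h, c, z2, lam_kin, lam_c)[0] < best_ll:
        h, c = best
    return float(h), float(c), int(res.nit), bool(res.success)


# ---------------------------------------------------------------------------
# public fitting interface

def _residualize_traits(traits: TraitMatrix) -> np.ndarray:
    """OLS-residualise covariates (intercept always) in original space."""
    from .homogenize import CovariateSpec, design_matrix
    y = traits.values
    if traits.covariates is not None and not traits.homogenized:
        x = design_matrix(CovariateSpec(), traits.covariates)
    else:
        x = np.ones((y.shape[0], 1))
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def fit_mle(traits: TraitMatrix, eigen: KinshipEigen, model: str = "AE",
            optimizer: str = "mle_a",
            rel: RelatednessMatrix | None = None) -> list[VarCompEstimate]:
    """Fit the AE (or ACE) model per trait by profile maximum likelihood.

    Covariates, when present, are residualised out by OLS before rotation.
    The null (σg² = 0) model is fitted alongside and the boundary-mixture
    LRT attached to every estimate.
    """
    if model not in ("AE", "ACE"):
        raise ValidationError(f"unknown model {model!r}")
    if optimizer not in ("mle_a", "mle_b"):
        raise ValidationError(f"unknown optimizer {optimizer!r}")
    if traits.ids != eigen.ids:
        raise ValidationError("trait rows and eigendecomposition ids differ")
    n = len(traits.ids)
    if n < 10:
        raise ValidationError("need at least 10 phenotyped individuals")

    resid = _residualize_traits(traits)
    if model == "ACE":
        rot, lam_kin, lam_c = _ace_eigen(eigen, rel)
    else:
        rot, lam_kin, lam_c = eigen.rotation, eigen.eigenvalues, None
    z = rot.T @ resid
    z2 = z**2

    out: list[VarCompEstimate] = []
    for t, name in enumerate(traits.trait_names):
        zt2 = z2[:, t]
        if np.var(resid[:, t]) <= 0:
            raise DegenerateTraitError(f"trait {name} has zero variance")
        if model == "AE":
            if optimizer == "mle_a":
                h2, n_iter, conv = _fit_ae_newton(zt2, lam_kin)
            else:
                h2, n_iter, conv = _fit_ae_grid(zt2, lam_kin)
            c2 = None
            ll, sp2 = _profile_loglik(h2, zt2, lam_kin)
        else:
            h2, c2, n_iter, conv = _fit_ace(zt2, lam_kin, lam_c)
            ll, sp2 = _profile_loglik_ace(h2, c2, zt2, lam_kin, lam_c)
        h2 = float(np.clip(h2, 0.0, 1.0))
        # null model: sigma_g2 = 0 (C retained under ACE)
        if model == "AE":
            ll0, _ = _profile_loglik(0.0, zt2, lam_kin)
        else:
            c0 = _fit_ace_null(zt2, lam_c)
            ll0, _ = _profile_loglik_ace(0.0, c0, zt2, lam_kin, lam_c)
        stat = max(0.0, 2.0 * (ll - ll0))
        if 2.0 * (ll - ll0) < -1e-6:
            raise ConvergenceError(f"trait {name}: full model log-likelihood "
                                   "below null — optimizer failure")
        p = _mixture_p(stat)
        sg2 = h2 * sp2
        sc2 = None if c2 is None else c2 * sp2
        se2 = sp2 - sg2 - (sc2 or 0.0)
        out.append(VarCompEstimate(
            trait=name, method=optimizer, model=model,
            sigma_g2=sg2, sigma_e2=max(se2, 0.0), sigma_c2=sc2,
            sigma_p2=sg2 + max(se2, 0.0) + (sc2 or 0.0),
            h2=h2, c2=c2, loglik=ll, lrt_stat=stat, lrt_p=p,
            converged=conv, n_iter=n_iter))
    return out


def _fit_ace_null(z2: np.ndarray, lam_c: np.ndarray) -> float:
    """Maximise the CE model (σg² = 0) over c² for the LRT null."""
    res = optimize.minimize_scalar(
        lambda c: -_profile_loglik_ace(0.0, c, z2, np.ones_like(z2), lam_c)[0],
        bounds=(0.0, 1.0 - 1e-9), method="bounded", options={"xatol": 1e-10})
    return float(np.clip(res.x, 0.0, 1.0))


def _mixture_p(stat: float) -> float:
    # ½:½ mixture of point mass at 0 and χ²₁; at the boundary report the
    # supremum of the continuous branch (0.5), matching common VC software
    if stat <= 0.0:
        return 0.5
    return 0.5 * float(stats.chi2.sf(stat, df=1))


def lrt_heritability(fit: VarCompEstimate, fit_null: VarCompEstimate) -> tuple[float, float]:
    """Boundary likelihood-ratio test of σg² > 0 from a full and a null fit."""
    if fit.loglik is None or fit_null.loglik is None:
        raise ValidationError("both fits must carry log-likelihoods")
    diff = fit.loglik - fit_null.loglik
    if diff < -1e-8:
        raise ConvergenceError("full-model likelihood below null beyond tolerance")
    stat = max(0.0, 2.0 * diff)
    return stat, _mixture_p(stat)
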