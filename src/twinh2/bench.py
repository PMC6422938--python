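"""Estimator concordance metrics, normality screening, and the end-to-end
simulation benchmark.

The benchmark simulates the reference twin design, fits every requested
estimator (two MLE optimizers, FPHI, APACE) to the same traits — raw and,
optionally, after inverse-normal homogenization — and summarises each
method against a reference vector: the simulated truth, or the average of
the two MLE estimates (the usual reference when truth is unknown).

Concordance per method: bias (mean estimate − reference), average spread
(mean |estimate − reference| / reference over traits whose reference
exceeds a small floor — the relative error diverges as the reference
approaches zero), and the least-squares slope/intercept plus Pearson r of
estimate versus reference.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TwinH2Error, ValidationError
from .fast import build_pairs, fit_apace, fit_fphi
from .homogenize import homogenize_traits
from .mle import estimates_to_frame, fit_mle
from .pedigree import compute_relatedness, eigendecompose, make_twin_pedigree
from .simulate import SimulationDesign, TraitMatrix, simulate_traits

__all__ = ["ConcordanceEntry", "NormalityResult", "BenchmarkConfig",
           "ConcordanceReport", "concordance", "normality_screen",
           "run_benchmark", "report_from_estimates"]

DEFAULT_SPREAD_FLOOR = 0.05


@dataclass(frozen=True)
class ConcordanceEntry:
    """Agreement summary of one estimate vector against a reference."""

    bias: float
    average_spread: float
    slope: float
    intercept: float
    pearson_r: float
    n_traits: int
    n_spread_excluded: int
    spread_floor: float


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro–Wilk statistic/p-value and sample excess kurtosis."""

    w: float
    p: float
    excess_kurtosis: float


def concordance(estimates: np.ndarray, reference: np.ndarray,
                spread_floor: float = DEFAULT_SPREAD_FLOOR) -> ConcordanceEntry:
    """Bias, relative spread and the least-squares line of ``estimates``
    on ``reference``."""
    est = np.asarray(estimates, float)
    ref = np.asarray(reference, float)
    if est.shape != ref.shape or est.ndim != 1 or est.size < 3:
        raise ValidationError("need equal-length 1-D vectors with n >= 3")
    if not (np.isfinite(est).all() and np.isfinite(ref).all()):
        raise ValidationError("non-finite values in concordance input")
    if np.ptp(ref) == 0.0:
        raise ValidationError("reference vector has zero variance")
    eligible = ref >= spread_floor
    spread = float(np.mean(np.abs(est[eligible] - ref[eligible]) / ref[eligible])) \
        if eligible.any() else np.nan
    fit = stats.linregress(ref, est)
    return ConcordanceEntry(
        bias=float(np.mean(est - ref)),
        average_spread=spread,
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n_traits=est.size,
        n_spread_excluded=int((~eligible).sum()),
        spread_floor=spread_floor)


def normality_screen(trait: np.ndarray) -> NormalityResult:
    """Shapiro–Wilk normality test plus excess kurtosis for one trait."""
    v = np.asarray(trait, float)
    if not 3 <= v.size <= 5000:
        raise ValidationError("Shapiro–Wilk supported for 3 <= n <= 5000")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite values")
    if np.ptp(v) == 0.0:
        raise ValidationError("constant trait has no distribution to test")
    w, p = stats.shapiro(v)
    return NormalityResult(w=float(w), p=float(p),
                           excess_kurtosis=float(stats.kurtosis(v, fisher=True)))


# ---------------------------------------------------------------------------
# benchmark driver

@dataclass(frozen=True)
class BenchmarkConfig:
    """Knobs of the simulation benchmark (defaults reproduce the reference
    twin design at reduced trait count)."""

    n_traits: int = 2000
    seed: int = 17
    n_mz_pairs: int = 125
    n_dz_pairs: int = 125
    methods: tuple[str, ...] = ("mle_a", "mle_b", "fphi", "apace")
    conditions: tuple[str, ...] = ("raw",)          # subset of {"raw", "int"}
    reference: str = "truth"                         # "truth" | "mle_mean"
    spread_floor: float = DEFAULT_SPREAD_FLOOR
    apace_max_unrelated_ratio: float | None = 10.0

    def __post_init__(self) -> None:
        bad = set(self.methods) - {"mle_a", "mle_b", "fphi", "apace"}
        if bad:
            raise ValidationError(f"unknown methods: {sorted(bad)}")
        if set(self.conditions) - {"raw", "int"} or not self.conditions:
            raise ValidationError("conditions must be a non-empty subset of {raw, int}")
        if self.reference not in ("truth", "mle_mean"):
            raise ValidationError("reference must be 'truth' or 'mle_mean'")
        if self.reference == "mle_mean" and not {"mle_a", "mle_b"} <= set(self.methods):
            raise ValidationError("mle_mean reference needs both MLE methods")


@dataclass(frozen=True)
class ConcordanceReport:
    """Benchmark output: per-trait estimates (long format), the per-method
    concordance table, and per-trait failure records."""

    estimates: pd.DataFrame          # trait, condition, method, h2, ...
    entries: pd.DataFrame            # condition, method, bias, spread, ...
    failures: pd.DataFrame           # condition, method, trait, error
    config: BenchmarkConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
        self.entries.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        self.failures.to_csv(outdir / "failures.tsv", sep="\t", index=False)
        for (cond, method), grp in self.estimates.groupby(["condition", "method"]):
            grp[["trait", "reference", "h2"]].to_csv(
                outdir / f"scatter_{cond}_{method}.csv", index=False)


def _fit_method(method: str, traits: TraitMatrix, eigen, rel,
                cfg: BenchmarkConfig):
    if method in ("mle_a", "mle_b"):
        return fit_mle(traits, eigen, model="AE", optimizer=method)
    if method == "fphi":
        return fit_fphi(traits, eigen)
    if method == "apace":
        pairs = build_pairs(rel)
        return fit_apace(traits, pairs, model="AE",
                         max_unrelated_ratio=cfg.apace_max_unrelated_ratio,
                         subsample_seed=cfg.seed)
    raise ValidationError(f"unknown method {method!r}")


def run_benchmark(cfg: BenchmarkConfig,
                  traits: TraitMatrix | None = None) -> ConcordanceReport:
    """Simulate (unless ``traits`` is supplied), fit every method under
    every condition, and build the concordance report.

    Per-trait fit failures are recorded in the report rather than raised.
    """
    ped = make_twin_pedigree(cfg.n_mz_pairs, cfg.n_dz_pairs, phenotype_founders=False)
    rel = compute_relatedness(ped)
    eigen = eigendecompose(rel)
    if traits is None:
        design = SimulationDesign(
            n_traits=cfg.n_traits,
            h2_values=np.linspace(0.0, 1.0, cfg.n_traits),
            seed=cfg.seed)
        traits = simulate_traits(ped, design)
    if traits.ids != eigen.ids:
        raise ValidationError("supplied traits do not match the configured pedigree")

    truth = (traits.truth.set_index("trait")["true_h2"]
             if traits.truth is not None else None)
    frames, failures = [], []
    for cond in cfg.conditions:
        data = traits if cond == "raw" else homogenize_traits(traits)
        per_method: dict[str, pd.DataFrame] = {}
        for method in cfg.methods:
            try:
                ests = _fit_method(method, data, eigen, rel, cfg)
            except TwinH2Error as exc:    # whole-method failure
                failures.append({"condition": cond, "method": method,
                                 "trait": "*", "error": str(exc)})
                continue
            frame = estimates_to_frame(ests)
            frame.insert(1, "condition", cond)
            per_method[method] = frame
        if cfg.reference == "mle_mean":
            ref = (per_method["mle_a"].set_index("trait")["h2"]
                   + per_method["mle_b"].set_index("trait")["h2"]) / 2.0
        else:
            if truth is None:
                raise ValidationError("truth reference requires simulated traits")
            ref = truth
        for method, frame in per_method.items():
            frame["reference"] = frame["trait"].map(ref)
            frames.append(frame)
    estimates = pd.concat(frames, ignore_index=True)

    entries = report_from_estimates(estimates, spread_floor=cfg.spread_floor)
    return ConcordanceReport(estimates=estimates, entries=entries,
                             failures=pd.DataFrame(
                                 failures, columns=["condition", "method",
                                                    "trait", "error"]),
                             config=cfg)


def report_from_estimates(estimates: pd.DataFrame,
                          spread_floor: float = DEFAULT_SPREAD_FLOOR) -> pd.DataFrame:
    """Concordance table recomputed from a per-trait estimates frame (the
    persisted TSV regenerates the identical report)."""
    rows = []
    for (cond, method), grp in estimates.groupby(["condition", "method"], sort=False):
        entry = concordance(grp["h2"].to_numpy(), grp["reference"].to_numpy(),
                            spread_floor=spread_floor)
        rows.append({"condition": cond, "method": method, **asdict(entry)})
    return pd.DataFrame(rows)
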