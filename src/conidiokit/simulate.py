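"""Synthetic data with the statistical structure the analyses assume.

Three generators mirror the three measured layers of the study design:

* progeny phenotype counts as independent multinomial draws per cross
  from the linear-probability genetic model ``p_i = 1/3 + X_i theta``;
* spore dispersal as isotropic bivariate-normal coordinates around the
  membrane center, reported as radial distances (so distances^2 / sigma^2
  are chi-squared with 2 df and the distances themselves are
  Rayleigh(sigma));
* germination as binomial colony counts out of the expected number of
  plated conidia.

A single global seed fans out to independent per-stream generators so
modules can be exercised separately yet reproducibly.
:func:`recovery_experiment` closes the loop: simulate counts, refit the
full model, and summarize bias, RMSE and confidence-interval coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersal import DistanceSample
from .germination import GerminationRecord
from .inheritance import (
    FULL_EPISTATIC,
    ConvergenceError,
    CrossCountsTable,
    GeneticDesign,
    ParameterVector,
    SingularDesignError,
    default_design,
    fit_model,
)
from .phenotypes import PhenotypeLabel

__all__ = [
    "SimulationConfig",
    "simulate_cross_counts",
    "simulate_dispersal",
    "simulate_germination",
    "recovery_experiment",
    "RecoverySummary",
]

#: Membrane radius (cm) and platter half-width (cm) of the dispersal
#: arena; available for optional boundary-truncation experiments.
MEMBRANE_RADIUS_CM = 3.0
PLATTER_HALF_WIDTH_CM = 22.86


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic generators.

    Cross sizes default to the observed per-cross progeny totals
    (396, 286, 366 classified conidiophores); the default effect vector
    is a moderate, well-inside-the-simplex setting used for recovery
    experiments; ``dispersal_sigma`` is chosen so that the mean radial
    distance ``sigma * sqrt(pi/2)`` matches the observed 4.7 cm mean
    movement; germination defaults mirror the plating assay (about
    100 expected colonies from 1e3 cells/ml x 0.1 ml, three replicates,
    39% baseline rate).
    """

    seed: int = 0
    n_per_cross: tuple[int, int, int] = (396, 286, 366)
    theta_true: ParameterVector = field(
        default_factory=lambda: ParameterVector(0.06, -0.03, 0.03,
                                                0.03, -0.03, 0.0))
    dispersal_sigma: float = 3.8
    n_colonies: int = 75
    germination_rate_true: float = 0.39
    expected_colonies: float = 100.0
    replicates: int = 3


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def stream_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Fan a global seed out to named independent generator streams."""
    streams = np.random.SeedSequence(seed).spawn(3)
    return {
        "counts": np.random.default_rng(streams[0]),
        "dispersal": np.random.default_rng(streams[1]),
        "germination": np.random.default_rng(streams[2]),
    }


def simulate_cross_counts(
    theta: ParameterVector,
    design: GeneticDesign | None = None,
    n_per_cross: tuple[int, int, int] = (396, 286, 366),
    seed=0,
) -> CrossCountsTable:
    """Multinomial progeny counts from the forward genetic model.

    Each cross draws ``n_i`` progeny with phenotype probabilities
    ``1/3 + X_i theta``; probabilities must lie strictly inside (0, 1)
    or the call refuses before sampling.
    """
    if design is None:
        design = default_design()
    rng = _rng(seed)
    probs = design.probabilities(theta)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError(
            "theta implies phenotype probabilities outside (0, 1); "
            f"range [{probs.min():.4f}, {probs.max():.4f}]")
    counts = np.zeros((3, 3), dtype=int)
    for i, n_i in enumerate(n_per_cross):
        if n_i < 0:
            raise ValueError("cross sizes must be non-negative")
        if n_i > 0:
            counts[i] = rng.multinomial(n_i, probs[i])
    if np.any(counts.sum(axis=1) == 0):
        # zero-progeny crosses cannot satisfy the analysis-table invariant
        return CrossCountsTable._unchecked(counts)
    return CrossCountsTable(counts=counts)


def simulate_dispersal(
    n_colonies: int,
    sigma: float,
    seed=0,
    strain_label: str = "synthetic",
    phenotype: PhenotypeLabel | None = None,
) -> DistanceSample:
    """Radial distances of isotropically dispersed spores.

    Coordinates are independent Normal(0, sigma^2) in x and y, so the
    returned distances are Rayleigh(sigma) and distances^2 / sigma^2
    follow a chi-squared distribution with 2 degrees of freedom.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    rng = _rng(seed)
    xy = rng.normal(0.0, sigma, size=(n_colonies, 2))
    return DistanceSample(distances=np.hypot(xy[:, 0], xy[:, 1]),
                          strain_label=strain_label, phenotype=phenotype)


def simulate_germination(
    rate_true: float,
    expected: float = 100.0,
    replicates: int = 3,
    seed=0,
    strain: str = "synthetic",
    carbon_source: str = "fructose/glucose",
    concentration: float = 0.1,
) -> GerminationRecord:
    """Binomial replicate colony counts at a true germination rate."""
    if not 0 <= rate_true <= 1:
        raise ValueError("rate_true must lie in [0, 1]")
    if expected <= 0:
        raise ValueError("expected colony count must be > 0")
    if replicates < 1:
        raise ValueError("at least one replicate is required")
    rng = _rng(seed)
    n_plated = int(round(expected))
    counts = tuple(int(c) for c in rng.binomial(n_plated, rate_true,
                                                size=replicates))
    return GerminationRecord(
        strain=strain, phenotype=None, carbon_source=carbon_source,
        concentration=concentration, replicate_colony_counts=counts,
        expected_colonies=expected)


@dataclass(frozen=True)
class RecoverySummary:
    """Aggregate of repeated simulate-and-refit experiments."""

    param_names: tuple[str, ...]
    bias: np.ndarray
    rmse: np.ndarray
    coverage: np.ndarray  # per-parameter fraction of CIs covering truth
    overall_coverage: float
    n_replicates: int
    n_failed: int


def recovery_experiment(
    theta_true: ParameterVector,
    design: GeneticDesign | None = None,
    n_per_cross: tuple[int, int, int] = (5000, 5000, 5000),
    n_replicates: int = 200,
    seed=0,
    ci_level: float = 0.95,
) -> RecoverySummary:
    """Repeatedly simulate counts and refit the full epistatic model.

    Reports per-parameter bias and RMSE of the ML estimates and the
    fraction of Wald intervals ``theta_hat +/- z * SE`` covering the
    truth, both per parameter and pooled.  Failed fits are counted and
    skipped.
    """
    from scipy import stats

    if design is None:
        design = default_design()
    rng = _rng(seed)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    truth = theta_true.as_array()
    names = FULL_EPISTATIC.free_params
    estimates, covered = [], []
    n_failed = 0
    for _ in range(n_replicates):
        table = simulate_cross_counts(theta_true, design, n_per_cross, rng)
        try:
            fit = fit_model(table, design, FULL_EPISTATIC, strict=True)
        except (ConvergenceError, SingularDesignError):
            n_failed += 1
            continue
        est = fit.theta_hat.as_array()
        ses = np.array([fit.standard_errors[name] for name in names])
        estimates.append(est)
        covered.append(np.abs(est - truth) <= z * ses)
    if not estimates:
        raise RuntimeError("every replicate failed to fit")
    est = np.array(estimates)
    cov = np.array(covered, dtype=float)
    return RecoverySummary(
        param_names=names,
        bias=est.mean(axis=0) - truth,
        rmse=np.sqrt(((est - truth) ** 2).mean(axis=0)),
        coverage=cov.mean(axis=0),
        overall_coverage=float(cov.mean()),
        n_replicates=len(estimates),
        n_failed=n_failed,
    )
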