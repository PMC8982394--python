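"""Multinomial inheritance models for conidiophore phenotype counts.

A cross between two homokaryotic parents of different conidiophore
phenotypes yields F2 progeny whose phenotypes (WT, Wrap, Bulky) are
counted; the three crosses A x B, B x C and A x C give a 3 x 3 table of
multinomial counts with fixed row totals.  The linear-probability model

    p_i = 1/3 + X_i theta

expresses the phenotype probabilities of cross *i* as deviations from
the uniform no-genetic-effect baseline, where ``theta`` holds three
allelic effects (alpha, beta, gamma -- one per hypothetical dominant
gene A, B, C) and three pairwise epistatic interactions (alpha_beta,
beta_gamma, alpha_gamma).  Models are fitted by maximum likelihood with
Fisher scoring, i.e. iteratively reweighted least squares (IRLS): the
score is ``sum_i n_i X_i' A_i (y_i - p_i)`` and the expected information
is ``sum_i n_i X_i' A_i X_i`` with weights ``A_i = diag(1/p_i)`` -- the
classical N X'AX information matrix of weighted least squares for
categorical data.  Nested models are compared by differences of Pearson
chi-squared statistics, and broad-sense heritability is the ratio of the
additive improvement over the no-effect model to the no-effect total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .phenotypes import PHENOTYPE_ORDER, PhenotypeLabel

__all__ = [
    "PARAM_NAMES",
    "ParameterVector",
    "CrossCountsTable",
    "GeneticDesign",
    "ModelSpec",
    "FitResult",
    "ComparisonResult",
    "HeritabilityEstimate",
    "MODEL_HIERARCHY",
    "HIERARCHY_COMPARISONS",
    "default_design",
    "pearson_chisq",
    "fit_model",
    "fit_environmental",
    "compare_nested",
    "heritability",
    "standard_errors",
    "hierarchy_table",
    "HierarchyReport",
    "SingularDesignError",
    "ConvergenceError",
]

#: Fixed parameter ordering: allelic effects first, then interactions.
PARAM_NAMES: tuple[str, ...] = (
    "alpha", "beta", "gamma", "alpha_beta", "beta_gamma", "alpha_gamma",
)

#: The three crosses, in the fixed order used by every counts table.
DEFAULT_CROSSES: tuple[tuple[PhenotypeLabel, PhenotypeLabel], ...] = (
    (PhenotypeLabel.WT, PhenotypeLabel.WRAP),
    (PhenotypeLabel.WRAP, PhenotypeLabel.BULKY),
    (PhenotypeLabel.WT, PhenotypeLabel.BULKY),
)

_PROB_FLOOR = 1e-6  # fitted probabilities are confined to (floor, 1-floor)


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the free columns of the design are collinear."""


class ConvergenceError(RuntimeError):
    """Raised in strict mode when IRLS fails to converge."""


@dataclass(frozen=True)
class ParameterVector:
    """Allelic effects and epistatic interactions (probability deviations).

    All six entries are dimensionless deviations on the probability
    scale; ``alpha``, ``beta``, ``gamma`` are the allelic effects of
    genes A (WT), B (Wrap) and C (Bulky), and ``alpha_beta``,
    ``beta_gamma``, ``alpha_gamma`` the pairwise epistatic interactions.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    alpha_beta: float = 0.0
    beta_gamma: float = 0.0
    alpha_gamma: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("parameter values must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ParameterVector":
        values = np.asarray(values, float)
        if values.shape != (6,):
            raise ValueError("expected 6 parameter values")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))


@dataclass(frozen=True)
class CrossCountsTable:
    """3 crosses x 3 phenotypes table of non-negative progeny counts."""

    counts: np.ndarray
    crosses: tuple[tuple[PhenotypeLabel, PhenotypeLabel], ...] = DEFAULT_CROSSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError("every cross must have at least one progeny")
        object.__setattr__(self, "counts", np.asarray(counts, float))
        if len(self.crosses) != 3:
            raise ValueError("exactly three crosses expected")

    @classmethod
    def _unchecked(cls, counts: np.ndarray,
                   crosses=DEFAULT_CROSSES) -> "CrossCountsTable":
        # for degenerate simulator output (zero-progeny crosses) only
        table = object.__new__(cls)
        object.__setattr__(table, "counts", np.asarray(counts, float))
        object.__setattr__(table, "crosses", crosses)
        return table

    @property
    def row_totals(self) -> np.ndarray:
        """Number of classified progeny per cross (n_i)."""
        return self.counts.sum(axis=1)

    @property
    def proportions(self) -> np.ndarray:
        """Observed phenotype proportions y_ij = N_ij / n_i."""
        return self.counts / self.row_totals[:, None]


@dataclass(frozen=True)
class GeneticDesign:
    """Per-cross 3x6 matrices mapping parameters to probability deviations.

    Each matrix column sums to zero over the three phenotype rows, so
    fitted probabilities ``1/3 + X_i theta`` always sum to one per cross.
    """

    per_cross: np.ndarray
    baseline: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        X = np.asarray(self.per_cross, float)
        if X.shape != (3, 3, 6):
            raise ValueError(f"design must be 3 crosses x 3 phenotypes x 6 "
                             f"parameters, got {X.shape}")
        colsums = X.sum(axis=1)
        if not np.allclose(colsums, 0.0, atol=1e-10):
            raise ValueError("each design column must sum to zero across "
                             "the phenotype rows of its cross")
        object.__setattr__(self, "per_cross", X)

    @property
    def stacked(self) -> np.ndarray:
        """The 9x6 matrix of all crosses stacked row-wise."""
        return self.per_cross.reshape(9, 6)

    def probabilities(self, theta: ParameterVector | np.ndarray) -> np.ndarray:
        """Phenotype probabilities 1/3 + X_i theta per cross (3x3)."""
        if isinstance(theta, ParameterVector):
            theta = theta.as_array()
        return self.baseline + self.per_cross @ np.asarray(theta, float)


def default_design() -> GeneticDesign:
    """Default reconstruction of the genetic design matrices.

    In cross U x V (U before V in the order A < B < C) the deviation of
    phenotype U is ``theta_U + theta_UV``, of phenotype V is
    ``theta_V - theta_UV``, and of the uninvolved third phenotype
    ``-theta_U - theta_V``, keeping each epistatic interaction private
    to its own cross.  The construction is column-sum-zero by design and
    the stacked 9x6 matrix has full column rank, so the six-parameter
    model is saturated on a three-cross table.  The sign asymmetry
    (``+`` on the alphabetically first gene of each cross) is an
    arbitrary but fixed convention.
    """
    X = np.zeros((3, 3, 6))
    gene_effect = {PhenotypeLabel.WT: 0, PhenotypeLabel.WRAP: 1,
                   PhenotypeLabel.BULKY: 2}
    interaction = {
        frozenset({PhenotypeLabel.WT, PhenotypeLabel.WRAP}): 3,
        frozenset({PhenotypeLabel.WRAP, PhenotypeLabel.BULKY}): 4,
        frozenset({PhenotypeLabel.WT, PhenotypeLabel.BULKY}): 5,
    }
    for i, (u, v) in enumerate(DEFAULT_CROSSES):
        k_uv = interaction[frozenset({u, v})]
        third = next(p for p in PHENOTYPE_ORDER if p not in (u, v))
        X[i, u.index, gene_effect[u]] += 1.0
        X[i, u.index, k_uv] += 1.0
        X[i, v.index, gene_effect[v]] += 1.0
        X[i, v.index, k_uv] -= 1.0
        X[i, third.index, gene_effect[u]] -= 1.0
        X[i, third.index, gene_effect[v]] -= 1.0
    return GeneticDesign(per_cross=X)


@dataclass(frozen=True)
class ModelSpec:
    """A member of the model hierarchy: which parameters are pinned to 0."""

    name: str
    zeroed_params: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.zeroed_params - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")

    @property
    def free_params(self) -> tuple[str, ...]:
        return tuple(p for p in PARAM_NAMES if p not in self.zeroed_params)

    @property
    def free_mask(self) -> np.ndarray:
        return np.array([p not in self.zeroed_params for p in PARAM_NAMES])

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True when this model is a restriction of ``other``."""
        return other.zeroed_params < self.zeroed_params


def _spec(name: str, *zeroed: str) -> ModelSpec:
    return ModelSpec(name=name, zeroed_params=frozenset(zeroed))


FULL_EPISTATIC = _spec("full_epistatic")
ADDITIVE = _spec("additive", "alpha_beta", "beta_gamma", "alpha_gamma")
ENVIRONMENTAL = _spec("environmental", *PARAM_NAMES)

#: The fitted model hierarchy, simplest last, as climbed in the report.
MODEL_HIERARCHY: tuple[ModelSpec, ...] = (
    FULL_EPISTATIC,
    _spec("ab_zero", "alpha_beta"),
    _spec("ab_alpha_zero", "alpha_beta", "alpha"),
    _spec("bc_zero", "beta_gamma"),
    _spec("bc_beta_zero", "beta_gamma", "beta"),
    _spec("ab_beta_zero", "alpha_beta", "beta"),
    _spec("ac_zero", "alpha_gamma"),
    _spec("ac_alpha_zero", "alpha_gamma", "alpha"),
    ADDITIVE,
    ENVIRONMENTAL,
)

#: Null-vs-alternative pairs reported alongside the hierarchy: the row
#: model is H0 and the named model is the more complex alternative.
HIERARCHY_COMPARISONS: dict[str, str] = {
    "ab_zero": "full_epistatic",
    "ab_alpha_zero": "ab_zero",
    "bc_zero": "full_epistatic",
    "bc_beta_zero": "bc_zero",
    "ab_beta_zero": "ab_zero",
    "ac_zero": "full_epistatic",
    "ac_alpha_zero": "ac_zero",
    "additive": "ab_zero",
    "environmental": "additive",
}


@dataclass(frozen=True)
class FitResult:
    """Converged ML fit of one model of the hierarchy."""

    spec: ModelSpec
    theta_hat: ParameterVector
    fitted_probs: np.ndarray
    expected_counts: np.ndarray
    chisq: float
    df: int
    iterations: int
    converged: bool
    standard_errors: dict[str, float] = field(default_factory=dict)
    information: np.ndarray | None = None
    log_likelihood: float = float("nan")

    @property
    def gof_pvalue(self) -> float:
        """Upper-tail chi-squared goodness-of-fit p (NaN on 0 df)."""
        if self.df <= 0:
            return float("nan")
        return float(stats.chi2.sf(self.chisq, self.df))


@dataclass(frozen=True)
class ComparisonResult:
    """Nested-model test: difference of Pearson chi-squared statistics."""

    h0_name: str
    ha_name: str
    delta_chisq: float
    delta_df: int
    p_value: float
    raw_delta_chisq: float = float("nan")


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Ratio of additive variation to total variation (broad H^2)."""

    chisq_environmental: float
    chisq_additive: float
    h_squared: float


def pearson_chisq(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson goodness-of-fit statistic over the 9 cells of a 3x3 table.

    ``X^2 = sum_ij (N_ij - E_ij)^2 / E_ij``; every expected cell must be
    strictly positive.
    """
    observed = np.asarray(observed, float)
    expected = np.asarray(expected, float)
    if observed.shape != (3, 3) or expected.shape != (3, 3):
        raise ValueError(
            f"expected 3x3 tables, got {observed.shape} and {expected.shape}")
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be > 0")
    return float(((observed - expected) ** 2 / expected).sum())


def _multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    mask = counts > 0
    return float((counts[mask] * np.log(probs[mask])).sum())


def fit_model(
    counts: CrossCountsTable,
    design: GeneticDesign | None = None,
    spec: ModelSpec = FULL_EPISTATIC,
    tol: float = 1e-8,
    max_iter: int = 100,
    strict: bool = False,
) -> FitResult:
    """Fit one inheritance model by maximum likelihood via IRLS.

    Fisher scoring on the multinomial score equations of the
    linear-probability model ``p_i = 1/3 + X_i theta`` with the
    parameters named in ``spec.zeroed_params`` pinned at zero:

    * score   ``U(theta) = sum_i n_i X~_i' diag(1/p_i) (y_i - p_i)``
    * information ``I(theta) = sum_i n_i X~_i' diag(1/p_i) X~_i``

    where ``X~`` keeps only the free columns -- the information is
    exactly the weighted least-squares matrix N X'AX with A the
    inverse-probability weights, recomputed each iteration.  Iteration
    starts from theta = 0 (uniform probabilities) and stops when
    ``max|delta theta| / max(1, max|theta|) < tol``.  Whenever a step
    would push any fitted probability outside (1e-6, 1 - 1e-6) the step
    is halved; an underflowing step raises.

    Parameters
    ----------
    counts : validated 3x3 cross counts.
    design : genetic design; the default reconstruction when omitted.
    spec : which model of the hierarchy to fit.
    tol, max_iter : IRLS stopping rule.
    strict : raise :class:`ConvergenceError` instead of returning a
        flagged result when the iteration cap is hit.
    """
    if design is None:
        design = default_design()
    free = spec.free_mask
    n_free = int(free.sum())
    n = counts.row_totals
    y = counts.proportions
    Xf = design.per_cross[:, :, free]  # (3, 3, k)

    if n_free:
        stacked = Xf.reshape(9, n_free)
        if np.linalg.matrix_rank(stacked) < n_free:
            collinear = _collinear_columns(stacked, spec.free_params)
            raise SingularDesignError(
                f"free design columns are collinear: {collinear}")

    theta = np.zeros(n_free)
    converged = n_free == 0
    iterations = 0
    for iterations in range(1, max_iter + 1) if n_free else ():
        p = design.baseline + Xf @ theta
        w = 1.0 / p
        score = np.einsum("ij,ijk->k", n[:, None] * w * (y - p), Xf)
        info = np.einsum("ijk,ijl,ij->kl", Xf, Xf, n[:, None] * w)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            collinear = _collinear_columns(Xf.reshape(9, n_free),
                                           spec.free_params)
            raise SingularDesignError(
                f"singular information matrix; collinear columns: {collinear}"
            ) from None
        # step-halving keeps every fitted probability inside (eps, 1-eps)
        scale = 1.0
        while True:
            candidate = theta + scale * step
            p_new = design.baseline + Xf @ candidate
            if np.all(p_new > _PROB_FLOOR) and np.all(p_new < 1 - _PROB_FLOOR):
                break
            scale *= 0.5
            if scale < 1e-12:
                raise ConvergenceError(
                    "step-halving underflow: fitted probabilities pinned "
                    "at the boundary of (0, 1)")
        delta = np.max(np.abs(scale * step)) / max(1.0, np.max(np.abs(candidate)))
        theta = candidate
        if delta < tol:
            converged = True
            break
    if not converged:
        msg = (f"IRLS did not converge in {max_iter} iterations "
               f"for model {spec.name!r}")
        if strict:
            raise ConvergenceError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    p_hat = design.baseline + Xf @ theta if n_free else np.full((3, 3),
                                                                design.baseline)
    expected = n[:, None] * p_hat
    chisq = pearson_chisq(counts.counts, expected)

    theta_full = np.zeros(6)
    theta_full[free] = theta
    ses: dict[str, float] = {}
    info_hat = None
    if n_free:
        w = 1.0 / p_hat
        info_hat = np.einsum("ijk,ijl,ij->kl", Xf, Xf, n[:, None] * w)
        try:
            cov = np.linalg.inv(info_hat)
            ses = {name: float(np.sqrt(cov[k, k]))
                   for k, name in enumerate(spec.free_params)}
        except np.linalg.LinAlgError:
            ses = {}
    return FitResult(
        spec=spec,
        theta_hat=ParameterVector.from_array(theta_full),
        fitted_probs=p_hat,
        expected_counts=expected,
        chisq=chisq,
        df=6 - n_free,
        iterations=iterations,
        converged=converged,
        standard_errors=ses,
        information=info_hat,
        log_likelihood=_multinomial_loglik(counts.counts, p_hat),
    )


def _collinear_columns(stacked: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Name a minimal set of columns whose removal restores full rank."""
    bad = []
    kept: list[int] = []
    for k in range(stacked.shape[1]):
        trial = kept + [k]
        if np.linalg.matrix_rank(stacked[:, trial]) < len(trial):
            bad.append(names[k])
        else:
            kept.append(k)
    return bad


def fit_environmental(counts: CrossCountsTable) -> FitResult:
    """Fit the no-genetic-effects model: uniform 1/3 per phenotype.

    All six parameters are zero, expected counts are n_i / 3, the
    Pearson statistic is computed on 6 residual degrees of freedom, and
    no iteration is needed.
    """
    return fit_model(counts, spec=ENVIRONMENTAL)


def compare_nested(h0: FitResult, ha: FitResult) -> ComparisonResult:
    """Test a restricted model H0 against a nested alternative HA.

    The statistic is the difference of Pearson chi-squared values,
    referred to the upper tail of a chi-squared distribution with
    ``df_H0 - df_HA`` degrees of freedom.  A numerically negative
    difference (possible only from finite convergence tolerances) is
    clamped to zero with a warning; the raw value is kept on the result.
    """
    if not h0.spec.is_nested_in(ha.spec):
        raise ValueError(
            f"{h0.spec.name!r} is not strictly nested in {ha.spec.name!r}")
    if not (h0.converged and ha.converged):
        raise ValueError("both fits must have converged")
    raw = h0.chisq - ha.chisq
    delta = raw
    if delta < 0:
        warnings.warn(
            f"negative chi-squared difference ({raw:.6g}) between nested "
            f"models {h0.spec.name!r} and {ha.spec.name!r}; clamped to 0",
            RuntimeWarning, stacklevel=2)
        delta = 0.0
    delta_df = h0.df - ha.df
    return ComparisonResult(
        h0_name=h0.spec.name,
        ha_name=ha.spec.name,
        delta_chisq=delta,
        delta_df=delta_df,
        p_value=float(stats.chi2.sf(delta, delta_df)),
        raw_delta_chisq=raw,
    )


def heritability(
    chisq_environmental: float,
    chisq_additive: float,
    ndigits: int | None = None,
) -> HeritabilityEstimate:
    """Broad-sense heritability from the nested chi-squared statistics.

    ``H^2 = (X^2_environmental - X^2_additive) / X^2_environmental`` --
    the share of the total (no-genetic-effect) lack of fit removed by
    the additive model.  ``ndigits`` optionally rounds the report (the
    conventional presentation uses 2 decimals).
    """
    if chisq_environmental <= 0:
        raise ValueError("environmental chi-squared must be > 0")
    h2 = (chisq_environmental - chisq_additive) / chisq_environmental
    if ndigits is not None:
        h2 = round(h2, ndigits)
    return HeritabilityEstimate(
        chisq_environmental=chisq_environmental,
        chisq_additive=chisq_additive,
        h_squared=float(h2),
    )


def standard_errors(fit: FitResult) -> dict[str, float]:
    """Per-free-parameter SEs: sqrt of the diagonal of inverse(N X'AX)."""
    if not fit.converged:
        raise ValueError("fit did not converge; standard errors undefined")
    if fit.information is None:
        return {}
    try:
        cov = np.linalg.inv(fit.information)
    except np.linalg.LinAlgError:
        raise SingularDesignError(
            "information matrix is singular at the optimum") from None
    return {name: float(np.sqrt(cov[k, k]))
            for k, name in enumerate(fit.spec.free_params)}


@dataclass(frozen=True)
class HierarchyReport:
    """Every model of the hierarchy fitted to one counts table."""

    fits: dict[str, FitResult]
    comparisons: dict[str, ComparisonResult]
    heritability: HeritabilityEstimate | None
    errors: dict[str, str]

    def to_frame(self):
        """Tabular summary, one row per model in hierarchy order."""
        import pandas as pd

        rows = []
        for spec in MODEL_HIERARCHY:
            name = spec.name
            if name in self.errors:
                rows.append({"model": name, "error": self.errors[name]})
                continue
            fit = self.fits[name]
            cmp_ = self.comparisons.get(name)
            rows.append({
                "model": name,
                "chisq": fit.chisq,
                "df": fit.df,
                "p": fit.gof_pvalue,
                "delta_chisq": cmp_.delta_chisq if cmp_ else np.nan,
                "delta_df": cmp_.delta_df if cmp_ else np.nan,
                "p_vs": cmp_.p_value if cmp_ else np.nan,
                "notes": f"HA = {cmp_.ha_name}" if cmp_ else "",
            })
        return pd.DataFrame(rows)


def hierarchy_table(
    counts: CrossCountsTable,
    design: GeneticDesign | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> HierarchyReport:
    """Fit the whole nested hierarchy and assemble the report.

    Fits every model from the saturated full-epistatic model down to the
    environmental (no genetic effect) model, attaches the nested
    comparison conventionally reported next to each restricted model,
    and ends with the heritability estimate computed from the
    environmental and additive rows.  A failing row is recorded and the
    remaining rows still run; heritability is undefined (None) when the
    environmental model already fits perfectly.
    """
    if design is None:
        design = default_design()
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for spec in MODEL_HIERARCHY:
        try:
            fits[spec.name] = fit_model(counts, design, spec,
                                        tol=tol, max_iter=max_iter)
        except (SingularDesignError, ConvergenceError, ValueError) as exc:
            errors[spec.name] = str(exc)
    comparisons: dict[str, ComparisonResult] = {}
    for h0_name, ha_name in HIERARCHY_COMPARISONS.items():
        if h0_name in fits and ha_name in fits:
            comparisons[h0_name] = compare_nested(fits[h0_name], fits[ha_name])
    h2: HeritabilityEstimate | None = None
    if "environmental" in fits and "additive" in fits:
        env, add = fits["environmental"], fits["additive"]
        if env.chisq > 0:
            h2 = heritability(env.chisq, add.chisq)
    return HierarchyReport(fits=fits, comparisons=comparisons,
                           heritability=h2, errors=errors)
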