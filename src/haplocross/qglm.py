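"""Quasibinomial logistic regression via IRLS, with sequential quasi-F tests.

Each barrier response is modelled as k successes out of n trials per cross
combination with a logit link.  Coefficients maximize the ordinary binomial
log-likelihood (iteratively reweighted least squares); overdispersion is
absorbed by a free dispersion parameter

    phi = Pearson X^2 / df_residual

which scales the coefficient covariance (phi * (X'WX)^-1), the t values,
and the analysis-of-deviance F statistics.  Term significance uses
sequential (type-I) analysis of deviance: terms are added in a stated
order and each addition is tested with

    F = (delta deviance / delta df) / phi_full

against F(delta df, df_residual of the fullest model in the sequence).

Model simplification follows the standard two-branch rule: if the
gd x female_pop interaction is significant, the genetic-distance effect is
re-fit within each female population separately; otherwise the interaction
is dropped and the main effects re-tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, special, stats

from .indices import BarrierObservation

logger = logging.getLogger(__name__)

TERMS = ("intercept", "gd", "female_pop", "gd:female_pop")

#: |linear predictor| above which the fit is flagged as (quasi-)separated
_SEPARATION_ETA = 30.0


class RankDeficiencyError(ValueError):
    """Design matrix not full rank; names the aliased column(s)."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration limit."""


@dataclass(frozen=True)
class DesignSpec:
    """A barrier response plus the ordered model terms to fit.

    ``terms`` is drawn from {intercept, gd, female_pop, gd:female_pop};
    the intercept is mandatory and the interaction requires both main
    effects.
    """

    response: str
    terms: tuple[str, ...]
    observations: tuple[BarrierObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "observations", tuple(self.observations))
        unknown = set(self.terms) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        if "intercept" not in self.terms:
            raise ValueError("intercept term is mandatory")
        if "gd:female_pop" in self.terms and not (
            "gd" in self.terms and "female_pop" in self.terms
        ):
            raise ValueError("interaction requires both main effects")
        if len(self.observations) < 2:
            raise ValueError("need at least two observations")


@dataclass(frozen=True)
class GlmFit:
    """A fitted quasibinomial logit model.

    ``beta`` are logit-scale coefficients in ``names`` order; ``se``/``t``
    are dispersion-scaled; ``p_values`` are two-sided t tests on
    ``df_residual`` degrees of freedom (the columns a model summary
    prints: Estimate, SE, t value, P).
    """

    names: tuple[str, ...]
    beta: np.ndarray = field(repr=False)
    se: np.ndarray = field(repr=False)
    t: np.ndarray = field(repr=False)
    p_values: np.ndarray = field(repr=False)
    dispersion: float
    deviance: float
    df_residual: int
    n_obs: int
    converged: bool
    iterations: int
    separation: bool = False
    cov: np.ndarray = field(default=None, repr=False)
    gd_range: tuple[float, float] = (0.0, 0.0)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def predict_gd(self, gd) -> np.ndarray:
        """Predicted barrier proportion at genetic distance(s), for gd-only fits."""
        if set(self.names) != {"intercept", "gd"}:
            raise ValueError("predict_gd requires an {intercept, gd} model")
        eta = self.coef("intercept") + self.coef("gd") * np.asarray(gd, dtype=float)
        return special.expit(eta)

    def summary_rows(self) -> list[dict]:
        return [
            {"term": nm, "estimate": float(b), "se": float(s),
             "t_value": float(t), "p": float(p)}
            for nm, b, s, t, p in zip(self.names, self.beta, self.se, self.t, self.p_values)
        ]


@dataclass(frozen=True)
class FTestResult:
    """Sequential quasi-F test for one added model term."""

    term: str
    f: float
    df1: int
    df2: int
    p_value: float


def build_design(
    observations: Sequence[BarrierObservation], terms: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...], np.ndarray, np.ndarray]:
    """Design matrix (treatment coding, first level as reference) plus k, n."""
    obs = list(observations)
    k = np.array([o.k for o in obs], dtype=float)
    n = np.array([o.n for o in obs], dtype=float)
    gd = np.array([o.gd for o in obs], dtype=float)
    pops = sorted({o.female_pop for o in obs})
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(obs)))
            names.append("intercept")
        elif term == "gd":
            cols.append(gd)
            names.append("gd")
        elif term == "female_pop":
            for p in pops[1:]:
                cols.append(np.array([1.0 if o.female_pop == p else 0.0 for o in obs]))
                names.append(f"female_pop[{p}]")
        elif term == "gd:female_pop":
            for p in pops[1:]:
                ind = np.array([1.0 if o.female_pop == p else 0.0 for o in obs])
                cols.append(gd * ind)
                names.append(f"gd:female_pop[{p}]")
    X = np.column_stack(cols)
    return X, tuple(names), k, n


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(names)) if diag[i] <= tol]
    if bad:
        raise RankDeficiencyError(
            f"aliased term(s): {', '.join(bad)} (design matrix rank-deficient)"
        )


def _binom_deviance(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    mu = n * p
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = special.xlogy(k, k / mu) + special.xlogy(n - k, (n - k) / (n - mu))
    return float(2.0 * np.sum(terms))


def fit_irls(
    X: np.ndarray,
    names: Sequence[str],
    k: np.ndarray,
    n: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    gd_range: tuple[float, float] = (0.0, 0.0),
) -> GlmFit:
    """IRLS for a binomial logit model with quasibinomial inference.

    Starting values come from the empirical logits with Haldane
    correction (k + 1/2) / (n + 1).  Convergence: relative deviance
    change below ``tol``.  Complete or quasi-complete separation
    (diverging linear predictor) is flagged, not fatal.
    """
    _check_rank(X, names)
    n_obs, n_coef = X.shape
    df_resid = n_obs - n_coef
    if df_resid < 0:
        raise ValueError("more coefficients than observations")
    if df_resid == 0:
        logger.warning("saturated model: no residual df, dispersion fixed at 1")

    p0 = (k + 0.5) / (n + 1.0)
    eta = np.log(p0 / (1.0 - p0))
    dev = np.inf
    converged = False
    beta = np.zeros(n_coef)
    it = 0
    for it in range(1, max_iter + 1):
        p = special.expit(eta)
        w = n * p * (1.0 - p)
        z = eta + (k / n - p) / (p * (1.0 - p))
        xtwx = X.T @ (X * w[:, None])
        beta = linalg.solve(xtwx, X.T @ (w * z), assume_a="pos")
        eta = X @ beta
        dev_new = _binom_deviance(k, n, special.expit(eta))
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        logger.warning("IRLS did not converge in %d iterations (deviance %.6g)", max_iter, dev)

    p = special.expit(eta)
    separation = bool(np.max(np.abs(eta)) > _SEPARATION_ETA)
    if separation:
        logger.warning("possible separation: |linear predictor| exceeds %.0f", _SEPARATION_ETA)
    w = n * p * (1.0 - p)
    xtwx = X.T @ (X * w[:, None])
    pearson = float(np.sum((k - n * p) ** 2 / (n * p * (1.0 - p))))
    phi = pearson / df_resid if df_resid > 0 else 1.0
    cov = phi * linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    return GlmFit(
        names=tuple(names), beta=beta, se=se, t=t, p_values=pvals,
        dispersion=phi, deviance=dev, df_residual=df_resid, n_obs=n_obs,
        converged=converged, iterations=it, separation=separation, cov=cov,
        gd_range=gd_range,
    )


def fit(design: DesignSpec, max_iter: int = 50, tol: float = 1e-10) -> GlmFit:
    """Fit the model a :class:`DesignSpec` describes."""
    X, names, k, n = build_design(design.observations, design.terms)
    gds = [o.gd for o in design.observations]
    return fit_irls(X, names, k, n, max_iter=max_iter, tol=tol,
                    gd_range=(min(gds), max(gds)))


def gd_only_fit(observations: Sequence[BarrierObservation], response: str = "") -> GlmFit:
    """Fit the two-parameter {intercept, gd} model used for threshold inversion."""
    response = response or (observations[0].barrier if observations else "")
    design = DesignSpec(response=response, terms=("intercept", "gd"),
                        observations=tuple(observations))
    return fit(design)


def sequential_f_tests(design: DesignSpec) -> list[FTestResult]:
    """Sequential (type-I) analysis of deviance with quasi-F tests.

    Models are grown term by term in ``design.terms`` order; each
    addition's deviance drop is scaled by the Pearson dispersion of the
    fullest model, with its residual df as the denominator df.
    """
    order = [t for t in design.terms if t != "intercept"]
    fits = []
    terms_so_far: list[str] = ["intercept"]
    fits.append(fit(DesignSpec(design.response, tuple(terms_so_far), design.observations)))
    for term in order:
        terms_so_far.append(term)
        fits.append(fit(DesignSpec(design.response, tuple(terms_so_far), design.observations)))
    full = fits[-1]
    phi, df2 = full.dispersion, full.df_residual
    out: list[FTestResult] = []
    for i, term in enumerate(order):
        prev, cur = fits[i], fits[i + 1]
        ddf = prev.df_residual - cur.df_residual
        ddev = prev.deviance - cur.deviance
        f = max(0.0, (ddev / ddf) / phi)
        out.append(FTestResult(term=term, f=f, df1=ddf, df2=df2,
                               p_value=float(stats.f.sf(f, ddf, df2))))
    return out


@dataclass(frozen=True)
class AnalysisReport:
    """Outcome of the interaction-driven model-simplification procedure.

    ``route`` is ``"per_population"`` (interaction significant: separate
    gd-only fits per female population), ``"main_effects"`` (interaction
    dropped, gd and female_pop re-tested), or ``"gd_only"`` (degenerate
    single-population input).
    """

    response: str
    route: str
    full_tests: tuple[FTestResult, ...]
    interaction_test: Optional[FTestResult]
    main_fit: Optional[GlmFit]
    main_tests: tuple[FTestResult, ...]
    per_population: dict[str, GlmFit]
    per_population_tests: dict[str, FTestResult]
    skipped_populations: tuple[str, ...]
    alpha: float

    def to_dict(self) -> dict:
        def ft(t: FTestResult) -> dict:
            return {"term": t.term, "F": t.f, "df1": t.df1, "df2": t.df2, "p": t.p_value}

        def fit_dict(f: GlmFit) -> dict:
            return {
                "coefficients": f.summary_rows(),
                "dispersion": f.dispersion,
                "deviance": f.deviance,
                "df_residual": f.df_residual,
                "n_obs": f.n_obs,
                "converged": f.converged,
            }

        return {
            "response": self.response,
            "route": self.route,
            "alpha": self.alpha,
            "full_model_tests": [ft(t) for t in self.full_tests],
            "interaction_test": ft(self.interaction_test) if self.interaction_test else None,
            "main_effects_model": fit_dict(self.main_fit) if self.main_fit else None,
            "main_effects_tests": [ft(t) for t in self.main_tests],
            "per_population": {p: fit_dict(f) for p, f in self.per_population.items()},
            "per_population_tests": {p: ft(t) for p, t in self.per_population_tests.items()},
            "skipped_populations": list(self.skipped_populations),
        }


def simplify_and_refit(design: DesignSpec, alpha: float = 0.05) -> AnalysisReport:
    """Fit the full interaction model, then simplify by the two-branch rule.

    Interaction significant at ``alpha`` -> re-fit genetic distance within
    each female population separately (populations with fewer than 3
    observations are skipped with a warning).  Not significant -> drop the
    interaction and re-test gd and female_pop sequentially in the
    main-effects model.  Single-population input falls straight through to
    a gd-only fit.
    """
    obs = design.observations
    pops = sorted({o.female_pop for o in obs})
    if len(pops) < 2:
        logger.info("%s: single population; fitting gd-only model", design.response)
        f = gd_only_fit(obs, design.response)
        seq = sequential_f_tests(
            DesignSpec(design.response, ("intercept", "gd"), obs))
        return AnalysisReport(
            response=design.response, route="gd_only", full_tests=tuple(seq),
            interaction_test=None, main_fit=f, main_tests=tuple(seq),
            per_population={}, per_population_tests={},
            skipped_populations=(), alpha=alpha,
        )

    full_terms = ("intercept", "gd", "female_pop", "gd:female_pop")
    full_design = DesignSpec(design.response, full_terms, obs)
    full_tests = sequential_f_tests(full_design)
    inter = next(t for t in full_tests if t.term == "gd:female_pop")

    if inter.p_value < alpha:
        logger.info(
            "%s: interaction significant (F=%.3f, p=%.4g); "
            "re-fitting gd within each female population",
            design.response, inter.f, inter.p_value,
        )
        per_fit: dict[str, GlmFit] = {}
        per_test: dict[str, FTestResult] = {}
        skipped: list[str] = []
        for p in pops:
            sub = tuple(o for o in obs if o.female_pop == p)
            if len(sub) < 3:
                logger.warning("%s: population %s has %d observations; skipped",
                               design.response, p, len(sub))
                skipped.append(p)
                continue
            per_fit[p] = gd_only_fit(sub, design.response)
            per_test[p] = sequential_f_tests(
                DesignSpec(design.response, ("intercept", "gd"), sub))[0]
        return AnalysisReport(
            response=design.response, route="per_population",
            full_tests=tuple(full_tests), interaction_test=inter,
            main_fit=None, main_tests=(), per_population=per_fit,
            per_population_tests=per_test, skipped_populations=tuple(skipped),
            alpha=alpha,
        )

    logger.info("%s: interaction not significant (F=%.3f, p=%.4g); dropping it",
                design.response, inter.f, inter.p_value)
    main_design = DesignSpec(design.response, ("intercept", "gd", "female_pop"), obs)
    main_tests = sequential_f_tests(main_design)
    main_fit = fit(main_design)
    return AnalysisReport(
        response=design.response, route="main_effects",
        full_tests=tuple(full_tests), interaction_test=inter,
        main_fit=main_fit, main_tests=tuple(main_tests),
        per_population={}, per_population_tests={}, skipped_populations=(),
        alpha=alpha,
    )


def report_text(report: AnalysisReport) -> str:
    """Human-readable model report (Estimate / SE / t value / P columns)."""
    lines = [f"Response: {report.response}", f"Route: {report.route}"]
    if report.interaction_test is not None:
        t = report.interaction_test
        lines.append(
            f"Interaction gd x female_pop: F{t.df1},{t.df2} = {t.f:.3f}, p = {t.p_value:.4g}"
        )

    def fit_block(f: GlmFit, indent: str = "") -> list[str]:
        out = [f"{indent}{'term':<22}{'Estimate':>10}{'SE':>10}{'t value':>10}{'P':>12}"]
        for row in f.summary_rows():
            out.append(
                f"{indent}{row['term']:<22}{row['estimate']:>10.3f}{row['se']:>10.3f}"
                f"{row['t_value']:>10.3f}{row['p']:>12.4g}"
            )
        out.append(f"{indent}dispersion = {f.dispersion:.4f}, deviance = {f.deviance:.4f}, "
                   f"df = {f.df_residual}")
        return out

    if report.route in ("main_effects", "gd_only") and report.main_fit is not None:
        for t in report.main_tests:
            lines.append(f"  {t.term}: F{t.df1},{t.df2} = {t.f:.3f}, p = {t.p_value:.4g}")
        lines.extend(fit_block(report.main_fit, "  "))
    else:
        for p in sorted(report.per_population):
            t = report.per_population_tests[p]
            lines.append(f"  {p}: gd F{t.df1},{t.df2} = {t.f:.3f}, p = {t.p_value:.4g}")
            lines.extend(fit_block(report.per_population[p], "    "))
        for p in report.skipped_populations:
            lines.append(f"  {p}: skipped (too few observations)")
    return "\n".join(lines)
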