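"""Binomial maximum-likelihood fitting and inference.

The central objects follow the Model/Results pattern: :class:`OSModel`
wraps a cohort table and a model spec and exposes the likelihood;
``OSModel.fit()`` runs seeded multi-start optimisation (Nelder-Mead
simplex with an L-BFGS quasi-Newton polish, in an unconstrained packed
space) and returns an :class:`OSResults` carrying the estimates,
goodness-of-fit, profile-likelihood confidence intervals, the asymptotic
correlation matrix and overdispersion diagnostics.

The likelihood is the per-patient Bernoulli form

    -2 log L = -2 * sum_cohorts [ x log p + (N - x) log(1 - p) ],

without the binomial coefficient: the constant does not affect
estimation and this convention keeps -2logL magnitudes directly
comparable across model specs and published fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import chi2, qmc

from .cohorts import HISTOLOGIES, STAGES, Cohort, classify_cohort_type
from .exceptions import (
    ConfigurationError,
    FitError,
    LungDRError,
    SingularHessianError,
)
from .models import ModelSpec, ParameterLayout, RadioParams
from .radiobiology import NT_ALPHA_BETA, OS_MAX_RT_ALONE, PROB_EPS

PROFILE_CHI2_1DF = float(chi2.ppf(0.95, 1))  # 3.8415: the "3.84 rule"


class _DesignData:
    """Vectorised arrays for the likelihood of one (cohorts, spec) pair."""

    def __init__(self, cohorts: Sequence[Cohort], spec: ModelSpec):
        n = len(cohorts)
        if n == 0:
            raise ConfigurationError("no cohorts supplied")
        self.cohorts = list(cohorts)
        self.spec = spec
        hists = HISTOLOGIES if spec.needs_histology else (None,)
        cells = [(s, h) for s in STAGES for h in hists]
        self.stage_idx = np.array([STAGES.index(s) for s, _ in cells])

        self.D = np.array([c.dose_gy for c in cohorts])
        self.d = np.array([c.dose_per_fraction_gy for c in cohorts])
        self.T = np.array([c.duration_days for c in cohorts])
        self.Y = np.array([c.years_before_reference for c in cohorts], dtype=float)
        self.N = np.array([c.n_patients for c in cohorts], dtype=float)
        self.x = np.array([c.survivors for c in cohorts], dtype=float)
        self.is_rt = np.array([c.treatment == "RT" for c in cohorts])
        self.is_ccrt = np.array([c.treatment == "cCRT" for c in cohorts])

        rg, ag = spec.repop_groups(), spec.ab_groups()
        W = np.empty((n, len(cells)))
        ab_idx = np.empty((n, len(cells)), dtype=np.intp)
        lam_idx = np.empty((n, len(cells)), dtype=np.intp)
        for i, c in enumerate(cohorts):
            if spec.needs_histology and c.histology_fractions is None:
                raise ConfigurationError(
                    f"cohort {c.id!r} lacks histology fractions required "
                    f"by {spec.name}"
                )
            ctype = (classify_cohort_type(c)
                     if spec.alpha_beta_grouping == "by_cohort_type" else None)
            for j, (s, h) in enumerate(cells):
                w = c.stage_fractions[s]
                if h is not None:
                    w *= c.histology_fractions[h]
                W[i, j] = w
                ab_idx[i, j] = ag.index(spec.ab_group(
                    treatment=c.treatment, stage=s, histology=h,
                    cohort_type=ctype))
                lam_idx[i, j] = rg.index(spec.repop_group(
                    treatment=c.treatment, stage=s, histology=h))
        self.W, self.ab_idx, self.lam_idx = W, ab_idx, lam_idx
        self.eqd2_nt = self.D * (NT_ALPHA_BETA + self.d) / (NT_ALPHA_BETA + 2.0)


class OSModel:
    """Dose-response model for cohort-level 2-year overall survival.

    Parameters
    ----------
    cohorts : sequence of Cohort
        The (curated) cohort table.
    spec : ModelSpec or str
        Which member of the model family to fit; a registry name such as
        ``"model5"`` is accepted.

    Examples
    --------
    >>> model = OSModel(cohorts, "model2")
    >>> res = model.fit(n_starts=20, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, cohorts: Sequence[Cohort], spec):
        from .models import get_model

        if isinstance(spec, str):
            spec = get_model(spec)
        self.spec = spec
        self.layout = ParameterLayout(spec)
        self.data = _DesignData(cohorts, spec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec,
                       apply_het_correction: bool = False) -> "OSModel":
        """Build the model from a DataFrame in the cohort CSV schema."""
        from .cohorts import cohorts_from_frame

        return cls(cohorts_from_frame(df, apply_het_correction), spec)

    @property
    def cohorts(self) -> list[Cohort]:
        return self.data.cohorts

    @property
    def n_params(self) -> int:
        return self.layout.n_params

    # -- likelihood ------------------------------------------------------
    def predict_from_values(self, values: np.ndarray,
                            y: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-cohort predicted OS proportion at a natural parameter vector."""
        dd, sl = self.data, self.layout.slices
        v = np.asarray(values, dtype=float)
        lam = v[sl["lam"]]
        tk = v[sl["t_k"]]
        ab = v[sl["alpha_beta"]]
        m = v[sl["m"]][0]
        e50 = v[sl["eqd2_tum50"]]

        ab_c = ab[dd.ab_idx]
        ff = (ab_c + dd.d[:, None]) / (ab_c + 2.0)
        repop = lam[dd.lam_idx] * np.maximum(dd.T[:, None] - tk[dd.lam_idx], 0.0)
        if self.spec.chemo_terms:
            rs = np.where(dd.is_ccrt, v[sl["rs"]][0], 1.0)
        else:
            rs = np.ones(len(dd.D))
        eqd2 = rs[:, None] * dd.D[:, None] * ff - repop
        e50c = e50[dd.stage_idx][None, :]
        resp = ndtr((eqd2 - e50c) / (m * e50c))

        if self.spec.chemo_terms:
            os_max = np.where(dd.is_rt, OS_MAX_RT_ALONE, v[sl["os_max"]][0]) / 100.0
            nt50 = v[sl["eqd2_nt50"]][0]
            m_nt = v[sl["m_nt"]][0]
            phi_nt = ndtr((dd.eqd2_nt - nt50) / (m_nt * nt50))
            if self.spec.slt_grouping == "by_stage":
                f = v[sl["f_slt"]][dd.stage_idx]
            else:
                f = np.ones(len(dd.stage_idx))
            slt = f[None, :] * phi_nt[:, None]
            yv = dd.Y if y is None else np.asarray(y, dtype=float)
            year = np.maximum(1.0 - v[sl["r_year"]][0] * yv, 0.0)
            os_cell = resp * os_max[:, None] * (1.0 - slt) * year[:, None]
        else:
            os_cell = resp
        p = (dd.W * np.clip(os_cell, PROB_EPS, 1.0 - PROB_EPS)).sum(axis=1)
        return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)

    def neg2_loglik_values(self, values: np.ndarray) -> float:
        p = self.predict_from_values(values)
        dd = self.data
        return float(-2.0 * np.sum(dd.x * np.log(p)
                                   + (dd.N - dd.x) * np.log1p(-p)))

    def neg2_loglik(self, params: RadioParams) -> float:
        """-2 log-likelihood at a :class:`RadioParams`."""
        return self.neg2_loglik_values(self.layout.values_from_params(params))

    def _objective_packed(self, z: np.ndarray) -> float:
        return self.neg2_loglik_values(self.layout.unpack(z))

    # -- fitting ----------------------------------------------------------
    def fit(self, n_starts: int = 20, seed: int = 0,
            init: Optional[RadioParams] = None) -> "OSResults":
        """Seeded multi-start maximum-likelihood fit.

        Start 1 is the neutral default (or ``init``); the remaining starts
        are a Latin-hypercube over the parameter boxes.  Each start runs a
        Nelder-Mead simplex followed by an L-BFGS-B polish in the packed
        (unconstrained) space; the best converged optimum wins.
        Deterministic for a given seed.
        """
        layout = self.layout
        starts = []
        v0 = (layout.default_init() if init is None
              else layout.values_from_params(init))
        starts.append(layout.pack(v0))
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=layout.n_params,
                                         seed=np.random.default_rng(seed))
            u = sampler.random(n_starts - 1)
            lo, hi = layout.lower, layout.upper
            vals = lo + (0.05 + 0.9 * u) * (hi - lo)
            for row in vals:
                w = row.copy()
                for key in ("eqd2_tum50", "f_slt"):
                    if key in layout.slices:
                        s = layout.slices[key]
                        w[s] = np.sort(w[s])
                starts.append(layout.pack(w))

        best = None
        n_converged = 0
        for z0 in starts:
            try:
                res = optimize.minimize(
                    self._objective_packed, z0, method="Nelder-Mead",
                    options={"maxfev": 400 * layout.n_params,
                             "xatol": 1e-6, "fatol": 1e-8, "adaptive": True})
                polish = optimize.minimize(
                    self._objective_packed, res.x, method="L-BFGS-B",
                    options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
                cand = polish if polish.fun <= res.fun else res
            except (FloatingPointError, LungDRError):
                continue
            if not np.isfinite(cand.fun):
                continue
            n_converged += 1
            if best is None or cand.fun < best.fun - 1e-12:
                best = cand
        if best is None:
            raise FitError(
                f"all {n_starts} optimisation starts failed for {self.spec.name}"
            )
        values = layout.unpack(best.x)
        return OSResults(
            model=self,
            values=values,
            z_opt=best.x.copy(),
            neg2_loglik=float(best.fun),
            converged=n_converged > 0,
            n_starts_used=n_starts,
        )


@dataclass(frozen=True)
class ProfileCI:
    """Profile-likelihood confidence interval for one parameter."""

    parameter: str
    lower: float
    upper: float
    truncated_low: bool = False
    truncated_high: bool = False
    level: float = 0.95


class Overdispersion(NamedTuple):
    """Pearson overdispersion factor and the RMS residual ratio sqrt(phi)."""

    phi: float
    rms_ratio: float


@dataclass
class OSResults:
    """Maximum-likelihood fit results.

    Attributes
    ----------
    values : ndarray
        Natural-scale estimates in layout order (``names``).
    estimates : RadioParams
        The same estimates as a structured parameter set.
    neg2_loglik, aic : float
        Goodness of fit; ``aic = neg2_loglik + 2 * n_params`` exactly.
    boundary_flags : set of str
        Parameters whose estimate sits on a box edge (profile CIs for
        these are truncated there).
    """

    model: OSModel
    values: np.ndarray
    z_opt: np.ndarray
    neg2_loglik: float
    converged: bool
    n_starts_used: int

    def __post_init__(self):
        self.estimates: RadioParams = self.model.layout.params_from_values(self.values)
        self.boundary_flags: set[str] = self.model.layout.boundary_names(self.values)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def names(self) -> tuple[str, ...]:
        return self.model.layout.names

    @property
    def n_params(self) -> int:
        return self.model.layout.n_params

    @property
    def aic(self) -> float:
        return self.neg2_loglik + 2.0 * self.n_params

    def qaic(self, phi: float) -> float:
        if phi <= 0:
            raise LungDRError(f"overdispersion factor phi = {phi} must be > 0")
        return self.neg2_loglik / phi + 2.0 * self.n_params

    def predict(self, y: Optional[np.ndarray] = None) -> np.ndarray:
        """Predicted per-cohort OS percentages at the estimates."""
        return 100.0 * self.model.predict_from_values(self.values, y=y)

    def value_of(self, parameter: str) -> float:
        return float(self.values[self.model.layout.index(parameter)])

    # -- inference --------------------------------------------------------
    def profile_ci(self, parameter: str, level: float = 0.95,
                   phi: float = 1.0) -> ProfileCI:
        return profile_ci(self, parameter, level=level, phi=phi)

    def correlation_matrix(self) -> pd.DataFrame:
        return correlation_matrix(self)

    def overdispersion(self) -> Overdispersion:
        return overdispersion_factor(self)

    def params_frame(self) -> pd.DataFrame:
        """Estimates as a tidy table (one row per parameter)."""
        return pd.DataFrame({
            "parameter": list(self.names),
            "estimate": self.values,
            "at_boundary": [n in self.boundary_flags for n in self.names],
        })

    def summary(self, ci: bool = False) -> str:
        """Plain-text summary table; ``ci=True`` adds profile-likelihood
        95% intervals (slow: one profile per parameter)."""
        dd = self.model.data
        lines = [
            "2-year OS dose-response fit",
            "=" * 62,
            f"model:            {self.spec.name}",
            f"cohorts:          {len(dd.cohorts)}"
            f"   patients: {int(dd.N.sum())}",
            f"free parameters:  {self.n_params}",
            f"-2 log-likelihood {self.neg2_loglik:.1f}",
            f"AIC:              {self.aic:.1f}",
            f"converged:        {self.converged}"
            f"   (starts: {self.n_starts_used})",
            "-" * 62,
        ]
        cis = {}
        if ci:
            for name in self.names:
                cis[name] = self.profile_ci(name)
        header = f"{'parameter':<22}{'estimate':>12}"
        if ci:
            header += f"{'95% CI (profile)':>24}"
        lines.append(header)
        for name, val in zip(self.names, self.values):
            row = f"{name:<22}{val:>12.4g}"
            if ci:
                c = cis[name]
                lo = f"{c.lower:.3g}" + ("*" if c.truncated_low else "")
                hi = f"{c.upper:.3g}" + ("*" if c.truncated_high else "")
                row += f"{'(' + lo + ', ' + hi + ')':>24}"
            if name in self.boundary_flags:
                row += "  [boundary]"
            lines.append(row)
        if ci and any(c.truncated_low or c.truncated_high for c in cis.values()):
            lines.append("* interval truncated at the boundary of the range explored")
        lines.append("=" * 62)
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Module-level operations.

def neg2_log_likelihood(p: RadioParams, cohorts: Sequence[Cohort],
                        spec: ModelSpec) -> float:
    """-2 log binomial likelihood of a parameter set on a cohort table."""
    return OSModel(cohorts, spec).neg2_loglik(p)


def fit_mle(cohorts: Sequence[Cohort], spec, n_starts: int = 20,
            seed: int = 0, init: Optional[RadioParams] = None) -> OSResults:
    """Fit a model spec to cohorts by multi-start maximum likelihood."""
    return OSModel(cohorts, spec).fit(n_starts=n_starts, seed=seed, init=init)


def model_scores(fit: OSResults, phi: float = 1.0) -> dict:
    """AIC and quasi-AIC of a fit; ``qaic = -2logL / phi + 2k``."""
    if phi <= 0:
        raise LungDRError(f"overdispersion factor phi = {phi} must be > 0")
    return {"aic": fit.aic, "qaic": fit.qaic(phi)}


def _is_nested(nested: ModelSpec, full: ModelSpec) -> bool:
    if nested.chemo_terms and not full.chemo_terms:
        return False
    for attr in ("repop_grouping", "alpha_beta_grouping", "slt_grouping"):
        a, b = getattr(nested, attr), getattr(full, attr)
        if a != b and a not in ("shared", "none"):
            return False
    return True


def lr_test(nested: OSResults, full: OSResults) -> float:
    """Likelihood-ratio test p-value for a nested pair of fits."""
    if not _is_nested(nested.spec, full.spec) or nested.n_params >= full.n_params:
        raise LungDRError(
            f"{nested.spec.name} is not nested in {full.spec.name}"
        )
    delta = nested.neg2_loglik - full.neg2_loglik
    df = full.n_params - nested.n_params
    if delta <= 0:
        return 1.0
    return float(chi2.sf(delta, df))


def _profile_objective(model: OSModel, idx: int, fixed_value: float):
    """Return f(z_free) minimising -2logL with parameter ``idx`` fixed."""
    layout = model.layout
    free = [i for i in range(layout.n_params) if i != idx]
    kind_slice = None
    for key in ("eqd2_tum50", "f_slt"):
        if key in layout.slices:
            s = layout.slices[key]
            if s.start <= idx < s.stop:
                kind_slice = s
    def natural_from(z_free):
        z = np.zeros(layout.n_params)
        z[free] = z_free
        z[idx] = 0.0
        v = layout.unpack(z)
        v[idx] = fixed_value
        if kind_slice is not None:
            # keep the stage-ordering constraint after overriding one member
            for j in range(kind_slice.start, idx):
                v[j] = min(v[j], fixed_value)
            for j in range(idx + 1, kind_slice.stop):
                v[j] = max(v[j], v[j - 1])
        return v

    def objective(z_free):
        return model.neg2_loglik_values(natural_from(z_free))

    return objective, free


def _profile_min(model: OSModel, idx: int, value: float,
                 z_warm: np.ndarray) -> tuple[float, np.ndarray]:
    objective, free = _profile_objective(model, idx, value)
    z0 = z_warm[free]
    res = optimize.minimize(objective, z0, method="L-BFGS-B",
                            options={"maxiter": 300, "ftol": 1e-12})
    res2 = optimize.minimize(objective, res.x, method="Nelder-Mead",
                             options={"maxfev": 150 * max(len(free), 1),
                                      "fatol": 1e-9, "adaptive": True})
    best = res2 if res2.fun < res.fun else res
    z_full = z_warm.copy()
    z_full[free] = best.x
    return float(best.fun), z_full


def profile_ci(fit: OSResults, parameter: str, level: float = 0.95,
               phi: float = 1.0) -> ProfileCI:
    """Profile-likelihood confidence interval.

    Each endpoint is the parameter value at which the profiled -2logL
    (all other parameters re-optimised) rises by chi2(1, level) — 3.84 at
    the 95% level — above the minimum, located by step-doubling then
    bisection to |delta - threshold| < 0.01.  With ``phi`` > 1 the
    threshold is inflated to 3.84 * phi (overdispersion mode).  Endpoints
    that hit the parameter's box are returned truncated.
    """
    model = fit.model
    layout = model.layout
    idx = layout.index(parameter)
    lo_box, hi_box = float(layout.lower[idx]), float(layout.upper[idx])
    threshold = float(chi2.ppf(level, 1)) * phi
    ref = fit.neg2_loglik
    theta = float(fit.values[idx])
    step0 = 0.05 * (hi_box - lo_box)

    def delta_at(v, z_warm):
        f, z = _profile_min(model, idx, v, z_warm)
        return f - ref, z

    def search(direction: int) -> tuple[float, bool]:
        edge = hi_box if direction > 0 else lo_box
        v_in, z_warm = theta, fit.z_opt.copy()
        g_in = 0.0
        step = step0
        v_out = None
        while True:
            v = v_in + direction * step
            if (direction > 0 and v >= edge) or (direction < 0 and v <= edge):
                g_edge, z_edge = delta_at(edge, z_warm)
                if g_edge < threshold:
                    return edge, True
                v_out, g_out = edge, g_edge
                break
            g, z = delta_at(v, z_warm)
            if g >= threshold:
                v_out, g_out = v, g
                break
            v_in, g_in, z_warm = v, g, z
            step *= 2.0
        # bisection on the profiled -2logL increase
        for _ in range(100):
            v_mid = 0.5 * (v_in + v_out)
            g_mid, z_mid = delta_at(v_mid, z_warm)
            if abs(g_mid - threshold) < 0.01:
                return v_mid, False
            if g_mid < threshold:
                v_in, z_warm = v_mid, z_mid
            else:
                v_out = v_mid
            if abs(v_out - v_in) < 1e-12 * max(1.0, abs(theta)):
                return v_mid, False
        warnings.warn(f"profile endpoint for {parameter} did not reach the "
                      f"3.84-rule tolerance; returning last bisection point")
        return 0.5 * (v_in + v_out), False

    upper, trunc_hi = search(+1)
    lower, trunc_lo = search(-1)
    return ProfileCI(parameter=parameter, lower=lower, upper=upper,
                     truncated_low=trunc_lo, truncated_high=trunc_hi,
                     level=level)


def correlation_matrix(fit: OSResults, rel_step: float = 1e-3) -> pd.DataFrame:
    """Asymptotic correlation matrix of the fitted parameters.

    Inverts the central-finite-difference Hessian of the negative
    log-likelihood (-2logL / 2) at the MLE, in the natural parameter
    space, then normalises to unit diagonal.
    """
    model, layout = fit.model, fit.model.layout
    if fit.boundary_flags:
        warnings.warn(
            "correlation matrix requested with boundary estimates: "
            + ", ".join(sorted(fit.boundary_flags))
        )
    theta = fit.values.copy()
    k = layout.n_params
    h = rel_step * (layout.upper - layout.lower)

    def f(v):
        return 0.5 * model.neg2_loglik_values(v)

    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])

    eigval, eigvec = np.linalg.eigh(H)
    tol = 1e-10 * max(abs(eigval).max(), 1.0)
    null = [i for i, ev in enumerate(eigval) if ev <= tol]
    if null:
        dirs = {tuple(np.round(eigvec[:, i], 4)): eigval[i] for i in null}
        names = [", ".join(f"{n}:{w:+.2f}" for n, w in
                           zip(layout.names, eigvec[:, i]) if abs(w) > 0.3)
                 for i in null]
        raise SingularHessianError(
            "singular Hessian at the optimum; null directions: "
            + " | ".join(names), null_directions=[eigvec[:, i] for i in null])
    cov = eigvec @ np.diag(1.0 / eigval) @ eigvec.T
    sd = np.sqrt(np.abs(np.diag(cov)))
    corr = cov / np.outer(sd, sd)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=layout.names, columns=layout.names)


def correlation_strength(r: float) -> str:
    """Classify a correlation coefficient: strong (|r| >= 0.7),
    moderate (0.3 <= |r| < 0.7), weak otherwise."""
    a = abs(r)
    if a >= 0.7:
        return "strong"
    if a >= 0.3:
        return "moderate"
    return "weak"


def overdispersion_factor(fit: OSResults) -> Overdispersion:
    """Pearson overdispersion factor.

    phi = sum (x - N p)^2 / (N p (1 - p)) over cohorts, divided by the
    residual degrees of freedom (cohorts - parameters).  The RMS residual
    ratio sqrt(phi) says how much larger model-data differences are than
    binomial statistics alone would produce.
    """
    dd = fit.model.data
    n, k = len(dd.cohorts), fit.n_params
    if n <= k:
        raise LungDRError(
            f"overdispersion needs more cohorts ({n}) than parameters ({k})"
        )
    p = fit.model.predict_from_values(fit.values)
    pearson = np.sum((dd.x - dd.N * p) ** 2 / (dd.N * p * (1.0 - p)))
    phi = float(pearson / (n - k))
    return Overdispersion(phi=phi, rms_ratio=float(np.sqrt(phi)))


@dataclass(frozen=True)
class CVResult:
    """10-fold cross-validation score (weighted held-out MSE, percent^2)."""

    score: float
    fold_scores: tuple[float, ...]
    n_folds_skipped: int
    seed: int


def cross_validate(cohorts: Sequence[Cohort], spec, k_folds: int = 10,
                   seed: int = 0, n_starts: int = 5) -> CVResult:
    """K-fold cross-validation of a model spec.

    Cohorts are partitioned into ``k_folds`` folds at random (seeded); for
    each fold the model is refitted to the remainder and scored on the
    held-out cohorts by the patient-weighted mean squared error
    ``sum_c N_c (OS_obs,c - OS_pred,c)^2 / sum_c N_c`` on the percent
    scale.  Returns the average across folds.  Folds whose training set
    cannot support the spec's group structure are skipped with a warning.
    """
    from .models import get_model

    if isinstance(spec, str):
        spec = get_model(spec)
    n = len(cohorts)
    if n < k_folds:
        raise LungDRError(f"need at least {k_folds} cohorts, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    scores, skipped = [], 0
    for fold in folds:
        test_ids = set(int(i) for i in fold)
        train = [c for i, c in enumerate(cohorts) if i not in test_ids]
        test = [cohorts[i] for i in sorted(test_ids)]
        try:
            fit = OSModel(train, spec).fit(n_starts=n_starts, seed=seed)
            test_model = OSModel(test, spec)
            pred = 100.0 * test_model.predict_from_values(fit.values)
        except (FitError, ConfigurationError) as exc:
            warnings.warn(f"cross-validation fold skipped: {exc}")
            skipped += 1
            continue
        obs = np.array([c.os2_observed for c in test])
        w = np.array([c.n_patients for c in test], dtype=float)
        scores.append(float(np.sum(w * (obs - pred) ** 2) / np.sum(w)))
    if not scores:
        raise FitError("every cross-validation fold failed")
    return CVResult(score=float(np.mean(scores)), fold_scores=tuple(scores),
                    n_folds_skipped=skipped, seed=seed)
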