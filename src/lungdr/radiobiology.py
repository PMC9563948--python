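"""Model equations: EQD2, probit dose-response, toxicity and OS prediction.

Tumour dose is expressed as the equivalent dose in 2 Gy fractions,

    EQD2_tum = RS * D * (α/β + d) / (α/β + 2)  -  λ * max(T - T_k, 0),

with RS = 1 except under concurrent chemo-RT.  2-year overall survival for
a single stage is a probit in EQD2 attenuated by the survival ceiling,
survival-limiting toxicity evaluated in normal-tissue EQD2 (generic
α/β = 3 Gy, no repopulation), and the publication-year trend:

    OS = Φ[(EQD2 - EQD2_tum50) / (m * EQD2_tum50)] * OS_max * (1 - SLT) * (1 - R*Y).

Cohort-level survival is the stage-fraction-weighted mixture.
"""

from __future__ import annotations

import math
from typing import Optional

from scipy.special import ndtr

from .cohorts import HISTOLOGIES, STAGES, Cohort, classify_cohort_type
from .exceptions import ConfigurationError, LungDRError
from .models import ModelSpec, RadioParams

#: Generic normal-tissue fractionation sensitivity (Gy).
NT_ALPHA_BETA = 3.0

#: Survival ceiling (percent) for cohorts treated with radiotherapy alone,
#: reflecting the ~15% distant-failure rate without chemotherapy.
OS_MAX_RT_ALONE = 85.0

#: Probability clip applied before the likelihood to avoid log(0).
PROB_EPS = 1e-9


def eqd2_tumour(D: float, d: float, T: float = 0.0, alpha_beta: float = 10.0,
                lam: float = 0.0, t_k: float = 0.0, rs: float = 1.0) -> float:
    """Tumour EQD2 with repopulation and radiosensitisation.

    May be negative for heavily protracted schedules; the probit link
    downstream remains defined, so no floor is applied.
    """
    if alpha_beta <= -2.0:
        raise LungDRError(f"alpha_beta = {alpha_beta} must exceed -2 Gy")
    return rs * D * (alpha_beta + d) / (alpha_beta + 2.0) - lam * max(T - t_k, 0.0)


def eqd2_normal_tissue(D: float, d: float) -> float:
    """Normal-tissue EQD2 of the prescribed dose: generic α/β = 3 Gy,
    no repopulation, no radiosensitisation."""
    return D * (NT_ALPHA_BETA + d) / (NT_ALPHA_BETA + 2.0)


def probit_response(eqd2: float, eqd50: float, m: float) -> float:
    """Probit (cumulative-normal) dose-response.

    Φ of the standardised EQD2 excess over the 50%-response dose, with
    relative slope ``m``: equals 0.5 at ``eqd2 = eqd50``.
    """
    if eqd50 <= 0:
        raise LungDRError(f"eqd50 = {eqd50} must be positive")
    if m <= 0:
        raise LungDRError(f"m = {m} must be positive")
    return float(ndtr((eqd2 - eqd50) / (m * eqd50)))


def slt_probability(eqd2_nt: float, eqd2_nt50: float, m_nt: float,
                    f_slt: float = 1.0) -> float:
    """Survival-limiting toxicity probability: a probit in normal-tissue
    EQD2 weighted by the stage fraction ``f_slt`` in [0, 1]."""
    if not 0.0 <= f_slt <= 1.0:
        raise LungDRError(f"f_slt = {f_slt} outside [0, 1]")
    if f_slt == 0.0:
        return 0.0
    return f_slt * probit_response(eqd2_nt, eqd2_nt50, m_nt)


def weekday_duration(n_fractions: int) -> int:
    """Overall time in days for daily fractions given five days per week:
    30 fractions take 40 days, 37 fractions take 51 days."""
    if n_fractions < 1:
        raise LungDRError("n_fractions must be >= 1")
    n = n_fractions - 1
    return 7 * (n // 5) + (n % 5) + 1


def _stage_os(D, d, T, y, treatment, stage, histology, cohort_type,
              p: RadioParams, spec: ModelSpec) -> float:
    """OS proportion for one (stage, histology) cell."""
    ab = p.alpha_beta[spec.ab_group(treatment=treatment, stage=stage,
                                    histology=histology,
                                    cohort_type=cohort_type)]
    rg = spec.repop_group(treatment=treatment, stage=stage, histology=histology)
    rs = p.rs if (spec.chemo_terms and treatment == "cCRT") else 1.0
    eqd2 = eqd2_tumour(D, d, T, ab, p.lam[rg], p.t_k[rg], rs)
    resp = probit_response(eqd2, p.eqd2_tum50[stage], p.m)
    if spec.chemo_terms:
        os_max = OS_MAX_RT_ALONE if treatment == "RT" else p.os_max
        f = 1.0 if spec.slt_grouping == "shared" else p.f_slt[stage]
        slt = slt_probability(eqd2_normal_tissue(D, d), p.eqd2_nt50, p.m_nt, f)
        year_factor = max(1.0 - p.r_year * y, 0.0)
    else:
        os_max, slt, year_factor = 100.0, 0.0, 1.0
    os = resp * os_max / 100.0 * (1.0 - slt) * year_factor
    return min(max(os, PROB_EPS), 1.0 - PROB_EPS)


def predict_stage_os(c: Cohort, stage: str, p: RadioParams, spec: ModelSpec,
                     y: Optional[float] = None) -> float:
    """Predicted 2-year OS *proportion* for patients of one stage in a cohort.

    ``y`` overrides the publication-year covariate (years before 2016);
    by default it is taken from the cohort.  Histology-grouped models
    marginalise over the cohort's histology mix.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    p = p.resolved(spec)
    if y is None:
        y = c.years_before_reference
    ctype = classify_cohort_type(c) if spec.alpha_beta_grouping == "by_cohort_type" else None
    args = (c.dose_gy, c.dose_per_fraction_gy, c.duration_days, y, c.treatment)
    if spec.needs_histology:
        if c.histology_fractions is None:
            raise ConfigurationError(
                f"cohort {c.id!r} lacks histology fractions required by {spec.name}"
            )
        return sum(
            c.histology_fractions[h]
            * _stage_os(*args, stage, h, ctype, p, spec)
            for h in HISTOLOGIES
        )
    return _stage_os(*args, stage, None, ctype, p, spec)


def predict_cohort_os(c: Cohort, p: RadioParams, spec: ModelSpec,
                      y: Optional[float] = None) -> float:
    """Predicted 2-year OS *percentage* for a cohort: the stage-fraction-
    weighted mixture of per-stage predictions."""
    p = p.resolved(spec)
    return 100.0 * sum(
        c.stage_fractions[s] * predict_stage_os(c, s, p, spec, y=y)
        for s in STAGES
        if c.stage_fractions[s] > 0.0
    )
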