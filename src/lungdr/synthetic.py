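"""Synthetic cohort-table generator.

Emulates the statistical structure of the 51-cohort LA-NSCLC survival
dataset: 10 RT-alone, 26 sequential and 15 concurrent chemo-RT cohorts;
prescribed doses 55–95 Gy at 1.3–3.0 Gy per fraction delivered five days a
week with up to a week of protraction (durations clipped to 16–60 days);
publication years 2000–2016; stage mixes drawn from per-treatment Dirichlet
distributions centred on the observed stage tables (dominated by IIIA/IIIB);
outcomes drawn binomially (optionally beta-binomially, to emulate the
between-centre overdispersion real compilations show) from a ground-truth
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohorts import HISTOLOGIES, STAGES, Cohort
from .exceptions import LungDRError
from .models import ModelSpec, RadioParams, get_model
from .radiobiology import predict_cohort_os, weekday_duration

#: Per-treatment stage-mix centres (fractions of patients in stages
#: I, II, IIIA, IIIB) matching the compiled 51-cohort dataset.
STAGE_MIX_CENTRES: dict[str, tuple[float, ...]] = {
    "RT": (0.097, 0.060, 0.431, 0.412),
    "sCRT": (0.071, 0.047, 0.409, 0.473),
    "cCRT": (0.002, 0.031, 0.542, 0.425),
}

#: Histology centre: squamous / adeno / other.
HISTOLOGY_CENTRE = (0.43, 0.30, 0.27)


def _default_truth() -> RadioParams:
    from .reference import model5_reference_params

    return model5_reference_params()


@dataclass
class SyntheticDesign:
    """Generator settings for simulated cohort tables.

    The defaults are the study conditions the generator emulates: cohort
    counts 10/26/15 by treatment, 20–400 patients per cohort, doses
    55–95 Gy at 1.3–3.0 Gy per fraction, years 2000–2016, and the full
    (model 5) reference parameter set as ground truth.
    """

    n_cohorts: Mapping[str, int] = field(
        default_factory=lambda: {"RT": 10, "sCRT": 26, "cCRT": 15})
    patients_range: tuple[int, int] = (20, 400)
    patients_multiplier: float = 1.0
    dose_range: tuple[float, float] = (55.0, 95.0)
    dpf_range: tuple[float, float] = (1.3, 3.0)
    year_range: tuple[int, int] = (2000, 2016)
    duration_range: tuple[float, float] = (16.0, 60.0)
    stage_concentration: float = 30.0
    truth: RadioParams = field(default_factory=_default_truth)
    truth_spec: ModelSpec | str = "model5"
    overdispersion_rho: float = 0.0
    with_histology: bool = False
    histology_concentration: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.truth_spec, str):
            self.truth_spec = get_model(self.truth_spec)
        for name in ("patients_range", "dose_range", "dpf_range",
                     "year_range", "duration_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise LungDRError(f"{name} {lo, hi} is degenerate")
        if self.overdispersion_rho < 0 or self.overdispersion_rho >= 1:
            raise LungDRError("overdispersion_rho must be in [0, 1)")
        # ground truth must be expressible under its own spec
        from .models import ParameterLayout

        ParameterLayout(self.truth_spec).pack(
            ParameterLayout(self.truth_spec).values_from_params(self.truth))


def sample_design(design: SyntheticDesign,
                  seed: Optional[int] = None) -> list[Cohort]:
    """Sample cohort schedules and stage mixes (outcomes not yet drawn;
    observed OS is set to a placeholder of 0%)."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    cohorts = []
    i = 0
    for treatment in ("RT", "sCRT", "cCRT"):
        centre = np.asarray(STAGE_MIX_CENTRES[treatment])
        alpha = design.stage_concentration * centre
        for _ in range(design.n_cohorts.get(treatment, 0)):
            i += 1
            D = rng.uniform(*design.dose_range)
            d = rng.uniform(*design.dpf_range)
            n_frac = max(int(round(D / d)), 1)
            T = weekday_duration(n_frac) + rng.integers(0, 8)
            T = float(np.clip(T, *design.duration_range))
            year = int(rng.integers(design.year_range[0],
                                    design.year_range[1] + 1))
            n_pat = int(round(rng.integers(design.patients_range[0],
                                           design.patients_range[1] + 1)
                              * design.patients_multiplier))
            frac = rng.dirichlet(alpha)
            frac = frac / frac.sum()
            hist = None
            if design.with_histology:
                h = rng.dirichlet(design.histology_concentration
                                  * np.asarray(HISTOLOGY_CENTRE))
                hist = dict(zip(HISTOLOGIES, (h / h.sum()).tolist()))
            cohorts.append(Cohort(
                id=f"sim{i:03d}",
                study=f"simstudy{i:03d}",
                publication_year=year,
                treatment=treatment,
                n_patients=max(n_pat, 1),
                os2_observed=0.0,
                dose_gy=D,
                dose_per_fraction_gy=d,
                n_fractions=n_frac,
                duration_days=T,
                stage_fractions=dict(zip(STAGES, frac.tolist())),
                het_corrected=True,
                histology_fractions=hist,
            ))
    return cohorts


def generate_dataset(design: SyntheticDesign,
                     seed: Optional[int] = None) -> list[Cohort]:
    """Sample a full synthetic cohort table with outcomes.

    Survivor counts are Binomial(N, p) with p the ground-truth model's
    predicted OS proportion, or beta-binomial with intra-cohort
    correlation ``overdispersion_rho`` when that is positive; observed OS
    is the realised percentage 100 x / N.
    """
    base_seed = design.seed if seed is None else seed
    cohorts = sample_design(design, seed=base_seed)
    rng = np.random.default_rng([base_seed, 1])  # outcome stream, distinct from design
    out = []
    for c in cohorts:
        p = predict_cohort_os(c, design.truth, design.truth_spec) / 100.0
        p = min(max(p, 1e-9), 1 - 1e-9)
        if design.overdispersion_rho > 0:
            rho = design.overdispersion_rho
            a = p * (1.0 - rho) / rho
            b = (1.0 - p) * (1.0 - rho) / rho
            p_draw = rng.beta(a, b)
            x = rng.binomial(c.n_patients, p_draw)
        else:
            x = rng.binomial(c.n_patients, p)
        out.append(replace(c, os2_observed=100.0 * x / c.n_patients))
    return out


def parameter_recovery(truth: RadioParams, truth_spec: ModelSpec | str,
                       fit_spec: Optional[ModelSpec | str] = None,
                       seeds: Sequence[int] = tuple(range(1, 11)),
                       patients_multiplier: float = 10.0,
                       n_starts: int = 12,
                       design: Optional[SyntheticDesign] = None):
    """Seeded parameter-recovery experiment.

    For each seed, generates a cohort table from ``truth`` under the
    default 51-cohort design (patient numbers scaled by
    ``patients_multiplier``), refits ``fit_spec`` (default: the truth
    spec), and tabulates the estimates.  Returns a DataFrame with one row
    per replicate, columns named after the fitted parameters, plus
    ``seed`` and ``neg2_loglik``.
    """
    import pandas as pd

    from .fitting import OSModel

    if fit_spec is None:
        fit_spec = truth_spec
    if isinstance(truth_spec, str):
        truth_spec = get_model(truth_spec)
    if isinstance(fit_spec, str):
        fit_spec = get_model(fit_spec)
    rows = []
    for s in seeds:
        des = design if design is not None else SyntheticDesign()
        des = replace(des, seed=int(s), truth=truth, truth_spec=truth_spec,
                      patients_multiplier=patients_multiplier)
        data = generate_dataset(des)
        fit = OSModel(data, fit_spec).fit(n_starts=n_starts, seed=int(s))
        row = {"seed": int(s), "neg2_loglik": fit.neg2_loglik}
        row.update(dict(zip(fit.names, fit.values)))
        rows.append(row)
    return pd.DataFrame(rows)
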