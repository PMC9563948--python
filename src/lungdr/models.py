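"""The nested model family and its parameterisation.

Five principal models of increasing detail:

* ``model1`` — probit tumour-control on repopulation-corrected EQD2 with a
  shared α/β, λ, T_k; stage-specific 50%-control doses.
* ``model2`` — adds concurrent-chemo radiosensitisation (RS), a survival
  ceiling OS_max, survival-limiting toxicity (SLT) in normal-tissue EQD2,
  and a publication-year trend R.
* ``model3`` — repopulation (λ, T_k) differs for cCRT vs RT/sCRT.
* ``model4`` — tumour α/β differs by stage (I & II, IIIA, IIIB).
* ``model5`` — the SLT weight F_SLT differs by stage.

Named appendix variants regroup α/β or repopulation by treatment, stage,
histology or IIIA/IIIB cohort balance.

Stage-ordered parameters (EQD2_tum50 and F_SLT, constrained
IIIB ≥ IIIA ≥ II ≥ I) are packed as a base value plus non-negative
increments; box-bounded scalars map onto the real line through a scaled
logit, keeping the optimiser unconstrained while making every constraint
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .cohorts import HISTOLOGIES, STAGES, CohortType
from .exceptions import ConfigurationError, ConstraintError

REPOP_GROUPINGS = ("shared", "by_treatment", "by_stage", "by_histology")
AB_GROUPINGS = ("shared", "by_stage", "by_treatment", "by_histology", "by_cohort_type")
SLT_GROUPINGS = ("none", "shared", "by_stage")

_LOG_FLOOR = 1e-300  # zero increments map to log(_LOG_FLOOR)
_FRAC_CLIP = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one member of the model family."""

    name: str
    chemo_terms: bool
    repop_grouping: str = "shared"
    alpha_beta_grouping: str = "shared"
    slt_grouping: str = "none"

    def __post_init__(self):
        if self.repop_grouping not in REPOP_GROUPINGS:
            raise ConfigurationError(f"unknown repop_grouping {self.repop_grouping!r}")
        if self.alpha_beta_grouping not in AB_GROUPINGS:
            raise ConfigurationError(
                f"unknown alpha_beta_grouping {self.alpha_beta_grouping!r}"
            )
        if self.slt_grouping not in SLT_GROUPINGS:
            raise ConfigurationError(f"unknown slt_grouping {self.slt_grouping!r}")
        if not self.chemo_terms and self.slt_grouping != "none":
            raise ConfigurationError(
                "survival-limiting toxicity requires the chemo-era terms"
            )
        if self.chemo_terms and self.slt_grouping == "none":
            raise ConfigurationError(
                "models with chemo terms always carry an SLT term "
                "(shared or by_stage)"
            )

    # -- parameter groups ------------------------------------------------
    def repop_groups(self) -> tuple[str, ...]:
        return {
            "shared": ("all",),
            "by_treatment": ("RT_sCRT", "cCRT"),
            "by_stage": ("I_II", "IIIA", "IIIB"),
            "by_histology": HISTOLOGIES,
        }[self.repop_grouping]

    def ab_groups(self) -> tuple[str, ...]:
        return {
            "shared": ("all",),
            "by_stage": ("I_II", "IIIA", "IIIB"),
            "by_treatment": ("RT", "sCRT", "cCRT"),
            "by_histology": HISTOLOGIES,
            "by_cohort_type": ("I_II", "III_MoreIIIA", "III_MoreIIIB"),
        }[self.alpha_beta_grouping]

    def repop_group(self, treatment=None, stage=None, histology=None) -> str:
        g = self.repop_grouping
        if g == "shared":
            return "all"
        if g == "by_treatment":
            _require(treatment, "treatment", "repopulation")
            return "cCRT" if treatment == "cCRT" else "RT_sCRT"
        if g == "by_stage":
            _require(stage, "stage", "repopulation")
            return "I_II" if stage in ("I", "II") else stage
        _require(histology, "histology", "repopulation")
        return histology

    def ab_group(self, treatment=None, stage=None, histology=None,
                 cohort_type=None) -> str:
        g = self.alpha_beta_grouping
        if g == "shared":
            return "all"
        if g == "by_stage":
            _require(stage, "stage", "alpha/beta")
            return "I_II" if stage in ("I", "II") else stage
        if g == "by_treatment":
            _require(treatment, "treatment", "alpha/beta")
            return treatment
        if g == "by_histology":
            _require(histology, "histology", "alpha/beta")
            return histology
        _require(stage, "stage", "alpha/beta")
        if stage in ("I", "II"):
            return "I_II"
        _require(cohort_type, "cohort_type", "alpha/beta")
        # Balanced cohorts are grouped with More-IIIA.
        if cohort_type == CohortType.MORE_IIIB:
            return "III_MoreIIIB"
        return "III_MoreIIIA"

    @property
    def needs_histology(self) -> bool:
        return (self.repop_grouping == "by_histology"
                or self.alpha_beta_grouping == "by_histology")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "chemo_terms": self.chemo_terms,
            "repop_grouping": self.repop_grouping,
            "alpha_beta_grouping": self.alpha_beta_grouping,
            "slt_grouping": self.slt_grouping,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        if set(d.keys()) == {"name"} or isinstance(d, str):
            return get_model(d["name"] if isinstance(d, Mapping) else d)
        return cls(**dict(d))


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "model1": ModelSpec("model1", chemo_terms=False),
    "model2": ModelSpec("model2", chemo_terms=True, slt_grouping="shared"),
    "model3": ModelSpec("model3", chemo_terms=True, repop_grouping="by_treatment",
                        slt_grouping="shared"),
    "model4": ModelSpec("model4", chemo_terms=True, repop_grouping="by_treatment",
                        alpha_beta_grouping="by_stage", slt_grouping="shared"),
    "model5": ModelSpec("model5", chemo_terms=True, repop_grouping="by_treatment",
                        alpha_beta_grouping="by_stage", slt_grouping="by_stage"),
    # Appendix-style regroupings of the full model.
    "model5_ab_treatment": ModelSpec(
        "model5_ab_treatment", chemo_terms=True, repop_grouping="by_treatment",
        alpha_beta_grouping="by_treatment", slt_grouping="by_stage"),
    "model5_repop_stage": ModelSpec(
        "model5_repop_stage", chemo_terms=True, repop_grouping="by_stage",
        alpha_beta_grouping="by_stage", slt_grouping="by_stage"),
    "model5_repop_histology": ModelSpec(
        "model5_repop_histology", chemo_terms=True, repop_grouping="by_histology",
        alpha_beta_grouping="by_stage", slt_grouping="by_stage"),
    "model5_ab_histology": ModelSpec(
        "model5_ab_histology", chemo_terms=True, repop_grouping="by_treatment",
        alpha_beta_grouping="by_histology", slt_grouping="by_stage"),
    "model5_ab_cohort_type": ModelSpec(
        "model5_ab_cohort_type", chemo_terms=True, repop_grouping="by_treatment",
        alpha_beta_grouping="by_cohort_type", slt_grouping="by_stage"),
}


def get_model(name: str) -> ModelSpec:
    """Look up a model spec by registry name (``model1`` … ``model5`` and
    the appendix variants)."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}"
        ) from None


def _require(value, what, context):
    if value is None:
        raise ConfigurationError(f"{context} grouping requires a {what}")


def _as_group_map(value, groups, what) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [g for g in groups if g not in value]
        if missing:
            raise ConfigurationError(f"{what} missing group(s) {missing}")
        return {g: float(value[g]) for g in groups}
    return {g: float(value) for g in groups}


@dataclass
class RadioParams:
    """Named parameter values, resolved per group.

    ``alpha_beta``, ``lam`` and ``t_k`` may be given as scalars (applied to
    every group of the model spec in use) or as mappings keyed by group
    name.  ``eqd2_tum50`` and ``f_slt`` are keyed by stage.
    """

    alpha_beta: Mapping[str, float] | float
    lam: Mapping[str, float] | float
    t_k: Mapping[str, float] | float
    m: float
    eqd2_tum50: Mapping[str, float]
    rs: float = 1.0
    os_max: float = 85.0
    eqd2_nt50: Optional[float] = None
    m_nt: Optional[float] = None
    r_year: float = 0.0
    f_slt: Optional[Mapping[str, float]] = None

    def resolved(self, spec: ModelSpec) -> "RadioParams":
        """Return a copy with group mappings expanded for ``spec``."""
        return replace(
            self,
            alpha_beta=_as_group_map(self.alpha_beta, spec.ab_groups(), "alpha_beta"),
            lam=_as_group_map(self.lam, spec.repop_groups(), "lam"),
            t_k=_as_group_map(self.t_k, spec.repop_groups(), "t_k"),
            eqd2_tum50=dict(self.eqd2_tum50),
            f_slt=None if self.f_slt is None else dict(self.f_slt),
        )


# --------------------------------------------------------------------------
# Parameter boxes ("ranges explored") and neutral initial values.

BOXES: dict[str, tuple[float, float]] = {
    "lam": (0.0, 3.0),           # Gy EQD2 per day
    "t_k": (16.0, 47.0),         # days
    "alpha_beta": (-1.9, 100.0),  # Gy; flat profiles above the box read "infinite"
    "m": (0.05, 1.0),
    "eqd2_tum50": (20.0, 120.0),  # Gy
    "rs": (0.8, 1.4),
    "os_max": (85.0, 100.0),     # percent
    "eqd2_nt50": (20.0, 150.0),  # Gy
    "m_nt": (0.05, 1.0),
    "r_year": (0.0, 0.05),       # per year
    "f_slt": (0.0, 1.0),
}

INITS: dict[str, float] = {
    "lam": 0.6,
    "t_k": 21.0,
    "alpha_beta": 10.0,
    "m": 0.3,
    "eqd2_tum50": 70.0,
    "rs": 1.1,
    "os_max": 92.0,
    "eqd2_nt50": 90.0,
    "m_nt": 0.5,
    "r_year": 0.01,
    "f_slt": 0.5,
}


class ParameterLayout:
    """Flat parameter vector layout for one model spec.

    Maps between (a) :class:`RadioParams`, (b) an ordered natural-value
    vector, and (c) an unconstrained packed vector the optimiser works in.
    Stage-ordered blocks (EQD2_tum50, F_SLT) are encoded base-plus-
    increment so the ordering constraint is exact.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        names: list[str] = []
        kinds: list[str] = []
        ordered_flags: list[bool] = []  # True for non-first members of ordered blocks
        self.slices: dict[str, slice] = {}

        def add_block(kind, labels, ordered=False):
            start = len(names)
            for i, lab in enumerate(labels):
                names.append(f"{kind}_{lab}" if lab else kind)
                kinds.append(kind)
                ordered_flags.append(ordered and i > 0)
            self.slices[kind] = slice(start, len(names))

        add_block("lam", spec.repop_groups())
        add_block("t_k", spec.repop_groups())
        add_block("alpha_beta", spec.ab_groups())
        add_block("m", [""])
        add_block("eqd2_tum50", STAGES, ordered=True)
        if spec.chemo_terms:
            add_block("rs", [""])
            add_block("os_max", [""])
            add_block("eqd2_nt50", [""])
            add_block("m_nt", [""])
            add_block("r_year", [""])
            if spec.slt_grouping == "by_stage":
                add_block("f_slt", STAGES, ordered=True)

        self.names: tuple[str, ...] = tuple(names)
        self._kinds = tuple(kinds)
        self._ordered = np.asarray(ordered_flags, dtype=bool)
        self.lower = np.array([BOXES[k][0] for k in kinds])
        self.upper = np.array([BOXES[k][1] for k in kinds])

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- natural <-> RadioParams ----------------------------------------
    def default_init(self) -> np.ndarray:
        return np.array([INITS[k] for k in self._kinds])

    def values_from_params(self, p: RadioParams) -> np.ndarray:
        p = p.resolved(self.spec)
        v = np.empty(self.n_params)
        v[self.slices["lam"]] = [p.lam[g] for g in self.spec.repop_groups()]
        v[self.slices["t_k"]] = [p.t_k[g] for g in self.spec.repop_groups()]
        v[self.slices["alpha_beta"]] = [p.alpha_beta[g] for g in self.spec.ab_groups()]
        v[self.slices["m"]] = p.m
        v[self.slices["eqd2_tum50"]] = [p.eqd2_tum50[s] for s in STAGES]
        if self.spec.chemo_terms:
            for key, val in (("rs", p.rs), ("os_max", p.os_max),
                             ("eqd2_nt50", p.eqd2_nt50), ("m_nt", p.m_nt),
                             ("r_year", p.r_year)):
                if val is None:
                    raise ConfigurationError(f"{key} is required by {self.spec.name}")
                v[self.slices[key]] = val
            if self.spec.slt_grouping == "by_stage":
                if p.f_slt is None:
                    raise ConfigurationError(f"f_slt is required by {self.spec.name}")
                v[self.slices["f_slt"]] = [p.f_slt[s] for s in STAGES]
        return v

    def params_from_values(self, v: Sequence[float]) -> RadioParams:
        v = np.asarray(v, dtype=float)
        spec = self.spec
        rg, ag = spec.repop_groups(), spec.ab_groups()
        kw = dict(
            lam=dict(zip(rg, v[self.slices["lam"]])),
            t_k=dict(zip(rg, v[self.slices["t_k"]])),
            alpha_beta=dict(zip(ag, v[self.slices["alpha_beta"]])),
            m=float(v[self.slices["m"]][0]),
            eqd2_tum50=dict(zip(STAGES, v[self.slices["eqd2_tum50"]])),
        )
        if spec.chemo_terms:
            kw.update(
                rs=float(v[self.slices["rs"]][0]),
                os_max=float(v[self.slices["os_max"]][0]),
                eqd2_nt50=float(v[self.slices["eqd2_nt50"]][0]),
                m_nt=float(v[self.slices["m_nt"]][0]),
                r_year=float(v[self.slices["r_year"]][0]),
            )
            if spec.slt_grouping == "by_stage":
                kw["f_slt"] = dict(zip(STAGES, v[self.slices["f_slt"]]))
            else:
                kw["f_slt"] = {s: 1.0 for s in STAGES}
        else:
            kw.update(rs=1.0, os_max=100.0, r_year=0.0)
        return RadioParams(**kw)

    # -- natural <-> packed ----------------------------------------------
    def pack(self, values: Sequence[float]) -> np.ndarray:
        """Map natural values to the unconstrained optimiser space.

        Raises :class:`ConstraintError` naming the violated bound for
        out-of-box or ordering-violating inputs.
        """
        v = np.asarray(values, dtype=float)
        z = np.empty_like(v)
        for i, name in enumerate(self.names):
            lo, hi = self.lower[i], self.upper[i]
            if self._ordered[i]:
                inc = v[i] - v[i - 1]
                if inc < -1e-9:
                    raise ConstraintError(
                        f"{name} = {v[i]} violates the stage ordering "
                        f"(must be >= {self.names[i - 1]} = {v[i - 1]})"
                    )
                if v[i] > hi + 1e-9:
                    raise ConstraintError(f"{name} = {v[i]} above upper bound {hi}")
                z[i] = np.log(max(inc, _LOG_FLOOR))
            else:
                if not (lo - 1e-9 <= v[i] <= hi + 1e-9):
                    raise ConstraintError(
                        f"{name} = {v[i]} outside box [{lo}, {hi}]"
                    )
                f = np.clip((v[i] - lo) / (hi - lo), _FRAC_CLIP, 1 - _FRAC_CLIP)
                z[i] = logit(f)
        return z

    def unpack(self, z: Sequence[float]) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        v = np.empty_like(z)
        for i in range(len(z)):
            lo, hi = self.lower[i], self.upper[i]
            if self._ordered[i]:
                v[i] = min(v[i - 1] + np.exp(min(z[i], 700.0)), hi)
            else:
                v[i] = lo + (hi - lo) * expit(z[i])
        return v

    def boundary_names(self, values, rtol: float = 1e-3) -> set[str]:
        """Names of parameters whose value sits at a box edge."""
        v = np.asarray(values, dtype=float)
        width = self.upper - self.lower
        at_edge = (v - self.lower <= rtol * width) | (self.upper - v <= rtol * width)
        return {n for n, flag in zip(self.names, at_edge) if flag}


def parameter_count(spec: ModelSpec) -> int:
    """Number of free scalar parameters of a model spec (8, 13, 15, 17, 21
    for models 1–5)."""
    return ParameterLayout(spec).n_params


def default_bounds_and_inits(spec: ModelSpec):
    """Return ``(lower, upper, init)`` arrays for the spec's layout, plus the
    neutral initial :class:`RadioParams`."""
    layout = ParameterLayout(spec)
    init = layout.default_init()
    return layout.lower.copy(), layout.upper.copy(), init, layout.params_from_values(init)
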