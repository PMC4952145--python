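"""Synthetic jurisdiction-year panels with planted positive deviants.

The generator emulates the statistical structure the screening pipeline
assumes: within each state, outcomes are linear in context (Z) and mechanism
(X) variables with Gaussian noise,

    Y = alpha + beta1 . Z + beta2 . X + sigma * eps,

and a chosen set of jurisdictions receives an additional negative mean shift
(in units of sigma) in specific (outcome, year) cells — the planted positive
deviants whose labels downstream recovery tests check against.

Continuous context variables follow a Gaussian copula: a correlated standard
normal score per variable, pushed through a marginal quantile transform
(log-normal for expenditures and population, scaled Beta for percentages),
so the generator reproduces heavy-tailed spending spreads while the imposed
correlation matrix controls collinearity.  Context and mechanism variables
are drawn once per jurisdiction and held fixed across years (they are slowly
varying attributes); outcome noise is independent across years and outcomes.

Coefficients in :class:`OutcomeSpec` act on *standardized* continuous
variables (theoretical mean/sd of the marginal), which makes signal variance
— and hence the implied R^2 — easy to control.  Ground truth reports the
equivalent raw-scale coefficients so estimates from a fit on the raw panel
can be compared to truth directly.

Seeding: one master seed; per-state, per-block substreams are derived from
(state-name CRC32, block id), so adding a state leaves the others' draws
untouched.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import Panel, VariableRoleMap
from .errors import ConfigError

# block ids for substream derivation
_B_CONTEXT, _B_MECH, _B_REPORT, _B_NOISE = 1, 2, 3, 4


@dataclass(frozen=True)
class MarginalSpec:
    """A univariate marginal: 'lognorm' (mu, sigma of the log), 'norm'
    (mean, sd) or 'beta_pct' (a, b, scale)."""

    dist: str
    params: Mapping[str, float]

    def moments(self) -> tuple[float, float]:
        p = self.params
        if self.dist == "lognorm":
            m = np.exp(p["mu"] + p["sigma"] ** 2 / 2.0)
            v = (np.exp(p["sigma"] ** 2) - 1.0) * np.exp(2 * p["mu"] + p["sigma"] ** 2)
            return float(m), float(np.sqrt(v))
        if self.dist == "norm":
            return float(p["mean"]), float(p["sd"])
        if self.dist == "beta_pct":
            a, b, sc = p["a"], p["b"], p["scale"]
            m = sc * a / (a + b)
            v = sc**2 * a * b / ((a + b) ** 2 * (a + b + 1.0))
            return float(m), float(np.sqrt(v))
        raise ConfigError(f"unknown marginal distribution {self.dist!r}")

    def from_normal_scores(self, g: np.ndarray) -> np.ndarray:
        """Quantile-transform standard-normal scores to this marginal."""
        p = self.params
        if self.dist == "lognorm":
            return np.exp(p["mu"] + p["sigma"] * g)
        if self.dist == "norm":
            return p["mean"] + p["sd"] * g
        if self.dist == "beta_pct":
            u = stats.norm.cdf(g)
            return p["scale"] * stats.beta.ppf(u, p["a"], p["b"])
        raise ConfigError(f"unknown marginal distribution {self.dist!r}")


@dataclass(frozen=True)
class CategoricalSpec:
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    reference: str

    def __post_init__(self):
        if len(self.levels) != len(self.probs):
            raise ConfigError("categorical levels and probs differ in length")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigError("categorical probabilities must sum to 1")
        if self.reference not in self.levels:
            raise ConfigError("reference level not among levels")


@dataclass(frozen=True)
class ContextSpec:
    continuous: Mapping[str, MarginalSpec]
    correlation: tuple[tuple[float, ...], ...]  # over continuous, declaration order
    categorical: Mapping[str, CategoricalSpec] = field(default_factory=dict)

    def correlation_matrix(self) -> np.ndarray:
        return np.asarray(self.correlation, dtype=float)


@dataclass(frozen=True)
class MechanismSpec:
    indicators: Mapping[str, float] = field(default_factory=dict)  # name -> P(=1)
    continuous: Mapping[str, MarginalSpec] = field(default_factory=dict)


@dataclass(frozen=True)
class OutcomeSpec:
    """Linear predictor for one outcome.

    ``beta_context`` keys are continuous context names (coefficient on the
    standardized value) or ``"var=level"`` dummy names; ``beta_mechanism``
    keys are indicator names (raw 0/1) or continuous mechanism names
    (standardized).  ``sigma`` is the noise standard deviation on the
    outcome's own scale.
    """

    alpha: float
    beta_context: Mapping[str, float]
    beta_mechanism: Mapping[str, float]
    sigma: float


@dataclass(frozen=True)
class PlantedShift:
    jurisdiction_id: str
    outcome: str
    year: int
    shift: float  # in units of sigma; <= 0 for lower-is-better outcomes


@dataclass(frozen=True)
class StateSpec:
    name: str
    n_jurisdictions: int


@dataclass(frozen=True)
class SimulationConfig:
    states: tuple[StateSpec, ...]
    years: tuple[int, ...]
    context: ContextSpec
    mechanism: MechanismSpec
    outcomes: Mapping[str, OutcomeSpec]
    reporting: Mapping[str, MarginalSpec]
    planted: tuple[PlantedShift, ...]
    seed: int
    context_time_varying: bool = False

    def jurisdiction_ids(self, state: str) -> list[str]:
        for s in self.states:
            if s.name == state:
                return [f"{state}-{i + 1:03d}" for i in range(s.n_jurisdictions)]
        raise ConfigError(f"unknown state {state!r}")

    def validate(self) -> None:
        R = self.context.correlation_matrix()
        k = len(self.context.continuous)
        if R.shape != (k, k):
            raise ConfigError("correlation matrix shape does not match continuous context count")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ConfigError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ConfigError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ConfigError("correlation matrix is not positive semi-definite")
        for name, spec in self.outcomes.items():
            if spec.sigma < 0:
                raise ConfigError(f"sigma for outcome {name!r} must be >= 0")
        all_ids = {j for s in self.states for j in self.jurisdiction_ids(s.name)}
        for ps in self.planted:
            if ps.shift > 0:
                raise ConfigError("planted shifts must be <= 0 (lower is better)")
            if ps.jurisdiction_id not in all_ids:
                raise ConfigError(f"planted shift names unknown jurisdiction {ps.jurisdiction_id!r}")
            if ps.outcome not in self.outcomes:
                raise ConfigError(f"planted shift names unknown outcome {ps.outcome!r}")
            if ps.year not in self.years:
                raise ConfigError(f"planted shift names unknown year {ps.year}")

    def role_map(self) -> VariableRoleMap:
        cat = {n: s.levels for n, s in self.context.categorical.items()}
        refs = {n: s.reference for n, s in self.context.categorical.items()}
        return VariableRoleMap(
            outcome_vars=tuple(self.outcomes),
            context_vars=tuple(self.context.continuous) + tuple(self.context.categorical),
            mechanism_vars=tuple(self.mechanism.indicators) + tuple(self.mechanism.continuous),
            reporting_vars=tuple(self.reporting),
            categorical_vars=cat,
            reference_levels=refs,
        )

    def to_dict(self) -> dict:
        def marg(m: MarginalSpec) -> dict:
            return {"dist": m.dist, "params": dict(m.params)}

        return {
            "states": [{"name": s.name, "n_jurisdictions": s.n_jurisdictions} for s in self.states],
            "years": list(self.years),
            "context": {
                "continuous": {n: marg(m) for n, m in self.context.continuous.items()},
                "correlation": [list(r) for r in self.context.correlation],
                "categorical": {
                    n: {"levels": list(c.levels), "probs": list(c.probs), "reference": c.reference}
                    for n, c in self.context.categorical.items()
                },
            },
            "mechanism": {
                "indicators": dict(self.mechanism.indicators),
                "continuous": {n: marg(m) for n, m in self.mechanism.continuous.items()},
            },
            "outcomes": {
                n: {
                    "alpha": o.alpha,
                    "beta_context": dict(o.beta_context),
                    "beta_mechanism": dict(o.beta_mechanism),
                    "sigma": o.sigma,
                }
                for n, o in self.outcomes.items()
            },
            "reporting": {n: marg(m) for n, m in self.reporting.items()},
            "planted": [dataclasses.asdict(p) for p in self.planted],
            "seed": self.seed,
            "context_time_varying": self.context_time_varying,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        def marg(m) -> MarginalSpec:
            return MarginalSpec(dist=m["dist"], params=dict(m["params"]))

        ctx = d["context"]
        mech = d.get("mechanism", {})
        cfg = cls(
            states=tuple(StateSpec(s["name"], int(s["n_jurisdictions"])) for s in d["states"]),
            years=tuple(int(y) for y in d["years"]),
            context=ContextSpec(
                continuous={n: marg(m) for n, m in ctx["continuous"].items()},
                correlation=tuple(tuple(float(x) for x in row) for row in ctx["correlation"]),
                categorical={
                    n: CategoricalSpec(tuple(c["levels"]), tuple(c["probs"]), c["reference"])
                    for n, c in ctx.get("categorical", {}).items()
                },
            ),
            mechanism=MechanismSpec(
                indicators=dict(mech.get("indicators", {})),
                continuous={n: marg(m) for n, m in mech.get("continuous", {}).items()},
            ),
            outcomes={
                n: OutcomeSpec(
                    alpha=float(o["alpha"]),
                    beta_context=dict(o["beta_context"]),
                    beta_mechanism=dict(o["beta_mechanism"]),
                    sigma=float(o["sigma"]),
                )
                for n, o in d["outcomes"].items()
            },
            reporting={n: marg(m) for n, m in d.get("reporting", {}).items()},
            planted=tuple(
                PlantedShift(p["jurisdiction_id"], p["outcome"], int(p["year"]), float(p["shift"]))
                for p in d.get("planted", [])
            ),
            seed=int(d["seed"]),
            context_time_varying=bool(d.get("context_time_varying", False)),
        )
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class GroundTruth:
    """Planted deviant labels and the true raw-scale coefficients."""

    planted: frozenset  # of (jurisdiction_id, outcome, year)
    true_coefficients: Mapping[str, Mapping[str, float]]  # outcome -> column -> beta
    sigmas: Mapping[str, float]

    def planted_jurisdictions(self) -> dict[str, set]:
        """jurisdiction_id -> set of its planted (outcome, year) cells."""
        out: dict[str, set] = {}
        for j, o, y in self.planted:
            out.setdefault(j, set()).add((o, y))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": sorted([j, o, y] for j, o, y in self.planted),
                "true_coefficients": {o: dict(c) for o, c in self.true_coefficients.items()},
                "sigmas": dict(self.sigmas),
            },
            indent=2,
        )


def _substream(seed: int, state: str, block: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(state.encode()), block, extra])
    )


def _psd_factor(R: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerant of semi-definite matrices."""
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def generate_panel(config: SimulationConfig) -> tuple[Panel, GroundTruth]:
    """Simulate the panel and return it with its ground truth.

    Deterministic given ``config.seed``; context and mechanism variables are
    drawn once per jurisdiction and repeated across years unless
    ``context_time_varying`` is set, in which case context scores are redrawn
    each year.
    """
    config.validate()
    rm = config.role_map()
    cont_names = list(config.context.continuous)
    A = _psd_factor(config.context.correlation_matrix())

    planted_lookup: dict[tuple[str, str, int], float] = {
        (p.jurisdiction_id, p.outcome, p.year): p.shift for p in config.planted
    }

    rows: list[dict] = []
    for state in config.states:
        ids = config.jurisdiction_ids(state.name)
        n_j = state.n_jurisdictions

        def draw_context(rng: np.random.Generator) -> dict[str, np.ndarray]:
            g = rng.standard_normal((n_j, len(cont_names))) @ A.T
            vals = {
                name: config.context.continuous[name].from_normal_scores(g[:, k])
                for k, name in enumerate(cont_names)
            }
            for name, cspec in config.context.categorical.items():
                vals[name] = rng.choice(cspec.levels, size=n_j, p=cspec.probs)
            return vals

        rng_ctx = _substream(config.seed, state.name, _B_CONTEXT)
        context_by_year: dict[int, dict[str, np.ndarray]] = {}
        if config.context_time_varying:
            for year in config.years:
                context_by_year[year] = draw_context(
                    _substream(config.seed, state.name, _B_CONTEXT, extra=year)
                )
        else:
            fixed = draw_context(rng_ctx)
            for year in config.years:
                context_by_year[year] = fixed

        rng_mech = _substream(config.seed, state.name, _B_MECH)
        mech_vals: dict[str, np.ndarray] = {}
        for name, prob in config.mechanism.indicators.items():
            mech_vals[name] = (rng_mech.random(n_j) < prob).astype(float)
        for name, marg in config.mechanism.continuous.items():
            mech_vals[name] = marg.from_normal_scores(rng_mech.standard_normal(n_j))

        rng_rep = _substream(config.seed, state.name, _B_REPORT)
        report_by_year = {
            year: {
                name: marg.from_normal_scores(rng_rep.standard_normal(n_j))
                for name, marg in config.reporting.items()
            }
            for year in config.years
        }

        # linear predictor pieces that do not depend on the year
        def signal(outcome: OutcomeSpec, ctx: dict[str, np.ndarray]) -> np.ndarray:
            s = np.full(n_j, outcome.alpha)
            for key, b in outcome.beta_context.items():
                if "=" in key:
                    var, lev = key.split("=", 1)
                    s = s + b * (ctx[var] == lev).astype(float)
                else:
                    m, sd = config.context.continuous[key].moments()
                    s = s + b * (ctx[key] - m) / sd
            for key, b in outcome.beta_mechanism.items():
                if key in config.mechanism.indicators:
                    s = s + b * mech_vals[key]
                else:
                    m, sd = config.mechanism.continuous[key].moments()
                    s = s + b * (mech_vals[key] - m) / sd
            return s

        for year in config.years:
            ctx = context_by_year[year]
            ycols: dict[str, np.ndarray] = {}
            for oname, ospec in config.outcomes.items():
                rng_noise = _substream(
                    config.seed, state.name, _B_NOISE,
                    extra=year * 131 + (zlib.crc32(oname.encode()) % 1_000_003),
                )
                eps = rng_noise.standard_normal(n_j)
                y = signal(ospec, ctx) + ospec.sigma * eps
                for i, jid in enumerate(ids):
                    shift = planted_lookup.get((jid, oname, year))
                    if shift is not None:
                        y[i] = y[i] + shift * ospec.sigma
                ycols[oname] = y
            for i, jid in enumerate(ids):
                row = {
                    rm.id_var: jid,
                    rm.state_var: state.name,
                    rm.year_var: year,
                }
                for name in cont_names:
                    row[name] = float(ctx[name][i])
                for name in config.context.categorical:
                    row[name] = str(ctx[name][i])
                for name in mech_vals:
                    row[name] = float(mech_vals[name][i])
                for name in config.outcomes:
                    row[name] = float(ycols[name][i])
                for name in config.reporting:
                    row[name] = float(report_by_year[year][name][i])
                rows.append(row)

    df = pd.DataFrame(rows, columns=list(rm.all_declared))
    panel = Panel(df=df, role_map=rm)

    true_coefs: dict[str, dict[str, float]] = {}
    for oname, ospec in config.outcomes.items():
        coefs: dict[str, float] = {}
        intercept = ospec.alpha
        for key, b in ospec.beta_context.items():
            if "=" in key:
                coefs[key] = b
            else:
                m, sd = config.context.continuous[key].moments()
                coefs[key] = b / sd
                intercept -= b * m / sd
        for key, b in ospec.beta_mechanism.items():
            if key in config.mechanism.indicators:
                coefs[key] = b
            else:
                m, sd = config.mechanism.continuous[key].moments()
                coefs[key] = b / sd
                intercept -= b * m / sd
        coefs["intercept"] = intercept
        true_coefs[oname] = coefs

    truth = GroundTruth(
        planted=frozenset((p.jurisdiction_id, p.outcome, p.year) for p in config.planted),
        true_coefficients=true_coefs,
        sigmas={n: o.sigma for n, o in config.outcomes.items()},
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Default study-shaped configuration


_DEFAULT_STATES = (("WA", 35), ("FL", 67), ("NY", 48))
_MULTI_PLANT = {"WA": 3, "FL": 7, "NY": 5}   # 15 = 10% of 150, >=2 cells each
_SINGLE_PLANT = {"WA": 2, "FL": 3, "NY": 2}  # 7 ~= 5% of 150, exactly 1 cell
_PLANT_SHIFT = -2.5  # in units of sigma
_R2_TARGETS = {
    "teen_birth_rate": 0.65,
    "late_prenatal_rate": 0.30,
    "infant_mortality_rate": 0.20,
    "low_birth_weight_pct": 0.45,
}


def _default_context() -> ContextSpec:
    continuous = {
        "total_expenditures": MarginalSpec("lognorm", {"mu": 14.0, "sigma": 1.0}),
        "population": MarginalSpec("lognorm", {"mu": 11.5, "sigma": 1.2}),
        "medicaid_births": MarginalSpec("lognorm", {"mu": 6.5, "sigma": 1.0}),
        "social_disadvantage": MarginalSpec("norm", {"mean": 0.0, "sd": 1.0}),
        "pct_child_poverty": MarginalSpec("beta_pct", {"a": 4.0, "b": 14.0, "scale": 100.0}),
        "pct_hs_education": MarginalSpec("beta_pct", {"a": 20.0, "b": 4.0, "scale": 100.0}),
        "pct_african_american": MarginalSpec("beta_pct", {"a": 1.5, "b": 10.0, "scale": 100.0}),
        "pct_hispanic": MarginalSpec("beta_pct", {"a": 1.5, "b": 8.0, "scale": 100.0}),
        "providers_per_capita": MarginalSpec("lognorm", {"mu": -5.8, "sigma": 0.5}),
    }
    names = list(continuous)
    k = len(names)
    R = np.full((k, k), 0.3)
    np.fill_diagonal(R, 1.0)
    # the disadvantage index is largely built from poverty: the deliberately
    # collinear pair (light-tailed marginals, so the raw-scale sample
    # correlation tracks the copula parameter closely)
    i, j = names.index("social_disadvantage"), names.index("pct_child_poverty")
    R[i, j] = R[j, i] = 0.85
    # expenditures scale with population, but both are heavy-tailed
    i, j = names.index("total_expenditures"), names.index("population")
    R[i, j] = R[j, i] = 0.5
    return ContextSpec(
        continuous=continuous,
        correlation=tuple(tuple(row) for row in R),
        categorical={
            "community_type": CategoricalSpec(
                levels=("metropolitan", "micropolitan", "rural"),
                probs=(0.52, 0.23, 0.25),
                reference="metropolitan",
            )
        },
    )


def _dummy_variance(cspec: CategoricalSpec, betas: Mapping[str, float], var: str) -> float:
    effects = np.array(
        [betas.get(f"{var}={lev}", 0.0) for lev in cspec.levels]
    )
    probs = np.asarray(cspec.probs)
    mean = float(effects @ probs)
    return float(((effects - mean) ** 2) @ probs)


def _sigma_for_target_r2(
    context: ContextSpec,
    mechanism: MechanismSpec,
    beta_context: Mapping[str, float],
    beta_mechanism: Mapping[str, float],
    r2: float,
) -> float:
    names = list(context.continuous)
    b = np.array([beta_context.get(n, 0.0) for n in names])
    R = context.correlation_matrix()
    signal = float(b @ R @ b)
    for var, cspec in context.categorical.items():
        signal += _dummy_variance(cspec, beta_context, var)
    for name, prob in mechanism.indicators.items():
        bm = beta_mechanism.get(name, 0.0)
        signal += bm**2 * prob * (1.0 - prob)
    for name in mechanism.continuous:
        signal += beta_mechanism.get(name, 0.0) ** 2
    return float(np.sqrt(signal * (1.0 - r2) / r2))


def default_study_config(seed: int) -> SimulationConfig:
    """Study-shaped default: 3 states (35/67/48 jurisdictions), 2 years,
    10 context variables (one 3-level categorical), 3 mechanism variables,
    4 lower-is-better outcomes, ~10% of jurisdictions planted at -2.5 sigma
    in 2-3 (outcome, year) cells and ~5% in exactly one cell.

    Noise levels are set per outcome from the closed-form signal variance so
    the implied full-model R^2 spans roughly 0.2-0.65 across outcomes.
    """
    context = _default_context()
    mechanism = MechanismSpec(
        indicators={"alt_provider": 0.5, "clinician_executive": 0.35},
        continuous={"service_delivery_score": MarginalSpec("norm", {"mean": 0.0, "sd": 1.0})},
    )
    years = (2009, 2010)

    base_betas = {
        "teen_birth_rate": (
            40.0,
            {
                "social_disadvantage": 5.0, "pct_child_poverty": 3.0,
                "pct_hs_education": -3.0, "pct_african_american": 1.0,
                "pct_hispanic": 1.0, "total_expenditures": -1.0,
                "population": 0.5, "medicaid_births": 1.5,
                "providers_per_capita": -0.5,
                "community_type=micropolitan": 2.0, "community_type=rural": 3.0,
            },
            {"alt_provider": -1.0, "clinician_executive": -0.5, "service_delivery_score": -1.5},
        ),
        "late_prenatal_rate": (
            20.0,
            {
                "social_disadvantage": 2.0, "pct_child_poverty": 1.5,
                "pct_hs_education": -1.0, "pct_african_american": 0.5,
                "pct_hispanic": 0.5, "total_expenditures": -0.5,
                "population": 0.3, "medicaid_births": 0.8,
                "providers_per_capita": -1.0,
                "community_type=micropolitan": 1.0, "community_type=rural": 2.0,
            },
            {"alt_provider": -0.8, "clinician_executive": -0.3, "service_delivery_score": -1.0},
        ),
        "infant_mortality_rate": (
            7.0,
            {
                "social_disadvantage": 0.8, "pct_child_poverty": 0.4,
                "pct_hs_education": -0.3, "pct_african_american": 0.4,
                "pct_hispanic": 0.1, "total_expenditures": -0.2,
                "population": 0.1, "medicaid_births": 0.3,
                "providers_per_capita": -0.2,
                "community_type=micropolitan": 0.3, "community_type=rural": 0.5,
            },
            {"alt_provider": -0.2, "clinician_executive": -0.1, "service_delivery_score": -0.3},
        ),
        "low_birth_weight_pct": (
            8.0,
            {
                "social_disadvantage": 1.0, "pct_child_poverty": 0.6,
                "pct_hs_education": -0.4, "pct_african_american": 0.6,
                "pct_hispanic": 0.2, "total_expenditures": -0.3,
                "population": 0.2, "medicaid_births": 0.4,
                "providers_per_capita": -0.3,
                "community_type=micropolitan": 0.4, "community_type=rural": 0.6,
            },
            {"alt_provider": -0.3, "clinician_executive": -0.2, "service_delivery_score": -0.5},
        ),
    }
    outcomes = {}
    for name, (alpha, bz, bx) in base_betas.items():
        sigma = _sigma_for_target_r2(context, mechanism, bz, bx, _R2_TARGETS[name])
        outcomes[name] = OutcomeSpec(alpha=alpha, beta_context=bz, beta_mechanism=bx, sigma=sigma)

    reporting = {
        "percap_mch_expend": MarginalSpec("lognorm", {"mu": 2.3, "sigma": 0.8}),
        "percap_wic_expend": MarginalSpec("lognorm", {"mu": 1.0, "sigma": 1.0}),
        "percap_fp_expend": MarginalSpec("lognorm", {"mu": 0.8, "sigma": 1.0}),
        "percap_mica_expend": MarginalSpec("lognorm", {"mu": 1.3, "sigma": 1.0}),
    }

    outcome_names = list(outcomes)
    cells = [(o, y) for o in outcome_names for y in years]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBEEF]))
    planted: list[PlantedShift] = []
    for sname, n_j in _DEFAULT_STATES:
        ids = [f"{sname}-{i + 1:03d}" for i in range(n_j)]
        n_multi, n_single = _MULTI_PLANT[sname], _SINGLE_PLANT[sname]
        chosen = rng.choice(len(ids), size=n_multi + n_single, replace=False)
        multi, single = chosen[:n_multi], chosen[n_multi:]
        for idx in multi:
            n_cells = int(rng.integers(2, 4))  # 2 or 3 cells
            for ci in rng.choice(len(cells), size=n_cells, replace=False):
                o, y = cells[ci]
                planted.append(PlantedShift(ids[idx], o, y, _PLANT_SHIFT))
        for idx in single:
            o, y = cells[int(rng.integers(len(cells)))]
            planted.append(PlantedShift(ids[idx], o, y, _PLANT_SHIFT))

    cfg = SimulationConfig(
        states=tuple(StateSpec(n, s) for n, s in _DEFAULT_STATES),
        years=years,
        context=context,
        mechanism=mechanism,
        outcomes=outcomes,
        reporting=reporting,
        planted=tuple(planted),
        seed=int(seed),
    )
    cfg.validate()
    return cfg
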