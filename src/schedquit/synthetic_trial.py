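"""Seeded synthetic three-arm cessation trial generator.

Emulates the trial's statistical structure so every downstream stage is
testable without the (unavailable) raw data: stratified three-arm
allocation, arm-dependent compliance confounded with abstinence through
a shared latent bivariate-normal draw, CO measurements consistent with
the compliance classification, and four follow-up visits with per-arm
response rates.

Latent structure.  For each participant draw ``(u, eps0)`` bivariate
standard normal; compliance in a scheduled arm is ``u <= Phi^-1(pi_c)``.
Each visit's outcome error is ``eps_v = lam*eps0 + sqrt(1-lam^2)*eta_v``
with ``corr(u, eps_v) = confound_rho``.  Untreated abstinence uses the
threshold ``Phi^-1(control prob)`` for everyone (controls and scheduled
noncompliers alike), so assignment affects outcomes only through
compliance — the exclusion restriction holds by construction.  Complier
thresholds are calibrated so the class-conditional abstinence
probability hits its configured target given the selection induced by
``confound_rho``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from ._bvn import bvn_cdf

__all__ = [
    "ARMS",
    "SCHEDULED_ARMS",
    "VISITS",
    "COBaselineModel",
    "CovariateModel",
    "TrialConfig",
    "TrialDataset",
    "stratified_allocate",
    "simulate_covariates",
    "simulate_compliance_and_outcome",
    "simulate_co",
    "apply_missingness",
    "generate_trial",
    "write_trial_csv",
    "read_trial_csv",
    "untreated_complier_prob",
    "implied_noncomplier_prob",
    "true_complier_effect",
]

ARMS = ("SSNP", "SS", "EUC")
SCHEDULED_ARMS = ("SSNP", "SS")
VISITS = ("2wk", "4wk", "6mo", "12mo")
Y_COLUMNS = tuple(f"y_{v}" for v in VISITS)

# Analyzable-set sizes and per-visit response counts by arm.
_DEFAULT_N = {"SSNP": 273, "SS": 268, "EUC": 279}
_DEFAULT_RESPONSE = {
    "SSNP": {"2wk": 212 / 273, "4wk": 192 / 273, "6mo": 171 / 273, "12mo": 151 / 273},
    "SS": {"2wk": 207 / 268, "4wk": 196 / 268, "6mo": 170 / 268, "12mo": 137 / 268},
    "EUC": {"2wk": 239 / 279, "4wk": 221 / 279, "6mo": 186 / 279, "12mo": 158 / 279},
}
# Proportion achieving >=50% CO reduction; structurally zero for EUC.
_DEFAULT_COMPLIANCE = {"SSNP": 0.509, "SS": 0.265, "EUC": 0.0}
# Untreated (control) abstinence probabilities per visit.  Placeholders:
# plausible magnitudes, not reported quantities.
_DEFAULT_CONTROL_ABST = {"2wk": 0.25, "4wk": 0.25, "6mo": 0.20, "12mo": 0.15}
# Complier causal probability differences vs the untreated state.
_DEFAULT_COMPLIER_EFFECT = {
    "SSNP": {"2wk": 0.26, "4wk": 0.29, "6mo": 0.26, "12mo": 0.22},
    "SS": {"2wk": 0.27, "4wk": 0.33, "6mo": 0.29, "12mo": 0.28},
}


@dataclass
class COBaselineModel:
    """Baseline expired CO (ppm) given cigarettes/day.

    Defaults (mean ~25 ppm at 23 cpd, SD 8) are placeholders: no
    baseline CO distribution was reported.
    """

    intercept: float = 10.0
    slope_per_cpd: float = 0.65
    sd: float = 8.0
    floor: float = 3.0


@dataclass
class CovariateModel:
    """Marginal covariate distributions (sampled independently)."""

    age_mean: float = 43.0
    age_sd: float = 11.0
    prob_female: float = 0.5
    race_levels: tuple[str, ...] = ("European American", "African American", "Hispanic or other")
    race_probs: tuple[float, ...] = (0.73, 0.18, 0.09)
    education_levels: tuple[str, ...] = ("some college", "<=high school", ">=college graduate")
    education_probs: tuple[float, ...] = (0.46, 0.20, 0.34)
    cpd_mean: float = 23.0
    cpd_sd: float = 10.0
    cpd_min: int = 10
    prob_depression_history: float = 0.25  # placeholder; prevalence not reported


def _copy_default(value):
    return field(default_factory=lambda: copy.deepcopy(value))


@dataclass
class TrialConfig:
    """Knobs of the synthetic trial generator.

    ``complier_abstinence_prob`` may be given directly per arm and
    visit; when ``None`` it is derived as (untreated complier
    probability under the latent selection) + ``complier_effect``, so
    the generating complier causal effect equals ``complier_effect``
    exactly.  ``noncomplier_abstinence_prob=None`` (default) leaves
    scheduled-arm noncompliers on the untreated threshold, which is what
    the exclusion restriction requires; supplying values overrides their
    class-conditional probabilities and deliberately breaks it (useful
    only for sensitivity checks).
    """

    n_per_arm: dict = _copy_default(_DEFAULT_N)
    compliance_prob: dict = _copy_default(_DEFAULT_COMPLIANCE)
    control_abstinence_prob: dict = _copy_default(_DEFAULT_CONTROL_ABST)
    complier_effect: dict = _copy_default(_DEFAULT_COMPLIER_EFFECT)
    complier_abstinence_prob: dict | None = None
    noncomplier_abstinence_prob: dict | None = None
    confound_rho: float = 0.3
    visit_noise_share: float = 0.5
    response_rate: dict = _copy_default(_DEFAULT_RESPONSE)
    co_baseline_model: COBaselineModel = field(default_factory=COBaselineModel)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def latent_weight(self) -> float:
        """Loading of the shared outcome latent; corr(u, eps0) = rho / weight."""
        return float(np.sqrt(1.0 - self.visit_noise_share))

    def validate(self) -> None:
        for arm, n in self.n_per_arm.items():
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
            if n <= 0:
                raise ValueError("arm counts must be positive")
        for arm in ARMS:
            p = self.compliance_prob.get(arm, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError("compliance probabilities must lie in [0, 1]")
        if self.compliance_prob.get("EUC", 0.0) != 0.0:
            raise ValueError("EUC has no schedule to comply with; its compliance_prob must be 0")
        for v in VISITS:
            if not 0.0 < self.control_abstinence_prob[v] < 1.0:
                raise ValueError("control abstinence probabilities must lie in (0, 1)")
            for arm in ARMS:
                r = self.response_rate[arm][v]
                if not 0.0 <= r <= 1.0:
                    raise ValueError("response rates must lie in [0, 1]")
        if not 0.0 <= self.visit_noise_share < 1.0:
            raise ValueError("visit_noise_share must lie in [0, 1)")
        if abs(self.confound_rho) >= 1.0:
            raise ValueError("|confound_rho| must be < 1")
        if abs(self.confound_rho) > self.latent_weight:
            raise ValueError(
                "|confound_rho| cannot exceed sqrt(1 - visit_noise_share); "
                "lower visit_noise_share or the correlation"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "TrialConfig":
        """Build a config from a (possibly partial) plain-dict description."""
        data = copy.deepcopy(data)
        kwargs: dict = {}
        for key in ("co_baseline_model", "covariate_model"):
            if key in data:
                sub = data.pop(key)
                model_cls = COBaselineModel if key == "co_baseline_model" else CovariateModel
                kwargs[key] = model_cls(**sub) if isinstance(sub, dict) else sub
        base = cls()
        for key, value in data.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(base, key), dict) and isinstance(value, dict):
                merged = copy.deepcopy(getattr(base, key))
                for k, v in value.items():
                    if isinstance(merged.get(k), dict) and isinstance(v, dict):
                        merged[k].update(v)
                    else:
                        merged[k] = v
                kwargs[key] = merged
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def resolved_complier_prob(self, arm: str, visit: str) -> float:
        """Target P(abstinent | complier) for a scheduled arm and visit."""
        if self.complier_abstinence_prob is not None:
            return self.complier_abstinence_prob[arm][visit]
        base = untreated_complier_prob(
            self.compliance_prob[arm], self.control_abstinence_prob[visit], self.confound_rho
        )
        target = base + self.complier_effect[arm][visit]
        if not 0.0 < target < 1.0:
            raise ValueError(
                f"complier effect for {arm}/{visit} pushes the target probability "
                f"outside (0, 1): {target:.3f}"
            )
        return target


def untreated_complier_prob(pi_c: float, p_control: float, rho: float) -> float:
    """P(abstinent without treatment | complier) under the latent selection."""
    if pi_c <= 0.0 or pi_c >= 1.0:
        return p_control
    t = norm.ppf(pi_c)
    return bvn_cdf(t, norm.ppf(p_control), rho) / pi_c


def implied_noncomplier_prob(pi_c: float, p_control: float, rho: float) -> float:
    """P(abstinent | noncomplier) implied by the structure (untreated threshold)."""
    if pi_c >= 1.0:
        return p_control
    if pi_c <= 0.0:
        return p_control
    t = norm.ppf(pi_c)
    b0 = norm.ppf(p_control)
    return (norm.cdf(b0) - bvn_cdf(t, b0, rho)) / (1.0 - pi_c)


def true_complier_effect(config: TrialConfig, arm: str, visit: str) -> float:
    """Generating causal probability difference among compliers."""
    base = untreated_complier_prob(
        config.compliance_prob[arm], config.control_abstinence_prob[visit], config.confound_rho
    )
    return config.resolved_complier_prob(arm, visit) - base


def _conditional_threshold(pi_c: float, p_target: float, rho: float, complier: bool) -> float:
    """Outcome threshold q with P(eps <= q | compliance class) = p_target."""
    if not 0.0 < p_target < 1.0:
        raise ValueError("class-conditional probabilities must lie in (0, 1)")
    t = norm.ppf(pi_c)

    if complier:
        def f(q):
            return bvn_cdf(t, q, rho) / pi_c - p_target
    else:
        def f(q):
            return (norm.cdf(q) - bvn_cdf(t, q, rho)) / (1.0 - pi_c) - p_target

    return optimize.brentq(f, -12.0, 12.0, xtol=1e-12)


def stratified_allocate(strata, n_per_arm, rng=None, arms: tuple[str, ...] = ARMS) -> np.ndarray:
    """Assign arms within strata, balanced relative to the marginal targets.

    Each stratum of size m gives every arm floor(m * target_share); the
    leftover slots go to the arms furthest below their marginal targets,
    so within a stratum no arm deviates from its proportional share by
    more than one.  Marginal totals in ``n_per_arm`` are always met
    exactly; when many small strata make that incompatible with
    within-one balance everywhere, a final repair pass moves single
    participants inside the least-disturbed strata.
    """
    strata = np.asarray(strata, dtype=object)
    n = len(strata)
    if n == 0:
        raise ValueError("strata table is empty")
    if isinstance(n_per_arm, dict):
        targets = {arm: int(n_per_arm[arm]) for arm in arms}
    else:
        targets = dict(zip(arms, (int(x) for x in n_per_arm)))
    if sum(targets.values()) != n:
        raise ValueError(
            f"arm targets sum to {sum(targets.values())} but {n} participants supplied"
        )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    labels = sorted(set(strata.tolist()), key=str)
    shares = {arm: targets[arm] / n for arm in arms}
    remaining = dict(targets)
    stratum_idx = {lab: np.flatnonzero(strata == lab) for lab in labels}
    stratum_counts = {lab: dict.fromkeys(arms, 0) for lab in labels}

    result = np.empty(n, dtype=object)
    for lab in labels:
        idx = stratum_idx[lab]
        m = len(idx)
        base = {arm: int(np.floor(m * shares[arm])) for arm in arms}
        r = m - sum(base.values())
        for arm in arms:
            remaining[arm] -= base[arm]
        order = list(rng.permutation(len(arms)))  # random tie-break
        extras = sorted(arms, key=lambda a: (-remaining[a], order[arms.index(a)]))[:r]
        for arm in extras:
            remaining[arm] -= 1
        assignment = [arm for arm in arms for _ in range(base[arm])] + list(extras)
        for arm in assignment:
            stratum_counts[lab][arm] += 1
        perm = rng.permutation(idx)
        result[perm] = assignment

    # Repair pass: enforce exact marginal totals, shifting one
    # participant at a time inside the stratum where the move disturbs
    # within-stratum balance least.
    counts = {arm: int(np.sum(result == arm)) for arm in arms}
    while counts != targets:
        over = max(arms, key=lambda a: counts[a] - targets[a])
        under = min(arms, key=lambda a: counts[a] - targets[a])
        best_lab = max(
            labels,
            key=lambda lab: stratum_counts[lab][over] - stratum_counts[lab][under],
        )
        candidates = stratum_idx[best_lab][result[stratum_idx[best_lab]] == over]
        result[rng.choice(candidates)] = under
        stratum_counts[best_lab][over] -= 1
        stratum_counts[best_lab][under] += 1
        counts[over] -= 1
        counts[under] += 1
    return result


def simulate_covariates(model: CovariateModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = model.age_mean + model.age_sd * rng.standard_normal(n)
    age = np.clip(np.round(age), 18, 90).astype(int)
    sex = np.where(rng.random(n) < model.prob_female, "female", "male")
    race = rng.choice(model.race_levels, size=n, p=np.asarray(model.race_probs) / np.sum(model.race_probs))
    education = rng.choice(
        model.education_levels, size=n, p=np.asarray(model.education_probs) / np.sum(model.education_probs)
    )
    cpd = np.round(model.cpd_mean + model.cpd_sd * rng.standard_normal(n))
    cpd = np.clip(cpd, model.cpd_min, None).astype(int)
    dep_hx = (rng.random(n) < model.prob_depression_history).astype(int)
    return pd.DataFrame(
        {"sex": sex, "race": race, "education": education, "age": age, "cpd": cpd, "dep_hx": dep_hx}
    )


def simulate_compliance_and_outcome(
    config: TrialConfig,
    arm: str,
    n: int,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw compliance flags and per-visit abstinence for one arm.

    Returns ``(complier, y)`` with ``y`` of shape ``(n, 4)``.  In the
    default parameterization the class-conditional abstinence
    probabilities are direct config targets, so ``covariates`` does not
    enter the outcome model; it is accepted for interface stability.
    """
    del covariates  # probabilities are parameterized directly
    pi_c = config.compliance_prob[arm]
    rho = config.confound_rho
    lam = config.latent_weight
    rho0 = rho / lam if lam > 0 else 0.0

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    u = z1
    eps0 = rho0 * z1 + np.sqrt(max(0.0, 1.0 - rho0**2)) * z2
    complier = u <= norm.ppf(pi_c)  # ppf(0) = -inf -> none; ppf(1) = +inf -> all

    y = np.zeros((n, len(VISITS)), dtype=int)
    for j, visit in enumerate(VISITS):
        p_control = config.control_abstinence_prob[visit]
        b0 = norm.ppf(p_control)
        if arm in SCHEDULED_ARMS and pi_c > 0.0:
            q_c = _conditional_threshold(pi_c, config.resolved_complier_prob(arm, visit), rho, True)
            if config.noncomplier_abstinence_prob is not None:
                q_nc = _conditional_threshold(
                    pi_c, config.noncomplier_abstinence_prob[arm][visit], rho, False
                )
            else:
                q_nc = b0  # exclusion restriction: untreated threshold
            thresholds = np.where(complier, q_c, q_nc)
        else:
            thresholds = np.full(n, b0)
        eps_v = lam * eps0 + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        y[:, j] = (eps_v <= thresholds).astype(int)
    return complier, y


def simulate_co(
    baseline_cpd,
    complier,
    rng: np.random.Generator,
    model: COBaselineModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (baseline, final) expired CO pairs consistent with compliance.

    The final reading is ``co_baseline * (1 - r)`` with the reduction
    fraction r drawn in [0.5, 0.8) for compliers and [-0.2, 0.5) for
    noncompliers, so the >=50% classification of the pair reproduces the
    complier flag exactly and both readings stay positive.
    """
    model = model or COBaselineModel()
    cpd = np.atleast_1d(np.asarray(baseline_cpd, dtype=float))
    complier = np.atleast_1d(np.asarray(complier, dtype=bool))
    if np.any(cpd <= 0):
        raise ValueError("baseline_cpd must be positive")
    n = len(cpd)
    co_baseline = model.intercept + model.slope_per_cpd * cpd + model.sd * rng.standard_normal(n)
    co_baseline = np.maximum(co_baseline, model.floor)
    r_comp = rng.uniform(0.5, 0.8, n)
    r_non = rng.uniform(-0.2, 0.5, n)
    r = np.where(complier, r_comp, r_non)
    co_final = co_baseline * (1.0 - r)
    return co_baseline, co_final


def apply_missingness(y: np.ndarray, response_rate, rng: np.random.Generator) -> np.ndarray:
    """Mask outcomes visit-wise: observed with the visit's response rate.

    ``response_rate`` is a mapping visit -> probability or an array of
    length 4.  Returns a float array with ``nan`` at unobserved visits.
    """
    if isinstance(response_rate, dict):
        rates = np.array([response_rate[v] for v in VISITS], dtype=float)
    else:
        rates = np.asarray(response_rate, dtype=float)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("response rates must lie in [0, 1]")
    y = np.asarray(y, dtype=float)
    observed = rng.random(y.shape) < rates
    return np.where(observed, y, np.nan)


@dataclass
class TrialDataset:
    """A generated trial: participant table plus provenance."""

    participants: pd.DataFrame
    config: TrialConfig
    seed: int | None
    generator_version: str = "0.1.0"


def generate_trial(config: TrialConfig | None = None, seed: int | None = None) -> TrialDataset:
    """Generate a full three-arm trial dataset, bit-reproducible per seed."""
    config = config or TrialConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    n_total = sum(config.n_per_arm[a] for a in ARMS)
    cov = simulate_covariates(config.covariate_model, n_total, rng)
    strata = (
        cov["sex"].astype(str)
        + "|" + cov["race"].astype(str)
        + "|" + np.where(cov["cpd"] >= 20, "cpd>=20", "cpd<20")
        + "|" + np.where(cov["dep_hx"] == 1, "dep", "nodep")
    )
    arm = stratified_allocate(strata.to_numpy(), config.n_per_arm, rng)

    complier = np.zeros(n_total, dtype=bool)
    y = np.zeros((n_total, len(VISITS)), dtype=float)
    co_baseline = np.zeros(n_total)
    co_final = np.zeros(n_total)
    for a in ARMS:
        idx = np.flatnonzero(arm == a)
        comp_a, y_a = simulate_compliance_and_outcome(config, a, len(idx), rng)
        co_b, co_f = simulate_co(cov["cpd"].to_numpy()[idx], comp_a, rng, config.co_baseline_model)
        y_a = apply_missingness(y_a, config.response_rate[a], rng)
        complier[idx] = comp_a
        y[idx] = y_a
        co_baseline[idx] = co_b
        co_final[idx] = co_f

    df = cov.copy()
    df.insert(0, "id", np.arange(1, n_total + 1))
    df.insert(1, "arm", arm)
    df["co_baseline"] = np.round(co_baseline, 4)
    df["co_final"] = np.round(co_final, 4)
    comp_col = pd.array(complier.astype(int), dtype="Int64")
    comp_col[np.asarray(arm == "EUC")] = pd.NA  # no schedule, no compliance label
    df["complier"] = comp_col
    for j, col in enumerate(Y_COLUMNS):
        df[col] = pd.array([pd.NA if np.isnan(v) else int(v) for v in y[:, j]], dtype="Int64")
    df = df[
        ["id", "arm", "sex", "race", "education", "age", "cpd", "dep_hx",
         "co_baseline", "co_final", "complier", *Y_COLUMNS]
    ]
    return TrialDataset(participants=df, config=config, seed=seed)


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write the participant table as CSV plus a sidecar config echo."""
    dataset.participants.to_csv(path, index=False, na_rep="NA")
    sidecar = {
        "seed": dataset.seed,
        "generator_version": dataset.generator_version,
        "config": asdict(dataset.config),
    }
    with open(f"{path}.config.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_trial_csv(path) -> pd.DataFrame:
    """Read a participant CSV written by :func:`write_trial_csv`."""
    df = pd.read_csv(path, na_values=["NA"])
    for col in ("complier", *Y_COLUMNS):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df
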