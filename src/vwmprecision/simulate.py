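"""Synthetic cohort and trial generation for the delayed-reproduction tasks.

Emulates the study design end to end so every downstream stage is testable
without real data: an age-structured cohort of school-aged children, each
completing 25 sensorimotor-control trials, 30 one-item memory trials, and
90 three-item sequential memory trials with coloured oriented bars.

Generative structure per participant:

* a sensorimotor circular SD (dial/matching noise), declining with age;
* per-condition mixture parameters (kappa, p(T), p(NT), p(U)); by default
  only kappa carries an age trend, with participant-level scatter on all
  parameters;
* a multiplicative kappa boost for the final serial position (recency).

Responses are drawn from the mixture on the doubled-angle space and then
perturbed with an independent von Mises motor deviate whose circular SD
equals the participant's sensorimotor SD, so that the variance-additivity
assumption of the sensorimotor correction holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mixture import MixtureParams, kappa_from_circular_sd

__all__ = [
    "COLOURS",
    "CohortConfig",
    "GenerativeParams",
    "ParticipantProfile",
    "TrialRecord",
    "ConfigError",
    "GenerationError",
    "generate_cohort",
    "generate_trials",
    "generate_dataset",
    "truncate_sessions",
    "sample_orientation_triples",
]

#: The study's five stimulus colours; they carry no generative role beyond
#: binding identity (which bar is probed).
COLOURS = ("red", "yellow", "green", "blue", "pink")

_PI = math.pi
_TWO_PI = 2.0 * math.pi

#: Age cut points mapping age in years to school year groups 3..8.
_YEAR_CUTS = (8.5, 9.9, 10.7, 11.7, 12.8)


class ConfigError(ValueError):
    """Raised for infeasible cohort configurations."""


class GenerationError(RuntimeError):
    """Raised when trial generation cannot satisfy its constraints."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and generative settings for a synthetic cohort.

    Defaults mirror the study design (87 participants aged 7.9-13.6 years;
    25/30/90 trials; 0.175 rad minimum separation; IQ weakly correlated
    with age) with generative magnitudes chosen to give precision values of
    the order observed in school-aged children on these tasks. Age trends
    are linear and centred at ``age_ref``; by default only kappa and the
    sensorimotor SD change with age.
    """

    n_participants: int = 87
    n_sensorimotor: int = 25
    n_vwm1: int = 30
    n_vwm3: int = 90
    age_min: float = 7.9
    age_max: float = 13.6
    age_ref: float = 11.26
    min_separation: float = 0.175

    # one-item memory concentration (doubled-angle scale)
    kappa_vwm1_intercept: float = 12.0
    kappa_vwm1_slope: float = 2.5
    kappa_vwm1_noise: float = 3.0
    alpha_vwm1: float = 0.97
    alpha_vwm1_noise: float = 0.0

    # three-item memory concentration and mixture weights
    kappa_vwm3_intercept: float = 5.5
    kappa_vwm3_slope: float = 0.8
    kappa_vwm3_noise: float = 0.8
    alpha_vwm3: float = 0.85
    alpha_vwm3_noise: float = 0.0
    beta_vwm3: float = 0.05
    beta_vwm3_noise: float = 0.0
    # age slopes on the mixture weights (0 by default: only kappa develops)
    alpha_vwm3_slope: float = 0.0
    beta_vwm3_slope: float = 0.0

    kappa_floor: float = 0.5
    recency_boost: float = 3.0

    # sensorimotor (motor + perceptual matching) circular SD, doubled scale
    sm_sd_intercept: float = 0.10
    sm_sd_slope: float = -0.010
    sm_sd_noise: float = 0.022
    sm_sd_floor: float = 0.03

    fsiq_mean: float = 113.0
    fsiq_sd: float = 12.0
    fsiq_age_corr: float = 0.26

    max_rejection_rounds: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_participants, self.n_sensorimotor, self.n_vwm1, self.n_vwm3) <= 0:
            raise ConfigError("all counts must be positive")
        if not (self.age_min < self.age_max):
            raise ConfigError("age range must be non-degenerate")
        if not (0.0 <= self.min_separation < _PI / 3):
            raise ConfigError("min_separation must lie in [0, pi/3)")
        if not (-1.0 < self.fsiq_age_corr < 1.0):
            raise ConfigError("fsiq_age_corr must lie in (-1, 1)")
        if self.recency_boost <= 0:
            raise ConfigError("recency_boost must be positive")
        for age in (self.age_min, self.age_max):
            rel = age - self.age_ref
            for name, icpt, slope in (
                ("kappa_vwm1", self.kappa_vwm1_intercept, self.kappa_vwm1_slope),
                ("kappa_vwm3", self.kappa_vwm3_intercept, self.kappa_vwm3_slope),
            ):
                if icpt + slope * rel <= 0:
                    raise ConfigError(f"mean {name} non-positive at age {age}")
            if self.sm_sd_intercept + self.sm_sd_slope * rel <= 0:
                raise ConfigError(f"mean sensorimotor SD non-positive at age {age}")
            a = self.alpha_vwm3 + self.alpha_vwm3_slope * rel
            b = self.beta_vwm3 + self.beta_vwm3_slope * rel
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0 and a + b <= 1.0):
                raise ConfigError(f"three-item mixture weights invalid at age {age}")
            if not (0.0 <= self.alpha_vwm1 <= 1.0):
                raise ConfigError("alpha_vwm1 must lie in [0, 1]")


@dataclass(frozen=True)
class GenerativeParams:
    """Per-participant generative parameters (synthetic cohorts only)."""

    kappa_vwm1: float
    alpha_vwm1: float
    kappa_vwm3: float
    alpha_vwm3: float
    beta_vwm3: float
    sensorimotor_sd: float
    recency_boost: float

    @property
    def vwm1(self) -> MixtureParams:
        return MixtureParams(
            self.kappa_vwm1, self.alpha_vwm1, 0.0, 1.0 - self.alpha_vwm1
        )

    @property
    def vwm3(self) -> MixtureParams:
        gamma = 1.0 - self.alpha_vwm3 - self.beta_vwm3
        return MixtureParams(self.kappa_vwm3, self.alpha_vwm3, self.beta_vwm3, gamma)


@dataclass(frozen=True)
class ParticipantProfile:
    """One synthetic participant: identity, covariates, generative truth."""

    id: str
    age: float
    year_group: int
    fsiq_e: float
    gen: GenerativeParams
    trial_seed: int


@dataclass(frozen=True)
class TrialRecord:
    """One delayed-reproduction trial as stored in the canonical table.

    Orientations are radians in ``[0, pi)``; ``stimulus_orientations`` are
    in presentation order, so ``probed_index`` is the probed serial
    position (0-based).
    """

    participant_id: str
    condition: str  # sensorimotor | vwm1 | vwm3
    trial_index: int
    stimulus_orientations: tuple[float, ...]
    stimulus_colours: tuple[str, ...]
    probed_index: int
    response_orientation: float


def _year_group(age: float) -> int:
    return 3 + int(np.searchsorted(_YEAR_CUTS, age, side="right"))


def _clip_simplex(alpha: float, beta: float, gamma_min: float = 0.01):
    """Clip (alpha, beta) so the implied simplex is valid with gamma >= gamma_min."""
    alpha = min(max(alpha, 0.0), 1.0 - gamma_min)
    beta = min(max(beta, 0.0), 1.0 - gamma_min - alpha)
    return alpha, beta


def generate_cohort(config: CohortConfig) -> list[ParticipantProfile]:
    """Sample a cohort of participant profiles. Deterministic given the seed.

    Ages are uniform on the configured range; estimated IQ is Gaussian with
    the configured correlation with age; generative parameters follow the
    configured linear age trends plus participant-level Gaussian scatter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ages = rng.uniform(config.age_min, config.age_max, size=n)
    z_age = (ages - ages.mean()) / max(ages.std(), 1e-12)
    rho = config.fsiq_age_corr
    z_iq = rho * z_age + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    fsiq = config.fsiq_mean + config.fsiq_sd * z_iq

    trial_seeds = rng.integers(0, 2**31 - 1, size=n)
    profiles = []
    for i in range(n):
        rel = ages[i] - config.age_ref
        k1 = max(
            config.kappa_floor,
            config.kappa_vwm1_intercept
            + config.kappa_vwm1_slope * rel
            + config.kappa_vwm1_noise * rng.standard_normal(),
        )
        k3 = max(
            config.kappa_floor,
            config.kappa_vwm3_intercept
            + config.kappa_vwm3_slope * rel
            + config.kappa_vwm3_noise * rng.standard_normal(),
        )
        a1, _ = _clip_simplex(
            config.alpha_vwm1 + config.alpha_vwm1_noise * rng.standard_normal(), 0.0
        )
        a3, b3 = _clip_simplex(
            config.alpha_vwm3
            + config.alpha_vwm3_slope * rel
            + config.alpha_vwm3_noise * rng.standard_normal(),
            config.beta_vwm3
            + config.beta_vwm3_slope * rel
            + config.beta_vwm3_noise * rng.standard_normal(),
        )
        sm = max(
            config.sm_sd_floor,
            config.sm_sd_intercept
            + config.sm_sd_slope * rel
            + config.sm_sd_noise * rng.standard_normal(),
        )
        profiles.append(
            ParticipantProfile(
                id=f"P{i + 1:03d}",
                age=float(ages[i]),
                year_group=_year_group(float(ages[i])),
                fsiq_e=float(fsiq[i]),
                gen=GenerativeParams(
                    kappa_vwm1=float(k1),
                    alpha_vwm1=float(a1),
                    kappa_vwm3=float(k3),
                    alpha_vwm3=float(a3),
                    beta_vwm3=float(b3),
                    sensorimotor_sd=float(sm),
                    recency_boost=config.recency_boost,
                ),
                trial_seed=int(trial_seeds[i]),
            )
        )
    return profiles


def sample_orientation_triples(
    rng: np.random.Generator,
    n: int,
    min_separation: float,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Sample (n, 3) orientations uniform on [0, pi) with pairwise circular
    separation >= ``min_separation``, by vectorized rejection sampling."""
    out = np.empty((n, 3))
    todo = np.arange(n)
    for _ in range(max_rounds):
        cand = rng.uniform(0.0, _PI, size=(todo.size, 3))
        ok = np.ones(todo.size, dtype=bool)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            d = np.abs(cand[:, i] - cand[:, j])
            sep = np.minimum(d, _PI - d)
            ok &= sep >= min_separation
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise GenerationError(
        f"orientation rejection sampling failed for {todo.size} trials "
        f"after {max_rounds} rounds"
    )


def _motor_kappa(sd: float) -> float:
    return kappa_from_circular_sd(sd)


def _mixture_responses(
    rng: np.random.Generator,
    targets2: np.ndarray,
    nontargets2: np.ndarray | None,
    kappa: np.ndarray,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Draw doubled-space responses from the mixture with per-trial kappa."""
    n = targets2.size
    u = rng.random(n)
    is_t = u < alpha
    is_nt = (~is_t) & (u < alpha + beta)
    means = targets2.copy()
    if nontargets2 is not None and nontargets2.size:
        pick = rng.integers(0, nontargets2.shape[1], size=n)
        means[is_nt] = nontargets2[np.arange(n), pick][is_nt]
    resp = (means + rng.vonmises(0.0, kappa)) % _TWO_PI
    is_u = ~(is_t | is_nt)
    resp[is_u] = rng.uniform(0.0, _TWO_PI, size=int(is_u.sum()))
    return resp


def generate_trials(profile: ParticipantProfile, config: CohortConfig) -> list[TrialRecord]:
    """Generate one participant's full session. Deterministic given the profile.

    Sensorimotor trials carry pure motor noise about the visible target;
    memory trials draw from the participant's mixture parameters (with the
    serial-position-3 kappa boost in the three-item task) and add an
    independent motor deviate on top.
    """
    rng = np.random.default_rng(profile.trial_seed)
    k_motor = _motor_kappa(profile.gen.sensorimotor_sd)
    records: list[TrialRecord] = []

    # -- sensorimotor control: match a visible bar; error is motor-only
    n_sm = config.n_sensorimotor
    targets = rng.uniform(0.0, _PI, size=n_sm)
    colours = rng.integers(0, len(COLOURS), size=n_sm)
    resp2 = (2.0 * targets + rng.vonmises(0.0, np.full(n_sm, k_motor))) % _TWO_PI
    for i in range(n_sm):
        records.append(
            TrialRecord(
                participant_id=profile.id,
                condition="sensorimotor",
                trial_index=i,
                stimulus_orientations=(float(targets[i]),),
                stimulus_colours=(COLOURS[colours[i]],),
                probed_index=0,
                response_orientation=float(resp2[i] / 2.0),
            )
        )

    # -- one-item memory: mixture (target / uniform) plus motor noise
    n1 = config.n_vwm1
    targets = rng.uniform(0.0, _PI, size=n1)
    colours = rng.integers(0, len(COLOURS), size=n1)
    g = profile.gen
    resp2 = _mixture_responses(
        rng, 2.0 * targets, None, np.full(n1, g.kappa_vwm1), g.alpha_vwm1, 0.0
    )
    resp2 = (resp2 + rng.vonmises(0.0, np.full(n1, k_motor))) % _TWO_PI
    for i in range(n1):
        records.append(
            TrialRecord(
                participant_id=profile.id,
                condition="vwm1",
                trial_index=i,
                stimulus_orientations=(float(targets[i]),),
                stimulus_colours=(COLOURS[colours[i]],),
                probed_index=0,
                response_orientation=float(resp2[i] / 2.0),
            )
        )

    # -- three-item sequential memory
    n3 = config.n_vwm3
    stims = sample_orientation_triples(
        rng, n3, config.min_separation, config.max_rejection_rounds
    )
    colour_idx = np.argsort(rng.random((n3, len(COLOURS))), axis=1)[:, :3]
    probed = rng.integers(0, 3, size=n3)
    rows = np.arange(n3)
    targets = stims[rows, probed]
    mask = np.ones_like(stims, dtype=bool)
    mask[rows, probed] = False
    nontargets = stims[mask].reshape(n3, 2)
    kappa_sp = np.where(probed == 2, g.kappa_vwm3 * g.recency_boost, g.kappa_vwm3)
    kappa_sp = np.minimum(kappa_sp, 700.0)
    resp2 = _mixture_responses(
        rng, 2.0 * targets, 2.0 * nontargets, kappa_sp, g.alpha_vwm3, g.beta_vwm3
    )
    resp2 = (resp2 + rng.vonmises(0.0, np.full(n3, k_motor))) % _TWO_PI
    for i in range(n3):
        records.append(
            TrialRecord(
                participant_id=profile.id,
                condition="vwm3",
                trial_index=i,
                stimulus_orientations=tuple(float(x) for x in stims[i]),
                stimulus_colours=tuple(COLOURS[j] for j in colour_idx[i]),
                probed_index=int(probed[i]),
                response_orientation=float(resp2[i] / 2.0),
            )
        )
    return records


def generate_dataset(config: CohortConfig):
    """Generate a full cohort and all its trials.

    Returns ``(profiles, trials)``; byte-identical for identical seeds.
    """
    profiles = generate_cohort(config)
    trials: list[TrialRecord] = []
    for profile in profiles:
        trials.extend(generate_trials(profile, config))
    return profiles, trials


def truncate_sessions(
    trials: list[TrialRecord],
    fraction_incomplete: float,
    seed: int,
    min_retained: int = 45,
) -> list[TrialRecord]:
    """Randomly truncate some participants' three-item sessions.

    Emulates participants who ran out of time: a ``fraction_incomplete``
    share of participants keep only a random number (>= ``min_retained``,
    < the full count) of their earliest three-item trials. Other
    conditions are untouched.
    """
    if not (0.0 <= fraction_incomplete < 1.0):
        raise ValueError("fraction_incomplete must lie in [0, 1)")
    if fraction_incomplete == 0.0:
        return list(trials)
    rng = np.random.default_rng(seed)
    pids = sorted({t.participant_id for t in trials})
    n_trunc = int(round(fraction_incomplete * len(pids)))
    chosen = set(rng.choice(pids, size=n_trunc, replace=False))
    full = {
        pid: max(
            (t.trial_index for t in trials if t.participant_id == pid and t.condition == "vwm3"),
            default=-1,
        )
        + 1
        for pid in chosen
    }
    keep_len = {
        pid: int(rng.integers(min_retained, full[pid])) if full[pid] > min_retained else full[pid]
        for pid in chosen
    }
    out = []
    for t in trials:
        if (
            t.condition == "vwm3"
            and t.participant_id in keep_len
            and t.trial_index >= keep_len[t.participant_id]
        ):
            continue
        out.append(t)
    return out
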