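"""Three-component mixture model of continuous-report response error.

The response on each trial is modelled as coming from one of three sources:

* the **target** item, reported with von Mises noise of concentration
  ``kappa`` (probability ``alpha``, p(T));
* a **non-target** item from the same trial — a misbinding/swap error —
  with the same ``kappa`` (probability ``beta``, p(NT), split evenly over
  the ``m`` non-targets);
* a **uniform** random orientation, i.e. a guess (probability
  ``gamma = 1 - alpha - beta``, p(U)).

All angles here are on the doubled (2*pi-periodic) representation of the
pi-periodic orientation space. Maximum-likelihood estimates are obtained by
expectation-maximization with multiple restarts; a brute-force grid search
over the same likelihood serves as an independent oracle for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "KAPPA_MAX",
    "MixtureParams",
    "TrialGeometry",
    "MixtureFit",
    "FitConfig",
    "InvalidParamsError",
    "vonmises_density",
    "mixture_loglik",
    "fit_em",
    "grid_oracle_fit",
    "simulate_responses",
    "kappa_from_circular_sd",
    "trials_to_arrays",
]

#: Upper concentration bound; beyond this the von Mises is numerically a
#: point mass and Bessel-ratio inversion is ill-conditioned.
KAPPA_MAX = 700.0

_TWO_PI = 2.0 * math.pi
_TINY = np.finfo(float).tiny


class InvalidParamsError(ValueError):
    """Raised for mixture parameters outside the valid simplex/bounds."""


@dataclass(frozen=True)
class MixtureParams:
    """Mixture parameters: concentration and the component probabilities.

    ``p_target + p_nontarget + p_uniform`` must equal 1 to 1e-10 and
    ``kappa`` must lie in ``[0, KAPPA_MAX]``.
    """

    kappa: float
    p_target: float
    p_nontarget: float
    p_uniform: float

    def __post_init__(self) -> None:
        probs = (self.p_target, self.p_nontarget, self.p_uniform)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise InvalidParamsError(f"probabilities must lie in [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-10:
            raise InvalidParamsError(f"probabilities must sum to 1: {probs}")
        if not (0.0 <= self.kappa <= KAPPA_MAX):
            raise InvalidParamsError(
                f"kappa must lie in [0, {KAPPA_MAX}], got {self.kappa}"
            )


@dataclass(frozen=True)
class TrialGeometry:
    """Angles for one trial on the doubled 2*pi-periodic space.

    ``nontargets`` holds the orientations of the unprobed items (empty for
    one-item trials, two entries for three-item trials). ``response`` is
    None for to-be-simulated geometries.
    """

    target: float
    nontargets: tuple[float, ...] = ()
    response: float | None = None


@dataclass(frozen=True)
class MixtureFit:
    """Result of a maximum-likelihood mixture fit."""

    params: MixtureParams
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_restarts_used: int = 1
    kappa_identifiable: bool = True


@dataclass(frozen=True)
class FitConfig:
    """EM fitter settings.

    One method-of-moments start plus ``n_random_restarts`` random starts;
    the best final log-likelihood wins. Convergence is declared when the
    log-likelihood improves by less than ``tol``.
    """

    tol: float = 1e-6
    max_iter: int = 10_000
    n_random_restarts: int = 9
    min_trials: int = 20
    kappa_max: float = KAPPA_MAX
    restart_seed: int = 7
    # kappa is flagged unidentifiable when the fitted target+nontarget mass
    # falls below this floor, or when the fit beats the pure-uniform
    # log-likelihood by less than 2 (the data are essentially uniform)
    identifiability_floor: float = 0.02


def vonmises_density(x, mu=0.0, kappa: float = 1.0):
    """von Mises density ``exp(kappa cos(x-mu)) / (2 pi I0(kappa))``.

    Evaluated with exponentially-scaled Bessel functions so it is stable up
    to ``kappa = KAPPA_MAX``. ``kappa = 0`` gives the uniform density
    ``1/(2 pi)``.
    """
    if kappa < 0:
        raise InvalidParamsError(f"kappa must be >= 0, got {kappa}")
    if kappa > KAPPA_MAX:
        raise InvalidParamsError(f"kappa {kappa} exceeds overflow guard {KAPPA_MAX}")
    x = np.asarray(x, dtype=float)
    out = np.exp(kappa * (np.cos(x - mu) - 1.0)) / (_TWO_PI * i0e(kappa))
    return float(out) if out.ndim == 0 else out


def _a1(kappa: float) -> float:
    """Bessel ratio A1(kappa) = I1(kappa) / I0(kappa)."""
    return float(i1e(kappa) / i0e(kappa))


def _a1inv(r: float, kappa_max: float = KAPPA_MAX) -> float:
    """Invert the Bessel ratio: find kappa with A1(kappa) = r.

    Two-regime closed-form approximation refined by Newton steps;
    clipped to ``[0, kappa_max]``.
    """
    if r <= 0.0:
        return 0.0
    if r >= 1.0:
        return kappa_max
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    k = min(max(k, 1e-8), kappa_max)
    for _ in range(25):
        a = _a1(k)
        deriv = 1.0 - a / k - a * a
        if deriv <= 0.0:
            break
        k_new = min(max(k - (a - r) / deriv, 1e-12), kappa_max)
        if abs(k_new - k) < 1e-12 * (1.0 + k):
            k = k_new
            break
        k = k_new
    return k


def kappa_from_circular_sd(sd: float, kappa_max: float = KAPPA_MAX) -> float:
    """Concentration whose Fisher circular SD equals ``sd`` (doubled scale)."""
    if sd < 0:
        raise InvalidParamsError(f"sd must be >= 0, got {sd}")
    return _a1inv(math.exp(-0.5 * sd * sd), kappa_max)


def trials_to_arrays(trials):
    """Unpack TrialGeometry sequence into (targets, nontargets, responses, m).

    All trials must share the same number of non-targets ``m``; responses
    may be None only if None for every trial (returned as None).
    """
    if not trials:
        raise InvalidParamsError("trial list is empty")
    m = len(trials[0].nontargets)
    if any(len(t.nontargets) != m for t in trials):
        raise InvalidParamsError("all trials must share the same number of non-targets")
    targets = np.array([t.target for t in trials], dtype=float)
    nontargets = np.array([t.nontargets for t in trials], dtype=float).reshape(
        len(trials), m
    )
    has_resp = [t.response is not None for t in trials]
    if all(has_resp):
        responses = np.array([t.response for t in trials], dtype=float)
    elif not any(has_resp):
        responses = None
    else:
        raise InvalidParamsError("either all or no trials may carry responses")
    return targets, nontargets, responses, m


def _component_densities(d_target, d_nontarget, kappa):
    f_t = vonmises_density(d_target, 0.0, kappa)
    f_n = vonmises_density(d_nontarget, 0.0, kappa) if d_nontarget.size else d_nontarget
    return f_t, f_n


def _trial_likelihoods(d_target, d_nontarget, m, params: MixtureParams):
    f_t, f_n = _component_densities(d_target, d_nontarget, params.kappa)
    p = params.p_target * f_t + params.p_uniform / _TWO_PI
    if m:
        p = p + (params.p_nontarget / m) * f_n.sum(axis=1)
    return np.maximum(p, _TINY), f_t, f_n


def mixture_loglik(trials, params: MixtureParams) -> float:
    """Log-likelihood of the response data under the mixture model.

    With ``m = 0`` (no non-targets) the misbinding component is absent and
    ``p_nontarget`` must be 0.
    """
    targets, nontargets, responses, m = trials_to_arrays(trials)
    if responses is None:
        raise InvalidParamsError("trials must carry responses")
    if m == 0 and params.p_nontarget > 0:
        raise InvalidParamsError("p_nontarget must be 0 when trials have no non-targets")
    d_t = responses - targets
    d_n = responses[:, None] - nontargets
    p, _, _ = _trial_likelihoods(d_t, d_n, m, params)
    return float(np.log(p).sum())


def _em_run(d_t, d_n, m, start: MixtureParams, config: FitConfig):
    """Single EM run from one start; returns (params, loglik, iters, converged)."""
    alpha, beta, kappa = start.p_target, start.p_nontarget, start.kappa
    gamma = 1.0 - alpha - beta
    ll_prev = -math.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        params = MixtureParams(kappa, alpha, beta, max(gamma, 0.0))
        p, f_t, f_n = _trial_likelihoods(d_t, d_n, m, params)
        ll = float(np.log(p).sum())
        if ll < ll_prev - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased ({ll_prev} -> {ll}) at iteration {it}"
            )
        if abs(ll - ll_prev) < config.tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        # E-step: component responsibilities
        r_t = alpha * f_t / p
        if m:
            r_n = (beta / m) * f_n / p[:, None]
            r_n_tot = r_n.sum(axis=1)
        else:
            r_n_tot = np.zeros_like(r_t)
        # M-step: probabilities are mean responsibilities
        alpha = float(r_t.mean())
        beta = float(r_n_tot.mean()) if m else 0.0
        gamma = max(1.0 - alpha - beta, 0.0)
        total = alpha + beta + gamma
        alpha, beta, gamma = alpha / total, beta / total, gamma / total
        # kappa from the responsibility-weighted resultant of component-aligned
        # errors; the component means are fixed at zero, so the sufficient
        # statistic is the cosine moment (not the full resultant length)
        c = float((r_t * np.cos(d_t)).sum())
        if m:
            c += float((r_n * np.cos(d_n)).sum())
        w = float(r_t.sum() + (r_n.sum() if m else 0.0))
        if w > 1e-12:
            rbar = min(max(c / w, 0.0), 1.0)
            kappa = _a1inv(rbar, config.kappa_max)
    params = MixtureParams(kappa, alpha, beta, max(1.0 - alpha - beta, 0.0))
    return params, ll_prev, it, converged


def _moment_start(d_t, m) -> MixtureParams:
    """Method-of-moments start: kappa from the all-target cosine moment."""
    rbar = max(float(np.cos(d_t).mean()), 0.0)
    kappa0 = _a1inv(rbar)
    if m:
        return MixtureParams(kappa0, 0.6, 0.2, 0.2)
    return MixtureParams(kappa0, 0.6, 0.0, 0.4)


def _random_start(rng, m) -> MixtureParams:
    w = rng.dirichlet(np.ones(3 if m else 2))
    kappa0 = float(np.exp(rng.uniform(math.log(0.5), math.log(100.0))))
    if m:
        return MixtureParams(kappa0, w[0], w[1], w[2])
    return MixtureParams(kappa0, w[0], 0.0, w[1])


def fit_em(trials, config: FitConfig | None = None) -> MixtureFit:
    """Maximum-likelihood mixture fit by expectation-maximization.

    Runs EM from a method-of-moments start plus random restarts and
    returns the best-likelihood solution. The log-likelihood is checked to
    be non-decreasing within every run. Non-convergence is reported via
    ``converged=False`` rather than raised.
    """
    config = config or FitConfig()
    targets, nontargets, responses, m = trials_to_arrays(trials)
    if responses is None:
        raise InvalidParamsError("trials must carry responses")
    n = targets.size
    if n < config.min_trials:
        raise InvalidParamsError(
            f"need >= {config.min_trials} trials to fit, got {n}"
        )
    d_t = responses - targets
    d_n = responses[:, None] - nontargets

    rng = np.random.default_rng(config.restart_seed)
    starts = [_moment_start(d_t, m)]
    starts += [_random_start(rng, m) for _ in range(config.n_random_restarts)]

    best = None
    for start in starts:
        try:
            params, ll, iters, conv = _em_run(d_t, d_n, m, start, config)
        except (FloatingPointError, ZeroDivisionError):  # degenerate start
            continue
        if best is None or ll > best[1]:
            best = (params, ll, iters, conv)
    if best is None:
        raise RuntimeError("all EM restarts failed")
    params, ll, iters, conv = best
    # kappa is unidentifiable when the data are essentially uniform: either
    # the von Mises components carry almost no mass, or the fit improves on
    # the pure-uniform log-likelihood by less than a trivial margin (a
    # near-zero-kappa solution with large weights is the same flat density)
    ll_uniform = -n * math.log(_TWO_PI)
    identifiable = (
        (params.p_target + params.p_nontarget) >= config.identifiability_floor
        and (ll - ll_uniform) > 2.0
    )
    return MixtureFit(
        params=params,
        log_likelihood=ll,
        n_iterations=iters,
        converged=conv,
        n_restarts_used=len(starts),
        kappa_identifiable=identifiable,
    )


def grid_oracle_fit(trials, kappa_grid, alpha_grid, beta_grid=None) -> MixtureFit:
    """Brute-force likelihood maximization over a parameter grid.

    Exhaustively evaluates :func:`mixture_loglik` at every grid point with
    ``alpha + beta <= 1`` and returns the arg-max. Intended as an
    independent oracle for the EM fitter on small datasets.
    """
    targets, nontargets, responses, m = trials_to_arrays(trials)
    if responses is None:
        raise InvalidParamsError("trials must carry responses")
    kappas = list(kappa_grid)
    alphas = list(alpha_grid)
    betas = [0.0] if (beta_grid is None or m == 0) else list(beta_grid)
    if not kappas or not alphas or not betas:
        raise InvalidParamsError("grid must be non-empty")
    d_t = responses - targets
    d_n = responses[:, None] - nontargets
    best_ll = -math.inf
    best_params = None
    for kappa in kappas:
        for alpha in alphas:
            for beta in betas:
                if alpha + beta > 1.0 + 1e-12:
                    continue
                gamma = max(1.0 - alpha - beta, 0.0)
                params = MixtureParams(kappa, alpha, beta, gamma)
                p, _, _ = _trial_likelihoods(d_t, d_n, m, params)
                ll = float(np.log(p).sum())
                if ll > best_ll:
                    best_ll = ll
                    best_params = params
    if best_params is None:
        raise InvalidParamsError("grid contained no valid parameter combination")
    return MixtureFit(
        params=best_params,
        log_likelihood=best_ll,
        n_iterations=0,
        converged=True,
        n_restarts_used=0,
    )


def simulate_responses(params: MixtureParams, geometries, seed: int):
    """Draw responses from the mixture for response-less trial geometries.

    Each response is, with probability ``p_target``, a von Mises deviate
    about the target; with ``p_nontarget``, about a uniformly chosen
    non-target; otherwise uniform on the circle. Deterministic given
    ``seed``. Returns new :class:`TrialGeometry` objects with responses.
    """
    targets, nontargets, responses, m = trials_to_arrays(geometries)
    if responses is not None:
        raise InvalidParamsError("geometries must not already carry responses")
    if m == 0 and params.p_nontarget > 0:
        raise InvalidParamsError("p_nontarget must be 0 when trials have no non-targets")
    rng = np.random.default_rng(seed)
    n = targets.size
    u = rng.random(n)
    is_target = u < params.p_target
    is_nontarget = (~is_target) & (u < params.p_target + params.p_nontarget)
    means = targets.copy()
    if m:
        pick = rng.integers(0, m, size=n)
        means[is_nontarget] = nontargets[np.arange(n), pick][is_nontarget]
    noise = rng.vonmises(0.0, max(params.kappa, 0.0), size=n)
    resp = (means + noise) % _TWO_PI
    uniform = rng.uniform(0.0, _TWO_PI, size=n)
    is_uniform = ~(is_target | is_nontarget)
    resp[is_uniform] = uniform[is_uniform]
    return [
        replace(g, response=float(r)) for g, r in zip(geometries, resp)
    ]
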