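"""Point-process simulators of cardiovascular variability.

Three scenarios:

1. *Uncoupled renewal / HDIG pairs* — independent point processes with
   exponential, Gaussian, inverse-Gaussian or history-dependent
   inverse-Gaussian (HDIG) inter-event intervals, used to measure the
   small-sample bias of the MIR estimator (true MIR = 0).
2. *Heartbeat -> pulse-arrival coupling* — the heartbeat process X follows the
   HDIG model: each interval w_i ~ IG(mean mu_i, shape lambda) with mu_i given
   by an AR(p) regression on past intervals whose poles place oscillations in
   the VLF/LF/HF bands of heart-period variability.  The pulse-arrival process
   is y_i = x_i + tau_i with AR(2) propagation delays tau_i of mean a0 = 300 ms
   oscillating at ~0.1 Hz; the delay SD sigma_PAT is *inversely* related to
   the X->Y coupling strength.
3. *Common LF driver* — X retains only VLF/HF HDIG dynamics and the same
   AR(2) LF process tau_i is injected both into the heartbeat intervals
   (w'_i = w_i + 2 tau_i) and into the delays (y_i = x_i + tau_i), so
   sigma_PAT acts as a *coupling* parameter.

The AR regressions act on deviations from the mean level (theta0, a0), so the
stationary means equal the stated values exactly while the poles, and hence
the spectra, are as specified.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from ._seeds import spawn_rng
from .events import EventSeries

__all__ = [
    "PoleSpec",
    "HDIGParams",
    "PATParams",
    "CARDIAC_POLES",
    "COMMON_DRIVER_POLES",
    "LF_POLES",
    "SIGMA_PAT_GRID",
    "ar_coeffs_from_poles",
    "simulate_renewal",
    "simulate_hdig",
    "calibrate_innovation_sd",
    "simulate_pat_process",
    "simulate_common_driver",
]

logger = logging.getLogger(__name__)

#: AR(5) pole set of the heartbeat-interval model: complex pairs at the LF
#: (modulus 0.8, phase +/-2*pi*0.1) and HF (0.92, +/-2*pi*0.25) bands plus a
#: real VLF pole 0.6.
CARDIAC_POLES = ((0.8, 2 * np.pi * 0.1), (0.92, 2 * np.pi * 0.25), 0.6)

#: AR(3) pole set of the common-driver heartbeat model: a real pole 0.92 and
#: the HF complex pair (0.92, +/-2*pi*0.25); the LF band is injected
#: separately through the shared delay process.
COMMON_DRIVER_POLES = (0.92, (0.92, 2 * np.pi * 0.25))

#: AR(2) pole pair of the pulse-arrival delay process (~0.1 Hz oscillation).
LF_POLES = ((0.8, 2 * np.pi * 0.1),)

#: Delay-SD grid, 10 to 235 ms in steps of 25 ms.
SIGMA_PAT_GRID = tuple(np.round(np.arange(0.010, 0.2351, 0.025), 3))


@dataclass(frozen=True)
class PoleSpec:
    """Transfer-function poles: real entries are signed moduli, 2-tuples
    (modulus rho, phase phi in rad) expand to complex-conjugate pairs."""

    poles: tuple

    def roots(self) -> np.ndarray:
        out: list[complex] = []
        for p in self.poles:
            if isinstance(p, (tuple, list)):
                rho, phi = p
                if abs(rho) >= 1:
                    raise ValueError(f"pole modulus {rho} not < 1")
                r = rho * np.exp(1j * phi)
                out.extend([r, np.conj(r)])
            else:
                if abs(p) >= 1:
                    raise ValueError(f"pole modulus {p} not < 1")
                out.append(complex(p))
        return np.asarray(out)


def ar_coeffs_from_poles(spec: PoleSpec | tuple | list) -> np.ndarray:
    """AR coefficients c_1..c_p whose characteristic polynomial has the given roots.

    For the recursion d_t = sum_j c_j d_{t-j} + e_t the characteristic
    polynomial is z^p - c_1 z^{p-1} - ... - c_p, so the coefficients are the
    negated non-leading coefficients of ``prod (z - root)``.
    """
    if not isinstance(spec, PoleSpec):
        spec = PoleSpec(tuple(spec))
    roots = spec.roots()
    poly = np.poly(roots)
    if np.max(np.abs(poly.imag)) > 1e-12:
        raise ValueError("poles must come in conjugate pairs")
    return -np.real(poly[1:])


@dataclass(frozen=True)
class HDIGParams:
    """History-dependent inverse-Gaussian interval model.

    Each interval w_i ~ IG(mean mu_i, shape lambda_shape) with
    mu_i = theta0 + sum_j theta_j (w_{i-j} - theta0); theta0 is the mean
    interval (s) and lambda_shape the IG shape (s).  theta defaults to the
    AR(5) cardiac pole set, giving VLF/LF/HF heart-period oscillations.
    """

    theta0: float = 1.0
    theta: np.ndarray = field(
        default_factory=lambda: ar_coeffs_from_poles(CARDIAC_POLES)
    )
    lambda_shape: float = 600.0

    def __post_init__(self) -> None:
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.lambda_shape <= 0:
            raise ValueError("lambda_shape must be > 0")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be > 0")
        if th.size and np.any(np.abs(np.roots(np.concatenate([[1.0], -th]))) >= 1):
            raise ValueError("AR polynomial is not stable")
        object.__setattr__(self, "theta", th)

    @property
    def p(self) -> int:
        return int(self.theta.size)


@dataclass(frozen=True)
class PATParams:
    """AR(2) pulse-arrival delay model: tau_i = a0 + AR(2) deviation.

    a0 is the mean delay (default 300 ms), (a1, a2) default to the LF pole
    pair (0.8, +/-2*pi*0.1) so delays oscillate at ~0.1 Hz, and sigma_pat is
    the target stationary SD of tau (s); the Gaussian innovation SD is
    derived from it in closed form.
    """

    sigma_pat: float
    a0: float = 0.3
    a1: float = float(ar_coeffs_from_poles(LF_POLES)[0])
    a2: float = float(ar_coeffs_from_poles(LF_POLES)[1])

    def __post_init__(self) -> None:
        if self.sigma_pat <= 0:
            raise ValueError("sigma_pat must be > 0")
        _check_ar2_stable(self.a1, self.a2)


def _check_ar2_stable(a1: float, a2: float) -> None:
    if not (abs(a2) < 1 and a2 + a1 < 1 and a2 - a1 < 1):
        raise ValueError(f"AR(2) coefficients (a1={a1}, a2={a2}) are not stationary")


# ---------------------------------------------------------------------------
# inverse-Gaussian sampling (Michael-Schucany-Haas transformation)


def _invgauss(
    rng: np.random.Generator, mean, shape: float, size=None
) -> np.ndarray | float:
    """IG(mean, shape) variates via the chi-square transformation with a
    uniform root choice; vectorized over ``mean``."""
    mean = np.asarray(mean, dtype=float)
    nu = rng.standard_normal(size if size is not None else mean.shape)
    y = nu * nu
    x = (
        mean
        + mean * mean * y / (2.0 * shape)
        - (mean / (2.0 * shape)) * np.sqrt(4.0 * mean * shape * y + (mean * y) ** 2)
    )
    u = rng.uniform(size=np.shape(x))
    out = np.where(u <= mean / (mean + x), x, mean * mean / x)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# scenario 1: renewal processes


def simulate_renewal(
    dist: str,
    n_events: int,
    seed: int | None = None,
    *,
    rate: float = 1.0,
    mu: float = 1.0,
    sigma: float = 0.2,
    lam: float = 600.0,
    t0: float = 0.0,
    label: str = "",
) -> EventSeries:
    """Renewal point process with i.i.d. inter-event intervals.

    dist : "exponential" (mean interval 1/rate, i.e. a Poisson process),
        "gaussian" (mean mu, SD sigma; draws resampled until positive) or
        "inverse_gaussian" (mean mu, shape lam).
    n_events : number of events; the series starts at ``t0`` (default 0) and
        contains n_events - 1 intervals.  Giving the two members of an
        uncoupled pair distinct origins avoids a shared t=0 timestamp, which
        would violate the no-simultaneous-events assumption.
    """
    if n_events < 2:
        raise ValueError("n_events must be >= 2")
    rng = spawn_rng(seed, 0)
    n_iv = n_events - 1
    if dist == "exponential":
        if rate <= 0:
            raise ValueError("rate must be > 0")
        w = rng.exponential(1.0 / rate, size=n_iv)
    elif dist == "gaussian":
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        w = rng.normal(mu, sigma, size=n_iv)
        n_resampled = 0
        while True:
            neg = w <= 0
            if not neg.any():
                break
            n_resampled += int(neg.sum())
            w[neg] = rng.normal(mu, sigma, size=int(neg.sum()))
        if n_resampled:
            logger.info(
                "gaussian renewal: resampled %d non-positive draws (%.1f%%)",
                n_resampled,
                100.0 * n_resampled / n_iv,
            )
    elif dist == "inverse_gaussian":
        if mu <= 0 or lam <= 0:
            raise ValueError("mu and lam must be > 0")
        w = _invgauss(rng, np.full(n_iv, mu), lam)
    else:
        raise ValueError(f"unknown distribution {dist!r}")
    times = t0 + np.concatenate([[0.0], np.cumsum(w)])
    return EventSeries(times=times, label=label or dist)


# ---------------------------------------------------------------------------
# scenario 2: HDIG heartbeat + AR(2) pulse-arrival delays


def _hdig_intervals(
    params: HDIGParams, n_intervals: int, rng: np.random.Generator, burn_in: int
) -> np.ndarray:
    th = params.theta
    p = th.size
    hist = np.full(p, params.theta0)  # hist[j-1] = w_{i-j}, most recent first
    out = np.empty(n_intervals + burn_in)
    floor = 0.1 * params.theta0
    n_clamped = 0
    for i in range(out.size):
        mu_i = params.theta0 + float(th @ (hist - params.theta0)) if p else params.theta0
        if mu_i <= 0:
            mu_i = floor
            n_clamped += 1
        w = float(_invgauss(rng, mu_i, params.lambda_shape))
        out[i] = w
        if p:
            hist[1:] = hist[:-1]
            hist[0] = w
    if n_clamped:
        logger.info("HDIG: clamped %d non-positive conditional means", n_clamped)
    return out[burn_in:]


def simulate_hdig(
    params: HDIGParams | None = None,
    n_events: int = 300,
    seed: int | None = None,
    burn_in: int = 200,
    t0: float = 0.0,
    label: str = "HDIG",
) -> EventSeries:
    """History-dependent inverse-Gaussian point process.

    Sequentially draws w_i ~ IG(mean mu_i, shape lambda) with mu_i from the
    AR regression on past intervals (deviations from theta0; history
    initialized at theta0).  ``burn_in`` warm-up intervals are discarded so
    the reported series is approximately stationary.
    """
    params = params or HDIGParams()
    if n_events < 2:
        raise ValueError("n_events must be >= 2")
    rng = spawn_rng(seed, 0)
    w = _hdig_intervals(params, n_events - 1, rng, burn_in)
    times = t0 + np.concatenate([[0.0], np.cumsum(w)])
    return EventSeries(times=times, label=label)


def calibrate_innovation_sd(a1: float, a2: float, sigma_pat: float) -> float:
    """Gaussian innovation SD giving a stationary AR(2) with SD ``sigma_pat``.

    Inverts the closed-form stationary variance of an AR(2):
    var(tau) = sigma_u^2 (1 - a2) / [(1 + a2)((1 - a2)^2 - a1^2)].
    """
    _check_ar2_stable(a1, a2)
    if sigma_pat <= 0:
        raise ValueError("sigma_pat must be > 0")
    factor = (1.0 + a2) * ((1.0 - a2) ** 2 - a1 * a1) / (1.0 - a2)
    if factor <= 0:
        raise ValueError("AR(2) coefficients give a non-positive variance factor")
    return float(sigma_pat * np.sqrt(factor))


def _ar2_deviations(
    params: PATParams, n: int, rng: np.random.Generator, burn_in: int
) -> np.ndarray:
    sd_u = calibrate_innovation_sd(params.a1, params.a2, params.sigma_pat)
    e = rng.normal(0.0, sd_u, size=n + burn_in)
    d = lfilter([1.0], [1.0, -params.a1, -params.a2], e)
    return d[burn_in:]


def _enforce_increasing(y: np.ndarray, on_violation: str, context: str) -> np.ndarray:
    """Handle strict-ordering violations of derived arrival times.

    "raise" (default) rejects the realization; "clip" minimally lifts each
    offending time to 1 ms past its predecessor (logged), which avoids the
    selection bias of discarding the large-delay-variability realizations
    that the top of the sigma_pat grid produces by construction.
    """
    bad = np.flatnonzero(np.diff(y) <= 0)
    if bad.size == 0:
        return y
    if on_violation == "raise":
        raise ValueError(
            f"{context}: arrival times are not strictly increasing for this "
            "realization (delay variability too large); pass "
            "on_violation='clip' to repair minimally"
        )
    if on_violation != "clip":
        raise ValueError("on_violation must be 'raise' or 'clip'")
    y = y.copy()
    n_clipped = 0
    for i in range(1, y.size):
        if y[i] <= y[i - 1]:
            y[i] = y[i - 1] + 1e-3
            n_clipped += 1
    logger.warning("%s: clipped %d non-increasing arrival times", context, n_clipped)
    return y


def simulate_pat_process(
    x: EventSeries,
    params: PATParams,
    seed: int | None = None,
    burn_in: int = 200,
    on_violation: str = "raise",
    label: str = "PAT",
) -> EventSeries:
    """Pulse-arrival process y_i = x_i + tau_i with AR(2) delays.

    tau_i = a0 + AR(2) deviation driven by Gaussian innovations whose SD is
    calibrated so SD(tau) = sigma_pat.  Non-positive delays are permitted
    (they occur by construction at the top of the sigma_pat grid) and only
    counted; a strict-ordering violation of y raises, or is minimally
    repaired with ``on_violation="clip"``.
    """
    rng = spawn_rng(seed, 0)
    tau = params.a0 + _ar2_deviations(params, x.n, rng, burn_in)
    n_nonpos = int(np.sum(tau <= 0))
    if n_nonpos:
        logger.info("PAT: %d of %d delays non-positive", n_nonpos, tau.size)
    y = _enforce_increasing(x.times + tau, on_violation, "PAT")
    return EventSeries(times=y, label=label)


# ---------------------------------------------------------------------------
# scenario 3: common LF driver


def simulate_common_driver(
    sigma_pat: float,
    n_events: int = 300,
    seed: int | None = None,
    *,
    theta0: float = 1.0,
    lambda_shape: float = 600.0,
    a0: float = 0.3,
    burn_in: int = 200,
    on_violation: str = "raise",
) -> tuple[EventSeries, EventSeries]:
    """Heartbeat and pulse-arrival processes sharing one LF driver.

    The heartbeat intervals follow an AR(3) HDIG model with VLF/HF poles only;
    the LF oscillation is injected by adding 2*tau_i to each interval, where
    tau_i is the *same* AR(2) delay realization used to place the pulse
    arrivals y_i = x_i + tau_i.  sigma_pat scales the shared component and
    therefore acts as a coupling parameter.  Non-positive composite intervals
    (rare large negative excursions of tau) are clamped at a 1 ms floor and
    counted.
    """
    if n_events < 2:
        raise ValueError("n_events must be >= 2")
    pat = PATParams(sigma_pat=sigma_pat, a0=a0)
    rng_tau = spawn_rng(seed, 0)
    rng_w = spawn_rng(seed, 1)
    tau = a0 + _ar2_deviations(pat, n_events, rng_tau, burn_in)
    hdig = HDIGParams(
        theta0=theta0,
        theta=ar_coeffs_from_poles(COMMON_DRIVER_POLES),
        lambda_shape=lambda_shape,
    )
    w = _hdig_intervals(hdig, n_events - 1, rng_w, burn_in)
    w_prime = w + 2.0 * tau[1:]
    n_clamped = int(np.sum(w_prime <= 0))
    if n_clamped:
        logger.info("common driver: clamped %d non-positive intervals", n_clamped)
        w_prime = np.maximum(w_prime, 1e-3)
    x_times = np.concatenate([[0.0], np.cumsum(w_prime)])
    y_times = _enforce_increasing(x_times + tau, on_violation, "common driver")
    x = EventSeries(times=x_times, label="X")
    y = EventSeries(times=y_times, label="Y")
    return x, y
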