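"""Per-slice binarization by a two-component beta mixture fitted with EM.

Model
-----
Within one 2D slice, each candidate pixel intensity y (rescaled to (0, 1))
is drawn from a mixture ``p0 * Beta(a0, b0) + (1 - p0) * Beta(a1, b1)``
with component 0 the background and component 1 the (brighter) signal.
The EM algorithm alternates posterior responsibilities (E-step) with
numerical maximization of the weighted beta log-likelihoods (M-step; there
is no closed form for the beta shape parameters). When two distinct
components are found, the binarization threshold is the intersection point
where the weighted component densities cross; otherwise the slice falls
back to a plain intensity-percentile threshold.

Candidate pixels are selected by a percentile pre-mask (default: keep the
top 1% of the slice) because the vast majority of pixels are background and
would otherwise swamp the signal component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import betaln, digamma
from scipy.stats import beta as beta_dist

logger = logging.getLogger(__name__)

_EPS = 1e-6
_LOG_BOUNDS = (np.log(1e-3), np.log(1e3))


# ---------------------------------------------------------------------------
# observations


@dataclass
class SliceObservation:
    """Candidate intensities of one (k, t) slice after pre-mask and rescale.

    ``values`` are the retained intensities min-max rescaled to [0, 1] and
    clamped to ``[eps, 1-eps]``; ``mask`` flags the retained pixels in the
    original 2D slice; ``raw_lo``/``raw_hi`` are the rescale endpoints (raw
    units) so thresholds can be mapped back onto raw intensities.
    """

    values: np.ndarray
    mask: np.ndarray
    raw: np.ndarray
    premask_value: float
    raw_lo: float
    raw_hi: float
    k: int = -1
    t: int = -1
    degenerate: bool = False


def premask_and_rescale(
    slice_: np.ndarray,
    premask_percentile: float = 99.0,
    eps: float = _EPS,
    k: int = -1,
    t: int = -1,
) -> SliceObservation:
    """Label the dim bulk of a slice background and rescale the rest to [0,1].

    Pixels strictly below the ``premask_percentile``-th percentile of the
    slice are labelled background and excluded from mixture fitting; the
    retained pixels are min-max rescaled to [0, 1] and clamped away from the
    endpoints (the beta density is unbounded or zero there).

    A constant slice, or a retained set with zero spread, yields a
    ``degenerate`` observation with an empty value vector.
    """
    raw = np.asarray(slice_, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={raw.ndim}")
    if not 0 <= premask_percentile <= 100:
        raise ValueError(f"premask_percentile must be in [0, 100], got {premask_percentile}")
    if raw.size == 0 or raw.max() == raw.min():
        return SliceObservation(
            values=np.empty(0),
            mask=np.zeros(raw.shape, dtype=bool),
            raw=raw,
            premask_value=float(raw.flat[0]) if raw.size else np.nan,
            raw_lo=np.nan,
            raw_hi=np.nan,
            k=k,
            t=t,
            degenerate=True,
        )
    cut = float(np.percentile(raw, premask_percentile))
    mask = raw >= cut
    vals = raw[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return SliceObservation(
            values=np.empty(0), mask=mask, raw=raw, premask_value=cut,
            raw_lo=lo, raw_hi=hi, k=k, t=t, degenerate=True,
        )
    values = np.clip((vals - lo) / (hi - lo), eps, 1.0 - eps)
    return SliceObservation(
        values=values, mask=mask, raw=raw, premask_value=cut,
        raw_lo=lo, raw_hi=hi, k=k, t=t,
    )


# ---------------------------------------------------------------------------
# mixture parameters


@dataclass
class BetaMixtureFit:
    """Fitted two-component beta mixture and the threshold derived from it.

    Component 1 is always the brighter component (larger mean a/(a+b)).
    ``threshold`` lives on the rescaled (0, 1) scale; ``threshold_raw`` is
    the same decision boundary in raw intensity units (+inf for a slice
    labelled entirely background).
    """

    alpha0: float
    beta0: float
    alpha1: float
    beta1: float
    p0: float
    loglik_trace: np.ndarray
    converged: bool
    n_components_detected: int
    threshold: float
    threshold_source: str  # "intersection" | "fallback_percentile"
    threshold_raw: float = np.nan
    n_iter: int = 0
    seed: int | None = None
    init_strategy: str = "random"

    @property
    def theta(self) -> tuple[float, float, float, float, float]:
        return (self.alpha0, self.beta0, self.alpha1, self.beta1, self.p0)

    @property
    def mean0(self) -> float:
        return self.alpha0 / (self.alpha0 + self.beta0)

    @property
    def mean1(self) -> float:
        return self.alpha1 / (self.alpha1 + self.beta1)


def beta_pdf(y, alpha: float, beta: float):
    """Beta density ``y**(a-1) * (1-y)**(b-1) / B(a, b)`` on (0, 1)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"beta shape parameters must be > 0, got ({alpha}, {beta})")
    return beta_dist.pdf(y, alpha, beta)


def _beta_logpdf(lny: np.ndarray, ln1my: np.ndarray, a: float, b: float) -> np.ndarray:
    return (a - 1.0) * lny + (b - 1.0) * ln1my - betaln(a, b)


def _component_logliks(values, theta):
    a0, b0, a1, b1, p0 = theta
    values = np.asarray(values, dtype=np.float64)
    lny = np.log(values)
    ln1my = np.log1p(-values)
    with np.errstate(divide="ignore"):
        la = np.log(p0) + _beta_logpdf(lny, ln1my, a0, b0)
        lb = np.log(1.0 - p0) + _beta_logpdf(lny, ln1my, a1, b1)
    return la, lb


def e_step(values, theta) -> np.ndarray:
    """Posterior responsibility of the bright component for each value.

    ``r1(y) = p1 f1(y) / (p0 f0(y) + p1 f1(y))``, computed in log space.
    """
    la, lb = _component_logliks(values, theta)
    den = np.logaddexp(la, lb)
    with np.errstate(invalid="ignore"):
        r1 = np.exp(lb - den)
    bad = ~np.isfinite(r1)
    if np.any(bad):
        logger.warning("e_step: %d degenerate densities, responsibility set to prior", bad.sum())
        r1 = np.where(bad, 1.0 - theta[4], r1)
    return r1


def loglik(values, theta) -> float:
    """Observed-data log-likelihood of the mixture."""
    la, lb = _component_logliks(values, theta)
    return float(np.logaddexp(la, lb).sum())


def _weighted_beta_mle(S1: float, S2: float, W: float, a_init: float, b_init: float):
    """Maximize the weighted beta log-likelihood over (log a, log b).

    The objective depends on the data only through the sufficient statistics
    ``S1 = sum w*log y``, ``S2 = sum w*log(1-y)``, ``W = sum w``, so each
    evaluation is O(1).
    """
    if W <= 0:
        return a_init, b_init, False

    def nll(u):
        a, b = np.exp(u)
        return -((a - 1.0) * S1 + (b - 1.0) * S2 - W * betaln(a, b))

    def grad(u):
        a, b = np.exp(u)
        da = S1 - W * (digamma(a) - digamma(a + b))
        db = S2 - W * (digamma(b) - digamma(a + b))
        return -np.array([da * a, db * b])

    x0 = np.clip(np.log([a_init, b_init]), *_LOG_BOUNDS)
    res = minimize(
        nll, x0, jac=grad, method="L-BFGS-B",
        bounds=[_LOG_BOUNDS, _LOG_BOUNDS],
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 200},
    )
    if res.fun > nll(x0):  # never accept a worse point than the previous iterate
        return a_init, b_init, False
    a, b = np.exp(res.x)
    return float(a), float(b), bool(res.success)


def m_step(values, responsibilities, theta):
    """One M-step: update p0 and the shape parameters of both components.

    ``p0`` becomes the mean class-0 responsibility; each component's (a, b)
    maximize its responsibility-weighted beta log-likelihood, initialized at
    the previous iterate. Guarantees ``Q(theta_new) >= Q(theta_old)``.
    """
    values = np.asarray(values, dtype=np.float64)
    r1 = np.asarray(responsibilities, dtype=np.float64)
    r0 = 1.0 - r1
    lny = np.log(values)
    ln1my = np.log1p(-values)
    p0 = float(r0.mean())
    a0, b0, _ = _weighted_beta_mle(r0 @ lny, r0 @ ln1my, r0.sum(), theta[0], theta[1])
    a1, b1, _ = _weighted_beta_mle(r1 @ lny, r1 @ ln1my, r1.sum(), theta[2], theta[3])
    return (a0, b0, a1, b1, p0)


# ---------------------------------------------------------------------------
# EM driver


def _initial_assignment(values, rng, strategy: str):
    n = len(values)
    if strategy == "random":
        z = rng.integers(0, 2, n).astype(bool)
    else:  # "split": threshold at a random central quantile; separates the init
        q = rng.uniform(30.0, 70.0)
        z = values >= np.percentile(values, q)
    if z.all() or not z.any():
        z[rng.integers(0, n)] = ~z[rng.integers(0, n)]
    return z


def _run_em(values, rng, strategy, max_iter, tol):
    lny = np.log(values)
    ln1my = np.log1p(-values)
    z = _initial_assignment(values, rng, strategy)
    r1 = z.astype(np.float64)
    r0 = 1.0 - r1
    p0 = float(r0.mean())
    a0, b0, _ = _weighted_beta_mle(r0 @ lny, r0 @ ln1my, r0.sum(), 2.0, 2.0)
    a1, b1, _ = _weighted_beta_mle(r1 @ lny, r1 @ ln1my, r1.sum(), 2.0, 2.0)
    theta = (a0, b0, a1, b1, p0)

    trace = []
    converged = False
    for _ in range(max_iter):
        r1 = e_step(values, theta)
        ll = loglik(values, theta)
        trace.append(ll)
        theta = m_step(values, r1, theta)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return theta, np.asarray(trace), converged


def _order_bright_second(theta):
    a0, b0, a1, b1, p0 = theta
    if a0 / (a0 + b0) > a1 / (a1 + b1):
        return (a1, b1, a0, b0, 1.0 - p0)
    return theta


def _is_collapsed(theta, collapse_delta, collapse_mean_tol) -> bool:
    a0, b0, a1, b1, p0 = theta
    if not (collapse_delta <= p0 <= 1.0 - collapse_delta):
        return True
    return abs(a1 / (a1 + b1) - a0 / (a0 + b0)) < collapse_mean_tol


def fit_two_beta_em(
    obs,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    fallback_percentile: float = 80.0,
    min_retained: int = 50,
    collapse_delta: float = 0.02,
    collapse_mean_tol: float = 0.02,
    n_restarts: int = 2,
) -> BetaMixtureFit:
    """Fit the two-component beta mixture to one slice's candidate values.

    The first attempt initializes by assigning every value to class 0 or 1
    uniformly at random. If that attempt collapses onto a single component
    (mixing weight outside ``[collapse_delta, 1-collapse_delta]``, component
    means closer than ``collapse_mean_tol``, or no convergence), further
    attempts re-initialize by splitting the values at a random central
    quantile, which starts the components separated. If no attempt yields
    two distinct components the slice is declared single-component and the
    threshold falls back to ``fallback_percentile``.

    ``obs`` may be a :class:`SliceObservation` or a bare array of values in
    (0, 1).
    """
    if isinstance(obs, SliceObservation):
        values = obs.values
        raw = obs.raw
        degenerate = obs.degenerate
    else:
        values = np.clip(np.asarray(obs, dtype=np.float64), _EPS, 1.0 - _EPS)
        raw = None
        degenerate = values.size > 0 and values.max() == values.min()
        obs = None

    def _fallback(theta, trace, converged, n_attempted_iters, strategy):
        if values.size:
            thr = float(np.percentile(values, fallback_percentile))
        else:
            thr = np.nan
        if raw is not None and raw.size and raw.max() > raw.min():
            # paper semantics: single-component slices are thresholded at the
            # fallback percentile of the whole slice's raw intensities
            thr_raw = float(np.percentile(raw, fallback_percentile))
            thr = thr_raw / 255.0
        elif raw is not None:
            thr_raw = np.inf  # constant slice: everything background
        else:
            thr_raw = np.nan
        a0, b0, a1, b1, p0 = theta
        return BetaMixtureFit(
            a0, b0, a1, b1, p0, trace, converged, 1, thr, "fallback_percentile",
            threshold_raw=thr_raw, n_iter=n_attempted_iters, seed=seed,
            init_strategy=strategy,
        )

    if degenerate or len(values) < min_retained:
        if not degenerate:
            logger.warning(
                "slice (k=%s, t=%s): only %d retained values (< %d); fallback threshold",
                getattr(obs, "k", None), getattr(obs, "t", None), len(values), min_retained,
            )
        return _fallback((np.nan,) * 5, np.empty(0), False, 0, "none")

    best = None
    for attempt in range(1 + n_restarts):
        strategy = "random" if attempt == 0 else "split"
        rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), attempt]))
        theta, trace, converged = _run_em(values, rng, strategy, max_iter, tol)
        theta = _order_bright_second(theta)
        collapsed = _is_collapsed(theta, collapse_delta, collapse_mean_tol)
        candidate = (theta, trace, converged, strategy, collapsed)
        if converged and not collapsed:
            best = candidate
            break
        if best is None:
            best = candidate

    theta, trace, converged, strategy, collapsed = best
    if collapsed or not converged:
        return _fallback(theta, trace, converged, len(trace), strategy)

    thr = intersect_threshold_theta(theta)
    if thr is None:
        logger.warning("no density intersection between component means; fallback threshold")
        return _fallback(theta, trace, converged, len(trace), strategy)

    if isinstance(obs, SliceObservation):
        thr_raw = obs.raw_lo + thr * (obs.raw_hi - obs.raw_lo)
    else:
        thr_raw = np.nan
    a0, b0, a1, b1, p0 = theta
    return BetaMixtureFit(
        a0, b0, a1, b1, p0, trace, converged, 2, float(thr), "intersection",
        threshold_raw=thr_raw, n_iter=len(trace), seed=seed, init_strategy=strategy,
    )


# ---------------------------------------------------------------------------
# threshold


def intersect_threshold_theta(theta, grid_size: int = 1024) -> float | None:
    """Root of ``p0 f0(y) - p1 f1(y)`` between the two component means.

    Sign changes are located on a dense grid over the open interval between
    the component means and refined by Brent's method; with several roots
    the one nearest the midpoint of the means is returned. ``None`` when no
    sign change exists in the interval.
    """
    a0, b0, a1, b1, p0 = theta
    m0 = a0 / (a0 + b0)
    m1 = a1 / (a1 + b1)
    lo, hi = sorted((m0, m1))
    if hi - lo < 1e-12 or not (0.0 < p0 < 1.0):
        return None

    def g(y):
        return p0 * beta_dist.pdf(y, a0, b0) - (1.0 - p0) * beta_dist.pdf(y, a1, b1)

    ys = np.linspace(lo, hi, grid_size)
    gs = g(ys)
    sign = np.sign(gs)
    changes = np.nonzero(np.diff(sign) != 0)[0]
    if len(changes) == 0:
        return None
    mid = 0.5 * (lo + hi)
    roots = []
    for i in changes:
        if gs[i] == 0.0:
            roots.append(ys[i])
            continue
        roots.append(brentq(g, ys[i], ys[i + 1], xtol=1e-14, rtol=8.9e-16))
    return float(min(roots, key=lambda r: abs(r - mid)))


def intersect_threshold(fit: BetaMixtureFit) -> float | None:
    """Density-intersection threshold of a fitted two-component mixture."""
    if fit.n_components_detected != 2:
        raise ValueError("intersection threshold requires a two-component fit")
    return intersect_threshold_theta(fit.theta)


# ---------------------------------------------------------------------------
# whole-stack binarization


@dataclass
class BinarizeParams:
    """Tunables of the per-slice binarization stage."""

    premask_percentile: float = 99.0
    fallback_percentile: float = 80.0
    min_retained: int = 50
    max_iter: int = 200
    tol: float = 1e-6
    eps: float = _EPS
    collapse_delta: float = 0.02
    collapse_mean_tol: float = 0.02
    n_restarts: int = 2


def _slice_seed(seed: int, k: int, t: int) -> int:
    return int(np.random.SeedSequence([abs(int(seed)), k, t]).generate_state(1)[0] % (2**31))


def _binarize_slice(slice_, params: BinarizeParams, seed: int, k: int, t: int):
    try:
        obs = premask_and_rescale(slice_, params.premask_percentile, params.eps, k=k, t=t)
        fit = fit_two_beta_em(
            obs,
            seed=_slice_seed(seed, k, t),
            max_iter=params.max_iter,
            tol=params.tol,
            fallback_percentile=params.fallback_percentile,
            min_retained=params.min_retained,
            collapse_delta=params.collapse_delta,
            collapse_mean_tol=params.collapse_mean_tol,
            n_restarts=params.n_restarts,
        )
        if np.isfinite(fit.threshold_raw):
            binary = (np.asarray(slice_, dtype=np.float64) >= fit.threshold_raw)
        else:
            binary = np.zeros(np.asarray(slice_).shape, dtype=bool)
        return binary.astype(np.uint8), fit, None
    except Exception as exc:  # never abort the stack for one bad slice
        logger.error("slice (k=%d, t=%d) failed: %s", k, t, exc)
        empty = np.zeros(np.asarray(slice_).shape, dtype=np.uint8)
        return empty, None, f"k={k},t={t}: {exc}"


def binarize_stack(stack, params: BinarizeParams | None = None, seed: int = 0, n_jobs: int = 1):
    """Binarize every (k, t) slice of a stack independently.

    Returns ``(binary, fits, errors)`` where ``binary`` is a uint8 array of
    the stack's shape with 1 = ROI, ``fits`` maps ``(k, t)`` to the slice's
    :class:`BetaMixtureFit` (or None on failure) and ``errors`` lists
    per-slice failures. Per-slice seeds are derived deterministically from
    ``(seed, k, t)`` so serial and parallel runs agree exactly.
    """
    params = params or BinarizeParams()
    data = stack.data if hasattr(stack, "voxel_size") else np.asarray(stack)
    I, J, K, T = data.shape
    slices = [(k, t) for t in range(T) for k in range(K)]

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_binarize_slice)(data[:, :, k, t], params, seed, k, t) for k, t in slices
        )
    else:
        results = [_binarize_slice(data[:, :, k, t], params, seed, k, t) for k, t in slices]

    binary = np.zeros(data.shape, dtype=np.uint8)
    fits = {}
    errors = []
    for (k, t), (b, fit, err) in zip(slices, results):
        binary[:, :, k, t] = b
        fits[(k, t)] = fit
        if err:
            errors.append(err)
    return binary, fits, errors
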