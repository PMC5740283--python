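"""Geographic cline models with exponential tails.

The centre of a cline is a sigmoid in signed transect distance x,

    p(x) = 1 / (1 + exp(-4 (x - c) / w)),

with centre c (where p = 0.5) and width w (inverse of the maximum slope).
Introgressed alleles beyond the centre are modelled by exponential tails:
on the left, for x < c - dL,

    p(x) = p(c - dL) * exp(4 tL (x - c + dL) / w),

and mirrored on the right, with tail offset d >= 0 (km from the centre to
where the tail takes over) and tail slope 0 < t <= 1.  Five variants are
fitted: no tail, left only, right only, mirror tails (shared d, t) and
both tails estimated separately.  Frequencies are fixed to 0 and 1 at the
cline ends.

Fitting maximizes a binomial (weighted-Bernoulli) likelihood with sample
size equal to the number of scored genotypes per locality, by bounded
derivative-free multistart optimization.  Models are compared by AICc
over the number of localities, and parameter uncertainty is summarized by
two-log-likelihood-unit profile support limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "VARIANTS",
    "PARAM_NAMES",
    "ClineData",
    "ClineModelFit",
    "SupportInterval",
    "cline_frequency",
    "negative_log_likelihood",
    "fit_cline",
    "select_model_aicc",
    "support_limits",
]

#: The five model variants, in fixed enumeration order.
VARIANTS: tuple[str, ...] = ("none", "left", "right", "mirror", "both")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "none": ("c", "w"),
    "left": ("c", "w", "deltaL", "tauL"),
    "right": ("c", "w", "deltaR", "tauR"),
    "mirror": ("c", "w", "delta", "tau"),
    "both": ("c", "w", "deltaL", "tauL", "deltaR", "tauR"),
}

_P_CLAMP = 1e-9


@dataclass
class ClineData:
    """Per-locality transect data: signed distance, hybrid index, and the
    effective binomial sample size (scored genotypes)."""

    x: np.ndarray
    h: np.ndarray
    n: np.ndarray
    locality_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if not (self.x.shape == self.h.shape == self.n.shape):
            raise ValueError("x, h, n must have equal length")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.h)):
            raise ValueError("non-finite transect data")
        if np.any((self.h < 0) | (self.h > 1)):
            raise ValueError("hybrid index outside [0, 1]")
        if np.any(self.n < 1):
            raise ValueError("every locality needs n >= 1 genotypes")

    @classmethod
    def from_transect(cls, points) -> "ClineData":
        pts = [p for p in points if p.h is not None and p.n_genotypes]
        return cls(
            np.array([p.distance for p in pts]),
            np.array([p.h for p in pts]),
            np.array([p.n_genotypes for p in pts]),
            tuple(p.locality_id for p in pts),
        )

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class SupportInterval:
    lower: float
    upper: float
    lower_open: bool = False   # True when the drop is not reached at the bound
    upper_open: bool = False


@dataclass
class ClineModelFit:
    variant: str
    params: dict[str, float]
    loglik: float
    n_free_parameters: int
    aicc: float
    delta_aicc: Optional[float] = None          # vs the best model, set by selection
    support: dict[str, SupportInterval] = field(default_factory=dict)

    @property
    def centre(self) -> float:
        return self.params["c"]

    @property
    def width(self) -> float:
        return self.params["w"]


def _check_params(theta: Sequence[float], variant: str) -> np.ndarray:
    names = PARAM_NAMES[variant]
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(names),):
        raise ValueError(f"variant {variant!r} takes parameters {names}")
    vals = dict(zip(names, theta))
    if vals["w"] <= 0:
        raise ValueError("width w must be positive")
    for nm, v in vals.items():
        if nm.startswith("delta") and v < 0:
            raise ValueError(f"{nm} must be >= 0")
        if nm.startswith("tau") and not 0 < v <= 1:
            raise ValueError(f"{nm} must be in (0, 1]")
    return theta


def _tails(variant: str, theta: np.ndarray):
    if variant == "none":
        return None, None
    if variant == "left":
        return (theta[2], theta[3]), None
    if variant == "right":
        return None, (theta[2], theta[3])
    if variant == "mirror":
        return (theta[2], theta[3]), (theta[2], theta[3])
    return (theta[2], theta[3]), (theta[4], theta[5])


def cline_frequency(x, theta: Sequence[float], variant: str = "none") -> np.ndarray:
    """Expected focal-allele frequency at signed distance(s) x."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    theta = _check_params(theta, variant)
    c, w = theta[0], theta[1]
    x = np.asarray(x, dtype=float)
    p = 1.0 / (1.0 + np.exp(np.clip(-4.0 * (x - c) / w, -700, 700)))
    left, right = _tails(variant, theta)
    # A tail describes introgressed alleles persisting BEYOND the sigmoid,
    # so its decay rate at the junction may not exceed the sigmoid's own:
    # the effective tail slope is capped at the junction slope ratio
    # (1 - pL on the left, pR on the right).  Without the cap a
    # zero-offset, slope-1 "tail" would degenerate into a faster-than-
    # sigmoid approach to the end frequencies.
    if left is not None:
        dL, tL = left
        xL = c - dL
        pL = 1.0 / (1.0 + np.exp(np.clip(-4.0 * (xL - c) / w, -700, 700)))
        tL = min(tL, 1.0 - pL)
        mask = x < xL
        p = np.where(mask, pL * np.exp(np.clip(4.0 * tL * (x - xL) / w, -700, 0)), p)
    if right is not None:
        dR, tR = right
        xR = c + dR
        pR = 1.0 / (1.0 + np.exp(np.clip(-4.0 * (xR - c) / w, -700, 700)))
        tR = min(tR, pR)
        mask = x > xR
        p = np.where(mask, 1.0 - (1.0 - pR) * np.exp(np.clip(-4.0 * tR * (x - xR) / w, -700, 0)), p)
    return p


def negative_log_likelihood(data: ClineData, theta: Sequence[float], variant: str = "none") -> float:
    """Binomial-error negative log-likelihood of the cline, with the
    observed hybrid index kept as a real fraction (weighted-Bernoulli
    form) and the expected frequency clamped away from 0 and 1."""
    p = np.clip(cline_frequency(data.x, theta, variant), _P_CLAMP, 1.0 - _P_CLAMP)
    return float(-np.sum(data.n * (data.h * np.log(p) + (1.0 - data.h) * np.log(1.0 - p))))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _bounds(data: ClineData, variant: str) -> list[tuple[float, float]]:
    xmin, xmax = float(data.x.min()), float(data.x.max())
    span = max(xmax - xmin, 1e-6)
    out = [(xmin, xmax), (span * 1e-3, 2.0 * span)]
    for nm in PARAM_NAMES[variant][2:]:
        out.append((0.0, span) if nm.startswith("delta") else (1e-6, 1.0))
    return out


def fit_cline(
    data: ClineData,
    variant: str = "none",
    restarts: int = 20,
    seed: int = 0,
    base_fit: Optional[ClineModelFit] = None,
) -> ClineModelFit:
    """Maximum-likelihood cline fit by bounded Powell search from
    ``restarts`` random start points drawn over data-driven boxes."""
    names = PARAM_NAMES[variant]
    K = len(names)
    if len(data) <= K:
        raise ValueError(f"variant {variant!r} has {K} parameters but only {len(data)} localities")
    bounds = _bounds(data, variant)
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)

    def _optimize(x0: np.ndarray):
        # simplex search on the box-projected objective: more robust than
        # coordinate-descent methods on the ridge that couples w with the
        # tail parameters
        return minimize(
            lambda t: negative_log_likelihood(data, np.clip(t, lo_b, hi_b), variant),
            x0,
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 4000, "adaptive": True},
        )

    starts = [np.array([(lo + hi) / 2 for lo, hi in bounds])]
    # data-driven start: crossing point of h = 0.5 and a width guess
    order = np.argsort(data.x)
    xs, hs = data.x[order], data.h[order]
    cross = np.nonzero(np.diff(np.signbit(hs - 0.5)))[0]
    c0 = float(xs[cross[0]]) if cross.size else float(np.median(xs))
    w0 = max((hi_b[0] - lo_b[0]) / 8.0, bounds[1][0])
    starts.append(np.array([c0, w0] + [(lo + hi) / 2 for lo, hi in bounds[2:]]))
    if K > 2:
        # tail variants: seed around the no-tail optimum so the narrow
        # (c, w) valley is found before the tail parameters are explored
        base = base_fit if base_fit is not None and base_fit.variant == "none" else \
            fit_cline(data, "none", restarts=max(restarts // 2, 4), seed=seed)
        cb, wb = base.params["c"], base.params["w"]
        # a tail absorbs part of the apparent width, so also try starts
        # with the sigmoid steeper than the no-tail fit suggests
        for w_frac, taus in ((1.0, (0.15, 0.5, 0.9)), (0.6, (0.15, 0.5))):
            for delta_frac in (0.1, 0.6, 1.5):
                for tau in taus:
                    extra = []
                    for nm in names[2:]:
                        extra.append(
                            min(delta_frac * wb, bounds[2][1])
                            if nm.startswith("delta") else tau
                        )
                    starts.append(
                        np.clip(np.array([cb, w_frac * wb, *extra]), lo_b, hi_b)
                    )
    for _ in range(restarts):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    for x0 in starts:
        res = _optimize(x0)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"no start converged for variant {variant!r}")
    best.x = np.clip(best.x, lo_b, hi_b)
    loglik = -float(best.fun)
    n = len(data)
    aicc = 2 * K - 2 * loglik + (2 * K * (K + 1)) / (n - K - 1) if n - K - 1 > 0 else np.inf
    return ClineModelFit(variant, dict(zip(names, map(float, best.x))), loglik, K, float(aicc))


def select_model_aicc(
    data: ClineData,
    restarts: int = 20,
    seed: int = 0,
    variants: Sequence[str] = VARIANTS,
) -> list[ClineModelFit]:
    """Fit all model variants and rank them by AICc (ascending).

    AICc = 2K - 2*loglik + 2K(K+1)/(n - K - 1) with n the number of
    localities.  Variants with n <= K + 1 are skipped with a warning.
    Each returned fit carries its AICc difference to the best model.
    """
    if len(data) < 6:
        raise ValueError("need at least 6 localities for model selection")
    fits = []
    base = None
    for i, variant in enumerate(variants):
        K = len(PARAM_NAMES[variant])
        if len(data) <= K + 1:
            warnings.warn(f"variant {variant!r} skipped: n={len(data)} <= K+1={K + 1}")
            continue
        fit = fit_cline(data, variant, restarts=restarts, seed=seed + i, base_fit=base)
        if variant == "none":
            base = fit
        fits.append(fit)
    fits.sort(key=lambda f: (f.aicc, f.n_free_parameters))
    for f in fits:
        f.delta_aicc = f.aicc - fits[0].aicc
    return fits


# ---------------------------------------------------------------------------
# support limits
# ---------------------------------------------------------------------------

def profile_interval(
    profile_nll: Callable[[float], float],
    mle_value: float,
    mle_nll: float,
    bounds: tuple[float, float],
    drop: float = 2.0,
    tol: float = 1e-3,
) -> SupportInterval:
    """Interval where the profiled log-likelihood stays within ``drop``
    units of its maximum, found by bisection on each side of the MLE.

    When the drop is not reached before a bound the limit is reported at
    the bound and flagged open-ended.
    """
    target = mle_nll + drop

    def g(v: float) -> float:
        return profile_nll(v) - target

    lo_b, hi_b = bounds
    out = {}
    for side, bound in (("lower", lo_b), ("upper", hi_b)):
        if g(bound) < 0:
            out[side] = (bound, True)
            continue
        a, b = (bound, mle_value) if side == "lower" else (mle_value, bound)
        # bisect for the sign change; g < 0 at the MLE, >= 0 at the bound
        lo, hi = (a, b) if side == "lower" else (b, a)
        # ensure lo is the "outside" end (g >= 0) and hi the inside (g < 0)
        while abs(hi - lo) > tol:
            mid = 0.5 * (lo + hi)
            if g(mid) >= 0:
                lo = mid
            else:
                hi = mid
        out[side] = (0.5 * (lo + hi), False)
    return SupportInterval(out["lower"][0], out["upper"][0],
                           out["lower"][1], out["upper"][1])


def support_limits(
    data: ClineData,
    fit: ClineModelFit,
    parameter: str,
    drop: float = 2.0,
    tol: float = 1e-3,
) -> SupportInterval:
    """Two-log-likelihood-unit support limits for one fitted parameter,
    profiling out the others by re-optimization from the MLE."""
    names = PARAM_NAMES[fit.variant]
    if parameter not in names:
        raise ValueError(f"parameter {parameter!r} not in variant {fit.variant!r}")
    idx = names.index(parameter)
    mle = np.array([fit.params[nm] for nm in names])
    dummy_bounds = _bounds(data, fit.variant)
    others = [i for i in range(len(names)) if i != idx]

    def profile_nll(value: float) -> float:
        if not others:
            theta = mle.copy()
            theta[idx] = value
            return negative_log_likelihood(data, theta, fit.variant)

        sub_lo = np.array([dummy_bounds[i][0] for i in others])
        sub_hi = np.array([dummy_bounds[i][1] for i in others])

        def obj(sub: np.ndarray) -> float:
            theta = mle.copy()
            theta[others] = np.clip(sub, sub_lo, sub_hi)
            theta[idx] = value
            return negative_log_likelihood(data, theta, fit.variant)

        res = minimize(
            obj,
            mle[others],
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 2000, "adaptive": True},
        )
        return float(res.fun)

    interval = profile_interval(
        profile_nll, float(mle[idx]), -fit.loglik, dummy_bounds[idx], drop=drop, tol=tol
    )
    fit.support[parameter] = interval
    return interval
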