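"""Closed-form equations for density-dependent cooperative (DDC) solid-phase binding.

A ligand in solution binds targets immobilized on beads.  Binding the first
target costs localization entropy; once localized, the ligand can engage
additional targets on the same surface patch with no further entropy loss, so
the effective affinity rises with the target surface density (TSD), here
represented by the ratio T/s of volumetric target concentration ``T`` (molar)
to packed-bead volume fraction ``s`` (dimensionless).

Three nested models are provided:

* ``langmuir`` — single-site mass action, rho = T/K_d.
* ``asymptotic_ddc`` — Poisson-distributed neighbouring targets, no ceiling on
  the number bound: rho = (T/K_nc) * exp(kappa_inf * T / s).
* ``complete_ddc`` — at most N targets bound per ligand (binomial occupancy):
  rho = (T/K_nc) * (1 + kappa*T/(N*s))**(N-1).

Here rho = f_B/(1 - f_B) is the bound/unbound ligand ratio and f_B the
fraction of ligand bound.  kappa (and kappa_inf) carry units of
(volume fraction) * M^-1 so that kappa*T/s is dimensionless.

All functions are pure and vectorized over ``T`` and ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "UM",
    "MODEL_NAMES",
    "BindingParams",
    "RetentionParams",
    "Condition",
    "DesignConstants",
    "rho_langmuir",
    "fraction_bound",
    "rho_asymptotic",
    "rho_complete",
    "rho_model",
    "rho_ctsd",
    "kc_from_params",
    "enhancement_factor",
    "retention",
    "loglog_slope",
    "has_inflection",
]

#: one micromolar, in molar units (the package works in molar throughout)
UM = 1e-6

MODEL_NAMES = ("langmuir", "asymptotic_ddc", "complete_ddc")


@dataclass(frozen=True)
class BindingParams:
    """Mechanistic binding parameters.

    Parameters
    ----------
    K_nc
        Non-cooperative dissociation constant (molar); governs binding of the
        first target and absorbs the localization-entropy cost.
    kappa
        Cooperativity constant of the complete model, (volume fraction)/M.
    kappa_inf
        Asymptotic cooperativity constant, same units as ``kappa``.
    N
        Maximum number of targets bound concurrently by one ligand.  Treated
        as a continuous effective parameter >= 1 (smooth cutoff).
    """

    K_nc: float
    kappa: float = 0.0
    kappa_inf: float = 0.0
    N: float = 1.0

    def __post_init__(self) -> None:
        if not self.K_nc > 0:
            raise ValueError(f"K_nc must be positive, got {self.K_nc}")
        if self.kappa < 0 or self.kappa_inf < 0:
            raise ValueError("cooperativity constants must be non-negative")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")


@dataclass(frozen=True)
class RetentionParams:
    """Assay nuisance parameters of the wash/retention step.

    ``b`` is the retained fraction of target-unbound ligand (background,
    e.g. sticking to the apparatus); ``r`` the retained fraction of
    target-bound ligand (r < 1 reflects loss of bound ligand during washes).
    """

    b: float = 0.0
    r: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0 and 0.0 <= self.r <= 1.0):
            raise ValueError(f"b and r must lie in [0, 1], got b={self.b}, r={self.r}")


@dataclass(frozen=True)
class Condition:
    """A single experimental condition (T, s).

    ``T`` is the volumetric target concentration in molar; ``s`` the fraction
    of reaction volume occupied by target-linked packed beads.  The target
    surface density is the ratio T/s.
    """

    T: float
    s: float

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.T > 0 and not self.s > 0:
            raise ValueError("s must be positive when T > 0")

    @property
    def tsd(self) -> float:
        return self.T / self.s


@dataclass(frozen=True)
class DesignConstants:
    """Constants shared by a VTSD/CTSD experiment pair.

    ``s_star`` is the fixed bead volume fraction of the VTSD design (0.06 for
    30 ul packed beads in 0.5 ml); ``T_star`` the highest target concentration,
    where the two designs coincide.  Under CTSD, s(T) = s_star * T / T_star.
    """

    s_star: float
    T_star: float

    def __post_init__(self) -> None:
        if not (self.s_star > 0 and self.T_star > 0):
            raise ValueError("s_star and T_star must be positive")

    def s_ctsd(self, T):
        """Bead volume fraction of target-linked beads along the CTSD dilution path."""
        return self.s_star * np.asarray(T, dtype=float) / self.T_star


# ---------------------------------------------------------------------------
# ratio / fraction primitives
# ---------------------------------------------------------------------------

def rho_langmuir(T, K_d: float):
    """Bound/unbound ligand ratio of single-site mass-action binding, T/K_d."""
    if not K_d > 0:
        raise ValueError(f"K_d must be positive, got {K_d}")
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be non-negative")
    return T / K_d


def fraction_bound(rho):
    """Convert a bound/unbound ratio rho into the bound fraction rho/(1+rho)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(rho), 1.0, rho / (1.0 + rho))
    return out


def _check_Ts(T, s):
    T = np.asarray(T, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), T.shape).copy() if np.ndim(s) == 0 else np.asarray(s, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be non-negative")
    if np.any((T > 0) & ~(s > 0)):
        raise ValueError("s must be positive wherever T > 0")
    return T, s


def rho_asymptotic(T, s, params: BindingParams):
    """Asymptotic-DDC bound/unbound ratio (T/K_nc) * exp(kappa_inf * T / s).

    Valid when the mean number of targets bound stays well below the ceiling
    N, i.e. at modest TSD.  Reduces to the Langmuir ratio as kappa_inf -> 0
    or T -> 0.
    """
    T, s = _check_Ts(T, s)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        x = np.where(T > 0, params.kappa_inf * T / np.where(s > 0, s, 1.0), 0.0)
        # overflow to inf is fine: fraction_bound maps inf to 1
        return (T / params.K_nc) * np.exp(x)


def rho_complete(T, s, params: BindingParams):
    """Complete-DDC bound/unbound ratio (T/K_nc) * (1 + kappa*T/(N*s))**(N-1).

    The exponent N-1 counts the up-to-N-1 additional targets beyond the first;
    the factor kappa*T/(N*s) is the per-slot statistical weight.  Approaches
    the asymptotic form as N -> infinity (with kappa_inf = kappa) and the
    Langmuir form when kappa = 0 or N = 1.
    """
    T, s = _check_Ts(T, s)
    N = params.N
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(T > 0, params.kappa * T / (N * np.where(s > 0, s, 1.0)), 0.0)
    return (T / params.K_nc) * np.power(1.0 + x, N - 1.0)


def rho_model(T, s, params: BindingParams, model: str):
    """Dispatch rho by model selector ('langmuir' | 'asymptotic_ddc' | 'complete_ddc')."""
    if model == "langmuir":
        return rho_langmuir(T, params.K_nc)
    if model == "asymptotic_ddc":
        return rho_asymptotic(T, s, params)
    if model == "complete_ddc":
        return rho_complete(T, s, params)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def rho_ctsd(T, params: BindingParams, consts: DesignConstants):
    """Complete-DDC ratio along the CTSD dilution path s = s_star * T / T_star.

    Substituting the path into the complete model cancels T from the TSD, so
    the result is exactly linear in T: rho = T / K_c with K_c given by
    :func:`kc_from_params`.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be non-negative")
    return T / kc_from_params(params, consts)


def enhancement_factor(params: BindingParams, consts: DesignConstants) -> float:
    """Affinity enhancement K_nc/K_c from constant high-TSD cooperative binding.

    Equals (1 + kappa*T_star/(N*s_star))**(N-1); 1 exactly when kappa = 0 or
    N = 1, and strictly increasing in kappa and in T_star/s_star otherwise.
    """
    x = params.kappa * consts.T_star / (params.N * consts.s_star)
    return float((1.0 + x) ** (params.N - 1.0))


def kc_from_params(params: BindingParams, consts: DesignConstants) -> float:
    """Cooperative dissociation constant K_c = K_nc / enhancement_factor.

    K_c is the effective Langmuir constant of a CTSD titration run at the
    maximal TSD T_star/s_star; K_c <= K_nc always.
    """
    return params.K_nc / enhancement_factor(params, consts)


def retention(T, s, params: BindingParams, ret: RetentionParams, model: str):
    """Retained ligand fraction after binding and washing.

    f_ret = b*(1 - f_B) + r*f_B, linear in the bound fraction f_B of the
    selected model; lies between min(b, r) and max(b, r).
    """
    f_B = fraction_bound(rho_model(T, s, params, model))
    return ret.b * (1.0 - f_B) + ret.r * f_B


# ---------------------------------------------------------------------------
# log-log slope and inflection analysis
# ---------------------------------------------------------------------------

def loglog_slope(T, s, params: BindingParams, model: str, design: str = "vtsd"):
    """Slope d ln(rho) / d ln(T) of the log-log ratio plot at fixed design.

    VTSD (s held fixed): 1 for Langmuir; 1 + kappa_inf*T/s (asymptotic,
    unbounded); 1 + (N-1)*c*T/(1+c*T) with c = kappa/(N*s) (complete, rising
    from 1 toward N).  CTSD: identically 1 for every model (rho is exactly
    proportional to T along the dilution path).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("log-log slope requires T > 0")
    if design.lower() == "ctsd":
        return np.ones_like(T)
    if design.lower() != "vtsd":
        raise ValueError(f"unknown design {design!r}")
    if model == "langmuir":
        return np.ones_like(T)
    if model == "asymptotic_ddc":
        return 1.0 + params.kappa_inf * T / s
    if model == "complete_ddc":
        c = params.kappa / (params.N * np.asarray(s, dtype=float))
        return 1.0 + (params.N - 1.0) * c * T / (1.0 + c * T)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def _log_rho_derivs(T: np.ndarray, s: float, params: BindingParams, model: str):
    """log of rho, rho', rho'' for the VTSD curve (all three are positive).

    Working in logs keeps the inflection analysis finite even where
    exp(kappa_inf*T/s) overflows.  Returns (log rho, log rho', log rho'');
    the complete model with N = 1 has rho'' = 0 and is handled by callers.
    """
    K = params.K_nc
    if model == "asymptotic_ddc":
        a = params.kappa_inf / s
        log_rho = np.log(T / K) + a * T
        log_d1 = a * T + np.log1p(a * T) - math.log(K)
        log_d2 = a * T + np.log(a * (2.0 + a * T)) - math.log(K)
        return log_rho, log_d1, log_d2
    if model == "complete_ddc":
        N = params.N
        c = params.kappa / (N * s)
        log1p_cT = np.log1p(c * T)
        log_rho = np.log(T / K) + (N - 1.0) * log1p_cT
        log_d1 = (N - 2.0) * log1p_cT + np.log1p(N * c * T) - math.log(K)
        # rho'' = c*(N-1)*(1+cT)^(N-3)*(2 + N*c*T) / K
        log_d2 = (
            math.log(c * (N - 1.0))
            + (N - 3.0) * log1p_cT
            + np.log(2.0 + N * c * T)
            - math.log(K)
        )
        return log_rho, log_d1, log_d2
    raise ValueError(f"inflection analysis is for DDC models, got {model!r}")


def _curvature_sign_fn(s: float, params: BindingParams, model: str):
    """Signed surrogate for f_B''(T): log(rho''*(1+rho)) - log(2*rho'^2).

    f_B'' = [rho''*(1+rho) - 2*rho'^2] / (1+rho)^3, so the sign of f_B'' is
    the sign of the returned difference of logs.
    """

    def g(T):
        T = np.asarray(T, dtype=float)
        log_rho, log_d1, log_d2 = _log_rho_derivs(T, s, params, model)
        pos = np.logaddexp(log_d2, log_d2 + log_rho)  # log(rho''*(1+rho))
        neg = math.log(2.0) + 2.0 * log_d1
        return pos - neg

    return g


def has_inflection(
    params: BindingParams,
    s_star: float,
    model: str,
    n_grid: int = 600,
) -> Tuple[bool, Optional[float]]:
    """Detect an inflection point of the VTSD binding curve f_B(T) on linear axes.

    Scans the sign of the second derivative of f_B over a log-spaced grid of
    T spanning 1e-6*K_nc to 1e6*K_nc and refines the bracketed sign change by
    root finding.  A Langmuir curve is concave everywhere (no inflection);
    strong cooperativity produces a convex region at low T and hence an
    inflection where the curve turns back to concave.  Weak cooperativity can
    raise affinity without ever producing an inflection.

    Returns ``(flag, T_inflection)`` with ``T_inflection`` the smallest root
    of f_B'' when the flag is set, else ``None``.
    """
    if model == "langmuir":
        return False, None
    if model not in ("asymptotic_ddc", "complete_ddc"):
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    if model == "asymptotic_ddc" and params.kappa_inf == 0.0:
        return False, None
    if model == "complete_ddc" and (params.kappa == 0.0 or params.N == 1.0):
        return False, None

    g = _curvature_sign_fn(s_star, params, model)
    T_grid = np.geomspace(1e-6 * params.K_nc, 1e6 * params.K_nc, n_grid)
    vals = g(T_grid)
    if not np.any(vals > 0):
        return False, None
    # first sign change bracket (convex region exists -> f_B'' crosses zero)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:  # positive over the whole grid: inflection beyond span
        return True, None
    lo, hi = T_grid[idx[0]], T_grid[idx[0] + 1]
    T_inf = brentq(lambda t: float(g(t)), lo, hi, xtol=1e-300, rtol=1e-12)
    return True, float(T_inf)
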