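"""Weighted nonlinear least-squares fitting of binding titrations.

Three estimators are provided, mirroring how solid-phase titrations are
analysed in practice:

* :func:`fit_langmuir_ctsd` — a Langmuir retention fit of a constant-TSD
  (CTSD) titration, estimating the cooperative dissociation constant K_c and
  the retention nuisance parameters b, r.
* :func:`fit_asymptotic_vtsd` — an asymptotic-DDC fit of a varying-TSD (VTSD)
  titration, estimating (K_nc, kappa_inf, b, r).
* :func:`fit_complete_joint` — the headline estimator: a simultaneous fit of
  a VTSD and a CTSD titration of the same ligand/target pair with one shared
  complete-DDC parameter set (K_nc, kappa, N, b, r).

All fits minimize sum_i w_i * (f_ret,i - model_i)^2 with weights from
:func:`weights_for`.  Optimization is multi-start bounded least squares
(scipy ``trf``) over a transformed parameter space: log for K and kappa
(positivity, scale), logit for b and r, linear for N in [1, 20].  Standard
errors come from the Gauss-Newton covariance at the optimum scaled by the
reduced chi-square.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .models import (
    BindingParams,
    DesignConstants,
    fraction_bound,
    kc_from_params,
    rho_asymptotic,
    rho_complete,
    rho_ctsd,
    rho_langmuir,
)

__all__ = [
    "TitrationPoint",
    "TitrationDataset",
    "FitResult",
    "weights_for",
    "fit_langmuir_ctsd",
    "fit_asymptotic_vtsd",
    "fit_complete_joint",
    "implied_kc",
]

_GEOMETRY_RTOL = 0.01  # designs must match their nominal geometry to 1%


@dataclass(frozen=True)
class TitrationPoint:
    """One measured titration point: condition (T, s) and retained fraction."""

    T: float
    s: float
    f_ret: float
    se: Optional[float] = None
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.f_ret < 0:
            raise ValueError("f_ret must be non-negative")
        if self.se is not None and not self.se > 0:
            raise ValueError("se must be positive when supplied")


@dataclass
class TitrationDataset:
    """A titration of one ligand against one immobilized target.

    ``design`` is 'VTSD' (bead amount fixed, TSD rises with T) or 'CTSD'
    (target-linked beads diluted with carrier beads, TSD constant).
    """

    design: str
    consts: DesignConstants
    points: List[TitrationPoint]
    ligand_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        self.design = self.design.upper()
        if self.design not in ("VTSD", "CTSD"):
            raise ValueError(f"design must be VTSD or CTSD, got {self.design!r}")
        self.validate_geometry()

    def validate_geometry(self) -> None:
        for i, p in enumerate(self.points):
            if self.design == "VTSD":
                if not math.isclose(p.s, self.consts.s_star, rel_tol=_GEOMETRY_RTOL):
                    raise ValueError(
                        f"VTSD point {i}: s={p.s} differs from s_star={self.consts.s_star} "
                        f"by more than {_GEOMETRY_RTOL:.0%}"
                    )
            else:
                s_expect = self.consts.s_star * p.T / self.consts.T_star
                ok = (p.T == 0 and p.s <= self.consts.s_star) or math.isclose(
                    p.s, s_expect, rel_tol=_GEOMETRY_RTOL
                )
                if not ok:
                    raise ValueError(
                        f"CTSD point {i}: s={p.s} is not proportional to T "
                        f"(expected {s_expect:.4g} at T={p.T:.4g})"
                    )

    @property
    def T(self) -> np.ndarray:
        return np.array([p.T for p in self.points])

    @property
    def s(self) -> np.ndarray:
        return np.array([p.s for p in self.points])

    @property
    def f_ret(self) -> np.ndarray:
        return np.array([p.f_ret for p in self.points])

    @property
    def se(self) -> Optional[np.ndarray]:
        if any(p.se is None for p in self.points):
            return None
        return np.array([p.se for p in self.points])

    def n_distinct_T(self) -> int:
        return np.unique(self.T).size


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one weighted fit."""

    model: str
    estimates: Dict[str, float]
    standard_errors: Dict[str, float]
    covariance: np.ndarray
    param_names: List[str]
    weighted_sse: float
    n_points: int
    n_free: int
    converged: bool
    n_restarts_used: int
    residuals: np.ndarray = field(repr=False, default=None)
    warnings: List[str] = field(default_factory=list)

    def nd_flags(self) -> Dict[str, bool]:
        """'not determined accurately': standard error > half the estimate."""
        return {
            k: bool(self.standard_errors.get(k, np.inf) > 0.5 * abs(v))
            for k, v in self.estimates.items()
        }

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "nd": self.nd_flags(),
            "covariance": np.asarray(self.covariance).tolist(),
            "param_names": self.param_names,
            "weighted_sse": self.weighted_sse,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def parameter_row(self) -> Dict[str, object]:
        """Flat table row: estimate and se per parameter, 'nd' when unreliable."""
        row: Dict[str, object] = {}
        nd = self.nd_flags()
        for k, v in self.estimates.items():
            row[k] = v
            row[f"{k}_se"] = "nd" if nd[k] else self.standard_errors[k]
        row["weighted_sse"] = self.weighted_sse
        row["converged"] = self.converged
        return row


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

def weights_for(
    points: Sequence[TitrationPoint],
    scheme: str = "auto",
    cv: float = 0.05,
    floor: float = 0.01,
) -> np.ndarray:
    """Per-point weights for the weighted least-squares objective.

    'supplied_se' uses w = 1/se^2 (inverse variance); 'proportional' assumes a
    constant coefficient of variation, w = 1/(cv*max(f_ret, floor))^2; 'uniform'
    gives every point weight 1.  'auto' picks supplied_se when every point has
    an se, else proportional.
    """
    if scheme == "auto":
        scheme = "supplied_se" if all(p.se is not None for p in points) else "proportional"
    if scheme == "supplied_se":
        if any(p.se is None for p in points):
            raise ValueError("supplied_se weighting requires an se on every point")
        se = np.array([p.se for p in points])
        return 1.0 / se**2
    if scheme == "proportional":
        f = np.array([p.f_ret for p in points])
        return 1.0 / (cv * np.maximum(f, floor)) ** 2
    if scheme == "uniform":
        return np.ones(len(points))
    raise ValueError(f"unknown weighting scheme {scheme!r}")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _logit(x: float) -> float:
    x = min(max(x, 1e-9), 1 - 1e-9)
    return math.log(x / (1 - x))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


_N_BOUNDS = (1.0, 20.0)


class _ParamSpec:
    """Maps a natural parameter to/from the unconstrained optimizer space."""

    def __init__(self, name: str, kind: str):
        self.name = name
        self.kind = kind  # 'log' | 'logit' | 'linear'

    def to_opt(self, x: float) -> float:
        if self.kind == "log":
            return math.log(x)
        if self.kind == "logit":
            return _logit(x)
        return x

    def from_opt(self, z: float) -> float:
        if self.kind == "log":
            return math.exp(z)
        if self.kind == "logit":
            return float(_sigmoid(z))
        return z

    def dnat_dopt(self, z: float) -> float:
        if self.kind == "log":
            return math.exp(z)
        if self.kind == "logit":
            s = float(_sigmoid(z))
            return s * (1 - s)
        return 1.0

    def bounds(self) -> Tuple[float, float]:
        if self.kind == "log":
            return (-60.0, 60.0)
        if self.kind == "logit":
            return (-20.0, 20.0)
        return _N_BOUNDS


# ---------------------------------------------------------------------------
# generic multi-start engine
# ---------------------------------------------------------------------------

def _run_fit(
    specs: List[_ParamSpec],
    model_fn: Callable[[Dict[str, float]], np.ndarray],
    y: np.ndarray,
    w: np.ndarray,
    starts_nat: List[Dict[str, float]],
    model_name: str,
) -> FitResult:
    sqrt_w = np.sqrt(w)

    def residual(z: np.ndarray) -> np.ndarray:
        nat = {sp.name: sp.from_opt(zi) for sp, zi in zip(specs, z)}
        return sqrt_w * (model_fn(nat) - y)

    lb = np.array([sp.bounds()[0] for sp in specs])
    ub = np.array([sp.bounds()[1] for sp in specs])

    best = None
    best_cost = np.inf
    n_used = 0
    for start in starts_nat:
        z0 = np.clip(
            [sp.to_opt(start[sp.name]) for sp in specs], lb + 1e-9, ub - 1e-9
        )
        try:
            sol = least_squares(
                residual, z0, bounds=(lb, ub), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        n_used += 1
        # strict improvement, ties broken by smaller parameter norm
        if sol.cost < best_cost * (1 - 1e-10) or (
            best is not None
            and abs(sol.cost - best_cost) <= 1e-10 * max(best_cost, 1.0)
            and np.linalg.norm(sol.x) < np.linalg.norm(best.x)
        ):
            best, best_cost = sol, sol.cost

    if best is None:
        raise RuntimeError("all optimizer starts failed")

    z = best.x
    nat = {sp.name: sp.from_opt(zi) for sp, zi in zip(specs, z)}
    n, p = y.size, len(specs)
    wsse = float(2.0 * best.cost)  # least_squares cost = 0.5*sum(res^2)

    # Gauss-Newton covariance in optimizer space, scaled by reduced chi-square
    J = best.jac
    dof = max(n - p, 1)
    s2 = wsse / dof
    JTJ = J.T @ J
    try:
        cov_z = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov_z = np.linalg.pinv(JTJ) * s2
    D = np.diag([sp.dnat_dopt(zi) for sp, zi in zip(specs, z)])
    cov_nat = D @ cov_z @ D
    cov_nat = 0.5 * (cov_nat + cov_nat.T)
    se = {sp.name: float(np.sqrt(max(cov_nat[i, i], 0.0))) for i, sp in enumerate(specs)}

    warnings: List[str] = []
    for i, sp in enumerate(specs):
        if sp.kind == "linear" and (
            abs(z[i] - lb[i]) < 1e-6 or abs(z[i] - ub[i]) < 1e-6
        ):
            warnings.append(f"{sp.name} pinned at bound {sp.from_opt(z[i]):g}")

    return FitResult(
        model=model_name,
        estimates=nat,
        standard_errors=se,
        covariance=cov_nat,
        param_names=[sp.name for sp in specs],
        weighted_sse=wsse,
        n_points=n,
        n_free=p,
        converged=bool(best.status > 0),
        n_restarts_used=n_used,
        residuals=best.fun / np.where(sqrt_w > 0, sqrt_w, 1.0),
        warnings=warnings,
    )


def _retention_curve(f_B: np.ndarray, b: float, r: float) -> np.ndarray:
    return b * (1.0 - f_B) + r * f_B


def _init_b_r(f: np.ndarray, T: np.ndarray) -> Tuple[float, float]:
    b0 = float(np.clip(f[T == 0].mean() if np.any(T == 0) else f.min(), 1e-4, 0.5))
    r0 = float(np.clip(f.max(), b0 + 0.05, 0.999))
    return b0, r0


def _init_K(T: np.ndarray, f: np.ndarray, b0: float, r0: float) -> float:
    """Half-max heuristic: T where retention crosses midway between b and r."""
    mid = 0.5 * (b0 + r0)
    mask = T > 0
    if not np.any(mask):
        return 1e-6
    order = np.argsort(T[mask])
    Ts, fs = T[mask][order], f[mask][order]
    above = fs >= mid
    if above.any() and not above.all():
        i = int(np.argmax(above))
        return float(Ts[max(i, 0)])
    return float(np.median(Ts))


# ---------------------------------------------------------------------------
# public fit functions
# ---------------------------------------------------------------------------

def fit_langmuir_ctsd(
    data: TitrationDataset,
    weights: str = "auto",
    n_random_starts: int = 0,
    seed: int = 0,
) -> FitResult:
    """Langmuir fit of a CTSD titration: estimates (K_c, b, r).

    Along the CTSD dilution path the complete-DDC model is exactly Langmuir in
    T with constant K_c, so this fit is the model-agnostic way to measure the
    cooperative dissociation constant.
    """
    if data.design != "CTSD":
        raise ValueError("fit_langmuir_ctsd requires a CTSD dataset")
    if data.n_distinct_T() < 4:
        raise ValueError("need at least 4 distinct T values for a Langmuir fit")
    T, y = data.T, data.f_ret
    w = weights_for(data.points, weights)

    specs = [_ParamSpec("K_c", "log"), _ParamSpec("b", "logit"), _ParamSpec("r", "logit")]

    def model_fn(nat: Dict[str, float]) -> np.ndarray:
        f_B = fraction_bound(rho_langmuir(T, nat["K_c"]))
        return _retention_curve(f_B, nat["b"], nat["r"])

    b0, r0 = _init_b_r(y, T)
    K0 = _init_K(T, y, b0, r0)
    starts = [
        {"K_c": K0 * m, "b": b0, "r": r0} for m in (0.1, 1.0, 10.0)
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(
            {"K_c": K0 * 10 ** rng.uniform(-2, 2), "b": rng.uniform(0.001, 0.3),
             "r": rng.uniform(0.3, 0.99)}
        )
    return _run_fit(specs, model_fn, y, w, starts, "langmuir")


def fit_asymptotic_vtsd(
    data: TitrationDataset,
    weights: str = "auto",
    fix_kappa_inf: Optional[float] = None,
    n_random_starts: int = 0,
    seed: int = 0,
) -> FitResult:
    """Asymptotic-DDC fit of a VTSD titration: estimates (K_nc, kappa_inf, b, r).

    ``fix_kappa_inf=0`` constrains the model to Langmuir (nested-model check).
    """
    if data.design != "VTSD":
        raise ValueError("fit_asymptotic_vtsd requires a VTSD dataset")
    if data.n_distinct_T() < 5:
        raise ValueError("need at least 5 distinct T values for an asymptotic-DDC fit")
    T, y = data.T, data.f_ret
    s_star = data.consts.s_star
    w = weights_for(data.points, weights)

    specs = [_ParamSpec("K_nc", "log"), _ParamSpec("b", "logit"), _ParamSpec("r", "logit")]
    free_kappa = fix_kappa_inf is None
    if free_kappa:
        specs.insert(1, _ParamSpec("kappa_inf", "log"))

    def model_fn(nat: Dict[str, float]) -> np.ndarray:
        ki = nat["kappa_inf"] if free_kappa else fix_kappa_inf
        params = BindingParams(K_nc=nat["K_nc"], kappa_inf=ki)
        f_B = fraction_bound(rho_asymptotic(T, s_star, params))
        return _retention_curve(f_B, nat["b"], nat["r"])

    b0, r0 = _init_b_r(y, T)
    K0 = _init_K(T, y, b0, r0)
    k0 = s_star / max(T[T > 0].max(), 1e-12)  # unit cooperative load at T_max
    starts = []
    for mK in (0.2, 1.0, 5.0):
        if free_kappa:
            for mk in (0.2, 1.0, 5.0):
                starts.append({"K_nc": K0 * mK, "kappa_inf": k0 * mk, "b": b0, "r": r0})
        else:
            starts.append({"K_nc": K0 * mK, "b": b0, "r": r0})
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        st = {"K_nc": K0 * 10 ** rng.uniform(-2, 2), "b": rng.uniform(0.001, 0.3),
              "r": rng.uniform(0.3, 0.99)}
        if free_kappa:
            st["kappa_inf"] = k0 * 10 ** rng.uniform(-2, 2)
        starts.append(st)
    return _run_fit(specs, model_fn, y, w, starts, "asymptotic_ddc")


def fit_complete_joint(
    vtsd: TitrationDataset,
    ctsd: TitrationDataset,
    weights: str = "auto",
    fix_kappa: Optional[float] = None,
    n_random_starts: int = 0,
    seed: int = 0,
) -> FitResult:
    """Joint complete-DDC fit of a VTSD + CTSD pair with one shared parameter set.

    Estimates (K_nc, kappa, N, b, r); b and r are shared between the designs
    (same ligand, beads and wash protocol).  N is continuous in [1, 20]; a fit
    pinned at either bound is flagged in ``warnings``.  ``fix_kappa=0``
    collapses the model to a pooled Langmuir fit (nested-model check).
    """
    if vtsd.design != "VTSD" or ctsd.design != "CTSD":
        raise ValueError("fit_complete_joint takes (VTSD dataset, CTSD dataset)")
    c1, c2 = vtsd.consts, ctsd.consts
    if not (
        math.isclose(c1.s_star, c2.s_star, rel_tol=1e-6)
        and math.isclose(c1.T_star, c2.T_star, rel_tol=1e-6)
    ):
        raise ValueError("VTSD and CTSD datasets must share (s_star, T_star)")

    consts = c1
    T_v, y_v = vtsd.T, vtsd.f_ret
    T_c, y_c = ctsd.T, ctsd.f_ret
    y = np.concatenate([y_v, y_c])
    w = np.concatenate(
        [weights_for(vtsd.points, weights), weights_for(ctsd.points, weights)]
    )
    n_v = T_v.size

    free_kappa = fix_kappa is None
    specs = [_ParamSpec("K_nc", "log")]
    if free_kappa:
        specs += [_ParamSpec("kappa", "log"), _ParamSpec("N", "linear")]
    specs += [_ParamSpec("b", "logit"), _ParamSpec("r", "logit")]

    def model_fn(nat: Dict[str, float]) -> np.ndarray:
        kappa = nat["kappa"] if free_kappa else fix_kappa
        N = nat.get("N", 1.0) if free_kappa else 1.0
        params = BindingParams(K_nc=nat["K_nc"], kappa=kappa, N=max(N, 1.0))
        f_B_v = fraction_bound(rho_complete(T_v, consts.s_star, params))
        f_B_c = fraction_bound(rho_ctsd(T_c, params, consts))
        f_B = np.concatenate([f_B_v, f_B_c])
        return _retention_curve(f_B, nat["b"], nat["r"])

    b0, r0 = _init_b_r(y, np.concatenate([T_v, T_c]))
    K0 = _init_K(T_v, y_v, b0, r0)
    k0 = consts.s_star / consts.T_star  # unit load at (T*, s*)
    starts = []
    if free_kappa:
        for mK in (0.3, 1.0, 10.0):
            for mk in (1.0, 5.0, 25.0):
                for N0 in (2.0, 4.0, 8.0):
                    starts.append(
                        {"K_nc": K0 * mK, "kappa": k0 * mk * N0, "N": N0, "b": b0, "r": r0}
                    )
    else:
        for mK in (0.2, 1.0, 5.0):
            starts.append({"K_nc": K0 * mK, "b": b0, "r": r0})
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        st = {"K_nc": K0 * 10 ** rng.uniform(-2, 2), "b": rng.uniform(0.001, 0.3),
              "r": rng.uniform(0.3, 0.99)}
        if free_kappa:
            st["kappa"] = k0 * 10 ** rng.uniform(-0.5, 2.5)
            st["N"] = rng.uniform(1.5, 12.0)
        starts.append(st)

    result = _run_fit(specs, model_fn, y, w, starts, "complete_ddc")
    result.estimates.setdefault("N", 1.0) if not free_kappa else None
    return result


def implied_kc(result: FitResult, consts: DesignConstants) -> Tuple[float, float]:
    """K_c implied by a joint complete-DDC fit, with a delta-method standard error.

    Propagates the covariance of (K_nc, kappa, N) through kc_from_params via a
    numerical gradient on the fitted scale.
    """
    est = result.estimates
    params = BindingParams(K_nc=est["K_nc"], kappa=est["kappa"], N=est["N"])
    kc = kc_from_params(params, consts)

    names = result.param_names
    idx = {n: i for i, n in enumerate(names)}
    grad = np.zeros(len(names))
    base = np.array([est[n] for n in names])
    for pname in ("K_nc", "kappa", "N"):
        i = idx[pname]
        h = max(abs(base[i]) * 1e-6, 1e-12)
        for sgn, store in ((1, "hi"), (-1, "lo")):
            pert = dict(est)
            pert[pname] = base[i] + sgn * h
            p = BindingParams(
                K_nc=pert["K_nc"], kappa=pert["kappa"], N=max(pert["N"], 1.0)
            )
            val = kc_from_params(p, consts)
            if sgn == 1:
                hi = val
            else:
                lo = val
        grad[i] = (hi - lo) / (2 * h)
    var = float(grad @ np.asarray(result.covariance) @ grad)
    return float(kc), float(np.sqrt(max(var, 0.0)))
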