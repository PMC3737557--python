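"""Brute-force statistical-mechanics reference for the DDC closed forms.

The closed-form ratios in :mod:`ddcbind.models` are derived by summing a
partition function over the number of additional targets a surface-localized
ligand can reach.  This module recomputes that sum term by term:

    rho = (T / K_nc) * sum_m P(m) * (1 + w)**m

where ``P(m)`` is the prior probability that ``m`` additional targets are
reachable (Poisson for the asymptotic model, binomial with N-1 slots for the
complete model) and ``w`` is the statistical weight gained by binding one
additional target.  The Poisson sum converges to exp(lambda*w) and the
binomial sum to (1 + p*w)**(N-1), which is exactly how the closed forms are
validated: any transcription error in the models module would show up as a
disagreement with this direct enumeration.

Accumulation is done in log space so extreme weights cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .models import BindingParams, rho_asymptotic, rho_complete

__all__ = [
    "OccupancyModel",
    "rho_by_enumeration",
    "occupancy_distribution_bound",
    "oracle_sweep",
]

_TAIL_TOL = 1e-12


@dataclass(frozen=True)
class OccupancyModel:
    """Prior distribution of additional reachable targets, plus binding weight.

    kind='poisson': extras ~ Poisson(mean_extra); maps to the asymptotic model
    via mean_extra * weight = kappa_inf * T / s.
    kind='binomial': extras ~ Binomial(slots, p) with slots = N - 1; maps to
    the complete model via p * weight = kappa * T / (N * s).
    """

    kind: str
    weight: float
    mean_extra: Optional[float] = None
    slots: Optional[int] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "binomial"):
            raise ValueError(f"kind must be 'poisson' or 'binomial', got {self.kind!r}")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.kind == "poisson":
            if self.mean_extra is None or self.mean_extra < 0:
                raise ValueError("poisson occupancy requires mean_extra >= 0")
        else:
            if self.slots is None or self.slots < 0 or int(self.slots) != self.slots:
                raise ValueError("binomial occupancy requires integer slots >= 0")
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise ValueError("binomial occupancy requires p in [0, 1]")


def _log_weighted_terms(occ: OccupancyModel, n_max: Optional[int] = None) -> np.ndarray:
    """log of P(m)*(1+w)^m for m = 0..m_top, truncated adaptively for Poisson."""
    log1pw = np.log1p(occ.weight)
    if occ.kind == "binomial":
        k = int(occ.slots)
        m = np.arange(k + 1)
        if occ.p == 0.0:
            logpmf = np.where(m == 0, 0.0, -np.inf)
        elif occ.p == 1.0:
            logpmf = np.where(m == k, 0.0, -np.inf)
        else:
            logpmf = (
                gammaln(k + 1) - gammaln(m + 1) - gammaln(k - m + 1)
                + m * np.log(occ.p) + (k - m) * np.log1p(-occ.p)
            )
        return logpmf + m * log1pw

    lam = float(occ.mean_extra)
    if lam == 0.0:
        return np.array([0.0])
    # weighted Poisson terms are proportional to Poisson(lam*(1+w)) terms;
    # truncate where the weighted tail is negligible relative to the mass
    lam_w = lam * (1.0 + occ.weight)
    if n_max is None:
        n_max = int(np.ceil(lam_w + 12.0 * np.sqrt(lam_w) + 60.0))
    m = np.arange(n_max + 1)
    log_terms = -lam + m * (np.log(lam) + log1pw) - gammaln(m + 1)
    # tail check: next term relative to the accumulated sum
    total = logsumexp(log_terms)
    log_next = -lam + (n_max + 1) * (np.log(lam) + log1pw) - gammaln(n_max + 2)
    # crude geometric bound on the tail beyond n_max
    ratio = lam_w / (n_max + 2)
    if ratio >= 1.0 or np.exp(log_next - total) / (1.0 - ratio) > _TAIL_TOL:
        tail = np.exp(log_next - total) / max(1.0 - ratio, 1e-16)
        raise ValueError(
            f"Poisson truncation at n_max={n_max} leaves relative tail mass ~{tail:.3g} "
            f"above the {_TAIL_TOL} tolerance; increase n_max"
        )
    return log_terms


def rho_by_enumeration(
    T: float, K_nc: float, occ: OccupancyModel, n_max: Optional[int] = None
) -> float:
    """Bound/unbound ratio by direct summation of the occupancy partition function."""
    if not K_nc > 0:
        raise ValueError("K_nc must be positive")
    if T < 0:
        raise ValueError("T must be non-negative")
    log_terms = _log_weighted_terms(occ, n_max)
    return float(T / K_nc * np.exp(logsumexp(log_terms)))


def occupancy_distribution_bound(occ: OccupancyModel, n_max: Optional[int] = None):
    """Posterior distribution of total targets bound, for a target-bound ligand.

    Conditional on the ligand being bound at all, the number of *extra*
    targets engaged is the prior occupancy reweighted by the Boltzmann factor
    (1+w)^m and renormalized; the total bound is n = 1 + extras.  For the
    binomial prior this posterior is Binomial(slots, p*(1+w)/(1+p*w)); for the
    Poisson prior it is Poisson(lambda*(1+w)).  Returns ``(n, prob)`` arrays.
    """
    log_terms = _log_weighted_terms(occ, n_max)
    prob = np.exp(log_terms - logsumexp(log_terms))
    n = 1 + np.arange(prob.size)
    return n, prob


def oracle_sweep(seed: int, n_points: int = 1000) -> dict:
    """Randomized comparison of closed forms against enumeration.

    Draws parameter sets spanning T/K_nc in [1e-3, 1e3], dimensionless
    cooperative load kappa*T/s in [0, 20] and N in {1..8}, computes rho both
    ways for the asymptotic (Poisson) and complete (binomial) models, and
    returns the maximum relative deviation observed.
    """
    rng = np.random.default_rng(seed)
    max_dev_asym = 0.0
    max_dev_complete = 0.0
    K = 1e-6
    for _ in range(n_points):
        T = K * 10 ** rng.uniform(-3, 3)
        load = rng.uniform(0.0, 20.0)  # kappa*T/s, dimensionless
        N = int(rng.integers(1, 9))
        s = 0.06

        # asymptotic model: kappa_inf*T/s = load split arbitrarily into lam*w
        lam = 10 ** rng.uniform(-1, 1.5)
        w = load / lam
        p_asym = BindingParams(K_nc=K, kappa_inf=load * s / T)
        closed = float(rho_asymptotic(T, s, p_asym))
        enum = rho_by_enumeration(T, K, OccupancyModel("poisson", w, mean_extra=lam))
        max_dev_asym = max(max_dev_asym, abs(enum - closed) / closed)

        # complete model: kappa*T/(N*s) = p*w with slots = N-1
        p_slot = rng.uniform(0.05, 1.0)
        w_b = (load / N) / p_slot
        p_comp = BindingParams(K_nc=K, kappa=load * s / T, N=N)
        closed = float(rho_complete(T, s, p_comp))
        enum = rho_by_enumeration(
            T, K, OccupancyModel("binomial", w_b, slots=N - 1, p=p_slot)
        )
        max_dev_complete = max(max_dev_complete, abs(enum - closed) / closed)

    return {
        "n_points": n_points,
        "max_rel_dev_asymptotic": max_dev_asym,
        "max_rel_dev_complete": max_dev_complete,
        "max_rel_dev": max(max_dev_asym, max_dev_complete),
    }
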