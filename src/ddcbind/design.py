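"""Experiment-design utilities over the (T, s) plane.

Once a complete-DDC parameter set is in hand, binding can be predicted for
any combination of target concentration T and bead volume fraction s.  The
surface f_B(T, s) makes the design trade-off explicit: lowering s at fixed T
raises the target surface density and hence the cooperative enhancement of
(typically unwanted) non-specific binding.  The constant-T profile answers
the practical question "how many beads do I need before non-specific
cooperativity is tolerable?", and the selectivity ratio compares retention
of a specific against a non-specific ligand at one condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .models import (
    BindingParams,
    Condition,
    DesignConstants,
    RetentionParams,
    fraction_bound,
    retention,
    rho_complete,
)

__all__ = [
    "BindingSurface",
    "binding_surface",
    "constant_T_profile",
    "selectivity_ratio",
    "DEFAULT_T_AXIS",
    "DEFAULT_S_AXIS",
]

# log-spaced defaults covering the experimental envelope with margin:
# T in [1e-3, 1e2] uM, s in [1e-4, 0.3] volume fraction
DEFAULT_T_AXIS = np.geomspace(1e-9, 1e-4, 61)
DEFAULT_S_AXIS = np.geomspace(1e-4, 0.3, 41)


@dataclass(frozen=True)
class BindingSurface:
    """Gridded bound fraction f_B over (T, s), with the design trajectories.

    ``f_B[i, j]`` is the bound fraction at ``s_axis[i]``, ``T_axis[j]``.
    ``vtsd_path`` / ``ctsd_path`` give (T, s) along the two titration designs.
    """

    T_axis: np.ndarray
    s_axis: np.ndarray
    f_B: np.ndarray
    vtsd_path: Tuple[np.ndarray, np.ndarray]
    ctsd_path: Tuple[np.ndarray, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns T_molar, s_volfrac, f_B."""
        Tg, sg = np.meshgrid(self.T_axis, self.s_axis)
        return pd.DataFrame(
            {"T_molar": Tg.ravel(), "s_volfrac": sg.ravel(), "f_B": self.f_B.ravel()}
        )


def binding_surface(
    params: BindingParams,
    consts: DesignConstants,
    T_axis: Optional[np.ndarray] = None,
    s_axis: Optional[np.ndarray] = None,
) -> BindingSurface:
    """Evaluate the complete-DDC bound fraction on a (T, s) grid.

    The VTSD line (s = s_star) and CTSD line (s = s_star * T / T_star) are
    recorded so the two titration designs can be overlaid on the surface.
    """
    T_axis = DEFAULT_T_AXIS if T_axis is None else np.asarray(T_axis, dtype=float)
    s_axis = DEFAULT_S_AXIS if s_axis is None else np.asarray(s_axis, dtype=float)
    if np.any(T_axis <= 0) or np.any(s_axis <= 0):
        raise ValueError("surface axes must be strictly positive")

    Tg, sg = np.meshgrid(T_axis, s_axis)
    f_B = fraction_bound(rho_complete(Tg, sg, params))

    vtsd = (T_axis, np.full_like(T_axis, consts.s_star))
    ctsd = (T_axis, consts.s_ctsd(T_axis))
    return BindingSurface(T_axis=T_axis, s_axis=s_axis, f_B=f_B,
                          vtsd_path=vtsd, ctsd_path=ctsd)


def constant_T_profile(
    params: BindingParams,
    T: float,
    s_range: Optional[np.ndarray] = None,
    tolerance: Optional[float] = None,
) -> dict:
    """Bound fraction versus bead concentration s at fixed T.

    At fixed T the TSD falls as s rises, so f_B decreases monotonically
    toward the Langmuir value T/(T + K_nc).  When ``tolerance`` is given, the
    smallest s in the range at which f_B drops to or below it is reported
    (``s_tolerable``; None if the curve never gets that low) — a direct guide
    to choosing a bead concentration that caps cooperative enhancement of
    non-specific binding.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    if tolerance is not None and not (0.0 < tolerance < 1.0):
        raise ValueError("tolerance must lie in (0, 1)")
    s_range = DEFAULT_S_AXIS if s_range is None else np.asarray(s_range, dtype=float)
    if np.any(s_range <= 0):
        raise ValueError("s values must be positive")
    s_sorted = np.sort(s_range)
    f_B = fraction_bound(rho_complete(np.full_like(s_sorted, T), s_sorted, params))

    s_tolerable = None
    if tolerance is not None:
        ok = f_B <= tolerance
        if ok.any():
            s_tolerable = float(s_sorted[int(np.argmax(ok))])
    return {
        "s": s_sorted,
        "f_B": f_B,
        "s_tolerable": s_tolerable,
        "langmuir_floor": float(T / (T + params.K_nc)),
    }


def selectivity_ratio(
    specific: Tuple[BindingParams, RetentionParams],
    nonspecific: Tuple[BindingParams, RetentionParams],
    cond: Condition,
) -> float:
    """Ratio of retained fractions, specific over non-specific, at one condition.

    Selection enriches what survives the wash, so the ratio is taken on
    retained fractions (background b and wash retention r included) rather
    than raw bound fractions.  Cooperative enhancement of the non-specific
    ligand (larger kappa) strictly decreases the ratio.  Returns ``inf`` when
    the non-specific retention is exactly zero.
    """
    p_s, ret_s = specific
    p_n, ret_n = nonspecific
    top = float(retention(cond.T, cond.s, p_s, ret_s, "complete_ddc"))
    bot = float(retention(cond.T, cond.s, p_n, ret_n, "complete_ddc"))
    if bot == 0.0:
        return float("inf")
    return top / bot
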