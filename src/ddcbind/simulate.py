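"""Seeded synthetic titration generator.

Emulates the bench protocol the models describe: a fixed amount of
radiolabeled ligand incubated with 30 ul of packed target-linked beads in a
0.5 ml reaction (bead volume fraction s* = 0.06), target concentration
titrated log-spaced from 0.0024 to 50 uM.  VTSD titrations hold the bead
amount fixed; CTSD titrations dilute maximal-TSD beads with target-free
carrier beads so that s is proportional to T.

Retained fractions are computed from the complete-DDC retention curve and
perturbed with multiplicative (proportional) Gaussian noise by default, the
error structure expected of scintillation-count ratios.  Every dataset is
reproducible from its scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

from .fitting import TitrationDataset, TitrationPoint
from .models import (
    UM,
    BindingParams,
    DesignConstants,
    RetentionParams,
    retention,
)

__all__ = [
    "NoiseModel",
    "Scenario",
    "default_grid",
    "make_titration",
    "reference_scenarios",
    "REFERENCE_T_MIN",
    "REFERENCE_T_MAX",
]

#: titration span of the reference protocol, molar
REFERENCE_T_MIN = 0.0024 * UM
REFERENCE_T_MAX = 50.0 * UM

#: bead volume fraction of the reference protocol (30 ul packed beads / 0.5 ml)
REFERENCE_S_STAR = 30.0 / 500.0


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic retained fractions.

    'proportional': sd_i = hypot(cv * f_i, floor) — multiplicative noise with
    an absolute floor, the default for count-ratio data.
    'additive': sd_i = sd for every point.
    'counting': Poisson counting statistics at ``counts`` expected total
    counts per point.
    """

    scheme: str = "proportional"
    cv: float = 0.05
    sd: float = 0.01
    floor: float = 0.005
    counts: float = 1e4

    def __post_init__(self) -> None:
        if self.scheme not in ("proportional", "additive", "counting"):
            raise ValueError(f"unknown noise scheme {self.scheme!r}")
        if min(self.cv, self.sd, self.floor, self.counts) < 0:
            raise ValueError("noise parameters must be non-negative")

    def sd_for(self, f_clean: np.ndarray) -> np.ndarray:
        if self.scheme == "proportional":
            return np.hypot(self.cv * f_clean, self.floor)
        if self.scheme == "additive":
            return np.full_like(f_clean, self.sd)
        return np.sqrt(np.maximum(f_clean, 1e-12) / self.counts)


@dataclass(frozen=True)
class Scenario:
    """Complete description of a simulated experiment."""

    true_binding: BindingParams
    true_retention: RetentionParams
    consts: DesignConstants
    T_grid: np.ndarray
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.T_grid, dtype=float)
        if T.size == 0:
            raise ValueError("T_grid must not be empty")
        if np.any(T < 0):
            raise ValueError("T_grid must be non-negative")
        object.__setattr__(self, "T_grid", T)

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)


def default_grid(
    T_min: float, T_max: float, n: int, include_zero: bool = False
) -> np.ndarray:
    """Log-spaced titration grid inclusive of both endpoints.

    ``include_zero`` prepends a T = 0 (background) point, which is valid for
    retention but excluded from any log-log analysis.
    """
    if not (0 < T_min < T_max):
        raise ValueError("need 0 < T_min < T_max")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    grid = np.geomspace(T_min, T_max, n)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


def make_titration(scn: Scenario, design: str) -> TitrationDataset:
    """Generate one noisy titration dataset under the scenario's truth.

    The noise-free curve is the complete-DDC retention at s = s_star (VTSD)
    or s = s_star * T / T_star (CTSD); per-point standard errors recorded in
    the dataset match the noise model's sd, so downstream inverse-variance
    weighting is correctly calibrated.  Retained fractions are clipped to
    [0, 1.05]; the ceiling sits above 1 so near-saturation noise is not
    censored asymmetrically (which would bias r).
    """
    design = design.upper()
    if design not in ("VTSD", "CTSD"):
        raise ValueError(f"design must be VTSD or CTSD, got {design!r}")
    T = scn.T_grid
    if design == "VTSD":
        s = np.full_like(T, scn.consts.s_star)
    else:
        s = scn.consts.s_ctsd(T)

    f_clean = retention(T, s, scn.true_binding, scn.true_retention, "complete_ddc")
    sd = scn.noise.sd_for(f_clean)

    # independent substreams per design so VTSD/CTSD noise is uncorrelated
    rng = np.random.default_rng([scn.seed, 0 if design == "VTSD" else 1])
    if scn.noise.scheme == "counting":
        counts = scn.noise.counts
        f_noisy = rng.poisson(np.maximum(f_clean, 0.0) * counts) / counts
    else:
        f_noisy = f_clean + rng.normal(0.0, 1.0, size=T.size) * sd
    f_noisy = np.clip(f_noisy, 0.0, 1.05)

    points = [
        TitrationPoint(
            T=float(Ti), s=float(si), f_ret=float(fi),
            se=float(sdi) if sdi > 0 else None,  # noise-free points carry no se
        )
        for Ti, si, fi, sdi in zip(T, s, f_noisy, sd)
    ]
    return TitrationDataset(
        design=design,
        consts=scn.consts,
        points=points,
        ligand_id=scn.name or "sim",
        target_id="sim",
    )


def _preset(
    name: str,
    K_c_uM: float,
    enhancement: float,
    N: float = 4.0,
    b: float = 0.02,
    r: float = 0.8,
    n_points: int = 13,
) -> Scenario:
    """Build a preset from its cooperative constant and enhancement fold.

    kappa is solved from enhancement = (1 + kappa*T*/(N*s*))**(N-1) and
    K_nc = K_c * enhancement, so each preset is specified by the two
    quantities a titration actually pins down.
    """
    consts = DesignConstants(s_star=REFERENCE_S_STAR, T_star=REFERENCE_T_MAX)
    x = enhancement ** (1.0 / (N - 1.0)) - 1.0 if N > 1 else 0.0
    kappa = x * N * consts.s_star / consts.T_star
    K_nc = K_c_uM * UM * enhancement
    return Scenario(
        true_binding=BindingParams(K_nc=K_nc, kappa=kappa, kappa_inf=kappa, N=N),
        true_retention=RetentionParams(b=b, r=r),
        consts=consts,
        T_grid=default_grid(REFERENCE_T_MIN, REFERENCE_T_MAX, n_points),
        name=name,
    )


def reference_scenarios() -> Dict[str, Scenario]:
    """Six synthetic presets spanning the observed cooperativity regimes.

    The labels follow the ligand∘target naming of the motivating experiments
    (aptamers NS1/NS2 and library N70 against histone-tail peptides), but the
    parameter values are synthetic constructions: they are chosen to
    reproduce the qualitative regimes — N = 4 targets per ligand, cooperative
    K_c in the fraction-of-a-micromolar to low-micromolar range, enhancement
    folds from ~10 up to 600, and one weak-cooperativity case whose binding
    curve gains affinity yet shows no inflection point.
    """
    presets = {
        "ns1_h3c_like": _preset("ns1_h3c_like", K_c_uM=0.21, enhancement=600.0),
        "ns1_h3k4me3_like": _preset("ns1_h3k4me3_like", K_c_uM=1.0, enhancement=150.0),
        "ns2_h3c_like": _preset("ns2_h3c_like", K_c_uM=1.0, enhancement=10.0),
        "ns2_h3k4me3_like": _preset("ns2_h3k4me3_like", K_c_uM=1.6, enhancement=40.0),
        "n70_h3c_like": _preset("n70_h3c_like", K_c_uM=0.5, enhancement=100.0),
        "n70_h3k4me3_like": _preset("n70_h3k4me3_like", K_c_uM=1.2, enhancement=30.0),
    }
    return presets
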