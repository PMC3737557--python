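"""Parameter-recovery calibration of the joint complete-DDC estimator.

Simulates the reference experiment many times at known truth and measures how
well the joint fit recovers it: a titration with 13 log-spaced VTSD points
and 9 CTSD points over 0.0024-50 uM, proportional measurement noise at 3% cv,
truth N = 4 with a 100-fold cooperative enhancement (K_c = 0.5 uM).  For each
replicate the joint complete-DDC fit and an independent Langmuir fit of the
CTSD arm are compared; the Langmuir K_c should agree with the joint-fit
implied K_c within combined 2-sigma standard errors.
"""

from __future__ import annotations

import dataclasses
from typing import Dict

import numpy as np

from .fitting import fit_complete_joint, fit_langmuir_ctsd, implied_kc
from .models import kc_from_params
from .simulate import NoiseModel, default_grid, make_titration, reference_scenarios

__all__ = ["recovery_study"]

N_VTSD_POINTS = 13
N_CTSD_POINTS = 9
NOISE_CV = 0.03


def recovery_study(seed: int, n_seeds: int = 200) -> Dict[str, float]:
    """Run the seeded recovery study and summarize estimator performance.

    Returns medians of the relative errors of K_nc and of the implied K_c,
    the fraction of runs with N recovered within +-1 of the true 4, and the
    fraction where the Langmuir-on-CTSD K_c and the joint-fit implied K_c
    agree within 2 combined standard errors.
    """
    base = reference_scenarios()["n70_h3c_like"]  # N = 4, enhancement = 100
    noise = NoiseModel(scheme="proportional", cv=NOISE_CV, floor=0.0)
    truth = base.true_binding
    true_kc = kc_from_params(truth, base.consts)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n_seeds) >> 1]  # < 2**31

    rows = []
    for child in child_seeds:
        scn_v = dataclasses.replace(base, noise=noise, seed=child)
        scn_c = dataclasses.replace(
            scn_v, T_grid=default_grid(base.T_grid.min(), base.T_grid.max(),
                                       N_CTSD_POINTS)
        )
        vtsd = make_titration(scn_v, "VTSD")
        ctsd = make_titration(scn_c, "CTSD")

        joint = fit_complete_joint(vtsd, ctsd)
        kc, kc_se = implied_kc(joint, base.consts)
        lang = fit_langmuir_ctsd(ctsd)
        lkc = lang.estimates["K_c"]
        lkc_se = lang.standard_errors["K_c"]

        rows.append(
            (
                abs(joint.estimates["K_nc"] - truth.K_nc) / truth.K_nc,
                abs(kc - true_kc) / true_kc,
                abs(joint.estimates["N"] - truth.N) <= 1.0,
                abs(kc - lkc) <= 2.0 * np.hypot(kc_se, lkc_se),
            )
        )
    arr = np.asarray(rows, dtype=float)
    return {
        "n_seeds": n_seeds,
        "median_rel_err_K_nc": float(np.median(arr[:, 0])),
        "median_rel_err_K_c": float(np.median(arr[:, 1])),
        "frac_N_within_1": float(arr[:, 2].mean()),
        "frac_kc_agreement": float(arr[:, 3].mean()),
    }
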