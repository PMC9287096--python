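"""Independent oracles, deliberately free of the package's term machinery.

Each risk equation is a *literal* transcription: plain arithmetic with the
same coefficient values as the packaged spec files, written out formula by
formula. The survival oracles are brute force: an Efron partial
log-likelihood evaluated on a 1-D grid, and explicit pair enumeration for
Harrell's C.
"""

from __future__ import annotations

import math

import numpy as np


def assign_risk_literal(
    sex, age, total_chol, hdl_chol, systolic_bp, cigarettes_per_day,
    diabetes, family_history_cvd, simd,
) -> float:
    if sex == "F":
        lp = (
            0.07203 * age
            + 0.12720 * total_chol
            - 0.52360 * hdl_chol
            + 0.01064 * systolic_bp
            + 0.02486 * cigarettes_per_day
            + 0.88450 * (1.0 if diabetes else 0.0)
            + 0.47750 * (1.0 if family_history_cvd else 0.0)
            + 0.09386 * (simd / 10.0)
        )
        return 1.0 - 0.9365 ** math.exp(lp - 4.90)
    lp = (
        0.05698 * age
        + 0.15580 * total_chol
        - 0.43470 * hdl_chol
        + 0.00954 * systolic_bp
        + 0.02005 * cigarettes_per_day
        + 0.66780 * (1.0 if diabetes else 0.0)
        + 0.27500 * (1.0 if family_history_cvd else 0.0)
        + 0.06296 * (simd / 10.0)
    )
    return 1.0 - 0.8831 ** math.exp(lp - 4.61)


def score2_risk_literal(
    sex, age, smoker, systolic_bp, diabetes, total_chol, hdl_chol
) -> float:
    cage = (age - 60.0) / 5.0
    csbp = (systolic_bp - 120.0) / 20.0
    ctchol = total_chol - 6.0
    chdl = (hdl_chol - 1.3) / 0.5
    smk = 1.0 if smoker else 0.0
    dm = 1.0 if diabetes else 0.0
    if sex == "F":
        lp = (
            0.4648 * cage
            + 0.7744 * smk
            + 0.3131 * csbp
            + 0.8096 * dm
            + 0.1002 * ctchol
            - 0.2606 * chdl
            - 0.1088 * smk * cage
            - 0.0277 * csbp * cage
            - 0.0226 * ctchol * cage
            + 0.0613 * chdl * cage
            - 0.1272 * dm * cage
        )
        return 1.0 - 0.9776 ** math.exp(lp)
    lp = (
        0.3742 * cage
        + 0.6012 * smk
        + 0.2777 * csbp
        + 0.6457 * dm
        + 0.1458 * ctchol
        - 0.2698 * chdl
        - 0.0755 * smk * cage
        - 0.0255 * csbp * cage
        - 0.0281 * ctchol * cage
        + 0.0426 * chdl * cage
        - 0.0983 * dm * cage
    )
    return 1.0 - 0.9605 ** math.exp(lp)


def pce_risk_literal(
    sex, age, total_chol_mgdl, hdl_chol_mgdl, systolic_bp, bp_treated,
    smoker, diabetes,
) -> float:
    la = math.log(age)
    lt = math.log(total_chol_mgdl)
    lh = math.log(hdl_chol_mgdl)
    ls = math.log(systolic_bp)
    smk = 1.0 if smoker else 0.0
    dm = 1.0 if diabetes else 0.0
    if sex == "F":
        lp = (
            -29.799 * la
            + 4.884 * la * la
            + 13.540 * lt
            - 3.114 * la * lt
            - 13.578 * lh
            + 3.149 * la * lh
            + (2.019 * ls if bp_treated else 1.957 * ls)
            + 7.574 * smk
            - 1.665 * la * smk
            + 0.661 * dm
        )
        return 1.0 - 0.9665 ** math.exp(lp - (-29.18))
    lp = (
        12.344 * la
        + 11.853 * lt
        - 2.664 * la * lt
        - 7.990 * lh
        + 1.769 * la * lh
        + (1.797 * ls if bp_treated else 1.764 * ls)
        + 7.837 * smk
        - 1.795 * la * smk
        + 0.658 * dm
    )
    return 1.0 - 0.9144 ** math.exp(lp - 61.18)


# ---------------------------------------------------------------------------
# survival oracles


def efron_partial_loglik(beta: float, times, status, x) -> float:
    """Cox partial log-likelihood with Efron tie handling, single covariate."""
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in np.unique(times[status == 1]):
        dead = (times == t) & (status == 1)
        at_risk = times >= t
        m = int(dead.sum())
        sum_r = float(np.exp(beta * x[at_risk]).sum())
        sum_d = float(np.exp(beta * x[dead]).sum())
        ll += beta * float(x[dead].sum())
        for ell in range(m):
            ll -= math.log(sum_r - (ell / m) * sum_d)
    return ll


def cox_beta_grid_search(times, status, x, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Argmax of the Efron partial likelihood on a dense 1-D grid."""
    grid = np.arange(lo, hi + step, step)
    vals = [efron_partial_loglik(b, times, status, x) for b in grid]
    return float(grid[int(np.argmax(vals))])


def harrell_c_enumeration(times, status, risks) -> float:
    """Harrell's C by explicit pair enumeration (risk ties count 1/2).

    A pair (i, j) is usable when the shorter time belongs to a subject whose
    event was observed; concordant when that subject had the higher risk.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    risks = np.asarray(risks, dtype=float)
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = times[i], times[j]
            if ti == tj:
                continue  # tied follow-up times: ordering undefined
            short, long_ = (i, j) if ti < tj else (j, i)
            if status[short] != 1:
                continue  # censored before the other: ordering unknown
            den += 1
            if risks[short] > risks[long_]:
                num += 1
            elif risks[short] == risks[long_]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den
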