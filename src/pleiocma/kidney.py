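"""Kidney-function phenotype algebra.

Estimated glomerular filtration rate (eGFR, mL/min/1.73 m^2) from serum
creatinine or cystatin C via the 2021 race-free CKD-EPI equations, and the
chronic kidney disease flag (eGFR below 60 mL/min/1.73 m^2).
"""

from __future__ import annotations

import numpy as np

__all__ = ["egfr_creatinine", "egfr_cystatin", "ckd_flag"]

# 2021 race-free CKD-EPI constants (creatinine in mg/dL, cystatin C in mg/L)
_CR_SCALE = 142.0
_CR_KAPPA = {"female": 0.7, "male": 0.9}
_CR_ALPHA = {"female": -0.241, "male": -0.302}
_CR_BETA = -1.200
_CR_AGE = 0.9938
_CR_FEMALE = 1.012

_CYS_SCALE = 133.0
_CYS_KAPPA = 0.8
_CYS_ALPHA = -0.499
_CYS_BETA = -1.328
_CYS_AGE = 0.996
_CYS_FEMALE = 0.932


def _female_mask(sex) -> np.ndarray:
    sex = np.asarray(sex)
    if sex.dtype.kind in "US O":
        return sex == "female"
    return sex.astype(bool)


def egfr_creatinine(scr, age, sex):
    """eGFR from serum creatinine (mg/dL), age (years) and sex.

    Implements the 2021 race-free CKD-EPI creatinine equation:
    ``142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200 * 0.9938^age * 1.012[female]``
    with k = 0.7 (female) / 0.9 (male) and a = -0.241 / -0.302.

    Accepts scalars or arrays; ``sex`` is ``"male"``/``"female"`` (or a
    boolean array, True = female).
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be strictly positive")
    female = _female_mask(sex)
    kappa = np.where(female, _CR_KAPPA["female"], _CR_KAPPA["male"])
    alpha = np.where(female, _CR_ALPHA["female"], _CR_ALPHA["male"])
    ratio = scr / kappa
    egfr = (
        _CR_SCALE
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** _CR_BETA
        * _CR_AGE**age
        * np.where(female, _CR_FEMALE, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def egfr_cystatin(scys, age, sex):
    """eGFR from serum cystatin C (mg/L), age (years) and sex.

    2021 race-free CKD-EPI cystatin C equation:
    ``133 * min(Scys/0.8, 1)^-0.499 * max(Scys/0.8, 1)^-1.328 * 0.996^age
    * 0.932[female]``.
    """
    scys = np.asarray(scys, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scys <= 0):
        raise ValueError("serum cystatin C must be strictly positive")
    female = _female_mask(sex)
    ratio = scys / _CYS_KAPPA
    egfr = (
        _CYS_SCALE
        * np.minimum(ratio, 1.0) ** _CYS_ALPHA
        * np.maximum(ratio, 1.0) ** _CYS_BETA
        * _CYS_AGE**age
        * np.where(female, _CYS_FEMALE, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def ckd_flag(egfr):
    """Chronic kidney disease indicator: eGFR strictly below 60 mL/min/1.73 m^2."""
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr < 0):
        raise ValueError("eGFR must be nonnegative")
    flag = egfr < 60.0
    return flag if flag.ndim else bool(flag)
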