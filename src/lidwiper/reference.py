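"""Normative-cohort reference values used as simulation defaults.

Population summary statistics of the four single-angular-frequency Zernike
coefficients of 5-mm corneal epithelial thickness maps in healthy adult
eyes (right-eye frame, ANSI-normalized basis, micrometres), from a 135-eye
/ 69-subject normative cohort (336 maps).  Only these four terms have
published population moments; all other coefficient variances default to
zero in simulations and are declared assumptions, not measurements.
"""

from __future__ import annotations

import numpy as np

from .zernike import ansi_index, n_terms

__all__ = [
    "TILT_COMA_MEANS_UM",
    "TILT_COMA_SDS_UM",
    "N_EYES",
    "N_SUBJECTS",
    "N_MAPS",
    "FIT_RMSE_MEAN_UM",
    "BASELINE_CENTRAL_THICKNESS_UM",
    "mean_coefficients",
    "coefficient_sds",
]

# (n, m) -> population mean / SD across eyes, um
TILT_COMA_MEANS_UM = {
    (1, -1): -1.13,  # Y-tilt
    (1, 1): 0.60,    # X-tilt
    (3, -1): 0.16,   # Y-coma
    (3, 1): -0.14,   # X-coma
}
TILT_COMA_SDS_UM = {
    (1, -1): 1.55,
    (1, 1): 0.76,
    (3, -1): 0.62,
    (3, 1): 0.38,
}

N_EYES = 135
N_SUBJECTS = 69
N_MAPS = 336
FIT_RMSE_MEAN_UM = 0.35

# Nominal central epithelial thickness; enters only through the piston term.
BASELINE_CENTRAL_THICKNESS_UM = 53.0


def mean_coefficients(
    central_thickness_um: float = BASELINE_CENTRAL_THICKNESS_UM,
    max_order: int = 5,
) -> np.ndarray:
    """Default 21-term mean coefficient vector (um): normative tilt/coma means,
    piston set to the nominal central thickness, everything else zero."""
    c = np.zeros(n_terms(max_order))
    c[0] = central_thickness_um
    for (n, m), mean in TILT_COMA_MEANS_UM.items():
        c[ansi_index(n, m).j] = mean
    return c


def coefficient_sds(max_order: int = 5) -> np.ndarray:
    """Default per-term between-eye SDs (um): normative values for tilt/coma,
    zero elsewhere."""
    s = np.zeros(n_terms(max_order))
    for (n, m), sd in TILT_COMA_SDS_UM.items():
        s[ansi_index(n, m).j] = sd
    return s
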