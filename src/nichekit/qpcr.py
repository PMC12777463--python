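"""Closed-form quantification utilities for qPCR and 3C readouts.

Relative expression by the delta-Cq rule assumes perfect doubling per PCR
cycle: a target amplifying three cycles later than the reference is present
at 2^-3 = 0.125 of its level. 3C interaction signals are normalized to the
same primer pair's signal on a BAC ligation library (PCR-efficiency
control) and, between samples, by a reference-locus ratio; both steps are
pure ratios, so their composition order is irrelevant.
"""

from __future__ import annotations

import numpy as np

from ._exceptions import ValidationError

__all__ = ["delta_cq", "normalize_3c"]


def _check_positive_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    if np.any(arr <= 0):
        raise ValidationError(f"{name} must be strictly positive")
    return arr


def delta_cq(cq_target, cq_reference):
    """Relative expression 2^-(Cq_target - Cq_reference).

    Accepts scalars or equally-shaped arrays of quantification cycles;
    returns a float for scalar input.
    """
    t = _check_positive_finite("cq_target", cq_target)
    r = _check_positive_finite("cq_reference", cq_reference)
    out = np.power(2.0, -(t - r))
    return float(out) if out.ndim == 0 else out


def normalize_3c(interaction_signal, bac_signal, sample_ref_signal, calibrator_ref_signal):
    """Normalized 3C interaction frequency.

    (interaction / BAC-library signal) scaled between samples by the
    calibrator/sample reference-locus ratio.
    """
    i = _check_positive_finite("interaction_signal", interaction_signal)
    b = _check_positive_finite("bac_signal", bac_signal)
    s = _check_positive_finite("sample_ref_signal", sample_ref_signal)
    c = _check_positive_finite("calibrator_ref_signal", calibrator_ref_signal)
    out = (i / b) * (c / s)
    return float(out) if out.ndim == 0 else out
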