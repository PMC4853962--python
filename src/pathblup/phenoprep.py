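"""Trait-specific preprocessing: angular transform for proportions and
plate-mean equalisation for assay batches."""
from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)


def arcsine_sqrt(p):
    """Angular (arcsine-square-root) transform asin(sqrt(p)) for proportions.

    The standard variance-stabilising transform for proportion data such as
    egg-to-adult viability.  Input must lie in [0, 1]; output is in [0, pi/2]
    radians and is monotone.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("arcsine_sqrt requires values in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def arcsine_squared(p):
    """Literal asin(p)^2 variant, offered for sensitivity checks only."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("arcsine_squared requires values in [0, 1]")
    out = np.arcsin(p) ** 2
    return float(out) if out.ndim == 0 else out


def plate_equalize(values, plate_labels):
    """Shift each plate's values so every plate mean equals the grand mean.

    Additive correction only: within-plate deviations and the overall grand
    mean are preserved exactly.  A single plate is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    plates = np.asarray(plate_labels)
    if len(values) != len(plates):
        raise ValueError("values and plate_labels must have equal length")
    uniq = np.unique(plates)
    if len(uniq) < 2:
        log.info("plate_equalize: single plate, returning values unchanged")
        return values.copy()
    grand = values.mean()
    out = values.copy()
    for plate in uniq:
        mask = plates == plate
        out[mask] += grand - values[mask].mean()
    return out
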