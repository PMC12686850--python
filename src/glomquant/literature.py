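"""Closed-form literature calculators.

Three small models connect whole-bulb glomerular counts and volumes to
the wider olfactory literature:

* **Abercrombie correction** for profile counts in sections of
  thickness T of objects with mean diameter d:
  ``Nv = N * T / (T + d)``, with N the measured (raw) density and Nv
  the corrected density. The inverse recovers raw counts from a
  published corrected estimate.
* **Glomeruli per odorant-receptor gene**: the glomerular count of a
  bulb divided by the number of intact OR genes in the mouse genome
  (1141 by default).
* **OSN-count linear model**: total glomerular volume (um^3) for the
  glomeruli of one OR gene as a function of the number of olfactory
  sensory neurons expressing it, ``y = 81.55 x + 168,700``.

Chained reproductions keep full precision through intermediates and
round only the final figure.
"""

from __future__ import annotations

__all__ = [
    "N_INTACT_OR_GENES",
    "OSN_MODEL_SLOPE",
    "OSN_MODEL_INTERCEPT",
    "abercrombie_correct",
    "abercrombie_invert",
    "abercrombie_factor",
    "glomeruli_per_or_gene",
    "total_volume_from_osn_count",
    "osn_count_from_total_volume",
    "total_volume_per_or",
]

#: intact odorant-receptor genes in the mouse genome
N_INTACT_OR_GENES = 1141

#: um^3 of glomerular volume per olfactory sensory neuron
OSN_MODEL_SLOPE = 81.55
#: um^3 baseline glomerular volume at zero OSNs
OSN_MODEL_INTERCEPT = 168_700.0


def abercrombie_factor(t: float, d: float) -> float:
    """Correction factor T/(T+d); in (0, 1] for T > 0, d >= 0."""
    if t <= 0:
        raise ValueError(f"section thickness must be positive, got {t}")
    if d < 0:
        raise ValueError(f"diameter must be non-negative, got {d}")
    return t / (t + d)


def abercrombie_correct(n_measured: float, t: float, d: float) -> float:
    """Corrected density Nv = N * T/(T + d)."""
    if n_measured < 0:
        raise ValueError("measured density must be non-negative")
    return n_measured * abercrombie_factor(t, d)


def abercrombie_invert(nv: float, t: float, d: float) -> float:
    """Measured density N = Nv * (T + d)/T (inverse of the correction)."""
    if nv < 0:
        raise ValueError("corrected density must be non-negative")
    return nv / abercrombie_factor(t, d)


def glomeruli_per_or_gene(count: float, n_genes: int = N_INTACT_OR_GENES) -> float:
    """Glomeruli per intact OR gene per olfactory bulb."""
    if n_genes < 1:
        raise ValueError(f"need at least 1 OR gene, got {n_genes}")
    return count / n_genes


def total_volume_from_osn_count(
    x: float,
    slope: float = OSN_MODEL_SLOPE,
    intercept: float = OSN_MODEL_INTERCEPT,
) -> float:
    """Total glomerular volume (um^3) for x OSNs: y = slope*x + intercept."""
    if x < 0:
        raise ValueError("OSN count must be non-negative")
    return slope * x + intercept


def osn_count_from_total_volume(
    y: float,
    slope: float = OSN_MODEL_SLOPE,
    intercept: float = OSN_MODEL_INTERCEPT,
) -> float:
    """OSN count implied by a total glomerular volume: x = (y - b)/m."""
    if y <= intercept:
        raise ValueError(
            f"total volume {y} is at or below the intercept {intercept}; "
            "the implied OSN count would be non-positive"
        )
    return (y - intercept) / slope


def total_volume_per_or(
    median_glomerular_volume: float, glomeruli_per_or: float
) -> float:
    """Total glomerular volume per OR gene: median per-glomerulus
    volume times the glomeruli-per-OR-gene ratio."""
    if median_glomerular_volume <= 0 or glomeruli_per_or <= 0:
        raise ValueError("inputs must be positive")
    return median_glomerular_volume * glomeruli_per_or
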