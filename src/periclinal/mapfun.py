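"""Haldane and Kosambi mapping functions (centimorgan <-> recombination fraction)."""

from __future__ import annotations

import enum
import math

__all__ = ["MappingFunction", "rf_to_cM", "cM_to_rf"]


class MappingFunction(str, enum.Enum):
    HALDANE = "HALDANE"
    KOSAMBI = "KOSAMBI"


def rf_to_cM(rf: float, fn: MappingFunction = MappingFunction.KOSAMBI) -> float:
    """Map distance in cM for a recombination fraction in [0, 0.5]."""
    if not 0.0 <= rf <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {rf}")
    if rf >= 0.5:
        return math.inf
    if fn is MappingFunction.HALDANE:
        return -50.0 * math.log(1.0 - 2.0 * rf)
    return 25.0 * math.log((1.0 + 2.0 * rf) / (1.0 - 2.0 * rf))


def cM_to_rf(d_cM: float, fn: MappingFunction = MappingFunction.HALDANE) -> float:
    """Recombination fraction for a map distance in cM (inverse mapping function)."""
    if d_cM < 0:
        raise ValueError(f"map distance must be >= 0, got {d_cM}")
    x = d_cM / 100.0
    if fn is MappingFunction.HALDANE:
        return 0.5 * (1.0 - math.exp(-2.0 * x))
    return 0.5 * math.tanh(2.0 * x)
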