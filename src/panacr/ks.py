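"""Ks-based divergence dating.

T (years) = Ks / (2 * r) with r in substitutions/site/year; reported in
million years (Mya), hence the 1e-6 factor. Ks is the number of synonymous
substitutions per synonymous site between a pair of sequences, and the
factor 2 accounts for substitutions accumulating along both lineages since
their split.
"""

from __future__ import annotations

import warnings

from .errors import UsageError


def divergence_time_mya(ks: float, rate: float) -> float:
    """Divergence time in Mya from Ks and a per-year substitution rate."""
    if rate <= 0:
        raise UsageError(f"substitution rate must be positive, got {rate}")
    if ks < 0:
        raise UsageError(f"Ks must be non-negative, got {ks}")
    return ks / (2.0 * rate) * 1e-6


def substitution_rate(ks: float, time_mya: float) -> float:
    """Per-site per-year substitution rate from Ks and a divergence time in Mya."""
    if time_mya <= 0:
        raise UsageError(f"divergence time must be positive, got {time_mya}")
    if ks < 0:
        raise UsageError(f"Ks must be non-negative, got {ks}")
    if ks == 0:
        warnings.warn("Ks = 0 yields a degenerate zero substitution rate", stacklevel=2)
    return ks / (2.0 * time_mya * 1e6)
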