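"""The five normalization strategies for bucket vectors.

TIC and BPC divide every bucket of a block by the block's intensity sum
or maximum; TIC_RT and BPC_RT do the same within each RT bucket (one row
of the RT x m/z array) separately; ISTD_add divides everything by the
summed signal of an infused internal standard (sorbic acid by
default).  All strategies are pure transforms: the input vector
is never modified.

The default scope normalizes each block (each grid) independently, since
blocks come from different acquisitions with unrelated absolute scales;
``scope="global"`` treats the whole vector as one block instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .buckets import BucketVector
from .errors import ConfigError, UserInputError
from .peaks import ChromPeakList

__all__ = [
    "STRATEGIES",
    "IstdSpec",
    "NormalizationSpec",
    "normalize",
    "extract_istd_intensity",
    "SORBIC_ACID_POS",
    "SORBIC_ACID_NEG",
]

STRATEGIES = ("TIC", "BPC", "TIC_RT", "BPC_RT", "ISTD_add")

# Sorbic acid C6H8O2, monoisotopic mass 112.052430 Da (standard atomic
# masses: C 12, H 1.00782503, O 15.99491462); expected ions are
# [M+H]+ = 113.059706 and [M-H]- = 111.045153 (proton 1.00727646 Da).
SORBIC_ACID_MONO = 112.0524295
_PROTON = 1.00727646688


@dataclass(frozen=True)
class IstdSpec:
    """Internal-standard extraction window."""

    name: str
    target_mz: float
    tolerance: float = 0.005  # Da; ~5 ppm accuracy at ~110 Da with margin
    polarity: str = "positive"

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ConfigError("ISTD m/z tolerance must be positive")


SORBIC_ACID_POS = IstdSpec("sorbic acid", SORBIC_ACID_MONO + _PROTON, polarity="positive")
SORBIC_ACID_NEG = IstdSpec("sorbic acid", SORBIC_ACID_MONO - _PROTON, polarity="negative")


@dataclass(frozen=True)
class NormalizationSpec:
    strategy: str = "TIC"
    scope: str = "per_block"  # or "global"
    istd: Optional[IstdSpec] = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ConfigError(
                f"unknown normalization {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.scope not in ("per_block", "global"):
            raise ConfigError(f"unknown normalization scope {self.scope!r}")


def _divide(arr: np.ndarray, denom: float, what: str) -> np.ndarray:
    if denom == 0.0:
        warnings.warn(f"{what} is all-zero; left unnormalized")
        return arr.copy()
    return arr / denom


def normalize(
    v: BucketVector,
    spec: NormalizationSpec,
    istd_intensity: Optional[float] = None,
) -> BucketVector:
    """Apply one normalization strategy to a (pre-normalization) vector.

    All-zero blocks or RT rows pass through unchanged with a warning
    (divide-by-zero guard).  ISTD_add requires a positive
    ``istd_intensity`` and raises otherwise: a missing standard is a
    hard acquisition failure, not something to silently absorb.
    """
    out = v.copy()
    strat = spec.strategy

    if strat == "ISTD_add":
        if istd_intensity is None or istd_intensity <= 0.0:
            raise UserInputError(
                "ISTD_add normalization: internal-standard intensity is zero "
                "or missing (standard not found in this run)"
            )
        for key in out.data:
            out.data[key] = out.data[key] / istd_intensity
        return out

    if spec.scope == "global" and strat in ("TIC", "BPC"):
        arrs = list(out.data.values())
        denom = sum(a.sum() for a in arrs) if strat == "TIC" else max(a.max() for a in arrs)
        for key in out.data:
            out.data[key] = _divide(out.data[key], denom, "vector")
        return out

    for key in out.data:
        arr = out.data[key]
        if strat == "TIC":
            out.data[key] = _divide(arr, float(arr.sum()), f"block {key}")
        elif strat == "BPC":
            out.data[key] = _divide(arr, float(arr.max()) if arr.size else 0.0, f"block {key}")
        else:  # TIC_RT / BPC_RT: each RT bucket (row) on its own
            denom = arr.sum(axis=1, keepdims=True) if strat == "TIC_RT" \
                else arr.max(axis=1, keepdims=True)
            zero_rows = denom == 0.0
            if zero_rows.any() and arr.size:
                warnings.warn(f"block {key}: {int(zero_rows.sum())} empty RT bucket(s)")
            out.data[key] = np.divide(arr, denom, out=arr.copy(), where=~zero_rows)
    return out


def extract_istd_intensity(peaklist: ChromPeakList, spec: IstdSpec) -> float:
    """Summed intensity of all MS1 peaks within tolerance of the target.

    The standard is infused isocratically, so its signal elutes across
    the whole RT range; everything within the m/z window counts.
    Returns 0.0 when nothing matches (the ISTD_add caller turns that
    into a hard error).
    """
    total = 0.0
    for p in peaklist.peaks:
        if p.ms_level == 1 and abs(p.mz - spec.target_mz) <= spec.tolerance:
            total += p.intensity
    return total
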