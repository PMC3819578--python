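"""Crone-Renkin relations between flow, clearance, extraction and permeability.

For a tracer delivered at blood flow F through a capillary bed with
permeability-surface area product PS, the unidirectional clearance is

    K1 = F (1 - exp(-PS / F))

so the single-transit extraction fraction is E = K1 / F = 1 - exp(-PS / F)
and, inverting, PS = -F ln(1 - E). All three functions are exact algebraic
inverses of each other and vectorize over numpy arrays. Inputs must share
units (conventionally mL hg^-1 min^-1); no rescaling is applied.

E = 1 (fully flow-limited uptake, PS -> infinity) is outside the domain:
finite data never reach it and the logarithm diverges there. A useful
corollary: whenever PS <= F, the extraction fraction cannot exceed
1 - 1/e ~ 0.63.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "extraction_fraction",
    "ps_product",
    "clearance_from_ps",
    "append_transfer_metrics",
]


def _check(cond: np.ndarray | bool, message: str) -> None:
    if not np.all(cond):
        raise DomainError(message)


def extraction_fraction(K1, F):
    """Single-transit extraction fraction E = K1 / F.

    Requires F > 0 and 0 <= K1 <= F (K1 > F would imply E > 1, for which no
    finite PS exists). Scalar in, scalar out; arrays broadcast.
    """
    K1 = np.asarray(K1, dtype=float)
    F = np.asarray(F, dtype=float)
    _check(F > 0, "flow F must be positive")
    _check(K1 >= 0, "clearance K1 must be nonnegative")
    _check(K1 <= F, "K1 exceeds F: extraction fraction would exceed 1")
    out = K1 / F
    return float(out) if out.ndim == 0 else out


def ps_product(F, E):
    """Permeability-surface area product PS = -F ln(1 - E).

    Requires F > 0 and 0 <= E < 1.
    """
    F = np.asarray(F, dtype=float)
    E = np.asarray(E, dtype=float)
    _check(F > 0, "flow F must be positive")
    _check(E >= 0, "extraction fraction must be nonnegative")
    _check(E < 1, "extraction fraction must be < 1 (PS diverges at E = 1)")
    out = -F * np.log1p(-E)
    return float(out) if out.ndim == 0 else out


def clearance_from_ps(F, PS):
    """Unidirectional clearance K1 = F (1 - exp(-PS / F)).

    Strictly increasing in PS, approaching F (flow-limited uptake) as
    PS -> infinity. Requires F > 0 and PS >= 0.
    """
    F = np.asarray(F, dtype=float)
    PS = np.asarray(PS, dtype=float)
    _check(F > 0, "flow F must be positive")
    _check(PS >= 0, "PS must be nonnegative")
    out = F * -np.expm1(-PS / F)
    return float(out) if out.ndim == 0 else out


def append_transfer_metrics(
    df: pd.DataFrame, flow_col: str = "F", clearance_col: str = "K1"
) -> pd.DataFrame:
    """Append ``E`` and ``PS`` columns computed row-wise from flow and clearance.

    Rows with missing flow or clearance get missing metrics; rows violating
    the domain (K1 > F) raise, as upstream estimates that imply E > 1 signal
    a unit mismatch rather than physiology.
    """
    out = df.copy()
    F = out[flow_col].to_numpy(dtype=float)
    K1 = out[clearance_col].to_numpy(dtype=float)
    E = np.full_like(F, np.nan)
    PS = np.full_like(F, np.nan)
    ok = np.isfinite(F) & np.isfinite(K1)
    if ok.any():
        E[ok] = extraction_fraction(K1[ok], F[ok])
        PS[ok] = ps_product(F[ok], E[ok])
    out["E"] = E
    out["PS"] = PS
    return out
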