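"""Cerebral blood flow from [15O]water by a linearized one-tissue model.

For a freely diffusible tracer with a vascular contribution, the measured
signal M(T) = C(T) + V0 ca(T) with dC/dt = K1 ca - k2 C integrates to the
exact linear relation

    M(T) = (K1 + k2 V0) int_0^T ca dt - k2 int_0^T M dt + V0 ca(T)

so the three regression coefficients (p1, p2, p3) = (K1 + k2 V0, k2, V0)
are estimable by non-negative least squares, and the flow follows as
F = K1 = p1 - p2 p3. CBF is identified with the water clearance (water is
treated as fully extracted over a single transit), reported in the
conventional mL hg^-1 min^-1 (100 x mL g^-1 min^-1 at unit tissue density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .curves import PlasmaCurve, TimeActivityCurve
from .exceptions import InvalidInputError

__all__ = ["PerfusionParams", "build_linear_system", "nnls_solve", "fit_cbf"]


@dataclass(frozen=True)
class PerfusionParams:
    """CBF estimate from one water-session fit.

    F is the water clearance in mL hg^-1 min^-1; k2_water in min^-1;
    V0_water in mL/cm^3. All are nonnegative by construction (the NNLS
    constraint); residual_norm is ||Ax - b||_2 of the linear system.
    """

    F: float
    k2_water: float
    V0_water: float
    residual_norm: float


def build_linear_system(
    tac: TimeActivityCurve, blood: PlasmaCurve, include_v0: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the linearized water-model regression at frame mid-times.

    Rows are frames; columns are [int ca dt, -int M dt, ca(T)] and the
    response is M(T). Because the response is a frame average, every column is
    likewise frame-averaged: ca and its running integral are accumulated by
    the trapezoidal rule on the blood sampling grid (refined with the frame
    edges) and averaged over each frame; the tissue integral accumulates the
    frame averages (each frame's average times its duration, half-weighted
    inside the current frame). Returns (A, b, mid_times).
    """
    lo, hi = blood.span
    f_lo, f_hi = tac.span
    if f_lo < lo - 1e-9 or f_hi > hi + 1e-9:
        raise InvalidInputError(
            f"blood curve span [{lo}, {hi}] min does not cover TAC span [{f_lo}, {f_hi}] min"
        )
    mids = tac.mid_times
    grid = np.unique(
        np.concatenate([blood.times, tac.frame_start, tac.frame_end])
    )
    grid = grid[(grid >= f_lo - 1e-12) & (grid <= f_hi + 1e-12)]
    ca_grid = blood.interp_activity(grid)
    cum_grid = blood.interp_cumulative(grid)
    ca_bar = np.empty(mids.size)
    int_ca = np.empty(mids.size)
    for i, (a0, b0) in enumerate(zip(tac.frame_start, tac.frame_end)):
        sel = (grid >= a0 - 1e-12) & (grid <= b0 + 1e-12)
        ca_bar[i] = np.trapezoid(ca_grid[sel], grid[sel]) / (b0 - a0)
        int_ca[i] = np.trapezoid(cum_grid[sel], grid[sel]) / (b0 - a0)
    durations = tac.durations
    M = tac.activity
    # frame-averaged int_0^t M dt with M piecewise-constant over frames
    cum = np.concatenate([[0.0], np.cumsum(M * durations)])
    int_M = cum[:-1] + 0.5 * M * durations
    cols = [int_ca, -int_M]
    if include_v0:
        cols.append(ca_bar)
    A = np.column_stack(cols)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(M))):
        raise InvalidInputError("non-finite values in the linear system")
    return A, M.copy(), mids


def nnls_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Lawson-Hanson non-negative least squares: argmin ||Ax - b|| s.t. x >= 0."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.ndim != 1 or A.shape[0] != b.size:
        raise InvalidInputError("A must be 2-D with rows matching b")
    if A.shape[0] < A.shape[1]:
        raise InvalidInputError("need at least as many rows as columns")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise InvalidInputError("non-finite entries in the least-squares system")
    x, _ = nnls(A, b)
    return x


def fit_cbf(
    tac: TimeActivityCurve,
    blood: PlasmaCurve,
    window: tuple[float, float] = (0.0, 3.0),
    include_v0: bool = True,
) -> PerfusionParams:
    """Estimate regional CBF from a water session.

    Frames whose mid-times fall inside the closed ``window`` (minutes) enter
    the regression. F is returned in mL hg^-1 min^-1.
    """
    A, b, mids = build_linear_system(tac, blood, include_v0=include_v0)
    mask = (mids >= window[0] - 1e-12) & (mids <= window[1] + 1e-12)
    if mask.sum() < A.shape[1] + 1:
        raise InvalidInputError(
            f"only {int(mask.sum())} frames inside window {window}; too few for the fit"
        )
    A, b = A[mask], b[mask]
    x = nnls_solve(A, b)
    if include_v0:
        p1, k2, v0 = x
    else:
        p1, k2 = x
        v0 = 0.0
    K1 = max(p1 - k2 * v0, 0.0)
    resid = A @ x - b
    return PerfusionParams(
        F=100.0 * K1,
        k2_water=float(k2),
        V0_water=float(v0),
        residual_norm=float(np.sqrt(resid @ resid)),
    )
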