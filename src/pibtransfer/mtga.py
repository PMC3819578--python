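"""Multitime graphical analysis (Gjedde-Patlak) of blood-brain transfer.

The tissue and arterial records are transformed into two derived variables,

* the apparent distribution volume ``V(T) = m(T) / ca(T)`` (mL/cm^3), and
* the normalized (exposure) time ``Theta(T) = int_0^T ca dt / ca(T)`` (min),

on which the multicompartment transfer model becomes a regression problem.
Three nested model orders are supported:

``full``        V = K Theta + Vg (1 - exp(-(K1 - K) Theta / Vg)) + Vo
``reversible``  the K = 0 reduction (single tissue compartment)
``linear``      the early-time limit V = K1 Theta + Vo

with K the net (irreversible) clearance, K1 the unidirectional clearance,
Vg the precursor-pool dynamic volume and Vo the vascular dynamic volume.
Because circulating metabolites that do not enter brain depress V(T) at later
times, fitting is restricted to an early window of real circulation time
(default 0-4 min, applied to frame mid-times).

Units follow the data: with tissue in kBq/cm^3 and plasma in kBq/mL, the
clearances come out in mL g^-1 min^-1 (tissue density 1 g/cm^3); multiply by
100 for the conventional mL hg^-1 min^-1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, lsq_linear

from .curves import PlasmaCurve, TimeActivityCurve
from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "MTGAVariables",
    "KineticParams",
    "compute_mtga_variables",
    "fit_mtga",
    "select_model",
    "patlak_plot_data",
    "model_v",
]

_N_FREE = {"linear": 2, "reversible": 3, "full": 4}


@dataclass(frozen=True)
class MTGAVariables:
    """Coordinates of the Gjedde-Patlak plot at the frame mid-times."""

    theta: np.ndarray  # normalized time, minutes
    v: np.ndarray  # apparent distribution volume, mL/cm^3
    frame_mid_times: np.ndarray  # real circulation time, minutes
    frame_durations: np.ndarray | None = None

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        v = np.asarray(self.v, dtype=float)
        mids = np.asarray(self.frame_mid_times, dtype=float)
        if not (theta.size == v.size == mids.size) or theta.ndim != 1:
            raise InvalidInputError("theta, v and frame_mid_times must align")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "frame_mid_times", mids)
        if self.frame_durations is not None:
            d = np.asarray(self.frame_durations, dtype=float)
            if d.size != theta.size:
                raise InvalidInputError("frame_durations must align with theta")
            object.__setattr__(self, "frame_durations", d)


@dataclass(frozen=True)
class KineticParams:
    """Transfer constants estimated from a Gjedde-Patlak regression.

    Clearances K and K1 carry the units of the data (mL g^-1 min^-1 for
    standard kBq inputs); Vg and Vo are in mL/cm^3. Standard errors come from
    the Jacobian at the solution; parameters fixed by the model order
    (e.g. K = 0 under ``reversible``) have SE 0.
    """

    K: float
    K1: float
    Vg: float
    Vo: float
    se_K: float
    se_K1: float
    se_Vg: float
    se_Vo: float
    model_tag: str
    rss: float = np.nan
    n_frames: int = 0
    window: tuple[float, float] = (np.nan, np.nan)


def model_v(theta, K: float, K1: float, Vg: float, Vo: float) -> np.ndarray:
    """Apparent distribution volume predicted by the full transfer model.

    Handles the degenerate limits Vg -> 0 (no exchangeable pool) and
    K1 -> K (no reversible component) continuously.
    """
    theta = np.asarray(theta, dtype=float)
    dK = K1 - K
    if Vg > 0 and dK > 0:
        pool = Vg * -np.expm1(-dK * theta / Vg)
    else:
        pool = np.zeros_like(theta)
    return K * theta + pool + Vo


def compute_mtga_variables(
    tac: TimeActivityCurve,
    plasma: PlasmaCurve,
    use_parent_correction: bool = False,
) -> MTGAVariables:
    """Transform a TAC and arterial curve into Gjedde-Patlak coordinates.

    The plasma integral is accumulated by the trapezoidal rule on the plasma
    sampling grid; ca and its running integral are then linearly interpolated
    to the frame mid-times. With ``use_parent_correction`` the plasma curve is
    first multiplied by its parent fraction (metabolite correction).
    """
    if use_parent_correction:
        plasma = plasma.parent_corrected()
    mids = tac.mid_times
    lo, hi = plasma.span
    if mids[0] < lo - 1e-9 or mids[-1] > hi + 1e-9:
        raise InvalidInputError("plasma curve does not cover the TAC frame mid-times")
    ca = plasma.interp_activity(mids)
    if np.any(ca <= 0):
        bad = int(np.argmax(ca <= 0))
        raise DegenerateInputError(
            f"ca(T) = 0 at frame {bad} (mid-time {mids[bad]:.3f} min); "
            "Patlak variables are undefined there"
        )
    integral = plasma.interp_cumulative(mids)
    return MTGAVariables(
        theta=integral / ca,
        v=tac.activity / ca,
        frame_mid_times=mids,
        frame_durations=tac.durations,
    )


def _window_mask(vars: MTGAVariables, window) -> np.ndarray:
    lo, hi = window
    return (vars.frame_mid_times >= lo - 1e-12) & (vars.frame_mid_times <= hi + 1e-12)


def _linear_start(theta, v):
    A = np.column_stack([theta, np.ones_like(theta)])
    res = lsq_linear(A, v, bounds=(0.0, np.inf))
    return res.x  # (K1, Vo)


def _linear_fit(theta, v, sigma):
    A = np.column_stack([theta, np.ones_like(theta)]) / sigma[:, None]
    b = v / sigma
    res = lsq_linear(A, b, bounds=(0.0, np.inf))
    K1, Vo = res.x
    resid = A @ res.x - b
    rss = float(resid @ resid)
    dof = max(theta.size - 2, 1)
    cov = np.linalg.pinv(A.T @ A) * (rss / dof)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return (K1, Vo), (se[0], se[1]), rss


def fit_mtga(
    vars: MTGAVariables,
    model_tag: str = "reversible",
    window: tuple[float, float] = (0.0, 4.0),
    weighting: str = "uniform",
) -> KineticParams:
    """Fit a transfer model to Gjedde-Patlak coordinates within a time window.

    ``window`` is a closed interval of real circulation time (minutes) applied
    to frame mid-times — not to the normalized-time axis. ``weighting`` is
    ``"uniform"`` or ``"duration"`` (sigma proportional to 1/sqrt(frame
    duration)). Nonlinear models start from a linear fit over the earliest
    minute of the window and restart from jittered initial values on failure.
    """
    if model_tag not in _N_FREE:
        raise InvalidInputError(f"unknown model_tag {model_tag!r}")
    mask = _window_mask(vars, window)
    theta = vars.theta[mask]
    v = vars.v[mask]
    n = theta.size
    if n < _N_FREE[model_tag] + 1:
        raise InsufficientDataError(
            f"{n} frames in window {window}; need at least {_N_FREE[model_tag] + 1} "
            f"for the {model_tag} model"
        )
    if weighting == "uniform":
        sigma = np.ones(n)
    elif weighting == "duration":
        if vars.frame_durations is None:
            raise InvalidInputError("duration weighting requires frame_durations")
        sigma = 1.0 / np.sqrt(vars.frame_durations[mask])
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")

    if model_tag == "linear":
        (K1, Vo), (se_K1, se_Vo), rss = _linear_fit(theta, v, sigma)
        return KineticParams(
            K=0.0, K1=float(K1), Vg=np.nan, Vo=float(Vo),
            se_K=0.0, se_K1=float(se_K1), se_Vg=np.nan, se_Vo=float(se_Vo),
            model_tag="linear", rss=rss, n_frames=n, window=tuple(window),
        )

    # start values: linear fit over the earliest minute, Vg at twice max(V)
    early = vars.frame_mid_times[mask] <= window[0] + 1.0
    if early.sum() >= 2:
        K1_0, Vo_0 = _linear_start(theta[early], v[early])
    else:
        K1_0, Vo_0 = _linear_start(theta, v)
    K1_0 = max(K1_0, 1e-6)
    Vg_0 = max(2.0 * float(np.max(v)), 1e-3)

    if model_tag == "reversible":
        def f(th, K1, Vg, Vo):
            return model_v(th, 0.0, K1, Vg, Vo)

        p0 = np.array([K1_0, Vg_0, max(Vo_0, 0.0)])
    else:  # full model, parameterized as (K, dK = K1 - K, Vg, Vo) to keep K <= K1
        def f(th, K, dK, Vg, Vo):
            return model_v(th, K, K + dK, Vg, Vo)

        p0 = np.array([1e-4, K1_0, Vg_0, max(Vo_0, 0.0)])

    rng = np.random.default_rng(0)
    last_exc: Exception | None = None
    best = None
    for attempt in range(4):
        start = p0 if attempt == 0 else p0 * rng.lognormal(0.0, 0.3, size=p0.size)
        try:
            popt, pcov = curve_fit(
                f, theta, v, p0=start, sigma=sigma, absolute_sigma=False,
                bounds=(0.0, np.inf), maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except RuntimeError as exc:
            last_exc = exc
            continue
        resid = (f(theta, *popt) - v) / sigma
        rss = float(resid @ resid)
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
        break  # restarts are for non-convergence only
    if best is None:
        raise ConvergenceError(f"MTGA {model_tag} fit failed to converge: {last_exc}")
    popt, pcov, rss = best
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))

    if model_tag == "reversible":
        K1, Vg, Vo = popt
        return KineticParams(
            K=0.0, K1=float(K1), Vg=float(Vg), Vo=float(Vo),
            se_K=0.0, se_K1=float(se[0]), se_Vg=float(se[1]), se_Vo=float(se[2]),
            model_tag="reversible", rss=rss, n_frames=n, window=tuple(window),
        )
    K, dK, Vg, Vo = popt
    var_K1 = pcov[0, 0] + pcov[1, 1] + 2.0 * pcov[0, 1]
    return KineticParams(
        K=float(K), K1=float(K + dK), Vg=float(Vg), Vo=float(Vo),
        se_K=float(se[0]), se_K1=float(np.sqrt(max(var_K1, 0.0))),
        se_Vg=float(se[2]), se_Vo=float(se[3]),
        model_tag="full", rss=rss, n_frames=n, window=tuple(window),
    )


def select_model(full_fit: KineticParams, z: float = 2.0) -> str:
    """Decide the model order from a full-model fit.

    Returns ``"reversible"`` when the net clearance K is not significantly
    different from zero (|K| < z * SE(K), default z = 2), i.e. single tissue
    compartment kinetics; otherwise ``"full"``.
    """
    if not np.isfinite(full_fit.se_K) or full_fit.se_K < 0:
        raise InvalidInputError("full fit must carry a finite SE for K")
    return "reversible" if abs(full_fit.K) < z * full_fit.se_K else "full"


def patlak_plot_data(vars: MTGAVariables, fit: KineticParams) -> pd.DataFrame:
    """Plot-ready table of observed and fitted Patlak coordinates."""
    K = 0.0 if not np.isfinite(fit.K) else fit.K
    Vg = 0.0 if not np.isfinite(fit.Vg) else fit.Vg
    if fit.model_tag == "linear":
        fitted = fit.K1 * vars.theta + fit.Vo
    else:
        fitted = model_v(vars.theta, K, fit.K1, Vg, fit.Vo)
    return pd.DataFrame(
        {
            "theta_min": vars.theta,
            "mid_time_min": vars.frame_mid_times,
            "v_observed": vars.v,
            "v_fitted": fitted,
        }
    )


def fit_results_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-region fit results in the standard CSV column order."""
    cols = [
        "subject_id", "region", "model", "K", "K1", "Vg", "Vo",
        "se_K", "se_K1", "se_Vg", "se_Vo", "window_lo", "window_hi", "rss", "n_frames",
    ]
    return pd.DataFrame(rows, columns=cols)
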