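"""Noncompartmental analysis of concentration-time profiles.

Endpoints: Cmax/Tmax from the observed maximum, AUC0-t by linear trapezoid
to the last positive concentration, terminal slope lambda_z by log-linear
least squares over the best terminal window (adjusted-R^2 selection,
>= 3 points after Tmax), and AUC0-inf = AUC0-t + Clast/lambda_z.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError
from .pk import ConcentrationProfile

__all__ = ["PKEndpoints", "compute_endpoints", "endpoint_table"]

#: Endpoint names used throughout the trial machinery.
ENDPOINT_NAMES = ("cmax", "auc_0_t", "auc_0_inf")


@dataclass(frozen=True)
class PKEndpoints:
    """Noncompartmental endpoints for one profile.

    ``auc_0_inf`` and ``lambda_z`` are NaN when no reliable terminal slope
    could be identified.
    """

    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_t: float  # ng*h/mL
    auc_0_inf: float  # ng*h/mL
    lambda_z: float  # 1/h
    lambda_z_r2: float  # adjusted R^2 of the terminal fit
    n_lambda_z_points: int = 0

    def get(self, name: str) -> float:
        return getattr(self, name)


def _terminal_slope(times: np.ndarray, conc: np.ndarray, i_tmax: int,
                    max_candidates: int = 40):
    """Best log-linear terminal window: maximize adjusted R^2, ties to more points.

    Candidate windows end at the last positive concentration and start at
    any point strictly after Tmax (>= 3 points).  On dense simulated grids
    the candidate start positions are thinned to ``max_candidates`` evenly
    spaced choices.  Adjusted R^2 values are compared at 1e-6 resolution so
    numerically tied windows resolve toward the longer one.
    """
    pos = conc > 0.0
    last = np.max(np.nonzero(pos)[0]) if pos.any() else -1
    first = i_tmax + 1
    if last - first + 1 < 3:
        return math.nan, math.nan, 0
    starts = np.arange(first, last - 1)  # window [s, last] with >= 3 points
    starts = starts[pos[starts]]
    if starts.size == 0:
        return math.nan, math.nan, 0
    if starts.size > max_candidates:
        idx = np.linspace(0, starts.size - 1, max_candidates).round().astype(int)
        starts = starts[np.unique(idx)]
    best = None
    for s in starts:
        t_win = times[s : last + 1]
        c_win = conc[s : last + 1]
        keep = c_win > 0
        if keep.sum() < 3:
            continue
        t_w, logc = t_win[keep], np.log(c_win[keep])
        n = t_w.size
        slope, intercept = np.polyfit(t_w, logc, 1)
        if slope >= 0:
            continue
        fitted = slope * t_w + intercept
        ss_res = float(np.sum((logc - fitted) ** 2))
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        if ss_tot == 0.0:
            continue
        adj_r2 = 1.0 - (ss_res / ss_tot) * (n - 1) / (n - 2)
        key = (round(adj_r2, 6), n)
        if best is None or key > best[0]:
            best = (key, -slope, adj_r2)
    if best is None:
        return math.nan, math.nan, 0
    (_, n_pts), lz, r2 = best
    return lz, r2, n_pts


def compute_endpoints(profile: ConcentrationProfile | tuple) -> PKEndpoints:
    """Compute NCA endpoints from a concentration-time profile.

    Accepts a :class:`ConcentrationProfile` or a ``(times, concentrations)``
    pair.  Requires >= 3 samples and non-negative concentrations.  An
    all-zero profile yields zero endpoints with a warning; a missing
    terminal slope yields NaN ``auc_0_inf``/``lambda_z``.
    """
    if isinstance(profile, ConcentrationProfile):
        times, conc = profile.times, profile.concentrations
    else:
        times = np.asarray(profile[0], dtype=float)
        conc = np.asarray(profile[1], dtype=float)
    if times.size < 3:
        raise InsufficientDataError(f"NCA requires >= 3 samples, got {times.size}")
    if np.any(conc < 0):
        raise DataError("concentrations must be non-negative")

    if not np.any(conc > 0):
        warnings.warn("all-zero concentration profile; endpoints are zero",
                      stacklevel=2)
        return PKEndpoints(0.0, float(times[0]), 0.0, 0.0, math.nan, math.nan, 0)

    i_tmax = int(np.argmax(conc))
    cmax = float(conc[i_tmax])
    tmax = float(times[i_tmax])

    i_last = int(np.max(np.nonzero(conc > 0)[0]))
    auc_0_t = float(np.trapezoid(conc[: i_last + 1], times[: i_last + 1]))
    c_last = float(conc[i_last])

    lambda_z, r2, n_pts = _terminal_slope(times, conc, i_tmax)
    if math.isnan(lambda_z):
        auc_0_inf = math.nan
    else:
        auc_0_inf = auc_0_t + c_last / lambda_z
    return PKEndpoints(
        cmax=cmax, tmax=tmax, auc_0_t=auc_0_t, auc_0_inf=auc_0_inf,
        lambda_z=lambda_z, lambda_z_r2=r2, n_lambda_z_points=n_pts,
    )


def endpoint_table(endpoints_by_subject: dict, formulation: str) -> pd.DataFrame:
    """Tidy endpoint table: subject_id, formulation, cmax, tmax, AUCs, lambda_z."""
    rows = []
    for subject_id, ep in endpoints_by_subject.items():
        rows.append({
            "subject_id": subject_id,
            "formulation": formulation,
            "cmax": ep.cmax,
            "tmax": ep.tmax,
            "auc_0_t": ep.auc_0_t,
            "auc_0_inf": ep.auc_0_inf,
            "lambda_z": ep.lambda_z,
        })
    return pd.DataFrame(rows)
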