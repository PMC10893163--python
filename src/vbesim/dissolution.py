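"""In vitro dissolution: profiles, the f2 similarity factor and Weibull release fits.

Dissolution profiles are percent-dissolved versus time (hours) with replicate
resolution.  Two formulations are compared with the model-independent
similarity factor

    f2 = 50 * log10( 100 / sqrt(1 + mean_t (R_t - T_t)^2) )

computed on replicate-mean profiles; f2 between 50 and 100 denotes similar
release.  Release kinetics are summarised by the four-parameter Weibull
cumulative-release model

    F(t) = Fmax * (1 - exp(-((t - lag)/alpha)^beta)),   t > lag

with Fmax the release plateau (%), lag the delay before release starts (h),
alpha the time scale (h) and beta the dimensionless shape.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ConvergenceError,
    DataError,
    GridMismatchError,
    InsufficientDataError,
    UnderdeterminedError,
)

__all__ = [
    "WeibullParams",
    "DissolutionProfile",
    "F2Result",
    "WeibullFit",
    "weibull_fraction",
    "weibull_release_rate",
    "compute_f2",
    "f2_from_profiles",
    "fit_weibull",
    "read_dissolution_csv",
    "write_dissolution_csv",
]

#: Sampling grid (hours) of the 24-h modified-release dissolution protocol.
USP_TIMES = (1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0, 24.0)


@dataclass(frozen=True)
class WeibullParams:
    """Weibull cumulative-release parameters.

    Parameters
    ----------
    fmax : float
        Maximum fraction dissolved, percent, in (0, 110].
    lag : float
        Lag time before release starts, hours, >= 0.
    alpha : float
        Scale parameter, hours, > 0 (time to reach 63.2% of ``fmax``
        after the lag).
    beta : float
        Shape parameter, dimensionless, > 0.
    cv : float
        Fractional coefficient of variation applied to each parameter when
        sampling virtual subjects (default 0.10, the inter-individual
        variability assigned to in vivo dissolution).
    """

    fmax: float
    lag: float = 0.0
    alpha: float = 8.0
    beta: float = 1.0
    cv: float = 0.10

    def __post_init__(self):
        if not (0.0 < self.fmax <= 110.0):
            raise DataError(f"fmax must be in (0, 110], got {self.fmax}")
        if not (self.lag >= 0.0):
            raise DataError(f"lag must be >= 0, got {self.lag}")
        if not (self.alpha > 0.0):
            raise DataError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0.0):
            raise DataError(f"beta must be > 0, got {self.beta}")
        if not (self.cv >= 0.0):
            raise DataError(f"cv must be >= 0, got {self.cv}")
        for name in ("fmax", "lag", "alpha", "beta", "cv"):
            if not math.isfinite(getattr(self, name)):
                raise DataError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullParams":
        return cls(**{k: float(v) for k, v in d.items()})


def weibull_fraction(params: WeibullParams, t) -> np.ndarray | float:
    """Percent dissolved at time ``t`` (hours) under the Weibull model.

    Returns 0 for t <= lag, and Fmax*(1 - exp(-((t-lag)/alpha)^beta))
    otherwise; monotone non-decreasing with asymptote Fmax.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise DataError("time values must be finite")
    x = np.maximum(t_arr - params.lag, 0.0) / params.alpha
    out = params.fmax * -np.expm1(-np.power(x, params.beta))
    return out if t_arr.ndim else float(out)


def weibull_release_rate(params: WeibullParams, t) -> np.ndarray | float:
    """Time derivative of :func:`weibull_fraction` in percent/hour.

    Zero at and before the lag.  For beta < 1 the rate diverges as
    t -> lag+ (integrable singularity); callers integrating it should
    split at the lag.
    """
    t_arr = np.asarray(t, dtype=float)
    x = (t_arr - params.lag) / params.alpha
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rate = np.where(
            x > 0.0,
            params.fmax
            * (params.beta / params.alpha)
            * np.power(np.maximum(x, 1e-300), params.beta - 1.0)
            * np.exp(-np.power(np.maximum(x, 0.0), params.beta)),
            0.0,
        )
    return rate if t_arr.ndim else float(rate)


@dataclass(frozen=True)
class DissolutionProfile:
    """Replicate-resolved percent-dissolved profile for one formulation.

    ``values`` has shape (n_replicates, n_timepoints); all replicates share
    the strictly increasing time grid ``times`` (hours).
    """

    formulation_id: str
    times: np.ndarray
    values: np.ndarray
    replicate_ids: tuple = ()

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if times.ndim != 1 or times.size < 1:
            raise DataError("times must be a 1-D array")
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            raise DataError("times must be finite and > 0")
        if np.any(np.diff(times) <= 0):
            raise DataError("times must be strictly increasing")
        if values.shape[1] != times.size:
            raise DataError(
                f"values shape {values.shape} inconsistent with {times.size} time points"
            )
        if np.any(~np.isfinite(values)):
            raise DataError("dissolved values must be finite")
        if np.any(values < 0) or np.any(values > 110):
            raise DataError("dissolved values must lie in [0, 110] percent")
        reps = self.replicate_ids or tuple(range(1, values.shape[0] + 1))
        if len(reps) != values.shape[0]:
            raise DataError("replicate_ids length mismatch")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "replicate_ids", tuple(reps))

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.times.size

    def mean_profile(self) -> np.ndarray:
        """Replicate-mean percent dissolved at each time point."""
        return self.values.mean(axis=0)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (self.formulation_id, rep, t, v)
            for rep, row in zip(self.replicate_ids, self.values)
            for t, v in zip(self.times, row)
        ]
        return pd.DataFrame(
            rows, columns=["formulation_id", "replicate", "time_h", "dissolved_pct"]
        )


@dataclass(frozen=True)
class F2Result:
    """Outcome of an f2 similarity comparison."""

    f2: float
    n_points_used: int
    similar: bool


def compute_f2(
    reference_mean: Sequence[float],
    test_mean: Sequence[float],
    *,
    times: Sequence[float] | None = None,
    truncate_85: bool = False,
) -> F2Result:
    """Similarity factor f2 between two mean dissolution profiles.

    Both series must be sampled on the same time grid (at least 2 points).
    ``similar`` is True when 50 <= f2 <= 100.

    Parameters
    ----------
    reference_mean, test_mean : array-like
        Replicate-mean percent dissolved, aligned point-by-point.
    times : array-like, optional
        Time grids of the two profiles; when given as a pair
        ``(ref_times, test_times)`` they are checked for equality.
    truncate_85 : bool
        Opt-in regulatory convention: keep at most one time point after
        both profiles have exceeded 85% dissolved.  Off by default.
    """
    r = np.asarray(reference_mean, dtype=float)
    t = np.asarray(test_mean, dtype=float)
    if times is not None:
        ref_times, test_times = (np.asarray(g, dtype=float) for g in times)
        if ref_times.shape != test_times.shape or not np.allclose(
            ref_times, test_times, rtol=0.0, atol=1e-9
        ):
            raise GridMismatchError("reference and test profiles use different time grids")
    if r.shape != t.shape or r.ndim != 1:
        raise GridMismatchError(
            f"profiles must be 1-D and aligned, got shapes {r.shape} and {t.shape}"
        )
    if np.any(~np.isfinite(r)) or np.any(~np.isfinite(t)):
        raise DataError("profile values must be finite")
    if truncate_85:
        above = (r >= 85.0) & (t >= 85.0)
        if above.any():
            keep = int(np.argmax(above)) + 1  # include the first point >= 85%
            r, t = r[:keep], t[:keep]
    n = r.size
    if n < 2:
        raise InsufficientDataError(f"f2 requires at least 2 time points, got {n}")
    msd = float(np.mean((r - t) ** 2))
    f2 = 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))
    return F2Result(f2=f2, n_points_used=n, similar=50.0 <= f2 <= 100.0)


def f2_from_profiles(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    *,
    truncate_85: bool = False,
    replicate_level: bool = False,
):
    """f2 between two profiles, on replicate means by default.

    With ``replicate_level=True`` returns the list of f2 values for every
    (reference replicate, test replicate) pairing instead of a single
    mean-profile result.
    """
    if reference.times.shape != test.times.shape or not np.allclose(
        reference.times, test.times
    ):
        raise GridMismatchError("profiles use different time grids")
    if replicate_level:
        return [
            compute_f2(r_row, t_row, truncate_85=truncate_85)
            for r_row in reference.values
            for t_row in test.values
        ]
    return compute_f2(
        reference.mean_profile(), test.mean_profile(), truncate_85=truncate_85
    )


# ---------------------------------------------------------------------------
# Weibull fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeibullFit:
    """Least-squares Weibull fit with diagnostics."""

    params: WeibullParams
    rss: float
    stderr: dict = field(default_factory=dict)
    n_points: int = 0
    n_starts_tried: int = 0

    def to_json_records(self) -> list[dict]:
        """Structured per-parameter records (parameter, estimate, stderr, rss)."""
        return [
            {
                "parameter": name,
                "estimate": getattr(self.params, name),
                "stderr": self.stderr.get(name),
                "rss": self.rss,
            }
            for name in ("fmax", "lag", "alpha", "beta")
        ]


def _initial_guesses(times: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Data-driven multi-start heuristics for the 4-parameter Weibull fit."""
    fmax0 = float(max(y.max(), 1e-3))
    target = 0.632 * fmax0
    above = y >= target
    t63 = float(times[np.argmax(above)]) if above.any() else float(times[-1])
    alpha0 = max(t63, 1e-2)
    base = np.array([fmax0, 0.0, alpha0, 1.0])
    starts = [base]
    # jittered starts around the heuristic; fits of this model are multimodal
    for _ in range(2):
        jitter = rng.uniform([0.8, 0.0, 0.5, 0.6], [1.1, 1.0, 1.5, 2.0])
        starts.append(base * np.array([jitter[0], 1.0, jitter[2], jitter[3]]) +
                      np.array([0.0, jitter[1] * min(times[0], 1.0), 0.0, 0.0]))
    return starts


def fit_weibull(
    profile: DissolutionProfile | tuple,
    *,
    n_starts: int = 3,
    seed: int = 0,
    max_nfev: int = 2000,
) -> WeibullFit:
    """Fit the Weibull release model to a profile's replicate-mean curve.

    Bounded nonlinear least squares (trust-region reflective) with
    ``n_starts`` starting points derived from data heuristics: Fmax from
    the plateau, alpha from the time to 63% of plateau, beta = 1, lag = 0,
    plus seeded jitter.  Returns the best (lowest-RSS) converged solution
    with approximate standard errors from the Jacobian.

    Raises
    ------
    UnderdeterminedError
        Fewer than 4 distinct time points.
    ConvergenceError
        No start converged.
    """
    if isinstance(profile, DissolutionProfile):
        times, y = profile.times, profile.mean_profile()
    else:
        times = np.asarray(profile[0], dtype=float)
        y = np.asarray(profile[1], dtype=float)
    if np.unique(times).size < 4:
        raise UnderdeterminedError(
            f"need >= 4 distinct time points for 4 free parameters, got {np.unique(times).size}"
        )
    if np.any(y < 0):
        raise DataError("dissolved values must be non-negative")

    t_max = float(times[-1])

    def residuals(theta):
        fmax, lag, alpha, beta = theta
        x = np.maximum(times - lag, 0.0) / alpha
        return fmax * -np.expm1(-np.power(x, beta)) - y

    lb = np.array([1e-6, 0.0, 1e-4, 0.05])
    ub = np.array([110.0, t_max, 20.0 * t_max, 12.0])
    rng = np.random.default_rng(seed)
    starts = _initial_guesses(times, y, rng)[:n_starts]

    best = None
    tried = 0
    failures = []
    for x0 in starts:
        tried += 1
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lb, ub), max_nfev=max_nfev,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        raise ConvergenceError(
            "Weibull fit failed to converge from any start",
            diagnostics={"n_starts": tried, "messages": failures},
        )
    sol, rss = best
    fmax, lag, alpha, beta = (float(v) for v in sol.x)
    params = WeibullParams(fmax=fmax, lag=lag, alpha=alpha, beta=beta)

    # asymptotic standard errors from (J'J)^-1 * s^2 (NaN when singular)
    stderr: dict[str, float] = {}
    dof = times.size - 4
    if dof > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (rss / dof)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            stderr = dict(zip(("fmax", "lag", "alpha", "beta"), map(float, se)))
        except np.linalg.LinAlgError:
            stderr = {}
    return WeibullFit(
        params=params, rss=rss, stderr=stderr,
        n_points=int(times.size), n_starts_tried=tried,
    )


# ---------------------------------------------------------------------------
# CSV I/O (long format: formulation_id, replicate, time_h, dissolved_pct)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["formulation_id", "replicate", "time_h", "dissolved_pct"]


def read_dissolution_csv(path) -> dict[str, DissolutionProfile]:
    """Read long-format dissolution CSV into profiles keyed by formulation."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"dissolution CSV {path} missing columns: {missing}")
    profiles = {}
    for form_id, group in df.groupby("formulation_id", sort=False):
        wide = group.pivot_table(
            index="replicate", columns="time_h", values="dissolved_pct", sort=True
        )
        if wide.isna().any().any():
            raise GridMismatchError(
                f"replicates of {form_id!r} do not share a common time grid"
            )
        profiles[str(form_id)] = DissolutionProfile(
            formulation_id=str(form_id),
            times=wide.columns.to_numpy(dtype=float),
            values=wide.to_numpy(dtype=float),
            replicate_ids=tuple(wide.index),
        )
    return profiles


def write_dissolution_csv(profiles, path) -> None:
    """Write one or more profiles to a long-format CSV."""
    if isinstance(profiles, DissolutionProfile):
        profiles = [profiles]
    frames = [p.to_long_frame() for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fit_json(fit: WeibullFit, path) -> None:
    """Emit fit results (params + per-parameter records) as JSON."""
    payload = {
        "params": fit.params.to_dict(),
        "rss": fit.rss,
        "n_points": fit.n_points,
        "records": fit.to_json_records(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
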