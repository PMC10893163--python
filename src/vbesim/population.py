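"""Seeded virtual populations with log-normal inter-individual variability.

Each varied parameter p is drawn log-normally with median equal to the base
value and log-SD sigma = sqrt(ln(1 + CV^2)), the standard pharmacometric
median-preserving parameterization; positivity is guaranteed by
construction.  Sampling is deterministic for a given seed, and independent
sub-streams (for the two arms of a parallel trial) are derived with
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dissolution import WeibullParams
from .errors import ConfigError
from .pk import CompoundParams

__all__ = ["PopulationSpec", "VirtualSubject", "sample_population", "default_cvs"]

#: Release parameters that can carry variability.
RELEASE_PARAMS = ("fmax", "lag", "alpha", "beta")
#: Compound parameters that can carry variability.
COMPOUND_PARAMS = (
    "volume_of_distribution",
    "clint_total",
    "ka",
    "fraction_absorbed",
    "fu_plasma",
    "renal_cl",
)
# fractions are clipped back into (0, 1] after sampling; fmax capped at 110
_FRACTION_PARAMS = {"fraction_absorbed", "fu_plasma"}


@dataclass(frozen=True)
class PopulationSpec:
    """How many subjects to draw and which parameters vary (CV per name)."""

    n: int
    parameter_cvs: dict = field(default_factory=dict)
    seed: int = 0
    distribution: str = "lognormal"

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError(f"population size must be >= 1, got {self.n}")
        if self.distribution != "lognormal":
            raise ConfigError(f"unsupported distribution {self.distribution!r}")
        known = set(RELEASE_PARAMS) | set(COMPOUND_PARAMS)
        for name, cv in self.parameter_cvs.items():
            if name not in known:
                raise ConfigError(
                    f"unknown parameter {name!r} in CV map; known: {sorted(known)}"
                )
            if cv < 0:
                raise ConfigError(f"CV for {name!r} must be >= 0, got {cv}")


@dataclass(frozen=True)
class VirtualSubject:
    """One sampled individual's release and disposition parameters."""

    subject_id: int
    compound: CompoundParams
    release: WeibullParams


def default_cvs(release_cv: float = 0.10, clearance_cv: float = 0.0,
                volume_cv: float = 0.0) -> dict:
    """CV map with 10% on each Weibull release parameter by default.

    Clearance/volume variability is off unless requested; which PK
    parameters varied in the source workflow is not public, so they are
    left as explicit knobs.
    """
    cvs = {name: release_cv for name in RELEASE_PARAMS}
    if clearance_cv > 0:
        cvs["clint_total"] = clearance_cv
    if volume_cv > 0:
        cvs["volume_of_distribution"] = volume_cv
    return cvs


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(n))


def sample_population(
    spec: PopulationSpec,
    base_compound: CompoundParams,
    base_release: WeibullParams,
) -> list[VirtualSubject]:
    """Draw ``spec.n`` virtual subjects around the base parameter set.

    Parameters named in ``spec.parameter_cvs`` are perturbed independently
    (no correlation structure by default; see :func:`sample_correlated` for
    the user-supplied-correlation hook).  A parameter whose base value is 0
    (e.g. a zero lag) stays 0: the log-normal family is degenerate there.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n
    factors: dict[str, np.ndarray] = {}
    # fixed iteration order over the canonical parameter lists keeps the
    # stream layout stable regardless of dict ordering in the CV map
    for name in RELEASE_PARAMS + COMPOUND_PARAMS:
        cv = spec.parameter_cvs.get(name, 0.0)
        if cv > 0:
            factors[name] = _lognormal_factors(rng, cv, n)

    subjects = []
    for i in range(n):
        rel_kwargs = {}
        for name in RELEASE_PARAMS:
            base = getattr(base_release, name)
            val = base * factors[name][i] if name in factors and base > 0 else base
            rel_kwargs[name] = val
        rel_kwargs["fmax"] = min(rel_kwargs["fmax"], 110.0)
        release = replace(base_release, **rel_kwargs)

        comp_kwargs = {}
        for name in COMPOUND_PARAMS:
            base = getattr(base_compound, name)
            if name in factors and base > 0:
                val = base * factors[name][i]
                if name in _FRACTION_PARAMS:
                    val = min(val, 1.0)
                comp_kwargs[name] = val
        compound = replace(base_compound, **comp_kwargs) if comp_kwargs else base_compound
        subjects.append(VirtualSubject(subject_id=i + 1, compound=compound,
                                       release=release))
    return subjects


def arm_seeds(seed: int, n_arms: int = 2) -> list[int]:
    """Decorrelated sub-seeds for independently sampled trial arms."""
    children = np.random.SeedSequence(seed).spawn(n_arms)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def population_frame(subjects: list[VirtualSubject]) -> pd.DataFrame:
    """Flat audit table of every subject's sampled parameters."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update({f"release_{k}": getattr(s.release, k) for k in RELEASE_PARAMS})
        row.update({k: getattr(s.compound, k) for k in COMPOUND_PARAMS})
        rows.append(row)
    return pd.DataFrame(rows)


def sample_correlated(
    spec: PopulationSpec,
    base_compound: CompoundParams,
    base_release: WeibullParams,
    correlation: np.ndarray,
    names: list[str],
) -> list[VirtualSubject]:
    """Correlated sampling hook: draw log-scale deviates with the given
    correlation matrix over ``names`` (subset of the known parameters).

    The marginal of each parameter matches :func:`sample_population`
    (median-preserving log-normal at its CV); only the joint changes.
    """
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (len(names), len(names)):
        raise ConfigError("correlation matrix shape does not match names")
    if not np.allclose(corr, corr.T) or np.any(np.diag(corr) != 1.0):
        raise ConfigError("correlation matrix must be symmetric with unit diagonal")
    known = set(RELEASE_PARAMS) | set(COMPOUND_PARAMS)
    for name in names:
        if name not in known:
            raise ConfigError(f"unknown parameter {name!r}")
        if name not in spec.parameter_cvs:
            raise ConfigError(f"parameter {name!r} has no CV in the population spec")
    sigmas = np.array([
        math.sqrt(math.log1p(spec.parameter_cvs[nm] ** 2)) for nm in names
    ])
    cov = corr * np.outer(sigmas, sigmas)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    z = rng.multivariate_normal(np.zeros(len(names)), cov, size=spec.n,
                                method="cholesky")
    factors = {nm: np.exp(z[:, j]) for j, nm in enumerate(names)}

    subjects = []
    for i in range(spec.n):
        rel_kwargs = {
            nm: getattr(base_release, nm) * factors[nm][i]
            for nm in names if nm in RELEASE_PARAMS and getattr(base_release, nm) > 0
        }
        if "fmax" in rel_kwargs:
            rel_kwargs["fmax"] = min(rel_kwargs["fmax"], 110.0)
        comp_kwargs = {}
        for nm in names:
            if nm in COMPOUND_PARAMS and getattr(base_compound, nm) > 0:
                val = getattr(base_compound, nm) * factors[nm][i]
                if nm in _FRACTION_PARAMS:
                    val = min(val, 1.0)
                comp_kwargs[nm] = val
        subjects.append(VirtualSubject(
            subject_id=i + 1,
            compound=replace(base_compound, **comp_kwargs) if comp_kwargs else base_compound,
            release=replace(base_release, **rel_kwargs) if rel_kwargs else base_release,
        ))
    return subjects
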