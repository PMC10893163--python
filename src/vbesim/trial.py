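"""Parallel-design virtual bioequivalence trials.

Each study samples two independent virtual populations (test and reference
arms) from the same variability spec — the worst case in which
inter-occasion variability equals inter-individual variability — simulates
every subject with the arm's formulation release, computes NCA endpoints,
and decides bioequivalence per endpoint from the 90% confidence interval of
the test/reference geometric mean ratio:

    log GMR = mean(log E_test) - mean(log E_ref)
    CI      = log GMR -+ t_{1-alpha, df_Welch} * sqrt(s_T^2/n_T + s_R^2/n_R)

GMR and CI are reported in percent; BE passes when the CI lies inside the
80-125% limits (boundaries inclusive).  The CI-within-limits rule is dual
to two one-sided tests (TOST) at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .dissolution import WeibullParams
from .errors import ConfigError, DataError
from .nca import ENDPOINT_NAMES, compute_endpoints
from .pk import CompoundParams, DosingRegimen, default_time_grid, simulate_subject
from .population import PopulationSpec, arm_seeds, sample_population

__all__ = [
    "TrialDesign",
    "EndpointResult",
    "TrialResult",
    "be_decision",
    "welch_log_ci",
    "run_vbe",
]


@dataclass(frozen=True)
class TrialDesign:
    """Parallel-design BE study configuration."""

    n_per_arm: int = 125
    endpoints: tuple = ENDPOINT_NAMES
    ci_level: float = 90.0
    be_limits: tuple = (80.0, 125.0)
    n_replicate_studies: int = 1
    seed: int = 0
    pooled_variance: bool = False

    def __post_init__(self):
        if self.n_per_arm < 3:
            raise ConfigError("parallel BE design requires n_per_arm >= 3")
        if not (0.0 < self.ci_level < 100.0):
            raise ConfigError(f"ci_level must be in (0, 100), got {self.ci_level}")
        lo, hi = self.be_limits
        if not (0.0 < lo < 100.0 < hi):
            raise ConfigError(f"BE limits must satisfy 0 < lower < 100 < upper, got {self.be_limits}")
        if self.n_replicate_studies < 1:
            raise ConfigError("n_replicate_studies must be >= 1")
        unknown = [e for e in self.endpoints if e not in ENDPOINT_NAMES]
        if unknown:
            raise ConfigError(f"unknown endpoints {unknown}; known: {ENDPOINT_NAMES}")


@dataclass(frozen=True)
class EndpointResult:
    """GMR and CI (percent) plus BE decision for one endpoint."""

    endpoint: str
    gmr: float
    ci_lower: float
    ci_upper: float
    passes: bool
    n_test: int = 0
    n_ref: int = 0


@dataclass(frozen=True)
class TrialResult:
    """One test-vs-reference study: per-endpoint results and overall call."""

    endpoints: dict
    overall_be: bool
    valid: bool = True
    warnings: tuple = ()
    study_seed: int = 0
    subject_endpoints: pd.DataFrame | None = field(default=None, compare=False)

    def forest_table(self) -> pd.DataFrame:
        """Forest-plot-ready rows (endpoint, gmr, lo, hi, pass)."""
        return pd.DataFrame([
            {"endpoint": r.endpoint, "gmr": r.gmr, "lo": r.ci_lower,
             "hi": r.ci_upper, "pass": r.passes}
            for r in self.endpoints.values()
        ])

    def to_dict(self) -> dict:
        return {
            "overall_be": self.overall_be,
            "valid": self.valid,
            "study_seed": self.study_seed,
            "warnings": list(self.warnings),
            "endpoints": {
                name: {"gmr": r.gmr, "ci_lower": r.ci_lower,
                       "ci_upper": r.ci_upper, "passes": r.passes}
                for name, r in self.endpoints.items()
            },
        }


def be_decision(gmr_ci: tuple, limits: tuple = (80.0, 125.0)) -> bool:
    """True iff the CI (percent) lies within the limits, boundaries inclusive."""
    lo, hi = gmr_ci
    if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
        raise DataError(f"malformed confidence interval {gmr_ci}")
    return limits[0] <= lo and hi <= limits[1]


def welch_log_ci(test_values, ref_values, *, ci_level: float = 90.0,
                 pooled: bool = False):
    """GMR and CI (percent) from log-scale endpoint samples of two arms.

    Welch two-sample interval by default (unequal variances, Satterthwaite
    df); ``pooled=True`` switches to the classical pooled-variance interval.
    Degenerate zero-variance arms give a point interval at the GMR.
    """
    x = np.log(np.asarray(test_values, dtype=float))
    y = np.log(np.asarray(ref_values, dtype=float))
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise DataError("need >= 2 endpoint values per arm")
    diff = x.mean() - y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    alpha = 1.0 - ci_level / 100.0
    if v1 == 0.0 and v2 == 0.0:
        gmr = 100.0 * math.exp(diff)
        return gmr, gmr, gmr
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    tcrit = float(t_dist.ppf(1.0 - alpha / 2.0, df))
    gmr = 100.0 * math.exp(diff)
    return gmr, 100.0 * math.exp(diff - tcrit * se), 100.0 * math.exp(diff + tcrit * se)


def _simulate_arm(subjects, regimen, grid):
    endpoints = []
    for s in subjects:
        profile = simulate_subject(s.compound, s.release, regimen, grid=grid)
        endpoints.append(compute_endpoints(profile))
    return endpoints


def run_vbe(
    test_release: WeibullParams,
    ref_release: WeibullParams,
    compound: CompoundParams,
    pop_spec: PopulationSpec,
    design: TrialDesign,
    regimen: DosingRegimen,
    grid: np.ndarray | None = None,
    keep_subject_table: bool = True,
) -> list[TrialResult]:
    """Run ``design.n_replicate_studies`` parallel VBE studies.

    Every study draws fresh, independent test and reference arms of
    ``design.n_per_arm`` subjects (sequential sub-seeds of ``design.seed``
    so replicate diagnostics are reproducible), simulates a full
    concentration-time profile per subject and applies the Welch-CI BE
    decision per endpoint.  A study in which more than 10% of an arm lacks
    a usable endpoint value is flagged invalid.
    """
    if grid is None:
        grid = default_time_grid(regimen)
    study_seed_roots = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(design.seed).spawn(design.n_replicate_studies)
    ]
    results = []
    for study_seed in study_seed_roots:
        seeds = arm_seeds(study_seed, 2)
        arms = {}
        for label, rel, seed in (("test", test_release, seeds[0]),
                                 ("ref", ref_release, seeds[1])):
            spec = replace(pop_spec, n=design.n_per_arm, seed=seed)
            subjects = sample_population(spec, compound, rel)
            arms[label] = _simulate_arm(subjects, regimen, grid)

        warnings_list = []
        valid = True
        endpoint_results = {}
        rows = []
        for label, eps in arms.items():
            for i, ep in enumerate(eps):
                rows.append({"arm": label, "subject": i + 1, "cmax": ep.cmax,
                             "tmax": ep.tmax, "auc_0_t": ep.auc_0_t,
                             "auc_0_inf": ep.auc_0_inf, "lambda_z": ep.lambda_z})
        for name in design.endpoints:
            tv = np.array([ep.get(name) for ep in arms["test"]])
            rv = np.array([ep.get(name) for ep in arms["ref"]])
            t_ok, r_ok = np.isfinite(tv) & (tv > 0), np.isfinite(rv) & (rv > 0)
            frac_missing = max(1.0 - t_ok.mean(), 1.0 - r_ok.mean())
            if frac_missing > 0.10:
                valid = False
                warnings_list.append(
                    f"endpoint {name}: {100 * frac_missing:.0f}% of an arm missing"
                )
            gmr, lo, hi = welch_log_ci(tv[t_ok], rv[r_ok],
                                       ci_level=design.ci_level,
                                       pooled=design.pooled_variance)
            endpoint_results[name] = EndpointResult(
                endpoint=name, gmr=gmr, ci_lower=lo, ci_upper=hi,
                passes=be_decision((lo, hi), design.be_limits),
                n_test=int(t_ok.sum()), n_ref=int(r_ok.sum()),
            )
        results.append(TrialResult(
            endpoints=endpoint_results,
            overall_be=all(r.passes for r in endpoint_results.values()),
            valid=valid,
            warnings=tuple(warnings_list),
            study_seed=study_seed,
            subject_endpoints=pd.DataFrame(rows) if keep_subject_table else None,
        ))
    return results
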