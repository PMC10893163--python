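"""Synthetic study inputs: dissolution replicates, compound configs, scenarios.

The generator emulates a 24-h modified-release dissolution study: Weibull
ground-truth curves sampled at the nine protocol times (1, 2, 4, 6, 8, 12,
16, 20, 24 h) with additive Gaussian replicate noise (default SD 1.5%,
reflecting the low variability typical of in vitro dissolution), 7
replicates for the reference formulation and 3 for each test formulation.

All shipped parameter sets are synthetic: they are chosen to produce the
qualitative patterns of interest (one test formulation similar to the
reference and bioequivalent, one faster-releasing formulation that passes
the f2 screen but fails the Cmax BE criterion) and make no claim of
matching any marketed product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dissolution import (
    USP_TIMES,
    DissolutionProfile,
    WeibullParams,
    weibull_fraction,
    write_dissolution_csv,
)
from .errors import ConfigError
from .pk import CompoundParams, DosingRegimen, InhibitorSpec

__all__ = [
    "ScenarioSpec",
    "default_scenario",
    "synthetic_compound",
    "ciprofloxacin_like_inhibitor",
    "generate_dissolution",
    "generate_scenario_bundle",
    "PRESETS",
]

#: Reference-like modified-release profile (synthetic).
REFERENCE_RELEASE = WeibullParams(fmax=92.0, lag=0.5, alpha=9.0, beta=1.15)
#: Test formulation similar to the reference (high f2, bioequivalent).
SIMILAR_RELEASE = WeibullParams(fmax=93.0, lag=0.4, alpha=9.8, beta=1.10)
#: Faster-releasing test formulation: passes the f2 screen (f2 just above
#: 50) but over-shoots Cmax, so it fails BE on Cmax while AUC passes.
FAST_RELEASE = WeibullParams(fmax=92.0, lag=0.4, alpha=7.2, beta=2.0)


def synthetic_compound() -> CompoundParams:
    """Synthetic BCS-1 modified-release compound parameter set.

    A dopamine-agonist-like profile: large distribution volume, mostly
    hepatic elimination split between CYP1A2 (fm 0.65) and CYP3A4 (fm 0.25)
    with a small renal component, oral clearance ~47 L/h and a terminal
    half-life near 8 h.  These are plausible round numbers, not measured
    values for any drug.
    """
    return CompoundParams(
        volume_of_distribution=525.0,
        clint_total=97.0,
        ka=2.0,
        fraction_absorbed=1.0,
        fu_plasma=0.85,
        hepatic_blood_flow=90.0,
        fm_cyp1a2=0.65,
        fm_cyp3a4=0.25,
        renal_cl=4.0,
        molecular_weight=260.4,
    )


def ciprofloxacin_like_inhibitor(unbound_concentration: float = 3.0) -> InhibitorSpec:
    """Dual CYP1A2/CYP3A4 competitive inhibitor.

    Ki 2 µM (CYP1A2) and 1.5 µM (CYP3A4) with incubation unbound fractions
    0.92 and 1; the default steady-state unbound concentration of 3 µM is a
    synthetic plausible value for a 500 mg BID fluoroquinolone regimen.
    """
    return InhibitorSpec(
        ki_cyp1a2=2.0, ki_cyp3a4=1.5,
        fu_inc_cyp1a2=0.92, fu_inc_cyp3a4=1.0,
        unbound_concentration=unbound_concentration,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Dissolution-generation scenario.

    ``formulations`` maps labels to ground-truth Weibull parameters;
    ``replicate_counts`` gives replicates per formulation (default 7 for
    the label ``"REF"``, 3 otherwise); ``noise_sd`` is the additive
    Gaussian noise SD in percent dissolved.
    """

    formulations: dict = field(default_factory=lambda: {
        "REF": REFERENCE_RELEASE,
        "TEST-SIMILAR": SIMILAR_RELEASE,
        "TEST-FAST": FAST_RELEASE,
    })
    replicate_counts: dict = field(default_factory=dict)
    noise_sd: float = 1.5
    time_grid: tuple = USP_TIMES
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(self.time_grid) < 2:
            raise ConfigError("time grid must have >= 2 points")

    def replicates_for(self, label: str) -> int:
        if label in self.replicate_counts:
            return int(self.replicate_counts[label])
        return 7 if label.upper() == "REF" else 3


def default_scenario(seed: int = 0, noise_sd: float = 1.5) -> ScenarioSpec:
    return ScenarioSpec(seed=seed, noise_sd=noise_sd)


def generate_dissolution(spec: ScenarioSpec):
    """Generate replicate dissolution profiles for every formulation.

    Per replicate the ground-truth Weibull curve is evaluated on the time
    grid and additive N(0, noise_sd^2) noise is applied, truncated at 0 and
    capped at 105%.  Deterministic for a given seed.

    Returns ``(profiles, ground_truth)``: a dict of
    :class:`DissolutionProfile` and the dict of true parameters.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    times = np.asarray(spec.time_grid, dtype=float)
    profiles = {}
    for label, params in spec.formulations.items():
        n_rep = spec.replicates_for(label)
        truth = weibull_fraction(params, times)
        noise = rng.normal(0.0, spec.noise_sd, size=(n_rep, times.size)) \
            if spec.noise_sd > 0 else np.zeros((n_rep, times.size))
        values = np.clip(truth[None, :] + noise, 0.0, 105.0)
        profiles[label] = DissolutionProfile(
            formulation_id=label, times=times, values=values,
        )
    return profiles, dict(spec.formulations)


PRESETS = ("be-pass", "be-fail-cmax", "ddi-demo", "power-sweep")


def _trial_config(test_label: str, ref_label: str, *, n_per_arm: int,
                  n_replicates: int, clearance_cv: float = 0.0) -> dict:
    cvs = {name: 0.10 for name in ("fmax", "lag", "alpha", "beta")}
    if clearance_cv > 0:
        cvs["clint_total"] = clearance_cv
    return {
        "dissolution_csv": "dissolution.csv",
        "compound": "compound.json",
        "reference": ref_label,
        "test": test_label,
        "regimen": {"events": [[0.0, 2.0]]},
        "population": {"parameter_cvs": cvs},
        "design": {
            "n_per_arm": n_per_arm,
            "endpoints": ["cmax", "auc_0_t", "auc_0_inf"],
            "ci_level": 90.0,
            "be_limits": [80.0, 125.0],
            "n_replicate_studies": n_replicates,
        },
    }


def generate_scenario_bundle(name: str, out_dir, seed: int = 0) -> dict:
    """Write a self-contained runnable scenario bundle and return its manifest.

    Presets
    -------
    be-pass
        TEST-SIMILAR vs REF; expected to conclude BE on all endpoints.
    be-fail-cmax
        TEST-FAST vs REF; expected to fail Cmax while both AUC endpoints
        pass.
    ddi-demo
        Steady-state interaction run with the dual CYP1A2/3A4 inhibitor.
    power-sweep
        Inputs for the study-power-vs-n sweep (8..200 subjects).
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = default_scenario(seed=seed)
    profiles, truth = generate_dissolution(spec)
    write_dissolution_csv(list(profiles.values()), out / "dissolution.csv")
    (out / "ground_truth.json").write_text(json.dumps(
        {k: p.to_dict() for k, p in truth.items()}, indent=2))
    (out / "compound.json").write_text(
        json.dumps(synthetic_compound().to_dict(), indent=2))

    manifest: dict = {"preset": name, "seed": seed, "files": ["dissolution.csv",
                      "ground_truth.json", "compound.json"]}
    if name == "be-pass":
        config = _trial_config("TEST-SIMILAR", "REF", n_per_arm=125, n_replicates=1)
        manifest["expected"] = {"overall_be": True}
    elif name == "be-fail-cmax":
        config = _trial_config("TEST-FAST", "REF", n_per_arm=125, n_replicates=1)
        manifest["expected"] = {"overall_be": False, "cmax_passes": False,
                                "auc_passes": True}
    elif name == "ddi-demo":
        config = _trial_config("TEST-SIMILAR", "REF", n_per_arm=12, n_replicates=1)
        (out / "inhibitor.json").write_text(
            json.dumps(ciprofloxacin_like_inhibitor().to_dict(), indent=2))
        config["inhibitor"] = "inhibitor.json"
        config["regimen"] = DosingRegimen.tid(2.0, 7).to_dict()
        manifest["expected"] = {"auc_ratio_above_1": True}
        manifest["files"].append("inhibitor.json")
    else:  # power-sweep
        config = _trial_config("TEST-SIMILAR", "REF", n_per_arm=40, n_replicates=1)
        config["power"] = {"n_min": 8, "n_max": 200, "target": 0.8, "alpha": 0.05}
        manifest["expected"] = {"null_power_near_alpha": True}

    config["seed"] = seed
    (out / "trial.json").write_text(json.dumps(config, indent=2))
    manifest["files"].append("trial.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
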