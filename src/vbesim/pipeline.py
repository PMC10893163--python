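"""End-to-end pipeline: dissolution fit -> f2 screen -> VBE trial -> power sweep.

A run is driven by a JSON trial config (see :mod:`vbesim.synthetic` for the
generated dialect) and writes all outputs plus a :class:`RunManifest` that
records the config hash and every stage's sub-seed, so any run can be
reproduced exactly from its manifest.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .dissolution import f2_from_profiles, fit_weibull, read_dissolution_csv
from .errors import ConfigError
from .nca import ENDPOINT_NAMES
from .pk import CompoundParams, DosingRegimen, InhibitorSpec, steady_state_auc_ratio
from .population import PopulationSpec
from .power import power_curve
from .trial import TrialDesign, run_vbe

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("vbesim")

_STAGES = ("fit", "trial", "power")


def stage_seeds(master_seed: int) -> dict:
    """Counter-based fan-out of the master seed to one sub-seed per stage."""
    return {
        name: int(np.random.SeedSequence(master_seed, spawn_key=(i,))
                  .generate_state(1)[0] % (2**31))
        for i, name in enumerate(_STAGES)
    }


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    config_hash: str
    master_seed: int
    stage_seeds: dict
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _load_json(path: Path) -> dict:
    if not path.exists():
        raise ConfigError(f"missing input file: {path}")
    return json.loads(path.read_text())


def run_pipeline(config_path, out_dir, seed: int | None = None):
    """Execute the full VBE workflow described by a trial config file.

    Stages: fit the Weibull model to each formulation's dissolution data,
    compute the f2 similarity of test vs reference (an f2 below 50 logs a
    warning but does not stop the run — f2 is a candidate-selection screen,
    not a gate), run the parallel VBE stud(ies), and optionally sweep study
    power over per-arm sample sizes.

    Returns ``(manifest, results)`` where ``results`` holds the fits, f2,
    trial results and power tables.
    """
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = _load_json(config_path)
    base = config_path.parent

    master_seed = int(config.get("seed", 0) if seed is None else seed)
    seeds = stage_seeds(master_seed)
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        master_seed=master_seed,
        stage_seeds=seeds,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    results: dict = {}

    # --- dissolution fits -------------------------------------------------
    diss_path = base / config["dissolution_csv"]
    if not diss_path.exists():
        raise ConfigError(f"missing input file: {diss_path}")
    profiles = read_dissolution_csv(diss_path)
    ref_label, test_label = config["reference"], config["test"]
    for label in (ref_label, test_label):
        if label not in profiles:
            raise ConfigError(f"formulation {label!r} not in dissolution data "
                              f"({sorted(profiles)})")
    log.info("fitting Weibull model to %d formulations", len(profiles))
    fits = {label: fit_weibull(prof, seed=seeds["fit"])
            for label, prof in profiles.items()}
    results["fits"] = fits
    _write(out / "weibull_fits.json", {
        label: {"params": f.params.to_dict(), "rss": f.rss, "stderr": f.stderr}
        for label, f in fits.items()
    }, manifest)

    # --- f2 screen --------------------------------------------------------
    f2 = f2_from_profiles(profiles[ref_label], profiles[test_label])
    results["f2"] = f2
    if not f2.similar:
        log.warning("f2 = %.2f below 50 for %s vs %s; continuing (f2 is a "
                    "selection screen, not a gate)", f2.f2, test_label, ref_label)
    _write(out / "f2.json", {"reference": ref_label, "test": test_label,
                             "f2": f2.f2, "n_points": f2.n_points_used,
                             "similar": f2.similar}, manifest)

    # --- trial ------------------------------------------------------------
    compound = CompoundParams.from_dict(_load_json(base / config["compound"]))
    regimen = DosingRegimen.from_dict(config["regimen"])
    design_cfg = dict(config.get("design", {}))
    design_cfg["endpoints"] = tuple(design_cfg.get("endpoints", ENDPOINT_NAMES))
    design_cfg["be_limits"] = tuple(design_cfg.get("be_limits", (80.0, 125.0)))
    design = TrialDesign(seed=seeds["trial"], **{
        k: v for k, v in design_cfg.items() if k != "seed"})
    pop_cfg = config.get("population", {})
    pop_spec = PopulationSpec(n=design.n_per_arm,
                              parameter_cvs=pop_cfg.get("parameter_cvs", {}),
                              seed=seeds["trial"])
    log.info("running %d VBE stud(ies), %d subjects/arm",
             design.n_replicate_studies, design.n_per_arm)
    studies = run_vbe(fits[test_label].params, fits[ref_label].params,
                      compound, pop_spec, design, regimen)
    results["studies"] = studies
    _write(out / "trial_results.json",
           [s.to_dict() for s in studies], manifest)
    studies[0].forest_table().to_csv(out / "forest.csv", index=False)
    manifest.outputs.append("forest.csv")
    if studies[0].subject_endpoints is not None:
        studies[0].subject_endpoints.to_csv(out / "subject_endpoints.csv",
                                            index=False)
        manifest.outputs.append("subject_endpoints.csv")

    # --- optional DDI check ----------------------------------------------
    if "inhibitor" in config:
        inhibitor = InhibitorSpec.from_dict(_load_json(base / config["inhibitor"]))
        ratio = steady_state_auc_ratio(compound, fits[ref_label].params,
                                       inhibitor)
        results["ddi_auc_ratio"] = ratio
        _write(out / "ddi.json", {"auc_ratio": ratio,
                                  "inhibitor": inhibitor.to_dict()}, manifest)

    # --- optional power sweep --------------------------------------------
    if "power" in config:
        pw = config["power"]
        table = studies[0].subject_endpoints
        curves = {}
        for name in design.endpoints:
            ref_vals = table.loc[table["arm"] == "ref", name].to_numpy()
            test_vals = table.loc[table["arm"] == "test", name].to_numpy()
            curves[name] = power_curve(
                ref_vals, test_vals,
                n_min=int(pw.get("n_min", 8)), n_max=int(pw.get("n_max", 200)),
                alpha=float(pw.get("alpha", 0.05)), endpoint=name,
            )
        results["power"] = curves
        import pandas as pd

        pd.concat([c.table() for c in curves.values()], ignore_index=True) \
            .to_csv(out / "power_curve.csv", index=False)
        manifest.outputs.append("power_curve.csv")
        target = pw.get("target")
        if target is not None:
            _write(out / "power_target.json", {
                name: {"target": target, "smallest_n": c.smallest_n(float(target))}
                for name, c in curves.items()
            }, manifest)

    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest, results


def _write(path: Path, payload, manifest: RunManifest) -> None:
    path.write_text(json.dumps(payload, indent=2))
    manifest.outputs.append(path.name)
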