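"""End-to-end reproducible runs: synthesise -> infer -> classify -> interpret.

A run is described by a plain-mapping config (YAML/JSON-friendly).
``validate_config`` normalises units to (M, h, Angstrom), fills and flags
defaults and rejects unknown keys, reporting *all* violations at once;
``run_experiment`` executes the stages and returns a self-describing
report whose every number traces back to the config or a stage
computation.  A single seed governs all stochastic stages through
stage-name-derived child seeds, so each stage is independently
reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
import zlib
from pathlib import Path

import numpy as np

from . import io as _io
from .inference import (VelocityRecord, bootstrap_confidence,
                        estimate_initial_velocity)
from .linker import linker_model
from .network import (RateParams, build_network, crossover_concentration,
                      product_fractions, run_to_completion)
from .synth import NoiseModel, generate_timecourses

log = logging.getLogger("autocyclase")

REPORT_SCHEMA_VERSION = 1

_DEFAULTS = {
    "seed": 0,
    "out_dir": None,
    "rates": {"mode": "lumped", "k_uni": 0.01, "k_bi": 130.0, "k_hyd": 0.0,
              "f_inactive": 0.0},
    "network": {"max_order": 4, "policy": "drop"},
    "c0_um": [2.5, 5.0, 10.0, 20.0],
    "t_grid_h": {"start": 0.0, "stop": 6.0, "n": 13},
    "noise": {"relative_sd": 0.02, "floor_sd": 1e-9, "n_replicates": 3},
    "inference": {"product": "E", "max_conversion": 0.10,
                  "thresholds": [0.90, 0.10], "n_boot": 1000},
    "linker": {"span_a": 35.0, "per_residue_a": 3.5, "n_linker": None,
               "enzyme_nterm_res": 5, "kuhn_a": 7.6, "contour_a": 3.8,
               "km_um": None},
}


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid config:\n  " + "\n  ".join(self.errors))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


def validate_config(raw: dict | None) -> dict:
    """Normalise a raw config mapping; raise :class:`ConfigError` listing
    every violation.  Concentrations given in uM are converted to M and
    the conversion is noted under ``_normalised``."""
    raw = copy.deepcopy(raw or {})
    errors: list[str] = []
    notes: list[str] = []
    cfg = copy.deepcopy(_DEFAULTS)

    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    for key, val in raw.items():
        if key not in _DEFAULTS:
            continue
        if isinstance(_DEFAULTS[key], dict) and key != "t_grid_h":
            if not isinstance(val, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            bad = set(val) - set(_DEFAULTS[key])
            if bad:
                errors.append(f"{key}: unknown keys {sorted(bad)}")
            for k2, v2 in val.items():
                if k2 in _DEFAULTS[key]:
                    cfg[key][k2] = v2
        else:
            cfg[key] = val

    for k in ("k_uni", "k_bi", "k_hyd"):
        if cfg["rates"].get(k, 0) < 0:
            errors.append(f"rates.{k}: must be >= 0")
    if not 0 <= cfg["rates"].get("f_inactive", 0) < 1:
        errors.append("rates.f_inactive: must be in [0, 1)")
    if cfg["network"]["max_order"] < 1:
        errors.append("network.max_order: must be >= 1")
    if cfg["network"]["policy"] not in ("drop", "absorb"):
        errors.append("network.policy: must be 'drop' or 'absorb'")
    try:
        c0_M = [float(c) * 1e-6 for c in cfg["c0_um"]]
        if any(c <= 0 for c in c0_M):
            errors.append("c0_um: concentrations must be > 0")
        notes.append("c0_um converted to M")
    except (TypeError, ValueError):
        errors.append("c0_um: expected a list of numbers")
        c0_M = []
    tg = cfg["t_grid_h"]
    if isinstance(tg, dict):
        missing = {"start", "stop", "n"} - set(tg)
        if missing:
            errors.append(f"t_grid_h: missing {sorted(missing)}")
            t_grid = []
        else:
            t_grid = list(np.linspace(tg["start"], tg["stop"], int(tg["n"])))
    else:
        t_grid = [float(t) for t in tg]
    if t_grid and (len(t_grid) < 4 or np.any(np.diff(t_grid) <= 0)):
        errors.append("t_grid_h: need >= 4 strictly increasing times")
    thr = cfg["inference"]["thresholds"]
    if not (0 <= thr[1] < thr[0] <= 1):
        errors.append("inference.thresholds: expected [hi, lo] with 0<=lo<hi<=1")

    if errors:
        raise ConfigError(errors)
    cfg["_c0_M"] = c0_M
    cfg["_t_grid_h"] = t_grid
    cfg["_normalised"] = notes
    return cfg


def run_experiment(config: dict | None = None, out_dir: str | None = None) -> dict:
    """Execute generate -> fit -> classify -> critical-concentration stages.

    Returns the report dict (JSON-serialisable); when ``out_dir`` (or the
    config's ``out_dir``) is set, writes ``report.json`` plus the
    synthetic time-course CSVs there.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    rp = RateParams(mode=cfg["rates"]["mode"], k_uni=cfg["rates"]["k_uni"],
                    k_bi=cfg["rates"]["k_bi"], k_hyd=cfg["rates"]["k_hyd"],
                    f_inactive=cfg["rates"]["f_inactive"])
    net = build_network(cfg["network"]["max_order"], rp,
                        cfg["network"]["policy"])
    stage = "synthesise"
    try:
        noise = NoiseModel(relative_sd=cfg["noise"]["relative_sd"],
                           floor_sd=cfg["noise"]["floor_sd"],
                           n_replicates=cfg["noise"]["n_replicates"],
                           seed=stage_seed(seed, stage))
        datasets = generate_timecourses(net, rp, cfg["_c0_M"],
                                        np.array(cfg["_t_grid_h"]), noise)

        stage = "initial-velocities"
        records = []
        for c0, reps in datasets.items():
            vs = [estimate_initial_velocity(
                tc, product=cfg["inference"]["product"],
                max_conversion=cfg["inference"]["max_conversion"]) for tc in reps]
            v0s = tuple(v.v0 for v in vs)
            records.append(VelocityRecord(
                c0=c0, v0=float(np.mean(v0s)),
                se=float(np.std(v0s, ddof=1) / np.sqrt(len(v0s))) if len(v0s) > 1 else 0.0,
                replicates=v0s, window=vs[0].window))

        stage = "fit"
        fit = bootstrap_confidence(records, n_boot=cfg["inference"]["n_boot"],
                                   seed=stage_seed(seed, stage))
        fit.thresholds = tuple(cfg["inference"]["thresholds"])

        stage = "product-fractions"
        fractions = {}
        for c0 in (min(cfg["_c0_M"]), max(cfg["_c0_M"])):
            tc = run_to_completion(net, rp, c0)
            fractions[f"{c0 * 1e6:g}uM"] = product_fractions(tc)
            cons = tc.conservation_errors()
            if max(cons.values()) > 1e-6:
                log.warning("conservation drift %s at C0=%g", cons, c0)

        stage = "linker"
        lk = cfg["linker"]
        lres = linker_model(span_A=lk["span_a"], per_residue_A=lk["per_residue_a"],
                            n_linker=lk["n_linker"],
                            enzyme_nterm_res=lk["enzyme_nterm_res"],
                            kuhn_length_A=lk["kuhn_a"],
                            contour_per_residue_A=lk["contour_a"],
                            km_M=lk["km_um"] * 1e-6 if lk["km_um"] else None)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {k: v for k, v in cfg.items() if not k.startswith("_")},
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s)
                        for s in ("synthesise", "fit")},
        "velocities": [
            {"c0_M": r.c0, "v0_M_per_h": r.v0, "se": r.se,
             "replicates": list(r.replicates), "window_h": list(r.window)}
            for r in records],
        "k1_hat_per_h": fit.k1_hat,
        "k2_hat_per_M_h": fit.k2_hat,
        "ci_k1": list(fit.ci_k1),
        "ci_k2": list(fit.ci_k2),
        "regimes": {f"{c0 * 1e6:g}uM": label for c0, label in fit.regimes.items()},
        "linear_fractions": {f"{c0 * 1e6:g}uM": fit.linear_fraction(c0)
                             for c0 in cfg["_c0_M"]},
        "product_fractions": fractions,
        "crossover_M": crossover_concentration(rp),
        "linker_model": {
            "n_res_required": lres.n_res_required,
            "n_flex": lres.n_flex,
            "ceff_M": lres.ceff_M,
            "km_M": lres.km_M,
            "c_star_M": lres.c_star_M,
        },
    }

    dest = out_dir or cfg.get("out_dir")
    if dest:
        dest = Path(dest)
        dest.mkdir(parents=True, exist_ok=True)
        with open(dest / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        for c0, reps in datasets.items():
            _io.write_timecourses(reps, dest / f"tc_{c0 * 1e6:g}uM.csv")
    return report
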