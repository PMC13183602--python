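"""Replication of the surrogate study design.

Three experiment families mirror the study around the mechanistic model:

* ``run_forward_matrix`` -- sex-specific, cross-sex and sex-inclusive
  forward surrogates for one cell type, each validated against male and
  female ground truth (the accuracy-matrix table).
* ``run_inhibition`` -- forward surrogates validated on transporter
  inhibition scenarios whose sampled activities lie (partly) below the
  training range: NHE3 mean -40% for the PCT, NKCC2 mean -70% for the
  mTAL.
* ``run_inverse`` -- inverse surrogates inferring the four transport
  parameters from observables (cytosolic [Na+], [K+] and transcellular
  Na+/K+ fluxes), probing parameter identifiability.  PCT inverse datasets
  jitter the (unobserved) SGLT2 activity by +/-10% so NHE3 competes with a
  nuisance apical Na+ pathway.

``replicate_all`` runs the full suite from one base seed and writes a
results directory (datasets/, surrogates/, reports/, provenance.json).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from episurf.cellmodel import ModelVariant, load_variant
from episurf.datagen import (Dataset, build_design, default_ranges,
                             generate_dataset, write_dataset)
from episurf.evaluate import MetricsReport, validate
from episurf.surrogate import (TrainConfig, TrainedSurrogate, save_surrogate,
                               train_surrogate)

__all__ = [
    "ResultsTable",
    "INHIBITION_DEFAULTS",
    "PCT_INVERSE_NUISANCE",
    "subseed",
    "run_forward_matrix",
    "run_inhibition",
    "run_inverse",
    "replicate_all",
]

SEXES = ("male", "female")

INHIBITION_DEFAULTS = {
    "pct": {"parameter": "NHE3", "mean_reduction_frac": 0.40,
            "half_width_frac": 0.2},
    "mtal": {"parameter": "NKCC2", "mean_reduction_frac": 0.70,
             "half_width_frac": 0.2},
}

# unobserved apical Na+ pathway jittered in PCT inverse data generation
PCT_INVERSE_NUISANCE = {"parameter": "SGLT2", "half_width_frac": 0.1}


def subseed(base: int, *tags: str) -> int:
    """Stable sub-seed (< 2^31) derived from a base seed and string tags."""
    words = [int(base) & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tags]
    return int(np.random.SeedSequence(words).generate_state(1)[0] % (1 << 31))


@dataclass
class ResultsTable:
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, base: str | Path) -> None:
        base = Path(base)
        base.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(base.with_suffix(".csv"), index=False,
                          float_format="%.10g")
        payload = {"provenance": self.provenance,
                   "rows": self.table.to_dict(orient="records")}
        base.with_suffix(".json").write_text(json.dumps(payload, indent=1))


def _config_hash(cell_type: str, sex: str) -> str:
    text = resources.files("episurf.config").joinpath(
        f"{cell_type}_{sex}.yaml").read_text()
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _provenance(cell_type: str, seed: int, **extra) -> dict:
    import episurf
    prov = {"cell_type": cell_type, "base_seed": int(seed),
            "config_hash": {s: _config_hash(cell_type, s) for s in SEXES},
            "software_version": episurf.__version__}
    prov.update(extra)
    return prov


def _grid_dataset(variant: ModelVariant, seed: int, levels: int,
                  nuisance=None) -> Dataset:
    design = build_design(default_ranges(variant), "grid", levels,
                          seed=seed, nuisance=nuisance)
    ds = generate_dataset(variant, design)
    ds.require_complete()
    return ds


def run_forward_matrix(cell_type: str, seed: int = 0, levels: int = 8,
                       n_val: int = 250, config: TrainConfig | None = None,
                       return_artifacts: bool = False):
    """Train M, F and M+F forward surrogates; validate each on both sexes.

    Returns a six-row :class:`ResultsTable` (trained_on x validated_on) with
    per-output and aggregate fractional MSE; with ``return_artifacts`` also
    returns the datasets, surrogates and validation truths for reuse.
    """
    config = config or TrainConfig()
    variants = {s: load_variant(f"{cell_type}_{s}") for s in SEXES}
    train_ds = {s: _grid_dataset(variants[s], subseed(seed, "grid", s), levels)
                for s in SEXES}
    surrogates: dict[str, TrainedSurrogate] = {}
    for tag, data in (("male", train_ds["male"]),
                      ("female", train_ds["female"]),
                      ("both", [train_ds["male"], train_ds["female"]])):
        cfg = TrainConfig(**{**_cfg_dict(config),
                             "seed": subseed(seed, "train", tag)})
        surrogates[tag] = train_surrogate(data, "forward", cfg)

    val_truth = {}
    for s in SEXES:
        design = build_design(default_ranges(variants[s]), "random", n_val,
                              seed=subseed(seed, "val", s))
        val_truth[s] = generate_dataset(variants[s], design)

    rows = []
    reports: dict[tuple[str, str], MetricsReport] = {}
    for trained_on, surr in surrogates.items():
        for validated_on in SEXES:
            report, _ = validate(surr, variants[validated_on],
                                 truth=val_truth[validated_on],
                                 scenario=f"{trained_on}->{validated_on}")
            reports[(trained_on, validated_on)] = report
            row = {"cell_type": cell_type, "trained_on": trained_on,
                   "validated_on": validated_on,
                   "aggregate_fmse": report.aggregate,
                   "n_samples": report.n_samples}
            row.update({f"fmse_{k}": v for k, v in report.per_output.items()})
            rows.append(row)
    result = ResultsTable(
        table=pd.DataFrame(rows),
        provenance=_provenance(cell_type, seed, experiment="forward_matrix",
                               levels=levels, n_val=n_val))
    if return_artifacts:
        return result, {"variants": variants, "train_datasets": train_ds,
                        "surrogates": surrogates, "val_truth": val_truth,
                        "reports": reports}
    return result


def _cfg_dict(c: TrainConfig) -> dict:
    return {"split_fraction": c.split_fraction,
            "learning_rate": c.learning_rate, "batch_size": c.batch_size,
            "max_epochs": c.max_epochs, "patience": c.patience,
            "seed": c.seed}


def run_inhibition(cell_type: str, spec: dict | None = None, seed: int = 0,
                   levels: int = 8, n_val: int = 250,
                   config: TrainConfig | None = None,
                   artifacts: dict | None = None):
    """Validate sex-specific forward surrogates under transporter inhibition.

    Returns (ResultsTable, scatter DataFrame).  Each sex contributes a
    baseline row (random design inside the training range) and an
    inhibition row (named transporter sampled below it); the scatter table
    holds both scenarios for plotting.
    """
    spec = spec or INHIBITION_DEFAULTS[cell_type]
    config = config or TrainConfig()
    rows = []
    scatters = []
    for s in SEXES:
        if artifacts is not None:
            variant = artifacts["variants"][s]
            surr = artifacts["surrogates"][s]
        else:
            variant = load_variant(f"{cell_type}_{s}")
            ds = _grid_dataset(variant, subseed(seed, "grid", s), levels)
            cfg = TrainConfig(**{**_cfg_dict(config),
                                 "seed": subseed(seed, "train", s)})
            surr = train_surrogate(ds, "forward", cfg)
        base_report, base_scatter = validate(
            surr, variant, n=n_val, seed=subseed(seed, "inh-base", s),
            design_mode="random", scenario="baseline")
        inh_report, inh_scatter = validate(
            surr, variant, n=n_val, seed=subseed(seed, "inh", s),
            design_mode="inhibition", inhibition=spec, scenario="inhibition")
        for rep in (base_report, inh_report):
            row = {"cell_type": cell_type, "sex": s, "scenario": rep.scenario,
                   "parameter": spec["parameter"],
                   "aggregate_fmse": rep.aggregate, "n_samples": rep.n_samples}
            row.update({f"fmse_{k}": v for k, v in rep.per_output.items()})
            rows.append(row)
        for sc in (base_scatter, inh_scatter):
            sc = sc.copy()
            sc["sex"] = s
            scatters.append(sc)
    result = ResultsTable(
        table=pd.DataFrame(rows),
        provenance=_provenance(cell_type, seed, experiment="inhibition",
                               inhibition=spec, levels=levels, n_val=n_val))
    return result, pd.concat(scatters, ignore_index=True)


def run_inverse(cell_type: str, sex: str, seed: int = 0, levels: int = 8,
                n_val: int = 250, config: TrainConfig | None = None):
    """Train and validate an inverse surrogate (observables -> parameters).

    Returns (ResultsTable, surrogate, scatter): one fractional-MSE row per
    inferred parameter, scored on fresh samples.
    """
    config = config or TrainConfig()
    variant = load_variant(f"{cell_type}_{sex}")
    nuisance = PCT_INVERSE_NUISANCE if cell_type == "pct" else None
    ds = _grid_dataset(variant, subseed(seed, "inv-grid", sex), levels,
                       nuisance=nuisance)
    cfg = TrainConfig(**{**_cfg_dict(config),
                         "seed": subseed(seed, "inv-train", sex)})
    surr = train_surrogate(ds, "inverse", cfg)
    report, scatter = validate(surr, variant, n=n_val,
                               seed=subseed(seed, "inv-val", sex),
                               design_mode="random", nuisance=nuisance,
                               scenario="inverse")
    rows = []
    for col, v in report.per_output.items():
        rows.append({"cell_type": cell_type, "sex": sex,
                     "parameter": col.removeprefix("frac_"), "fmse": v,
                     "n_samples": report.n_samples})
    result = ResultsTable(
        table=pd.DataFrame(rows),
        provenance=_provenance(cell_type, seed, experiment="inverse",
                               sex=sex, levels=levels, n_val=n_val,
                               nuisance=nuisance))
    return result, surr, scatter


def replicate_all(seed: int = 0, outdir: str | Path = "results",
                  levels: int = 8, n_val: int = 250,
                  config: TrainConfig | None = None) -> dict:
    """Run the full study suite for both cell types and write all artifacts.

    Layout: ``datasets/`` (CSV+JSON pairs), ``surrogates/`` (bundles),
    ``reports/`` (metric tables and scatter CSVs), ``provenance.json``.
    """
    outdir = Path(outdir)
    (outdir / "datasets").mkdir(parents=True, exist_ok=True)
    (outdir / "surrogates").mkdir(exist_ok=True)
    (outdir / "reports").mkdir(exist_ok=True)
    summary: dict = {"seed": int(seed), "levels": levels, "n_val": n_val}

    for cell_type in ("pct", "mtal"):
        fwd, art = run_forward_matrix(cell_type, seed=seed, levels=levels,
                                      n_val=n_val, config=config,
                                      return_artifacts=True)
        fwd.write(outdir / "reports" / f"forward_matrix_{cell_type}")
        for s in SEXES:
            write_dataset(art["train_datasets"][s],
                          outdir / "datasets" / f"{cell_type}_{s}_train_grid")
        for tag, surr in art["surrogates"].items():
            save_surrogate(surr,
                           outdir / "surrogates" / f"{cell_type}_{tag}_forward")
        # reuse the per-sex surrogates for the inhibition scenario
        inh_art = {"variants": art["variants"],
                   "surrogates": {s: art["surrogates"][s] for s in SEXES}}
        inh, scatter = run_inhibition(cell_type, seed=seed, levels=levels,
                                      n_val=n_val, config=config,
                                      artifacts=inh_art)
        inh.write(outdir / "reports" / f"inhibition_{cell_type}")
        scatter.to_csv(outdir / "reports" / f"inhibition_scatter_{cell_type}.csv",
                       index=False, float_format="%.10g")
        inv_frames = []
        for s in SEXES:
            inv, inv_surr, _ = run_inverse(cell_type, s, seed=seed,
                                           levels=levels, n_val=n_val,
                                           config=config)
            inv_frames.append(inv.table)
            save_surrogate(inv_surr,
                           outdir / "surrogates" / f"{cell_type}_{s}_inverse")
        inv_all = ResultsTable(
            table=pd.concat(inv_frames, ignore_index=True),
            provenance=_provenance(cell_type, seed, experiment="inverse"))
        inv_all.write(outdir / "reports" / f"inverse_{cell_type}")
        summary[cell_type] = {
            "forward_matrix": fwd.table.to_dict(orient="records"),
            "inhibition": inh.table.to_dict(orient="records"),
            "inverse": inv_all.table.to_dict(orient="records"),
        }

    import episurf
    provenance = {"seed": int(seed), "levels": levels, "n_val": n_val,
                  "software_version": episurf.__version__,
                  "config_hash": {
                      ct: {s: _config_hash(ct, s) for s in SEXES}
                      for ct in ("pct", "mtal")}}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
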