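"""Parameter designs and mechanistic-model dataset generation.

Training data for the surrogate are produced by sweeping the four varied
transport parameters of a variant over multiplicative ranges (default
50%-200% of baseline).  Three design modes exist:

``grid``
    Full factorial with log-spaced levels per parameter, ordered along a
    boustrophedon ("snake") path so consecutive points differ in exactly one
    parameter by one level -- the continuation ordering that lets every
    solve warm-start from its neighbour.
``random``
    i.i.d. log-uniform vectors over the ranges (validation sets).
``inhibition``
    One parameter drawn uniformly around a reduced mean (transporter
    inhibition, deliberately below the training range); the others stay
    log-uniform over their training ranges.

Datasets are written as a CSV table plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from episurf.cellmodel import (ConfigurationError, ConvergenceError,
                               ModelVariant, SteadyState,
                               apply_parameter_fractions,
                               relax_to_steady_state, solve_steady_state)

__all__ = [
    "ParameterRange",
    "Design",
    "Dataset",
    "FormatError",
    "default_ranges",
    "build_design",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "OUTPUT_COLUMNS",
]

OUTPUT_COLUMNS = ("Na_cell", "K_cell", "Va", "Vb", "J_Na_trans", "J_K_trans")


class FormatError(ValueError):
    """Dataset file pair is inconsistent or incomplete."""


@dataclass(frozen=True)
class ParameterRange:
    name: str
    lo_frac: float = 0.5
    hi_frac: float = 2.0

    def __post_init__(self):
        if not (0 < self.lo_frac < self.hi_frac):
            raise ConfigurationError("require 0 < lo_frac < hi_frac")


@dataclass(frozen=True)
class Design:
    """An ordered list of parameter vectors, as fractions of baseline."""

    mode: str
    param_names: tuple[str, ...]
    fractions: np.ndarray            # (n, 4)
    seed: int
    levels: int | None = None
    inhibition: Mapping | None = None
    nuisance: Mapping | None = None  # e.g. {"parameter": "SGLT2", "half_width_frac": 0.1}
    ranges: tuple[ParameterRange, ...] = ()

    @property
    def n(self) -> int:
        return self.fractions.shape[0]

    def describe(self) -> dict:
        d = {"mode": self.mode, "param_names": list(self.param_names),
             "n": int(self.n), "seed": int(self.seed)}
        if self.levels is not None:
            d["levels"] = int(self.levels)
        if self.inhibition:
            d["inhibition"] = dict(self.inhibition)
        if self.nuisance:
            d["nuisance"] = dict(self.nuisance)
        d["ranges"] = [[r.name, r.lo_frac, r.hi_frac] for r in self.ranges]
        return d


def default_ranges(variant: ModelVariant) -> list[ParameterRange]:
    """The 50%-200% training ranges on the variant's four varied parameters."""
    return [ParameterRange(name) for name in variant.varied_parameters]


def _snake_order(levels: int, d: int) -> np.ndarray:
    """Full-factorial index matrix ordered so that consecutive rows differ
    in exactly one coordinate by one level (boustrophedon path)."""
    idx = np.zeros((levels ** d, d), dtype=int)
    row = 0

    def recurse(depth, prefix, reverse):
        nonlocal row
        rng = range(levels - 1, -1, -1) if reverse else range(levels)
        if depth == d - 1:
            for i in rng:
                idx[row, :depth] = prefix
                idx[row, depth] = i
                row += 1
            return
        flip = reverse
        for i in rng:
            recurse(depth + 1, prefix + [i], flip)
            flip = not flip

    recurse(0, [], False)
    return idx


def build_design(ranges: Sequence[ParameterRange], mode: str,
                 n_or_levels: int, seed: int = 0,
                 inhibition: Mapping | None = None,
                 nuisance: Mapping | None = None) -> Design:
    """Build a parameter design over four multiplicative ranges.

    ``n_or_levels`` is the per-parameter level count for ``grid`` mode
    (levels**4 points) and the sample count for ``random``/``inhibition``.
    ``inhibition`` is ``{"parameter", "mean_reduction_frac",
    "half_width_frac"}``: the named parameter is drawn uniformly on
    [mean - hw, mean + hw] x baseline with mean = 1 - mean_reduction_frac.
    """
    ranges = tuple(ranges)
    if len(ranges) != 4:
        raise ConfigurationError("exactly four parameter ranges are required")
    names = tuple(r.name for r in ranges)
    rng = np.random.default_rng(seed)

    if mode == "grid":
        levels = int(n_or_levels)
        if levels < 2:
            raise ConfigurationError("grid mode needs at least 2 levels")
        axes = [np.geomspace(r.lo_frac, r.hi_frac, levels) for r in ranges]
        idx = _snake_order(levels, 4)
        fractions = np.column_stack([axes[j][idx[:, j]] for j in range(4)])
        return Design(mode="grid", param_names=names, fractions=fractions,
                      seed=seed, levels=levels, nuisance=_nuis(nuisance),
                      ranges=ranges)

    n = int(n_or_levels)
    if n < 1:
        raise ConfigurationError("need at least one sample")
    if mode == "random":
        cols = [np.exp(rng.uniform(math.log(r.lo_frac), math.log(r.hi_frac), n))
                for r in ranges]
        return Design(mode="random", param_names=names,
                      fractions=np.column_stack(cols), seed=seed,
                      nuisance=_nuis(nuisance), ranges=ranges)
    if mode == "inhibition":
        if not inhibition or "parameter" not in inhibition:
            raise ConfigurationError("inhibition mode needs an inhibition spec")
        target = inhibition["parameter"]
        if target not in names:
            raise ConfigurationError(
                f"inhibition parameter {target!r} not among {names}")
        mean = 1.0 - float(inhibition["mean_reduction_frac"])
        hw = float(inhibition.get("half_width_frac", 0.2))
        if mean - hw <= 0:
            raise ConfigurationError("inhibition interval must stay positive")
        cols = []
        for r in ranges:
            if r.name == target:
                cols.append(rng.uniform(mean - hw, mean + hw, n))
            else:
                cols.append(np.exp(rng.uniform(math.log(r.lo_frac),
                                               math.log(r.hi_frac), n)))
        spec = {"parameter": target,
                "mean_reduction_frac": float(inhibition["mean_reduction_frac"]),
                "half_width_frac": hw}
        return Design(mode="inhibition", param_names=names,
                      fractions=np.column_stack(cols), seed=seed,
                      inhibition=spec, nuisance=_nuis(nuisance), ranges=ranges)
    raise ConfigurationError(f"unknown design mode {mode!r}")


def _nuis(nuisance):
    if nuisance is None:
        return None
    return {"parameter": str(nuisance["parameter"]),
            "half_width_frac": float(nuisance.get("half_width_frac", 0.1))}


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------

@dataclass
class Dataset:
    """Table of sampled transport parameters with solved model outputs."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)

    def require_complete(self):
        if not bool(self.table["converged"].all()):
            bad = int((~self.table["converged"].astype(bool)).sum())
            raise FormatError(f"dataset has {bad} unconverged rows")


def _solve_point(variant, fracs_map, guess):
    act, mem = apply_parameter_fractions(variant, fracs_map)
    return solve_steady_state(variant, act, mem, initial_guess=guess)


def generate_dataset(variant: ModelVariant, design: Design,
                     version: str | None = None) -> Dataset:
    """Solve the mechanistic model at every design point.

    Warm-start policy: grid designs start each point from the previous
    converged solution along the snake path; random/inhibition designs start
    from the already-solved point nearest in log-fraction space.  Failed
    solves fall back to a cold start and then to the pseudo-transient
    relaxation oracle; points that still fail are recorded unconverged.
    """
    names = design.param_names
    if set(names) != set(variant.varied_parameters):
        raise ConfigurationError(
            f"design parameters {names} do not match variant "
            f"{variant.varied_parameters}")
    fr = design.fractions
    n = design.n

    nuis_col = None
    if design.nuisance is not None:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(design.seed), 0x4E75]))
        hw = design.nuisance["half_width_frac"]
        nuis_col = np.exp(rng.uniform(math.log(1 - hw), math.log(1 + hw), n))

    logfr = np.log(fr)
    solved_states: list[SteadyState | None] = [None] * n
    rows = []
    prev_state = None
    solved_idx: list[int] = []
    for i in range(n):
        fr_map = {p: float(fr[i, j]) for j, p in enumerate(names)}
        if nuis_col is not None:
            fr_map[design.nuisance["parameter"]] = float(nuis_col[i])
        if design.mode == "grid":
            guesses = [prev_state, None]
        else:
            nearest = None
            if solved_idx:
                d2 = ((logfr[solved_idx] - logfr[i]) ** 2).sum(axis=1)
                nearest = solved_states[solved_idx[int(np.argmin(d2))]]
            guesses = [nearest, None]
        state = None
        for guess in guesses:
            try:
                state = _solve_point(variant, fr_map, guess)
                break
            except ConvergenceError:
                continue
        if state is None:
            try:
                act, mem = apply_parameter_fractions(variant, fr_map)
                relaxed = relax_to_steady_state(variant, act, mem)
                state = solve_steady_state(variant, act, mem,
                                           initial_guess=relaxed)
            except ConvergenceError:
                state = None
        row = {}
        for j, p in enumerate(names):
            row[f"frac_{p}"] = fr[i, j]
        for j, p in enumerate(names):
            row[f"abs_{p}"] = fr[i, j] * _baseline_value(variant, p)
        if nuis_col is not None:
            row[f"nuisance_{design.nuisance['parameter']}_frac"] = float(nuis_col[i])
        if state is not None:
            row.update(
                Na_cell=state.cytosol.concentrations["Na"],
                K_cell=state.cytosol.concentrations["K"],
                Va=state.Va, Vb=state.Vb,
                J_Na_trans=state.fluxes.basolateral["Na"],
                J_K_trans=state.fluxes.basolateral["K"],
                converged=True, iterations=state.iterations,
            )
            solved_states[i] = state
            solved_idx.append(i)
            prev_state = state
        else:
            row.update(Na_cell=np.nan, K_cell=np.nan, Va=np.nan, Vb=np.nan,
                       J_Na_trans=np.nan, J_K_trans=np.nan,
                       converged=False, iterations=-1)
        rows.append(row)

    table = pd.DataFrame(rows)
    meta = {
        "variant": variant.name,
        "cell_type": variant.cell_type,
        "sex": variant.sex,
        "design": design.describe(),
        "seed": int(design.seed),
        "n_rows": int(n),
        "n_converged": int(table["converged"].sum()),
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "software_version": version or _pkg_version(),
    }
    failing = table.index[~table["converged"].astype(bool)].tolist()
    if failing:
        meta["incomplete"] = True
        meta["failed_rows"] = failing
    return Dataset(table=table, metadata=meta)


def _baseline_value(variant: ModelVariant, name: str) -> float:
    from episurf.cellmodel import _VARIED
    kind, target = _VARIED[name]
    if kind == "activity":
        return getattr(variant.baseline_activities, target)
    side, solute = target
    return getattr(variant.membranes, side).permeabilities.get(solute, 0.0)


def _pkg_version() -> str:
    import episurf
    return episurf.__version__


# --------------------------------------------------------------------------
# Dataset I/O: CSV + JSON sidecar
# --------------------------------------------------------------------------

def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    return base.with_suffix(".csv"), base.with_suffix(".json")


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write ``<path>.csv`` and ``<path>.json``; released datasets must be
    complete (all rows converged)."""
    ds.require_complete()
    csv_path, json_path = _paths(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    ds.table.to_csv(csv_path, index=False, float_format="%.17g")
    meta = dict(ds.metadata)
    meta["n_rows"] = int(len(ds.table))
    meta["columns"] = list(ds.table.columns)
    json_path.write_text(json.dumps(meta, indent=1))


def read_dataset(path: str | Path) -> Dataset:
    csv_path, json_path = _paths(path)
    if not csv_path.exists() or not json_path.exists():
        raise FormatError(f"missing dataset file pair at {csv_path.with_suffix('')}")
    meta = json.loads(json_path.read_text())
    table = pd.read_csv(csv_path, float_precision="round_trip")
    if len(table) != int(meta.get("n_rows", -1)):
        raise FormatError(
            f"row count mismatch: table has {len(table)}, "
            f"sidecar declares {meta.get('n_rows')}")
    required = set(meta.get("columns", [])) | set(OUTPUT_COLUMNS) | {"converged"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return Dataset(table=table, metadata=meta)
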