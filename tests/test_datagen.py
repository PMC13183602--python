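"""Design construction, continuation-ordered generation, and dataset I/O."""

import json

import numpy as np
import pytest

from episurf.cellmodel import ConfigurationError
from episurf.datagen import (Dataset, FormatError, ParameterRange,
                             build_design, default_ranges, generate_dataset,
                             read_dataset, write_dataset)

RANGES = [ParameterRange(n) for n in ("p1", "p2", "p3", "p4")]


class TestDesigns:
    def test_grid_size_is_levels_to_the_fourth(self):
        d = build_design(RANGES, "grid", 8, seed=0)
        assert d.n == 4096
        assert d.fractions.min() == pytest.approx(0.5)
        assert d.fractions.max() == pytest.approx(2.0)

    def test_snake_ordering_changes_one_coordinate_by_one_level(self):
        d = build_design(RANGES, "grid", 5, seed=0)
        levels = np.geomspace(0.5, 2.0, 5)
        idx = np.array([[int(np.argmin(np.abs(levels - f))) for f in row]
                        for row in d.fractions])
        steps = np.abs(np.diff(idx, axis=0))
        assert np.all(steps.sum(axis=1) == 1)
        assert np.all(steps.max(axis=1) == 1)

    def test_random_design_reproducible_and_in_bounds(self):
        a = build_design(RANGES, "random", 250, seed=5)
        b = build_design(RANGES, "random", 250, seed=5)
        assert a.n == 250
        assert np.array_equal(a.fractions, b.fractions)
        assert a.fractions.min() >= 0.5 and a.fractions.max() <= 2.0

    def test_log_uniform_median_near_geometric_midpoint(self):
        d = build_design(RANGES, "random", 4000, seed=1)
        med = np.median(d.fractions, axis=0)
        assert np.all(np.abs(np.log(med)) < 0.1)

    def test_inhibition_mean_reduction(self):
        d = build_design(RANGES, "inhibition", 250, seed=2,
                         inhibition={"parameter": "p2",
                                     "mean_reduction_frac": 0.40,
                                     "half_width_frac": 0.2})
        col = d.fractions[:, 1]
        assert col.mean() == pytest.approx(0.60, rel=0.02)
        assert col.min() >= 0.4 and col.max() <= 0.8

    def test_inhibition_70pct_lies_below_training_range(self):
        d = build_design(RANGES, "inhibition", 250, seed=3,
                         inhibition={"parameter": "p1",
                                     "mean_reduction_frac": 0.70,
                                     "half_width_frac": 0.2})
        assert d.fractions[:, 0].max() < 0.5

    def test_inhibition_unknown_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            build_design(RANGES, "inhibition", 10, seed=0,
                         inhibition={"parameter": "nope",
                                     "mean_reduction_frac": 0.4})

    @pytest.mark.parametrize("mode,n", [("grid", 1), ("random", 0)])
    def test_size_preconditions(self, mode, n):
        with pytest.raises(ConfigurationError):
            build_design(RANGES, mode, n)


class TestGeneration:
    def test_single_baseline_point_matches_direct_solve(self, variants):
        from episurf.cellmodel import solve_steady_state
        v = variants["mtal_male"]
        d = build_design(default_ranges(v), "random", 1, seed=0)
        # overwrite with the exact baseline vector
        d.fractions[0, :] = 1.0
        ds = generate_dataset(v, d)
        st = solve_steady_state(v)
        row = ds.table.iloc[0]
        assert row["Na_cell"] == pytest.approx(st.cytosol.concentrations["Na"], rel=1e-9)
        assert row["Va"] == pytest.approx(st.Va, rel=1e-9)
        assert row["J_K_trans"] == pytest.approx(st.fluxes.basolateral["K"], rel=1e-9)

    def test_generation_deterministic(self, variants):
        v = variants["mtal_male"]
        d = build_design(default_ranges(v), "random", 12, seed=9)
        a = generate_dataset(v, d)
        b = generate_dataset(v, d)
        assert a.table.drop(columns="iterations").equals(
            b.table.drop(columns="iterations"))
        assert a.table["iterations"].equals(b.table["iterations"])

    def test_warm_start_beats_cold_start(self, variants):
        """Continuation along the snake path needs fewer Newton iterations
        than solving every grid point from the cold-start guess."""
        from episurf.cellmodel import apply_parameter_fractions, solve_steady_state
        v = variants["pct_male"]
        d = build_design(default_ranges(v), "grid", 5, seed=0)
        ds = generate_dataset(v, d)
        warm_mean = ds.table["iterations"].mean()
        rng = np.random.default_rng(0)
        sample = rng.choice(d.n, size=60, replace=False)
        cold_iters = []
        for i in sample:
            fr = {p: float(d.fractions[i, j])
                  for j, p in enumerate(d.param_names)}
            act, mem = apply_parameter_fractions(v, fr)
            cold_iters.append(solve_steady_state(v, act, mem).iterations)
        assert warm_mean < np.mean(cold_iters)

    def test_design_variant_mismatch_rejected(self, variants):
        d = build_design(RANGES, "random", 5, seed=0)
        with pytest.raises(ConfigurationError):
            generate_dataset(variants["pct_male"], d)


class TestDatasetIO:
    @pytest.fixture()
    def small_dataset(self, variants):
        v = variants["mtal_female"]
        d = build_design(default_ranges(v), "random", 6, seed=4)
        return generate_dataset(v, d)

    def test_round_trip(self, tmp_path, small_dataset):
        base = tmp_path / "ds"
        write_dataset(small_dataset, base)
        back = read_dataset(base)
        for col in small_dataset.table.columns:
            a = small_dataset.table[col].to_numpy()
            b = back.table[col].to_numpy()
            if a.dtype.kind == "f":
                np.testing.assert_allclose(a, b, rtol=1e-15)
            else:
                assert (a == b).all()
        assert back.metadata["variant"] == small_dataset.metadata["variant"]

    def test_tampered_row_count_detected(self, tmp_path, small_dataset):
        base = tmp_path / "ds"
        write_dataset(small_dataset, base)
        meta = json.loads(base.with_suffix(".json").read_text())
        meta["n_rows"] = 99
        base.with_suffix(".json").write_text(json.dumps(meta))
        with pytest.raises(FormatError, match="row count"):
            read_dataset(base)

    def test_missing_column_named_in_error(self, tmp_path, small_dataset):
        base = tmp_path / "ds"
        write_dataset(small_dataset, base)
        table = small_dataset.table.drop(columns=["Va"])
        table.to_csv(base.with_suffix(".csv"), index=False)
        with pytest.raises(FormatError, match="Va"):
            read_dataset(base)

    def test_incomplete_dataset_refused_for_release(self, small_dataset):
        ds = Dataset(table=small_dataset.table.copy(),
                     metadata=dict(small_dataset.metadata))
        ds.table.loc[0, "converged"] = False
        with pytest.raises(FormatError, match="unconverged"):
            write_dataset(ds, "/tmp/never-written")
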