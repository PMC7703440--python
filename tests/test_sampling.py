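"""Bias templates, checklist simulation, non-detection inference, record I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, spearmanr

import sdmbias as sb
from sdmbias.errors import (
    EmptyEffortError,
    InvalidParameterError,
    ParseError,
    UnsampleableCommunityError,
)
from sdmbias.grid import simpson_evenness
from sdmbias.sampling import (
    calibrate_bias_template,
    infer_nondetections,
    read_records,
    records_frame,
    simulate_checklists,
    template_from_records,
    write_records,
)
from sdmbias.species import Community


def uniform_community(grid, prevalences, seed=0):
    """Community with prescribed prevalences, presence spread evenly."""
    rng = np.random.default_rng(seed)
    n = grid.n_cells
    presence = np.zeros((n, len(prevalences)), dtype=np.uint8)
    for j, p in enumerate(prevalences):
        k = int(round(p * n))
        presence[rng.choice(n, size=k, replace=False), j] = 1
    return Community(presence=presence)


class TestBiasTemplateCalibration:
    def test_no_bias_is_uniform(self, small_grid):
        t = calibrate_bias_template(small_grid, 1.0, seed=0, label="none")
        assert np.all(t.relative_weight == 1.0)
        assert t.evenness == 1.0

    def test_reaches_low_evenness_target(self, small_grid):
        t = calibrate_bias_template(small_grid, 0.1, seed=2, tol=0.01)
        assert t.evenness == pytest.approx(0.1, abs=0.01)
        assert t.relative_weight.max() == pytest.approx(1.0)

    def test_evenness_decreases_with_gamma(self, small_grid):
        z = sb.gaussian_field(small_grid, 50.0, 3)
        evs = [simpson_evenness(np.exp(g * (z - z.max()))).evenness
               for g in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(b < a for a, b in zip(evs, evs[1:]))

    def test_unreachable_target(self, small_grid):
        with pytest.raises(InvalidParameterError):
            calibrate_bias_template(small_grid, 1.0 / small_grid.n_cells,
                                    seed=0)

    def test_anchored_template_correlates_with_anchor(self, small_grid):
        anchor = sb.gaussian_field(small_grid, 40.0, 11)
        t = calibrate_bias_template(small_grid, 0.3, seed=5, anchor=anchor)
        rho = spearmanr(anchor, t.relative_weight).statistic
        assert rho > 0.3


class TestTemplateFromRecords:
    def test_relative_weights(self):
        g = sb.build_grid(1, 3, 10.0)
        rec = pd.DataFrame({"cell_id": [0] * 10 + [1] * 5})
        t = template_from_records(rec, g)
        assert np.allclose(t.relative_weight, [1.0, 0.5, 0.0])

    def test_equal_counts_even(self):
        g = sb.build_grid(1, 3, 10.0)
        rec = pd.DataFrame({"cell_id": [0, 1, 2] * 4})
        t = template_from_records(rec, g)
        assert np.all(t.relative_weight == 1.0)
        assert t.evenness == pytest.approx(1.0)

    def test_single_cell_evenness_floor(self):
        g = sb.build_grid(2, 2, 10.0)
        t = template_from_records(pd.DataFrame({"cell_id": [0, 0, 0]}), g)
        assert t.evenness == pytest.approx(1.0 / 4)

    def test_empty_table(self, small_grid):
        with pytest.raises(EmptyEffortError):
            template_from_records(pd.DataFrame({"cell_id": []}), small_grid)


class TestSimulateChecklists:
    def test_single_weighted_cell_gets_all_events(self, small_grid):
        com = uniform_community(small_grid, [1.0])  # present everywhere
        w = np.zeros(small_grid.n_cells)
        w[7] = 1.0
        t = sb.BiasTemplate(relative_weight=w, evenness=np.nan)
        cl = simulate_checklists(com, t, 20, draws_per_event=1, seed=0)
        assert np.all(cl.event_cells == 7)

    def test_single_species_forced_outcome(self, small_grid):
        com = uniform_community(small_grid, [1.0])
        t = sb.BiasTemplate(relative_weight=np.ones(small_grid.n_cells),
                            evenness=1.0)
        cl = simulate_checklists(com, t, 7, draws_per_event=1, seed=1)
        assert cl.n_events == 7
        assert all(np.array_equal(d, [0]) for d in cl.detected)

    def test_detection_ratio_tracks_prevalence(self):
        # two species, prevalences 0.4 vs 0.1, both present in the only
        # sampled cell: detections should split ~4:1
        g = sb.build_grid(2, 5, 10.0)
        presence = np.zeros((10, 2), dtype=np.uint8)
        presence[:4, 0] = 1   # prevalence 0.4
        presence[0, 1] = 1    # prevalence 0.1
        com = Community(presence=presence)
        w = np.zeros(10)
        w[0] = 1.0            # only cell 0 (both present) is sampled
        t = sb.BiasTemplate(relative_weight=w, evenness=np.nan)
        cl = simulate_checklists(com, t, 2000, draws_per_event=1, seed=3)
        counts = cl.species_record_counts()
        ratio = counts[0] / counts[1]
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_empty_cells_redrawn(self, small_grid):
        com = uniform_community(small_grid, [0.25], seed=1)
        t = sb.BiasTemplate(relative_weight=np.ones(small_grid.n_cells),
                            evenness=1.0)
        cl = simulate_checklists(com, t, 50, draws_per_event=1, seed=2)
        occupied = np.flatnonzero(com.presence[:, 0])
        assert set(cl.event_cells).issubset(set(occupied))
        assert cl.n_empty_redraws > 0

    def test_unsampleable_community(self, small_grid):
        com = uniform_community(small_grid, [0.25], seed=1)
        w = np.zeros(small_grid.n_cells)
        empty = np.flatnonzero(com.presence[:, 0] == 0)
        w[empty[0]] = 1.0
        t = sb.BiasTemplate(relative_weight=w, evenness=np.nan)
        with pytest.raises(UnsampleableCommunityError):
            simulate_checklists(com, t, 5, seed=0)

    def test_effort_follows_template_weights(self):
        # chi-square goodness of fit of event locations to the template
        g = sb.build_grid(5, 5, 10.0)
        com = uniform_community(g, [1.0])
        t = calibrate_bias_template(g, 0.5, seed=4, tol=0.01)
        cl = simulate_checklists(com, t, 10_000, draws_per_event=1, seed=5)
        counts = np.bincount(cl.event_cells, minlength=25)
        expected = t.relative_weight / t.relative_weight.sum() * cl.n_events
        assert chisquare(counts, expected).pvalue > 0.01

    def test_record_evenness_approaches_template_evenness(self):
        g = sb.build_grid(5, 5, 10.0)
        com = uniform_community(g, [1.0])
        t = calibrate_bias_template(g, 0.35, seed=6, tol=0.01)
        cl = simulate_checklists(com, t, 50_000, draws_per_event=1, seed=7)
        e = simpson_evenness(cl.record_counts_by_cell(g)).evenness
        assert e == pytest.approx(t.evenness, abs=0.05)


class TestDetectionMatrix:
    def test_nondetection_inference_row(self, small_grid):
        com = uniform_community(small_grid, [1.0, 1.0], seed=2)
        w = np.ones(small_grid.n_cells)
        t = sb.BiasTemplate(relative_weight=w, evenness=1.0)
        cl = simulate_checklists(com, t, 10, draws_per_event=1, seed=0)
        mat = infer_nondetections(cl, [0, 1])
        for i, det in enumerate(cl.detected):
            row = np.zeros(2, dtype=np.uint8)
            row[det] = 1
            assert np.array_equal(mat.matrix[i], row)

    def test_disjoint_modeled_set_all_zero(self, small_grid):
        com = uniform_community(small_grid, [1.0, 0.5], seed=2)
        t = sb.BiasTemplate(relative_weight=np.ones(small_grid.n_cells),
                            evenness=1.0)
        cl = simulate_checklists(com, t, 10, draws_per_event=1, seed=0)
        only_sp1 = [i for i, d in enumerate(cl.detected)
                    if np.array_equal(d, [0])]
        mat = infer_nondetections(cl, [1])
        assert np.all(mat.matrix[only_sp1] == 0)

    def test_column_sums_conserve_records(self, small_community, small_grid):
        t = sb.BiasTemplate(relative_weight=np.ones(small_grid.n_cells),
                            evenness=1.0)
        cl = simulate_checklists(small_community, t, 8, seed=4)
        modeled = [0, 3, 7]
        mat = infer_nondetections(cl, modeled)
        expected = cl.species_record_counts()[modeled]
        assert np.array_equal(mat.matrix.sum(axis=0), expected)


class TestRecordIO:
    def test_round_trip(self, small_community, small_grid, tmp_path):
        t = sb.BiasTemplate(relative_weight=np.ones(small_grid.n_cells),
                            evenness=1.0)
        cl = simulate_checklists(small_community, t, 6, seed=9)
        path = tmp_path / "records.csv"
        write_records(cl, small_grid, path)
        back = read_records(path, small_grid,
                            n_species=small_community.size)
        assert np.array_equal(back.event_cells, cl.event_cells)
        for a, b in zip(back.detected, cl.detected):
            assert np.array_equal(a, b)

    def test_missing_column_rejected(self, small_grid, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"event_id": [0], "cell_id": [0]}).to_csv(path,
                                                               index=False)
        with pytest.raises(ParseError):
            read_records(path, small_grid)

    def test_malformed_species_value(self, small_grid, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"event_id": [0], "cell_id": [0],
                      "species": ["spix"], "surrogate_date": ["2000-01-01"],
                      "observer": ["obs0"]}).to_csv(path, index=False)
        with pytest.raises(ParseError, match="line"):
            read_records(path, small_grid)

    def test_records_frame_shape(self, small_community, small_grid):
        t = sb.BiasTemplate(relative_weight=np.ones(small_grid.n_cells),
                            evenness=1.0)
        cl = simulate_checklists(small_community, t, 5, seed=2)
        frame = records_frame(cl, small_grid)
        assert len(frame) == cl.total_records
        assert list(frame.columns) == ["event_id", "cell_id", "species",
                                       "surrogate_date", "observer"]
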