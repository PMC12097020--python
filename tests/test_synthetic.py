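"""Generator correctness: determinism, planted structure, closed forms."""

import numpy as np
import pandas as pd
import pytest

from covpanel import (
    ConfigurationError,
    SimConfig,
    simulate_cohort,
    simulate_spatial_organoid,
    simulate_trajectories,
)


def _tiny(seed=0, **kw):
    base = dict(
        seed=seed,
        n_patients=2,
        cells_per_patient=200,
        n_background_genes=20,
        genes_detected_mean=10,
        genes_detected_sd=2,
        frac_qc_violators=0.0,
        t_cell_count=50,
        n_timepoints=4,
    )
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_identical_outputs():
    c1, t1 = simulate_cohort(_tiny(seed=5))
    c2, t2 = simulate_cohort(_tiny(seed=5))
    for pid in c1:
        assert (c1[pid].X != c2[pid].X).nnz == 0
        pd.testing.assert_frame_equal(c1[pid].obs, c2[pid].obs)
        pd.testing.assert_frame_equal(t1.flags[pid], t2.flags[pid])
    s1 = simulate_spatial_organoid(_tiny(seed=5))
    s2 = simulate_spatial_organoid(_tiny(seed=5))
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(
        simulate_trajectories(_tiny(seed=5)), simulate_trajectories(_tiny(seed=5))
    )


def test_different_seed_differs():
    c1, _ = simulate_cohort(_tiny(seed=1))
    c2, _ = simulate_cohort(_tiny(seed=2))
    assert (c1["P01"].X != c2["P01"].X).nnz > 0


def test_adding_a_patient_does_not_perturb_earlier_patients():
    c2, t2 = simulate_cohort(_tiny(n_patients=2))
    c3, t3 = simulate_cohort(_tiny(n_patients=3))
    assert (c2["P01"].X != c3["P01"].X).nnz == 0
    pd.testing.assert_frame_equal(t2.flags["P02"], t3.flags["P02"])


def test_zero_positivity_probs_yield_zero_positives():
    cfg = _tiny(
        subclones_per_patient=1,
        subclone_weights=[1.0],
        positivity_probs=np.zeros((2, 1, 9)),
    )
    cohort, truth = simulate_cohort(cfg)
    for pid in cohort:
        assert not truth.flags[pid].to_numpy().any()
        # antigen genes are the first 9 columns: all-zero counts
        assert cohort[pid].X[:, :9].nnz == 0


def test_two_antigen_coverage_matches_closed_form():
    """p(a)=p(b)=0.5 independent: union coverage 0.75 within 3 binomial SEs."""
    probs = np.zeros((1, 1, 9))
    probs[0, 0, :2] = 0.5
    cfg = _tiny(n_patients=1, cells_per_patient=10_000, positivity_probs=probs,
                subclones_per_patient=1, subclone_weights=[1.0])
    _, truth = simulate_cohort(cfg)
    panel = list(cfg.antigens[:2])
    assert truth.expected_coverage(panel, "P01") == pytest.approx(0.75)
    emp = truth.empirical_coverage(panel, "P01")
    se = np.sqrt(0.75 * 0.25 / 10_000)
    assert abs(emp - 0.75) < 3 * se


def test_expected_coverage_monotone_in_panel_size():
    cfg = _tiny()
    _, truth = simulate_cohort(cfg)
    bank = list(cfg.antigens)
    prev = 0.0
    for k in range(1, len(bank) + 1):
        cov = truth.expected_coverage(bank[:k], "P01")
        assert cov >= prev - 1e-12
        prev = cov


def test_true_positive_survives_dropout_with_nonzero_count():
    """Observed antigen count is nonzero iff the transcript survived; the
    survival rate matches 1 - dropout_rate."""
    probs = np.full((1, 1, 9), 1.0)  # every cell truly positive for all
    cfg = _tiny(n_patients=1, cells_per_patient=4000, dropout_rate=0.3,
                positivity_probs=probs, subclones_per_patient=1,
                subclone_weights=[1.0])
    cohort, _ = simulate_cohort(cfg)
    observed = (cohort["P01"].X[:, :9].toarray() > 0).mean()
    se = np.sqrt(0.7 * 0.3 / (4000 * 9))
    assert abs(observed - 0.7) < 4 * se


def test_qc_violators_recorded_and_constructed():
    cfg = _tiny(frac_qc_violators=0.1, n_background_genes=3000,
                genes_detected_mean=1000, genes_detected_sd=100)
    cohort, truth = simulate_cohort(cfg)
    for pid, adata in cohort.items():
        planted = truth.qc_violators[pid]
        assert len(planted) == 20  # 10% of 200
        obs = adata.obs.loc[planted["barcode"]]
        for _, row in planted.iterrows():
            cell = adata.obs.loc[row["barcode"]]
            if row["rule"] == "high_mito":
                assert cell["mito_fraction"] > 0.20
            elif row["rule"] == "low_genes":
                assert cell["detected_genes"] < 200
            else:
                assert cell["detected_genes"] > 2500
        # non-violators violate nothing
        others = adata.obs.drop(planted["barcode"])
        assert (others["mito_fraction"] <= 0.20).all()
        assert others["detected_genes"].between(200, 2500).all()
        assert (obs.index == planted["barcode"]).all()


def test_invalid_simplex_weights_rejected():
    with pytest.raises(ConfigurationError):
        _tiny(subclones_per_patient=2, subclone_weights=[0.7, 0.7])


def test_detected_genes_matches_matrix():
    cohort, _ = simulate_cohort(_tiny())
    a = cohort["P01"]
    np.testing.assert_array_equal(
        a.obs["detected_genes"].to_numpy(),
        np.asarray((a.X > 0).sum(axis=1)).ravel(),
    )


# --- spatial ---------------------------------------------------------------

def test_spatial_no_t_cells_only_tumor_rows():
    table = simulate_spatial_organoid(_tiny(t_cell_count=0))
    assert (table["class"] == "tumor").all()


def test_spatial_tumor_cells_inside_disc():
    cfg = _tiny(spatial_radius_um=300.0)
    table = simulate_spatial_organoid(cfg)
    r = np.hypot(table["x"], table["y"])
    assert (r <= 300.0 + 1e-9).all()


def test_spatial_uniform_mode_constant_density_across_rings():
    """Uniform placement: counts per ring proportional to ring area."""
    cfg = _tiny(t_cell_count=5000, spatial_radius_um=300.0)
    table = simulate_spatial_organoid(cfg)
    t = table[table["class"] == "t_cell"]
    r = np.hypot(t["x"], t["y"]).to_numpy()
    edges = np.array([0, 100, 200, 300.0])
    counts, _ = np.histogram(r, bins=edges)
    areas = np.pi * np.diff(edges**2)
    density = counts / areas
    expected = 5000 / (np.pi * 300.0**2)
    for d, c in zip(density, counts):
        se = np.sqrt(c) / areas[np.argmax(density == d)] if c else expected
        assert abs(d - expected) / expected < 0.15


def test_rim_mode_concentrates_t_cells_outside():
    table = simulate_spatial_organoid(_tiny(t_cell_mode="rim", t_cell_count=1000,
                                            spatial_radius_um=300.0))
    t = table[table["class"] == "t_cell"]
    r = np.hypot(t["x"], t["y"])
    assert (r >= 0.8 * 300.0 - 1e-9).all()


def test_nonpositive_radius_rejected():
    with pytest.raises(ConfigurationError):
        _tiny(spatial_radius_um=0.0)


# --- trajectories ----------------------------------------------------------

def test_zero_step_sd_gives_zero_path_lengths():
    tracks = simulate_trajectories(_tiny(walk_step_sd_um=0.0))
    for _, g in tracks.groupby("cell_id"):
        assert np.allclose(np.diff(g[["x", "y"]], axis=0), 0)


def test_trajectory_shape_and_time_order():
    cfg = _tiny(t_cell_count=7, n_timepoints=6)
    tracks = simulate_trajectories(cfg)
    sizes = tracks.groupby("cell_id").size()
    assert (sizes == 6).all() and len(sizes) == 7
    for _, g in tracks.groupby("cell_id"):
        assert g["time_h"].is_monotonic_increasing


def test_mean_path_length_matches_rayleigh_expectation():
    """100 Gaussian steps of per-axis SD 1 µm: mean path = 100*sqrt(pi/2)."""
    cfg = _tiny(t_cell_count=2000, n_timepoints=101, walk_step_sd_um=1.0)
    tracks = simulate_trajectories(cfg)
    lengths = (
        tracks.sort_values(["cell_id", "time_h"])
        .groupby("cell_id")[["x", "y"]]
        .apply(lambda g: np.hypot(*np.diff(g.to_numpy(), axis=0).T).sum())
    )
    expected = 100 * np.sqrt(np.pi / 2)
    per_path_var = 100 * (2 - np.pi / 2)
    se = np.sqrt(per_path_var / 2000)
    assert abs(lengths.mean() - expected) < 3 * se


def test_too_few_timepoints_rejected():
    with pytest.raises(ConfigurationError):
        simulate_trajectories(_tiny(n_timepoints=1))
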