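import dataclasses

import numpy as np
import pytest
from scipy import stats

from ki67assay._seeds import child_rng
from ki67assay.concordance import correlations
from ki67assay.survival import logrank
from ki67assay.synthetic import (
    CellMap,
    CohortConfig,
    HistologyConfig,
    Nucleus,
    RaterModel,
    expected_event_rate,
    generate_cellmap,
    generate_cohort,
    generate_paired_scores,
    render_field,
    sample_histology_config,
)


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------


def test_child_streams_are_reproducible_and_independent():
    a1 = child_rng(7, "x").random(5)
    a2 = child_rng(7, "x").random(5)
    b = child_rng(7, "y").random(5)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)


# ---------------------------------------------------------------------------
# cell maps
# ---------------------------------------------------------------------------


def test_theta_zero_gives_zero_fraction():
    m = generate_cellmap(HistologyConfig(theta=0.0), seed=1)
    assert m.true_ki67_fraction == 0.0


def test_theta_one_gives_unit_fraction():
    m = generate_cellmap(HistologyConfig(theta=1.0), seed=1)
    assert m.true_ki67_fraction == 1.0


def test_fraction_within_binomial_band():
    # ~2000 tumor cells at theta = 0.10; realized fraction must sit inside the
    # exact binomial 99% band (oracle: binomial quantiles).
    cfg = HistologyConfig(
        theta=0.10, tumor_density=7600.0, width=1024, height=1024
    )
    m = generate_cellmap(cfg, seed=5)
    n = len(m.tumor_nuclei)
    assert n > 1500
    lo = stats.binom.ppf(0.005, n, 0.10) / n
    hi = stats.binom.ppf(0.995, n, 0.10) / n
    assert lo <= m.true_ki67_fraction <= hi


def test_generation_is_bit_reproducible():
    cfg = HistologyConfig(theta=0.3)
    assert generate_cellmap(cfg, seed=9).to_dict() == generate_cellmap(cfg, seed=9).to_dict()
    assert generate_cellmap(cfg, seed=9).to_dict() != generate_cellmap(cfg, seed=10).to_dict()


def test_zero_tumor_density_sets_degenerate_flag():
    m = generate_cellmap(HistologyConfig(tumor_density=0.0), seed=2)
    assert m.degenerate
    assert m.true_ki67_fraction is None


def test_nuclei_inside_extent_and_disjoint(clean_map):
    xy = np.array([n.center for n in clean_map.nuclei])
    r = np.array([n.radius for n in clean_map.nuclei])
    assert (xy[:, 0] >= 0).all() and (xy[:, 0] < clean_map.width).all()
    assert (xy[:, 1] >= 0).all() and (xy[:, 1] < clean_map.height).all()
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert (d > (r[:, None] + r[None, :])).all()


def test_mean_fraction_unbiased_over_replicates():
    # >=500 tumor cells per map; mean fraction within 3 MC SE of theta.
    cfg = HistologyConfig(theta=0.10, tumor_density=2200.0, width=1024, height=1024)
    fracs = np.array(
        [generate_cellmap(cfg, seed=s).true_ki67_fraction for s in range(400)]
    )
    se = fracs.std(ddof=1) / np.sqrt(fracs.size)
    assert abs(fracs.mean() - 0.10) < 3 * se


def test_nucleus_invariants_enforced():
    with pytest.raises(ValueError):
        Nucleus(0, (1, 1), -1.0, "invasive_tumor", False, 0.1)
    with pytest.raises(ValueError):
        Nucleus(0, (1, 1), 3.0, "invasive_tumor", True, 0.1)  # positive below floor
    with pytest.raises(ValueError):
        Nucleus(0, (1, 1), 3.0, "astrocyte", False, 0.1)


def test_cellmap_json_round_trip(tmp_path, clean_map):
    path = tmp_path / "m.json"
    clean_map.to_json(path)
    assert CellMap.from_json(path).to_dict() == clean_map.to_dict()


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def test_render_deterministic(clean_map):
    a = render_field(clean_map, 1.0)
    b = render_field(clean_map, 1.0)
    assert np.array_equal(a, b)


def test_render_empty_map_is_background_only():
    m = CellMap(64, 64, 0.5, [], seed=0, degenerate=True)
    img = render_field(m, 1.0)
    assert np.unique(img.reshape(-1, 3), axis=0).shape[0] == 1


def test_render_rejects_nonpositive_contrast(clean_map):
    with pytest.raises(ValueError):
        render_field(clean_map, 0.0)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def test_clean_scenario_returns_base_config(rng):
    base = HistologyConfig()
    cfg, name = sample_histology_config(base, rng, scenario_probs={})
    assert name == "clean" and cfg == base


def test_scenario_probs_validated(rng):
    with pytest.raises(ValueError):
        sample_histology_config(HistologyConfig(), rng, {"lymphocyte_rich": 1.5})


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def test_zero_hazard_stratum_has_zero_events():
    df = generate_cohort(CohortConfig(n_cases=300, seed=3))
    pepi0 = (
        df["pT"].isin([1, 2]) & (df["nodal"] == "N0") & (df["ki67_surgical"] <= 2.7)
    )
    assert pepi0.sum() > 20
    assert df.loc[pepi0, "relapse_event"].sum() == 0


def test_full_censoring_gives_no_events():
    df = generate_cohort(CohortConfig(n_cases=100, censoring_rate=1.0, seed=4))
    assert not df["relapse_event"].any()


def test_invalid_cohort_size_rejected():
    with pytest.raises(ValueError):
        generate_cohort(CohortConfig(n_cases=0))


def test_equal_hazards_give_null_logrank():
    # mean chi-square over replicates approaches its df (= 1)
    stats_ = []
    for s in range(150):
        cfg = CohortConfig(
            n_cases=80,
            hazard_modified_pepi0=0.004,
            hazard_le10=0.004,
            hazard_gt10=0.004,
            seed=s,
        )
        df = generate_cohort(cfg)
        groups = (df["ki67_month1"] > 10).to_numpy()
        if groups.all() or not groups.any() or df["relapse_event"].sum() == 0:
            continue
        res = logrank(df["rfs_months"], df["relapse_event"], groups)
        stats_.append(res.statistic)
    stats_ = np.array(stats_)
    se = np.sqrt(2.0 / stats_.size)  # chi2(1) variance is 2
    assert abs(stats_.mean() - 1.0) < 3 * np.sqrt(stats_.var(ddof=1) / stats_.size) + 3 * se


def test_stratum_event_rates_match_hazards():
    cfg = CohortConfig(n_cases=500, seed=8)
    df = generate_cohort(cfg)
    pepi0 = df["pT"].isin([1, 2]) & (df["nodal"] == "N0") & (df["ki67_surgical"] <= 2.7)
    gt10 = ~pepi0 & (df["ki67_month1"] > 10)
    le10 = ~pepi0 & ~gt10
    for mask, hazard in ((pepi0, cfg.hazard_modified_pepi0),
                         (gt10, cfg.hazard_gt10), (le10, cfg.hazard_le10)):
        n = int(mask.sum())
        if n == 0:
            continue
        p = expected_event_rate(cfg, hazard)
        observed = int(df.loc[mask, "relapse_event"].sum())
        assert stats.binom.ppf(0.005, n, p) <= observed <= stats.binom.ppf(0.995, n, p)


def test_cohort_reproducible():
    a = generate_cohort(CohortConfig(n_cases=50, seed=6))
    b = generate_cohort(CohortConfig(n_cases=50, seed=6))
    assert a.equals(b)


# ---------------------------------------------------------------------------
# paired rater scores
# ---------------------------------------------------------------------------


def test_noiseless_large_count_converges_to_truth():
    model = RaterModel(sigma_field=0.0, cells_counted=100_000, seed=1)
    pairs = generate_paired_scores([0.3, 0.07], model, model)
    for theta in (0.3, 0.07):
        row = pairs.iloc[[0.3, 0.07].index(theta)]
        assert abs(row["score_a"] - 100 * theta) < 0.5
        assert abs(row["score_b"] - 100 * theta) < 0.5


def test_exact_theta_endpoints():
    model = RaterModel(seed=2)
    pairs = generate_paired_scores([0.0, 1.0], model, model)
    assert pairs["score_a"].tolist() == [0.0, 100.0]
    assert pairs["score_b"].tolist() == [0.0, 100.0]


def test_default_calibration_hits_spearman_band(rng):
    # default sigma/cells on the default mixture: Spearman in [0.85, 0.95]
    from ki67assay.synthetic import default_theta_mixture

    rhos = []
    for s in range(12):
        thetas = default_theta_mixture(60, np.random.default_rng(s))
        pairs = generate_paired_scores(
            thetas, RaterModel(seed=2 * s), RaterModel(seed=2 * s + 1)
        )
        rhos.append(correlations(pairs)[1])
    assert 0.85 <= np.mean(rhos) <= 0.95


def test_rater_model_validation():
    with pytest.raises(ValueError):
        RaterModel(sigma_field=-0.1).validate()
    with pytest.raises(ValueError):
        RaterModel(cells_counted=0).validate()
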