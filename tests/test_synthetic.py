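"""The synthetic-cohort generator: geometry, point processes, markers, survival."""
import math

import numpy as np
import pytest
import shapely

from tampol.errors import GenerationError
from tampol.synthetic import (
    SimConfig, SurvivalModel, _apply_attraction, assign_marker_intensities,
    assign_planted_classes, config_from_dict, config_to_dict,
    generate_cohort, generate_core_geometry, sample_cells, simulate_survival,
)


def test_degenerate_epithelium_fraction_rejected():
    cfg = SimConfig(epithelium_fraction={"tumour_centre": 0.0, "invasive_margin": 0.3})
    with pytest.raises(GenerationError):
        cfg.validate()
    with pytest.raises(GenerationError):
        generate_core_geometry(cfg, np.random.default_rng(0), "tumour_centre")


def test_core_disc_area_is_quarter_pi(rng):
    g = generate_core_geometry(SimConfig(), rng, "tumour_centre")
    total = g.area_epithelium_mm2 + g.area_stroma_mm2
    assert total == pytest.approx(math.pi / 4, rel=2e-3)
    assert total == pytest.approx(g.core.area / 1e6)  # areas sum to the disc area


def test_epithelium_fraction_hit_across_seeds():
    cfg = SimConfig()
    for seed in range(20):
        g = generate_core_geometry(cfg, np.random.default_rng(seed), "invasive_margin")
        frac = g.area_epithelium_mm2 / (g.area_epithelium_mm2 + g.area_stroma_mm2)
        assert abs(frac - 0.30) <= 0.05
        # polygon-measure oracle: reported area equals the shapely measure
        assert g.area_epithelium_mm2 == pytest.approx(g.epithelium.area / 1e6)


def test_zero_intensity_yields_zero_cells(rng):
    cfg = SimConfig()
    cfg.cell_intensity_per_mm2 = {k: 0.0 for k in cfg.cell_intensity_per_mm2}
    g = generate_core_geometry(cfg, rng, "tumour_centre")
    cells = sample_cells(g, cfg, rng, "first_metastasis")
    assert len(cells) == 0


def test_poisson_counts_unbiased():
    """Mean count over seeds matches intensity x area within 3 standard errors."""
    cfg = SimConfig()
    g = generate_core_geometry(cfg, np.random.default_rng(99), "tumour_centre")
    area = g.area_epithelium_mm2 + g.area_stroma_mm2
    rate = 700.0
    cfg.cell_intensity_per_mm2 = {
        k: (rate if k[0] == "tumour" else 0.0) for k in cfg.cell_intensity_per_mm2}
    # same per-compartment rate -> homogeneous over the whole core
    n_rep = 200
    counts = [len(sample_cells(g, cfg, np.random.default_rng(s), "first_metastasis"))
              for s in range(n_rep)]
    expected = rate * area  # ~ 550 for a 1-mm core
    se = math.sqrt(expected / n_rep)
    assert abs(np.mean(counts) - expected) <= 3 * se


def test_cell_compartments_match_geometry_oracle(rng):
    cfg = SimConfig()
    g = generate_core_geometry(cfg, rng, "tumour_centre")
    cells = sample_cells(g, cfg, rng, "first_metastasis")
    in_epi = shapely.contains_xy(g.epithelium, cells["x_um"].to_numpy(),
                                 cells["y_um"].to_numpy())
    assert (np.where(in_epi, "epithelium", "stroma") == cells["compartment"]).all()


def test_attraction_moves_macrophages_closer_and_relabels(rng):
    from scipy.spatial import cKDTree
    cfg = SimConfig()
    g = generate_core_geometry(cfg, rng, "tumour_centre")
    cells = sample_cells(g, cfg, rng, "first_metastasis")
    mac = cells["phenotype"] == "macrophage"
    planted = assign_planted_classes(int(mac.sum()), (0.25, 0.5, 0.25), rng)
    tum_xy = cells.loc[cells["phenotype"] == "tumour", ["x_um", "y_um"]].to_numpy()
    before, _ = cKDTree(tum_xy).query(cells.loc[mac, ["x_um", "y_um"]].to_numpy())
    moved = _apply_attraction(cells, planted, g, cfg, rng)
    after, _ = cKDTree(tum_xy).query(moved.loc[mac, ["x_um", "y_um"]].to_numpy())
    assert (after <= before + 1e-9).all()
    assert np.median(after[planted == "M1"]) < np.median(after[planted == "M2"])
    in_epi = shapely.contains_xy(g.epithelium, moved["x_um"].to_numpy(),
                                 moved["y_um"].to_numpy())
    assert (np.where(in_epi, "epithelium", "stroma") == moved["compartment"]).all()


def test_zero_log_sd_gives_deterministic_intensities(rng):
    cfg = SimConfig()
    cfg.marker_model = {
        "M1": {m: (2.0, 0.0) for m in ("CD86", "HLADR", "CD163", "MRC1")},
        "mixed": {m: (1.0, 0.0) for m in ("CD86", "HLADR", "CD163", "MRC1")},
        "M2": {m: (0.5, 0.0) for m in ("CD86", "HLADR", "CD163", "MRC1")},
        "CD68_macrophage": (3.0, 0.0), "KRT_tumour": (4.0, 0.0),
        "background": (0.0, 0.0),
    }
    g = generate_core_geometry(cfg, rng, "tumour_centre")
    cells = sample_cells(g, cfg, rng, "first_metastasis")
    mac = (cells["phenotype"] == "macrophage").to_numpy()
    planted = np.full(len(cells), None, dtype=object)
    planted[mac] = "M1"
    out = assign_marker_intensities(cells, planted, cfg, rng)
    assert out.loc[mac, "CD86"].to_numpy() == pytest.approx(math.exp(2.0))
    assert out.loc[mac, "CD68"].to_numpy() == pytest.approx(math.exp(3.0))
    assert out.loc[~mac, "CD86"].to_numpy() == pytest.approx(1.0)


def test_exponential_survival_moments(rng):
    model = SurvivalModel(baseline_rate_per_day=1 / 500, censor_high_days=math.inf)
    t, e = simulate_survival(np.zeros(1000), model, rng)
    assert e.all()  # infinite censoring window observes every event
    assert abs(np.mean(t) - 500) <= 3 * 500 / math.sqrt(1000)


def test_survival_hazard_ordering_between_groups(rng):
    model = SurvivalModel(baseline_rate_per_day=1 / 500, censor_high_days=math.inf)
    lp = np.repeat([0.0, math.log(3)], 2000)
    t, _ = simulate_survival(lp, model, rng)
    assert np.mean(t[2000:]) < np.mean(t[:2000])
    assert np.mean(t[:2000]) / np.mean(t[2000:]) == pytest.approx(3.0, rel=0.15)


def test_cohort_shape_and_truth_alignment():
    coh = generate_cohort(SimConfig(n_patients=5, seed=11))
    assert len(coh.clinical) == 5
    assert len(coh.samples) == 10  # primary + first metastasis per patient
    assert len(coh.cores) == 40    # 2 regions x 2 cores x 10 samples
    n_mac = sum(1 for c in coh.cores for cell in c.cells
                if cell.phenotype == "macrophage")
    assert len(coh.truth_cells) == n_mac
    assert set(coh.truth_patients["patient_id"]) == {r.patient_id for r in coh.clinical}


def test_same_seed_gives_byte_identical_exports(tmp_path):
    for d in ("a", "b"):
        generate_cohort(SimConfig(n_patients=2, seed=5)).to_csv(tmp_path / d)
    for name in ("cells.csv", "areas.csv", "clinical.csv", "samples.csv",
                 "truth_cells.csv", "truth_patients.csv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_adding_patients_preserves_earlier_ones(tmp_path):
    small = generate_cohort(SimConfig(n_patients=2, seed=5))
    big = generate_cohort(SimConfig(n_patients=3, seed=5))
    a = small.cores[0]
    b = big.cores[0]
    assert a.core_id == b.core_id and len(a.cells) == len(b.cells)
    assert a.cells[0].intensity == b.cells[0].intensity


def test_config_dict_round_trip():
    cfg = SimConfig(n_patients=9, seed=42)
    back = config_from_dict(config_to_dict(cfg))
    assert back == cfg
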