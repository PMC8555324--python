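"""Comparison orchestration, QA study and report rendering."""
import copy
import json

import numpy as np
import pandas as pd
import pytest

from beammatch.config import BeamLineConfig, GantryPerturbation
from beammatch.report import (
    QA_CRITERIA,
    optics_summary,
    paired_model_stats,
    qa_table,
    render_report,
    run_idd_comparison,
    run_optics_comparison,
    run_qa_study,
)
from beammatch.synthetic import NominalEnergyGrid, simulate_gantry

from oracles import textbook_paired_t, textbook_pearson


@pytest.fixture(scope="module")
def gantry_pair(config):
    grid = NominalEnergyGrid(np.array([70.0, 150.0, 226.09]))
    a = simulate_gantry("G2", GantryPerturbation(dose_noise=0.002, spot_jitter_mm=0.1),
                        config, seed=11, energies=grid)
    b = simulate_gantry("G4", GantryPerturbation.matched_default(), config,
                        seed=12, energies=grid)
    return a, b


def test_idd_comparison_identical_gantries_zero_gamma(config):
    grid = NominalEnergyGrid(np.array([100.0, 180.0]))
    a = simulate_gantry("G2", GantryPerturbation(), config, seed=1, energies=grid,
                        include_spot_planes=False)
    rows = run_idd_comparison(a, copy.deepcopy(a))
    cross = rows[rows.gantry == "cross"]
    assert np.allclose(cross.mean_gamma, 0.0)
    assert np.all(cross.passing_rate == 100.0)


def test_idd_comparison_intra_gantry_passes(gantry_pair):
    """Measured vs spectrum-reconstructed curves pass 1 mm/1% at every energy."""
    rows = run_idd_comparison(*gantry_pair)
    intra = rows[rows.kind == "measured-vs-computed"]
    assert len(intra) == 6  # 3 energies x 2 gantries
    assert np.all(intra.passing_rate == 100.0)
    assert intra.mean_gamma.max() < 0.2


def test_idd_comparison_model_residual_inflates_computed_differences(config):
    """When the basis is too coarse to represent a small cross-gantry range
    offset, the reconstruction distortion adds to the real difference, so
    computed-computed disagreement exceeds measured-measured disagreement."""
    grid = NominalEnergyGrid(np.array([100.0, 150.0, 200.0]))
    a = simulate_gantry("G2", GantryPerturbation(), config,
                        seed=21, energies=grid, include_spot_planes=False)
    b = simulate_gantry("G4", GantryPerturbation(range_offset_mm=0.3), config,
                        seed=22, energies=grid, include_spot_planes=False)
    rows = run_idd_comparison(a, b, basis_step_mev=2.0)
    mm = rows[rows.kind == "measured-vs-measured"].mean_gamma.mean()
    cc = rows[rows.kind == "computed-vs-computed"].mean_gamma.mean()
    assert cc > mm


def test_optics_comparison_identical_gantries(config):
    grid = NominalEnergyGrid(np.array([150.0]))
    a = simulate_gantry("G2", GantryPerturbation(), config, seed=2, energies=grid)
    rows = run_optics_comparison(a, copy.deepcopy(a))
    cross = rows[rows.kind.isin(["cross-measured", "cross-computed"])]
    assert np.allclose(cross.sigma_rel_diff_pct, 0.0, atol=1e-9)
    mom = rows[rows.kind == "cross-moments"]
    assert np.allclose(mom[["dA_pct", "dB_pct", "dC_pct"]].to_numpy(float), 0.0, atol=1e-9)


def test_optics_comparison_envelope_and_summary(gantry_pair):
    rows = run_optics_comparison(*gantry_pair)
    cross = rows[rows.kind == "cross-measured"]
    # generator envelope: isocenter sigma differences within +/-10%
    assert np.all(np.abs(cross.sigma_rel_diff_pct) <= 10.0)
    summ = optics_summary(rows)
    one = summ[(summ.kind == "cross-measured") & (summ.metric == "sigma_rel_diff_pct")]
    v = cross.sigma_rel_diff_pct
    assert one["mean"].iloc[0] == pytest.approx(v.mean())
    assert one["min"].iloc[0] == pytest.approx(v.min())
    assert one["max"].iloc[0] == pytest.approx(v.max())


def test_qa_study_zero_perturbation_all_pass():
    perts = {"G2": GantryPerturbation(), "G4": GantryPerturbation()}
    rec = run_qa_study(n_per_cohort=2, perturbations=perts, seed=0,
                       cohorts=("prostate",))
    assert set(rec.arm) == {"M2G2", "M2G4", "M4G2", "M4G4"}
    assert np.all(rec.passing_rate == 100.0)


@pytest.fixture(scope="module")
def qa_records():
    return run_qa_study(n_per_cohort=4, seed=5, cohorts=("prostate", "lung"))


def test_qa_criteria_monotonicity(qa_records):
    """3 mm/3% never passes fewer points than 2 mm/3%, plan by plan."""
    wide = qa_records.pivot_table(
        index=["plan_id", "arm"], columns="criteria", values="passing_rate"
    )
    assert np.all(wide["3mm/3%"] >= wide["2mm/3%"])


def test_qa_table_aggregation(qa_records):
    tbl = qa_table(qa_records)
    row = tbl[(tbl.arm == "M2G2") & (tbl.cohort == "prostate") & (tbl.criteria == "3mm/3%")]
    sub = qa_records.query(
        "arm == 'M2G2' and cohort == 'prostate' and criteria == '3mm/3%'"
    ).passing_rate
    assert row.mean_passing_rate.iloc[0] == pytest.approx(sub.mean())
    assert row["min"].iloc[0] == sub.min() and row["max"].iloc[0] == sub.max()


def test_paired_stats_against_textbook_formulas(qa_records):
    stats = paired_model_stats(qa_records, ("M2G2", "M4G2"))
    grp = qa_records.query("cohort == 'prostate' and criteria == '3mm/3%'")
    x = grp[grp.arm == "M2G2"].set_index("plan_id").passing_rate
    y = grp[grp.arm == "M4G2"].set_index("plan_id").passing_rate.reindex(x.index)
    t_o, p_o = textbook_paired_t(x, y)
    r_o = textbook_pearson(x, y)
    row = stats[(stats.cohort == "prostate") & (stats.criteria == "3mm/3%")].iloc[0]
    assert row.t == pytest.approx(t_o, rel=1e-9)
    assert row.p == pytest.approx(p_o, rel=1e-9)
    assert row.pearson_r == pytest.approx(r_o, rel=1e-9)
    assert row.mean_diff_pct == pytest.approx(float((x - y).mean()), abs=1e-12)


def test_paired_stats_self_comparison(qa_records):
    doubled = pd.concat(
        [qa_records, qa_records.assign(arm=qa_records.arm.str.replace("M2", "M9"))]
    )
    stats = paired_model_stats(doubled, ("M2G2", "M9G2"))
    assert np.allclose(stats.mean_diff_pct, 0.0)
    assert np.allclose(stats.pearson_r, 1.0)


def test_paired_stats_errors(qa_records):
    broken = qa_records[~((qa_records.arm == "M4G2") & (qa_records.plan_id == "prostate-01"))]
    with pytest.raises(ValueError):
        paired_model_stats(broken, ("M2G2", "M4G2"))


def test_paired_stats_null_calibration():
    """Two independent noise-only arms are not flagged significant too often."""
    rng = np.random.default_rng(77)
    n_sig = 0
    for _ in range(100):
        rates_a = 98.0 + rng.normal(0, 0.8, 12)
        rates_b = 98.0 + rng.normal(0, 0.8, 12)
        rec = pd.DataFrame(
            {
                "plan_id": [f"p{i}" for i in range(12)] * 2,
                "cohort": "prostate",
                "criteria": "3mm/3%",
                "arm": ["A1"] * 12 + ["A2"] * 12,
                "passing_rate": np.concatenate([rates_a, rates_b]),
            }
        )
        p = paired_model_stats(rec, ("A1", "A2")).p.iloc[0]
        n_sig += p <= 0.05
    assert n_sig <= 10  # p > 0.05 in at least 90% of null replicates


def test_render_report_roundtrip_and_determinism(tmp_path, qa_records):
    stats = paired_model_stats(qa_records, ("M2G2", "M4G2"))
    cfg = {"beamline": BeamLineConfig(), "perturbation": GantryPerturbation.qa_default()}
    out1 = tmp_path / "run1"
    out2 = tmp_path / "run2"
    for out in (out1, out2):
        render_report(out, qa_records=qa_records, qa_stats=stats, config=cfg,
                      seeds={"seed": 5})
    # identical inputs produce byte-identical tables
    for name in ("qa_records.csv", "qa_table.csv", "qa_stats.csv", "manifest.json"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    manifest = json.loads((out1 / "manifest.json").read_text())
    assert manifest["seeds"] == {"seed": 5}
    assert manifest["config"]["perturbation"]["sigma_scale"] == 1.023


def test_render_report_empty_inputs(tmp_path):
    written = render_report(tmp_path / "empty")
    for path in written:
        assert path.exists()
    idd = pd.read_csv(tmp_path / "empty" / "idd_comparison.csv")
    assert list(idd.columns) == [
        "energy", "kind", "gantry", "passing_rate", "mean_gamma", "n_evaluated"
    ]
    assert idd.empty
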