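"""Intra-/cross-gantry comparison tables, model-sharing QA study and reports.

This module orchestrates the full beam-matching analysis:

* :func:`run_idd_comparison` — per nominal energy, fit each gantry's
  effective energy spectrum, reconstruct the computed curve and run 1 mm/1 %
  gamma analysis for the three comparison kinds (measured vs computed per
  gantry; two gantries' measured curves; two gantries' computed curves).
* :func:`run_optics_comparison` — per energy and axis, extract the
  equivalent average spot at five planes, fit Gaussian sigmas and the
  free-drift moments, and tabulate intra- and cross-gantry relative
  differences of sigmas and moments.
* :func:`run_qa_study` — simulate model-sharing patient-specific QA: for each
  plan, the four model/delivery arms (M2G2, M2G4, M4G2, M4G4) are scored with
  2-D gamma at each criterion.
* :func:`paired_model_stats` — paired t-test and Pearson correlation between
  arms sharing the delivery gantry.
* :func:`render_report` — CSV tables and a JSON manifest (plus optional
  plots).

Convention: gantry A (the first argument / the lower-numbered gantry) is the
reference curve in cross-gantry gamma analyses and the denominator of
relative differences; for intra-gantry comparisons the measured distribution
is the reference and the computed one is evaluated.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .config import DetectorSpec, GantryPerturbation
from .gamma import GammaCriteria, gamma_1d, gamma_2d
from .idd import EffectiveSpectrumModel, build_basis, normalize_unity
from .optics import (
    FermiEygesModel,
    SpotPattern,
    average_spot,
    cross_sections,
    extract_spots,
    fit_gaussian,
    five_spot_pattern,
    relative_difference,
)
from .synthetic import GantryDataset, qa_field_template, simulate_qa_pair

__all__ = [
    "IDD_CRITERIA",
    "QA_CRITERIA",
    "run_idd_comparison",
    "run_optics_comparison",
    "optics_summary",
    "run_qa_study",
    "qa_table",
    "paired_model_stats",
    "render_report",
]

IDD_CRITERIA = GammaCriteria(dta_mm=1.0, dose_diff_pct=1.0)
QA_CRITERIA = (
    GammaCriteria(dta_mm=2.0, dose_diff_pct=3.0, low_dose_threshold_pct=10.0),
    GammaCriteria(dta_mm=3.0, dose_diff_pct=3.0, low_dose_threshold_pct=10.0),
)


def _criteria_label(c: GammaCriteria) -> str:
    return f"{c.dta_mm:g}mm/{c.dose_diff_pct:g}%"


def run_idd_comparison(
    gantry_a: GantryDataset,
    gantry_b: GantryDataset,
    criteria: GammaCriteria = IDD_CRITERIA,
    basis_half_width_mev: float = 10.0,
    basis_step_mev: float = 0.5,
) -> pd.DataFrame:
    """Gamma agreement of measured and spectrum-reconstructed IDD curves.

    Returns one row per (energy, comparison kind) with columns
    ``energy, kind, gantry, passing_rate, mean_gamma, n_evaluated``.
    """
    energies = sorted(gantry_a.idd_curves)
    if sorted(gantry_b.idd_curves) != energies:
        raise ValueError("gantry datasets must cover the same nominal energies")
    rows = []
    for e in energies:
        meas = {
            "A": normalize_unity(gantry_a.idd_curves[e]),
            "B": normalize_unity(gantry_b.idd_curves[e]),
        }
        comp = {}
        for label, ds in (("A", gantry_a), ("B", gantry_b)):
            basis = build_basis(
                e,
                meas[label].depth_mm,
                ds.config,
                half_width_mev=basis_half_width_mev,
                step_mev=basis_step_mev,
            )
            comp[label] = EffectiveSpectrumModel(meas[label], basis).fit().reconstruction()
        pairs = [
            ("measured-vs-computed", "A", meas["A"], comp["A"]),
            ("measured-vs-computed", "B", meas["B"], comp["B"]),
            ("measured-vs-measured", "cross", meas["A"], meas["B"]),
            ("computed-vs-computed", "cross", comp["A"], comp["B"]),
        ]
        for kind, who, ref, ev in pairs:
            res = gamma_1d(ref, ev, criteria)
            rows.append(
                {
                    "energy": e,
                    "kind": kind,
                    "gantry": who,
                    "passing_rate": res.passing_rate,
                    "mean_gamma": res.mean_gamma,
                    "n_evaluated": res.n_evaluated,
                }
            )
    return pd.DataFrame(rows)


def _gantry_optics(ds: GantryDataset, energy: float, pattern: SpotPattern):
    """Per-axis measured sigmas at the five planes and fitted FE results."""
    planes = ds.spot_planes[energy]
    if not planes:
        raise ValueError(f"gantry {ds.gantry_id} has no spot planes at {energy} MeV")
    z, sig_x, sig_y = [], [], []
    for plane in planes:
        rois = extract_spots(plane, pattern)
        eq = average_spot(rois, plane.pitch_mm)
        (px, vx), (py, vy) = cross_sections(eq)
        sig_x.append(fit_gaussian(px, vx).sigma_mm)
        sig_y.append(fit_gaussian(py, vy).sigma_mm)
        z.append(plane.z_mm)
    z = np.asarray(z)
    out = {}
    for axis, sig in (("x", np.asarray(sig_x)), ("y", np.asarray(sig_y))):
        fe = FermiEygesModel(z, sig, axis).fit()
        out[axis] = {"z": z, "sigma_meas": sig, "fe": fe}
    return out


def run_optics_comparison(
    gantry_a: GantryDataset,
    gantry_b: GantryDataset,
    pattern: SpotPattern | None = None,
    energies: list[float] | None = None,
) -> pd.DataFrame:
    """Spot-sigma and beam-optics moment comparisons per energy and axis.

    Row kinds: ``intra-A`` / ``intra-B`` (computed FE-model sigma vs measured
    sigma at the isocenter), ``cross-measured`` / ``cross-computed``
    (isocenter sigma relative difference, gantry A baseline) and
    ``cross-moments`` (relative differences of A, B, C).  Energies whose spot
    fits fail are flagged with ``error`` instead of aborting the run.
    """
    pattern = pattern or five_spot_pattern()
    energies = energies or sorted(gantry_a.spot_planes)
    rows = []
    for e in energies:
        try:
            oa = _gantry_optics(gantry_a, e, pattern)
            ob = _gantry_optics(gantry_b, e, pattern)
        except (ValueError, RuntimeError) as err:
            rows.append({"energy": e, "kind": "error", "detail": str(err)})
            continue
        for axis in ("x", "y"):
            a, b = oa[axis], ob[axis]
            i0 = int(np.argmin(np.abs(a["z"])))
            sa_meas = float(a["sigma_meas"][i0])
            sb_meas = float(b["sigma_meas"][i0])
            sa_comp = float(a["fe"].sigma_at(0.0))
            sb_comp = float(b["fe"].sigma_at(0.0))
            ma, mb = a["fe"].moments, b["fe"].moments
            rows += [
                {
                    "energy": e, "axis": axis, "kind": "intra-A",
                    "sigma_meas_mm": sa_meas, "sigma_comp_mm": sa_comp,
                    "sigma_rel_diff_pct": relative_difference(sa_comp, sa_meas),
                },
                {
                    "energy": e, "axis": axis, "kind": "intra-B",
                    "sigma_meas_mm": sb_meas, "sigma_comp_mm": sb_comp,
                    "sigma_rel_diff_pct": relative_difference(sb_comp, sb_meas),
                },
                {
                    "energy": e, "axis": axis, "kind": "cross-measured",
                    "sigma_rel_diff_pct": relative_difference(sb_meas, sa_meas),
                },
                {
                    "energy": e, "axis": axis, "kind": "cross-computed",
                    "sigma_rel_diff_pct": relative_difference(sb_comp, sa_comp),
                },
                {
                    "energy": e, "axis": axis, "kind": "cross-moments",
                    "dA_pct": relative_difference(mb.A, ma.A),
                    "dB_pct": relative_difference(mb.B, ma.B),
                    "dC_pct": relative_difference(mb.C, ma.C),
                },
            ]
    return pd.DataFrame(rows)


def optics_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean and (min-max) of every numeric comparison metric, per row kind."""
    out = []
    metrics = ["sigma_rel_diff_pct", "dA_pct", "dB_pct", "dC_pct"]
    for kind, grp in rows.groupby("kind"):
        for m in metrics:
            if m in grp.columns and grp[m].notna().any():
                v = grp[m].dropna()
                out.append(
                    {"kind": kind, "metric": m, "mean": v.mean(),
                     "min": v.min(), "max": v.max(), "n": len(v)}
                )
    return pd.DataFrame(out)


ARM_LABELS = ("M2G2", "M2G4", "M4G2", "M4G4")


def _relative_perturbation(
    delivery: GantryPerturbation, model: GantryPerturbation
) -> GantryPerturbation:
    """Mismatch of the delivered beam relative to the beam model in use."""
    return GantryPerturbation(
        range_offset_mm=delivery.range_offset_mm - model.range_offset_mm,
        spectrum_sigma_scale=delivery.spectrum_sigma_scale / model.spectrum_sigma_scale,
        sigma_scale=delivery.sigma_scale / model.sigma_scale,
        spot_jitter_mm=delivery.spot_jitter_mm,
        dose_noise=delivery.dose_noise,
        seed=delivery.seed,
    )


def run_qa_study(
    n_per_cohort: int = 12,
    perturbations: dict[str, GantryPerturbation] | None = None,
    criteria_list: tuple[GammaCriteria, ...] = QA_CRITERIA,
    seed: int = 0,
    cohorts: tuple[str, ...] = ("prostate", "lung", "NPC"),
    detector: DetectorSpec | None = None,
) -> pd.DataFrame:
    """Simulated model-sharing patient-specific QA table (Table-1 analogue).

    ``perturbations`` maps gantry label -> true machine deviation from the
    nominal beam model; the default pair is a noise-only first gantry and a
    second gantry at the matched-tolerance envelope (sigma scale 1.023,
    0.3 mm range offset).  Each plan's field is shared across all four arms,
    and both arms delivered on the same gantry share the delivery's random
    draw, as in a real measurement session.
    """
    if n_per_cohort < 2:
        raise ValueError("need at least 2 plans per cohort")
    if perturbations is None:
        perturbations = {
            "G2": GantryPerturbation(spot_jitter_mm=0.3, dose_noise=0.005),
            "G4": GantryPerturbation.qa_default(),
        }
    (g_lo, p_lo), (g_hi, p_hi) = sorted(perturbations.items())
    models = {g_lo: p_lo, g_hi: p_hi}
    detector = detector or DetectorSpec.matrixx()
    root = np.random.SeedSequence(int(seed))
    records = []
    for cohort in cohorts:
        for i in range(n_per_cohort):
            field_seq, *del_seqs = root.spawn(3)
            field = qa_field_template(cohort, np.random.default_rng(field_seq))
            plan_id = f"{cohort}-{i + 1:02d}"
            for delivered, del_seq in zip((g_lo, g_hi), del_seqs):
                for model in (g_lo, g_hi):
                    pert = _relative_perturbation(perturbations[delivered], models[model])
                    computed, measured = simulate_qa_pair(
                        field, pert, detector, rng=np.random.default_rng(del_seq)
                    )
                    for crit in criteria_list:
                        res = gamma_2d(measured, computed, crit)
                        records.append(
                            {
                                "plan_id": plan_id,
                                "cohort": cohort,
                                "model": model,
                                "delivered": delivered,
                                "arm": f"M{model[-1]}G{delivered[-1]}",
                                "criteria": _criteria_label(crit),
                                "passing_rate": res.passing_rate,
                                "mean_gamma": res.mean_gamma,
                            }
                        )
    return pd.DataFrame(records)


def qa_table(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate QA records into mean passing rate and range per arm/cohort."""
    if records.empty:
        return pd.DataFrame(
            columns=["arm", "cohort", "criteria", "mean_passing_rate", "min", "max", "n"]
        )
    grp = records.groupby(["arm", "cohort", "criteria"])["passing_rate"]
    out = grp.agg(mean_passing_rate="mean", min="min", max="max", n="count").reset_index()
    return out


def paired_model_stats(
    records: pd.DataFrame, arm_pair: tuple[str, str]
) -> pd.DataFrame:
    """Paired t-test and Pearson correlation between two QA arms (Table-2 analogue).

    The two arms must cover identical plan sets (e.g. M2G2 vs M4G2: same
    delivery gantry, different beam model).
    """
    a, b = arm_pair
    rows = []
    for (cohort, crit), grp in records.groupby(["cohort", "criteria"]):
        pa = grp[grp["arm"] == a].set_index("plan_id")["passing_rate"]
        pb = grp[grp["arm"] == b].set_index("plan_id")["passing_rate"]
        if not pa.index.sort_values().equals(pb.index.sort_values()):
            raise ValueError(f"arms {a} and {b} are not paired over the same plans")
        if len(pa) < 3:
            raise ValueError("need at least 3 paired plans for the statistics")
        pb = pb.reindex(pa.index)
        diff = pa - pb
        if np.allclose(diff, diff.iloc[0]):
            # degenerate paired sample (identical arms): t undefined, r = 1
            t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(pa, pb)
        if np.isclose(pa.std(ddof=0), 0) or np.isclose(pb.std(ddof=0), 0):
            r, rp = (1.0, 0.0) if pa.equals(pb) else (np.nan, np.nan)
        else:
            r, rp = sps.pearsonr(pa, pb)
        rows.append(
            {
                "comparison": f"{a} versus {b}",
                "cohort": cohort,
                "criteria": crit,
                "mean_diff_pct": float(diff.mean()),
                "t": float(t),
                "p": float(p),
                "pearson_r": float(r),
                "r_p": float(rp),
                "n": len(pa),
            }
        )
    return pd.DataFrame(rows)


def render_report(
    out_dir: str | Path,
    idd_rows: pd.DataFrame | None = None,
    optics_rows: pd.DataFrame | None = None,
    qa_records: pd.DataFrame | None = None,
    qa_stats: pd.DataFrame | None = None,
    config: dict | None = None,
    seeds: dict | None = None,
    plots: bool = False,
) -> list[Path]:
    """Write CSV tables, a reproducibility manifest and optional figures.

    Empty or missing tables still produce header-only CSVs so downstream
    tooling sees a stable layout.  The manifest records the package version,
    the configuration sections and every seed used.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = {
        "idd_comparison.csv": (
            idd_rows,
            ["energy", "kind", "gantry", "passing_rate", "mean_gamma", "n_evaluated"],
        ),
        "optics_comparison.csv": (
            optics_rows,
            ["energy", "axis", "kind", "sigma_meas_mm", "sigma_comp_mm",
             "sigma_rel_diff_pct", "dA_pct", "dB_pct", "dC_pct"],
        ),
        "qa_records.csv": (
            qa_records,
            ["plan_id", "cohort", "model", "delivered", "arm", "criteria",
             "passing_rate", "mean_gamma"],
        ),
        "qa_stats.csv": (
            qa_stats,
            ["comparison", "cohort", "criteria", "mean_diff_pct", "t", "p",
             "pearson_r", "r_p", "n"],
        ),
    }
    for name, (df, columns) in tables.items():
        path = out / name
        if df is None or df.empty:
            pd.DataFrame(columns=columns).to_csv(path, index=False)
        else:
            df.to_csv(path, index=False)
        written.append(path)

    if qa_records is not None and not qa_records.empty:
        path = out / "qa_table.csv"
        qa_table(qa_records).to_csv(path, index=False)
        written.append(path)
    if optics_rows is not None and not optics_rows.empty and "kind" in optics_rows:
        path = out / "optics_summary.csv"
        optics_summary(optics_rows).to_csv(path, index=False)
        written.append(path)

    manifest = {
        "software": "beammatch",
        "version": __version__,
        "config": {k: asdict(v) for k, v in (config or {}).items() if v is not None},
        "seeds": seeds or {},
        "baseline_convention": "gantry A (first argument) is the gamma reference "
        "and the denominator of relative differences",
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(mpath)

    if plots:
        written += _render_plots(out, idd_rows, optics_rows, qa_records)
    return written


def _render_plots(out: Path, idd_rows, optics_rows, qa_records) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if idd_rows is not None and not idd_rows.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        for kind, grp in idd_rows.groupby("kind"):
            g = grp.groupby("energy")["mean_gamma"].mean()
            ax.plot(g.index, g.values, marker="o", ms=3, label=kind)
        ax.set_xlabel("nominal energy (MeV)")
        ax.set_ylabel("mean gamma (1 mm/1%)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out / "idd_mean_gamma.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if optics_rows is not None and not optics_rows.empty and "sigma_rel_diff_pct" in optics_rows:
        sub = optics_rows.dropna(subset=["sigma_rel_diff_pct"])
        if not sub.empty:
            fig, ax = plt.subplots(figsize=(7, 4))
            for (kind, axis), grp in sub.groupby(["kind", "axis"]):
                ax.plot(grp["energy"], grp["sigma_rel_diff_pct"], marker="o",
                        ms=3, label=f"{kind} ({axis})")
            ax.axhline(0, color="k", lw=0.5)
            ax.set_xlabel("nominal energy (MeV)")
            ax.set_ylabel("sigma relative difference (%)")
            ax.legend(fontsize=7)
            fig.tight_layout()
            path = out / "spot_sigma_differences.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    if qa_records is not None and not qa_records.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        tbl = qa_table(qa_records)
        for crit, grp in tbl.groupby("criteria"):
            ax.scatter(grp["arm"] + " " + grp["cohort"], grp["mean_passing_rate"],
                       label=crit, s=18)
        ax.set_ylabel("mean passing rate (%)")
        ax.tick_params(axis="x", rotation=60, labelsize=7)
        ax.legend()
        fig.tight_layout()
        path = out / "qa_passing_rates.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
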