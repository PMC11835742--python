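"""Configuration and the end-to-end pipeline driver.

A :class:`RunConfig` names the inputs (or asks for a synthetic cohort) and
collects the numeric settings of every stage.  :func:`run_pipeline` executes
the requested stages in order — measures, group statistics, classifier,
model fit, perturbation — and writes JSON/TSV artifacts stamped with the
configuration hash, package version and master seed.  One master seed derives
per-stage seeds through ``numpy.random.SeedSequence([master, stage_index])``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .classify import assemble_features, permutation_significance, repeated_split_eval
from .geometry import generate_geometry
from .hopf import HopfParams, build_coupling, estimate_frequencies, fit_G
from .perturbation import PerturbationSpec, perturb_and_measure
from .stats import compare_measures, node_level_analysis, outcome_correlation
from .synthetic import CohortSpec, generate_cohort, generate_connectome
from .turbulence import REPORT_LAMBDAS, ScaleSet, compute_profile

log = logging.getLogger("neuroturb")

STAGE_SEEDS = {"synth": 0, "measures": 1, "stats": 2, "classify": 3,
               "fit_model": 4, "perturb": 5}


def stage_seed(master: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from the master seed."""
    return int(
        np.random.SeedSequence([master, STAGE_SEEDS[stage]]).generate_state(1)[0]
        % 2**31
    )


@dataclass
class RunConfig:
    """Settings of a full analysis run (YAML-loadable)."""

    out_dir: str = "neuroturb_out"
    # inputs; when timeseries_dir is None a synthetic cohort is generated
    timeseries_dir: str | None = None
    coords_file: str | None = None
    connectome_file: str | None = None
    labels_file: str | None = None
    # synthetic cohort settings
    n_regions: int = 60
    n_volumes: int = 300
    tr: float = 2.0
    group_sizes: tuple[int, int, int] = (20, 20, 20)
    group_G: tuple[float, float, float] = (1.28, 1.55, 1.23)
    outcome_correlation: float = 0.4
    n_longrange: int = 40
    # measures
    band: tuple[float, float] = (0.008, 0.08)
    n_trim: int = 10
    lambdas: tuple[float, ...] = ScaleSet().lambdas
    fit_range: tuple[float, float] = (10.0, 75.0)
    # stats
    n_perm: int = 1000
    fdr_q: float = 0.05
    node_quantile: float = 0.30
    # classifier
    clf_n_reps: int = 100
    clf_train_frac: float = 0.9
    clf_balance_to: int = 32
    clf_n_null: int = 1000
    clf_mode: str = "repeated_split"
    # model fit / perturbation
    g_grid: tuple[float, ...] = tuple(np.round(np.arange(0.6, 1.85, 0.1), 2))
    fit_n_reps: int = 5
    perturb_delta_a_max: float = 0.1
    perturb_n_trials: int = 100
    # stage toggles
    stages: tuple[str, ...] = ("synth", "measures", "stats", "classify")
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("timeseries_dir", "coords_file", "connectome_file", "labels_file"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")
        if not (0 < self.band[0] < self.band[1] < 1 / (2 * self.tr)):
            raise ValueError("band must lie strictly inside (0, Nyquist)")
        unknown = set(self.stages) - set(STAGE_SEEDS)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("group_sizes", "group_G", "band", "lambdas", "fit_range",
                    "g_grid", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stamp(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
    }


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"_meta": _stamp(config), **payload}
    path.write_text(json.dumps(payload, indent=1, default=str))


def run_pipeline(config: RunConfig) -> int:
    """Execute the configured stages; returns 0 on success, 1 on failure.

    Artifacts are written under ``config.out_dir``; on a stage failure the
    partial artifacts are retained and ``MANIFEST.json`` marks the run
    incomplete and names the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages_completed": [], "complete": False, **_stamp(config)}
    timings: dict[str, float] = {}

    try:
        # --- inputs -------------------------------------------------------
        t0 = time.time()
        if config.timeseries_dir is None:
            geom = generate_geometry(config.n_regions, seed=stage_seed(config.master_seed, "synth"))
            connectome = generate_connectome(
                geom, n_longrange=config.n_longrange,
                seed=stage_seed(config.master_seed, "synth") + 1,
            )
            spec = CohortSpec(
                n_regions=config.n_regions, n_volumes=config.n_volumes,
                tr=config.tr, group_sizes=tuple(config.group_sizes),
                group_G=tuple(config.group_G),
                outcome_correlation=config.outcome_correlation,
                seed=stage_seed(config.master_seed, "synth"),
            )
            records = generate_cohort(spec, geom, connectome)
            if "synth" in config.stages:
                io.write_cohort(out / "cohort", records, spec_echo=asdict(config))
                io.write_coords(out / "coords.tsv", geom)
                io.write_labels(out / "rsn_labels.txt", geom.rsn_labels)
                io.write_matrix(out / "connectome.tsv", connectome)
                manifest["stages_completed"].append("synth")
        else:
            if config.coords_file is None:
                raise ValueError("coords_file is required with external timeseries")
            labels = io.read_labels(config.labels_file) if config.labels_file else None
            geom = io.read_coords(config.coords_file, rsn_labels=labels)
            connectome = (
                io.read_matrix(config.connectome_file)
                if config.connectome_file else None
            )
            records = io.read_cohort(config.timeseries_dir)
        timings["inputs"] = time.time() - t0

        # --- measures -----------------------------------------------------
        profiles = {}
        if {"measures", "stats", "classify"} & set(config.stages):
            t0 = time.time()
            scales = ScaleSet(config.lambdas)
            for rec in records:
                profiles[rec.subject_id] = compute_profile(
                    rec.bold, geom, scales,
                    low_hz=config.band[0], high_hz=config.band[1],
                    n_trim=config.n_trim, fit_range=config.fit_range,
                )
            for pid, prof in profiles.items():
                io.write_profile(out / f"{pid}_profile.json", prof)
            manifest["stages_completed"].append("measures")
            timings["measures"] = time.time() - t0

        groups = {g: [r for r in records if r.group == g]
                  for g in {"control", "responder", "non_responder"}}

        # --- stats --------------------------------------------------------
        if "stats" in config.stages:
            t0 = time.time()
            tables = {}
            for label, recs in groups.items():
                if not recs:
                    continue
                rows = []
                for r in recs:
                    prof = profiles[r.subject_id]
                    row = {
                        f"turbulence_lam{lam:g}": prof.at_scale(prof.turbulence, lam)
                        for lam in REPORT_LAMBDAS
                    }
                    row.update({
                        f"information_transfer_lam{lam:g}":
                            prof.at_scale(prof.information_transfer, lam)
                        for lam in REPORT_LAMBDAS
                    })
                    row["information_cascade"] = prof.information_cascade
                    rows.append(row)
                tables[label] = pd.DataFrame(rows)
            comparisons = compare_measures(
                tables, n_perm=config.n_perm, q=config.fdr_q,
                seed=stage_seed(config.master_seed, "stats"),
            )
            comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)

            node_groups = {
                label: np.vstack([
                    profiles[r.subject_id].at_scale(
                        profiles[r.subject_id].node_metastability, 0.01
                    )
                    for r in recs
                ])
                for label, recs in groups.items() if recs
            }
            node_reports = node_level_analysis(
                node_groups, geom, quantile=config.node_quantile,
                n_perm=config.n_perm, q=config.fdr_q,
                seed=stage_seed(config.master_seed, "stats"),
            )
            _write_json(
                out / "node_level.json",
                {
                    f"{a}__vs__{b}": {
                        "n_significant": int(r.significant_mask.sum()),
                        "n_selected": int(r.selected_mask.sum()),
                        "rsn_counts": r.rsn_counts,
                    }
                    for (a, b), r in node_reports.items()
                },
                config,
            )

            patients = [r for r in records if r.group != "control"]
            if len(patients) >= 5:
                turb = [
                    profiles[r.subject_id].at_scale(
                        profiles[r.subject_id].turbulence, 0.01
                    )
                    for r in patients
                ]
                pct = [r.hamd6_pct_change for r in patients]
                rho, pval = outcome_correlation(np.asarray(turb), np.asarray(pct))
                _write_json(
                    out / "outcome_correlation.json",
                    {"measure": "turbulence_lam0.01", "rho": rho, "p": pval},
                    config,
                )
            manifest["stages_completed"].append("stats")
            timings["stats"] = time.time() - t0

        # --- classifier ---------------------------------------------------
        if "classify" in config.stages:
            t0 = time.time()
            patients = [r for r in records if r.group != "control"]
            table = assemble_features(
                {r.subject_id: profiles[r.subject_id] for r in patients},
                {r.subject_id: r.group for r in patients},
            )
            report = repeated_split_eval(
                table, n_reps=config.clf_n_reps, train_frac=config.clf_train_frac,
                balance_to=config.clf_balance_to,
                seed=stage_seed(config.master_seed, "classify"),
                mode=config.clf_mode,
            )
            report = permutation_significance(
                table, report, n_null=config.clf_n_null,
                seed=stage_seed(config.master_seed, "classify") + 1,
                train_frac=config.clf_train_frac,
                balance_to=config.clf_balance_to, mode=config.clf_mode,
            )
            _write_json(out / "classifier_report.json", asdict(report), config)
            table.X.assign(response=table.y).to_csv(
                out / "feature_table.tsv", sep="\t"
            )
            manifest["stages_completed"].append("classify")
            timings["classify"] = time.time() - t0

        # --- model fit + perturbation ------------------------------------
        if {"fit_model", "perturb"} & set(config.stages):
            t0 = time.time()
            coupling = build_coupling(geom, connectome)
            fits = {}
            for label, recs in groups.items():
                if not recs:
                    continue
                series = [r.bold for r in recs]
                omegas = np.mean(
                    [estimate_frequencies(ts, config.band) for ts in series], axis=0
                )
                template = HopfParams(
                    omegas=omegas, G=1.0, duration=config.n_volumes * config.tr,
                    seed=stage_seed(config.master_seed, "fit_model"),
                )
                fit = fit_G(
                    series, geom, coupling, template,
                    np.asarray(config.g_grid), n_reps=config.fit_n_reps,
                    out_tr=config.tr,
                )
                fits[label] = (fit, template)
                _write_json(
                    out / f"fit_{label}.json",
                    {
                        "g_grid": list(fit.g_grid),
                        "error_curve": list(fit.error_curve),
                        "g_opt": fit.g_opt,
                        "n_reps_per_g": fit.n_reps_per_g,
                    },
                    config,
                )
            manifest["stages_completed"].append("fit_model")
            timings["fit_model"] = time.time() - t0

            if "perturb" in config.stages:
                t0 = time.time()
                for label, (fit, template) in fits.items():
                    pspec = PerturbationSpec(
                        delta_a_max=config.perturb_delta_a_max,
                        n_trials=config.perturb_n_trials,
                        seed=stage_seed(config.master_seed, "perturb"),
                    )
                    from dataclasses import replace as _replace
                    report = perturb_and_measure(
                        _replace(template, G=fit.g_opt), coupling, geom, pspec,
                        out_tr=config.tr,
                    )
                    _write_json(
                        out / f"perturbation_{label}.json",
                        {
                            "susceptibility": report.susceptibility,
                            "info_capability": report.info_capability,
                        },
                        config,
                    )
                    np.savetxt(
                        out / f"perturbation_{label}_trials.tsv",
                        report.per_trial_delta, fmt="%.17g",
                    )
                manifest["stages_completed"].append("perturb")
                timings["perturb"] = time.time() - t0

        manifest["complete"] = True
        return 0
    except Exception as exc:  # noqa: BLE001 - report and mark incomplete
        log.error("pipeline failed: %s", exc)
        manifest["error"] = str(exc)
        return 1
    finally:
        manifest["timings_s"] = timings
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, default=str))
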