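"""End-to-end orchestration: cohort -> LEiDA -> fit -> EC -> perturbation.

Runs the full two-stage workflow on a synthetic benchmark scene (or a
cohort loaded from disk): characterize each group's PMS model-free, fit a
Hopf model's global coupling to the source group's PMS, optimize its
effective connectivity against the source group's grand-average phase FC,
and sweep unilateral perturbations toward the target group's PMS.  Every
stage's outputs and derived seeds are logged to a manifest; a rerun with
the same config regenerates every file byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fitting, leida, perturbation, synthetic
from ._seeds import derive_seed
from .config import RunConfig
from .hopf import default_spec
from .io import save_cohort, write_matrix
from .signals import bandpass_filter, estimate_node_frequencies, instantaneous_phase

__all__ = ["run_full_pipeline"]

log = logging.getLogger("metastates")


def _hash_config(config: RunConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def run_full_pipeline(config: RunConfig, out_dir, cohort=None, connectome=None) -> dict:
    """Execute all five stages and write reports under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``).  A cohort and
    connectome may be supplied; otherwise the benchmark scene defined by
    the config is generated.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _hash_config(config),
        "seeds": {},
        "stages": [],
    }
    stage_ctx = "setup"
    try:
        # 1 — cohort
        stage_ctx = "simulate-cohort"
        t0 = time.perf_counter()
        if cohort is None:
            cohort, connectome, _truth = synthetic.make_benchmark_scene(
                config.n_nodes,
                seed=config.seed,
                n_subjects_per_group=config.n_subjects_per_group,
                t_points=config.t_points,
                tr_seconds=config.tr_seconds,
            )
        elif connectome is None:
            raise ValueError("a connectome must accompany a supplied cohort")
        save_cohort(cohort, out / "cohort")
        write_matrix(out / "connectome.tsv", connectome.weights)
        manifest["seeds"]["cohort"] = config.seed
        manifest["stages"].append({
            "name": stage_ctx,
            "outputs": ["cohort/manifest.tsv", "connectome.tsv"],
        })
        log.info("%s done in %.1fs", stage_ctx, time.perf_counter() - t0)

        # 2 — LEiDA
        stage_ctx = "leida"
        t0 = time.perf_counter()
        stream = leida.build_eigenvector_stream(cohort, config.band_hz)
        centroids, labels = leida.cluster_eigenvectors(
            stream, config.k, config.kmeans_restarts,
            seed=derive_seed(config.seed, 2),
            reference_group=config.reference_group,
        )
        pms = leida.occupancy(labels, stream.group_of, config.k)
        subj_occ = leida.subject_occupancies(
            labels, stream.subject_of, stream.group_of, config.k
        )
        stats = leida.pairwise_occupancy_tests(
            subj_occ, config.k, n_perm=config.n_perm,
            seed=derive_seed(config.seed, 3),
        )
        write_matrix(out / "centroids.tsv", centroids.centroids)
        pms.to_frame().to_csv(out / "pms.tsv", sep="\t", index=False)
        subj_occ.to_csv(out / "subject_occupancy.tsv", sep="\t", index=False)
        stats.to_csv(out / "statistics.tsv", sep="\t", index=False)
        manifest["seeds"]["leida"] = derive_seed(config.seed, 2)
        manifest["stages"].append({
            "name": stage_ctx,
            "outputs": ["centroids.tsv", "pms.tsv", "subject_occupancy.tsv",
                        "statistics.tsv"],
        })
        log.info("%s done in %.1fs", stage_ctx, time.perf_counter() - t0)

        # 3 — fit the source-group model
        stage_ctx = "fit"
        t0 = time.perf_counter()
        freqs = estimate_node_frequencies(cohort, config.band_hz)
        gmin, gmax, gstep = config.g_grid
        grid = np.round(np.arange(gmin, gmax + gstep / 2, gstep), 10)
        fit = fitting.fit_global_coupling(
            pms.probability_vector(config.source_group),
            centroids, freqs, connectome.weights,
            g_grid=grid, t_points=config.fit_t_points, n_runs=config.fit_runs,
            seed=derive_seed(config.seed, 4),
            tr_seconds=config.tr_seconds, band=config.band_hz,
        )
        pd.DataFrame({"g": fit.g_grid, "kl": fit.kl_curve}).to_csv(
            out / "fit_curve.tsv", sep="\t", index=False
        )
        (out / "fit_best.json").write_text(json.dumps({
            "g_best": fit.g_best,
            "kl_best": float(fit.kl_curve.min()),
            "pms_sim_best": fit.pms_sim_best.tolist(),
        }, indent=2) + "\n")
        manifest["seeds"]["fit"] = derive_seed(config.seed, 4)
        manifest["stages"].append({
            "name": stage_ctx, "outputs": ["fit_curve.tsv", "fit_best.json"],
        })
        log.info("%s done in %.1fs", stage_ctx, time.perf_counter() - t0)

        # 4 — effective-connectivity optimization
        stage_ctx = "optimize-ec"
        t0 = time.perf_counter()
        source_phases = [
            instantaneous_phase(
                bandpass_filter(s, cohort.tr_seconds, config.band_hz),
                cohort.tr_seconds,
            )
            for s, g in zip(cohort.series, cohort.group_labels)
            if g == config.source_group
        ]
        fc_emp = fitting.grand_average_fc(source_phases)
        spec = default_spec(
            freqs, connectome.weights, fit.g_best, tr_seconds=config.tr_seconds
        )
        ec = fitting.optimize_effective_connectivity(
            spec, fc_emp,
            epsilon=config.ec["epsilon"], tol=config.ec["tol"],
            max_iter=int(config.ec["max_iter"]),
            t_points=int(config.ec["t_points"]),
            band=config.band_hz, seed=derive_seed(config.seed, 5),
        )
        write_matrix(out / "effective_connectivity.tsv", ec.ec)
        pd.DataFrame({
            "iteration": np.arange(1, ec.iterations + 1),
            "discrepancy": ec.discrepancy_history,
        }).to_csv(out / "ec_log.tsv", sep="\t", index=False)
        manifest["seeds"]["optimize-ec"] = derive_seed(config.seed, 5)
        manifest["stages"].append({
            "name": stage_ctx,
            "outputs": ["effective_connectivity.tsv", "ec_log.tsv"],
        })
        log.info("%s done in %.1fs", stage_ctx, time.perf_counter() - t0)

        # 5 — perturbation toward the target PMS
        stage_ctx = "perturb"
        t0 = time.perf_counter()
        pert = config.perturbation
        if pert["protocol"] == "synchronization":
            grid_full = np.round(np.linspace(-0.02, 0.18, 21), 10)
        else:
            grid_full = np.round(np.linspace(-0.02, -0.22, 11), 10)
        n_int = min(int(pert["n_intensities"]), grid_full.size)
        idx = np.unique(np.round(np.linspace(0, grid_full.size - 1, n_int)).astype(int))
        protocol = perturbation.PerturbationProtocol(
            name=pert["protocol"], intensities=grid_full[idx]
        )
        pmap = perturbation.perturb_sweep(
            spec.with_coupling_matrix(ec.ec), protocol,
            pms.probability_vector(config.target_group), centroids,
            band=config.band_hz, t_points=int(pert["t_points"]),
            n_reps=int(pert["n_reps"]), seed=derive_seed(config.seed, 6),
        )
        report = perturbation.transition_report(pmap)
        pmap.to_frame().to_csv(out / "kl_landscape.tsv", sep="\t", index=False)
        report.per_node_best.to_csv(out / "per_node_best.tsv", sep="\t", index=False)
        (out / "global_best.json").write_text(json.dumps({
            "node": report.global_best[0],
            "intensity": report.global_best[1],
            "kl": report.global_best[2],
            "baseline_kl": report.baseline_kl,
            "achieved": report.achieved,
        }, indent=2) + "\n")
        # PMS evolution along the globally best node's sweep
        best_node = report.global_best[0] - 1
        evo = pd.DataFrame(
            pmap.pms[best_node],
            columns=[f"substate_{i + 1}" for i in range(pmap.pms.shape[2])],
        )
        evo.insert(0, "intensity", protocol.intensities)
        evo.to_csv(out / "pms_evolution.tsv", sep="\t", index=False)
        manifest["seeds"]["perturb"] = derive_seed(config.seed, 6)
        manifest["stages"].append({
            "name": stage_ctx,
            "outputs": ["kl_landscape.tsv", "per_node_best.tsv",
                        "global_best.json", "pms_evolution.tsv"],
        })
        log.info("%s done in %.1fs", stage_ctx, time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage_ctx!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
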