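"""Full-analysis orchestration: ensemble → profiles → fit/classify → core/PCA → conservation.

A single :class:`AnalysisConfig` names the inputs (conformer directory,
experimental curves, alignment, B-factor reference) and the tunables
(q grid, cosine threshold, core volume cutoff, rounds, seeds).  Stages whose
inputs are absent are skipped, not failed; every artifact carries the config
hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .conservation import (
    build_conservation_table,
    correlate_and_flag,
    map_columns_to_reference,
    read_alignment,
    sequence_conservation_score,
)
from .dynamics import (
    DEFAULT_CORE_VOLUME_CUTOFF,
    cluster_pc_space,
    ensemble_pca,
    find_invariant_core,
    movement_similarity_matrix,
    per_residue_pc_amplitude,
    per_residue_rmsf,
    rmsf_bfactor_correlation,
)
from .fitting import classify_by_cosine, combination_chi2_study, fit_volume_fractions
from .saxs import debye_profile, default_q_grid, read_profile, rg_from_coordinates
from .structures import load_ensemble, read_conformer, write_ensemble_pdb

logger = logging.getLogger("saxsemble")

__all__ = ["AnalysisConfig", "run_full_analysis", "write_report"]


@dataclass
class AnalysisConfig:
    """Inputs and tunables of the full pipeline.

    Paths set to None skip the corresponding stage.  Defaults mirror the
    analysis conditions: cosine threshold 0.1, core ellipsoid cutoff
    150 Å³, combination counts (1, 2, 3, 5, 10, 20, 50) at 10,000 rounds.
    """

    ensemble_dir: str | None = None
    experimental_curves: tuple[str, ...] = ()
    alignment_path: str | None = None
    alignment_reference_id: str | None = None
    bfactor_reference: str | None = None
    atom_name: str = "P"
    q_min: float = 0.006
    q_max: float = 0.45
    q_points: int = 101
    cosine_threshold: float = 0.1
    core_volume_cutoff: float | None = DEFAULT_CORE_VOLUME_CUTOFF
    n_reference_classes: int = 3
    combination_counts: tuple[int, ...] = (1, 2, 3, 5, 10, 20, 50)
    combination_rounds: int = 10_000
    run_combination_study: bool = False
    pca_components_report: int = 10
    flag_quantile: float = 0.25
    seed: int = 0
    out_dir: str = "saxsemble_out"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("experimental_curves", "combination_counts"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _stage(report: dict, name: str, fn) -> Any:
    """Run one stage; on failure record the error and let downstream skip."""
    t0 = time.perf_counter()
    try:
        result = fn()
        report["stages"][name] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s: ok (%.2fs)", name, time.perf_counter() - t0)
        return result
    except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
        report["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
        logger.warning("stage %s failed: %s", name, exc)
        return None


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute every stage whose inputs are present; return the report bundle.

    The bundle is a dict of stage outputs (native objects plus JSON-ready
    summaries) with provenance (config hash, seed, package version).
    Stage failures are recorded and downstream stages that need the failed
    output are skipped.
    """
    report: dict[str, Any] = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "stages": {},
    }

    q_grid = default_q_grid(config.q_min, config.q_max, config.q_points)

    ensemble = None
    if config.ensemble_dir:
        ensemble = _stage(
            report, "load_ensemble",
            lambda: load_ensemble(config.ensemble_dir, atom_name=config.atom_name),
        )
    else:
        report["stages"]["load_ensemble"] = {"status": "skipped"}

    profiles = None
    if ensemble is not None:
        profiles = _stage(
            report, "profiles", lambda: [debye_profile(c, q_grid) for c in ensemble]
        )
        if profiles is not None:
            report["rg_by_id"] = {c.id: rg_from_coordinates(c) for c in ensemble}

    # --- SAXS fitting and classification ---------------------------------
    if profiles is not None and config.experimental_curves:
        curves = _stage(
            report, "read_experimental",
            lambda: [read_profile(p) for p in config.experimental_curves],
        )
        if curves:
            exp = curves[0]
            fit = _stage(report, "fit_volume_fractions",
                         lambda: fit_volume_fractions(profiles, exp))
            if fit is not None:
                report["fit"] = fit.as_dict()
                # references: the top-populated conformers, one per class
                order = np.argsort(fit.nu)[::-1][: config.n_reference_classes]
                refs = [profiles[i] for i in sorted(order, key=lambda i: -fit.nu[i])]
                assignment = _stage(
                    report, "classify",
                    lambda: classify_by_cosine(profiles, refs, config.cosine_threshold),
                )
                if assignment is not None:
                    report["classification"] = {
                        "reference_ids": [r.label for r in refs],
                        "labels": dict(zip(assignment.member_ids, assignment.labels)),
                        "class_sizes": {
                            lab: len(assignment.members_of(lab))
                            for lab in assignment.class_labels
                        },
                    }
                    if config.run_combination_study:
                        study = _stage(
                            report, "combination_study",
                            lambda: combination_chi2_study(
                                assignment, {p.label: p for p in profiles}, exp,
                                counts_per_class=config.combination_counts,
                                rounds=config.combination_rounds,
                                seed=config.seed,
                            ),
                        )
                        if study is not None:
                            report["combination_study"] = study.summary.reset_index().to_dict("list")
            if len(curves) > 1 and report.get("classification"):
                from .fitting import titration_population_series

                ref_ids = report["classification"]["reference_ids"]
                refs = [p for p in profiles if p.label in ref_ids]
                series = _stage(
                    report, "titration",
                    lambda: titration_population_series(curves, refs),
                )
                if series is not None:
                    report["titration"] = series.to_dict("index")
    else:
        report["stages"]["fit_volume_fractions"] = {"status": "skipped"}

    # --- conformational analysis -----------------------------------------
    rmsf = None
    core = None
    if ensemble is not None:
        core = _stage(
            report, "invariant_core",
            lambda: find_invariant_core(ensemble, config.core_volume_cutoff),
        )
        core_subset = list(core.core_residues) if core is not None else None
        if core is not None:
            report["core"] = {
                "n_core": core.n_core,
                "core_residues": [int(r) for r in core.core_residues],
                "volume_cutoff": core.volume_cutoff,
            }
        superposed = ensemble.superposed(core_subset)
        rmsf = _stage(report, "rmsf",
                      lambda: per_residue_rmsf(superposed, presuperposed=True))
        pca = _stage(report, "pca",
                     lambda: ensemble_pca(superposed, presuperposed=True))
        if pca is not None:
            k = min(config.pca_components_report, len(pca.eigenvalues))
            report["pca"] = {
                "eigenvalues": [float(v) for v in pca.eigenvalues[:k]],
                "cumulative_variance_fractions": [float(v) for v in pca.variance_fractions[:k]],
                "per_residue_amplitude_pc1": [float(v) for v in per_residue_pc_amplitude(pca, 0)],
            }
            labels = _stage(report, "pc_clusters", lambda: cluster_pc_space(pca))
            if labels is not None and ensemble is not None:
                report["pc_clusters"] = dict(
                    zip((c.id for c in ensemble), (int(l) for l in labels))
                )
            report["_pca_object"] = pca
        amsm = _stage(
            report, "amsm",
            lambda: movement_similarity_matrix(superposed, presuperposed=True),
        )
        if amsm is not None:
            report["_amsm_object"] = amsm
        if rmsf is not None:
            report["_rmsf"] = rmsf
        if rmsf is not None and config.bfactor_reference:
            def _bcorr():
                ref = read_conformer(config.bfactor_reference, atom_name=config.atom_name)
                if ref.bfactors is None:
                    raise ValueError("reference structure has no B-factor column")
                r, _, _ = rmsf_bfactor_correlation(rmsf, ref.bfactors)
                return r

            r = _stage(report, "rmsf_bfactor", _bcorr)
            if r is not None:
                report["rmsf_bfactor_pearson_r"] = r
    for name in ("invariant_core", "rmsf", "pca", "amsm"):
        report["stages"].setdefault(name, {"status": "skipped"})

    # --- conservation -----------------------------------------------------
    if config.alignment_path and rmsf is not None:
        def _conservation():
            msa = read_alignment(config.alignment_path)
            ref_id = config.alignment_reference_id or msa.ids[0]
            mapping = map_columns_to_reference(msa, ref_id)
            scs = sequence_conservation_score(msa, mapping)
            rmsf_series = pd.Series(rmsf, index=ensemble.residue_numbers)
            core_res = core.core_residues if core is not None else ()
            table = build_conservation_table(
                scs, rmsf_series, core_residues=(), flag_quantile=config.flag_quantile
            )
            stats = correlate_and_flag(table, squared=True)
            return table, stats

        out = _stage(report, "conservation", _conservation)
        if out is not None:
            table, stats = out
            report["conservation"] = stats
            report["_conservation_table"] = table
    else:
        report["stages"]["conservation"] = {"status": "skipped"}

    return report


def write_report(report: dict, out_dir: str | Path) -> list[Path]:
    """Write the report bundle: JSON summary plus TSV tables and trajectories.

    Private keys (leading underscore) hold in-memory objects; they are
    rendered to TSV/PDB files rather than JSON.  Returns the written paths.
    """
    if not any(s.get("status") == "ok" for s in report.get("stages", {}).values()):
        raise ValueError("no successful stage output to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    serializable = {k: v for k, v in report.items() if not k.startswith("_")}
    summary = out_dir / "report.json"
    with open(summary, "w") as fh:
        json.dump({"schema_version": 1, **serializable}, fh, indent=2, default=str)
    written.append(summary)

    rmsf = report.get("_rmsf")
    pca = report.get("_pca_object")
    if rmsf is not None and pca is not None:
        table = pd.DataFrame({"residue": pca.residue_numbers, "rmsf": rmsf})
        for c in range(min(5, len(pca.eigenvalues))):
            table[f"pc{c + 1}_amplitude"] = per_residue_pc_amplitude(pca, c)
        path = out_dir / "per_residue.tsv"
        table.to_csv(path, sep="\t", index=False)
        written.append(path)
    if pca is not None:
        from .dynamics import interpolate_pc_trajectory

        for c in range(min(2, len(pca.eigenvalues))):
            traj = interpolate_pc_trajectory(pca, component=c, n_frames=11)
            path = out_dir / f"pc{c + 1}_trajectory.pdb"
            write_ensemble_pdb(traj, path)
            written.append(path)
    amsm = report.get("_amsm_object")
    if amsm is not None:
        path = out_dir / "amsm.tsv"
        amsm.to_frame().to_csv(path, sep="\t")
        written.append(path)
    ctable = report.get("_conservation_table")
    if ctable is not None:
        path = out_dir / "conservation.tsv"
        ctable.table.to_csv(path, sep="\t")
        written.append(path)
    return written
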