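"""End-to-end orchestration: simulate -> normalize -> models ->
hippocampal -> wholebrain, with a run manifest and a readable report.

A single JSON config holds every tunable; unknown keys are rejected with
the offending name. All randomness flows from named seeds, so a rerun
with the same config produces identical result files.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .agenorm import normalize_cohort
from .core import Cohort
from .io import load_cohort_dir, save_cohort, save_matrix
from .ica import ICAConfig, analyze_wholebrain
from .mahalanobis import MahalanobisConfig
from .progression import (duration_group_analysis, gradient_test,
                          hippocampal_binnings, hippocampal_profiles)
from .simulate import SimulationConfig, simulate_cohort
from .topology import DEFAULT_N_BINS, build_topology

#: topologies entering the gradient test per deviation modality; the RSN
#: bins span both hemispheres, where structural edges are unreliable, so
#: M_SC is tested against three topologies (alpha 0.05/3) and M_FC
#: against four (alpha 0.05/4).
DEFAULT_TOPOLOGIES = {"FC": ("LEN", "SC", "FC", "RSN"),
                      "SC": ("LEN", "SC", "FC")}


def _from_dict(cls, d: dict, name: str):
    unknown = set(d) - set(cls.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mahalanobis: MahalanobisConfig = field(default_factory=MahalanobisConfig)
    ica: ICAConfig = field(default_factory=ICAConfig)
    topologies: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_TOPOLOGIES.items()})
    cohort_dir: str | None = None      # load instead of simulating
    hemispheres: tuple[str, ...] = ("ipsi", "contra")
    duration_boundaries: tuple[float, float] = (10.0, 30.0)
    full: bool = False                 # 500x500 permutations; else 100x100
    reduced_permutations: tuple[int, int] = (100, 100)
    write_matrices: bool = False       # write corrected connectome TSVs
    rmse_denominator: str = "n"        # or "n-2" for the age-fit RMSE

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "mahalanobis" in d:
            d["mahalanobis"] = _from_dict(MahalanobisConfig, d["mahalanobis"],
                                          "mahalanobis")
        if "ica" in d:
            d["ica"] = _from_dict(ICAConfig, d["ica"], "ica")
        if "topologies" in d:
            d["topologies"] = {k: tuple(v) for k, v in d["topologies"].items()}
        for key in ("hemispheres", "duration_boundaries", "reduced_permutations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")


def _gradient_dict(res) -> dict:
    return {"F": res.F, "df1": res.df1, "df2": res.df2, "p": res.p,
            "bin_means": res.bin_means, "monotone_decrease": res.monotone_decrease,
            "pairwise_p": res.pairwise_p, "verdict": res.verdict,
            "alpha": res.alpha, "n_patients": res.n_patients}


def run_hippocampal_stage(cohort: Cohort, corrected, config: PipelineConfig,
                          mcfg: MahalanobisConfig) -> dict:
    """Gradient tests for every (modality, topology, hemisphere) cell."""
    results = {}
    durations = {p.subject_id: p.duration for p in cohort.patients()}
    for modality, kinds in config.topologies.items():
        alpha = 0.05 / len(kinds)
        for kind in kinds:
            binnings = hippocampal_binnings(cohort, kind)
            for hemi in config.hemispheres:
                profiles = hippocampal_profiles(cohort, corrected, binnings,
                                                modality, mcfg, hemi)
                test = gradient_test(profiles, alpha=alpha)
                cell = {
                    "gradient": _gradient_dict(test),
                    "per_patient_M": {p.patient_id: p.M for p in profiles},
                    "retained_pairs": {p.patient_id:
                                       [b.retained_pairs for b in p.bins]
                                       for p in profiles},
                }
                if test.verdict and hemi == "ipsi":
                    dga = duration_group_analysis(
                        profiles, durations, config.duration_boundaries)
                    cell["duration_groups"] = {
                        "sizes": dga.group_sizes,
                        "interaction_F": dga.interaction_F,
                        "interaction_p": dga.interaction_p,
                        "per_group": {g: _gradient_dict(r)
                                      for g, r in dga.group_results.items()},
                    }
                results[f"M_{modality}|{kind}|{hemi}"] = cell
    return results


def run_pipeline(config: PipelineConfig | str | Path, out_dir,
                 seed: int | None = None) -> Path:
    """Execute every stage and write artifacts + manifest + report."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_json(config)
    if seed is not None:
        config = replace(config,
                         simulation=replace(config.simulation, seed=seed),
                         mahalanobis=replace(config.mahalanobis, seed=seed),
                         ica=replace(config.ica, seed=seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mcfg = config.mahalanobis
    if not config.full:
        mcfg = mcfg.reduced(*config.reduced_permutations)

    from importlib.metadata import version as _pkg_version
    try:
        version = _pkg_version("netprog")
    except Exception:
        version = "unknown"
    manifest = {"version": version, "config": config.to_dict(),
                "seeds": {"simulation": config.simulation.seed,
                          "mahalanobis": mcfg.seed, "ica": config.ica.seed},
                "stage_seconds": {}, "warnings": []}
    caught: list[str] = []

    def timed(name):
        class _T:
            def __enter__(self):
                self.t = time.perf_counter()
                self.ctx = warnings.catch_warnings(record=True)
                self.log = self.ctx.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, *exc):
                manifest["stage_seconds"][name] = round(
                    time.perf_counter() - self.t, 3)
                for w in self.log:
                    caught.append(f"{name}: {w.message}")
                self.ctx.__exit__(*exc)
        return _T()

    try:
        with timed("simulate"):
            if config.cohort_dir:
                cohort = load_cohort_dir(config.cohort_dir)
                truth = None
            else:
                cohort, truth = simulate_cohort(config.simulation)
                save_cohort(cohort, out / "cohort")

        with timed("normalize"):
            corrected = normalize_cohort(
                cohort, rmse_denominator=config.rmse_denominator)
            for modality, model in corrected.models.items():
                _write_json(out / f"age_model.{modality}.json", {
                    "modality": modality,
                    "rmse_denominator": model.rmse_denominator,
                    "n_unfittable_edges": int(np.triu(model.unfittable, 1).sum()),
                    "median_rmse": float(np.nanmedian(model.rmse)),
                })
            if config.write_matrices:
                mdir = out / "corrected"
                mdir.mkdir(exist_ok=True)
                for (sid, modality), c in corrected.res.items():
                    save_matrix(c.matrix, mdir / f"{sid}.{modality}_res.tsv")
                for (sid, modality), c in corrected.corr.items():
                    save_matrix(c.matrix, mdir / f"{sid}.{modality}_corr.tsv")

        with timed("models"):
            all_kinds = sorted({k for v in config.topologies.values() for k in v})
            models = {k: build_topology(cohort, k) for k in all_kinds}
            tdir = out / "topologies"
            tdir.mkdir(exist_ok=True)
            binning_log = {}
            for kind, model in models.items():
                if model.matrices:
                    for side, m in model.matrices.items():
                        save_matrix(np.nan_to_num(m), tdir / f"T_{kind}.{side}.tsv")
                binnings = hippocampal_binnings(cohort, kind)
                binning_log[kind] = {side: [b.tolist() for b in bn.bins]
                                     for side, bn in binnings.items()}
            _write_json(tdir / "binnings.json", binning_log)

        with timed("hippocampal"):
            hip = run_hippocampal_stage(cohort, corrected, config, mcfg)
            _write_json(out / "hippocampal.json", hip)

        with timed("wholebrain"):
            wb = analyze_wholebrain(cohort, corrected, config.ica, models)
            wb_out = {
                "n_pca_components": wb.runs.n_pca_components,
                "n_runs_converged": wb.runs.n_runs_converged,
                "n_merged_components": len(wb.merged.components),
                "identification_frequencies": wb.merged.frequencies,
                "duration_rho": wb.merged.duration_rho,
                "duration_p": wb.merged.duration_p,
                "selected": wb.merged.selected,
            }
            if wb.degree is not None:
                wb_out["fc_density"] = wb.degree.fc_density
                wb_out["sc_density"] = wb.degree.sc_density
                np.savetxt(out / "degree.fc.csv", wb.degree.fc_degree,
                           delimiter=",")
                np.savetxt(out / "degree.sc.csv", wb.degree.sc_degree,
                           delimiter=",")
            if wb.model_correlations is not None:
                wb_out["model_correlations"] = {
                    block: {k: {"r": c.r, "p": c.p, "n": c.n,
                                "method": c.method,
                                "significant": c.significant}
                            for k, c in corr.items()}
                    for block, corr in wb.model_correlations.items()}
            _write_json(out / "wholebrain.json", wb_out)
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    manifest["warnings"] = caught
    _write_json(out / "manifest.json", manifest)
    write_report(out)
    return out


def write_report(out_dir) -> Path:
    """Regenerate the human-readable report from the result JSONs."""
    out = Path(out_dir)
    lines = ["# netprog run report", ""]
    hip_path = out / "hippocampal.json"
    if hip_path.exists():
        hip = json.loads(hip_path.read_text())
        lines.append("## Hippocampal network change (group-mean M per bin)")
        lines.append("")
        lines.append("| analysis | bin means | RM-ANOVA p | verdict |")
        lines.append("|---|---|---|---|")
        for key in sorted(hip):
            g = hip[key]["gradient"]
            means = ", ".join(f"{m:.2f}" for m in g["bin_means"])
            p = "nan" if g["p"] is None else f"{g['p']:.4g}"
            lines.append(f"| {key} | {means} | {p} | {g['verdict']} |")
        lines.append("")
    wb_path = out / "wholebrain.json"
    if wb_path.exists():
        wb = json.loads(wb_path.read_text())
        lines.append("## Whole-brain hybrid ICA")
        lines.append("")
        lines.append(f"- PCA components: {wb['n_pca_components']}; "
                     f"runs converged: {wb['n_runs_converged']}; "
                     f"merged components: {wb['n_merged_components']}")
        if wb.get("selected") is not None:
            i = wb["selected"]
            lines.append(f"- selected component {i}: Spearman rho = "
                         f"{wb['duration_rho'][i]:.3f} "
                         f"(p = {wb['duration_p'][i]:.3g}), identification "
                         f"frequency {wb['identification_frequencies'][i]:.2f}")
        else:
            lines.append("- no component significantly related to duration")
        if "model_correlations" in wb:
            lines.append("")
            lines.append("| block | model | r | p | significant |")
            lines.append("|---|---|---|---|---|")
            for block, corr in wb["model_correlations"].items():
                for kind, c in corr.items():
                    r = "nan" if c["r"] is None else f"{c['r']:.3f}"
                    p = "nan" if c["p"] is None else f"{c['p']:.3g}"
                    lines.append(f"| {block} | {kind} | {r} | {p} | "
                                 f"{c['significant']} |")
        lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
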