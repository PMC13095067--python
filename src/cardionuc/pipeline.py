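"""End-to-end orchestration of the synthetic phenotyping analysis.

``run_pipeline`` executes the requested stages in dependency order inside a
run directory and records a manifest (config, seed, per-stage outputs,
SHA-256 digests, machine-readable warnings).  Stages:

``simulate``
    Seeded synthetic fixtures: territory scenes (two-channel TIFF + mask
    TIFF), displacement and calcium-ratio traces (CSV), external-calcium
    response curves (CSV), DE tables (TSV), plus ground-truth tables.
``profile``
    Radial binning, per-nucleus profiles, pooled min-max normalization,
    heatmap PNG, shape descriptors.
``beats`` / ``calcium``
    Beat segmentation and summaries; calcium-transient metrics and Hill
    EC50 fits.
``degs``
    DEG filtering, per-chromosome summaries, enrichment tests, bar chart.
``compare``
    Two-way ANOVA (group x bin) on the normalized radial profiles.
``report``
    One markdown document assembling whatever stages ran; missing stages
    are marked absent rather than failing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import degs as degs_mod
from . import radial, synthetic, traces as traces_mod

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report", "ALL_STAGES"]

ALL_STAGES = ("simulate", "profile", "beats", "calcium", "degs", "compare", "report")

_STAGE_DEPS = {
    "profile": "simulate",
    "beats": "simulate",
    "calcium": "simulate",
    "degs": "simulate",
    "compare": "profile",
}


class PipelineError(RuntimeError):
    """A stage failed or its upstream outputs are missing."""


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; JSON round-trips losslessly."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    groups: tuple[str, ...] = ("control", "mutant")
    n_nuclei_per_group: int = 30
    territory_mu: dict[str, float] = field(
        default_factory=lambda: {"control": 0.45, "mutant": 0.70}
    )
    scene: dict = field(default_factory=dict)
    n_traces_per_group: int = 6
    trace: dict = field(default_factory=dict)
    trace_group_overrides: dict[str, dict] = field(
        default_factory=lambda: {
            "mutant": {"rise_time": 0.26, "decay_time": 0.20, "amplitude_mu": 0.7,
                       "amplitude_cv": 0.12, "timing_jitter_sd": 0.02},
            "control": {"amplitude_cv": 0.05, "timing_jitter_sd": 0.005},
        }
    )
    calcium_baseline: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "mutant": 1.25}
    )
    calcium_ec50: dict[str, float] = field(
        default_factory=lambda: {"control": 0.7, "mutant": 1.1}
    )
    calcium_hill: float = 2.0
    calcium_fmax: float = 1.0
    calcium_noise_sd: float = 0.02
    deg: dict = field(default_factory=dict)
    deg_tables: tuple[str, ...] = ("cm", "eht")
    bin_mode: str = "equal_width"
    n_bins: int = 10
    normalize_scope: str = "global"
    padj_max: float = 0.05
    lfc_min: float = 0.5
    onset_fraction: float = 0.10

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if len(self.groups) != 2:
            raise ValueError("exactly two groups are supported")
        for g in self.groups:
            if g not in self.territory_mu:
                raise ValueError(f"territory_mu missing group {g!r}")
        if self.n_nuclei_per_group < 2:
            raise ValueError("need at least 2 nuclei per group")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "groups", "deg_tables"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scene_params(cfg: RunConfig, group: str, index: int) -> synthetic.SceneParams:
    overrides = dict(cfg.scene)
    overrides["territory_radial_mu"] = cfg.territory_mu[group]
    # one sub-seed per nucleus, derived from the run seed (kept below 2**31)
    overrides["seed"] = (cfg.seed * 100003 + zlib.crc32(f"{group}:{index}".encode())) % (2**31)
    return synthetic.SceneParams(**overrides)


def _trace_params(cfg: RunConfig, group: str, index: int, modality: str,
                  baseline: float = 0.0) -> synthetic.TraceParams:
    overrides = dict(cfg.trace)
    overrides.update(cfg.trace_group_overrides.get(group, {}))
    overrides["modality"] = modality
    overrides["baseline"] = baseline
    overrides["seed"] = (
        cfg.seed * 99991 + zlib.crc32(f"{group}:{index}:{modality}".encode())
    ) % (2**31)
    return synthetic.TraceParams(**overrides)


# --------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: RunConfig, run: Path, manifest: dict) -> None:
    import tifffile

    img_dir = run / "images"
    msk_dir = run / "masks"
    trc_dir = run / "traces"
    ca_dir = run / "calcium"
    deg_dir = run / "degs_input"
    for d in (img_dir, msk_dir, trc_dir, ca_dir, deg_dir):
        d.mkdir(parents=True, exist_ok=True)

    gt_rows = []
    for group in cfg.groups:
        for i in range(cfg.n_nuclei_per_group):
            sp = _scene_params(cfg, group, i)
            mask = synthetic.make_nucleus_mask(sp)
            mask.nucleus_id = f"{group}_{i:03d}"
            mask.group_label = group
            scene = synthetic.render_territory_scene(mask, sp)
            tifffile.imwrite(img_dir / f"{group}_{i:03d}.tif",
                             scene.image.astype(np.float32))
            tifffile.imwrite(msk_dir / f"{group}_{i:03d}.tif",
                             mask.raster.astype(np.uint8))
            gt_rows.append({"nucleus_id": mask.nucleus_id, "group": group,
                            "gt_mean_radius": scene.gt_mean_radius})
    pd.DataFrame(gt_rows).to_csv(run / "territory_ground_truth.csv", index=False)

    beat_gts = []
    for group in cfg.groups:
        for i in range(cfg.n_traces_per_group):
            tp = _trace_params(cfg, group, i, "displacement")
            trace, gt = synthetic.simulate_beat_trace(tp)
            df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
            df.to_csv(trc_dir / f"{group}_{i:02d}.csv", index=False)
            gt.insert(0, "trace_id", f"{group}_{i:02d}")
            gt.insert(1, "group", group)
            beat_gts.append(gt)

            cp = _trace_params(cfg, group, i, "calcium_ratio",
                              baseline=cfg.calcium_baseline[group])
            ca_trace, _ = synthetic.simulate_beat_trace(cp)
            pd.DataFrame({"time_s": ca_trace.times, "value": ca_trace.samples}).to_csv(
                ca_dir / f"transient_{group}_{i:02d}.csv", index=False)
    pd.concat(beat_gts, ignore_index=True).to_csv(run / "beat_ground_truth.csv", index=False)

    for group in cfg.groups:
        c, f = synthetic.simulate_calcium_response(
            ec50=cfg.calcium_ec50[group], hill_coef=cfg.calcium_hill,
            fmax=cfg.calcium_fmax, noise_sd=cfg.calcium_noise_sd,
            seed=(cfg.seed * 7919 + zlib.crc32(group.encode())) % (2**31))
        pd.DataFrame({"calcium_mM": c, "force": f}).to_csv(
            ca_dir / f"response_{group}.csv", index=False)

    deg_over = dict(cfg.deg)
    deg_over.setdefault("enriched_chromosomes", {"1": 5.0, "2": 3.0, "3": 2.0, "4": 2.0})
    deg_over.setdefault("ecm_enriched_multiplier", 2.0)
    for k, name in enumerate(cfg.deg_tables):
        deg_over["seed"] = (cfg.seed * 6007 + k) % (2**31)
        table = synthetic.simulate_deg_table(synthetic.DEGSimParams(**deg_over))
        table.to_csv(deg_dir / f"table_{name}.tsv", sep="\t", index=False)


def _stage_profile(cfg: RunConfig, run: Path, manifest: dict) -> None:
    import tifffile

    img_dir, msk_dir = run / "images", run / "masks"
    if not img_dir.is_dir():
        raise PipelineError("profile stage requires outputs of the 'simulate' stage")
    profiles, shape_rows = [], []
    for img_path in sorted(img_dir.glob("*.tif")):
        mask_path = msk_dir / img_path.name
        image = tifffile.imread(img_path)
        if image.ndim != 3 or image.shape[0] < 2:
            raise PipelineError(f"{img_path.name}: expected a multi-channel image")
        raster = tifffile.imread(mask_path).astype(bool)
        group = img_path.stem.rsplit("_", 1)[0]
        mask = radial.NuclearMask(raster=raster, nucleus_id=img_path.stem,
                                  group_label=group, probe_id="probe1")
        binmap = radial.compute_distance_bins(mask, n_bins=cfg.n_bins, mode=cfg.bin_mode)
        profiles.append(radial.profile_intensity(
            image[1], binmap, nucleus_id=mask.nucleus_id,
            probe_id="probe1", group_label=group))
        sd = radial.shape_descriptors(mask)
        shape_rows.append({"nucleus_id": mask.nucleus_id, "group": group,
                           **dataclasses.asdict(sd)})

    matrix = radial.normalize_profiles(profiles, scope=cfg.normalize_scope)
    if matrix.degenerate:
        manifest["warnings"].append(
            {"stage": "profile", "kind": "degenerate_normalization"})
    out = run / "profiles"
    out.mkdir(exist_ok=True)
    matrix.per_nucleus.to_csv(out / "per_nucleus_profiles.csv", index=False)
    matrix.values.to_csv(out / "profile_matrix.csv")
    pd.DataFrame(shape_rows).to_csv(out / "shape_descriptors.csv", index=False)
    _heatmap_png(matrix, out / "heatmap.png")


def _heatmap_png(matrix: radial.ProfileMatrix, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 2.2))
    im = ax.imshow(matrix.values.to_numpy(), vmin=0, vmax=1, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(matrix.values.index)), matrix.values.index)
    ax.set_xticks(range(matrix.values.shape[1]),
                  [str(k + 1) for k in range(matrix.values.shape[1])])
    ax.set_xlabel("radial bin (1 = center, 10 = periphery)")
    fig.colorbar(im, ax=ax, label="normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _read_trace_csv(path: Path, modality: str, pacing_rate: float) -> traces_mod.BeatTrace:
    df = pd.read_csv(path)
    dt = np.diff(df["time_s"].to_numpy())
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise PipelineError(f"{path.name}: non-uniform sampling")
    return traces_mod.BeatTrace(samples=df["value"].to_numpy(),
                                frame_rate=1.0 / dt[0],
                                pacing_rate=pacing_rate, modality=modality)


def _stage_beats(cfg: RunConfig, run: Path, manifest: dict) -> None:
    trc_dir = run / "traces"
    if not trc_dir.is_dir():
        raise PipelineError("beats stage requires outputs of the 'simulate' stage")
    pacing = cfg.trace.get("pacing_rate", 1.0)
    beat_rows, summary_rows = [], []
    for path in sorted(trc_dir.glob("*.csv")):
        trace = _read_trace_csv(path, "displacement", pacing)
        beats = traces_mod.detect_beats(trace, onset_fraction=cfg.onset_fraction)
        for b in beats:
            beat_rows.append({"trace_id": path.stem, **dataclasses.asdict(b)})
        s = traces_mod.summarize_trace(beats)
        summary_rows.append({"trace_id": path.stem,
                             "group": path.stem.rsplit("_", 1)[0],
                             **dataclasses.asdict(s)})
    out = run / "beats"
    out.mkdir(exist_ok=True)
    pd.DataFrame(beat_rows).to_csv(out / "per_beat.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "per_trace_summary.csv", index=False)


def _stage_calcium(cfg: RunConfig, run: Path, manifest: dict) -> None:
    ca_dir = run / "calcium"
    if not ca_dir.is_dir():
        raise PipelineError("calcium stage requires outputs of the 'simulate' stage")
    pacing = cfg.trace.get("pacing_rate", 1.0)
    rows = []
    for path in sorted(ca_dir.glob("transient_*.csv")):
        trace = _read_trace_csv(path, "calcium_ratio", pacing)
        m = traces_mod.calcium_metrics(trace, onset_fraction=cfg.onset_fraction)
        if m.n_excluded:
            manifest["warnings"].append({"stage": "calcium", "kind": "excluded_transients",
                                         "trace": path.stem, "n": m.n_excluded})
        rows.append({"trace_id": path.stem,
                     "group": path.stem.removeprefix("transient_").rsplit("_", 1)[0],
                     **dataclasses.asdict(m)})
    fits = {}
    for path in sorted(ca_dir.glob("response_*.csv")):
        df = pd.read_csv(path)
        fit = traces_mod.fit_calcium_response(df["calcium_mM"].to_numpy(),
                                              df["force"].to_numpy())
        fits[path.stem.removeprefix("response_")] = {
            "ec50_mM": fit.ec50, "hill": fit.hill, "fmax": fit.fmax,
            "residual": fit.residual, "status": fit.status,
            "ec50_in_range": fit.ec50_in_range,
        }
    out = run / "calcium_metrics"
    out.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "transient_metrics.csv", index=False)
    (out / "ec50_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))


def _stage_degs(cfg: RunConfig, run: Path, manifest: dict) -> None:
    deg_dir = run / "degs_input"
    if not deg_dir.is_dir():
        raise PipelineError("degs stage requires outputs of the 'simulate' stage")
    out = run / "degs"
    out.mkdir(exist_ok=True)
    for path in sorted(deg_dir.glob("table_*.tsv")):
        name = path.stem.removeprefix("table_")
        table = degs_mod.read_deg_table(path)
        res = degs_mod.filter_degs(table, padj_max=cfg.padj_max, lfc_min=cfg.lfc_min)
        summary = degs_mod.summarize_by_chromosome(res.subset, table)
        enr = degs_mod.enrichment_test(summary)
        summary.to_csv(out / f"chromosome_summary_{name}.csv", index=False)
        enr.to_csv(out / f"enrichment_{name}.csv", index=False)
        _deg_barplot(summary, out / f"deg_percent_{name}.png")


def _deg_barplot(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.bar(summary["chromosome"], summary["deg_percent"], color="#34618d")
    ax.set_xlabel("chromosome")
    ax.set_ylabel("DEGs (% of genes)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _stage_compare(cfg: RunConfig, run: Path, manifest: dict) -> None:
    path = run / "profiles" / "per_nucleus_profiles.csv"
    if not path.is_file():
        raise PipelineError("compare stage requires outputs of the 'profile' stage")
    per_nucleus = pd.read_csv(path)
    result = radial.compare_radial_distributions(per_nucleus)
    out = run / "stats"
    out.mkdir(exist_ok=True)
    result.anova.to_csv(out / "anova.csv")
    result.per_bin.to_csv(out / "per_bin.csv", index=False)
    (out / "summary.json").write_text(json.dumps({
        "interaction_p": result.interaction_p,
        "group_p": result.group_p,
        "bin_p": result.bin_p,
        "adjustment": result.adjustment,
    }, indent=2))


# --------------------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "profile": _stage_profile,
    "beats": _stage_beats,
    "calcium": _stage_calcium,
    "degs": _stage_degs,
    "compare": _stage_compare,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write ``manifest.json``.

    Reruns with an identical config and seed produce bit-identical data
    outputs (the manifest timestamp is stored under its own key so manifests
    compare equal modulo timestamps).
    """
    config.validate()
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.to_json()), "seed": config.seed,
                      "stages_run": [], "outputs": {}, "warnings": []}
    ordered = [s for s in ALL_STAGES if s in config.stages]
    for stage in ordered:
        dep = _STAGE_DEPS.get(stage)
        if dep and dep not in ordered and not _stage_outputs_present(run, dep):
            raise PipelineError(
                f"stage '{stage}' requires outputs of stage '{dep}', which did not run")
        if stage == "report":
            make_report(run)
        else:
            _STAGE_FUNCS[stage](config, run, manifest)
        manifest["stages_run"].append(stage)
    for path in sorted(run.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(run))] = _sha256(path)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (run / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return run


def _stage_outputs_present(run: Path, stage: str) -> bool:
    probes = {"simulate": run / "images", "profile": run / "profiles"}
    return probes.get(stage, run).exists()


def make_report(run: Path) -> Path:
    """Assemble a markdown report; absent stages are marked, not fatal."""
    run = Path(run)
    lines = ["# Synthetic phenotyping run report", ""]
    manifest_path = run / "manifest.json"
    if manifest_path.is_file():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"Seed: {manifest['seed']}")
        for w in manifest.get("warnings", []):
            lines.append(f"- WARNING: {json.dumps(w)}")
        lines.append("")

    lines.append("## Chromosome-territory radial profiles")
    if (run / "profiles" / "profile_matrix.csv").is_file():
        lines.append((run / "profiles" / "profile_matrix.csv").read_text())
        lines.append("![heatmap](profiles/heatmap.png)")
    else:
        lines.append("_absent (profile stage did not run)_")

    lines.append("\n## Group comparison (two-way ANOVA)")
    if (run / "stats" / "summary.json").is_file():
        lines.append("```json\n" + (run / "stats" / "summary.json").read_text() + "\n```")
    else:
        lines.append("_absent (compare stage did not run)_")

    lines.append("\n## Beat summaries")
    if (run / "beats" / "per_trace_summary.csv").is_file():
        lines.append((run / "beats" / "per_trace_summary.csv").read_text())
    else:
        lines.append("_absent (beats stage did not run)_")

    lines.append("\n## Calcium metrics and EC50 fits")
    if (run / "calcium_metrics" / "ec50_fits.json").is_file():
        lines.append("```json\n" + (run / "calcium_metrics" / "ec50_fits.json").read_text() + "\n```")
    else:
        lines.append("_absent (calcium stage did not run)_")

    lines.append("\n## DEGs per chromosome")
    deg_files = sorted((run / "degs").glob("chromosome_summary_*.csv")) \
        if (run / "degs").is_dir() else []
    if deg_files:
        for f in deg_files:
            lines.append(f"### {f.stem}")
            lines.append(f.read_text())
    else:
        lines.append("_absent (degs stage did not run)_")

    out = run / "report.md"
    out.write_text("\n".join(lines))
    return out
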