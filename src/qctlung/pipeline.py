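"""Top-level per-subject and per-cohort pipelines.

``run_subject`` chains the stages for one scan pair: lung segmentation ->
airway segmentation -> analysis exclusions -> density metrics -> airway
tree extraction, measurement and per-generation normalization.  A failure
in the post-bronchodilator scan leaves the baseline results intact.

``run_cohort`` maps a manifest of subjects through ``run_subject``,
assembles the cohort tables, and writes CSV outputs; given the same
manifest and configuration the outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import airways, cohort, density, io, lungseg
from .core import CTVolume

logger = logging.getLogger("qctlung")

__all__ = ["PipelineConfig", "find_trachea_seed", "run_subject", "run_cohort"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis pipeline.

    Defaults: lung threshold -320 HU (between parenchyma and soft tissue),
    congestion threshold -500 HU, analysis HU range [-1000, 0], histogram
    bin width 1 HU, airway leak ratio 2x per relaxation step, generations
    1..6 analysed (trachea = 1), alpha = 0.05 with Bonferroni m = 6 across
    generations.
    """

    lung_threshold_hu: float = -320.0
    congestion_threshold_hu: float = -500.0
    analysis_hu_range: tuple[float, float] = (-1000.0, 0.0)
    bin_width: float = 1.0
    airway_initial_threshold_hu: float = -950.0
    airway_final_threshold_hu: float = -400.0
    airway_step_hu: float = 25.0
    leak_ratio: float = 2.0
    max_generation: int = 6
    generation_offset: int = 0  # 0: trachea = generation 1
    percent_change_mean_convention: str = "magnitude"
    alpha: float = 0.05
    bonferroni_m: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.lung_threshold_hu, self.congestion_threshold_hu,
                    *self.analysis_hu_range):
            if not -1024.0 <= thr <= 3071.0:
                raise ValueError(f"threshold {thr} outside [-1024, 3071] HU")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        tup = data.get("analysis_hu_range")
        if tup is not None:
            data["analysis_hu_range"] = tuple(tup)
        return cls(**data)


def find_trachea_seed(
    volume: CTVolume, threshold_hu: float = -950.0, min_voxels: int = 50
) -> tuple[int, int, int]:
    """Locate a seed voxel inside the trachea.

    The trachea is the most superior interior air component: among
    sub-threshold components not connected to the grid border and at least
    ``min_voxels`` large, the one reaching the lowest slice index is
    chosen, and the centroid of its top cross-section returned.
    """
    from scipy import ndimage

    air = volume.values < threshold_hu
    labels, n = ndimage.label(air, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        raise ValueError("no air below trachea threshold")
    border = set()
    for f in (labels[0], labels[-1], labels[:, 0], labels[:, -1],
              labels[:, :, 0], labels[:, :, -1]):
        border.update(np.unique(f).tolist())
    border.discard(0)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    best_lab, best_z = None, None
    for lab in range(1, n + 1):
        if lab in border or sizes[lab - 1] < min_voxels:
            continue
        zmin = int(np.argmax((labels == lab).any(axis=(1, 2))))
        if best_z is None or zmin < best_z:
            best_lab, best_z = lab, zmin
    if best_lab is None:
        raise ValueError("no interior airway component found")
    sl = labels[best_z + 2] if best_z + 2 < labels.shape[0] else labels[best_z]
    ys, xs = np.nonzero(sl == best_lab)
    if ys.size == 0:
        sl = labels[best_z]
        ys, xs = np.nonzero(sl == best_lab)
        return (best_z, int(ys.mean()), int(xs.mean()))
    return (best_z + 2, int(round(ys.mean())), int(round(xs.mean())))


def _analyse_timepoint(
    volume: CTVolume, config: PipelineConfig
) -> tuple[density.DensityMetrics, list[airways.GenerationSummary], dict]:
    lung = lungseg.segment_lung_fields(volume, threshold_hu=config.lung_threshold_hu)
    seed = find_trachea_seed(volume)
    lumen = airways.segment_airway_tree(
        volume, seed,
        initial_threshold_hu=config.airway_initial_threshold_hu,
        final_threshold_hu=config.airway_final_threshold_hu,
        step_hu=config.airway_step_hu,
        leak_ratio=config.leak_ratio,
    )
    analysis, excluded = lungseg.apply_analysis_exclusions(
        volume, lung, lumen, hu_range=config.analysis_hu_range
    )
    metrics = density.compute_density_metrics(volume, analysis,
                                              bin_width=config.bin_width)
    tree = airways.extract_centerline_tree(
        lumen, spacing=volume.spacing, origin=volume.origin, root_hint=seed
    )
    airways.measure_tree(volume, tree)
    gens = airways.per_generation_summary(tree, max_generation=config.max_generation)
    info = {"excluded": excluded, "seed": list(seed),
            "n_segments": len(tree.segments), "max_generation": tree.max_generation}
    return metrics, gens, info


def run_subject(
    pre: CTVolume | str,
    tlc: float,
    post: CTVolume | str | None = None,
    subject_id: str = "subject",
    group: str = "control",
    spirometry: dict[str, float] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[cohort.SubjectRecord, dict]:
    """Run the full analysis for one subject (pre scan, optional post scan).

    Returns the populated record and a per-stage info dict.  A post-scan
    failure is logged and leaves the record valid with post fields absent.
    """
    config = config or PipelineConfig()
    if isinstance(pre, (str, Path)):
        pre = io.read_volume(pre)
    metrics, gens, info_pre = _analyse_timepoint(pre, config)
    record = cohort.SubjectRecord(
        subject_id=subject_id, group=group, tlc=tlc,
        spirometry=spirometry or {},
        pre_density=metrics,
        pre_generations=[airways.normalize_to_subject(g, tlc) for g in gens
                         if g.flag != "absent"],
    )
    info = {"pre": info_pre}
    if post is not None:
        try:
            if isinstance(post, (str, Path)):
                post = io.read_volume(post)
            m_post, g_post, info_post = _analyse_timepoint(post, config)
            record.post_density = m_post
            record.post_generations = [
                airways.normalize_to_subject(g, tlc) for g in g_post
                if g.flag != "absent"
            ]
            info["post"] = info_post
        except Exception as exc:  # isolation: baseline results survive
            logger.warning("subject %s: post scan failed: %s", subject_id, exc)
            info["post_error"] = str(exc)
    return record, info


def run_cohort(
    manifest: str | pd.DataFrame,
    out_dir: str,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every subject of a manifest and write the cohort tables.

    The manifest needs columns ``subject_id, group, tlc, pre_path`` and
    optionally ``post_path`` plus spirometry columns (``fvc_pct`` etc.).
    Subjects whose baseline scan fails are excluded (logged); the run
    continues.  Outputs are deterministic given (manifest, config).
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, log_rows = [], []
    for _, row in manifest.iterrows():
        spiro = {v: float(row[v]) for v in cohort.SPIRO_VARS if v in row and pd.notna(row[v])}
        post = row.get("post_path")
        post = None if (post is None or (isinstance(post, float) and np.isnan(post))) else post
        try:
            rec, info = run_subject(
                pre=row["pre_path"], post=post, tlc=float(row["tlc"]),
                subject_id=str(row["subject_id"]), group=str(row["group"]),
                spirometry=spiro, config=config,
            )
            records.append(rec)
            log_rows.append({"subject_id": rec.subject_id, "status": "ok",
                             **{f"pre_{k}": v for k, v in info["pre"].items()
                                if not isinstance(v, dict)},
                             "post_error": info.get("post_error", "")})
        except Exception as exc:
            logger.warning("subject %s excluded: %s", row["subject_id"], exc)
            log_rows.append({"subject_id": str(row["subject_id"]),
                             "status": f"excluded: {exc}"})
    n_groups = pd.Series([r.group for r in records]).value_counts()
    if len(n_groups) and (n_groups < 2).any():
        raise ValueError(f"need >= 2 subjects per group, got {n_groups.to_dict()}")

    tables = cohort.build_study_tables(records, alpha=config.alpha,
                                       max_generation=config.max_generation)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    # per-subject flat table
    rows = []
    for r in records:
        base = {"subject_id": r.subject_id, "group": r.group, "tlc": r.tlc,
                **r.spirometry}
        if r.pre_density:
            base.update({f"pre_{k}": v for k, v in r.pre_density.as_dict().items()})
        if r.post_density:
            base.update({f"post_{k}": v for k, v in r.post_density.as_dict().items()})
        for g in r.pre_generations:
            base[f"pre_gen{g.generation}_area"] = g.mean_area
            base[f"pre_gen{g.generation}_wall"] = g.mean_wall
            base[f"pre_gen{g.generation}_area_over_tlc"] = g.area_over_tlc
            base[f"pre_gen{g.generation}_wall_over_area"] = g.wall_over_area
        rows.append(base)
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    pd.DataFrame(log_rows).to_csv(out / "run_log.csv", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
    return tables
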