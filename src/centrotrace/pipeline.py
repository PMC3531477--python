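"""End-to-end orchestration: simulate -> quantify -> normalize -> compare,
plus the generation-model report.  All randomness flows from one top-level
seed, split per stage and group by fixed offsets, so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dilution import (
    EmbryoModelParams,
    cellularization_cycle,
    density_ratio,
    label_fraction_at_mitosis,
    meiotic_dilution_factor,
    mendelian_transmission_fraction,
)
from .inheritance import (
    GermlineParams,
    NonConvergentError,
    autosome_trajectory,
    sample_autosome_lineages,
    stabilization_generation,
    x_expected_trajectory,
    y_trajectory,
)
from .quantify import (
    SegmentationParams,
    cell_total,
    compare_groups,
    measurements_frame,
    normalize_to_control,
    segment_spots,
)
from .synthetic import SceneConfig, generate_cross_panel, generate_scene

logger = logging.getLogger(__name__)

# fixed seed offsets so stages can be rerun independently
_SPERM_OFFSET = 1_000
_EMBRYO_OFFSET = 5_000
_GROUP_STRIDE = 211


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one quantification experiment.

    ``groups`` maps a group label to the sperm perturbation factor applied
    to the father; a "control" group with factor 1 is mandatory.
    """

    seed: int = 0
    groups: dict[str, float] = field(default_factory=lambda: {"control": 1.0, "depleted": 0.5})
    n_sperm_scenes: int = 3
    n_sperm_nuclei: int = 12
    n_embryos: int = 3
    n_embryo_nuclei: int = 6
    scene: SceneConfig = field(default_factory=SceneConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if "control" not in self.groups:
            raise ConfigError("missing control group (a 'control' entry with factor 1 is required)")
        for label, factor in self.groups.items():
            if factor <= 0:
                raise ConfigError(f"group {label!r} has nonpositive factor {factor}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scene" in raw:
            raw["scene"] = SceneConfig(**raw["scene"])
        if "segmentation" in raw:
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        return cls(**raw)


def quantify_scene(scene, params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment one scene and tabulate per-spot corrected intensities."""
    regions = segment_spots(scene.gfp_image, params, nucleus_labels=scene.nucleus_masks)
    return measurements_frame(regions)


def _nucleus_totals(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.empty:
        return pd.DataFrame(columns=["nucleus_id", "total"])
    out = frame.groupby("nucleus_id", as_index=False)["corrected"].sum()
    return out.rename(columns={"corrected": "total"})


def run_quantification_experiment(config: RunConfig) -> dict:
    """Full image path for every group: generate, segment, correct,
    normalize to the control mean (100 a.u.), and compare groups.

    Sperm scenes carry the perturbation on every spot; embryo scenes carry
    it on the paternal half-set only.
    """
    group_order = ["control"] + sorted(g for g in config.groups if g != "control")
    per_nucleus_rows = []
    per_spot_frames = []
    totals: dict[tuple[str, str], list[float]] = {}

    for gi, label in enumerate(group_order):
        factor = config.groups[label]
        # sperm panel: factor scales every spot
        sperm_cfg = replace(
            config.scene,
            stage="sperm",
            n_nuclei=config.n_sperm_nuclei,
            base_intensity=config.scene.base_intensity * factor,
        )
        sperm_totals = []
        for i in range(config.n_sperm_scenes):
            scfg = replace(sperm_cfg, seed=config.seed + _SPERM_OFFSET + gi * _GROUP_STRIDE + i)
            scene = generate_scene(scfg)
            spots = quantify_scene(scene, config.segmentation)
            spots.insert(0, "group", label)
            spots.insert(1, "stage", "sperm")
            spots.insert(2, "scene", i)
            per_spot_frames.append(spots)
            for r in _nucleus_totals(spots).itertuples():
                sperm_totals.append(float(r.total))
                per_nucleus_rows.append(
                    dict(group=label, stage="sperm", scene=i, nucleus_id=int(r.nucleus_id), total=float(r.total))
                )
        totals[(label, "sperm")] = sperm_totals

        # embryo panel: factor scales the paternal half-set only
        embryo_cfg = replace(
            config.scene,
            stage="embryo_metaphase",
            n_nuclei=config.n_embryo_nuclei,
            seed=config.seed + _EMBRYO_OFFSET + gi * _GROUP_STRIDE,
        )
        embryo_totals = []
        for i, scene in enumerate(generate_cross_panel(factor, config.n_embryos, embryo_cfg)):
            spots = quantify_scene(scene, config.segmentation)
            spots.insert(0, "group", label)
            spots.insert(1, "stage", "embryo")
            spots.insert(2, "scene", i)
            per_spot_frames.append(spots)
            for r in _nucleus_totals(spots).itertuples():
                embryo_totals.append(float(r.total))
                per_nucleus_rows.append(
                    dict(group=label, stage="embryo", scene=i, nucleus_id=int(r.nucleus_id), total=float(r.total))
                )
        totals[(label, "embryo")] = embryo_totals

    per_nucleus = pd.DataFrame(
        per_nucleus_rows, columns=["group", "stage", "scene", "nucleus_id", "total"]
    )
    per_spot = (
        pd.concat(per_spot_frames, ignore_index=True)
        if per_spot_frames
        else pd.DataFrame()
    )

    # normalize each stage to its control mean (control mean -> 100 a.u.)
    normalized = np.full(len(per_nucleus), np.nan)
    for stage in ("sperm", "embryo"):
        control = totals[("control", stage)]
        sel = per_nucleus["stage"] == stage
        normalized[sel.to_numpy()] = normalize_to_control(
            per_nucleus.loc[sel, "total"].to_numpy(), control
        )
    per_nucleus["normalized_au"] = normalized

    summary: dict = {"seed": config.seed, "groups": {}, "comparisons": {}}
    for label in group_order:
        summary["groups"][label] = {}
        for stage in ("sperm", "embryo"):
            vals = normalize_to_control(totals[(label, stage)], totals[("control", stage)])
            summary["groups"][label][stage] = {
                "n": int(len(vals)),
                "mean_au": float(np.mean(vals)),
                "sd_au": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
    for label in group_order:
        if label == "control":
            continue
        summary["comparisons"][label] = {"factor": config.groups[label]}
        for stage in ("sperm", "embryo"):
            cmp = compare_groups(totals[("control", stage)], totals[(label, stage)])
            summary["comparisons"][label][stage] = cmp
    return {"per_spot": per_spot, "per_nucleus": per_nucleus, "summary": summary}


def run_model_report(
    params: GermlineParams | None = None,
    perturbation_factor: float = 1.0,
    horizon: int = 20,
    tol: float = 1e-9,
    stochastic_lineages: int = 0,
    seed: int = 0,
) -> dict:
    """Generation-model trajectories plus the closed-form arithmetic models."""
    params = params or GermlineParams()
    n = params.n_generations
    auto = autosome_trajectory(params, n)
    ys = y_trajectory(params, n)
    xs = x_expected_trajectory(params, n)
    rows = [
        {"generation": 0, "chromosome_class": cls, "parental_origin": origin, "level": params.founder_level}
        for cls, origin in (
            ("autosome", "paternal"),
            ("autosome", "maternal"),
            ("X", "maternal"),
            ("Y", "paternal"),
        )
    ]
    for t in range(1, n + 1):
        p, m = auto[t - 1]
        rows.append({"generation": t, "chromosome_class": "autosome", "parental_origin": "paternal", "level": p})
        rows.append({"generation": t, "chromosome_class": "autosome", "parental_origin": "maternal", "level": m})
        rows.append({"generation": t, "chromosome_class": "X", "parental_origin": "maternal", "level": xs[t - 1]})
        rows.append({"generation": t, "chromosome_class": "Y", "parental_origin": "paternal", "level": ys[t - 1]})
    trajectories = pd.DataFrame(rows, columns=["generation", "chromosome_class", "parental_origin", "level"])

    try:
        stab: int | str = stabilization_generation(params, horizon=horizon, tol=tol)
    except NonConvergentError as exc:  # reported, not raised
        stab = f"non-convergent: {exc}"
    p_final, m_final = auto[-1]
    summary: dict = {
        "mode": params.mode,
        "founder_level": params.founder_level,
        "n_generations": n,
        "stabilization_generation": stab,
        "final_paternal_maternal_difference": p_final - m_final,
        "final_levels": {"autosome_paternal": p_final, "autosome_maternal": m_final, "X": xs[-1], "Y": ys[-1]},
        "perturbation": {
            "factor": perturbation_factor,
            "embryo_mix_relative_total": (perturbation_factor + 1.0) / 2.0,
        },
        "dilution": {
            "meiotic_dilution_factor": meiotic_dilution_factor(),
            "cellularization_cycle": {"diploid": cellularization_cycle(2), "haploid": cellularization_cycle(1)},
            "density_ratio_haploid_vs_diploid": density_ratio(),
            "mendelian_transmission_fraction": {
                f: mendelian_transmission_fraction(f) for f in ("hemizygous", "homozygous")
            },
            "label_fraction_at_mitosis": {k: label_fraction_at_mitosis(k) for k in (1, 2, 3)},
        },
    }
    if stochastic_lineages > 0:
        levels, last = sample_autosome_lineages(params, n, stochastic_lineages, seed=seed)
        out = {}
        for sex, det in (("male", p_final), ("female", m_final)):
            sub = levels[last == sex]
            out[sex] = {
                "n": int(sub.size),
                "mean": float(sub.mean()),
                "sem": float(sub.std(ddof=1) / np.sqrt(sub.size)),
                "deterministic": det,
            }
        summary["stochastic_crosscheck"] = out
    return {"trajectories": trajectories, "summary": summary}


def write_report(outdir, tables: dict[str, pd.DataFrame], summary: dict, config_text: str, seed: int) -> dict[str, Path]:
    """Write CSV tables, a summary JSON and a plain-text run log.

    Output bytes depend only on the inputs, so reruns with the same seed
    reproduce the files exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        paths[name] = outdir / f"{name}.csv"
        frame.to_csv(paths[name], index=False)
    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    paths["log"] = outdir / "run_log.txt"
    with open(paths["log"], "w") as fh:
        fh.write(f"centrotrace version: {__version__}\n")
        fh.write(f"numpy version: {np.__version__}\n")
        fh.write(f"seed: {seed}\n")
        fh.write("config:\n")
        fh.write(config_text if config_text.endswith("\n") else config_text + "\n")
    return paths
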