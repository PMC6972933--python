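"""End-to-end driver: subjects -> selection -> connectomics -> laterality.

A pipeline run processes each subject's left and right hemisphere through
the virtual dissection and endpoint analysis, then aggregates hemispheric
totals (tract count, tract volume, mean FA) across subjects into
laterality indices and a paired t-test.

Subjects come in two flavors:

* **phantom subjects** — generated on the fly from a ``PhantomConfig``
  base and a per-subject seed; the generated ILF/AF bundles serve as the
  reference tractograms, exactly as anatomically identified bundles would.
  ``right_count_factor`` scales the right-hemisphere VOF count to emulate
  a lateralized population.
* **file subjects** — pre-existing tractogram/parcellation/FA/reference
  paths per hemisphere.

Every run writes a ``run_log.json`` echoing the full configuration, the
seed and per-filter rejection counts, so a run is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    build_connectivity_matrix,
    compute_tract_metrics,
    connection_ratios,
    endpoint_ratios,
    mean_fa,
    tract_volume,
)
from .connectogram import export_connectogram
from .laterality import laterality_index, summarize_subjects
from .phantom import Phantom, PhantomConfig, make_phantom
from .selection import SelectionCriteria, run_selection
from .tract_io import (
    read_parcellation,
    read_scalar_volume,
    read_tractogram,
    write_tractogram,
)

__all__ = ["PipelineConfig", "SubjectSpec", "run_pipeline"]


@dataclass
class SubjectSpec:
    subject_id: str
    seed: int | None = None                      # phantom mode
    paths: dict[str, dict[str, str]] | None = None  # file mode: hemi -> {tracts, parcellation, labels, ...}


@dataclass
class PipelineConfig:
    out_dir: str = "vof_pipeline_out"
    seed: int = 0
    hemispheres: tuple[str, ...] = ("L", "R")
    subjects: list[SubjectSpec] = field(default_factory=list)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    right_count_factor: float = 1.0
    tract_format: str = "tck"
    write_outputs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        subjects = [
            SubjectSpec(
                subject_id=str(s.get("id", f"subject{i:02d}")),
                seed=s.get("seed"),
                paths=s.get("paths"),
            )
            for i, s in enumerate(raw.pop("subjects", []), start=1)
        ]
        phantom = PhantomConfig(**raw.pop("phantom", {}))
        criteria = SelectionCriteria(**raw.pop("criteria", {}))
        cfg = cls(subjects=subjects, phantom=phantom, criteria=criteria,
                  **{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.hemispheres = tuple(cfg.hemispheres)
        return cfg


class StageError(RuntimeError):
    def __init__(self, subject: str, stage: str, cause: Exception):
        super().__init__(f"subject {subject!r}, stage {stage!r}: {cause}")
        self.subject, self.stage, self.cause = subject, stage, cause


def _phantom_for(config: PipelineConfig, spec: SubjectSpec, hemisphere: str) -> Phantom:
    seed = spec.seed if spec.seed is not None else config.seed
    n_vof = config.phantom.n_vof
    if hemisphere == "R":
        n_vof = int(round(n_vof * config.right_count_factor))
    return make_phantom(replace(config.phantom, hemisphere=hemisphere, n_vof=n_vof, seed=seed))


def _load_subject_hemi(spec: SubjectSpec, hemisphere: str) -> dict[str, Any]:
    paths = (spec.paths or {}).get(hemisphere)
    if paths is None:
        raise ValueError(f"subject {spec.subject_id}: no paths for hemisphere {hemisphere}")
    data: dict[str, Any] = {
        "tractogram": read_tractogram(paths["tracts"]),
        "parcellation": read_parcellation(paths["parcellation"], paths["labels"]),
        "fa": read_scalar_volume(paths["fa"]) if "fa" in paths else None,
        "roa": read_scalar_volume(paths["roa"]) if "roa" in paths else None,
        "ilf": read_tractogram(paths["ilf"]) if "ilf" in paths else None,
        "af": read_tractogram(paths["af"]) if "af" in paths else None,
    }
    return data


def _process_hemisphere(
    config: PipelineConfig, spec: SubjectSpec, hemisphere: str, out_dir: Path | None
) -> dict[str, Any]:
    if spec.paths is not None:
        data = _load_subject_hemi(spec, hemisphere)
    else:
        ph = _phantom_for(config, spec, hemisphere)
        data = {
            "tractogram": ph.tractogram,
            "parcellation": ph.parcellation,
            "fa": ph.fa,
            "roa": None,
            "ilf": ph.bundle("ilf"),
            "af": ph.bundle("af"),
        }
    criteria = replace(
        config.criteria,
        hemisphere=hemisphere,
        lateral_reference=data["ilf"],
        posterior_reference=data["af"],
        roa=data["roa"] if data["roa"] is not None else config.criteria.roa,
    )
    report = run_selection(data["tractogram"], data["parcellation"], criteria)
    matrix = build_connectivity_matrix(report, data["parcellation"], hemisphere)
    ratios = endpoint_ratios(matrix, data["parcellation"].table)
    conn = connection_ratios(matrix) if matrix.total() > 0 else pd.Series(dtype=np.float64)
    metrics = compute_tract_metrics(
        data["tractogram"], report, data["parcellation"], data["fa"], hemisphere
    )
    accepted = data["tractogram"].subset(report.accepted)
    totals = {
        "n_tracts": float(len(report.accepted)),
        "volume_mm3": tract_volume(list(accepted), data["parcellation"].affine)
        if len(accepted) else 0.0,
        "mean_fa": mean_fa(list(accepted), data["fa"])
        if len(accepted) and data["fa"] is not None else np.nan,
    }
    result = {
        "report": report,
        "matrix": matrix,
        "endpoint_ratios": ratios,
        "connection_ratios": conn,
        "metrics": metrics,
        "totals": totals,
    }
    if out_dir is not None:
        prefix = out_dir / hemisphere
        out_dir.mkdir(parents=True, exist_ok=True)
        (prefix.with_suffix(".report.json")).write_text(json.dumps(report.to_dict(), indent=1))
        matrix.counts.to_csv(prefix.with_suffix(".matrix.tsv"), sep="\t")
        pd.concat(ratios, names=["group", "parcel"]).rename("percent").to_csv(
            prefix.with_suffix(".endpoint_ratios.tsv"), sep="\t"
        )
        conn.rename("percent").rename_axis(["parcel_a", "parcel_b"]).to_csv(
            prefix.with_suffix(".connection_ratios.tsv"), sep="\t"
        )
        metrics.to_csv(prefix.with_suffix(".metrics.tsv"), sep="\t", index=False)
        write_tractogram(accepted, prefix.with_suffix(f".accepted.{config.tract_format}"),
                         config.tract_format, affine=data["parcellation"].affine,
                         dimensions=data["parcellation"].labels.shape)
        if matrix.total() > 0:
            export_connectogram(matrix, data["parcellation"].table,
                                prefix.with_suffix(".connectogram.tsv"))
    return result


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all subjects and hemispheres; return (and optionally write) the
    per-subject results, the subject laterality table and group summaries."""
    out_root = Path(config.out_dir) if config.write_outputs else None
    subjects = config.subjects or [SubjectSpec("subject01", seed=config.seed)]
    per_subject: dict[str, dict[str, Any]] = {}
    for spec in subjects:
        per_subject[spec.subject_id] = {}
        for hemi in config.hemispheres:
            try:
                sub_dir = out_root / spec.subject_id if out_root else None
                per_subject[spec.subject_id][hemi] = _process_hemisphere(
                    config, spec, hemi, sub_dir
                )
            except StageError:
                raise
            except Exception as exc:
                raise StageError(spec.subject_id, f"hemisphere {hemi}", exc) from exc

    rows = []
    for sid, hemis in per_subject.items():
        for quantity in ("n_tracts", "volume_mm3", "mean_fa"):
            L = hemis.get("L", {}).get("totals", {}).get(quantity, np.nan)
            R = hemis.get("R", {}).get("totals", {}).get(quantity, np.nan)
            li = laterality_index(L, R) if np.isfinite(L) and np.isfinite(R) else np.nan
            rows.append({"subject": sid, "quantity": quantity, "L": L, "R": R, "LI": li})
    laterality_table = pd.DataFrame(rows)

    summaries = {}
    if len(subjects) >= 2 and set(config.hemispheres) >= {"L", "R"}:
        for quantity in ("n_tracts", "volume_mm3", "mean_fa"):
            sub = laterality_table[laterality_table["quantity"] == quantity]
            L, R = sub["L"].to_numpy(), sub["R"].to_numpy()
            if np.all(np.isfinite(L)) and np.all(np.isfinite(R)):
                summaries[quantity] = summarize_subjects(L, R, quantity)

    results = {
        "per_subject": per_subject,
        "laterality": laterality_table,
        "summaries": summaries,
    }
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)
        laterality_table.to_csv(out_root / "laterality_subjects.tsv", sep="\t", index=False)
        if summaries:
            pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()]).to_csv(
                out_root / "group_summary.tsv", sep="\t", index=False
            )
        log = {
            "version": __version__,
            "seed": config.seed,
            "n_subjects": len(subjects),
            "hemispheres": list(config.hemispheres),
            "criteria": {
                "group_a": list(config.criteria.group_a),
                "group_b": list(config.criteria.group_b),
                "endpoint_radius_mm": config.criteria.endpoint_radius_mm,
                "required_axis": config.criteria.required_axis,
                "min_axis_fraction": config.criteria.min_axis_fraction,
                "slab_mm": config.criteria.slab_mm,
                "slab_majority": config.criteria.slab_majority,
            },
            "phantom": {
                k: v for k, v in dataclasses.asdict(config.phantom).items()
                if not isinstance(v, dict)
            },
            "right_count_factor": config.right_count_factor,
            "rejections": {
                sid: {h: r["report"].rejections for h, r in hemis.items()}
                for sid, hemis in per_subject.items()
            },
        }
        (out_root / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return results
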