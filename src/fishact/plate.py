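"""Multi-well experiments: region cropping, batch processing, run manifests.

A :class:`WellLayout` maps rectangular pixel regions of the plate image to
well ids (one animal per well) and well ids to condition labels.
:func:`run_experiment` runs the full workflow — crop, per-well activity
trace, binning, heat map, cessation table, group comparison — and writes a
machine-readable manifest so identical reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import Frame, FrameSequence, load_sequence
from .pipeline import PipelineConfig, process_sequence
from . import analysis

__all__ = ["WellRegion", "WellLayout", "RunConfig", "crop_wells", "run_experiment"]

log = logging.getLogger("fishact")


@dataclass(frozen=True)
class WellRegion:
    """Half-open pixel rectangle [row_min, row_max) x [col_min, col_max)."""

    well_id: str
    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise ValueError(f"well {self.well_id!r} has an empty region")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError(f"well {self.well_id!r} has negative coordinates")


@dataclass
class WellLayout:
    plate_name: str
    wells: list[WellRegion]
    condition_map: dict[str, str]

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate well ids in layout")
        for i, w1 in enumerate(self.wells):
            for w2 in self.wells[i + 1:]:
                if (w1.row_min < w2.row_max and w2.row_min < w1.row_max
                        and w1.col_min < w2.col_max and w2.col_min < w1.col_max):
                    raise ValueError(
                        f"wells {w1.well_id!r} and {w2.well_id!r} overlap")

    def condition_of(self, well_id: str) -> str:
        return self.condition_map.get(well_id, "unknown")

    @classmethod
    def from_json(cls, path: str | Path) -> "WellLayout":
        with open(path) as fh:
            data = json.load(fh)
        wells = [WellRegion(**w) for w in data["wells"]]
        return cls(plate_name=data.get("plate_name", "plate"),
                   wells=wells, condition_map=data.get("condition_map", {}))

    def to_json(self, path: str | Path) -> None:
        data = {
            "plate_name": self.plate_name,
            "wells": [asdict(w) for w in self.wells],
            "condition_map": self.condition_map,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)


@dataclass
class RunConfig:
    input_dir: str
    layout: WellLayout
    output_dir: str
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    bin_width: float = 300.0
    capture_interval: float = 1.0
    exclude_outlier: bool = True
    cessation_hold: float = 600.0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["layout"] = WellLayout(
            plate_name=data["layout"].get("plate_name", "plate"),
            wells=[WellRegion(**w) for w in data["layout"]["wells"]],
            condition_map=data["layout"].get("condition_map", {}),
        )
        if "pipeline" in data:
            data["pipeline"] = PipelineConfig(**data["pipeline"])
        return cls(**data)


def crop_wells(seq: FrameSequence, layout: WellLayout) -> dict[str, FrameSequence]:
    """Cut one sub-sequence per well; timestamps are preserved.

    Pixel (r, c) of well w corresponds to plate pixel
    (r + row_min, c + col_min).
    """
    h, w = seq.shape
    out: dict[str, FrameSequence] = {}
    for well in layout.wells:
        if well.row_max > h or well.col_max > w:
            raise ValueError(
                f"well {well.well_id!r} [{well.row_min}:{well.row_max}, "
                f"{well.col_min}:{well.col_max}] exceeds frame bounds {h}x{w}")
        frames = [
            Frame(f.pixels[well.row_min:well.row_max, well.col_min:well.col_max],
                  f.timestamp)
            for f in seq.frames
        ]
        out[well.well_id] = FrameSequence(frames=frames,
                                          capture_interval=seq.capture_interval)
    return out


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "input_dir": str(config.input_dir),
            "layout": {
                "plate_name": config.layout.plate_name,
                "wells": [asdict(w) for w in config.layout.wells],
                "condition_map": config.layout.condition_map,
            },
            "pipeline": asdict(config.pipeline),
            "bin_width": config.bin_width,
            "capture_interval": config.capture_interval,
            "exclude_outlier": config.exclude_outlier,
            "cessation_hold": config.cessation_hold,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_experiment(config: RunConfig) -> dict:
    """Process a whole plate; returns the run manifest (also written to disk).

    Per-well failures are logged and skipped; their count is reported in the
    manifest under ``n_failures`` (callers can map it to an exit status).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    seq = load_sequence(config.input_dir, capture_interval=config.capture_interval)
    out_dir.mkdir(parents=True, exist_ok=True)

    crops = crop_wells(seq, config.layout)
    traces, failures = [], []
    for well_id, sub in crops.items():
        cond = config.layout.condition_of(well_id)
        try:
            tr = process_sequence(sub, config.pipeline,
                                  animal_id=well_id, condition=cond)
        except Exception as exc:  # noqa: BLE001 - a bad well must not kill the run
            log.error("well %s failed: %s", well_id, exc)
            failures.append({"well_id": well_id, "error": str(exc)})
            continue
        tr.to_csv(out_dir / f"trace_{well_id}.csv")
        traces.append(tr)
        log.info("well %s (%s): %d samples, mean activity %.3f",
                 well_id, cond, len(tr), tr.activities.mean())

    manifest: dict = {
        "plate_name": config.layout.plate_name,
        "config_hash": _config_hash(config),
        "n_frames": len(seq),
        "n_wells": len(crops),
        "n_failures": len(failures),
        "failures": failures,
        "versions": _versions(),
    }

    if traces:
        by_cond: dict[str, list] = {}
        for tr in traces:
            by_cond.setdefault(tr.condition, []).append(tr)
        groups = [analysis.ConditionGroup(condition=c, traces=ts)
                  for c, ts in by_cond.items()]

        # binned traces
        binned_rows = []
        for tr in traces:
            b = analysis.bin_trace(tr, config.bin_width)
            for t0, m in zip(b.bin_start_times, b.bin_means):
                binned_rows.append({"animal_id": tr.animal_id,
                                    "condition": tr.condition,
                                    "bin_start_s": t0, "mean_activity": m})
        pd.DataFrame(binned_rows).to_csv(out_dir / "binned.csv", index=False,
                                         float_format="%.9g")

        # heat map
        hm = analysis.heatmap_matrix(groups, config.bin_width)
        hm.to_csv(out_dir / "heatmap.csv", float_format="%.9g")
        analysis.plot_heatmap(hm, out_dir / "heatmap.png")

        # cessation (death) table
        cess_rows = []
        for tr in traces:
            t_star = analysis.detect_cessation(tr, epsilon=0.0,
                                               hold=config.cessation_hold)
            cess_rows.append({"animal_id": tr.animal_id, "condition": tr.condition,
                              "cessation_time_s": t_star})
        pd.DataFrame(cess_rows).to_csv(out_dir / "cessation.csv", index=False)

        # group comparison on per-animal means
        stat_groups = []
        for g in groups:
            if config.exclude_outlier and len(g.traces) >= 3:
                g = analysis.exclude_highest_variance(g)
            stat_groups.append(g)
        if len(stat_groups) >= 2 and all(len(g.traces) >= 2 for g in stat_groups):
            comp = analysis.compare_groups(stat_groups)
            comp.to_dataframe().to_csv(out_dir / "comparison.csv", index=False,
                                       float_format="%.9g")
            manifest["anova_p"] = comp.anova_p
            manifest["f_statistic"] = comp.f_statistic

        manifest["group_means"] = {
            g.condition: float(g.mean_activity_per_animal.mean()) for g in groups
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %d wells, %d failures", len(crops), len(failures))
    return manifest


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "fishact": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
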