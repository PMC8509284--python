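"""End-to-end simulated study orchestration.

A study is a set of cohorts (group, timepoint, n) imaged with one
protocol.  For every subject the pipeline runs phantom generation, the
three acquisitions, the three voxel-wise fits, ROI statistics and — for
the ADC map — whole-kidney histogram metrics; afterwards the group
statistics layer compares cohorts.  All randomness derives from a single
master seed through a stable counter scheme, so adding a cohort to a
configuration does not perturb the subjects of existing cohorts, and a
re-run with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .groupstats import GroupComparison, compare_groups, comparisons_table
from .histogram import histogram_metrics
from .phantom import EllipseGeometry, make_phantom, region_mask
from .presets import tissue_parameters
from .relaxometry import fit_adc, fit_t1_ir, fit_t2
from .roi import RegionStatistics, cohort_table, region_means
from .synthesis import Protocol, synthesize_subject

__all__ = ["CohortConfig", "StudyConfig", "StudyResult", "run_study", "subject_seed"]

log = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    group: str
    timepoint: str = "none"
    n: int = 1

    @property
    def name(self) -> str:
        return f"{self.group}_{self.timepoint}" if self.timepoint != "none" else self.group


@dataclass
class StudyConfig:
    """Everything needed to reproduce a simulated study."""

    cohorts: list[CohortConfig] = field(
        default_factory=lambda: [
            CohortConfig("control", "none", 22),
            CohortConfig("isogenic", "w3", 7),
            CohortConfig("allogenic", "w3", 5),
        ]
    )
    protocol: Protocol = field(default_factory=Protocol)
    shape: tuple[int, int] = (128, 128)
    master_seed: int = 0
    r2_floor: float = 0.9
    compute_stderr: bool = False
    outdir: str | None = None
    write_intermediates: bool = False

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("study needs at least one cohort")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ValueError(f"cohort names must be unique, got {names}")
        for c in self.cohorts:
            if c.n < 1:
                raise ValueError(f"cohort {c.name!r} must have n >= 1, has n={c.n}")
        seeds = [
            subject_seed(self.master_seed, c.group, c.timepoint, i)
            for c in self.cohorts
            for i in range(c.n)
        ]
        if len(set(seeds)) != len(seeds):
            raise ValueError("derived subject seeds collide; change the master seed")

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        d = dataclasses.asdict(self)
        d["protocol"] = self.protocol.to_dict()
        d["shape"] = self.shape
        return listify(d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        cohorts = [CohortConfig(**c) for c in d.pop("cohorts", [])]
        proto = d.pop("protocol", {})
        if isinstance(proto, dict):
            for k in ("ti_ms", "te_ms", "b_s_per_mm2"):
                if k in proto:
                    proto[k] = tuple(proto[k])
            proto = Protocol(**proto)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(cohorts=cohorts or cls().cohorts, protocol=proto, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def subject_seed(master_seed: int, group: str, timepoint: str, index: int) -> int:
    """Stable per-subject seed: CRC of the cohort identity, offset by index.

    Independent of cohort ordering, so reconfiguring a study leaves
    existing subjects' data untouched.  Always < 2**31.
    """
    tag = f"{group}:{timepoint}:{index}"
    return (zlib.crc32(tag.encode()) ^ (master_seed * 2654435761)) % (2**31 - 1)


@dataclass
class SubjectResult:
    subject_id: str
    cohort: CohortConfig
    seed: int
    region_stats: list[RegionStatistics]
    adc_metrics: "object"  # HistogramMetrics


@dataclass
class StudyResult:
    """Result bundle of one simulated study."""

    config: StudyConfig
    region_table: pd.DataFrame
    histogram_table: pd.DataFrame
    comparisons: list[GroupComparison]
    manifest: dict
    failures: list[tuple[str, str]]

    @property
    def ok(self) -> bool:
        return not self.failures

    def comparisons_table(self) -> pd.DataFrame:
        return comparisons_table(self.comparisons)


def _run_subject(cohort: CohortConfig, index: int, config: StudyConfig, outdir: Path | None):
    seed = subject_seed(config.master_seed, cohort.group, cohort.timepoint, index)
    subject_id = f"{cohort.name}_{index:02d}"
    params = tissue_parameters(
        cohort.group, cohort.timepoint, protocol=config.protocol,
        label_map=None if config.shape == (128, 128) else _label_cache(config.shape),
    )
    phantom = make_phantom(params, shape=config.shape, seed=seed)
    series = synthesize_subject(phantom, config.protocol, seed=seed)

    fits = {
        "t1": fit_t1_ir(series["t1"], r2_floor=config.r2_floor, compute_stderr=config.compute_stderr),
        "t2": fit_t2(series["t2"], r2_floor=config.r2_floor),
        "adc": fit_adc(series["dwi"], r2_floor=config.r2_floor),
    }
    stats = [
        region_means(m, phantom.label_map, subject_id, cohort.group, cohort.timepoint)
        for m in fits.values()
    ]
    wk = region_mask(phantom.label_map, "whole_kidney") & fits["adc"].mask
    metrics = histogram_metrics(fits["adc"].values[wk])

    if outdir is not None and config.write_intermediates:
        from . import io as _io

        sdir = outdir / "subjects" / subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        _io.save_phantom(phantom, sdir / "phantom")
        for name, s in series.items():
            _io.save_series(s, sdir / f"series_{name}", phantom.voxel_size_mm)
        for name, m in fits.items():
            _io.save_map(m, sdir / f"map_{name}", phantom.voxel_size_mm)
    return SubjectResult(subject_id, cohort, seed, stats, metrics)


_LABEL_CACHE: dict = {}


def _label_cache(shape):
    if shape not in _LABEL_CACHE:
        from .phantom import make_label_map

        _LABEL_CACHE[shape] = make_label_map(shape)
    return _LABEL_CACHE[shape]


def _group_comparisons(region_df: pd.DataFrame, hist_df: pd.DataFrame) -> list[GroupComparison]:
    """The canonical comparison battery over whatever cohorts are present."""
    out: list[GroupComparison] = []
    if not region_df.empty:
        canonical = {
            "T1_ms": ("cortex", "osom", "isom"),
            "T2_ms": ("cortex", "osom", "isom"),
            "ADC_e3mm2s": ("cortex", "om"),
        }
        for (kind, region), sub in region_df.groupby(["map_kind", "region"], sort=False):
            if region not in canonical.get(kind, ()):
                continue
            samples = {
                f"{g}_{tp}" if tp != "none" else g: grp["mean"].to_numpy()
                for (g, tp), grp in sub.groupby(["group", "timepoint"], sort=False)
                if len(grp) >= 2
            }
            if len(samples) >= 2:
                design = "3-group" if len(samples) >= 3 else "2-group"
                out.extend(
                    compare_groups(samples, design=design, metric=f"{kind}:{region}", shapiro=False)
                )
    if not hist_df.empty:
        for metric in ("sd", "iqr", "entropy", "mean", "kurtosis", "skewness"):
            samples = {
                f"{g}_{tp}" if tp != "none" else g: grp[metric].to_numpy()
                for (g, tp), grp in hist_df.groupby(["group", "timepoint"], sort=False)
                if len(grp) >= 2 and g != "control"
            }
            if len(samples) == 2:
                out.extend(compare_groups(samples, design="2-group", metric=f"ADC_hist:{metric}", shapiro=False))
    return out


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full simulate-fit-summarize pipeline for one configuration.

    A failing subject is logged and skipped; the study continues and the
    failure is recorded in the result bundle.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    subjects: list[SubjectResult] = []
    failures: list[tuple[str, str]] = []
    for cohort in config.cohorts:
        for i in range(cohort.n):
            sid = f"{cohort.name}_{i:02d}"
            try:
                subjects.append(_run_subject(cohort, i, config, outdir))
            except Exception as exc:  # noqa: BLE001 - stage failures must not kill the study
                log.error("subject %s failed: %s", sid, exc)
                failures.append((sid, str(exc)))

    region_df = cohort_table([s for subj in subjects for s in subj.region_stats])
    hist_rows = []
    for subj in subjects:
        row = {
            "subject_id": subj.subject_id,
            "group": subj.cohort.group,
            "timepoint": subj.cohort.timepoint,
        }
        row.update(subj.adc_metrics.to_dict())
        hist_rows.append(row)
    hist_df = pd.DataFrame(hist_rows)

    comparisons = _group_comparisons(region_df, hist_df)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "subject_seeds": {s.subject_id: s.seed for s in subjects},
        "n_failures": len(failures),
    }

    if outdir is not None:
        region_df.to_csv(outdir / "region_stats.csv", index=False)
        hist_df.to_csv(outdir / "adc_histogram.csv", index=False)
        comparisons_table(comparisons).to_csv(outdir / "comparisons.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(_json_default(manifest), indent=2, sort_keys=True) + "\n")

    return StudyResult(
        config=config,
        region_table=region_df,
        histogram_table=hist_df,
        comparisons=comparisons,
        manifest=manifest,
        failures=failures,
    )


def _json_default(obj):
    if isinstance(obj, dict):
        return {k: _json_default(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_default(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return None
    return obj
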