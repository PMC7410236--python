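"""Pipeline orchestration for the two study arms plus EEG profiling.

``run_invivo`` chains registration, SD projection, binarization, fractal
complexity and the motility index over paired pre/post time-lapse stacks
and runs the paired statistics; ``run_exvivo`` segments section images,
extracts morphology graphs and compares the per-cell metrics across
treatment groups; ``run_eeg`` profiles traces spectrally; ``run_demo``
exercises all three arms on synthetic inputs and writes a Markdown report.
Every run writes a JSON manifest echoing the full configuration, the
package version, timestamps and SHA-256 hashes of the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .dynamics import motility_index, series_complexity
from .eeg import EEGTrace, amplitude_distribution, bandpass, power_spectrum, spectrogram
from .errors import ConfigError, DataError
from .morphometry import extract_graph, morphometrics, segment_cells
from .preprocessing import TimeLapseStack, project_and_binarize, register_stack
from .stats_report import GroupSample, PairedSample, group_comparison, paired_comparison, summarize
from .synthetic_data import (
    CellSpec,
    EEGPreset,
    TimelapseSpec,
    generate_cell_image,
    generate_eeg,
    generate_paired_cohort,
)

__all__ = [
    "CellConfig",
    "TimelapseConfig",
    "InvivoConfig",
    "ExvivoConfig",
    "EEGConfig",
    "RunConfig",
    "load_config",
    "analyze_stack",
    "run_invivo",
    "run_exvivo",
    "run_eeg",
    "run_demo",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CellConfig(_Strict):
    n_roots: int = 4
    branch_prob: float = 0.7
    max_depth: int = 3
    segment_len_um: float = 12.0
    soma_radius_um: float = 4.0
    pixel_size_um: float = 0.4

    def to_spec(self, seed: int = 0) -> CellSpec:
        return CellSpec(seed=seed, **self.model_dump())


class TimelapseConfig(_Strict):
    cell: CellConfig = CellConfig()
    n_frames: int = 10
    n_slices: int = 8
    frame_interval_s: float = 30.0
    motility_level: float = 0.12
    drift_px: tuple[int, int, int] = (0, 1, 1)
    noise_sigma: float = 4.0

    def to_spec(self, seed: int = 0) -> TimelapseSpec:
        d = self.model_dump()
        cell = CellSpec(seed=seed, **d.pop("cell"))
        return TimelapseSpec(cell=cell, seed=seed, **d)


class InvivoConfig(_Strict):
    n_cells: int = 18
    effect: float = -0.17
    timelapse: TimelapseConfig = TimelapseConfig()


class ExvivoConfig(_Strict):
    n_cells_per_condition: int = 25
    region: str = "frontal_cortex"
    conditions: dict[str, CellConfig] = {
        "control": CellConfig(),
        "ketamine_xylazine": CellConfig(branch_prob=0.5),
        "thiopental": CellConfig(),
    }


class EEGConfig(_Strict):
    states: list[str] = ["wake", "ketamine_xylazine", "pentobarbital"]
    duration_s: float = 120.0
    fs_hz: float = 1000.0
    band: tuple[float, float] = (0.5, 300.0)


class RunConfig(_Strict):
    arm: str = "demo"
    seed: int = 0
    out_dir: str = "gliamorphdyn_out"
    invivo: InvivoConfig = InvivoConfig()
    exvivo: ExvivoConfig = ExvivoConfig()
    eeg: EEGConfig = EEGConfig()


def load_config(path) -> RunConfig:
    """Load and strictly validate a YAML run configuration."""
    import yaml

    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig(**raw)
    except (ValidationError, TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _write_manifest(out_dir: Path, config: dict, files: list[Path]) -> Path:
    manifest = {
        "software": {"name": "gliamorphdyn", "version": __version__},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "outputs": {
            str(f.relative_to(out_dir)): hashlib.sha256(f.read_bytes()).hexdigest()
            for f in files
            if f.exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def analyze_stack(stack: TimeLapseStack, reference_index: int = 0) -> dict:
    """Full in vivo metric chain on one stack: register, SD-project,
    binarize, fractal complexity and volume-normalized motility index."""
    registered, shifts = register_stack(stack, reference_index)
    masks = project_and_binarize(registered)
    complexity = series_complexity(masks)
    motility = motility_index(masks, registered.volume_um3)
    return {
        "shifts": shifts,
        "mean_dimension": complexity.mean_dimension,
        "per_frame_dimension": complexity.per_frame_dimension,
        "global_coefficient": motility.global_coefficient,
        "normalized_index": motility.normalized_index,
        "volume_um3": motility.stack_volume_um3,
        "n_frames": stack.n_frames,
    }


def run_invivo(cfg: InvivoConfig, seed: int = 0, out_dir=None) -> dict:
    """Paired pre/during-anesthesia arm on a synthetic cohort.

    Returns the per-cell dataframe and the paired test results for the
    complexity and motility metrics; optionally writes CSVs, a Markdown
    report section and a manifest to ``out_dir``.
    """
    pre_spec = cfg.timelapse.to_spec(seed=seed)
    cohort = generate_paired_cohort(cfg.n_cells, pre_spec, cfg.effect, seed=seed)
    rows = []
    for i, pair in enumerate(cohort):
        for phase in ("pre", "post"):
            res = analyze_stack(pair[phase])
            rows.append(
                {
                    "cell_id": i,
                    "phase": phase,
                    "mean_dimension": res["mean_dimension"],
                    "normalized_index": res["normalized_index"],
                    "global_coefficient": res["global_coefficient"],
                    "volume_um3": res["volume_um3"],
                    "n_frames": res["n_frames"],
                }
            )
    df = pd.DataFrame(rows)
    wide = df.pivot(index="cell_id", columns="phase", values=["mean_dimension", "normalized_index"])
    tests = {}
    for metric in ("mean_dimension", "normalized_index"):
        sample = PairedSample(
            wide[(metric, "pre")].to_numpy(), wide[(metric, "post")].to_numpy(), metric
        )
        tests[metric] = paired_comparison(sample)
    result = {"cells": df, "tests": tests}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells_csv = out_dir / "invivo_cells.csv"
        df.to_csv(cells_csv, index=False)
        stats_csv = out_dir / "invivo_stats.csv"
        _tests_to_frame(tests).to_csv(stats_csv, index=False)
        _write_manifest(out_dir, {"arm": "invivo", "seed": seed, **cfg.model_dump()},
                        [cells_csv, stats_csv])
        result["out_dir"] = out_dir
    return result


def _tests_to_frame(tests: dict) -> pd.DataFrame:
    rows = []
    for metric, t in tests.items():
        rows.append(
            {
                "metric": metric,
                "test": t.test_name,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "n": t.n,
                "significant": t.significant,
            }
        )
        for ph in t.posthoc:
            rows.append(
                {
                    "metric": metric,
                    "test": f"posthoc {ph.group_a} vs {ph.group_b}",
                    "statistic": ph.statistic,
                    "p_value": ph.p_raw,
                    "p_adjusted": ph.p_adj,
                    "n": t.n,
                    "significant": ph.p_adj < t.alpha,
                }
            )
    return pd.DataFrame(rows)


_EXVIVO_METRICS = [
    "complexity_index",
    "cea_um2",
    "cell_body_area_um2",
    "cytoplasm_area_um2",
    "n_segments",
    "total_ramification_length_um",
]


def run_exvivo(cfg: ExvivoConfig, seed: int = 0, out_dir=None) -> dict:
    """Ex vivo arm: per-condition synthetic sections, segmentation, graph
    morphometry and Kruskal-Wallis/Sidak comparisons per metric."""
    rng = np.random.default_rng(seed)
    rows = []
    for condition, cell_cfg in cfg.conditions.items():
        for i in range(cfg.n_cells_per_condition):
            spec = cell_cfg.to_spec(seed=int(rng.integers(0, 2**31 - 1)))
            image, _ = generate_cell_image(spec)
            segs = segment_cells(image, (spec.pixel_size_um, spec.pixel_size_um))
            if not segs:
                continue  # logged via row absence; run continues
            graph = extract_graph(segs[0])
            rec = morphometrics(segs[0], graph, region=cfg.region, condition=condition)
            row = dataclasses.asdict(rec)
            row["cell_id"] = f"{condition}_{i}"
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("no cells detected in any condition")
    tests = {}
    sizes = df.groupby("condition").size()
    if len(sizes) >= 2 and sizes.min() >= 3:
        for metric in _EXVIVO_METRICS:
            groups = {c: g[metric].to_numpy() for c, g in df.groupby("condition")}
            tests[metric] = group_comparison(GroupSample(groups, metric, cfg.region))
    else:
        import logging

        logging.getLogger(__name__).info(
            "group tests skipped: need >= 2 conditions with >= 3 cells each"
        )
    summary = summarize(df, metrics=_EXVIVO_METRICS)
    result = {"cells": df, "tests": tests, "summary": summary}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells_csv = out_dir / "exvivo_cells.csv"
        df.to_csv(cells_csv, index=False)
        summary_csv = out_dir / "exvivo_summary.csv"
        summary.to_csv(summary_csv, index=False)
        stats_csv = out_dir / "exvivo_stats.csv"
        _tests_to_frame(tests).to_csv(stats_csv, index=False)
        _write_manifest(out_dir, {"arm": "exvivo", "seed": seed, **cfg.model_dump()},
                        [cells_csv, summary_csv, stats_csv])
        result["out_dir"] = out_dir
    return result


def run_eeg(cfg: EEGConfig, seed: int = 0, out_dir=None, traces: dict | None = None) -> dict:
    """EEG arm: band-pass, power spectrum with WHM, amplitude distribution
    and sliding-FFT spectrogram per state (synthetic presets by default)."""
    if traces is None:
        traces = {
            state: generate_eeg(
                EEGPreset(state=state, fs_hz=cfg.fs_hz, duration_s=cfg.duration_s, seed=seed)
            )
            for state in cfg.states
        }
    profiles = {}
    rows = []
    for state, trace in traces.items():
        filt = bandpass(trace, *cfg.band)
        spec = power_spectrum(filt)
        dist = amplitude_distribution(filt)
        sgram = spectrogram(filt)
        profiles[state] = {
            "trace": filt,
            "spectrum": spec,
            "distribution": dist,
            "spectrogram": sgram,
        }
        rows.append(
            {
                "state": state,
                "whm_hz": spec.whm_hz,
                "excess_kurtosis": dist.excess_kurtosis,
                "peak_hz": float(spec.freqs_hz[int(np.argmax(spec.power))]),
                "duration_s": trace.duration_s,
            }
        )
    summary = pd.DataFrame(rows)
    result = {"profiles": profiles, "summary": summary}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = []
        summary_csv = out_dir / "eeg_summary.csv"
        summary.to_csv(summary_csv, index=False)
        files.append(summary_csv)
        for state, prof in profiles.items():
            spec_csv = out_dir / f"eeg_spectrum_{state}.csv"
            pd.DataFrame(
                {"freq_hz": prof["spectrum"].freqs_hz, "power": prof["spectrum"].power}
            ).to_csv(spec_csv, index=False)
            files.append(spec_csv)
        _write_manifest(out_dir, {"arm": "eeg", "seed": seed, **cfg.model_dump()}, files)
        result["out_dir"] = out_dir
    return result


def run_demo(seed: int = 0, out_dir="gliamorphdyn_demo") -> dict:
    """One-command synthetic end-to-end demo of all three arms.

    Uses a reduced cohort (8 cells) so the demo stays interactive; the
    statistical arms of the full study conditions are exercised by the
    acceptance suite instead.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=seed, out_dir=str(out_dir))
    invivo_cfg = cfg.invivo.model_copy(update={"n_cells": 8})
    invivo = run_invivo(invivo_cfg, seed=seed, out_dir=out_dir / "invivo")
    exvivo_cfg = cfg.exvivo.model_copy(update={"n_cells_per_condition": 12})
    exvivo = run_exvivo(exvivo_cfg, seed=seed, out_dir=out_dir / "exvivo")
    eeg_cfg = cfg.eeg.model_copy(update={"duration_s": 60.0})
    eeg = run_eeg(eeg_cfg, seed=seed, out_dir=out_dir / "eeg")

    report = [
        "# Synthetic end-to-end demo",
        "",
        "## EEG state profiles",
        eeg["summary"].to_markdown(index=False),
        "",
        "## In vivo paired comparisons (pre vs during anesthesia)",
        _tests_to_frame(invivo["tests"]).to_markdown(index=False),
        "",
        "## Ex vivo group summaries",
        exvivo["summary"].to_markdown(index=False),
        "",
        "## Ex vivo group tests",
        _tests_to_frame(exvivo["tests"]).to_markdown(index=False),
        "",
    ]
    report_md = out_dir / "report.md"
    report_md.write_text("\n".join(report))
    _write_manifest(out_dir, {"arm": "demo", "seed": seed}, [report_md])
    return {"invivo": invivo, "exvivo": exvivo, "eeg": eeg, "report": report_md}
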