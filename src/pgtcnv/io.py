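"""File formats, configuration and the end-to-end pipeline driver.

TSV dialect throughout: tab-separated, a single '#'-prefixed header line,
no quoting.  Bin counts are BED-like (chrom, start, end, count), one file
per sample, strictly validated against the active grid.  Pipeline
configuration is YAML or JSON validated against an explicit key schema
(unknown keys are rejected); every report embeds the resolved
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bins import BinCounts, BinGrid, build_bin_grid
from .classify import ClassifierConfig, classify_embryo, expected_unbalanced_catalogue
from .cnvcall import (
    CallerConfig,
    ReferencePanel,
    build_reference,
    call_sample,
)
from .cohort import tabulate
from .karyotype import CytobandMap, load_cytoband_map, reduced_cytoband_map
from .simulate import CohortSpec, GroupSpec, SimulationConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "read_bin_counts",
    "write_bin_counts",
    "write_reference_panel",
    "read_reference_panel",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def write_bin_counts(counts: BinCounts, grid: BinGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcount\n")
        for chrom, start, end, c in zip(grid.chroms, grid.starts, grid.ends,
                                        counts.counts):
            fh.write(f"{chrom}\t{start}\t{end}\t{c}\n")


def read_bin_counts(path, grid: BinGrid,
                    sample_id: str | None = None) -> BinCounts:
    """Read a BED-like count file and validate it against ``grid``.

    Rows must appear in grid order with matching coordinates; malformed
    rows are reported with their line number.
    """
    path = Path(path)
    counts = np.zeros(len(grid), dtype=np.int64)
    i = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            chrom, start, end, count = parts
            try:
                start_i, end_i, count_i = int(start), int(end), int(count)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer field") from None
            if count_i < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if i >= len(grid):
                raise ValueError(f"{path}:{lineno}: more rows than grid bins")
            if (chrom != grid.chroms[i] or start_i != grid.starts[i]
                    or end_i != grid.ends[i]):
                raise ValueError(
                    f"{path}:{lineno}: not grid-ordered (expected "
                    f"{grid.chroms[i]}:{grid.starts[i]}-{grid.ends[i]}, got "
                    f"{chrom}:{start_i}-{end_i})")
            counts[i] = count_i
            i += 1
    if i != len(grid):
        raise ValueError(f"{path}: {i} rows but grid has {len(grid)} bins")
    return BinCounts(sample_id or path.stem, counts, int(counts.sum()))


def write_reference_panel(panel: ReferencePanel, grid: BinGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_samples={panel.n_samples}\n")
        fh.write("#chrom\tstart\tend\tfactor\tmasked\n")
        for chrom, start, end, f, m in zip(grid.chroms, grid.starts,
                                           grid.ends, panel.factors,
                                           panel.mask):
            fh.write(f"{chrom}\t{start}\t{end}\t{f:.6g}\t{int(m)}\n")


def read_reference_panel(path, grid: BinGrid) -> ReferencePanel:
    factors = np.ones(len(grid))
    mask = np.zeros(len(grid), dtype=bool)
    n_samples = 0
    i = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#n_samples="):
                n_samples = int(line.strip().split("=", 1)[1])
                continue
            if line.startswith("#") or not line.strip():
                continue
            _chrom, _s, _e, f, m = line.rstrip("\n").split("\t")
            factors[i] = float(f)
            mask[i] = bool(int(m))
            i += 1
    if i != len(grid):
        raise ValueError(f"{path}: panel length {i} != grid length {len(grid)}")
    return ReferencePanel(factors, mask, n_samples)


# -- pipeline configuration ------------------------------------------------

_GROUP_KEYS = {"label", "maternal", "paternal", "n_embryos"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    seed: int = 0
    genome: str = "reduced"             # "full" or "reduced"
    bin_size: int = 1_000_000
    n_panel: int = 20
    groups: tuple[GroupSpec, ...] = ()
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    out_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for section, klass in (("simulation", SimulationConfig),
                               ("caller", CallerConfig),
                               ("classifier", ClassifierConfig)):
            if section in raw and isinstance(raw[section], dict):
                allowed = {f.name for f in dataclasses.fields(klass)}
                bad = set(raw[section]) - allowed
                if bad:
                    raise ConfigError(
                        f"unknown {section} key(s): {sorted(bad)}")
                sec = dict(raw[section])
                if "gc_bias" in sec:
                    sec["gc_bias"] = tuple(sec["gc_bias"])
                if "mosaic_fraction_range" in sec:
                    sec["mosaic_fraction_range"] = tuple(
                        sec["mosaic_fraction_range"])
                raw[section] = klass(**sec)
        if "groups" in raw:
            groups = []
            for g in raw["groups"]:
                bad = set(g) - _GROUP_KEYS
                if bad:
                    raise ConfigError(f"unknown group key(s): {sorted(bad)}")
                groups.append(GroupSpec(**g))
            raw["groups"] = tuple(groups)
        if raw.get("genome") not in (None, "full", "reduced"):
            raise ConfigError(f"genome must be 'full' or 'reduced', "
                              f"got {raw.get('genome')!r}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def cytoband_map(self) -> CytobandMap:
        return (load_cytoband_map() if self.genome == "full"
                else reduced_cytoband_map())

    def to_jsonable(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            return obj
        return {f.name: conv(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """simulate -> qc -> normalize -> segment -> call -> classify ->
    tabulate, returning a JSON-ready report.

    Identical (config, seed) pairs produce identical reports.  Any stage
    error is re-raised annotated with the stage and sample id.
    """
    if not cfg.groups:
        raise ConfigError("pipeline config lists no cohort groups")
    m = cfg.cytoband_map()
    grid = build_bin_grid(m, cfg.bin_size, seed=cfg.seed)

    panel_cfg = dataclasses.replace(cfg.simulation, de_novo_rate=0.0,
                                    mosaic_rate=0.0, failure_prob=0.0)
    panel_spec = CohortSpec(
        groups=(GroupSpec("panel", "46,XX", "46,XY", cfg.n_panel),),
        config=panel_cfg)
    panel_counts, _ = simulate_cohort(panel_spec, grid, m,
                                      seed=cfg.seed + 1_000_003)
    try:
        panel = build_reference(panel_counts, grid, cfg.caller)
    except Exception as exc:
        raise RuntimeError(f"stage makepanel failed: {exc}") from exc

    spec = CohortSpec(groups=cfg.groups, config=cfg.simulation)
    all_counts, truth = simulate_cohort(spec, grid, m, seed=cfg.seed,
                                        classifier_cfg=cfg.classifier)

    embryos = []
    records = []
    group_of = dict(zip(truth["sample_id"], truth["group"]))
    karyos = {g.label: (g.maternal, g.paternal) for g in cfg.groups}
    catalogues = {}
    from .karyotype import parse_karyotype, resolve_breakpoints
    for label, (mk, fk) in karyos.items():
        km = resolve_breakpoints(parse_karyotype(mk), m)
        kf = resolve_breakpoints(parse_karyotype(fk), m)
        catalogues[label] = (km, kf,
                             expected_unbalanced_catalogue(km, kf, m))
    for counts in all_counts:
        sid = counts.sample_id
        label = group_of[sid]
        km, kf, catalogue = catalogues[label]
        try:
            callset = call_sample(counts, panel, grid, cfg.caller)
        except Exception as exc:
            raise RuntimeError(f"stage call failed on {sid}: {exc}") from exc
        entry = {
            "sample_id": sid,
            "group": label,
            "informative": callset.qc.informative,
            "qc_reasons": list(callset.qc.reasons),
            "noise": None if not np.isfinite(callset.qc.noise)
                     else round(float(callset.qc.noise), 4),
        }
        if callset.qc.informative:
            cls = classify_embryo(callset, km, kf, m, cfg.classifier,
                                  catalogue=catalogue)
            entry.update({
                "sex": callset.sex,
                "category": cls.category,
                "transferable": cls.transferable,
                "segments": [
                    {"chrom": s.chrom, "start": s.start, "end": s.end,
                     "call": s.call, "mosaic_fraction": round(s.mosaic_fraction, 3),
                     "size_mb": round(s.size_mb, 1), "origin": ev.origin}
                    for s, ev in zip(callset.segments, cls.evidence)],
            })
            records.append({"group": label, "informative": True,
                            "category": cls.category})
        else:
            records.append({"group": label, "informative": False,
                            "category": None})
        embryos.append(entry)

    table = tabulate(pd.DataFrame(records), "group",
                     group_order=[g.label for g in cfg.groups])
    report = {
        "config": cfg.to_jsonable(),
        "seed": cfg.seed,
        "n_embryos": len(embryos),
        "embryos": embryos,
        "cohort": {
            "counts": table.counts.reset_index().to_dict(orient="records"),
            "rates": table.rates.reset_index().to_dict(orient="records"),
        },
        "truth": truth.to_dict(orient="records"),
    }
    # ensure the report is JSON-serializable
    json.dumps(report, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
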