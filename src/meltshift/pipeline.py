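"""End-to-end run orchestration: simulate/load -> fit -> shifts -> report.

A run is configured by a :class:`RunConfig` (deserializable from YAML),
executed deterministically from a single seed, and leaves behind a shift
table, an optional CETSA table, a DEP table, the resolved configuration and
a JSON run report whose class counts always partition the input proteins.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cetsa import analyze_cetsa_table
from .curves import FitSettings, QcThresholds
from .io import read_abundance_table, read_cetsa_table, write_abundance_table, write_shift_table
from .shifts import ShiftSettings, analyze_shifts, classify_dep
from .simulate import SimulationConfig, simulate_dataset, truths_to_frame

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_report", "StageError"]

log = logging.getLogger("meltshift")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {reason}")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_table: str | None = None
    cetsa_table: str | None = None
    simulate: SimulationConfig | None = None
    fit: FitSettings = field(default_factory=FitSettings)
    qc: QcThresholds = field(default_factory=QcThresholds)
    shifts: ShiftSettings = field(default_factory=ShiftSettings)
    cetsa_method: str = "auto"
    dep_fold_cutoff: float = 2.0
    dep_q_cutoff: float = 0.05
    out_dir: str = "meltshift_out"
    seed: int = 0
    top_k: int = 20
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.input_table is None and self.simulate is None:
            raise ValueError("config needs either an input_table or a simulate block")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if kw.get("simulate") is not None:
            sim = dict(kw["simulate"])
            for key in ("temperatures", "slope_range", "tm_range", "plateau_range",
                        "base_intensity_range", "effect_distribution"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            kw["simulate"] = SimulationConfig(**sim)
        for name, typ in (("fit", FitSettings), ("qc", QcThresholds), ("shifts", ShiftSettings)):
            if isinstance(kw.get(name), dict):
                sub = dict(kw[name])
                for key, val in sub.items():
                    if isinstance(val, list):
                        sub[key] = tuple(val)
                kw[name] = typ(**sub)
        return cls(**kw)

    def to_dict(self) -> dict:
        return _listify(asdict(self))


def _listify(obj):
    """Tuples -> lists recursively so the config is YAML-safe-dumpable."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class RunReport:
    """Deterministic summary of a pipeline run."""

    n_proteins: int
    n_qc_pass: int
    n_stabilized: int
    n_destabilized: int
    n_unchanged: int
    n_qc_failed: int
    top_candidates: list[dict]
    dep_up: int | None
    dep_down: int | None
    version: str
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: RunConfig) -> str:
    """Hash of the scientific settings only — file-system paths excluded so
    identical analyses hash identically wherever they run."""
    d = config.to_dict()
    for key in ("input_table", "cetsa_table", "out_dir"):
        d.pop(key, None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def make_report(
    shift_table: pd.DataFrame,
    dep_table: pd.DataFrame | None,
    config: RunConfig,
    top_k: int | None = None,
) -> RunReport:
    """Summarize persisted intermediates into a run report.

    The class counts always satisfy the partition
    stabilized + destabilized + unchanged + qc_failed = total.
    """
    if shift_table is None or shift_table.empty:
        raise StageError("report", "shift table is empty")
    k = top_k if top_k is not None else config.top_k
    counts = shift_table["stability_class"].value_counts()
    ranked = shift_table.dropna(subset=["rank"]).sort_values("rank")
    top = ranked.head(k)[
        ["protein_id", "tm_control", "tm_treated", "delta_tm", "q_value",
         "stability_class", "rank"]
    ].to_dict("records")
    return RunReport(
        n_proteins=len(shift_table),
        n_qc_pass=int(shift_table["qc_pass"].sum()),
        n_stabilized=int(counts.get("stabilized", 0)),
        n_destabilized=int(counts.get("destabilized", 0)),
        n_unchanged=int(counts.get("unchanged", 0)),
        n_qc_failed=int(counts.get("qc_failed", 0)),
        top_candidates=top,
        dep_up=int((dep_table["dep_class"] == "up").sum()) if dep_table is not None else None,
        dep_down=int((dep_table["dep_class"] == "down").sum()) if dep_table is not None else None,
        version=__version__,
        config_hash=_config_hash(config),
        seed=config.seed,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline and persist artifacts into config.out_dir.

    Stages: acquire (simulate or load) -> shift analysis -> DEP analysis ->
    CETSA (if a table is configured) -> report.  Fully deterministic for a
    fixed config (including seed).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # --- acquire ---------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            sim.seed = config.seed
        log.info("simulating %d proteins (seed=%d)", sim.n_proteins, sim.seed)
        table, truths = simulate_dataset(sim)
        write_abundance_table(table, out / "abundance.tsv")
        truths_to_frame(truths).to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        try:
            table, report = read_abundance_table(config.input_table)
        except Exception as err:  # noqa: BLE001 - stage boundary
            raise StageError("load", str(err)) from err
        log.info("loaded %d records / %d proteins", report.n_records, report.n_proteins)

    # --- shift analysis --------------------------------------------------
    log.info(
        "shift analysis: mode=%s delta_threshold=%.2f q_cutoff=%.3f r2_min=%.2f "
        "plateau_max=%.2f min_points=%d",
        config.shifts.mode, config.shifts.delta_threshold, config.shifts.q_cutoff,
        config.qc.r2_min, config.qc.plateau_max, config.fit.min_points,
    )
    try:
        shift_table = analyze_shifts(table, config.fit, config.qc, config.shifts)
    except Exception as err:  # noqa: BLE001
        raise StageError("shifts", str(err)) from err
    write_shift_table(shift_table, out / "shifts.tsv")

    # --- differential expression ----------------------------------------
    try:
        dep_table = classify_dep(table, config.dep_fold_cutoff, config.dep_q_cutoff)
        dep_table.to_csv(out / "dep.tsv", sep="\t", index=False)
    except Exception as err:  # noqa: BLE001
        raise StageError("dep", str(err)) from err

    # --- CETSA (optional) -------------------------------------------------
    if config.cetsa_table is not None:
        try:
            cetsa_df = read_cetsa_table(config.cetsa_table)
            cetsa_res = analyze_cetsa_table(cetsa_df, config.cetsa_method)
            cetsa_res.to_csv(out / "cetsa.tsv", sep="\t", index=False)
        except Exception as err:  # noqa: BLE001
            raise StageError("cetsa", str(err)) from err

    # --- report -----------------------------------------------------------
    report = make_report(shift_table, dep_table, config)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    log.info(
        "done: %d proteins, %d stabilized, %d destabilized",
        report.n_proteins, report.n_stabilized, report.n_destabilized,
    )
    return report
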