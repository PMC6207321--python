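"""Reproducible end-to-end pipeline: simulate -> gate -> stats -> model.

A single structured config (YAML) drives every stage; each run writes a
manifest echoing the config, the package and library versions, the seed
and SHA-256 hashes of every artefact, so identical (config, seed) pairs
are verifiably identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import EVENING_DAYS, MORNING_DAYS, SampleRecord
from .flood import flood_from_records
from .gating import SubsetGates, classify_subsets, derive_gates, gate_neutrophils, subset_concentration
from .io import read_cohort, write_cohort
from .panel import MFI_MARKERS
from .plotting import export_biplot
from .stats import cohort_table, rm_anova_oneway, rm_anova_twoway, subset_mfi_table
from .synthetic import (
    NEUTROPHIL_SUBSETS,
    default_cohort_config,
    default_lps_config,
    simulate_cohort,
    simulate_lps_sample,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; flags and keyword overrides win over the file."""

    out_dir: str = "floodcyto_out"
    seed: int = 1
    log_level: str = "INFO"
    input_metadata: str | None = None  # existing cohort; None -> simulate
    io_format: str = "delimited"
    n_subjects: int = 28
    events_per_sample: int = 20_000
    n_lps_samples: int = 4
    gates: dict | None = None  # explicit gate dict; None -> derive from controls
    alpha: float = 0.05
    multiplicity: str = "tukey"
    k_c: int | None = None
    k_r: int = 2
    coverage: float = 0.80
    flood_analyses: tuple[str, ...] = ("tfl", "tfl+lps")
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "flood_analyses" in kwargs:
            kwargs["flood_analyses"] = tuple(kwargs["flood_analyses"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["flood_analyses"] = list(self.flood_analyses)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig, command: str):
        self.data = {
            "command": command,
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "floodcyto": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "files": {},
        }

    def add(self, *paths: Path) -> None:
        for p in paths:
            self.data["files"][str(p.name)] = _sha256(Path(p))

    def write(self, out_dir: Path, name: str) -> Path:
        path = out_dir / name
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return path


def _load_or_simulate(config: RunConfig) -> list[SampleRecord]:
    if config.input_metadata:
        return read_cohort(config.input_metadata, format=config.io_format)
    cohort_cfg = default_cohort_config(
        n_subjects=config.n_subjects, events_per_sample=config.events_per_sample
    )
    return simulate_cohort(cohort_cfg, seed=config.seed)


def _gates_for(config: RunConfig, records: list[SampleRecord]) -> SubsetGates:
    if config.gates is not None:
        return SubsetGates.from_dict(config.gates)
    controls = [r for r in records if r.group == "control"]
    if not controls:
        raise ValueError("no control (morning day 1) samples to derive gates from")
    pooled = np.vstack([r.events.values for r in controls])
    from .core import EventMatrix

    return derive_gates(EventMatrix(values=pooled, panel=controls[0].events.panel))


def cmd_simulate(config: RunConfig) -> Path:
    """Simulate the cohort (plus LPS samples) and write it to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = _load_or_simulate(config)
    lps_cfg = default_lps_config(events_per_sample=config.events_per_sample)
    for i in range(config.n_lps_samples):
        records.append(
            simulate_lps_sample(lps_cfg, seed=config.seed + 10_000 + i, subject=f"LPS{i + 1:02d}")
        )
    table = write_cohort(records, out / "cohort", format=config.io_format)
    manifest = _Manifest(config, "simulate")
    manifest.add(table)
    manifest.write(out, "manifest_simulate.json")
    return table


def cmd_gate(config: RunConfig, records: list[SampleRecord] | None = None):
    """Gate every sample; write the per-sample result table and the gates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = _load_or_simulate(config)
    tfl = [r for r in records if r.session != "lps"]
    gates = _gates_for(config, tfl)
    rows = []
    for rec in records:
        mask = gate_neutrophils(rec.events, gates)
        result = classify_subsets(rec.events, mask, gates)
        conc = subset_concentration(result, rec.counter_concentration)
        for label in (*NEUTROPHIL_SUBSETS, "total"):
            rows.append(
                {
                    "subject": rec.subject,
                    "time": rec.time_label,
                    "label": label,
                    "events": int(np.sum(result.labels == label))
                    if label != "total"
                    else int(np.isin(result.labels, NEUTROPHIL_SUBSETS).sum()),
                    "fraction": result.subset_fractions.get(label, 1.0),
                    "concentration": conc[label],
                }
            )
    gating_path = out / "gating_results.tsv"
    pd.DataFrame(rows).to_csv(gating_path, sep="\t", index=False)
    gates_path = out / "gates.yaml"
    with open(gates_path, "w") as fh:
        yaml.safe_dump(gates.to_dict(), fh)
    manifest = _Manifest(config, "gate")
    manifest.add(gating_path, gates_path)
    manifest.write(out, "manifest_gate.json")
    return gates, gating_path


def cmd_stats(config: RunConfig, records: list[SampleRecord] | None = None) -> Path:
    """Cohort inference: fold-change contrasts and two-way MFI ANOVA."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = _load_or_simulate(config)
    tfl = [r for r in records if r.session != "lps"]
    gates = _gates_for(config, tfl)
    table = cohort_table(tfl, gates)
    table_path = out / "cohort_table.tsv"
    table.to_csv(table_path, sep="\t", index=False)

    measures = ["total", *NEUTROPHIL_SUBSETS] + [f"mfi_{m}" for m in MFI_MARKERS]
    contrast_rows = []
    summaries = {}
    complete = table[table["complete"]]
    for session, days in (("morning", MORNING_DAYS), ("evening", EVENING_DAYS)):
        sub = complete[complete["session"] == session]
        for measure in measures:
            wide = sub.pivot_table(
                index="subject", columns="day", values=measure, sort=True
            ).reindex(columns=list(days))
            wide.columns = [f"d{d}" for d in days]
            try:
                res = rm_anova_oneway(
                    wide.dropna(), alpha=config.alpha, multiplicity=config.multiplicity
                )
            except ValueError as exc:
                logger.warning("skipping %s %s: %s", session, measure, exc)
                continue
            summaries[f"{session}:{measure}"] = {
                "F": res.f_statistic,
                "p": res.p_value,
                "n_subjects": res.n_subjects,
            }
            for c in res.contrasts:
                contrast_rows.append(
                    {"session": session, "measure": measure,
                     **res.contrasts_frame().iloc[res.contrasts.index(c)].to_dict()}
                )
    contrasts_path = out / "contrasts.tsv"
    pd.DataFrame(contrast_rows).to_csv(contrasts_path, sep="\t", index=False)

    # two-way (subset x time) analysis of the morning subset MFIs
    morning = [r for r in tfl if r.session == "morning"]
    mfi_long = subset_mfi_table(morning, gates)
    twoway = {}
    for marker in MFI_MARKERS:
        try:
            res = rm_anova_twoway(
                mfi_long, dv=f"mfi_{marker}", subject="subject",
                within=("subset", "time"), alpha=config.alpha,
            )
        except ValueError as exc:
            logger.warning("two-way ANOVA for %s skipped: %s", marker, exc)
            continue
        twoway[marker] = {
            src: {
                "F": float(res.anova_table.loc[src, "F"]),
                "p": float(res.anova_table.loc[src, "p"]),
            }
            for src in ("subset", "time", "subset:time")
        }
    summary_path = out / "stats_summary.json"
    with open(summary_path, "w") as fh:
        json.dump({"oneway": summaries, "twoway_mfi": twoway}, fh, indent=1)

    manifest = _Manifest(config, "stats")
    manifest.add(table_path, contrasts_path, summary_path)
    manifest.write(out, "manifest_stats.json")
    return contrasts_path


def cmd_flood(config: RunConfig, records: list[SampleRecord] | None = None) -> dict:
    """Fit the response model(s); write model files, biplots and overlaps."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = _load_or_simulate(config)
        lps_cfg = default_lps_config(events_per_sample=config.events_per_sample)
        for i in range(config.n_lps_samples):
            records.append(
                simulate_lps_sample(
                    lps_cfg, seed=config.seed + 10_000 + i, subject=f"LPS{i + 1:02d}"
                )
            )
    tfl = [r for r in records if r.session != "lps"]
    gates = _gates_for(config, tfl)
    manifest = _Manifest(config, "flood")
    outputs = {}
    for analysis in config.flood_analyses:
        group = tfl if analysis == "tfl" else records
        results, per_sample = flood_from_records(
            group, gates, k_c=config.k_c, k_r=config.k_r, coverage=config.coverage
        )
        tag = analysis.replace("+", "_")
        model_path = out / f"flood_model_{tag}.json"
        results.save(model_path)
        plot_dir = out / f"biplots_{tag}"
        # plot a representative subject plus the LPS samples to keep runs light
        subjects = {k[0] for k in per_sample}
        rep = sorted(s for s in subjects if not s.startswith("LPS"))[0]
        selected = {
            k: v for k, v in per_sample.items()
            if k[0] == rep or k[0].startswith("LPS")
        }
        artefacts = export_biplot(results, selected, plot_dir)
        manifest.add(model_path, artefacts["loadings"], artefacts["explained"], artefacts["overlap"])
        outputs[analysis] = {"model": model_path, "artefacts": artefacts}
    manifest.write(out, "manifest_flood.json")
    return outputs


def cmd_all(config: RunConfig) -> None:
    """Full pipeline; one shared simulated cohort feeds every stage."""
    records = _load_or_simulate(config)
    lps_cfg = default_lps_config(events_per_sample=config.events_per_sample)
    lps = [
        simulate_lps_sample(lps_cfg, seed=config.seed + 10_000 + i, subject=f"LPS{i + 1:02d}")
        for i in range(config.n_lps_samples)
    ]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(records + lps, out / "cohort", format=config.io_format)
    cmd_gate(config, records + lps)
    cmd_stats(config, records)
    cmd_flood(config, records + lps)
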