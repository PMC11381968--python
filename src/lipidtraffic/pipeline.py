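"""End-to-end orchestration: match -> quality filters -> traffic -> reports.

``run_pipeline`` chains the stages on one configuration and writes a
reproducible report bundle: the filtered sheet, per-test filter results,
per-category traffic assignments, the switch-analysis JSON, one SVG diagram
per lipid class, and a run log recording every threshold, seed and package
version.  Identical configuration (including seed) yields byte-identical
outputs; inputs are never mutated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .qc import CHAIN_PRESETS, results_frame, run_filter_chain
from .signal_sheet import read_signal_sheet, write_signal_sheet
from .svg import render_switch_svg
from .targetlib import match_features, read_library
from .traffic import (
    CompartmentNetwork,
    call_presence,
    classify_traffic,
    switch_analysis,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All paths, thresholds and seeds for one pipeline run."""

    sheet: str
    metadata: str
    network: str
    out_dir: str
    library: str | None = None  # None: skip matching (sheet already annotated)
    chain: str = "matched"
    phenotypes: tuple[str, str] | None = None  # None: infer the two from metadata
    lipid_classes: Sequence[str] = ()  # empty: every annotated class
    blank_factor: float | None = None
    qc_r_min: float | None = None
    prevalence: float | None = None
    presence_min_frac: float = 0.66
    mz_tol: float = 0.001
    rt_mode: str = "window"
    rt_halfwidth: float = 0.25
    area_threshold: float = 100_000.0
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chain not in CHAIN_PRESETS:
            raise PipelineError("config", f"unknown chain {self.chain!r}")
        if not 0 < self.presence_min_frac <= 1:
            raise PipelineError("config", "presence_min_frac must be in (0, 1]")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    data = yaml.safe_load(Path(path).read_text())
    if "phenotypes" in data and data["phenotypes"] is not None:
        data["phenotypes"] = tuple(data["phenotypes"])
    return PipelineConfig(**data)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, str(e)) from e

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``config.out_dir``.

    Returns the run log (also written as ``run_log.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sheet = _stage("read")(read_signal_sheet)(config.sheet, config.metadata)
    network = _stage("network")(CompartmentNetwork.from_json)(config.network)

    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }
    log["stages"]["input"] = {"n_features": len(sheet.features), "n_samples": len(sheet.samples)}

    if config.library is not None:
        library = _stage("library")(read_library)(config.library)
        sheet, match_report = _stage("match")(match_features)(
            sheet,
            library,
            mz_tol=config.mz_tol,
            rt_mode=config.rt_mode,
            rt_halfwidth=config.rt_halfwidth,
            area_threshold=config.area_threshold,
        )
        log["stages"]["match"] = match_report.to_dict()

    filtered, results = _stage("qc")(run_filter_chain)(
        sheet,
        chain=config.chain,
        blank_factor=config.blank_factor,
        qc_r_min=config.qc_r_min,
        prevalence=config.prevalence,
    )
    all_results = [r for rs in results.values() for r in rs]
    results_frame(all_results).to_csv(out / "filter_results.csv", index=False)
    log["stages"]["qc"] = {
        "chain": config.chain,
        **{name: sum(r.passed for r in rs) for name, rs in results.items()},
        "n_passing_all": len(filtered.features),
    }
    write_signal_sheet(filtered, out / "filtered_sheet.csv", out / "filtered_metadata.csv")

    phenos = config.phenotypes
    if phenos is None:
        seen = sorted(
            {s.phenotype for s in filtered.samples if s.role == "analytical" and s.phenotype}
        )
        if len(seen) != 2:
            raise PipelineError(
                "traffic", f"need exactly 2 phenotypes, metadata has {seen}"
            )
        phenos = (seen[0], seen[1])

    classes = list(config.lipid_classes) or sorted(
        {f.lipid_class for f in filtered.features if f.lipid_class}
    )
    if not classes:
        raise PipelineError("traffic", "no annotated lipid classes in filtered sheet")

    switch_report: dict = {}
    assignment_rows: list[dict] = []
    for k, lipid_class in enumerate(classes):
        pres = {
            ph: _stage("presence")(call_presence)(
                filtered, ph, min_frac=config.presence_min_frac, lipid_class=lipid_class
            )
            for ph in phenos
        }
        cls = {
            ph: _stage("classify")(classify_traffic)(pres[ph], network, lipid_class)
            for ph in phenos
        }
        comparisons = _stage("switch")(switch_analysis)(
            cls[phenos[0]],
            cls[phenos[1]],
            n_perm=config.n_perm,
            seed=config.seed + k,
        )
        switch_report[lipid_class] = [c.to_dict() for c in comparisons]
        for ph in phenos:
            for cat, lipids in cls[ph].category_sets().items():
                for lipid in sorted(lipids):
                    assignment_rows.append(
                        {
                            "lipid_class": lipid_class,
                            "phenotype": ph,
                            "category": cat,
                            "lipid_id": lipid,
                        }
                    )
            for lipid in sorted(cls[ph].other_set):
                assignment_rows.append(
                    {
                        "lipid_class": lipid_class,
                        "phenotype": ph,
                        "category": "other",
                        "lipid_id": lipid,
                    }
                )
        svg = render_switch_svg(
            network,
            comparisons,
            title=f"{lipid_class}: {phenos[0]} vs {phenos[1]}",
        )
        (out / f"switch_{lipid_class}.svg").write_text(svg)

    pd.DataFrame(
        assignment_rows, columns=["lipid_class", "phenotype", "category", "lipid_id"]
    ).to_csv(out / "traffic_assignments.csv", index=False)
    (out / "switch_report.json").write_text(
        json.dumps(switch_report, indent=2, sort_keys=True) + "\n"
    )
    log["stages"]["traffic"] = {
        "phenotypes": list(phenos),
        "lipid_classes": classes,
        "n_assignments": len(assignment_rows),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log
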