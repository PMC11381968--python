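"""Ground-truth simulator for multi-compartment, two-phenotype lipidomics studies.

The generator emulates the structure of a high-throughput LCMS plate:
analytical wells per (phenotype, compartment) group, extraction blanks,
and two pooled QC stocks pipetted at 25/50/100% strength with three
technical replicates per level.  Lipid variables are planted with known
traffic categories (A, per-edge B, per-compartment U, per-non-adjacent-pair
N2) for each phenotype, with a configurable fraction shared between
phenotypes, so that every pipeline stage can be scored against ground
truth.

Intensities of present cells are log-normal around a base level with a
stated coefficient of variation; detection failure (dropout) zeroes present
cells at a fixed rate, which is what stresses the two-thirds presence rule.
Contaminant features are enriched in blanks so they fail the blank-ratio
test, and are level-independent in QC wells so they fail the dilution
linearity test.  Everything is reproducible from one master seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .signal_sheet import FeatureRecord, SampleMeta, SignalSheet
from .traffic import CompartmentNetwork, TrafficClassification

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticError",
    "default_network",
    "simulate_study",
    "score_recovery",
    "recovery_summary",
]


class SyntheticError(ValueError):
    pass


def default_network() -> CompartmentNetwork:
    """Three-compartment path network (e.g. liver - serum - brain)."""
    return CompartmentNetwork.from_edges(
        ["liver", "serum", "brain"], [("liver", "serum"), ("serum", "brain")]
    )


@dataclass
class SimulationConfig:
    """Study design and noise model for one simulated plate.

    Defaults mirror the emulated study design: two phenotypes, a
    three-compartment path network, 6 analytical samples per (phenotype,
    compartment) group, two QC stocks at dilution levels 0.25/0.5/1.0 with
    3 technical replicates each, 20% log-normal intensity noise and 20%
    dropout among present cells.
    """

    network: CompartmentNetwork = field(default_factory=default_network)
    phenotypes: tuple[str, str] = ("F", "H")
    n_samples_per_group: int = 6
    planted_counts: Mapping[str, int] = field(
        default_factory=lambda: {"A": 10, "B": 6, "U": 6, "N2": 6}
    )
    overlap_fraction: Mapping[str, float] | float = 0.5
    lipid_class: str = "TG"
    base_intensity: float = 1_000_000.0
    noise_cv: float = 20.0  # percent
    dropout_rate: float = 0.2
    blank_level: float = 1_000.0
    n_blanks: int = 6
    contaminant_count: int = 5
    qc_stocks: int = 2
    qc_levels: tuple[float, ...] = (0.25, 0.5, 1.0)
    qc_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phenotypes) != 2:
            raise SyntheticError("exactly two phenotypes required")
        if self.n_samples_per_group < 1:
            raise SyntheticError("n_samples_per_group must be >= 1")
        if any(c < 0 for c in self.planted_counts.values()):
            raise SyntheticError("planted counts must be >= 0")
        if self.noise_cv < 0 or not 0 <= self.dropout_rate <= 1:
            raise SyntheticError("invalid noise_cv or dropout_rate")

    def overlap_for(self, category: str) -> float:
        if isinstance(self.overlap_fraction, Mapping):
            frac = self.overlap_fraction.get(category, 0.5)
        else:
            frac = self.overlap_fraction
        if not 0 <= frac <= 1:
            raise SyntheticError(f"overlap fraction for {category!r} must be in [0,1]")
        return frac


@dataclass
class GroundTruth:
    """Planted compartment patterns and intended categories per phenotype."""

    presence: dict[str, dict[str, set[str]]]  # phenotype -> lipid -> compartments
    categories: dict[str, dict[str, str]]  # phenotype -> lipid -> category label
    contaminants: set[str]

    def category_sets(self, phenotype: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for lipid, cat in self.categories[phenotype].items():
            out.setdefault(cat, set()).add(lipid)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "presence": {
                        ph: {k: sorted(v) for k, v in m.items()}
                        for ph, m in self.presence.items()
                    },
                    "categories": self.categories,
                    "contaminants": sorted(self.contaminants),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _category_instances(net: CompartmentNetwork) -> list[tuple[str, set[str]]]:
    """(category label, compartment pattern) for every plantable instance."""
    out: list[tuple[str, set[str]]] = [("A", set(net.compartments))]
    for e in net.edges:
        k = net.edge_key(*e)
        out.append((f"B@{k[0]}-{k[1]}", {k[0], k[1]}))
    for c in net.compartments:
        out.append((f"U@{c}", {c}))
    for p in net.nonadjacent_pairs():
        out.append((f"N2@{p[0]}|{p[1]}", {p[0], p[1]}))
    return out


def _lognormal_factors(rng: np.random.Generator, cv_percent: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv_percent == 0:
        return 1.0 if size is None else np.ones(size)
    cv = cv_percent / 100.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_study(config: SimulationConfig) -> tuple[SignalSheet, GroundTruth]:
    """Generate one synthetic signal sheet plus its ground truth.

    Raises :class:`SyntheticError` for infeasible designs (e.g. N2 lipids
    requested on a network with no non-adjacent pair).
    """
    net = config.network
    rng = np.random.default_rng(config.seed)
    instances = _category_instances(net)
    if not net.nonadjacent_pairs() and config.planted_counts.get("N2", 0) > 0:
        raise SyntheticError(
            "network has no non-adjacent compartment pair; cannot plant N2 lipids"
        )

    # -- plant lipids -----------------------------------------------------
    ph1, ph2 = config.phenotypes
    presence: dict[str, dict[str, set[str]]] = {ph1: {}, ph2: {}}
    categories: dict[str, dict[str, str]] = {ph1: {}, ph2: {}}
    lipid_ids: list[str] = []
    counter = 0

    def new_lipid() -> str:
        nonlocal counter
        counter += 1
        return f"{config.lipid_class}(sim:{counter:03d})"

    for label, pattern in instances:
        base_cat = label.split("@")[0]
        count = int(config.planted_counts.get(base_cat, 0))
        if count == 0:
            continue
        n_shared = int(round(config.overlap_for(base_cat) * count))
        shared = [new_lipid() for _ in range(n_shared)]
        only1 = [new_lipid() for _ in range(count - n_shared)]
        only2 = [new_lipid() for _ in range(count - n_shared)]
        for lid in shared + only1:
            presence[ph1][lid] = set(pattern)
            categories[ph1][lid] = label
        for lid in shared + only2:
            presence[ph2][lid] = set(pattern)
            categories[ph2][lid] = label
        lipid_ids.extend(shared + only1 + only2)

    contaminants = {f"CONT{i + 1:02d}" for i in range(config.contaminant_count)}

    # -- samples ----------------------------------------------------------
    samples: list[SampleMeta] = []
    for ph in config.phenotypes:
        for comp in net.compartments:
            for r in range(1, config.n_samples_per_group + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{ph}_{comp}_{r:02d}",
                        role="analytical",
                        compartment=comp,
                        phenotype=ph,
                        replicate=r,
                    )
                )
    for r in range(1, config.n_blanks + 1):
        samples.append(SampleMeta(sample_id=f"BLANK_{r:02d}", role="blank", replicate=r))
    for stock in range(1, config.qc_stocks + 1):
        for level in config.qc_levels:
            for r in range(1, config.qc_replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"QC{stock}_L{int(level * 100)}_{r}",
                        role="qc",
                        qc_stock=f"stock{stock}",
                        qc_level=level,
                        replicate=r,
                    )
                )

    # -- features ---------------------------------------------------------
    all_ids = lipid_ids + sorted(contaminants)
    features = []
    mzs = rng.uniform(400.0, 1200.0, size=len(all_ids))
    rts = rng.uniform(0.5, 18.5, size=len(all_ids))
    for i, lid in enumerate(all_ids):
        features.append(
            FeatureRecord(
                feature_id=f"F{i + 1:04d}",
                mz=float(round(mzs[i], 4)),
                rt=float(round(rts[i], 2)),
                annotation=lid,
                lipid_class="" if lid in contaminants else config.lipid_class,
            )
        )

    # -- intensities ------------------------------------------------------
    inten = np.zeros((len(features), len(samples)))
    base = config.base_intensity
    for j, s in enumerate(samples):
        for i, lid in enumerate(all_ids):
            if s.role == "analytical":
                if lid in contaminants:
                    # same mean as in blanks: fails the 3x blank-ratio test
                    inten[i, j] = config.blank_level * _lognormal_factors(
                        rng, config.noise_cv, None
                    )
                elif s.compartment in presence[s.phenotype].get(lid, ()):
                    if rng.uniform() < config.dropout_rate:
                        inten[i, j] = 0.0
                    else:
                        inten[i, j] = base * _lognormal_factors(
                            rng, config.noise_cv, None
                        )
            elif s.role == "blank":
                level = config.blank_level if lid in contaminants else base / 1000.0
                inten[i, j] = level * _lognormal_factors(rng, config.noise_cv, None)
            else:  # qc: pooled material, scales with dilution level
                if lid in contaminants:
                    inten[i, j] = config.blank_level  # level-independent
                else:
                    inten[i, j] = (
                        base
                        * s.qc_level
                        * _lognormal_factors(rng, config.noise_cv, None)
                    )
    sheet = SignalSheet(features, samples, inten)
    truth = GroundTruth(presence=presence, categories=categories, contaminants=contaminants)
    return sheet, truth


# -- recovery scoring ------------------------------------------------------


def score_recovery(
    truth: GroundTruth,
    classifications: Mapping[str, TrafficClassification],
) -> list[dict]:
    """Per-category precision/recall of a classification pair vs ground truth.

    ``classifications`` maps phenotype label to its TrafficClassification.
    Precision is None (undefined) when the predicted set is empty.
    """
    rows = []
    for ph, cls in classifications.items():
        if ph not in truth.categories:
            raise SyntheticError(f"phenotype {ph!r} not in ground truth")
        true_sets = truth.category_sets(ph)
        pred_sets = cls.category_sets()
        for label in sorted(set(true_sets) | {k for k, v in pred_sets.items() if v}):
            t = true_sets.get(label, set())
            p = pred_sets.get(label, set())
            tp = len(t & p)
            rows.append(
                {
                    "phenotype": ph,
                    "category": label,
                    "n_true": len(t),
                    "n_pred": len(p),
                    "precision": tp / len(p) if p else None,
                    "recall": tp / len(t) if t else None,
                }
            )
    return rows


def recovery_summary(rows: Sequence[dict]) -> dict[str, float]:
    """Macro-averaged precision and recall over categories with defined values."""
    precisions = [r["precision"] for r in rows if r["precision"] is not None]
    recalls = [r["recall"] for r in rows if r["recall"] is not None]
    return {
        "precision": float(np.mean(precisions)) if precisions else math.nan,
        "recall": float(np.mean(recalls)) if recalls else math.nan,
    }
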