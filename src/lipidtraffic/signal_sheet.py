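"""Signal sheets: the feature x sample intensity table at the centre of the pipeline.

A signal sheet holds one intensity value per (feature, sample) cell, where a
feature is an LCMS signal with an m/z and retention-time coordinate (and,
once matched against a target library, a lipid annotation), and a sample is
an extraction well with a role: an analytical sample, an extraction blank,
or a pooled quality-control (QC) well injected at a known dilution level.

Missing values are encoded as 0 and mean "no signal" throughout: presence
calling downstream is "signal strength > 0", so zero and absent are
operationally identical.  Layout is features-as-rows, samples-as-columns;
sample metadata lives in a separate table keyed by ``sample_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "FeatureRecord",
    "SignalSheet",
    "SignalSheetError",
    "read_signal_sheet",
    "write_signal_sheet",
    "total_signal",
    "log10_transform",
]

ROLES = ("analytical", "blank", "qc")
QC_LEVELS = (0.25, 0.5, 1.0)

#: Reserved (non-sample) columns of the sheet file, in order.
FEATURE_COLUMNS = ("feature_id", "mz", "rt", "annotation", "lipid_class")
METADATA_COLUMNS = (
    "sample_id",
    "role",
    "compartment",
    "phenotype",
    "qc_stock",
    "qc_level",
    "replicate",
)


class SignalSheetError(ValueError):
    """Raised when a sheet or its metadata violates a structural invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample column.

    ``qc_stock`` and ``qc_level`` are required exactly when ``role == "qc"``;
    QC levels are dilution fractions drawn from {0.25, 0.5, 1.0} (wells
    pipetted at 25, 50 or 100% strength).
    """

    sample_id: str
    role: str = "analytical"
    compartment: str = ""
    phenotype: str = ""
    qc_stock: str = ""
    qc_level: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise SignalSheetError("sample_id must be non-empty")
        if self.role not in ROLES:
            raise SignalSheetError(
                f"sample {self.sample_id!r}: role {self.role!r} not in {ROLES}"
            )
        if self.role == "qc":
            if not self.qc_stock:
                raise SignalSheetError(
                    f"QC sample {self.sample_id!r} requires a qc_stock"
                )
            if self.qc_level is None or not any(
                math.isclose(self.qc_level, lv) for lv in QC_LEVELS
            ):
                raise SignalSheetError(
                    f"QC sample {self.sample_id!r}: qc_level {self.qc_level!r} "
                    f"not in {QC_LEVELS}"
                )
        else:
            if self.qc_stock or self.qc_level is not None:
                raise SignalSheetError(
                    f"sample {self.sample_id!r}: qc fields only allowed for role=qc"
                )
        if self.replicate < 1:
            raise SignalSheetError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


@dataclass(frozen=True)
class FeatureRecord:
    """One LCMS feature: an (m/z, Rt) coordinate with optional lipid identity."""

    feature_id: str
    mz: float
    rt: float
    annotation: str = ""
    lipid_class: str = ""

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise SignalSheetError("feature_id must be non-empty")
        if not self.mz > 0:
            raise SignalSheetError(
                f"feature {self.feature_id!r}: mz must be > 0, got {self.mz}"
            )
        if self.rt < 0:
            raise SignalSheetError(
                f"feature {self.feature_id!r}: rt must be >= 0, got {self.rt}"
            )


@dataclass
class SignalSheet:
    """A validated feature x sample intensity matrix with metadata.

    Invariants checked on construction: matrix shape equals
    (len(features), len(samples)); all intensities finite and >= 0; feature
    and sample identifiers unique.
    """

    features: list[FeatureRecord]
    samples: list[SampleMeta]
    intensities: np.ndarray = field(repr=False)
    #: True for log-scale (transformed) sheets, where negative cells are legal.
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.features), len(self.samples)):
            raise SignalSheetError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"({len(self.features)} features, {len(self.samples)} samples)"
            )
        if self.intensities.size and not np.all(np.isfinite(self.intensities)):
            raise SignalSheetError("intensities must be finite")
        if not self.log_scale and self.intensities.size and self.intensities.min() < 0:
            bad = np.argwhere(self.intensities < 0)[0]
            raise SignalSheetError(
                f"negative intensity at feature "
                f"{self.features[bad[0]].feature_id!r}, sample "
                f"{self.samples[bad[1]].sample_id!r}"
            )
        fids = [f.feature_id for f in self.features]
        if len(set(fids)) != len(fids):
            dup = next(x for x in fids if fids.count(x) > 1)
            raise SignalSheetError(f"duplicate feature_id {dup!r}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            dup = next(x for x in sids if sids.count(x) > 1)
            raise SignalSheetError(f"duplicate sample_id {dup!r}")
        self._findex = {fid: i for i, fid in enumerate(fids)}
        self._sindex = {sid: j for j, sid in enumerate(sids)}

    # -- lookups -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._findex[feature_id]
        except KeyError:
            raise SignalSheetError(f"unknown feature {feature_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sindex[sample_id]
        except KeyError:
            raise SignalSheetError(f"unknown sample {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.intensities[:, self.sample_index(sample_id)]

    def row(self, feature_id: str) -> np.ndarray:
        return self.intensities[self.feature_index(feature_id), :]

    def samples_where(self, **conditions) -> list[SampleMeta]:
        """Samples whose metadata fields equal the given values."""
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in conditions.items()):
                out.append(s)
        return out

    def subset(
        self,
        feature_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "SignalSheet":
        """New sheet restricted to the given features/samples (order preserved)."""
        fi = (
            [self.feature_index(f) for f in feature_ids]
            if feature_ids is not None
            else list(range(len(self.features)))
        )
        si = (
            [self.sample_index(s) for s in sample_ids]
            if sample_ids is not None
            else list(range(len(self.samples)))
        )
        return SignalSheet(
            features=[self.features[i] for i in fi],
            samples=[self.samples[j] for j in si],
            intensities=self.intensities[np.ix_(fi, si)]
            if fi and si
            else np.zeros((len(fi), len(si))),
            log_scale=self.log_scale,
        )

    def with_annotations(
        self, annotation: dict[str, str], lipid_class: dict[str, str] | None = None
    ) -> "SignalSheet":
        """New sheet with feature annotations replaced (keyed by feature_id)."""
        lipid_class = lipid_class or {}
        feats = [
            replace(
                f,
                annotation=annotation.get(f.feature_id, f.annotation),
                lipid_class=lipid_class.get(f.feature_id, f.lipid_class),
            )
            for f in self.features
        ]
        return SignalSheet(feats, list(self.samples), self.intensities.copy())

    def to_frame(self) -> pd.DataFrame:
        """Sheet as a DataFrame in the on-disk layout (feature columns first)."""
        df = pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "mz": [f.mz for f in self.features],
                "rt": [f.rt for f in self.features],
                "annotation": [f.annotation for f in self.features],
                "lipid_class": [f.lipid_class for f in self.features],
            }
        )
        for j, s in enumerate(self.samples):
            df[s.sample_id] = self.intensities[:, j]
        return df


# -- I/O -------------------------------------------------------------------


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def read_metadata(path: str | Path, dialect: str | None = None) -> list[SampleMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SignalSheetError(f"metadata file {path} lacks columns {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=r["sample_id"],
                role=r["role"],
                compartment=r["compartment"],
                phenotype=r["phenotype"],
                qc_stock=r["qc_stock"],
                qc_level=float(r["qc_level"]) if r["qc_level"] != "" else None,
                replicate=int(r["replicate"]) if r["replicate"] != "" else 1,
            )
        )
    return out


def read_signal_sheet(
    path: str | Path,
    metadata_path: str | Path,
    dialect: str | None = None,
    transpose: bool = False,
    mz_window: tuple[float, float] | None = None,
) -> SignalSheet:
    """Read a signal sheet plus its sample-metadata table.

    The sheet file carries feature columns (``feature_id, mz, rt`` and
    optionally ``annotation, lipid_class``) followed by one intensity column
    per sample.  Every sample column must be described in the metadata table;
    unparseable intensity cells are reported with their coordinates.  Empty
    cells read as 0 (no signal).  ``transpose`` tolerates samples-as-rows
    input.  ``mz_window``, when given, rejects features outside the
    acquisition window.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names="feature_id")
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise SignalSheetError(f"sheet {path} lacks required column {col!r}")
    meta = {m.sample_id: m for m in read_metadata(metadata_path, dialect)}
    sample_cols = [c for c in df.columns if c not in FEATURE_COLUMNS]
    unknown = [c for c in sample_cols if c not in meta]
    if unknown:
        raise SignalSheetError(
            f"no metadata for sample column(s) {unknown} in {path}"
        )

    features = []
    for i, r in df.iterrows():
        try:
            mz = float(r["mz"])
            rt = float(r["rt"])
        except ValueError as e:
            raise SignalSheetError(f"row {i}: unparseable mz/rt ({e})") from None
        if mz_window is not None and not (mz_window[0] <= mz <= mz_window[1]):
            raise SignalSheetError(
                f"feature {r['feature_id']!r}: mz {mz} outside acquisition "
                f"window {mz_window}"
            )
        features.append(
            FeatureRecord(
                feature_id=r["feature_id"],
                mz=mz,
                rt=rt,
                annotation=r.get("annotation", ""),
                lipid_class=r.get("lipid_class", ""),
            )
        )

    inten = np.zeros((len(features), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            if raw == "":
                continue
            try:
                inten[i, j] = float(raw)
            except ValueError:
                raise SignalSheetError(
                    f"unparseable intensity {raw!r} at row {i}, column {col!r}"
                ) from None
    return SignalSheet(features, [meta[c] for c in sample_cols], inten)


def write_signal_sheet(
    sheet: SignalSheet, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write a sheet (and optionally its metadata) as CSV/TSV; round-trips exactly."""
    path = Path(path)
    sheet.to_frame().to_csv(path, sep=_sep_for(path, None), index=False)
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        rows = []
        for s in sheet.samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "role": s.role,
                    "compartment": s.compartment,
                    "phenotype": s.phenotype,
                    "qc_stock": s.qc_stock,
                    "qc_level": "" if s.qc_level is None else s.qc_level,
                    "replicate": s.replicate,
                }
            )
        pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
            metadata_path, sep=_sep_for(metadata_path, None), index=False
        )


# -- simple transforms -----------------------------------------------------


def total_signal(sheet: SignalSheet, sample_id: str) -> float:
    """Sum of all feature intensities for one sample."""
    return float(sheet.column(sample_id).sum())


def log10_transform(sheet: SignalSheet, pseudocount: float = 1.0) -> SignalSheet:
    """Cell-wise log10(x + pseudocount); requires positivity of the argument."""
    if pseudocount < 0:
        raise SignalSheetError("pseudocount must be >= 0")
    if pseudocount == 0 and sheet.intensities.size and sheet.intensities.min() <= 0:
        raise SignalSheetError(
            "log10 with pseudocount 0 requires strictly positive intensities"
        )
    return SignalSheet(
        list(sheet.features),
        list(sheet.samples),
        np.log10(sheet.intensities + pseudocount),
        log_scale=True,
    )
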