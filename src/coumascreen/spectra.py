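"""MS2 spectrum and feature-table containers plus readers/writers.

Spectra travel as MGF (``BEGIN IONS``/``END IONS`` blocks, MZmine
feature-based-networking export dialect); quantification tables as
comma- or tab-delimited text with one column per sample. Parsing of MGF
is delegated to :mod:`pyteomics.mgf`.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "FeatureTable",
    "SpectrumFormatError",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_annotations",
    "read_annotations",
]


class SpectrumFormatError(ValueError):
    """Raised for malformed MGF entries or invalid feature tables."""


@dataclass(frozen=True)
class Spectrum:
    """One MS2 scan: a precursor m/z and its fragment peak list.

    Peaks are stored sorted ascending by m/z with near-duplicate m/z
    (within 1e-6) merged by intensity summation. ``flagged_empty`` marks
    entries that arrived with zero peaks but are retained for bookkeeping.
    """

    node_id: str
    precursor_mz: float
    peaks: Tuple[Tuple[float, float], ...] = ()
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise SpectrumFormatError(
                f"spectrum {self.node_id}: precursor m/z must be positive"
            )
        cleaned: List[Tuple[float, float]] = []
        for mz, inten in sorted(self.peaks):
            if mz <= 0:
                raise SpectrumFormatError(
                    f"spectrum {self.node_id}: non-positive peak m/z {mz}"
                )
            if inten < 0:
                raise SpectrumFormatError(
                    f"spectrum {self.node_id}: negative intensity at m/z {mz}"
                )
            if cleaned and mz - cleaned[-1][0] < 1e-6:
                cleaned[-1] = (cleaned[-1][0], cleaned[-1][1] + inten)
            else:
                cleaned.append((float(mz), float(inten)))
        object.__setattr__(self, "peaks", tuple(cleaned))

    @property
    def flagged_empty(self) -> bool:
        return len(self.peaks) == 0

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)

    def base_peak(self) -> Optional[Tuple[float, float]]:
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p[1])

    def with_id(self, node_id: str) -> "Spectrum":
        return replace(self, node_id=str(node_id))


def read_mgf(path: str | Path) -> List[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    ``PEPMASS`` becomes the precursor m/z; ``FEATURE_ID`` is preferred over
    ``SCANS`` as the node id (MZmine FBMN convention); ``RTINSECONDS`` maps
    to retention time. Entries with no peaks are retained (``flagged_empty``).
    """
    path = Path(path)
    spectra: List[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise SpectrumFormatError(
                    f"{path.name}: entry {i} is missing PEPMASS"
                )
            node_id = params.get("feature_id") or params.get("scans")
            if node_id is None:
                node_id = f"entry{i}"
            rt = params.get("rtinseconds")
            peaks = tuple(
                zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
            )
            spectra.append(
                Spectrum(
                    node_id=str(node_id),
                    precursor_mz=float(pepmass[0]),
                    peaks=peaks,
                    retention_time=float(rt) if rt is not None else None,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; round-trips through :func:`read_mgf`."""
    entries = []
    for spec in spectra:
        params = {
            "pepmass": (spec.precursor_mz, None),
            "feature_id": spec.node_id,
            "scans": spec.node_id,
        }
        if spec.retention_time is not None:
            params["rtinseconds"] = spec.retention_time
        entries.append(
            {
                "params": params,
                "m/z array": spec.mz,
                "intensity array": spec.intensities,
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh)


@dataclass
class FeatureTable:
    """Features x samples matrix of peak areas with per-sample group labels."""

    feature_ids: List[str]
    feature_mz: List[float]
    feature_rt: List[float]
    samples: List[str]
    groups: Dict[str, str]
    areas: np.ndarray
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        nf, ns = self.areas.shape
        if nf != len(self.feature_ids) or ns != len(self.samples):
            raise SpectrumFormatError(
                f"area matrix {self.areas.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.samples)} samples"
            )
        if nf == 0:
            raise SpectrumFormatError("no features")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise SpectrumFormatError(f"samples without group label: {missing}")
        if np.any(self.areas < 0):
            raise SpectrumFormatError("negative peak areas are not allowed")

    @property
    def n_features(self) -> int:
        return self.areas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.areas.shape[1]

    def group_labels(self) -> List[str]:
        """Group label per sample, in sample order."""
        return [self.groups[s] for s in self.samples]

    def samples_in_group(self, group: str) -> List[int]:
        return [j for j, s in enumerate(self.samples) if self.groups[s] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=self.feature_ids, columns=self.samples)


_ID_COLUMNS = ("feature_id", "row id", "id", "feature")
_MZ_COLUMNS = ("mz", "row m/z", "m/z", "feature_mz")
_RT_COLUMNS = ("rt", "row retention time", "retention_time", "rtinseconds")


def _find_column(columns: Sequence[str], aliases: Sequence[str]) -> Optional[str]:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_feature_table(path: str | Path, group_map: Mapping[str, str]) -> FeatureTable:
    """Read a delimited feature quantification table (MZmine-export style).

    The delimiter (comma vs tab) is sniffed. Columns named after the id,
    m/z and rt aliases are metadata; every remaining column must appear in
    `group_map`. Missing areas are imputed as 0 and counted in
    ``n_imputed``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
    df = pd.read_csv(path, sep=delimiter)
    if df.empty:
        raise SpectrumFormatError("no features")

    id_col = _find_column(df.columns, _ID_COLUMNS)
    mz_col = _find_column(df.columns, _MZ_COLUMNS)
    rt_col = _find_column(df.columns, _RT_COLUMNS)
    meta = [c for c in (id_col, mz_col, rt_col) if c is not None]
    sample_cols = [c for c in df.columns if c not in meta]
    unknown = [c for c in sample_cols if c not in group_map]
    if unknown:
        raise SpectrumFormatError(
            f"samples absent from group map: {sorted(unknown)}"
        )

    areas = df[sample_cols].to_numpy(dtype=float)
    n_imputed = int(np.isnan(areas).sum())
    areas = np.nan_to_num(areas, nan=0.0)

    feature_ids = (
        df[id_col].astype(str).tolist() if id_col else [str(i) for i in range(len(df))]
    )
    feature_mz = df[mz_col].astype(float).tolist() if mz_col else [0.0] * len(df)
    feature_rt = df[rt_col].astype(float).tolist() if rt_col else [0.0] * len(df)

    return FeatureTable(
        feature_ids=feature_ids,
        feature_mz=feature_mz,
        feature_rt=feature_rt,
        samples=sample_cols,
        groups={s: group_map[s] for s in sample_cols},
        areas=areas,
        n_imputed=n_imputed,
    )


ANNOTATION_COLUMNS = [
    "node_id",
    "precursor_mz",
    "class_call",
    "diagnostic_score",
    "losses_detected",
    "library_matches",
    "modification_call",
    "tier",
]


def write_annotations(results: Sequence, path: str | Path) -> None:
    """Write per-node annotation results as a TSV report.

    Accepts any sequence of objects exposing the annotation fields (see
    ``screen.AnnotationResult``). Rows are ordered by node id for
    deterministic output.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "node_id": r.node_id,
                "precursor_mz": f"{r.precursor_mz:.4f}",
                "class_call": ";".join(r.class_calls),
                "diagnostic_score": (
                    "" if r.diagnostic_score is None else f"{r.diagnostic_score:.4f}"
                ),
                "losses_detected": ";".join(sorted(r.losses_detected)),
                "library_matches": ";".join(
                    f"{name}({dppm:+.1f}ppm)" for name, dppm in r.library_matches
                ),
                "modification_call": (
                    ""
                    if r.modification_call is None
                    else f"{r.modification_call[0]}+{'+'.join(r.modification_call[1])}"
                ),
                "tier": r.tier,
            }
        )
    rows.sort(key=lambda row: str(row["node_id"]))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=ANNOTATION_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation report back as a DataFrame (string-typed fields)."""
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")
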