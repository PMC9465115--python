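"""Spectral-library I/O: read, validate, filter and summarise precursor tables.

A spectral library is the empirical reference for window design: one row per
peptide precursor with its quadrupole coordinate (m/z), trapped-ion-mobility
coordinate (reduced mobility 1/K0, in V*s/cm^2) and charge state.  Three text
dialects are supported:

* ``generic``      -- columns ``mz``, ``im``, ``charge`` (optional
  ``intensity``, ``sequence``); the package's own round-trippable format.
* ``diann_fragpipe`` -- DIA-NN / FragPipe library exports
  (``PrecursorMz``, ``IonMobility``, ``PrecursorCharge``, ``ModifiedPeptide``).
* ``spectronaut``  -- Spectronaut library exports (same column names).

Files may be TSV or CSV (the delimiter is sniffed from the header line) and
may be gzip-compressed (by ``.gz`` extension).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrecursorRecord",
    "SpectralLibrary",
    "ParseReport",
    "read_library",
    "write_library",
    "filter_precursors",
    "library_summary",
]

#: column maps per dialect: internal name -> source column name
_DIALECT_COLUMNS = {
    "generic": {
        "mz": "mz",
        "im": "im",
        "charge": "charge",
        "intensity": "intensity",
        "sequence": "sequence",
    },
    "diann_fragpipe": {
        "mz": "PrecursorMz",
        "im": "IonMobility",
        "charge": "PrecursorCharge",
        "intensity": "LibraryIntensity",
        "sequence": "ModifiedPeptide",
    },
    "spectronaut": {
        "mz": "PrecursorMz",
        "im": "IonMobility",
        "charge": "PrecursorCharge",
        "intensity": "LibraryIntensity",
        "sequence": "ModifiedPeptide",
    },
}

_PHOSPHO_TOKENS = ("Phospho", "UniMod:21", "unimod:21")


def _is_phospho(sequence: str | None) -> bool:
    """A precursor is phosphorylated iff its modified sequence carries a
    phospho annotation in either dialect convention."""
    if not sequence:
        return False
    return any(tok in sequence for tok in _PHOSPHO_TOKENS)


@dataclass(frozen=True)
class PrecursorRecord:
    """One library precursor.

    Parameters
    ----------
    mz : float
        Precursor mass-to-charge (Th); must be positive.
    im : float
        Reduced ion mobility 1/K0 (V*s/cm^2); must be positive.
    charge : int
        Precursor charge state, >= 1.
    intensity : float
        Abundance in arbitrary units (default 1.0).
    sequence : str or None
        Modified-peptide string, when the source provides one.
    is_phospho : bool
        True iff ``sequence`` carries a phosphorylation annotation.
    """

    mz: float
    im: float
    charge: int
    intensity: float = 1.0
    sequence: str | None = None
    is_phospho: bool = False

    def __post_init__(self) -> None:
        if not (self.mz > 0 and self.im > 0 and self.charge >= 1):
            raise ValueError(
                f"invalid precursor: mz={self.mz}, im={self.im}, charge={self.charge}"
            )


@dataclass(frozen=True)
class ParseReport:
    """Bookkeeping for one :func:`read_library` call."""

    n_rows: int
    n_parsed: int
    n_dropped: int
    n_deduplicated: int


@dataclass(frozen=True)
class SpectralLibrary:
    """An ordered, deduplicated collection of precursors.

    Construction deduplicates on ``(sequence, charge)`` when a sequence is
    present and on ``(mz, im, charge)`` otherwise; the first occurrence wins.
    """

    records: tuple[PrecursorRecord, ...]
    source_format: str = "generic"
    filters_applied: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @staticmethod
    def from_records(
        records: Iterable[PrecursorRecord],
        source_format: str = "generic",
        deduplicate: bool = True,
    ) -> "SpectralLibrary":
        recs = list(records)
        if deduplicate:
            seen: set = set()
            out = []
            for r in recs:
                key = (
                    (r.sequence, r.charge)
                    if r.sequence is not None
                    else (r.mz, r.im, r.charge)
                )
                if key in seen:
                    continue
                seen.add(key)
                out.append(r)
            recs = out
        return SpectralLibrary(tuple(recs), source_format=source_format)

    # -- columnar views -----------------------------------------------------

    @property
    def mz(self) -> np.ndarray:
        return np.array([r.mz for r in self.records], dtype=float)

    @property
    def im(self) -> np.ndarray:
        return np.array([r.im for r in self.records], dtype=float)

    @property
    def charge(self) -> np.ndarray:
        return np.array([r.charge for r in self.records], dtype=int)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([r.intensity for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz": self.mz,
                "im": self.im,
                "charge": self.charge,
                "intensity": self.intensity,
                "sequence": [r.sequence for r in self.records],
            }
        )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def _detect_dialect(columns: Sequence[str]) -> str:
    cols = set(columns)
    generic = {"mz", "im", "charge"} <= cols
    tool = {"PrecursorMz", "IonMobility", "PrecursorCharge"} <= cols
    if generic and tool:
        raise ValueError("ambiguous library dialect: header matches both generic and tool columns")
    if generic:
        return "generic"
    if tool:
        # DIA-NN/FragPipe and Spectronaut share the mapped column names;
        # resolve by a marker column, defaulting to diann_fragpipe.
        return "spectronaut" if "FragmentLossType" in cols and "ExcludeFromAssay" in cols else "diann_fragpipe"
    raise ValueError(f"unknown library dialect: columns {sorted(cols)[:10]}")


def read_library(path: str | Path, format: str = "auto") -> tuple[SpectralLibrary, ParseReport]:
    """Read a spectral library from a delimited text file.

    Rows with missing or non-numeric m/z, mobility or charge are dropped and
    counted in the returned :class:`ParseReport`.  Record order follows file
    row order.  Raises on unreadable files, unknown/ambiguous dialects and on
    zero valid records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")

    dialect = _detect_dialect(df.columns) if format == "auto" else format
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _DIALECT_COLUMNS[dialect]
    for key in ("mz", "im", "charge"):
        if colmap[key] not in df.columns:
            raise ValueError(f"dialect {dialect!r}: required column {colmap[key]!r} missing")

    n_rows = len(df)
    mz = pd.to_numeric(df[colmap["mz"]], errors="coerce")
    im = pd.to_numeric(df[colmap["im"]], errors="coerce")
    charge = pd.to_numeric(df[colmap["charge"]], errors="coerce")
    valid = mz.notna() & im.notna() & charge.notna() & (mz > 0) & (im > 0) & (charge >= 1)

    has_int = colmap["intensity"] in df.columns
    has_seq = colmap["sequence"] in df.columns
    intensity = (
        pd.to_numeric(df[colmap["intensity"]], errors="coerce").fillna(1.0)
        if has_int
        else pd.Series(1.0, index=df.index)
    )
    sequence = df[colmap["sequence"]] if has_seq else pd.Series(None, index=df.index, dtype=object)

    records = []
    for i in df.index[valid]:
        seq = sequence[i]
        seq = None if (seq is None or (isinstance(seq, float) and np.isnan(seq))) else str(seq)
        records.append(
            PrecursorRecord(
                mz=float(mz[i]),
                im=float(im[i]),
                charge=int(charge[i]),
                intensity=float(intensity[i]),
                sequence=seq,
                is_phospho=_is_phospho(seq),
            )
        )
    if not records:
        raise ValueError(f"{path}: no valid precursor records")
    lib = SpectralLibrary.from_records(records, source_format=dialect)
    report = ParseReport(
        n_rows=n_rows,
        n_parsed=int(valid.sum()),
        n_dropped=int(n_rows - valid.sum()),
        n_deduplicated=int(valid.sum()) - len(lib),
    )
    return lib, report


def write_library(lib: SpectralLibrary, path: str | Path, sep: str = "\t") -> Path:
    """Write a library in the generic dialect (lossless round-trip)."""
    path = Path(path)
    df = lib.to_frame()
    # shortest-repr floats (pandas default) round-trip exactly
    df.to_csv(path, sep=sep, index=False)
    return path


def filter_precursors(
    lib: SpectralLibrary,
    mz_range: tuple[float, float],
    im_range: tuple[float, float],
    charges: Iterable[int],
) -> SpectralLibrary:
    """Restrict a library to an m/z interval, an IM interval and a charge set.

    Both intervals are closed.  An empty result is returned (not raised); the
    applied filters are recorded on the returned library.
    """
    charges = set(int(c) for c in charges)
    if not charges:
        raise ValueError("charges must be nonempty")
    if not (mz_range[0] <= mz_range[1] and im_range[0] <= im_range[1]):
        raise ValueError("ranges must be ordered intervals")
    kept = tuple(
        r
        for r in lib.records
        if mz_range[0] <= r.mz <= mz_range[1]
        and im_range[0] <= r.im <= im_range[1]
        and r.charge in charges
    )
    return SpectralLibrary(
        kept,
        source_format=lib.source_format,
        filters_applied={
            "mz_range": (float(mz_range[0]), float(mz_range[1])),
            "im_range": (float(im_range[0]), float(im_range[1])),
            "charges": tuple(sorted(charges)),
        },
    )


def library_summary(lib: SpectralLibrary) -> dict:
    """Record count, per-charge counts, coordinate ranges and phospho fraction."""
    n = len(lib)
    if n == 0:
        return {
            "n_records": 0,
            "per_charge": {},
            "mz_range": None,
            "im_range": None,
            "phospho_fraction": None,
        }
    charges = lib.charge
    per_charge = {int(c): int((charges == c).sum()) for c in np.unique(charges)}
    return {
        "n_records": n,
        "per_charge": per_charge,
        "mz_range": (float(lib.mz.min()), float(lib.mz.max())),
        "im_range": (float(lib.im.min()), float(lib.im.max())),
        "phospho_fraction": sum(r.is_phospho for r in lib.records) / n,
    }
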