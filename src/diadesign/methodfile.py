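"""Instrument method-file (window table) reading and writing.

The dialect is an openly specified CSV analog of timsTOF dia-PASEF window
tables: a header naming the columns, one row per isolation window plus one
MS1 row per cycle, ``#``-prefixed comment lines allowed.  IM start/end
reflect the ramp direction (start = high IM, end = low IM).  The reader is
permissive: column order is free, header names accept common synonyms, and
the delimiter (comma or tab) is sniffed.

Formatting contract (so files diff cleanly): IM values are printed with six
decimals, m/z values with four; re-reading a written file reconstructs every
window at that printed precision.
"""

from __future__ import annotations

import re
from pathlib import Path

from .geometry import (
    AcquisitionScheme,
    DEFAULT_FRAME_OVERHEAD,
    DEFAULT_RAMP_TIME,
    DiaPasefScan,
    IsolationWindow,
)

__all__ = ["write_method_file", "read_method_file", "METHOD_FILE_HEADER"]

METHOD_FILE_HEADER = (
    "type,cycle id,start IM [1/K0],end IM [1/K0],start mass [m/z],end mass [m/z],CE [eV]"
)

#: normalized header synonyms -> canonical field
_HEADER_SYNONYMS = {
    "type": "type",
    "mstype": "type",
    "cycleid": "cycle_id",
    "cycle": "cycle_id",
    "startim": "im_start",
    "imstart": "im_start",
    "endim": "im_end",
    "imend": "im_end",
    "startmass": "mz_start",
    "startmz": "mz_start",
    "mzstart": "mz_start",
    "mass start": "mz_start",
    "endmass": "mz_end",
    "endmz": "mz_end",
    "mzend": "mz_end",
    "ce": "ce",
    "collisionenergy": "ce",
}


def _normalize_header(name: str) -> str:
    name = re.sub(r"\[.*?\]", "", name)  # strip unit annotations
    return re.sub(r"[\s_\-/]", "", name).lower()


def write_method_file(scheme: AcquisitionScheme, path: str | Path) -> Path:
    """Write a scheme as a window table: one MS1 row per cycle followed by one
    PASEF row per window, high-IM-first within each scan."""
    if scheme.n_windows == 0:
        raise ValueError("cannot write an empty scheme")
    path = Path(path)
    lines = ["# diadesign dia-PASEF window table", METHOD_FILE_HEADER]
    for _ in range(scheme.ms1_frames_per_cycle):
        lines.append("ms1,0,-,-,-,-,-")
    for scan in scheme.scans:
        for w in scan.windows:
            lines.append(
                f"pasef,{scan.index},{w.im_high:.6f},{w.im_low:.6f},"
                f"{w.mz_start:.4f},{w.mz_end:.4f},-"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_method_file(
    path: str | Path,
    *,
    ramp_time: float = DEFAULT_RAMP_TIME,
    frame_overhead: float = DEFAULT_FRAME_OVERHEAD,
) -> AcquisitionScheme:
    """Reconstruct an :class:`AcquisitionScheme` from a window table.

    PASEF rows are grouped into scans by cycle id and ordered high-IM-first;
    timing comes from the arguments (the file stores only geometry).
    Geometry inconsistencies are reported with their row numbers.
    """
    path = Path(path)
    rows = []
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(sep)]
            if header is None:
                header = [_HEADER_SYNONYMS.get(_normalize_header(f)) for f in fields]
                required = {"type", "cycle_id", "im_start", "im_end", "mz_start", "mz_end"}
                missing = required - set(h for h in header if h)
                if missing:
                    raise ValueError(f"{path}: missing required columns {sorted(missing)}")
                continue
            rows.append((lineno, dict(zip(header, fields))))

    if header is None:
        raise ValueError(f"{path}: no header line found")

    ms1_count = 0
    by_cycle: dict[int, list] = {}
    for lineno, row in rows:
        kind = row["type"].lower()
        if kind in ("ms1", "ms"):
            ms1_count += 1
            continue
        if kind not in ("pasef", "diapasef", "ms2"):
            raise ValueError(f"{path}:{lineno}: unknown row type {row['type']!r}")
        try:
            cycle = int(float(row["cycle_id"]))
            im_start = float(row["im_start"])
            im_end = float(row["im_end"])
            mz_start = float(row["mz_start"])
            mz_end = float(row["mz_end"])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable numeric field ({exc})") from None
        if not (im_start > im_end and mz_start < mz_end):
            raise ValueError(
                f"{path}:{lineno}: inconsistent window geometry "
                f"(need start IM > end IM and start mass < end mass)"
            )
        by_cycle.setdefault(cycle, []).append(
            IsolationWindow(mz_start=mz_start, mz_end=mz_end, im_low=im_end, im_high=im_start)
        )
    if not by_cycle:
        raise ValueError(f"{path}: no pasef rows")

    scans = []
    for i, cycle in enumerate(sorted(by_cycle), start=1):
        windows = tuple(sorted(by_cycle[cycle], key=lambda w: -w.im_high))
        scans.append(DiaPasefScan(index=i, windows=windows))

    all_windows = [w for s in scans for w in s.windows]
    mz_range = (min(w.mz_start for w in all_windows), max(w.mz_end for w in all_windows))
    im_range = (min(w.im_low for w in all_windows), max(w.im_high for w in all_windows))
    return AcquisitionScheme(
        scans=tuple(scans),
        mz_range=mz_range,
        im_range=im_range,
        ms1_frames_per_cycle=max(ms1_count, 1),
        ramp_time=ramp_time,
        frame_overhead=frame_overhead,
    )
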