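"""Event-level and histogram containers plus all on-disk formats.

Supported formats
-----------------
* CSV event lists: one header row, a ``fl`` column (linear fluorescence,
  arbitrary units) and an optional ``ssc`` side-scatter column.
* A deliberately minimal FCS subset: FCS 3.0, list mode, single dataset,
  32-bit float data, linear amplification only.  Anything outside that
  subset is rejected loudly rather than guessed at.
* Tab-delimited peak tables: one row per fitted peak followed by summary
  rows carrying the derived 2C, P and P% of the tube.  UTF-8, '.' decimal
  separator, one header line, numbers at 6 significant digits so the file
  round-trips losslessly at that precision.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    ParameterError,
    UnsupportedScaleError,
)

__all__ = [
    "EventTable",
    "FcmHistogram",
    "StandardDef",
    "PISUM",
    "SOLANUM",
    "read_events",
    "write_events",
    "bin_events",
    "write_peak_table",
    "read_peak_table",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class EventTable:
    """Per-event linear fluorescence (and optional side scatter) of one tube."""

    fluorescence: np.ndarray
    side_scatter: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 1:
            raise ParameterError("fluorescence must be a 1D array")
        if self.fluorescence.size and self.fluorescence.min() < 0:
            raise ParameterError("fluorescence intensities must be >= 0")
        if self.side_scatter is not None:
            self.side_scatter = np.asarray(self.side_scatter, dtype=float)
            if self.side_scatter.shape != self.fluorescence.shape:
                raise ParameterError(
                    "side_scatter must parallel fluorescence (same length)"
                )
        self.meta.setdefault("n_events", int(self.fluorescence.size))
        if self.meta["n_events"] != self.fluorescence.size:
            raise ParameterError("recorded event count disagrees with data length")

    def __len__(self) -> int:
        return int(self.fluorescence.size)


@dataclass
class FcmHistogram:
    """Binned channel counts on a linear fluorescence axis.

    ``gain`` is the intensity-units-per-channel scale; the center of channel
    ``i`` sits at ``(i + 0.5) * gain``.
    """

    channel_counts: np.ndarray
    gain: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_counts = np.asarray(self.channel_counts, dtype=np.int64)
        if self.channel_counts.ndim != 1:
            raise ParameterError("channel_counts must be a 1D array")
        if self.channel_counts.size and self.channel_counts.min() < 0:
            raise ParameterError("channel counts must be non-negative")
        if self.gain <= 0:
            raise ParameterError("gain must be > 0")

    @property
    def n_channels(self) -> int:
        return int(self.channel_counts.size)

    @property
    def channel_centers(self) -> np.ndarray:
        """Channel centers in channel units (index + 0.5)."""
        return np.arange(self.n_channels, dtype=float) + 0.5

    def total(self) -> int:
        return int(self.channel_counts.sum())


@dataclass(frozen=True)
class StandardDef:
    """An internal calibration standard of known 2C DNA amount (pg)."""

    name: str
    two_c_pg: float
    role: str = "primary"
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.two_c_pg <= 0:
            raise ParameterError("standard 2C must be > 0 pg")
        if self.role not in ("primary", "secondary"):
            raise ParameterError("standard role must be 'primary' or 'secondary'")
        if self.role == "secondary" and not self.provenance:
            raise ParameterError(
                "a secondary standard must record the primary it was "
                "calibrated against"
            )


#: Primary plant reference standard.
PISUM = StandardDef("Pisum sativum 'Ctirad'", 8.76, "primary")

#: Secondary standard for samples whose 2C nearly coincides with Pisum's.
SOLANUM = StandardDef(
    "Solanum pseudocapsicum",
    2.57,
    "secondary",
    provenance="calibrated by repeated measurement against "
    "Pisum sativum 'Ctirad' (2C = 8.76 pg)",
)


# ---------------------------------------------------------------------------
# event files


def read_events(path, format: Optional[str] = None) -> EventTable:
    """Read an event list from CSV or minimal FCS.

    ``format`` is ``'csv'`` or ``'fcs'``; when omitted it is inferred from
    the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        return _read_csv_events(path)
    if format == "fcs":
        return _read_fcs_events(path)
    raise ParameterError(f"unknown event format {format!r}")


def write_events(events: EventTable, path, format: Optional[str] = None) -> None:
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        _write_csv_events(events, path)
    elif format == "fcs":
        _write_fcs_events(events, path)
    else:
        raise ParameterError(f"unknown event format {format!r}")


def _read_csv_events(path: Path) -> EventTable:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path} as CSV events: {exc}") from exc
    cols = {c.lower(): c for c in frame.columns}
    if "fl" in cols:
        fl = frame[cols["fl"]].to_numpy(dtype=float)
    elif frame.shape[1] >= 1:
        fl = frame.iloc[:, 0].to_numpy(dtype=float)
    else:
        raise FormatError(f"{path}: no fluorescence column")
    if len(fl) == 0:
        raise EmptyInputError(f"{path}: zero events")
    ssc = frame[cols["ssc"]].to_numpy(dtype=float) if "ssc" in cols else None
    return EventTable(fl, ssc, meta={"path": str(path), "sample_id": path.stem})


def _write_csv_events(events: EventTable, path: Path) -> None:
    data = {"fl": events.fluorescence}
    if events.side_scatter is not None:
        data["ssc"] = events.side_scatter
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


# -- minimal FCS 3.0 subset --------------------------------------------------

_FCS_HEADER = struct.Struct("10s8s8s8s8s8s8s")


def _write_fcs_events(events: EventTable, path: Path) -> None:
    """Write a single-dataset, list-mode, float, linear FCS 3.0 file."""
    has_ssc = events.side_scatter is not None
    n_par = 2 if has_ssc else 1
    tot = len(events)
    cols = [events.fluorescence]
    names = ["FL1"]
    if has_ssc:
        cols.append(events.side_scatter)
        names.append("SSC")
    data = np.column_stack(cols).astype("<f4").tobytes()

    kw = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$PAR": str(n_par),
        "$TOT": str(tot),
    }
    for i, (name, col) in enumerate(zip(names, cols), start=1):
        rng = max(1024.0, float(col.max()) * 1.1 if len(col) else 1024.0)
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = f"{rng:.0f}"
    if "sample_id" in events.meta:
        kw["$SMNO"] = str(events.meta["sample_id"])

    # two-pass offset computation: data begins right after TEXT
    def build_text(begin_data: int, end_data: int) -> bytes:
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        parts = []
        for key in sorted(kw):
            parts.append(key)
            parts.append(kw[key])
        return ("/" + "/".join(parts) + "/").encode("ascii")

    text = build_text(0, 0)
    for _ in range(3):
        begin_data = 58 + len(text)
        end_data = begin_data + len(data) - 1
        new_text = build_text(begin_data, end_data)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    begin_data = 58 + len(text)
    end_data = begin_data + len(data) - 1
    header = _FCS_HEADER.pack(
        b"FCS3.0    ",
        b"%8d" % 58,
        b"%8d" % (58 + len(text) - 1),
        b"%8d" % begin_data,
        b"%8d" % end_data,
        b"%8d" % 0,
        b"%8d" % 0,
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _read_fcs_events(path: Path) -> EventTable:
    raw = path.read_bytes()
    if len(raw) < 58 or not raw.startswith(b"FCS"):
        raise FormatError(f"{path}: not an FCS file")
    version = raw[:10].decode("ascii", "replace").strip()
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        try:
            return int(raw[lo:hi].decode("ascii").strip() or 0)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed FCS header") from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    if not (0 < text_start < text_end < len(raw)):
        raise FormatError(f"{path}: bad TEXT segment offsets")
    text = raw[text_start : text_end + 1].decode("utf-8", "replace")
    delim = text[0]
    tokens = text.strip(delim).split(delim)
    if len(tokens) % 2:
        raise FormatError(f"{path}: odd TEXT keyword/value count")
    kw = {k.strip().upper(): v for k, v in zip(tokens[::2], tokens[1::2])}

    if kw.get("$NEXTDATA", "0").strip() not in ("", "0"):
        raise FormatError(f"{path}: multi-dataset FCS files are not supported")
    if kw.get("$MODE", "L").strip().upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) FCS is supported")
    datatype = kw.get("$DATATYPE", "").strip().upper()
    if datatype != "F":
        raise FormatError(
            f"{path}: only $DATATYPE F is supported (got {datatype!r})"
        )
    n_par = int(kw.get("$PAR", "0"))
    tot = int(kw.get("$TOT", "0"))
    if n_par < 1:
        raise FormatError(f"{path}: $PAR missing")
    if tot == 0:
        raise EmptyInputError(f"{path}: zero events")
    names = []
    for i in range(1, n_par + 1):
        amp = kw.get(f"$P{i}E", "0,0").replace(" ", "")
        if amp not in ("0,0", "0.0,0.0", "0,0.0", "0.0,0"):
            raise UnsupportedScaleError(
                f"{path}: parameter {i} uses log amplification ($P{i}E={amp}); "
                "only linear parameters are supported"
            )
        if kw.get(f"$P{i}B", "32").strip() != "32":
            raise FormatError(f"{path}: only 32-bit float parameters supported")
        names.append(kw.get(f"$P{i}N", f"P{i}").strip())

    begin = int(kw.get("$BEGINDATA", "0") or 0) or _offset(26, 34)
    end = int(kw.get("$ENDDATA", "0") or 0) or _offset(34, 42)
    byteord = kw.get("$BYTEORD", "1,2,3,4").replace(" ", "")
    if byteord == "1,2,3,4":
        dtype = "<f4"
    elif byteord == "4,3,2,1":
        dtype = ">f4"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")
    expected = 4 * n_par * tot
    blob = raw[begin : end + 1]
    if len(blob) < expected:
        raise FormatError(f"{path}: DATA segment truncated")
    arr = np.frombuffer(blob[:expected], dtype=dtype).reshape(tot, n_par)

    fl_idx = next(
        (i for i, n in enumerate(names) if n.upper().startswith("FL")), 0
    )
    ssc_idx = next(
        (i for i, n in enumerate(names) if n.upper().startswith("SS")), None
    )
    fl = arr[:, fl_idx].astype(float)
    ssc = arr[:, ssc_idx].astype(float) if ssc_idx is not None else None
    meta = {"path": str(path), "sample_id": kw.get("$SMNO", path.stem)}
    return EventTable(fl, ssc, meta=meta)


# ---------------------------------------------------------------------------
# binning


def bin_events(
    events: EventTable, n_channels: int = 1024, gain: float = 1.0
) -> FcmHistogram:
    """Bin events onto a linear channel axis.

    Events at or beyond the top of scale accumulate in the last channel and
    are additionally counted in ``meta['overflow']``; the histogram total
    always equals the event count.
    """
    if n_channels < 64:
        raise ParameterError("n_channels must be >= 64")
    if gain <= 0:
        raise ParameterError("gain must be > 0")
    idx = np.floor(events.fluorescence / gain).astype(np.int64)
    overflow = int((idx >= n_channels).sum())
    idx = np.clip(idx, 0, n_channels - 1)
    counts = np.bincount(idx, minlength=n_channels) if len(events) else np.zeros(
        n_channels, dtype=np.int64
    )
    meta = dict(events.meta)
    meta["overflow"] = overflow
    return FcmHistogram(counts, gain=gain, meta=meta)


# ---------------------------------------------------------------------------
# peak tables

_PEAK_COLUMNS = [
    "sample_id",
    "role",
    "k",
    "position_ch",
    "position_pg",
    "cv",
    "area",
    "value",
]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_peak_table(peaks, measurement, path, header_lines=()) -> None:
    """Write the tab-delimited peak description of one tube.

    One row per fitted peak (role, endocycle index k, position in channel
    units and pg, CV, area) followed by summary rows carrying the derived
    2C, P and P% of the sample.  ``header_lines`` are emitted as leading
    '#'-prefixed provenance comments.
    """
    if not peaks:
        raise ParameterError("peak table requires at least one peak")
    path = Path(path)
    sample_id = getattr(measurement, "sample_id", "sample")
    rows = []
    for p in peaks:
        rows.append(
            [
                sample_id,
                p.role,
                "" if p.k is None else str(p.k),
                _fmt(float(p.position)),
                _fmt(None if p.position_pg is None else float(p.position_pg)),
                _fmt(float(p.cv)),
                _fmt(float(p.area)),
                "",
            ]
        )
    for name, value in (
        ("2C", measurement.two_c_pg),
        ("P", measurement.p_pg),
        ("P%", measurement.p_percent),
    ):
        rows.append([sample_id, name, "", "", "", "", "", _fmt(float(value))])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_PEAK_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_peak_table(path):
    """Parse a peak table back into (peak rows, summary dict).

    Peak rows come back as plain dicts (the fitted-peak schema), summaries
    as a ``{'2C': .., 'P': .., 'P%': ..}`` mapping.
    """
    from .peaks import PeakFit  # deferred: io stays import-light

    path = Path(path)
    peaks, summary = [], {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty peak table")
    header = lines[0].split("\t")
    if header != _PEAK_COLUMNS:
        raise FormatError(f"{path}: unexpected peak-table columns {header}")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        vals = dict(zip(header, ln.split("\t")))
        if vals["role"] in ("2C", "P", "P%"):
            summary[vals["role"]] = float(vals["value"])
            continue
        peaks.append(
            PeakFit(
                position=float(vals["position_ch"]),
                sd=float(vals["cv"]) * float(vals["position_ch"]),
                cv=float(vals["cv"]),
                area=float(vals["area"]),
                role=vals["role"],
                k=int(vals["k"]) if vals["k"] else None,
                position_pg=float(vals["position_pg"])
                if vals["position_pg"]
                else None,
            )
        )
    return peaks, summary
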