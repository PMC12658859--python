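"""Minimal FCS 3.0 reader/writer for list-mode floating-point event tables.

Mass-cytometry acquisition software exports integrated per-event intensities
as FCS 3.0: a 58-byte ASCII HEADER with segment offsets, a delimited TEXT
segment of $-keywords, and a binary DATA segment.  This module writes
list-mode ($MODE L) single-precision float ($DATATYPE F, $PnB 32) files and
reads back $DATATYPE F or D with either byte order — enough to round-trip
gated event tables with any flow-cytometry tool.

Keyword values containing the delimiter are not escaped (channel names here
never contain '/'); the reader treats doubled delimiters as empty values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_DELIM = "/"
_HEADER_LEN = 58


class FcsFormatError(ValueError):
    """Malformed or unsupported FCS content."""


def write_fcs(path: str | Path, table: pd.DataFrame) -> None:
    """Write an event table (rows = events, columns = channels) as FCS 3.0."""
    data = np.ascontiguousarray(table.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape if data.ndim == 2 else (0, len(table.columns))
    names = [str(c) for c in table.columns]
    if any(_DELIM in n for n in names):
        raise FcsFormatError(f"channel names must not contain {_DELIM!r}")

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_events)),
        ("$PAR", str(n_par)),
    ]
    for i, name in enumerate(names, start=1):
        col_max = float(np.max(data[:, i - 1])) if n_events else 0.0
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(np.ceil(col_max)) + 1)),
        ]

    def render_text(begin_data: int, end_data: int) -> bytes:
        kv = keywords + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kv) + _DELIM
        return text.encode("ascii")

    # data offsets depend on the TEXT length, which depends on the offsets'
    # digit count: iterate to a fixed point (two passes always suffice here).
    begin_data = end_data = 0
    for _ in range(4):
        text = render_text(begin_data, end_data)
        new_begin = _HEADER_LEN + len(text)
        new_end = new_begin + data.nbytes - 1 if data.nbytes else 0
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render_text(begin_data, end_data)

    text_begin = _HEADER_LEN
    text_end = _HEADER_LEN + len(text) - 1

    def fmt_offset(value: int) -> bytes:
        # header slots are 8 ASCII chars; 0 means "see TEXT keywords"
        return (b"%8d" % value) if value <= 99_999_999 else b"%8d" % 0

    header = b"FCS3.0    "
    header += fmt_offset(text_begin) + fmt_offset(text_end)
    header += fmt_offset(begin_data) + fmt_offset(end_data if data.nbytes else 0)
    header += fmt_offset(0) + fmt_offset(0)  # no ANALYSIS segment
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read a list-mode FCS 3.0 file into a DataFrame (columns = $PnN names)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN or not raw.startswith(b"FCS3"):
        raise FcsFormatError("not an FCS 3.x file: bad or truncated header")

    def header_offset(slot: int) -> int:
        start = 10 + 8 * slot
        field = raw[start:start + 8].decode("ascii", errors="replace").strip()
        try:
            return int(field) if field else 0
        except ValueError:
            raise FcsFormatError(f"malformed header offset field {field!r}") from None

    text_begin, text_end = header_offset(0), header_offset(1)
    if not (0 < text_begin < text_end < len(raw)):
        raise FcsFormatError("invalid TEXT segment offsets in header")
    text = raw[text_begin:text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text[1:].rstrip(delim).split(delim) if len(text) > 1 else []
    if len(parts) % 2:
        parts.append("")
    kw = {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}

    if "$DATATYPE" not in kw:
        raise FcsFormatError("missing $DATATYPE keyword")
    datatype = kw["$DATATYPE"].strip().upper()
    if datatype not in ("F", "D"):
        raise FcsFormatError(f"unsupported $DATATYPE {datatype!r} (only F/D)")
    try:
        n_events = int(kw["$TOT"])
        n_par = int(kw["$PAR"])
    except (KeyError, ValueError):
        raise FcsFormatError("missing or malformed $TOT/$PAR") from None

    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8
    dtype = np.dtype(f"{endian}f{itemsize}")

    begin_data = int(kw.get("$BEGINDATA", "0") or 0) or header_offset(2)
    nbytes = n_events * n_par * itemsize
    if nbytes and not (0 < begin_data and begin_data + nbytes <= len(raw)):
        raise FcsFormatError("DATA segment exceeds file size")

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}N", f"P{i}"))
        bits = kw.get(f"$P{i}B", str(itemsize * 8))
        if bits.strip() != str(itemsize * 8):
            raise FcsFormatError(f"$P{i}B={bits} inconsistent with $DATATYPE {datatype}")

    if nbytes == 0:
        return pd.DataFrame({name: np.array([], dtype=f"f{itemsize}") for name in names})
    values = np.frombuffer(raw, dtype=dtype, count=n_events * n_par, offset=begin_data)
    return pd.DataFrame(values.reshape(n_events, n_par), columns=names)
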