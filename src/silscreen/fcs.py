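"""Minimal FCS 3.0/3.1 list-mode reader and writer (float data only).

Covers what the screen pipeline needs — writing simulated wells and reading
them (or instrument exports with float list-mode data) back: single data
segment, ``$DATATYPE F``, 32-bit parameters, little- or big-endian.  Not a
general FCS implementation (no integer data, no analysis segment, no
multi-dataset files).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

_HEADER_LEN = 58
_DELIM = b"/"


def write_fcs(path, channels: Mapping[str, np.ndarray]) -> None:
    """Write channels (equal-length 1-D arrays) as an FCS 3.1 float32 file."""
    names = list(channels)
    cols = [np.asarray(channels[n], dtype=np.float32) for n in names]
    n_events = cols[0].size
    if any(c.size != n_events for c in cols):
        raise ValueError("all channels must have the same length")
    data = np.column_stack(cols).astype("<f4").tobytes()

    def text_segment(begin_data: int, end_data: int) -> bytes:
        kv = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": f"{begin_data:010d}", "$ENDDATA": f"{end_data:010d}",
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
            "$NEXTDATA": "0", "$PAR": str(len(names)), "$TOT": str(n_events),
        }
        for i, (name, col) in enumerate(zip(names, cols), start=1):
            rng = max(1.0, float(col.max()) if n_events else 1.0)
            kv[f"$P{i}N"] = name
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            kv[f"$P{i}R"] = f"{rng:.6g}"
        parts = [_DELIM]
        for k, v in kv.items():
            parts.append(k.encode("ascii") + _DELIM + v.encode("ascii") + _DELIM)
        return b"".join(parts)

    # $BEGINDATA/$ENDDATA are zero-padded to fixed width, so the TEXT length
    # does not change when the real offsets are substituted.
    probe = text_segment(0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(probe) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text = text_segment(data_begin, data_end)
    assert len(text) == len(probe)

    def off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:  # offsets too large for the header slot -> TEXT only
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_begin) + off(text_end) + \
        off(data_begin) + off(data_end) + off(0) + off(0)
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header + text + data)


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1]
    tokens = raw[1:].split(delim)
    if tokens and tokens[-1] == b"":
        tokens = tokens[:-1]
    kv = {}
    for i in range(0, len(tokens) - 1, 2):
        kv[tokens[i].decode("ascii", "replace").strip()] = \
            tokens[i + 1].decode("ascii", "replace")
    return kv

def read_fcs(path):
    """Read a float list-mode FCS file.

    Returns ``(names, data, text)`` with ``data`` an (events, parameters)
    float32 array and ``text`` the raw keyword dictionary.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw[:3] == b"FCS":
        raise ValueError("not an FCS file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = _parse_text(raw[text_begin:text_end + 1])

    data_begin = int(text.get("$BEGINDATA") or raw[26:34])
    data_end = int(text.get("$ENDDATA") or raw[34:42])
    if text.get("$DATATYPE") != "F":
        raise ValueError(f"unsupported $DATATYPE {text.get('$DATATYPE')!r} (float only)")
    if text.get("$MODE", "L") != "L":
        raise ValueError("only list mode ($MODE L) is supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    byteord = text.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord.startswith("1") else ">f4"
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    buf = raw[data_begin:data_end + 1]
    data = np.frombuffer(buf, dtype=dtype, count=n_par * n_tot).reshape(n_tot, n_par)
    return names, data.astype(np.float32), text
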