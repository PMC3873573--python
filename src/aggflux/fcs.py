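"""Minimal FCS 3.1 reader/writer for the cytometry event tables.

Writes list-mode, little-endian float32 data with one parameter per pulse
feature (``$PnN`` names like ``BV421-H`` / ``BV421-A`` / ``BV421-W``) and no
spillover.  Simulator truth labels are never stored in the FCS file itself;
:func:`write_fcs` places them in a sidecar CSV keyed by event index, so
downstream gating cannot accidentally depend on them.

The reader handles float (``$DATATYPE F``) and unsigned-integer
(``$DATATYPE I``) dialects in either byte order and checks the event count
against ``$TOT``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs", "TRUTH_SIDECAR_SUFFIX"]

TRUTH_SIDECAR_SUFFIX = ".truth.csv"
_DELIM = b"/"


def _pulse_columns(events: pd.DataFrame) -> list[str]:
    return [c for c in events.columns if not c.startswith("truth_")]


def write_fcs(events: pd.DataFrame, path) -> Path:
    """Write events as FCS 3.1 (float32, little-endian); truth to a sidecar.

    Returns the FCS path.  An empty event table produces a valid 0-event
    file.
    """
    path = Path(path)
    cols = _pulse_columns(events)
    data = events[cols].to_numpy(dtype="<f4")
    n_tot, n_par = data.shape
    payload = data.tobytes()

    keywords = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
    }
    for i, name in enumerate(cols, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        rng = float(events[name].max()) if n_tot else 1.0
        keywords[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)

    # data offsets appear inside TEXT: fix their width, then resolve
    for _ in range(2):
        text = _DELIM
        kw = dict(keywords)
        kw.setdefault("$BEGINDATA", "0" * 10)
        kw.setdefault("$ENDDATA", "0" * 10)
        for k, v in kw.items():
            text += k.encode() + _DELIM + str(v).encode() + _DELIM
        text_begin = 58
        text_end = text_begin + len(text) - 1
        data_begin = text_end + 1
        data_end = data_begin + len(payload) - 1 if payload else 0
        keywords["$BEGINDATA"] = f"{data_begin:010d}"
        keywords["$ENDDATA"] = f"{max(data_end, 0):010d}"

    header = b"FCS3.1    " + b"".join(
        f"{v:8d}".encode() for v in (text_begin, text_end, data_begin,
                                     max(data_end, 0), 0, 0))
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)

    truth_cols = [c for c in events.columns if c.startswith("truth_")]
    if truth_cols:
        sidecar = events[truth_cols].copy()
        sidecar.insert(0, "event_index", np.arange(len(events)))
        sidecar.to_csv(path.with_suffix(path.suffix + TRUTH_SIDECAR_SUFFIX),
                       index=False)
    return path


def read_fcs(path) -> tuple[pd.DataFrame, dict]:
    """Read an FCS 3.0/3.1 file; returns (event table, keyword metadata).

    Column names are the ``$PnN`` parameter names.  Raises on a ``$TOT``
    that disagrees with the DATA segment size and on missing width
    parameters for any channel that has height/area ones.
    """
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError("not an FCS 3.0/3.1 file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin:text_end + 1]
    delim = text[:1]
    parts = text[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    kw = {parts[i].decode(): parts[i + 1].decode()
          for i in range(0, len(parts) - 1, 2)}

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    _check_width_parameters(names)

    data_begin = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    payload = raw[data_begin:data_end + 1] if n_tot else b""

    little = kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4"
    order = "<" if little else ">"
    dtype = kw.get("$DATATYPE", "F")
    if dtype == "F":
        itemsize = 4
        np_dtype = f"{order}f4"
    elif dtype == "D":
        itemsize = 8
        np_dtype = f"{order}f8"
    elif dtype == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (16, 32):
            raise ValueError("only uniform 16/32-bit integer data supported")
        itemsize = next(iter(bits)) // 8
        np_dtype = f"{order}u{itemsize}"
    else:
        raise ValueError(f"unsupported $DATATYPE {dtype!r}")

    expected = n_tot * n_par * itemsize
    if len(payload) < expected:
        raise ValueError(
            f"$TOT={n_tot} disagrees with DATA segment "
            f"({len(payload)} bytes, expected {expected})")
    values = np.frombuffer(payload[:expected], dtype=np_dtype)
    table = pd.DataFrame(values.reshape(n_tot, n_par), columns=names)
    table.index.name = "event_index"
    return table, kw


def _check_width_parameters(names: list[str]) -> None:
    channels = {}
    for n in names:
        if n.endswith(("-H", "-A", "-W")):
            channels.setdefault(n[:-2], set()).add(n[-1])
    for ch, feats in channels.items():
        if {"H", "A"} <= feats and "W" not in feats:
            raise ValueError(
                f"channel {ch!r} lacks a pulse width parameter "
                f"({ch}-W); pulse-shape analysis needs it")
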