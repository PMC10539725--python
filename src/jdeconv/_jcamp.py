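"""Minimal JCAMP-DX 1D reader/writer.

Covers what NMR spectra in the wild actually use for single blocks:
``##XYDATA=(X++(Y..Y))`` tables in AFFN (plain numbers) and in the ASDF
squeezed forms SQZ, DIF and DUP. Writing emits uncompressed AFFN only, for
maximal interoperability. The frequency axis is reconstructed from
FIRSTX/LASTX/NPOINTS (times XFACTOR) and ``.OBSERVE FREQUENCY`` is carried
through when present.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["read_jcampdx", "write_jcampdx"]

_SQZ = {c: v for v, c in enumerate("@ABCDEFGHI")}
_SQZ.update({c: -(v + 1) for v, c in enumerate("abcdefghi")})
_DIF = {"%": 0}
_DIF.update({c: v + 1 for v, c in enumerate("JKLMNOPQR")})
_DIF.update({c: -(v + 1) for v, c in enumerate("jklmnopqr")})
_DUP = {c: v + 1 for v, c in enumerate("STUVWXYZs")}

# AFFN numbers inside data tables must not use exponential notation: the
# letter E is an SQZ pseudo-digit, so "1.0E5" would be ambiguous (the
# JCAMP-DX standard forbids exponents in tables for exactly this reason)
_TOKEN = re.compile(
    r"[@A-Ia-i%J-Rj-rS-Zs][0-9]*(?:\.[0-9]+)?"  # pseudo-digit token
    r"|[+-]?[0-9]+(?:\.[0-9]+)?"  # AFFN number, fixed notation only
)


def _decode_token(tok: str, prev_y: Optional[float], last_action) -> Tuple[List[float], tuple]:
    """Decode one ASDF token into y values.

    ``last_action`` is ("value", v) or ("diff", d), used by DUP tokens.
    Returns the produced values and the new last_action.
    """
    head = tok[0]
    if head in _SQZ:
        v = float(_SQZ[head]) if len(tok) == 1 else float(
            f"{'-' if _SQZ[head] < 0 else ''}{abs(_SQZ[head])}{tok[1:]}"
        )
        return [v], ("value", v)
    if head in _DIF:
        if prev_y is None:
            raise ValueError("DIF token with no preceding ordinate")
        d = float(_DIF[head]) if len(tok) == 1 else float(
            f"{'-' if _DIF[head] < 0 else ''}{abs(_DIF[head])}{tok[1:]}"
        )
        return [prev_y + d], ("diff", d)
    if head in _DUP:
        count = int(_DUP[head]) if len(tok) == 1 else int(f"{_DUP[head]}{tok[1:]}")
        if last_action is None:
            raise ValueError("DUP token with no preceding datum")
        kind, val = last_action
        out = []
        y = prev_y
        for _ in range(count - 1):
            y = y + val if kind == "diff" else val
            out.append(y)
        return out, last_action
    v = float(tok)
    return [v], ("value", v)


def _parse_xydata(lines: List[str]) -> Tuple[List[float], List[float]]:
    xs: List[float] = []
    ys: List[float] = []
    line_ended_in_dif = False
    for line in lines:
        line = line.split("$$")[0].strip()
        if not line:
            continue
        tokens = _TOKEN.findall(line)
        if not tokens:
            continue
        xs.append(float(tokens[0]))
        action = None
        first = True
        for tok in tokens[1:]:
            prev = ys[-1] if ys else None
            produced, action = _decode_token(tok, prev, action)
            if first and line_ended_in_dif and ys:
                # in DIF form the first ordinate of a line is a checkpoint
                # repeating the previous line's last value; drop it
                first = False
                continue
            ys.extend(produced)
            first = False
        line_ended_in_dif = action is not None and action[0] == "diff"
    return xs, ys


def read_jcampdx(path: str) -> Dict:
    """Parse a single-block JCAMP-DX file with an (X++(Y..Y)) table.

    Returns a dict with ``y`` (numpy array, YFACTOR applied), ``firstx``,
    ``lastx``, ``npoints`` (XFACTOR applied) and ``observe_mhz`` (or None).
    """
    header: Dict[str, str] = {}
    data_lines: List[str] = []
    in_data = False
    with open(path, "r") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("##"):
                in_data = False
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.split("$$")[0].strip()
                header[key] = value
                if key == "XYDATA":
                    if "(X++(Y..Y))" not in value.replace(" ", ""):
                        raise ValueError(f"unsupported XYDATA form {value!r}")
                    in_data = True
            elif in_data:
                data_lines.append(line)

    if "XYDATA" not in header:
        raise ValueError("no ##XYDATA record found")
    xfactor = float(header.get("XFACTOR", "1") or 1)
    yfactor = float(header.get("YFACTOR", "1") or 1)
    npoints = int(float(header["NPOINTS"])) if "NPOINTS" in header else None
    # FIRSTX/LASTX are true axis values; XFACTOR applies to table abscissae only
    firstx = float(header["FIRSTX"])
    lastx = float(header["LASTX"]) if "LASTX" in header else None

    _, ys = _parse_xydata(data_lines)
    y = np.asarray(ys, dtype=float) * yfactor
    if npoints is not None and y.size != npoints:
        raise ValueError(f"decoded {y.size} ordinates but NPOINTS = {npoints}")

    observe = None
    for key in (".OBSERVEFREQUENCY", "$OBSERVEFREQUENCY"):
        if key in header:
            observe = float(header[key].split()[0])
            break

    return {
        "y": y,
        "firstx": firstx,
        "lastx": lastx,
        "npoints": y.size,
        "observe_mhz": observe,
        "xunits": header.get("XUNITS", "HZ").upper(),
        "title": header.get("TITLE", ""),
    }


def write_jcampdx(
    path: str,
    y: np.ndarray,
    firstx: float,
    lastx: float,
    observe_mhz: Optional[float] = None,
    title: str = "jdeconv spectrum",
    per_line: int = 6,
) -> None:
    """Write a single-block uncompressed AFFN (X++(Y..Y)) JCAMP-DX file."""
    y = np.asarray(y, dtype=float)
    n = y.size
    firstx, lastx = float(firstx), float(lastx)
    step = (lastx - firstx) / (n - 1)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=5.01",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        "##XUNITS=HZ",
        "##YUNITS=ARBITRARY UNITS",
    ]
    if observe_mhz is not None:
        lines.append(f"##.OBSERVE FREQUENCY={float(observe_mhz)!r}")
    lines += [
        f"##FIRSTX={firstx!r}",
        f"##LASTX={lastx!r}",
        f"##NPOINTS={n}",
        f"##FIRSTY={float(y[0])!r}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, n, per_line):
        chunk = y[i : i + per_line]
        x = firstx + i * step
        # fixed-point only: exponential notation is not legal in the table
        lines.append(" ".join([f"{x:.6f}"] + [f"{v:.15f}" for v in chunk]))
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
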