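"""Reading and writing labeled spectra sets.

Primary format is delimited text: a header row carrying the ppm axis, then
one row per sample with ``sample_id``, ``label`` and the intensities.  A
minimal JCAMP-DX reader (AFFN ``(X++(Y..Y))`` tables only) assembles a set
from a directory of single-spectrum files.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LabeledSpectraSet

_ID_COL, _LABEL_COL = "sample_id", "label"


def write_spectra(spectra: LabeledSpectraSet, path, sep: str = ",") -> None:
    df = pd.DataFrame(spectra.X,
                      columns=[str(float(v)) for v in spectra.ppm])
    df.insert(0, _LABEL_COL, spectra.labels)
    df.insert(0, _ID_COL, spectra.patient_ids)
    df.to_csv(path, sep=sep, index=False)


def read_spectra(path, sep: str = ",") -> LabeledSpectraSet:
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spectra file {path}: {exc}") from exc
    for col in (_ID_COL, _LABEL_COL):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing required column {col!r}; the format needs "
                f"columns [{_ID_COL}, {_LABEL_COL}, <ppm values...>]"
            )
    ids = df[_ID_COL].astype(str).to_numpy(dtype=object)
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate sample_id(s): "
            f"{sorted(set(ids[dup.to_numpy()]))}"
        )
    labels = df[_LABEL_COL].astype(str).to_numpy(dtype=object)
    value_cols = [c for c in df.columns if c not in (_ID_COL, _LABEL_COL)]
    try:
        ppm = np.asarray([float(c) for c in value_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric ppm header: {exc}") from exc
    values = df[value_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for i in range(values.shape[0]):
            try:
                np.asarray(values[i], dtype=float)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric intensity in row for sample "
                    f"{ids[i]!r}"
                ) from None
    return LabeledSpectraSet(ppm=ppm, X=values.astype(float), labels=labels,
                             patient_ids=ids)


# --------------------------------------------------------------------------
# minimal JCAMP-DX

_LDR = re.compile(r"^##(?P<key>[^=]+)=\s*(?P<value>.*)$")


def read_jcampdx(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read one JCAMP-DX spectrum (AFFN ``(X++(Y..Y))`` data tables only).

    Returns (x, y, header).  x is converted with XFACTOR and returned
    ascending; DIF/DUP/SQZ compressed forms are not supported.
    """
    header: dict = {}
    ys: list[float] = []
    in_table = False
    for raw in Path(path).read_text().splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            key = m.group("key").strip().upper()
            header[key] = m.group("value").strip()
            in_table = key == "XYDATA"
            if in_table and "(X++(Y..Y))" not in header[key].replace(" ", ""):
                raise ValueError(f"{path}: only (X++(Y..Y)) XYDATA supported")
            continue
        if in_table:
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unsupported or compressed XYDATA line "
                    f"{line!r}"
                ) from exc
            ys.extend(vals[1:])  # first value is the line's X check value
    if not ys:
        raise ValueError(f"{path}: no XYDATA table found")
    n = int(float(header.get("NPOINTS", len(ys))))
    if len(ys) != n:
        raise ValueError(f"{path}: NPOINTS={n} but {len(ys)} Y values read")
    firstx = float(header["FIRSTX"])
    lastx = float(header["LASTX"])
    yfactor = float(header.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, n)
    y = np.asarray(ys, dtype=float) * yfactor
    if x[0] > x[-1]:
        x, y = x[::-1].copy(), y[::-1].copy()
    return x, y, header


def read_jcampdx_dir(directory, label_key: str = "$CLASS") -> LabeledSpectraSet:
    """Assemble a LabeledSpectraSet from a directory of JCAMP-DX files.

    The class label is taken from the ``##$CLASS=`` record, else from the
    filename suffix after a double underscore (``<id>__<label>.dx``); the
    sample id is the filename stem.  All files must share one ppm axis.
    """
    files = sorted(p for p in Path(directory).iterdir()
                   if p.suffix.lower() in (".dx", ".jdx", ".jcamp"))
    if not files:
        raise ValueError(f"no JCAMP-DX files (*.dx, *.jdx) in {directory}")
    axis = None
    rows, labels, ids = [], [], []
    for path in files:
        x, y, header = read_jcampdx(path)
        if axis is None:
            axis = x
        elif x.size != axis.size or not np.allclose(x, axis):
            raise ValueError(f"{path}: ppm axis differs from {files[0]}")
        stem = path.stem
        label = header.get(label_key.upper(), "")
        if not label and "__" in stem:
            label = stem.rsplit("__", 1)[1]
        if not label:
            raise ValueError(
                f"{path}: no class label (##{label_key}= record or "
                f"'<id>__<label>' filename)"
            )
        rows.append(y)
        labels.append(label)
        ids.append(stem)
    return LabeledSpectraSet(ppm=axis, X=np.vstack(rows),
                             labels=np.array(labels, dtype=object),
                             patient_ids=np.array(ids, dtype=object))
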