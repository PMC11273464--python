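"""Minimal reader/writer for the dense Weka ARFF dialect.

Supports ``@relation``, ``@attribute NAME numeric|real|integer`` and
``@attribute NAME {a,b,c}`` declarations, comma-separated ``@data`` rows,
quoted values, and ``?`` as the missing marker.  Sparse rows, date/string
attributes and per-instance weights are out of scope.
"""

from __future__ import annotations

import io
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datasets import FeatureSpec, LabelSpec, MultiLabelDataset

__all__ = ["read_arff_dataset", "write_arff_dataset"]

_ATTR_RE = re.compile(r"@attribute\s+(?:'([^']+)'|\"([^\"]+)\"|(\S+))\s+(.+)", re.IGNORECASE)


class ArffError(ValueError):
    pass


def _split_csv_line(line: str) -> list[str]:
    """Split one @data line on commas, honouring single/double quotes."""
    out, buf, quote = [], [], None
    for ch in line:
        if quote:
            if ch == quote:
                quote = None
            else:
                buf.append(ch)
        elif ch in "'\"":
            quote = ch
        elif ch == ",":
            out.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    if quote:
        raise ArffError(f"unterminated quote in data line: {line!r}")
    out.append("".join(buf).strip())
    return out


def _parse(text: str) -> tuple[str, list[tuple[str, tuple[str, ...] | None]], list[list[str]]]:
    relation = "dataset"
    attrs: list[tuple[str, tuple[str, ...] | None]] = []
    data: list[list[str]] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if in_data:
            values = _split_csv_line(line)
            if len(values) != len(attrs):
                raise ArffError(
                    f"data row has {len(values)} values, expected {len(attrs)}: {line!r}"
                )
            data.append(values)
        elif low.startswith("@relation"):
            relation = line.split(None, 1)[1].strip().strip("'\"") if " " in line else relation
        elif low.startswith("@attribute"):
            m = _ATTR_RE.match(line)
            if not m:
                raise ArffError(f"malformed attribute line: {line!r}")
            name = next(g for g in m.groups()[:3] if g is not None)
            spec = m.group(4).strip()
            if spec.startswith("{"):
                if not spec.endswith("}"):
                    raise ArffError(f"malformed nominal spec: {line!r}")
                cats = tuple(v.strip().strip("'\"") for v in _split_csv_line(spec[1:-1]))
                attrs.append((name, cats))
            elif spec.lower() in ("numeric", "real", "integer"):
                attrs.append((name, None))
            else:
                raise ArffError(f"unsupported attribute type {spec!r}")
        elif low.startswith("@data"):
            if not attrs:
                raise ArffError("@data before any @attribute")
            in_data = True
        else:
            raise ArffError(f"unrecognised header line: {line!r}")
    if not in_data:
        raise ArffError("no @data section")
    return relation, attrs, data


def read_arff_dataset(
    path,
    label_names: Iterable[str],
    positives: dict[str, str] | None = None,
    ordinal_features: Iterable[str] = (),
) -> MultiLabelDataset:
    """Read an ARFF file, treating ``label_names`` (nominal attributes) as
    the labels in their file order.

    ``positives`` optionally names the "present" class of binary labels
    (default: the last declared class).  ``ordinal_features`` lists nominal
    attributes whose declared category order is a rank order.
    """
    label_names = list(label_names)
    positives = positives or {}
    ordinal = set(ordinal_features)
    with open(path) as fh:
        relation, attrs, data = _parse(fh.read())

    names = [a[0] for a in attrs]
    for lab in label_names:
        if lab not in names:
            raise ArffError(f"label attribute {lab!r} not in file")

    feats: list[FeatureSpec] = []
    labels: list[LabelSpec] = []
    xcols: dict[str, pd.Series] = {}
    ycols: dict[str, pd.Series] = {}
    for j, (name, cats) in enumerate(attrs):
        col = pd.Series([row[j] for row in data], dtype=object)
        is_missing = col == "?"
        if name in label_names:
            if cats is None:
                raise ArffError(f"label attribute {name!r} must be nominal")
            if bool(is_missing.any()):
                raise ArffError(f"label {name!r} has missing values")
            positive = positives.get(name) if len(cats) == 2 else None
            labels.append(LabelSpec(name, cats, positive))
            ycols[name] = col.astype(str)
        elif cats is None:
            feats.append(FeatureSpec(name, "numeric"))
            xcols[name] = pd.to_numeric(col.where(~is_missing, other=None)).astype(float)
        else:
            kind = "ordinal" if name in ordinal else "nominal"
            feats.append(FeatureSpec(name, kind, cats))
            xcols[name] = col.where(~is_missing, other=None)

    labels.sort(key=lambda l: label_names.index(l.name))
    X = pd.DataFrame({f.name: xcols[f.name] for f in feats})
    Y = pd.DataFrame({l.name: ycols[l.name] for l in labels})
    return MultiLabelDataset(relation, tuple(feats), tuple(labels), X, Y)


def _fmt_value(v, numeric: bool) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "?"
    if numeric:
        f = float(v)
        return repr(int(f)) if f.is_integer() else repr(f)
    s = str(v)
    if any(c in s for c in " ,{}%"):
        return f"'{s}'"
    return s


def write_arff_dataset(dataset: MultiLabelDataset, path) -> None:
    """Write input features and labels (extras are dropped) as dense ARFF.

    Values round-trip losslessly through :func:`read_arff_dataset` apart
    from feature roles and ordinal flags, which ARFF cannot express.
    """
    buf = io.StringIO()
    buf.write(f"@relation {_fmt_value(dataset.name, False)}\n\n")
    cols: list[tuple[str, bool]] = []
    for f in dataset.features:
        if f.kind == "numeric":
            buf.write(f"@attribute {_fmt_value(f.name, False)} numeric\n")
            cols.append((f.name, True))
        else:
            cats = ",".join(_fmt_value(c, False) for c in f.categories)
            buf.write(f"@attribute {_fmt_value(f.name, False)} {{{cats}}}\n")
            cols.append((f.name, False))
    for l in dataset.labels:
        cats = ",".join(_fmt_value(c, False) for c in l.classes)
        buf.write(f"@attribute {_fmt_value(l.name, False)} {{{cats}}}\n")
    buf.write("\n@data\n")
    Xn = dataset.X
    Yn = dataset.Y
    for i in range(dataset.n_samples):
        parts = [_fmt_value(Xn[name].iloc[i], numeric) for name, numeric in cols]
        parts += [_fmt_value(Yn[l.name].iloc[i], False) for l in dataset.labels]
        buf.write(",".join(parts) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
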