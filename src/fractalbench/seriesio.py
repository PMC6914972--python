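"""Plain-text series files.

A series file is one value per line at full double precision, optionally
preceded by ``#``-prefixed metadata lines (generator, target_alpha, seed, n)
and optionally in two-column ``index,value`` CSV form.  Text was chosen over
binary containers deliberately: the series are short and a methods toolbox
benefits from being diffable and human-inspectable.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .generators import Series

__all__ = ["read_series", "write_series"]

_META_KEYS = ("generator", "target_alpha", "seed", "n")


def write_series(s: Series, path: str | os.PathLike) -> None:
    """Write a series with its provenance header; 17 significant digits."""
    lines = [f"# generator: {s.generator}"]
    if s.target_alpha is not None:
        lines.append(f"# target_alpha: {s.target_alpha!r}")
    if s.seed is not None:
        lines.append(f"# seed: {s.seed}")
    lines.append(f"# n: {s.n}")
    lines.extend(f"{v:.17g}" for v in s.values)
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write series to {path!r}: {exc}") from exc


def read_series(path: str | os.PathLike) -> Series:
    """Read a series file written by :func:`write_series` or any one-column
    (or ``index,value`` two-column) numeric text file."""
    meta: dict[str, str] = {}
    values: list[float] = []
    try:
        with open(path) as fh:
            raw_lines = fh.readlines()
    except OSError as exc:
        raise OSError(f"cannot read series from {path!r}: {exc}") from exc
    for lineno, line in enumerate(raw_lines, start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith("#"):
            body = text.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                if key.strip() in _META_KEYS:
                    meta[key.strip()] = val.strip()
            continue
        fields = text.split(",") if "," in text else text.split()
        try:
            value = float(fields[-1])
        except ValueError:
            # a header row like "index,value" is tolerated once at the top
            if not values and not all(_is_number(f) for f in fields):
                continue
            raise ValueError(
                f"{path}:{lineno}: non-numeric value {fields[-1]!r}"
            ) from None
        if not np.isfinite(value):
            raise ValueError(f"{path}:{lineno}: non-finite value {text!r}")
        values.append(value)
    if len(values) < 2:
        raise ValueError(f"{path}: fewer than 2 numeric values")
    return Series(
        np.array(values),
        generator=meta.get("generator", "external"),
        target_alpha=_maybe_float(meta.get("target_alpha")),
        seed=_maybe_int(meta.get("seed")),
    )


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def _maybe_float(text: Optional[str]) -> Optional[float]:
    return None if text in (None, "None", "") else float(text)


def _maybe_int(text: Optional[str]) -> Optional[int]:
    return None if text in (None, "None", "") else int(text)
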