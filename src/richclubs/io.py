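"""Edge-list and curve file formats.

Edge lists are the sole required interchange format: one link per line,
``source target [weight]`` separated by whitespace (or an explicit
delimiter), ``#`` starting a comment.  Unweighted input assigns weight
1 to every link.  Validation is strict -- self-loops, duplicate pairs
and non-positive weights are errors with line numbers, never silently
coerced -- because both E and C change if duplicates were aggregated.

Curves are written as tab-separated tables with a commented header
recording the control kind, ensemble size, seed, significance level and
tool version.  Floats are formatted with 17 significant digits so a
read-back reproduces every numeric field exactly.  Undefined values are
the literal string ``NA`` (not empty cells, which spreadsheet tools
mangle).
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .curves import RichClubCurve
from .graph import NetworkError, WeightedNetwork

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_richness_file",
    "write_curve",
    "read_curve",
    "EdgeListError",
]

PathLike = Union[str, Path]

CURVE_COLUMNS = (
    "threshold",
    "N",
    "E",
    "C",
    "c_rand_mean",
    "phi_norm",
    "p_value",
    "significant",
)


class EdgeListError(NetworkError):
    """Malformed edge-list input, reported with file/line context."""


def _fields(line: str, delimiter: str | None) -> list[str]:
    body = line.split("#", 1)[0]
    return body.split(delimiter) if delimiter else body.split()


def read_edgelist(
    path: PathLike,
    weighted: bool = True,
    delimiter: str | None = None,
    nodes_path: PathLike | None = None,
) -> WeightedNetwork:
    """Parse a whitespace/``delimiter``-separated edge list.

    Expects 2 columns per line (unweighted; weight 1 assigned) or 3
    (weighted).  ``nodes_path`` optionally names a one-column node list
    so isolated nodes can be declared.  An empty file yields an empty
    network with a warning.
    """
    path = Path(path)
    records: list[tuple[str, str, float]] = []
    seen: dict[tuple[str, str], int] = {}
    want = 3 if weighted else 2
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = _fields(raw, delimiter)
            if not fields:
                continue
            if len(fields) < want:
                raise EdgeListError(
                    f"{path}:{lineno}: expected {want} columns, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if u == v:
                raise EdgeListError(f"{path}:{lineno}: self-loop on node {u!r}")
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise EdgeListError(
                    f"{path}:{lineno}: duplicate link {u!r}-{v!r} "
                    f"(first seen at line {seen[key]})"
                )
            seen[key] = lineno
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise EdgeListError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
                if not (np.isfinite(w) and w > 0):
                    raise EdgeListError(
                        f"{path}:{lineno}: weight must be positive and finite, got {w}"
                    )
            else:
                w = 1.0
            records.append((u, v, w))
    extra: list[str] = []
    if nodes_path is not None:
        with Path(nodes_path).open() as fh:
            for raw in fh:
                fields = _fields(raw, delimiter)
                if fields:
                    extra.append(fields[0])
    if not records and not extra:
        warnings.warn(f"{path}: empty edge list; returning an empty network")
    return WeightedNetwork.from_edges(records, extra_nodes=extra)


def write_edgelist(net: WeightedNetwork, path: PathLike, weighted: bool = True) -> None:
    """Write one ``source<TAB>target[<TAB>weight]`` line per link."""
    path = Path(path)
    with path.open("w") as fh:
        for (u, v), w in zip(net.edge_labels(), net.weights):
            if weighted:
                fh.write(f"{u}\t{v}\t{format(float(w), '.17g')}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_richness_file(
    path: PathLike, delimiter: str | None = None
) -> dict[str, float]:
    """Two-column ``node value`` file -> custom richness mapping.

    Same comment/delimiter dialect as edge lists.
    """
    path = Path(path)
    out: dict[str, float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = _fields(raw, delimiter)
            if not fields:
                continue
            if len(fields) < 2:
                raise EdgeListError(f"{path}:{lineno}: expected 2 columns")
            node = fields[0]
            if node in out:
                raise EdgeListError(f"{path}:{lineno}: duplicate node {node!r}")
            try:
                out[node] = float(fields[1])
            except ValueError:
                raise EdgeListError(
                    f"{path}:{lineno}: non-numeric richness {fields[1]!r}"
                ) from None
    return out


def _fmt(x: float) -> str:
    return "NA" if np.isnan(x) else format(float(x), ".17g")


def write_curve(curve: RichClubCurve, path: PathLike) -> None:
    """Serialize a :class:`~richclubs.curves.RichClubCurve` to TSV."""
    from . import __version__

    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# richclubs {__version__}\n")
        fh.write(f"# control_kind: {curve.kind}\n")
        fh.write(f"# n_rand: {curve.n_rand}\n")
        fh.write(f"# seed: {curve.seed}\n")
        fh.write(f"# alpha: {format(curve.alpha, '.17g')}\n")
        fh.write("\t".join(CURVE_COLUMNS) + "\n")
        for j in range(curve.thresholds.size):
            undef = np.isnan(curve.phi_norm[j])
            sig = "NA" if np.isnan(curve.p_value[j]) else str(bool(curve.significant[j])).lower()
            row = [
                _fmt(curve.thresholds[j]),
                str(int(curve.N[j])),
                str(int(curve.E[j])),
                _fmt(curve.C[j]),
                _fmt(curve.c_rand_mean[j]),
                _fmt(curve.phi_norm[j]) if not undef else "NA",
                _fmt(curve.p_value[j]),
                sig,
            ]
            fh.write("\t".join(row) + "\n")


def read_curve(path: PathLike) -> pd.DataFrame:
    """Read a curve TSV back into a DataFrame (NA -> NaN / pandas NA)."""
    df = pd.read_csv(
        Path(path),
        sep="\t",
        comment="#",
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
        dtype={"significant": "string"},
    )
    if list(df.columns) != list(CURVE_COLUMNS):
        raise EdgeListError(f"{path}: unexpected curve columns {list(df.columns)}")
    # unmapped entries (the NA marker) stay missing
    df["significant"] = df["significant"].map({"true": True, "false": False})
    return df
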