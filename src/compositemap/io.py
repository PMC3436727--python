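"""Plain-text readers and writers for linkage maps and merge artifacts.

Canonical on-disk map format is a 4-column TSV (``linkage_group``, ``marker``,
``position``, ``marker_type``); the reader additionally tolerates comma
delimiters, CRLF line endings, ``#`` comment lines and a missing type column
(defaulting to DArT, the dominant marker technology on these maps).  The
writer always emits tab-delimited LF text so outputs are byte-reproducible.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .model import (
    ComponentMap,
    CompositeLocus,
    CompositeMap,
    MapFormatError,
    MarkerLocus,
    normalize_marker_type,
)

__all__ = [
    "read_component_map",
    "write_component_map",
    "read_composite_map",
    "write_composite_map",
    "write_merge_log",
]

_MAP_HEADER = ("linkage_group", "marker", "position", "marker_type")
_COMPOSITE_HEADER = (
    "linkage_group",
    "marker",
    "position",
    "marker_type",
    "support",
    "n_support",
    "multicopy",
    "added_in_round",
)
_LOG_HEADER = (
    "building_lg",
    "round",
    "component_map",
    "component_lg",
    "n_common",
    "rho",
    "orientation",
    "fit_value",
    "slope",
    "intercept",
    "residual_rmse",
    "markers_added",
    "markers_skipped",
)


def _data_lines(path: Path) -> list[tuple[int, str]]:
    lines = []
    with open(path, "r", newline="") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lines.append((i, line))
    if not lines:
        raise MapFormatError(f"{path}: empty map file")
    return lines


def _split(line: str) -> list[str]:
    delim = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(delim)]


def _is_header(fields: list[str]) -> bool:
    if len(fields) < 3:
        return True
    try:
        float(fields[2])
        return False
    except ValueError:
        return True


def read_component_map(
    path: str | Path,
    map_id: str | None = None,
    family_size: int | None = None,
) -> ComponentMap:
    """Read a component linkage map from a TSV/CSV file.

    Loci are sorted by position within each LG; positions are preserved
    verbatim (no shift of the per-LG minimum to 0 is applied on read).

    Raises :class:`MapFormatError` on duplicate (marker, LG) rows, negative or
    unparseable positions (with the offending line number) and empty files.
    """
    path = Path(path)
    if map_id is None:
        map_id = path.stem
    lines = _data_lines(path)
    if _is_header(_split(lines[0][1])):
        lines = lines[1:]
        if not lines:
            raise MapFormatError(f"{path}: no data rows")

    groups: dict[str, list[MarkerLocus]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, line in lines:
        fields = _split(line)
        if len(fields) < 3:
            raise MapFormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
        lg, name = fields[0], fields[1]
        try:
            position = float(fields[2])
        except ValueError:
            raise MapFormatError(
                f"{path}:{lineno}: unparseable position {fields[2]!r}"
            ) from None
        if position < 0:
            raise MapFormatError(f"{path}:{lineno}: negative position {position}")
        if (name, lg) in seen:
            raise MapFormatError(f"{path}:{lineno}: duplicate locus {name!r} on LG {lg!r}")
        seen.add((name, lg))
        mtype = normalize_marker_type(fields[3] if len(fields) > 3 else None)
        groups.setdefault(lg, []).append(MarkerLocus(name, lg, position, mtype))

    for lg in groups:
        groups[lg].sort(key=lambda l: (l.position, l.name))
    return ComponentMap(map_id=map_id, linkage_groups=groups, family_size=family_size)


def write_component_map(cmap: ComponentMap, path: str | Path) -> None:
    """Write a component map in the canonical 4-column TSV dialect."""
    with open(Path(path), "w", newline="\n") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAP_HEADER)
        for lg, loci in cmap.linkage_groups.items():
            for locus in loci:
                w.writerow([lg, locus.name, repr(locus.position), locus.marker_type])


def write_composite_map(
    composite: CompositeMap,
    path: str | Path,
    format: str = "tsv",
    full_precision: bool = True,
) -> None:
    """Write a composite map.

    ``format="tsv"`` emits one row per composite position with provenance
    columns; with ``full_precision`` the write -> read round trip is exact,
    otherwise positions render at 0.1 cM reporting granularity.
    ``format="mapchart"`` emits MapChart-compatible chart text: one ``group``
    block per LG of name/position pairs.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="\n") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_COMPOSITE_HEADER)
            for lg, loci in composite.linkage_groups.items():
                for locus in loci:
                    pos = repr(locus.position) if full_precision else f"{locus.position:.1f}"
                    w.writerow(
                        [
                            lg,
                            locus.name,
                            pos,
                            locus.marker_type,
                            ",".join(sorted(locus.support)),
                            len(locus.support),
                            int(locus.is_multicopy),
                            locus.added_in_round,
                        ]
                    )
    elif format == "mapchart":
        with open(path, "w", newline="\n") as fh:
            for lg, loci in composite.linkage_groups.items():
                fh.write(f"group {lg}\n")
                for locus in loci:
                    fh.write(f"{locus.name} {locus.position:.1f}\n")
                fh.write("\n")
    else:
        raise ValueError(f"unknown composite map format {format!r}")


def read_composite_map(path: str | Path) -> CompositeMap:
    """Read a composite map written by :func:`write_composite_map` (tsv)."""
    path = Path(path)
    lines = _data_lines(path)
    header = _split(lines[0][1])
    if tuple(header) != _COMPOSITE_HEADER:
        raise MapFormatError(f"{path}: not a composite map TSV (unexpected header)")
    groups: dict[str, list[CompositeLocus]] = {}
    for lineno, line in lines[1:]:
        f = _split(line)
        if len(f) != len(_COMPOSITE_HEADER):
            raise MapFormatError(f"{path}:{lineno}: expected {len(_COMPOSITE_HEADER)} columns")
        lg = f[0]
        groups.setdefault(lg, []).append(
            CompositeLocus(
                name=f[1],
                linkage_group=lg,
                position=float(f[2]),
                marker_type=f[3],
                support=set(f[4].split(",")) if f[4] else set(),
                is_multicopy=bool(int(f[6])),
                added_in_round=int(f[7]),
            )
        )
    return CompositeMap(linkage_groups=groups)


def write_merge_log(composite: CompositeMap, path: str | Path) -> None:
    """Write the merge audit trail, one row per merge round, in build order."""
    with open(Path(path), "w", newline="\n") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_LOG_HEADER)
        for r in composite.merge_log:
            w.writerow(
                [
                    r.building_lg,
                    r.round_index,
                    r.component_map_id,
                    r.component_lg,
                    r.n_common,
                    f"{r.rho:.6f}",
                    r.orientation,
                    f"{r.fit_value:.6f}",
                    f"{r.slope:.6f}",
                    f"{r.intercept:.6f}",
                    f"{r.residual_rmse:.6f}",
                    r.markers_added,
                    r.markers_skipped,
                ]
            )
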