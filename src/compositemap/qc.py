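"""Composite-map validation surface.

Covers the quality checks run on the merged map: composite-vs-component
marker-order correlations, the per-LG summary table (lengths, marker counts
by type, unique loci, average marker intervals), the chi-square test of
whether multicopy DArT positions are spread evenly across linkage groups,
multicopy accounting and redundant-clone flagging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import find_shared_markers
from .model import ChiSquareResult, ComponentMap, CompositeMap, MarkerLocus
from .stats import spearman_rho

__all__ = [
    "correlation_table",
    "summary_table",
    "multicopy_chisquare",
    "multicopy_chisquare_from_composite",
    "MulticopyAccounting",
    "multicopy_accounting",
    "flag_redundant",
]


def _composite_lg_as_loci(composite: CompositeMap, lg: str) -> list[MarkerLocus]:
    return [
        MarkerLocus(l.name, lg, max(l.position, 0.0), l.marker_type)
        for l in composite.linkage_groups[lg]
    ]


def correlation_table(
    composite: CompositeMap,
    component_maps: list[ComponentMap],
    excluded_lgs: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Signed Spearman order correlations between each composite LG and the
    best-matching LG of each component map.

    For every (composite LG, component map) cell the component LG sharing the
    most markers is compared; cells with < 2 shared markers are undefined
    (NaN).  ``used_in_build`` marks pairs whose marker order actually entered
    the merge (from the merge log); ``excluded`` marks pairs ruled out by the
    colinearity pre-screen.  Row/column averages are computed only over
    defined cells (see the ``attrs`` of the returned frame).
    """
    excluded_lgs = excluded_lgs or set()
    used = {(r.component_map_id, r.component_lg, r.building_lg) for r in composite.merge_log}
    rows = []
    for lg in composite.linkage_groups:
        comp_loci = _composite_lg_as_loci(composite, lg)
        comp_names = {l.name for l in comp_loci}
        for cmap in component_maps:
            best_lg, best_shared = None, 0
            for clg, loci in cmap.linkage_groups.items():
                shared = sum(1 for l in loci if l.name in comp_names)
                if shared > best_shared:
                    best_lg, best_shared = clg, shared
            if best_lg is None:
                rows.append((lg, cmap.map_id, None, 0, np.nan, False, False))
                continue
            anchors = find_shared_markers(comp_loci, cmap.linkage_groups[best_lg])
            rho = spearman_rho(anchors.positions_a, anchors.positions_b)
            rows.append(
                (
                    lg,
                    cmap.map_id,
                    best_lg,
                    anchors.n,
                    np.nan if rho is None else rho,
                    (cmap.map_id, best_lg, lg) in used,
                    (cmap.map_id, best_lg) in excluded_lgs,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "composite_lg",
            "map_id",
            "component_lg",
            "n_common",
            "rho",
            "used_in_build",
            "excluded",
        ],
    )
    table.attrs["lg_averages"] = table.groupby("composite_lg")["rho"].mean().to_dict()
    used_only = table[table["used_in_build"]]
    table.attrs["lg_averages_used"] = used_only.groupby("composite_lg")["rho"].mean().to_dict()
    table.attrs["map_averages"] = table.groupby("map_id")["rho"].mean().to_dict()
    return table


def summary_table(composite: CompositeMap, position_decimals: int = 1) -> pd.DataFrame:
    """Per-LG summary: length, marker positions by type, unique loci and
    average marker interval, with a totals row.

    Co-located markers are collapsed at the reporting granularity
    (``position_decimals``, default 0.1 cM) when counting unique loci; the
    average interval is LG length / (unique loci - 1), and the totals-row
    interval is total length / (total unique loci - number of LGs).
    """
    rows = []
    for lg, loci in composite.linkage_groups.items():
        positions = [round(l.position, position_decimals) for l in loci]
        unique = len(set(positions))
        length = max((l.position for l in loci), default=0.0)
        counts = {"DArT": 0, "SSR": 0, "gene": 0, "other": 0}
        mc_dart = 0
        for l in loci:
            counts[l.marker_type] = counts.get(l.marker_type, 0) + 1
            if l.is_multicopy and l.marker_type == "DArT":
                mc_dart += 1
        interval = length / (unique - 1) if unique >= 2 else np.nan
        rows.append(
            {
                "lg": lg,
                "length_cm": length,
                "dart": counts["DArT"],
                "ssr": counts["SSR"],
                "gene": counts["gene"],
                "other": counts["other"],
                "total": len(loci),
                "unique_loci": unique,
                "avg_interval_cm": interval,
                "multicopy_dart": mc_dart,
            }
        )
    table = pd.DataFrame(rows).set_index("lg")
    totals = table.sum(numeric_only=True)
    n_lgs = len(table)
    denom = totals["unique_loci"] - n_lgs
    totals["avg_interval_cm"] = totals["length_cm"] / denom if denom > 0 else np.nan
    table.loc["Total"] = totals
    for col in ("dart", "ssr", "gene", "other", "total", "unique_loci", "multicopy_dart"):
        table[col] = table[col].astype(int)
    return table


def multicopy_chisquare(
    per_lg_dart_positions, per_lg_multicopy_positions
) -> ChiSquareResult:
    """Test whether multicopy DArT positions are evenly spread across LGs.

    The expected multicopy count for LG i is
    (total multicopy positions / total DArT positions) x DArT positions on
    LG i, i.e. proportional allocation by DArT content; the statistic is the
    usual sum of (obs - exp)^2 / exp with df = (number of LGs) - 1.
    Only DArT positions enter either side of the test.
    """
    dart = np.asarray(per_lg_dart_positions, dtype=float)
    mc = np.asarray(per_lg_multicopy_positions, dtype=float)
    if dart.size != mc.size:
        raise ValueError("per-LG count vectors must have equal length")
    if dart.size < 2:
        raise ValueError("chi-square test needs >= 2 linkage groups")
    if np.any(dart < 0) or np.any(mc < 0):
        raise ValueError("counts must be non-negative")
    expected = mc.sum() / dart.sum() * dart
    if np.any(expected == 0):
        raise ValueError("an expected count of 0 makes the statistic undefined")
    statistic = float(((mc - expected) ** 2 / expected).sum())
    df = int(dart.size - 1)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=float(sps.chi2.sf(statistic, df)),
        observed=mc.tolist(),
        expected=expected.tolist(),
    )


def multicopy_chisquare_from_composite(composite: CompositeMap) -> ChiSquareResult:
    """Run the multicopy test on per-LG counts taken from a composite map."""
    dart, mc = [], []
    for loci in composite.linkage_groups.values():
        dart.append(sum(1 for l in loci if l.marker_type == "DArT"))
        mc.append(sum(1 for l in loci if l.marker_type == "DArT" and l.is_multicopy))
    return multicopy_chisquare(dart, mc)


@dataclass
class MulticopyAccounting:
    """Position bookkeeping: total positions = distinct markers + extra copies."""

    n_distinct_markers: int
    n_multicopy_markers: int
    n_multicopy_positions: int
    n_total_positions: int
    copies_histogram: dict[int, int]  # copies -> number of markers

    def verify(self) -> None:
        extra = sum((c - 1) * n for c, n in self.copies_histogram.items() if c >= 2)
        assert self.n_total_positions == self.n_distinct_markers + extra
        assert self.n_multicopy_positions == sum(
            c * n for c, n in self.copies_histogram.items() if c >= 2
        )


def multicopy_accounting(composite: CompositeMap) -> MulticopyAccounting:
    copies = composite.copies_per_marker()
    hist: dict[int, int] = {}
    for c in copies.values():
        hist[c] = hist.get(c, 0) + 1
    multicopy = {m for m, c in copies.items() if c >= 2}
    acc = MulticopyAccounting(
        n_distinct_markers=len(copies),
        n_multicopy_markers=len(multicopy),
        n_multicopy_positions=sum(copies[m] for m in multicopy),
        n_total_positions=composite.n_positions,
        copies_histogram=dict(sorted(hist.items())),
    )
    acc.verify()
    return acc


def flag_redundant(
    composite: CompositeMap, tolerance_cm: float = 0.0
) -> list[set[str]]:
    """Flag candidate redundant markers (identical clones of one genomic
    fragment under different names).

    Two markers are linked when they share at least one LG and their
    positions coincide within ``tolerance_cm`` on *every* LG where both
    occur; groups are the connected components of that relation.  Flags are
    candidates for sequence-level follow-up, which is outside this package.
    """
    pos: dict[str, dict[str, float]] = {}
    for lg, loci in composite.linkage_groups.items():
        for l in loci:
            pos.setdefault(l.name, {})[lg] = l.position

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    def coincide_everywhere(a: str, b: str) -> bool:
        common = pos[a].keys() & pos[b].keys()
        return bool(common) and all(
            abs(pos[a][lg] - pos[b][lg]) <= tolerance_cm + 1e-12 for lg in common
        )

    for lg, loci in composite.linkage_groups.items():
        ordered = sorted(loci, key=lambda l: l.position)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                if b.position - a.position > tolerance_cm + 1e-12:
                    break
                if coincide_everywhere(a.name, b.name):
                    union(a.name, b.name)

    groups: dict[str, set[str]] = {}
    for name in parent:
        groups.setdefault(find(name), set()).add(name)
    return sorted((g for g in groups.values() if len(g) >= 2), key=lambda g: sorted(g)[0])
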