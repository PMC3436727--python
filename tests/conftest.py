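from __future__ import annotations

import pytest

from compositemap.model import ComponentMap, CompositeLocus, CompositeMap, MarkerLocus


def make_map(map_id: str, lgs: dict[str, list[tuple[str, float]]], family_size=None,
             marker_type: str = "DArT") -> ComponentMap:
    """Build a ComponentMap from {lg: [(marker, position), ...]} shorthand."""
    groups = {
        lg: sorted(
            (MarkerLocus(name, lg, pos, marker_type) for name, pos in loci),
            key=lambda l: (l.position, l.name),
        )
        for lg, loci in lgs.items()
    }
    return ComponentMap(map_id, groups, family_size)


def make_composite(lgs: dict[str, list[tuple[str, float, set[str]]]],
                   marker_type: str = "DArT") -> CompositeMap:
    """Build a CompositeMap from {lg: [(marker, position, support), ...]}."""
    groups = {
        lg: sorted(
            (
                CompositeLocus(name, lg, pos, marker_type, set(support))
                for name, pos, support in loci
            ),
            key=lambda l: (l.position, l.name),
        )
        for lg, loci in lgs.items()
    }
    comp = CompositeMap(linkage_groups=groups)
    comp.annotate_multicopy()
    return comp


@pytest.fixture
def toy_pair():
    """Two maps sharing 3 of 5 markers on LG1 and disjoint on LG2."""
    m1 = make_map(
        "M1",
        {
            "LG1": [("mA", 0.0), ("mB", 10.0), ("mC", 20.0), ("mD", 30.0), ("mE", 40.0)],
            "LG2": [("mF", 0.0), ("mG", 15.0)],
        },
        family_size=500,
    )
    m2 = make_map(
        "M2",
        {
            "LG1": [("mA", 0.0), ("mC", 11.0), ("mE", 21.0), ("mX", 25.0)],
            "LG2": [("mY", 0.0), ("mZ", 9.0)],
        },
        family_size=180,
    )
    return m1, m2
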