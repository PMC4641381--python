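"""Venn partition of per-comparison significant protein lists.

Each significant protein is assigned to exactly one region (the exact set
of comparisons where it is significant) and one regulation class: "up" or
"down" when every comparison agrees on direction, "contra" when any pair
disagrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

import pandas as pd

DIRECTIONS = ("up", "down")


@dataclass
class VennPartition:
    """Region and class assignment for the union of significant proteins."""

    comparisons: Tuple[str, ...]
    region_of: Dict[str, FrozenSet[str]]
    class_of: Dict[str, str]
    direction_of: Dict[str, Dict[str, str]]

    def region_counts(self) -> Dict[FrozenSet[str], int]:
        counts: Dict[FrozenSet[str], int] = {}
        for region in self.region_of.values():
            counts[region] = counts.get(region, 0) + 1
        return counts

    def to_json_dict(self) -> dict:
        regions: Dict[str, dict] = {}
        for protein in sorted(self.region_of):
            key = "&".join(sorted(self.region_of[protein]))
            entry = regions.setdefault(key, {"proteins": [], "classes": {}})
            entry["proteins"].append(protein)
            entry["classes"][protein] = self.class_of[protein]
        return {"comparisons": list(self.comparisons), "regions": regions}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)


def partition(sig: Mapping[str, pd.DataFrame]) -> VennPartition:
    """Build the Venn partition from per-comparison significant lists.

    ``sig`` maps comparison label -> frame with columns ``protein`` and
    ``direction`` (values "up"/"down"; anything else, including "none",
    is an input error).  Proteins must be unique within a list.
    """
    comparisons = tuple(sig)
    membership: Dict[str, Dict[str, str]] = {}
    for comparison, frame in sig.items():
        if frame["protein"].duplicated().any():
            raise ValueError(f"duplicate proteins in comparison {comparison!r}")
        for protein, direction in zip(frame["protein"], frame["direction"]):
            if direction not in DIRECTIONS:
                raise ValueError(
                    f"protein {protein!r} in {comparison!r} has direction "
                    f"{direction!r}; expected one of {DIRECTIONS}"
                )
            membership.setdefault(str(protein), {})[comparison] = direction

    region_of, class_of = {}, {}
    for protein, dirs in membership.items():
        region_of[protein] = frozenset(dirs)
        uniq = set(dirs.values())
        class_of[protein] = uniq.pop() if len(uniq) == 1 else "contra"
    return VennPartition(
        comparisons=comparisons,
        region_of=region_of,
        class_of=class_of,
        direction_of=membership,
    )


def common_coherent(part: VennPartition) -> List[Tuple[str, str]]:
    """Proteins significant in every comparison with one shared direction.

    Returns (protein, direction) pairs sorted by protein; contra-regulated
    proteins in the all-comparisons region are excluded.
    """
    full = frozenset(part.comparisons)
    out = [
        (protein, part.class_of[protein])
        for protein, region in part.region_of.items()
        if region == full and part.class_of[protein] != "contra"
    ]
    return sorted(out)


def unique_sets(part: VennPartition) -> Dict[str, List[Tuple[str, str]]]:
    """Singleton-region proteins per comparison, with direction."""
    out: Dict[str, List[Tuple[str, str]]] = {c: [] for c in part.comparisons}
    for protein, region in part.region_of.items():
        if len(region) == 1:
            (comparison,) = region
            out[comparison].append((protein, part.class_of[protein]))
    return {c: sorted(v) for c, v in out.items()}
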