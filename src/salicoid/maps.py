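"""Linkage-map container and TSV round-trip.

A linkage map is a set of named linkage groups, each an ordered list of
(marker, cM) pairs with non-decreasing cM.  The file format is a three-column
TSV: linkage_group, marker, cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import pandas as pd


@dataclass
class LinkageMap:
    #: group name -> list of (marker name, cM), sorted by cM
    groups: Dict[str, List[Tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for name, entries in self.groups.items():
            cms = [cm for _, cm in entries]
            if any(b < a - 1e-9 for a, b in zip(cms, cms[1:])):
                raise ValueError(f"cM not non-decreasing in group {name}")
            for marker, _ in entries:
                if marker in seen:
                    raise ValueError(f"duplicate marker name {marker!r}")
                seen.add(marker)

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def group_length(self, name: str) -> float:
        entries = self.groups[name]
        if len(entries) < 2:
            return 0.0
        cms = [cm for _, cm in entries]
        return max(cms) - min(cms)

    @property
    def total_cm(self) -> float:
        return sum(self.group_length(g) for g in self.groups)

    def positions(self) -> Dict[str, Tuple[str, float]]:
        """marker -> (group, cM)."""
        return {m: (g, cm) for g, entries in self.groups.items()
                for m, cm in entries}

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, m, cm) for g, entries in self.groups.items()
                for m, cm in entries]
        return pd.DataFrame(rows, columns=["linkage_group", "marker", "cM"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinkageMap":
        groups: Dict[str, List[Tuple[str, float]]] = {}
        for g, sub in df.groupby("linkage_group", sort=False):
            sub = sub.sort_values("cM", kind="stable")
            groups[str(g)] = list(zip(sub["marker"].astype(str),
                                      sub["cM"].astype(float)))
        return cls(groups)

    @classmethod
    def from_tsv(cls, path) -> "LinkageMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
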