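"""Linkage-map vs physical-map comparison: synteny and rearrangements.

A correspondence table pairs each confidently classified marker's genetic
position (linkage group, cM) with its physical position (chromosome, bp
midpoint of the ortholog locus).  From it we derive: syntenic partnerships
(a chromosome is a partner of a linkage group when it carries at least
``min_markers`` of the group's markers), fission-or-fusion events (one per
chromosome split over >= 2 groups and per group joining >= 2 chromosomes;
direction is never assigned, since without an outgroup a fission in one
lineage is indistinguishable from a fusion in the other), inversions
(maximal marker runs whose physical order opposes the dominant orientation
of their group/chromosome pair), and single-marker translocations (markers
stranded on a non-partner chromosome, with physically and genetically
adjacent markers merged into one event).

Unplaced scaffolds (labels starting with ``scaff``) are treated as
chromosomes for partnership and translocation screening but are excluded
from fission/fusion calling: linking an unplaced assembly fragment to a
group documents the assembly, not a rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

FISSION_OR_FUSION = "fission_or_fusion"
INVERSION = "inversion"
TRANSLOCATION = "translocation_single_marker"

DEFAULT_MIN_MARKERS = 3
DEFAULT_MIN_INV_MARKERS = 3
UNPLACED_PREFIX = "scaff"

CORR_COLUMNS = ["marker", "linkage_group", "cM", "chrom", "bp"]


class ParameterError(ValueError):
    pass


def make_correspondence(rows: Sequence[Tuple[str, str, float, str, float]]
                        ) -> pd.DataFrame:
    """Build a correspondence table from (marker, lg, cM, chrom, bp) tuples."""
    df = pd.DataFrame(rows, columns=CORR_COLUMNS)
    if df["marker"].duplicated().any():
        dupes = df.loc[df["marker"].duplicated(), "marker"].tolist()
        raise ParameterError(f"duplicate markers in correspondence: {dupes}")
    return df


@dataclass
class PartnerEntry:
    linkage_group: str
    chrom: str
    n_markers: int
    bp_min: float
    bp_max: float
    markers: Tuple[str, ...]
    majority: bool = False


@dataclass
class PartnerTable:
    entries: List[PartnerEntry] = field(default_factory=list)

    def partners_of_group(self, lg: str) -> Set[str]:
        return {e.chrom for e in self.entries if e.linkage_group == lg}

    def groups_of_chrom(self, chrom: str) -> Set[str]:
        return {e.linkage_group for e in self.entries if e.chrom == chrom}

    def as_mapping(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for e in self.entries:
            out.setdefault(e.linkage_group, set()).add(e.chrom)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "linkage_group": e.linkage_group, "chrom": e.chrom,
            "n_markers": e.n_markers, "bp_min": e.bp_min, "bp_max": e.bp_max,
            "majority": e.majority} for e in self.entries])


@dataclass
class RearrangementEventCall:
    type: str
    members: Tuple[str, ...]
    linkage_groups: Tuple[str, ...]
    chromosomes: Tuple[str, ...]
    cm_span: Optional[Tuple[float, float]] = None
    bp_span: Optional[Tuple[float, float]] = None

    @property
    def support(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "type": self.type,
            "members": list(self.members),
            "linkage_groups": list(self.linkage_groups),
            "chromosomes": list(self.chromosomes),
            "cm_span": list(self.cm_span) if self.cm_span else None,
            "bp_span": list(self.bp_span) if self.bp_span else None,
            "support": self.support,
        }


def assign_syntenic_groups(corr: pd.DataFrame,
                           min_markers: int = DEFAULT_MIN_MARKERS
                           ) -> PartnerTable:
    """Partner chromosomes (with bp ranges) for every linkage group."""
    if corr.empty:
        raise ParameterError("empty correspondence table")
    table = PartnerTable()
    for lg, sub in corr.groupby("linkage_group", sort=False):
        per_chrom = sub.groupby("chrom")
        counts = per_chrom.size()
        majority_chrom = counts.idxmax()
        for chrom, csub in per_chrom:
            if len(csub) < min_markers:
                continue
            table.entries.append(PartnerEntry(
                linkage_group=str(lg), chrom=str(chrom),
                n_markers=len(csub),
                bp_min=float(csub["bp"].min()), bp_max=float(csub["bp"].max()),
                markers=tuple(csub["marker"]),
                majority=(chrom == majority_chrom)))
    return table


def detect_fission_fusion(partners: PartnerTable,
                          unplaced_prefix: str = UNPLACED_PREFIX
                          ) -> List[RearrangementEventCall]:
    """One undirected fission-or-fusion event per split chromosome or group."""
    placed = [e for e in partners.entries
              if not e.chrom.startswith(unplaced_prefix)]
    events: List[RearrangementEventCall] = []
    seen: Set[frozenset] = set()

    by_chrom: Dict[str, List[PartnerEntry]] = {}
    by_group: Dict[str, List[PartnerEntry]] = {}
    for e in placed:
        by_chrom.setdefault(e.chrom, []).append(e)
        by_group.setdefault(e.linkage_group, []).append(e)

    def add(entries: List[PartnerEntry]) -> None:
        members = tuple(sorted(m for e in entries for m in e.markers))
        key = frozenset(members)
        if key in seen:
            return
        seen.add(key)
        events.append(RearrangementEventCall(
            type=FISSION_OR_FUSION, members=members,
            linkage_groups=tuple(sorted({e.linkage_group for e in entries})),
            chromosomes=tuple(sorted({e.chrom for e in entries})),
            bp_span=(min(e.bp_min for e in entries),
                     max(e.bp_max for e in entries))))

    for chrom in sorted(by_chrom):
        if len(by_chrom[chrom]) >= 2:
            add(by_chrom[chrom])
    for lg in sorted(by_group):
        if len(by_group[lg]) >= 2:
            add(by_group[lg])
    return events


def _collapse_ties(sub: pd.DataFrame) -> List[pd.DataFrame]:
    """Split a cM-sorted table into blocks of tied cM positions."""
    blocks: List[pd.DataFrame] = []
    start = 0
    cms = sub["cM"].to_numpy()
    for i in range(1, len(sub) + 1):
        if i == len(sub) or cms[i] != cms[start]:
            blocks.append(sub.iloc[start:i])
            start = i
    return blocks


def _descending_runs(bp: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal strictly descending runs as (start, end) block indices."""
    runs = []
    i = 0
    while i < len(bp) - 1:
        if bp[i + 1] < bp[i]:
            j = i + 1
            while j < len(bp) - 1 and bp[j + 1] < bp[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_inversions(corr: pd.DataFrame,
                      min_inv_markers: int = DEFAULT_MIN_INV_MARKERS
                      ) -> List[RearrangementEventCall]:
    """Inversions: maximal runs opposing the dominant physical orientation.

    Per (linkage group, chromosome) pair with enough markers, markers are
    taken in cM order and maximal strictly descending runs of bp with at
    least ``min_inv_markers`` markers are reported as inversions.  The
    orientation of the physical axis is a map convention; it is chosen by
    parsimony — the orientation implying fewer inversion events (ties:
    fewer inverted markers, then the sign of the Kendall rank correlation)
    — which also makes detection invariant under reversing a group's cM
    axis.  Markers at tied cM positions form unordered blocks and
    contribute no breakpoints.
    """
    events: List[RearrangementEventCall] = []
    for (lg, chrom), sub in corr.groupby(["linkage_group", "chrom"], sort=True):
        if len(sub) < 2 * min_inv_markers:
            continue
        sub = sub.sort_values(["cM", "marker"], kind="stable")
        blocks = _collapse_ties(sub)
        if len(blocks) < 2:
            continue
        bp = np.array([b["bp"].mean() for b in blocks])
        tau = kendalltau(np.arange(len(bp)), bp).statistic
        tau = 0.0 if tau is None or np.isnan(tau) else float(tau)

        runs_fwd = _descending_runs(bp)
        runs_rev = _descending_runs(-bp)
        # breakpoint parsimony first; the rank-correlation sign settles ties
        key_fwd = (len(runs_fwd), 0 if tau >= 0 else 1)
        key_rev = (len(runs_rev), 0 if tau <= 0 else 1)
        chosen = runs_fwd if key_fwd <= key_rev else runs_rev
        qualified = []
        for i, j in chosen:
            members = [m for b in blocks[i:j + 1] for m in b["marker"]]
            if len(members) >= min_inv_markers:
                qualified.append(members)
        for members in qualified:
            rows = sub[sub["marker"].isin(members)]
            events.append(RearrangementEventCall(
                type=INVERSION, members=tuple(members),
                linkage_groups=(str(lg),), chromosomes=(str(chrom),),
                cm_span=(float(rows["cM"].min()), float(rows["cM"].max())),
                bp_span=(float(rows["bp"].min()), float(rows["bp"].max()))))
    return events


def detect_single_marker_translocations(corr: pd.DataFrame,
                                        partners: PartnerTable
                                        ) -> List[RearrangementEventCall]:
    """Markers stranded on a non-partner chromosome, merged when adjacent.

    Two stranded markers reflect one biological event when they are
    consecutive in bp order among the markers anchored to the same source
    chromosome and within one intervening marker on their shared linkage
    group.
    """
    mapping = partners.as_mapping()
    flagged = corr[[chrom not in mapping.get(lg, set())
                    for lg, chrom in zip(corr["linkage_group"], corr["chrom"])]]
    if flagged.empty:
        return []

    # adjacency on the physical axis: consecutive among all corr markers of
    # the source chromosome
    bp_rank: Dict[str, int] = {}
    for chrom, sub in corr.groupby("chrom"):
        for rank, marker in enumerate(sub.sort_values("bp")["marker"]):
            bp_rank[marker] = rank
    cm_rank: Dict[str, int] = {}
    for lg, sub in corr.groupby("linkage_group"):
        for rank, marker in enumerate(sub.sort_values("cM")["marker"]):
            cm_rank[marker] = rank

    markers = list(flagged.sort_values(["chrom", "bp"]).itertuples())
    parent = {m.marker: m.marker for m in markers}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(markers, markers[1:]):
        if a.chrom != b.chrom or a.linkage_group != b.linkage_group:
            continue
        if abs(bp_rank[a.marker] - bp_rank[b.marker]) != 1:
            continue
        if abs(cm_rank[a.marker] - cm_rank[b.marker]) > 2:
            continue
        parent[find(a.marker)] = find(b.marker)

    groups: Dict[str, List] = {}
    for m in markers:
        groups.setdefault(find(m.marker), []).append(m)
    events = []
    for _, group in sorted(groups.items()):
        events.append(RearrangementEventCall(
            type=TRANSLOCATION,
            members=tuple(sorted(m.marker for m in group)),
            linkage_groups=tuple(sorted({m.linkage_group for m in group})),
            chromosomes=tuple(sorted({m.chrom for m in group})),
            cm_span=(min(m.cM for m in group), max(m.cM for m in group)),
            bp_span=(min(m.bp for m in group), max(m.bp for m in group))))
    events.sort(key=lambda e: e.members)
    return events


def rearrangement_rate(n_events: int, t_divergence_my: float) -> float:
    """Events per My per genome: n / (2 t).

    The factor 2 counts both diverging lineages' worth of branch length,
    e.g. 13 events over 45 My gives 0.14 events/My/genome.
    """
    if t_divergence_my <= 0:
        raise ParameterError("t_divergence must be > 0")
    if n_events < 0:
        raise ParameterError("n_events must be >= 0")
    return n_events / (2.0 * t_divergence_my)


def map_coverage(corr: pd.DataFrame, assigned_total_bp: float
                 ) -> Tuple[float, float]:
    """(covered bp, percent of sequence assigned to linkage groups).

    Covered = sum over chromosomes of the bp span between the outermost
    anchored markers.
    """
    if assigned_total_bp <= 0:
        raise ParameterError("assigned_total must be > 0")
    if corr.empty:
        return 0.0, 0.0
    spans = corr.groupby("chrom")["bp"].agg(["min", "max"])
    covered = float((spans["max"] - spans["min"]).sum())
    return covered, 100.0 * covered / assigned_total_bp
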