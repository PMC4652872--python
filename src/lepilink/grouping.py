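"""Co-segregation grouping of dominant markers from a female-informative backcross.

Because female Lepidoptera lack crossing-over, every progeny inherits one
intact maternal homolog per chromosome: two dominant markers on the same
chromosome must show either identical or exactly complementary band
patterns across the progeny (up to genotyping error).  Grouping is
therefore exact single-linkage clustering of segregation patterns with an
explicit mismatch tolerance (default 0), with the complement treated as
phase reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .popsim import COHORT_CONTROL, COHORT_SURVIVOR, MISSING

__all__ = [
    "SegregationPattern",
    "MarkerGroupCall",
    "LinkageGroupAssignment",
    "segregation_pattern",
    "group_dominant_markers",
]

_DOMINANT_TOKENS = {"present", "absent", MISSING}


@dataclass(frozen=True)
class SegregationPattern:
    """Bit vector of band presence over progeny, with a missing mask."""

    marker: str
    calls: np.ndarray  # int8; 1 = present, 0 = absent; undefined where masked
    valid: np.ndarray  # bool; False where the call is missing
    informative: bool

    @property
    def n_missing(self) -> int:
        return int((~self.valid).sum())


def segregation_pattern(column: pd.Series, marker: Optional[str] = None) -> SegregationPattern:
    """Convert a dominant marker column into a presence/absence bit pattern.

    Missing cells ("NA") are masked.  A pattern with fewer than two states
    among its unmasked calls is flagged uninformative.  Codominant
    (size-pair) columns are rejected.
    """
    name = marker if marker is not None else str(column.name)
    values = column.astype(str).to_numpy()
    bad = set(values) - _DOMINANT_TOKENS
    if bad:
        raise ValueError(
            f"marker {name}: not a dominant presence/absence column "
            f"(unexpected values {sorted(bad)[:3]})"
        )
    valid = values != MISSING
    calls = (values == "present").astype(np.int8)
    states = set(calls[valid].tolist())
    return SegregationPattern(
        marker=name, calls=calls, valid=valid, informative=len(states) == 2
    )


@dataclass(frozen=True)
class MarkerGroupCall:
    group: int
    phase: str  # '+' same as reference pattern, '-' complement
    n_mismatch: int  # disagreements with the group reference pattern


@dataclass
class LinkageGroupAssignment:
    """Partition of dominant markers into linkage groups with per-marker phase."""

    assignments: Dict[str, MarkerGroupCall]
    reference_patterns: Dict[int, SegregationPattern]
    excluded: List[Tuple[str, str]] = field(default_factory=list)
    unresolved: List[str] = field(default_factory=list)
    progeny_ids: Tuple[str, ...] = ()

    @property
    def n_groups(self) -> int:
        return len(self.reference_patterns)

    def markers_of(self, group: int) -> List[str]:
        return sorted(m for m, c in self.assignments.items() if c.group == group)

    def partition(self) -> frozenset:
        """The partition as a frozenset of frozensets of marker ids."""
        return frozenset(
            frozenset(self.markers_of(g)) for g in self.reference_patterns
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "marker": m,
                "group": c.group,
                "phase": c.phase,
                "n_mismatch": c.n_mismatch,
            }
            for m, c in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["marker", "group", "phase", "n_mismatch"])

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.reference_patterns):
            members = self.markers_of(g)
            rows.append(
                {
                    "group": g,
                    "n_markers": len(members),
                    "reference_marker": self.reference_patterns[g].marker,
                    "markers": ";".join(members),
                }
            )
        return pd.DataFrame(
            rows, columns=["group", "n_markers", "reference_marker", "markers"]
        )


def _pattern_distance(
    a: SegregationPattern, b: SegregationPattern
) -> Tuple[Optional[int], int, int]:
    """(distance, n_compared, direct_mismatches) over jointly unmasked progeny.

    Distance is the smaller of the direct and complemented mismatch counts
    (phase is free).  Returns distance None when no progeny are jointly
    scored.
    """
    both = a.valid & b.valid
    n = int(both.sum())
    if n == 0:
        return None, 0, 0
    direct = int((a.calls[both] != b.calls[both]).sum())
    return min(direct, n - direct), n, direct


def group_dominant_markers(
    matrix: pd.DataFrame,
    max_mismatch: int = 0,
    min_progeny: int = 20,
    max_missing_frac: float = 0.2,
    cohorts: Sequence[str] = (COHORT_SURVIVOR, COHORT_CONTROL),
    markers: Optional[Sequence[str]] = None,
) -> LinkageGroupAssignment:
    """Partition dominant markers into linkage groups by co-segregation.

    Two markers are linked iff their patterns agree at >= (n_compared -
    max_mismatch) jointly scored progeny, either directly (same phase) or
    after complementing one (opposite phase); linkage groups are the
    connected components of the link graph.  With ``max_mismatch > 0`` a
    marker whose removal disconnects its component bridges two otherwise
    separate groups at the tolerance boundary; such markers are reported
    unresolved and assigned to neither.

    Groups are numbered by descending size, ties by smallest member id.
    Markers with more than ``max_missing_frac`` missing progeny calls, or
    monomorphic over the progeny, are excluded with a reason.
    """
    progeny = matrix[matrix["cohort"].isin(cohorts)]
    if len(progeny) < min_progeny:
        raise ValueError(
            f"only {len(progeny)} progeny in cohorts {tuple(cohorts)}; "
            f"need at least {min_progeny}"
        )

    if markers is None:
        meta = {"id", "sex", "role", "cohort"}
        markers = [
            c
            for c in matrix.columns
            if c not in meta and set(progeny[c].astype(str)) <= _DOMINANT_TOKENS
        ]
    if not markers:
        raise ValueError("no dominant marker columns found")

    excluded: List[Tuple[str, str]] = []
    patterns: Dict[str, SegregationPattern] = {}
    for m in markers:
        pat = segregation_pattern(progeny[m], marker=m)
        if pat.n_missing > max_missing_frac * len(progeny):
            excluded.append((m, f"missing>{max_missing_frac:.0%}"))
        elif not pat.informative:
            excluded.append((m, "uninformative"))
        else:
            patterns[m] = pat
    if not patterns:
        raise ValueError("no informative dominant markers")

    ids = sorted(patterns)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dist, n_cmp, _ = _pattern_distance(patterns[a], patterns[b])
            if dist is not None and dist <= max_mismatch:
                graph.add_edge(a, b)

    # Tolerance-boundary bridges: only possible with a nonzero tolerance
    # (at tolerance 0 every within-group pair links directly).
    unresolved: List[str] = []
    if max_mismatch > 0:
        for v in sorted(nx.articulation_points(graph)):
            unresolved.append(v)
        if unresolved:
            graph.remove_nodes_from(unresolved)

    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))

    assignments: Dict[str, MarkerGroupCall] = {}
    reference_patterns: Dict[int, SegregationPattern] = {}
    for gnum, members in enumerate(components, start=1):
        ref = patterns[members[0]]
        reference_patterns[gnum] = ref
        for m in members:
            dist, n_cmp, direct = _pattern_distance(patterns[m], ref)
            phase = "+" if direct <= (n_cmp - direct) else "-"
            assignments[m] = MarkerGroupCall(
                group=gnum, phase=phase, n_mismatch=0 if dist is None else dist
            )

    return LinkageGroupAssignment(
        assignments=assignments,
        reference_patterns=reference_patterns,
        excluded=excluded,
        unresolved=unresolved,
        progeny_ids=tuple(progeny["id"].astype(str)),
    )
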