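"""Recombination-fraction estimation and locus ordering from selected progeny.

In a male-informative family the F1 father is heterozygous and recombines;
the mother contributes an intact resistant-line homolog (achiasmatic female
meiosis, and survivors of the discriminating dose are homozygous resistant,
forcing the maternal trait allele).  Each rr-selected offspring therefore
exposes exactly one informative (paternal) meiosis, in both backcross and
F2 designs:

* trait-marker distance: a selected offspring is recombinant iff it is
  heterozygous at a codominant marker (the paternal gamete carried the
  allele not linked to the resistance allele), so r-hat is the heterozygote
  fraction;
* marker-marker distance: paternal alleles are recovered by subtracting
  the known maternal contribution, and an offspring is recombinant iff its
  paternal alleles derive from different F1 homologs.

Estimates pool across families by summed counts.  Locus order minimizes
the sum of adjacent r-hat over permutations (exhaustive up to a cutoff),
and map distances use the Haldane function d = -50 ln(1 - 2r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .popsim import COHORT_SURVIVOR, MISSING, MarkerDef

__all__ = [
    "RecombinationEstimate",
    "GeneticMap",
    "parse_size_pair",
    "estimate_r_trait_marker",
    "infer_paternal_haplotypes",
    "estimate_r_marker_marker",
    "pool_families",
    "order_loci",
    "haldane_cM",
    "compose_r",
]


def parse_size_pair(cell: str) -> Optional[Tuple[int, int]]:
    """Parse a codominant genotype cell like '272/282' (unordered pair)."""
    if cell == MISSING or cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    parts = str(cell).split("/")
    if len(parts) != 2 or not all(p.isdigit() for p in parts):
        raise ValueError(f"malformed size pair {cell!r}")
    a, b = int(parts[0]), int(parts[1])
    return (a, b) if a <= b else (b, a)


@dataclass
class RecombinationEstimate:
    """r-hat between two loci with its binomial standard error."""

    locus_a: str
    locus_b: str
    n_informative: int
    n_recombinant: int
    per_family: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    excluded: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_recombinant > self.n_informative:
            raise ValueError("n_recombinant cannot exceed n_informative")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.locus_a, self.locus_b))

    @property
    def r(self) -> float:
        if self.n_informative == 0:
            raise ZeroDivisionError("no informative meioses")
        return self.n_recombinant / self.n_informative

    @property
    def se(self) -> float:
        r = self.r
        return math.sqrt(r * (1.0 - r) / self.n_informative)

    @property
    def unlinked(self) -> bool:
        return self.r > 0.5


def estimate_r_trait_marker(
    matrix: pd.DataFrame,
    marker: MarkerDef,
    r_linked_allele: Optional[int] = None,
    cohort: str = COHORT_SURVIVOR,
    family: str = "family",
) -> RecombinationEstimate:
    """Trait-marker recombination fraction from rr-selected progeny.

    The maternal contribution is the intact resistant-line homolog, so the
    paternal allele is the one left after removing ``marker.allele_res``
    from the genotype pair; the offspring is recombinant iff that allele
    differs from ``r_linked_allele`` (default: the resistant-line allele,
    i.e. recombinant iff heterozygous).  Genotypes carrying an allele
    absent from the parents are flagged and excluded.
    """
    if marker.allele_res == marker.allele_sus:
        raise ValueError(
            f"marker {marker.id}: F1 father homozygous "
            f"({marker.allele_res}/{marker.allele_sus}), uninformative"
        )
    if r_linked_allele is None:
        r_linked_allele = marker.allele_res
    if r_linked_allele not in (marker.allele_res, marker.allele_sus):
        raise ValueError(
            f"r-linked allele {r_linked_allele} is not an F1 allele of {marker.id}"
        )
    parental = {marker.allele_res, marker.allele_sus}
    selected = matrix[matrix["cohort"] == cohort]
    n = nrec = 0
    excluded: List[str] = []
    for _, row in selected.iterrows():
        pair = parse_size_pair(row[marker.id])
        if pair is None:
            continue
        if not set(pair) <= parental or marker.allele_res not in pair:
            excluded.append(str(row["id"]))
            continue
        maternal = marker.allele_res
        paternal = pair[1] if pair[0] == maternal else pair[0]
        n += 1
        nrec += int(paternal != r_linked_allele)
    return RecombinationEstimate(
        locus_a="R",
        locus_b=marker.id,
        n_informative=n,
        n_recombinant=nrec,
        per_family={family: (n, nrec)},
        excluded=excluded,
    )


def infer_paternal_haplotypes(
    matrix: pd.DataFrame,
    markers: Sequence[MarkerDef],
    maternal: Optional[Mapping[str, int]] = None,
    cohort: str = COHORT_SURVIVOR,
) -> Tuple[pd.DataFrame, List[Tuple[str, str]]]:
    """Recover paternal alleles by subtracting the known maternal allele.

    For each selected offspring and marker, the paternal allele is the
    genotype pair minus the maternal allele; a homozygous offspring whose
    shared allele is also the maternal allele resolves to that allele.
    Cells where the maternal allele is absent from the pair are pedigree
    inconsistencies: left missing and reported as (individual, marker).
    """
    if maternal is None:
        maternal = {m.id: m.allele_res for m in markers}
    selected = matrix[matrix["cohort"] == cohort]
    inconsistent: List[Tuple[str, str]] = []
    out: Dict[str, List[object]] = {m.id: [] for m in markers}
    ids: List[str] = []
    for _, row in selected.iterrows():
        ids.append(str(row["id"]))
        for m in markers:
            pair = parse_size_pair(row[m.id])
            if pair is None:
                out[m.id].append(pd.NA)
                continue
            mat = maternal[m.id]
            if mat not in pair:
                inconsistent.append((str(row["id"]), m.id))
                out[m.id].append(pd.NA)
                continue
            paternal = pair[1] if pair[0] == mat else pair[0]
            out[m.id].append(paternal)
    frame = pd.DataFrame(out, index=ids, dtype="Int64")
    return frame, inconsistent


def estimate_r_marker_marker(
    paternal: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    phase: Mapping[str, Tuple[int, int]],
    family: str = "family",
) -> RecombinationEstimate:
    """Marker-marker recombination fraction from paternal haplotypes.

    ``phase[m]`` gives the F1 father's (homolog-0 allele, homolog-1 allele)
    at marker ``m``, known from the grandparents; phase inference from
    progeny is out of scope.  An offspring is recombinant iff its paternal
    alleles at the two markers derive from different homologs.
    """
    for m in (marker_a, marker_b):
        if m not in phase:
            raise ValueError(f"phase unknown for marker {m}")
        if phase[m][0] == phase[m][1]:
            raise ValueError(f"marker {m}: F1 father homozygous, uninformative")
    n = nrec = 0
    excluded: List[str] = []
    for ident, row in paternal.iterrows():
        alleles = (row[marker_a], row[marker_b])
        if any(pd.isna(x) for x in alleles):
            continue
        sources = []
        ok = True
        for m, allele in zip((marker_a, marker_b), alleles):
            h0, h1 = phase[m]
            if allele == h0:
                sources.append(0)
            elif allele == h1:
                sources.append(1)
            else:
                ok = False
        if not ok:
            excluded.append(str(ident))
            continue
        n += 1
        nrec += int(sources[0] != sources[1])
    return RecombinationEstimate(
        locus_a=marker_a,
        locus_b=marker_b,
        n_informative=n,
        n_recombinant=nrec,
        per_family={family: (n, nrec)},
        excluded=excluded,
    )


def pool_families(
    estimates: Sequence[RecombinationEstimate],
) -> RecombinationEstimate:
    """Pool per-family estimates of one locus pair by summed counts."""
    if not estimates:
        raise ValueError("no estimates to pool")
    first = estimates[0]
    per_family: Dict[str, Tuple[int, int]] = {}
    n = nrec = 0
    for est in estimates:
        if est.pair != first.pair:
            raise ValueError(
                f"mismatched locus pairs: {sorted(first.pair)} vs {sorted(est.pair)}"
            )
        n += est.n_informative
        nrec += est.n_recombinant
        per_family.update(est.per_family)
    if n == 0:
        raise ValueError("zero informative meioses in pooled estimate")
    return RecombinationEstimate(
        locus_a=first.locus_a,
        locus_b=first.locus_b,
        n_informative=n,
        n_recombinant=nrec,
        per_family=per_family,
        excluded=[x for e in estimates for x in e.excluded],
    )


@dataclass(frozen=True)
class GeneticMap:
    """Ordered loci with adjacent recombination fractions."""

    loci: Tuple[str, ...]
    adjacent_r: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.adjacent_r) != len(self.loci) - 1:
            raise ValueError("adjacent fraction count must be locus count - 1")

    def render(self) -> str:
        """Chain rendering, e.g. 'Bre-5–(0.16)–R–(0.10)–RpL22–(0.06)–RpS24'."""
        parts = [self.loci[0]]
        for r, locus in zip(self.adjacent_r, self.loci[1:]):
            parts.append(f"–({r:.2f})–{locus}")
        return "".join(parts)

    def haldane_distances(self) -> Tuple[float, ...]:
        return tuple(haldane_cM(r) for r in self.adjacent_r)


def _normalize_pairwise(
    pairwise: Mapping, loci: Optional[Iterable[str]] = None
) -> Tuple[List[str], Dict[frozenset, float]]:
    table: Dict[frozenset, float] = {}
    found = set()
    for key, value in pairwise.items():
        pair = frozenset(key)
        if len(pair) != 2:
            raise ValueError(f"bad locus pair {key!r}")
        table[pair] = float(value)
        found |= pair
    ids = sorted(found if loci is None else loci)
    return ids, table


def _chain_cost(order: Sequence[str], table: Mapping[frozenset, float]) -> float:
    cost = 0.0
    for a, b in zip(order, order[1:]):
        pair = frozenset((a, b))
        if pair not in table:
            raise ValueError(f"missing pairwise estimate for {sorted(pair)}")
        cost += table[pair]
    return cost


def _double_recombinants(order: Sequence[str], table) -> float:
    # Expected double-crossover load under no interference: sum of products
    # of adjacent interval fractions.  Used only to break ordering ties.
    rs = [table[frozenset((a, b))] for a, b in zip(order, order[1:])]
    return sum(r1 * r2 for r1, r2 in zip(rs, rs[1:]))


def _canonical(order: Tuple[str, ...]) -> Tuple[str, ...]:
    return order if order[0] <= order[-1] else order[::-1]


def order_loci(
    pairwise: Mapping,
    loci: Optional[Iterable[str]] = None,
    exhaustive_max: int = 8,
) -> GeneticMap:
    """Order loci into a map minimizing the sum of adjacent r-hat.

    Keys of ``pairwise`` are unordered locus pairs.  Up to
    ``exhaustive_max`` loci every permutation is scored (orientation
    canonicalized so the lexicographically smaller terminal comes first);
    ties break by fewer implied double recombinants, then lexicographically.
    Larger problems fall back to greedy seriation from the tightest pair.
    """
    ids, table = _normalize_pairwise(pairwise, loci)
    if len(ids) < 2:
        raise ValueError("need at least two loci to order")
    if len(ids) == 2:
        order = _canonical(tuple(ids))
        return GeneticMap(order, (_chain_cost(order, table),))

    if len(ids) <= exhaustive_max:
        best = None
        for perm in permutations(ids):
            order = _canonical(perm)
            if order != perm:
                continue  # score each orientation once
            key = (_chain_cost(order, table), _double_recombinants(order, table), order)
            if best is None or key < best:
                best = key
        order = best[2]
    else:
        order = _greedy_seriation(ids, table)
    rs = tuple(table[frozenset(p)] for p in zip(order, order[1:]))
    return GeneticMap(tuple(order), rs)


def _greedy_seriation(ids: Sequence[str], table) -> Tuple[str, ...]:
    pairs = sorted(table.items(), key=lambda kv: (kv[1], sorted(kv[0])))
    chain = list(sorted(pairs[0][0]))
    remaining = [x for x in ids if x not in chain]
    while remaining:
        best = None
        for locus in remaining:
            for end, pos in ((chain[0], 0), (chain[-1], len(chain))):
                pair = frozenset((locus, end))
                if pair not in table:
                    continue
                key = (table[pair], locus)
                if best is None or key < best[0]:
                    best = (key, locus, pos)
        if best is None:
            raise ValueError("greedy seriation stalled: missing pairwise estimates")
        _, locus, pos = best
        chain.insert(pos, locus)
        remaining.remove(locus)
    return _canonical(tuple(chain))


def haldane_cM(r: float) -> float:
    """Haldane map distance d = -50 ln(1 - 2r), in centimorgans.

    Fractions at or beyond 0.5 (unlinked) map to infinity.
    """
    if r < 0.0:
        raise ValueError("recombination fraction must be >= 0")
    if r >= 0.5:
        return math.inf
    return -50.0 * math.log1p(-2.0 * r)


def compose_r(r1: float, r2: float) -> float:
    """Recombination fraction across two adjacent intervals, no interference."""
    return r1 + r2 - 2.0 * r1 * r2
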