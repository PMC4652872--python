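"""Forward simulator of lepidopteran mapping families.

Simulates the two family types used to map a recessive Bt-resistance locus:

* a *female-informative* backcross, exploiting achiasmatic oogenesis in
  female Lepidoptera (no crossing-over in female meiosis), which assigns
  the trait to a whole linkage group via dominant AFLP-style markers; and
* *male-informative* backcross / F2 families, in which recombination in
  the heterozygous F1 father orders loci within the group via codominant
  fragment-size (EPIC-style) markers.

Founders are a homozygous-resistant line (``r/r`` at the trait locus,
modelled on SP15) and a susceptible line (``s/s``, modelled on GR).
Progeny are pushed through a discriminating-dose bioassay in which, under
the default fully recessive model, only ``r/r`` larvae survive.

Male meiosis uses independent per-interval Bernoulli crossovers (Haldane
model, no interference); female meiosis transmits one intact homolog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DOMINANT",
    "CODOMINANT",
    "COHORT_SURVIVOR",
    "COHORT_DEAD",
    "COHORT_CONTROL",
    "COHORT_PARENT",
    "MISSING",
    "MarkerDef",
    "TraitLocus",
    "Individual",
    "FamilyDesign",
    "RecombMap",
    "GroupLayout",
    "SimulatedFamily",
    "build_layouts",
    "meiosis_female",
    "meiosis_male",
    "apply_bioassay",
    "simulate_family",
    "f2301_panel",
    "f2301_design",
    "mapping_panel",
    "mapping_design",
]

DOMINANT = "dominant"
CODOMINANT = "codominant"

# Band scoring for dominant (presence/absence) markers.
PRESENT = 1
ABSENT = 0

# Trait alleles encoded on haplotypes.
R_ALLELE = 1  # resistant
S_ALLELE = 0  # susceptible

COHORT_SURVIVOR = "treated-survivor"
COHORT_DEAD = "treated-dead"
COHORT_CONTROL = "control"
COHORT_PARENT = "parent"

MISSING = "NA"

#: Default discriminating-dose survival probabilities (fully recessive trait).
RECESSIVE_SURVIVAL: Mapping[str, float] = {"rr": 1.0, "rs": 0.0, "ss": 0.0}


@dataclass(frozen=True)
class MarkerDef:
    """A marker locus on the panel.

    ``allele_res`` / ``allele_sus`` are the alleles carried by the
    resistant-grandparent and susceptible-grandparent homologs of the
    informative F1 parent.  For dominant markers these are band presence
    (1) / absence (0), with the band on exactly one homolog; the
    non-informative mate is always band-absent, matching the AFLP scoring
    scheme.  For codominant markers they are fragment sizes in bp.
    """

    id: str
    group: int
    position: int
    kind: str
    allele_res: int
    allele_sus: int

    def __post_init__(self) -> None:
        if self.kind not in (DOMINANT, CODOMINANT):
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.group < 1:
            raise ValueError("linkage-group index must be >= 1")
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.kind == DOMINANT:
            if {self.allele_res, self.allele_sus} != {PRESENT, ABSENT}:
                raise ValueError(
                    f"dominant marker {self.id}: alleles must be exactly "
                    "{presence, absence} (1, 0) in some order"
                )
        else:
            if self.allele_res <= 0 or self.allele_sus <= 0:
                raise ValueError(
                    f"codominant marker {self.id}: fragment sizes must be positive"
                )


@dataclass(frozen=True)
class TraitLocus:
    """The recessive resistance locus and its discriminating-dose model."""

    group: int
    position: int
    id: str = "R"
    survival: Mapping[str, float] = field(
        default_factory=lambda: dict(RECESSIVE_SURVIVAL)
    )

    def __post_init__(self) -> None:
        for key in ("rr", "rs", "ss"):
            p = self.survival[key]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival[{key}] = {p} outside [0, 1]")


@dataclass
class Individual:
    """A simulated moth: per-group homolog pairs plus bookkeeping.

    ``genome[g]`` is a pair of haplotypes (numpy int vectors over the loci
    of group ``g`` in map order).  ``maternal_origin[g]`` records, for
    progeny of an F1 mother, which grandparental homolog the maternal
    gamete derives from (0 = resistant grandparent, 1 = susceptible,
    -1 = not applicable); this is simulator ground truth, not data an
    analysis stage may read.
    """

    id: str
    sex: str
    role: str
    genome: Dict[int, Tuple[np.ndarray, np.ndarray]]
    cohort: str = COHORT_PARENT
    maternal_origin: Dict[int, int] = field(default_factory=dict)
    trait_genotype: Optional[str] = None


@dataclass(frozen=True)
class FamilyDesign:
    """Cross topology and cohort sizes for one simulated family.

    ``informative_sex`` selects which F1 parent is heterozygous-tracked:
    the mother (linkage-group assignment) or the father (recombination
    mapping).  ``cross`` is either a backcross to the resistant line or an
    F1 x F1 intercross.  If ``n_survivor_target`` is set, treated progeny
    are drawn until that many bioassay survivors have accumulated
    (non-survivors are retained with cohort "treated-dead"); otherwise
    exactly ``n_treated`` progeny are drawn and bioassayed.
    """

    name: str
    informative_sex: str
    cross: str
    n_treated: int = 0
    n_control: int = 0
    n_survivor_target: Optional[int] = None
    false_negative: float = 0.0
    false_positive: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.informative_sex not in ("female", "male"):
            raise ValueError("informative_sex must be 'female' or 'male'")
        if self.cross not in ("backcross", "F2"):
            raise ValueError("cross must be 'backcross' or 'F2'")
        if self.n_treated < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        for rate in (self.false_negative, self.false_positive):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("bioassay error rates must lie in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


@dataclass(frozen=True)
class GroupLayout:
    """Ordered loci of one linkage group (markers plus trait if present)."""

    group: int
    locus_ids: Tuple[str, ...]
    kinds: Tuple[str, ...]
    allele_res: np.ndarray
    allele_sus: np.ndarray
    trait_index: Optional[int]

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


class RecombMap:
    """Per-group recombination fractions between adjacent loci (male meiosis).

    Female meiosis is achiasmatic by construction and never consults this map.
    """

    def __init__(self, fractions: Mapping[int, Sequence[float]]):
        self._fractions: Dict[int, np.ndarray] = {}
        for group, rs in fractions.items():
            arr = np.asarray(rs, dtype=float)
            if arr.size and (arr.min() < 0.0 or arr.max() > 0.5):
                raise ValueError(f"group {group}: fractions must lie in [0, 0.5]")
            self._fractions[int(group)] = arr

    @classmethod
    def uniform(cls, layouts: Mapping[int, GroupLayout], r: float) -> "RecombMap":
        return cls({g: [r] * max(lay.n_loci - 1, 0) for g, lay in layouts.items()})

    def fractions(self, group: int) -> np.ndarray:
        try:
            return self._fractions[group]
        except KeyError:
            raise KeyError(f"no recombination fractions for group {group}") from None

    @property
    def groups(self) -> Tuple[int, ...]:
        return tuple(sorted(self._fractions))


def build_layouts(
    markers: Sequence[MarkerDef], trait: Optional[TraitLocus] = None
) -> Dict[int, GroupLayout]:
    """Arrange markers (and the trait locus) into per-group map order.

    Positions within a group must be distinct; loci are ordered by
    increasing position.  A trait locus on a group with no markers yields a
    trait-only layout with a warning (the trait is still simulated).
    """
    by_group: Dict[int, List[Tuple[int, str, str, int, int]]] = {}
    for m in markers:
        by_group.setdefault(m.group, []).append(
            (m.position, m.id, m.kind, m.allele_res, m.allele_sus)
        )
    if trait is not None:
        entry = (trait.position, trait.id, "trait", R_ALLELE, S_ALLELE)
        if trait.group not in by_group:
            warnings.warn(
                f"trait group {trait.group} carries no markers; "
                "trait simulated on its own group",
                stacklevel=2,
            )
            by_group[trait.group] = [entry]
        else:
            by_group[trait.group].append(entry)

    layouts: Dict[int, GroupLayout] = {}
    for group, loci in by_group.items():
        loci.sort()
        positions = [p for p, *_ in loci]
        if len(set(positions)) != len(positions):
            raise ValueError(f"group {group}: locus positions must be distinct")
        layouts[group] = GroupLayout(
            group=group,
            locus_ids=tuple(lid for _, lid, *_ in loci),
            kinds=tuple(k for _, _, k, *_ in loci),
            allele_res=np.array([a for *_, a, _ in loci], dtype=np.int64),
            allele_sus=np.array([b for *_, _, b in loci], dtype=np.int64),
            trait_index=next(
                (i for i, (_, _, k, *_rest) in enumerate(loci) if k == "trait"), None
            ),
        )
    return layouts


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def _draw_female(
    parent: Individual, group: int, rng: np.random.Generator
) -> Tuple[int, np.ndarray]:
    if parent.sex != "female":
        raise ValueError(
            f"achiasmatic meiosis requires a female parent, got {parent.sex!r}"
        )
    idx = int(rng.integers(2))
    return idx, parent.genome[group][idx].copy()


def meiosis_female(
    parent: Individual, group: int, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from achiasmatic female meiosis: an intact homolog.

    Either homolog is transmitted with probability 1/2; the returned
    haplotype is never a mosaic of the two.
    """
    return _draw_female(parent, group, rng)[1]


def meiosis_male(
    parent: Individual, group: int, rmap: RecombMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from male meiosis under the no-interference model.

    The starting homolog is chosen with probability 1/2; between adjacent
    loci i and i+1 the source homolog switches independently with
    probability ``rmap[i]`` (Haldane model).
    """
    if parent.sex != "male":
        raise ValueError(f"male meiosis requires a male parent, got {parent.sex!r}")
    hap0, hap1 = parent.genome[group]
    n = len(hap0)
    fractions = rmap.fractions(group)
    if len(fractions) != n - 1:
        raise ValueError(
            f"group {group}: {len(fractions)} fractions for {n} loci "
            f"(need {n - 1})"
        )
    start = int(rng.integers(2))
    if n == 1:
        return (hap0 if start == 0 else hap1).copy()
    switches = rng.random(n - 1) < fractions
    source = np.empty(n, dtype=np.int64)
    source[0] = start
    source[1:] = (start + np.cumsum(switches)) % 2
    return np.where(source == 0, hap0, hap1)


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


def _f1_individual(
    layouts: Mapping[int, GroupLayout], sex: str, ident: str
) -> Individual:
    """An F1: homolog 0 from the resistant grandparent, homolog 1 susceptible."""
    genome = {
        g: (lay.allele_res.copy(), lay.allele_sus.copy()) for g, lay in layouts.items()
    }
    return Individual(id=ident, sex=sex, role="F1", genome=genome)


def _resline_hap(lay: GroupLayout) -> np.ndarray:
    # Resistant-line mate: band-absent at AFLPs (the scoring scheme requires
    # the non-informative parent to lack the band), resistant-line allele at
    # codominant loci, resistant at the trait.
    hap = lay.allele_res.copy()
    for i, kind in enumerate(lay.kinds):
        if kind == DOMINANT:
            hap[i] = ABSENT
    return hap


def _resline_individual(
    layouts: Mapping[int, GroupLayout], sex: str, ident: str
) -> Individual:
    genome = {g: (_resline_hap(lay), _resline_hap(lay)) for g, lay in layouts.items()}
    return Individual(id=ident, sex=sex, role="grandparent", genome=genome)


def _grandparent(
    layouts: Mapping[int, GroupLayout], side: str, sex: str, ident: str
) -> Individual:
    """Founder grandparents, scored so each AFLP band shows in exactly one.

    The grandparent that contributed the band homolog to the F1 is
    band-heterozygous; the other grandparent lacks the band.  Codominant
    loci and the trait are homozygous for the line allele.
    """
    genome: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for g, lay in layouts.items():
        line = lay.allele_res.copy() if side == "res" else lay.allele_sus.copy()
        other = line.copy()
        for i, kind in enumerate(lay.kinds):
            if kind == DOMINANT:
                other[i] = ABSENT
        genome[g] = (line, other)
    return Individual(id=ident, sex=sex, role="grandparent", genome=genome)


# ---------------------------------------------------------------------------
# Bioassay
# ---------------------------------------------------------------------------


def _trait_genotype(ind: Individual, trait: TraitLocus, layouts) -> str:
    lay = layouts[trait.group]
    idx = lay.trait_index
    a = ind.genome[trait.group][0][idx] + ind.genome[trait.group][1][idx]
    return {2: "rr", 1: "rs", 0: "ss"}[int(a)]


def _survives(
    genotype: str,
    trait: TraitLocus,
    false_negative: float,
    false_positive: float,
    rng: np.random.Generator,
) -> bool:
    p = trait.survival[genotype]
    p_eff = p * (1.0 - false_negative) + (1.0 - p) * false_positive
    return bool(rng.random() < p_eff)


def apply_bioassay(
    progeny: Sequence[Individual],
    trait: TraitLocus,
    rng: np.random.Generator,
    false_negative: float = 0.0,
    false_positive: float = 0.0,
) -> List[str]:
    """Discriminating-dose bioassay: label each progeny survivor or dead.

    Survival is drawn from the genotype's survival probability, mixed with
    the false-negative rate (true survivors scored dead) and false-positive
    rate (true dead scored survivors).  Labels are written onto the
    individuals and returned.
    """
    labels = []
    for ind in progeny:
        if ind.trait_genotype is None:
            raise ValueError(f"{ind.id}: progeny carries no trait genotype")
        ok = _survives(ind.trait_genotype, trait, false_negative, false_positive, rng)
        ind.cohort = COHORT_SURVIVOR if ok else COHORT_DEAD
        labels.append(ind.cohort)
    return labels


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFamily:
    """A simulated family plus its scored genotype matrix and ground truth."""

    design: FamilyDesign
    markers: Tuple[MarkerDef, ...]
    trait: TraitLocus
    individuals: List[Individual]
    genotypes: pd.DataFrame

    @property
    def progeny(self) -> List[Individual]:
        return [i for i in self.individuals if i.role == "progeny"]

    def truth_partition(self) -> Dict[str, int]:
        """Ground-truth linkage group per marker id."""
        return {m.id: m.group for m in self.markers}


def _score(ind: Individual, markers, layouts, locus_pos) -> Dict[str, str]:
    row: Dict[str, str] = {}
    for m in markers:
        g, i = locus_pos[m.id]
        a, b = int(ind.genome[g][0][i]), int(ind.genome[g][1][i])
        if m.kind == DOMINANT:
            row[m.id] = "present" if PRESENT in (a, b) else "absent"
        else:
            lo, hi = sorted((a, b))
            row[m.id] = f"{lo}/{hi}"
    return row


def simulate_family(
    design: FamilyDesign,
    markers: Sequence[MarkerDef],
    trait: TraitLocus,
    rmap: RecombMap,
) -> SimulatedFamily:
    """Simulate one family and score its genotype matrix.

    RNG contract: a single generator is seeded from ``design.seed``; draws
    occur in a fixed order (treated progeny first, then controls; within a
    progeny, groups in sorted order, maternal gamete before paternal,
    then the bioassay draw for treated progeny), so output is bit-identical
    across runs for a given seed.
    """
    layouts = build_layouts(markers, trait)
    rng = np.random.default_rng(design.seed)
    locus_pos = {
        lid: (g, i)
        for g, lay in layouts.items()
        for i, lid in enumerate(lay.locus_ids)
    }

    gp_res = _grandparent(layouts, "res", "male", "gp_res")
    gp_sus = _grandparent(layouts, "sus", "female", "gp_sus")
    if design.informative_sex == "female":
        mother = _f1_individual(layouts, "female", "f1_female")
        father = (
            _resline_individual(layouts, "male", "line_res_male")
            if design.cross == "backcross"
            else _f1_individual(layouts, "male", "f1_male")
        )
    else:
        father = _f1_individual(layouts, "male", "f1_male")
        mother = (
            _resline_individual(layouts, "female", "line_res_female")
            if design.cross == "backcross"
            else _f1_individual(layouts, "female", "f1_female")
        )

    groups = sorted(layouts)

    def make_progeny(ident: str) -> Individual:
        genome: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
        origin: Dict[int, int] = {}
        for g in groups:
            idx, mat = _draw_female(mother, g, rng)
            pat = meiosis_male(father, g, rmap, rng)
            genome[g] = (mat, pat)
            origin[g] = idx if mother.role == "F1" else -1
        ind = Individual(
            id=ident,
            sex="female" if rng.integers(2) else "male",
            role="progeny",
            genome=genome,
            maternal_origin=origin,
        )
        ind.trait_genotype = _trait_genotype(ind, trait, layouts)
        return ind

    individuals: List[Individual] = [gp_res, gp_sus, mother, father]
    treated: List[Individual] = []
    if design.n_survivor_target is not None:
        target = design.n_survivor_target
        survivors = 0
        max_draws = max(1000, 200 * max(target, 1))
        while survivors < target and len(treated) < max_draws:
            ind = make_progeny(f"{design.name}_t{len(treated) + 1:04d}")
            apply_bioassay(
                [ind], trait, rng, design.false_negative, design.false_positive
            )
            if ind.cohort == COHORT_SURVIVOR:
                survivors += 1
            treated.append(ind)
        if survivors < target:
            raise RuntimeError(
                f"{design.name}: only {survivors}/{target} survivors after "
                f"{len(treated)} treated progeny"
            )
    else:
        for k in range(design.n_treated):
            ind = make_progeny(f"{design.name}_t{k + 1:04d}")
            apply_bioassay(
                [ind], trait, rng, design.false_negative, design.false_positive
            )
            treated.append(ind)
    controls = []
    for k in range(design.n_control):
        ind = make_progeny(f"{design.name}_c{k + 1:04d}")
        ind.cohort = COHORT_CONTROL
        controls.append(ind)
    individuals.extend(treated)
    individuals.extend(controls)

    rows = []
    for ind in individuals:
        row = {"id": ind.id, "sex": ind.sex, "role": ind.role, "cohort": ind.cohort}
        row.update(_score(ind, markers, layouts, locus_pos))
        rows.append(row)
    genotypes = pd.DataFrame(rows)
    return SimulatedFamily(
        design=design,
        markers=tuple(markers),
        trait=trait,
        individuals=individuals,
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# Study-design panels
# ---------------------------------------------------------------------------


def f2301_panel(
    n_markers: int = 161,
    n_groups: int = 31,
    trait_group: int = 8,
) -> Tuple[List[MarkerDef], TraitLocus, RecombMap]:
    """Marker panel emulating family F2301: dominant AFLPs over 31 groups.

    Markers are spread round-robin over the groups; the band sits on the
    resistant-grandparent homolog for alternating markers so both phases
    occur.  The trait locus sits mid-group on ``trait_group`` (group 8 in
    the study).  Male-meiosis fractions are uniform 0.1 per interval (the
    backcross father is homozygous, so they do not affect scoring).
    """
    markers = []
    for i in range(n_markers):
        group = (i % n_groups) + 1
        position = 10 * (i // n_groups + 1)
        on_res = i % 2 == 0
        markers.append(
            MarkerDef(
                id=f"AFLP{i + 1:03d}",
                group=group,
                position=position,
                kind=DOMINANT,
                allele_res=PRESENT if on_res else ABSENT,
                allele_sus=ABSENT if on_res else PRESENT,
            )
        )
    trait = TraitLocus(group=trait_group, position=25)
    layouts = build_layouts(markers, trait)
    rmap = RecombMap.uniform(layouts, 0.1)
    return markers, trait, rmap


def f2301_design(
    seed: int, n_survivors: int = 29, n_control: int = 30
) -> FamilyDesign:
    """The female-informative backcross design of family F2301.

    Treated progeny are bioassayed until ``n_survivors`` homozygous-resistant
    survivors accumulate; 30 untreated controls match the study's 59
    genotyped progeny (29 survivors + 30 controls).
    """
    return FamilyDesign(
        name="F2301",
        informative_sex="female",
        cross="backcross",
        n_survivor_target=n_survivors,
        n_control=n_control,
        seed=seed,
    )


#: Codominant fragment sizes (resistant-line, susceptible-line) for the
#: chromosome-17 walk markers; the RpL22 sizes echo the study's 272/282 bp.
_MAPPING_SIZES = {
    "Bre-5": (331, 341),
    "RpL22": (272, 282),
    "RpS24": (214, 224),
}


def mapping_panel() -> Tuple[List[MarkerDef], TraitLocus, RecombMap]:
    """Male-informative mapping panel: Bre-5 -(0.16)- R -(0.10)- RpL22 -(0.06)- RpS24.

    One linkage group carrying the trait locus between Bre-5 and RpL22,
    with the adjacent recombination fractions of the study's preliminary
    map.
    """
    group = 1
    order = ["Bre-5", "RpL22", "RpS24"]
    positions = {"Bre-5": 10, "RpL22": 30, "RpS24": 40}
    markers = [
        MarkerDef(
            id=name,
            group=group,
            position=positions[name],
            kind=CODOMINANT,
            allele_res=_MAPPING_SIZES[name][0],
            allele_sus=_MAPPING_SIZES[name][1],
        )
        for name in order
    ]
    trait = TraitLocus(group=group, position=20)
    rmap = RecombMap({group: [0.16, 0.10, 0.06]})
    return markers, trait, rmap


def mapping_design(
    seed: int,
    n_survivors: int = 72,
    n_control: int = 20,
    cross: str = "backcross",
    name: str = "G2016",
) -> FamilyDesign:
    """A male-informative family: F1 father, rr-selected treated progeny."""
    return FamilyDesign(
        name=name,
        informative_sex="male",
        cross=cross,
        n_survivor_target=n_survivors,
        n_control=n_control,
        seed=seed,
    )
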