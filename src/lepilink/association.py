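"""Signed interaction chi-squared association of linkage groups with survival.

Each linkage group is tested on the 2x2 table of homolog class (resistant-
vs susceptible-grandparent maternal homolog) by treatment cohort
(bioassay survivors vs untreated controls).  The statistic is the Pearson
interaction chi-squared with one degree of freedom and no continuity
correction,

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),

carrying the sign of (ad - bc): positive when the resistant-grandparent
homolog is enriched among survivors.  Significance is judged against
Bonferroni-corrected thresholds over the number of groups tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import LinkageGroupAssignment
from .popsim import COHORT_CONTROL, COHORT_SURVIVOR, MISSING

__all__ = [
    "AssociationResult",
    "signed_interaction_chi2",
    "homolog_call",
    "anchor_marker_signs",
    "associate_groups",
    "plot_association",
]

RESISTANT = "resistant-homolog"
SUSCEPTIBLE = "susceptible-homolog"
AMBIGUOUS = "ambiguous"

DEFAULT_ALPHAS = (0.05, 0.005, 0.001)


def signed_interaction_chi2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Signed 2x2 interaction chi-squared (1 df, no continuity correction).

    Rows are cohorts (survivors a,b; controls c,d), columns homolog
    classes (resistant-grandparent a,c; susceptible b,d).  Returns the
    signed statistic and the two-sided p-value from the chi-squared
    distribution on its magnitude.  A zero margin leaves the statistic
    undefined and raises ValueError.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError(f"zero margin in table ({a}, {b}; {c}, {d})")
    cross = a * d - b * c
    magnitude = n * cross**2 / math.prod(margins)
    signed = math.copysign(magnitude, cross) if cross else 0.0
    return signed, float(stats.chi2.sf(magnitude, df=1))


def homolog_call(
    row: Mapping[str, str], marker_signs: Mapping[str, int]
) -> str:
    """Which maternal homolog a progeny carries, by majority vote.

    ``marker_signs[m]`` is +1 when the band of marker ``m`` rides the
    resistant-grandparent homolog, -1 when it rides the susceptible one.
    A present band therefore votes for the homolog of its sign; an absent
    band votes for the other.  Ties or zero informative calls are
    ambiguous.
    """
    score = 0
    n_votes = 0
    for m, sign in marker_signs.items():
        call = row.get(m, MISSING)
        if call == MISSING or call is None:
            continue
        if call not in ("present", "absent"):
            raise ValueError(f"marker {m}: unexpected call {call!r}")
        score += sign if call == "present" else -sign
        n_votes += 1
    if n_votes == 0 or score == 0:
        return AMBIGUOUS
    return RESISTANT if score > 0 else SUSCEPTIBLE


def anchor_marker_signs(
    matrix: pd.DataFrame,
    assignment: LinkageGroupAssignment,
    resistant_grandparent: str = "gp_res",
    susceptible_grandparent: str = "gp_sus",
) -> Dict[str, int]:
    """Orient each grouped marker's band to a grandparental homolog.

    A band present in the resistant grandparent and absent in the
    susceptible one rides the resistant homolog (+1), and vice versa (-1).
    Markers whose grandparent calls do not discriminate are oriented via
    their grouping phase relative to anchored group mates; a group with no
    anchored marker at all keeps its (arbitrary) grouping orientation.
    """
    rows = matrix.set_index("id")
    try:
        res_row = rows.loc[resistant_grandparent]
        sus_row = rows.loc[susceptible_grandparent]
    except KeyError as exc:
        raise ValueError(f"grandparent row missing from matrix: {exc}") from exc

    direct: Dict[str, Optional[int]] = {}
    for m in assignment.assignments:
        r, s = str(res_row[m]), str(sus_row[m])
        if r == "present" and s == "absent":
            direct[m] = 1
        elif r == "absent" and s == "present":
            direct[m] = -1
        else:
            direct[m] = None

    signs: Dict[str, int] = {}
    for g in assignment.reference_patterns:
        members = assignment.markers_of(g)
        phase = {m: 1 if assignment.assignments[m].phase == "+" else -1 for m in members}
        votes = [direct[m] * phase[m] for m in members if direct[m] is not None]
        orientation = 1 if not votes else (1 if sum(votes) >= 0 else -1)
        for m in members:
            signs[m] = direct[m] if direct[m] is not None else orientation * phase[m]
    return signs


@dataclass
class AssociationResult:
    """Per-group association of homolog class with bioassay survival."""

    group: int
    a: int  # survivors, resistant-grandparent homolog
    b: int  # survivors, susceptible-grandparent homolog
    c: int  # controls, resistant-grandparent homolog
    d: int  # controls, susceptible-grandparent homolog
    chi2_signed: float
    p: float
    n_ambiguous: int
    tested: bool = True
    significant: Dict[float, bool] = field(default_factory=dict)

    @property
    def sign(self) -> str:
        if not self.tested or self.chi2_signed == 0:
            return "0"
        return "+" if self.chi2_signed > 0 else "-"


def associate_groups(
    matrix: pd.DataFrame,
    assignment: LinkageGroupAssignment,
    resistant_grandparent: str = "gp_res",
    susceptible_grandparent: str = "gp_sus",
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> List[AssociationResult]:
    """Test every linkage group for association with bioassay survival.

    Homolog classes are called per individual by phase-adjusted majority
    vote over the group's markers; ambiguous individuals are excluded
    listwise per group.  Bonferroni thresholds use alpha/m with m the
    number of groups whose statistic is defined.
    """
    survivors = matrix[matrix["cohort"] == COHORT_SURVIVOR]
    controls = matrix[matrix["cohort"] == COHORT_CONTROL]
    if survivors.empty:
        raise ValueError("matrix has no treated-survivor cohort")
    if controls.empty:
        raise ValueError("matrix has no control cohort")

    signs = anchor_marker_signs(
        matrix, assignment, resistant_grandparent, susceptible_grandparent
    )

    def vote_scores(cohort_df: pd.DataFrame, members: List[str]) -> np.ndarray:
        # Vectorized tally of phase-adjusted votes: present = +sign,
        # absent = -sign, missing = 0; same rule as homolog_call.
        raw = cohort_df[members].to_numpy(dtype=object)
        votes = np.where(raw == "present", 1, np.where(raw == "absent", -1, 0))
        return votes @ np.array([signs[m] for m in members])

    results: List[AssociationResult] = []
    for g in sorted(assignment.reference_patterns):
        members = assignment.markers_of(g)
        counts = {"a": 0, "b": 0, "c": 0, "d": 0}
        n_ambiguous = 0
        for cohort_df, keys in ((survivors, ("a", "b")), (controls, ("c", "d"))):
            scores = vote_scores(cohort_df, members)
            counts[keys[0]] += int((scores > 0).sum())
            counts[keys[1]] += int((scores < 0).sum())
            n_ambiguous += int((scores == 0).sum())
        try:
            chi2_signed, p = signed_interaction_chi2(
                counts["a"], counts["b"], counts["c"], counts["d"]
            )
            tested = True
        except ValueError:
            chi2_signed, p, tested = float("nan"), float("nan"), False
        results.append(
            AssociationResult(
                group=g,
                a=counts["a"],
                b=counts["b"],
                c=counts["c"],
                d=counts["d"],
                chi2_signed=chi2_signed,
                p=p,
                n_ambiguous=n_ambiguous,
                tested=tested,
            )
        )

    m = sum(r.tested for r in results)
    for r in results:
        r.significant = {
            alpha: bool(r.tested and r.p <= alpha / m) for alpha in alphas
        }
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    alphas = sorted(results[0].significant, reverse=True) if results else []
    rows = []
    for r in results:
        row = {
            "group": r.group,
            "a": r.a,
            "b": r.b,
            "c": r.c,
            "d": r.d,
            "signed_chi2": r.chi2_signed,
            "p": r.p,
            "n_ambiguous": r.n_ambiguous,
        }
        for alpha in alphas:
            row[f"pass_{str(alpha).split('.')[1]}"] = r.significant[alpha]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_association(
    results: Sequence[AssociationResult],
    path: str,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> None:
    """Bar chart of signed chi-squared per linkage group with Bonferroni lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = sum(r.tested for r in results) or 1
    groups = [r.group for r in results]
    values = [0.0 if not r.tested else r.chi2_signed for r in results]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(groups, values, color="0.4")
    styles = ["-", "--", ":"]
    for alpha, ls in zip(alphas, styles):
        thr = float(stats.chi2.isf(alpha / m, df=1))
        ax.axhline(thr, ls=ls, color="k", lw=0.8, label=f"P = {alpha} (Bonferroni)")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("linkage group")
    ax.set_ylabel("signed interaction $\\chi^2$")
    ax.legend(fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
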