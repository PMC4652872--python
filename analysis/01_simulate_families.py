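"""Simulate the mapping families and write their genotype matrices.

Produces the female-informative backcross used for linkage-group
assignment (29 treated survivors + 30 untreated controls, 161 dominant
AFLP-style markers on 31 chromosomes) and three male-informative families
(72 rr-selected progeny in total) genotyped at codominant chromosome-walk
markers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_results, f2301_family, mapping_families

from lepilink import io, popsim


def main() -> None:
    results = ensure_results()

    family, markers, trait = f2301_family()
    io.write_genotype_table(family.genotypes, results / "f2301_genotypes.tsv")
    io.write_marker_table(markers, results / "f2301_markers.tsv")
    counts = family.genotypes["cohort"].value_counts()
    print(
        f"F2301-like family: {len(markers)} dominant markers on "
        f"{len({m.group for m in markers})} chromosomes; "
        f"{counts.get('treated-survivor', 0)} treated survivors, "
        f"{counts.get('control', 0)} controls "
        f"({counts.get('treated-dead', 0)} treated progeny died)."
    )

    families, mk, tr, _ = mapping_families()
    io.write_marker_table(mk, results / "walk_markers.tsv")
    io.write_phase_table(
        {m.id: m.allele_res for m in mk}, results / "walk_phase.tsv"
    )
    for name, fam in families.items():
        io.write_genotype_table(fam.genotypes, results / f"{name}_genotypes.tsv")
        n_sel = (fam.genotypes["cohort"] == "treated-survivor").sum()
        print(
            f"{name} ({fam.design.cross}, male-informative): "
            f"{n_sel} rr-selected progeny, {fam.design.n_control} controls."
        )
    print(f"Tables written under {results}/")


if __name__ == "__main__":
    main()
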