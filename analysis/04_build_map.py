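"""Estimate recombination fractions and order the chromosome-walk loci.

Pools trait-marker and marker-marker recombination estimates over the
three male-informative families (72 rr-selected progeny), orders the four
loci by minimum adjacent r-hat, and renders the genetic map chain with
Haldane distances.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_results, mapping_families

from lepilink import recombmap


def main() -> None:
    results = ensure_results()
    families, markers, trait, rmap = mapping_families()

    # trait-marker estimates per family, pooled by summed counts
    pooled = {}
    for marker in markers:
        per_family = [
            recombmap.estimate_r_trait_marker(
                fam.genotypes, marker, family=name
            )
            for name, fam in families.items()
        ]
        pooled[marker.id] = recombmap.pool_families(per_family)

    # marker-marker estimates from paternal haplotypes, pooled likewise
    phase = {m.id: (m.allele_res, m.allele_sus) for m in markers}
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            per_family = []
            for name, fam in families.items():
                paternal, _ = recombmap.infer_paternal_haplotypes(
                    fam.genotypes, markers
                )
                per_family.append(
                    recombmap.estimate_r_marker_marker(
                        paternal, a.id, b.id, phase, family=name
                    )
                )
            pooled[(a.id, b.id)] = recombmap.pool_families(per_family)

    rows = []
    pairwise = {}
    for est in pooled.values():
        rows.append(
            {
                "locus_a": est.locus_a,
                "locus_b": est.locus_b,
                "n": est.n_informative,
                "nrec": est.n_recombinant,
                "r": round(est.r, 4),
                "se": round(est.se, 4),
                "families": ";".join(
                    f"{k}:{v[1]}/{v[0]}" for k, v in est.per_family.items()
                ),
            }
        )
        pairwise[(est.locus_a, est.locus_b)] = est.r
    pd.DataFrame(rows).to_csv(results / "walk_estimates.tsv", sep="\t", index=False)

    gmap = recombmap.order_loci(pairwise)
    (results / "walk_map.txt").write_text(gmap.render() + "\n", encoding="utf-8")

    n_total = pooled[markers[0].id].n_informative
    print(f"Pooled {n_total} informative (paternal) meioses over "
          f"{len(families)} families.")
    for m in markers:
        est = pooled[m.id]
        print(
            f"  trait–{m.id}: r = {est.r:.3f} ± {est.se:.3f} "
            f"({est.n_recombinant}/{est.n_informative} recombinant)"
        )
    print(f"Locus order (min adjacent r-hat): {gmap.render()}")
    cm = [f"{d:.1f}" for d in gmap.haldane_distances()]
    print(f"Haldane distances (cM): {', '.join(cm)}")


if __name__ == "__main__":
    main()
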