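"""Annotate the three resistance INDEL alleles on the ABCA2-like CDS.

Applies the described edits to the synthetic 1,742-codon reference,
translates, and reports frameshifts, premature stops, and the protein
features lost downstream — all three alleles truncate the transporter
before the second nucleotide-binding fold (NBF2).  Also scans the
reference protein for N-glycosylation sequons.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_results

from lepilink import consequence, io


def main() -> None:
    results = ensure_results()
    cds = consequence.make_synthetic_abca2_cds()
    features = consequence.default_feature_table()
    edits = consequence.resistance_allele_edits()

    io.write_fasta([cds], results / "abca2_synthetic_cds.fasta")
    io.write_edits(edits, results / "abca2_edits.tsv")
    io.write_feature_table(features, results / "abca2_features.tsv")

    reference = consequence.translate(cds.sequence)
    print(
        f"Reference {cds.id}: {len(cds)} nt -> {len(reference.protein)} aa "
        f"(stop at codon {reference.stop_codon})."
    )

    reports = [consequence.classify_consequence(cds, e, features) for e in edits]
    io.write_consequence_reports(reports, results / "abca2_consequences.tsv")
    nbf2 = next(f for f in features if f.name == "NBF2")
    for r in reports:
        before = r.premature_stop is not None and r.premature_stop < nbf2.aa_start
        print(
            f"  {r.allele}: net {r.net_change:+d} bp, frame shift {r.frame_shift}, "
            f"first affected codon {r.first_affected_codon}, "
            f"stop at codon {r.premature_stop} -> {r.classification}; "
            f"{'truncates before NBF2' if before else 'NBF2 retained'} "
            f"({len(r.features_lost)} features lost)."
        )

    sequons = consequence.scan_sequons(reference.protein)
    print(f"N-glycosylation sequons (N-X-S/T, X != P) in the reference: "
          f"{len(sequons)} sites.")


if __name__ == "__main__":
    main()
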