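"""Umbrella pipeline: simulate -> group -> associate -> map -> annotate.

A configuration (YAML, see ``io.load_config``) selects stages and wires
their input/output paths.  Every run writes a structured log recording the
package version, resolved seed, and per-stage counts; a missing stage
dependency raises :class:`PipelineError` naming the absent artifact.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from . import __version__, association, consequence, grouping, io, popsim, recombmap

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger("lepilink")

STAGES = ("simulate", "group", "associate", "map", "annotate")


class PipelineError(RuntimeError):
    """A stage could not run (bad config or missing upstream artifact)."""


def _require(config: Dict, stage: str, key: str, produced: Dict[str, Path]) -> Path:
    """Resolve a stage input either from config paths or an upstream stage."""
    paths = config.get("paths", {})
    if key in produced:
        return produced[key]
    if key in paths:
        p = Path(paths[key])
        if not p.exists():
            raise PipelineError(f"stage '{stage}': input file {p} does not exist")
        return p
    raise PipelineError(
        f"stage '{stage}' requires '{key}': not in config paths and no "
        f"earlier stage produced it"
    )


def _panel(config: Dict):
    name = config.get("panel", "f2301")
    if name == "f2301":
        return popsim.f2301_panel()
    if name == "mapping":
        return popsim.mapping_panel()
    raise PipelineError(f"unknown panel {name!r} (expected 'f2301' or 'mapping')")


def _design(config: Dict, seed: int) -> popsim.FamilyDesign:
    fam = dict(config.get("family", {}))
    fam.setdefault("name", "demo")
    fam.setdefault("informative_sex", "female")
    fam.setdefault("cross", "backcross")
    fam["seed"] = seed
    return popsim.FamilyDesign(**fam)


def run_pipeline(
    config: Dict,
    out_prefix: str,
    seed: Optional[int] = None,
    stages: Optional[Sequence[str]] = None,
) -> Dict[str, Path]:
    """Execute the selected stages; returns the artifact paths written."""
    out = Path(out_prefix)
    out.parent.mkdir(parents=True, exist_ok=True)
    log_path = Path(f"{out_prefix}pipeline.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    resolved_seed = int(config.get("seed", 0) if seed is None else seed)
    selected = list(stages if stages is not None else config.get("stages", STAGES))
    unknown = [s for s in selected if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}")
    logger.info(
        "lepilink %s: stages=%s seed=%d out_prefix=%s",
        __version__, ",".join(selected), resolved_seed, out_prefix,
    )

    produced: Dict[str, Path] = {}
    try:
        if "simulate" in selected:
            _stage_simulate(config, out_prefix, resolved_seed, produced)
        if "group" in selected:
            _stage_group(config, out_prefix, produced)
        if "associate" in selected:
            _stage_associate(config, out_prefix, produced)
        if "map" in selected:
            _stage_map(config, out_prefix, produced)
        if "annotate" in selected:
            _stage_annotate(config, out_prefix, produced)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return produced


def _stage_simulate(config, out_prefix, seed, produced) -> None:
    markers, trait, rmap = _panel(config)
    design = _design(config, seed)
    family = popsim.simulate_family(design, markers, trait, rmap)
    produced["genotypes"] = Path(f"{out_prefix}genotypes.tsv")
    produced["markers"] = Path(f"{out_prefix}markers.tsv")
    io.write_genotype_table(family.genotypes, produced["genotypes"])
    io.write_marker_table(markers, produced["markers"])
    phase = {m.id: m.allele_res for m in markers if m.kind == popsim.CODOMINANT}
    if phase:
        produced["phase"] = Path(f"{out_prefix}phase.tsv")
        io.write_phase_table(phase, produced["phase"])
    n_surv = int((family.genotypes["cohort"] == popsim.COHORT_SURVIVOR).sum())
    logger.info(
        "simulate: family=%s markers=%d survivors=%d controls=%d",
        design.name, len(markers), n_surv, design.n_control,
    )


def _stage_group(config, out_prefix, produced) -> None:
    path = _require(config, "group", "genotypes", produced)
    matrix, n_masked = io.read_genotype_table(path)
    assignment = grouping.group_dominant_markers(
        matrix,
        max_mismatch=int(config.get("max_mismatch", 0)),
        min_progeny=int(config.get("min_progeny", 20)),
    )
    produced["assignment"] = Path(f"{out_prefix}assignment.tsv")
    produced["group_summary"] = Path(f"{out_prefix}group_summary.tsv")
    assignment.to_frame().to_csv(produced["assignment"], sep="\t", index=False)
    assignment.summary_frame().to_csv(produced["group_summary"], sep="\t", index=False)
    logger.info(
        "group: %d markers -> %d groups (%d excluded, %d unresolved, %d masked cells)",
        len(assignment.assignments), assignment.n_groups,
        len(assignment.excluded), len(assignment.unresolved), n_masked,
    )


def _stage_associate(config, out_prefix, produced) -> None:
    geno_path = _require(config, "associate", "genotypes", produced)
    matrix, _ = io.read_genotype_table(geno_path)
    assignment = _assignment_from_matrix(config, matrix)
    results = association.associate_groups(matrix, assignment)
    produced["association"] = Path(f"{out_prefix}association.tsv")
    association.results_to_frame(results).to_csv(
        produced["association"], sep="\t", index=False
    )
    if config.get("plot", False):
        produced["association_plot"] = Path(f"{out_prefix}association.png")
        association.plot_association(results, str(produced["association_plot"]))
    top = max((r for r in results if r.tested), key=lambda r: r.chi2_signed)
    logger.info(
        "associate: %d groups tested; top group %d signed chi2 %.2f (p=%.3g)",
        sum(r.tested for r in results), top.group, top.chi2_signed, top.p,
    )


def _assignment_from_matrix(config, matrix):
    return grouping.group_dominant_markers(
        matrix,
        max_mismatch=int(config.get("max_mismatch", 0)),
        min_progeny=int(config.get("min_progeny", 20)),
    )


def _stage_map(config, out_prefix, produced) -> None:
    geno_path = _require(config, "map", "genotypes", produced)
    marker_path = _require(config, "map", "markers", produced)
    phase_path = _require(config, "map", "phase", produced)
    matrix, _ = io.read_genotype_table(geno_path)
    markers = [
        m for m in io.read_marker_table(marker_path) if m.kind == popsim.CODOMINANT
    ]
    phase = io.read_phase_table(phase_path)
    if not markers:
        raise PipelineError("stage 'map': no codominant markers in panel")

    trait_ests = {}
    for m in markers:
        est = recombmap.estimate_r_trait_marker(
            matrix, m, r_linked_allele=phase.get(m.id, m.allele_res)
        )
        trait_ests[m.id] = est
    paternal, inconsistent = recombmap.infer_paternal_haplotypes(matrix, markers)
    f1_phase = {m.id: (m.allele_res, m.allele_sus) for m in markers}
    pair_ests = {}
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            pair_ests[(a.id, b.id)] = recombmap.estimate_r_marker_marker(
                paternal, a.id, b.id, f1_phase
            )

    rows = []
    pairwise = {}
    for est in list(trait_ests.values()) + list(pair_ests.values()):
        rows.append(
            {
                "locus_a": est.locus_a,
                "locus_b": est.locus_b,
                "n": est.n_informative,
                "nrec": est.n_recombinant,
                "r": est.r,
                "se": est.se,
                "unlinked": est.unlinked,
            }
        )
        pairwise[(est.locus_a, est.locus_b)] = est.r
    produced["estimates"] = Path(f"{out_prefix}estimates.tsv")
    pd.DataFrame(rows).to_csv(produced["estimates"], sep="\t", index=False)

    gmap = recombmap.order_loci(
        pairwise, exhaustive_max=int(config.get("exhaustive_max", 8))
    )
    produced["map"] = Path(f"{out_prefix}map.txt")
    produced["map"].write_text(gmap.render() + "\n", encoding="utf-8")
    logger.info(
        "map: %d loci ordered; %d pedigree inconsistencies; rendering %s",
        len(gmap.loci), len(inconsistent), gmap.render(),
    )


def _stage_annotate(config, out_prefix, produced) -> None:
    paths = config.get("paths", {})
    if config.get("synthetic_reference", False):
        cds = consequence.make_synthetic_abca2_cds()
        edits = list(consequence.resistance_allele_edits())
        features = list(consequence.default_feature_table())
    else:
        cds = io.read_fasta(_require(config, "annotate", "cds", produced))[0]
        edits = io.read_edits(_require(config, "annotate", "edits", produced))
        features = io.read_feature_table(
            _require(config, "annotate", "features", produced)
        )
    reports = [consequence.classify_consequence(cds, e, features) for e in edits]
    produced["consequences"] = Path(f"{out_prefix}consequences.tsv")
    io.write_consequence_reports(reports, produced["consequences"])
    logger.info(
        "annotate: %d alleles on %s; classifications %s",
        len(reports), cds.id, ",".join(r.classification for r in reports),
    )
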