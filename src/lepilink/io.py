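"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV with "NA" as the single missing token; sequences
are FASTA (wrapped at 60 columns on write).  Writers round-trip through
their readers.
"""

from __future__ import annotations

import re
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consequence import CdsEdit, CdsRecord, ConsequenceReport, ProteinFeature
from .popsim import MISSING, MarkerDef

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_table",
    "write_marker_table",
    "read_fasta",
    "write_fasta",
    "read_edits",
    "write_edits",
    "read_feature_table",
    "write_feature_table",
    "write_consequence_reports",
    "read_phase_table",
    "write_phase_table",
    "load_config",
]

PathLike = Union[str, Path]

REQUIRED_GENOTYPE_COLUMNS = ("id", "sex", "role", "cohort")
_VALID_CELL = re.compile(r"^(present|absent|NA|\d+/\d+)$")
_SIZE_LIKE = re.compile(r"/")


def write_genotype_table(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_genotype_table(path: PathLike) -> Tuple[pd.DataFrame, int]:
    """Read a genotype matrix; returns (matrix, n_unknown_tokens_masked).

    Marker cells must be 'present'/'absent', a size pair like '272/282',
    or 'NA'.  Tokens containing '/' that are not valid size pairs are
    malformed (error); any other unknown token is masked to NA and
    counted.  Duplicate individual ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype table missing columns {missing_cols}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate individual ids: {sorted(set(dupes))}")
    n_masked = 0
    marker_cols = [c for c in df.columns if c not in REQUIRED_GENOTYPE_COLUMNS]
    for col in marker_cols:
        values = df[col]
        bad = ~values.map(lambda v: bool(_VALID_CELL.match(v)))
        if bad.any():
            malformed = [v for v in values[bad] if _SIZE_LIKE.search(v)]
            if malformed:
                raise ValueError(
                    f"column {col}: malformed size pair(s) {sorted(set(malformed))[:3]}"
                )
            n_masked += int(bad.sum())
            df.loc[bad, col] = MISSING
    return df, n_masked


def write_marker_table(markers: Sequence[MarkerDef], path: PathLike) -> None:
    rows = [
        {
            "id": m.id,
            "group": m.group,
            "position": m.position,
            "kind": m.kind,
            "allele_A": m.allele_res,
            "allele_B": m.allele_sus,
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_table(path: PathLike) -> List[MarkerDef]:
    """Marker panel TSV: id, group, position, kind, allele_A, allele_B.

    allele_A is the allele on the resistant-grandparent homolog of the
    informative F1 parent; allele_B the susceptible-grandparent allele.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"id", "group", "position", "kind", "allele_A", "allele_B"}
    if not needed <= set(df.columns):
        raise ValueError(f"marker table missing columns {sorted(needed - set(df.columns))}")
    return [
        MarkerDef(
            id=str(r.id),
            group=int(r.group),
            position=int(r.position),
            kind=str(r.kind),
            allele_res=int(r.allele_A),
            allele_sus=int(r.allele_B),
        )
        for r in df.itertuples()
    ]


def read_fasta(path: PathLike, is_reference: bool = True) -> List[CdsRecord]:
    """Read CDS records; sequences are uppercased, CRLF tolerated."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id}")
        if "-" in seq:
            raise ValueError(f"record {rec.id}: gap characters not allowed")
        records.append(CdsRecord(id=rec.id, sequence=seq, is_reference=is_reference))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[CdsRecord], path: PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")  # wraps at 60 columns


def write_edits(edits: Sequence[CdsEdit], path: PathLike) -> None:
    rows = [
        {
            "allele": e.allele,
            "kind": e.kind,
            "start": e.start,
            "end": e.end,
            "insert_seq": e.insert or ".",
        }
        for e in edits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edits(path: PathLike) -> List[CdsEdit]:
    df = pd.read_csv(path, sep="\t", dtype={"insert_seq": str}, keep_default_na=False)
    return [
        CdsEdit(
            allele=str(r.allele),
            kind=str(r.kind),
            start=int(r.start),
            end=int(r.end),
            insert="" if r.insert_seq in (".", "") else str(r.insert_seq),
        )
        for r in df.itertuples()
    ]


def write_feature_table(features: Sequence[ProteinFeature], path: PathLike) -> None:
    rows = [asdict(f) for f in features]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_table(path: PathLike) -> List[ProteinFeature]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    features = [
        ProteinFeature(
            name=str(r.name),
            aa_start=int(r.aa_start),
            aa_end=int(r.aa_end),
            note=str(getattr(r, "note", "")),
        )
        for r in df.itertuples(index=False)
    ]
    names = [f.name for f in features]
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    return features


def write_consequence_reports(
    reports: Sequence[ConsequenceReport], path: PathLike
) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "allele": r.allele,
                "net_change_bp": r.net_change,
                "frame_shift": r.frame_shift,
                "first_affected_codon": r.first_affected_codon,
                "premature_stop_codon": (
                    r.premature_stop if r.premature_stop is not None else MISSING
                ),
                "protein_length": r.protein_length,
                "classification": r.classification,
                "features_lost": ";".join(f"{n}({w})" for n, w in r.features_lost)
                or MISSING,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_phase_table(phase: Mapping[str, int], path: PathLike) -> None:
    rows = [{"locus": k, "r_linked_allele": v} for k, v in phase.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phase_table(path: PathLike) -> Dict[str, int]:
    """Phase TSV: locus, r_linked_allele (the allele on the r-bearing homolog)."""
    df = pd.read_csv(path, sep="\t")
    if not {"locus", "r_linked_allele"} <= set(df.columns):
        raise ValueError("phase table needs columns locus, r_linked_allele")
    return {str(r.locus): int(r.r_linked_allele) for r in df.itertuples()}


def load_config(path: PathLike) -> Dict:
    """Load a YAML pipeline configuration into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"config {path} is not a mapping")
    return config
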