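"""CDS INDEL application, translation, and truncation consequence calling.

Applies described coding-sequence edits (deletion, insertion, replacement,
duplication) to an ABCA2-like reference CDS, translates with the standard
genetic code, detects frameshifts and premature stop codons, and maps the
truncation onto a protein feature table (transmembrane helices, ECD loops,
nucleotide-binding folds, transporter motifs).  Also scans for
N-glycosylation sequons (Asn-Xaa-Ser/Thr, Xaa != Pro).

Coordinates are 1-based inclusive on the CDS throughout, matching the
"nucleotides 3,127-3,131" style used when describing such alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "CdsRecord",
    "CdsEdit",
    "ProteinFeature",
    "TranslationResult",
    "ConsequenceReport",
    "codon_index",
    "apply_edit",
    "translate",
    "classify_consequence",
    "scan_sequons",
    "make_synthetic_abca2_cds",
    "default_feature_table",
    "resistance_allele_edits",
]

_DNA = set("ACGT")
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_STOPS = {"TAA", "TAG", "TGA"}

DELETION = "deletion"
INSERTION = "insertion"
REPLACEMENT = "replacement"
DUPLICATION = "duplication"

FRAMESHIFT_TRUNCATION = "frameshift-truncation"
IN_FRAME_INDEL = "in-frame-indel"
NONSENSE = "nonsense"
SILENT_BOUNDARY = "silent-boundary"


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what}: non-ACGT characters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class CdsRecord:
    """A start-to-stop reading frame; reference records end in a stop codon."""

    id: str
    sequence: str
    is_reference: bool = True

    def __post_init__(self) -> None:
        seq = _check_dna(self.sequence, f"CDS {self.id}")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 6:
            raise ValueError(f"CDS {self.id}: length {len(seq)} < 6")
        if self.is_reference:
            if len(seq) % 3:
                raise ValueError(f"CDS {self.id}: length not divisible by 3")
            if seq[-3:] not in _STOPS:
                raise ValueError(f"CDS {self.id}: reference must end in a stop codon")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsEdit:
    """A described INDEL on the CDS, 1-based inclusive coordinates.

    * deletion: remove ``start..end``;
    * insertion: place ``insert`` immediately after position ``start``
      (``end`` must equal ``start``);
    * replacement: remove ``start..end`` and place ``insert`` at the site;
    * duplication: ``start..end`` is the post-duplication interval of the
      inserted copy, i.e. a copy of the template occupying those positions
      immediately 5' of the site; ``insert``, if given, must equal it.
    """

    allele: str
    kind: str
    start: int
    end: int
    insert: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (DELETION, INSERTION, REPLACEMENT, DUPLICATION):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"{self.allele}: bad interval {self.start}..{self.end}")
        if self.insert:
            object.__setattr__(self, "insert", _check_dna(self.insert, self.allele))
        if self.kind == DELETION and self.insert:
            raise ValueError(f"{self.allele}: deletion carries an insert")
        if self.kind == INSERTION:
            if self.end != self.start:
                raise ValueError(f"{self.allele}: insertion interval must be a point")
            if not self.insert:
                raise ValueError(f"{self.allele}: insertion without sequence")

    @property
    def n_deleted(self) -> int:
        if self.kind in (DELETION, REPLACEMENT):
            return self.end - self.start + 1
        return 0

    def inserted_seq(self, reference: str) -> str:
        """The inserted sequence (for duplications, the template copy)."""
        if self.kind == DUPLICATION:
            span = self.end - self.start + 1
            t_start, t_end = self.start - span, self.start - 1
            if t_start < 1:
                raise ValueError(f"{self.allele}: duplication template out of bounds")
            template = reference[t_start - 1 : t_end]
            if self.insert and self.insert != template:
                raise ValueError(
                    f"{self.allele}: stated duplication {self.insert} does not "
                    f"match template {template} at {t_start}..{t_end}"
                )
            return template
        if self.kind == DELETION:
            return ""
        return self.insert

    @property
    def first_changed_position(self) -> int:
        """Lowest reference-frame nucleotide position the edit touches."""
        if self.kind == INSERTION:
            return self.start + 1
        return self.start


@dataclass(frozen=True)
class ProteinFeature:
    """A named amino-acid interval (1-based inclusive) on the protein."""

    name: str
    aa_start: int
    aa_end: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.aa_start < 1 or self.aa_end < self.aa_start:
            raise ValueError(f"{self.name}: bad interval {self.aa_start}..{self.aa_end}")


def codon_index(nt_position: int) -> int:
    """Codon number holding a 1-based CDS nucleotide position."""
    if nt_position < 1:
        raise ValueError("CDS positions are 1-based")
    return (nt_position - 1) // 3 + 1


def apply_edit(cds: CdsRecord, edit: CdsEdit) -> str:
    """Apply one edit; output length = input - deleted + inserted."""
    seq = cds.sequence
    if edit.end > len(seq):
        raise ValueError(
            f"{edit.allele}: interval {edit.start}..{edit.end} exceeds CDS "
            f"length {len(seq)}"
        )
    if edit.kind == INSERTION:
        return seq[: edit.start] + edit.insert + seq[edit.start :]
    if edit.kind == DUPLICATION:
        copy = edit.inserted_seq(seq)
        site = edit.start - 1  # insert after the template's last base
        return seq[:site] + copy + seq[site:]
    # deletion / replacement: remove the closed interval, insert at the site
    return seq[: edit.start - 1] + edit.insert + seq[edit.end :]


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    stop_codon: Optional[int]  # codon index of the first stop, 1-based
    has_stop: bool


def translate(sequence: str) -> TranslationResult:
    """Standard-code frame-1 translation up to (not including) the first stop."""
    seq = _check_dna(sequence, "sequence")
    if len(seq) < 3:
        raise ValueError("need at least one codon")
    usable = len(seq) - len(seq) % 3
    protein_full = str(Seq(seq[:usable]).translate())
    stop = protein_full.find("*")
    if stop == -1:
        return TranslationResult(protein=protein_full, stop_codon=None, has_stop=False)
    return TranslationResult(
        protein=protein_full[:stop], stop_codon=stop + 1, has_stop=True
    )


@dataclass(frozen=True)
class ConsequenceReport:
    """Translated consequence of one edit, mapped onto protein features."""

    allele: str
    net_change: int  # inserted - deleted, bp
    frame_shift: int  # (deleted - inserted) mod 3; 0 = in frame
    first_affected_codon: int
    premature_stop: Optional[int]  # codon index, or None
    protein_length: int
    features_lost: Tuple[Tuple[str, str], ...]  # (name, "whole" | "partial")
    classification: str


def classify_consequence(
    cds: CdsRecord,
    edit: CdsEdit,
    features: Sequence[ProteinFeature] = (),
) -> ConsequenceReport:
    """Frameshift/stop consequence of an edit, with lost protein features.

    The frame shift is ``(deleted - inserted) mod 3`` — the phase by which
    the downstream reading frame leads the reference.  A stop is premature
    when its codon index falls below the reference stop's.  A feature is
    lost wholly when it lies entirely at/after the premature stop, and
    partly when the stop lands inside it.
    """
    ref = translate(cds.sequence)
    inserted = edit.inserted_seq(cds.sequence)
    edited_seq = apply_edit(cds, edit)
    edited = translate(edited_seq)

    net = len(inserted) - edit.n_deleted
    frame_shift = (edit.n_deleted - len(inserted)) % 3
    first_codon = codon_index(edit.first_changed_position)

    ref_stop = ref.stop_codon if ref.has_stop else len(ref.protein) + 1
    premature = (
        edited.stop_codon
        if edited.has_stop and edited.stop_codon < ref_stop
        else None
    )

    lost: List[Tuple[str, str]] = []
    if premature is not None:
        for f in features:
            if f.aa_end > len(ref.protein):
                raise ValueError(
                    f"feature {f.name} exceeds protein length {len(ref.protein)}"
                )
            if f.aa_start >= premature:
                lost.append((f.name, "whole"))
            elif f.aa_end >= premature:
                lost.append((f.name, "partial"))

    if net == 0 and not edit.n_deleted and not inserted:
        classification = SILENT_BOUNDARY
    elif frame_shift != 0:
        classification = FRAMESHIFT_TRUNCATION
    elif premature is not None:
        classification = NONSENSE
    else:
        classification = IN_FRAME_INDEL

    return ConsequenceReport(
        allele=edit.allele,
        net_change=net,
        frame_shift=frame_shift,
        first_affected_codon=first_codon,
        premature_stop=premature,
        protein_length=len(edited.protein),
        features_lost=tuple(lost),
        classification=classification,
    )


_SEQUON = re.compile(r"(?=N[^P][ST])")


def scan_sequons(protein: str) -> List[int]:
    """1-based positions of N-glycosylation sequons N-X-S/T with X != P."""
    protein = protein.upper()
    bad = set(protein) - _AA20
    if bad:
        raise ValueError(f"non-standard amino acids {sorted(bad)}")
    return [m.start() + 1 for m in _SEQUON.finditer(protein)]


# ---------------------------------------------------------------------------
# Synthetic ABCA2-like reference fixture
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

#: The 73-bp segment deleted by the R01 allele (CDS nt 2,889-2,961).
R01_DELETED_SEGMENT = (
    "GCTAGGAGTTCTGCGTTACGTCATGTCTTTATCACCAACCATTAGAACTAGGTGGTTGTCGTTGGAAGAAGGG"
)
#: The 5-bp segment deleted by the R02 allele (CDS nt 3,127-3,131).
R02_DELETED_SEGMENT = "ACAAG"
#: The 5-bp template duplicated by the R03 allele (CDS nt 4,099-4,103).
R03_TEMPLATE = "GAATA"


def make_synthetic_abca2_cds(n_codons: int = 1742, seed: int = 2015) -> CdsRecord:
    """A synthetic reference CDS with ABCA2's dimensions.

    1,742 sense codons plus a terminal TAA (5,229 nt for the default),
    starting with ATG and free of internal stops.  Random codons are
    overwritten with the described local sequences at the three mutation
    sites (the 73-bp R01 segment at nt 2,889-2,961, ACAAG at 3,127-3,131,
    GAATA at 4,099-4,103), so the R01 replacement reproduces the
    documented Leu->Gly at codon 964 followed by a stop at codon 965.
    Elsewhere the sequence is a synthetic stand-in sized like the real
    transcript; a real CDS FASTA can be substituted without code change.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    codons += [
        _NONSTOP_CODONS[i]
        for i in rng.integers(len(_NONSTOP_CODONS), size=n_codons - 1)
    ]
    codons.append("TAA")
    seq = list("".join(codons))

    if n_codons >= 1380:  # room for all three documented sites
        def plant(pos: int, segment: str) -> None:
            seq[pos - 1 : pos - 1 + len(segment)] = segment

        plant(2889, R01_DELETED_SEGMENT)
        plant(3127, R02_DELETED_SEGMENT)
        plant(4099, R03_TEMPLATE)
        # Codon 1368 starts TA...: keep its third base pyrimidine so the
        # reference carries no in-frame stop there.
        seq[4103] = "T"
        # Codon 963 ends in the planted G; dodge a chance TAG.
        if "".join(seq[2886:2889]) in _STOPS:
            seq[2886:2888] = "CT"

    record = CdsRecord(id=f"ABCA2-synthetic-{n_codons}aa", sequence="".join(seq))
    if translate(record.sequence).stop_codon != n_codons + 1:
        raise AssertionError("synthetic CDS builder produced an internal stop")
    return record


def default_feature_table() -> Tuple[ProteinFeature, ...]:
    """Approximate ABCA2 feature intervals on the 1,742-aa protein.

    Two six-helix transmembrane domains with large extracellular loops
    after TM I and TM VII, NBF1 (with TpM1) between the domains, and NBF2
    (with TpM2) after TM XII.  Interval placement is synthetic but honours
    the published topology: the ECD2 loop spans the first two mutation
    sites (aa 964 and 1,043), TM XII ends one residue before aa 1,368, and
    NBF2 starts downstream of all three premature stops.
    """
    return (
        ProteinFeature("TM I", 40, 62),
        ProteinFeature("ECD1", 63, 560, "extracellular loop 1"),
        ProteinFeature("TM II", 561, 583),
        ProteinFeature("TM III", 600, 622),
        ProteinFeature("TM IV", 640, 662),
        ProteinFeature("TM V", 680, 702),
        ProteinFeature("TM VI", 720, 742),
        ProteinFeature("NBF1", 780, 940, "nucleotide-binding fold 1"),
        ProteinFeature("TpM1", 900, 914, "transporter motif 1"),
        ProteinFeature("TM VII", 945, 960),
        ProteinFeature("ECD2", 961, 1149, "extracellular loop 2"),
        ProteinFeature("TM VIII", 1150, 1172),
        ProteinFeature("TM IX", 1190, 1212),
        ProteinFeature("TM X", 1230, 1252),
        ProteinFeature("TM XI", 1280, 1302),
        ProteinFeature("TM XII", 1345, 1366),
        ProteinFeature("NBF2", 1400, 1650, "nucleotide-binding fold 2"),
        ProteinFeature("TpM2", 1550, 1564, "transporter motif 2"),
    )


def resistance_allele_edits() -> Tuple[CdsEdit, ...]:
    """The three described resistance INDELs of the ABCA2 CDS.

    R01: 73-bp deletion at nt 2,889-2,961 replaced by the 8-bp intron-derived
    insert CGGTTAAG (net -65); R02: 5-bp ACAAG deletion at nt 3,127-3,131;
    R03: 5-bp GAATA duplication whose inserted copy occupies nt 4,104-4,108.
    """
    return (
        CdsEdit("Ha2Ab-R01", REPLACEMENT, 2889, 2961, "CGGTTAAG"),
        CdsEdit("Ha2Ab-R02", DELETION, 3127, 3131),
        CdsEdit("Ha2Ab-R03", DUPLICATION, 4104, 4108, "GAATA"),
    )
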