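"""Domain types and disk formats for functional-gene reference databases.

A reference database couples gene families (short symbols such as ``phoD``,
each attached to a metabolic process) with two kinds of protein records:
*representatives*, which carry a family label and whose best hits yield
annotations, and *homologues*, decoy sequences related to but distinct from
the target families whose best hits veto an annotation.  On disk a database
is one protein FASTA plus one tab-separated id map; hit tables follow the
12-column BLAST tabular convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AA_ALPHABET",
    "DEFAULT_PROCESSES",
    "HOMOLOGUE_TOKEN",
    "UNASSIGNED",
    "GeneFamily",
    "RefSeqRecord",
    "ReferenceDatabase",
    "AlignmentHit",
    "FilterParams",
    "Annotation",
    "read_fasta",
    "write_fasta",
    "read_db",
    "write_db",
    "read_hits",
    "write_hits",
    "write_profile",
    "read_profile",
]

#: 20 standard amino acids plus the ambiguity letter X.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Reserved family token marking decoy records in an id map.
HOMOLOGUE_TOKEN = "homologue"

#: Family value of a query that received no annotation.
UNASSIGNED = "UNASSIGNED"

#: The ten phosphorus metabolic processes plus a catch-all bucket.
DEFAULT_PROCESSES = (
    "two-component system",
    "transporters",
    "organic phosphoester hydrolysis",
    "pyruvate metabolism",
    "pentose phosphate pathway",
    "phosphotransferase system",
    "oxidative phosphorylation",
    "phosphonate and phosphinate metabolism",
    "purine metabolism",
    "pyrimidine metabolism",
    "others",
)


@dataclass(frozen=True)
class GeneFamily:
    """One gene family: a short symbol tied to a metabolic process."""

    name: str
    process: str = "others"
    description: str = ""
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene family name must be non-empty")


@dataclass(frozen=True)
class RefSeqRecord:
    """One database protein: a family representative or a homologue decoy."""

    id: str
    sequence: str
    role: str  # "representative" | "homologue"
    family: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.role not in ("representative", "homologue"):
            raise ValueError(f"record {self.id!r}: unknown role {self.role!r}")
        if self.role == "representative" and not self.family:
            raise ValueError(f"representative {self.id!r} lacks a family")
        if self.role == "homologue" and self.family is not None:
            raise ValueError(f"homologue {self.id!r} must not carry a family")


class ReferenceDatabase:
    """Families plus records, with the structural invariants enforced.

    Invariants: every representative's family is declared, every family has
    at least one representative, record ids are unique, and every family
    process is drawn from the declared process list.
    """

    def __init__(
        self,
        families: Iterable[GeneFamily],
        records: Iterable[RefSeqRecord],
        name: str = "phoscyc-db",
        version: str = "0",
        parameters: dict | None = None,
        processes: Sequence[str] = DEFAULT_PROCESSES,
    ) -> None:
        self.families: dict[str, GeneFamily] = {}
        for fam in families:
            if fam.name in self.families:
                raise ValueError(f"duplicate family {fam.name!r}")
            if fam.process not in processes:
                raise ValueError(
                    f"family {fam.name!r}: process {fam.process!r} not in the "
                    "declared process list"
                )
            self.families[fam.name] = fam
        self.records: dict[str, RefSeqRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise ValueError(f"duplicate record id {rec.id!r}")
            if rec.role == "representative" and rec.family not in self.families:
                raise ValueError(
                    f"representative {rec.id!r} references unknown family "
                    f"{rec.family!r}"
                )
            self.records[rec.id] = rec
        covered = {r.family for r in self.records.values() if r.role == "representative"}
        missing = set(self.families) - covered
        if missing:
            raise ValueError(
                f"families without a representative: {sorted(missing)}"
            )
        self.name = name
        self.version = version
        self.parameters = dict(parameters or {})
        self.processes = tuple(processes)

    # -- views ------------------------------------------------------------
    @property
    def representatives(self) -> list[RefSeqRecord]:
        return [r for r in self.records.values() if r.role == "representative"]

    @property
    def homologues(self) -> list[RefSeqRecord]:
        return [r for r in self.records.values() if r.role == "homologue"]

    def members(self, family: str) -> list[RefSeqRecord]:
        """Representatives of one family."""
        if family not in self.families:
            raise KeyError(f"unknown family {family!r}")
        return [r for r in self.representatives if r.family == family]

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ReferenceDatabase {self.name!r}: {len(self.families)} families, "
            f"{len(self.representatives)} representatives, "
            f"{len(self.homologues)} homologues>"
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One homology-search result row (BLAST tabular, 12 columns).

    Coordinates are 1-based inclusive, matching the BLAST convention.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")


@dataclass(frozen=True)
class FilterParams:
    """Best-hit acceptance thresholds (all inclusive).

    Defaults follow the published annotation contract: identity >= 30.0 %,
    hit length >= 25 aa, e-value <= 1e-5.  The genome-annotation preset
    raises ``min_identity`` to 70.0.
    """

    min_identity: float = 30.0
    min_aln_len: int = 25
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity outside [0, 100]")
        if self.min_aln_len < 1:
            raise ValueError("min_aln_len must be >= 1")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")

    @classmethod
    def genome_preset(cls) -> "FilterParams":
        """Stricter identity gate suited to annotating whole genomes."""
        return cls(min_identity=70.0, min_aln_len=25, max_evalue=1e-5)


@dataclass(frozen=True)
class Annotation:
    """Per-query family call with the reason for any rejection."""

    query_id: str
    family: str = UNASSIGNED
    best_hit: AlignmentHit | None = None
    rejection_reason: str = "none"  # none | no_hit | failed_filter | homologue_hit

    def __post_init__(self) -> None:
        assigned = self.family != UNASSIGNED
        if assigned != (self.rejection_reason == "none"):
            raise ValueError(
                f"annotation {self.query_id!r}: family/rejection_reason mismatch"
            )
        if assigned and self.best_hit is None:
            raise ValueError(f"annotation {self.query_id!r}: assigned without a hit")

    @property
    def assigned(self) -> bool:
        return self.family != UNASSIGNED


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into ``[(id, sequence), ...]`` in file order.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased.  Terminal stop codons (``*``) are stripped; internal stops
    or letters outside the amino-acid alphabet are rejected with the record
    id in the message, as are duplicate ids and empty files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"record {rid!r}: empty sequence")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rid!r}: invalid characters {sorted(bad)} in sequence"
            )
        out.append((rid, seq))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Reference-database disk layout: FASTA + TSV id map
# ---------------------------------------------------------------------------

def read_db(
    fasta_path: str | Path,
    idmap_path: str | Path | None = None,
    homologue_token: str = HOMOLOGUE_TOKEN,
    header_delimiter: str | None = None,
    processes: Sequence[str] = DEFAULT_PROCESSES,
) -> ReferenceDatabase:
    """Load a reference database from a FASTA plus an id→family TSV map.

    The map has a header row and columns ``id``, ``family`` and optionally
    ``process``; the reserved ``homologue_token`` in the family column marks
    decoys.  As a compatibility fallback for releases that encode the family
    directly in sequence identifiers, ``header_delimiter`` (e.g. ``"|"``)
    derives the family from the last delimited id field instead of a map.
    """
    seqs = read_fasta(fasta_path)
    fam_of: dict[str, str] = {}
    proc_of: dict[str, str] = {}
    if idmap_path is not None:
        df = pd.read_csv(idmap_path, sep="\t", dtype=str)
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError("id map must have at least id and family columns")
        id_col, fam_col = cols[0], cols[1]
        if df[id_col].duplicated().any():
            dup = df[id_col][df[id_col].duplicated()].iloc[0]
            raise ValueError(f"duplicate id map row for {dup!r}")
        for _, row in df.iterrows():
            fam_of[row[id_col]] = row[fam_col]
            if len(cols) >= 3 and pd.notna(row[cols[2]]):
                proc_of[row[fam_col]] = row[cols[2]]
        missing = set(fam_of) - {i for i, _ in seqs}
        if missing:
            raise ValueError(
                f"id map references ids absent from FASTA: {sorted(missing)[:5]}"
            )
    elif header_delimiter is not None:
        for rid, _ in seqs:
            if header_delimiter not in rid:
                raise ValueError(
                    f"id {rid!r} lacks the family delimiter {header_delimiter!r}"
                )
            fam_of[rid] = rid.rsplit(header_delimiter, 1)[1]
    else:
        raise ValueError("either idmap_path or header_delimiter is required")

    records: list[RefSeqRecord] = []
    fam_names: set[str] = set()
    for rid, seq in seqs:
        if rid not in fam_of:
            raise ValueError(f"FASTA id {rid!r} absent from the id map")
        fam = fam_of[rid]
        if fam == homologue_token:
            records.append(RefSeqRecord(rid, seq, role="homologue"))
        else:
            records.append(RefSeqRecord(rid, seq, role="representative", family=fam))
            fam_names.add(fam)
    families = [
        GeneFamily(name, process=proc_of.get(name, "others")) for name in sorted(fam_names)
    ]
    return ReferenceDatabase(families, records, processes=processes)


def write_db(db: ReferenceDatabase, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a database as ``db.faa`` + ``db.idmap.tsv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "db.faa"
    idmap = out / "db.idmap.tsv"
    ordered = sorted(db.records.values(), key=lambda r: r.id)
    write_fasta(((r.id, r.sequence) for r in ordered), fasta)
    rows = []
    for r in ordered:
        fam = r.family if r.role == "representative" else HOMOLOGUE_TOKEN
        proc = db.families[r.family].process if r.role == "representative" else ""
        rows.append((r.id, fam, proc))
    pd.DataFrame(rows, columns=["id", "family", "process"]).to_csv(
        idmap, sep="\t", index=False
    )
    return fasta, idmap


# ---------------------------------------------------------------------------
# BLAST tabular hit files
# ---------------------------------------------------------------------------

_HIT_FIELDS = (
    ("query_id", str), ("subject_id", str), ("identity", float),
    ("aln_len", int), ("mismatches", int), ("gap_opens", int),
    ("q_start", int), ("q_end", int), ("s_start", int), ("s_end", int),
    ("evalue", float), ("bitscore", float),
)


def read_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column BLAST tabular file; an empty file yields []."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            kwargs = {}
            for (name, conv), raw in zip(_HIT_FIELDS, parts):
                try:
                    kwargs[name] = conv(raw)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse field {name!r} "
                        f"from {raw!r}"
                    ) from exc
            hits.append(AlignmentHit(**kwargs))
    return hits


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits back out as 12-column BLAST tabular text."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:g}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# Abundance profiles (family x sample TSV)
# ---------------------------------------------------------------------------

def write_profile(profile, path: str | Path) -> None:
    """Serialize an abundance profile as a family x sample TSV.

    Rows (families) and columns (samples) are written in lexicographic
    order so output is deterministic.  ``profile`` is an
    :class:`~phoscyc.annotator.AbundanceProfile` or a plain DataFrame.
    """
    df = profile.matrix if hasattr(profile, "matrix") else profile
    df = df.sort_index().sort_index(axis=1)
    df.to_csv(path, sep="\t", index_label="family")


def read_profile(path: str | Path) -> pd.DataFrame:
    """Read back a profile TSV into a family x sample DataFrame."""
    return pd.read_csv(path, sep="\t", index_col="family")
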