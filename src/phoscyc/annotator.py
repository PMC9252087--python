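"""Best-hit annotation under identity / hit-length / e-value filters, and
gene-family abundance as read coverage per gigabase.

Annotation is single-label: only the best hit per query is considered.  A
best hit that lands on a homologue decoy is a terminal rejection even when
a lower-ranked hit to a representative would have passed the filters —
that veto is exactly the false-positive control the decoys exist for.

Family abundance for one sample is

    coverage = sum over the family's ORFs of (N * l / L) / S

with N the reads mapped to the ORF, L the ORF length in nucleotides, l the
read length in bases (a per-sample constant) and S the sample's sequencing
size in gigabases (total sequenced bases / 1e9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dbmodel import (
    UNASSIGNED,
    AlignmentHit,
    Annotation,
    FilterParams,
    ReferenceDatabase,
)

__all__ = [
    "ReadMapping",
    "AbundanceProfile",
    "filter_hits",
    "hit_passes",
    "assign_families",
    "coverage",
    "profile",
    "read_mappings_tsv",
    "write_mappings_tsv",
]


@dataclass(frozen=True)
class ReadMapping:
    """Read-mapping statistics for one ORF in one sample."""

    sample: str
    orf_id: str
    n_reads: int      # N: reads mapped to the ORF
    orf_len: int      # L: ORF length, nucleotides
    read_len: float   # l: read length, bases (per-sample constant)
    gigabases: float  # S: sample sequencing size, Gb

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("read count must be >= 0")
        if self.orf_len <= 0:
            raise ValueError("ORF length must be > 0")
        if self.read_len <= 0:
            raise ValueError("read length must be > 0")
        if self.gigabases <= 0:
            raise ValueError("sequencing size must be > 0")

    @property
    def depth_per_gb(self) -> float:
        """This ORF's contribution: (N * l / L) / S."""
        return (self.n_reads * self.read_len / self.orf_len) / self.gigabases


@dataclass
class AbundanceProfile:
    """Family x sample coverage matrix plus per-sample read metadata."""

    matrix: pd.DataFrame
    sample_meta: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if vals.size and (not (vals >= 0).all() or not pd.notna(vals).all()):
            raise ValueError("coverages must be finite and >= 0")


def hit_passes(hit: AlignmentHit, params: FilterParams) -> bool:
    """Inclusive thresholds: identity >=, aligned length >=, e-value <=."""
    return (
        hit.identity >= params.min_identity
        and hit.aln_len >= params.min_aln_len
        and hit.evalue <= params.max_evalue
    )


def filter_hits(
    hits: Iterable[AlignmentHit], params: FilterParams
) -> list[AlignmentHit]:
    """Keep exactly the hits passing all three gates, order preserved."""
    return [h for h in hits if hit_passes(h, params)]


def assign_families(
    hits: Sequence[AlignmentHit],
    db: ReferenceDatabase,
    params: FilterParams | None = None,
    query_ids: Sequence[str] | None = None,
) -> list[Annotation]:
    """Turn best hits into per-query family calls.

    ``hits`` must already be best-hit reduced (one row per query).  Each
    query resolves to exactly one of four outcomes: the subject's family;
    ``failed_filter`` when the best hit misses a threshold; ``homologue_hit``
    when the (filter-passing) best hit lands on a decoy; or ``no_hit``.
    Queries with no hit row are only reported when ``query_ids`` supplies
    the full query universe.
    """
    params = params or FilterParams()
    seen: set[str] = set()
    annotations: list[Annotation] = []
    for hit in hits:
        if hit.query_id in seen:
            raise ValueError(f"multiple hits for query {hit.query_id!r}; "
                             "reduce to best hits first")
        seen.add(hit.query_id)
        if hit.subject_id not in db.records:
            raise KeyError(
                f"hit subject {hit.subject_id!r} absent from the database"
            )
        subject = db.records[hit.subject_id]
        if not hit_passes(hit, params):
            annotations.append(
                Annotation(hit.query_id, UNASSIGNED, hit, "failed_filter")
            )
        elif subject.role == "homologue":
            annotations.append(
                Annotation(hit.query_id, UNASSIGNED, hit, "homologue_hit")
            )
        else:
            annotations.append(Annotation(hit.query_id, subject.family, hit, "none"))
    if query_ids is not None:
        for qid in query_ids:
            if qid not in seen:
                annotations.append(Annotation(qid, UNASSIGNED, None, "no_hit"))
    return annotations


def coverage(mappings: Iterable[ReadMapping]) -> float:
    """Summed per-ORF read depth per gigabase for one family in one sample."""
    return sum(m.depth_per_gb for m in mappings)


def profile(
    annotations: Sequence[Annotation],
    mappings: Sequence[ReadMapping],
    families: Iterable[str] | None = None,
) -> AbundanceProfile:
    """Aggregate ORF coverages into a family x sample abundance matrix.

    Each cell (f, s) sums the coverage of sample s's ORFs annotated to
    family f.  Unassigned ORFs are excluded; families that received no ORF
    get 0.  Duplicate (orf, sample) mapping rows are an error.
    """
    seen_pairs: set[tuple[str, str]] = set()
    for m in mappings:
        key = (m.orf_id, m.sample)
        if key in seen_pairs:
            raise ValueError(f"duplicate mapping row for ORF {m.orf_id!r} "
                             f"in sample {m.sample!r}")
        seen_pairs.add(key)
    fam_of = {a.query_id: a.family for a in annotations if a.assigned}
    fam_index = sorted(set(families) if families is not None else set(fam_of.values()))
    samples = sorted({m.sample for m in mappings})
    mat = pd.DataFrame(0.0, index=fam_index, columns=samples)
    meta: dict[str, dict[str, float]] = {}
    for m in mappings:
        meta.setdefault(m.sample, {"read_len": m.read_len, "gigabases": m.gigabases})
        fam = fam_of.get(m.orf_id)
        if fam is None or fam not in mat.index:
            continue
        mat.loc[fam, m.sample] += m.depth_per_gb
    mat.index.name = "family"
    return AbundanceProfile(mat, meta)


# ---------------------------------------------------------------------------
# Mapping TSV io: columns sample, orf_id, N, L, l, S
# ---------------------------------------------------------------------------

_MAPPING_COLS = ["sample", "orf_id", "N", "L", "l", "S"]


def read_mappings_tsv(path: str | Path) -> list[ReadMapping]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MAPPING_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"mapping TSV missing columns {missing}")
    return [
        ReadMapping(str(r["sample"]), str(r["orf_id"]), int(r["N"]),
                    int(r["L"]), float(r["l"]), float(r["S"]))
        for _, r in df.iterrows()
    ]


def write_mappings_tsv(mappings: Iterable[ReadMapping], path: str | Path) -> None:
    rows = [
        (m.sample, m.orf_id, m.n_reads, m.orf_len, m.read_len, m.gigabases)
        for m in mappings
    ]
    pd.DataFrame(rows, columns=_MAPPING_COLS).to_csv(path, sep="\t", index=False)
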