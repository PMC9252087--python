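"""Deterministic synthetic fixtures with the statistical structure the
pipeline assumes: gene families with controlled within-family divergence,
near-threshold homologue decoys, unrelated true-negative families, mock
genomes with known family content, and read-mapping tables that invert the
coverage formula exactly.

All generators are pure functions of a :class:`SynthSpec`: the stream for
each artefact is seeded from ``(spec.seed, artefact, index)``, so e.g.
``make_decoys(spec, fam)`` regenerates the same family ancestor that
``make_families(spec)`` used without shared state.

The mutation model is substitution-only by default, so target identities
are analytically controllable: two sequences independently mutated from a
common ancestor at rates d1 and d2 match at a position with probability
(1-d1)(1-d2) + d1*d2/19 (a substituted letter is drawn uniformly from the
19 alternatives).  An indel-rate knob exists but defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotator import ReadMapping
from .dbmodel import (
    DEFAULT_PROCESSES,
    GeneFamily,
    RefSeqRecord,
    ReferenceDatabase,
)
from .validator import TruthLabel

__all__ = [
    "AMINO_ACIDS",
    "SynthSpec",
    "random_protein",
    "mutate",
    "make_families",
    "make_decoys",
    "make_negatives",
    "make_mock_genome",
    "make_read_mappings",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# rng stream tags, so independent artefacts never share draws
_ANCESTOR, _MEMBER, _DECOY, _NEGATIVE, _GENOME = range(5)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study design.

    Defaults describe a desk-scale benchmark: 10 families of 8 members at
    length 300 aa, within-family divergence 0.15 (members ~72 % identical
    to each other, ~85 % to the ancestor), decoys at divergence 0.45
    (≈ 50 % identity to members — between true members and background),
    and 50 unrelated negatives (background identity ≈ 5-10 %).
    """

    seed: int = 0
    n_families: int = 10
    members_per_family: int = 8
    ancestor_length: int = 300
    within_divergence: float = 0.15
    decoy_divergence: float = 0.45
    decoys_per_family: int = 1
    n_negatives: int = 50
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_divergence <= 1.0):
            raise ValueError("within_divergence outside [0, 1]")
        if not (0.0 <= self.decoy_divergence <= 1.0):
            raise ValueError("decoy_divergence outside [0, 1]")
        for name in ("n_families", "members_per_family", "ancestor_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_negatives < 0 or self.decoys_per_family < 0:
            raise ValueError("counts must be >= 0")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *stream])

    def family_name(self, index: int) -> str:
        return f"fam{index:03d}"


def random_protein(rng: np.random.Generator, length: int) -> str:
    """A uniform random sequence over the 20 standard amino acids."""
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def mutate(
    rng: np.random.Generator,
    sequence: str,
    divergence: float,
    indel_rate: float = 0.0,
) -> str:
    """Substitute an i.i.d. ``divergence`` fraction of positions.

    Substituted positions receive one of the 19 alternative letters
    uniformly.  With ``indel_rate`` > 0, each position additionally
    deletes or duplicates with that probability (half each).
    """
    letters = np.array(list(sequence))
    hit = rng.random(len(letters)) < divergence
    for pos in np.nonzero(hit)[0]:
        choices = AMINO_ACIDS[AMINO_ACIDS != letters[pos]]
        letters[pos] = rng.choice(choices)
    if indel_rate > 0.0:
        out: list[str] = []
        for ch in letters:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r > 1 - indel_rate / 2:
                out.append(ch)  # duplication
        letters = np.array(out) if out else letters[:1]
    return "".join(letters)


def _family_ancestor(spec: SynthSpec, index: int) -> str:
    return random_protein(spec.rng(_ANCESTOR, index), spec.ancestor_length)


def make_families(
    spec: SynthSpec,
) -> tuple[ReferenceDatabase, list[tuple[str, str]], list[TruthLabel]]:
    """Generate families, splitting members into database and queries.

    Per family an ancestor is drawn and ``members_per_family`` members are
    derived by independent substitution at ``within_divergence``.  The
    first half of each family's members become database representatives;
    the second half become truth-labelled positive queries.  Decoy records
    (see :func:`make_decoys`) are included as homologues when
    ``decoys_per_family`` > 0.
    """
    if spec.members_per_family < 2:
        raise ValueError("members_per_family must be >= 2 to split "
                         "representatives from queries")
    families: list[GeneFamily] = []
    records: list[RefSeqRecord] = []
    queries: list[tuple[str, str]] = []
    truth: list[TruthLabel] = []
    processes = DEFAULT_PROCESSES
    for fi in range(spec.n_families):
        fam = spec.family_name(fi)
        families.append(GeneFamily(fam, process=processes[fi % len(processes)]))
        ancestor = _family_ancestor(spec, fi)
        rng = spec.rng(_MEMBER, fi)
        n_db = spec.members_per_family - spec.members_per_family // 2
        for mi in range(spec.members_per_family):
            seq = mutate(rng, ancestor, spec.within_divergence, spec.indel_rate)
            if mi < n_db:
                records.append(
                    RefSeqRecord(f"{fam}_rep{mi:02d}", seq,
                                 "representative", fam, source="synthetic")
                )
            else:
                qid = f"{fam}_query{mi:02d}"
                queries.append((qid, seq))
                truth.append(TruthLabel(qid, True, fam))
        records.extend(make_decoys(spec, fam))
    db = ReferenceDatabase(
        families, records, name="synthetic-db",
        parameters={"spec": spec.__dict__.copy()},
    )
    return db, queries, truth


def make_decoys(spec: SynthSpec, family: str) -> list[RefSeqRecord]:
    """Homologue decoy records for one family.

    Decoys diverge from the family ancestor at ``decoy_divergence``, so
    their identity to representatives lies between true members and
    unrelated background.  Requires ``decoy_divergence`` strictly above
    ``within_divergence``, otherwise decoys would be indistinguishable
    from members.
    """
    index = _family_index(spec, family)
    if spec.decoys_per_family == 0:
        return []
    if spec.decoy_divergence <= spec.within_divergence:
        raise ValueError(
            "decoy_divergence must exceed within_divergence to separate "
            "decoys from family members"
        )
    ancestor = _family_ancestor(spec, index)
    rng = spec.rng(_DECOY, index)
    return [
        RefSeqRecord(f"{family}_decoy{di:02d}",
                     mutate(rng, ancestor, spec.decoy_divergence, spec.indel_rate),
                     "homologue", source="synthetic-decoy")
        for di in range(spec.decoys_per_family)
    ]


def _family_index(spec: SynthSpec, family: str) -> int:
    for fi in range(spec.n_families):
        if spec.family_name(fi) == family:
            return fi
    raise KeyError(f"unknown synthetic family {family!r}")


def make_negatives(
    spec: SynthSpec,
) -> tuple[list[tuple[str, str]], list[TruthLabel]]:
    """Unrelated true-negative queries: independent random sequences whose
    identity to any database family sits at the ~5-10 % background level."""
    rng = spec.rng(_NEGATIVE)
    queries = [
        (f"neg{ni:04d}", random_protein(rng, spec.ancestor_length))
        for ni in range(spec.n_negatives)
    ]
    truth = [TruthLabel(qid, False) for qid, _ in queries]
    return queries, truth


def make_mock_genome(
    spec: SynthSpec,
    families_present: Iterable[str],
    n_background: int = 10,
    genome_id: str = "mock_genome",
) -> tuple[list[tuple[str, str]], str]:
    """A mock genome proteome plus its GFF3 annotation.

    The proteome holds one fresh member per present family (a new mutation
    of the family ancestor at ``within_divergence``) and ``n_background``
    unrelated proteins; the GFF lists exactly the present families via
    ``gene=`` attributes, so a faithful annotation run yields detection
    ratio 1.0.
    """
    present = sorted(set(families_present))
    if not present:
        raise ValueError("families_present must be non-empty")
    indices = [_family_index(spec, f) for f in present]
    rng = spec.rng(_GENOME, *(i + 1 for i in indices))
    proteome: list[tuple[str, str]] = []
    gff_lines = ["##gff-version 3"]
    pos = 1
    for fam, fi in zip(present, indices):
        ancestor = _family_ancestor(spec, fi)
        seq = mutate(rng, ancestor, spec.within_divergence, spec.indel_rate)
        orf_id = f"{genome_id}_{fam}"
        proteome.append((orf_id, seq))
        end = pos + 3 * len(seq) - 1
        gff_lines.append(
            f"{genome_id}\tsynthetic\tCDS\t{pos}\t{end}\t.\t+\t0\t"
            f"ID={orf_id};gene={fam};product={fam} protein"
        )
        pos = end + 100
    for bi in range(n_background):
        orf_id = f"{genome_id}_bg{bi:03d}"
        proteome.append((orf_id, random_protein(rng, spec.ancestor_length)))
        end = pos + 3 * spec.ancestor_length - 1
        gff_lines.append(
            f"{genome_id}\tsynthetic\tCDS\t{pos}\t{end}\t.\t+\t0\t"
            f"ID={orf_id};product=hypothetical protein"
        )
        pos = end + 100
    return proteome, "\n".join(gff_lines) + "\n"


def make_read_mappings(
    profile_truth: dict[str, dict[str, float]],
    read_len: float = 150.0,
    orf_len: int = 1500,
    gigabases: float = 5.0,
    tol: float = 1e-9,
) -> tuple[list[ReadMapping], dict[str, str]]:
    """Invert the coverage formula: witnesses such that profiling recovers
    ``profile_truth`` exactly.

    ``profile_truth`` maps family -> sample -> target coverage.  One ORF is
    emitted per (family, sample) with read count N solved from
    coverage = (N * l / L) / S, i.e. N = coverage * S * L / l.  A target
    not representable with integer N raises, reporting the nearest
    achievable coverage.  Returns the mappings plus the orf -> family map
    needed to build matching annotations.
    """
    mappings: list[ReadMapping] = []
    orf_families: dict[str, str] = {}
    for fam in sorted(profile_truth):
        for sample in sorted(profile_truth[fam]):
            target = profile_truth[fam][sample]
            if target < 0:
                raise ValueError("target coverage must be >= 0")
            n_exact = target * gigabases * orf_len / read_len
            n = round(n_exact)
            achieved = (n * read_len / orf_len) / gigabases
            if abs(achieved - target) > tol:
                raise ValueError(
                    f"coverage {target} not representable with integer read "
                    f"count (nearest achievable: {achieved})"
                )
            orf_id = f"{fam}__{sample}__orf"
            orf_families[orf_id] = fam
            mappings.append(
                ReadMapping(sample, orf_id, int(n), orf_len, read_len, gigabases)
            )
    return mappings, orf_families
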