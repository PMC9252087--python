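"""Validation of annotation accuracy: confusion metrics over threshold
sweeps on truth-labelled gene sets, and detection ratios on mock genomes.

Two designs are covered.  The first scores annotations of a simulated gene
set — target-family positives mixed with unrelated negatives — as a
confusion matrix and derives accuracy, PPV, specificity, sensitivity and
NPV, optionally sweeping the identity and hit-length filters over a dense
grid.  The second annotates whole proteomes of mock genomes and compares
the predicted family count against the genome's own annotation file: the
detection ratio classifies each genome as overestimated (> 1), exactly
estimated (= 1) or underestimated (< 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .builder import FamilyRules
from .dbmodel import (
    UNASSIGNED,
    AlignmentHit,
    Annotation,
    FilterParams,
    ReferenceDatabase,
)

__all__ = [
    "TruthLabel",
    "ConfusionCounts",
    "MetricSet",
    "SweepGrid",
    "GenomeEval",
    "GenomeSummary",
    "default_identity_grid",
    "default_length_grid",
    "score_queries",
    "metrics",
    "sweep",
    "family_detection_rate",
    "eval_genome",
    "summarize_genomes",
    "extract_annotated_families",
]


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one query: target (with its family) or negative."""

    query_id: str
    is_target: bool
    true_family: str | None = None

    def __post_init__(self) -> None:
        if self.is_target != (self.true_family is not None):
            raise ValueError(
                f"truth for {self.query_id!r}: is_target and true_family disagree"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five confusion ratios; None where the denominator is zero."""

    accuracy: float | None
    ppv: float | None
    specificity: float | None
    sensitivity: float | None
    npv: float | None


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, PPV, specificity, sensitivity and NPV from raw counts.

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    PPV         = TP / (TP + FP)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    NPV         = TN / (TN + FN)

    A zero denominator yields None rather than raising.
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    c = counts
    return MetricSet(
        accuracy=ratio(c.tp + c.tn, c.total),
        ppv=ratio(c.tp, c.tp + c.fp),
        specificity=ratio(c.tn, c.tn + c.fp),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        npv=ratio(c.tn, c.tn + c.fn),
    )


def score_queries(
    annotations: Sequence[Annotation],
    truth: Sequence[TruthLabel],
    level: str = "binary",
) -> ConfusionCounts:
    """Tabulate annotations against truth labels.

    ``binary`` level asks only target-vs-nontarget: a target assigned to
    any family is a TP.  ``family`` level additionally requires the
    assigned family to equal the true family; a target assigned to the
    wrong family counts as a false positive (not a false negative), so
    that PPV penalizes cross-family confusion.
    """
    if level not in ("binary", "family"):
        raise ValueError(f"unknown scoring level {level!r}")
    truth_of = {t.query_id: t for t in truth}
    tp = fp = tn = fn = 0
    for ann in annotations:
        if ann.query_id not in truth_of:
            raise KeyError(f"no truth label for query {ann.query_id!r}")
        t = truth_of[ann.query_id]
        if t.is_target:
            if not ann.assigned:
                fn += 1
            elif level == "binary" or ann.family == t.true_family:
                tp += 1
            else:
                fp += 1
        else:
            if ann.assigned:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

def default_identity_grid() -> np.ndarray:
    """Identity axis 0.2 .. 99.9 % in 0.1 steps (998 points)."""
    return np.arange(2, 1000) / 10.0


def default_length_grid() -> np.ndarray:
    """Hit-length axis 2 .. 99 aa in steps of one (98 points)."""
    return np.arange(2, 100, dtype=float)


@dataclass
class SweepGrid:
    """Confusion counts and metrics over an identity x hit-length grid.

    ``counts[name]`` holds a (n_identity, n_length) integer array for each
    of tp/fp/tn/fn; ``metric(name)`` derives the ratio arrays with NaN in
    zero-denominator cells (reported as missing, never as 0).
    """

    identity_axis: np.ndarray
    length_axis: np.ndarray
    counts: dict[str, np.ndarray]
    level: str

    def __post_init__(self) -> None:
        for ax in (self.identity_axis, self.length_axis):
            if len(ax) == 0 or not np.all(np.diff(ax) > 0):
                raise ValueError("sweep axes must be strictly increasing")

    def cell(self, i: int, j: int) -> ConfusionCounts:
        return ConfusionCounts(
            int(self.counts["tp"][i, j]), int(self.counts["fp"][i, j]),
            int(self.counts["tn"][i, j]), int(self.counts["fn"][i, j]),
        )

    def metric(self, name: str) -> np.ndarray:
        c = self.counts
        num_den = {
            "accuracy": (c["tp"] + c["tn"], c["tp"] + c["fp"] + c["tn"] + c["fn"]),
            "ppv": (c["tp"], c["tp"] + c["fp"]),
            "specificity": (c["tn"], c["tn"] + c["fp"]),
            "sensitivity": (c["tp"], c["tp"] + c["fn"]),
            "npv": (c["tn"], c["tn"] + c["fn"]),
        }
        num, den = num_den[name]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den.astype(float)
        out[den == 0] = np.nan
        return out


def _query_states(
    best_hits: Sequence[AlignmentHit],
    truth: Sequence[TruthLabel],
    db: ReferenceDatabase,
    max_evalue: float,
    level: str,
):
    """Per-query (identity, length, category) tuples for the sweep.

    Category: 0 = can never be assigned at any threshold (no hit, e-value
    fail, or homologue best hit — a decoy vetoes regardless of how the
    identity/length gates move); 1 = assignable and counts TP when
    assigned; 2 = assignable and counts FP when assigned.
    """
    truth_of = {t.query_id: t for t in truth}
    hit_of = {h.query_id: h for h in best_hits}
    if len(hit_of) != len(best_hits):
        raise ValueError("best_hits must contain one hit per query")
    states = []
    for t in truth_of.values():
        hit = hit_of.get(t.query_id)
        if hit is None or hit.evalue > max_evalue:
            states.append((0.0, 0.0, 0, t.is_target))
            continue
        subject = db.records.get(hit.subject_id)
        if subject is None:
            raise KeyError(f"hit subject {hit.subject_id!r} absent from database")
        if subject.role == "homologue":
            states.append((0.0, 0.0, 0, t.is_target))
            continue
        if not t.is_target:
            cat = 2
        elif level == "binary" or subject.family == t.true_family:
            cat = 1
        else:
            cat = 2
        states.append((hit.identity, float(hit.aln_len), cat, t.is_target))
    return states


def sweep(
    best_hits: Sequence[AlignmentHit],
    truth: Sequence[TruthLabel],
    db: ReferenceDatabase,
    identity_grid: np.ndarray | None = None,
    length_grid: np.ndarray | None = None,
    level: str = "binary",
    max_evalue: float = 1e-5,
) -> SweepGrid:
    """Evaluate the confusion matrix at every (identity, hit length) cell.

    Equivalent to re-running filter + assignment + scoring per cell, but
    computed with one pass: each query is binned once by its best hit's
    (identity, length) and cumulative suffix sums over the grid recover
    the per-cell assigned counts exactly.
    """
    if not truth:
        raise ValueError("empty truth set")
    id_axis = np.asarray(
        default_identity_grid() if identity_grid is None else identity_grid, float
    )
    len_axis = np.asarray(
        default_length_grid() if length_grid is None else length_grid, float
    )
    states = _query_states(best_hits, truth, db, max_evalue, level)

    ni, nj = len(id_axis), len(len_axis)

    def suffix2d(m: np.ndarray) -> np.ndarray:
        """suffix2d(m)[i, j] = sum of m[i', j'] over i' >= i and j' >= j."""
        m = np.flip(np.flip(m, 0).cumsum(0), 0)
        return np.flip(np.flip(m, 1).cumsum(1), 1)

    def bin_index(axis: np.ndarray, value: float) -> int:
        """Highest axis index whose threshold the value still satisfies."""
        return int(np.searchsorted(axis, value, side="right")) - 1

    # placed[c][i, j] = queries of category c whose best hit lands exactly
    # in bin (i, j); c=1 counts TP when assigned, c=2 counts FP; the extra
    # "target FP" plane tracks targets assigned to a wrong family so that
    # TP+FN stays constant per cell at family level.
    placed = {k: np.zeros((ni, nj), dtype=np.int64) for k in (1, 2, "t2")}
    n_target = sum(1 for *_, is_t in states if is_t)
    n_nontarget = len(states) - n_target
    for ident, length, cat, is_t in states:
        if cat == 0:
            continue
        i, j = bin_index(id_axis, ident), bin_index(len_axis, length)
        if i < 0 or j < 0:
            continue
        placed[cat][i, j] += 1
        if cat == 2 and is_t:
            placed["t2"][i, j] += 1
    tp = suffix2d(placed[1])
    fp = suffix2d(placed[2])
    wrong_family_targets = suffix2d(placed["t2"])
    fn = n_target - tp - wrong_family_targets
    tn = n_nontarget - (fp - wrong_family_targets)
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return SweepGrid(id_axis, len_axis, counts, level)


def family_detection_rate(
    annotations: Sequence[Annotation],
    truth: Sequence[TruthLabel],
    family: str,
) -> float:
    """Percent of a family's truth-positive queries annotated to it."""
    members = {t.query_id for t in truth if t.is_target and t.true_family == family}
    if not members:
        raise ValueError(f"family {family!r} has no truth-positive queries")
    # annotations may omit no-hit queries; those count as not recovered
    recovered = sum(
        1 for a in annotations if a.query_id in members and a.family == family
    )
    return 100.0 * recovered / len(members)


# ---------------------------------------------------------------------------
# Mock-genome evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeEval:
    """Predicted vs annotated family counts for one genome."""

    genome_id: str
    predicted_families: int
    annotated_families: int
    detection_ratio: float
    klass: str  # overestimated | exact | underestimated

    def __post_init__(self) -> None:
        if self.annotated_families <= 0:
            raise ValueError("annotated family count must be > 0")


def eval_genome(
    genome_id: str,
    predicted_families: Iterable[str] | int,
    annotated_families: Iterable[str] | int,
) -> GenomeEval:
    """Detection ratio = predicted / annotated family count.

    Classification compares the exact rational count ratio to 1 — ratios
    of small integers need no tolerance.
    """
    n_pred = (
        predicted_families if isinstance(predicted_families, int)
        else len(set(predicted_families))
    )
    n_annot = (
        annotated_families if isinstance(annotated_families, int)
        else len(set(annotated_families))
    )
    if n_annot <= 0:
        raise ValueError(f"genome {genome_id!r}: annotated family count is 0")
    ratio = Fraction(n_pred, n_annot)
    if ratio > 1:
        klass = "overestimated"
    elif ratio == 1:
        klass = "exact"
    else:
        klass = "underestimated"
    return GenomeEval(genome_id, n_pred, n_annot, float(ratio), klass)


@dataclass(frozen=True)
class GenomeSummary:
    n_genomes: int
    overestimated: int
    exact: int
    underestimated: int
    min_ratio: float
    max_ratio: float
    mean_ratio: float
    sd_ratio: float


def summarize_genomes(evals: Sequence[GenomeEval]) -> GenomeSummary:
    """Class counts plus min/max/mean and the sample (n-1) SD of ratios."""
    if not evals:
        raise ValueError("no genome evaluations to summarize")
    ratios = np.array([e.detection_ratio for e in evals])
    classes = [e.klass for e in evals]
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return GenomeSummary(
        n_genomes=len(evals),
        overestimated=classes.count("overestimated"),
        exact=classes.count("exact"),
        underestimated=classes.count("underestimated"),
        min_ratio=float(ratios.min()),
        max_ratio=float(ratios.max()),
        mean_ratio=float(ratios.mean()),
        sd_ratio=sd,
    )


def extract_annotated_families(
    gff_path: str | Path,
    family_rules: FamilyRules,
) -> set[str]:
    """Families a genome's own GFF3 annotation declares.

    Scans the ``gene``, ``Name`` and ``product`` attributes of every
    feature line and matches them against the keyword rules used for
    candidate extraction, giving the truth side of the detection ratio.
    """
    path = Path(gff_path)
    if not path.exists():
        raise FileNotFoundError(path)
    found: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF line "
                    f"({len(parts)} columns, expected 9)"
                )
            attrs: dict[str, str] = {}
            for item in parts[8].split(";"):
                item = item.strip()
                if not item or "=" not in item:
                    continue
                key, val = item.split("=", 1)
                attrs[key] = val
            texts = [attrs[k] for k in ("gene", "Name", "product") if k in attrs]
            if texts:
                found |= family_rules.matching_families(*texts)
    return found
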