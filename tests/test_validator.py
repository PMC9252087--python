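"""Confusion scoring, threshold sweeps, detection ratios and GFF truth."""

import numpy as np
import pytest

from phoscyc import annotator, validator
from phoscyc.builder import FamilyRules
from phoscyc.dbmodel import (
    UNASSIGNED,
    AlignmentHit,
    Annotation,
    FilterParams,
    GeneFamily,
    RefSeqRecord,
    ReferenceDatabase,
)
from phoscyc.validator import ConfusionCounts, TruthLabel


def _hit(q, s, identity, aln_len=50, evalue=1e-10):
    return AlignmentHit(q, s, identity, aln_len, 0, 0, 1, aln_len, 1, aln_len,
                        evalue, 100.0)


def _assigned(q, fam):
    return Annotation(q, fam, _hit(q, "rep", 80), "none")


def _unassigned(q, reason="no_hit"):
    return Annotation(q, UNASSIGNED, None, reason)


class TestScoreQueries:
    def test_perfect_binary_separation(self):
        anns = [_assigned("p1", "phoD"), _assigned("p2", "pstS"),
                _unassigned("n1"), _unassigned("n2")]
        truth = [TruthLabel("p1", True, "phoD"), TruthLabel("p2", True, "pstS"),
                 TruthLabel("n1", False), TruthLabel("n2", False)]
        c = validator.score_queries(anns, truth, "binary")
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_wrong_family_is_tp_binary_fp_family(self):
        anns = [_assigned("p1", "pstS")]
        truth = [TruthLabel("p1", True, "phoD")]
        b = validator.score_queries(anns, truth, "binary")
        f = validator.score_queries(anns, truth, "family")
        assert (b.tp, b.fp, b.fn) == (1, 0, 0)
        assert (f.tp, f.fp, f.fn) == (0, 1, 0)

    def test_counts_match_exhaustive_tabulation(self):
        """20 mixed queries scored by brute-force enumeration."""
        rng = np.random.default_rng(0)
        fams = ["phoD", "pstS"]
        anns, truth = [], []
        for i in range(20):
            qid = f"q{i}"
            is_target = bool(rng.integers(2))
            true_fam = fams[rng.integers(2)] if is_target else None
            truth.append(TruthLabel(qid, is_target, true_fam))
            call = rng.integers(3)  # 0: unassigned, 1/2: one of the families
            anns.append(_unassigned(qid) if call == 0
                        else _assigned(qid, fams[call - 1]))
        for level in ("binary", "family"):
            tp = fp = tn = fn = 0
            for a, t in zip(anns, truth):
                if t.is_target and a.assigned:
                    if level == "binary" or a.family == t.true_family:
                        tp += 1
                    else:
                        fp += 1
                elif t.is_target:
                    fn += 1
                elif a.assigned:
                    fp += 1
                else:
                    tn += 1
            c = validator.score_queries(anns, truth, level)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            assert c.total == 20

    def test_missing_truth_label_raises(self):
        with pytest.raises(KeyError):
            validator.score_queries([_assigned("q", "phoD")], [], "binary")


class TestMetrics:
    def test_formula_arithmetic(self):
        m = validator.metrics(ConfusionCounts(tp=85, fp=15, tn=0, fn=0))
        assert m.ppv == pytest.approx(0.85)
        m = validator.metrics(ConfusionCounts(tp=0, fp=0, tn=100, fn=0))
        assert m.specificity == 1.0
        m = validator.metrics(ConfusionCounts(tp=999, fp=0, tn=0, fn=1))
        assert m.sensitivity == pytest.approx(0.999)

    def test_zero_denominators_are_none_not_errors(self):
        m = validator.metrics(ConfusionCounts(0, 0, 0, 0))
        assert m.accuracy is None and m.ppv is None and m.npv is None


@pytest.fixture(scope="module")
def sweep_setup():
    """A small database plus hand-placed best hits spanning the grid."""
    db = ReferenceDatabase(
        [GeneFamily("phoD"), GeneFamily("pstS")],
        [RefSeqRecord("repD", "MKVLWAAGH", "representative", "phoD"),
         RefSeqRecord("repS", "MKVLWAAGR", "representative", "pstS"),
         RefSeqRecord("dec", "MKVLWAAGW", "homologue")],
    )
    rng = np.random.default_rng(42)
    hits, truth = [], []
    for i in range(50):
        qid = f"q{i}"
        kind = rng.integers(4)
        ident = float(rng.integers(50, 999)) / 10.0
        length = int(rng.integers(5, 90))
        if kind == 0:        # target hitting its own family
            hits.append(_hit(qid, "repD", ident, length))
            truth.append(TruthLabel(qid, True, "phoD"))
        elif kind == 1:      # target hitting the wrong family
            hits.append(_hit(qid, "repS", ident, length))
            truth.append(TruthLabel(qid, True, "phoD"))
        elif kind == 2:      # negative hitting a representative
            hits.append(_hit(qid, "repD", ident, length))
            truth.append(TruthLabel(qid, False))
        else:                # decoy best hit (veto) or no hit at all
            is_target = bool(rng.integers(2))
            if rng.integers(2):
                hits.append(_hit(qid, "dec", ident, length))
            truth.append(TruthLabel(qid, is_target, "phoD" if is_target else None))
    return db, hits, truth


def _naive_cell(hits, truth, db, min_id, min_len, level):
    best = {h.query_id: h for h in hits}
    anns = []
    params = FilterParams(min_identity=min_id, min_aln_len=int(min_len))
    anns = annotator.assign_families(
        list(best.values()), db, params, query_ids=[t.query_id for t in truth]
    )
    return validator.score_queries(anns, truth, level)


class TestSweep:
    def test_default_axes_shapes(self):
        assert len(validator.default_identity_grid()) == 998
        assert len(validator.default_length_grid()) == 98
        assert validator.default_identity_grid()[0] == pytest.approx(0.2)
        assert validator.default_identity_grid()[-1] == pytest.approx(99.9)
        assert validator.default_length_grid()[0] == 2
        assert validator.default_length_grid()[-1] == 99

    @pytest.mark.parametrize("level", ["binary", "family"])
    def test_cumulative_equals_naive_recomputation(self, sweep_setup, level):
        db, hits, truth = sweep_setup
        id_axis = np.arange(10, 1000, 10) / 10.0   # 99 identity points
        len_axis = np.arange(4, 84, 4, dtype=float)  # 20 length points
        grid = validator.sweep(hits, truth, db, id_axis, len_axis, level=level)
        for i in range(0, len(id_axis), 7):
            for j in range(0, len(len_axis), 3):
                naive = _naive_cell(hits, truth, db, id_axis[i], len_axis[j], level)
                got = grid.cell(i, j)
                assert (got.tp, got.fp, got.tn, got.fn) == \
                    (naive.tp, naive.fp, naive.tn, naive.fn), (i, j)

    def test_monotonicity_along_identity_axis(self, sweep_setup):
        db, hits, truth = sweep_setup
        grid = validator.sweep(hits, truth, db, level="binary")
        sens = grid.metric("sensitivity")
        spec = grid.metric("specificity")
        for j in range(0, len(grid.length_axis), 13):
            s = sens[:, j]
            s = s[~np.isnan(s)]
            assert np.all(np.diff(s) <= 1e-12)
            p = spec[:, j]
            p = p[~np.isnan(p)]
            assert np.all(np.diff(p) >= -1e-12)

    def test_class_totals_constant_over_grid(self, sweep_setup):
        db, hits, truth = sweep_setup
        grid = validator.sweep(hits, truth, db, level="binary")
        c = grid.counts
        n_target = sum(t.is_target for t in truth)
        assert np.all(c["tp"] + c["fn"] == n_target)
        assert np.all(c["tn"] + c["fp"] == len(truth) - n_target)

    def test_permissive_corner_maximizes_sensitivity(self, sweep_setup):
        db, hits, truth = sweep_setup
        grid = validator.sweep(hits, truth, db, level="binary")
        sens = grid.metric("sensitivity")
        assert np.nanmax(sens) == pytest.approx(sens[0, 0])

    def test_empty_truth_rejected(self, sweep_setup):
        db, hits, _ = sweep_setup
        with pytest.raises(ValueError):
            validator.sweep(hits, [], db)


class TestFamilyDetectionRate:
    def _truth(self):
        return [TruthLabel(f"p{i}", True, "phoD") for i in range(10)]

    def test_full_and_partial_recovery(self):
        truth = self._truth()
        all_found = [_assigned(f"p{i}", "phoD") for i in range(10)]
        assert validator.family_detection_rate(all_found, truth, "phoD") == 100.0
        half = [_assigned(f"p{i}", "phoD") for i in range(5)] + \
            [_unassigned(f"p{i}") for i in range(5, 10)]
        assert validator.family_detection_rate(half, truth, "phoD") == 50.0

    def test_per_family_rates_match_enumeration(self):
        rng = np.random.default_rng(7)
        fams = ["phoD", "pstS", "gcd"]
        truth, anns = [], []
        for i in range(30):
            fam = fams[rng.integers(3)]
            qid = f"p{i}"
            truth.append(TruthLabel(qid, True, fam))
            r = rng.integers(3)
            anns.append(_assigned(qid, fam) if r == 0
                        else _assigned(qid, fams[(fams.index(fam) + 1) % 3])
                        if r == 1 else _unassigned(qid))
        for fam in fams:
            members = [t.query_id for t in truth if t.true_family == fam]
            hitcount = sum(
                1 for a in anns if a.query_id in members and a.family == fam
            )
            assert validator.family_detection_rate(anns, truth, fam) == \
                pytest.approx(100.0 * hitcount / len(members))

    def test_absent_family_rejected(self):
        with pytest.raises(ValueError):
            validator.family_detection_rate([], self._truth(), "gcd")


class TestGenomeEval:
    def test_exact(self):
        ev = validator.eval_genome("g", 10, 10)
        assert ev.detection_ratio == 1.0 and ev.klass == "exact"

    def test_overestimated(self):
        ev = validator.eval_genome("g", 12, 10)
        assert ev.detection_ratio == pytest.approx(1.2)
        assert ev.klass == "overestimated"

    def test_underestimated_and_sets(self):
        ev = validator.eval_genome("g", {"a", "b"}, {"a", "b", "c", "d"})
        assert ev.klass == "underestimated"
        assert ev.detection_ratio == pytest.approx(0.5)

    def test_zero_annotated_rejected(self):
        with pytest.raises(ValueError):
            validator.eval_genome("g", 5, 0)


class TestSummarizeGenomes:
    def test_all_exact(self):
        evals = [validator.eval_genome(f"g{i}", 4, 4) for i in range(2)]
        s = validator.summarize_genomes(evals)
        assert s.exact == 2 and s.mean_ratio == 1.0 and s.sd_ratio == 0.0

    def test_mixed_classes(self):
        evals = [validator.eval_genome("g1", 1, 2), validator.eval_genome("g2", 3, 2)]
        s = validator.summarize_genomes(evals)
        assert s.underestimated == 1 and s.overestimated == 1
        assert s.mean_ratio == pytest.approx(1.0)

    def test_moments_match_direct_formula(self):
        rng = np.random.default_rng(1)
        evals = [
            validator.eval_genome(f"g{i}", int(rng.integers(1, 20)),
                                  int(rng.integers(1, 20)))
            for i in range(50)
        ]
        ratios = np.array([e.detection_ratio for e in evals])
        s = validator.summarize_genomes(evals)
        assert s.mean_ratio == pytest.approx(ratios.mean())
        assert s.sd_ratio == pytest.approx(
            np.sqrt(((ratios - ratios.mean()) ** 2).sum() / (len(ratios) - 1))
        )
        assert s.overestimated + s.exact + s.underestimated == s.n_genomes == 50


GFF = """##gff-version 3
ctg1\tsrc\tCDS\t1\t900\t.\t+\t0\tID=orf1;gene=phoD;product=alkaline phosphatase D
ctg1\tsrc\tCDS\t1000\t1900\t.\t+\t0\tID=orf2;product=hypothetical protein
ctg1\tsrc\tCDS\t2000\t2900\t.\t-\t0\tID=orf3;gene=pstS
ctg1\tsrc\tCDS\t3000\t3900\t.\t-\t0\tID=orf4;product=phosphate ABC transporter PstS
"""


class TestExtractAnnotatedFamilies:
    RULES = FamilyRules({"phoD": ["phoD"], "pstS": ["pstS"], "gcd": ["gcd"]})

    def test_gene_and_product_attributes(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(GFF)
        fams = validator.extract_annotated_families(p, self.RULES)
        assert fams == {"phoD", "pstS"}

    def test_no_match_gives_empty_set(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text("ctg\tsrc\tCDS\t1\t9\t.\t+\t0\tID=x;product=ribosome\n")
        assert validator.extract_annotated_families(p, self.RULES) == set()

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text("##gff-version 3\nctg\tsrc\tCDS\t1\t9\n")
        with pytest.raises(ValueError, match=":2"):
            validator.extract_annotated_families(p, self.RULES)
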