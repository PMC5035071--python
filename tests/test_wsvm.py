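import numpy as np
import pytest
from sklearn.svm import SVC

from lmrsvm import wsvm
from lmrsvm.genome_io import Genome, GenomicInterval
from lmrsvm.labeling import LabeledTraining
from lmrsvm.wsvm import CvMetrics, WsvmModel, WsvmWeights, choose_best, fscore

from _oracles import qp_svm_reference


def _data(X, y, sets):
    return LabeledTraining(X=np.asarray(X, float), set_labels=np.asarray(sets),
                           y=np.asarray(y), intervals=[None] * len(y), k=5)


def _random_instance(rng, n_max=120, d_max=30):
    n, d = int(rng.integers(20, n_max)), int(rng.integers(3, d_max))
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, 1, -1)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    sets = np.where(y == 1, rng.choice(["RP", "LP"], n),
                    rng.choice(["LN", "RN"], n))
    return _data(X, y, sets)


class TestWeights:
    def test_order_constraints(self):
        with pytest.raises(ValueError):
            WsvmWeights(1.0, 2.0, 1.0, 1.0)   # C_RP < C_LP
        with pytest.raises(ValueError):
            WsvmWeights(2.0, 1.0, 2.0, 1.0)   # C_RN < C_LN
        with pytest.raises(ValueError):
            WsvmWeights(1.0, -1.0, 1.0, 1.0)

    def test_per_sample_lookup(self):
        w = WsvmWeights(4.0, 3.0, 1.0, 2.0)
        np.testing.assert_array_equal(
            w.per_sample(np.array(["RP", "LP", "LN", "RN"])),
            [4.0, 3.0, 1.0, 2.0])


class TestTrain:
    def test_symmetric_separable_analytic(self):
        # +/-1 in 1-D with huge penalties: hard-margin optimum w=1, b=0
        X = np.array([[-1.0], [1.0]])
        data = _data(X, [-1, 1], ["RN", "RP"])
        m = wsvm.train(data, WsvmWeights(1e6, 1e6, 1e6, 1e6), tol=1e-10)
        assert m.w[0] == pytest.approx(1.0, abs=1e-8)
        assert m.b == pytest.approx(0.0, abs=1e-8)
        assert np.all(m.slacks(X, np.array([-1.0, 1.0])) < 1e-8)

    def test_single_class_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            wsvm.train(_data(X, [1, 1, 1, 1], ["RP"] * 4),
                       WsvmWeights(1, 1, 1, 1))

    def test_equal_weights_match_standard_svm(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            data = _random_instance(rng)
            m = wsvm.train(data, WsvmWeights(2.0, 2.0, 2.0, 2.0), tol=1e-10)
            ref = SVC(kernel="linear", C=2.0, tol=1e-6).fit(data.X, data.y)
            # both near-optimal; agreement limited by libsvm's own slack
            assert np.max(np.abs(m.decision(data.X) -
                                 ref.decision_function(data.X))) < 1e-4

    def test_weighted_objective_matches_qp_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(3):
            data = _random_instance(rng)
            wts = WsvmWeights(10.0, 0.5, 0.3, 5.0)
            m = wsvm.train(data, wts, tol=1e-9)
            C = wts.per_sample(data.set_labels)
            obj = m.primal_objective(data.X, data.y.astype(float), C)
            _, _, obj_ref = qp_svm_reference(data.X, data.y, C)
            assert obj == pytest.approx(obj_ref, rel=1e-6)

    def test_kkt_certificate(self):
        rng = np.random.default_rng(2)
        data = _random_instance(rng)
        wts = WsvmWeights(5.0, 1.0, 0.5, 3.0)
        m = wsvm.train(data, wts, tol=1e-8)
        assert m.kkt_gap <= 1e-8
        # primal feasibility by construction of the slacks; duality gap small
        yf = data.y.astype(float)
        C = wts.per_sample(data.set_labels)
        a = m.alpha
        dual = a.sum() - 0.5 * (a * yf) @ (data.X @ data.X.T) @ (a * yf)
        primal = m.primal_objective(data.X, yf, C)
        assert primal - dual <= 1e-6 * max(1.0, primal)

    def test_scaling_leaves_separable_hyperplane_unchanged(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 0.3, (20, 3)),
                       rng.normal(2, 0.3, (20, 3))])
        y = np.array([-1] * 20 + [1] * 20)
        sets = np.array(["RN"] * 20 + ["RP"] * 20)
        data = _data(X, y, sets)
        m1 = wsvm.train(data, WsvmWeights(100, 100, 100, 100), tol=1e-10)
        m2 = wsvm.train(data, WsvmWeights(1000, 1000, 1000, 1000), tol=1e-10)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-6)
        assert m1.b == pytest.approx(m2.b, abs=1e-6)


class TestFscore:
    def test_examples(self):
        m = fscore(50, 50, 100)
        assert (m.recall, m.precision, m.f) == (0.5, 0.5, 0.5)
        assert fscore(0, 10, 5).f == 0.0
        assert fscore(0, 0, 0).f == 0.0

    def test_random_counts_match_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tp, fn, pp = (int(rng.integers(0, 100)) for _ in range(3))
            m = fscore(tp, fn, pp)
            r = tp / (tp + fn) if tp + fn else 0.0
            p = tp / pp if pp else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            assert (m.recall, m.precision, m.f) == \
                (pytest.approx(r), pytest.approx(p), pytest.approx(f))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fscore(-1, 0, 0)


class TestGenomicCoverage:
    def _const_model(self, b):
        return WsvmModel(w=np.zeros(4**5), b=b,
                         weights=WsvmWeights(1, 1, 1, 1), k=5)

    def test_always_positive_covers_everything(self, toy_genome):
        cov = wsvm.genomic_coverage(self._const_model(1.0), toy_genome,
                                    "chrT", window=2000, step=500)
        assert cov == pytest.approx(1.0)

    def test_always_negative_covers_nothing(self, toy_genome):
        cov = wsvm.genomic_coverage(self._const_model(-1.0), toy_genome,
                                    "chrT", window=2000, step=500)
        assert cov == 0.0

    def test_planted_block_detected(self):
        # 100 kb random chromosome with a 10 kb poly-G block; a detector for
        # GGGGG content covers the block within one window size
        rng = np.random.default_rng(5)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)]))
        seq[40_000:50_000] = "G" * 10_000
        g = Genome({"chr1": "".join(seq)})
        w = np.zeros(4**5)
        from lmrsvm.kmer import kmer_index
        w[kmer_index("GGGGG")] = 1.0
        model = WsvmModel(w=w, b=-0.4, weights=WsvmWeights(1, 1, 1, 1), k=5)
        cov = wsvm.genomic_coverage(model, g, "chr1", 2000, 500)
        assert cov == pytest.approx(0.1, abs=0.04)

    def test_missing_proxy_chromosome(self, toy_genome):
        with pytest.raises(KeyError):
            wsvm.genomic_coverage(self._const_model(1.0), toy_genome, "chrZ")


class TestChooseBest:
    def _cand(self, delta, cr, cl, tp, fn, pp):
        return (delta, WsvmWeights(cr, cl, cl, cr), CvMetrics(tp, fn, pp),
                0.01, None)

    def test_single_candidate_returned(self):
        c = self._cand(0.95, 10, 1, 50, 50, 60)
        assert choose_best([c]) is c

    def test_precision_breaks_f_tie(self):
        # both have F = 0.8; precisions 0.8 vs 0.9: the 0.9 candidate wins
        a = self._cand(0.90, 10, 1, 80, 20, 100)
        b = self._cand(0.95, 10, 1, 90, 35, 100)
        assert a[2].f == pytest.approx(b[2].f)
        assert choose_best([a, b]) is b

    def test_lexicographic_tie_break(self):
        a = self._cand(0.95, 10, 1, 50, 10, 60)
        b = self._cand(0.90, 10, 1, 50, 10, 60)
        assert choose_best([a, b]) is b

    def test_empty_candidates_error(self):
        with pytest.raises(RuntimeError, match="coverage cap"):
            choose_best([])


class TestSelectModel:
    def test_grid_of_one_returns_that_point(self, sim, pipe):
        from lmrsvm import labeling
        neg_data = labeling.assemble_training([], pipe.negatives, sim.genome, 5)
        wts = WsvmWeights(1e4, 100.0, 100.0, 1e4)
        sel = wsvm.select_model(
            pipe.ranked, neg_data, sim.genome, weight_grid=[wts],
            delta_grid=[0.95], ln_quantile=0.15, coverage_cap=1.0, seed=3)
        assert sel.weights == wts
        assert sel.config.delta == 0.95
        assert len(sel.report) == 1 and sel.report[0].selected

    def test_selection_report_audit(self, pipe):
        # exhaustive audit of the grid search run by the pipeline fixture
        rows = pipe.selection.report
        ok = [r for r in rows if not r.excluded]
        sel = [r for r in rows if r.selected]
        assert len(sel) == 1
        sel = sel[0]
        assert not sel.excluded
        best_f = max(r.metrics.f for r in ok)
        group = [r for r in ok if r.metrics.f >= best_f - 0.005]
        assert sel.metrics.precision == max(r.metrics.precision for r in group)
        for r in rows:
            if r.excluded:
                assert r.coverage > 0.05 and not r.selected


class TestModelSerialization:
    def test_roundtrip(self, tmp_path, pipe):
        path = tmp_path / "model.txt"
        wsvm.save_model(pipe.model, path)
        back = wsvm.load_model(path)
        np.testing.assert_array_equal(back.w, pipe.model.w)
        assert back.b == pipe.model.b
        assert back.weights == pipe.model.weights
        assert back.k == pipe.model.k
        assert back.delta == pipe.model.delta

    def test_checksum_detects_corruption(self, tmp_path, pipe):
        path = tmp_path / "model.txt"
        wsvm.save_model(pipe.model, path)
        text = path.read_text().splitlines()
        text[-1] = repr(float(text[-1]) + 1.0)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValueError, match="checksum"):
            wsvm.load_model(path)
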