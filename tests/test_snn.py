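import numpy as np
import pytest

from exospect.errors import (
    DegenerateFeatureError,
    InstabilityError,
    NoCompetitionError,
    RankError,
)
from exospect.intervals import GenomicInterval
from exospect.seqmap import NucleotideSequence
from exospect.simulate import GeneModelParams, simulate_gene
from exospect.snn import (
    OrderParameterState,
    PrototypeSet,
    SegmentFeature,
    detect_initial_intervals,
    evolve_order_parameters,
    initial_order_parameters,
    learn_prototypes,
    load_prototypes,
    partition_segments,
    save_prototypes,
    segment_features,
)


def _feat(q, label="exon"):
    q = np.asarray(q, dtype=float)
    return SegmentFeature(GenomicInterval("s", 0, 30, "candidate"), q)


class TestSegmentFeatures:
    def test_deterministic_and_unit_norm(self, strong_gene):
        seq, truth = strong_gene
        iv = GenomicInterval(seq.id, 0, 300)
        f1 = segment_features(seq, iv)
        f2 = segment_features(seq, iv)
        assert np.array_equal(f1.q, f2.q)
        assert np.linalg.norm(f1.q) == pytest.approx(1.0, abs=1e-9)

    def test_exon_and_intron_features_differ(self):
        """A strongly periodic exon segment and a uniform intron segment
        have clearly distinct spectral signatures."""
        for seed in range(5):
            seq, truth = simulate_gene(
                GeneModelParams(periodicity_strength=1.0, seed=seed)
            )
            exon = next(iv for iv in truth if iv.label == "exon" and iv.length >= 117)
            intron = next(iv for iv in truth if iv.label == "intron" and iv.length >= 117)
            qe = segment_features(seq, GenomicInterval(seq.id, exon.start, exon.end)).q
            qi = segment_features(seq, GenomicInterval(seq.id, intron.start, intron.end)).q
            assert float(qe @ qi) < 0.9

    def test_all_n_segment_is_degenerate(self):
        seq = NucleotideSequence("s", "N" * 120)
        with pytest.raises(DegenerateFeatureError):
            segment_features(seq, GenomicInterval("s", 0, 120))

    def test_short_segment_rejected(self, strong_gene):
        seq, _ = strong_gene
        with pytest.raises(ValueError, match="shorter"):
            segment_features(seq, GenomicInterval(seq.id, 0, 20))


class TestLearnPrototypes:
    def test_orthonormal_prototypes_are_self_adjoint(self):
        feats = [_feat([1, 0, 0]), _feat([0, 1, 0])]
        ps = learn_prototypes(feats, ["exon", "intron"])
        assert np.allclose(ps.adjoints, ps.prototypes, atol=1e-12)

    def test_oblique_adjoints_match_closed_form(self):
        """For v1=(1,0), v2=(1/sqrt2,1/sqrt2) the 2x2 inverse gives
        adjoints (1,-1) and (0, sqrt2)."""
        s = 1 / np.sqrt(2)
        ps = learn_prototypes(
            [_feat([1, 0]), _feat([s, s])], ["exon", "intron"]
        )
        assert ps.adjoints[0] @ ps.prototypes[1] == pytest.approx(0.0, abs=1e-12)
        assert ps.adjoints[0] @ ps.prototypes[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(ps.adjoints[0], [1.0, -1.0], atol=1e-12)
        assert np.allclose(ps.adjoints[1], [0.0, np.sqrt(2)], atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(RankError):
            learn_prototypes([_feat([1, 0])], ["exon"])

    def test_dependent_class_means_rejected(self):
        with pytest.raises(RankError):
            learn_prototypes(
                [_feat([1, 0]), _feat([1, 0])], ["exon", "intron"]
            )

    def test_biorthogonality_on_trained_prototypes(self, trained_prototypes):
        ps = trained_prototypes
        gram = ps.adjoints @ ps.prototypes.T
        assert np.max(np.abs(gram - np.eye(ps.n_classes))) < 1e-8


class TestInitialOrderParameters:
    def test_prototype_input_projects_to_unit_vector(self):
        ps = learn_prototypes([_feat([1, 0]), _feat([0, 1])], ["exon", "intron"])
        xi = initial_order_parameters(_feat([1, 0]), ps)
        assert np.allclose(xi, [1.0, 0.0], atol=1e-12)

    def test_orthogonal_input_projects_to_zero(self):
        ps = learn_prototypes(
            [_feat([1, 0, 0]), _feat([0, 1, 0])], ["exon", "intron"]
        )
        xi = initial_order_parameters(_feat([0, 0, 1]), ps)
        assert np.allclose(xi, 0.0, atol=1e-12)

    def test_matches_direct_dot_products(self, rng):
        ps = learn_prototypes(
            [_feat([1, 0, 0]), _feat([0.6, 0.8, 0])], ["exon", "intron"]
        )
        q = rng.normal(size=3)
        xi = initial_order_parameters(_feat(q), ps)
        expected = [float(np.dot(ps.adjoints[k], q)) for k in range(2)]
        assert np.allclose(xi, expected, atol=1e-12)

    def test_dimension_mismatch(self):
        ps = learn_prototypes([_feat([1, 0]), _feat([0, 1])], ["exon", "intron"])
        with pytest.raises(ValueError, match="dimension"):
            initial_order_parameters(_feat([1, 0, 0]), ps)


class TestEvolveOrderParameters:
    def test_largest_initial_parameter_wins_and_saturates(self):
        winner, xi, _ = evolve_order_parameters(
            OrderParameterState(xi=np.array([0.9, 0.1]))
        )
        assert winner == 0
        # surviving amplitude tends to sqrt(lambda / C) = 1
        assert abs(xi[0]) == pytest.approx(1.0, abs=1e-3)
        assert abs(xi[1]) < 1e-3

    def test_exact_tie_breaks_to_lowest_index(self):
        winner, _, _ = evolve_order_parameters(
            OrderParameterState(xi=np.array([0.5, 0.5]))
        )
        assert winner == 0

    def test_sign_is_irrelevant_to_competition(self):
        from scipy.integrate import solve_ivp

        xi0 = np.array([0.3, -0.6])

        def rhs(_, xi):
            total = xi @ xi
            return xi - (total - xi**2) * xi - total * xi

        ref = solve_ivp(rhs, (0, 200), xi0, rtol=1e-10, atol=1e-12)
        winner, xi, _ = evolve_order_parameters(OrderParameterState(xi=xi0))
        assert winner == 1
        assert int(np.argmax(ref.y[:, -1] ** 2)) == 1
        assert np.allclose(np.abs(xi), np.abs(ref.y[:, -1]), atol=1e-3)

    def test_all_zero_initialization_rejected(self):
        with pytest.raises(NoCompetitionError):
            evolve_order_parameters(OrderParameterState(xi=np.zeros(3)))

    def test_divergence_reported_with_step_size(self):
        state = OrderParameterState(
            xi=np.array([50.0, 40.0]), step_size=5.0, max_iters=200
        )
        with pytest.raises(InstabilityError, match="step_size"):
            evolve_order_parameters(state)

    def test_winner_take_all_random_initializations(self, rng):
        for m in (2, 3, 5):
            for _ in range(25):
                xi0 = rng.uniform(-1, 1, size=m)
                if np.all(xi0 == 0):
                    continue
                expected = int(np.argmax(xi0**2))
                winner, _, _ = evolve_order_parameters(
                    OrderParameterState(xi=xi0, max_iters=5000)
                )
                assert winner == expected


class TestSegmentationAndDetection:
    def test_partition_covers_sequence_minus_short_tail(self):
        bounds = partition_segments(1000, segment_length=117)
        covered = sum(b - a for a, b in bounds)
        assert 1000 - covered < 30
        assert bounds[0][0] == 0
        for (a1, b1), (a2, b2) in zip(bounds, bounds[1:]):
            assert b1 == a2

    def test_fixed_segment_count(self):
        bounds = partition_segments(1000, n_segments=4)
        assert len(bounds) == 4
        assert all(b - a == 250 for a, b in bounds)

    def test_run_merging(self, trained_prototypes, monkeypatch):
        """Segment labels E,E,I,E merge into [0,2L) and [3L,4L)."""
        import exospect.snn as snn_mod

        labels = iter(["exon", "exon", "intron", "exon"])
        monkeypatch.setattr(
            snn_mod, "classify_feature", lambda *a, **k: next(labels)
        )
        seq, _ = simulate_gene(
            GeneModelParams(
                n_exons=1,
                exon_length=("fixed", 234),
                intron_length=("fixed", 117),
                seed=0,
            )
        )
        out = snn_mod.detect_initial_intervals(
            seq, trained_prototypes, segment_length=117
        )
        assert [(iv.start, iv.end) for iv in out] == [(0, 234), (351, 468)]

    def test_all_intron_labels_give_empty_list(self, trained_prototypes, monkeypatch):
        import exospect.snn as snn_mod

        monkeypatch.setattr(
            snn_mod, "classify_feature", lambda *a, **k: "intron"
        )
        g = np.random.default_rng(3)
        seq = NucleotideSequence("s", "".join(g.choice(list("ACGT"), 1000)))
        out = snn_mod.detect_initial_intervals(seq, trained_prototypes)
        assert out == []

    def test_every_true_exon_overlaps_a_detection(self, trained_prototypes):
        seq, truth = simulate_gene(GeneModelParams(periodicity_strength=1.0, seed=0))
        out = detect_initial_intervals(seq, trained_prototypes)
        cover = np.zeros(seq.n, dtype=bool)
        for iv in out:
            cover[iv.start : iv.end] = True
        for iv in truth:
            if iv.label == "exon":
                assert cover[iv.start : iv.end].any()


class TestPrototypeSerialization:
    def test_roundtrip_preserves_biorthogonality(self, trained_prototypes, tmp_path):
        path = tmp_path / "protos.json"
        save_prototypes(trained_prototypes, path)
        back = load_prototypes(path)
        assert back.labels == trained_prototypes.labels
        assert np.allclose(back.prototypes, trained_prototypes.prototypes)
        gram = back.adjoints @ back.prototypes.T
        assert np.max(np.abs(gram - np.eye(back.n_classes))) < 1e-8

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "nope.json"
        path.write_text("{}")
        with pytest.raises(ValueError, match="prototype"):
            load_prototypes(path)
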