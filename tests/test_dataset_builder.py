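"""Tests for dataset construction: filtering, negative sampling, identity
computation (against an independent Gotoh DP oracle), redundancy removal,
and the splitting/fold machinery."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from saeppi.dataset_builder import (
    PairSample,
    SplitSpec,
    alignment_score,
    filter_proteins,
    holdout_split,
    make_folds,
    pairwise_identity,
    remove_redundant,
    sample_negatives,
)
from saeppi.sequence_codec import ProteinRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a: str, b: str, open_cost: float = 10.0, extend_cost: float = 0.5) -> float:
    """Independent affine-gap global alignment score (Gotoh three-state DP).

    A gap of length L costs open + (L-1) * extend; end gaps are penalized.
    """
    n, m = len(a), len(b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a residue vs gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Y[0, j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] - open_cost,
                X[i - 1, j] - extend_cost,
                Y[i - 1, j] - open_cost,
            )
            Y[i, j] = max(
                M[i, j - 1] - open_cost,
                Y[i, j - 1] - extend_cost,
                X[i, j - 1] - open_cost,
            )
    return max(M[n, m], X[n, m], Y[n, m])


def records_with_compartments(spec):
    """spec: dict compartment -> number of proteins."""
    out = []
    i = 0
    for comp, count in spec.items():
        for _ in range(count):
            out.append(ProteinRecord(f"p{i}", "ACDEFGHIKLMNPQRSTVWY" * 3, comp))
            i += 1
    return out


class TestFilterProteins:
    def test_short_sequences_removed_and_logged(self, make_seq):
        records = [
            ProteinRecord("short", make_seq(49), "nucleus"),
            ProteinRecord("ok", make_seq(50), "nucleus"),
        ]
        kept, log = filter_proteins(records)
        assert [r.id for r in kept] == ["ok"]
        assert log["min_length"] == ["short"]

    def test_multi_location_removed(self, make_seq):
        records = [ProteinRecord(f"p{i}", make_seq(60)) for i in range(3)]
        locations = {
            "p0": ["nucleus"],
            "p1": ["nucleus", "cytoplasm"],
            # p2 has no annotation
        }
        kept, log = filter_proteins(records, locations=locations)
        assert [r.id for r in kept] == ["p0"]
        assert kept[0].compartment == "nucleus"
        assert log["multi_location"] == ["p1"] and log["no_location"] == ["p2"]

    def test_all_valid_passes_through(self, make_seq):
        records = [ProteinRecord(f"p{i}", make_seq(60), "er") for i in range(4)]
        kept, log = filter_proteins(records)
        assert kept == records and not any(log.values())

    def test_empty_result_raises(self, make_seq):
        with pytest.raises(ValueError, match="min_length"):
            filter_proteins([ProteinRecord("p", make_seq(10), "er")])


class TestSampleNegatives:
    def test_exhaustive_small_case(self):
        records = records_with_compartments({"a": 3, "b": 2})
        pairs = sample_negatives(records, 6, seed=0)
        keys = {p.key() for p in pairs}
        assert len(keys) == 6
        comp = {r.id: r.compartment for r in records}
        assert all(comp[p.idA] != comp[p.idB] for p in pairs)

    def test_n_zero_empty(self):
        assert sample_negatives(records_with_compartments({"a": 2, "b": 2}), 0) == []

    def test_over_capacity_reports_maximum(self):
        records = records_with_compartments({"a": 3, "b": 2})
        with pytest.raises(ValueError, match="only 6"):
            sample_negatives(records, 7, seed=0)

    def test_deterministic_and_cross_compartment(self, rng):
        records = records_with_compartments(
            {f"c{i}": 17 for i in range(6)}
        )  # 102 proteins over 6 compartments
        a = sample_negatives(records, 500, seed=11)
        b = sample_negatives(records, 500, seed=11)
        assert a == b
        comp = {r.id: r.compartment for r in records}
        assert all(comp[p.idA] != comp[p.idB] for p in a)
        assert all(p.label == 0 for p in a)
        assert len({p.key() for p in a}) == 500

    def test_excludes_positive_pairs(self):
        records = records_with_compartments({"a": 2, "b": 2})
        # a: p0 p1; b: p2 p3 -> 4 cross pairs
        positives = {frozenset(("p0", "p2")), frozenset(("p1", "p3"))}
        pairs = sample_negatives(records, 2, seed=0, exclude=positives)
        assert {p.key() for p in pairs} == {
            frozenset(("p0", "p3")),
            frozenset(("p1", "p2")),
        }

    def test_single_compartment_rejected(self):
        with pytest.raises(ValueError, match="compartments"):
            sample_negatives(records_with_compartments({"a": 5}), 1)


class TestPairwiseIdentity:
    def test_identical_sequences_are_one(self, make_seq):
        seq = make_seq(60)
        assert pairwise_identity(seq, seq) == 1.0

    def test_disjoint_alphabets_are_zero(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_symmetry(self, make_seq):
        a, b = make_seq(50), make_seq(45)
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a), abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")

    @pytest.mark.parametrize("trial", range(5))
    def test_score_matches_gotoh_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=60))
        b = "".join(rng.choice(aas, size=60))
        assert alignment_score(a, b) == pytest.approx(gotoh_score(a, b), abs=1e-6)

    def test_identity_in_unit_interval(self, make_seq):
        ident = pairwise_identity(make_seq(40), make_seq(80))
        assert 0.0 <= ident <= 1.0


class TestRemoveRedundant:
    def _fixture(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        train_seq = "".join(rng.choice(aas, size=80))
        train = [ProteinRecord("train0", train_seq)]
        # planted homolog: identical to the training protein -> identity 1.0
        homolog = ProteinRecord("homolog", train_seq)
        clean1 = ProteinRecord("clean1", "".join(rng.choice(aas, size=80)))
        clean2 = ProteinRecord("clean2", "".join(rng.choice(aas, size=80)))
        sequences = {r.id: r.seq for r in (homolog, clean1, clean2, *train)}
        pairs = [
            PairSample("homolog", "clean1", 1),
            PairSample("clean1", "clean2", 0),
        ]
        return pairs, train, sequences

    def test_planted_homolog_pair_removed(self, rng):
        pairs, train, sequences = self._fixture(rng)
        kept, removed = remove_redundant(pairs, train, sequences, threshold=0.25)
        assert [p.key() for p in kept] == [frozenset(("clean1", "clean2"))]
        assert len(removed) == 1
        assert removed[0].test_protein == "homolog"
        assert removed[0].train_protein == "train0"
        assert removed[0].identity == 1.0

    def test_unreachable_threshold_removes_nothing(self, rng):
        pairs, train, sequences = self._fixture(rng)
        kept, removed = remove_redundant(pairs, train, sequences, threshold=1.01)
        assert kept == pairs and removed == []

    def test_monotone_in_threshold(self, rng):
        pairs, train, sequences = self._fixture(rng)
        removed_counts = [
            len(remove_redundant(pairs, train, sequences, threshold=t)[1])
            for t in (0.1, 0.3, 0.6, 0.95)
        ]
        assert removed_counts == sorted(removed_counts, reverse=True)


class TestSplits:
    def _samples(self, n_pos, n_neg):
        return [PairSample(f"a{i}", f"b{i}", 1) for i in range(n_pos)] + [
            PairSample(f"c{i}", f"d{i}", 0) for i in range(n_neg)
        ]

    def test_fold_sizes_and_partition(self):
        samples = self._samples(50, 50)
        folds = make_folds(samples, k=10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert (sizes == 10).all()
        assert set(folds) == set(range(10))

    def test_stratification_within_one(self):
        samples = self._samples(37, 63)
        folds = make_folds(samples, k=10, seed=3)
        labels = np.array([s.label for s in samples])
        for f in range(10):
            pos = int(((folds == f) & (labels == 1)).sum())
            assert 3 <= pos <= 4  # 37/10 rounded either way

    def test_fold_determinism_and_bounds(self):
        samples = self._samples(12, 8)
        assert np.array_equal(make_folds(samples, k=5, seed=9), make_folds(samples, k=5, seed=9))
        with pytest.raises(ValueError):
            make_folds(samples, k=21, seed=0)
        with pytest.raises(ValueError):
            make_folds(samples, k=1, seed=0)

    def test_holdout_split_conserves_samples(self):
        samples = self._samples(60, 40)
        pretrain, holdout = holdout_split(samples, 20, seed=4)
        assert len(pretrain) == 80 and len(holdout) == 20
        assert sorted(tuple(sorted(p.key())) for p in pretrain + holdout) == sorted(
            tuple(sorted(p.key())) for p in samples
        )
        assert not {p.key() for p in pretrain} & {p.key() for p in holdout}

    def test_holdout_determinism(self):
        samples = self._samples(30, 30)
        assert holdout_split(samples, 10, seed=1) == holdout_split(samples, 10, seed=1)

    def test_holdout_validation(self):
        samples = self._samples(5, 5)
        with pytest.raises(ValueError):
            holdout_split(samples, 0)
        with pytest.raises(ValueError):
            holdout_split(samples, 10)


def test_split_spec_validation():
    with pytest.raises(ValueError):
        SplitSpec(identity_threshold=1.5)
    with pytest.raises(ValueError):
        SplitSpec(n_folds=1)
    assert SplitSpec().n_folds == 10 and SplitSpec().identity_threshold == 0.25
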