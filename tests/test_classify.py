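import numpy as np
import pytest

from fsatool import (
    AnnotationTrack,
    KeyResidueList,
    capture_stats,
    classify,
    composition_by_class,
    summarize_fractions,
)
from fsatool.chem import ChemClassScheme
from fsatool.classify import LABELS
from fsatool.errors import IncompatibleInputsError, KeyRangeError

from conftest import make_emap


def _flags(L, positions, class_idx=0, K=6):
    f = np.zeros((L, K), dtype=bool)
    for p in positions:
        f[p - 1, class_idx] = True
    return f


def _track(labels, query=None):
    L = len(labels)
    return AnnotationTrack(
        labels=tuple(labels),
        query=query or "A" * L,
        natural_classes=tuple(frozenset() for _ in range(L)),
        designed_classes=tuple(frozenset() for _ in range(L)),
        query_deviates=tuple(False for _ in range(L)),
    )


class TestTruthTable:
    def test_four_way_labels(self):
        # position 1: natural only; 2: designed only; 3: both; 4,5: neither
        nat = make_emap(_flags(5, [1, 3]))
        des = make_emap(_flags(5, [2, 3]))
        track = classify(nat, des)
        assert track.labels == (
            "functional",
            "adaptable",
            "structural",
            "unlabeled",
            "unlabeled",
        )

    def test_every_position_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        nat = make_emap(rng.random((40, 6)) < 0.3)
        des = make_emap(rng.random((40, 6)) < 0.3)
        track = classify(nat, des)
        assert all(l in LABELS for l in track.labels)

    def test_swapping_inputs_exchanges_functional_and_adaptable(self):
        rng = np.random.default_rng(1)
        nat = make_emap(rng.random((30, 6)) < 0.4)
        des = make_emap(rng.random((30, 6)) < 0.4)
        fwd = np.array(classify(nat, des).labels)
        rev = np.array(classify(des, nat).labels)
        np.testing.assert_array_equal(fwd == "functional", rev == "adaptable")
        np.testing.assert_array_equal(fwd == "structural", rev == "structural")
        np.testing.assert_array_equal(fwd == "unlabeled", rev == "unlabeled")

    def test_identical_inputs_yield_no_functional_or_adaptable(self):
        rng = np.random.default_rng(2)
        emap = make_emap(rng.random((25, 6)) < 0.3)
        labels = set(classify(emap, emap).labels)
        assert "functional" not in labels and "adaptable" not in labels

    def test_same_class_mode_requires_shared_class(self):
        nat = make_emap(_flags(5, [1], class_idx=0))  # acidic enriched
        des = make_emap(_flags(5, [1], class_idx=1))  # basic enriched
        assert classify(nat, des, convergence_mode="same_class").labels[0] == "unlabeled"
        assert classify(nat, des, convergence_mode="any").labels[0] == "structural"
        des2 = make_emap(_flags(5, [1], class_idx=0))
        assert (
            classify(nat, des2, convergence_mode="same_class").labels[0] == "structural"
        )

    def test_provenance_classes_recorded(self):
        nat = make_emap(_flags(5, [1], class_idx=2))
        des = make_emap(np.zeros((5, 6), dtype=bool))
        track = classify(nat, des)
        assert track.natural_classes[0] == frozenset({"hydrophilic"})
        assert track.designed_classes[0] == frozenset()

    def test_query_deviates_when_own_class_not_enriched(self):
        # natural conserves acidic chemistry while the query residue is K
        nat = make_emap(_flags(5, [1], class_idx=0), query="KAAAA")
        des = make_emap(np.zeros((5, 6), dtype=bool), query="KAAAA")
        track = classify(nat, des)
        assert track.query_deviates[0] is True
        nat2 = make_emap(_flags(5, [1], class_idx=0), query="DAAAA")
        track2 = classify(nat2, des)
        assert track2.query_deviates[0] is False

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(IncompatibleInputsError, match="length"):
            classify(make_emap(np.zeros((5, 6), bool)), make_emap(np.zeros((6, 6), bool)))

    def test_mismatched_schemes_rejected(self):
        other = ChemClassScheme.from_dict(
            {
                "charged": "DEKR",
                "polar": "STNQHCY",
                "apolar": "AVLIMFW",
                "gly": "G",
                "pro": "P",
            }
        )
        nat = make_emap(np.zeros((5, 6), bool))
        des = make_emap(np.zeros((5, 5), bool), scheme=other)
        with pytest.raises(IncompatibleInputsError, match="scheme"):
            classify(nat, des)


class TestSummaries:
    def test_all_unlabeled_track(self):
        fr = summarize_fractions(_track(["unlabeled"] * 8))
        assert fr["unlabeled"] == 100.0
        assert sum(fr.values()) == pytest.approx(100.0, abs=0.1)

    def test_ten_position_toy_fractions(self):
        labels = ["functional"] * 2 + ["structural"] * 3 + ["adaptable"] + ["unlabeled"] * 4
        fr = summarize_fractions(_track(labels))
        assert fr == {
            "functional": 20.0,
            "structural": 30.0,
            "adaptable": 10.0,
            "unlabeled": 40.0,
        }

    def test_composition_of_functional_class(self):
        track = _track(
            ["functional", "functional", "functional", "unlabeled"], query="SSHA"
        )
        comp = composition_by_class(track)
        assert comp["functional"]["total"] == 3
        assert comp["functional"]["percentages"]["S"] == pytest.approx(200 / 3)
        assert comp["functional"]["percentages"]["H"] == pytest.approx(100 / 3)

    def test_empty_label_has_zero_total(self):
        comp = composition_by_class(_track(["unlabeled"] * 4))
        assert comp["functional"] == {"total": 0, "counts": {}, "percentages": {}}


class TestCaptureStats:
    def test_empty_key_list(self):
        stats = capture_stats(_track(["unlabeled"] * 5), KeyResidueList(entries=()))
        assert stats == {
            "n_functional": 0,
            "n_structural": 0,
            "n_adaptable": 0,
            "n_unlabeled": 0,
            "n_keys": 0,
        }

    def test_toy_counts(self):
        track = _track(["functional", "structural", "unlabeled", "adaptable"])
        keys = KeyResidueList(entries=((1, "DIP"), (2, "lasso"), (3, "other")))
        stats = capture_stats(track, keys)
        assert stats["n_keys"] == 3
        assert stats["n_functional"] == 1
        assert stats["n_structural"] == 1
        assert stats["n_adaptable"] == 0
        assert stats["n_unlabeled"] == 1
        assert (
            stats["n_functional"]
            + stats["n_structural"]
            + stats["n_adaptable"]
            + stats["n_unlabeled"]
            == stats["n_keys"]
        )

    def test_out_of_range_key_named(self):
        with pytest.raises(KeyRangeError, match="DIP"):
            capture_stats(
                _track(["unlabeled"] * 3), KeyResidueList(entries=((9, "DIP"),))
            )

    def test_key_list_tsv_roundtrip(self, tmp_path):
        f = tmp_path / "keys.tsv"
        f.write_text("199\tAsp_DIP\n453\tArg_lasso\n")
        keys = KeyResidueList.from_tsv(f)
        assert keys.positions == (199, 453)
        assert keys.entries[0][1] == "Asp_DIP"
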