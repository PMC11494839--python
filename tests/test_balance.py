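"""Stratified split and SMOTE oversampling: counts, determinism, convexity."""

import numpy as np
import pytest

from duralseg.balance import (
    SmoteSpec,
    SplitSpec,
    nearest_neighbors,
    smote_oversample,
    stratified_split,
)
from duralseg.records import DatasetManifest, SampleRecord

RNG = np.random.default_rng(21)


def _manifest(n_sdh, n_edh, size=8, with_masks=True, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for label, n in (("SDH", n_sdh), ("EDH", n_edh)):
        for i in range(n):
            img = rng.random((size, size)).astype(np.float32)
            mask = (rng.random((size, size)) > 0.6).astype(np.uint8) if with_masks else None
            recs.append(SampleRecord(image=img, mask=mask, label=label,
                                     id=f"{label.lower()}_{i}"))
    return DatasetManifest(recs)


class TestStratifiedSplit:
    def test_study_counts_reproduced(self):
        """56/173 at 20% must give test {11, 35} and train {45, 138}."""
        train, test = stratified_split(_manifest(56, 173), SplitSpec(0.2, seed=0))
        assert test.counts_by_class == {"SDH": 11, "EDH": 35}
        assert train.counts_by_class == {"SDH": 45, "EDH": 138}
        assert len(test) == 46 and len(train) == 183

    def test_zero_fraction(self):
        train, test = stratified_split(_manifest(5, 5), SplitSpec(0.0))
        assert len(test) == 0 and len(train) == 10

    def test_deterministic(self):
        m = _manifest(20, 30)
        t1 = stratified_split(m, SplitSpec(0.2, seed=4))
        t2 = stratified_split(m, SplitSpec(0.2, seed=4))
        assert [r.id for r in t1[1]] == [r.id for r in t2[1]]

    def test_disjoint_and_exhaustive(self):
        m = _manifest(13, 17)
        train, test = stratified_split(m, SplitSpec(0.3, seed=1))
        ids_train = {r.id for r in train}
        ids_test = {r.id for r in test}
        assert not (ids_train & ids_test)
        assert len(ids_train | ids_test) == 30

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(1.0)


class TestNearestNeighbors:
    def test_collinear_obvious_nearest(self):
        vecs = [np.array([0.0]), np.array([1.0]), np.array([10.0])]
        assert nearest_neighbors(vecs, 0, 1) == [1]

    def test_self_never_returned(self):
        vecs = [RNG.random(4) for _ in range(8)]
        for q in range(8):
            assert q not in nearest_neighbors(vecs, q, 5)

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_matches_exhaustive_pairwise_oracle(self, metric):
        rng = np.random.default_rng(13)
        vecs = [rng.random(6) for _ in range(20)]
        for q in range(20):
            got = nearest_neighbors(vecs, q, 3, metric)
            # independent brute force: python loop over pairs
            dists = []
            for j in range(20):
                if j == q:
                    continue
                if metric == "euclidean":
                    d = float(np.sqrt(((vecs[q] - vecs[j]) ** 2).sum()))
                else:
                    d = 1 - float(vecs[q] @ vecs[j] /
                                  (np.linalg.norm(vecs[q]) * np.linalg.norm(vecs[j])))
                dists.append((d, j))
            expected = [j for _, j in sorted(dists)[:3]]
            assert got == expected

    def test_tie_broken_by_lower_index(self):
        vecs = [np.array([0.0]), np.array([1.0]), np.array([-1.0])]
        assert nearest_neighbors(vecs, 0, 1) == [1]

    def test_k_bounds(self):
        vecs = [np.zeros(2)] * 3
        with pytest.raises(ValueError):
            nearest_neighbors(vecs, 0, 0)
        with pytest.raises(ValueError):
            nearest_neighbors(vecs, 0, 3)


class TestSmote:
    def test_study_targets_reach_828(self):
        m = _manifest(45, 138)
        spec = SmoteSpec(per_class_target={"SDH": 414, "EDH": 414},
                         k_neighbors=5, seed=0)
        out = smote_oversample(m, spec)
        assert out.counts_by_class == {"SDH": 414, "EDH": 414}
        assert len(out) == 828

    def test_noop_targets(self):
        m = _manifest(5, 8)
        out = smote_oversample(m, SmoteSpec(per_class_target={"SDH": 5, "EDH": 8},
                                            k_neighbors=2))
        assert len(out) == 13
        assert not any(r.synthetic for r in out)

    def test_identical_parents_give_identical_child(self):
        img = RNG.random((4, 4)).astype(np.float32)
        recs = [SampleRecord(image=img.copy(), mask=None, label="SDH", id=f"s{i}")
                for i in range(2)]
        recs.append(SampleRecord(image=RNG.random((4, 4)).astype(np.float32) + 0,
                                 mask=None, label="EDH", id="e0"))
        out = smote_oversample(DatasetManifest(recs),
                               SmoteSpec(per_class_target={"SDH": 3}, k_neighbors=1))
        synth = [r for r in out if r.synthetic][0]
        np.testing.assert_allclose(synth.image, img, atol=1e-7)

    def test_synthetic_pixels_convex_in_parents(self):
        """Every synthetic pixel lies within [min, max] of the class's pixels."""
        m = _manifest(6, 4, size=5)
        out = smote_oversample(m, SmoteSpec(per_class_target={"SDH": 20, "EDH": 10},
                                            k_neighbors=3, seed=2))
        for label in ("SDH", "EDH"):
            reals = np.stack([r.image for r in m if r.label == label])
            lo = reals.min(axis=0) - 1e-6
            hi = reals.max(axis=0) + 1e-6
            for r in out:
                if r.synthetic and r.label == label:
                    assert (r.image >= lo).all() and (r.image <= hi).all()

    def test_masks_interpolated_and_binary(self):
        m = _manifest(6, 4, size=5, with_masks=True)
        out = smote_oversample(m, SmoteSpec(per_class_target={"SDH": 12, "EDH": 4},
                                            k_neighbors=2, seed=1))
        for r in out:
            if r.synthetic:
                assert set(np.unique(r.mask)) <= {0, 1}

    def test_real_records_pass_through_unmodified(self):
        m = _manifest(4, 4, size=4)
        originals = {r.id: r.image.copy() for r in m}
        out = smote_oversample(m, SmoteSpec(per_class_target={"SDH": 8, "EDH": 8},
                                            k_neighbors=2, seed=0))
        for r in out:
            if not r.synthetic:
                np.testing.assert_array_equal(r.image, originals[r.id])

    def test_deterministic(self):
        m = _manifest(5, 5, size=4)
        spec = SmoteSpec(per_class_target={"SDH": 9, "EDH": 9}, k_neighbors=2, seed=6)
        o1 = smote_oversample(m, spec)
        o2 = smote_oversample(m, spec)
        for a, b in zip(o1, o2):
            np.testing.assert_array_equal(a.image, b.image)

    def test_k_too_large_rejected(self):
        m = _manifest(3, 10)
        with pytest.raises(ValueError, match="k_neighbors"):
            smote_oversample(m, SmoteSpec(per_class_target={"SDH": 6}, k_neighbors=3))

    def test_target_below_count_rejected(self):
        m = _manifest(5, 5)
        with pytest.raises(ValueError, match="below current"):
            smote_oversample(m, SmoteSpec(per_class_target={"SDH": 3}, k_neighbors=2))

    def test_shape_mismatch_rejected(self):
        recs = [SampleRecord(image=np.zeros((4, 4), np.float32), mask=None,
                             label="SDH", id="a"),
                SampleRecord(image=np.zeros((5, 5), np.float32), mask=None,
                             label="SDH", id="b")]
        with pytest.raises(ValueError, match="shape"):
            smote_oversample(DatasetManifest(recs),
                             SmoteSpec(per_class_target={"SDH": 4}, k_neighbors=1))
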