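"""Index backends: exact oracle, PQ/ADC, IVF, ITQ, mosaic, persistence."""

import numpy as np
import pytest

from patchseek.encoding import unit_normalize
from patchseek.index import (
    ExactIndex,
    ITQHasher,
    ITQLSHIndex,
    IVFPQIndex,
    ProductQuantizer,
    build_exact,
    build_itq_lsh,
    build_ivfpq,
    load_index,
    mosaic_select,
    save_index,
)
from patchseek.patching import PatchRef
from patchseek.synthetic import gen_embedding_clusters


@pytest.fixture(scope="module")
def small_set():
    values, _ = gen_embedding_clusters(500, dim=16, n_clusters=50, noise_sd=0.1, seed=1)
    return values


class TestExactIndex:
    def test_self_match_distance_zero(self, small_set):
        idx = build_exact(small_set)
        res = idx.search(small_set[17], k=1)
        assert res.item_ids[0] == 17
        assert res.distances[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_distance_sqrt2(self):
        X = np.eye(4)
        idx = build_exact(X)
        res = idx.search(np.array([0.0, 0.0, 0.0, 1.0]), k=4)
        assert res.distances[1] == pytest.approx(np.sqrt(2))

    def test_antipodal_distance_two(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        res = build_exact(X).search(np.array([1.0, 0.0]), k=2)
        assert res.distances[1] == pytest.approx(2.0)

    def test_non_unit_rows_rejected(self):
        with pytest.raises(ValueError, match="unit-norm"):
            build_exact(np.ones((3, 4)))

    def test_dimension_mismatch_rejected(self, small_set):
        with pytest.raises(ValueError, match="dimension"):
            build_exact(small_set).search(np.ones(5), k=1)


class TestProductQuantizer:
    def test_lossless_codebook_reproduces_exact_distances(self):
        rng = np.random.default_rng(0)
        X = unit_normalize(rng.standard_normal((20, 8))).values
        pq = ProductQuantizer(m=1, ksub=20, seed=0).fit(X)
        codes = pq.transform(X)
        q = unit_normalize(rng.standard_normal((1, 8))).values[0]
        adc = pq.adc_distance(q, codes)
        exact = np.linalg.norm(X - q, axis=1)
        np.testing.assert_allclose(adc, exact, atol=1e-6)

    def test_code_memory_is_m_bytes_per_item(self, small_set):
        pq = ProductQuantizer(m=8, ksub=16, seed=0).fit(small_set)
        codes = pq.transform(small_set).astype(np.uint8)
        assert codes.shape == (500, 8)
        assert codes.nbytes < small_set.astype(np.float32).nbytes

    def test_adc_error_moderate_vs_oracle(self):
        rng = np.random.default_rng(1)
        X = unit_normalize(rng.standard_normal((100, 16))).values
        pq = ProductQuantizer(m=4, ksub=8, seed=0).fit(X)
        codes = pq.transform(X)
        q = unit_normalize(rng.standard_normal((1, 16))).values[0]
        adc = pq.adc_distance(q, codes)
        exact = np.linalg.norm(X - q, axis=1)
        rel = np.abs(adc - exact) / exact
        assert rel.mean() < 0.3

    def test_indivisible_dimension_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ProductQuantizer(m=3).fit(np.ones((10, 8)))

    def test_ksub_exceeding_items_rejected(self, small_set):
        with pytest.raises(ValueError, match="ksub"):
            ProductQuantizer(m=2, ksub=501).fit(small_set)


class TestIVFPQ:
    def test_lossless_settings_match_exact_oracle(self, small_set):
        """nprobe=nlist with a per-point codebook reproduces brute force."""
        exact = build_exact(small_set)
        ivf = build_ivfpq(small_set, nlist=4, m=1, ksub=500, nprobe=4, seed=0)
        rng = np.random.default_rng(2)
        for qi in rng.integers(0, 500, 25):
            t = exact.search(small_set[qi], k=10)
            a = ivf.search(small_set[qi], k=10)
            np.testing.assert_array_equal(t.item_ids, a.item_ids)

    def test_nprobe_one_stays_in_planted_cluster(self):
        values, labels = gen_embedding_clusters(400, dim=16, n_clusters=8,
                                                noise_sd=0.02, seed=4)
        ivf = build_ivfpq(values, nlist=8, m=4, ksub=64, nprobe=1, seed=0)
        res = ivf.search(values[0], k=5)
        assert (labels[res.item_ids] == labels[0]).all()

    def test_excess_nprobe_clamped_with_warning(self, small_set):
        ivf = build_ivfpq(small_set, nlist=4, m=2, ksub=16, seed=0)
        with pytest.warns(UserWarning, match="clamped"):
            res = ivf.search(small_set[0], k=3, nprobe=99)
        assert len(res) == 3

    def test_short_result_flagged_incomplete(self, small_set):
        ivf = build_ivfpq(small_set, nlist=50, m=2, ksub=16, nprobe=1, seed=0)
        with pytest.warns(UserWarning, match="probed lists"):
            res = ivf.search(small_set[0], k=100, nprobe=1)
        assert not res.complete and len(res) < 100

    def test_distances_sorted_nonnegative(self, small_set):
        ivf = build_ivfpq(small_set, nlist=8, m=4, ksub=32, nprobe=4, seed=0)
        res = ivf.search(small_set[3], k=20)
        assert np.all(res.distances >= 0)
        assert np.all(np.diff(res.distances) >= -1e-12)


class TestITQ:
    def test_identical_vectors_identical_codes(self, small_set):
        itq = build_itq_lsh(small_set, n_bits=32, seed=0)
        codes = itq.hasher_.transform(np.vstack([small_set[5], small_set[5]]))
        np.testing.assert_array_equal(codes[0], codes[1])
        assert itq.search(small_set[5], k=1).distances[0] == 0

    def test_quantization_error_non_increasing(self, small_set):
        hasher = ITQHasher(n_bits=16, n_iter=30, seed=0).fit(small_set)
        errs = np.array(hasher.quantization_errors_)
        assert np.all(np.diff(errs) <= 1e-6)

    def test_more_bits_no_worse_recall(self, clustered_embeddings):
        values, _ = clustered_embeddings
        exact = build_exact(values)
        rng = np.random.default_rng(0)
        queries = rng.integers(0, len(values), 60)
        recalls = {}
        for bits in (32, 64):
            itq = build_itq_lsh(values, n_bits=bits, seed=0)
            rec = [
                len(set(exact.search(values[q], 10).item_ids)
                    & set(itq.search(values[q], 10).item_ids)) / 10
                for q in queries
            ]
            recalls[bits] = np.mean(rec)
        assert recalls[64] >= recalls[32]

    def test_zero_iterations_rejected(self, small_set):
        with pytest.raises(ValueError, match="n_iter"):
            ITQHasher(n_bits=8, n_iter=0).fit(small_set)


class TestMosaicSelect:
    def test_full_fraction_selects_all(self, small_set):
        coords = np.arange(500, dtype=float)[:, None]
        ids = mosaic_select(small_set, coords, fraction=1.0, n_clusters=5, seed=0)
        np.testing.assert_array_equal(ids, np.arange(500))

    def test_single_cluster_picks_nearest_to_centroid(self):
        rng = np.random.default_rng(3)
        values = unit_normalize(rng.standard_normal((100, 8))).values
        coords = rng.standard_normal((100, 2))
        ids = mosaic_select(values, coords, fraction=0.2, n_clusters=1, seed=0)
        assert len(ids) == 20
        # brute-force oracle: rank by distance to the global centroid in
        # the same standardized feature+coordinate space
        def z(a):
            sd = a.std(axis=0)
            sd[sd == 0] = 1
            return (a - a.mean(0)) / sd
        X = np.concatenate([z(values), z(coords)], axis=1)
        d = np.sum((X - X.mean(0)) ** 2, axis=1)
        oracle = np.sort(np.argsort(d, kind="stable")[:20])
        np.testing.assert_array_equal(ids, oracle)

    def test_two_separated_clusters_split_evenly(self):
        values, labels = gen_embedding_clusters(100, dim=8, n_clusters=2,
                                                noise_sd=0.02, seed=5)
        coords = np.stack([labels * 100.0, np.zeros(100)], axis=1)
        ids = mosaic_select(values, coords, fraction=0.1, n_clusters=2, seed=0)
        assert len(ids) == 10
        assert (labels[ids] == 0).sum() == 5 and (labels[ids] == 1).sum() == 5

    def test_too_many_clusters_rejected(self, small_set):
        with pytest.raises(ValueError, match="n_clusters"):
            mosaic_select(small_set, np.zeros((500, 2)), 0.5, n_clusters=501)


class TestPersistence:
    @pytest.mark.parametrize("backend", ["exact", "ivfpq", "itq_lsh"])
    def test_round_trip_preserves_search(self, small_set, tmp_path, backend):
        meta = [PatchRef(f"s{i % 7}", 64 * i, 0, 64) for i in range(500)]
        from patchseek.encoding import EmbeddingMatrix
        emb = EmbeddingMatrix(small_set, meta)
        if backend == "exact":
            idx = build_exact(emb)
        elif backend == "ivfpq":
            idx = build_ivfpq(emb, nlist=8, m=4, ksub=32, nprobe=4, seed=0)
        else:
            idx = build_itq_lsh(emb, n_bits=32, seed=0)
        path = tmp_path / "idx.bin"
        save_index(idx, path)
        back = load_index(path)
        assert back.backend == backend
        assert back.n_items == 500 and back.dim == 16
        assert back.item_meta_[3].slide_id == "s3"
        rng = np.random.default_rng(1)
        for qi in rng.integers(0, 500, 20):
            a = idx.search(small_set[qi], k=10)
            b = back.search(small_set[qi], k=10)
            np.testing.assert_array_equal(a.item_ids, b.item_ids)
            np.testing.assert_allclose(a.distances, b.distances, atol=1e-12)

    def test_truncated_file_errors_cleanly(self, small_set, tmp_path):
        path = tmp_path / "idx.bin"
        save_index(build_exact(small_set), path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="truncated"):
            load_index(path)

    def test_wrong_magic_rejected(self, tmp_path):
        path = tmp_path / "junk.bin"
        path.write_bytes(b"not an index file")
        with pytest.raises(ValueError, match="not a patchseek"):
            load_index(path)
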