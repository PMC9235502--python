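"""Network forward contract: shapes, oracle equivalence, invariances."""

import numpy as np
import pytest

from mhc2bind import AffinityRecord, AlleleRegistry, ModelConfig, encode_pair, forward
from mhc2bind.alphabet import DEFAULT_ALPHABET
from mhc2bind.model import (
    backward_batch,
    embed,
    forward_batch,
    init_params,
    load_params,
    make_kernels,
    pack_batch,
    save_params,
    trainable_keys,
)

from conftest import TINY_MODEL

LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_peptide(rng, L):
    return "".join(LETTERS[rng.integers(0, 20, L)])


def random_pseudo(rng):
    return "".join(LETTERS[rng.integers(0, 20, 34)])


def naive_bicl(X, Y, params, config):
    """Brute-force reference: explicit loops over rows, kernels, positions.

    Written independently of the vectorized path: pads the peptide per
    kernel size, generates each kernel as relu(W_k @ Y) and accumulates the
    Frobenius inner product term by term.
    """
    L, d = X.shape
    R = L - config.core_length + 1
    columns = []
    for M in config.kernel_sizes:
        W = params[f"conv{M}_W"]
        b = params[f"conv{M}_b"]
        a = (M - config.core_length) // 2
        Xp = np.zeros((L + 2 * a, d))
        Xp[a : a + L] = X
        for k in range(W.shape[0]):
            kernel = np.maximum(W[k] @ Y, 0.0)  # (M, d)
            col = np.zeros(R)
            for i in range(R):
                acc = 0.0
                for m in range(M):
                    for e in range(d):
                        acc += kernel[m, e] * Xp[i + m, e]
                col[i] = max(acc + b[k], 0.0)
            columns.append(col)
    return np.stack(columns, axis=1)  # (R, h0)


def single_forward_c0(peptide, pseudo, params, config):
    """Vectorized C0 (post-activation, pre-batchnorm) for one pair."""
    enc_pep = DEFAULT_ALPHABET.encode(peptide)
    enc_pse = DEFAULT_ALPHABET.encode(pseudo)
    pep = enc_pep[None, :]
    pse = enc_pse[None, :]
    lengths = np.array([len(peptide)])
    _, _, _, cache = forward_batch(params, config, pep, pse, lengths, return_cache=True)
    return cache["C0"][0]


class TestBiclOracle:
    def test_matches_brute_force_on_random_instances(self):
        """Vectorized convolution equals the naive triple loop to 1e-5."""
        rng = np.random.default_rng(0)
        config = ModelConfig(
            embed_dim=3, kernel_sizes=(9, 11), kernels_per_size=(2, 2),
            fc_sizes=(4,), dropout_rate=0.0,
        )
        for _ in range(100):
            params = init_params(config, rng)
            # nonzero pad-free random embeddings drive both paths
            peptide = random_peptide(rng, int(rng.integers(9, 21)))
            pseudo = random_pseudo(rng)
            X = params["pep_emb"][DEFAULT_ALPHABET.encode(peptide)]
            Y = params["pse_emb"][DEFAULT_ALPHABET.encode(pseudo)]
            expected = naive_bicl(X, Y, params, config)
            got = single_forward_c0(peptide, pseudo, params, config)
            np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_zero_weight_matrix_gives_zero_kernels(self):
        rng = np.random.default_rng(1)
        params = init_params(TINY_MODEL, rng)
        params["conv9_W"][:] = 0.0
        Y = rng.normal(size=(34, TINY_MODEL.embed_dim))
        kernels = make_kernels(Y, params, 9)
        assert kernels.shape == (3, 9, TINY_MODEL.embed_dim)
        assert np.all(kernels == 0.0)

    def test_kernel_shape_full_scale(self):
        rng = np.random.default_rng(2)
        config = ModelConfig()  # d=16, 256 kernels of size 9
        params = init_params(config, rng)
        Y = rng.normal(size=(34, 16))
        assert make_kernels(Y, params, 9).shape == (256, 9, 16)

    def test_identical_pseudo_sequences_identical_kernels(self, registry):
        rng = np.random.default_rng(3)
        params = init_params(TINY_MODEL, rng)
        Y = params["pse_emb"][DEFAULT_ALPHABET.encode(registry["DRB1*01:01"])]
        k1 = make_kernels(Y, params, 9)
        k2 = make_kernels(Y.copy(), params, 9)
        np.testing.assert_array_equal(k1, k2)


class TestShapeLaw:
    @pytest.mark.parametrize("L", range(9, 31))
    def test_all_kernel_sizes_yield_L_minus_8_rows(self, L):
        rng = np.random.default_rng(L)
        config = ModelConfig(
            embed_dim=3, kernel_sizes=(9, 11, 13, 15), kernels_per_size=(2, 2, 2, 2),
            fc_sizes=(4,), dropout_rate=0.0,
        )
        params = init_params(config, rng)
        c0 = single_forward_c0(random_peptide(rng, L), random_pseudo(rng), params, config)
        assert c0.shape == (L - 8, config.n_channels)

    def test_default_config_channel_count(self):
        assert ModelConfig().n_channels == 512

    def test_even_flank_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_sizes=(10,), kernels_per_size=(4,))


class TestEmbedding:
    def test_shapes_and_pad_row(self, registry):
        rng = np.random.default_rng(4)
        params = init_params(TINY_MODEL, rng)
        rec = AffinityRecord("ACDEFGHIKLMNPQR", "DRB1*01:01", 0.5)
        X, Y = embed(encode_pair(rec, registry), params)
        assert X.shape == (15, 4) and Y.shape == (34, 4)
        assert np.all(params["pep_emb"][DEFAULT_ALPHABET.pad_index] == 0.0)

    def test_identical_residues_identical_rows(self, registry):
        rng = np.random.default_rng(5)
        params = init_params(TINY_MODEL, rng)
        rec = AffinityRecord("AADEFGHIK", "DRB1*01:01", 0.5)
        X, _ = embed(encode_pair(rec, registry), params)
        np.testing.assert_array_equal(X[0], X[1])


class TestHeadAndPooling:
    def test_zero_network_outputs_half(self, registry):
        """All-zero activations through a zero output layer give sigmoid(0)."""
        config = ModelConfig(
            embed_dim=4, kernel_sizes=(9,), kernels_per_size=(3,),
            fc_sizes=(5,), dropout_rate=0.0, use_batchnorm=False,
        )
        params = init_params(config, np.random.default_rng(6))
        for key in trainable_keys(params):
            params[key][...] = 0.0
        rec = AffinityRecord("ACDEFGHIKLM", "DRB1*01:01", 0.5)
        assert forward(encode_pair(rec, registry), params, config) == pytest.approx(0.5)

    def test_max_pool_matches_explicit_loop(self, registry):
        """Channel-wise masked max equals a per-channel loop over valid rows."""
        config = ModelConfig(
            embed_dim=4, kernel_sizes=(9, 11), kernels_per_size=(3, 2),
            fc_sizes=(6,), dropout_rate=0.0, use_batchnorm=False,
        )
        params = init_params(config, np.random.default_rng(7))
        recs = [
            AffinityRecord("ACDEFGHIKLMNPQR", "DRB1*01:01", 0.5),
            AffinityRecord("WYACDEFGH", "H-2-IAb", 0.5),  # shorter: padded rows
        ]
        pairs = [encode_pair(r, registry) for r in recs]
        pep, pse, lengths, _ = pack_batch(pairs)
        _, _, _, cache = forward_batch(params, config, pep, pse, lengths, return_cache=True)
        CN, mask = cache["CN"], cache["rows_mask"]
        _, _, g = cache["pool_cache"]
        for b in range(len(recs)):
            valid = int(mask[b].sum())
            for j in range(CN.shape[2]):
                expected = max(CN[b, i, j] for i in range(valid))
                assert g[b, j] == pytest.approx(expected)

    def test_duplicated_row_leaves_pool_unchanged(self):
        # max over rows is idempotent under duplication
        rows = np.array([[1.0, -2.0], [3.0, 0.5]])
        assert np.array_equal(rows.max(0), np.vstack([rows, rows[1]]).max(0))

    def test_score_max_pooling_identity(self, registry):
        """With score pooling and no batchnorm the pooled prediction equals
        the max per-start core score exactly."""
        config = ModelConfig(
            embed_dim=4, kernel_sizes=(9, 11), kernels_per_size=(3, 2),
            fc_sizes=(6, 5), dropout_rate=0.0, use_batchnorm=False,
            pooling="score_max",
        )
        params = init_params(config, np.random.default_rng(8))
        rec = AffinityRecord("ACDEFGHIKLMNPQR", "DRB1*01:01", 0.5)
        trace = forward(encode_pair(rec, registry), params, config, return_trace=True)
        assert trace.z_hat == pytest.approx(np.max(trace.core_scores), abs=1e-12)


class TestForwardProperties:
    def test_output_in_unit_interval(self, registry, tiny_records):
        params = init_params(TINY_MODEL, np.random.default_rng(9))
        for rec in tiny_records[:10]:
            z = forward(encode_pair(rec, registry), params, TINY_MODEL)
            assert 0.0 < z < 1.0

    def test_eval_deterministic_and_batch_order_invariant(self, registry, tiny_records):
        params = init_params(TINY_MODEL, np.random.default_rng(10))
        pairs = [encode_pair(r, registry) for r in tiny_records[:8]]
        pep, pse, lengths, _ = pack_batch(pairs)
        z1, _, _ = forward_batch(params, TINY_MODEL, pep, pse, lengths)
        z2, _, _ = forward_batch(params, TINY_MODEL, pep, pse, lengths)
        np.testing.assert_array_equal(z1, z2)
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        z3, _, _ = forward_batch(params, TINY_MODEL, pep[perm], pse[perm], lengths[perm])
        np.testing.assert_allclose(z3, z1[perm], atol=1e-12)

    def test_allele_sensitivity(self):
        """Changing one pseudo residue changes the convolution output."""
        rng = np.random.default_rng(11)
        config = ModelConfig(
            embed_dim=4, kernel_sizes=(9,), kernels_per_size=(4,),
            fc_sizes=(4,), dropout_rate=0.0,
        )
        params = init_params(config, rng)
        peptide = random_peptide(rng, 14)
        pseudo = random_pseudo(rng)
        mutated = pseudo[:17] + ("A" if pseudo[17] != "A" else "C") + pseudo[18:]
        c0_a = single_forward_c0(peptide, pseudo, params, config)
        c0_b = single_forward_c0(peptide, mutated, params, config)
        assert np.abs(c0_a - c0_b).max() > 0.0

    def test_translation_covariance_size9_group(self):
        """Shifting peptide content by one position shifts the size-9 rows."""
        rng = np.random.default_rng(12)
        config = ModelConfig(
            embed_dim=4, kernel_sizes=(9,), kernels_per_size=(3,),
            fc_sizes=(4,), dropout_rate=0.0,
        )
        params = init_params(config, rng)
        pseudo = random_pseudo(rng)
        pep = random_peptide(rng, 12)
        shifted = "A" + pep  # prepend one residue
        c0 = single_forward_c0(pep, pseudo, params, config)
        c0s = single_forward_c0(shifted, pseudo, params, config)
        np.testing.assert_allclose(c0s[1:], c0, atol=1e-10)

    def test_extension_preserves_existing_windows(self):
        """Appending residues adds candidate cores without removing any:
        the new window set is a superset, checked via the size-9 rows."""
        rng = np.random.default_rng(13)
        config = ModelConfig(
            embed_dim=4, kernel_sizes=(9,), kernels_per_size=(3,),
            fc_sizes=(4,), dropout_rate=0.0,
        )
        params = init_params(config, rng)
        pseudo = random_pseudo(rng)
        pep = random_peptide(rng, 11)
        extended = pep + "KL"
        c0 = single_forward_c0(pep, pseudo, params, config)
        c0e = single_forward_c0(extended, pseudo, params, config)
        assert c0e.shape[0] == c0.shape[0] + 2
        np.testing.assert_allclose(c0e[: c0.shape[0]], c0, atol=1e-10)

    def test_short_peptide_rejected(self, registry):
        params = init_params(TINY_MODEL, np.random.default_rng(14))
        pep = DEFAULT_ALPHABET.encode("ACDEFGH")[None, :]
        pse = DEFAULT_ALPHABET.encode(registry["H-2-IAb"])[None, :]
        with pytest.raises(ValueError):
            forward_batch(params, TINY_MODEL, pep, pse, np.array([7]))


class TestGradients:
    def test_backward_matches_finite_differences(self, registry, tiny_records):
        """Analytic gradients agree with central differences on every
        parameter tensor (training mode, batchnorm on, dropout off)."""
        config = ModelConfig(
            embed_dim=3, kernel_sizes=(9, 11), kernels_per_size=(2, 2),
            fc_sizes=(4, 3), dropout_rate=0.0,
        )
        rng = np.random.default_rng(15)
        params = init_params(config, rng)
        pairs = [encode_pair(r, registry) for r in tiny_records[:5]]
        pep, pse, lengths, targets = pack_batch(pairs)

        def total_loss():
            z, _, _, cache = forward_batch(
                params, config, pep, pse, lengths, training=True,
                rng=np.random.default_rng(0), return_cache=True,
            )
            return float(np.mean((z - targets) ** 2)), cache, z

        base, cache, z = total_loss()
        dz = 2.0 * (z - targets) / len(z)
        grads = backward_batch(params, config, cache, dz)
        eps = 1e-6
        check_rng = np.random.default_rng(16)
        for key in trainable_keys(params):
            flat = params[key].reshape(-1)
            gflat = grads[key].reshape(-1)
            for i in check_rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = total_loss()
                flat[i] = orig - eps
                lm, _, _ = total_loss()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(fd, abs=1e-7, rel=1e-4), key

    def test_pad_embedding_gradient_frozen(self, registry, tiny_records):
        params = init_params(TINY_MODEL, np.random.default_rng(17))
        pairs = [encode_pair(r, registry) for r in tiny_records[:6]]
        pep, pse, lengths, targets = pack_batch(pairs)
        z, _, _, cache = forward_batch(
            params, TINY_MODEL, pep, pse, lengths, training=True,
            rng=np.random.default_rng(0), return_cache=True,
        )
        grads = backward_batch(params, TINY_MODEL, cache, 2 * (z - targets) / len(z))
        assert np.all(grads["pep_emb"][DEFAULT_ALPHABET.pad_index] == 0.0)
        assert np.all(grads["pse_emb"][DEFAULT_ALPHABET.pad_index] == 0.0)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        params = init_params(TINY_MODEL, np.random.default_rng(18))
        path = tmp_path / "model.npz"
        save_params(path, params, TINY_MODEL)
        loaded, config = load_params(path)
        assert config == TINY_MODEL
        for key, value in params.items():
            np.testing.assert_array_equal(loaded[key], value)
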