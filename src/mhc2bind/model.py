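"""Binding-interaction convolutional network for MHC-II affinity regression.

The network scores a (peptide, allele) pair by scanning every candidate
9-mer binding core of the peptide with convolution kernels that are
*generated from the allele's 34-residue pseudo sequence*: for each kernel k
of size M, a learned weight matrix ``W_k`` (M x 34) maps the embedded pseudo
sequence ``Y`` (34 x d) to a kernel ``relu(W_k @ Y)`` (M x d), which is then
correlated (Frobenius inner product) with each M-residue window of the
embedded peptide. Kernel sizes above 9 see (M-9)/2 flanking residues on each
side of the candidate core; the peptide is padded symmetrically so every
size yields the same L-8 rows, one per candidate core start. The rows pass
through fully connected layers, a masked max-pool over candidate cores, and
a sigmoid output in (0, 1).

Everything here runs on numpy with hand-written backward passes; gradients
are validated against finite differences in the test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .alphabet import DEFAULT_ALPHABET, Alphabet
from .data import CORE_LENGTH, PSEUDO_LENGTH, EncodedPair

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale model: 16-dimensional embeddings,
    256/128/64/64 kernels of sizes 9/11/13/15, two fully connected layers of
    256 and 128 units, dropout 0.25 and batch normalization after the
    convolution and each fully connected layer.

    ``pooling`` selects how candidate-core rows are reduced: ``channel_max``
    takes a per-channel max over rows before the output layer (the printed
    formulation); ``score_max`` pools the per-row pre-sigmoid scores, which
    makes the pooled prediction exactly the max of the per-core scores.
    """

    embed_dim: int = 16
    kernel_sizes: tuple[int, ...] = (9, 11, 13, 15)
    kernels_per_size: tuple[int, ...] = (256, 128, 64, 64)
    fc_sizes: tuple[int, ...] = (256, 128)
    dropout_rate: float = 0.25
    use_batchnorm: bool = True
    pooling: str = "channel_max"
    core_length: int = CORE_LENGTH

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != len(self.kernels_per_size):
            raise ValueError("kernel_sizes and kernels_per_size must have equal length")
        for m in self.kernel_sizes:
            if m < self.core_length or (m - self.core_length) % 2:
                raise ValueError(
                    f"kernel size {m} must be >= {self.core_length} and differ by an even flank"
                )
        if self.pooling not in ("channel_max", "score_max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if not self.fc_sizes:
            raise ValueError("at least one fully connected layer is required")

    @property
    def n_channels(self) -> int:
        return sum(self.kernels_per_size)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("kernel_sizes", "kernels_per_size", "fc_sizes"):
            d[key] = tuple(d[key])
        return cls(**d)


def init_params(
    config: ModelConfig,
    rng: np.random.Generator,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> dict[str, np.ndarray]:
    """Initialize all learnable tensors (uniform fan-in scaling, seeded).

    The padding token's embedding rows are zero and stay zero throughout
    training so that flank/batch padding is information-free.
    """
    d = config.embed_dim
    params: dict[str, np.ndarray] = {}
    params["pep_emb"] = rng.uniform(-0.5, 0.5, size=(alphabet.size, d))
    params["pse_emb"] = rng.uniform(-0.5, 0.5, size=(alphabet.size, d))
    params["pep_emb"][alphabet.pad_index] = 0.0
    params["pse_emb"][alphabet.pad_index] = 0.0
    for m, h in zip(config.kernel_sizes, config.kernels_per_size):
        bound = 1.0 / np.sqrt(PSEUDO_LENGTH)
        params[f"conv{m}_W"] = rng.uniform(-bound, bound, size=(h, m, PSEUDO_LENGTH))
        params[f"conv{m}_b"] = np.zeros(h)
    sizes = (config.n_channels,) + tuple(config.fc_sizes)
    params["bn0_gamma"] = np.ones(sizes[0])
    params["bn0_beta"] = np.zeros(sizes[0])
    params["bn0_mean"] = np.zeros(sizes[0])
    params["bn0_var"] = np.ones(sizes[0])
    for n in range(1, len(sizes)):
        fan_in = sizes[n - 1]
        bound = 1.0 / np.sqrt(fan_in)
        params[f"fc{n}_W"] = rng.uniform(-bound, bound, size=(fan_in, sizes[n]))
        params[f"fc{n}_b"] = np.zeros(sizes[n])
        params[f"bn{n}_gamma"] = np.ones(sizes[n])
        params[f"bn{n}_beta"] = np.zeros(sizes[n])
        params[f"bn{n}_mean"] = np.zeros(sizes[n])
        params[f"bn{n}_var"] = np.ones(sizes[n])
    bound = 1.0 / np.sqrt(sizes[-1])
    params["out_w"] = rng.uniform(-bound, bound, size=sizes[-1])
    params["out_b"] = np.zeros(())
    return params


def trainable_keys(params: dict[str, np.ndarray]) -> list[str]:
    """Keys of tensors updated by the optimizer (excludes batchnorm running stats)."""
    return [k for k in params if not (k.endswith("_mean") or k.endswith("_var"))]


# ---------------------------------------------------------------------------
# batching


def pack_batch(
    pairs: Sequence[EncodedPair],
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of encoded pairs to a rectangular batch.

    Returns ``(pep_ids, pseudo_ids, lengths, targets)``; peptides are padded
    to the batch maximum length with the pad token. ``targets`` contains NaN
    where a pair has no target.
    """
    B = len(pairs)
    lengths = np.array([p.peptide_length for p in pairs], dtype=np.int64)
    lmax = int(lengths.max())
    pep = np.full((B, lmax), alphabet.pad_index, dtype=np.int64)
    pse = np.empty((B, PSEUDO_LENGTH), dtype=np.int64)
    targets = np.full(B, np.nan)
    for i, p in enumerate(pairs):
        pep[i, : p.peptide_length] = p.peptide_ids
        pse[i] = p.pseudo_ids
        if p.target is not None:
            targets[i] = p.target
    return pep, pse, lengths, targets


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(x, -60.0, 60.0)))


def _index_add(out: np.ndarray, ids: np.ndarray, values: np.ndarray) -> None:
    """Row-indexed accumulation ``out[ids[n]] += values[n]`` via a one-hot
    matmul (much faster than np.add.at for a small row count)."""
    onehot = np.zeros((out.shape[0], len(ids)))
    onehot[ids, np.arange(len(ids))] = 1.0
    out += onehot @ values


def _masked_bn_forward(x, mask, gamma, beta, run_mean, run_var, training):
    """Batchnorm over the channel axis, restricted to mask-valid entries.

    ``x``: (B, R, h); ``mask``: (B, R) float in {0, 1}. Running statistics
    are updated in place in training mode.
    """
    w = mask[..., None]
    if training:
        n = w.sum()
        mu = (x * w).sum(axis=(0, 1)) / n
        xc = x - mu
        var = (xc * xc * w).sum(axis=(0, 1)) / n
        run_mean *= 1.0 - _BN_MOMENTUM
        run_mean += _BN_MOMENTUM * mu
        run_var *= 1.0 - _BN_MOMENTUM
        run_var += _BN_MOMENTUM * var
    else:
        mu = run_mean
        xc = x - mu
        var = run_var
        n = None
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = xc * inv
    y = gamma * xhat + beta
    cache = (xc, xhat, inv, gamma, w, n, training)
    return y, cache


def _masked_bn_backward(dy, cache):
    xc, xhat, inv, gamma, w, n, training = cache
    dy = dy * w
    dgamma = (dy * xhat).sum(axis=(0, 1))
    dbeta = dy.sum(axis=(0, 1))
    dxhat = dy * gamma
    if not training:
        return dxhat * inv, dgamma, dbeta
    dvar = (dxhat * xc).sum(axis=(0, 1)) * (-0.5) * inv**3
    dmu = (dxhat * (-inv)).sum(axis=(0, 1)) + dvar * (-2.0 * (xc * w).sum(axis=(0, 1)) / n)
    dx = (dxhat * inv + dvar * 2.0 * xc / n + dmu / n) * w
    return dx, dgamma, dbeta


def forward_batch(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    pep_ids: np.ndarray,
    pseudo_ids: np.ndarray,
    lengths: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Run the network on a padded batch.

    Returns ``(z, core_scores, rows_mask)`` — and a cache for the backward
    pass when ``return_cache`` is set. ``z`` (B,) is the pooled affinity
    prediction; ``core_scores`` (B, R) holds the per-candidate-core sigmoid
    scores used for binding-core calling (max-pool removed), with NaN at
    invalid rows.
    """
    if training and config.dropout_rate > 0 and rng is None:
        raise ValueError("training mode with dropout requires an rng")
    B, lmax = pep_ids.shape
    if int(lengths.min()) < config.core_length:
        raise ValueError(f"all peptides must have length >= {config.core_length}")
    R = lmax - config.core_length + 1
    rows_mask = (np.arange(R)[None, :] < (lengths - config.core_length + 1)[:, None]).astype(float)

    X = params["pep_emb"][pep_ids]  # (B, Lmax, d)
    # batches carry few distinct alleles, so kernels are generated once per
    # unique pseudo sequence and indexed back into the batch
    uniq_pse, inverse = np.unique(pseudo_ids, axis=0, return_inverse=True)
    Yu = params["pse_emb"][uniq_pse]  # (U, 34, d)

    # --- allele-conditioned convolution, one group per kernel size;
    # the window-kernel contraction runs as one matmul per unique allele
    allele_rows = [np.flatnonzero(inverse == u) for u in range(len(uniq_pse))]
    d = X.shape[2]
    group_caches = []
    s_parts = []
    for m in config.kernel_sizes:
        W = params[f"conv{m}_W"]  # (h, m, 34)
        b = params[f"conv{m}_b"]
        h = W.shape[0]
        a = (m - config.core_length) // 2
        if a:
            Xp = np.pad(X, ((0, 0), (a, a), (0, 0)))
        else:
            Xp = X
        # V[b, i, e, j] = Xp[b, i + j, e] : window j-th position, channel e
        V = np.lib.stride_tricks.sliding_window_view(Xp, m, axis=1)  # (B, R, d, m)
        A = np.einsum("kmq,uqe->ukme", W, Yu)  # kernel pre-activation per allele
        K = np.maximum(A, 0.0)  # generated kernels, (U, h, m, d)
        Kp = np.ascontiguousarray(K.transpose(0, 1, 3, 2)).reshape(-1, h, d * m)
        S = np.empty((B, R, h))
        v_flats = []
        for u, rows in enumerate(allele_rows):
            Vr = V[rows].reshape(-1, d * m)  # (n*R, d*m)
            S[rows] = (Vr @ Kp[u].T).reshape(len(rows), R, h)
            v_flats.append(Vr)
        S += b
        s_parts.append(S)
        group_caches.append((m, A, K, Kp, v_flats))
    C0_pre = np.concatenate(s_parts, axis=2)  # (B, R, h0)
    C0 = np.maximum(C0_pre, 0.0)

    bn_caches = {}
    if config.use_batchnorm:
        C, bn_caches[0] = _masked_bn_forward(
            C0, rows_mask, params["bn0_gamma"], params["bn0_beta"],
            params["bn0_mean"], params["bn0_var"], training,
        )
    else:
        C = C0

    fc_caches = []
    drop_masks = {}
    for n in range(1, len(config.fc_sizes) + 1):
        Z = C @ params[f"fc{n}_W"] + params[f"fc{n}_b"]
        if config.use_batchnorm:
            Zn, bn_caches[n] = _masked_bn_forward(
                Z, rows_mask, params[f"bn{n}_gamma"], params[f"bn{n}_beta"],
                params[f"bn{n}_mean"], params[f"bn{n}_var"], training,
            )
        else:
            Zn = Z
        H = np.maximum(Zn, 0.0)
        if training and config.dropout_rate > 0:
            keep = (rng.random(H.shape) >= config.dropout_rate) / (1.0 - config.dropout_rate)
            H = H * keep
            drop_masks[n] = keep
        fc_caches.append((C, Z, Zn, H))
        C = H
    CN = C  # (B, R, hN)

    u = CN @ params["out_w"] + params["out_b"]  # per-row pre-sigmoid scores (B, R)
    core_scores = np.where(rows_mask > 0, _sigmoid(u), np.nan)

    neg = np.finfo(float).min
    if config.pooling == "channel_max":
        masked = np.where(rows_mask[..., None] > 0, CN, neg)
        arg = masked.argmax(axis=1)  # (B, hN)
        g = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]
        pre = g @ params["out_w"] + params["out_b"]
        pool_cache = ("channel_max", arg, g)
    else:
        masked_u = np.where(rows_mask > 0, u, neg)
        arg = masked_u.argmax(axis=1)  # (B,)
        pre = np.take_along_axis(masked_u, arg[:, None], axis=1)[:, 0]
        pool_cache = ("score_max", arg, None)
    z = _sigmoid(pre)

    if not return_cache:
        return z, core_scores, rows_mask
    cache = dict(
        pep_ids=pep_ids, uniq_pse=uniq_pse, inverse=inverse, rows_mask=rows_mask,
        allele_rows=allele_rows, X=X, Yu=Yu,
        group_caches=group_caches, C0_pre=C0_pre, C0=C0,
        bn_caches=bn_caches, fc_caches=fc_caches, drop_masks=drop_masks,
        CN=CN, pool_cache=pool_cache, pre=pre, z=z, training=training,
    )
    return z, core_scores, rows_mask, cache


def backward_batch(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    cache: dict,
    dz: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss with upstream gradient ``dz`` on z."""
    grads = {k: np.zeros_like(v) for k, v in params.items()
             if not (k.endswith("_mean") or k.endswith("_var"))}
    z = cache["z"]
    rows_mask = cache["rows_mask"]
    CN = cache["CN"]
    dpre = dz * z * (1.0 - z)

    kind, arg, g = cache["pool_cache"]
    dCN = np.zeros_like(CN)
    if kind == "channel_max":
        grads["out_w"] += (dpre[:, None] * g).sum(axis=0)
        grads["out_b"] += dpre.sum()
        dg = dpre[:, None] * params["out_w"]  # (B, hN)
        np.put_along_axis(dCN, arg[:, None, :], dg[:, None, :], axis=1)
    else:
        du_row = dpre  # gradient lands on the argmax row's score
        rows = arg
        b_idx = np.arange(len(rows))
        grads["out_w"] += (du_row[:, None] * CN[b_idx, rows]).sum(axis=0)
        grads["out_b"] += du_row.sum()
        dCN[b_idx, rows] = du_row[:, None] * params["out_w"]

    dC = dCN
    for n in range(len(config.fc_sizes), 0, -1):
        Cin, Z, Zn, H = cache["fc_caches"][n - 1]
        if n in cache["drop_masks"]:
            dC = dC * cache["drop_masks"][n]
        dZn = dC * (Zn > 0)
        if config.use_batchnorm:
            dZ, dgam, dbet = _masked_bn_backward(dZn, cache["bn_caches"][n])
            grads[f"bn{n}_gamma"] += dgam
            grads[f"bn{n}_beta"] += dbet
        else:
            dZ = dZn
        grads[f"fc{n}_W"] += np.einsum("bri,brj->ij", Cin, dZ)
        grads[f"fc{n}_b"] += dZ.sum(axis=(0, 1))
        dC = dZ @ params[f"fc{n}_W"].T

    if config.use_batchnorm:
        dC0, dgam, dbet = _masked_bn_backward(dC, cache["bn_caches"][0])
        grads["bn0_gamma"] += dgam
        grads["bn0_beta"] += dbet
    else:
        dC0 = dC
    dC0_pre = dC0 * (cache["C0_pre"] > 0)

    X, Yu = cache["X"], cache["Yu"]
    allele_rows = cache["allele_rows"]
    B, lmax, d = X.shape
    dX = np.zeros_like(X)
    dYu = np.zeros_like(Yu)
    offset = 0
    for (m, A, K, Kp, v_flats) in cache["group_caches"]:
        h = K.shape[1]
        dS = dC0_pre[:, :, offset : offset + h]  # (B, R, h)
        offset += h
        R = dS.shape[1]
        grads[f"conv{m}_b"] += dS.sum(axis=(0, 1))
        dV = np.empty((B, R, d, m))
        dKp = np.empty_like(Kp)  # (U, h, d*m), gradients aggregate per allele
        for u, rows in enumerate(allele_rows):
            dSr = dS[rows].reshape(-1, h)  # (n*R, h)
            dV[rows] = (dSr @ Kp[u]).reshape(len(rows), R, d, m)
            dKp[u] = dSr.T @ v_flats[u]
        dK = dKp.reshape(K.shape[0], h, d, m).transpose(0, 1, 3, 2)
        dA = dK * (A > 0)
        grads[f"conv{m}_W"] += np.einsum("ukme,uqe->kmq", dA, Yu, optimize=True)
        dYu += np.einsum("ukme,kmq->uqe", dA, params[f"conv{m}_W"], optimize=True)
        a = (m - config.core_length) // 2
        dXp = np.zeros((B, lmax + 2 * a, d))
        for j in range(m):
            dXp[:, j : j + R, :] += dV[:, :, :, j]
        dX += dXp[:, a : a + lmax, :] if a else dXp

    _index_add(grads["pep_emb"], cache["pep_ids"].reshape(-1), dX.reshape(-1, d))
    _index_add(grads["pse_emb"], cache["uniq_pse"].reshape(-1), dYu.reshape(-1, d))
    # padding embeddings are frozen at zero
    grads["pep_emb"][DEFAULT_ALPHABET.pad_index] = 0.0
    grads["pse_emb"][DEFAULT_ALPHABET.pad_index] = 0.0
    return grads


# ---------------------------------------------------------------------------
# single-example views (readable contracts; thin wrappers over the batch path)


@dataclass
class ForwardTrace:
    """Intermediate tensors of one forward pass, for inspection and tests."""

    X: np.ndarray
    Y: np.ndarray
    C0: np.ndarray
    CN: np.ndarray
    g: np.ndarray | None
    z_hat: float
    core_scores: np.ndarray
    valid_rows: int


def embed(encoded: EncodedPair, params: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Embedding-table lookup: peptide rows X (L x d) and pseudo rows Y (34 x d)."""
    return params["pep_emb"][encoded.peptide_ids], params["pse_emb"][encoded.pseudo_ids]


def make_kernels(Y: np.ndarray, params: dict[str, np.ndarray], kernel_size: int) -> np.ndarray:
    """Generate the allele-conditioned kernel stack relu(W_k @ Y), shape (h, M, d)."""
    W = params[f"conv{kernel_size}_W"]
    return np.maximum(np.einsum("kmq,qe->kme", W, Y), 0.0)


def forward(
    encoded: EncodedPair,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    return_trace: bool = False,
):
    """Predict the affinity of one encoded pair in eval mode."""
    pep, pse, lengths, _ = pack_batch([encoded])
    out = forward_batch(params, config, pep, pse, lengths, training=False,
                        return_cache=return_trace)
    if not return_trace:
        z, core_scores, _ = out
        return float(z[0])
    z, core_scores, rows_mask, cache = out
    kind, arg, g = cache["pool_cache"]
    return ForwardTrace(
        X=cache["X"][0], Y=cache["Yu"][cache["inverse"][0]],
        C0=cache["C0"][0], CN=cache["CN"][0],
        g=g[0] if g is not None else None, z_hat=float(z[0]),
        core_scores=core_scores[0][rows_mask[0] > 0],
        valid_rows=int(rows_mask[0].sum()),
    )


# ---------------------------------------------------------------------------
# checkpoints


def _alphabet_hash(alphabet: Alphabet = DEFAULT_ALPHABET) -> str:
    text = alphabet.canonical_tokens + alphabet.unknown_token + alphabet.pad_token
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def save_params(path, params: dict[str, np.ndarray], config: ModelConfig) -> None:
    """Serialize one parameter set with its config and alphabet stamp."""
    meta = json.dumps({
        "version": _CHECKPOINT_VERSION,
        "config": config.to_dict(),
        "alphabet": _alphabet_hash(),
    })
    np.savez(path, __meta__=np.array(meta), **params)


def load_params(path) -> tuple[dict[str, np.ndarray], ModelConfig]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        if meta["alphabet"] != _alphabet_hash():
            raise ValueError("checkpoint was built with a different alphabet")
        params = {k: npz[k] for k in npz.files if k != "__meta__"}
    return params, ModelConfig.from_dict(meta["config"])
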