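"""Thrifty CNN models and k-mer table baselines for somatic hypermutation.

Every model maps a parent nucleotide sequence to two per-site outputs:

* a mutation rate profile ``lambda_i > 0`` (exponential waiting-time rate),
* a conditional substitution probability (CSP) row ``p_i`` over A,C,G,T —
  the distribution of the new base given a mutation, with the parent base
  forced to probability 0.

The thrifty architecture is: trainable embedding of each overlapping 3-mer
(65 tokens: 64 canonical + 1 wildcard) -> length-preserving 1-D convolution
(kernel x embed_dim x filters, bias, symmetric zero padding) -> ReLU ->
dropout (training only) -> per-site affine heads. A kernel of size k sees k
consecutive 3-mers, i.e. k+2 bases of context, so kernel 11 is effectively
a 13-mer model while its parameter count grows only linearly in kernel.

The two outputs can share everything but the final layer ("joined"), only
the embedding ("hybrid"), or nothing ("independent").

Networks are implemented directly in NumPy (forward + analytic backward);
at these sizes (2k-6k parameters) this trains in seconds on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqcore import N_CODE, NucSequence, encode_3mers, kmer_indices_from_codes, seq_codes

N_3MER_TOKENS = 65  # 64 canonical 3-mers + 1 wildcard

WIRINGS = ("joined", "hybrid", "independent")
FAMILIES = ("thrifty", "kmer_table")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture descriptor for a thrifty CNN or a k-mer table model."""

    family: str = "thrifty"
    wiring: str = "joined"
    kernel: int = 11
    embed_dim: int = 7
    filters: int = 19
    dropout: float = 0.3
    k: int = 5  # kmer_table only
    activation: str = "relu"
    rate_link: str = "exp"
    per_site_wrapper: bool = False
    sequence_length_for_wrapper: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "thrifty":
            if self.wiring not in WIRINGS:
                raise ValueError(f"unknown wiring {self.wiring!r}")
            if self.kernel % 2 == 0 or self.kernel < 1:
                raise ValueError("kernel must be odd and >= 1")
        if self.family == "kmer_table" and (self.k % 2 == 0 or self.k < 1):
            raise ValueError("k must be odd and >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.per_site_wrapper and self.sequence_length_for_wrapper < 1:
            raise ValueError("wrapper requires sequence_length_for_wrapper >= 1")


# Named presets: (kernel, embed, filters, dropout).
PRESETS = {
    "joined_large": ModelConfig(wiring="joined", kernel=11, embed_dim=7, filters=19, dropout=0.3),
    "indep_medium": ModelConfig(wiring="independent", kernel=9, embed_dim=7, filters=16, dropout=0.2),
    "indep_large": ModelConfig(wiring="independent", kernel=11, embed_dim=7, filters=19, dropout=0.3),
    "small": ModelConfig(wiring="joined", kernel=7, embed_dim=6, filters=14, dropout=0.1),
}


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax_masked(logits: np.ndarray, parent_codes: np.ndarray) -> np.ndarray:
    """Row-wise softmax with the parent-base logit forced to -inf.

    ``logits`` has shape (..., 4); ``parent_codes`` shape (...). Sites with
    an ambiguous parent base (code 4) get an unmasked softmax; such sites
    are always excluded from losses and metrics anyway.
    """
    z = logits.copy()
    known = parent_codes < 4
    idx = np.where(known)
    z[idx + (parent_codes[known],)] = -np.inf
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Adamable:
    """Shared plumbing: a dict of named parameter arrays."""

    config: ModelConfig
    params: dict[str, np.ndarray]

    def count_parameters(self) -> int:
        """Exact count of trainable scalars."""
        return int(sum(p.size for p in self.params.values()))

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def reg_loss_and_grads(self, grads: dict[str, np.ndarray]) -> float:
        """Add any regularization gradient in place; return the penalty."""
        return 0.0

    # -- rate link -----------------------------------------------------
    def _link(self, s: np.ndarray) -> np.ndarray:
        if self.config.rate_link == "exp":
            return np.exp(s)
        return np.log1p(np.exp(-np.abs(s))) + np.maximum(s, 0.0)  # softplus

    def _link_grad(self, s: np.ndarray, rates: np.ndarray) -> np.ndarray:
        if self.config.rate_link == "exp":
            return rates
        return 1.0 / (1.0 + np.exp(-s))  # sigmoid

    # -- prediction ----------------------------------------------------
    def predict(self, parent: "NucSequence | str") -> tuple[np.ndarray, np.ndarray]:
        """Per-site rates and CSP matrix for one parent sequence.

        Dropout is disabled; repeated calls are identical.
        """
        codes = seq_codes(parent)
        inputs = self.encode_batch(codes[None, :])
        rates, logits, _ = self.forward_batch(inputs, train=False)
        csp = _softmax_masked(logits[0], codes)
        return rates[0], csp

    # -- checkpointing -------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        names = sorted(self.params)
        cfg = {
            "format_version": 1,
            "base_order": "ACGT",
            "model_config": dataclasses.asdict(self.config),
            "weights_manifest": [
                {"name": n, "shape": list(self.params[n].shape)} for n in names
            ],
        }
        (d / "config.json").write_text(json.dumps(cfg, indent=1))
        np.savez(d / "weights.npz", **{n: self.params[n] for n in names})

    @staticmethod
    def load(directory) -> "_Adamable":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        config = ModelConfig(**cfg["model_config"])
        model = build_model(config, seed=0)
        with np.load(d / "weights.npz") as npz:
            for entry in cfg["weights_manifest"]:
                n = entry["name"]
                arr = npz[n]
                if list(arr.shape) != entry["shape"]:
                    raise ValueError(f"weight {n}: shape mismatch in checkpoint")
                model.params[n] = arr.copy()
        return model


class _ConvStack:
    """Embedding + padded 1-D convolution + ReLU (+ dropout), with backward.

    Parameter keys (under ``prefix``): ``embed`` (65, d), ``conv_w``
    (kernel*d, filters), ``conv_b`` (filters,).
    """

    def __init__(self, prefix: str, kernel: int, embed_dim: int, filters: int):
        self.prefix = prefix
        self.kernel = kernel
        self.embed_dim = embed_dim
        self.filters = filters

    def init_params(self, rng: np.random.Generator, params: dict, shared_embed: str | None = None):
        if shared_embed is None:
            params[f"{self.prefix}embed"] = rng.normal(
                0.0, 0.3, size=(N_3MER_TOKENS, self.embed_dim)
            )
            self.embed_key = f"{self.prefix}embed"
        else:
            self.embed_key = shared_embed
        fan_in = self.kernel * self.embed_dim
        params[f"{self.prefix}conv_w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(fan_in, self.filters)
        )
        params[f"{self.prefix}conv_b"] = np.zeros(self.filters)

    def forward(self, tokens, params, train, dropout, rng):
        E = params[self.embed_key]
        W, b = params[f"{self.prefix}conv_w"], params[f"{self.prefix}conv_b"]
        B, L = tokens.shape
        k, d = self.kernel, self.embed_dim
        X = E[tokens]  # (B, L, d)
        half = (k - 1) // 2
        Xp = np.zeros((B, L + k - 1, d))
        Xp[:, half : half + L] = X
        # (B, L, d, k) -> (B, L, k, d) -> (B*L, k*d)
        win = np.lib.stride_tricks.sliding_window_view(Xp, k, axis=1)
        Xw = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * L, k * d)
        Y = Xw @ W + b
        A = _relu(Y)
        if train and dropout > 0:
            keep = rng.random(A.shape) >= dropout
            D = A * keep / (1.0 - dropout)
        else:
            keep = None
            D = A
        cache = (tokens, Xw, Y, keep, (B, L))
        return D.reshape(B, L, self.filters), cache

    def backward(self, dD, cache, params, grads, dropout):
        tokens, Xw, Y, keep, (B, L) = cache
        k, d = self.kernel, self.embed_dim
        W = params[f"{self.prefix}conv_w"]
        dD = dD.reshape(B * L, self.filters)
        if keep is not None:
            dD = dD * keep / (1.0 - dropout)
        dY = dD * (Y > 0)
        grads[f"{self.prefix}conv_w"] += Xw.T @ dY
        grads[f"{self.prefix}conv_b"] += dY.sum(axis=0)
        dXw = (dY @ W.T).reshape(B, L, k, d)
        half = (k - 1) // 2
        dXp = np.zeros((B, L + k - 1, d))
        for j in range(k):
            dXp[:, j : j + L] += dXw[:, :, j]
        dX = dXp[:, half : half + L]
        np.add.at(grads[self.embed_key], tokens, dX)


class ThriftyModel(_Adamable):
    """3-mer-embedding convolutional SHM model (joined/hybrid/independent)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.family != "thrifty":
            raise ValueError("config.family must be 'thrifty'")
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c = config
        if c.wiring == "joined":
            self.stack = _ConvStack("", c.kernel, c.embed_dim, c.filters)
            self.stack.init_params(rng, self.params)
            self.stacks = {"rate": self.stack, "csp": self.stack}
        elif c.wiring == "hybrid":
            self.params["embed"] = rng.normal(0.0, 0.3, size=(N_3MER_TOKENS, c.embed_dim))
            sr = _ConvStack("rate_", c.kernel, c.embed_dim, c.filters)
            sc = _ConvStack("csp_", c.kernel, c.embed_dim, c.filters)
            sr.init_params(rng, self.params, shared_embed="embed")
            sc.init_params(rng, self.params, shared_embed="embed")
            self.stacks = {"rate": sr, "csp": sc}
        else:  # independent
            sr = _ConvStack("rate_", c.kernel, c.embed_dim, c.filters)
            sc = _ConvStack("csp_", c.kernel, c.embed_dim, c.filters)
            sr.init_params(rng, self.params)
            sc.init_params(rng, self.params)
            self.stacks = {"rate": sr, "csp": sc}
        f = c.filters
        self.params["head_rate_w"] = rng.normal(0.0, 0.1, size=(f,))
        self.params["head_rate_b"] = np.zeros(1)
        self.params["head_csp_w"] = rng.normal(0.0, 0.1, size=(f, 4))
        self.params["head_csp_b"] = np.zeros(4)

    def encode_batch(self, codes: np.ndarray) -> np.ndarray:
        """Per-site 3-mer tokens for a (B, L) batch of base codes."""
        B, L = codes.shape
        tokens = np.empty((B, L), dtype=np.int64)
        for i in range(B):
            tokens[i] = _tokens_from_codes(codes[i])
        return tokens

    def forward_batch(self, tokens, train=False, rng=None):
        joined = self.config.wiring == "joined"
        Dr, cache_r = self.stacks["rate"].forward(
            tokens, self.params, train, self.config.dropout, rng
        )
        if joined:
            Dc, cache_c = Dr, cache_r
        else:
            Dc, cache_c = self.stacks["csp"].forward(
                tokens, self.params, train, self.config.dropout, rng
            )
        s = Dr @ self.params["head_rate_w"] + self.params["head_rate_b"][0]
        logits = Dc @ self.params["head_csp_w"] + self.params["head_csp_b"]
        rates = self._link(s)
        cache = (cache_r, cache_c, Dr, Dc, s, rates)
        return rates, logits, cache

    def backward_batch(self, cache, d_rates, d_logits, grads):
        cache_r, cache_c, Dr, Dc, s, rates = cache
        ds = d_rates * self._link_grad(s, rates)  # (B, L)
        grads["head_rate_w"] += np.einsum("blf,bl->f", Dr, ds)
        grads["head_rate_b"][0] += ds.sum()
        grads["head_csp_w"] += np.einsum("blf,blo->fo", Dc, d_logits)
        grads["head_csp_b"] += d_logits.sum(axis=(0, 1))
        dDr = ds[..., None] * self.params["head_rate_w"]
        dDc = d_logits @ self.params["head_csp_w"].T
        if self.config.wiring == "joined":
            self.stack.backward(
                dDr + dDc, cache_r, self.params, grads, self.config.dropout
            )
        else:
            self.stacks["rate"].backward(dDr, cache_r, self.params, grads, self.config.dropout)
            self.stacks["csp"].backward(dDc, cache_c, self.params, grads, self.config.dropout)


def _tokens_from_codes(codes: np.ndarray) -> np.ndarray:
    from .seqcore import WILDCARD_3MER

    n = len(codes)
    tokens = np.full(n, WILDCARD_3MER, dtype=np.int64)
    if n >= 3:
        left, mid, right = codes[:-2], codes[1:-1], codes[2:]
        valid = (left != N_CODE) & (mid != N_CODE) & (right != N_CODE)
        tokens[1:-1] = np.where(
            valid, 16 * left.astype(np.int64) + 4 * mid + right, WILDCARD_3MER
        )
    return tokens


class KmerTableModel(_Adamable):
    """Classical k-mer context table: one log-rate and one CSP logit row per
    k-mer, plus a shared trainable wildcard row for ambiguous contexts."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.family != "kmer_table":
            raise ValueError("config.family must be 'kmer_table'")
        self.config = config
        n = 4**config.k + 1  # + wildcard row
        self.params = {
            "log_rates": np.zeros(n),
            "csp_logits": np.zeros((n, 4)),
        }

    def encode_batch(self, codes: np.ndarray) -> np.ndarray:
        B, L = codes.shape
        ctx = np.empty((B, L), dtype=np.int64)
        for i in range(B):
            ctx[i] = kmer_indices_from_codes(codes[i], self.config.k)
        return ctx

    def forward_batch(self, ctx, train=False, rng=None):
        s = self.params["log_rates"][ctx]
        logits = self.params["csp_logits"][ctx]
        rates = self._link(s)
        return rates, logits, (ctx, s, rates)

    def backward_batch(self, cache, d_rates, d_logits, grads):
        ctx, s, rates = cache
        ds = d_rates * self._link_grad(s, rates)
        np.add.at(grads["log_rates"], ctx, ds)
        np.add.at(grads["csp_logits"], ctx, d_logits)


class PerSiteWrapperModel(_Adamable):
    """Multiplies a base model's rates by a trainable per-position factor.

    ``rate_i = base_rate_i * exp(log_factor_i)`` for absolute position i;
    the CSP output is passed through unchanged. Training applies an L2
    penalty pulling the log factors toward 0 (slight regularization of the
    per-position mutabilities) so positions with little data stay near
    factor 1.
    """

    def __init__(self, base: _Adamable, config: ModelConfig,
                 penalty: float = 1e-4):
        self.config = config
        self.base = base
        self.penalty = penalty
        self.params = dict(base.params)
        self.params["log_factors"] = np.zeros(config.sequence_length_for_wrapper)
        base.params = self.params  # share storage

    def encode_batch(self, codes: np.ndarray) -> np.ndarray:
        if codes.shape[1] > self.params["log_factors"].size:
            raise ValueError(
                f"sequence length {codes.shape[1]} exceeds wrapper positions "
                f"{self.params['log_factors'].size}"
            )
        return self.base.encode_batch(codes)

    def forward_batch(self, inputs, train=False, rng=None):
        base_rates, logits, base_cache = self.base.forward_batch(inputs, train, rng)
        L = inputs.shape[1]
        factors = np.exp(self.params["log_factors"][:L])
        rates = base_rates * factors
        return rates, logits, (base_cache, base_rates, factors, rates, L)

    def backward_batch(self, cache, d_rates, d_logits, grads):
        base_cache, base_rates, factors, rates, L = cache
        grads["log_factors"][:L] += (d_rates * rates).sum(axis=0)
        self.base.backward_batch(base_cache, d_rates * factors, d_logits, grads)

    def reg_loss_and_grads(self, grads):
        lf = self.params["log_factors"]
        grads["log_factors"] += 2.0 * self.penalty * lf
        return float(self.penalty * np.sum(lf**2))


def build_model(config: ModelConfig, seed: int = 0) -> _Adamable:
    """Construct a model (with deterministic initialization) from a config."""
    if config.family == "thrifty":
        base: _Adamable = ThriftyModel(config, seed=seed)
    else:
        base = KmerTableModel(config, seed=seed)
    if config.per_site_wrapper:
        return PerSiteWrapperModel(base, config)
    return base


def load_model(directory) -> _Adamable:
    return _Adamable.load(directory)


def predict(model: _Adamable, parent: "NucSequence | str"):
    """Functional alias for ``model.predict``: (RateProfile, CSPMatrix)."""
    return model.predict(parent)


def count_parameters(model: _Adamable) -> int:
    return model.count_parameters()
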