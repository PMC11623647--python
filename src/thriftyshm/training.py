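"""Two-part likelihood, combined loss, training loop, branch-length fitting.

The mutation model: site i of a parent sequence mutates within branch
length t with probability 1 - exp(-t * lambda_i) (exponential waiting
time, independent across sites); given a mutation, the new base follows
the model's conditional substitution probabilities. Training minimizes

    location NLL + w * CSP cross-entropy,   w = 0.01 by default,

both summed over the batch. The per-pair offset t is by default the
normalized mutation count, so the model can learn lambda on a common
scale irrespective of evolutionary time on a particular branch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .models import _Adamable, _softmax_masked
from .pcpdata import PCPDataset, ParentChildPair, default_branch_length, mutation_indicators
from .seqcore import N_CODE

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


@dataclass
class TrainingConfig:
    epochs: int = 100
    csp_loss_weight: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    joint_branch_length_optimization: bool = False
    optimizer: str = "adam"
    early_stopping: bool = False
    early_stopping_patience: int = 10
    branch_length_max: float = 5.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.csp_loss_weight < 0:
            raise ValueError("csp_loss_weight must be >= 0")


def site_mutation_prob(rate, t):
    """P(site mutates) = 1 - exp(-t*rate), via expm1 for stability."""
    return -np.expm1(-np.asarray(t) * np.asarray(rate))


def location_nll(rates, t, indicators, mask) -> float:
    """Negative log-likelihood of mutation locations under the offset model.

    -sum over unmasked sites of [ y*log(1 - exp(-t*lam)) - (1-y)*t*lam ].
    Probabilities are clamped at PROB_FLOOR (with a warning) so an
    indicated site with t*lam == 0 yields a large finite penalty.
    """
    rates = np.asarray(rates, dtype=float)
    y = np.asarray(indicators, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    u = t * rates
    p = -np.expm1(-u)
    if np.any(y & m & (p < PROB_FLOOR)):
        warnings.warn("mutation probability clamped at floor for an observed mutation")
    p = np.maximum(p, PROB_FLOOR)
    per_site = np.where(y, -np.log(p), u)
    return float(per_site[m].sum())


def csp_cross_entropy(csp, child_codes, indicators, mask) -> float:
    """Categorical cross-entropy of the observed new base at mutated sites."""
    csp = np.asarray(csp, dtype=float)
    y = np.asarray(indicators, dtype=bool) & np.asarray(mask, dtype=bool)
    if not y.any():
        return 0.0
    idx = np.where(y)[0]
    probs = csp[idx, np.asarray(child_codes)[idx]]
    if np.any(probs == 0.0):
        # p(parent base) is exactly 0 by construction, so this means the
        # "child" base equals the parent base at an indicated site.
        raise ValueError(
            "CSP probability 0 at an indicated site; child base equals "
            "parent base (internal inconsistency)"
        )
    return float(-np.log(np.maximum(probs, PROB_FLOOR)).sum())


def combined_loss(location_nll_value: float, csp_ce: float, weight: float = 0.01) -> float:
    """Summed two-part loss with the cross-entropy down-weighted."""
    return float(location_nll_value + weight * csp_ce)


# ---------------------------------------------------------------------------
# Batch assembly


class _Batchified:
    """Padded array views of a PCP dataset for vectorized training."""

    def __init__(self, ds: PCPDataset):
        self.n = len(ds)
        self.max_len = max(len(p) for p in ds)
        L = self.max_len
        self.parent = np.full((self.n, L), N_CODE, dtype=np.int8)
        self.child = np.full((self.n, L), N_CODE, dtype=np.int8)
        self.mask = np.zeros((self.n, L), dtype=bool)
        self.y = np.zeros((self.n, L), dtype=bool)
        self.t = np.zeros(self.n)
        for i, p in enumerate(ds):
            li = len(p)
            self.parent[i, :li] = p.parent.codes()
            self.child[i, :li] = p.child.codes()
            self.mask[i, :li] = p.site_mask
            self.y[i, :li] = mutation_indicators(p)
            t = p.branch_length
            self.t[i] = default_branch_length(p) if t is None else t


def _batch_loss_and_grads(model, enc, bat_idx, batch: _Batchified, weight,
                          train=True, rng=None, grads=None):
    """Forward + loss (+ backward into ``grads`` if given) for one batch."""
    parent = batch.parent[bat_idx]
    child = batch.child[bat_idx]
    mask = batch.mask[bat_idx]
    y = batch.y[bat_idx]
    t = batch.t[bat_idx][:, None]
    inputs = enc[bat_idx]
    rates, logits, cache = model.forward_batch(inputs, train=train, rng=rng)

    u = t * rates
    p = np.maximum(-np.expm1(-u), PROB_FLOOR)
    loc = np.where(y, -np.log(p), u)
    loc_nll = float(loc[mask].sum())

    probs = _softmax_masked(logits, parent)
    mut = y & mask
    ce = 0.0
    if mut.any():
        b_idx, l_idx = np.where(mut)
        pc = probs[b_idx, l_idx, child[b_idx, l_idx]]
        ce = float(-np.log(np.maximum(pc, PROB_FLOOR)).sum())

    total = loc_nll + weight * ce

    if grads is not None:
        du = np.where(y, -np.exp(-u) / p, 1.0)
        du[~mask] = 0.0
        d_rates = du * t
        d_logits = np.zeros_like(logits)
        if mut.any():
            one_hot = np.zeros_like(logits)
            one_hot[b_idx, l_idx, child[b_idx, l_idx]] = 1.0
            d_logits[b_idx, l_idx] = weight * (probs[b_idx, l_idx] - one_hot[b_idx, l_idx])
        model.backward_batch(cache, d_rates, d_logits, grads)
        total += model.reg_loss_and_grads(grads)
    return total


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.step_count = 0

    def step(self, params, grads):
        self.step_count += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1 = 1 - b1**self.step_count
        c2 = 1 - b2**self.step_count
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + eps)


def train_model(model: _Adamable, dataset: PCPDataset, config: TrainingConfig,
                val_dataset: PCPDataset | None = None):
    """Train a model by minibatch Adam on the combined two-part loss.

    Pairs lacking a branch length get the normalized mutation count as
    offset. Deterministic given (seed, config, dataset order). Returns
    (model, trace) where trace is a list of per-epoch dicts.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    batch = _Batchified(dataset)
    enc = model.encode_batch(batch.parent)
    val = _Batchified(val_dataset) if val_dataset is not None else None
    val_enc = model.encode_batch(val.parent) if val is not None else None

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    weight = config.csp_loss_weight
    trace = []
    best_val, patience = np.inf, 0
    order = np.arange(batch.n)
    for epoch in range(config.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        for b0 in range(0, batch.n, config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            grads = model.zero_grads()
            loss = _batch_loss_and_grads(
                model, enc, idx, batch, weight, train=True, rng=rng, grads=grads
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss in epoch {epoch}, batch starting at {b0}"
                )
            opt.step(model.params, grads)
            epoch_loss += loss
        record = {"epoch": epoch, "train_loss": epoch_loss}
        if config.joint_branch_length_optimization:
            # Alternating blocks: one epoch of model updates, then one
            # branch-length pass holding the model fixed.
            _update_branch_lengths_in_place(model, batch, enc, config.branch_length_max)
        if val is not None:
            record["val_loss"] = _batch_loss_and_grads(
                model, val_enc, np.arange(val.n), val, weight, train=False
            )
            if config.early_stopping:
                if record["val_loss"] < best_val - 1e-9:
                    best_val, patience = record["val_loss"], 0
                else:
                    patience += 1
                    if patience >= config.early_stopping_patience:
                        trace.append(record)
                        logger.info("early stopping at epoch %d", epoch)
                        break
        trace.append(record)
    return model, trace


# ---------------------------------------------------------------------------
# Branch-length optimization


def _pair_branch_length(rates, y, mask, t_max, xatol=1e-6):
    """argmax over t >= 0 of the location log-likelihood with rates fixed."""
    lam_mut = rates[mask & y]
    lam_not = rates[mask & ~y]
    if lam_mut.size == 0:
        return 0.0, False
    s_not = lam_not.sum()

    def neg_ll(t):
        p = np.maximum(-np.expm1(-t * lam_mut), PROB_FLOOR)
        return -(np.log(p).sum() - t * s_not)

    res = minimize_scalar(neg_ll, bounds=(1e-9, t_max), method="bounded",
                          options={"xatol": xatol})
    t_hat = float(res.x)
    at_bound = t_hat > t_max - 10 * xatol
    return t_hat, at_bound


def _update_branch_lengths_in_place(model, batch: _Batchified, enc, t_max):
    rates, _, _ = model.forward_batch(enc, train=False)
    for i in range(batch.n):
        t_hat, _ = _pair_branch_length(rates[i], batch.y[i], batch.mask[i], t_max)
        batch.t[i] = t_hat


def optimize_branch_lengths(model: _Adamable, dataset: PCPDataset,
                            t_max: float = 5.0) -> PCPDataset:
    """Per-pair maximum-likelihood branch lengths with the model fixed.

    1-D bounded optimization (tolerance 1e-6 in t); pairs with zero
    mutations get t = 0 exactly. Hitting the upper bound is logged.
    """
    out = []
    for p in dataset:
        rates, _ = model.predict(p.parent)
        y = mutation_indicators(p)
        t_hat, at_bound = _pair_branch_length(rates, y, p.site_mask, t_max)
        if at_bound:
            logger.warning(
                "pair %s: branch length hit upper bound %g", p.pair_id, t_max
            )
        out.append(p.with_branch_length(t_hat))
    prov = dict(dataset.provenance)
    prov.setdefault("transforms", []).append("optimize_branch_lengths")
    return PCPDataset(out, prov)
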