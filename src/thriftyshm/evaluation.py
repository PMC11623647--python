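"""Model assessment for rare-mutation site prediction.

Site-level metrics pool sites across all pairs of an evaluation set:
AUROC (midrank tie handling), AUPRC (step-interpolated average
precision), R-precision (precision among the R top-ranked sites, R =
observed mutation count), substitution accuracy (argmax CSP vs observed
new base), an observed-vs-expected binned fit with its overlap summary,
and held-out log-likelihoods.

Because mutations are rare (class fractions of order 1e-2), AUPRC and
R-precision are the discriminative metrics of interest; the positive
fraction rho is the chance-level baseline for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .pcpdata import PCPDataset, mutation_indicators
from .training import PROB_FLOOR, site_mutation_prob


@dataclass
class BinaryPredictionSet:
    """Pooled per-site scores and observed mutation labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def rho(self) -> float:
        """Positive fraction: chance level for AUPRC and R-precision."""
        return self.n_positive / self.labels.size


def auroc(preds: BinaryPredictionSet) -> float:
    """P(random positive outscores random negative); ties count 1/2."""
    npos = preds.n_positive
    if npos == 0 or npos == preds.labels.size:
        raise ValueError("AUROC requires at least one positive and one negative")
    return float(roc_auc_score(preds.labels, preds.scores))


def auprc(preds: BinaryPredictionSet) -> float:
    """Step-interpolated average precision over descending-score thresholds."""
    if preds.n_positive == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(preds.labels, preds.scores))


def r_precision(preds: BinaryPredictionSet) -> float:
    """Precision among the R top-scoring sites, R = number of positives.

    Ties at the cutoff are broken by stable input order.
    """
    R = preds.n_positive
    if R == 0:
        raise ValueError("R-precision requires at least one positive")
    top = np.argsort(-preds.scores, kind="stable")[:R]
    return float(preds.labels[top].mean())


def substitution_accuracy(csp_rows: np.ndarray, child_codes: np.ndarray) -> float:
    """Fraction of mutated sites where argmax CSP equals the observed base.

    ``csp_rows``: (n_mutations, 4) CSP rows at mutated sites;
    ``child_codes``: observed new-base codes. Argmax ties break toward
    the first base in A,C,G,T order.
    """
    csp_rows = np.asarray(csp_rows, dtype=float)
    if csp_rows.shape[0] == 0:
        raise ValueError("substitution accuracy requires at least one mutated site")
    return float((csp_rows.argmax(axis=1) == np.asarray(child_codes)).mean())


@dataclass
class BinnedFit:
    """Observed vs expected mutation counts in predicted-probability bins."""

    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    meta: dict = field(default_factory=dict)


def binned_fit(site_probs, indicators, n_bins: int = 30) -> BinnedFit:
    """Bin sites by predicted mutation probability (log-spaced bins).

    expected_b = sum of predicted probabilities of sites in bin b;
    observed_b = number of observed mutations among sites in bin b.
    """
    p = np.asarray(site_probs, dtype=float)
    y = np.asarray(indicators, dtype=bool)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("site probabilities must lie in (0, 1]")
    lo, hi = p.min(), p.max()
    if lo == hi:
        edges = np.array([lo * (1 - 1e-9), hi])
        n_bins = 1
    else:
        edges = np.geomspace(lo, hi, n_bins + 1)
        edges[0] *= 1 - 1e-12  # make the lowest site fall inside bin 0
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)
    observed = np.bincount(which[y], minlength=n_bins).astype(float)
    expected = np.bincount(which, weights=p, minlength=n_bins)
    return BinnedFit(edges, observed, expected,
                     {"n_bins": n_bins, "spacing": "log"})


def overlap(fit: BinnedFit) -> float:
    """Histogram intersection over the average histogram area.

    sum_b min(observed_b, expected_b) / ((sum observed + sum expected)/2);
    1 iff the two histograms are identical.
    """
    o, e = fit.observed, fit.expected
    tot = o.sum() + e.sum()
    if tot == 0:
        raise ValueError("overlap undefined: both histograms are all-zero")
    return float(np.minimum(o, e).sum() / (tot / 2.0))


def pooled_predictions(model, dataset: PCPDataset):
    """Pool per-site probabilities, labels and CSP rows across a dataset.

    Returns (BinaryPredictionSet over unmasked sites, CSP rows at mutated
    sites, child codes at mutated sites, per-pair records).
    """
    scores, labels = [], []
    mut_rows, mut_child = [], []
    per_pair = []
    for p in dataset:
        rates, csp = model.predict(p.parent)
        t = p.branch_length
        if t is None:
            raise ValueError(f"pair {p.pair_id!r} lacks a branch length")
        probs = site_mutation_prob(rates, t)
        y = mutation_indicators(p)
        m = p.site_mask
        scores.append(probs[m])
        labels.append(y[m])
        mut = m & y
        if mut.any():
            mut_rows.append(csp[mut])
            mut_child.append(p.child.codes()[mut])
        per_pair.append({"pair_id": p.pair_id, "n_sites": int(m.sum()),
                         "n_mutations": int(mut.sum())})
    preds = BinaryPredictionSet(np.concatenate(scores), np.concatenate(labels))
    rows = np.concatenate(mut_rows) if mut_rows else np.empty((0, 4))
    child = np.concatenate(mut_child) if mut_child else np.empty(0, dtype=np.int8)
    return preds, rows, child, per_pair


def heldout_loglik(model, dataset: PCPDataset) -> dict:
    """Location and CSP log-likelihoods (per pair and totals).

    Branch lengths should first be set by ``optimize_branch_lengths``.
    """
    per_pair = []
    for p in dataset:
        rates, csp = model.predict(p.parent)
        t = p.branch_length
        if t is None:
            raise ValueError(f"pair {p.pair_id!r} lacks a branch length")
        y = mutation_indicators(p)
        m = p.site_mask
        u = t * rates
        prob = np.maximum(-np.expm1(-u), PROB_FLOOR)
        loc = float(np.where(y, np.log(prob), -u)[m].sum())
        mut = m & y
        if mut.any():
            pc = csp[mut][np.arange(mut.sum()), p.child.codes()[mut]]
            csp_ll = float(np.log(np.maximum(pc, PROB_FLOOR)).sum())
        else:
            csp_ll = 0.0
        per_pair.append({"pair_id": p.pair_id, "location_loglik": loc,
                         "csp_loglik": csp_ll, "total": loc + csp_ll})
    return {
        "per_pair": per_pair,
        "location_loglik": sum(r["location_loglik"] for r in per_pair),
        "csp_loglik": sum(r["csp_loglik"] for r in per_pair),
        "total_loglik": sum(r["total"] for r in per_pair),
    }


def evaluate_model(model, dataset: PCPDataset, n_bins: int = 30,
                   metrics=("auroc", "auprc", "r_precision",
                            "substitution_accuracy", "overlap")) -> dict:
    """Full pooled evaluation; returns a flat metrics dict plus metadata."""
    preds, rows, child, per_pair = pooled_predictions(model, dataset)
    out: dict = {"n_sites": int(preds.labels.size),
                 "n_mutations": preds.n_positive,
                 "rho": preds.rho}
    if "auroc" in metrics:
        out["auroc"] = auroc(preds)
    if "auprc" in metrics:
        out["auprc"] = auprc(preds)
    if "r_precision" in metrics:
        out["r_precision"] = r_precision(preds)
    if "substitution_accuracy" in metrics:
        out["substitution_accuracy"] = substitution_accuracy(rows, child)
    if "overlap" in metrics:
        # sites with probability 0 (e.g. t = 0 pairs) carry no mass in
        # either histogram and are excluded from the binning
        pos = preds.scores > 0
        fit = binned_fit(preds.scores[pos], preds.labels[pos], n_bins=n_bins)
        out["overlap"] = overlap(fit)
        out["bin_meta"] = fit.meta
    out["per_pair"] = per_pair
    return out
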