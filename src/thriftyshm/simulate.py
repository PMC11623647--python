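"""Synthetic parent-child pair generator with a known context model.

The generator draws parent sequences, then mutates each site independently
with probability 1 - exp(-t * lambda(context)) where lambda comes from a
known k-mer rate table (the ground truth), and draws the new base from the
ground-truth conditional substitution probabilities. Mutation happens in a
single simultaneous round, with contexts evaluated on the parent only —
exactly the generative model the estimators assume, so parameter recovery
is well-posed.

Ground truths carry AID-style hotspot motifs (e.g. WRC / GYW) so the data
shows the context-dependent rate structure characteristic of somatic
hypermutation. The default branch-length distribution is LogNormal with
median 0.01 and log-sd 1.0, giving a median of about 3 mutations per
300 nt pair — the rare-mutation regime of out-of-frame BCR repertoire
data (per-pair medians of 1-7).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pcpdata import PCPDataset, ParentChildPair
from .seqcore import BASES, NucSequence, kmer_indices_from_codes

IUPAC = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "W": (0, 3), "S": (1, 2), "R": (0, 2), "Y": (1, 3),
}

# Classic AID hotspots on both strands: WRC (focal C, motif starts 2 bases
# left of the focal site) and its reverse complement GYW (focal G at the
# motif start). Offsets give the motif's first base relative to the focal
# site.
DEFAULT_HOTSPOTS = (("WRC", 10.0, -2), ("GYW", 10.0, 0))


@dataclass
class GroundTruthModel:
    """Known k-mer rate/CSP tables used to generate data.

    ``rates``: positive rate per k-mer (4**k entries); ``csp``: per-k-mer
    probability row over A,C,G,T with the central (parent) base at 0;
    ``hotspots``: (IUPAC motif, multiplier, offset of motif start from the
    focal site) triples that were applied when the table was built.
    Sites whose k-mer window overhangs the sequence or contains N get the
    mean rate 1 and a uniform CSP over the 3 non-parent bases.
    """

    k: int
    rates: np.ndarray
    csp: np.ndarray
    hotspots: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.csp = np.asarray(self.csp, dtype=float)
        if self.rates.shape != (4**self.k,) or self.csp.shape != (4**self.k, 4):
            raise ValueError("rate/CSP table shapes do not match k")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be strictly positive")
        if not np.allclose(self.csp.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("CSP rows must sum to 1")

    def site_rates(self, parent_codes: np.ndarray) -> np.ndarray:
        ctx = kmer_indices_from_codes(parent_codes, self.k)
        wild = ctx == 4**self.k
        out = np.where(wild, 1.0, self.rates[np.where(wild, 0, ctx)])
        return out

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k,
            "rates": self.rates.tolist(),
            "csp": self.csp.tolist(),
            "hotspots": [list(h) for h in self.hotspots],
            "meta": self.meta,
        }))

    @staticmethod
    def load(path) -> "GroundTruthModel":
        d = json.loads(Path(path).read_text())
        return GroundTruthModel(
            k=d["k"], rates=np.array(d["rates"]), csp=np.array(d["csp"]),
            hotspots=tuple(tuple(h) for h in d["hotspots"]), meta=d.get("meta", {}),
        )


def motif_matches_kmer(kmer_digits, motif: str, offset: int, k: int) -> bool:
    """Does the motif (starting ``offset`` bases from the focal site) match
    this k-mer? The whole motif must lie inside the k-mer window."""
    half = k // 2
    for j, sym in enumerate(motif):
        pos = half + offset + j
        if pos < 0 or pos >= k:
            raise ValueError(
                f"hotspot motif {motif!r} at offset {offset} does not fit "
                f"inside a {k}-mer window"
            )
        if kmer_digits[pos] not in IUPAC[sym]:
            return False
    return True


def random_ground_truth(k: int, seed: int,
                        hotspots="auto") -> GroundTruthModel:
    """Random k-mer ground truth with hotspot boosts.

    Base log-rates are i.i.d. Normal(0, 0.5^2); contexts matched by a
    hotspot motif are multiplied by its multiplier; rates are then
    rescaled to mean 1. CSP rows are Dirichlet(1,1,1) over the three
    non-parent bases. ``hotspots="auto"`` applies the default AID motifs
    when they fit the k-mer window (k >= 5) and none otherwise; an
    explicit motif that does not fit is an error.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be odd")
    if isinstance(hotspots, str) and hotspots == "auto":
        hotspots = DEFAULT_HOTSPOTS if k >= 5 else ()
    rng = np.random.default_rng(seed)
    n = 4**k
    rates = np.exp(rng.normal(0.0, 0.5, size=n))
    half = k // 2
    digits_all = np.array(list(itertools.product(range(4), repeat=k)))
    for motif, mult, offset in hotspots:
        if mult <= 0:
            raise ValueError("hotspot multipliers must be > 0")
        hit = np.ones(n, dtype=bool)
        for j, sym in enumerate(motif):
            pos = half + offset + j
            if pos < 0 or pos >= k:
                raise ValueError(
                    f"hotspot motif {motif!r} at offset {offset} does not "
                    f"fit inside a {k}-mer window"
                )
            hit &= np.isin(digits_all[:, pos], IUPAC[sym])
        rates[hit] *= mult
    rates /= rates.mean()
    csp = np.zeros((n, 4))
    central = digits_all[:, half]
    draws = rng.dirichlet(np.ones(3), size=n)
    for b in range(4):
        rows = central == b
        others = [x for x in range(4) if x != b]
        csp[np.ix_(rows, others)] = draws[rows]
    return GroundTruthModel(k=k, rates=rates, csp=csp, hotspots=tuple(hotspots),
                            meta={"seed": seed, "log_rate_sd": 0.5})


def _mutate_once(truth: GroundTruthModel, codes: np.ndarray, t: float,
                 rng: np.random.Generator) -> np.ndarray:
    lam = truth.site_rates(codes)
    p_mut = -np.expm1(-t * lam)
    mutate = (rng.random(len(codes)) < p_mut) & (codes != 4)
    child = codes.copy()
    if mutate.any():
        ctx = kmer_indices_from_codes(codes, truth.k)
        idx = np.where(mutate)[0]
        rows = np.empty((idx.size, 4))
        known = ctx[idx] != 4**truth.k
        rows[known] = truth.csp[ctx[idx[known]]]
        if not known.all():
            # wildcard context: uniform over the three non-parent bases
            uni = np.full((np.count_nonzero(~known), 4), 1 / 3)
            uni[np.arange(uni.shape[0]), codes[idx[~known]]] = 0.0
            rows[~known] = uni
        u = rng.random(idx.size)
        child[idx] = (u[:, None] >= rows.cumsum(axis=1)).sum(axis=1)
    return child


def simulate_child(truth: GroundTruthModel, parent: "NucSequence | str",
                   t: float, seed=None, rng: np.random.Generator | None = None,
                   pair_id: str = "sim", rounds: int = 1) -> ParentChildPair:
    """Mutate a parent under the ground-truth model.

    By default mutation is a single simultaneous round with contexts read
    off the parent — exactly the model the estimators assume. ``rounds > 1``
    enables a flagged extension that splits t into equal slices and
    re-evaluates contexts on the evolving sequence between slices.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if not isinstance(parent, NucSequence):
        parent = NucSequence(parent)
    codes = parent.codes()
    for _ in range(rounds):
        codes = _mutate_once(truth, codes, t / rounds, rng)
    child_str = "".join("ACGTN"[c] for c in codes)
    return ParentChildPair(pair_id=pair_id, parent=parent,
                           child=NucSequence(child_str), branch_length=float(t))


def simulate_dataset(truth: GroundTruthModel, n_pairs: int, length: int,
                     t_distribution=("lognormal", 0.01, 1.0),
                     seed: int = 0, record_true_t: bool = True) -> PCPDataset:
    """Simulate a dataset of parent-child pairs with recorded true t.

    Parents are i.i.d. uniform over A,C,G,T. ``t_distribution`` is either
    ("lognormal", median, log_sd), ("fixed", t), or a callable rng->t.
    The default gives a median of ~3 mutations per 300 nt pair.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    if callable(t_distribution):
        draw_t = t_distribution
    elif t_distribution[0] == "lognormal":
        _, median, sd = t_distribution
        draw_t = lambda r: float(np.exp(r.normal(np.log(median), sd)))
    elif t_distribution[0] == "fixed":
        draw_t = lambda r, _t=float(t_distribution[1]): _t
    else:
        raise ValueError(f"unknown t_distribution {t_distribution!r}")
    pairs = []
    true_t = {}
    width = len(str(n_pairs))
    for i in range(n_pairs):
        parent = NucSequence("".join(rng.choice(list(BASES), size=length)))
        t = draw_t(rng)
        pid = f"sim_{i:0{width}d}"
        p = simulate_child(truth, parent, t, rng=rng, pair_id=pid)
        p = ParentChildPair(pair_id=pid, parent=p.parent, child=p.child,
                            sample_id="sim", family_id=pid,
                            branch_length=float(t) if record_true_t else None)
        pairs.append(p)
        true_t[pid] = float(t)
    prov = {"source": "simulate_dataset", "seed": seed, "n_pairs": n_pairs,
            "length": length, "true_t": true_t,
            "t_distribution": repr(t_distribution),
            "generator": "numpy.random.default_rng (PCG64)"}
    return PCPDataset(pairs, prov)
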