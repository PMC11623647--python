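"""Parent-child pair (PCP) data model, I/O, filtering and masking.

A PCP is one edge of a clonal-family tree: two equal-length nucleotide
sequences (parent above, child below) with an optional branch length t.
The per-pair boolean ``site_mask`` records which sites participate in
losses and metrics; sites where either sequence is N are always masked.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from .seqcore import N_CODE, NucSequence, is_fourfold_degenerate

REQUIRED_COLUMNS = ("pair_id", "parent", "child")
OPTIONAL_COLUMNS = ("sample_id", "family_id", "branch_length")


@dataclass(frozen=True)
class ParentChildPair:
    pair_id: str
    parent: NucSequence
    child: NucSequence
    sample_id: str = ""
    family_id: str = ""
    branch_length: float | None = None
    site_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.parent) != len(self.child):
            raise ValueError(
                f"pair {self.pair_id!r}: parent length {len(self.parent)} "
                f"!= child length {len(self.child)}"
            )
        if self.branch_length is not None and not self.branch_length >= 0:
            raise ValueError(
                f"pair {self.pair_id!r}: branch length must be >= 0, "
                f"got {self.branch_length}"
            )
        base_mask = (self.parent.codes() != N_CODE) & (self.child.codes() != N_CODE)
        if self.site_mask is None:
            mask = base_mask
        else:
            mask = np.asarray(self.site_mask, dtype=bool)
            if mask.shape != (len(self.parent),):
                raise ValueError(
                    f"pair {self.pair_id!r}: site_mask length {mask.size} "
                    f"!= sequence length {len(self.parent)}"
                )
            mask = mask & base_mask
        object.__setattr__(self, "site_mask", mask)

    def __len__(self) -> int:
        return len(self.parent)

    def with_mask(self, mask: np.ndarray) -> "ParentChildPair":
        return dataclasses.replace(self, site_mask=np.asarray(mask, dtype=bool))

    def with_branch_length(self, t: float) -> "ParentChildPair":
        return dataclasses.replace(self, branch_length=float(t))


def mutation_indicators(pcp: ParentChildPair) -> np.ndarray:
    """Boolean array: True exactly at unmasked sites where parent != child."""
    return (pcp.parent.codes() != pcp.child.codes()) & pcp.site_mask


def mutation_count(pcp: ParentChildPair) -> int:
    return int(mutation_indicators(pcp).sum())


def default_branch_length(pcp: ParentChildPair) -> float:
    """Normalized mutation count: mutated unmasked sites / unmasked sites.

    This is the default per-pair offset t when no branch length is supplied.
    """
    n_sites = int(pcp.site_mask.sum())
    if n_sites == 0:
        raise ValueError(f"pair {pcp.pair_id!r} has zero unmasked sites")
    return mutation_count(pcp) / n_sites


@dataclass
class PCPDataset:
    """Ordered collection of parent-child pairs with provenance metadata."""

    pairs: list[ParentChildPair]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pair_ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ParentChildPair]:
        return iter(self.pairs)

    def __getitem__(self, i: int) -> ParentChildPair:
        return self.pairs[i]

    def map(self, fn: Callable[[ParentChildPair], ParentChildPair], note: str = "") -> "PCPDataset":
        prov = dict(self.provenance)
        if note:
            prov.setdefault("transforms", []).append(note)
        return PCPDataset([fn(p) for p in self.pairs], prov)

    def with_default_branch_lengths(self) -> "PCPDataset":
        """Fill missing branch lengths with the normalized mutation count."""
        return self.map(
            lambda p: p
            if p.branch_length is not None
            else p.with_branch_length(default_branch_length(p)),
            note="default_branch_lengths",
        )


def read_pcp_table(path, dialect: str | None = None) -> PCPDataset:
    """Read a PCP table (CSV or TSV with header) into a validated dataset.

    Required columns: pair_id, parent, child. Optional: sample_id,
    family_id, branch_length. Gapped sequences are rejected.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect) if dialect else None
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    pairs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if "-" in d["parent"] or "-" in d["child"]:
            raise ValueError(
                f"pair {d['pair_id']!r}: gapped sequences are not supported"
            )
        t = d.get("branch_length", "")
        pairs.append(
            ParentChildPair(
                pair_id=d["pair_id"],
                parent=NucSequence(d["parent"]),
                child=NucSequence(d["child"]),
                sample_id=d.get("sample_id", ""),
                family_id=d.get("family_id", ""),
                branch_length=float(t) if t not in ("", None) else None,
            )
        )
    return PCPDataset(pairs, {"source": str(path), "n_read": len(pairs)})


def write_pcp_table(ds: PCPDataset, path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    rows = [
        {
            "pair_id": p.pair_id,
            "sample_id": p.sample_id,
            "family_id": p.family_id,
            "parent": str(p.parent),
            "child": str(p.child),
            "branch_length": "" if p.branch_length is None else repr(p.branch_length),
        }
        for p in ds
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_pcp_fasta_pair(parent_path, child_path) -> PCPDataset:
    """Build a dataset from two FASTA files with matched record ids."""
    from .seqcore import read_fasta

    parents = dict(read_fasta(parent_path))
    children = dict(read_fasta(child_path))
    if set(parents) != set(children):
        only_p = sorted(set(parents) - set(children))
        only_c = sorted(set(children) - set(parents))
        raise ValueError(
            f"record id mismatch between FASTA files: "
            f"parent-only {only_p[:3]}, child-only {only_c[:3]}"
        )
    pairs = [
        ParentChildPair(pair_id=name, parent=parents[name], child=children[name])
        for name in parents
    ]
    return PCPDataset(pairs, {"source": f"{parent_path}+{child_path}"})


def filter_max_mutations(ds: PCPDataset, limit: int = 10) -> PCPDataset:
    """Keep pairs with strictly fewer than ``limit`` mutations.

    Mirrors the standard edge filter that drops improperly aligned long
    branches; the number removed is recorded in provenance.
    """
    kept = [p for p in ds if mutation_count(p) < limit]
    prov = dict(ds.provenance)
    prov.setdefault("filters", []).append(
        {"filter": "max_mutations", "limit": limit, "removed": len(ds) - len(kept)}
    )
    return PCPDataset(kept, prov)


def restrict_region(ds: PCPDataset, start: int, end: int) -> PCPDataset:
    """Mask all sites outside the 0-based inclusive window [start, end].

    The default evaluation window for bulk IgH repertoire data is
    [80, 319], the region with reliable sequencing coverage.
    """
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    if start < 0:
        raise ValueError(f"start {start} < 0")
    min_len = min((len(p) for p in ds), default=0)
    if ds.pairs and end >= min_len:
        raise ValueError(
            f"region [{start}, {end}] extends beyond shortest sequence "
            f"(length {min_len})"
        )

    def _restrict(p: ParentChildPair) -> ParentChildPair:
        mask = p.site_mask.copy()
        mask[:start] = False
        mask[end + 1:] = False
        return p.with_mask(mask)

    return ds.map(_restrict, note=f"restrict_region[{start},{end}]")


def apply_synonymous_mask(pcp: ParentChildPair, frame_offset: int = 0) -> ParentChildPair:
    """Keep only 4-fold-degenerate third codon positions in the loss mask.

    The parent defines the reading frame (starting at ``frame_offset``); a
    third position stays unmasked only when its parent codon prefix is
    4-fold degenerate, so any mutation there is synonymous. Codons with N
    in the prefix and incomplete terminal codons are masked.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    n = len(pcp)
    keep = np.zeros(n, dtype=bool)
    parent = str(pcp.parent)
    for codon_start in range(frame_offset, n - 2, 3):
        prefix = parent[codon_start : codon_start + 2]
        if "N" not in prefix and is_fourfold_degenerate(prefix):
            keep[codon_start + 2] = True
    return pcp.with_mask(pcp.site_mask & keep)


def mask_synonymous(ds: PCPDataset, frame_offset: int = 0) -> PCPDataset:
    return ds.map(
        lambda p: apply_synonymous_mask(p, frame_offset),
        note=f"synonymous_mask(frame={frame_offset})",
    )
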