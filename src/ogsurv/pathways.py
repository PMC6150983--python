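"""Overlapping pathway collections and the latent-effect expansion.

A pathway is a named, ordered set of genes; pathways may share genes.  The
latent-effect device of overlapping-group regression rewrites the gene
coefficient vector as beta = S @ gamma, where gamma stacks one latent
coefficient per (pathway, member gene) slot and S is the binary q x u
incidence mapping latent slots back to genes.  Equivalently the design
matrix gains a duplicated column for every extra pathway a gene belongs to,
turning overlapping groups into disjoint blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

UNMAPPED_POLICIES = ("discard", "extra_group")


@dataclass(frozen=True)
class PathwayCollection:
    """Named, possibly overlapping gene sets.

    Parameters
    ----------
    names : tuple of str
        Pathway names, in order.
    members : tuple of tuple of str
        Member genes per pathway, order preserved, no duplicates within a
        pathway.
    unmapped_policy : {"discard", "extra_group"}
        What downstream alignment does with expression genes absent from
        every pathway: drop them, or gather them into one extra group.
    """

    names: tuple
    members: tuple
    unmapped_policy: str = "discard"
    gene_universe: tuple = field(init=False)

    def __post_init__(self):
        if len(self.names) == 0:
            raise ValueError("no gene sets")
        if len(self.names) != len(self.members):
            raise ValueError("names and members length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate pathway names")
        if self.unmapped_policy not in UNMAPPED_POLICIES:
            raise ValueError(f"unmapped_policy must be one of {UNMAPPED_POLICIES}")
        seen = {}
        for name, genes in zip(self.names, self.members):
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate gene within pathway {name!r}")
            for g in genes:
                seen.setdefault(g, None)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "members", tuple(tuple(m) for m in self.members))
        object.__setattr__(self, "gene_universe", tuple(seen))

    @property
    def G(self) -> int:
        return len(self.names)

    @property
    def q(self) -> int:
        return len(self.gene_universe)

    @property
    def sizes(self) -> tuple:
        return tuple(len(m) for m in self.members)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_universe)}

    def pathways_of(self, gene: str) -> list:
        return [i for i, m in enumerate(self.members) if gene in m]

    def with_policy(self, policy: str) -> "PathwayCollection":
        return PathwayCollection(self.names, self.members, policy)


@dataclass(frozen=True)
class LatentExpansion:
    """The q x u binary incidence S of a collection's latent slots.

    Column j belongs to pathway ``latent_group_of[j]`` and gene
    ``gene_of[j]``; columns are ordered pathway-by-pathway (collection
    order), genes within a pathway in membership order, so every pathway
    occupies a contiguous latent block.
    """

    S: np.ndarray
    latent_group_of: np.ndarray
    gene_of: np.ndarray
    gene_universe: tuple

    @property
    def u(self) -> int:
        return self.S.shape[1]

    @property
    def q(self) -> int:
        return self.S.shape[0]

    def group_slices(self) -> list:
        """Per-pathway contiguous column slices of the latent design."""
        out = []
        for g in range(self.latent_group_of.max() + 1):
            idx = np.flatnonzero(self.latent_group_of == g)
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out


def read_gmt(path, unmapped_policy: str = "discard") -> PathwayCollection:
    """Read gene sets from a GMT file (name, description, genes...).

    Duplicate genes within a line are deduplicated with a logged warning;
    pathway order follows line order.
    """
    names, members = [], []
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("no gene sets")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name, genes = fields[0], fields[2:]
        genes = [g for g in genes if g]
        dedup = list(dict.fromkeys(genes))
        if len(dedup) != len(genes):
            logger.warning("GMT line %d (%s): duplicate genes removed", lineno, name)
        names.append(name)
        members.append(tuple(dedup))
    return PathwayCollection(tuple(names), tuple(members), unmapped_policy)


def write_gmt(collection: PathwayCollection, path, descriptions=None) -> None:
    """Write a collection as GMT; descriptions default to the pathway name."""
    with open(path, "w") as fh:
        for i, (name, genes) in enumerate(zip(collection.names, collection.members)):
            desc = name if descriptions is None else descriptions[i]
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_gene_universe(collection: PathwayCollection, path) -> None:
    Path(path).write_text("\n".join(collection.gene_universe) + "\n")


def build_chain_structure(sizes, overlaps, prefix: str = "g") -> PathwayCollection:
    """Build a chain of pathways where consecutive pathways share genes.

    Genes are laid out on a single index line 1..q as contiguous blocks:
    pathway i+1 starts ``overlaps[i]`` genes before the end of pathway i,
    so the shared genes sit at the end of pathway i's range.  Overlap 0
    makes consecutive pathways disjoint.
    """
    sizes = [int(s) for s in sizes]
    overlaps = [int(o) for o in overlaps]
    if len(overlaps) != len(sizes) - 1:
        raise ValueError("need exactly len(sizes) - 1 consecutive overlaps")
    if any(s <= 0 for s in sizes):
        raise ValueError("pathway sizes must be positive")
    for i, o in enumerate(overlaps):
        if o < 0 or o >= min(sizes[i], sizes[i + 1]):
            raise ValueError(
                f"overlap {o} between pathways {i + 1} and {i + 2} must satisfy "
                f"0 <= overlap < min(sizes)"
            )
    names, members = [], []
    start = 1
    for i, size in enumerate(sizes):
        members.append(tuple(f"{prefix}{j}" for j in range(start, start + size)))
        names.append(f"P{i + 1}")
        if i < len(overlaps):
            start = start + size - overlaps[i]
    return PathwayCollection(tuple(names), tuple(members))


def expand(collection: PathwayCollection) -> LatentExpansion:
    """Latent-effect expansion: one column per (pathway, member gene) slot."""
    gidx = collection.gene_index()
    u = sum(collection.sizes)
    S = np.zeros((collection.q, u), dtype=np.int8)
    group_of = np.empty(u, dtype=np.intp)
    gene_of = np.empty(u, dtype=np.intp)
    col = 0
    for g, genes in enumerate(collection.members):
        for gene in genes:
            S[gidx[gene], col] = 1
            group_of[col] = g
            gene_of[col] = gidx[gene]
            col += 1
    return LatentExpansion(S, group_of, gene_of, collection.gene_universe)


def collapse(gamma, expansion: LatentExpansion) -> np.ndarray:
    """Fold latent coefficients back to gene coefficients: beta = S @ gamma."""
    gamma = np.asarray(gamma, dtype=float).ravel()
    if gamma.size != expansion.u:
        raise ValueError(f"gamma has length {gamma.size}, expected u = {expansion.u}")
    beta = np.zeros(expansion.q)
    np.add.at(beta, expansion.gene_of, gamma)
    return beta


def apply_unmapped_policy(collection: PathwayCollection, data_genes) -> PathwayCollection:
    """Reconcile a collection with the genes present in an expression matrix.

    Pathway members absent from the data are dropped.  Data genes in no
    pathway are discarded or collected into an ``UNGROUPED`` pathway,
    according to ``collection.unmapped_policy``.
    """
    data_genes = list(data_genes)
    present = set(data_genes)
    names, members = [], []
    for name, genes in zip(collection.names, collection.members):
        kept = tuple(g for g in genes if g in present)
        if kept:
            names.append(name)
            members.append(kept)
    mapped = set(g for m in members for g in m)
    leftover = [g for g in data_genes if g not in mapped]
    if leftover and collection.unmapped_policy == "extra_group":
        names.append("UNGROUPED")
        members.append(tuple(leftover))
    elif leftover:
        logger.info("discarding %d genes mapped to no pathway", len(leftover))
    return PathwayCollection(tuple(names), tuple(members), collection.unmapped_policy)
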