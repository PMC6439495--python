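"""COX1 haplotype collapsing, substitution distances and haplotype networks.

Aligned mitochondrial sequences are collapsed into haplotypes (identical at all
unambiguous positions), pairwise distances are substitution counts over
positions where both bases are unambiguous, and the haplotype network is a
minimum spanning network: a minimum spanning tree on the distance matrix plus
every alternative edge of equal weight (every edge belonging to some MST).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import SequenceAlignment

__all__ = [
    "HaplotypeTable",
    "collapse_haplotypes",
    "pairwise_substitutions",
    "distance_matrix",
    "build_network",
]

_UNAMBIG = frozenset("ACGT")


@dataclass
class HaplotypeTable:
    """Haplotypes ordered by descending count then first occurrence (H1, H2, ...)."""

    names: list                 # "H1", "H2", ...
    sequences: list             # representative sequence per haplotype
    members: list               # list of sample-id lists
    ambiguous_members: list     # sample ids merged via N/gap-masked matching
    group_counts: pd.DataFrame | None = None

    @property
    def counts(self) -> list:
        return [len(m) for m in self.members]

    def __len__(self) -> int:
        return len(self.names)


def _compatible(a: str, b: str) -> bool:
    """True when the sequences agree at every position where both are unambiguous."""
    return all(x == y or x not in _UNAMBIG or y not in _UNAMBIG
               for x, y in zip(a, b))


def collapse_haplotypes(aln: SequenceAlignment, groups: dict | None = None) -> HaplotypeTable:
    """Merge identical sequences into haplotypes.

    Fully unambiguous sequences cluster by exact identity. A sequence carrying
    N/gap characters joins the haplotype it is compatible with (equal wherever
    both are unambiguous); when several qualify it joins the most frequent one
    (ties: earliest haplotype) and is flagged as ambiguous — partial reads must
    not inflate the haplotype count. Naming is deterministic: H1, H2, ... by
    descending total count, then first occurrence.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    clean_idx = [i for i, s in enumerate(aln.seqs) if set(s) <= _UNAMBIG]
    dirty_idx = [i for i in range(len(aln)) if i not in set(clean_idx)]
    reps: list = []          # representative sequences
    member_ids: list = []    # per haplotype: member indexes
    first_seen: list = []
    seq_to_h: dict = {}
    for i in clean_idx:
        s = aln.seqs[i]
        if s in seq_to_h:
            member_ids[seq_to_h[s]].append(i)
        else:
            seq_to_h[s] = len(reps)
            reps.append(s)
            member_ids.append([i])
            first_seen.append(i)
    ambiguous: list = []
    for i in dirty_idx:
        s = aln.seqs[i]
        options = [h for h, r in enumerate(reps) if _compatible(s, r)]
        if options:
            h = max(options, key=lambda h: (len(member_ids[h]), -first_seen[h]))
            member_ids[h].append(i)
            ambiguous.append(aln.ids[i])
        else:
            reps.append(s)
            member_ids.append([i])
            first_seen.append(i)
    order = sorted(range(len(reps)),
                   key=lambda h: (-len(member_ids[h]), first_seen[h]))
    names = [f"H{k + 1}" for k in range(len(order))]
    sequences = [reps[h] for h in order]
    members = [[aln.ids[i] for i in sorted(member_ids[h])] for h in order]
    table = HaplotypeTable(names=names, sequences=sequences, members=members,
                           ambiguous_members=ambiguous)
    if groups is not None:
        group_names = list(dict.fromkeys(groups.values()))
        data = {
            g: [sum(groups.get(m) == g for m in mem) for mem in members]
            for g in group_names
        }
        table.group_counts = pd.DataFrame(data, index=names)
    return table


def pairwise_substitutions(seq_a: str, seq_b: str) -> int:
    """Substitutions between two aligned sequences, ignoring positions where
    either base is ambiguous (anything outside ACGT)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences of unequal length")
    return sum(1 for x, y in zip(seq_a.upper(), seq_b.upper())
               if x in _UNAMBIG and y in _UNAMBIG and x != y)


def distance_matrix(table: HaplotypeTable) -> np.ndarray:
    n = len(table)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_substitutions(
                table.sequences[i], table.sequences[j]
            )
    return d


def build_network(table: HaplotypeTable) -> nx.Graph:
    """Minimum spanning network over haplotypes.

    Contains every edge that belongs to at least one minimum spanning tree of
    the complete distance graph: an edge (u, v, w) is included iff u and v are
    not connected using only edges of weight strictly less than w (Kruskal
    argument). Node attributes: ``count`` and ``sequence``; edge attribute:
    ``weight`` (substitution count between its endpoints).
    """
    n = len(table)
    d = distance_matrix(table)
    g = nx.Graph()
    for k in range(n):
        g.add_node(table.names[k], count=len(table.members[k]),
                   sequence=table.sequences[k])
    if n == 1:
        return g
    edges = sorted(
        ((d[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: e[0],
    )
    uf = nx.utils.UnionFind(range(n))
    k = 0
    while k < len(edges):
        w = edges[k][0]
        tier = []
        while k < len(edges) and edges[k][0] == w:
            tier.append(edges[k])
            k += 1
        # include every edge of this weight joining components formed by
        # strictly smaller weights
        keep = [(i, j) for _, i, j in tier if uf[i] != uf[j]]
        for i, j in keep:
            g.add_edge(table.names[i], table.names[j], weight=int(w))
        for i, j in keep:
            uf.union(i, j)
    return g


def network_edges_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [(u, v, data["weight"]) for u, v, data in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["haplotype_a", "haplotype_b", "substitutions"])
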