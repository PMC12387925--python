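"""Exact significance tests for multi-set gene-list intersections.

Null model: each named set is drawn independently and uniformly without
replacement from a common background universe of known size, with the set
sizes fixed at their observed values.  For two sets the intersection size
is exactly hypergeometric.  For m sets the distribution of
|A_1 ∩ ... ∩ A_m| is built by a forward recursion that is linear in the
number of sets: conditional on the running intersection having size j,
intersecting with the next set of size n_k gives a hypergeometric
Hyp(N, j, n_k) count, so

    P_k(i) = sum_j P_{k-1}(j) * HypPMF(i; N, j, n_k),   P_1 = point mass at n_1.

The upper-tail probability of the observed overlap is the reported p-value;
at observed overlap 0 it is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "read_gene_sets",
    "intersection_counts",
    "intersection_distribution",
    "expected_overlap",
    "exact_overlap_pvalue",
    "overlap_table",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene-identifier sets plus the background universe size.

    The background size is a required user input: it is the number of genes
    that could in principle have appeared in any of the lists (e.g. all
    annotated genes in the genome release used for mapping).
    """

    background_size: int
    sets: Mapping[str, frozenset]

    def __post_init__(self):
        if self.background_size < 1:
            raise ValueError("background_size must be a positive integer")
        frozen = {}
        for name, members in self.sets.items():
            members = list(members)
            if len(members) != len(set(members)):
                raise ValueError(f"set {name!r} contains duplicate identifiers")
            if len(members) > self.background_size:
                raise ValueError(
                    f"set {name!r} is larger than the background universe"
                )
            frozen[name] = frozenset(members)
        object.__setattr__(self, "sets", frozen)

    def sizes(self, names: Sequence[str] | None = None) -> list[int]:
        names = list(names) if names is not None else list(self.sets)
        return [len(self.sets[n]) for n in names]


def read_gene_sets(paths: Mapping[str, str | Path], background_size: int) -> GeneSetCollection:
    """Load newline-delimited gene-ID files into a collection."""
    sets = {}
    for name, path in paths.items():
        ids = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        sets[name] = frozenset(ids)
        if len(ids) != len(sets[name]):
            raise ValueError(f"duplicate gene identifiers in {path}")
    return GeneSetCollection(background_size=background_size, sets=sets)


def intersection_counts(collection: GeneSetCollection) -> dict[tuple[str, ...], int]:
    """Size of the intersection of every nonempty subset of the named sets."""
    names = list(collection.sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = frozenset.intersection(*(collection.sets[n] for n in combo))
            out[combo] = len(inter)
    return out


def intersection_distribution(background_size: int, set_sizes: Sequence[int]) -> np.ndarray:
    """Exact pmf of the total intersection size of independently drawn sets.

    Returns an array p where p[i] = P(|intersection| = i), i = 0..min(sizes),
    computed by the forward recursion described in the module docstring.
    """
    sizes = [int(s) for s in set_sizes]
    if len(sizes) < 1:
        raise ValueError("need at least one set size")
    if any(s < 0 or s > background_size for s in sizes):
        raise ValueError("set sizes must lie in [0, background_size]")
    pmf = np.zeros(sizes[0] + 1)
    pmf[sizes[0]] = 1.0
    for n_k in sizes[1:]:
        cur_max = len(pmf) - 1
        new_max = min(cur_max, n_k)
        i = np.arange(new_max + 1)
        j = np.arange(cur_max + 1)
        # transition[i, j] = P(next intersection = i | current = j)
        transition = hypergeom.pmf(
            i[:, None], background_size, j[None, :], n_k
        )
        pmf = transition @ pmf
        pmf = np.clip(pmf, 0.0, None)
        pmf /= pmf.sum()
    return pmf


def expected_overlap(background_size: int, set_sizes: Sequence[int]) -> float:
    """Null expectation of the total intersection size: N * prod(n_i / N)."""
    e = float(background_size)
    for s in set_sizes:
        e *= s / background_size
    return e


def exact_overlap_pvalue(
    collection: GeneSetCollection,
    names: Sequence[str] | None = None,
    observed: int | None = None,
) -> float:
    """P(intersection >= observed) for the chosen subset of sets.

    ``observed`` defaults to the actual intersection size of the named sets.
    For two sets this equals the hypergeometric upper tail exactly.
    """
    names = list(names) if names is not None else list(collection.sets)
    sizes = collection.sizes(names)
    if observed is None:
        observed = len(frozenset.intersection(*(collection.sets[n] for n in names)))
    observed = int(observed)
    if observed < 0 or observed > min(sizes):
        raise ValueError(
            f"observed overlap {observed} outside [0, {min(sizes)}] "
            "(cannot exceed the smallest set)"
        )
    if observed == 0:
        return 1.0
    pmf = intersection_distribution(collection.background_size, sizes)
    p = float(pmf[observed:].sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def overlap_table(collection: GeneSetCollection, min_degree: int = 2) -> pd.DataFrame:
    """Tidy results for every subset of sets of size >= ``min_degree``:
    observed intersection, null expectation and exact upper-tail p-value."""
    counts = intersection_counts(collection)
    rows = []
    for combo, observed in sorted(counts.items(), key=lambda kv: (len(kv[0]), kv[0])):
        if len(combo) < min_degree:
            continue
        sizes = collection.sizes(combo)
        rows.append(
            {
                "subset": " & ".join(combo),
                "degree": len(combo),
                "observed": observed,
                "expected": expected_overlap(collection.background_size, sizes),
                "p_value": exact_overlap_pvalue(collection, combo, observed),
            }
        )
    return pd.DataFrame(rows)
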