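"""Recombination analysis: minimal template switches and the PHI test.

Two complementary questions are answered here.  Per clone: what is the
smallest number of template switches (crossovers) that would derive this
sequence from a set of candidate parental haplotypes, and which sites
remain unexplained?  Per sample: is there statistical evidence for
recombination at all, via the pairwise homoplasy index (PHI)?

Minimal crossovers
------------------
Informative sites are the alignment columns where the candidate parents
differ from each other; the child is compared to the parents only at those
columns.  A dynamic program over the ordered informative sites, with one
state per parent and unit cost per parent change, yields the minimum
switch count.  Sites where the child matches no parent are reported
separately as unexplained (unique) polymorphisms and never force a switch.
Gaps count as a fifth character state, since indels are genuine haplotype
markers at this locus.

PHI
---
For each pair of parsimony-informative sites the *refined incompatibility*
is the minimum number of extra (homoplasious) state changes any tree must
invoke, computed as the cycle rank E - V + C of the bipartite
partition-intersection graph of the two sites (0 for compatible pairs; for
binary sites this is the four-gamete test).  The statistic is the mean
refined incompatibility over pairs of sites at most ``window`` apart in
the informative-site ordering.  Under clonal evolution incompatibility is
unrelated to genomic position, so permuting the site order gives the null
distribution; recombination makes nearby pairs *more* compatible than
distant ones, so small observed statistics give small p-values.  A normal
approximation using exact permutation moments (Mantel-type) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import inf

import numpy as np
from scipy.stats import norm

from .seqio import MultipleAlignment

logger = logging.getLogger(__name__)

__all__ = ["CrossoverResult", "PhiResult", "min_crossovers", "phi_test"]


@dataclass(frozen=True)
class CrossoverResult:
    child_id: str
    parent_ids: tuple[str, ...]
    informative_sites: tuple[int, ...]  # 1-based, parents differ here
    path: tuple[str, ...]  # parent id per explained informative site
    explained_sites: tuple[int, ...]  # sites on the path
    k_switches: int
    breakpoint_intervals: tuple[tuple[int, int], ...]
    unexplained_sites: tuple[int, ...]  # child matches no parent


def min_crossovers(
    child: tuple[str, str] | str,
    parents: list[tuple[str, str]],
    sites: list[int] | None = None,
) -> CrossoverResult:
    """Minimal-switch explanation of a child sequence by candidate parents.

    ``child`` is ``(id, sequence)`` (a bare sequence gets id ``"child"``);
    ``parents`` is a list of at least two ``(id, sequence)`` pairs of the
    same alignment length.  ``sites`` optionally restricts the scan to
    those 1-based columns (e.g. known polymorphic sites); by default all
    columns are scanned for parent-vs-parent differences.

    Among minimal-switch paths, the one with lexicographically earliest
    breakpoints (switches as early as possible; parent ties by list order)
    is reported.  Breakpoints are open intervals ``(position_after,
    position_before)`` between consecutive explained sites assigned to
    different parents.
    """
    if isinstance(child, str):
        child = ("child", child)
    child_id, child_seq = child
    if len(parents) < 2:
        raise ValueError("need at least two candidate parents")
    parent_ids = tuple(pid for pid, _ in parents)
    parent_seqs = [seq for _, seq in parents]
    length = len(parent_seqs[0])
    if any(len(s) != length for s in parent_seqs) or len(child_seq) != length:
        raise ValueError("child and parents must share one alignment length")

    positions = sites if sites is not None else range(1, length + 1)
    informative = [
        p for p in positions if len({s[p - 1] for s in parent_seqs}) > 1
    ]
    if not informative:
        raise ValueError("parents are identical at every considered site")

    explained: list[int] = []
    allowed: list[list[int]] = []  # parent indices matching child per site
    unexplained: list[int] = []  # child matches no parent (unique sites)
    informative_set = set(informative)
    for p in positions:
        c = child_seq[p - 1]
        if c == "N":
            if p in informative_set:
                logger.info(
                    "child %s has N at informative site %d; skipped", child_id, p
                )
            continue
        matches = [i for i, s in enumerate(parent_seqs) if s[p - 1] == c]
        if not matches:
            unexplained.append(p)
        elif p in informative_set:
            explained.append(p)
            allowed.append(matches)

    if not explained:
        return CrossoverResult(
            child_id=child_id,
            parent_ids=parent_ids,
            informative_sites=tuple(informative),
            path=(),
            explained_sites=(),
            k_switches=0,
            breakpoint_intervals=(),
            unexplained_sites=tuple(unexplained),
        )

    m, np_ = len(explained), len(parents)
    # suffix_min[i][p]: min switches over sites i.. given parent p at site i
    suffix = [[inf] * np_ for _ in range(m)]
    for p in allowed[m - 1]:
        suffix[m - 1][p] = 0
    for i in range(m - 2, -1, -1):
        for p in allowed[i]:
            suffix[i][p] = min(
                (q != p) + suffix[i + 1][q] for q in allowed[i + 1]
            )

    best = min(suffix[0][p] for p in allowed[0])
    # left-to-right reconstruction; switch as early as optimality permits
    cur = next(p for p in allowed[0] if suffix[0][p] == best)
    path_idx = [cur]
    remaining = best
    for i in range(1, m):
        options = [
            q
            for q in allowed[i]
            if (q != cur) + suffix[i][q] == remaining
        ]
        switches = [q for q in options if q != cur]
        nxt = switches[0] if switches else options[0]
        remaining -= nxt != cur
        cur = nxt
        path_idx.append(cur)

    breakpoints = tuple(
        (explained[i - 1], explained[i])
        for i in range(1, m)
        if path_idx[i] != path_idx[i - 1]
    )
    return CrossoverResult(
        child_id=child_id,
        parent_ids=parent_ids,
        informative_sites=tuple(informative),
        path=tuple(parent_ids[i] for i in path_idx),
        explained_sites=tuple(explained),
        k_switches=best,
        breakpoint_intervals=breakpoints,
        unexplained_sites=tuple(unexplained),
    )


# ---------------------------------------------------------------------------
# PHI


@dataclass(frozen=True)
class PhiResult:
    statistic: float
    p_value: float
    window: int
    n_informative: int
    n_permutations: int
    method: str
    computable: bool = True


def _informative_columns(aln: MultipleAlignment) -> list[int]:
    """Parsimony-informative columns: >=2 states, each in >=2 sequences.

    Gap is a fifth state; N is treated as missing.
    """
    out = []
    for pos in range(1, aln.length + 1):
        col = [c for c in aln.column(pos) if c != "N"]
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append(pos)
    return out


def _refined_incompatibility(col_a: list[str], col_b: list[str]) -> int:
    """Cycle rank of the bipartite partition-intersection graph.

    Equals the minimum number of homoplasies any tree needs to fit both
    sites; 0 iff the pair is compatible (generalised four-gamete test).
    """
    edges = set()
    for a, b in zip(col_a, col_b):
        if a == "N" or b == "N":
            continue
        edges.add((a, b))
    states_a = {a for a, _ in edges}
    states_b = {b for _, b in edges}
    nodes = [("a", s) for s in states_a] + [("b", s) for s in states_b]
    index = {node: i for i, node in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    components = len(nodes)
    for a, b in edges:
        ra, rb = find(index[("a", a)]), find(index[("b", b)])
        if ra != rb:
            parent[ra] = rb
            components -= 1
    return len(edges) - len(nodes) + components


def _mantel_moments(M: np.ndarray, B: np.ndarray) -> tuple[float, float]:
    """Exact mean/variance of S = sum_{i!=j} M[s(i),s(j)] B[i,j] over
    uniformly random permutations s (Mantel permutation moments)."""
    n = M.shape[0]

    def stats(A: np.ndarray) -> tuple[float, float, float]:
        a0 = A.sum()
        a1 = (A**2).sum()
        a2 = (A.sum(axis=1) ** 2).sum()
        return a0, a1, a2

    a0, a1, a2 = stats(M)
    b0, b1, b2 = stats(B)
    n2 = n * (n - 1)
    n3 = n2 * (n - 2)
    n4 = n3 * (n - 3)
    mean = a0 * b0 / n2
    esq = (
        2 * a1 * b1 / n2
        + 4 * (a2 - a1) * (b2 - b1) / n3
        + (a0**2 + 2 * a1 - 4 * a2) * (b0**2 + 2 * b1 - 4 * b2) / n4
    )
    return mean, esq - mean**2


def phi_test(
    aln: MultipleAlignment,
    window: int = 100,
    n_permutations: int = 1000,
    seed: int | None = None,
    method: str = "permutation",
) -> PhiResult:
    """Pairwise homoplasy index test for recombination.

    ``window`` is measured in informative-site ranks; pairs farther apart
    are ignored by the statistic.  ``method`` is ``"permutation"``
    (default; requires ``seed`` for reproducibility) or ``"normal"``
    (Mantel-moment approximation).  With fewer than 4 sequences or fewer
    than 2 informative sites the result is flagged not computable.
    """
    info = _informative_columns(aln)
    n = len(info)
    if len(aln) < 4 or n < 2:
        return PhiResult(
            statistic=float("nan"),
            p_value=float("nan"),
            window=window,
            n_informative=n,
            n_permutations=0,
            method=method,
            computable=False,
        )

    cols = [list(aln.column(p)) for p in info]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = _refined_incompatibility(cols[i], cols[j])

    ii, jj = np.triu_indices(n, k=1)
    near = (jj - ii) <= window
    pi, pj = ii[near], jj[near]
    observed = float(M[pi, pj].mean())

    if method == "normal":
        B = np.zeros((n, n))
        B[pi, pj] = B[pj, pi] = 1.0
        mean_s, var_s = _mantel_moments(M, B)
        npairs = 2 * len(pi)
        mean, var = mean_s / npairs, var_s / npairs**2
        if var <= 0:
            p = 1.0
        else:
            p = float(norm.cdf((observed - mean) / np.sqrt(var)))
        return PhiResult(observed, p, window, n, 0, "normal")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        stat = M[perm[pi], perm[pj]].mean()
        if stat <= observed + 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return PhiResult(observed, float(p), window, n, n_permutations, "permutation")
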