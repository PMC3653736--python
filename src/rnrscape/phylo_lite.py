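"""Desk-scale distance phylogenetics for the co-inheritance question.

Per-gene trees are built from Poisson-corrected protein distances by
neighbor joining (deterministic, with lexicographic tie-breaking), and
topological congruence between two gene families — do nrdA and nrdB share
one evolutionary history? — is quantified by the Robinson–Foulds distance on
the genomes carrying both genes. The report prints raw and normalized RF
without imposing a verdict threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .curation import CuratedCall, accepted
from .formats_io import SequenceRecord

GAP_CHARS = {"-", "."}


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("entries must be finite and non-negative")
        self.matrix = m


def protein_distance(seqs: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances from an aligned protein set.

    p is the mismatch fraction over mutually non-gap columns and
    d = -ln(1 - p). Saturated pairs (p >= 1) or pairs with no shared
    non-gap column are errors naming the offending pair.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    width = len(seqs[0].seq)
    if any(len(s.seq) != width for s in seqs):
        raise ValueError("sequences must be aligned (equal length)")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i].seq.upper(), seqs[j].seq.upper()
            overlap = mismatch = 0
            for x, y in zip(a, b):
                if x in GAP_CHARS or y in GAP_CHARS:
                    continue
                overlap += 1
                if x != y:
                    mismatch += 1
            if overlap == 0:
                raise ValueError(f"no shared non-gap columns: {seqs[i].id} vs {seqs[j].id}")
            p = mismatch / overlap
            if p >= 1:
                raise ValueError(f"saturated pair (p >= 1): {seqs[i].id} vs {seqs[j].id}")
            d[i, j] = d[j, i] = -math.log(1 - p)
    return DistanceMatrix(labels=[s.id for s in seqs], matrix=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration, deterministic under label permutation.

    The Q-matrix argmin is tie-broken lexicographically on the (sorted) label
    pair, so permuting input order never changes the topology. Negative
    branch-length estimates are clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # active nodes: newick subtree strings keyed by a representative label
    nodes: dict[str, str] = {}
    reps: list[str] = []
    D: dict[tuple[str, str], float] = {}
    for i, lab in enumerate(dm.labels):
        nodes[lab] = lab
        reps.append(lab)
    for i in range(n):
        for j in range(n):
            D[(dm.labels[i], dm.labels[j])] = float(dm.matrix[i, j])

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else D[(a, b)]

    while len(reps) > 3:
        m = len(reps)
        r = {a: sum(dist(a, b) for b in reps) for a in reps}
        best: Optional[tuple[float, str, str]] = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = sorted((reps[ai], reps[bi]))
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                cand = (q, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best  # type: ignore[misc]
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_rep = min(a, b)
        merged = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        for c in reps:
            if c in (a, b):
                continue
            dnew = 0.5 * (dist(a, c) + dist(b, c) - dab)
            D[(new_rep, c)] = D[(c, new_rep)] = max(dnew, 0.0)
        reps = [c for c in reps if c not in (a, b)] + [new_rep]
        nodes.pop(a), nodes.pop(b)
        nodes[new_rep] = merged

    a, b, c = sorted(reps)
    la = max(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)), 0.0)
    lb = max(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)), 0.0)
    lc = max(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)), 0.0)
    newick = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# Robinson–Foulds
# ---------------------------------------------------------------------------

def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Raw and normalized Robinson–Foulds distance between two unrooted trees.

    raw = bipartitions present in exactly one tree; normalized =
    raw / (2 (n - 3)). The trees must share one leaf set of n >= 4.
    """
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have differing leaf sets; restrict before comparing")
    n = len(l1)
    if n < 4:
        raise ValueError("RF comparison needs at least 4 leaves")
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    raw = int(dendropy.calculate.treecompare.symmetric_difference(a, b))
    return raw, raw / (2 * (n - 3))


def congruence_report(
    calls: Sequence[CuratedCall],
    family1: str,
    family2: str,
    alignments: Mapping[str, Sequence[SequenceRecord]],
) -> dict:
    """Compare per-family NJ topologies on genomes carrying both genes.

    ``alignments`` maps family -> aligned protein records whose ids are
    genome ids. Leaves are restricted to genomes with accepted calls of both
    families (at least 4 required).
    """
    have: dict[str, set[str]] = {family1: set(), family2: set()}
    for c in accepted(calls):
        if c.family in have:
            have[c.family].add(c.genome_id)
    shared = sorted(have[family1] & have[family2])
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 genomes with accepted {family1} and {family2} calls, found {len(shared)}"
        )
    trees = {}
    for fam in (family1, family2):
        recs = [r for r in alignments[fam] if r.id in shared]
        missing = set(shared) - {r.id for r in recs}
        if missing:
            raise ValueError(f"alignment for {fam} lacks genomes: {sorted(missing)}")
        trees[fam] = neighbor_joining(protein_distance(recs))
    raw, norm = rf_distance(trees[family1], trees[family2])
    return {
        "family1": family1,
        "family2": family2,
        "n_shared_genomes": len(shared),
        "genomes": shared,
        "rf_raw": raw,
        "rf_normalized": norm,
        "tree1": trees[family1],
        "tree2": trees[family2],
    }
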