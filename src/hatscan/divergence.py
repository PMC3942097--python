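"""Pairwise evolutionary distances and neighbor-joining trees.

Distances operate on pre-aligned sequences with *pairwise deletion*: for
each pair, columns where either sequence carries a gap or an ambiguous
base are dropped before counting.  Two metrics are provided:

* **p-distance** — the proportion of differing sites among compared
  sites.
* **Tamura 3-parameter distance** — corrects the p-distance for
  multiple hits using the transition/transversion split (P, Q) and the
  GC content theta of the pair::

      h = 2 * theta * (1 - theta)
      d = -h * ln(1 - P/h - Q) - 0.5 * (1 - h) * ln(1 - 2Q)

Transitions are A<->G and C<->T; everything else is a transversion.
Trees are built with Saitou–Nei neighbor joining and carried as
scikit-bio ``TreeNode`` objects (unrooted, trifurcating root).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .seqcore import Sequence

__all__ = [
    "PairwiseAlignment",
    "DistanceMatrix",
    "SaturationError",
    "UndefinedDistanceError",
    "p_distance",
    "tamura_3p_distance",
    "distance_matrix",
    "nj_tree",
    "write_newick",
    "read_newick",
    "write_phylip_matrix",
    "read_phylip_matrix",
]

_GAP = frozenset("-.")
_UNAMBIG = frozenset("ACGT")
_PURINES = frozenset("AG")


class SaturationError(ValueError):
    """Distance correction undefined: substitution saturation (log arg <= 0)."""


class UndefinedDistanceError(ValueError):
    """No comparable sites between a pair of sequences."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """Site counts of one aligned pair after pairwise deletion.

    ``compared_sites`` counts columns where both sequences carry an
    unambiguous base; ``diffs`` splits into ``transitions`` +
    ``transversions``.  ``gc_mean`` is the mean GC fraction of the two
    sequences over compared sites (the theta of the T92 correction).
    """

    seq_a: str
    seq_b: str
    compared_sites: int
    diffs: int
    transitions: int
    transversions: int
    gc_mean: float

    @classmethod
    def from_sequences(cls, a: Sequence | str, b: Sequence | str) -> "PairwiseAlignment":
        ra = a.residues if isinstance(a, Sequence) else str(a).upper()
        rb = b.residues if isinstance(b, Sequence) else str(b).upper()
        ida = a.id if isinstance(a, Sequence) else "seq_a"
        idb = b.id if isinstance(b, Sequence) else "seq_b"
        if len(ra) != len(rb):
            raise ValueError(
                f"aligned sequences must have equal length ({ida}: {len(ra)}, {idb}: {len(rb)})"
            )
        compared = diffs = ts = tv = 0
        gc = 0
        for x, y in zip(ra, rb):
            if x not in _UNAMBIG or y not in _UNAMBIG:
                continue  # gap or ambiguity: pairwise deletion
            compared += 1
            gc += (x in "GC") + (y in "GC")
            if x != y:
                diffs += 1
                if (x in _PURINES) == (y in _PURINES):
                    ts += 1
                else:
                    tv += 1
        gc_mean = gc / (2 * compared) if compared else float("nan")
        return cls(ida, idb, compared, diffs, ts, tv, gc_mean)


def p_distance(aln: PairwiseAlignment) -> float:
    """Proportion of differing sites among pairwise-comparable positions."""
    if aln.compared_sites < 1:
        raise UndefinedDistanceError(
            f"no comparable sites between {aln.seq_a!r} and {aln.seq_b!r}"
        )
    return aln.diffs / aln.compared_sites


def tamura_3p_distance(aln: PairwiseAlignment, theta: float | None = None) -> float:
    """Tamura (1992) three-parameter distance.

    ``theta`` defaults to the mean GC content of the pair over compared
    sites; passing it explicitly supports closed-form spot checks.
    """
    if aln.compared_sites < 1:
        raise UndefinedDistanceError(
            f"no comparable sites between {aln.seq_a!r} and {aln.seq_b!r}"
        )
    P = aln.transitions / aln.compared_sites
    Q = aln.transversions / aln.compared_sites
    if theta is None:
        theta = aln.gc_mean
    h = 2.0 * theta * (1.0 - theta)
    if P == 0.0 and Q == 0.0:
        return 0.0
    arg1 = 1.0 - (P / h if h > 0 else math.inf) - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturationError(
            f"substitution saturation between {aln.seq_a!r} and {aln.seq_b!r}: "
            f"P={P:.4f}, Q={Q:.4f}, theta={theta:.4f}"
        )
    return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.d[i, j])


def distance_matrix(seqs: list[Sequence], metric: str = "p") -> DistanceMatrix:
    """All pairwise distances under a metric, with pairwise deletion.

    ``metric`` is ``"p"`` or ``"t92"``.  Per-pair errors (no comparable
    sites, saturation) propagate with the offending pair named.
    """
    if metric not in ("p", "t92"):
        raise ValueError(f"unknown metric {metric!r}")
    fn = p_distance if metric == "p" else tamura_3p_distance
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = PairwiseAlignment.from_sequences(seqs[i], seqs[j])
            d[i, j] = d[j, i] = fn(aln)
    return DistanceMatrix(tuple(s.id for s in seqs), d)


def nj_tree(m: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising the rate-corrected criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` is joined; ties break to the
    lowest (i, j) label-index pair.  Negative branch lengths are clamped
    to zero and flagged on the returned tree as
    ``tree.negative_branches_clamped``.  The result is unrooted,
    represented with a trifurcating root.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")
    if not np.all(np.isfinite(m.d)):
        raise ValueError("non-finite distances")

    d = m.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in m.labels]
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (k - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))))
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        d2 = np.zeros((k - 1, k - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # final three-way join: closed-form branch lengths
    a, b, c = nodes
    la = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    lb = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    a.length, b.length, c.length = la, lb, lc
    root = TreeNode()
    root.extend([a, b, c])
    root.negative_branches_clamped = clamped
    return root


def write_newick(t: TreeNode) -> str:
    buf = io.StringIO()
    t.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(s: str) -> TreeNode:
    try:
        return TreeNode.read(io.StringIO(s), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise ValueError(f"malformed newick: {exc}") from exc


def write_phylip_matrix(m: DistanceMatrix) -> str:
    """Square PHYLIP-style distance matrix text."""
    lines = [f"{len(m.labels)}"]
    for lab, row in zip(m.labels, m.d):
        lines.append(lab + "  " + "  ".join(f"{x:.6f}" for x in row))
    return "\n".join(lines) + "\n"


def read_phylip_matrix(text: str) -> DistanceMatrix:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(tuple(labels), np.asarray(rows))
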