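"""Distance-based placement of (partially masked) consensus mitogenomes.

Distances are uncorrected p-distances with pairwise deletion: for each pair,
comparable sites are the positions where both sequences carry a plain base
(A/C/G/T; N and '-' are excluded), and the distance is the fraction of
comparable sites that differ (optionally counting transversions only, the
damage-immune subset). Pairs with fewer than ``min_comparable`` comparable
sites are flagged undefined. Trees come from standard neighbor joining
(Q-criterion, Saitou–Nei updates) with lowest-index tie-breaking, so the
output is deterministic; negative branch lengths are clamped to zero and the
clamping is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PURINES


class PanelError(ValueError):
    pass


class UndefinedDistanceError(RuntimeError):
    pass


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}


@dataclass
class AlignedPanel:
    """Equal-length aligned sequences over {A,C,G,T,N,-} with labels."""

    labels: list
    sequences: list

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise PanelError("labels and sequences must pair up")
        if len({len(s) for s in self.sequences} or {0}) > 1:
            raise PanelError("aligned sequences must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def encoded(self) -> np.ndarray:
        arr = np.empty((len(self.sequences), len(self.sequences[0])), dtype=np.int8)
        for i, s in enumerate(self.sequences):
            try:
                arr[i] = [_ENC[c] for c in s.upper()]
            except KeyError as exc:
                raise PanelError(
                    f"{self.labels[i]}: illegal character {exc.args[0]!r}"
                ) from exc
        return arr


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray  # substitutions per comparable site; NaN when undefined
    n_comparable: np.ndarray
    mode: str = "all"

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


_IS_PURINE = np.array([1, 0, 1, 0, 0], dtype=np.int8)  # A,C,G,T,N/-


def pairwise_distance(
    panel: AlignedPanel, mode: str = "all", min_comparable: int = 100
) -> DistanceMatrix:
    """Pairwise p-distance matrix with pairwise deletion of masked sites."""
    if len(panel) < 2:
        raise PanelError("need at least two sequences")
    if mode not in ("all", "transversions_only"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = panel.encoded()
    n = arr.shape[0]
    values = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    plain = arr < 4
    purine = _IS_PURINE[arr]
    for i in range(n):
        for j in range(i + 1, n):
            both = plain[i] & plain[j]
            m = int(both.sum())
            comp[i, j] = comp[j, i] = m
            if m < min_comparable:
                values[i, j] = values[j, i] = np.nan
                continue
            diff = (arr[i] != arr[j]) & both
            if mode == "transversions_only":
                diff &= purine[i] != purine[j]
            d = float(diff.sum()) / m
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(panel.labels), values=values, n_comparable=comp, mode=mode)


@dataclass
class TreeNode:
    label: str = None
    children: list = field(default_factory=list)  # (child, branch_length)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})" + (self.label or "")

    def leaf_labels(self) -> list:
        if not self.children:
            return [self.label]
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_labels())
        return out


@dataclass
class NJResult:
    tree: TreeNode
    newick: str
    clamped_negative_branches: int = 0


def neighbor_joining(matrix: DistanceMatrix) -> NJResult:
    """Saitou–Nei neighbor joining; deterministic lowest-index tie-breaks.

    Requires every pair defined and n >= 3. The returned tree is unrooted,
    represented with a trifurcating root holding the last three lineages.
    """
    if not matrix.defined[~np.eye(len(matrix.labels), dtype=bool)].all():
        raise UndefinedDistanceError(
            "distance matrix has undefined pairs; lower min_comparable or mask less"
        )
    n = len(matrix.labels)
    if n < 3:
        raise PanelError("neighbor joining needs at least 3 taxa")
    D = matrix.values.astype(float).copy()
    nodes = [TreeNode(label=l) for l in matrix.labels]
    active = list(range(n))
    clamped = 0

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        parent = TreeNode(
            children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))]
        )
        # Saitou–Nei distance update for the new node, reusing row i
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        active.remove(j)
    # resolve the final three lineages with the three-point formulas
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode(
        children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj)), (nodes[k], clamp(lk))]
    )
    return NJResult(tree=root, newick=root.newick(), clamped_negative_branches=clamped)


def nearest_reference(
    query: str,
    references: AlignedPanel,
    mode: str = "all",
    min_comparable: int = 100,
    query_label: str = "query",
) -> list:
    """References ranked by p-distance to the query.

    The query must share the panel's coordinate frame (same-reference
    consensus sequences do by construction). Ties break toward the pair with
    more comparable sites, then label order. Returns a list of
    (label, distance, n_comparable); raises if no pair is defined.
    """
    panel = AlignedPanel(
        labels=[query_label] + list(references.labels),
        sequences=[query] + list(references.sequences),
    )
    dm = pairwise_distance(panel, mode=mode, min_comparable=min_comparable)
    ranked = []
    for idx, label in enumerate(references.labels, start=1):
        d = dm.values[0, idx]
        if not np.isnan(d):
            ranked.append((label, float(d), int(dm.n_comparable[0, idx])))
    if not ranked:
        raise UndefinedDistanceError(
            "no reference shares enough comparable sites with the query"
        )
    order = {label: i for i, label in enumerate(references.labels)}
    ranked.sort(key=lambda t: (t[1], -t[2], order[t[0]]))
    return ranked
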