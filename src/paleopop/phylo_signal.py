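"""Abouheif-Moran test for phylogenetic autocorrelation of tip traits.

The test is Moran's I with a purely topological proximity matrix: for
tips i != j the Abouheif proximity is

    A_ij = 1 / prod dd(v)   over every internal node v on the path from
                            i to j (the MRCA and all intermediate
                            internal nodes), dd(v) = number of children

with the diagonal holding the row complement A_ii = 1 - sum_{j!=i} A_ij
so every row sums to 1 (the row-normalized convention).  Branch lengths
play no role.  The statistic

    Cmean = sum_{i!=j} W_ij z_i z_j / n

uses trait values standardized to mean 0 and unit variance (divisor n)
and W the off-diagonal proximities row-normalized over off-diagonal
mass.  Significance is one-tailed (greater), by permuting the
tip-to-value assignment; the add-one estimator
p = (1 + #{permuted >= observed}) / (n_permutations + 1) avoids p = 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np


@dataclass
class ProximityMatrix:
    labels: list[str]
    A: np.ndarray


@dataclass
class SignalResult:
    variable: str
    cmean_observed: float
    p_value: float
    n_permutations: int
    seed: int | None


def _leaf_paths(tree: dendropy.Tree):
    """Per-leaf list of ancestor nodes, root-first, plus the leaves."""
    leaves = list(tree.leaf_node_iter())
    anc = {}
    for leaf in leaves:
        chain = []
        node = leaf.parent_node
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[leaf] = chain[::-1]  # root ... parent(leaf)
    return leaves, anc


def abouheif_proximity(tree: dendropy.Tree) -> ProximityMatrix:
    """Topological Abouheif proximities with row-complement diagonal."""
    leaves, anc = _leaf_paths(tree)
    n = len(leaves)
    if n < 3:
        raise ValueError("Abouheif proximity needs a rooted tree with >= 3 tips")
    labels = [leaf.taxon.label for leaf in leaves]
    A = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ai, aj = anc[leaves[i]], anc[leaves[j]]
        k = 0  # depth of the MRCA in the two root-first chains
        while k < min(len(ai), len(aj)) and ai[k] is aj[k]:
            k += 1
        path_nodes = ai[k - 1 : ] + aj[k:]  # MRCA + intermediates on both sides
        prod = 1.0
        for v in path_nodes:
            prod *= len(v.child_nodes())
        A[i, j] = A[j, i] = 1.0 / prod
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    return ProximityMatrix(labels=labels, A=A)


def _align_values(labels: Sequence[str], values) -> np.ndarray:
    if isinstance(values, Mapping):
        missing = [lab for lab in labels if lab not in values]
        extra = [k for k in values if k not in set(labels)]
        if missing or extra:
            raise ValueError(
                f"tip/value mismatch; tips without values: {missing}; "
                f"values without tips: {extra}"
            )
        return np.array([float(values[lab]) for lab in labels])
    arr = np.asarray(values, dtype=float)
    if len(arr) != len(labels):
        raise ValueError(f"got {len(arr)} values for {len(labels)} tips")
    return arr


def _cmean(W: np.ndarray, z: np.ndarray) -> float:
    return float(z @ W @ z) / len(z)


def abouheif_cmean(tree: dendropy.Tree, values, n_permutations: int = 999,
                   seed: int | None = None, variable: str = "",
                   exhaustive: bool = False) -> SignalResult:
    """Abouheif's Cmean with a one-tailed (greater) permutation p-value.

    ``values`` is either a mapping from tip label to value or a sequence
    aligned to the tree's leaf order.  With ``exhaustive=True`` (small
    trees only) all n! relabelings are enumerated and the p-value is the
    exact fraction of relabelings with Cmean >= observed.
    """
    prox = abouheif_proximity(tree)
    x = _align_values(prox.labels, values)
    if np.std(x) == 0:
        raise ValueError(f"{variable or 'trait'}: zero variance; Cmean undefined")
    z = (x - x.mean()) / x.std()  # divisor n

    W = prox.A.copy()
    np.fill_diagonal(W, 0.0)
    W /= W.sum(axis=1, keepdims=True)
    obs = _cmean(W, z)

    n = len(z)
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to <= 8 tips")
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        stats_all = np.einsum("pi,ij,pj->p", z[perms], W, z[perms]) / n
        p = float(np.mean(stats_all >= obs - 1e-12))
        return SignalResult(variable, obs, p, n_permutations=math.factorial(n), seed=seed)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)], dtype=np.intp)
    Z = z[perms]
    stats_all = np.einsum("pi,ij,pj->p", Z, W, Z) / n
    n_ge = int(np.sum(stats_all >= obs - 1e-12))
    p = (1 + n_ge) / (n_permutations + 1)
    return SignalResult(variable, obs, p, n_permutations=n_permutations, seed=seed)
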