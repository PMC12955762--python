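"""Ground-truth structural similarity: Kabsch superposition and TM-score.

The TM-score between two chains with a known residue correspondence is

    TM = (1 / L_norm) * sum_i 1 / (1 + (d_i / d0(L_norm))**2)

where d_i are CA-CA distances of corresponding residues after an optimal
rigid superposition, L_norm is the length of the normalizing chain, and
d0(L) = 1.24 * (L - 15)**(1/3) - 1.8 (clamped below at 0.5 A) is the
length-dependent distance scale.  Scores lie in (0, 1]; values above 0.5
conventionally indicate the same fold.

Maximizing the score over superpositions is non-convex; this module uses
the established fragment-seed strategy: superpose on contiguous seed
windows of the correspondence, then iteratively re-superpose on the
residue subset within a distance cutoff until the subset is stable,
sweeping several cutoffs, and keep the best-scoring superposition.  For
short correspondences (<= 20 pairs) every contiguous window is used as a
seed, making the search exhaustive over its candidate set.

The residue correspondence is an input: it is never inferred here.
Synthetic benchmark structures share indices by construction, and
equal-length homologs use the identity correspondence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .structures import AssemblyStructure, ChainStructure

#: seed windows enumerate every contiguous window at or below this size
EXHAUSTIVE_LIMIT = 20
#: offsets added to d0 for the distance-cutoff sweep during refinement
DCUT_OFFSETS = (0.5, 1.5, 2.5, 3.5)
#: maximum refinement iterations per (seed, cutoff)
MAX_REFINE_ITER = 20


@dataclass
class Superposition:
    """A proper rigid transform ``x -> x @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TMScoreResult:
    """TM-scores under both normalizations plus the optimizing transform."""

    tm_query: float
    tm_target: float
    d0_query: float
    d0_target: float
    superposition: Superposition
    n_corresponding: int

    @property
    def tm_max(self) -> float:
        return max(self.tm_query, self.tm_target)


def kabsch(X: np.ndarray, Y: np.ndarray) -> Superposition:
    """Least-squares proper rigid superposition of point set X onto Y.

    Returns the rotation R (det +1; reflections excluded by the
    determinant correction in the SVD construction) and translation t
    minimizing RMSD of ``X @ R.T + t`` against Y.

    Raises
    ------
    ValueError
        If fewer than 3 point pairs are given.  Degenerate (collinear)
        sets are accepted; a valid minimizer is still returned.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both be (N, 3)")
    if X.shape[0] < 3:
        raise ValueError("Kabsch superposition requires at least 3 point pairs")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = X @ R.T + t - Y
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def d0(L: int) -> float:
    """TM-score normalization distance for a chain of length L (Angstrom).

    ``1.24 * cbrt(L - 15) - 1.8``, clamped below at 0.5 A (the raw formula
    is negative for L <= 15).  Monotone non-decreasing in L.
    """
    if L < 1:
        raise ValueError("length must be >= 1")
    return max(0.5, 1.24 * np.cbrt(L - 15.0) - 1.8)


def score_at_superposition(
    query: ChainStructure,
    target: ChainStructure,
    correspondence,
    superposition: Superposition,
    normalize_by: str = "query",
) -> float:
    """TM-score functional at a fixed superposition.

    ``correspondence`` is a sequence of ``(i_query, j_target)`` index
    pairs.  The score is 1 exactly iff every corresponding distance is 0
    and the correspondence covers the normalizing length.
    """
    pairs = np.asarray(list(correspondence), dtype=int)
    if pairs.size == 0:
        raise ValueError("empty correspondence")
    if normalize_by == "query":
        L_norm = len(query)
    elif normalize_by == "target":
        L_norm = len(target)
    else:
        raise ValueError("normalize_by must be 'query' or 'target'")
    moved = superposition.apply(query.ca_coords[pairs[:, 0]])
    d2 = np.sum((moved - target.ca_coords[pairs[:, 1]]) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / d0(L_norm) ** 2)) / L_norm)


def _seed_windows(n: int) -> list:
    """Contiguous (start, length) seed windows over an n-pair correspondence."""
    if n <= EXHAUSTIVE_LIMIT:
        return [
            (start, length)
            for length in range(min(3, n), n + 1)
            for start in range(0, n - length + 1)
        ]
    lengths = sorted({n, max(4, int(np.ceil(n / 2))), max(4, int(np.ceil(n / 4)))},
                     reverse=True)
    stride = max(1, n // 20)
    return [
        (start, length)
        for length in lengths
        for start in range(0, n - length + 1, stride)
    ]


def _search_best(X: np.ndarray, Y: np.ndarray, d0_norm: float, L_norm: int):
    """Fragment-seed TM-score maximization for one normalization.

    X, Y are the (N, 3) corresponding coordinate sets.  Returns
    (best score, best Superposition).
    """
    n = X.shape[0]
    d0_sq = d0_norm * d0_norm

    def full_score(sup: Superposition) -> float:
        diff = sup.apply(X) - Y
        d2 = np.sum(diff * diff, axis=1)
        return float(np.sum(1.0 / (1.0 + d2 / d0_sq)) / L_norm)

    best_score = -np.inf
    best_sup = None
    for start, length in _seed_windows(n):
        if length < 3:
            continue
        sl = slice(start, start + length)
        seed_sup = kabsch(X[sl], Y[sl])
        s = full_score(seed_sup)
        if s > best_score:
            best_score, best_sup = s, seed_sup
        for off in DCUT_OFFSETS:
            d_cut2 = (d0_norm + off) ** 2
            sup = seed_sup
            prev_sel = None
            for _ in range(MAX_REFINE_ITER):
                diff = sup.apply(X) - Y
                d2 = np.sum(diff * diff, axis=1)
                sel = d2 < d_cut2
                if sel.sum() < 3:
                    break
                if prev_sel is not None and np.array_equal(sel, prev_sel):
                    break
                prev_sel = sel
                sup = kabsch(X[sel], Y[sel])
                s = full_score(sup)
                if s > best_score:
                    best_score, best_sup = s, sup
    return best_score, best_sup


def tm_score(
    query: ChainStructure,
    target: ChainStructure,
    correspondence=None,
) -> TMScoreResult:
    """Maximized TM-score between two chains for a given correspondence.

    If ``correspondence`` is None, the identity correspondence is used
    (requires equal lengths).  Both normalizations are optimized
    independently; ``tm_max`` is the canonical similarity label.  The
    returned score is never below the score at the all-pair Kabsch
    superposition, which is always among the seeds.
    """
    if correspondence is None:
        if len(query) != len(target):
            raise ValueError(
                "identity correspondence requires equal lengths; "
                f"got {len(query)} and {len(target)}"
            )
        correspondence = [(i, i) for i in range(len(query))]
    pairs = np.asarray(list(correspondence), dtype=int)
    if pairs.size == 0:
        raise ValueError("empty correspondence")
    X = query.ca_coords[pairs[:, 0]]
    Y = target.ca_coords[pairs[:, 1]]

    d0_q, d0_t = d0(len(query)), d0(len(target))
    tm_q, sup_q = _search_best(X, Y, d0_q, len(query))
    tm_t, sup_t = _search_best(X, Y, d0_t, len(target))
    sup = sup_q if tm_q >= tm_t else sup_t
    return TMScoreResult(
        tm_query=tm_q,
        tm_target=tm_t,
        d0_query=d0_q,
        d0_target=d0_t,
        superposition=sup,
        n_corresponding=pairs.shape[0],
    )


def _concat_chains(assembly: AssemblyStructure, order) -> ChainStructure:
    coords = np.concatenate([assembly.chains[i].ca_coords for i in order], axis=0)
    seq = "".join(assembly.chains[i].sequence for i in order)
    return ChainStructure(chain_id="+", sequence=seq, ca_coords=coords)


def assembly_tm(
    a: AssemblyStructure,
    b: AssemblyStructure,
    chain_mapping: str = "identity",
) -> TMScoreResult:
    """TM-score between two assemblies of equal chain counts.

    Chains are concatenated in a mapped order and scored with the
    identity residue correspondence.  ``identity`` keeps the stored
    chain order; ``best_permutation`` exhaustively maximizes ``tm_max``
    over permutations of b's chains (chain count <= 8).
    """
    if len(a) != len(b):
        raise ValueError(f"chain counts differ: {len(a)} vs {len(b)}")
    n = len(a)
    if chain_mapping == "identity":
        perms = [tuple(range(n))]
    elif chain_mapping == "best_permutation":
        if n > 8:
            raise ValueError(
                "best_permutation supports at most 8 chains; use identity mapping"
            )
        lens_a = [len(c) for c in a.chains]
        lens_b = [len(c) for c in b.chains]
        perms = [
            p for p in itertools.permutations(range(n))
            if all(lens_b[p[i]] == lens_a[i] for i in range(n))
        ]
        if not perms:
            raise ValueError("no chain permutation matches the per-chain lengths")
    else:
        raise ValueError("chain_mapping must be 'identity' or 'best_permutation'")

    cat_a = _concat_chains(a, range(n))
    best = None
    for p in perms:
        if chain_mapping == "identity" and any(
            len(a.chains[i]) != len(b.chains[i]) for i in range(n)
        ):
            raise ValueError("per-chain lengths differ under identity mapping")
        res = tm_score(cat_a, _concat_chains(b, p))
        if best is None or res.tm_max > best.tm_max:
            best = res
    return best


def pairwise_tm_table(structures, ids=None):
    """tm_max for all unordered pairs of a structure list.

    Returns a pandas DataFrame with columns ``id1, id2, tm_max`` — the
    training-label ("pairs.tsv") format.
    """
    import pandas as pd

    if ids is None:
        ids = [s.source or s.chain_id for s in structures]
    rows = []
    for i in range(len(structures)):
        for j in range(i + 1, len(structures)):
            si, sj = structures[i], structures[j]
            L = min(len(si), len(sj))
            corr = [(k, k) for k in range(L)]
            res = tm_score(si, sj, corr)
            rows.append({"id1": ids[i], "id2": ids[j], "tm_max": res.tm_max})
    return pd.DataFrame(rows)
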