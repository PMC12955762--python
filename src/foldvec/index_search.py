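"""Embedding store and cosine k-NN retrieval (exact and HNSW).

The store keeps L2-normalized vectors, so cosine similarity is a dot
product.  ``query_exact`` is the full-scan reference search — a total
order with ties broken by id — and the yardstick against which the
approximate backend's recall is measured.  The approximate backend is a
self-contained Hierarchical Navigable Small World (HNSW) graph:
multi-layer greedy search with an ef-bounded candidate frontier, the
standard trade of exactness for sub-linear query time.  Returned
similarities are always computed exactly; only the candidate set is
approximate.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class QueryResult:
    """Ordered retrieval hits for one query."""

    query_id: str
    hits: list  # (id, cosine similarity), similarity non-increasing


@dataclass
class EmbeddingStore:
    """Unique ids with L2-normalized embedding rows and raw norms."""

    ids: list
    matrix: np.ndarray          # (N, D), rows unit-norm
    norms: np.ndarray           # original vector norms
    granularity: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1] if self.matrix.size else 0


def build_store(embeddings, metadata: dict | None = None) -> EmbeddingStore:
    """Collect structure embeddings into a store.

    ``embeddings`` is an iterable of :class:`~foldvec.model.StructureEmbedding`
    (or ``(id, vector)`` pairs).  Duplicate ids and dimension mismatches
    raise immediately, naming the offender.
    """
    ids, rows, norms, gran = [], [], [], []
    seen = set()
    dim = None
    for item in embeddings:
        if hasattr(item, "vector"):
            sid, vec, g = item.id, item.vector, item.granularity
        else:
            sid, vec = item
            g = "chain"
        if sid in seen:
            raise ValueError(f"duplicate id {sid!r} in embedding stream")
        seen.add(sid)
        vec = np.asarray(vec, dtype=float).ravel()
        if dim is None:
            dim = vec.shape[0]
        elif vec.shape[0] != dim:
            raise ValueError(
                f"dimension mismatch for {sid!r}: {vec.shape[0]} != {dim}"
            )
        n = float(np.linalg.norm(vec))
        if n == 0.0:
            raise ValueError(f"zero-norm embedding for {sid!r}")
        ids.append(sid)
        rows.append(vec / n)
        norms.append(n)
        gran.append(g)
    matrix = np.asarray(rows) if rows else np.empty((0, 0))
    return EmbeddingStore(ids=ids, matrix=matrix,
                          norms=np.asarray(norms), granularity=gran,
                          metadata=dict(metadata or {}))


def save_store(store: EmbeddingStore, path: str) -> None:
    """Persist a store to one HDF5 file with an embedded JSON manifest."""
    import h5py

    manifest = {
        "dim": store.dim,
        "count": len(store),
        "granularity": store.granularity,
        **store.metadata,
    }
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=store.matrix)
        fh.create_dataset("norms", data=store.norms)
        fh.create_dataset("ids", data=np.array(store.ids, dtype="S"))
        fh.attrs["manifest"] = json.dumps(manifest)


def load_store(path: str) -> EmbeddingStore:
    import h5py

    with h5py.File(path, "r") as fh:
        manifest = json.loads(fh.attrs["manifest"])
        ids = [s.decode() for s in fh["ids"][()]]
        matrix = fh["matrix"][()]
        norms = fh["norms"][()]
    gran = manifest.pop("granularity", ["chain"] * len(ids))
    manifest.pop("dim", None)
    manifest.pop("count", None)
    return EmbeddingStore(ids=ids, matrix=matrix, norms=norms,
                          granularity=gran, metadata=manifest)


def _normalize_query(vector, dim: int) -> np.ndarray:
    q = np.asarray(vector, dtype=float).ravel()
    if q.shape[0] != dim:
        raise ValueError(f"query dimension {q.shape[0]} != store dimension {dim}")
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ValueError("zero-norm query vector")
    return q / n


def query_exact(store: EmbeddingStore, vector, k: int,
                query_id: str = "external") -> QueryResult:
    """Top-k by cosine similarity, full scan; ties broken by id.

    ``k`` larger than the store is clamped to the store size.
    """
    if len(store) == 0:
        raise ValueError("cannot query an empty store")
    if k < 1:
        raise ValueError("k must be >= 1")
    q = _normalize_query(vector, store.dim)
    sims = store.matrix @ q
    k = min(k, len(store))
    order = sorted(range(len(store)), key=lambda i: (-sims[i], store.ids[i]))[:k]
    return QueryResult(query_id=query_id,
                       hits=[(store.ids[i], float(sims[i])) for i in order])


# --------------------------------------------------------------------------
# HNSW
# --------------------------------------------------------------------------

class HNSWIndex:
    """Hierarchical Navigable Small World graph over a store's vectors.

    Distances are ``1 - cosine``; vectors are already unit-norm in the
    store.  ``M`` bounds per-node degree on the upper layers (2M on the
    base layer); ``ef_construction`` is the frontier width while
    building.  Construction is deterministic given the seed.
    """

    def __init__(self, store: EmbeddingStore, M: int = 16,
                 ef_construction: int = 200, seed: int = 0):
        if len(store) == 0:
            raise ValueError("cannot index an empty store")
        self.store = store
        self.M = int(M)
        self.ef_construction = int(ef_construction)
        self.seed = int(seed)
        self._mL = 1.0 / np.log(self.M)
        self._build()

    # ---- construction ----------------------------------------------------
    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        n = len(self.store)
        X = self.store.matrix
        levels = np.minimum(
            (-np.log(rng.uniform(1e-12, 1.0, size=n)) * self._mL).astype(int), 32
        )
        self.levels = levels
        max_level = int(levels.max())
        # graph[l][node] -> list of neighbour ints
        self.graph = [dict() for _ in range(max_level + 1)]
        self.entry = 0
        self.max_level = int(levels[0])
        for l in range(levels[0] + 1):
            self.graph[l][0] = []
        for i in range(1, n):
            self._insert(i, X)

    def _dist(self, X, i: int, q: np.ndarray) -> float:
        return 1.0 - float(X[i] @ q)

    def _dist_many(self, X, idx, q: np.ndarray):
        return 1.0 - X[np.asarray(idx, dtype=int)] @ q

    def _search_layer(self, X, q: np.ndarray, entry: int, ef: int, layer: int):
        """ef-bounded best-first search on one layer; returns (dist, node) list."""
        g = self.graph[layer]
        d0 = self._dist(X, entry, q)
        visited = {entry}
        candidates = [(d0, entry)]            # min-heap
        results = [(-d0, entry)]              # max-heap of current best ef
        while candidates:
            dc, c = heapq.heappop(candidates)
            if dc > -results[0][0]:
                break
            neigh = [u for u in g[c] if u not in visited]
            if not neigh:
                continue
            visited.update(neigh)
            dists = self._dist_many(X, neigh, q)
            worst = -results[0][0]
            for u, du in zip(neigh, dists):
                if len(results) < ef or du < worst:
                    heapq.heappush(candidates, (du, u))
                    heapq.heappush(results, (-du, u))
                    if len(results) > ef:
                        heapq.heappop(results)
                    worst = -results[0][0]
        return sorted((-d, u) for d, u in results)

    def _select_neighbours(self, X, q: np.ndarray, candidates, m: int):
        """Diversity-pruned neighbour selection (closest first, keep a
        candidate only if it is nearer to q than to every kept one)."""
        selected = []
        for d, u in candidates:
            if len(selected) >= m:
                break
            if not selected:
                selected.append((d, u))
                continue
            d_sel = self._dist_many(X, [v for _, v in selected], X[u])
            if d < d_sel.min():
                selected.append((d, u))
        # pad with the nearest skipped candidates
        if len(selected) < m:
            chosen = {u for _, u in selected}
            for d, u in candidates:
                if len(selected) >= m:
                    break
                if u not in chosen:
                    selected.append((d, u))
        return [u for _, u in selected]

    def _insert(self, i: int, X) -> None:
        level = int(self.levels[i])
        q = X[i]
        ep = self.entry
        # greedy descent through layers above the node's level
        for l in range(self.max_level, level, -1):
            ep = self._search_layer(X, q, ep, 1, l)[0][1]
        for l in range(min(level, self.max_level), -1, -1):
            found = self._search_layer(X, q, ep, self.ef_construction, l)
            m_max = self.M if l > 0 else 2 * self.M
            neighbours = self._select_neighbours(X, q, found, self.M)
            self.graph[l][i] = list(neighbours)
            for u in neighbours:
                lst = self.graph[l][u]
                lst.append(i)
                if len(lst) > m_max:
                    d = self._dist_many(X, lst, X[u])
                    cands = sorted(zip(d, lst))
                    self.graph[l][u] = self._select_neighbours(
                        X, X[u], cands, m_max)
            ep = found[0][1]
        if level > self.max_level:
            for l in range(self.max_level + 1, level + 1):
                self.graph[l][i] = []
            self.max_level = level
            self.entry = i

    # ---- queries ----------------------------------------------------------
    def search(self, vector, k: int, ef_search: int = 128) -> list:
        """Approximate top-k (node index, similarity) for a query vector."""
        X = self.store.matrix
        q = _normalize_query(vector, self.store.dim)
        ep = self.entry
        for l in range(self.max_level, 0, -1):
            ep = self._search_layer(X, q, ep, 1, l)[0][1]
        found = self._search_layer(X, q, ep, max(ef_search, k), 0)
        out = [(u, 1.0 - d) for d, u in found[:k]]
        out.sort(key=lambda t: (-t[1], self.store.ids[t[0]]))
        return out

    # ---- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        """Persist the graph (CSR per layer) alongside index parameters."""
        arrays = {"levels": self.levels,
                  "params": np.array([self.M, self.ef_construction, self.seed,
                                      self.entry, self.max_level])}
        for l, g in enumerate(self.graph):
            nodes = np.array(sorted(g), dtype=np.int64)
            indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
            indices = []
            for j, u in enumerate(nodes):
                indices.extend(g[u])
                indptr[j + 1] = len(indices)
            arrays[f"layer{l}.nodes"] = nodes
            arrays[f"layer{l}.indptr"] = indptr
            arrays[f"layer{l}.indices"] = np.array(indices, dtype=np.int64)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str, store: EmbeddingStore) -> "HNSWIndex":
        idx = cls.__new__(cls)
        idx.store = store
        with np.load(path) as data:
            M, efc, seed, entry, max_level = data["params"]
            idx.M, idx.ef_construction, idx.seed = int(M), int(efc), int(seed)
            idx.entry, idx.max_level = int(entry), int(max_level)
            idx._mL = 1.0 / np.log(idx.M)
            idx.levels = data["levels"]
            idx.graph = []
            l = 0
            while f"layer{l}.nodes" in data:
                nodes = data[f"layer{l}.nodes"]
                indptr = data[f"layer{l}.indptr"]
                indices = data[f"layer{l}.indices"]
                idx.graph.append({
                    int(u): [int(v) for v in indices[indptr[j]:indptr[j + 1]]]
                    for j, u in enumerate(nodes)
                })
                l += 1
        return idx


def build_ann_index(store: EmbeddingStore, backend: str = "hnsw",
                    M: int = 16, ef_construction: int = 200,
                    seed: int = 0) -> HNSWIndex:
    """Build the approximate cosine index over a store."""
    if backend != "hnsw":
        raise ValueError(f"unsupported ANN backend {backend!r}; only 'hnsw'")
    return HNSWIndex(store, M=M, ef_construction=ef_construction, seed=seed)


def query_ann(index: HNSWIndex, vector, k: int, ef_search: int = 128,
              query_id: str = "external") -> QueryResult:
    """Approximate top-k; similarities of returned ids are exact."""
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(index.store))
    hits = index.search(vector, k, ef_search=ef_search)
    return QueryResult(query_id=query_id,
                       hits=[(index.store.ids[u], float(s)) for u, s in hits])


def recall_at_k(index: HNSWIndex, queries, k: int = 10,
                ef_search: int = 128) -> float:
    """Mean overlap between approximate and exact top-k over query vectors."""
    total = 0.0
    queries = list(queries)
    for q in queries:
        exact = {i for i, _ in query_exact(index.store, q, k).hits}
        approx = {i for i, _ in query_ann(index, q, k, ef_search).hits}
        total += len(exact & approx) / len(exact)
    return total / len(queries)
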