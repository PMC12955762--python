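"""Benchmark statistics for structure-similarity search.

Implements the retrieval metrics used throughout the benchmarks:

* three pair-labelling schemes — hierarchical classification (family /
  superfamily / fold), TM-score thresholds (TP at 0.6/0.7/0.8, FP below
  0.5, the gap ignored), and topology-combination matching for
  multidomain proteins (TP = identical topology multisets, FP = disjoint
  architecture sets);
* per-query *sensitivity to the first false positive*: the fraction (and
  count) of true positives ranked above the highest-ranked false
  positive, with ignore pairs removed from consideration but not
  blocking;
* pooled precision-recall curves with step-summed area (AUPRC);
* redundancy-aware split construction: k-fold cross-validation by family
  and random superfamily holdout.

Scores are ranked descending; ties are broken by target id so that
tie-sensitive statistics are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TP, FP, IGNORE = "TP", "FP", "ignore"


@dataclass(frozen=True)
class LabelingScheme:
    """How query-target pairs are labelled TP / FP / ignore.

    kind ``classification`` uses the fold/superfamily/family hierarchy at
    the given ``level``; ``tm_threshold`` uses ``tp_threshold`` (>= is TP)
    and ``fp_threshold`` (< is FP); ``topology_combination`` compares
    per-structure topology multisets and architecture sets.
    """

    kind: str = "classification"
    level: str = "family"
    tp_threshold: float = 0.8
    fp_threshold: float = 0.5

    def __post_init__(self):
        if self.kind not in ("classification", "tm_threshold",
                             "topology_combination"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "classification" and self.level not in (
                "family", "superfamily", "fold"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.kind == "tm_threshold" and not self.tp_threshold > self.fp_threshold:
            raise ValueError("tp_threshold must exceed fp_threshold")


@dataclass
class BenchmarkReport:
    """Aggregate benchmark result for one method under one scheme."""

    per_query_fraction: dict
    per_query_count: dict
    perfect_fraction: float
    pr_precision: np.ndarray
    pr_recall: np.ndarray
    auprc: float
    scheme: LabelingScheme
    method: str = ""
    n_queries_skipped: int = 0


def _topology_fields(s: str):
    return tuple(t.strip() for t in str(s).split(",") if t.strip())


def _architectures(topologies) -> set:
    # topology "c.a.t" -> architecture "c.a" (one classification level up)
    return {".".join(t.split(".")[:2]) for t in topologies}


def label_pair(meta1: dict, meta2: dict, scheme: LabelingScheme,
               tm_max: float | None = None) -> str:
    """Label one (non-self) pair under a scheme."""
    if scheme.kind == "tm_threshold":
        if tm_max is None:
            raise ValueError("tm_threshold labelling needs the pair tm_max")
        if tm_max >= scheme.tp_threshold:
            return TP
        if tm_max < scheme.fp_threshold:
            return FP
        return IGNORE
    if scheme.kind == "classification":
        same_fam = meta1["family"] == meta2["family"]
        same_sf = meta1["superfamily"] == meta2["superfamily"]
        same_fold = meta1["fold"] == meta2["fold"]
        if not same_fold:
            return FP
        if scheme.level == "family":
            return TP if same_fam else IGNORE
        if scheme.level == "superfamily":
            return TP if (same_sf and not same_fam) else IGNORE
        return TP if (same_fold and not same_sf) else IGNORE
    # topology_combination
    t1 = sorted(_topology_fields(meta1.get("topologies", "")))
    t2 = sorted(_topology_fields(meta2.get("topologies", "")))
    if not t1 or not t2:
        raise ValueError("topology labelling needs non-empty topology lists")
    if t1 == t2:
        return TP
    if _architectures(t1).isdisjoint(_architectures(t2)):
        return FP
    return IGNORE


def label_pairs(metadata: pd.DataFrame, scheme: LabelingScheme,
                pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Label all unordered non-self pairs.

    ``metadata`` is indexed by structure id with columns ``fold``,
    ``superfamily``, ``family`` (and ``topologies`` for the topology
    scheme).  For the TM-threshold scheme, ``pairs`` must provide
    ``id1, id2, tm_max`` rows; ids referenced there but missing from the
    metadata raise an error naming them.

    Returns a DataFrame with columns ``id1, id2, label``.
    """
    if scheme.kind == "tm_threshold":
        if pairs is None:
            raise ValueError("tm_threshold labelling needs a pairs table")
        missing = (set(pairs["id1"]) | set(pairs["id2"])) - set(metadata.index)
        if missing:
            raise ValueError(f"ids missing from metadata: {sorted(missing)[:10]}")
        out = pairs[["id1", "id2"]].copy()
        out["label"] = [
            label_pair({}, {}, scheme, tm_max=tm) for tm in pairs["tm_max"]
        ]
        return out
    ids = list(metadata.index)
    meta = {i: metadata.loc[i].to_dict() for i in ids}
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            rows.append({
                "id1": ids[a], "id2": ids[b],
                "label": label_pair(meta[ids[a]], meta[ids[b]], scheme),
            })
    return pd.DataFrame(rows)


def sensitivity_to_first_fp(labels_in_rank_order) -> tuple:
    """Per-query sensitivity: TPs retrieved before the first FP.

    ``labels_in_rank_order`` holds TP/FP/ignore labels of one query's
    targets, best score first.  Ignore entries neither count nor block.
    Returns ``(fraction, count)``; fraction is 1.0 when no FP exists and
    None when the query has no TPs at all (such queries are skipped).
    """
    labels = [l for l in labels_in_rank_order if l != IGNORE]
    total_tp = sum(1 for l in labels if l == TP)
    if total_tp == 0:
        return None, 0
    count = 0
    for l in labels:
        if l == FP:
            break
        count += 1
    return count / total_tp, count


def pr_curve(scores, labels) -> tuple:
    """Pooled precision-recall curve and step-summed AUPRC.

    ``labels`` are TP/FP strings or booleans; ignore pairs must be
    excluded beforehand.  Pairs are pooled and sorted by descending
    score; tied scores share one threshold.  The area is
    ``sum_i (R_i - R_{i-1}) * P_i`` over the distinct thresholds.

    Returns ``(precision array, recall array, auprc)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([l == TP if isinstance(l, str) else bool(l) for l in labels])
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = int(y.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("PR curve needs at least one TP and one FP")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], y[order]
    # indices where a threshold ends (last element of each tie group)
    distinct = np.where(np.diff(s_sorted))[0]
    cut = np.r_[distinct, s_sorted.shape[0] - 1]
    tp_cum = np.cumsum(y_sorted)[cut]
    n_cum = cut + 1
    precision = tp_cum / n_cum
    recall = tp_cum / n_pos
    auprc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return precision, recall, auprc


def auprc_score(scores, positives) -> float:
    """Convenience wrapper: AUPRC of boolean positives under scores."""
    return pr_curve(scores, positives)[2]


def sensitivity_distribution(fractions) -> tuple:
    """Sorted (best-to-worst) sensitivity curve and perfect-sensitivity share."""
    fr = np.asarray([f for f in fractions if f is not None], dtype=float)
    if fr.size == 0:
        raise ValueError("no queries with defined sensitivity")
    curve = np.sort(fr)[::-1]
    return curve, float(np.mean(curve == 1.0))


def build_family_cv_splits(metadata: pd.DataFrame, k: int = 10, seed: int = 0):
    """Partition families into k groups; each test fold holds all
    structures of its families (redundancy-aware cross-validation).

    Returns a list of ``(train_ids, test_ids)`` tuples.
    """
    families = sorted(metadata["family"].unique())
    if k > len(families):
        raise ValueError(f"k={k} exceeds the {len(families)} families")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(families))
    groups = [order[i::k] for i in range(k)]
    splits = []
    for g in groups:
        gset = set(g)
        test = [i for i in metadata.index if metadata.loc[i, "family"] in gset]
        train = [i for i in metadata.index if metadata.loc[i, "family"] not in gset]
        splits.append((train, test))
    return splits


def holdout_superfamilies(metadata: pd.DataFrame, fraction: float = 0.05,
                          seed: int = 0):
    """Withhold ceil(fraction * S) superfamilies entirely from training."""
    sfs = sorted(metadata["superfamily"].unique())
    n_hold = int(np.ceil(fraction * len(sfs)))
    rng = np.random.default_rng(seed)
    held = set(rng.choice(sfs, size=n_hold, replace=False))
    test = [i for i in metadata.index if metadata.loc[i, "superfamily"] in held]
    train = [i for i in metadata.index if metadata.loc[i, "superfamily"] not in held]
    return train, test


@dataclass
class _RankedList:
    query: str
    targets: list
    scores: np.ndarray


def _ranked_lists(ids, score_of):
    """Per-query descending ranked lists, self excluded, ties by target id."""
    lists = {}
    for q in ids:
        targets = [t for t in ids if t != q]
        sc = np.array([score_of(q, t) for t in targets])
        order = sorted(range(len(targets)), key=lambda i: (-sc[i], targets[i]))
        lists[q] = _RankedList(query=q, targets=[targets[i] for i in order],
                               scores=sc[[*order]])
    return lists


def run_benchmark(score_of, labeled_pairs: pd.DataFrame,
                  scheme: LabelingScheme, method: str = "") -> BenchmarkReport:
    """All-versus-all benchmark of one scoring function.

    ``score_of(id1, id2)`` returns the predicted similarity (symmetric);
    ``labeled_pairs`` holds TP/FP/ignore labels for every unordered
    non-self pair.  Sensitivity to the first FP is computed per query on
    descending ranked lists; the precision-recall curve pools all
    labelled (non-ignored) unordered pairs.
    """
    label = {}
    for row in labeled_pairs.itertuples(index=False):
        label[(row.id1, row.id2)] = row.label
        label[(row.id2, row.id1)] = row.label
    ids = sorted({i for pair in label for i in pair})

    lists = _ranked_lists(ids, score_of)
    per_fraction, per_count, skipped = {}, {}, 0
    for q, rl in lists.items():
        frac, count = sensitivity_to_first_fp(
            [label[(q, t)] for t in rl.targets]
        )
        if frac is None:
            skipped += 1
            continue
        per_fraction[q] = frac
        per_count[q] = count
    if not per_fraction:
        raise ValueError("no query has any true positive under this scheme")
    _, perfect = sensitivity_distribution(per_fraction.values())

    mask = labeled_pairs["label"] != IGNORE
    pool = labeled_pairs[mask]
    scores = np.array([score_of(r.id1, r.id2)
                       for r in pool.itertuples(index=False)])
    precision, recall, auprc = pr_curve(scores, list(pool["label"]))

    return BenchmarkReport(
        per_query_fraction=per_fraction,
        per_query_count=per_count,
        perfect_fraction=perfect,
        pr_precision=precision,
        pr_recall=recall,
        auprc=auprc,
        scheme=scheme,
        method=method,
        n_queries_skipped=skipped,
    )
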