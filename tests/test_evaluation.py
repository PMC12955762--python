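"""Benchmark statistics: labelling schemes, sensitivity, PR curves, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from foldvec.evaluation import (FP, IGNORE, TP, LabelingScheme,
                                build_family_cv_splits, holdout_superfamilies,
                                label_pair, label_pairs, pr_curve,
                                run_benchmark, sensitivity_distribution,
                                sensitivity_to_first_fp)


META = pd.DataFrame({
    "id": ["a1", "a2", "b1", "c1"],
    "fold": ["f1", "f1", "f1", "f2"],
    "superfamily": ["f1.s1", "f1.s1", "f1.s2", "f2.s1"],
    "family": ["f1.s1.x", "f1.s1.y", "f1.s2.z", "f2.s1.w"],
}).set_index("id")


# --------------------------------------------------------------------------
# labelling
# --------------------------------------------------------------------------

def test_family_level_labels():
    scheme = LabelingScheme("classification", "family")
    same_fam = label_pair({"family": "x", "superfamily": "s", "fold": "f"},
                          {"family": "x", "superfamily": "s", "fold": "f"}, scheme)
    assert same_fam == TP
    # same superfamily, different family: neither TP nor FP at family level
    mid = label_pair({"family": "x", "superfamily": "s", "fold": "f"},
                     {"family": "y", "superfamily": "s", "fold": "f"}, scheme)
    assert mid == IGNORE
    diff = label_pair({"family": "x", "superfamily": "s", "fold": "f"},
                      {"family": "w", "superfamily": "t", "fold": "g"}, scheme)
    assert diff == FP


def test_superfamily_and_fold_levels():
    m1 = {"family": "x", "superfamily": "s", "fold": "f"}
    m2 = {"family": "y", "superfamily": "s", "fold": "f"}
    m3 = {"family": "z", "superfamily": "t", "fold": "f"}
    sf = LabelingScheme("classification", "superfamily")
    fl = LabelingScheme("classification", "fold")
    assert label_pair(m1, m2, sf) == TP
    assert label_pair(m1, m1, sf) == IGNORE      # same family
    assert label_pair(m1, m3, fl) == TP
    assert label_pair(m1, m2, fl) == IGNORE      # same superfamily


def test_tm_threshold_gap_is_ignored():
    scheme = LabelingScheme("tm_threshold", tp_threshold=0.6)
    assert label_pair({}, {}, scheme, tm_max=0.55) == IGNORE
    assert label_pair({}, {}, scheme, tm_max=0.65) == TP
    assert label_pair({}, {}, scheme, tm_max=0.45) == FP


def test_topology_combination_labels():
    scheme = LabelingScheme("topology_combination")
    a = {"topologies": "1.10.8,2.40.50"}
    same = {"topologies": "2.40.50,1.10.8"}     # same multiset, any order
    disjoint = {"topologies": "3.30.70"}
    overlap = {"topologies": "1.10.9"}          # shares architecture 1.10
    assert label_pair(a, same, scheme) == TP
    assert label_pair(a, disjoint, scheme) == FP
    assert label_pair(a, overlap, scheme) == IGNORE


def test_label_pairs_trichotomy():
    for scheme in (LabelingScheme("classification", lvl)
                   for lvl in ("family", "superfamily", "fold")):
        out = label_pairs(META, scheme)
        assert len(out) == 6                     # all unordered non-self pairs
        assert set(out["label"]) <= {TP, FP, IGNORE}


def test_missing_ids_reported():
    pairs = pd.DataFrame({"id1": ["a1"], "id2": ["nope"], "tm_max": [0.9]})
    with pytest.raises(ValueError, match="nope"):
        label_pairs(META, LabelingScheme("tm_threshold", tp_threshold=0.8),
                    pairs=pairs)


# --------------------------------------------------------------------------
# sensitivity to the first FP
# --------------------------------------------------------------------------

@pytest.mark.parametrize("labels,frac,count", [
    ([TP, TP, FP, TP], 2 / 3, 2),
    ([TP, TP, TP], 1.0, 3),
    ([FP, TP, TP], 0.0, 0),
    ([TP, IGNORE, FP, TP], 1 / 2, 1),   # ignores neither count nor block
    ([IGNORE, TP, TP], 1.0, 2),
])
def test_sensitivity_examples(labels, frac, count):
    f, c = sensitivity_to_first_fp(labels)
    assert f == pytest.approx(frac)
    assert c == count


def test_query_without_tps_is_skipped():
    f, c = sensitivity_to_first_fp([FP, IGNORE, FP])
    assert f is None and c == 0


def test_sensitivity_distribution_perfect_share():
    curve, share = sensitivity_distribution([1.0, 1.0, 0.5, 0.0])
    assert share == pytest.approx(0.5)
    assert all(b <= a for a, b in zip(curve, curve[1:]))
    _, zero = sensitivity_distribution([0.0, 0.0])
    assert zero == 0.0


# --------------------------------------------------------------------------
# precision-recall
# --------------------------------------------------------------------------

def test_perfect_separation_auprc_one():
    _, _, auprc = pr_curve([0.9, 0.8, 0.2, 0.1], [TP, TP, FP, FP])
    assert auprc == pytest.approx(1.0)


def test_hand_enumerated_auprc():
    """[TP, TP, FP, TP] at descending scores -> AUPRC 11/12."""
    _, _, auprc = pr_curve([0.9, 0.8, 0.7, 0.6], [TP, TP, FP, TP])
    assert auprc == pytest.approx(11 / 12)


def test_tied_scores_share_threshold():
    p, r, auprc = pr_curve([0.5, 0.5, 0.5], [TP, FP, TP])
    assert len(p) == 1
    assert p[0] == pytest.approx(2 / 3)
    assert auprc == pytest.approx(2 / 3)


def test_degenerate_labels_rejected():
    with pytest.raises(ValueError):
        pr_curve([0.5, 0.4], [TP, TP])


def test_random_labels_auprc_near_prevalence():
    """Permuted labels give mean AUPRC ~= prevalence (resampling check).

    Mean average precision under a random ranking sits slightly above the
    prevalence pi, by roughly (1 - pi)/n_pos; with 200 positives that
    offset is negligible next to the tolerance used here.
    """
    rng = np.random.default_rng(0)
    n_pos, n_neg = 200, 400
    scores = rng.uniform(size=n_pos + n_neg)
    base = np.array([True] * n_pos + [False] * n_neg)
    aucs = []
    for _ in range(200):
        y = rng.permutation(base)
        aucs.append(pr_curve(scores, y)[2])
    prevalence = n_pos / (n_pos + n_neg)
    se = np.std(aucs) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - prevalence) < (1 - prevalence) / n_pos + 3 * se


@given(st.integers(0, 500))
def test_step_sum_matches_sklearn_average_precision(seed):
    """The step-summed area equals scikit-learn's average precision."""
    from sklearn.metrics import average_precision_score

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    scores = rng.choice(np.linspace(0, 1, 7), size=n)   # force ties
    y = rng.integers(0, 2, size=n).astype(bool)
    if y.all() or not y.any():
        y[0] = ~y[0]
    _, _, auprc = pr_curve(scores, y)
    assert auprc == pytest.approx(average_precision_score(y, scores), abs=1e-12)


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------

def _big_meta(n_folds=4, sf_per_fold=2, fam_per_sf=2, members=3):
    rows = []
    for f in range(n_folds):
        for s in range(sf_per_fold):
            for a in range(fam_per_sf):
                for m in range(members):
                    rows.append({
                        "id": f"f{f}s{s}a{a}m{m}", "fold": f"f{f}",
                        "superfamily": f"f{f}.s{s}",
                        "family": f"f{f}.s{s}.a{a}",
                    })
    return pd.DataFrame(rows).set_index("id")


def test_family_cv_even_partition():
    meta = _big_meta()          # 16 families
    splits = build_family_cv_splits(meta, k=4, seed=0)
    fams_per_fold = [len({meta.loc[i, "family"] for i in test})
                     for _, test in splits]
    assert fams_per_fold == [4, 4, 4, 4]


def test_family_cv_disjoint_and_complete():
    meta = _big_meta()
    splits = build_family_cv_splits(meta, k=4, seed=1)
    seen = set()
    for train, test in splits:
        test_fams = {meta.loc[i, "family"] for i in test}
        train_fams = {meta.loc[i, "family"] for i in train}
        assert test_fams.isdisjoint(train_fams)
        assert seen.isdisjoint(test_fams)
        seen |= test_fams
    assert seen == set(meta["family"].unique())


def test_family_cv_deterministic():
    meta = _big_meta()
    assert build_family_cv_splits(meta, 4, seed=5) == \
        build_family_cv_splits(meta, 4, seed=5)


def test_family_cv_k_too_large():
    with pytest.raises(ValueError):
        build_family_cv_splits(_big_meta(), k=100, seed=0)


def test_superfamily_holdout_ceiling_rule():
    meta = _big_meta(n_folds=20, sf_per_fold=2, fam_per_sf=1, members=1)  # 40 sf
    train, test = holdout_superfamilies(meta, fraction=0.05, seed=0)
    held = {meta.loc[i, "superfamily"] for i in test}
    assert len(held) == 2
    assert held.isdisjoint({meta.loc[i, "superfamily"] for i in train})
    assert holdout_superfamilies(meta, 0.05, seed=3) == \
        holdout_superfamilies(meta, 0.05, seed=3)


# --------------------------------------------------------------------------
# run_benchmark
# --------------------------------------------------------------------------

def test_oracle_scoring_itself_is_perfect(mini_pairs):
    """Scoring pairs by the ground-truth TM under a TM-threshold scheme
    yields AUPRC 1.0 and perfect sensitivity for every query."""
    scheme = LabelingScheme("tm_threshold", tp_threshold=0.8)
    tm = {}
    for r in mini_pairs.itertuples(index=False):
        tm[(r.id1, r.id2)] = tm[(r.id2, r.id1)] = r.tm_max
    meta = pd.DataFrame({"id": sorted({i for p in tm for i in p}),
                         "fold": "", "superfamily": "", "family": ""}
                        ).set_index("id")
    labelled = label_pairs(meta, scheme, pairs=mini_pairs)
    rep = run_benchmark(lambda a, b: tm[(a, b)], labelled, scheme,
                        method="oracle")
    assert rep.auprc == pytest.approx(1.0)
    assert rep.perfect_fraction == pytest.approx(1.0)


def test_constant_scorer_degenerates_to_prevalence():
    scheme = LabelingScheme("tm_threshold", tp_threshold=0.8)
    pairs = pd.DataFrame({
        "id1": ["a", "a", "a", "b", "b", "c"],
        "id2": ["b", "c", "d", "c", "d", "d"],
        "tm_max": [0.9, 0.3, 0.9, 0.3, 0.3, 0.3],
    })
    meta = pd.DataFrame({"id": list("abcd"), "fold": "", "superfamily": "",
                         "family": ""}).set_index("id")
    labelled = label_pairs(meta, scheme, pairs=pairs)
    rep = run_benchmark(lambda a, b: 0.5, labelled, scheme)
    prevalence = 2 / 6
    assert rep.auprc == pytest.approx(prevalence)
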