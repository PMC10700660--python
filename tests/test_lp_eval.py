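"""Splitting, exhaustive ranking oracle, metric algebra, target prediction."""

import numpy as np
import pytest

from oreganokg.kge import TrainConfig, make_model, train
from oreganokg.lp_eval import (
    EvalReport,
    IndexedGraph,
    KnownIndex,
    evaluate,
    metrics_from_ranks,
    predict_top_targets,
    rank_triple,
    report_table,
    split_graph,
    write_report_tsv,
)
from oreganokg.schema import KnowledgeGraph, Triple


def random_graph(n_e=20, n_r=3, n=60, seed=0):
    rng = np.random.default_rng(seed)
    seen = set()
    while len(seen) < n:
        h = int(rng.integers(n_e))
        t = int(rng.integers(n_e))
        if h != t:
            seen.add((h, int(rng.integers(n_r)), t))
    return np.array(sorted(seen), dtype=np.int64)


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------


def test_split_partition_and_sizes():
    triples = random_graph(n=100, n_e=30)
    (train_t, test_t), = split_graph(triples, k=1, test_fraction=0.1, seed=4)
    assert test_t.shape[0] == 10 and train_t.shape[0] == 90
    all_rows = {tuple(r) for r in triples}
    assert {tuple(r) for r in train_t} | {tuple(r) for r in test_t} == all_rows
    assert not ({tuple(r) for r in train_t} & {tuple(r) for r in test_t})


def test_split_covers_test_entities_in_train():
    triples = random_graph(n=80, n_e=25, seed=2)
    for train_t, test_t in split_graph(triples, k=5, test_fraction=0.15, seed=1):
        ents = set(train_t[:, 0]) | set(train_t[:, 2])
        rels = set(train_t[:, 1])
        for h, r, t in test_t:
            assert h in ents and t in ents and r in rels


def test_split_determinism_and_independence():
    triples = random_graph()
    s1 = split_graph(triples, k=3, seed=7)
    s2 = split_graph(triples, k=3, seed=7)
    for (a1, b1), (a2, b2) in zip(s1, s2):
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
    # different splits are (almost surely) different resamples
    assert not np.array_equal(s1[0][1], s1[1][1])


def test_split_singleton_entities_stay_in_train():
    # a star graph: entity 0 is in every triple; leaves are singletons
    triples = np.array([(0, 0, i) for i in range(1, 8)], dtype=np.int64)
    (train_t, test_t), = split_graph(triples, k=1, test_fraction=0.4, seed=0)
    ents = set(train_t[:, 0]) | set(train_t[:, 2])
    for h, r, t in test_t:
        assert h in ents and t in ents


# --------------------------------------------------------------------------
# ranking vs exhaustive oracle
# --------------------------------------------------------------------------


def brute_force_ranks(model, triple, known_set, mode, tie="optimistic"):
    """Independent all-candidate loop using only model.score on singletons."""
    h, r, t = triple
    n = model.n_entities

    def score1(a, b, c):
        return float(model.score(np.array([a]), np.array([b]), np.array([c]))[0])

    s_true_t = score1(h, r, t)
    tail_rank = 1
    for cand in range(n):
        if cand == t:
            continue
        if mode == "filtered" and (h, r, cand) in known_set:
            continue
        s = score1(h, r, cand)
        if s > s_true_t or (tie == "pessimistic" and s == s_true_t):
            tail_rank += 1
    s_true_h = score1(h, r, t)
    head_rank = 1
    for cand in range(n):
        if cand == h:
            continue
        if mode == "filtered" and (cand, r, t) in known_set:
            continue
        s = score1(cand, r, t)
        if s > s_true_h or (tie == "pessimistic" and s == s_true_h):
            head_rank += 1
    return head_rank, tail_rank


@pytest.mark.parametrize("mode", ["raw", "filtered"])
@pytest.mark.parametrize("tie", ["optimistic", "pessimistic"])
def test_rank_matches_exhaustive_oracle(mode, tie):
    triples = random_graph(n_e=20, n_r=3, n=60, seed=3)
    model = make_model("distmult", 20, 3, TrainConfig(dim=4, seed=8))
    # force score ties: several entities share one embedding row
    model.params["E"][5] = model.params["E"][6] = model.params["E"][7]
    known = KnownIndex(triples)
    known_set = {tuple(row) for row in triples}
    for row in triples[:25]:
        expected = brute_force_ranks(model, tuple(row), known_set, mode, tie)
        got = rank_triple(model, tuple(row), known, mode=mode, tie_policy=tie)
        assert got == expected


def test_filtered_rank_never_worse_than_raw():
    triples = random_graph(seed=5)
    model = make_model("transe", 20, 3, TrainConfig(dim=4, seed=1))
    known = KnownIndex(triples)
    for row in triples:
        hr_f, tr_f = rank_triple(model, tuple(row), known, mode="filtered")
        hr_r, tr_r = rank_triple(model, tuple(row), known, mode="raw")
        assert hr_f <= hr_r and tr_f <= tr_r


# --------------------------------------------------------------------------
# metric algebra
# --------------------------------------------------------------------------


def test_metrics_hand_computation():
    m = metrics_from_ranks([1, 2, 4])
    assert m["mrr"] == pytest.approx(7 / 12)
    assert m["hits@1"] == pytest.approx(1 / 3)
    assert m["hits@10"] == 1.0
    perfect = metrics_from_ranks([1, 1, 1])
    assert perfect == {"mrr": 1.0, "hits@1": 1.0, "hits@10": 1.0}


def test_report_invariants_and_average():
    per_split = [
        {"mrr": 0.5, "hits@1": 0.2, "hits@10": 0.8},
        {"mrr": 0.7, "hits@1": 0.4, "hits@10": 0.9},
    ]
    rep = EvalReport("distmult", 2, "filtered", "optimistic", per_split, [0, 1])
    assert rep.mrr == pytest.approx(0.6)
    assert rep.hits1 == pytest.approx(0.3)
    assert rep.hits10 == pytest.approx(0.85)
    assert rep.hits1 <= rep.hits10 and rep.mrr >= rep.hits1


def test_evaluate_protocol_shape_and_serialization(tmp_path):
    g = KnowledgeGraph.from_triples(
        [Triple(f"COMPOUND:{i}", "has_target", f"TARGET:{(i * 3) % 7}") for i in range(40)]
        + [Triple(f"COMPOUND:{i}", "has_indication", f"INDICATION:{i % 5}") for i in range(40)]
    )
    ig = IndexedGraph.from_graph(g)
    cfg = TrainConfig(dim=8, epochs=2, seed=0)
    rep = evaluate("distmult", ig, cfg, k=5, test_fraction=0.1, seed=3)
    assert rep.k == 5 and len(rep.per_split) == 5 and len(rep.split_seeds) == 5
    avg = rep.averaged()
    assert avg["mrr"] == pytest.approx(np.mean([s["mrr"] for s in rep.per_split]))
    path = tmp_path / "report.tsv"
    write_report_tsv([rep], path)
    lines = path.read_text().splitlines()
    assert len([l for l in lines if "\tsplit_" in l]) == 5 * 3
    assert len([l for l in lines if "\taverage\t" in l]) == 3
    table = report_table([rep])
    assert list(table.index) == ["MRR", "Hit@1", "Hit@10"]
    assert list(table.columns) == ["distmult"]


def test_evaluate_pools_reciprocal_ranks_exactly():
    """MRR/Hit@N equal an independent recomputation from the raw rank list."""
    g = KnowledgeGraph.from_triples(
        [Triple(f"COMPOUND:{i % 25}", "has_target", f"TARGET:{(i * 2) % 9}") for i in range(50)]
    )
    ig = IndexedGraph.from_graph(g)
    cfg = TrainConfig(dim=6, epochs=1, seed=1)
    splits = split_graph(ig.triples, k=1, test_fraction=0.2, seed=9)
    model = train(splits[0][0], len(ig.entities), len(ig.relations), "distmult",
                  TrainConfig(**{**cfg.__dict__, "seed": cfg.seed}))
    known = KnownIndex(ig.triples)
    ranks = []
    for row in splits[0][1]:
        hr, tr = rank_triple(model, tuple(row), known)
        ranks += [hr, tr]
    rep = evaluate("distmult", ig, cfg, k=1, test_fraction=0.2, seed=9)
    assert rep.per_split[0]["mrr"] == pytest.approx(float(np.mean([1 / r for r in ranks])))
    assert rep.per_split[0]["hits@10"] == pytest.approx(
        sum(r <= 10 for r in ranks) / len(ranks)
    )


# --------------------------------------------------------------------------
# target prediction
# --------------------------------------------------------------------------


def _prediction_setup():
    triples = [Triple(f"COMPOUND:{i}", "has_target", f"TARGET:{i % 4}") for i in range(12)]
    triples.append(Triple("COMPOUND:0", "is_substance_that_treats", "DISEASE:0"))
    g = KnowledgeGraph.from_triples(triples)
    ig = IndexedGraph.from_graph(g)
    model = make_model("distmult", len(ig.entities), len(ig.relations), TrainConfig(dim=4, seed=2))
    return ig, model, KnownIndex(ig.triples)


def test_predict_top_targets_contract():
    ig, model, known = _prediction_setup()
    out = predict_top_targets(model, ig, "COMPOUND:0", k=10, known=known)
    names = [n for n, _ in out]
    scores = [s for _, s in out]
    assert all(n.startswith("TARGET:") for n in names)
    assert "TARGET:0" not in names  # known true target excluded
    assert scores == sorted(scores, reverse=True)
    assert len(out) <= 10


def test_predict_single_unknown_candidate():
    ig, model, known = _prediction_setup()
    out = predict_top_targets(model, ig, "COMPOUND:1", k=10, known=known)
    assert len(out) == 3  # 4 targets minus the known one


def test_predict_unknown_compound_raises():
    ig, model, known = _prediction_setup()
    with pytest.raises(KeyError):
        predict_top_targets(model, ig, "COMPOUND:999", known=known)


def test_predict_all_entities_flag():
    ig, model, known = _prediction_setup()
    out = predict_top_targets(model, ig, "COMPOUND:0", k=50, known=known, all_entities=True)
    assert any(not n.startswith("TARGET:") for n, _ in out)


# --------------------------------------------------------------------------
# random-model baseline
# --------------------------------------------------------------------------


def test_untrained_model_hits_at_ten_matches_random_expectation():
    """A frozen random model ranks uniformly: pooled Hit@10 stays within 3
    binomial sigma of 10/|E| (raw mode), catching direction bugs."""
    triples = random_graph(n_e=60, n_r=2, n=400, seed=11)
    ig_ents = 60

    def factory(train_triples, seed):
        return make_model("complex", ig_ents, 2, TrainConfig(dim=8, seed=seed))

    from oreganokg.lp_eval import IndexedGraph as IG

    ig = IG([f"COMPOUND:{i}" for i in range(ig_ents)], ["r0", "r1"], triples)
    cfg = TrainConfig(dim=8, epochs=0, seed=13)
    rep = evaluate("complex", ig, cfg, k=5, test_fraction=0.2, seed=13,
                   mode="raw", model_factory=factory)
    p = 10 / ig_ents
    n_obs = 2 * 5 * 80  # both directions, 5 splits, 80 test triples each
    sigma = np.sqrt(p * (1 - p) / n_obs)
    assert abs(rep.hits10 - p) <= 3 * sigma
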