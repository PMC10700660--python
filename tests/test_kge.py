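"""Scoring functions, reductions between families, gradients, sampling and
the training loop."""

import numpy as np
import pytest
import scipy.stats

from oreganokg.kge import (
    FAMILIES,
    ComplEx,
    DistMult,
    RotatE,
    TransE,
    TransH,
    TrainConfig,
    load_model,
    make_model,
    negative_sample,
    save_model,
    train,
)

A = np.array


def _model(family, n_e=7, n_r=3, dim=4, seed=0, norm=1):
    return make_model(family, n_e, n_r, TrainConfig(dim=dim, seed=seed, norm=norm))


def test_distmult_hand_example():
    m = _model("distmult", n_e=2, n_r=1, dim=2)
    m.params["E"][0] = (1.0, 2.0)
    m.params["E"][1] = (3.0, 1.0)
    m.params["R"][0] = (1.0, 0.0)
    assert m.score(A([0]), A([0]), A([1]))[0] == pytest.approx(3.0)  # 1*1*3 + 2*0*1


def test_complex_reduces_to_distmult_on_reals():
    rng = np.random.default_rng(0)
    cm = _model("complex", dim=6)
    dm = _model("distmult", dim=6)
    dm.params["E"] = rng.normal(size=(7, 6))
    dm.params["R"] = rng.normal(size=(3, 6))
    cm.params["E_re"] = dm.params["E"].copy()
    cm.params["R_re"] = dm.params["R"].copy()
    cm.params["E_im"][:] = 0.0
    cm.params["R_im"][:] = 0.0
    h, r, t = A([0, 1, 2]), A([0, 1, 2]), A([3, 4, 5])
    np.testing.assert_allclose(cm.score(h, r, t), dm.score(h, r, t), rtol=0, atol=0)


def test_rotate_zero_phase_is_pure_translation_free_distance():
    m = _model("rotate", dim=5, norm=1)
    m.params["T"][:] = 0.0
    m.params["E_im"][:] = 0.0
    te = _model("transe", dim=5, norm=1)
    te.params["E"] = m.params["E_re"].copy()
    te.params["R"][:] = 0.0
    h, r, t = A([0, 1]), A([0, 1]), A([2, 3])
    np.testing.assert_allclose(m.score(h, r, t), te.score(h, r, t), atol=1e-12)
    # identity rotation, h == t: score 0 is the maximum
    assert m.score(A([2]), A([0]), A([2]))[0] == 0.0


def test_transh_reduces_to_transe_when_normal_is_orthogonal():
    th = _model("transh", dim=6)
    te = _model("transe", dim=6, norm=2)
    rng = np.random.default_rng(1)
    E = rng.normal(size=(7, 6))
    E[:, 5] = 0.0  # embeddings live in the first 5 dims
    th.params["E"] = E.copy()
    te.params["E"] = E.copy()
    w = np.zeros(6)
    w[5] = 1.0  # normal orthogonal to every embedding
    th.params["W"][:] = w
    D = rng.normal(size=(3, 6))
    D[:, 5] = 0.0
    th.params["D"] = D.copy()
    te.params["R"] = D.copy()
    h, r, t = A([0, 1, 2]), A([0, 1, 2]), A([3, 4, 5])
    np.testing.assert_allclose(th.score(h, r, t), te.score(h, r, t), atol=1e-12)


@pytest.mark.parametrize("family", ["transe", "transh", "transr", "rotate"])
def test_translational_scores_are_nonpositive(family):
    m = _model(family, seed=3)
    rng = np.random.default_rng(0)
    h = rng.integers(0, 7, size=50)
    r = rng.integers(0, 3, size=50)
    t = rng.integers(0, 7, size=50)
    assert (m.score(h, r, t) <= 0).all()


def test_transe_perfect_composition_scores_zero():
    m = _model("transe", dim=3)
    m.params["E"][0] = (1.0, 2.0, 3.0)
    m.params["R"][0] = (0.5, -1.0, 0.0)
    m.params["E"][1] = (1.5, 1.0, 3.0)  # e_h + r == e_t
    assert m.score(A([0]), A([0]), A([1]))[0] == 0.0


def test_score_index_out_of_range():
    m = _model("distmult")
    with pytest.raises(IndexError):
        m.score(A([99]), A([0]), A([0]))


# the p-norm choice only applies to the translation-distance families
_GRAD_CASES = [("transe", 1), ("transe", 2), ("rotate", 1), ("rotate", 2),
               ("transh", 2), ("transr", 2), ("complex", 2), ("distmult", 2)]


@pytest.mark.parametrize("family, norm", _GRAD_CASES)
def test_analytic_gradients_match_finite_differences(family, norm):
    """Central differences at random points, 1e-5 relative tolerance."""
    rng = np.random.default_rng(42)
    m = _model(family, dim=5, seed=7, norm=norm)
    eps = 1e-6
    checked = 0
    for _ in range(100):
        h = int(rng.integers(0, 7))
        r = int(rng.integers(0, 3))
        t = int(rng.integers(0, 7))
        if h == t:
            t = (t + 1) % 7
        ha, ra, ta = A([h]), A([r]), A([t])
        grads = {k: np.zeros_like(v) for k, v in m.params.items()}
        m._grad(ha, ra, ta, np.ones(1), grads)
        name = list(m.params)[int(rng.integers(0, len(m.params)))]
        P = m.params[name]
        rows = (h, t) if name.startswith("E") else (r,)
        ix = (rows[int(rng.integers(0, len(rows)))],) + tuple(
            int(rng.integers(0, s)) for s in P.shape[1:]
        )
        orig = P[ix]
        P[ix] = orig + eps
        sp = float(m._score(ha, ra, ta)[0])
        P[ix] = orig - eps
        sm = float(m._score(ha, ra, ta)[0])
        P[ix] = orig
        numeric = (sp - sm) / (2 * eps)
        analytic = float(grads[name][ix])
        assert abs(numeric - analytic) <= 1e-5 * max(1.0, abs(numeric), abs(analytic))
        checked += 1
    assert checked == 100


@pytest.mark.parametrize("family", FAMILIES)
def test_score_all_matches_batched_score(family):
    m = _model(family, seed=11)
    n = m.n_entities
    tails = m.score_all_tails(2, 1)
    heads = m.score_all_heads(1, 3)
    np.testing.assert_allclose(tails, m.score(np.full(n, 2), np.full(n, 1), np.arange(n)), atol=1e-12)
    np.testing.assert_allclose(heads, m.score(np.arange(n), np.full(n, 1), np.full(n, 3)), atol=1e-12)


# --------------------------------------------------------------------------
# negative sampling
# --------------------------------------------------------------------------


def test_negative_sample_two_entities():
    rng = np.random.default_rng(0)
    for _ in range(20):
        nh, nr, nt = negative_sample((0, 0, 1), 2, rng)
        assert nr == 0
        assert (nh, nt) in {(1, 1), (0, 0)}  # the only possible corruptions


def test_negative_sample_head_tail_balance_and_uniformity():
    rng = np.random.default_rng(123)
    n, n_e = 10_000, 7
    heads = 0
    replacements = []
    for _ in range(n):
        nh, _, nt = negative_sample((2, 0, 5), n_e, rng)
        if nh != 2:
            heads += 1
            assert nt == 5 and nh != 2
            replacements.append(("h", nh))
        else:
            assert nt != 5
            replacements.append(("t", nt))
    p = heads / n
    sigma = 0.5 / np.sqrt(n)
    assert abs(p - 0.5) <= 3 * sigma
    # chi-square uniformity of the replacement entity over the 6 candidates
    for side, orig in (("h", 2), ("t", 5)):
        counts = [sum(1 for s, e in replacements if s == side and e == c)
                  for c in range(n_e) if c != orig]
        assert scipy.stats.chisquare(counts).pvalue > 1e-4


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


def toy_triples(n_e=12, n_r=2, n=30, seed=0):
    rng = np.random.default_rng(seed)
    seen = set()
    while len(seen) < n:
        seen.add((int(rng.integers(n_e)), int(rng.integers(n_r)), int(rng.integers(n_e))))
    return sorted(seen)


@pytest.mark.parametrize("family", FAMILIES)
def test_training_loss_trends_down(family):
    """Mean epoch loss decreases on a 30-triple toy graph; resampled
    negatives allow transient upticks of at most 10%."""
    cfg = TrainConfig(dim=8, epochs=30, lr=0.05, seed=5, batch_size=30, negatives=64)
    model = train(toy_triples(), 12, 2, family, cfg)
    losses = model.loss_history_
    assert losses[-1] < 0.6 * losses[0]
    for a, b in zip(losses, losses[1:]):
        assert b <= 1.10 * a


@pytest.mark.parametrize("family", FAMILIES)
def test_training_is_bit_deterministic(family):
    cfg = TrainConfig(dim=6, epochs=3, seed=9, batch_size=16)
    m1 = train(toy_triples(), 12, 2, family, cfg)
    m2 = train(toy_triples(), 12, 2, family, cfg)
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])


def test_duplicate_triples_do_not_change_the_model():
    cfg = TrainConfig(dim=6, epochs=4, seed=2, batch_size=16)
    base = toy_triples()
    m1 = train(base, 12, 2, "distmult", cfg)
    m2 = train(base + base, 12, 2, "distmult", cfg)
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])


def test_train_empty_graph_raises():
    with pytest.raises(ValueError):
        train([], 5, 1, "transe", TrainConfig(dim=4, epochs=1))


def test_rotate_relation_moduli_stay_unit_after_training():
    cfg = TrainConfig(dim=6, epochs=5, seed=1, batch_size=16, lr=0.05)
    model = train(toy_triples(), 12, 2, "rotate", cfg)
    theta = model.params["T"]
    moduli = np.abs(np.exp(1j * theta))
    np.testing.assert_allclose(moduli, 1.0, atol=1e-12)


def test_checkpoint_round_trip(tmp_path):
    cfg = TrainConfig(dim=6, epochs=2, seed=3)
    model = train(toy_triples(), 12, 2, "complex", cfg)
    save_model(model, tmp_path / "ckpt")
    back = load_model(tmp_path / "ckpt")
    assert back.family == "complex" if hasattr(back, "family") else True
    h, r, t = A([0, 1]), A([0, 1]), A([2, 3])
    np.testing.assert_allclose(back.score(h, r, t), model.score(h, r, t), atol=0)
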