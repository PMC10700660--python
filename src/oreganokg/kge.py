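"""Knowledge-graph embedding models: TransE, TransH, TransR, RotatE, ComplEx
and DistMult, trained from scratch with negative sampling.

Each family assigns a d-dimensional parameter vector to every entity and a
family-specific parameter set to every relation, and scores a triple
(h, r, t) so that higher means more plausible:

* TransE     s = -||e_h + r - e_t||_p
* TransH     s = -||P_r(e_h) + d_r - P_r(e_t)||_2,  P_r(x) = x - (w_r.x) w_r
* TransR     s = -||M_r e_h + r - M_r e_t||_2
* RotatE     s = -||e_h o r - e_t||  (complex; r_i = exp(i theta_i), |r_i|=1)
* ComplEx    s = Re( sum_i e_h,i r_i conj(e_t,i) )
* DistMult   s = sum_i e_h,i r_i e_t,i

Translational families train with a margin ranking loss
max(0, gamma + s(neg) - s(pos)); the bilinear families (ComplEx, DistMult)
with a logistic loss softplus(-y s).  Gradients are analytic (verified
against central finite differences in the test suite) and optimisation is
seeded mini-batch SGD with optional Adagrad per-parameter scaling, so
identical seeds give bit-identical models.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

FAMILIES = ("transe", "transh", "transr", "rotate", "complex", "distmult")


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The evaluation protocol fixes the epoch budget (default 50); everything
    else is explicit configuration with package defaults.
    """

    dim: int = 64
    epochs: int = 50
    lr: float = 0.01
    margin: float = 1.0
    negatives: int = 1
    batch_size: int = 128
    seed: int = 0
    norm: int = 1  # p-norm for TransE / RotatE distances
    optimizer: str = "adagrad"  # "adagrad" | "sgd"

    def __post_init__(self) -> None:
        if self.dim < 1 or self.epochs < 0 or self.negatives < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.norm not in (1, 2):
            raise ValueError("norm must be 1 or 2")
        if self.optimizer not in ("adagrad", "sgd"):
            raise ValueError("optimizer must be 'adagrad' or 'sgd'")


def _xavier(rng: np.random.Generator, shape: tuple[int, ...], dim: int) -> np.ndarray:
    bound = 6.0 / np.sqrt(dim)
    return rng.uniform(-bound, bound, size=shape)


class BaseModel:
    """Shared machinery: named parameter arrays, scoring, analytic gradients.

    Subclasses implement `_score` over index arrays and `_grad`, which
    scatter-adds d(score)/d(params), weighted by an upstream gradient, into
    dense buffers.
    """

    family: str = ""
    margin_loss: bool = True  # False -> logistic loss

    def __init__(self, n_entities: int, n_relations: int, dim: int, rng: np.random.Generator, norm: int = 1):
        if n_entities < 1 or n_relations < 1:
            raise ValueError("model needs at least one entity and one relation")
        self.n_entities = n_entities
        self.n_relations = n_relations
        self.dim = dim
        self.norm = norm
        self.params: dict[str, np.ndarray] = {}
        self._init_params(rng)

    def _init_params(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def score(self, h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
        h, r, t = (np.asarray(x, dtype=np.int64) for x in (h, r, t))
        if not (h.shape == r.shape == t.shape):
            raise ValueError("index arrays must share a shape")
        if h.max(initial=0) >= self.n_entities or t.max(initial=0) >= self.n_entities:
            raise IndexError("entity index out of range")
        if r.max(initial=0) >= self.n_relations:
            raise IndexError("relation index out of range")
        return self._score(h, r, t)

    def _score(self, h, r, t) -> np.ndarray:
        raise NotImplementedError

    def _grad(self, h, r, t, gout, grads: dict[str, np.ndarray]) -> None:
        raise NotImplementedError

    # candidate scoring for ranking; default falls back to batched score()
    def score_all_tails(self, h: int, r: int) -> np.ndarray:
        n = self.n_entities
        return self._score(np.full(n, h), np.full(n, r), np.arange(n))

    def score_all_heads(self, r: int, t: int) -> np.ndarray:
        n = self.n_entities
        return self._score(np.arange(n), np.full(n, r), np.full(n, t))

    def post_update(self) -> None:
        """Constraint projection applied after each optimizer step."""


def _lp_dist_grad(u: np.ndarray, norm: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (||u||_p per row, d||u||_p/du)."""
    if norm == 1:
        return np.abs(u).sum(axis=1), np.sign(u)
    d = np.sqrt((u * u).sum(axis=1))
    safe = np.where(d > 0, d, 1.0)
    return d, u / safe[:, None]


class TransE(BaseModel):
    family = "transe"

    def _init_params(self, rng):
        self.params["E"] = _xavier(rng, (self.n_entities, self.dim), self.dim)
        self.params["R"] = _xavier(rng, (self.n_relations, self.dim), self.dim)

    def _score(self, h, r, t):
        u = self.params["E"][h] + self.params["R"][r] - self.params["E"][t]
        return -_lp_dist_grad(u, self.norm)[0]

    def _grad(self, h, r, t, gout, grads):
        u = self.params["E"][h] + self.params["R"][r] - self.params["E"][t]
        gu = -_lp_dist_grad(u, self.norm)[1] * gout[:, None]
        np.add.at(grads["E"], h, gu)
        np.add.at(grads["R"], r, gu)
        np.add.at(grads["E"], t, -gu)


class TransH(BaseModel):
    """Translation on a relation-specific hyperplane; the normal vectors w_r
    are renormalized to unit length after every update."""

    family = "transh"

    def _init_params(self, rng):
        self.params["E"] = _xavier(rng, (self.n_entities, self.dim), self.dim)
        self.params["D"] = _xavier(rng, (self.n_relations, self.dim), self.dim)
        w = _xavier(rng, (self.n_relations, self.dim), self.dim)
        self.params["W"] = w / np.linalg.norm(w, axis=1, keepdims=True)

    def _parts(self, h, r, t):
        E = self.params["E"]
        w = self.params["W"][r]
        z = E[h] - E[t]
        a = (w * z).sum(axis=1)
        u = z - a[:, None] * w + self.params["D"][r]
        d = np.sqrt((u * u).sum(axis=1))
        return w, z, a, u, d

    def _score(self, h, r, t):
        return -self._parts(h, r, t)[4]

    def _grad(self, h, r, t, gout, grads):
        w, z, a, u, d = self._parts(h, r, t)
        safe = np.where(d > 0, d, 1.0)
        uh = u / safe[:, None]
        uw = (uh * w).sum(axis=1)
        gh = (-uh + uw[:, None] * w) * gout[:, None]          # ds/dh
        gw = (uw[:, None] * z + a[:, None] * uh) * gout[:, None]  # ds/dw
        gd = -uh * gout[:, None]                               # ds/dd_r
        np.add.at(grads["E"], h, gh)
        np.add.at(grads["E"], t, -gh)
        np.add.at(grads["W"], r, gw)
        np.add.at(grads["D"], r, gd)

    def post_update(self):
        W = self.params["W"]
        W /= np.linalg.norm(W, axis=1, keepdims=True)

    def score_all_tails(self, h, r):
        E, w = self.params["E"], self.params["W"][r]
        proj = E - np.outer(E @ w, w)
        u = proj[h] + self.params["D"][r] - proj
        return -np.sqrt((u * u).sum(axis=1))

    def score_all_heads(self, r, t):
        E, w = self.params["E"], self.params["W"][r]
        proj = E - np.outer(E @ w, w)
        u = proj + self.params["D"][r] - proj[t]
        return -np.sqrt((u * u).sum(axis=1))


class TransR(BaseModel):
    """Translation in a relation-specific space via a d x d projection."""

    family = "transr"

    def _init_params(self, rng):
        self.params["E"] = _xavier(rng, (self.n_entities, self.dim), self.dim)
        self.params["R"] = _xavier(rng, (self.n_relations, self.dim), self.dim)
        eye = np.eye(self.dim)
        noise = _xavier(rng, (self.n_relations, self.dim, self.dim), self.dim) * 0.1
        self.params["M"] = eye[None, :, :] + noise

    def _parts(self, h, r, t):
        E, M = self.params["E"], self.params["M"][r]
        z = E[h] - E[t]
        u = np.einsum("bij,bj->bi", M, z) + self.params["R"][r]
        d = np.sqrt((u * u).sum(axis=1))
        return M, z, u, d

    def _score(self, h, r, t):
        return -self._parts(h, r, t)[3]

    def _grad(self, h, r, t, gout, grads):
        M, z, u, d = self._parts(h, r, t)
        safe = np.where(d > 0, d, 1.0)
        uh = u / safe[:, None]
        gz = -np.einsum("bij,bi->bj", M, uh) * gout[:, None]
        gM = -np.einsum("bi,bj->bij", uh, z) * gout[:, None, None]
        gr = -uh * gout[:, None]
        np.add.at(grads["E"], h, gz)
        np.add.at(grads["E"], t, -gz)
        np.add.at(grads["R"], r, gr)
        np.add.at(grads["M"], r, gM)


class RotatE(BaseModel):
    """Rotation in the complex plane; relations are phase vectors, so every
    relation coordinate has modulus exactly 1 by construction."""

    family = "rotate"

    def _init_params(self, rng):
        self.params["E_re"] = _xavier(rng, (self.n_entities, self.dim), self.dim)
        self.params["E_im"] = _xavier(rng, (self.n_entities, self.dim), self.dim)
        self.params["T"] = rng.uniform(0.0, 2.0 * np.pi, size=(self.n_relations, self.dim))

    def _parts(self, h, r, t):
        hre, him = self.params["E_re"][h], self.params["E_im"][h]
        theta = self.params["T"][r]
        c, s = np.cos(theta), np.sin(theta)
        wre = hre * c - him * s
        wim = hre * s + him * c
        ure = wre - self.params["E_re"][t]
        uim = wim - self.params["E_im"][t]
        m = np.sqrt(ure * ure + uim * uim)
        return c, s, wre, wim, ure, uim, m

    def _dist(self, m):
        if self.norm == 1:
            return m.sum(axis=1)
        return np.sqrt((m * m).sum(axis=1))

    def _score(self, h, r, t):
        return -self._dist(self._parts(h, r, t)[6])

    def _grad(self, h, r, t, gout, grads):
        c, s, wre, wim, ure, uim, m = self._parts(h, r, t)
        safe_m = np.where(m > 0, m, 1.0)
        if self.norm == 1:
            gre, gim = -ure / safe_m, -uim / safe_m
        else:
            d = np.sqrt((m * m).sum(axis=1))
            safe_d = np.where(d > 0, d, 1.0)[:, None]
            gre, gim = -ure / safe_d, -uim / safe_d
        gre = gre * gout[:, None]
        gim = gim * gout[:, None]
        np.add.at(grads["E_re"], h, gre * c + gim * s)
        np.add.at(grads["E_im"], h, -gre * s + gim * c)
        np.add.at(grads["E_re"], t, -gre)
        np.add.at(grads["E_im"], t, -gim)
        np.add.at(grads["T"], r, gre * (-wim) + gim * wre)

    def score_all_tails(self, h, r):
        c, s, wre, wim, *_ = self._parts(np.array([h]), np.array([r]), np.array([h]))
        ure = wre - self.params["E_re"]
        uim = wim - self.params["E_im"]
        return -self._dist(np.sqrt(ure * ure + uim * uim))

    def score_all_heads(self, r, t):
        theta = self.params["T"][r]
        c, s = np.cos(theta), np.sin(theta)
        hre, him = self.params["E_re"], self.params["E_im"]
        wre = hre * c - him * s
        wim = hre * s + him * c
        ure = wre - self.params["E_re"][t]
        uim = wim - self.params["E_im"][t]
        return -self._dist(np.sqrt(ure * ure + uim * uim))


class ComplEx(BaseModel):
    family = "complex"
    margin_loss = False

    def _init_params(self, rng):
        for name in ("E_re", "E_im"):
            self.params[name] = _xavier(rng, (self.n_entities, self.dim), self.dim)
        for name in ("R_re", "R_im"):
            self.params[name] = _xavier(rng, (self.n_relations, self.dim), self.dim)

    def _score(self, h, r, t):
        hre, him = self.params["E_re"][h], self.params["E_im"][h]
        rre, rim = self.params["R_re"][r], self.params["R_im"][r]
        tre, tim = self.params["E_re"][t], self.params["E_im"][t]
        return (
            (hre * rre * tre) + (him * rre * tim) + (hre * rim * tim) - (him * rim * tre)
        ).sum(axis=1)

    def _grad(self, h, r, t, gout, grads):
        hre, him = self.params["E_re"][h], self.params["E_im"][h]
        rre, rim = self.params["R_re"][r], self.params["R_im"][r]
        tre, tim = self.params["E_re"][t], self.params["E_im"][t]
        g = gout[:, None]
        np.add.at(grads["E_re"], h, (rre * tre + rim * tim) * g)
        np.add.at(grads["E_im"], h, (rre * tim - rim * tre) * g)
        np.add.at(grads["E_re"], t, (hre * rre - him * rim) * g)
        np.add.at(grads["E_im"], t, (him * rre + hre * rim) * g)
        np.add.at(grads["R_re"], r, (hre * tre + him * tim) * g)
        np.add.at(grads["R_im"], r, (hre * tim - him * tre) * g)

    def score_all_tails(self, h, r):
        hre, him = self.params["E_re"][h], self.params["E_im"][h]
        rre, rim = self.params["R_re"][r], self.params["R_im"][r]
        a = hre * rre - him * rim   # Re(h o r)
        b = hre * rim + him * rre   # Im(h o r)
        return self.params["E_re"] @ a + self.params["E_im"] @ b

    def score_all_heads(self, r, t):
        rre, rim = self.params["R_re"][r], self.params["R_im"][r]
        tre, tim = self.params["E_re"][t], self.params["E_im"][t]
        a = rre * tre + rim * tim
        b = rre * tim - rim * tre
        return self.params["E_re"] @ a + self.params["E_im"] @ b


class DistMult(BaseModel):
    family = "distmult"
    margin_loss = False

    def _init_params(self, rng):
        self.params["E"] = _xavier(rng, (self.n_entities, self.dim), self.dim)
        self.params["R"] = _xavier(rng, (self.n_relations, self.dim), self.dim)

    def _score(self, h, r, t):
        return (self.params["E"][h] * self.params["R"][r] * self.params["E"][t]).sum(axis=1)

    def _grad(self, h, r, t, gout, grads):
        E, R = self.params["E"], self.params["R"]
        g = gout[:, None]
        np.add.at(grads["E"], h, R[r] * E[t] * g)
        np.add.at(grads["E"], t, E[h] * R[r] * g)
        np.add.at(grads["R"], r, E[h] * E[t] * g)

    def score_all_tails(self, h, r):
        return self.params["E"] @ (self.params["E"][h] * self.params["R"][r])

    def score_all_heads(self, r, t):
        return self.params["E"] @ (self.params["R"][r] * self.params["E"][t])


_MODEL_CLASSES: dict[str, type[BaseModel]] = {
    "transe": TransE,
    "transh": TransH,
    "transr": TransR,
    "rotate": RotatE,
    "complex": ComplEx,
    "distmult": DistMult,
}


def make_model(
    family: str, n_entities: int, n_relations: int, cfg: TrainConfig
) -> BaseModel:
    family = family.lower()
    if family not in _MODEL_CLASSES:
        raise ValueError(f"unknown embedding family: {family!r} (choose from {FAMILIES})")
    rng = np.random.default_rng(cfg.seed)
    return _MODEL_CLASSES[family](n_entities, n_relations, cfg.dim, rng, norm=cfg.norm)


# --------------------------------------------------------------------------
# negative sampling and training
# --------------------------------------------------------------------------


def negative_sample(
    triple: tuple[int, int, int], n_entities: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Corrupt one triple: with probability 1/2 the head, else the tail, is
    replaced by a uniformly drawn entity different from the original."""
    if n_entities < 2:
        raise ValueError("need at least 2 entities to corrupt")
    h, r, t = triple
    corrupt_head = bool(rng.integers(0, 2))
    orig = h if corrupt_head else t
    draw = int(rng.integers(0, n_entities - 1))
    if draw >= orig:
        draw += 1
    return (draw, r, t) if corrupt_head else (h, r, draw)


def _corrupt_batch(
    h: np.ndarray, t: np.ndarray, n_entities: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized negative sampling for a batch (same protocol as
    :func:`negative_sample`)."""
    b = h.shape[0]
    corrupt_head = rng.integers(0, 2, size=b).astype(bool)
    orig = np.where(corrupt_head, h, t)
    draw = rng.integers(0, n_entities - 1, size=b)
    draw = np.where(draw >= orig, draw + 1, draw)
    nh = np.where(corrupt_head, draw, h)
    nt = np.where(corrupt_head, t, draw)
    return nh, nt


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train(
    triples: Sequence[tuple[int, int, int]] | np.ndarray,
    n_entities: int,
    n_relations: int,
    family: str,
    cfg: TrainConfig,
) -> BaseModel:
    """Train one embedding model over index triples.

    Duplicate triples are removed before training, so a graph and its exact
    duplicate yield the same model.  The per-epoch mean loss is recorded on
    the returned model as ``loss_history_``; a non-finite loss aborts.
    """
    arr = np.asarray(sorted(set(map(tuple, np.asarray(triples, dtype=np.int64).tolist()))), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot train on an empty graph")
    model = make_model(family, n_entities, n_relations, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    accum = {k: np.zeros_like(v) for k, v in model.params.items()} if cfg.optimizer == "adagrad" else None
    n = arr.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        total = 0.0
        count = 0
        for start in range(0, n, cfg.batch_size):
            batch = arr[perm[start : start + cfg.batch_size]]
            if cfg.negatives > 1:
                batch = np.repeat(batch, cfg.negatives, axis=0)
            h, r, t = batch[:, 0], batch[:, 1], batch[:, 2]
            nh, nt = _corrupt_batch(h, t, n_entities, rng)
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            if model.margin_loss:
                s_pos = model._score(h, r, t)
                s_neg = model._score(nh, r, nt)
                viol = cfg.margin + s_neg - s_pos
                active = viol > 0
                loss = np.where(active, viol, 0.0)
                gpos = np.where(active, -1.0, 0.0)
                gneg = np.where(active, 1.0, 0.0)
                model._grad(h, r, t, gpos, grads)
                model._grad(nh, r, nt, gneg, grads)
            else:
                s_pos = model._score(h, r, t)
                s_neg = model._score(nh, r, nt)
                loss = _softplus(-s_pos) + _softplus(s_neg)
                model._grad(h, r, t, -_sigmoid(-s_pos), grads)
                model._grad(nh, r, nt, _sigmoid(s_neg), grads)
            batch_loss = float(loss.sum())
            if not np.isfinite(batch_loss):
                raise ArithmeticError(
                    f"non-finite loss at epoch {epoch} (family={family}); "
                    "reduce the learning rate"
                )
            total += batch_loss
            count += loss.shape[0]
            for name, g in grads.items():
                if cfg.optimizer == "adagrad":
                    accum[name] += g * g
                    model.params[name] -= cfg.lr * g / np.sqrt(accum[name] + 1e-10)
                else:
                    model.params[name] -= cfg.lr * g
            model.post_update()
        history.append(total / max(count, 1))
    model.loss_history_ = history  # type: ignore[attr-defined]
    model.config_ = cfg  # type: ignore[attr-defined]
    return model


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------


def save_model(model: BaseModel, path: str | Path) -> None:
    """Persist parameter arrays (.npz) plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    cfg = getattr(model, "config_", None)
    meta = {
        "family": model.family,
        "dim": model.dim,
        "norm": model.norm,
        "n_entities": model.n_entities,
        "n_relations": model.n_relations,
        "config": asdict(cfg) if cfg is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> BaseModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    cls = _MODEL_CLASSES[meta["family"]]
    model = cls.__new__(cls)
    model.n_entities = meta["n_entities"]
    model.n_relations = meta["n_relations"]
    model.dim = meta["dim"]
    model.norm = meta["norm"]
    with np.load(path.with_suffix(".npz")) as data:
        model.params = {k: data[k].copy() for k in data.files}
    return model
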