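"""Wasserstein adversarially regularized graph autoencoder.

The generator is a 2-layer graph convolutional encoder

    Z = A_bar . ReLU( A_bar X W1 ) . W2 ,      Z in R^{N x d'}

The embedding layer is linear by default: the Wasserstein regularizer
matches the rows of Z to a standard-normal prior, which a rectified
(non-negative) output could never satisfy, and a rectified embedding
layer makes Z = 0 an absorbing fixed point of training (both loss
gradients vanish there).  A rectified output (``final_activation='relu'``)
is available for comparison.  Decoding uses an inner-product decoder p(A_ij = 1) = sigmoid(z_i^T z_j) trained by
a positively reweighted binary cross-entropy over all entries of the
self-looped adjacency.  A critic MLP with two hidden layers estimates the
1-Wasserstein distance between the encoded rows and a standard-normal
prior N(0, I_{d'}); the encoder minimizes it, the critic maximizes it
under a gradient penalty that enforces (approximate) 1-Lipschitzness.

All forward passes, gradients (including the gradient-penalty second-order
terms) and the Adam optimizer are implemented directly in numpy, so
training is bit-deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

EPS = 1e-12


# --------------------------------------------------------------------------
# parameters


@dataclass
class EncoderParams:
    W1: np.ndarray  # d x h
    W2: np.ndarray  # h x d'
    dropout_rate: float = 0.1
    final_activation: str = "linear"  # 'linear' or 'relu'

    @property
    def d_prime(self) -> int:
        return self.W2.shape[1]


@dataclass
class CriticParams:
    W3: np.ndarray  # h1 x d'
    b1: np.ndarray
    W4: np.ndarray  # h2 x h1
    b2: np.ndarray
    W5: np.ndarray  # h2
    b3: float

    def flat(self) -> List[np.ndarray]:
        return [self.W3, self.b1, self.W4, self.b2, self.W5,
                np.atleast_1d(np.asarray(self.b3, dtype=float))]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    epochs, dropout and gp_lambda are the user-facing knobs; the rest are
    sensible fixed defaults exposed for completeness.
    """

    epochs: int = 500
    gp_lambda: float = 10.0
    lr_gen: float = 1e-3
    lr_critic: float = 1e-3
    critic_steps: int = 5
    seed: int = 0
    hidden_h: int = 128
    d_prime: int = 32
    dropout: float = 0.1
    critic_hidden: Tuple[int, int] = (64, 64)
    critic_mode: str = "gp"  # 'gp' (gradient penalty) or 'clip'
    clip_value: float = 0.01
    final_activation: str = "linear"  # embedding-layer activation

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")
        if self.critic_mode not in ("gp", "clip"):
            raise ValueError("critic_mode must be 'gp' or 'clip'")


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_encoder(
    rng: np.random.Generator, d: int, hidden: int, d_prime: int, dropout: float,
    final_activation: str = "linear",
) -> EncoderParams:
    return EncoderParams(
        W1=_glorot(rng, d, hidden), W2=_glorot(rng, hidden, d_prime),
        dropout_rate=dropout, final_activation=final_activation,
    )


def init_critic(rng: np.random.Generator, d_prime: int, hidden: Tuple[int, int]) -> CriticParams:
    h1, h2 = hidden
    return CriticParams(
        W3=_glorot(rng, h1, d_prime), b1=np.zeros(h1),
        W4=_glorot(rng, h2, h1), b2=np.zeros(h2),
        W5=_glorot(rng, h2, 1).ravel(), b3=0.0,
    )


# --------------------------------------------------------------------------
# encoder / decoder


def encode(
    X: np.ndarray,
    A_bar: np.ndarray,
    enc: EncoderParams,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
):
    """Two-layer GCN forward pass.

    Dropout is applied after the first activation during training only;
    evaluation mode is deterministic.  Returns Z and, in training mode,
    the cached intermediates needed for backprop.
    """
    X = np.asarray(X, dtype=float)
    A_bar = np.asarray(A_bar, dtype=float)
    if X.shape[0] != A_bar.shape[0] or A_bar.shape[0] != A_bar.shape[1]:
        raise ValueError("X rows and A_bar dimensions must agree")
    if X.shape[1] != enc.W1.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} features but W1 expects {enc.W1.shape[0]}"
        )
    AX = A_bar @ X
    S1 = AX @ enc.W1
    H1 = np.maximum(S1, 0.0)
    if training and enc.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode encode needs an rng for dropout")
        keep = 1.0 - enc.dropout_rate
        D = (rng.random(H1.shape) < keep) / keep
        H1d = H1 * D
    else:
        D = None
        H1d = H1
    AH = A_bar @ H1d
    S2 = AH @ enc.W2
    Z = np.maximum(S2, 0.0) if enc.final_activation == "relu" else S2
    if training:
        return Z, {"AX": AX, "S1": S1, "D": D, "H1d": H1d, "AH": AH, "S2": S2}
    return Z


def encoder_backward(dZ, cache, enc: EncoderParams, A_bar: np.ndarray):
    """Gradients of a scalar loss wrt (W1, W2) given dL/dZ."""
    dS2 = dZ * (cache["S2"] > 0) if enc.final_activation == "relu" else dZ
    dW2 = cache["AH"].T @ dS2
    dH1d = A_bar @ (dS2 @ enc.W2.T)  # A_bar symmetric
    dH1 = dH1d * cache["D"] if cache["D"] is not None else dH1d
    dS1 = dH1 * (cache["S1"] > 0)
    dW1 = cache["AX"].T @ dS1
    return dW1, dW2


def decode(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder: P_ij = sigmoid(z_i^T z_j); symmetric."""
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("non-finite embeddings passed to decode")
    S = Z @ Z.T
    return 1.0 / (1.0 + np.exp(-S))


def _bce_weights(T: np.ndarray, pos_weight: Optional[float]):
    if pos_weight is None:
        n_pos = T.sum()
        n_neg = T.size - n_pos
        pos_weight = float(n_neg / n_pos) if n_pos > 0 else 1.0
    return pos_weight


def reconstruction_loss(
    P: np.ndarray, A: np.ndarray, pos_weight: Optional[float] = None
) -> float:
    """Mean binary cross-entropy of decoded edge probabilities.

    Self-loops are counted as positives (targets = A + I); the positive
    class is reweighted by the graph's zero/one ratio unless an explicit
    ``pos_weight`` is given (``pos_weight=1`` disables reweighting).
    Probabilities at exactly 0/1 are clamped by an epsilon.
    """
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    if P.shape != A.shape:
        raise ValueError("P and A must have the same shape")
    T = np.minimum(A + np.eye(A.shape[0]), 1.0)
    pw = _bce_weights(T, pos_weight)
    Pc = np.clip(P, EPS, 1.0 - EPS)
    loss = pw * T * (-np.log(Pc)) + (1.0 - T) * (-np.log(1.0 - Pc))
    return float(loss.mean())


def reconstruction_loss_grad_Z(
    Z: np.ndarray, A: np.ndarray, pos_weight: Optional[float] = None
):
    """(loss, dL/dZ) in a numerically stable softplus formulation."""
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A, dtype=float)
    n = Z.shape[0]
    T = np.minimum(A + np.eye(n), 1.0)
    pw = _bce_weights(T, pos_weight)
    S = Z @ Z.T
    # softplus(s) = log(1 + e^s), stable for large |s|
    sp_pos = np.logaddexp(0.0, S)    # -log(1 - sigma(S))
    sp_neg = np.logaddexp(0.0, -S)   # -log sigma(S)
    loss = float((pw * T * sp_neg + (1.0 - T) * sp_pos).mean())
    P = 1.0 / (1.0 + np.exp(-S))
    G = (-pw * T * (1.0 - P) + (1.0 - T) * P) / (n * n)
    dZ = (G + G.T) @ Z
    return loss, dZ


# --------------------------------------------------------------------------
# critic


def critic_forward(V: np.ndarray, crit: CriticParams, cache: bool = False):
    """Critic MLP: W5 . relu(W4 . relu(W3 v + b1) + b2) + b3, scalar per row."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    A1 = V @ crit.W3.T + crit.b1
    H1 = np.maximum(A1, 0.0)
    A2 = H1 @ crit.W4.T + crit.b2
    H2 = np.maximum(A2, 0.0)
    F = H2 @ crit.W5 + crit.b3
    if cache:
        return F, {"V": V, "A1": A1, "H1": H1, "A2": A2, "H2": H2}
    return F


def critic_backward(dF: np.ndarray, cache, crit: CriticParams):
    """Gradients wrt critic parameters and input given dL/dF (per sample)."""
    dH2 = dF[:, None] * crit.W5[None, :]
    dA2 = dH2 * (cache["A2"] > 0)
    dW4 = dA2.T @ cache["H1"]
    db2 = dA2.sum(axis=0)
    dH1 = dA2 @ crit.W4
    dA1 = dH1 * (cache["A1"] > 0)
    dW3 = dA1.T @ cache["V"]
    db1 = dA1.sum(axis=0)
    dW5 = cache["H2"].T @ dF
    db3 = float(dF.sum())
    dV = dA1 @ crit.W3
    return {"W3": dW3, "b1": db1, "W4": dW4, "b2": db2, "W5": dW5, "b3": db3}, dV


def critic_input_gradient(V: np.ndarray, crit: CriticParams):
    """Per-sample gradient of the critic output wrt its input.

    Also returns the intermediates needed for the gradient-penalty
    backward pass (ReLU masks treated as locally constant).
    """
    _, c = critic_forward(V, crit, cache=True)
    m1 = (c["A1"] > 0).astype(float)
    m2 = (c["A2"] > 0).astype(float)
    u2 = m2 * crit.W5[None, :]            # B x h2
    u1 = m1 * (u2 @ crit.W4)              # B x h1
    g = u1 @ crit.W3                      # B x d'
    return g, {"m1": m1, "m2": m2, "u1": u1, "u2": u2, "c": c}


def gradient_penalty(V: np.ndarray, crit: CriticParams):
    """WGAN-GP penalty mean((||grad_v f|| - 1)^2) and its parameter gradients."""
    g, aux = critic_input_gradient(V, crit)
    norms = np.linalg.norm(g, axis=1)
    B = g.shape[0]
    gp = float(((norms - 1.0) ** 2).mean())
    # d gp / d g, guarding the non-differentiable point ||g|| = 0
    safe = np.where(norms > EPS, norms, 1.0)
    dg = (2.0 * (norms - 1.0) / safe)[:, None] * g / B
    dg[norms <= EPS] = 0.0
    # backprop through g = (m1 * (W4^T (m2 * W5))) W3 with masks frozen
    du1 = dg @ crit.W3.T
    dW3 = aux["u1"].T @ dg
    q1 = du1 * aux["m1"]
    dW4 = aux["u2"].T @ q1
    du2 = q1 @ crit.W4.T
    dW5 = (aux["m2"] * du2).sum(axis=0)
    grads = {
        "W3": dW3,
        "b1": np.zeros_like(crit.b1),
        "W4": dW4.T if dW4.shape != crit.W4.shape else dW4,
        "b2": np.zeros_like(crit.b2),
        "W5": dW5,
        "b3": 0.0,
    }
    return gp, grads


def adversarial_losses(
    Z: np.ndarray,
    prior_samples: np.ndarray,
    crit: CriticParams,
    gp_lambda: float,
    interp_eps: Optional[np.ndarray] = None,
):
    """Critic loss (to minimize) and the generator's adversarial term.

    critic_loss = -(mean f(r) - mean f(z)) + gp_lambda * GP at random
    interpolates between prior and encoded samples; gen_reg = -mean f(z)
    is the term the generator adds to its objective.
    """
    Z = np.asarray(Z, dtype=float)
    R = np.asarray(prior_samples, dtype=float)
    if Z.shape != R.shape:
        raise ValueError("prior sample batch must match embedding batch")
    f_r = critic_forward(R, crit)
    f_z = critic_forward(Z, crit)
    w_term = float(f_r.mean() - f_z.mean())
    if interp_eps is None:
        interp_eps = np.full((Z.shape[0], 1), 0.5)
    V = interp_eps * R + (1.0 - interp_eps) * Z
    gp, _ = gradient_penalty(V, crit)
    critic_loss = -w_term + gp_lambda * gp
    gen_reg = float(-f_z.mean())
    return critic_loss, gen_reg


# --------------------------------------------------------------------------
# optimization


class Adam:
    """Plain Adam on a dict of named arrays."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            g = np.asarray(g, dtype=float)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class WargaModel:
    """Trained (or initialized) generator + critic with their config."""

    encoder: EncoderParams
    critic: CriticParams
    config: TrainConfig
    meta: dict = field(default_factory=dict)

    def embed(self, X: np.ndarray, A_bar: np.ndarray) -> np.ndarray:
        """Evaluation-mode embeddings (deterministic)."""
        return encode(X, A_bar, self.encoder, training=False)

    def save(self, path: str) -> None:
        import json

        np.savez(
            path,
            W1=self.encoder.W1, W2=self.encoder.W2,
            W3=self.critic.W3, b1=self.critic.b1,
            W4=self.critic.W4, b2=self.critic.b2,
            W5=self.critic.W5, b3=np.atleast_1d(self.critic.b3),
            config=np.frombuffer(
                json.dumps(
                    {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in self.config.__dict__.items()}
                ).encode(), dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path: str) -> "WargaModel":
        import json

        with np.load(path) as z:
            cfg = json.loads(bytes(z["config"].tobytes()).decode())
            cfg["critic_hidden"] = tuple(cfg["critic_hidden"])
            return cls(
                encoder=EncoderParams(
                    W1=z["W1"], W2=z["W2"], dropout_rate=cfg["dropout"],
                    final_activation=cfg.get("final_activation", "linear"),
                ),
                critic=CriticParams(
                    W3=z["W3"], b1=z["b1"], W4=z["W4"], b2=z["b2"],
                    W5=z["W5"], b3=float(z["b3"][0]),
                ),
                config=TrainConfig(**cfg),
            )


def _check_finite(value: float, component: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite loss in component '{component}'; "
            "lower the learning rates or gp_lambda"
        )


def train(
    X_aug: np.ndarray,
    A_bar: np.ndarray,
    A: np.ndarray,
    cfg: TrainConfig,
):
    """Alternating minimax training of the adversarial graph autoencoder.

    Per epoch: ``critic_steps`` full-batch critic updates (maximizing the
    Wasserstein objective, gradient-penalized), then one generator update
    minimizing reconstruction + adversarial term.  Fully deterministic
    given ``cfg.seed``.

    Returns (Z, model, loss_trace) with Z the evaluation-mode embeddings.
    """
    X_aug = np.asarray(X_aug, dtype=float)
    n, d = X_aug.shape
    rng = np.random.default_rng(cfg.seed)
    enc = init_encoder(rng, d, cfg.hidden_h, cfg.d_prime, cfg.dropout,
                       cfg.final_activation)
    crit = init_critic(rng, cfg.d_prime, cfg.critic_hidden)

    enc_params = {"W1": enc.W1, "W2": enc.W2}
    crit_params = {"W3": crit.W3, "b1": crit.b1, "W4": crit.W4,
                   "b2": crit.b2, "W5": crit.W5}
    opt_g = Adam(enc_params, cfg.lr_gen)
    opt_c = Adam(crit_params, cfg.lr_critic)
    b3 = np.zeros(1)  # critic output bias updated by plain accumulation via Adam
    opt_b3 = Adam({"b3": b3}, cfg.lr_critic)

    trace: List[dict] = []
    for epoch in range(cfg.epochs):
        # ---- critic updates (encoder frozen, eval mode) ----
        Z_fixed = encode(X_aug, A_bar, enc, training=False)
        c_loss = gp_val = 0.0
        for _ in range(cfg.critic_steps):
            R = rng.standard_normal(Z_fixed.shape)
            f_r, cache_r = critic_forward(R, crit, cache=True)
            f_z, cache_z = critic_forward(Z_fixed, crit, cache=True)
            g_r, _ = critic_backward(np.full(n, -1.0 / n), cache_r, crit)
            g_z, _ = critic_backward(np.full(n, 1.0 / n), cache_z, crit)
            grads = {k: g_r[k] + g_z[k] for k in g_r}
            gp = 0.0
            if cfg.critic_mode == "gp" and cfg.gp_lambda > 0:
                eps_i = rng.random((n, 1))
                V = eps_i * R + (1.0 - eps_i) * Z_fixed
                gp, gp_grads = gradient_penalty(V, crit)
                for k in ("W3", "W4", "W5"):
                    grads[k] = grads[k] + cfg.gp_lambda * gp_grads[k]
            opt_c.step({k: grads[k] for k in crit_params})
            opt_b3.step({"b3": np.atleast_1d(grads["b3"])})
            crit.b3 = float(b3[0])
            if cfg.critic_mode == "clip":
                for k in crit_params:
                    np.clip(crit_params[k], -cfg.clip_value, cfg.clip_value,
                            out=crit_params[k])
            c_loss = -(f_r.mean() - f_z.mean()) + cfg.gp_lambda * gp
            gp_val = gp
        _check_finite(c_loss, "critic loss")

        # ---- generator update (training mode, dropout active) ----
        Z_tr, cache = encode(X_aug, A_bar, enc, training=True, rng=rng)
        rec, dZ_rec = reconstruction_loss_grad_Z(Z_tr, A)
        f_z, cache_z = critic_forward(Z_tr, crit, cache=True)
        adv = float(-f_z.mean())
        _, dZ_adv = critic_backward(np.full(n, -1.0 / n), cache_z, crit)
        dW1, dW2 = encoder_backward(dZ_rec + dZ_adv, cache, enc, A_bar)
        _check_finite(rec, "reconstruction loss")
        _check_finite(adv, "adversarial term")
        opt_g.step({"W1": dW1, "W2": dW2})
        trace.append({"epoch": epoch, "rec": rec, "adv": adv,
                      "critic": float(c_loss), "gp": float(gp_val)})

    Z = encode(X_aug, A_bar, enc, training=False)
    model = WargaModel(encoder=enc, critic=crit, config=cfg,
                       meta={"n_spots": n, "n_features": d})
    return Z, model, trace
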