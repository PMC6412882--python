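"""Exercise-quality evaluation: joint-class LSTM classifier, general
(best) features, and cosine-derived scoring.

Each of M actions is performed at L quality levels, giving P = M*L joint
classes.  An LSTM-based classifier predicts the joint class; its final
bias-free dense layer is the classifier matrix C mapping the feature space
onto class scores.  For every joint class a "general feature" — the
feature the trained classifier scores maximally for that class — is found
by minimizing the condition loss ||G*C - S||^2 with the score matrix S.
A performed exercise is scored by the cosine angle between its extracted
feature and the general features of the predicted action's L levels,
scaled to [0, interval] and discretized into three bands.

The same feature (the input to the final dense layer) is used both to
learn G and to compute the cosine score, so the two comparisons live in
one space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (LSTM, SGD, Dense, Module, Tensor, softmax_cross_entropy)

__all__ = [
    "EvalHeads", "QualityScore", "LossWeights", "LstmEvaluator",
    "build_lstm_classifier", "prediction_loss", "build_score_matrix",
    "condition_loss", "learn_general_features", "cosine_score",
    "evaluate_sample", "score_to_label", "evaluation_loss", "total_loss",
    "resize_signal", "train_evaluation_model",
]


@dataclass
class EvalHeads:
    """Classifier matrix C (N_f x P), general features G (P x N_f), score
    matrix S (P x P); row m*L+l of G is the best feature of action m at
    level l."""

    C: np.ndarray
    G: np.ndarray
    S: np.ndarray
    n_actions: int
    n_levels: int


@dataclass
class QualityScore:
    cosine_score: float          # best cosine similarity, in [0, 1]
    evaluation: float            # cosine_score * interval
    level_label: int             # Eq-banded label: 2 = best band
    per_level: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class LossWeights:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class EvalTrainConfig:
    lstm_dims: tuple = (224, 224, 196)
    dense_dims: tuple = (128, 64)    # hidden, feature dim N_f
    resize_len: int = 128
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    epochs: int = 40
    batch_size: int = 32
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    temperature: float = 0.1         # evaluation-loss soft-label relaxation
    warmup_fraction: float = 0.5     # epochs trained on L_p + L_c only


class LstmEvaluator(Module):
    """Three LSTM layers, two hidden dense layers producing the feature f,
    and a bias-free dense classifier C over the P joint classes."""

    def __init__(self, n_actions: int, n_levels: int, cfg: EvalTrainConfig,
                 rng: np.random.Generator):
        self.n_actions = n_actions
        self.n_levels = n_levels
        self.lstm = LSTM(3, cfg.lstm_dims, rng)
        h1, nf = cfg.dense_dims
        self.fc1 = Dense(cfg.lstm_dims[-1], h1, rng)
        self.fc2 = Dense(h1, nf, rng)
        self.classifier = Dense(nf, n_actions * n_levels, rng, bias=False)

    def features(self, x: Tensor) -> Tensor:
        # the feature layer is linear: signed features span the full
        # direction space the cosine score compares in
        h = self.lstm(x)
        return self.fc2(self.fc1(h).relu())

    def __call__(self, inputs) -> Tensor:
        return self.classifier(self.features(inputs[0]))

    @property
    def C(self) -> np.ndarray:
        return self.classifier.W.data


def build_lstm_classifier(n_actions: int = 4, n_levels: int = 3,
                          cfg: EvalTrainConfig | None = None,
                          seed: int = 0) -> LstmEvaluator:
    cfg = cfg or EvalTrainConfig()
    return LstmEvaluator(n_actions, n_levels, cfg,
                         np.random.default_rng(seed))


def resize_signal(values: np.ndarray, length: int) -> np.ndarray:
    """Per-axis linear interpolation of a (T, 3) signal onto a fixed length."""
    values = np.asarray(values, dtype=float)
    T = len(values)
    src = np.linspace(0.0, 1.0, T)
    dst = np.linspace(0.0, 1.0, length)
    return np.stack([np.interp(dst, src, values[:, a]) for a in range(3)],
                    axis=1)


def prediction_loss(logits: Tensor, y: np.ndarray) -> Tensor:
    """Cross-entropy of the softmax posterior at the joint-class labels."""
    loss, _ = softmax_cross_entropy(logits, y)
    return loss


def build_score_matrix(M: int, L: int) -> np.ndarray:
    """P x P score matrix with a single 1 on the diagonal entry t = m*L + l
    of every joint class — the identity over joint classes."""
    if M < 1 or L < 1:
        raise ValueError("M and L must be >= 1")
    P = M * L
    S = np.zeros((P, P))
    for m in range(M):
        for l in range(L):
            t = m * L + l
            S[t, t] = 1.0
    return S


def condition_loss(G: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    """Squared Frobenius norm ||G C - S||^2."""
    G, C, S = (np.asarray(a, dtype=float) for a in (G, C, S))
    if G.shape[1] != C.shape[0] or (G.shape[0],) + (C.shape[1],) != S.shape:
        raise ValueError(f"incompatible shapes {G.shape}, {C.shape}, {S.shape}")
    R = G @ C - S
    return float((R * R).sum())


def learn_general_features(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Global minimizer of the condition loss: least-squares G with C and S
    fixed (G = S C^+)."""
    Gt, *_ = np.linalg.lstsq(np.asarray(C).T, np.asarray(S).T, rcond=None)
    return Gt.T


def cosine_score(feat: np.ndarray, gen: np.ndarray) -> float:
    """Angle-normalized similarity: 1 - arccos(cos(feat, gen)) / pi.

    1 for parallel, 0.5 for orthogonal, 0 for antipodal; scale-invariant.
    Zero vectors are rejected.
    """
    feat = np.asarray(feat, dtype=float)
    gen = np.asarray(gen, dtype=float)
    nf, ng = np.linalg.norm(feat), np.linalg.norm(gen)
    if nf == 0 or ng == 0:
        raise ValueError("cosine score undefined for zero vectors")
    c = np.clip(feat @ gen / (nf * ng), -1.0, 1.0)
    return float(1.0 - np.arccos(c) / np.pi)


def score_to_label(evaluation: float, interval: float = 100.0) -> int:
    """Discretize an evaluation in [0, interval] into three equal bands;
    the top boundary closes upward (interval itself maps to 2)."""
    if not (0.0 <= evaluation <= interval):
        raise ValueError(f"evaluation {evaluation} outside [0, {interval}]")
    x = 100.0 * evaluation / interval
    if x < 33.0:
        return 0
    if x < 66.0:
        return 1
    return 2


def evaluate_sample(feat: np.ndarray, heads: EvalHeads, predicted_action: int,
                    interval: float = 100.0) -> QualityScore:
    """Score a feature against the predicted action's per-level general
    features; the evaluation is the best similarity scaled by `interval`."""
    if not (0 <= predicted_action < heads.n_actions):
        raise ValueError("predicted action out of range")
    L = heads.n_levels
    rows = heads.G[predicted_action * L:(predicted_action + 1) * L]
    if np.linalg.norm(feat) == 0:   # degenerate feature: no direction
        per_level = np.zeros(L)
    else:
        per_level = np.array([cosine_score(feat, g) for g in rows])
    best = float(per_level.max())
    evaluation = best * interval
    return QualityScore(cosine_score=best, evaluation=evaluation,
                        level_label=score_to_label(evaluation, interval),
                        per_level=per_level)


def evaluation_loss(level_scores: Tensor, y_level: np.ndarray,
                    temperature: float = 0.1) -> Tensor:
    """Differentiable relaxation of the band cross-entropy.

    The evaluation is the best per-level similarity (the max), on the score
    scale [0, 1].  The hard band label is non-differentiable, so band
    membership is relaxed to a softmax over negative distances between the
    evaluation and the three band centers (1/6, 1/2, 5/6), sharpened by
    `temperature`.  Level index 0 means the best quality, so its target is
    the top band: minimizing this loss pushes good performances toward high
    evaluations and bad ones toward low evaluations, which is what makes
    the reported score bands meaningful.
    """
    B, L = level_scores.data.shape
    onehot = np.zeros((B, L))
    onehot[np.arange(B), level_scores.data.argmax(axis=1)] = 1.0
    e = (level_scores * Tensor(onehot)).sum(axis=1, keepdims=True)  # (B, 1)
    centers = (np.arange(L) + 0.5) / L                              # (L,)
    logits = (e - Tensor(centers)).abs() * (-1.0 / temperature)
    y_band = (L - 1) - y_level
    return prediction_loss(logits, y_band)


def total_loss(L_p, L_c, L_e, w: LossWeights):
    return w.alpha * L_p + w.beta * L_c + w.gamma * L_e


@dataclass
class EvalHistory:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)
    condition: list = field(default_factory=list)


def _batch_level_scores(f: Tensor, G: np.ndarray, actions: np.ndarray,
                        n_levels: int) -> Tensor:
    """Cosine-derived scores of each sample's feature against the G rows of
    its (predicted) action's levels; differentiable in f."""
    B = f.data.shape[0]
    rows = (actions[:, None] * n_levels + np.arange(n_levels)[None, :])
    Gsel = G[rows]                                    # (B, L, N_f)
    gnorm = np.linalg.norm(Gsel, axis=2) + 1e-12      # (B, L)
    num = (f.reshape(B, 1, -1) * Tensor(Gsel)).sum(axis=2)      # (B, L)
    fnorm = ((f * f).sum(axis=1, keepdims=True) + 1e-12) ** 0.5  # (B, 1)
    cosine = num * (fnorm ** -1.0) * Tensor(1.0 / gnorm)
    return cosine.arccos() * (-1.0 / np.pi) + 1.0


def train_evaluation_model(X: np.ndarray, y_action: np.ndarray,
                           y_level: np.ndarray,
                           cfg: EvalTrainConfig | None = None,
                           n_actions: int | None = None,
                           n_levels: int | None = None
                           ) -> tuple[LstmEvaluator, EvalHeads, EvalHistory]:
    """Alternating training of the evaluator.

    Each epoch: (1) SGD on alpha*L_p + beta*L_c + gamma*L_e with G fixed,
    (2) C refreshed implicitly (it is the live last-layer weight),
    (3) G re-solved in closed form.  X is (n, T, 3) resized signals.
    """
    cfg = cfg or EvalTrainConfig()
    M = n_actions if n_actions is not None else int(y_action.max()) + 1
    L = n_levels if n_levels is not None else int(y_level.max()) + 1
    y_joint = y_action * L + y_level
    S = build_score_matrix(M, L)
    n = len(X)
    w = cfg.weights
    warmup = int(round(cfg.warmup_fraction * cfg.epochs))
    # Recurrent training occasionally lands in a chance-level basin from a
    # bad initialization; a collapsed warm-up (training accuracy still near
    # chance) triggers a deterministic re-initialization.
    collapse_threshold = max(0.3, 3.0 / (M * L))
    for attempt in range(3):
        offset = 1000 * attempt
        model = LstmEvaluator(M, L, cfg,
                              np.random.default_rng(cfg.seed + offset))
        G = learn_general_features(model.C, S)
        opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(cfg.seed + 1 + offset)
        hist = EvalHistory()
        collapsed = False
        for epoch in range(cfg.epochs):
            gamma = 0.0 if epoch < warmup else w.gamma
            order = rng.permutation(n)
            ep_loss, correct = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = Tensor(X[idx])
                opt.zero_grad()
                f = model.features(xb)
                logits = model.classifier(f)
                L_p, probs = softmax_cross_entropy(logits, y_joint[idx])
                pred_joint = probs.argmax(axis=1)
                correct += int((pred_joint == y_joint[idx]).sum())
                GC = Tensor(G) @ model.classifier.W - Tensor(S)
                L_c = (GC ** 2.0).sum()
                if gamma > 0:
                    pred_action = pred_joint // L
                    scores = _batch_level_scores(f, G, pred_action, L)
                    L_e = evaluation_loss(scores, y_level[idx],
                                          cfg.temperature)
                else:
                    L_e = Tensor(0.0)
                loss = w.alpha * L_p + w.beta * L_c + gamma * L_e
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"evaluation training diverged at epoch {epoch}")
                loss.backward()
                opt.step()
                ep_loss += float(loss.data) * len(idx)
            G = learn_general_features(model.C, S)
            hist.loss.append(ep_loss / n)
            hist.accuracy.append(correct / n)
            hist.condition.append(condition_loss(G, model.C, S))
            if (epoch == warmup - 1 and warmup >= 5
                    and hist.accuracy[-1] < collapse_threshold):
                collapsed = True
                break
        if not collapsed:
            break
    heads = EvalHeads(C=model.C.copy(), G=G, S=S, n_actions=M, n_levels=L)
    return model, heads, hist


def score_dataset(model: LstmEvaluator, heads: EvalHeads, X: np.ndarray,
                  interval: float = 100.0, batch_size: int = 128):
    """Predict the joint class and score every sample; returns
    (pred_action, list of QualityScore)."""
    scores = []
    actions = []
    for start in range(0, len(X), batch_size):
        xb = Tensor(X[start:start + batch_size])
        f = model.features(xb)
        logits = model.classifier(f).data
        pred = logits.argmax(axis=1) // heads.n_levels
        for i, m in enumerate(pred):
            scores.append(evaluate_sample(f.data[i], heads, int(m), interval))
        actions.extend(int(m) for m in pred)
    return np.array(actions), scores
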