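"""The CNN family for movement recognition.

Four networks share one construction vocabulary:

* GB-CNN   — gravity and body components stacked as six input channels,
             two conv+pool stages, two hidden layers, softmax.
* S-CNN    — raw window in, flattened PFSA transition matrix out (MSE
             regression); its trunk doubles as a feature extractor for
             classification.
* D-CNN    — per-feature windows split into N_p channel-fitted segments,
             one conv+pool path per segment, merged, classified.
* MP-CNN   — the fused model: a top branch (GB-CNN, optionally plus the
             D-CNN) and a bottom branch (S-CNN).  A middle path applies
             `fusion_depth` conv+pool stages to the concatenated second
             pooling maps; the classifier head sees the middle-path output,
             the GB hidden-2 features, the S-CNN output layer, and (variant
             2) the D-CNN fusion features.

Training is plain SGD with momentum and weight decay; the S-CNN and D-CNN
can serve as pre-trained initializations for the fused model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (SGD, Conv1d, Dense, Module, Tensor, concat, max_pool1d,
                 softmax_cross_entropy)

__all__ = [
    "NetworkSpec", "TrainConfig", "SMALL_SPEC",
    "GBCNN", "SCNN", "SCNNClassifier", "DCNN", "MPCNN",
    "build_gbcnn", "build_scnn", "build_scnn_classifier", "build_dcnn",
    "build_mpcnn", "train", "predict", "accuracy",
]


@dataclass
class NetworkSpec:
    """Architecture hyperparameters shared across the family."""

    window: int = 80
    conv_kernels: tuple = (5, 3)
    conv_maps: tuple = (16, 32)
    pool: int = 2
    hidden: tuple = (1024, 512)
    n_classes: int = 4
    n_parts: int = 4          # D-CNN channels per feature
    fusion_depth: int = 1     # conv+pool stages in the MP-CNN middle path
    fusion_maps: int = 32

    def __post_init__(self):
        if self.fusion_depth not in (0, 1, 2, 3):
            raise ValueError("fusion_depth must be in {0, 1, 2, 3}")


# compact preset used for desk-scale experiments and the synthetic benchmark
SMALL_SPEC = NetworkSpec(conv_maps=(8, 16), hidden=(64, 32), fusion_maps=16)


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


def _pooled_len(W: int, stages: int, pool: int) -> int:
    for _ in range(stages):
        W //= pool
    return W


class GBCNN(Module):
    """Gravity+body classifier: merged six-channel input, two conv+pool
    stages, two hidden layers, softmax head."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        k1, k2 = spec.conv_kernels
        o1, o2 = spec.conv_maps
        self.conv1 = Conv1d(6, o1, k1, rng)
        self.conv2 = Conv1d(o1, o2, k2, rng)
        L = _pooled_len(spec.window, 2, spec.pool)
        self.fc1 = Dense(o2 * L, spec.hidden[0], rng)
        self.fc2 = Dense(spec.hidden[0], spec.hidden[1], rng)
        self.out = Dense(spec.hidden[1], spec.n_classes, rng)

    def forward_parts(self, x: Tensor):
        h = max_pool1d(self.conv1(x).relu(), self.spec.pool)
        pooled = max_pool1d(self.conv2(h).relu(), self.spec.pool)
        B = x.data.shape[0]
        flat = pooled.reshape(B, -1)
        h2 = self.fc2(self.fc1(flat).relu()).relu()
        return self.out(h2), pooled, h2

    def __call__(self, inputs) -> Tensor:
        return self.forward_parts(inputs[0])[0]


class SCNN(Module):
    """Raw-window regressor onto the flattened transition matrix."""

    def __init__(self, spec: NetworkSpec, n_states: int,
                 rng: np.random.Generator):
        self.spec = spec
        self.n_states = n_states
        k1, k2 = spec.conv_kernels
        o1, o2 = spec.conv_maps
        self.conv1 = Conv1d(3, o1, k1, rng)
        self.conv2 = Conv1d(o1, o2, k2, rng)
        L = _pooled_len(spec.window, 2, spec.pool)
        self.fc1 = Dense(o2 * L, spec.hidden[0], rng)
        self.out = Dense(spec.hidden[0], n_states * n_states, rng)

    def forward_parts(self, x: Tensor):
        h = max_pool1d(self.conv1(x).relu(), self.spec.pool)
        pooled = max_pool1d(self.conv2(h).relu(), self.spec.pool)
        B = x.data.shape[0]
        h1 = self.fc1(pooled.reshape(B, -1)).relu()
        return self.out(h1), pooled, h1

    def __call__(self, inputs) -> Tensor:
        return self.forward_parts(inputs[0])[0]


class SCNNClassifier(Module):
    """S-CNN trunk plus a softmax head: classification through the
    transition-probability feature space."""

    def __init__(self, spec: NetworkSpec, n_states: int,
                 rng: np.random.Generator):
        self.scnn = SCNN(spec, n_states, rng)
        self.head = Dense(n_states * n_states, spec.n_classes, rng)

    def __call__(self, inputs) -> Tensor:
        feats, _, _ = self.scnn.forward_parts(inputs[0])
        return self.head(feats.relu())


class DCNN(Module):
    """Channel-assigned segment classifier.

    Input is (B, 2*N_p, 3, L): gravity and body windows, each split into
    N_p segments routed to their matching channel.  Each segment gets its
    own conv+pool path; the concatenated maps get one more conv+pool.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        k1, k2 = spec.conv_kernels
        o1, o2 = spec.conv_maps
        n_paths = 2 * spec.n_parts
        self.paths = [Conv1d(3, o1, k1, rng) for _ in range(n_paths)]
        self.merge = Conv1d(n_paths * o1, o2, k2, rng)
        seg = spec.window // spec.n_parts
        L = _pooled_len(seg, 2, spec.pool)
        self.fc1 = Dense(o2 * L, spec.hidden[0], rng)
        self.fc2 = Dense(spec.hidden[0], spec.hidden[1], rng)
        self.out = Dense(spec.hidden[1], spec.n_classes, rng)

    def forward_parts(self, x: Tensor):
        B = x.data.shape[0]
        n_paths = 2 * self.spec.n_parts
        maps = []
        for p in range(n_paths):
            seg = x.narrow(1, p, 1).reshape(B, 3, -1)
            maps.append(max_pool1d(self.paths[p](seg).relu(), self.spec.pool))
        merged = concat(maps, axis=1)
        pooled = max_pool1d(self.merge(merged).relu(), self.spec.pool)
        h2 = self.fc2(self.fc1(pooled.reshape(B, -1)).relu()).relu()
        return self.out(h2), pooled, h2

    def __call__(self, inputs) -> Tensor:
        return self.forward_parts(inputs[0])[0]


class MPCNN(Module):
    """Fused multipath classifier (variant 1: GB+S; variant 2: GB+D+S)."""

    def __init__(self, spec: NetworkSpec, n_states: int,
                 rng: np.random.Generator, variant: int = 1):
        if variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        self.spec = spec
        self.variant = variant
        o2 = spec.conv_maps[1]
        self.gb = GBCNN(spec, rng)
        self.s = SCNN(spec, n_states, rng)
        self.d = DCNN(spec, rng) if variant == 2 else None

        L = _pooled_len(spec.window, 2, spec.pool)  # second-pooling length
        feat_dim = spec.hidden[1] + n_states * n_states  # gb h2 + s output
        self.middle = []
        if spec.fusion_depth > 0:
            c_in = 2 * o2
            Lm = L
            for _ in range(spec.fusion_depth):
                self.middle.append(Conv1d(c_in, spec.fusion_maps,
                                          spec.conv_kernels[1], rng))
                c_in = spec.fusion_maps
                Lm //= spec.pool
            if Lm < 1:
                raise ValueError("fusion_depth too large for the window; "
                                 "middle path collapsed to zero length")
            feat_dim += spec.fusion_maps * Lm
        if variant == 2:
            seg = spec.window // spec.n_parts
            Ld = _pooled_len(seg, 2, spec.pool)
            self.d_fuse = Conv1d(o2, spec.fusion_maps, spec.conv_kernels[1],
                                 rng)
            feat_dim += spec.fusion_maps * (Ld // spec.pool) + spec.hidden[1]
        self.fc1 = Dense(feat_dim, spec.hidden[0], rng)
        self.fc2 = Dense(spec.hidden[0], spec.hidden[1], rng)
        self.out = Dense(spec.hidden[1], spec.n_classes, rng)

    def __call__(self, inputs) -> Tensor:
        x_gb, x_s = inputs[0], inputs[1]
        B = x_gb.data.shape[0]
        _, gb_pool, gb_h2 = self.gb.forward_parts(x_gb)
        s_out, s_pool, _ = self.s.forward_parts(x_s)
        feats = [gb_h2, s_out]
        if self.middle:
            m = concat([gb_pool, s_pool], axis=1)
            for conv in self.middle:
                m = max_pool1d(conv(m).relu(), self.spec.pool)
            feats.append(m.reshape(B, -1))
        if self.variant == 2:
            _, d_pool, d_h2 = self.d.forward_parts(inputs[2])
            df = max_pool1d(self.d_fuse(d_pool).relu(), self.spec.pool)
            feats.extend([df.reshape(B, -1), d_h2])
        h = concat(feats, axis=1)
        h2 = self.fc2(self.fc1(h).relu()).relu()
        return self.out(h2)

    def load_pretrained(self, scnn: SCNN | None = None,
                        dcnn: DCNN | None = None) -> None:
        """Initialize sub-network weights from separately trained models."""
        if scnn is not None:
            self.s.load_state_dict(scnn.state_dict())
        if dcnn is not None:
            if self.d is None:
                raise ValueError("variant 1 has no D-CNN sub-network")
            self.d.load_state_dict(dcnn.state_dict())


def build_gbcnn(spec: NetworkSpec, seed: int = 0) -> GBCNN:
    return GBCNN(spec, np.random.default_rng(seed))


def build_scnn(spec: NetworkSpec, n_states: int, seed: int = 0) -> SCNN:
    return SCNN(spec, n_states, np.random.default_rng(seed))


def build_scnn_classifier(spec: NetworkSpec, n_states: int,
                          seed: int = 0) -> SCNNClassifier:
    return SCNNClassifier(spec, n_states, np.random.default_rng(seed))


def build_dcnn(spec: NetworkSpec, seed: int = 0) -> DCNN:
    return DCNN(spec, np.random.default_rng(seed))


def build_mpcnn(spec: NetworkSpec, n_states: int, seed: int = 0,
                variant: int = 1, fusion_depth: int | None = None) -> MPCNN:
    if fusion_depth is not None:
        spec = replace(spec, fusion_depth=fusion_depth)
    return MPCNN(spec, n_states, np.random.default_rng(seed), variant=variant)


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)


def train(model: Module, inputs: list[np.ndarray], targets: np.ndarray,
          cfg: TrainConfig, pretrained: dict | None = None) -> TrainHistory:
    """SGD training loop.

    Integer `targets` mean classification (softmax cross-entropy); float
    targets mean regression (MSE, the S-CNN case).  `pretrained` may carry
    {"scnn": SCNN, "dcnn": DCNN} to initialize an MP-CNN's sub-networks.
    Raises on NaN loss.
    """
    if pretrained:
        if not isinstance(model, MPCNN):
            raise ValueError("pretrained initialization targets the MP-CNN")
        model.load_pretrained(scnn=pretrained.get("scnn"),
                              dcnn=pretrained.get("dcnn"))
    classification = np.issubdtype(np.asarray(targets).dtype, np.integer)
    n = len(targets)
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    hist = TrainHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = [Tensor(x[idx]) for x in inputs]
            opt.zero_grad()
            out = model(xb)
            if classification:
                loss, probs = softmax_cross_entropy(out, targets[idx])
                correct += int((probs.argmax(axis=1) == targets[idx]).sum())
            else:
                loss = ((out - Tensor(targets[idx])) ** 2.0).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (NaN/inf loss) at epoch {epoch}")
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
        hist.loss.append(ep_loss / n)
        if classification:
            hist.accuracy.append(correct / n)
    return hist


def predict(model: Module, inputs: list[np.ndarray],
            batch_size: int = 256) -> np.ndarray:
    """Forward pass in batches; returns raw outputs (logits or regression)."""
    outs = []
    n = len(inputs[0])
    for start in range(0, n, batch_size):
        xb = [Tensor(x[start:start + batch_size]) for x in inputs]
        outs.append(model(xb).data)
    return np.concatenate(outs, axis=0)


def accuracy(model: Module, inputs: list[np.ndarray],
             y: np.ndarray) -> float:
    return float((predict(model, inputs).argmax(axis=1) == y).mean())


def save_checkpoint(path, model: MPCNN, spec: NetworkSpec, n_states: int,
                    variant: int) -> None:
    """Weights as an npz plus a JSON sidecar with the architecture."""
    import json
    from pathlib import Path

    path = Path(path)
    state = model.state_dict()
    np.savez_compressed(path, **{f"p{i}": a for i, a in enumerate(state)})
    sidecar = {"spec": {k: list(v) if isinstance(v, tuple) else v
                        for k, v in vars(spec).items()},
               "n_states": n_states, "variant": variant}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[MPCNN, NetworkSpec, int, int]:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    raw = sidecar["spec"]
    spec = NetworkSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in raw.items()})
    model = build_mpcnn(spec, sidecar["n_states"], seed=0,
                        variant=sidecar["variant"])
    with np.load(path) as data:
        state = [data[f"p{i}"] for i in range(len(data.files))]
    model.load_state_dict(state)
    return model, spec, sidecar["n_states"], sidecar["variant"]
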