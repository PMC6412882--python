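"""End-to-end orchestration: dataset assembly and the three-task training
schedule (state-CNN targets and training, GMM-GMR and D-CNN, fused MP-CNN
with pre-trained sub-networks), plus the evaluation-model stage.

Everything here is a pure function of (recordings, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import evaluate as ev
from . import gmr, models, pfsa
from .preprocess import (SignalRecording, denoise_normalize,
                         gravity_body_split, segment_repetitions,
                         sliding_windows)

__all__ = [
    "PipelineConfig", "WindowDataset", "build_window_dataset",
    "compute_transition_targets", "fit_class_models", "assign_segments",
    "build_segment_dataset", "run_recognition", "run_evaluation",
    "train_test_split_subjects", "benchmark_config",
]


@dataclass
class PipelineConfig:
    window_size: int = 80
    window_overlap: float = 0.5
    median_size: int = 3
    lowpass_cutoff_hz: float = 0.3
    lowpass_order: int = 3
    fs: float = 32.0
    n_reps: int = 10
    K_q: int = 10                 # quantization levels per axis
    C_states: int = 6             # dictionary states per class
    K_g: int = 5                  # GMM components per class per feature
    N_p: int = 4                  # D-CNN parts/channels per feature
    spec: models.NetworkSpec = field(default_factory=lambda: models.SMALL_SPEC)
    train_cfg: models.TrainConfig = field(default_factory=models.TrainConfig)
    eval_cfg: ev.EvalTrainConfig = field(default_factory=ev.EvalTrainConfig)
    test_fraction: float = 0.3    # held-out subject fraction

    def content_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)
        return hashlib.sha256(
            json.dumps(self, default=enc, sort_keys=True).encode()
        ).hexdigest()[:16]


def benchmark_config() -> PipelineConfig:
    """Desk-scale configuration of the synthetic benchmark: compact
    networks and epoch counts sized so the full study (recognition with all
    sub-networks over several seeds, plus the evaluation model) runs in
    minutes on one CPU while every model converges."""
    return PipelineConfig(
        spec=models.SMALL_SPEC,
        train_cfg=models.TrainConfig(epochs=12),
        eval_cfg=ev.EvalTrainConfig(
            lstm_dims=(24, 24, 20), dense_dims=(24, 16), resize_len=48,
            epochs=60, batch_size=16, lr=0.03),
    )


@dataclass
class WindowDataset:
    """Model-ready windows: normalized raw, stacked gravity+body, labels."""

    X_raw: np.ndarray       # (N, 3, W) denoised, min-max normalized
    X_gb: np.ndarray        # (N, 6, W) gravity (3) then body (3)
    y_action: np.ndarray
    y_level: np.ndarray
    subject: np.ndarray
    origin: list

    def __len__(self) -> int:
        return len(self.y_action)


def build_window_dataset(recordings: list[SignalRecording],
                         cfg: PipelineConfig) -> WindowDataset:
    raws, gbs, ya, yl, subj, origin = [], [], [], [], [], []
    for rec in recordings:
        for win in sliding_windows(rec, cfg.window_size, cfg.window_overlap):
            clean = denoise_normalize(win, cfg.median_size)
            pair = gravity_body_split(clean, cfg.lowpass_cutoff_hz,
                                      cfg.lowpass_order, rec.fs)
            raws.append(clean.values.T)
            gbs.append(np.concatenate([pair.gravity.T, pair.body.T], axis=0))
            ya.append(rec.action_label)
            yl.append(rec.level_label)
            subj.append(rec.subject)
            origin.append(win.origin)
    return WindowDataset(np.stack(raws), np.stack(gbs), np.array(ya),
                         np.array(yl), np.array(subj), origin)


def train_test_split_subjects(ds: WindowDataset, test_fraction: float = 0.3,
                              seed: int = 0):
    """Subject-disjoint split (windows of one subject never straddle the
    boundary)."""
    subjects = np.unique(ds.subject)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_test = max(1, int(round(test_fraction * len(subjects))))
    test_subjects = set(perm[:n_test].tolist())
    test_mask = np.array([s in test_subjects for s in ds.subject])
    return ~test_mask, test_mask


def compute_transition_targets(ds: WindowDataset, train_mask: np.ndarray,
                               cfg: PipelineConfig):
    """Fit per-axis quantizers and the state dictionary on training windows,
    then compute every window's averaged transition-matrix target."""
    train_idx = np.where(train_mask)[0]
    quantizers = [
        pfsa.fit_quantizer([ds.X_raw[i, a] for i in train_idx], cfg.K_q)
        for a in range(3)
    ]
    encoded: dict[int, list] = {}
    enc_cache: list = [None] * len(ds)
    for i in train_idx:
        enc = pfsa.encode_window(ds.X_raw[i].T, quantizers)
        enc_cache[i] = enc
        encoded.setdefault(int(ds.y_action[i]), []).extend(enc)
    D = pfsa.build_state_dictionary(encoded, cfg.C_states)
    n = len(D)
    targets = np.empty((len(ds), n * n))
    map_cache: dict = {}

    def mapped(s):
        if s not in map_cache:
            map_cache[s] = pfsa.map_state(s, D)
        return map_cache[s]

    for i in range(len(ds)):
        enc = enc_cache[i] or pfsa.encode_window(ds.X_raw[i].T, quantizers)
        mats = []
        for axis_states in enc:
            m = [mapped(s) for s in axis_states]
            if len(m) < 2:
                m = m * 2
            mats.append(pfsa.transition_matrix(m, D).pi)
        targets[i] = np.mean(mats, axis=0).reshape(-1)
    return targets, quantizers, D


def fit_class_models(ds: WindowDataset, train_mask: np.ndarray,
                     cfg: PipelineConfig, seed: int = 0):
    """Per-class GMM-GMR models of the gravity and body features."""
    out: dict[int, dict[str, gmr.GmmGmrModel]] = {}
    W = cfg.window_size
    t = np.tile((np.arange(W) + 0.5) / W, 1)
    for cls in np.unique(ds.y_action):
        idx = np.where(train_mask & (ds.y_action == cls))[0]
        out[int(cls)] = {}
        for name, sl in (("gravity", slice(0, 3)), ("body", slice(3, 6))):
            feats = ds.X_gb[idx][:, sl, :]          # (n, 3, W)
            pts = np.concatenate([
                np.column_stack([t, f.T]) for f in feats], axis=0)
            out[int(cls)][name] = gmr.fit_gmm_gmr(pts, cfg.K_g,
                                                  seed=seed + int(cls))
    return out


def _trajectory_stats(model: gmr.GmmGmrModel, W: int):
    times = (np.arange(W) + 0.5) / W
    traj = gmr.conditional_trajectory(model, times)
    inv = np.linalg.inv(traj.cov)
    return traj.mean, inv


def assign_segments(ds: WindowDataset, class_models: dict,
                    cfg: PipelineConfig,
                    labels: np.ndarray | None = None) -> np.ndarray:
    """Route each window's gravity/body parts to their best-matching model
    parts (vectorized equivalent of per-window dynamic assignment).

    With `labels`, each window uses its own class's model; otherwise the
    class model with the lowest total matched cost wins.
    Returns (N, 2*N_p, 3, W/N_p).
    """
    from scipy.optimize import linear_sum_assignment

    W, N_p = cfg.window_size, cfg.N_p
    L = W // N_p
    N = len(ds)
    classes = sorted(class_models)
    stats = {c: {f: _trajectory_stats(class_models[c][f], W)
                 for f in ("gravity", "body")} for c in classes}
    feats = {"gravity": ds.X_gb[:, 0:3, :].transpose(0, 2, 1),
             "body": ds.X_gb[:, 3:6, :].transpose(0, 2, 1)}   # (N, W, 3)
    # cost[c][f] has shape (N, N_p, N_p)
    cost: dict = {}
    for c in classes:
        cost[c] = {}
        for f in ("gravity", "body"):
            mean, inv = stats[c][f]
            cm = np.empty((N, N_p, N_p))
            for i in range(N_p):
                seg = feats[f][:, i * L:(i + 1) * L]           # (N, L, 3)
                for j in range(N_p):
                    sl = slice(j * L, (j + 1) * L)
                    diff = seg - mean[sl][None]
                    cm[:, i, j] = np.einsum("nlc,lcd,nld->nl", diff,
                                            inv[sl], diff,
                                            optimize=True).mean(axis=1)
            cost[c][f] = cm

    X_d = np.empty((N, 2 * N_p, 3, L))
    for nidx in range(N):
        if labels is not None:
            best_c = int(labels[nidx])
        else:
            totals = []
            for c in classes:
                tot = 0.0
                for f in ("gravity", "body"):
                    r, col = linear_sum_assignment(cost[c][f][nidx])
                    tot += cost[c][f][nidx][r, col].sum()
                totals.append(tot)
            best_c = classes[int(np.argmin(totals))]
        for fi, f in enumerate(("gravity", "body")):
            r, col = linear_sum_assignment(cost[best_c][f][nidx])
            mapping = np.empty(N_p, dtype=int)
            mapping[r] = col            # segment -> channel
            inv_map = np.empty(N_p, dtype=int)
            inv_map[mapping] = np.arange(N_p)
            for ch in range(N_p):
                seg = feats[f][nidx, inv_map[ch] * L:(inv_map[ch] + 1) * L]
                X_d[nidx, fi * N_p + ch] = seg.T
    return X_d


def build_segment_dataset(recordings: list[SignalRecording],
                          cfg: PipelineConfig):
    """Single-repetition segments resized to a fixed length, for the
    evaluation model.  Recordings that defeat segmentation are skipped."""
    X, ya, yl, subj = [], [], [], []
    for rec in recordings:
        try:
            res = segment_repetitions(rec, cfg.n_reps)
        except Exception:
            continue
        for seg in res.segments:
            X.append(ev.resize_signal(seg, cfg.eval_cfg.resize_len))
            ya.append(rec.action_label)
            yl.append(rec.level_label)
            subj.append(rec.subject)
    return (np.stack(X), np.array(ya), np.array(yl), np.array(subj))


@dataclass
class RecognitionResult:
    accuracies: dict
    histories: dict
    n_states: int
    n_train: int
    n_test: int
    model: models.MPCNN | None = None
    variant: int = 1


def run_recognition(recordings: list[SignalRecording], cfg: PipelineConfig,
                    seed: int = 0, variant: int = 2,
                    include_subnetworks: bool = True,
                    cache_dir=None) -> RecognitionResult:
    """The three-task schedule on a subject-disjoint split.

    Task 1: transition-matrix targets and S-CNN training.
    Task 2: GMM-GMR models, dynamic assignment, D-CNN training.
    Task 3: MP-CNN with the S-CNN (and D-CNN) as pre-trained weights.
    Returns test accuracies of the fused model and (optionally) each
    sub-network.  With `cache_dir`, the symbolic-coding targets (the slow
    stage) are cached on disk keyed by the config/split hash.
    """
    ds = build_window_dataset(recordings, cfg)
    train_mask, test_mask = train_test_split_subjects(
        ds, cfg.test_fraction, seed)
    tr, te = np.where(train_mask)[0], np.where(test_mask)[0]
    y = ds.y_action
    spec = cfg.spec
    tc = models.TrainConfig(**{**vars(cfg.train_cfg), "seed": seed})

    # Task 1 — state-CNN
    targets = None
    if cache_dir is not None:
        from pathlib import Path
        key = hashlib.sha256(
            (cfg.content_hash() + str(len(ds)) + str(tr[:50].tolist()))
            .encode()).hexdigest()[:16]
        cache_file = Path(cache_dir) / f"targets_{key}.npz"
        if cache_file.exists():
            targets = np.load(cache_file)["targets"]
            n_states = int(round(np.sqrt(targets.shape[1])))
    if targets is None:
        targets, quantizers, D = compute_transition_targets(
            ds, train_mask, cfg)
        n_states = len(D)
        if cache_dir is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(cache_file, targets=targets)
    scnn = models.build_scnn(spec, n_states, seed=seed)
    h_s = models.train(scnn, [ds.X_raw[tr]], targets[tr], tc)

    # Task 2 — GMM-GMR + D-CNN
    class_models = fit_class_models(ds, train_mask, cfg, seed=seed)
    X_d = np.empty((len(ds), 2 * cfg.N_p, 3, cfg.window_size // cfg.N_p))
    X_d[tr] = assign_segments(
        _subset(ds, tr), class_models, cfg, labels=y[tr])
    X_d[te] = assign_segments(_subset(ds, te), class_models, cfg)
    dcnn = models.build_dcnn(spec, seed=seed)
    h_d = models.train(dcnn, [X_d[tr]], y[tr], tc)

    # Task 3 — fused model with pre-trained sub-networks
    mp = models.build_mpcnn(spec, n_states, seed=seed, variant=variant)
    mp_inputs_tr = [ds.X_gb[tr], ds.X_raw[tr]]
    mp_inputs_te = [ds.X_gb[te], ds.X_raw[te]]
    pre = {"scnn": scnn}
    if variant == 2:
        mp_inputs_tr.append(X_d[tr])
        mp_inputs_te.append(X_d[te])
        pre["dcnn"] = dcnn
    h_mp = models.train(mp, mp_inputs_tr, y[tr], tc, pretrained=pre)

    accs = {"mpcnn": models.accuracy(mp, mp_inputs_te, y[te]),
            "dcnn": models.accuracy(dcnn, [X_d[te]], y[te])}
    hists = {"scnn": h_s, "dcnn": h_d, "mpcnn": h_mp}
    if include_subnetworks:
        gb = models.build_gbcnn(spec, seed=seed)
        hists["gbcnn"] = models.train(gb, [ds.X_gb[tr]], y[tr], tc)
        accs["gbcnn"] = models.accuracy(gb, [ds.X_gb[te]], y[te])
        sc = models.build_scnn_classifier(spec, n_states, seed=seed)
        sc.scnn.load_state_dict(scnn.state_dict())
        hists["scnn_cls"] = models.train(sc, [ds.X_raw[tr]], y[tr], tc)
        accs["scnn"] = models.accuracy(sc, [ds.X_raw[te]], y[te])
    return RecognitionResult(accuracies=accs, histories=hists,
                             n_states=n_states, n_train=len(tr),
                             n_test=len(te), model=mp, variant=variant)


def _subset(ds: WindowDataset, idx: np.ndarray) -> WindowDataset:
    return WindowDataset(ds.X_raw[idx], ds.X_gb[idx], ds.y_action[idx],
                         ds.y_level[idx], ds.subject[idx],
                         [ds.origin[i] for i in idx])


@dataclass
class EvaluationResult:
    joint_accuracy: float
    median_scores: dict          # (action, level) -> median evaluation
    heads: ev.EvalHeads
    history: ev.EvalHistory
    n_train: int
    n_test: int


def run_evaluation(recordings: list[SignalRecording], cfg: PipelineConfig,
                   seed: int = 0, interval: float = 100.0
                   ) -> EvaluationResult:
    """Train the quality-evaluation model on repetition segments and score
    the held-out subjects."""
    X, ya, yl, subj = build_segment_dataset(recordings, cfg)
    subjects = np.unique(subj)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_test = max(1, int(round(cfg.test_fraction * len(subjects))))
    test_set = set(perm[:n_test].tolist())
    te = np.array([s in test_set for s in subj])
    tr = ~te
    ecfg = ev.EvalTrainConfig(**{**vars(cfg.eval_cfg), "seed": seed})
    model, heads, hist = ev.train_evaluation_model(
        X[tr], ya[tr], yl[tr], ecfg)
    logits = []
    feats = []
    from .nn import Tensor
    for start in range(0, te.sum(), 128):
        xb = Tensor(X[te][start:start + 128])
        f = model.features(xb)
        feats.append(f.data)
        logits.append(model.classifier(f).data)
    feats = np.concatenate(feats)
    logits = np.concatenate(logits)
    L = heads.n_levels
    pred_joint = logits.argmax(axis=1)
    y_joint = ya[te] * L + yl[te]
    joint_acc = float((pred_joint == y_joint).mean())
    med: dict = {}
    evals = np.array([
        ev.evaluate_sample(feats[i], heads, int(pred_joint[i] // L),
                           interval).evaluation
        for i in range(len(feats))])
    for action in np.unique(ya[te]):
        for level in np.unique(yl[te]):
            m = (ya[te] == action) & (yl[te] == level)
            if m.any():
                med[(int(action), int(level))] = float(np.median(evals[m]))
    return EvaluationResult(joint_accuracy=joint_acc, median_scores=med,
                            heads=heads, history=hist,
                            n_train=int(tr.sum()), n_test=int(te.sum()))
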