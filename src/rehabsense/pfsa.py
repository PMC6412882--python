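"""Symbolic state-transition features: quantization, two-pass LZW coding,
state dictionaries, and PFSA transition-probability matrices.

The pipeline turns a 1-D signal into a sequence of quantization levels,
parses it with a fixed LZW dictionary into multi-level "states", maps rare
states onto a small per-class state dictionary by token-level Levenshtein
distance, and summarizes the state sequence as a row-stochastic transition
matrix.  The flattened matrix is the regression target of the state CNN.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LevelQuantizer", "LzwTable", "StateDictionary", "TransitionMatrix",
    "fit_quantizer", "symbolize", "lzw_build_table", "lzw_encode",
    "build_state_dictionary", "map_state", "levenshtein", "transition_matrix",
    "window_transition_target",
]

State = tuple[int, ...]


class DegenerateDataError(ValueError):
    pass


@dataclass
class LevelQuantizer:
    """Equal-count quantizer: K_q levels split at empirical quantile points."""

    n_levels: int
    boundaries: np.ndarray  # K_q - 1 ascending thresholds

    def to_json(self) -> str:
        return json.dumps({"n_levels": self.n_levels,
                           "boundaries": self.boundaries.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "LevelQuantizer":
        d = json.loads(s)
        return cls(d["n_levels"], np.asarray(d["boundaries"], dtype=float))


@dataclass
class LzwTable:
    """Ordered, prefix-closed set of token-strings grown by the LZW pass."""

    entries: list[State]

    def __post_init__(self):
        self._set = set(self.entries)

    def __contains__(self, s: State) -> bool:
        return s in self._set

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, s: State) -> None:
        if s not in self._set:
            self.entries.append(s)
            self._set.add(s)


@dataclass
class StateDictionary:
    """The most frequent LZW states per class, deduplicated across classes."""

    states: list[State]

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ValueError("state dictionary contains duplicates")
        self._index = {s: i for i, s in enumerate(self.states)}

    def __len__(self) -> int:
        return len(self.states)

    def index(self, s: State) -> int:
        return self._index[s]

    def to_json(self) -> str:
        return json.dumps([list(s) for s in self.states])

    @classmethod
    def from_json(cls, s: str) -> "StateDictionary":
        return cls([tuple(x) for x in json.loads(s)])


@dataclass
class TransitionMatrix:
    """Row-stochastic PFSA transition probabilities over a state dictionary."""

    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 2 or self.pi.shape[0] != self.pi.shape[1]:
            raise ValueError("pi must be square")
        if np.any(self.pi < 0) or not np.allclose(self.pi.sum(axis=1), 1.0,
                                                  atol=1e-9):
            raise ValueError("pi must be row-stochastic")

    def flatten(self) -> np.ndarray:
        return self.pi.reshape(-1)


def fit_quantizer(training_signals, K_q: int = 10) -> LevelQuantizer:
    """Concatenate all training signals, sort ascending, and place level
    boundaries at the equal-count split points.

    Boundary values themselves belong to the lower level (ties go down).
    """
    if K_q < 2:
        raise ValueError("K_q must be >= 2")
    v = np.sort(np.concatenate([np.asarray(s, dtype=float).ravel()
                                for s in training_signals]))
    if len(v) < K_q:
        raise ValueError("need at least K_q samples to fit the quantizer")
    idx = [(i * len(v)) // K_q - 1 for i in range(1, K_q)]
    boundaries = v[idx]
    if np.any(np.diff(boundaries) <= 0) or len(set(boundaries.tolist())) != K_q - 1:
        raise DegenerateDataError(
            "training values too concentrated for distinct level boundaries")
    return LevelQuantizer(K_q, boundaries)


def symbolize(q: LevelQuantizer, series) -> np.ndarray:
    """Map each sample to its level index; a value equal to a boundary maps
    to the level below it."""
    x = np.asarray(series, dtype=float).ravel()
    return np.searchsorted(q.boundaries, x, side="left").astype(int)


def lzw_build_table(seq) -> LzwTable:
    """First LZW pass: grow the table from the single tokens present.

    P starts at the first token; on a miss P+C is added and P resets to C,
    on a hit P extends to P+C.
    """
    seq = [int(s) for s in seq]
    if len(seq) == 0:
        raise ValueError("cannot build LZW table from an empty sequence")
    table = LzwTable([])
    for tok in seq:  # seed with single tokens in order of first appearance
        table.add((tok,))
    P: State = (seq[0],)
    for C in seq[1:]:
        PC = P + (C,)
        if PC in table:
            P = PC
        else:
            table.add(PC)
            P = (C,)
    return table


def lzw_encode(seq, table: LzwTable) -> list[State]:
    """Second LZW pass: greedy longest-match parse with the FIXED table.

    Emits the matched entry at every break plus the final pending P.
    Concatenating the emitted states reproduces the input exactly.
    """
    seq = [int(s) for s in seq]
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    if (seq[0],) not in table:
        raise KeyError(f"token {seq[0]} absent from table")
    out: list[State] = []
    P: State = (seq[0],)
    for C in seq[1:]:
        if (C,) not in table:
            raise KeyError(f"token {C} absent from table")
        PC = P + (C,)
        if PC in table:
            P = PC
        else:
            out.append(P)
            P = (C,)
    out.append(P)
    return out


def build_state_dictionary(encoded_per_class: dict[int, list[list[State]]],
                           C_states: int = 6) -> StateDictionary:
    """Per class, keep the C_states most frequently emitted states; the
    dictionary is their union, deduplicated in class-then-rank order.

    Frequency ties prefer the longer (more specific) state, then
    lexicographic order, so builds are deterministic.
    """
    states: list[State] = []
    seen: set[State] = set()
    for cls in sorted(encoded_per_class):
        counts: Counter = Counter()
        for enc in encoded_per_class[cls]:
            counts.update(enc)
        if len(counts) == 0:
            raise ValueError(f"class {cls} emitted no states")
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))
        if len(ranked) < C_states:
            warnings.warn(f"class {cls} has only {len(ranked)} distinct states "
                          f"(< {C_states}); taking all", stacklevel=2)
        for s, _ in ranked[:C_states]:
            if s not in seen:
                seen.add(s)
                states.append(s)
    return StateDictionary(states)


def levenshtein(a: State, b: State) -> int:
    """Token-level edit distance (insert/delete/substitute, unit costs)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def map_state(s_u: State, D: StateDictionary) -> State:
    """Quantize a state onto the dictionary: the entry minimizing token-level
    Levenshtein distance; ties go to the earlier dictionary entry."""
    if len(D) == 0:
        raise ValueError("empty state dictionary")
    if s_u in D._index:
        return s_u
    best = min(D.states, key=lambda sk: (levenshtein(s_u, sk), D.index(sk)))
    return best


def transition_matrix(states: list[State], D: StateDictionary) -> TransitionMatrix:
    """Count consecutive transitions of a mapped state sequence and
    row-normalize; rows without outgoing transitions become uniform."""
    if len(states) < 2:
        raise ValueError("need at least 2 states for a transition matrix")
    n = len(D)
    counts = np.zeros((n, n))
    idx = [D.index(s) for s in states]
    for a, b in zip(idx[:-1], idx[1:]):
        counts[a, b] += 1
    rows = counts.sum(axis=1)
    pi = np.empty_like(counts)
    for i in range(n):
        if rows[i] == 0:
            pi[i] = 1.0 / n
        else:
            pi[i] = counts[i] / rows[i]
    return TransitionMatrix(pi)


def encode_window(window_values: np.ndarray,
                  quantizers: list[LevelQuantizer]) -> list[list[State]]:
    """Per-axis symbolize then two-pass LZW (table built from the window's
    own sequence, encoding with that fixed table)."""
    out = []
    for a in range(3):
        sym = symbolize(quantizers[a], window_values[:, a])
        table = lzw_build_table(sym)
        out.append(lzw_encode(sym, table))
    return out


def window_transition_target(window_values: np.ndarray,
                             quantizers: list[LevelQuantizer],
                             D: StateDictionary) -> np.ndarray:
    """Per-axis encode → map onto D → transition matrix, averaged over the
    three axes and flattened row-major (the state-CNN regression target)."""
    mats = []
    for enc in encode_window(window_values, quantizers):
        mapped = [map_state(s, D) for s in enc]
        if len(mapped) < 2:
            mapped = mapped * 2  # degenerate single-state window
        mats.append(transition_matrix(mapped, D).pi)
    return np.mean(mats, axis=0).reshape(-1)
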