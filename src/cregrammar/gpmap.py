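"""Genotype-phenotype maps over symbolic CRE sequences.

A CRE's latent phenotype phi is a scalar that is linear in one-hot sequence
features:

    phi(s) = theta0 + sum_i theta_add[i, s_i]
                    + sum_{i<j allowed} theta_pair[i, j, s_i, s_j]

with the allowed pair set determined by the architecture: none (additive),
adjacent positions only (neighbor), or all position pairs (pairwise).
Because adding a constant to all characters at one position (and similar
shifts of pair blocks) leaves phi unchanged, parameters are only defined up
to a gauge.  Two gauges are provided: the uniform gauge (zero mean over
characters at every position, and zero row/column means of every pair
block) and the consensus gauge (all parameters that involve only consensus
characters are zero, so phi(consensus) = theta0).  Both are verified to
preserve phi rather than trusted algebraically.

Characters that cannot occur at a position (e.g. promoter codes at site
positions) simply have no parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GPMapParams",
    "FeatureMap",
    "allowed_pairs",
    "phi",
    "phi_many",
    "one_hot_encode",
    "gauge_fix_uniform",
    "gauge_fix_consensus",
    "position_averaged_params",
    "ParamSummary",
]

ARCHITECTURES = ("additive", "neighbor", "pairwise")


def allowed_pairs(length: int, architecture: str) -> list[tuple[int, int]]:
    """Position pairs (i < j) carrying interaction parameters."""
    if architecture == "additive":
        return []
    if architecture == "neighbor":
        return [(i, i + 1) for i in range(length - 1)]
    if architecture == "pairwise":
        return [(i, j) for i in range(length) for j in range(i + 1, length)]
    raise ValueError(f"unknown architecture {architecture!r}")


@dataclass
class GPMapParams:
    """Constant + position-specific additive + position-pair parameters.

    ``position_alphabets[i]`` lists the characters allowed at position i;
    ``theta_add`` maps (i, char) and ``theta_pair`` maps (i, j, char_i,
    char_j) with i < j restricted to the architecture's allowed pairs.
    """

    position_alphabets: tuple[tuple[str, ...], ...]
    architecture: str = "pairwise"
    theta0: float = 0.0
    theta_add: dict = field(default_factory=dict)
    theta_pair: dict = field(default_factory=dict)
    gauge: str = "none"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        self.position_alphabets = tuple(tuple(a) for a in self.position_alphabets)
        ok = set(allowed_pairs(self.length, self.architecture))
        for i, j, *_ in self.theta_pair:
            if (i, j) not in ok:
                raise ValueError(f"pair ({i},{j}) not allowed for {self.architecture}")

    @property
    def length(self) -> int:
        return len(self.position_alphabets)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return allowed_pairs(self.length, self.architecture)

    def add(self, i: int, ch: str) -> float:
        return self.theta_add.get((i, ch), 0.0)

    def pair(self, i: int, j: int, a: str, b: str) -> float:
        return self.theta_pair.get((i, j, a, b), 0.0)

    def check_sequence(self, seq: str) -> None:
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != parameter grid {self.length}")
        for i, ch in enumerate(seq):
            if ch not in self.position_alphabets[i]:
                raise KeyError(f"character {ch!r} not allowed at position {i}")

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "position_alphabets": [list(a) for a in self.position_alphabets],
            "architecture": self.architecture,
            "gauge": self.gauge,
            "theta0": self.theta0,
            "theta_add": [[i, ch, v] for (i, ch), v in sorted(self.theta_add.items())],
            "theta_pair": [
                [i, j, a, b, v] for (i, j, a, b), v in sorted(self.theta_pair.items())
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GPMapParams":
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        return cls(
            position_alphabets=tuple(tuple(a) for a in obj["position_alphabets"]),
            architecture=obj["architecture"],
            gauge=obj.get("gauge", "none"),
            theta0=float(obj["theta0"]),
            theta_add={(i, ch): float(v) for i, ch, v in obj["theta_add"]},
            theta_pair={(i, j, a, b): float(v) for i, j, a, b, v in obj["theta_pair"]},
        )


def phi(seq: str, params: GPMapParams) -> float:
    """Latent phenotype of one encoded sequence."""
    params.check_sequence(seq)
    val = params.theta0
    for i, ch in enumerate(seq):
        val += params.add(i, ch)
    for i, j in params.pairs:
        val += params.pair(i, j, seq[i], seq[j])
    return float(val)


def phi_many(seqs, params: GPMapParams) -> np.ndarray:
    """Vectorized phi over an iterable of sequences."""
    fm = FeatureMap(params.position_alphabets, params.architecture)
    X = fm.encode_many(seqs)
    return X @ fm.weights_from_params(params) + params.theta0


class FeatureMap:
    """One-hot feature layout for a fixed-length symbolic alphabet.

    Features are ordered: the additive block (one indicator per
    (position, allowed character)) followed by the pair block (one
    indicator per (i, j, char_i, char_j) over the architecture's allowed
    position pairs).  Every encoded sequence has exactly L ones in the
    additive block and ``len(pairs)`` ones in the pair block.
    """

    def __init__(self, position_alphabets, architecture: str = "pairwise"):
        self.position_alphabets = tuple(tuple(a) for a in position_alphabets)
        self.architecture = architecture
        self.length = len(self.position_alphabets)
        self.pairs = allowed_pairs(self.length, architecture)
        self.add_keys: list[tuple[int, str]] = [
            (i, ch) for i, alpha in enumerate(self.position_alphabets) for ch in alpha
        ]
        self.pair_keys: list[tuple[int, int, str, str]] = [
            (i, j, a, b)
            for (i, j) in self.pairs
            for a in self.position_alphabets[i]
            for b in self.position_alphabets[j]
        ]
        self._add_index = {k: n for n, k in enumerate(self.add_keys)}
        self._pair_index = {k: len(self.add_keys) + n for n, k in enumerate(self.pair_keys)}

    @property
    def n_additive(self) -> int:
        return len(self.add_keys)

    @property
    def n_features(self) -> int:
        return len(self.add_keys) + len(self.pair_keys)

    def encode(self, seq: str) -> np.ndarray:
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != {self.length}")
        x = np.zeros(self.n_features)
        for i, ch in enumerate(seq):
            if (i, ch) not in self._add_index:
                raise KeyError(f"character {ch!r} not allowed at position {i}")
            x[self._add_index[(i, ch)]] = 1.0
        for i, j in self.pairs:
            x[self._pair_index[(i, j, seq[i], seq[j])]] = 1.0
        return x

    def encode_many(self, seqs) -> np.ndarray:
        return np.array([self.encode(s) for s in seqs])

    def decode(self, x: np.ndarray) -> str:
        """Recover the sequence from its additive one-hot block."""
        chars = [None] * self.length
        for n, (i, ch) in enumerate(self.add_keys):
            if x[n] == 1.0:
                if chars[i] is not None:
                    raise ValueError(f"two characters set at position {i}")
                chars[i] = ch
        if any(c is None for c in chars):
            raise ValueError("not a valid one-hot encoding")
        return "".join(chars)

    def weights_from_params(self, params: GPMapParams) -> np.ndarray:
        w = np.zeros(self.n_features)
        for k, v in params.theta_add.items():
            w[self._add_index[k]] = v
        for k, v in params.theta_pair.items():
            w[self._pair_index[k]] = v
        return w

    def params_from_weights(self, w: np.ndarray, theta0: float = 0.0) -> GPMapParams:
        theta_add = {k: float(w[self._add_index[k]]) for k in self.add_keys}
        theta_pair = {k: float(w[self._pair_index[k]]) for k in self.pair_keys}
        return GPMapParams(
            self.position_alphabets, self.architecture, float(theta0), theta_add, theta_pair
        )


def one_hot_encode(seq: str, position_alphabets, architecture: str = "pairwise") -> np.ndarray:
    """One-hot feature vector (additive block + pair block) for one sequence."""
    return FeatureMap(position_alphabets, architecture).encode(seq)


def gauge_fix_uniform(params: GPMapParams) -> GPMapParams:
    """Zero-mean gauge: closed-form mean subtraction, phi-preserving.

    Every pair block first sheds its row means, column means and grand
    mean into the additive parameters and the constant; then every
    position's additive parameters shed their mean into the constant.
    """
    theta0 = params.theta0
    add = {k: params.theta_add.get(k, 0.0) for k in _all_add_keys(params)}
    pair = {}
    for (i, j) in params.pairs:
        ai, aj = params.position_alphabets[i], params.position_alphabets[j]
        A = np.array([[params.pair(i, j, a, b) for b in aj] for a in ai])
        g = A.mean()
        r = A.mean(axis=1)
        c = A.mean(axis=0)
        A2 = A - r[:, None] - c[None, :] + g
        for ia, a in enumerate(ai):
            for ib, b in enumerate(aj):
                pair[(i, j, a, b)] = float(A2[ia, ib])
            add[(i, a)] += r[ia] - g
        for ib, b in enumerate(aj):
            add[(j, b)] += c[ib] - g
        theta0 += g
    for i, alpha in enumerate(params.position_alphabets):
        m = np.mean([add[(i, ch)] for ch in alpha])
        for ch in alpha:
            add[(i, ch)] = float(add[(i, ch)] - m)
        theta0 += m
    return replace(
        params, theta0=float(theta0), theta_add=add, theta_pair=pair, gauge="uniform"
    )


def gauge_fix_consensus(params: GPMapParams, consensus: str) -> GPMapParams:
    """Consensus gauge via finite differences of phi around the consensus.

    theta0' = phi(consensus); theta_add'[i,a] is the effect of substituting
    a at i into the consensus; theta_pair'[i,j,a,b] is the double
    substitution minus the two singles.  For models that are at most
    pairwise this reconstruction reproduces phi exactly, and every
    parameter involving only consensus characters vanishes.
    """
    params.check_sequence(consensus)
    base = phi(consensus, params)

    def sub(seq, i, ch):
        return seq[:i] + ch + seq[i + 1 :]

    single = {}
    add = {}
    for i, alpha in enumerate(params.position_alphabets):
        for a in alpha:
            single[(i, a)] = phi(sub(consensus, i, a), params)
            add[(i, a)] = float(single[(i, a)] - base)
    pair = {}
    for (i, j) in params.pairs:
        for a in params.position_alphabets[i]:
            for b in params.position_alphabets[j]:
                both = phi(sub(sub(consensus, i, a), j, b), params)
                pair[(i, j, a, b)] = float(both - single[(i, a)] - single[(j, b)] + base)
    return replace(
        params, theta0=float(base), theta_add=add, theta_pair=pair, gauge="consensus"
    )


def _all_add_keys(params: GPMapParams):
    return [(i, ch) for i, alpha in enumerate(params.position_alphabets) for ch in alpha]


@dataclass
class ParamSummary:
    """Position-averaged parameter summaries (heatmap-style tables).

    ``additive_mean[char]`` averages theta_add over the positions where the
    character can occur; ``pair_mean.loc[a, b]`` averages theta_pair over
    all allowed position pairs, with rows the 5' character and columns the
    3' character.  ``pair_table`` keeps the unaveraged position-specific
    values.
    """

    additive_mean: "pd.Series"
    pair_mean: "pd.DataFrame"
    pair_table: dict


def position_averaged_params(
    params: GPMapParams, exclude_chars: tuple[str, ...] = ("O", "_")
) -> ParamSummary:
    """Average parameters across CRE positions (gauge should be fixed first).

    The pad character is excluded from the summaries by default; characters
    that never occur at any position are simply absent (missing, not zero).
    """
    import pandas as pd

    add_vals: dict[str, list[float]] = {}
    for (i, ch), v in params.theta_add.items():
        if ch in exclude_chars:
            continue
        add_vals.setdefault(ch, []).append(v)
    additive_mean = pd.Series({ch: float(np.mean(vs)) for ch, vs in sorted(add_vals.items())})

    pair_vals: dict[tuple[str, str], list[float]] = {}
    for (i, j, a, b), v in params.theta_pair.items():
        if a in exclude_chars or b in exclude_chars:
            continue
        pair_vals.setdefault((a, b), []).append(v)
    chars_5p = sorted({a for a, _ in pair_vals})
    chars_3p = sorted({b for _, b in pair_vals})
    pair_mean = pd.DataFrame(np.nan, index=chars_5p, columns=chars_3p)
    for (a, b), vs in pair_vals.items():
        pair_mean.loc[a, b] = float(np.mean(vs))
    return ParamSummary(additive_mean, pair_mean, dict(params.theta_pair))
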