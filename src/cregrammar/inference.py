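"""Maximum-likelihood fitting of latent-phenotype models to MPRA activities.

The observation model, in the global-epistasis (GE) style, factors the data
into three learned pieces:

1. a genotype-phenotype map phi(x) — linear in one-hot features for the
   additive / nearest-neighbor / pairwise architectures, or a small
   multilayer perceptron for the "black box" architecture;
2. a monotone saturating measurement nonlinearity
   g(phi) = a + sum_k b_k tanh(c_k phi + d_k) with b_k, c_k >= 0, mapping
   the latent phenotype to the most probable measurement value; and
3. a heteroskedastic noise model for the measurement y around yhat = g(phi):
   either a Jones-Faddy skewed-t (mode-centred at yhat, with log scale and
   both log shape parameters degree-<=2 polynomials of yhat) or a gaussian
   with a log-sigma polynomial of yhat.

All parameters are fit jointly by minibatch Adam on the mean negative log
likelihood of the training split, with early stopping on the validation
split.  Model quality is summarized by held-out R^2 / Pearson r and by
predictive information — the mutual information in bits between the latent
phenotype and the measurement, estimated as H(y) - H(y|phi) with H(y) from
a Kozachenko-Leonenko nearest-neighbor entropy estimator.  Parameter
uncertainties come from a parametric bootstrap that keeps the sequences
fixed and resimulates only the measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from . import _autodiff as ad
from .gpmap import FeatureMap, gauge_fix_uniform

__all__ = [
    "Hyperparameters",
    "Dataset",
    "MeasurementProcess",
    "FitResult",
    "BootstrapEnsemble",
    "split_dataset",
    "ge_predict",
    "noise_logpdf",
    "noise_sample",
    "fit_model",
    "multi_restart_fit",
    "predictive_information",
    "predictive_information_values",
    "knn_entropy_bits",
    "fit_metrics",
    "parametric_bootstrap",
    "BlackboxGPMap",
]

LN2 = float(np.log(2.0))


@dataclass
class Hyperparameters:
    """Training hyperparameters; defaults follow the published fitting setup."""

    learning_rate: float = 0.001
    epochs: int = 1000
    batch_size: int = 200
    patience: int = 30
    restarts: int = 25
    n_components: int = 20  # tanh components K of the GE nonlinearity
    noise_family: str = "skewed-t"  # or "gaussian"
    heteroskedasticity_order: int = 2
    noise_warmup_epochs: int = 100  # epochs with noise parameters frozen

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.batch_size, self.patience) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.noise_family not in ("skewed-t", "gaussian"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")


@dataclass
class Dataset:
    """Encoded sequences, measurements, and a train/val/test split."""

    seqs: np.ndarray
    y: np.ndarray
    split: np.ndarray
    position_alphabets: tuple
    replicate: np.ndarray | None = None

    def rows(self, which: str):
        idx = np.flatnonzero(self.split == which)
        return [self.seqs[i] for i in idx], self.y[idx]

    def __len__(self):
        return len(self.y)


def split_dataset(
    table: pd.DataFrame,
    fractions=(0.8, 0.1, 0.1),
    seed: int = 0,
    replicate_mode: bool = False,
    seq_col: str = "encoded_text",
    y_col: str = "log2_activity",
) -> Dataset:
    """Random disjoint exhaustive 80-10-10 split of a measurement table.

    Rounding rule: val and test sizes are floored, the remainder goes to
    train.  With ``replicate_mode`` every (sequence, replicate) pair from
    the ``activity_rep*`` columns becomes its own row (y = log2 of the
    per-replicate activity), so replicate measurements land in different
    splits independently.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if replicate_mode:
        rep_cols = [c for c in table.columns if c.startswith("activity_rep")]
        if not rep_cols:
            raise ValueError("replicate_mode requires activity_rep* columns")
        frames = []
        for k, c in enumerate(rep_cols, start=1):
            sub = table[[seq_col, c]].dropna()
            sub = sub[sub[c] > 0]
            frames.append(
                pd.DataFrame(
                    {seq_col: sub[seq_col], "y": np.log2(sub[c]), "replicate": k}
                )
            )
        tidy = pd.concat(frames, ignore_index=True)
        seqs = tidy[seq_col].to_numpy()
        y = tidy["y"].to_numpy(float)
        replicate = tidy["replicate"].to_numpy()
    else:
        seqs = table[seq_col].to_numpy()
        y = table[y_col].to_numpy(float)
        replicate = None
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 rows to split")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all encoded sequences must share one length")
    L = lengths.pop()
    position_alphabets = tuple(
        tuple(sorted({s[i] for s in seqs})) for i in range(L)
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    split = np.empty(n, dtype=object)
    split[order[:n_val]] = "val"
    split[order[n_val : n_val + n_test]] = "test"
    split[order[n_val + n_test :]] = "train"
    return Dataset(np.asarray(seqs, dtype=object), y, split, position_alphabets, replicate)


# ---------------------------------------------------------------------------
# Measurement process: GE nonlinearity + noise model (numpy inference path)
# ---------------------------------------------------------------------------


@dataclass
class MeasurementProcess:
    """GE nonlinearity and noise parameters on their natural scale.

    ``b`` and ``c`` are non-negative, which makes g non-decreasing.  The
    noise polynomials give log scale (and, for the skewed-t, the two log
    shape parameters) as functions of the predicted value yhat.
    """

    a: float = 0.0
    b: np.ndarray = field(default_factory=lambda: np.zeros(0))
    c: np.ndarray = field(default_factory=lambda: np.zeros(0))
    d: np.ndarray = field(default_factory=lambda: np.zeros(0))
    noise_family: str = "gaussian"
    scale_coef: np.ndarray = field(default_factory=lambda: np.zeros(1))
    shape_a_coef: np.ndarray | None = None
    shape_b_coef: np.ndarray | None = None

    def __post_init__(self):
        self.b = np.asarray(self.b, float)
        self.c = np.asarray(self.c, float)
        self.d = np.asarray(self.d, float)
        if np.any(self.b * self.c < 0):
            raise ValueError("b_k * c_k must be >= 0 for a monotone nonlinearity")
        if self.noise_family == "skewed-t" and (
            self.shape_a_coef is None or self.shape_b_coef is None
        ):
            raise ValueError("skewed-t noise requires both shape polynomials")


def _poly(coef, x):
    out = np.zeros_like(np.asarray(x, float))
    for k, ck in enumerate(np.asarray(coef, float)):
        out = out + ck * np.asarray(x, float) ** k
    return out


def ge_predict(phi, mp: MeasurementProcess):
    """Most probable measurement yhat = a + sum_k b_k tanh(c_k phi + d_k)."""
    phi = np.asarray(phi, float)
    if mp.b.size == 0:
        return np.full_like(phi, mp.a)
    t = np.tanh(np.multiply.outer(phi, mp.c) + mp.d)
    return mp.a + t @ mp.b


def _skewt_mode(a, b):
    """Mode of the standard Jones-Faddy skew-t with shapes (a, b)."""
    return (a - b) * np.sqrt(a + b) / (np.sqrt(2 * a + 1) * np.sqrt(2 * b + 1))


def _skewt_logpdf(y, loc, s, a, b):
    """log density of the mode-centred Jones-Faddy skew-t at ``y``."""
    z = (np.asarray(y, float) - loc) / s + _skewt_mode(a, b)
    q = a + b + z**2
    r = np.sqrt(q)
    logC = (
        -(a + b - 1.0) * np.log(2.0)
        - (gammaln(a) + gammaln(b) - gammaln(a + b))
        - 0.5 * np.log(a + b)
    )
    return (
        logC
        - np.log(s)
        + (a + 0.5) * (np.log(r + z) - np.log(r))
        + (b + 0.5) * (np.log(r - z) - np.log(r))
    )


def noise_logpdf(y, yhat, mp: MeasurementProcess):
    """Log density of measurement ``y`` given predicted value ``yhat``."""
    yhat = np.asarray(yhat, float)
    s = np.exp(_poly(mp.scale_coef, yhat))
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("noise scale must be positive and finite over the data range")
    if mp.noise_family == "gaussian":
        return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * ((np.asarray(y) - yhat) / s) ** 2
    a = np.exp(_poly(mp.shape_a_coef, yhat))
    b = np.exp(_poly(mp.shape_b_coef, yhat))
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("invalid skewed-t shape parameters")
    return _skewt_logpdf(y, yhat, s, a, b)


def noise_sample(rng: np.random.Generator, yhat, mp: MeasurementProcess):
    """Draw one measurement per yhat from the fitted noise model."""
    yhat = np.asarray(yhat, float)
    s = np.exp(_poly(mp.scale_coef, yhat))
    if mp.noise_family == "gaussian":
        return rng.normal(yhat, s)
    a = np.exp(_poly(mp.shape_a_coef, yhat))
    b = np.exp(_poly(mp.shape_b_coef, yhat))
    # Jones-Faddy representation: B ~ Beta(a,b), T = sqrt(a+b)(2B-1)/(2 sqrt(B(1-B)))
    B = rng.beta(a, b)
    T = np.sqrt(a + b) * (2 * B - 1) / (2 * np.sqrt(B * (1 - B)))
    return yhat + s * (T - _skewt_mode(a, b))


# ---------------------------------------------------------------------------
# Black-box genotype-phenotype map
# ---------------------------------------------------------------------------


class BlackboxGPMap:
    """Feed-forward phi: two hidden layers of 32 tanh units on the additive
    one-hot block.  Makes no assumption about interaction order."""

    def __init__(self, feature_map: FeatureMap, weights: dict):
        self.feature_map = feature_map
        self.weights = weights  # W1, b1, W2, b2, w3, b3 (ndarrays)

    def phi_from_features(self, X: np.ndarray) -> np.ndarray:
        w = self.weights
        h1 = np.tanh(X @ w["W1"] + w["b1"])
        h2 = np.tanh(h1 @ w["W2"] + w["b2"])
        return (h2 @ w["w3"] + w["b3"]).ravel()

    def phi_many(self, seqs) -> np.ndarray:
        return self.phi_from_features(self.feature_map.encode_many(seqs))


def blackbox_phi(X: np.ndarray, weights: dict) -> np.ndarray:
    """phi of one-hot additive features under MLP ``weights`` (zero weights
    give a constant phi)."""
    h1 = np.tanh(X @ weights["W1"] + weights["b1"])
    h2 = np.tanh(h1 @ weights["W2"] + weights["b2"])
    return (h2 @ weights["w3"] + weights["b3"]).ravel()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A fitted model: GP map, measurement process, history, and metrics."""

    architecture: str
    gpmap: object  # GPMapParams or BlackboxGPMap
    measurement: MeasurementProcess
    history: pd.DataFrame
    seed: int
    val_loss: float
    metrics: dict
    feature_map: FeatureMap | None = None
    restart_metrics: list | None = None

    def predict_phi(self, seqs) -> np.ndarray:
        if isinstance(self.gpmap, BlackboxGPMap):
            return self.gpmap.phi_many(seqs)
        fm = self.feature_map
        X = fm.encode_many(seqs)
        return X @ fm.weights_from_params(self.gpmap) + self.gpmap.theta0

    def predict(self, seqs) -> np.ndarray:
        return ge_predict(self.predict_phi(seqs), self.measurement)

    def loglik(self, y, seqs) -> np.ndarray:
        return noise_logpdf(y, self.predict(seqs), self.measurement)


class _Model:
    """Autodiff parameter set + forward pass for one architecture."""

    def __init__(self, fm_full: FeatureMap, fm_add: FeatureMap, architecture, hp, rng, y_train):
        self.architecture = architecture
        self.hp = hp
        self.fm_full = fm_full
        self.fm_add = fm_add
        K = hp.n_components
        p = {}
        if architecture == "blackbox":
            n_in = fm_add.n_features
            p["W1"] = ad.Var(rng.normal(0, 0.3 / np.sqrt(n_in), (n_in, 32)))
            p["b1"] = ad.Var(np.zeros((1, 32)))
            p["W2"] = ad.Var(rng.normal(0, 0.3 / np.sqrt(32), (32, 32)))
            p["b2"] = ad.Var(np.zeros((1, 32)))
            p["w3"] = ad.Var(rng.normal(0, 0.3 / np.sqrt(32), (32, 1)))
            p["b3"] = ad.Var(np.zeros((1, 1)))
        else:
            n_in = fm_full.n_features
            p["w"] = ad.Var(rng.normal(0, 0.05, (n_in, 1)))
            p["w0"] = ad.Var(np.zeros((1, 1)))
        # GE nonlinearity: raw b,c passed through softplus to stay positive
        p["a"] = ad.Var(np.full((1, 1), float(np.mean(y_train))))
        p["braw"] = ad.Var(np.full((1, K), -1.0) + rng.normal(0, 0.05, (1, K)))
        p["craw"] = ad.Var(np.full((1, K), 0.0) + rng.normal(0, 0.05, (1, K)))
        p["d"] = ad.Var(np.linspace(-2, 2, K).reshape(1, K))
        # noise polynomials (coefficient list, constant term first)
        s0 = float(np.log(max(np.std(y_train), 1e-3) * 0.5))
        order = hp.heteroskedasticity_order
        p["s_coef"] = ad.Var(np.array([[s0]] + [[0.0]] * order))
        if hp.noise_family == "skewed-t":
            p["a_coef"] = ad.Var(np.array([[np.log(3.0)]] + [[0.0]] * order))
            p["b_coef"] = ad.Var(np.array([[np.log(3.0)]] + [[0.0]] * order))
        self.params = p

    def leaves(self):
        return list(self.params.values())

    def _phi(self, X: np.ndarray) -> ad.Var:
        p = self.params
        Xv = ad.Var(X)
        if self.architecture == "blackbox":
            h1 = ad.tanh(Xv @ p["W1"] + p["b1"])
            h2 = ad.tanh(h1 @ p["W2"] + p["b2"])
            return h2 @ p["w3"] + p["b3"]
        return Xv @ p["w"] + p["w0"]

    def _yhat(self, phiv: ad.Var) -> ad.Var:
        p = self.params
        b = ad.softplus(p["braw"])
        c = ad.softplus(p["craw"])
        t = ad.tanh(phiv * c + p["d"])  # (B, K)
        return p["a"] + ad.vsum(t * b, axis=1, keepdims=True)

    @staticmethod
    def _polyv(coef: ad.Var, x: ad.Var) -> ad.Var:
        total = _slice_row(coef, 0)
        xk = None
        for k in range(1, coef.value.shape[0]):
            xk = x if k == 1 else xk * x
            total = total + _slice_row(coef, k) * xk
        return total

    def _nll(self, X: np.ndarray, y: np.ndarray) -> ad.Var:
        p = self.params
        yv = np.asarray(y, float).reshape(-1, 1)
        yhat = self._yhat(self._phi(X))
        logs = self._polyv(p["s_coef"], yhat)
        if self.hp.noise_family == "gaussian":
            resid = (ad.Var(yv) - yhat) * ad.exp(-logs)
            ll = -0.5 * np.log(2 * np.pi) - logs - 0.5 * resid * resid
        else:
            a = ad.exp(self._polyv(p["a_coef"], yhat))
            b = ad.exp(self._polyv(p["b_coef"], yhat))
            s = ad.exp(logs)
            mode = (
                (a - b)
                * ad.sqrt(a + b)
                / (ad.sqrt(a * 2.0 + 1.0) * ad.sqrt(b * 2.0 + 1.0))
            )
            z = (ad.Var(yv) - yhat) / s + mode
            r = ad.sqrt(a + b + z * z)
            logC = (
                -(a + b - 1.0) * np.log(2.0)
                - (ad.gammaln(a) + ad.gammaln(b) - ad.gammaln(a + b))
                - 0.5 * ad.log(a + b)
            )
            ll = (
                logC
                - logs
                + (a + 0.5) * (ad.log(r + z) - ad.log(r))
                + (b + 0.5) * (ad.log(r - z) - ad.log(r))
            )
        return -ad.vmean(ll)

    # -- numpy (no-graph) evaluation for val/test loss --------------------
    def nll_value(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(self._nll(X, y).value)

    def export(self, X_train: np.ndarray) -> tuple[object, MeasurementProcess]:
        """Extract parameters, standardizing phi over the training rows.

        phi and the nonlinearity g are only jointly identified up to an
        affine map (g can absorb any rescaling of phi), so phi is fixed to
        mean 0 / SD 1 on the training data and the inverse transform is
        folded into g's c_k and d_k.  This makes GP-map parameters
        comparable across restarts and bootstrap refits.
        """
        p = {k: v.value for k, v in self.params.items()}
        phi_tr = self._phi(X_train).value.ravel()
        m = float(np.mean(phi_tr))
        s = float(np.std(phi_tr))
        if s < 1e-12:
            m, s = 0.0, 1.0
        c = np.logaddexp(0, p["craw"]).ravel()
        mp = MeasurementProcess(
            a=float(p["a"].item()),
            b=np.logaddexp(0, p["braw"]).ravel(),
            c=c * s,
            d=p["d"].ravel() + c * m,
            noise_family=self.hp.noise_family,
            scale_coef=p["s_coef"].ravel().copy(),
            shape_a_coef=p["a_coef"].ravel().copy() if "a_coef" in p else None,
            shape_b_coef=p["b_coef"].ravel().copy() if "b_coef" in p else None,
        )
        if self.architecture == "blackbox":
            w = {k: p[k].copy() for k in ("W1", "b1", "W2", "b2", "w3", "b3")}
            w["w3"] = w["w3"] / s
            w["b3"] = (w["b3"] - m) / s
            gp = BlackboxGPMap(self.fm_add, w)
        else:
            gp = self.fm_full.params_from_weights(
                p["w"].ravel() / s, float((p["w0"].item() - m) / s)
            )
        return gp, mp


def _slice_row(v: ad.Var, k: int) -> ad.Var:
    """Select row k of a (n,1) Var as a (1,1) Var (differentiable)."""

    def back(g):
        v.grad[k] += np.sum(g)

    return ad.Var(v.value[k : k + 1], (v,), back)


def _lbfgs_polish(model: _Model, X: np.ndarray, y: np.ndarray, maxiter: int = 300) -> None:
    """Refine all parameters in place by L-BFGS on the full-batch NLL."""
    from scipy.optimize import minimize

    names = sorted(model.params)
    shapes = {k: model.params[k].value.shape for k in names}
    sizes = {k: model.params[k].value.size for k in names}

    def unpack(vec):
        off = 0
        for k in names:
            model.params[k].value = vec[off : off + sizes[k]].reshape(shapes[k])
            off += sizes[k]

    def fun(vec):
        unpack(vec)
        loss = model._nll(X, y)
        if not np.isfinite(loss.value):
            return 1e30, np.zeros(sum(sizes.values()))
        loss.backward()
        grad = np.concatenate([model.params[k].grad.ravel() for k in names])
        return float(loss.value), grad

    x0 = np.concatenate([model.params[k].value.ravel() for k in names])
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    unpack(res.x)


class _Adam:
    def __init__(self, leaves, lr):
        self.leaves = leaves
        self.lr = lr
        self.m = [np.zeros_like(v.value) for v in leaves]
        self.v = [np.zeros_like(v.value) for v in leaves]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, leaf in enumerate(self.leaves):
            g = leaf.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            leaf.value = leaf.value - self.lr * mh / (np.sqrt(vh) + eps)


def fit_model(
    dataset: Dataset,
    architecture: str = "pairwise",
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one model by minibatch Adam with early stopping on validation loss.

    Deterministic given (dataset, architecture, hp, seed).  Raises if the
    loss becomes non-finite, naming the epoch.
    """
    hp = hp or Hyperparameters()
    rng = np.random.default_rng(seed)
    fm_full = FeatureMap(
        dataset.position_alphabets,
        architecture if architecture != "blackbox" else "additive",
    )
    fm_add = FeatureMap(dataset.position_alphabets, "additive")
    tr_seqs, tr_y = dataset.rows("train")
    va_seqs, va_y = dataset.rows("val")
    if len(tr_y) == 0 or len(va_y) == 0:
        raise ValueError("dataset must contain train and val rows")
    enc = fm_add if architecture == "blackbox" else fm_full
    Xtr = enc.encode_many(tr_seqs)
    Xva = enc.encode_many(va_seqs)

    model = _Model(fm_full, fm_add, architecture, hp, rng, tr_y)
    opt = _Adam(model.leaves(), hp.learning_rate)
    n = len(tr_y)
    best_val = np.inf
    best_state = None
    best_epoch = -1
    hist = []
    wait = 0
    # Freezing the noise parameters early keeps the optimizer from the
    # local optimum where tail noise inflates instead of the mean fitting.
    noise_leaves = [model.params[k] for k in ("s_coef", "a_coef", "b_coef")
                    if k in model.params]
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        batch_losses = []
        frozen = epoch < hp.noise_warmup_epochs
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            loss = model._nll(Xtr[idx], tr_y[idx])
            if not np.isfinite(loss.value):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            loss.backward()
            if frozen:
                for leaf in noise_leaves:
                    leaf.grad[:] = 0.0
            opt.step()
            batch_losses.append(float(loss.value))
        val_loss = model.nll_value(Xva, va_y)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"training diverged (non-finite val loss) at epoch {epoch}")
        hist.append((epoch, float(np.mean(batch_losses)), val_loss))
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = {k: v.value.copy() for k, v in model.params.items()}
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= hp.patience:
                break
    for k, v in model.params.items():
        v.value = best_state[k]
    # Deterministic full-batch polish: minibatch Adam stalls short of the
    # optimum when the jointly learned noise scale sharpens the loss, so
    # finish with L-BFGS on the full training likelihood, keeping the
    # polished parameters only if the validation loss does not degrade.
    _lbfgs_polish(model, Xtr, tr_y)
    val_polished = model.nll_value(Xva, va_y)
    if np.isfinite(val_polished) and val_polished <= best_val:
        best_val = val_polished
    else:
        for k, v in model.params.items():
            v.value = best_state[k]
    gp, mp = model.export(Xtr)
    history = pd.DataFrame(hist, columns=["epoch", "train_loss", "val_loss"])
    fit = FitResult(
        architecture=architecture,
        gpmap=gp,
        measurement=mp,
        history=history,
        seed=seed,
        val_loss=float(best_val),
        metrics={"best_epoch": best_epoch},
        feature_map=fm_full if architecture != "blackbox" else None,
    )
    te_seqs, te_y = dataset.rows("test")
    if len(te_y) >= 3:
        fit.metrics.update(fit_metrics(fit, te_seqs, te_y))
    return fit


def multi_restart_fit(
    dataset: Dataset,
    architecture: str = "pairwise",
    hp: Hyperparameters | None = None,
    n_restarts: int = 1,
    base_seed: int = 0,
) -> FitResult:
    """Run ``fit_model`` from seeds base_seed..base_seed+n-1 on the same
    split; return the restart with the best validation loss, recording the
    per-restart metrics for stability analysis."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    fits, records, failures = [], [], []
    for k in range(n_restarts):
        try:
            f = fit_model(dataset, architecture, hp, seed=base_seed + k)
        except RuntimeError as err:
            failures.append(str(err))
            continue
        fits.append(f)
        records.append({"seed": base_seed + k, "val_loss": f.val_loss, **f.metrics})
    if not fits:
        raise RuntimeError("all restarts diverged: " + "; ".join(failures))
    best = min(fits, key=lambda f: f.val_loss)
    best.restart_metrics = records
    return best


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def knn_entropy_bits(y, k: int = 5) -> float:
    """Kozachenko-Leonenko differential entropy of a 1-D sample, in bits."""
    y = np.asarray(y, float).reshape(-1, 1)
    n = len(y)
    tree = cKDTree(y)
    dist, _ = tree.query(y, k=k + 1)
    r = np.maximum(dist[:, k], 1e-300)
    h_nats = digamma(n) - digamma(k) + float(np.mean(np.log(2.0 * r)))
    return h_nats / LN2


def predictive_information_values(y, logpdf, k: int = 5) -> tuple[float, float]:
    """I = H(y) - H(y|phi) in bits from per-row conditional log densities.

    ``logpdf`` holds natural-log densities p(y_i | g(phi_i)).  Returns the
    estimate and a standard error from the per-row spread of the
    conditional term.
    """
    y = np.asarray(y, float)
    logpdf = np.asarray(logpdf, float)
    if np.std(y) == 0:
        warnings.warn("degenerate measurements (zero variance); I = 0", stacklevel=2)
        return 0.0, 0.0
    h_y = knn_entropy_bits(y, k=k)
    h_cond_rows = -logpdf / LN2
    info = h_y - float(np.mean(h_cond_rows))
    se = float(np.std(h_cond_rows, ddof=1) / np.sqrt(len(y)))
    return info, se


def predictive_information(fit: FitResult, seqs, y, k: int = 5) -> tuple[float, float]:
    """Predictive information of a fitted model on held-out rows, in bits."""
    if len(y) < 30:
        raise ValueError("need at least 30 test rows")
    return predictive_information_values(y, fit.loglik(np.asarray(y, float), seqs), k=k)


def fit_metrics(fit: FitResult, seqs, y) -> dict:
    """Held-out R^2 and Pearson r between predictions and measurements.

    R^2 = 1 - SS_res/SS_tot, which can be negative for models worse than
    the mean (a constant prediction gives R^2 <= 0 by this convention).
    """
    y = np.asarray(y, float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows")
    yhat = fit.predict(seqs)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if np.std(yhat) == 0:
        r = 0.0
    else:
        r = float(pearsonr(y, yhat)[0])
    return {"r2": r2, "pearson_r": r}


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapEnsemble:
    """Refitted parameter sets (uniform gauge) and per-parameter SDs."""

    fits: list
    sd_theta0: float
    sd_add: dict
    sd_pair: dict
    n_requested: int
    n_dropped: int


def parametric_bootstrap(
    fit: FitResult,
    dataset: Dataset,
    n: int = 20,
    seed: int = 0,
    hp: Hyperparameters | None = None,
) -> BootstrapEnsemble:
    """Parameter uncertainties by simulate-and-refit with fixed sequences.

    Each replicate redraws every measurement from the fitted noise model at
    that sequence's predicted value (the sequences and the split are kept
    fixed), refits from a fresh seed, and the per-parameter SDs are taken
    across replicates after uniform gauge fixing — so they do not depend on
    the gauge of the original fit.
    """
    if isinstance(fit.gpmap, BlackboxGPMap):
        raise ValueError("bootstrap SDs are defined for linear architectures only")
    hp = hp or Hyperparameters()
    rng = np.random.default_rng(seed)
    yhat_all = fit.predict(list(dataset.seqs))
    refits = []
    dropped = 0
    for rep in range(n):
        y_star = noise_sample(rng, yhat_all, fit.measurement)
        boot = Dataset(
            dataset.seqs, y_star, dataset.split, dataset.position_alphabets, dataset.replicate
        )
        try:
            refits.append(fit_model(boot, fit.architecture, hp, seed=seed + 1000 + rep))
        except RuntimeError as err:
            dropped += 1
            warnings.warn(f"bootstrap replicate {rep} dropped: {err}", stacklevel=2)
    if not refits:
        raise RuntimeError("all bootstrap replicates diverged")
    fixed = [gauge_fix_uniform(f.gpmap) for f in refits]
    add_keys = sorted(fixed[0].theta_add)
    pair_keys = sorted(fixed[0].theta_pair)
    sd_add = {
        k: float(np.std([p.theta_add[k] for p in fixed], ddof=0)) for k in add_keys
    }
    sd_pair = {
        k: float(np.std([p.theta_pair[k] for p in fixed], ddof=0)) for k in pair_keys
    }
    sd0 = float(np.std([p.theta0 for p in fixed], ddof=0))
    return BootstrapEnsemble(refits, sd0, sd_add, sd_pair, n, dropped)
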