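"""Gated-attention multiple-instance learning with multi-task heads.

A slide is a bag of patch embeddings.  A projection layer maps raw
backbone features to a shared d-dimensional space, a gated attention
module scores each patch

    s_n = softmax_n( W · ( tanh(V h_n + b_v) ⊙ sigmoid(U h_n + b_u) ) )

and the bag is aggregated as the attention-weighted sum h_bag = Σ s_n h_n.
Task heads predict per-patient molecular labels from h_bag: 3-class
mutation-effect heads trained with inverse-frequency-weighted
cross-entropy, and scalar gene-set expression heads trained with MSE.
The total loss is the plain sum over all tasks.

Training uses Adam (lr 1e-4, β₁ 0.9, β₂ 0.999, L2 weight decay 1e-5)
with gradient accumulation over sub-batches of whole slides, and keeps
the epoch maximising the overall score (Σ AUC + Σ Spearman ρ) on the
evaluation split.  Forward and backward passes are written directly in
numpy; bags may have any number of patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from ._rng import substream

__all__ = [
    "GatedAttentionParams",
    "GatedAttentionMIL",
    "attention_scores",
    "aggregate",
    "mean_pool",
    "class_weights",
    "total_loss",
    "split_cohort",
    "train",
    "evaluate",
]


@dataclass
class GatedAttentionParams:
    """Attention weights W (1×d), V (d×d), U (d×d) and optional biases."""

    W: np.ndarray
    V: np.ndarray
    U: np.ndarray
    b_w: float = 0.0
    b_v: np.ndarray | None = None
    b_u: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64).reshape(-1)
        self.V = np.asarray(self.V, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64)
        d = self.W.shape[0]
        if self.V.shape != (d, d) or self.U.shape != (d, d):
            raise ValueError("V and U must be d×d matching W")
        if self.b_v is None:
            self.b_v = np.zeros(d)
        if self.b_u is None:
            self.b_u = np.zeros(d)
        for name in ("W", "V", "U", "b_v", "b_u"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite entries in {name}")


def attention_scores(H: np.ndarray, params: GatedAttentionParams) -> np.ndarray:
    """Softmax attention weights over the rows of ``H`` (N×d).

    Computed with max-subtraction stabilisation; weights are positive and
    sum to one.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("H must be a non-empty N×d matrix")
    if H.shape[1] != params.W.shape[0]:
        raise ValueError("H rows must match attention dimension")
    gate = np.tanh(H @ params.V.T + params.b_v) * _sigmoid(H @ params.U.T + params.b_u)
    logits = gate @ params.W + params.b_w
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def aggregate(H: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Attention pooling: convex combination ``Σ s_n h_n`` of bag rows."""
    H = np.asarray(H, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (H.shape[0],):
        raise ValueError("weight vector length must equal number of rows")
    if not np.isclose(s.sum(), 1.0, atol=1e-6):
        raise ValueError("attention weights must sum to 1")
    return s @ H


def mean_pool(H: np.ndarray) -> np.ndarray:
    """Unweighted column means — the ablation replacing attention pooling."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("H must be a non-empty N×d matrix")
    return H.mean(axis=0)


def class_weights(labels, n_classes: int = 3) -> np.ndarray:
    """Inverse-frequency weights w_c = 1/p_c from training labels."""
    labels = np.asarray(labels)
    labels = labels[labels >= 0]
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        absent = np.flatnonzero(counts == 0).tolist()
        raise ValueError(
            f"class(es) {absent} absent from training labels; re-split the cohort"
        )
    p = counts / counts.sum()
    return 1.0 / p


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def total_loss(
    class_logits: list[np.ndarray] | None,
    class_labels: np.ndarray | None,
    weights: list[np.ndarray] | None,
    reg_preds: np.ndarray | None = None,
    reg_targets: np.ndarray | None = None,
) -> float:
    """Sum of per-task weighted cross-entropies and MSEs for one batch.

    ``class_labels`` is n×T_cls with -1 marking a missing label (that
    slide contributes nothing to that task); ``reg_targets`` uses NaN the
    same way.  Per-slide task losses are averaged over the slides that
    carry the label, then summed across tasks.
    """
    loss = 0.0
    if class_logits is not None:
        class_labels = np.atleast_2d(np.asarray(class_labels))
        if not np.issubdtype(class_labels.dtype, np.integer):
            raise ValueError("class labels must be integers (-1 for missing)")
        for t, logits in enumerate(class_logits):
            logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
            if not np.all(np.isfinite(logits)):
                raise ValueError("non-finite classification logits")
            y = class_labels[:, t]
            observed = y >= 0
            if not observed.any():
                continue
            logp = _log_softmax(logits[observed])
            w = np.asarray(weights[t], dtype=np.float64)
            per_slide = -w[y[observed]] * logp[np.arange(observed.sum()), y[observed]]
            loss += per_slide.mean()
    if reg_preds is not None:
        reg_preds = np.atleast_2d(np.asarray(reg_preds, dtype=np.float64))
        reg_targets = np.atleast_2d(np.asarray(reg_targets, dtype=np.float64))
        if not np.all(np.isfinite(reg_preds)):
            raise ValueError("non-finite regression predictions")
        for j in range(reg_targets.shape[1]):
            y = reg_targets[:, j]
            observed = np.isfinite(y)
            if not observed.any():
                continue
            loss += np.mean((reg_preds[observed, j] - y[observed]) ** 2)
    return float(loss)


def split_cohort(
    patient_ids: list[str],
    class_labels: np.ndarray | None = None,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    max_attempts: int = 1000,
) -> dict[str, np.ndarray]:
    """Patient-level train/val/test partition of slide indices.

    All slides of a patient land in one partition.  When classification
    labels are given, the draw is repeated until every partition holds at
    least one positive (class-1) slide for every task; an unsatisfiable
    constraint raises after ``max_attempts``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    patient_ids = list(patient_ids)
    patients = sorted(set(patient_ids))
    n = len(patients)
    n_val = max(int(round(fractions[1] * n)), 1)
    n_test = max(int(round(fractions[2] * n)), 1)
    if n_val + n_test >= n:
        raise ValueError("too few patients for the requested fractions")
    rng = substream(seed, "split_cohort")
    labels = None if class_labels is None else np.atleast_2d(np.asarray(class_labels))
    for _ in range(max_attempts):
        order = rng.permutation(n)
        groups = {
            "train": set(patients[i] for i in order[: n - n_val - n_test]),
            "val": set(patients[i] for i in order[n - n_val - n_test : n - n_test]),
            "test": set(patients[i] for i in order[n - n_test :]),
        }
        split = {
            name: np.array([i for i, p in enumerate(patient_ids) if p in members])
            for name, members in groups.items()
        }
        if labels is None:
            return split
        ok = all(
            (labels[idx][:, t] == 1).any()
            for idx in split.values()
            for t in range(labels.shape[1])
        )
        if ok:
            return split
    raise ValueError(
        f"could not satisfy the positive-label-per-partition constraint in "
        f"{max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# estimator


class GatedAttentionMIL(BaseEstimator):
    """Multi-task gated-attention MIL network, trained with numpy Adam.

    Parameters follow scikit-learn conventions; fitted state lives in
    trailing-underscore attributes (``params_``, ``heads_``,
    ``history_``, ``best_epoch_``).

    Parameters
    ----------
    d_proj : shared feature dimension after the projection layer.
    pooling : "attention" for gated attention, "mean" for the ablation
        that replaces it with an unweighted mean.
    lr, beta1, beta2, weight_decay : Adam hyperparameters.
    epochs : training epochs; the returned model is the best epoch by
        overall validation score (ties to the earliest epoch).
    batch_slides, grad_accum_subbatches : one optimizer step consumes
        ``batch_slides`` slides per sub-batch, accumulated and averaged
        over ``grad_accum_subbatches`` sub-batches.
    """

    def __init__(
        self,
        d_proj: int = 256,
        n_classes: int = 3,
        pooling: str = "attention",
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        weight_decay: float = 1e-5,
        epochs: int = 100,
        batch_slides: int = 2,
        grad_accum_subbatches: int = 8,
        split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
        select_best_epoch: bool = True,
        seed: int = 0,
    ):
        self.d_proj = d_proj
        self.n_classes = n_classes
        self.pooling = pooling
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_slides = batch_slides
        self.grad_accum_subbatches = grad_accum_subbatches
        self.split_fractions = split_fractions
        self.select_best_epoch = select_best_epoch
        self.seed = seed

    # -- parameter containers ------------------------------------------------

    def _init_params(self, d_raw: int, n_cls_tasks: int, n_reg_tasks: int) -> dict:
        rng = substream(self.seed, "mil_init")
        d = self.d_proj

        def xavier(shape):
            fan = sum(shape)
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan)

        p = {
            "P": xavier((d_raw, d)),
            "b_p": np.zeros(d),
            "V": xavier((d, d)),
            "b_v": np.zeros(d),
            "U": xavier((d, d)),
            "b_u": np.zeros(d),
            "W": xavier((d,)),
            "b_w": np.zeros(1),
        }
        # heads start at zero: predictions begin neutral and move in the
        # gradient's (label-consistent) direction from the first step
        for t in range(n_cls_tasks):
            p[f"C{t}"] = np.zeros((d, self.n_classes))
            p[f"c{t}"] = np.zeros(self.n_classes)
        for j in range(n_reg_tasks):
            p[f"R{j}"] = np.zeros(d)
            p[f"r{j}"] = np.zeros(1)
        return p

    # -- forward / backward --------------------------------------------------

    def _forward(self, X: np.ndarray, p: dict) -> dict:
        H = X @ p["P"] + p["b_p"]
        if self.pooling == "attention":
            A = np.tanh(H @ p["V"].T + p["b_v"])
            G = _sigmoid(H @ p["U"].T + p["b_u"])
            logits = (A * G) @ p["W"] + p["b_w"][0]
            logits = logits - logits.max()
            e = np.exp(logits)
            s = e / e.sum()
            cache = {"A": A, "G": G}
        else:
            s = np.full(X.shape[0], 1.0 / X.shape[0])
            cache = {}
        z = s @ H
        cache.update({"X": X, "H": H, "s": s, "z": z})
        return cache

    def _bag_loss_grads(
        self,
        cache: dict,
        y_cls: np.ndarray,
        y_reg: np.ndarray,
        cls_w: list[np.ndarray],
        p: dict,
        grads: dict,
    ) -> float:
        z = cache["z"]
        dz = np.zeros_like(z)
        loss = 0.0
        for t in range(len(cls_w)):
            y = int(y_cls[t])
            if y < 0:
                continue
            logits = z @ p[f"C{t}"] + p[f"c{t}"]
            logp = _log_softmax(logits)
            prob = np.exp(logp)
            w = cls_w[t][y]
            loss += -w * logp[y]
            dlogits = w * prob
            dlogits[y] -= w
            grads[f"C{t}"] += np.outer(z, dlogits)
            grads[f"c{t}"] += dlogits
            dz += p[f"C{t}"] @ dlogits
        for j, y in enumerate(np.atleast_1d(y_reg)):
            if not np.isfinite(y):
                continue
            pred = z @ p[f"R{j}"] + p[f"r{j}"][0]
            loss += (pred - y) ** 2
            dpred = 2.0 * (pred - y)
            grads[f"R{j}"] += dpred * z
            grads[f"r{j}"] += dpred
            dz += dpred * p[f"R{j}"]

        H, s, X = cache["H"], cache["s"], cache["X"]
        dH = s[:, None] * dz[None, :]
        if self.pooling == "attention":
            ds = H @ dz
            dE = s * (ds - s @ ds)
            A, G = cache["A"], cache["G"]
            M = A * G
            grads["W"] += M.T @ dE
            grads["b_w"] += dE.sum()
            dM = dE[:, None] * p["W"][None, :]
            dpreA = dM * G * (1.0 - A**2)
            dpreG = dM * A * G * (1.0 - G)
            grads["V"] += dpreA.T @ H
            grads["b_v"] += dpreA.sum(axis=0)
            grads["U"] += dpreG.T @ H
            grads["b_u"] += dpreG.sum(axis=0)
            dH += dpreA @ p["V"] + dpreG @ p["U"]
        grads["P"] += X.T @ dH
        grads["b_p"] += dH.sum(axis=0)
        return float(loss)

    # -- fit / predict -------------------------------------------------------

    def fit(self, bags, y_class=None, y_reg=None, patient_ids=None):
        """Train on a list of bags with per-slide multi-task labels.

        ``y_class``: n_slides×T_cls ints in {0..n_classes-1}, -1 missing.
        ``y_reg``: n_slides×T_reg floats, NaN missing.  ``patient_ids``
        groups slides for the patient-level split; defaults to one
        patient per slide.
        """
        bags = [np.asarray(b, dtype=np.float64) for b in bags]
        n = len(bags)
        if n == 0:
            raise ValueError("empty cohort")
        y_class = (
            np.full((n, 0), -1, dtype=np.int64)
            if y_class is None
            else np.atleast_2d(np.asarray(y_class, dtype=np.int64))
        )
        y_reg = (
            np.full((n, 0), np.nan)
            if y_reg is None
            else np.atleast_2d(np.asarray(y_reg, dtype=np.float64))
        )
        if patient_ids is None:
            patient_ids = [f"pt{i}" for i in range(n)]
        n_cls, n_reg = y_class.shape[1], y_reg.shape[1]
        d_raw = bags[0].shape[1]

        self.split_ = split_cohort(
            patient_ids,
            y_class if n_cls else None,
            self.split_fractions,
            seed=self.seed,
        )
        train_idx, val_idx = self.split_["train"], self.split_["val"]
        self.class_weights_ = [
            class_weights(y_class[train_idx, t], self.n_classes) for t in range(n_cls)
        ]

        p = self._init_params(d_raw, n_cls, n_reg)
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(val) for k, val in p.items()}
        rng = substream(self.seed, "mil_train_shuffle")
        step = 0
        history: list[dict] = []
        best_score, best_epoch, best_params = -np.inf, -1, {k: a.copy() for k, a in p.items()}

        chunk = self.batch_slides * self.grad_accum_subbatches
        for epoch in range(self.epochs):
            order = rng.permutation(train_idx)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), chunk):
                batch = order[start : start + chunk]
                grads = {k: np.zeros_like(val) for k, val in p.items()}
                batch_loss = 0.0
                for i in batch:
                    cache = self._forward(bags[i], p)
                    batch_loss += self._bag_loss_grads(
                        cache, y_class[i], y_reg[i], self.class_weights_, p, grads
                    )
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                step += 1
                for k in p:
                    g = grads[k] / len(batch) + self.weight_decay * p[k]
                    m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                    v[k] = self.beta2 * v[k] + (1 - self.beta2) * g**2
                    mhat = m[k] / (1 - self.beta1**step)
                    vhat = v[k] / (1 - self.beta2**step)
                    p[k] = p[k] - self.lr * mhat / (np.sqrt(vhat) + 1e-8)
                epoch_loss += batch_loss / len(batch)
                n_batches += 1

            self.params_raw_ = p
            eval_bags = [bags[i] for i in val_idx]
            score = evaluate(
                self, eval_bags, y_class[val_idx], y_reg[val_idx], _params=p
            )["overall"]
            history.append(
                {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "val_score": score}
            )
            if score > best_score:  # strict: ties keep the earliest epoch
                best_score, best_epoch = score, epoch
                best_params = {k: a.copy() for k, a in p.items()}

        self.n_cls_tasks_, self.n_reg_tasks_ = n_cls, n_reg
        self.params_raw_ = best_params if (self.select_best_epoch and self.epochs) else p
        self.best_epoch_ = best_epoch if self.epochs else -1
        self.history_ = history
        self.params_ = GatedAttentionParams(
            W=self.params_raw_["W"],
            V=self.params_raw_["V"],
            U=self.params_raw_["U"],
            b_w=float(self.params_raw_["b_w"][0]),
            b_v=self.params_raw_["b_v"],
            b_u=self.params_raw_["b_u"],
        )
        return self

    def _ensure_fitted(self) -> None:
        if not hasattr(self, "params_raw_"):
            raise RuntimeError("model is not fitted")

    def embed(self, bag: np.ndarray, _params: dict | None = None) -> np.ndarray:
        """Bag-level representation h_bag (attention-pooled, pre-head)."""
        p = _params if _params is not None else (self._ensure_fitted() or self.params_raw_)
        return self._forward(np.asarray(bag, dtype=np.float64), p)["z"]

    def attention(self, bag: np.ndarray) -> np.ndarray:
        self._ensure_fitted()
        return self._forward(np.asarray(bag, dtype=np.float64), self.params_raw_)["s"]

    def predict_proba(self, bags, _params: dict | None = None) -> list[np.ndarray]:
        """Per classification task: n_bags×n_classes softmax probabilities."""
        p = _params if _params is not None else (self._ensure_fitted() or self.params_raw_)
        n_cls = sum(1 for k in p if k.startswith("C"))
        out = [np.empty((len(bags), self.n_classes)) for _ in range(n_cls)]
        for i, bag in enumerate(bags):
            z = self._forward(np.asarray(bag, dtype=np.float64), p)["z"]
            for t in range(n_cls):
                out[t][i] = np.exp(_log_softmax(z @ p[f"C{t}"] + p[f"c{t}"]))
        return out

    def predict_regression(self, bags, _params: dict | None = None) -> np.ndarray:
        p = _params if _params is not None else (self._ensure_fitted() or self.params_raw_)
        n_reg = sum(1 for k in p if k.startswith("R"))
        out = np.empty((len(bags), n_reg))
        for i, bag in enumerate(bags):
            z = self._forward(np.asarray(bag, dtype=np.float64), p)["z"]
            for j in range(n_reg):
                out[i, j] = z @ p[f"R{j}"] + p[f"r{j}"][0]
        return out

    def predict(self, bags) -> np.ndarray:
        """Argmax class per bag for each classification task (n×T_cls)."""
        probs = self.predict_proba(bags)
        return np.stack([pr.argmax(axis=1) for pr in probs], axis=1)

    def save(self, path) -> None:
        self._ensure_fitted()
        arrays = {k: np.asarray(v) for k, v in self.params_raw_.items()}
        arrays["__config__"] = np.frombuffer(
            repr(self.get_params()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "GatedAttentionMIL":
        import ast

        data = np.load(path)
        config = ast.literal_eval(bytes(data["__config__"]).decode())
        model = cls(**config)
        model.params_raw_ = {k: data[k] for k in data.files if k != "__config__"}
        model.n_cls_tasks_ = sum(1 for k in model.params_raw_ if k.startswith("C"))
        model.n_reg_tasks_ = sum(1 for k in model.params_raw_ if k.startswith("R"))
        model.params_ = GatedAttentionParams(
            W=model.params_raw_["W"],
            V=model.params_raw_["V"],
            U=model.params_raw_["U"],
            b_w=float(model.params_raw_["b_w"][0]),
            b_v=model.params_raw_["b_v"],
            b_u=model.params_raw_["b_u"],
        )
        return model


def evaluate(
    model: GatedAttentionMIL,
    bags,
    y_class: np.ndarray | None = None,
    y_reg: np.ndarray | None = None,
    positive_class: int = 1,
    _params: dict | None = None,
) -> dict:
    """Per-task AUC / Spearman ρ and the overall score (their sum).

    Classification AUC is one-vs-rest on the probability of the
    functional-mutation class (class 1 by default).  Tasks whose
    evaluation labels take a single value are skipped with a warning and
    excluded from the sum.
    """
    result: dict = {"auc": [], "spearman": []}
    overall = 0.0
    if y_class is not None and np.asarray(y_class).size:
        y_class = np.atleast_2d(np.asarray(y_class, dtype=np.int64))
        probs = model.predict_proba(bags, _params=_params)
        for t in range(y_class.shape[1]):
            y = y_class[:, t]
            obs = y >= 0
            y_bin = (y[obs] == positive_class).astype(int)
            if len(np.unique(y_bin)) < 2:
                warnings.warn(f"classification task {t}: single label value, skipped")
                result["auc"].append(np.nan)
                continue
            auc = roc_auc_score(y_bin, probs[t][obs, positive_class])
            result["auc"].append(float(auc))
            overall += auc
    if y_reg is not None and np.asarray(y_reg).size:
        y_reg = np.atleast_2d(np.asarray(y_reg, dtype=np.float64))
        preds = model.predict_regression(bags, _params=_params)
        for j in range(y_reg.shape[1]):
            y = y_reg[:, j]
            obs = np.isfinite(y)
            if len(np.unique(y[obs])) < 2:
                warnings.warn(f"regression task {j}: constant target, skipped")
                result["spearman"].append(np.nan)
                continue
            rho = spearmanr(preds[obs, j], y[obs]).statistic
            result["spearman"].append(float(rho))
            overall += rho
    result["overall"] = float(overall)
    return result


def train(cohort, config: dict | None = None) -> GatedAttentionMIL:
    """Fit a :class:`GatedAttentionMIL` on a synthetic cohort object."""
    model = GatedAttentionMIL(**(config or {}))
    model.fit(
        cohort.bags,
        y_class=cohort.class_labels,
        y_reg=cohort.reg_targets,
        patient_ids=cohort.patient_ids,
    )
    return model
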