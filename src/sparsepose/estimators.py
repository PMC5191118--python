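"""Pose estimators: lazy (weighted nearest-neighbor) and eager (neural net).

Both estimators follow the scikit-learn estimator contract (``fit``,
``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) and operate on flattened quaternion matrices:

* ``X`` — input features, shape ``(n_samples, 4 * n_input_segments)``:
  the scalar-first quaternions of the measured segments of one body half,
  pelvis-referenced (the pelvis itself, being the identity, carries no
  information and is excluded).
* ``y`` — targets, shape ``(n_samples, 4 * n_output_segments)``: the
  quaternions of the remaining segments of that half.

:class:`WeightedNeighborPoseRegressor` implements the lazy learner: the
distance between a query and a stored pose is the mean quaternion shortest
angle over the input segments,

    d_n = (1/S) * sum_s 2 * arccos(|[(q_s)^-1 ⊗ q_s^n]_1|),

the k nearest poses are combined componentwise with weights

    w_n = (max(d) - d_n) / sum_n (max(d) - d_n)

evaluated over the k-nearest set, and each output quaternion is normalized
to unit norm.

:class:`NeuralPoseRegressor` implements the eager learner: a feedforward
network (default two tanh hidden layers of 250 and 100 units, linear
output) trained with a full-batch gradient method on the mean squared error
of the quaternion components.  Output norms are not constrained during
training; predictions are normalized per quaternion.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import quaternions as qt

__all__ = [
    "pose_distance",
    "neighbor_weights",
    "WeightedNeighborPoseRegressor",
    "NeuralPoseRegressor",
    "PoseReconstructor",
]


def _check_quat_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 3 and X.shape[-1] == 4:
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2 or X.shape[1] % 4 != 0:
        raise ValueError(
            f"{name} must be (n_samples, 4 * n_segments) or (n_samples, n_segments, 4), "
            f"got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X


def pose_distance(a, b, absolute: bool = True) -> np.ndarray:
    """Mean quaternion shortest angle (radians) between two feature vectors.

    ``a`` and ``b`` are flattened quaternion vectors (``4*S`` components) or
    matrices thereof; segments must be in the same order.
    """
    a = _check_quat_matrix(np.atleast_2d(a), "a")
    b = _check_quat_matrix(np.atleast_2d(b), "b")
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature vectors have mismatched segment counts")
    S = a.shape[1] // 4
    qa = a.reshape(a.shape[0], S, 4)
    qb = b.reshape(b.shape[0], S, 4)
    ang = qt.shortest_angle(qa, qb, absolute=absolute)
    out = ang.mean(axis=-1)
    return out[0] if out.shape == (1,) else out


def _distance_matrix(Q: np.ndarray, T: np.ndarray, absolute: bool = True) -> np.ndarray:
    """Pairwise mean shortest angle between query rows and training rows.

    For unit quaternions the scalar part of ``a^-1 ⊗ b`` equals the 4-D dot
    product ``a · b``, so the distance reduces to
    ``mean_s 2*arccos(|a_s · b_s|)`` — one matrix product per segment.
    """
    m, n = Q.shape[0], T.shape[0]
    S = Q.shape[1] // 4
    D = np.zeros((m, n))
    for s in range(S):
        dots = Q[:, 4 * s : 4 * s + 4] @ T[:, 4 * s : 4 * s + 4].T
        if absolute:
            dots = np.abs(dots)
        D += 2.0 * np.arccos(np.clip(dots, -1.0, 1.0))
    D /= S
    return D


def neighbor_weights(distances, scope_max: float | None = None) -> np.ndarray:
    """Neighbor weights ``w_n = (max(d) - d_n) / sum(max(d) - d_n)``.

    Evaluated over the supplied distance set (the k nearest).  When every
    distance equals the maximum the formula is 0/0; the continuous-limit
    fallback is uniform ``1/k`` (this covers ``k=1``).  The farthest of the
    k receives weight 0 whenever distances differ.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a nonempty 1-D sequence")
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and nonnegative")
    top = float(np.max(d)) if scope_max is None else float(scope_max)
    w = top - d
    s = w.sum()
    if s <= 0.0:
        return np.full(d.size, 1.0 / d.size)
    return w / s


class WeightedNeighborPoseRegressor(RegressorMixin, BaseEstimator):
    """Lazy pose estimator: weighted nearest-neighbor search over a pose
    database.

    Parameters
    ----------
    n_neighbors : int, default=500
        Number of neighbors ``k`` combined into the weighted pose.
    weight_scope : {"neighbors", "database"}, default="neighbors"
        "neighbors" evaluates the weight formula over the k-nearest set and
        renormalizes there (weights sum to 1).  "database" is the literal
        all-N reading: max and normalizing sum are taken over the whole
        database, and only the k nearest terms enter the average (the final
        per-quaternion normalization absorbs the missing mass).
    sign_align : bool, default=True
        Flip each neighbor's output quaternions into the hemisphere of the
        nearest neighbor's before the componentwise weighted sum, making the
        average well defined across the double cover.
    absolute_angle : bool, default=True
        Use the double-cover-invariant shortest angle.  ``False`` selects
        the literal signed-arccos variant (comparison only).

    Notes
    -----
    Search is an exhaustive linear scan; distance ties at the k-th neighbor
    are broken by lower database index (stable sort), so predictions are
    invariant to permuting the database order.  With ``n_neighbors=1`` the
    single neighbor's row is returned verbatim (the weighted average with
    weight vector ``[1.0]``), so querying a training pose recalls it
    bit-identically.
    """

    def __init__(
        self,
        n_neighbors: int = 500,
        weight_scope: str = "neighbors",
        sign_align: bool = True,
        absolute_angle: bool = True,
    ):
        self.n_neighbors = n_neighbors
        self.weight_scope = weight_scope
        self.sign_align = sign_align
        self.absolute_angle = absolute_angle

    def fit(self, X, y):
        X = _check_quat_matrix(X, "X")
        y = _check_quat_matrix(y, "y")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of samples")
        if not (1 <= int(self.n_neighbors) <= X.shape[0]):
            raise ValueError(
                f"n_neighbors={self.n_neighbors} must be in [1, n_samples={X.shape[0]}]"
            )
        if self.weight_scope not in ("neighbors", "database"):
            raise ValueError("weight_scope must be 'neighbors' or 'database'")
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def kneighbors(self, X):
        """Distances (radians), indices and weights of the k nearest poses.

        Returns arrays of shape ``(n_queries, k)``; distances are
        nondecreasing along the last axis and weights sum to 1 per row
        (under the default weight scope).
        """
        X = _check_quat_matrix(X, "X")
        if X.shape[1] != self.n_features_in_:
            raise ValueError("query feature length does not match training features")
        k = int(self.n_neighbors)
        D = _distance_matrix(X, self.X_, absolute=self.absolute_angle)
        # stable sort → ties broken by lower database index
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        dist = np.take_along_axis(D, order, axis=1)
        if self.weight_scope == "database":
            top = D.max(axis=1)
            denom = (top[:, None] - D).sum(axis=1)
            w = (top[:, None] - dist)
            safe = denom > 0
            w[safe] /= denom[safe, None]
            w[~safe] = 1.0 / k
        else:
            w = np.stack([neighbor_weights(row) for row in dist])
        return dist, order, w

    def predict(self, X):
        X = _check_quat_matrix(X, "X")
        dist, idx, w = self.kneighbors(X)
        k = int(self.n_neighbors)
        if k == 1:
            return self.y_[idx[:, 0]].copy()
        T = self.y_.shape[1] // 4
        neigh = self.y_[idx]  # (m, k, 4T)
        blocks = neigh.reshape(neigh.shape[0], k, T, 4)
        if self.sign_align:
            ref = blocks[:, :1, :, :]  # nearest neighbor
            dots = np.sum(blocks * ref, axis=-1, keepdims=True)
            blocks = np.where(dots < 0.0, -blocks, blocks)
        avg = np.einsum("mk,mktc->mtc", w, blocks)
        norms = np.linalg.norm(avg, axis=-1, keepdims=True)
        if np.any(norms < 1e-12):
            raise ValueError("degenerate quaternion average (norm < 1e-12)")
        return (avg / norms).reshape(X.shape[0], 4 * T)


class NeuralPoseRegressor(RegressorMixin, BaseEstimator):
    """Eager pose estimator: feedforward quaternion-component regression.

    A function-fitting network — tanh hidden layers, linear output — maps
    the 4·S input components to the 4·T output components.  Training
    minimizes full-batch mean squared error with a deterministic Adam
    optimizer, stops after ``max_epochs`` or once the gradient norm has not
    decreased for ``stall_window`` consecutive epochs, and keeps the weights
    with the best validation loss seen.  Inputs are standardized (constants
    stored on the model); output quaternion norms are left free during
    training and normalized only at prediction.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default=(250, 100)
    max_epochs : int, default=1000
    stall_window : int, default=6
        Consecutive non-decreasing-gradient epochs that end training.
    learning_rate : float, default=0.01
    validation_fraction : float, default=0.1
        Fraction of samples held out to select the best epoch; 0 tracks the
        training loss instead.
    random_state : int or None
        Seeds initialization and the validation split; training is
        bit-reproducible given the seed.
    """

    def __init__(
        self,
        hidden_layer_sizes=(250, 100),
        max_epochs: int = 1000,
        stall_window: int = 6,
        learning_rate: float = 0.01,
        validation_fraction: float = 0.1,
        random_state=None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_epochs = max_epochs
        self.stall_window = stall_window
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, X, coefs, intercepts):
        a = X
        acts = [a]
        for i, (W, b) in enumerate(zip(coefs, intercepts)):
            z = a @ W + b
            a = z if i == len(coefs) - 1 else np.tanh(z)
            acts.append(a)
        return acts

    def _loss_grad(self, X, Y, coefs, intercepts):
        n = X.shape[0]
        acts = self._forward(X, coefs, intercepts)
        out = acts[-1]
        resid = out - Y
        loss = float(np.mean(resid**2))
        scale = 2.0 / resid.size
        delta = scale * resid
        gW, gb = [], []
        for i in range(len(coefs) - 1, -1, -1):
            gW.append(acts[i].T @ delta)
            gb.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ coefs[i].T) * (1.0 - acts[i] ** 2)
        return loss, gW[::-1], gb[::-1]

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = _check_quat_matrix(X, "X")
        Y = _check_quat_matrix(y, "y")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and y must have the same number of samples")
        if any(int(h) <= 0 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if int(self.max_epochs) < 1:
            raise ValueError("max_epochs must be >= 1")

        rng = np.random.default_rng(self.random_state)
        n, d_in = X.shape
        d_out = Y.shape[1]

        # input standardization
        self.input_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0
        self.input_scale_ = scale
        Xs = (X - self.input_mean_) / self.input_scale_

        # validation split
        if self.validation_fraction > 0 and n > 4:
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx, tr_idx = None, np.arange(n)
        Xtr, Ytr = Xs[tr_idx], Y[tr_idx]
        Xval = Xs[val_idx] if val_idx is not None else None
        Yval = Y[val_idx] if val_idx is not None else None

        # Glorot-uniform initialization
        sizes = [d_in] + [int(h) for h in self.hidden_layer_sizes] + [d_out]
        coefs, intercepts = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            lim = np.sqrt(6.0 / (a + b))
            coefs.append(rng.uniform(-lim, lim, size=(a, b)))
            intercepts.append(np.zeros(b))

        self.initial_loss_ = self._loss_grad(Xtr, Ytr, coefs, intercepts)[0]

        # full-batch Adam
        lr, b1, b2, eps = float(self.learning_rate), 0.9, 0.999, 1e-8
        mW = [np.zeros_like(W) for W in coefs]
        vW = [np.zeros_like(W) for W in coefs]
        mb = [np.zeros_like(b) for b in intercepts]
        vb = [np.zeros_like(b) for b in intercepts]

        best_loss = np.inf
        best = ([W.copy() for W in coefs], [b.copy() for b in intercepts])
        prev_gnorm = np.inf
        stall = 0
        losses, gnorms = [], []

        for epoch in range(1, int(self.max_epochs) + 1):
            loss, gW, gb = self._loss_grad(Xtr, Ytr, coefs, intercepts)
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            gnorm = float(np.sqrt(sum((g**2).sum() for g in gW + gb)))
            losses.append(loss)
            gnorms.append(gnorm)

            monitor = loss
            if Xval is not None:
                monitor = self._loss_grad(Xval, Yval, coefs, intercepts)[0]
            if monitor < best_loss:
                best_loss = monitor
                best = ([W.copy() for W in coefs], [b.copy() for b in intercepts])

            # gradient-stall stopping: N consecutive epochs without a
            # decrease of the gradient norm end the run
            if gnorm >= prev_gnorm:
                stall += 1
            else:
                stall = 0
            prev_gnorm = gnorm
            if stall >= int(self.stall_window):
                break

            t = epoch
            for i in range(len(coefs)):
                mW[i] = b1 * mW[i] + (1 - b1) * gW[i]
                vW[i] = b2 * vW[i] + (1 - b2) * gW[i] ** 2
                mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                mhW = mW[i] / (1 - b1**t)
                vhW = vW[i] / (1 - b2**t)
                mhb = mb[i] / (1 - b1**t)
                vhb = vb[i] / (1 - b2**t)
                coefs[i] -= lr * mhW / (np.sqrt(vhW) + eps)
                intercepts[i] -= lr * mhb / (np.sqrt(vhb) + eps)

        self.coefs_, self.intercepts_ = best
        self.best_loss_ = float(best_loss)
        self.loss_curve_ = np.asarray(losses)
        self.gradient_norms_ = np.asarray(gnorms)
        self.final_loss_ = self._loss_grad(Xtr, Ytr, self.coefs_, self.intercepts_)[0]
        self.n_epochs_ = len(losses)
        self.n_features_in_ = d_in
        return self

    def decision_function(self, X):
        """Raw network output (quaternion components, not normalized)."""
        X = _check_quat_matrix(X, "X")
        if X.shape[1] != self.n_features_in_:
            raise ValueError("query feature length does not match training features")
        Xs = (X - self.input_mean_) / self.input_scale_
        return self._forward(Xs, self.coefs_, self.intercepts_)[-1]

    def predict(self, X):
        out = self.decision_function(X)
        T = out.shape[1] // 4
        blocks = out.reshape(out.shape[0], T, 4)
        norms = np.linalg.norm(blocks, axis=-1, keepdims=True)
        if np.any(norms < 1e-12):
            raise ValueError("degenerate network output (quaternion norm < 1e-12)")
        return (blocks / norms).reshape(out.shape)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Store the trained network (weights, scaling, spec) as NPZ."""
        data = {
            "n_layers": np.array(len(self.coefs_)),
            "input_mean": self.input_mean_,
            "input_scale": self.input_scale_,
            "hidden_layer_sizes": np.asarray(self.hidden_layer_sizes),
            "random_state": np.array(-1 if self.random_state is None else self.random_state),
        }
        for i, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            data[f"W{i}"] = W
            data[f"b{i}"] = b
        np.savez(path, **data)

    @classmethod
    def load(cls, path) -> "NeuralPoseRegressor":
        with np.load(path) as d:
            seed = int(d["random_state"])
            est = cls(
                hidden_layer_sizes=tuple(int(h) for h in d["hidden_layer_sizes"]),
                random_state=None if seed < 0 else seed,
            )
            n = int(d["n_layers"])
            est.coefs_ = [d[f"W{i}"] for i in range(n)]
            est.intercepts_ = [d[f"b{i}"] for i in range(n)]
            est.input_mean_ = d["input_mean"]
            est.input_scale_ = d["input_scale"]
            est.n_features_in_ = est.coefs_[0].shape[0]
        return est


class PoseReconstructor(BaseEstimator):
    """Full-body pose estimation from one base estimator per body half.

    Fits a clone of ``base_estimator`` for the upper and the lower body on a
    pelvis-referenced :class:`~sparsepose.database.MotionDatabase`, and
    assembles predictions into complete 23-segment poses: measured segments
    are copied from the input, the pelvis is the identity, and the remaining
    segments come from the two regressors.
    """

    def __init__(self, base_estimator=None, config="D"):
        self.base_estimator = base_estimator
        self.config = config

    def fit(self, db):
        from sklearn.base import clone

        from .database import get_configuration

        cfg = get_configuration(self.config)
        if not db.referenced:
            raise ValueError("fit requires a pelvis-referenced database")
        base = (
            WeightedNeighborPoseRegressor()
            if self.base_estimator is None
            else self.base_estimator
        )
        self.config_ = cfg
        self.segments_ = db.segments
        self.estimators_ = {}
        for half in ("upper", "lower"):
            est = clone(base)
            est.fit(db.features(cfg, half), db.targets(cfg, half))
            self.estimators_[half] = est
        return self

    def predict(self, db) -> np.ndarray:
        """Full-body quaternions ``(n, n_segments, 4)`` for each query pose."""
        cfg = self.config_
        if not db.referenced:
            raise ValueError("predict requires a pelvis-referenced database")
        n = len(db)
        out = np.empty((n, len(self.segments_), 4))
        out[:, self.segments_.index("Pelvis"), :] = qt.IDENTITY
        for half in ("upper", "lower"):
            for s in cfg.inputs(half):
                out[:, self.segments_.index(s), :] = db.segment_quats(s)
            pred = self.estimators_[half].predict(db.features(cfg, half))
            outs = cfg.outputs(half)
            blocks = pred.reshape(n, len(outs), 4)
            for j, s in enumerate(outs):
                out[:, self.segments_.index(s), :] = blocks[:, j, :]
        return out
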