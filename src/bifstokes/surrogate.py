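"""Neural-network surrogates for bifurcation conductances.

Conductance components vary smoothly with the dimensionless geometry
parameters, so a small feedforward regressor trained on batches of Stokes
solves replaces further simulations.  Two parameter spaces are supported:

* ``straight`` -- (D1, D2, alpha, beta) uniform on [0.5, 1]^2 x [0, pi/2]^2
  with L = 2 and straight walls, invalid geometries rejection-sampled away;
* ``particle`` -- (X0, Y0, R) uniform on [-1, 1]^2 x (0, 0.3] for a fixed
  cylinder in the symmetric bifurcation (D1 = D2 = 1, alpha = beta = pi/4),
  keeping only particles clear of the walls.

One independent model is trained per conductance component.  The network is
fixed at three hidden layers of 20 rectified-linear units; inputs are
z-scored, training minimizes the mean squared error with a full-batch
quasi-Newton optimizer (L-BFGS), and the reported MSEs are on the raw
conductance scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BifurcationSpec, build_bifurcation, validate_spec
from .network_reduction import conductance_tensor
from .stokes_solver import SolverOptions

__all__ = [
    "TrainingSet",
    "SurrogateModel",
    "TrainingReport",
    "generate_dataset",
    "train_surrogate",
    "predict_conductance",
    "save_model",
    "load_model",
]

SPACES = {
    "straight": ("D1", "D2", "alpha", "beta"),
    "particle": ("X0", "Y0", "R"),
}


@dataclass
class TrainingSet:
    space: str
    inputs: pd.DataFrame  # one row per geometry
    targets: pd.DataFrame  # columns G0, G1, G2
    seed: int
    train_idx: np.ndarray
    val_idx: np.ndarray

    @property
    def feature_names(self):
        return SPACES[self.space]


@dataclass
class TrainingReport:
    mse_train: float
    mse_validation: float
    n_train: int
    n_validation: int
    iterations: int


@dataclass
class SurrogateModel:
    """Deterministic forward pass of the trained [in,20,20,20,1] network."""

    space: str
    target: str  # "G0" | "G1" | "G2"
    weights: list  # list of (W, b) arrays, output layer last
    x_mean: np.ndarray
    x_std: np.ndarray
    x_min: np.ndarray
    x_max: np.ndarray
    training_seed: int
    layer_sizes: list = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.x_mean):
            raise ValueError(
                f"expected {len(self.x_mean)} features, got {X.shape[1]}")
        if (X < self.x_min - 1e-12).any() or (X > self.x_max + 1e-12).any():
            warnings.warn("parameters outside the training hypercube: "
                          "the surrogate is extrapolating", stacklevel=2)
        a = (X - self.x_mean) / self.x_std
        for W, b in self.weights[:-1]:
            a = np.maximum(a @ W + b, 0.0)
        W, b = self.weights[-1]
        return (a @ W + b).ravel()


def _sample_row(space: str, rng: np.random.Generator):
    if space == "straight":
        return {
            "D1": rng.uniform(0.5, 1.0),
            "D2": rng.uniform(0.5, 1.0),
            "alpha": rng.uniform(0.0, math.pi / 2),
            "beta": rng.uniform(0.0, math.pi / 2),
        }
    if space == "particle":
        return {
            "X0": rng.uniform(-1.0, 1.0),
            "Y0": rng.uniform(-1.0, 1.0),
            "R": rng.uniform(0.0, 0.3),
        }
    raise ValueError(f"unknown parameter space {space!r}")


def _row_spec(space: str, row: dict) -> BifurcationSpec:
    if space == "straight":
        return BifurcationSpec(D1=row["D1"], D2=row["D2"],
                               alpha=row["alpha"], beta=row["beta"], L=2.0)
    return BifurcationSpec(D1=1.0, D2=1.0, alpha=math.pi / 4,
                           beta=math.pi / 4, L=2.0,
                           particle=(row["X0"], row["Y0"], row["R"]))


def generate_dataset(space: str, n: int, seed: int,
                     options: SolverOptions | None = None,
                     val_fraction: float = 0.2) -> TrainingSet:
    """Rejection-sample ``n`` valid geometries and solve each for (G0,G1,G2).

    Rows whose solve reports a residual warning are re-solved at doubled
    boundary resolution.  The 80/20 train/validation split is drawn from the
    same seeded generator, so identical (space, n, seed) reproduce the
    dataset bit for bit.
    """
    if n < 10:
        raise ValueError("need at least 10 rows")
    if options is None:
        from .stokes_solver import FAST
        options = FAST
    rng = np.random.default_rng(seed)
    rows, targets = [], []
    attempts = 0
    while len(rows) < n:
        attempts += 1
        if attempts > max(100 * n, 1000) and len(rows) < attempts / 100:
            raise RuntimeError(
                "parameter-space acceptance rate below 1%: misconfigured")
        row = _sample_row(space, rng)
        spec = _row_spec(space, row)
        row_r = row.get("R")
        if row_r is not None and row_r < 1e-3:
            continue
        if not validate_spec(spec).ok:
            continue
        domain = build_bifurcation(spec)
        cond = _solve_row(domain, options)
        if cond is None:
            continue
        rows.append(row)
        targets.append(dict(zip(("G0", "G1", "G2"), cond.triple)))
    inputs = pd.DataFrame(rows, columns=list(SPACES[space]))
    targ = pd.DataFrame(targets)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    return TrainingSet(space, inputs, targ, seed,
                       train_idx=np.sort(perm[n_val:]),
                       val_idx=np.sort(perm[:n_val]))


def _solve_row(domain, options):
    cond, sols = conductance_tensor(domain, options, return_solutions=True)
    if any("warning" in s.residual_report for s in sols):
        # escalate to the reference resolution once
        cond = conductance_tensor(domain, SolverOptions())
    return cond


def train_surrogate(dataset: TrainingSet, target: str = "G1",
                    seed: int = 0, hidden=(20, 20, 20),
                    max_iter: int = 5000, tol: float = 1e-9):
    """Fit one conductance component; returns (SurrogateModel, report)."""
    from sklearn.neural_network import MLPRegressor

    X = dataset.inputs.to_numpy(dtype=float)
    y = dataset.targets[target].to_numpy(dtype=float)
    tr, va = dataset.train_idx, dataset.val_idx
    mean = X[tr].mean(axis=0)
    std = X[tr].std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std

    if np.ptp(y[tr]) < 1e-15:
        # constant target: the zero-hidden-weight network is exact
        const = float(y[tr][0])
        sizes = [X.shape[1], *hidden, 1]
        weights = []
        fan_in = X.shape[1]
        for h in hidden:
            weights.append((np.zeros((fan_in, h)), np.zeros(h)))
            fan_in = h
        weights.append((np.zeros((fan_in, 1)), np.full(1, const)))
        model = SurrogateModel(dataset.space, target, weights, mean, std,
                               X.min(axis=0), X.max(axis=0), seed, sizes)
        return model, TrainingReport(0.0, 0.0, len(tr), len(va), 0)

    # train on the z-scored target so the optimizer's gradient tolerance is
    # meaningful at conductance scale (~1e-2); fold the unscaling into the
    # linear output layer afterwards
    y_mean, y_std = y[tr].mean(), y[tr].std()
    reg = MLPRegressor(hidden_layer_sizes=hidden, activation="relu",
                       solver="lbfgs", alpha=0.0, max_iter=max_iter,
                       tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg.fit(Xs[tr], (y[tr] - y_mean) / y_std)
    if not np.isfinite(reg.loss_):
        raise RuntimeError("training diverged to a non-finite loss")
    weights = [(W.copy(), b.copy())
               for W, b in zip(reg.coefs_, reg.intercepts_)]
    W_out, b_out = weights[-1]
    weights[-1] = (W_out * y_std, b_out * y_std + y_mean)
    model = SurrogateModel(dataset.space, target, weights, mean, std,
                           X.min(axis=0), X.max(axis=0), seed,
                           [X.shape[1], *hidden, 1])
    pred = model.predict(X)
    report = TrainingReport(
        mse_train=float(np.mean((pred[tr] - y[tr]) ** 2)),
        mse_validation=float(np.mean((pred[va] - y[va]) ** 2)),
        n_train=len(tr), n_validation=len(va),
        iterations=int(reg.n_iter_))
    return model, report


def predict_conductance(model: SurrogateModel, params) -> np.ndarray:
    """Vectorized forward pass; warns when extrapolating."""
    return model.predict(params)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: SurrogateModel, path) -> None:
    doc = {
        "space": model.space,
        "target": model.target,
        "layer_sizes": list(model.layer_sizes),
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "x_min": model.x_min.tolist(),
        "x_max": model.x_max.tolist(),
        "training_seed": model.training_seed,
        "weights": [{"W": W.tolist(), "b": b.tolist()}
                    for W, b in model.weights],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> SurrogateModel:
    with open(path) as fh:
        doc = json.load(fh)
    weights = [(np.asarray(d["W"], dtype=float),
                np.asarray(d["b"], dtype=float)) for d in doc["weights"]]
    return SurrogateModel(doc["space"], doc["target"], weights,
                          np.asarray(doc["x_mean"]), np.asarray(doc["x_std"]),
                          np.asarray(doc["x_min"]), np.asarray(doc["x_max"]),
                          doc["training_seed"], doc["layer_sizes"])
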