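"""Trainable coarse-grained potential with force-matching.

The potential energy of a CG conformation ``R`` with bead embeddings ``z`` is
modelled as a sum of type-pair radial terms expanded in a smooth basis::

    U(R, z; theta) = sum_{i<j, r_ij < r_c}  theta[p(z_i, z_j), :] . phi(r_ij)

where ``phi`` are Gaussian radial basis functions under a cosine cutoff
envelope that brings the energy (and its gradient) smoothly to zero at the
receptive-field radius ``r_c`` (default 10 A).  The energy depends on
interatomic distances only, so it is exactly invariant under translations,
rotations and reflections, and the forces — the analytic negative coordinate
gradient — are exactly equivariant.  The model carries no prior terms: at
``theta = 0`` the energy and all forces are identically zero.

Because the energy is linear in ``theta``, predicted forces are a linear map
of the parameters; a closed-form least-squares solution of the force-matching
problem exists and serves as an independent check on the mini-batch trainer.

Training minimizes the force-matching loss

    L = (1/K) sum_k  1/(3 N_k)  || F_pred(R_k) - F_label(R_k) ||^2

with K conformations per batch and N_k beads in conformation k (the mean is
over force components, making the loss an expected squared error per component
in (kcal/mol/A)^2 regardless of system size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cg_mapping import BeadTypingError, CGFrame
from .dataset_builder import CGDataset

__all__ = [
    "TrainingError",
    "PairRBFPotential",
    "LossBatch",
    "TrainConfig",
    "model_energy",
    "model_forces",
    "force_matching_loss",
    "train",
    "fit_least_squares",
    "evaluate_forces",
    "neighbor_pairs",
]


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


def neighbor_pairs(coords: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """All pairs (i < j) within *cutoff*, by exact all-pairs search.

    Exact and allocation-light for the system sizes this package targets
    (toy molecules and sub-1000-bead domains).
    """
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    d = coords[ii] - coords[jj]
    r = np.linalg.norm(d, axis=1)
    keep = r < cutoff
    return ii[keep], jj[keep]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class PairRBFPotential:
    """Type-pair radial-basis potential, linear in its parameters.

    Parameters
    ----------
    n_types:
        Number of bead embedding values the model accepts.
    cutoff:
        Receptive field in A; no interaction beyond it.
    n_basis:
        Number of Gaussian radial basis functions spanning (0, cutoff).
    params:
        Coefficient array of shape ``(n_pair_types, n_basis)`` where
        ``n_pair_types = n_types (n_types + 1) / 2`` (unordered type pairs).
        Zero-initialized when omitted.
    """

    n_types: int
    cutoff: float = 10.0
    n_basis: int = 32
    params: np.ndarray | None = None
    #: basis centres and width, derived from cutoff/n_basis unless given
    centers: np.ndarray = field(default=None, repr=False)
    width: float = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.centers is None:
            self.centers = np.linspace(0.0, self.cutoff, self.n_basis)
        else:
            self.centers = np.asarray(self.centers, dtype=float)
            self.n_basis = len(self.centers)
        if self.width is None:
            self.width = float(self.centers[1] - self.centers[0]) if self.n_basis > 1 else self.cutoff
        if self.params is None:
            self.params = np.zeros((self.n_pair_types, self.n_basis))
        else:
            self.params = np.asarray(self.params, dtype=float)
            if self.params.shape != (self.n_pair_types, self.n_basis):
                raise ValueError(
                    f"params must have shape {(self.n_pair_types, self.n_basis)}"
                )

    @property
    def n_pair_types(self) -> int:
        return self.n_types * (self.n_types + 1) // 2

    @property
    def n_params(self) -> int:
        return self.n_pair_types * self.n_basis

    def pair_type(self, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """Index of the unordered type pair (t1, t2)."""
        lo = np.minimum(t1, t2)
        hi = np.maximum(t1, t2)
        return hi * (hi + 1) // 2 + lo

    def _check_types(self, bead_types: np.ndarray) -> None:
        if bead_types.size and (bead_types.min() < 0 or bead_types.max() >= self.n_types):
            raise BeadTypingError(
                f"bead type out of range [0, {self.n_types}): "
                f"{sorted(set(bead_types.tolist()) - set(range(self.n_types)))}"
            )

    def _basis(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Basis values and radial derivatives at distances *r* (< cutoff)."""
        dr = r[:, None] - self.centers[None, :]
        g = np.exp(-0.5 * (dr / self.width) ** 2)
        envelope = 0.5 * (1.0 + np.cos(np.pi * r / self.cutoff))
        d_envelope = -0.5 * np.pi / self.cutoff * np.sin(np.pi * r / self.cutoff)
        phi = g * envelope[:, None]
        dphi = g * (-dr / self.width**2) * envelope[:, None] + g * d_envelope[:, None]
        return phi, dphi

    # -- evaluation ---------------------------------------------------------

    def energy(self, frame: CGFrame) -> float:
        """Potential energy in kcal/mol."""
        self._check_types(frame.bead_types)
        ii, jj = neighbor_pairs(frame.coords, self.cutoff)
        if ii.size == 0:
            return 0.0
        r = np.linalg.norm(frame.coords[ii] - frame.coords[jj], axis=1)
        phi, _ = self._basis(r)
        p = self.pair_type(frame.bead_types[ii], frame.bead_types[jj])
        return float(np.einsum("kb,kb->", phi, self.params[p]))

    def forces(self, frame: CGFrame) -> np.ndarray:
        """Analytic forces, -dU/dR, in kcal/mol/A."""
        self._check_types(frame.bead_types)
        n = frame.n_beads
        out = np.zeros((n, 3))
        ii, jj = neighbor_pairs(frame.coords, self.cutoff)
        if ii.size == 0:
            return out
        d = frame.coords[ii] - frame.coords[jj]
        r = np.linalg.norm(d, axis=1)
        _, dphi = self._basis(r)
        p = self.pair_type(frame.bead_types[ii], frame.bead_types[jj])
        du_dr = np.einsum("kb,kb->k", dphi, self.params[p])  # dU/dr per pair
        pair_force = -(du_dr / r)[:, None] * d  # force on i; on j it is opposite
        np.add.at(out, ii, pair_force)
        np.add.at(out, jj, -pair_force)
        return out

    def force_features(self, frame: CGFrame) -> np.ndarray:
        """Design tensor G of shape (n, 3, n_params) with forces = G @ params.ravel().

        Exposes the linearity of the model; used by the least-squares fit and
        by the trainer's per-batch quadratic-form precomputation.
        """
        self._check_types(frame.bead_types)
        n = frame.n_beads
        g = np.zeros((n, 3, self.n_pair_types, self.n_basis))
        ii, jj = neighbor_pairs(frame.coords, self.cutoff)
        if ii.size:
            d = frame.coords[ii] - frame.coords[jj]
            r = np.linalg.norm(d, axis=1)
            _, dphi = self._basis(r)
            p = self.pair_type(frame.bead_types[ii], frame.bead_types[jj])
            unit = d / r[:, None]
            contrib = -unit[:, :, None] * dphi[:, None, :]  # (pairs, 3, basis)
            for k in range(len(ii)):
                g[ii[k], :, p[k], :] += contrib[k]
                g[jj[k], :, p[k], :] -= contrib[k]
        return g.reshape(n, 3, self.n_params)

    def copy(self) -> "PairRBFPotential":
        return PairRBFPotential(
            n_types=self.n_types,
            cutoff=self.cutoff,
            n_basis=self.n_basis,
            params=self.params.copy(),
            centers=self.centers.copy(),
            width=self.width,
        )

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Versioned checkpoint: hyperparameters as JSON attrs plus parameters."""
        meta = {
            "format": "nohcg-pair-rbf/1",
            "n_types": self.n_types,
            "cutoff": self.cutoff,
            "n_basis": self.n_basis,
            "width": self.width,
        }
        np.savez(
            path,
            params=self.params,
            centers=self.centers,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "PairRBFPotential":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format") != "nohcg-pair-rbf/1":
                raise ValueError(f"unrecognized checkpoint format: {meta.get('format')}")
            return cls(
                n_types=int(meta["n_types"]),
                cutoff=float(meta["cutoff"]),
                n_basis=int(meta["n_basis"]),
                params=data["params"],
                centers=data["centers"],
                width=float(meta["width"]),
            )


def model_energy(model: PairRBFPotential, frame: CGFrame) -> float:
    """Scalar potential energy of *frame* under *model* (kcal/mol)."""
    return model.energy(frame)


def model_forces(model: PairRBFPotential, frame: CGFrame) -> np.ndarray:
    """Predicted bead forces, the negative energy gradient (kcal/mol/A)."""
    return model.forces(frame)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

@dataclass
class LossBatch:
    """Predicted and labelled forces for K conformations (possibly ragged)."""

    predicted: list[np.ndarray]
    labeled: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.predicted) != len(self.labeled):
            raise ValueError("predicted and labeled lists must align")
        for p, f in zip(self.predicted, self.labeled):
            if np.shape(p) != np.shape(f) or np.shape(p)[0] < 1:
                raise ValueError("per-conformation force shapes must agree, N_k >= 1")


def force_matching_loss(batch: LossBatch) -> float:
    """Mean squared force deviation, averaged per component then per conformation.

    ``L = (1/K) sum_k (1/(3 N_k)) sum_{i,a} (F_pred - F_label)^2`` in
    (kcal/mol/A)^2.
    """
    if len(batch.predicted) == 0:
        raise ValueError("empty batch")
    total = 0.0
    for pred, lab in zip(batch.predicted, batch.labeled):
        resid = np.asarray(pred, dtype=float) - np.asarray(lab, dtype=float)
        total += float(np.sum(resid**2)) / (3.0 * resid.shape[0])
    return total / len(batch.predicted)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer settings for the mini-batch Adam trainer."""

    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 5e-3
    lr_decay: float = 1.0  # multiplicative per-epoch factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")


def _active_columns(model: PairRBFPotential, datasets) -> np.ndarray:
    """Parameter columns whose pair type is realized in any dataset.

    Features of unrealized type pairs are identically zero, so the loss is
    flat along them; restricting the quadratic forms to realized pairs keeps
    the cost proportional to the chemistry actually present.
    """
    pairs: set[int] = set()
    for dataset in datasets:
        for frame in dataset.frames:
            t = np.unique(frame.bead_types)
            grid_a, grid_b = np.meshgrid(t, t)
            pairs.update(model.pair_type(grid_a.ravel(), grid_b.ravel()).tolist())
    cols = [
        p * model.n_basis + b for p in sorted(pairs) for b in range(model.n_basis)
    ]
    return np.asarray(cols, dtype=int)


def _batch_quadratics(
    model: PairRBFPotential, dataset: CGDataset, batch_size: int, cols: np.ndarray
):
    """Per-batch quadratic forms of the loss, restricted to active columns.

    For a linear model the per-conformation loss is
    ``(theta^T A theta - 2 b.theta + c) / (3 N_k)`` with
    ``A = G^T G``, ``b = G^T F``, ``c = ||F||^2``; batches store the
    conformation-averaged forms so each epoch costs O(P^2) per batch.
    """
    out = []
    n = len(dataset)
    for start in range(0, n, batch_size):
        idx = range(start, min(start + batch_size, n))
        a = np.zeros((len(cols), len(cols)))
        b = np.zeros(len(cols))
        c = 0.0
        for i in idx:
            frame = dataset.frames[i]
            if frame.forces is None:
                raise ValueError("training frames must carry force labels")
            g = model.force_features(frame).reshape(-1, model.n_params)[:, cols]
            f = frame.forces.ravel()
            w = 1.0 / (3.0 * frame.n_beads)
            a += w * (g.T @ g)
            b += w * (g.T @ f)
            c += w * float(f @ f)
        k = len(idx)
        out.append((a / k, b / k, c / k))
    return out


def _quadratic_loss(theta: np.ndarray, quads) -> float:
    k = len(quads)
    return sum(float(theta @ a @ theta - 2.0 * b @ theta + c) for a, b, c in quads) / k


def train(
    model: PairRBFPotential,
    train_set: CGDataset,
    val_set: CGDataset,
    config: TrainConfig,
) -> tuple[PairRBFPotential, dict]:
    """Minimize the force-matching loss with mini-batch Adam.

    Deterministic given ``config.seed`` (batch order shuffling is the only
    randomness).  Returns the best-validation-loss model and a history dict
    with per-epoch ``train_loss`` and ``val_loss``.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    cols = _active_columns(model, [train_set, val_set])
    quads = _batch_quadratics(model, train_set, config.batch_size, cols)
    val_quads = _batch_quadratics(model, val_set, max(len(val_set), 1), cols)

    theta = model.params.ravel()[cols].copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    t = 0
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_theta = theta.copy()
    for epoch in range(config.epochs):
        for bi in rng.permutation(len(quads)):
            a, b, _ = quads[bi]
            grad = 2.0 * (a @ theta - b)
            t += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            theta -= lr * m_hat / (np.sqrt(v_hat) + eps)
        lr *= config.lr_decay
        train_loss = _quadratic_loss(theta, quads)
        val_loss = _quadratic_loss(theta, val_quads)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_theta = theta.copy()

    trained = model.copy()
    full = trained.params.ravel()
    full[cols] = best_theta
    trained.params = full.reshape(model.params.shape)
    return trained, history


def fit_least_squares(
    model: PairRBFPotential, dataset: CGDataset, ridge: float = 0.0
) -> PairRBFPotential:
    """Closed-form force-matching solution via the normal equations.

    Solves ``min_theta sum_k ||G_k theta - F_k||^2 / (3 N_k)`` exactly
    (optionally ridge-regularized); for a linear model this is the global
    optimum the iterative trainer approaches.
    """
    cols = _active_columns(model, [dataset])
    a = np.zeros((len(cols), len(cols)))
    b = np.zeros(len(cols))
    for frame in dataset.frames:
        if frame.forces is None:
            raise ValueError("frames must carry force labels")
        g = model.force_features(frame).reshape(-1, model.n_params)[:, cols]
        w = 1.0 / (3.0 * frame.n_beads)
        a += w * (g.T @ g)
        b += w * (g.T @ frame.forces.ravel())
    if ridge > 0:
        a = a + ridge * np.eye(len(cols))
    theta, *_ = np.linalg.lstsq(a, b, rcond=None)
    fitted = model.copy()
    full = fitted.params.ravel()
    full[cols] = theta
    fitted.params = full.reshape(model.params.shape)
    return fitted


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_forces(model: PairRBFPotential, dataset: CGDataset) -> dict:
    """Force-component MAE overall and grouped by bead type.

    Returns ``{"mae": float, "per_type_mae": {type_id: float},
    "n_components": int}`` with MAE taken over all Cartesian force components
    (kcal/mol/A).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    abs_sum = 0.0
    n_comp = 0
    type_sums: dict[int, float] = {}
    type_counts: dict[int, int] = {}
    for frame in dataset.frames:
        if frame.forces is None:
            raise ValueError("frames must carry force labels")
        err = np.abs(model.forces(frame) - frame.forces)
        abs_sum += float(err.sum())
        n_comp += err.size
        for t in np.unique(frame.bead_types):
            sel = frame.bead_types == t
            type_sums[int(t)] = type_sums.get(int(t), 0.0) + float(err[sel].sum())
            type_counts[int(t)] = type_counts.get(int(t), 0) + int(sel.sum() * 3)
    return {
        "mae": abs_sum / n_comp,
        "per_type_mae": {t: type_sums[t] / type_counts[t] for t in sorted(type_sums)},
        "n_components": n_comp,
    }
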