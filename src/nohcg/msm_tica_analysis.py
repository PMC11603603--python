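"""Thermodynamic-consistency analysis: TICA, microstate MSMs, free-energy surfaces.

The analysis pipeline mirrors the standard Markov-state-model workflow for
protein trajectories:

1. featurize each frame by its pairwise C-alpha distances (rigid-motion
   invariant, fixed ``i < j`` ordering);
2. project onto the slowest linearly decorrelating directions with
   time-lagged independent component analysis (TICA), solving the symmetrized
   lagged generalized eigenproblem ``C_tau v = lambda C_0 v``;
3. discretize the projected space with seeded k-means microstates;
4. estimate a reversible Markov state model at lag ``tau`` from
   sliding-window transition counts (after discarding an initial fraction of
   each trajectory), with the stationary distribution from the model's left
   eigenvector;
5. turn stationary weights into a two-dimensional free-energy surface over an
   80 x 80 grid of the first two components, in units of k_B T;
6. locate the native macrostate — the macrostate containing the conformation
   of minimum C-alpha RMSD (optimal Kabsch superposition) to a reference
   structure — and report per-macrostate equilibrium probabilities and RMSDs.

Coarse-grained trajectories are projected with the *all-atom* means and TICA
vectors (no refitting), so both resolutions land in the same reduced space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

__all__ = [
    "TICAModel",
    "MSMResult",
    "FreeEnergySurface",
    "featurize_ca_distances",
    "tica_fit",
    "tica_transform",
    "project_cg",
    "cluster_kmeans",
    "estimate_msm",
    "stationary_distribution",
    "free_energy_surface",
    "kabsch_rmsd",
    "macrostate_stats",
    "assign_macrostates",
]


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def featurize_ca_distances(
    trajectory: np.ndarray, ca_indices: np.ndarray | list[int] | None = None
) -> np.ndarray:
    """All unique pairwise C-alpha distances per frame.

    *trajectory* is (T, n, 3); *ca_indices* selects the C-alpha atoms/beads
    (all sites when omitted).  Columns are ordered lexicographically by the
    index pair (i < j).
    """
    coords = np.asarray(trajectory, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("trajectory must be (T, n, 3)")
    if ca_indices is not None:
        coords = coords[:, np.asarray(ca_indices, dtype=int), :]
    n = coords.shape[1]
    if n < 2:
        raise ValueError("need at least two C-alpha sites")
    ii, jj = np.triu_indices(n, k=1)
    return np.linalg.norm(coords[:, ii, :] - coords[:, jj, :], axis=2)


# ---------------------------------------------------------------------------
# TICA
# ---------------------------------------------------------------------------

@dataclass
class TICAModel:
    """Result of the symmetrized TICA eigenproblem."""

    mean: np.ndarray              # (d,)
    cov: np.ndarray               # (d, d) instantaneous covariance
    cov_lagged: np.ndarray        # (d, d) symmetrized lagged covariance
    eigenvalues: np.ndarray       # descending, real
    components: np.ndarray        # (d, n_components) projection vectors
    lag: int
    regularization: float = 0.0


def tica_fit(
    features: np.ndarray | list[np.ndarray],
    lag: int,
    regularization: float = 1e-10,
    strict: bool = False,
) -> TICAModel:
    """Fit TICA at integer lag *lag* (frames) on one or more feature arrays.

    Uses the symmetrized estimators
    ``C0 = (X'X + Y'Y) / 2m`` and ``Ct = (X'Y + Y'X) / 2m`` over all lagged
    pairs (X instantaneous, Y lagged), then solves ``Ct v = lambda C0 v``.
    Symmetrization makes the eigenvalues real and at most 1.  A small ridge is
    added to C0 when it is singular (reported on the model; an error instead
    when ``strict``).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    blocks = [np.asarray(f, dtype=float) for f in
              (features if isinstance(features, list) else [features])]
    d = blocks[0].shape[1]
    pairs_x, pairs_y = [], []
    for block in blocks:
        if block.shape[0] > lag:
            pairs_x.append(block[:-lag])
            pairs_y.append(block[lag:])
    if not pairs_x:
        raise ValueError("no trajectory longer than the lag")
    x = np.concatenate(pairs_x)
    y = np.concatenate(pairs_y)
    mean = np.concatenate([x, y]).mean(axis=0)
    xc, yc = x - mean, y - mean
    m = x.shape[0]
    c0 = (xc.T @ xc + yc.T @ yc) / (2.0 * m)
    ct = (xc.T @ yc + yc.T @ xc) / (2.0 * m)

    applied = 0.0
    try:
        scipy.linalg.cholesky(c0)
    except scipy.linalg.LinAlgError:
        if strict:
            raise ValueError("singular instantaneous covariance (strict mode)")
        applied = regularization * max(np.trace(c0) / d, 1.0)
        c0 = c0 + applied * np.eye(d)
    eigval, eigvec = scipy.linalg.eigh(ct, c0)
    order = np.argsort(eigval)[::-1]
    return TICAModel(
        mean=mean,
        cov=c0,
        cov_lagged=ct,
        eigenvalues=eigval[order],
        components=eigvec[:, order],
        lag=lag,
        regularization=applied,
    )


def tica_transform(
    model: TICAModel, features: np.ndarray, n_components: int = 4
) -> np.ndarray:
    """Project mean-centred features onto the leading TICA components."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {features.shape[1]} != model dimension "
            f"{model.mean.shape[0]}"
        )
    return (features - model.mean) @ model.components[:, :n_components]


def project_cg(
    model: TICAModel, cg_features: np.ndarray, n_components: int = 3
) -> np.ndarray:
    """Project CG features with the all-atom TICA basis, without refitting.

    The all-atom means and projection vectors are applied as-is, so all-atom
    and CG data share one reduced space; projecting the all-atom features
    themselves reproduces :func:`tica_transform` exactly.
    """
    return tica_transform(model, cg_features, n_components=n_components)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_kmeans(
    projections: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, "KMeans"]:
    """Seeded k-means microstates (k-means++ init); returns (labels, estimator)."""
    projections = np.asarray(projections, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > projections.shape[0]:
        raise ValueError("k exceeds the number of frames")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(projections)
    return labels.astype(np.int64), km


# ---------------------------------------------------------------------------
# MSM estimation
# ---------------------------------------------------------------------------

@dataclass
class MSMResult:
    """Reversible MSM over the largest connected set of microstates."""

    transition_matrix: np.ndarray     # (m, m), row-stochastic
    lag: int
    stationary: np.ndarray            # (m,)
    active_states: np.ndarray         # original microstate labels of the rows
    count_matrix: np.ndarray
    macrostates: np.ndarray | None = None  # per-active-state macrostate labels
    connected: bool = True


def _count_transitions(label_blocks, n_states: int, lag: int) -> np.ndarray:
    counts = np.zeros((n_states, n_states))
    for labels in label_blocks:
        if len(labels) > lag:
            np.add.at(counts, (labels[:-lag], labels[lag:]), 1.0)
    return counts


def _largest_connected(counts: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components

    n_comp, assignment = connected_components(counts > 0, directed=True,
                                              connection="strong")
    sizes = np.bincount(assignment, minlength=n_comp)
    # weight by counts so an isolated self-looping state does not win
    weights = np.array([
        counts[assignment == c][:, assignment == c].sum() for c in range(n_comp)
    ])
    best = int(np.argmax(weights + sizes * 1e-9))
    return np.flatnonzero(assignment == best)


def _reversible_mle(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 10000):
    """Maximum-likelihood reversible transition matrix (fixed-point iteration).

    Iterates ``x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)`` on the
    symmetric flux matrix x; converges to the reversible MLE for connected
    count matrices.
    """
    c_sym = counts + counts.T
    c_row = counts.sum(axis=1)
    x = c_sym.copy()
    x_row = x.sum(axis=1)
    for _ in range(max_iter):
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new_row = x_new.sum(axis=1)
        delta = np.max(np.abs(x_new_row / x_new_row.sum() - x_row / x_row.sum()))
        x, x_row = x_new, x_new_row
        if delta < tol:
            break
    t = x / x_row[:, None]
    pi = x_row / x_row.sum()
    return t, pi


def estimate_msm(
    labels: np.ndarray | list[np.ndarray],
    lag: int,
    frame_discard_fraction: float = 0.10,
    reversible: bool = True,
) -> MSMResult:
    """Estimate an MSM from per-trajectory microstate label sequences.

    The leading *frame_discard_fraction* of each trajectory is removed (to
    avoid bias from the chosen starting conformations), sliding-window
    transitions are counted at *lag*, the largest strongly connected state set
    is retained, and the reversible maximum-likelihood transition matrix is
    estimated (row-normalized counts when ``reversible=False``).  The
    stationary distribution is the leading left eigenvector.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if not 0.0 <= frame_discard_fraction < 1.0:
        raise ValueError("frame_discard_fraction must lie in [0, 1)")
    blocks = [np.asarray(b, dtype=np.int64) for b in
              (labels if isinstance(labels, list) else [labels])]
    blocks = [b[int(np.floor(frame_discard_fraction * len(b))):] for b in blocks]
    n_states = int(max(b.max() for b in blocks if b.size)) + 1
    counts = _count_transitions(blocks, n_states, lag)

    active = _largest_connected(counts)
    connected = len(active) == len(np.flatnonzero(counts.sum(axis=1) + counts.sum(axis=0)))
    sub = counts[np.ix_(active, active)]
    if reversible:
        t, pi = _reversible_mle(sub)
    else:
        rows = sub.sum(axis=1)
        rows[rows == 0] = 1.0
        t = sub / rows[:, None]
        pi = stationary_distribution(t)
    return MSMResult(
        transition_matrix=t,
        lag=lag,
        stationary=pi,
        active_states=active,
        count_matrix=sub,
        connected=connected,
    )


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized."""
    eigval, eigvec = scipy.linalg.eig(t.T)
    idx = int(np.argmax(eigval.real))
    pi = np.abs(eigvec[:, idx].real)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """Two-dimensional free energy in k_B T units, min-shifted to 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray       # (nx, ny); NaN on empty bins
    temperature: float
    populated: np.ndarray = field(default=None)  # boolean mask

    def __post_init__(self) -> None:
        if self.populated is None:
            self.populated = np.isfinite(self.free_energy)


def free_energy_surface(
    projections: np.ndarray,
    weights: np.ndarray | None = None,
    grid: int = 80,
    temperature: float = 350.0,
    extent: tuple[float, float, float, float] | None = None,
) -> FreeEnergySurface:
    """Weighted 2-D free-energy surface over the first two projection columns.

    Each frame contributes its equilibrium weight to its bin; the surface is
    ``F = -ln(p)`` in k_B T units, shifted so the minimum over populated bins
    is exactly 0.  Weights need not be normalized (uniform rescaling cancels).
    The grid spans the data range unless *extent* is given.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.ndim != 2 or projections.shape[1] < 2:
        raise ValueError("projections must have at least two columns")
    xy = projections[:, :2]
    if weights is None:
        weights = np.ones(len(xy))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(xy),):
        raise ValueError("weights must have one entry per frame")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    if extent is None:
        extent = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())
    x_edges = np.linspace(extent[0], extent[1], grid + 1)
    y_edges = np.linspace(extent[2], extent[3], grid + 1)
    hist, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(x_edges, y_edges),
                                weights=weights / total)
    if not np.any(hist > 0):
        raise ValueError("all grid bins are empty")
    with np.errstate(divide="ignore"):
        f = -np.log(hist, where=hist > 0, out=np.full_like(hist, np.nan))
    f -= np.nanmin(f)
    return FreeEnergySurface(
        x_edges=x_edges, y_edges=y_edges, free_energy=f, temperature=temperature
    )


# ---------------------------------------------------------------------------
# RMSD and macrostates
# ---------------------------------------------------------------------------

def kabsch_rmsd(coords: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD after optimal superposition (Kabsch, proper rotation)."""
    p = np.asarray(coords, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return float(np.sqrt(np.mean(np.sum((pc @ rot - qc) ** 2, axis=1))))


def assign_macrostates(msm: MSMResult, n_macrostates: int, seed: int = 0) -> np.ndarray:
    """Group microstates into macrostates by their slow-eigenvector signature.

    k-means on the stationary-weighted leading right eigenvectors of the
    transition matrix — a lightweight spectral lumping that separates
    metastable basins.  Stores the assignment on the MSM and returns it.
    """
    if n_macrostates < 1 or n_macrostates > msm.transition_matrix.shape[0]:
        raise ValueError("invalid macrostate count")
    t = msm.transition_matrix
    eigval, eigvec = scipy.linalg.eig(t)
    order = np.argsort(eigval.real)[::-1]
    n_vec = min(n_macrostates, t.shape[0])
    basis = eigvec[:, order[:n_vec]].real
    km = KMeans(n_clusters=n_macrostates, random_state=seed, n_init=10)
    macro = km.fit_predict(basis).astype(np.int64)
    msm.macrostates = macro
    return macro


def macrostate_stats(
    msm: MSMResult,
    trajectories: list[np.ndarray],
    labels: list[np.ndarray],
    reference: np.ndarray,
    n_macrostates: int = 2,
    frame_discard_fraction: float = 0.10,
    seed: int = 0,
) -> dict:
    """Per-macrostate equilibrium probability and C-alpha RMSD statistics.

    *trajectories* holds (T, n, 3) coordinate arrays aligned with the
    microstate *labels* used to build *msm* (same discard fraction applied);
    *reference* is the native-structure coordinate set on the same sites.
    The native macrostate is the one containing the frame of minimum RMSD.
    Returns ``{"macrostates": {id: {"probability", "mean_rmsd", "min_rmsd"}},
    "native_macrostate": id}``.
    """
    if msm.macrostates is None:
        assign_macrostates(msm, n_macrostates, seed=seed)
    state_to_macro = {int(s): int(m) for s, m in zip(msm.active_states, msm.macrostates)}
    state_to_row = {int(s): i for i, s in enumerate(msm.active_states)}

    rmsds: dict[int, list[float]] = {}
    for coords, labs in zip(trajectories, labels):
        coords = np.asarray(coords, dtype=float)
        labs = np.asarray(labs, dtype=np.int64)
        if coords.shape[0] != labs.shape[0]:
            raise ValueError("trajectory and label lengths differ")
        if coords.shape[1] != np.asarray(reference).shape[0]:
            raise ValueError("reference does not share the trajectory's site set")
        start = int(np.floor(frame_discard_fraction * len(labs)))
        for frame, lab in zip(coords[start:], labs[start:]):
            macro = state_to_macro.get(int(lab))
            if macro is None:
                continue
            rmsds.setdefault(macro, []).append(kabsch_rmsd(frame, reference))

    stats = {}
    for macro in sorted(set(state_to_macro.values())):
        prob = float(sum(
            msm.stationary[state_to_row[s]]
            for s, m in state_to_macro.items() if m == macro
        ))
        values = rmsds.get(macro, [])
        stats[macro] = {
            "probability": prob,
            "mean_rmsd": float(np.mean(values)) if values else float("nan"),
            "min_rmsd": float(np.min(values)) if values else float("nan"),
        }
    native = min(
        (m for m in stats if np.isfinite(stats[m]["min_rmsd"])),
        key=lambda m: stats[m]["min_rmsd"],
    )
    return {"macrostates": stats, "native_macrostate": native}
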