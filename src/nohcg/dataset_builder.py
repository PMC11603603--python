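"""Dataset curation: domain filters, stride/split, RSA and HDF5 round-trip.

Training data are coordinate-force pairs held in per-domain HDF5 groups, one
subgroup per simulation temperature (the mdCATH organization at reduced
complexity)::

    /<domain>/                attrs: residues, noh_atoms, helix_fraction,
                                     sheet_fraction
    /<domain>/types           int64 [n]       bead embeddings
    /<domain>/<T>/coords      float32 [F,n,3] angstrom
    /<domain>/<T>/forces      float32 [F,n,3] kcal/mol/A

Curation keeps domains with at most 150 residues, at most 1000 no-hydrogen
atoms, and a combined helix+sheet fraction of at least one half (boundaries
inclusive), pools all temperatures as extra variability, subsamples with a
stride (default 25), and splits frames into train/validation/test with a
seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .cg_mapping import CGFrame

__all__ = [
    "DatasetFormatError",
    "DomainRecord",
    "SplitSpec",
    "CGDataset",
    "filter_domains",
    "select_scaleup",
    "stride_and_split",
    "compute_rsa",
    "write_cg_dataset",
    "read_cg_dataset",
    "read_domain_records",
]

#: mdCATH simulation temperatures pooled into the training data (K).
TEMPERATURES = (320, 348, 379, 413, 450)


class DatasetFormatError(ValueError):
    """Raised when an HDF5 dataset file deviates from the documented layout."""


@dataclass
class DomainRecord:
    """Metadata and trajectory handles for one protein domain."""

    domain_id: str
    n_residues: int
    n_noh_atoms: int
    helix_fraction: float
    sheet_fraction: float
    #: temperature (K) -> (coords [F,n,3], forces [F,n,3])
    trajectories: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    bead_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_residues <= 0 or self.n_noh_atoms <= 0:
            raise ValueError(f"{self.domain_id}: counts must be positive")
        for frac in (self.helix_fraction, self.sheet_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.domain_id}: fractions must lie in [0, 1]")

    @property
    def ss_fraction(self) -> float:
        return self.helix_fraction + self.sheet_fraction


@dataclass
class SplitSpec:
    """Stride and train/validation/test fractions with a seed."""

    stride: int = 25
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if any(f < 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must be non-negative and sum to 1")


@dataclass
class CGDataset:
    """A flat list of labelled CG frames with domain/temperature provenance."""

    frames: list[CGFrame] = field(default_factory=list)
    domain_ids: list[str] = field(default_factory=list)
    temperatures: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.domain_ids) == len(self.temperatures)):
            raise ValueError("frames, domain_ids, temperatures must align")

    def __len__(self) -> int:
        return len(self.frames)

    def subset(self, idx) -> "CGDataset":
        idx = np.asarray(idx, dtype=int)
        return CGDataset(
            frames=[self.frames[i] for i in idx],
            domain_ids=[self.domain_ids[i] for i in idx],
            temperatures=[self.temperatures[i] for i in idx],
        )

    @classmethod
    def from_records(cls, records: list[DomainRecord]) -> "CGDataset":
        """Flatten filtered domain records into a labelled frame list."""
        ds = cls()
        for rec in records:
            if rec.bead_types is None:
                raise ValueError(f"{rec.domain_id}: bead types missing")
            for temp in sorted(rec.trajectories):
                coords, forces = rec.trajectories[temp]
                for c, f in zip(coords, forces):
                    ds.frames.append(
                        CGFrame(coords=c, bead_types=rec.bead_types, forces=f)
                    )
                    ds.domain_ids.append(rec.domain_id)
                    ds.temperatures.append(temp)
        return ds


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _require_metadata(rec: DomainRecord) -> None:
    for attr in ("n_residues", "n_noh_atoms", "helix_fraction", "sheet_fraction"):
        if getattr(rec, attr) is None:
            raise ValueError(f"domain {rec.domain_id}: missing metadata {attr}")


def filter_domains(
    records: list[DomainRecord],
    max_residues: int = 150,
    max_noh_atoms: int = 1000,
    min_ss_fraction: float = 0.5,
) -> list[DomainRecord]:
    """Training-set curation filter (boundaries inclusive, order preserved).

    Keeps domains with at most *max_residues* residues, at most *max_noh_atoms*
    no-hydrogen atoms, and at least *min_ss_fraction* combined helix+sheet
    content.
    """
    for rec in records:
        _require_metadata(rec)
    return [
        rec
        for rec in records
        if rec.n_residues <= max_residues
        and rec.n_noh_atoms <= max_noh_atoms
        and rec.ss_fraction >= min_ss_fraction
    ]


def select_scaleup(
    records: list[DomainRecord],
    min_residues: int = 150,
    max_residues: int = 250,
    min_ss_fraction: float = 0.5,
) -> list[DomainRecord]:
    """Band-pass selection of larger domains for scale-up evaluation."""
    for rec in records:
        _require_metadata(rec)
    return [
        rec
        for rec in records
        if min_residues <= rec.n_residues <= max_residues
        and rec.ss_fraction >= min_ss_fraction
    ]


# ---------------------------------------------------------------------------
# Stride and split
# ---------------------------------------------------------------------------

def stride_and_split(
    dataset: CGDataset, spec: SplitSpec
) -> tuple[CGDataset, CGDataset, CGDataset]:
    """Subsample every ``spec.stride``-th frame, then split by seeded shuffle.

    The stride is applied to the dataset's frame order (frames are stored
    per-domain, per-temperature contiguously, so this is a per-trajectory
    stride for single-trajectory inputs).  Splits are disjoint, reproducible
    from the seed, and exhaust the strided frames:
    ``|train| + |val| + |test| == ceil(N / stride)``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    strided = np.arange(0, len(dataset), spec.stride)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(strided))
    n = len(strided)
    n_train = int(round(spec.fractions[0] * n))
    n_val = int(round(spec.fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    idx_train = strided[np.sort(order[:n_train])]
    idx_val = strided[np.sort(order[n_train:n_train + n_val])]
    idx_test = strided[np.sort(order[n_train + n_val:])]
    return dataset.subset(idx_train), dataset.subset(idx_val), dataset.subset(idx_test)


# ---------------------------------------------------------------------------
# Relative shape anisotropy
# ---------------------------------------------------------------------------

def compute_rsa(coords: np.ndarray) -> float:
    """Relative shape anisotropy (kappa^2) from the gyration tensor.

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2 with l the
    gyration-tensor eigenvalues; 0 for spherically symmetric arrangements,
    1 for collinear ones.  Invariant under rotation, translation and uniform
    scaling.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    centred = coords - coords.mean(axis=0)
    gyration = centred.T @ centred / coords.shape[0]
    lam = np.linalg.eigvalsh(gyration)
    trace = lam.sum()
    if trace <= 0:
        raise ValueError("degenerate (zero-extent) coordinates")
    pair_sum = lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
    return float(1.0 - 3.0 * pair_sum / trace**2)


# ---------------------------------------------------------------------------
# HDF5 round-trip
# ---------------------------------------------------------------------------

def write_cg_dataset(dataset: CGDataset, path) -> None:
    """Write a CG dataset in the documented per-domain/per-temperature layout."""
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (dom, temp) in enumerate(zip(dataset.domain_ids, dataset.temperatures)):
        groups.setdefault((dom, temp), []).append(i)
    with h5py.File(path, "w") as fh:
        for (dom, temp), idx in groups.items():
            g = fh.require_group(dom)
            frames = [dataset.frames[i] for i in idx]
            if "types" not in g:
                g.create_dataset("types", data=frames[0].bead_types, dtype="int64")
            tg = g.create_group(str(temp))
            tg.create_dataset(
                "coords", data=np.stack([f.coords for f in frames]), dtype="<f4"
            )
            tg.create_dataset(
                "forces", data=np.stack([f.forces for f in frames]), dtype="<f4"
            )


def read_cg_dataset(path) -> CGDataset:
    """Read a CG dataset written by :func:`write_cg_dataset`."""
    ds = CGDataset()
    with h5py.File(path, "r") as fh:
        for dom in sorted(fh):
            g = fh[dom]
            if "types" not in g:
                raise DatasetFormatError(f"group '{dom}' is missing 'types'")
            types = g["types"][()]
            for temp in sorted(k for k in g if k != "types"):
                tg = g[temp]
                for name in ("coords", "forces"):
                    if name not in tg:
                        raise DatasetFormatError(
                            f"group '{dom}/{temp}' is missing '{name}'"
                        )
                coords = tg["coords"][()]
                forces = tg["forces"][()]
                for c, f in zip(coords, forces):
                    ds.frames.append(CGFrame(coords=c, bead_types=types, forces=f))
                    ds.domain_ids.append(dom)
                    ds.temperatures.append(int(temp))
    return ds


def read_domain_records(path) -> list[DomainRecord]:
    """Read per-domain metadata and trajectories from a fixture/dataset file."""
    records = []
    with h5py.File(path, "r") as fh:
        for dom in sorted(fh):
            g = fh[dom]
            try:
                rec = DomainRecord(
                    domain_id=dom,
                    n_residues=int(g.attrs["residues"]),
                    n_noh_atoms=int(g.attrs["noh_atoms"]),
                    helix_fraction=float(g.attrs["helix_fraction"]),
                    sheet_fraction=float(g.attrs["sheet_fraction"]),
                )
            except KeyError as exc:
                raise DatasetFormatError(
                    f"group '{dom}' is missing metadata attribute {exc}"
                ) from None
            if "types" in g:
                rec.bead_types = g["types"][()]
            for temp in sorted(k for k in g if k != "types"):
                tg = g[temp]
                if "forces" not in tg:
                    raise DatasetFormatError(f"group '{dom}/{temp}' is missing 'forces'")
                rec.trajectories[int(temp)] = (tg["coords"][()], tg["forces"][()])
            records.append(rec)
    return records
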