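"""Connectome containers, consistency-based edge masking, and TSV I/O.

A connectome here is a weighted undirected network over atlas regions.
Edge weights are streamline counts from deterministic tractography;
optional per-edge diffusion scalars (tract-average gFA in [0, 1] and
ADC in mm^2/s) are defined exactly on the support of the weights.

Group analyses of streamline-count networks conventionally discard
inconsistent connections: an edge is kept only if it is present
(count > 0) in at least a given fraction of subjects (default one half,
ties retained). :func:`consistency_mask` builds that mask from a cohort
and :func:`apply_mask` applies it per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, default_atlas

__all__ = [
    "Connectome",
    "CohortConnectomes",
    "ConsistencyMask",
    "consistency_mask",
    "apply_mask",
    "apply_mask_cohort",
]


def _check_symmetric(a: np.ndarray, name: str, tol: float = 1e-10) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=tol, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")


@dataclass
class Connectome:
    """Single-subject weighted undirected brain network.

    Parameters
    ----------
    weights : ndarray (n, n)
        Symmetric nonnegative streamline counts, zero diagonal.
    gfa, adc : ndarray (n, n), optional
        Per-edge tract-average scalars, symmetric and defined exactly on
        the support of ``weights`` (zero where ``weights`` is zero).
    subject_id : str
    """

    weights: np.ndarray
    gfa: np.ndarray | None = None
    adc: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        _check_symmetric(w, "weights")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.diagonal(w).any():
            raise ValueError("weights must have a zero diagonal")
        self.weights = w
        support = w > 0
        for name in ("gfa", "adc"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            _check_symmetric(m, name)
            if m.shape != w.shape:
                raise ValueError(f"{name} shape {m.shape} != weights shape {w.shape}")
            if np.any((m != 0) & ~support):
                raise ValueError(f"{name} defined outside the weight support")
            setattr(self, name, m)
        if self.gfa is not None and ((self.gfa < 0).any() or (self.gfa > 1).any()):
            raise ValueError("gfa values must lie in [0, 1]")
        if self.adc is not None and (self.adc[support] <= 0).any():
            raise ValueError("adc must be positive on present edges")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def support(self) -> np.ndarray:
        """Boolean matrix of present edges (count > 0)."""
        return self.weights > 0


@dataclass
class CohortConnectomes:
    """Stack of subject connectomes sharing one atlas and node order."""

    atlas: RegionAtlas
    connectomes: list[Connectome] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.connectomes) == 0:
            raise ValueError("empty cohort")
        n = self.atlas.n_regions
        for c in self.connectomes:
            if c.n_regions != n:
                raise ValueError(
                    f"subject {c.subject_id!r}: matrix dimension {c.n_regions} "
                    f"does not match atlas dimension {n}"
                )
        ids = [c.subject_id for c in self.connectomes]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.connectomes)

    def __iter__(self):
        return iter(self.connectomes)

    def __getitem__(self, i: int) -> Connectome:
        return self.connectomes[i]

    @property
    def subject_ids(self) -> list[str]:
        return [c.subject_id for c in self.connectomes]

    def weight_stack(self) -> np.ndarray:
        """All weight matrices as one (n_subjects, n, n) array."""
        return np.stack([c.weights for c in self.connectomes])

    def subset(self, keep: Sequence[bool] | np.ndarray) -> "CohortConnectomes":
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (len(self),):
            raise ValueError("subset mask length must match cohort size")
        return CohortConnectomes(self.atlas, [c for c, k in zip(self.connectomes, keep) if k])

    # ---- I/O ---------------------------------------------------------

    @classmethod
    def from_directory(
        cls,
        weights_dir: str | Path,
        atlas: RegionAtlas | None = None,
        gfa_dir: str | Path | None = None,
        adc_dir: str | Path | None = None,
        subject_ids: Iterable[str] | None = None,
    ) -> "CohortConnectomes":
        """Read ``<subject_id>.tsv`` square matrices from a directory.

        Optional parallel directories supply gFA and ADC matrices under
        the same file names.
        """
        weights_dir = Path(weights_dir)
        if subject_ids is None:
            files = sorted(weights_dir.glob("*.tsv"))
            subject_ids = [f.stem for f in files]
        atlas = atlas if atlas is not None else default_atlas()
        conns = []
        for sid in subject_ids:
            w = _read_matrix(weights_dir / f"{sid}.tsv")
            gfa = _read_matrix(Path(gfa_dir) / f"{sid}.tsv") if gfa_dir else None
            adc = _read_matrix(Path(adc_dir) / f"{sid}.tsv") if adc_dir else None
            conns.append(Connectome(w, gfa=gfa, adc=adc, subject_id=sid))
        return cls(atlas, conns)

    def to_directory(
        self,
        weights_dir: str | Path,
        gfa_dir: str | Path | None = None,
        adc_dir: str | Path | None = None,
    ) -> None:
        Path(weights_dir).mkdir(parents=True, exist_ok=True)
        for d in (gfa_dir, adc_dir):
            if d is not None:
                Path(d).mkdir(parents=True, exist_ok=True)
        for c in self.connectomes:
            _write_matrix(Path(weights_dir) / f"{c.subject_id}.tsv", c.weights)
            if gfa_dir is not None and c.gfa is not None:
                _write_matrix(Path(gfa_dir) / f"{c.subject_id}.tsv", c.gfa)
            if adc_dir is not None and c.adc is not None:
                _write_matrix(Path(adc_dir) / f"{c.subject_id}.tsv", c.adc)


def _read_matrix(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return df.to_numpy(dtype=float)


def _write_matrix(path: Path, a: np.ndarray) -> None:
    pd.DataFrame(a).to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


@dataclass
class ConsistencyMask:
    """Group-consistency edge mask.

    ``retained[i, j]`` is true iff the edge (i, j) is present (weight > 0)
    in at least ``threshold`` of the cohort's subjects; edges present in
    less than that fraction are discarded (ties at the threshold kept).
    """

    retained: np.ndarray
    threshold: float
    presence_freq: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.retained, dtype=bool)
        f = np.asarray(self.presence_freq, dtype=float)
        _check_symmetric(f, "presence_freq")
        if r.shape != f.shape:
            raise ValueError("retained and presence_freq shapes differ")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must lie in (0, 1]")
        np.fill_diagonal(r, False)
        if not (r == r.T).all():
            raise ValueError("retained must be symmetric")
        self.retained, self.presence_freq = r, f

    @property
    def n_retained_edges(self) -> int:
        return int(self.retained.sum() // 2)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.retained.astype(int)).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = 0.5) -> "ConsistencyMask":
        r = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=bool)
        return cls(r, threshold, presence_freq=r.astype(float))


def consistency_mask(cohort: CohortConnectomes, threshold: float = 0.5) -> ConsistencyMask:
    """Build the group-consistency edge mask for a cohort.

    Edge presence means a strictly positive streamline count. An edge is
    retained iff its presence frequency across subjects is >= ``threshold``
    (the default 0.5 discards edges present in less than half the cohort).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    stack = cohort.weight_stack()
    freq = (stack > 0).mean(axis=0)
    retained = freq >= threshold
    np.fill_diagonal(retained, False)
    return ConsistencyMask(retained=retained, threshold=threshold, presence_freq=freq)


def apply_mask(c: Connectome, mask: ConsistencyMask) -> Connectome:
    """Zero all edges (weights, gfa, adc) outside the retained set."""
    if mask.retained.shape != c.weights.shape:
        raise ValueError(
            f"mask dimension {mask.retained.shape} != connectome {c.weights.shape}"
        )
    keep = mask.retained
    w = np.where(keep, c.weights, 0.0)
    gfa = np.where(keep & (w > 0), c.gfa, 0.0) if c.gfa is not None else None
    adc = np.where(keep & (w > 0), c.adc, 0.0) if c.adc is not None else None
    return Connectome(w, gfa=gfa, adc=adc, subject_id=c.subject_id)


def apply_mask_cohort(cohort: CohortConnectomes, mask: ConsistencyMask) -> CohortConnectomes:
    """Apply one consistency mask to every subject in the cohort."""
    return CohortConnectomes(cohort.atlas, [apply_mask(c, mask) for c in cohort])
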