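"""Species-by-trait tables, Gower mixed-type dissimilarity, and PCoA.

Functional structure statistics in this package run on a Gower
dissimilarity computed from a mixed table of continuous and binary
traits (the study design this emulates codes diet, foraging method and
foraging location as non-exclusive binary attributes next to body mass
and generation length).  Gower's coefficient averages range-scaled
absolute differences (continuous) and mismatch indicators (binary) over
the traits observed in both species of a pair, so missing values are
handled by pairwise deletion.

Principal coordinates analysis of the Gower matrix provides the reduced
trait space in which convex-hull functional richness (FRic) is
measured; a square-root correction is applied when the dissimilarity is
not Euclidean-embeddable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = ["TraitTable", "gower", "pcoa", "PCoAResult"]

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass
class TraitTable:
    """A species x trait table with per-column types.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by species label, one column per trait.  Missing
        values are allowed (NaN).
    types : mapping of str to {"continuous", "binary"}
        Type of every trait column.
    """

    data: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index.name = "species"
        if self.data.shape[1] < 1:
            raise ValueError("trait table needs at least one trait column")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate species: {dupes}")
        missing_types = set(self.data.columns) - set(self.types)
        if missing_types:
            raise ValueError(f"no type declared for traits: {sorted(missing_types)}")
        for col, kind in self.types.items():
            if kind not in (CONTINUOUS, BINARY):
                raise ValueError(f"trait {col!r}: unknown type {kind!r}")
            if kind == BINARY and col in self.data:
                vals = self.data[col].dropna().unique()
                if not np.isin(vals, [0.0, 1.0]).all():
                    raise ValueError(f"binary trait {col!r} has values outside {{0,1}}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.types[c] == CONTINUOUS]

    @property
    def binary_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.types[c] == BINARY]

    def standardized_matrix(self) -> pd.DataFrame:
        """Continuous traits z-scored, binary traits left as 0/1.

        Puts all traits on a comparable scale for Euclidean operations
        (e.g. the environmental-filtering kernel of the simulator).
        """
        out = self.data.copy()
        for col in self.continuous_columns:
            x = out[col]
            sd = x.std(ddof=0)
            out[col] = (x - x.mean()) / sd if sd > 0 else 0.0
        return out

    def subset(self, species: Sequence[str]) -> "TraitTable":
        missing = sorted(set(species) - set(self.data.index))
        if missing:
            raise ValueError(f"unknown species: {missing}")
        return TraitTable(self.data.loc[list(species)], dict(self.types))

    # -- I/O ------------------------------------------------------------

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = self.data.copy()
        for col in self.binary_columns:
            df[col] = df[col].astype("Int64")
        df.to_csv(path, index_label="species")
        if sidecar is not None:
            Path(sidecar).write_text(yaml.safe_dump({"traits": self.types}))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        types: Mapping[str, str] | None = None,
        sidecar: str | Path | None = None,
    ) -> "TraitTable":
        if types is None:
            if sidecar is None:
                raise ValueError("provide trait types directly or via a sidecar file")
            types = yaml.safe_load(Path(sidecar).read_text())["traits"]
        df = pd.read_csv(path, index_col="species")
        return cls(df, dict(types))


def gower(
    table: TraitTable,
    weights: Mapping[str, float] | None = None,
    binary_mode: str = "symmetric",
) -> DistanceMatrix:
    """Gower dissimilarity for a mixed continuous/binary trait table.

    ``d(a, b) = sum_k w_k delta_k s_k / sum_k w_k delta_k`` where for a
    continuous trait ``s_k = |x_a - x_b| / range_k`` (range taken over
    the whole table, so distances are comparable across assemblages
    drawn from the same pool), for a binary trait ``s_k`` is the
    mismatch indicator, and ``delta_k = 1`` only when both species have
    the trait recorded.

    Parameters
    ----------
    weights : mapping, optional
        Nonnegative per-trait weights ``w_k`` (default: equal).  Useful
        for downweighting groups of binary columns that expand a single
        conceptual trait.
    binary_mode : {"symmetric", "asymmetric"}
        ``"symmetric"`` scores 0/0 as agreement (mismatch indicator);
        ``"asymmetric"`` (Jaccard-style) drops joint absences from the
        comparison.

    Raises
    ------
    ValueError
        If a species pair shares no usable trait (the pair is named).
    """
    if binary_mode not in ("symmetric", "asymmetric"):
        raise ValueError("binary_mode must be 'symmetric' or 'asymmetric'")
    species = table.species
    n = len(species)
    if n < 2:
        raise ValueError("Gower dissimilarity requires at least 2 species")
    w = {c: 1.0 for c in table.data.columns}
    if weights is not None:
        unknown = sorted(set(weights) - set(w))
        if unknown:
            raise ValueError(f"weights given for unknown traits: {unknown}")
        w.update({c: float(v) for c, v in weights.items()})
        if any(v < 0 for v in w.values()):
            raise ValueError("trait weights must be nonnegative")

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in table.data.columns:
        x = table.data[col].to_numpy(dtype=float)
        present = ~np.isnan(x)
        both = present[:, None] & present[None, :]
        wk = w[col]
        if wk == 0:
            continue
        if table.types[col] == CONTINUOUS:
            rng = np.nanmax(x) - np.nanmin(x) if present.any() else 0.0
            if rng == 0 or not np.isfinite(rng):
                warnings.warn(
                    f"continuous trait {col!r} is constant; excluded from Gower",
                    stacklevel=2,
                )
                continue
            s = np.abs(x[:, None] - x[None, :]) / rng
            delta = both
        else:
            s = (x[:, None] != x[None, :]).astype(float)
            if binary_mode == "asymmetric":
                joint_absent = (x[:, None] == 0) & (x[None, :] == 0)
                delta = both & ~joint_absent
            else:
                delta = both
        s = np.where(delta, s, 0.0)
        num += wk * s * delta
        den += wk * delta

    bad = (den == 0) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no usable trait"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(np.clip(d, 0.0, 1.0), ids=species)


@dataclass
class PCoAResult:
    """Principal coordinates of a dissimilarity matrix.

    ``coordinates`` holds one row per object on the retained axes
    (positive eigenvalues only, sorted nonincreasing); ``corrected``
    records whether the square-root correction was applied.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    corrected: bool


def pcoa(
    dm: DistanceMatrix,
    correction: str = "sqrt",
    n_axes: int | None = None,
    neg_tol: float = 1e-8,
) -> PCoAResult:
    """Principal coordinates analysis with optional sqrt correction.

    The double-centred eigendecomposition is delegated to scikit-bio.
    When negative eigenvalues exceed ``neg_tol`` relative to the largest
    eigenvalue and ``correction="sqrt"``, off-diagonal dissimilarities
    are replaced by their square roots (which renders Gower
    dissimilarities Euclidean-embeddable) and the decomposition redone.
    """
    if correction not in ("sqrt", "none"):
        raise ValueError("correction must be 'sqrt' or 'none'")

    def decompose(mat: DistanceMatrix):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _skbio_pcoa(mat, method="eigh")
        return res

    def min_max_gram_eig(mat: DistanceMatrix) -> tuple[float, float]:
        # smallest/largest eigenvalue of the double-centred Gram matrix
        # (skbio clamps negatives, so detect non-Euclidean input here)
        d2 = mat.data**2
        n = d2.shape[0]
        j = np.eye(n) - np.full((n, n), 1.0 / n)
        w = np.linalg.eigvalsh(-0.5 * j @ d2 @ j)
        return float(w[0]), float(w[-1])

    corrected = False
    if correction == "sqrt":
        lo, hi = min_max_gram_eig(dm)
        if lo < -neg_tol * max(hi, 1e-300):
            dm = DistanceMatrix(np.sqrt(dm.data), ids=dm.ids)
            corrected = True
    res = decompose(dm)
    eig = res.eigvals.to_numpy()

    pos = eig > neg_tol * max(abs(eig).max(), 1e-300)
    coords = res.samples.to_numpy()[:, pos]
    eig = eig[pos]
    rank = coords.shape[1]
    if n_axes is not None:
        if n_axes > rank:
            warnings.warn(
                f"requested {n_axes} axes but rank is {rank}; clipping", stacklevel=2
            )
        coords = coords[:, : min(n_axes, rank)]
        eig = eig[: min(n_axes, rank)]
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PCoAResult(coordinates=frame, eigenvalues=eig, corrected=corrected)
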