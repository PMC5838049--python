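"""Per-assemblage taxonomic, functional and phylogenetic diversity.

Implements the index panel of an elevational community survey: species
richness and Pielou's evenness, Bray-Curtis dissimilarity with the
square-root + Wisconsin double standardization recommended before
nonmetric multidimensional scaling (NMDS), Faith's phylogenetic
diversity, convex-hull functional richness (FRic) in a reduced Gower
trait space, and the abundance-weighted observed mean pairwise
functional (PW) and phylogenetic (MPD) distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .phylo import Phylogeny
from .simulate import SurveyDetections
from .traits import PCoAResult, TraitTable, gower, pcoa

__all__ = [
    "CommunityMatrix",
    "survey_aggregate",
    "richness_evenness",
    "ordination_transform",
    "bray_curtis",
    "nmds",
    "NMDSResult",
    "faith_pd",
    "fric",
    "fric_axes",
    "summarize",
]

METADATA_COLUMNS = ["plot", "season", "elevation"]


@dataclass
class CommunityMatrix:
    """Assemblage x species abundances with season/elevation metadata.

    ``abundance`` is a nonnegative integer DataFrame (rows =
    assemblages, columns = species); ``metadata`` (optional) carries
    ``plot``, ``season`` and ``elevation`` per assemblage.  An
    assemblage's species set is defined by abundance > 0.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ab = self.abundance
        if (ab.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.metadata is not None and not self.metadata.index.equals(ab.index):
            raise ValueError("metadata index must match abundance index")

    @property
    def assemblages(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def relative_abundance(self) -> pd.DataFrame:
        totals = self.abundance.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"assemblages with no individuals: {empty}")
        return self.abundance.div(totals, axis=0)

    def species_present(self, assemblage: str) -> list[str]:
        row = self.abundance.loc[assemblage]
        return list(row.index[row > 0])

    def drop_absent_species(self) -> "CommunityMatrix":
        """Remove species with zero abundance in every assemblage."""
        present = self.abundance.columns[self.abundance.sum(axis=0) > 0]
        return CommunityMatrix(self.abundance[list(present)], self.metadata)

    # -- I/O ------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = self.abundance.copy()
        if self.metadata is not None:
            df = pd.concat([self.metadata, df], axis=1)
        df.to_csv(path, index_label="assemblage")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col="assemblage")
        meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
        metadata = df[meta_cols] if meta_cols else None
        abundance = df.drop(columns=meta_cols)
        return cls(abundance, metadata)


def survey_aggregate(detections: SurveyDetections) -> pd.Series:
    """Abundance estimate from repeat surveys.

    Per transect, take the elementwise maximum count over repeats (the
    best single-visit estimate for that transect); sum the transect
    maxima to get the assemblage abundance vector.
    """
    if detections.n_repeats < 1:
        raise ValueError("need at least one survey repeat")
    per_transect = detections.counts.max(axis=1)  # (transect, species)
    total = per_transect.sum(axis=0)
    return pd.Series(total, index=detections.species, name="abundance")


def richness_evenness(abundance: pd.Series | np.ndarray) -> tuple[int, float]:
    """Species richness and Pielou's evenness of one assemblage.

    ``SE = H / ln(SR)`` with ``H`` the Shannon entropy of relative
    abundances.  For a single-species assemblage evenness is undefined
    and returned as NaN.
    """
    x = np.asarray(abundance, dtype=float)
    x = x[x > 0]
    sr = int(x.size)
    if sr == 0:
        raise ValueError("assemblage has no species present")
    if sr == 1:
        return 1, float("nan")
    f = x / x.sum()
    h = float(-(f * np.log(f)).sum())
    return sr, h / np.log(sr)


def ordination_transform(cm: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Square-root then Wisconsin double standardization.

    The relative abundances are square-root transformed, each species
    column is divided by its maximum, then each assemblage row by its
    row total -- the transformation recommended before NMDS on
    Bray-Curtis distances.  All-zero species columns are left at zero.
    """
    rel = cm.relative_abundance if isinstance(cm, CommunityMatrix) else cm
    m = np.sqrt(np.asarray(rel, dtype=float))
    if (m.sum(axis=1) == 0).any():
        raise ValueError("all-zero assemblage row")
    colmax = m.max(axis=0)
    scaled = np.divide(m, colmax, out=np.zeros_like(m), where=colmax > 0)
    out = scaled / scaled.sum(axis=1, keepdims=True)
    index = rel.index if hasattr(rel, "index") else None
    columns = rel.columns if hasattr(rel, "columns") else None
    return pd.DataFrame(out, index=index, columns=columns)


def bray_curtis(m: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between assemblage rows."""
    x = np.asarray(m, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative input")
    if (x.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero rows")
    d = squareform(pdist(x, metric="braycurtis"))
    ids = list(m.index) if hasattr(m, "index") else None
    return DistanceMatrix(d, ids=ids)


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float


def nmds(
    dm: DistanceMatrix,
    k_dims: int = 2,
    n_starts: int = 16,
    seed: int = 0,
    max_iter: int = 1000,
) -> NMDSResult:
    """Nonmetric multidimensional scaling (Kruskal stress-1).

    Runs scikit-learn's nonmetric SMACOF (isotonic regression of
    configuration distances on dissimilarity ranks) from ``n_starts``
    random initializations and keeps the best; ``stress`` is Kruskal's
    stress-1 in [0, 1].  Deterministic given ``seed``.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("NMDS needs at least 3 assemblages")
    if k_dims >= n - 1:
        warnings.warn(
            f"k_dims={k_dims} with n={n}: zero stress is trivially attainable",
            stacklevel=2,
        )
    model = MDS(
        n_components=k_dims,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        eps=1e-12,
        random_state=int(seed),
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(dm.data)
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k_dims)]
    )
    return NMDSResult(coordinates=frame, stress=float(model.stress_))


def faith_pd(
    tree: Phylogeny, community: Iterable[str], include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of a species set.

    The total branch length of the minimal subtree spanning the
    community; with ``include_root`` (the default) the path from the
    community's MRCA up to the root is counted as well.
    """
    members = set(community)
    if not members:
        raise ValueError("community is empty")
    missing = sorted(members - set(tree.tip_labels))
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    lengths = tree._require_lengths()
    depth = tree.depths
    marked = np.zeros(tree.n_nodes, dtype=bool)
    n_below = np.zeros(tree.n_nodes, dtype=int)
    total = 0.0
    mrca_depth = 0.0
    k = len(members)
    for node in range(tree.n_nodes):
        ch = tree.children[node]
        if not ch:
            if tree.labels[node] in members:
                marked[node] = True
                n_below[node] = 1
        else:
            n_below[node] = sum(n_below[c] for c in ch)
            marked[node] = n_below[node] > 0
        if marked[node] and node != tree.root:
            total += lengths[node]
        if n_below[node] == k:
            mrca_depth = max(mrca_depth, depth[node])
    if not include_root:
        total -= mrca_depth
    return float(total)


def fric_axes(gower_dm: DistanceMatrix, min_community_size: int, cap: int = 6) -> int:
    """Default number of PCoA axes for FRic: ``min(s_min - 1, cap)``."""
    return max(1, min(min_community_size - 1, cap))


def fric(coords: pd.DataFrame, community: Iterable[str]) -> float:
    """Functional richness: convex-hull volume in the reduced trait space.

    ``coords`` holds species coordinates on the retained ordination
    axes.  A community with too few species for a full-dimensional hull
    is measured in the first ``size - 1`` axes (with a warning); fully
    degenerate (e.g. coplanar) point sets return volume 0.
    """
    members = list(dict.fromkeys(community))
    missing = sorted(set(members) - set(coords.index))
    if missing:
        raise ValueError(f"species without coordinates: {missing}")
    pts = coords.loc[members].to_numpy(dtype=float)
    m = pts.shape[1]
    if len(members) <= m:
        m = len(members) - 1
        if m < 1:
            warnings.warn("community of one species: FRic is 0", stacklevel=2)
            return 0.0
        warnings.warn(
            f"community of {len(members)} species: FRic measured in {m} axes",
            stacklevel=2,
        )
        pts = pts[:, :m]
    if m == 1:
        return float(pts[:, 0].max() - pts[:, 0].min())
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate point set: FRic is 0", stacklevel=2)
        return 0.0


def summarize(
    cm: CommunityMatrix,
    tree: Phylogeny,
    traits: TraitTable,
    gower_dm: DistanceMatrix | None = None,
    coords: pd.DataFrame | None = None,
    include_root: bool = True,
    abundance_weighted: bool = True,
    pcoa_axes: int | None = None,
) -> pd.DataFrame:
    """Per-assemblage diversity panel: SR, SE, FRic, PD, PW, MPD.

    PW and MPD are the observed abundance-weighted mean pairwise Gower
    and patristic distances (the quantities whose standardized effect
    sizes are S.E.S. PW and NRI).  When not supplied, the Gower matrix
    and the PCoA coordinates for FRic are computed here; the number of
    retained axes defaults to ``min(smallest richness - 1, 6)`` after
    square-root correction of the Gower matrix.
    """
    from .structure import weighted_mpd  # local import, avoids cycle

    if gower_dm is None:
        gower_dm = gower(traits)
    if coords is None:
        sizes = [len(cm.species_present(a)) for a in cm.assemblages]
        n_axes = pcoa_axes or fric_axes(gower_dm, min(sizes))
        coords = pcoa(gower_dm, correction="sqrt", n_axes=n_axes).coordinates
    patristic = tree.patristic_distances()
    rel = cm.relative_abundance
    rows = []
    for a in cm.assemblages:
        present = cm.species_present(a)
        sr, se = richness_evenness(cm.abundance.loc[a])
        f = rel.loc[a]
        row = {
            "assemblage": a,
            "SR": sr,
            "SE": se,
            "FRic": fric(coords, present),
            "PD": faith_pd(tree, present, include_root=include_root),
            "PW": weighted_mpd(gower_dm, f, abundance_weighted=abundance_weighted),
            "MPD": weighted_mpd(patristic, f, abundance_weighted=abundance_weighted),
        }
        if cm.metadata is not None:
            for col in cm.metadata.columns:
                row[col] = cm.metadata.loc[a, col]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("assemblage")
    lead = [c for c in METADATA_COLUMNS if c in out.columns]
    return out[lead + ["SR", "SE", "FRic", "PD", "PW", "MPD"]]
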