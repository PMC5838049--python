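"""Abundance-weighted mean pairwise distance and its null-model effect sizes.

The functional and phylogenetic structure of an assemblage is scored by
the standardized effect size of its abundance-weighted mean pairwise
distance under the "taxa labels" randomization: species names are
shuffled across the tips/rows of the (functional or phylogenetic)
distance matrix of the full species pool, holding community composition
and abundances fixed.  With the conventional sign flip,

    ses = -1 * (observed - mean(null)) / sd(null)

a positive value indicates clustering (species more similar than
expected) and a negative value overdispersion.  Applied to patristic
distances this is the net relatedness index (NRI); applied to Gower
functional distances it is S.E.S. PW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .phylo import Phylogeny

__all__ = [
    "SESResult",
    "weighted_mpd",
    "taxa_labels_null",
    "ses",
    "nri",
    "ses_pw",
]

#: null standard deviations at or below this (relative) level are
#: treated as degenerate: the effect size is undefined, not +-inf
_DEGENERATE_SD = 1e-10


@dataclass
class SESResult:
    """Observed statistic, null summary, and standardized effect size."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    n_null: int
    p_quantile: float
    flavor: str = "functional"
    status: str = "ok"

    def significant(self, alpha: float = 0.05, two_sided: bool = True) -> bool:
        """Rank-based rejection at level ``alpha`` (two-sided by default)."""
        if self.status != "ok":
            return False
        if two_sided:
            return self.p_quantile < alpha / 2 or self.p_quantile > 1 - alpha / 2
        return self.p_quantile < alpha


def _present_vector(
    dm: DistanceMatrix, abundance: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (in dm order) and relative abundances of present species."""
    ids = list(dm.ids)
    pos = {s: i for i, s in enumerate(ids)}
    missing = sorted(set(abundance.index) - set(ids))
    if missing:
        raise ValueError(f"species not in distance matrix: {missing}")
    present = abundance[abundance > 0]
    if len(present) < 2:
        raise ValueError("mean pairwise distance needs >= 2 species present")
    idx = np.array([pos[s] for s in present.index])
    f = present.to_numpy(dtype=float)
    f = f / f.sum()
    return idx, f


def _mpd_from_submatrix(
    d_sub: np.ndarray,
    f: np.ndarray,
    abundance_weighted: bool,
    include_conspecific: bool = False,
) -> float | np.ndarray:
    """Weighted MPD for one (s, s) submatrix or a stack (m, s, s)."""
    s = f.size
    if abundance_weighted:
        w = np.outer(f, f)
    else:
        w = np.full((s, s), 1.0 / (s * s))
    if not include_conspecific:
        np.fill_diagonal(w, 0.0)
    w = w / w.sum()
    return np.einsum("...ij,ij->...", d_sub, w)


def weighted_mpd(
    dm: DistanceMatrix,
    abundance: pd.Series,
    abundance_weighted: bool = True,
    include_conspecific: bool = False,
) -> float:
    """Mean pairwise distance among the individuals of an assemblage.

    With abundance weighting, pairs are weighted by the product of
    relative abundances ``f_i f_j`` over heterospecific pairs only
    (``i != j``; conspecific zero-distance pairs are excluded):

        MPD = sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j

    ``include_conspecific=True`` switches to the Rao quadratic-entropy
    weighting, which keeps the ``i = j`` pairs at distance zero in the
    average.  The unweighted variant is the plain mean over
    off-diagonal entries of the present species.
    """
    idx, f = _present_vector(dm, abundance)
    d_sub = dm.data[np.ix_(idx, idx)]
    return float(
        _mpd_from_submatrix(d_sub, f, abundance_weighted, include_conspecific)
    )


def taxa_labels_null(dm: DistanceMatrix, seed: int = 0) -> DistanceMatrix:
    """One draw of the "taxa labels" null: shuffle names across the matrix.

    The rows/columns of ``dm`` are relabelled by a uniform random
    permutation of the full species pool, leaving the multiset of
    distances (and any community data) untouched.
    """
    rng = np.random.default_rng(int(seed))
    ids = np.array(dm.ids)
    return DistanceMatrix(dm.data, ids=list(rng.permutation(ids)))


def ses(
    dm: DistanceMatrix,
    abundance: pd.Series,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    flavor: str = "functional",
) -> SESResult:
    """Standardized effect size of weighted MPD under the taxa-labels null.

    The null distribution holds community composition and abundances
    fixed and permutes species labels over the full distance-matrix
    pool ``n_null`` times.  The effect size uses the sample (n-1)
    standard deviation of the null values and the conventional sign
    flip (positive = clustering).  ``p_quantile`` is the mid-ranked
    proportion of null values at or below the observed value,

        p = (#{null < obs} + 0.5 #{null = obs} + 1) / (n_null + 1),

    so small values indicate clustering and large values
    overdispersion.  Deterministic given ``seed``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    idx, f = _present_vector(dm, abundance)
    d = dm.data
    observed = float(_mpd_from_submatrix(d[np.ix_(idx, idx)], f, abundance_weighted))

    rng = np.random.default_rng(int(seed))
    n_pool = d.shape[0]
    perms = rng.permuted(
        np.broadcast_to(np.arange(n_pool), (n_null, n_pool)).copy(), axis=1
    )
    null_idx = perms[:, idx]  # (n_null, s)
    d_null = d[null_idx[:, :, None], null_idx[:, None, :]]
    null_vals = np.asarray(_mpd_from_submatrix(d_null, f, abundance_weighted))

    null_mean = float(null_vals.mean())
    null_sd = float(null_vals.std(ddof=1)) if n_null > 1 else 0.0
    below = int((null_vals < observed).sum())
    ties = int((null_vals == observed).sum())
    p_quantile = (below + 0.5 * ties + 1.0) / (n_null + 1.0)

    scale = max(1.0, abs(null_mean))
    if null_sd <= _DEGENERATE_SD * scale:
        return SESResult(
            observed=observed,
            null_mean=null_mean,
            null_sd=null_sd,
            ses=float("nan"),
            n_null=n_null,
            p_quantile=p_quantile,
            flavor=flavor,
            status="degenerate null (sd = 0)",
        )
    return SESResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=-1.0 * (observed - null_mean) / null_sd,
        n_null=n_null,
        p_quantile=p_quantile,
        flavor=flavor,
    )


def nri(
    tree: Phylogeny,
    abundance: pd.Series,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> SESResult:
    """Net relatedness index: sign-flipped SES of MPD on the phylogeny."""
    return ses(
        tree.patristic_distances(),
        abundance,
        n_null=n_null,
        seed=seed,
        abundance_weighted=abundance_weighted,
        flavor="phylogenetic",
    )


def ses_pw(
    gower_dm: DistanceMatrix,
    abundance: pd.Series,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> SESResult:
    """S.E.S. PW: sign-flipped SES of the mean pairwise functional distance."""
    return ses(
        gower_dm,
        abundance,
        n_null=n_null,
        seed=seed,
        abundance_weighted=abundance_weighted,
        flavor="functional",
    )
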