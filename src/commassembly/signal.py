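"""Phylogenetic conservatism tests for continuous and binary traits.

Blomberg's K compares the observed partitioning of trait variance on
the tree with its Brownian-motion expectation via generalized least
squares: K ~ 1 under Brownian evolution, K < 1 for weaker-than-Brownian
signal, K > 1 for stronger.  Significance comes from permuting trait
values across tips.

The Fritz-Purvis D statistic scores a binary trait by its sum of
sister-clade differences, scaled between the mean of that sum under a
phylogenetically random null (tip permutations; D ~ 1) and under a
threshold-Brownian null matched to the observed prevalence (D ~ 0);
negative D marks traits more conserved than Brownian expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .phylo import Phylogeny, TreeError
from .traits import TraitTable

__all__ = [
    "KResult",
    "DResult",
    "blomberg_k",
    "fritz_purvis_d",
    "signal_table",
]


@dataclass
class KResult:
    K: float
    mse0: float
    mse: float
    expected_ratio: float
    p_perm: float
    n_perm: int


@dataclass
class DResult:
    D: float
    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    p_random: float
    p_brownian: float
    n_sim: int


def _align_trait(tree: Phylogeny, x) -> np.ndarray:
    """Trait values in tip order; errors on missing or extra species."""
    labels = tree.tip_labels
    if isinstance(x, pd.Series):
        missing = sorted(set(labels) - set(x.index))
        if missing:
            raise ValueError(f"trait undefined for tips: {missing}")
        x = x.loc[labels]
    arr = np.asarray(x, dtype=float)
    if arr.shape != (len(labels),):
        raise ValueError(f"trait must have one value per tip ({len(labels)})")
    if np.isnan(arr).any():
        raise ValueError("trait contains missing values")
    return arr


def _k_statistics(
    X: np.ndarray, cho, Vi_rowsum: np.ndarray, trV: float, n: int
):
    """Vectorized K for trait columns of X given a Cholesky factor of V."""
    A = cho_solve(cho, X)  # V^-1 X, (n, m)
    sum_vi = Vi_rowsum.sum()
    ahat = Vi_rowsum @ X / sum_vi  # (m,)
    R = X - ahat  # residuals, (n, m)
    mse0 = (R * R).sum(axis=0) / (n - 1)
    # V^-1 (x - a 1) = V^-1 x - a * (V^-1 1)
    VinvR = A - Vi_rowsum[:, None] * ahat[None, :]
    mse = (R * VinvR).sum(axis=0) / (n - 1)
    expected = (trV - n / sum_vi) / (n - 1)
    return (mse0 / mse) / expected, mse0, mse, expected


def blomberg_k(
    tree: Phylogeny,
    x: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Blomberg's K for a continuous trait with a permutation test.

    The GLS ancestral estimate is ``a = (1'V^-1 x)/(1'V^-1 1)`` with
    ``V`` the Brownian variance-covariance matrix of the tree; K is the
    observed ``MSE0/MSE`` ratio scaled by its Brownian expectation
    ``(tr V - n / sum(V^-1)) / (n - 1)``.  The permutation p-value is
    one-sided (greater): the proportion of tip relabelings with a K at
    least as large, with the add-one correction.  ``n_perm = 0`` skips
    the test (``p_perm`` is NaN).
    """
    xv = _align_trait(tree, x)
    n = xv.size
    if n < 3:
        raise TreeError("Blomberg's K needs at least 3 tips")
    if np.ptp(xv) == 0:
        raise ValueError("trait is constant; K is undefined")
    V = tree.vcv()
    try:
        cho = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise TreeError(
            "singular variance-covariance matrix (zero-length tip branches?); "
            "consider jittering branch lengths"
        ) from exc
    Vi_rowsum = cho_solve(cho, np.ones(n))
    trV = float(np.trace(V))

    K, mse0, mse, expected = _k_statistics(xv[:, None], cho, Vi_rowsum, trV, n)
    k_obs = float(K[0])

    p_perm = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(int(seed))
        Xp = rng.permuted(
            np.broadcast_to(xv[:, None], (n, n_perm)).copy(), axis=0
        )
        Kp, _, _, _ = _k_statistics(Xp, cho, Vi_rowsum, trV, n)
        p_perm = (int((Kp >= k_obs).sum()) + 1.0) / (n_perm + 1.0)

    return KResult(
        K=k_obs,
        mse0=float(mse0[0]),
        mse=float(mse[0]),
        expected_ratio=float(expected),
        p_perm=p_perm,
        n_perm=n_perm,
    )


# ----------------------------------------------------------------------
# Fritz-Purvis D
# ----------------------------------------------------------------------


def _sister_diff_sums(tree: Phylogeny, tip_values: np.ndarray) -> np.ndarray:
    """Sum of sister-clade differences per trait column.

    Tips-to-root pass: each internal node takes the unweighted mean of
    its daughters' values and contributes the summed absolute deviation
    of the daughters from that mean (for a bifurcation this is simply
    the absolute difference between the two daughter values; polytomies
    contribute one term per daughter).
    """
    n_nodes = tree.n_nodes
    m = tip_values.shape[1]
    vals = np.zeros((n_nodes, m))
    vals[tree.tip_nodes] = tip_values
    total = np.zeros(m)
    for node in range(n_nodes):
        ch = tree.children[node]
        if not ch:
            continue
        cv = vals[list(ch)]
        mean = cv.mean(axis=0)
        vals[node] = mean
        total += np.abs(cv - mean).sum(axis=0)
    return total


def _brownian_tips(tree: Phylogeny, m: int, rng: np.random.Generator) -> np.ndarray:
    """(n_tips, m) Brownian tip values via root-to-tip accumulation."""
    lengths = tree._require_lengths()
    bm = np.zeros((tree.n_nodes, m))
    incr = rng.standard_normal((tree.n_nodes, m)) * np.sqrt(lengths)[:, None]
    for node in range(tree.n_nodes - 1, -1, -1):
        for c in tree.children[node]:
            bm[c] = bm[node] + incr[c]
    return bm[tree.tip_nodes]


def _threshold_columns(liab: np.ndarray, n_ones: int) -> np.ndarray:
    """Binarize each column at the quantile giving exactly n_ones ones."""
    out = np.zeros_like(liab)
    top = np.argpartition(-liab, n_ones - 1, axis=0)[:n_ones]
    np.put_along_axis(out, top, 1.0, axis=0)
    return out


def fritz_purvis_d(
    tree: Phylogeny,
    x: pd.Series | np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
) -> DResult:
    """Fritz-Purvis D for a binary trait.

    ``D = (d_obs - mean(d_Brownian)) / (mean(d_random) - mean(d_Brownian))``
    where ``d`` is the sum of sister-clade differences, the random null
    permutes trait values across tips, and the Brownian null thresholds
    simulated liabilities at the observed prevalence (``n_sim`` draws
    each).  ``p_random`` is the proportion of random draws with
    ``d <= d_obs`` (departure from phylogenetic randomness) and
    ``p_brownian`` the proportion of Brownian draws with ``d >= d_obs``
    (departure from Brownian conservatism), both add-one corrected.
    """
    xv = _align_trait(tree, x)
    if not np.isin(xv, [0.0, 1.0]).all():
        raise ValueError("trait must be binary (0/1)")
    n = xv.size
    n_ones = int(xv.sum())
    if n_ones == 0 or n_ones == n:
        raise ValueError("monomorphic binary trait; D is undefined")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")

    d_obs = float(_sister_diff_sums(tree, xv[:, None])[0])

    rng = np.random.default_rng(int(seed))
    perms = rng.permuted(np.broadcast_to(xv[:, None], (n, n_sim)).copy(), axis=0)
    d_random = _sister_diff_sums(tree, perms)

    liab = _brownian_tips(tree, n_sim, rng)
    d_brownian = _sister_diff_sums(tree, _threshold_columns(liab, n_ones))

    mean_r = float(d_random.mean())
    mean_b = float(d_brownian.mean())
    denom = mean_r - mean_b
    if abs(denom) <= 1e-12 * max(mean_r, 1.0):
        raise ValueError(
            "random and Brownian null means coincide (tree too small?); "
            "D is undefined"
        )
    return DResult(
        D=(d_obs - mean_b) / denom,
        d_obs=d_obs,
        d_random_mean=mean_r,
        d_brownian_mean=mean_b,
        p_random=(int((d_random <= d_obs).sum()) + 1.0) / (n_sim + 1.0),
        p_brownian=(int((d_brownian >= d_obs).sum()) + 1.0) / (n_sim + 1.0),
        n_sim=n_sim,
    )


def signal_table(
    tree: Phylogeny,
    traits: TraitTable,
    n_perm: int = 999,
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trait conservatism tests: K for continuous, D for binary.

    A failing trait (constant, monomorphic, ...) gets its error message
    in the ``error`` column; the remaining traits are still computed.
    Deterministic given ``seed`` (one derived seed per trait).
    """
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(traits.data.columns))
    rows = []
    for col, child in zip(traits.data.columns, children):
        sub_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
        kind = traits.types[col]
        row: dict = {"trait": col, "type": kind}
        try:
            series = traits.data[col]
            if kind == "continuous":
                res = blomberg_k(tree, series, n_perm=n_perm, seed=sub_seed)
                row.update({"statistic": "K", "value": res.K, "p": res.p_perm})
            else:
                res = fritz_purvis_d(tree, series, n_sim=n_sim, seed=sub_seed)
                row.update(
                    {
                        "statistic": "D",
                        "value": res.D,
                        "d_obs": res.d_obs,
                        "p_random": res.p_random,
                        "p_brownian": res.p_brownian,
                    }
                )
        except (ValueError, TreeError) as exc:
            row.update({"statistic": "K" if kind == "continuous" else "D",
                        "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
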