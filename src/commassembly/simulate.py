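"""Synthetic phylogenies, traits, communities and repeat-survey counts.

The generator emulates the statistical structure of a transect-based
bird community study along an elevational gradient: an ultrametric
species-pool phylogeny (~125 tips), a mixed trait table (2 continuous +
15 binary traits) evolved with strong phylogenetic signal, six
assemblages (three elevation plots x two seasons, richness 35-57)
assembled under filtering / limiting-similarity / neutral regimes, and
a repeat-survey detection process (3 transects x 8 repeats per plot)
whose per-transect maximum-over-repeats is the abundance estimator.

Every simulator is a pure function of its seed: a single named random
stream (`numpy.random.Generator`) is created per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny, TreeError
from .traits import TraitTable, gower

__all__ = [
    "AssemblyRegime",
    "SimConfig",
    "SurveyDetections",
    "SimulatedStudy",
    "simulate_tree",
    "simulate_continuous_traits",
    "simulate_binary_traits",
    "assemble_community",
    "simulate_survey",
    "simulate_dataset",
    "DEFAULT_BINARY_NAMES",
    "DEFAULT_CONTINUOUS_NAMES",
]

REGIME_KINDS = ("filtering", "limiting_similarity", "neutral")

#: trait names mirroring a typical passerine functional-trait coding:
#: two continuous life-history traits plus 15 non-exclusive binary
#: attributes (migratory status, 5 diet, 4 foraging method, 5 foraging
#: location columns).
DEFAULT_CONTINUOUS_NAMES = ["body_mass", "generation_length"]
DEFAULT_BINARY_NAMES = [
    "migratory",
    "diet_invertebrate",
    "diet_fruit",
    "diet_seed",
    "diet_nectar",
    "diet_vertebrate",
    "glean",
    "probe",
    "sally",
    "leap",
    "forage_ground",
    "forage_understory",
    "forage_shrub",
    "forage_canopy",
    "forage_air",
]


@dataclass
class AssemblyRegime:
    """How an assemblage is drawn from the regional species pool.

    kind
        ``"filtering"`` favours species near a trait-space optimum
        (probability proportional to ``exp(-strength * ||x - opt||^2)``
        on standardized traits), ``"limiting_similarity"`` favours
        species far (in Gower distance) from those already selected,
        ``"neutral"`` draws uniformly without replacement.
    strength
        Nonnegative; 0 reduces every kind to neutral.
    trait_optimum
        Filtering only; a point in standardized trait space.  When
        omitted, the position of a randomly chosen pool species is used.
    """

    kind: str
    strength: float = 0.0
    trait_optimum: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in REGIME_KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("regime strength must be nonnegative")


@dataclass
class SurveyDetections:
    """Raw repeat-survey counts, indexed (transect, repeat, species)."""

    counts: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (transect, repeat, species)")
        if self.counts.shape[2] != len(self.species):
            raise ValueError("species axis does not match species labels")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def n_transects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.counts.shape[1]


def _default_regimes() -> dict[str, AssemblyRegime]:
    # high elevation: environmental filtering; mid: neutral; low: weak
    # limiting similarity -- the qualitative pattern the emulated study
    # design is built to detect.
    return {
        "high": AssemblyRegime("filtering", strength=20.0),
        "mid": AssemblyRegime("neutral"),
        "low": AssemblyRegime("limiting_similarity", strength=4.0),
    }


def _default_richness() -> dict[tuple[str, str], int]:
    return {
        ("high", "wintering"): 46,
        ("mid", "wintering"): 44,
        ("low", "wintering"): 35,
        ("high", "breeding"): 57,
        ("mid", "breeding"): 43,
        ("low", "breeding"): 43,
    }


@dataclass
class SimConfig:
    """Study-scale simulation settings.

    Defaults mirror the emulated survey design: a 125-species pool, two
    continuous plus fifteen binary traits evolved with full phylogenetic
    signal (``lambda_signal = 1``), three elevation plots (filtering /
    neutral / limiting-similarity) sampled in two seasons at the
    observed richness values, lognormal(0, 1) abundances, and 3
    transects x 8 repeats with detection probability 0.8.
    """

    n_species: int = 125
    birth_rate: float = 1.0
    n_continuous_traits: int = 2
    n_binary_traits: int = 15
    lambda_signal: float = 1.0
    binary_prevalence: float = 0.5
    regimes: dict[str, AssemblyRegime] = field(default_factory=_default_regimes)
    richness: dict[tuple[str, str], int] = field(default_factory=_default_richness)
    elevations: dict[str, float] = field(
        default_factory=lambda: {"high": 2470.0, "mid": 1602.0, "low": 1270.0}
    )
    abundance_shape: float = 1.0
    n_transects: int = 3
    n_repeats: int = 8
    detect_p: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0.0 <= self.lambda_signal <= 1.0:
            raise ValueError("lambda_signal must lie in [0, 1]")
        for key, r in self.richness.items():
            if not 1 <= r <= self.n_species:
                raise ValueError(f"richness {key}: must be in [1, n_species]")


# ----------------------------------------------------------------------
# phylogeny
# ----------------------------------------------------------------------


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` extant tips.

    Lineages split at per-lineage rate ``birth_rate``; after the last
    split an additional exponential waiting time elapses before the
    present, so every pending branch (in particular the youngest
    cherry) has strictly positive length and the Brownian
    variance-covariance matrix is nonsingular.  Tips are labelled
    ``sp001 ...`` in tree order.  Deterministic given ``seed``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(int(seed))

    # active lineages as (parent_slot); record birth time of each node.
    # node records: (birth_time, children_record_ids); root born at 0.
    birth_time = [0.0]
    children_of: list[list[int]] = [[]]
    active = [0]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active[k]
        left, right = len(birth_time), len(birth_time) + 1
        birth_time.extend([t, t])
        children_of[parent] = [left, right]
        children_of.extend([[], []])
        active[k] = left
        active.append(right)
    t += rng.exponential(1.0 / (birth_rate * n_species))

    # convert to postorder arrays with edge length = child time span
    width = max(3, len(str(n_species)))
    children: list[list[int]] = []
    lengths: list[float] = []
    labels: list[str | None] = []
    counter = [0]

    def build(rec: int, is_root: bool) -> int:
        kids = [build(c, False) for c in children_of[rec]]
        end = t if not children_of[rec] else birth_time[children_of[rec][0]]
        children.append(kids)
        lengths.append(float("nan") if is_root else end - birth_time[rec])
        if kids:
            labels.append(None)
        else:
            counter[0] += 1
            labels.append(f"sp{counter[0]:0{width}d}")
        return len(children) - 1

    build(0, True)
    return Phylogeny(children, lengths, labels)


# ----------------------------------------------------------------------
# trait evolution
# ----------------------------------------------------------------------


def _lambda_trait_matrix(
    tree: Phylogeny, k: int, lambda_signal: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``k`` traits with covariance ``lam*V_offdiag + diag(V)``.

    Simulated as ``sqrt(lam) * BM + sqrt(1-lam) * independent`` where the
    Brownian component accumulates N(0, branch length) increments from
    root to tip and the independent component has the matching tip
    variance; the two mix to a Pagel-lambda covariance exactly.
    """
    if not 0.0 <= lambda_signal <= 1.0:
        raise ValueError("lambda_signal must lie in [0, 1]")
    lengths = tree._require_lengths()
    n_nodes = tree.n_nodes
    bm = np.zeros((n_nodes, k))
    incr = rng.standard_normal((n_nodes, k)) * np.sqrt(lengths)[:, None]
    for node in range(n_nodes - 1, -1, -1):  # preorder
        for c in tree.children[node]:
            bm[c] = bm[node] + incr[c]
    tips = tree.tip_nodes
    tip_var = tree.depths[tips]
    indep = rng.standard_normal((len(tips), k)) * np.sqrt(tip_var)[:, None]
    lam = lambda_signal
    return np.sqrt(lam) * bm[tips] + np.sqrt(1.0 - lam) * indep


def simulate_continuous_traits(
    tree: Phylogeny,
    k: int,
    lambda_signal: float = 1.0,
    seed: int = 0,
    names: list[str] | None = None,
) -> TraitTable:
    """Continuous traits from a Pagel-lambda Brownian model.

    ``lambda_signal = 1`` gives pure Brownian motion on the tree (each
    trait multivariate normal with the tree's variance-covariance
    matrix); ``0`` gives independent tips with the same marginal
    variances.
    """
    rng = np.random.default_rng(int(seed))
    X = _lambda_trait_matrix(tree, k, lambda_signal, rng)
    if names is None:
        names = [f"cont{j + 1:02d}" for j in range(k)]
    df = pd.DataFrame(X, index=tree.tip_labels, columns=names)
    return TraitTable(df, {c: "continuous" for c in names})


def simulate_binary_traits(
    tree: Phylogeny,
    k: int,
    lambda_signal: float = 1.0,
    prevalence: float = 0.5,
    seed: int = 0,
    names: list[str] | None = None,
) -> TraitTable:
    """Binary traits by thresholding Pagel-lambda Brownian liabilities.

    Each simulated liability is cut at its empirical quantile so that
    the realized fraction of 1s matches ``prevalence`` to within
    ``1/n_species`` (the threshold model for discrete characters).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    n = tree.n_tips
    n_ones = int(round(prevalence * n))
    if n_ones < 1 or n_ones > n - 1:
        raise ValueError(
            f"prevalence {prevalence} is degenerate for {n} species "
            "(all-0 or all-1 after thresholding)"
        )
    rng = np.random.default_rng(int(seed))
    liab = _lambda_trait_matrix(tree, k, lambda_signal, rng)
    X = np.zeros_like(liab)
    top = np.argpartition(-liab, n_ones - 1, axis=0)[:n_ones]
    np.put_along_axis(X, top, 1.0, axis=0)
    if names is None:
        names = [f"bin{j + 1:02d}" for j in range(k)]
    df = pd.DataFrame(X, index=tree.tip_labels, columns=names)
    return TraitTable(df, {c: "binary" for c in names})


# ----------------------------------------------------------------------
# community assembly and surveys
# ----------------------------------------------------------------------


def _gumbel_top_k(log_w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling of k items without replacement (Gumbel trick)."""
    g = rng.gumbel(size=log_w.shape)
    return np.argsort(-(log_w + g))[:k]


def assemble_community(
    traits: TraitTable,
    regime: AssemblyRegime,
    richness: int,
    abundance_shape: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Draw one assemblage from the species pool under a regime.

    Returns integer abundances over the full pool (zero for species not
    selected).  Abundances of selected species are i.i.d. discretized
    lognormal(0, ``abundance_shape``), always >= 1.  Deterministic given
    ``seed``.
    """
    pool = traits.species
    n = len(pool)
    if richness > n:
        raise ValueError(f"richness {richness} exceeds pool size {n}")
    rng = np.random.default_rng(int(seed))

    if regime.kind == "neutral" or regime.strength == 0:
        chosen = rng.choice(n, size=richness, replace=False)
    elif regime.kind == "filtering":
        X = traits.standardized_matrix().to_numpy(dtype=float)
        if regime.trait_optimum is not None:
            opt = np.asarray(regime.trait_optimum, dtype=float)
            if opt.shape != (X.shape[1],):
                raise ValueError(
                    f"trait_optimum must have {X.shape[1]} entries, one per trait"
                )
        else:
            opt = X[rng.integers(n)]
        d2 = ((X - opt) ** 2).sum(axis=1)
        chosen = _gumbel_top_k(-regime.strength * d2, richness, rng)
    else:  # limiting_similarity
        D = gower(traits).data
        first = int(rng.integers(n))
        selected = [first]
        min_d = D[first].copy()
        while len(selected) < richness:
            logw = regime.strength * min_d
            logw[selected] = -np.inf
            w = np.exp(logw - logw[np.isfinite(logw)].max())
            w[selected] = 0.0
            w /= w.sum()
            nxt = int(rng.choice(n, p=w))
            selected.append(nxt)
            min_d = np.minimum(min_d, D[nxt])
        chosen = np.array(selected)

    abundance = np.zeros(n, dtype=int)
    abundance[chosen] = np.ceil(
        rng.lognormal(mean=0.0, sigma=abundance_shape, size=richness)
    ).astype(int)
    return pd.Series(abundance, index=pool, name="abundance")


def simulate_survey(
    truth: pd.Series,
    n_transects: int = 3,
    n_repeats: int = 8,
    detect_p: float = 0.8,
    seed: int = 0,
) -> SurveyDetections:
    """Repeat-survey detection counts for one assemblage.

    Each species' true abundance is allocated to transects uniformly
    (multinomial); each repeat independently detects each allocated
    individual with probability ``detect_p``, so
    ``counts[t, r, s] ~ Binomial(allocation[t, s], detect_p)``.
    """
    if not 0.0 <= detect_p <= 1.0:
        raise ValueError("detect_p must lie in [0, 1]")
    rng = np.random.default_rng(int(seed))
    species = list(truth.index)
    abund = truth.to_numpy(dtype=int)
    alloc = np.stack(
        [rng.multinomial(a, np.full(n_transects, 1.0 / n_transects)) for a in abund],
        axis=1,
    )  # (transect, species)
    counts = rng.binomial(
        alloc[:, None, :], detect_p, size=(n_transects, n_repeats, len(species))
    )
    return SurveyDetections(counts=counts, species=species)


# ----------------------------------------------------------------------
# whole-study bundle
# ----------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """All artifacts of one simulated study."""

    tree: Phylogeny
    traits: TraitTable
    truth: "pd.DataFrame"  # true abundances, assemblage x species
    detections: dict[str, SurveyDetections]
    observed: "pd.DataFrame"  # survey-aggregated abundances
    metadata: pd.DataFrame  # plot, season, elevation per assemblage


def simulate_dataset(cfg: SimConfig) -> SimulatedStudy:
    """Simulate tree, traits, assemblages and surveys for a whole study.

    Per-stage seeds are derived from ``cfg.seed`` via a
    ``SeedSequence`` spawn, so every stage is independently replayable
    and the bundle is bit-identical across runs with the same config.
    """
    from .diversity import survey_aggregate  # local import, avoids cycle

    ss = np.random.SeedSequence(int(cfg.seed))
    stage = {
        name: int(child.generate_state(1, np.uint32)[0] % (2**31))
        for name, child in zip(
            ("tree", "cont", "bin", "assemble", "survey"), ss.spawn(5)
        )
    }
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, seed=stage["tree"])
    cont_names = (
        DEFAULT_CONTINUOUS_NAMES
        if cfg.n_continuous_traits == len(DEFAULT_CONTINUOUS_NAMES)
        else None
    )
    bin_names = (
        DEFAULT_BINARY_NAMES
        if cfg.n_binary_traits == len(DEFAULT_BINARY_NAMES)
        else None
    )
    cont = simulate_continuous_traits(
        tree, cfg.n_continuous_traits, cfg.lambda_signal, seed=stage["cont"],
        names=cont_names,
    )
    binary = simulate_binary_traits(
        tree, cfg.n_binary_traits, cfg.lambda_signal, cfg.binary_prevalence,
        seed=stage["bin"], names=bin_names,
    )
    traits = TraitTable(
        pd.concat([cont.data, binary.data], axis=1), {**cont.types, **binary.types}
    )

    rows, meta_rows, detections = {}, {}, {}
    for k, ((plot, season), richness) in enumerate(sorted(cfg.richness.items())):
        name = f"{plot}_{season}"
        regime = cfg.regimes[plot]
        truth_row = assemble_community(
            traits, regime, richness, cfg.abundance_shape,
            seed=stage["assemble"] + k,
        )
        det = simulate_survey(
            truth_row, cfg.n_transects, cfg.n_repeats, cfg.detect_p,
            seed=stage["survey"] + k,
        )
        rows[name] = truth_row
        detections[name] = det
        meta_rows[name] = {
            "plot": plot,
            "season": season,
            "elevation": cfg.elevations.get(plot, np.nan),
        }

    truth = pd.DataFrame(rows).T
    observed = pd.DataFrame(
        {name: survey_aggregate(det) for name, det in detections.items()}
    ).T
    metadata = pd.DataFrame(meta_rows).T
    return SimulatedStudy(
        tree=tree,
        traits=traits,
        truth=truth,
        detections=detections,
        observed=observed,
        metadata=metadata,
    )
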