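"""End-to-end study orchestration and season/elevation comparisons.

``run_pipeline`` takes a :class:`StudyConfig` naming either input files
(tree, trait table, community matrix) or a simulation block, and writes
the full analysis as tidy CSVs: the per-assemblage diversity panel
(``summary.csv``), the per-trait conservatism tests (``signal.csv``),
the functional and phylogenetic standardized effect sizes
(``ses.csv``), season comparisons (``comparisons.csv``), the NMDS
ordination (``ordination.csv``), and a JSON run log recording seeds and
package versions.  Outputs are a pure function of (inputs, config,
seed).

The classical comparison statistics (paired t, Pearson r, one-sample t)
are secondary descriptive outputs; the primary per-assemblage inference
is the rank-based null-quantile p-value attached to each effect size.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .diversity import (
    CommunityMatrix,
    bray_curtis,
    fric_axes,
    nmds,
    ordination_transform,
    summarize,
)
from .phylo import Phylogeny, load_tree
from .simulate import SimConfig, simulate_dataset
from .structure import nri, ses_pw
from .signal import signal_table
from .traits import TraitTable, gower, pcoa

__all__ = ["StudyConfig", "ComparisonReport", "run_pipeline", "compare_seasons"]


@dataclass
class StudyConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``sim`` (a :class:`SimConfig`) or the three input
    paths (``tree_path``, ``traits_path`` + ``trait_types``,
    ``community_path``) must be provided.
    """

    sim: SimConfig | None = None
    tree_path: str | None = None
    traits_path: str | None = None
    trait_types: dict[str, str] | None = None
    community_path: str | None = None
    n_null: int = 999
    n_perm: int = 999
    n_sim: int = 1000
    seed: int = 0
    outdir: str = "results"
    include_root: bool = True
    abundance_weighted: bool = True
    pcoa_axes: int | None = None
    binary_gower: str = "symmetric"
    nmds_dims: int = 2

    def __post_init__(self) -> None:
        has_paths = self.tree_path or self.traits_path or self.community_path
        if (self.sim is None) == (not has_paths):
            raise ValueError("provide exactly one of a sim block or input paths")
        if self.sim is None and not (
            self.tree_path and self.traits_path and self.community_path
        ):
            raise ValueError("tree, traits and community paths are all required")
        for name in ("n_null", "n_perm", "n_sim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "regimes" in sim_raw:
                from .simulate import AssemblyRegime

                sim_raw["regimes"] = {
                    k: AssemblyRegime(**v) for k, v in sim_raw["regimes"].items()
                }
            if "richness" in sim_raw:
                sim_raw["richness"] = {
                    tuple(k.split("/")): v for k, v in sim_raw["richness"].items()
                }
            raw["sim"] = SimConfig(**sim_raw)
        return cls(**raw)


@dataclass
class ComparisonReport:
    """Classical season/structure comparison statistics."""

    paired_t: pd.DataFrame  # per flavor: wintering vs breeding, paired by plot
    pearson: dict  # r and p between S.E.S. PW and NRI across assemblages
    one_sample_t: pd.DataFrame  # per flavor: all ses values against zero

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for flavor, row in self.paired_t.iterrows():
            rows.append(
                {
                    "comparison": "paired_t_wintering_vs_breeding",
                    "flavor": flavor,
                    "statistic": row["t"],
                    "p": row["p"],
                    "n": row["n_pairs"],
                }
            )
        rows.append(
            {
                "comparison": "pearson_sespw_vs_nri",
                "flavor": "both",
                "statistic": self.pearson["r"],
                "p": self.pearson["p"],
                "n": self.pearson["n"],
            }
        )
        for flavor, row in self.one_sample_t.iterrows():
            rows.append(
                {
                    "comparison": "one_sample_t_vs_zero",
                    "flavor": flavor,
                    "statistic": row["t"],
                    "p": row["p"],
                    "n": row["n"],
                }
            )
        return pd.DataFrame(rows)


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    """Classical paired t on the differences, guarding degenerate input."""
    n = diff.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        raise ValueError("zero variance: all pairwise differences identical")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def compare_seasons(ses_table: pd.DataFrame) -> ComparisonReport:
    """Season and cross-flavor comparisons of effect sizes.

    ``ses_table`` needs columns ``plot``, ``season``, ``flavor`` and
    ``ses`` with seasons ``wintering``/``breeding`` paired by plot.
    Returns the paired t-test of wintering vs breeding per flavor, the
    Pearson correlation between the functional and phylogenetic effect
    sizes across assemblages, and one-sample t-tests of each flavor's
    effect sizes against zero (all two-sided).
    """
    required = {"plot", "season", "flavor", "ses"}
    missing = required - set(ses_table.columns)
    if missing:
        raise ValueError(f"ses table lacks columns: {sorted(missing)}")

    paired_rows = {}
    for flavor, sub in ses_table.groupby("flavor"):
        wide = sub.pivot(index="plot", columns="season", values="ses")
        if not {"wintering", "breeding"} <= set(wide.columns):
            raise ValueError(f"flavor {flavor!r}: need both seasons for pairing")
        wide = wide.dropna()
        if wide.shape[0] < 2:
            raise ValueError(f"flavor {flavor!r}: fewer than 2 complete plot pairs")
        diff = (wide["wintering"] - wide["breeding"]).to_numpy()
        t, p = _paired_t(diff)
        paired_rows[flavor] = {"t": t, "p": p, "n_pairs": diff.size}
    paired = pd.DataFrame(paired_rows).T

    wide = ses_table.pivot_table(
        index=["plot", "season"], columns="flavor", values="ses"
    ).dropna()
    if wide.shape[0] < 3 or wide.shape[1] < 2:
        raise ValueError("Pearson correlation needs >= 3 assemblages, both flavors")
    cols = list(wide.columns)
    x, y = wide[cols[0]].to_numpy(), wide[cols[1]].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant effect sizes: correlation undefined")
    if np.allclose(x, y):
        pearson = {"r": 1.0, "p": 0.0, "n": x.size}
    else:
        r, p = stats.pearsonr(x, y)
        pearson = {"r": float(r), "p": float(p), "n": x.size}

    one_rows = {}
    for flavor, sub in ses_table.groupby("flavor"):
        vals = sub["ses"].dropna().to_numpy()
        t, p = stats.ttest_1samp(vals, 0.0)
        one_rows[flavor] = {"t": float(t), "p": float(p), "n": vals.size}
    one = pd.DataFrame(one_rows).T

    return ComparisonReport(paired_t=paired, pearson=pearson, one_sample_t=one)


def _load_inputs(cfg: StudyConfig):
    if cfg.sim is not None:
        study = simulate_dataset(cfg.sim)
        cm = CommunityMatrix(study.observed.astype(int), study.metadata)
        return study.tree, study.traits, cm
    tree = load_tree(cfg.tree_path)
    traits = TraitTable.from_csv(cfg.traits_path, types=cfg.trait_types)
    cm = CommunityMatrix.from_csv(cfg.community_path)
    return tree, traits, cm


def _check_labels(tree: Phylogeny, traits: TraitTable, cm: CommunityMatrix) -> None:
    tips = set(tree.tip_labels)
    trait_sp = set(traits.species)
    comm_sp = set(cm.species)
    problems = []
    if comm_sp - tips:
        problems.append(f"community species missing from tree: {sorted(comm_sp - tips)}")
    if comm_sp - trait_sp:
        problems.append(
            f"community species missing from traits: {sorted(comm_sp - trait_sp)}"
        )
    if problems:
        raise ValueError("; ".join(problems))


def run_pipeline(cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run the whole analysis and write its artifacts to ``cfg.outdir``.

    The species pool for the null models is the set of species present
    in at least one assemblage; tree and traits are restricted to it,
    so species absent everywhere do not affect any statistic.
    """
    tree, traits, cm = _load_inputs(cfg)
    cm = cm.drop_absent_species()
    _check_labels(tree, traits, cm)
    pool = cm.species
    tree = tree.prune_to(pool)
    traits = traits.subset(pool)

    gower_dm = gower(traits, binary_mode=cfg.binary_gower)
    sizes = [len(cm.species_present(a)) for a in cm.assemblages]
    n_axes = cfg.pcoa_axes or fric_axes(gower_dm, min(sizes))
    coords = pcoa(gower_dm, correction="sqrt", n_axes=n_axes).coordinates

    summary = summarize(
        cm,
        tree,
        traits,
        gower_dm=gower_dm,
        coords=coords,
        include_root=cfg.include_root,
        abundance_weighted=cfg.abundance_weighted,
    )

    ss = np.random.SeedSequence(int(cfg.seed))
    seed_signal, seed_ses, seed_nmds = (
        int(c.generate_state(1, np.uint32)[0] % (2**31)) for c in ss.spawn(3)
    )

    signal = signal_table(
        tree, traits, n_perm=cfg.n_perm, n_sim=cfg.n_sim, seed=seed_signal
    )

    rel = cm.relative_abundance
    ses_rows = []
    for k, a in enumerate(cm.assemblages):
        f = rel.loc[a]
        for flavor, res in (
            ("functional", ses_pw(gower_dm, f, cfg.n_null, seed_ses + 2 * k,
                                  cfg.abundance_weighted)),
            ("phylogenetic", nri(tree, f, cfg.n_null, seed_ses + 2 * k + 1,
                                 cfg.abundance_weighted)),
        ):
            row = {
                "assemblage": a,
                "flavor": flavor,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "ses": res.ses,
                "p_quantile": res.p_quantile,
                "status": res.status,
            }
            if cm.metadata is not None:
                for col in cm.metadata.columns:
                    row[col] = cm.metadata.loc[a, col]
            ses_rows.append(row)
    ses_df = pd.DataFrame(ses_rows)

    transformed = ordination_transform(cm)
    bc = bray_curtis(transformed)
    ordination = nmds(bc, k_dims=cfg.nmds_dims, seed=seed_nmds)
    ord_df = ordination.coordinates.copy()
    ord_df["stress"] = ordination.stress
    if cm.metadata is not None:
        ord_df = pd.concat([cm.metadata, ord_df], axis=1)

    comparisons = (
        compare_seasons(ses_df).to_frame()
        if {"plot", "season"} <= set(ses_df.columns)
        else pd.DataFrame()
    )

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6g"
    summary.to_csv(outdir / "summary.csv", float_format=float_fmt)
    signal.to_csv(outdir / "signal.csv", float_format=float_fmt)
    ses_df.to_csv(outdir / "ses.csv", index=False, float_format=float_fmt)
    ord_df.to_csv(outdir / "ordination.csv", index_label="assemblage",
                  float_format=float_fmt)
    if not comparisons.empty:
        comparisons.to_csv(outdir / "comparisons.csv", index=False,
                           float_format=float_fmt)

    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "master_seed": cfg.seed,
        "stage_seeds": {
            "signal": seed_signal,
            "ses_base": seed_ses,
            "nmds": seed_nmds,
        },
        "n_null": cfg.n_null,
        "n_perm": cfg.n_perm,
        "n_sim": cfg.n_sim,
        "pcoa_axes": n_axes,
        "pool_size": len(pool),
        "config": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if isinstance(v, (int, float, str, bool, type(None)))
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    return {
        "summary": summary,
        "signal": signal,
        "ses": ses_df,
        "ordination": ord_df,
        "comparisons": comparisons,
    }
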