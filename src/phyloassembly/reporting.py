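"""Configuration-driven pipeline: load inputs, run every analysis stage,
write a report bundle (CSV/JSON tables, optional figures, run manifest).

Stage seeding: every randomized quantity draws from a generator derived from
the master seed by a stable label that includes the stage name and plot id,
so results are independent of plot processing order and adding a stage never
perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._rng import derive_rng
from .assembly_dynamics import (
    ColonistTestOptions,
    ExtinctionTestOptions,
    colonist_relatedness_test,
    count_significant,
    extinction_relatedness_test,
    partition_plot,
    pool_colonizer_test,
    results_to_dataframe,
)
from .community_change import (
    ancova_biomass,
    build_change_records,
    compare_jaccard_years,
    diversity_change_regression,
    mean_pairwise_jaccard,
    ols_fit,
)
from .errors import PhyloAssemblyError
from .null_models import NullConstraintSpec, null_test
from .phylo_core import Phylogeny, read_newick
from .tables import (
    CommunityTable,
    clade_tags_from_metadata,
    load_composition,
    load_plots,
    load_species_metadata,
    pool_from_metadata,
)

__all__ = ["RunConfig", "AnalysisInputs", "load_inputs", "run_full_analysis"]


@dataclass
class RunConfig:
    """Paths, options and seed for one analysis run."""

    tree_path: str
    composition_path: str
    plots_path: str
    species_path: str
    out_dir: str = "results"
    n_randomizations: int = 1000
    n_perm_jaccard: int = 999
    alpha: float = 0.05
    seed: int = 0
    exclude_legumes: bool = False
    exclude_grasses: bool = False
    colonists_as_residents: bool = False
    restricted_colonist_pool: bool = False
    prune_tips: tuple[str, ...] = field(default_factory=tuple)
    make_figures: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PhyloAssemblyError(f"unknown config keys: {sorted(unknown)}")
        if "prune_tips" in raw:
            raw["prune_tips"] = tuple(raw["prune_tips"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["prune_tips"] = list(self.prune_tips)
        return d


@dataclass
class AnalysisInputs:
    tree: Phylogeny
    species: pd.DataFrame
    sown: CommunityTable
    final: CommunityTable
    plots: pd.DataFrame


def load_inputs(config: RunConfig) -> AnalysisInputs:
    """Load and cross-validate the four input files."""
    species = load_species_metadata(config.species_path)
    tree = read_newick(
        Path(config.tree_path).read_text(),
        prune=config.prune_tips or None,
        clade_tags=None,
    )
    tags = clade_tags_from_metadata(species)
    missing = set(tags) - set(tree.tip_labels)
    if missing:
        raise PhyloAssemblyError(
            f"species.csv lists species absent from the tree: {sorted(missing)[:5]}..."
        )
    tree = tree.with_clade_tags(tags)
    plots = load_plots(config.plots_path)
    sown = load_composition(config.composition_path, "sown", plots=plots)
    final = load_composition(config.composition_path, "final", plots=plots)
    for tbl in (sown, final):
        tree.validate_species(tbl.species)
    return AnalysisInputs(tree, species, sown, final, plots)


# -- stages ----------------------------------------------------------------


def stage_sown_dispersion(inputs: AnalysisInputs, config: RunConfig) -> pd.DataFrame:
    """PD and MNND randomization tests of each sown polyculture against the
    internal pool (with the at-least-one-grass constraint). Monocultures are
    excluded (MNND undefined; singleton PD is identically zero) and recorded."""
    internal = pool_from_metadata(inputs.species, "internal")
    rows = []
    for plot in inputs.sown.plot_ids:
        comm = inputs.sown.members(plot)
        if len(comm) < 2:
            rows.append({"plot_id": plot, "excluded": True, "reason": "monoculture"})
            continue
        for metric in ("PD", "MNND"):
            spec = NullConstraintSpec(
                pool=internal,
                required_tag="grass",
                n_randomizations=config.n_randomizations,
            )
            res = null_test(
                metric,
                comm,
                spec,
                inputs.tree,
                alpha=config.alpha,
                rng=derive_rng(config.seed, f"sown-dispersion:{plot}:{metric}"),
            )
            rows.append({"plot_id": plot, "excluded": False, "reason": "", **res.as_dict()})
    return pd.DataFrame(rows)


def _partitions(inputs: AnalysisInputs):
    return [
        partition_plot(inputs.sown.members(p), inputs.final.members(p), p)
        for p in inputs.sown.plot_ids
    ]


def _excluded_tags(config: RunConfig) -> frozenset[str]:
    tags = set()
    if config.exclude_legumes:
        tags.add("legume")
    if config.exclude_grasses:
        tags.add("grass")
    return frozenset(tags)


def stage_assembly(inputs: AnalysisInputs, config: RunConfig) -> dict:
    """Per-plot colonist and extinction relatedness tests plus the pool-level
    tests of which species colonized / went extinct anywhere."""
    tree = inputs.tree
    parts = _partitions(inputs)
    excluded = _excluded_tags(config)
    regional = pool_from_metadata(inputs.species, "regional")

    restricted_pool = None
    if config.restricted_colonist_pool:
        observed_colonists = frozenset().union(*[p.colonize for p in parts])
        restricted_pool = observed_colonists

    colonist_results, colonist_skipped = [], []
    for part in parts:
        opts = ColonistTestOptions(
            residents="sown_plus_colonists" if config.colonists_as_residents else "sown",
            excluded_tags=excluded,
            pool=restricted_pool if restricted_pool is not None else regional,
            n_randomizations=config.n_randomizations,
        )
        try:
            colonist_results.append(
                colonist_relatedness_test(
                    part,
                    None,
                    tree,
                    opts,
                    alpha=config.alpha,
                    rng=derive_rng(config.seed, f"colonist:{part.plot_id}"),
                )
            )
        except PhyloAssemblyError as exc:
            colonist_skipped.append({"plot_id": part.plot_id, "reason": str(exc)})

    extinction_results, extinction_skipped = [], []
    for part in parts:
        opts = ExtinctionTestOptions(
            colonists_as_residents=config.colonists_as_residents,
            excluded_tags=excluded,
            n_randomizations=config.n_randomizations,
        )
        try:
            extinction_results.append(
                extinction_relatedness_test(
                    part,
                    tree,
                    opts,
                    alpha=config.alpha,
                    rng=derive_rng(config.seed, f"extinction:{part.plot_id}"),
                )
            )
        except PhyloAssemblyError as exc:
            extinction_skipped.append({"plot_id": part.plot_id, "reason": str(exc)})

    pool_tests = {}
    colonized_anywhere = frozenset().union(*[p.colonize for p in parts])
    extinct_anywhere = frozenset().union(*[p.extinct for p in parts])
    for name, focal in (("colonizers", colonized_anywhere), ("extinctions", extinct_anywhere)):
        if len(focal) >= 2:
            pool_tests[name] = pool_colonizer_test(
                focal,
                regional,
                tree,
                n_randomizations=config.n_randomizations,
                alpha=config.alpha,
                rng=derive_rng(config.seed, f"pool:{name}"),
            ).as_dict()
        else:
            pool_tests[name] = {"skipped": f"only {len(focal)} focal species"}

    summary = {
        "colonist": count_significant(colonist_results, config.alpha).as_dict()
        if colonist_results
        else {},
        "extinction": count_significant(extinction_results, config.alpha).as_dict()
        if extinction_results
        else {},
        "colonist_skipped": colonist_skipped,
        "extinction_skipped": extinction_skipped,
    }
    return {
        "colonist_results": colonist_results,
        "extinction_results": extinction_results,
        "pool_tests": pool_tests,
        "summary": summary,
    }


def stage_change(inputs: AnalysisInputs, config: RunConfig) -> dict:
    """Change records, Jaccard convergence, and the regression battery."""
    records = build_change_records(inputs.sown, inputs.final, inputs.tree)

    j1 = mean_pairwise_jaccard(inputs.sown)
    j2 = mean_pairwise_jaccard(inputs.final)
    d_j, p_j = compare_jaccard_years(
        inputs.sown,
        inputs.final,
        n_perm=config.n_perm_jaccard,
        rng=derive_rng(config.seed, "jaccard"),
    )
    jaccard_summary = {
        "mean_sown": j1[0],
        "se_sown": j1[1],
        "mean_final": j2[0],
        "se_final": j2[1],
        "n_pairs": j1[2],
        "delta_mean": d_j,
        "p_permutation": p_j,
        "n_permutations": config.n_perm_jaccard,
    }

    reg_rows = []
    for metric in ("richness", "pd", "mnnd"):
        res, n_used = diversity_change_regression(records, metric)
        reg_rows.append({"analysis": f"d_{metric}_vs_sown_{metric}", **res.as_dict(), "n": n_used})
    for x, y, name in (
        ("sown_pd", "biomass_year1", "biomass1_vs_sown_pd"),
        ("sown_richness", "biomass_year1", "biomass1_vs_sown_richness"),
        ("sown_mnnd", "biomass_year1", "biomass1_vs_sown_mnnd"),
        ("final_pd", "biomass_year2", "biomass2_vs_final_pd"),
        ("final_richness", "biomass_year2", "biomass2_vs_final_richness"),
        ("final_mnnd", "biomass_year2", "biomass2_vs_final_mnnd"),
        ("sown_pd", "d_biomass", "d_biomass_vs_sown_pd"),
        ("d_pd", "d_biomass", "d_biomass_vs_d_pd"),
        ("d_richness", "d_biomass", "d_biomass_vs_d_richness"),
    ):
        sub = records[[x, y]].dropna()
        if len(sub) >= 3 and sub[x].nunique() > 1:
            res = ols_fit(sub[x], sub[y])
            reg_rows.append({"analysis": name, **res.as_dict()})
    regressions = pd.DataFrame(reg_rows)
    return {"records": records, "jaccard": jaccard_summary, "regressions": regressions}


def stage_ancova(records: pd.DataFrame) -> dict:
    return ancova_biomass(records).as_dict()


# -- figures ---------------------------------------------------------------


def _write_figures(records: pd.DataFrame, out: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    written = []

    def scatter_fit(x, y, xlab, ylab, fname, color_by_legume=None):
        sub = records[[x, y] + ([color_by_legume] if color_by_legume else [])].dropna()
        fig, ax = plt.subplots(figsize=(4.2, 3.4))
        if color_by_legume:
            for status, marker in (("initiated-with", "o"), ("colonized-by", "+"), ("never", "x")):
                sel = sub[sub[color_by_legume] == status]
                ax.scatter(sel[x], sel[y], marker=marker, label=status, alpha=0.8)
            ax.legend(fontsize=7)
        else:
            ax.scatter(sub[x], sub[y], alpha=0.8)
        if len(sub) >= 3 and sub[x].nunique() > 1:
            fit = ols_fit(sub[x], sub[y])
            xs = pd.Series([sub[x].min(), sub[x].max()])
            ax.plot(xs, fit.intercept + fit.slope * xs, "k--", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        fig.tight_layout()
        path = figdir / fname
        fig.savefig(path)
        plt.close(fig)
        written.append(str(path))

    scatter_fit("sown_pd", "d_pd", "sown PD", "change in PD", "d_pd_vs_sown_pd.svg")
    scatter_fit("sown_mnnd", "d_mnnd", "sown MNND", "change in MNND", "d_mnnd_vs_sown_mnnd.svg")
    scatter_fit(
        "d_pd", "d_biomass", "change in PD", "change in biomass (g/m^2)",
        "d_biomass_vs_d_pd.svg", color_by_legume="legume_status",
    )
    return written


# -- orchestration ---------------------------------------------------------


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a map of table name -> file path. If any stage fails, a FAILED
    marker naming the error is left in the output directory so partial
    bundles are never mistaken for complete ones.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    try:
        paths = _run_all_stages(config, out)
    except Exception as exc:
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return paths


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _run_all_stages(config: RunConfig, out: Path) -> dict:
    inputs = load_inputs(config)
    paths = {}

    disp = stage_sown_dispersion(inputs, config)
    paths["dispersion_sown"] = out / "dispersion_sown.csv"
    disp.to_csv(paths["dispersion_sown"], index=False)

    assembly = stage_assembly(inputs, config)
    paths["colonist_tests"] = out / "colonist_tests.csv"
    results_to_dataframe(assembly["colonist_results"]).to_csv(
        paths["colonist_tests"], index=False
    )
    paths["extinction_tests"] = out / "extinction_tests.csv"
    results_to_dataframe(assembly["extinction_results"]).to_csv(
        paths["extinction_tests"], index=False
    )
    paths["assembly_summary"] = out / "assembly_summary.json"
    _json_dump(assembly["summary"], paths["assembly_summary"])
    paths["pool_tests"] = out / "pool_tests.json"
    _json_dump(assembly["pool_tests"], paths["pool_tests"])

    change = stage_change(inputs, config)
    paths["change_records"] = out / "change_records.csv"
    change["records"].to_csv(paths["change_records"], index=False)
    paths["regressions"] = out / "regressions.csv"
    change["regressions"].to_csv(paths["regressions"], index=False)
    paths["jaccard"] = out / "jaccard.json"
    _json_dump(change["jaccard"], paths["jaccard"])

    paths["ancova"] = out / "ancova.json"
    try:
        _json_dump(stage_ancova(change["records"]), paths["ancova"])
    except ValueError as exc:
        _json_dump({"skipped": str(exc)}, paths["ancova"])

    if config.make_figures:
        for f in _write_figures(change["records"], out):
            paths[Path(f).stem] = Path(f)

    manifest = {
        "package_version": __version__,
        "config": config.as_dict(),
        "input_hashes": {
            "tree": _sha256(config.tree_path),
            "composition": _sha256(config.composition_path),
            "plots": _sha256(config.plots_path),
            "species": _sha256(config.species_path),
        },
        "tables": sorted(str(p) for p in paths.values()),
    }
    paths["manifest"] = out / "manifest.json"
    _json_dump(manifest, paths["manifest"])
    return {k: str(v) for k, v in paths.items()}
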