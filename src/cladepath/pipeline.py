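"""End-to-end orchestration of the two analyses.

* richness mode: what drives the species richness of genera — genus-level
  composite niche-diversity variables, GLS path models under Brownian-motion
  covariance on the genus tree, ranked by CICc.
* speciation mode: what drives tip speciation rates — DR and per-trait TR
  statistics, phylogenetic independent contrasts, OLS-through-the-origin
  path models ranked by AIC (and CICc).

Multivariate niche constructs (host-use location, environmental niche)
enter path models as their first two ordination axes; a reported
construct-level edge is the sum of the axis-paired standardized
coefficients, matching the "combined effects of the first two components"
reporting convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .niche import EnvGrid, build_niche_table, shannon_breadth
from .pathmodels import (
    CausalDAG,
    PathModel,
    PathModelError,
    compare_models,
    decompose_effects,
    quantile_normalize,
)
from .rates import dr_statistic, pic, resolve_polytomies, tr_statistic
from .trees import (
    Tree,
    assign_genus_clades,
    collapse_to_genera,
    prune_to_tips,
    read_genus_map,
    read_newick,
)

__all__ = [
    "RunConfig",
    "aggregate_genus_niche",
    "run_richness_analysis",
    "run_speciation_analysis",
    "expand_construct_dag",
    "combine_construct_coefficients",
]


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML key-value file)."""

    mode: str = "speciation"  # or "richness"
    tree: str = ""
    incidence: str = ""
    occurrences: str = ""
    grids: list = field(default_factory=list)  # grid stems
    grid_dir: str = "."
    genus_map: str = ""
    richness: str = ""
    dags: list = field(default_factory=list)  # DAG text files
    min_occurrences: int = 10
    k_axes: int = 2
    normalize: bool = True
    tr_signed: bool = False
    tr_dr_weighting: bool = False
    tr_per_unit_depth: bool = False
    outdir: str = "cladepath_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        for key in ("tree", "incidence", "occurrences"):
            p = getattr(cfg, key)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        return cfg


def _hash(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv().encode()
    elif isinstance(obj, pd.Series):
        payload = obj.to_csv().encode()
    else:
        payload = str(obj).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


class _Audit:
    """Structured per-stage log: operation, input hashes, note."""

    def __init__(self):
        self.entries = []
        self.warnings = []

    def log(self, operation: str, note: str = "", **inputs):
        self.entries.append(
            {
                "operation": operation,
                "inputs": {k: _hash(v) for k, v in inputs.items()},
                "note": note,
            }
        )

    def write(self, path):
        Path(path).write_text(
            json.dumps({"log": self.entries, "warnings": self.warnings}, indent=1)
        )


# ----------------------------------------------------- genus aggregation

def aggregate_genus_niche(
    niche_table: pd.DataFrame,
    incidence: pd.DataFrame,
    members: dict[str, list[str]],
) -> pd.DataFrame:
    """Composite genus niche-diversity variables.

    host_diversity: Shannon index over the members' pooled host-family
    usage (summed incidences).  env_diversity: total variance (sum over the
    environmental PC axes) of the members' scores.  Singleton genera score 0
    on both — with one species there is no within-genus diversity.
    """
    pc_cols = [c for c in niche_table.columns if c.startswith("env_pc")]
    rows = {}
    for genus, mem in members.items():
        mem = [m for m in mem if m in niche_table.index and m in incidence.index]
        if not mem:
            raise ValueError(f"genus {genus!r} has no niche-characterized members")
        if len(mem) == 1:
            rows[genus] = {"host_diversity": 0.0, "env_diversity": 0.0, "n_members": 1}
            continue
        pooled = incidence.loc[mem].sum(axis=0)
        hd = shannon_breadth(pooled)
        ev = float(niche_table.loc[mem, pc_cols].var(ddof=0).sum())
        rows[genus] = {
            "host_diversity": hd,
            "env_diversity": ev,
            "n_members": len(mem),
        }
    return pd.DataFrame(rows).T.sort_index()


# -------------------------------------------------- construct expansion

def expand_construct_dag(
    dag: CausalDAG, construct_axes: dict[str, list[str]]
) -> CausalDAG:
    """Expand construct-level edges to variable-level edges.

    A construct with k axes contributes k variables.  An edge between two
    k-axis constructs expands axis-wise (axis 1 -> axis 1, axis 2 -> axis 2);
    an edge between a construct and a single variable expands to one edge
    per axis.  Correlations expand the same way.
    """

    def axes(v):
        return construct_axes.get(v, [v])

    nodes = [a for v in dag.nodes for a in axes(v)]
    edges, corrs = [], []
    for u, v in dag.edges:
        au, av = axes(u), axes(v)
        if len(au) == len(av):
            edges += list(zip(au, av))
        else:
            edges += [(a, b) for a in au for b in av]
    for pr in dag.correlations:
        u, v = sorted(pr, key=dag.nodes.index)
        au, av = axes(u), axes(v)
        if len(au) == len(av):
            corrs += list(zip(au, av))
        else:
            corrs += [(a, b) for a in au for b in av]
    return CausalDAG(nodes, edges, corrs, name=dag.name)


def combine_construct_coefficients(
    dag: CausalDAG,
    fit: PathModel,
    construct_axes: dict[str, list[str]],
) -> dict[tuple[str, str], float]:
    """Construct-level edge value = sum of the expanded axis coefficients."""

    def axes(v):
        return construct_axes.get(v, [v])

    cmap = fit.coefficient_map()
    out = {}
    for u, v in dag.edges:
        au, av = axes(u), axes(v)
        if len(au) == len(av):
            pairs = list(zip(au, av))
        else:
            pairs = [(a, b) for a in au for b in av]
        out[(u, v)] = float(sum(cmap[p] for p in pairs))
    return out


# -------------------------------------------------------------- loaders

def _load_inputs(cfg: RunConfig, audit: _Audit):
    tree = read_newick(cfg.tree)
    incidence = pd.read_csv(cfg.incidence, sep="\t", index_col=0)
    occ = pd.read_csv(cfg.occurrences, sep="\t")
    grids = [EnvGrid.read(cfg.grid_dir, stem) for stem in cfg.grids]
    audit.log(
        "load_inputs",
        tree=tree.newick(),
        incidence=incidence,
        occurrences=occ,
        grids=[g.name for g in grids],
    )
    return tree, incidence, occ, grids


def _check_degenerate(data: pd.DataFrame):
    nun = data.nunique()
    bad = nun.index[nun < 3].tolist()
    if bad:
        raise ValueError(f"degenerate variables (fewer than 3 distinct values): {bad}")


def _normalize(data: pd.DataFrame, on: bool) -> pd.DataFrame:
    if not on:
        return data
    return pd.DataFrame(
        {c: quantile_normalize(data[c]) for c in data.columns}, index=data.index
    )


def _write_fit_reports(fits, outdir: Path, comparison: pd.DataFrame, effects):
    outdir.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
    for f in fits:
        stem = f.dag.name or "model"
        f.coefficients_.to_csv(outdir / f"{stem}_coefficients.tsv", sep="\t", index=False)
        (outdir / f"{stem}_fit.json").write_text(json.dumps(f.summary(), indent=1))
    if effects is not None:
        effects.to_csv(outdir / "effects.tsv", sep="\t", index=False)


# ------------------------------------------------------ richness analysis

RICHNESS_DAGS = {
    "direct_and_indirect": CausalDAG(
        ["env_diversity", "host_diversity", "richness"],
        [
            ("env_diversity", "host_diversity"),
            ("env_diversity", "richness"),
            ("host_diversity", "richness"),
        ],
        name="direct_and_indirect",
    ),
    "indirect_only": CausalDAG(
        ["env_diversity", "host_diversity", "richness"],
        [("env_diversity", "host_diversity"), ("host_diversity", "richness")],
        name="indirect_only",
    ),
}


def run_richness_analysis(cfg: RunConfig) -> dict:
    """Genus species-richness path analysis from raw inputs.

    Builds the species niche table, collapses the tree to one tip per genus
    (misplaced congeners dropped), assembles per-genus richness and
    composite diversity variables, normalizes, fits the candidate DAGs by
    GLS under Brownian-motion covariance on the genus tree, and writes a
    CICc comparison plus effect decomposition.
    """
    audit = _Audit()
    outdir = Path(cfg.outdir)
    tree, incidence, occ, grids = _load_inputs(cfg, audit)
    genus_map = read_genus_map(cfg.genus_map)
    richness = pd.read_csv(cfg.richness, sep="\t", index_col=0).iloc[:, 0]

    table = build_niche_table(
        incidence, occ, grids, n_min=cfg.min_occurrences, k_axes=cfg.k_axes
    )
    tree = prune_to_tips(tree, [t for t in tree.tip_labels if t in table.index])
    audit.log("build_niche_table", niche=table)

    counts = occ.groupby("species").size().to_dict()
    members = assign_genus_clades(tree, genus_map)
    members = {g: m for g, m in members.items() if m}
    genus_tree, reps = collapse_to_genera(tree, genus_map, counts)
    summary = aggregate_genus_niche(table, incidence, members)
    data = summary[["host_diversity", "env_diversity"]].copy()
    data["richness"] = richness.reindex(data.index)
    data = data.dropna()
    if len(data) < 10:
        raise ValueError(f"only {len(data)} genera with complete data (need >= 10)")
    genus_tree = prune_to_tips(genus_tree, list(data.index))
    data = data.loc[genus_tree.tip_labels]
    _check_degenerate(data)
    data = _normalize(data, cfg.normalize)
    audit.log("assemble_genus_data", data=data)

    dags = (
        [CausalDAG.from_text(Path(p).read_text(), name=Path(p).stem) for p in cfg.dags]
        if cfg.dags
        else list(RICHNESS_DAGS.values())
    )
    fits = [
        PathModel(dag=d, mode="gls-bm", tree=genus_tree).fit(data) for d in dags
    ]
    comparison = compare_models(fits, criterion="cicc")
    best = next(f for f in fits if (f.dag.name or "") == comparison["name"].iloc[0])
    effects = best.effects()
    audit.log("fit_models", comparison=comparison)
    _write_fit_reports(fits, outdir, comparison, effects)
    data.rename_axis("genus").to_csv(outdir / "genus_variables.tsv", sep="\t")
    audit.write(outdir / "audit.json")
    return {
        "fits": fits,
        "comparison": comparison,
        "effects": effects,
        "data": data,
        "genus_tree": genus_tree,
    }


# ---------------------------------------------------- speciation analysis

SPECIATION_CONSTRUCTS = {"env_rate": ["env_rate1", "env_rate2"],
                         "host_rate": ["host_rate1", "host_rate2"]}

SPECIATION_DAGS = {
    # family without host breadth: special forms of the general model
    "env_to_host": CausalDAG(
        ["env_rate", "host_rate", "dr"],
        [("env_rate", "host_rate"), ("env_rate", "dr"), ("host_rate", "dr")],
        name="env_to_host",
    ),
    "host_to_env": CausalDAG(
        ["env_rate", "host_rate", "dr"],
        [("host_rate", "env_rate"), ("env_rate", "dr"), ("host_rate", "dr")],
        name="host_to_env",
    ),
    "env_indirect_only": CausalDAG(
        ["env_rate", "host_rate", "dr"],
        [("env_rate", "host_rate"), ("host_rate", "dr")],
        name="env_indirect_only",
    ),
}

SPECIATION_DAGS_BREADTH = {
    "breadth_env_to_host": CausalDAG(
        ["env_rate", "host_rate", "breadth_rate", "dr"],
        [
            ("env_rate", "host_rate"),
            ("env_rate", "dr"),
            ("host_rate", "breadth_rate"),
            ("host_rate", "dr"),
            ("breadth_rate", "dr"),
        ],
        name="breadth_env_to_host",
    ),
    "breadth_host_to_env": CausalDAG(
        ["env_rate", "host_rate", "breadth_rate", "dr"],
        [
            ("host_rate", "env_rate"),
            ("env_rate", "dr"),
            ("host_rate", "breadth_rate"),
            ("host_rate", "dr"),
            ("breadth_rate", "dr"),
        ],
        name="breadth_host_to_env",
    ),
}


def speciation_variables(
    tree: Tree,
    niche_table: pd.DataFrame,
    *,
    tr_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Contrast-level variable matrix for the speciation models.

    DR per tip and TR per niche trait are computed on ``tree``; PICs of each
    are taken on the binary-resolved tree, giving one row per internal node.
    Columns: dr, env_rate1/2, host_rate1/2, breadth_rate.
    """
    tr_kwargs = tr_kwargs or {}
    trait_cols = {
        "env_rate1": "env_pc1",
        "env_rate2": "env_pc2",
        "host_rate1": "host_pco1",
        "host_rate2": "host_pco2",
        "breadth_rate": "host_breadth",
    }
    tips = pd.DataFrame({"dr": dr_statistic(tree)})
    for out_col, src in trait_cols.items():
        if src not in niche_table.columns:
            continue
        tips[out_col] = tr_statistic(tree, niche_table[src], **tr_kwargs)
    missing = [t for t in tree.tip_labels if t not in niche_table.index]
    if missing:
        raise ValueError(f"tree tips without niche data: {missing[:5]}")
    _check_degenerate(tips)
    binary = resolve_polytomies(tree)
    contrasts = {c: pic(binary, tips[c])["contrast"] for c in tips.columns}
    return pd.DataFrame(contrasts)


def run_speciation_analysis(cfg: RunConfig) -> dict:
    """Branch-specific speciation-rate path analysis from raw inputs.

    DR and TR statistics per tip, PICs, normalization, then two model
    families fitted as OLS-through-the-origin path models on the contrasts:
    with and without the host-breadth rate.  Models are compared by AIC and
    CICc; the best model of each family is decomposed into direct, indirect
    and total effects at the construct level.
    """
    audit = _Audit()
    outdir = Path(cfg.outdir)
    tree, incidence, occ, grids = _load_inputs(cfg, audit)
    table = build_niche_table(
        incidence, occ, grids, n_min=cfg.min_occurrences, k_axes=cfg.k_axes
    )
    tree = prune_to_tips(tree, [t for t in tree.tip_labels if t in table.index])
    audit.log("build_niche_table", niche=table)

    tr_kwargs = dict(
        signed=cfg.tr_signed,
        dr_weighting=cfg.tr_dr_weighting,
        per_unit_depth=cfg.tr_per_unit_depth,
    )
    data = speciation_variables(tree, table, tr_kwargs=tr_kwargs)
    _check_degenerate(data)
    data = _normalize(data, cfg.normalize)
    audit.log("speciation_variables", data=data)

    results = {}
    all_fits = []
    for family, dags in (
        ("no_breadth", SPECIATION_DAGS),
        ("with_breadth", SPECIATION_DAGS_BREADTH),
    ):
        fits = []
        for d in dags.values():
            expanded = expand_construct_dag(d, SPECIATION_CONSTRUCTS)
            f = PathModel(dag=expanded, mode="contrasts-ols").fit(data)
            f.construct_dag_ = d
            fits.append(f)
        comparison = compare_models(fits, criterion="aic")
        best = next(f for f in fits if f.dag.name == comparison["name"].iloc[0])
        combined = combine_construct_coefficients(
            best.construct_dag_, best, SPECIATION_CONSTRUCTS
        )
        effects = decompose_effects(best.construct_dag_, combined)
        results[family] = {
            "fits": fits,
            "comparison": comparison,
            "effects": effects,
            "combined_coefficients": combined,
        }
        fam_dir = outdir / family
        _write_fit_reports(fits, fam_dir, comparison, effects)
        all_fits.extend(fits)
        audit.log(f"fit_models_{family}", comparison=comparison)
    data.rename_axis("node").to_csv(outdir / "contrast_variables.tsv", sep="\t")
    audit.write(outdir / "audit.json")
    results["data"] = data
    results["tree"] = tree
    return results
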