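"""Synthetic data with the statistical structure the pipeline assumes.

Generates birth-death phylogenies, Brownian-motion traits with clade-
specific rate multipliers, phylogenetically clustered host-use incidence,
spatially autocorrelated environmental surfaces with species occurrence
points, and linear-Gaussian path-model data with known standardized
coefficients.  One root seed is split into named per-component streams
(NumPy SeedSequence spawning), so adding a generator never perturbs
another's draws and every output is bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from scipy import stats

from .pathmodels import CausalDAG, PathModelError
from .trees import Tree, prune_to_tips, write_newick

__all__ = [
    "SimConfig",
    "component_rng",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_host_matrix",
    "simulate_env_world",
    "simulate_sem",
    "simulate_rate_world",
    "write_bundle",
]


class SimulationError(RuntimeError):
    pass


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent, named substream of the root seed."""
    key = zlib.crc32(component.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic world.

    The defaults mirror the analysis conditions: a ~371-species Nearctic
    clade on a birth-death tree, ~20 usable host plant families, at least 10
    occurrence records per species on 5-arc-min-style grids, and moderate
    phylogenetic clustering of host use.
    """

    seed: int = 0
    n_tips: int = 371
    birth: float = 1.0
    death: float = 0.25
    n_traits: int = 2
    sigma2: float = 1.0
    clade_rate_multipliers: dict = field(default_factory=dict)
    n_families: int = 20
    host_clustering: float = 0.6
    host_prevalence: float = 0.25
    grid_shape: tuple = (40, 60)
    autocorr_cells: float = 4.0
    n_env: int = 4
    occurrences_min: int = 10
    occurrences_mean: int = 40
    dispersal_scatter: float = 3.0
    sem_coefficients: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_tips < 3:
            raise SimulationError("need at least 3 tips")
        if self.birth < 0 or self.death < 0:
            raise SimulationError("rates must be non-negative")


# ------------------------------------------------------------------ trees

def simulate_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    rng: np.random.Generator | None = None,
    max_retries: int = 1000,
) -> Tree:
    """Birth-death tree conditioned (by rejection) on the extant tip count.

    A Gillespie walk runs until the extant lineage count first reaches
    ``n_tips``; a final shared waiting time is added to every pendant branch
    so the extant tree is ultrametric in real time.  Lineages that went
    extinct are pruned.  Tips are labeled s001, s002, ...
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_tips < 2:
        raise SimulationError("need at least 2 tips")
    for _ in range(max_retries):
        parent = [-1, 0, 0]
        children = [[1, 2], [], []]
        start = [0.0, 0.0, 0.0]
        active = [1, 2]
        t = 0.0
        failed = False
        while len(active) < n_tips:
            k = len(active)
            if k == 0:
                failed = True
                break
            t += rng.exponential(1.0 / (k * (birth + death)))
            i = active[rng.integers(k)]
            if rng.random() < birth / (birth + death):
                a, b = len(parent), len(parent) + 1
                parent.extend([i, i])
                children[i] = [a, b]
                children.extend([[], []])
                start.extend([t, t])
                active.remove(i)
                active.extend([a, b])
            else:
                active.remove(i)  # extinct; pruned below
        if failed:
            continue
        t += rng.exponential(1.0 / (n_tips * (birth + death)))
        lengths = np.zeros(len(parent))
        labels: list[str | None] = [None] * len(parent)
        end = list(start)
        for i in active:
            end[i] = t
        for i in range(1, len(parent)):
            if children[i]:
                end[i] = start[children[i][0]]
            lengths[i] = end[i] - start[i]
        width = max(3, len(str(n_tips)))
        for k, i in enumerate(sorted(active)):
            labels[i] = f"s{k + 1:0{width}d}"
        full = _assemble(parent, children, lengths, labels)
        return prune_to_tips(full, [l for l in labels if l])
    raise SimulationError(f"whole-tree extinction in {max_retries} attempts")


def _assemble(parent, children, lengths, labels) -> Tree:
    # dead tips are unlabeled; give them throwaway labels then prune
    lab = list(labels)
    k = 0
    for i, c in enumerate(children):
        if not c and lab[i] is None:
            lab[i] = f"__dead{k}"
            k += 1
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Tree(parent, children, lengths, lab)


# ----------------------------------------------------------------- traits

def _edge_rates(tree: Tree, clade_rate_multipliers: dict, sigma2: float) -> np.ndarray:
    """Per-node BM rate; a clade is anchored by a tuple of tip labels whose
    MRCA subtree gets the multiplier."""
    rate = np.full(tree.n_nodes, sigma2, dtype=float)
    for anchor, mult in clade_rate_multipliers.items():
        tips = [anchor] if isinstance(anchor, str) else list(anchor)
        try:
            ids = [tree.tip_id(t) for t in tips]
        except Exception as exc:
            raise SimulationError(f"unknown clade anchor {anchor!r}") from exc
        node = ids[0]
        for j in ids[1:]:
            node = tree.mrca(node, j)
        if len(ids) == 1:
            node = int(tree.parent[node])
        stack = [node]
        while stack:
            v = stack.pop()
            rate[v] = sigma2 * mult
            stack.extend(tree.children[v])
    return rate


def simulate_bm_traits(
    tree: Tree,
    n_traits: int = 1,
    sigma2: float = 1.0,
    clade_rate_multipliers: dict | None = None,
    root_value: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Brownian traits evolved edge-by-edge: increments N(0, sigma^2 * l),
    with sigma^2 multiplied inside designated clades."""
    if rng is None:
        rng = np.random.default_rng()
    if tree.n_tips < 3:
        raise SimulationError("need at least 3 tips")
    rate = _edge_rates(tree, clade_rate_multipliers or {}, sigma2)
    cols = {}
    order = tree.preorder()
    for k in range(n_traits):
        val = np.zeros(tree.n_nodes)
        val[tree.root] = root_value
        for v in order:
            if v == tree.root:
                continue
            val[v] = val[tree.parent[v]] + rng.normal(
                0.0, np.sqrt(rate[v] * tree.lengths[v])
            )
        cols[f"trait{k + 1}"] = {tree.labels[t]: val[t] for t in tree.tips}
    return pd.DataFrame(cols).loc[tree.tip_labels]


# --------------------------------------------------------------- host use

def simulate_host_matrix(
    tree: Tree,
    n_families: int = 20,
    clustering: float = 0.6,
    prevalence: float = 0.25,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phylogenetically clustered binary host-use incidence.

    Per family, a latent score mixes a standardized Brownian component
    (evolved on the tree with pendant branches collapsed, so sister tips in
    a cherry share it exactly) with iid noise:
    z = sqrt(c) * B + sqrt(1-c) * eps.  Thresholding at the prevalence
    quantile gives the incidence; every species keeps at least one family.
    """
    if n_families < 2:
        raise SimulationError("need at least 2 host families")
    if not 0.0 <= clustering <= 1.0:
        raise SimulationError("clustering must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    n = tree.n_tips
    # tree with pendant branches zeroed: shared history only
    shared = tree.copy()
    for t in shared.tips:
        shared.lengths[t] = 0.0
    d = shared.depths()
    sd = np.array([max(np.sqrt(d[t]), 1e-12) for t in shared.tips])
    tau = float(stats.norm.ppf(1 - prevalence))
    inc = np.zeros((n, n_families), dtype=int)
    latent = np.zeros((n, n_families))
    for f in range(n_families):
        if clustering > 0:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b = simulate_bm_traits(shared, 1, 1.0, rng=rng).to_numpy()[:, 0] / sd
        else:
            b = np.zeros(n)
        z = np.sqrt(clustering) * b + np.sqrt(1 - clustering) * rng.standard_normal(n)
        latent[:, f] = z
        inc[:, f] = (z > tau).astype(int)
    for i in range(n):
        if inc[i].sum() == 0:
            inc[i, int(np.argmax(latent[i]))] = 1
    fams = [f"fam{j + 1:02d}" for j in range(n_families)]
    return pd.DataFrame(inc, index=tree.tip_labels, columns=fams)


# ------------------------------------------------------------ environment

def simulate_env_world(
    tree: Tree,
    grid_shape: tuple = (40, 60),
    n_env: int = 4,
    autocorr_cells: float = 4.0,
    occurrences_min: int = 10,
    occurrences_mean: int = 40,
    dispersal_scatter: float = 3.0,
    cell_size: float = 1.0 / 12.0,
    lon_min: float = -125.0,
    lat_min: float = 30.0,
    rng: np.random.Generator | None = None,
):
    """Autocorrelated environmental surfaces plus occurrence points.

    Surfaces are Gaussian random fields (kernel-smoothed white noise with
    smoothing length ``autocorr_cells``).  Species range centroids evolve by
    Brownian motion on the tree in (lon, lat); occurrences scatter around
    the centroid (sd ``dispersal_scatter`` cells) and are snapped to cell
    centers.  Returns (list of EnvGrid, occurrence DataFrame).
    """
    from .niche import EnvGrid

    if rng is None:
        rng = np.random.default_rng()
    nr, nc = grid_shape
    if nr < 10 or nc < 10:
        raise SimulationError("grid must be at least 10x10")
    grids = []
    for k in range(n_env):
        noise = rng.standard_normal((nr, nc))
        smooth = gaussian_filter(noise, sigma=autocorr_cells, mode="reflect")
        smooth = (smooth - smooth.mean()) / smooth.std()
        grids.append(EnvGrid(f"env{k + 1}", smooth, lon_min, lat_min, cell_size))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cent = simulate_bm_traits(tree, 2, 1.0, rng=rng)
    # map centroids into the middle 80% of the box
    rows = []
    g0 = grids[0]
    for dim, (lo, hi) in zip(
        cent.columns, [(g0.lon_min, g0.lon_max), (g0.lat_min, g0.lat_max)]
    ):
        v = cent[dim]
        span = hi - lo
        vmin, vmax = v.min(), v.max()
        scale = 0.8 * span / max(vmax - vmin, 1e-12)
        cent[dim] = lo + 0.1 * span + (v - vmin) * scale
    for sp in tree.tip_labels:
        n_occ = occurrences_min + rng.poisson(max(occurrences_mean - occurrences_min, 0))
        lon0, lat0 = cent.loc[sp, "trait1"], cent.loc[sp, "trait2"]
        for _ in range(n_occ):
            lon = lon0 + rng.normal(0, dispersal_scatter * cell_size)
            lat = lat0 + rng.normal(0, dispersal_scatter * cell_size)
            lon = float(np.clip(lon, g0.lon_min + cell_size / 2, g0.lon_max - cell_size / 2))
            lat = float(np.clip(lat, g0.lat_min + cell_size / 2, g0.lat_max - cell_size / 2))
            r, c = g0.cell_index(lon, lat)
            clon, clat = g0.cell_center(r, c)
            rows.append({"species": sp, "lon": clon, "lat": clat})
    return grids, pd.DataFrame(rows)


# -------------------------------------------------------------------- SEM

def simulate_sem(
    dag: CausalDAG,
    coefficients: dict,
    n: int,
    rng: np.random.Generator | int | None = None,
    exog_correlations: dict | None = None,
) -> pd.DataFrame:
    """Linear-Gaussian recursive system with unit-variance variables.

    ``coefficients`` maps edges (u, v) to the population *standardized*
    coefficient; residual variances are solved so every variable has exactly
    unit population variance.  Raises if the coefficients imply a negative
    residual variance.
    """
    if isinstance(rng, int) or rng is None:
        rng = np.random.default_rng(rng)
    for e in dag.edges:
        if tuple(e) not in coefficients:
            raise PathModelError(f"missing coefficient for edge {e}")
    exog_correlations = exog_correlations or {}
    order = dag.causal_order()
    cov = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    data = pd.DataFrame(index=pd.RangeIndex(n), columns=order, dtype=float)

    # exogenous block, possibly correlated
    exog = dag.exogenous
    Sig = np.eye(len(exog))
    for pr in dag.correlations:
        u, w = sorted(pr, key=order.index)
        r = float(exog_correlations.get((u, w), exog_correlations.get((w, u), 0.0)))
        i, j = exog.index(u), exog.index(w)
        Sig[i, j] = Sig[j, i] = r
        cov.loc[u, w] = cov.loc[w, u] = r
    L = np.linalg.cholesky(Sig)
    E = rng.standard_normal((n, len(exog))) @ L.T
    for j, v in enumerate(exog):
        data[v] = E[:, j]

    for v in order:
        pa = dag.parents(v)
        if not pa:
            continue
        b = np.array([coefficients[(u, v)] for u in pa])
        Spp = cov.loc[pa, pa].to_numpy()
        explained = float(b @ Spp @ b)
        resid = 1.0 - explained
        if resid < 0:
            raise PathModelError(
                f"coefficients for {v} imply negative residual variance ({resid:.3f})"
            )
        data[v] = data[pa].to_numpy() @ b + np.sqrt(resid) * rng.standard_normal(n)
        # update population covariances involving v
        for w in order:
            if w == v:
                continue
            cov.loc[v, w] = cov.loc[w, v] = float(
                b @ cov.loc[pa, w].to_numpy()
            )
        cov.loc[v, v] = 1.0
    return data


# --------------------------------------------------- end-to-end rate world

def simulate_rate_world(
    n_tips: int = 300,
    coefficients: tuple[float, float] = (0.7, 0.5),
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
):
    """Tree plus tip variables obeying env_rate -> host_rate -> speciation.

    The three variables evolve as coupled Brownian motions: per-edge
    increments satisfy the chain structurally (d_host = b1 d_env + noise,
    d_spec = b2 d_host + noise, all with per-unit-length unit variance), so
    the generating linear system holds *exactly* at the level of
    phylogenetic independent contrasts, with population standardized
    coefficients equal to ``coefficients``.  Returns (tree, trait table
    with columns env_rate / host_rate / speciation).
    """
    if rng is None:
        rng = component_rng(seed, "rate_world")
    b1, b2 = coefficients
    tree = simulate_tree(n_tips, birth, death, rng=rng)
    order = tree.preorder()
    env = np.zeros(tree.n_nodes)
    host = np.zeros(tree.n_nodes)
    spec = np.zeros(tree.n_nodes)
    for v in order:
        if v == tree.root:
            continue
        l = tree.lengths[v]
        p = tree.parent[v]
        de = rng.normal(0, np.sqrt(l))
        dh = b1 * de + np.sqrt(max(1 - b1**2, 0)) * rng.normal(0, np.sqrt(l))
        ds = b2 * dh + np.sqrt(max(1 - b2**2, 0)) * rng.normal(0, np.sqrt(l))
        env[v] = env[p] + de
        host[v] = host[p] + dh
        spec[v] = spec[p] + ds
    traits = pd.DataFrame(
        {
            "env_rate": {tree.labels[t]: env[t] for t in tree.tips},
            "host_rate": {tree.labels[t]: host[t] for t in tree.tips},
            "speciation": {tree.labels[t]: spec[t] for t in tree.tips},
        }
    ).loc[tree.tip_labels]
    return tree, traits


# ------------------------------------------------------------------ bundle

def write_bundle(cfg: SimConfig, outdir) -> dict:
    """Emit a complete synthetic input bundle (Newick tree, incidence TSV,
    occurrence TSV, grid files, truth JSON) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(
        cfg.n_tips, cfg.birth, cfg.death, rng=component_rng(cfg.seed, "tree")
    )
    traits = simulate_bm_traits(
        tree,
        cfg.n_traits,
        cfg.sigma2,
        cfg.clade_rate_multipliers,
        rng=component_rng(cfg.seed, "traits"),
    )
    hosts = simulate_host_matrix(
        tree,
        cfg.n_families,
        cfg.host_clustering,
        cfg.host_prevalence,
        rng=component_rng(cfg.seed, "hosts"),
    )
    grids, occ = simulate_env_world(
        tree,
        cfg.grid_shape,
        cfg.n_env,
        cfg.autocorr_cells,
        cfg.occurrences_min,
        cfg.occurrences_mean,
        cfg.dispersal_scatter,
        rng=component_rng(cfg.seed, "env"),
    )
    write_newick(tree, outdir / "tree.nwk")
    traits.rename_axis("species").to_csv(outdir / "traits.tsv", sep="\t")
    hosts.rename_axis("species").to_csv(outdir / "incidence.tsv", sep="\t")
    occ.to_csv(outdir / "occurrences.tsv", sep="\t", index=False)
    for g in grids:
        g.write(outdir)
    truth = asdict(cfg)
    truth["grid_names"] = [g.name for g in grids]
    truth["clade_rate_multipliers"] = {
        (k if isinstance(k, str) else "|".join(k)): v
        for k, v in cfg.clade_rate_multipliers.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return {"tree": tree, "traits": traits, "hosts": hosts, "grids": grids, "occ": occ}
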