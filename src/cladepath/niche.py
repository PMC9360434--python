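"""Host-use and environmental niche descriptors per species.

Host use enters as a binary species x plant-family incidence matrix, coded
efficiently via Jaccard distances and principal coordinates; host breadth is
Shannon's diversity index over the families a species uses.  The
environmental niche is summarized by masking gridded layers with each
species' occurrence points (mean and interquartile range per variable),
then reduced by PCA on the correlation matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "jaccard_distances",
    "pcoa",
    "pca",
    "shannon_breadth",
    "filter_min_occurrences",
    "EnvGrid",
    "extract_env",
    "summarize_env",
    "annualize",
    "summarize_categorical",
    "Ordination",
    "build_niche_table",
]


class NicheError(ValueError):
    pass


# ---------------------------------------------------------------- host use

def _check_incidence(m: pd.DataFrame) -> pd.DataFrame:
    m = m.astype(float)
    if not np.isin(m.to_numpy(), (0.0, 1.0)).all():
        raise NicheError("incidence matrix must be binary")
    if (m.sum(axis=1) == 0).any():
        bad = m.index[m.sum(axis=1) == 0].tolist()
        raise NicheError(f"species with no host family: {bad[:5]}")
    if m.index.has_duplicates or m.columns.has_duplicates:
        raise NicheError("duplicate species or family labels")
    return m


def jaccard_distances(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between species' host-family sets:
    d(i,j) = 1 - |A∩B| / |A∪B|."""
    m = _check_incidence(m)
    d = squareform(pdist(m.to_numpy(dtype=bool), metric="jaccard"))
    return pd.DataFrame(d, index=m.index, columns=m.index)


@dataclass
class Ordination:
    """Coordinates on k axes plus eigenvalues and variance fractions,
    ordered by decreasing eigenvalue."""

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.proportion_explained) > 1e-12):
            raise NicheError("variance fractions must be non-increasing")


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    # ordination axes are sign-ambiguous; make the largest-|.| entry positive
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def pcoa(d: pd.DataFrame, k: int = 2) -> Ordination:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -d^2/2 and eigendecomposes.  Axes with non-positive
    eigenvalues are discarded (no Cailliez/Lingoes correction); variance
    fractions are computed over the positive eigenvalues only.
    """
    D = np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise NicheError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0):
        raise NicheError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(np.abs(vals).max(), 1.0) * 1e-12
    npos = int(np.sum(vals > tol))
    if k > npos:
        raise NicheError(f"requested {k} axes but only {npos} positive eigenvalues")
    pos = vals[:npos]
    coords = _fix_signs(vecs[:, :k] * np.sqrt(vals[:k]))
    labels = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    return Ordination(
        pd.DataFrame(coords, index=labels, columns=[f"PCo{i+1}" for i in range(k)]),
        pos[:k],
        pos[:k] / pos.sum(),
    )


def pca(features: pd.DataFrame, k: int = 2) -> Ordination:
    """PCA on standardized variables (correlation matrix).

    Constant columns are dropped with a warning; scores are returned for the
    first k components with variance fractions relative to the full rank.
    """
    X = features.astype(float)
    if X.isna().any().any():
        raise NicheError("missing values in feature matrix")
    if len(X) < 2:
        raise NicheError("need at least 2 species for PCA")
    sd = X.std(ddof=1)
    const = sd.index[sd == 0].tolist()
    if const:
        warnings.warn(f"dropping constant columns: {const}", stacklevel=2)
        X = X.drop(columns=const)
        sd = sd.drop(const)
    if X.shape[1] == 0:
        raise NicheError("no non-constant variables")
    Z = (X - X.mean()) / sd
    full = min(Z.shape[0] - 1, Z.shape[1])
    if k > full:
        raise NicheError(f"k={k} exceeds rank {full}")
    p = _SkPCA(n_components=full, svd_solver="full").fit(Z)
    scores = _fix_signs(p.transform(Z)[:, :k])
    return Ordination(
        pd.DataFrame(scores, index=X.index, columns=[f"PC{i+1}" for i in range(k)]),
        p.explained_variance_[:k],
        p.explained_variance_ratio_[:k],
    )


def shannon_breadth(row) -> float:
    """Shannon's diversity index H = -sum p_i ln p_i (nats) over host-family
    usage; accepts incidences (equal weights) or counts."""
    x = np.asarray(row, dtype=float)
    if np.any(x < 0):
        raise NicheError("negative usage values")
    tot = x.sum()
    if tot <= 0:
        raise NicheError("all-zero usage vector")
    p = x[x > 0] / tot
    return float(-(p * np.log(p)).sum())


# ------------------------------------------------------------- occurrences

def filter_min_occurrences(occ: pd.DataFrame, n_min: int = 10) -> pd.DataFrame:
    """Keep species with >= n_min occurrence rows (the threshold is
    inclusive).  Expects columns species, lon, lat."""
    counts = occ.groupby("species").size()
    keep = counts.index[counts >= n_min]
    if len(keep) == 0:
        warnings.warn("no species passed the occurrence filter", stacklevel=2)
    return occ[occ["species"].isin(keep)].reset_index(drop=True)


# ----------------------------------------------------------------- grids

@dataclass
class EnvGrid:
    """Named 2-D layer with a geographic bounding box.

    Row 0 is the northern edge; ``cell_size`` is in degrees (5 arc-min =
    1/12 degree).  Missing cells are NaN.
    """

    name: str
    values: np.ndarray
    lon_min: float
    lat_min: float
    cell_size: float
    categorical: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise NicheError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise NicheError("cell size must be positive")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.values.shape[1] * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.values.shape[0] * self.cell_size

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        col = int(np.floor((lon - self.lon_min) / self.cell_size))
        row = int(np.floor((self.lat_max - lat) / self.cell_size))
        nr, nc = self.values.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise NicheError("point outside grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.lon_min + (col + 0.5) * self.cell_size,
            self.lat_max - (row + 0.5) * self.cell_size,
        )

    # -- plain-text + JSON sidecar I/O ---------------------------------
    def write(self, directory, stem: str | None = None) -> None:
        directory = Path(directory)
        stem = stem or self.name
        np.savetxt(directory / f"{stem}.txt", self.values, fmt="%.10g")
        meta = {
            "name": self.name,
            "lon_min": self.lon_min,
            "lat_min": self.lat_min,
            "cell_size": self.cell_size,
            "categorical": self.categorical,
            "missing": "nan",
        }
        (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, directory, stem: str) -> "EnvGrid":
        directory = Path(directory)
        meta = json.loads((directory / f"{stem}.json").read_text())
        values = np.loadtxt(directory / f"{stem}.txt", ndmin=2)
        return cls(
            meta.get("name", stem),
            values,
            meta["lon_min"],
            meta["lat_min"],
            meta["cell_size"],
            bool(meta.get("categorical", False)),
        )


def extract_env(occ: pd.DataFrame, grid: EnvGrid) -> dict[str, np.ndarray]:
    """Grid-cell values at each species' occurrence points.

    Points outside the bounding box and points landing on missing cells are
    dropped (with a warning for out-of-box points).  Raises if no point
    overlaps the grid at all.
    """
    out: dict[str, list[float]] = {}
    n_outside = 0
    n_inside = 0
    for sp, lon, lat in occ[["species", "lon", "lat"]].itertuples(index=False):
        try:
            r, c = grid.cell_index(float(lon), float(lat))
        except NicheError:
            n_outside += 1
            continue
        n_inside += 1
        v = grid.values[r, c]
        if np.isfinite(v):
            out.setdefault(sp, []).append(float(v))
    if n_inside == 0:
        raise NicheError(f"no occurrence point overlaps grid {grid.name!r}")
    if n_outside:
        warnings.warn(f"{n_outside} points outside grid {grid.name!r} dropped", stacklevel=2)
    return {sp: np.asarray(v) for sp, v in out.items()}


def summarize_env(values) -> tuple[float, float]:
    """(mean, interquartile range).  The range spans the 25th-75th quantiles
    (type-7 linear interpolation) rather than min-max, to resist outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise NicheError("empty value list")
    q25, q75 = np.quantile(v, [0.25, 0.75])
    return float(v.mean()), float(q75 - q25)


def summarize_categorical(values) -> tuple[float, int]:
    """(modal class, class richness) for categorical layers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise NicheError("empty value list")
    classes, counts = np.unique(v, return_counts=True)
    return float(classes[np.argmax(counts)]), int(len(classes))


def annualize(monthly: list[EnvGrid], how: str = "mean") -> EnvGrid:
    """Collapse monthly layers to an annual one: mean for intensive
    variables (temperature-like), sum for fluxes (precipitation-like)."""
    if not monthly:
        raise NicheError("no layers to annualize")
    stack = np.stack([g.values for g in monthly])
    if how == "mean":
        vals = np.nanmean(stack, axis=0)
    elif how == "sum":
        vals = np.nansum(stack, axis=0)
        vals[np.all(np.isnan(stack), axis=0)] = np.nan
    else:
        raise NicheError(f"unknown annualization rule {how!r}")
    g0 = monthly[0]
    return EnvGrid(g0.name, vals, g0.lon_min, g0.lat_min, g0.cell_size, g0.categorical)


# --------------------------------------------------------------- assembly

def build_niche_table(
    incidence: pd.DataFrame,
    occ: pd.DataFrame,
    grids: list[EnvGrid],
    *,
    n_min: int = 10,
    k_axes: int = 2,
) -> pd.DataFrame:
    """Per-species niche descriptors.

    Columns: host-use PCo axes, host breadth H, per-variable environmental
    mean and interquartile range, and environmental PC scores.  Species must
    pass the occurrence filter and appear in the incidence matrix.
    """
    occ = filter_min_occurrences(occ, n_min)
    species = sorted(set(occ["species"]) & set(incidence.index))
    if not species:
        raise NicheError("no species with both host and occurrence data")
    inc = incidence.loc[species]
    occ = occ[occ["species"].isin(species)]

    host_ord = pcoa(jaccard_distances(inc), k=k_axes)
    table = host_ord.coords.copy()
    table.columns = [f"host_{c.lower()}" for c in table.columns]
    table["host_breadth"] = [shannon_breadth(inc.loc[s]) for s in species]

    env_cols = {}
    for g in grids:
        vals = extract_env(occ, g)
        if g.categorical:
            mode_, rich = {}, {}
            for s in species:
                if s not in vals or len(vals[s]) == 0:
                    raise NicheError(f"no usable {g.name} values for {s}")
                mode_[s], rich[s] = summarize_categorical(vals[s])
            env_cols[f"{g.name}_mode"] = mode_
            env_cols[f"{g.name}_richness"] = rich
        else:
            means, iqrs = {}, {}
            for s in species:
                if s not in vals or len(vals[s]) == 0:
                    raise NicheError(f"no usable {g.name} values for {s}")
                means[s], iqrs[s] = summarize_env(vals[s])
            env_cols[f"{g.name}_mean"] = means
            env_cols[f"{g.name}_iqr"] = iqrs
    env = pd.DataFrame(env_cols).loc[species]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns possible on tiny grids
        env_ord = pca(env, k=min(k_axes, max(1, min(env.shape) - 1)))
    for i, c in enumerate(env_ord.coords.columns):
        table[f"env_pc{i+1}"] = env_ord.coords[c]
    for c in env.columns:
        table[c] = env[c]
    if table.isna().any().any():
        raise NicheError("missing entries in assembled niche table")
    return table
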