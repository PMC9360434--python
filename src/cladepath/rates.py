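"""Tip-level rate statistics on a rooted phylogeny.

Implements four quantities used to relate niche evolution to speciation:

* the DR statistic — an equal-splits speciation-rate index for each tip:
  the inverse of the root-path branch lengths, with each successively more
  rootward branch down-weighted by a factor of 1/2;
* maximum-likelihood ancestral states of a continuous trait under Brownian
  motion (equivalently, GLS / best linear unbiased prediction given the BM
  tip covariance);
* the TR statistic — a per-tip trait-rate index: the sum of between-node
  differences in reconstructed states along the tip-to-root path, with the
  tip's observed value as the terminal state;
* Felsenstein's phylogenetic independent contrasts (PICs).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .trees import Tree, TreeError, root_to_tip_path

__all__ = [
    "dr_statistic",
    "bm_ancestral_states",
    "tr_statistic",
    "pic",
    "resolve_polytomies",
    "tip_rate_table",
]


def dr_statistic(tree: Tree) -> pd.Series:
    """Equal-splits diversification-rate index per tip.

    DR_i = (sum_{j>=1} l_j 2^{-(j-1)})^{-1}, with j = 1 at the tip's own
    branch and increasing toward the root.  Units are inverse branch-length
    units (e.g. lineages per unit time on a time tree).
    """
    out = {}
    for tip in tree.tip_labels:
        s = 0.0
        for j, (length, _) in enumerate(root_to_tip_path(tree, tip)):
            s += length * 2.0 ** (-j)
        if s <= 0:
            raise TreeError(f"tip {tip!r} has zero weighted root-path length")
        out[tip] = 1.0 / s
    return pd.Series(out, name="dr")


def _regularized_covariance(tree: Tree, eps_scale: float = 1e-8):
    """BM tip covariance, with a tiny ridge if zero-length tips make it
    singular (epsilon = eps_scale x tree height)."""
    V = tree.tip_covariance()
    try:
        np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        V = V + np.eye(len(V)) * eps_scale * tree.height()
        warnings.warn("singular BM covariance; added epsilon ridge", stacklevel=3)
    return V


def bm_ancestral_states(tree: Tree, x: Mapping[str, float] | pd.Series) -> pd.Series:
    """ML internal-node states of a continuous trait under Brownian motion.

    The root state is the GLS mean (1'V^-1 1)^-1 1'V^-1 x with V the BM tip
    covariance; every other internal node's estimate is the conditional
    expectation given the tips, which coincides with the GLS root estimate of
    the tree re-rooted at that node.  Estimates are indexed by internal node
    id.
    """
    x = pd.Series(x)
    missing = [t for t in tree.tip_labels if t not in x.index]
    if missing:
        raise TreeError(f"trait values missing for tips: {missing[:5]}")
    xv = x.reindex(tree.tip_labels).to_numpy(dtype=float)
    if not np.all(np.isfinite(xv)):
        raise TreeError("non-finite trait values")

    V = _regularized_covariance(tree)
    ones = np.ones(len(xv))
    Vinv_x = np.linalg.solve(V, xv)
    Vinv_1 = np.linalg.solve(V, ones)
    mu = float(ones @ Vinv_x / (ones @ Vinv_1))
    resid_w = np.linalg.solve(V, xv - mu)

    d = tree.depths()
    pos = {t: k for k, t in enumerate(tree.tips)}
    # ancestor sets for MRCA-depth lookups
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    est = {}
    for a in internal:
        in_sub = set(tree.subtree_tips(a))
        anc_depth = {}
        v = a
        while True:
            anc_depth[v] = d[v]
            if v == tree.root:
                break
            v = int(tree.parent[v])
        c = np.empty(len(xv))
        for t in tree.tips:
            if t in in_sub:
                c[pos[t]] = d[a]
            else:
                u = int(tree.parent[t])
                while u not in anc_depth:
                    u = int(tree.parent[u])
                c[pos[t]] = anc_depth[u]
        est[a] = mu + float(c @ resid_w)
    return pd.Series(est, name=x.name)


def tr_statistic(
    tree: Tree,
    x: Mapping[str, float] | pd.Series,
    *,
    signed: bool = False,
    dr_weighting: bool = False,
    per_unit_depth: bool = False,
) -> pd.Series:
    """Trait-rate index per tip.

    Sums between-node differences in BM ancestral states along each tip's
    root path; the tip's own observed value is the child state of its
    pendant edge.  Differences are absolute by default (rates are
    non-negative); ``signed=True`` keeps the raw signed sum, ``dr_weighting``
    applies the DR-style 2^{-(j-1)} down-weighting, and ``per_unit_depth``
    divides by the tip's root-path length.
    """
    x = pd.Series(x)
    anc = bm_ancestral_states(tree, x)
    state = {v: anc[v] for v in anc.index}
    for t in tree.tips:
        state[t] = float(x[tree.labels[t]])
    d = tree.depths()
    out = {}
    for tip in tree.tip_labels:
        s = 0.0
        v = tree.tip_id(tip)
        j = 0
        while v != tree.root:
            p = int(tree.parent[v])
            diff = state[v] - state[p]
            if not signed:
                diff = abs(diff)
            s += diff * (2.0 ** (-j) if dr_weighting else 1.0)
            v = p
            j += 1
        if per_unit_depth:
            s /= d[tree.tip_id(tip)]
        out[tip] = s
    name = f"tr_{x.name}" if x.name else "tr"
    return pd.Series(out, name=name)


def resolve_polytomies(tree: Tree) -> Tree:
    """Binary version of the tree: polytomies resolved in input order with
    zero-length internal branches (ladderized toward the first children)."""
    if tree.is_binary():
        return tree
    warnings.warn("resolving polytomies with zero-length branches", stacklevel=2)
    parent = list(tree.parent)
    children = [list(c) for c in tree.children]
    lengths = list(tree.lengths)
    labels = list(tree.labels)
    for v in list(range(len(parent))):
        while len(children[v]) > 2:
            # pull the first two children under a new zero-length node
            a, b = children[v][0], children[v][1]
            i = len(parent)
            parent.append(v)
            children.append([a, b])
            lengths.append(0.0)
            labels.append(None)
            parent[a] = parent[b] = i
            children[v] = [i] + children[v][2:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-length branches are intended here
        return Tree(parent, children, lengths, labels)


def pic(tree: Tree, x: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Felsenstein's phylogenetic independent contrasts.

    Returns one row per internal node of the (binary-resolved) tree with the
    standardized contrast and the contrast variance (sum of the adjusted
    child branch lengths).  A binary n-tip tree yields n - 1 contrasts; under
    Brownian motion with rate sigma^2 they are iid N(0, sigma^2).
    """
    x = pd.Series(x)
    tree = resolve_polytomies(tree)
    missing = [t for t in tree.tip_labels if t not in x.index]
    if missing:
        raise TreeError(f"trait values missing for tips: {missing[:5]}")

    val = np.zeros(tree.n_nodes)
    bl = np.array(tree.lengths, dtype=float)
    rows = []
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            val[v] = float(x[tree.labels[v]])
            continue
        a, b = kids
        vsum = bl[a] + bl[b]
        if vsum <= 0:
            raise TreeError(f"zero combined branch length at node {v}")
        rows.append((v, (val[a] - val[b]) / np.sqrt(vsum), vsum))
        val[v] = (val[a] * bl[b] + val[b] * bl[a]) / vsum
        bl[v] = bl[v] + bl[a] * bl[b] / vsum
    df = pd.DataFrame(rows, columns=["node", "contrast", "contrast_var"])
    return df.set_index("node")


def tip_rate_table(
    tree: Tree,
    traits: pd.DataFrame | None = None,
    **tr_kwargs,
) -> pd.DataFrame:
    """Per-tip DR plus one TR column per trait column."""
    cols = [dr_statistic(tree)]
    if traits is not None:
        for c in traits.columns:
            cols.append(tr_statistic(tree, traits[c], **tr_kwargs))
    return pd.concat(cols, axis=1)
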