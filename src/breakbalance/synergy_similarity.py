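"""Similarity of chromatin context-dependency patterns between proteins.

A protein's CCD pattern is its vector of per-feature synergy scores (sparse:
non-significant entries are zero).  Pattern similarity is the cosine

    cos(A, B) = sum_i A_i B_i / (||A|| ||B||)

chosen because it behaves well on zero-inflated vectors.  Two uses:

* enrichment of similarity among physically interacting protein pairs
  (BioGRID-style edge lists), tested against the distribution of mean cosines
  of randomly drawn protein pairs;
* similarity of the same protein's pattern measured in two cell types, with a
  feature-eligibility rule for sparsely sampled reporter pools (a feature
  counts only if at least ``min_iprs`` reporters sit in it, z > 0.5).

Maximal cliques of the interaction graph identify complexes whose members
share CCD patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .indel_quant import ConfigurationError, ValidationError, logger


def cosine(a, b) -> float:
    """Cosine similarity of two synergy vectors; all-zero vectors are
    rejected (undefined direction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("synergy vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine undefined for an all-zero synergy vector")
    return float(a @ b / (na * nb))


def load_interaction_graph(edges: pd.DataFrame, proteins=None) -> nx.Graph:
    """Undirected interaction graph from an edge table (protein_a, protein_b,
    optional method).  Self-loops are dropped; when ``proteins`` is given the
    graph is induced on that set (proteins with significant CCDs)."""
    required = {"protein_a", "protein_b"}
    if not required <= set(edges.columns):
        raise ValidationError(f"edge table needs columns {sorted(required)}")
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = row.protein_a, row.protein_b
        if a == b:
            continue
        if proteins is not None and (a not in proteins or b not in proteins):
            continue
        method = getattr(row, "method", None)
        g.add_edge(a, b, method=method)
    return g


@dataclass
class SimilarityResult:
    """Interacting-pair similarity versus the random-pair null."""

    pair_scores: pd.DataFrame
    observed_mean: float
    null_means: np.ndarray
    z_vs_null: float
    p_two_sided: float
    n_pairs: int
    n_draws: int
    seed: int
    notes: dict = field(default_factory=dict)


def _pair_means(
    vectors: np.ndarray, n_pairs: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean cosine over ``n_pairs`` distinct random unordered pairs, repeated
    ``n_draws`` times.  Vectors are pre-normalized so a cosine is a dot."""
    n = vectors.shape[0]
    all_pairs = n * (n - 1) // 2
    if all_pairs < n_pairs:
        raise ConfigurationError(
            f"universe of {n} proteins has only {all_pairs} distinct pairs; "
            f"cannot draw {n_pairs}"
        )
    iu, ju = np.triu_indices(n, k=1)
    sims = vectors @ vectors.T
    flat = sims[iu, ju]
    means = np.empty(n_draws)
    for d in range(n_draws):
        idx = rng.choice(all_pairs, size=n_pairs, replace=False)
        means[d] = flat[idx].mean()
    return means


def interacting_pair_test(
    synergy: pd.DataFrame,
    graph: nx.Graph,
    n_draws: int = 1000,
    seed: int = 0,
) -> SimilarityResult:
    """Test whether interacting protein pairs have more similar CCD patterns
    than random pairs.

    The observed statistic is the mean cosine over graph edges; the null is
    the mean cosine of equally many random distinct pairs from the same
    protein universe (without replacement within a draw, self-pairs excluded,
    known-interacting pairs not excluded), repeated ``n_draws`` times.  The
    p-value comes from a Gaussian fit to the null means, which resolves tail
    probabilities below the 1/n_draws empirical granularity.
    """
    from scipy import stats

    edges = [(a, b) for a, b in graph.edges() if a in synergy.index and b in synergy.index]
    if not edges:
        raise ConfigurationError("interaction graph contributes no scorable edges")
    norms = np.linalg.norm(synergy.to_numpy(), axis=1)
    if (norms == 0).any():
        bad = synergy.index[norms == 0].tolist()
        raise ValidationError(f"all-zero synergy vectors: {bad}")
    unit = synergy.to_numpy() / norms[:, None]
    pos = {p: i for i, p in enumerate(synergy.index)}

    pair_scores = pd.DataFrame(
        [(a, b, float(unit[pos[a]] @ unit[pos[b]])) for a, b in edges],
        columns=["protein_a", "protein_b", "cosine"],
    )
    observed = float(pair_scores["cosine"].mean())

    rng = np.random.default_rng(seed)
    null_means = _pair_means(unit, len(edges), n_draws, rng)
    mu, sd = float(null_means.mean()), float(null_means.std(ddof=1))
    if sd == 0:
        z = 0.0
        p = 1.0 if observed == mu else 0.0
    else:
        z = (observed - mu) / sd
        p = float(2 * stats.norm.sf(abs(z)))
    return SimilarityResult(
        pair_scores=pair_scores,
        observed_mean=observed,
        null_means=null_means,
        z_vs_null=float(z),
        p_two_sided=p,
        n_pairs=len(edges),
        n_draws=n_draws,
        seed=seed,
    )


def find_cliques(graph: nx.Graph, min_size: int = 4) -> list[tuple[str, ...]]:
    """All maximal cliques of at least ``min_size`` proteins, each sorted by
    name, in deterministic overall order."""
    cliques = [tuple(sorted(c, key=str)) for c in nx.find_cliques(graph) if len(c) >= min_size]
    return sorted(cliques)


@dataclass
class CrossCellTypeResult:
    """Per-protein cross-cell-type similarity with its random-protein null."""

    scores: pd.Series
    features_used: list[str]
    observed_mean: float
    null_means: np.ndarray
    null_ci: tuple[float, float]
    n_draws: int
    seed: int


def eligible_features(
    cfm_b: pd.DataFrame, min_iprs: int = 2, z_cut: float = 0.5
) -> list[str]:
    """Features of cell type B sampled by at least ``min_iprs`` reporters
    embedded in them (standardized level above ``z_cut``)."""
    counts = (cfm_b > z_cut).sum(axis=0)
    return [f for f in cfm_b.columns if counts[f] >= min_iprs]


def cross_celltype_similarity(
    sm_a: pd.DataFrame,
    sm_b: pd.DataFrame,
    cfm_b: pd.DataFrame,
    min_iprs: int = 2,
    z_cut: float = 0.5,
    n_draws: int = 1000,
    seed: int = 0,
) -> CrossCellTypeResult:
    """Similarity of matched proteins' CCD patterns between cell types A and B.

    Features are restricted to those sufficiently sampled in B's reporter pool
    (:func:`eligible_features`) and shared with A's matrix.  The observed
    score per protein is the signed cosine of its two restricted vectors; the
    null redraws, per draw, a without-replacement random set of A proteins to
    stand in for the matched ones, and the 95% CI of the null mean is
    reported.
    """
    feats = [f for f in eligible_features(cfm_b, min_iprs, z_cut) if f in sm_a.columns]
    if not feats:
        raise ValidationError("no eligible shared features between cell types")
    matched = [p for p in sm_b.index if p in sm_a.index]
    if not matched:
        raise ValidationError("no matched proteins between the two synergy matrices")

    a = sm_a.loc[:, feats]
    b = sm_b.loc[matched, feats]
    usable = [
        p
        for p in matched
        if np.linalg.norm(a.loc[p]) > 0 and np.linalg.norm(b.loc[p]) > 0
    ]
    dropped = sorted(set(matched) - set(usable))
    if dropped:
        logger.info("proteins with zero restricted vectors skipped: %s", dropped)
    if not usable:
        raise ValidationError("all matched proteins have zero restricted vectors")
    scores = pd.Series(
        {p: cosine(a.loc[p], b.loc[p]) for p in usable}, name="cosine"
    )

    # null: random screen proteins paired with the tested proteins
    a_pool = a.index[np.linalg.norm(a.to_numpy(), axis=1) > 0]
    if len(a_pool) < len(usable):
        raise ConfigurationError("screen universe smaller than the matched set")
    rng = np.random.default_rng(seed)
    b_unit = b.loc[usable].to_numpy()
    b_unit = b_unit / np.linalg.norm(b_unit, axis=1)[:, None]
    a_all = a.loc[a_pool].to_numpy()
    a_all = a_all / np.linalg.norm(a_all, axis=1)[:, None]
    null_means = np.empty(n_draws)
    for d in range(n_draws):
        idx = rng.choice(len(a_pool), size=len(usable), replace=False)
        null_means[d] = float(np.mean(np.sum(a_all[idx] * b_unit, axis=1)))
    lo, hi = np.percentile(null_means, [2.5, 97.5])
    return CrossCellTypeResult(
        scores=scores,
        features_used=feats,
        observed_mean=float(scores.mean()),
        null_means=null_means,
        null_ci=(float(lo), float(hi)),
        n_draws=n_draws,
        seed=seed,
    )
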