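"""Chromatin context-dependency (CCD) detection by three-step linear modeling.

A protein has a CCD when its per-reporter delta log2 MMEJ:NHEJ scores
correlate with the chromatin features measured at the reporter integration
sites.  Detection proceeds in three steps:

1. *Any-effect pre-filter* — an omnibus sum of squared per-reporter z-scores
   against the mock-derived per-reporter null, chi-square reference, with a
   deliberately lenient BH cutoff (default 0.25) so step 2 controls the
   reported FDR.
2. *Principal component regression* — the protein's delta vector is regressed
   on the top principal components of the chromatin feature matrix (smallest
   number of PCs explaining >= 90% variance, capped well below the number of
   reporters to avoid saturated fits); the overall-model F-test p-value, BH
   corrected across proteins, is the CCD FDR (significant at < 0.05).
3. *Per-feature synergy scores* — for significant proteins only, the slope of
   the simple linear fit of delta against each standardized feature.  A
   positive slope (N-synergy) means the protein favors NHEJ where the feature
   is high; a negative slope (M-synergy) means it favors MMEJ there.  Slopes
   with p >= 0.05 are stored as exact zeros, so synergy vectors are sparse.

Mock samples are pushed through the identical pipeline as negative controls
and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .effect_screen import DeltaMatrix, benjamini_hochberg
from .indel_quant import ConfigurationError, ValidationError, logger

SYNERGY_M = "M"
SYNERGY_N = "N"
SYNERGY_MIXED = "mixed"
SYNERGY_NONE = "none"

LINK_BOTH = "global_and_ccd"
LINK_CCD_ONLY = "ccd_only"
LINK_GLOBAL_ONLY = "global_only"
LINK_NONE = "none"


@dataclass
class CcdParams:
    """Tunable thresholds of the three-step procedure."""

    step1_fdr: float = 0.25       # lenient any-effect pre-filter
    ccd_fdr: float = 0.05         # reported CCD significance (step 2)
    slope_p: float = 0.05         # per-feature slope retention (step 3)
    pc_variance: float = 0.90     # cumulative variance for PC count
    min_shared_iprs: int = 6


@dataclass
class CcdResults:
    """Per-protein CCD statistics and the synergy score matrix.

    ``table`` has one row per condition (protein, ccd_p, ccd_fdr, significant,
    synergy_class, is_mock); ``synergy`` / ``slopes`` / ``slope_p`` /
    ``intercepts`` are condition x feature matrices.  ``synergy`` holds the
    sparsified scores (non-significant cells are exact zeros); ``slopes``
    keeps the raw per-feature fits for diagnostics.
    """

    table: pd.DataFrame
    synergy: pd.DataFrame
    slopes: pd.DataFrame
    slope_p: pd.DataFrame
    intercepts: pd.DataFrame
    n_pcs: int = 0
    params: CcdParams = field(default_factory=CcdParams)


def standardize_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature across reporters (population sd).

    Rows are reporter barcodes, columns chromatin features.  Constant or
    missing-valued features are rejected by name.
    """
    if raw.shape[0] < 3:
        raise ValidationError("need >= 3 reporters to standardize features")
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValidationError(f"missing values in features: {bad}")
    sd = raw.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance features: {zero}")
    return (raw - raw.mean()) / sd


def _pca_scores(cfm: pd.DataFrame, variance: float, cap: int) -> np.ndarray:
    """Principal component scores of the feature matrix across reporters."""
    from sklearn.decomposition import PCA

    pca = PCA()
    scores = pca.fit_transform(cfm.to_numpy())
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance) + 1)
    k = max(1, min(k, cap))
    return scores[:, :k]


def _ftest_regression(y: np.ndarray, X: np.ndarray) -> float:
    """Overall F-test p of OLS y ~ 1 + X, robust at the perfect-fit and
    constant-response edges (p = 0 and p = 1 respectively)."""
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-300:
        return 1.0
    if ss_res <= 1e-12 * ss_tot:
        return 0.0
    df_resid = n - k - 1
    if df_resid <= 0:
        return 1.0
    f = ((ss_tot - ss_res) / k) / (ss_res / df_resid)
    return float(stats.f.sf(f, k, df_resid))


def _feature_fits(y: np.ndarray, cfm: np.ndarray):
    """Simple per-feature linear fits of y on each standardized feature.

    Returns (slopes, intercepts, two-sided p).  Perfect fits get p = 0,
    zero-variance responses slope 0 / p 1.
    """
    n, m = cfm.shape
    slopes = np.zeros(m)
    icepts = np.zeros(m)
    pvals = np.ones(m)
    y_c = y - y.mean()
    ss_y = float(y_c @ y_c)
    for j in range(m):
        x = cfm[:, j]
        x_c = x - x.mean()
        ss_x = float(x_c @ x_c)
        if ss_x == 0 or ss_y == 0:
            icepts[j] = y.mean()
            continue
        slope = float(x_c @ y_c) / ss_x
        slopes[j] = slope
        icepts[j] = y.mean() - slope * x.mean()
        r2 = slope**2 * ss_x / ss_y
        if r2 >= 1 - 1e-12:
            pvals[j] = 0.0
        else:
            t = slope * np.sqrt(ss_x) / np.sqrt((ss_y - slope**2 * ss_x) / (n - 2))
            pvals[j] = 2 * stats.t.sf(abs(t), n - 2)
    return slopes, icepts, pvals


def ccd_test(
    dm: DeltaMatrix,
    cfm: pd.DataFrame,
    mock_ids=None,
    params: CcdParams | None = None,
) -> CcdResults:
    """Run the three-step CCD procedure on a delta matrix.

    ``cfm`` is the standardized reporter x feature matrix.  Conditions sharing
    fewer than ``params.min_shared_iprs`` reporters with ``cfm`` are skipped
    with a log entry.  Mocks are analysed identically (their BH correction is
    applied within the mock set) and flagged ``is_mock``.
    """
    params = params or CcdParams()
    mock_ids = frozenset(mock_ids) if mock_ids is not None else dm.mock_ids
    mocks = dm.mock_rows()
    if len(mocks) < 2:
        raise ConfigurationError("need >= 2 mock rows for the per-reporter null")
    shared = [c for c in dm.delta.columns if c in cfm.index]
    if len(shared) < params.min_shared_iprs:
        raise ValidationError("too few reporters shared between deltas and features")
    cfm = cfm.loc[shared]
    delta = dm.delta[shared]
    mock_mu = mocks[shared].mean()
    mock_sd = mocks[shared].std(ddof=1)
    if (mock_sd == 0).any():
        raise ValidationError("per-reporter mock sd is zero for some reporter")

    n_ipr = len(shared)
    cap = max(1, n_ipr - 3)
    pc_all = _pca_scores(cfm, params.pc_variance, cap)
    n_pcs = pc_all.shape[1]

    records = []
    slope_rows: dict[str, np.ndarray] = {}
    p_rows: dict[str, np.ndarray] = {}
    icept_rows: dict[str, np.ndarray] = {}

    for cond, row in delta.iterrows():
        avail = row.notna().to_numpy()
        if avail.sum() < params.min_shared_iprs:
            logger.warning("condition %s skipped: only %d reporters", cond, avail.sum())
            continue
        y = row.to_numpy(dtype=float)[avail]
        z = (y - mock_mu.to_numpy()[avail]) / mock_sd.to_numpy()[avail]
        omnibus = float(z @ z)
        step1_p = float(stats.chi2.sf(omnibus, df=int(avail.sum())))

        k_eff = min(n_pcs, max(1, int(avail.sum()) - 3))
        step2_p = _ftest_regression(y, pc_all[avail][:, :k_eff])
        records.append(
            {
                "protein": cond,
                "is_mock": cond in mock_ids,
                "n_iprs": int(avail.sum()),
                "omnibus": omnibus,
                "step1_p": step1_p,
                "ccd_p": step2_p,
            }
        )
        slopes, icepts, pvals = _feature_fits(y, cfm.to_numpy()[avail])
        slope_rows[cond] = slopes
        p_rows[cond] = pvals
        icept_rows[cond] = icepts

    table = pd.DataFrame(records).set_index("protein")

    # Step 1 gate and step 2 BH within non-mocks; mocks corrected separately
    table["step1_fdr"] = np.nan
    table["ccd_fdr"] = np.nan
    for is_mock in (False, True):
        grp = table.index[table["is_mock"] == is_mock]
        if not len(grp):
            continue
        table.loc[grp, "step1_fdr"] = benjamini_hochberg(
            np.clip(table.loc[grp, "step1_p"].to_numpy(), 1e-300, 1.0)
        )
        passed = grp[table.loc[grp, "step1_fdr"] <= params.step1_fdr]
        if len(passed):
            table.loc[passed, "ccd_fdr"] = benjamini_hochberg(
                np.clip(table.loc[passed, "ccd_p"].to_numpy(), 1e-300, 1.0)
            )
    table["significant"] = table["ccd_fdr"] < params.ccd_fdr

    features = list(cfm.columns)
    synergy = pd.DataFrame(0.0, index=table.index, columns=features)
    slopes = pd.DataFrame(np.nan, index=table.index, columns=features)
    slope_p = pd.DataFrame(np.nan, index=table.index, columns=features)
    intercepts = pd.DataFrame(np.nan, index=table.index, columns=features)
    for cond in table.index:
        slopes.loc[cond] = slope_rows[cond]
        slope_p.loc[cond] = p_rows[cond]
        intercepts.loc[cond] = icept_rows[cond]
        if table.loc[cond, "significant"]:
            keep = p_rows[cond] < params.slope_p
            synergy.loc[cond, keep] = slope_rows[cond][keep]

    table["synergy_class"] = [
        classify_synergy(synergy.loc[c]) if table.loc[c, "significant"] else SYNERGY_NONE
        for c in table.index
    ]
    return CcdResults(
        table=table,
        synergy=synergy,
        slopes=slopes,
        slope_p=slope_p,
        intercepts=intercepts,
        n_pcs=n_pcs,
        params=params,
    )


def classify_synergy(scores) -> str:
    """M / N / mixed / none from the signs of the significant (nonzero) scores."""
    s = np.asarray(scores, dtype=float)
    neg, pos = (s < 0).any(), (s > 0).any()
    if neg and pos:
        return SYNERGY_MIXED
    if neg:
        return SYNERGY_M
    if pos:
        return SYNERGY_N
    return SYNERGY_NONE


def ccd_vs_global(ccd: CcdResults, glob: pd.DataFrame) -> pd.Series:
    """Joint label per protein from CCD and global-effect significance.

    ``glob`` is the output of :func:`effect_screen.global_effect_test`.
    Proteins present in only one result set are labeled with the available
    evidence and logged.
    """
    labels = {}
    ccd_sig = ccd.table["significant"]
    glob_sig = glob["direction"] != "none"
    universe = set(ccd_sig.index) | set(glob_sig.index)
    for prot in sorted(universe, key=str):
        c = bool(ccd_sig.get(prot, False))
        g = bool(glob_sig.get(prot, False))
        if prot not in ccd_sig.index or prot not in glob_sig.index:
            logger.warning("protein %s present in only one result set", prot)
        if c and g:
            labels[prot] = LINK_BOTH
        elif c:
            labels[prot] = LINK_CCD_ONLY
        elif g:
            labels[prot] = LINK_GLOBAL_ONLY
        else:
            labels[prot] = LINK_NONE
    return pd.Series(labels, name="global_link")


def estimate_feature_delta(
    ccd: CcdResults, protein: str, feature: str, level_z: float = 1.0
) -> float:
    """Estimated delta log2 MMEJ:NHEJ at a feature level of ``level_z``
    standard deviations above the reporter mean (default +1), from the step-3
    fit: intercept + slope * level_z."""
    if feature not in ccd.synergy.columns or protein not in ccd.synergy.index:
        raise KeyError(f"no stored fit for ({protein!r}, {feature!r})")
    slope = float(ccd.synergy.loc[protein, feature])
    intercept = float(ccd.intercepts.loc[protein, feature])
    return intercept + slope * level_z


def cluster_synergies(
    synergy: pd.DataFrame, n_clusters: int = 3
) -> tuple[list[str], pd.Series]:
    """Agglomerative clustering of protein synergy vectors.

    Euclidean distance, average linkage; rows are sorted by protein name
    before linkage so ties resolve deterministically.  Returns the dendrogram
    leaf order and cluster labels at ``n_clusters``.
    """
    from scipy.cluster import hierarchy

    if synergy.shape[0] < 2:
        raise ValidationError("need >= 2 proteins to cluster")
    sm = synergy.sort_index(key=lambda idx: idx.map(str))
    link = hierarchy.linkage(sm.to_numpy(), method="average", metric="euclidean")
    order = [sm.index[i] for i in hierarchy.leaves_list(link)]
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return order, pd.Series(labels, index=sm.index, name="cluster")
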