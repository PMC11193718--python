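"""Knockout-screen effect statistics on the MMEJ:NHEJ balance.

The screen measures, per knockout and reporter, the change in log2 MMEJ:NHEJ
balance relative to the average of mock-KO controls (samples processed without
a gene-targeting guide).  Delta scores are computed per replicate against the
replicate's own mock mean, so replicate-wide batch shifts cancel, and then
averaged over replicates.  A protein's *global* effect is the mean delta over
reporters; it is tested against the empirical null formed by the mock samples'
global scores (z-test), with Benjamini-Hochberg control across proteins.
Inhibitor experiments, which have a single vehicle control per replicate, use
a two-sample t-test across replicates instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .indel_quant import (
    ConfigurationError,
    ValidationError,
    annotate_samples,
    balance_table,
    logger,
    spectra_from_frame,
)

FAVORS_MMEJ = "favors_MMEJ"
FAVORS_NHEJ = "favors_NHEJ"
NO_DIRECTION = "none"


@dataclass
class DeltaMatrix:
    """Condition x reporter matrix of delta log2 MMEJ:NHEJ scores.

    ``delta`` rows are conditions (mock samples included), columns reporter
    barcodes; cells are replicate-averaged deltas, NaN where the reporter was
    filtered out in that condition.  ``support`` holds the number of
    replicates behind each cell.
    """

    delta: pd.DataFrame
    support: pd.DataFrame
    mock_ids: frozenset = field(default_factory=frozenset)

    @property
    def conditions(self) -> list[str]:
        return list(self.delta.index)

    @property
    def iprs(self) -> list[str]:
        return list(self.delta.columns)

    def mock_rows(self) -> pd.DataFrame:
        return self.delta.loc[self.delta.index.isin(self.mock_ids)]

    def non_mock_rows(self) -> pd.DataFrame:
        return self.delta.loc[~self.delta.index.isin(self.mock_ids)]

    def to_tsv(self, path) -> None:
        self.delta.to_csv(path, sep="\t", index_label="condition")


def screen_balance(
    counts: pd.DataFrame, samples: pd.DataFrame, min_reads_per_class: int = 1
) -> pd.DataFrame:
    """Balance records, annotated with the sample sheet, from a long indel
    count table (convenience wrapper over the quantification module)."""
    balance = balance_table(spectra_from_frame(counts), min_reads_per_class)
    return annotate_samples(balance, samples)


def delta_scores(
    balance: pd.DataFrame,
    mock_ids,
    condition_col: str = "condition",
    replicate_col: str = "replicate",
) -> DeltaMatrix:
    """Delta log2 MMEJ:NHEJ per condition and reporter, mock-centred.

    For each replicate and reporter, delta = balance(condition) minus the mean
    balance of the mock conditions in the same replicate; the cell value is
    the unweighted mean of per-replicate deltas.  Mock rows are retained and
    centred against the same mock mean, so per-reporter mock deltas average to
    zero.  Reporters absent from all mocks of a replicate yield missing cells
    (logged).  Cells supported by fewer than 2 replicates are kept but the
    support matrix flags them.
    """
    mock_ids = frozenset(mock_ids)
    if len(mock_ids & set(balance[condition_col])) < 2:
        raise ConfigurationError("need at least 2 mock conditions in the balance table")

    pivot = balance.pivot_table(
        index=[condition_col, replicate_col],
        columns="ipr_barcode",
        values="log2_mmej_nhej",
        aggfunc="mean",
    )
    is_mock = pivot.index.get_level_values(condition_col).isin(mock_ids)
    mock_mean = pivot[is_mock].groupby(level=replicate_col).mean()

    deltas = pivot.subtract(
        mock_mean.reindex(pivot.index.get_level_values(replicate_col)).to_numpy()
    )
    n_missing_null = int(
        (pivot.notna() & deltas.isna()).to_numpy().sum()
    )
    if n_missing_null:
        logger.warning(
            "%d condition cells dropped: reporter absent from all mocks of the replicate",
            n_missing_null,
        )
    delta = deltas.groupby(level=condition_col).mean()
    support = deltas.notna().groupby(level=condition_col).sum().astype(int)
    low = (support.to_numpy() < 2) & (support.to_numpy() > 0)
    if low.any():
        logger.info("%d delta cells supported by a single replicate", int(low.sum()))
    return DeltaMatrix(delta=delta, support=support, mock_ids=mock_ids)


def global_effect_test(
    dm: DeltaMatrix, mock_ids=None, fdr_threshold: float = 0.001
) -> pd.DataFrame:
    """Per-protein global effect z-test against the empirical mock null.

    The global score is the mean delta over available reporters.  The null
    mean and standard deviation come from the mock samples' global scores (the
    33 mocks give a stable empirical null); two-sided normal p-values are BH
    corrected across non-mock proteins.  A knockout lowering the MMEJ:NHEJ
    ratio (negative score) marks a protein that favors MMEJ.
    """
    mock_ids = frozenset(mock_ids) if mock_ids is not None else dm.mock_ids
    scores = dm.delta.mean(axis=1, skipna=True)
    mock_scores = scores[scores.index.isin(mock_ids)].dropna()
    if len(mock_scores) < 2:
        raise ConfigurationError("need >= 2 mock global scores for the null")
    mu, sd = float(mock_scores.mean()), float(mock_scores.std(ddof=1))
    if sd == 0:
        raise ValidationError("mock global scores have zero variance (degenerate null)")

    out = pd.DataFrame({"global_score": scores})
    out["z"] = (out["global_score"] - mu) / sd
    out["p"] = 2 * stats.norm.sf(np.abs(out["z"]))
    out["is_mock"] = out.index.isin(mock_ids)

    tested = out.loc[~out["is_mock"] & out["p"].notna()]
    out["fdr"] = np.nan
    if len(tested):
        # extreme z-scores underflow to p = 0; clip for the BH step
        out.loc[tested.index, "fdr"] = benjamini_hochberg(
            np.clip(tested["p"].to_numpy(), 1e-300, 1.0)
        )
    significant = out["fdr"] < fdr_threshold
    out["direction"] = NO_DIRECTION
    out.loc[significant & (out["global_score"] < 0), "direction"] = FAVORS_MMEJ
    out.loc[significant & (out["global_score"] > 0), "direction"] = FAVORS_NHEJ
    out.index.name = "protein"
    return out


def global_effect_ttest(condition_scores, control_scores) -> tuple[float, float]:
    """Two-sided two-sample t-test of per-replicate global scores.

    Used for inhibitor experiments where each replicate has a single vehicle
    control sample.  Returns (p, effect) with effect = mean difference.  With
    zero variance in both groups and a nonzero difference the p-value
    degenerates to 0.0 (logged); identical groups give p = 1.
    """
    cond = np.asarray(condition_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    if len(cond) < 2 or len(ctrl) < 2:
        raise ValidationError("t-test needs >= 2 replicates per group")
    effect = float(cond.mean() - ctrl.mean())
    if cond.std(ddof=1) == 0 and ctrl.std(ddof=1) == 0:
        if effect == 0:
            return 1.0, effect
        logger.warning("degenerate t-test: zero variance with nonzero difference; p -> 0")
        return 0.0, effect
    t, p = stats.ttest_ind(cond, ctrl, equal_var=True)
    return float(p), effect


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
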