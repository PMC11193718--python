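"""Chromatin-compartment-dependent repair-signature shifts in tumor genomes.

Somatic deletions carry pathway signatures: a deletion longer than 5 bp with
at least 2 bp of junctional microhomology is attributed to MMEJ, one longer
than 5 bp with no microhomology to error-prone NHEJ (1 bp of microhomology is
ambiguous and left unclassified).  Constitutive lamina-associated domains
(cLADs) proxy heterochromatin, constitutive inter-LADs (ciLADs) euchromatin;
a deletion counts toward a compartment only when fully contained in one
labeled interval.

For a gene of interest (GOI), case tumors (single-GOI loss-of-function
driver, no confounding repair deficiency or treatment signature, >= 500
substitutions) are compared with tissue-matched controls: per cancer subtype,
signature counts are summed over samples (Eq. of pooled counts), the Het/Eu
balance shift

    delta = log2(MMEJ_Het/NHEJ_Het) - log2(MMEJ_Eu/NHEJ_Eu)

is z-scored against a 1000-draw bootstrap of the controls, subtype z-scores
are combined per GOI by Stouffer's method (Z = sum z / sqrt(k)), and GOIs are
called at Benjamini-Hochberg adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .effect_screen import benjamini_hochberg
from .indel_quant import ConfigurationError, ValidationError, logger

MMEJ_SIG = "MMEJ_sig"
NHEJ_SIG = "NHEJ_sig"
UNCLASSIFIED = "unclassified"

HET = "Het"  # cLAD
EU = "Eu"    # ciLAD
NEITHER = "neither"

COUNT_COLS = ["mmej_het", "nhej_het", "mmej_eu", "nhej_eu"]

# genes of interest: repair proteins with significant screen CCDs that are
# recurrently lost in tumors, plus full BRCA1/BRCA2 deficiency
DEFAULT_GOIS = (
    "ATM", "ATR", "ATRX", "BLM", "CHEK2", "EGFR", "FANCD2", "FANCF", "FANCM",
    "HELQ", "INO80E", "L3MBTL2", "MEN1", "PARG", "RAD17", "SETD2", "SMC5",
    "TRRAP", "USP", "XRCC1", "BRCA1", "BRCA2",
)

MIN_CASES_TOTAL = 5
MIN_CASES_SUBTYPE = 3
MIN_CONTROLS = 5
MIN_SUBSTITUTIONS = 500

LONG_MH_SIZE_LO = 1400     # 1.4 kb
LONG_MH_SIZE_HI = 272900   # 272.9 kb (95% interval of MH-deletion sizes)


# ---------------------------------------------------------------------------
# microhomology and deletion classification
# ---------------------------------------------------------------------------

def _fetch(ref, chrom: str, start: int, end: int) -> str:
    """Reference slice [start, end) from a mapping of sequences or a pyfaidx /
    pysam-style accessor.  Out-of-range coordinates are an error."""
    start, end = int(start), int(end)
    if start < 0:
        raise ValidationError(f"negative coordinate {start} on {chrom}")
    if hasattr(ref, "fetch"):  # pysam.FastaFile
        seq = ref.fetch(chrom, start, end)
    else:  # dict of strings or pyfaidx.Fasta
        record = ref[chrom]
        seq = record[start:end]
        seq = getattr(seq, "seq", seq)
    return str(seq).upper()


def _seq_len(ref, chrom: str) -> int:
    if hasattr(ref, "get_reference_length"):
        return ref.get_reference_length(chrom)
    return len(ref[chrom])


def compute_microhomology(ref, chrom: str, start: int, end: int) -> int:
    """Junctional microhomology length of the deletion [start, end).

    The maximum of the right-side homology (longest common prefix of the
    deleted sequence and the downstream flank) and the left-side homology
    (longest common suffix of the deleted sequence and the upstream flank),
    capped at the deletion length.
    """
    if end <= start:
        raise ValidationError(f"empty deletion [{start}, {end})")
    clen = _seq_len(ref, chrom)
    if end > clen:
        raise ValidationError(f"deletion [{start}, {end}) outside {chrom} (len {clen})")
    L = end - start
    deleted = _fetch(ref, chrom, start, end)
    down = _fetch(ref, chrom, end, min(end + L, clen))
    up = _fetch(ref, chrom, max(start - L, 0), start)

    m_right = 0
    for a, b in zip(deleted, down):
        if a != b:
            break
        m_right += 1
    m_left = 0
    for a, b in zip(reversed(deleted), reversed(up)):
        if a != b:
            break
        m_left += 1
    return min(max(m_left, m_right), L)


def classify_deletion(length: int, mh_len: int) -> str:
    """MMEJ signature: > 5 bp with >= 2 bp microhomology; NHEJ signature:
    > 5 bp with none.  Everything else (short deletions, 1 bp microhomology)
    is unclassified and never enters compartment counts."""
    if length < 1 or mh_len < 0:
        raise ValidationError("length must be >= 1 and mh_len >= 0")
    if length > 5 and mh_len >= 2:
        return MMEJ_SIG
    if length > 5 and mh_len == 0:
        return NHEJ_SIG
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

class LadIndex:
    """Containment lookup over labeled cLAD/ciLAD intervals (0-based
    half-open, non-overlapping within each label)."""

    LABELS = {"cLAD": HET, "ciLAD": EU}

    def __init__(self, intervals: pd.DataFrame):
        missing = {"chrom", "start", "end", "label"} - set(intervals.columns)
        if missing:
            raise ValidationError(f"LAD table missing columns: {sorted(missing)}")
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for row in intervals.itertuples(index=False):
            if row.label not in self.LABELS:
                raise ValidationError(f"unknown LAD label {row.label!r}")
            if row.end <= row.start:
                raise ValidationError(f"empty interval {row.chrom}:{row.start}-{row.end}")
            key = (row.chrom, row.label)
            self._trees.setdefault(key, IntervalTree()).addi(int(row.start), int(row.end))

    @classmethod
    def from_bed(cls, path) -> "LadIndex":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValidationError(f"BED line {ln}: need 4 columns, got {len(parts)}")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
                except ValueError as exc:
                    raise ValidationError(f"BED line {ln}: {exc}") from exc
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))

    def assign(self, chrom: str, start: int, end: int) -> str:
        """Het / Eu when [start, end) is fully contained in a cLAD / ciLAD;
        neither otherwise (including boundary-spanning deletions)."""
        for label, compartment in self.LABELS.items():
            tree = self._trees.get((chrom, label))
            if tree is None:
                continue
            for iv in tree[start]:
                if iv.begin <= start and end <= iv.end:
                    return compartment
        return NEITHER


def assign_compartment(deletion, lads: LadIndex) -> str:
    """Compartment of one deletion record (any object with chrom/start/end)."""
    return lads.assign(deletion.chrom, int(deletion.start), int(deletion.end))


# ---------------------------------------------------------------------------
# deletion table I/O and annotation
# ---------------------------------------------------------------------------

def read_deletions_tsv(path) -> pd.DataFrame:
    """Deletion table TSV: sample_id, chrom, start, end (0-based half-open),
    optional mh_len."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = {"sample_id", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ValidationError(f"deletion table missing columns: {sorted(missing)}")
    if (df["end"] <= df["start"]).any():
        raise ValidationError("deletion table has rows with end <= start")
    return df


def read_deletions_vcf(path, sample_id: str | None = None) -> pd.DataFrame:
    """Deletions from a VCF; the 1-based anchor-base convention is converted
    to 0-based half-open coordinates (REF 'GACGT' -> ALT 'G' at POS p deletes
    [p, p+4))."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    default_sample = sample_id or (vcf.samples[0] if vcf.samples else "sample")
    rows = []
    for var in vcf:  # POS is the 1-based position of the first REF base
        for alt in var.ALT or []:
            if len(var.REF) > len(alt) and var.REF.startswith(alt):
                start0 = (var.POS - 1) + len(alt)  # deleted bases follow the anchor
                end0 = (var.POS - 1) + len(var.REF)
                rows.append((default_sample, var.CHROM, start0, end0))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])


def annotate_deletions(
    dels: pd.DataFrame, lads: LadIndex, ref=None
) -> pd.DataFrame:
    """Add length, mh_len (computed from ``ref`` when absent), signature class
    and compartment columns to a deletion table."""
    out = dels.copy()
    out["length"] = out["end"] - out["start"]
    if "mh_len" not in out.columns or out["mh_len"].isna().any():
        if ref is None:
            raise ConfigurationError(
                "mh_len absent from the deletion table and no reference given"
            )
        out["mh_len"] = [
            compute_microhomology(ref, r.chrom, r.start, r.end)
            for r in out.itertuples(index=False)
        ]
    out["mh_len"] = out["mh_len"].astype(int)
    out["class"] = [
        classify_deletion(int(l), int(m)) for l, m in zip(out["length"], out["mh_len"])
    ]
    out["compartment"] = [
        lads.assign(r.chrom, int(r.start), int(r.end)) for r in out.itertuples(index=False)
    ]
    return out


# ---------------------------------------------------------------------------
# sample selection (filters I-IV)
# ---------------------------------------------------------------------------

def _gene_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    s = str(value).strip()
    return {g for g in s.split(",") if g} if s else set()


def filter_samples(
    meta: pd.DataFrame, goi: str, gois=DEFAULT_GOIS,
    min_substitutions: int = MIN_SUBSTITUTIONS,
) -> pd.DataFrame:
    """Assign case/control/excluded roles for one GOI.

    Requires columns: sample_id, cancer_subtype, dataset, driver_lof_genes
    (comma-separated LOF driver genes among the GOIs), driver_genes (any
    driver among the GOIs), other_repair_deficiency, mutagenic_signature,
    n_substitutions.  A case carries a LOF driver in exactly one GOI (the
    target), passes the deficiency/signature/substitution filters; a control
    passes the same filters with no GOI driver of any kind.
    """
    required = {
        "sample_id", "cancer_subtype", "dataset", "driver_lof_genes",
        "driver_genes", "other_repair_deficiency", "mutagenic_signature",
        "n_substitutions",
    }
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"sample metadata missing columns: {sorted(missing)}")
    gois = set(gois)
    out = meta.copy()
    roles = []
    for row in out.itertuples(index=False):
        clean = (
            not bool(row.other_repair_deficiency)
            and not bool(row.mutagenic_signature)
            and int(row.n_substitutions) >= min_substitutions
        )
        lof = _gene_set(row.driver_lof_genes) & gois
        anyd = (_gene_set(row.driver_genes) | lof) & gois
        if clean and lof == {goi} and len(anyd) == 1:
            roles.append("case")
        elif clean and not anyd:
            roles.append("control")
        else:
            roles.append("excluded")
    out["role"] = roles
    return out


def eligible_gois(meta: pd.DataFrame, gois=DEFAULT_GOIS) -> list[str]:
    """GOIs with at least 5 case samples overall of which 3 share a cancer
    subtype."""
    selected = []
    for goi in gois:
        roles = filter_samples(meta, goi, gois)
        cases = roles[roles["role"] == "case"]
        if len(cases) >= MIN_CASES_TOTAL and (
            cases.groupby("cancer_subtype").size() >= MIN_CASES_SUBTYPE
        ).any():
            selected.append(goi)
    return selected


# ---------------------------------------------------------------------------
# counts and statistics
# ---------------------------------------------------------------------------

def sample_count_matrix(annotated: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Per-sample signature counts by compartment (columns mmej_het, nhej_het,
    mmej_eu, nhej_eu); samples without classified deletions get zero rows."""
    keep = annotated[
        annotated["class"].isin([MMEJ_SIG, NHEJ_SIG])
        & annotated["compartment"].isin([HET, EU])
    ]
    table = (
        keep.groupby(["sample_id", "class", "compartment"]).size().unstack(["class", "compartment"], fill_value=0)
    )
    out = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"), columns=COUNT_COLS)
    mapping = {
        (MMEJ_SIG, HET): "mmej_het",
        (NHEJ_SIG, HET): "nhej_het",
        (MMEJ_SIG, EU): "mmej_eu",
        (NHEJ_SIG, EU): "nhej_eu",
    }
    for key, col in mapping.items():
        if key in table.columns:
            shared = table.index.intersection(out.index)
            out.loc[shared, col] = table.loc[shared, key]
    return out


def aggregate_counts(counts: pd.DataFrame) -> np.ndarray:
    """Pooled signature counts over a sample group (sum of per-sample
    counts)."""
    return counts[COUNT_COLS].to_numpy().sum(axis=0)


def het_eu_stat(counts) -> tuple[float, bool]:
    """Het/Eu pathway-balance shift from pooled counts.

    Returns (delta, corrected): delta = log2(MMEJ_Het/NHEJ_Het) -
    log2(MMEJ_Eu/NHEJ_Eu).  When any of the four counts is zero, 0.5 is added
    to all four (continuity correction, flagged); all four zero is an error.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (4,):
        raise ValidationError("expected 4 pooled counts (mmej/nhej x het/eu)")
    if (c == 0).all():
        raise ValidationError("all four compartment counts are zero")
    corrected = bool((c == 0).any())
    if corrected:
        c = c + 0.5
    return float(np.log2(c[0] / c[1]) - np.log2(c[2] / c[3])), corrected


def _het_eu_stat_rows(c: np.ndarray) -> np.ndarray:
    """Vectorized Het/Eu statistic over rows of pooled counts with per-row
    continuity correction."""
    c = c.astype(float)
    zero = (c == 0).any(axis=1)
    c[zero] += 0.5
    return np.log2(c[:, 0] / c[:, 1]) - np.log2(c[:, 2] / c[:, 3])


@dataclass
class CompartmentStat:
    """Bootstrap-calibrated Het/Eu shift of one GOI-subtype stratum."""

    goi: str
    cancer_subtype: str
    dataset: str
    n_cases: int
    n_controls: int
    delta_het_eu: float
    corrected: bool
    bootstrap_mean: float
    bootstrap_sd: float
    z_case: float


def bootstrap_z(
    case_counts: pd.DataFrame,
    control_counts: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    goi: str = "",
    cancer_subtype: str = "",
    dataset: str = "",
) -> CompartmentStat:
    """Z-score the pooled case Het/Eu shift against a control bootstrap.

    Each bootstrap draw resamples as many control samples (with replacement)
    as there are cases, re-pools counts and recomputes the statistic, so the
    bootstrap distribution is the null of a case-sized pool drawn from the
    controls; z_case is the case statistic standardized by the bootstrap mean
    and sd.  Degenerate controls (sd 0) are an error.
    """
    if len(control_counts) < MIN_CONTROLS:
        raise ConfigurationError(
            f"need >= {MIN_CONTROLS} control samples, got {len(control_counts)}"
        )
    case_total = aggregate_counts(case_counts)
    delta, corrected = het_eu_stat(case_total)

    ctrl = control_counts[COUNT_COLS].to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ctrl), size=(n_boot, len(case_counts)))
    pooled = ctrl[idx].sum(axis=1)  # (n_boot, 4)
    if (pooled == 0).all(axis=1).any():
        raise ValidationError("a bootstrap draw pooled zero counts in all classes")
    boot = _het_eu_stat_rows(pooled)
    mu, sd = float(boot.mean()), float(boot.std(ddof=1))
    if sd == 0:
        raise ValidationError("bootstrap sd is zero (degenerate controls)")
    return CompartmentStat(
        goi=goi,
        cancer_subtype=cancer_subtype,
        dataset=dataset,
        n_cases=len(case_counts),
        n_controls=len(control_counts),
        delta_het_eu=delta,
        corrected=corrected,
        bootstrap_mean=mu,
        bootstrap_sd=sd,
        z_case=(delta - mu) / sd,
    )


def stouffer(z_scores) -> tuple[float, float]:
    """Stouffer-combined Z over subtypes (Z = sum z / sqrt(k)) and its
    two-sided normal p-value."""
    z = np.asarray(list(z_scores), dtype=float)
    if z.size == 0:
        raise ValidationError("no z-scores to combine")
    Z = float(z.sum() / np.sqrt(z.size))
    return Z, float(2 * stats.norm.sf(abs(Z)))


def analyze_cohort(
    dels: pd.DataFrame,
    meta: pd.DataFrame,
    lads: LadIndex,
    gois=None,
    ref=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full tumor analysis: annotate deletions, select GOIs, compute
    per-stratum bootstrap z-scores and per-GOI Stouffer-combined, BH-adjusted
    results.

    Strata are (cancer_subtype, dataset) pairs — datasets of one subtype stay
    separate because their baseline balances differ.  Strata lacking cases,
    enough controls, or nonzero counts are skipped with a log entry.  Returns
    (per-stratum table, per-GOI table with p_adj and significance at 0.05).
    """
    annotated = annotate_deletions(dels, lads, ref=ref)
    gois = list(gois) if gois is not None else eligible_gois(meta)
    counts_all = sample_count_matrix(annotated, meta["sample_id"])

    strata_rows: list[CompartmentStat] = []
    goi_rows = []
    rng = np.random.default_rng(seed)
    for goi in gois:
        roles = filter_samples(meta, goi)
        zs = []
        for (subtype, dataset), grp in roles.groupby(["cancer_subtype", "dataset"]):
            case_ids = grp.loc[grp["role"] == "case", "sample_id"]
            ctrl_ids = grp.loc[grp["role"] == "control", "sample_id"]
            if len(case_ids) == 0 or len(ctrl_ids) < MIN_CONTROLS:
                continue
            try:
                st = bootstrap_z(
                    counts_all.loc[case_ids],
                    counts_all.loc[ctrl_ids],
                    n_boot=n_boot,
                    seed=int(rng.integers(2**31)),
                    goi=goi,
                    cancer_subtype=subtype,
                    dataset=dataset,
                )
            except (ValidationError, ConfigurationError) as exc:
                logger.warning("stratum (%s, %s, %s) skipped: %s", goi, subtype, dataset, exc)
                continue
            strata_rows.append(st)
            zs.append(st.z_case)
        if zs:
            Z, p = stouffer(zs)
            goi_rows.append({"goi": goi, "k": len(zs), "Z": Z, "p": p})
        else:
            logger.warning("GOI %s has no analyzable strata", goi)

    strata_df = pd.DataFrame([s.__dict__ for s in strata_rows])
    goi_df = pd.DataFrame(goi_rows)
    if len(goi_df):
        goi_df["p_adj"] = benjamini_hochberg(np.clip(goi_df["p"].to_numpy(), 1e-300, 1.0))
        goi_df["significant"] = goi_df["p_adj"] < 0.05
    return strata_df, goi_df


def long_mh_deletions(
    sv: pd.DataFrame,
    lads: LadIndex,
    case_samples,
    control_samples,
    size_lo: int = LONG_MH_SIZE_LO,
    size_hi: int = LONG_MH_SIZE_HI,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare the Het/Eu distribution of long microhomology-assisted
    deletions (mh >= 2 bp, size within [size_lo, size_hi], fully contained in
    a labeled compartment) between two cohorts.

    The statistic is log2(Het count / Eu count) per cohort (0.5 added to both
    when either is zero); the case cohort is z-scored against a bootstrap of
    case-cohort-sized pools of the control cohort's samples.
    """
    sv = sv.copy()
    sv["length"] = sv["end"] - sv["start"]
    keep = sv[(sv["mh_len"] >= 2) & (sv["length"] >= size_lo) & (sv["length"] <= size_hi)].copy()
    keep["compartment"] = [
        lads.assign(r.chrom, int(r.start), int(r.end)) for r in keep.itertuples(index=False)
    ]
    keep = keep[keep["compartment"].isin([HET, EU])]

    def per_sample(samples) -> pd.DataFrame:
        sub = keep[keep["sample_id"].isin(samples)]
        tab = sub.groupby(["sample_id", "compartment"]).size().unstack(fill_value=0)
        out = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=[HET, EU])
        for col in (HET, EU):
            if col in tab.columns:
                shared = tab.index.intersection(out.index)
                out.loc[shared, col] = tab.loc[shared, col]
        return out

    def log_ratio(c: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(c).astype(float)
        zero = (c == 0).any(axis=1)
        c[zero] += 0.5
        return np.log2(c[:, 0] / c[:, 1])

    case_counts = per_sample(list(case_samples))
    ctrl_counts = per_sample(list(control_samples))
    if len(ctrl_counts) < MIN_CONTROLS:
        raise ConfigurationError(f"need >= {MIN_CONTROLS} control samples")
    case_total = case_counts.to_numpy().sum(axis=0)
    if case_total.sum() == 0:
        raise ValidationError("case cohort has no qualifying long MH deletions")
    observed = float(log_ratio(case_total)[0])

    rng = np.random.default_rng(seed)
    ctrl = ctrl_counts.to_numpy()
    idx = rng.integers(0, len(ctrl), size=(n_boot, len(case_counts)))
    boot = log_ratio(ctrl[idx].sum(axis=1))
    mu, sd = float(boot.mean()), float(boot.std(ddof=1))
    if sd == 0:
        raise ValidationError("bootstrap sd is zero (degenerate controls)")
    z = (observed - mu) / sd
    return {
        "case_het": int(case_total[0]),
        "case_eu": int(case_total[1]),
        "control_het": int(ctrl.sum(axis=0)[0]),
        "control_eu": int(ctrl.sum(axis=0)[1]),
        "log2_het_eu_case": observed,
        "bootstrap_mean": mu,
        "bootstrap_sd": sd,
        "z_case": float(z),
        "p": float(2 * stats.norm.sf(abs(z))),
    }
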