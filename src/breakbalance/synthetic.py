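"""Synthetic screens and tumor cohorts with planted ground truth.

The generators reproduce the statistical structure the analysis modules
assume, so every stage of the pipeline can be exercised and calibrated
without external data:

* a reporter x feature chromatin matrix organised in four chromatin states
  (euchromatin; triple heterochromatin = H3K9me2/3 + late replication +
  LMNB1; H3K27me3 heterochromatin; other), with block-correlated features;
* indel count tables for a knockout screen with planted global effects
  (gamma, log2 units) and per-feature synergies (beta, log2 units per
  feature sd), mock controls, replicates, and negative-binomial read depth;
* error-free amplicon reads realizing a given indel spectrum exactly;
* tumor deletion cohorts with compartment-dependent MMEJ/NHEJ rates over an
  alternating cLAD/ciLAD genome model.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indel_quant import (
    MMEJ_DEL,
    NHEJ_INS,
    ConfigurationError,
    IndelSpectrum,
    ReporterReference,
    ValidationError,
)
from . import tumor_ccd

OTHER_DEL = -2  # lumped non-signature indel class

STATE_EU = "euchromatin"
STATE_TRIPLE = "triple_heterochromatin"
STATE_K27 = "H3K27me3_heterochromatin"
STATE_OTHER = "other"
STATES = (STATE_EU, STATE_TRIPLE, STATE_K27, STATE_OTHER)
HET_STATES = {STATE_TRIPLE, STATE_K27}

# 25 K562-style chromatin features grouped by the state they define
FEATURE_BLOCKS: dict[str, str] = {
    **{
        f: STATE_EU
        for f in (
            "H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K9ac", "H4K5acK8ac",
            "H2AFZ", "DNAse", "TTseq", "POL2", "POL2S2", "H3K36me3",
        )
    },
    **{f: STATE_TRIPLE for f in ("H3K9me2", "H3K9me3", "LMNB1", "late_replication")},
    **{f: STATE_K27 for f in ("H3K27me3", "EZH2")},
    **{
        f: STATE_OTHER
        for f in ("H3K79me2", "H4K20me1", "m5C", "SMC3", "CTCF", "HDAC1", "HDAC2")
    },
}
K562_FEATURES = tuple(FEATURE_BLOCKS)


def sim_chromatin(
    n_ipr: int = 19, seed: int = 0, features=K562_FEATURES
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardized reporter x feature matrix plus per-reporter state labels.

    Reporters cycle through the four chromatin states; features of a state's
    defining block are elevated in that state and share a block-level latent
    term, giving within-block correlations around 0.8.  Columns are z-scored
    (population sd).
    """
    if n_ipr < 6:
        raise ConfigurationError("need >= 6 reporters to populate all four states")
    rng = np.random.default_rng(seed)
    iprs = [f"IPR{i + 1:02d}" for i in range(n_ipr)]
    states = pd.Series([STATES[i % 4] for i in range(n_ipr)], index=iprs, name="state")

    block_latent = {s: rng.normal(size=n_ipr) for s in STATES}
    data = {}
    for feat in features:
        block = FEATURE_BLOCKS.get(feat, STATE_OTHER)
        elevated = (states == block).to_numpy().astype(float)
        data[feat] = 1.5 * elevated + block_latent[block] + 0.5 * rng.normal(size=n_ipr)
    cfm = pd.DataFrame(data, index=iprs)
    cfm = (cfm - cfm.mean()) / cfm.std(ddof=0)
    return cfm, states


@dataclass
class ScreenTruth:
    """Planted parameters of one simulated knockout screen."""

    chromatin: pd.DataFrame
    states: pd.Series
    global_effects: pd.Series            # gamma per condition, 0 for mocks
    synergies: pd.DataFrame              # beta per condition x feature, 0 for mocks
    baseline_logit: pd.Series            # per-reporter logit of the MMEJ odds
    read_depth_mean: float = 3000.0
    dispersion: float = 0.2              # NB overdispersion: var = mu + a mu^2
    n_replicates: int = 3
    other_frac: float = 0.2
    intact_frac: float = 0.3
    seed: int = 0
    mock_ids: frozenset = field(default_factory=frozenset)


def make_screen_truth(
    n_proteins: int = 519,
    n_mock: int = 33,
    n_ipr: int = 19,
    n_replicates: int = 3,
    read_depth_mean: float = 3000.0,
    dispersion: float = 0.2,
    global_effects: dict | None = None,
    synergies: dict | None = None,
    seed: int = 0,
) -> ScreenTruth:
    """Assemble a screen truth record mirroring the study design defaults
    (519 targeted proteins, 33 mocks, 19 reporters, 3 replicates, ~3000
    reads per reporter).

    ``global_effects`` maps protein -> gamma (log2 units); ``synergies`` maps
    protein -> {feature: beta}.  Unmentioned proteins and all mocks have zero
    effects.  The baseline MMEJ logit is 0.5 higher in heterochromatin
    states, mirroring the higher MMEJ:NHEJ ratio observed there.
    """
    cfm, states = sim_chromatin(n_ipr=n_ipr, seed=seed)
    proteins = [f"P{i + 1:03d}" for i in range(n_proteins)]
    mocks = [f"mock{i + 1:02d}" for i in range(n_mock)]
    conditions = proteins + mocks

    gamma = pd.Series(0.0, index=conditions)
    for prot, g in (global_effects or {}).items():
        if prot not in gamma.index:
            raise ConfigurationError(f"unknown protein {prot!r} in global_effects")
        gamma[prot] = g
    beta = pd.DataFrame(0.0, index=conditions, columns=cfm.columns)
    for prot, fx in (synergies or {}).items():
        for feat, b in fx.items():
            beta.loc[prot, feat] = b
    if (gamma[mocks] != 0).any() or (beta.loc[mocks] != 0).any().any():
        raise ConfigurationError("mock conditions must have zero planted effects")

    baseline = pd.Series(
        [0.5 if states[i] in HET_STATES else 0.0 for i in cfm.index], index=cfm.index
    )
    return ScreenTruth(
        chromatin=cfm,
        states=states,
        global_effects=gamma,
        synergies=beta,
        baseline_logit=baseline,
        read_depth_mean=read_depth_mean,
        dispersion=dispersion,
        n_replicates=n_replicates,
        seed=seed,
        mock_ids=frozenset(mocks),
    )


def sim_screen(truth: ScreenTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate indel count tables for a screen truth record.

    Per (condition, replicate, reporter): total reads are negative binomial
    (mean ``read_depth_mean``, dispersion ``dispersion``); fixed fractions go
    to the lumped 'other' and intact classes, and the remaining signature
    reads split between the -7 (MMEJ) and +1 (NHEJ) classes with MMEJ
    probability logistic(baseline + gamma + beta . features).  Returns
    (long count table, sample sheet); sample ids are ``condition__r<rep>``.
    """
    sig_frac = 1.0 - truth.other_frac - truth.intact_frac
    if not (0 < sig_frac <= 1) or truth.other_frac < 0 or truth.intact_frac < 0:
        raise ConfigurationError("other/intact fractions must be in [0,1) and sum < 1")
    rng = np.random.default_rng(truth.seed)
    cfm = truth.chromatin
    conditions = list(truth.global_effects.index)
    n_cond, n_ipr = len(conditions), len(cfm)

    # MMEJ probability per condition x reporter.  gamma/beta are in log2
    # units of the MMEJ:NHEJ ratio; since log2(p/(1-p)) = logit(p)/ln 2, a
    # planted effect of gamma shifts the natural-log odds by gamma * ln 2 and
    # the recovered delta log2 MMEJ:NHEJ equals gamma exactly.
    logit = truth.baseline_logit.to_numpy()[None, :] + np.log(2.0) * (
        truth.global_effects.to_numpy()[:, None]
        + truth.synergies.to_numpy() @ cfm.to_numpy().T
    )
    p_mmej = 1.0 / (1.0 + np.exp(-logit))

    a = truth.dispersion
    mu = truth.read_depth_mean
    frames = []
    sizes = np.array([MMEJ_DEL, NHEJ_INS, OTHER_DEL, 0])
    for rep in range(1, truth.n_replicates + 1):
        if a > 0:
            totals = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mu), size=(n_cond, n_ipr))
        else:
            totals = rng.poisson(mu, size=(n_cond, n_ipr))
        pvals = np.empty((n_cond, n_ipr, 4))
        pvals[..., 0] = sig_frac * p_mmej
        pvals[..., 1] = sig_frac * (1.0 - p_mmej)
        pvals[..., 2] = truth.other_frac
        pvals[..., 3] = truth.intact_frac
        counts = rng.multinomial(totals, pvals)  # (n_cond, n_ipr, 4)
        frame = pd.DataFrame(
            {
                "sample_id": np.repeat(
                    [f"{c}__r{rep}" for c in conditions], n_ipr * 4
                ),
                "ipr_barcode": np.tile(np.repeat(cfm.index.to_numpy(), 4), n_cond),
                "indel_size": np.tile(sizes, n_cond * n_ipr),
                "count": counts.reshape(-1),
            }
        )
        frames.append(frame)
    counts_df = pd.concat(frames, ignore_index=True)
    counts_df = counts_df[counts_df["count"] > 0].reset_index(drop=True)

    samples = pd.DataFrame(
        [
            {
                "sample_id": f"{c}__r{rep}",
                "condition": c,
                "replicate": rep,
                "cell_line": "synthetic",
            }
            for rep in range(1, truth.n_replicates + 1)
            for c in conditions
        ]
    )
    return counts_df, samples


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

#: anchors use G/T alphabet and the variable region A/C, so edits in the
#: break window can never create spurious anchor matches
SIM_REFERENCE = ReporterReference(
    upstream_anchor="GGTTGGTTGG",
    barcode_length=8,
    left_anchor="GTGGTGGTGG",
    right_anchor="TGGTTGTTGG",
    reference_gap=20,
    dialect="original",
)


def make_barcodes(n: int, length: int = 8, seed: int = 0, min_dist: int = 3) -> list[str]:
    """Random A/C barcodes with pairwise Hamming distance >= ``min_dist`` so
    the one-mismatch demultiplexer resolves them uniquely."""
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise ConfigurationError("cannot place barcodes at the requested distance")
        cand = "".join(rng.choice(["A", "C"], size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_dist for bc in barcodes):
            barcodes.append(cand)
    return barcodes


def _gap_sequence(gap: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(["A", "C"], size=gap))


def sim_reads(
    spectrum: IndelSpectrum,
    ref: ReporterReference = SIM_REFERENCE,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Error-free reads realizing ``spectrum`` exactly, as (read_id, sequence)
    pairs ready for FASTQ output.

    Deletions remove bases from the centre of the break window, insertions
    add A/C bases there; an indel size exceeding the window is an error.
    """
    rng = np.random.default_rng(seed)
    gap = ref.effective_gap
    template_gap = _gap_sequence(gap, rng)
    reads = []
    i = 0
    for size, n in sorted(spectrum.counts.items()):
        if size < 0 and -size > gap:
            raise ValidationError(f"deletion of {-size} nt exceeds the {gap} nt window")
        if size >= 0:
            mid = gap // 2
            window = template_gap[:mid] + "".join(rng.choice(["A", "C"], size=size)) + template_gap[mid:]
        else:
            keep = gap + size
            left = keep // 2
            window = template_gap[:left] + template_gap[gap - (keep - left):]
        seq = (
            ref.upstream_anchor
            + spectrum.ipr_barcode
            + ref.left_anchor
            + window
            + ref.right_anchor
        )
        for _ in range(n):
            reads.append((f"{spectrum.sample_id}:{spectrum.ipr_barcode}:{i}", seq))
            i += 1
    return reads


def write_fastq(reads, path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# tumor cohorts
# ---------------------------------------------------------------------------

@dataclass
class TumorTruth:
    """Planted parameters of one simulated tumor cohort.

    ``control_means`` are the expected per-sample deletion counts per
    (compartment, class); ``case_effect`` multiplies those rates for cases.
    The genome model alternates cLAD/ciLAD intervals on one chromosome.
    """

    n_cases: int = 10
    n_controls: int = 30
    control_means: dict = field(
        default_factory=lambda: {
            ("Het", "MMEJ"): 30.0,
            ("Het", "NHEJ"): 15.0,
            ("Eu", "MMEJ"): 15.0,
            ("Eu", "NHEJ"): 30.0,
        }
    )
    case_effect: dict = field(default_factory=dict)  # (compartment, class) -> factor
    goi: str = "ATM"
    cancer_subtype: str = "synthA"
    dataset: str = "ds1"
    n_intervals_per_label: int = 10
    interval_length: int = 1_000_000
    seed: int = 0


def _lad_model(truth: TumorTruth) -> pd.DataFrame:
    rows = []
    pos = 0
    for i in range(truth.n_intervals_per_label):
        for label in ("cLAD", "ciLAD"):
            rows.append(("chr1", pos, pos + truth.interval_length, label))
            pos += truth.interval_length
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def sim_tumors(
    truth: TumorTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (deletion table, sample metadata, LAD intervals).

    Per sample, compartment and class, deletion counts are Poisson with the
    control mean times the case effect (cases only); positions are uniform
    and fully contained within a compartment interval; MMEJ-class deletions
    get microhomology >= 2 and NHEJ-class exactly 0, both with length > 5.
    Metadata satisfies the case/control filters by construction.
    """
    if truth.interval_length <= 0:
        raise ConfigurationError("interval_length must be positive")
    rng = np.random.default_rng(truth.seed)
    lads = _lad_model(truth)
    intervals = {
        "Het": lads[lads["label"] == "cLAD"].reset_index(drop=True),
        "Eu": lads[lads["label"] == "ciLAD"].reset_index(drop=True),
    }

    samples = [(f"case{i + 1:03d}", True) for i in range(truth.n_cases)] + [
        (f"ctrl{i + 1:03d}", False) for i in range(truth.n_controls)
    ]
    del_rows = []
    for sample_id, is_case in samples:
        for (compartment, cls), mean in truth.control_means.items():
            rate = mean * (truth.case_effect.get((compartment, cls), 1.0) if is_case else 1.0)
            n = rng.poisson(rate)
            if n == 0:
                continue
            ivs = intervals[compartment]
            lengths = 6 + rng.poisson(6, size=n)
            mh = (
                2 + rng.geometric(0.5, size=n) - 1
                if cls == "MMEJ"
                else np.zeros(n, dtype=int)
            )
            which = rng.integers(0, len(ivs), size=n)
            iv_start = ivs["start"].to_numpy()[which]
            iv_end = ivs["end"].to_numpy()[which]
            starts = rng.integers(iv_start, iv_end - lengths)
            for j in range(n):
                del_rows.append(
                    (sample_id, "chr1", int(starts[j]), int(starts[j] + lengths[j]), int(mh[j]))
                )
    dels = pd.DataFrame(
        del_rows, columns=["sample_id", "chrom", "start", "end", "mh_len"]
    )

    meta = pd.DataFrame(
        {
            "sample_id": [s for s, _ in samples],
            "cancer_subtype": truth.cancer_subtype,
            "dataset": truth.dataset,
            "driver_lof_genes": [truth.goi if c else "" for _, c in samples],
            "driver_genes": [truth.goi if c else "" for _, c in samples],
            "other_repair_deficiency": False,
            "mutagenic_signature": False,
            "n_substitutions": 1000,
        }
    )
    return dels, meta, lads


def tumor_lad_index(lads: pd.DataFrame) -> "tumor_ccd.LadIndex":
    """LadIndex over a simulated LAD interval table."""
    return tumor_ccd.LadIndex(lads)
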