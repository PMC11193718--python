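"""Indel spectrum quantification for barcoded integrated pathway reporters (IPRs).

Each IPR is a barcoded reporter inserted at a mapped genomic site. After Cas9
cutting and repair, amplicon reads over the break site carry characteristic
indels: a +1 insertion is the NHEJ signature (``NHEJ_ins``), a -7 deletion the
MMEJ signature (``MMEJ_del``).  The MMEJ:NHEJ balance of one reporter in one
sample is ``log2(counts[-7] / counts[+1])``.

Reads are assigned to reporters by barcode (at most one mismatch, unique hit)
and scored by the spacing between two constant anchor sequences flanking the
break-site window; the indel size is the observed spacing minus the reference
spacing.  All coordinates are read-local.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger("breakbalance")

NHEJ_INS = 1   # +1 insertion, NHEJ signature indel
MMEJ_DEL = -7  # -7 deletion, MMEJ signature indel

_ACGT = set("ACGT")

# extra constant-region length of the v2 reporter relative to the original
V2_EXTRA_NT = 8


class ConfigurationError(ValueError):
    """Invalid analysis configuration (thresholds, whitelists, references)."""


class ValidationError(ValueError):
    """Malformed input data."""


@dataclass(frozen=True)
class ReporterReference:
    """Constant-sequence layout of the reporter amplicon.

    The read layout is::

        [upstream_anchor][barcode][...][left_anchor][break window][right_anchor]

    ``reference_gap`` is the unedited distance (nt) between the end of
    ``left_anchor`` and the start of ``right_anchor``.  The ``v2`` dialect
    reporter carries an extra 8 nt in its constant region, shifting reference
    coordinates by exactly that amount.
    """

    upstream_anchor: str
    barcode_length: int
    left_anchor: str
    right_anchor: str
    reference_gap: int
    dialect: str = "original"

    def __post_init__(self) -> None:
        for name in ("upstream_anchor", "left_anchor", "right_anchor"):
            seq = getattr(self, name)
            if not seq or not set(seq) <= _ACGT:
                raise ConfigurationError(
                    f"{name} must be nonempty uppercase ACGT, got {seq!r}"
                )
        if self.barcode_length <= 0:
            raise ConfigurationError("barcode_length must be > 0")
        if self.reference_gap < 0:
            raise ConfigurationError("reference_gap must be >= 0")
        if self.dialect not in ("original", "v2"):
            raise ConfigurationError(f"unknown dialect {self.dialect!r}")

    @property
    def effective_gap(self) -> int:
        """Reference anchor spacing, including the v2 8-nt offset."""
        return self.reference_gap + (V2_EXTRA_NT if self.dialect == "v2" else 0)


@dataclass
class IndelSpectrum:
    """Per (sample, IPR) counts of indel classes; key 0 is the intact read."""

    sample_id: str
    ipr_barcode: str
    counts: dict[int, int] = field(default_factory=dict)
    unassigned: int = 0

    def add(self, indel_size: int, n: int = 1) -> None:
        self.counts[indel_size] = self.counts.get(indel_size, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def nhej_reads(self) -> int:
        return self.counts.get(NHEJ_INS, 0)

    @property
    def mmej_reads(self) -> int:
        return self.counts.get(MMEJ_DEL, 0)

    def validate(self) -> None:
        for size, n in self.counts.items():
            if n < 0:
                raise ValidationError(
                    f"negative count {n} for indel size {size} "
                    f"({self.sample_id}, {self.ipr_barcode})"
                )


@dataclass
class BalanceRecord:
    """MMEJ:NHEJ balance of one reporter in one sample.

    ``log2_mmej_nhej`` is defined only when both signature classes have reads;
    ``ipr_frequency`` is the fraction of the sample's assigned reads carried by
    this reporter.
    """

    sample_id: str
    ipr_barcode: str
    log2_mmej_nhej: float
    mmej_reads: int
    nhej_reads: int
    total_reads: int
    ipr_frequency: float


@dataclass
class CallResult:
    """Output of :func:`call_indels`: spectra per barcode plus reads whose
    barcode could not be resolved at all (no whitelist hit or ambiguous)."""

    spectra: dict[str, IndelSpectrum]
    unassigned_barcode: int = 0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_barcode(observed: str, whitelist: Iterable[str]) -> str | None:
    """Unique whitelist barcode within one mismatch of ``observed``, else None."""
    hits = [bc for bc in whitelist if len(bc) == len(observed) and _hamming(bc, observed) <= 1]
    if len(hits) == 1:
        return hits[0]
    return None


def _iter_sequences(reads) -> Iterator[str]:
    """Yield uppercase read sequences from a FASTQ path, an open handle, or an
    iterable of sequence strings / SeqRecords."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        from Bio import SeqIO

        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq).upper()
        return
    for item in reads:
        if isinstance(item, str):
            yield item.upper()
        else:  # SeqRecord or Seq
            yield str(getattr(item, "seq", item)).upper()


def call_indels(
    reads,
    ref: ReporterReference,
    barcode_whitelist: Iterable[str],
    sample_id: str = "sample",
) -> CallResult:
    """Assign reads to reporters and score indel sizes by anchor spacing.

    A read is scanned for ``upstream_anchor``; the ``barcode_length`` bases
    after it are matched against the whitelist (<=1 mismatch, unique hit
    required).  The indel size is the observed distance between ``left_anchor``
    and ``right_anchor`` minus the reference spacing.  Reads with an unmatched
    or ambiguous barcode are counted in ``unassigned_barcode``; reads whose
    anchors are missing or out of order are counted in the spectrum's
    ``unassigned``.  Short or malformed reads never raise.
    """
    whitelist = list(barcode_whitelist)
    if not whitelist:
        raise ConfigurationError("barcode whitelist is empty")
    result = CallResult(spectra={bc: IndelSpectrum(sample_id, bc) for bc in whitelist})

    for seq in _iter_sequences(reads):
        up = seq.find(ref.upstream_anchor)
        if up < 0:
            result.unassigned_barcode += 1
            continue
        bc_start = up + len(ref.upstream_anchor)
        observed_bc = seq[bc_start : bc_start + ref.barcode_length]
        if len(observed_bc) < ref.barcode_length:
            result.unassigned_barcode += 1
            continue
        barcode = _match_barcode(observed_bc, whitelist)
        if barcode is None:
            result.unassigned_barcode += 1
            continue
        spectrum = result.spectra[barcode]

        left = seq.find(ref.left_anchor, bc_start + ref.barcode_length)
        if left < 0:
            spectrum.unassigned += 1
            continue
        gap_start = left + len(ref.left_anchor)
        right = seq.find(ref.right_anchor, gap_start)
        if right < 0:
            spectrum.unassigned += 1
            continue
        spectrum.add(right - gap_start - ref.effective_gap)

    # reporters never observed stay present with empty counts; callers may drop
    return result


def read_count_table(path) -> list[IndelSpectrum]:
    """Load spectra from a TSV with columns sample_id, ipr_barcode, indel_size,
    count.  Duplicate (sample, barcode, size) rows are summed."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ipr_barcode": str})
    return spectra_from_frame(df)


def spectra_from_frame(df: pd.DataFrame) -> list[IndelSpectrum]:
    """Reconstruct spectra from a long count DataFrame (same columns as the
    TSV count table)."""
    required = {"sample_id", "ipr_barcode", "indel_size", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"count table missing columns: {sorted(missing)}")
    spectra: dict[tuple[str, str], IndelSpectrum] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        size, count = row.indel_size, row.count
        if float(size) != int(size):
            raise ValidationError(f"non-integer indel size {size!r} in row {i}")
        if float(count) != int(count) or int(count) < 0:
            raise ValidationError(f"invalid count {count!r} in row {i}")
        key = (row.sample_id, row.ipr_barcode)
        spectra.setdefault(key, IndelSpectrum(*key)).add(int(size), int(count))
    return list(spectra.values())


def write_count_table(spectra: Iterable[IndelSpectrum], path) -> None:
    """Write spectra in the TSV layout read by :func:`read_count_table`."""
    rows = [
        (s.sample_id, s.ipr_barcode, size, n)
        for s in spectra
        for size, n in sorted(s.counts.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "ipr_barcode", "indel_size", "count"]).to_csv(
        path, sep="\t", index=False
    )


def compute_balance(
    spectrum: IndelSpectrum, min_reads_per_class: int = 1
) -> BalanceRecord | None:
    """log2 MMEJ:NHEJ balance of one spectrum, or None when either signature
    class has fewer than ``min_reads_per_class`` reads.

    The default threshold is 1 read; the RPE-1 inhibitor analysis uses 40.
    ``ipr_frequency`` is filled by :func:`balance_table`; standalone calls get 0.
    """
    import math

    if min_reads_per_class < 1:
        raise ConfigurationError("min_reads_per_class must be >= 1")
    mmej, nhej = spectrum.mmej_reads, spectrum.nhej_reads
    if mmej < min_reads_per_class or nhej < min_reads_per_class:
        return None
    return BalanceRecord(
        sample_id=spectrum.sample_id,
        ipr_barcode=spectrum.ipr_barcode,
        log2_mmej_nhej=math.log2(mmej / nhej),
        mmej_reads=mmej,
        nhej_reads=nhej,
        total_reads=spectrum.total,
        ipr_frequency=0.0,
    )


def balance_table(
    spectra: Iterable[IndelSpectrum], min_reads_per_class: int = 1
) -> pd.DataFrame:
    """Balance records for a collection of spectra, as a tidy DataFrame.

    IPR frequency is computed within each sample as the reporter's assigned
    reads over all assigned reads of that sample (all spectra contribute to the
    denominator, including reporters whose balance is undefined).
    """
    spectra = list(spectra)
    totals: dict[str, int] = {}
    for s in spectra:
        s.validate()
        totals[s.sample_id] = totals.get(s.sample_id, 0) + s.total
    rows = []
    for s in spectra:
        rec = compute_balance(s, min_reads_per_class)
        if rec is None:
            continue
        denom = totals[s.sample_id]
        rec.ipr_frequency = s.total / denom if denom else 0.0
        rows.append(rec.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "ipr_barcode",
            "log2_mmej_nhej",
            "mmej_reads",
            "nhej_reads",
            "total_reads",
            "ipr_frequency",
        ],
    )


def filter_iprs(
    records: pd.DataFrame,
    freq_threshold: float = 0.0,
    min_replicates: int = 1,
    condition_col: str = "condition",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Apply the reporter-level filters used before CCD analysis.

    Reporters below ``freq_threshold`` IPR frequency in a sample are dropped
    from that sample; reporters observed in fewer than ``min_replicates``
    replicates of a condition are dropped from that condition entirely.  The
    RPE-1 analyses use frequency thresholds 0.0025 (p53-KO) / 0.0075
    (p53/BRCA1-dKO) and require presence in all three replicates.
    """
    if not 0.0 <= freq_threshold <= 1.0:
        raise ConfigurationError("freq_threshold must lie in [0, 1]")
    for col in (condition_col, replicate_col):
        if col not in records.columns:
            raise ValidationError(f"records lack required column {col!r}")
    kept = records[records["ipr_frequency"] >= freq_threshold].copy()
    support = kept.groupby([condition_col, "ipr_barcode"])[replicate_col].nunique()
    ok = support[support >= min_replicates].index
    idx = pd.MultiIndex.from_frame(kept[[condition_col, "ipr_barcode"]])
    return kept[idx.isin(ok)].reset_index(drop=True)


def load_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition, replicate and optional cell_line."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing = {"sample_id", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def annotate_samples(balance: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Join balance records with the sample sheet on sample_id."""
    merged = balance.merge(samples, on="sample_id", how="left", validate="many_to_one")
    orphan = merged["condition"].isna()
    if orphan.any():
        bad = merged.loc[orphan, "sample_id"].unique()[:5]
        raise ValidationError(f"samples absent from sample sheet: {list(bad)}")
    return merged


def load_reporter_reference(path) -> ReporterReference:
    """Reporter layout from a YAML mapping with the ReporterReference fields."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigurationError("reporter reference YAML must be a mapping")
    return ReporterReference(**data)
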