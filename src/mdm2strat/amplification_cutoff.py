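"""MDM2 amplification cutoff from mutual exclusivity with TP53 mutation.

MDM2 amplification and inactivating TP53 mutation are alternative ways for a
tumor to silence the p53 pathway, so a tumor gains nothing from having both.
Under that assumption, the copy-number level at which the two alterations
become mutually exclusive marks *functionally relevant* amplification: scan a
grid of copy-number cutoffs, count tumors carrying both an MDM2 log2 CN ratio
at or above the cutoff and a functional (inactivating) TP53 mutation, and
take the smallest cutoff at which the co-occurrence count reaches — and
stays at — zero.  Missense TP53 variants that retain transactivation
competence are corrected to wild-type before counting.

The derived cutoff (log2 ratio 2.25, i.e. ~9.5 copies over a diploid
baseline) then converts per-tumor-type amplification fractions into
projected annual U.S. case counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel_curation import MutationCall, classify_tp53, load_transactivation_table

__all__ = [
    "TumorSample",
    "CooccurrenceCurve",
    "cn_to_log2_ratio",
    "log2_ratio_to_cn",
    "annotate_functional_tp53",
    "functional_mutation_flags",
    "cooccurrence_curve",
    "linear_trend_r2",
    "find_exclusivity_threshold",
    "amplification_rate_table",
    "project_incidence",
    "format_rate",
    "samples_from_counts",
    "load_amplification_counts",
    "load_incidence_map",
    "default_cutoff_grid",
]


@dataclass(frozen=True)
class TumorSample:
    """One tumor with its MDM2 copy-number ratio and TP53 mutation calls."""

    sample_id: str
    tumor_type: str
    mdm2_log2_ratio: float
    tp53_mutations: tuple[MutationCall, ...] = ()


def cn_to_log2_ratio(copy_number: float, baseline: float = 2.0) -> float:
    """log2(copy number / baseline); diploid baseline 2 maps 9.5 copies to
    a ratio of ~2.25."""
    if copy_number <= 0 or baseline <= 0:
        raise ValidationError("copy number and baseline must be positive")
    return math.log2(copy_number / baseline)


def log2_ratio_to_cn(log2_ratio: float, baseline: float = 2.0) -> float:
    """Inverse of :func:`cn_to_log2_ratio`."""
    if baseline <= 0:
        raise ValidationError("baseline must be positive")
    return baseline * 2.0 ** log2_ratio


def annotate_functional_tp53(
    sample: TumorSample, transactivation: Mapping[str, str] | None = None
) -> bool:
    """True iff the sample carries at least one inactivating TP53 mutation.

    Transactivation-competent missense variants do not set the flag: such
    tumors are treated as p53 wild-type, mirroring the cell-panel rule.
    """
    status = classify_tp53(
        sample.tp53_mutations, dna_available=True, transactivation=transactivation
    )
    # heterozygous inactivating calls in tumors still inactivate one allele;
    # for exclusivity counting any inactivating call sets the flag
    return status in ("MUTANT", "HETEROZYGOUS")


def functional_mutation_flags(
    tumor_table: pd.DataFrame, transactivation: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse a long tumor mutation table to one row per sample.

    Input columns: sample_id, tumor_type, mdm2_log2_ratio,
    tp53_protein_change, tp53_consequence (mutation columns empty for WT
    samples; one row per mutation).  Output: sample_id, tumor_type,
    mdm2_log2_ratio, functional_tp53_mutation (bool).
    """
    if transactivation is None:
        transactivation = load_transactivation_table()
    flags = []
    for (sid, ttype, ratio), grp in tumor_table.groupby(
        ["sample_id", "tumor_type", "mdm2_log2_ratio"], sort=False
    ):
        calls = [
            MutationCall("TP53", pc, cons)
            for pc, cons in zip(grp["tp53_protein_change"], grp["tp53_consequence"])
            if isinstance(cons, str) and cons
        ]
        sample = TumorSample(sid, ttype, float(ratio), tuple(calls))
        flags.append((sid, ttype, float(ratio),
                      annotate_functional_tp53(sample, transactivation)))
    return pd.DataFrame(
        flags,
        columns=["sample_id", "tumor_type", "mdm2_log2_ratio",
                 "functional_tp53_mutation"],
    )


@dataclass
class CooccurrenceCurve:
    """Co-occurrence of amplification and functional TP53 mutation per cutoff."""

    cutoffs: np.ndarray  # log2-ratio grid, strictly increasing
    counts: np.ndarray  # samples with (ratio >= cutoff) & mutation
    rates: np.ndarray  # counts / samples above cutoff (0 where none above)
    r2: float = math.nan
    exclusivity_threshold: float | None = None


def default_cutoff_grid(lo: float = 0.0, hi: float = 4.0, step: float = 0.05) -> np.ndarray:
    """Default log2-ratio cutoff grid."""
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def cooccurrence_curve(
    samples: pd.DataFrame, cutoff_grid: Sequence[float] | None = None
) -> CooccurrenceCurve:
    """Count samples with (MDM2 log2 ratio >= cutoff) AND functional TP53
    mutation at every cutoff on the grid.

    ``samples`` must carry ``mdm2_log2_ratio`` and
    ``functional_tp53_mutation`` columns (see
    :func:`functional_mutation_flags`).  Counts are non-increasing in the
    cutoff by construction.
    """
    grid = np.asarray(
        default_cutoff_grid() if cutoff_grid is None else cutoff_grid, dtype=float
    )
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValidationError("cutoff grid must be strictly increasing")
    if samples.empty:
        z = np.zeros(grid.size)
        return CooccurrenceCurve(grid, z.astype(int), z)
    ratio = samples["mdm2_log2_ratio"].to_numpy(float)
    mut = samples["functional_tp53_mutation"].to_numpy(bool)
    above = ratio[:, None] >= grid[None, :]
    counts = (above & mut[:, None]).sum(axis=0)
    n_above = above.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(n_above > 0, counts / np.maximum(n_above, 1), 0.0)
    return CooccurrenceCurve(grid, counts.astype(int), rates)


def linear_trend_r2(curve: CooccurrenceCurve, use: str = "counts") -> float:
    """R² of an ordinary least-squares line through co-occurrence vs cutoff.

    A constant curve has no explainable variance; R² is 0 by convention.
    """
    y = np.asarray(getattr(curve, use), dtype=float)
    x = curve.cutoffs
    if x.size < 3:
        raise ValidationError("need >= 3 grid points for a trend fit")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    return 1.0 - sse / sst


def find_exclusivity_threshold(curve: CooccurrenceCurve) -> float | None:
    """Smallest cutoff with zero co-occurrence at it *and* at every larger
    cutoff; None when co-occurrence never vanishes."""
    counts = np.asarray(curve.counts)
    if counts.size == 0:
        return None
    suffix_nonzero = np.maximum.accumulate((counts > 0)[::-1])[::-1]
    idx = np.nonzero(~suffix_nonzero)[0]
    return float(curve.cutoffs[idx[0]]) if idx.size else None


# ---------------------------------------------------------------------------
# Amplification rates and incidence projection
# ---------------------------------------------------------------------------


def format_rate(rate_pct: float) -> float:
    """Display rounding for an amplification rate in percent: one decimal
    below 10%, whole percent at or above 10%."""
    return round(rate_pct, 1) if rate_pct < 10 else float(round(rate_pct))


def amplification_rate_table(
    samples: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Per-tumor-type amplification rate at a log2-ratio ``threshold``.

    Returns columns tumor_type, amplified, total, rate (display-rounded
    percent).  Tumor types with zero samples are omitted.
    """
    rows = []
    for ttype, grp in samples.groupby("tumor_type", sort=False):
        total = len(grp)
        if total == 0:
            continue
        amp = int((grp["mdm2_log2_ratio"] >= threshold).sum())
        rate = format_rate(100.0 * amp / total)
        rows.append((ttype, amp, total, rate))
    return pd.DataFrame(rows, columns=["tumor_type", "amplified", "total", "rate"])


def project_incidence(
    rate_table: pd.DataFrame, incidence_map: Mapping[str, float]
) -> tuple[pd.DataFrame, int]:
    """Projected annual U.S. cases with functionally relevant amplification.

    projected = round(display-rounded rate% x annual incidence); zero-rate
    rows project 0 (rendered "-").  Tumor types missing from the incidence
    map are skipped with a warning.  Returns (table, total).
    """
    import logging

    rows = []
    for row in rate_table.itertuples(index=False):
        if row.tumor_type not in incidence_map:
            logging.getLogger(__name__).warning(
                "no incidence entry for %s; row skipped", row.tumor_type
            )
            continue
        inc = float(incidence_map[row.tumor_type])
        projected = int(round(row.rate / 100.0 * inc))
        rows.append(
            (row.tumor_type, row.amplified, row.total, row.rate, inc, projected)
        )
    table = pd.DataFrame(
        rows,
        columns=["tumor_type", "amplified", "total", "rate",
                 "annual_incidence", "projected"],
    )
    total = int(table["projected"].sum()) if len(table) else 0
    return table, total


def samples_from_counts(counts: pd.DataFrame, threshold: float = 2.25) -> pd.DataFrame:
    """Expand per-type (amplified, total) counts into a flagged sample table.

    Amplified samples are placed above the threshold, the rest at diploid
    ratio 0, all TP53 wild-type — a minimal sample-level representation of a
    published rate table that exercises the real counting code path.
    """
    rows = []
    for row in counts.itertuples(index=False):
        for k in range(int(row.total)):
            ratio = threshold + 0.25 if k < int(row.amplified) else 0.0
            rows.append(
                (f"{row.tumor_type}-{k:04d}", row.tumor_type, ratio, False)
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "tumor_type", "mdm2_log2_ratio",
                 "functional_tp53_mutation"],
    )


def _load_data_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("mdm2strat.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_amplification_counts() -> pd.DataFrame:
    """Published pan-cancer TCGA MDM2 amplification counts (log2 ratio >=
    2.25 cutoff): tumor_type, amplified, total."""
    return _load_data_tsv("tcga_mdm2_amplification_counts.tsv")


def load_incidence_map() -> dict[str, float]:
    """Annual U.S. incidence (cases/year) per tumor type."""
    df = _load_data_tsv("us_annual_incidence.tsv")
    return dict(zip(df["tumor_type"], df["annual_incidence"].astype(float)))
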