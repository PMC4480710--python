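"""Rule-based curation of a cell-line screening panel.

A screened panel is filtered through a fixed exclusion cascade before any
response-stratification analysis:

1. replicate QC (poor growth or high CV of untreated cultures),
2. lack of genomic DNA,
3. misidentified lines (SNP profile contradicts the line's own reference),
4. redundant lines (synonymous with another line already in the panel),
5. viral p53-inactivating sequences (HPV E6, SV40 TAg, adenovirus E1B),
6. TP53 mutant/WT heterozygotes.

Survivors are then classified functionally TP53 wild-type or mutant: missense
variants are interpreted through a transactivation lookup table (a missense
retaining transactivation competence counts as wild-type), truncating /
splice / deletion / rearrangement events are inactivating by consequence, and
configured silent-but-splice-disrupting variants force mutant status.
Finally, wild-type lines that sit in the lowest tail of TP53 transcript
expression *and* fail to respond to MDM2 inhibition are reannotated mutant
(cryptic inactivation not visible to exon sequencing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCall",
    "ExclusionAudit",
    "CurationConfig",
    "IdentityResult",
    "STATUS_WT",
    "STATUS_MUTANT",
    "STATUS_HETEROZYGOUS",
    "STATUS_UNKNOWN",
    "VIRAL_FLAG_COLUMNS",
    "EXCLUSION_STAGES",
    "load_transactivation_table",
    "percent_genotype_match",
    "resolve_identity",
    "flag_viral",
    "classify_tp53",
    "flag_low_expression_wt",
    "apply_exclusion_cascade",
]

STATUS_WT = "WT"
STATUS_MUTANT = "MUTANT"
STATUS_HETEROZYGOUS = "HETEROZYGOUS"
STATUS_UNKNOWN = "UNKNOWN"

#: Registry columns holding the viral qPCR detection flags.
VIRAL_FLAG_COLUMNS = ["hpv16", "hpv18", "hpv31", "hpv33", "hpv45", "sv40", "e1b"]

#: Cascade stages in application order; reason attribution = first failure.
EXCLUSION_STAGES = [
    "poor_growth_or_cv",
    "no_dna",
    "misidentified",
    "redundant",
    "viral",
    "heterozygous",
]

#: Consequences that inactivate p53 regardless of the transactivation table.
INACTIVATING_CONSEQUENCES = {
    "nonsense",
    "frameshift",
    "splice",
    "deletion",
    "rearrangement",
}


@dataclass(frozen=True)
class MutationCall:
    """One TP53 (or other gene) mutation call for a cell line or tumor."""

    gene: str
    protein_change: str
    consequence: str  # missense|nonsense|frameshift|splice|deletion|silent|rearrangement
    zygosity: str = "homozygous"  # homozygous|heterozygous
    transactivation_class: str = "unknown"  # functional|non_functional|unknown


@dataclass
class CurationConfig:
    """Tunables of the exclusion cascade.

    cv_threshold / min_count: replicate-QC limits (CV unitless, count in
    relative cell-count units).  match_threshold: percent SNP genotype
    concordance above which two profiles are called the same line.
    expr_quantile: fraction of WT lines counted as "low TP53 expression" for
    the cryptic-inactivation reannotation.  response_rule: 'censored' flags
    lines whose IC50 is right-censored; 'threshold' flags IC50 >
    ic50_threshold μM.  splice_disrupting_silent: silent protein changes
    known to disrupt splicing, forcing mutant status.
    """

    cv_threshold: float = 0.3
    min_count: float = 200.0
    match_threshold: float = 80.0
    expr_quantile: float = 0.1
    response_rule: str = "censored"
    ic50_threshold: float = 50.0
    splice_disrupting_silent: tuple[str, ...] = ("T125T",)


def load_transactivation_table() -> dict[str, str]:
    """Packaged missense -> transactivation class lookup.

    A compact extract of systematic yeast transactivation assay
    classifications keyed by protein change; ``functional`` means the mutant
    protein retains transcriptional activity (treated as wild-type).
    """
    ref = resources.files("mdm2strat.data").joinpath("transactivation_classes.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["protein_change"], df["transactivation_class"]))


# ---------------------------------------------------------------------------
# Identity resolution
# ---------------------------------------------------------------------------

_CALL_CODES = {"AA": 1, "AB": 2, "BB": 3}


def _encode_calls(calls: Sequence[str]) -> np.ndarray:
    return np.array([_CALL_CODES.get(str(c).upper(), 0) for c in calls], dtype=np.int8)


def percent_genotype_match(calls_a: Sequence[str], calls_b: Sequence[str]) -> float:
    """Percent concordance over positions with a definite call in both vectors.

    Calls are AA/AB/BB; anything else (NC, empty, NaN) is a no-call and is
    excluded from the comparison.  Returns NaN when no position is comparable
    (undefined-match signal).
    """
    a, b = _encode_calls(calls_a), _encode_calls(calls_b)
    if a.size != b.size:
        raise ValidationError("genotype vectors differ in length")
    both = (a > 0) & (b > 0)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return 100.0 * float(((a == b) & both).sum()) / n


def _pairwise_match(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Percent-match matrix between encoded call matrices (rows = samples)."""
    out = np.full((x.shape[0], y.shape[0]), np.nan)
    for i in range(x.shape[0]):  # row-wise keeps memory flat for big panels
        both = (x[i] > 0) & (y > 0)
        n = both.sum(axis=1)
        hits = ((x[i] == y) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(n > 0, 100.0 * hits / n, np.nan)
    return out


@dataclass
class IdentityResult:
    misidentified: set[str]
    synonymous_clusters: list[list[str]]
    redundant: set[str]
    best_reference_match: pd.DataFrame  # line_id, best_ref, pct, self_pct


def resolve_identity(
    panel: pd.DataFrame,
    reference_panel: pd.DataFrame,
    match_threshold: float = 80.0,
) -> IdentityResult:
    """Resolve misidentified and synonymous lines by SNP concordance.

    ``panel`` and ``reference_panel`` are call tables (rows = line names,
    columns = SNPs, values AA/AB/BB/NC).  A line is *misidentified* when the
    reference profile filed under its own name disagrees (self-match below
    threshold) while some differently-named reference profile matches above
    threshold.  Within-panel pairs above threshold form *synonymous* clusters
    (connected components); the lexicographically smallest member of each
    cluster is retained, the rest are redundant.  Cluster membership takes
    precedence over the misidentification call, keeping the two categories
    disjoint.
    """
    if not (50.0 < match_threshold < 100.0):
        raise ValidationError("match_threshold must lie in (50, 100)")
    ids = list(panel.index)
    enc = np.stack([_encode_calls(panel.loc[i]) for i in ids]) if ids else np.empty((0, 0), np.int8)
    ref_ids = list(reference_panel.index)
    ref_enc = (
        np.stack([_encode_calls(reference_panel.loc[r]) for r in ref_ids])
        if ref_ids
        else np.empty((0, enc.shape[1] if ids else 0), np.int8)
    )

    # within-panel synonymy
    pp = _pairwise_match(enc, enc) if ids else np.empty((0, 0))
    parent = {i: i for i in ids}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isfinite(pp[i, j]) and pp[i, j] >= match_threshold:
                ri, rj = find(ids[i]), find(ids[j])
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    clusters = sorted(
        (sorted(g) for g in groups.values() if len(g) > 1), key=lambda g: g[0]
    )
    clustered = {m for g in clusters for m in g}
    redundant = {m for g in clusters for m in g[1:]}

    # reference comparison
    rows = []
    misidentified: set[str] = set()
    if ref_ids and ids:
        pr = _pairwise_match(enc, ref_enc)
        ref_pos = {r: k for k, r in enumerate(ref_ids)}
        for i, line in enumerate(ids):
            self_pct = pr[i, ref_pos[line]] if line in ref_pos else np.nan
            other = [(pr[i, k], r) for k, r in enumerate(ref_ids) if r != line]
            best_pct, best_ref = max(
                other, key=lambda t: (-np.inf if np.isnan(t[0]) else t[0]),
                default=(np.nan, None),
            )
            rows.append((line, best_ref, best_pct, self_pct))
            if (
                line in ref_pos
                and np.isfinite(self_pct)
                and self_pct < match_threshold
                and np.isfinite(best_pct)
                and best_pct >= match_threshold
                and line not in clustered
            ):
                misidentified.add(line)
    best_df = pd.DataFrame(
        rows, columns=["line_id", "best_ref", "pct", "self_pct"]
    )
    return IdentityResult(misidentified, clusters, redundant, best_df)


# ---------------------------------------------------------------------------
# Per-record rules
# ---------------------------------------------------------------------------


def flag_viral(record: Mapping) -> tuple[bool, str | None]:
    """Excluded iff any viral detection flag is set; returns the flag name."""
    for col in VIRAL_FLAG_COLUMNS:
        if bool(record.get(col, False)):
            return True, col
    return False, None


def _is_inactivating(
    call: MutationCall,
    transactivation: Mapping[str, str],
    splice_silent: Iterable[str],
) -> bool:
    cons = call.consequence.lower()
    if cons in INACTIVATING_CONSEQUENCES:
        return True
    if cons == "missense":
        cls = call.transactivation_class
        if cls == "unknown":
            cls = transactivation.get(call.protein_change, "unknown")
        if cls == "unknown":
            logger.warning(
                "missense %s absent from transactivation table; "
                "treating as non_functional", call.protein_change,
            )
            cls = "non_functional"
        return cls != "functional"
    if cons == "silent":
        return call.protein_change in set(splice_silent)
    return False


def classify_tp53(
    calls: Sequence[MutationCall],
    dna_available: bool = True,
    transactivation: Mapping[str, str] | None = None,
    splice_disrupting_silent: Iterable[str] = ("T125T",),
) -> str:
    """Functional TP53 status of one line from its mutation calls.

    No DNA -> UNKNOWN.  Any *heterozygous* inactivating call ->
    HETEROZYGOUS (ambiguous, excluded downstream).  Any homozygous
    inactivating call -> MUTANT.  Calls that do not inactivate (functional
    missense such as Q331R, ordinary silent changes) leave the line WT, as
    does an empty call list.
    """
    if not dna_available:
        return STATUS_UNKNOWN
    if transactivation is None:
        transactivation = load_transactivation_table()
    calls = list(calls)
    if not calls:
        return STATUS_WT
    inactivating = [
        c for c in calls
        if _is_inactivating(c, transactivation, splice_disrupting_silent)
    ]
    if any(c.zygosity == "heterozygous" for c in inactivating):
        return STATUS_HETEROZYGOUS
    if inactivating:
        if any(
            c.consequence.lower() == "missense"
            and transactivation.get(c.protein_change) == "functional"
            for c in calls
        ):
            logger.warning(
                "conflicting calls (functional missense plus inactivating); "
                "classifying MUTANT"
            )
        return STATUS_MUTANT
    return STATUS_WT


def flag_low_expression_wt(
    wt_records: pd.DataFrame,
    expr_quantile: float = 0.1,
    response_rule: str = "censored",
    ic50_threshold: float = 50.0,
) -> list[str]:
    """WT lines that are both low-expressing and non-responsive.

    Returns line ids in the lowest ``expr_quantile`` of TP53 expression among
    WT lines whose response is censored (default rule) or above
    ``ic50_threshold``.  These are reannotated mutant by the cascade (cryptic
    inactivation).  ``expr_quantile <= 0`` flags nothing.
    """
    if wt_records.empty or expr_quantile <= 0:
        return []
    cut = float(np.quantile(wt_records["tp53_expression"].to_numpy(float), expr_quantile))
    low = wt_records["tp53_expression"] <= cut
    if response_rule == "censored":
        nonresp = wt_records["censored"].astype(bool)
    elif response_rule == "threshold":
        nonresp = wt_records["censored"].astype(bool) | (
            wt_records["ic50_um"] > ic50_threshold
        )
    else:
        raise ValidationError(f"unknown response_rule {response_rule!r}")
    return sorted(wt_records.loc[low & nonresp, "line_id"])


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


@dataclass
class ExclusionAudit:
    """Ordered per-stage exclusion counts plus a per-line ledger."""

    counts: dict[str, int]
    survivors: int
    n_input: int
    ledger: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["line_id", "stage", "reason"])
    )
    reannotated: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.survivors + sum(self.counts.values()) != self.n_input:
            raise AssertionError("audit does not conserve line count")


def _mutation_calls_by_line(mutations: pd.DataFrame | None) -> dict[str, list[MutationCall]]:
    calls: dict[str, list[MutationCall]] = {}
    if mutations is None or mutations.empty:
        return calls
    for row in mutations.itertuples(index=False):
        calls.setdefault(row.line_id, []).append(
            MutationCall(
                gene=row.gene,
                protein_change=row.protein_change,
                consequence=row.consequence,
                zygosity=row.zygosity,
            )
        )
    return calls


def apply_exclusion_cascade(
    registry: pd.DataFrame,
    mutations: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    reference_genotypes: pd.DataFrame | None = None,
    config: CurationConfig | None = None,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the six-stage exclusion cascade and status annotation.

    Stages run in the fixed order QC -> no-DNA -> misidentified -> redundant
    -> viral -> heterozygous; a line is excluded at its first failing stage
    only.  Survivors receive a TP53 ``status`` (WT/MUTANT), after which the
    low-expression/non-responder reannotation flips qualifying WT lines to
    MUTANT (membership unchanged).  Returns the curated registry and an
    :class:`ExclusionAudit` satisfying survivors + Σcounts = input size.
    """
    cfg = config or CurationConfig()
    transactivation = load_transactivation_table()
    reg = registry.reset_index(drop=True).copy()
    calls_by_line = _mutation_calls_by_line(mutations)

    counts = {s: 0 for s in EXCLUSION_STAGES}
    ledger_rows: list[tuple[str, str, str]] = []
    active = reg["line_id"].tolist()

    def exclude(line_id: str, stage: str, reason: str) -> None:
        counts[stage] += 1
        ledger_rows.append((line_id, stage, reason))
        active.remove(line_id)

    by_id = reg.set_index("line_id", drop=False)

    # 1. replicate QC
    for lid in list(active):
        rec = by_id.loc[lid]
        if rec["cv"] > cfg.cv_threshold:
            exclude(lid, "poor_growth_or_cv", "high_cv")
        elif rec["mean_count"] < cfg.min_count:
            exclude(lid, "poor_growth_or_cv", "poor_growth")

    # 2. no genomic DNA
    for lid in list(active):
        if not bool(by_id.loc[lid, "dna_available"]):
            exclude(lid, "no_dna", "no_dna")

    # 3/4. identity resolution among lines still in play
    if genotypes is not None and reference_genotypes is not None:
        present = [l for l in active if l in genotypes.index]
        ident = resolve_identity(
            genotypes.loc[present], reference_genotypes, cfg.match_threshold
        )
        for lid in list(active):
            if lid in ident.misidentified:
                exclude(lid, "misidentified", "best_match_other_name")
        for lid in list(active):
            if lid in ident.redundant:
                exclude(lid, "redundant", "synonymous_cluster_member")

    # 5. viral sequences
    for lid in list(active):
        hit, flag = flag_viral(by_id.loc[lid])
        if hit:
            exclude(lid, "viral", flag)

    # 6. TP53 classification; heterozygotes out, status kept for the rest
    status: dict[str, str] = {}
    for lid in list(active):
        st = classify_tp53(
            calls_by_line.get(lid, []),
            dna_available=bool(by_id.loc[lid, "dna_available"]),
            transactivation=transactivation,
            splice_disrupting_silent=cfg.splice_disrupting_silent,
        )
        if st == STATUS_HETEROZYGOUS:
            exclude(lid, "heterozygous", "heterozygous_tp53")
        elif st == STATUS_UNKNOWN:  # unreachable after stage 2; belt-and-braces
            exclude(lid, "no_dna", "no_dna")
        else:
            status[lid] = st

    curated = reg[reg["line_id"].isin(active)].copy()
    curated["status"] = curated["line_id"].map(status)
    curated["reannotated"] = False

    wt = curated[curated["status"] == STATUS_WT]
    flagged = flag_low_expression_wt(
        wt, cfg.expr_quantile, cfg.response_rule, cfg.ic50_threshold
    )
    curated.loc[curated["line_id"].isin(flagged), "status"] = STATUS_MUTANT
    curated.loc[curated["line_id"].isin(flagged), "reannotated"] = True

    audit = ExclusionAudit(
        counts=counts,
        survivors=len(curated),
        n_input=len(reg),
        ledger=pd.DataFrame(ledger_rows, columns=["line_id", "stage", "reason"]),
        reannotated=flagged,
    )
    audit.check()
    return curated.reset_index(drop=True), audit
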