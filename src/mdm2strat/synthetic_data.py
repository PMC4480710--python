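"""Synthetic fixtures with the statistical structure the pipeline assumes.

Real inputs to this kind of analysis — a proprietary 260-line inhibitor
screen and a TCGA copy-number/mutation extract — are not redistributable, so
every stage is exercised on generated data instead.  The generators plant
known ground truth:

* a screen registry of 260 cell lines whose exclusion-category composition
  matches the published curation cascade (26 poor-growth/high-CV, 1 without
  DNA, 5 misidentified, 22 redundant, 8 virally infected, 25 TP53
  heterozygotes, leaving 173 curated lines of which 58 end up functionally
  wild-type and 115 mutant);
* dose-response series drawn from known 4PL parameters (wild-type lines
  sensitive with IC50 log-uniform on 0.01-5 μM, mutant lines censored at
  the 50 μM top dose);
* SNP genotype panels with planted duplicate and misidentified lines;
* a two-batch expression matrix with 20 shared lines under a known affine
  shift, and four wild-type lines planted in a separable low-TP53-expression
  region that are also non-responders;
* a tumor table of 3856 samples in which MDM2 amplification and inactivating
  TP53 mutation are mutually exclusive above a planted copy-number threshold
  (9.5 copies, log2 ratio ~2.25).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponse, compute_auc, four_pl
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TumorTableSpec",
    "FixtureSpec",
    "ScreenFixture",
    "DEFAULT_CATEGORY_COUNTS",
    "DEFAULT_DOSES",
    "gen_screen_registry",
    "gen_dose_response_set",
    "gen_genotype_panels",
    "gen_expression_matrix",
    "gen_tumor_cn_table",
    "gen_mutation_matrix",
]

#: Exclusion-category composition of the default 260-line registry.
DEFAULT_CATEGORY_COUNTS = {
    "poor_growth_or_cv": 26,
    "no_dna": 1,
    "misidentified": 5,
    "redundant": 22,
    "viral": 8,
    "heterozygous": 25,
    "curated_wt": 58,
    "curated_mutant": 115,
}

#: 10-point, 3-fold titration down from the 50 μM top dose (μM, ascending).
DEFAULT_DOSES = tuple(50.0 / 3.0 ** k for k in reversed(range(10)))

_TISSUES = [
    "lung", "breast", "colon", "pancreas", "skin", "ovary",
    "prostate", "stomach", "brain", "bone", "blood", "cervix",
]

_NONFUNCTIONAL_MISSENSE = [
    "R175H", "R248W", "R248Q", "R273H", "R273C", "R282W", "G245S", "R249S",
    "Y220C", "V157F", "C176F", "H179R", "M237I", "C242F", "G266E", "R280K",
]
_NONSENSE = ["R196*", "R213*", "E171*", "W146*"]
_FRAMESHIFT = ["P152fs", "T155fs", "A159fs"]

_DEFAULT_TUMOR_MIX = {
    "Liposarcoma": 14, "Glioblastoma Multiforme": 562,
    "Bladder Urothelial Carcinoma": 152, "Stomach Adenocarcinoma": 273,
    "Lung Adenocarcinoma": 437, "Skin Cutaneous Melanoma": 273,
    "Brain Lower Grade Glioma": 220, "Breast Invasive Carcinoma": 926,
    "Ovarian Serous Cystadenocarcinoma": 576,
    "Uterine Corpus Endometrial Carcinoma": 493,
    "Lung Squamous Cell Carcinoma": 387,
    "Head and Neck Squamous Cell Carcinoma": 337,
    "Kidney Renal Papillary Cell Carcinoma": 117,
}

_CANCER_GENES = [
    "KRAS", "PTEN", "PIK3CA", "APC", "BRAF", "EGFR", "CDKN2A", "RB1", "NRAS",
    "SMAD4", "STK11", "FBXW7", "CTNNB1", "NF1", "ATM", "ERBB2", "MET", "ALK",
    "KIT", "PDGFRA", "IDH1", "IDH2", "VHL", "MLH1", "MSH2", "MSH6", "BRCA1",
    "BRCA2", "PALB2", "CHEK2", "NOTCH1", "NOTCH2", "FGFR1", "FGFR2", "FGFR3",
    "JAK2", "FLT3", "NPM1", "DNMT3A", "TET2", "ASXL1", "EZH2", "KDM6A",
    "ARID1A", "SMARCA4", "SMARCB1", "BAP1", "SETD2", "PBRM1", "KEAP1",
    "NFE2L2", "AKT1", "MTOR", "TSC1", "TSC2", "RHEB", "GNAS", "GNAQ",
    "GNA11", "HRAS", "MAP2K1", "CDH1", "AXIN1", "WT1",
]


@dataclass
class TumorTableSpec:
    """Generative spec for the TCGA-like tumor table."""

    n_samples: int = 3856
    tumor_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TUMOR_MIX)
    )
    true_exclusivity_cn: float = 9.5
    background_mutation_rate: float = 0.4
    functional_missense_rate: float = 0.03
    amp_prob_wt: float = 0.06
    amp_prob_mut: float = 0.10
    diploid_log2_sd: float = 0.15
    amp_log2_max: float = 3.5

    def validate(self) -> None:
        if self.true_exclusivity_cn <= 2:
            raise ValidationError("true_exclusivity_cn must exceed the diploid 2")
        for name in ("background_mutation_rate", "functional_missense_rate",
                     "amp_prob_wt", "amp_prob_mut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class FixtureSpec:
    """Spec for the whole fixture bundle; defaults are the study conditions."""

    seed: int = 0
    n_lines: int = 260
    category_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    n_low_expression_wt: int = 4
    n_snps: int = 400
    n_replicates: int = 6
    poc_noise_sd: float = 5.0
    tumor: TumorTableSpec = field(default_factory=TumorTableSpec)

    def validate(self) -> None:
        for cat, n in self.category_counts.items():
            if n < 0:
                raise ValidationError(f"category {cat!r} has negative count {n}")
        if self.n_low_expression_wt < 0:
            raise ValidationError("n_low_expression_wt must be >= 0")
        total = sum(self.category_counts.values())
        if total != self.n_lines:
            raise ValidationError(
                f"category counts sum to {total}, not n_lines={self.n_lines}: "
                + ", ".join(f"{c}={n}" for c, n in self.category_counts.items())
            )
        if self.n_low_expression_wt > self.category_counts.get("curated_mutant", 0):
            raise ValidationError(
                "category curated_mutant too small for n_low_expression_wt"
            )
        self.tumor.validate()


@dataclass
class ScreenFixture:
    """Generated screen bundle: registry plus every auxiliary table."""

    registry: pd.DataFrame
    mutations: pd.DataFrame
    genotypes: pd.DataFrame
    reference_genotypes: pd.DataFrame
    dose_poc: pd.DataFrame  # long: line_id, dose_um, poc
    compound_counts: pd.DataFrame  # long: line_id, dose_um, count
    vehicle_counts: pd.DataFrame  # line_id, rep1..repK
    true_params: pd.DataFrame  # line_id, a, b, c, d

    def dose_response(self, line_id: str) -> DoseResponse:
        sub = self.dose_poc[self.dose_poc["line_id"] == line_id]
        reps = self.vehicle_counts.set_index("line_id").loc[line_id].to_numpy(float)
        return DoseResponse(
            line_id,
            sub["dose_um"].to_numpy(float),
            sub["poc"].to_numpy(float),
            untreated_counts=reps,
        )


# ---------------------------------------------------------------------------
# Low-level generators
# ---------------------------------------------------------------------------


def gen_dose_response_set(
    params,
    doses=DEFAULT_DOSES,
    noise_sd: float = 5.0,
    seed: int | None = None,
) -> np.ndarray:
    """POC series from 4PL parameters plus truncated Gaussian noise.

    ``params`` is a sequence of (A, B, C, D) tuples; returns an array of
    shape (n_lines, n_doses).  ``noise_sd`` is in POC units; noise is
    clipped at zero (POC cannot be negative); ``noise_sd=0`` returns exact
    curve values.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValidationError("doses must be positive")
    if np.any(np.diff(doses) <= 0):
        raise ValidationError("doses must be strictly increasing")
    rng = np.random.default_rng(seed)
    out = np.stack([four_pl(doses, *p) for p in params]) if len(params) else (
        np.empty((0, doses.size))
    )
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _random_calls(rng: np.random.Generator, n_snps: int) -> np.ndarray:
    return rng.choice(["AA", "AB", "BB"], size=n_snps, p=[0.36, 0.48, 0.16])


def _mask_nocalls(
    rng: np.random.Generator, calls: np.ndarray, rate: float = 0.04
) -> np.ndarray:
    out = calls.copy()
    out[rng.random(calls.size) < rate] = "NC"
    return out


def gen_genotype_panels(
    n_lines: int,
    n_snps: int = 400,
    planted_pairs: int = 2,
    planted_misidentified: int = 1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standalone test/reference genotype panels with planted structure.

    The last ``planted_pairs`` panel lines duplicate the first lines'
    profiles (synonymy); ``planted_misidentified`` lines carry the profile of
    a reference-only entry while their own-name reference disagrees.  Calls
    include ~4% no-calls.
    """
    if n_snps < 1:
        raise ValidationError("n_snps must be >= 1")
    if planted_pairs + planted_misidentified > n_lines:
        raise ValidationError("planted lines exceed n_lines")
    rng = np.random.default_rng(seed)
    ids = [f"GL{i:03d}" for i in range(n_lines)]
    true = {i: _random_calls(rng, n_snps) for i in ids}
    panel = {}
    ref = {}
    n_dup = planted_pairs
    n_mis = planted_misidentified
    for k, lid in enumerate(ids):
        if k >= n_lines - n_dup:  # duplicates of the leading lines
            src = ids[k - (n_lines - n_dup)]
            panel[lid] = _mask_nocalls(rng, true[src])
            # no own-name reference entry for a novel duplicate
        elif k < n_mis:
            phantom = f"REFX{k:02d}"
            phantom_profile = _random_calls(rng, n_snps)
            panel[lid] = _mask_nocalls(rng, phantom_profile)
            ref[phantom] = _mask_nocalls(rng, phantom_profile)
            ref[lid] = _mask_nocalls(rng, true[lid])  # disagrees with panel
        else:
            panel[lid] = _mask_nocalls(rng, true[lid])
            ref[lid] = _mask_nocalls(rng, true[lid])
    snp_cols = [f"rs{j:05d}" for j in range(n_snps)]
    panel_df = pd.DataFrame.from_dict(panel, orient="index", columns=snp_cols)
    ref_df = pd.DataFrame.from_dict(ref, orient="index", columns=snp_cols)
    return panel_df.loc[ids], ref_df


# ---------------------------------------------------------------------------
# Screen registry
# ---------------------------------------------------------------------------


def _exact_cv_replicates(
    rng: np.random.Generator, mean: float, cv: float, k: int
) -> np.ndarray:
    """Replicate counts whose sample mean and sample CV (ddof=1) are exact."""
    z = rng.standard_normal(k)
    z = z - z.mean()
    sd = z.std(ddof=1)
    while sd == 0:  # pragma: no cover - measure-zero
        z = rng.standard_normal(k)
        z = z - z.mean()
        sd = z.std(ddof=1)
    z /= sd
    return mean * (1.0 + cv * z)


def gen_screen_registry(
    spec: FixtureSpec | None = None, seed: int | None = None
) -> ScreenFixture:
    """Generate the full screening-registry bundle for a fixture spec.

    Every line carries its ground-truth category in ``true_category``;
    category counts are disjoint by construction, so the exclusion cascade
    recovers them exactly.  Deterministic under (spec, seed); ``seed``
    overrides ``spec.seed`` when given.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cc = spec.category_counts
    n_dup = cc.get("redundant", 0)
    n_low = spec.n_low_expression_wt
    n_seq_mutant = cc.get("curated_mutant", 0) - n_low

    # base (non-duplicate) line ids and category assignment
    base_cats = (
        ["poor_growth_or_cv"] * cc.get("poor_growth_or_cv", 0)
        + ["no_dna"] * cc.get("no_dna", 0)
        + ["misidentified"] * cc.get("misidentified", 0)
        + ["viral"] * cc.get("viral", 0)
        + ["heterozygous"] * cc.get("heterozygous", 0)
        + ["curated_wt"] * cc.get("curated_wt", 0)
        + ["low_expression_wt"] * n_low
        + ["curated_mutant"] * n_seq_mutant
    )
    n_base = len(base_cats)
    base_ids = [f"CL{i:04d}" for i in range(n_base)]
    rng.shuffle(base_cats)
    cat_by_id = dict(zip(base_ids, base_cats))

    # redundant duplicates attach to curated parents (parent id sorts first,
    # so the cluster representative rule keeps the parent)
    curated_ids = [
        i for i in base_ids
        if cat_by_id[i] in ("curated_wt", "curated_mutant", "low_expression_wt")
    ]
    if n_dup:
        n_parents = max(1, n_dup - n_dup // 10)  # a few clusters of three
        if n_parents > len(curated_ids):
            raise ValidationError(
                "category redundant too large for the curated pool"
            )
        parents = list(rng.choice(curated_ids, size=n_parents, replace=False))
        dup_parent: dict[str, str] = {}
        suffixes = ["B", "C", "D"]
        k = 0
        while len(dup_parent) < n_dup:
            parent = parents[k % n_parents]
            taken = sum(1 for p in dup_parent.values() if p == parent)
            dup_parent[f"{parent}-{suffixes[taken]}"] = parent
            k += 1
    else:
        dup_parent = {}
    dup_ids = sorted(dup_parent)
    all_ids = base_ids + dup_ids
    for d in dup_ids:
        cat_by_id[d] = "redundant"

    # --- genotypes -------------------------------------------------------
    true_geno = {i: _random_calls(rng, spec.n_snps) for i in base_ids}
    phantoms = {}
    geno_rows, ref_rows = {}, {}
    for lid in base_ids:
        cat = cat_by_id[lid]
        if cat == "no_dna":
            geno_rows[lid] = np.array(["NC"] * spec.n_snps)
            ref_rows[lid] = _mask_nocalls(rng, true_geno[lid])
        elif cat == "misidentified":
            phantom_name = f"REFX{len(phantoms):02d}"
            profile = _random_calls(rng, spec.n_snps)
            phantoms[phantom_name] = profile
            geno_rows[lid] = _mask_nocalls(rng, profile)
            ref_rows[lid] = _mask_nocalls(rng, true_geno[lid])
        else:
            geno_rows[lid] = _mask_nocalls(rng, true_geno[lid])
            ref_rows[lid] = _mask_nocalls(rng, true_geno[lid])
    for d, parent in dup_parent.items():
        geno_rows[d] = _mask_nocalls(rng, true_geno[parent])
    for name, profile in phantoms.items():
        ref_rows[name] = _mask_nocalls(rng, profile)
    snp_cols = [f"rs{j:05d}" for j in range(spec.n_snps)]
    genotypes = pd.DataFrame.from_dict(geno_rows, orient="index", columns=snp_cols)
    reference = pd.DataFrame.from_dict(ref_rows, orient="index", columns=snp_cols)

    # --- per-line phenotype fields --------------------------------------
    records = []
    mut_rows: list[tuple[str, str, str, str, str]] = []
    params_rows = []
    viral_assigned = 0
    wt_functional_assigned = False
    special_mutant_budget = ["deletion", "deletion", "deletion",
                            "rearrangement", "silent"]

    for lid in all_ids:
        cat = cat_by_id[lid]
        tissue = _TISSUES[rng.integers(len(_TISSUES))]
        # replicate QC fields
        if cat == "poor_growth_or_cv" and rng.random() < 0.5:
            mean, cv = float(rng.uniform(600, 2000)), float(rng.uniform(0.45, 0.8))
        elif cat == "poor_growth_or_cv":
            mean, cv = float(rng.uniform(20, 120)), float(rng.uniform(0.03, 0.12))
        else:
            mean, cv = float(rng.uniform(600, 2000)), float(rng.uniform(0.03, 0.12))
        reps = _exact_cv_replicates(rng, mean, cv, spec.n_replicates)

        dna = cat != "no_dna"
        flags = dict.fromkeys(
            ["hpv16", "hpv18", "hpv31", "hpv33", "hpv45", "sv40", "e1b"], False
        )
        if cat == "viral":
            flags[["hpv16", "hpv16", "hpv16", "hpv18", "hpv18", "hpv18",
                   "sv40", "sv40"][viral_assigned % 8]] = True
            viral_assigned += 1

        # TP53 mutation calls
        if cat == "heterozygous":
            change = _NONFUNCTIONAL_MISSENSE[
                rng.integers(len(_NONFUNCTIONAL_MISSENSE))
            ]
            mut_rows.append((lid, "TP53", change, "missense", "heterozygous"))
        elif cat == "curated_mutant":
            if special_mutant_budget:
                kind = special_mutant_budget.pop()
                if kind == "deletion":
                    mut_rows.append((lid, "TP53", "E5_E8del", "deletion", "homozygous"))
                elif kind == "rearrangement":
                    mut_rows.append(
                        (lid, "TP53", "intron1_rearr", "rearrangement", "homozygous")
                    )
                else:  # silent variant that disrupts splicing
                    mut_rows.append((lid, "TP53", "T125T", "silent", "homozygous"))
            else:
                u = rng.random()
                if u < 0.65:
                    change = _NONFUNCTIONAL_MISSENSE[
                        rng.integers(len(_NONFUNCTIONAL_MISSENSE))
                    ]
                    cons = "missense"
                elif u < 0.85:
                    change, cons = _NONSENSE[rng.integers(len(_NONSENSE))], "nonsense"
                elif u < 0.95:
                    change, cons = (
                        _FRAMESHIFT[rng.integers(len(_FRAMESHIFT))], "frameshift"
                    )
                else:
                    change, cons = "X225_splice", "splice"
                mut_rows.append((lid, "TP53", change, cons, "homozygous"))
        elif cat == "curated_wt" and not wt_functional_assigned:
            # the transactivation-competent missense precedent (22Rv1-style)
            mut_rows.append((lid, "TP53", "Q331R", "missense", "homozygous"))
            wt_functional_assigned = True

        # expression and response
        if cat == "low_expression_wt":
            expr = float(rng.normal(3.0, 0.3))
        elif cat == "curated_wt":
            expr = float(rng.normal(8.0, 1.0))
        else:
            expr = float(rng.normal(7.5, 1.2))

        sensitive_cats = {"curated_wt"}
        insensitive_cats = {"curated_mutant", "low_expression_wt", "viral"}
        if cat in sensitive_cats:
            ic50 = float(10 ** rng.uniform(np.log10(0.01), np.log10(5.0)))
            censored = False
        elif cat in insensitive_cats:
            ic50, censored = 50.0, True
        elif cat == "heterozygous":
            if rng.random() < 0.5:
                ic50 = float(10 ** rng.uniform(np.log10(0.5), np.log10(20.0)))
                censored = False
            else:
                ic50, censored = 50.0, True
        else:  # excluded before response matters; arbitrary mixture
            if rng.random() < 0.3:
                ic50, censored = 50.0, True
            else:
                ic50 = float(10 ** rng.uniform(np.log10(0.01), np.log10(50.0)))
                censored = False

        # true 4PL parameters consistent with the planted response
        if censored:
            a = float(rng.normal(100, 2))
            b = float(rng.uniform(88, 99))
            c, d = float(rng.uniform(1, 30)), 1.0
        else:
            a = float(rng.normal(100, 2))
            b = float(rng.uniform(0, 8))
            c, d = ic50, float(rng.uniform(0.9, 1.6))
        params_rows.append((lid, a, b, c, d))
        auc = compute_auc(
            DoseResponse(lid, np.asarray(DEFAULT_DOSES), four_pl(
                np.asarray(DEFAULT_DOSES), a, b, c, d
            ))
        )

        records.append(
            dict(
                line_id=lid, tissue=tissue, true_category=cat,
                mean_count=float(np.mean(reps)), cv=cv, dna_available=dna,
                **flags, tp53_expression=expr, ic50_um=ic50,
                censored=censored, auc=float(auc),
                **{f"untr_rep{j + 1}": float(reps[j]) for j in range(spec.n_replicates)},
            )
        )

    order = rng.permutation(len(all_ids))
    registry = pd.DataFrame([records[i] for i in order]).reset_index(drop=True)
    mutations = pd.DataFrame(
        mut_rows,
        columns=["line_id", "gene", "protein_change", "consequence", "zygosity"],
    ).sort_values("line_id").reset_index(drop=True)
    true_params = pd.DataFrame(params_rows, columns=["line_id", "a", "b", "c", "d"])

    # --- dose-response series -------------------------------------------
    doses = np.asarray(DEFAULT_DOSES)
    poc = gen_dose_response_set(
        [tuple(r[1:]) for r in params_rows], doses, spec.poc_noise_sd,
        seed=rng.integers(2**31),
    )
    ids_in_param_order = [r[0] for r in params_rows]
    dose_poc = pd.DataFrame(
        {
            "line_id": np.repeat(ids_in_param_order, doses.size),
            "dose_um": np.tile(doses, len(ids_in_param_order)),
            "poc": poc.ravel(),
        }
    )
    veh = registry[["line_id"] + [f"untr_rep{j+1}" for j in range(spec.n_replicates)]]
    veh = veh.rename(
        columns={f"untr_rep{j+1}": f"rep{j+1}" for j in range(spec.n_replicates)}
    )
    veh_mean = veh.set_index("line_id").mean(axis=1)
    compound = dose_poc.copy()
    compound["count"] = (
        compound["poc"].to_numpy() / 100.0
        * veh_mean.loc[compound["line_id"]].to_numpy()
    )
    compound = compound[["line_id", "dose_um", "count"]]

    return ScreenFixture(
        registry=registry,
        mutations=mutations,
        genotypes=genotypes,
        reference_genotypes=reference,
        dose_poc=dose_poc,
        compound_counts=compound,
        vehicle_counts=veh.reset_index(drop=True),
        true_params=true_params,
    )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

TP53_PROBESET = "201746_at"


def gen_expression_matrix(
    registry: pd.DataFrame,
    n_probesets: int = 200,
    planted_low_tp53_lines: list[str] | None = None,
    n_shared: int = 20,
    seed: int | None = None,
    affine_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two expression batches (probe sets x lines) with a known affine shift.

    The TP53 probe set row reproduces the registry's ``tp53_expression``
    values, so planted low-expressing lines occupy a separable low region.
    ``n_shared`` lines appear in both batches; batch2 equals a per-probe-set
    affine transform of batch1 (plus optional Gaussian noise), which
    :func:`~mdm2strat.response_stratification.combine_expression_batches`
    inverts.  Returns (batch1, batch2, shared_lines).
    """
    rng = np.random.default_rng(seed)
    lines = registry["line_id"].tolist()
    if planted_low_tp53_lines:
        missing = set(planted_low_tp53_lines) - set(lines)
        if missing:
            raise ValidationError(f"planted lines not in registry: {sorted(missing)}")
        sub = registry.set_index("line_id").loc[list(planted_low_tp53_lines)]
        if not sub["censored"].astype(bool).all():
            raise ValidationError("planted low-TP53 lines must be non-responders")
    if n_shared < 20:
        logger.warning(
            "only %d shared lines requested for batch overlap; "
            "calibration will be weak", n_shared,
        )

    probes = [TP53_PROBESET] + [f"2{i:05d}_at" for i in range(1, n_probesets)]
    base = rng.normal(7.0, 1.5, size=n_probesets)[:, None] + rng.normal(
        0.0, 1.0, size=(n_probesets, len(lines))
    )
    base[0] = registry.set_index("line_id").loc[lines, "tp53_expression"].to_numpy()
    full = pd.DataFrame(base, index=probes, columns=lines)

    shuffled = list(rng.permutation(lines))
    n_b1 = max(len(lines) * 3 // 5, min(n_shared, len(lines)))
    b1_lines = shuffled[:n_b1]
    shared = sorted(b1_lines[: min(n_shared, len(b1_lines))])
    b2_only = shuffled[n_b1:]

    slope = rng.uniform(0.8, 1.25, size=n_probesets)
    intercept = rng.normal(0.0, 0.5, size=n_probesets)
    batch1 = full[b1_lines]
    b2_cols = shared + b2_only
    raw2 = full[b2_cols].to_numpy() * slope[:, None] + intercept[:, None]
    if affine_noise_sd > 0:
        raw2 = raw2 + rng.normal(0.0, affine_noise_sd, size=raw2.shape)
    batch2 = pd.DataFrame(raw2, index=probes, columns=b2_cols)
    return batch1, batch2, shared


# ---------------------------------------------------------------------------
# Tumor table and mutation matrix
# ---------------------------------------------------------------------------


def gen_tumor_cn_table(
    spec: TumorTableSpec | None = None, seed: int | None = None
) -> pd.DataFrame:
    """TCGA-like tumor table with planted mutual exclusivity.

    Samples with MDM2 copy number at or above ``true_exclusivity_cn`` never
    carry an inactivating TP53 mutation; below it, moderate gain and
    mutation co-occur at the background rate, with the mutant amplification
    tail reaching up to (but not across) the planted threshold.  A small
    fraction of samples carry transactivation-competent missense variants
    at any copy number — the functional-mutation correction removes them
    from the co-occurrence counts.  Long format, one row per mutation;
    mutation columns empty for wild-type samples.
    """
    spec = spec or TumorTableSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    types = list(spec.tumor_type_mix)
    w = np.array([spec.tumor_type_mix[t] for t in types], dtype=float)
    w /= w.sum()
    cap = float(np.log2(spec.true_exclusivity_cn / 2.0))

    rows = []
    for k in range(spec.n_samples):
        sid = f"TS{k:05d}"
        ttype = types[rng.choice(len(types), p=w)]
        inactivating = rng.random() < spec.background_mutation_rate
        if inactivating:
            if rng.random() < spec.amp_prob_mut:
                ratio = float(rng.uniform(1.0, cap - 1e-9))
            else:
                ratio = float(rng.normal(0.0, spec.diploid_log2_sd))
                ratio = min(ratio, cap - 1e-9)
            u = rng.random()
            if u < 0.7:
                change = _NONFUNCTIONAL_MISSENSE[
                    rng.integers(len(_NONFUNCTIONAL_MISSENSE))
                ]
                cons = "missense"
            elif u < 0.9:
                change, cons = _NONSENSE[rng.integers(len(_NONSENSE))], "nonsense"
            else:
                change, cons = _FRAMESHIFT[rng.integers(len(_FRAMESHIFT))], "frameshift"
            rows.append((sid, ttype, round(ratio, 4), change, cons))
        else:
            if rng.random() < spec.amp_prob_wt:
                ratio = float(rng.uniform(0.5, spec.amp_log2_max))
            else:
                ratio = float(rng.normal(0.0, spec.diploid_log2_sd))
            if rng.random() < spec.functional_missense_rate:
                rows.append((sid, ttype, round(ratio, 4), "Q331R", "missense"))
            else:
                rows.append((sid, ttype, round(ratio, 4), "", ""))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "tumor_type", "mdm2_log2_ratio",
                 "tp53_protein_change", "tp53_consequence"],
    )


def gen_mutation_matrix(
    line_ids: list[str],
    n_genes: int = 64,
    n_mutated_genes: int = 25,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binary mutation matrix (lines x genes) for the association screen.

    ``n_mutated_genes`` genes carry at least one mutant line (count
    1 + Poisson(2)); the rest are all wild-type, mirroring a targeted cancer
    gene panel where only a subset is ever mutated.  Mutations are
    independent of response by construction.
    """
    if n_mutated_genes > n_genes:
        raise ValidationError("n_mutated_genes cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = (_CANCER_GENES * (n_genes // len(_CANCER_GENES) + 1))[:n_genes]
    mat = np.zeros((len(line_ids), n_genes), dtype=int)
    mutated = rng.choice(n_genes, size=n_mutated_genes, replace=False)
    for g in mutated:
        k = min(1 + rng.poisson(2.0), max(len(line_ids) - 1, 1))
        idx = rng.choice(len(line_ids), size=k, replace=False)
        mat[idx, g] = 1
    return pd.DataFrame(mat, index=line_ids, columns=genes)
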