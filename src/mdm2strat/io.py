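"""TSV dialects shared by the pipeline stages, plus input validation.

All tables are plain tab-separated text.  Registry booleans are serialized
as True/False; genotype matrices are lines x SNPs with calls AA/AB/BB/NC.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = [
    "REGISTRY_COLUMNS",
    "MUTATION_COLUMNS",
    "TUMOR_COLUMNS",
    "read_registry",
    "read_mutations",
    "read_genotypes",
    "read_tumor_table",
    "write_tsv",
    "write_fixture",
    "validate_inputs",
]

REGISTRY_COLUMNS = [
    "line_id", "tissue", "mean_count", "cv", "dna_available",
    "hpv16", "hpv18", "hpv31", "hpv33", "hpv45", "sv40", "e1b",
    "tp53_expression", "ic50_um", "censored", "auc",
]
_REGISTRY_BOOL = ["dna_available", "hpv16", "hpv18", "hpv31", "hpv33",
                  "hpv45", "sv40", "e1b", "censored"]

MUTATION_COLUMNS = ["line_id", "gene", "protein_change", "consequence", "zygosity"]

TUMOR_COLUMNS = [
    "sample_id", "tumor_type", "mdm2_log2_ratio",
    "tp53_protein_change", "tp53_consequence",
]


def _require(df: pd.DataFrame, cols: list[str], what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} {path}: missing columns {missing}")


def _coerce_bool(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns and df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False, True: True, False: False})
        df[c] = df[c].astype(bool)
    return df


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, REGISTRY_COLUMNS, "registry", path)
    return _coerce_bool(df, _REGISTRY_BOOL)


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, MUTATION_COLUMNS, "mutation table", path)
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Genotype matrix; first column is the line name, the rest SNP calls."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df.fillna("NC")


def read_tumor_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"tp53_protein_change": str, "tp53_consequence": str},
    )
    _require(df, TUMOR_COLUMNS, "tumor table", path)
    for c in ("tp53_protein_change", "tp53_consequence"):
        df[c] = df[c].fillna("")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_fixture(fixture, out_dir) -> dict[str, Path]:
    """Write every table of a :class:`~mdm2strat.synthetic_data.ScreenFixture`."""
    out = Path(out_dir)
    paths = {}
    for name, df, index in [
        ("registry", fixture.registry, False),
        ("mutations", fixture.mutations, False),
        ("genotypes", fixture.genotypes, True),
        ("reference_genotypes", fixture.reference_genotypes, True),
        ("dose_poc", fixture.dose_poc, False),
        ("compound_counts", fixture.compound_counts, False),
        ("vehicle_counts", fixture.vehicle_counts, False),
        ("true_params", fixture.true_params, False),
    ]:
        p = out / f"{name}.tsv"
        write_tsv(df, p, index=index)
        paths[name] = p
    return paths


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema and cross-reference checks over a bundle of input TSVs.

    ``paths`` maps the table kind (registry / mutations / genotypes /
    tumor) to a file path.  Returns a list of human-readable diagnostics;
    an empty list means the bundle is consistent.
    """
    diags: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    readers = {
        "registry": read_registry,
        "mutations": read_mutations,
        "genotypes": read_genotypes,
        "tumor": read_tumor_table,
    }
    for kind, path in paths.items():
        if kind not in readers:
            diags.append(f"unknown input kind {kind!r}")
            continue
        if not Path(path).exists():
            diags.append(f"{kind}: file not found: {path}")
            continue
        try:
            tables[kind] = readers[kind](path)
        except ValidationError as exc:
            diags.append(str(exc))
        except Exception as exc:  # malformed file
            diags.append(f"{kind}: unreadable ({exc})")

    reg = tables.get("registry")
    if reg is not None:
        dups = reg["line_id"][reg["line_id"].duplicated()].tolist()
        if dups:
            diags.append(f"registry: duplicate line_id entries: {sorted(set(dups))}")
    if reg is not None and "mutations" in tables:
        unknown = set(tables["mutations"]["line_id"]) - set(reg["line_id"])
        if unknown:
            diags.append(
                f"mutations: line_ids absent from registry: {sorted(unknown)[:10]}"
            )
    if reg is not None and "genotypes" in tables:
        missing = set(reg.loc[reg["dna_available"], "line_id"]) - set(
            tables["genotypes"].index
        )
        if missing:
            diags.append(
                f"genotypes: no profile for {len(missing)} registry lines "
                f"(e.g. {sorted(missing)[:5]})"
            )
    tumor = tables.get("tumor")
    if tumor is not None:
        dupm = tumor.duplicated(
            ["sample_id", "tp53_protein_change", "tp53_consequence"]
        )
        if dupm.any():
            diags.append(f"tumor: {int(dupm.sum())} duplicated mutation rows")
    return diags
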