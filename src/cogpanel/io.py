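"""Readers and writers for the panel's tabular interchange formats.

Phenotypes travel as tidy CSV (animal_id, strain, sex, age_months, trait,
value); genotypes as a GeneNetwork-style TSV (marker, chromosome,
position_cM, then one column per strain with B = B6/B6 homozygote and
H = B6/D2 heterozygote); expression as a genes x strains TSV. All writers
emit deterministically ordered, plain-text output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .simulate import GenotypeMatrix

PHENO_COLUMNS = ["animal_id", "strain", "sex", "age_months", "trait", "value"]
GENO_CODES = {0: "B", 1: "H"}
GENO_DECODE = {"B": 0, "H": 1}


def write_phenotypes(records: pd.DataFrame, path: str | Path) -> None:
    out = records[PHENO_COLUMNS].sort_values(
        ["trait", "strain", "age_months", "animal_id"]
    )
    out.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} missing columns: {missing}")
    bad = df[(df["value"] < 0) | (df["value"] > 100)]
    if len(bad):
        raise ValueError(
            f"phenotype file {path}: {len(bad)} values outside [0, 100]"
        )
    return df


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    coded = geno.calls.replace(GENO_CODES)
    out = geno.map.copy()
    for strain in geno.strains:
        out[strain] = coded[strain].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["marker", "chromosome", "position_cM"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"genotype file {path} missing columns: {missing}")
    strains = [c for c in df.columns if c not in meta]
    calls = df[strains].apply(lambda col: col.map(GENO_DECODE))
    if calls.isna().any().any():
        raise ValueError(f"genotype file {path}: codes must be B or H")
    calls.index = df["marker"]
    return GenotypeMatrix(map=df[meta].copy(), calls=calls.astype("int8"))


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.sort_index().to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def read_module_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"gene", "module"} <= set(df.columns):
        raise ValueError(f"module file {path} needs 'gene' and 'module' columns")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
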