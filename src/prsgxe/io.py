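"""Tab-delimited readers/writers for the three standard input tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import InvalidInputError
from .scoring import WEIGHT_COLUMNS, validate_weight_table


def read_weight_table(path) -> pd.DataFrame:
    """Weight table TSV: ``variant_id chrom pos effect_allele weight pvalue``."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_weight_table(table)


def write_weight_table(weights: pd.DataFrame, path) -> None:
    validate_weight_table(weights)
    weights.loc[:, WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dosages(path) -> pd.DataFrame:
    """Dosage TSV: first column ``sample_id``, then one column per variant."""
    table = pd.read_csv(path, sep="\t")
    if table.columns[0] != "sample_id":
        raise InvalidInputError("dosage table must start with a 'sample_id' column")
    table = table.set_index("sample_id")
    if table.index.duplicated().any():
        raise InvalidInputError("duplicate sample ids in dosage table")
    vals = table.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 2)).any():
        raise InvalidInputError("dosages must lie in [0, 2]")
    return table


def write_dosages(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV with a ``sample_id`` column; categorical dtypes restored lazily."""
    table = pd.read_csv(path, sep="\t")
    if "sample_id" not in table.columns:
        raise InvalidInputError("phenotype table must contain a 'sample_id' column")
    return table.set_index("sample_id")


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=True, index_label="sample_id")


def write_tsv(table: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)
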