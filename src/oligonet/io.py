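"""Plain-text I/O: TSV matrices and tables, GMT gene sets, JSON manifests."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .annotation import ANNOTATION_COLUMNS


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV (gene ids in the first column).

    Floats use %.17g so a reloaded matrix is bit-identical to the one in
    memory (stage resumption must not perturb downstream results).
    """
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.reset_index()[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"categories": str})
    table["categories"] = table["categories"].fillna("")
    return table.set_index("gene_id")


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    """Write gene sets in GMT format (name, description, members...)."""
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = fields[2:]
    return sets


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
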