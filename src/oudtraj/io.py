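"""Readers and writers for the plain-text interchange formats.

Events and truth tables are tab-delimited with headers; pathways use the
standard GMT layout (set name, description, then member genes, all
tab-separated); gene-evidence and drug-target tables are TSVs where an empty
cell means "absent".
"""

from __future__ import annotations

import math

import pandas as pd

from .kg.weights import DrugTargetEvidence, GeneEvidence


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"concept_id": str, "domain": str})
    df["day"] = df["day"].astype(int)
    return df


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["event_day"] = df["event_day"].astype("Int64")
    return df


def write_gmt(pathways, path) -> None:
    """``pathways`` is an iterable of ``(name, description, members)``."""
    with open(path, "w", newline="\n") as fh:
        for name, desc, members in pathways:
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append((parts[0], parts[1], [p for p in parts[2:] if p]))
    return out


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value is pd.NA:
        return None
    return cast(value)


def read_gene_evidence(path) -> list[GeneEvidence]:
    """TSV columns: gene, r_rep, flag_mvp, flag_oud_only, flag_mtag, posterior, p_rank."""
    df = pd.read_csv(path, sep="\t")
    return gene_evidence_from_frame(df)


def gene_evidence_from_frame(df: pd.DataFrame) -> list[GeneEvidence]:
    out = []
    for row in df.to_dict("records"):
        out.append(
            GeneEvidence(
                gene=str(row["gene"]),
                r_rep=_opt(row.get("r_rep"), int),
                flag_mvp=bool(_opt(row.get("flag_mvp"), int) or 0),
                flag_oud_only=bool(_opt(row.get("flag_oud_only"), int) or 0),
                flag_mtag=bool(_opt(row.get("flag_mtag"), int) or 0),
                posterior=_opt(row.get("posterior"), float),
                p_rank=_opt(row.get("p_rank"), int),
            )
        )
    return out


def read_drug_targets(path) -> list[DrugTargetEvidence]:
    """TSV columns: gene, drug_id, drug_name, pchembl, ant, ago, ph3, app, bbb, res."""
    df = pd.read_csv(path, sep="\t")
    return drug_targets_from_frame(df)


def drug_targets_from_frame(df: pd.DataFrame) -> list[DrugTargetEvidence]:
    out = []
    for row in df.to_dict("records"):
        out.append(
            DrugTargetEvidence(
                gene=str(row["gene"]),
                drug_id=str(row["drug_id"]),
                drug_name=str(row["drug_name"]),
                pchembl=_opt(row.get("pchembl"), float),
                ant=_opt(row.get("ant"), int) or 0,
                ago=_opt(row.get("ago"), int) or 0,
                ph3=_opt(row.get("ph3"), int) or 0,
                app=_opt(row.get("app"), int) or 0,
                bbb=_opt(row.get("bbb"), int) or 0,
                res=_opt(row.get("res"), int) or 0,
            )
        )
    return out
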