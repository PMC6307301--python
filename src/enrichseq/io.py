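"""Tabular and sequence I/O: count tables, sample metadata, taxonomy, FASTA.

All on-disk formats are plain text: TSV for tables, FASTA for sequences,
JSON for ground truth and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class ConsistencyError(ValueError):
    """Inputs that should describe the same entities disagree."""


@dataclass
class CountMatrix:
    """Feature x sample table of non-negative integer read counts.

    ``counts`` is a pandas DataFrame (rows = feature ids, columns = sample
    ids); ``meta`` is indexed by sample id with columns ``source``, ``day``
    and ``molecule`` (DNA or RNA).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        if self.meta is not None:
            missing = set(self.counts.columns) - set(self.meta.index)
            if missing:
                raise ConsistencyError(
                    f"samples missing from metadata: {sorted(missing)}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[sample_id].to_numpy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        meta = self.meta.loc[ids] if self.meta is not None else None
        return CountMatrix(self.counts[ids].copy(), meta)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata match all keyword conditions."""
        if self.meta is None:
            raise ConsistencyError("count matrix has no sample metadata")
        mask = pd.Series(True, index=self.meta.index)
        for key, value in conditions.items():
            mask &= self.meta[key] == value
        return list(self.meta.index[mask])

    def write_tsv(self, counts_path, meta_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        if meta_path is not None and self.meta is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, counts_path, meta_path=None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
        return cls(counts, meta)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV -> DataFrame indexed by feature id with the 7 rank columns.

    Accepts either one semicolon-joined ``lineage`` column or seven rank
    columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "lineage" in df.columns:
        return split_lineages(df["lineage"])
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ConsistencyError(f"taxonomy table lacks rank columns: {missing}")
    return df[list(RANKS)]


def split_lineages(lineages: pd.Series) -> pd.DataFrame:
    parts = lineages.str.split(";", expand=True)
    parts = parts.reindex(columns=range(len(RANKS)))
    parts.columns = list(RANKS)
    return parts.apply(lambda c: c.str.strip())


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out["lineage"] = out[list(RANKS)].agg(";".join, axis=1)
    out[["lineage"]].to_csv(path, sep="\t", index_label="feature_id")
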