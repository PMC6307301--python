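"""Degree-of-enrichment and RNA:DNA activity statistics.

Two pseudocounted ratios drive the analysis of why enrichment culturing
recovers "uncultured" strains:

* the **enrichment ratio** (a_t + 1) / (a_0 + 1) between a species'
  recruited read count at its isolation stage and at day 0 — a ratio
  strictly > 1 means the species was abundance-enriched when isolated;
* the **activity ratio** (16S rRNA reads + 1) / (16S rRNA gene reads + 1)
  of a taxon in one sample — strictly > 1 classifies the taxon as
  metabolically active, <= 1 as dormant.

The +1 pseudocount guards against zero day-0 or DNA abundances: a detected
or isolated species must carry at least one latent read.  Both boundaries
are strict: a ratio of exactly 1 is *not* enriched / *not* active.
Counts entering either ratio must come from libraries rarefied to a common
depth (per molecule for the activity ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ConsistencyError, CountMatrix, RANKS
from .recruitment import RecruitmentProfile


def enrichment_ratio(a_t: int, a_0: int) -> float:
    """(a_t + 1) / (a_0 + 1), the pseudocounted degree of enrichment."""
    if a_t < 0 or a_0 < 0:
        raise ValueError("read counts must be non-negative")
    return (a_t + 1) / (a_0 + 1)


def activity_ratio(rna: int, dna: int) -> float:
    """(rna + 1) / (dna + 1), the 16S rRNA : rRNA gene activity ratio."""
    if rna < 0 or dna < 0:
        raise ValueError("read counts must be non-negative")
    return (rna + 1) / (dna + 1)


def classify_active(ratio: float) -> bool:
    """Active iff the activity ratio is strictly greater than 1."""
    return ratio > 1.0


@dataclass
class EnrichmentRecord:
    """Per-species, per-source enrichment time course."""

    species_id: str
    source: str
    a_0: int
    a_t: dict[int, int]             # day -> recruited reads
    isolation_day: int
    ratio_t: dict[int, float]
    enriched_at_isolation: bool


def classify_enrichment(
    profiles: Iterable[RecruitmentProfile],
    isolate_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
    molecule: str = "DNA",
) -> tuple[list[EnrichmentRecord], dict[str, float]]:
    """Build enrichment records and the not-enriched summary.

    ``isolate_meta`` is indexed by isolate id with ``source`` and
    ``isolation_day`` columns; ``sample_meta`` maps sample ids to (source,
    day, molecule).  One record is produced per (isolate, source); the
    summary fraction counts species isolated *after* enrichment (isolation
    day > 0) whose ratio at the isolation day is <= 1.
    """
    sm = sample_meta[sample_meta["molecule"] == molecule]
    records = []
    for profile in profiles:
        if profile.isolate_id not in isolate_meta.index:
            raise ConsistencyError(f"no metadata for isolate {profile.isolate_id}")
        info = isolate_meta.loc[profile.isolate_id]
        source = info["source"]
        day_samples = sm[sm["source"] == source]
        day0_ids = list(day_samples.index[day_samples["day"] == 0])
        if not day0_ids:
            raise ConsistencyError(f"source {source} lacks a day-0 {molecule} sample")
        a_0 = sum(profile.counts_per_sample.get(s, 0) for s in day0_ids)
        a_t, ratio_t = {}, {}
        for day in sorted(day_samples["day"].unique()):
            ids = list(day_samples.index[day_samples["day"] == day])
            reads = sum(profile.counts_per_sample.get(s, 0) for s in ids)
            a_t[int(day)] = reads
            ratio_t[int(day)] = enrichment_ratio(reads, a_0)
        iso_day = int(info["isolation_day"])
        if iso_day not in ratio_t:
            raise ConsistencyError(
                f"{profile.isolate_id}: no {molecule} sample at isolation day {iso_day}"
            )
        records.append(
            EnrichmentRecord(
                species_id=profile.isolate_id,
                source=source,
                a_0=a_0,
                a_t=a_t,
                isolation_day=iso_day,
                ratio_t=ratio_t,
                enriched_at_isolation=ratio_t[iso_day] > 1.0,
            )
        )
    post = [r for r in records if r.isolation_day > 0]
    n_not = sum(not r.enriched_at_isolation for r in post)
    summary = {
        "n_species": float(len(records)),
        "n_isolated_after_enrichment": float(len(post)),
        "n_not_enriched": float(n_not),
        "frac_not_enriched": n_not / len(post) if post else float("nan"),
    }
    return records, summary


def enrichment_records_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for day, reads in sorted(r.a_t.items()):
            rows.append(
                {
                    "species_id": r.species_id,
                    "source": r.source,
                    "day": day,
                    "a_0": r.a_0,
                    "a_t": reads,
                    "ratio": r.ratio_t[day],
                    "isolation_day": r.isolation_day,
                    "enriched_at_isolation": r.enriched_at_isolation,
                }
            )
    return pd.DataFrame(rows)


def _pair_samples(
    rna_meta: pd.DataFrame, dna_meta: pd.DataFrame
) -> list[tuple[str, str, str, int]]:
    """Match RNA and DNA samples on (source, day); error on unpaired RNA."""
    dna_lookup = {
        (row["source"], row["day"]): sid for sid, row in dna_meta.iterrows()
    }
    pairs = []
    for sid, row in rna_meta.iterrows():
        key = (row["source"], row["day"])
        if key not in dna_lookup:
            raise ConsistencyError(f"RNA sample {sid} has no DNA partner {key}")
        pairs.append((sid, dna_lookup[key], row["source"], int(row["day"])))
    return pairs


def aggregate_activity(
    rna_counts: CountMatrix,
    dna_counts: CountMatrix,
    taxonomy: pd.DataFrame | None = None,
    rank: str = "otu",
) -> pd.DataFrame:
    """Per-taxon activity ratios for every paired (source, day) sample.

    Reads are summed within each taxon at ``rank`` *before* the +1 ratio
    (sum-then-ratio), so rank-level ratios equal the ratio of the rank's
    marginal counts.  ``rank="otu"`` keeps features as-is.  Emits the
    log10 ratio alongside for plotting.
    """
    if rank != "otu":
        if taxonomy is None:
            raise ValueError(f"a taxonomy table is required for rank={rank!r}")
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        missing = set(rna_counts.feature_ids) - set(taxonomy.index)
        if missing:
            raise ConsistencyError(
                f"taxonomy lacks features: {sorted(missing)[:5]}"
            )
    pairs = _pair_samples(
        rna_counts.meta[rna_counts.meta["molecule"] == "RNA"],
        dna_counts.meta[dna_counts.meta["molecule"] == "DNA"],
    )
    rows = []
    for rna_id, dna_id, source, day in pairs:
        rna = rna_counts.counts[rna_id]
        dna = dna_counts.counts[dna_id]
        if rank == "otu":
            grouped = pd.DataFrame({"rna": rna, "dna": dna})
        else:
            groups = taxonomy.loc[rna.index, rank].fillna("unclassified")
            grouped = pd.DataFrame({"rna": rna, "dna": dna}).groupby(groups).sum()
        for taxon, row in grouped.iterrows():
            ratio = activity_ratio(int(row["rna"]), int(row["dna"]))
            rows.append(
                {
                    "taxon": taxon,
                    "source": source,
                    "day": day,
                    "rna": int(row["rna"]),
                    "dna": int(row["dna"]),
                    "ratio": ratio,
                    "log10_ratio": float(np.log10(ratio)),
                    "active": classify_active(ratio),
                }
            )
    return pd.DataFrame(rows)


def proportion_active(
    activity: pd.DataFrame, weight: str = "taxa"
) -> pd.DataFrame:
    """Fraction of present taxa called active, per (source, day) group.

    A taxon is present when rna + dna > 0.  ``weight="taxa"`` counts taxa;
    ``weight="reads"`` weights each taxon by its total reads.  A mean
    across sources is appended per day (source = "mean").
    """
    present = activity[(activity["rna"] + activity["dna"]) > 0]
    if present.empty:
        raise ValueError("no taxa present in any group")
    rows = []
    for (source, day), grp in present.groupby(["source", "day"]):
        if weight == "taxa":
            prop = grp["active"].mean()
        elif weight == "reads":
            w = grp["rna"] + grp["dna"]
            prop = float((grp["active"] * w).sum() / w.sum())
        else:
            raise ValueError("weight must be 'taxa' or 'reads'")
        rows.append({"source": source, "day": day, "proportion_active": float(prop)})
    table = pd.DataFrame(rows)
    means = (
        table.groupby("day")["proportion_active"]
        .mean()
        .reset_index()
        .assign(source="mean")
    )
    return pd.concat([table, means], ignore_index=True)[
        ["source", "day", "proportion_active"]
    ]
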