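"""Cofactor pathway-completeness screen: prototroph vs auxotroph calls and
syntrophic donor-recipient nomination.

A genome is scored against an ordered list of core biosynthesis genes; a
complete core (by default, every gene) makes it a prototroph, otherwise the
presence of a salvage transporter downgrades it to an auxotroph that can
scavenge the cofactor.  Prototroph groups positively associated with
auxotroph groups in the co-occurrence network are nominated as potential
cofactor donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

PROTOTROPH = "prototroph"
AUXOTROPH_SALVAGE = "auxotroph_salvage"
AUXOTROPH = "auxotroph"


@dataclass
class PathwayDef:
    """Ordered core-gene definition of one cofactor biosynthesis pathway."""

    name: str
    core_synthesis_genes: list[str]
    salvage_transporters: list[str] = field(default_factory=list)
    ligase: str | None = None

    def __post_init__(self) -> None:
        if not self.core_synthesis_genes:
            raise ValueError(f"pathway {self.name!r} has no core genes")
        seen = (
            self.core_synthesis_genes
            + self.salvage_transporters
            + ([self.ligase] if self.ligase else [])
        )
        if len(set(seen)) != len(seen):
            raise ValueError(f"pathway {self.name!r} lists duplicate gene symbols")


def biotin_pathway() -> PathwayDef:
    """De novo biotin synthesis (bioC->bioB) with the BioYM ECF salvage
    transporter; birA (biotin-protein ligase) is tracked but not scored."""
    return PathwayDef(
        name="biotin",
        core_synthesis_genes=["bioC", "bioH", "bioF", "bioA", "bioD", "bioB"],
        salvage_transporters=["bioY", "bioM"],
        ligase="birA",
    )


def cobalamin_pathway() -> PathwayDef:
    """Anaerobic corrinoid (vitamin B12) biosynthesis.

    This ~20-symbol gene list is an editorial default drawn from the
    standard anaerobic cobalamin route (cysG/cbi/cob), not a published
    per-study set; swap in your own definition for serious use.
    """
    return PathwayDef(
        name="cobalamin",
        core_synthesis_genes=[
            "cysG", "cbiK", "cbiL", "cbiH", "cbiF", "cbiG", "cbiD",
            "cbiJ", "cbiE", "cbiT", "cbiC", "cbiA", "cbiB", "cobD",
            "cobQ", "cobO", "cobU", "cobS", "cobT", "cobC",
        ],
        salvage_transporters=["btuB", "btuF", "btuC", "btuD"],
    )


def default_pathways() -> list[PathwayDef]:
    return [biotin_pathway(), cobalamin_pathway()]


def read_pathways_yaml(path) -> list[PathwayDef]:
    raw = yaml.safe_load(open(path))
    return [
        PathwayDef(
            name=entry["name"],
            core_synthesis_genes=list(entry["core_synthesis_genes"]),
            salvage_transporters=list(entry.get("salvage_transporters", [])),
            ligase=entry.get("ligase"),
        )
        for entry in raw["pathways"]
    ]


def write_pathways_yaml(pathways: Iterable[PathwayDef], path) -> None:
    payload = {
        "pathways": [
            {
                "name": p.name,
                "core_synthesis_genes": p.core_synthesis_genes,
                "salvage_transporters": p.salvage_transporters,
                **({"ligase": p.ligase} if p.ligase else {}),
            }
            for p in pathways
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _is_present(presence: Mapping[str, object], gene: str) -> bool:
    return bool(presence.get(gene, 0))


def completeness(
    presence: Mapping[str, object], pathway: PathwayDef
) -> tuple[float, list[str]]:
    """Fraction of core genes present and the missing genes in pathway order.

    ``presence`` maps gene symbol -> truthy/falsy; unlisted genes count as
    absent.
    """
    core = pathway.core_synthesis_genes
    missing = [g for g in core if not _is_present(presence, g)]
    return (len(core) - len(missing)) / len(core), missing


def classify_trophy(
    presence: Mapping[str, object],
    pathway: PathwayDef,
    prototroph_min: float = 1.0,
) -> str:
    """Prototroph iff completeness >= prototroph_min; otherwise a salvage
    transporter makes the genome an auxotroph_salvage, else auxotroph."""
    score, _ = completeness(presence, pathway)
    if score >= prototroph_min:
        return PROTOTROPH
    if any(_is_present(presence, g) for g in pathway.salvage_transporters):
        return AUXOTROPH_SALVAGE
    return AUXOTROPH


def screen_genomes(
    presence_table: pd.DataFrame,
    pathways: Iterable[PathwayDef],
    prototroph_min: float = 1.0,
    group_column: str = "family",
) -> pd.DataFrame:
    """Trophy table: one row per (genome, pathway) with score and class."""
    pathways = list(pathways)
    rows = []
    for genome, row in presence_table.iterrows():
        presence = row.to_dict()
        group = str(presence.pop(group_column, "unclassified"))
        for pw in pathways:
            score, missing = completeness(presence, pw)
            rows.append(
                {
                    "genome_id": genome,
                    "group": group,
                    "cofactor": pw.name,
                    "completeness": score,
                    "missing": ",".join(missing),
                    "trophy": classify_trophy(presence, pw, prototroph_min),
                }
            )
    return pd.DataFrame(rows)


def syntrophy_candidates(
    trophy: pd.DataFrame, associations: pd.DataFrame
) -> pd.DataFrame:
    """Donor -> recipient pairs supported by positive group associations.

    For every association with net_sign == "positive", a (donor group,
    recipient group, cofactor) row is emitted whenever one side holds a
    prototroph genome and the other an auxotroph (salvage or not) for that
    cofactor.  Negative or mixed associations never yield candidates;
    association groups with no screened genome are skipped with a warning.
    """
    import warnings

    by_group: dict[tuple[str, str], set[str]] = {}
    for _, row in trophy.iterrows():
        by_group.setdefault((row["group"], row["cofactor"]), set()).add(row["trophy"])

    cofactors = sorted(trophy["cofactor"].unique())
    rows = []
    for _, assoc in associations.iterrows():
        if assoc["net_sign"] != "positive":
            continue
        ga, gb = assoc["group_a"], assoc["group_b"]
        for cofactor in cofactors:
            ta = by_group.get((ga, cofactor))
            tb = by_group.get((gb, cofactor))
            if ta is None or tb is None:
                unmapped = ga if ta is None else gb
                warnings.warn(f"no screened genome for group {unmapped!r}; pair skipped")
                continue
            for donor, d_classes, recipient, r_classes in (
                (ga, ta, gb, tb),
                (gb, tb, ga, ta),
            ):
                if PROTOTROPH in d_classes and (
                    AUXOTROPH in r_classes or AUXOTROPH_SALVAGE in r_classes
                ):
                    rows.append(
                        {
                            "donor_group": donor,
                            "recipient_group": recipient,
                            "cofactor": cofactor,
                        }
                    )
    return pd.DataFrame(rows, columns=["donor_group", "recipient_group", "cofactor"])
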