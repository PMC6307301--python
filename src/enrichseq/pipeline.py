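"""One-shot orchestration: simulate -> recruit -> diversity -> ratios ->
network -> trophy, with a YAML config, per-stage seeds and a manifest.

Every stage writes into its own subdirectory of the run's output directory
and never touches another stage's outputs.  A single global seed is fanned
out to per-stage child seeds by stable hashing, so enabling or disabling
one stage does not reshuffle the randomness of the others.  The manifest
records every parameter (with provenance: study default vs user override),
the seed, and a sha256 checksum of every output file; identical config and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import culturability, diversity, network, pathways, recruitment, synthetic
from .io import CountMatrix

ALL_STAGES = (
    "simulate",
    "recruit",
    "diversity",
    "enrichment",
    "activity",
    "network",
    "trophy",
)

# parameters whose defaults are the original study's stated values
STUDY_DEFAULTS = {
    "recruit.min_identity": 0.99,
    "rarefaction.depth": "min",
    "enrichment.boundary": "ratio > 1",
    "activity.boundary": "ratio > 1",
    "network.threshold": 0.7,
    "network.max_zeros": 2,
    "network.majority": 1,
}


def _default_params() -> dict:
    return {
        "simulate": {},
        "recruit": {"min_identity": 0.99, "min_overlap": 200},
        "rarefaction": {"depth": "min"},
        "enrichment": {"boundary": "ratio > 1"},
        "activity": {"boundary": "ratio > 1", "rank": "family"},
        "network": {"threshold": 0.7, "max_zeros": 2, "majority": 1, "min_pairs": 9},
        "trophy": {"prototroph_min": 1.0, "pathways_file": None},
    }


@dataclass
class RunConfig:
    """Validated pipeline configuration with study-value defaults."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    overrides: dict = field(default_factory=dict)
    params: dict = field(init=False)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        merged = _default_params()
        for stage, values in self.overrides.items():
            if stage not in merged:
                raise ValueError(f"unknown config section {stage!r}")
            merged[stage].update(values)
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        return cls(
            outdir=raw.get("outdir", "enrichseq_run"),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            overrides={
                k: v
                for k, v in raw.items()
                if k not in ("outdir", "seed", "stages")
            },
        )

    def provenance(self) -> dict[str, str]:
        out = {}
        for stage, values in self.params.items():
            for key, value in values.items():
                dotted = f"{stage}.{key}"
                if dotted in STUDY_DEFAULTS:
                    tag = (
                        "study_default"
                        if value == STUDY_DEFAULTS[dotted]
                        else "user_override"
                    )
                else:
                    tag = "package_default"
                out[dotted] = tag
        return out


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {k: v for k, v in sorted(_flatten(p).items())},
        "provenance": config.provenance(),
        "outputs": {},
    }

    def register(stage: str, directory: Path) -> None:
        manifest["outputs"][stage] = {
            f.name: _sha256(f) for f in sorted(directory.iterdir()) if f.is_file()
        }

    needs_upstream = [s for s in config.stages if s != "simulate"]
    if needs_upstream and "simulate" not in config.stages:
        raise ValueError(
            f"stage {needs_upstream[0]!r} requires outputs of stage 'simulate'"
        )

    dataset = None
    rarefied_dna = rarefied_rna = None
    net = assoc = None

    if "simulate" in config.stages:
        sim_dir = outdir / "simulate"
        sim_kwargs = dict(p.get("simulate", {}))
        sim_kwargs.pop("rng_seed", None)
        sim_params = synthetic.SimParams(
            **sim_kwargs, rng_seed=stage_seed(config.seed, "simulate")
        )
        dataset = synthetic.simulate_dataset(sim_params)
        dataset.write(sim_dir)
        register("simulate", sim_dir)

    if dataset is not None and set(config.stages) - {"simulate"}:
        rseed = stage_seed(config.seed, "rarefaction")
        depth = p["rarefaction"]["depth"]
        rarefied_dna = diversity.rarefy(dataset.counts_dna, depth, rseed)
        rarefied_rna = diversity.rarefy(dataset.counts_rna, depth, rseed + 1)

    if "diversity" in config.stages:
        div_dir = outdir / "diversity"
        div_dir.mkdir(exist_ok=True)
        rarefied_dna.write_tsv(div_dir / "rarefied_dna.tsv")
        rarefied_rna.write_tsv(div_dir / "rarefied_rna.tsv")
        diversity.alpha_diversity(rarefied_dna).write_tsv(div_dir / "alpha.tsv")
        diversity.novel_otu_gain_by_source(rarefied_dna).to_csv(
            div_dir / "novel_otu_gain.tsv", sep="\t"
        )
        register("diversity", div_dir)

    profiles = None
    if "recruit" in config.stages or "enrichment" in config.stages:
        rec_dir = outdir / "recruit"
        rec_dir.mkdir(exist_ok=True)
        isolates = [
            recruitment.IsolateSeq(
                iso, seq,
                isolation_day=int(dataset.isolate_meta.loc[iso, "isolation_day"]),
                source=dataset.isolate_meta.loc[iso, "source"],
            )
            for iso, seq in dataset.isolates.items()
        ]
        profiles = recruitment.recruit_all(
            isolates,
            dataset.references,
            rarefied_dna,
            min_identity=p["recruit"]["min_identity"],
            min_overlap=p["recruit"]["min_overlap"],
        )
        recruitment.profiles_to_frame(profiles).to_csv(
            rec_dir / "recruitment.tsv", sep="\t", index_label="isolate_id"
        )
        recruitment.match_details_frame(profiles).to_csv(
            rec_dir / "match_details.tsv", sep="\t", index=False
        )
        register("recruit", rec_dir)

    if "enrichment" in config.stages:
        enr_dir = outdir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        records, summary = culturability.classify_enrichment(
            profiles, dataset.isolate_meta, rarefied_dna.meta
        )
        culturability.enrichment_records_frame(records).to_csv(
            enr_dir / "enrichment.tsv", sep="\t", index=False
        )
        (enr_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        register("enrichment", enr_dir)

    if "activity" in config.stages:
        act_dir = outdir / "activity"
        act_dir.mkdir(exist_ok=True)
        activity = culturability.aggregate_activity(
            rarefied_rna, rarefied_dna, dataset.taxonomy, rank=p["activity"]["rank"]
        )
        activity.to_csv(act_dir / "activity.tsv", sep="\t", index=False)
        culturability.proportion_active(activity).to_csv(
            act_dir / "proportion_active.tsv", sep="\t", index=False
        )
        register("activity", act_dir)

    if "network" in config.stages:
        net_dir = outdir / "network"
        net_dir.mkdir(exist_ok=True)
        dna = rarefied_dna.subset_samples(
            rarefied_dna.samples_where(molecule="DNA")
        )
        filtered = network.filter_features(
            dna, p["network"]["max_zeros"], p["network"]["majority"]
        )
        net = network.build_network(
            filtered,
            threshold=p["network"]["threshold"],
            min_pairs=p["network"]["min_pairs"],
            taxonomy=dataset.taxonomy,
        )
        net.write(
            net_dir / "edges.tsv", net_dir / "nodes.tsv", net_dir / "network.graphml"
        )
        assoc, isolated = network.group_associations(net, dataset.taxonomy)
        assoc.to_csv(net_dir / "family_associations.tsv", sep="\t", index=False)
        (net_dir / "isolated_groups.txt").write_text("\n".join(isolated) + "\n")
        register("network", net_dir)

    if "trophy" in config.stages:
        tro_dir = outdir / "trophy"
        tro_dir.mkdir(exist_ok=True)
        pw_file = p["trophy"]["pathways_file"]
        pws = (
            pathways.read_pathways_yaml(pw_file)
            if pw_file
            else pathways.default_pathways()
        )
        presence, planted = _presence_table(dataset, pws, config.seed)
        trophy = pathways.screen_genomes(
            presence, pws, prototroph_min=p["trophy"]["prototroph_min"]
        )
        trophy.to_csv(tro_dir / "trophy.tsv", sep="\t", index=False)
        if assoc is None:
            raise ValueError(
                "stage 'trophy' requires outputs of stage 'network'"
            )
        candidates = pathways.syntrophy_candidates(trophy, assoc)
        candidates.to_csv(tro_dir / "syntrophy_candidates.tsv", sep="\t", index=False)
        register("trophy", tro_dir)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _presence_table(dataset, pws, seed):
    """Synthetic gene-presence tables planted on the simulated families:
    planted-edge driver families are prototrophs, their followers salvage
    auxotrophs."""
    families = sorted(dataset.taxonomy["family"].unique())
    drivers = [
        dataset.taxonomy.loc[a, "family"] for a, _, s in dataset.truth.planted_edges
    ]
    followers = [
        dataset.taxonomy.loc[b, "family"]
        for _, b, s in dataset.truth.planted_edges
        if s > 0
    ]
    return synthetic.generate_genome_tables(
        families,
        {pw.name: pw.core_synthesis_genes for pw in pws},
        {pw.name: pw.salvage_transporters or ["none"] for pw in pws},
        prototroph_families=drivers,
        salvage_families=followers,
        rng_seed=stage_seed(seed, "trophy"),
    )


def _flatten(params: dict) -> dict:
    out = {}
    for stage, values in params.items():
        for key, value in values.items():
            out[f"{stage}.{key}"] = value
    return out
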