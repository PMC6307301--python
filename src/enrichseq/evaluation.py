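"""Truth-recovery evaluation of the classifiers on simulated datasets.

Given a simulated experiment with planted ground truth, these helpers run
the real analysis chain (recruitment -> enrichment ratios, paired
RNA:DNA ratios, co-occurrence network) and score it against the truth:
balanced accuracy for the enriched/not and active/dormant calls, and the
fraction of seeds in which planted family associations come back with the
correct net sign.

Evaluation is restricted to taxa at detectable relative abundance
(default >= 1%): below that, a handful of multinomial reads cannot carry a
ratio signal in either direction.  Planted correlation-pair taxa are
excluded from the *enrichment* score because their abundance fluctuates by
design, so a per-day enriched/not truth label is not defined for them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import network as network_mod
from .culturability import aggregate_activity, classify_enrichment
from .io import CountMatrix
from .recruitment import IsolateSeq, recruit_all
from .synthetic import SimDataset, SimParams, simulate_dataset


def _balanced(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    tpr = tp / (tp + fn) if tp + fn else float("nan")
    tnr = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "balanced_accuracy": (tpr + tnr) / 2,
        "tpr": tpr,
        "tnr": tnr,
        "n": float(tp + tn + fp + fn),
    }


def recruit_isolates(
    dataset: SimDataset, counts: CountMatrix, **recruit_kwargs
) -> list:
    """Run the recruitment matcher for every simulated isolate."""
    isolates = [
        IsolateSeq(
            iso, seq,
            isolation_day=int(dataset.isolate_meta.loc[iso, "isolation_day"]),
            source=dataset.isolate_meta.loc[iso, "source"],
        )
        for iso, seq in dataset.isolates.items()
    ]
    return recruit_all(isolates, dataset.references, counts, **recruit_kwargs)


def enrichment_truth_recovery(
    dataset: SimDataset,
    profiles: list,
    counts: CountMatrix,
    min_abundance: float = 0.01,
) -> dict[str, float]:
    """Balanced accuracy of the enriched/not call against planted truth.

    The classifier is run per source (every isolate is assessed in every
    sediment source) and scored on (taxon, source, day > 0) cells whose
    latent abundance reaches ``min_abundance`` at either endpoint.
    """
    params = dataset.params
    truth = dataset.truth
    planted = {t for a, b, _ in truth.planted_edges for t in (a, b)}
    taxon_index = {t: i for i, t in enumerate(params.taxon_ids)}
    days = list(params.days)
    tp = tn = fp = fn = 0
    for si, source in enumerate(params.source_ids):
        iso_meta = dataset.isolate_meta.copy()
        iso_meta["source"] = source
        records, _ = classify_enrichment(profiles, iso_meta, counts.meta)
        for record in records:
            taxon = truth.isolate_to_taxon[record.species_id]
            if taxon in planted:
                continue
            ti = taxon_index[taxon]
            for day, ratio in record.ratio_t.items():
                if day == days[0]:
                    continue
                di = days.index(day)
                reach = max(
                    dataset.latent[ti, si, di], dataset.latent[ti, si, 0]
                )
                if reach < min_abundance:
                    continue
                predicted = ratio > 1.0
                actual = bool(truth.true_enriched.loc[taxon, day])
                tp += actual and predicted
                fn += actual and not predicted
                fp += (not actual) and predicted
                tn += (not actual) and not predicted
    return _balanced(tp, tn, fp, fn)


def activity_truth_recovery(
    dataset: SimDataset, min_abundance: float = 0.01
) -> dict[str, float]:
    """Balanced accuracy of the active/dormant call against planted truth."""
    params = dataset.params
    table = aggregate_activity(dataset.counts_rna, dataset.counts_dna, rank="otu")
    taxon_index = {t: i for i, t in enumerate(params.taxon_ids)}
    source_index = {s: i for i, s in enumerate(params.source_ids)}
    day_index = {d: i for i, d in enumerate(params.days)}
    tp = tn = fp = fn = 0
    for _, row in table.iterrows():
        abundance = dataset.latent[
            taxon_index[row["taxon"]],
            source_index[row["source"]],
            day_index[row["day"]],
        ]
        if abundance < min_abundance:
            continue
        actual = bool(dataset.truth.true_active.loc[row["taxon"], row["day"]])
        predicted = bool(row["active"])
        tp += actual and predicted
        fn += actual and not predicted
        fp += (not actual) and predicted
        tn += (not actual) and not predicted
    return _balanced(tp, tn, fp, fn)


def planted_sign_recovery(
    base_params: SimParams, n_seeds: int = 20, seed_offset: int = 0
) -> dict[str, float]:
    """Fraction of seeds recovering every planted family association sign."""
    from dataclasses import replace

    recovered = 0
    for seed in range(n_seeds):
        params = replace(base_params, rng_seed=seed_offset + seed)
        ds = simulate_dataset(params, with_sequences=False)
        filtered = network_mod.filter_features(ds.counts_dna)
        net = network_mod.build_network(filtered, taxonomy=ds.taxonomy)
        assoc, _ = network_mod.group_associations(net, ds.taxonomy)
        signs = {
            (row["group_a"], row["group_b"]): row["net_sign"]
            for _, row in assoc.iterrows()
        }
        good = True
        for a, b, sign in ds.truth.planted_edges:
            fa, fb = sorted(
                (ds.taxonomy.loc[a, "family"], ds.taxonomy.loc[b, "family"])
            )
            wanted = "positive" if sign > 0 else "negative"
            if signs.get((fa, fb)) != wanted:
                good = False
        recovered += good
    return {"fraction_recovered": recovered / n_seeds, "n": float(n_seeds)}
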