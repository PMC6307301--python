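"""Rarefaction and alpha diversity: normalization by random subsampling,
richness estimators (bias-corrected Chao1, ACE), Shannon and Simpson
indices, rarefaction curves, and the novel-OTU gain of enrichment.

Estimator conventions: Shannon uses natural log; Simpson is reported as the
Gini-Simpson form 1 - sum(p^2) with the raw dominance sum(p^2) alongside;
Chao1 is the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)); ACE follows
Chao & Lee with the conventional rare-abundance cutoff of 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix


def _column(values) -> np.ndarray:
    col = np.asarray(values)
    if (col < 0).any():
        raise ValueError("negative counts")
    if col.sum() <= 0:
        raise ValueError("diversity is undefined for an all-zero column")
    return col[col > 0].astype(float)


def shannon(values) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log)."""
    p = _column(values)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def simpson(values) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    return 1.0 - dominance(values)


def dominance(values) -> float:
    """Raw Simpson concentration sum p_i^2."""
    p = _column(values)
    p /= p.sum()
    return float((p * p).sum())


def chao1(values) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    col = _column(values)
    s_obs = col.size
    f1 = int((col == 1).sum())
    f2 = int((col == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(values, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (Chao & Lee).

    Raises when every rare feature is a singleton (coverage zero), matching
    the standard convention.
    """
    col = _column(values).astype(int)
    rare = col[col <= rare_cutoff]
    s_abund = int((col > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if f1 == n_rare:
        raise ValueError(
            "ACE is undefined when all rare features are singletons"
        )
    c_ace = 1.0 - f1 / n_rare
    top = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = max(s_rare / c_ace * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def ace_components(values, rare_cutoff: int = 10) -> dict[str, float]:
    col = _column(values).astype(int)
    rare = col[col <= rare_cutoff]
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare if n_rare else float("nan")
    out = {
        "S_rare": float(rare.size),
        "S_abund": float((col > rare_cutoff).sum()),
        "C_ace": c_ace,
    }
    if rare.size and n_rare > 1 and c_ace > 0:
        top = sum(
            i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1)
        )
        out["gamma2"] = max(
            rare.size / c_ace * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
        )
    else:
        out["gamma2"] = float("nan")
    return out


def rarefy(
    counts: CountMatrix, depth: int | str = "min", rng_seed: int = 0
) -> CountMatrix:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` uses the smallest column sum (the common floor-normalisation choice).
    Column sums of the result equal ``depth`` exactly.
    """
    totals = counts.counts.sum(axis=0)
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValueError(
            f"samples shallower than depth {depth}: {list(shallow.index)}"
        )
    rng = np.random.default_rng(rng_seed)
    out = {}
    for sample in counts.sample_ids:
        col = counts.counts[sample].to_numpy().astype(np.int64)
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=counts.counts.index)
    return CountMatrix(rarefied, counts.meta)


@dataclass
class DiversityReport:
    """Per-sample alpha-diversity table."""

    table: pd.DataFrame

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


def alpha_diversity(counts: CountMatrix, rare_cutoff: int = 10) -> DiversityReport:
    rows = {}
    for sample in counts.sample_ids:
        col = counts.column(sample)
        pos = col[col > 0]
        comp = ace_components(col, rare_cutoff)
        try:
            ace_val = ace(col, rare_cutoff)
        except ValueError:
            ace_val = float("nan")
        rows[sample] = {
            "S_obs": float(pos.size),
            "F1": float((pos == 1).sum()),
            "F2": float((pos == 2).sum()),
            "chao1": chao1(col),
            "ace": ace_val,
            **comp,
            "shannon": shannon(col),
            "simpson_gini": simpson(col),
            "dominance": dominance(col),
        }
    return DiversityReport(pd.DataFrame.from_dict(rows, orient="index"))


def rarefaction_curve(
    values,
    depths: Sequence[int],
    reps: int = 10,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Mean observed richness and Shannon H per subsampling depth."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    col = np.asarray(values).astype(np.int64)
    total = int(col.sum())
    depths = list(depths)
    if any(depths[i] >= depths[i + 1] for i in range(len(depths) - 1)):
        raise ValueError("depths must be strictly ascending")
    if depths and depths[-1] > total:
        raise ValueError("depths exceed the column total")
    rng = np.random.default_rng(rng_seed)
    # nested prefixes of one shuffled read vector per replicate: a prefix of
    # a random permutation is a uniform subsample without replacement, and
    # richness is monotone along the prefix chain, so the curve mean is
    # monotone exactly rather than up to Monte-Carlo noise
    reads = np.repeat(np.arange(col.size), col)
    acc = {d: ([], []) for d in depths}
    for _ in range(reps):
        rng.shuffle(reads)
        for d in depths:
            sub = np.bincount(reads[: int(d)], minlength=col.size)
            acc[d][0].append(int((sub > 0).sum()))
            acc[d][1].append(shannon(sub))
    rows = [
        (d, float(np.mean(acc[d][0])), float(np.mean(acc[d][1]))) for d in depths
    ]
    return pd.DataFrame(rows, columns=["depth", "mean_S_obs", "mean_shannon"])


def detected_features(counts: CountMatrix, sample_ids: Iterable[str]) -> set[str]:
    sub = counts.counts[list(sample_ids)]
    return set(sub.index[(sub > 0).any(axis=1)])


def novel_otu_gain(
    counts: CountMatrix,
    day0_samples: Sequence[str],
    enriched_samples: Sequence[str],
) -> dict[str, float]:
    """Novel-feature gain of enrichment relative to the day-0 community.

    Returns both readings of the statistic: ``gain_over_day0`` =
    |novel features| / |day-0 features|, and ``richness_change`` =
    (|post richness| - |day-0 richness|) / |day-0 richness|.
    """
    if not day0_samples or not enriched_samples:
        raise ValueError("both sample sets must be non-empty")
    base = detected_features(counts, day0_samples)
    if not base:
        raise ValueError("no features detected in the day-0 samples")
    post = detected_features(counts, enriched_samples)
    novel = post - base
    return {
        "n_day0": float(len(base)),
        "n_novel": float(len(novel)),
        "gain_over_day0": len(novel) / len(base),
        "richness_change": (len(post) - len(base)) / len(base),
    }


def novel_otu_gain_by_source(
    counts: CountMatrix, molecule: str = "DNA"
) -> pd.DataFrame:
    """Per-source and pooled novel-OTU gain using sample metadata."""
    meta = counts.meta
    rows = []
    sources = sorted(meta["source"].unique())
    for src in [*sources, None]:
        sel = meta["molecule"] == molecule
        if src is not None:
            sel &= meta["source"] == src
        day0 = list(meta.index[sel & (meta["day"] == 0)])
        post = list(meta.index[sel & (meta["day"] > 0)])
        stats = novel_otu_gain(counts, day0, post)
        rows.append({"source": src or "pooled", **stats})
    return pd.DataFrame(rows).set_index("source")
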