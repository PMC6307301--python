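"""Recruit amplicon-library features to cultured isolates by percent identity.

An isolate's near-full-length 16S sequence is aligned (semi-global, free
end gaps) against every representative feature sequence; features reaching
``min_identity`` over at least ``min_overlap`` aligned columns are treated
as the same species, and their per-sample read counts are summed into the
isolate's recruitment profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._align import semiglobal_align
from .io import ConsistencyError, CountMatrix

DEFAULT_MIN_IDENTITY = 0.99
DEFAULT_MIN_OVERLAP = 200
PREFILTER_K = 12       # minimum screen length for the prefilter to engage
MAX_PREFILTER_K = 24

_ALPHABET = set("ACGTN")


@dataclass
class IsolateSeq:
    """A cultured strain's 16S sequence with its isolation metadata."""

    isolate_id: str
    sequence: str
    isolation_day: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 300:
            raise ValueError(
                f"{self.isolate_id}: isolate 16S sequence shorter than 300 nt"
            )
        extra = set(self.sequence) - _ALPHABET
        if extra:
            raise ValueError(
                f"{self.isolate_id}: sequence has non-A/C/G/T/N characters {sorted(extra)}"
            )


@dataclass
class RecruitmentProfile:
    """Per-sample read counts recruited to one isolate."""

    isolate_id: str
    matched_feature_ids: set[str]
    counts_per_sample: dict[str, int]
    match_details: list[tuple[str, float, int]] = field(default_factory=list)
    params_used: dict = field(default_factory=dict)


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Percent identity and overlap of the optimal end-gap-free alignment.

    Identity is matches / aligned columns, terminal gaps excluded; columns
    involving ``N`` never count as matches.  Returns (identity, overlap);
    identity is 0.0 when the optimal overlap is empty.
    """
    _, matches, columns = semiglobal_align(seq_a, seq_b)
    if columns == 0:
        return 0.0, 0
    return matches / columns, columns


def _guaranteed_run(min_identity: float, min_overlap: int) -> int:
    """Longest exact match run any admissible pair must contain.

    With d mismatch/gap columns among L >= min_overlap aligned columns the
    matches split into at most d + 1 runs (pigeonhole); the bound is
    minimised either at the smallest admissible overlap or in the
    long-alignment limit.
    """
    if min_identity >= 1.0:
        return min_overlap
    d0 = int((1.0 - min_identity) * min_overlap)
    run_small = (min_overlap - d0) // (d0 + 1)
    run_limit = int(min_identity / (1.0 - min_identity))
    return min(run_small, run_limit)


def _prefilter_is_lossless(min_identity: float, min_overlap: int, k: int) -> bool:
    """Any pair at >= min_identity over >= min_overlap columns must share an
    exact k-mer."""
    return _guaranteed_run(min_identity, min_overlap) >= k


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def recruit(
    isolate: IsolateSeq,
    features: Mapping[str, str],
    counts: CountMatrix,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    use_prefilter: bool = True,
    _feature_kmers: dict[str, set[str]] | None = None,
) -> RecruitmentProfile:
    """Match one isolate against representative sequences and sum counts.

    A shared-12-mer prefilter skips hopeless alignments when the thresholds
    guarantee it cannot change the result; zero matches yield an all-zero
    profile rather than an error.
    """
    unknown = set(features) - set(counts.feature_ids)
    if unknown:
        raise ConsistencyError(
            f"feature sequences absent from the count table: {sorted(unknown)[:5]}"
        )
    # the screen length grows with the thresholds' guaranteed match run (a
    # longer shared k-mer skips more hopeless alignments) but stays lossless
    k = min(MAX_PREFILTER_K, _guaranteed_run(min_identity, min_overlap))
    prefilter = use_prefilter and k >= PREFILTER_K
    iso_kmers = _kmers(isolate.sequence, k) if prefilter else None

    matched: set[str] = set()
    details: list[tuple[str, float, int]] = []
    for fid, fseq in features.items():
        if iso_kmers is not None:
            fk = (
                _feature_kmers[fid]
                if _feature_kmers is not None
                else _kmers(fseq, k)
            )
            if not (iso_kmers & fk):
                continue
        identity, overlap = pairwise_identity(isolate.sequence, fseq)
        if identity >= min_identity and overlap >= min_overlap:
            matched.add(fid)
            details.append((fid, identity, overlap))

    if matched:
        sums = counts.counts.loc[sorted(matched)].sum(axis=0)
    else:
        sums = pd.Series(0, index=counts.sample_ids)
    return RecruitmentProfile(
        isolate_id=isolate.isolate_id,
        matched_feature_ids=matched,
        counts_per_sample={s: int(v) for s, v in sums.items()},
        match_details=details,
        params_used={"min_identity": min_identity, "min_overlap": min_overlap},
    )


def recruit_all(
    isolates: Iterable[IsolateSeq],
    features: Mapping[str, str],
    counts: CountMatrix,
    **kwargs,
) -> list[RecruitmentProfile]:
    k = min(
        MAX_PREFILTER_K,
        _guaranteed_run(
            kwargs.get("min_identity", DEFAULT_MIN_IDENTITY),
            kwargs.get("min_overlap", DEFAULT_MIN_OVERLAP),
        ),
    )
    feature_kmers = (
        {fid: _kmers(fseq, k) for fid, fseq in features.items()}
        if k >= PREFILTER_K and kwargs.get("use_prefilter", True)
        else None
    )
    return [
        recruit(iso, features, counts, _feature_kmers=feature_kmers, **kwargs)
        for iso in isolates
    ]


def profiles_to_frame(profiles: Iterable[RecruitmentProfile]) -> pd.DataFrame:
    """Isolate x sample table of recruited read counts."""
    rows = {p.isolate_id: p.counts_per_sample for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def match_details_frame(profiles: Iterable[RecruitmentProfile]) -> pd.DataFrame:
    rows = [
        (p.isolate_id, fid, identity, overlap)
        for p in profiles
        for fid, identity, overlap in p.match_details
    ]
    return pd.DataFrame(rows, columns=["isolate_id", "feature_id", "identity", "overlap"])
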