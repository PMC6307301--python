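"""Synthetic enrichment-culture communities with planted ground truth.

The generator emulates the study design the downstream statistics expect:
several sediment sources incubated in an enrichment culture and sampled at
a handful of time points (days 0-30), with paired DNA (16S rRNA gene) and
RNA (16S rRNA) amplicon libraries per sample.  Three ecological guilds
shape the dynamics:

* **r-strategists** start in a rare dormant seed bank, bloom to an interior
  peak day after the nutrient flush, then collapse;
* **k-strategists** grow slowly and monotonically;
* **inert** taxa keep a constant expected relative abundance.

Per-taxon trajectories are deterministic and log-linear; each (taxon,
source) pair carries a lognormal multiplier held constant across days, so
within-source abundance *ratios* reflect the expected dynamics.  RNA
libraries scale each taxon's DNA proportion by an activity factor (> 1 for
active, < 1 for dormant taxa) before renormalisation, so the
(RNA+1):(DNA+1) ratio encodes the planted activity state.  Selected taxon
pairs carry planted positive or negative log-scale correlations for the
co-occurrence network to recover.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._align import semiglobal_align
from .io import RANKS, CountMatrix, write_fasta, write_taxonomy

# trajectory shape constants (log10 relative abundance, per day where rates)
INERT_LOG10_RANGE = (-3.5, -1.5)
K_START_RANGE = (-3.5, -2.5)
K_SLOPE_RANGE = (0.04, 0.08)
R_PEAK_RANGE = (-1.5, -0.5)
R_DECLINE_FACTOR = 0.5     # collapse at half the bloom rate
SOURCE_JITTER_SD = 0.2     # per-(taxon, source) lognormal sd, constant in time
PLANTED_BASE_RANGE = (-2.2, -1.8)
DRIVER_SD = 0.5            # per-sample log10 variation of a planted driver
DRIVER_CLIP = 1.6          # avoid a follower freakishly dominating a sample
FOLLOWER_SD = 0.05         # residual noise of the correlated follower
MAX_PLANTED_MASS = 0.5     # planted taxa never exceed half the community

_NUCS = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Study-design parameters of the synthetic enrichment experiment."""

    n_sources: int = 3
    days: tuple[int, ...] = (0, 5, 12, 21, 30)
    n_taxa: int = 200
    depth: int = 50_443
    frac_r_strategist: float = 0.15
    frac_k_strategist: float = 0.15
    frac_inert: float = 0.70
    seedbank_log10_abundance_range: tuple[float, float] = (-5.0, -4.0)
    activity_factor_active: float = 4.0
    activity_factor_dormant: float = 0.2
    # linear decline of the planted active fraction over the incubation
    active_frac_day0: float = 0.27
    active_frac_last: float = 0.13
    planted_edge_list: tuple[tuple[int, int, int], ...] = (
        (0, 1, +1),
        (2, 3, +1),
        (4, 5, -1),
    )
    seq_length: int = 1400
    isolate_divergence: float = 0.003
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_r_strategist + self.frac_k_strategist + self.frac_inert
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"strategist fractions must sum to 1, got {total}")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if not (
            self.activity_factor_dormant < 1.0 < self.activity_factor_active
        ):
            raise ValueError(
                "need activity_factor_dormant < 1 < activity_factor_active"
            )
        if self.n_taxa < 2:
            raise ValueError("need at least two taxa")
        seen: set[int] = set()
        for i, j, s in self.planted_edge_list:
            if not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa) or i == j:
                raise ValueError(f"invalid planted pair ({i}, {j})")
            if s not in (-1, 1):
                raise ValueError("planted edge sign must be +1 or -1")
            if seen & {i, j}:
                raise ValueError("planted pairs must not share taxa")
            seen.update((i, j))

    @property
    def taxon_ids(self) -> list[str]:
        return [f"otu{i:04d}" for i in range(self.n_taxa)]

    @property
    def source_ids(self) -> list[str]:
        return [f"src{i + 1}" for i in range(self.n_sources)]

    def active_fraction(self, day: int) -> float:
        last = max(self.days)
        if last == 0:
            return self.active_frac_day0
        span = self.active_frac_day0 - self.active_frac_last
        return self.active_frac_day0 - span * (day / last)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated experiment."""

    strategist_class: dict[str, str]
    true_enriched: pd.DataFrame        # taxa x days, bool
    true_active: pd.DataFrame          # taxa x days, bool
    activity_factors: pd.DataFrame     # taxa x days, float
    expected_relative: pd.DataFrame    # taxa x days, expected normalized abundance
    planted_edges: list[tuple[str, str, int]]
    isolate_to_taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_enriched.iloc[:, 0].any():
            raise ValueError("no taxon may be enriched at day 0")

    def to_json(self, path) -> None:
        payload = {
            "strategist_class": self.strategist_class,
            "true_enriched": {
                str(d): self.true_enriched[d].astype(bool).to_dict()
                for d in self.true_enriched.columns
            },
            "true_active": {
                str(d): self.true_active[d].astype(bool).to_dict()
                for d in self.true_active.columns
            },
            "planted_edges": [list(e) for e in self.planted_edges],
            "isolate_to_taxon": self.isolate_to_taxon,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class Trajectories:
    """Latent relative abundances plus the noise-free expectation."""

    latent: np.ndarray             # taxa x sources x days, rows normalized
    expected_relative: np.ndarray  # taxa x days (source-independent)
    classes: np.ndarray            # 'r' | 'k' | 'inert' per taxon


def _assign_classes(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_taxa
    classes = np.array(["inert"] * n, dtype=object)
    planted = {i for pair in params.planted_edge_list for i in pair[:2]}
    eligible = np.array([i for i in range(n) if i not in planted])
    n_r = int(round(params.frac_r_strategist * n))
    n_k = int(round(params.frac_k_strategist * n))
    if n_r + n_k > len(eligible):
        raise ValueError("not enough non-planted taxa for the r/k fractions")
    order = rng.permutation(eligible)
    classes[order[:n_r]] = "r"
    classes[order[n_r : n_r + n_k]] = "k"
    return classes


def simulate_trajectories(
    params: SimParams, rng: np.random.Generator | None = None
) -> Trajectories:
    """Latent per-source relative-abundance trajectories.

    Returns normalized abundances of shape (n_taxa, n_sources, n_days)
    together with the deterministic (noise-free) normalized expectation used
    as ground truth for enrichment calls.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    n, days = params.n_taxa, np.asarray(params.days, dtype=float)
    classes = _assign_classes(params, rng)

    exp_log10 = np.empty((n, len(days)))
    lo, hi = INERT_LOG10_RANGE
    for i in range(n):
        if classes[i] == "inert":
            exp_log10[i] = rng.uniform(lo, hi)
        elif classes[i] == "k":
            start = rng.uniform(*K_START_RANGE)
            slope = rng.uniform(*K_SLOPE_RANGE)
            exp_log10[i] = start + slope * days
        else:  # r-strategist: seed bank -> bloom -> collapse
            start = rng.uniform(*params.seedbank_log10_abundance_range)
            interior = params.days[1:-1] or params.days[1:]
            peak_day = float(rng.choice(interior))
            peak = rng.uniform(*R_PEAK_RANGE)
            rise = (peak - start) / peak_day
            traj = np.where(
                days <= peak_day,
                start + rise * days,
                peak - R_DECLINE_FACTOR * rise * (days - peak_day),
            )
            exp_log10[i] = np.maximum(traj, start)

    planted = {i for pair in params.planted_edge_list for i in pair[:2]}
    for i in planted:
        exp_log10[i] = rng.uniform(*PLANTED_BASE_RANGE)

    expected = np.power(10.0, exp_log10)
    expected_rel = expected / expected.sum(axis=0, keepdims=True)

    jitter = rng.normal(0.0, SOURCE_JITTER_SD, size=(n, params.n_sources))
    log10_latent = exp_log10[:, None, :] + jitter[:, :, None]
    latent = np.power(10.0, log10_latent)
    latent /= latent.sum(axis=0, keepdims=True)

    # Planted correlated pairs are set directly in proportion space: the
    # driver fluctuates per sample and the follower tracks (or mirrors) its
    # log10 deviation.  Planting after closure keeps the pair's log-linear
    # correlation exact — renormalising mirrored raw abundances would add a
    # shared -log(total) term that attenuates negative correlations.
    if params.planted_edge_list:
        shape = (params.n_sources, len(days))
        targets = {}
        for i, j, sign in params.planted_edge_list:
            dev = np.clip(
                rng.normal(0.0, DRIVER_SD, size=shape), -DRIVER_CLIP, DRIVER_CLIP
            )
            eps = rng.normal(0.0, FOLLOWER_SD, size=shape)
            targets[i] = np.power(10.0, exp_log10[i, None, :] + dev)
            targets[j] = np.power(10.0, exp_log10[j, None, :] + sign * dev + eps)
        idx = sorted(targets)
        q = np.stack([targets[i] for i in idx])       # planted x sources x days
        mass = q.sum(axis=0)
        over = mass > MAX_PLANTED_MASS
        if over.any():
            q[:, over] *= MAX_PLANTED_MASS / mass[over]
            mass = q.sum(axis=0)
        rest = np.setdiff1d(np.arange(n), idx)
        latent[rest] *= (1.0 - mass) / latent[rest].sum(axis=0)
        latent[idx] = q

    return Trajectories(latent, expected_rel, classes)


def _activity_truth(
    params: SimParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nested shrinking active sets following the planted day schedule."""
    order = rng.permutation(params.n_taxa)
    active = pd.DataFrame(
        False, index=params.taxon_ids, columns=list(params.days)
    )
    for day in params.days:
        k = int(round(params.active_fraction(day) * params.n_taxa))
        active.loc[np.array(params.taxon_ids)[order[:k]], day] = True
    factors = active.map(
        lambda a: params.activity_factor_active
        if a
        else params.activity_factor_dormant
    )
    return active, factors


def sample_counts(
    latent: np.ndarray,
    depth: int,
    molecule: str,
    truth: SimTruth,
    rng_seed: int,
    *,
    taxon_ids: Sequence[str],
    source_ids: Sequence[str],
    days: Sequence[int],
) -> CountMatrix:
    """Multinomial read counts at ``depth`` for every (source, day) sample.

    RNA libraries scale each taxon's proportion by its activity factor for
    that day and renormalize; column sums equal ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if molecule not in ("DNA", "RNA"):
        raise ValueError("molecule must be 'DNA' or 'RNA'")
    rng = np.random.default_rng(rng_seed)
    cols, meta_rows = {}, []
    for si, src in enumerate(source_ids):
        for di, day in enumerate(days):
            p = latent[:, si, di].astype(float)
            if molecule == "RNA":
                p = p * truth.activity_factors[day].to_numpy()
            p = p / p.sum()
            name = f"{src}_d{day}_{molecule}"
            cols[name] = rng.multinomial(depth, p)
            meta_rows.append((name, src, day, molecule))
    counts = pd.DataFrame(cols, index=list(taxon_ids))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "source", "day", "molecule"]
    ).set_index("sample_id")
    return CountMatrix(counts, meta)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_NUCS[rng.integers(0, 4, size=length)])


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    sites = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for s in sites:
        choices = [c for c in "ACGT" if c != out[s]]
        out[s] = choices[rng.integers(0, 3)]
    return "".join(out)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def generate_sequences(
    n_taxa: int,
    seq_length: int = 1400,
    isolate_divergence: float = 0.003,
    rng_seed: int = 0,
    isolate_taxa: Sequence[int] | None = None,
    max_retries: int = 20,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Reference 16S sequences per taxon plus diverged isolate sequences.

    References are mutually < 97% identical (resampled until satisfied;
    random sequences virtually always are — colliding pairs are screened by
    a shared 25-mer, which any >= 97% identity / >= 200 nt overlap pair must
    contain, before alignment).  Each isolate carries
    Binomial(seq_length, divergence) substitutions relative to its source
    reference.  Returns (references, isolates, isolate_to_taxon).
    """
    if not (0.0 <= isolate_divergence <= 0.05):
        raise ValueError("isolate divergence must be within [0, 0.05]")
    rng = np.random.default_rng(rng_seed)
    ids = [f"otu{i:04d}" for i in range(n_taxa)]
    refs: dict[str, str] = {}
    kmers: dict[str, set[str]] = {}
    k = 25
    for tid in ids:
        for attempt in range(max_retries + 1):
            cand = _random_seq(seq_length, rng)
            ck = _kmer_set(cand, k)
            clash = False
            for other, oset in kmers.items():
                if ck & oset:
                    _, matches, cols = semiglobal_align(cand, refs[other])
                    if cols >= 200 and matches / cols >= 0.97:
                        clash = True
                        break
            if not clash:
                refs[tid] = cand
                kmers[tid] = ck
                break
        else:
            raise RuntimeError(
                f"could not generate a sufficiently dissimilar reference for {tid}"
            )
    if isolate_taxa is None:
        isolate_taxa = range(n_taxa)
    isolates: dict[str, str] = {}
    iso_to_taxon: dict[str, str] = {}
    for i in isolate_taxa:
        tid = ids[i]
        n_subs = int(rng.binomial(seq_length, isolate_divergence))
        iso_id = f"iso_{tid}"
        isolates[iso_id] = _mutate(refs[tid], n_subs, rng)
        iso_to_taxon[iso_id] = tid
    return refs, isolates, iso_to_taxon


def make_taxonomy(params: SimParams) -> pd.DataFrame:
    """Deterministic 7-rank lineages; planted-pair taxa get private families
    so family-level association recovery is unambiguous."""
    planted = sorted({i for pair in params.planted_edge_list for i in pair[:2]})
    rows = []
    for i, tid in enumerate(params.taxon_ids):
        if i in planted:
            fam = f"PlantedFam{i:02d}"
            order = "OrderP"
        else:
            fam = f"Family{i % 12:02d}"
            order = f"Order{(i % 12) % 6}"
        rows.append(
            (
                tid,
                "Bacteria",
                f"Phylum{i % 4}",
                f"Class{i % 6}",
                order,
                fam,
                f"Genus{i:04d}",
                f"Species{i:04d}",
            )
        )
    df = pd.DataFrame(rows, columns=["feature_id", *RANKS]).set_index("feature_id")
    return df


@dataclass
class SimDataset:
    """One complete simulated enrichment experiment."""

    params: SimParams
    truth: SimTruth
    latent: np.ndarray
    counts_dna: CountMatrix
    counts_rna: CountMatrix
    taxonomy: pd.DataFrame
    references: dict[str, str]
    isolates: dict[str, str]
    isolate_meta: pd.DataFrame  # isolate_id -> taxon, source, isolation_day

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts_dna.write_tsv(outdir / "counts_dna.tsv")
        self.counts_rna.write_tsv(outdir / "counts_rna.tsv")
        meta = pd.concat([self.counts_dna.meta, self.counts_rna.meta])
        meta.to_csv(outdir / "sample_metadata.tsv", sep="\t", index_label="sample_id")
        write_taxonomy(self.taxonomy, outdir / "taxonomy.tsv")
        if self.references:
            write_fasta(self.references, outdir / "references.fasta")
        if self.isolates:
            write_fasta(self.isolates, outdir / "isolates.fasta")
            self.isolate_meta.to_csv(
                outdir / "isolate_metadata.tsv", sep="\t", index_label="isolate_id"
            )
        self.truth.to_json(outdir / "truth.json")


def simulate_dataset(params: SimParams, with_sequences: bool = True) -> SimDataset:
    """Run the full generator: trajectories, truth, paired counts, sequences."""
    ss = np.random.SeedSequence(params.rng_seed)
    s_traj, s_act, s_dna, s_rna, s_seq, s_iso = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]
    traj = simulate_trajectories(params, s_traj)
    days = list(params.days)
    ids = params.taxon_ids
    active, factors = _activity_truth(params, s_act)

    expected = pd.DataFrame(traj.expected_relative, index=ids, columns=days)
    enriched = expected.gt(expected[days[0]], axis=0)
    enriched[days[0]] = False

    truth = SimTruth(
        strategist_class=dict(zip(ids, traj.classes)),
        true_enriched=enriched,
        true_active=active,
        activity_factors=factors,
        expected_relative=expected,
        planted_edges=[
            (ids[i], ids[j], s) for i, j, s in params.planted_edge_list
        ],
    )

    kw = dict(taxon_ids=ids, source_ids=params.source_ids, days=days)
    counts_dna = sample_counts(
        traj.latent, params.depth, "DNA", truth,
        int(s_dna.integers(2**31)), **kw,
    )
    counts_rna = sample_counts(
        traj.latent, params.depth, "RNA", truth,
        int(s_rna.integers(2**31)), **kw,
    )

    refs: dict[str, str] = {}
    isolates: dict[str, str] = {}
    iso_meta = pd.DataFrame(
        columns=["taxon", "source", "isolation_day"]
    )
    if with_sequences:
        refs, isolates, iso_to_taxon = generate_sequences(
            params.n_taxa,
            params.seq_length,
            params.isolate_divergence,
            int(s_seq.integers(2**31)),
        )
        truth.isolate_to_taxon = iso_to_taxon
        rows = []
        for iso, tid in iso_to_taxon.items():
            # colonies are picked at every enrichment stage, independently of
            # whether the species happens to be enriched just then
            iso_day = int(days[int(s_iso.integers(len(days)))])
            src = params.source_ids[int(s_iso.integers(params.n_sources))]
            rows.append((iso, tid, src, iso_day))
        iso_meta = pd.DataFrame(
            rows, columns=["isolate_id", "taxon", "source", "isolation_day"]
        ).set_index("isolate_id")

    return SimDataset(
        params=params,
        truth=truth,
        latent=traj.latent,
        counts_dna=counts_dna,
        counts_rna=counts_rna,
        taxonomy=make_taxonomy(params),
        references=refs,
        isolates=isolates,
        isolate_meta=iso_meta,
    )


def generate_genome_tables(
    families: Sequence[str],
    pathway_genes: dict[str, list[str]],
    salvage_genes: dict[str, list[str]],
    prototroph_families: Sequence[str],
    salvage_families: Sequence[str],
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic genome gene-presence tables, one genome per family.

    Prototroph families carry every core gene of every pathway;
    salvage-auxotroph families keep at most a third of the core genes plus
    the first salvage transporter; remaining families lack both.  Returns
    (presence table with a ``family`` column, genome -> planted class map).
    """
    rng = np.random.default_rng(rng_seed)
    all_genes = sorted(
        {g for gs in pathway_genes.values() for g in gs}
        | {g for gs in salvage_genes.values() for g in gs}
    )
    rows, planted = {}, {}
    for fam in families:
        genome = f"gen_{fam}"
        present: set[str] = set()
        if fam in prototroph_families:
            planted[genome] = "prototroph"
            for gs in pathway_genes.values():
                present.update(gs)
        elif fam in salvage_families:
            planted[genome] = "auxotroph_salvage"
            for name, gs in pathway_genes.items():
                keep = rng.integers(0, max(1, len(gs) // 3) + 1)
                present.update(rng.choice(gs, size=keep, replace=False))
                present.add(salvage_genes[name][0])
        else:
            planted[genome] = "auxotroph"
            for gs in pathway_genes.values():
                keep = rng.integers(0, max(1, len(gs) // 3) + 1)
                present.update(rng.choice(gs, size=keep, replace=False))
        rows[genome] = [1 if g in present else 0 for g in all_genes]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=all_genes)
    table.insert(0, "family", [g[4:] for g in table.index])
    return table, planted
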