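"""Synthetic two-group RNA-seq data with a planted ceRNA truth network.

Emulates a corpus-cavernosum experiment contrasting aged rats with erectile
dysfunction (A-ED) against negative controls (NC): negative-binomial counts
for three RNA classes, a miRNA target-prediction table, gene sets, phenotype
(ICP/MAP) tables, qPCR plates and raw reads — each with the ground truth the
generator planted, so every downstream stage can be tested without external
data.

Planted signal.  Each of ``n_planted_triplets`` ceRNA modules consists of one
up-regulated lncRNA, one up-regulated mRNA and a set of ``sponges_per_triplet``
shared miRNAs drawn from a pool of down-regulated miRNAs (one pool miRNA per
module, so the pool size equals the number of modules).  Across samples the
group-mean shifts make each sponge miRNA anti-correlated with both its lncRNA
and mRNA while the lncRNA and mRNA co-vary positively — exactly the structure
the correlation screens and the hypergeometric sponge test look for.  miRNA
repression is simulated marginally (opposite fold change), not kinetically.

Counts are NB(mu, phi) with variance mu + phi * mu^2 and
mu = baseline * fc^[sample in A-ED] * libsize; baselines are log-uniform per
feature, library-size multipliers log-uniform per sample (so normalization has
to do real work).  A single seed drives every sub-generator through documented
SeedSequence stream splitting, making each fixture individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import (
    GROUP_CASE,
    GROUP_CONTROL,
    ExpressionMatrix,
    GeneSetCollection,
    QCReport,
    ReadRecord,
    TargetTable,
    TARGET_COLUMNS,
)

# stream indices for SeedSequence splitting; append only, never reorder
_STREAMS = {
    "structure": 0,
    "lncRNA": 1,
    "miRNA": 2,
    "mRNA": 3,
    "targets": 4,
    "gene_sets": 5,
    "phenotype": 6,
    "qpcr": 7,
    "reads": 8,
}


class ConfigError(ValueError):
    """Raised when a SimulationConfig field violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic A-ED vs NC experiment.

    Defaults describe the reference condition used throughout the test suite:
    10 samples per group, 20 planted ceRNA modules among ~2,000 null decoy
    features, 6-fold planted effects, NB dispersion 0.1, 5% background
    targeting and 0.5-2x library-size spread.
    """

    seed: int = 0
    n_per_group: int = 10
    n_lnc: int = 120
    n_mir: int = 120
    n_mrna: int = 1820
    n_planted_triplets: int = 20
    lnc_fc: float = 6.0
    mrna_fc: float = 6.0
    mir_fc: float = 6.0
    sponges_per_triplet: int = 4
    dispersion: float = 0.1
    baseline_mean_log_range: tuple[float, float] = (math.log(20.0), math.log(2000.0))
    target_density: float = 0.05
    lib_size_range: tuple[float, float] = (0.5, 2.0)

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError("n_per_group: need >= 3 samples per group")
        for name in ("n_lnc", "n_mir", "n_mrna"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be positive")
        if not (
            0
            <= self.n_planted_triplets
            <= min(self.n_lnc, self.n_mir, self.n_mrna)
        ):
            raise ConfigError(
                "n_planted_triplets: must be in [0, min(n_lnc, n_mir, n_mrna)]"
            )
        for name in ("lnc_fc", "mrna_fc", "mir_fc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: fold changes must be positive")
        if self.sponges_per_triplet < 1:
            raise ConfigError("sponges_per_triplet: must be >= 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion: must be positive")
        lo, hi = self.baseline_mean_log_range
        if not lo <= hi:
            raise ConfigError("baseline_mean_log_range: lower bound exceeds upper")
        if not 0.0 <= self.target_density <= 1.0:
            raise ConfigError("target_density: must lie in [0, 1]")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ConfigError("lib_size_range: need 0 < low <= high")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for one named fixture stream."""
        child = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(child[_STREAMS[stream]])


@dataclass
class TruthNetwork:
    """Ground truth planted by the generator.

    ``planted_pairs`` are the true ceRNA (lncRNA, mRNA) pairs;
    ``planted_sponges`` maps each pair to its set of shared sponge miRNAs;
    ``direction`` maps every feature id to "up", "down" or "null".
    """

    planted_pairs: set[tuple[str, str]]
    planted_sponges: dict[tuple[str, str], frozenset[str]]
    direction: dict[str, str]

    @property
    def planted_lncrnas(self) -> set[str]:
        return {l for l, _ in self.planted_pairs}

    @property
    def planted_mrnas(self) -> set[str]:
        return {m for _, m in self.planted_pairs}

    @property
    def planted_mirnas(self) -> set[str]:
        out: set[str] = set()
        for s in self.planted_sponges.values():
            out |= s
        return out

    def to_json_dict(self) -> dict:
        return {
            "planted_pairs": sorted(map(list, self.planted_pairs)),
            "planted_sponges": {
                f"{l}|{m}": sorted(s) for (l, m), s in sorted(self.planted_sponges.items())
            },
            "direction": dict(sorted(self.direction.items())),
        }


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(1, n + 1)]


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    aed = [f"AED_{i:02d}" for i in range(1, n_per_group + 1)]
    nc = [f"NC_{i:02d}" for i in range(1, n_per_group + 1)]
    samples = aed + nc
    groups = pd.Series(
        [GROUP_CASE] * n_per_group + [GROUP_CONTROL] * n_per_group, index=samples
    )
    return samples, groups


def plan_truth(config: SimulationConfig) -> TruthNetwork:
    """Deterministic truth layout: module k uses the k-th feature of each class.

    Sponge sets are ``sponges_per_triplet``-subsets of the planted miRNA pool,
    always containing the module's own miRNA (drawn from the "structure"
    stream).
    """
    config.validate()
    rng = config.rng("structure")
    lnc_ids = _feature_ids("LNC", config.n_lnc)
    mir_ids = _feature_ids("MIR", config.n_mir)
    mrna_ids = _feature_ids("MRN", config.n_mrna)
    k = config.n_planted_triplets
    pool = mir_ids[:k]
    s = min(config.sponges_per_triplet, max(k, 1))
    pairs: set[tuple[str, str]] = set()
    sponges: dict[tuple[str, str], frozenset[str]] = {}
    for i in range(k):
        pair = (lnc_ids[i], mrna_ids[i])
        pairs.add(pair)
        others = [m for m in pool if m != pool[i]]
        extra = rng.choice(len(others), size=s - 1, replace=False) if s > 1 else []
        sponges[pair] = frozenset([pool[i]] + [others[j] for j in extra])
    direction = {f: "null" for f in lnc_ids + mir_ids + mrna_ids}
    for l, m in pairs:
        direction[l] = "up"
        direction[m] = "up"
    for mir in {m for ss in sponges.values() for m in ss}:
        direction[mir] = "down"
    return TruthNetwork(planted_pairs=pairs, planted_sponges=sponges, direction=direction)


def _baselines_and_libsizes(
    config: SimulationConfig, n_features: int, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    # draw order is part of the stream contract: baselines first, then libsizes
    lo, hi = config.baseline_mean_log_range
    baseline = np.exp(rng.uniform(lo, hi, size=n_features))
    lib_lo, lib_hi = config.lib_size_range
    libsize = np.exp(rng.uniform(math.log(lib_lo), math.log(lib_hi), size=n_samples))
    return baseline, libsize


def planted_library_sizes(config: SimulationConfig, rna_class: str) -> pd.Series:
    """True per-sample library-size multipliers for one class (generator truth)."""
    config.validate()
    n = {"lncRNA": config.n_lnc, "miRNA": config.n_mir, "mRNA": config.n_mrna}[rna_class]
    samples, _ = _sample_ids(config.n_per_group)
    _, libsize = _baselines_and_libsizes(config, n, len(samples), config.rng(rna_class))
    return pd.Series(libsize, index=samples)


def _simulate_class(
    config: SimulationConfig,
    rna_class: str,
    ids: list[str],
    fold_change: np.ndarray,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    samples, groups = _sample_ids(config.n_per_group)
    baseline, libsize = _baselines_and_libsizes(config, len(ids), len(samples), rng)
    in_case = groups.to_numpy() == GROUP_CASE
    mu = baseline[:, None] * np.where(in_case[None, :], fold_change[:, None], 1.0)
    mu = mu * libsize[None, :]
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(n=r, p=r / (r + mu))
    if rna_class == "miRNA":
        lengths = pd.Series(np.full(len(ids), 22, dtype=np.int64), index=ids)
    else:
        lengths = pd.Series(
            np.round(np.exp(rng.uniform(math.log(200), math.log(10_000), len(ids))))
            .astype(np.int64),
            index=ids,
        )
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        groups=groups,
        rna_class=rna_class,
        lengths=lengths,
    )


def simulate_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, TruthNetwork]:
    """Generate (lncRNA, miRNA, mRNA) count matrices and the planted truth."""
    truth = plan_truth(config)
    out: list[ExpressionMatrix] = []
    for rna_class, prefix, n, fc in (
        ("lncRNA", "LNC", config.n_lnc, config.lnc_fc),
        ("miRNA", "MIR", config.n_mir, config.mir_fc),
        ("mRNA", "MRN", config.n_mrna, config.mrna_fc),
    ):
        ids = _feature_ids(prefix, n)
        fold = np.ones(n)
        for i, f in enumerate(ids):
            d = truth.direction[f]
            if d == "up":
                fold[i] = fc
            elif d == "down":
                fold[i] = 1.0 / fc
        out.append(_simulate_class(config, rna_class, ids, fold, config.rng(rna_class)))
    return out[0], out[1], out[2], truth


_TOOLS = ("TargetScan", "miRcode", "miRDB")


def simulate_target_table(config: SimulationConfig, truth: TruthNetwork) -> TargetTable:
    """Planted sponge relations plus i.i.d. background targeting.

    Every planted sponge relation (miRNA->lncRNA and miRNA->mRNA of its pair)
    is present; every other miRNA x feature pair is included independently
    with probability ``target_density``.  Each pair carries 1-3 pseudo-tool
    votes.
    """
    config.validate()
    rng = config.rng("targets")
    mir_ids = _feature_ids("MIR", config.n_mir)
    planted: set[tuple[str, str, str]] = set()
    for (l, m), sponges in truth.planted_sponges.items():
        for mir in sponges:
            planted.add((mir, l, "lncRNA"))
            planted.add((mir, m, "mRNA"))
    rows: list[tuple[str, str, str]] = sorted(planted)
    for cls, targets in (
        ("lncRNA", _feature_ids("LNC", config.n_lnc)),
        ("mRNA", _feature_ids("MRN", config.n_mrna)),
    ):
        mask = rng.random((len(mir_ids), len(targets))) < config.target_density
        for i, j in zip(*np.nonzero(mask)):
            key = (mir_ids[i], targets[j], cls)
            if key not in planted:
                rows.append(key)
    n_votes = rng.integers(1, 4, size=len(rows))
    tools = [
        frozenset(rng.choice(_TOOLS, size=k, replace=False).tolist()) for k in n_votes
    ]
    df = pd.DataFrame(
        [
            {"mirna": m, "target": t, "target_class": c, "tools": v}
            for (m, t, c), v in zip(rows, tools)
        ],
        columns=TARGET_COLUMNS,
    )
    return TargetTable(df)


def simulate_gene_sets(
    config: SimulationConfig,
    truth: TruthNetwork,
    n_sets: int = 10,
    set_size: tuple[int, int] = (15, 40),
    n_enriched: int = 2,
) -> tuple[GeneSetCollection, set[str]]:
    """Gene sets over the mRNA universe; returns (collection, enriched set ids).

    Enriched sets are stuffed with planted (up-regulated) mRNAs so that a
    query of network mRNAs over-represents them; background sets are uniform
    draws from the universe.
    """
    config.validate()
    rng = config.rng("gene_sets")
    universe = _feature_ids("MRN", config.n_mrna)
    planted = sorted(truth.planted_mrnas)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    enriched: set[str] = set()
    for i in range(n_sets):
        sid = f"SET{i + 1:03d}"
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        if i < n_enriched and planted:
            n_hit = min(len(planted), max(1, size // 2))
            hit_idx = rng.choice(len(planted), size=n_hit, replace=False)
            members = {planted[j] for j in hit_idx}
            rest = rng.choice(len(universe), size=size, replace=False)
            for j in rest:
                if len(members) >= size:
                    break
                members.add(universe[j])
            sets[sid] = (f"planted-enriched set {i + 1}", frozenset(members))
            enriched.add(sid)
        else:
            idx = rng.choice(len(universe), size=size, replace=False)
            sets[sid] = (f"background set {i + 1}", frozenset(universe[j] for j in idx))
    return GeneSetCollection(sets), enriched


def simulate_phenotype(
    config: SimulationConfig,
    n_below: int = 7,
    n_above: int = 15,
    threshold: float = 0.35,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-animal (MAP, ICP) table with a known ICP/MAP split at ``threshold``.

    ``n_below`` animals get ratios drawn strictly below the threshold (true
    A-ED), ``n_above`` strictly above (true NC); MAP is Gaussian around
    100 mmHg.  Returns (table, true group labels by animal).
    """
    config.validate()
    if n_below < 0 or n_above < 0 or n_below + n_above == 0:
        raise ConfigError("n_below/n_above: need a positive number of animals")
    rng = config.rng("phenotype")
    n = n_below + n_above
    ratios = np.concatenate(
        [
            rng.uniform(0.45 * threshold, 0.9 * threshold, size=n_below),
            rng.uniform(1.15 * threshold, 2.0 * threshold, size=n_above),
        ]
    )
    animals = [f"rat_{i:02d}" for i in range(1, n + 1)]
    map_ = rng.normal(100.0, 8.0, size=n)
    table = pd.DataFrame(
        {"animal": animals, "ICP": ratios * map_, "MAP": map_}
    )
    labels = pd.Series(
        [GROUP_CASE] * n_below + [GROUP_CONTROL] * n_above, index=animals
    )
    return table, labels


@dataclass
class QPCRPlate:
    """Ct values per (gene, sample, replicate) with reference gene/calibrator."""

    ct: pd.DataFrame  # columns: gene, sample, replicate, ct
    reference_gene: str
    groups: pd.Series  # sample -> group
    calibrator_group: str = GROUP_CONTROL

    def __post_init__(self):
        need = ["gene", "sample", "replicate", "ct"]
        missing = [c for c in need if c not in self.ct.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns: {missing}")
        if not np.isfinite(self.ct["ct"]).all() or (self.ct["ct"] <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        per_sample = self.ct.groupby("sample")["gene"].apply(set)
        lacking = [s for s, genes in per_sample.items() if self.reference_gene not in genes]
        if lacking:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing for samples {lacking}"
            )


def simulate_qpcr(
    config: SimulationConfig,
    true_fold_changes: dict[str, float] | None = None,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    reference_gene: str = "Actb",
) -> tuple[QPCRPlate, dict[str, float]]:
    """qPCR plate for the two groups with known per-gene fold changes.

    A gene with true A-ED/NC fold change F has target Ct lowered by log2(F)
    in A-ED samples; the reference gene is flat.  Per-sample Ct offsets
    (pipetting/loading) are added to all genes of a sample and cancel in the
    delta-delta-Ct.  Returns (plate, true ddCt per gene); with zero noise the
    estimator recovers these exactly.
    """
    config.validate()
    if n_replicates < 1:
        raise ConfigError("n_replicates: must be >= 1")
    if ct_noise_sd < 0:
        raise ConfigError("ct_noise_sd: must be non-negative")
    if true_fold_changes is None:
        true_fold_changes = {"geneA": 2.0, "geneB": 0.5}
    rng = config.rng("qpcr")
    samples, groups = _sample_ids(config.n_per_group)
    sample_offset = rng.normal(0.0, 0.5, size=len(samples))
    base_ct = {g: float(rng.uniform(22.0, 30.0)) for g in true_fold_changes}
    rows = []
    for si, s in enumerate(samples):
        in_case = groups[s] == GROUP_CASE
        for gene in [reference_gene, *true_fold_changes]:
            if gene == reference_gene:
                ct0 = 18.0
            else:
                ct0 = base_ct[gene]
                if in_case:
                    ct0 -= math.log2(true_fold_changes[gene])
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "sample": s,
                        "replicate": rep,
                        "ct": ct0 + sample_offset[si] + noise,
                    }
                )
    plate = QPCRPlate(
        ct=pd.DataFrame(rows),
        reference_gene=reference_gene,
        groups=groups,
        calibrator_group=GROUP_CONTROL,
    )
    true_ddct = {g: -math.log2(f) for g, f in true_fold_changes.items()}
    return plate, true_ddct


_DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTC"
_BASES = np.array(list("ACGT"))


def simulate_reads(
    config: SimulationConfig,
    n_reads: int = 1000,
    read_length: int = 100,
    frac_adapter: float = 0.10,
    frac_high_n: float = 0.05,
    frac_low_quality: float = 0.05,
    adapter: str = _DEFAULT_ADAPTER,
) -> tuple[list[ReadRecord], list[str], QCReport]:
    """FASTQ-ready reads with planted QC failures and exact bookkeeping.

    Failure categories are disjoint by construction (a planted adapter read
    has no N and high quality, etc.), so the returned truth report equals the
    per-rule counts an order-respecting filter must produce.  Reads are
    shuffled before return; order carries no information.
    """
    config.validate()
    fracs = (frac_adapter, frac_high_n, frac_low_quality)
    if any(f < 0 for f in fracs) or sum(fracs) > 1:
        raise ConfigError("read failure fractions must be >= 0 and sum to <= 1")
    if read_length < 2 * len(adapter):
        raise ConfigError("read_length: too short to embed the adapter")
    rng = config.rng("reads")
    n_ad = int(round(frac_adapter * n_reads))
    n_hn = int(round(frac_high_n * n_reads))
    n_lq = int(round(frac_low_quality * n_reads))
    reads: list[ReadRecord] = []
    for i in range(n_reads):
        seq = _BASES[rng.integers(0, 4, size=read_length)]
        qual = rng.integers(30, 41, size=read_length)
        if i < n_ad:
            pos = int(rng.integers(0, read_length - len(adapter) + 1))
            seq[pos : pos + len(adapter)] = list(adapter)
        elif i < n_ad + n_hn:
            # > 10% N: plant 15% of positions
            k = max(int(0.15 * read_length), int(0.10 * read_length) + 1)
            idx = rng.choice(read_length, size=k, replace=False)
            seq[idx] = "N"
        elif i < n_ad + n_hn + n_lq:
            # > 50% bases at Q <= 20: plant 60% at Q=10
            k = max(int(0.60 * read_length), int(0.50 * read_length) + 1)
            idx = rng.choice(read_length, size=k, replace=False)
            qual[idx] = 10
        else:
            # guard against an accidental adapter hit in a "clean" read
            while adapter in "".join(seq):  # pragma: no cover - p ~ 4^-20
                seq = _BASES[rng.integers(0, 4, size=read_length)]
        reads.append(
            ReadRecord(
                id=f"read_{i + 1:05d}",
                sequence="".join(seq),
                qualities=tuple(int(q) for q in qual),
            )
        )
    order = rng.permutation(n_reads)
    reads = [reads[i] for i in order]
    truth = QCReport(
        n_total=n_reads,
        n_kept=n_reads - n_ad - n_hn - n_lq,
        fail_adapter=n_ad,
        fail_n_content=n_hn,
        fail_low_quality=n_lq,
    )
    return reads, [adapter], truth
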