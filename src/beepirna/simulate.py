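"""Synthetic small-RNA study generator.

Emulates the design of a three-stage larval-gut small-RNA experiment: three
ordered developmental groups with three biological replicates each, piRNA-like
24-33 nt loci with a cytosine-biased first base, contaminating
rRNA/tRNA/snRNA/snoRNA/scRNA and miRNA reads, negative-binomial replicate
counts, and planted group-wise fold changes with complementary target sites
embedded in random transcripts. Every quantity the downstream analysis is
supposed to recover is recorded in a truth table.

All randomness flows from one integer seed through numpy's Generator, so a
config + seed pair reproduces every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import revcomp, write_fasta, write_fastq, write_gff3

BASES = "ACGT"
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")

#: pathway-category design mirrored on the development / immune / energy
#: metabolism split used for honey-bee gut regulatory networks
DEFAULT_PATHWAY_CATEGORIES = {
    "development": [
        "path:P001",  # Wnt signaling
        "path:P002",  # Hippo signaling
        "path:P003",  # Notch signaling
        "path:P004",  # mTOR signaling
        "path:P005",  # TGF-beta signaling
        "path:P006",  # Hedgehog signaling
        "path:P007",  # FoxO signaling
    ],
    "immune": [
        "path:P008",  # Endocytosis
        "path:P009",  # Jak/STAT signaling
        "path:P010",  # Ubiquitin-mediated proteolysis
        "path:P011",  # Lysosome
        "path:P012",  # Phagosome
        "path:P013",  # Toll and Imd signaling
        "path:P014",  # Apoptosis
    ],
    "energy-metabolism": [
        "path:P015",  # Sulfur metabolism
        "path:P016",  # Nitrogen metabolism
        "path:P017",  # Oxidative phosphorylation
    ],
}

PATHWAY_LABELS = {
    "path:P001": "Wnt signaling pathway",
    "path:P002": "Hippo signaling pathway",
    "path:P003": "Notch signaling pathway",
    "path:P004": "mTOR signaling pathway",
    "path:P005": "TGF-beta signaling pathway",
    "path:P006": "Hedgehog signaling pathway",
    "path:P007": "FoxO signaling pathway",
    "path:P008": "Endocytosis",
    "path:P009": "Jak-STAT signaling pathway",
    "path:P010": "Ubiquitin mediated proteolysis",
    "path:P011": "Lysosome",
    "path:P012": "Phagosome",
    "path:P013": "Toll and Imd signaling pathway",
    "path:P014": "Apoptosis",
    "path:P015": "Sulfur metabolism",
    "path:P016": "Nitrogen metabolism",
    "path:P017": "Oxidative phosphorylation",
}


class SizingError(ValueError):
    """Requested loci/sites do not fit into the available sequence."""


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study.

    Defaults are the study conditions the downstream acceptance checks run
    under: 3 groups x 3 replicates, 1e5 piRNA-locus reads per replicate,
    500 piRNA loci of which 10% carry a planted |log2FC| = 2 effect.
    """

    seed: int = 0
    genome_length: int = 200_000
    chrom_name: str = "chr1"
    n_pirna_loci: int = 500
    pirna_length_range: tuple[int, int] = (24, 33)
    # C-dominant, matching the observed first-base cytosine bias
    first_base_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.15, "C": 0.55, "G": 0.10, "T": 0.20}
    )
    ping_pong_10A: bool = False
    n_ncrna_loci: dict[str, int] = field(
        default_factory=lambda: {"rRNA": 20, "tRNA": 20, "snRNA": 10, "snoRNA": 10, "scRNA": 5}
    )
    ncrna_length_range: tuple[int, int] = (60, 150)
    n_mirna: int = 50
    mirna_length_range: tuple[int, int] = (20, 24)
    n_transcripts: int = 300
    transcript_length_range: tuple[int, int] = (300, 600)
    n_replicates: int = 3
    groups: tuple[str, ...] = ("Am4", "Am5", "Am6")
    mean_depth: int = 100_000
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    planted_log2fc_range: tuple[float, float] = (2.0, 2.0)
    target_site_rate: float = 3.0
    # contaminant read rates, relative to mean_depth
    ncrna_contamination: float = 0.25
    mirna_contamination: float = 0.05
    abundance_sigma: float = 0.8
    sequencing_error_rate: float = 0.0
    site_edits: int = 0
    site_edits_in_core: bool = True
    enriched_term: str = "path:P001"
    enriched_frac_target: float = 0.8
    enriched_frac_background: float = 0.1

    def validate(self) -> None:
        w = self.first_base_weights
        if abs(sum(w.values()) - 1.0) > 1e-9 or any(v < 0 for v in w.values()):
            raise ValueError("first_base_weights must be non-negative and sum to 1")
        lo, hi = self.pirna_length_range
        if not (18 <= lo <= hi <= 40):
            raise ValueError("pirna_length_range must satisfy 18 <= low <= high <= 40")
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, val in [
            ("genome_length", self.genome_length),
            ("n_pirna_loci", self.n_pirna_loci),
            ("n_mirna", self.n_mirna),
            ("n_transcripts", self.n_transcripts),
            ("n_replicates", self.n_replicates),
            ("mean_depth", self.mean_depth),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        unknown = set(self.n_ncrna_loci) - set(NCRNA_CLASSES)
        if unknown:
            raise ValueError(f"unknown ncRNA classes: {sorted(unknown)}")

    def replicate_ids(self) -> list[str]:
        return [f"{g}_r{i + 1}" for g in self.groups for i in range(self.n_replicates)]

    def rep_to_group(self) -> dict[str, str]:
        return {rep: rep.rsplit("_r", 1)[0] for rep in self.replicate_ids()}

    def comparisons(self) -> list[tuple[str, str]]:
        """Consecutive (earlier, later) group pairs, e.g. (Am4, Am5)."""
        return [(self.groups[i], self.groups[i + 1]) for i in range(len(self.groups) - 1)]


@dataclass
class TruthTable:
    """Ground truth for one simulated study.

    loci: one row per piRNA locus (interval, sequence, per-group true mean
    replicate count, per-comparison true log2FC, DE flag).
    sites: one row per planted target site (locus_id, transcript_id, interval,
    edits, energy class).
    """

    loci: pd.DataFrame
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _pirna_sequence(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> str:
    bases = list(BASES)
    probs = np.array([cfg.first_base_weights.get(b, 0.0) for b in bases])
    first = bases[rng.choice(4, p=probs / probs.sum())]
    rest = _random_seq(rng, length - 1)
    seq = first + rest
    if cfg.ping_pong_10A and length >= 10:
        seq = seq[:9] + "A" + seq[10:]
    return seq


def _place_intervals(rng: np.random.Generator, lengths: list[int], genome_length: int) -> list[int]:
    """Non-overlapping starts for the given locus lengths, in random order."""
    total = sum(lengths)
    free = genome_length - total
    if free < 0:
        raise SizingError(
            f"{len(lengths)} loci totalling {total} bp do not fit in a "
            f"{genome_length} bp genome (short by {-free} bp)"
        )
    n = len(lengths)
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts, pos = [], 0
    for i, length in enumerate(lengths):
        pos += gaps[i]
        starts.append(pos)
        pos += length
    return starts


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Build the genome sequence and its locus annotation table.

    Returns (genome: {chrom: seq}, features: DataFrame). piRNA, ncRNA and
    miRNA loci are non-overlapping; each locus sequence is written into the
    genome (reverse-complemented on the minus strand) so that every locus read
    maps back exactly.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    lo, hi = config.pirna_length_range
    plan: list[tuple[str, str, int]] = []  # (feature_id, type, length)
    for i in range(config.n_pirna_loci):
        plan.append((f"piL{i:05d}", "piRNA_locus", int(rng.integers(lo, hi + 1))))
    for cls in NCRNA_CLASSES:
        nlo, nhi = config.ncrna_length_range
        for i in range(config.n_ncrna_loci.get(cls, 0)):
            plan.append((f"{cls}{i:03d}", cls, int(rng.integers(nlo, nhi + 1))))
    mlo, mhi = config.mirna_length_range
    for i in range(config.n_mirna):
        plan.append((f"mir{i:03d}", "miRNA", int(rng.integers(mlo, mhi + 1))))

    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]
    starts = _place_intervals(rng, [p[2] for p in plan], config.genome_length)

    genome = np.array(list(_random_seq(rng, config.genome_length)))
    rows = []
    seen: set[str] = set()
    for (fid, ftype, length), start in zip(plan, starts):
        strand = "+" if rng.random() < 0.5 else "-"
        if ftype == "piRNA_locus":
            seq = _pirna_sequence(rng, length, config)
            while seq in seen:  # distinct locus sequences keep mapping unique
                seq = _pirna_sequence(rng, length, config)
            seen.add(seq)
        else:
            seq = _random_seq(rng, length)
        genome[start : start + length] = list(seq if strand == "+" else revcomp(seq))
        rows.append((fid, ftype, config.chrom_name, start, start + length, strand, seq))

    features = pd.DataFrame(
        rows, columns=["feature_id", "type", "chrom", "start", "end", "strand", "sequence"]
    )
    features = features.sort_values("start", kind="mergesort").reset_index(drop=True)
    return {config.chrom_name: "".join(genome)}, features


def assign_effects(
    config: SimulationConfig, features: pd.DataFrame, rng: np.random.Generator
) -> TruthTable:
    """Draw baseline abundances and plant group-wise fold changes.

    Baseline relative abundances are lognormal; a de_fraction subset of loci
    receives a signed log2 step at one group transition, spread round-robin
    over transitions. True per-group mean replicate counts are mean_depth *
    relative weight (no renormalisation, so null loci stay exactly null).
    """
    loci = features[features["type"] == "piRNA_locus"].reset_index(drop=True).copy()
    n = len(loci)
    comparisons = config.comparisons()
    weights = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    weights /= weights.sum() if n else 1.0

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    f_lo, f_hi = config.planted_log2fc_range
    magnitudes = rng.uniform(f_lo, f_hi, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    transition = np.arange(n_de) % max(len(comparisons), 1)

    loci["base_weight"] = weights
    loci["de"] = False
    loci["de_comparison"] = ""
    planted = np.zeros((n, max(len(comparisons), 1)))
    for j, idx in enumerate(de_idx):
        loci.loc[idx, "de"] = True
        t = transition[j]
        loci.loc[idx, "de_comparison"] = f"{comparisons[t][0]} vs {comparisons[t][1]}"
        planted[idx, t] = signs[j] * magnitudes[j]

    # group means: cumulative product of the planted steps along group order
    for gi, group in enumerate(config.groups):
        step = planted[:, :gi].sum(axis=1) if gi else np.zeros(n)
        loci[f"mean_{group}"] = config.mean_depth * weights * np.power(2.0, step)
    for t, (g1, g2) in enumerate(comparisons):
        loci[f"log2fc_{g1}_vs_{g2}"] = planted[:, t]

    loci = loci.rename(columns={"feature_id": "locus_id"})
    return TruthTable(loci=loci)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, size / (size + mean[pos]))
    return out


def generate_counts(
    config: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> pd.DataFrame:
    """True per-locus, per-replicate piRNA read counts (pre-contamination)."""
    reps = config.replicate_ids()
    rep2group = config.rep_to_group()
    counts = {}
    for rep in reps:
        mean = truth.loci[f"mean_{rep2group[rep]}"].to_numpy()
        counts[rep] = _nb_counts(rng, mean, config.nb_dispersion)
    return pd.DataFrame(counts, index=truth.loci["locus_id"])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    for i in range(len(arr)):
        if rng.random() < rate:
            arr[i] = BASES[(BASES.index(arr[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def generate_reads(
    config: SimulationConfig,
    features: pd.DataFrame,
    truth: TruthTable,
    outdir: str | Path,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Write one FASTQ per replicate; return the true piRNA count matrix.

    piRNA reads are exact locus copies (optional uniform substitution noise);
    contaminating reads are windows of annotated ncRNA loci and exact mature
    miRNA sequences, at rates relative to mean_depth. Read order within a
    replicate is a seeded permutation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = generate_counts(config, truth, rng)
    loci_seqs = truth.loci["sequence"].to_list()

    nc = features[features["type"].isin(NCRNA_CLASSES)].reset_index(drop=True)
    mir = features[features["type"] == "miRNA"].reset_index(drop=True)
    nc_w = np.exp(rng.normal(0.0, 1.0, size=len(nc)))
    nc_w /= nc_w.sum() if len(nc) else 1.0
    mir_w = np.exp(rng.normal(0.0, 1.0, size=len(mir)))
    mir_w /= mir_w.sum() if len(mir) else 1.0

    for rep in config.replicate_ids():
        reads: list[str] = []
        col = counts[rep].to_numpy()
        for seq, c in zip(loci_seqs, col):
            if c:
                reads.extend([seq] * int(c))
        n_nc = rng.poisson(config.mean_depth * config.ncrna_contamination) if len(nc) else 0
        if n_nc:
            picks = rng.choice(len(nc), size=n_nc, p=nc_w)
            for i in picks:
                locus = nc.iloc[int(i)]
                llen = locus.end - locus.start
                wlen = int(rng.integers(18, min(33, llen) + 1))
                wstart = int(rng.integers(0, llen - wlen + 1))
                reads.append(locus.sequence[wstart : wstart + wlen])
        n_mi = rng.poisson(config.mean_depth * config.mirna_contamination) if len(mir) else 0
        if n_mi:
            picks = rng.choice(len(mir), size=n_mi, p=mir_w)
            reads.extend(mir.iloc[int(i)].sequence for i in picks)
        if config.sequencing_error_rate > 0:
            reads = [_mutate(rng, s, config.sequencing_error_rate) for s in reads]
        order = rng.permutation(len(reads))
        write_fastq(
            outdir / f"{rep}.fastq",
            ((f"{rep}.{k + 1}", reads[j]) for k, j in enumerate(order)),
        )
    return counts


def _edit_site(rng: np.random.Generator, site: str, pirna_len: int, edits: int, in_core: bool) -> str:
    """Introduce `edits` mismatches into a planted antisense site.

    piRNA position k (1-based, 5' end) pairs with site position len-k; the
    core region is piRNA positions 2-13.
    """
    if edits <= 0:
        return site
    positions = list(range(2, min(13, pirna_len) + 1)) if in_core else list(
        range(14, pirna_len + 1)
    )
    chosen = rng.choice(len(positions), size=min(edits, len(positions)), replace=False)
    arr = list(site)
    for c in chosen:
        k = positions[int(c)]
        j = len(site) - k
        # replace with the same base as the piRNA base's complement partner's
        # non-pairing alternative: shift to a base that neither WC- nor GU-pairs
        pir_base = revcomp(site)[k - 1]
        bad = {b for b in BASES if not _pairs(pir_base, b)}
        arr[j] = sorted(bad)[int(rng.integers(0, len(bad)))]
    return "".join(arr)


def _pairs(p: str, t: str) -> bool:
    wc = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    gu = {("G", "T"), ("T", "G")}
    return (p, t) in wc or (p, t) in gu


def generate_transcripts_and_sites(
    config: SimulationConfig, truth: TruthTable, rng: np.random.Generator
):
    """Random transcripts with planted antisense sites for the DE piRNA loci.

    Returns (transcripts: {id: seq}, sites: DataFrame, gene2term rows,
    categories dict). Each DE locus receives ~Poisson(target_site_rate)+1
    target transcripts carrying its reverse-complement site (with configured
    edits). Every transcript gets >= 1 annotation term; the configured
    enriched pathway term is concentrated among targeted transcripts.
    """
    tlo, thi = config.transcript_length_range
    tx_ids = [f"gene{i:05d}" for i in range(config.n_transcripts)]
    transcripts = {tid: _random_seq(rng, int(rng.integers(tlo, thi + 1))) for tid in tx_ids}

    de_loci = truth.loci[truth.loci["de"]]
    site_rows = []
    targeted: set[str] = set()
    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in tx_ids}
    for row in de_loci.itertuples(index=False):
        n_sites = int(rng.poisson(config.target_site_rate)) + 1
        n_sites = min(n_sites, config.n_transcripts)
        if n_sites == 0:
            continue
        picks = rng.choice(config.n_transcripts, size=n_sites, replace=False)
        for p in picks:
            tid = tx_ids[int(p)]
            seq = transcripts[tid]
            site = revcomp(row.sequence)
            if len(site) > len(seq):
                raise SizingError(f"site ({len(site)} nt) longer than transcript {tid}")
            site = _edit_site(rng, site, len(row.sequence), config.site_edits, config.site_edits_in_core)
            # keep planted sites disjoint so none is overwritten later
            start = None
            for _ in range(50):
                cand = int(rng.integers(0, len(seq) - len(site) + 1))
                if all(cand + len(site) <= s or cand >= e for s, e in occupied[tid]):
                    start = cand
                    break
            if start is None:
                continue
            occupied[tid].append((start, start + len(site)))
            transcripts[tid] = seq[:start] + site + seq[start + len(site):]
            energy_class = "strong" if config.site_edits == 0 and len(site) >= 20 else "weak"
            site_rows.append((row.locus_id, tid, start, start + len(site), config.site_edits, energy_class))
            targeted.add(tid)

    sites = pd.DataFrame(
        site_rows,
        columns=["locus_id", "transcript_id", "start", "end", "edits", "energy_class"],
    )

    # gene -> term map with one designed enriched pathway term
    all_paths = sorted(PATHWAY_LABELS)
    go_terms = [f"GO:S{i:04d}" for i in range(30)]
    gene2term: list[tuple[str, str, str, str]] = []
    for tid in tx_ids:
        p_enriched = config.enriched_frac_target if tid in targeted else config.enriched_frac_background
        terms: set[str] = set()
        if rng.random() < p_enriched:
            terms.add(config.enriched_term)
        n_extra = int(rng.integers(1, 4))
        for t in rng.choice(len(all_paths), size=n_extra, replace=False):
            terms.add(all_paths[int(t)])
        terms.add(go_terms[int(rng.integers(0, len(go_terms)))])
        for term in sorted(terms):
            label = PATHWAY_LABELS.get(term, term)
            ns = "pathway" if term.startswith("path:") else "GO"
            gene2term.append((tid, term, label, ns))

    return transcripts, sites, gene2term, dict(DEFAULT_PATHWAY_CATEGORIES)


@dataclass
class StudyPaths:
    """File layout of one written synthetic study."""

    root: Path

    @property
    def genome(self) -> Path:
        return self.root / "genome.fa"

    @property
    def annotations(self) -> Path:
        return self.root / "annotations.gff3"

    @property
    def mirna(self) -> Path:
        return self.root / "mirna.fa"

    @property
    def transcripts(self) -> Path:
        return self.root / "transcripts.fa"

    @property
    def reads_dir(self) -> Path:
        return self.root / "reads"

    @property
    def truth_loci(self) -> Path:
        return self.root / "truth_loci.tsv"

    @property
    def truth_sites(self) -> Path:
        return self.root / "truth_sites.tsv"

    @property
    def true_counts(self) -> Path:
        return self.root / "true_counts.tsv"

    @property
    def terms(self) -> Path:
        return self.root / "terms.tsv"

    @property
    def categories(self) -> Path:
        return self.root / "categories.yaml"

    @property
    def config_echo(self) -> Path:
        return self.root / "config.yaml"

    def fastq(self, replicate: str) -> Path:
        return self.reads_dir / f"{replicate}.fastq"


@dataclass
class Study:
    """In-memory handles of a generated study plus its on-disk layout."""

    config: SimulationConfig
    genome: dict[str, str]
    features: pd.DataFrame
    truth: TruthTable
    counts: pd.DataFrame
    transcripts: dict[str, str]
    categories: dict[str, list[str]]
    paths: StudyPaths


def simulate_study(config: SimulationConfig, outdir: str | Path) -> Study:
    """Generate and write a complete synthetic study under `outdir`."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    paths = StudyPaths(Path(outdir))
    paths.root.mkdir(parents=True, exist_ok=True)

    genome, features = generate_genome(config, rng)
    truth = assign_effects(config, features, rng)
    counts = generate_reads(config, features, truth, paths.reads_dir, rng)
    transcripts, sites, gene2term, categories = generate_transcripts_and_sites(config, truth, rng)
    truth.sites = sites

    write_fasta(paths.genome, genome)
    write_gff3(paths.annotations, features)
    mirnas = {
        row.feature_id: row.sequence
        for row in features[features["type"] == "miRNA"].itertuples(index=False)
    }
    write_fasta(paths.mirna, mirnas)
    write_fasta(paths.transcripts, transcripts)
    truth.loci.to_csv(paths.truth_loci, sep="\t", index=False)
    sites.to_csv(paths.truth_sites, sep="\t", index=False)
    counts.to_csv(paths.true_counts, sep="\t")
    pd.DataFrame(gene2term).to_csv(paths.terms, sep="\t", index=False, header=False)
    with open(paths.categories, "w") as fh:
        yaml.safe_dump(categories, fh)
    with open(paths.config_echo, "w") as fh:
        yaml.safe_dump(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            fh,
        )
    return Study(config, genome, features, truth, counts, transcripts, categories, paths)
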