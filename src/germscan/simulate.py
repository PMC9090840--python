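"""Seeded, truth-annotated synthetic datasets for the whole pipeline.

The generator emulates the statistical structure of a paired
germline/somatic sequencing design in a species undergoing programmed
genome rearrangement:

* a genome of somatic chromosomes plus germline-restricted scaffolds
  (default ~20% of total germline genome content), with non-overlapping
  genes; germline-scaffold genes form multi-copy families and ~55% of those
  families also get paralogous copies on somatic chromosomes;
* per-base Poisson depth for a germline sample (uniform genome-wide) and a
  somatic sample (collapsed to a small residual on germline scaffolds);
* stage-structured negative-binomial gonadal counts in eight groups
  (UD, EF, MF, LF, PM, EM, MM, LM) where germline-scaffold genes are high
  in prospective and mid-stage males and near-zero in females and
  undifferentiated larvae; a set of moderately male-biased somatic genes
  populates the classifier's candidate pool the way the real genome does;
* optionally, embryo counts in pre-/post-rearrangement groups where most
  germline genes are silent and a few are moderately expressed.

Elimination is whole-sequence in truth; an optional mosaic switch plants a
half-eliminated sequence for negative testing of the mixed-sequence
detector.  Everything is deterministic for a fixed (config, seed) pair.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .formats import (
    BedRecord,
    DepthTrack,
    GeneModel,
    SeqDict,
    write_bed,
    write_bedgraph,
    write_counts,
    write_gff3_genes,
    write_sample_sheet,
    write_seqdict,
)

__all__ = [
    "GenomeConfig",
    "DepthSimConfig",
    "ExpressionSimConfig",
    "FullSimConfig",
    "TruthBundle",
    "generate_genome",
    "simulate_depth",
    "simulate_counts",
    "simulate_embryo_counts",
    "generate_bundle",
    "generate_dataset",
]

GROUP_SIZES = {"UD": 2, "EF": 2, "MF": 6, "LF": 2, "PM": 4, "EM": 4, "MM": 6, "LM": 2}
FEMALE_LIKE = ("UD", "EF", "MF", "LF")


@dataclass
class GenomeConfig:
    """Layout of the synthetic germline genome.

    Sequence lengths are drawn with mild variation and rescaled so germline
    scaffolds hold `germline_fraction` of `total_length`.  `family_sizes`
    pins exact germline family copy numbers (name -> copies); when None,
    `n_gsr_families` family sizes are drawn from a geometric distribution
    clipped to [1, max_family_size].
    """

    total_length: int = 10_000_000
    n_somatic_chroms: int = 8
    n_germline_scaffolds: int = 6
    germline_fraction: float = 0.20
    min_seq_length: int = 10_000
    n_somatic_genes: int = 1000
    n_gsr_families: int = 30
    family_sizes: dict[str, int] | None = None
    family_size_p: float = 0.5  # geometric parameter for drawn family sizes
    max_family_size: int = 77
    somatic_paralog_fraction: float = 0.55
    somatic_paralog_max_copies: int = 3
    gene_length_range: tuple[int, int] = (2_000, 5_000)
    n_noncoding: int = 12
    n_mosaic: int = 0  # germline scaffolds only half-eliminated (negative testing)

    def __post_init__(self) -> None:
        if self.n_somatic_chroms < 1 or self.n_germline_scaffolds < 1:
            raise ValueError("need at least one sequence per class")
        if not (0 < self.germline_fraction < 1):
            raise ValueError("germline_fraction must be in (0,1)")
        if self.family_sizes is not None:
            for name, k in self.family_sizes.items():
                if k < 1:
                    raise ValueError(f"family {name!r} has size {k} < 1")
        if not (0 <= self.somatic_paralog_fraction <= 1):
            raise ValueError("somatic_paralog_fraction must be in [0,1]")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad gene_length_range")
        if self.n_mosaic > self.n_germline_scaffolds:
            raise ValueError("n_mosaic exceeds number of germline scaffolds")


@dataclass
class DepthSimConfig:
    """Per-base Poisson depth model.

    lambda_g: sperm depth everywhere. lambda_s: blood depth on somatic
    (retained) sequence. lambda_r: residual blood depth on eliminated
    sequence (default lambda_s / 50).  Planted regions exceed the score-2
    threshold in expectation when lambda_s / lambda_r > 4; setting
    lambda_r = lambda_s gives the no-elimination null.
    """

    lambda_g: float = 30.0
    lambda_s: float = 30.0
    lambda_r: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_g <= 0 or self.lambda_s <= 0:
            raise ValueError("lambda_g and lambda_s must be > 0")
        if self.lambda_r is not None and self.lambda_r < 0:
            raise ValueError("lambda_r must be >= 0")

    @property
    def residual(self) -> float:
        return self.lambda_r if self.lambda_r is not None else self.lambda_s / 50.0


@dataclass
class ExpressionSimConfig:
    """Stage-structured negative-binomial count model.

    Counts ~ NB(mean = group mean x library multiplier, variance =
    mu + phi mu^2).  Germline-scaffold genes follow `gsg_mu` in male groups
    and `mu_low` in female-like groups; somatic genes share a log-normal
    baseline across sexes.  `male_biased_multiple` x (number of planted GSGs)
    somatic genes are made moderately male-biased (log2 fold change drawn
    from `decoy_lfc_range`) so the top-fraction step of the classifier has a
    realistic candidate pool; `sex_symmetric=True` switches every gene to the
    baseline (null calibration mode).
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    gsg_mu: dict[str, float] = field(
        default_factory=lambda: {"PM": 800.0, "EM": 150.0, "MM": 800.0, "LM": 150.0}
    )
    mu_low: float = 1.0
    baseline_median: float = 30.0
    baseline_sigma: float = 1.0
    male_biased_multiple: float = 4.2
    decoy_lfc_range: tuple[float, float] = (2.6, 4.8)
    decoy_floor: float = 20.0
    dispersion: float = 0.2
    libsize_sigma: float = 0.15
    sex_symmetric: bool = False
    # embryo block
    embryo_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"pre_pgr": 3, "post_pgr": 3}
    )
    embryo_expressed_fraction: float = 0.3
    embryo_mu_low: float = 0.3
    embryo_mu_expressed: float = 3.0
    n_embryo_high: int = 6
    embryo_mu_high: float = 80.0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} has no samples")
        if any(v < 0 for v in self.gsg_mu.values()) or self.mu_low < 0:
            raise ValueError("means must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")


@dataclass
class FullSimConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    depth: DepthSimConfig = field(default_factory=DepthSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    embryo: bool = False


@dataclass
class TruthBundle:
    """A full synthetic dataset plus the ground truth that produced it."""

    seed: int
    config: FullSimConfig
    seqdict: SeqDict
    germline_seqs: set[str]
    germline_regions: dict[str, list[tuple[int, int]]]
    genes: list[GeneModel]
    gene_truth: pd.DataFrame  # index gene_id; compartment_truth, expression_class, ...
    sperm: DepthTrack
    blood: DepthTrack
    counts: pd.DataFrame
    sheet: pd.Series
    embryo_counts: pd.DataFrame | None = None
    embryo_sheet: pd.Series | None = None

    @property
    def truth_germline_bases(self) -> int:
        return sum(e - s for regs in self.germline_regions.values() for s, e in regs)


# ---------------------------------------------------------------------------
# genome + genes


def _sequence_lengths(cfg: GenomeConfig, rng: np.random.Generator) -> SeqDict:
    g_total = int(round(cfg.total_length * cfg.germline_fraction))
    s_total = cfg.total_length - g_total

    def split(total: int, n: int) -> list[int]:
        w = rng.uniform(0.7, 1.3, size=n)
        lens = np.floor(total * w / w.sum()).astype(int)
        lens[-1] += total - int(lens.sum())
        return [int(x) for x in lens]

    items: list[tuple[str, int]] = []
    for i, length in enumerate(split(s_total, cfg.n_somatic_chroms), 1):
        items.append((f"chr{i}", length))
    for i, length in enumerate(split(g_total, cfg.n_germline_scaffolds), 1):
        items.append((f"gsc{i}", length))
    for name, length in items:
        if length < cfg.min_seq_length:
            raise ValueError(
                f"sequence {name!r} length {length} below min_seq_length "
                f"{cfg.min_seq_length}; raise total_length or lower counts"
            )
    return SeqDict(items)


def _place_genes(
    per_seq: dict[str, list[tuple[str, str, int, str]]],
    seqdict: SeqDict,
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Place (gene_id, name, length, biotype) tuples non-overlapping on each
    sequence via random cut positions in the free space."""
    genes: list[GeneModel] = []
    for seq, specs in per_seq.items():
        if not specs:
            continue
        total_len = sum(s[2] for s in specs)
        free = seqdict[seq] - total_len
        if free < 0:
            raise ValueError(
                f"sequence {seq!r} (length {seqdict[seq]}) too short to host "
                f"{len(specs)} genes totalling {total_len} bp"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=len(specs)))
        offset = 0
        for (gid, name, length, biotype), cut in zip(specs, cuts):
            start = int(cut) + offset
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, name, seq, start, start + length, strand, biotype))
            offset += length
    return genes


def generate_genome(
    cfg: GenomeConfig, seed: int | np.random.Generator
) -> tuple[SeqDict, dict[str, list[tuple[int, int]]], list[GeneModel], pd.DataFrame]:
    """Build the genome layout, truth germline regions, and gene models.

    Returns (seqdict, germline_regions, genes, gene_truth).  gene_truth is
    indexed by gene id with the truth compartment, family name and
    expression class of every gene.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqdict = _sequence_lengths(cfg, rng)
    somatic_seqs = [n for n in seqdict if n.startswith("chr")]
    germ_seqs = [n for n in seqdict if n.startswith("gsc")]

    # truth: whole-sequence elimination; optional mosaics are half-eliminated
    germline_regions: dict[str, list[tuple[int, int]]] = {}
    mosaic = set(germ_seqs[: cfg.n_mosaic])
    for name in germ_seqs:
        L = seqdict[name]
        germline_regions[name] = [(0, L // 2)] if name in mosaic else [(0, L)]

    # germline families
    if cfg.family_sizes is not None:
        fam_sizes = dict(cfg.family_sizes)
    else:
        sizes = np.minimum(
            rng.geometric(cfg.family_size_p, size=cfg.n_gsr_families), cfg.max_family_size
        )
        fam_sizes = {f"gsfam{i + 1:03d}": int(s) for i, s in enumerate(sizes)}

    lo, hi = cfg.gene_length_range
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:05d}"

    per_seq: dict[str, list[tuple[str, str, int, str]]] = {n: [] for n in seqdict}
    truth_rows: list[dict] = []
    g_weights = np.array([seqdict[n] for n in germ_seqs], dtype=float)
    g_weights /= g_weights.sum()
    s_weights = np.array([seqdict[n] for n in somatic_seqs], dtype=float)
    s_weights /= s_weights.sum()

    def add_gene(seq: str, name: str, biotype: str, cls: str) -> None:
        gid = next_id()
        length = int(rng.integers(lo, hi + 1))
        per_seq[seq].append((gid, name, length, biotype))
        truth_rows.append(
            {"gene_id": gid, "name": name, "seq": seq, "biotype": biotype,
             "expression_class": cls}
        )

    for fam, n_copies in fam_sizes.items():
        for _ in range(n_copies):
            seq = str(rng.choice(germ_seqs, p=g_weights))
            add_gene(seq, fam, "protein_coding", "gsr_male")

    # somatic paralogs of a fraction of germline families (sex-symmetric)
    fam_names = list(fam_sizes)
    n_para = int(round(cfg.somatic_paralog_fraction * len(fam_names)))
    para_fams = rng.choice(fam_names, size=n_para, replace=False) if n_para else []
    for fam in para_fams:
        for _ in range(int(rng.integers(1, cfg.somatic_paralog_max_copies + 1))):
            seq = str(rng.choice(somatic_seqs, p=s_weights))
            add_gene(seq, str(fam), "protein_coding", "somatic_null")

    # somatic background genes, single-copy names
    for i in range(cfg.n_somatic_genes):
        seq = str(rng.choice(somatic_seqs, p=s_weights))
        add_gene(seq, f"smg{i + 1:05d}", "protein_coding", "somatic_null")

    # a few non-coding records to exercise the biotype filter
    nc_types = ("rRNA", "tRNA", "lncRNA")
    for i in range(cfg.n_noncoding):
        seq = str(rng.choice(list(seqdict.names()), p=None))
        add_gene(seq, f"nc{i + 1:03d}", nc_types[i % len(nc_types)], "noncoding")

    genes = _place_genes(per_seq, seqdict, rng)
    by_id = {g.gene_id: g for g in genes}
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    truth["start"] = [by_id[i].start for i in truth.index]
    truth["end"] = [by_id[i].end for i in truth.index]

    def truth_compartment(row) -> str:
        regs = germline_regions.get(row["seq"], [])
        inside = any(s <= row["start"] and row["end"] <= e for s, e in regs)
        return "GSR" if inside else "somatic"

    truth["compartment_truth"] = truth.apply(truth_compartment, axis=1)
    # mosaic scaffolds can strand a germline family copy on retained sequence
    truth.loc[
        (truth["compartment_truth"] == "somatic") & (truth["expression_class"] == "gsr_male"),
        "expression_class",
    ] = "somatic_null"
    genes_sorted = sorted(genes, key=lambda g: (g.seq, g.start))
    return seqdict, germline_regions, genes_sorted, truth


# ---------------------------------------------------------------------------
# depth


def simulate_depth(
    seqdict: SeqDict,
    germline_regions: dict[str, list[tuple[int, int]]],
    cfg: DepthSimConfig,
    seed: int | np.random.Generator,
) -> tuple[DepthTrack, DepthTrack]:
    """Poisson per-base depth: sperm uniform at lambda_g genome-wide; blood
    at lambda_s on retained sequence and lambda_r inside germline regions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sperm: dict[str, np.ndarray] = {}
    blood: dict[str, np.ndarray] = {}
    for name, length in seqdict.items():
        sperm[name] = rng.poisson(cfg.lambda_g, size=length)
        b = rng.poisson(cfg.lambda_s, size=length)
        for s, e in germline_regions.get(name, []):
            b[s:e] = rng.poisson(cfg.residual, size=e - s)
        blood[name] = b
    return (
        DepthTrack("sperm", seqdict, sperm),
        DepthTrack("blood", seqdict, blood),
    )


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mu + phi mu^2 (gamma-Poisson mixture)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        r = 1.0 / phi
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    gene_truth: pd.DataFrame,
    cfg: ExpressionSimConfig,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw the gonadal count matrix.

    Returns (counts, sheet, gene_truth_out) where gene_truth_out adds the
    realized expression class (decoy selection happens here) and the mean
    matrix parameters are reflected in the class labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = gene_truth.copy()
    gene_ids = truth.index.to_numpy()
    n_genes = len(gene_ids)

    samples: list[str] = []
    groups: list[str] = []
    for group, n in cfg.group_sizes.items():
        for i in range(1, n + 1):
            samples.append(f"{group}_{i}")
            groups.append(group)
    sheet = pd.Series(groups, index=samples, name="group")

    is_gsg = (truth["expression_class"] == "gsr_male").to_numpy()
    is_coding = (truth["biotype"] == "protein_coding").to_numpy()
    n_gsg = int(is_gsg.sum())

    # per-gene shared baseline (log-normal around baseline_median)
    base = cfg.baseline_median * np.exp(
        rng.normal(0.0, cfg.baseline_sigma, size=n_genes)
    )

    # select somatic decoys: moderately male-biased somatic genes
    decoy_mask = np.zeros(n_genes, dtype=bool)
    if not cfg.sex_symmetric and n_gsg > 0:
        eligible = np.flatnonzero(
            (truth["expression_class"] == "somatic_null").to_numpy() & is_coding
        )
        n_decoy = min(int(round(cfg.male_biased_multiple * n_gsg)), eligible.size)
        chosen = rng.choice(eligible, size=n_decoy, replace=False)
        decoy_mask[chosen] = True
        truth.iloc[chosen, truth.columns.get_loc("expression_class")] = (
            "somatic_male_moderate"
        )
    decoy_f = cfg.decoy_floor + cfg.baseline_median * np.exp(
        rng.normal(0.0, 0.75, size=n_genes)
    )
    decoy_lfc = rng.uniform(*cfg.decoy_lfc_range, size=n_genes)

    lib = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=len(samples)))

    mu = np.empty((n_genes, len(samples)))
    for j, group in enumerate(groups):
        col = base.copy()
        if not cfg.sex_symmetric:
            if group in cfg.gsg_mu:  # male groups
                col[is_gsg] = cfg.gsg_mu[group]
                col[decoy_mask] = decoy_f[decoy_mask] * 2.0 ** decoy_lfc[decoy_mask]
            else:  # female-like groups
                col[is_gsg] = cfg.mu_low
                col[decoy_mask] = decoy_f[decoy_mask]
        mu[:, j] = col * lib[j]

    counts = pd.DataFrame(
        _nb_draw(rng, mu, cfg.dispersion), index=truth.index, columns=samples
    )
    return counts, sheet, truth


def simulate_embryo_counts(
    gene_truth: pd.DataFrame,
    cfg: ExpressionSimConfig,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Embryo counts bracketing genome rearrangement.

    Somatic genes keep their baseline scale; most germline-scaffold genes
    are near-silent, a configurable fraction is lowly expressed, and a small
    planted set is highly expressed in both windows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = gene_truth
    gene_ids = truth.index.to_numpy()
    n_genes = len(gene_ids)
    is_gsg = (truth["compartment_truth"] == "GSR").to_numpy()

    samples: list[str] = []
    groups: list[str] = []
    for group, n in cfg.embryo_group_sizes.items():
        for i in range(1, n + 1):
            samples.append(f"{group}_{i}")
            groups.append(group)
    sheet = pd.Series(groups, index=samples, name="group")

    mu_gene = cfg.baseline_median * np.exp(rng.normal(0.0, cfg.baseline_sigma, n_genes))
    gsg_idx = np.flatnonzero(is_gsg)
    mu_gene[gsg_idx] = cfg.embryo_mu_low
    n_expr = int(round(cfg.embryo_expressed_fraction * gsg_idx.size))
    expr_idx = rng.choice(gsg_idx, size=n_expr, replace=False) if n_expr else []
    mu_gene[expr_idx] = cfg.embryo_mu_expressed
    n_high = min(cfg.n_embryo_high, gsg_idx.size)
    high_idx = rng.choice(gsg_idx, size=n_high, replace=False) if n_high else []
    mu_gene[high_idx] = cfg.embryo_mu_high

    mu = np.tile(mu_gene[:, None], (1, len(samples)))
    counts = pd.DataFrame(
        _nb_draw(rng, mu, cfg.dispersion), index=truth.index, columns=samples
    )
    return counts, sheet


# ---------------------------------------------------------------------------
# bundle + files


def generate_bundle(config: FullSimConfig | None = None, seed: int = 0) -> TruthBundle:
    """Generate a full in-memory dataset from one seed."""
    cfg = config if config is not None else FullSimConfig()
    seqdict, regions, genes, truth = generate_genome(cfg.genome, substream(seed, "genome"))
    sperm, blood = simulate_depth(seqdict, regions, cfg.depth, substream(seed, "depth"))
    counts, sheet, truth = simulate_counts(truth, cfg.expression, substream(seed, "counts"))
    embryo_counts = embryo_sheet = None
    if cfg.embryo:
        embryo_counts, embryo_sheet = simulate_embryo_counts(
            truth, cfg.expression, substream(seed, "embryo")
        )
    return TruthBundle(
        seed=seed,
        config=cfg,
        seqdict=seqdict,
        germline_seqs={n for n in seqdict if n.startswith("gsc")},
        germline_regions=regions,
        genes=genes,
        gene_truth=truth,
        sperm=sperm,
        blood=blood,
        counts=counts,
        sheet=sheet,
        embryo_counts=embryo_counts,
        embryo_sheet=embryo_sheet,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def generate_dataset(
    config: FullSimConfig | None = None, seed: int = 0, outdir: str | Path = "."
) -> dict:
    """Generate a dataset and write it to outdir.

    Writes genome.tsv, sperm.bedgraph, blood.bedgraph, genes.gff3,
    truth.bed, counts.tsv, samples.tsv (plus embryo_counts.tsv /
    embryo_samples.tsv when the embryo block is on) and manifest.json
    holding the seed, the config echo, and per-file sha256 checksums.
    Returns the manifest dict.
    """
    cfg = config if config is not None else FullSimConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(cfg, seed)

    files: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        try:
            writer(path)
        except OSError as exc:  # pragma: no cover
            raise OSError(f"failed writing {path}: {exc}") from exc
        files[name] = path

    emit("genome.tsv", lambda p: write_seqdict(bundle.seqdict, p))
    emit("sperm.bedgraph", lambda p: write_bedgraph(bundle.sperm, p))
    emit("blood.bedgraph", lambda p: write_bedgraph(bundle.blood, p))
    emit("genes.gff3", lambda p: write_gff3_genes(bundle.genes, p))
    emit(
        "truth.bed",
        lambda p: write_bed(
            [
                BedRecord(seq, s, e, f"germline_{seq}", 0.0)
                for seq, regs in bundle.germline_regions.items()
                for s, e in regs
            ],
            p,
        ),
    )
    emit("counts.tsv", lambda p: write_counts(bundle.counts, p))
    emit("samples.tsv", lambda p: write_sample_sheet(bundle.sheet, p))
    if cfg.embryo:
        emit("embryo_counts.tsv", lambda p: write_counts(bundle.embryo_counts, p))
        emit("embryo_samples.tsv", lambda p: write_sample_sheet(bundle.embryo_sheet, p))

    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "files": sorted(files),
        "checksums": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
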