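"""Synthetic gene tables, count matrices, condition pairs and sequences.

The generator states the world the analyses assume: right-skewed (log-normal)
per-gene half-lives in hours with an optional 24 h assay ceiling, a
multiplicative X-chromosome stability effect, RPKM positively and mRNA
length negatively rank-correlated with half-life (induced through a Gaussian
copula so the marginals stay log-normal), realistic per-chromosome gene
counts (X = 353, autosomes totalling 11,326), paired ribo-seq/RNA-seq Poisson
counts whose density ratio is elevated on X, and random CDS/3'-UTR sequences
with controllable GC3 and word composition.

Every generator is a pure function of ``(params, seed)``: calling the
operations individually with their default RNGs or through
:func:`generate_bundle` yields identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .karyotype import HUMAN, Karyotype
from .tables import GeneTable, IntervalRecord, SeqRecord, reverse_complement

__all__ = [
    "SyntheticParams",
    "SyntheticBundle",
    "default_gene_counts",
    "generate_gene_table",
    "generate_ribo_dataset",
    "generate_condition_pair",
    "generate_sequences",
    "generate_bundle",
    "write_bundle",
]

# Approximate human protein-coding gene counts per autosome; used only as
# proportions and renormalized to the requested autosomal total.
_HUMAN_AUTOSOME_WEIGHTS: dict[str, int] = {
    "1": 2058, "2": 1309, "3": 1078, "4": 752, "5": 876, "6": 1048,
    "7": 989, "8": 677, "9": 786, "10": 733, "11": 1298, "12": 1034,
    "13": 327, "14": 830, "15": 613, "16": 873, "17": 1197, "18": 270,
    "19": 1472, "20": 544, "21": 234, "22": 488,
}

# spawn keys so stand-alone generator calls reproduce the bundle exactly
_KEY_TABLE, _KEY_RIBO, _KEY_PAIR, _KEY_SEQ = 1, 2, 3, 4


def default_gene_counts(n_x: int = 353, n_autosomal: int = 11_326,
                        karyotype: Karyotype = HUMAN) -> dict[str, int]:
    """Per-chromosome gene counts: X fixed, autosomes proportional to real
    human chromosome gene counts, renormalized by largest remainder."""
    weights = {c: _HUMAN_AUTOSOME_WEIGHTS.get(c, 1) for c in karyotype.autosomes}
    total_w = sum(weights.values())
    exact = {c: n_autosomal * w / total_w for c, w in weights.items()}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    short = n_autosomal - sum(counts.values())
    for c in sorted(exact, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    counts["X"] = n_x
    return counts


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the generating process (defaults are the stated world)."""

    genes_per_chromosome: Mapping[str, int] | None = None
    halflife_log_mean: float = math.log(7.0) - 0.75 ** 2 / 2  # autosomal mean ~7 h
    halflife_log_sd: float = 0.75
    x_stability_multiplier: float = 1.46
    halflife_cap_h: float | None = 24.0
    rpkm_halflife_spearman_target: float = 0.30
    length_halflife_spearman_target: float = -0.25
    rpkm_log_mean: float = math.log(10.0) - 0.5
    rpkm_log_sd: float = 1.0
    length_log_mean: float = math.log(1800.0) - 0.55 ** 2 / 2
    length_log_sd: float = 0.55
    ribo_density_x_multiplier: float = 1.3
    density_log_sd: float = 0.25
    library_size_ribo: int = 20_000_000
    library_size_rna: int = 50_000_000
    gc3_by_chromosome: Mapping[str, float] | None = None
    gc3_default: float = 0.55
    housekeeping_fraction: float = 0.5
    invalid_cds_fraction: float = 0.0
    pair_noise_log_sd: float = 0.10
    utr_length_mean: int = 200
    gene_spacing_bp: int = 10_000
    seed: int = 0
    karyotype: Karyotype = HUMAN

    def __post_init__(self) -> None:
        if self.x_stability_multiplier <= 0 or self.ribo_density_x_multiplier <= 0:
            raise ConfigurationError("effect multipliers must be positive")
        for name in ("rpkm_halflife_spearman_target", "length_halflife_spearman_target"):
            if abs(getattr(self, name)) >= 1:
                raise ConfigurationError(f"{name} must lie in (-1, 1)")
        if not (0 <= self.housekeeping_fraction <= 1):
            raise ConfigurationError("housekeeping_fraction must lie in [0, 1]")
        if not (0 <= self.invalid_cds_fraction <= 1):
            raise ConfigurationError("invalid_cds_fraction must lie in [0, 1]")
        if self.library_size_ribo <= 0 or self.library_size_rna <= 0:
            raise ConfigurationError("library sizes must be positive")
        if self.halflife_cap_h is not None and self.halflife_cap_h <= 0:
            raise ConfigurationError("halflife_cap_h must be positive or None")
        gpc = self.counts()
        if not gpc:
            raise ConfigurationError("genes_per_chromosome must be non-empty")
        if any(n <= 0 for n in gpc.values()):
            raise ConfigurationError("gene counts must be positive")
        for c, v in (self.gc3_by_chromosome or {}).items():
            if not (0 <= v <= 1):
                raise ConfigurationError(f"gc3 target for {c} outside [0, 1]")
        if not (0 <= self.gc3_default <= 1):
            raise ConfigurationError("gc3_default outside [0, 1]")

    def counts(self) -> dict[str, int]:
        if self.genes_per_chromosome is not None:
            return dict(self.genes_per_chromosome)
        return default_gene_counts(karyotype=self.karyotype)

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    gene_table: GeneTable
    ribo_counts: pd.Series
    rna_counts: pd.Series
    condition_pair: pd.DataFrame
    cds: list[SeqRecord]
    utr_intervals: list[IntervalRecord]
    genome: dict[str, SeqRecord]
    truth: dict


def _spearman_to_pearson(rho_s: float) -> float:
    # bivariate-normal relation between Spearman's rho and the latent
    # Pearson correlation of the Gaussian copula
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_gene_table(
    params: SyntheticParams, rng: np.random.Generator | None = None
) -> tuple[GeneTable, dict]:
    """Draw the gene table and return it with the generating truth.

    Half-lives are log-normal; X-linked half-lives are multiplied by
    ``x_stability_multiplier`` before the optional cap at ``halflife_cap_h``
    (truncated, flagged in the ``capped`` column, not resampled). RPKM and
    mRNA length come from the same Gaussian copula as the half-life so the
    target Spearman correlations hold in rank space.
    """
    rng = rng if rng is not None else params.rng(_KEY_TABLE)
    counts = params.counts()
    karyotype = params.karyotype
    chroms = [c for c in karyotype.names if c in counts]
    if set(counts) - set(chroms):
        raise ConfigurationError(
            f"genes_per_chromosome outside karyotype: {sorted(set(counts) - set(chroms))}"
        )
    n_total = sum(counts[c] for c in chroms)

    r_hr = _spearman_to_pearson(params.rpkm_halflife_spearman_target)
    r_hl = _spearman_to_pearson(params.length_halflife_spearman_target)
    corr = np.array(
        [
            [1.0, r_hr, r_hl],
            [r_hr, 1.0, r_hr * r_hl],  # conditional independence given half-life
            [r_hl, r_hr * r_hl, 1.0],
        ]
    )
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_total, 3)) @ chol.T

    half_life = np.exp(params.halflife_log_mean + params.halflife_log_sd * z[:, 0])
    rpkm = np.exp(params.rpkm_log_mean + params.rpkm_log_sd * z[:, 1])
    length = np.maximum(
        150, np.round(np.exp(params.length_log_mean + params.length_log_sd * z[:, 2]))
    ).astype(int)

    frames = []
    arm_boundaries: dict[str, int] = {}
    offset = 0
    spacing = params.gene_spacing_bp
    for chrom in chroms:
        n_c = counts[chrom]
        is_x = not karyotype.is_autosome(chrom)
        hl = half_life[offset : offset + n_c].copy()
        if is_x:
            hl *= params.x_stability_multiplier
        capped = np.zeros(n_c, dtype=bool)
        if params.halflife_cap_h is not None:
            capped = hl > params.halflife_cap_h
            hl = np.minimum(hl, params.halflife_cap_h)
        chrom_len = length[offset : offset + n_c]
        starts = spacing * (1 + np.arange(n_c))
        # two arms: boundary midway between the two central genes
        arm_boundaries[chrom] = int(spacing * (1 + n_c // 2) - spacing // 2)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": [f"g{chrom}_{i:05d}" for i in range(n_c)],
                    "chromosome": chrom,
                    "strand": rng.choice(["+", "-"], size=n_c),
                    "start": starts,
                    "end": starts + chrom_len - 1,
                    "half_life_h": hl,
                    "rpkm": rpkm[offset : offset + n_c],
                    "mrna_length_bp": chrom_len,
                    "is_housekeeping": rng.random(n_c) < params.housekeeping_fraction,
                    "capped": capped,
                }
            )
        )
        offset += n_c

    df = pd.concat(frames, ignore_index=True)
    table = GeneTable(df, dataset_label=f"synthetic(seed={params.seed})",
                      karyotype=karyotype)

    x_names = [c for c in chroms if not karyotype.is_autosome(c)]
    a_mask = df["chromosome"].isin([c for c in chroms if karyotype.is_autosome(c)])
    truth = {
        "params": _params_to_dict(params),
        "arm_boundaries": arm_boundaries,
        "per_chromosome_mean_half_life": df.groupby("chromosome")["half_life_h"]
        .mean().to_dict(),
        "autosomal_mean_half_life": float(df.loc[a_mask, "half_life_h"].mean()),
        "x_mean_half_life": float(df.loc[df["chromosome"].isin(x_names),
                                         "half_life_h"].mean()),
        "n_capped": int(df["capped"].sum()),
    }
    truth["realized_xaa_half_life"] = (
        truth["x_mean_half_life"] / truth["autosomal_mean_half_life"]
    )
    return table, truth


def generate_ribo_dataset(
    params: SyntheticParams,
    gene_table: GeneTable,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Poisson ribo-seq/RNA-seq counts for every gene in the table.

    RNA counts have expectation rpkm * length_kb * library_millions; ribo
    counts multiply that expectation (rescaled to the ribo library) by a
    per-gene log-normal density that is ``ribo_density_x_multiplier``-fold
    higher on the X chromosome.
    """
    rng = rng if rng is not None else params.rng(_KEY_RIBO)
    df = gene_table.df
    if df["rpkm"].isna().any() or df["mrna_length_bp"].isna().any():
        raise InputError("gene table must carry rpkm and mrna_length_bp")
    rpkm = df["rpkm"].to_numpy(dtype=float)
    length = df["mrna_length_bp"].to_numpy(dtype=float)
    is_x = ~df["chromosome"].isin(list(params.karyotype.autosomes)).to_numpy()

    density = np.exp(
        rng.normal(-params.density_log_sd ** 2 / 2, params.density_log_sd, len(df))
    )
    density[is_x] *= params.ribo_density_x_multiplier

    mu_rna = rpkm * length * params.library_size_rna / 1e9
    mu_ribo = rpkm * density * length * params.library_size_ribo / 1e9
    rna = rng.poisson(mu_rna)
    ribo = rng.poisson(mu_ribo)
    idx = pd.Index(df["gene_id"], name="gene_id")
    return pd.Series(ribo, index=idx, name="ribo_count"), pd.Series(
        rna, index=idx, name="rna_count"
    )


def generate_condition_pair(
    params: SyntheticParams,
    gene_table: GeneTable,
    global_destabilization: float = 5.3 / 8.1,
    x_extra_effect: float = 0.9,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Paired control/treatment half-lives.

    treatment = control * global_destabilization * (x_extra_effect on X)
    with per-gene log-normal noise (``pair_noise_log_sd``).
    """
    if global_destabilization <= 0 or x_extra_effect <= 0:
        raise ConfigurationError("condition-pair factors must be positive")
    rng = rng if rng is not None else params.rng(_KEY_PAIR)
    df = gene_table.df
    if df["half_life_h"].isna().all():
        raise InputError("gene table carries no half-lives")
    control = df["half_life_h"].to_numpy(dtype=float)
    is_x = ~df["chromosome"].isin(list(params.karyotype.autosomes)).to_numpy()
    factor = np.where(is_x, global_destabilization * x_extra_effect,
                      global_destabilization)
    if params.pair_noise_log_sd > 0:
        noise = np.exp(
            rng.normal(-params.pair_noise_log_sd ** 2 / 2,
                       params.pair_noise_log_sd, len(df))
        )
    else:
        noise = 1.0
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "control": control,
            "treatment": control * factor * noise,
        }
    )


def _random_cds(rng: np.random.Generator, n_codons: int, gc3: float) -> str:
    bases = np.array(list("ACGT"))
    first_two = bases[rng.integers(0, 4, size=(n_codons, 2))]
    gc_third = rng.random(n_codons) < gc3
    thirds = np.where(
        gc_third,
        np.where(rng.random(n_codons) < 0.5, "G", "C"),
        np.where(rng.random(n_codons) < 0.5, "A", "T"),
    )
    codons = np.column_stack([first_two, thirds])
    codons[0] = ["A", "T", "G"]
    return "".join(codons.ravel())


def generate_sequences(
    params: SyntheticParams,
    gene_table: GeneTable,
    rng: np.random.Generator | None = None,
) -> tuple[list[SeqRecord], list[IntervalRecord], dict[str, SeqRecord]]:
    """Random CDS, 3'-UTR intervals and the synthetic genome carrying them.

    Each gene gets a CDS starting with ATG (length a multiple of 3, >= 60 nt)
    whose third-codon GC matches the chromosome's GC3 target, and a 3'-UTR
    interval pointing at a stretch of the generated chromosome sequence.
    ``invalid_cds_fraction`` of the CDS are deliberately spoiled (too short
    or start codon replaced) to exercise downstream filters.
    """
    rng = rng if rng is not None else params.rng(_KEY_SEQ)
    df = gene_table.df
    gc3_map = dict(params.gc3_by_chromosome or {})
    bases = np.array(list("ACGT"))

    n = len(df)
    invalid_ids: dict[str, str] = {}
    if params.invalid_cds_fraction > 0:
        n_bad = int(round(params.invalid_cds_fraction * n))
        bad_idx = rng.choice(n, size=n_bad, replace=False)
        for rank, i in enumerate(bad_idx):
            invalid_ids[df["gene_id"].iloc[i]] = (
                "too_short" if rank % 2 == 0 else "no_start_codon"
            )

    cds: list[SeqRecord] = []
    utr_seqs: dict[str, str] = {}
    for _, row in df.iterrows():
        gid, chrom = row["gene_id"], row["chromosome"]
        gc3 = gc3_map.get(chrom, params.gc3_default)
        n_codons = int(rng.integers(20, 301))
        seq = _random_cds(rng, n_codons, gc3)
        kind = invalid_ids.get(gid)
        if kind == "too_short":
            seq = seq[:30]
        elif kind == "no_start_codon":
            seq = "GTG" + seq[3:]
        cds.append(SeqRecord(id=f"{gid}_cds", sequence=seq, chromosome=chrom))
        utr_len = int(rng.integers(params.utr_length_mean // 2,
                                   params.utr_length_mean * 3 // 2 + 1))
        utr_seqs[gid] = "".join(bases[rng.integers(0, 4, size=utr_len)])

    intervals: list[IntervalRecord] = []
    genome: dict[str, SeqRecord] = {}
    for chrom, sub in df.groupby("chromosome", sort=False):
        parts: list[str] = []
        pos = 0
        for _, row in sub.iterrows():
            gid, strand = row["gene_id"], row["strand"]
            strand = strand if strand in ("+", "-") else "+"
            spacer = "".join(bases[rng.integers(0, 4, size=50)])
            sense = utr_seqs[gid]
            placed = sense if strand == "+" else reverse_complement(sense)
            start = pos + len(spacer)
            end = start + len(placed)
            intervals.append(
                IntervalRecord(chrom, start, end, strand, name=f"{gid}_utr3")
            )
            parts.append(spacer)
            parts.append(placed)
            pos = end
        genome[chrom] = SeqRecord(id=chrom, sequence="".join(parts),
                                  chromosome=chrom)
    return cds, intervals, genome


def generate_bundle(params: SyntheticParams) -> SyntheticBundle:
    """Generate the complete, mutually consistent dataset."""
    table, truth = generate_gene_table(params)
    ribo, rna = generate_ribo_dataset(params, table)
    pair = generate_condition_pair(params, table)
    cds, intervals, genome = generate_sequences(params, table)
    truth = dict(truth)
    truth["planted_invalid_cds"] = int(
        round(params.invalid_cds_fraction * len(table))
    )
    truth["condition_pair_defaults"] = {
        "global_destabilization": 5.3 / 8.1,
        "x_extra_effect": 0.9,
    }
    return SyntheticBundle(
        gene_table=table, ribo_counts=ribo, rna_counts=rna,
        condition_pair=pair, cds=cds, utr_intervals=intervals,
        genome=genome, truth=truth,
    )


def _params_to_dict(params: SyntheticParams) -> dict:
    d = {}
    for name in params.__dataclass_fields__:
        v = getattr(params, name)
        if name == "karyotype":
            v = v.name or list(v.names)
        elif isinstance(v, Mapping):
            v = dict(v)
        d[name] = v
    return d


def write_bundle(bundle: SyntheticBundle, out_dir) -> None:
    """Persist a bundle as plain-text files (TSV/FASTA/BED/JSON)."""
    import json
    from pathlib import Path

    from .tables import write_bed, write_fasta, write_gene_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_table(bundle.gene_table, out / "genes.tsv")
    bundle.ribo_counts.to_frame().to_csv(out / "ribo_counts.tsv", sep="\t")
    bundle.rna_counts.to_frame().to_csv(out / "rna_counts.tsv", sep="\t")
    bundle.condition_pair.to_csv(out / "pair.tsv", sep="\t", index=False)
    write_fasta(bundle.cds, out / "cds.fasta")
    write_bed(bundle.utr_intervals, out / "utr.bed")
    write_fasta(bundle.genome.values(), out / "genome.fasta")
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True, default=str)
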