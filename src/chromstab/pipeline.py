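"""End-to-end orchestration from a single configuration.

``run_pipeline`` drives the stages in dependency order (simulate/ingest ->
stability -> resample -> spatial -> ribodensity -> seqfeat -> stratify ->
paired), writing one TSV/JSON artifact per stage into a run directory and a
machine-readable report of per-stage record counts and parameters. With
identical config and seeds the numeric outputs are byte-identical.

Configs may be built in Python or loaded from a TOML file via
:meth:`RunConfig.from_toml`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .karyotype import HUMAN, MOUSE, Karyotype
from .nulls import resample_null, sliding_window_profile
from .ribosome import (
    FilterThresholds,
    add_density,
    apply_filters,
    build_ribo_table,
    density_by_chromosome,
)
from .seqfeat import filter_cds, gc_by_chromosome, kmer_word_matrix, uv_scale_pca
from .simulate import SyntheticParams, generate_bundle, write_bundle
from .stats import (
    chromosome_summary,
    paired_condition_delta,
    pairwise_chromosome_tests,
    spearman_by_group,
    stratify_housekeeping,
    summaries_to_frame,
    x_vs_autosomes_test,
    xaa_ratio,
)
from .tables import (
    extract_utr_sequences,
    group_by_chromosome,
    read_bed,
    read_fasta,
    read_gene_table,
)

__all__ = ["RunConfig", "RunReport", "StageRecord", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "stability",
    "resample",
    "spatial",
    "ribodensity",
    "seqfeat",
    "stratify",
    "paired",
)

_KARYOTYPES = {"human": HUMAN, "mouse": MOUSE}


@dataclass
class RunConfig:
    out_dir: Path
    simulate: SyntheticParams | None = None
    genes_path: Path | None = None
    ribo_counts_path: Path | None = None
    rna_counts_path: Path | None = None
    pair_path: Path | None = None
    cds_path: Path | None = None
    utr_bed_path: Path | None = None
    genome_path: Path | None = None
    arms_path: Path | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    karyotype: Karyotype = HUMAN
    stages: tuple[str, ...] = ALL_STAGES
    value_name: str = "half_life_h"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    window_size: int = 30
    step: int = 1
    resample_n_draw: int | None = None  # default: number of X genes
    resample_B: int = 100_000
    seed: int = 0
    correction: str = "bonferroni"
    exclude_capped: bool = False
    pca_components: int = 2

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw: dict = {}
        for key in (
            "out_dir", "genes_path", "ribo_counts_path", "rna_counts_path",
            "pair_path", "cds_path", "utr_bed_path", "genome_path", "arms_path",
        ):
            if key in raw:
                kw[key] = Path(raw[key])
        for key in (
            "column_map", "value_name", "window_size", "step", "resample_n_draw",
            "resample_B", "seed", "correction", "exclude_capped", "pca_components",
        ):
            if key in raw:
                kw[key] = raw[key]
        if "stages" in raw:
            kw["stages"] = tuple(raw["stages"])
        if "karyotype" in raw:
            try:
                kw["karyotype"] = _KARYOTYPES[raw["karyotype"]]
            except KeyError:
                raise ConfigurationError(f"unknown karyotype {raw['karyotype']!r}")
        if "thresholds" in raw:
            t = dict(raw["thresholds"])
            if "exclusion" in t:
                t["exclusion"] = frozenset(t["exclusion"])
            kw["thresholds"] = FilterThresholds(**t)
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", kw.get("seed", 0))
            if "halflife_cap_h" in sim and sim["halflife_cap_h"] in (0, "none"):
                sim["halflife_cap_h"] = None
            kw["simulate"] = SyntheticParams(**sim)
        if "out_dir" not in kw:
            raise ConfigurationError("config must set out_dir")
        return cls(**kw)

    def validate(self) -> None:
        if (self.simulate is None) == (self.genes_path is None):
            raise ConfigurationError(
                "exactly one of a simulate block or genes_path is required"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        if self.correction not in ("bonferroni", "holm"):
            raise ConfigurationError(f"unknown correction {self.correction!r}")
        if self.simulate is None:
            if "ribodensity" in self.stages and (
                self.ribo_counts_path is None or self.rna_counts_path is None
            ):
                raise ConfigurationError(
                    "ribodensity stage enabled but count tables missing"
                )
            if "seqfeat" in self.stages and (
                self.cds_path is None
                or self.utr_bed_path is None
                or self.genome_path is None
            ):
                raise ConfigurationError(
                    "seqfeat stage enabled but cds/utr/genome inputs missing"
                )
            if "paired" in self.stages and self.pair_path is None:
                raise ConfigurationError("paired stage enabled but pair_path missing")
            if "spatial" in self.stages and self.arms_path is None:
                raise ConfigurationError("spatial stage enabled but arms_path missing")


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    seconds: float


@dataclass
class RunReport:
    stages: list[StageRecord]
    config_echo: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config_echo,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }


def _config_echo(config: RunConfig) -> dict:
    echo: dict = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, Path):
            v = str(v)
        elif isinstance(v, SyntheticParams):
            from .simulate import _params_to_dict

            v = _params_to_dict(v)
        elif isinstance(v, FilterThresholds):
            v = {**dataclasses.asdict(v), "exclusion": sorted(v.exclusion)}
        elif isinstance(v, Karyotype):
            v = v.name or list(v.names)
        elif isinstance(v, tuple):
            v = list(v)
        echo[f.name] = v
    return echo


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every enabled stage and write its outputs under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(stages=[], config_echo=_config_echo(config))
    t0 = time.perf_counter()

    # --- data acquisition -------------------------------------------------
    arm_boundaries: dict[str, int] | None = None
    bundle = None
    if config.simulate is not None:
        bundle = generate_bundle(config.simulate)
        table = bundle.gene_table
        write_bundle(bundle, out / "simulated")
        arm_boundaries = bundle.truth["arm_boundaries"]
        report.stages.append(
            StageRecord("simulate", 0, len(table), time.perf_counter() - t0)
        )
    else:
        table = read_gene_table(
            config.genes_path, config.column_map, config.karyotype
        )
        if config.arms_path is not None:
            arms = pd.read_csv(config.arms_path, sep="\t", comment="#")
            arm_boundaries = dict(
                zip(arms["chromosome"].astype(str), arms["centromere"].astype(int))
            )
        report.stages.append(
            StageRecord("ingest", len(table), len(table), time.perf_counter() - t0)
        )

    value = config.value_name
    n_in = len(table)

    # --- stability --------------------------------------------------------
    if "stability" in config.stages:
        t = time.perf_counter()
        summaries = chromosome_summary(
            table, value, exclude_capped=config.exclude_capped
        )
        sframe = summaries_to_frame(summaries)
        sframe.to_csv(out / "summaries.tsv", sep="\t", index=False)
        pw = pairwise_chromosome_tests(
            table, value, config.correction, exclude_capped=config.exclude_capped
        )
        pw.to_csv(out / "pairwise_p.tsv", sep="\t")
        n_pairs = len(pw) * (len(pw) - 1) // 2
        xa = x_vs_autosomes_test(table, value, n_comparisons=n_pairs,
                                 exclude_capped=config.exclude_capped)
        tests = pd.DataFrame(
            [
                {
                    "test": "x_vs_autosomes",
                    "statistic": xa.statistic,
                    "p_value": xa.p_value,
                    "corrected": xa.corrected,
                    "n_comparisons": xa.n_comparisons,
                    "xaa_ratio": xaa_ratio(table, value,
                                           exclude_capped=config.exclude_capped),
                }
            ]
        )
        tests.to_csv(out / "stability_tests.tsv", sep="\t", index=False)
        corr_rows = []
        for other in ("rpkm", "mrna_length_bp"):
            if table.df[other].notna().sum() >= 3:
                rho = spearman_by_group(table, value, other)
                corr_rows.append({"pair": f"{value}~{other}",
                                  "rho_X": rho["X"], "rho_A": rho["A"]})
        if corr_rows:
            pd.DataFrame(corr_rows).to_csv(out / "correlations.tsv", sep="\t",
                                           index=False)
        report.stages.append(
            StageRecord("stability", n_in, len(sframe), time.perf_counter() - t)
        )

    # --- resampling null --------------------------------------------------
    if "resample" in config.stages:
        t = time.perf_counter()
        auto = table.autosomal_values(value, exclude_capped=config.exclude_capped)
        x_vals = table.x_values(value, exclude_capped=config.exclude_capped)
        n_draw = config.resample_n_draw or len(x_vals)
        res = resample_null(
            auto, n_draw=n_draw, B=config.resample_B,
            observed=float(x_vals.mean()), seed=config.seed,
        )
        with open(out / "resampling.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=1, sort_keys=True)
        pd.DataFrame(
            {
                "bin_low": res.hist_edges[:-1],
                "bin_high": res.hist_edges[1:],
                "count": res.hist_counts,
            }
        ).to_csv(out / "histogram.tsv", sep="\t", index=False)
        report.stages.append(
            StageRecord("resample", len(auto), res.B, time.perf_counter() - t)
        )

    # --- spatial profiles -------------------------------------------------
    if "spatial" in config.stages:
        t = time.perf_counter()
        if arm_boundaries is None:
            raise ConfigurationError("spatial stage requires arm boundaries")
        profiles = sliding_window_profile(
            table, value, config.window_size, config.step, arm_boundaries
        )
        rows = [
            {
                "chromosome": p.chromosome,
                "arm": p.arm,
                "window_index": w.index,
                "mean": w.mean,
                "center_gene": w.gene_ids[-(-p.window_size // 2) - 1],
            }
            for p in profiles
            for w in p.windows
        ]
        pd.DataFrame(
            rows, columns=["chromosome", "arm", "window_index", "mean", "center_gene"]
        ).to_csv(out / "windows.tsv", sep="\t", index=False)
        report.stages.append(
            StageRecord("spatial", n_in, len(rows), time.perf_counter() - t)
        )

    # --- ribosome density ---------------------------------------------------
    if "ribodensity" in config.stages:
        t = time.perf_counter()
        if bundle is not None:
            ribo_counts, rna_counts = bundle.ribo_counts, bundle.rna_counts
        else:
            ribo_counts = pd.read_csv(
                config.ribo_counts_path, sep="\t", index_col="gene_id"
            ).iloc[:, 0]
            rna_counts = pd.read_csv(
                config.rna_counts_path, sep="\t", index_col="gene_id"
            ).iloc[:, 0]
        records = build_ribo_table(table, ribo_counts, rna_counts)
        kept, removed = apply_filters(records, config.thresholds)
        dens = add_density(kept)
        dens.to_csv(out / "densities.tsv", sep="\t", index=False)
        result = density_by_chromosome(dens, config.karyotype, config.correction)
        summaries_to_frame(result.summaries).to_csv(
            out / "density_summaries.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "test": "x_vs_autosomes",
                    "statistic": result.xa_test.statistic,
                    "p_value": result.xa_test.p_value,
                    "p_value_corrected": result.xa_test_corrected.p_value,
                    "n_comparisons": result.xa_test_corrected.n_comparisons,
                    "xa_density_ratio": result.xa_ratio,
                    **{f"removed_{k}": v for k, v in removed.items()},
                }
            ]
        ).to_csv(out / "density_tests.tsv", sep="\t", index=False)
        report.stages.append(
            StageRecord("ribodensity", len(records), len(dens),
                        time.perf_counter() - t)
        )

    # --- sequence features --------------------------------------------------
    if "seqfeat" in config.stages:
        t = time.perf_counter()
        if bundle is not None:
            cds = bundle.cds
            intervals = bundle.utr_intervals
            genome = bundle.genome
        else:
            cds = read_fasta(config.cds_path)
            intervals = read_bed(config.utr_bed_path)
            genome = {r.id: r for r in read_fasta(config.genome_path)}
        valid, rejected = filter_cds(cds)
        gc_by_chromosome(valid).to_csv(out / "gc_by_chromosome.tsv", sep="\t",
                                       index=False)
        utrs = extract_utr_sequences(intervals, genome)
        id_to_chrom = dict(zip(table.df["gene_id"], table.df["chromosome"]))
        regrouped = []
        for rec in utrs:
            gene = rec.id.removesuffix("_utr3")
            chrom = id_to_chrom.get(gene, rec.chromosome)
            regrouped.append(type(rec)(rec.id, rec.sequence, chrom))
        km = kmer_word_matrix(group_by_chromosome(regrouped))
        km.frame.to_csv(out / "kmer_matrix.tsv", sep="\t",
                        index_label="chromosome")
        pca = uv_scale_pca(km, n_components=config.pca_components)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t",
                          index_label="chromosome")
        pd.DataFrame(
            {
                "component": list(pca.scores.columns),
                "explained_variance_pct": pca.explained_variance_pct,
                "explained_remaining_pct": pca.explained_remaining_pct,
            }
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        report.stages.append(
            StageRecord("seqfeat", len(cds), len(valid), time.perf_counter() - t)
        )

    # --- housekeeping stratification ----------------------------------------
    if "stratify" in config.stages:
        t = time.perf_counter()
        strat = stratify_housekeeping(table, value)
        rows = [
            {
                "compartment": comp,
                "housekeeping": flag,
                "n": s.n,
                "mean": s.mean,
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "count_ratio_hk_to_non": strat.count_ratio[comp],
            }
            for (comp, flag), s in sorted(strat.cells.items())
        ]
        pd.DataFrame(rows).to_csv(out / "housekeeping.tsv", sep="\t", index=False)
        report.stages.append(
            StageRecord("stratify", n_in, len(rows), time.perf_counter() - t)
        )

    # --- paired conditions ---------------------------------------------------
    if "paired" in config.stages:
        t = time.perf_counter()
        if bundle is not None:
            pair = bundle.condition_pair
        else:
            pair = pd.read_csv(config.pair_path, sep="\t")
        delta = paired_condition_delta(pair, table)
        delta.to_csv(out / "paired_delta.tsv", sep="\t", index=False)
        report.stages.append(
            StageRecord("paired", len(pair), len(delta), time.perf_counter() - t)
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True, default=str)
    return report
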