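"""End-to-end orchestration: simulate -> assign -> filter -> stats -> classify
-> targeted ASE, from one config, with reproducible seeds.

``run_pipeline`` exercises three strands on synthetic inputs with known
ground truth and writes every intermediate as CSV (with a seed-stamped header
comment) plus a summary of per-stage tallies:

1. read level — a toy genome pair with annotations, chain and reads is
   generated, reads are competitively assigned, counted into conserved
   constitutive exons, and the parental mismap filter is evaluated;
2. count level — NB counts for the full 2 species x 2 conditions design are
   simulated, CPM-filtered, pushed through the cis/trans contrast battery and
   classified into regulatory and dominance categories;
3. targeted — amplicon allele counts and qPCR Ct tables for a small panel are
   simulated and analysed with the overdispersed logistic and factorial
   trans models.

``load_supplementary_counts`` ingests externally deposited count matrices
whose column names follow the ``<GENOTYPE>_<allele>_<condition>_<rep>``
convention.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign as asn
from . import classify as cls
from . import stats as st
from . import synthetic as syn
from . import targeted as tgt
from .containers import AlleleCountMatrix, parse_sample_name

logger = logging.getLogger("cistrans")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults mirror the study conditions."""

    outdir: str = "cistrans_run"
    seed: int = 0
    tissue: str = "hemocyte"
    # count-level simulation
    n_genes: int = 600
    effect_size: float = 2.0
    dispersion: float = 0.05
    n_replicates: int | None = None      # None -> 3 hemocyte / 5 fat body
    # filters and thresholds
    alpha: float = 0.05
    min_lfc: float = 1.25
    cpm_max: float = 3.0
    min_libraries: int | None = None     # None -> 3 hemocyte / 5 fat body
    mismap_threshold: float = 0.01
    # read-level simulation
    genome_genes: int = 8
    snp_rate: float = 0.01
    indel_rate: float = 0.002
    n_reads: int = 2000
    read_length: int = 100
    # targeted panel
    panel_size: int = 13
    amplicon_depth: int = 2000
    amplicon_samples: int = 10
    amplicon_overdispersion: float = 0.01
    qpcr_noise_sd: float = 0.2
    qpcr_replicates: int = 10

    def validate(self, n_libraries: int | None = None) -> None:
        positive = {
            "alpha": self.alpha, "min_lfc": self.min_lfc, "cpm_max": self.cpm_max,
            "mismap_threshold": self.mismap_threshold, "n_genes": self.n_genes,
            "dispersion": self.dispersion,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if n_libraries is not None and self.resolved_min_libraries() > n_libraries:
            raise ValueError(
                f"min_libraries={self.resolved_min_libraries()} exceeds the "
                f"{n_libraries} libraries in the design")

    def resolved_replicates(self) -> int:
        return self.n_replicates or syn.DEFAULT_REPLICATES[self.tissue]

    def resolved_min_libraries(self) -> int:
        return self.min_libraries or asn.MIN_LIBRARIES[self.tissue]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _write_csv(df: pd.DataFrame, path, seed: int, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cistrans output, seed={seed}\n")
        df.to_csv(fh, index=index)


def _read_stage(config: RunConfig, outdir: Path) -> dict:
    """Toy genome pair -> assignment -> counting -> mismap filter."""
    sim = syn.simulate_genome_pair(
        n_genes=config.genome_genes, snp_rate=config.snp_rate,
        indel_rate=config.indel_rate, seed=config.seed,
        n_reads=config.n_reads, read_length=config.read_length,
    )
    sim.write(outdir / "readsim")
    genomes = asn.GenomeSet.from_sequences(sim.pair.seq_a, sim.pair.seq_b)
    assignments = asn.assign_reads(sim.reads, genomes)
    tallies = assignments["verdict"].value_counts().to_dict()
    exons = asn.derive_conserved_constitutive_exons(
        sim.pair.annotation_a, sim.pair.annotation_b, sim.pair.chain)
    merged = assignments.merge(sim.truth, on="read_id")
    counts_by_lib = {}
    for origin in ("sim", "sec"):
        sub = merged[merged["origin"] == origin]
        counts_by_lib[f"parent_{origin}"] = asn.count_alleles(
            sub, exons, sim.pair.chain, sim.pair.annotation_a, sim.pair.annotation_b,
            config.read_length)
    gene_counts = pd.DataFrame(counts_by_lib).fillna(0).astype(int)
    gene_counts.index.names = ["gene_id", "allele"]
    mismap = asn.estimate_mismap(
        gene_counts, {"parent_sim": "sim", "parent_sec": "sec"},
        threshold=config.mismap_threshold)
    _write_csv(gene_counts.reset_index(), outdir / "read_counts.csv", config.seed)
    _write_csv(mismap.reset_index(), outdir / "mismap_report.csv", config.seed)
    for verdict in asn.VERDICTS:
        logger.info("read stage: %s reads %d", verdict, tallies.get(verdict, 0))
    return {
        "verdict_tallies": {v: int(tallies.get(v, 0)) for v in asn.VERDICTS},
        "n_conserved_genes": sum(1 for s in exons.segments.values() if s),
        "n_mismap_filtered": int(mismap["filtered"].sum()),
    }


def _count_stage(config: RunConfig, outdir: Path) -> dict:
    """Simulated counts -> CPM filter -> contrasts -> categories."""
    truth = syn.make_mixed_truth(
        config.n_genes, config.seed + 1, effect_size=config.effect_size,
        dispersion=config.dispersion)
    design = syn.make_design(config.tissue, config.n_replicates, seed=config.seed + 2)
    matrix = syn.simulate_counts(truth, design, seed=config.seed + 3)
    libs = matrix.meta.set_index("sample_id")["library_size"]
    retained = asn.cpm_filter(matrix.counts, libs, config.cpm_max,
                              config.resolved_min_libraries())
    filtered = matrix.subset_genes(matrix.genes[retained])
    logger.info("count stage: %d of %d genes pass the CPM filter",
                retained.sum(), len(retained))
    estimates = st.fit_contrasts(filtered)
    regulatory = cls.classify_regulatory(estimates, alpha=config.alpha)
    dominance_in = st.fit_parent_hybrid_contrasts(filtered)
    dominance = cls.classify_dominance(dominance_in, alpha=config.alpha,
                                       min_lfc=config.min_lfc)
    _write_csv(truth, outdir / "truth.csv", config.seed)
    matrix.to_csv(outdir / "counts.csv", outdir / "sample_meta.csv",
                  header_comment=f"cistrans output, seed={config.seed}")
    _write_csv(estimates, outdir / "regulatory_estimates.csv", config.seed)
    _write_csv(regulatory, outdir / "regulatory_categories.csv", config.seed)
    _write_csv(dominance_in, outdir / "dominance_contrasts.csv", config.seed)
    _write_csv(dominance, outdir / "dominance_categories.csv", config.seed)
    cat_counts = cls.category_counts(regulatory)
    _write_csv(cat_counts, outdir / "category_counts.csv", config.seed)
    ctrl = regulatory[regulatory["context"] == "control"]
    return {
        "n_genes_simulated": int(config.n_genes),
        "n_genes_post_cpm": int(retained.sum()),
        "regulatory_counts_control":
            ctrl["category"].value_counts().to_dict(),
        "dominance_counts_control":
            dominance[dominance["context"] == "control"]["category"]
            .value_counts().to_dict(),
    }


def _targeted_stage(config: RunConfig, outdir: Path) -> dict:
    """Amplicon + qPCR panel with a mix of balanced and strongly biased genes."""
    rng = np.random.default_rng(config.seed + 7)
    genes = [f"panel{g:02d}" for g in range(config.panel_size)]
    logit_c = {g: float(rng.normal(0, 1.2)) for g in genes}
    logit_w = {g: logit_c[g] + float(rng.normal(0, 0.5)) for g in genes}
    amp = syn.simulate_amplicon(
        genes, logit_c, logit_w, overdispersion=config.amplicon_overdispersion,
        n_samples=config.amplicon_samples, depth=config.amplicon_depth,
        seed=config.seed + 8)
    ase = tgt.fit_allele_models(amp)
    gdna = tgt.gdna_bias_check(amp)
    # qPCR truth: per genotype x treatment log2 expression consistent with
    # the amplicon cis effects plus a trans component
    rows = []
    for g in genes:
        trans = float(rng.normal(0, 1.0))
        base = float(rng.normal(4, 1))
        cis2 = logit_c[g] / np.log(4.0)  # same cis on the log2 allele scale
        for treatment in ("control", "wasp"):
            resp = 1.0 if treatment == "wasp" else 0.0
            rows += [
                (g, "sim_parent", treatment, base + cis2 + trans + resp),
                (g, "sec_parent", treatment, base + resp),
                (g, "hybrid", treatment, base + resp),
            ]
    expr = pd.DataFrame(rows, columns=["gene", "genotype", "treatment", "log2_expr"])
    qpcr = syn.simulate_qpcr(expr, noise_sd=config.qpcr_noise_sd,
                             n_replicates=config.qpcr_replicates, seed=config.seed + 9)
    props = ase.assign(
        prop_control=lambda d: 1 / (1 + np.exp(-d["logit_control"])),
        prop_wasp=lambda d: 1 / (1 + np.exp(-d["logit_wasp"])))
    prop_long = pd.concat([
        props[["gene", "prop_control"]].rename(columns={"prop_control": "prop_sim"})
        .assign(treatment="control"),
        props[["gene", "prop_wasp"]].rename(columns={"prop_wasp": "prop_sim"})
        .assign(treatment="wasp"),
    ], ignore_index=True)
    alleles = tgt.decompose_qpcr(qpcr, prop_long)
    trans_est = tgt.fit_trans_models(alleles)
    _write_csv(amp, outdir / "amplicon_counts.csv", config.seed)
    _write_csv(ase, outdir / "ase_estimates.csv", config.seed)
    _write_csv(gdna, outdir / "gdna_bias.csv", config.seed)
    _write_csv(qpcr, outdir / "qpcr_table.csv", config.seed)
    _write_csv(alleles, outdir / "qpcr_alleles.csv", config.seed)
    _write_csv(trans_est, outdir / "trans_estimates.csv", config.seed)
    return {
        "n_panel_genes": len(genes),
        "n_gdna_unbiased": int(gdna["unbiased"].sum()),
        "n_significant_ase": int((np.sign(ase["ci_control_lo"])
                                  == np.sign(ase["ci_control_hi"])).sum()),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the summary report."""
    design_cols = 2 * (2 * config.resolved_replicates() + 2 * config.resolved_replicates())
    config.validate(n_libraries=design_cols)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    summary: dict = {"seed": config.seed, "tissue": config.tissue}
    for name, stage in (("read_level", _read_stage),
                        ("count_level", _count_stage),
                        ("targeted", _targeted_stage)):
        try:
            summary[name] = stage(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def load_supplementary_counts(
    path, tissue: str = "hemocyte", dialect: str = "canonical"
) -> tuple[AlleleCountMatrix, list[str]]:
    """Parse a deposited count CSV into an :class:`AlleleCountMatrix`.

    Column names must follow ``<GENOTYPE>_<allele>_<condition>_<rep>``
    (genotype in upper case, allele in lower case).  Returns the matrix plus
    the list of unparseable columns; raises if no column parses.  Library
    sizes are taken as column sums (hybrid allele pairs: sum over the pair),
    the only depth information such a matrix carries.
    """
    df = pd.read_csv(path, index_col=0, comment="#")
    meta_rows, bad = [], []
    for col in df.columns:
        parsed = parse_sample_name(col)
        if parsed is None:
            bad.append(col)
        else:
            meta_rows.append(parsed)
    if not meta_rows:
        raise ValueError(f"no parseable columns in {path}: {bad}")
    if bad:
        logger.warning("unparseable columns ignored: %s", bad)
    meta = pd.DataFrame(meta_rows)
    meta["tissue"] = tissue
    lib_id = []
    for r in meta.itertuples():
        if r.genotype == "hybrid":
            lib_id.append(f"HYBRID_{r.condition}_{r.replicate}")
        else:
            lib_id.append(r.sample_id)
    meta["library_id"] = lib_id
    counts = df[meta["sample_id"]]
    col_sums = counts.sum(axis=0)
    lib_size = {
        lib: float(col_sums[sub["sample_id"]].sum())
        for lib, sub in meta.groupby("library_id")
    }
    meta["library_size"] = meta["library_id"].map(lib_size)
    return AlleleCountMatrix(counts, meta), bad
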