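"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the design of an interspecific allele-specific
expression study: two parental *Drosophila* species and their F1 hybrids,
each sampled in two immune tissues (3 hemocyte or 5 fat-body replicate
libraries per group) under control and immune-challenged conditions.  Hybrid
libraries contribute two allele-level count columns that share one physical
library and one trans environment; only the cis component separates their
means.  Counts are negative binomial with gene-wise dispersion phi in the
mean-dispersion parameterisation var = mu + phi * mu**2.

Per-gene ground truth is expressed as log2 fold changes: ``cis_lfc`` (sim
allele over sec allele), ``trans_lfc`` (parental divergence minus cis), and
species-specific immune-response effects.  Parental divergence is
cis_lfc + trans_lfc by construction.

A second generator builds paired toy genomes (FASTA), annotations (GFF3), an
alignment chain and simulated reads (FASTQ) with per-read origin truth, to
exercise the competitive read-assignment pipeline; further generators emit
overdispersed amplicon allele counts (beta-binomial) and qPCR Ct tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .assign import Chain, derive_conserved_constitutive_exons, write_chain, write_gff3
from .containers import AlleleCountMatrix, sample_name

#: replicate libraries per group, mirroring the study design
DEFAULT_REPLICATES = {"hemocyte": 3, "fat_body": 5}

CATEGORIES = ("conserved", "cis", "trans", "cis_plus_trans", "cis_by_trans", "compensatory")

TRUTH_COLUMNS = [
    "gene_id", "base_log_expr", "cis_lfc", "trans_lfc",
    "response_lfc_sim", "response_lfc_sec", "cis_response_lfc",
    "dispersion", "true_category",
]


def truth_category(cis_lfc: float, trans_lfc: float, tol: float = 1e-9) -> str:
    """Regulatory-mode label implied by the generating effect values."""
    cis_on = abs(cis_lfc) > tol
    trans_on = abs(trans_lfc) > tol
    if not cis_on and not trans_on:
        return "conserved"
    if cis_on and not trans_on:
        return "cis"
    if trans_on and not cis_on:
        return "trans"
    if abs(cis_lfc + trans_lfc) <= tol:
        return "compensatory"
    return "cis_plus_trans" if np.sign(cis_lfc) == np.sign(trans_lfc) else "cis_by_trans"


def make_truth(
    n_genes: int,
    seed: int,
    base_log_expr: float | np.ndarray | None = None,
    cis_lfc: float | np.ndarray = 0.0,
    trans_lfc: float | np.ndarray = 0.0,
    response_lfc_sim: float | np.ndarray = 0.0,
    response_lfc_sec: float | np.ndarray = 0.0,
    cis_response_lfc: float | np.ndarray = 0.0,
    dispersion: float | np.ndarray = 0.1,
) -> pd.DataFrame:
    """Assemble a per-gene ground-truth table.

    ``base_log_expr`` defaults to N(5, 1.5) draws on the log2-CPM scale
    (median ~32 CPM, a typical filtered-gene abundance).  Scalar effects are
    broadcast to all genes.
    """
    rng = np.random.default_rng(seed)
    if base_log_expr is None:
        base_log_expr = rng.normal(5.0, 1.5, n_genes)
    t = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n_genes)],
        "base_log_expr": np.broadcast_to(np.asarray(base_log_expr, float), (n_genes,)).copy(),
        "cis_lfc": np.broadcast_to(np.asarray(cis_lfc, float), (n_genes,)).copy(),
        "trans_lfc": np.broadcast_to(np.asarray(trans_lfc, float), (n_genes,)).copy(),
        "response_lfc_sim": np.broadcast_to(np.asarray(response_lfc_sim, float), (n_genes,)).copy(),
        "response_lfc_sec": np.broadcast_to(np.asarray(response_lfc_sec, float), (n_genes,)).copy(),
        "cis_response_lfc": np.broadcast_to(np.asarray(cis_response_lfc, float), (n_genes,)).copy(),
        "dispersion": np.broadcast_to(np.asarray(dispersion, float), (n_genes,)).copy(),
    })
    if (t["dispersion"] <= 0).any():
        raise ValueError("dispersion must be positive")
    t["true_category"] = [truth_category(c, tr) for c, tr in zip(t["cis_lfc"], t["trans_lfc"])]
    return t


def make_mixed_truth(
    n_genes: int,
    seed: int,
    effect_size: float = 2.0,
    dispersion: float = 0.05,
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Truth table with genes split evenly across regulatory categories,
    each active component at +-``effect_size`` log2 fold change."""
    rng = np.random.default_rng(seed)
    cats = np.array(categories)[np.arange(n_genes) % len(categories)]
    sign = rng.choice([-1.0, 1.0], n_genes)
    cis = np.where(np.isin(cats, ["cis", "cis_plus_trans", "cis_by_trans", "compensatory"]),
                   sign * effect_size, 0.0)
    trans = np.zeros(n_genes)
    trans[cats == "trans"] = sign[cats == "trans"] * effect_size
    trans[cats == "cis_plus_trans"] = cis[cats == "cis_plus_trans"]
    trans[cats == "cis_by_trans"] = -0.5 * cis[cats == "cis_by_trans"]
    trans[cats == "compensatory"] = -cis[cats == "compensatory"]
    return make_truth(n_genes, seed + 1, cis_lfc=cis, trans_lfc=trans, dispersion=dispersion)


def make_design(
    tissue: str = "hemocyte",
    n_replicates: int | None = None,
    mean_library_size: float = 5e6,
    library_size_cv: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample metadata table for one tissue: parents (allele='total') and
    hybrid allele pairs sharing one physical library per replicate."""
    if n_replicates is None:
        n_replicates = DEFAULT_REPLICATES[tissue]
    rng = np.random.default_rng(seed)
    rows = []
    for condition in ("control", "challenged"):
        for genotype in ("sim_parent", "sec_parent"):
            for rep in range(1, n_replicates + 1):
                size = mean_library_size * rng.lognormal(0.0, library_size_cv)
                sid = sample_name(genotype, "total", condition, rep)
                rows.append((sid, genotype, "total", condition, tissue, rep, sid, size))
        for rep in range(1, n_replicates + 1):
            size = mean_library_size * rng.lognormal(0.0, library_size_cv)
            lib = f"HYBRID_{condition}_{rep}"
            for allele in ("sim", "sec"):
                sid = sample_name("hybrid", allele, condition, rep)
                rows.append((sid, "hybrid", allele, condition, tissue, rep, lib, size))
    return pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "allele", "condition", "tissue",
        "replicate", "library_id", "library_size",
    ])


def _log2_mean(truth: pd.DataFrame, meta_row) -> np.ndarray:
    """Expected log2 CPM for every gene in one sample."""
    base = truth["base_log_expr"].to_numpy()
    cis = truth["cis_lfc"].to_numpy()
    trans = truth["trans_lfc"].to_numpy()
    r_sim = truth["response_lfc_sim"].to_numpy()
    r_sec = truth["response_lfc_sec"].to_numpy()
    r_cis = truth["cis_response_lfc"].to_numpy()
    challenged = meta_row.condition == "challenged"
    g, a = meta_row.genotype, meta_row.allele
    if g == "sim_parent":
        return base + cis + trans + (r_sim if challenged else 0.0)
    if g == "sec_parent":
        return base + (r_sec if challenged else 0.0)
    # hybrid allele columns: one chromosome per allele, so half the baseline;
    # the alleles share the hybrid trans environment and differ only in cis
    r_hyb = 0.5 * (r_sim + r_sec)
    if a == "sim":
        return base - 1.0 + cis + (r_hyb + r_cis if challenged else 0.0)
    if a == "sec":
        return base - 1.0 + (r_hyb if challenged else 0.0)
    raise ValueError(f"hybrid sample with allele {a!r}")


def simulate_counts(truth: pd.DataFrame, design: pd.DataFrame, seed: int) -> AlleleCountMatrix:
    """Draw NB counts for every gene x sample of the design.

    Expected counts are ``2**log2cpm * library_size / 1e6``; the variance is
    mu + phi*mu^2 with gene-wise phi from the truth table.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    groups = design.groupby(["genotype", "allele", "condition"]).size()
    if (groups < 2).any():
        raise ValueError("each group needs >= 2 replicates")
    if (design["library_size"] <= 0).any():
        raise ValueError("library sizes must be positive")
    if (truth["dispersion"] <= 0).any():
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    phi = truth["dispersion"].to_numpy()
    r = 1.0 / phi
    cols = {}
    for row in design.itertuples():
        mu = 2.0 ** _log2_mean(truth, row) * (row.library_size / 1e6)
        p = r / (r + mu)
        cols[row.sample_id] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(cols, index=truth["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    return AlleleCountMatrix(counts, design)


# ---------------------------------------------------------------------------
# Paired toy genomes, annotations, chain and reads
# ---------------------------------------------------------------------------

@dataclass
class GenomePair:
    """Two toy genomes related by SNPs/indels, with annotations and a chain.

    Genome A plays the *D. simulans* line, genome B the *D. sechellia* line.
    ``variants`` records SNP positions on both coordinate systems; every
    variant lies inside an aligned chain block by construction.
    """

    seq_a: str
    seq_b: str
    annotation_a: pd.DataFrame
    annotation_b: pd.DataFrame
    chain: Chain
    variants: pd.DataFrame


@dataclass
class ReadSimulation:
    pair: GenomePair
    reads: list[tuple[str, str]]
    truth: pd.DataFrame  # read_id, origin, gene_id, start

    def write(self, outdir) -> dict[str, Path]:
        """Emit FASTA x2, GFF3 x2, chain, FASTQ and the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta_a": outdir / "genome_sim.fa", "fasta_b": outdir / "genome_sec.fa",
            "gff_a": outdir / "annot_sim.gff3", "gff_b": outdir / "annot_sec.gff3",
            "chain": outdir / "sim_to_sec.chain", "fastq": outdir / "reads.fastq",
            "truth": outdir / "read_truth.csv",
        }
        _write_fasta(paths["fasta_a"], "chrA", self.pair.seq_a)
        _write_fasta(paths["fasta_b"], "chrB", self.pair.seq_b)
        write_gff3(self.pair.annotation_a, paths["gff_a"], seqid="chrA")
        write_gff3(self.pair.annotation_b, paths["gff_b"], seqid="chrB")
        write_chain(self.pair.chain, paths["chain"])
        with open(paths["fastq"], "w") as fh:
            for read_id, seq in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _write_fasta(path, name, seq, width=70):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def _mutate(seq_a: str, snp_rate: float, indel_rate: float, rng):
    """Derive genome B from A; returns (seq_b, a2b map, variants)."""
    bases = "ACGT"
    a2b = np.full(len(seq_a), -1, dtype=np.int64)
    out = []
    variants = []
    i = 0
    while i < len(seq_a):
        u = rng.random()
        if indel_rate > 0 and u < indel_rate / 2:       # deletion from B
            i += int(rng.integers(1, 4))
            continue
        if indel_rate > 0 and u < indel_rate:            # insertion into B
            for _ in range(int(rng.integers(1, 4))):
                out.append(bases[rng.integers(4)])
        base = seq_a[i]
        if rng.random() < snp_rate:
            alt = bases[rng.integers(4)]
            while alt == base:
                alt = bases[rng.integers(4)]
            variants.append((i, len(out), base, alt))
            base = alt
        a2b[i] = len(out)
        out.append(base)
        i += 1
    variants = pd.DataFrame(variants, columns=["pos_a", "pos_b", "ref", "alt"])
    return "".join(out), a2b, variants


def _chain_from_map(a2b: np.ndarray, len_b: int) -> Chain:
    """Chain blocks from the per-base alignment map (runs of consecutive mapping)."""
    blocks = []
    start_a = None
    prev_a = prev_b = None
    for a_pos in np.flatnonzero(a2b >= 0):
        b_pos = a2b[a_pos]
        if start_a is not None and a_pos == prev_a + 1 and b_pos == prev_b + 1:
            prev_a, prev_b = a_pos, b_pos
            continue
        if start_a is not None:
            blocks.append((start_a, prev_a + 1, a2b[start_a], prev_b + 1))
        start_a, prev_a, prev_b = a_pos, a_pos, b_pos
    if start_a is not None:
        blocks.append((start_a, prev_a + 1, a2b[start_a], prev_b + 1))
    return Chain("chrA", len(a2b), "chrB", len_b, np.array(blocks))


def simulate_genome_pair(
    n_genes: int = 10,
    snp_rate: float = 0.01,
    indel_rate: float = 0.0,
    seed: int = 0,
    n_reads: int = 1000,
    read_length: int = 100,
    sim_fraction: float = 0.5,
    p_alt_transcript: float = 0.3,
    p_species_exon: float = 0.2,
) -> ReadSimulation:
    """Build a genome pair plus reads labelled with their true origin.

    Genes carry 1-3 exons; a fraction get a second transcript missing one
    exon (so that exon is not constitutive) and a fraction get an extra exon
    annotated in only one species (to exercise the conserved-exon filter).
    Reads are drawn from annotated exons of the origin genome, entirely
    within one exon (no splicing).
    """
    if not (0 <= snp_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq_parts: list[str] = []
    annot_rows = []  # gene, transcript, start, end, species_only (None/'a'/'b')
    pos = 0
    for gi in range(n_genes):
        gene = f"g{gi:03d}"
        spacer = int(rng.integers(150, 251))
        seq_parts.append("".join(bases[b] for b in rng.integers(0, 4, spacer)))
        pos += spacer
        n_ex = int(rng.integers(1, 4))
        exons = []
        for ei in range(n_ex):
            if ei > 0:
                intron = int(rng.integers(60, 121))
                seq_parts.append("".join(bases[b] for b in rng.integers(0, 4, intron)))
                pos += intron
            elen = int(rng.integers(max(150, read_length + 20), 301))
            seq_parts.append("".join(bases[b] for b in rng.integers(0, 4, elen)))
            exons.append((pos, pos + elen))
            pos += elen
        species_only = None
        if rng.random() < p_species_exon:
            # an extra exon annotated in only one species' annotation
            intron = int(rng.integers(60, 121))
            seq_parts.append("".join(bases[b] for b in rng.integers(0, 4, intron)))
            pos += intron
            elen = int(rng.integers(max(150, read_length + 20), 301))
            seq_parts.append("".join(bases[b] for b in rng.integers(0, 4, elen)))
            species_only = ("a" if rng.random() < 0.5 else "b", (pos, pos + elen))
            pos += elen
        transcripts = {f"{gene}.t1": list(exons)}
        if n_ex >= 2 and rng.random() < p_alt_transcript:
            drop = int(rng.integers(0, n_ex))
            transcripts[f"{gene}.t2"] = [e for j, e in enumerate(exons) if j != drop]
        for tx, exs in transcripts.items():
            for s, e in exs:
                annot_rows.append((gene, tx, s, e, None))
            if species_only is not None:
                s, e = species_only[1]
                annot_rows.append((gene, tx, s, e, species_only[0]))
    seq_a = "".join(seq_parts)
    seq_b, a2b, variants = _mutate(seq_a, snp_rate, indel_rate, rng)
    chain = _chain_from_map(a2b, len(seq_b))

    annot = pd.DataFrame(annot_rows, columns=["gene_id", "transcript_id", "start", "end", "only"])
    annot_a = annot[(annot["only"].isna()) | (annot["only"] == "a")].copy()
    annot_b_src = annot[(annot["only"].isna()) | (annot["only"] == "b")].copy()
    # map B's exon boundaries through the alignment: first/last aligned base
    b_rows = []
    for row in annot_b_src.itertuples():
        mapped = a2b[row.start:row.end]
        mapped = mapped[mapped >= 0]
        if len(mapped) < 2:
            continue  # exon effectively deleted in B
        b_rows.append((row.gene_id, row.transcript_id, int(mapped.min()), int(mapped.max()) + 1))
    annot_a = annot_a[["gene_id", "transcript_id", "start", "end"]].reset_index(drop=True)
    annot_a["seqid"] = "chrA"
    annot_b = pd.DataFrame(b_rows, columns=["gene_id", "transcript_id", "start", "end"])
    annot_b["seqid"] = "chrB"

    pair = GenomePair(seq_a, seq_b, annot_a, annot_b, chain, variants)
    conserved = derive_conserved_constitutive_exons(annot_a, annot_b, chain)
    usable = any(seg[1] - seg[0] >= read_length
                 for segs in conserved.segments.values() for seg in segs)
    if not usable:
        raise ValueError(
            "mutation rates so high that no conserved exon of at least one "
            "read length survives")

    # reads drawn from annotated exons of the origin genome
    reads, truth_rows = [], []
    for ri in range(n_reads):
        origin = "sim" if rng.random() < sim_fraction else "sec"
        annot_o, seq_o = (annot_a, seq_a) if origin == "sim" else (annot_b, seq_b)
        exon_pool = annot_o.drop_duplicates(["gene_id", "start", "end"])
        exon_pool = exon_pool[exon_pool["end"] - exon_pool["start"] >= read_length]
        lens = (exon_pool["end"] - exon_pool["start"]).to_numpy(float)
        ex = exon_pool.iloc[int(rng.choice(len(exon_pool), p=lens / lens.sum()))]
        start = int(rng.integers(ex["start"], ex["end"] - read_length + 1))
        seq = seq_o[start:start + read_length]
        read_id = f"r{ri:06d}"
        reads.append((read_id, seq))
        truth_rows.append((read_id, origin, ex["gene_id"], start))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "origin", "gene_id", "start"])
    return ReadSimulation(pair, reads, truth)


# ---------------------------------------------------------------------------
# Amplicon allele counts (beta-binomial) and qPCR Ct tables
# ---------------------------------------------------------------------------

def _beta_binomial(p, rho, depth, rng):
    if rho < 0:
        raise ValueError("overdispersion must be >= 0")
    if rho == 0:
        return int(rng.binomial(depth, p))
    theta = (1.0 - rho) / rho
    q = rng.beta(p * theta, (1.0 - p) * theta)
    return int(rng.binomial(depth, q))


def simulate_amplicon(
    genes: list[str],
    logit_control: dict[str, float] | float,
    logit_wasp: dict[str, float] | float,
    overdispersion: float = 0.01,
    n_samples: int = 10,
    depth: int = 2000,
    seed: int = 0,
    n_gdna: int = 4,
    gdna_overdispersion: float = 0.0,
) -> pd.DataFrame:
    """Amplicon allele-count table: cDNA rows per treatment plus gDNA rows.

    The sim-allele count at a gene's diagnostic SNP is beta-binomial with
    mean ``expit(logit)`` and overdispersion ``rho`` (rho=0 is binomial).
    gDNA templates are drawn at logit 0 (the 50:50 two-chromosome ratio).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if overdispersion < 0 or gdna_overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    rng = np.random.default_rng(seed)

    def _logit(spec, gene):
        return spec[gene] if isinstance(spec, dict) else float(spec)

    rows = []
    for gene in genes:
        for treatment, spec in (("control", logit_control), ("wasp", logit_wasp)):
            p = expit(_logit(spec, gene))
            for s in range(1, n_samples + 1):
                k = _beta_binomial(p, overdispersion, depth, rng)
                rows.append((gene, f"cDNA_{treatment}_{s}", "cDNA", treatment, k, depth - k))
        for s in range(1, n_gdna + 1):
            k = _beta_binomial(0.5, gdna_overdispersion, depth, rng)
            rows.append((gene, f"gDNA_{s}", "gDNA", "control", k, depth - k))
    return pd.DataFrame(
        rows, columns=["gene", "sample_id", "template", "treatment", "count_sim", "count_sec"]
    )


def simulate_qpcr(
    expression: pd.DataFrame,
    noise_sd: float = 0.2,
    n_replicates: int = 10,
    seed: int = 0,
    ct_ref: float = 20.0,
    n_technical: int = 2,
) -> pd.DataFrame:
    """qPCR Ct table from a truth table of log2 relative expression.

    ``expression`` needs columns gene, genotype, treatment, log2_expr.  The
    encoding is dCt = ct_ref - ct_gene = log2_expr, so doubling expression
    raises dCt by one.  Gaussian noise of sd ``noise_sd`` is added to each
    technical replicate's target Ct.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    required = {"gene", "genotype", "treatment", "log2_expr"}
    if not required <= set(expression.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for row in expression.itertuples():
        for rep in range(1, n_replicates + 1):
            sid = f"{row.genotype}_{row.treatment}_{rep}"
            for tech in range(1, n_technical + 1):
                ct_gene = ct_ref - row.log2_expr + rng.normal(0.0, noise_sd)
                rows.append((sid, row.genotype, row.treatment, row.gene, rep, tech,
                             ct_gene, ct_ref))
    return pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "treatment", "gene", "replicate", "tech_rep",
        "ct_gene", "ct_ref",
    ])
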