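"""Targeted allele-resolved statistics for a small gene panel.

Complements the genome-wide RNA-seq contrasts with two higher-replication
assays on a hand-picked panel (13 genes in the motivating design):

* amplicon sequencing of F1 hybrid cDNA — reads carry diagnostic SNPs that
  assign them to a parental allele; per gene the log odds (logit) that a
  transcript derives from the *D. simulans* allele is estimated under control
  and immune-challenged conditions with an overdispersed (beta-binomial)
  logistic model.  Hybrid genomic DNA, which must sit at 50:50, controls for
  PCR bias;
* qPCR of parents and hybrids — expression on the dCt = Ct_ref - Ct_gene
  scale is split into per-allele values using the amplicon proportions
  (parental dCt is divided by two, one chromosome per allele), and a full
  factorial linear model of allele x species x treatment estimates the trans
  contribution per condition (the species:allele coefficient) and its change
  with treatment (the three-way interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import expit
from scipy.stats import betabinom
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.numdiff import approx_hess3

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# SNP-level allele counting
# ---------------------------------------------------------------------------

def count_snp_alleles(
    reads: pd.DataFrame,
    snps: pd.DataFrame,
    consistency_tol: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count parental alleles at each gene's first (most 5') SNP.

    ``reads`` columns: sample_id, template, treatment, gene, start (0-based
    offset of the read on the amplicon), seq.  ``snps`` columns: gene,
    position, sim_base, sec_base.  Only the first SNP from the 5' end is
    used for counting; for genes with several SNPs a consistency report
    compares per-SNP pooled allele proportions (flagged when they differ by
    more than ``consistency_tol``).  Reads not covering the first SNP are
    excluded and tallied.

    Returns ``(table, report)`` where ``table`` has one row per
    sample x gene with count_sim / count_sec at the first SNP plus an
    ``excluded`` tally, and ``report`` has one row per gene x SNP.
    """
    counts: dict[tuple, list[int]] = {}
    per_snp: dict[tuple, list[int]] = {}
    first_snp = snps.groupby("gene")["position"].min()
    snps_idx = snps.set_index(["gene", "position"]).sort_index()
    for row in reads.itertuples():
        gene_snps = snps_idx.loc[row.gene]
        rstart, rend = int(row.start), int(row.start) + len(row.seq)
        for pos, srow in gene_snps.iterrows():
            if not (rstart <= pos < rend):
                continue
            base = row.seq[pos - rstart].upper()
            hit = 0 if base == srow["sim_base"].upper() else (
                1 if base == srow["sec_base"].upper() else None)
            if hit is None:
                continue
            k = (row.gene, pos)
            per_snp.setdefault(k, [0, 0])[hit] += 1
        key = (row.sample_id, row.template, row.treatment, row.gene)
        rec = counts.setdefault(key, [0, 0, 0])
        fpos = int(first_snp[row.gene])
        if rstart <= fpos < rend:
            base = row.seq[fpos - rstart].upper()
            srow = gene_snps.loc[fpos]
            if base == srow["sim_base"].upper():
                rec[0] += 1
            elif base == srow["sec_base"].upper():
                rec[1] += 1
            else:
                rec[2] += 1
        else:
            rec[2] += 1
    table = pd.DataFrame(
        [(s, tm, tr, g, c[0], c[1], c[2]) for (s, tm, tr, g), c in counts.items()],
        columns=["sample_id", "template", "treatment", "gene",
                 "count_sim", "count_sec", "excluded"],
    )
    rep_rows = []
    for gene, gdf in snps.groupby("gene"):
        props = {}
        for pos in gdf["position"]:
            sim, sec = per_snp.get((gene, pos), [0, 0])
            props[pos] = sim / (sim + sec) if sim + sec else np.nan
        valid = [v for v in props.values() if not np.isnan(v)]
        spread = max(valid) - min(valid) if len(valid) > 1 else 0.0
        for pos, p in props.items():
            rep_rows.append((gene, pos, p, spread, spread <= consistency_tol))
    report = pd.DataFrame(
        rep_rows, columns=["gene", "position", "prop_sim", "spread", "consistent"])
    return table, report


# ---------------------------------------------------------------------------
# Overdispersed logistic allele model
# ---------------------------------------------------------------------------

@dataclass
class AseEstimate:
    """Per-gene allele-specific expression estimate from amplicon counts."""

    gene: str
    logit_control: float
    ci_control: tuple[float, float]
    logit_wasp: float
    ci_wasp: tuple[float, float]
    p_interaction: float
    p_interaction_adj: float
    overdispersion: float
    flagged: bool  # degenerate counts; CI unbounded


def _betabin_nll(params, k, n, t):
    b0, b1, r = params
    p = expit(b0 + b1 * t)
    rho = expit(r)
    theta = np.clip((1.0 - rho) / rho, 1e-6, 1e7)
    a = np.clip(p * theta, 1e-10, None)
    b = np.clip((1.0 - p) * theta, 1e-10, None)
    return -np.sum(betabinom.logpmf(k, n, a, b))


def fit_allele_model(table: pd.DataFrame, gene: str, n_tests: int = 1) -> AseEstimate:
    """Overdispersed logistic model of the sim-allele fraction for one gene.

    The binomial logit has a treatment fixed effect; overdispersion enters as
    a beta-binomial dispersion parameter, the likelihood analogue of an
    observation-level random intercept.  ``logit_control`` and ``logit_wasp``
    come from the model coefficients with delta-method 95% CIs;
    ``p_interaction`` is the Wald test of the allele x treatment interaction
    (the treatment coefficient), Bonferroni-adjusted over ``n_tests`` panel
    genes.
    """
    sub = table[(table["gene"] == gene) & (table["template"] == "cDNA")]
    if sub.empty:
        raise ValueError(f"no cDNA rows for gene {gene!r}")
    for tr in ("control", "wasp"):
        if (sub["treatment"] == tr).sum() < 2:
            raise ValueError(f"need >= 2 samples per treatment (missing {tr!r})")
    k = sub["count_sim"].to_numpy(dtype=float)
    n = (sub["count_sim"] + sub["count_sec"]).to_numpy(dtype=float)
    t = (sub["treatment"] == "wasp").to_numpy(dtype=float)
    flagged = bool((k == 0).all() or (k == n).all())

    phat = np.clip(k.sum() / n.sum(), 1e-4, 1 - 1e-4)
    x0 = np.array([np.log(phat / (1 - phat)), 0.0, -4.6])
    res = optimize.minimize(
        _betabin_nll, x0, args=(k, n, t), method="L-BFGS-B",
        bounds=[(-15, 15), (-15, 15), (-12, 4)],
    )
    b0, b1, r = res.x
    hess = approx_hess3(res.x, _betabin_nll, args=(k, n, t))
    try:
        cov = np.linalg.pinv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
    if not np.all(np.diag(cov)[:2] > 0):
        # curvature matrix not PD (flat overdispersion direction): fall back
        # to the observed information of the fixed effects alone
        cov = np.full((3, 3), 0.0)
        cov[:2, :2] = np.linalg.pinv(hess[:2, :2])
    var0 = max(cov[0, 0], 0.0)
    var_w = max(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1], 0.0)
    var1 = max(cov[1, 1], 0.0)
    se0, se_w, se1 = np.sqrt(var0), np.sqrt(var_w), np.sqrt(var1)
    if flagged:
        se0 = se_w = np.inf
    # small-sample critical value: the Wald normal quantile undercovers at
    # the panel's typical replication (~10 samples), a t on n - 2 df does not
    tcrit = sps.t.ppf(0.975, max(len(k) - 2, 1))
    p_int = 2.0 * sps.norm.sf(abs(b1) / se1) if se1 > 0 else np.nan
    return AseEstimate(
        gene=gene,
        logit_control=float(b0),
        ci_control=(float(b0 - tcrit * se0), float(b0 + tcrit * se0)),
        logit_wasp=float(b0 + b1),
        ci_wasp=(float(b0 + b1 - tcrit * se_w), float(b0 + b1 + tcrit * se_w)),
        p_interaction=float(p_int),
        p_interaction_adj=float(min(1.0, p_int * n_tests)) if np.isfinite(p_int) else np.nan,
        overdispersion=float(expit(r)),
        flagged=flagged,
    )


def fit_allele_models(table: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Fit every panel gene; Bonferroni family size = number of genes."""
    if genes is None:
        genes = sorted(table.loc[table["template"] == "cDNA", "gene"].unique())
    ests = [fit_allele_model(table, g, n_tests=len(genes)) for g in genes]
    return pd.DataFrame([{
        "gene": e.gene,
        "logit_control": e.logit_control,
        "ci_control_lo": e.ci_control[0], "ci_control_hi": e.ci_control[1],
        "logit_wasp": e.logit_wasp,
        "ci_wasp_lo": e.ci_wasp[0], "ci_wasp_hi": e.ci_wasp[1],
        "p_interaction": e.p_interaction, "p_interaction_adj": e.p_interaction_adj,
        "overdispersion": e.overdispersion, "flagged": e.flagged,
    } for e in ests])


def gdna_bias_check(table: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """Per-gene PCR-bias control on hybrid gDNA: the exact binomial CI of the
    sim-allele proportion must cover 0.5 (two chromosomes, one per allele)."""
    rows = []
    for gene, gdf in table[table["template"] == "gDNA"].groupby("gene"):
        sim = int(gdf["count_sim"].sum())
        total = sim + int(gdf["count_sec"].sum())
        if total == 0:
            rows.append((gene, np.nan, np.nan, np.nan, False, True))
            continue
        lo, hi = proportion_confint(sim, total, alpha=1 - conf, method="beta")
        rows.append((gene, sim / total, lo, hi, bool(lo <= 0.5 <= hi), False))
    return pd.DataFrame(
        rows, columns=["gene", "prop_sim", "ci_lo", "ci_hi", "unbiased", "untestable"])


# ---------------------------------------------------------------------------
# qPCR allele decomposition and trans model
# ---------------------------------------------------------------------------

def decompose_qpcr(
    qpcr: pd.DataFrame,
    proportions: pd.DataFrame,
    linear_scale: bool = False,
) -> pd.DataFrame:
    """Split qPCR dCt values into per-allele expression levels.

    Technical replicates are averaged per biological sample first.  For
    hybrids the dCt is multiplied by the gene x treatment sim-allele
    proportion (and 1 - proportion for the sec allele); parental dCt is
    divided by two and labelled with that parent's own allele.  With
    ``linear_scale`` the split is instead done on the linear scale
    (2**dCt x proportion, re-logged) — the default keeps the literal
    multiply-the-dCt rule.

    ``proportions`` columns: gene, treatment, prop_sim.
    """
    if qpcr["ct_ref"].isna().any():
        raise ValueError("missing reference-gene Ct")
    df = qpcr.copy()
    df["dct"] = df["ct_ref"] - df["ct_gene"]
    agg = (df.groupby(["sample_id", "genotype", "treatment", "gene"], sort=False)["dct"]
           .mean().reset_index())
    props = proportions.set_index(["gene", "treatment"])["prop_sim"]
    rows = []
    for row in agg.itertuples():
        if row.genotype == "hybrid":
            key = (row.gene, row.treatment)
            if key not in props.index:
                raise ValueError(f"missing allele proportion for {key}")
            p = float(props[key])
            if linear_scale:
                vals = {"sim": np.log2(2.0 ** row.dct * p),
                        "sec": np.log2(2.0 ** row.dct * (1 - p))}
            else:
                vals = {"sim": row.dct * p, "sec": row.dct * (1 - p)}
            for allele, v in vals.items():
                rows.append((row.gene, row.sample_id, "hybrids", allele, row.treatment, v))
        else:
            allele = "sim" if row.genotype == "sim_parent" else "sec"
            v = row.dct - 1.0 if linear_scale else row.dct / 2.0
            rows.append((row.gene, row.sample_id, "parents", allele, row.treatment, v))
    return pd.DataFrame(rows, columns=["gene", "sample_id", "species", "allele",
                                       "treatment", "expr"])


@dataclass
class TransEstimate:
    """Trans-regulatory divergence of one gene from the qPCR factorial."""

    gene: str
    trans_control: float
    ci_control: tuple[float, float]
    trans_wasp: float
    ci_wasp: tuple[float, float]
    p_lrt: float
    p_threeway: float
    threeway: float


def fit_trans_model(allele_table: pd.DataFrame, gene: str) -> TransEstimate:
    """Full factorial linear model of per-allele expression for one gene.

    Design: allele (sim=1) x species (parents=1) x treatment (wasp=1) with
    all interactions (7 terms + intercept).  The trans divergence per
    condition is the species:allele coefficient with the intercept anchored
    at that condition; ``trans_wasp = trans_control + threeway`` exactly.
    ``p_lrt`` compares the full model against the nested model without any
    species terms (allele, treatment, allele:treatment), a 4-df likelihood
    ratio test of whether parental allele differences deviate from hybrid
    ones at all.
    """
    import statsmodels.api as sm

    sub = allele_table[allele_table["gene"] == gene]
    a = (sub["allele"] == "sim").to_numpy(dtype=float)
    s = (sub["species"] == "parents").to_numpy(dtype=float)
    t = (sub["treatment"] == "wasp").to_numpy(dtype=float)
    cells = set(zip(a, s, t))
    if len(cells) < 8:
        raise ValueError("all eight allele x species x treatment cells must be populated")
    y = sub["expr"].to_numpy(dtype=float)
    X_full = np.column_stack([np.ones_like(a), a, s, t, a * s, a * t, s * t, a * s * t])
    X_nested = np.column_stack([np.ones_like(a), a, t, a * t])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design")
    full = sm.OLS(y, X_full).fit()
    nested = sm.OLS(y, X_nested).fit()
    lr, p_lrt, _ = full.compare_lr_test(nested)

    cov = full.cov_params()
    b = full.params
    trans_control = b[4]                 # species:allele at treatment = control
    trans_wasp = b[4] + b[7]             # re-anchored at treatment = wasp
    se_c = np.sqrt(cov[4, 4])
    se_w = np.sqrt(cov[4, 4] + cov[7, 7] + 2 * cov[4, 7])
    return TransEstimate(
        gene=gene,
        trans_control=float(trans_control),
        ci_control=(float(trans_control - Z95 * se_c), float(trans_control + Z95 * se_c)),
        trans_wasp=float(trans_wasp),
        ci_wasp=(float(trans_wasp - Z95 * se_w), float(trans_wasp + Z95 * se_w)),
        p_lrt=float(p_lrt),
        p_threeway=float(full.pvalues[7]),
        threeway=float(b[7]),
    )


def fit_trans_models(allele_table: pd.DataFrame) -> pd.DataFrame:
    genes = sorted(allele_table["gene"].unique())
    ests = [fit_trans_model(allele_table, g) for g in genes]
    return pd.DataFrame([{
        "gene": e.gene,
        "trans_control": e.trans_control,
        "ci_control_lo": e.ci_control[0], "ci_control_hi": e.ci_control[1],
        "trans_wasp": e.trans_wasp,
        "ci_wasp_lo": e.ci_wasp[0], "ci_wasp_hi": e.ci_wasp[1],
        "p_lrt": e.p_lrt, "p_threeway": e.p_threeway, "threeway": e.threeway,
    } for e in ests])
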