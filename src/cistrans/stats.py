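"""Per-gene negative-binomial GLM contrasts for cis/trans decomposition.

The estimands, per gene and per context (control, challenged, and the
response to challenge, i.e. their difference):

* parental divergence ``P`` — log2 fold change of the *D. simulans* parent
  over the *D. sechellia* parent (cis + trans combined);
* cis divergence ``C`` — log2 fold change of the sim allele over the sec
  allele within F1 hybrids, where both alleles share one trans environment;
* trans divergence ``T = P - C`` — the remainder attributable to diffusible
  factors.

Counts are modelled as NB with gene-wise dispersion phi (var = mu + phi*mu^2)
in a one-group-per-condition means model with log(effective library size)
offsets; the two allele columns of a hybrid library share the physical
library's size as offset, so allele proportions rather than depths drive the
cis estimates.  Dispersions maximise the Cox-Reid adjusted profile likelihood
on a grid and are shrunk toward an abundance trend.  Each contrast is tested
with a quasi-likelihood F-test: the deviance difference between the full fit
and a fit constrained to the contrast's null, scaled by an empirical-Bayes
moderated quasi-likelihood dispersion.  FDR control is Benjamini-Hochberg per
contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .containers import AlleleCountMatrix

LN2 = np.log(2.0)

CONTEXTS = ("control", "challenged", "response")
COMPONENTS = ("parental", "cis", "trans")


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def tmm_norm_factors(
    counts: pd.DataFrame | np.ndarray,
    library_sizes: np.ndarray,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (product normalised to 1).

    M values (log2 relative expression vs a reference sample) are doubly
    trimmed — ``logratio_trim`` from each tail of M and ``abundance_trim``
    from each tail of A — and averaged with inverse asymptotic-variance
    weights.  The reference sample is the one whose upper-quartile CPM is
    closest to the mean upper quartile.
    """
    y = np.asarray(counts, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need at least two samples")
    if (y.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample")
    cpm = y / libs * 1e6
    uq = np.array([np.quantile(cpm[:, j][cpm[:, j] > 0], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(y.shape[1])
    yr, Nr = y[:, ref], libs[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, Nj = y[:, j], libs[j]
        keep = (yj > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        pj, pr = yj[keep] / Nj, yr[keep] / Nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (Nj - yj[keep]) / (Nj * yj[keep]) + (Nr - yr[keep]) / (Nr * yr[keep])
        lo_m, hi_m = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(A, [abundance_trim, 1 - abundance_trim])
        sel = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if sel.sum() == 0 or np.isclose(M[sel], M[sel][0]).all():
            tmm = M[sel].mean() if sel.sum() else 0.0
        else:
            tmm = np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel])
        factors[j] = 2.0 ** tmm
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB likelihood primitives (vectorised over genes)
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, phi):
    """Sum over samples of the NB log-pmf; phi is (G, 1)."""
    r = 1.0 / phi
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))).sum(axis=1)


def _nb_unit_deviance(y, mu, phi):
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    term2 = (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
    return 2.0 * (term1 - term2)


def _nb_deviance(y, mu, phi):
    return _nb_unit_deviance(y, mu, phi).sum(axis=1)


def _fit_means(y, group_idx, offset, phi, n_groups, tol=1e-10, max_iter=60):
    """MLE of per-group log means in the one-hot design, per gene.

    Each group's coefficient solves a 1-D score equation, so Newton steps
    decouple by group and vectorise across genes.  Returns beta (G, K).
    """
    G = y.shape[0]
    beta = np.full((G, n_groups), -30.0)
    phi_c = phi[:, None]
    for k in range(n_groups):
        m = group_idx == k
        yk = y[:, m]
        ok = offset[m][None, :]
        eo = np.exp(offset[m]).sum()
        b = np.log((yk.sum(axis=1) + 0.1) / eo)
        for _ in range(max_iter):
            mu = np.exp(np.clip(b[:, None] + ok, -40, 40))
            denom = 1.0 + phi_c * mu
            f = ((yk - mu) / denom).sum(axis=1)
            fp = -(mu * (1.0 + phi_c * yk) / denom**2).sum(axis=1)
            step = np.clip(f / np.where(fp == 0, -1e-12, fp), -3.0, 3.0)
            b_new = np.clip(b - step, -30.0, 30.0)
            if np.max(np.abs(b_new - b)) < tol:
                b = b_new
                break
            b = b_new
        beta[:, k] = b
    return beta


def _mu_from_beta(beta, group_idx, offset):
    return np.exp(np.clip(beta[:, group_idx] + offset[None, :], -40, 40))


def _adjusted_profile_loglik(y, group_idx, offset, phi, n_groups):
    """Cox-Reid adjusted profile log-likelihood at dispersion phi (per gene).

    With the one-hot design the observed information is diagonal by group, so
    the CR adjustment is half the sum of log group-wise working-weight sums.
    """
    beta = _fit_means(y, group_idx, offset, phi, n_groups)
    mu = _mu_from_beta(beta, group_idx, offset)
    phi_c = phi[:, None]
    ll = _nb_loglik(y, mu, phi_c)
    w = mu / (1.0 + phi_c * mu)
    cr = 0.0
    for k in range(n_groups):
        cr = cr + np.log(w[:, group_idx == k].sum(axis=1) + 1e-300)
    return ll - 0.5 * cr


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Per-gene dispersions with their raw, trended and common components."""

    dispersion: np.ndarray  # shrunken, used for fitting
    raw: np.ndarray
    trend: np.ndarray
    common: float
    prior_df: float
    mean_log_cpm: np.ndarray


def _grid_argmax(grid_log, scores):
    """Per-row argmax of score curves with 3-point parabolic refinement."""
    j = np.argmax(scores, axis=1)
    x = grid_log[j].copy()
    interior = (j > 0) & (j < len(grid_log) - 1)
    ji = j[interior]
    rows = np.flatnonzero(interior)
    y0 = scores[rows, ji - 1]
    y1 = scores[rows, ji]
    y2 = scores[rows, ji + 1]
    denom = y0 - 2 * y1 + y2
    ok = denom < -1e-12
    shift = np.zeros(len(rows))
    shift[ok] = 0.5 * (y0 - y2)[ok] / denom[ok]
    step = grid_log[1] - grid_log[0]
    x[interior] = grid_log[ji] + np.clip(shift, -1, 1) * step
    return x


def estimate_dispersion(
    counts: np.ndarray,
    group_idx: np.ndarray,
    offset: np.ndarray,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
    n_bins: int = 20,
) -> DispersionModel:
    """Cox-Reid dispersion estimates shrunk toward an abundance trend.

    The CR adjusted profile likelihood is evaluated on a log-spaced grid; the
    raw estimate maximises a gene's own curve, the trend maximises the summed
    curve of genes in the same abundance bin, and the shrunken estimate
    maximises the weighted combination ``APL_g + (prior_df / df_res) *
    mean-bin APL`` (then clipped between raw and trend so shrinkage never
    overshoots).
    """
    y = np.asarray(counts, dtype=float)
    G, n = y.shape
    n_groups = int(group_idx.max()) + 1
    df_res = n - n_groups
    if df_res < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    if grid is None:
        grid = np.logspace(-4, np.log10(16), 25)
    grid_log = np.log(grid)
    apl = np.empty((G, len(grid)))
    for p, phi in enumerate(grid):
        apl[:, p] = _adjusted_profile_loglik(y, group_idx, offset, np.full(G, phi), n_groups)

    raw = np.exp(_grid_argmax(grid_log, apl))
    common = float(np.exp(_grid_argmax(grid_log, apl.sum(axis=0)[None, :])[0]))

    mean_log_cpm = np.log2(y.mean(axis=1) / np.exp(offset).mean() * 1e6 + 0.25)
    n_bins = max(1, min(n_bins, G // 20))
    if n_bins < 2:
        trend = np.full(G, common)
        bin_mean_apl = np.broadcast_to(apl.mean(axis=0), apl.shape)
    else:
        qs = np.quantile(mean_log_cpm, np.linspace(0, 1, n_bins + 1))
        bin_of = np.clip(np.searchsorted(qs[1:-1], mean_log_cpm, side="right"), 0, n_bins - 1)
        centers, bin_phi = [], []
        bin_mean_apl = np.empty_like(apl)
        for b in range(n_bins):
            m = bin_of == b
            if m.sum() == 0:
                continue
            centers.append(mean_log_cpm[m].mean())
            bin_phi.append(np.exp(_grid_argmax(grid_log, apl[m].sum(axis=0)[None, :])[0]))
            bin_mean_apl[m] = apl[m].mean(axis=0)
        order = np.argsort(centers)
        trend = np.exp(np.interp(mean_log_cpm,
                                 np.array(centers)[order], np.log(np.array(bin_phi))[order]))
    weight = prior_df / df_res
    score = apl + weight * bin_mean_apl
    shrunk = np.exp(_grid_argmax(grid_log, score))
    lo = np.minimum(raw, trend)
    hi = np.maximum(raw, trend)
    shrunk = np.clip(shrunk, lo, hi)
    return DispersionModel(shrunk, raw, trend, common, prior_df, mean_log_cpm)


# ---------------------------------------------------------------------------
# Full and constrained fits; quasi-likelihood F-test
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """A fitted one-hot NB GLM bundle for a gene x sample matrix."""

    y: np.ndarray
    group_idx: np.ndarray
    group_keys: list
    offset: np.ndarray
    phi: np.ndarray
    beta: np.ndarray          # natural-log group means (G, K)
    beta_report: np.ndarray   # beta with 0.5 pseudo-count for all-zero groups
    deviance: np.ndarray
    df_residual: int
    s2_post: np.ndarray
    prior_df_ql: float

    @property
    def n_groups(self) -> int:
        return len(self.group_keys)


def fit_glm(
    counts: np.ndarray,
    group_idx: np.ndarray,
    group_keys: list,
    offset: np.ndarray,
    phi: np.ndarray,
    prior_df_ql: float = 10.0,
) -> GLMFit:
    """Fit the means model and moderate the quasi-likelihood scales.

    The per-gene QL scale ``s2 = deviance / df_res`` is squeezed toward the
    common scale with ``prior_df_ql`` prior degrees of freedom.
    """
    y = np.asarray(counts, dtype=float)
    n_groups = len(group_keys)
    df_res = y.shape[1] - n_groups
    if df_res < 1:
        raise ValueError("zero residual degrees of freedom")
    beta = _fit_means(y, group_idx, offset, phi, n_groups)
    mu = _mu_from_beta(beta, group_idx, offset)
    dev = _nb_deviance(y, mu, phi[:, None])
    s2 = dev / df_res
    s2_common = float(np.mean(s2)) if len(s2) else 1.0
    s2_post = (prior_df_ql * s2_common + df_res * s2) / (prior_df_ql + df_res)
    s2_post = np.maximum(s2_post, 1e-8)
    # pseudo-count of 0.5 for all-zero groups, LFC reporting only
    beta_report = beta.copy()
    for k in range(n_groups):
        m = group_idx == k
        zero = y[:, m].sum(axis=1) == 0
        if zero.any():
            beta_report[zero, k] = np.log(0.5 / np.exp(offset[m]).sum())
    return GLMFit(y, group_idx, group_keys, offset, phi, beta, beta_report,
                  dev, df_res, s2_post, prior_df_ql)


def _fit_constrained(fit: GLMFit, contrast: np.ndarray, max_iter=40, tol=1e-9):
    """Refit under the null c'beta = 0 (null-space IRLS, batched over genes);
    returns the constrained deviance."""
    c = np.asarray(contrast, dtype=float)
    Z = linalg.null_space(c[None, :])          # (K, K-1), orthonormal
    U = Z[fit.group_idx]                       # (n, J)
    y = fit.y
    phi_c = fit.phi[:, None]
    gamma = fit.beta @ Z                       # projection of the full fit
    eye = np.eye(Z.shape[1]) * 1e-9
    eta_prev = None
    for _ in range(max_iter):
        eta = np.clip(gamma @ U.T + fit.offset[None, :], -40, 40)
        mu = np.exp(eta)
        w = mu / (1.0 + phi_c * mu)
        z = (eta - fit.offset[None, :]) + (y - mu) / mu
        A = np.einsum("gn,nj,nk->gjk", w, U, U) + eye
        b = np.einsum("gn,nj->gj", w * z, U)
        gamma = np.linalg.solve(A, b[..., None])[..., 0]
        if eta_prev is not None and np.max(np.abs(eta - eta_prev)) < tol:
            break
        eta_prev = eta
    mu = np.exp(np.clip(gamma @ U.T + fit.offset[None, :], -40, 40))
    return _nb_deviance(y, mu, phi_c)


def ql_f_test(fit: GLMFit, contrast: np.ndarray):
    """Quasi-likelihood F-test of c'beta = 0 for every gene.

    F = (constrained deviance - full deviance) / s2_post on (1, df_res +
    prior_df) degrees of freedom.  Returns (lfc, F, p) arrays; lfc is the
    contrast on the log2 scale (reported with the zero-group pseudo-count).
    """
    c = np.asarray(contrast, dtype=float)
    dev0 = _fit_constrained(fit, c)
    delta = np.maximum(dev0 - fit.deviance, 0.0)
    F = delta / fit.s2_post
    p = sps.f.sf(F, 1, fit.df_residual + fit.prior_df_ql)
    lfc = (fit.beta_report @ c) / LN2
    return lfc, F, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The cis/trans contrast battery
# ---------------------------------------------------------------------------

REQUIRED_GROUPS = [
    ("sim_parent", "total"), ("sec_parent", "total"), ("hybrid", "sim"), ("hybrid", "sec"),
]


def _build_groups(meta: pd.DataFrame):
    keys = []
    for condition in ("control", "challenged"):
        for genotype, allele in REQUIRED_GROUPS:
            keys.append((genotype, allele, condition))
    key_of = {k: i for i, k in enumerate(keys)}
    tuples = list(zip(meta["genotype"], meta["allele"], meta["condition"]))
    missing = set(keys) - set(tuples)
    if missing:
        raise ValueError(f"design is missing groups: {sorted(missing)}")
    idx = np.array([key_of[t] for t in tuples])
    return idx, keys, key_of


def _contrast(key_of, plus, minus):
    c = np.zeros(len(key_of))
    for k in plus:
        c[key_of[k]] += 1.0
    for k in minus:
        c[key_of[k]] -= 1.0
    return c


def library_offsets(matrix: AlleleCountMatrix, normalize: bool = True) -> np.ndarray:
    """Per-sample log effective-library-size offsets.

    TMM factors are computed on the *physical* libraries (hybrid allele pairs
    summed), and each library's factor is shared by both of its allele
    columns.  A shared offset cancels from the within-library cis contrast,
    so allele proportions rather than per-column scaling drive cis estimates;
    per-allele-column TMM would instead be badly biased whenever many genes
    carry strong cis effects (the factor would absorb part of the signal).
    """
    meta = matrix.meta
    libs = meta["library_size"].to_numpy(dtype=float)
    if not normalize:
        return np.log(libs)
    total = hybrid_total_matrix(matrix)
    lib_sizes = total.meta["library_size"].to_numpy(dtype=float)
    factors = tmm_norm_factors(total.counts.to_numpy(dtype=float), lib_sizes)
    factor_of = dict(zip(total.meta["library_id"], factors))
    return np.log(libs * meta["library_id"].map(factor_of).to_numpy(dtype=float))


def prepare_fit(
    matrix: AlleleCountMatrix,
    dispersion: DispersionModel | None = None,
    prior_df_disp: float = 10.0,
    prior_df_ql: float = 10.0,
    normalize: bool = True,
) -> tuple[GLMFit, DispersionModel, dict]:
    """Normalise, estimate dispersions if needed, and fit the 8-group model."""
    group_idx, keys, key_of = _build_groups(matrix.meta)
    y = matrix.counts.to_numpy(dtype=float)
    offset = library_offsets(matrix, normalize)
    if dispersion is None:
        dispersion = estimate_dispersion(y, group_idx, offset, prior_df=prior_df_disp)
    fit = fit_glm(y, group_idx, keys, offset, dispersion.dispersion, prior_df_ql=prior_df_ql)
    return fit, dispersion, key_of


def fit_contrasts(
    matrix: AlleleCountMatrix,
    dispersion: DispersionModel | None = None,
    prior_df_disp: float = 10.0,
    prior_df_ql: float = 10.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Parental, cis and trans divergence per gene in all three contexts.

    Returns one row per gene x context with log2 fold changes, QL F-test
    p-values and BH FDRs; lfc_trans is exactly lfc_parental - lfc_cis.
    """
    fit, _, key_of = prepare_fit(matrix, dispersion, prior_df_disp, prior_df_ql, normalize)

    def P(cond):  # parental: simP - secP
        return _contrast(key_of, [("sim_parent", "total", cond)], [("sec_parent", "total", cond)])

    def C(cond):  # cis: hybrid sim allele - sec allele
        return _contrast(key_of, [("hybrid", "sim", cond)], [("hybrid", "sec", cond)])

    contrast_of = {}
    for cond in ("control", "challenged"):
        contrast_of[("parental", cond)] = P(cond)
        contrast_of[("cis", cond)] = C(cond)
        contrast_of[("trans", cond)] = P(cond) - C(cond)
    contrast_of[("parental", "response")] = P("challenged") - P("control")
    contrast_of[("cis", "response")] = C("challenged") - C("control")
    contrast_of[("trans", "response")] = (
        contrast_of[("parental", "response")] - contrast_of[("cis", "response")]
    )

    genes = matrix.genes
    frames = []
    for context in CONTEXTS:
        cols = {"gene_id": genes, "context": context}
        lfcs = {}
        for comp in COMPONENTS:
            lfc, _, p = ql_f_test(fit, contrast_of[(comp, context)])
            lfcs[comp] = lfc
            cols[f"p_{comp}"] = p
            cols[f"fdr_{comp}"] = bh_fdr(p)
        cols["lfc_parental"] = lfcs["parental"]
        cols["lfc_cis"] = lfcs["cis"]
        cols["lfc_trans"] = lfcs["parental"] - lfcs["cis"]  # definitional identity
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    order = ["gene_id", "context", "lfc_parental", "lfc_cis", "lfc_trans",
             "p_parental", "p_cis", "p_trans", "fdr_parental", "fdr_cis", "fdr_trans"]
    return out[order]


# ---------------------------------------------------------------------------
# Hybrid-vs-parent contrasts (total expression) for dominance calls
# ---------------------------------------------------------------------------

def hybrid_total_matrix(matrix: AlleleCountMatrix) -> AlleleCountMatrix:
    """Collapse hybrid allele columns to per-library totals; parents pass through."""
    meta = matrix.meta
    keep = meta["genotype"] != "hybrid"
    counts = matrix.counts.loc[:, meta.loc[keep, "sample_id"]].copy()
    new_meta = meta.loc[keep].copy()
    hyb = meta[meta["genotype"] == "hybrid"]
    rows = []
    for lib, sub in hyb.groupby("library_id", sort=False):
        total = matrix.counts[sub["sample_id"]].sum(axis=1)
        counts[lib] = total
        first = sub.iloc[0]
        rows.append({
            "sample_id": lib, "genotype": "hybrid", "allele": "total",
            "condition": first["condition"], "tissue": first["tissue"],
            "replicate": first["replicate"], "library_id": lib,
            "library_size": first["library_size"],
        })
    new_meta = pd.concat([new_meta, pd.DataFrame(rows)], ignore_index=True)
    return AlleleCountMatrix(counts[new_meta["sample_id"]], new_meta)


def fit_parent_hybrid_contrasts(
    matrix: AlleleCountMatrix,
    prior_df_disp: float = 10.0,
    prior_df_ql: float = 10.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Hybrid total expression vs each parent, per context.

    Returns one row per gene x context with lfc/p/fdr of hybrid-vs-sim-parent
    and hybrid-vs-sec-parent, the inputs of the dominance classification.
    """
    total = hybrid_total_matrix(matrix)
    meta = total.meta
    keys = [(g, c) for c in ("control", "challenged")
            for g in ("sim_parent", "sec_parent", "hybrid")]
    key_of = {k: i for i, k in enumerate(keys)}
    tuples = list(zip(meta["genotype"], meta["condition"]))
    missing = set(keys) - set(tuples)
    if missing:
        raise ValueError(f"design is missing groups: {sorted(missing)}")
    group_idx = np.array([key_of[t] for t in tuples])
    y = total.counts.to_numpy(dtype=float)
    libs = meta["library_size"].to_numpy(dtype=float)
    factors = tmm_norm_factors(y, libs) if normalize else np.ones(len(libs))
    offset = np.log(libs * factors)
    disp = estimate_dispersion(y, group_idx, offset, prior_df=prior_df_disp)
    fit = fit_glm(y, group_idx, keys, offset, disp.dispersion, prior_df_ql=prior_df_ql)

    def one(parent, cond):
        c = np.zeros(len(keys))
        c[key_of[("hybrid", cond)]] = 1.0
        c[key_of[(parent, cond)]] = -1.0
        return c

    contrast_of = {}
    for cond in ("control", "challenged"):
        contrast_of[("sim", cond)] = one("sim_parent", cond)
        contrast_of[("sec", cond)] = one("sec_parent", cond)
    for parent in ("sim", "sec"):
        contrast_of[(parent, "response")] = (
            contrast_of[(parent, "challenged")] - contrast_of[(parent, "control")]
        )
    frames = []
    for context in CONTEXTS:
        cols = {"gene_id": total.genes, "context": context}
        for parent in ("sim", "sec"):
            lfc, _, p = ql_f_test(fit, contrast_of[(parent, context)])
            cols[f"lfc_vs_{parent}"] = lfc
            cols[f"p_vs_{parent}"] = p
            cols[f"fdr_vs_{parent}"] = bh_fdr(p)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def fit_response_screen(
    matrix: AlleleCountMatrix,
    prior_df_disp: float = 10.0,
    prior_df_ql: float = 10.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Challenged-vs-control contrast within each genotype (total expression).

    Used to delimit the immune-responsive gene set: genes significant in at
    least one genotype.
    """
    total = hybrid_total_matrix(matrix)
    meta = total.meta
    keys = [(g, c) for g in ("sim_parent", "sec_parent", "hybrid")
            for c in ("control", "challenged")]
    key_of = {k: i for i, k in enumerate(keys)}
    group_idx = np.array([key_of[t] for t in zip(meta["genotype"], meta["condition"])])
    y = total.counts.to_numpy(dtype=float)
    libs = meta["library_size"].to_numpy(dtype=float)
    factors = tmm_norm_factors(y, libs) if normalize else np.ones(len(libs))
    offset = np.log(libs * factors)
    disp = estimate_dispersion(y, group_idx, offset, prior_df=prior_df_disp)
    fit = fit_glm(y, group_idx, keys, offset, disp.dispersion, prior_df_ql=prior_df_ql)
    frames = []
    for genotype in ("sim_parent", "sec_parent", "hybrid"):
        c = np.zeros(len(keys))
        c[key_of[(genotype, "challenged")]] = 1.0
        c[key_of[(genotype, "control")]] = -1.0
        lfc, _, p = ql_f_test(fit, c)
        frames.append(pd.DataFrame({
            "gene_id": total.genes, "genotype": genotype,
            "lfc_response": lfc, "p_response": p, "fdr_response": bh_fdr(p),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Correlation of total divergence with its components
# ---------------------------------------------------------------------------

def divergence_correlation(
    estimates: pd.DataFrame, component: str, context: str
) -> tuple[float, float, float]:
    """Pearson correlation of lfc_parental with lfc_cis or lfc_trans across
    genes, with a Fisher-z 95% CI.  Returns (r, lo, hi)."""
    if component not in ("cis", "trans"):
        raise ValueError("component must be 'cis' or 'trans'")
    sub = estimates[estimates["context"] == context]
    x = sub["lfc_parental"].to_numpy()
    yv = sub[f"lfc_{component}"].to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    if np.std(x) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in fold changes")
    r = float(sps.pearsonr(x, yv).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    se = 1.0 / np.sqrt(len(x) - 3)
    return r, float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se))
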