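"""Regulatory-mode and dominance classification, and motif association tests.

Genes are binned into the standard categories of interspecific regulatory
divergence from the significance and direction of their parental, cis and
trans contrasts: cis, trans, cis+trans (reinforcing), cis x trans
(antagonistic), compensatory (cis and trans cancel, parents equal),
conserved, or ambiguous.  Many ambiguous genes are borderline cases where
parental divergence crossed the significance threshold but neither component
did; when the cis or trans point estimate explains at least half the parental
divergence the gene is rescued to that component.

Dominance compares hybrid total expression with each parent: a hybrid
"differs" from a parent only when the contrast is both significant and at
least ``min_lfc`` (default 1.25) log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

REGULATORY_CATEGORIES = (
    "cis", "trans", "cis_plus_trans", "cis_by_trans", "compensatory", "conserved", "ambiguous",
)
DOMINANCE_CATEGORIES = (
    "underdominant", "overdominant", "additive", "dominant_sim", "dominant_sec", "conserved",
)


def classify_regulatory(estimates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign each row (gene x context) a regulatory-divergence category.

    Rules, applied on FDR significance at level ``alpha``:

    * cis — significant ASE in hybrids, no significant trans divergence;
    * trans — significant trans divergence, no significant ASE;
    * cis_plus_trans / cis_by_trans — ASE, parental and trans all
      significant, with cis and trans in the same / opposite direction;
    * compensatory — ASE and trans significant but parents not diverged;
    * conserved — nothing significant;
    * ambiguous — the rest.  An ambiguous gene whose |lfc_cis| or |lfc_trans|
      is at least half of |lfc_parental| is rescued to that component
      (recorded in ``ambiguous_rescue``; ``effective_category`` folds the
      rescue in, for tallies of cis-/trans-diverged genes).
    """
    for col in ("fdr_parental", "fdr_cis", "fdr_trans"):
        if col not in estimates.columns or estimates[col].isna().any():
            raise ValueError(f"missing FDR values in column {col}")
    sig_p = estimates["fdr_parental"].to_numpy() < alpha
    sig_c = estimates["fdr_cis"].to_numpy() < alpha
    sig_t = estimates["fdr_trans"].to_numpy() < alpha
    lfc_p = estimates["lfc_parental"].to_numpy()
    lfc_c = estimates["lfc_cis"].to_numpy()
    lfc_t = estimates["lfc_trans"].to_numpy()

    category = np.full(len(estimates), "ambiguous", dtype=object)
    category[sig_c & ~sig_t] = "cis"
    category[sig_t & ~sig_c] = "trans"
    both = sig_c & sig_t
    category[both & sig_p & (lfc_c * lfc_t > 0)] = "cis_plus_trans"
    category[both & sig_p & (lfc_c * lfc_t <= 0)] = "cis_by_trans"
    category[both & ~sig_p] = "compensatory"
    category[~sig_c & ~sig_t & ~sig_p] = "conserved"

    rescue = np.full(len(estimates), "none", dtype=object)
    amb = category == "ambiguous"
    half = 0.5 * np.abs(lfc_p)
    cis_ok = amb & (np.abs(lfc_c) >= half)
    trans_ok = amb & (np.abs(lfc_t) >= half)
    # both components explain half: the larger magnitude wins, ties go to cis
    rescue[cis_ok] = "cis"
    rescue[trans_ok & ~cis_ok] = "trans"
    rescue[cis_ok & trans_ok & (np.abs(lfc_t) > np.abs(lfc_c))] = "trans"

    effective = category.copy()
    effective[rescue != "none"] = rescue[rescue != "none"]

    out = estimates[["gene_id"]].copy()
    if "context" in estimates.columns:
        out["context"] = estimates["context"].to_numpy()
    out["category"] = category
    out["ambiguous_rescue"] = rescue
    out["effective_category"] = effective
    return out


def classify_dominance(
    contrasts: pd.DataFrame, alpha: float = 0.05, min_lfc: float = 1.25
) -> pd.DataFrame:
    """Dominance of hybrid expression relative to the parents.

    ``contrasts`` holds per gene (x context) the hybrid-vs-parent log2 fold
    changes and FDRs (columns lfc_vs_sim, fdr_vs_sim, lfc_vs_sec,
    fdr_vs_sec).  The hybrid differs from a parent iff FDR < alpha and
    |lfc| >= min_lfc.  Differs from both in the same direction: over-/under-
    dominant; in opposite directions: additive (between the parents); from
    one parent only: dominance of the other parent; from neither: conserved.
    """
    lfc_s = contrasts["lfc_vs_sim"].to_numpy()
    lfc_e = contrasts["lfc_vs_sec"].to_numpy()
    diff_s = (contrasts["fdr_vs_sim"].to_numpy() < alpha) & (np.abs(lfc_s) >= min_lfc)
    diff_e = (contrasts["fdr_vs_sec"].to_numpy() < alpha) & (np.abs(lfc_e) >= min_lfc)

    category = np.full(len(contrasts), "conserved", dtype=object)
    both = diff_s & diff_e
    category[both & (lfc_s > 0) & (lfc_e > 0)] = "overdominant"
    category[both & (lfc_s < 0) & (lfc_e < 0)] = "underdominant"
    category[both & (lfc_s * lfc_e < 0)] = "additive"
    category[diff_s & ~diff_e] = "dominant_sec"   # resembles the sechellia parent
    category[~diff_s & diff_e] = "dominant_sim"   # resembles the simulans parent
    out = contrasts[["gene_id"]].copy()
    if "context" in contrasts.columns:
        out["context"] = contrasts["context"].to_numpy()
    out["category"] = category
    return out


def chi2_association(flag_a, flag_b, correction: bool = False):
    """Pearson chi-square on the 2x2 table of two boolean gene labellings.

    Returns (chi2, p, table); (nan, nan, table) with a warning flag when a
    marginal is zero (untestable).
    """
    a = np.asarray(flag_a, dtype=bool)
    b = np.asarray(flag_b, dtype=bool)
    table = np.array([
        [np.sum(a & b), np.sum(a & ~b)],
        [np.sum(~a & b), np.sum(~a & ~b)],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan, table
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue), table


def motif_association(
    motifs: pd.DataFrame,
    estimates: pd.DataFrame,
    context: str = "control",
    alpha: float = 0.05,
    correction: bool = False,
) -> pd.DataFrame:
    """Test motif presence against regulatory divergence, per motif.

    ``motifs`` has columns gene_id, motif, present_sim, present_sec (0/1).
    Two tests per motif: (a) motif present in *both* species vs
    trans-divergence (fdr_trans < alpha); (b) motif present in exactly one
    species vs cis-divergence (fdr_cis < alpha).  Chi-square without
    continuity correction by default.
    """
    est = estimates[estimates["context"] == context].set_index("gene_id") \
        if "context" in estimates.columns else estimates.set_index("gene_id")
    rows = []
    for motif, mdf in motifs.groupby("motif"):
        mdf = mdf.set_index("gene_id")
        genes = mdf.index.intersection(est.index)
        mdf = mdf.loc[genes]
        sub = est.loc[genes]
        both = (mdf["present_sim"] == 1) & (mdf["present_sec"] == 1)
        one = (mdf["present_sim"].astype(int) + mdf["present_sec"].astype(int)) == 1
        trans_div = sub["fdr_trans"] < alpha
        cis_div = sub["fdr_cis"] < alpha
        chi_t, p_t, _ = chi2_association(both, trans_div, correction)
        chi_c, p_c, _ = chi2_association(one, cis_div, correction)
        rows.append((motif, chi_t, p_t, chi_c, p_c,
                     bool(np.isnan(p_t)), bool(np.isnan(p_c))))
    return pd.DataFrame(rows, columns=[
        "motif", "chi2_trans", "p_trans", "chi2_cis", "p_cis",
        "untestable_trans", "untestable_cis",
    ])


def category_counts(classified: pd.DataFrame, column: str = "category") -> pd.DataFrame:
    """Tally genes per category (and context, when present)."""
    keys = ["context", column] if "context" in classified.columns else [column]
    return classified.groupby(keys, sort=False).size().rename("n_genes").reset_index()
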