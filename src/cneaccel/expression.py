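"""Sex-biased expression calling and the cross-species transition analysis.

The differential-expression caller is a deliberately simple, self-contained
negative-binomial procedure: median-of-ratios size factors, a per-gene
method-of-moments dispersion with a floor, and an exact-style conditional test
on group total pseudo-counts (the sum of the group's normalised counts, which
under the null is negative-binomial with the pooled mean and scaled
dispersion).  Externally computed DE labels can be supplied instead to bypass
it entirely.  Downstream, genes are classed XX-biased / XO-biased / Non at
FDR < 0.01, and one-to-one orthologs between two species populate a 3x3
transition table whose cells are tested for enrichment of elements'
nearest-neighbor genes by Fisher's exact test with BH correction across the
nine cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact, nbinom
from statsmodels.stats.multitest import multipletests

from .stats import fisher_exact_2x3, odds_ratio_2x2

__all__ = [
    "normalize_counts",
    "de_test",
    "classify_sex_bias",
    "neighbor_bias_proportions",
    "transition_association",
    "TransitionTable",
    "CLASSES",
]

logger = logging.getLogger(__name__)

CLASSES = ("XX-biased", "XO-biased", "Non")
DISPERSION_FLOOR = 0.01
DISPERSION_CAP = 10.0
DISPERSION_PRIOR_DF = 20.0  # shrinkage weight toward the across-gene median


def normalize_counts(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference over genes
    nonzero in every sample); upper-quartile fallback when no such gene exists."""
    mat = counts.to_numpy(dtype=float)
    if np.any(mat.sum(axis=0) == 0):
        raise ValueError("no all-zero sample allowed")
    allpos = np.all(mat > 0, axis=1)
    if allpos.any():
        logref = np.log(mat[allpos]).mean(axis=1)
        factors = np.exp(np.median(np.log(mat[allpos]) - logref[:, None], axis=0))
    else:
        logger.warning("no gene nonzero in all samples; upper-quartile factors")
        uq = np.array([np.percentile(col[col > 0], 75) for col in mat.T])
        factors = uq / np.exp(np.mean(np.log(uq)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _exact_nb_pvalue(sa: int, sb: int, na: int, nb_: int, mu0: float, alpha: float) -> float:
    """Conditional two-sided exact-style NB test on group totals.

    Group totals of ``k`` replicates with per-replicate mean ``mu0`` and
    dispersion ``alpha`` are NB(k*mu0, alpha/k); conditioning on sa+sb, the
    p-value sums the probabilities of splits no more probable than observed.
    """
    t = sa + sb
    if t == 0:
        return 1.0
    if t > 200000:  # likelihood-ratio chi-square fallback for huge totals
        return _lr_pvalue(sa, sb, na, nb_, mu0, alpha)

    def nb_params(k):
        size = k / alpha if alpha > 0 else np.inf
        mean = k * mu0
        return size, size / (size + mean)

    ra, pa = nb_params(na)
    rb, pb = nb_params(nb_)
    a = np.arange(t + 1)
    logp = nbinom.logpmf(a, ra, pa) + nbinom.logpmf(t - a, rb, pb)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return float(min(1.0, prob[prob <= prob[sa] * (1 + 1e-12)].sum()))


def _lr_pvalue(sa, sb, na, nb_, mu0, alpha) -> float:
    def ll(s, k, mu):
        size = k / alpha
        p = size / (size + k * mu)
        return nbinom.logpmf(s, size, p)

    l0 = ll(sa, na, mu0) + ll(sb, nb_, mu0)
    l1 = ll(sa, na, sa / na) + ll(sb, nb_, sb / nb_)
    return float(chi2.sf(max(0.0, 2 * (l1 - l0)), df=1))


def de_test(
    counts: pd.DataFrame,
    group_a,
    group_b,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Per-gene differential expression between two replicate groups.

    Returns a frame indexed like ``counts`` with ``log2fc`` (B over A), ``p``
    and BH ``q``; genes with zero counts everywhere get p = 1 and are flagged.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    sub = counts[group_a + group_b]
    factors = normalize_counts(sub)
    norm = sub / factors
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    na, nb_ = a.shape[1], b.shape[1]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    mu0 = (a.sum(axis=1) + b.sum(axis=1)) / (na + nb_)
    # pooled within-group method-of-moments dispersion, moderated toward the
    # across-gene median: with few replicates the raw per-gene estimate is too
    # noisy to keep the exact test calibrated
    ss = ((a - mu_a[:, None]) ** 2).sum(axis=1) + ((b - mu_b[:, None]) ** 2).sum(axis=1)
    df = na + nb_ - 2
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu0) / mu0**2
    raw = np.clip(np.nan_to_num(raw, nan=0.0), 0.0, DISPERSION_CAP)
    expressed = raw[mu0 > 0]
    if len(expressed):
        # 10-90% trimmed mean: the median of a few-df chi-square estimate is
        # biased low, a plain mean is outlier-sensitive
        q10, q90 = np.quantile(expressed, [0.1, 0.9])
        mid = expressed[(expressed >= q10) & (expressed <= q90)]
        common = float(mid.mean()) if len(mid) else float(expressed.mean())
    else:
        common = dispersion_floor
    w = df / (df + DISPERSION_PRIOR_DF)
    disp = np.clip(w * raw + (1 - w) * common, dispersion_floor, DISPERSION_CAP)
    sa = np.rint(a.sum(axis=1)).astype(np.int64)
    sb = np.rint(b.sum(axis=1)).astype(np.int64)
    allzero = mu0 == 0
    pvals = np.ones(len(sub))
    for i in range(len(sub)):
        if allzero[i]:
            continue
        pvals[i] = _exact_nb_pvalue(int(sa[i]), int(sb[i]), na, nb_, float(mu0[i]), float(disp[i]))
    out = pd.DataFrame(index=sub.index)
    out["mean_a"] = mu_a
    out["mean_b"] = mu_b
    out["log2fc"] = np.log2((mu_b + 0.5) / (mu_a + 0.5))
    out["dispersion"] = disp
    out["p"] = pvals
    out["q"] = multipletests(pvals, method="fdr_bh")[1]
    out["all_zero"] = allzero
    return out


def classify_sex_bias(
    de_results: pd.DataFrame,
    q_threshold: float = 0.01,
    a_label: str = "XX-biased",
    b_label: str = "XO-biased",
) -> pd.Series:
    """Per-gene bias class at FDR < ``q_threshold``.

    Group A is the XX side of the contrast and group B the XO side, so a
    positive ``log2fc`` (higher in B) gives the XO-biased label.
    """
    cls = np.where(
        (de_results["q"] < q_threshold) & (de_results["log2fc"] > 0),
        b_label,
        np.where(
            (de_results["q"] < q_threshold) & (de_results["log2fc"] < 0),
            a_label,
            "Non",
        ),
    )
    return pd.Series(cls, index=de_results.index, name="bias_class")


def neighbor_bias_proportions(
    calls: dict,
    neighbor_genes: set,
    max_exact_total: int = 2000,
) -> pd.DataFrame:
    """Per-comparison 2x3 association of neighbor status with bias class.

    ``calls`` maps comparison name -> per-gene class Series.  Rows report the
    class proportions among neighbor genes and among all other genes, with an
    exact (or chi-square at scale) independence p, BH-corrected across
    comparisons.
    """
    rows = []
    for comparison, series in calls.items():
        genes = set(series.index)
        neigh = genes & neighbor_genes
        if not neigh:
            logger.warning("no neighbor gene present for %s; skipped", comparison)
            continue
        other = genes - neigh
        table = np.array(
            [
                [sum(series[g] == c for g in neigh) for c in CLASSES],
                [sum(series[g] == c for g in other) for c in CLASSES],
            ]
        )
        p = fisher_exact_2x3(table, max_exact_total=max_exact_total)
        row = dict(comparison=comparison, p=p)
        for j, c in enumerate(CLASSES):
            row[f"neighbor_{c}"] = int(table[0, j])
            row[f"other_{c}"] = int(table[1, j])
            row[f"neighbor_prop_{c}"] = table[0, j] / table[0].sum()
            row[f"other_prop_{c}"] = table[1, j] / max(1, table[1].sum())
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


@dataclass
class TransitionTable:
    """3x3 cross-species transition structure with per-cell neighbor tests."""

    cells: pd.DataFrame          # class_a, class_b, n, n_neighbor, odds_ratio, p, q
    n_orthologs: int
    n_neighbors: int
    n_excluded: int
    discordance_p: float         # one-sided: neighbors enriched among class changers
    discordance_table: np.ndarray


def transition_association(
    calls_a: pd.Series,
    calls_b: pd.Series,
    orthologs,
    neighbor_genes: set,
    alternative: str = "two-sided",
) -> TransitionTable:
    """Place one-to-one orthologs in the 3x3 class-pair grid and test each cell.

    ``orthologs`` is an iterable of (gene_a, gene_b) pairs; ``neighbor_genes``
    holds species-A gene ids neighboring accelerated elements.  Each cell gets
    a 2x2 Fisher test (in-cell vs not x neighbor vs not); odds ratios use the
    Haldane-Anscombe correction on zero margins while p-values come from the
    uncorrected exact test.  A one-sided discordance test (class differs
    between species vs neighbor status) is also computed.
    """
    pairs = []
    excluded = 0
    for ga, gb in orthologs:
        if ga in calls_a.index and gb in calls_b.index:
            pairs.append((ga, calls_a[ga], calls_b[gb]))
        else:
            excluded += 1
    if excluded:
        logger.info("excluded %d orthologs lacking a call in one species", excluded)
    n = len(pairs)
    is_neigh = np.array([ga in neighbor_genes for ga, _, _ in pairs])
    n_neigh = int(is_neigh.sum())
    rows = []
    for ca in CLASSES:
        for cb in CLASSES:
            in_cell = np.array([(a == ca and b == cb) for _, a, b in pairs])
            k = int(in_cell.sum())
            kn = int((in_cell & is_neigh).sum())
            table = np.array(
                [[kn, k - kn], [n_neigh - kn, (n - k) - (n_neigh - kn)]]
            )
            if k == 0 or k == n or n_neigh == 0:
                p = 1.0
            else:
                # orient as neighbor vs not x in-cell vs not for the test
                t = np.array([[kn, n_neigh - kn], [k - kn, (n - k) - (n_neigh - kn)]])
                p = float(fisher_exact(t, alternative=alternative)[1])
            rows.append(
                dict(
                    class_a=ca,
                    class_b=cb,
                    n=k,
                    n_neighbor=kn,
                    odds_ratio=odds_ratio_2x2(table),
                    p=p,
                )
            )
    cells = pd.DataFrame(rows)
    cells["q"] = multipletests(cells["p"], method="fdr_bh")[1]
    discordant = np.array([a != b for _, a, b in pairs])
    dt = np.array(
        [
            [int((discordant & is_neigh).sum()), int((discordant & ~is_neigh).sum())],
            [int((~discordant & is_neigh).sum()), int((~discordant & ~is_neigh).sum())],
        ]
    )
    if n and n_neigh and 0 < discordant.sum() < n:
        disc_p = float(fisher_exact(dt, alternative="greater")[1])
    else:
        disc_p = 1.0
    return TransitionTable(
        cells=cells,
        n_orthologs=n,
        n_neighbors=n_neigh,
        n_excluded=excluded,
        discordance_p=disc_p,
        discordance_table=dt,
    )
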