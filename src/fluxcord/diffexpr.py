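"""Negative-binomial differential expression for two-accession counts.

Implements the DESeq-style workflow for a transcript x sample integer
count matrix with two accession groups (default three biological
replicates each): median-of-ratios size factors, per-transcript
method-of-moments dispersions shrunk toward a mean-dispersion trend, a
conditioned exact negative-binomial test on condition-summed counts,
Benjamini-Hochberg adjustment, T/S/N significance calls, a closed-form
variance-stabilizing transformation, and the 2^-ΔΔCt qPCR utility.

Counts follow NB(μ, α) with Var = μ + α μ²; α is the overdispersion.
The direction convention is fixed throughout: positive log2 fold change
(call "T") means higher expression in the high-lipid accession A.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Transcript x sample non-negative integer counts with accessions.

    ``accessions`` maps each sample id (column) to its accession label;
    exactly two levels are expected for testing.
    """

    counts: pd.DataFrame
    accessions: dict[str, str]

    def __post_init__(self):
        self.counts.index.name = "transcript_id"
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ValueError("counts must be integers")
        missing = set(self.counts.columns) - set(self.accessions)
        if missing:
            raise ValueError(f"samples without accession label: {sorted(missing)}")

    def samples_of(self, accession: str) -> list[str]:
        return [s for s in self.counts.columns if self.accessions[s] == accession]

    @property
    def levels(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            if self.accessions[s] not in seen:
                seen.append(self.accessions[s])
        return seen

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#accession\t"
                + "\t".join(self.accessions[s] for s in self.counts.columns)
                + "\n"
            )
            self.counts.to_csv(fh, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        acc_line = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#accession\t"):
                    acc_line = line.rstrip("\n").split("\t")[1:]
                elif not line.startswith("#"):
                    break
        df = pd.read_csv(path, sep="\t", index_col="transcript_id", comment="#")
        if acc_line is None:
            raise ValueError(f"{path}: missing '#accession' header line")
        return cls(counts=df, accessions=dict(zip(df.columns, acc_line)))


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    s_j = median over transcripts i (with all-positive counts) of
    k_ij / geometric_mean_i, the DESeq estimator.
    """
    arr = counts.values.astype(float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no transcript has positive counts in every sample; "
            "cannot form the geometric-mean reference "
            "(consider a pseudo-reference fallback)"
        )
    logs = np.log(arr[allpos])
    ref = logs.mean(axis=1, keepdims=True)  # log geometric mean per row
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return counts / sf


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    accessions: dict[str, str],
) -> pd.DataFrame:
    """Per-transcript NB dispersion α with trend shrinkage.

    Method of moments on normalized counts, pooled within accessions:
    with base mean q and pooled within-group variance w, the raw
    estimate is α = max(0, (w − q·mean(1/s)) / q²) — the shot-noise term
    accounts for division by the size factors.  The working dispersion
    is the maximum of the per-transcript estimate and a log-log
    least-squares mean-dispersion trend (maximum sharing, the classic
    DESeq default; deliberately conservative for few replicates),
    floored at 1e-8.

    Returns a frame with columns alpha_mom, alpha_trend, alpha.
    """
    sf = sf.reindex(counts.columns)
    z = counts.values / sf.values
    groups = [
        [j for j, s in enumerate(counts.columns) if accessions[s] == lev]
        for lev in dict.fromkeys(accessions[s] for s in counts.columns)
    ]
    q = z.mean(axis=1)
    num = np.zeros(len(counts))
    dof = 0
    for idx in groups:
        if len(idx) < 2:
            continue
        num += z[:, idx].var(axis=1, ddof=1) * (len(idx) - 1)
        dof += len(idx) - 1
    if dof == 0:
        raise ValueError("need >=2 replicates in at least one accession")
    w = num / dof
    xi = float(np.mean(1.0 / sf.values))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(q > 0, (w - xi * q) / np.maximum(q, 1e-300) ** 2, 0.0)
    alpha_mom = np.maximum(alpha_mom, 0.0)

    fit_mask = (q > 0) & (alpha_mom > 0)
    if fit_mask.sum() >= 10:
        b1, b0 = np.polyfit(np.log(q[fit_mask]), np.log(alpha_mom[fit_mask]), 1)
        with np.errstate(over="ignore"):
            alpha_trend = np.where(
                q > 0, np.exp(b0 + b1 * np.log(np.maximum(q, 1e-300))), 0.0
            )
        alpha_trend = np.clip(alpha_trend, 0.0, 1e3)
    else:  # too few informative transcripts for a trend
        alpha_trend = np.full(len(q), max(np.median(alpha_mom), DISPERSION_FLOOR))

    alpha = np.maximum(np.maximum(alpha_mom, alpha_trend), DISPERSION_FLOOR)
    return pd.DataFrame(
        {"alpha_mom": alpha_mom, "alpha_trend": alpha_trend, "alpha": alpha},
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# exact test


def _nb_logpmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    if alpha <= DISPERSION_FLOOR:
        return stats.poisson.logpmf(k, mu)
    r = 1.0 / alpha
    return stats.nbinom.logpmf(k, r, r / (r + mu))


def nb_exact_test(
    k_a: int,
    k_b: int,
    mu_a: float,
    mu_b: float,
    alpha_a: float,
    alpha_b: float,
) -> float:
    """Two-sided conditioned exact NB test on condition-summed counts.

    With A ~ NB(mu_a, alpha_a) and B ~ NB(mu_b, alpha_b) independent,
    conditions on the total k_a + k_b and sums the joint probabilities
    of all splits (a, b) no more likely than the observed one:

        p = Σ_{a+b=K, P(a,b) <= P(k_a,k_b)} P(a,b) / Σ_{a+b=K} P(a,b)

    For large totals the summation window is restricted to splits whose
    probability exceeds 1e-16 of the maximum (with renormalization by
    construction, since both numerator and denominator use the window).
    """
    if k_a < 0 or k_b < 0 or k_a != int(k_a) or k_b != int(k_b):
        raise ValueError("counts must be non-negative integers")
    k_a, k_b = int(k_a), int(k_b)
    total = k_a + k_b
    if total == 0:
        return 1.0

    if total > 20000:
        # window around the conditional mode, wide enough that omitted
        # terms are < 1e-16 of the max (normal-approximation 10 sd)
        frac = mu_a / (mu_a + mu_b)
        center = total * frac
        sd_a = np.sqrt(mu_a + alpha_a * mu_a**2)
        sd_b = np.sqrt(mu_b + alpha_b * mu_b**2)
        half = 10.0 * np.sqrt(sd_a**2 + sd_b**2)
        lo = max(0, int(min(center, k_a) - half))
        hi = min(total, int(max(center, k_a) + half))
        a = np.arange(lo, hi + 1)
    else:
        a = np.arange(0, total + 1)

    logp = _nb_logpmf(a, mu_a, alpha_a) + _nb_logpmf(total - a, mu_b, alpha_b)
    m = logp.max()
    probs = np.exp(logp - m)
    obs_idx = np.searchsorted(a, k_a)
    if obs_idx >= len(a) or a[obs_idx] != k_a:  # observed outside window => tiny p
        return float(min(1.0, 2.0 * np.exp(-m) / probs.sum()))
    obs = probs[obs_idx]
    p = probs[probs <= obs * (1 + 1e-12)].sum() / probs.sum()
    return float(min(1.0, max(p, 1e-300)))


def adjust_bh(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# calls, VST, ddct


def call_transcripts(
    de: pd.DataFrame,
    padj_threshold: float = 0.01,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Attach T/S/N calls: significant and >fold-threshold change.

    T = higher in the high-lipid accession A, S = higher in B.
    """
    de = de.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        up = de["mean_A"].values > fold_threshold * de["mean_B"].values
        dn = de["mean_B"].values > fold_threshold * de["mean_A"].values
    sig = de["padj"].values < padj_threshold
    call = np.where(sig & up, "T", np.where(sig & dn, "S", "N"))
    de["call"] = call
    return de


def vst(mu: float | np.ndarray, alpha: float) -> float | np.ndarray:
    """Closed-form NB variance-stabilizing transformation.

    g(μ) = (2/√α) ln(√(αμ) + √(1+αμ)); strictly increasing, g(0)=0,
    with derivative 1/√(μ + αμ²).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mu = np.asarray(mu, dtype=float)
    if (mu < 0).any():
        raise ValueError("mu must be non-negative")
    out = (2.0 / np.sqrt(alpha)) * np.log(
        np.sqrt(alpha * mu) + np.sqrt(1.0 + alpha * mu)
    )
    return float(out) if out.ndim == 0 else out


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative abundance by the 2^-ΔΔCt method."""
    cts = [ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control]
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct_val = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct_val))


# ---------------------------------------------------------------------------
# driver


def run_de(
    cm: CountMatrix,
    accession_a: str | None = None,
    padj_threshold: float = 0.01,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Full differential-expression pass on a two-accession count matrix.

    ``accession_a`` names the high-lipid accession (direction anchor);
    defaults to the first accession level in column order.  Returns a
    frame indexed by transcript_id with mean_A, mean_B, log2fc, pvalue,
    padj and call.

    The test follows the condition-sum construction: each condition's
    summed count is compared against an NB fit whose mean is the pooled
    (null) base mean scaled by that condition's total size factor and
    whose variance propagates the per-sample NB variances.
    """
    levels = cm.levels
    if len(levels) != 2:
        raise ValueError(f"expected exactly two accessions, got {levels}")
    acc_a = accession_a if accession_a is not None else levels[0]
    if acc_a not in levels:
        raise ValueError(f"accession_a {acc_a!r} not in {levels}")
    acc_b = next(l for l in levels if l != acc_a)
    cols_a, cols_b = cm.samples_of(acc_a), cm.samples_of(acc_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 replicates per accession")

    sf = size_factors(cm.counts)
    disp = estimate_dispersions(cm.counts, sf, cm.accessions)
    z = normalized_counts(cm.counts, sf)

    mean_a = z[cols_a].mean(axis=1).values
    mean_b = z[cols_b].mean(axis=1).values
    q0 = z.mean(axis=1).values  # pooled base mean under the null
    sa = sf[cols_a].values
    sb = sf[cols_b].values
    SA, SA2 = sa.sum(), (sa**2).sum()
    SB, SB2 = sb.sum(), (sb**2).sum()
    alpha = disp["alpha"].values
    ka = cm.counts[cols_a].sum(axis=1).values.astype(int)
    kb = cm.counts[cols_b].sum(axis=1).values.astype(int)

    pvals = np.ones(len(z))
    for i in range(len(z)):
        if ka[i] + kb[i] == 0:
            continue
        mu_a = q0[i] * SA
        mu_b = q0[i] * SB
        # variance of the condition sum: Σ_j (q s_j + α q² s_j²)
        a_sum_a = alpha[i] * SA2 / SA**2
        a_sum_b = alpha[i] * SB2 / SB**2
        pvals[i] = nb_exact_test(ka[i], kb[i], mu_a, mu_b, a_sum_a, a_sum_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(
            (mean_a > 0) & (mean_b > 0),
            np.log2(mean_a / np.where(mean_b > 0, mean_b, 1.0)),
            np.where(
                (mean_a == 0) & (mean_b == 0),
                0.0,
                np.where(mean_a > 0, np.inf, -np.inf),
            ),
        )
    de = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": adjust_bh(pvals),
        },
        index=cm.counts.index,
    )
    return call_transcripts(de, padj_threshold, fold_threshold)
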