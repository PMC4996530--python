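"""Label-free differential protein abundance.

The stage mirrors the standard limma-style workflow for LFQ protein
group tables: filter unreliable identifications, log2-transform with
zeros treated as not-detected, equalise intensity distributions by
cyclic loess normalization, estimate per-sample quality weights,
fit a per-protein linear model (diet + system block) by weighted least
squares on the observed entries, shrink residual variances with an
empirical-Bayes prior (moderated t-statistics), and control the false
discovery rate by Benjamini-Hochberg adjustment.  Fold changes are
reported on the raw intensity scale with the signed convention
(ratio if >= 1, else minus the reciprocal).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinGroupTable",
    "DAResult",
    "read_maxquant",
    "filter_proteins",
    "log2_transform",
    "cyclic_loess_normalize",
    "sample_weights",
    "squeeze_var",
    "fit_moderated",
    "bh_adjust",
    "fold_change_raw",
]


@dataclass
class ProteinGroupTable:
    """LFQ intensities (proteins x samples; 0 encodes not-detected) with
    protein metadata and sample annotations.

    ``meta`` is indexed like ``intensities`` and carries at least
    ``unique_peptides`` plus boolean ``reverse`` / ``contaminant``
    flags; ``samples`` is indexed by sample name with ``diet``,
    ``system`` and ``tank`` columns.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy(float) < 0).any():
            raise ValueError("LFQ intensities must be non-negative")
        if not self.intensities.index.equals(self.meta.index):
            raise ValueError("intensity matrix and metadata indices differ")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")
        for col in ("diet", "system"):
            if col not in self.samples.columns:
                raise ValueError(f"sample table needs a {col!r} column")


def read_maxquant(path, samples: pd.DataFrame) -> ProteinGroupTable:
    """Read a MaxQuant ``proteinGroups.txt``-dialect tab-delimited table.

    Expects columns 'Majority protein IDs', 'Gene names', 'Unique
    peptides', 'Reverse', 'Potential contaminant' ('+' marks a flag) and
    one 'LFQ intensity <sample>' column per sample named in ``samples``.
    """
    raw = pd.read_csv(path, sep="\t")
    prefix = "LFQ intensity "
    cols = {c[len(prefix):]: c for c in raw.columns if c.startswith(prefix)}
    unknown = set(samples.index) - set(cols)
    if unknown:
        raise ValueError(f"sample map names columns absent from the table: {sorted(unknown)}")
    intens = raw[[cols[s] for s in samples.index]].fillna(0.0)
    intens.columns = list(samples.index)
    idx = pd.Index(range(len(raw)), name="protein")
    acc = raw.get("Majority protein IDs")
    if acc is not None and acc.notna().all() and acc.is_unique:
        idx = pd.Index(acc, name="protein")
    intens.index = idx
    raw.index = idx
    meta = pd.DataFrame(
        {
            "accession": raw.get("Majority protein IDs", pd.Series("", index=raw.index)),
            "gene": raw.get("Gene names", pd.Series("", index=raw.index)),
            "unique_peptides": raw.get("Unique peptides", pd.Series(0, index=raw.index)),
            "reverse": raw.get("Reverse", pd.Series("", index=raw.index)).fillna("") == "+",
            "contaminant": raw.get("Potential contaminant", pd.Series("", index=raw.index)).fillna("") == "+",
        }
    )
    return ProteinGroupTable(intens, meta, samples)


def filter_proteins(
    table: ProteinGroupTable, min_unique_peptides: int = 2, min_detected: int = 3
) -> ProteinGroupTable:
    """Keep proteins with >= 2 unique peptides, not reverse/contaminant,
    and detected (nonzero) in at least ``min_detected`` samples of at
    least one diet group."""
    diets = table.samples["diet"]
    sizes = diets.value_counts()
    if (sizes < min_detected).any():
        small = list(sizes.index[sizes < min_detected])
        raise ValueError(
            f"group(s) {small} have fewer than {min_detected} samples; the "
            "replicate rule cannot be satisfied"
        )
    ok = (
        (table.meta["unique_peptides"] >= min_unique_peptides)
        & ~table.meta["reverse"]
        & ~table.meta["contaminant"]
    )
    detected = table.intensities > 0
    by_group = pd.DataFrame(
        {d: detected.loc[:, diets.index[diets == d]].sum(axis=1) for d in sizes.index}
    )
    ok &= (by_group >= min_detected).any(axis=1)
    return ProteinGroupTable(
        table.intensities.loc[ok], table.meta.loc[ok], table.samples
    )


def log2_transform(intensities: pd.DataFrame) -> pd.DataFrame:
    """log2 of intensities with zeros mapped to missing (NaN)."""
    x = intensities.to_numpy(float)
    if (x < 0).any():
        raise ValueError("intensities must be non-negative")
    with np.errstate(divide="ignore"):
        y = np.log2(np.where(x > 0, x, np.nan))
    return pd.DataFrame(y, index=intensities.index, columns=intensities.columns)


def cyclic_loess_normalize(
    matrix: pd.DataFrame,
    span: float = 0.7,
    iterations: int = 3,
    min_observed: int = 10,
) -> pd.DataFrame:
    """Cyclic loess normalization of a log2 intensity matrix.

    For every pair of samples, a loess curve of M = x_i - x_j against
    A = (x_i + x_j)/2 is fitted on jointly observed entries and half the
    fitted offset subtracted from one sample and added to the other;
    the cycle over all pairs repeats ``iterations`` times.  Missing
    entries are untouched.  Samples with fewer than ``min_observed``
    values are excluded (with a warning) and returned unchanged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    X = matrix.to_numpy(float).copy()
    observed = np.isfinite(X).sum(axis=0)
    included = [j for j in range(X.shape[1]) if observed[j] >= min_observed]
    skipped = [matrix.columns[j] for j in range(X.shape[1]) if j not in included]
    if skipped:
        warnings.warn(
            f"samples excluded from normalization (fewer than {min_observed} "
            f"observed values): {skipped}",
            stacklevel=2,
        )
    for _ in range(iterations):
        for i, j in itertools.combinations(included, 2):
            both = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            if both.sum() < min_observed:
                continue
            a = (X[both, i] + X[both, j]) / 2.0
            m = X[both, i] - X[both, j]
            spread = float(a.max() - a.min())
            f = lowess(
                m, a, frac=span, return_sorted=False,
                delta=0.01 * spread if spread > 0 else 0.0,
            )
            X[both, i] -= f / 2.0
            X[both, j] += f / 2.0
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# linear modelling


def design_matrix(samples: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + diet treatment dummies + system block dummies.

    Returns (X, column names, diet levels).  The first diet level (in
    sorted order) is the reference.
    """
    diets = sorted(samples["diet"].unique())
    systems = sorted(samples["system"].unique())
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    for d in diets[1:]:
        cols.append((samples["diet"] == d).to_numpy(float))
        names.append(f"diet[{d}]")
    for s in systems[1:]:
        cols.append((samples["system"] == s).to_numpy(float))
        names.append(f"system[{s}]")
    return np.column_stack(cols), names, diets


def _contrast_vector(names: list[str], diets: list[str], a: str, b: str) -> np.ndarray:
    """Coefficient vector for the difference diet a - diet b."""
    c = np.zeros(len(names))
    for d, sign in ((a, 1.0), (b, -1.0)):
        if d != diets[0]:
            c[names.index(f"diet[{d}]")] = sign
    return c


def _fit_patterns(
    Y: np.ndarray, X: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[bytes, tuple]]:
    """Per-protein WLS on observed entries, grouped by missingness pattern.

    Returns (beta, s2, df_resid, pattern cache).  Proteins whose
    observed design is rank-deficient or leaves no residual df get NaN
    everywhere.  The cache maps pattern bytes to (mask, (X'WX)^-1,
    protein indices, residual matrix) for reuse when forming contrast
    standard errors and sample-level variance factors.
    """
    n_prot, n_samp = Y.shape
    p = X.shape[1]
    beta = np.full((n_prot, p), np.nan)
    s2 = np.full(n_prot, np.nan)
    dfr = np.zeros(n_prot)
    finite = np.isfinite(Y)
    cache: dict[bytes, tuple] = {}
    patterns: dict[bytes, list[int]] = {}
    for g in range(n_prot):
        patterns.setdefault(finite[g].tobytes(), []).append(g)
    for key, idx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        Xm = X[mask]
        wm = w[mask]
        if Xm.shape[0] == 0:
            continue
        Xw = Xm * wm[:, None]
        xtx = Xm.T @ Xw
        rank = np.linalg.matrix_rank(Xm)
        df = int(mask.sum()) - rank
        if rank < p or df < 0:
            continue  # rank-deficient after missingness: skip these proteins
        xtx_inv = np.linalg.pinv(xtx)
        Ym = Y[np.ix_(idx, np.flatnonzero(mask))]
        B = Ym @ Xw @ xtx_inv.T
        resid = Ym - B @ Xm.T
        rss = (resid**2 * wm[None, :]).sum(axis=1)
        beta[idx] = B
        dfr[idx] = df
        s2[idx] = rss / df if df > 0 else np.nan
        cache[key] = (mask, xtx_inv, np.asarray(idx), resid)
    return beta, s2, dfr, cache


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def squeeze_var(s2: np.ndarray, df: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of residual variances.

    Moment-matches a scaled inverse-chi-square prior to the observed
    log-variances: with e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2),
    the prior df d0 solves trigamma(d0/2) = var(e) - mean(trigamma(d_g/2))
    and s0^2 follows from the mean of e.  Returns (d0, s0^2, posterior
    variances (d0 s0^2 + d_g s_g^2)/(d0 + d_g)).
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    ok = np.isfinite(s2) & (df > 0) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    post = np.full_like(s2, np.nan)
    if math.isinf(d0):
        post[ok] = s02
    else:
        post[ok] = (d0 * s02 + df[ok] * s2[ok]) / (d0 + df[ok])
    return d0, s02, post


@dataclass
class DAResult:
    """Differential-abundance output: one table per pairwise diet
    contrast plus the empirical-Bayes hyperparameters and sample
    weights used."""

    tables: dict[str, pd.DataFrame]
    d0: float
    s02: float
    weights: pd.Series
    skipped: list[str] = field(default_factory=list)

    def significant(self, contrast: str, alpha: float = 0.1) -> pd.DataFrame:
        t = self.tables[contrast]
        return t[t["adj_p_value"] < alpha].sort_values("adj_p_value")


def sample_weights(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> pd.Series:
    """Per-sample quality weights from a gene-by-sample heteroscedastic
    model, normalized to geometric mean 1.

    Iterates between per-protein weighted least squares and per-sample
    variance-factor estimation from leverage-corrected squared
    standardized residuals; noisy samples get small weights.  Falls
    back to unit weights with a warning if the iteration does not
    converge.
    """
    X, names, _ = design_matrix(samples.loc[matrix.columns])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = matrix.to_numpy(float)
    n_samp = Y.shape[1]
    w = np.ones(n_samp)
    converged = False
    for _ in range(max_iter):
        beta, s2, dfr, cache = _fit_patterns(Y, X, w)
        ok = np.isfinite(s2) & (dfr > 0) & (s2 > 0)
        if ok.sum() < 2:
            break
        num = np.zeros(n_samp)
        den = np.zeros(n_samp)
        for key, (mask, xtx_inv, idx, resid) in cache.items():
            keep = ok[idx]
            if not keep.any():
                continue
            Xm = X[mask]
            wm = w[mask]
            h = np.einsum("ij,jk,ik->i", Xm, xtx_inv, Xm * wm[:, None])
            u = resid[keep] ** 2 / s2[idx[keep]][:, None]
            num[mask] += u.sum(axis=0)
            den[mask] += int(keep.sum()) * np.clip(1.0 - h, 1e-6, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(den > 0, num / den, 1.0)
        v = np.clip(v, 1e-8, None)
        w_new = 1.0 / v
        w_new /= np.exp(np.mean(np.log(w_new)))
        if np.max(np.abs(np.log(w_new / w))) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        warnings.warn("sample-weight estimation did not converge; using unit weights",
                      stacklevel=2)
        w = np.ones(n_samp)
    w /= np.exp(np.mean(np.log(w)))
    return pd.Series(w, index=matrix.columns, name="weight")


def fit_moderated(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    weights: pd.Series | None = None,
) -> DAResult:
    """Per-protein weighted least squares with empirical-Bayes moderated
    t-statistics for every pairwise diet contrast.

    Missing entries are dropped per protein with the residual df
    adjusted; proteins whose observed design is rank deficient are
    skipped (listed in ``DAResult.skipped``).  Moderated t uses the
    posterior variance on d0 + d_g degrees of freedom; p-values are BH
    adjusted within each contrast.
    """
    samp = samples.loc[matrix.columns]
    X, names, diets = design_matrix(samp)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    w = np.ones(X.shape[0]) if weights is None else weights.loc[matrix.columns].to_numpy(float)
    Y = matrix.to_numpy(float)
    beta, s2, dfr, cache = _fit_patterns(Y, X, w)
    fitted = np.isfinite(s2) & (dfr > 0)
    skipped = [str(matrix.index[g]) for g in np.flatnonzero(~fitted)]
    d0, s02, post = squeeze_var(s2[fitted], dfr[fitted])
    post_all = np.full_like(s2, np.nan)
    post_all[fitted] = post
    df_total = np.where(fitted, np.inf if math.isinf(d0) else dfr + d0, np.nan)

    # unscaled contrast variances per missingness pattern
    tables: dict[str, pd.DataFrame] = {}
    for a, b in itertools.combinations(diets, 2):
        cvec = _contrast_vector(names, diets, b, a)  # effect of b relative to a
        logfc = beta @ cvec
        cvar = np.full(Y.shape[0], np.nan)
        for key, (mask, xtx_inv, idx, _resid) in cache.items():
            cvar[idx] = float(cvec @ xtx_inv @ cvec)
        se = np.sqrt(post_all * cvar)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = logfc / se
        pval = np.full_like(tstat, np.nan)
        okp = np.isfinite(tstat) & np.isfinite(df_total)
        pval[okp] = 2.0 * stats.t.sf(np.abs(tstat[okp]), df_total[okp])
        adj = bh_adjust(pval)
        tables[f"{b} vs {a}"] = pd.DataFrame(
            {
                "logFC": logfc,
                "t": tstat,
                "p_value": pval,
                "adj_p_value": adj,
                "df_resid": dfr,
                "df_total": df_total,
                "s2": s2,
                "s2_post": post_all,
            },
            index=matrix.index,
        )
    wser = pd.Series(w, index=matrix.columns, name="weight")
    return DAResult(tables, d0, s02, wser, skipped)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    arr = np.asarray(p, float)
    out = np.full_like(arr, np.nan)
    ok = np.isfinite(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def fold_change_raw(
    table: ProteinGroupTable, numerator_diet: str, denominator_diet: str
) -> pd.DataFrame:
    """Signed fold changes of raw (non-normalized) LFQ group means.

    Group means average detected (nonzero) intensities.  A ratio below
    one is reported as minus its reciprocal, so |fold change| >= 1.
    Proteins detected in only one of the two groups are marked 'ND'
    (not detected) in the other; fold change is then undefined.
    """
    diets = table.samples["diet"]
    for d in (numerator_diet, denominator_diet):
        if d not in set(diets):
            raise ValueError(f"unknown diet {d!r}")
    x = table.intensities.replace(0.0, np.nan)
    mean_num = x.loc[:, diets.index[diets == numerator_diet]].mean(axis=1)
    mean_den = x.loc[:, diets.index[diets == denominator_diet]].mean(axis=1)
    fc = np.full(len(x), np.nan)
    status = np.full(len(x), "ok", dtype=object)
    for i, (mn, md) in enumerate(zip(mean_num, mean_den)):
        if np.isnan(mn) and np.isnan(md):
            status[i] = "undetected"
        elif np.isnan(md):
            status[i] = f"ND in {denominator_diet}"
        elif np.isnan(mn):
            status[i] = f"ND in {numerator_diet}"
        else:
            r = mn / md
            fc[i] = r if r >= 1.0 else -1.0 / r
    return pd.DataFrame(
        {
            "mean_" + numerator_diet: mean_num,
            "mean_" + denominator_diet: mean_den,
            "fold_change": fc,
            "status": status,
        },
        index=table.intensities.index,
    )
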