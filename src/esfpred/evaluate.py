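"""Performance metrics and statistical comparisons.

Implements the evaluation toolkit used throughout: masked mean absolute
error, rank-statistic ROC AUC with half-credit for ties, the product-moment
correlation in its textbook summation form, a paired two-tailed t-test,
per-protein error cross-correlation matrices, error-versus-observed
profiles, kink-detection AUC from predicted bend angles, and
randomized-target background fits.

Degenerate inputs (single-class labels, constant vectors, zero-variance
differences) raise :class:`DegenerateMetricError` rather than returning a
silently meaningless number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import rankdata


class DegenerateMetricError(ValueError):
    """A metric is undefined for the given input (constant/single-class)."""


def _clean_pair(x, y, mask=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    return x[keep], y[keep]


def mae(observed, predicted, mask=None) -> float:
    """Mean absolute error over unmasked, defined pairs."""
    o, p = _clean_pair(observed, predicted, mask)
    if len(o) == 0:
        raise DegenerateMetricError("all pairs masked or undefined")
    return float(np.mean(np.abs(o - p)))


def roc_auc(scores, labels) -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic; ties get half credit.

    Identical to the area under the cutoff-sweep sensitivity /
    (1 - specificity) curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    keep = np.isfinite(s) & ~pd.isna(y)
    s, y = s[keep], y[keep].astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateMetricError("both classes must be present for AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pearson(x, y) -> float:
    """Product-moment correlation, summation form.

    C = (n Sxy - Sx Sy) / sqrt(n Sxx - Sx^2) / sqrt(n Syy - Sy^2)
    """
    x, y = _clean_pair(x, y)
    n = len(x)
    if n < 2:
        raise DegenerateMetricError("need at least 2 pairs")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    denom_x = n * sxx - sx * sx
    denom_y = n * syy - sy * sy
    if denom_x <= 0 or denom_y <= 0:
        raise DegenerateMetricError("constant input vector")
    return float((n * sxy - sx * sy) / (np.sqrt(denom_x) * np.sqrt(denom_y)))


def paired_t_test(a, b) -> tuple[float, float]:
    """Paired two-tailed t-test: returns (t, p) with n-1 degrees of freedom.

    p comes from the regularized incomplete beta closed form of the Student
    t distribution. Zero variance of the differences is degenerate.
    """
    a, b = _clean_pair(a, b)
    n = len(a)
    if n < 2:
        raise DegenerateMetricError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateMetricError("zero variance of paired differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return t, p


def correlation_p_value(r: float, n: int) -> float:
    """Two-tailed p for a correlation r on n pairs (t with n-2 df)."""
    if n < 3:
        raise DegenerateMetricError("need at least 3 pairs")
    r = float(np.clip(r, -0.9999999999, 0.9999999999))
    df = n - 2
    t2 = r * r * df / (1.0 - r * r)
    return float(betainc(df / 2.0, 0.5, df / (df + t2)))


def mae_cross_correlation(per_protein_scores: pd.DataFrame) -> pd.DataFrame:
    """Feature-by-feature Pearson matrix of protein-wise performance scores.

    ``per_protein_scores`` has one row per protein and one column per
    feature score (MAE per feature; an AUC column may be included for the
    binary feature). Needs at least 3 proteins.
    """
    if len(per_protein_scores) < 3:
        raise ValueError("need per-protein scores for at least 3 proteins")
    cols = list(per_protein_scores.columns)
    n = len(cols)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson(per_protein_scores[cols[i]], per_protein_scores[cols[j]])
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=cols, columns=cols)


def error_vs_observed_profile(observed, predicted, n_bins: int = 10) -> pd.DataFrame:
    """Mean absolute error per equal-width bin of the observed values.

    Empty bins are reported with NaN. Reveals whether extreme observed
    values carry larger prediction errors.
    """
    o, p = _clean_pair(observed, predicted)
    if len(o) == 0:
        raise DegenerateMetricError("no defined pairs")
    lo, hi = o.min(), o.max()
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(o, edges[1:-1]), 0, n_bins - 1)
    ae = np.abs(o - p)
    mean_ae = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            mean_ae[b] = ae[sel].mean()
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "mean_ae": mean_ae, "n": counts,
    })


def kink_auc(predicted_kappa, kink_angles, threshold_deg: float = 30.0) -> float:
    """AUC for detecting kinked positions from predicted bend angles.

    Positions are labeled kinked when the observed kink angle is at least
    ``threshold_deg``; predicted kappa serves as the score. Pairs where
    either quantity is undefined are dropped.
    """
    score, kink = _clean_pair(predicted_kappa, kink_angles)
    labels = (kink >= threshold_deg).astype(int)
    return roc_auc(score, labels)


def randomized_background(inputs, targets, n_shuffles: int = 5, seed: int = 0,
                          epochs: int = 100, lr: float = 0.1,
                          batch_size: int = 16,
                          hidden_per_feature: int = 2) -> tuple[float, float]:
    """Fit correlation achievable on permuted targets (chance background).

    Targets are randomly redistributed among the residues, a single-output
    network is trained on them, and the correlation between its fit and the
    shuffled targets is recorded; the mean and SD over ``n_shuffles``
    repetitions are returned. A real fit is only meaningful when it clears
    this background.
    """
    from .model import build_network, train

    X = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    corrs = []
    for s in range(n_shuffles):
        y_perm = rng.permutation(y)
        net = build_network(X.shape[1], 1, hidden_per_feature,
                            seed=int(rng.integers(2 ** 31)), target_names=["flex"])
        if epochs > 0:
            net = train(net, X, y_perm[:, None], epochs=epochs, lr=lr,
                        seed=int(rng.integers(2 ** 31)), batch_size=batch_size)
        pred = net.forward(X)[:, 0]
        try:
            corrs.append(pearson(pred, y_perm))
        except DegenerateMetricError:
            corrs.append(0.0)
    return float(np.mean(corrs)), float(np.std(corrs))


def loo_report(per_protein_scores_a: pd.DataFrame,
               per_protein_scores_b: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate per-protein scores into AMAE +- SD (and paired p-values).

    Rows are features; with a second score table the two models are
    compared feature-wise by the paired two-tailed t-test.
    """
    rows = []
    for col in per_protein_scores_a.columns:
        a = per_protein_scores_a[col].to_numpy(dtype=float)
        row = {"feature": col, "amae_a": np.nanmean(a), "sd_a": np.nanstd(a, ddof=1)}
        if per_protein_scores_b is not None and col in per_protein_scores_b:
            b = per_protein_scores_b[col].to_numpy(dtype=float)
            row["amae_b"] = np.nanmean(b)
            row["sd_b"] = np.nanstd(b, ddof=1)
            try:
                _t, p = paired_t_test(a, b)
                row["p_value"] = p
            except DegenerateMetricError:
                row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
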