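"""Relating equilibrium structural features to residue flexibility.

Flexibility here is any per-residue fluctuation measure — a normal-mode
derived B-factor for a full dataset, or an MD-derived RMSF for a handful
of simulated chains. The questions answered by this module:

* how strongly does each ESF correlate with the fluctuation profile,
  protein by protein;
* how well can a small network predict fluctuations from different input
  feature sets (raw PSSM encoding, observed ESFs, cross-validated
  predicted ESFs, or both), compared against a randomized-target
  background;
* how much of that is explained by two structure-only baselines — distance
  from the membrane mid-plane (|z|) and the TM / non-TM binary split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluate
from .features import ESF_NAMES, esf_matrix
from .model import EncoderConfig, build_network, encode_chain, train


def esf_flex_correlations(corpus, flex_by_protein=None, tm_only: bool = True) -> pd.DataFrame:
    """Per-feature correlation with flexibility, protein-wise mean +- SD.

    For each protein, Pearson correlation between each ESF and the
    fluctuation profile (its own ``flex`` attribute unless
    ``flex_by_protein`` overrides); degenerate proteins are skipped.
    Returns a DataFrame indexed by feature with columns mean, sd, n_proteins.
    """
    per_protein = {name: [] for name in ESF_NAMES}
    for i, prot in enumerate(corpus):
        flex = prot.flex if flex_by_protein is None else flex_by_protein[i]
        flex = np.asarray(flex, dtype=float)
        sel = prot.segments.tm_flag if tm_only else np.ones(len(flex), dtype=bool)
        for name in ESF_NAMES:
            x = prot.esf_table[name].to_numpy(dtype=float)[sel]
            y = flex[sel]
            try:
                per_protein[name].append(evaluate.pearson(x, y))
            except evaluate.DegenerateMetricError:
                continue
    rows = []
    for name in ESF_NAMES:
        vals = np.asarray(per_protein[name])
        rows.append({
            "feature": name,
            "mean": vals.mean() if len(vals) else np.nan,
            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "n_proteins": len(vals),
        })
    return pd.DataFrame(rows).set_index("feature")


def build_feature_set(mode: str, corpus=None, loo_result=None,
                      cfg: EncoderConfig | None = None,
                      tm_only: bool = True):
    """Stacked per-residue input vectors for flexibility regression.

    Modes: ``pssm`` (window encoding + composition, 200-dim),
    ``esf_observed`` (8 scaled observed ESFs), ``esf_predicted`` (8 scaled
    leave-one-out predicted ESFs), ``esf_both`` (16-dim concatenation).
    Returns ``(X, y, protein_index)`` restricted to TM residues when
    ``tm_only``; masked observed ESFs are imputed at the neutral 0.5.
    """
    if corpus is None:
        raise ValueError(f"mode {mode!r} requires a corpus")
    needs_pred = mode in ("esf_predicted", "esf_both")
    if needs_pred and loo_result is None:
        raise ValueError(f"mode {mode!r} requires leave-one-out predictions")
    cfg = cfg or EncoderConfig()
    X_parts, y_parts, idx_parts = [], [], []
    for i, prot in enumerate(corpus):
        sel = prot.segments.tm_flag if tm_only else np.ones(len(prot.chain), dtype=bool)
        if mode == "pssm":
            feats = encode_chain(prot.pssm, cfg)
        else:
            obs, mask = esf_matrix(prot.esf_table)
            obs = np.where(mask, obs, 0.5)
            if mode == "esf_observed":
                feats = obs
            else:
                pred = np.asarray(loo_result.predictions[prot.protein_id], dtype=float)
                feats = pred if mode == "esf_predicted" else np.hstack([pred, obs])
        X_parts.append(feats[sel])
        y_parts.append(np.asarray(prot.flex, dtype=float)[sel])
        idx_parts.append(np.full(sel.sum(), i))
    return np.vstack(X_parts), np.concatenate(y_parts), np.concatenate(idx_parts)


def train_flex_predictor(feature_set: np.ndarray, flex_targets: np.ndarray,
                         epochs: int = 300, lr: float = 0.1, seed: int = 0,
                         batch_size: int = 16, n_background: int = 5):
    """Single-output network (2 hidden units) regressing flexibility.

    Targets are min-max scaled to [0, 1] internally. Returns a dict with
    the trained model, the fit correlation, the randomized-target
    background (mean, sd) and the correlation's two-tailed p-value.
    """
    X = np.asarray(feature_set, dtype=float)
    y = np.asarray(flex_targets, dtype=float).ravel()
    if len(y) < 30:
        raise ValueError("need at least 30 residues to fit a flexibility model")
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise evaluate.DegenerateMetricError("constant flexibility targets")
    y01 = (y - lo) / (hi - lo)
    net = build_network(X.shape[1], 1, hidden_per_feature=2, seed=seed,
                        target_names=["flex"])
    net = train(net, X, y01[:, None], epochs=epochs, lr=lr, seed=seed,
                batch_size=batch_size)
    pred = net.forward(X)[:, 0]
    fit_corr = evaluate.pearson(pred, y01)
    bg_mean, bg_sd = evaluate.randomized_background(
        X, y01, n_shuffles=n_background, seed=seed, epochs=epochs, lr=lr,
        batch_size=batch_size)
    p = evaluate.correlation_p_value(fit_corr, len(y01))
    return {"model": net, "fit_correlation": fit_corr,
            "background_mean": bg_mean, "background_sd": bg_sd, "p_value": p}


def z_baseline(flex, z) -> float:
    """Correlation between |z| (distance from the membrane mid-plane) and flex."""
    z = np.asarray(z, dtype=float)
    return evaluate.pearson(np.abs(z), flex)


def tm_binary_baseline(flex, tm_flag) -> float:
    """Point-biserial correlation between the non-TM indicator and flexibility.

    Residues are labeled 0 inside the membrane and 1 outside; a strongly
    positive value means the apparent predictability of flexibility may
    just reflect the TM / non-TM split.
    """
    labels = 1.0 - np.asarray(tm_flag, dtype=float)
    if len(np.unique(labels)) < 2:
        raise evaluate.DegenerateMetricError("both TM and non-TM residues required")
    return evaluate.pearson(labels, flex)
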