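"""PSSM-window encoding, feed-forward networks and the leave-one-out protocol.

The predictor is a single-hidden-layer sigmoid network. Inputs are the
logistic-squashed PSSM rows of the target residue and its sequence
neighbors in a 9-residue window (positions beyond the termini zero-filled)
plus the protein's 20-dim amino acid composition: 20 * 9 + 20 = 200 inputs
at defaults. The hidden layer always holds twice as many units as there
are output features — 16 for the integrated 8-feature model, 2 for an
individual single-feature model — which keeps the total parameter counts
of the two designs within a few percent of each other.

Training is plain stochastic gradient backpropagation on a masked MSE for
a fixed number of epochs; masked targets contribute no gradient. Weights,
encoder settings and scaling ranges round-trip through JSON model files so
predictions are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import PSSMProfile
from .features import ESF_NAMES, SCALING_RANGES


@dataclass
class EncoderConfig:
    window: int = 9
    pssm_squash: str = "logistic"
    include_composition: bool = True

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if self.pssm_squash not in ("logistic", "identity"):
            raise ValueError(f"unknown squash {self.pssm_squash!r}")

    @property
    def n_inputs(self) -> int:
        return 20 * self.window + (20 if self.include_composition else 0)


def _squash(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-x))
    return x


def encode_residue(pssm: PSSMProfile, i: int, cfg: EncoderConfig | None = None) -> np.ndarray:
    """Input vector for residue i: squashed window rows + composition.

    Window positions beyond the termini are zero-filled (post-squash zeros,
    distinguishing "no residue" from a neutral score of 0.5).
    """
    cfg = cfg or EncoderConfig()
    L = len(pssm)
    if not (0 <= i < L):
        raise IndexError(f"residue index {i} outside chain of length {L}")
    half = cfg.window // 2
    parts = []
    squashed = _squash(pssm.logodds, cfg.pssm_squash)
    for off in range(-half, half + 1):
        j = i + off
        if 0 <= j < L:
            parts.append(squashed[j])
        else:
            parts.append(np.zeros(20))
    if cfg.include_composition:
        parts.append(pssm.composition)
    return np.concatenate(parts)


def encode_chain(pssm: PSSMProfile, cfg: EncoderConfig | None = None) -> np.ndarray:
    cfg = cfg or EncoderConfig()
    return np.stack([encode_residue(pssm, i, cfg) for i in range(len(pssm))])


# ---------------------------------------------------------------------------
# Network

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class NetworkModel:
    W1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray
    W2: np.ndarray  # (n_hidden, n_out)
    b2: np.ndarray
    target_names: list[str]
    scaling_ranges: dict = field(default_factory=lambda: dict(SCALING_RANGES))
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    seed: int = 0
    training: dict = field(default_factory=dict)
    left_out_id: str | None = None
    left_out_sequence: str | None = None
    loss_trace: list[float] = field(default_factory=list)

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.W1.shape[0], self.W1.shape[1], self.W2.shape[1])

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Scaled (0, 1) outputs for a batch of input vectors."""
        H = _sigmoid(X @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2)

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            W1=self.W1.copy(), b1=self.b1.copy(), W2=self.W2.copy(), b2=self.b2.copy(),
            target_names=list(self.target_names), scaling_ranges=dict(self.scaling_ranges),
            encoder=EncoderConfig(**asdict(self.encoder)), seed=self.seed,
            training=dict(self.training), left_out_id=self.left_out_id,
            left_out_sequence=self.left_out_sequence, loss_trace=list(self.loss_trace))

    def to_json(self, path) -> None:
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "target_names": self.target_names,
            "scaling_ranges": {k: list(v) for k, v in self.scaling_ranges.items()},
            "encoder": asdict(self.encoder),
            "seed": self.seed,
            "training": self.training,
            "left_out_id": self.left_out_id,
            "left_out_sequence": self.left_out_sequence,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            W1=np.asarray(d["W1"]), b1=np.asarray(d["b1"]),
            W2=np.asarray(d["W2"]), b2=np.asarray(d["b2"]),
            target_names=d["target_names"],
            scaling_ranges={k: tuple(v) for k, v in d["scaling_ranges"].items()},
            encoder=EncoderConfig(**d["encoder"]), seed=d.get("seed", 0),
            training=d.get("training", {}), left_out_id=d.get("left_out_id"),
            left_out_sequence=d.get("left_out_sequence"))


def build_network(n_in: int, n_out: int, hidden_per_feature: int = 2,
                  seed: int = 0, target_names: list[str] | None = None,
                  encoder: EncoderConfig | None = None) -> NetworkModel:
    """Fresh network with ``hidden_per_feature * n_out`` sigmoid hidden units.

    Weights and biases initialized uniform(-0.5, 0.5) from ``seed``.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("n_in and n_out must be >= 1")
    n_hidden = hidden_per_feature * n_out
    rng = np.random.default_rng(seed)
    return NetworkModel(
        W1=rng.uniform(-0.5, 0.5, (n_in, n_hidden)),
        b1=rng.uniform(-0.5, 0.5, n_hidden),
        W2=rng.uniform(-0.5, 0.5, (n_hidden, n_out)),
        b2=rng.uniform(-0.5, 0.5, n_out),
        target_names=target_names or [f"y{j}" for j in range(n_out)],
        encoder=encoder or EncoderConfig(),
        seed=seed)


def count_parameters(spec) -> int:
    """Trainable weights + biases of a model or a (n_in, n_hidden, n_out) spec."""
    if isinstance(spec, NetworkModel):
        n_in, n_h, n_out = spec.layer_sizes
    else:
        n_in, n_h, n_out = spec
    return n_in * n_h + n_h + n_h * n_out + n_out


def compare_parameter_counts(integrated_spec, individual_specs) -> float:
    """Percent difference 100 * (P_integrated - P_individual) / P_individual."""
    p_int = count_parameters(integrated_spec)
    p_ind = sum(count_parameters(s) for s in individual_specs)
    return 100.0 * (p_int - p_ind) / p_ind


# ---------------------------------------------------------------------------
# Training

def train(model: NetworkModel, inputs: np.ndarray, targets: np.ndarray,
          masks: np.ndarray | None = None, epochs: int = 300, lr: float = 0.1,
          seed: int = 0, batch_size: int = 16) -> NetworkModel:
    """Stochastic-gradient backpropagation on a masked MSE, fixed epoch count.

    The sample order is reshuffled every epoch from ``seed``; masked targets
    contribute zero gradient and are excluded from the loss normalization.
    Returns a new model carrying the per-epoch loss trace.
    """
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    M = np.ones_like(Y, dtype=bool) if masks is None else np.asarray(masks, dtype=bool)
    if M.ndim == 1:
        M = M[:, None]
    if not M.any():
        raise ValueError("all targets are masked; nothing to train on")
    Yf = np.where(M, np.nan_to_num(Y), 0.0)
    m = model.copy()
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trace = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb, mb = X[idx], Yf[idx], M[idx]
            if not mb.any():
                continue
            H = _sigmoid(xb @ m.W1 + m.b1)
            P = _sigmoid(H @ m.W2 + m.b2)
            err = np.where(mb, P - yb, 0.0)
            # error summed over output units, averaged over batch rows: the
            # per-output gradient scale is then identical for a multi-output
            # network and a bank of single-output networks.
            d2 = (2.0 / len(idx)) * err * P * (1.0 - P)
            d1 = (d2 @ m.W2.T) * H * (1.0 - H)
            m.W2 -= lr * (H.T @ d2)
            m.b2 -= lr * d2.sum(axis=0)
            m.W1 -= lr * (xb.T @ d1)
            m.b1 -= lr * d1.sum(axis=0)
        P_all = m.forward(X)
        mse = float((np.where(M, P_all - Yf, 0.0) ** 2).sum() / M.sum())
        trace.append(mse)
    m.loss_trace = trace
    m.training = {"epochs": epochs, "lr": lr, "batch_size": batch_size, "seed": seed}
    return m


def predict(model: NetworkModel, pssm: PSSMProfile) -> pd.DataFrame:
    """Per-residue predictions in native units (deterministic given model).

    Columns follow ``model.target_names``; scaled sigmoid outputs are mapped
    back through the model's stored scaling ranges.
    """
    X = encode_chain(pssm, model.encoder)
    scaled = model.forward(X)
    out = {}
    for j, name in enumerate(model.target_names):
        lo, hi = model.scaling_ranges.get(name, (0.0, 1.0))
        out[name] = scaled[:, j] * (hi - lo) + lo
    return pd.DataFrame(out)


def predict_scaled(model: NetworkModel, pssm: PSSMProfile) -> np.ndarray:
    return model.forward(encode_chain(pssm, model.encoder))


# ---------------------------------------------------------------------------
# Leave-one-out protocol

@dataclass
class ProteinData:
    """Encoded training material for one protein."""

    protein_id: str
    X: np.ndarray          # (L, n_in)
    Y: np.ndarray          # (L, n_out) scaled targets
    mask: np.ndarray       # (L, n_out) True where defined
    sequence: str = ""


@dataclass
class LOOResult:
    mode: str
    target_names: list[str]
    predictions: dict      # id -> (L, n_out) scaled predictions from the excluded model
    models: dict           # id -> NetworkModel | list[NetworkModel]
    training_ids: dict     # id -> tuple of protein ids the model was trained on


def corpus_to_protein_data(corpus, cfg: EncoderConfig | None = None,
                           targets: str = "esf") -> list[ProteinData]:
    """Encode a synthetic corpus (or anything shaped like it) for training.

    ``targets='esf'`` uses the eight scaled ESFs; ``targets='tm'`` uses the
    binary TM flag as a single output.
    """
    from .features import esf_matrix

    cfg = cfg or EncoderConfig()
    out = []
    for prot in corpus:
        X = encode_chain(prot.pssm, cfg)
        if targets == "esf":
            Y, mask = esf_matrix(prot.esf_table)
        elif targets == "tm":
            Y = prot.segments.tm_flag.astype(float)[:, None]
            mask = np.ones_like(Y, dtype=bool)
        else:
            raise ValueError(f"unknown target set {targets!r}")
        out.append(ProteinData(protein_id=prot.protein_id, X=X, Y=Y, mask=mask,
                               sequence=prot.chain.sequence))
    return out


def loo_protocol(proteins: list[ProteinData], mode: str = "integrated",
                 cfg: EncoderConfig | None = None, epochs: int = 300,
                 lr: float = 0.1, seed: int = 0, batch_size: int = 16,
                 hidden_per_feature: int = 2) -> LOOResult:
    """Leave-one-out training: protein k is predicted by the model that never saw k.

    Modes: ``integrated`` (one multi-output network per fold),
    ``individual`` (one single-output network per feature per fold),
    ``tm`` (single-output network; targets must already be 1-dim).
    """
    if len(proteins) < 2:
        raise ValueError("leave-one-out needs at least 2 proteins")
    if mode not in ("integrated", "individual", "tm"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or EncoderConfig()
    n_out = proteins[0].Y.shape[1]
    if mode == "integrated" and n_out == 8:
        names = list(ESF_NAMES)
    elif mode == "tm":
        names = ["tm"]
    else:
        names = list(ESF_NAMES[:n_out]) if n_out <= 8 else [f"y{j}" for j in range(n_out)]
    predictions, models, training_ids = {}, {}, {}
    for k, left_out in enumerate(proteins):
        rest = [p for j, p in enumerate(proteins) if j != k]
        X = np.vstack([p.X for p in rest])
        Y = np.vstack([p.Y for p in rest])
        M = np.vstack([p.mask for p in rest])
        fold_seed = (seed * 1_000_003 + k) % (2 ** 31)
        if mode in ("integrated", "tm"):
            net = build_network(X.shape[1], n_out, hidden_per_feature,
                                seed=fold_seed, target_names=names, encoder=cfg)
            net = train(net, X, Y, M, epochs=epochs, lr=lr, seed=fold_seed,
                        batch_size=batch_size)
            net.left_out_id = left_out.protein_id
            net.left_out_sequence = left_out.sequence
            pred = net.forward(left_out.X)
            models[left_out.protein_id] = net
        else:
            nets = []
            cols = []
            for j in range(n_out):
                netj = build_network(X.shape[1], 1, hidden_per_feature,
                                     seed=fold_seed + 7919 * (j + 1),
                                     target_names=[names[j]], encoder=cfg)
                netj = train(netj, X, Y[:, j:j + 1], M[:, j:j + 1], epochs=epochs,
                             lr=lr, seed=fold_seed + 7919 * (j + 1),
                             batch_size=batch_size)
                netj.left_out_id = left_out.protein_id
                netj.left_out_sequence = left_out.sequence
                cols.append(netj.forward(left_out.X)[:, 0])
                nets.append(netj)
            pred = np.column_stack(cols)
            models[left_out.protein_id] = nets
        predictions[left_out.protein_id] = pred
        training_ids[left_out.protein_id] = tuple(p.protein_id for p in rest)
    return LOOResult(mode=mode, target_names=names, predictions=predictions,
                     models=models, training_ids=training_ids)


# ---------------------------------------------------------------------------
# Model selection for unseen sequences

def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity (matches / alignment length)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for (s1, e1), (s2, e2) in zip(aln.aligned[0], aln.aligned[1])
        for i, j in zip(range(s1, e1), range(s2, e2))
        if a[i] == b[j]
    )
    return matches / max(aln.length, 1)


def select_model_for_query(loo_models: list[NetworkModel], query_sequence: str) -> NetworkModel:
    """The LOO model whose left-out protein is most similar to the query.

    Ties broken by first index. Mirrors the rule that an unseen sequence is
    predicted by the model trained without its closest relative.
    """
    if not loo_models:
        raise ValueError("no models to select from")
    scores = [
        sequence_identity(m.left_out_sequence or "", query_sequence)
        for m in loo_models
    ]
    return loo_models[int(np.argmax(scores))]
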