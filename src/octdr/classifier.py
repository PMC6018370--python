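"""Two-stage deep fusion classification network (DFCN).

Stage 1 screens normal vs diabetic retinopathy (DR); stage 2 grades DR
eyes as subclinical vs mild/moderate.  Each stage is a fusion network:

* 36 per-(layer, feature) stacked autoencoders — one per CDF descriptor
  slot — pretrained greedily layer-wise and unsupervised on their own
  slot's vectors, with a nonnegativity penalty on the weights;
* a softmax head trained by cross-entropy on the concatenated codes
  (36 slots x final code dimension).

Everything is plain numpy with deterministic full-batch gradient descent:
the step size adapts by backtracking (a step is only accepted if the
objective does not increase), so loss traces are monotone and runs with
the same seed are bit-identical.  The nonnegativity penalty is an L1
penalty on the negative part of each weight matrix, applied as a proximal
step, so a large penalty drives negative weights exactly to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SLOTS = 36  # 12 layers x 3 feature families

SCREEN_CLASSES = ("normal", "dr")
GRADE_CLASSES = ("subclinical", "mild_moderate")

_DR_GRADES = ("subclinical", "mild_moderate")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training schedule shared by all 36 slots."""

    input_dim: int = 64
    hidden_dims: tuple[int, ...] = (32, 8)
    nonnegativity_weight: float = 1e-3
    epochs: int = 60
    learning_rate: float = 4.0
    head_epochs: int = 250
    head_learning_rate: float = 1.0
    head_l2: float = 1e-4
    fine_tune: bool = False
    fine_tune_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.input_dim,) + tuple(self.hidden_dims)
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ValueError("hidden dims must be strictly decreasing from input_dim")
        if self.nonnegativity_weight < 0:
            raise ValueError("nonnegativity_weight must be >= 0")

    @property
    def code_dim(self) -> int:
        return self.hidden_dims[-1]


@dataclass
class EncoderStack:
    """Greedy-pretrained encoder (and decoder) layers for one slot.

    Inputs are centred on the slot's training-set mean CDF before the
    first sigmoid layer: across-eye variation of a CDF slot is small
    compared to its mean shape, and centring makes that variation the
    quantity the autoencoder actually has to encode.
    """

    enc_layers: list[tuple[np.ndarray, np.ndarray]]   # (W, b) per layer
    dec_layers: list[tuple[np.ndarray, np.ndarray]]   # reversed order
    input_mean: np.ndarray | None = None              # (G,) slot mean CDF
    loss_traces: list[list[float]] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        if self.input_mean is not None:
            X = X - self.input_mean
        for W, b in self.enc_layers:
            X = _sigmoid(X @ W + b)
        return X

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Encode then decode (decoder outputs are linear)."""
        Z = self.encode(X)
        for W, b in self.dec_layers:
            Z = Z @ W + b
        if self.input_mean is not None:
            Z = Z + self.input_mean
        return Z


def _nonneg_prox(W: np.ndarray, step: float) -> np.ndarray:
    """Proximal step of the L1 penalty on the negative part."""
    return np.where(W < 0, np.minimum(W + step, 0.0), W)


def _ae_objective(X, W1, b1, W2, b2, lam) -> float:
    H = _sigmoid(X @ W1 + b1)
    Y = H @ W2 + b2
    mse = float(((Y - X) ** 2).mean())
    pen = lam * float(np.maximum(-W1, 0).sum() + np.maximum(-W2, 0).sum())
    return mse + pen


def _train_ae_layer(X: np.ndarray, hidden: int, spec: AutoencoderSpec,
                    rng: np.random.Generator):
    """One autoencoder layer: sigmoid code, linear reconstruction.

    Full-batch gradient descent with backtracking (only nonincreasing
    steps are accepted), then the nonnegativity proximal step.
    """
    n, d = X.shape
    lam = spec.nonnegativity_weight
    W1 = rng.normal(0, 1.0 / np.sqrt(d), (d, hidden))
    b1 = np.zeros(hidden)
    W2 = rng.normal(0, 1.0 / np.sqrt(hidden), (hidden, d))
    b2 = np.zeros(d)
    lr = spec.learning_rate
    loss = _ae_objective(X, W1, b1, W2, b2, lam)
    trace = [loss]
    for _ in range(spec.epochs):
        H = _sigmoid(X @ W1 + b1)
        Y = H @ W2 + b2
        dY = 2.0 * (Y - X) / (n * d)
        gW2 = H.T @ dY
        gb2 = dY.sum(axis=0)
        dH = (dY @ W2.T) * H * (1 - H)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        accepted = False
        for _try in range(8):
            nW1 = _nonneg_prox(W1 - lr * gW1, lr * lam)
            nW2 = _nonneg_prox(W2 - lr * gW2, lr * lam)
            nb1, nb2 = b1 - lr * gb1, b2 - lr * gb2
            new_loss = _ae_objective(X, nW1, nb1, nW2, nb2, lam)
            if new_loss <= loss + 1e-15:
                W1, b1, W2, b2, loss = nW1, nb1, nW2, nb2, new_loss
                lr = min(lr * 1.5, 100.0)
                accepted = True
                break
            lr *= 0.5
        trace.append(loss)
        if not accepted:
            break
    return (W1, b1), (W2, b2), trace


def pretrain_autoencoders(descriptors: list, spec: AutoencoderSpec,
                          ) -> list[EncoderStack]:
    """Greedy layer-wise unsupervised pretraining of all 36 slots.

    Each slot trains on its own CDF vectors only.  Deterministic for a
    fixed seed (per-slot streams are spawned from one seed sequence).
    """
    if len(descriptors) < 2:
        raise ValueError("need at least 2 training descriptors")
    slot_data = _slot_matrix(descriptors, spec.input_dim)
    children = np.random.SeedSequence(spec.seed).spawn(N_SLOTS)
    stacks = []
    for i in range(N_SLOTS):
        rng = np.random.default_rng(children[i])
        mean = slot_data[i].mean(axis=0)
        X = slot_data[i] - mean
        enc, dec, traces = [], [], []
        for hidden in spec.hidden_dims:
            (W1, b1), (W2, b2), trace = _train_ae_layer(X, hidden, spec, rng)
            enc.append((W1, b1))
            dec.insert(0, (W2, b2))
            traces.append(trace)
            X = _sigmoid(X @ W1 + b1)
        stacks.append(EncoderStack(enc_layers=enc, dec_layers=dec,
                                   input_mean=mean, loss_traces=traces))
    return stacks


def _slot_matrix(descriptors: list, input_dim: int) -> np.ndarray:
    """(36, n, G) array of per-slot CDF vectors."""
    out = np.empty((N_SLOTS, len(descriptors), input_dim))
    for j, d in enumerate(descriptors):
        if len(d.cdfs) != N_SLOTS:
            raise ValueError(f"descriptor must hold {N_SLOTS} CDFs")
        for i, cdf in enumerate(d.cdfs):
            if cdf.values.size != input_dim:
                raise ValueError(
                    f"CDF grid length {cdf.values.size} != spec input_dim {input_dim}")
            out[i, j] = cdf.values
    return out


@dataclass
class FusionNetwork:
    """One stage of the DFCN: 36 encoder stacks + a softmax head."""

    stage: str                       # "screen" or "grade"
    encoders: list[EncoderStack]
    head_W: np.ndarray
    head_b: np.ndarray
    classes: tuple[str, str]
    input_dim: int
    code_mean: np.ndarray | None = None  # training-set fused-code statistics
    code_sd: np.ndarray | None = None
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.encoders) != N_SLOTS:
            raise ValueError(f"fusion network must hold exactly {N_SLOTS} encoders")

    def fuse(self, descriptors: list) -> np.ndarray:
        """Concatenated standardized codes (n, 36 * code_dim)."""
        slot_data = _slot_matrix(descriptors, self.input_dim)
        Z = np.concatenate(
            [self.encoders[i].encode(slot_data[i]) for i in range(N_SLOTS)], axis=1)
        if self.code_mean is not None:
            Z = (Z - self.code_mean) / self.code_sd
        return Z

    def predict_proba(self, descriptors: list) -> np.ndarray:
        """(n, 2) class probabilities, columns ordered as ``classes``."""
        Z = self.fuse(descriptors)
        logits = Z @ self.head_W + self.head_b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "classes": list(self.classes),
            "input_dim": self.input_dim,
            "head_W": self.head_W.tolist(),
            "head_b": self.head_b.tolist(),
            "code_mean": None if self.code_mean is None else self.code_mean.tolist(),
            "code_sd": None if self.code_sd is None else self.code_sd.tolist(),
            "encoders": [
                {"enc": [[W.tolist(), b.tolist()] for W, b in s.enc_layers],
                 "dec": [[W.tolist(), b.tolist()] for W, b in s.dec_layers],
                 "input_mean": (None if s.input_mean is None
                                else s.input_mean.tolist())}
                for s in self.encoders
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FusionNetwork":
        encoders = [
            EncoderStack(
                enc_layers=[(np.array(W), np.array(b)) for W, b in s["enc"]],
                dec_layers=[(np.array(W), np.array(b)) for W, b in s["dec"]],
                input_mean=(None if s.get("input_mean") is None
                            else np.array(s["input_mean"])))
            for s in payload["encoders"]
        ]
        return cls(stage=payload["stage"], encoders=encoders,
                   head_W=np.array(payload["head_W"]),
                   head_b=np.array(payload["head_b"]),
                   classes=tuple(payload["classes"]),
                   input_dim=int(payload["input_dim"]),
                   code_mean=(None if payload.get("code_mean") is None
                              else np.array(payload["code_mean"])),
                   code_sd=(None if payload.get("code_sd") is None
                            else np.array(payload["code_sd"])))


def _labels_for_stage(labels: list[str], stage: str) -> tuple[np.ndarray, tuple[str, str]]:
    if stage == "screen":
        classes = SCREEN_CLASSES
        y = []
        for lab in labels:
            if lab == "normal":
                y.append(0)
            elif lab in _DR_GRADES or lab == "dr":
                y.append(1)
            else:
                raise ValueError(f"unknown label {lab!r} for the screening stage")
    elif stage == "grade":
        classes = GRADE_CLASSES
        y = []
        for lab in labels:
            if lab not in GRADE_CLASSES:
                raise ValueError(
                    f"grading stage accepts only DR subjects, got label {lab!r}")
            y.append(GRADE_CLASSES.index(lab))
    else:
        raise ValueError("stage must be 'screen' or 'grade'")
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError(f"a class is absent from the training labels for {stage}")
    return y, classes


def _softmax_xent(Z, Y1h, W, b, l2) -> float:
    logits = Z @ W + b
    logits -= logits.max(axis=1, keepdims=True)
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return float(-(Y1h * logp).sum() / Z.shape[0] + 0.5 * l2 * (W**2).sum())


def train_stage(descriptors: list, labels: list[str], stage: str,
                spec: AutoencoderSpec,
                encoders: list[EncoderStack] | None = None) -> FusionNetwork:
    """Train one stage: (optionally reuse) pretrained encoders + softmax head.

    Encoders are frozen by default; with ``spec.fine_tune`` the whole stack
    is refined jointly by backpropagation after head training.
    """
    if len(descriptors) != len(labels):
        raise ValueError("descriptors and labels must align")
    y, classes = _labels_for_stage(list(labels), stage)
    if encoders is None:
        encoders = pretrain_autoencoders(descriptors, spec)

    net = FusionNetwork(stage=stage, encoders=encoders,
                        head_W=np.zeros((N_SLOTS * spec.code_dim, 2)),
                        head_b=np.zeros(2), classes=classes,
                        input_dim=spec.input_dim)
    Z_raw = net.fuse(descriptors)
    net.code_mean = Z_raw.mean(axis=0)
    net.code_sd = np.maximum(Z_raw.std(axis=0), 1e-6)
    Z = (Z_raw - net.code_mean) / net.code_sd
    n = Z.shape[0]
    Y1h = np.zeros((n, 2))
    Y1h[np.arange(n), y] = 1.0

    W, b = net.head_W, net.head_b
    lr = spec.head_learning_rate
    loss = _softmax_xent(Z, Y1h, W, b, spec.head_l2)
    trace = [loss]
    for _ in range(spec.head_epochs):
        logits = Z @ W + b
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        G = (P - Y1h) / n
        gW = Z.T @ G + spec.head_l2 * W
        gb = G.sum(axis=0)
        accepted = False
        for _try in range(8):
            nW, nb = W - lr * gW, b - lr * gb
            new_loss = _softmax_xent(Z, Y1h, nW, nb, spec.head_l2)
            if new_loss <= loss + 1e-15:
                W, b, loss = nW, nb, new_loss
                lr = min(lr * 1.5, 1e3)
                accepted = True
                break
            lr *= 0.5
        trace.append(loss)
        if not accepted:
            break
    net.head_W, net.head_b, net.loss_trace = W, b, trace

    if spec.fine_tune:
        _fine_tune(net, descriptors, Y1h, spec)
    return net


def _fine_tune(net: FusionNetwork, descriptors: list, Y1h: np.ndarray,
               spec: AutoencoderSpec) -> None:
    """Joint cross-entropy refinement of encoders + head (fixed small lr)."""
    slot_data = _slot_matrix(descriptors, spec.input_dim)
    n = Y1h.shape[0]
    lr = 0.1 * spec.head_learning_rate
    code_dim = spec.code_dim
    for _ in range(spec.fine_tune_epochs):
        acts = []  # per slot: list of layer activations
        codes = []
        for i in range(N_SLOTS):
            x0 = slot_data[i]
            if net.encoders[i].input_mean is not None:
                x0 = x0 - net.encoders[i].input_mean
            a = [x0]
            for Wl, bl in net.encoders[i].enc_layers:
                a.append(_sigmoid(a[-1] @ Wl + bl))
            acts.append(a)
            codes.append(a[-1])
        Z = np.concatenate(codes, axis=1)
        if net.code_mean is not None:
            Z = (Z - net.code_mean) / net.code_sd
        logits = Z @ net.head_W + net.head_b
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        G = (P - Y1h) / n
        gZ = G @ net.head_W.T
        if net.code_sd is not None:
            gZ = gZ / net.code_sd
        net.head_W = net.head_W - lr * (Z.T @ G + spec.head_l2 * net.head_W)
        net.head_b = net.head_b - lr * G.sum(axis=0)
        for i in range(N_SLOTS):
            d = gZ[:, i * code_dim:(i + 1) * code_dim]
            layers = net.encoders[i].enc_layers
            for li in range(len(layers) - 1, -1, -1):
                Wl, bl = layers[li]
                h = acts[i][li + 1]
                d = d * h * (1 - h)
                gW = acts[i][li].T @ d
                gb = d.sum(axis=0)
                d = d @ Wl.T
                layers[li] = (Wl - lr * gW, bl - lr * gb)


@dataclass
class Diagnosis:
    """Final call for one eye/subject: screen first, grade only if DR."""

    stage1: str                      # "normal" or "dr"
    stage1_probability: float        # probability of DR
    stage2: str | None = None        # set only when stage1 == "dr"
    stage2_probability: float | None = None  # probability of mild/moderate

    def __post_init__(self) -> None:
        if not 0.0 <= self.stage1_probability <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.stage1 == "normal" and self.stage2 is not None:
            raise ValueError("stage2 must be unset for a normal stage-1 call")


def classify(descriptor, screen_net: FusionNetwork, grade_net: FusionNetwork,
             threshold: float = 0.5) -> Diagnosis:
    """Two-stage diagnosis of one descriptor.

    Stage 1 thresholds the DR probability; stage 2 runs only on
    stage-1-positive cases.  Probabilities are returned for ROC curves.
    """
    if screen_net.input_dim != grade_net.input_dim:
        raise ValueError("screen and grade networks were trained on different grids")
    p_dr = float(screen_net.predict_proba([descriptor])[0, 1])
    if p_dr >= threshold:
        p_mm = float(grade_net.predict_proba([descriptor])[0, 1])
        stage2 = GRADE_CLASSES[int(p_mm >= 0.5)]
        return Diagnosis(stage1="dr", stage1_probability=p_dr,
                         stage2=stage2, stage2_probability=p_mm)
    return Diagnosis(stage1="normal", stage1_probability=p_dr)
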