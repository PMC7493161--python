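"""Encoder/decoder/task-head architectures and latent fusion.

Each modality gets an independent autoencoder: an encoder ``q(x)`` mapping
the input to a latent ``z``, and a mirrored decoder ``p(z)`` whose final
layer is a sigmoid because all inputs are scaled to [0, 1]. A task head is
either a linear classifier to ``C`` logits or a small two-layer survival
network producing one log-relative-hazard per sample.

Integration modes
-----------------
single  one modality, head on its latent
concat  complementary integration: head on the concatenated latents
cross   consensus integration: head on the element-wise average of latents
        (requires equal latent dims)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import MLP, Dense, ReLU, Sigmoid

__all__ = [
    "NetworkSpec", "ModelBundle",
    "build_autoencoder", "build_classifier_head", "build_survival_head",
    "build_bundle", "encode", "decode", "classify", "hazard",
    "fuse_concat", "fuse_average", "default_latent_dim",
    "save_bundle", "load_bundle",
]


def default_latent_dim(input_dim: int) -> int:
    """Latent size convention: 10 for 100-dim (PCA) inputs, 100 for
    1000-dim (top-variance) inputs — i.e. one tenth of the input width,
    bounded below by 2."""
    return max(2, input_dim // 10)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one modality's autoencoder plus the task head kind.

    ``encoder_hidden`` lists the widths of the encoder's hidden layers;
    by default a single hidden layer at the geometric mean of the input
    and latent widths. The decoder mirrors the encoder.
    """

    input_dim: int
    latent_dim: int
    encoder_hidden: tuple[int, ...] = ()
    head: str = "classifier"  # "classifier" or "survival"
    n_classes: int = 0
    survival_hidden: int = 32

    def __post_init__(self):
        if self.input_dim <= 0 or self.latent_dim <= 0:
            raise ValueError("dimensions must be positive")
        if self.head not in ("classifier", "survival"):
            raise ValueError(f"unknown head kind: {self.head!r}")
        if self.head == "classifier" and self.n_classes < 2:
            raise ValueError("classifier head needs n_classes >= 2")
        if not self.encoder_hidden:
            gm = int(round(np.sqrt(self.input_dim * self.latent_dim)))
            object.__setattr__(self, "encoder_hidden", (max(gm, self.latent_dim),))


def build_autoencoder(spec: NetworkSpec, rng: np.random.Generator) -> tuple[MLP, MLP]:
    """Build the (encoder, decoder) pair for one modality."""
    enc_layers: list = []
    d = spec.input_dim
    for w in spec.encoder_hidden:
        enc_layers += [Dense(d, w, rng), ReLU()]
        d = w
    enc_layers.append(Dense(d, spec.latent_dim, rng))
    encoder = MLP(enc_layers)

    dec_layers: list = []
    d = spec.latent_dim
    for w in reversed(spec.encoder_hidden):
        dec_layers += [Dense(d, w, rng), ReLU()]
        d = w
    dec_layers += [Dense(d, spec.input_dim, rng), Sigmoid()]
    decoder = MLP(dec_layers)
    return encoder, decoder


def build_classifier_head(latent_dim: int, n_classes: int,
                          rng: np.random.Generator) -> MLP:
    """Single linear layer from the (fused) latent to C logits."""
    return MLP([Dense(latent_dim, n_classes, rng)])


def build_survival_head(latent_dim: int, rng: np.random.Generator,
                        hidden: int = 32) -> MLP:
    """Two-layer network from the (fused) latent to a scalar hazard."""
    return MLP([Dense(latent_dim, hidden, rng), ReLU(), Dense(hidden, 1, rng)])


@dataclass
class ModelBundle:
    """One (encoder, decoder) pair per modality plus a shared task head."""

    specs: list[NetworkSpec]
    encoders: list[MLP]
    decoders: list[MLP]
    head: MLP
    mode: str  # "single" | "concat" | "cross"
    modality_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in ("single", "concat", "cross"):
            raise ValueError(f"unknown integration mode: {self.mode!r}")
        if self.mode == "single" and len(self.specs) != 1:
            raise ValueError("single mode takes exactly one modality")
        if self.mode == "cross" and len(self.specs) < 2:
            raise ValueError("cross mode needs >= 2 modalities")
        # concat with a single modality is permitted: it degenerates to the
        # single-modality model (used by the reduction property)
        dims = [s.latent_dim for s in self.specs]
        if self.mode == "cross" and len(set(dims)) != 1:
            raise ValueError("cross mode requires equal latent dims")
        head_in = self.head.layers[0].W.shape[0]
        expected = sum(dims) if self.mode == "concat" else dims[0]
        if head_in != expected:
            raise ValueError(
                f"head input dim {head_in} != expected {expected} for mode {self.mode}")
        if not self.modality_names:
            self.modality_names = [f"m{i + 1}" for i in range(len(self.specs))]

    @property
    def head_input_dim(self) -> int:
        return self.head.layers[0].W.shape[0]

    def fuse(self, latents: list[np.ndarray]) -> np.ndarray:
        if self.mode == "concat" and len(latents) > 1:
            return fuse_concat(latents)
        if self.mode == "cross":
            return fuse_average(latents)
        return latents[0]

    def predict(self, xs: list[np.ndarray]) -> np.ndarray:
        """Forward pass: encode each modality, fuse, apply the head."""
        zs = [encode(enc, x, spec) for enc, x, spec in
              zip(self.encoders, xs, self.specs)]
        return self.head.forward(self.fuse(zs))

    def get_state(self) -> list[list[np.ndarray]]:
        mods = self.encoders + self.decoders + [self.head]
        return [m.get_state() for m in mods]

    def set_state(self, state: list[list[np.ndarray]]) -> None:
        mods = self.encoders + self.decoders + [self.head]
        for m, s in zip(mods, state):
            m.set_state(s)


def build_bundle(specs: list[NetworkSpec], mode: str, seed: int,
                 modality_names: list[str] | None = None) -> ModelBundle:
    """Construct a fully initialized model bundle from network specs.

    All modality specs must agree on head kind (and class count); the
    shared task head consumes the concatenated latent in ``concat`` mode
    and a single latent width otherwise.
    """
    if len({(s.head, s.n_classes) for s in specs}) != 1:
        raise ValueError("all specs must share the same head configuration")
    rng = np.random.default_rng(seed)
    encoders, decoders = [], []
    for spec in specs:
        enc, dec = build_autoencoder(spec, rng)
        encoders.append(enc)
        decoders.append(dec)
    head_in = (sum(s.latent_dim for s in specs) if mode == "concat"
               else specs[0].latent_dim)
    if specs[0].head == "classifier":
        head = build_classifier_head(head_in, specs[0].n_classes, rng)
    else:
        head = build_survival_head(head_in, rng, specs[0].survival_hidden)
    return ModelBundle(specs=list(specs), encoders=encoders, decoders=decoders,
                       head=head, mode=mode,
                       modality_names=list(modality_names or []))


def _check_dim(x: np.ndarray, dim: int, what: str) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x))
    if x.shape[1] != dim:
        raise ValueError(f"{what}: expected dim {dim}, got {x.shape[1]}")
    return x


def encode(encoder: MLP, x: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Hidden features z = q(x); rows are samples."""
    return encoder.forward(_check_dim(x, spec.input_dim, "encode"))


def decode(decoder: MLP, z: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Reconstruction x_hat = p(z)."""
    return decoder.forward(_check_dim(z, spec.latent_dim, "decode"))


def classify(head: MLP, z: np.ndarray) -> np.ndarray:
    """Class logits c(z)."""
    return head.forward(np.atleast_2d(z))


def hazard(head: MLP, z: np.ndarray) -> np.ndarray:
    """Per-sample log relative hazard h = s(z), returned as a vector."""
    return head.forward(np.atleast_2d(z)).reshape(-1)


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a bundle to one checkpoint file (.npz) with an embedded
    JSON description of the architecture for exact reconstruction."""
    meta = {"mode": bundle.mode,
            "modality_names": bundle.modality_names,
            "specs": [asdict(s) for s in bundle.specs]}
    arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, module_state in enumerate(bundle.get_state()):
        for j, arr in enumerate(module_state):
            arrays[f"mod{i}_p{j}"] = arr
    np.savez(Path(path), **arrays)


def load_bundle(path) -> ModelBundle:
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["_meta"]).decode())
        specs = []
        for s in meta["specs"]:
            s["encoder_hidden"] = tuple(s["encoder_hidden"])
            specs.append(NetworkSpec(**s))
        bundle = build_bundle(specs, meta["mode"], seed=0,
                              modality_names=list(meta["modality_names"]))
        state = []
        for i in range(len(bundle.get_state())):
            module_state, j = [], 0
            while f"mod{i}_p{j}" in npz:
                module_state.append(npz[f"mod{i}_p{j}"])
                j += 1
            state.append(module_state)
        bundle.set_state(state)
    return bundle


def fuse_concat(latents: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-modality latents along features (complementary fusion)."""
    if len(latents) < 2:
        raise ValueError("concat fusion needs >= 2 modalities")
    mats = [np.atleast_2d(z) for z in latents]
    n = {m.shape[0] for m in mats}
    if len(n) != 1:
        raise ValueError("sample-count mismatch across modalities")
    return np.concatenate(mats, axis=1)


def fuse_average(latents: list[np.ndarray]) -> np.ndarray:
    """Element-wise average of per-modality latents (consensus fusion)."""
    mats = [np.atleast_2d(z) for z in latents]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("latent shape mismatch across modalities")
    return np.mean(mats, axis=0)
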