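"""Training procedures for single-modality, ConcatAE and CrossAE models.

Single-modality / ConcatAE (complementary integration): each epoch first
runs one full pass of minibatch gradient updates on the encoder/decoder
pairs with the (summed) reconstruction loss, then one full pass on the
encoders plus task head with the task loss (cross-entropy or Cox negative
partial likelihood) on the fused latent.

CrossAE (consensus integration) trains in three sequential steps:
(1) per-modality autoencoder training with the summed reconstruction loss;
(2) cross-modality reconstruction — modality 1's decoder reconstructs x1
from modality 2's latent and vice versa — which pulls the paired latents
toward a modality-invariant representation;
(3) task training on the element-wise average of the latents.

All loops consume randomness from a single seeded generator, so runs are
bit-reproducible; survival minibatches without any observed event are
skipped (the partial likelihood is undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses
from .containers import OmicsMatrix, SurvivalTable
from .evaluation import MetricsReport, classification_metrics, concordance_index, \
    paired_hidden_distance
from .models import ModelBundle, NetworkSpec, build_bundle, default_latent_dim, encode
from .nn import Adam
from .preprocess import FittedTransform, minmax_apply, minmax_fit, pca_apply, \
    pca_fit, stratified_folds, variance_select_apply, variance_select_fit

__all__ = ["TaskData", "TrainConfig", "TrainResult",
           "train_single", "train_concat", "train_cross",
           "predict_labels", "predict_hazard",
           "run_cross_validation", "CVResult"]


@dataclass
class TaskData:
    """Aligned per-modality inputs plus the endpoint targets."""

    xs: list[np.ndarray]
    labels: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self):
        self.xs = [np.atleast_2d(np.asarray(x, dtype=np.float64)) for x in self.xs]
        ns = {x.shape[0] for x in self.xs}
        if len(ns) != 1:
            raise ValueError("modalities disagree on sample count")
        n = ns.pop()
        if self.labels is not None:
            self.labels = np.asarray(self.labels).reshape(-1).astype(int)
            if self.labels.shape[0] != n:
                raise ValueError("label count mismatch")
        if (self.time is None) != (self.event is None):
            raise ValueError("survival data needs both time and event")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=np.float64).reshape(-1)
            self.event = np.asarray(self.event).reshape(-1).astype(int)
            if self.time.shape[0] != n or self.event.shape[0] != n:
                raise ValueError("survival field length mismatch")

    @property
    def n(self) -> int:
        return self.xs[0].shape[0]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults follow the study protocol: Adam at learning rate 0.001 for
    200 epochs, batch size 32 for classification and 128 for survival.
    ``epochs_per_cross_step`` budgets the three CrossAE phases.
    """

    endpoint: str = "classification"  # "classification" | "survival"
    epochs: int = 200
    batch_size: int | None = None
    learning_rate: float = 0.001
    seed: int = 0
    epochs_per_cross_step: tuple[int, int, int] = (100, 100, 200)
    eval_every: int = 1
    interleave_cross_steps: bool = False

    def __post_init__(self):
        if self.endpoint not in ("classification", "survival"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("invalid epochs or learning rate")

    @property
    def effective_batch_size(self) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 32 if self.endpoint == "classification" else 128


@dataclass
class TrainResult:
    bundle: ModelBundle
    trace: pd.DataFrame
    best_epoch: int | None = None
    best_val_metric: float | None = None


def predict_labels(bundle: ModelBundle, xs: list[np.ndarray]) -> np.ndarray:
    return bundle.predict(xs).argmax(axis=1)


def predict_hazard(bundle: ModelBundle, xs: list[np.ndarray]) -> np.ndarray:
    return bundle.predict(xs).reshape(-1)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _recon_epoch(bundle: ModelBundle, data: TaskData, opt: Adam,
                 batch_size: int, rng: np.random.Generator) -> float:
    """One pass of encoder/decoder updates with the summed per-modality MSE."""
    total, batches = 0.0, 0
    for idx in _batches(data.n, batch_size, rng):
        loss = 0.0
        for enc, dec, x in zip(bundle.encoders, bundle.decoders, data.xs):
            xb = x[idx]
            z = enc.forward(xb)
            xh = dec.forward(z)
            loss += losses.mse_recon(xb, xh)
            gz = dec.backward(losses.mse_recon_grad(xb, xh).astype(np.float32))
            enc.backward(gz)
        opt.step()
        total += loss
        batches += 1
    return total / max(batches, 1)


def _cross_epoch(bundle: ModelBundle, data: TaskData, opt: Adam,
                 batch_size: int, rng: np.random.Generator) -> float:
    """One pass of cross-modality reconstruction updates (two modalities)."""
    enc1, enc2 = bundle.encoders
    dec1, dec2 = bundle.decoders
    x1, x2 = data.xs
    total, batches = 0.0, 0
    for idx in _batches(data.n, batch_size, rng):
        x1b, x2b = x1[idx], x2[idx]
        z1 = enc1.forward(x1b)
        z2 = enc2.forward(x2b)
        xh12 = dec1.forward(z2)  # modality 1 reconstructed from z2
        xh21 = dec2.forward(z1)  # modality 2 reconstructed from z1
        total += losses.cross_recon_loss(x1b, x2b, xh12, xh21)
        gz2 = dec1.backward(losses.mse_recon_grad(x1b, xh12).astype(np.float32))
        enc2.backward(gz2)
        gz1 = dec2.backward(losses.mse_recon_grad(x2b, xh21).astype(np.float32))
        enc1.backward(gz1)
        opt.step()
        batches += 1
    return total / max(batches, 1)


def _split_fused_grad(bundle: ModelBundle, g: np.ndarray) -> list[np.ndarray]:
    if bundle.mode == "concat":
        dims = [s.latent_dim for s in bundle.specs]
        return list(np.split(g, np.cumsum(dims)[:-1], axis=1))
    if bundle.mode == "cross":
        return [g / len(bundle.specs)] * len(bundle.specs)
    return [g]


def _task_epoch(bundle: ModelBundle, data: TaskData, opt: Adam,
                batch_size: int, rng: np.random.Generator,
                endpoint: str) -> float:
    """One pass of encoder+head updates with the task loss."""
    total, batches = 0.0, 0
    for idx in _batches(data.n, batch_size, rng):
        if endpoint == "survival" and data.event[idx].sum() == 0:
            continue  # partial likelihood undefined without events
        zs = [enc.forward(x[idx]) for enc, x in zip(bundle.encoders, data.xs)]
        fused = bundle.fuse(zs)
        out = bundle.head.forward(fused)
        if endpoint == "classification":
            yb = data.labels[idx]
            total += losses.cross_entropy_loss(out, yb)
            g_out = losses.cross_entropy_grad(out, yb)
        else:
            h = out.reshape(-1)
            tb, cb = data.time[idx], data.event[idx]
            total += losses.cox_nll(h, tb, cb)
            g_out = losses.cox_nll_grad(h, tb, cb).reshape(-1, 1)
        g_fused = bundle.head.backward(g_out.astype(np.float32))
        for enc, g in zip(bundle.encoders, _split_fused_grad(bundle, g_fused)):
            enc.backward(g)
        opt.step()
        batches += 1
    return total / max(batches, 1)


def _val_metric(bundle: ModelBundle, val: TaskData, endpoint: str) -> float:
    if endpoint == "classification":
        return classification_metrics(predict_labels(bundle, val.xs), val.labels)[0]
    return concordance_index(predict_hazard(bundle, val.xs), val.time, val.event)


def _check_endpoint_data(data: TaskData, endpoint: str) -> None:
    if endpoint == "classification" and data.labels is None:
        raise ValueError("classification endpoint requires labels")
    if endpoint == "survival":
        if data.time is None:
            raise ValueError("survival endpoint requires time and event")
        if data.event.sum() == 0:
            raise ValueError("survival training data contains no events")


def _train_joint(bundle: ModelBundle, data: TaskData, config: TrainConfig,
                 val: TaskData | None) -> TrainResult:
    """Shared loop behind train_single and train_concat."""
    _check_endpoint_data(data, config.endpoint)
    rng = np.random.default_rng(config.seed)
    bs = config.effective_batch_size
    opt_recon = Adam(bundle.encoders + bundle.decoders, lr=config.learning_rate)
    opt_task = Adam(bundle.encoders + [bundle.head], lr=config.learning_rate)
    rows = []
    best_state, best_metric, best_epoch = None, -np.inf, None
    for epoch in range(config.epochs):
        recon = _recon_epoch(bundle, data, opt_recon, bs, rng)
        task = _task_epoch(bundle, data, opt_task, bs, rng, config.endpoint)
        row = {"epoch": epoch, "recon_loss": recon, "task_loss": task}
        if val is not None and (epoch + 1) % config.eval_every == 0:
            m = _val_metric(bundle, val, config.endpoint)
            row["val_metric"] = m
            if m > best_metric:
                best_metric, best_epoch = m, epoch
                best_state = bundle.get_state()
        rows.append(row)
    if best_state is not None:
        bundle.set_state(best_state)
    return TrainResult(bundle, pd.DataFrame(rows), best_epoch,
                       None if best_state is None else best_metric)


def train_single(bundle: ModelBundle, data: TaskData, config: TrainConfig,
                 val: TaskData | None = None) -> TrainResult:
    """Alternating reconstruction/task training for one modality."""
    if len(bundle.specs) != 1:
        raise ValueError("train_single expects a one-modality bundle")
    return _train_joint(bundle, data, config, val)


def train_concat(bundle: ModelBundle, data: TaskData, config: TrainConfig,
                 val: TaskData | None = None) -> TrainResult:
    """ConcatAE training: independent autoencoders, task head on the
    concatenated latents. With a single modality this reduces exactly to
    :func:`train_single`."""
    if len(bundle.specs) != len(data.xs):
        raise ValueError("bundle/data modality count mismatch")
    return _train_joint(bundle, data, config, val)


def train_cross(bundle: ModelBundle, data: TaskData, config: TrainConfig,
                val: TaskData | None = None) -> TrainResult:
    """CrossAE three-step training (two modalities).

    Step budgets come from ``config.epochs_per_cross_step``; with
    ``interleave_cross_steps`` the three phases advance one epoch at a
    time instead of sequentially.
    """
    if bundle.mode != "cross" or len(bundle.specs) != 2:
        raise ValueError("train_cross expects a two-modality cross bundle")
    if len({s.latent_dim for s in bundle.specs}) != 1:
        raise ValueError("cross training requires equal latent dims")
    _check_endpoint_data(data, config.endpoint)
    rng = np.random.default_rng(config.seed)
    bs = config.effective_batch_size
    e1, e2, e3 = config.epochs_per_cross_step
    opt_recon = Adam(bundle.encoders + bundle.decoders, lr=config.learning_rate)
    opt_cross = Adam(bundle.encoders + bundle.decoders, lr=config.learning_rate)
    opt_task = Adam(bundle.encoders + [bundle.head], lr=config.learning_rate)
    rows = []
    best_state, best_metric, best_epoch = None, -np.inf, None

    def recon_one(epoch):
        rows.append({"phase": "recon", "epoch": epoch,
                     "loss": _recon_epoch(bundle, data, opt_recon, bs, rng)})

    def cross_one(epoch):
        rows.append({"phase": "cross", "epoch": epoch,
                     "loss": _cross_epoch(bundle, data, opt_cross, bs, rng)})

    def task_one(epoch):
        nonlocal best_state, best_metric, best_epoch
        loss = _task_epoch(bundle, data, opt_task, bs, rng, config.endpoint)
        row = {"phase": "task", "epoch": epoch, "loss": loss}
        if val is not None and (epoch + 1) % config.eval_every == 0:
            m = _val_metric(bundle, val, config.endpoint)
            row["val_metric"] = m
            if m > best_metric:
                best_metric, best_epoch = m, epoch
                best_state = bundle.get_state()
        rows.append(row)

    if config.interleave_cross_steps:
        for epoch in range(max(e1, e2, e3)):
            if epoch < e1:
                recon_one(epoch)
            if epoch < e2:
                cross_one(epoch)
            if epoch < e3:
                task_one(epoch)
    else:
        for epoch in range(e1):
            recon_one(epoch)
        for epoch in range(e2):
            cross_one(epoch)
        for epoch in range(e3):
            task_one(epoch)

    if best_state is not None:
        bundle.set_state(best_state)
    return TrainResult(bundle, pd.DataFrame(rows), best_epoch,
                       None if best_state is None else best_metric)


# ---------------------------------------------------------------------------
# Cross-validated pipeline
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Aggregated cross-validation output."""

    reports: dict[str, MetricsReport]
    fold_details: pd.DataFrame
    distances: pd.DataFrame | None = None  # per-sample paired-latent distances
    bundles: list = field(default_factory=list)  # trained bundle per fold

    def __str__(self) -> str:
        return "; ".join(f"{k}: {v}" for k, v in self.reports.items())


def _fit_modality_pipeline(train: OmicsMatrix, feature_mode: str,
                           n_components: int, top_k: int) -> list[FittedTransform]:
    """Train-fitted transform chain for one modality (leakage-free)."""
    steps: list[FittedTransform] = []
    t_mm = minmax_fit(train)
    steps.append(t_mm)
    cur = minmax_apply(t_mm, train)
    if feature_mode == "pca":
        t_pca = pca_fit(cur, n_components=n_components)
        steps.append(t_pca)
        cur = pca_apply(t_pca, cur)
        # rescale PC scores to [0,1] so the sigmoid decoder can match them
        t_mm2 = minmax_fit(cur)
        steps.append(t_mm2)
    elif feature_mode == "variance":
        steps.append(variance_select_fit(cur, k=top_k))
    elif feature_mode != "none":
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    return steps


def _apply_pipeline(steps: list[FittedTransform], m: OmicsMatrix) -> np.ndarray:
    for t in steps:
        if t.kind == "minmax":
            m = minmax_apply(t, m)
        elif t.kind == "variance_select":
            m = variance_select_apply(t, m)
        elif t.kind == "pca":
            m = pca_apply(t, m)
    return m.values


def run_cross_validation(modalities: list[OmicsMatrix], *,
                         integration: str,
                         labels: np.ndarray | None = None,
                         survival: SurvivalTable | None = None,
                         feature_mode: str = "pca",
                         n_components: int = 100,
                         top_k: int = 1000,
                         latent_dim: int | None = None,
                         config: TrainConfig | None = None,
                         n_folds: int = 4,
                         seed: int = 0) -> CVResult:
    """Stratified n-fold pipeline: fit transforms on train, train the model,
    pick the best-validation checkpoint, report test metrics mean ± std.

    Stratification uses the class label for classification and the event
    indicator for survival; checkpoint selection only ever sees the
    validation split.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    ids0 = modalities[0].sample_ids
    for m in modalities[1:]:
        if m.sample_ids != ids0:
            raise ValueError(f"sample IDs of modality {m.modality_name!r} "
                             "do not match the first modality")
    endpoint = "classification" if labels is not None else "survival"
    if endpoint == "survival" and survival is None:
        raise ValueError("provide labels or a survival table")
    config = config or TrainConfig(endpoint=endpoint)
    if config.endpoint != endpoint:
        config = replace(config, endpoint=endpoint)

    strata = labels if endpoint == "classification" else survival.event
    folds = stratified_folds(strata, n_folds=n_folds, seed=seed)

    metric_names = (["accuracy", "weighted_precision", "weighted_recall"]
                    if endpoint == "classification" else ["c_index"])
    fold_values: dict[str, list[float]] = {m: [] for m in metric_names}
    detail_rows, dist_rows, bundles = [], [], []

    for fold in folds:
        pipelines = [_fit_modality_pipeline(m.subset_samples(fold.train_idx),
                                            feature_mode, n_components, top_k)
                     for m in modalities]
        split_xs = {name: [] for name in ("train", "val", "test")}
        for m, steps in zip(modalities, pipelines):
            for name, idx in (("train", fold.train_idx), ("val", fold.val_idx),
                              ("test", fold.test_idx)):
                split_xs[name].append(_apply_pipeline(steps, m.subset_samples(idx)))

        def make_task(name, idx):
            if endpoint == "classification":
                return TaskData(split_xs[name], labels=np.asarray(labels)[idx])
            return TaskData(split_xs[name], time=survival.time[idx],
                            event=survival.event[idx])

        train_data = make_task("train", fold.train_idx)
        val_data = make_task("val", fold.val_idx)
        test_data = make_task("test", fold.test_idx)

        specs = []
        for x, m in zip(split_xs["train"], modalities):
            d_in = x.shape[1]
            ld = latent_dim or default_latent_dim(d_in)
            specs.append(NetworkSpec(
                input_dim=d_in, latent_dim=ld,
                head="classifier" if endpoint == "classification" else "survival",
                n_classes=int(np.max(labels) + 1) if endpoint == "classification" else 0))
        mode = integration
        fold_seed = config.seed + 7919 * fold.fold_index
        bundle = build_bundle(specs, mode, seed=fold_seed,
                              modality_names=[m.modality_name for m in modalities])
        fold_cfg = replace(config, seed=fold_seed)
        if mode == "cross":
            result = train_cross(bundle, train_data, fold_cfg, val=val_data)
        elif mode == "concat":
            result = train_concat(bundle, train_data, fold_cfg, val=val_data)
        else:
            result = train_single(bundle, train_data, fold_cfg, val=val_data)

        if endpoint == "classification":
            pred = predict_labels(result.bundle, test_data.xs)
            acc, prec, rec = classification_metrics(pred, test_data.labels)
            vals = {"accuracy": acc, "weighted_precision": prec,
                    "weighted_recall": rec}
        else:
            h = predict_hazard(result.bundle, test_data.xs)
            vals = {"c_index": concordance_index(h, test_data.time,
                                                 test_data.event)}
        bundles.append(result.bundle)
        for k, v in vals.items():
            fold_values[k].append(v)
        detail_rows.append({"fold": fold.fold_index, **vals,
                            "best_epoch": result.best_epoch,
                            "best_val_metric": result.best_val_metric})

        if len(modalities) >= 2 and mode in ("concat", "cross"):
            zs = [encode(enc, x, spec) for enc, x, spec in
                  zip(result.bundle.encoders, test_data.xs, result.bundle.specs)]
            for a in range(len(zs)):
                for b in range(a + 1, len(zs)):
                    if zs[a].shape[1] != zs[b].shape[1]:
                        continue
                    d, _ = paired_hidden_distance(zs[a], zs[b])
                    pair = (f"{modalities[a].modality_name}+"
                            f"{modalities[b].modality_name}")
                    dist_rows += [{"fold": fold.fold_index, "pair": pair,
                                   "method": mode, "distance": float(v)}
                                  for v in d]

    reports = {name: MetricsReport(name, endpoint, fold_values[name])
               for name in metric_names}
    return CVResult(reports, pd.DataFrame(detail_rows),
                    pd.DataFrame(dist_rows) if dist_rows else None, bundles)
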