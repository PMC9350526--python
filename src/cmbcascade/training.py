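"""Training protocol for both cascade stages.

Adam (initial learning rate 2e-4), up to 500 epochs, batch size 6, early
stopping on validation total loss, five-fold cross-validation, and
per-stage sensitivity-loss weights (coarse lambda=10, fine lambda=1).
Channel widths can be divided by ``width_factor`` so the identical topology
trains at desk scale.

Fine-stage training data are ROI crops: positives centred (with +-4 px
jitter) on ground-truth lesion components, hard negatives centred on
false-positive components of the trained coarse stage, capped at a 1:1
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import cascade as casc
from . import losses, metrics, nets, nn
from .autograd import no_grad
from .phantom import AugmentationPolicy, BinaryMask, ImageSlice, augment

__all__ = ["TrainConfig", "EarlyStopping", "make_folds", "train_stage",
           "build_fine_patches", "crossvalidate", "evaluate_cascade"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (both stages share the recipe)."""

    stage: str = "coarse"                 # {"coarse", "fine"}
    learning_rate: float = 2e-4
    max_epochs: int = 500
    batch_size: int = 6
    early_stopping_patience: int = 25
    n_folds: int = 5
    lambda_sen: float | None = None       # None -> stage default (10 / 1)
    coarse_input_size: tuple = (352, 448)
    roi_size: int = 32
    width_factor: int = 1
    dilation_rates: tuple = (6, 8, 12)
    augment: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.stage not in ("coarse", "fine"):
            raise ValueError("stage must be 'coarse' or 'fine'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def lam(self) -> float:
        if self.lambda_sen is not None:
            return self.lambda_sen
        return losses.LAMBDA_COARSE if self.stage == "coarse" else losses.LAMBDA_FINE


class EarlyStopping:
    """Stop when the monitored value fails to improve for `patience` epochs."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0
        self.best_epoch = -1

    def update(self, value: float, epoch: int) -> bool:
        """Record one epoch; returns True when training should halt."""
        if value < self.best - self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def make_folds(dataset_ids, n_folds: int, seed: int):
    """Seeded shuffled partition into n_folds (train_ids, val_ids) splits."""
    ids = list(dataset_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} items, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    chunks = np.array_split(order, n_folds)
    folds = []
    for k in range(n_folds):
        val = [ids[i] for i in chunks[k]]
        train = [ids[i] for j, c in enumerate(chunks) if j != k for i in c]
        folds.append((train, val))
    return folds


def _as_batch(pairs, idx):
    imgs = np.stack([np.asarray(pairs[i][0].pixels if isinstance(pairs[i][0], ImageSlice)
                                else pairs[i][0], dtype=np.float32) for i in idx])
    masks = np.stack([np.asarray(pairs[i][1].labels if isinstance(pairs[i][1], BinaryMask)
                                 else pairs[i][1], dtype=np.float32) for i in idx])
    return imgs[:, None], masks[:, None]


def _build_model(config: TrainConfig, seed: int):
    if config.stage == "coarse":
        return nets.build_coarse_net(width_factor=config.width_factor, seed=seed)
    return nets.build_fine_net(width_factor=config.width_factor,
                               dilation_rates=config.dilation_rates, seed=seed)


def _epoch_losses(model, pairs, lam):
    """Mean loss components over a dataset in eval mode (no grad use)."""
    model.eval()
    tot = np.zeros(4)
    for i in range(len(pairs)):
        x, y = _as_batch(pairs, [i])
        with no_grad():
            p = model(x)
        lb = losses.bce_loss(p, y).item()
        ld = losses.dice_loss(p, y).item()
        ls = losses.sen_loss(p, y).item()
        tot += (lb, ld, ls, lb + ld + lam * ls)
    model.train()
    return tot / len(pairs)


def train_stage(train_pairs, config: TrainConfig, val_pairs=None, model=None,
                log_csv=None):
    """Train one stage; returns (model, history DataFrame).

    ``train_pairs`` are (image, mask) pairs: whole slices for the coarse
    stage, ROI patches for the fine stage (see build_fine_patches).  The
    model with the best validation total loss is returned (training loss is
    monitored when no validation set is given).
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = _build_model(config, seed=int(rng.integers(2**31)))
    lam = config.lam
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    stopper = EarlyStopping(config.early_stopping_patience)
    policy = AugmentationPolicy(seed=config.seed) if config.augment else None

    best_state = model.state_dict()
    best_val = np.inf
    history = []
    n = len(train_pairs)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_bce = epoch_dice = epoch_sen = epoch_tot = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_pairs[i] for i in idx]
            if policy is not None:
                batch = [augment(ImageSlice(np.asarray(im.pixels if isinstance(im, ImageSlice) else im)),
                                 BinaryMask(np.asarray(mk.labels if isinstance(mk, BinaryMask) else mk)),
                                 policy, rng=rng)
                         for im, mk in batch]
            x, y = _as_batch(batch, range(len(batch)))
            p = model(x)
            lb = losses.bce_loss(p, y)
            ld = losses.dice_loss(p, y)
            ls = losses.sen_loss(p, y)
            loss = lb + ld + lam * ls
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_bce += lb.item(); epoch_dice += ld.item()
            epoch_sen += ls.item(); epoch_tot += loss.item()
            n_batches += 1
        row = {"epoch": epoch,
               "l_bce": epoch_bce / n_batches, "l_dice": epoch_dice / n_batches,
               "l_sen": epoch_sen / n_batches, "l_total": epoch_tot / n_batches}
        if val_pairs:
            vb, vd, vs, vt = _epoch_losses(model, val_pairs, lam)
            row.update({"val_l_bce": vb, "val_l_dice": vd, "val_l_sen": vs,
                        "val_l_total": vt})
            vsen, vdsc = _val_seg_quality(model, val_pairs)
            row.update({"val_sen": vsen, "val_dsc": vdsc})
            monitored = vt
        else:
            monitored = row["l_total"]
        history.append(row)
        if monitored < best_val:
            best_val = monitored
            best_state = model.state_dict()
        if stopper.update(monitored, epoch):
            break
    model.load_state_dict(best_state)
    hist = pd.DataFrame(history)
    if log_csv is not None:
        hist.to_csv(log_csv, index=False)
    return model, hist


def _val_seg_quality(model, pairs, threshold: float = 0.5):
    """Mean per-image SEN and DSC of the thresholded direct prediction."""
    model.eval()
    sens, dscs = [], []
    for img, mask in pairs:
        x, y = _as_batch([(img, mask)], [0])
        with no_grad():
            p = model(x).data[0, 0]
        pm = metrics.pixel_metrics(metrics.confusion(
            (p >= threshold).astype(np.uint8),
            np.asarray(y[0, 0], dtype=np.uint8)))
        sens.append(pm["sen"]); dscs.append(pm["dsc"])
    model.train()
    return float(np.mean(sens)), float(np.mean(dscs))


def build_fine_patches(pairs, config: TrainConfig, coarse_model=None):
    """ROI training set for the fine stage.

    Positives: windows centred on ground-truth components with +-4 px jitter.
    Negatives: windows centred on coarse-stage false-positive components
    (requires ``coarse_model``), capped at one negative per positive.
    """
    rng = np.random.default_rng(config.seed + 1)
    size = config.roi_size
    positives, negatives = [], []
    for img, mask in pairs:
        px = img.pixels if isinstance(img, ImageSlice) else np.asarray(img)
        lab = mask.labels if isinstance(mask, BinaryMask) else np.asarray(mask)
        truth_comps = casc.extract_components(lab)
        for comp in truth_comps:
            jitter = rng.integers(-4, 5, size=2)
            cy = comp.centroid[0] + jitter[0]
            cx = comp.centroid[1] + jitter[1]
            jcomp = replace(comp, centroid=(float(cy), float(cx)))
            roi = casc.crop_roi(px, jcomp, size)
            win = roi.window
            positives.append((roi.image_crop, lab[win].copy()))
        if coarse_model is not None:
            coarse_model.eval()
            prob = casc._predict(coarse_model, px)
            if hasattr(coarse_model, "train"):
                coarse_model.train()
            pred_comps = casc.extract_components(binarize_arr(prob))
            for comp in pred_comps:
                if lab[comp.pixel_rows, comp.pixel_cols].any():
                    continue  # overlaps truth: not a false positive
                roi = casc.crop_roi(px, comp, size)
                negatives.append((roi.image_crop, lab[roi.window].copy()))
    rng.shuffle(negatives)
    negatives = negatives[:len(positives)]
    patches = positives + negatives
    order = rng.permutation(len(patches))
    return [(ImageSlice(patches[i][0]), BinaryMask(patches[i][1])) for i in order]


def binarize_arr(prob, threshold: float = 0.5):
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def evaluate_cascade(pairs, coarse_model, fine_model, cconfig=None):
    """Run the full cascade on (image, mask) pairs; per-image metric table."""
    cconfig = cconfig or casc.CascadeConfig()
    coarse_model.eval(); fine_model.eval()
    preds, truths, probs = [], [], []
    for img, mask in pairs:
        final, fused, _ = casc.run_cascade(img, coarse_model, fine_model, cconfig)
        preds.append(final.labels)
        probs.append(fused)
        truths.append(mask.labels if isinstance(mask, BinaryMask) else np.asarray(mask))
    per_image = metrics.evaluate_pairs(preds, truths)
    return per_image, preds, probs, truths


def train_cascade(train_pairs, config: TrainConfig, val_pairs=None,
                  coarse_epochs=None, fine_epochs=None):
    """Convenience: train coarse then fine stage; returns both models."""
    ccfg = replace(config, stage="coarse", lambda_sen=None,
                   max_epochs=coarse_epochs or config.max_epochs)
    coarse_model, chist = train_stage(train_pairs, ccfg, val_pairs=val_pairs)
    fcfg = replace(config, stage="fine", lambda_sen=None, seed=config.seed + 1,
                   max_epochs=fine_epochs or config.max_epochs)
    patches = build_fine_patches(train_pairs, fcfg, coarse_model=coarse_model)
    val_patches = build_fine_patches(val_pairs, fcfg) if val_pairs else None
    fine_model, fhist = train_stage(patches, fcfg, val_pairs=val_patches)
    return coarse_model, fine_model, chist, fhist


def crossvalidate(pairs, config: TrainConfig, pipeline: str = "coarse",
                  coarse_epochs=None, fine_epochs=None) -> pd.DataFrame:
    """K-fold cross-validation; one row per fold plus a mean +- SD row.

    Fold rows carry the per-fold mean of each of the six pixel metrics over
    that fold's validation images, with the within-fold SD in ``*_sd``
    columns.  The final row (index "mean") averages the fold means; its
    ``*_sd`` entries are the SD of the fold means.
    """
    folds = make_folds(range(len(pairs)), config.n_folds, config.seed)
    rows = []
    for k, (train_idx, val_idx) in enumerate(folds):
        tr = [pairs[i] for i in train_idx]
        va = [pairs[i] for i in val_idx]
        fold_seed = config.seed + 1000 * (k + 1)
        fcfg = replace(config, seed=fold_seed)
        if pipeline == "cascade":
            cm, fm, _, _ = train_cascade(tr, fcfg, coarse_epochs=coarse_epochs,
                                         fine_epochs=fine_epochs)
            per_image, *_ = evaluate_cascade(va, cm, fm,
                                             casc.CascadeConfig(roi_size=config.roi_size))
        else:
            ccfg = replace(fcfg, stage="coarse",
                           max_epochs=coarse_epochs or config.max_epochs)
            model, _ = train_stage(tr, ccfg)
            model.eval()
            with no_grad():
                preds = [binarize_arr(model(np.asarray(im.pixels if isinstance(im, ImageSlice) else im,
                                                       dtype=np.float32)[None, None]).data[0, 0])
                         for im, _ in va]
            truths = [mk.labels if isinstance(mk, BinaryMask) else np.asarray(mk)
                      for _, mk in va]
            per_image = metrics.evaluate_pairs(preds, truths)
        summ = metrics.summarize(per_image)
        row = {"fold": f"Fold {k + 1}"}
        for m in metrics.METRIC_NAMES:
            row[m] = summ[f"{m}_mean"]
            row[f"{m}_sd"] = summ[f"{m}_sd"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("fold")
    mean_row = {}
    for m in metrics.METRIC_NAMES:
        vals = table[m].to_numpy()
        mean_row[m] = float(vals.mean())
        mean_row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    table.loc["mean"] = mean_row
    return table
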