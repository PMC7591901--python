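"""Cell-based 3D detection network for binding-site centers.

Follows the YOLO-style single-shot detection scheme: a stack of 3x3x3
convolutions with three stride-2 poolings maps a cubic density image to an
8x8x8 grid of cells, each predicting a probability score s_hat that the
cell contains a binding-site center plus the center's fractional position
(x_hat, y_hat, z_hat) within the cell, all squashed through a sigmoid.

Cartesian decoding of a cell (i, j, k):

    X = c_size * v_size * (i + x_hat) + O_x       (and likewise Y, Z)

Training minimizes

    Loss = sum_i (s_i - s_hat_i)^2
         + lambda * sum_i s_i * ||r_i - r_hat_i||^2
         + gamma * L2(conv weights)

where the coordinate term is gated by the binary target score s_i, so only
cells that truly contain a center are penalized for their coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("voxsite")

from . import nn
from .voxelizer import GridSpec, VoxelGrid

N_CELLS_PER_AXIS = 8


# ---------------------------------------------------------------------------
# Configuration and tensors

@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The defaults reproduce the full-size detector: ten conv layers
    (32,32,32,32,32,64,64,64,128,4) with stride-2 pooling after layers
    2, 5 and 8 (1-based), 3x3x3 kernels, lambda=5 coordinate weight,
    gamma=1e-5 L2 weight, Adam with learning rate decaying 1e-3 -> 1e-5
    over 400 epochs, minibatch 16.
    """

    conv_filters: tuple = (32, 32, 32, 32, 32, 64, 64, 64, 128, 4)
    pool_after: tuple = (2, 5, 8)
    kernel: int = 3
    cube_size: int = 64
    n_channels: int = 11
    cell_size: int = 8
    lambda_coord: float = 5.0
    gamma_l2: float = 1e-5
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    epochs: int = 400
    minibatch: int = 16
    augment: bool = True
    seed: int = 0
    score_bias_init: float = -2.5

    def __post_init__(self):
        if self.conv_filters[-1] != 4:
            raise ValueError("last layer must have 4 filters (s, x, y, z)")
        if self.cube_size // (2 ** len(self.pool_after)) != N_CELLS_PER_AXIS:
            raise ValueError(
                f"poolings must reduce cube_size {self.cube_size} to "
                f"{N_CELLS_PER_AXIS} cells per axis")


def toy_config(**overrides) -> ModelConfig:
    """Small CPU-scale profile: 32-voxel cube, four conv layers, two poolings
    (the first on the raw densities, halving the working resolution)."""
    kw = dict(conv_filters=(16, 32, 32, 4), pool_after=(0, 1), cube_size=32,
              epochs=25, lr_start=3e-3, lr_end=3e-4, augment=False)
    kw.update(overrides)
    return ModelConfig(**kw)


@dataclass
class DetectionTensor:
    """Raw 8x8x8x4 network output for one tile (s_hat, x_hat, y_hat, z_hat)."""

    cells: np.ndarray  # (8, 8, 8, 4), all components in (0, 1)
    tile_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        self.tile_origin = np.asarray(self.tile_origin, dtype=float)


@dataclass
class TargetTensor:
    """Ground-truth encoding: binary cell scores + fractional coordinates."""

    s: np.ndarray       # (8, 8, 8) binary
    coords: np.ndarray  # (8, 8, 8, 3), defined only where s == 1

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.float32)


# ---------------------------------------------------------------------------
# Model construction

class DetectionModel:
    """Sequential conv net mapping a density cube to the 8^3 x 4 cell tensor."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers = []
        c_in = config.n_channels
        n_layers = len(config.conv_filters)
        if 0 in config.pool_after:
            # reduced-resolution profile: pool the raw densities first
            layers.append(nn.MaxPool2())
        for i, c_out in enumerate(config.conv_filters, start=1):
            last = i == n_layers
            bias = 0.0
            conv = nn.Conv3D(c_in, c_out, config.kernel, rng, bias_init=bias)
            if last:
                # a low initial score bias keeps the mostly-negative cells
                # from dominating early gradients
                conv.b[0] = config.score_bias_init
            layers.append(conv)
            if not last:
                layers.append(nn.BatchNorm(c_out))
                layers.append(nn.ReLU())
            if i in config.pool_after:
                layers.append(nn.MaxPool2())
            c_in = c_out
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(layers)

    @property
    def n_conv_layers(self) -> int:
        return len(self.net.conv_layers())

    def forward(self, grids: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, cube, cube, cube, C) densities -> (B, 8, 8, 8, 4) predictions."""
        x = np.asarray(grids, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        out = self.net.forward(x, train=train)
        assert out.shape[1:] == (8, 8, 8, 4)
        return out

    def predict_tile(self, grid: VoxelGrid) -> DetectionTensor:
        out = self.forward(grid.values, train=False)[0]
        return DetectionTensor(cells=out, tile_origin=grid.origin)

    def l2(self) -> float:
        return sum(c.l2() for c in self.net.conv_layers())


def build_model(config: ModelConfig | None = None) -> DetectionModel:
    """Construct the detection network (validates the pooling arithmetic)."""
    return DetectionModel(config or ModelConfig())


# ---------------------------------------------------------------------------
# Target encoding / decoding

def encode_targets(sites: Sequence, tile_origin, spec: GridSpec,
                   config: ModelConfig | None = None) -> TargetTensor:
    """Mark cells containing true binding-site centers with s=1 and the
    center's fractional position within the cell.

    Cells are half-open boxes; a center exactly on a boundary belongs to the
    lower-index cell.  When two centers fall in one cell only one can be
    encoded: the site whose ligand has more heavy atoms wins, ties broken by
    lower ligand residue id.
    """
    origin = np.asarray(tile_origin, dtype=float)
    cell_edge = spec.cell_size * spec.voxel_size
    s = np.zeros((8, 8, 8), dtype=np.float32)
    coords = np.zeros((8, 8, 8, 3), dtype=np.float32)
    claimed: dict[tuple, tuple] = {}
    for site in sites:
        rel = (np.asarray(site.center, dtype=float) - origin) / cell_edge
        idx = np.floor(rel).astype(int)
        if np.any(idx < 0) or np.any(idx >= 8):
            continue
        key = tuple(idx)
        n_heavy = len(getattr(site, "ligand", []) or [])
        res_id = (site.ligand[0].residue_id
                  if getattr(site, "ligand", None) else ())
        rank = (-n_heavy, res_id)
        if key in claimed and claimed[key] <= rank:
            continue
        claimed[key] = rank
        s[key] = 1.0
        coords[key] = rel - idx
    return TargetTensor(s=s, coords=coords)


@dataclass
class RawPrediction:
    """Decoded cell output: Cartesian center + probability score."""

    center: np.ndarray
    score: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)


def decode(tensor: DetectionTensor, spec: GridSpec) -> list[RawPrediction]:
    """Decode every cell of one tile to a Cartesian center prediction.

    No thresholding happens here; all 512 cells are returned.
    """
    cells = tensor.cells
    cell_edge = spec.cell_size * spec.voxel_size
    ijk = np.stack(np.meshgrid(*[np.arange(8)] * 3, indexing="ij"), axis=-1)
    centers = cell_edge * (ijk + cells[..., 1:4]) + tensor.tile_origin
    scores = cells[..., 0]
    return [RawPrediction(center=c, score=float(sc))
            for c, sc in zip(centers.reshape(-1, 3), scores.ravel())]


# ---------------------------------------------------------------------------
# Loss

def detection_loss(pred, target: TargetTensor, lambda_coord: float = 5.0,
                   gamma_l2: float = 1e-5,
                   model: DetectionModel | None = None) -> float:
    """The three-term detection loss for one tile (see module docstring)."""
    cells = pred.cells if isinstance(pred, DetectionTensor) else np.asarray(pred)
    score_term = float(np.sum((target.s - cells[..., 0]) ** 2))
    diff = target.coords - cells[..., 1:4]
    coord_term = float(np.sum(target.s[..., None] * diff ** 2))
    l2_term = model.l2() if model is not None else 0.0
    return score_term + lambda_coord * coord_term + gamma_l2 * l2_term


def _loss_and_grad(out: np.ndarray, s: np.ndarray, xyz: np.ndarray,
                   lam: float) -> tuple[float, float, np.ndarray]:
    """Batched data loss and its gradient w.r.t. the sigmoid outputs."""
    ds = out[..., 0] - s
    score_term = float(np.sum(ds ** 2))
    diff = out[..., 1:4] - xyz
    gated = s[..., None] * diff
    coord_term = float(np.sum(gated * diff))
    grad = np.empty_like(out)
    grad[..., 0] = 2.0 * ds
    grad[..., 1:4] = 2.0 * lam * gated
    return score_term, coord_term, grad


# ---------------------------------------------------------------------------
# Training

def train(dataset, config: ModelConfig,
          model: DetectionModel | None = None,
          provider: Callable[[int, np.random.Generator], list] | None = None,
          log_path=None, restarts: int = 0,
          restart_threshold: float = 0.8, restart_check_epoch: int = 12):
    """Train the detector with Adam on (VoxelGrid | array, TargetTensor) pairs.

    ``dataset`` is a sequence of (grid, target) samples; alternatively a
    ``provider(epoch, rng)`` callable may regenerate the samples each epoch
    (used for random-rotation augmentation).  The learning rate decays
    exponentially from lr_start to lr_end over the epoch budget.  Returns
    (model, history) where history is a list of per-epoch dicts.

    The squared-error score term has a poor local optimum where the network
    scores every cell near zero (one positive cell per tile is simply never
    learned, leaving a per-sample score loss ~1).  With ``restarts`` > 0 a
    run whose per-sample score loss exceeds ``restart_threshold`` at
    ``restart_check_epoch`` (or at the end) is abandoned and retrained from
    a deterministically re-derived weight seed, like the multi-start
    strategy of other non-convex fitters.
    """
    if provider is None and not dataset:
        raise ValueError("empty training dataset")
    if model is not None:
        restarts = 0
    for attempt in range(restarts + 1):
        cfg = (config if attempt == 0
               else replace_config_seed(config, config.seed + 7919 * attempt))
        model_a, history = _train_once(
            dataset, cfg, model, provider,
            abort_epoch=(restart_check_epoch if attempt < restarts else None),
            abort_threshold=restart_threshold)
        collapsed = history[-1]["score_loss"] > restart_threshold
        if not collapsed or attempt == restarts:
            break
        logger.warning("training collapsed to the all-background optimum "
                       "(attempt %d); restarting with a new weight seed",
                       attempt + 1)
    if log_path is not None:
        import pandas as pd
        pd.DataFrame(history).to_csv(log_path, index=False)
    return model_a, history


def replace_config_seed(config: ModelConfig, seed: int) -> ModelConfig:
    from dataclasses import replace as _dc_replace
    return _dc_replace(config, seed=int(seed) % (2 ** 31 - 1))


def _train_once(dataset, config: ModelConfig, model, provider,
                abort_epoch: int | None, abort_threshold: float):
    rng = np.random.default_rng(config.seed + 1)
    model = model or build_model(config)
    opt = nn.Adam(model.net.params(), lr=config.lr_start)
    history = []
    for epoch in range(config.epochs):
        if config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            opt.lr = config.lr_start * (config.lr_end / config.lr_start) ** frac
        samples = provider(epoch, rng) if provider is not None else list(dataset)
        order = rng.permutation(len(samples))
        tot_score = tot_coord = 0.0
        for start in range(0, len(order), config.minibatch):
            batch = [samples[i] for i in order[start:start + config.minibatch]]
            grids = np.stack([
                g.values if isinstance(g, VoxelGrid) else np.asarray(g, np.float32)
                for g, _ in batch])
            s = np.stack([t.s for _, t in batch])
            xyz = np.stack([t.coords for _, t in batch])
            out = model.forward(grids, train=True)
            score_term, coord_term, grad = _loss_and_grad(
                out, s, xyz, config.lambda_coord)
            model.net.backward(grad.astype(np.float32))
            for conv in model.net.conv_layers():
                conv.add_l2_grad(config.gamma_l2)
            opt.step()
            tot_score += score_term
            tot_coord += coord_term
        l2 = model.l2()
        rec = {
            "epoch": epoch,
            "lr": opt.lr,
            "score_loss": tot_score / len(samples),
            "coord_loss": config.lambda_coord * tot_coord / len(samples),
            "l2_loss": config.gamma_l2 * l2,
        }
        rec["loss"] = rec["score_loss"] + rec["coord_loss"] + rec["l2_loss"]
        history.append(rec)
        if (abort_epoch is not None and epoch + 1 >= abort_epoch
                and rec["score_loss"] > abort_threshold):
            break  # stuck in the all-background basin; caller may restart
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints

def save_model(model: DetectionModel, path) -> None:
    """Serialize weights + embedded ModelConfig to a .npz checkpoint."""
    arrays = {}
    for i, (p, _) in enumerate(model.net.params()):
        arrays[f"p{i}"] = p
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, nn.BatchNorm):
            arrays[f"bn{i}_mean"] = layer.run_mean
            arrays[f"bn{i}_var"] = layer.run_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> DetectionModel:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    for k in ("conv_filters", "pool_after"):
        cfg_dict[k] = tuple(cfg_dict[k])
    model = build_model(ModelConfig(**cfg_dict))
    for i, (p, _) in enumerate(model.net.params()):
        p[...] = data[f"p{i}"]
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, nn.BatchNorm):
            layer.run_mean[...] = data[f"bn{i}_mean"]
            layer.run_var[...] = data[f"bn{i}_var"]
    return model
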