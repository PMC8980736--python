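"""The three-subnetwork fully connected docking surrogate.

Architecture: the flattened pocket grid (8000) and ligand tensors (6732)
each pass through their own subnetwork — a projection to width d followed
by (n-1) width-d blocks — the two d-vectors are concatenated and fed to a
third subnetwork of the same depth, which ends in two linear heads: 91
energy summary statistics (13 terms x 7 statistics) and one pK. Every
dense layer carries spectral normalization, a bias, LeakyReLU and
dropout; the (n-1) shape-matched layers of each subnetwork add an
identity skip connection. Trainable parameters excluding the pK head
number

    N(n, d) = (3(n-1) + 2) d^2 + (8000 + 6732 + 91 + 3n) d + 91,

which reproduces the reference counts 45,618,267 (n=10, d=1024),
12,055,131 (n=6, d=512) and 4,913,499 (n=6, d=256) exactly; the pK head
adds d + 1.

Training minimizes the mean over examples of the summed squared error
across all 92 outputs with Adam (default learning rate 1e-6) and is
bit-reproducible given the seed.

`DockingSurrogate` / `SurrogateResults` wrap the functional API in the
model/results idiom: the model holds data and configuration, ``fit()``
returns a results object carrying the trained network, loss history and
diagnostics.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import targets as tg
from .ligand import LIGAND_FLAT_SIZE, LigandGraph
from .nn import Adam, SpectralDense, leaky_relu, leaky_relu_grad
from .pocket import PocketGrid

__all__ = [
    "ModelConfig",
    "SurrogateNetwork",
    "TrainingExample",
    "DockingSurrogate",
    "SurrogateResults",
    "build_model",
    "count_parameters",
    "parameter_count_formula",
    "predict",
    "predict_batch",
    "train",
    "split_dataset",
    "evaluate_correlation",
    "CorrelationResult",
    "POCKET_FLAT_SIZE",
    "N_OUTPUTS",
]

POCKET_FLAT_SIZE = 8000
N_OUTPUTS = tg.TARGET_LENGTH  # 92
_N_STATS_OUT = tg.N_TERMS * tg.N_STATS  # 91


@dataclass
class ModelConfig:
    """Hyperparameters of the surrogate and its training loop.

    ``n_blocks`` is the number of dense layers per subnetwork (reference
    settings: 10 or 6), ``hidden`` their width d (2048/1024/512/256).
    The 1e-6 learning rate is the reference default for raw energy
    targets; small synthetic runs use larger rates.
    """

    n_blocks: int = 10
    hidden: int = 1024
    dropout: float = 0.2
    leaky_slope: float = 0.3
    learning_rate: float = 1e-6
    batch_size: int = 64
    epochs: int = 100
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.hidden < 1:
            raise ValueError("n_blocks and hidden must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training hyperparameters")


def parameter_count_formula(n_blocks: int, hidden: int,
                            include_pk_head: bool = False) -> int:
    """Closed-form trainable-parameter count of the canonical wiring."""
    n, d = n_blocks, hidden
    count = (3 * (n - 1) + 2) * d * d \
        + (POCKET_FLAT_SIZE + LIGAND_FLAT_SIZE + _N_STATS_OUT + 3 * n) * d \
        + _N_STATS_OUT
    if include_pk_head:
        count += d + 1
    return count


class SurrogateNetwork:
    """The wired network: two encoders, a predictor, two linear heads."""

    def __init__(self, config: ModelConfig, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        d, n = config.hidden, config.n_blocks
        rng = np.random.default_rng(config.seed)
        mk = lambda i, o: SpectralDense(rng, i, o, dtype)  # noqa: E731
        self.protein_layers = [mk(POCKET_FLAT_SIZE, d)] + \
            [mk(d, d) for _ in range(n - 1)]
        self.ligand_layers = [mk(LIGAND_FLAT_SIZE, d)] + \
            [mk(d, d) for _ in range(n - 1)]
        self.predictor_layers = [mk(2 * d, d)] + \
            [mk(d, d) for _ in range(n - 1)]
        self.head_stats = mk(d, _N_STATS_OUT)
        self.head_pk = mk(d, 1)

    # ------------------------------------------------------------------
    def _all_layers(self) -> list[SpectralDense]:
        return (self.protein_layers + self.ligand_layers
                + self.predictor_layers + [self.head_stats, self.head_pk])

    def subnetworks(self) -> dict[str, list[SpectralDense]]:
        return {"protein": self.protein_layers,
                "ligand": self.ligand_layers,
                "predictor": self.predictor_layers}

    def power_iteration(self) -> None:
        for layer in self._all_layers():
            layer.power_iteration()

    def zero_grad(self) -> None:
        for layer in self._all_layers():
            layer.zero_grad()

    def trainable(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.trainable())
        return out

    # ------------------------------------------------------------------
    def _sub_forward(self, layers, x, rng, caches):
        cfg = self.config
        keep = 1.0 - cfg.dropout
        for k, layer in enumerate(layers):
            h = layer.forward(x)
            a = leaky_relu(h, cfg.leaky_slope)
            mask = None
            if rng is not None and cfg.dropout > 0.0:
                mask = (rng.random(a.shape, dtype=np.float32) >= cfg.dropout)
                mask = mask.astype(self.dtype) / self.dtype(keep)
                a = a * mask
            skip = k > 0  # shape-matched layers get the identity skip
            y = a + x if skip else a
            if caches is not None:
                caches.append((layer, x, h, mask, skip))
            x = y
        return x

    def _sub_backward(self, caches, dy):
        slope = self.config.leaky_slope
        for layer, x, h, mask, skip in reversed(caches):
            da = dy if mask is None else dy * mask
            dh = da * leaky_relu_grad(h, slope)
            dx = layer.backward(x, dh)
            dy = dx + dy if skip else dx
        return dy

    def forward(self, xp, xl, rng=None, cache=None):
        """Forward pass; pass a Generator as ``rng`` to enable dropout."""
        xp = np.ascontiguousarray(xp, dtype=self.dtype)
        xl = np.ascontiguousarray(xl, dtype=self.dtype)
        if xp.ndim != 2 or xp.shape[1] != POCKET_FLAT_SIZE:
            raise ValueError(f"pocket input must be (B, {POCKET_FLAT_SIZE})")
        if xl.ndim != 2 or xl.shape[1] != LIGAND_FLAT_SIZE:
            raise ValueError(f"ligand input must be (B, {LIGAND_FLAT_SIZE})")
        cp = [] if cache is not None else None
        cl = [] if cache is not None else None
        cz = [] if cache is not None else None
        hp = self._sub_forward(self.protein_layers, xp, rng, cp)
        hl = self._sub_forward(self.ligand_layers, xl, rng, cl)
        z = np.concatenate([hp, hl], axis=1)
        hz = self._sub_forward(self.predictor_layers, z, rng, cz)
        stats = self.head_stats.forward(hz)
        pk = self.head_pk.forward(hz)
        out = np.concatenate([stats, pk], axis=1)
        if cache is not None:
            cache.update(protein=cp, ligand=cl, predictor=cz, hz=hz)
        return out

    def backward(self, cache, dy):
        d = self.config.hidden
        hz = cache["hz"]
        dhz = self.head_stats.backward(hz, dy[:, :_N_STATS_OUT])
        dhz = dhz + self.head_pk.backward(hz, dy[:, _N_STATS_OUT:])
        dz = self._sub_backward(cache["predictor"], dhz)
        self._sub_backward(cache["protein"], dz[:, :d])
        self._sub_backward(cache["ligand"], dz[:, d:])

    # ------------------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for k, v in layer.state().items():
                out[f"layer{i:03d}_{k}"] = v
        return out

    def load_state(self, arrays) -> None:
        for i, layer in enumerate(self._all_layers()):
            layer.load_state(
                {k: arrays[f"layer{i:03d}_{k}"]
                 for k in ("W", "b", "u", "v", "sigma")})


def build_model(config: ModelConfig) -> SurrogateNetwork:
    """Build the surrogate with seeded, deterministic initialization."""
    return SurrogateNetwork(config)


def count_parameters(model: SurrogateNetwork,
                     include_pk_head: bool = False) -> int:
    """Trainable weights + biases; spectral-norm u/v vectors excluded."""
    layers = (model.protein_layers + model.ligand_layers
              + model.predictor_layers + [model.head_stats])
    if include_pk_head:
        layers = layers + [model.head_pk]
    return sum(layer.n_parameters() for layer in layers)


# ----------------------------------------------------------------------
@dataclass
class TrainingExample:
    """One (pocket, ligand, targets) triple with its provenance ids."""

    pocket: PocketGrid
    ligand: LigandGraph
    targets: tg.SummaryTargets
    protein_id: str = ""
    complex_id: str = ""

    def target_vector(self) -> np.ndarray:
        vec = self.targets.to_vector()
        if not np.isfinite(vec).all():
            raise ValueError(f"non-finite target for {self.complex_id!r}")
        return vec


def _stack_examples(examples):
    xp = np.stack([ex.pocket.flatten() for ex in examples])
    xl = np.stack([ex.ligand.flatten() for ex in examples])
    y = np.stack([ex.target_vector() for ex in examples]).astype(np.float32)
    return xp, xl, y


def predict_batch(model: SurrogateNetwork, xp, xl,
                  batch_size: int = 256) -> np.ndarray:
    """Deterministic evaluation-mode predictions for stacked inputs."""
    xp = np.asarray(xp, dtype=model.dtype)
    xl = np.asarray(xl, dtype=model.dtype)
    outs = [model.forward(xp[i:i + batch_size], xl[i:i + batch_size])
            for i in range(0, xp.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


def predict(model: SurrogateNetwork, pocket: PocketGrid,
            ligand: LigandGraph) -> tg.SummaryTargets:
    """Evaluation-mode prediction for a single (pocket, ligand) pair."""
    out = predict_batch(model, pocket.flatten()[None, :],
                        ligand.flatten()[None, :])[0]
    if not np.isfinite(out).all():
        raise RuntimeError("model produced non-finite predictions")
    return tg.SummaryTargets.from_vector(out.astype(np.float64))


def _loss_and_grad(pred, y):
    resid = (pred - y).astype(np.float64)
    loss = float(np.mean(np.sum(resid * resid, axis=1)))
    grad = (2.0 / pred.shape[0]) * resid
    return loss, grad.astype(pred.dtype)


def _eval_loss(model, xp, xl, y, batch_size):
    pred = predict_batch(model, xp, xl, batch_size)
    resid = (pred - y).astype(np.float64)
    return float(np.mean(np.sum(resid * resid, axis=1)))


def train(model: SurrogateNetwork, examples, config: ModelConfig | None = None,
          validation=None, verbose: bool = False):
    """Train in place; returns ``(model, history)``.

    ``examples`` is a list of :class:`TrainingExample` or a pre-stacked
    ``(xp, xl, y)`` triple. ``validation`` (same forms) enables per-epoch
    validation loss and early stopping with the configured patience (the
    best-validation-loss parameters are restored). Two runs with the same
    seed produce identical loss histories.
    """
    config = config or model.config
    if isinstance(examples, (list, tuple)) and examples and \
            isinstance(examples[0], TrainingExample):
        xp, xl, y = _stack_examples(examples)
    else:
        xp, xl, y = examples
    if xp.shape[0] < 1:
        raise ValueError("at least one training example required")
    val = None
    if validation is not None:
        if isinstance(validation, (list, tuple)) and validation and \
                isinstance(validation[0], TrainingExample):
            val = _stack_examples(validation)
        else:
            val = validation

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    opt = Adam(model.trainable(), lr=config.learning_rate)
    n = xp.shape[0]
    rows = []
    best_val = math.inf
    best_state = None
    best_epoch = -1
    bad_epochs = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            for layer in model._all_layers():
                layer.power_iteration()
            cache: dict = {}
            pred = model.forward(xp[idx], xl[idx], rng=rng, cache=cache)
            loss, grad = _loss_and_grad(pred, y[idx])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or standardize targets")
            model.zero_grad()
            model.backward(cache, grad)
            opt.step()
            epoch_loss += loss * idx.size
        row = {"epoch": epoch, "train_loss": epoch_loss / n}
        if val is not None:
            vloss = _eval_loss(model, *val, config.batch_size)
            row["val_loss"] = vloss
            if vloss < best_val:
                best_val, best_epoch, bad_epochs = vloss, epoch, 0
                best_state = {k: v.copy()
                              for k, v in model.state().items()}
            else:
                bad_epochs += 1
        rows.append(row)
        if verbose:
            print(f"epoch {epoch:4d}  " +
                  "  ".join(f"{k}={v:.5g}" for k, v in row.items()
                            if k != "epoch"))
        if val is not None and bad_epochs >= config.patience:
            break
    if best_state is not None:
        model.load_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    return model, history


def split_dataset(examples, train_fraction: float = 0.7, seed: int = 0,
                  protein_disjoint: bool = False):
    """Shuffled train/validation split; ``floor(fraction * N)`` train items.

    With ``protein_disjoint`` whole protein-id groups go to one side and
    the sizes approximate the fraction (no protein appears on both
    sides).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if len(examples) < 2:
        raise ValueError("need at least two examples to split")
    rng = np.random.default_rng(seed)
    if not protein_disjoint:
        perm = rng.permutation(len(examples))
        n_train = int(math.floor(train_fraction * len(examples)))
        return ([examples[i] for i in perm[:n_train]],
                [examples[i] for i in perm[n_train:]])
    groups: dict[str, list[int]] = {}
    for i, ex in enumerate(examples):
        groups.setdefault(ex.protein_id, []).append(i)
    names = sorted(groups)
    order = rng.permutation(len(names))
    target = train_fraction * len(examples)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for gi in order:
        members = groups[names[gi]]
        if len(train_idx) + len(members) / 2.0 <= target or not train_idx:
            train_idx.extend(members)
        else:
            val_idx.extend(members)
    if not val_idx:
        raise ValueError(
            "protein-disjoint split needs at least two protein groups")
    return ([examples[i] for i in train_idx],
            [examples[i] for i in val_idx])


@dataclass
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    pvalue: float


def evaluate_correlation(predicted, reference) -> CorrelationResult:
    """Pearson r plus the ordinary-least-squares line through the data."""
    x = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    fit = sps.linregress(x, y)
    return CorrelationResult(float(fit.rvalue), float(fit.slope),
                             float(fit.intercept), float(fit.pvalue))


# ----------------------------------------------------------------------
class DockingSurrogate:
    """Model object: a dataset plus a configuration, ready to ``fit()``.

    Mirrors the model/results split of the statistical-modelling stack:
    the model holds the training examples and hyperparameters; ``fit``
    trains a fresh network and returns a :class:`SurrogateResults`.
    """

    def __init__(self, examples: list[TrainingExample],
                 config: ModelConfig | None = None) -> None:
        if not examples:
            raise ValueError("at least one training example required")
        self.examples = list(examples)
        self.config = config or ModelConfig()

    @classmethod
    def from_dataset(cls, examples, config=None) -> "DockingSurrogate":
        return cls(examples, config)

    @property
    def nobs(self) -> int:
        return len(self.examples)

    def fit(self, validation=None, verbose: bool = False
            ) -> "SurrogateResults":
        """Train a fresh network on the held data.

        ``validation`` may be None, a fraction in (0, 1) carved off with
        the model seed, or an explicit list of examples.
        """
        train_examples = self.examples
        val_examples = None
        if isinstance(validation, float):
            train_examples, val_examples = split_dataset(
                self.examples, 1.0 - validation, seed=self.config.seed)
        elif validation is not None:
            val_examples = list(validation)
        network = build_model(self.config)
        network, history = train(network, train_examples, self.config,
                                 validation=val_examples, verbose=verbose)
        return SurrogateResults(self, network, history,
                                n_train=len(train_examples),
                                n_validation=len(val_examples or ()))


class SurrogateResults:
    """Fit results: the trained network, loss history and diagnostics."""

    def __init__(self, model: DockingSurrogate | None,
                 network: SurrogateNetwork, history: pd.DataFrame,
                 n_train: int = 0, n_validation: int = 0) -> None:
        self.model = model
        self.network = network
        self.config = network.config
        self.history = history
        self.n_train = n_train
        self.n_validation = n_validation

    # -- prediction ----------------------------------------------------
    def predict(self, pocket: PocketGrid,
                ligand: LigandGraph) -> tg.SummaryTargets:
        return predict(self.network, pocket, ligand)

    def predict_batch(self, xp, xl, batch_size: int = 256) -> np.ndarray:
        return predict_batch(self.network, xp, xl, batch_size)

    def predict_pk(self, xp, xl) -> np.ndarray:
        return self.predict_batch(xp, xl)[:, -1]

    def predict_stat(self, xp, xl, term: str = tg.REQUIRED_TERM,
                     stat: str = "min") -> np.ndarray:
        col = (tg.DEFAULT_TERM_NAMES.index(term) * tg.N_STATS
               + tg.STAT_NAMES.index(stat))
        return self.predict_batch(xp, xl)[:, col]

    # -- reporting -----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return count_parameters(self.network, include_pk_head=True)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Docking surrogate fit",
            "=" * 54,
            f"{'subnetwork depth (n_blocks)':36s}{cfg.n_blocks:>18d}",
            f"{'hidden width (d)':36s}{cfg.hidden:>18d}",
            f"{'trainable parameters (with pK head)':36s}"
            f"{self.n_parameters:>18,d}",
            f"{'dropout / LeakyReLU slope':36s}"
            f"{f'{cfg.dropout:g} / {cfg.leaky_slope:g}':>18s}",
            f"{'learning rate (Adam)':36s}{cfg.learning_rate:>18g}",
            f"{'training examples':36s}{self.n_train:>18d}",
            f"{'validation examples':36s}{self.n_validation:>18d}",
            f"{'epochs run':36s}{len(self.history):>18d}",
        ]
        if len(self.history):
            lines.append(f"{'final training loss':36s}"
                         f"{self.history['train_loss'].iloc[-1]:>18.6g}")
            if "val_loss" in self.history:
                best = self.history["val_loss"].min()
                lines.append(f"{'best validation loss':36s}{best:>18.6g}")
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Write weights (npz) plus a JSON sidecar with the config."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.network.state())
        sidecar = {"config": asdict(self.config),
                   "n_train": self.n_train,
                   "n_validation": self.n_validation,
                   "format_version": 1}
        (path / "config.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "SurrogateResults":
        path = Path(path)
        sidecar = json.loads((path / "config.json").read_text())
        config = ModelConfig(**sidecar["config"])
        network = build_model(config)
        with np.load(path / "weights.npz") as arrays:
            network.load_state(arrays)
        return cls(None, network, pd.DataFrame(),
                   n_train=sidecar.get("n_train", 0),
                   n_validation=sidecar.get("n_validation", 0))
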