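"""Differentiable architecture search (DARTS) over windowed residue tensors.

The sixth base predictor does not use a hand-designed network: a small
convolutional cell is *searched*. Every edge (i, j) of a cell DAG carries
a softmax-weighted mixture over a discrete operation space O

    o_bar(x) = sum_o softmax(alpha^(i,j))_o * o(x),

each intermediate node sums the edge outputs of all its predecessors,
and the cell output concatenates the intermediate nodes along channels.
The continuous architecture weights alpha are optimized against
validation loss while the network weights w are optimized against
training loss (first-order alternation); afterwards each edge keeps its
argmax operation and each node its two strongest incoming edges, and the
resulting discrete network is retrained from scratch.

Input is the per-residue 20 x 20 x 3 profile-window tensor; the
classifier head pools over the amino-acid axis only, keeping window
position, and maps to one disorder probability per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, maximum, pad2d, softmax
from .errors import ContractError, DataError, ParameterError
from .layers import Adam, Dense, Module, bce_loss
from .types import PredictionTrack

# ---------------------------------------------------------------------------
# Operation space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperationSpace:
    """Ordered inventory of candidate edge operations."""

    names: tuple = (
        "zero",
        "identity",
        "sep_conv_3",
        "sep_conv_5",
        "dil_conv_3",
        "dil_conv_5",
        "max_pool_3",
        "avg_pool_3",
    )

    def __post_init__(self):
        if not self.names:
            raise ParameterError("operation space must be nonempty")

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_SPACE = OperationSpace()


class _Zero(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x * 0.0


class _Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


class _SepConv(Module):
    """ReLU + depthwise k x k (optionally dilated) + pointwise 1 x 1."""

    def __init__(self, rng, channels: int, k: int, dilation: int = 1):
        super().__init__()
        self.k, self.dilation, self.channels = k, dilation, channels
        scale = 1.0 / np.sqrt(k * k)
        self.Wd = self.param("Wd", rng.uniform(-scale, scale, (channels, k, k)))
        scale_p = 1.0 / np.sqrt(channels)
        self.Wp = self.param("Wp", rng.uniform(-scale_p, scale_p, (channels, channels)))
        self.b = self.param("b", np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        pad = self.dilation * (self.k // 2)
        xp = pad2d(x.relu(), pad)
        out = None
        for ki in range(self.k):
            for kj in range(self.k):
                oi, oj = ki * self.dilation, kj * self.dilation
                view = xp[:, :, oi : oi + H, oj : oj + W]
                w = self.Wd[:, ki, kj].reshape(1, C, 1, 1)
                term = view * w
                out = term if out is None else out + term
        flat = out.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        mixed = flat @ self.Wp + self.b
        return mixed.reshape(B, H, W, C).transpose(0, 3, 1, 2)


class _Pool(Module):
    def __init__(self, mode: str, k: int = 3):
        super().__init__()
        self.mode, self.k = mode, k

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        xp = pad2d(x, self.k // 2)
        views = [
            xp[:, :, i : i + H, j : j + W]
            for i in range(self.k)
            for j in range(self.k)
        ]
        if self.mode == "max":
            out = views[0]
            for v in views[1:]:
                out = maximum(out, v)
            return out
        out = views[0]
        for v in views[1:]:
            out = out + v
        return out * (1.0 / len(views))


def make_operation(rng, name: str, channels: int) -> Module:
    if name == "zero":
        return _Zero()
    if name == "identity":
        return _Identity()
    if name == "sep_conv_3":
        return _SepConv(rng, channels, 3)
    if name == "sep_conv_5":
        return _SepConv(rng, channels, 5)
    if name == "dil_conv_3":
        return _SepConv(rng, channels, 3, dilation=2)
    if name == "dil_conv_5":
        return _SepConv(rng, channels, 5, dilation=2)
    if name == "max_pool_3":
        return _Pool("max")
    if name == "avg_pool_3":
        return _Pool("avg")
    raise ParameterError(f"unknown operation {name!r}")


def mixed_operation(alpha: np.ndarray, candidate_outputs: list[np.ndarray]) -> np.ndarray:
    """Softmax(alpha)-weighted sum of candidate operation outputs."""
    alpha = np.asarray(alpha, dtype=float)
    if len(candidate_outputs) != alpha.size:
        raise ContractError(
            f"{alpha.size} weights for {len(candidate_outputs)} candidates"
        )
    maps = [np.asarray(c, dtype=float) for c in candidate_outputs]
    shape = maps[0].shape
    for idx, m in enumerate(maps):
        if m.shape != shape:
            raise ContractError(f"candidate {idx} has shape {m.shape}, expected {shape}")
    e = np.exp(alpha - alpha.max())
    w = e / e.sum()
    return sum(wi * m for wi, m in zip(w, maps))


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------

CELL_TYPES = ("normal", "reduction")


def cell_edges(n_nodes: int) -> list[tuple[int, int]]:
    """All DAG edges of a cell with 2 input nodes and n intermediate nodes."""
    return [(i, j) for j in range(2, n_nodes + 2) for i in range(j)]


@dataclass
class ArchitectureEncoding:
    """Continuous mixing weights alpha per cell type and edge."""

    n_nodes: int
    space: OperationSpace
    alphas: dict  # cell_type -> {(i, j): np.ndarray of len |O|}

    def validate(self) -> None:
        for cell_type in CELL_TYPES:
            edges = self.alphas.get(cell_type, {})
            for edge in cell_edges(self.n_nodes):
                vec = np.asarray(edges[edge], dtype=float)
                if vec.shape != (len(self.space),):
                    raise ContractError(f"alpha{edge} has shape {vec.shape}")
                if not np.isfinite(vec).all():
                    raise ContractError(f"alpha{edge} is not finite")

    def edge_weights(self, cell_type: str, edge: tuple[int, int]) -> np.ndarray:
        vec = np.asarray(self.alphas[cell_type][edge], dtype=float)
        e = np.exp(vec - vec.max())
        return e / e.sum()


@dataclass
class DiscreteCell:
    """Argmax-discretized cell: per intermediate node, exactly two incoming
    edges, each carrying one named (non-zero) operation."""

    n_nodes: int
    edges: dict  # node j -> [(source i, op name), (source i, op name)]

    def validate(self, space: OperationSpace) -> None:
        for j in range(2, self.n_nodes + 2):
            incoming = self.edges.get(j, [])
            if len(incoming) != 2:
                raise ContractError(f"node {j} has {len(incoming)} incoming edges, expected 2")
            for i, op in incoming:
                if i >= j:
                    raise ContractError(f"edge ({i}, {j}) is not a DAG edge")
                if op == "zero":
                    raise ContractError(f"edge ({i}, {j}) carries the zero operation")
                if op not in space.names:
                    raise ContractError(f"edge ({i}, {j}) names unknown operation {op!r}")


@dataclass
class SearchConfig:
    n_nodes: int = 2
    channels: int = 4
    layout: tuple = ("normal", "reduction", "normal")
    epochs: int = 4
    batch_size: int = 32
    lr_weights: float = 2e-2
    lr_alpha: float = 5e-2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_nodes", "channels", "batch_size"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.epochs < 0 or self.lr_weights <= 0 or self.lr_alpha <= 0:
            raise ParameterError("epochs must be >= 0 and learning rates positive")


# ---------------------------------------------------------------------------
# Cells and networks
# ---------------------------------------------------------------------------


class _Pointwise(Module):
    def __init__(self, rng, c_in: int, c_out: int):
        super().__init__()
        scale = 1.0 / np.sqrt(c_in)
        self.W = self.param("W", rng.uniform(-scale, scale, (c_in, c_out)))
        self.b = self.param("b", np.zeros(c_out))
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        out = flat @ self.W + self.b
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)


class SearchCell(Module):
    """A cell with mixture operations on every edge (continuous relaxation)."""

    def __init__(self, rng, space: OperationSpace, c_in: int, channels: int,
                 n_nodes: int, reduction: bool):
        super().__init__()
        self.space, self.n_nodes, self.reduction = space, n_nodes, reduction
        self.pre = None
        if c_in != channels:
            self.pre = self.add_child("pre", _Pointwise(rng, c_in, channels))
        self.ops: dict = {}
        for edge in cell_edges(n_nodes):
            for name in space.names:
                op = make_operation(rng, name, channels)
                self.add_child(f"op_{edge[0]}_{edge[1]}_{name}", op)
                self.ops[edge + (name,)] = op

    def __call__(self, s0: Tensor, s1: Tensor, alphas: dict) -> Tensor:
        if self.pre is not None:
            s0, s1 = self.pre(s0), self.pre(s1)
        nodes = [s0, s1]
        for j in range(2, self.n_nodes + 2):
            acc = None
            for i in range(j):
                weights = softmax(alphas[(i, j)], axis=0)
                mixed = None
                for o, name in enumerate(self.space.names):
                    term = weights[o] * self.ops[(i, j, name)](nodes[i])
                    mixed = term if mixed is None else mixed + term
                acc = mixed if acc is None else acc + mixed
            nodes.append(acc)
        out = concat(nodes[2:], axis=1)
        if self.reduction:
            out = out[:, :, ::2, ::2]
        return out


class DiscreteNetCell(Module):
    """A cell instantiated from a discretized genotype."""

    def __init__(self, rng, space: OperationSpace, genotype: DiscreteCell,
                 c_in: int, channels: int, reduction: bool):
        super().__init__()
        genotype.validate(space)
        self.genotype, self.reduction = genotype, reduction
        self.pre = None
        if c_in != channels:
            self.pre = self.add_child("pre", _Pointwise(rng, c_in, channels))
        self.ops: dict = {}
        for j, incoming in genotype.edges.items():
            for idx, (i, name) in enumerate(incoming):
                op = make_operation(rng, name, channels)
                self.add_child(f"op_{i}_{j}_{idx}_{name}", op)
                self.ops[(i, j, idx)] = op

    def __call__(self, s0: Tensor, s1: Tensor) -> Tensor:
        if self.pre is not None:
            s0, s1 = self.pre(s0), self.pre(s1)
        nodes = [s0, s1]
        for j in range(2, self.genotype.n_nodes + 2):
            acc = None
            for idx, (i, _name) in enumerate(self.genotype.edges[j]):
                term = self.ops[(i, j, idx)](nodes[i])
                acc = term if acc is None else acc + term
            nodes.append(acc)
        out = concat(nodes[2:], axis=1)
        if self.reduction:
            out = out[:, :, ::2, ::2]
        return out


def _head_geometry(layout: tuple, n_nodes: int, channels: int,
                   height: int = 20) -> tuple[int, int]:
    h = height
    for cell_type in layout:
        if cell_type == "reduction":
            h = -(-h // 2)
    return n_nodes * channels, h


class _NetworkBase(Module):
    """Shared macro-structure: pointwise stem, cell stack (both inputs of a
    cell are the previous cell's output), and a head that averages over
    the amino-acid axis only before the final linear map."""

    def __init__(self, rng, config: SearchConfig):
        super().__init__()
        self.config = config
        self.stem = self.add_child("stem", _Pointwise(rng, 3, config.channels))
        c_out, h_out = _head_geometry(config.layout, config.n_nodes, config.channels)
        self.head = self.add_child("head", Dense(rng, c_out * h_out, 1))

    def _forward_cells(self, x: Tensor) -> Tensor:
        raise NotImplementedError

    def __call__(self, tensors: np.ndarray) -> Tensor:
        x = np.asarray(tensors, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (20, 20, 3):
            raise ContractError(f"residue tensors must be (L, 20, 20, 3), got {x.shape}")
        t = Tensor(x.transpose(0, 3, 1, 2))  # (B, 3, 20, 20)
        out = self._forward_cells(self.stem(t).relu())
        B, C, H, W = out.shape
        pooled = out.mean(axis=3)  # keep window-position axis
        return self.head(pooled.reshape(B, C * H)).sigmoid().reshape(B)


class SearchNetwork(_NetworkBase):
    def __init__(self, config: SearchConfig, space: OperationSpace, seed: int):
        rng = np.random.default_rng(seed)
        super().__init__(rng, config)
        self.space = space
        self.alpha_params: dict = {ct: {} for ct in CELL_TYPES}
        for ct in CELL_TYPES:
            for edge in cell_edges(config.n_nodes):
                t = Tensor(1e-3 * rng.standard_normal(len(space)), requires_grad=True)
                self.alpha_params[ct][edge] = t
        self.cells = []
        c_in = config.channels
        for k, cell_type in enumerate(config.layout):
            cell = SearchCell(
                rng, space, c_in, config.channels, config.n_nodes,
                reduction=cell_type == "reduction",
            )
            self.add_child(f"cell{k}", cell)
            self.cells.append((cell_type, cell))
            c_in = config.n_nodes * config.channels

    def _forward_cells(self, s: Tensor) -> Tensor:
        for cell_type, cell in self.cells:
            s = cell(s, s, self.alpha_params[cell_type])
        return s

    def weight_parameters(self) -> list[Tensor]:
        return self.parameters()

    def arch_parameters(self) -> list[Tensor]:
        return [
            self.alpha_params[ct][edge]
            for ct in CELL_TYPES
            for edge in cell_edges(self.config.n_nodes)
        ]

    def encoding(self) -> ArchitectureEncoding:
        alphas = {
            ct: {edge: t.data.copy() for edge, t in self.alpha_params[ct].items()}
            for ct in CELL_TYPES
        }
        return ArchitectureEncoding(self.config.n_nodes, self.space, alphas)


class DiscreteNetwork(_NetworkBase):
    def __init__(self, config: SearchConfig, space: OperationSpace,
                 genotypes: dict, seed: int):
        rng = np.random.default_rng(seed)
        super().__init__(rng, config)
        self.space, self.genotypes = space, genotypes
        self.cells = []
        c_in = config.channels
        for k, cell_type in enumerate(config.layout):
            cell = DiscreteNetCell(
                rng, space, genotypes[cell_type], c_in, config.channels,
                reduction=cell_type == "reduction",
            )
            self.add_child(f"cell{k}", cell)
            self.cells.append(cell)
            c_in = config.n_nodes * config.channels

    def _forward_cells(self, s: Tensor) -> Tensor:
        for cell in self.cells:
            s = cell(s, s)
        return s


def cell_forward(s0: np.ndarray, s1: np.ndarray,
                 cell: SearchCell | DiscreteNetCell,
                 alphas: dict | None = None) -> np.ndarray:
    """Evaluate one cell on two input feature maps (numpy in, numpy out)."""
    t0, t1 = Tensor(np.asarray(s0, float)), Tensor(np.asarray(s1, float))
    if isinstance(cell, SearchCell):
        if alphas is None:
            raise ContractError("a continuous cell needs alpha vectors")
        wrapped = {e: Tensor(np.asarray(a, float)) for e, a in alphas.items()}
        return cell(t0, t1, wrapped).data
    return cell(t0, t1).data


# ---------------------------------------------------------------------------
# Search, discretization, retraining
# ---------------------------------------------------------------------------


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def bilevel_search(train_set, validation_set, space: OperationSpace = DEFAULT_SPACE,
                   config: SearchConfig | None = None):
    """First-order alternating search.

    ``train_set`` and ``validation_set`` are (tensors, labels) pairs with
    tensors of shape (N, 20, 20, 3). Architecture weights step against
    validation loss, network weights against training loss. Returns the
    final :class:`ArchitectureEncoding` and the loss history.
    """
    config = config or SearchConfig()
    X_tr, y_tr = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    X_va, y_va = np.asarray(validation_set[0], float), np.asarray(validation_set[1], float)
    if X_tr.shape[0] == 0 or X_va.shape[0] == 0:
        raise DataError("train and validation splits must both be nonempty")

    network = SearchNetwork(config, space, seed=config.seed)
    optim_w = Adam(network.weight_parameters(), lr=config.lr_weights)
    optim_a = Adam(network.arch_parameters(), lr=config.lr_alpha)
    rng = np.random.default_rng(config.seed + 1)
    history = {"train_loss": [], "val_loss": [], "val_epoch": []}

    def full_validation_loss() -> float:
        losses = [
            bce_loss(network(X_va[s : s + config.batch_size]),
                     y_va[s : s + config.batch_size]).item()
            * min(config.batch_size, X_va.shape[0] - s)
            for s in range(0, X_va.shape[0], config.batch_size)
        ]
        return float(np.sum(losses) / X_va.shape[0])

    history["val_epoch"].append(full_validation_loss())
    for _epoch in range(config.epochs):
        val_iter = _batches(X_va.shape[0], config.batch_size, rng)
        val_idx_list = list(val_iter)
        for step, tr_idx in enumerate(_batches(X_tr.shape[0], config.batch_size, rng)):
            va_idx = val_idx_list[step % len(val_idx_list)]
            # architecture step on validation loss
            optim_a.zero_grad()
            optim_w.zero_grad()
            loss_a = bce_loss(network(X_va[va_idx]), y_va[va_idx])
            loss_a.backward()
            optim_a.step()
            # weight step on training loss
            optim_a.zero_grad()
            optim_w.zero_grad()
            loss_w = bce_loss(network(X_tr[tr_idx]), y_tr[tr_idx])
            loss_w.backward()
            optim_w.step()
            history["val_loss"].append(loss_a.item())
            history["train_loss"].append(loss_w.item())
        history["val_epoch"].append(full_validation_loss())

    return network.encoding(), history


def discretize(encoding: ArchitectureEncoding,
               space: OperationSpace = DEFAULT_SPACE) -> dict:
    """Argmax discretization: per edge the strongest non-zero operation,
    per node the two strongest incoming edges; ties break toward the
    lowest operation index / lowest source node."""
    encoding.validate()
    genotypes = {}
    for cell_type in CELL_TYPES:
        edges: dict = {}
        for j in range(2, encoding.n_nodes + 2):
            candidates = []
            for i in range(j):
                weights = encoding.edge_weights(cell_type, (i, j))
                best_op, best_w = None, -np.inf
                for o, name in enumerate(space.names):
                    if name == "zero":
                        continue
                    if weights[o] > best_w + 1e-15:
                        best_op, best_w = name, weights[o]
                candidates.append((i, best_op, best_w))
            candidates.sort(key=lambda t: (-t[2], t[0]))
            edges[j] = [(i, op) for i, op, _w in sorted(candidates[:2])]
        genotype = DiscreteCell(n_nodes=encoding.n_nodes, edges=edges)
        genotype.validate(space)
        genotypes[cell_type] = genotype
    return genotypes


def train_discrete(network: DiscreteNetwork, train_set, epochs: int = 20,
                   batch_size: int = 32, lr: float = 2e-2, seed: int = 0) -> list[float]:
    """Retrain a discretized network from scratch; returns per-epoch loss."""
    X, y = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    if X.shape[0] == 0:
        raise DataError("empty training set")
    optim = Adam(network.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    log = []
    for _epoch in range(epochs):
        losses = []
        for idx in _batches(X.shape[0], batch_size, rng):
            optim.zero_grad()
            loss = bce_loss(network(X[idx]), y[idx])
            loss.backward()
            optim.step()
            losses.append(loss.item())
        log.append(float(np.mean(losses)))
    return log


def darts_predict(network: DiscreteNetwork, tensors: np.ndarray,
                  record_id: str = "prediction", batch_size: int = 64) -> PredictionTrack:
    """Per-residue probabilities from a trained discrete network."""
    tensors = np.asarray(tensors, dtype=float)
    if tensors.ndim != 4 or tensors.shape[1:] != (20, 20, 3):
        raise ContractError(f"expected (L, 20, 20, 3) tensors, got {tensors.shape}")
    probs = np.concatenate([
        network(tensors[start : start + batch_size]).data
        for start in range(0, tensors.shape[0], batch_size)
    ])
    return PredictionTrack(id=record_id, probabilities=np.clip(probs, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Genotype serialization
# ---------------------------------------------------------------------------


def write_genotypes(genotypes: dict, path) -> None:
    with open(path, "w") as fh:
        for cell_type in CELL_TYPES:
            genotype = genotypes[cell_type]
            fh.write(f"[{cell_type}] nodes={genotype.n_nodes}\n")
            for j in sorted(genotype.edges):
                pairs = ", ".join(f"({i}, {op})" for i, op in genotype.edges[j])
                fh.write(f"  node {j} <- {pairs}\n")


def read_genotypes(path) -> dict:
    genotypes: dict = {}
    current, edges, n_nodes = None, {}, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                if current is not None:
                    genotypes[current] = DiscreteCell(n_nodes=n_nodes, edges=edges)
                current = line[1 : line.index("]")]
                n_nodes = int(line.split("nodes=")[1])
                edges = {}
            elif line.startswith("node"):
                head, tail = line.split("<-")
                j = int(head.split()[1])
                pairs = []
                for chunk in tail.split("),"):
                    chunk = chunk.strip().strip("()")
                    i, op = chunk.split(",")
                    pairs.append((int(i), op.strip()))
                edges[j] = pairs
    if current is not None:
        genotypes[current] = DiscreteCell(n_nodes=n_nodes, edges=edges)
    return genotypes
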