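"""Mixture-of-experts permeability models.

One expert per molecular representation (message-passing graph embedding,
2D descriptors, ECFP, MACCS) produces a hidden vector; a gating network over
the concatenated input emits softmax weights; the gated sum feeds a linear
head.  The classifier trains with binary cross-entropy (optionally plus a
distillation term supplied by the caller); the regression variant routes node
states through multi-head self-attention before readout and appends
assay-condition features (pH, temperature) encoded either as bins (ONEHOT) or
as standardized global values (GLOBAL).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat
from .chemdata import Assay, Label, LabeledRecord, MoleculeRecord
from .featurize import FeatureBundle, NodeFeatureSchema, Standardizer, MolGraph
from .nets import (
    AttentionConfig,
    BatchedGraph,
    DMPNNEncoder,
    MLP,
    MPConfig,
    SelfAttentionBlock,
    glorot,
    readout,
)

__all__ = [
    "MacroPPConfig",
    "ConditionEncoding",
    "ModelCheckpoint",
    "MacroPPClassifier",
    "MacroPPRegressor",
    "gate_weights",
    "moe_combine",
    "fit_classifier",
    "fit_regressor",
    "prepare_bundles",
]

_ASSAYS = [a.value for a in Assay]
EXPERT_NAMES = ("graph", "descriptors", "ecfp", "maccs")


@dataclass
class MacroPPConfig:
    mp: MPConfig = field(default_factory=MPConfig)
    experts: tuple[str, ...] = EXPERT_NAMES
    expert_hidden: int = 32
    shared_input: bool = False      # literal reading: every expert sees the full concat
    use_assay_onehot: bool = True
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    l1_node_in: float = 0.0   # sparsity pressure on the encoder input projection
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.experts) < 1:
            raise ValueError("need at least one expert")
        unknown = set(self.experts) - set(EXPERT_NAMES)
        if unknown:
            raise ValueError(f"unknown expert(s): {sorted(unknown)}")


@dataclass
class ConditionEncoding:
    """How pH / temperature assay conditions enter the regression model."""

    mode: str = "GLOBAL"  # GLOBAL (standardized raw values) or ONEHOT (bins) or NONE
    ph_bins: tuple[float, ...] = (6.5, 7.0, 7.6)
    temperature_bins: tuple[float, ...] = (30.0, 40.0)
    ph_default: float = 7.4
    temperature_default: float = 37.0

    def __post_init__(self) -> None:
        if self.mode not in ("GLOBAL", "ONEHOT", "NONE"):
            raise ValueError(f"unknown condition mode {self.mode!r}")

    @property
    def dim(self) -> int:
        if self.mode == "GLOBAL":
            return 3  # ph, temperature, missing indicator
        if self.mode == "ONEHOT":
            return (len(self.ph_bins) + 1) + (len(self.temperature_bins) + 1) + 1
        return 0

    def encode(self, conditions: dict | None) -> np.ndarray:
        if self.mode == "NONE":
            return np.zeros(0)
        missing = conditions is None or ("ph" not in conditions and "temperature" not in conditions)
        cond = conditions or {}
        ph = float(cond.get("ph", self.ph_default))
        temp = float(cond.get("temperature", self.temperature_default))
        if self.mode == "GLOBAL":
            return np.array([ph, temp, 1.0 if missing else 0.0])
        vec = np.zeros(self.dim)
        vec[int(np.searchsorted(self.ph_bins, ph))] = 1.0
        off = len(self.ph_bins) + 1
        vec[off + int(np.searchsorted(self.temperature_bins, temp))] = 1.0
        if missing:
            vec[-1] = 1.0
        return vec


def _assay_onehot(assay: Assay) -> np.ndarray:
    vec = np.zeros(len(_ASSAYS))
    vec[_ASSAYS.index(assay.value)] = 1.0
    return vec


class _BundleCache:
    """Featurize each unique SMILES once; reused across epochs and models."""

    def __init__(self, schema: NodeFeatureSchema | None = None):
        self.schema = schema or NodeFeatureSchema()
        self._cache: dict[str, FeatureBundle] = {}

    def get(self, smiles: str) -> FeatureBundle:
        if smiles not in self._cache:
            self._cache[smiles] = FeatureBundle.from_smiles(smiles, self.schema)
        return self._cache[smiles]


def prepare_bundles(
    records: Sequence[LabeledRecord],
    cache: _BundleCache | None = None,
) -> tuple[list[FeatureBundle], np.ndarray]:
    """Featurize labeled records; returns (bundles, labels). EXCLUDED refused."""
    cache = cache or _BundleCache()
    bundles, labels = [], []
    for lr in records:
        if lr.label is Label.EXCLUDED:
            raise ValueError("EXCLUDED records must be filtered out before training")
        bundles.append(cache.get(lr.record.smiles))
        labels.append(int(lr.label))
    return bundles, np.asarray(labels, dtype=np.float64)


def gate_weights(logits: Tensor) -> Tensor:
    """Softmax gate: probability simplex over experts (rows sum to 1)."""
    return logits.softmax(axis=-1)


def moe_combine(expert_outputs: Sequence[Tensor], gate: Tensor) -> Tensor:
    """o = sum_i g_i * e_i with per-sample gate weights (gate: (b, N))."""
    n = len(expert_outputs)
    if gate.data.shape[-1] != n:
        raise ValueError(f"gate width {gate.data.shape[-1]} != number of experts {n}")
    out = None
    for i, e in enumerate(expert_outputs):
        gi = gate.slice_cols(i, i + 1)
        term = e * gi
        out = term if out is None else out + term
    return out


@dataclass
class ModelCheckpoint:
    """Everything needed to reproduce predictions bit-identically."""

    params: dict[str, np.ndarray]
    schema_json: str
    standardizer: dict
    cond_standardizer: dict | None
    config: dict
    kind: str  # "classifier" | "regressor"
    training_log: list[dict] = field(default_factory=list)

    def save(self, path) -> None:
        # written with a fixed zip timestamp so identical runs are byte-identical
        import zipfile

        meta = json.dumps(
            {
                "schema_json": self.schema_json,
                "standardizer": self.standardizer,
                "cond_standardizer": self.cond_standardizer,
                "config": self.config,
                "kind": self.kind,
                "training_log": self.training_log,
                "param_names": list(self.params.keys()),
            }
        )
        arrays = {f"p_{i}": v for i, v in enumerate(self.params.values())}
        arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            for name, arr in arrays.items():
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.ascontiguousarray(arr))
                zf.writestr(
                    zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0)),
                    buf.getvalue(),
                )

    @classmethod
    def load(cls, path) -> "ModelCheckpoint":
        with np.load(path if str(path).endswith(".npz") else str(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {
                name: z[f"p_{i}"].copy() for i, name in enumerate(meta["param_names"])
            }
        return cls(
            params=params,
            schema_json=meta["schema_json"],
            standardizer=meta["standardizer"],
            cond_standardizer=meta.get("cond_standardizer"),
            config=meta["config"],
            kind=meta["kind"],
            training_log=meta["training_log"],
        )


class _MoECore:
    """Shared parameter bank for classifier and regressor variants."""

    def __init__(
        self,
        rng: np.random.Generator,
        config: MacroPPConfig,
        d_node: int,
        d_edge: int,
        d_desc: int,
        d_global: int,
        attention: AttentionConfig | None = None,
    ):
        self.config = config
        self.d_global = d_global
        h = config.expert_hidden
        self.encoder = DMPNNEncoder(rng, d_node, d_edge, config.mp)
        self.attention = (
            SelfAttentionBlock(rng, config.mp.hidden_dim, attention) if attention else None
        )
        rep_dims = {
            "graph": config.mp.hidden_dim,
            "descriptors": d_desc + d_global,
            "ecfp": 2048,
            "maccs": 167,
        }
        self.rep_dims = rep_dims
        total = sum(rep_dims[e] for e in config.experts)
        self.experts: dict[str, MLP] = {}
        for name in config.experts:
            d_in = total if config.shared_input else rep_dims[name]
            self.experts[name] = MLP(rng, [d_in, h, h])
        self.gate_w = Parameter(glorot(rng, total, len(config.experts)))
        self.gate_b = Parameter(np.zeros(len(config.experts)))
        self.head_w = Parameter(glorot(rng, h, 1))
        self.head_b = Parameter(np.zeros(1))

    def parameters(self) -> list[Parameter]:
        out = self.encoder.parameters()
        if self.attention is not None:
            out += self.attention.parameters()
        for name in self.config.experts:
            out += self.experts[name].parameters()
        out += [self.gate_w, self.gate_b, self.head_w, self.head_b]
        return out

    def named_parameters(self) -> dict[str, Parameter]:
        return {f"param_{i}": p for i, p in enumerate(self.parameters())}

    def _graph_embedding(self, batch: BatchedGraph) -> Tensor:
        x = self.encoder.node_states(batch)
        if self.attention is not None:
            # block-diagonal self-attention: nodes attend within their own molecule
            parts = []
            for gid in range(batch.n_graphs):
                idx = np.flatnonzero(batch.graph_ids == gid)
                from .autodiff import gather_rows

                xi = gather_rows(x, idx)
                parts.append(self.attention(xi))
            x = concat(parts, axis=0)
        return readout(x, batch.graph_ids, batch.n_graphs, self.config.mp.readout)

    def forward(
        self,
        batch: BatchedGraph,
        desc: np.ndarray,
        ecfp: np.ndarray,
        maccs: np.ndarray,
        glob: np.ndarray,
    ) -> Tensor:
        reps: dict[str, Tensor] = {}
        if "graph" in self.config.experts:
            reps["graph"] = self._graph_embedding(batch)
        if "descriptors" in self.config.experts:
            reps["descriptors"] = Tensor(np.concatenate([desc, glob], axis=1))
        if "ecfp" in self.config.experts:
            reps["ecfp"] = Tensor(ecfp)
        if "maccs" in self.config.experts:
            reps["maccs"] = Tensor(maccs)
        ordered = [reps[e] for e in self.config.experts]
        gate_in = concat(ordered, axis=1) if len(ordered) > 1 else ordered[0]
        gate = gate_weights(gate_in @ self.gate_w + self.gate_b)
        expert_in = gate_in if self.config.shared_input else None
        outs = [
            self.experts[name](expert_in if expert_in is not None else reps[name])
            for name in self.config.experts
        ]
        combined = moe_combine(outs, gate)
        return combined @ self.head_w + self.head_b  # (b, 1) raw output


def _record_of(item):
    return item.record if isinstance(item, LabeledRecord) else item


class _Dataset:
    """Featurized arrays for a record list, aligned by position."""

    def __init__(
        self,
        items: Sequence,
        cache: _BundleCache,
        standardizer: Standardizer,
        cond_encoding: ConditionEncoding | None,
        cond_standardizer: Standardizer | None,
        use_assay_onehot: bool,
    ):
        self.graphs: list[MolGraph] = []
        desc, ecfp, maccs, glob = [], [], [], []
        for item in items:
            rec = _record_of(item)
            b = cache.get(rec.smiles)
            self.graphs.append(b.graph)
            desc.append(b.descriptors)
            ecfp.append(b.ecfp)
            maccs.append(b.maccs)
            g = _assay_onehot(rec.assay) if use_assay_onehot else np.zeros(0)
            if cond_encoding is not None and cond_encoding.dim:
                cv = cond_encoding.encode(rec.conditions)
                if cond_encoding.mode == "GLOBAL" and cond_standardizer is not None:
                    cv = np.concatenate(
                        [cond_standardizer.transform(cv[None, :2])[0], cv[2:]]
                    )
                g = np.concatenate([g, cv])
            glob.append(g)
        self.desc = standardizer.transform(np.asarray(desc))
        self.ecfp = np.asarray(ecfp)
        self.maccs = np.asarray(maccs)
        self.glob = np.asarray(glob).reshape(len(items), -1)

    def __len__(self) -> int:
        return len(self.graphs)

    def slice(self, idx: np.ndarray):
        return (
            BatchedGraph([self.graphs[i] for i in idx]),
            self.desc[idx],
            self.ecfp[idx],
            self.maccs[idx],
            self.glob[idx],
        )


class _ModelBase:
    def __init__(
        self,
        core: _MoECore,
        cache: _BundleCache,
        standardizer: Standardizer,
        config: MacroPPConfig,
        cond_encoding: ConditionEncoding | None = None,
        cond_standardizer: Standardizer | None = None,
    ):
        self.core = core
        self.cache = cache
        self.standardizer = standardizer
        self.config = config
        self.cond_encoding = cond_encoding
        self.cond_standardizer = cond_standardizer
        self.training_log: list[dict] = []

    def _dataset(self, items: Sequence) -> _Dataset:
        return _Dataset(
            items,
            self.cache,
            self.standardizer,
            self.cond_encoding,
            self.cond_standardizer,
            self.config.use_assay_onehot,
        )

    def _forward_values(self, items: Sequence, chunk: int = 256) -> np.ndarray:
        from .autodiff import no_grad

        ds = self._dataset(items)
        out = []
        with no_grad():
            for start in range(0, len(ds), chunk):
                idx = np.arange(start, min(start + chunk, len(ds)))
                z = self.core.forward(*ds.slice(idx))
                out.append(z.data[:, 0])
        return np.concatenate(out) if out else np.zeros(0)

    def to_checkpoint(self, kind: str) -> ModelCheckpoint:
        return ModelCheckpoint(
            params={k: p.data.copy() for k, p in self.core.named_parameters().items()},
            schema_json=self.cache.schema.to_json(),
            standardizer=self.standardizer.to_dict(),
            cond_standardizer=(
                self.cond_standardizer.to_dict() if self.cond_standardizer else None
            ),
            config=_config_dict(self.config, self.cond_encoding),
            kind=kind,
            training_log=self.training_log,
        )

    def _load_params(self, params: dict[str, np.ndarray]) -> None:
        named = self.core.named_parameters()
        if set(named) != set(params):
            raise ValueError("checkpoint parameter names do not match model")
        for k, p in named.items():
            p.data = params[k].copy()


def _config_dict(config: MacroPPConfig, cond: ConditionEncoding | None) -> dict:
    d = asdict(config)
    d["mp"] = asdict(config.mp)
    d["experts"] = list(config.experts)
    if cond is not None:
        c = asdict(cond)
        c["ph_bins"] = list(cond.ph_bins)
        c["temperature_bins"] = list(cond.temperature_bins)
        d["condition_encoding"] = c
    return d


def _config_from_dict(d: dict) -> tuple[MacroPPConfig, ConditionEncoding | None]:
    d = dict(d)
    cond = None
    if "condition_encoding" in d:
        c = dict(d.pop("condition_encoding"))
        c["ph_bins"] = tuple(c["ph_bins"])
        c["temperature_bins"] = tuple(c["temperature_bins"])
        cond = ConditionEncoding(**c)
    mp = MPConfig(**d.pop("mp"))
    cfg = MacroPPConfig(mp=mp, **{k: (tuple(v) if k == "experts" else v) for k, v in d.items()})
    return cfg, cond


class MacroPPClassifier(_ModelBase):
    """Binary permeability classifier (sigmoid over the MoE head logit)."""

    def predict_logits(self, items: Sequence) -> np.ndarray:
        return self._forward_values(items)

    def predict_proba(self, items: Sequence) -> np.ndarray:
        z = self.predict_logits(items)
        return np.where(
            z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z))
        )

    @classmethod
    def from_checkpoint(cls, ckpt: ModelCheckpoint) -> "MacroPPClassifier":
        if ckpt.kind != "classifier":
            raise ValueError(f"checkpoint is a {ckpt.kind}, not a classifier")
        config, _ = _config_from_dict(ckpt.config)
        schema = NodeFeatureSchema.from_json(ckpt.schema_json)
        cache = _BundleCache(schema)
        rng = np.random.default_rng(config.seed)
        core = _MoECore(
            rng, config, schema.dim, _EDGE_DIM, len(_DESC_NAMES), _n_global(config, None)
        )
        model = cls(core, cache, Standardizer.from_dict(ckpt.standardizer), config)
        model._load_params(ckpt.params)
        model.training_log = list(ckpt.training_log)
        return model


class MacroPPRegressor(_ModelBase):
    """Condition-aware -log10(P_app) regressor with node self-attention."""

    def predict(self, items: Sequence) -> np.ndarray:
        return self._forward_values(items)

    @classmethod
    def from_checkpoint(cls, ckpt: ModelCheckpoint) -> "MacroPPRegressor":
        if ckpt.kind != "regressor":
            raise ValueError(f"checkpoint is a {ckpt.kind}, not a regressor")
        config, cond = _config_from_dict(ckpt.config)
        schema = NodeFeatureSchema.from_json(ckpt.schema_json)
        cache = _BundleCache(schema)
        rng = np.random.default_rng(config.seed)
        core = _MoECore(
            rng,
            config,
            schema.dim,
            _EDGE_DIM,
            len(_DESC_NAMES),
            _n_global(config, cond),
            attention=AttentionConfig(n_heads=2, d_k=config.mp.hidden_dim // 2),
        )
        cond_std = (
            Standardizer.from_dict(ckpt.cond_standardizer) if ckpt.cond_standardizer else None
        )
        model = cls(core, cache, Standardizer.from_dict(ckpt.standardizer), config, cond, cond_std)
        model._load_params(ckpt.params)
        model.training_log = list(ckpt.training_log)
        return model


from .featurize import DESCRIPTOR_NAMES as _DESC_NAMES
from .featurize import EDGE_DIM as _EDGE_DIM


def _n_global(config: MacroPPConfig, cond: ConditionEncoding | None) -> int:
    n = len(_ASSAYS) if config.use_assay_onehot else 0
    if cond is not None:
        n += cond.dim
    return n


def _bce_from_logits(z: Tensor, y: np.ndarray) -> Tensor:
    p = z.sigmoid().clip_probs()
    yt = Tensor(y.reshape(-1, 1))
    return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()


def fit_classifier(
    train: Sequence[LabeledRecord],
    val: Sequence[LabeledRecord],
    config: MacroPPConfig | None = None,
    seed: int = 0,
    cache: _BundleCache | None = None,
    teacher_logits: np.ndarray | None = None,
    distill_config=None,
) -> tuple[MacroPPClassifier, ModelCheckpoint]:
    """Train the MoE classifier by Adam on BCE with early stopping.

    If ``teacher_logits`` (aligned with ``train``) and a distillation config
    with lambda > 0 are given, the loss gains the temperature-scaled soft-label
    divergence term.  With lambda = 0 the training trajectory is bit-identical
    to the plain classifier under the same seed.
    """
    config = config or MacroPPConfig()
    if not val:
        raise ValueError("validation set must be non-empty (early stopping)")
    y_train = np.array([int(lr.label) for lr in train], dtype=np.float64)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set contains a single class")
    y_val = np.array([int(lr.label) for lr in val], dtype=np.float64)

    cache = cache or _BundleCache()
    desc_rows = np.asarray([cache.get(lr.record.smiles).descriptors for lr in train])
    standardizer = Standardizer().fit(desc_rows)

    rng = np.random.default_rng(seed)
    schema = cache.schema
    core = _MoECore(
        rng, config, schema.dim, _EDGE_DIM, len(_DESC_NAMES), _n_global(config, None)
    )
    model = MacroPPClassifier(core, cache, standardizer, config)
    ds_train = model._dataset(train)

    use_soft = (
        teacher_logits is not None
        and distill_config is not None
        and distill_config.lam > 0.0
    )
    if use_soft:
        from .distill import soft_probability

        T = distill_config.temperature
        p_teacher = soft_probability(np.asarray(teacher_logits, dtype=np.float64), T)
        p_teacher = np.clip(p_teacher, 1e-7, 1.0 - 1e-7)

    params = core.parameters()
    opt = Adam(params, lr=config.lr)
    n = len(train)
    best_val = np.inf
    best_snapshot = [p.data.copy() for p in params]
    patience_left = config.patience

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z = core.forward(*ds_train.slice(idx))
            loss = _bce_from_logits(z, y_train[idx])
            if use_soft:
                if distill_config.divergence == "MSE_LOGITS":
                    zdiff = z - Tensor(
                        np.asarray(teacher_logits)[idx].reshape(-1, 1)
                    )
                    soft = (zdiff * zdiff).mean()
                else:
                    p_t = p_teacher[idx].reshape(-1, 1)
                    p_s = (z * (1.0 / T)).sigmoid().clip_probs()
                    kl = Tensor(p_t) * (Tensor(np.log(p_t)) - p_s.log()) + Tensor(
                        1.0 - p_t
                    ) * (Tensor(np.log(1.0 - p_t)) - (1.0 - p_s).log())
                    soft = kl.mean()
                    if distill_config.t_squared_scaling:
                        soft = soft * (T * T)
                loss = loss + soft * distill_config.lam
            opt.zero_grad()
            loss.backward()
            opt.step()
            if config.l1_node_in > 0 and not config.mp.test_mode_identity:
                # proximal step: soft-threshold the input projection so unused
                # feature channels are driven to exactly zero
                thr = config.lr * config.l1_node_in
                for w in core.encoder.node_in.weights:
                    w.data = np.sign(w.data) * np.maximum(np.abs(w.data) - thr, 0.0)
            epoch_loss += float(loss.data) * len(idx)
        val_probs = model.predict_proba(val)
        val_bce = float(
            -np.mean(
                y_val * np.log(np.clip(val_probs, 1e-7, 1 - 1e-7))
                + (1 - y_val) * np.log(np.clip(1 - val_probs, 1e-7, 1 - 1e-7))
            )
        )
        model.training_log.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_loss": val_bce}
        )
        if val_bce < best_val - 1e-12:
            best_val = val_bce
            best_snapshot = [p.data.copy() for p in params]
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    for p, snap in zip(params, best_snapshot):
        p.data = snap
    return model, model.to_checkpoint("classifier")


def fit_regressor(
    train: Sequence[MoleculeRecord],
    val: Sequence[MoleculeRecord],
    encoding: ConditionEncoding | None = None,
    config: MacroPPConfig | None = None,
    seed: int = 0,
    cache: _BundleCache | None = None,
) -> tuple[MacroPPRegressor, ModelCheckpoint]:
    """Train the attention-augmented regressor on squared error."""
    import warnings as _warnings

    config = config or MacroPPConfig()
    encoding = encoding or ConditionEncoding()
    if not val:
        raise ValueError("validation set must be non-empty (early stopping)")
    t_train = np.array([_record_of(r).neg_log_papp for r in train], dtype=np.float64)
    t_val = np.array([_record_of(r).neg_log_papp for r in val], dtype=np.float64)
    if not np.isfinite(t_train).all():
        raise ValueError("targets must be finite")
    if np.ptp(t_train) == 0.0:
        _warnings.warn("all training targets equal; R^2 undefined")

    cache = cache or _BundleCache()
    desc_rows = np.asarray([cache.get(_record_of(r).smiles).descriptors for r in train])
    standardizer = Standardizer().fit(desc_rows)
    cond_std = None
    if encoding.mode == "GLOBAL":
        raw = np.asarray(
            [
                [
                    (r.conditions or {}).get("ph", encoding.ph_default)
                    if (r := _record_of(item)) is not None
                    else encoding.ph_default,
                    (r.conditions or {}).get("temperature", encoding.temperature_default),
                ]
                for item in train
            ]
        )
        cond_std = Standardizer().fit(raw)

    rng = np.random.default_rng(seed)
    schema = cache.schema
    core = _MoECore(
        rng,
        config,
        schema.dim,
        _EDGE_DIM,
        len(_DESC_NAMES),
        _n_global(config, encoding),
        attention=AttentionConfig(n_heads=2, d_k=config.mp.hidden_dim // 2),
    )
    model = MacroPPRegressor(core, cache, standardizer, config, encoding, cond_std)
    ds_train = model._dataset(train)

    params = core.parameters()
    opt = Adam(params, lr=config.lr)
    n = len(train)
    best_val = np.inf
    best_snapshot = [p.data.copy() for p in params]
    patience_left = config.patience

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z = core.forward(*ds_train.slice(idx))
            diff = z - Tensor(t_train[idx].reshape(-1, 1))
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        preds = model.predict(val)
        val_mse = float(np.mean((preds - t_val) ** 2))
        model.training_log.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_loss": val_mse}
        )
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_snapshot = [p.data.copy() for p in params]
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    for p, snap in zip(params, best_snapshot):
        p.data = snap
    return model, model.to_checkpoint("regressor")
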