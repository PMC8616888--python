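"""Experiment drivers for the 1D deconvolution benchmark.

Everything needed to reproduce the benchmark end to end: dataset generation,
base/interval/ProbOut training, the noise-response sweep, and the three
failure-mode detection protocols (prediction-error, adversarial, atypical
artifact).  Each driver is a plain function over a ``TrainedModels`` bundle,
fully determined by an :class:`ExperimentConfig` and a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adversarial import AttackConfig, adversarial_perturb, make_adversarial_target
from .baselines import mcdrop_uncertainty
from .intervals import IntervalNetwork, forward_interval, wrap_network
from .metrics import (
    directionality_accuracy,
    empirical_coverage,
    heatmap_change_correlation,
    pwcc,
    uncertainty_score,
)
from .nets import (
    PredictionNetwork,
    ProbOutNetwork,
    make_conv_net,
    make_probout_net,
    train_network,
)
from .synthetic import (
    InverseProblem,
    SampleSet,
    insert_artifact,
    make_dataset,
    make_forward_operator,
    random_block_mask,
    simulate_measurements,
)
from .training import TrainingConfig, select_beta, train_inn

__all__ = [
    "ExperimentConfig",
    "TrainedModels",
    "METHODS",
    "build_problem",
    "train_models",
    "uncertainty_heatmaps",
    "predictions",
    "run_noise_sweep",
    "run_error_detection",
    "run_adv_detection",
    "run_artifact_detection",
    "run_repetitions",
    "evaluate_directionality",
    "evaluate_coverage",
    "write_manifest",
]

METHODS = ("inn", "mcdrop", "probout")


@dataclass
class ExperimentConfig:
    """Full experiment specification; (config, seed) determines every run."""

    # inverse problem
    n: int = 512
    nu: float = 8.0
    noise_mode: str = "none"
    sigma: float = 0.0
    # dataset
    n_total: int = 2000
    split_sizes: tuple[int, int, int] = (1600, 200, 200)
    jump_count_range: tuple[int, int] = (4, 12)
    height_range: tuple[float, float] = (0.0, 1.0)
    # architecture
    n_layers: int = 10
    channels: int = 32
    kernel_size: int = 5
    dropout_rate: float = 0.1
    # training schedules
    base_epochs: int = 100
    inn_epochs: int = 100
    probout_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta: float | None = None  # None -> mean-absolute-error heuristic
    interval_layers: tuple[int, ...] | None = None
    # evaluation
    mcdrop_T: int = 64
    sigma_grid: tuple[float, ...] = (0.0, 0.01, 0.02, 0.05, 0.1)
    methods: tuple[str, ...] = METHODS
    repetitions: int = 3
    # failure-mode protocols
    adv_region_size: int = 50
    adv_depth_factor: float = 1.5
    adv_max_iterations: int = 200
    artifact_length: int = 50
    artifact_amplitude: float = 1.0
    n_protocol_samples: int | None = None  # None -> full test split
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class TrainedModels:
    """Trained model bundle for one (config, seed)."""

    config: ExperimentConfig
    problem: InverseProblem
    data: SampleSet
    base: PredictionNetwork
    inn: IntervalNetwork
    probout: ProbOutNetwork | None
    beta: float
    logs: dict = field(default_factory=dict)


def build_problem(cfg: ExperimentConfig) -> InverseProblem:
    A = make_forward_operator(cfg.n, cfg.nu)
    return InverseProblem(n=cfg.n, nu=cfg.nu, A=A,
                          noise_mode=cfg.noise_mode, sigma=cfg.sigma)


def _as_batch(z: np.ndarray) -> np.ndarray:
    """Dataset rows (N, n) -> conv-net batches (N, 1, n)."""
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[None]
    return z[:, None, :]


def train_models(cfg: ExperimentConfig, seed: int | None = None,
                 methods: tuple[str, ...] | None = None) -> TrainedModels:
    """Generate data and train all requested models from scratch."""
    seed = cfg.seed if seed is None else seed
    methods = cfg.methods if methods is None else methods
    problem = build_problem(cfg)
    data = make_dataset(problem, cfg.n_total, cfg.split_sizes, seed=seed,
                        jump_count_range=cfg.jump_count_range,
                        height_range=cfg.height_range)
    z_tr, x_tr = data.subset("train")
    zb, xb = _as_batch(z_tr), _as_batch(x_tr)
    logs = {}

    base = make_conv_net(n_layers=cfg.n_layers, channels=cfg.channels,
                         kernel_size=cfg.kernel_size,
                         dropout_rate=cfg.dropout_rate, seed=seed)
    logs["base"] = train_network(
        base, zb, xb, epochs=cfg.base_epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=seed,
    )

    beta = cfg.beta if cfg.beta is not None else select_beta(base, zb, xb)
    inn = wrap_network(base, interval_layers=cfg.interval_layers, beta=beta)
    if "inn" in methods:
        tcfg = TrainingConfig(beta=beta, epochs=cfg.inn_epochs,
                              batch_size=cfg.batch_size,
                              learning_rate=cfg.learning_rate, seed=seed,
                              interval_layers=cfg.interval_layers)
        _, logs["inn"] = train_inn(inn, zb, xb, tcfg)

    probout = None
    if "probout" in methods:
        probout = make_probout_net(n_layers=cfg.n_layers,
                                   channels=cfg.channels,
                                   kernel_size=cfg.kernel_size, seed=seed + 1)
        logs["probout"] = train_network(
            probout.net, zb, xb, epochs=cfg.probout_epochs,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            seed=seed + 1, loss="probout",
        )
    return TrainedModels(config=cfg, problem=problem, data=data, base=base,
                         inn=inn, probout=probout, beta=beta, logs=logs)


def uncertainty_heatmaps(models: TrainedModels, method: str, z: np.ndarray,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-sample uncertainty heatmaps for one method; z has shape (N, n)."""
    zb = _as_batch(z)
    if method == "inn":
        lo, hi, _ = forward_interval(models.inn, zb, validate=False)
        return uncertainty_score(lo, hi)[:, 0, :]
    if method == "mcdrop":
        rng = np.random.default_rng(0) if rng is None else rng
        return mcdrop_uncertainty(models.base, zb, T=models.config.mcdrop_T,
                                  seed=rng)[:, 0, :]
    if method == "probout":
        if models.probout is None:
            raise ValueError("ProbOut model was not trained")
        return models.probout.uncertainty(zb)[:, 0, :]
    raise ValueError(f"unknown method {method!r}")


def predictions(models: TrainedModels, method: str, z: np.ndarray) -> np.ndarray:
    zb = _as_batch(z)
    if method == "probout":
        if models.probout is None:
            raise ValueError("ProbOut model was not trained")
        return models.probout.predict(zb)[:, 0, :]
    return models.base.forward(zb)[:, 0, :]


def run_noise_sweep(models: TrainedModels, noise_mode: str = "measurement",
                    sigma_grid=None, methods=None,
                    seed: int = 0) -> pd.DataFrame:
    """Mean test-set uncertainty per method across a noise-level grid.

    Clean test signals are re-measured at each sigma under ``noise_mode``
    and the mean uncertainty heatmap value is recorded; one row per
    (sigma, method).
    """
    cfg = models.config
    sigma_grid = cfg.sigma_grid if sigma_grid is None else sigma_grid
    methods = cfg.methods if methods is None else methods
    sel = models.data.splits == "test"
    x_test = models.data.signals[sel]
    rng = np.random.default_rng(seed)
    rows = []
    for sigma in sigma_grid:
        prob = InverseProblem(n=cfg.n, nu=cfg.nu, A=models.problem.A,
                              noise_mode=noise_mode if sigma > 0 else "none",
                              sigma=float(sigma))
        _, z = simulate_measurements(prob, x_test, rng)
        for method in methods:
            u = uncertainty_heatmaps(models, method, z, rng=rng)
            rows.append(dict(sigma=float(sigma), method=method,
                             mean_uncertainty=float(np.mean(u))))
    return pd.DataFrame(rows)


def run_error_detection(models: TrainedModels, methods=None,
                        seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-sample PWCC between uncertainty and absolute error on the test set.

    Returns the per-sample table and an aggregate with mean, std and the
    count of undefined (constant-argument) samples per method.
    """
    cfg = models.config
    methods = cfg.methods if methods is None else methods
    z_test, x_test = models.data.subset("test")
    rng = np.random.default_rng(seed)
    rows = []
    for method in methods:
        u = uncertainty_heatmaps(models, method, z_test, rng=rng)
        pred = predictions(models, method, z_test)
        for i in range(z_test.shape[0]):
            rows.append(dict(sample=i, method=method,
                             pwcc=pwcc(pred[i], x_test[i], u[i]),
                             mse=float(np.mean((pred[i] - x_test[i]) ** 2))))
    df = pd.DataFrame(rows)
    agg = {}
    for method in methods:
        vals = df.loc[df.method == method, "pwcc"]
        agg[method] = dict(mean=float(vals.mean()), std=float(vals.std()),
                           n_undefined=int(vals.isna().sum()))
    return df, agg


def _protocol_indices(models: TrainedModels, seed: int):
    n_test = int(np.sum(models.data.splits == "test"))
    k = models.config.n_protocol_samples
    if k is None or k >= n_test:
        return np.arange(n_test)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_test, size=k, replace=False))


def run_adv_detection(models: TrainedModels, methods=None,
                      seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Adversarial-artifact detection protocol.

    For each test input z: build an adversarial target by darkening a random
    contiguous region of the reconstruction, attack the base network with
    box-constrained L-BFGS to get z_adv, then correlate the change in each
    method's uncertainty heatmap with the change in the reconstruction.
    """
    cfg = models.config
    methods = cfg.methods if methods is None else methods
    z_test, _ = models.data.subset("test")
    idx = _protocol_indices(models, seed)
    rng = np.random.default_rng(seed)
    z_sel = z_test[idx]
    # inputs z = A x leave [0, 1] slightly (the forward operator is not
    # range-preserving); widen the box to the valid input range
    box = (min(0.0, float(z_sel.min())), max(1.0, float(z_sel.max())))
    atk = AttackConfig(region_size=cfg.adv_region_size,
                       depth_factor=cfg.adv_depth_factor,
                       max_iterations=cfg.adv_max_iterations, box=box,
                       seed=seed)
    x_rec = predictions(models, "inn", z_sel)  # base-network reconstructions
    z_adv = np.empty_like(z_sel)
    for j in range(z_sel.shape[0]):
        mask = random_block_mask(cfg.n, cfg.adv_region_size, rng) > 0
        tar = make_adversarial_target(x_rec[j], mask, cfg.adv_depth_factor)
        z_adv[j] = adversarial_perturb(models.base, z_sel[j], tar, atk)
    change = np.abs(x_rec - models.base.forward(_as_batch(z_adv))[:, 0, :])
    return _change_correlations(models, methods, z_sel, z_adv, change, rng)


def run_artifact_detection(models: TrainedModels, methods=None,
                           seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Atypical (out-of-distribution) artifact detection protocol.

    A contiguous block artifact is added to each clean test signal, the
    measurements are re-simulated, and the change in each method's
    uncertainty heatmap is correlated with the binary insertion mask.
    """
    cfg = models.config
    methods = cfg.methods if methods is None else methods
    idx = _protocol_indices(models, seed)
    sel = models.data.splits == "test"
    z_test = models.data.inputs[sel][idx]
    x_clean = models.data.signals[sel][idx]
    rng = np.random.default_rng(seed)
    masks = np.empty_like(x_clean)
    z_ood = np.empty_like(z_test)
    for j in range(x_clean.shape[0]):
        mask = random_block_mask(cfg.n, cfg.artifact_length, rng)
        x_ood, _ = insert_artifact(x_clean[j], mask, cfg.artifact_amplitude)
        _, z_ood[j] = simulate_measurements(models.problem, x_ood, rng)
        masks[j] = mask
    return _change_correlations(models, methods, z_test, z_ood, masks, rng)


def _change_correlations(models, methods, z_ref, z_pert, change_maps, rng):
    rows = []
    agg = {}
    for method in methods:
        u_ref = uncertainty_heatmaps(models, method, z_ref, rng=rng)
        u_pert = uncertainty_heatmaps(models, method, z_pert, rng=rng)
        vals = []
        for j in range(z_ref.shape[0]):
            r = heatmap_change_correlation(u_ref[j], u_pert[j], change_maps[j])
            rows.append(dict(sample=j, method=method, correlation=r))
            vals.append(r)
        vals = np.asarray(vals, dtype=float)
        finite = vals[np.isfinite(vals)]
        agg[method] = dict(
            mean=float(np.mean(finite)) if finite.size else float("nan"),
            std=float(np.std(finite, ddof=1)) if finite.size > 1 else float("nan"),
            n_excluded=int(np.sum(~np.isfinite(vals))),
        )
    return pd.DataFrame(rows), agg


def evaluate_directionality(models: TrainedModels, n_bins: int = 20,
                            split: str = "test") -> pd.DataFrame:
    """DR-binned directionality accuracy of the INN on a data split."""
    z, x = models.data.subset(split)
    lo, hi, pred = forward_interval(models.inn, _as_batch(z), validate=False)
    return directionality_accuracy(lo[:, 0, :], hi[:, 0, :], pred[:, 0, :],
                                   x, n_bins=n_bins)


def evaluate_coverage(models: TrainedModels, lam: float = 2.0,
                      split: str = "test") -> float:
    """Empirical coverage of intervals enlarged by lam*beta on a split."""
    z, x = models.data.subset(split)
    lo, hi, _ = forward_interval(models.inn, _as_batch(z), validate=False)
    return empirical_coverage(lo[:, 0, :], hi[:, 0, :], x, lam, models.beta)


_PROTOCOLS = {
    "errdetect": run_error_detection,
    "advdetect": run_adv_detection,
    "artdetect": run_artifact_detection,
}


def run_repetitions(cfg: ExperimentConfig, protocol: str,
                    seed: int | None = None,
                    methods=None) -> tuple[pd.DataFrame, dict]:
    """Repeat a detection protocol over independent complete runs.

    Retrains all models ``cfg.repetitions`` times with consecutive seeds,
    runs the protocol each time, and aggregates the per-run means into a
    per-method mean ± standard deviation (the reporting convention for the
    benchmark tables).  Returns (per-run table, aggregate dict).
    """
    if protocol not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    fn = _PROTOCOLS[protocol]
    base_seed = cfg.seed if seed is None else seed
    methods = cfg.methods if methods is None else methods
    rows = []
    for k in range(cfg.repetitions):
        s = base_seed + k
        models = train_models(cfg, seed=s, methods=methods)
        _, agg = fn(models, methods=methods, seed=s)
        for m in methods:
            rows.append(dict(run=k, seed=s, method=m, mean=agg[m]["mean"]))
    df = pd.DataFrame(rows)
    out = {}
    for m in methods:
        vals = df.loc[df.method == m, "mean"].to_numpy(dtype=float)
        out[m] = dict(mean=float(np.nanmean(vals)),
                      std=float(np.nanstd(vals, ddof=1))
                      if len(vals) > 1 else float("nan"),
                      n_runs=int(len(vals)))
    return df, out


def write_manifest(outdir, cfg: ExperimentConfig, seed: int):
    """Record everything needed to re-run an experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = cfg.to_dict()
    blob = json.dumps(d, sort_keys=True).encode()
    manifest = dict(
        config=d,
        seed=int(seed),
        config_hash=hashlib.sha256(blob).hexdigest(),
        versions=dict(numpy=np.__version__, pandas=pd.__version__),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
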