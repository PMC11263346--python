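"""Seeded end-to-end runners for the three simulations.

* Simulation 1 — continual function learning: three architectures
  (context-blind baseline, context-vector network, one-expert-per-cause
  ensemble) learn four polynomials with shared structure in a fully
  blocked curriculum; measures interference, reuse, and the lesion
  factorization of shared vs task-specific knowledge.
* Simulation 2 — schema learning: a feedforward context-vector network
  learns the cafe/bar transition graphs under blocked vs interleaved
  curricula; measures test-phase two-alternative forced-choice accuracy
  and latent-cause cluster purity, optionally sweeping the stickiness
  prior.
* Simulation 3 — event segmentation: a recurrent (GRU) context-vector
  network predicts upcoming frames of a synthetic event-stream corpus;
  inferred latent-cause switches are scored against ground-truth event
  labels (adjusted mutual information) and simulated annotator boundary
  probabilities (scaled point-biserial), with permutation nulls.

Every runner is a pure function of (config, seed): same config + seed
gives a byte-identical results table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lci import (
    SCRPParams,
    LatentCauseRegistry,
    infer_step,
    lc_likelihoods,
    lc_posterior_map,
    scrp_prior,
)
from .metrics import (
    adjusted_mutual_information,
    cluster_purity,
    extract_boundaries,
    permutation_pvalue,
    point_biserial,
    scaled_point_biserial,
)
from .networks import FFNet, GRUNet, SEMEnsemble
from .taskgen import (
    SchemaTask,
    generate_event_corpus,
    make_curriculum,
    make_noisy_cis,
    sample_polynomial_taskset,
    sample_schema_trial,
)

__all__ = [
    "ExperimentConfig",
    "default_config",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "sweep_stickiness",
    "aggregate_runs",
    "save_results",
]


@dataclass
class ExperimentConfig:
    """Everything that determines a run; serialized verbatim with results."""

    simulation: int
    models: tuple = ("baseline", "lcnet", "sem")
    alpha: float = 0.5
    stickiness: float = 1.0
    temperature: float = 1.0
    context_dim: int = 32
    hidden_dim: int = 64
    learning_rate: float = 0.01
    init_scale: float = 1.0
    ctx_init_scale: float | None = None
    context_unit_norm: bool = True
    optimizer: str = "sgd"
    n_runs: int = 10
    seed: int = 0
    task: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["models"] = tuple(d.get("models", ()))
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


def default_config(simulation: int, **overrides) -> ExperimentConfig:
    """Reference configuration per simulation (desk scale).

    Softmax temperatures are set once per simulation from the scale of the
    prediction losses in that task so that learned loss gaps dominate the
    likelihood (see docs/methods.md); learning rates are shared across all
    models within a simulation.
    """
    if simulation == 1:
        cfg = ExperimentConfig(
            simulation=1,
            models=("baseline", "lcnet", "sem"),
            temperature=0.005,
            context_dim=32,
            hidden_dim=64,
            learning_rate=0.01,
            n_runs=10,
            task=dict(
                n_tasks=4, degree=3, coeff_scale=1.0, shared_scale=1.5,
                x_range=[-1.0, 1.0], cis_noise_rate=0.1, obs_per_epoch=500,
                cis_input_gain=1.0, n_test_points=50, criterion_var_frac=0.25,
                criterion_window=20,
            ),
        )
    elif simulation == 2:
        cfg = ExperimentConfig(
            simulation=2,
            models=("lcnet",),
            temperature=0.06,
            context_dim=128,
            context_unit_norm=False,
            ctx_init_scale=2.0,
            hidden_dim=64,
            learning_rate=0.01,
            n_runs=10,
            task=dict(state_dim=32, smoothing_weight=1.0, n_train=400, n_test=20),
        )
    elif simulation == 3:
        cfg = ExperimentConfig(
            simulation=3,
            models=("lcnet_gru",),
            temperature=0.05,
            alpha=10.0,
            stickiness=15.0,
            context_dim=16,
            context_unit_norm=False,
            hidden_dim=32,
            learning_rate=0.05,
            n_runs=6,
            task=dict(
                n_videos=3, n_classes=12, frames_per_video=500, frame_dim=30,
                persistence=0.99, obs_noise=0.1, n_subjects=20, jitter=2,
                n_perm=1000, checkpoint_every=250, n_controls=1,
            ),
        )
    else:
        raise ValueError(f"unknown simulation id {simulation}")
    return cfg.replace(**overrides) if overrides else cfg


def _rngs(seed_key: list[int], n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed_key).spawn(n)]


# ------------------------------------------------------------- Simulation 1

class _PrototypePredictor:
    """Per-LC running-mean prototype of the context-indicative signal.

    Serves as ``predict_fn`` for LC inference over CIS observations: a
    known LC predicts its prototype; the not-yet-created LC predicts the
    uninformative 0.5 vector (the Bayes guess for unseen binary data).
    Prototypes are keyed by the (immutable) context vector bytes.
    """

    def __init__(self, dim: int, fill: float = 0.5):
        self.dim = dim
        self.fill = fill
        self._protos: dict[bytes, tuple[np.ndarray, int]] = {}

    def __call__(self, x_prev, c) -> np.ndarray:
        entry = self._protos.get(np.asarray(c).tobytes())
        if entry is None:
            return np.full(self.dim, self.fill)
        total, n = entry
        return total / n

    def update(self, c, obs) -> None:
        key = np.asarray(c).tobytes()
        total, n = self._protos.get(key, (np.zeros(self.dim), 0))
        self._protos[key] = (total + obs, n + 1)


def _scale_cis(cis: np.ndarray, gain: float = 3.0) -> np.ndarray:
    """Scale a binary CIS to a fixed norm (``gain``/sqrt(2)) for network input.

    The context-blind baseline consumes the CIS directly.  Two constraints:
    the raw 0/1 vector's squared norm (~64 for 128 bits) makes online SGD
    diverge at any learning rate the scalar-input models can use, so it
    must be normalized; but the CIS must remain the *dominant* input
    (gain > 1) — as in the task design, where the cue is 128-dimensional
    against a scalar x — because the ~50% overlap between different tasks'
    binary patterns is what drives the baseline's cross-task interference.
    """
    cis = np.asarray(cis, dtype=float)
    return cis * (gain / np.sqrt(cis.size))


def _infer_eval(predict_fn, registry, params, x_prev, x_curr, temperature):
    """MAP inference without touching the registry (test-time assignment)."""
    if registry.K == 0:
        return 0
    prior = scrp_prior(registry, params)
    lik, _ = lc_likelihoods(predict_fn, registry, x_prev, x_curr, temperature)
    _, map_lc = lc_posterior_map(prior, lik)
    return map_lc


def _run_sim1_once(cfg: ExperimentConfig, run: int) -> pd.DataFrame:
    t = cfg.task
    task_rng, net_rng, lci_rng, stream_rng = _rngs([cfg.seed, run, 1], 4)
    ts = sample_polynomial_taskset(
        n_tasks=t["n_tasks"], degree=t["degree"], coeff_scale=t["coeff_scale"],
        x_range=tuple(t["x_range"]), rng=task_rng, cis_noise_rate=t["cis_noise_rate"],
        shared_scale=t["shared_scale"],
    )
    cis_dim = ts.cis_vectors.shape[1]
    params = SCRPParams(cfg.alpha, cfg.stickiness)
    nets: dict[str, object] = {}
    if "baseline" in cfg.models:
        nets["baseline"] = FFNet(1 + cis_dim, 0, 1, cfg.hidden_dim, "tanh",
                                 cfg.init_scale, net_rng)
    if "lcnet" in cfg.models:
        nets["lcnet"] = FFNet(1, cfg.context_dim, 1, cfg.hidden_dim, "tanh",
                              cfg.init_scale, net_rng, ctx_init_scale=cfg.ctx_init_scale)
        lc_registry = LatentCauseRegistry(cfg.context_dim, lci_rng, unit_norm=True)
        lc_proto = _PrototypePredictor(cis_dim)
    if "sem" in cfg.models:
        sem_init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, run, 2]))
        nets["sem"] = SEMEnsemble(
            lambda rng: FFNet(1, 0, 1, cfg.hidden_dim, "tanh", cfg.init_scale, rng)
        )
        sem_registry = LatentCauseRegistry(cfg.context_dim, lci_rng, unit_norm=True)
        sem_proto = _PrototypePredictor(cis_dim)

    n_obs = t["obs_per_epoch"]
    x_grid = np.linspace(*ts.x_range, t["n_test_points"])
    train_losses: dict[str, list[list[float]]] = {m: [] for m in cfg.models}
    rows = []

    def record(model, measure, value, epoch=-1, poly=-1, obs=-1):
        rows.append((run, model, "blocked", epoch, poly, obs, measure, float(value)))

    for epoch in range(t["n_tasks"]):
        for m in cfg.models:
            train_losses[m].append([])
        for j in range(n_obs):
            x = stream_rng.uniform(*ts.x_range)
            y = ts.task(epoch, x)
            cis_noisy = make_noisy_cis(ts.cis_vectors[epoch], t["cis_noise_rate"], stream_rng)
            if "baseline" in nets:
                loss = nets["baseline"].train_step(
                    np.concatenate([[x], _scale_cis(cis_noisy, t["cis_input_gain"])]), None, [y],
                    cfg.learning_rate,
                )
                train_losses["baseline"][epoch].append(loss)
            if "lcnet" in nets:
                tr = infer_step(lc_proto, lc_registry, params, cis_noisy, cis_noisy,
                                lci_rng, t=epoch * n_obs + j, temperature=cfg.temperature)
                c = lc_registry.context_vectors[tr.map_lc]
                lc_proto.update(c, cis_noisy)
                loss = nets["lcnet"].train_step([x], c, [y], cfg.learning_rate)
                train_losses["lcnet"][epoch].append(loss)
            if "sem" in nets:
                tr = infer_step(sem_proto, sem_registry, params, cis_noisy, cis_noisy,
                                lci_rng, t=epoch * n_obs + j, temperature=cfg.temperature)
                cvec = sem_registry.context_vectors[tr.map_lc]
                sem_proto.update(cvec, cis_noisy)
                expert = nets["sem"].select_or_spawn(tr.map_lc, sem_init_rng)
                loss = expert.train_step([x], None, [y], cfg.learning_rate)
                train_losses["sem"][epoch].append(loss)

        # end-of-epoch test on every polynomial with its clean CIS cue
        for poly in range(t["n_tasks"]):
            y_true = ts.task(poly, x_grid)
            cis = ts.cis_vectors[poly].astype(float)
            if "baseline" in nets:
                preds = np.array([
                    nets["baseline"].forward(np.concatenate([[x], _scale_cis(cis, t["cis_input_gain"])]), None)[0]
                    for x in x_grid
                ])
                record("baseline", "test_mse", np.mean((preds - y_true) ** 2), epoch, poly)
            if "lcnet" in nets:
                k = _infer_eval(lc_proto, lc_registry, params, cis, cis, cfg.temperature)
                c = lc_registry.all_vectors()[k]
                preds = np.array([nets["lcnet"].forward([x], c)[0] for x in x_grid])
                record("lcnet", "test_mse", np.mean((preds - y_true) ** 2), epoch, poly)
            if "sem" in nets:
                k = _infer_eval(sem_proto, sem_registry, params, cis, cis, cfg.temperature)
                if k < len(nets["sem"]):
                    expert = nets["sem"].experts[k]
                else:  # task never seen: a fresh expert, as SEM would spawn one
                    expert = nets["sem"].factory(
                        np.random.default_rng(np.random.SeedSequence([cfg.seed, run, 3, poly]))
                    )
                preds = np.array([expert.forward([x], None)[0] for x in x_grid])
                record("sem", "test_mse", np.mean((preds - y_true) ** 2), epoch, poly)

    # within-epoch learning curves and observations-to-criterion; the
    # criterion is relative (a fixed fraction of the current task's output
    # variance) so that task-amplitude draws do not dominate comparisons
    win, frac = t["criterion_window"], t["criterion_var_frac"]
    for m in cfg.models:
        for epoch in range(t["n_tasks"]):
            losses = np.asarray(train_losses[m][epoch])
            for j, v in enumerate(losses):
                record(m, "train_mse", v, epoch, poly=epoch, obs=j)
            thresh = frac * ts.task(epoch, x_grid).var()
            ma = np.convolve(losses, np.ones(win) / win, mode="valid")
            hit = np.flatnonzero(ma < thresh)
            n_to = (hit[0] + win) if hit.size else n_obs  # censored at epoch length
            record(m, "obs_to_criterion", n_to, epoch, poly=epoch)

    # lesion probe: shared pathway alone vs the generating shared term
    if "lcnet" in nets:
        lesioned = np.array([nets["lcnet"].forward([x], None, lesioned=True)[0]
                             for x in x_grid])
        corr = np.corrcoef(lesioned, ts.shared(x_grid))[0, 1]
        record("lcnet", "lesion_shared_corr", corr, epoch=t["n_tasks"] - 1)
        record("lcnet", "n_lcs", lc_registry.K)
    if "sem" in nets:
        record("sem", "n_lcs", sem_registry.K)

    return pd.DataFrame(
        rows, columns=["run", "model", "condition", "epoch", "poly", "obs",
                       "measure", "value"]
    )


def run_sim1(config: ExperimentConfig) -> pd.DataFrame:
    """Blocked continual learning of polynomials with shared structure."""
    if config.simulation != 1:
        raise ValueError("config.simulation must be 1")
    return pd.concat(
        [_run_sim1_once(config, r) for r in range(config.n_runs)], ignore_index=True
    )


# ------------------------------------------------------------- Simulation 2

def _run_sim2_once(cfg: ExperimentConfig, run: int, condition: str) -> pd.DataFrame:
    t = cfg.task
    cond_key = 0 if condition == "blocked" else 1
    task_rng, net_rng, lci_rng, sched_rng, trial_rng = _rngs([cfg.seed, run, 4, cond_key], 5)
    task = SchemaTask.sample(t["state_dim"], t["smoothing_weight"], task_rng)
    schedule = make_curriculum(condition, t["n_train"], t["n_test"], sched_rng)
    net = FFNet(task.dim, cfg.context_dim, task.dim, cfg.hidden_dim, "tanh",
                cfg.init_scale, net_rng, ctx_init_scale=cfg.ctx_init_scale,
                optimizer=cfg.optimizer)
    registry = LatentCauseRegistry(cfg.context_dim, lci_rng,
                                   unit_norm=cfg.context_unit_norm)
    params = SCRPParams(cfg.alpha, cfg.stickiness)
    predict = lambda xp, c: net.forward(xp, c)  # noqa: E731
    w = task.smoothing_weight

    rows = []
    test_lcs, test_ctx = [], []
    x_prev = None
    last_obs = None
    global_t = 0
    for trial_idx, (phase, context) in enumerate(zip(schedule.phases, schedule.contexts)):
        trial = sample_schema_trial(task, context, trial_rng, prev_obs=last_obs)
        n_correct, n_choice = 0, 0
        for j in range(4):
            x_curr = trial.inputs[j]
            trace = infer_step(
                predict, registry, params,
                np.zeros(task.dim) if x_prev is None else x_prev, x_curr,
                lci_rng, t=global_t,
                inference_enabled=bool(trial.inference_enabled[j]) or registry.prev_lc is None,
                temperature=cfg.temperature,
            )
            c = registry.context_vectors[trace.map_lc]
            if j in (1, 2):  # schema-discriminating 2AFC about the next state
                pred = net.forward(x_curr, c)
                target_obs = trial.inputs[j + 1]
                foil_obs = w * task.state_vectors[trial.foil_ids[j]] + (1 - w) * x_curr
                n_correct += int(
                    np.linalg.norm(pred - target_obs) < np.linalg.norm(pred - foil_obs)
                )
                n_choice += 1
            if phase == "train" and x_prev is not None:
                # test phase gives no feedback, so weights are frozen there
                net.train_step(x_prev, c, x_curr, cfg.learning_rate)
            if phase == "test":
                test_lcs.append(trace.map_lc)
                test_ctx.append(context)
            x_prev = x_curr
            global_t += 1
        last_obs = trial.inputs[-1]
        rows.append((run, "lcnet", condition, trial_idx, phase, "accuracy",
                     n_correct / n_choice))

    df = pd.DataFrame(rows, columns=["run", "model", "condition", "trial", "phase",
                                     "measure", "value"])
    test_acc = df.loc[df.phase == "test", "value"].mean()
    purity = cluster_purity(np.asarray(test_lcs), np.asarray(test_ctx))
    summary = pd.DataFrame(
        [
            (run, "lcnet", condition, -1, "summary", "test_accuracy", test_acc),
            (run, "lcnet", condition, -1, "summary", "test_purity", purity),
            (run, "lcnet", condition, -1, "summary", "n_lcs", float(registry.K)),
        ],
        columns=df.columns,
    )
    return pd.concat([df, summary], ignore_index=True)


def run_sim2(config: ExperimentConfig) -> pd.DataFrame:
    """Blocked vs interleaved schema learning with a sticky-CRP prior."""
    if config.simulation != 2:
        raise ValueError("config.simulation must be 2")
    tables = [
        _run_sim2_once(config, r, cond)
        for cond in ("blocked", "interleaved")
        for r in range(config.n_runs)
    ]
    return pd.concat(tables, ignore_index=True)


def sweep_stickiness(config: ExperimentConfig, values) -> pd.DataFrame:
    """run_sim2 across stickiness values; adds a ``stickiness`` column."""
    tables = []
    for lam in values:
        tab = run_sim2(config.replace(stickiness=float(lam)))
        tab["stickiness"] = float(lam)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


# ------------------------------------------------------------- Simulation 3

def _run_sim3_once(cfg: ExperimentConfig, run: int, corpus, train: bool) -> pd.DataFrame:
    t = cfg.task
    frame_dim = corpus.videos[0].shape[1]
    net_rng, lci_rng, perm_rng = _rngs([cfg.seed, run, 5, int(not train)], 3)
    net = GRUNet(frame_dim, cfg.context_dim, frame_dim, cfg.hidden_dim,
                 cfg.init_scale, net_rng, optimizer=cfg.optimizer)
    registry = LatentCauseRegistry(cfg.context_dim, lci_rng,
                                   unit_norm=cfg.context_unit_norm)
    params = SCRPParams(cfg.alpha, cfg.stickiness)
    model_name = "lcnet_gru" if train else "untrained"

    h_pre = net.init_hidden()
    x_prev = None
    global_t = 0
    lc_seqs = []
    k_over_time = []
    for frames in corpus.videos:
        lc_seq = np.empty(len(frames), dtype=int)
        for i, x_curr in enumerate(frames):
            xp = np.zeros(frame_dim) if x_prev is None else x_prev
            trace = infer_step(
                lambda a, c: net.forward(a, c, h_pre), registry, params,
                xp, x_curr, lci_rng, t=global_t, temperature=cfg.temperature,
            )
            c = registry.context_vectors[trace.map_lc]
            if x_prev is not None:
                if train:
                    net.train_step(x_prev, c, x_curr, h_pre, cfg.learning_rate)
                h_pre = net.step(x_prev, c, h_pre)
            lc_seq[i] = trace.map_lc
            x_prev = x_curr
            global_t += 1
            if global_t % t["checkpoint_every"] == 0:
                k_over_time.append((global_t, registry.K))
        lc_seqs.append(lc_seq)

    labels = np.concatenate(corpus.event_labels)
    full_lc = np.concatenate(lc_seqs)
    probs = np.concatenate(corpus.subject_boundary_prob)
    bounds = np.concatenate([extract_boundaries(s) for s in lc_seqs])

    ami = adjusted_mutual_information(full_lc, labels)
    null = np.array([
        adjusted_mutual_information(perm_rng.permutation(full_lc), labels)
        for _ in range(t["n_perm"])
    ])
    ami_q975 = float(np.percentile(null, 97.5))
    ami_p = float((1 + np.sum(null >= ami)) / (1 + t["n_perm"]))

    rows = [
        (run, model_name, "corpus", -1, "ami", ami),
        (run, model_name, "corpus", -1, "ami_null_q975", ami_q975),
        (run, model_name, "corpus", -1, "ami_pvalue", ami_p),
        (run, model_name, "corpus", -1, "purity", cluster_purity(full_lc, labels)),
        (run, model_name, "corpus", -1, "n_lcs", float(registry.K)),
        (run, model_name, "corpus", -1, "n_boundaries", float(bounds.sum())),
    ]
    try:
        r_pb = point_biserial(bounds, probs)
        spb = scaled_point_biserial(bounds, probs)
        p_pb = permutation_pvalue(r_pb, bounds, probs, point_biserial,
                                  n_perm=t["n_perm"], rng=perm_rng)
        rows += [
            (run, model_name, "corpus", -1, "point_biserial", r_pb),
            (run, model_name, "corpus", -1, "scaled_point_biserial", spb),
            (run, model_name, "corpus", -1, "point_biserial_pvalue", p_pb),
        ]
    except ValueError:  # degenerate segmentation (e.g. a single LC throughout)
        rows.append((run, model_name, "corpus", -1, "point_biserial_pvalue", 1.0))
    for ckpt, K in k_over_time:
        rows.append((run, model_name, "corpus", ckpt, "n_lcs_t", float(K)))
        upto = min(ckpt, len(full_lc))
        rows.append((run, model_name, "corpus", ckpt, "ami_t",
                     adjusted_mutual_information(full_lc[:upto], labels[:upto])))
    return pd.DataFrame(rows, columns=["run", "model", "condition", "checkpoint",
                                       "measure", "value"])


def run_sim3(config: ExperimentConfig) -> pd.DataFrame:
    """Event segmentation of a synthetic persistent-event corpus."""
    if config.simulation != 3:
        raise ValueError("config.simulation must be 3")
    t = config.task
    corpus_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    corpus = generate_event_corpus(
        n_videos=t["n_videos"], n_classes=t["n_classes"],
        frames_per_video=t["frames_per_video"], frame_dim=t["frame_dim"],
        persistence=t["persistence"], obs_noise=t["obs_noise"],
        n_subjects=t["n_subjects"], rng=corpus_rng, jitter=t["jitter"],
    )
    tables = [_run_sim3_once(config, r, corpus, train=True) for r in range(config.n_runs)]
    tables += [
        _run_sim3_once(config, config.n_runs + r, corpus, train=False)
        for r in range(t.get("n_controls", 1))
    ]
    return pd.concat(tables, ignore_index=True)


# ------------------------------------------------------------- aggregation

def aggregate_runs(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean, standard error, and n per design cell across runs.

    All tables must share one column layout (a homogeneous design); cells
    are every column except ``run`` and ``value``.  Output is sorted by
    the group keys, so it is independent of input order.
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    cols = list(tables[0].columns)
    for tab in tables[1:]:
        if list(tab.columns) != cols:
            raise ValueError("heterogeneous designs cannot be aggregated")
    full = pd.concat(tables, ignore_index=True)
    keys = [c for c in cols if c not in ("run", "value")]
    agg = (
        full.groupby(keys, dropna=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
        .sort_values(keys, kind="stable")
        .reset_index(drop=True)
    )
    agg["se"] = agg["sd"] / np.sqrt(agg["n"])
    return agg.drop(columns="sd")


def save_results(outdir, config: ExperimentConfig, table: pd.DataFrame,
                 log: str = "") -> None:
    """Standard results directory: config.yaml, results.csv, summary.json, log.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    table.to_csv(outdir / "results.csv", index=False)
    summary = aggregate_runs([table])
    summary.to_json(outdir / "summary.json", orient="records", indent=2)
    (outdir / "log.txt").write_text(log or "completed\n")
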