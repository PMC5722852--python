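"""Sample-wise MLP percept classifier with Levenberg-Marquardt training.

The network is a feedforward perceptron with two hidden layers of logistic
units (default topology 19-19-5-1).  It is applied *statically* to every
time sample of a trial: each 19-vector of channel values at time t_i is
mapped to an output u(t_i) in (0, 1), and the trial-level decision
statistic is the mean squared output

    y = (1/N) sum_i u(t_i)^2 .

A trial is classified left-oriented when y >= 0.5 and right-oriented when
y < 0.5.  Training minimizes the mean squared error

    mu = (1/K) sum_k (d_k - y_k)^2 ,   d_k = 1 (L) / 0 (R),

by a damped Gauss-Newton (Levenberg-Marquardt) iteration on the flattened
parameter vector, using the analytic Jacobian of each y_k obtained by
backpropagating through the time average and the logistic layers.  The
training is restarted from multiple random initializations and the network
with the smallest mu is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import Trial

LABELS = ("L", "R")

#: Target value d for each percept label (left = 1, right = 0).
TARGET = {"L": 1.0, "R": 0.0}


def logistic(eta: np.ndarray) -> np.ndarray:
    """Logistic activation F(eta) = 1/(1+exp(-eta)) (stable for large |eta|)."""
    return expit(eta)


@dataclass
class MLPParams:
    """Weights and thresholds of the three trainable layers.

    ``w1`` has shape (H0, H1), ``w2`` (H1, H2), ``w3`` (H2,); thresholds
    ``th1`` (H1,), ``th2`` (H2,) and the scalar ``th3``.  The default
    topology is H0 = H1 = 19, H2 = 5, one output unit.
    """

    w1: np.ndarray
    th1: np.ndarray
    w2: np.ndarray
    th2: np.ndarray
    w3: np.ndarray
    th3: float

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.th1 = np.asarray(self.th1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.th2 = np.asarray(self.th2, dtype=float)
        self.w3 = np.asarray(self.w3, dtype=float).reshape(-1)
        h0, h1 = self.w1.shape
        h1b, h2 = self.w2.shape
        if h1 != h1b or self.th1.shape != (h1,) or self.th2.shape != (h2,):
            raise ValueError("inconsistent layer shapes")
        if self.w3.shape != (h2,):
            raise ValueError("output layer must have a single unit")
        for arr in (self.w1, self.th1, self.w2, self.th2, self.w3):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")
        if not np.isfinite(self.th3):
            raise ValueError("parameters must be finite")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return self.w1.shape[0], self.w1.shape[1], self.w2.shape[1]

    @property
    def n_params(self) -> int:
        h0, h1, h2 = self.sizes
        return h0 * h1 + h1 + h1 * h2 + h2 + h2 + 1

    # -- flattened-vector view used by the LM optimizer ------------------

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.w1.ravel(), self.th1, self.w2.ravel(), self.th2, self.w3, [self.th3]]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, sizes: tuple[int, int, int]) -> "MLPParams":
        h0, h1, h2 = sizes
        parts = np.split(
            np.asarray(vec, dtype=float),
            np.cumsum([h0 * h1, h1, h1 * h2, h2, h2]),
        )
        return cls(
            w1=parts[0].reshape(h0, h1),
            th1=parts[1],
            w2=parts[2].reshape(h1, h2),
            th2=parts[3],
            w3=parts[4],
            th3=float(parts[5][0]),
        )

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        sizes: tuple[int, int, int] = (19, 19, 5),
        scale: float = 0.5,
    ) -> "MLPParams":
        """Uniform(-scale, scale) initialization of all parameters."""
        h0, h1, h2 = sizes
        u = lambda *shape: rng.uniform(-scale, scale, size=shape)
        return cls(u(h0, h1), u(h1), u(h1, h2), u(h2), u(h2), float(u()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "sizes": list(self.sizes),
                "w1": self.w1.tolist(),
                "th1": self.th1.tolist(),
                "w2": self.w2.tolist(),
                "th2": self.th2.tolist(),
                "w3": self.w3.tolist(),
                "th3": self.th3,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPParams":
        d = json.loads(text)
        return cls(
            np.array(d["w1"]), np.array(d["th1"]), np.array(d["w2"]),
            np.array(d["th2"]), np.array(d["w3"]), float(d["th3"]),
        )


# -- forward model -------------------------------------------------------


def _forward_batch(
    params: MLPParams, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hidden activations and outputs for a batch of samples (n, H0)."""
    a1 = logistic(x @ params.w1 - params.th1)
    a2 = logistic(a1 @ params.w2 - params.th2)
    u = logistic(a2 @ params.w3 - params.th3)
    return a1, a2, u


def forward_sample(params: MLPParams, x: np.ndarray) -> float:
    """Network output u in (0, 1) for one 19-vector of channel values."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.sizes[0],):
        raise ValueError(f"input must be a {params.sizes[0]}-vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return float(_forward_batch(params, x[None, :])[2][0])


def forward_trial(params: MLPParams, trial: Trial) -> float:
    """Mean squared output y over a trial's time samples."""
    data = np.asarray(trial.data, dtype=float)
    if data.shape[1] < 1:
        raise ValueError("trial must contain at least one sample")
    _, _, u = _forward_batch(params, data.T)
    return float(np.mean(u**2))


def classify(y: float) -> str:
    """Decision rule: y >= 0.5 -> 'L' (boundary inclusive), y < 0.5 -> 'R'."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"decision statistic must be in [0, 1], got {y}")
    return "L" if y >= 0.5 else "R"


def loss(params: MLPParams, trials: list[Trial], targets: np.ndarray) -> float:
    """Mean squared classification error mu = (1/K) sum (d_k - y_k)^2."""
    targets = np.asarray(targets, dtype=float)
    if len(trials) == 0 or len(trials) != len(targets):
        raise ValueError("trials and targets must be non-empty and equal-length")
    y = np.array([forward_trial(params, tr) for tr in trials])
    return float(np.mean((targets - y) ** 2))


# -- Levenberg-Marquardt training ----------------------------------------


@dataclass
class TrainConfig:
    n_restarts: int = 50
    max_iter: int = 100
    lambda_init: float = 1e-3
    tol: float = 1e-9
    seed: int = 0
    sizes: tuple[int, int, int] = (19, 19, 5)
    init_scale: float = 0.5


@dataclass
class RestartResult:
    params: MLPParams
    mu: float
    seed: int
    iterations: int
    converged: bool
    mu_history: list[float] = field(default_factory=list)  # accepted steps


@dataclass
class TrainingResult:
    restarts: list[RestartResult]
    best_index: int


def _stack_trials(trials: list[Trial]) -> np.ndarray:
    """(K, N, P) array of sample vectors; all trials must share N and P."""
    shapes = {tr.data.shape for tr in trials}
    if len(shapes) != 1:
        raise ValueError("all training trials must share channel count and length")
    return np.stack([tr.data.T for tr in trials])  # (K, N, P)


def _y_and_jacobian(
    params: MLPParams, xs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Decision statistics y_k and their Jacobian d y_k / d theta.

    ``xs`` is (K, N, P).  The gradient backpropagates the per-sample
    weight (2/N) u_i through the logistic layers and accumulates it into
    the flattened parameter layout of :meth:`MLPParams.to_vector`.
    """
    k, n, p = xs.shape
    h0, h1, h2 = params.sizes
    flat = xs.reshape(k * n, p)
    a1, a2, u = _forward_batch(params, flat)
    y = np.mean(u.reshape(k, n) ** 2, axis=1)

    # per-sample sensitivity of y to the output unit's pre-activation
    c = (2.0 / n) * (u**2) * (1.0 - u)  # (k*n,)
    cr = c.reshape(k, n)
    a1r, a2r = a1.reshape(k, n, h1), a2.reshape(k, n, h2)

    g_w3 = np.einsum("kni,kn->ki", a2r, cr)
    g_th3 = -cr.sum(axis=1)[:, None]

    d2 = (c[:, None] * params.w3[None, :]) * a2 * (1.0 - a2)  # (k*n, h2)
    d2r = d2.reshape(k, n, h2)
    g_w2 = np.einsum("knp,kni->kpi", a1r, d2r).reshape(k, h1 * h2)
    g_th2 = -d2r.sum(axis=1)

    d1 = (d2 @ params.w2.T) * a1 * (1.0 - a1)  # (k*n, h1)
    d1r = d1.reshape(k, n, h1)
    g_w1 = np.einsum("knp,kni->kpi", xs, d1r).reshape(k, h0 * h1)
    g_th1 = -d1r.sum(axis=1)

    jac = np.concatenate([g_w1, g_th1, g_w2, g_th2, g_w3, g_th3], axis=1)
    return y, jac


def _y_batch(params: MLPParams, xs: np.ndarray) -> np.ndarray:
    k, n, p = xs.shape
    _, _, u = _forward_batch(params, xs.reshape(k * n, p))
    return np.mean(u.reshape(k, n) ** 2, axis=1)


def _lm_single(
    xs: np.ndarray,
    d: np.ndarray,
    init: MLPParams,
    config: TrainConfig,
) -> tuple[MLPParams, float, int, bool, list[float]]:
    """One LM run from one initialization.

    Marquardt-scaled damping: the normal matrix is J'J + lambda*diag(J'J)
    (with a small floor on the diagonal), so the step size adapts to the
    Jacobian's scale.  lambda starts at ``lambda_init``, is divided by 10
    on an accepted step and multiplied by 10 on a rejected one; iteration
    stops when an accepted step improves mu by less than ``tol``, when
    the damping explodes, or at ``max_iter``.  Accepted steps never
    increase mu.
    """
    sizes = init.sizes
    params = init
    k = len(d)
    lam = config.lambda_init
    y, jac_y = _y_and_jacobian(params, xs)
    r = d - y
    mu = float(np.mean(r**2))
    history = [mu]
    converged = False
    iterations = 0

    for iterations in range(1, config.max_iter + 1):
        jac = -jac_y  # residual Jacobian dr/dtheta
        jtj = jac.T @ jac
        jtr = jac.T @ r
        diag = np.diag(jtj).copy()
        floor = max(diag.max(), 1e-300) * 1e-12
        np.clip(diag, floor, None, out=diag)
        accepted = False
        while lam < 1e12:
            try:
                step = np.linalg.solve(
                    jtj + lam * np.diag(diag), -jtr
                )
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand_vec = params.to_vector() + step
            if not np.all(np.isfinite(cand_vec)):
                lam *= 10.0
                continue
            cand = MLPParams.from_vector(cand_vec, sizes)
            y_new = _y_batch(cand, xs)
            mu_new = float(np.mean((d - y_new) ** 2))
            if np.isfinite(mu_new) and mu_new < mu:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True
            break
        improvement = mu - mu_new
        params, mu = cand, mu_new
        history.append(mu)
        lam = max(lam / 10.0, 1e-15)
        y, jac_y = _y_and_jacobian(params, xs)
        r = d - y
        if improvement < config.tol:
            converged = True
            break

    return params, mu, iterations, converged, history


def labels_to_targets(labels) -> np.ndarray:
    """Map percept labels to desired outputs d (L -> 1, R -> 0)."""
    try:
        return np.array([TARGET[l] for l in labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from exc


def train_lm(
    trials: list[Trial],
    targets,
    config: TrainConfig | None = None,
) -> TrainingResult:
    """Multi-restart Levenberg-Marquardt training.

    ``targets`` may be the d_k array (0/1) or the label strings.  Each
    restart draws its initialization from an independent seeded stream;
    non-finite excursions abort the restart (flagged, not fatal) and the
    restart with the smallest final mu becomes ``best_index``.
    """
    config = config or TrainConfig()
    targets = np.asarray(targets)
    if targets.dtype.kind in "US":
        d = labels_to_targets(targets)
    else:
        d = targets.astype(float)
    if len(trials) == 0 or len(trials) != len(d):
        raise ValueError("trials and targets must be non-empty and equal-length")
    if len(np.unique(d)) < 2:
        raise ValueError("training set must contain both classes")

    xs = _stack_trials(trials)
    if xs.shape[2] != config.sizes[0]:
        raise ValueError(
            f"trial channel count {xs.shape[2]} != network input size {config.sizes[0]}"
        )

    restarts = []
    for i in range(config.n_restarts):
        ss = np.random.SeedSequence([int(config.seed), i])
        restart_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(restart_seed)
        init = MLPParams.random(rng, config.sizes, config.init_scale)
        if config.max_iter == 0:
            y0 = _y_batch(init, xs)
            mu0 = float(np.mean((d - y0) ** 2))
            restarts.append(RestartResult(init, mu0, restart_seed, 0, False, [mu0]))
            continue
        try:
            params, mu, iters, conv, hist = _lm_single(xs, d, init, config)
        except FloatingPointError:
            restarts.append(
                RestartResult(init, float("inf"), restart_seed, 0, False, [])
            )
            continue
        restarts.append(RestartResult(params, mu, restart_seed, iters, conv, hist))

    mus = np.array([r.mu for r in restarts])
    return TrainingResult(restarts=restarts, best_index=int(np.argmin(mus)))


def select_best(result: TrainingResult) -> MLPParams:
    """The restart with the smallest mu (ties -> lowest restart index)."""
    if not result.restarts:
        raise ValueError("empty training result")
    return result.restarts[result.best_index].params


# -- evaluation ----------------------------------------------------------


@dataclass
class AccuracyReport:
    rho: float       # percent correct overall
    rho_L: float     # percent correct among L trials
    rho_R: float     # percent correct among R trials
    n_correct: int
    n_total: int
    n_L: int
    n_R: int


def accuracy(params: MLPParams, trials: list[Trial], labels=None) -> AccuracyReport:
    """Recognition accuracy rho = 100 * N_p / N, overall and per class."""
    if labels is None:
        labels = [tr.label for tr in trials]
    labels = list(labels)
    if len(trials) == 0 or len(labels) != len(trials):
        raise ValueError("need a non-empty, label-matched evaluation set")
    preds = [classify(forward_trial(params, tr)) for tr in trials]
    correct = np.array([p == l for p, l in zip(preds, labels)])
    is_l = np.array([l == "L" for l in labels])
    n = len(labels)
    n_l = int(is_l.sum())
    n_r = n - n_l
    rho_l = 100.0 * correct[is_l].mean() if n_l else float("nan")
    rho_r = 100.0 * correct[~is_l].mean() if n_r else float("nan")
    return AccuracyReport(
        rho=100.0 * correct.mean(),
        rho_L=float(rho_l),
        rho_R=float(rho_r),
        n_correct=int(correct.sum()),
        n_total=n,
        n_L=n_l,
        n_R=n_r,
    )


def split_trials(
    trials: list[Trial], n_per_class: int = 35, seed: int = 0
) -> tuple[list[Trial], list[Trial]]:
    """Balanced random train/test split: n_per_class trials per label for
    training, the remainder held out."""
    rng = np.random.default_rng(seed)
    by_class = {lab: [i for i, tr in enumerate(trials) if tr.label == lab] for lab in LABELS}
    for lab, idx in by_class.items():
        if len(idx) < n_per_class:
            raise ValueError(
                f"not enough {lab} trials for a balanced split "
                f"({len(idx)} < {n_per_class})"
            )
    train_idx: set[int] = set()
    for lab in LABELS:
        chosen = rng.choice(by_class[lab], size=n_per_class, replace=False)
        train_idx.update(int(i) for i in chosen)
    train = [trials[i] for i in sorted(train_idx)]
    test = [trials[i] for i in range(len(trials)) if i not in train_idx]
    return train, test


def balanced_subset(trials: list[Trial], seed: int = 0) -> list[Trial]:
    """Class-balanced random subset (equal L and R counts).

    Chance-level checks compare accuracy against a binomial distribution
    centred on 50%, which presumes balanced classes: on an unbalanced
    set a constant (label-independent) classifier scores the majority
    class fraction, not 50%.  Evaluating on a balanced subset makes any
    label-independent classifier sit at 50% in expectation.
    """
    rng = np.random.default_rng(seed)
    by_class = {lab: [t for t in trials if t.label == lab] for lab in LABELS}
    n = min(len(v) for v in by_class.values())
    if n == 0:
        raise ValueError("need trials of both classes")
    out = []
    for lab in LABELS:
        idx = rng.choice(len(by_class[lab]), size=n, replace=False)
        out.extend(by_class[lab][i] for i in sorted(idx))
    return out


def cross_subject_matrix(
    nets: dict[int, MLPParams], datasets: dict[int, list[Trial]]
) -> pd.DataFrame:
    """Accuracy rho_{h,r}: subject h's network evaluated on subject r's
    held-out trials.  The diagonal is the within-subject accuracy."""
    if set(nets) != set(datasets):
        raise ValueError("networks and datasets must cover the same subjects")
    subjects = sorted(nets)
    mat = pd.DataFrame(index=subjects, columns=subjects, dtype=float)
    for h in subjects:
        for r in subjects:
            mat.loc[h, r] = accuracy(nets[h], datasets[r]).rho
    mat.index.name = "trained_on_h"
    mat.columns.name = "evaluated_on_r"
    return mat


def sweep_topology_and_duration(
    sessions: list[tuple],
    h1_grid=(19,),
    h2_grid=(5,),
    t_grid=(1.0,),
    config: TrainConfig | None = None,
    n_per_class: int = 35,
    preprocess_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Mean held-out accuracy versus hidden-layer sizes and trial duration.

    ``sessions`` is a list of ``(recording, events)`` pairs (one per
    subject).  Each grid axis is swept with the other parameters at their
    defaults (H1 = 19, H2 = 5, T = 1 s), retraining with the (typically
    reduced) restart budget in ``config``; the reported value is the mean
    held-out rho over all restarts and subjects.  ``preprocess_kwargs``
    are forwarded to :func:`neckernet.preprocess.preprocess_session`
    (e.g. ``zero_phase=False`` for causal filtering, under which trial
    windows carry no smeared-in information from outside the window).
    """
    from .preprocess import preprocess_session

    config = config or TrainConfig(n_restarts=5, max_iter=40)
    pp_kwargs = preprocess_kwargs or {}
    rows = []

    def _mean_rho(trials, sizes) -> float:
        cfg = TrainConfig(
            n_restarts=config.n_restarts, max_iter=config.max_iter,
            lambda_init=config.lambda_init, tol=config.tol,
            seed=config.seed, sizes=sizes, init_scale=config.init_scale,
        )
        train, test = split_trials(trials, n_per_class, seed=config.seed)
        result = train_lm(train, [tr.label for tr in train], cfg)
        rhos = [accuracy(r.params, test).rho for r in result.restarts if np.isfinite(r.mu)]
        return float(np.mean(rhos))

    def _trials_at(t_sec: float):
        return [preprocess_session(rec, ev, T=t_sec, **pp_kwargs) for rec, ev in sessions]

    base_trials = _trials_at(1.0)
    p = base_trials[0][0].data.shape[0]

    for h1 in h1_grid:
        vals = [_mean_rho(tr, (p, int(h1), 5)) for tr in base_trials]
        rows.append({"axis": "H1", "value": h1, "mean_rho": float(np.mean(vals))})
    for h2 in h2_grid:
        vals = [_mean_rho(tr, (p, p, int(h2))) for tr in base_trials]
        rows.append({"axis": "H2", "value": h2, "mean_rho": float(np.mean(vals))})
    for t_sec in t_grid:
        vals = [_mean_rho(tr, (p, p, 5)) for tr in _trials_at(float(t_sec))]
        rows.append({"axis": "T", "value": t_sec, "mean_rho": float(np.mean(vals))})

    return pd.DataFrame(rows)
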