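"""Trial-based hyperparameter optimisation with a TPE or random sampler.

Each trial samples a learning rate (log-uniform), dropout rate and
momentum (uniform) and a model variant (categorical), then scores the
configuration by 5-fold cross-validated mean absolute label error.  The
Tree-structured Parzen Estimator here is a compact from-scratch
implementation of the standard algorithm: after a few random startup
trials the observations are split at a quantile into "good" and "bad"
sets, Parzen mixtures l(x) and g(x) are fitted to each, candidates are
drawn from l and the candidate maximising l(x)/g(x) is suggested.
Fully deterministic given the seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .models import VARIANTS, ModelSpec
from .training import TrainConfig, cross_validate

__all__ = ["SearchSpace", "TrialRecord", "StudyResult", "run_study", "best_trial"]


@dataclass
class SearchSpace:
    lr_bounds: tuple = (1e-4, 1e-1)       # log-uniform
    dropout_bounds: tuple = (0.0, 0.5)    # uniform
    momentum_bounds: tuple = (0.5, 0.99)  # uniform
    variants: tuple = VARIANTS            # categorical

    def __post_init__(self) -> None:
        for lo, hi in (self.lr_bounds, self.dropout_bounds, self.momentum_bounds):
            if not lo < hi:
                raise ValueError("search-space bounds must satisfy lower < upper")
        if not self.variants:
            raise ValueError("at least one model variant is required")
        bad = [v for v in self.variants if v not in VARIANTS]
        if bad:
            raise ValueError(f"unknown variants {bad}")


@dataclass
class TrialRecord:
    index: int
    params: dict
    variant: str
    objective: float
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


@dataclass
class StudyResult:
    trials: list[TrialRecord] = field(default_factory=list)

    @property
    def best(self) -> TrialRecord:
        return best_trial(self)


def best_trial(study: StudyResult) -> TrialRecord:
    """Trial with minimal objective; ties break to the earliest index."""
    if not study.trials:
        raise ValueError("study has no trials")
    return min(study.trials, key=lambda t: (t.objective, t.index))


# ---------------------------------------------------------------------------
# samplers


class RandomSampler:
    def __init__(self, space: SearchSpace, seed: int):
        self.space = space
        self.rng = np.random.default_rng(seed)

    def suggest(self, history: list[TrialRecord]) -> dict:
        s, r = self.space, self.rng
        return {
            "lr_max": float(np.exp(r.uniform(np.log(s.lr_bounds[0]), np.log(s.lr_bounds[1])))),
            "dropout_rate": float(r.uniform(*s.dropout_bounds)),
            "momentum": float(r.uniform(*s.momentum_bounds)),
            "variant": s.variants[r.integers(len(s.variants))],
        }


class TPESampler:
    """Tree-structured Parzen Estimator over the four search dimensions."""

    def __init__(self, space: SearchSpace, seed: int,
                 n_startup: int = 5, gamma: float = 0.25, n_candidates: int = 24):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self._random = RandomSampler(space, seed)
        self._random.rng = self.rng  # share the stream for reproducibility

    @staticmethod
    def _mixture_logpdf(x: np.ndarray, obs: np.ndarray, lo: float, hi: float):
        """Parzen mixture of Gaussians at the observations + a uniform prior."""
        width = hi - lo
        if obs.size == 0:
            return np.full_like(x, -np.log(width))
        bw = max(obs.std() * obs.size ** (-0.2), width / 20.0)
        z = (x[:, None] - obs[None, :]) / bw
        comp = np.exp(-0.5 * z * z) / (bw * np.sqrt(2 * np.pi))
        # one extra uniform component acts as the prior
        dens = (comp.sum(axis=1) + 1.0 / width) / (obs.size + 1)
        return np.log(np.maximum(dens, 1e-300))

    def _suggest_numeric(self, good: np.ndarray, bad: np.ndarray,
                         lo: float, hi: float) -> float:
        n_cand = self.n_candidates
        picks = []
        for _ in range(n_cand):
            if good.size and self.rng.random() < good.size / (good.size + 1):
                bw = max(good.std() * good.size ** (-0.2), (hi - lo) / 20.0)
                c = good[self.rng.integers(good.size)] + self.rng.normal(0, bw)
                picks.append(float(np.clip(c, lo, hi)))
            else:
                picks.append(float(self.rng.uniform(lo, hi)))
        cand = np.array(picks)
        score = self._mixture_logpdf(cand, good, lo, hi) - self._mixture_logpdf(
            cand, bad, lo, hi
        )
        return float(cand[int(np.argmax(score))])

    def _suggest_categorical(self, good: list, bad: list, choices: tuple):
        k = len(choices)
        pg = np.array([1.0 + good.count(c) for c in choices]) / (k + len(good))
        pb = np.array([1.0 + bad.count(c) for c in choices]) / (k + len(bad))
        ratio = pg / pb
        cand_idx = self.rng.choice(k, size=min(self.n_candidates, 4 * k), p=pg / pg.sum())
        best = max(set(cand_idx.tolist()), key=lambda i: (ratio[i], -i))
        return choices[best]

    def suggest(self, history: list[TrialRecord]) -> dict:
        if len(history) < self.n_startup:
            return self._random.suggest(history)
        ordered = sorted(history, key=lambda t: t.objective)
        n_good = max(1, int(np.ceil(self.gamma * len(ordered))))
        good, bad = ordered[:n_good], ordered[n_good:]
        s = self.space
        glr = np.log([t.params["lr_max"] for t in good])
        blr = np.log([t.params["lr_max"] for t in bad])
        lr = np.exp(
            self._suggest_numeric(glr, blr, np.log(s.lr_bounds[0]), np.log(s.lr_bounds[1]))
        )
        dr = self._suggest_numeric(
            np.array([t.params["dropout_rate"] for t in good]),
            np.array([t.params["dropout_rate"] for t in bad]),
            *s.dropout_bounds,
        )
        mom = self._suggest_numeric(
            np.array([t.params["momentum"] for t in good]),
            np.array([t.params["momentum"] for t in bad]),
            *s.momentum_bounds,
        )
        variant = self._suggest_categorical(
            [t.variant for t in good], [t.variant for t in bad], s.variants
        )
        return {"lr_max": float(lr), "dropout_rate": float(dr),
                "momentum": float(mom), "variant": variant}


# ---------------------------------------------------------------------------


def run_study(
    sample_set,
    space: SearchSpace | None = None,
    n_trials: int = 20,
    sampler: str = "TPE",
    seed: int = 0,
    train_config: TrainConfig | None = None,
    width_scale: float = 1.0,
    modalities: tuple | None = None,
) -> StudyResult:
    """Run ``n_trials`` sampled configurations, each scored by 5-fold CV."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or SearchSpace()
    base = train_config or TrainConfig()
    sampler_obj = {"TPE": TPESampler, "random": RandomSampler}[sampler](space, seed)
    study = StudyResult()
    for i in range(n_trials):
        params = sampler_obj.suggest(study.trials)
        spec = ModelSpec(
            variant=params["variant"],
            modalities=modalities or ("PPG", "GSR", "ET", "fNIRS"),
            dropout_rate=params["dropout_rate"],
            width_scale=width_scale,
        )
        cfg = TrainConfig(
            lr_max=params["lr_max"],
            momentum=params["momentum"],
            batch_size=base.batch_size,
            epochs_per_fold=base.epochs_per_fold,
            folds=base.folds,
            holdout_fraction=base.holdout_fraction,
            seed=seed + 7919 * i,
        )
        t0 = time.perf_counter()
        _, objective = cross_validate(spec, sample_set, cfg)
        study.trials.append(
            TrialRecord(
                index=i,
                params={k: v for k, v in params.items() if k != "variant"},
                variant=params["variant"],
                objective=objective,
                duration_s=time.perf_counter() - t0,
            )
        )
    return study
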