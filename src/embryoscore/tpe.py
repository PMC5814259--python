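"""Tree-structured Parzen Estimator (TPE) hyperparameter sampler.

A compact sequential model-based optimizer: past trials are split at the
gamma quantile of the objective into "good" and "bad" sets; each parameter
gets two Parzen density estimates l(x) (good) and g(x) (bad) — Gaussian
kernels for numeric parameters, smoothed category counts for categorical
ones — and the next point maximizes l(x)/g(x) over a batch of candidates
drawn from l.  Parameters are treated independently.  Minimizes the
objective; pass the negative of a score to maximize.
"""

from __future__ import annotations

import numpy as np


class TPESampler:
    """Suggest/observe interface over a search-space dict.

    The space maps parameter name -> ("int", lo, hi) | ("float", lo, hi) |
    ("logfloat", lo, hi) | ("cat", [choices]).
    """

    def __init__(self, space: dict, seed: int = 0, n_startup: int = 8, gamma: float = 0.25, n_candidates: int = 24):
        for name, spec in space.items():
            kind = spec[0]
            if kind == "cat":
                if not spec[1]:
                    raise ValueError(f"{name}: empty categorical choices")
            elif kind in ("int", "float", "logfloat"):
                if spec[1] > spec[2]:
                    raise ValueError(f"{name}: lower bound exceeds upper bound")
            else:
                raise ValueError(f"{name}: unknown parameter kind {kind!r}")
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[tuple[dict, float]] = []

    # ------------------------------------------------------------------
    def _random_point(self) -> dict:
        point = {}
        for name, spec in self.space.items():
            kind = spec[0]
            if kind == "cat":
                point[name] = spec[1][int(self.rng.integers(len(spec[1])))]
            elif kind == "int":
                point[name] = int(self.rng.integers(spec[1], spec[2] + 1))
            elif kind == "float":
                point[name] = float(self.rng.uniform(spec[1], spec[2]))
            else:  # logfloat
                point[name] = float(np.exp(self.rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        return point

    def _numeric_value(self, name: str, value) -> float:
        if self.space[name][0] == "logfloat":
            return float(np.log(value))
        return float(value)

    def _sample_param(self, name: str, good: list, bad: list):
        spec = self.space[name]
        kind = spec[0]
        if kind == "cat":
            choices = spec[1]
            lg = np.array([1.0 + sum(1 for v in good if v == c) for c in choices])
            lb = np.array([1.0 + sum(1 for v in bad if v == c) for c in choices])
            lg, lb = lg / lg.sum(), lb / lb.sum()
            cand = self.rng.choice(len(choices), size=self.n_candidates, p=lg)
            best = cand[np.argmax(lg[cand] / lb[cand])]
            return choices[int(best)]
        lo, hi = spec[1], spec[2]
        if kind == "logfloat":
            lo, hi = np.log(lo), np.log(hi)
        gv = np.array([self._numeric_value(name, v) for v in good])
        bv = np.array([self._numeric_value(name, v) for v in bad]) if bad else np.array([])
        width = max(hi - lo, 1e-12)
        bw = max(width / max(len(gv), 1) ** 0.5 / 2.0, width * 0.05)

        def density(x, obs):
            if len(obs) == 0:
                return np.full_like(x, 1.0 / width)
            d = np.exp(-0.5 * ((x[:, None] - obs[None, :]) / bw) ** 2)
            return d.mean(axis=1) / (bw * np.sqrt(2 * np.pi)) + 1e-12

        centers = gv[self.rng.integers(len(gv), size=self.n_candidates)]
        cand = np.clip(centers + self.rng.standard_normal(self.n_candidates) * bw, lo, hi)
        score = density(cand, gv) / density(cand, bv)
        x = float(cand[np.argmax(score)])
        if kind == "logfloat":
            return float(np.exp(x))
        if kind == "int":
            return int(np.clip(round(x), spec[1], spec[2]))
        return x

    # ------------------------------------------------------------------
    def suggest(self) -> dict:
        """Propose the next hyperparameter point."""
        if len(self.trials) < self.n_startup:
            return self._random_point()
        losses = np.array([loss for _, loss in self.trials])
        n_good = max(1, int(np.ceil(self.gamma * len(losses))))
        order = np.argsort(losses, kind="stable")
        good_idx, bad_idx = order[:n_good], order[n_good:]
        point = {}
        for name in self.space:
            good = [self.trials[i][0][name] for i in good_idx]
            bad = [self.trials[i][0][name] for i in bad_idx]
            point[name] = self._sample_param(name, good, bad)
        return point

    def observe(self, point: dict, loss: float) -> None:
        """Record a completed trial (lower loss is better)."""
        self.trials.append((dict(point), float(loss)))

    @property
    def best(self) -> tuple[dict, float]:
        if not self.trials:
            raise ValueError("no trials observed yet")
        i = int(np.argmin([loss for _, loss in self.trials]))
        return self.trials[i]


def minimize(objective, space: dict, budget: int, seed: int = 0) -> tuple[dict, float]:
    """Run TPE for ``budget`` evaluations; return (best point, best loss)."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    sampler = TPESampler(space, seed=seed)
    for _ in range(budget):
        point = sampler.suggest()
        sampler.observe(point, objective(point))
    return sampler.best
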