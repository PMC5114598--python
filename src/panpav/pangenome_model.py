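"""Pangenome and core-genome accumulation curves and nonlinear model fits.

For every subset size k of the N lines, pangenome size (genes present in at
least one subset line) and core size (genes present in all subset lines) are
computed over all C(N, k) subsets — or a seeded sample when N is large — and
the per-k means are fitted by nonlinear least squares: a power law
y = A·x^B + C for the pangenome and an exponential y = A·e^(B·x) + C for the
core genome.  The new-gene curve counts, for ordered additions of lines,
genes present in the added line and absent from all previous ones, averaged
over random orders.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import PavMatrix

__all__ = ["PanCurve", "FittedModel", "count_combinations", "subset_counts",
           "build_curve", "fit_power_law", "fit_exponential", "extrapolate",
           "new_gene_curve"]

MAX_EXHAUSTIVE_LINES = 15


def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k)."""
    if k < 0 or n < 0:
        raise ValueError("n and k must be >= 0")
    if k > n:
        raise ValueError(f"k={k} > n={n}")
    return math.comb(n, k)


def subset_counts(pav: PavMatrix, subset: Sequence[str]
                  ) -> tuple[int, int, int]:
    """(pan, core, new) gene counts for an ordered subset of lines.

    pan = genes present in >=1 subset line; core = genes present in all;
    new = genes present in the last (added) line but absent from all lines
    before it in the given order.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    unknown = [l for l in subset if l not in pav.df.columns]
    if unknown:
        raise ValueError(f"unknown lines: {unknown}")
    sub = pav.df[list(subset)].to_numpy()
    pan = int((sub.sum(axis=1) > 0).sum())
    core = int((sub.sum(axis=1) == len(subset)).sum())
    added = sub[:, -1] == 1
    if len(subset) > 1:
        prior_absent = sub[:, :-1].sum(axis=1) == 0
        new = int((added & prior_absent).sum())
    else:
        new = int(added.sum())
    return pan, core, new


@dataclass
class PanCurve:
    """Per-subset-size pangenome/core/new-gene counts and their means."""

    k_values: list[int]
    pan_sizes: dict[int, list[int]]
    core_sizes: dict[int, list[int]]
    new_genes: dict[int, list[int]]
    unit: str = "genes"

    @property
    def pan_means(self) -> np.ndarray:
        return np.array([np.mean(self.pan_sizes[k]) for k in self.k_values])

    @property
    def core_means(self) -> np.ndarray:
        return np.array([np.mean(self.core_sizes[k]) for k in self.k_values])

    @property
    def new_means(self) -> np.ndarray:
        return np.array([np.mean(self.new_genes[k]) for k in self.k_values])

    def all_points(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        data = {"pan": self.pan_sizes, "core": self.core_sizes,
                "new": self.new_genes}[which]
        x = np.concatenate([[k] * len(data[k]) for k in self.k_values])
        y = np.concatenate([data[k] for k in self.k_values])
        return x.astype(float), y.astype(float)


def build_curve(pav: PavMatrix, mode: str = "all_subsets",
                max_subsets: int = 200, seed: int = 0,
                unit: str = "genes") -> PanCurve:
    """Accumulation statistics over subsets of every size.

    ``all_subsets`` enumerates every combination (refused above
    ``MAX_EXHAUSTIVE_LINES`` lines); ``sampled`` draws ``max_subsets`` random
    subsets per size with a seed.  New-gene counts come from random addition
    orders (one per evaluated subset, the added line being the last element).
    """
    lines = pav.line_ids
    n = len(lines)
    if n < 2:
        raise ValueError("need >= 2 lines")
    if mode == "all_subsets" and n > MAX_EXHAUSTIVE_LINES:
        raise ValueError(
            f"all_subsets refused for {n} > {MAX_EXHAUSTIVE_LINES} lines; "
            "use mode='sampled'")
    rng = np.random.default_rng(seed)
    pan_sizes: dict[int, list[int]] = {}
    core_sizes: dict[int, list[int]] = {}
    new_genes: dict[int, list[int]] = {}
    for k in range(1, n + 1):
        pan_sizes[k], core_sizes[k], new_genes[k] = [], [], []
        if mode == "all_subsets":
            combos = [list(c) for c in itertools.combinations(lines, k)]
        elif mode == "sampled":
            n_draw = min(max_subsets, count_combinations(n, k))
            combos = []
            seen = set()
            while len(combos) < n_draw:
                c = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
                if c not in seen:
                    seen.add(c)
                    combos.append([lines[i] for i in c])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for combo in combos:
            order = list(combo)
            rng.shuffle(order)
            pan, core, new = subset_counts(pav, order)
            pan_sizes[k].append(pan)
            core_sizes[k].append(core)
            new_genes[k].append(new)
    return PanCurve(list(range(1, n + 1)), pan_sizes, core_sizes,
                    new_genes, unit=unit)


def new_gene_curve(pav: PavMatrix, n_orders: int = 200,
                   seed: int = 0) -> np.ndarray:
    """Mean new genes at each addition step over random line orders."""
    lines = pav.line_ids
    rng = np.random.default_rng(seed)
    arr = pav.presence
    idx = np.arange(len(lines))
    totals = np.zeros(len(lines))
    for _ in range(n_orders):
        rng.shuffle(idx)
        seen = np.zeros(arr.shape[0], dtype=bool)
        for step, j in enumerate(idx):
            present = arr[:, j] == 1
            totals[step] += int((present & ~seen).sum())
            seen |= present
    return totals / n_orders


# ---------------------------------------------------------------------------
# Nonlinear fits
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted 3-parameter growth/decay model y = A·x^B + C or A·e^(Bx) + C."""

    form: str  # power_law | exponential
    A: float
    B: float
    C: float
    standard_errors: tuple[float, float, float]
    covariance: np.ndarray = field(repr=False, default=None)

    def predicted(self, n) -> np.ndarray | float:
        x = np.asarray(n, dtype=float)
        if self.form == "power_law":
            y = self.A * x ** self.B + self.C
        else:
            y = self.A * np.exp(self.B * x) + self.C
        return y if y.shape else float(y)

    def _gradient(self, x: float) -> np.ndarray:
        if self.form == "power_law":
            dA = x ** self.B
            dB = self.A * x ** self.B * math.log(x)
        else:
            dA = math.exp(self.B * x)
            dB = self.A * x * math.exp(self.B * x)
        return np.array([dA, dB, 1.0])


class FitError(RuntimeError):
    def __init__(self, msg: str, last_params=None, residual_norm=None):
        super().__init__(msg)
        self.last_params = last_params
        self.residual_norm = residual_norm


def _fit(form: str, func: Callable, x: np.ndarray, y: np.ndarray,
         starts: Sequence[tuple[float, float, float]]) -> FittedModel:
    """Levenberg-Marquardt from several scale-aware starts; best SSE wins.

    Saturating curves live on the A<0, B<0 branch of the power law, so a
    mirrored start is always tried alongside the growth-branch start.
    """
    if len(x) < 4:
        raise ValueError("need >= 4 points to fit 3 parameters")
    best = None
    last_err = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(func, x, y, p0=p0, maxfev=20000)
        except RuntimeError as err:
            last_err = err
            continue
        sse = float(((y - func(x, *popt)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        resid = float(np.linalg.norm(y - func(x, *starts[0])))
        raise FitError(f"{form} fit did not converge: {last_err}",
                       last_params=starts[0], residual_norm=resid)
    _, popt, pcov = best
    se = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, None)))
    return FittedModel(form, float(popt[0]), float(popt[1]), float(popt[2]),
                       se, covariance=pcov)


def fit_power_law(k_values: Sequence[float], means: Sequence[float]
                  ) -> FittedModel:
    """Least-squares fit of y = A·x^B + C to per-k means."""
    x = np.asarray(k_values, float)
    y = np.asarray(means, float)
    rng_y = float(y.max() - y.min())
    a0 = rng_y if rng_y > 0 else 1.0
    starts = [(a0, 0.5, float(y.min())),       # growing branch
              (-a0, -0.5, float(y.max())),     # saturating branch
              (a0, -0.5, float(y.min()))]      # decaying branch
    return _fit("power_law", lambda x, A, B, C: A * x ** B + C, x, y,
                starts)


def fit_exponential(k_values: Sequence[float], means: Sequence[float]
                    ) -> FittedModel:
    """Least-squares fit of y = A·e^(B·x) + C to per-k means."""
    x = np.asarray(k_values, float)
    y = np.asarray(means, float)
    rng_y = float(y.max() - y.min())
    a0 = rng_y if rng_y > 0 else 1.0
    starts = [(a0, -0.5, float(y.min())),      # decaying toward C
              (-a0, -0.5, float(y.max()))]     # growing toward C
    return _fit("exponential", lambda x, A, B, C: A * np.exp(B * x) + C,
                x, y, starts)


def extrapolate(model: FittedModel, n: float) -> tuple[float, float]:
    """Point prediction at n with a delta-method standard error."""
    pred = float(model.predicted(n))
    if model.covariance is None:
        return pred, float("nan")
    g = model._gradient(float(n))
    var = float(g @ model.covariance @ g)
    return pred, math.sqrt(max(var, 0.0))
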