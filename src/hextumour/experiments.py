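"""Experiment harness: scenario quartets, division-rate sensitivity sweeps,
growth-curve comparison statistics and the random-mutualism control.

Growth trajectories are compared with the two-sample Kolmogorov-Smirnov
statistic over the per-step cancer-cell counts: when the associated p value
exceeds 0.05 the two trajectories are considered statistically similar.
Group comparisons use the Kruskal-Wallis rank test followed by Dunn's
post-hoc pairwise test with Bonferroni correction.

Seeding: replicate experiments derive one child seed per (rate, replicate)
from a master seed; the paired conditions of a replicate share that seed
(shared initial state) for variance reduction, so a pair differs only
through the ecological switches under study.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScenarioConfig
from .engine import ModelState, run_model
from .io import history_frame


@dataclass
class GrowthCurve:
    """Cancer-cell count per step of one run."""

    steps: np.ndarray
    n_cancer: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=int)
        self.n_cancer = np.asarray(self.n_cancer, dtype=int)
        if self.steps.shape != self.n_cancer.shape:
            raise ValueError("steps and n_cancer must have equal length")
        if np.any(self.n_cancer < 0):
            raise ValueError("cancer counts must be non-negative")

    @property
    def final_n(self) -> int:
        return int(self.n_cancer[-1])

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.n_cancer, self.steps))


@dataclass
class QuartetResult:
    """The four-scenario design: ±mutualism × ±predation at one rate."""

    curves: dict[tuple[bool, bool], GrowthCurve]   # (mutualism, predation)
    division_rate: float
    seed: int


@dataclass
class ComparisonResult:
    """KS and/or Kruskal-Wallis + Dunn comparison of scenario groups."""

    kw_statistic: float
    kw_df: int
    kw_p: float
    dunn_table: pd.DataFrame
    ks_distance: Optional[float] = None
    ks_p: Optional[float] = None

    @property
    def similar(self) -> Optional[bool]:
        """KS similarity rule: trajectories are similar when p > 0.05."""
        return None if self.ks_p is None else bool(self.ks_p > 0.05)


@dataclass
class ReplicateSummary:
    n_higher: int
    n_equal: int
    n_lower: int

    @property
    def fraction_higher(self) -> float:
        total = self.n_higher + self.n_equal + self.n_lower
        return self.n_higher / total if total else float("nan")


def derive_seed(master: int, *keys: float) -> int:
    """Deterministic child seed from a master seed and experiment keys."""
    ints = [int(master)] + [int(round(float(k) * 1_000_000)) for k in keys]
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2 ** 31))


def growth_curve(state: ModelState) -> GrowthCurve:
    return GrowthCurve(
        steps=np.array([r.step for r in state.history]),
        n_cancer=np.array([r.n_cancer for r in state.history]),
    )


def run_scenario(config: ScenarioConfig) -> tuple[GrowthCurve, pd.DataFrame]:
    """Run one scenario to ``max_steps``; returns the growth curve and the
    full per-step history table.  Deterministic given (config, seed)."""
    state = run_model(config)
    return growth_curve(state), history_frame(state.history)


def run_quartet(base: ScenarioConfig) -> QuartetResult:
    """Run the four ±mutualism × ±predation scenarios.

    All four share ``base.seed`` (shared initial state) and every other
    parameter, so the curves differ only through the two switches.
    """
    curves: dict[tuple[bool, bool], GrowthCurve] = {}
    for mut, pred in itertools.product((True, False), repeat=2):
        cfg = base.replace(mutualism_enabled=mut, predation_enabled=pred,
                           random_mutualism=False)
        curves[(mut, pred)], _ = run_scenario(cfg)
    return QuartetResult(curves=curves, division_rate=base.division_rate,
                         seed=base.seed)


def ks_distance(a: GrowthCurve, b: GrowthCurve) -> tuple[float, float]:
    """Two-sample KS statistic (sup ECDF difference) between the per-step
    count samples of two growth curves, with the asymptotic p value."""
    if len(a.n_cancer) == 0 or len(b.n_cancer) == 0:
        raise ValueError("growth curves must be non-empty")
    res = stats.ks_2samp(a.n_cancer, b.n_cancer, method="asymp")
    return float(res.statistic), float(res.pvalue)


def dunn_test(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's post-hoc pairwise test with tie correction and Bonferroni
    adjustment over all k(k−1)/2 pairs.

    z for pair (i, j) is the difference of mean ranks over the pooled
    sample divided by ``sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))`` where
    ``T = Σ(t³−t)/(12(N−1))`` sums over tie groups.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for lab, s in zip(labels, samples):
        mean_ranks[lab] = ranks[pos:pos + len(s)].mean()
        pos += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for (la, sa), (lb, sb) in itertools.combinations(zip(labels, samples), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / len(sa) + 1.0 / len(sb)))
        z = (mean_ranks[la] - mean_ranks[lb]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": la, "group_b": lb, "z": z, "p": p,
                     "p_adjusted": min(1.0, p * n_pairs)})
    return pd.DataFrame(rows)


def kruskal_wallis_with_dunn(groups: Mapping[str, Sequence[float]]
                             ) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis across ≥2 groups plus Dunn's post hoc."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for lab, s in groups.items():
        if len(s) < 2:
            raise ValueError(f"group {lab!r} needs at least two observations")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    h, p = stats.kruskal(*samples)
    return ComparisonResult(kw_statistic=float(h), kw_df=len(groups) - 1,
                            kw_p=float(p), dunn_table=dunn_test(groups))


def summarize_replicates(
    pairs: Sequence[tuple[GrowthCurve, GrowthCurve]],
    metric: str = "final",
) -> ReplicateSummary:
    """Score paired (+mutualism, −mutualism) replicates.

    A pair counts as "mutualism higher" when the +mutualism member's growth
    trajectory ends higher (final cancer count, or area under the curve for
    ``metric='auc'``); exact ties count as "no difference".
    """
    if not pairs:
        raise ValueError("need at least one pair")
    if metric not in ("final", "auc"):
        raise ValueError("metric must be 'final' or 'auc'")
    key = (lambda c: c.final_n) if metric == "final" else (lambda c: c.auc)
    n_higher = n_equal = n_lower = 0
    for plus, minus in pairs:
        a, b = key(plus), key(minus)
        if a > b:
            n_higher += 1
        elif a == b:
            n_equal += 1
        else:
            n_lower += 1
    return ReplicateSummary(n_higher, n_equal, n_lower)


def paired_mutualism_replicates(
    rates: Sequence[float],
    n_pairs: int,
    base: ScenarioConfig,
    master_seed: int,
    predation: bool = True,
) -> tuple[list[tuple[GrowthCurve, GrowthCurve]], pd.DataFrame]:
    """Run ``n_pairs`` paired (+/−mutualism) replicates, cycling through
    ``rates``; each pair shares a derived seed and the predation setting."""
    pairs: list[tuple[GrowthCurve, GrowthCurve]] = []
    rows = []
    for k in range(n_pairs):
        rate = float(rates[k % len(rates)])
        seed = derive_seed(master_seed, rate, k)
        cfg = base.replace(division_rate=rate, seed=seed,
                           predation_enabled=predation,
                           random_mutualism=False)
        plus, _ = run_scenario(cfg.replace(mutualism_enabled=True))
        minus, _ = run_scenario(cfg.replace(mutualism_enabled=False))
        pairs.append((plus, minus))
        rows.append({"pair": k, "division_rate": rate, "seed": seed,
                     "final_n_mutualism": plus.final_n,
                     "final_n_no_mutualism": minus.final_n})
    return pairs, pd.DataFrame(rows)


def sensitivity_sweep(
    rates: Sequence[float],
    n_replicates: int,
    base: ScenarioConfig,
    master_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Division-rate sensitivity sweep of immune-evasion similarity.

    For every rate, replicate and mutualism condition, runs the
    predation/no-predation pair and records the KS distance between the two
    growth curves — the violin-plot data behind the evasion summary.
    """
    master = base.seed if master_seed is None else master_seed
    rows = []
    for rate in rates:
        for rep in range(n_replicates):
            seed = derive_seed(master, rate, rep)
            for mut in (True, False):
                cfg = base.replace(division_rate=float(rate), seed=seed,
                                   mutualism_enabled=mut,
                                   random_mutualism=False)
                pred, _ = run_scenario(cfg.replace(predation_enabled=True))
                free, _ = run_scenario(cfg.replace(predation_enabled=False))
                d, p = ks_distance(pred, free)
                rows.append({
                    "division_rate": float(rate),
                    "condition": "mutualism" if mut else "no_mutualism",
                    "replicate": rep,
                    "seed": seed,
                    "final_n": pred.final_n,
                    "final_n_no_predation": free.final_n,
                    "ks_distance": d,
                    "ks_p": p,
                })
    return pd.DataFrame(rows)


def advantaged_rate_schedule(history: pd.DataFrame) -> list[float]:
    """Per-step fraction of cancer cells that are mutualistic with the
    proliferation advantage (oncoprotein above threshold); used to replay a
    contact-mutualism run as a random-mutualism rate schedule."""
    n = history["n_cancer"].to_numpy(dtype=float)
    adv = history["n_mutualistic_advantaged"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, adv / np.maximum(n, 1), 0.0)
    return [float(min(1.0, max(0.0, v))) for v in frac[1:]]  # steps 1..T


def mean_advantaged_fraction(history: pd.DataFrame,
                             from_step: Optional[int]) -> float:
    """Time-averaged advantaged-cell fraction from ``from_step`` onward."""
    if from_step is None:
        return float("nan")
    sub = history[history["step"] >= from_step]
    frac = sub["n_mutualistic_advantaged"] / sub["n_cancer"].clip(lower=1)
    return float(frac.mean())


def randomisation_experiment(base: ScenarioConfig) -> dict:
    """Contact mutualism vs rate-matched random mutualism vs no mutualism.

    For each predation setting, runs the contact-mutualism scenario, replays
    its per-step advantaged-cell rate as the random-mutualism schedule, and
    runs the no-mutualism control — six growth curves compared with
    Kruskal-Wallis (df = 5) and Dunn's post hoc.
    """
    groups: dict[str, np.ndarray] = {}
    schedules: dict[bool, list[float]] = {}
    fractions: dict[bool, float] = {}
    for pred in (False, True):
        cfg = base.replace(predation_enabled=pred, mutualism_enabled=True,
                           random_mutualism=False)
        state = run_model(cfg)
        hist = history_frame(state.history)
        curve = growth_curve(state)
        schedules[pred] = advantaged_rate_schedule(hist)
        fractions[pred] = mean_advantaged_fraction(
            hist, state.first_contact_step)
        tag = "+pred" if pred else "-pred"
        groups[f"mutualism{tag}"] = curve.n_cancer
        rand_cfg = cfg.replace(mutualism_enabled=False, random_mutualism=True,
                               random_mutualism_rate=schedules[pred] or [0.0])
        rand_curve, _ = run_scenario(rand_cfg)
        groups[f"random{tag}"] = rand_curve.n_cancer
        none_curve, _ = run_scenario(
            cfg.replace(mutualism_enabled=False, random_mutualism=False))
        groups[f"none{tag}"] = none_curve.n_cancer
    comparison = kruskal_wallis_with_dunn(groups)
    return {
        "comparison": comparison,
        "schedules": schedules,
        "mean_advantaged_fraction": fractions,
        "groups": groups,
    }
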