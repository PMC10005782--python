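"""Per-microtubule dynamics statistics and condition-level comparisons.

The estimators follow a whole-lifetime accounting: because catastrophe
propensity depends on microtubule age and lattice history, events are counted
over the full life of each microtubule (from emanation at the seed to
complete depolymerization back to it) rather than per phase:

* catastrophe frequency ``f_cat`` — catastrophes observed in a lifetime
  divided by the total duration of its growth excursions.  An excursion runs
  from the lifetime start (or a rescue) to the next catastrophe; under the
  default convention it includes pause time interleaved between elongation
  periods but never shrinkage time.
* rescue frequency ``f_res`` — rescues divided by the total time spent
  shrinking within the lifetime (undefined when no shrinkage was observed).
* percent time in pause — summed pause durations divided by the lifetime.

Catastrophes are transitions into shrinkage from either growth or pause;
rescues are transitions out of shrinkage into either growth or pause.

Condition summaries report the mean / SD / SEM over microtubules of each
per-microtubule statistic (the convention used for dot plots and histograms
of events per microtubule) alongside pooled event-per-time frequencies
(total events / total time), which are the consistent estimators of the
underlying transition rates and are what the closed-form oracle predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kymo import ST_GROWTH, ST_PAUSE, ST_SHRINK, LifetimeRecord

__all__ = [
    "Conventions",
    "DynamicsSummary",
    "ConditionSummary",
    "ComparisonResult",
    "summarize_lifetime",
    "summarize_lifetimes",
    "aggregate_condition",
    "compare_conditions",
]

STATISTICS = ["growth_rate", "f_cat", "f_res", "pause_pct",
              "n_cat", "n_res", "n_pause", "lifetime"]


class StatsError(ValueError):
    """Invalid statistics input or configuration."""


@dataclass(frozen=True)
class Conventions:
    """Accounting conventions for lifetime statistics.

    catastrophe_denominator
        ``excursion_incl_pauses`` (default): growth-excursion time includes
        pauses interleaved between elongation periods, excludes shrinkage.
        ``growth_only``: elongation time alone.
    lifetime_end
        ``seed_return`` (default): the lifetime includes the terminal
        shrinkage back to the seed.  ``terminal_shrink_onset``: it ends at
        the onset of the terminal shrinkage.
    include_censored
        Whether microtubules still present at movie end contribute their
        observed times and events (default True).
    """

    catastrophe_denominator: str = "excursion_incl_pauses"
    lifetime_end: str = "seed_return"
    include_censored: bool = True

    def __post_init__(self) -> None:
        if self.catastrophe_denominator not in ("excursion_incl_pauses", "growth_only"):
            raise StatsError(f"unknown catastrophe_denominator {self.catastrophe_denominator!r}")
        if self.lifetime_end not in ("seed_return", "terminal_shrink_onset"):
            raise StatsError(f"unknown lifetime_end {self.lifetime_end!r}")


@dataclass
class DynamicsSummary:
    """Whole-lifetime statistics of a single microtubule.

    Times in seconds, frequencies in min^-1, growth rate in um/min;
    ``f_res`` is NaN when no shrinkage was observed.
    """

    mt_id: str | None
    growth_rate: float
    n_cat: int
    n_res: int
    n_pause: int
    t_grow: float
    t_shrink: float
    t_pause: float
    t_excursion: float
    lifetime: float
    f_cat: float
    f_res: float
    pause_pct: float
    censored: bool


def summarize_lifetime(
    life: LifetimeRecord,
    conv: Conventions | None = None,
    mt_id: str | None = None,
) -> DynamicsSummary:
    """Compute the whole-lifetime statistics of one microtubule."""
    conv = conv or Conventions()
    life.validate()
    segs = list(life.segments)
    drop_terminal_shrink = (
        conv.lifetime_end == "terminal_shrink_onset"
        and not life.censored
        and segs[-1].state == ST_SHRINK
    )
    timed = segs[:-1] if drop_terminal_shrink else segs

    t_grow = sum(s.duration for s in timed if s.state == ST_GROWTH)
    t_pause = sum(s.duration for s in timed if s.state == ST_PAUSE)
    t_shrink = sum(s.duration for s in timed if s.state == ST_SHRINK)
    lifetime = t_grow + t_pause + t_shrink

    n_cat = n_res = 0
    for a, b in zip(segs, segs[1:]):
        if b.state == ST_SHRINK and a.state != ST_SHRINK:
            n_cat += 1
        if a.state == ST_SHRINK and b.state != ST_SHRINK:
            n_res += 1
    n_pause = sum(1 for s in segs if s.state == ST_PAUSE)

    if conv.catastrophe_denominator == "excursion_incl_pauses":
        t_excursion = t_grow + t_pause
    else:
        t_excursion = t_grow
    f_cat = 60.0 * n_cat / t_excursion if t_excursion > 0 else np.nan
    f_res = 60.0 * n_res / t_shrink if t_shrink > 0 else np.nan

    grow_segs = [s for s in segs if s.state == ST_GROWTH]
    w = np.array([s.duration for s in grow_segs])
    growth_rate = float(np.average([s.slope for s in grow_segs], weights=w)) \
        if w.sum() > 0 else np.nan
    pause_pct = 100.0 * t_pause / lifetime if lifetime > 0 else np.nan

    return DynamicsSummary(
        mt_id=mt_id, growth_rate=growth_rate,
        n_cat=n_cat, n_res=n_res, n_pause=n_pause,
        t_grow=t_grow, t_shrink=t_shrink, t_pause=t_pause,
        t_excursion=t_excursion, lifetime=lifetime,
        f_cat=f_cat, f_res=f_res, pause_pct=pause_pct,
        censored=life.censored,
    )


def summarize_lifetimes(
    lifetimes: list[LifetimeRecord],
    conv: Conventions | None = None,
    mt_id: str | None = None,
) -> list[DynamicsSummary]:
    """Summarize each lifetime, honoring the censoring convention."""
    conv = conv or Conventions()
    out = []
    for k, life in enumerate(lifetimes):
        if life.censored and not conv.include_censored:
            continue
        label = f"{mt_id}/{k}" if mt_id is not None else None
        out.append(summarize_lifetime(life, conv, mt_id=label))
    return out


@dataclass
class ConditionSummary:
    """Per-condition aggregate of microtubule summaries.

    ``stats`` holds mean / sd / sem / n per statistic (microtubules with an
    undefined f_res are excluded from the f_res aggregates only); ``pooled``
    holds the total-events / total-time frequencies and the pooled pause
    fraction; ``table`` is the per-microtubule table the aggregates came
    from.
    """

    label: str
    n_microtubules: int
    stats: pd.DataFrame
    pooled: dict[str, float] = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def summaries_table(summaries: list[DynamicsSummary], condition: str | None = None) -> pd.DataFrame:
    rows = [vars(s).copy() for s in summaries]
    df = pd.DataFrame(rows)
    if condition is not None:
        df["condition"] = condition
    return df


def aggregate_condition(
    summaries: list[DynamicsSummary],
    label: str = "",
) -> ConditionSummary:
    """Aggregate per-microtubule summaries into condition-level statistics."""
    if not summaries:
        raise StatsError("cannot aggregate an empty condition")
    table = summaries_table(summaries, condition=label or None)
    rows = {}
    for stat in STATISTICS:
        x = table[stat].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        n = x.size
        mean = float(np.mean(x)) if n else np.nan
        sd = float(np.std(x, ddof=1)) if n > 1 else np.nan
        rows[stat] = {"mean": mean, "sd": sd,
                      "sem": sd / np.sqrt(n) if n > 1 else np.nan, "n": n}
    stats_df = pd.DataFrame(rows).T[["mean", "sd", "sem", "n"]]
    tot_exc = float(table["t_excursion"].sum())
    tot_shrink = float(table["t_shrink"].sum())
    tot_life = float(table["lifetime"].sum())
    pooled = {
        "f_cat": 60.0 * table["n_cat"].sum() / tot_exc if tot_exc > 0 else np.nan,
        "f_res": 60.0 * table["n_res"].sum() / tot_shrink if tot_shrink > 0 else np.nan,
        "pause_fraction": float(table["t_pause"].sum() / tot_life) if tot_life > 0 else np.nan,
    }
    return ConditionSummary(
        label=label, n_microtubules=len(summaries),
        stats=stats_df, pooled=pooled, table=table,
    )


@dataclass
class ComparisonResult:
    """Many-to-one comparison of conditions against a reference.

    ``table`` is tidy: condition, statistic, fold_change (ratio of condition
    mean to reference mean), p_adj (adjusted per the chosen method; NaN for
    the reference itself), method, alpha.
    """

    reference: str
    method: str
    alpha: float
    table: pd.DataFrame


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def _perm_maxt(ref: np.ndarray, groups: list[np.ndarray], n_perm: int,
               rng: np.random.Generator) -> np.ndarray:
    """Many-to-one max-|t| permutation adjustment (strong FWER control)."""
    def tstat(a, b):
        na, nb = a.size, b.size
        sp = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        if sp <= 0:
            return 0.0
        return (a.mean() - b.mean()) / np.sqrt(sp * (1 / na + 1 / nb))

    obs = np.array([abs(tstat(g, ref)) for g in groups])
    pooled = np.concatenate([ref] + list(groups))
    sizes = [ref.size] + [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    exceed = np.zeros(len(groups))
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, splits)
        mx = max(abs(tstat(p, parts[0])) for p in parts[1:])
        exceed += mx >= obs - 1e-12
    return (1.0 + exceed) / (n_perm + 1.0)


def compare_conditions(
    conditions: list[ConditionSummary],
    reference: str,
    method: str = "dunnett",
    alpha: float = 0.01,
    statistics: list[str] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ComparisonResult:
    """Fold-changes and many-to-one adjusted p-values against a reference.

    Methods: ``dunnett`` (many-to-one parametric), ``anova`` (one-way ANOVA
    followed by pairwise t vs reference, Holm-adjusted), ``kruskal_wallis``
    (rank analogue with Mann-Whitney pairwise, Holm-adjusted), ``t_test``
    (unadjusted pairwise unpaired t), ``permutation`` (max-|t| resampling,
    ``n_permutations`` draws).
    """
    statistics = statistics or ["growth_rate", "f_cat", "f_res", "pause_pct"]
    by_label = {c.label: c for c in conditions}
    if reference not in by_label:
        raise StatsError(f"reference condition {reference!r} not found")
    if method not in ("dunnett", "anova", "kruskal_wallis", "t_test", "permutation"):
        raise StatsError(f"unknown method {method!r}")
    ref = by_label[reference]
    others = [c for c in conditions if c.label != reference]
    rng = np.random.default_rng(seed)

    rows = []
    for stat in statistics:
        ref_vals = ref.table[stat].dropna().to_numpy(dtype=float)
        samples = [c.table[stat].dropna().to_numpy(dtype=float) for c in others]
        if method in ("dunnett", "anova", "t_test", "permutation"):
            for lbl, s in zip([reference] + [c.label for c in others],
                              [ref_vals] + samples):
                if s.size < 2:
                    raise StatsError(
                        f"condition {lbl!r} has n<2 non-missing values of {stat!r}; "
                        f"method {method!r} requires a variance"
                    )
        ref_mean = float(np.mean(ref_vals)) if ref_vals.size else np.nan
        if method == "dunnett":
            res = sps.dunnett(*samples, control=ref_vals)
            pvals = np.asarray(res.pvalue, dtype=float)
        elif method == "t_test":
            pvals = np.array([sps.ttest_ind(s, ref_vals).pvalue for s in samples])
        elif method == "anova":
            pvals = _holm(np.array([sps.ttest_ind(s, ref_vals).pvalue for s in samples]))
        elif method == "kruskal_wallis":
            pvals = _holm(np.array([
                sps.mannwhitneyu(s, ref_vals, alternative="two-sided").pvalue
                for s in samples
            ]))
        else:  # permutation
            pvals = _perm_maxt(ref_vals, samples, n_permutations, rng)
        rows.append({"condition": reference, "statistic": stat,
                     "fold_change": 1.0, "p_adj": np.nan})
        for c, p in zip(others, pvals):
            mean = float(c.table[stat].dropna().mean())
            rows.append({
                "condition": c.label, "statistic": stat,
                "fold_change": mean / ref_mean if ref_mean not in (0.0,) and np.isfinite(ref_mean) else np.nan,
                "p_adj": float(p),
            })
    table = pd.DataFrame(rows)
    table["method"] = method
    table["alpha"] = alpha
    return ComparisonResult(reference=reference, method=method, alpha=alpha, table=table)
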