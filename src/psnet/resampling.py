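"""Size-matched resampling nulls and statistical comparison.

To compare a diagnosis-subgroup network with the all-patients network
despite differing patient counts, the all-patients cohort is repeatedly
downsampled (uniformly, without replacement) to the subgroup's patient
count; each sample is rebuilt into a sharing network with the *same*
threshold and isolate policy and frozen professional attributes, and the
resulting distribution of each statistic serves as the null.

The observed subgroup value is then tested against the M sampled values
with a two-sided one-sample Wilcoxon signed-rank test (zero differences
dropped) and an exact sign test ("nonparametric median test").  Note that
because the observed value is itself a network statistic on the same
scale as the null draws, these tests are anticonservative by
construction; :func:`compare_stat` additionally reports an empirical
rank (Monte Carlo) p-value, which is uniform under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from psnet import metrics as _metrics
from psnet import network as _network
from psnet.metrics import SCALAR_STATS


@dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray
    n_patients: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        finite = self.values[np.isfinite(self.values)]
        return float(finite.mean()) if finite.size else float("nan")

    @property
    def median(self) -> float:
        finite = self.values[np.isfinite(self.values)]
        return float(np.median(finite)) if finite.size else float("nan")


@dataclass
class ComparisonResult:
    statistic: str
    observed: float
    null_mean: float
    null_median: float
    wilcoxon_p: float
    median_test_p: float
    rank_p: float
    degenerate: bool = False


def sample_matched_cohort(
    all_visits: pd.DataFrame, n_patients: int, seed: int
) -> pd.DataFrame:
    """All visits of a uniform without-replacement sample of patients."""
    patients = np.array(sorted(all_visits["patient_id"].unique()))
    if n_patients > patients.size:
        raise ValueError(
            f"n_patients={n_patients} exceeds the {patients.size} available patients"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(patients, size=n_patients, replace=False)
    return all_visits[all_visits["patient_id"].isin(set(chosen))].copy()


def null_distribution(
    all_visits: pd.DataFrame,
    professionals: pd.DataFrame,
    n_patients: int,
    M: int = 100,
    seed: int = 0,
    min_shared: int = 5,
    keep_isolates: bool = True,
    statistics: Sequence[str] | None = None,
) -> dict[str, NullDistribution]:
    """M seeded downsampled networks -> per-statistic null value vectors.

    Professional attributes are frozen (resolved once on the full cohort)
    and passed in; patient-level exclusions are NOT re-run inside samples.
    ``statistics`` may restrict computation (e.g. skip betweenness for
    speed); default is every scalar statistic plus the relative ratios.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(M)
    wanted = set(statistics) if statistics is not None else None
    with_btw = wanted is None or any("betweenness" in s for s in wanted)
    collected: dict[str, list[float]] = {}
    for m in range(M):
        draw_seed = int(child_seeds[m].generate_state(1)[0])
        sample = sample_matched_cohort(all_visits, n_patients, seed=draw_seed)
        net = _network.build_sharing_network(
            sample,
            min_shared=min_shared,
            keep_isolates=keep_isolates,
            professionals=professionals,
        )
        stats_ = _metrics.network_summary(net, with_betweenness=with_btw)
        row = stats_.to_row()
        for name, value in row.items():
            if wanted is not None and name not in wanted:
                continue
            collected.setdefault(name, []).append(float(value))
    return {
        name: NullDistribution(name, np.array(vals), n_patients, seed)
        for name, vals in collected.items()
    }


def compare_stat(observed: float, null: NullDistribution) -> ComparisonResult:
    """Two-sided tests of the M null values against the observed value.

    wilcoxon_p: one-sample Wilcoxon signed-rank of (null - observed)
    against location 0, zero differences dropped.  median_test_p: exact
    sign test (binomial on values above/below the observed, ties
    dropped).  rank_p: 2 * min(rank tail probabilities) of the observed
    among the null values, the exchangeability-valid alternative.
    """
    values = np.asarray(null.values, dtype=float)
    if values.size < 10:
        raise ValueError("null distribution needs >= 10 values")
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    diffs = values - observed
    nonzero = diffs[diffs != 0]
    degenerate = nonzero.size == 0
    if degenerate:
        wilcoxon_p = 1.0
        median_test_p = 1.0
    else:
        wilcoxon_p = float(
            sps.wilcoxon(nonzero, alternative="two-sided").pvalue
        )
        k_above = int(np.sum(nonzero > 0))
        median_test_p = float(sps.binomtest(k_above, nonzero.size, 0.5).pvalue)
    n_below = int(np.sum(values < observed))
    n_above = int(np.sum(values > observed))
    lower = (n_below + 1) / (values.size + 1)
    upper = (n_above + 1) / (values.size + 1)
    rank_p = min(1.0, 2.0 * min(lower, upper))
    return ComparisonResult(
        statistic=null.statistic,
        observed=float(observed),
        null_mean=null.mean,
        null_median=null.median,
        wilcoxon_p=wilcoxon_p,
        median_test_p=median_test_p,
        rank_p=rank_p,
        degenerate=degenerate,
    )


def comparison_table(
    observed: _metrics.NetworkStats,
    nulls: dict[str, NullDistribution],
) -> pd.DataFrame:
    """Comparison report: one row per statistic available in both."""
    obs_row = observed.to_row()
    rows = []
    for name, null in nulls.items():
        if name not in obs_row or not np.isfinite(obs_row[name]):
            continue
        r = compare_stat(obs_row[name], null)
        rows.append(
            {
                "statistic": name,
                "null_mean": r.null_mean,
                "null_median": r.null_median,
                "observed": r.observed,
                "wilcoxon_p": r.wilcoxon_p,
                "median_test_p": r.median_test_p,
                "rank_p": r.rank_p,
                "degenerate": r.degenerate,
            }
        )
    order = {s: i for i, s in enumerate(SCALAR_STATS)}
    rows.sort(key=lambda r: (order.get(r["statistic"], 99), r["statistic"]))
    return pd.DataFrame(rows)
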