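"""Hit selection, matched/random control construction, and replication.

Season-associated CpGs are enriched for intermediate methylation, so any
downstream comparison risks reflecting the distributional properties of
the hits rather than their biology. Matched controls — background CpGs
whose methylation beta distribution is indistinguishable from a hit's by
a two-sample Kolmogorov-Smirnov test — address this; random controls
provide an unmatched reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CpGSet:
    """A labelled set of CpG identifiers with provenance.

    ``provenance`` records the thresholds and seed that produced the set
    so the selection is reproducible from the stored object alone.
    """

    label: str
    cpg_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cpg_ids = list(self.cpg_ids)
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("CpG ids must be unique")

    def __len__(self):
        return len(self.cpg_ids)

    def __contains__(self, item):
        return item in set(self.cpg_ids)


@dataclass
class ReplicationReport:
    """Cross-dataset replication and attenuation summary."""

    n_shared: int
    peak_day_rho: float
    peak_day_p: float
    amplitude_deltas: pd.Series
    wilcoxon_stat: float
    wilcoxon_p: float
    n_replicated: int


def select_soc_cpgs(ewas: pd.DataFrame, fdr_threshold: float = 0.05,
                    min_amplitude_pct: float = 4.0) -> CpGSet:
    """Select seasonal hits: FDR below threshold AND amplitude at least
    ``min_amplitude_pct`` percent methylation.

    A pure filter over the EWAS table; the thresholds are recorded in the
    returned set's provenance.
    """
    sel = (ewas["q_value"] < fdr_threshold) & (ewas["amplitude_pct"] >= min_amplitude_pct)
    return CpGSet(
        label="soc_cpg",
        cpg_ids=ewas.index[sel].tolist(),
        provenance={"fdr_threshold": fdr_threshold,
                    "min_amplitude_pct": min_amplitude_pct},
    )


def _exclusion_ids(exclusions) -> set:
    out = set()
    for e in exclusions or []:
        out.update(e.cpg_ids if isinstance(e, CpGSet) else e)
    return out


def select_matched_controls(targets: CpGSet, background: pd.DataFrame,
                            exclusions=None, ks_p_threshold: float = 0.1,
                            seed: int = 0) -> CpGSet:
    """One distribution-matched control CpG per target.

    Candidates are drawn without replacement from the background matrix
    (samples x CpGs betas), excluding the targets themselves and any
    CpG in ``exclusions``. Matching is greedy in shuffled target order:
    the first candidate whose beta distribution is not distinguishable
    from the target's by a two-sided two-sample KS test (p > threshold)
    is accepted and removed from the pool.

    Raises
    ------
    ValueError
        If the candidate pool is exhausted before some target is matched
        (the error names the target).
    """
    rng = np.random.default_rng(seed)
    excluded = _exclusion_ids(exclusions) | set(targets.cpg_ids)
    pool = [c for c in background.columns if c not in excluded]
    if len(pool) < len(targets):
        raise ValueError("background smaller than target set after exclusions")
    pool = list(rng.permutation(pool))
    order = list(rng.permutation(targets.cpg_ids))
    assigned: dict = {}
    taken: set = set()
    for tgt in order:
        tvec = background[tgt].dropna().to_numpy()
        found = None
        for cand in pool:
            if cand in taken:
                continue
            cvec = background[cand].dropna().to_numpy()
            if stats.ks_2samp(tvec, cvec).pvalue > ks_p_threshold:
                found = cand
                break
        if found is None:
            raise ValueError(f"no admissible matched control for target {tgt!r}")
        assigned[tgt] = found
        taken.add(found)
    controls = [assigned[t] for t in targets.cpg_ids]
    return CpGSet(
        label="matched_control", cpg_ids=controls,
        provenance={"ks_p_threshold": ks_p_threshold, "seed": seed,
                    "targets": list(targets.cpg_ids)},
    )


def select_random_controls(n: int, background, exclusions=None,
                           seed: int = 0) -> CpGSet:
    """Uniform sample of ``n`` control CpGs from background, without
    replacement, excluding any CpG in ``exclusions``."""
    ids = list(getattr(background, "columns", background))
    excluded = _exclusion_ids(exclusions)
    pool = [c for c in ids if c not in excluded]
    if len(pool) < n:
        raise ValueError(f"background has only {len(pool)} CpGs after exclusions, need {n}")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(pool, size=n, replace=False))
    return CpGSet(label="random_control", cpg_ids=chosen,
                  provenance={"seed": seed, "n": n})


def assert_disjoint(*sets: CpGSet) -> None:
    """Raise if any two CpG sets share a member."""
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            common = set(a.cpg_ids) & set(b.cpg_ids)
            if common:
                raise AssertionError(
                    f"sets {a.label!r} and {b.label!r} overlap: {sorted(common)[:5]}")


def circular_peak_correlation(days_a, days_b, period: float = 365.0):
    """Fisher-Lee circular correlation of two vectors of peak days.

    Offered as an alternative to the linear Spearman statistic, which is
    sensitive to where the 1 January cut falls in the year.
    """
    a = 2 * np.pi * np.asarray(days_a, float) / period
    b = 2 * np.pi * np.asarray(days_b, float) / period
    num = 0.0
    da = np.subtract.outer(a, a)
    db = np.subtract.outer(b, b)
    iu = np.triu_indices(len(a), 1)
    num = np.sum(np.sin(da[iu]) * np.sin(db[iu]))
    den = np.sqrt(np.sum(np.sin(da[iu]) ** 2) * np.sum(np.sin(db[iu]) ** 2))
    return float(num / den) if den > 0 else np.nan


def replication_stats(ewas_a: pd.DataFrame, ewas_b: pd.DataFrame,
                      cpgs: CpGSet, fdr_threshold: float = 0.05,
                      circular: bool = False) -> ReplicationReport:
    """Cross-dataset replication and attenuation statistics.

    Over the CpGs present in both tables: Spearman correlation of peak
    days (linear day-of-year values by default; Fisher-Lee circular
    correlation if ``circular``), paired amplitude deltas (b - a) with a
    two-sided Wilcoxon signed-rank test (Pratt zero handling; all-zero
    deltas report p = 1), and the count replicating at FDR < threshold
    in table b.
    """
    shared = [c for c in cpgs.cpg_ids if c in ewas_a.index and c in ewas_b.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 CpGs shared between the two tables")
    a = ewas_a.loc[shared]
    b = ewas_b.loc[shared]
    if circular:
        rho = circular_peak_correlation(a["peak_day"], b["peak_day"])
        rho_p = np.nan
    else:
        rho, rho_p = stats.spearmanr(a["peak_day"], b["peak_day"])
    deltas = (b["amplitude_pct"] - a["amplitude_pct"]).rename("amplitude_delta")
    if np.allclose(deltas, 0.0):
        w_stat, w_p = 0.0, 1.0
    else:
        res = stats.wilcoxon(deltas, zero_method="pratt", alternative="two-sided")
        w_stat, w_p = float(res.statistic), float(res.pvalue)
    n_rep = int((b["q_value"] < fdr_threshold).sum())
    return ReplicationReport(
        n_shared=len(shared), peak_day_rho=float(rho), peak_day_p=float(rho_p),
        amplitude_deltas=deltas, wilcoxon_stat=w_stat, wilcoxon_p=w_p,
        n_replicated=n_rep,
    )
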