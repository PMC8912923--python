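"""Genomic context of seasonal hits: clustering, enrichment, gametes.

CpGs that sit within a few kilobases of each other tend to carry the
same signal, so enrichment tests over raw CpG sets double-count
clustered loci. Clusters are formed by single-linkage chaining of CpGs
whose nearest neighbour is within a maximum gap (default 5 kbp);
cluster-adjusted analyses sample one CpG per cluster ("de-clustering").

Annotation tracks are either genomic intervals (0-based, half-open, as
in BED) or explicit CpG-id sets. Enrichment of a CpG set against a
track uses a two-sided Fisher exact test on the 2x2 overlap table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hits import CpGSet

MAX_CLUSTER_GAP_BP = 5000


@dataclass
class CpGCluster:
    chrom: str
    cpg_ids: list
    span_bp: int

    @property
    def is_singleton(self) -> bool:
        return len(self.cpg_ids) == 1


@dataclass
class AnnotationTrack:
    """Genomic intervals (0-based half-open) or a CpG-id set.

    Exactly one of ``intervals`` (DataFrame with chrom/start/end) and
    ``cpg_ids`` should be provided.
    """

    name: str
    intervals: pd.DataFrame | None = None
    cpg_ids: set | None = None

    def __post_init__(self):
        if (self.intervals is None) == (self.cpg_ids is None):
            raise ValueError("provide exactly one of intervals or cpg_ids")
        if self.intervals is not None:
            iv = self.intervals
            if (iv["start"] < 0).any() or (iv["start"] >= iv["end"]).any():
                raise ValueError("intervals must satisfy 0 <= start < end")
        if self.cpg_ids is not None:
            self.cpg_ids = set(self.cpg_ids)


@dataclass
class EnrichmentResult:
    set_label: str
    track_name: str
    fold: float
    p_value: float
    set_overlap: int
    set_total: int
    bg_overlap: int
    bg_total: int
    cluster_adjusted: bool = False


@dataclass
class GameteStatus:
    cpg_id: str
    sperm_pct: float
    oocyte_pct: float
    status: str


def build_clusters(coordinates: pd.DataFrame,
                   max_gap_bp: int = MAX_CLUSTER_GAP_BP) -> list[CpGCluster]:
    """Single-linkage CpG clusters with inter-CpG gap <= ``max_gap_bp``.

    ``coordinates`` is a frame indexed by CpG id with ``chrom`` and
    ``pos`` (1-based) columns. Every CpG lands in exactly one cluster;
    lone CpGs become singletons. The inclusive gap rule means positions
    exactly ``max_gap_bp`` apart chain together.

    Raises
    ------
    ValueError
        On duplicate (chrom, pos) pairs.
    """
    if coordinates[["chrom", "pos"]].duplicated().any():
        dup = coordinates[coordinates[["chrom", "pos"]].duplicated()].index.tolist()
        raise ValueError(f"duplicate (chrom, pos) coordinates: {dup[:5]}")
    clusters: list[CpGCluster] = []
    for chrom, grp in coordinates.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        ids = grp.index.to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp) + 1
        for seg_ids, seg_pos in zip(np.split(ids, breaks), np.split(pos, breaks)):
            clusters.append(CpGCluster(chrom=str(chrom), cpg_ids=list(seg_ids),
                                       span_bp=int(seg_pos[-1] - seg_pos[0])))
    return clusters


def decluster(cpg_set, clusters: list[CpGCluster], seed: int = 0) -> CpGSet:
    """Sample one CpG per cluster; singletons always pass through.

    Only cluster members that are in ``cpg_set`` are candidates; a
    cluster with several set members contributes exactly one of them.
    Deterministic under ``seed``.
    """
    ids = list(cpg_set.cpg_ids) if isinstance(cpg_set, CpGSet) else list(cpg_set)
    id_set = set(ids)
    covered = set()
    for cl in clusters:
        covered.update(cl.cpg_ids)
    missing = id_set - covered
    if missing:
        raise ValueError(f"CpGs absent from the clustering: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    chosen = []
    for cl in clusters:
        members = [c for c in cl.cpg_ids if c in id_set]
        if not members:
            continue
        if len(members) == 1:
            chosen.append(members[0])
        else:
            chosen.append(members[int(rng.integers(len(members)))])
    label = cpg_set.label if isinstance(cpg_set, CpGSet) else "custom"
    prov = dict(getattr(cpg_set, "provenance", {}))
    prov.update({"declustered": True, "seed": seed})
    return CpGSet(label=label, cpg_ids=chosen, provenance=prov)


def _merge_intervals(iv: pd.DataFrame):
    """Per-chrom sorted, merged (start, end) arrays."""
    merged = {}
    for chrom, grp in iv.groupby("chrom"):
        grp = grp.sort_values("start")
        starts, ends = [], []
        for s, e in zip(grp["start"], grp["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def track_distances(coordinates: pd.DataFrame, track: AnnotationTrack) -> pd.Series:
    """Distance (bp) from each CpG to the nearest track interval edge.

    A CpG inside an interval has distance 0; CpGs on chromosomes with no
    track interval get +inf. For CpG-id-set tracks the distance is 0 for
    members and +inf otherwise.
    """
    if track.cpg_ids is not None:
        d = np.where(coordinates.index.isin(track.cpg_ids), 0.0, np.inf)
        return pd.Series(d, index=coordinates.index)
    merged = _merge_intervals(track.intervals)
    out = np.full(len(coordinates), np.inf)
    pos0 = coordinates["pos"].to_numpy() - 1  # 1-based CpG -> 0-based
    chroms = coordinates["chrom"].to_numpy()
    for chrom, (starts, ends) in merged.items():
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) == 0:
            continue
        p = pos0[sel]
        i = np.searchsorted(starts, p, side="right")
        dist = np.full(len(p), np.inf)
        has_prev = i > 0
        prev = np.clip(i - 1, 0, None)
        inside = has_prev & (p < ends[prev])
        dist[inside] = 0.0
        gap_prev = np.where(has_prev, p - (ends[prev] - 1), np.inf)
        gap_next = np.where(i < len(starts), starts[np.clip(i, 0, len(starts) - 1)] - p, np.inf)
        dist = np.where(inside, 0.0, np.minimum(gap_prev, gap_next))
        out[sel] = dist
    return pd.Series(out, index=coordinates.index)


def overlap_enrichment(cpg_set, track: AnnotationTrack, background,
                       coordinates: pd.DataFrame | None = None,
                       proximity_bp: int = 0,
                       cluster_adjusted: bool = False) -> EnrichmentResult:
    """Fold enrichment and Fisher exact p of a CpG set against a track.

    A CpG "overlaps" the track if it lies within ``proximity_bp`` of any
    interval (0 = direct overlap) or is a member of an id-set track.
    Fold is ``(set_overlap/set_total) / (bg_overlap/bg_total)`` with the
    background including the set; the two-sided Fisher test is on set vs
    background-minus-set. With no background overlap the fold is NaN but
    the Fisher p is still reported.

    The set must be a subset of the background.
    """
    set_ids = list(cpg_set.cpg_ids) if isinstance(cpg_set, CpGSet) else list(cpg_set)
    bg_ids = list(background.cpg_ids) if isinstance(background, CpGSet) else list(background)
    if not set(set_ids) <= set(bg_ids):
        raise ValueError("CpG set must be a subset of the background")
    if track.cpg_ids is not None and proximity_bp == 0:
        overlap = pd.Series(pd.Index(bg_ids).isin(track.cpg_ids), index=bg_ids)
    else:
        if coordinates is None:
            raise ValueError("interval tracks / proximity require CpG coordinates")
        dist = track_distances(coordinates.loc[bg_ids], track)
        overlap = dist <= proximity_bp
    set_total = len(set_ids)
    bg_total = len(bg_ids)
    set_ov = int(overlap.loc[set_ids].sum())
    bg_ov = int(overlap.sum())
    rest_ov = bg_ov - set_ov
    rest_total = bg_total - set_total
    table = [[set_ov, set_total - set_ov], [rest_ov, rest_total - rest_ov]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    fold = np.nan
    if bg_ov > 0:
        fold = (set_ov / set_total) / (bg_ov / bg_total)
    label = cpg_set.label if isinstance(cpg_set, CpGSet) else "custom"
    return EnrichmentResult(set_label=label, track_name=track.name, fold=fold,
                            p_value=float(p), set_overlap=set_ov,
                            set_total=set_total, bg_overlap=bg_ov,
                            bg_total=bg_total, cluster_adjusted=cluster_adjusted)


def cluster_adjusted_enrichment(cpg_set, track: AnnotationTrack, background,
                                coordinates: pd.DataFrame,
                                max_gap_bp: int = MAX_CLUSTER_GAP_BP,
                                proximity_bp: int = 0, n_draws: int = 100,
                                seed: int = 0) -> EnrichmentResult:
    """Median enrichment over repeated de-clustered draws.

    Both the set and the background are de-clustered (one CpG per
    cluster) before each enrichment computation; the median fold and
    median p over ``n_draws`` seeded draws are reported, so a single
    unlucky within-cluster sample does not drive the result.
    """
    set_ids = set(cpg_set.cpg_ids) if isinstance(cpg_set, CpGSet) else set(cpg_set)
    bg_ids = list(background.cpg_ids) if isinstance(background, CpGSet) else list(background)
    clusters = build_clusters(coordinates.loc[bg_ids], max_gap_bp)
    folds, ps, results = [], [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_draws):
        # one representative per background cluster; clusters containing set
        # members are represented by one of those members so that the
        # de-clustered set remains a subset of the de-clustered background
        set_d, bg_d = [], []
        for cl in clusters:
            members = [c for c in cl.cpg_ids if c in set_ids]
            if members:
                pick = members[int(rng.integers(len(members)))]
                set_d.append(pick)
            else:
                pick = cl.cpg_ids[int(rng.integers(len(cl.cpg_ids)))]
            bg_d.append(pick)
        res = overlap_enrichment(set_d, track, bg_d, coordinates,
                                 proximity_bp, cluster_adjusted=True)
        folds.append(res.fold)
        ps.append(res.p_value)
        results.append(res)
    med = results[0]
    return EnrichmentResult(
        set_label=med.set_label, track_name=track.name,
        fold=float(np.nanmedian(folds)), p_value=float(np.median(ps)),
        set_overlap=med.set_overlap, set_total=med.set_total,
        bg_overlap=med.bg_overlap, bg_total=med.bg_total, cluster_adjusted=True)


def proximity_curve(cpg_set, coordinates: pd.DataFrame, track: AnnotationTrack,
                    distances, n_boot: int = 1000, seed: int = 0,
                    declustered: bool = True,
                    max_gap_bp: int = MAX_CLUSTER_GAP_BP) -> pd.DataFrame:
    """Proportion of a CpG set within each distance of a track, with CIs.

    For each distance d, the proportion of the (optionally de-clustered)
    set lying within d bp of a track interval is reported with a
    bootstrap percentile 95% CI over ``n_boot`` resamples of the CpG set.

    Returns a frame with columns distance, proportion, ci_low, ci_high;
    proportions are non-decreasing in distance by construction.
    """
    ids = list(cpg_set.cpg_ids) if isinstance(cpg_set, CpGSet) else list(cpg_set)
    if len(ids) == 0:
        raise ValueError("empty CpG set")
    distances = np.asarray(sorted(distances), dtype=float)
    if (distances <= 0).any():
        raise ValueError("distances must be positive")
    rng = np.random.default_rng(seed)
    if declustered:
        clusters = build_clusters(coordinates.loc[ids], max_gap_bp)
        ids = decluster(ids, clusters, seed=int(rng.integers(2 ** 31))).cpg_ids
    d = track_distances(coordinates.loc[ids], track).to_numpy()
    n = len(d)
    rows = []
    for dist in distances:
        hit = d <= dist
        prop = hit.mean()
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = hit[idx].mean()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((dist, prop, lo, hi))
    return pd.DataFrame(rows, columns=["distance", "proportion", "ci_low", "ci_high"])


def classify_gamete_status(sperm_pct: float, oocyte_pct: float,
                           cpg_id: str = "") -> GameteStatus:
    """Classify a CpG by its gametic methylation percentages.

    - ``oo_gDMR``: sperm < 25% and oocyte > 75% (oocyte-methylated
      germline DMR);
    - ``sperm_gDMR``: oocyte < 25% and sperm > 75% (the symmetric case);
    - ``sperm_hypo_only``: sperm <= 25% without oocyte hypermethylation;
    - ``none`` otherwise.

    The sperm-hypomethylation threshold is inclusive (<= 25) while the
    oo-gDMR sperm condition is strict (< 25); a CpG at exactly 25% sperm
    methylation can therefore be sperm_hypo_only but never oo_gDMR.
    """
    for v in (sperm_pct, oocyte_pct):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"gamete methylation {v} outside [0, 100]")
    if sperm_pct < 25.0 and oocyte_pct > 75.0:
        status = "oo_gDMR"
    elif oocyte_pct < 25.0 and sperm_pct > 75.0:
        status = "sperm_gDMR"
    elif sperm_pct <= 25.0:
        status = "sperm_hypo_only"
    else:
        status = "none"
    return GameteStatus(cpg_id=cpg_id, sperm_pct=sperm_pct,
                        oocyte_pct=oocyte_pct, status=status)
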