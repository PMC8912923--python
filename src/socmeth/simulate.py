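"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a year-round-conception child cohort measured on
a methylation array: beta-valued methylation with intermediately
methylated "hotspot" CpGs, a sinusoidal conception-date effect injected
on the logit2 (M-value) scale, additive covariate / batch / latent
cell-composition structure, Hardy-Weinberg genotypes passing the MAF
and homozygote-count filters with optional spiked cis-mQTL effects,
clustered genomic CpG positions, and an annotation track whose overlap
with hit CpGs exceeds background by a configurable fold. A truth table
per CpG (true amplitude, peak day, mQTL assignment) enables power and
recovery studies for every downstream stage.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, SampleMetadata
from .context import AnnotationTrack
from .mqtl import GenotypeMatrix
from .preprocess import GESTATION_DAYS, beta_to_m, conception_theta, m_to_beta

DAYS_PER_YEAR = 365.25


def logit_amplitude_for_beta_amplitude(beta_amplitude_pct: float,
                                       baseline_beta: float = 0.5) -> float:
    """Logit2 half-amplitude that yields a given beta-scale amplitude.

    The seasonal signal is injected on the M-value scale, so the
    beta-scale peak-to-nadir distance depends on the baseline. This
    solves ``m_to_beta(m0 + A) - m_to_beta(m0 - A) = amp`` for A by
    bisection (the left side is increasing in A).
    """
    amp = beta_amplitude_pct / 100.0
    m0 = beta_to_m(baseline_beta)
    lo, hi = 0.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if m_to_beta(m0 + mid) - m_to_beta(m0 - mid) < amp:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults describe a year-round-conception cohort of 250 children
    with 2000 array CpGs of which 50 carry a seasonal signal sized to a
    ~6% beta-scale amplitude at intermediate methylation, residual
    M-value noise of 0.3, a rainy-season methylation peak (day 244,
    early September), and genotypes at common SNPs (MAF 0.15-0.5) with
    cis-mQTL spiked at half the hit CpGs at an effect sized to explain
    roughly 9% of methylation variance.
    """

    n_samples: int = 250
    n_cpgs: int = 2000
    n_hit_cpgs: int = 50
    amplitude_logit: float = 0.1735
    peak_day: float | None = 244.0
    baseline_beta: float = 0.5
    noise_sd_logit: float = 0.3
    covariate_effects: dict = field(default_factory=lambda: {"sex": 0.1})
    n_batches: int = 2
    batch_effect_sd: float = 0.15
    n_cell_factors: int = 5
    cell_loading_sd: float = 0.1
    conception_concentration: float = 0.0
    n_snps: int = 100
    maf_range: tuple = (0.15, 0.5)
    mqtl_effect_logit: float = 0.146
    mqtl_hit_fraction: float = 0.5
    cluster_gap_bp: int = 5000
    clustered_hit_fraction: float = 0.5
    track_enrichment_fold: float = 10.0
    track_background_rate: float = 0.05
    years: tuple = (2010, 2011)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.baseline_beta < 1.0):
            raise ValueError("baseline_beta must lie strictly inside (0, 1)")
        if self.maf_range[0] <= 0.10 or self.maf_range[1] > 0.5:
            raise ValueError("maf_range must lie within (0.10, 0.5]")
        if self.peak_day is not None and not (0 <= self.peak_day < 365):
            raise ValueError("peak_day must lie in [0, 365)")
        if self.conception_concentration < 0:
            raise ValueError("conception_concentration must be non-negative")


@dataclass
class SimulatedCohort:
    """A generated cohort with its ground truth.

    ``truth`` is indexed by CpG id with columns is_hit, baseline_beta,
    amplitude_logit, amplitude_beta_pct, peak_day, mqtl_snp.
    """

    methylation: MethylationMatrix
    metadata: SampleMetadata
    genotypes: GenotypeMatrix
    tracks: list
    truth: pd.DataFrame
    config: SimConfig


def simulate_conception_dates(n: int, concentration: float = 0.0,
                              peak_day: float = 244.0, seed: int = 0,
                              years: tuple = (2010, 2011)) -> list[dt.date]:
    """Draw conception dates with a circular (von Mises) day-of-year law.

    ``concentration`` 0 gives uniform coverage of the year; larger
    values concentrate conceptions around ``peak_day``. The calendar
    year of each date is drawn uniformly from ``years``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    mu = 2.0 * np.pi * peak_day / DAYS_PER_YEAR - np.pi
    angles = (rng.vonmises(mu=mu, kappa=concentration, size=n) + np.pi) % (2.0 * np.pi)
    frac = angles / (2.0 * np.pi)
    out = []
    year_choices = rng.choice(list(years), size=n)
    for f, year in zip(frac, year_choices):
        year = int(year)
        year_len = (dt.date(year + 1, 1, 1) - dt.date(year, 1, 1)).days
        out.append(dt.date(year, 1, 1) + dt.timedelta(days=int(f * year_len)))
    return out


def simulate_seasonal_cpg(dates, baseline_beta: float, amplitude_logit: float,
                          peak_day: float = 244.0, noise_sd_logit: float = 0.0,
                          seed: int = 0) -> np.ndarray:
    """Beta values for one CpG with a sinusoidal conception-date effect.

    The signal is injected on the logit2 scale:

        M_i = logit2(baseline) + A * sin(theta_i - theta_peak + pi/2) + e_i

    so that methylation is maximal for conceptions at ``peak_day`` and
    minimal half a year away; e_i ~ N(0, noise_sd_logit^2). The M-values
    are inverse-transformed, so all outputs lie strictly in (0, 1).
    """
    if len(dates) == 0:
        raise ValueError("dates must be non-empty")
    if not (0.0 < baseline_beta < 1.0):
        raise ValueError("baseline_beta must lie strictly inside (0, 1)")
    if noise_sd_logit < 0:
        raise ValueError("noise_sd_logit must be non-negative")
    rng = np.random.default_rng(seed)
    theta = np.array([conception_theta(d) for d in dates])
    theta_peak = 2.0 * np.pi * peak_day / DAYS_PER_YEAR
    m = beta_to_m(baseline_beta) \
        + amplitude_logit * np.sin(theta - theta_peak + np.pi / 2.0)
    if noise_sd_logit > 0:
        m = m + rng.normal(0.0, noise_sd_logit, size=len(theta))
    return m_to_beta(m)


def simulate_genotypes(n: int, n_snps: int, maf_range=(0.15, 0.5),
                       positions=None, chroms=None, seed: int = 0,
                       max_resample: int = 1000) -> GenotypeMatrix:
    """Hardy-Weinberg dosages at common SNPs passing the analysis filters.

    Each SNP's allele frequency is drawn uniformly from ``maf_range``
    (whose lower bound must exceed 0.10) and dosages are Binomial(2, maf)
    draws. SNPs whose *empirical* MAF falls at or below 10% or with fewer
    than 10 homozygous carriers are re-drawn, so every emitted SNP passes
    the filters at the configured sample size.
    """
    if maf_range[0] <= 0.10 or maf_range[1] > 0.5:
        raise ValueError("maf_range must lie within (0.10, 0.5]")
    rng = np.random.default_rng(seed)
    cols = {}
    for s in range(n_snps):
        for attempt in range(max_resample):
            maf = rng.uniform(*maf_range)
            g = rng.binomial(2, maf, size=n)
            freq = g.mean() / 2.0
            emp_maf = min(freq, 1.0 - freq)
            n_hom = int(((g == 0) | (g == 2)).sum())
            if emp_maf > 0.10 and n_hom >= 10:
                break
        else:
            raise RuntimeError("could not draw a SNP passing filters; "
                               "sample size too small for the MAF range")
        cols[f"snp{s:05d}"] = g
    dosages = pd.DataFrame(cols, index=pd.Index([f"S{i:04d}" for i in range(n)],
                                                name="sample_id"))
    snp_ids = list(dosages.columns)
    if positions is None:
        positions = np.sort(rng.integers(1, 50_000_000, size=n_snps))
    if chroms is None:
        chroms = ["chr1"] * n_snps
    info = pd.DataFrame({"chrom": chroms, "pos": positions}, index=snp_ids)
    return GenotypeMatrix(dosages=dosages, info=info)


def place_cpgs_and_tracks(n_cpgs: int, hit_ids, cluster_gap_bp: int = 5000,
                          enrichment_fold: float = 1.0, seed: int = 0,
                          clustered_hit_fraction: float = 0.5,
                          background_rate: float = 0.05, n_chroms: int = 4):
    """CpG coordinates with cluster structure and an enriched track.

    CpG ids are ``cg0000000 .. cg{n-1}``, distributed over ``n_chroms``
    chromosomes with large inter-CpG gaps, except that a configurable
    fraction of hit CpGs is placed within ``cluster_gap_bp`` of its
    successor (forming 2-CpG clusters). The returned annotation track
    covers hit CpGs at a rate calibrated so that the fold enrichment of
    hits over the *full* background equals ``enrichment_fold`` in
    expectation.

    Returns ``(coordinates, [track])``.
    """
    if enrichment_fold < 1.0:
        raise ValueError("enrichment_fold must be >= 1")
    ids = [f"cg{i:07d}" for i in range(n_cpgs)]
    hit_ids = set(hit_ids)
    if not hit_ids <= set(ids):
        raise ValueError("hit_ids must be a subset of the generated CpG ids")
    rng = np.random.default_rng(seed)
    per_chrom = int(np.ceil(n_cpgs / n_chroms))
    chroms, positions = [], []
    cursor, chrom_i, on_chrom = 1_000_000, 0, 0
    force_close = False
    for cid in ids:
        if on_chrom >= per_chrom:
            chrom_i += 1
            on_chrom = 0
            cursor = 1_000_000
            force_close = False
        if on_chrom == 0:
            pos = cursor
        elif force_close:
            pos = cursor + int(rng.integers(500, cluster_gap_bp))
        else:
            pos = cursor + int(rng.integers(cluster_gap_bp * 4, cluster_gap_bp * 20))
        chroms.append(f"chr{chrom_i + 1}")
        positions.append(pos)
        cursor = pos
        on_chrom += 1
        force_close = (cid in hit_ids) and (rng.random() < clustered_hit_fraction)
    coords = pd.DataFrame({"chrom": chroms, "pos": positions},
                          index=pd.Index(ids, name="cpg_id"))

    n_hit = len(hit_ids)
    n_rest = n_cpgs - n_hit
    # solve p_hit so that p_hit / ((n_hit p_hit + n_rest p_bg) / n) == fold
    if enrichment_fold == 1.0:
        p_hit = background_rate
    else:
        denom = n_cpgs - enrichment_fold * n_hit
        if denom <= 0:
            raise ValueError("enrichment_fold too large for this hit fraction")
        p_hit = enrichment_fold * background_rate * n_rest / denom
        if p_hit > 1.0:
            raise ValueError("enrichment_fold too large for the background rate")
    intervals = []
    for cid in ids:
        p = p_hit if cid in hit_ids else background_rate
        if rng.random() < p:
            pos0 = coords.loc[cid, "pos"] - 1
            intervals.append((coords.loc[cid, "chrom"], max(pos0 - 50, 0), pos0 + 50))
    track = AnnotationTrack(name="sim_track", intervals=pd.DataFrame(
        intervals, columns=["chrom", "start", "end"]))
    return coords, [track]


def simulate_followup(cohort: SimulatedCohort, amplitude_scale: float = 0.5,
                      seed: int = 1) -> SimulatedCohort:
    """A follow-up measurement of the same individuals at a later age.

    Re-measures the same cohort (same individuals, conception dates,
    genotypes, CpG coordinates and truth) with the seasonal amplitude
    scaled by ``amplitude_scale`` — emulating attenuation of the
    conception-season effect with age — and fresh technical/biological
    noise (new batch, cell-factor and residual draws).
    """
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    truth = cohort.truth
    n, p = cfg.n_samples, cfg.n_cpgs
    theta = cohort.metadata["theta"].to_numpy()
    base = truth["baseline_beta"].to_numpy()
    is_hit = truth["is_hit"].to_numpy()
    peaks = np.where(is_hit, truth["peak_day"].to_numpy(), 0.0)

    M = np.tile(beta_to_m(base), (n, 1))
    theta_peak = 2.0 * np.pi * peaks / DAYS_PER_YEAR
    season = np.sin(theta[:, None] - theta_peak[None, :] + np.pi / 2.0)
    M += amplitude_scale * cfg.amplitude_logit * season * is_hit[None, :]

    meta = cohort.metadata.frame
    cov_numeric = {"sex": meta["sex"].to_numpy(dtype=float),
                   "age": meta["age"].to_numpy(dtype=float) - meta["age"].mean(),
                   "intervention": (meta["intervention"].cat.codes
                                    if hasattr(meta["intervention"], "cat")
                                    else meta["intervention"]).to_numpy(dtype=float)}
    for name, coef in (cfg.covariate_effects or {}).items():
        M += coef * cov_numeric[name][:, None]
    batch = (meta["batch"].cat.codes if hasattr(meta["batch"], "cat")
             else meta["batch"]).to_numpy()
    if cfg.n_batches > 1 and cfg.batch_effect_sd > 0:
        batch_load = rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_batches, p))
        batch_load -= batch_load.mean(axis=0, keepdims=True)
        M += batch_load[batch, :]
    if cfg.n_cell_factors > 0:
        scores = rng.normal(size=(n, cfg.n_cell_factors))
        loadings = rng.normal(0.0, cfg.cell_loading_sd, size=(p, cfg.n_cell_factors))
        M += scores @ loadings.T
    ids = list(truth.index)
    for cpg, snp in truth["mqtl_snp"].dropna().items():
        g = cohort.genotypes.dosages[snp].to_numpy(dtype=float)
        M[:, ids.index(cpg)] += cfg.mqtl_effect_logit * (g - g.mean())
    if cfg.noise_sd_logit > 0:
        M += rng.normal(0.0, cfg.noise_sd_logit, size=M.shape)

    betas = pd.DataFrame(m_to_beta(M), index=cohort.methylation.betas.index,
                         columns=cohort.methylation.betas.columns)
    new_truth = truth.copy()
    new_truth["amplitude_logit"] = truth["amplitude_logit"] * amplitude_scale
    amp_beta = (m_to_beta(beta_to_m(base) + amplitude_scale * cfg.amplitude_logit)
                - m_to_beta(beta_to_m(base) - amplitude_scale * cfg.amplitude_logit)) * 100.0
    new_truth["amplitude_beta_pct"] = np.where(is_hit, amp_beta, 0.0)
    return SimulatedCohort(
        methylation=MethylationMatrix(betas=betas,
                                      cpg_info=cohort.methylation.cpg_info),
        metadata=cohort.metadata, genotypes=cohort.genotypes,
        tracks=cohort.tracks, truth=new_truth, config=cfg)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort: methylation, metadata, genotypes, tracks.

    Deterministic given ``config.seed``; all randomness flows through a
    single generator. Covariate and cell-factor effects are additive on
    the logit2 scale; seasonal signal is carried only by the hit CpGs;
    spiked cis-mQTL SNPs are appended to the genotype panel and placed
    within the cis window of their target CpG.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sub = lambda: int(rng.integers(2 ** 31))  # noqa: E731

    dates = simulate_conception_dates(cfg.n_samples, cfg.conception_concentration,
                                      cfg.peak_day if cfg.peak_day is not None else 244.0,
                                      seed=sub(), years=cfg.years)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    sex = rng.integers(0, 2, size=cfg.n_samples)
    age = rng.normal(2.0, 0.1, size=cfg.n_samples)
    batch = rng.integers(0, cfg.n_batches, size=cfg.n_samples)
    intervention = rng.integers(0, 2, size=cfg.n_samples)
    meta = SampleMetadata(pd.DataFrame({
        "conception_date": dates,
        "collection_date": [d + dt.timedelta(days=GESTATION_DAYS + 730) for d in dates],
        "sex": sex,
        "age": age,
        "batch": pd.Categorical([f"b{b}" for b in batch]),
        "intervention": pd.Categorical([f"g{g}" for g in intervention]),
    }, index=pd.Index(sample_ids, name="sample_id")))
    theta = meta["theta"].to_numpy()

    ids = [f"cg{i:07d}" for i in range(cfg.n_cpgs)]
    hit_idx = rng.choice(cfg.n_cpgs, size=cfg.n_hit_cpgs, replace=False)
    hit_ids = {ids[i] for i in hit_idx}
    # the requested track fold may be infeasible for tiny cohorts (the
    # hit overlap probability would exceed 1); clamp to the attainable fold
    feasible = cfg.n_cpgs / (cfg.track_background_rate *
                             (cfg.n_cpgs - cfg.n_hit_cpgs) + max(cfg.n_hit_cpgs, 1))
    fold = min(cfg.track_enrichment_fold, 0.95 * feasible)
    coords, tracks = place_cpgs_and_tracks(
        cfg.n_cpgs, hit_ids, cfg.cluster_gap_bp, max(fold, 1.0),
        seed=sub(), clustered_hit_fraction=cfg.clustered_hit_fraction,
        background_rate=cfg.track_background_rate)

    # baselines: hits intermediately methylated; background a lo/hi/mid mix
    is_hit = np.zeros(cfg.n_cpgs, dtype=bool)
    is_hit[hit_idx] = True
    base = np.empty(cfg.n_cpgs)
    mix = rng.random(cfg.n_cpgs)
    base[mix < 0.4] = rng.uniform(0.05, 0.25, size=int((mix < 0.4).sum()))
    sel = (mix >= 0.4) & (mix < 0.8)
    base[sel] = rng.uniform(0.75, 0.95, size=int(sel.sum()))
    base[mix >= 0.8] = rng.uniform(0.30, 0.70, size=int((mix >= 0.8).sum()))
    spread = min(cfg.baseline_beta - 0.05, 0.95 - cfg.baseline_beta, 0.15)
    base[is_hit] = rng.uniform(cfg.baseline_beta - spread,
                               cfg.baseline_beta + spread,
                               size=cfg.n_hit_cpgs)

    if cfg.peak_day is None:
        peaks = rng.uniform(0.0, 365.0, size=cfg.n_cpgs)
    else:
        peaks = np.full(cfg.n_cpgs, float(cfg.peak_day))

    M = np.tile(beta_to_m(base), (cfg.n_samples, 1))
    theta_peak = 2.0 * np.pi * peaks / DAYS_PER_YEAR
    season = np.sin(theta[:, None] - theta_peak[None, :] + np.pi / 2.0)
    M += cfg.amplitude_logit * season * is_hit[None, :]

    cov_numeric = {"sex": sex.astype(float), "age": age - age.mean(),
                   "intervention": intervention.astype(float)}
    for name, coef in (cfg.covariate_effects or {}).items():
        if name not in cov_numeric:
            raise ValueError(f"unknown covariate effect {name!r}")
        M += coef * cov_numeric[name][:, None]

    # batch effects are probe-specific, as on real arrays: each batch
    # shifts each CpG by its own random offset
    if cfg.n_batches > 1 and cfg.batch_effect_sd > 0:
        batch_load = rng.normal(0.0, cfg.batch_effect_sd,
                                size=(cfg.n_batches, cfg.n_cpgs))
        batch_load -= batch_load.mean(axis=0, keepdims=True)
        M += batch_load[batch, :]

    if cfg.n_cell_factors > 0:
        scores = rng.normal(size=(cfg.n_samples, cfg.n_cell_factors))
        loadings = rng.normal(0.0, cfg.cell_loading_sd,
                              size=(cfg.n_cpgs, cfg.n_cell_factors))
        M += scores @ loadings.T

    genotypes = simulate_genotypes(
        cfg.n_samples, cfg.n_snps, cfg.maf_range,
        positions=np.sort(rng.integers(1, 60_000_000, size=cfg.n_snps)),
        chroms=list(rng.choice([f"chr{c + 1}" for c in range(4)], size=cfg.n_snps)),
        seed=sub())

    mqtl_map = pd.Series(pd.NA, index=ids, dtype="object")
    if cfg.mqtl_effect_logit != 0.0 and cfg.mqtl_hit_fraction > 0:
        n_spike = int(round(cfg.n_hit_cpgs * cfg.mqtl_hit_fraction))
        spike_cpgs = [ids[i] for i in hit_idx[:n_spike]]
        spike_geno = simulate_genotypes(
            cfg.n_samples, n_spike, cfg.maf_range, seed=sub(),
            positions=[int(coords.loc[c, "pos"]) + 10_000 for c in spike_cpgs],
            chroms=[coords.loc[c, "chrom"] for c in spike_cpgs])
        new_ids = [f"snp_cis_{c}" for c in spike_cpgs]
        spike_geno.dosages.columns = new_ids
        spike_geno.info.index = pd.Index(new_ids)
        for c, snp in zip(spike_cpgs, new_ids):
            g = spike_geno.dosages[snp].to_numpy(dtype=float)
            j = ids.index(c)
            M[:, j] += cfg.mqtl_effect_logit * (g - g.mean())
            mqtl_map.loc[c] = snp
        genotypes = GenotypeMatrix(
            dosages=pd.concat([genotypes.dosages, spike_geno.dosages], axis=1),
            info=pd.concat([genotypes.info[["chrom", "pos"]],
                            spike_geno.info[["chrom", "pos"]]]))

    if cfg.noise_sd_logit > 0:
        M += rng.normal(0.0, cfg.noise_sd_logit, size=M.shape)

    betas = pd.DataFrame(m_to_beta(M), index=pd.Index(sample_ids, name="sample_id"),
                         columns=pd.Index(ids, name="cpg_id"))
    methylation = MethylationMatrix(betas=betas, cpg_info=coords)

    amp_beta = (m_to_beta(beta_to_m(base) + cfg.amplitude_logit)
                - m_to_beta(beta_to_m(base) - cfg.amplitude_logit)) * 100.0
    truth = pd.DataFrame({
        "is_hit": is_hit,
        "baseline_beta": base,
        "amplitude_logit": np.where(is_hit, cfg.amplitude_logit, 0.0),
        "amplitude_beta_pct": np.where(is_hit, amp_beta, 0.0),
        "peak_day": np.where(is_hit, peaks, np.nan),
        "mqtl_snp": mqtl_map.to_numpy(),
    }, index=pd.Index(ids, name="cpg_id"))

    return SimulatedCohort(methylation=methylation, metadata=meta,
                           genotypes=genotypes, tracks=tracks, truth=truth,
                           config=cfg)
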