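"""Synthetic dormancy time-course datasets with full ground truth.

The generator emulates the statistical structure the analysis assumes: a
season-long bulk RNA-seq time course of flower buds for three cultivars
(three replicate trees at ~11 dates each), ten temporal expression
clusters whose latent profiles are smooth Gaussian bumps peaking in
successive stages, cultivar-dependent timing of post-onset development
(each cultivar traverses endodormancy at a rate set by its
dormancy-release date, shifting expression peaks like contrasted
chilling requirements do), negative-binomial read counts with per-sample
library sizes, planted marker genes, planted annotation enrichments,
logistic bud-break forcing curves, and a qPCR-like dataset for a
held-out fourth cultivar with its own calendar.

Everything is reproducible from a single seed: independent RNG streams
are spawned per output (counts, annotations, qPCR, bud break) from one
``SeedSequence``, so each output is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BudphaseError, ExpressionMatrix, validate_metadata
from .enrichment import AnnotationTable
from .phenology import BudBreakSeries, StageCalendar, assign_stage_labels

SEASON_START = pd.Timestamp("2015-07-01")

#: Sampling grid: 11 dates from midsummer organogenesis to early spring;
#: the staggered release dates fall on sampling dates, so each cultivar
#: has exactly one sample inside its release window.
DEFAULT_DATES = tuple(pd.Timestamp(d) for d in (
    "2015-07-15", "2015-08-15", "2015-09-15", "2015-10-15", "2015-11-15",
    "2015-12-01", "2015-12-15", "2016-01-15", "2016-02-15", "2016-03-08",
    "2016-03-15",
))

#: Dormancy-release dates: staggered over ten weeks like contrasted
#: early/mid/late cultivars, each on a sampling date so that the stage
#: classes sit at consistent trajectory phases across cultivars. The
#: held-out qPCR cultivar releases a further fortnight after the latest
#: training cultivar (a ~2-interval calendar extrapolation).
DEFAULT_RELEASE = {
    "cv_early": pd.Timestamp("2015-12-15"),
    "cv_mid": pd.Timestamp("2016-01-15"),
    "cv_late": pd.Timestamp("2016-02-15"),
    "cv_heldout": pd.Timestamp("2016-03-01"),
}
DEFAULT_FLOWERING = {
    "cv_early": pd.Timestamp("2016-03-20"),
    "cv_mid": pd.Timestamp("2016-04-05"),
    "cv_late": pd.Timestamp("2016-04-15"),
    "cv_heldout": pd.Timestamp("2016-04-12"),
}

#: Cluster-size proportions of a ~6700-gene DEG set partitioned into ten
#: profile clusters (a few very small clusters, several large ones).
_CLUSTER_SIZE_WEIGHTS = (1549, 70, 113, 884, 156, 989, 648, 612, 924, 739)

#: Latent-profile peak days (since SEASON_START) for the reference
#: cultivar, one per cluster, spanning midsummer to early spring.
DEFAULT_PEAK_DAYS = (19.0, 48.0, 78.0, 111.0, 140.0, 165.0, 190.0, 212.0,
                     240.0, 258.0)

#: Secondary peaks: cluster -> (day, relative weight). The default makes
#: the last cluster bimodal (high in summer organogenesis AND in spring
#: ecodormancy), a profile type seen in dormancy time courses that also
#: separates it from the neighbouring late-winter cluster.
DEFAULT_SECONDARY_PEAKS: dict[int, tuple[float, float]] = {10: (25.0, 0.8)}

MARKER_CLUSTERS = (1, 4, 5, 7, 8, 9, 10)
QPCR_REFERENCE_GENES = ("REF_RPII", "REF_EF1")


def default_calendars(release=None, flowering=None,
                      release_window_days: int = 14) -> dict[str, StageCalendar]:
    release = dict(DEFAULT_RELEASE if release is None else release)
    flowering = dict(DEFAULT_FLOWERING if flowering is None else flowering)
    return {
        cv: StageCalendar(
            cultivar=cv,
            organogenesis=("2015-07-01", "2015-08-31"),
            paradormancy=("2015-09-01", "2015-09-30"),
            endodormancy_onset="2015-10-01",
            release_date=release[cv],
            flowering_date=flowering[cv],
            release_window_days=release_window_days,
        )
        for cv in release
    }


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic dataset.

    Defaults mirror a three-cultivar, 11-date, 3-replicate design
    (~99 RNA-seq samples) with 2000 genes in ten clusters, plus a fourth
    held-out qPCR cultivar whose post-endodormancy profiles are shifted
    two fortnightly intervals (28 days) after the reference cultivar's.
    """

    n_genes: int = 2000
    n_clusters: int = 10
    cluster_sizes: tuple | None = None
    cultivars: tuple = ("cv_early", "cv_mid", "cv_late")
    qpcr_cultivar: str = "cv_heldout"
    reference_cultivar: str = "cv_mid"
    dates: tuple = DEFAULT_DATES
    replicates: int = 3
    peak_days: tuple = DEFAULT_PEAK_DAYS
    secondary_peaks: dict = field(
        default_factory=lambda: dict(DEFAULT_SECONDARY_PEAKS))
    bump_width_days: float = 21.0
    amplitude_range: tuple = (4.0, 9.0)
    base_log_mean: float = np.log(30.0)
    base_log_sd: float = 1.2
    profile_noise_sd: float = 0.12
    profile_wiggle_sd: float = 0.22
    profile_warp_sd: float = 0.25
    profile_warp_max: float = 0.4
    peak_jitter_sd_days: float = 2.5
    peak_jitter_max_days: float = 5.0
    marker_noise_sd: float = 0.05
    nb_dispersion: float | None = 100.0
    library_size_range: tuple = (8.0e6, 1.2e7)
    gene_length_range: tuple = (500, 5000)
    release_dates: dict = field(default_factory=lambda: dict(DEFAULT_RELEASE))
    flowering_dates: dict = field(default_factory=lambda: dict(DEFAULT_FLOWERING))
    release_window_days: int = 14
    # annotations
    n_sets: dict = field(default_factory=lambda: {
        "tf_target": 30, "motif": 40, "go_term": 50})
    background_rate: float = 0.10
    enrichment_fold: float = 5.0
    n_planted_per_kind: int = 3
    # qPCR
    qpcr_mult_noise_sd: float = 0.2
    qpcr_cq_sd: float = 0.2
    qpcr_tech_reps: int = 2
    # bud break
    budbreak_n_buds: int | None = 30
    budbreak_slope_days: float = 6.0
    seed: int = 0

    def resolved_cluster_sizes(self) -> np.ndarray:
        if self.cluster_sizes is not None:
            sizes = np.asarray(self.cluster_sizes, dtype=int)
            if len(sizes) != self.n_clusters or sizes.sum() != self.n_genes:
                raise BudphaseError(
                    "cluster_sizes must have n_clusters entries summing to n_genes")
            return sizes
        weights = np.asarray(_CLUSTER_SIZE_WEIGHTS[: self.n_clusters], dtype=float)
        if len(weights) < self.n_clusters:
            weights = np.r_[weights,
                            np.full(self.n_clusters - len(weights), weights.mean())]
        share = weights / weights.sum() * self.n_genes
        sizes = np.floor(share).astype(int)
        remainder = share - sizes
        for i in np.argsort(-remainder)[: self.n_genes - sizes.sum()]:
            sizes[i] += 1
        if (sizes < 1).any():
            raise BudphaseError("every cluster needs at least one gene")
        return sizes

    def validate(self) -> None:
        if len(self.peak_days) < self.n_clusters:
            raise BudphaseError("need one peak day per cluster")
        self.resolved_cluster_sizes()
        if self.enrichment_fold < 1:
            raise BudphaseError("enrichment fold must be >= 1")
        for cv in (*self.cultivars, self.qpcr_cultivar):
            if cv not in self.release_dates or cv not in self.flowering_dates:
                raise BudphaseError(f"missing release/flowering date for {cv!r}")
        if self.reference_cultivar not in self.cultivars:
            raise BudphaseError("reference cultivar must be among the cultivars")


def clean_config(**overrides) -> SimulationConfig:
    """A noiseless variant: deterministic counts, exact latent profiles."""
    base = dict(profile_noise_sd=0.0, profile_wiggle_sd=0.0,
                profile_warp_sd=0.0, peak_jitter_sd_days=0.0,
                marker_noise_sd=0.0, nb_dispersion=None,
                qpcr_mult_noise_sd=0.0, qpcr_cq_sd=0.0, budbreak_n_buds=None)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class GroundTruth:
    """Planted structure the analysis should recover."""

    gene_cluster: pd.Series  # gene_id -> cluster label 1..k
    marker_genes: dict  # cluster label -> gene_id
    family_table: pd.DataFrame
    metadata: pd.DataFrame  # with true stage labels
    calendars: dict  # cultivar -> StageCalendar
    enriched_pairs: dict = field(default_factory=dict)  # kind -> [(cluster, set)]
    gene_params: pd.DataFrame | None = None  # base/amp/jitter/noise_sd per gene
    qpcr_metadata: pd.DataFrame | None = None
    qpcr_curves: pd.DataFrame | None = None

    @property
    def release_dates(self) -> dict:
        return {cv: cal.release_date for cv, cal in self.calendars.items()}


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(stream,)))


def _gene_params(config: SimulationConfig, rng: np.random.Generator):
    """Per-gene latent-profile parameters.

    Each gene follows its cluster's bump up to a peak offset (jitter), a
    gene-specific systematic deviation (a localized multiplicative warp,
    identical across replicates and cultivars — genes track the cluster
    trend imperfectly), and per-sample lognormal noise. Markers are the
    first gene of each cluster and are the cleanest representatives:
    well expressed, no peak offset, no warp, low noise.
    """
    sizes = config.resolved_cluster_sizes()
    gene_ids = pd.Index([f"g{i:04d}" for i in range(config.n_genes)],
                        name="gene_id")
    cluster = np.repeat(np.arange(1, config.n_clusters + 1), sizes)
    assignment = pd.Series(cluster, index=gene_ids, name="cluster")

    params = pd.DataFrame(index=gene_ids)
    params["base"] = rng.normal(config.base_log_mean, config.base_log_sd,
                                config.n_genes)
    params["amp"] = rng.uniform(*config.amplitude_range, config.n_genes)
    if config.peak_jitter_sd_days > 0:
        params["jitter"] = np.clip(
            rng.normal(0.0, config.peak_jitter_sd_days, config.n_genes),
            -config.peak_jitter_max_days, config.peak_jitter_max_days)
    else:
        params["jitter"] = 0.0
    params["noise_sd"] = config.profile_noise_sd
    # per-date biological fluctuation shared by all trees and cultivars
    # (weather-driven); replicate averaging cannot remove it, so genes
    # with a large wiggle are genuinely worse cluster representatives
    params["wiggle_sd"] = config.profile_wiggle_sd
    if config.profile_warp_sd > 0:
        w = rng.normal(0.0, config.profile_warp_sd, config.n_genes)
        params["warp_w"] = np.clip(w, -config.profile_warp_max,
                                   config.profile_warp_max)
    else:
        params["warp_w"] = 0.0
    params["warp_loc"] = rng.uniform(0.0, 260.0, config.n_genes)

    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    marker_genes = {}
    for c in range(1, config.n_clusters + 1):
        g = gene_ids[starts[c - 1]]
        marker_genes[c] = g
        params.loc[g, ["base", "amp", "jitter", "noise_sd", "warp_w",
                       "wiggle_sd"]] = [
            config.base_log_mean + 2.0, float(config.amplitude_range[1]),
            0.0, config.marker_noise_sd, 0.0, 0.0]
    lengths = pd.Series(rng.integers(*config.gene_length_range, config.n_genes),
                        index=gene_ids, name="length_bp")
    return assignment, marker_genes, params, lengths


def _family_table(config: SimulationConfig, rng: np.random.Generator,
                  gene_ids: pd.Index, marker_genes: dict) -> pd.DataFrame:
    """Markers are singletons; ~10% of other genes sit in large families."""
    family_id = pd.Series([f"fam_{g}" for g in gene_ids], index=gene_ids)
    family_size = pd.Series(1, index=gene_ids, dtype=int)
    markers = set(marker_genes.values())
    candidates = [g for g in gene_ids if g not in markers]
    n_in_fams = int(0.1 * len(candidates))
    chosen = rng.choice(len(candidates), size=n_in_fams, replace=False)
    pos = 0
    fam_no = 0
    chosen_ids = [candidates[i] for i in sorted(chosen)]
    while pos < len(chosen_ids):
        size = int(rng.integers(6, 31))
        members = chosen_ids[pos: pos + size]
        for g in members:
            family_id[g] = f"FAM{fam_no:03d}"
            family_size[g] = len(members)
        pos += size
        fam_no += 1
    return pd.DataFrame({"gene_id": gene_ids, "family_id": family_id.values,
                         "family_size": family_size.values})


def _latent_abundance(config: SimulationConfig, cultivar: str,
                      dates: pd.DatetimeIndex,
                      assignment: pd.Series, params: pd.DataFrame,
                      rng: np.random.Generator,
                      n_draws: int = 1,
                      wiggle: np.ndarray | None = None) -> np.ndarray:
    """Latent (unnormalized) transcript abundance, genes x (dates*draws).

    Cultivar differences are modeled as a post-onset time warp: until
    endodormancy onset every cultivar traverses the same developmental
    trajectory (organogenesis/paradormancy are synchronous); after onset,
    a cultivar progresses at a rate inversely proportional to its
    onset-to-release span — the chilling-requirement analogue — so every
    cultivar reaches the identical latent state on its own release date.
    After release, ecodormancy progresses in real time for every cultivar
    (growth resumption is temperature-driven, shared within one orchard).
    Profile features (peaks, secondary peaks, gene warps) live on the
    reference cultivar's physiological time axis.
    """
    cal_onset = (pd.Timestamp("2015-10-01") - SEASON_START).days
    ref_release = (config.release_dates[config.reference_cultivar]
                   - SEASON_START).days
    cv_release = (config.release_dates[cultivar] - SEASON_START).days
    ref_span = ref_release - cal_onset
    cv_span = cv_release - cal_onset
    if cv_span <= 0:
        raise BudphaseError(f"{cultivar!r}: release date before onset")
    rate = ref_span / cv_span
    t = np.asarray([(d - SEASON_START).days for d in dates], dtype=float)
    tau = np.where(
        t <= cal_onset, t,
        np.where(t <= cv_release,
                 cal_onset + (t - cal_onset) * rate,
                 ref_release + (t - cv_release)))
    peaks = np.asarray(config.peak_days[: config.n_clusters])
    params = params.loc[assignment.index]
    base = params["base"].to_numpy()
    amp = params["amp"].to_numpy()
    jitter = params["jitter"].to_numpy()
    noise_sd = params["noise_sd"].to_numpy()
    warp_w = params["warp_w"].to_numpy()
    warp_loc = params["warp_loc"].to_numpy()

    gene_peak = peaks[assignment.to_numpy() - 1] + jitter
    x = (tau[None, :] - gene_peak[:, None]) / config.bump_width_days
    # bump acts affinely on abundance (peak/baseline fold change 1 + amp),
    # so all cluster members share one z-profile shape up to peak offset,
    # gene-specific warp, and noise
    bump = np.exp(-0.5 * x ** 2)
    for c, (day2, weight) in (config.secondary_peaks or {}).items():
        in_c = assignment.to_numpy() == c
        if not in_c.any():
            continue
        x2 = (tau[None, :] - (day2 + jitter[in_c][:, None])) \
            / config.bump_width_days
        bump[in_c] = bump[in_c] + weight * np.exp(-0.5 * x2 ** 2)
    shape = 1.0 + amp[:, None] * bump
    # systematic gene-specific deviation from the cluster trend: a
    # localized multiplicative warp (positive by construction), shared by
    # replicates and cultivars
    if np.any(warp_w != 0):
        xw = (tau[None, :] - warp_loc[:, None]) / config.bump_width_days
        shape = shape * np.exp(warp_w[:, None] * np.exp(-0.5 * xw ** 2))
    if wiggle is not None:
        # per-(gene, date) lognormal factor shared by every replicate tree
        shape = shape * np.exp(wiggle)
    shape = np.repeat(shape, n_draws, axis=1)
    log_base = np.repeat(base[:, None], shape.shape[1], axis=1)
    if np.any(noise_sd > 0):
        log_base = log_base + rng.normal(0.0, 1.0, shape.shape) * noise_sd[:, None]
    return np.exp(log_base) * shape


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_counts(config: SimulationConfig
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """RNA-seq count matrix + metadata + ground truth for the 3 cultivars."""
    config.validate()
    rng = _rng(config, 0)
    assignment, marker_genes, params, lengths = _gene_params(config, rng)
    family = _family_table(config, rng, assignment.index, marker_genes)
    calendars = default_calendars(config.release_dates, config.flowering_dates,
                                  config.release_window_days)

    dates = pd.DatetimeIndex(config.dates)
    # the date-level wiggle is drawn once and shared across cultivars:
    # it emulates weather-driven transcriptome fluctuations at a calendar
    # date, which affect every tree alike
    wiggle = rng.normal(0.0, 1.0, (config.n_genes, len(dates))) \
        * params["wiggle_sd"].to_numpy()[:, None]
    sample_ids, meta_rows, cols = [], [], []
    for cultivar in config.cultivars:
        a = _latent_abundance(config, cultivar, dates, assignment, params,
                              rng, n_draws=config.replicates, wiggle=wiggle)
        # column order: date-major, replicate-minor
        for di, d in enumerate(dates):
            for rep in range(1, config.replicates + 1):
                sid = f"{cultivar}_{d.strftime('%Y%m%d')}_t{rep}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "cultivar": cultivar,
                                  "tree": f"{cultivar}_tree{rep}", "date": d,
                                  "stage": pd.NA})
                cols.append(a[:, di * config.replicates + rep - 1])
    abundance = np.column_stack(cols)

    weights = abundance * lengths.to_numpy()[:, None]
    frac = weights / weights.sum(axis=0, keepdims=True)
    lib = rng.uniform(*config.library_size_range, len(sample_ids))
    mean_counts = frac * lib[None, :]
    if config.nb_dispersion is None:
        counts_arr = mean_counts
    else:
        r = float(config.nb_dispersion)
        counts_arr = rng.negative_binomial(
            r, r / (r + mean_counts)).astype(float)

    counts = ExpressionMatrix(
        pd.DataFrame(counts_arr, index=assignment.index, columns=sample_ids),
        unit="count", gene_lengths=lengths)
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    metadata = assign_stage_labels(
        metadata, {cv: calendars[cv] for cv in config.cultivars})
    truth = GroundTruth(gene_cluster=assignment, marker_genes=marker_genes,
                        family_table=family, metadata=metadata,
                        calendars=calendars, gene_params=params)
    return counts, metadata, truth


def simulate_annotations(config: SimulationConfig, truth: GroundTruth
                         ) -> dict[str, AnnotationTable]:
    """Annotation tables (TF targets, motifs, GO) with planted enrichments.

    Background membership is uniform Bernoulli(background_rate); for each
    kind, ``n_planted_per_kind`` (cluster, set) pairs carry fold x the
    background rate inside the cluster.
    """
    if config.enrichment_fold < 1:
        raise BudphaseError("enrichment fold must be >= 1")
    rng = _rng(config, 1)
    genes = truth.gene_cluster.index
    cluster = truth.gene_cluster.to_numpy()
    tables, planted = {}, {}
    target_clusters = [c for c in MARKER_CLUSTERS]
    for kind, n_sets in config.n_sets.items():
        if kind == "go_term":
            set_ids = [f"GO:{i + 1:07d}" for i in range(n_sets)]
        else:
            prefix = "TF" if kind == "tf_target" else "MOTIF"
            set_ids = [f"{prefix}{i + 1:03d}" for i in range(n_sets)]
        pairs = []
        planted_pairs = []
        for j in range(config.n_planted_per_kind):
            planted_pairs.append(
                (target_clusters[j % len(target_clusters)], set_ids[j]))
        for sid_i, sid in enumerate(set_ids):
            rate = np.full(len(genes), config.background_rate)
            for c, s in planted_pairs:
                if s == sid:
                    rate = np.where(cluster == c,
                                    min(1.0, config.enrichment_fold
                                        * config.background_rate), rate)
            member = rng.random(len(genes)) < rate
            pairs.extend({"gene_id": g, "set_id": sid}
                         for g in genes[member])
        tables[kind] = AnnotationTable(kind, pd.DataFrame(
            pairs, columns=["gene_id", "set_id"]), frozenset(genes))
        planted[kind] = planted_pairs
    truth.enriched_pairs = planted
    return tables


def simulate_qpcr(config: SimulationConfig, truth: GroundTruth,
                  gene_ids=None) -> dict:
    """Cq tables + dilution standards for the held-out qPCR cultivar.

    Latent profiles of the assayed genes (by default the planted marker
    panel; pass ``gene_ids`` to assay a selected panel instead) for the
    fourth cultivar (own calendar and post-endodormancy shift) are
    converted to Cq through planted standard curves (slope ~ -3.32, i.e.
    ~100% efficiency) with multiplicative expression noise and additive
    Cq noise; two constitutive reference genes are generated flat.
    """
    rng = _rng(config, 2)
    cultivar = config.qpcr_cultivar
    dates = pd.DatetimeIndex(config.dates)
    if gene_ids is None:
        panel_clusters = [c for c in MARKER_CLUSTERS if c <= config.n_clusters]
        marker_ids = [truth.marker_genes[c] for c in panel_clusters]
    else:
        marker_ids = list(gene_ids)
    sub = truth.gene_cluster.loc[marker_ids]

    if truth.gene_params is not None:
        params = truth.gene_params.loc[marker_ids].copy()
    else:
        params = pd.DataFrame(index=pd.Index(marker_ids))
        params["amp"] = float(np.mean(config.amplitude_range))
        params["jitter"] = 0.0
        params["warp_w"] = 0.0
        params["warp_loc"] = 0.0
        params["wiggle_sd"] = 0.0
    params["base"] = 0.0  # quantities are later ratio-normalized
    params["noise_sd"] = 0.0  # platform noise is added below
    wiggle = rng.normal(0.0, 1.0, (len(marker_ids), len(dates))) \
        * params["wiggle_sd"].to_numpy()[:, None]
    a = _latent_abundance(config, cultivar, dates, sub, params, rng,
                          n_draws=config.replicates, wiggle=wiggle)

    gene_ids = [*marker_ids, *QPCR_REFERENCE_GENES]
    latent = np.vstack([a, np.ones((len(QPCR_REFERENCE_GENES),
                                    a.shape[1]))])
    # scale per gene so sample quantities sit inside the standards range
    latent = latent / latent.mean(axis=1, keepdims=True)

    slopes = -3.32193 + rng.normal(0.0, 0.05, len(gene_ids))
    intercepts = rng.uniform(19.0, 24.0, len(gene_ids))
    curves = pd.DataFrame({"gene_id": gene_ids, "slope": slopes,
                           "intercept": intercepts})

    std_rows = []
    std_q = np.array([10.0, 1.0, 0.1, 0.01, 0.001])
    for gi, g in enumerate(gene_ids):
        cq = intercepts[gi] + slopes[gi] * np.log10(std_q)
        if config.qpcr_cq_sd > 0:
            cq = cq + rng.normal(0.0, config.qpcr_cq_sd, cq.shape)
        std_rows.extend({"gene_id": g, "dilution_quantity": q, "cq": c}
                        for q, c in zip(std_q, cq))
    standards = pd.DataFrame(std_rows)

    meta_rows, cq_rows = [], []
    for di, d in enumerate(dates):
        for rep in range(1, config.replicates + 1):
            sid = f"{cultivar}_{d.strftime('%Y%m%d')}_t{rep}"
            meta_rows.append({"sample_id": sid, "cultivar": cultivar,
                              "tree": f"{cultivar}_tree{rep}", "date": d,
                              "stage": pd.NA})
            col = di * config.replicates + rep - 1
            for gi, g in enumerate(gene_ids):
                q = latent[gi, col]
                if config.qpcr_mult_noise_sd > 0:
                    q = q * np.exp(rng.normal(0.0, config.qpcr_mult_noise_sd))
                base_cq = intercepts[gi] + slopes[gi] * np.log10(q)
                for _tech in range(config.qpcr_tech_reps):
                    cq = base_cq
                    if config.qpcr_cq_sd > 0:
                        cq = cq + rng.normal(0.0, config.qpcr_cq_sd)
                    cq_rows.append({"sample_id": sid, "gene_id": g,
                                    "cq": float(cq)})
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    metadata = assign_stage_labels(
        metadata, {cultivar: truth.calendars[cultivar]})
    truth.qpcr_metadata = metadata
    truth.qpcr_curves = curves
    return {"cq": pd.DataFrame(cq_rows), "standards": standards,
            "metadata": metadata, "curves": curves,
            "marker_genes": marker_ids,
            "reference_genes": list(QPCR_REFERENCE_GENES)}


def simulate_budbreak(config: SimulationConfig, truth: GroundTruth
                      ) -> dict[str, BudBreakSeries]:
    """Fortnightly forcing-test series with a logistic 50% crossing at the
    planted release date (binomial noise over ``budbreak_n_buds`` buds)."""
    rng = _rng(config, 3)
    out = {}
    obs_dates = pd.date_range("2015-11-01", "2016-04-01", freq="14D")
    for cultivar, cal in truth.calendars.items():
        t = np.asarray([(d - cal.release_date).days for d in obs_dates],
                       dtype=float)
        p = 100.0 / (1.0 + np.exp(-t / config.budbreak_slope_days))
        if config.budbreak_n_buds is not None:
            n = int(config.budbreak_n_buds)
            p = rng.binomial(n, p / 100.0) / n * 100.0
        out[cultivar] = BudBreakSeries(cultivar, obs_dates, p)
    return out


@dataclass
class SyntheticDataset:
    """Bundle of every synthetic output plus its ground truth."""

    config: SimulationConfig
    counts: ExpressionMatrix
    metadata: pd.DataFrame
    truth: GroundTruth
    annotations: dict
    qpcr: dict
    budbreak: dict


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    config = config or SimulationConfig()
    counts, metadata, truth = simulate_counts(config)
    annotations = simulate_annotations(config, truth)
    qpcr = simulate_qpcr(config, truth)
    budbreak = simulate_budbreak(config, truth)
    return SyntheticDataset(config=config, counts=counts, metadata=metadata,
                            truth=truth, annotations=annotations, qpcr=qpcr,
                            budbreak=budbreak)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every artifact as plain text (TSV/CSV/JSON)."""
    import json
    from pathlib import Path

    from .containers import write_gene_lengths, write_metadata
    from .phenology import write_budbreak

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.counts.to_tsv(outdir / "counts.tsv")
    write_gene_lengths(dataset.counts.gene_lengths, outdir / "lengths.tsv")
    write_metadata(dataset.metadata, outdir / "metadata.tsv")
    dataset.truth.family_table.to_csv(outdir / "families.tsv", sep="\t",
                                      index=False)
    for kind, table in dataset.annotations.items():
        table.to_tsv(outdir / f"annotations_{kind}.tsv")
    dataset.qpcr["cq"].to_csv(outdir / "qpcr_cq.csv", index=False)
    dataset.qpcr["standards"].to_csv(outdir / "standards.csv", index=False)
    write_metadata(dataset.qpcr["metadata"], outdir / "qpcr_metadata.tsv")
    write_budbreak(dataset.budbreak, outdir / "budbreak.csv")
    truth = {
        "gene_cluster": {g: int(c) for g, c
                         in dataset.truth.gene_cluster.items()},
        "marker_genes": {int(c): g for c, g
                         in dataset.truth.marker_genes.items()},
        "stages": dict(zip(dataset.metadata["sample_id"],
                           dataset.metadata["stage"].astype(str))),
        "qpcr_stages": dict(zip(dataset.qpcr["metadata"]["sample_id"],
                                dataset.qpcr["metadata"]["stage"].astype(str))),
        "calendars": {cv: cal.to_dict()
                      for cv, cal in dataset.truth.calendars.items()},
        "enriched_pairs": {k: [[int(c), s] for c, s in v]
                           for k, v in dataset.truth.enriched_pairs.items()},
        "seed": dataset.config.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
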