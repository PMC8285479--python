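"""Synthetic data generators with known ground truth for every pipeline stage.

Each generator emulates one input modality of the dormancy analyses:

* 384-well viability plates with alternating positive/negative control
  columns and compound x treatment interaction effects,
* a tumour cohort in which a latent GR-activity variable drives a gene
  signature and couples a candidate enhancer's chromatin accessibility to a
  target gene's expression against uncorrelated background enhancers,
* viewpoint-anchored 4C fragment profiles with region-localized condition
  effects,
* label-free proteomics (LFQ) matrices with intensity-dependent (MNAR)
  missingness,
* two-channel immunofluorescence images with touching nuclei, an uneven
  background gradient, and a marker-positive subpopulation.

Ground truth is always returned as a sidecar object; analysis code never
reads it.  All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

N_ROWS, N_COLS = 16, 24


@dataclass
class PlateSimConfig:
    """Simulation settings for a 384-well differential-viability screen.

    Control wells sit in two dedicated columns (1-based indices, default 2
    and 23) and alternate positive/negative down each column by row parity.
    Compound wells fill the remaining columns, one compound x concentration
    per well, replicated on ``replicate_count`` plates per arm.

    The raw signal anchors the negative control at ``baseline_viability`` and
    the positive control at ``kill_floor`` so that NPI normalization recovers
    the simulated fractional viability:
    ``raw = kill_floor + viability * (baseline - kill_floor) + noise``.
    ``interaction_set`` maps compound id -> additive viability shift applied
    in non-vehicle arms only (negative = sensitization, positive = tolerance).
    """

    n_compounds: int = 80
    concentrations: tuple[float, ...] = (1.0, 5.0)
    arms: tuple[str, ...] = ("vehicle", "pretreat")
    replicate_count: int = 3
    control_columns: tuple[int, int] = (2, 23)
    baseline_viability: float = 1000.0
    kill_floor: float = 50.0
    well_noise_sd: float = 0.05
    viability_mean: float = 0.85
    viability_sd: float = 0.15
    interaction_set: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _compound_wells(control_columns: tuple[int, int]) -> list[tuple[int, int]]:
    return [
        (r, c)
        for c in range(1, N_COLS + 1)
        if c not in control_columns
        for r in range(1, N_ROWS + 1)
    ]


def gen_plates(cfg: PlateSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate screen plates.

    Returns
    -------
    plates : long-format table (plate, row, column, role, compound,
        concentration_uM, arm, replicate, value) with raw signal.
    truth : per-compound table (compound, viability, interaction_shift).
    """
    if cfg.kill_floor >= cfg.baseline_viability:
        raise ValueError("kill_floor must be below baseline_viability")
    slots = _compound_wells(cfg.control_columns)
    per_plate = len(slots)
    needed = cfg.n_compounds * len(cfg.concentrations)
    n_plates = -(-needed // per_plate)  # ceil: plates per (arm, replicate)
    rng = np.random.default_rng(cfg.seed)

    compounds = [f"cmpd_{i:04d}" for i in range(cfg.n_compounds)]
    unknown = set(cfg.interaction_set) - set(compounds)
    if unknown:
        raise ValueError(f"interaction_set names unknown compounds: {sorted(unknown)}")
    viability = np.clip(
        rng.normal(cfg.viability_mean, cfg.viability_sd, cfg.n_compounds), 0.0, 1.2
    )
    truth = pd.DataFrame(
        {
            "compound": compounds,
            "viability": viability,
            "interaction_shift": [
                cfg.interaction_set.get(c, 0.0) for c in compounds
            ],
        }
    )
    shift = dict(zip(truth["compound"], truth["interaction_shift"]))
    viab = dict(zip(truth["compound"], truth["viability"]))

    # fixed assignment of (compound, concentration) to plate slots
    assignments = [
        (c, conc) for conc in cfg.concentrations for c in compounds
    ]
    span = cfg.baseline_viability - cfg.kill_floor
    records = []
    for arm in cfg.arms:
        treated = arm != "vehicle"
        for rep in range(1, cfg.replicate_count + 1):
            for p in range(n_plates):
                plate_id = f"{arm}_r{rep}_p{p + 1}"
                # control columns, alternating by row parity
                for col in cfg.control_columns:
                    for row in range(1, N_ROWS + 1):
                        role = "pos_ctrl" if row % 2 == 1 else "neg_ctrl"
                        mean = (
                            cfg.kill_floor if role == "pos_ctrl"
                            else cfg.baseline_viability
                        )
                        value = mean + rng.normal(0.0, cfg.well_noise_sd) * span
                        records.append(
                            (plate_id, row, col, role, "", np.nan, arm, rep, value)
                        )
                for slot, (row, col) in enumerate(slots):
                    idx = p * per_plate + slot
                    if idx >= len(assignments):
                        records.append(
                            (plate_id, row, col, "empty", "", np.nan, arm, rep,
                             np.nan)
                        )
                        continue
                    compound, conc = assignments[idx]
                    v = viab[compound] + (shift[compound] if treated else 0.0)
                    value = (
                        cfg.kill_floor
                        + v * span
                        + rng.normal(0.0, cfg.well_noise_sd) * span
                    )
                    records.append(
                        (plate_id, row, col, "compound", compound, conc, arm,
                         rep, value)
                    )
    plates = pd.DataFrame.from_records(
        records,
        columns=[
            "plate", "row", "column", "role", "compound",
            "concentration_uM", "arm", "replicate", "value",
        ],
    )
    return plates, truth


# ---------------------------------------------------------------------------
# tumour cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Simulated tumour cohort coupling enhancer accessibility to expression.

    A per-sample latent GR-activity variable ``a ~ N(0,1)`` drives the
    signature genes (``x = signature_loading * a + noise``).  GR (NR3C1)
    expression is a noisy readout of the latent activity.  The candidate
    enhancer's accessibility and the target gene's expression share a common
    component of weight ``linkage_effect``; when ``gr_gated`` the shared
    component is only active in samples whose GR expression lies in the top
    half of the cohort, reproducing the GR-dependence of the linkage.
    Background enhancers and neighbour genes are generated independently of
    the target gene.

    ``linkage_effect = 1.2`` gives an implied accessibility-expression
    correlation of b^2/(b^2+1) ~ 0.59 among linked samples at unit noise.
    """

    n_samples: int = 200
    n_signature_genes: int = 253
    n_background_enhancers: int = 306
    n_neighbor_genes: int = 4
    signature_loading: float = 1.0
    linkage_effect: float = 1.2
    gr_gated: bool = False
    gr_readout_sd: float = 0.5
    noise_sd: float = 1.0
    target_gene: str = "CDKN1C"
    gr_gene: str = "NR3C1"
    candidate_enhancer: str = "CERES"
    seed: int = 0

    # CDKN1C-proximal neighbours on chr11p15.5
    neighbor_names: tuple[str, ...] = ("KCNQ1", "SLC22A18", "PHLDA2", "NAP1L4")


@dataclass
class CohortData:
    """Expression + accessibility matrices over a shared sample set."""

    expression: pd.DataFrame      # genes x samples
    accessibility: pd.DataFrame   # enhancers x samples
    enhancer_bed: pd.DataFrame    # chrom, start, end, name (0-based half-open)
    samples: pd.DataFrame         # sample metadata


def gen_cohort(cfg: CohortSimConfig) -> tuple[CohortData, pd.DataFrame]:
    """Simulate a cohort; returns (data, truth).

    ``truth`` is a per-sample table with the latent activity, the GR gate
    indicator and the shared linkage component; its attribute
    ``truth.attrs['linked']`` records whether a true linkage was injected.
    """
    if cfg.n_samples < 4:
        raise ValueError("need >= 4 samples; downstream correlations undefined")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    latent = rng.standard_normal(n)
    gr_expr = latent + rng.normal(0.0, cfg.gr_readout_sd, n)
    if cfg.gr_gated:
        gate = (gr_expr > np.median(gr_expr)).astype(float)
    else:
        gate = np.ones(n)

    sig_names = [f"SIG{i:04d}" for i in range(cfg.n_signature_genes)]
    sig = (
        cfg.signature_loading * latent[None, :]
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_signature_genes, n))
    )

    shared = rng.standard_normal(n)
    target = (
        cfg.linkage_effect * gate * shared + rng.normal(0.0, cfg.noise_sd, n)
    )
    candidate = (
        cfg.linkage_effect * gate * shared + rng.normal(0.0, cfg.noise_sd, n)
    )
    neighbors = rng.normal(
        0.0, cfg.noise_sd, (cfg.n_neighbor_genes, n)
    )
    neighbor_names = list(cfg.neighbor_names[: cfg.n_neighbor_genes])
    neighbor_names += [
        f"NBR{i}" for i in range(len(neighbor_names), cfg.n_neighbor_genes)
    ]

    background = rng.normal(
        0.0, cfg.noise_sd, (cfg.n_background_enhancers, n)
    )
    bg_names = [f"enh_{i:04d}" for i in range(cfg.n_background_enhancers)]

    expression = pd.DataFrame(
        np.vstack([sig, target[None, :], gr_expr[None, :], neighbors]),
        index=sig_names + [cfg.target_gene, cfg.gr_gene] + neighbor_names,
        columns=samples,
    )
    accessibility = pd.DataFrame(
        np.vstack([candidate[None, :], background]),
        index=[cfg.candidate_enhancer] + bg_names,
        columns=samples,
    )
    # enhancer intervals tiled around the CDKN1C locus on chr11p15.5
    starts = 2_650_000 + 1000 * np.arange(cfg.n_background_enhancers + 1)
    enhancer_bed = pd.DataFrame(
        {
            "chrom": "chr11",
            "start": starts,
            "end": starts + 600,
            "name": [cfg.candidate_enhancer] + bg_names,
        }
    )
    meta = pd.DataFrame({"sample": samples}).set_index("sample")
    truth = pd.DataFrame(
        {
            "sample": samples,
            "latent_activity": latent,
            "gr_gate": gate,
            "shared_component": shared,
        }
    ).set_index("sample")
    truth.attrs["linked"] = cfg.linkage_effect != 0.0
    truth.attrs["signature_genes"] = sig_names
    return CohortData(expression, accessibility, enhancer_bed, meta), truth


# ---------------------------------------------------------------------------
# 4C profiles
# ---------------------------------------------------------------------------


@dataclass
class FourCSimConfig:
    """Simulated viewpoint-anchored 4C fragment profile for two conditions.

    Fragments tile one chromosome contiguously.  The baseline contact signal
    decays with distance from the viewpoint; condition 2 multiplies the
    signal by the declared effect inside each effect region and is otherwise
    exchangeable with condition 1.  ``dispersion`` is the sd of multiplicative
    log-normal noise per fragment x replicate.
    """

    n_fragments: int = 120
    chrom: str = "chr11"
    span_start: int = 2_750_000          # 0-based half-open tiling start
    fragment_length: int = 1500
    viewpoint_index: int | None = None   # default: middle fragment
    base_signal: float = 100.0
    decay_scale_bp: float = 60_000.0
    effect_regions: tuple[tuple[int, int, float], ...] = ()
    # (start, end, fold) with 1-based inclusive coordinates, as printed
    dispersion: float = 0.1
    replicate_count: int = 2
    conditions: tuple[str, str] = ("vehicle", "GC")
    seed: int = 0


def gen_fourc(cfg: FourCSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one 4C viewpoint profile under two conditions.

    Returns
    -------
    profile : tidy table (chrom, start, end, condition, replicate, signal)
        with 1-based inclusive fragment coordinates.
    truth : per-fragment table (chrom, start, end, fold) of the injected
        condition-2 fold change.
    """
    starts0 = cfg.span_start + cfg.fragment_length * np.arange(cfg.n_fragments)
    ends0 = starts0 + cfg.fragment_length
    span_end1 = int(ends0[-1])
    for rs, re, fold in cfg.effect_regions:
        if rs > re:
            raise ValueError(f"effect region start {rs} > end {re}")
        if rs < cfg.span_start + 1 or re > span_end1:
            raise ValueError(
                f"effect region {rs}-{re} outside simulated span "
                f"{cfg.span_start + 1}-{span_end1}"
            )
    mid = 0.5 * (starts0 + ends0)
    vp_index = (cfg.n_fragments // 2 if cfg.viewpoint_index is None
                else cfg.viewpoint_index)
    vp = mid[vp_index]
    base = cfg.base_signal * np.exp(-np.abs(mid - vp) / cfg.decay_scale_bp)

    fold = np.ones(cfg.n_fragments)
    for rs, re, f in cfg.effect_regions:
        inside = (mid >= rs - 1) & (mid < re)  # region converted to 0-based
        fold[inside] *= f

    rng = np.random.default_rng(cfg.seed)
    records = []
    starts1 = starts0 + 1  # emit 1-based inclusive, matching printed style
    for cond_i, cond in enumerate(cfg.conditions):
        mult = fold if cond_i == 1 else np.ones_like(fold)
        for rep in range(1, cfg.replicate_count + 1):
            noise = np.exp(rng.normal(0.0, cfg.dispersion, cfg.n_fragments))
            signal = base * mult * noise
            for i in range(cfg.n_fragments):
                records.append(
                    (cfg.chrom, int(starts1[i]), int(ends0[i]), cond, rep,
                     signal[i])
                )
    profile = pd.DataFrame.from_records(
        records, columns=["chrom", "start", "end", "condition", "replicate",
                          "signal"]
    )
    truth = pd.DataFrame(
        {"chrom": cfg.chrom, "start": starts1, "end": ends0, "fold": fold}
    )
    return profile, truth


# ---------------------------------------------------------------------------
# LFQ proteomics
# ---------------------------------------------------------------------------


@dataclass
class LFQSimConfig:
    """Simulated log2 LFQ matrix with intensity-dependent missingness.

    True protein abundances are drawn from N(abundance_mean, abundance_sd).
    A subset of proteins carries an additive log2 shift in the second group.
    Missingness is missing-not-at-random: the probability that a measurement
    drops out decreases logistically with its intensity,
    ``P(missing) = sigmoid((dropout_mid - value) / dropout_scale)``, scaled
    so that ``missing_rate = 0`` yields a complete matrix.
    """

    n_proteins: int = 1000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"vehicle": 3, "GC": 3}
    )
    n_differential: int = 50
    log2_shift: float = 2.0
    noise_sd: float = 0.3
    abundance_mean: float = 25.0
    abundance_sd: float = 3.0
    missing_rate: float = 0.2
    dropout_scale: float = 1.5
    seed: int = 0


def gen_lfq(cfg: LFQSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an LFQ matrix.

    Returns
    -------
    matrix : protein x sample log2 intensities with NaN for missing values.
    groups : table (sample, group).
    truth : per-protein table (protein, differential, true_shift).
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    samples, labels = [], []
    for g, k in cfg.group_sizes.items():
        for j in range(1, k + 1):
            samples.append(f"{g}_{j}")
            labels.append(g)
    n_s = len(samples)

    abund = rng.normal(cfg.abundance_mean, cfg.abundance_sd, cfg.n_proteins)
    diff_idx = np.arange(min(cfg.n_differential, cfg.n_proteins))
    shifts = np.zeros(cfg.n_proteins)
    shifts[diff_idx] = cfg.log2_shift
    group_arr = np.asarray(labels)
    second_group = list(cfg.group_sizes)[1] if len(cfg.group_sizes) > 1 else None
    effect = (
        (group_arr == second_group).astype(float)[None, :]
        if second_group else np.zeros((1, n_s))
    )
    values = (
        abund[:, None]
        + shifts[:, None] * effect
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_proteins, n_s))
    )
    if cfg.missing_rate > 0:
        # calibrate the dropout midpoint so the overall missing fraction
        # matches missing_rate while low intensities drop out preferentially
        mid = np.quantile(values, cfg.missing_rate) + 0.0
        p_miss = 1.0 / (1.0 + np.exp((values - mid) / cfg.dropout_scale))
        p_miss *= cfg.missing_rate / max(p_miss.mean(), 1e-12)
        values = np.where(rng.uniform(size=values.shape) < p_miss, np.nan, values)

    matrix = pd.DataFrame(values, index=proteins, columns=samples)
    groups = pd.DataFrame({"sample": samples, "group": labels})
    truth = pd.DataFrame(
        {"protein": proteins, "differential": shifts != 0.0, "true_shift": shifts}
    )
    return matrix, groups, truth


# ---------------------------------------------------------------------------
# immunofluorescence images
# ---------------------------------------------------------------------------


@dataclass
class ImageSimConfig:
    """Simulated 2-channel (nuclear / marker) immunofluorescence field.

    Nuclei are disks with a cosine-tapered edge over an additive low-frequency
    background gradient.  ``touching_fraction`` of the nuclei are placed in
    pairs overlapping by 10-20 % of radius — enough to merge under naive
    thresholding while remaining separable by watershed.  The first
    ``round(marker_positive_fraction * n_nuclei)`` nuclei are marker-positive
    (deterministic assignment); marker intensity per nucleus is constant at
    its class mean plus pixel noise.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    n_nuclei: int = 30
    radius_um: tuple[float, float] = (4.0, 6.5)
    touching_fraction: float = 0.0
    background_amplitude: float = 300.0
    nuclear_intensity: float = 3000.0
    noise_sd: float = 60.0
    marker_positive_fraction: float = 0.0
    marker_negative_mean: float = 400.0
    marker_positive_mean: float = 3000.0
    marker_sd: float = 60.0
    edge_taper_um: float = 1.0
    seed: int = 0


@dataclass
class ImageTruth:
    """Ground truth for a simulated field."""

    labels: np.ndarray          # int label map, 0 = background
    centers: np.ndarray         # (n, 2) row/col pixel coordinates
    radii_um: np.ndarray
    positive: np.ndarray        # bool per nucleus (label i -> positive[i-1])


def _place_centers(cfg: ImageSimConfig, rng: np.random.Generator):
    """Rejection-sample nucleus centers: singletons well separated, plus
    touching pairs at 10-20 % radial overlap."""
    h, w = cfg.shape
    px = cfg.pixel_size_um
    r_lo, r_hi = cfg.radius_um
    n_pairs = int(round(cfg.touching_fraction * cfg.n_nuclei / 2.0))
    n_single = cfg.n_nuclei - 2 * n_pairs
    margin = r_hi / px + 3
    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def ok(y, x, r_um, min_gap_um=2.0):
        for (cy, cx), cr in zip(centers, radii):
            d_um = np.hypot(y - cy, x - cx) * px
            if d_um < r_um + cr + min_gap_um:
                return False
        return True

    max_tries = 20000
    tries = 0
    while n_single > 0 or n_pairs > 0:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place all nuclei; lower n_nuclei or radius"
            )
        r_um = rng.uniform(r_lo, r_hi)
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if n_pairs > 0:
            r2_um = rng.uniform(r_lo, r_hi)
            overlap = rng.uniform(0.10, 0.20) * min(r_um, r2_um)
            d_px = (r_um + r2_um - 2 * overlap) / px
            theta = rng.uniform(0, 2 * np.pi)
            y2, x2 = y + d_px * np.sin(theta), x + d_px * np.cos(theta)
            if not (margin <= y2 <= h - margin and margin <= x2 <= w - margin):
                continue
            if ok(y, x, r_um + r2_um) and ok(y2, x2, r_um + r2_um):
                centers += [(y, x), (y2, x2)]
                radii += [r_um, r2_um]
                n_pairs -= 1
        else:
            if ok(y, x, r_um):
                centers.append((y, x))
                radii.append(r_um)
                n_single -= 1
    return np.asarray(centers, float), np.asarray(radii, float)


def gen_image(cfg: ImageSimConfig) -> tuple[np.ndarray, np.ndarray, ImageTruth]:
    """Simulate one field.

    Returns
    -------
    nuclear : float64 nuclear-channel image.
    marker : float64 marker-channel image.
    truth : :class:`ImageTruth` with the ground-truth label map, centers,
        radii and positivity flags.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    px = cfg.pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w]

    # low-frequency background: tilted plane plus a broad sinusoid
    gy, gx = rng.uniform(-1, 1, 2)
    background = cfg.background_amplitude * (
        0.5 + 0.25 * (gy * yy / h + gx * xx / w)
        + 0.25 * np.sin(2 * np.pi * (yy / h + 0.5 * xx / w))
    )

    nuclear = background.copy()
    marker = 0.25 * background.copy()
    labels = np.zeros(cfg.shape, dtype=np.int32)

    if cfg.n_nuclei > 0:
        centers, radii = _place_centers(cfg, rng)
        n_pos = int(round(cfg.marker_positive_fraction * cfg.n_nuclei))
        positive = np.zeros(cfg.n_nuclei, bool)
        positive[:n_pos] = True
        for i, ((cy, cx), r_um) in enumerate(zip(centers, radii), start=1):
            r_px = r_um / px
            taper = max(cfg.edge_taper_um / px, 1.0)
            d = np.hypot(yy - cy, xx - cx)
            # cosine-tapered disk profile in [0, 1]
            profile = np.clip((r_px - d) / taper, 0.0, 1.0)
            profile = 0.5 - 0.5 * np.cos(np.pi * np.clip(profile, 0, 1))
            nuclear += cfg.nuclear_intensity * profile
            inside = d <= r_px
            labels[inside] = i
            level = (
                cfg.marker_positive_mean if positive[i - 1]
                else cfg.marker_negative_mean
            )
            marker += level * profile
    else:
        centers = np.zeros((0, 2))
        radii = np.zeros(0)
        positive = np.zeros(0, bool)

    nuclear += rng.normal(0.0, cfg.noise_sd, cfg.shape)
    marker += rng.normal(0.0, cfg.marker_sd, cfg.shape)
    nuclear = np.clip(nuclear, 0, None)
    marker = np.clip(marker, 0, None)
    truth = ImageTruth(labels=labels, centers=centers, radii_um=radii,
                       positive=positive)
    return nuclear, marker, truth
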