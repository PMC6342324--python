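"""Synthetic data generators for every pipeline input.

The generators reproduce the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any external imaging data:

* per-cell allelic count tables under three generative models of single-cell
  allelic imbalance — the *coin-flip* binomial model, the *all-or-none*
  monoallelic model (observed through per-allele false-detection noise), and
  independent negative-binomial transcriptional bursting;
* binomial-thinning operators for false detection and detection efficiency;
* spatially clustered allelic identities on a simulated tissue section;
* three-channel spot fields with chromatic offset, localization jitter and
  spurious spots, with ground-truth assignments;
* single-plane grayscale images of bright RNA foci (Gaussian blobs on a
  noisy background) with a ground-truth focus table.

All generators are bit-reproducible given a seed; see :mod:`allelesim._rng`
for the stream-splitting rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._rng import stream
from .counts import make_counts, validate_counts

__all__ = [
    "GeneratorConfig",
    "NegBinParams",
    "TissueLayout",
    "SpotFieldSpec",
    "gen_coin_flip_population",
    "gen_all_or_none_population",
    "gen_bursting_population",
    "apply_false_detection",
    "apply_detection_downsampling",
    "gen_tissue_layout",
    "assign_clustered_identities",
    "gen_spot_field",
    "gen_foci_image",
    "render_foci_channels",
]


# --------------------------------------------------------------------------
# configuration / domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the per-cell count generators.

    ``total_count_model`` names the distribution of per-cell total RNA
    counts: ``"poisson"`` with mean ``lam`` (default 3, the low-count regime
    of kidney tissue where measured means per cell are ~2.6-3.5), or
    ``"empirical"`` with an explicit ``count_vector`` that is resampled with
    replacement.  ``p_bl6`` is the population-level C57BL/6J allelic ratio;
    ``fdr_bl6`` / ``fdr_jf1`` are the per-RNA probabilities that an RNA of
    that true identity is detected as the opposite allele.
    """

    n_cells: int
    p_bl6: float = 0.5
    total_count_model: str = "poisson"
    lam: float = 3.0
    count_vector: np.ndarray | None = None
    fdr_bl6: float = 0.0
    fdr_jf1: float = 0.0
    detection_rate: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("p_bl6", "fdr_bl6", "fdr_jf1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.detection_rate <= 1.0:
            raise ValueError("detection_rate must lie in (0, 1]")
        if self.total_count_model == "poisson":
            if self.lam <= 0:
                raise ValueError("Poisson mean lam must be > 0")
        elif self.total_count_model == "empirical":
            if self.count_vector is None or len(self.count_vector) == 0:
                raise ValueError("empirical total_count_model needs a count_vector")
        else:
            raise ValueError(
                f"unknown total_count_model {self.total_count_model!r}; "
                "expected 'poisson' or 'empirical'"
            )

    def draw_totals(self, rng: np.random.Generator) -> np.ndarray:
        if self.total_count_model == "poisson":
            return rng.poisson(self.lam, size=self.n_cells)
        pool = np.asarray(self.count_vector, dtype=np.int64)
        return rng.choice(pool, size=self.n_cells, replace=True)


@dataclass(frozen=True)
class NegBinParams:
    """Negative-binomial description of one allele's mRNA count distribution.

    Parameterized so the count pmf is ``NB(r, p)`` with mean ``r (1-p)/p``
    and variance ``r (1-p)/p^2``.  In the two-state bursting picture
    ``burst_size = (1-p)/p`` RNAs per burst and ``burst_frequency = r``
    bursts per mRNA lifetime.
    """

    p: float
    r: float

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")

    @property
    def burst_size(self) -> float:
        return (1.0 - self.p) / self.p

    @property
    def burst_frequency(self) -> float:
        return self.r

    @property
    def mean(self) -> float:
        return self.r * (1.0 - self.p) / self.p

    @property
    def variance(self) -> float:
        return self.r * (1.0 - self.p) / self.p**2

    @classmethod
    def from_bursting(cls, burst_size: float, burst_frequency: float) -> "NegBinParams":
        if burst_size <= 0 or burst_frequency <= 0:
            raise ValueError("burst_size and burst_frequency must be > 0")
        return cls(p=1.0 / (1.0 + burst_size), r=burst_frequency)


@dataclass
class TissueLayout:
    """Cell positions on a tissue section plus their allelic identities."""

    positions: np.ndarray  # (n, 2) pixel coordinates
    identities: np.ndarray  # (n,) strings in {"BL6", "JF1"}
    seed_size: int = 1
    cluster_ids: np.ndarray | None = None
    extent: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.identities = np.asarray(self.identities)
        if len(self.positions) != len(self.identities):
            raise ValueError("positions and identities must have equal length")

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def bl6_fraction(self) -> float:
        return float(np.mean(self.identities == "BL6"))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "assignment": self.identities,
            }
        )
        if self.cluster_ids is not None:
            df["cluster_id"] = self.cluster_ids
        return df


@dataclass(frozen=True)
class SpotFieldSpec:
    """Parameters of the three-channel synthetic spot field.

    Each guide spot gains a BL6 partner with probability ``coloc_prob_bl6``,
    a JF1 partner with ``coloc_prob_jf1``, otherwise no partner.  Partners
    sit at guide position + ``chromatic_shift`` + isotropic Gaussian jitter.
    Spurious allele-channel spots are uniform with ``spurious_density`` spots
    per pixel^2 in each allele channel.  The regime emulated is the measured
    one in tissue, where roughly half of guide spots can be assigned an
    allele.
    """

    image_extent: tuple[float, float] = (512.0, 512.0)
    n_guide: int = 1000
    chromatic_shift: tuple[float, float] = (0.4, -0.3)
    localization_jitter_sd: float = 0.15
    coloc_prob_bl6: float = 0.3
    coloc_prob_jf1: float = 0.3
    spurious_density: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self):
        if self.coloc_prob_bl6 < 0 or self.coloc_prob_jf1 < 0:
            raise ValueError("colocalization probabilities must be >= 0")
        if self.coloc_prob_bl6 + self.coloc_prob_jf1 > 1.0 + 1e-12:
            raise ValueError("coloc_prob_bl6 + coloc_prob_jf1 must be <= 1")
        if self.spurious_density < 0:
            raise ValueError("spurious_density must be >= 0")
        if self.n_guide < 0:
            raise ValueError("n_guide must be >= 0")


# --------------------------------------------------------------------------
# per-cell count generators
# --------------------------------------------------------------------------


def gen_coin_flip_population(cfg: GeneratorConfig) -> pd.DataFrame:
    """Simulate the binomial (coin-flip) model of allelic imbalance.

    Every detected RNA's allelic origin is an independent Bernoulli draw at
    the population ratio: per cell, the total count comes from the configured
    total-count model and ``n_bl6 ~ Binomial(total, p_bl6)``.
    """
    rng = stream(cfg.rng_seed, "coin_flip")
    totals = cfg.draw_totals(rng)
    n_bl6 = rng.binomial(totals, cfg.p_bl6)
    return make_counts(n_bl6, totals - n_bl6, total=totals)


def gen_all_or_none_population(cfg: GeneratorConfig) -> pd.DataFrame:
    """Simulate random monoallelic (all-or-none) expression with noise.

    Each cell is assigned a single allelic identity (Bernoulli at
    ``p_bl6``); all its RNAs carry that identity; each RNA then flips to the
    opposite identity independently at the false-detection rate of its true
    identity (``fdr_bl6`` for BL6 RNAs, ``fdr_jf1`` for JF1 RNAs).
    """
    rng = stream(cfg.rng_seed, "all_or_none")
    totals = cfg.draw_totals(rng)
    is_bl6 = rng.random(cfg.n_cells) < cfg.p_bl6
    n_bl6 = np.where(is_bl6, totals, 0)
    counts = make_counts(n_bl6, totals - n_bl6, total=totals)
    return apply_false_detection(
        counts, cfg.fdr_bl6, cfg.fdr_jf1, rng_seed=cfg.rng_seed
    )


def gen_bursting_population(
    n_cells: int,
    params_bl6: NegBinParams,
    params_jf1: NegBinParams,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate independent negative-binomial bursting of the two alleles.

    Each allele's count is drawn independently per cell from its NB(r, p),
    so the alleles are uncorrelated by construction.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = stream(rng_seed, "bursting")
    n_bl6 = rng.negative_binomial(params_bl6.r, params_bl6.p, size=n_cells)
    n_jf1 = rng.negative_binomial(params_jf1.r, params_jf1.p, size=n_cells)
    return make_counts(n_bl6, n_jf1, total=n_bl6 + n_jf1)


def apply_false_detection(
    counts: pd.DataFrame,
    fdr_bl6: float,
    fdr_jf1: float,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Flip each RNA's allelic identity independently at its per-allele rate.

    Binomial thinning in both directions: ``Binomial(n_bl6, fdr_bl6)`` BL6
    RNAs become JF1 and vice versa.  Per-cell totals are preserved exactly.
    """
    for name, v in (("fdr_bl6", fdr_bl6), ("fdr_jf1", fdr_jf1)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    validate_counts(counts)
    rng = stream(rng_seed, "false_detection")
    flips_b2j = rng.binomial(counts["n_bl6"].to_numpy(), fdr_bl6)
    flips_j2b = rng.binomial(counts["n_jf1"].to_numpy(), fdr_jf1)
    out = counts.copy()
    out["n_bl6"] = counts["n_bl6"].to_numpy() - flips_b2j + flips_j2b
    out["n_jf1"] = counts["n_jf1"].to_numpy() - flips_j2b + flips_b2j
    return out


def apply_detection_downsampling(
    counts: pd.DataFrame,
    detection_rate: float,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Retain each RNA independently with probability ``detection_rate``.

    Binomial thinning per allele; a negative-binomial input distribution
    stays negative binomial with the thinned mean.
    """
    if not 0.0 < detection_rate <= 1.0:
        raise ValueError("detection_rate must lie in (0, 1]")
    validate_counts(counts)
    if detection_rate == 1.0:
        return counts.copy()
    rng = stream(rng_seed, "downsampling")
    out = counts.copy()
    for col in ("n_bl6", "n_jf1", "n_unassigned", "n_dual"):
        if col in out.columns:
            out[col] = rng.binomial(counts[col].to_numpy(), detection_rate)
    return out


# --------------------------------------------------------------------------
# tissue layout with clustered identities
# --------------------------------------------------------------------------


def neighbor_table(positions: np.ndarray, seed_size: int) -> np.ndarray:
    """Sorted nearest-neighbour index lists used by the cluster partition.

    Computed once per set of positions; repeated simulations on the same
    positions (the seeded-cluster null) reuse it.
    """
    n = len(positions)
    k = min(n, max(4 * seed_size, 16))
    _, neigh = cKDTree(positions).query(positions, k=k)
    return np.atleast_2d(neigh)


def _cluster_partition(
    positions: np.ndarray,
    seed_size: int,
    rng: np.random.Generator,
    neighbors: np.ndarray | None = None,
) -> np.ndarray:
    """Partition cells into spatial clusters of ``seed_size`` members.

    Iteratively pick a random unassigned cell and group it with its
    ``seed_size - 1`` nearest unassigned neighbours.  The final cluster may
    be smaller when ``n`` is not a multiple of ``seed_size``.
    Returns an integer cluster id per cell.
    """
    n = len(positions)
    cluster_ids = np.full(n, -1, dtype=np.int64)
    if seed_size == 1:
        cluster_ids[:] = rng.permutation(n)
        return cluster_ids

    # the per-cluster scan walks each neighbour list until it finds enough
    # unassigned cells, falling back to a brute scan over the remainder when
    # a list is exhausted (rare, end of fill)
    neigh = neighbor_table(positions, seed_size) if neighbors is None else neighbors

    order = rng.permutation(n)
    next_cluster = 0
    for start in order:
        if cluster_ids[start] != -1:
            continue
        members = [start]
        for j in neigh[start][1:]:
            if len(members) == seed_size:
                break
            if cluster_ids[j] == -1:
                members.append(j)
        if len(members) < seed_size:
            free = np.flatnonzero(cluster_ids == -1)
            free = free[~np.isin(free, members)]
            if len(free):
                d = np.linalg.norm(positions[free] - positions[start], axis=1)
                take = free[np.argsort(d)][: seed_size - len(members)]
                members.extend(take.tolist())
        cluster_ids[members] = next_cluster
        next_cluster += 1
    return cluster_ids


def assign_clustered_identities(
    positions: np.ndarray,
    p_bl6: float,
    seed_size: int,
    rng: np.random.Generator,
    neighbors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign allelic identities in spatial clusters of fixed size.

    Cells are partitioned into clusters of ``seed_size`` nearest neighbours;
    cluster identities are a shuffled multiset with ``round(n_clusters *
    p_bl6)`` BL6 labels, so the population allelic ratio is preserved up to
    the quota rounding.  Residual imbalance beyond one cell per cluster is
    corrected by flipping one randomly chosen cluster.

    Returns ``(identities, cluster_ids)``.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if seed_size < 1:
        raise ValueError("seed_size must be >= 1")
    if n < seed_size:
        raise ValueError("n_cells must be >= seed_size")
    cluster_ids = _cluster_partition(positions, seed_size, rng, neighbors=neighbors)
    n_clusters = int(cluster_ids.max()) + 1
    n_bl6_clusters = int(round(n_clusters * p_bl6))
    labels = np.array(["JF1"] * n_clusters, dtype=object)
    labels[: n_bl6_clusters] = "BL6"
    rng.shuffle(labels)
    identities = labels[cluster_ids].astype(str)

    # quota correction: if rounding at the cluster level left the realized
    # cell-level ratio off by more than one cluster's worth, flip one cluster
    target = p_bl6 * n
    realized = float(np.sum(identities == "BL6"))
    if abs(realized - target) > seed_size:
        want_bl6 = realized < target
        pool = np.unique(cluster_ids[identities == ("JF1" if want_bl6 else "BL6")])
        if len(pool):
            flip = rng.choice(pool)
            identities[cluster_ids == flip] = "BL6" if want_bl6 else "JF1"
    return identities, cluster_ids


def gen_tissue_layout(
    n_cells: int,
    p_bl6: float = 0.5,
    seed_size: int = 1,
    extent: tuple[float, float] = (1000.0, 1000.0),
    rng_seed: int = 0,
) -> TissueLayout:
    """Generate a tissue section with spatially clustered allelic identities.

    Positions are uniform in the ``extent`` rectangle; identities follow
    :func:`assign_clustered_identities` at the requested ratio and cluster
    (seed) size.  ``seed_size=1`` is the fully random (permutation-null)
    layout.
    """
    if n_cells < seed_size:
        raise ValueError("n_cells must be >= seed_size")
    rng = stream(rng_seed, "tissue_layout")
    positions = rng.uniform(0, extent, size=(n_cells, 2))
    identities, cluster_ids = assign_clustered_identities(
        positions, p_bl6, seed_size, rng
    )
    return TissueLayout(
        positions=positions,
        identities=identities,
        seed_size=seed_size,
        cluster_ids=cluster_ids,
        extent=tuple(extent),
    )


# --------------------------------------------------------------------------
# spot fields
# --------------------------------------------------------------------------


def _spot_frame(xy: np.ndarray, channel: str, intensity=None, cell_id=None) -> pd.DataFrame:
    n = len(xy)
    return pd.DataFrame(
        {
            "channel": channel,
            "x": xy[:, 0] if n else np.empty(0),
            "y": xy[:, 1] if n else np.empty(0),
            "z": np.zeros(n, dtype=np.int64),
            "intensity": np.ones(n) if intensity is None else intensity,
            "cell_id": np.full(n, -1, dtype=np.int64) if cell_id is None else cell_id,
        }
    )


def gen_spot_field(
    spec: SpotFieldSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate guide/BL6/JF1 spot tables plus a ground-truth table.

    Returns ``(guide, bl6, jf1, truth)`` where ``truth`` has one row per
    guide spot with its true assignment (``BL6``/``JF1``/``none``) and the
    index of its partner spot in the corresponding allele table (-1 if
    none).  Allele-channel spots are the true partners (shifted and
    jittered) followed by spurious uniform spots.
    """
    rng = stream(spec.rng_seed, "spot_field")
    w, h = spec.image_extent
    guide_xy = rng.uniform(0, (w, h), size=(spec.n_guide, 2))

    u = rng.random(spec.n_guide)
    assignment = np.where(
        u < spec.coloc_prob_bl6,
        "BL6",
        np.where(u < spec.coloc_prob_bl6 + spec.coloc_prob_jf1, "JF1", "none"),
    )

    shift = np.asarray(spec.chromatic_shift, dtype=float)
    partner_index = np.full(spec.n_guide, -1, dtype=np.int64)
    allele_xy = {"BL6": [], "JF1": []}
    for allele in ("BL6", "JF1"):
        idx = np.flatnonzero(assignment == allele)
        jitter = rng.normal(0, spec.localization_jitter_sd, size=(len(idx), 2))
        allele_xy[allele] = guide_xy[idx] + shift + jitter
        partner_index[idx] = np.arange(len(idx))

    n_spurious = rng.poisson(spec.spurious_density * w * h, size=2)
    tables = {}
    for ch, n_sp in zip(("BL6", "JF1"), n_spurious):
        sp = rng.uniform(0, (w, h), size=(n_sp, 2))
        xy = np.vstack([allele_xy[ch], sp]) if len(allele_xy[ch]) else sp
        tables[ch] = _spot_frame(xy, ch)

    truth = pd.DataFrame(
        {
            "guide_id": np.arange(spec.n_guide),
            "true_assignment": assignment,
            "partner_index": partner_index,
        }
    )
    return _spot_frame(guide_xy, "guide"), tables["BL6"], tables["JF1"], truth


# --------------------------------------------------------------------------
# foci images
# --------------------------------------------------------------------------


def _place_separated(
    n: int,
    extent: tuple[int, int],
    min_sep: float,
    rng: np.random.Generator,
    margin: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample n points with pairwise separation >= min_sep."""
    h, w = extent
    if n == 0:
        return np.empty((0, 2))
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} foci with separation {min_sep:.1f} px "
                f"in a {w}x{h} image; enlarge the extent or reduce n"
            )
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
        tries += 1
    return np.asarray(pts)


def gen_foci_image(
    n_foci: int,
    extent: tuple[int, int] = (256, 256),
    psf_sd: float = 2.0,
    intensity_range: tuple[float, float] = (500.0, 1500.0),
    background_level: float = 100.0,
    noise_sd: float = 10.0,
    rng_seed: int = 0,
    bl6_fraction: float = 0.5,
    snv_contrast: float = 8.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a guide-channel image of isolated RNA foci plus its truth table.

    The image is ``background + Gaussian noise + one symmetric 2D Gaussian
    blob per focus``; centers are rejection-placed with pairwise separation
    >= 4 * psf_sd.  The truth table carries each focus's center, guide
    amplitude, per-SNV-channel amplitudes (the dominant channel is
    ``snv_contrast`` times brighter than the minor one) and its true
    allelic identity.

    Returns ``(image, truth)``; use :func:`render_foci_channels` to render
    the matching SNV-channel images from ``truth``.
    """
    h, w = extent
    rng = stream(rng_seed, "foci_image")
    margin = 4 * psf_sd
    if n_foci > 0 and (w <= 2 * margin or h <= 2 * margin):
        raise ValueError("extent too small for the required focus separation")
    centers = _place_separated(n_foci, extent, 4 * psf_sd, rng, margin)
    amp = rng.uniform(*intensity_range, size=n_foci)
    is_bl6 = rng.random(n_foci) < bl6_fraction
    amp_major = amp
    amp_minor = amp / snv_contrast
    truth = pd.DataFrame(
        {
            "x": centers[:, 0] if n_foci else np.empty(0),
            "y": centers[:, 1] if n_foci else np.empty(0),
            "guide_amplitude": amp,
            "bl6_amplitude": np.where(is_bl6, amp_major, amp_minor),
            "jf1_amplitude": np.where(is_bl6, amp_minor, amp_major),
            "true_assignment": np.where(is_bl6, "BL6", "JF1"),
        }
    )
    image = _render(extent, centers, amp, psf_sd, background_level, noise_sd, rng)
    return image, truth


def render_foci_channels(
    truth: pd.DataFrame,
    extent: tuple[int, int] = (256, 256),
    psf_sd: float = 2.0,
    background_level: float = 100.0,
    noise_sd: float = 10.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the BL6 and JF1 SNV-channel images matching a truth table."""
    rng = stream(rng_seed, "foci_channels")
    centers = truth[["x", "y"]].to_numpy()
    bl6 = _render(
        extent, centers, truth["bl6_amplitude"].to_numpy(), psf_sd,
        background_level, noise_sd, rng,
    )
    jf1 = _render(
        extent, centers, truth["jf1_amplitude"].to_numpy(), psf_sd,
        background_level, noise_sd, rng,
    )
    return bl6, jf1


def _render(extent, centers, amplitudes, psf_sd, background, noise_sd, rng):
    h, w = extent
    image = np.full((h, w), float(background))
    if noise_sd > 0:
        image += rng.normal(0, noise_sd, size=(h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for (cx, cy), a in zip(centers, amplitudes):
        # render only a local window; blobs are compact
        r = int(np.ceil(5 * psf_sd))
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        gx = xx[y0:y1, x0:x1] - cx
        gy = yy[y0:y1, x0:x1] - cy
        image[y0:y1, x0:x1] += a * np.exp(-(gx**2 + gy**2) / (2 * psf_sd**2))
    return image
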