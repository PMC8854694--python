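"""Synthetic raw-data generators with known ground truth.

Every analysis stage in the package can be exercised end-to-end on data from
this module: embryo track tables emulating manual TrackMate-style exports of
dividing epiblast cells, FLIM photon-decay stacks with region-dependent
lifetimes and Poisson shot noise, images with junctional versus uniform
apical intensity patterns, and correlated-random-walk migration tracks.

The generators' defaults encode the study conditions the analyses were built
for: 7.5-min frame interval, three embryos per genotype, divisions at the
apical surface of a circular midsagittal epiblast section, a 20 MHz
repetition rate with 256 time bins for FLIM, and FLIPPER-TR-scale lifetimes.
Ground-truth labels are always recorded before any nuisance (jitter, noise)
is added, so they are invariant to it by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from epiquant._util import check_finite, polygon_mask
from epiquant.flim import FlimStack


# --------------------------------------------------------------------------
# embryo division tracks
# --------------------------------------------------------------------------

@dataclass
class EmbryoSimConfig:
    """Conditions for the daughter-cell tracking simulation.

    ``p_basal_wt`` is each wild-type daughter's probability of net basal
    movement (study estimate 51/56). ``p_apical_mut`` is each mutant
    daughter's probability of net apical movement; within a mutant division
    whose two drawn fates differ, the apical fate is routed to the
    apically positioned sibling with probability ``apical_sibling_bias``,
    emulating the observation that it is almost always the more apical
    daughter that delaminates.
    """

    n_embryos: int = 3
    n_divisions_per_embryo: Union[int, Sequence[int]] = 10
    frame_interval_min: float = 7.5
    n_frames: int = 12
    epiblast_radius_um: float = 30.0
    basement_radius_um: float = 60.0
    p_basal_wt: float = 51.0 / 56.0
    p_apical_mut: float = 0.5
    apical_sibling_bias: float = 0.9
    genotype: str = "wildtype"
    jitter_sd_um: float = 0.0
    centre_drift_sd_um: float = 0.0
    follow_frames: Optional[int] = None  # frames after division to keep
    seed: int = 0

    def __post_init__(self):
        for name in ("p_basal_wt", "p_apical_mut", "apical_sibling_bias"):
            v = getattr(self, name)
            check_finite(name, v)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        check_finite("radii", [self.epiblast_radius_um, self.basement_radius_um])
        check_finite("jitter_sd_um", self.jitter_sd_um)
        check_finite("frame_interval_min", self.frame_interval_min)
        if not 0 < self.epiblast_radius_um < self.basement_radius_um:
            raise ValueError("need basement_radius > epiblast_radius > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.genotype not in ("wildtype", "mutant"):
            raise ValueError("genotype must be 'wildtype' or 'mutant'")

    def divisions_per_embryo(self) -> list:
        n = self.n_divisions_per_embryo
        if np.isscalar(n):
            return [int(n)] * self.n_embryos
        n = [int(v) for v in n]
        if len(n) != self.n_embryos:
            raise ValueError("n_divisions_per_embryo sequence length must "
                             "equal n_embryos")
        return n


def generate_embryo_tracks(config: EmbryoSimConfig):
    """Simulate mother/daughter tracks for apical divisions in the epiblast.

    Returns ``(table, ground_truth)``. The table follows the package track
    schema (embryo_id, track_id, role, frame, t_min, x_um, y_um,
    centre_x_um, centre_y_um) plus ``division_id`` and ``genotype``.
    Geometry is built in centred coordinates (relative to the true
    embryonic-region centre) and the per-frame centre (including drift and
    rigid jitter) is added back afterwards, so jitter correction recovers
    the noise-free geometry and ground-truth labels exactly.
    """
    rng = np.random.default_rng(config.seed)
    # jitter uses its own stream so the underlying geometry is identical
    # with and without jitter at a fixed seed
    jitter_rng = np.random.default_rng([config.seed, 2**20 + 7])

    if config.n_frames < 6:
        raise ValueError("need n_frames >= 6 to fit mother and daughter tracks")

    rows = []
    truth = {}
    mutant = config.genotype == "mutant"
    for e, n_div in enumerate(config.divisions_per_embryo()):
        embryo = f"{config.genotype}_embryo{e}"
        # true centre path (drift); jitter added later
        drift = (jitter_rng.normal(0.0, config.centre_drift_sd_um,
                                   size=(config.n_frames, 2))
                 if config.centre_drift_sd_um > 0 else
                 np.zeros((config.n_frames, 2)))
        centre_path = np.cumsum(drift, axis=0)
        jitter = (jitter_rng.normal(0.0, config.jitter_sd_um,
                                    size=(config.n_frames, 2))
                  if config.jitter_sd_um > 0 else
                  np.zeros((config.n_frames, 2)))
        offset = centre_path + jitter  # added to centred coords and centre

        for k in range(n_div):
            div = f"{embryo}_div{k}"
            fd = int(rng.integers(3, config.n_frames - 2))  # daughters get >= 3 frames
            phi = rng.uniform(0.0, 2.0 * np.pi)
            u = np.array([np.cos(phi), np.sin(phi)])  # outward radial unit

            # mother approaches the apical surface over three frames (INM)
            r_start = config.epiblast_radius_um + rng.uniform(5.0, 15.0)
            radii = np.linspace(r_start, config.epiblast_radius_um, 3)
            mother_id = f"{div}_m"
            for i, f in enumerate(range(fd - 3, fd)):
                pos = radii[i] * u
                rows.append(_track_row(embryo, mother_id, "mother", f,
                                       config, pos, offset[f], div))
            mother_final = config.epiblast_radius_um * u

            # daughter fates
            if mutant:
                apical_fate = rng.random(2) < config.p_apical_mut
            else:
                apical_fate = ~(rng.random(2) < config.p_basal_wt)
            bias_draw = rng.random()  # consumed every division for stream stability
            axis_angle = rng.uniform(0.0, 2.0 * np.pi)
            a = np.array([np.cos(axis_angle), np.sin(axis_angle)])
            if abs(np.dot(a, u)) < 1e-6:  # avoid exactly tangential axes (sibling tie)
                a = np.array([np.cos(axis_angle + 0.3), np.sin(axis_angle + 0.3)])
            delta = 1.5  # um: half the sister separation right after division
            starts = {1: mother_final + delta * a, 2: mother_final - delta * a}
            # apical sibling = the daughter nearer the centre (origin) at birth
            apical_sib = min(starts, key=lambda i: np.linalg.norm(starts[i]))
            if mutant and apical_fate.sum() == 1:
                target = apical_sib if bias_draw < config.apical_sibling_bias \
                    else ({1, 2} - {apical_sib}).pop()
                apical_fate = np.array([target == 1, target == 2])

            thetas = np.where(apical_fate,
                              rng.uniform(5.0, 85.0, size=2),
                              rng.uniform(95.0, 175.0, size=2))
            signs = rng.choice([-1.0, 1.0], size=2)
            dists = rng.uniform(8.0, 20.0, size=2)
            f_end = config.n_frames - 1
            if config.follow_frames is not None:
                f_end = min(f_end, fd + int(config.follow_frames))
            ref = -u  # mother -> centre (origin) direction
            for j in (1, 2):
                ang = np.radians(signs[j - 1] * thetas[j - 1])
                rot = np.array([[np.cos(ang), -np.sin(ang)],
                                [np.sin(ang), np.cos(ang)]])
                final = mother_final + dists[j - 1] * (rot @ ref)
                did = f"{div}_d{j}"
                frames = np.arange(fd, f_end + 1)
                path = np.linspace(starts[j], final, len(frames))
                for f, pos in zip(frames, path):
                    rows.append(_track_row(embryo, did, f"daughter_{j}", f,
                                           config, pos, offset[f], div))
                truth[did] = {
                    "embryo_id": embryo,
                    "division_id": div,
                    "true_direction": "apical" if apical_fate[j - 1] else "basal",
                    "sibling_position": ("apical_daughter" if j == apical_sib
                                         else "basal_daughter"),
                    "theta_true_deg": float(thetas[j - 1]),
                    "d_true_um": float(dists[j - 1]),
                }

    table = pd.DataFrame(rows)
    ground_truth = {"daughters": truth, "config": asdict(config)}
    return table, ground_truth


def _track_row(embryo, track_id, role, frame, config, centred_pos, offset, div):
    pos = centred_pos + offset
    return {
        "embryo_id": embryo, "track_id": track_id, "role": role,
        "frame": int(frame), "t_min": frame * config.frame_interval_min,
        "x_um": pos[0], "y_um": pos[1],
        "centre_x_um": offset[0], "centre_y_um": offset[1],
        "division_id": div, "genotype": config.genotype,
    }


# --------------------------------------------------------------------------
# FLIM decay stacks
# --------------------------------------------------------------------------

@dataclass
class FlimSimConfig:
    """Conditions for the FLIM decay-stack simulation.

    ``regions`` is a list of ``(polygon, true_lifetime_ns)`` pairs with
    polygons as (row, col) vertices. Each region pixel's decay histogram is
    the wrapped (periodic) mono-exponential of its region's lifetime with a
    mean of ``photons_per_pixel_mean`` photons; pixels outside every region
    carry only ``background_count_level`` counts spread uniformly in time.
    """

    image_shape: tuple = (64, 64)
    regions: list = field(default_factory=list)
    rep_rate: float = 20e6
    n_time_bins: int = 256
    photons_per_pixel_mean: float = 1e4
    background_count_level: float = 0.0
    pixel_size_nm: float = 135.0
    noise: str = "poisson"  # "poisson" or "none"
    seed: int = 0

    def __post_init__(self):
        check_finite("photons_per_pixel_mean", self.photons_per_pixel_mean)
        if self.photons_per_pixel_mean < 0:
            raise ValueError("photons_per_pixel_mean must be >= 0")
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")
        if self.background_count_level < 0:
            raise ValueError("background_count_level must be >= 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        for _, tau in self.regions:
            if tau <= 0:
                raise ValueError("true_lifetime must be positive")


def monoexp_bin_probabilities(tau_ns: float, period_ns: float,
                              n_bins: int) -> np.ndarray:
    """Bin probabilities of a wrapped mono-exponential decay.

    The decay exp(-t/tau) excited periodically with period T wraps onto
    [0, T); integrating over equal bins gives a geometric sequence.
    """
    edges = np.linspace(0.0, period_ns, n_bins + 1)
    cdf = -np.expm1(-edges / tau_ns)
    return np.diff(cdf) / cdf[-1]


def generate_flim_stack(config: FlimSimConfig):
    """Simulate a per-pixel photon-decay stack with known region lifetimes.

    Returns ``(stack, ground_truth)`` where the ground truth carries each
    region's true lifetime and pixel mask plus the background mask. Warns
    (but proceeds) when a lifetime reaches the aliasing regime
    tau >= period / (2 pi), where the first-harmonic phase wraps.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    period_ns = 1e9 / config.rep_rate
    n = config.n_time_bins
    if n < 8:
        raise ValueError("n_time_bins must be >= 8")

    expected = np.zeros((n, h, w), dtype=float)
    expected += config.background_count_level / n  # uniform-in-time background
    region_masks = []
    for poly, tau in config.regions:
        verts = np.asarray(poly, float)
        if (verts < -0.5).any() or (verts[:, 0] > h - 0.5).any() \
                or (verts[:, 1] > w - 0.5).any():
            raise ValueError("region polygon extends outside the image")
        if tau >= period_ns / (2.0 * np.pi):
            warnings.warn(
                f"lifetime {tau} ns reaches the aliasing regime for a "
                f"{period_ns:.1f} ns period; phase estimates will wrap",
                stacklevel=2)
        mask = polygon_mask((h, w), verts)
        probs = monoexp_bin_probabilities(tau, period_ns, n)
        expected[:, mask] = (config.photons_per_pixel_mean * probs[:, None]
                             + config.background_count_level / n)
        region_masks.append(mask)

    if config.noise == "poisson":
        decay = rng.poisson(expected).astype(np.uint32)
    else:
        decay = expected

    stack = FlimStack(decay=decay, rep_rate=config.rep_rate,
                      pixel_size_nm=config.pixel_size_nm)
    any_region = np.zeros((h, w), bool)
    for m in region_masks:
        any_region |= m
    ground_truth = {
        "region_lifetimes_ns": [tau for _, tau in config.regions],
        "region_masks": region_masks,
        "background_mask": ~any_region,
        "config": {k: v for k, v in asdict(config).items() if k != "regions"},
    }
    return stack, ground_truth


# --------------------------------------------------------------------------
# apical intensity-profile images
# --------------------------------------------------------------------------

@dataclass
class ProfileSimConfig:
    """Conditions for the apical F-actin intensity-pattern simulation.

    The apical surface is a straight horizontal path at ``path_row`` from
    ``path_cols[0]`` to ``path_cols[1]``. In ``junctional`` mode the signal
    concentrates in Gaussian spots at ``junction_positions`` (row, col);
    in ``uniform`` mode it forms a ridge of constant line density along the
    path (the mutant phenotype: F-actin spread homogeneously over the apical
    surface instead of enriched at the junctions). The nucleus polygon is
    filled with ``nucleus_mean``, the normalizer used by the profile
    pipeline to cancel depth-dependent attenuation.
    """

    image_shape: tuple = (96, 192)
    path_row: float = 30.0
    path_cols: tuple = (20.0, 172.0)
    junction_positions: Optional[list] = None  # default: the two path ends
    junction_amplitude: float = 60.0
    uniform_amplitude: float = 12.0
    spot_sigma_px: float = 2.5
    nucleus_polygon: Optional[np.ndarray] = None
    nucleus_mean: float = 40.0
    noise_sd: float = 0.0
    mode: str = "junctional"
    seed: int = 0

    def __post_init__(self):
        if self.junction_amplitude < 0 or self.uniform_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in ("junctional", "uniform"):
            raise ValueError("mode must be 'junctional' or 'uniform'")
        if self.nucleus_mean <= 0:
            raise ValueError("nucleus_mean must be positive")
        if self.junction_positions is None:
            self.junction_positions = [
                (self.path_row, self.path_cols[0]),
                (self.path_row, self.path_cols[1]),
            ]
        if self.nucleus_polygon is None:
            r, (c0, c1) = self.path_row, self.path_cols
            self.nucleus_polygon = np.array([
                [r + 20, c0 + 30], [r + 20, c1 - 30],
                [r + 45, c1 - 30], [r + 45, c0 + 30],
            ])

    def path(self) -> np.ndarray:
        return np.array([[self.path_row, self.path_cols[0]],
                         [self.path_row, self.path_cols[1]]])


def matched_uniform_amplitude(config: ProfileSimConfig) -> float:
    """Uniform-mode amplitude whose along-path integrated intensity matches
    the junctional mode of the same config (same total signal, different
    shape)."""
    s = np.linspace(config.path_cols[0], config.path_cols[1], 2048)
    prof = np.zeros_like(s)
    for (_, cj) in config.junction_positions:
        prof += config.junction_amplitude * np.exp(
            -((s - cj) ** 2) / (2.0 * config.spot_sigma_px ** 2))
    return float(prof.mean())


def generate_profile_image(config: ProfileSimConfig):
    """Simulate an apical intensity image with a known expected profile.

    Returns ``(image, ground_truth)``; the ground truth holds the expected
    noise-free on-path intensity on a percent grid, the nuclear mean, and
    the expected normalized profile (expected intensity / nucleus_mean).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    image = np.zeros((h, w), float)
    sig2 = 2.0 * config.spot_sigma_px ** 2

    if config.mode == "junctional":
        for (rj, cj) in config.junction_positions:
            image += config.junction_amplitude * np.exp(
                -((rr - rj) ** 2 + (cc - cj) ** 2) / sig2)
    else:
        c0, c1 = config.path_cols
        on_span = (cc >= c0) & (cc <= c1)
        image += np.where(
            on_span,
            config.uniform_amplitude * np.exp(-((rr - config.path_row) ** 2) / sig2),
            0.0)

    nuc_mask = polygon_mask((h, w), config.nucleus_polygon)
    image[nuc_mask] = config.nucleus_mean
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=(h, w))

    percent = np.linspace(0.0, 100.0, 201)
    s = config.path_cols[0] + percent / 100.0 * (config.path_cols[1]
                                                 - config.path_cols[0])
    expected = np.zeros_like(s)
    if config.mode == "junctional":
        for (_, cj) in config.junction_positions:
            expected += config.junction_amplitude * np.exp(-((s - cj) ** 2) / sig2)
    else:
        expected += config.uniform_amplitude
    ground_truth = {
        "percent": percent,
        "expected_intensity": expected,
        "expected_normalized": expected / config.nucleus_mean,
        "nucleus_mean": config.nucleus_mean,
        "mode": config.mode,
        "config": None,
    }
    return image, ground_truth


# --------------------------------------------------------------------------
# migration tracks
# --------------------------------------------------------------------------

def generate_migration_tracks(n_cells: int = 20, step_length_um=2.0,
                              turning_kappa: float = 2.0, n_steps: int = 30,
                              dt_min: float = 5.0, seed: int = 0,
                              start_spread_um: float = 100.0) -> pd.DataFrame:
    """Correlated random walks emulating cells migrating from an explant.

    Headings evolve by von Mises turning increments with concentration
    ``turning_kappa`` (``np.inf`` gives perfectly straight paths).
    ``step_length_um`` may be a scalar or a callable ``f(rng, n) -> array``
    drawing per-step lengths. Returns a tidy track table
    (cell_id, t_min, x_um, y_um).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cells):
        start = rng.uniform(-start_spread_um, start_spread_um, size=2)
        heading = rng.uniform(0.0, 2.0 * np.pi)
        if np.isinf(turning_kappa):
            turns = np.zeros(n_steps)
        else:
            turns = rng.vonmises(0.0, turning_kappa, size=n_steps)
        if callable(step_length_um):
            steps = np.asarray(step_length_um(rng, n_steps), float)
        else:
            steps = np.full(n_steps, float(step_length_um))
        headings = heading + np.cumsum(turns)
        dxy = steps[:, None] * np.column_stack([np.cos(headings),
                                                np.sin(headings)])
        pos = np.vstack([start, start + np.cumsum(dxy, axis=0)])
        for i, p in enumerate(pos):
            rows.append({"cell_id": f"cell{c}", "t_min": i * dt_min,
                         "x_um": p[0], "y_um": p[1]})
    return pd.DataFrame(rows)
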