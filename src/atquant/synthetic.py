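"""Synthetic serial-section stacks with known ground truth.

Emulates what the real acquisition produces — three channels (SYP pre-
synaptic, PSD95 post-synaptic, OC amyloid-beta) of diffraction-limited
puncta spanning several 70 nm sections, section-to-section rigid jitter,
background with a gentle gradient, shot and read noise, and single-section
noise specks — while recording everything a recovery test needs: true
puncta (centroid, volume at the half-maximum isosurface), true pre/post
pairs, true A-beta-overlapped post-synapses, true per-section jitter and
true per-channel burden.

Puncta are rendered as isotropic 3D Gaussians sampled on the anisotropic
voxel grid; the "true volume" of a punctum is the set of voxel centres
within its half-maximum radius, which is unambiguous for both the default
Gaussian render and the hard-edged ``solid`` render used for exactness
checks.  True pre/post pairs are constructed at centroid offsets below the
pairing criterion, and unpaired post-synapses are kept away from every
pre-synaptic centroid so the constructed pairing fraction is also the true
fraction recoverable under the 0.5 um criterion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stack_io import ImageStack, RegionOfInterest, VoxelGeometry

PRE_CHANNEL = "SYP"
POST_CHANNEL = "PSD95"
AB_CHANNEL = "OC"
CHANNELS = (PRE_CHANNEL, POST_CHANNEL, AB_CHANNEL)

#: Half-max radius r relates to the Gaussian sigma by r = sigma*sqrt(2 ln 2).
_HALFMAX = np.sqrt(2.0 * np.log(2.0))

# Fixed substream registry: append-only so adding a stream never perturbs
# the draws of an existing one.
_STREAMS = [
    "placement.SYP", "placement.PSD95", "placement.OC",
    "jitter",
    "noise.SYP", "noise.PSD95", "noise.OC",
    "specks.SYP", "specks.PSD95", "specks.OC",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(name),)))


@dataclass
class SimulationConfig:
    """Everything that determines one simulated ROI.

    Densities are objects per um^3 of field volume.  Defaults emulate
    moderately dense adult human neuropil at array-tomography resolution:
    pre- and post-synaptic puncta at 0.25 /um^3 (2.5e8 per mm^3),
    diffraction-limited half-max radius 0.2 +/- 0.05 um, 30% of
    pre-synapses with a post partner within ``pairing_offset_max_um``
    (kept below the 0.5 um pairing criterion so constructed pairs are
    detectable by design), 30% of post-synapses overlapped by an A-beta
    blob, a 16-bit-scale background of 50 counts with shot noise, and
    integer section jitter up to 3 px.
    """

    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    field_size: tuple[int, int] = (256, 256)
    n_sections: int = 20
    density_per_um3: dict = field(default_factory=lambda: {
        PRE_CHANNEL: 0.25, POST_CHANNEL: 0.25, AB_CHANNEL: 0.05})
    exact_count: dict = field(default_factory=dict)  # channel -> int, overrides Poisson
    radius_mean_um: float = 0.2
    radius_sd_um: float = 0.05
    radius_min_um: float = 0.1
    amplitude_mean: float = 400.0
    amplitude_sd: float = 40.0
    render: str = "gaussian"  # or "solid": hard-edged half-max ellipsoid
    pairing_fraction: float = 0.3
    pairing_offset_max_um: float = 0.3
    unpaired_exclusion_um: float = 0.7
    coloc_fraction: float = 0.3
    ab_exclusion_um: float = 0.5
    background: float = 50.0
    gradient_amplitude: float = 10.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    speck_rate: float = 5.0  # single-section specks per section per channel
    speck_amplitude: float = 400.0
    jitter_max_px: int = 3
    subpixel_jitter: bool = False
    min_separation_um: float = 0.0  # dart-throwing minimum centre distance
    seed: int = 0

    def __post_init__(self) -> None:
        for ch, d in self.density_per_um3.items():
            if d < 0:
                raise ValueError(f"density for {ch} must be >= 0")
        for name in ("pairing_fraction", "coloc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.jitter_max_px < 0:
            raise ValueError("jitter_max_px must be >= 0")
        if 2.0 * self.radius_mean_um < 2.0 * self.geometry.dz:
            raise ValueError(
                f"mean punctum diameter {2 * self.radius_mean_um} um is below two section "
                f"thicknesses ({2 * self.geometry.dz} um); true puncta would not span 2 sections")

    @property
    def field_volume_um3(self) -> float:
        g = self.geometry
        return self.field_size[0] * g.dy * self.field_size[1] * g.dx * self.n_sections * g.dz

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["field_size"] = list(self.field_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = VoxelGeometry.from_dict(d["geometry"])
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        return cls(**d)


@dataclass
class Punctum:
    punctum_id: int
    channel: str
    centroid_um: tuple[float, float, float]  # (x, y, z)
    radius_um: float
    amplitude: float
    volume_um3: float = 0.0  # voxel centres within the half-max radius


@dataclass
class GroundTruthManifest:
    """Everything true about one simulated ROI, JSON-serializable.

    ``truth_masks`` (the per-channel half-max foreground) is carried in
    memory for exactness tests but is regenerable and not serialized.
    """

    seed: int
    puncta: dict = field(default_factory=dict)           # channel -> list[Punctum]
    pairs: list = field(default_factory=list)            # (pre_id, post_id, distance_um)
    coloc_post_ids: list = field(default_factory=list)
    coloc_pre_ids: list = field(default_factory=list)
    jitter_px: list = field(default_factory=list)        # per-section (drow, dcol)
    burden_pct: dict = field(default_factory=dict)       # channel -> true burden %
    speck_count: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    truth_masks: dict | None = None

    @property
    def pairing_fraction_true(self) -> float:
        n_pre = len(self.puncta.get(PRE_CHANNEL, []))
        return len(self.pairs) / n_pre if n_pre else 0.0

    @property
    def coloc_fraction_true(self) -> float:
        n_post = len(self.puncta.get(POST_CHANNEL, []))
        return len(self.coloc_post_ids) / n_post if n_post else 0.0

    def expected_quant(self) -> dict:
        """Manifest-derived expected readouts (counts, densities, burden, fractions)."""
        cfg = SimulationConfig.from_dict(self.config)
        vol = cfg.field_volume_um3
        out: dict = {"analysed_volume_um3": vol}
        for ch in self.puncta:
            out[f"count.{ch}"] = len(self.puncta[ch])
            out[f"density_per_mm3.{ch}"] = len(self.puncta[ch]) / vol * 1e9
            out[f"burden_pct.{ch}"] = self.burden_pct.get(ch)
        out["pairing_fraction"] = self.pairing_fraction_true
        out["coloc_fraction.post"] = self.coloc_fraction_true
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = {
            "seed": self.seed,
            "puncta": {ch: [asdict(p) for p in ps] for ch, ps in self.puncta.items()},
            "pairs": self.pairs,
            "coloc_post_ids": self.coloc_post_ids,
            "coloc_pre_ids": self.coloc_pre_ids,
            "jitter_px": self.jitter_px,
            "burden_pct": self.burden_pct,
            "speck_count": self.speck_count,
            "config": self.config,
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(d, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        man = cls(seed=d["seed"], pairs=[tuple(p) for p in d["pairs"]],
                  coloc_post_ids=d["coloc_post_ids"], coloc_pre_ids=d["coloc_pre_ids"],
                  jitter_px=[tuple(j) for j in d["jitter_px"]],
                  burden_pct=d["burden_pct"], speck_count=d["speck_count"],
                  config=d["config"])
        for ch, ps in d["puncta"].items():
            man.puncta[ch] = [Punctum(**{**p, "centroid_um": tuple(p["centroid_um"])}) for p in ps]
        return man


def _place_centres(rng: np.random.Generator, n: int, cfg: SimulationConfig,
                   min_sep: float, avoid: np.ndarray | None = None,
                   avoid_dist: float = 0.0) -> np.ndarray:
    """Uniform dart-throwing placement in physical (x, y, z) um.

    Keeps an in-plane margin of one mean radius so blobs stay mostly in
    field; rejects candidates closer than ``min_sep`` to an accepted centre
    or closer than ``avoid_dist`` to any point of ``avoid``.
    """
    g = cfg.geometry
    x_max = cfg.field_size[1] * g.dx
    y_max = cfg.field_size[0] * g.dy
    z_max = cfg.n_sections * g.dz
    margin = cfg.radius_mean_um
    if x_max <= 2 * margin or y_max <= 2 * margin:
        raise ValueError(
            f"field {cfg.field_size} too small to place puncta of radius {cfg.radius_mean_um} um")
    placed: list[np.ndarray] = []
    attempts = 0
    max_attempts = max(1000, 200 * n)
    while len(placed) < n:
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} puncta with min separation {min_sep} um; field too crowded")
        attempts += 1
        c = np.array([
            rng.uniform(margin, x_max - margin),
            rng.uniform(margin, y_max - margin),
            rng.uniform(0.0, z_max),
        ])
        if avoid is not None and avoid.size and np.min(np.linalg.norm(avoid - c, axis=1)) < avoid_dist:
            continue
        if min_sep > 0 and placed and np.min(np.linalg.norm(np.array(placed) - c, axis=1)) < min_sep:
            continue
        placed.append(c)
    return np.array(placed).reshape(n, 3)


def _draw_radii_amps(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    radii = np.maximum(rng.normal(cfg.radius_mean_um, cfg.radius_sd_um, n), cfg.radius_min_um)
    amps = np.maximum(rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, n), 1.0)
    return radii, amps


def _render_channel(puncta: list[Punctum], cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render puncta onto a zero background; return (image, half-max truth mask).

    Each punctum also gets its ``volume_um3`` filled in from its own
    half-max voxel set.
    """
    g = cfg.geometry
    shape = (cfg.n_sections, *cfg.field_size)
    img = np.zeros(shape, dtype=np.float64)
    truth = np.zeros(shape, dtype=bool)
    spacing = np.array([g.dz, g.dy, g.dx])
    for p in puncta:
        cx, cy, cz = p.centroid_um
        centre = np.array([cz, cy, cx])  # (z, y, x) physical
        sigma = p.radius_um / _HALFMAX
        extent = 4.0 * sigma
        lo = np.maximum(np.floor((centre - extent) / spacing - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((centre + extent) / spacing - 0.5).astype(int) + 1, shape)
        if np.any(lo >= hi):
            p.volume_um3 = 0.0
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
        d2 = (((zz + 0.5) * g.dz - cz) ** 2
              + ((yy + 0.5) * g.dy - cy) ** 2
              + ((xx + 0.5) * g.dx - cx) ** 2)
        inside = d2 <= p.radius_um ** 2  # half-max set, boundary inclusive
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        if cfg.render == "solid":
            img[sub] = np.maximum(img[sub], p.amplitude * inside)
        else:
            img[sub] += p.amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
        truth[sub] |= inside
        p.volume_um3 = float(inside.sum()) * g.voxel_volume_um3
    return img, truth


def _add_specks(img: np.ndarray, rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Add single-section bright specks (the noise the 2-section rule removes)."""
    n_sec, n_row, n_col = img.shape
    sigma_px = max(cfg.radius_mean_um / _HALFMAX / cfg.geometry.dx, 0.8)
    half = int(np.ceil(4 * sigma_px))
    total = 0
    for z in range(n_sec):
        for _ in range(rng.poisson(cfg.speck_rate)):
            r = rng.uniform(half, n_row - half)
            c = rng.uniform(half, n_col - half)
            rr, cc = np.meshgrid(
                np.arange(int(r) - half, int(r) + half + 1),
                np.arange(int(c) - half, int(c) + half + 1), indexing="ij")
            blob = cfg.speck_amplitude * np.exp(
                -((rr + 0.5 - r) ** 2 + (cc + 0.5 - c) ** 2) / (2 * sigma_px ** 2))
            img[z, rr, cc] += blob
            total += 1
    return total


def apply_section_jitter(roi: RegionOfInterest, jitter_px: list[tuple[float, float]]) -> RegionOfInterest:
    """Translate each section by its (drow, dcol) vector, constant-fill 0.

    The same vector is applied to every channel of a section, as physical
    ribbon misalignment affects all channels identically.  Integer vectors
    shift exactly; fractional vectors use linear interpolation.
    """
    n_sec = next(iter(roi.channels.values())).n_sections
    if len(jitter_px) != n_sec:
        raise ValueError(f"need {n_sec} jitter vectors, got {len(jitter_px)}")

    def shift_stack(stack: ImageStack) -> ImageStack:
        out = np.empty_like(np.asarray(stack.voxels, dtype=np.float64))
        for z, (dr, dc) in enumerate(jitter_px):
            if float(dr).is_integer() and float(dc).is_integer():
                out[z] = _int_shift(stack.voxels[z], int(dr), int(dc))
            else:
                out[z] = ndimage.shift(np.asarray(stack.voxels[z], dtype=np.float64),
                                       (dr, dc), order=1, mode="constant", cval=0.0)
        return stack.with_voxels(out)

    return roi.map_channels(shift_stack)


def _int_shift(section: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(np.asarray(section, dtype=np.float64))
    n_row, n_col = section.shape
    r0, r1 = max(dr, 0), min(n_row + dr, n_row)
    c0, c1 = max(dc, 0), min(n_col + dc, n_col)
    out[r0:r1, c0:c1] = section[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def add_noise(stack: ImageStack, config: SimulationConfig,
              rng: np.random.Generator | None = None) -> ImageStack:
    """Background gradient, then Poisson shot noise, then Gaussian read noise.

    The gradient is zero-mean across the field so a blank field keeps mean
    intensity equal to ``background``.  Output is clamped at zero.
    """
    if rng is None:
        rng = _rng(config.seed, f"noise.{stack.channel_name}" if
                   f"noise.{stack.channel_name}" in _STREAMS else "noise.SYP")
    img = np.asarray(stack.voxels, dtype=np.float64).copy()
    n_sec, n_row, n_col = img.shape
    if config.background or config.gradient_amplitude:
        u = (np.arange(n_col) + 0.5) / n_col - 0.5
        v = (np.arange(n_row) + 0.5) / n_row - 0.5
        plane = config.background + config.gradient_amplitude * (u[None, :] + v[:, None])
        img += plane[None, :, :]
    if config.poisson_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
    if config.gaussian_noise_sd > 0:
        # camera ADU output is integer; quantize after read noise
        img = np.round(img + rng.normal(0.0, config.gaussian_noise_sd, img.shape))
    return stack.with_voxels(np.maximum(img, 0.0))


def simulate_roi(config: SimulationConfig, *, case_id: str = "sim",
                 treatment: str = "other", roi_index: int = 0,
                 ) -> tuple[RegionOfInterest, GroundTruthManifest]:
    """Generate one three-channel ROI and its ground-truth manifest.

    Construction order: place pre-synaptic puncta; give a fraction of them
    a post partner at a sub-criterion offset; fill remaining post-synaptic
    density with unpaired puncta excluded from the neighbourhood of every
    pre centroid; centre A-beta blobs on a fraction of post-synapses and
    scatter the rest away from post centroids; render; record truth; apply
    shared per-section jitter (normalized so the middle section is the
    fixed reference); add noise and single-section specks.
    """
    g = config.geometry
    vol = config.field_volume_um3

    def n_for(ch: str, rng: np.random.Generator) -> int:
        if ch in config.exact_count:
            return int(config.exact_count[ch])
        return int(rng.poisson(config.density_per_um3.get(ch, 0.0) * vol))

    man = GroundTruthManifest(seed=config.seed, config=config.to_dict(), truth_masks={})

    # --- pre-synaptic puncta ---
    rng_pre = _rng(config.seed, "placement.SYP")
    n_pre = n_for(PRE_CHANNEL, rng_pre)
    pre_centres = _place_centres(rng_pre, n_pre, config, config.min_separation_um)
    pre_radii, pre_amps = _draw_radii_amps(rng_pre, n_pre, config)
    pre = [Punctum(i, PRE_CHANNEL, tuple(pre_centres[i]), float(pre_radii[i]), float(pre_amps[i]))
           for i in range(n_pre)]

    # --- post-synaptic puncta: constructed partners + excluded independents ---
    rng_post = _rng(config.seed, "placement.PSD95")
    n_post_target = n_for(POST_CHANNEL, rng_post)
    paired_mask = rng_post.random(n_pre) < config.pairing_fraction
    post: list[Punctum] = []
    pairs: list[tuple[int, int, float]] = []
    x_max = config.field_size[1] * g.dx
    y_max = config.field_size[0] * g.dy
    z_max = config.n_sections * g.dz
    m = config.radius_mean_um
    for i in np.nonzero(paired_mask)[0]:
        for _ in range(100):
            direction = rng_post.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng_post.uniform(0.0, config.pairing_offset_max_um)
            c = pre_centres[i] + direction * dist
            if m <= c[0] <= x_max - m and m <= c[1] <= y_max - m and 0.0 <= c[2] <= z_max:
                break
        pid = len(post)
        post.append(Punctum(pid, POST_CHANNEL, tuple(c), 0.0, 0.0))
        pairs.append((int(i), pid, float(dist)))
    n_indep = max(0, n_post_target - len(post))
    if n_indep:
        indep = _place_centres(rng_post, n_indep, config, config.min_separation_um,
                               avoid=pre_centres, avoid_dist=config.unpaired_exclusion_um)
        for c in indep:
            post.append(Punctum(len(post), POST_CHANNEL, tuple(c), 0.0, 0.0))
    post_radii, post_amps = _draw_radii_amps(rng_post, len(post), config)
    for p, r, a in zip(post, post_radii, post_amps):
        p.radius_um, p.amplitude = float(r), float(a)

    # --- A-beta blobs: centred on colocalized posts + scattered independents ---
    rng_ab = _rng(config.seed, "placement.OC")
    n_ab_target = n_for(AB_CHANNEL, rng_ab)
    coloc_mask = rng_ab.random(len(post)) < config.coloc_fraction
    ab: list[Punctum] = []
    coloc_post_ids = [int(i) for i in np.nonzero(coloc_mask)[0]]
    for i in coloc_post_ids:
        # concentric and at least as large as the post punctum, so the post
        # object's own-volume overlap is far above the 25% criterion
        r = max(float(rng_ab.normal(config.radius_mean_um, config.radius_sd_um)),
                post[i].radius_um * 1.1)
        a = max(float(rng_ab.normal(config.amplitude_mean, config.amplitude_sd)), 1.0)
        ab.append(Punctum(len(ab), AB_CHANNEL, post[i].centroid_um, r, a))
    n_ab_indep = max(0, n_ab_target - len(ab))
    if n_ab_indep:
        post_centres = np.array([p.centroid_um for p in post]).reshape(-1, 3)
        indep = _place_centres(rng_ab, n_ab_indep, config, config.min_separation_um,
                               avoid=post_centres if len(post) else None,
                               avoid_dist=config.ab_exclusion_um)
        radii, amps = _draw_radii_amps(rng_ab, n_ab_indep, config)
        for c, r, a in zip(indep, radii, amps):
            ab.append(Punctum(len(ab), AB_CHANNEL, tuple(c), float(r), float(a)))

    man.puncta = {PRE_CHANNEL: pre, POST_CHANNEL: post, AB_CHANNEL: ab}
    man.pairs = pairs
    man.coloc_post_ids = coloc_post_ids
    # pre-synapses sharing a constructed A-beta blob via their paired post
    paired_post = {j: i for i, j, _ in pairs}
    man.coloc_pre_ids = sorted(paired_post[j] for j in coloc_post_ids if j in paired_post)

    # --- render and record truth ---
    channels: dict[str, ImageStack] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for ch in CHANNELS:
            img, truth = _render_channel(man.puncta[ch], config)
            man.truth_masks[ch] = truth
            man.burden_pct[ch] = 100.0 * truth.sum() / truth.size
            channels[ch] = ImageStack(img, geometry=g, channel_name=ch)
    roi = RegionOfInterest(case_id=case_id, treatment_label=treatment,
                           roi_index=roi_index, channels=channels)

    # --- jitter (shared across channels; middle section is the reference) ---
    rng_j = _rng(config.seed, "jitter")
    n_sec = config.n_sections
    if config.jitter_max_px > 0:
        if config.subpixel_jitter:
            jit = rng_j.uniform(-config.jitter_max_px, config.jitter_max_px, (n_sec, 2))
        else:
            jit = rng_j.integers(-config.jitter_max_px, config.jitter_max_px + 1,
                                 (n_sec, 2)).astype(float)
        jit -= jit[n_sec // 2]
    else:
        jit = np.zeros((n_sec, 2))
    man.jitter_px = [tuple(map(float, v)) for v in jit]
    if np.any(jit):
        roi = apply_section_jitter(roi, man.jitter_px)

    # --- specks + noise ---
    def corrupt(stack: ImageStack) -> ImageStack:
        ch = stack.channel_name
        img = np.asarray(stack.voxels, dtype=np.float64).copy()
        man.speck_count[ch] = _add_specks(img, _rng(config.seed, f"specks.{ch}"), config)
        return add_noise(stack.with_voxels(img), config, _rng(config.seed, f"noise.{ch}"))

    roi = roi.map_channels(corrupt)
    return roi, man
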