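"""Synthetic polar-domain IVOCT pullback generator with ground truth.

Emulates the statistical structure of clinical intravascular OCT volumes of
interest (VOIs): stacks of contiguous polar (r, theta) frames with an
eccentric lumen, a guidewire shadow, multiplicative speckle on a smoothly
attenuating tissue profile, and — for calcification VOIs — a signal-poor
lesion arc with a sharp front border whose geometry drifts smoothly along the
pullback (z) direction. Every quantity a downstream stage needs is emitted as
ground truth: per-A-line lumen offsets, guidewire A-line indices, and binary
calcific masks.

Default geometry targets roughly 10% calcific pixels over a mixed
normal/calcification dataset (26:34 VOI split) measured in the 200-pixel
lumen-aligned crop used for training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

NORMAL = "normal"
CALCIFICATION = "calcification"


@dataclass
class LesionParams:
    """Geometry of a calcific lesion arc and its smooth drift along z.

    Angles in degrees, radial quantities in pixels. Sinusoidal modulations
    (random phases per VOI) keep neighbouring frames strongly correlated.
    """

    arc_center_deg: float = 120.0
    arc_extent_deg: float = 160.0
    depth_px: float = 20.0
    thickness_px: float = 80.0
    center_drift_deg_per_frame: float = 0.8
    extent_mod_frac: float = 0.15     # relative arc-extent modulation amplitude
    depth_mod_px: float = 5.0
    thickness_mod_frac: float = 0.10
    mod_period_frames: float = 40.0
    attenuation: float = 0.22         # lesion intensity multiplier (signal-poor)

    def validate(self) -> None:
        if not (0.0 < self.arc_extent_deg <= 360.0):
            raise ValueError("arc extent must lie in (0, 360] degrees")
        if min(self.depth_px, self.thickness_px) < 0:
            raise ValueError("lesion depth/thickness must be non-negative")


@dataclass
class PhantomConfig:
    """Parameters of one synthetic VOI. ``seed`` fully determines the output."""

    n_alines: int = 496
    n_radial: int = 400
    n_frames: int = 50
    label: str = CALCIFICATION
    lumen_radius_mean: float = 90.0
    lumen_amplitude: float = 18.0
    guidewire_width: int = 18
    guidewire_center_deg: float | None = None   # None: drawn from seed
    lesion: LesionParams = field(default_factory=LesionParams)
    speckle_scale: float = 0.35
    tissue_peak: float = 0.85
    tissue_attenuation_px: float = 110.0
    background: float = 0.02
    calcific_prevalence_target: float = 0.10    # informational; see module docstring
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_alines, self.n_radial, self.n_frames) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.n_frames > 200 or self.n_frames < 1:
            raise ValueError("n_frames must lie in [1, 200]")
        if not 0 <= self.guidewire_width < self.n_alines:
            raise ValueError("guidewire width out of range")
        self.lesion.validate()
        lumen_max = self.lumen_radius_mean + self.lumen_amplitude
        if self.label == CALCIFICATION:
            reach = lumen_max + self.lesion.depth_px + self.lesion.thickness_px \
                + self.lesion.depth_mod_px \
                + self.lesion.thickness_mod_frac * self.lesion.thickness_px
            if reach >= self.n_radial:
                raise ValueError(
                    f"lesion geometry (max radial reach {reach:.0f}px) exceeds "
                    f"n_radial={self.n_radial}")
        elif self.label != NORMAL:
            raise ValueError(f"unknown label {self.label!r}")
        if lumen_max >= self.n_radial:
            raise ValueError("lumen exceeds image depth")


@dataclass
class PolarPullback:
    """One synthetic VOI: frames, lumen traces, guidewire shadow, masks."""

    frames: np.ndarray          # (n_frames, n_radial, n_alines) float32 in [0,1]
    lumen: np.ndarray           # (n_frames, n_alines) int, first tissue pixel
    guidewire: list[np.ndarray]  # per-frame sorted A-line indices
    masks: np.ndarray           # (n_frames, n_radial, n_alines) uint8
    voi_label: str
    voi_id: str = "voi"
    config: PhantomConfig | None = None
    lesion_truth: pd.DataFrame | None = None  # per-frame generated geometry

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def validate(self) -> None:
        n, nr, na = self.frames.shape
        if self.lumen.shape != (n, na) or self.masks.shape != (n, nr, na):
            raise ValueError("frames, lumen and masks must share the frame count")
        if self.lumen.min() < 0 or self.lumen.max() >= nr:
            raise ValueError("lumen offsets out of [0, n_radial)")


def _arc_alines(center_deg: float, extent_deg: float, n_alines: int) -> np.ndarray:
    """A-line indices covered by a circular arc (wraps through theta = 0)."""
    deg_per = 360.0 / n_alines
    half = extent_deg / 2.0
    a = np.arange(n_alines) * deg_per
    d = np.abs((a - center_deg + 180.0) % 360.0 - 180.0)
    return np.flatnonzero(d <= half)


def _smooth(f: np.ndarray, period: float, phase: float) -> np.ndarray:
    return np.sin(2.0 * np.pi * f / period + phase)


def generate_voi(config: PhantomConfig, *, voi_id: str = "voi") -> PolarPullback:
    """Render one VOI deterministically from ``config.seed``."""
    config.validate()
    return _generate(config, [(config.lesion, config.n_frames)], voi_id=voi_id)


def generate_voi_with_archetypes(config: PhantomConfig,
                                 archetypes: list[LesionParams | None],
                                 block_fractions: list[float] | None = None,
                                 *, voi_id: str = "voi") -> PolarPullback:
    """VOI whose frames come from contiguous blocks of distinct lesion
    morphologies (used for cluster-recovery experiments).

    A ``None`` archetype is a plaque-free block: those frames carry no lesion
    and empty masks, so a calcification VOI's lesion can span only part of
    its frames — as in clinical stacks where the lesion enters and leaves
    the imaged segment.
    """
    config.validate()
    for a in archetypes:
        if a is not None:
            a.validate()
    k = len(archetypes)
    if block_fractions is None:
        block_fractions = [1.0 / k] * k
    if len(block_fractions) != k or abs(sum(block_fractions) - 1.0) > 1e-6:
        raise ValueError("block_fractions must match archetypes and sum to 1")
    edges = np.floor(np.cumsum([0.0] + list(block_fractions)) * config.n_frames).astype(int)
    edges[-1] = config.n_frames
    blocks = []
    for i, arch in enumerate(archetypes):
        n = int(edges[i + 1] - edges[i])
        if n < 1:
            raise ValueError("every archetype must contribute at least one frame")
        blocks.append((arch, n))
    return _generate(config, blocks, voi_id=voi_id)


def _generate(config: PhantomConfig, blocks, *, voi_id: str) -> PolarPullback:
    rng = np.random.default_rng(config.seed)
    na, nr, nf = config.n_alines, config.n_radial, config.n_frames
    deg_per = 360.0 / na

    # per-VOI random phases so drift differs between VOIs but is z-smooth
    ph_lumen_theta = rng.uniform(0, 2 * np.pi)
    ph_lumen_z = rng.uniform(0, 2 * np.pi)
    ph_ext = rng.uniform(0, 2 * np.pi)
    ph_dep = rng.uniform(0, 2 * np.pi)
    ph_thk = rng.uniform(0, 2 * np.pi)
    gw_center = (config.guidewire_center_deg if config.guidewire_center_deg is not None
                 else rng.uniform(0, 360.0))
    gw_drift = rng.uniform(-0.3, 0.3)   # deg per frame

    frames = np.empty((nf, nr, na), dtype=np.float32)
    masks = np.zeros((nf, nr, na), dtype=np.uint8)
    lumen = np.empty((nf, na), dtype=np.int64)
    guidewire: list[np.ndarray] = []
    truth_rows = []

    r = np.arange(nr, dtype=np.float32)[:, None]
    theta = np.arange(na, dtype=np.float32) * (2 * np.pi / na)

    frame_blocks = []
    for arch, n in blocks:
        frame_blocks.extend([arch] * n)

    for f in range(nf):
        arch = frame_blocks[f]
        lum = (config.lumen_radius_mean
               + config.lumen_amplitude
               * np.sin(theta + ph_lumen_theta + 0.12 * f + 0.35 * np.sin(
                   2 * np.pi * f / 60.0 + ph_lumen_z)))
        lum_i = np.clip(np.round(lum).astype(np.int64), 0, nr - 1)
        lumen[f] = lum_i

        depth = r - lum_i[None, :]
        tissue = depth >= 0
        img = np.where(
            tissue,
            config.tissue_peak * np.exp(-np.maximum(depth, 0) / config.tissue_attenuation_px),
            config.background).astype(np.float32)

        is_calc = config.label == CALCIFICATION and arch is not None
        if is_calc:
            center = arch.arc_center_deg + arch.center_drift_deg_per_frame * f
            extent = arch.arc_extent_deg * (
                1.0 + arch.extent_mod_frac * _smooth(np.float64(f), arch.mod_period_frames, ph_ext))
            extent = float(np.clip(extent, 1.0, 360.0))
            dep = arch.depth_px + arch.depth_mod_px * _smooth(
                np.float64(f), arch.mod_period_frames, ph_dep)
            thk = arch.thickness_px * (
                1.0 + arch.thickness_mod_frac * _smooth(np.float64(f), arch.mod_period_frames, ph_thk))
            arc = _arc_alines(center % 360.0, extent, na)
            front = lum_i[arc] + int(round(dep))
            back = front + max(1, int(round(thk)))
            in_lesion = (r >= front[None, :].astype(np.float32)) & (r < back[None, :])
            img[:, arc] = np.where(in_lesion, img[:, arc] * arch.attenuation, img[:, arc])
            m = np.zeros((nr, na), dtype=np.uint8)
            m[:, arc] = in_lesion.astype(np.uint8)
            masks[f] = m
            truth_rows.append({"frame": f, "arc_center_deg": center % 360.0,
                               "arc_extent_deg": extent, "depth_px": int(round(dep)),
                               "thickness_px": max(1, int(round(thk)))})
        else:
            truth_rows.append({"frame": f, "arc_center_deg": np.nan,
                               "arc_extent_deg": 0.0, "depth_px": 0, "thickness_px": 0})

        # multiplicative exponential speckle, clipped to [0, 1]
        sp = rng.exponential(1.0, size=(nr, na)).astype(np.float32)
        img = img * ((1.0 - config.speckle_scale) + config.speckle_scale * sp)
        np.clip(img, 0.0, 1.0, out=img)

        # guidewire shadow: contiguous circular run of zeroed A-lines
        gwc = (gw_center + gw_drift * f) % 360.0
        gw = _arc_alines(gwc, config.guidewire_width * deg_per, na)
        img[:, gw] = 0.0
        masks[f][:, gw] = 0
        guidewire.append(np.sort(gw))

        frames[f] = img

    pb = PolarPullback(frames=frames, lumen=lumen, guidewire=guidewire,
                       masks=masks, voi_label=config.label, voi_id=voi_id,
                       config=config, lesion_truth=pd.DataFrame(truth_rows))
    pb.validate()
    return pb


def generate_dataset(n_vois_normal: int, n_vois_calc: int,
                     group_structure: list[LesionParams] | None = None,
                     seed: int = 0, *, base_config: PhantomConfig | None = None,
                     frames_range: tuple[int, int] = (20, 60)) -> list[PolarPullback]:
    """A mixed list of VOIs, each independently seeded from the master seed.

    VOI frame counts are drawn uniformly from ``frames_range``. When
    ``group_structure`` is given, every calcification VOI's frames are drawn
    from those planted lesion archetypes in contiguous blocks.
    """
    if min(n_vois_normal, n_vois_calc) < 0:
        raise ValueError("VOI counts must be >= 0")
    base = base_config if base_config is not None else PhantomConfig()
    master = np.random.default_rng(seed)
    n_total = n_vois_normal + n_vois_calc
    voi_seeds = master.integers(0, 2**31 - 1, size=n_total)
    n_frames_all = master.integers(frames_range[0], frames_range[1] + 1, size=n_total)
    labels = [NORMAL] * n_vois_normal + [CALCIFICATION] * n_vois_calc

    out = []
    for i, (label, s, nf) in enumerate(zip(labels, voi_seeds, n_frames_all)):
        cfg = replace(base, label=label, seed=int(s), n_frames=int(nf))
        vid = f"voi{i:03d}_{label[:4]}"
        if label == CALCIFICATION and group_structure:
            out.append(generate_voi_with_archetypes(cfg, list(group_structure), voi_id=vid))
        else:
            out.append(generate_voi(cfg, voi_id=vid))
    return out


# ---------------------------------------------------------------------------
# on-disk format: frames.tif + masks.tif + lumen.csv + meta.json per VOI
# ---------------------------------------------------------------------------

def write_voi(pullback: PolarPullback, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "frames.tif", pullback.frames)
    tifffile.imwrite(out / "masks.tif", pullback.masks)
    n, _, na = pullback.frames.shape
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n), na),
        "aline": np.tile(np.arange(na), n),
        "offset": pullback.lumen.ravel(),
    })
    df.to_csv(out / "lumen.csv", index=False)
    meta = {
        "voi_id": pullback.voi_id,
        "label": pullback.voi_label,
        "n_frames": int(n),
        "guidewire": [g.tolist() for g in pullback.guidewire],
        "config": asdict(pullback.config) if pullback.config else None,
    }
    (out / "meta.json").write_text(json.dumps(meta))
    return out


def read_voi(voi_dir: str | Path) -> PolarPullback:
    d = Path(voi_dir)
    frames = tifffile.imread(d / "frames.tif")
    masks = tifffile.imread(d / "masks.tif")
    meta = json.loads((d / "meta.json").read_text())
    df = pd.read_csv(d / "lumen.csv")
    n = meta["n_frames"]
    na = frames.shape[2]
    lumen = df["offset"].to_numpy().reshape(n, na)
    cfg = None
    if meta.get("config"):
        c = dict(meta["config"])
        c["lesion"] = LesionParams(**c["lesion"])
        cfg = PhantomConfig(**c)
    pb = PolarPullback(
        frames=frames, lumen=lumen,
        guidewire=[np.asarray(g, dtype=np.int64) for g in meta["guidewire"]],
        masks=masks, voi_label=meta["label"], voi_id=meta["voi_id"], config=cfg)
    pb.validate()
    return pb
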