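"""Polar-domain preprocessing: guidewire zeroing, lumen alignment, crop,
log transform and Gaussian speckle reduction.

The chain maps a raw polar frame plus its lumen trace to the fixed-size tensor
every network consumes: A-lines inside the guidewire shadow are zeroed, each
A-line is pixel-shifted radially so the lumen boundary sits at row 0, the
first ``crop_depth`` pixels (~1 mm) from the lumen are kept, and intensities
are log-transformed, rescaled to [0, 1] per frame and smoothed with a small
Gaussian. Masks follow the same integer geometric operations but are never
filtered, so they stay binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .phantom import PolarPullback


@dataclass
class PreprocessConfig:
    crop_depth: int = 200
    gauss_kernel: tuple[int, int] = (7, 7)
    gauss_sigma: float = 1.0
    log_epsilon: float = 1e-6

    def validate(self, n_radial: int | None = None) -> None:
        if self.crop_depth <= 0:
            raise ValueError("crop_depth must be positive")
        if n_radial is not None and self.crop_depth > n_radial:
            raise ValueError("crop_depth exceeds image depth")
        if any(k % 2 == 0 or k < 1 for k in self.gauss_kernel):
            raise ValueError("Gaussian kernel dims must be odd")
        if self.gauss_sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be > 0")


@dataclass
class AlignedFrame:
    """A lumen-aligned (and possibly cropped/denoised) polar frame.

    Row 0 of every non-guidewire A-line is the lumen boundary pixel of that
    A-line; ``shifts`` records the per-A-line radial shift applied, enabling
    an exact un-shift of the retained depth range.
    """

    image: np.ndarray                     # (depth, n_alines) float
    mask: np.ndarray                      # same shape, binary
    shifts: np.ndarray                    # (n_alines,) int, pixels shifted up
    guidewire: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    frame_id: int = 0

    def validate(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image/mask shape mismatch")
        if self.shifts.shape[0] != self.image.shape[1]:
            raise ValueError("shifts length must equal n_alines")


def detect_guidewire_alines(frame: np.ndarray, lumen: np.ndarray | None = None,
                            *, c: float = 3.0, rel_floor: float = 0.05,
                            min_width: int = 4) -> np.ndarray:
    """Locate the guidewire shadow as the widest circular run of dark A-lines.

    Sums each A-line's intensity beyond the lumen and flags A-lines whose sum
    falls below an adaptive threshold ``min(median - c*MAD,
    rel_floor*median)``; the maximal circularly-contiguous run of flagged
    A-lines wider than ``min_width`` is returned (empty array if none). The
    relative floor matters when signal-poor lesions darken a wide arc: the
    shadow carries essentially zero intensity, an attenuated lesion does not,
    and the floor keeps the lesion arc out of the flagged set.
    """
    nr, na = frame.shape
    if lumen is not None:
        r = np.arange(nr)[:, None]
        sums = np.where(r >= lumen[None, :], frame, 0.0).sum(axis=0)
    else:
        sums = frame.sum(axis=0)
    med = np.median(sums)
    mad = np.median(np.abs(sums - med))
    low = sums < min(med - c * mad, rel_floor * med) - 1e-12

    if not low.any():
        return np.empty(0, dtype=np.int64)
    if low.all():
        return np.arange(na, dtype=np.int64)

    # longest run on the circle: cut at a non-flagged A-line, then scan linearly
    start = int(np.argmin(low))  # first False
    rolled = np.roll(low, -start)
    best_len, best_at, run, run_at = 0, 0, 0, 0
    for i, v in enumerate(rolled):
        if v:
            if run == 0:
                run_at = i
            run += 1
            if run > best_len:
                best_len, best_at = run, run_at
        else:
            run = 0
    if best_len < min_width:
        return np.empty(0, dtype=np.int64)
    idx = (np.arange(best_at, best_at + best_len) + start) % na
    return np.sort(idx.astype(np.int64))


def zero_guidewire(frame: np.ndarray, alines: np.ndarray,
                   mask: np.ndarray | None = None):
    """Zero the listed A-lines in the image (and mask); others untouched."""
    out = frame.copy()
    alines = np.asarray(alines, dtype=np.int64)
    out[:, alines] = 0.0
    if mask is None:
        return out
    m = mask.copy()
    m[:, alines] = 0
    return out, m


def pixel_shift_align(frame: np.ndarray, mask: np.ndarray,
                      lumen_trace: np.ndarray, *,
                      guidewire: np.ndarray | None = None,
                      frame_id: int = 0) -> AlignedFrame:
    """Shift each A-line up by its lumen offset so tissue starts at row 0.

    Integer shifts, zero fill for the vacated deep pixels; the identical shift
    is applied to the mask.
    """
    nr, na = frame.shape
    lumen_trace = np.asarray(lumen_trace)
    if lumen_trace.shape[0] != na:
        raise ValueError(f"lumen trace has {lumen_trace.shape[0]} entries, "
                         f"frame has {na} A-lines")
    if lumen_trace.min() < 0 or lumen_trace.max() >= nr:
        raise ValueError("lumen offsets out of [0, n_radial)")
    shifts = lumen_trace.astype(np.int64)

    rows = np.arange(nr)[:, None] + shifts[None, :]     # source row per target
    valid = rows < nr
    rows = np.where(valid, rows, 0)
    cols = np.broadcast_to(np.arange(na)[None, :], (nr, na))
    image = np.where(valid, frame[rows, cols], 0.0).astype(frame.dtype)
    msk = np.where(valid, mask[rows, cols], 0).astype(mask.dtype)
    gw = (np.sort(np.asarray(guidewire, dtype=np.int64))
          if guidewire is not None else np.empty(0, dtype=np.int64))
    af = AlignedFrame(image=image, mask=msk, shifts=shifts, guidewire=gw,
                      frame_id=frame_id)
    af.validate()
    return af


def undo_shift(aligned: AlignedFrame, n_radial: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`pixel_shift_align` on the retained depth range.

    Pixels shifted beyond the aligned frame's depth are irrecoverable and come
    back as zeros.
    """
    depth, na = aligned.image.shape
    nr = n_radial if n_radial is not None else depth
    img = np.zeros((nr, na), dtype=aligned.image.dtype)
    msk = np.zeros((nr, na), dtype=aligned.mask.dtype)
    for a in range(na):
        o = aligned.shifts[a]
        take = min(depth, nr - o)
        img[o:o + take, a] = aligned.image[:take, a]
        msk[o:o + take, a] = aligned.mask[:take, a]
    return img, msk


def crop_log_smooth(aligned: AlignedFrame, cfg: PreprocessConfig) -> AlignedFrame:
    """Crop to the first ``crop_depth`` rows, log-transform, rescale to [0, 1]
    per frame, and Gaussian-filter; the mask is cropped but never filtered."""
    cfg.validate()
    depth = aligned.image.shape[0]
    if cfg.crop_depth > depth:
        raise ValueError(f"crop_depth {cfg.crop_depth} exceeds {depth} rows")
    img = aligned.image[:cfg.crop_depth].astype(np.float64)
    msk = aligned.mask[:cfg.crop_depth].copy()

    img = np.log(img + cfg.log_epsilon)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

    radius = (np.asarray(cfg.gauss_kernel) - 1) // 2
    img = ndimage.gaussian_filter(
        img, sigma=cfg.gauss_sigma,
        truncate=float(radius.min()) / cfg.gauss_sigma, mode="nearest")

    # smoothing bleeds neighbours into the shadow; restore the exact-zero contract
    if aligned.guidewire.size:
        img[:, aligned.guidewire] = 0.0

    out = AlignedFrame(image=img.astype(np.float32), mask=msk,
                       shifts=aligned.shifts, guidewire=aligned.guidewire,
                       frame_id=aligned.frame_id)
    out.validate()
    return out


def preprocess_frame(frame: np.ndarray, mask: np.ndarray,
                     lumen_trace: np.ndarray, cfg: PreprocessConfig, *,
                     guidewire: np.ndarray | None = None,
                     frame_id: int = 0) -> AlignedFrame:
    """detect -> zero -> shift -> crop/log/smooth for a single frame."""
    gw = guidewire if guidewire is not None else \
        detect_guidewire_alines(frame, lumen_trace)
    img, msk = zero_guidewire(frame, gw, mask)
    aligned = pixel_shift_align(img, msk, lumen_trace, guidewire=gw,
                                frame_id=frame_id)
    return crop_log_smooth(aligned, cfg)


def preprocess_voi(pullback: PolarPullback,
                   cfg: PreprocessConfig | None = None, *,
                   use_truth_guidewire: bool = True) -> list[AlignedFrame]:
    """Apply the full chain to every frame of a VOI, in order.

    With ``use_truth_guidewire`` the generator's ground-truth guidewire
    indices bypass the intensity-based detector (the detector remains the
    fallback for data without that annotation).
    """
    cfg = cfg if cfg is not None else PreprocessConfig()
    cfg.validate(n_radial=pullback.frames.shape[1])
    out = []
    for f in range(pullback.n_frames):
        gw = pullback.guidewire[f] if (use_truth_guidewire and pullback.guidewire) else None
        try:
            out.append(preprocess_frame(
                pullback.frames[f], pullback.masks[f], pullback.lumen[f],
                cfg, guidewire=gw, frame_id=f))
        except Exception as exc:
            raise type(exc)(f"frame {f} of VOI {pullback.voi_id!r}: {exc}") from exc
    return out


def write_preprocessed(frames: list[AlignedFrame], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "aligned.tif", np.stack([f.image for f in frames]))
    tifffile.imwrite(out / "aligned_masks.tif", np.stack([f.mask for f in frames]))
    prov = [{"frame_id": f.frame_id, "shifts": f.shifts.tolist(),
             "guidewire": f.guidewire.tolist()} for f in frames]
    (out / "provenance.json").write_text(json.dumps(prov))
    return out


def read_preprocessed(in_dir: str | Path) -> list[AlignedFrame]:
    d = Path(in_dir)
    imgs = tifffile.imread(d / "aligned.tif")
    msks = tifffile.imread(d / "aligned_masks.tif")
    prov = json.loads((d / "provenance.json").read_text())
    return [AlignedFrame(image=imgs[i], mask=msks[i],
                         shifts=np.asarray(p["shifts"], dtype=np.int64),
                         guidewire=np.asarray(p["guidewire"], dtype=np.int64),
                         frame_id=p["frame_id"])
            for i, p in enumerate(prov)]
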