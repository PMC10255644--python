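"""Fixed-size 50%-overlap segmentation of labeled recordings.

Windows are anchored at each labeled interval's start and slide by half a
window; a window is emitted only if it fits entirely inside its interval,
so no window ever mixes two behaviors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from henrec._seeding import substream
from henrec.signals_io import InertialRecording, LabelInterval

logger = logging.getLogger(__name__)

VALID_WS = (64, 128, 256, 512, 1024)


@dataclass(frozen=True)
class WindowingSpec:
    """Window size in samples and the sampling frequency it applies to.

    Window length in seconds is WL = WS / SF; the stride is WS/2 samples
    (50% overlap, the only overlap this pipeline uses).
    """

    ws: int
    sf: float
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.ws not in VALID_WS:
            raise ValueError(f"WS must be one of {VALID_WS}, got {self.ws}")
        stride = self.ws * (1 - self.overlap_fraction)
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError("stride WS*(1-overlap) must be an integer")

    @property
    def wl(self) -> float:
        return window_length(self.ws, self.sf)

    @property
    def stride_samples(self) -> int:
        return int(round(self.ws * (1 - self.overlap_fraction)))


@dataclass(frozen=True)
class WindowInstance:
    """One WS x 6 labeled segment cut from a recording."""

    hen_id: str
    behavior: str
    start_s: float
    samples: np.ndarray = field(repr=False)  # (WS, 6): acc x/y/z, gyr x/y/z
    source_interval: LabelInterval | None = None

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ValueError("window samples must be (WS, 6)")


def window_length(ws: int, sf: float) -> float:
    """Window length in seconds: WL = WS / SF."""
    if ws <= 0 or sf <= 0:
        raise ValueError("WS and SF must be positive")
    return ws / sf


def segment(
    rec: InertialRecording,
    labels: Sequence[LabelInterval],
    spec: WindowingSpec,
) -> list[WindowInstance]:
    """Cut 50%-overlapped windows from every labeled interval of one hen.

    Windows start at the interval start and advance by WS/2 samples; only
    windows whose full WS samples lie inside the interval are emitted.
    Intervals shorter than one window yield nothing (logged, not an error).
    """
    if abs(rec.sampling_frequency - spec.sf) > 1e-9:
        raise ValueError(
            f"recording SF {rec.sampling_frequency} != spec SF {spec.sf}"
        )
    t = rec.timestamps
    chans = rec.data[
        ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
    ].to_numpy()
    ws, stride = spec.ws, spec.stride_samples
    out: list[WindowInstance] = []
    for interval in labels:
        if interval.hen_id != rec.hen_id:
            raise ValueError(
                f"label for hen {interval.hen_id!r} given with recording "
                f"for hen {rec.hen_id!r}"
            )
        # first sample at or after the interval start
        i0 = int(np.searchsorted(t, interval.start_s - 1e-12))
        # last sample strictly before the (end-exclusive) interval end
        i_end = int(np.searchsorted(t, interval.end_s - 1e-12)) - 1
        n_in = i_end - i0 + 1
        if n_in < ws:
            logger.debug(
                "interval %s [%.3f, %.3f) shorter than WL, no windows",
                interval.behavior, interval.start_s, interval.end_s,
            )
            continue
        for s in range(i0, i_end - ws + 2, stride):
            out.append(
                WindowInstance(
                    hen_id=rec.hen_id,
                    behavior=interval.behavior,
                    start_s=float(t[s]),
                    samples=chans[s : s + ws],
                    source_interval=interval,
                )
            )
    return out


def _class_counts(windows: Sequence[WindowInstance]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for w in windows:
        counts[w.behavior] = counts.get(w.behavior, 0) + 1
    return counts


def equalize_counts(
    windows: Sequence[WindowInstance],
    target_counts: Mapping[str, int],
    seed: int,
) -> list[WindowInstance]:
    """Under-sample per class to exact target counts (EQ condition).

    Classes absent from ``target_counts`` are kept untouched. Sampling is
    uniform without replacement and reproducible under ``seed``.
    """
    available = _class_counts(windows)
    for cls, tgt in target_counts.items():
        if available.get(cls, 0) < tgt:
            raise ValueError(
                f"target {tgt} for class {cls!r} exceeds available "
                f"{available.get(cls, 0)}"
            )
    rng = substream(seed, "equalize_counts")
    kept_idx: list[int] = []
    by_class: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_class.setdefault(w.behavior, []).append(i)
    for cls, idxs in by_class.items():
        if cls in target_counts:
            chosen = rng.choice(len(idxs), size=target_counts[cls], replace=False)
            kept_idx.extend(idxs[j] for j in sorted(chosen))
        else:
            kept_idx.extend(idxs)
    kept_idx.sort()
    return [windows[i] for i in kept_idx]


def standardize_across_sf(
    windows_by_sf: Mapping[float, Sequence[WindowInstance]],
    seed: int,
    reference_sf: float = 50.0,
) -> dict[float, list[WindowInstance]]:
    """Match window counts across sampling frequencies to the 50 Hz condition.

    Higher sampling frequencies lose fewer samples at interval edges and so
    yield slightly more windows; to compare conditions fairly every
    (class, hen) cell is randomly subsampled down to that cell's count at
    the reference frequency. Cells already at or below the reference count
    are untouched (logged).
    """
    if reference_sf not in windows_by_sf:
        raise ValueError(f"reference SF {reference_sf} Hz missing from input")

    def cell_key(w: WindowInstance) -> tuple[str, str]:
        return (w.behavior, w.hen_id)

    ref_counts: dict[tuple[str, str], int] = {}
    for w in windows_by_sf[reference_sf]:
        ref_counts[cell_key(w)] = ref_counts.get(cell_key(w), 0) + 1

    out: dict[float, list[WindowInstance]] = {}
    for sf, windows in windows_by_sf.items():
        if sf == reference_sf:
            out[sf] = list(windows)
            continue
        rng = substream(seed, "standardize_across_sf", str(sf))
        by_cell: dict[tuple[str, str], list[int]] = {}
        for i, w in enumerate(windows):
            by_cell.setdefault(cell_key(w), []).append(i)
        kept: list[int] = []
        for cell, idxs in by_cell.items():
            tgt = ref_counts.get(cell, len(idxs))
            if len(idxs) <= tgt:
                if len(idxs) < tgt:
                    logger.debug(
                        "cell %s at %g Hz below reference count (%d < %d)",
                        cell, sf, len(idxs), tgt,
                    )
                kept.extend(idxs)
            else:
                chosen = rng.choice(len(idxs), size=tgt, replace=False)
                kept.extend(idxs[j] for j in sorted(chosen))
        kept.sort()
        out[sf] = [windows[i] for i in kept]
    return out
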