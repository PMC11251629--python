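"""MUAP similarity and EMG feature extraction.

Similarity between two MUAPs uses the normalised mean square error:

    NMSE(a, b) = mean((a - b)^2) / ((P_a + P_b) / 2),

where P is the mean square of each template over the compared support.
NMSE is 0 for identical templates, 2 against an all-zero template and 4 for
a sign-flipped copy.  Before comparison each template is cropped to the
minimal rectangular electrode subgrid whose channels all have a peak
absolute amplitude above 75 % of the channel-wise average; a pair is then
compared on the union bounding box of the two individual crops.

Windowed RMS features (default 200-ms windows with 50-ms overlap, i.e. a
150-ms step) summarise the interference EMG for regression tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .muap import MUAPTemplate, MUAPSequence
from .synthesis import EMGRecording

__all__ = ["CropResult", "crop_muap", "nmse", "SimilarityMatrix",
           "similarity_matrix", "angle_similarity_curve", "pool_curve_stats",
           "RMSFeatures", "rms_features", "window_average"]


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

@dataclass
class CropResult:
    values: np.ndarray                 # cropped (rows, cols, T)
    row_slice: slice
    col_slice: slice
    degenerate: bool = False           # no channel above threshold


def _bbox_once(values: np.ndarray) -> tuple[slice, slice, bool]:
    peak = np.max(np.abs(values), axis=2)
    threshold = 0.75 * peak.mean()
    above = peak > threshold
    if not above.any():
        r, c = np.unravel_index(np.argmax(peak), peak.shape)
        return slice(r, r + 1), slice(c, c + 1), True
    rows = np.nonzero(above.any(axis=1))[0]
    cols = np.nonzero(above.any(axis=0))[0]
    return (slice(int(rows[0]), int(rows[-1]) + 1),
            slice(int(cols[0]), int(cols[-1]) + 1), False)


def crop_muap(muap: MUAPTemplate | np.ndarray) -> CropResult:
    """Crop to the high-amplitude subgrid (75 %-of-mean rule, iterated).

    The one-shot rule — keep the bounding box of channels whose peak absolute
    amplitude exceeds 0.75x the mean of the channel peaks — is applied
    repeatedly on its own output until the box is stable, which makes the
    operation idempotent.  A template with no channel above threshold (e.g.
    all-zero input) degenerates to the single peak channel and is flagged.
    """
    values = muap.values if isinstance(muap, MUAPTemplate) else np.asarray(muap)
    if values.ndim != 3:
        raise ValueError("expected a (rows, cols, T) template")
    r0, c0 = 0, 0
    sub = values
    degenerate = False
    while True:
        rs, cs, degenerate = _bbox_once(sub)
        new = sub[rs, cs]
        if new.shape == sub.shape:
            break
        r0, c0 = r0 + rs.start, c0 + cs.start
        sub = new
    return CropResult(sub, slice(r0, r0 + sub.shape[0]),
                      slice(c0, c0 + sub.shape[1]), degenerate)


def _union_support(a_vals: np.ndarray, b_vals: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    ca, cb = crop_muap(a_vals), crop_muap(b_vals)
    r0 = min(ca.row_slice.start, cb.row_slice.start)
    r1 = max(ca.row_slice.stop, cb.row_slice.stop)
    c0 = min(ca.col_slice.start, cb.col_slice.start)
    c1 = max(ca.col_slice.stop, cb.col_slice.stop)
    return a_vals[r0:r1, c0:c1], b_vals[r0:r1, c0:c1]


def nmse(a: MUAPTemplate | np.ndarray, b: MUAPTemplate | np.ndarray,
         crop: bool = True) -> float:
    """Normalised mean square error between two templates.

    With ``crop=True`` both templates are first cropped and compared on the
    union bounding box of their individual crops; ``crop=False`` compares on
    the full common shape.
    """
    av = a.values if isinstance(a, MUAPTemplate) else np.asarray(a, float)
    bv = b.values if isinstance(b, MUAPTemplate) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError("templates must share shape")
    if crop:
        av, bv = _union_support(av, bv)
    p_a = np.mean(av ** 2)
    p_b = np.mean(bv ** 2)
    if p_a == 0 and p_b == 0:
        raise ValueError("NMSE undefined for two all-zero templates")
    return float(np.mean((av - bv) ** 2) / ((p_a + p_b) / 2.0))


# ---------------------------------------------------------------------------
# Similarity matrices and angle curves
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    labels: list[tuple[str, int]]      # (muscle, unit) identifiers
    values: np.ndarray                 # pairwise NMSE, symmetric, zero diag
    threshold: float = 0.2

    @property
    def similar(self) -> np.ndarray:
        """Boolean map at the NMSE threshold (True = similar, NMSE < 0.2)."""
        return self.values < self.threshold

    def block(self, muscle_a: str, muscle_b: str) -> np.ndarray:
        ia = [i for i, (m, _) in enumerate(self.labels) if m == muscle_a]
        ib = [i for i, (m, _) in enumerate(self.labels) if m == muscle_b]
        return self.values[np.ix_(ia, ib)]


def similarity_matrix(muaps: list[tuple[tuple[str, int], MUAPTemplate]],
                      threshold: float = 0.2) -> SimilarityMatrix:
    """All pairwise NMSE values between labelled templates."""
    if len(muaps) < 2:
        raise ValueError("need at least two templates")
    labels = [lab for lab, _ in muaps]
    n = len(muaps)
    vals = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            v = nmse(muaps[i][1], muaps[k][1])
            vals[i, k] = vals[k, i] = v
    return SimilarityMatrix(labels, vals, threshold)


def angle_similarity_curve(seq: MUAPSequence, baseline_index: int = 0
                           ) -> np.ndarray:
    """NMSE of every keyframe template against the baseline keyframe.

    With the baseline at the neutral posture and a monotone parameter
    trajectory the curve grows away from zero as the movement departs the
    baseline (templates morph progressively away from their initial shape).
    """
    if not 0 <= baseline_index < len(seq.templates):
        raise IndexError("baseline_index out of range")
    base = seq.templates[baseline_index]
    return np.array([nmse(t, base) if k != baseline_index else 0.0
                     for k, t in enumerate(seq.templates)])


def pool_curve_stats(sequences: list[MUAPSequence], baseline_index: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-keyframe mean and variance of the angle-similarity curves of a pool."""
    curves = np.stack([angle_similarity_curve(s, baseline_index)
                       for s in sequences])
    return curves.mean(axis=0), curves.var(axis=0)


def save_similarity(sm: SimilarityMatrix, tsv_path, png_path=None) -> None:
    """Export a similarity matrix as TSV (and optionally a heatmap image)."""
    import pandas as pd
    names = [f"{m}:{u}" for m, u in sm.labels]
    pd.DataFrame(sm.values, index=names, columns=names).to_csv(
        tsv_path, sep="\t", float_format="%.6g")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        im = axes[0].imshow(sm.values, cmap="viridis_r")
        axes[0].set_title("NMSE")
        fig.colorbar(im, ax=axes[0])
        axes[1].imshow(sm.values > sm.threshold, cmap="gray_r")
        axes[1].set_title(f"NMSE > {sm.threshold}")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def save_curve(curve: np.ndarray, angles: np.ndarray, tsv_path,
               png_path=None, variance: np.ndarray | None = None) -> None:
    """Export an angle-similarity curve as TSV (and optionally a line plot)."""
    import pandas as pd
    df = pd.DataFrame({"normalized_angle": angles, "nmse": curve})
    if variance is not None:
        df["variance"] = variance
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(angles, curve)
        if variance is not None:
            sd = np.sqrt(variance)
            ax.fill_between(angles, curve - sd, curve + sd, alpha=0.3)
        ax.set_xlabel("normalised joint angle")
        ax.set_ylabel("NMSE vs baseline")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# RMS features
# ---------------------------------------------------------------------------

@dataclass
class RMSFeatures:
    window_s: float
    step_s: float
    times: np.ndarray                  # window centre times, seconds
    values: np.ndarray                 # (n_windows, n_channels)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def rms_features(emg: EMGRecording, window_s: float = 0.200,
                 overlap_s: float = 0.050,
                 step_s: float | None = None) -> RMSFeatures:
    """Per-channel RMS over sliding windows.

    Window starts advance by ``window_s - overlap_s`` (or an explicit
    ``step_s``); windows that would run past the record end are dropped.
    """
    step = step_s if step_s is not None else window_s - overlap_s
    if step <= 0:
        raise ValueError("window step must be positive")
    win = int(round(window_s * emg.fs))
    hop = int(round(step * emg.fs))
    if win > emg.n_samples:
        raise ValueError("window longer than the record")
    n_win = (emg.n_samples - win) // hop + 1
    values = np.empty((n_win, emg.n_channels))
    times = np.empty(n_win)
    for w in range(n_win):
        seg = emg.values[:, w * hop:w * hop + win]
        values[w] = np.sqrt(np.mean(seg ** 2, axis=1))
        times[w] = (w * hop + win / 2.0) / emg.fs
    return RMSFeatures(window_s, step, times, values)


def window_average(series: np.ndarray, fs: float, n_samples_ref: int,
                   fs_ref: float, window_s: float = 0.200,
                   overlap_s: float = 0.050,
                   step_s: float | None = None) -> np.ndarray:
    """Mean of a (label) series over the same windows as :func:`rms_features`.

    ``n_samples_ref``/``fs_ref`` describe the EMG record that defined the
    windows; the label series may run at a different rate (e.g. 40-Hz joint
    angles next to 2-kHz EMG).
    """
    step = step_s if step_s is not None else window_s - overlap_s
    win = int(round(window_s * fs_ref))
    hop = int(round(step * fs_ref))
    n_win = (n_samples_ref - win) // hop + 1
    series = np.asarray(series, dtype=float)
    out = np.empty(n_win)
    for w in range(n_win):
        t0 = w * hop / fs_ref
        t1 = (w * hop + win) / fs_ref
        i0 = int(np.floor(t0 * fs))
        i1 = max(int(np.ceil(t1 * fs)), i0 + 1)
        out[w] = series[i0:min(i1, series.size)].mean()
    return out
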