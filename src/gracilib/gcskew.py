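"""Windowed and cumulative GC skew with replication origin/terminus calls.

On a correctly assembled, bidirectionally replicating circular bacterial
chromosome the leading strand carries a G excess, so the per-window skew
(G−C)/(G+C) changes sign at the replication origin and terminus and its
running sum forms a two-arm, sawtooth-like curve with the global minimum at
the origin and the global maximum at the terminus. A genome whose cumulative
curve deviates strongly from that two-segment shape (poor piecewise-linear
fit) is either misassembled or not replicating bidirectionally — which is
what makes the skew a cheap assembly-verification tool for finished MAGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gencode import normalize_dna

BIDIRECTIONAL = "bidirectional-consistent"
INCONSISTENT = "inconsistent"


@dataclass
class SkewProfile:
    window_starts: np.ndarray
    skew: np.ndarray  # (G-C)/(G+C) per window
    cumulative: np.ndarray  # running sum of window skews
    ori_position: int  # coordinate of the cumulative minimum (end of its window)
    ter_position: int  # coordinate of the cumulative maximum (end of its window)
    verdict: str
    fit_quality: float
    zero_gc_windows: list[int] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"window_start": self.window_starts, "skew": self.skew,
             "cumulative": self.cumulative}
        )

    def plot(self, path) -> None:
        """Write a window-skew + cumulative-skew figure (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax1 = plt.subplots(figsize=(9, 4))
        ax1.scatter(self.window_starts, self.skew, s=6, c="0.6", label="GC skew")
        ax1.set_xlabel("genome position (bp)")
        ax1.set_ylabel("GC skew (G−C)/(G+C)")
        ax2 = ax1.twinx()
        ax2.plot(self.window_starts, self.cumulative, c="green", label="cumulative")
        ax2.set_ylabel("cumulative GC skew")
        for pos, lab in ((self.ori_position, "ori"), (self.ter_position, "ter")):
            ax1.axvline(pos, ls="--", c="k", lw=0.8)
            ax1.annotate(lab, (pos, ax1.get_ylim()[1]))
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _two_arm_fit_quality(cum: np.ndarray, i_min: int, i_max: int) -> float:
    """R² of the two-segment piecewise-linear interpolant through the extrema.

    The cumulative curve is predicted by linear interpolation between its
    value at the origin (minimum) and terminus (maximum) along both circular
    arcs; quality is 1 − SS_res/SS_tot, clipped to [0, 1].
    """
    n = len(cum)
    if n < 3 or i_min == i_max:
        return 0.0
    pred = np.empty(n)
    lo, hi = cum[i_min], cum[i_max]
    # arc from min to max (ascending), walking forward circularly
    span_up = (i_max - i_min) % n
    span_dn = n - span_up
    for k in range(span_up + 1):
        pred[(i_min + k) % n] = lo + (hi - lo) * k / span_up
    for k in range(1, span_dn):
        pred[(i_max + k) % n] = hi - (hi - lo) * k / span_dn
    ss_res = float(np.sum((cum - pred) ** 2))
    ss_tot = float(np.sum((cum - cum.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def skew_profile(
    genome: str,
    window: int = 1000,
    step: int = 1000,
    circular: bool = True,
    min_fit_quality: float = 0.9,
) -> SkewProfile:
    """Windowed GC skew, cumulative skew and ori/ter calls.

    Windows start every ``step`` bases and wrap past the end when the
    sequence is circular (for non-circular input the trailing windows are
    truncated and a warning is issued). A window with no G or C gets skew 0
    and is flagged. The origin is called at the global minimum of the
    cumulative curve and the terminus at the global maximum, the convention
    matching a leading-strand G excess on the plus strand; the verdict is
    bidirectional-consistent when the two-segment piecewise-linear fit to
    the cumulative curve reaches ``min_fit_quality``.
    """
    seq = normalize_dna(genome.seq if hasattr(genome, "seq") else genome)
    n = len(seq)
    if n < 2 * window:
        raise ValueError(f"genome length {n} shorter than two windows of {window}")
    if not circular:
        warnings.warn("non-circular input: windows do not wrap the origin")

    starts = np.arange(0, n, step)
    gc_codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = (gc_codes == ord("G")).astype(np.int64)
    is_c = (gc_codes == ord("C")).astype(np.int64)
    cg = np.cumsum(is_g)
    cc = np.cumsum(is_c)

    def _range_count(cs, a, b):  # [a, b) with circular wrap
        if b <= n:
            return cs[b - 1] - (cs[a - 1] if a else 0)
        return (cs[n - 1] - (cs[a - 1] if a else 0)) + cs[b - n - 1]

    skews = np.zeros(len(starts))
    zero_gc = []
    for i, s in enumerate(starts):
        e = s + window
        if not circular:
            e = min(e, n)
        g = _range_count(cg, int(s), int(e))
        c = _range_count(cc, int(s), int(e))
        if g + c == 0:
            zero_gc.append(int(s))
            skews[i] = 0.0
        else:
            skews[i] = (g - c) / (g + c)
    cumulative = np.cumsum(skews)
    i_min = int(np.argmin(cumulative))
    i_max = int(np.argmax(cumulative))
    quality = _two_arm_fit_quality(cumulative, i_min, i_max)
    # cumulative[i] is attained at the *end* of window i: the skew sign
    # change (the replication boundary) sits there, not at the window start
    return SkewProfile(
        window_starts=starts,
        skew=skews,
        cumulative=cumulative,
        ori_position=int(starts[i_min] + window) % n,
        ter_position=int(starts[i_max] + window) % n,
        verdict=BIDIRECTIONAL if quality >= min_fit_quality else INCONSISTENT,
        fit_quality=quality,
        zero_gc_windows=zero_gc,
    )
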