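"""Peak-set co-localization, the screen that motivates pair analysis.

Builds two synthetic peak sets where most peaks of factor A sit inside a peak
of factor B, and reports the co-localization fraction (>= 1 bp intersection,
half-open intervals).
"""
import numpy as np

from spice import Peak, peak_overlap

rng = np.random.default_rng(0)

b_peaks = []
for i in range(300):
    start = int(rng.integers(0, 3_000_000))
    b_peaks.append(Peak(chrom="chr1", start=start, end=start + 400, name=f"B{i}"))

a_peaks = []
for i, b in enumerate(b_peaks):
    if rng.random() < 0.88:  # most A peaks co-localize with a B peak
        center = int(rng.integers(b.start, b.end))
        a_peaks.append(Peak(chrom="chr1", start=center - 150, end=center + 150))
    else:
        start = int(rng.integers(4_000_000, 8_000_000))
        a_peaks.append(Peak(chrom="chr1", start=start, end=start + 300))

summary = peak_overlap(a_peaks, b_peaks)
print(
    f"{summary.n_a_overlapping_b}/{summary.n_a} peaks "
    f"({100 * summary.fraction_a:.1f}%) of set A co-localize with set B"
)

# Each A peak is counted once no matter how many B peaks it touches;
# touching-but-not-overlapping intervals ([x,y) vs [y,z)) do not count.
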