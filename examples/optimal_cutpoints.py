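"""Where to put the cut if dichotomization is unavoidable.

Builds the cut-point table for a range of skewness values: the percentile
maximizing the dichotomization efficiency D, and the smallest/largest
percentiles at which D still exceeds 0.6 (i.e. at least 60% of the
adjustment precision gain is retained).
"""

from dichoteff import cutpoint_frame, cutpoint_table

table = cutpoint_frame(cutpoint_table((0.0, 2.0, 5.0, 10.0, 20.0), threshold=0.6))
print(table.to_string(index=False))

print(
    "\nEach row: skew-normal shape; the split percentile maximizing D; and "
    "the range of percentiles keeping D > 0.6. The optimum drifts from the "
    "median (no skew) to about the 67th percentile once the shape parameter "
    "exceeds ~5, and the acceptable band shifts right with it."
)
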