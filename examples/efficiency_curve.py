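"""How much adjustment precision survives dichotomization, as a function
of where the split falls.

Evaluates the dichotomization efficiency D over a percentile grid for a
normal covariate and a strongly right-skewed one, and prints both curves.
D is the fraction of the precision gain from full covariate adjustment
that remains when the covariate enters the model dichotomized at its
tau-th percentile; 1.0 would mean no loss.
"""

import numpy as np

from dichoteff import efficiency_curve

grid = np.round(np.arange(0.1, 0.95, 0.05), 2)

print("tau    D (no skew, shape 0)   D (strong skew, shape 10)")
flat = dict(efficiency_curve(0.0, grid))
skew = dict(efficiency_curve(10.0, grid))
for tau in grid:
    print(f"{tau:4.2f}   {flat[tau]:8.4f}               {skew[tau]:8.4f}")

best_flat = max(flat, key=flat.get)
best_skew = max(skew, key=skew.get)
print(
    f"\nWithout skew the best split is the median (tau={best_flat:.2f}, "
    f"D={flat[best_flat]:.3f}); with shape 10 it moves to tau={best_skew:.2f} "
    f"(D={skew[best_skew]:.3f}). Splitting a skewed covariate at the median "
    f"costs precision that a two-thirds split would keep."
)
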