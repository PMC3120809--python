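"""The three Bland-Altman views for discrete ordinal data.

On integer ratings the classic mean-difference scatter collapses onto a
small lattice; this script renders the multiplicity-aware scatter, the
3-D bar chart over the same lattice, and the bar chart of differences,
for the built-in consultation example.  Figures land in ./ba_figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ordagree import ba_limits, ba_plot_data, difference_distribution
from ordagree.blandaltman import (
    plot_difference_bars,
    plot_grid_3d,
    plot_mean_difference,
)
from ordagree.datasets import participation_item1, participation_item1_pairs

out = Path("ba_figures")
out.mkdir(exist_ok=True)

pairs = participation_item1_pairs()
diffs = difference_distribution(participation_item1())
data = ba_plot_data(pairs)

print(f"{len(data.points)} occupied (average, difference) lattice cells "
      f"for n = {data.n} encounters; the largest holds "
      f"{max(p[2] for p in data.points)} of them.")

ax = plot_mean_difference(pairs, ba_limits(diffs))
ax.figure.savefig(out / "mean_difference.png", dpi=150, bbox_inches="tight")
plt.close(ax.figure)

ax = plot_difference_bars(diffs)
ax.figure.savefig(out / "difference_bars.png", dpi=150, bbox_inches="tight")
plt.close(ax.figure)

ax = plot_grid_3d(pairs)
ax.figure.savefig(out / "grid_3d.png", dpi=150, bbox_inches="tight")
plt.close(ax.figure)

print(f"wrote 3 figures to {out}/")
print("The apparent 'trumpet' in the scatter is a boundary artefact: when")
print("both raters choose the extreme category the difference can only be 0.")
print("The bar chart of differences is the honest summary on a short scale.")
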