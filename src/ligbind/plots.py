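"""Optional matplotlib helpers: build-up curves and epitope bar maps.

Imported lazily (matplotlib is not required for the analysis itself).
"""

from __future__ import annotations

import numpy as np

from .buildup import BuildUpFit, EpitopeMap, SaturationSeries, buildup_model


def plot_buildup(series: SaturationSeries, fit: BuildUpFit | None = None, ax=None):
    """Scatter eta(t) for one proton, with the fitted curve if given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.asarray(series.times)
    ax.plot(t, series.eta, "o", label=series.proton_id)
    if fit is not None:
        tt = np.linspace(0, t.max() * 1.05, 200)
        ax.plot(tt, buildup_model(tt, fit.STD_max, fit.k_sat), "-",
                label=f"fit: STD0={fit.STD0:.2f}/s")
    ax.set_xlabel("saturation time (s)")
    ax.set_ylabel("STD amplification factor")
    ax.legend()
    return ax


def plot_epitope_map(emap: EpitopeMap, ax=None):
    """Bar chart of normalized STD0 (percent) per proton."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = [f"{pid}\n{shift:.2f} ppm" for pid, shift, _ in emap.entries]
    ax.bar(labels, [pct for _, _, pct in emap.entries])
    ax.set_ylabel("normalized STD0 (%)")
    ax.set_title(emap.ligand_id)
    return ax
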