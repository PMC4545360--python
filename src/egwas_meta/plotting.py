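"""Optional basic Manhattan-plot renderer over the plot-data table.

The pipeline's primary plotting output is the TSV produced by
``manhattan_data``; this module renders it when matplotlib is available.
"""

from __future__ import annotations

import numpy as np


def plot_manhattan(manhattan: dict, path: str | None = None):
    """Render gene-level -log10 p by cumulative genome coordinate.

    ``manhattan`` is the dict returned by :func:`egwas_meta.manhattan_data`;
    the dashed line marks the genome-wide (Bonferroni) threshold.  Returns
    the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = manhattan["table"]
    fig, ax = plt.subplots(figsize=(9, 3.2))
    chroms = list(dict.fromkeys(table["chromosome"]))
    for i, ch in enumerate(chroms):
        sub = table[table["chromosome"] == ch]
        ax.scatter(sub["x"], sub["neg_log10_p"], s=6,
                   color="#444444" if i % 2 else "#999999", linewidths=0)
    threshold = manhattan.get("threshold")
    if threshold:
        ax.axhline(-np.log10(threshold), linestyle="--", color="black", linewidth=0.8)
    for row in table.itertuples(index=False):
        if row.label:
            ax.annotate(row.label, (row.x, row.neg_log10_p), fontsize=6,
                        textcoords="offset points", xytext=(0, 2))
    ax.set_xlabel("genomic position (cumulative)")
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.set_xticks([])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
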