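"""Minimal plotting: final internode length along the main stem."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_length_by_rank"]


def plot_length_by_rank(
    internodes: pd.DataFrame | dict[str, pd.DataFrame],
    path: str | Path,
    min_rank: int = 5,
) -> None:
    """Plot length-by-rank pattern(s) to ``path`` (PNG/PDF by extension).

    ``internodes`` is a per-internode summary frame with ``rank`` and
    ``final_cm`` columns, or a mapping label -> frame to overlay scenarios.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(internodes, pd.DataFrame):
        internodes = {"simulated": internodes}
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in internodes.items():
        sel = df[df["rank"] >= min_rank]
        ax.plot(sel["rank"], sel["final_cm"], marker="o", label=label)
    ax.set_xlabel("rank along main stem")
    ax.set_ylabel("internode length (cm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
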