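"""Optional run plots: training loss (dotted), validation accuracy (solid),
query epochs as vertical bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .active_learning import QueryEvent


def plot_run(curve: pd.DataFrame, query_log: list[QueryEvent], out_path: str | Path) -> Path:
    """Write a loss/accuracy curve figure for one run and return its path."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(curve["epoch"], curve["train_loss"], "b:", label="training loss")
    ax2 = ax.twinx()
    ax2.plot(curve["epoch"], curve["val_accuracy"], "-", color="tab:orange",
             label="validation accuracy")
    for event in query_log:
        if event.epoch > 0:
            ax.axvline(event.epoch, color="grey", alpha=0.4, lw=0.8)
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean minibatch loss")
    ax2.set_ylabel("validation accuracy")
    ax.legend(loc="upper left")
    ax2.legend(loc="upper right")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
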