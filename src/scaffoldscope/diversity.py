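"""Scaffold frequency census and cumulative scaffold frequency (CSF) curves.

The CSF curve answers "what fraction of the library do the top-N most
frequent scaffolds represent?".  A steep curve means a redundant library
(few scaffolds carry many molecules); a shallow curve means a diverse one.
The percentage denominator is the *whole* prepared library, so molecules
lacking a given representation (e.g. no Level-2 scaffold) cap the curve
below 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class FrequencyTable:
    """Scaffold -> occurrence count for one representation of one library."""

    representation: str
    counts: dict[str, int]
    n_molecules: int

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def sorted_items(self) -> list[tuple[str, int]]:
        """Counts descending; ties broken by scaffold string for determinism."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class CSFCurve:
    """Sorted counts and their running coverage percentages."""

    scaffolds: list[str]
    sorted_counts: list[int]
    cumulative_pct: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.scaffolds) + 1),
                "scaffold": self.scaffolds,
                "count": self.sorted_counts,
                "cumulative_pct": self.cumulative_pct,
            }
        )


def count_frequencies(fragments: Iterable[tuple[str, str]], n_molecules: int,
                      representation: str = "") -> FrequencyTable:
    """Count occurrences per distinct scaffold over ``(molecule_id, scaffold)`` pairs."""
    counts: dict[str, int] = {}
    for _mol_id, scaffold in fragments:
        counts[scaffold] = counts.get(scaffold, 0) + 1
    return FrequencyTable(representation=representation, counts=counts, n_molecules=n_molecules)


def csf_curve(table: FrequencyTable, top_n: int = 1000) -> CSFCurve:
    """Cumulative coverage of the ``top_n`` most frequent scaffolds."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if not table.counts:
        raise ValueError("cannot build a CSF curve from an empty frequency table")
    items = table.sorted_items()[:top_n]
    scaffolds = [s for s, _ in items]
    counts = [c for _, c in items]
    running = 0
    pct = []
    for c in counts:
        running += c
        pct.append(100.0 * running / table.n_molecules)
    return CSFCurve(scaffolds=scaffolds, sorted_counts=counts, cumulative_pct=pct)


def coverage_at(table: FrequencyTable, n: int) -> float:
    """Cumulative percentage at rank ``n`` (capped at the table size)."""
    if not table.counts:
        return 0.0
    items = table.sorted_items()
    n = min(n, len(items))
    total = sum(c for _, c in items[:n])
    return 100.0 * total / table.n_molecules


def plot_csf(curves: dict[str, CSFCurve], out_path: str, title: str = "",
             top_n: int = 1000) -> None:
    """Write a CSF comparison plot (one line per library) as vector graphics."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, curve in sorted(curves.items()):
        ranks = range(1, len(curve.cumulative_pct) + 1)
        ax.plot(list(ranks), curve.cumulative_pct, label=name)
    ax.set_xlabel(f"Top-N scaffolds (N ≤ {top_n})")
    ax.set_ylabel("Cumulative scaffold frequency (%)")
    ax.set_ylim(0, 100)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, metadata={"Date": None} if str(out_path).endswith(".svg") else None)
    plt.close(fig)


__all__ = ["CSFCurve", "FrequencyTable", "count_frequencies", "coverage_at", "csf_curve", "plot_csf"]
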