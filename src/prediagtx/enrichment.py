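"""Hypergeometric overrepresentation analysis against GMT gene sets.

Given a gene list drawn from a finite universe (the genes that survived
preprocessing) and a collection of named gene sets, each set is scored by
the upper-tail hypergeometric probability of observing at least the seen
overlap, with BH adjustment across sets.  The gene ratio k/n (overlap over
list size) is reported for dot-plot style visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genewise import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.sets:
            if not name:
                raise ValueError("gene-set names must be non-empty")
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: set) -> "GeneSetCollection":
        return GeneSetCollection(
            {k: frozenset(v & universe) for k, v in self.sets.items()},
            dict(self.descriptions),
        )


def read_gmt(path: str) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, members = parts[0], parts[1], parts[2:]
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(path: str, collection: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(
    gene_list: list | set,
    collection: GeneSetCollection,
    universe: list | set,
) -> pd.DataFrame:
    """Overrepresentation of ``gene_list`` in each set of ``collection``.

    The list must be a subset of the universe; sets are intersected with
    the universe before testing.  Returns one row per set with the overlap
    k, set size K, list size n, universe size N, the upper-tail
    hypergeometric p-value P(X >= k), BH q across sets, and gene ratio k/n.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not universe:
        raise ValueError("empty universe")
    if not gene_list:
        raise ValueError("empty gene list")
    stray = gene_list - universe
    if stray:
        raise ValueError(f"gene list contains genes outside the universe: {sorted(stray)[:5]}")
    restricted = collection.restricted_to(universe)
    N, n = len(universe), len(gene_list)
    rows = []
    for name, members in restricted.sets.items():
        K = len(members)
        k = len(gene_list & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "overlap_k": k,
                "set_size_K": K,
                "list_size_n": n,
                "universe_N": N,
                "p_value": min(p, 1.0),
                "gene_ratio": k / n,
            }
        )
    columns = [
        "set", "description", "overlap_k", "set_size_K", "list_size_n",
        "universe_N", "p_value", "gene_ratio",
    ]
    out = pd.DataFrame(rows, columns=columns).set_index("set")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    order = np.lexsort((out.index.astype(str), out["p_value"].to_numpy()))
    return out.iloc[order]


def plot_dotplot(results: pd.DataFrame, top: int = 15, ax=None):
    """Basic gene-ratio dot plot of the most enriched sets."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * min(top, len(results)) + 1.5))
    shown = results.nsmallest(top, "p_value")
    sc = ax.scatter(
        shown["gene_ratio"],
        range(len(shown)),
        s=20 + 10 * shown["overlap_k"],
        c=-np.log10(np.maximum(shown["p_value"], 1e-300)),
        cmap="viridis",
    )
    ax.set_yticks(range(len(shown)), shown.index)
    ax.invert_yaxis()
    ax.set_xlabel("gene ratio (k / n)")
    plt.colorbar(sc, ax=ax, label="-log10 p")
    return ax
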