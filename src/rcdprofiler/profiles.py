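"""Presence/absence matrix assembly and binary profile geometry."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .model import Category, PresenceCall, PresenceMatrix, RcdError


def build_matrix(
    calls: Iterable[PresenceCall],
    species_order: Sequence[str],
    family_order: Sequence[str],
    categories: Optional[Mapping[str, Category]] = None,
) -> PresenceMatrix:
    """Assemble a species x family binary matrix from presence calls.

    Pairs without a call become 0 with empty provenance; duplicate calls
    for a pair violate the one-call-per-pair contract and raise.  The
    result is independent of call order.
    """
    species_order = list(species_order)
    family_order = list(family_order)
    sp_index = {s: i for i, s in enumerate(species_order)}
    fam_index = {f: i for i, f in enumerate(family_order)}
    cells = np.zeros((len(species_order), len(family_order)), dtype=np.int8)
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.species_id, c.family_id)
        if c.species_id not in sp_index:
            raise RcdError(f"call for unknown species {c.species_id!r}")
        if c.family_id not in fam_index:
            raise RcdError(f"call for unknown family {c.family_id!r}")
        if key in seen:
            raise RcdError(f"duplicate call for {key}")
        seen.add(key)
        if c.present:
            cells[sp_index[c.species_id], fam_index[c.family_id]] = 1
            provenance[key] = c.supporting_proteins
    data = pd.DataFrame(cells, index=species_order, columns=family_order)
    return PresenceMatrix(
        data=data, provenance=provenance, categories=dict(categories or {})
    )


def category_counts(
    matrix: PresenceMatrix, category: Category | str
) -> dict[str, int]:
    """Per-species count of present families within one category."""
    category = Category(category)
    fams = [f for f in matrix.family_ids
            if matrix.categories.get(f) == category]
    if not fams:
        raise RcdError(f"no families of category {category.value!r} in matrix")
    sums = matrix.data[fams].sum(axis=1)
    return {sp: int(v) for sp, v in sums.items()}


def binary_distance(matrix: PresenceMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance between 0/1 species profiles
    (= sqrt of the Hamming mismatch count); symmetric, zero diagonal."""
    X = matrix.values() if isinstance(matrix, PresenceMatrix) else np.asarray(matrix)
    if X.ndim != 2 or X.shape[0] < 2:
        raise RcdError("binary_distance needs a 2-D matrix with >=2 rows")
    return squareform(pdist(X.astype(float), metric="euclidean"))


def plot_heatmap(
    matrix: PresenceMatrix,
    tree=None,
    path: Optional[str] = None,
    title: str = "",
):
    """Two-color presence/absence heatmap, rows ordered by dendrogram
    when a linkage tree is given.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = tree.leaf_order() if tree is not None else range(len(matrix.species_ids))
    df = matrix.data.iloc[list(order)]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * df.shape[1]), max(3, 0.22 * df.shape[0]))
    )
    ax.imshow(df.to_numpy(), aspect="auto", cmap="copper", vmin=0, vmax=1)
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(df.shape[0]), df.index, fontsize=6)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
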