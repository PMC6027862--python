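"""Backtracking unigenes to per-organ read counts and expression snapshots.

Because each organ's cDNA pool is sequenced separately, every original read
carries an organ label, and each final unigene can be backtracked through
the cluster chain to the reads that collapsed into it.  The resulting
unigene x organ count matrix is a single-time-point expression snapshot:
presence of a gene in an organ means at least one of that organ's reads is
reachable from the unigene, and the count is how many times the sequence was
found there.  This is membership counting over low-depth full-length reads,
not RNA-seq quantification.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .clustering import ClusterChain
from .io import get_logger

ORGANS: tuple[str, ...] = ("bud", "root", "leaf", "stem")

_log = get_logger("snapshot")


def backtrack_counts(
    chain: ClusterChain,
    organ_of_read: Mapping[str, str],
    organs: tuple[str, ...] = ORGANS,
) -> pd.DataFrame:
    """Unigene x organ matrix of original-read counts reachable through the chain."""
    expansion = chain.backtrack()
    rows: dict[str, list[int]] = {}
    organ_index = {o: i for i, o in enumerate(organs)}
    for rep, leaves in expansion.items():
        counts = [0] * len(organs)
        for read_id in leaves:
            organ = organ_of_read.get(read_id)
            if organ is None:
                raise ValueError(f"read {read_id!r} has no organ label")
            if organ not in organ_index:
                raise ValueError(f"read {read_id!r} has unknown organ {organ!r}")
            counts[organ_index[organ]] += 1
        rows[rep] = counts
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(organs))
    return matrix.sort_index().astype(int)


def upset_tally(matrix: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Exclusive organ-subset membership counts (all 15 categories reported).

    A unigene belongs to the exact subset of organs where its count reaches
    ``min_reads`` (default: any membership at all).  Categories are ordered by
    subset size then organ order; zero-count categories are included so the
    15 rows always sum to the number of unigenes.
    """
    organs = list(matrix.columns)
    categories: list[tuple[str, ...]] = []
    for size in range(1, len(organs) + 1):
        for combo in combinations(range(len(organs)), size):
            categories.append(tuple(organs[i] for i in combo))
    tallies = {cat: 0 for cat in categories}
    present = matrix >= min_reads
    for _, row in present.iterrows():
        cat = tuple(o for o in organs if row[o])
        if cat:
            tallies[cat] += 1
    return pd.DataFrame(
        {
            "category": ["+".join(cat) for cat in categories],
            "n_unigenes": [tallies[cat] for cat in categories],
        }
    )


def normalize_to_reference(
    matrix: pd.DataFrame, reference_id: str
) -> tuple[pd.DataFrame, list[str]]:
    """Per-organ expression ratios against a reference gene (e.g. an actin).

    ratio(u, o) = count(u, o) / count(reference, o).  Organs where the
    reference has zero count are flagged (returned) and their ratios set to
    NaN rather than silently dropped.
    """
    if reference_id not in matrix.index:
        raise KeyError(f"reference {reference_id!r} not in matrix")
    ref = matrix.loc[reference_id]
    undefined = [o for o in matrix.columns if ref[o] == 0]
    ratios = matrix.div(ref.where(ref > 0), axis=1)
    if undefined:
        _log.warning("reference %s has zero count in organs: %s", reference_id, undefined)
    return ratios, undefined


def gene_set_snapshot(
    matrix: pd.DataFrame,
    annotation: Mapping[str, Iterable[str]],
    term: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Sub-matrix of unigenes annotated with ``term`` (case-insensitive exact).

    Rows are ordered by total count (descending, ties by id) — the gene-set
    heat-map ordering.  Unigenes absent from the annotation are excluded and
    reported back; an unmatched term yields an empty sub-matrix plus a
    warning.
    """
    term_lower = term.lower()
    missing = [u for u in matrix.index if u not in annotation]
    selected = [
        u
        for u in matrix.index
        if u in annotation and any(t.lower() == term_lower for t in annotation[u])
    ]
    if not selected:
        _log.warning("term %r matched no annotated unigene", term)
        return matrix.iloc[0:0], missing
    sub = matrix.loc[selected]
    sub = sub.loc[sorted(selected, key=lambda u: (-int(sub.loc[u].sum()), u))]
    return sub, missing


def snapshot_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Optional heat-map rendering of a (sub-)matrix; darker = more reads."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, max(2, 0.25 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="Greens")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
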