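"""Hierarchical subspot cell-type assignment from marker gene sets.

Expression is first rescaled per gene to a [0, 1] unit-maximum scale so
marker sets of different absolute expression become comparable.  Each
subspot is scored as the mean rescaled value of every gene set; the L1 cell
class with the highest score wins, and the L2 subtype is the argmax among
the winning class's L2 sets.  Only the single winning label is emitted (no
soft posterior), but all scores are retained so soft analysis stays
possible.  Ties break to the lexicographically smallest label and are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSetHierarchy:
    """L1 cell classes with nested L2 subtypes, each a marker gene list."""

    l1_sets: dict[str, list[str]]
    l2_sets: dict[str, list[str]]
    l2_parent: dict[str, str]

    def __post_init__(self) -> None:
        for name, genes in {**self.l1_sets, **self.l2_sets}.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        for l2, parent in self.l2_parent.items():
            if parent not in self.l1_sets:
                raise ValueError(f"L2 set {l2!r} has unknown parent {parent!r}")
        missing = set(self.l2_sets) - set(self.l2_parent)
        if missing:
            raise ValueError(f"L2 sets without a parent: {sorted(missing)}")

    def l2_of_class(self, l1: str) -> list[str]:
        return sorted(l2 for l2, p in self.l2_parent.items() if p == l1)

    def overlapping_markers(self) -> set[str]:
        """Markers appearing in more than one L2 set (permitted, but flagged)."""
        seen: dict[str, int] = {}
        for genes in self.l2_sets.values():
            for g in set(genes):
                seen[g] = seen.get(g, 0) + 1
        return {g for g, n in seen.items() if n > 1}

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GeneSetHierarchy":
        """Build from a long table with columns level, class, subtype, gene."""
        l1 = {
            str(k): sorted(g["gene"])
            for k, g in table[table["level"] == "L1"].groupby("class")
        }
        l2_rows = table[table["level"] == "L2"]
        l2 = {str(k): sorted(g["gene"]) for k, g in l2_rows.groupby("subtype")}
        parent = (
            l2_rows.drop_duplicates("subtype").set_index("subtype")["class"].astype(str).to_dict()
        )
        return cls(l1, l2, parent)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"level": "L1", "class": k, "subtype": "", "gene": g}
            for k, genes in sorted(self.l1_sets.items())
            for g in genes
        ] + [
            {"level": "L2", "class": self.l2_parent[k], "subtype": k, "gene": g}
            for k, genes in sorted(self.l2_sets.items())
            for g in genes
        ]
        return pd.DataFrame(rows)


def rescale_unit_max(expr: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene (row) by its maximum over units; all-zero rows stay 0."""
    expr = expr.astype(float)
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    gmax = expr.max(axis=1)
    gmax = gmax.where(gmax > 0, 1.0)
    return expr.div(gmax, axis=0)


def score_gene_sets(rescaled: pd.DataFrame, sets: dict[str, list[str]]) -> pd.DataFrame:
    """Mean rescaled value of each gene set per unit (units x sets, in [0, 1])."""
    cols = {}
    for name, genes in sets.items():
        present = [g for g in genes if g in rescaled.index]
        if not present:
            raise KeyError(f"gene set {name!r} has no genes in the matrix")
        cols[name] = rescaled.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


def _argmax_with_tie(scores: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series]:
    # columns sorted so exact ties resolve to the lexicographically smallest label
    ordered = scores[sorted(scores.columns)]
    arr = ordered.to_numpy()
    best = arr.argmax(axis=1)
    label = pd.Series(np.asarray(ordered.columns)[best], index=scores.index)
    value = pd.Series(arr[np.arange(len(arr)), best], index=scores.index)
    tie = pd.Series((arr == value.to_numpy()[:, None]).sum(axis=1) > 1, index=scores.index)
    return label, value, tie


def hierarchical_assign(
    scores: pd.DataFrame, hierarchy: GeneSetHierarchy
) -> pd.DataFrame:
    """Assign L1 then L2 labels per subspot from per-set scores.

    ``scores`` must carry one column per L1 set and per L2 set.  L1 is the
    argmax over the L1 columns; L2 is the argmax over the L2 sets belonging
    to the winning L1 class, so the winning L2's parent always equals the
    winning L1.  Exact ties set the tie flag.  The full score table is
    attached unchanged alongside the calls.
    """
    for name in list(hierarchy.l1_sets) + list(hierarchy.l2_sets):
        if name not in scores.columns:
            raise KeyError(f"missing score column for gene set {name!r}")
    l1_label, l1_score, l1_tie = _argmax_with_tie(scores[list(hierarchy.l1_sets)])
    l2_label = np.full(len(scores), "", dtype=object)
    l2_score = np.full(len(scores), np.nan)
    l2_tie = np.zeros(len(scores), dtype=bool)
    for l1 in hierarchy.l1_sets:
        members = hierarchy.l2_of_class(l1)
        sel = (l1_label == l1).to_numpy()
        if not sel.any() or not members:
            continue
        lab, val, tie = _argmax_with_tie(scores.loc[sel, members])
        l2_label[sel] = lab.to_numpy()
        l2_score[sel] = val.to_numpy()
        l2_tie[sel] = tie.to_numpy()
    l2_label = pd.Series(l2_label, index=scores.index)
    l2_score = pd.Series(l2_score, index=scores.index)
    l2_tie = pd.Series(l2_tie, index=scores.index)
    calls = pd.DataFrame(
        {
            "l1": l1_label,
            "l2": l2_label,
            "l1_score": l1_score,
            "l2_score": l2_score,
            "tie": l1_tie | l2_tie,
        }
    )
    # hierarchy constraint holds by construction; assert it anyway
    assigned = calls["l2"] != ""
    parents = calls.loc[assigned, "l2"].map(hierarchy.l2_parent)
    assert (parents == calls.loc[assigned, "l1"]).all(), "L2 label escaped its L1 class"
    return calls


def composition_table(
    calls: pd.Series, region_labels: pd.Series, notes: list[str] | None = None
) -> pd.DataFrame:
    """Per-region label proportions (rows = regions, columns = labels, rows sum to 1).

    Regions with no subspots are omitted; a note is recorded when ``notes``
    is supplied.
    """
    region_labels = region_labels.reindex(calls.index)
    tab = pd.crosstab(region_labels, calls)
    if notes is not None:
        for region in pd.unique(region_labels.dropna()):
            if region not in tab.index:
                notes.append(f"region {region!r} empty; row omitted")
    totals = tab.sum(axis=1)
    tab = tab.loc[totals > 0]
    return tab.div(tab.sum(axis=1), axis=0)
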